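"""Synthetic sex-stratified pool-seq generator with known ground truth.

The generator emits per-site allele counts (sync dialect) for a female and a
male pool drawn from a simulated population, together with the ground-truth
sex-linked intervals, so the whole scan pipeline can be exercised and scored.

Generative model
----------------
* **Background SNPs** occur at ``snp_density`` per bp with minor-allele
  frequency drawn uniformly from ``[maf_low, maf_high]``.  Each individual's
  genotype is drawn binomially at the population frequency, identically for
  both sexes, so finite pool size contributes sampling variance exactly as
  in real pool-seq.
* **XY sites** (inside an ``XY`` truth region): every male is heterozygous —
  the Y haplotype carries the alternate allele — and every female is
  homozygous reference, so the population truth is female frequency 0 and
  male frequency 0.5.  ``ZW`` regions are the mirror image.
* **Degenerate strata** (``stratum_W_deleted``): the W copy of the segment
  is gone, so females are hemizygous — their reads come from n_f source
  chromosomes instead of 2·n_f.  The pools emulate a full-sib family (the
  typical pooled design): a daughter's single Z is paternal while sons also
  carry the maternal Z, so sites where the maternal Z differs are
  heterozygous in every male and absent from every female.  Z polymorphism
  at background sites inside the stratum is shared by both sexes, sampled
  from the females' n_f copies.  Such segments surface as XY-patterned SNPs
  inside a ZW region — the classic signature of W degeneration.
  ``stratum_Y_deleted`` mirrors all of this.
* **Read sampling**: per pool per site, depth ~ Poisson(``mean_depth``),
  each read drawn uniformly from the pool's source chromosomes, then
  miscalled to a uniformly chosen other nucleotide with probability
  ``error_rate``.

Output is deterministic given the seed: the same configuration yields a
byte-identical sync file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .seqio import ChromTable, PoolSite, write_bed, write_sync
from .windowscan import Window

__all__ = [
    "SYSTEMS",
    "TruthRegion",
    "SimConfig",
    "SimResult",
    "OverlapStats",
    "simulate",
    "write_sim",
    "truth_overlap",
    "female_source_copies",
    "male_source_copies",
]

SYSTEMS = ("XY", "ZW", "stratum_W_deleted", "stratum_Y_deleted")

_SLOT_BASE = ("A", "T", "C", "G")


@dataclass(frozen=True)
class TruthRegion:
    """A ground-truth sex-linked interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    system: str
    sexlinked_site_density: float = 0.002  # sex-linked sites per bp

    def __post_init__(self) -> None:
        if self.system not in SYSTEMS:
            raise ValueError(f"system must be one of {SYSTEMS}, got {self.system!r}")
        if self.end <= self.start or self.start < 0:
            raise ValueError(f"bad region bounds {self.start}..{self.end}")
        if not 0.0 <= self.sexlinked_site_density <= 1.0:
            raise ValueError("sexlinked_site_density must be in [0, 1]")

    @property
    def w_deleted(self) -> bool:
        return self.system == "stratum_W_deleted"

    @property
    def y_deleted(self) -> bool:
        return self.system == "stratum_Y_deleted"


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    Defaults mirror a realistic sex-pool experiment: ~1 SNP per 200 bp,
    minor-allele frequencies uniform on [0.05, 0.5], pools of 30 females and
    28 males, 40× expected depth per pool and a 0.2% per-base miscall rate.
    """

    chroms: ChromTable
    snp_density: float = 0.005
    maf_low: float = 0.05
    maf_high: float = 0.5
    n_females: int = 30
    n_males: int = 28
    mean_depth: float = 40.0
    error_rate: float = 0.002
    truth_regions: tuple[TruthRegion, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.snp_density <= 1.0:
            raise ValueError("snp_density must be in [0, 1]")
        if not 0.0 <= self.maf_low <= self.maf_high <= 0.5:
            raise ValueError("require 0 <= maf_low <= maf_high <= 0.5")
        if self.n_females < 1 or self.n_males < 1:
            raise ValueError("pool sizes must be >= 1")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        by_chrom: dict[str, list[TruthRegion]] = {}
        for r in self.truth_regions:
            if r.chrom not in self.chroms:
                raise ValueError(f"truth region on unknown chromosome {r.chrom!r}")
            if r.end > self.chroms.length(r.chrom):
                raise ValueError(
                    f"truth region {r.chrom}:{r.start}-{r.end} extends beyond "
                    f"chromosome end {self.chroms.length(r.chrom)}"
                )
            by_chrom.setdefault(r.chrom, []).append(r)
        for chrom, regs in by_chrom.items():
            regs = sorted(regs, key=lambda r: r.start)
            for a, b in zip(regs, regs[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"overlapping truth regions on {chrom}: "
                        f"{a.start}-{a.end} and {b.start}-{b.end}"
                    )

    def swapped_sexes(self) -> "SimConfig":
        """The mirrored experiment: pool sizes exchanged, XY↔ZW systems."""
        mirror = {
            "XY": "ZW",
            "ZW": "XY",
            "stratum_W_deleted": "stratum_Y_deleted",
            "stratum_Y_deleted": "stratum_W_deleted",
        }
        regions = tuple(replace(r, system=mirror[r.system]) for r in self.truth_regions)
        return replace(
            self, n_females=self.n_males, n_males=self.n_females, truth_regions=regions
        )

    def header_lines(self) -> list[str]:
        regions = ";".join(
            f"{r.chrom}:{r.start}-{r.end}:{r.system}:{r.sexlinked_site_density:g}"
            for r in self.truth_regions
        )
        return [
            "sexscan simulate",
            f"seed={self.seed}",
            f"chroms={','.join(f'{n}:{l}' for n, l in self.chroms)}",
            f"snp_density={self.snp_density:g} maf=[{self.maf_low:g},{self.maf_high:g}]",
            f"n_females={self.n_females} n_males={self.n_males}",
            f"mean_depth={self.mean_depth:g} error_rate={self.error_rate:g}",
            f"truth_regions={regions or 'none'}",
        ]


def female_source_copies(system: Optional[str], n_females: int) -> int:
    """Chromosome copies the female pool's reads are drawn from at a site."""
    return n_females if system == "stratum_W_deleted" else 2 * n_females

def male_source_copies(system: Optional[str], n_males: int) -> int:
    return n_males if system == "stratum_Y_deleted" else 2 * n_males


@dataclass(frozen=True)
class SimResult:
    sites: tuple[PoolSite, ...]
    config: SimConfig

    @property
    def truth_regions(self) -> tuple[TruthRegion, ...]:
        return self.config.truth_regions


# site classes
_BG, _XY, _ZW, _SW, _SY = 0, 1, 2, 3, 4
_CLASS_OF_SYSTEM = {
    "XY": _XY,
    "ZW": _ZW,
    "stratum_W_deleted": _SW,
    "stratum_Y_deleted": _SY,
}


def simulate(config: SimConfig) -> SimResult:
    """Run the generative model; deterministic under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    nf2 = 2 * config.n_females
    nm2 = 2 * config.n_males
    e = config.error_rate
    sites: list[PoolSite] = []

    for chrom, length in config.chroms:
        regions = sorted(
            (r for r in config.truth_regions if r.chrom == chrom), key=lambda r: r.start
        )
        # background sites genome-wide
        n_bg = rng.binomial(length, config.snp_density)
        bg_pos = np.sort(rng.choice(length, size=n_bg, replace=False))
        # sex-linked sites inside each truth region
        sl_pos_parts: list[np.ndarray] = []
        sl_cls_parts: list[np.ndarray] = []
        for r in regions:
            span = r.end - r.start
            n_sl = rng.binomial(span, r.sexlinked_site_density)
            pos = r.start + np.sort(rng.choice(span, size=n_sl, replace=False))
            sl_pos_parts.append(pos)
            sl_cls_parts.append(np.full(n_sl, _CLASS_OF_SYSTEM[r.system], dtype=np.int8))
        if sl_pos_parts:
            sl_pos = np.concatenate(sl_pos_parts)
            sl_cls = np.concatenate(sl_cls_parts)
            bg_pos = bg_pos[~np.isin(bg_pos, sl_pos)]  # sex-linked wins collisions
        else:
            sl_pos = np.empty(0, dtype=np.int64)
            sl_cls = np.empty(0, dtype=np.int8)

        pos = np.concatenate([bg_pos, sl_pos])
        cls = np.concatenate([np.zeros(len(bg_pos), dtype=np.int8), sl_cls])
        order = np.argsort(pos, kind="stable")
        pos, cls = pos[order], cls[order]
        n = len(pos)
        if n == 0:
            continue

        # hemizygosity applies to every site inside a stratum region
        fem_copies = np.full(n, nf2, dtype=np.int64)
        male_copies = np.full(n, nm2, dtype=np.int64)
        for r in regions:
            inside = (pos >= r.start) & (pos < r.end)
            if r.w_deleted:
                fem_copies[inside] = config.n_females
            elif r.y_deleted:
                male_copies[inside] = config.n_males

        ref = rng.integers(0, 4, size=n)
        alt = (ref + rng.integers(1, 4, size=n)) % 4
        p = rng.uniform(config.maf_low, config.maf_high, size=n)

        # alternate-allele copy counts in each pool's source chromosomes
        kf = rng.binomial(fem_copies, p)
        km = rng.binomial(male_copies, p)
        het_f = fem_copies // 2  # one alt copy per female: ZW / stratum_Y sites
        het_m = male_copies // 2
        kf = np.select(
            [cls == _XY, cls == _ZW, cls == _SW, cls == _SY],
            [0, het_f, 0, het_f],
            default=kf,
        )
        km = np.select(
            [cls == _XY, cls == _ZW, cls == _SW, cls == _SY],
            [het_m, 0, het_m, 0],
            default=km,
        )

        depth_f = rng.poisson(config.mean_depth, size=n)
        depth_m = rng.poisson(config.mean_depth, size=n)
        alt_f = rng.binomial(depth_f, kf / fem_copies)
        alt_m = rng.binomial(depth_m, km / male_copies)
        ref_f = depth_f - alt_f
        ref_m = depth_m - alt_m
        # sequencing errors: each read independently miscalled w.p. error_rate
        err_rf = rng.binomial(ref_f, e)
        err_af = rng.binomial(alt_f, e)
        err_rm = rng.binomial(ref_m, e)
        err_am = rng.binomial(alt_m, e)

        for i in range(n):
            fc = [0, 0, 0, 0, 0, 0]
            mc = [0, 0, 0, 0, 0, 0]
            r_i, a_i = int(ref[i]), int(alt[i])
            fc[r_i] += int(ref_f[i] - err_rf[i])
            fc[a_i] += int(alt_f[i] - err_af[i])
            mc[r_i] += int(ref_m[i] - err_rm[i])
            mc[a_i] += int(alt_m[i] - err_am[i])
            for counts, n_err, source in (
                (fc, int(err_rf[i]), r_i),
                (fc, int(err_af[i]), a_i),
                (mc, int(err_rm[i]), r_i),
                (mc, int(err_am[i]), a_i),
            ):
                if n_err:
                    others = [b for b in range(4) if b != source]
                    draws = rng.multinomial(n_err, [1 / 3] * 3)
                    for b, d in zip(others, draws):
                        counts[b] += int(d)
            sites.append(
                PoolSite(
                    chrom,
                    int(pos[i]) + 1,  # sync is 1-based
                    _SLOT_BASE[r_i],
                    tuple(fc),
                    tuple(mc),
                )
            )

    return SimResult(tuple(sites), config)


def write_sim(
    result: SimResult, sync_path: str | Path, truth_bed_path: str | Path
) -> None:
    """Write the sync file (provenance header + counts) and the truth BED5."""
    write_sync(result.sites, sync_path, header_lines=result.config.header_lines())
    write_bed(
        [
            (r.chrom, r.start, r.end, r.system, r.sexlinked_site_density * 1e6)
            for r in result.truth_regions
        ],
        truth_bed_path,
    )


@dataclass(frozen=True)
class OverlapStats:
    """Window-level recovery of the truth regions by a top-window set."""

    recall: float
    precision: float
    n_truth_windows: int
    n_top_windows: int
    precision_defined: bool


def _overlaps(w: Window, r: TruthRegion) -> bool:
    return w.chrom == r.chrom and w.start < r.end and r.start < w.end


def truth_overlap(
    top_windows: Sequence[Window],
    truth: Sequence[TruthRegion],
    all_windows: Sequence[Window],
) -> OverlapStats:
    """Recall and precision of window-level truth recovery.

    Recall: fraction of windows overlapping a truth region that made the top
    set.  Precision: fraction of top windows overlapping any truth region
    (reported 0 with ``precision_defined=False`` for an empty top set).
    """
    truth_keys = {
        w.key() for w in all_windows if any(_overlaps(w, r) for r in truth)
    }
    top_keys = {w.key() for w in top_windows}
    recall = len(truth_keys & top_keys) / len(truth_keys) if truth_keys else 0.0
    if top_windows:
        hit = sum(1 for w in top_windows if any(_overlaps(w, r) for r in truth))
        precision = hit / len(top_windows)
        defined = True
    else:
        precision, defined = 0.0, False
    return OverlapStats(recall, precision, len(truth_keys), len(top_windows), defined)
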