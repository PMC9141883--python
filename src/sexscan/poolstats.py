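"""Per-site statistics on two sex-stratified pools.

Given per-site allele counts from a female and a male pool, this module
computes nucleotide diversity (Π), the Π-based fixation index

    F_ST = (Π_total − Π_within) / Π_total,

and the sex-pattern classification of each SNP:

* **XY-patterned**: one allele is fixed in the female pool while the male
  pool is polymorphic for an alternate allele — the footprint of a
  male-heterogametic (XY) system, where the Y-linked allele sits near
  frequency 0.5 in the male pool and is absent from females.
* **ZW-patterned**: the mirror image (fixed in males, polymorphic in
  females), the footprint of female heterogamety.

Π is the unbiased without-replacement estimator: the probability that two
reads drawn from the pool without replacement carry different nucleotides.
Deletion and N reads are excluded from all frequencies — the statistics are
nucleotide-only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from .seqio import NUCLEOTIDES, PoolSite

__all__ = [
    "Thresholds",
    "SiteFreqs",
    "PatternCall",
    "site_freqs",
    "pool_pi",
    "site_fst",
    "classify_sex_pattern",
    "call_site",
    "call_sites",
    "site_table",
]

# tie-break order for equal counts: alphabetical base order
_ALPHA_ORDER = {"A": 0, "C": 1, "G": 2, "T": 3}
# slot indexes of A, T, C, G in a sync count vector
_NUC_SLOTS = (0, 1, 2, 3)
_SLOT_BASE = {0: "A", 1: "T", 2: "C", 3: "G"}


@dataclass(frozen=True)
class Thresholds:
    """Operationalization of "fixed" and "polymorphic" for pattern calls.

    Parameters
    ----------
    fixed_max_minor:
        Maximum minor-allele frequency for a pool to count as fixed.  The
        default 0.0 tolerates no minor reads (strict fixation).
    poly_min, poly_max:
        The frequency band within which the alternate allele must fall for a
        pool to count as polymorphic.  The heterogametic pool's sex-linked
        allele is expected at 0.5; the default [0.3, 0.7] band absorbs
        binomial sampling noise at typical pool depths.
    min_cov:
        Minimum nucleotide (A/C/G/T) coverage per pool to classify a site.
    min_minor_reads:
        Minimum combined minor-allele read count for a site to be treated as
        a SNP at all (suppresses sequencing-error singletons).
    """

    fixed_max_minor: float = 0.0
    poly_min: float = 0.3
    poly_max: float = 0.7
    min_cov: int = 10
    min_minor_reads: int = 2

    def __post_init__(self) -> None:
        if not (0.0 <= self.fixed_max_minor < self.poly_min <= self.poly_max <= 1.0):
            raise ValueError(
                "require 0 <= fixed_max_minor < poly_min <= poly_max <= 1, got "
                f"{self.fixed_max_minor}, {self.poly_min}, {self.poly_max}"
            )
        if self.min_cov < 1:
            raise ValueError(f"min_cov must be >= 1, got {self.min_cov}")
        if self.min_minor_reads < 1:
            raise ValueError(f"min_minor_reads must be >= 1, got {self.min_minor_reads}")


@dataclass(frozen=True)
class SiteFreqs:
    """Major/minor alleles (over the combined pools) and per-pool frequencies.

    Frequencies are of the minor allele, over A/C/G/T reads only.
    ``minor_allele`` is ``None`` iff the site is monomorphic across both
    pools (after the ``min_minor_reads`` suppression rule).
    """

    chrom: str
    pos: int
    major_allele: str
    minor_allele: Optional[str]
    female_freq: float
    male_freq: float
    female_cov: int
    male_cov: int


@dataclass(frozen=True)
class PatternCall:
    """Sex-pattern classification of one site plus its supporting numbers."""

    chrom: str
    pos: int
    pattern: str  # "XY", "ZW" or "none"
    fst: Optional[float]
    female_freq: float
    male_freq: float
    female_cov: int
    male_cov: int
    low_coverage: bool = False

    @property
    def fixed_pool_freq(self) -> Optional[float]:
        if self.pattern == "XY":
            return self.female_freq
        if self.pattern == "ZW":
            return self.male_freq
        return None

    @property
    def variable_pool_freq(self) -> Optional[float]:
        if self.pattern == "XY":
            return self.male_freq
        if self.pattern == "ZW":
            return self.female_freq
        return None


def _nuc(counts: tuple[int, ...]) -> tuple[int, int, int, int]:
    return counts[0], counts[1], counts[2], counts[3]


def site_freqs(site: PoolSite, min_minor_reads: int = 2) -> Optional[SiteFreqs]:
    """Extract major/minor alleles and per-pool minor-allele frequencies.

    The major allele is the highest combined (female+male) A/C/G/T count,
    ties broken alphabetically; the minor allele is the second-highest,
    provided its combined count reaches ``min_minor_reads``.  Alleles beyond
    the top two are ignored (biallelic SNP framing).  Returns ``None`` when
    both pools have zero nucleotide coverage (site skipped, not fatal).
    """
    f = _nuc(site.female_counts)
    m = _nuc(site.male_counts)
    fcov = sum(f)
    mcov = sum(m)
    if fcov == 0 and mcov == 0:
        return None
    combined = [f[i] + m[i] for i in _NUC_SLOTS]
    order = sorted(
        _NUC_SLOTS, key=lambda i: (-combined[i], _ALPHA_ORDER[_SLOT_BASE[i]])
    )
    major_slot = order[0]
    minor_slot: Optional[int] = None
    if combined[order[1]] >= min_minor_reads:
        minor_slot = order[1]
    if minor_slot is None:
        return SiteFreqs(
            site.chrom, site.pos, _SLOT_BASE[major_slot], None, 0.0, 0.0, fcov, mcov
        )
    female_freq = f[minor_slot] / fcov if fcov else 0.0
    male_freq = m[minor_slot] / mcov if mcov else 0.0
    return SiteFreqs(
        site.chrom,
        site.pos,
        _SLOT_BASE[major_slot],
        _SLOT_BASE[minor_slot],
        female_freq,
        male_freq,
        fcov,
        mcov,
    )


def pool_pi(counts: tuple[int, ...]) -> Optional[float]:
    """Nucleotide diversity of one pool's count vector.

    Π = 1 − Σ_a c_a(c_a−1) / [C(C−1)] over a ∈ {A,C,G,T}: the probability
    that two reads drawn without replacement differ.  Accepts a 4- or 6-slot
    vector (N/del slots are ignored).  Returns ``None`` when nucleotide
    coverage C < 2 (undefined).
    """
    nuc = counts[:4]
    c_total = sum(nuc)
    if c_total < 2:
        return None
    same = sum(c * (c - 1) for c in nuc)
    den = c_total * (c_total - 1)
    return (den - same) / den


def site_fst(site: PoolSite) -> Optional[float]:
    """Π-based F_ST between the female and male pools at one site.

    F_ST = (Π_total − Π_within)/Π_total with Π_within the mean of the two
    per-pool Π and Π_total the Π of the element-wise summed counts.  Returns
    0 when Π_total = 0 (no variation), ``None`` when either pool has
    nucleotide coverage < 2 (site excluded from plots and windows).  Tiny
    negative estimates are clamped to 0.
    """
    pi_f = pool_pi(site.female_counts)
    pi_m = pool_pi(site.male_counts)
    if pi_f is None or pi_m is None:
        return None
    total = tuple(a + b for a, b in zip(site.female_counts[:4], site.male_counts[:4]))
    pi_t = pool_pi(total)
    assert pi_t is not None  # both pools have >= 2 reads
    if pi_t == 0.0:
        return 0.0
    fst = (pi_t - (pi_f + pi_m) / 2.0) / pi_t
    return min(1.0, max(0.0, fst))


def classify_sex_pattern(
    freqs: SiteFreqs, thresholds: Thresholds = Thresholds()
) -> PatternCall:
    """Classify a site as XY-patterned, ZW-patterned, or neither.

    XY: the female pool is fixed (minor-allele frequency ≤ ``fixed_max_minor``)
    and the male pool is polymorphic for the alternate allele
    (frequency in [``poly_min``, ``poly_max``]).  ZW is the mirror image.
    The thresholds invariant ``fixed_max_minor < poly_min`` makes the two
    patterns mutually exclusive.  Sites with nucleotide coverage below
    ``min_cov`` in either pool are returned as ``none`` with
    ``low_coverage=True`` and are excluded from window counts.
    """
    t = thresholds
    low_cov = freqs.female_cov < t.min_cov or freqs.male_cov < t.min_cov
    pattern = "none"
    if not low_cov and freqs.minor_allele is not None:
        if (
            freqs.female_freq <= t.fixed_max_minor
            and t.poly_min <= freqs.male_freq <= t.poly_max
        ):
            pattern = "XY"
        elif (
            freqs.male_freq <= t.fixed_max_minor
            and t.poly_min <= freqs.female_freq <= t.poly_max
        ):
            pattern = "ZW"
    return PatternCall(
        freqs.chrom,
        freqs.pos,
        pattern,
        None,
        freqs.female_freq,
        freqs.male_freq,
        freqs.female_cov,
        freqs.male_cov,
        low_coverage=low_cov,
    )


def call_site(
    site: PoolSite, thresholds: Thresholds = Thresholds()
) -> Optional[PatternCall]:
    """Frequencies, F_ST and pattern call for one site (None if no coverage)."""
    freqs = site_freqs(site, thresholds.min_minor_reads)
    if freqs is None:
        return None
    call = classify_sex_pattern(freqs, thresholds)
    fst = site_fst(site)
    return PatternCall(
        call.chrom,
        call.pos,
        call.pattern,
        fst,
        call.female_freq,
        call.male_freq,
        call.female_cov,
        call.male_cov,
        low_coverage=call.low_coverage,
    )


def call_sites(
    sites: Iterable[PoolSite], thresholds: Thresholds = Thresholds()
) -> Iterator[PatternCall]:
    """Stream pattern calls over a site stream, skipping zero-coverage sites."""
    for site in sites:
        call = call_site(site, thresholds)
        if call is not None:
            yield call


def site_table(calls: Iterable[PatternCall]):
    """Per-site result table (the data behind the genome-scan panels)."""
    import pandas as pd

    rows = [
        {
            "chrom": c.chrom,
            "pos": c.pos,
            "fst": float("nan") if c.fst is None else c.fst,
            "pattern": c.pattern,
            "female_freq": c.female_freq,
            "male_freq": c.male_freq,
            "female_cov": c.female_cov,
            "male_cov": c.male_cov,
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "pos",
            "fst",
            "pattern",
            "female_freq",
            "male_freq",
            "female_cov",
            "male_cov",
        ],
    )
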