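"""Candidate sex-determining regions and presence/absence tabulation.

Top windows on one chromosome that are adjacent (or separated by at most a
configurable number of missing windows) are merged into candidate regions —
a formalization of the contiguous blocks of male/female differentiation a
genome scan is meant to reveal.  The module also carries the simple
coordinate arithmetic used when reporting such regions (span in Mb,
structural-variant length from breakpoints) and tabulates presence/absence
of a feature by sex.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .windowscan import Window

__all__ = [
    "CandidateRegion",
    "PresenceRecord",
    "merge_top_windows",
    "span_mb",
    "sv_length",
    "presence_by_sex",
]


@dataclass(frozen=True)
class CandidateRegion:
    """A merged run of top windows: one putative sex-determining region."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    pattern: str  # "XY" or "ZW"
    n_windows: int
    total_snps: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"region end must exceed start: {self.start}..{self.end}")


@dataclass(frozen=True)
class PresenceRecord:
    """Presence/absence of a genomic feature in one sexed sample."""

    sample_id: str
    sex: str  # "male" or "female"
    present: bool
    covariate: Optional[int] = None  # e.g. B-chromosome count

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")


def merge_top_windows(
    top: Sequence[Window],
    pattern: str,
    max_gap_windows: int = 1,
    window_size: Optional[int] = None,
) -> list[CandidateRegion]:
    """Merge near-adjacent top windows into candidate regions.

    Windows on one chromosome merge when separated by at most
    ``max_gap_windows`` missing windows; bridging single dropouts (the
    default) reconstructs regions that are continuous in truth but patchy at
    the window level.  ``window_size`` defaults to the largest window span
    in the input.  Input need not be sorted.
    """
    if max_gap_windows < 0:
        raise ValueError("max_gap_windows must be >= 0")
    if not top:
        return []
    size = window_size or max(w.end - w.start for w in top)
    ordered = sorted(top, key=lambda w: (w.chrom, w.start))
    regions: list[CandidateRegion] = []
    cur = ordered[0]
    chrom, start, end = cur.chrom, cur.start, cur.end
    n_windows, total = 1, cur.count(pattern)
    for w in ordered[1:]:
        gap_bp = w.start - end
        missing = int(round(gap_bp / size)) if gap_bp > 0 else 0
        if w.chrom == chrom and missing <= max_gap_windows:
            end = max(end, w.end)
            n_windows += 1
            total += w.count(pattern)
        else:
            regions.append(CandidateRegion(chrom, start, end, pattern, n_windows, total))
            chrom, start, end = w.chrom, w.start, w.end
            n_windows, total = 1, w.count(pattern)
    regions.append(CandidateRegion(chrom, start, end, pattern, n_windows, total))
    return regions


def span_mb(start_mb: float, end_mb: float) -> float:
    """Span of a region given its bounds in Mb (end − start)."""
    if end_mb <= start_mb:
        raise ValueError(f"end must exceed start: {start_mb}..{end_mb}")
    return end_mb - start_mb


def sv_length(bp_left: int, bp_right: int) -> int:
    """Structural-variant length as the breakpoint difference (right − left)."""
    if bp_right <= bp_left:
        raise ValueError(f"right breakpoint must exceed left: {bp_left}..{bp_right}")
    return bp_right - bp_left


def presence_by_sex(records: Iterable[PresenceRecord]):
    """2×2 sex-by-presence counts plus the fraction present per sex.

    Returns a DataFrame indexed by sex with columns ``present``, ``absent``,
    ``n`` and ``fraction_present``; cell counts always sum to the record
    count.
    """
    import pandas as pd

    records = list(records)
    if not records:
        raise ValueError("presence_by_sex requires at least one record")
    counts = {("female", True): 0, ("female", False): 0, ("male", True): 0, ("male", False): 0}
    for r in records:
        counts[(r.sex, r.present)] += 1
    rows = []
    for sex in ("female", "male"):
        present = counts[(sex, True)]
        absent = counts[(sex, False)]
        n = present + absent
        rows.append(
            {
                "sex": sex,
                "present": present,
                "absent": absent,
                "n": n,
                "fraction_present": present / n if n else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("sex")
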