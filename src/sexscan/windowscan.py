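"""Fixed-width window scan: count sex-patterned SNPs, rank the top windows.

The genome is tiled with non-overlapping fixed-width windows (100 kb by
default, last window truncated at the chromosome end).  Each window tallies
XY- and ZW-patterned SNPs separately; the scan statistic is the top fraction
(default 1%) of windows ranked by one pattern's count, summarized per
chromosome as window counts, SNP totals and fold enrichment relative to the
chromosome's share of all windows.
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_right
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .poolstats import PatternCall
from .seqio import ChromTable

__all__ = [
    "Window",
    "make_windows",
    "count_patterned",
    "top_percent",
    "per_chromosome_summary",
    "windows_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Window:
    """A 0-based half-open genomic interval with per-pattern SNP tallies."""

    chrom: str
    start: int
    end: int
    xy_count: int = 0
    zw_count: int = 0

    def count(self, pattern: str) -> int:
        if pattern == "XY":
            return self.xy_count
        if pattern == "ZW":
            return self.zw_count
        raise ValueError(f"pattern must be 'XY' or 'ZW', got {pattern!r}")

    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


def make_windows(chroms: ChromTable, size: int = 100_000) -> list[Window]:
    """Tile every chromosome with windows [0,size), [size,2·size), …

    The last window is truncated at the chromosome end; counts start at 0.
    """
    if size < 1:
        raise ValueError(f"window size must be >= 1, got {size}")
    windows: list[Window] = []
    for chrom, length in chroms:
        for start in range(0, length, size):
            windows.append(Window(chrom, start, min(start + size, length)))
    return windows


def count_patterned(
    windows: Sequence[Window], calls: Iterable[PatternCall]
) -> tuple[list[Window], int]:
    """Tally pattern calls into windows; returns (windows, n_skipped).

    A call at 1-based position ``pos`` increments the window containing the
    0-based coordinate ``pos − 1``.  Calls with ``pattern == "none"`` are
    ignored; calls on chromosomes without windows (or beyond the last
    window) are skipped with a warning and counted in ``n_skipped``.
    """
    by_chrom: dict[str, tuple[list[int], list[int], list[int]]] = {}
    for idx, w in enumerate(windows):
        starts, ends, idxs = by_chrom.setdefault(w.chrom, ([], [], []))
        starts.append(w.start)
        ends.append(w.end)
        idxs.append(idx)
    xy = [0] * len(windows)
    zw = [0] * len(windows)
    n_skipped = 0
    for call in calls:
        if call.pattern not in ("XY", "ZW"):
            continue
        entry = by_chrom.get(call.chrom)
        coord = call.pos - 1
        if entry is not None:
            starts, ends, idxs = entry
            j = bisect_right(starts, coord) - 1
            if j >= 0 and coord < ends[j]:
                if call.pattern == "XY":
                    xy[idxs[j]] += 1
                else:
                    zw[idxs[j]] += 1
                continue
        n_skipped += 1
    if n_skipped:
        logger.warning("%d pattern calls fell outside the window set", n_skipped)
    counted = [
        replace(w, xy_count=w.xy_count + xy[i], zw_count=w.zw_count + zw[i])
        for i, w in enumerate(windows)
    ]
    return counted, n_skipped


def top_percent(
    windows: Sequence[Window],
    q: float = 0.01,
    pattern: str = "ZW",
    nonzero_only: bool = False,
) -> list[Window]:
    """The top ``ceil(q · N)`` windows by one pattern's SNP count.

    Ranking is by count descending, ties broken by genome order (the order
    of ``windows``, which :func:`make_windows` emits chromosome by
    chromosome), so borderline ties are reproducible.  ``q·N`` is evaluated
    with a tiny tolerance so that decimal fractions such as 0.01 behave as
    their intended rational value.  With ``nonzero_only`` the cut applies
    only to windows holding at least one SNP of the chosen pattern.
    """
    if not 0.0 < q <= 1.0:
        raise ValueError(f"q must be in (0, 1], got {q}")
    pool = list(windows)
    if nonzero_only:
        pool = [w for w in pool if w.count(pattern) > 0]
    n = len(pool)
    if n == 0:
        raise ValueError("empty window set")
    k = max(1, math.ceil(q * n - 1e-9))
    order = sorted(range(n), key=lambda i: (-pool[i].count(pattern), i))
    return [pool[i] for i in order[:k]]


def per_chromosome_summary(
    top: Sequence[Window], all_windows: Sequence[Window], pattern: str
):
    """Per-chromosome summary of the top-window set.

    For each chromosome (in ``all_windows`` order): the number of top
    windows, the total patterned SNPs they hold, and the fold enrichment

        (n_top_on_chrom / n_top_total) / (n_all_on_chrom / n_all_total).

    Chromosomes absent from the top set are reported with zeros.
    """
    import pandas as pd

    chrom_order: list[str] = []
    n_all: dict[str, int] = {}
    for w in all_windows:
        if w.chrom not in n_all:
            chrom_order.append(w.chrom)
        n_all[w.chrom] = n_all.get(w.chrom, 0) + 1
    n_top: dict[str, int] = {}
    snps: dict[str, int] = {}
    for w in top:
        if w.chrom not in n_all:
            raise ValueError(
                f"top window on {w.chrom!r} but that chromosome has no windows"
            )
        n_top[w.chrom] = n_top.get(w.chrom, 0) + 1
        snps[w.chrom] = snps.get(w.chrom, 0) + w.count(pattern)
    n_top_total = len(top)
    n_all_total = len(all_windows)
    rows = []
    for chrom in chrom_order:
        k = n_top.get(chrom, 0)
        if n_top_total and k:
            fold = (k / n_top_total) / (n_all[chrom] / n_all_total)
        else:
            fold = 0.0
        rows.append(
            {
                "chrom": chrom,
                "n_top_windows": k,
                "total_patterned_snps": snps.get(chrom, 0),
                "fold_enrichment": fold,
            }
        )
    return pd.DataFrame(
        rows, columns=["chrom", "n_top_windows", "total_patterned_snps", "fold_enrichment"]
    )


def windows_table(
    windows: Sequence[Window],
    top_xy: Sequence[Window] = (),
    top_zw: Sequence[Window] = (),
):
    """Per-window table with top-set membership flags."""
    import pandas as pd

    xy_keys = {w.key() for w in top_xy}
    zw_keys = {w.key() for w in top_zw}
    rows = [
        {
            "chrom": w.chrom,
            "start": w.start,
            "end": w.end,
            "xy_count": w.xy_count,
            "zw_count": w.zw_count,
            "in_top_xy": w.key() in xy_keys,
            "in_top_zw": w.key() in zw_keys,
        }
        for w in windows
    ]
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "xy_count", "zw_count", "in_top_xy", "in_top_zw"],
    )
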