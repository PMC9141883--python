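"""Readers and writers for the file formats touched by a pool-seq sex scan.

The central on-disk format is the Popoolation2 ``sync`` dialect: one line per
genomic site with tab-separated ``chrom  pos  ref`` columns followed by one
``A:T:C:G:N:del`` count column per pool.  Alongside it this module reads
samtools-style two-sample text pileups (with per-base PHRED filtering),
two-column chromosome-size tables, and writes BED5 intervals and TSV result
tables.

Conventions
-----------
* sync and pileup positions are 1-based; BED intervals and genome windows are
  0-based half-open.  Conversion happens only at these module boundaries.
* Pool identity (which column holds the female pool) is always an explicit
  parameter — it is a property of how the libraries were built and can never
  be inferred from the file.
* The sync count field must have exactly six colon-separated slots; any other
  arity is a :class:`FormatError`, because silently misparsed count columns
  are the worst possible failure mode for downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "SYNC_SLOTS",
    "NUCLEOTIDES",
    "FormatError",
    "PoolSite",
    "ChromTable",
    "read_sync",
    "write_sync",
    "read_two_pool_pileup",
    "parse_pileup_bases",
    "read_chrom_sizes",
    "write_bed",
    "write_table",
    "read_table",
]

#: Slot order of a sync count column.
SYNC_SLOTS = ("A", "T", "C", "G", "N", "del")

#: The four nucleotide slots (indexes 0..3 of a count vector).
NUCLEOTIDES = ("A", "T", "C", "G")

_BASE_SLOT = {"A": 0, "T": 1, "C": 2, "G": 3, "N": 4}


class FormatError(ValueError):
    """An input file violates its format contract (message names the line)."""


@dataclass(frozen=True)
class PoolSite:
    """Allele counts of one genomic site in the female and male pools.

    ``female_counts`` and ``male_counts`` are 6-tuples in
    :data:`SYNC_SLOTS` order (A, T, C, G, N, del).
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    female_counts: tuple[int, int, int, int, int, int]
    male_counts: tuple[int, int, int, int, int, int]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for name, counts in (("female", self.female_counts), ("male", self.male_counts)):
            if len(counts) != 6:
                raise ValueError(f"{name}_counts must have 6 slots, got {len(counts)}")
            if any(c < 0 for c in counts):
                raise ValueError(f"{name}_counts must be non-negative, got {counts}")

    @property
    def female_coverage(self) -> int:
        """Total reads in the female pool (all six slots)."""
        return sum(self.female_counts)

    @property
    def male_coverage(self) -> int:
        return sum(self.male_counts)

    def swapped(self) -> "PoolSite":
        """The same site with the pool labels exchanged."""
        return PoolSite(self.chrom, self.pos, self.ref, self.male_counts, self.female_counts)


@dataclass(frozen=True)
class ChromTable:
    """Ordered chromosome names and lengths; order defines plotting order."""

    names: tuple[str, ...]
    lengths: tuple[int, ...]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, int]]) -> "ChromTable":
        names: list[str] = []
        lengths: list[int] = []
        seen: set[str] = set()
        for name, length in pairs:
            if name in seen:
                raise ValueError(f"duplicate chromosome name: {name!r}")
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
            seen.add(name)
            names.append(name)
            lengths.append(int(length))
        return cls(tuple(names), tuple(lengths))

    def __contains__(self, name: object) -> bool:
        return name in self.names

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(zip(self.names, self.lengths))

    def __len__(self) -> int:
        return len(self.names)

    def length(self, name: str) -> int:
        try:
            return self.lengths[self.names.index(name)]
        except ValueError:
            raise KeyError(f"unknown chromosome: {name!r}") from None

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown chromosome: {name!r}") from None

    @property
    def total_length(self) -> int:
        return sum(self.lengths)


# ---------------------------------------------------------------------------
# sync
# ---------------------------------------------------------------------------


def _parse_count_field(field: str, lineno: int) -> tuple[int, int, int, int, int, int]:
    parts = field.split(":")
    if len(parts) != 6:
        raise FormatError(
            f"line {lineno}: count field {field!r} has {len(parts)} slots, expected 6 (A:T:C:G:N:del)"
        )
    try:
        counts = tuple(int(p) for p in parts)
    except ValueError:
        raise FormatError(f"line {lineno}: non-integer count in field {field!r}") from None
    if any(c < 0 for c in counts):
        raise FormatError(f"line {lineno}: negative count in field {field!r}")
    return counts  # type: ignore[return-value]


def read_sync(
    path: str | Path, female_col: int, male_col: int
) -> Iterator[PoolSite]:
    """Stream :class:`PoolSite` records from a Popoolation2 sync file.

    ``female_col`` / ``male_col`` are 0-based indexes into the pool columns
    (the columns after chrom, pos, ref).  Lines starting with ``#`` are
    treated as comment/provenance headers and skipped.
    """
    if female_col < 0 or male_col < 0:
        raise ValueError("pool column indexes must be >= 0")
    if female_col == male_col:
        raise ValueError("female_col and male_col must differ")
    n_pool_cols = max(female_col, male_col) + 1
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3 + n_pool_cols:
                raise FormatError(
                    f"line {lineno}: expected at least {3 + n_pool_cols} fields, got {len(fields)}"
                )
            chrom, pos_s, ref = fields[0], fields[1], fields[2].upper()
            try:
                pos = int(pos_s)
            except ValueError:
                raise FormatError(f"line {lineno}: non-integer position {pos_s!r}") from None
            if pos < 1:
                raise FormatError(f"line {lineno}: position must be >= 1, got {pos}")
            if ref not in _BASE_SLOT:
                ref = "N"  # unknown reference bases are accepted but flagged N
            female = _parse_count_field(fields[3 + female_col], lineno)
            male = _parse_count_field(fields[3 + male_col], lineno)
            yield PoolSite(chrom, pos, ref, female, male)


def write_sync(
    sites: Iterable[PoolSite],
    path: str | Path,
    header_lines: Sequence[str] = (),
) -> None:
    """Write sites as sync with the female pool in column 0, male in column 1.

    ``header_lines`` are written first, each prefixed with ``# `` (provenance:
    config echo, seed).  :func:`read_sync` skips them, so write→read
    round-trips reproduce the counts bit-exactly.
    """
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        for s in sites:
            f = ":".join(str(c) for c in s.female_counts)
            m = ":".join(str(c) for c in s.male_counts)
            fh.write(f"{s.chrom}\t{s.pos}\t{s.ref}\t{f}\t{m}\n")


# ---------------------------------------------------------------------------
# pileup
# ---------------------------------------------------------------------------


def parse_pileup_bases(
    bases: str, quals: str, ref: str, min_baseq: int
) -> tuple[tuple[int, int, int, int, int, int], int]:
    """Parse one pileup base string into a 6-slot count vector.

    Returns ``(counts, n_filtered)`` where ``n_filtered`` is the number of
    calls dropped for quality below ``min_baseq``, so that
    ``sum(counts) + n_filtered`` equals the quality-bearing call depth.

    Grammar handled: ``.``/``,`` (reference match), base letters, ``*``/``#``
    (deletion placeholder, tallied in the del slot), ``^`` + mapping quality
    (read start, no call), ``$`` (read end), ``+N<seq>``/``-N<seq>`` indel
    spans (consumed, no call), ``>``/``<`` (reference skip: consumes a quality
    char but contributes no count).
    """
    if min_baseq < 0:
        raise ValueError(f"min_baseq must be >= 0, got {min_baseq}")
    counts = [0, 0, 0, 0, 0, 0]
    n_filtered = 0
    i = 0
    q = 0
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            i += 2  # caret is followed by mapping-quality char
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise FormatError(f"malformed indel span at offset {i} in {bases!r}")
            span = int(bases[i + 1 : j])
            i = j + span
            continue
        # every remaining symbol consumes one quality character
        if q >= len(quals):
            raise FormatError("base and quality strings disagree in length")
        phred = ord(quals[q]) - 33
        q += 1
        i += 1
        if c in "><":
            continue
        if phred < min_baseq:
            n_filtered += 1
            continue
        if c in ".,":
            counts[_BASE_SLOT.get(ref.upper(), 4)] += 1
        elif c in "*#":
            counts[5] += 1
        else:
            counts[_BASE_SLOT.get(c.upper(), 4)] += 1
    if q != len(quals):
        raise FormatError("base and quality strings disagree in length")
    return tuple(counts), n_filtered  # type: ignore[return-value]


def read_two_pool_pileup(
    path: str | Path,
    min_baseq: int = 20,
    female_sample: int = 0,
) -> Iterator[PoolSite]:
    """Stream :class:`PoolSite` records from a two-sample samtools text pileup.

    Each line must carry ``chrom pos ref`` plus two ``depth bases quals``
    sample triplets.  Base calls with PHRED quality below ``min_baseq`` are
    excluded from the counts.  ``female_sample`` (0 or 1) says which triplet
    is the female pool.
    """
    if min_baseq < 0:
        raise ValueError(f"min_baseq must be >= 0, got {min_baseq}")
    if female_sample not in (0, 1):
        raise ValueError("female_sample must be 0 or 1")
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise FormatError(
                    f"line {lineno}: expected 9 fields (two sample triplets), got {len(fields)}"
                )
            chrom, pos_s, ref = fields[0], fields[1], fields[2].upper()
            try:
                pos = int(pos_s)
            except ValueError:
                raise FormatError(f"line {lineno}: non-integer position {pos_s!r}") from None
            if pos < 1:
                raise FormatError(f"line {lineno}: position must be >= 1, got {pos}")
            if ref not in _BASE_SLOT:
                ref = "N"
            pools = []
            for k in range(2):
                depth_s, bases, quals = fields[3 + 3 * k : 6 + 3 * k]
                try:
                    depth = int(depth_s)
                except ValueError:
                    raise FormatError(
                        f"line {lineno}: non-integer depth {depth_s!r}"
                    ) from None
                if depth == 0:
                    pools.append((0, 0, 0, 0, 0, 0))
                    continue
                try:
                    counts, _ = parse_pileup_bases(bases, quals, ref, min_baseq)
                except FormatError as exc:
                    raise FormatError(f"line {lineno}: {exc}") from None
                pools.append(counts)
            female = pools[female_sample]
            male = pools[1 - female_sample]
            yield PoolSite(chrom, pos, ref, female, male)


# ---------------------------------------------------------------------------
# chromosome sizes, BED, TSV
# ---------------------------------------------------------------------------


def read_chrom_sizes(path: str | Path) -> ChromTable:
    """Read a two-column ``name<TAB>length`` table into a :class:`ChromTable`."""
    pairs: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"line {lineno}: expected 2 tab-separated fields")
            try:
                length = int(fields[1])
            except ValueError:
                raise FormatError(f"line {lineno}: non-integer length {fields[1]!r}") from None
            if length <= 0:
                raise FormatError(f"line {lineno}: non-positive length {length}")
            pairs.append((fields[0], length))
    try:
        return ChromTable.from_pairs(pairs)
    except ValueError as exc:
        raise FormatError(str(exc)) from None


def write_bed(
    intervals: Iterable[tuple[str, int, int, str, float]], path: str | Path
) -> None:
    """Write 0-based half-open intervals as 5-column BED (no header)."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score in intervals:
            if start >= end:
                raise ValueError(f"BED interval start >= end: {chrom}:{start}-{end}")
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score:g}\n")


def write_table(df, path: str | Path) -> None:
    """Write a result table as headered TSV."""
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path):
    import pandas as pd

    return pd.read_csv(path, sep="\t")
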