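"""Genomic interval data model, BED/TSS I/O, and exact interval algebra.

All coordinates are 0-based half-open (BED convention).  Every operation
here is deterministic: set-valued outputs are emitted sorted by
``(chrom, start, end)`` and ties in nearest-gene lookups are broken by
lexicographically smallest gene id.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "read_bed",
    "write_bed",
    "overlaps",
    "intersect_keep",
    "subtract_keep",
    "nearest_gene",
    "nearest_interval",
    "point_interval_distance",
    "read_tss_table",
    "write_tss_table",
    "read_gtf_tss",
]


@dataclass(order=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` on ``chrom``.

    Sorting and equality use ``(chrom, start, end)`` only, so interval
    sets have one deterministic order regardless of labels.
    """

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)
    strand: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand is not None and self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to its transcription start site.

    ``tss`` is a 0-based base position; for ``-`` strand genes it is the
    rightmost base of the annotated span (the 5' end on that strand).
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id}: tss must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------

_SKIP_PREFIXES = ("#", "track", "browser")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 records, preserving input order.

    Lines starting with ``#``, ``track`` or ``browser`` and blank lines
    are skipped.  Malformed lines raise ``ValueError`` naming the line
    number.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = cols[3] if len(cols) > 3 and cols[3] != "." else None
            score: float | None = None
            if len(cols) > 4 and cols[4] != ".":
                try:
                    score = float(cols[4])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-numeric score") from exc
            strand = cols[5] if len(cols) > 5 and cols[5] != "" else None
            try:
                out.append(GenomicInterval(cols[0], start, end, name, score, strand))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def _fmt_score(score: float | None) -> str:
    if score is None:
        return "."
    if float(score).is_integer() and abs(score) < 1e15:
        return str(int(score))
    return format(score, "g")


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write BED records; emits BED6 columns only when any label is set."""
    ivs = list(intervals)
    six = any(i.name is not None or i.score is not None or i.strand is not None for i in ivs)
    with open(path, "w") as fh:
        for iv in ivs:
            if six:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                    f"{_fmt_score(iv.score)}\t{iv.strand or '.'}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two half-open spans share at least one base."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def _build_trees(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def intersect_keep(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> tuple[list[GenomicInterval], float]:
    """Members of ``a`` overlapping any member of ``b``, plus capture fraction.

    The capture fraction is ``|result| / |a|`` (NaN when ``a`` is empty).
    Coordinates of kept members are unmodified; output is sorted.
    """
    trees = _build_trees(b)
    kept = [iv for iv in a if iv.chrom in trees and trees[iv.chrom].overlaps(iv.start, iv.end)]
    kept.sort()
    frac = math.nan if len(a) == 0 else len(kept) / len(a)
    return kept, frac


def subtract_keep(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Members of ``a`` with no overlap in ``b`` (sorted).

    Together with :func:`intersect_keep` this partitions ``a``.
    """
    trees = _build_trees(b)
    kept = [
        iv
        for iv in a
        if iv.chrom not in trees or not trees[iv.chrom].overlaps(iv.start, iv.end)
    ]
    kept.sort()
    return kept


def point_interval_distance(pos: int, iv: GenomicInterval) -> int:
    """Distance from a base position to an interval: 0 inside, else to the
    nearer edge base (``start`` or ``end - 1``)."""
    if iv.start <= pos < iv.end:
        return 0
    return min(abs(pos - iv.start), abs(pos - (iv.end - 1)))


def nearest_gene(
    e: GenomicInterval, genes: Sequence[GeneModel]
) -> tuple[str | None, float]:
    """Nearest gene TSS to an enhancer.

    Distance is 0 when the TSS lies inside the enhancer, else the gap to
    the nearer enhancer edge.  Ties break to the lexicographically
    smallest gene id.  With no same-chromosome gene the distance is
    infinite and the gene id is ``None``.
    """
    if not genes:
        raise ValueError("gene collection is empty")
    best_id: str | None = None
    best_d = math.inf
    for g in genes:
        if g.chrom != e.chrom:
            continue
        d = point_interval_distance(g.tss, e)
        if d < best_d or (d == best_d and best_id is not None and g.gene_id < best_id):
            best_id, best_d = g.gene_id, d
    return best_id, best_d


class _ChromIndex:
    """Sorted per-chromosome edge arrays for fast point-to-interval distance."""

    def __init__(self, intervals: Sequence[GenomicInterval]):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[int]]] = {}
        per: dict[str, list[tuple[int, int, int]]] = {}
        for idx, iv in enumerate(intervals):
            per.setdefault(iv.chrom, []).append((iv.start, iv.end, idx))
        for chrom, rows in per.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            idxs = [r[2] for r in rows]
            self.by_chrom[chrom] = (starts, ends, idxs)

    def nearest(self, chrom: str, pos: int) -> tuple[int | None, float]:
        """Return (original index, distance) of the nearest interval."""
        if chrom not in self.by_chrom:
            return None, math.inf
        starts, ends, idxs = self.by_chrom[chrom]
        # candidate: intervals straddling pos, plus nearest neighbors by start
        j = int(np.searchsorted(starts, pos, side="right"))
        best_i, best_d = None, math.inf
        # ends are not monotone in start order, so the left scan is exhaustive
        for k in range(j - 1, -1, -1):
            d = 0 if pos < ends[k] else pos - (ends[k] - 1)
            if d < best_d:
                best_i, best_d = k, d
            if best_d == 0:
                break
        for k in range(j, len(starts)):
            if starts[k] - pos > best_d:
                break
            d = starts[k] - pos
            if d < best_d or (d == best_d and best_i is not None and idxs[k] < idxs[best_i]):
                best_i, best_d = k, d
            if best_d == 0:
                break
        return (idxs[best_i] if best_i is not None else None), best_d


def nearest_interval(
    chrom: str, pos: int, intervals: Sequence[GenomicInterval], index: _ChromIndex | None = None
) -> tuple[GenomicInterval | None, float]:
    """Nearest interval to a point (e.g. a TSS), with edge distance."""
    if index is None:
        index = _ChromIndex(intervals)
    i, d = index.nearest(chrom, pos)
    return (intervals[i] if i is not None else None), d


# ---------------------------------------------------------------------------
# Gene model I/O
# ---------------------------------------------------------------------------


def read_tss_table(path: str | Path) -> list[GeneModel]:
    """Read a TSS table: TSV with columns gene_id, chrom, strand, tss."""
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = {c: i for i, c in enumerate(header)}
        for need in ("gene_id", "chrom", "strand", "tss"):
            if need not in cols:
                raise ValueError(f"{path}: missing column {need!r}")
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            f = raw.rstrip("\n").split("\t")
            gid = f[cols["gene_id"]]
            if gid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene_id {gid!r}")
            seen.add(gid)
            genes.append(
                GeneModel(gid, f[cols["chrom"]], f[cols["strand"]], int(f[cols["tss"]]))
            )
    return genes


def write_tss_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\n")


_GTF_GENE_ID = re.compile(r'gene_id "([^"]+)"')


def read_gtf_tss(path: str | Path, feature_types: tuple[str, ...] = ("gene", "transcript")) -> list[GeneModel]:
    """Extract TSS positions from a GTF file (1-based, converted on read).

    The 5' end of each ``gene``/``transcript`` feature is taken as the TSS;
    the first record per gene id wins.
    """
    genes: dict[str, GeneModel] = {}
    with open(path) as fh:
        for raw in fh:
            if raw.startswith("#") or not raw.strip():
                continue
            f = raw.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] not in feature_types:
                continue
            m = _GTF_GENE_ID.search(f[8])
            if m is None:
                continue
            gid = m.group(1)
            if gid in genes:
                continue
            start1, end1, strand = int(f[3]), int(f[4]), f[6]
            tss = start1 - 1 if strand == "+" else end1 - 1
            genes[gid] = GeneModel(gid, f[0], strand, tss)
    return list(genes.values())
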