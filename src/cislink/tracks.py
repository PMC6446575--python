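"""Binned coverage tracks, bedGraph I/O, metaprofiles and signal matrices.

Tracks hold one value array per chromosome on a fixed bin grid.  "RPGC"
(reads per genomic content) normalization scales a coverage track so the
base-pair-weighted genome-wide mean is 1, i.e. 1x coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .intervals import GenomicInterval

__all__ = [
    "SignalTrack",
    "Metaprofile",
    "coverage_track",
    "read_bedgraph",
    "write_bedgraph",
    "metaprofile",
    "signal_matrix",
    "correlate_tracks",
]

logger = logging.getLogger(__name__)


@dataclass
class SignalTrack:
    bin_size: int
    genome: dict[str, int]  # chromosome lengths in bp
    values: dict[str, np.ndarray]
    normalization: str = "raw"

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for chrom, length in self.genome.items():
            n = -(-length // self.bin_size)
            v = self.values.get(chrom)
            if v is None or len(v) != n:
                raise ValueError(f"{chrom}: expected {n} bins")
            if not np.all(np.isfinite(v)) or (v < 0).any():
                raise ValueError(f"{chrom}: values must be finite and >= 0")

    def genome_mean(self) -> float:
        """Base-pair-weighted mean over the whole genome."""
        total, length = 0.0, 0
        for chrom, L in self.genome.items():
            w = np.full(len(self.values[chrom]), self.bin_size, dtype=float)
            w[-1] = L - (len(w) - 1) * self.bin_size
            total += float(self.values[chrom] @ w)
            length += L
        return total / length

    def value_at(self, chrom: str, pos: int) -> float:
        return float(self.values[chrom][pos // self.bin_size])


def coverage_track(
    fragments: Sequence[GenomicInterval],
    genome: dict[str, int],
    bin_size: int = 25,
    normalization: str = "RPGC",
) -> SignalTrack:
    """Fragment-base coverage per bin (divided by bin width).

    RPGC multiplies by genome length / total fragment bases so the
    genome-wide mean is 1.  A fragment extending past its chromosome end
    is an error.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    values: dict[str, np.ndarray] = {}
    per_chrom: dict[str, list[GenomicInterval]] = {c: [] for c in genome}
    total_bases = 0
    for f in fragments:
        if f.chrom not in genome:
            raise ValueError(f"fragment on unknown chromosome {f.chrom}")
        if f.end > genome[f.chrom]:
            raise ValueError(
                f"fragment {f.chrom}:{f.start}-{f.end} beyond chromosome end"
            )
        per_chrom[f.chrom].append(f)
        total_bases += f.length
    for chrom, L in genome.items():
        n_bins = -(-L // bin_size)
        diff = np.zeros(n_bins * bin_size + 1, dtype=np.float64)
        frs = per_chrom[chrom]
        if frs:
            starts = np.fromiter((f.start for f in frs), dtype=np.int64, count=len(frs))
            ends = np.fromiter((f.end for f in frs), dtype=np.int64, count=len(frs))
            np.add.at(diff, starts, 1.0)
            np.add.at(diff, ends, -1.0)
        per_bp = np.cumsum(diff[:-1])
        values[chrom] = per_bp.reshape(n_bins, bin_size).sum(axis=1) / bin_size
    norm = "raw"
    if normalization.upper() == "RPGC":
        if total_bases > 0:
            scale = sum(genome.values()) / total_bases
            for chrom in values:
                values[chrom] *= scale
        norm = "RPGC"
    elif normalization != "raw":
        raise ValueError(f"unknown normalization {normalization!r}")
    return SignalTrack(bin_size, dict(genome), values, norm)


# ---------------------------------------------------------------------------
# bedGraph I/O
# ---------------------------------------------------------------------------


def read_bedgraph(
    path: str | Path, genome: dict[str, int], bin_size: int, normalization: str = "raw"
) -> SignalTrack:
    """Materialize run-length bedGraph records onto the bin grid.

    Interval values are distributed by base-pair-weighted mean; bases not
    covered by any record count as 0.
    """
    acc = {
        c: np.zeros(-(-L // bin_size), dtype=np.float64) for c, L in genome.items()
    }
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            chrom, start, end, val = f[0], int(f[1]), int(f[2]), float(f[3])
            if chrom not in genome:
                continue
            end = min(end, genome[chrom])
            b0, b1 = start // bin_size, (end - 1) // bin_size
            arr = acc[chrom]
            if b0 == b1:
                arr[b0] += val * (end - start)
            else:
                arr[b0] += val * ((b0 + 1) * bin_size - start)
                arr[b1] += val * (end - b1 * bin_size)
                if b1 > b0 + 1:
                    arr[b0 + 1 : b1] += val * bin_size
    values: dict[str, np.ndarray] = {}
    for chrom, L in genome.items():
        widths = np.full(len(acc[chrom]), bin_size, dtype=np.float64)
        widths[-1] = L - (len(widths) - 1) * bin_size
        values[chrom] = acc[chrom] / widths
    return SignalTrack(bin_size, dict(genome), values, normalization)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    """Write run-length-merged records; zero-valued runs are omitted."""
    with open(path, "w") as fh:
        for chrom in track.genome:
            v = track.values[chrom]
            L = track.genome[chrom]
            # run boundaries where the value changes
            change = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(v)]))
            for b0, b1 in zip(starts, ends):
                val = v[b0]
                if val == 0:
                    continue
                bp0 = b0 * track.bin_size
                bp1 = min(b1 * track.bin_size, L)
                fh.write(f"{chrom}\t{bp0}\t{bp1}\t{format(val, '.10g')}\n")


# ---------------------------------------------------------------------------
# Metaprofiles and matrices
# ---------------------------------------------------------------------------


@dataclass
class Metaprofile:
    flank: int
    bin: int
    offsets: np.ndarray  # bin-center offsets relative to region centers
    values: np.ndarray  # mean signal per offset bin
    n_regions: int
    n_dropped: int = 0


def _region_profiles(
    track: SignalTrack, regions: Sequence[GenomicInterval], flank: int, bin: int
) -> tuple[np.ndarray, list[int], int]:
    """Per-region binned signal around region centers.

    Returns (matrix, kept indices, dropped count); regions whose window
    is truncated by a chromosome end are dropped.
    """
    if flank <= 0 or bin <= 0 or (2 * flank) % bin != 0:
        raise ValueError("require flank, bin > 0 and 2*flank divisible by bin")
    n_off = 2 * flank // bin
    rows, kept = [], []
    dropped = 0
    for i, r in enumerate(regions):
        if r.chrom not in track.genome:
            dropped += 1
            continue
        center = (r.start + r.end) // 2
        lo, hi = center - flank, center + flank
        if lo < 0 or hi > track.genome[r.chrom]:
            dropped += 1
            continue
        bp = np.arange(lo, hi)
        vals = track.values[r.chrom][bp // track.bin_size]
        rows.append(vals.reshape(n_off, bin).mean(axis=1))
        kept.append(i)
    if not rows:
        raise ValueError("all regions dropped (chromosome-end truncation)")
    if dropped:
        logger.info("metaprofile: dropped %d/%d truncated regions", dropped, len(regions))
    return np.vstack(rows), kept, dropped


def metaprofile(
    track: SignalTrack,
    regions: Sequence[GenomicInterval],
    flank: int = 2000,
    bin: int = 25,
) -> Metaprofile:
    """Mean signal as a function of offset from aligned region centers."""
    if not regions:
        raise ValueError("regions must be non-empty")
    mat, kept, dropped = _region_profiles(track, regions, flank, bin)
    offsets = np.arange(-flank, flank, bin) + bin / 2.0
    return Metaprofile(flank, bin, offsets, mat.mean(axis=0), len(kept), dropped)


def signal_matrix(
    track: SignalTrack,
    regions: Sequence[GenomicInterval],
    flank: int = 2000,
    bin: int = 25,
    sort: bool = True,
) -> np.ndarray:
    """Per-region x offset signal matrix, rows sorted by descending mean.

    Column means equal the metaprofile values exactly (shared sampling)."""
    mat, _, _ = _region_profiles(track, regions, flank, bin)
    if sort:
        order = np.argsort(-mat.mean(axis=1), kind="stable")
        mat = mat[order]
    return mat


def correlate_tracks(
    track_a: SignalTrack,
    track_b: SignalTrack,
    regions: Sequence[GenomicInterval],
) -> float:
    """Pearson r between two tracks over per-region mean signals."""
    if len(regions) < 3:
        raise ValueError("need >= 3 regions")

    def region_means(track: SignalTrack) -> np.ndarray:
        out = np.empty(len(regions))
        for i, r in enumerate(regions):
            bp = np.arange(r.start, min(r.end, track.genome[r.chrom]))
            out[i] = track.values[r.chrom][bp // track.bin_size].mean()
        return out

    a, b = region_means(track_a), region_means(track_b)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in per-region means; r undefined")
    return float(np.corrcoef(a, b)[0, 1])
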