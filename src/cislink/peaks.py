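"""Local-Poisson peak calling, enhancer filtering, and differential
accessibility classification.

The peak caller is a sliding-window simplification of the MACS2 approach:
fragment midpoints are counted in fixed windows, the null rate is the
maximum of several local/background scales, the Poisson upper tail gives a
p-value, and Benjamini-Hochberg significant windows are merged into peaks.

Classification into "closed"/"opened"/"stable" enhancer sets for a
condition contrast comes in two modes: *presence* (a peak in one condition
and none in the other) and *counts* (negative-binomial test on the
per-enhancer fragment count matrix).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .counts import CountMatrix
from .de import bh_adjust, nb_wald_test
from .intervals import GenomicInterval, intersect_keep, subtract_keep

__all__ = [
    "PeakCallParams",
    "EnhancerClassification",
    "call_peaks",
    "filter_to_enhancers",
    "count_fragments_per_enhancer",
    "classify_presence",
    "classify_counts",
    "set_overlap_fraction",
    "enhancer_id",
]


@dataclass
class PeakCallParams:
    """Sliding-window peak-calling parameters.

    Defaults echo a 177-bp window (average insert), 88-bp step (half
    window), local backgrounds of 1 kb / 10 kb plus the genome-wide rate,
    and a 0.1% FDR threshold.
    """

    window_size: int = 177
    step: int = 88
    background_scales: tuple[int, ...] = (1000, 10000)  # genome-wide is implicit
    q_threshold: float = 0.001
    merge_gap: int | None = None  # defaults to window_size

    def __post_init__(self) -> None:
        if self.window_size <= 0 or self.step <= 0:
            raise ValueError("window_size and step must be positive")
        if not (0 < self.q_threshold < 1):
            raise ValueError("q_threshold must be in (0, 1)")
        if self.merge_gap is None:
            self.merge_gap = self.window_size


@dataclass
class EnhancerClassification:
    """Closed / opened / stable enhancer sets for one condition contrast.

    The three sets partition the enhancers accessible in either condition
    of the contrast."""

    contrast: tuple[str, str]
    closed: list[GenomicInterval] = field(default_factory=list)
    opened: list[GenomicInterval] = field(default_factory=list)
    stable: list[GenomicInterval] = field(default_factory=list)


def _midpoints_by_chrom(fragments: Sequence[GenomicInterval]) -> dict[str, np.ndarray]:
    per: dict[str, list[int]] = {}
    for f in fragments:
        per.setdefault(f.chrom, []).append((f.start + f.end) // 2)
    return {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in per.items()}


def call_peaks(
    fragments: Sequence[GenomicInterval],
    genome: Mapping[str, int],
    params: PeakCallParams | None = None,
) -> list[GenomicInterval]:
    """Call peaks from fragment midpoints by local-Poisson window scan.

    Each window of ``window_size`` bp (stepped by ``step``) is scored by
    its midpoint count k against lambda = max over background scales of
    (local count x window/scale), including the genome-wide rate; p =
    P(Poisson(lambda) >= k); q by BH across all windows genome-wide.
    Windows with q <= q_threshold are merged when the gap between them is
    <= merge_gap.  Returned peaks carry the minimum window q as score.
    """
    params = params or PeakCallParams()
    mids = _midpoints_by_chrom(fragments)
    if not fragments:
        return []
    total_mid = sum(len(v) for v in mids.values())
    total_len = sum(genome.values())
    for chrom in mids:
        if chrom not in genome:
            raise ValueError(f"fragment chromosome {chrom!r} not in genome")

    win, step = params.window_size, params.step
    all_chroms: list[str] = []
    all_starts: list[np.ndarray] = []
    all_counts: list[np.ndarray] = []
    all_lambda: list[np.ndarray] = []
    lam_genome = total_mid * win / total_len
    for chrom, L in genome.items():
        if L < win:
            continue
        starts = np.arange(0, L - win + 1, step, dtype=np.int64)
        m = mids.get(chrom, np.empty(0, dtype=np.int64))
        k = np.searchsorted(m, starts + win) - np.searchsorted(m, starts)
        centers = starts + win // 2
        lam = np.full(len(starts), lam_genome, dtype=float)
        for scale in params.background_scales:
            lo = np.maximum(centers - scale // 2, 0)
            hi = np.minimum(centers + scale // 2, L)
            local = np.searchsorted(m, hi) - np.searchsorted(m, lo)
            # exclude the focal window so its own signal does not inflate
            # the background estimate
            np.maximum(lam, (local - k) * win / (hi - lo - win), out=lam)
        all_chroms.append(chrom)
        all_starts.append(starts)
        all_counts.append(k)
        all_lambda.append(lam)
    if not all_starts:
        return []

    k = np.concatenate(all_counts)
    lam = np.concatenate(all_lambda)
    p = stats.poisson.sf(k - 1, lam)  # upper tail P(X >= k)
    q = bh_adjust(p)

    peaks: list[GenomicInterval] = []
    offset = 0
    for chrom, starts in zip(all_chroms, all_starts):
        qc = q[offset : offset + len(starts)]
        offset += len(starts)
        sig = np.flatnonzero(qc <= params.q_threshold)
        if sig.size == 0:
            continue
        cur_start = int(starts[sig[0]])
        cur_end = cur_start + win
        cur_q = float(qc[sig[0]])
        for i in sig[1:]:
            s = int(starts[i])
            if s - cur_end <= params.merge_gap:
                cur_end = s + win
                cur_q = min(cur_q, float(qc[i]))
            else:
                peaks.append(GenomicInterval(chrom, cur_start, cur_end, score=cur_q))
                cur_start, cur_end, cur_q = s, s + win, float(qc[i])
        peaks.append(GenomicInterval(chrom, cur_start, cur_end, score=cur_q))
    peaks.sort()
    for i, pk in enumerate(peaks, start=1):
        pk.name = f"peak_{i}"
    return peaks


def filter_to_enhancers(
    peaks: Sequence[GenomicInterval], marked: Sequence[GenomicInterval]
) -> tuple[list[GenomicInterval], float]:
    """Restrict peaks to histone-marked enhancer regions.

    Returns the accessible-enhancer set and the capture fraction (share
    of peaks falling in marked enhancers; NaN when there are no peaks).
    """
    return intersect_keep(peaks, marked)


def enhancer_id(iv: GenomicInterval) -> str:
    return iv.name if iv.name is not None else f"{iv.chrom}:{iv.start}-{iv.end}"


def count_fragments_per_enhancer(
    enhancers: Sequence[GenomicInterval],
    fragments_by_sample: Mapping[str, Sequence[GenomicInterval]],
    conditions: Mapping[str, str],
) -> CountMatrix:
    """Fragment-midpoint counts per enhancer per sample.

    A fragment belongs to an enhancer iff its midpoint lies in
    ``[start, end)``."""
    ids = [enhancer_id(e) for e in enhancers]
    data: dict[str, np.ndarray] = {}
    for sample, frags in fragments_by_sample.items():
        mids = _midpoints_by_chrom(frags)
        counts = np.zeros(len(enhancers), dtype=np.int64)
        for i, e in enumerate(enhancers):
            m = mids.get(e.chrom)
            if m is not None:
                counts[i] = np.searchsorted(m, e.end) - np.searchsorted(m, e.start)
        data[sample] = counts
    counts_df = pd.DataFrame(data, index=pd.Index(ids, name="feature_id"))
    cond = pd.Series({s: conditions[s] for s in counts_df.columns})
    return CountMatrix(counts_df, cond)


def classify_presence(
    peaks_by_condition: Mapping[str, Sequence[GenomicInterval]],
    enhancers: Sequence[GenomicInterval],
    contrast: tuple[str, str],
) -> EnhancerClassification:
    """Presence/absence classification over a condition contrast.

    closed: enhancer overlaps a peak in condition A but none in B;
    opened: the converse; stable: remaining enhancers overlapping a peak
    in either condition.
    """
    cond_a, cond_b = contrast
    for c in contrast:
        if c not in peaks_by_condition:
            raise KeyError(f"unknown condition {c!r}")
    in_a, _ = intersect_keep(enhancers, peaks_by_condition[cond_a])
    in_b, _ = intersect_keep(enhancers, peaks_by_condition[cond_b])
    closed = subtract_keep(in_a, peaks_by_condition[cond_b])
    opened = subtract_keep(in_b, peaks_by_condition[cond_a])
    either = sorted(set((iv.key() for iv in in_a)) | set((iv.key() for iv in in_b)))
    drop = {iv.key() for iv in closed} | {iv.key() for iv in opened}
    by_key = {iv.key(): iv for iv in list(in_a) + list(in_b)}
    stable = [by_key[k] for k in either if k not in drop]
    return EnhancerClassification(contrast, closed, opened, stable)


def classify_counts(
    counts: CountMatrix,
    contrast: tuple[str, str],
    enhancers: Sequence[GenomicInterval] | None = None,
    q_cut: float = 0.05,
    lfc_cut: float = 0.0,
) -> tuple[pd.DataFrame, EnhancerClassification]:
    """Count-mode classification via the negative-binomial Wald test.

    ``log2fc`` is condition B versus A, so ``closed`` means significantly
    lower accessibility in B (the treated condition of the contrast).
    """
    results = nb_wald_test(counts, contrast)
    sig = results["q"] < q_cut
    closed_ids = set(results.index[sig & (results["log2fc"] < -lfc_cut)])
    opened_ids = set(results.index[sig & (results["log2fc"] > lfc_cut)])
    cls = EnhancerClassification(contrast)
    if enhancers is not None:
        by_id = {enhancer_id(e): e for e in enhancers}
        cls.closed = sorted(by_id[i] for i in closed_ids if i in by_id)
        cls.opened = sorted(by_id[i] for i in opened_ids if i in by_id)
        cls.stable = sorted(
            by_id[i] for i in results.index if i in by_id and i not in closed_ids and i not in opened_ids
        )
    results = results.copy()
    results["class"] = "stable"
    results.loc[list(closed_ids), "class"] = "closed"
    results.loc[list(opened_ids), "class"] = "opened"
    return results, cls


def set_overlap_fraction(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> float:
    """Fraction of A-members overlapping at least one B-member."""
    _, frac = intersect_keep(a, b)
    return frac
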