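"""Enhancer-gene linkage within a TSS window, random-gene null sets, and
rank-based distance-distribution comparisons.

A gene is "linked" to an enhancer set when the distance from its TSS to
the nearest enhancer (edge distance, zero inside) is at most the linkage
window (default 100 kb).  Gene sets are compared on their nearest-enhancer
distance distributions with a tie-corrected Kruskal-Wallis omnibus test
and Dunn pairwise post hoc comparisons (Holm-adjusted by default).

Genes with no same-chromosome enhancer have infinite distance: they count
as unlinked in linkage fractions but are excluded from the rank tests
(the excluded count is reported).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GeneModel, GenomicInterval, _ChromIndex

__all__ = [
    "LinkageReport",
    "linked_fraction",
    "sample_random_genes",
    "kruskal_wallis",
    "dunn_posthoc",
    "run_linkage_analysis",
    "LinkageAnalysis",
]


@dataclass
class LinkageReport:
    gene_set: str
    enhancer_set: str
    n_genes: int
    linked_fraction: float
    distances: np.ndarray  # nearest-enhancer distance per gene (inf allowed)
    window: int

    @property
    def n_infinite(self) -> int:
        return int(np.isinf(self.distances).sum())

    @property
    def median_distance(self) -> float:
        finite = self.distances[np.isfinite(self.distances)]
        return float(np.median(finite)) if finite.size else math.nan


def linked_fraction(
    genes: Sequence[GeneModel],
    enhancers: Sequence[GenomicInterval],
    window: int = 100_000,
    gene_set: str = "genes",
    enhancer_set: str = "enhancers",
) -> LinkageReport:
    """Fraction of genes with an enhancer within ``window`` bp of the TSS."""
    if window <= 0:
        raise ValueError("window must be positive")
    if not genes:
        raise ValueError("gene set is empty")
    if enhancers:
        index = _ChromIndex(list(enhancers))
        distances = np.array(
            [index.nearest(g.chrom, g.tss)[1] for g in genes], dtype=float
        )
    else:
        distances = np.full(len(genes), math.inf)
    frac = float(np.mean(distances <= window))
    return LinkageReport(gene_set, enhancer_set, len(genes), frac, distances, window)


def sample_random_genes(
    universe: Sequence[GeneModel], n: int, seed: int | np.random.Generator = 0
) -> list[GeneModel]:
    """Uniform sample of n genes without replacement (seeded)."""
    if n > len(universe):
        raise ValueError("n exceeds universe size")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(len(universe), size=n, replace=False)
    return [universe[i] for i in sorted(idx)]


def _tie_term(all_values: np.ndarray) -> float:
    _, counts = np.unique(all_values, return_counts=True)
    return float(np.sum(counts**3 - counts))


def kruskal_wallis(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    When every value across all groups is identical the statistic is
    defined as H = 0 with p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for g in groups:
        if g.size == 0:
            raise ValueError("each group needs >= 1 value")
        if not np.all(np.isfinite(g)):
            raise ValueError("groups must contain only finite values")
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    tie = _tie_term(pooled)
    correction = 1.0 - tie / (n_total**3 - n_total) if n_total > 1 else 0.0
    if correction == 0.0:
        return 0.0, 1.0
    h_raw = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + g.size]
        start += g.size
        h_raw += g.size * (r.mean() - (n_total + 1) / 2.0) ** 2
    h = (12.0 / (n_total * (n_total + 1))) * h_raw / correction
    p = float(stats.chi2.sf(h, df=len(groups) - 1))
    return float(h), p


def dunn_posthoc(
    groups: Sequence[np.ndarray],
    labels: Sequence[str] | None = None,
    adjust: str = "holm",
) -> pd.DataFrame:
    """Dunn pairwise z-tests on pooled ranks with tie correction.

    Returns a DataFrame with columns group_a, group_b, z, p, p_adj.
    Adjustment is Holm by default ("none" disables it).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need >= 2 groups")
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + g.size].mean())
        sizes.append(g.size)
        start += g.size
    tie = _tie_term(pooled)
    var_term = n_total * (n_total + 1) / 12.0 - tie / (12.0 * (n_total - 1))
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        denom = math.sqrt(var_term * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if denom == 0 else (mean_ranks[i] - mean_ranks[j]) / denom
        p = 2.0 * float(stats.norm.sf(abs(z)))
        rows.append({"group_a": labels[i], "group_b": labels[j], "z": z, "p": min(p, 1.0)})
    df = pd.DataFrame(rows)
    if adjust == "holm":
        m = len(df)
        order = np.argsort(df["p"].to_numpy(), kind="stable")
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * df["p"].iloc[idx])
            adj[idx] = min(running, 1.0)
        df["p_adj"] = adj
    elif adjust == "none":
        df["p_adj"] = df["p"]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return df


@dataclass
class LinkageAnalysis:
    """Linkage fractions plus omnibus/post hoc results per enhancer set."""

    table: pd.DataFrame  # gene_set x enhancer_set linkage summary
    omnibus: pd.DataFrame  # enhancer_set, H, p, n_excluded_infinite
    posthoc: pd.DataFrame  # enhancer_set + Dunn pairwise rows
    reports: dict[tuple[str, str], LinkageReport] = field(default_factory=dict)


def run_linkage_analysis(
    gene_sets: Mapping[str, Sequence[GeneModel]],
    enhancer_sets: Mapping[str, Sequence[GenomicInterval]],
    universe: Sequence[GeneModel],
    window: int = 100_000,
    n_null_draws: int = 1,
    seed: int = 0,
) -> LinkageAnalysis:
    """Linkage fractions and distance-distribution tests for every
    (gene set x enhancer set) cell, with size-matched random gene sets.

    For each supplied gene set a random set of the same size is drawn
    from the universe (``random_<name>``; numbered when n_null_draws >
    1).  Per enhancer set, finite nearest-enhancer distances of all gene
    sets (random included) are compared by Kruskal-Wallis with Dunn post
    hoc.
    """
    rng = np.random.default_rng([11, seed])
    all_sets: dict[str, Sequence[GeneModel]] = dict(gene_sets)
    for name, genes in gene_sets.items():
        for draw in range(n_null_draws):
            label = f"random_{name}" if n_null_draws == 1 else f"random_{name}_{draw}"
            all_sets[label] = sample_random_genes(universe, len(genes), rng)

    rows, om_rows, ph_frames = [], [], []
    reports: dict[tuple[str, str], LinkageReport] = {}
    for enh_name, enhancers in enhancer_sets.items():
        group_labels, group_values = [], []
        for set_name, genes in all_sets.items():
            rep = linked_fraction(
                list(genes), list(enhancers), window, set_name, enh_name
            )
            reports[(set_name, enh_name)] = rep
            rows.append(
                {
                    "gene_set": set_name,
                    "enhancer_set": enh_name,
                    "n_genes": rep.n_genes,
                    "linked_fraction": rep.linked_fraction,
                    "median_distance": rep.median_distance,
                    "n_infinite": rep.n_infinite,
                }
            )
            finite = rep.distances[np.isfinite(rep.distances)]
            if finite.size:
                group_labels.append(set_name)
                group_values.append(finite)
        if len(group_values) >= 2:
            h, p = kruskal_wallis(group_values)
            om_rows.append(
                {
                    "enhancer_set": enh_name,
                    "H": h,
                    "p": p,
                    "n_excluded_infinite": int(
                        sum(reports[(s, enh_name)].n_infinite for s in all_sets)
                    ),
                }
            )
            ph = dunn_posthoc(group_values, group_labels)
            ph.insert(0, "enhancer_set", enh_name)
            ph_frames.append(ph)
    posthoc = (
        pd.concat(ph_frames, ignore_index=True)
        if ph_frames
        else pd.DataFrame(columns=["enhancer_set", "group_a", "group_b", "z", "p", "p_adj"])
    )
    return LinkageAnalysis(pd.DataFrame(rows), pd.DataFrame(om_rows), posthoc, reports)
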