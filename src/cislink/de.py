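"""Simplified negative-binomial differential expression.

A deliberately small Wald-test engine in the DESeq2 mold: median-of-ratios
size factors, per-feature method-of-moments dispersion, delta-method
standard errors on the log2 fold change, and Benjamini-Hochberg adjustment.
No dispersion shrinkage, no outlier filtering, no fold-change shrinkage —
the integration analyses downstream, not the DE engine, are the point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .counts import CountMatrix

__all__ = [
    "size_factors",
    "bh_adjust",
    "nb_wald_test",
    "classify_genes",
    "GeneSets",
]

_LN2_SQ = math.log(2.0) ** 2
_DISPERSION_FLOOR = 1e-8
_PSEUDOCOUNT = 0.5


def size_factors(counts: CountMatrix | pd.DataFrame, method: str = "median-of-ratios") -> pd.Series:
    """Per-sample normalization factors.

    ``median-of-ratios``: for features with nonzero counts in every
    sample, factor_j = median_i of count_ij / geometric-mean_i.
    ``cpm``: factor_j = library size / mean library size (fallback when
    no feature is nonzero everywhere).
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    x = mat.to_numpy(dtype=float)
    if method == "cpm":
        lib = x.sum(axis=0)
        if lib.sum() == 0:
            raise ValueError("all-zero count matrix")
        return pd.Series(lib / lib.mean(), index=mat.columns)
    if method != "median-of-ratios":
        raise ValueError(f"unknown size-factor method {method!r}")
    keep = (x > 0).all(axis=1)
    if not keep.any():
        raise ValueError(
            "no feature has nonzero counts in all samples; "
            "use size_factors(..., method='cpm')"
        )
    xk = x[keep]
    geomean = np.exp(np.log(xk).mean(axis=1))
    factors = np.median(xk / geomean[:, None], axis=0)
    return pd.Series(factors, index=mat.columns)


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def nb_wald_test(
    counts: CountMatrix,
    contrast: tuple[str, str],
    size_factor_method: str = "median-of-ratios",
) -> pd.DataFrame:
    """Per-feature Wald test of condition B versus condition A.

    Returns a DataFrame indexed by feature id with columns ``base_mean``,
    ``log2fc`` (positive = higher in B), ``se``, ``p``, ``q``.

    Model: counts are NB with per-feature dispersion ``alpha`` estimated
    by method of moments on size-factor-normalized counts (floored at
    1e-8).  With group means ``m`` (pseudo-count 0.5), the delta-method
    variance of the log2 group mean is ``(1/m + alpha) / (n ln(2)^2)``;
    the two group variances add.
    """
    cond_a, cond_b = contrast
    samples_a = counts.samples_for(cond_a)
    samples_b = counts.samples_for(cond_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("each condition needs >= 2 replicates")

    sub = counts.subset([cond_a, cond_b])
    sf = size_factors(sub, method=size_factor_method)
    norm = sub.counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    cols = list(sub.counts.columns)
    idx_a = [cols.index(s) for s in samples_a]
    idx_b = [cols.index(s) for s in samples_b]
    xa, xb = norm[:, idx_a], norm[:, idx_b]
    na, nb = xa.shape[1], xb.shape[1]

    ma = xa.mean(axis=1) + _PSEUDOCOUNT
    mb = xb.mean(axis=1) + _PSEUDOCOUNT
    log2fc = np.log2(mb / ma)
    base_mean = norm.mean(axis=1)

    # method-of-moments NB dispersion per group, averaged
    def _alpha(x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=1) + _PSEUDOCOUNT
        var = x.var(axis=1, ddof=1)
        return (var - mu) / mu**2

    alpha = np.maximum((_alpha(xa) + _alpha(xb)) / 2.0, _DISPERSION_FLOOR)

    var_log2fc = ((1.0 / ma + alpha) / na + (1.0 / mb + alpha) / nb) / _LN2_SQ
    se = np.sqrt(var_log2fc)
    z = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    q = bh_adjust(p)

    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "p": p,
            "q": q,
        },
        index=pd.Index(sub.counts.index, name="feature_id"),
    )


@dataclass
class GeneSets:
    """Significant gene sets from one (or two) contrasts."""

    induced: set[str]
    repressed: set[str]
    lps_inducible: set[str]
    table: pd.DataFrame  # results with an added ``class`` column


def classify_genes(
    results: pd.DataFrame,
    q_cut: float = 0.05,
    fc_cut: float | None = None,
    lps_results: pd.DataFrame | None = None,
) -> GeneSets:
    """Label features induced / repressed / null at an FDR cut.

    ``fc_cut`` is a linear fold-change filter (e.g. 1.5 keeps only
    |FC| > 1.5).  ``lps_results`` is an optional second contrast (LPS vs
    vehicle) used to flag LPS-inducible genes by the same rule.
    """
    lfc_cut = 0.0 if fc_cut is None else math.log2(fc_cut)
    sig = results["q"] < q_cut
    induced = set(results.index[sig & (results["log2fc"] > lfc_cut)])
    repressed = set(results.index[sig & (results["log2fc"] < -lfc_cut)])
    lps_inducible: set[str] = set()
    if lps_results is not None:
        lps_sig = lps_results["q"] < q_cut
        lps_inducible = set(lps_results.index[lps_sig & (lps_results["log2fc"] > lfc_cut)])
    table = results.copy()
    table["class"] = "null"
    table.loc[list(induced), "class"] = "induced"
    table.loc[list(repressed), "class"] = "repressed"
    return GeneSets(induced, repressed, lps_inducible, table)
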