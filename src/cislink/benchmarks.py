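"""Seeded calibration and recovery benchmarks.

Each function re-runs a stage of the pipeline on freshly simulated data
with planted truth and measures how well the stage recovers it (or how
well it behaves under the null).  The same routines back the acceptance
test suite and the repository's acceptance script, so the numbers those
two report are computed by one code path.
"""

from __future__ import annotations

import math

import numpy as np

from .de import bh_adjust, nb_wald_test
from .intervals import (
    GeneModel,
    GenomicInterval,
    intersect_keep,
    nearest_gene,
    overlaps,
    point_interval_distance,
    subtract_keep,
)
from .linkage import dunn_posthoc, kruskal_wallis, linked_fraction, sample_random_genes
from .motifs import load_builtin_pwms, scan_sequence, set_enrichment
from .peaks import call_peaks, classify_counts
from .simulate import (
    Annotation,
    GroundTruth,
    SimulationConfig,
    generate_annotation,
    place_gene_tss,
    simulate_chip_track,
    simulate_count_matrix,
)
from .tracks import metaprofile

__all__ = [
    "make_study",
    "interval_algebra_oracle",
    "peak_null_calibration",
    "peak_recovery",
    "da_count_mode_recovery",
    "da_null_call_rate",
    "de_lfc_recovery",
    "chip_metaprofile_metrics",
    "linkage_recovery",
    "linkage_null_calibration",
    "motif_planted_enrichment",
    "scan_oracle_max_diff",
    "stat_oracle_max_diff",
]


def make_study(seed: int) -> tuple[SimulationConfig, Annotation, GroundTruth]:
    """Default-size synthetic study (4 x 10 Mb, 300 enhancers, 1000 genes)."""
    cfg = SimulationConfig(seed=seed)
    annotation, truth = generate_annotation(cfg)
    return cfg, annotation, truth


# ---------------------------------------------------------------------------
# interval algebra vs O(n^2) brute force
# ---------------------------------------------------------------------------


def _random_intervals(rng: np.random.Generator, n: int) -> list[GenomicInterval]:
    chroms = ("chr1", "chr2")
    out = []
    for _ in range(n):
        s = int(rng.integers(0, 100_000))
        out.append(
            GenomicInterval(chroms[rng.integers(0, 2)], s, s + int(rng.integers(1, 500)))
        )
    return out


def interval_algebra_oracle(seed: int, n: int = 1000) -> dict[str, float]:
    """Mismatch counts between the interval algebra and brute force on
    n random intervals (overlap on all pairs, intersect/subtract
    membership, nearest gene over a 200-gene panel)."""
    rng = np.random.default_rng([21, seed])
    a = _random_intervals(rng, n)
    b = _random_intervals(rng, n)

    overlap_mismatch = 0
    hit_any = [False] * n
    for i, x in enumerate(a):
        for y in b:
            brute = x.chrom == y.chrom and max(x.start, y.start) < min(x.end, y.end)
            if overlaps(x, y) != brute:
                overlap_mismatch += 1
            hit_any[i] = hit_any[i] or brute
    kept, _ = intersect_keep(a, b)
    removed = subtract_keep(a, b)
    expect_keep = sorted(iv for iv, h in zip(a, hit_any) if h)
    set_mismatch = int(kept != expect_keep)
    set_mismatch += int(sorted(kept + removed) != sorted(a))

    genes = [
        GeneModel(f"g{i:03d}", ("chr1", "chr2")[rng.integers(0, 2)], "+",
                  int(rng.integers(0, 100_000)))
        for i in range(200)
    ]
    nearest_mismatch = 0
    for e in a:
        gid, d = nearest_gene(e, genes)
        cands = {
            g.gene_id: point_interval_distance(g.tss, e)
            for g in genes if g.chrom == e.chrom
        }
        best = min(cands.values())
        if d != best or gid != min(g for g, dd in cands.items() if dd == best):
            nearest_mismatch += 1
    return {
        "n": n,
        "overlap_mismatches": overlap_mismatch,
        "set_mismatches": set_mismatch,
        "nearest_mismatches": nearest_mismatch,
    }


# ---------------------------------------------------------------------------
# peak caller
# ---------------------------------------------------------------------------


def peak_null_calibration(
    seed: int, n_seeds: int = 20, genome_length: int = 2_000_000
) -> dict[str, float]:
    """Fraction of windows called significant on homogeneous Poisson
    fragments (should be ~0 under FDR control)."""
    fracs = []
    win, step = 177, 88
    n_win = len(range(0, genome_length - win + 1, step))
    for k in range(n_seeds):
        rng = np.random.default_rng([22, seed, k])
        mids = np.sort(rng.integers(50, genome_length - 50,
                                    size=rng.poisson(2e-3 * genome_length)))
        frags = [GenomicInterval("chr1", int(m) - 50, int(m) + 50) for m in mids]
        pk = call_peaks(frags, {"chr1": genome_length})
        n_sig = sum((p.end - p.start - win) // step + 1 for p in pk)
        fracs.append(n_sig / n_win)
    return {"n": n_seeds, "mean_sig_window_fraction": float(np.mean(fracs)),
            "max_sig_window_fraction": float(np.max(fracs))}


def peak_recovery(seed: int, genome_length: int = 10_000_000,
                  n_planted: int = 200, fold: float = 8.0) -> dict[str, float]:
    """Detection-level Jaccard for planted fold-enriched 177-bp windows on
    a background of ~4 expected fragment midpoints per window."""
    rng = np.random.default_rng([23, seed])
    bg_rate = 4 / 177
    mids = list(rng.integers(50, genome_length - 50,
                             size=rng.poisson(bg_rate * genome_length)))
    anchors = np.arange(1000, genome_length - 1200, 2000)
    pos = np.sort(rng.choice(anchors, size=n_planted, replace=False))
    planted = [GenomicInterval("chr1", int(s), int(s) + 177) for s in pos]
    for p in planted:
        mids.extend(rng.integers(p.start, p.end,
                                 size=rng.poisson((fold - 1) * bg_rate * 177)))
    frags = [GenomicInterval("chr1", int(m) - 50, int(m) + 50) for m in sorted(mids)]
    called = call_peaks(frags, {"chr1": genome_length})
    recovered, _ = intersect_keep(planted, called)
    matched, _ = intersect_keep(called, planted)
    fp = len(called) - len(matched)
    jaccard = len(recovered) / (n_planted + fp)
    return {"n": n_planted, "n_called": len(called), "n_recovered": len(recovered),
            "false_positives": fp, "jaccard": jaccard}


# ---------------------------------------------------------------------------
# differential accessibility / expression calibration
# ---------------------------------------------------------------------------


def da_count_mode_recovery(
    seed: int, n_features: int = 5000, n_affected: int = 500, lfc: float = -1.5,
    mean: float = 100.0, dispersion: float = 0.05, n_reps: int = 4,
) -> dict[str, float]:
    """Sensitivity and empirical FDR of count-mode closure calls at q<0.05."""
    cm, affected = simulate_count_matrix(
        n_features, n_affected, lfc, mean, dispersion, n_reps, seed=seed
    )
    results, _ = classify_counts(cm, ("A", "B"))
    called = (results["class"] == "closed").to_numpy()
    tp = int((called & affected).sum())
    return {
        "n": n_features,
        "sensitivity": tp / n_affected,
        "fdr": (int(called.sum()) - tp) / max(int(called.sum()), 1),
    }


def da_null_call_rate(
    seed: int, n_seeds: int = 20, n_features: int = 5000,
    mean: float = 100.0, dispersion: float = 0.05, n_reps: int = 4,
) -> dict[str, float]:
    """Mean fraction of features called at q<0.05 when nothing is planted."""
    fracs = []
    for k in range(n_seeds):
        cm, _ = simulate_count_matrix(
            n_features, 0, 0.0, mean, dispersion, n_reps, seed=seed * 1000 + k
        )
        res = nb_wald_test(cm, ("A", "B"))
        fracs.append(float((res["q"] < 0.05).mean()))
    return {"n": n_seeds, "mean_call_rate": float(np.mean(fracs))}


def de_lfc_recovery(
    seed: int, n_genes: int = 2000, n_affected: int = 200, lfc: float = -1.5,
    mean: float = 200.0, dispersion: float = 0.05, n_reps: int = 3,
) -> dict[str, float]:
    """Median estimated log2 fold change over genes planted at ``lfc``."""
    cm, affected = simulate_count_matrix(
        n_genes, n_affected, lfc, mean, dispersion, n_reps, seed=seed
    )
    res = nb_wald_test(cm, ("A", "B"))
    return {
        "n": n_genes,
        "median_lfc": float(np.median(res["log2fc"].to_numpy()[affected])),
        "planted_lfc": lfc,
    }


# ---------------------------------------------------------------------------
# ChIP metaprofile
# ---------------------------------------------------------------------------


def chip_metaprofile_metrics(
    cfg: SimulationConfig, truth: GroundTruth
) -> dict[str, float]:
    """Metaprofile of the simulated ChIP track over planted-closed
    enhancers: central-bin placement of the maximum and center/flank
    signal ratio."""
    track = simulate_chip_track(cfg, truth)
    prof = metaprofile(track, truth.enhancer_set("T0_closed"))
    n = len(prof.values)
    center = float(prof.values[n // 2 - 1 : n // 2 + 1].mean())
    flank = float((prof.values[:8].mean() + prof.values[-8:].mean()) / 2.0)
    argmax_offset = int(np.argmax(prof.values)) - (n // 2)
    return {
        "n": prof.n_regions,
        "argmax_offset_bins": argmax_offset,
        "center_signal": center,
        "flank_signal": flank,
        "center_to_flank_ratio": center / flank,
    }


# ---------------------------------------------------------------------------
# linkage
# ---------------------------------------------------------------------------


def linkage_recovery(
    cfg: SimulationConfig, annotation: Annotation, truth: GroundTruth, seed: int = 0
) -> dict[str, float]:
    """Planted link-probability recovery (repressed and null gene classes
    versus the closed enhancer set) and the Kruskal-Wallis comparison of
    repressed versus uniformly random genes."""
    by_id = {g.gene_id: g for g in annotation.genes}
    repressed = [by_id[g] for g in truth.gene_ids("repressed")]
    nulls = [by_id[g] for g in truth.gene_ids("null")]
    closed = truth.enhancer_set("T0_closed")
    rep = linked_fraction(repressed, closed, window=cfg.link_window)
    nul = linked_fraction(nulls, closed, window=cfg.link_window)
    rng = np.random.default_rng([24, seed])
    random_genes = sample_random_genes(annotation.genes, len(repressed), rng)
    rnd = linked_fraction(random_genes, closed, window=cfg.link_window)
    groups = [
        rep.distances[np.isfinite(rep.distances)],
        rnd.distances[np.isfinite(rnd.distances)],
    ]
    _, p = kruskal_wallis(groups)
    return {
        "n": len(repressed),
        "repressed_linked_fraction": rep.linked_fraction,
        "null_linked_fraction": nul.linked_fraction,
        "planted_target": cfg.link_prob_target,
        "planted_background": cfg.link_prob_background,
        "kw_p_repressed_vs_random": p,
    }


def linkage_null_calibration(
    cfg: SimulationConfig, truth: GroundTruth, seed: int = 0,
    n_seeds: int = 50, n_genes_per_group: int = 100, link_prob: float = 0.2,
) -> dict[str, float]:
    """Kruskal-Wallis rejection rate at alpha=0.05 when two gene groups
    are placed with identical link probabilities (should be <= nominal)."""
    closed = truth.enhancer_set("T0_closed")
    rejections = 0
    for k in range(n_seeds):
        rng = np.random.default_rng([25, seed, k])
        groups = []
        for _ in range(2):
            genes = []
            for i in range(n_genes_per_group):
                chrom, tss, _ = place_gene_tss(
                    rng, cfg.genome, closed, closed, link_prob, cfg.link_window
                )
                genes.append(GeneModel(f"g{i}", chrom, "+", tss))
            rep = linked_fraction(genes, closed, window=cfg.link_window)
            groups.append(rep.distances[np.isfinite(rep.distances)])
        _, p = kruskal_wallis(groups)
        rejections += p < 0.05
    return {"n": n_seeds, "rejection_rate": rejections / n_seeds}


# ---------------------------------------------------------------------------
# motifs
# ---------------------------------------------------------------------------


def motif_planted_enrichment(
    cfg: SimulationConfig, annotation: Annotation, truth: GroundTruth
) -> dict[str, float]:
    """DR4 enrichment of planted-closed enhancers vs the marked set."""
    fasta = {c: a.tobytes().decode() for c, a in annotation.sequences.items()}
    closed = truth.enhancer_set("T0_closed")
    table = set_enrichment(closed, annotation.marked, fasta, load_builtin_pwms())
    row = table.loc["LXRE_DR4"]
    return {
        "n": len(closed),
        "target_rate": float(row["target_rate"]),
        "background_rate": float(row["background_rate"]),
        "fold_enrichment": float(row["fold_enrichment"]),
        "q": float(row["q"]),
    }


def scan_oracle_max_diff(seed: int, n_seqs: int = 10, seq_len: int = 50) -> dict[str, float]:
    """Max |difference| between vectorized window scores and per-position
    brute-force summation over random sequences (both strands)."""
    rng = np.random.default_rng([26, seed])
    pwm = load_builtin_pwms()[0]
    lom = pwm.log_odds
    rc = str.maketrans("ACGT", "TGCA")
    max_diff = 0.0
    for _ in range(n_seqs):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=seq_len))
        res = scan_sequence(seq, pwm)
        best = -math.inf
        for s in (seq, seq.translate(rc)[::-1]):
            for i in range(len(s) - pwm.length + 1):
                best = max(
                    best,
                    sum(lom[k, "ACGT".index(s[i + k])] for k in range(pwm.length)),
                )
        max_diff = max(max_diff, abs(res.best_score - best))
    return {"n": n_seqs, "max_abs_diff": max_diff}


# ---------------------------------------------------------------------------
# statistical oracles
# ---------------------------------------------------------------------------


def stat_oracle_max_diff(seed: int, n_trials: int = 100) -> dict[str, float]:
    """Max deviation of BH, Kruskal-Wallis and Dunn from independent
    reference implementations on randomized small samples."""
    from scipy import stats as sps
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng([27, seed])
    bh_diff = kw_diff = dunn_diff = 0.0
    for _ in range(n_trials):
        p = rng.random(int(rng.integers(1, 30)))
        bh_diff = max(bh_diff, float(np.max(np.abs(
            bh_adjust(p) - multipletests(p, method="fdr_bh")[1]
        ))))
        groups = [
            rng.integers(0, 10, size=int(rng.integers(3, 15))).astype(float)
            for _ in range(3)
        ]
        if len(np.unique(np.concatenate(groups))) > 1:
            h, pv = kruskal_wallis(groups)
            h_ref, p_ref = sps.kruskal(*groups)
            kw_diff = max(kw_diff, abs(h - h_ref), abs(pv - p_ref))
        df = dunn_posthoc(groups, labels=["0", "1", "2"], adjust="none")
        # reference: z from scipy rank machinery assembled independently
        pooled = np.concatenate(groups)
        ranks = sps.rankdata(pooled)
        sizes = [len(g) for g in groups]
        bounds = np.cumsum([0] + sizes)
        mr = [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(3)]
        _, counts = np.unique(pooled, return_counts=True)
        tie = float(np.sum(counts**3 - counts))
        n = len(pooled)
        var = n * (n + 1) / 12.0 - tie / (12.0 * (n - 1))
        for row in df.itertuples():
            i, j = int(row.group_a), int(row.group_b)
            denom = math.sqrt(var * (1 / sizes[i] + 1 / sizes[j]))
            z_ref = 0.0 if denom == 0 else (mr[i] - mr[j]) / denom
            dunn_diff = max(dunn_diff, abs(row.z - z_ref))
    return {"n": n_trials, "bh_max_diff": bh_diff, "kw_max_diff": kw_diff,
            "dunn_max_diff": dunn_diff}
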