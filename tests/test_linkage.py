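"""Enhancer-gene linkage fractions and rank-based distance tests."""

import math

import numpy as np
import pytest
from scipy import stats

from cislink.intervals import GeneModel, GenomicInterval, point_interval_distance
from cislink.linkage import (
    dunn_posthoc,
    kruskal_wallis,
    linked_fraction,
    run_linkage_analysis,
    sample_random_genes,
)
from conftest import random_intervals


def _genes(rng, n, chroms=("chr1", "chr2"), max_pos=100_000):
    return [
        GeneModel(f"g{i:03d}", chroms[rng.integers(0, len(chroms))], "+",
                  int(rng.integers(0, max_pos)))
        for i in range(n)
    ]


class TestLinkedFraction:
    def test_tss_inside_enhancers_gives_one(self):
        genes = [GeneModel("g1", "c", "+", 150), GeneModel("g2", "c", "+", 160)]
        rep = linked_fraction(genes, [GenomicInterval("c", 100, 200)])
        assert rep.linked_fraction == 1.0
        assert np.all(rep.distances == 0)

    def test_other_chromosome_gives_zero_and_infinite(self):
        genes = [GeneModel("g1", "chr1", "+", 150)]
        rep = linked_fraction(genes, [GenomicInterval("chr2", 100, 200)])
        assert rep.linked_fraction == 0.0
        assert rep.n_infinite == 1

    def test_empty_gene_set_errors(self):
        with pytest.raises(ValueError, match="empty"):
            linked_fraction([], [GenomicInterval("c", 0, 10)])

    def test_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(21)
        genes = _genes(rng, 500)
        enhancers = random_intervals(rng, 300)
        rep = linked_fraction(genes, enhancers, window=5000)
        for g, d in zip(genes, rep.distances):
            cands = [
                point_interval_distance(g.tss, e)
                for e in enhancers if e.chrom == g.chrom
            ]
            assert d == (min(cands) if cands else math.inf)
        expect = np.mean([d <= 5000 for d in rep.distances])
        assert rep.linked_fraction == pytest.approx(expect)

    def test_monotone_in_window(self):
        rng = np.random.default_rng(22)
        genes = _genes(rng, 200)
        enhancers = random_intervals(rng, 50)
        fracs = [
            linked_fraction(genes, enhancers, window=w).linked_fraction
            for w in (100, 1000, 5000, 20_000, 100_000)
        ]
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))


class TestSampleRandomGenes:
    def test_full_universe_and_seed_reproducibility(self):
        rng = np.random.default_rng(23)
        universe = _genes(rng, 40)
        assert sample_random_genes(universe, 40, seed=1) == universe
        a = sample_random_genes(universe, 10, seed=5)
        b = sample_random_genes(universe, 10, seed=5)
        assert a == b

    def test_inclusion_frequency_is_uniform(self):
        rng = np.random.default_rng(24)
        universe = _genes(rng, 20)
        hits = np.zeros(20)
        draws = 10_000
        g = np.random.default_rng(0)
        for _ in range(draws):
            for gene in sample_random_genes(universe, 5, seed=g):
                hits[universe.index(gene)] += 1
        freq = hits / draws
        assert np.allclose(freq, 5 / 20, atol=0.02)


class TestKruskalWallis:
    def test_identical_values_give_p_one(self):
        h, p = kruskal_wallis([np.ones(5), np.ones(7)])
        assert (h, p) == (0.0, 1.0)

    def test_matches_scipy_on_simple_groups(self):
        groups = [np.array([1, 2, 3.0]), np.array([4, 5, 6.0]), np.array([7, 8, 9.0])]
        h, p = kruskal_wallis(groups)
        h_ref, p_ref = stats.kruskal(*groups)
        assert abs(h - h_ref) < 1e-10 and abs(p - p_ref) < 1e-10

    def test_matches_scipy_with_ties_on_random_samples(self):
        rng = np.random.default_rng(25)
        for _ in range(50):
            groups = [
                rng.integers(0, 8, size=rng.integers(3, 20)).astype(float)
                for _ in range(rng.integers(2, 5))
            ]
            if all(np.all(g == groups[0][0]) for g in groups):
                continue
            h, p = kruskal_wallis(groups)
            h_ref, p_ref = stats.kruskal(*groups)
            assert abs(h - h_ref) < 1e-10 and abs(p - p_ref) < 1e-10

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(26)
        groups = [rng.random(10), rng.random(12)]
        h1, _ = kruskal_wallis(groups)
        h2, _ = kruskal_wallis([np.exp(5 * g) for g in groups])
        assert h1 == pytest.approx(h2, abs=1e-10)


def _dunn_oracle(groups):
    """Textbook Dunn z statistics computed from scratch (hand ranking)."""
    pooled = sorted((v, gi) for gi, g in enumerate(groups) for v in g)
    n = len(pooled)
    ranks = {}
    i = 0
    while i < n:
        j = i
        while j < n and pooled[j][0] == pooled[i][0]:
            j += 1
        avg = (i + 1 + j) / 2.0
        for k in range(i, j):
            ranks.setdefault(k, avg)
        i = j
    mean_rank = [0.0] * len(groups)
    sizes = [len(g) for g in groups]
    for k, (_, gi) in enumerate(pooled):
        mean_rank[gi] += ranks[k]
    mean_rank = [m / s for m, s in zip(mean_rank, sizes)]
    # tie correction
    from collections import Counter

    t = sum(c**3 - c for c in Counter(v for v, _ in pooled).values())
    var = n * (n + 1) / 12.0 - t / (12.0 * (n - 1))
    out = {}
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            z = (mean_rank[i] - mean_rank[j]) / math.sqrt(
                var * (1 / sizes[i] + 1 / sizes[j])
            )
            out[(i, j)] = z
    return out


class TestDunnPosthoc:
    def test_identical_groups_give_zero_z(self):
        df = dunn_posthoc([np.ones(5), np.ones(5)])
        assert df["z"].iloc[0] == 0.0 and df["p"].iloc[0] == 1.0

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(27)
        for _ in range(20):
            groups = [
                rng.integers(0, 10, size=rng.integers(4, 15)).astype(float)
                for _ in range(3)
            ]
            df = dunn_posthoc(groups, labels=["0", "1", "2"])
            oracle = _dunn_oracle(groups)
            for row in df.itertuples():
                z_ref = oracle[(int(row.group_a), int(row.group_b))]
                assert abs(row.z - z_ref) < 1e-10
                p_ref = 2 * stats.norm.sf(abs(z_ref))
                assert abs(row.p - min(p_ref, 1.0)) < 1e-10

    def test_adjusted_p_at_least_raw(self):
        rng = np.random.default_rng(28)
        groups = [rng.random(12) for _ in range(4)]
        df = dunn_posthoc(groups)
        assert np.all(df["p_adj"].to_numpy() >= df["p"].to_numpy() - 1e-15)


class TestRunLinkageAnalysis:
    def test_empty_enhancer_sets_give_zero_fractions(self):
        rng = np.random.default_rng(29)
        universe = _genes(rng, 50)
        ana = run_linkage_analysis(
            {"setA": universe[:10]}, {"closed": []}, universe, seed=0
        )
        assert np.all(ana.table["linked_fraction"] == 0.0)

    def test_same_seed_gives_identical_tables(self):
        rng = np.random.default_rng(30)
        universe = _genes(rng, 100)
        enh = {"closed": random_intervals(rng, 30)}
        a = run_linkage_analysis({"s": universe[:20]}, enh, universe, seed=4)
        b = run_linkage_analysis({"s": universe[:20]}, enh, universe, seed=4)
        assert a.table.equals(b.table)
        assert a.omnibus.equals(b.omnibus)

    def test_planted_linkage_geometry_recovered(self, sim_default):
        cfg, annotation, truth = sim_default
        by_id = {g.gene_id: g for g in annotation.genes}
        repressed = [by_id[g] for g in truth.gene_ids("repressed")]
        nulls = [by_id[g] for g in truth.gene_ids("null")]
        closed = truth.enhancer_set("T0_closed")
        rep = linked_fraction(repressed, closed, window=cfg.link_window)
        nul = linked_fraction(nulls, closed, window=cfg.link_window)
        assert abs(rep.linked_fraction - cfg.link_prob_target) <= 0.05
        assert abs(nul.linked_fraction - cfg.link_prob_background) <= 0.05
        ana = run_linkage_analysis(
            {"repressed": repressed}, {"closed": closed}, annotation.genes, seed=1
        )
        assert ana.omnibus["p"].iloc[0] < 0.01
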