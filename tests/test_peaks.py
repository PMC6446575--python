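"""Peak calling, enhancer filtering, counting, and classification."""

import math

import numpy as np
import pytest
from scipy import stats

from cislink.intervals import GenomicInterval, overlaps
from cislink.peaks import (
    call_peaks,
    classify_counts,
    classify_presence,
    count_fragments_per_enhancer,
    filter_to_enhancers,
    set_overlap_fraction,
)
from conftest import random_intervals


def _frags_from_midpoints(mids, chrom="chr1", half=50):
    return [GenomicInterval(chrom, int(m) - half, int(m) + half) for m in sorted(mids)]


class TestCallPeaks:
    def test_empty_fragments_give_empty_peaks(self):
        assert call_peaks([], {"chr1": 10_000}) == []

    def test_uniform_fragments_give_zero_peaks(self):
        # one midpoint in every window position: perfectly flat signal
        mids = np.arange(50, 200_000 - 50, 40)
        peaks = call_peaks(_frags_from_midpoints(mids), {"chr1": 200_000})
        assert peaks == []

    def test_poisson_tail_matches_direct_summation(self):
        # the caller's p-value is P(X >= k | lambda); check the scipy route
        # against brute-force pmf summation at the spec's example point
        k, lam = 20, 5.0
        term = math.exp(-lam) * lam**k / math.factorial(k)
        direct = 0.0
        for i in range(k, 200):
            direct += term
            term *= lam / (i + 1)
        assert stats.poisson.sf(k - 1, lam) == pytest.approx(direct, rel=1e-12)

    def test_planted_enrichment_is_recovered(self):
        rng = np.random.default_rng(8)
        L = 1_000_000
        mids = list(rng.integers(50, L - 50, size=int(4 / 177 * L)))
        planted = [(100_000, 100_177), (500_000, 500_177)]
        for s, e in planted:
            mids.extend(rng.integers(s, e, size=60))
        peaks = call_peaks(_frags_from_midpoints(mids), {"chr1": L})
        for s, e in planted:
            target = GenomicInterval("chr1", s, e)
            assert any(overlaps(p, target) for p in peaks)
        assert all(p.score is not None and p.score <= 0.001 for p in peaks)

    def test_merging_respects_gap(self):
        rng = np.random.default_rng(9)
        L = 500_000
        mids = list(rng.integers(50, L - 50, size=int(4 / 177 * L)))
        mids.extend(rng.integers(100_000, 100_177, size=80))
        mids.extend(rng.integers(102_000, 102_177, size=80))  # > merge gap away
        peaks = call_peaks(_frags_from_midpoints(mids), {"chr1": L})
        hits = [p for p in peaks if 99_000 < p.start < 103_000]
        assert len(hits) == 2


class TestFilterToEnhancers:
    def test_marked_superset_captures_everything(self):
        rng = np.random.default_rng(10)
        peaks = random_intervals(rng, 40)
        kept, frac = filter_to_enhancers(peaks, peaks)
        assert frac == 1.0 and len(kept) == len(peaks)

    def test_empty_peaks_undefined_fraction(self):
        kept, frac = filter_to_enhancers([], [GenomicInterval("c", 0, 5)])
        assert kept == [] and math.isnan(frac)

    def test_decoy_construction_yields_designed_capture(self, sim_default):
        """~30% of accessible regions are planted outside the marked set."""
        _, annotation, _ = sim_default
        _, frac = filter_to_enhancers(annotation.accessible, annotation.marked)
        assert frac == pytest.approx(0.7, abs=0.02)


class TestCountFragments:
    def test_half_open_midpoint_rule(self):
        enh = [GenomicInterval("c", 100, 200, name="e")]
        frags = {
            "s1": [
                GenomicInterval("c", 50, 150),  # midpoint 100 -> counted
                GenomicInterval("c", 150, 250),  # midpoint 200 -> not counted
            ]
        }
        cm = count_fragments_per_enhancer(enh, frags, {"s1": "A"})
        assert cm.counts.loc["e", "s1"] == 1

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(13)
        enhancers = []
        pos = 0
        for i in range(50):  # disjoint enhancers so each midpoint maps once
            pos += int(rng.integers(100, 2000))
            enhancers.append(GenomicInterval("chr1", pos, pos + 400, name=f"e{i}"))
            pos += 400
        frags = _frags_from_midpoints(rng.integers(50, pos + 5000, size=10_000))
        cm = count_fragments_per_enhancer(enhancers, {"s": frags}, {"s": "A"})
        for e in enhancers:
            expect = sum(
                1 for f in frags if e.start <= (f.start + f.end) // 2 < e.end
            )
            assert cm.counts.loc[e.name, "s"] == expect
        assert cm.counts["s"].sum() <= len(frags)


class TestClassifyPresence:
    def _setup(self):
        rng = np.random.default_rng(14)
        enhancers = random_intervals(rng, 200)
        peaks_a = random_intervals(rng, 100)
        peaks_b = random_intervals(rng, 100)
        return enhancers, {"A": peaks_a, "B": peaks_b}

    def test_identical_peak_sets_give_no_changes(self):
        enhancers, pk = self._setup()
        cls = classify_presence({"A": pk["A"], "B": pk["A"]}, enhancers, ("A", "B"))
        assert cls.closed == [] and cls.opened == []

    def test_empty_b_closes_all_a_accessible(self):
        enhancers, pk = self._setup()
        cls = classify_presence({"A": pk["A"], "B": []}, enhancers, ("A", "B"))
        expect = sorted(e for e in enhancers if any(overlaps(e, p) for p in pk["A"]))
        assert cls.closed == expect and cls.opened == []

    def test_matches_brute_force_set_logic_and_partitions(self):
        enhancers, pk = self._setup()
        cls = classify_presence(pk, enhancers, ("A", "B"))
        for e in enhancers:
            in_a = any(overlaps(e, p) for p in pk["A"])
            in_b = any(overlaps(e, p) for p in pk["B"])
            key = e.key()
            assert (key in {i.key() for i in cls.closed}) == (in_a and not in_b)
            assert (key in {i.key() for i in cls.opened}) == (in_b and not in_a)
            assert (key in {i.key() for i in cls.stable}) == (in_a and in_b)
        universe = sorted(cls.closed + cls.opened + cls.stable)
        assert len(universe) == len(cls.closed) + len(cls.opened) + len(cls.stable)

    def test_swapping_conditions_swaps_closed_and_opened(self):
        enhancers, pk = self._setup()
        fwd = classify_presence(pk, enhancers, ("A", "B"))
        rev = classify_presence(pk, enhancers, ("B", "A"))
        assert fwd.closed == rev.opened and fwd.opened == rev.closed

    def test_unknown_condition_rejected(self):
        enhancers, pk = self._setup()
        with pytest.raises(KeyError):
            classify_presence(pk, enhancers, ("A", "C"))


class TestClassifyCounts:
    def test_planted_closure_recovered(self, sim_default):
        from cislink.peaks import count_fragments_per_enhancer
        from cislink.simulate import atac_sample_conditions, simulate_atac_fragments

        cfg, annotation, truth = sim_default
        frags = simulate_atac_fragments(cfg, annotation, truth)
        cm = count_fragments_per_enhancer(
            annotation.marked, frags, atac_sample_conditions(cfg)
        )
        _, cls = classify_counts(cm, ("vehicle", "T0"), annotation.marked)
        called = {iv.name for iv in cls.closed}
        true_closed = set(
            truth.enhancers.loc[truth.enhancers["class"] == "T0_closed", "id"]
        )
        tp = len(called & true_closed)
        assert tp / len(true_closed) >= 0.8
        assert (len(called) - tp) / len(called) <= 0.10


class TestSetOverlapFraction:
    def test_self_is_one_disjoint_is_zero(self):
        a = [GenomicInterval("c", 0, 10), GenomicInterval("c", 50, 60)]
        b = [GenomicInterval("c", 100, 110)]
        assert set_overlap_fraction(a, a) == 1.0
        assert set_overlap_fraction(a, b) == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(15)
        a = random_intervals(rng, 300)
        b = random_intervals(rng, 300)
        expect = sum(
            1 for iv in a if any(overlaps(iv, other) for other in b)
        ) / len(a)
        assert set_overlap_fraction(a, b) == pytest.approx(expect)
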