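"""Coverage tracks, bedGraph I/O, metaprofiles, and track correlation."""

import numpy as np
import pytest

from cislink.intervals import GenomicInterval
from cislink.tracks import (
    SignalTrack,
    correlate_tracks,
    coverage_track,
    metaprofile,
    read_bedgraph,
    signal_matrix,
    write_bedgraph,
)

GENOME = {"chr1": 10_000, "chr2": 5_000}


def _random_fragments(rng, n=300, flen=100):
    out = []
    for _ in range(n):
        chrom = ("chr1", "chr2")[rng.integers(0, 2)]
        s = int(rng.integers(0, GENOME[chrom] - flen))
        out.append(GenomicInterval(chrom, s, s + flen))
    return out


class TestCoverageTrack:
    def test_single_fragment_fills_one_bin(self):
        track = coverage_track(
            [GenomicInterval("chr1", 0, 100)], GENOME, bin_size=100, normalization="raw"
        )
        assert track.values["chr1"][0] == 1.0
        assert track.values["chr1"][1:].sum() == 0.0

    def test_rpgc_genome_mean_is_one(self):
        rng = np.random.default_rng(1)
        track = coverage_track(_random_fragments(rng), GENOME, bin_size=25)
        assert track.genome_mean() == pytest.approx(1.0, abs=1e-9)

    def test_matches_per_base_brute_force(self):
        rng = np.random.default_rng(2)
        frags = _random_fragments(rng, n=100)
        track = coverage_track(frags, GENOME, bin_size=7, normalization="raw")
        for chrom, L in GENOME.items():
            n_bins = -(-L // 7)
            per_bp = np.zeros(n_bins * 7)
            for f in frags:
                if f.chrom == chrom:
                    per_bp[f.start : f.end] += 1
            expect = per_bp.reshape(n_bins, 7).sum(axis=1) / 7
            assert np.allclose(track.values[chrom], expect)

    def test_fragment_beyond_chromosome_end_rejected(self):
        with pytest.raises(ValueError, match="beyond"):
            coverage_track([GenomicInterval("chr2", 4950, 5050)], GENOME)


class TestBedgraphIO:
    def test_constant_file_gives_constant_track(self, tmp_path):
        p = tmp_path / "c.bedgraph"
        p.write_text("chr1\t0\t10000\t2.5\nchr2\t0\t5000\t2.5\n")
        track = read_bedgraph(p, GENOME, bin_size=50)
        for chrom in GENOME:
            assert np.allclose(track.values[chrom], 2.5)

    def test_grid_aligned_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        values = {
            c: np.round(rng.random(-(-L // 50)) * 4, 3) for c, L in GENOME.items()
        }
        track = SignalTrack(50, GENOME, values)
        p = tmp_path / "rt.bedgraph"
        write_bedgraph(track, p)
        back = read_bedgraph(p, GENOME, bin_size=50)
        for chrom in GENOME:
            assert np.allclose(back.values[chrom], values[chrom], atol=1e-9)

    def test_misaligned_intervals_use_bp_weighted_mean(self, tmp_path):
        p = tmp_path / "m.bedgraph"
        # bin 100: bin0 gets 30 bp of 1.0 + 50 bp of 3.0 -> (30 + 150)/100
        p.write_text("chr1\t20\t50\t1.0\nchr1\t50\t100\t3.0\n")
        track = read_bedgraph(p, GENOME, bin_size=100)
        assert track.values["chr1"][0] == pytest.approx(1.8)


class TestMetaprofile:
    def _constant_track(self, value=3.0, bin_size=25):
        vals = {c: np.full(-(-L // bin_size), value) for c, L in GENOME.items()}
        return SignalTrack(bin_size, GENOME, vals)

    def test_constant_track_gives_constant_profile(self):
        regions = [GenomicInterval("chr1", 4000, 4500)]
        prof = metaprofile(self._constant_track(), regions, flank=1000, bin=25)
        assert np.allclose(prof.values, 3.0)
        assert len(prof.values) == 2 * 1000 // 25

    def test_single_region_profile_equals_binned_signal(self):
        rng = np.random.default_rng(4)
        vals = {c: rng.random(-(-L // 25)) for c, L in GENOME.items()}
        track = SignalTrack(25, GENOME, vals)
        region = GenomicInterval("chr1", 4000, 4500)  # center 4250, grid-aligned
        prof = metaprofile(track, [region], flank=1000, bin=25)
        center = 4250
        expect = vals["chr1"][(center - 1000) // 25 : (center + 1000) // 25]
        assert np.allclose(prof.values, expect)

    def test_truncated_regions_dropped_and_all_dropped_errors(self):
        track = self._constant_track()
        regions = [
            GenomicInterval("chr1", 0, 100),  # window crosses chrom start
            GenomicInterval("chr1", 4000, 4500),
        ]
        prof = metaprofile(track, regions, flank=1000, bin=25)
        assert prof.n_regions == 1 and prof.n_dropped == 1
        with pytest.raises(ValueError, match="dropped"):
            metaprofile(track, [GenomicInterval("chr1", 0, 100)], flank=1000, bin=25)

    def test_planted_bumps_peak_at_central_bin(self, sim_default):
        from cislink.simulate import simulate_chip_track

        cfg, _, truth = sim_default
        track = simulate_chip_track(cfg, truth)
        prof = metaprofile(track, truth.enhancer_set("T0_closed"))
        n = len(prof.values)
        assert np.argmax(prof.values) in (n // 2 - 1, n // 2)


class TestSignalMatrix:
    def test_column_means_equal_metaprofile_exactly(self):
        rng = np.random.default_rng(5)
        vals = {c: rng.random(-(-L // 25)) * 5 for c, L in GENOME.items()}
        track = SignalTrack(25, GENOME, vals)
        regions = [
            GenomicInterval("chr1", 3000, 3400),
            GenomicInterval("chr1", 6000, 6500),
            GenomicInterval("chr2", 2000, 2300),
        ]
        prof = metaprofile(track, regions, flank=1000, bin=25)
        unsorted = signal_matrix(track, regions, flank=1000, bin=25, sort=False)
        assert np.array_equal(unsorted.mean(axis=0), prof.values)
        # sorting permutes rows, which only reorders the summation
        mat = signal_matrix(track, regions, flank=1000, bin=25)
        assert np.allclose(mat.mean(axis=0), prof.values, rtol=0, atol=1e-12)

    def test_rows_sorted_by_descending_mean(self):
        rng = np.random.default_rng(6)
        vals = {c: rng.random(-(-L // 25)) for c, L in GENOME.items()}
        track = SignalTrack(25, GENOME, vals)
        regions = [GenomicInterval("chr1", s, s + 300) for s in (2000, 4000, 6000)]
        mat = signal_matrix(track, regions, flank=500, bin=25)
        means = mat.mean(axis=1)
        assert np.all(np.diff(means) <= 1e-12)


class TestCorrelateTracks:
    def _tracks_and_regions(self):
        rng = np.random.default_rng(7)
        vals = {c: rng.random(-(-L // 25)) for c, L in GENOME.items()}
        a = SignalTrack(25, GENOME, vals)
        regions = [GenomicInterval("chr1", s, s + 200) for s in range(1000, 9000, 500)]
        return a, vals, regions

    def test_self_correlation_is_one(self):
        a, _, regions = self._tracks_and_regions()
        assert correlate_tracks(a, a, regions) == pytest.approx(1.0)

    def test_reflected_track_gives_minus_one(self):
        a, vals, regions = self._tracks_and_regions()
        b = SignalTrack(25, GENOME, {c: 10.0 - v for c, v in vals.items()})
        assert correlate_tracks(a, b, regions) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        a, vals, regions = self._tracks_and_regions()
        rng = np.random.default_rng(8)
        other = {c: rng.random(len(v)) for c, v in vals.items()}
        b = SignalTrack(25, GENOME, other)
        r = correlate_tracks(a, b, regions)

        def means(vv):
            out = []
            for reg in regions:
                bp = np.arange(reg.start, reg.end)
                out.append(vv[reg.chrom][bp // 25].mean())
            return np.array(out)

        x, y = means(vals), means(other)
        xm, ym = x - x.mean(), y - y.mean()
        expect = float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))
        assert r == pytest.approx(expect, abs=1e-12)

    def test_zero_variance_errors(self):
        track = SignalTrack(
            25, GENOME, {c: np.ones(-(-L // 25)) for c, L in GENOME.items()}
        )
        regions = [GenomicInterval("chr1", s, s + 100) for s in (1000, 2000, 3000)]
        with pytest.raises(ValueError, match="variance"):
            correlate_tracks(track, track, regions)
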