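"""Insulation, segmentation, aggregation and fusion detection."""

import numpy as np
import pytest
from scipy.interpolate import RegularGridInterpolator

from tadfuse import (GenomeSpec, TadSegmentation, ValidationError,
                     aggregate_tads, call_boundaries, detect_fusions,
                     derive_condition_two, expected_contacts, generate_genome,
                     ice_balance, insulation_score, intra_inter_ratio,
                     observed_over_expected, segment_tads, simulate_contacts)
from tadfuse.tads import _bilinear_resize

from conftest import dense_matrix


def toeplitz_matrix(n=20, decay=1.0):
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
    with np.errstate(divide="ignore"):
        w = (d + 1.0) ** -decay
    np.fill_diagonal(w, 0.0)
    return dense_matrix(w, balanced=True)


class TestInsulation:
    def test_toeplitz_is_flat_on_interior_bins(self):
        track = insulation_score(toeplitz_matrix(), window=3)
        s = track.score[np.isfinite(track.score)]
        assert s.size > 0
        assert np.allclose(s, 0.0, atol=1e-12)

    def test_two_block_junction_matches_hand_enumeration(self):
        # 12 bins, within-block 10, between-block 1, blocks [0,6) [6,12), w=2
        n, w = 12, 2
        left = (np.arange(n) < 6).astype(int)
        m = np.where(np.add.outer(left, left) % 2 == 0, 10.0, 1.0)
        np.fill_diagonal(m, 0.0)
        track = insulation_score(dense_matrix(m, balanced=True), window=w)
        # diamond at the junction bin 6: rows {4,5} x cols {6,7} - all cross
        assert track.raw[6] == pytest.approx(1.0, abs=1e-12)
        # diamond at bin 5: rows {3,4} x cols {5,6} -> {(3,5),(4,5)} within,
        # {(3,6),(4,6)} across
        assert track.raw[5] == pytest.approx((10 + 10 + 1 + 1) / 4, abs=1e-12)

    def test_fused_boundary_gains_insulation(self, two_chrom_spec):
        t1 = generate_genome(two_chrom_spec, 5, 10, seed=3,
                             compartment_delta=0.0, tad_delta=1.0, depth=2e7)
        t2 = derive_condition_two(t1, 2, 0, 0.0, seed=4)
        tracks = []
        for t, s in ((t1, 10), (t2, 11)):
            bal = ice_balance(simulate_contacts(t, two_chrom_spec, seed=s))
            tracks.append(insulation_score(bal, 5))
        bins = two_chrom_spec.bins()
        deltas = []
        for chrom, b in t2.fusion_events:
            off, _ = bins.chrom_span(chrom)
            deltas.append(tracks[1].score[off + b] - tracks[0].score[off + b])
        assert np.mean(deltas) > 0

    def test_short_chromosome_warns_all_missing(self):
        with pytest.warns(RuntimeWarning):
            track = insulation_score(toeplitz_matrix(n=8), window=4)
        assert np.isnan(track.score).all()


class TestBoundaryCalling:
    def test_constant_track_has_no_boundaries(self):
        track = insulation_score(toeplitz_matrix(), window=3)
        assert call_boundaries(track, 0.0) == {"chr1": []}

    def test_planted_boundary_recovered_exactly_noise_free(self, tiny_spec):
        truth = generate_genome(tiny_spec, 2, 30, seed=7, compartment_delta=0.0,
                                tad_delta=1.0, depth=1e6)
        bal = ice_balance(expected_contacts(truth, tiny_spec))
        called = call_boundaries(insulation_score(bal, 4), 0.1)
        assert called["chr1"] == truth.tad_boundaries["chr1"]

    def test_plateau_minimum_resolves_leftmost(self, tiny_spec):
        bins = tiny_spec.bins()
        from tadfuse.tads import InsulationTrack
        score = np.zeros(30)
        score[10:12] = -1.0          # two-bin plateau
        strength = np.full(30, 1.0)
        track = InsulationTrack(bins, np.exp(score), score, strength, window=2)
        assert call_boundaries(track, 0.5) == {"chr1": [10]}


class TestSegmentation:
    def test_no_boundaries_single_tad(self, tiny_spec):
        seg = segment_tads({"chr1": []}, tiny_spec.bins())
        assert seg.intervals["chr1"] == [(0, 30)]

    def test_boundaries_tile_exactly(self, tiny_spec):
        seg = segment_tads({"chr1": [10, 20]}, tiny_spec.bins())
        assert seg.intervals["chr1"] == [(0, 10), (10, 20), (20, 30)]
        assert seg.boundaries("chr1") == [10, 20]

    def test_sliver_merged_into_weaker_side(self, tiny_spec):
        # boundaries 10 and 11 leave a 1-bin sliver; min_tad=3 drops one
        seg = segment_tads({"chr1": [10, 11]}, tiny_spec.bins(), min_tad=3)
        ivs = seg.intervals["chr1"]
        assert all(e - s >= 3 for s, e in ivs)
        pos = 0
        for s, e in ivs:
            assert s == pos
            pos = e
        assert pos == 30

    def test_non_interior_boundary_rejected(self, tiny_spec):
        with pytest.raises(ValidationError):
            segment_tads({"chr1": [0]}, tiny_spec.bins())


class TestIntraInter:
    def test_hand_matrix_matches_brute_force(self):
        rng = np.random.default_rng(9)
        n = 20
        w = rng.random((n, n)) + 0.1
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        m = dense_matrix(w, balanced=True)
        seg = segment_tads({"chr1": [8]}, m.bins)
        res = intra_inter_ratio(m, seg)
        intra = [w[i, j] for s, e in [(0, 8), (8, 20)]
                 for i in range(s, e) for j in range(i + 1, e)]
        span = 12
        inter = [w[i, j] for i in range(0, 8) for j in range(8, 20) if j - i <= span]
        assert res["intra_mean"] == pytest.approx(np.mean(intra))
        assert res["inter_mean"] == pytest.approx(np.mean(inter))
        assert res["ratio"] == pytest.approx(np.mean(intra) / np.mean(inter))

    def test_zero_inter_reported_missing(self):
        w = np.zeros((10, 10))
        w[:5, :5] = 1.0
        w[5:, 5:] = 1.0
        np.fill_diagonal(w, 0.0)
        m = dense_matrix(w, balanced=True)
        seg = segment_tads({"chr1": [5]}, m.bins)
        res = intra_inter_ratio(m, seg)
        assert res["inter_mean"] == 0.0
        assert np.isnan(res["ratio"])

    def test_boundary_attenuation_raises_ratio(self, two_chrom_spec):
        t1 = generate_genome(two_chrom_spec, 5, 10, seed=3,
                             compartment_delta=0.0, tad_delta=1.0, depth=1e7)
        t2 = derive_condition_two(t1, 0, 0, 0.4, seed=4)
        ratios = []
        for t, s in ((t1, 20), (t2, 21)):
            bal = ice_balance(simulate_contacts(t, two_chrom_spec, seed=s))
            ins = insulation_score(bal, 5)
            seg = segment_tads(call_boundaries(ins, 0.1), two_chrom_spec.bins(), 3, ins)
            ratios.append(intra_inter_ratio(bal, seg)["ratio"])
        assert ratios[1] > ratios[0]


class TestAggregateTads:
    def test_uniform_oe_gives_flat_aggregate(self):
        n = 60
        w = np.ones((n, n))
        oe = dense_matrix(w, balanced=True, is_oe=True)
        seg = segment_tads({"chr1": [20, 40]}, oe.bins)
        agg = aggregate_tads(oe, seg, target_size=10)
        assert np.allclose(agg[np.isfinite(agg)], 1.0)

    def test_bilinear_resize_matches_scipy_oracle(self):
        rng = np.random.default_rng(12)
        mat = rng.random((10, 10))
        mat = (mat + mat.T) / 2
        target = 20
        got = _bilinear_resize(mat, target)
        interp = RegularGridInterpolator((np.arange(10), np.arange(10)), mat,
                                         method="linear")
        xs = np.linspace(0, 9, target)
        gx, gy = np.meshgrid(xs, xs, indexing="ij")
        expect = interp(np.stack([gx.ravel(), gy.ravel()], axis=1)).reshape(target, target)
        assert np.allclose(got, expect, atol=1e-9)

    def test_native_size_is_identity(self):
        rng = np.random.default_rng(13)
        mat = rng.random((8, 8))
        assert np.array_equal(_bilinear_resize(mat, 8), mat)

    def test_aggregate_symmetric(self, two_chrom_spec):
        truth = generate_genome(two_chrom_spec, 5, 10, seed=3, depth=1e7)
        bal = ice_balance(simulate_contacts(truth, two_chrom_spec, seed=8))
        oe = observed_over_expected(bal)
        ins = insulation_score(bal, 5)
        seg = segment_tads(call_boundaries(ins, 0.1), two_chrom_spec.bins(), 3, ins)
        agg = aggregate_tads(oe, seg, target_size=20)
        ok = np.isfinite(agg) & np.isfinite(agg.T)
        assert np.allclose(agg[ok], agg.T[ok], atol=1e-9)


class TestFusionDetection:
    def make_seg(self, intervals, n=30):
        spec = GenomeSpec(("chr1",), (n * 100_000,), 100_000)
        return TadSegmentation(spec.bins(), {"chr1": intervals})

    def test_simple_merge_detected(self):
        seg1 = self.make_seg([(0, 10), (10, 20), (20, 30)])
        seg2 = self.make_seg([(0, 20), (20, 30)])
        events = detect_fusions(seg1, seg2, tol=1)
        assert len(events) == 1
        ev = events[0]
        assert ev.lost_boundaries == [10]
        assert ev.fused_interval == (0, 20)
        assert ev.merged_from == [(0, 10), (10, 20)]
        assert ev.merged_bin_interval() == (1, 19)

    def test_identical_segmentations_no_events(self):
        seg = self.make_seg([(0, 10), (10, 20), (20, 30)])
        assert detect_fusions(seg, seg, tol=1) == []

    def test_shifted_boundary_within_tolerance_not_a_fusion(self):
        seg1 = self.make_seg([(0, 10), (10, 20), (20, 30)])
        seg2 = self.make_seg([(0, 11), (11, 20), (20, 30)])
        assert detect_fusions(seg1, seg2, tol=1) == []

    def test_planted_fusions_recovered_noise_free(self, two_chrom_spec):
        t1 = generate_genome(two_chrom_spec, 5, 10, seed=21,
                             compartment_delta=0.0, tad_delta=1.0, depth=1e7)
        t2 = derive_condition_two(t1, 3, 0, 0.3, seed=22)
        segs = []
        for t in (t1, t2):
            bal = ice_balance(expected_contacts(t, two_chrom_spec))
            ins = insulation_score(bal, 5)
            segs.append(segment_tads(call_boundaries(ins, 0.1),
                                     two_chrom_spec.bins(), 3, ins))
        events = detect_fusions(*segs, tol=1)
        detected = sorted((e.chrom, b) for e in events for b in e.lost_boundaries)
        assert detected == sorted(t2.fusion_events)
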