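"""Planted-truth generator: determinism, model shape, parameter recovery."""

import numpy as np
import pytest

from tadfuse import (GenomeSpec, ValidationError, derive_condition_two,
                     expected_contacts, fused_intervals, generate_genome,
                     orientation_track, simulate_contacts, simulate_deg_table)
from tadfuse.simulate import _bin_categories


class TestGenerateGenome:
    def test_two_tads_one_boundary_deterministic(self, tiny_spec):
        # 30 bins, 2 TADs -> exactly one interior boundary, same for same seed
        t1 = generate_genome(tiny_spec, 2, 5, seed=7)
        t2 = generate_genome(tiny_spec, 2, 5, seed=7)
        assert len(t1.tad_boundaries["chr1"]) == 1
        assert t1.tad_boundaries == t2.tad_boundaries
        assert np.array_equal(t1.compartment_labels, t2.compartment_labels)

    def test_seed_changes_positions_not_counts(self, tiny_spec):
        t7 = generate_genome(tiny_spec, 3, 5, seed=7)
        t8 = generate_genome(tiny_spec, 3, 5, seed=8)
        assert len(t7.tad_boundaries["chr1"]) == len(t8.tad_boundaries["chr1"]) == 2

    def test_boundaries_partition_with_min_size(self, two_chrom_spec):
        t = generate_genome(two_chrom_spec, 10, 10, seed=1, min_tad_bins=5)
        for chrom in two_chrom_spec.chrom_names:
            bs = t.tad_boundaries[chrom]
            edges = [0] + bs + [250]
            sizes = np.diff(edges)
            assert len(bs) == 9
            assert (sizes >= 5).all()

    def test_compartments_alternate_in_blocks(self, two_chrom_spec):
        t = generate_genome(two_chrom_spec, 2, 10, seed=3)
        lab = t.compartment_labels[:250]
        runs = [len(list(_grp)) for _, _grp in __import__("itertools").groupby(lab)]
        # interior runs are approximately the target length; edges truncated
        assert all(5 <= r <= 15 for r in runs[1:-1])
        assert set(lab) == {"A", "B"}

    def test_too_many_tads_rejected(self, tiny_spec):
        with pytest.raises(ValidationError):
            generate_genome(tiny_spec, 31, 5, seed=0, min_tad_bins=1)


class TestSimulateContacts:
    def test_seeded_determinism_symmetry_zero_diagonal(self, tiny_spec):
        t = generate_genome(tiny_spec, 2, 5, seed=7, depth=1e5)
        m1 = simulate_contacts(t, tiny_spec, seed=11)
        m2 = simulate_contacts(t, tiny_spec, seed=11)
        blk = m1.blocks["chr1"]
        assert np.array_equal(blk, m2.blocks["chr1"])
        assert np.array_equal(blk, blk.T)
        assert np.diagonal(blk).sum() == 0

    def test_total_count_conservation(self, two_chrom_spec):
        t = generate_genome(two_chrom_spec, 2, 10, seed=1, depth=1e6,
                            compartment_delta=0.3, tad_delta=0.5)
        e = expected_contacts(t, two_chrom_spec)
        assert e.total() == pytest.approx(1e6, rel=1e-9)
        m = simulate_contacts(t, two_chrom_spec, seed=2)
        assert m.total() == pytest.approx(1e6, rel=0.01)

    def test_power_law_slope_recovered_from_expectation(self):
        # pure power law: mean diagonal decay of the expectation is d^-alpha
        spec = GenomeSpec(("chr1",), (30_000_000,), 100_000)
        for alpha in (0.8, 1.2):
            t = generate_genome(spec, 1, 10, seed=0, decay_exponent=alpha,
                                compartment_delta=0.0, tad_delta=0.0, depth=1e7)
            lam = expected_contacts(t, spec).blocks["chr1"]
            d = np.arange(1, 300)
            means = np.array([np.diagonal(lam, k).mean() for k in d])
            slope = np.polyfit(np.log(d), np.log(means), 1)[0]
            assert slope == pytest.approx(-alpha, abs=1e-9)

    def test_within_tad_enrichment_at_equal_distance(self, tiny_spec):
        t = generate_genome(tiny_spec, 2, 5, seed=7, compartment_delta=0.0,
                            tad_delta=1.0, depth=1e6)
        lam = expected_contacts(t, tiny_spec).blocks["chr1"]
        b = t.tad_boundaries["chr1"][0]
        tid = (np.arange(30) >= b).astype(int)
        d = 3
        same = [lam[i, i + d] for i in range(27) if tid[i] == tid[i + d]]
        cross = [lam[i, i + d] for i in range(27) if tid[i] != tid[i + d]]
        assert np.mean(same) / np.mean(cross) == pytest.approx(2.0)

    def test_nonpositive_decay_rejected(self, tiny_spec):
        with pytest.raises(ValidationError):
            generate_genome(tiny_spec, 2, 5, seed=0, decay_exponent=0.0)


class TestDeriveConditionTwo:
    def test_single_fusion_removes_the_only_boundary(self, tiny_spec):
        t1 = generate_genome(tiny_spec, 2, 5, seed=7)
        t2 = derive_condition_two(t1, 1, 0, 0.0, seed=1)
        assert t2.tad_boundaries["chr1"] == []
        assert t2.fusion_events == [("chr1", t1.tad_boundaries["chr1"][0])]

    def test_identity_when_nothing_changes(self, tiny_spec):
        t1 = generate_genome(tiny_spec, 3, 5, seed=7)
        t2 = derive_condition_two(t1, 0, 0, 0.25, seed=1)
        assert t2.tad_boundaries == t1.tad_boundaries
        assert np.array_equal(t2.compartment_labels, t1.compartment_labels)
        assert t2.tad_delta == pytest.approx(t1.tad_delta / 0.75)

    def test_switch_directions_recorded_consistently(self, two_chrom_spec):
        t1 = generate_genome(two_chrom_spec, 2, 10, seed=9)
        t2 = derive_condition_two(t1, 0, 25, 0.0, seed=4)
        assert len(t2.switch_bins) == 25
        for i, direction in t2.switch_bins:
            before, after = t1.compartment_labels[i], t2.compartment_labels[i]
            assert (before, after) == (("A", "B") if direction == "AB" else ("B", "A"))

    def test_requesting_too_many_fusions_errors(self, tiny_spec):
        t1 = generate_genome(tiny_spec, 2, 5, seed=7)
        with pytest.raises(ValidationError):
            derive_condition_two(t1, 2, 0, 0.0, seed=1)


class TestDegTable:
    def test_empty_table(self, tiny_spec):
        t1 = generate_genome(tiny_spec, 2, 5, seed=7)
        t2 = derive_condition_two(t1, 1, 0, 0.0, seed=1)
        degs, truth = simulate_deg_table((t1, t2), tiny_spec, 0, 0.5, 1.0, seed=0)
        assert len(degs) == 0 and truth.gene == []

    def test_omega_below_one_rejected(self, tiny_spec):
        t1 = generate_genome(tiny_spec, 2, 5, seed=7)
        t2 = derive_condition_two(t1, 1, 0, 0.0, seed=1)
        with pytest.raises(ValidationError):
            simulate_deg_table((t1, t2), tiny_spec, 10, 0.5, 0.5, seed=0)

    def test_table_contract(self, two_chrom_spec):
        t1 = generate_genome(two_chrom_spec, 5, 10, seed=2)
        t2 = derive_condition_two(t1, 2, 0, 0.0, seed=3)
        degs, truth = simulate_deg_table((t1, t2), two_chrom_spec, 300, 0.4, 3.0, seed=5)
        assert len(degs) == 300
        assert (degs["padj"] < 0.05).all()
        up = degs["direction"] == "up"
        assert int(up.sum()) == 120
        assert (degs.loc[up, "log2fc"] > 0).all()
        assert (degs.loc[~up, "log2fc"] < 0).all()

    def test_neutral_omega_matches_binomial_share(self, two_chrom_spec):
        # omega = 1: up-genes land in merged-TAD bins at their bin share
        t1 = generate_genome(two_chrom_spec, 5, 10, seed=2)
        t2 = derive_condition_two(t1, 2, 0, 0.0, seed=3)
        share = np.mean(_bin_categories(t1, t2, two_chrom_spec, 1) == "merged_tad")
        hits = total = 0
        for r in range(50):
            degs, truth = simulate_deg_table((t1, t2), two_chrom_spec, 200, 1.0, 1.0,
                                             seed=100 + r)
            hits += sum(c == "merged_tad" for c in truth.category)
            total += len(truth.category)
        p_hat = hits / total
        se = np.sqrt(share * (1 - share) / total)
        assert abs(p_hat - share) < 3 * se


def test_orientation_track_sign_structure(two_chrom_spec):
    t = generate_genome(two_chrom_spec, 2, 10, seed=6)
    track = orientation_track(t, noise_sd=0.0, seed=0)
    assert np.array_equal(track > 0, t.compartment_labels == "A")
    noisy = orientation_track(t, noise_sd=0.3, seed=1)
    assert np.corrcoef(noisy, track)[0, 1] > 0.9


def test_fused_intervals_exclude_terminal_bins(two_chrom_spec):
    t1 = generate_genome(two_chrom_spec, 5, 10, seed=2)
    t2 = derive_condition_two(t1, 2, 0, 0.0, seed=3)
    for chrom, s, e in fused_intervals(t2, two_chrom_spec):
        lost = [b for c, b in t2.fusion_events if c == chrom and s <= b < e]
        assert lost, "each interval contains a lost boundary"
        retained = t2.tad_boundaries[chrom]
        # terminals excluded: interval endpoints sit 1 bin inside the fused TAD
        assert (s - 1 in retained) or (s - 1 == 0)
        assert (e + 1 in retained) or (e + 1 == 250)
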