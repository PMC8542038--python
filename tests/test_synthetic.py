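"""Generator tests: exact planted bookkeeping, the expected-contact model
against brute-force oracles, Poisson sampling statistics, and the marker and
gene emissions."""
import numpy as np
import pytest
from scipy import stats

import chromarch as ca
from chromarch.errors import DomainError, ParameterError
from chromarch.genome import GenomeSpec
from chromarch.synthetic import (ACTIVE_MARKS, INACTIVE_MARKS,
                                 ArchitectureTruth, generate_gene_table,
                                 generate_marker_tracks)


def toy_truth(labels, boundaries, loops, *, comp_factor=4, tad_factor=2,
              alpha=1.0, rho=1.4, tau=2.0, loop_boost=3.0, depth=100.0,
              weaken_mu=None, lost=None):
    """Hand-built single-chromosome truth for worked examples."""
    labels = np.asarray(labels, dtype=np.int8)
    n_fine = labels.size * comp_factor
    spec = GenomeSpec((("chr1", n_fine),), 25_000, 0)
    boundaries = np.asarray(boundaries, dtype=int)
    loops = np.asarray(loops, dtype=int).reshape(-1, 2)
    return ArchitectureTruth(
        spec=spec, comp_factor=comp_factor, tad_factor=tad_factor,
        alpha=alpha, rho=rho, tau=tau, loop_boost=loop_boost, depth=depth,
        labels={1: {"chr1": labels}, 2: {"chr1": labels.copy()}},
        boundaries={"chr1": boundaries},
        weaken_mu={"chr1": np.zeros(boundaries.size) if weaken_mu is None
                   else np.asarray(weaken_mu, float)},
        loops={"chr1": loops},
        lost={"chr1": np.zeros(loops.shape[0], bool) if lost is None
              else np.asarray(lost, bool)},
        flip_set={"chr1": np.empty(0, int)})


class TestPlanting:
    def test_zero_flip_fraction_leaves_labels_identical(self):
        spec = ca.synthetic_genome(2, 25, comp_factor=4, seed=3)
        t = ca.plant_architecture(spec, 0.0, 0.2, 0.2, seed=3,
                                  comp_factor=4, tad_factor=2, depth=100)
        for c in spec.names:
            np.testing.assert_array_equal(t.labels[1][c], t.labels[2][c])
            assert t.flip_set[c].size == 0

    def test_flip_count_exact_on_1000_compartment_bins(self):
        # 12.1% of 1000 compartment bins -> exactly 121 flipped
        spec = ca.synthetic_genome(5, 200, comp_factor=4, seed=5)
        t = ca.plant_architecture(spec, 0.121, 0.0, 0.0, seed=5,
                                  comp_factor=4, tad_factor=2, depth=100)
        n_flipped = sum(v.size for v in t.flip_set.values())
        assert n_flipped == 121
        diff = sum(int(np.sum(t.labels[1][c] != t.labels[2][c]))
                   for c in spec.names)
        assert diff == 121

    def test_weakened_set_is_half_of_boundaries(self):
        spec = ca.synthetic_genome(2, 40, comp_factor=4, seed=9)
        t = ca.plant_architecture(spec, 0.0, 0.5, 0.0, seed=9,
                                  comp_factor=4, tad_factor=2, depth=100)
        total = sum(t.boundaries[c].size for c in spec.names)
        weakened = sum(t.weakened_boundaries(c).size for c in spec.names)
        assert weakened == round(0.5 * total)
        for c in spec.names:  # weakened boundaries are real boundaries
            assert set(t.weakened_boundaries(c)) <= set(t.boundaries[c])

    def test_loop_loss_count_exact(self):
        spec = ca.synthetic_genome(2, 40, comp_factor=4, seed=1)
        t = ca.plant_architecture(spec, 0.0, 0.0, 0.3, seed=1,
                                  comp_factor=4, tad_factor=2, depth=100)
        total = sum(t.loops[c].shape[0] for c in spec.names)
        lost = sum(int(t.lost[c].sum()) for c in spec.names)
        assert lost == round(0.3 * total)
        for c in spec.names:
            assert t.loops_active(2, c).shape[0] == t.loops[c].shape[0] - int(t.lost[c].sum())

    @pytest.mark.parametrize("bad", [-0.1, 1.5])
    def test_fraction_outside_unit_interval_rejected(self, bad):
        spec = ca.synthetic_genome(1, 25, comp_factor=4, seed=0)
        with pytest.raises(ParameterError):
            ca.plant_architecture(spec, bad, 0.0, 0.0, seed=0,
                                  comp_factor=4, tad_factor=2)

    def test_boundaries_strictly_increasing_and_loops_separated(self, small_truth):
        for c in small_truth.spec.names:
            b = small_truth.boundaries[c]
            assert np.all(np.diff(b) > 0)
            px = small_truth.loops[c]
            assert np.all(px[:, 1] - px[:, 0] >= 2)


class TestExpectedContact:
    def test_unit_distance_no_multipliers(self):
        # adjacent bins in different compartments and different TADs
        t = toy_truth(labels=[1, -1, 1, -1, 1, -1], boundaries=[2], loops=[],
                      comp_factor=4, tad_factor=2, depth=100.0, alpha=1.0)
        # fine bins 3 and 4: compartments differ, TADs differ (boundary at
        # tad bin 2 = fine bin 4)
        assert t.expected_contact(3, 4) == pytest.approx(100.0)

    def test_multiplier_composition(self):
        # same-TAD, same-compartment adjacent pair: rho=1.5, tau=2 -> 3x
        t = toy_truth(labels=[1, 1, 1, 1, 1, 1], boundaries=[], loops=[],
                      rho=1.5, tau=2.0, depth=100.0)
        assert t.expected_contact(0, 1) == pytest.approx(300.0)

    def test_diagonal_uses_unit_distance(self):
        t = toy_truth(labels=[1, -1, 1, -1, 1, -1], boundaries=[], loops=[],
                      depth=50.0, rho=1.4, tau=2.0)
        # self-contact: same compartment and same TAD trivially
        assert t.expected_contact(0, 0) == pytest.approx(50.0 * 1.4 * 2.0)

    def test_cross_chromosome_pair_rejected(self, small_truth):
        n1 = small_truth.spec.n_bins("chr1")
        with pytest.raises(DomainError):
            small_truth.expected_contact(0, n1)  # chr1 x chr2

    def test_expected_matrix_matches_brute_force_rule(self):
        """Full 48-bin expected matrix equals an independently coded double
        loop applying the distance/compartment/TAD/loop rule."""
        labels = np.array([1, -1, -1, 1, 1, -1, 1, -1, 1, -1, 1, 1], dtype=np.int8)
        boundaries = np.array([5, 11, 17])
        loops = np.array([[3, 20], [10, 40]])
        mu = np.array([0.0, 0.5, 0.0])
        t = toy_truth(labels, boundaries, loops, weaken_mu=mu,
                      comp_factor=4, tad_factor=2, depth=10.0,
                      alpha=0.8, rho=1.3, tau=1.9, loop_boost=2.5)
        n = 48
        bf_fine = boundaries * 2
        for cond in (1, 2):
            expect = np.empty((n, n))
            for i in range(n):
                for j in range(n):
                    d = max(abs(i - j), 1)
                    e = 10.0 * d ** -0.8
                    if labels[i // 4] == labels[j // 4]:
                        e *= 1.3
                    di = int(np.searchsorted(bf_fine, i, side="right"))
                    dj = int(np.searchsorted(bf_fine, j, side="right"))
                    if di == dj:
                        e *= 1.9
                    elif abs(di - dj) == 1 and cond == 2 and mu[min(di, dj)] > 0:
                        e *= 1.9 ** mu[min(di, dj)]
                    lo, hi = min(i, j), max(i, j)
                    if i != j and any(a == lo and b == hi for a, b in loops):
                        e *= 2.5
                    expect[i, j] = e
            np.testing.assert_allclose(t.expected_matrix("chr1", cond), expect,
                                       rtol=1e-12)
            # scalar accessor agrees with the matrix path on sampled pixels
            for i, j in [(0, 0), (3, 20), (20, 3), (10, 40), (7, 30), (44, 47)]:
                assert t.expected_contact(i, j, cond) == pytest.approx(
                    expect[i, j], rel=1e-12)

    def test_expected_matrix_symmetric(self, small_truth):
        for cond in (1, 2):
            e = small_truth.expected_matrix("chr1", cond)
            np.testing.assert_allclose(e, e.T, rtol=0, atol=0)


class TestSampling:
    def test_seed_determinism(self, small_truth):
        a = ca.sample_contact_matrix(small_truth, 1, seed=5)
        b = ca.sample_contact_matrix(small_truth, 1, seed=5)
        for c in small_truth.spec.names:
            np.testing.assert_array_equal(a[c].counts, b[c].counts)
        d = ca.sample_contact_matrix(small_truth, 1, seed=6)
        assert any(not np.array_equal(a[c].counts, d[c].counts)
                   for c in small_truth.spec.names)

    def test_zero_depth_gives_empty_matrix(self):
        t = toy_truth(labels=[1, -1, 1, -1, 1, 1], boundaries=[4], loops=[],
                      depth=0.0)
        m = ca.sample_contact_matrix(t, 1, seed=0)["chr1"]
        assert m.counts.sum() == 0

    def test_monte_carlo_mean_matches_expectation(self):
        """Entrywise replicate mean agrees with the expected matrix: ~99.7%
        of entries inside 3 standard errors, and the total count obeys
        Poisson concentration."""
        labels = np.array([1, -1, 1, 1, -1, 1, -1, -1, 1, 1, -1, 1], np.int8)
        t = toy_truth(labels, boundaries=[6, 14], loops=[[5, 30]],
                      comp_factor=4, tad_factor=2, depth=1e4)
        e = t.expected_matrix("chr1", 1)
        n_rep = 200
        acc = np.zeros_like(e)
        for r in range(n_rep):
            acc += ca.sample_contact_matrix(t, 1, seed=1000 + r)["chr1"].counts
        mean = acc / n_rep
        se = np.sqrt(e / n_rep)
        frac_in = np.mean(np.abs(mean - e) <= 3 * se + 1e-9)
        assert frac_in > 0.985
        total = ca.sample_contact_matrix(t, 1, seed=1)["chr1"].counts
        iu = np.triu_indices_from(e)
        exp_total = e[iu].sum()
        obs_total = total[iu].sum()
        assert abs(obs_total - exp_total) <= 4 * np.sqrt(exp_total)


class TestMarkerTracks:
    def test_noiseless_limit_is_label_indicator(self, small_truth):
        tr = generate_marker_tracks(small_truth, np.inf, seed=1)
        lab = small_truth.labels_fine(1, "chr1")
        for mark in ACTIVE_MARKS:
            v = tr[mark]["chr1"].values
            assert np.all(v[lab == 1] > v[lab == -1].max())
            assert np.unique(v).size == 2
        for mark in INACTIVE_MARKS:
            v = tr[mark]["chr1"].values
            assert np.all(v[lab == -1] > v[lab == 1].max())

    def test_snr5_correlates_with_a_indicator(self):
        spec = ca.synthetic_genome(1, 125, comp_factor=4, seed=2)  # 500 bins
        t = ca.plant_architecture(spec, 0.0, 0.0, 0.0, seed=2,
                                  comp_factor=4, tad_factor=2, depth=100)
        tr = generate_marker_tracks(t, 5.0, seed=3)
        ind = (t.labels_fine(1, "chr1") == 1).astype(float)
        r = np.corrcoef(tr["H3K27ac"]["chr1"].values, ind)[0, 1]
        assert r > 0.8

    def test_all_b_chromosome_active_track_flat(self):
        t = toy_truth(labels=[-1] * 12, boundaries=[], loops=[], depth=100)
        tr = generate_marker_tracks(t, 5.0, seed=4)
        v = tr["H3K4me1"]["chr1"].values
        # two halves of an all-B chromosome are statistically identical
        res = stats.ttest_ind(v[:24], v[24:])
        assert res.pvalue > 0.01

    def test_condition2_tracks_follow_condition2_labels(self, small_truth):
        tr2 = generate_marker_tracks(small_truth, np.inf, seed=1, condition=2)
        lab2 = small_truth.labels_fine(2, "chr1")
        v = tr2["H3K27ac"]["chr1"].values
        assert np.all(v[lab2 == 1] > v[lab2 == -1].max())


class TestGeneTable:
    def test_effect_direction_orders_class_means(self):
        spec = ca.synthetic_genome(2, 60, comp_factor=4, seed=8)
        t = ca.plant_architecture(spec, 0.15, 0.0, 0.0, seed=8,
                                  comp_factor=4, tad_factor=2, depth=100)
        g = generate_gene_table(t, 2000, de_effect=4.0, seed=8)
        lfc = np.log2((g.fpkm_ko + 0.01) / (g.fpkm_wt + 0.01))
        m = {k: lfc[g.true_class == k].mean() for k in ("A->B", "stable", "B->A")}
        assert m["A->B"] < m["stable"] < m["B->A"]

    def test_near_null_effect_centers_all_classes(self):
        spec = ca.synthetic_genome(2, 60, comp_factor=4, seed=8)
        t = ca.plant_architecture(spec, 0.15, 0.0, 0.0, seed=8,
                                  comp_factor=4, tad_factor=2, depth=100)
        g = generate_gene_table(t, 2000, de_effect=1.0001, seed=8,
                                background_de_fraction=0.0)
        lfc = np.log2((g.fpkm_ko + 0.01) / (g.fpkm_wt + 0.01))
        for k in ("A->B", "stable", "B->A"):
            sub = lfc[g.true_class == k]
            if sub.size:
                assert abs(np.median(sub)) < 0.15
        assert (g.de_flag == "ns").all()

    def test_determinism_and_coordinates_within_genome(self, small_truth):
        a = generate_gene_table(small_truth, 300, 4.0, seed=2)
        b = generate_gene_table(small_truth, 300, 4.0, seed=2)
        assert a.equals(b)
        for row in a.itertuples():
            assert 0 <= row.start < row.end <= \
                small_truth.spec.n_bins(row.chrom) * small_truth.spec.bin_size


def test_truth_roundtrips_through_json(tmp_path, small_truth):
    p = tmp_path / "truth.json"
    small_truth.to_json(p)
    back = ArchitectureTruth.from_json(p)
    assert back.spec.chromosomes == small_truth.spec.chromosomes
    for c in small_truth.spec.names:
        np.testing.assert_array_equal(back.labels[2][c], small_truth.labels[2][c])
        np.testing.assert_array_equal(back.loops[c], small_truth.loops[c])
        np.testing.assert_allclose(back.weaken_mu[c], small_truth.weaken_mu[c])
    assert back.expected_contact(0, 1, 2) == small_truth.expected_contact(0, 1, 2)


class TestExpectedContactProperties:
    """Invariants of the generative model over random bin pairs."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @staticmethod
    def _truth():
        spec = ca.synthetic_genome(2, 25, comp_factor=4, seed=5)
        return ca.plant_architecture(spec, 0.1, 0.5, 0.3, seed=5,
                                     comp_factor=4, tad_factor=2, depth=500.0)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(i=st.integers(0, 199), j=st.integers(0, 199), cond=st.sampled_from([1, 2]))
    def test_symmetry_and_positivity(self, i, j, cond):
        t = self._truth()
        n1 = t.spec.n_bins("chr1")
        same_chrom = (i < n1) == (j < n1)
        if not same_chrom:
            with pytest.raises(DomainError):
                t.expected_contact(i, j, cond)
            return
        e = t.expected_contact(i, j, cond)
        assert e == t.expected_contact(j, i, cond)
        assert e > 0

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(i=st.integers(0, 90), d=st.integers(1, 8))
    def test_expected_decays_with_distance_within_structure(self, i, d):
        """At equal multiplier context, expectation decreases with distance:
        compare against a multiplier-free reference computed from the rule."""
        t = self._truth()
        e1 = t.expected_contact(i, i + d)
        # upper bound: all multipliers on; lower bound: none
        hi = t.depth * d ** -t.alpha * t.rho * t.tau * t.loop_boost
        lo = t.depth * d ** -t.alpha
        assert lo - 1e-9 <= e1 <= hi + 1e-9
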