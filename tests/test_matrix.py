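"""Matrix I/O, KR balancing against an independent Sinkhorn oracle, and
observed/expected normalization."""
import numpy as np
import pytest

import chromarch as ca
from chromarch.errors import (ConvergenceError, DegeneracyError, FormatError,
                              StateError)
from chromarch.genome import GenomeSpec
from chromarch.matrix import (BinTrack, ContactMatrix, distance_normalize,
                              kr_balance, read_triplets, write_triplets)

from conftest import random_symmetric


def sinkhorn_oracle(a, tol=1e-12, max_iter=100_000):
    """Independent row/column alternating scaling of the matrix itself to
    doubly-stochastic form (no shared code with kr_balance)."""
    b = a.astype(float).copy()
    for _ in range(max_iter):
        b = b / b.sum(axis=1, keepdims=True)
        b = b / b.sum(axis=0, keepdims=True)
        if max(abs(b.sum(axis=1) - 1).max(), abs(b.sum(axis=0) - 1).max()) < tol:
            break
    return b


class TestTripletIO:
    def test_single_entry_mirrored(self, tmp_path):
        g = GenomeSpec((("chr1", 20),), 1000)
        p = tmp_path / "m.txt"
        p.write_text("chr1 0 1 5\n")
        m = read_triplets(p, g)["chr1"]
        assert m.counts[0, 1] == m.counts[1, 0] == 5
        assert m.counts.sum() == 10

    def test_roundtrip(self, tmp_path, rng):
        g = GenomeSpec((("chr1", 20), ("chr2", 25)), 1000)
        mats = {}
        for c, n in g.chromosomes:
            a = np.round(10 * random_symmetric(n, rng))
            mats[c] = ContactMatrix(c, 1000, a)
        p = tmp_path / "m.txt"
        write_triplets(mats, p)
        back = read_triplets(p, g)
        for c, _ in g.chromosomes:
            np.testing.assert_array_equal(back[c].counts, mats[c].counts)

    def test_duplicate_entries_summed(self, tmp_path):
        g = GenomeSpec((("chr1", 20),), 1000)
        lines = ["chr1 2 5 3", "chr1 2 5 4", "chr1 5 5 2", "chr1 5 5 1"]
        (tmp_path / "m.txt").write_text("\n".join(lines) + "\n")
        # oracle: dictionary accumulation
        acc = {}
        for ln in lines:
            _, i, j, v = ln.split()
            acc[(int(i), int(j))] = acc.get((int(i), int(j)), 0) + int(v)
        m = read_triplets(tmp_path / "m.txt", g)["chr1"]
        assert m.counts[2, 5] == m.counts[5, 2] == acc[(2, 5)]
        assert m.counts[5, 5] == acc[(5, 5)]

    def test_out_of_range_index_names_line(self, tmp_path):
        g = GenomeSpec((("chr1", 20),), 1000)
        (tmp_path / "m.txt").write_text("chr1 0 1 5\nchr1 3 25 1\n")
        with pytest.raises(FormatError, match=":2"):
            read_triplets(tmp_path / "m.txt", g)

    def test_unknown_chromosome_rejected(self, tmp_path):
        g = GenomeSpec((("chr1", 20),), 1000)
        (tmp_path / "m.txt").write_text("chrX 0 1 5\n")
        with pytest.raises(FormatError, match="chrX"):
            read_triplets(tmp_path / "m.txt", g)


class TestKRBalance:
    def test_identity_pattern_is_fixed_point(self):
        m = ContactMatrix("c", 1000, np.eye(12))
        kr = kr_balance(m, mask_percentile=0)
        v = kr.balancing
        np.testing.assert_allclose(v, v[0], rtol=1e-9)
        np.testing.assert_allclose(kr.counts.sum(axis=1),
                                   kr.counts.sum(axis=1).mean(), rtol=1e-8)

    def test_matches_independent_sinkhorn_oracle(self, rng):
        a = random_symmetric(6, rng)
        kr = kr_balance(ContactMatrix("c", 1000, a), tol=1e-12,
                        max_iter=100_000, mask_percentile=0)
        target = kr.counts.sum(axis=1).mean()
        oracle = sinkhorn_oracle(a) * target
        np.testing.assert_allclose(kr.counts, oracle, rtol=1e-6)
        rs = kr.counts.sum(axis=1)
        assert np.max(np.abs(rs - target)) / target < 1e-10

    def test_zero_row_masked_rest_balanced(self, rng):
        a = random_symmetric(6, rng)
        a[3, :] = 0
        a[:, 3] = 0
        kr = kr_balance(ContactMatrix("c", 1000, a), mask_percentile=0)
        assert not np.isfinite(kr.balancing[3])
        assert np.all(kr.counts[3, :] == 0) and np.all(kr.counts[:, 3] == 0)
        keep = np.ones(6, bool)
        keep[3] = False
        rs = kr.counts[keep].sum(axis=1)
        np.testing.assert_allclose(rs, rs.mean(), rtol=1e-7)

    def test_percentile_masking_drops_weak_rows(self, rng):
        a = random_symmetric(50, rng) + 1
        a[7, :] *= 1e-4
        a[:, 7] *= 1e-4
        kr = kr_balance(ContactMatrix("c", 1000, a), mask_percentile=5.0)
        assert not np.isfinite(kr.balancing[7])

    def test_scale_equivariance(self, rng):
        a = random_symmetric(8, rng)
        k1 = kr_balance(ContactMatrix("c", 1000, a), mask_percentile=0)
        k2 = kr_balance(ContactMatrix("c", 1000, 7.5 * a), mask_percentile=0)
        np.testing.assert_allclose(k2.counts, 7.5 * k1.counts, rtol=1e-6)

    def test_preserves_symmetry_and_zero_pattern(self, rng):
        a = np.round(random_symmetric(10, rng) * 5)
        kr = kr_balance(ContactMatrix("c", 1000, a), mask_percentile=0)
        np.testing.assert_allclose(kr.counts, kr.counts.T)
        keep = np.isfinite(kr.balancing)
        sub = np.ix_(keep, keep)
        assert np.array_equal(kr.counts[sub] == 0, a[sub] == 0)

    def test_nonconvergence_reports_residual(self, rng):
        a = random_symmetric(6, rng)
        with pytest.raises(ConvergenceError) as exc:
            kr_balance(ContactMatrix("c", 1000, a), tol=1e-14, max_iter=2)
        assert exc.value.residual is not None and exc.value.residual > 0

    def test_too_few_unmasked_bins(self):
        a = np.zeros((5, 5))
        a[0, 0] = 1
        with pytest.raises(DegeneracyError):
            kr_balance(ContactMatrix("c", 1000, a))


class TestDistanceNormalize:
    def _kr(self, counts):
        return kr_balance(ContactMatrix("c", 1000, counts), mask_percentile=0)

    def test_pure_decay_becomes_one(self):
        n = 12
        idx = np.arange(n)
        a = 1.0 / (np.abs(idx[:, None] - idx[None, :]) + 1.0)
        m = ContactMatrix("c", 1000, a, stage="kr", balancing=np.ones(n))
        oe = distance_normalize(m)
        for k in range(1, n):
            np.testing.assert_allclose(np.diagonal(oe.counts, k), 1.0, rtol=1e-12)

    def test_hand_computed_offset_means(self):
        a = np.array([[4.0, 2, 1, 0],
                      [2, 4, 3, 1],
                      [1, 3, 4, 2],
                      [0, 1, 2, 4]])
        m = ContactMatrix("c", 1000, a, stage="kr", balancing=np.ones(4))
        oe = distance_normalize(m)
        expect = a.copy()
        for k in range(4):
            d = np.diagonal(a, k)
            mean = d.mean()
            for i in range(4 - k):
                expect[i, i + k] = expect[i + k, i] = (a[i, i + k] / mean
                                                       if mean else 0.0)
        np.testing.assert_allclose(oe.counts, expect, rtol=1e-12)

    def test_all_zero_offset_yields_zero(self):
        a = np.ones((5, 5))
        k = 2
        for i in range(5 - k):
            a[i, i + k] = a[i + k, i] = 0.0
        m = ContactMatrix("c", 1000, a, stage="kr", balancing=np.ones(5))
        oe = distance_normalize(m)
        assert np.all(np.diagonal(oe.counts, k) == 0)

    def test_raw_input_rejected(self, rng):
        with pytest.raises(StateError):
            distance_normalize(ContactMatrix("c", 1000, random_symmetric(5, rng)))

    def test_result_symmetric(self, rng):
        oe = distance_normalize(self._kr(random_symmetric(15, rng)))
        np.testing.assert_allclose(oe.counts, oe.counts.T)


class TestCoarsen:
    def test_block_sum(self, rng):
        a = random_symmetric(12, rng)
        c = ContactMatrix("c", 1000, a).coarsen(3)
        assert c.n_bins == 4 and c.bin_size == 3000
        assert c.counts[0, 1] == pytest.approx(a[0:3, 3:6].sum())

    def test_track_coarsen_means(self):
        t = BinTrack("c", 1000, np.array([1.0, 3.0, 2.0, 6.0]), "m")
        c = t.coarsen(2)
        np.testing.assert_allclose(c.values, [2.0, 4.0])


def test_oe_is_flat_under_featureless_model():
    """With rho=tau=loop_boost=1 the generative model is pure distance decay,
    so every O/E offset mean is ~1 (within Monte-Carlo error)."""
    spec = ca.synthetic_genome(1, 25, comp_factor=4, seed=1)
    t = ca.plant_architecture(spec, 0.0, 0.0, 0.0, seed=1, comp_factor=4,
                              tad_factor=2, rho=1.0, tau=1.0, loop_boost=1.0,
                              depth=5e4)
    m = ca.sample_contact_matrix(t, 1, seed=2)["chr1"]
    oe = distance_normalize(kr_balance(m, mask_percentile=0))
    vals = []
    for k in range(1, 40):
        vals.append(np.diagonal(oe.counts, k).mean())
    np.testing.assert_allclose(vals, 1.0, atol=0.05)
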