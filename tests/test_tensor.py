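"""Mode-wise tensor algebra: unfoldings, mode products, norms, CP, HOSVD."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from csecsi import (
    Tensor3,
    CPModel,
    coupled_hosvd,
    cp_reconstruct,
    fold,
    ho_norm,
    mode_product,
    truncated_hosvd,
    unfold,
)
from conftest import coupled_pair, cp_tensor, random_factors


def brute_force_unfold(arr, mode):
    """Element-by-element index-mapping oracle for the unfolding convention."""
    dims = arr.shape
    rest = [d for i, d in enumerate(dims) if i != mode - 1]
    out = np.zeros((dims[mode - 1], rest[0] * rest[1]), dtype=arr.dtype)
    for i in range(dims[0]):
        for j in range(dims[1]):
            for k in range(dims[2]):
                idx = (i, j, k)
                row = idx[mode - 1]
                others = [idx[n] for n in range(3) if n != mode - 1]
                col = others[0] * rest[1] + others[1]
                out[row, col] = arr[i, j, k]
    return out


class TestUnfold:
    def test_degenerate_singleton(self):
        t = Tensor3(np.array([[[5.0]]]))
        for mode in (1, 2, 3):
            assert unfold(t, mode).shape == (1, 1)
            assert unfold(t, mode)[0, 0] == 5.0

    @pytest.mark.parametrize("mode", [1, 2, 3])
    def test_round_trip(self, rng, mode):
        t = Tensor3(rng.standard_normal((3, 4, 5)))
        back = fold(unfold(t, mode), mode, t.dims)
        np.testing.assert_array_equal(back.data, t.data)

    @pytest.mark.parametrize("mode", [1, 2, 3])
    def test_matches_index_mapping_oracle(self, mode):
        arr = np.arange(8.0).reshape(2, 2, 2)
        np.testing.assert_array_equal(unfold(arr, mode), brute_force_unfold(arr, mode))

    def test_invalid_mode(self):
        with pytest.raises(ValueError):
            unfold(np.zeros((2, 2, 2)), 4)


class TestModeProduct:
    def test_identity(self, rng):
        t = Tensor3(rng.standard_normal((3, 4, 5)))
        for mode, d in zip((1, 2, 3), t.dims):
            np.testing.assert_allclose(mode_product(t, np.eye(d), mode).data, t.data)

    def test_unitary_invariance_of_norm(self, rng):
        t = Tensor3(rng.standard_normal((4, 4, 4)))
        q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        assert ho_norm(mode_product(t, q, 2)) == pytest.approx(ho_norm(t))

    def test_matches_triple_loop_oracle(self, rng):
        t = rng.standard_normal((2, 2, 2))
        m = rng.standard_normal((3, 2))
        got = mode_product(t, m, 2).data
        want = np.zeros((2, 3, 2))
        for i in range(2):
            for j in range(3):
                for k in range(2):
                    want[i, j, k] = sum(m[j, l] * t[i, l, k] for l in range(2))
        np.testing.assert_allclose(got, want)

    def test_cross_mode_commutativity(self, rng):
        t = Tensor3(rng.standard_normal((3, 4, 5)))
        a = rng.standard_normal((2, 3))
        b = rng.standard_normal((6, 4))
        left = mode_product(mode_product(t, a, 1), b, 2)
        right = mode_product(mode_product(t, b, 2), a, 1)
        np.testing.assert_allclose(left.data, right.data)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            mode_product(np.zeros((2, 2, 2)), np.zeros((2, 3)), 1)


class TestHoNorm:
    def test_zero_and_three_four_five(self):
        assert ho_norm(np.zeros((2, 3, 4))) == 0.0
        arr = np.zeros((2, 2, 2))
        arr[0, 0, 0], arr[1, 1, 1] = 3.0, 4.0
        assert ho_norm(arr) == pytest.approx(5.0)

    def test_equals_frobenius_of_every_unfolding(self, rng):
        t = rng.standard_normal((3, 4, 5)) + 1j * rng.standard_normal((3, 4, 5))
        for mode in (1, 2, 3):
            assert ho_norm(t) == pytest.approx(np.linalg.norm(unfold(t, mode)))


class TestCPReconstruct:
    def test_rank_one_unit_vectors(self):
        e = np.zeros((3, 1))
        e[0] = 1.0
        model = CPModel([e, e.copy(), e.copy()], np.array([2.0]), 1)
        data = cp_reconstruct(model).data
        assert data[0, 0, 0] == pytest.approx(2.0)
        assert np.sum(np.abs(data)) == pytest.approx(2.0)

    def test_permutation_invariance(self, rng):
        f = random_factors(1, (3, 4, 5), 3)
        amp = np.array([1.0, 2.0, 3.0])
        m1 = CPModel(f, amp, 3)
        perm = [2, 0, 1]
        m2 = CPModel([fi[:, perm] for fi in f], amp[perm], 3)
        np.testing.assert_allclose(cp_reconstruct(m1).data, cp_reconstruct(m2).data)

    def test_matches_identity_tensor_contraction_oracle(self, rng):
        f1, f2, f3 = random_factors(2, (2, 3, 2), 2)
        amp = np.array([1.5, 0.5])
        got = cp_reconstruct(CPModel([f1, f2, f3], amp, 2)).data
        want = np.zeros((2, 3, 2))
        for i in range(2):
            for j in range(3):
                for k in range(2):
                    for r in range(2):
                        want[i, j, k] += amp[r] * f1[i, r] * f2[j, r] * f3[k, r]
        np.testing.assert_allclose(got, want)


class TestTruncatedHosvd:
    def test_exact_rank_lossless(self):
        t = cp_tensor(random_factors(3, (6, 7, 5), 2))
        core, us = truncated_hosvd(t, 2)
        rec = core
        for n, u in enumerate(us, start=1):
            rec = mode_product(rec, u, n)
        assert ho_norm(Tensor3(rec.data - t.data)) / ho_norm(t) < 1e-8

    def test_loadings_orthonormal(self, rng):
        t = Tensor3(rng.standard_normal((5, 6, 7)))
        _, us = truncated_hosvd(t, 3)
        for u in us:
            np.testing.assert_allclose(u.conj().T @ u, np.eye(3), atol=1e-10)

    def test_singleton_mode_matches_matrix_svd(self, rng):
        mat = rng.standard_normal((6, 8))
        t = Tensor3(mat[:, :, None])  # third mode singleton
        _, us = truncated_hosvd(t, 1)
        u, _, _ = np.linalg.svd(mat, full_matrices=False)
        # leading left singular vector up to sign
        assert abs(abs(np.dot(us[0][:, 0], u[:, 0])) - 1) < 1e-10

    def test_full_rank_machine_precision(self, rng):
        t = Tensor3(rng.standard_normal((4, 4, 4)))
        core, us = truncated_hosvd(t, 4)
        rec = core
        for n, u in enumerate(us, start=1):
            rec = mode_product(rec, u, n)
        np.testing.assert_allclose(rec.data, t.data, atol=1e-12)

    def test_rank_exceeds_dimension(self):
        with pytest.raises(ValueError):
            truncated_hosvd(np.zeros((2, 5, 5)), 3)


class TestCoupledHosvd:
    def test_identical_inputs_span_same_subspace(self, rng):
        t = Tensor3(rng.standard_normal((6, 5, 4)))
        sub = coupled_hosvd(t, t, 3)
        _, us = truncated_hosvd(t, 3)
        # principal angles between the joint and the single-tensor mode-1 basis
        s = np.linalg.svd(sub.common_loading.conj().T @ us[0], compute_uv=False)
        np.testing.assert_allclose(s, 1.0, atol=1e-10)

    def test_noiseless_pair_lossless(self):
        _, _, t1, t2 = coupled_pair(5, rank=3)
        sub = coupled_hosvd(t1, t2, 3)
        for i, t in enumerate((t1, t2)):
            rec = sub.cores[i]
            for n, u in enumerate((sub.common_loading, sub.loadings_2[i],
                                   sub.loadings_3[i]), start=1):
                rec = mode_product(rec, u, n)
            assert ho_norm(Tensor3(rec.data - t.data)) ** 2 / ho_norm(t) ** 2 < 1e-8

    def test_common_loading_contains_true_factor_space(self):
        (f1, _, _), _, t1, t2 = coupled_pair(6, rank=3)
        sub = coupled_hosvd(t1, t2, 3)
        q, _ = np.linalg.qr(f1)
        s = np.linalg.svd(sub.common_loading.conj().T @ q, compute_uv=False)
        assert np.all(np.arccos(np.clip(s, -1, 1)) < 1e-6)

    def test_first_mode_mismatch(self, rng):
        with pytest.raises(ValueError):
            coupled_hosvd(np.zeros((3, 4, 5)), np.zeros((4, 4, 5)), 2)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000), st.sampled_from([1, 2, 3]))
def test_fold_unfold_property(seed, mode):
    rng = np.random.default_rng(seed)
    dims = tuple(rng.integers(1, 6, size=3))
    t = Tensor3(rng.standard_normal(dims))
    np.testing.assert_array_equal(fold(unfold(t, mode), mode, dims).data, t.data)
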