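"""Candidate estimation, selection, reliability and the top-level decompositions."""

import itertools

import numpy as np
import pytest

from csecsi import (
    Tensor3,
    add_noise_at_snr,
    candidate_estimates,
    coupled_hosvd,
    cp_reconstruct,
    csecsi,
    ho_norm,
    match_permutation,
    rank_sweep,
    reconstruction_error,
    reliability,
    secsi,
    tsfe,
    CPModel,
)
from csecsi.model import CoupledCP
from conftest import coupled_pair, cp_tensor, random_factors


class TestReconstructionError:
    def test_exact_model_zero(self):
        f = random_factors(0, (4, 5, 6), 2)
        t = cp_tensor(f)
        model = CPModel.from_raw_factors(*f)
        assert reconstruction_error(model, t) < 1e-12

    def test_zero_model_gives_one(self, rng):
        t = Tensor3(rng.standard_normal((3, 3, 3)))
        model = CPModel([np.zeros((3, 1))] * 3, np.zeros(1), 1)
        assert reconstruction_error(model, t) == pytest.approx(1.0)

    def test_noise_scaling_identity(self):
        """With noise scaled to SNR s, ||Xhat - X||^2 / ||X0||^2 = 10^(-s/10) exactly."""
        f = random_factors(1, (5, 6, 7), 2)
        t0 = cp_tensor(f)
        snr = 20.0
        noisy = add_noise_at_snr(t0, snr, seed=9)
        model = CPModel.from_raw_factors(*f)
        xhat = cp_reconstruct(model).data
        ratio = ho_norm(xhat - noisy.data) ** 2 / ho_norm(t0) ** 2
        assert ratio == pytest.approx(10 ** (-snr / 10), rel=1e-10)
        # e_rec itself (noisy denominator) is close but not exactly equal
        assert reconstruction_error(model, noisy) == pytest.approx(0.01, rel=0.05)

    def test_zero_tensor_rejected(self):
        model = CPModel([np.ones((2, 1))] * 3, np.ones(1), 1)
        with pytest.raises(ValueError):
            reconstruction_error(model, np.zeros((2, 2, 2)))


class TestMatchPermutation:
    def test_identity_and_swap(self, rng):
        a = rng.standard_normal((6, 3))
        assert match_permutation(a, a).mapping.tolist() == [0, 1, 2]
        swapped = a[:, [1, 0, 2]]
        # column j of `swapped` aligned back to a's order
        assert match_permutation(a, swapped).mapping.tolist() == [1, 0, 2]

    def test_matches_exhaustive_search(self, rng):
        a = rng.standard_normal((5, 3))
        b = rng.standard_normal((5, 3))
        got = match_permutation(a, b).mapping
        an = a / np.linalg.norm(a, axis=0)
        bn = b / np.linalg.norm(b, axis=0)
        best, best_val = None, -np.inf
        for perm in itertools.permutations(range(3)):
            val = sum(abs(an[:, i] @ bn[:, perm[i]]) for i in range(3))
            if val > best_val:
                best, best_val = perm, val
        assert got.tolist() == list(best)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            match_permutation(np.zeros((3, 2)), np.zeros((3, 3)))


class TestReliability:
    def test_identical_matrices(self, rng):
        a = rng.standard_normal((6, 3))
        assert reliability(a, a) == pytest.approx(100.0)

    def test_orthogonal_columns_give_zero(self):
        a = np.eye(4)[:, :2]
        b = np.eye(4)[:, 2:]
        assert reliability(a, b) == pytest.approx(0.0)

    def test_invariant_to_permutation_and_unit_scaling(self, rng):
        a = (rng.standard_normal((5, 3)) + 1j * rng.standard_normal((5, 3)))
        perm = [2, 0, 1]
        d = np.exp(1j * rng.uniform(0, 2 * np.pi, 3))
        b = a[:, perm] * d
        assert reliability(a, b) == pytest.approx(100.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            reliability(np.zeros((3, 2)), np.ones((3, 2)))


class TestCandidateEstimates:
    def test_rank_one_single_direct_estimate(self):
        _, _, t1, t2 = coupled_pair(3, rank=1)
        sub = coupled_hosvd(t1, t2, 1)
        cs = candidate_estimates(sub, t1, t2)
        assert len(cs) == 1
        assert cs.candidates[0].coupled

    @pytest.mark.parametrize("rank", [2, 3])
    def test_noiseless_all_eight_exact(self, rank):
        _, _, t1, t2 = coupled_pair(4, rank=rank)
        sub = coupled_hosvd(t1, t2, rank)
        cs = candidate_estimates(sub, t1, t2)
        assert len(cs) == 8
        for c in cs:
            assert c.valid
            assert max(c.e_rec) < 1e-8

    def test_coupling_flags(self):
        _, _, t1, t2 = coupled_pair(5, rank=2)
        sub = coupled_hosvd(t1, t2, 2)
        cs = candidate_estimates(sub, t1, t2)
        flags = {c.label: c.coupled for c in cs}
        assert all(flags[l] for l in ("I", "II", "III", "IV"))
        assert not any(flags[l] for l in ("V", "VI", "VII", "VIII"))

    def test_coupled_candidates_share_common_factor(self):
        _, _, t1, t2 = coupled_pair(6, rank=3)
        sub = coupled_hosvd(t1, t2, 3)
        cs = candidate_estimates(sub, t1, t2)
        for c in cs:
            if c.coupled:
                np.testing.assert_array_equal(c.models[0].factors[0],
                                              c.models[1].factors[0])


class TestSelection:
    def test_per_tensor_argmin(self):
        _, _, t1, t2 = coupled_pair(7, rank=2)
        res = csecsi(t1, t2, 2)
        table = res.candidate_table
        for i in range(2):
            best = min(c.e_rec[i] for c in table if c.valid)
            assert res.residuals[i] <= best + 1e-12

    def test_duplicate_input_full_reliability(self, rng):
        t = Tensor3(rng.standard_normal((6, 5, 4)))
        res = csecsi(t, t, 2)
        assert res.reliability == pytest.approx(100.0)

    def test_noiseless_selected_exact(self):
        _, _, t1, t2 = coupled_pair(8, rank=3)
        res = csecsi(t1, t2, 3)
        assert max(res.residuals) < 1e-8


class TestCsecsi:
    @pytest.mark.parametrize("rank", [2, 3, 4])
    def test_exact_recovery_tsfe(self, rank):
        truth1, truth2, t1, t2 = coupled_pair(9, rank=rank)
        res = csecsi(t1, t2, rank)
        assert tsfe(res.selected[0].factors, truth1) < 1e-8
        assert tsfe(res.selected[1].factors, truth2) < 1e-8

    def test_reliability_decreases_with_noise(self):
        """At fixed true rank, REL falls as the SNR drops (seeded averages)."""
        rels = {}
        for snr in (30.0, 0.0):
            vals = []
            for seed in range(8):
                _, _, t1, t2 = coupled_pair(100 + seed, rank=3)
                n1 = add_noise_at_snr(t1, snr, seed)
                n2 = add_noise_at_snr(t2, snr, seed + 1000)
                vals.append(csecsi(n1, n2, 3).reliability)
            rels[snr] = np.mean(vals)
        assert rels[30.0] > rels[0.0]

    def test_complex_exact_recovery(self):
        truth1, truth2, t1, t2 = coupled_pair(10, rank=3, complex_field=True)
        res = csecsi(t1, t2, 3)
        assert max(res.residuals) < 1e-8
        assert tsfe(res.selected[0].factors, truth1) < 1e-8


class TestSecsi:
    def test_noiseless_rank2(self):
        f = random_factors(11, (6, 7, 5), 2)
        t = cp_tensor(f)
        model = secsi(t, 2)
        assert reconstruction_error(model, t) < 1e-8

    def test_rank_one_direct(self):
        f = random_factors(12, (5, 4, 6), 1)
        t = cp_tensor(f)
        model = secsi(t, 1)
        assert reconstruction_error(model, t) < 1e-8

    def test_consistent_with_csecsi_on_duplicate_input(self):
        f = random_factors(13, (6, 6, 6), 2)
        t = cp_tensor(f)
        m_single = secsi(t, 2)
        res = csecsi(t, t, 2)
        assert tsfe(m_single.factors, res.selected[0].factors) < 1e-8


class TestRankSweep:
    def test_rank_one_always_hundred_and_flag_excludes_it(self):
        _, _, t1, t2 = coupled_pair(14, rank=2)
        n1 = add_noise_at_snr(t1, 10.0, 1)
        n2 = add_noise_at_snr(t2, 10.0, 2)
        df = rank_sweep(n1, n2, [1, 2, 3])
        assert df.loc[df["rank"] == 1, "reliability"].iloc[0] == pytest.approx(100.0)
        assert not df.loc[df["rank"] == 1, "best"].iloc[0]

    def test_noiseless_residual_decreases_with_rank(self):
        _, _, t1, t2 = coupled_pair(15, rank=4)
        df = rank_sweep(t1, t2, [2, 3, 4])
        assert df["e_rec_1"].is_monotonic_decreasing
        assert df["e_rec_2"].is_monotonic_decreasing

    def test_empty_ranks_rejected(self):
        _, _, t1, t2 = coupled_pair(16, rank=2)
        with pytest.raises(ValueError):
            rank_sweep(t1, t2, [])


class TestModelInterface:
    def test_fit_summary_and_accessors(self):
        truth1, _, t1, t2 = coupled_pair(17, rank=2)
        res = CoupledCP(t1, t2).fit(rank=2)
        assert res.rank == 2
        assert res.reliability == pytest.approx(100.0)
        assert tsfe(res.factors(1), truth1) < 1e-8
        assert ho_norm(res.resid(1)) / ho_norm(t1) < 1e-6
        text = res.summary()
        assert "reliability" in text and "Candidate table" in text

    def test_mode_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            CoupledCP(rng.standard_normal((3, 4, 5)), rng.standard_normal((4, 4, 5)))
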