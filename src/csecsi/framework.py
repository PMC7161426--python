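"""The coupled semi-algebraic CP framework (C-SECSI) and its single-tensor variant.

Pipeline: joint truncated HOSVD -> simultaneous matrix diagonalizations ->
eight candidate factor-matrix estimates (four coupled, four uncoupled) ->
per-tensor selection by minimum reconstruction error -> reliability of the two
selected common-factor estimates.  The reliability doubles as a rank-control
statistic: it peaks when the assumed rank matches the true (shared) rank.

Everything here is deterministic; all randomness lives in data generation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .smd import IllConditionedError, build_smds, build_smds_single, joint_diagonalize
from .tensor import (
    CPModel,
    CoupledSubspace,
    Tensor3,
    coupled_hosvd,
    cp_reconstruct,
    ho_norm,
    khatri_rao,
    truncated_hosvd,
    unfold,
    _data,
    _normalize_columns,
)

__all__ = [
    "Candidate",
    "CandidateSet",
    "CoupledResult",
    "PermutationMap",
    "DecompositionOptions",
    "reconstruction_error",
    "candidate_estimates",
    "select_final",
    "match_permutation",
    "reliability",
    "csecsi",
    "secsi",
    "rank_sweep",
]

_TIE_TOL = 1e-12


@dataclass
class DecompositionOptions:
    jd_tol: float = 1e-10
    jd_max_sweeps: int = 200


@dataclass
class Candidate:
    label: str  # I..VIII (I..VI for the single-tensor variant)
    coupled: bool
    models: list  # CPModel per tensor
    e_rec: tuple  # per-tensor reconstruction errors
    provenance: dict = field(default_factory=dict)
    valid: bool = True
    note: str = ""


@dataclass
class CandidateSet:
    candidates: list

    def __post_init__(self):
        labels = [c.label for c in self.candidates]
        if len(set(labels)) != len(labels):
            raise ValueError("candidate labels must be unique")

    def __iter__(self):
        return iter(self.candidates)

    def __len__(self):
        return len(self.candidates)

    def table(self) -> pd.DataFrame:
        rows = []
        for c in self.candidates:
            row = {"label": c.label, "coupled": c.coupled, "valid": c.valid}
            for i, e in enumerate(c.e_rec, start=1):
                row[f"e_rec_{i}"] = e
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class PermutationMap:
    mapping: np.ndarray  # column j of the second matrix aligns to column mapping.index... see match_permutation

    def __post_init__(self):
        m = np.asarray(self.mapping, dtype=int)
        if sorted(m.tolist()) != list(range(len(m))):
            raise ValueError("mapping must be a permutation")
        self.mapping = m

    def matrix(self) -> np.ndarray:
        r = len(self.mapping)
        p = np.zeros((r, r))
        p[self.mapping, np.arange(r)] = 1.0
        return p


@dataclass
class CoupledResult:
    selected: list  # CPModel per tensor
    reliability: float  # percent in [0, 100]
    residuals: tuple  # per-tensor e_rec of the selected models
    candidate_table: CandidateSet
    assumed_rank: int
    selected_labels: tuple = ()

    def summary(self) -> pd.DataFrame:
        return self.candidate_table.table()


# ---------------------------------------------------------------------------
# error / similarity measures


def reconstruction_error(model: CPModel, t) -> float:
    """Squared relative higher-order-norm error ||X_hat - X||_H^2 / ||X||_H^2."""
    x = _data(t)
    denom = ho_norm(x) ** 2
    if denom == 0:
        raise ValueError("reconstruction error undefined for a zero-norm tensor")
    xhat = cp_reconstruct(model).data
    return float(ho_norm(xhat - x) ** 2 / denom)


def match_permutation(a: np.ndarray, b: np.ndarray) -> PermutationMap:
    """Permutation p maximizing sum_r |<a_r / ||a_r||, b_{p[r]} / ||b_{p[r]}||>|.

    ``b[:, p.mapping]`` is the column order of ``b`` aligned to ``a``.
    """
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("matrices must have the same shape")
    an, _ = _normalize_columns(a, fix_phase=False)
    bn, _ = _normalize_columns(b, fix_phase=False)
    sim = np.abs(an.conj().T @ bn)  # sim[r, s] = |<a_r, b_s>|
    row, col = linear_sum_assignment(-sim)
    mapping = np.empty(a.shape[1], dtype=int)
    mapping[row] = col
    return PermutationMap(mapping)


def reliability(f1_hat_1: np.ndarray, f1_hat_2: np.ndarray) -> float:
    """Percent similarity of two common-factor estimates.

    Columns of both matrices are unit-normalized, the permutation ambiguity is
    resolved by matching, the remaining per-column unit-modulus scaling
    ambiguity by the optimal phase per matched pair, and
    REL = (1 - 1/2 ||F2 P - F1||_F^2 / ||F1||_F^2) * 100, clipped to [0, 100].
    (With unit columns and optimal phases this equals the mean absolute
    correlation of matched columns, in percent.)
    """
    a = np.asarray(f1_hat_1)
    b = np.asarray(f1_hat_2)
    if a.shape != b.shape:
        raise ValueError("common-factor estimates must have the same shape")
    if np.linalg.norm(a) == 0:
        raise ValueError("zero-norm reference matrix")
    an, _ = _normalize_columns(a, fix_phase=False)
    bn, _ = _normalize_columns(b, fix_phase=False)
    p = match_permutation(an, bn)
    bp = bn[:, p.mapping]
    inner = np.einsum("ir,ir->r", an.conj(), bp)
    phase = np.where(np.abs(inner) == 0, 1.0,
                     (inner / np.where(np.abs(inner) == 0, 1, np.abs(inner))).conj())
    diff = bp * phase - an
    rel = (1.0 - 0.5 * np.linalg.norm(diff) ** 2 / np.linalg.norm(an) ** 2) * 100.0
    return float(np.clip(rel, 0.0, 100.0))


# ---------------------------------------------------------------------------
# candidate assembly helpers


def _ls_factor(x: np.ndarray, mode: int, kr: np.ndarray) -> np.ndarray:
    """Least-squares factor for one mode given the Khatri-Rao of the other two."""
    sol, *_ = np.linalg.lstsq(kr, unfold(x, mode).T, rcond=None)
    return sol.T


def _kr_for_mode(mode: int, f1, f2, f3) -> np.ndarray:
    if mode == 1:
        return khatri_rao(f2, f3)
    if mode == 2:
        return khatri_rao(f1, f3)
    return khatri_rao(f1, f2)


def _fit_model(f1, f2, f3, x: np.ndarray) -> CPModel:
    """Normalize factor columns and refit the component amplitudes by LS."""
    u1, _ = _normalize_columns(f1)
    u2, _ = _normalize_columns(f2)
    u3, _ = _normalize_columns(np.asarray(f3, dtype=complex), fix_phase=False)
    # normal equations via the Hadamard-of-Grams identity (memory-light)
    g = (u1.conj().T @ u1) * (u2.conj().T @ u2) * (u3.conj().T @ u3)
    rhs = np.einsum("ijk,ir,jr,kr->r", x, u1.conj(), u2.conj(), u3.conj())
    c, *_ = np.linalg.lstsq(g, rhs, rcond=None)
    amp = np.abs(c)
    phase = np.where(amp == 0, 1.0, c / np.where(amp == 0, 1, amp))
    u3 = u3 * phase
    if np.max(np.abs(u3.imag)) < 1e-14 * max(1.0, float(np.max(np.abs(u3.real)))):
        u3 = u3.real
    return CPModel([u1, u2, u3], amp, u1.shape[1])


def _rank1_split(f1: np.ndarray, x: np.ndarray):
    """Given the common factor, factor the rest of a tensor into rank-1 pairs.

    Solves F1 @ K = unfold(x, 1) and splits each row of K (an M2 x M3 matrix
    in C order) by its dominant singular pair.
    """
    k, *_ = np.linalg.lstsq(f1, unfold(x, 1), rcond=None)
    m2, m3 = x.shape[1], x.shape[2]
    r = f1.shape[1]
    f2 = np.zeros((m2, r), dtype=complex)
    f3 = np.zeros((m3, r), dtype=complex)
    for j in range(r):
        g = k[j].reshape(m2, m3)
        u, s, vh = np.linalg.svd(g, full_matrices=False)
        f2[:, j] = u[:, 0] * np.sqrt(s[0])
        f3[:, j] = vh[0].conj() * np.sqrt(s[0])
    return f2, f3


def _align_scale(f1_ref: np.ndarray, f1_other: np.ndarray):
    """Permutation aligning ``f1_other`` to ``f1_ref`` and the per-column scales
    lambda with f1_other[:, p] ~ lambda * f1_ref."""
    p = match_permutation(f1_ref, f1_other)
    fo = f1_other[:, p.mapping]
    denom = np.einsum("ir,ir->r", f1_ref.conj(), f1_ref)
    lam = np.einsum("ir,ir->r", f1_ref.conj(), fo) / np.where(denom == 0, 1, denom)
    lam = np.where(np.abs(lam) < 1e-12, 1.0, lam)
    return p.mapping, lam


def _solve_smd_sets(sets, options: DecompositionOptions):
    out = []
    for s in sets:
        try:
            out.append(joint_diagonalize(s, options.jd_tol, options.jd_max_sweeps))
        except IllConditionedError as err:
            out.append(err)
    return out


def _joint_ls_common(x1, x2, kr1, kr2):
    stacked_x = np.hstack([unfold(x1, 1), unfold(x2, 1)])
    stacked_kr = np.vstack([kr1, kr2])
    sol, *_ = np.linalg.lstsq(stacked_kr, stacked_x.T, rcond=None)
    return sol.T


def _maybe_real(f, like):
    if not np.iscomplexobj(like) and np.iscomplexobj(f):
        if np.max(np.abs(f.imag)) < 1e-8 * max(1.0, float(np.max(np.abs(f.real)))):
            return f.real.copy()
    return f


# ---------------------------------------------------------------------------
# candidate estimates


def candidate_estimates(subspace: CoupledSubspace, t1, t2,
                        options: DecompositionOptions | None = None) -> CandidateSet:
    """The eight C-SECSI candidate factor sets (single direct estimate for rank 1)."""
    options = options or DecompositionOptions()
    x1, x2 = _data(t1), _data(t2)
    r = subspace.rank

    if r == 1:
        models = []
        for i, x in enumerate((x1, x2)):
            models.append(
                _fit_model(subspace.common_loading, subspace.loadings_2[i],
                           subspace.loadings_3[i], x)
            )
        e = tuple(reconstruction_error(m, x) for m, x in zip(models, (x1, x2)))
        cand = Candidate("I", True, models, e,
                         provenance={"all": "joint truncated HOSVD leading vectors"})
        return CandidateSet([cand])

    u1 = subspace.common_loading
    u2 = subspace.loadings_2
    u3 = subspace.loadings_3
    xs = (x1, x2)
    candidates = []

    def finalize(label, coupled, f1s, f2s, f3s, provenance):
        """Build per-tensor models; f1s is a single shared matrix or a pair."""
        try:
            models, errs = [], []
            for i in range(2):
                f1 = f1s if isinstance(f1s, np.ndarray) else f1s[i]
                m = _fit_model(_maybe_real(f1, xs[i]), _maybe_real(f2s[i], xs[i]),
                               _maybe_real(f3s[i], xs[i]), xs[i])
                models.append(m)
                errs.append(reconstruction_error(m, xs[i]))
            candidates.append(Candidate(label, coupled, models, tuple(errs), provenance))
        except (np.linalg.LinAlgError, ValueError) as err:
            candidates.append(Candidate(label, coupled, [], (np.inf, np.inf),
                                        provenance, valid=False, note=str(err)))

    def invalid(label, coupled, provenance, err):
        candidates.append(Candidate(label, coupled, [], (np.inf, np.inf),
                                    provenance, valid=False, note=str(err)))

    # --- coupled candidates from the non-common modes (I-IV) -----------------
    # labels: I = mode-3 rhs, II = mode-3 lhs, III = mode-2 rhs, IV = mode-2 lhs
    label_iter = iter(["I", "II", "III", "IV"])
    for diag_mode in (3, 2):
        other = 2 if diag_mode == 3 else 3
        u_other = u2 if other == 2 else u3
        try:
            sets = build_smds(subspace, diag_mode)
        except IllConditionedError as err:
            invalid(next(label_iter), True, {"smd": f"mode {diag_mode} rhs"}, err)
            invalid(next(label_iter), True, {"smd": f"mode {diag_mode} lhs"}, err)
            continue
        sols = _solve_smd_sets(sets, options)

        # rhs pooled: shared transform -> common factor; diagonals -> diag-mode factor
        label = next(label_iter)
        prov = {"common": "transform (pooled rhs)", "diag_mode_factor": "diagonals",
                "other": "least squares", "smd": f"mode {diag_mode} rhs"}
        if isinstance(sols[0], Exception):
            invalid(label, True, prov, sols[0])
        else:
            sol = sols[0]
            f1 = u1 @ sol.transform
            f_diag, f_other = [], []
            start = 0
            try:
                for i in range(2):
                    n_i = sets[0].slice_counts[i]
                    fd = sol.diagonals[start:start + n_i, :]
                    start += n_i
                    kr = (_kr_for_mode(other, f1, None, fd) if diag_mode == 3
                          else _kr_for_mode(other, f1, fd, None))
                    # mode 3 diagonalized: fd estimates F3 -> F2 by LS (kr(F1, F3))
                    # mode 2 diagonalized: fd estimates F2 -> F3 by LS (kr(F1, F2))
                    fo = _ls_factor(xs[i], other, kr)
                    f_diag.append(fd)
                    f_other.append(fo)
                if diag_mode == 3:
                    finalize(label, True, f1, f_other, f_diag, prov)
                else:
                    finalize(label, True, f1, f_diag, f_other, prov)
            except (np.linalg.LinAlgError, ValueError) as err:
                invalid(label, True, prov, err)

        # lhs per tensor: transform -> the *other* non-common factor;
        # diagonals -> diag-mode factor; common factor by joint LS
        label = next(label_iter)
        prov = {"common": "joint LS", "diag_mode_factor": "diagonals",
                "other": "transform", "smd": f"mode {diag_mode} lhs"}
        lhs_sols = sols[1:3]
        if any(isinstance(s, Exception) for s in lhs_sols):
            invalid(label, True, prov,
                    next(s for s in lhs_sols if isinstance(s, Exception)))
        else:
            try:
                f_diag, f_other, f1_tmp = [], [], []
                for i in range(2):
                    sol = lhs_sols[i]
                    fo = u_other[i] @ sol.transform
                    fd = sol.diagonals
                    f2_i = fo if other == 2 else fd
                    f3_i = fd if other == 2 else fo
                    f1_i = _ls_factor(xs[i], 1, khatri_rao(f2_i, f3_i))
                    f_diag.append(fd)
                    f_other.append(fo)
                    f1_tmp.append(f1_i)
                # align tensor 2's component order and column scale to tensor 1's
                perm, lam = _align_scale(f1_tmp[0], f1_tmp[1])
                f_diag[1] = f_diag[1][:, perm] * lam
                f_other[1] = f_other[1][:, perm]
                f2s = [f_other[i] if other == 2 else f_diag[i] for i in range(2)]
                f3s = [f_diag[i] if other == 2 else f_other[i] for i in range(2)]
                f1 = _joint_ls_common(x1, x2, khatri_rao(f2s[0], f3s[0]),
                                      khatri_rao(f2s[1], f3s[1]))
                finalize(label, True, f1, f2s, f3s, prov)
            except (np.linalg.LinAlgError, ValueError) as err:
                invalid(label, True, prov, err)

    # --- uncoupled candidates from the common mode (V-VIII) ------------------
    # labels: V/VI = tensor-1 mode-1 rhs/lhs, VII/VIII = tensor-2 mode-1 rhs/lhs
    try:
        mode1_sets = build_smds(subspace, 1)
    except IllConditionedError as err:
        for label in ("V", "VI", "VII", "VIII"):
            invalid(label, False, {"smd": "mode 1"}, err)
        mode1_sets = []
    if mode1_sets:
        mode1_sols = _solve_smd_sets(mode1_sets, options)
        labels = ["V", "VI", "VII", "VIII"]
        for idx, (s, sol) in enumerate(zip(mode1_sets, mode1_sols)):
            label = labels[idx]
            i = s.tensor_index
            j = 1 - i
            prov = {"common": f"diagonals (tensor {i + 1} mode-1 {s.side})",
                    "own_transform_factor": "transform", "rest": "least squares",
                    "smd": f"tensor {i + 1} mode 1 {s.side}"}
            if isinstance(sol, Exception):
                invalid(label, False, prov, sol)
                continue
            try:
                f1 = sol.diagonals  # M1 x R: the common factor, read per tensor
                if s.side == "rhs":
                    f2_i = u2[i] @ sol.transform
                    f3_i = _ls_factor(xs[i], 3, khatri_rao(f1, f2_i))
                else:
                    f3_i = u3[i] @ sol.transform
                    f2_i = _ls_factor(xs[i], 2, khatri_rao(f1, f3_i))
                f2_j, f3_j = _rank1_split(f1, xs[j])
                f2s, f3s = [None, None], [None, None]
                f2s[i], f3s[i] = f2_i, f3_i
                f2s[j], f3s[j] = f2_j, f3_j
                finalize(label, False, f1, f2s, f3s, prov)
            except (np.linalg.LinAlgError, ValueError) as err:
                invalid(label, False, prov, err)

    return CandidateSet(candidates)


# ---------------------------------------------------------------------------
# selection


def select_final(cs: CandidateSet, t1, t2) -> CoupledResult:
    """Minimum-reconstruction-error selection, independently per tensor.

    Ties within 1e-12 prefer a coupled candidate (coupling is the framework's
    prior assumption).  The reliability compares the two selected common-factor
    estimates.
    """
    valid = [c for c in cs if c.valid]
    if not valid:
        raise IllConditionedError("no valid candidate to select from")
    rank = valid[0].models[0].rank
    selected, labels = [], []
    for i in range(2):
        best = None
        for c in valid:
            if best is None:
                best = c
                continue
            d = c.e_rec[i] - best.e_rec[i]
            if d < -_TIE_TOL or (abs(d) <= _TIE_TOL and c.coupled and not best.coupled):
                best = c
        selected.append(best)
        labels.append(best.label)
    models = [selected[0].models[0], selected[1].models[1]]
    rel = reliability(models[0].factors[0], models[1].factors[0])
    residuals = (selected[0].e_rec[0], selected[1].e_rec[1])
    return CoupledResult(models, rel, residuals, cs, rank, tuple(labels))


# ---------------------------------------------------------------------------
# top-level entry points


def csecsi(t1, t2, rank: int, options: DecompositionOptions | None = None) -> CoupledResult:
    """Coupled semi-algebraic CP decomposition of two tensors sharing mode 1."""
    options = options or DecompositionOptions()
    sub = coupled_hosvd(t1, t2, rank)
    cs = candidate_estimates(sub, t1, t2, options)
    return select_final(cs, t1, t2)


def secsi(t, rank: int, options: DecompositionOptions | None = None) -> CPModel:
    """Single-tensor semi-algebraic CP decomposition (minimum-e_rec selection)."""
    options = options or DecompositionOptions()
    x = _data(t)
    core, loadings = truncated_hosvd(x, rank)
    if rank == 1:
        return _fit_model(loadings[0], loadings[1], loadings[2], x)
    best_model, best_err = None, np.inf
    for diag_mode in (3, 2, 1):
        rest = [m for m in (1, 2, 3) if m != diag_mode]
        try:
            sets = build_smds_single(core.data, loadings[diag_mode - 1], diag_mode)
        except IllConditionedError:
            continue
        for s in sets:
            try:
                sol = joint_diagonalize(s, options.jd_tol, options.jd_max_sweeps)
                # rhs transform -> factor of the first remaining mode,
                # lhs transform -> factor of the second remaining mode
                t_mode = rest[0] if s.side == "rhs" else rest[1]
                ls_mode = rest[1] if s.side == "rhs" else rest[0]
                fs = {diag_mode: sol.diagonals,
                      t_mode: loadings[t_mode - 1] @ sol.transform}
                kr = _kr_for_mode(ls_mode, fs.get(1), fs.get(2), fs.get(3))
                fs[ls_mode] = _ls_factor(x, ls_mode, kr)
                model = _fit_model(_maybe_real(fs[1], x), _maybe_real(fs[2], x),
                                   _maybe_real(fs[3], x), x)
                err = reconstruction_error(model, x)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if err < best_err:
                best_model, best_err = model, err
    if best_model is None:
        raise IllConditionedError("all SECSI candidates failed")
    return best_model


def rank_sweep(t1, t2, ranks, options: DecompositionOptions | None = None) -> pd.DataFrame:
    """Run the coupled decomposition for each assumed rank; report REL and e_rec.

    The argmax-REL flag excludes rank 1, whose reliability is trivially 100.
    """
    ranks = list(ranks)
    if not ranks or any(r < 1 for r in ranks):
        raise ValueError("ranks must be a nonempty list of integers >= 1")
    rows = []
    for r in ranks:
        res = csecsi(t1, t2, r, options)
        rows.append({"rank": r, "reliability": res.reliability,
                     "e_rec_1": res.residuals[0], "e_rec_2": res.residuals[1]})
    df = pd.DataFrame(rows)
    eligible = df[df["rank"] > 1]
    df["best"] = False
    if len(eligible):
        df.loc[eligible["reliability"].idxmax(), "best"] = True
    return df
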