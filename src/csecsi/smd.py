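"""Simultaneous matrix diagonalization (SMD) problems built from HOSVD cores.

For a rank-R CP tensor with truncated HOSVD ``X = S x1 U1 x2 U2 x3 U3`` and
factors ``Fn = Un @ Tn``, the core merged along one mode has jointly
diagonalizable slice products.  E.g. along mode 3, the slices of ``S x3 U3``
are ``Y_k = T1 @ diag(F3[k]) @ T2.T``; right-multiplying by the inverse of a
well-conditioned pivot slice gives ``Y_k Y_p^{-1} = T1 D_k T1^{-1}``, a set
with the *shared* eigenvector matrix T1.  Left products expose T2 (after a
transpose) instead.  For two tensors with a common first mode the right-side
sets of modes 2 and 3 can be pooled across both tensors (they share T1); the
left-side sets and all common-mode (mode-1) sets cannot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tensor import CoupledSubspace, mode_product

__all__ = [
    "SMDSet",
    "SMDSolution",
    "IllConditionedError",
    "select_pivot",
    "build_smds",
    "build_smds_single",
    "joint_diagonalize",
]

_COND_LIMIT = 1e12


class IllConditionedError(np.linalg.LinAlgError):
    """Raised when every available pivot slice is numerically singular."""


@dataclass
class SMDSet:
    """One joint-diagonalization problem instance.

    ``matrices`` are the slice products; for pooled (coupled) sets,
    ``slice_counts`` records how many came from each tensor so the diagonal
    entries can be routed back to the right factor matrix.
    """

    matrices: list
    source_mode: int
    side: str  # "rhs" | "lhs"
    pivot_index: tuple
    coupled: bool
    tensor_index: int | None = None  # 0/1 for per-tensor sets, None when pooled
    slice_counts: tuple = ()

    def __post_init__(self):
        if self.side not in ("rhs", "lhs"):
            raise ValueError("side must be 'rhs' or 'lhs'")
        sizes = {m.shape for m in self.matrices}
        if len(sizes) != 1 or any(s[0] != s[1] for s in sizes):
            raise ValueError("all SMD matrices must be square with a common size")


@dataclass
class SMDSolution:
    transform: np.ndarray  # R x R invertible diagonalizer
    diagonals: np.ndarray  # K x R diagonal entries of T^-1 A_k T
    offdiag_residual: float  # off-diagonal energy / total energy of the set
    converged: bool = True
    n_sweeps: int = 0


def select_pivot(slices) -> int:
    """Index of the slice with the smallest 2-norm condition number."""
    if len(slices) == 0:
        raise ValueError("need at least one slice")
    conds = []
    for s in slices:
        sv = np.linalg.svd(np.asarray(s), compute_uv=False)
        conds.append(np.inf if sv[-1] == 0 else sv[0] / sv[-1])
    best = int(np.argmin(conds))
    if conds[best] > _COND_LIMIT:
        raise IllConditionedError(
            f"all {len(slices)} core slices numerically singular (best cond {conds[best]:.2e})"
        )
    return best


def _merged_slices(core: np.ndarray, loading: np.ndarray, mode: int):
    """Slices of the core merged (re-expanded) along ``mode``.

    Returns a list of R x R matrices indexed along the merged mode, arranged so
    each slice is ``T_a @ diag(F_mode[k]) @ T_b.T`` with (a, b) the remaining
    modes in increasing order.
    """
    merged = mode_product(core, loading, mode).data
    if mode == 1:
        return [merged[m, :, :] for m in range(merged.shape[0])]
    if mode == 2:
        return [merged[:, j, :] for j in range(merged.shape[1])]
    return [merged[:, :, k] for k in range(merged.shape[2])]


def _slice_products(slices, side: str):
    """Pivot-normalized slice products plus the chosen pivot index.

    rhs: ``Y_k @ Y_p^{-1}``  (shared left transform).
    lhs: ``(Y_p^{-1} @ Y_k).T``  (transform = the right-side factor's T).
    """
    p = select_pivot(slices)
    pinv_ = np.linalg.inv(slices[p])
    if side == "rhs":
        mats = [s @ pinv_ for s in slices]
    else:
        mats = [(pinv_ @ s).T for s in slices]
    return mats, p


def build_smds(subspace: CoupledSubspace, diag_mode: int):
    """All SMD problem instances for one diagonalization mode of a coupled pair.

    Modes 2 and 3 (non-common): one pooled rhs set whose shared transform is T1
    (the common factor's transform) plus one lhs set per tensor.  Mode 1
    (common): the common factor sits in the diagonal entries, so the sets
    cannot be pooled — two per-tensor sets per side.
    """
    if diag_mode not in (1, 2, 3):
        raise ValueError("diag_mode must be 1, 2 or 3")
    if subspace.rank < 2:
        raise ValueError("SMDs require rank >= 2")
    loadings = {
        1: [subspace.common_loading, subspace.common_loading],
        2: subspace.loadings_2,
        3: subspace.loadings_3,
    }[diag_mode]
    per_tensor_slices = [
        _merged_slices(subspace.cores[i].data, loadings[i], diag_mode) for i in (0, 1)
    ]
    sets = []
    if diag_mode in (2, 3):
        pooled, pivots, counts = [], [], []
        for sl in per_tensor_slices:
            mats, p = _slice_products(sl, "rhs")
            pooled.extend(mats)
            pivots.append(p)
            counts.append(len(mats))
        sets.append(
            SMDSet(pooled, diag_mode, "rhs", tuple(pivots), True, None, tuple(counts))
        )
        for i, sl in enumerate(per_tensor_slices):
            mats, p = _slice_products(sl, "lhs")
            sets.append(SMDSet(mats, diag_mode, "lhs", (p,), False, i, (len(mats),)))
    else:
        for i, sl in enumerate(per_tensor_slices):
            for side in ("rhs", "lhs"):
                mats, p = _slice_products(sl, side)
                sets.append(SMDSet(mats, 1, side, (p,), False, i, (len(mats),)))
    return sets


def build_smds_single(core: np.ndarray, loading: np.ndarray, diag_mode: int):
    """The two per-mode SMD sets (rhs, lhs) for a single tensor."""
    slices = _merged_slices(core, loading, diag_mode)
    out = []
    for side in ("rhs", "lhs"):
        mats, p = _slice_products(slices, side)
        out.append(SMDSet(mats, diag_mode, side, (p,), False, 0, (len(mats),)))
    return out


# ---------------------------------------------------------------------------
# Non-unitary joint diagonalization


def _offdiag_cost(b: np.ndarray) -> float:
    d = np.einsum("kii->ki", b)
    return float(np.sum(np.abs(b) ** 2) - np.sum(np.abs(d) ** 2))


def _eig_init(a: np.ndarray):
    """Candidate diagonalizers from eigenvectors of fixed generic combinations."""
    k = a.shape[0]
    rng = np.random.default_rng(12345)  # fixed: deterministic framework
    combos = [np.ones(k)]
    combos += [rng.standard_normal(k) for _ in range(2)]
    cands = [np.eye(a.shape[1], dtype=a.dtype)]
    for c in combos:
        m = np.tensordot(c, a, axes=(0, 0))
        try:
            _, vec = np.linalg.eig(m)
        except np.linalg.LinAlgError:
            continue
        if np.linalg.cond(vec) < _COND_LIMIT:
            cands.append(vec)
    return cands


def joint_diagonalize(s: SMDSet, tol: float = 1e-10, max_sweeps: int = 200) -> SMDSolution:
    """Find an invertible T minimizing the summed off-diagonal energy of T^-1 A_k T.

    Eigen-initialization from generic linear combinations of the set, refined by
    damped multiplicative updates ``T <- T (I + W)`` where W solves the pairwise
    linearized off-diagonal least-squares problem; backtracking keeps the
    objective non-increasing.
    """
    a = np.stack([np.asarray(m, dtype=complex) for m in s.matrices])
    k, r, _ = a.shape
    energy = float(np.sum(np.abs(a) ** 2))
    if energy == 0:
        return SMDSolution(np.eye(r), np.zeros((k, r)), 0.0, True, 0)
    if r == 1:
        return SMDSolution(np.ones((1, 1)), a[:, 0, 0][:, None], 0.0, True, 0)

    best_t, best_cost = None, np.inf
    for t0 in _eig_init(a):
        try:
            t0inv = np.linalg.inv(t0)
        except np.linalg.LinAlgError:
            continue
        b = np.einsum("ij,kjl,lm->kim", t0inv, a, t0)
        c = _offdiag_cost(b)
        if c < best_cost:
            best_t, best_cost = t0, c
    t = best_t
    cost = best_cost

    eye = np.eye(r, dtype=complex)
    converged = False
    sweep = 0
    for sweep in range(1, max_sweeps + 1):
        tinv = np.linalg.inv(t)
        b = np.einsum("ij,kjl,lm->kim", tinv, a, t)
        d = np.einsum("kii->ki", b)  # (k, r)
        # pairwise linearized update: for i != j minimize sum_k |B_ij + W_ij (d_ki - d_kj)|^2
        delta = d[:, None, :] - d[:, :, None]  # delta[k, i, j] = d_kj - d_ki
        denom = np.sum(np.abs(delta) ** 2, axis=0)
        numer = np.sum(np.conj(delta) * b, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.where(denom > 0, numer / np.where(denom == 0, 1, denom), 0.0)
        np.fill_diagonal(w, 0.0)
        wn = np.linalg.norm(w)
        if wn > 0.7:  # keep I + W well away from singularity
            w = w * (0.7 / wn)
        improved = False
        step = 1.0
        for _ in range(12):
            t_new = t @ (eye + step * w)
            try:
                tinv_new = np.linalg.inv(t_new)
            except np.linalg.LinAlgError:
                step *= 0.5
                continue
            b_new = np.einsum("ij,kjl,lm->kim", tinv_new, a, t_new)
            c_new = _offdiag_cost(b_new)
            if c_new < cost:
                t, cost = t_new, c_new
                improved = True
                break
            step *= 0.5
        if not improved:
            converged = True
            break
        if cost <= tol * energy or abs(best_cost - cost) <= tol * max(cost, energy * 1e-16):
            converged = True
            break
        best_cost = cost

    # normalize: unit columns, largest-magnitude entry real-positive
    norms = np.linalg.norm(t, axis=0)
    norms = np.where(norms == 0, 1.0, norms)
    t = t / norms
    idx = np.argmax(np.abs(t), axis=0)
    lead = t[idx, np.arange(r)]
    phase = np.where(np.abs(lead) == 0, 1.0, lead / np.abs(np.where(lead == 0, 1, lead)))
    t = t / phase
    if np.linalg.cond(t) > _COND_LIMIT:
        raise IllConditionedError("joint diagonalization produced a singular transform")
    tinv = np.linalg.inv(t)
    b = np.einsum("ij,kjl,lm->kim", tinv, a, t)
    diagonals = np.einsum("kii->ki", b).copy()
    residual = _offdiag_cost(b) / energy
    return SMDSolution(t, diagonals, float(residual), converged, sweep)
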