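"""Three-way tensor algebra: unfoldings, mode products, CP models, (coupled) HOSVD.

The unfolding convention used throughout: ``unfold(t, n)`` moves mode *n* to the
front and reshapes in C order, i.e. element ``(i1, i2, i3)`` of the tensor sits in
row ``i_n`` and the remaining modes cycle in their natural order with the last one
varying fastest.  Under this convention the mode-1 unfolding of a CP model is
``F1 @ khatri_rao(F2, F3).T`` (scipy's column-wise Khatri-Rao), and the mode-3
slice ``t[:, :, k]`` of a CP tensor equals ``F1 @ diag(F3[k]) @ F2.T``.

All operations are defined over complex scalars; real input is the special case
with zero imaginary part.  Conjugation enters only through Hermitian transposes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse.linalg

__all__ = [
    "Tensor3",
    "CPModel",
    "CoupledCPModel",
    "CoupledSubspace",
    "unfold",
    "fold",
    "mode_product",
    "ho_norm",
    "cp_reconstruct",
    "truncated_hosvd",
    "coupled_hosvd",
    "khatri_rao",
]


def _as_3way(data: np.ndarray) -> np.ndarray:
    arr = np.asarray(data)
    if arr.ndim != 3:
        raise ValueError(f"expected a 3-way array, got ndim={arr.ndim}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("tensor entries must be finite")
    return arr


@dataclass
class Tensor3:
    """A three-way array with named modes."""

    data: np.ndarray
    mode_names: tuple = ("mode1", "mode2", "mode3")

    def __post_init__(self):
        self.data = _as_3way(self.data)
        self.mode_names = tuple(self.mode_names)
        if len(self.mode_names) != 3:
            raise ValueError("mode_names must have length 3")

    @property
    def dims(self) -> tuple:
        return self.data.shape

    @property
    def is_complex(self) -> bool:
        return np.iscomplexobj(self.data)

    def copy(self) -> "Tensor3":
        return Tensor3(self.data.copy(), self.mode_names)


def _data(t) -> np.ndarray:
    return t.data if isinstance(t, Tensor3) else _as_3way(t)


def unfold(t, mode: int) -> np.ndarray:
    """Mode-n unfolding: M_mode x (product of the other dims) matrix."""
    if mode not in (1, 2, 3):
        raise ValueError(f"mode must be 1, 2 or 3, got {mode}")
    arr = _data(t)
    return np.moveaxis(arr, mode - 1, 0).reshape(arr.shape[mode - 1], -1)


def fold(mat: np.ndarray, mode: int, dims) -> Tensor3:
    """Inverse of :func:`unfold` for the given target dims."""
    if mode not in (1, 2, 3):
        raise ValueError(f"mode must be 1, 2 or 3, got {mode}")
    dims = tuple(dims)
    rest = [dims[i] for i in range(3) if i != mode - 1]
    arr = np.asarray(mat).reshape(dims[mode - 1], *rest)
    return Tensor3(np.moveaxis(arr, 0, mode - 1))


def mode_product(t, m: np.ndarray, mode: int) -> Tensor3:
    """n-mode product t x_n m; ``unfold(result, n) == m @ unfold(t, n)``."""
    arr = _data(t)
    m = np.asarray(m)
    if m.ndim != 2 or m.shape[1] != arr.shape[mode - 1]:
        raise ValueError(
            f"matrix of shape {m.shape} cannot multiply mode {mode} of dims {arr.shape}"
        )
    dims = list(arr.shape)
    dims[mode - 1] = m.shape[0]
    return fold(m @ unfold(arr, mode), mode, dims)


def ho_norm(t) -> float:
    """Higher-order norm: sqrt of the sum of squared entry magnitudes."""
    return float(np.linalg.norm(_data(t).ravel()))


def khatri_rao(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise Khatri-Rao product (rows of ``a`` vary slowest)."""
    return scipy.linalg.khatri_rao(a, b)


# ---------------------------------------------------------------------------
# CP models


def _normalize_columns(f: np.ndarray, fix_phase: bool = True):
    """Unit-norm columns; optionally rotate each so its largest entry is real-positive.

    Returns (normalized matrix, removed complex scales s) with f == normalized * s.
    """
    f = np.asarray(f)
    norms = np.linalg.norm(f, axis=0)
    norms = np.where(norms == 0, 1.0, norms)
    out = f / norms
    scales = norms.astype(complex)
    if fix_phase:
        idx = np.argmax(np.abs(out), axis=0)
        lead = out[idx, np.arange(out.shape[1])]
        phase = np.where(np.abs(lead) == 0, 1.0, lead / np.abs(np.where(lead == 0, 1, lead)))
        out = out / phase
        scales = scales * phase
    if not np.iscomplexobj(f):
        out = out.real if np.max(np.abs(out.imag)) == 0 else out
    return out, scales


@dataclass
class CPModel:
    """CP model with unit-norm factor columns; the scale lives in ``amplitudes``.

    The phase convention fixes modes 1 and 2 (largest-magnitude entry of each
    column real-positive); residual complex phase is carried by the mode-3
    columns so the amplitudes stay real and nonnegative.
    """

    factors: list
    amplitudes: np.ndarray
    rank: int

    def __post_init__(self):
        if len(self.factors) != 3:
            raise ValueError("a CPModel needs exactly 3 factor matrices")
        self.factors = [np.asarray(f) for f in self.factors]
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        for f in self.factors:
            if f.shape[1] != self.rank:
                raise ValueError("factor column count does not match rank")
        if self.amplitudes.shape != (self.rank,):
            raise ValueError("amplitudes must have length rank")
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be nonnegative")

    @classmethod
    def from_raw_factors(cls, f1, f2, f3) -> "CPModel":
        """Build a normalized model from raw (arbitrarily scaled) factors."""
        f1, s1 = _normalize_columns(f1)
        f2, s2 = _normalize_columns(f2)
        f3n = np.asarray(f3, dtype=complex)
        norms3 = np.linalg.norm(f3n, axis=0)
        norms3 = np.where(norms3 == 0, 1.0, norms3)
        f3n = f3n / norms3
        total = s1 * s2 * norms3
        # push the residual phase of the total scale into mode 3
        amp = np.abs(total)
        phase = np.where(amp == 0, 1.0, total / np.where(amp == 0, 1, amp))
        f3n = f3n * phase
        if np.max(np.abs(f3n.imag)) < 1e-14 * max(1.0, np.max(np.abs(f3n.real))):
            f3n = f3n.real
        f1 = f1.real if not np.iscomplexobj(f1) else f1
        return cls([f1, f2, f3n], amp, f1.shape[1])

    @property
    def dims(self):
        return tuple(f.shape[0] for f in self.factors)


@dataclass
class CoupledCPModel:
    """Two CP models constrained to share the first-mode factor."""

    shared_factor: np.ndarray
    per_tensor: list  # two (F2, F3, amplitudes) triples
    rank: int

    def __post_init__(self):
        self.shared_factor = np.asarray(self.shared_factor)
        if len(self.per_tensor) != 2:
            raise ValueError("expected per-tensor blocks for exactly two tensors")
        for f2, f3, amp in self.per_tensor:
            if f2.shape[1] != self.rank or f3.shape[1] != self.rank:
                raise ValueError("per-tensor factor rank mismatch")
            if len(amp) != self.rank:
                raise ValueError("amplitude length mismatch")

    def model(self, which: int) -> CPModel:
        """The CP model of tensor ``which`` (1 or 2)."""
        f2, f3, amp = self.per_tensor[which - 1]
        return CPModel([self.shared_factor, f2, f3], np.asarray(amp, float), self.rank)


def cp_reconstruct(model, which: int | None = None) -> Tensor3:
    """Reconstruct the tensor of a CP (or one side of a coupled CP) model."""
    if isinstance(model, CoupledCPModel):
        if which not in (1, 2):
            raise ValueError("which must be 1 or 2 for a coupled model")
        model = model.model(which)
    f1, f2, f3 = model.factors
    data = np.einsum("ir,jr,kr,r->ijk", f1, f2, f3, model.amplitudes)
    return Tensor3(data)


# ---------------------------------------------------------------------------
# HOSVD


def _svd_economy(mat: np.ndarray, r: int):
    """Leading-r left singular vectors and values; truncated solver for large mats."""
    m, n = mat.shape
    if min(m, n) > max(4 * r + 10, 30) and mat.size > 200_000:
        # deterministic Lanczos start vector
        v0 = np.ones(min(m, n))
        u, s, _ = scipy.sparse.linalg.svds(mat, k=r, v0=v0)
        order = np.argsort(s)[::-1]
        return u[:, order], s[order]
    u, s, _ = scipy.linalg.svd(mat, full_matrices=False)
    return u[:, :r], s[:r]


def _leading_left_singular(mat: np.ndarray, r: int) -> np.ndarray:
    return _svd_economy(mat, r)[0]


def truncated_hosvd(t, rank: int):
    """Truncated HOSVD: per-mode leading left singular vectors and the core.

    Returns ``(core, [U1, U2, U3])`` with ``core = t x1 U1^H x2 U2^H x3 U3^H``.
    """
    arr = _data(t)
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if any(rank > d for d in arr.shape):
        raise ValueError(f"rank {rank} exceeds a tensor dimension {arr.shape}")
    loadings = [_leading_left_singular(unfold(arr, n), rank) for n in (1, 2, 3)]
    core = arr
    for n, u in enumerate(loadings, start=1):
        core = mode_product(core, u.conj().T, n).data
    return Tensor3(core), loadings


@dataclass
class CoupledSubspace:
    """Joint truncated HOSVD of two tensors sharing mode 1.

    ``common_loading`` holds the leading left singular vectors of the column-wise
    concatenation of the two mode-1 unfoldings; modes 2 and 3 are truncated per
    tensor; ``cores[i] = t_i x1 U1^H x2 U2_i^H x3 U3_i^H``.
    """

    common_loading: np.ndarray
    loadings_2: list
    loadings_3: list
    cores: list
    singular_values: np.ndarray
    rank: int
    dims: list = field(default_factory=list)


def coupled_hosvd(t1, t2, rank: int) -> CoupledSubspace:
    a1, a2 = _data(t1), _data(t2)
    if a1.shape[0] != a2.shape[0]:
        raise ValueError("tensors must share their first-mode dimension")
    if rank < 1:
        raise ValueError("rank must be >= 1")
    for a in (a1, a2):
        if any(rank > d for d in a.shape):
            raise ValueError(f"rank {rank} exceeds a tensor dimension {a.shape}")
    joint = np.hstack([unfold(a1, 1), unfold(a2, 1)])
    u1, s1 = _svd_economy(joint, rank)
    loadings_2, loadings_3, cores = [], [], []
    for a in (a1, a2):
        u2 = _leading_left_singular(unfold(a, 2), rank)
        u3 = _leading_left_singular(unfold(a, 3), rank)
        core = mode_product(mode_product(mode_product(a, u1.conj().T, 1), u2.conj().T, 2), u3.conj().T, 3)
        loadings_2.append(u2)
        loadings_3.append(u3)
        cores.append(core)
    return CoupledSubspace(
        common_loading=u1,
        loadings_2=loadings_2,
        loadings_3=loadings_3,
        cores=cores,
        singular_values=s1[:rank],
        rank=rank,
        dims=[a1.shape, a2.shape],
    )
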