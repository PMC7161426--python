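"""Coupled alternating least squares (C-ALS) baselines.

The shared first-mode factor is solved from the column-wise concatenation of
both tensors' mode-1 unfoldings against the stacked Khatri-Rao products; the
non-shared factors are ordinary per-tensor LS updates.  The "normalized"
variant weights each tensor's rows of the shared-factor system inversely to
its noise standard deviation, which matters when the two tensors carry noise
of very different variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tensor import (
    CoupledCPModel,
    Tensor3,
    coupled_hosvd,
    cp_reconstruct,
    ho_norm,
    khatri_rao,
    unfold,
    _data,
)

__all__ = ["ALSOptions", "coupled_als", "coupled_als_normalized"]


@dataclass
class ALSOptions:
    max_iters: int = 1000
    rel_tol: float = 1e-8
    init: str = "hosvd"  # "hosvd" | "random"
    seed: int = 0
    variance_weights: tuple | None = None

    def __post_init__(self):
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be positive")
        if self.init not in ("hosvd", "random"):
            raise ValueError("init must be 'hosvd' or 'random'")


def _init_factors(x1, x2, rank, opts: ALSOptions):
    if opts.init == "hosvd":
        sub = coupled_hosvd(x1, x2, rank)
        return (sub.common_loading.copy(),
                [sub.loadings_2[0].copy(), sub.loadings_2[1].copy()],
                [sub.loadings_3[0].copy(), sub.loadings_3[1].copy()])
    rng = np.random.default_rng(opts.seed)

    def draw(m):
        f = rng.standard_normal((m, rank))
        if np.iscomplexobj(x1) or np.iscomplexobj(x2):
            f = (f + 1j * rng.standard_normal((m, rank))) / np.sqrt(2)
        return f

    return (draw(x1.shape[0]),
            [draw(x1.shape[1]), draw(x2.shape[1])],
            [draw(x1.shape[2]), draw(x2.shape[2])])


def _ls(kr, xt):
    sol, *_ = np.linalg.lstsq(kr, xt, rcond=None)
    return sol.T


def _objective(f1, f2s, f3s, xs):
    total = 0.0
    for i in range(2):
        xhat = np.einsum("ir,jr,kr->ijk", f1, f2s[i], f3s[i])
        total += ho_norm(xhat - xs[i]) ** 2
    return total


def _to_model(f1, f2s, f3s) -> CoupledCPModel:
    rank = f1.shape[1]
    norms1 = np.linalg.norm(f1, axis=0)
    norms1 = np.where(norms1 == 0, 1.0, norms1)
    f1n = f1 / norms1
    per_tensor = []
    for i in range(2):
        n2 = np.linalg.norm(f2s[i], axis=0)
        n3 = np.linalg.norm(f3s[i], axis=0)
        n2 = np.where(n2 == 0, 1.0, n2)
        n3 = np.where(n3 == 0, 1.0, n3)
        per_tensor.append((f2s[i] / n2, f3s[i] / n3, norms1 * n2 * n3))
    return CoupledCPModel(f1n, per_tensor, rank)


def _run_als(x1, x2, rank, opts: ALSOptions, weights, init_factors=None):
    xs = (np.asarray(x1), np.asarray(x2))
    if init_factors is not None:
        f1 = np.array(init_factors[0], copy=True)
        f2s = [np.array(f, copy=True) for f in init_factors[1]]
        f3s = [np.array(f, copy=True) for f in init_factors[2]]
    else:
        f1, f2s, f3s = _init_factors(*xs, rank, opts)
    x1_unf = unfold(xs[0], 1)
    x2_unf = unfold(xs[1], 1)
    prev = _objective(f1, f2s, f3s, xs)
    scale = ho_norm(xs[0]) ** 2 + ho_norm(xs[1]) ** 2
    for _ in range(opts.max_iters):
        for i in range(2):
            f2s[i] = _ls(khatri_rao(f1, f3s[i]), unfold(xs[i], 2).T)
            f3s[i] = _ls(khatri_rao(f1, f2s[i]), unfold(xs[i], 3).T)
        stacked_kr = np.vstack([weights[0] * khatri_rao(f2s[0], f3s[0]),
                                weights[1] * khatri_rao(f2s[1], f3s[1])])
        stacked_x = np.hstack([weights[0] * x1_unf, weights[1] * x2_unf])
        f1 = _ls(stacked_kr, stacked_x.T)
        obj = _objective(f1, f2s, f3s, xs)
        if abs(prev - obj) <= opts.rel_tol * max(prev, scale * 1e-16):
            prev = obj
            break
        prev = obj
    return _to_model(f1, f2s, f3s)


def coupled_als(t1, t2, rank: int, opts: ALSOptions | None = None,
                init_factors=None) -> CoupledCPModel:
    """Coupled CP decomposition by alternating least squares.

    ``init_factors`` optionally supplies a starting point ``(f1, [f2_1, f2_2],
    [f3_1, f3_2])`` overriding ``opts.init``.
    """
    opts = opts or ALSOptions()
    return _run_als(_data(t1), _data(t2), rank, opts, (1.0, 1.0), init_factors)


def _estimate_noise_std(x1, x2, rank, opts: ALSOptions):
    """Per-tensor noise std from the residual of a short unweighted fit."""
    warm = ALSOptions(max_iters=min(20, opts.max_iters), rel_tol=opts.rel_tol,
                      init=opts.init, seed=opts.seed)
    model = _run_als(x1, x2, rank, warm, (1.0, 1.0))
    stds = []
    for i, x in enumerate((x1, x2)):
        res = cp_reconstruct(model, i + 1).data - x
        stds.append(max(np.sqrt(np.mean(np.abs(res) ** 2)), 1e-30))
    return tuple(stds)


def coupled_als_normalized(t1, t2, rank: int, opts: ALSOptions | None = None) -> CoupledCPModel:
    """C-ALS with the shared-factor system row-weighted by 1/noise-std per tensor."""
    opts = opts or ALSOptions()
    x1, x2 = _data(t1), _data(t2)
    if opts.variance_weights is not None:
        w = tuple(float(v) for v in opts.variance_weights)
        if any(v <= 0 for v in w):
            raise ValueError("variance weights must be positive")
    else:
        s1, s2 = _estimate_noise_std(x1, x2, rank, opts)
        w = (1.0 / s1, 1.0 / s2)
    wmax = max(w)
    w = (w[0] / wmax, w[1] / wmax)
    return _run_als(x1, x2, rank, opts, w)
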