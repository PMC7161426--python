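"""Simulation benchmarks: factor generators, calibrated noise, TSFE/TMSFE/CCDF,
and the built-in experiment designs used to characterize the framework.

Designs
-------
reliability_vs_rank
    Random Gaussian factors, both tensors the same true rank; sweep the assumed
    rank and record the reliability per SNR.  The reliability peaks at the true
    rank.
rank_mismatch
    The tensors have different ranks but share their leading components; the
    reliability sweep shows local maxima at both ranks.
ccdf_collinear
    Sine-signature common factor, collinear third factors (swamp-inducing);
    CCDF of the TSFE across methods.
secsi_vs_csecsi
    Only the second tensor's third factor is collinear (ill-conditioned);
    coupled vs. uncoupled estimation accuracy.
unequal_noise
    Complex tensors with a fixed SNR on tensor 1 while tensor 2's SNR varies;
    TMSFE per method as a function of SNR_2.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .als import ALSOptions, coupled_als, coupled_als_normalized
from .framework import DecompositionOptions, csecsi, secsi
from .tensor import Tensor3, ho_norm, CPModel, _data

__all__ = [
    "FactorSpec",
    "NoiseSpec",
    "BenchmarkResult",
    "gen_random_factors",
    "gen_correlated_factor",
    "gen_sine_signatures",
    "add_noise_at_snr",
    "tsfe",
    "ccdf",
    "run_experiment",
    "DESIGNS",
]


@dataclass
class FactorSpec:
    dims: tuple
    rank: int
    field: str = "real"  # "real" | "complex"
    correlation: tuple | None = None  # optional rho per factor (None entries allowed)
    signature_kind: str = "gaussian"  # "gaussian" | "sine" (first factor)

    def __post_init__(self):
        if self.field not in ("real", "complex"):
            raise ValueError("field must be 'real' or 'complex'")
        if self.correlation is not None:
            for rho in self.correlation:
                if rho is not None and not (0 <= rho < 1):
                    raise ValueError("correlation must satisfy 0 <= rho < 1")


@dataclass
class NoiseSpec:
    snr_db: tuple  # (SNR_1, SNR_2) in dB
    seed: int = 0


@dataclass
class BenchmarkResult:
    design: str
    table: pd.DataFrame  # long format: realization, method, metric, value, ...
    config: dict = field(default_factory=dict)

    def aggregate(self, by=("method",), metric="tsfe") -> pd.DataFrame:
        sub = self.table[self.table["metric"] == metric]
        return sub.groupby(list(by))["value"].mean().reset_index()


# ---------------------------------------------------------------------------
# generators


def _draw(rng, shape, complex_field):
    if complex_field:
        return (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) / np.sqrt(2)
    return rng.standard_normal(shape)


def gen_random_factors(spec: FactorSpec, seed: int):
    """I.i.d. unit-variance Gaussian factor matrices (circularly symmetric when complex)."""
    rng = np.random.default_rng(seed)
    complex_field = spec.field == "complex"
    factors = []
    for n, m in enumerate(spec.dims):
        rho = None
        if spec.correlation is not None:
            rho = spec.correlation[n]
        if n == 0 and spec.signature_kind == "sine":
            factors.append(gen_sine_signatures(n_samples=m))
            continue
        if rho:
            factors.append(_correlated(rng, m, spec.rank, rho, complex_field))
        else:
            factors.append(_draw(rng, (m, spec.rank), complex_field))
    return factors


def _correlated(rng, m, rank, rho, complex_field):
    base = _draw(rng, (m, 1), complex_field)
    g = _draw(rng, (m, rank), complex_field)
    return np.sqrt(rho) * base + np.sqrt(1 - rho) * g


def gen_correlated_factor(dims: int, rank: int, rho: float, seed: int) -> np.ndarray:
    """Columns sqrt(rho)*b + sqrt(1-rho)*g_j: every pair has expected correlation rho."""
    if not (0 <= rho < 1):
        raise ValueError("rho must satisfy 0 <= rho < 1")
    rng = np.random.default_rng(seed)
    return _correlated(rng, dims, rank, rho, False)


def gen_sine_signatures(n_samples: int = 40, fs_hz: float = 1000.0,
                        f=(10.0, 20.0, 30.0)) -> np.ndarray:
    """Damped/growing sine signatures in the physiological frequency range.

    Columns: sin(2 pi f1 t + pi/3), sin(2 pi f2 t) * exp(+t * 10 Hz),
    sin(2 pi f3 t) * exp(-t * 3 Hz), sampled at t_k = k / fs.
    """
    if fs_hz <= 0:
        raise ValueError("fs_hz must be positive")
    t = np.arange(n_samples) / fs_hz
    return np.column_stack([
        np.sin(2 * np.pi * f[0] * t + np.pi / 3),
        np.sin(2 * np.pi * f[1] * t) * np.exp(t * 10.0),
        np.sin(2 * np.pi * f[2] * t) * np.exp(-t * 3.0),
    ])


def add_noise_at_snr(t, snr_db: float, seed: int) -> Tensor3:
    """Additive white Gaussian noise rescaled so the realized SNR is exact."""
    x = _data(t)
    sig = ho_norm(x)
    if sig == 0:
        raise ValueError("cannot set an SNR for a zero-norm tensor")
    rng = np.random.default_rng(seed)
    n = _draw(rng, x.shape, np.iscomplexobj(x))
    n *= sig / ho_norm(n) * 10 ** (-snr_db / 20)
    return Tensor3(x + n)


def _cp_from_factors(factors) -> Tensor3:
    return Tensor3(np.einsum("ir,jr,kr->ijk", *factors))


# ---------------------------------------------------------------------------
# error measures


def _scaled_colwise_error(fh, f):
    """||a_r fh_r - f_r||^2 summed over columns, with the optimal complex a_r."""
    num = np.einsum("ir,ir->r", fh.conj(), f)
    den = np.einsum("ir,ir->r", fh.conj(), fh).real
    a = np.where(den == 0, 0.0, num / np.where(den == 0, 1, den))
    diff = fh * a - f
    return float(np.sum(np.abs(diff) ** 2))


def tsfe(estimated, truth) -> float:
    """Total squared factor error after resolving permutation and column scaling.

    (1/N) sum_n min_P ||Fhat_n P - F_n||_F^2 / ||F_n||_F^2 with one permutation
    shared across all modes (the CP components are paired across modes) and the
    per-column complex scaling resolved before the norm.
    """
    estimated = [np.asarray(f) for f in estimated]
    truth = [np.asarray(f) for f in truth]
    if len(estimated) != len(truth):
        raise ValueError("factor lists must have the same length")
    r = truth[0].shape[1]
    for fh, f in zip(estimated, truth):
        if fh.shape != f.shape:
            raise ValueError("factor shapes must match")
    best = np.inf
    for perm in itertools.permutations(range(r)):
        perm = list(perm)
        total = 0.0
        for fh, f in zip(estimated, truth):
            total += _scaled_colwise_error(fh[:, perm], f) / np.linalg.norm(f) ** 2
        best = min(best, total)
    return best / len(truth)


def ccdf(samples) -> pd.DataFrame:
    """Empirical complementary CDF evaluated at the sorted sample points."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("need at least one sample")
    thresholds = np.sort(samples)
    frac = (samples[None, :] > thresholds[:, None]).mean(axis=1)
    return pd.DataFrame({"threshold": thresholds, "ccdf": frac})


# ---------------------------------------------------------------------------
# experiment designs


def _model_factors(model: CPModel):
    f1, f2, f3 = model.factors
    return [f1 * model.amplitudes, f2, f3]


def _coupled_tensors(f1, f2s, f3s):
    t1 = _cp_from_factors([f1, f2s[0], f3s[0]])
    t2 = _cp_from_factors([f1, f2s[1], f3s[1]])
    return t1, t2


def _tsfe_pair(res_models, truths):
    """Mean TSFE over the two tensors of a coupled estimate."""
    vals = []
    for model, truth in zip(res_models, truths):
        vals.append(tsfe(_model_factors(model), truth))
    return float(np.mean(vals)), vals


def _gen_coupled(seed, dims, rank, field="real", sine=False, rho3=(None, None)):
    """One coupled pair with shared first factor; returns (truth1, truth2, t1, t2)."""
    rng = np.random.default_rng(seed)
    complex_field = field == "complex"
    if sine:
        f1 = gen_sine_signatures(n_samples=dims[0])
    else:
        f1 = _draw(rng, (dims[0], rank), complex_field)
    f2s, f3s = [], []
    for i in range(2):
        f2s.append(_draw(rng, (dims[1], rank), complex_field))
        if rho3[i]:
            f3s.append(_correlated(rng, dims[2], rank, rho3[i], complex_field))
        else:
            f3s.append(_draw(rng, (dims[2], rank), complex_field))
    t1, t2 = _coupled_tensors(f1, f2s, f3s)
    return ([f1, f2s[0], f3s[0]], [f1, f2s[1], f3s[1]], t1, t2)


def _design_reliability_vs_rank(config, rows):
    dims = tuple(config.get("dims", (8, 8, 8)))
    true_rank = config.get("true_rank", 3)
    snrs = config.get("snr_db", (-0.5, 0.0, 5.0))
    assumed = config.get("assumed_ranks", (2, 3, 4, 5, 6))
    n_real = config["realizations"]
    seed = config["seed"]
    ss = np.random.SeedSequence([seed, 101])
    child = ss.generate_state(2 * n_real * len(snrs)) % (2**31)
    idx = 0
    for snr in snrs:
        for real in range(n_real):
            truth1, truth2, t1, t2 = _gen_coupled(int(child[idx]), dims, true_rank)
            n1 = add_noise_at_snr(t1, snr, int(child[idx + 1]))
            n2 = add_noise_at_snr(t2, snr, int(child[idx + 1]) + 1)
            idx += 2
            for r in assumed:
                res = csecsi(n1, n2, r)
                rows.append({"design": "reliability_vs_rank", "method": "csecsi",
                             "realization": real, "snr_db": snr, "assumed_rank": r,
                             "metric": "reliability", "value": res.reliability})


def _design_rank_mismatch(config, rows):
    dims = tuple(config.get("dims", (8, 8, 8)))
    ranks = tuple(config.get("true_ranks", (4, 2)))
    shared = config.get("shared_components", min(ranks))
    snr = config.get("snr_db", 25.0)
    assumed = config.get("assumed_ranks", (2, 3, 4, 5, 6))
    n_real = config["realizations"]
    seed = config["seed"]
    ss = np.random.SeedSequence([seed, 202])
    child = ss.generate_state(2 * n_real) % (2**31)
    for real in range(n_real):
        rng = np.random.default_rng(int(child[2 * real]))
        r_max = max(ranks)
        f1 = rng.standard_normal((dims[0], r_max))
        tensors = []
        for i, r_i in enumerate(ranks):
            cols = np.arange(shared).tolist() + list(range(shared, r_i)) if i == 1 else list(range(r_i))
            f1_i = f1[:, cols[:r_i]]
            f2 = rng.standard_normal((dims[1], r_i))
            f3 = rng.standard_normal((dims[2], r_i))
            tensors.append(_cp_from_factors([f1_i, f2, f3]))
        n1 = add_noise_at_snr(tensors[0], snr, int(child[2 * real + 1]))
        n2 = add_noise_at_snr(tensors[1], snr, int(child[2 * real + 1]) + 1)
        for r in assumed:
            res = csecsi(n1, n2, r)
            rows.append({"design": "rank_mismatch", "method": "csecsi",
                         "realization": real, "snr_db": snr, "assumed_rank": r,
                         "metric": "reliability", "value": res.reliability})


def _als_models(model):
    return [model.model(1), model.model(2)]


def _apply_methods(methods, n1, n2, rank, truths, rows, base, extra_methods=None):
    for name in methods:
        if name == "csecsi":
            res = csecsi(n1, n2, rank)
            models = res.selected
        elif name == "secsi":
            models = [secsi(n1, rank), secsi(n2, rank)]
        elif name == "c-als":
            models = _als_models(coupled_als(n1, n2, rank))
        elif name == "c-als-normalized":
            models = _als_models(coupled_als_normalized(n1, n2, rank))
        elif extra_methods and name in extra_methods:
            models = extra_methods[name](n1, n2, rank)
        else:
            raise ValueError(f"unknown method '{name}'")
        mean_err, per = _tsfe_pair(models, truths)
        rows.append({**base, "method": name, "metric": "tsfe", "value": mean_err})
        for i, v in enumerate(per, start=1):
            rows.append({**base, "method": name, "metric": f"tsfe_{i}", "value": v})


def _design_ccdf_collinear(config, rows, extra_methods=None):
    dims = tuple(config.get("dims", (40, 4, 10)))
    rank = config.get("rank", 3)
    rho = config.get("rho", 0.9)
    snr = config.get("snr_db", 25.0)
    methods = config.get("methods", ("csecsi", "c-als"))
    n_real = config["realizations"]
    seed = config["seed"]
    ss = np.random.SeedSequence([seed, 303])
    child = ss.generate_state(2 * n_real) % (2**31)
    for real in range(n_real):
        truth1, truth2, t1, t2 = _gen_coupled(int(child[2 * real]), dims, rank,
                                              sine=True, rho3=(rho, rho))
        n1 = add_noise_at_snr(t1, snr, int(child[2 * real + 1]))
        n2 = add_noise_at_snr(t2, snr, int(child[2 * real + 1]) + 1)
        base = {"design": "ccdf_collinear", "realization": real, "snr_db": snr,
                "assumed_rank": rank}
        _apply_methods(methods, n1, n2, rank, (truth1, truth2), rows, base, extra_methods)


def _design_secsi_vs_csecsi(config, rows, extra_methods=None):
    dims = tuple(config.get("dims", (40, 4, 10)))
    rank = config.get("rank", 3)
    rho = config.get("rho", 0.98)
    snr = config.get("snr_db", 25.0)
    sine = config.get("sine", dims[0] == 40)
    methods = config.get("methods", ("csecsi", "secsi"))
    n_real = config["realizations"]
    seed = config["seed"]
    ss = np.random.SeedSequence([seed, 404])
    child = ss.generate_state(2 * n_real) % (2**31)
    field = config.get("field", "real")
    for real in range(n_real):
        truth1, truth2, t1, t2 = _gen_coupled(int(child[2 * real]), dims, rank,
                                              field=field, sine=sine, rho3=(None, rho))
        n1 = add_noise_at_snr(t1, snr, int(child[2 * real + 1]))
        n2 = add_noise_at_snr(t2, snr, int(child[2 * real + 1]) + 1)
        base = {"design": "secsi_vs_csecsi", "realization": real, "snr_db": snr,
                "assumed_rank": rank}
        _apply_methods(methods, n1, n2, rank, (truth1, truth2), rows, base, extra_methods)


def _design_unequal_noise(config, rows, extra_methods=None):
    dims = tuple(config.get("dims", (3, 8, 7)))
    rank = config.get("rank", 3)
    snr1 = config.get("snr1_db", 30.0)
    snr2_list = config.get("snr2_db", (0.0, 30.0, 60.0))
    methods = config.get("methods", ("csecsi", "c-als", "c-als-normalized"))
    n_real = config["realizations"]
    seed = config["seed"]
    ss = np.random.SeedSequence([seed, 505])
    child = ss.generate_state(2 * n_real * len(snr2_list)) % (2**31)
    idx = 0
    for snr2 in snr2_list:
        for real in range(n_real):
            truth1, truth2, t1, t2 = _gen_coupled(int(child[idx]), dims, rank,
                                                  field="complex")
            n1 = add_noise_at_snr(t1, snr1, int(child[idx + 1]))
            n2 = add_noise_at_snr(t2, snr2, int(child[idx + 1]) + 1)
            idx += 2
            base = {"design": "unequal_noise", "realization": real,
                    "snr_db": snr2, "assumed_rank": rank}
            _apply_methods(methods, n1, n2, rank, (truth1, truth2), rows, base,
                           extra_methods)


DESIGNS = {
    "reliability_vs_rank": _design_reliability_vs_rank,
    "rank_mismatch": _design_rank_mismatch,
    "ccdf_collinear": _design_ccdf_collinear,
    "secsi_vs_csecsi": _design_secsi_vs_csecsi,
    "unequal_noise": _design_unequal_noise,
}


def run_experiment(config: dict, extra_methods: dict | None = None) -> BenchmarkResult:
    """Run one built-in design; fully reproducible given (design, seed, realizations).

    ``config`` needs at least ``design``, ``seed`` and ``realizations``; each
    design documents its further keys.  ``extra_methods`` maps names to
    callables ``(t1, t2, rank) -> [model1, model2]`` for external backends.
    """
    config = dict(config)
    design = config.get("design")
    if design not in DESIGNS:
        raise ValueError(f"unknown design '{design}'; choose from {sorted(DESIGNS)}")
    config.setdefault("realizations", 200)
    config.setdefault("seed", 0)
    rows = []
    fn = DESIGNS[design]
    if design in ("reliability_vs_rank", "rank_mismatch"):
        fn(config, rows)
    else:
        fn(config, rows, extra_methods)
    return BenchmarkResult(design, pd.DataFrame(rows), config)
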