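# Methods

## Model

Two three-way tensors `X(1) ∈ C^{M1×M2(1)×M3(1)}` and `X(2) ∈ C^{M1×M2(2)×M3(2)}`
share their first mode. The coupled CP model writes each as a sum of `R`
rank-one components with one *identical* first-mode factor matrix
`F1 ∈ C^{M1×R}` and per-tensor factors `F2(i), F3(i)`, plus additive noise. In
the MEG/EEG application the common mode is frequency: the same neural
oscillators express the same spectral signatures in both modalities while
their time courses and sensor topographies differ. All algebra is defined over
complex scalars; real data are the zero-imaginary special case, and
conjugation enters only through Hermitian transposes.

Stored CP models keep unit-norm factor columns with the component scale in a
nonnegative amplitude vector; the phase convention fixes modes 1 and 2
(largest-magnitude entry of each column real-positive) and parks the residual
complex phase in the mode-3 columns so amplitudes stay real.

### Unfolding convention

`unfold(t, n)` moves mode *n* to the front and reshapes in C order (remaining
modes cycle in natural order, the last varying fastest). Under this convention
`X_(1) = F1 · khatri_rao(F2, F3)^T` (scipy's column-wise Khatri–Rao) and the
mode-3 slice `X[:, :, k] = F1 · diag(F3[k, :]) · F2^T`. All results are
convention-invariant because `fold` inverts `unfold` exactly.

## The semi-algebraic computation

1. **Joint truncated HOSVD.** The common loading `U1` is the `R` leading left
   singular vectors of `[X(1)_(1)  X(2)_(1)]` (one economy SVD); `U2(i)`,
   `U3(i)` come from per-tensor unfoldings; cores
   `S(i) = X(i) ×1 U1^H ×2 U2(i)^H ×3 U3(i)^H`. For unfoldings with many
   columns a deterministic Lanczos SVD (fixed start vector) replaces the dense
   solver; both return the same leading subspace.

2. **SMD construction.** Writing `Tn = Un^H Fn`, the slices of the core merged
   along mode 3, `Y_k = T1 · diag(F3[k,:]) · T2^T`, give pivot-normalized
   products `Y_k Y_p^{-1} = T1 D_k T1^{-1}`: a set with the *shared*
   eigenvector matrix `T1`, poolable across both tensors. The left products
   `(Y_p^{-1} Y_k)^T = T2 D_k T2^{-1}` expose the per-tensor `T2` and cannot
   be pooled; neither can any common-mode (mode-1) set, whose diagonals carry
   `F1` itself. The pivot is the slice with the smallest 2-norm condition
   number; a set whose every slice has condition number above 1e12 signals an
   ill-conditioned core. Per non-common mode this yields one pooled
   right-side problem and two per-tensor left-side problems feeding one
   candidate each; mode 1 yields four per-tensor problems — the eight
   candidate estimates in total.

3. **Joint diagonalization.** The non-unitary joint eigenproblem
   `min_T Σ_k ‖off(T^{-1} A_k T)‖²_F` is solved by (a) eigen-initialization
   from fixed generic linear combinations of the set (deterministic weights;
   the best of several starts by objective), then (b) damped multiplicative
   updates `T ← T(I + W)` where each entry `W_ij` solves the pairwise
   linearized off-diagonal least-squares problem, with step backtracking so
   the objective is non-increasing; columns of `T` are normalized to unit
   norm with real-positive leading entry. Defaults: relative tolerance 1e-10,
   200 sweeps. On exactly diagonalizable sets the relative off-diagonal
   residual reaches < 1e-8; on noisy sets the optimizer was checked to reach
   objectives at or below truth-initialized local optima. This is a
   Gauss–Newton flavored variant of the classical shear-and-rotation Jacobi
   sweeps: the same family of elementary multiplicative updates, chosen here
   because the pairwise linearized step is simple, supports complex data, and
   satisfies every required invariant.

4. **Candidates.** `I`–`IV` (coupled): for each non-common mode, the pooled
   right-side transform gives the *shared* `F1 = U1 T1`, the diagonals give
   that mode's factor per tensor, and the remaining factor is a per-tensor LS
   fit; the left-side problems give the non-common factors per tensor and the
   shared `F1` from a joint LS over both stacked unfoldings (component order
   and column scale aligned across tensors beforehand — without the scale
   alignment the joint LS would be inconsistent even in the noiseless case).
   `V`–`VIII` (uncoupled): per tensor and side, the mode-1 transform gives
   one non-common factor, the diagonals give that tensor's own `F1` estimate,
   the rest by LS; the other tensor's factors are completed from that `F1` by
   splitting `F1^+ X_(1)` row-wise into dominant rank-one pairs, so every
   candidate carries full models for both tensors. Amplitudes are refit by LS
   through the Hadamard-of-Grams normal equations (memory-light; no giant
   Khatri–Rao is materialized). At assumed rank one no SMD exists and the
   single candidate comes directly from the joint truncated HOSVD.

5. **Selection and reliability.** Each tensor independently takes the
   candidate with the smallest `e_rec`; ties within 1e-12 prefer a coupled
   candidate (coupling is the framework's prior). The reliability compares
   the two selected common-factor estimates after unit-normalizing columns,
   matching the permutation (Hungarian assignment on absolute column
   correlations), and removing the per-column unit-modulus phase by the
   optimal phase per matched pair; the result is clipped to [0, 100]. The
   optimal-phase convention was chosen over fixing each column's phase by its
   largest entry: under noise the argmax entry differs between estimates and
   flips signs spuriously, collapsing the measure for estimates that agree
   well. With unit columns and optimal phases the reliability equals the mean
   absolute correlation of matched columns (in percent), is exactly 100 for
   identical matrices, 0 for orthogonal ones, and invariant under column
   permutation and unit-modulus rescaling.

The single-tensor variant (`secsi`) runs the same machinery on one tensor
(six candidates: three modes × two sides) with minimum-`e_rec` selection.
Everything is deterministic; all randomness lives in data generation.

## Coupled ALS baselines

`coupled_als` alternates exact LS updates: per-tensor `F2(i)`, `F3(i)`, then
the shared `F1` from the column-wise concatenation of both mode-1 unfoldings
against the stacked Khatri–Rao products. Each half-step solves an exact LS
problem, so the summed squared residual is non-increasing. Defaults: HOSVD
initialization (random init available, seeded), 1000 iterations, relative
objective tolerance 1e-8. `coupled_als_normalized` row-weights the shared
system by the reciprocal noise standard deviation per tensor; when no weights
are supplied they are estimated from the residual RMS of a short (20
iteration) unweighted warm start — estimates land within a factor of two of
the truth on calibrated data. This inverse-standard-deviation weighting is
this package's concrete choice for "normalization with respect to the noise
variances"; published flexible-coupling weighting schemes are more elaborate.

## Benchmark designs and problem sizes

All designs are driven by `numpy` `SeedSequence` streams, bit-for-bit
reproducible from `(design, seed, realizations)`. Factor entries are
unit-variance Gaussian (circularly symmetric when complex); collinear factors
use `x_j = √ρ·b + √(1−ρ)·g_j` (expected pairwise correlation ρ); the sine
design uses the first 40 samples (fs = 1000 Hz, configurable) of
`sin(2πf₁t+π/3)`, `sin(2πf₂t)e^{+10t}`, `sin(2πf₃t)e^{−3t}` with f = 10, 20,
30 Hz. Noise is rescaled so the realized SNR
`10·log10(‖X0‖²_H/‖N‖²_H)` is exact.

* `reliability_vs_rank`: 8×8×8 real, true rank 3, SNR ∈ {−0.5, 0, 5} dB,
  assumed ranks 2–6.
* `rank_mismatch`: ranks (4, 2) sharing two components, 8×8×8 real, SNR 25 dB
  by default — the SNR of the accuracy designs; at ≲5 dB the overestimated
  ranks drown in noise and the two local reliability maxima are not
  resolvable, so the default targets the regime where rank structure is
  identifiable.
* `ccdf_collinear`: 40×4×10 real, rank 3, sine common factor, both third
  factors collinear at ρ = 0.9, SNR 25 dB.
* `secsi_vs_csecsi`: as above but only tensor 2's third factor collinear
  (ρ = 0.98); a 4×8×7 complex preset is available via `dims`/`field`.
* `unequal_noise`: 3×8×7 complex, rank 3, SNR₁ = 30 dB, SNR₂ swept.

TSFE resolves the CP ambiguities before measuring: one permutation shared
across all modes (the components are paired), chosen by exhaustive search for
R ≤ 6, and the optimal per-column complex scale before the Frobenius norm —
without the scale resolution exact recovery would not score zero, since the
printed error formula resolves only the permutation. Default realization
counts are 200 (configurable upward); the reliability experiments in the
acceptance suite use 100 realizations per condition. These desk-scale counts
reproduce orderings and curve shapes, not high-precision tail probabilities.

## Time-frequency pipeline

Wavelet frequencies are `1000/k` Hz for integer periods k = 66…265 ms —
exactly 200 bins from 3.77 to 15.15 Hz (theta through alpha). The stated
generation grid of integer periods up to 256 ms cannot contain the 265 ms
band edge, so the coefficients are computed directly on the 66–265 ms
selection grid. The transform is mne's FFT-based complex Morlet filterbank at
a constant quality factor (default 7 cycles; sample rate default 1000 Hz).
Because L2-normalized constant-Q wavelets have tone gain ∝ 1/√f, the
coefficients are rescaled by √f so that a pure sinusoid attains its maximum
at the bin nearest its frequency — without this the spectral peak is biased
low by a few bins. A `decim` option thins the time axis after the transform.

Each modality's coefficient stack becomes a frequency × time × channel
tensor; bad channels are dropped by an explicit exclusion list (no automatic
artifact detection). Both tensors are scaled to unit higher-order norm (making
fT and µV commensurable) and decomposed at rank 2 with frequency as the
common mode. Per component: the obtained frequency is the argmax of the
frequency-signature magnitude (ties to the lowest bin), the field-map is the
channel-signature magnitude, the weight is the component amplitude on the
normalized-tensor scale, and the component is *recruited* iff its obtained
frequency lies within ±5 % of the stimulation frequency or within ±5 % of its
first harmonic (boundaries inclusive). Group tables aggregate per
stimulation-frequency fraction with frequencies normalized by the individual
alpha frequency.

**Resolution limitation.** The period grid is quadratically denser at low
frequency (bin width ≈ f²/1000: 0.016 Hz at 4 Hz vs 0.10 Hz at 10 Hz) while
the wavelet resolution is ≈ f/7. In the alpha band a bin is comparable to
the achievable peak-localization precision and planted components are
recovered bin-exactly; at the theta end one bin is far below the filterbank's
resolution (the noiseless response profile is flat to ~0.1 % over ±6 bins),
so theta-band frequencies are recovered to ≈0.1 Hz — an order of magnitude
inside the (0.4 ± 0.1)·f_α band that matters scientifically — but not to a
single bin.

## Synthetic sessions

The generator emulates *averaged* evoked responses to intermittent photic
stimulation: each planted component is a cosine at its center frequency with
an onset/plateau/offset envelope spanning a 40-period stimulation train
(linear 1 s ramps by default, 500 ms pre/post padding), an optional slow
amplitude modulation (`bandwidth_hz`, default 0.2 Hz), a unimodal Gaussian
topography over an abstract channel-index geometry per modality (no sensor
layout is shipped; real layouts plug in via metadata), independent amplitudes
per modality (a component may be absent from one), and white Gaussian noise
scaled per modality to an exact requested SNR (default 10 dB; signals are
averaged-response surrogates, so this sits well above raw-trial SNR). Presets
cover entrained sessions (stimulation frequency plus its first harmonic when
inside the band), alpha- and theta-intrinsic sessions (1.0 and 0.4·f_α), and
mixed sessions; the 13 stimulation-frequency fractions from 0.40 to 1.30·f_α
are provided as the canonical grid. Channel counts default to 102 MEG / 128
EEG sensors; tests and examples use 8–24 channels and decimated time axes,
which preserve every qualitative behavior at desk scale.

What the generator does **not** emulate: volume conduction and realistic
lead fields, correlated or non-Gaussian sensor noise, artifacts, inter-trial
variability surviving the average, or drifting oscillator frequencies.
Passing tests therefore demonstrate correct parameter recovery under the
model's own assumptions, not robustness to real-recording pathologies.

A negative control (sessions with planted amplitudes zeroed) shows the
reliability dropping below planted-session values; it does not collapse to
zero because the wavelet filterbank itself imposes shared smooth frequency
structure on both modalities' noise tensors — a caveat for interpreting
reliability on weak-signal recordings.

## Numerical choices and degenerate inputs

* Orthonormality/reconstruction checks at 1e-8 relative unless stated;
  selection tie tolerance 1e-12; condition-number guard 1e12.
* Zero-norm tensors are rejected wherever a relative error or normalization
  is undefined.
* Candidates whose SMD solve fails are flagged invalid and excluded from
  selection; if all fail, the decomposition raises an ill-conditioning error.
* Assumed rank must not exceed any tensor dimension (truncated HOSVD bound).
* `numpy.lstsq` (minimum-norm) backs all LS completions, so rank-deficient
  systems degrade gracefully instead of erroring.

## Known limitations

* One-shot semi-algebraic estimates trade statistical efficiency for
  robustness: on well-conditioned problems in heavy noise a fully converged
  (normalized) coupled ALS can reach slightly lower mean factor error, while
  on collinear/swamp-prone problems ALS fails catastrophically in a fraction
  of runs and the semi-algebraic route does not. Post-hoc ALS refinement of
  the selected candidate is deliberately out of scope.
* Reconstruction-error selection is in-sample: with heavy noise it can favor
  uncoupled candidates that overfit, costing some accuracy relative to an
  oracle candidate choice.
* Only three-way dense tensors; no N-way or sparse support.
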