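# csecsi — coupled semi-algebraic CP decomposition for MEG/EEG tensors

Simultaneously recorded MEG and EEG see the same cortical oscillators through
different physics, units and sensor counts. When both recordings are expanded
into complex Morlet time-frequency tensors (frequency × time × channel), the
two tensors share their frequency content but nothing else — the natural model
is a **coupled canonical polyadic (CP) decomposition**: two three-way tensors
constrained to one identical factor matrix along the common (frequency) mode,

```
X(1) = Σ_r  f1_r ∘ f2_r(1) ∘ f3_r(1) + N(1)
X(2) = Σ_r  f1_r ∘ f2_r(2) ∘ f3_r(2) + N(2)
```

with shared frequency signatures `f1_r` and per-modality time signatures and
channel topographies. This package implements the **C-SECSI** framework for
computing that decomposition semi-algebraically, together with the simulation
benchmarks that characterize it and a photic-driving (flicker-stimulation)
analysis pipeline built on it.

The method, in brief:

1. **Joint truncated HOSVD** — one economy SVD of the column-wise
   concatenation of both mode-1 unfoldings gives the common subspace; modes 2
   and 3 are truncated per tensor (cores `S(i)`).
2. **Simultaneous matrix diagonalizations (SMDs)** — pivot-normalized slice
   products of the merged cores are jointly diagonalizable; the sets from the
   two non-common modes can be pooled across tensors (their shared transform
   reveals the common factor), the common-mode sets cannot and are solved per
   tensor.
3. **Eight candidate factor sets** (`I`–`IV` coupled, `V`–`VIII` uncoupled)
   assembled from transforms, diagonals and least-squares completions.
4. **Selection** — per tensor, the candidate with the smallest relative
   reconstruction error `e_rec = ‖X̂ − X‖²_H / ‖X‖²_H`.
5. **Reliability** — the percent similarity of the two selected common-factor
   estimates (permutation and per-column scaling resolved),
   `REL = (1 − ½‖F̂1(2)P − F̂1(1)‖²_F / ‖F̂1(1)‖²_F)·100`. It peaks when the
   assumed rank matches the true shared rank, so it doubles as a rank-control
   statistic; at rank one it is exactly 100 because no SMD is needed.

Coupled ALS baselines (plain and noise-variance-weighted), the benchmark
designs (rank control, rank mismatch, collinear/swamp robustness, unequal
noise), and a ground-truth synthetic MEG-EEG session generator are included.

## Worked example

```python
import numpy as np
from csecsi import CoupledCP, Tensor3, add_noise_at_snr

rng = np.random.default_rng(0)
f1 = rng.standard_normal((8, 3))          # shared factor, rank 3
t = []
for i in range(2):
    f2 = rng.standard_normal((8, 3))
    f3 = rng.standard_normal((8, 3))
    clean = Tensor3(np.einsum("ir,jr,kr->ijk", f1, f2, f3))
    t.append(add_noise_at_snr(clean, 20.0, seed=i))

res = CoupledCP(t[0], t[1]).fit(rank=3)
print(res.summary())
```

```
Coupled CP decomposition (semi-algebraic, REC PS selection)
============================================================
assumed rank:        3
reliability:         99.95 %
selected candidates: ('V', 'VIII')
residual e_rec:      (8.463e-03, 8.626e-03)

Candidate table:
label  coupled  valid  e_rec_1  e_rec_2
    I     True   True 0.008582 0.008987
   II     True   True 0.008839 0.009023
  III     True   True 0.008848 0.008887
   IV     True   True 0.008778 0.008916
    V    False   True 0.008463 0.009627
   VI    False   True 0.008485 0.009627
  VII    False   True 0.009488 0.008648
 VIII    False   True 0.009488 0.008626
```

All eight candidates fit near the 20 dB noise floor (`e_rec ≈ 0.009 ≈
10^(−20/10)`); each tensor independently picked an uncoupled candidate, yet
the two common-factor estimates agree to 99.95 % — the coupling is real. A
rank sweep shows the reliability-based rank control:

```python
print(CoupledCP(t[0], t[1]).rank_sweep([1, 2, 3, 4]).to_string(index=False))
```

```
 rank  reliability  e_rec_1  e_rec_2  best
    1   100.000000 0.158009 0.290984 False
    2    97.725457 0.096873 0.106364 False
    3    99.951996 0.008463 0.008626  True
    4    91.967057 0.008487 0.007961 False
```

Rank 1 is trivially 100 % and excluded from the argmax; the reliability is
maximal at the true rank 3, where the residual also reaches the noise floor.

## Photic-driving pipeline

`csecsi.synthetic` generates coupled MEG-EEG sessions with known planted
oscillators (entrained at the stimulation frequency and/or intrinsic
alpha/theta components); `csecsi.tfr` turns multichannel signals into the
200-bin wavelet tensors (3.77–15.15 Hz, periods 66–265 ms);
`csecsi.pipeline.decompose_session` runs the rank-2 coupled decomposition and
classifies each component as recruited (obtained frequency within ±5 % of the
stimulation frequency or its first harmonic) or non-recruited. A command-line
interface mirrors the library:

```sh
csecsi simulate --preset entrained --f-alpha 10 --fraction 0.55 --seed 1 --out sess/
csecsi pipeline --session sess/ --decim 10 --out out/
csecsi benchmark --design ccdf_collinear --realizations 200 --seed 0 --out bench/
csecsi decompose --t1 a.h5 --t2 b.h5 --rank 2 --out dec/
```

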