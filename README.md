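# synergylab

Neuromechanics analysis of balance-recovery lunges: lunge-cycle
segmentation from force-plate and marker data, surface-EMG envelope
processing and coactivation indices, muscle-synergy extraction by Gaussian
non-negative matrix factorization, spatiotemporal primitive metrics, and
sagittal-plane joint kinematics and inverse dynamics. The package is aimed
at motor-control and biomechanics researchers who record multirate trials
(3-D markers at ~250 Hz, 13-channel EMG and triaxial ground reaction force
at 1 kHz) of stepping or lunging tasks and want a tested, reproducible
implementation of the full processing chain. Because raw participant
recordings of this kind are rarely shared, every stage is exercised against
a bundled synthetic-trial generator with known ground truth.

## The model

Concatenated, normalized EMG envelopes form a non-negative matrix
**V** (m × n, m = 13 muscles). Muscle synergies factorize it as

    V ≈ V_R = W H

with **W** (m × r) the non-negative *motor modules* (time-invariant muscle
weightings) and **H** (r × n) the non-negative *motor primitives*
(time-dependent activation coefficients), fitted by multiplicative updates

    H ← H ⊙ (WᵀV) ⊘ (WᵀW H),   W ← W ⊙ (V Hᵀ) ⊘ (W H Hᵀ)

until the relative change of R² = 1 − ‖V − WH‖²_F / ‖V − mean(V)‖²_F over
the last 20 iterations drops below 0.01%. Each rank is fitted from 10
random restarts (best R² kept); the model order is selected from the
R²-vs-rank curve over ranks 1..round(0.75 m) by repeatedly dropping the
lowest-rank point of a straight-line fit until the fit MSE falls below
10⁻⁵. Primitives are summarized by their **center of activity**
(CoA — circular mean of the primitive treated as a mass distribution on
the cycle circle, θ_t = 2π(t−1)/n, CoA = atan2(Σ sinθ_t H_t, Σ cosθ_t H_t)
mapped back to cycle points) and **full width at half maximum** (FWHM —
points above half of the minimum-subtracted maximum), and classified
across trials by shape clustering into fundamental (single-peaked) swing,
touchdown, weight-acceptance and stabilization synergies or combined
blends.

Cycles run from lift-off (foot acceleration-and-jerk rule on the
fifth-metatarsal trace) through touchdown (first non-zero GRF) to the
knee-angle steady state (divisive energy-statistic change-point detection
on the post-flexion slope), and are time-normalized to 200 points — 50
swing, 150 stance.

## Worked example

```python
import numpy as np
from synergylab import (SyntheticSpec, generate_envelopes, select_rank,
                        nmf, compute_coa, compute_fwhm)

spec = SyntheticSpec(seed=7)          # 4 synergies at points 25/60/85/120,
v, truth = generate_envelopes(spec)   # sigma 6, 25 cycles, noise sd 0.05
rank, curve = select_rank(v, seed=7)
dec = nmf(v, rank=rank, seed=7)
coas = sorted(compute_coa(p) for p in dec.mean_primitives())
print(rank, round(dec.r2, 3))
print([round(c, 1) for c in coas])
print([compute_fwhm(p) for p in dec.mean_primitives()])
```

prints

```
4 0.966
[25.4, 61.7, 83.6, 117.6]
[14, 14, 14, 15]
```

i.e. the model-order search recovers the four generative synergies with
96.6% reconstruction, the centers of activity land within ~2.5 normalized
points of the generative centers (25/60/85/120), and the FWHM of 14–15
points matches the analytic width 2√(2 ln 2)·σ ≈ 14.1 of the σ = 6
generative primitives.

A command-line interface covers the same stages over trial files:

```
synergy-lab simulate --seed 4 --n-cycles 25 --out trials/
synergy-lab segment  --in trials/S01_forward_stable.tsv --out events.json
synergy-lab emg      --in trials/S01_forward_stable.tsv --events events.json --out env.tsv
synergy-lab synergies --in env.tsv --seed 2 --out syn/
synergy-lab kinetics --in trials/S01_forward_stable.tsv --events events.json --out joints.tsv
synergy-lab run      --config run.yaml
```

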