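# nicdclock

Tools for studying how the cell cycle shapes Notch signalling and the
somitogenesis segmentation clock. The package implements a mechanistic
model in which the Notch intracellular domain (NICD) is phosphorylated in
its PEST degron only while CDK2 (G1/S) or CDK1 (late G2/M) is active, and
phosphorylated NICD (pNICD) is degraded much faster than the
unphosphorylated form — so NICD levels dip twice per cell cycle. On top of
the single-cell model it provides population-level "virtual experiments"
(double-thymidine release time courses, 3 h drug treatments read out as
Western-blot-style fold changes, FACS-style DNA-content gating), a
Kuramoto phase-coupled-oscillator model of the posterior presomitic
mesoderm whose natural frequencies are anti-correlated with NICD, and the
somite-size statistics used to detect treatment-induced somite enlargement
(log2 fold changes of successive somite lengths, paired t-tests vs DMSO).

It is aimed at quantitative/developmental biologists who want to simulate
these protocols with known ground truth, calibrate the kinetic rates to
band-intensity time courses, or analyse somite-boundary measurements.

## Model

Per cell, with cycle position θ advancing at unit speed on a cycle of
length T:

```
dn/dt = α − (k_base + k₂·a₂(θ) + k₁·a₁(θ))·n − δₙ·n
dp/dt =     (k_base + k₂·a₂(θ) + k₁·a₁(θ))·n − δₚ·p,   δₚ ≥ δₙ
```

where a₂, a₁ are the CDK2/CDK1 activity windows (boxcar by default) and
total NICD, n + p, is what a blot lane measures. Population averages over
synchronized or asynchronous ensembles give the virtual readouts. Drugs
enter as parameter maps: γ-secretase inhibition (LY411575) sets α = 0,
NEDDylation inhibition (MLN4924) sets δₚ = δₙ, CDK1/CDK2 inhibitors scale
k₁ or k₂ by (1 − inhibition). The PSM clock is a mean-field Kuramoto
ensemble, dφᵢ/dt = ωᵢ + (K/N)Σⱼ sin(φⱼ − φᵢ), with
ωᵢ = ω_ref·max(ε, 1 − β·(NICDᵢ − NICD_ref)/NICD_ref). Somite statistics
follow the boundary-series definitions S_j = b_j − b_{j−1},
r_j = S_j/S_{j+1}, log2(r_j), with position +1 the last-formed somite.

## Worked example

```python
import numpy as np
from nicdclock import (run_release_experiment, run_treatment_experiment,
                       cdk_inhibition_shift, modal_phase)

tc = run_release_experiment(n_cells=1000, seed=1)
for t, tot, fr in zip(tc.times, tc.mean_total, tc.phase_fractions):
    print(f"{t:5.1f} h  total NICD {tot:5.3f}  modal phase {modal_phase(fr)}")
```

```
  0.0 h  total NICD 1.727  modal phase G1
  2.0 h  total NICD 0.442  modal phase S
  4.0 h  total NICD 0.413  modal phase S
  6.0 h  total NICD 1.130  modal phase G2
  8.0 h  total NICD 0.562  modal phase G2
 10.0 h  total NICD 0.898  modal phase G1
 12.0 h  total NICD 1.557  modal phase G1
```

The synchronized population moves G1 → S (2–4 h) → G2 (6 h) → late G2/M
(8 h) → back to G1 (10–12 h), and population-mean total NICD dips twice —
during the CDK2 window (2–4 h) and again in the CDK1 window (8 h) — before
recovering.

```python
for drug in ("MLN4924", "PurvalanolB", "RO3306", "LY411575"):
    r = run_treatment_experiment(n_cells=1000, treatment=drug, seed=2)
    print(drug, round(r.fold_total, 2))
# MLN4924 2.02   PurvalanolB 1.28   RO3306 1.16   LY411575 0.08

control, treated, delta = cdk_inhibition_shift(seed=3)
print(f"clock period {control:.1f} -> {treated:.1f} min (delay {delta:.1f})")
# clock period 130.0 -> 147.3 min (delay 17.3)
```

Blocking pNICD degradation or CDK phosphorylation raises total NICD above
the DMSO control; blocking NICD production depletes it. Raising NICD in
the CDK2-window cells slows those oscillators and lengthens the locked
tissue period — the segmentation-clock delay.

A command-line interface exposes the same drivers
(`nicdclock simulate-release|simulate-treatment|simulate-clock|fit|
somite-stats|synth`, each with `--config/--seed/--out/--force`).

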