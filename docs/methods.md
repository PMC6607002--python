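# Methods

## Single-cell model

Each cell carries a cycle position θ ∈ [0, T) advancing at unit speed
(no birth/death bookkeeping; the population size is fixed), an
unphosphorylated NICD amount n and a phosphorylated amount p (arbitrary
units). The kinetics are linear:

    dn/dt = α − (k_eff(θ) + δₙ)·n
    dp/dt = k_eff(θ)·n − δₚ·p
    k_eff(θ) = k_base + k₂·a₂(θ) + k₁·a₁(θ)

with a₂, a₁ ∈ {0, 1} boxcar indicators of the CDK2 and CDK1 activity
windows. The model deliberately collapses the multi-site phospho-isoform
ladder into a single phosphorylated state and absorbs SCF/FBXW7
recruitment into the elevated degradation rate δₚ; production has no
transcriptional feedback. Phosphorylation conserves total NICD
instantaneously (dn/dt + dp/dt = α − δₙn − δₚp), so all cell-cycle
dependence of total NICD comes from routing material into the
faster-degrading pool.

## Default parameters

Cell cycle (hours): G1 7, S 5, G2 3, M 1 (T = 16), matching a fast
HEK293-like cycle in which a synchronized release shows an S-phase
majority at 2–4 h, G2 at 6 h, late G2/M at 8 h and G1 re-entry by 10 h.
Windows: CDK2 a₂ = 1 on [7, 11) (CyclinE/A–CDK2, G1/S boundary through
most of S); CDK1 a₁ = 1 on [13.5, 15.5). The CDK1 window was placed to
rise in late G2 — CyclinB/CDK1 activates before nuclear-envelope breakdown
— and to switch off at anaphase. With the default kinetics this is also
what produces the second population-NICD minimum at the 8 h sampling
point: because recovery (rate δₙ + k_base ≈ 0.55/h) is much slower than
the in-window collapse (≈ 4.55/h), a window starting at 14 h would push
the observed grid minimum to 10 h instead.

Double-thymidine arrest: release_point 6.5 h (late G1, just before G1/S),
positional dispersion 0.5 h, normal truncated at ±2 sd.

Kinetics (per hour unless noted): α = 1 au/h, δₙ = 0.35 (unphosphorylated
half-life ≈ 2 h), δₚ = 5, k₁ = k₂ = 4, k_base = 0.2. These give clear
fold changes in the 3 h treatment experiments and the two release minima
at the observed grid times; all are configurable and δₚ ≥ δₙ is enforced
as the model premise. Drug map: DMSO identity; LY411575 α′ = 0; MLN4924
δₚ′ = δₙ (the SCF route is removed but FBXW7-independent turnover is
retained, so total NICD stays bounded); Roscovitine/Purvalanol B/
GSK650394A k₂′ = (1 − inhibition)k₂; RO-3306 k₁′ likewise; DRB is mapped
onto the CDK2 channel (it inhibits CDK7/9; the assignment is a declared
simplification). Default inhibition 0.95, in line with the ≥ 94–99%
CDK2-inhibition figures reported for these compounds at assay
concentrations. λ-phosphatase is a readout transform only (the phospho
band is counted in the unphosphorylated band), matching its use on
lysates.

## Numerical integration

Under boxcar windows the system is linear with piecewise-constant
coefficients, so trajectories are propagated exactly: between consecutive
window crossings the closed-form solution (two real exponential modes,
with the δₚ → δₙ + k resonance handled by its t·e^{−λt} limit) is applied,
vectorised over cells in an event loop that advances every cell to its own
next crossing. This is machine-precision accurate and removes any
discontinuity error. The optional logistic-ramp windows (ramp_width > 0)
use LSODA at rtol 1e-8 / atol 1e-10 instead.

## Population experiments

Synchronized release starts every cell at the constant-kinase fixed point
for its arrest position (cells sat arrested far longer than the NICD
turnover time). Asynchronous cultures are drawn uniformly on the cycle —
the stationary phase distribution of a non-growing population — and burned
in for three full cycles before t = 0 so each cell sits on its periodic
orbit; the frozen per-position fixed point is *not* the stationary state
of a moving cell, and without burn-in the "stationary" control would drift
by ~20% over the first cycle. Treatment experiments dose a burned-in
culture for 3 h; control and treated arms share the population (same
seed), so the DMSO fold change is exactly 1 and the treatment effect is
isolated by pairing — mirroring the contralateral-half design of the
explant experiments.

The blot readout multiplies true (n, p) lane means by a shared lognormal
loading factor and per-band lognormal noise, then divides by a simulated
loading-control band; the loading factor cancels exactly and the
normalized band CV is √((1 + c²)² − 1) for band CV c. The FACS readout
maps θ to DNA content (1 in G1, linear 1→2 across S, 2 in G2/M), applies
lognormal measurement noise, and gates at 1.25/1.75. Hard gates assign
the outer quarters of S to the flanking gates, so gated fractions are
compared against the analytic gating expectation, not the raw phase
fractions — the same bias real PI histograms show, which is why
deconvolution models exist; none is implemented here (simple gating is a
documented deviation).

## Calibration

`NicdTimeCourseModel.fit()` minimises squared error between observed and
simulated mean-total curves (and mean-p when provided) over free rates in
log space (rates strictly positive), with box bounds, Latin-hypercube
multi-starts (default 16) and TRF least squares. The simulated population
(size and seed) is fixed across the fit so the objective is
deterministic. Standard errors come from the Gauss-Newton Jacobian at the
optimum. A flat-likelihood flag is raised when converged starts agree in
RSS to < 1e-6 (relative) while their estimates disperse by more than
1.5× — the degenerate-input contract for uninformative data. The fitting
target is the mean-total time course; fitting fold-change tables or phase
fractions instead would be possible but is not implemented.

## Segmentation clock

The posterior PSM is a mean-field Kuramoto ensemble (sinusoidal coupling —
the minimal phase-coupling choice consistent with locking onto an average
frequency). Frequencies come from static per-cell steady NICD levels
(cells frozen at their cycle positions for the clock simulation, the
"pool of oscillators" reading) through
ω = ω_ref·max(0.05, 1 − β·(NICD − NICD_ref)/NICD_ref), with NICD_ref the
control-population mean so the control tissue runs at ω_ref. Defaults:
ω_ref = 2π/130 rad/min, β = 0.5, N = 200, K = max(10·sd(ω), 0.2·mean(ω)).
The tissue period is 2π over the slope of a linear fit to the ensemble-
mean unwrapped phase after discarding the first 30% of the trajectory,
and requires the order parameter r > 0.5 throughout the retained window
(a DesynchronizationError names the measured r otherwise) and at least
five retained cycles. For narrow frequency dispersion the locked
frequency is the mean natural frequency to first order; mean period and
2π/mean-frequency then agree to O(sd²), and the mean-frequency statistic
is the one reported. CDK inhibition raises NICD in the affected cells,
lowers their ω, and *lengthens* the locked period — the delay observed
in drug-treated PSM explants; the implementation follows the
anti-correlation assumption and the experimental delay direction
throughout.

## Somite statistics

Boundary positions b_j are indexed from the posterior-most boundary
(j = 0) anteriorly; S_j = |b_j − b_{j−1}|, r_j = S_j/S_{j+1},
log2(r_j), with position +1 (j = 1) the last-formed somite. Group
comparisons pair treated and control samples by list order and report
mean ± SEM of the per-sample log2 fold change, a two-sided paired t-test,
and a normality check on the paired differences — Lilliefors by default
(mean and sd estimated from the data), with a fixed-parameter KS option.
No multiple-testing correction is applied across somite positions by
default. Zero-variance differences yield an indeterminate-p flag rather
than a number. Ratios are computed on unsigned lengths; series recorded
with anterior-decreasing coordinates are normalised on load.

## Synthetic data

The clock-and-wavefront generator sets somite length = clock period ×
wavefront regression speed (growth-rate modulation of the wavefront is
out of scope). A treatment multiplies the period by period_factor from
the (onset + commitment_lag)-th somite formed onward; commitment_lag
defaults to 3, encoding that the next three boundaries are already
specified in the anterior PSM when the drug arrives — so the enlargement
appears at position +1 but not +2 when four somites form after dosing.
Lengths carry lognormal noise (CV 0.1 default; lognormal everywhere for
positivity). Release-dataset and treatment-panel generators wrap the
experiment drivers with blot noise and always emit a ground-truth
sidecar; every generator is a pure function of (parameters, seed).

## Problem sizes and determinism

Default simulations use 1000 cells for release experiments (the timeline
readouts are insensitive to this from a few hundred cells up), 150–200
cells inside calibration objectives, N = 150–200 oscillators, and
1000–1500 simulated datasets for the type-I-error calibration of the
paired t-test. All randomness flows through numpy Generators seeded
explicitly; the CLI fans one global seed into named per-module
substreams, so identical (config, seed) runs are digest-identical.

## Known limitations

Two-state phosphorylation only; no explicit FBXW7 species or
ubiquitylation step; no cell division or population growth (the
asynchronous age distribution of an exponentially growing culture would
tilt the uniform weights by up to 2×); no spatial phase gradient, wave
patterns or Delta-Notch synchronisation mechanics in the clock model; no
image-level gel or in situ simulation. The synthetic generators emulate
multiplicative measurement noise and protocol structure but not
systematic artefacts (saturation, background, gel smile), so passing
recovery tests demonstrate correctness of the estimation machinery under
the stated noise model, not robustness to real blot pathology.
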