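# Methods

## Trapped-particle signal model

A particle held in an optical trap near its equilibrium experiences a
harmonic restoring force counterbalanced by thermal agitation. Its position
is modelled as an Ornstein–Uhlenbeck (OU) process with relaxation time
τ = γ/k, where k is the trap stiffness and γ = k_B·T/D the drag coefficient
(Einstein relation). Released from a deterministic position, the position
variance grows as

    σ²(t) = (k_B·T/k) · (1 − e^(−2·k·D·t/(k_B·T))) = σ∞² · (1 − e^(−2t/τ)),

saturating at the equipartition value σ∞² = k_B·T/k. The simulator uses the
**exact OU transition**

    x_{i+1} = x_i·e^(−Δt/τ) + ξ_i·sqrt(σ∞²·(1 − e^(−2Δt/τ))),  ξ_i ~ N(0,1),

rather than Euler–Maruyama, so the transient-variance check against the
closed form is unbiased at any sampling rate and needs no step-size tuning.

The photodetector voltage is

    v(t) = (b + c₁·x(t) + c₂·x(t)²) · (1 + m·sin(2π·f_c·t))
           + a_g·sin(2π·f_g·t) + ε(t),

with baseline b, linear/quadratic position couplings c₁/c₂, carrier
modulation (f_c = 1 kHz, depth m = 0.5 at the canonical 5 kHz sampling
rate), grid interference (f_g = 50 Hz) and white Gaussian sensor noise ε.
For the no-particle class the x(t) terms are absent. The quadratic coupling
lets classes differ in spectral shape, not only variance — the working
hypothesis being that optical-property differences (refractive index,
polarizability) are what make similar cells distinguishable.

Units are SI throughout: positions in meters, voltages in volts.

### Class presets

The physical magnitude of k for trapped cells is not recoverable from the
recordings; defaults are order-of-magnitude pN/µm-scale choices, exposed in
configuration and not claims:

| class        | k (N/m) | D (m²/s) | c₁ (V/m) | c₂ (V/m²) |
|--------------|---------|----------|----------|-----------|
| no_particle  | —       | —        | —        | —         |
| mock         | 1.5e−6  | 3.0e−14  | 2e6      | 0         |
| hst6         | 3.0e−6  | 2.7e−14  | 8e6      | 5e12      |
| ps           | 6.0e−6  | 5.7e−14  | 3e7      | 2e13      |

Diffusion coefficients correspond to ~15–17 µm cells and an 8 µm bead in a
1 mPa·s medium at 37 °C; the polystyrene control is stiffest (largest
refractive-index contrast). The observable that separates classes in the
filtered band is the carrier-modulation amplitude c₁·σ∞ (plus the
quadratic term's spectral signature); its ~2.7× steps between classes were
calibrated once so that the desk-scale leave-one-out accuracy target
(≥ 0.9) is achievable, as the evaluation design requires, and sit far
outside the per-entity jitter.

Entities within a class draw their k, D, b, c₁, c₂ and noise SD from
lognormal distributions with 10% relative SD (mean-preserving), so
entity-level leave-one-out is meaningful: held-out entities are genuinely
new parameter draws.

A **chance-level control preset** gives all four classes identically
distributed signals while respecting the type invariants (the no-particle
class must lack a trap, particle classes must have one): particle classes
keep identical traps but all couplings are zero, so every class records
baseline + carrier + grid + noise. This control uses no entity jitter: each
epoch is then an independent draw of one fixed process, which is what the
binomial error model behind the "accuracy ≈ 0.25" check presumes. With
jitter, a small cohort's few entity signatures dominate the across-run mean
and chance behaviour is approached only as the cohort grows.

### What the generator does not emulate

No electromagnetic/Mie scattering, lens geometry, or glycan biochemistry is
modelled; class differences are phenomenological parameter differences.
Real recordings may carry drifts, detector nonlinearity, partial trapping
events and non-Gaussian noise absent here. Passing the synthetic end-to-end
experiments therefore demonstrates that the *pipeline* is correct and
leak-free, not that real cells of these types are separable — that evidence
must come from instrument data.

## Preprocessing

Causal single-pass 2nd-order Butterworth high-pass at 500 Hz (the
acquisition chain is real-time, so no zero-phase forward–backward pass),
then non-overlapping 2-s epochs (trailing remainder discarded), then
artifact rejection: an epoch is rejected iff any sample's |z| exceeds 5,
with z referenced to the mean/SD of the entire filtered acquisition.
Rejection is applied to filtered samples (it follows filtering in the
chain). Both the reference population (acquisition vs. epoch) and the
aggregation (max vs. mean |z|) are configurable, as the rejection rule's
reference is a genuinely open choice. A zero-variance acquisition defines
z = 0 (all epochs accepted, logged).

## Features

54 per epoch, canonical order fixed by `ilof.features.FEATURE_NAMES`.

* **Time statistics**: sample SD (n−1), RMS, standardized 3rd/4th moments
  (kurtosis not excess-corrected: Gaussian → 3), IQR with linear
  interpolation, Shannon entropy (bits) of a 128-bin equal-width amplitude
  histogram. The bin count is fixed (and configurable) because nothing pins
  the estimator; fixed bins keep the feature deterministic. Numerically
  constant epochs report skew = kurt = 0 and entropy 0.
* **Nakagami (μ, ω)**: method-of-moments on magnitudes r = |x| of the
  zero-mean filtered epoch: μ̂ = (E[r²])²/Var(r²), ω̂ = E[r²]. Moments are
  closed-form and directly testable against simulated Nakagami samples
  (recovery within 5% at n = 10⁵); when Var(r²) = 0, μ̂ is capped at 10⁶
  and flagged. The Nakagami family is the classical model for scattered-echo
  envelopes.
* **Envelope DCT**: ε = |analytic signal| (Hilbert transform), then the
  plain cosine sums E[l] = Σ_k ε[k]·cos(πl(2k+1)/2N) for l = 1…N−1 (DC
  excluded; computed as scipy's unnormalized DCT-II divided by 2, verified
  against the O(N²) sum to 1e−9). Features: the 30 largest magnitudes in
  descending order (magnitude, not signed value — magnitude ordering is
  permutation-stable), the smallest n whose sorted top-n reaches 98% of the
  total L2 norm (0 for an all-zero spectrum), the trapezoidal area of the
  magnitude spectrum over its 0–fs/2 axis, the peak magnitude, and the sum
  of squares. Thirty coefficients (not twenty) are kept: that is the count
  consistent with a 54-feature total.
* **Wavelet-packet relative powers**: for Haar and Db10 at levels j = 1…6,
  energy of the level's lowest-frequency packet node over the total energy
  of all 2^j nodes. The periodized transform is used so level energies
  conserve signal energy to 1e−9, making the [0,1] range exact. The exact
  node/normalization convention is not canonical; an "all-details"
  complement is selectable.

Feature extraction is pure and deterministic; all 54 values are finite even
for degenerate epochs.

## Classification and evaluation

Per-feature z-score normalization is fitted on training epochs only (sample
SD; constant features map to 0 and are flagged) and applied to test epochs
with the stored training statistics. The Random Forest grid is
6 × 5 × 6 = 180 combinations — trees {10, 20, 50, 100, 200, 500},
per-split predictors {4, 7, 10, 15, 20} (including round(√54) = 7), minimum
leaf {1, 3, 5, 10, 20, 50} — selected by mean **macro** F-measure over
stratified 5-fold CV (macro because the cohort is class-unbalanced), with
ties broken toward fewer trees then larger leaves (the cheaper model). CV
folds stratify by epoch; entity-stratified folds would also be defensible
but tuning happens strictly inside each run's training set, so no held-out
entity is involved either way.

Evaluation is **entity-level leave-one-out**: each run's test set is one
entity per class (all of its epochs), training is everything else, and a
hard guard raises if any entity appears on both sides. Accuracy is
epoch-level (each 2-s portion is a test sample); an entity-level
majority-vote accuracy is reported alongside. Each run derives its seed
from (master seed, run index), so results are independent of execution
order and reproducible under subsampling.

The **speed rate** draws test epochs uniformly without replacement until the
first correct classification (500 repetitions per entity); exhausting all
epochs without a correct call contributes the full epoch count and is
reported separately as a failure, since no convention is canonical.
Seconds = 2 × portions.

### Desk-scale study conditions

The full 29,250-run plan at 80 s per entity is a multi-day computation; the
package's default experiment uses 3 entities per class, 8-s acquisitions
(4 epochs each), 50 subsampled runs and a 12-combination grid
(2 × 2 × 3) — small enough for minutes-scale runs while still exercising
tuning, training, testing and SR end to end. The combinational arithmetic of
the full plan (29,250; 900; 26,325,000) is computed exactly regardless.

## Force analysis

The restoring trajectory s(t), tracked at 4 Hz, is fitted to
s(t) = s_eq + (s0 − s_eq)·e^(−t/τ) by bounded least squares (τ > 0). The
optimizer's parameters are rescaled internally (positions ~µm, τ ~s differ
by six orders of magnitude) so convergence tolerances bite on all three
parameters; the equilibrium point s_eq is estimated by the fit, not assumed
to be the final frame. Velocity is the analytic derivative of the fit —
finite differences of 4 Hz positions are noise-dominated, though a
finite-difference mode can be had by differencing the raw positions
directly. Force follows the wall-corrected Stokes law F = 6π·ξ·η·r·v with
ξ = 3.08 and η = 10⁻³ Pa·s (PBS), both overridable. For the exponential
model the force-vs-displacement profile is linear through the origin with
slope 6π·ξ·η·r/τ (harmonic-trap consistency), the maximum force is
6π·ξ·η·r·|s0 − s_eq|/τ, and the inertial-to-drag ratio is the constant
m/(6π·ξ·η·r·τ), negligible (≪ 1) at cell scale — the low-Reynolds
assumption behind dropping the inertial term.

## Numerical choices and degenerate inputs

* OU transition coefficients computed in double precision from τ and σ∞²;
  paths generated by an AR(1) filter recursion.
* Vote ties in prediction break by lexicographic class order; grid-score
  ties break toward the cheaper model (fewer trees, larger leaves).
* Epochs shorter than 31 samples (DCT) or 64 samples (6 wavelet levels) are
  rejected with explicit errors.
* All randomness flows from explicit integer seeds via `numpy` seed
  sequences keyed as (master seed, stage/entity/run index); identical seeds
  give bit-identical outputs.

## Known limitations

* Class separability is asserted only for the synthetic presets; the
  physical parameter values are plausible but not fitted to any instrument.
* The desk-scale SR estimate saturates at 1.0 portions when the classifier
  is perfect on the separated preset, so it exercises the machinery rather
  than discriminating SR conventions.
* The artifact-rejection reference population and the wavelet-packet node
  convention are open interpretation points; both are configuration
  switches rather than fixed claims.
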