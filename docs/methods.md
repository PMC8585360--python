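# Methods

## Physical model

The single-point diamond tool is treated as a rigid cone indenting an
elastic–plastic half-space. With flank angle φ (angle between the cone side
and the bone surface; φ = 45° for the 90° cone) and depth *h* (mm), the
indentation geometry is

- surface diameter d = 2h/tanφ,
- indented volume V = πh³/(3 tan²φ),
- forward projected area A_p = h²/tanφ,
- horizontal projected area A = πh²/(8 tan²φ) as used by the yield law
  (this operative form is kept as published; a purely geometric projection
  would be πh²/tan²φ).

Three mechanistic normal-force laws are provided: the Sneddon conical
contact force F_z = (2/π)·E·h²·tanφ for the elastic regime, the
yield-limited force F_z = δ_s·A once the bone yields, and its depth
integral F_z = π·δ_s·h³/(24 tan²φ) ≡ δ_s·V/(8 tan²φ). Because the
micro–nano lamellar structure makes δ_s effectively depth-dependent, the
law actually calibrated and used for prediction is the empirical power law
F_z = C·V^α. With α < 1 the force is concave in volume: each extra unit of
indented volume costs less force than the last.

The tangential (ploughing) force follows from anisotropy of shear strength.
Cortical bone is a bundle of axially oriented osteons; shearing along them
is easy, shearing diagonally across them is hard. The shear stress is
modelled as τ_p(θ) = τ_s·(C1 + C2·sin(C3·θ + θ0)) and the ploughing
coefficient — the ratio F_p/F_z, treated as a material/orientation property
— inherits the same shape:

    f_p(θ) = C1 + C2·sin(C3·θ + θ0),      F_p = f_p(θ)·F_z.

### Angle and convention choices

- θ and θ0 are carried in **degrees** (the design angles are 0°, 45°, 90°);
  the sinusoid argument is evaluated in **radians**, so C3 has units
  rad/deg. Only this convention reproduces the published endpoint values
  (0.294 + 0.934·sin(0.45·45 rad) = 1.2145 ≈ 1.21).
- The published closed form that multiplies the sinusoid by f_p(θ0) is
  retained behind `convention="literal"`, but it double-counts the
  reference level (it would give f_p(0°) = 0.085 instead of the measured
  0.29), so the default "canonical" form evaluates the sinusoid directly.
- Likewise the published merged prefactor (≈ f_p(θ0)·C ≈ 208) is available
  via `tangential_force(..., legacy_prefactor=True)` but is not the
  default, because it is inconsistent with the measured coefficients under
  the canonical convention.

## Parameters

| Parameter | Units | Default | Meaning |
|---|---|---|---|
| φ | deg | 45 | cone flank angle (90° included cone) |
| E | MPa | 15000 | elastic modulus (bovine cortical bone, 10–22 GPa range) |
| δ_s | MPa | 150 | yield strength |
| τ_s | MPa | 3 | inherent shear strength |
| C, α | N·mm⁻³ᵅ, – | 707.53, 0.39 | calibrated power law |
| C1, C2 | – | 0.294, 0.934 | sinusoid offset and amplitude |
| C3 | rad/deg | 0.45 (alias) / 0.0317 (first branch) | phase rate |
| θ0 | deg | 0 | phase offset (held fixed in fitting by default) |

## Preprocessing

Raw 1 kHz force traces are cleaned with a Hampel filter: a sample deviating
from its rolling median by more than k·1.4826·MAD is replaced by that
median. The window parameter is a 5-sample **half-width** (11-sample
interior windows); k defaults to 3. Windows are truncated at the series
ends rather than padded, to avoid fabricating data at trace boundaries. A
zero window MAD flags any nonzero deviation.

The standard filter is a single pass and is therefore *not* idempotent on
noisy signals: replacing an outlier shrinks the local MAD, so a second pass
can flag borderline neighbours (on a 1%-noise plateau, a re-run touches
roughly 1.5% of samples). `until_converged=True` iterates the pass to a
fixed point, which is idempotent on any input; on signals that are clean
apart from isolated spikes the single pass is already a fixed point.

Steady-state segmentation finds the longest contiguous run with the normal
channel above 10% of its robust (95th-percentile) maximum, then keeps the
central 1 − 2·trim fraction (default trim 0.1, i.e. the central 80%), which
discards the 50 ms engagement ramps. Trial summaries are means/SDs over the
retained window; the per-trial ploughing coefficient is the ratio of the
channel means.

## Calibration

- **Power law**: ordinary least squares of log F_z on log V (statsmodels),
  the multiplicative-error reading of the original weighted fit whose
  weights were not specified; C = exp(intercept). A direct nonlinear fit on
  the newton scale is available (`mode="direct"`). Two distinct points give
  the exact interpolating law; diagnostics need three or more.
- **Sinusoid**: least squares of f_p(θ) = C1 + C2·sin(C3·θ + θ0) with
  θ0 fixed at 0 (fitting it is opt-in), C2 ≥ 0, and the first-branch phase
  constraint 0 < C3·θ_max ≤ π. The three-angle design {0°, 45°, 90°} aliases
  C3: with x = C3·45° in radians, any x + 2πk fits the same three values, so
  the canonical report carries the first-branch rate (x ≈ 1.4253 rad,
  C3 ≈ 0.0317 rad/deg) and lists the aliases — the third alias is the
  published 0.45. For that design the least-squares optimum interpolates
  the per-angle means, so the fit is taken from the closed-form three-mean
  solver (C1 = m0, cos x = (m90 − m0)/(2(m45 − m0)), C2 = (m45 − m0)/sin x);
  denser designs are fitted numerically (variable-projection grid start,
  then bounded `scipy.optimize.least_squares`). Infeasible means (|cos x|
  > 1, or falling at 45°) raise an explicit branch error rather than
  silently wrapping around.
- **Diagnostics**: R² = 1 − SSE/SST on the fitting scale, the standard
  regression F statistic with (model, residual) degrees of freedom, raw
  residuals, and per-point relative errors 100·|pred − obs|/obs. The
  historical F-measure and per-replicate error-rate columns published with
  the reference data follow definitions that cannot be reconstructed; the
  standard definitions are used and no result depends on matching them.

Note the published aliased phase rate oscillates with a ~14° period in θ,
so the fitted curve is only meaningful at (and near) the design angles;
positivity of f_p over the whole quadrant holds for the first-branch rate.

## Synthetic data generator

The generator emulates the reference experiment: a full factorial of UCT
{0.5, 0.6, 0.7, 0.8} mm × cutting angle {0°, 45°, 90°} with 5 replicates
(60 trials), 10 mm stroke at 100 mm/min (6 s of engagement), 1 kHz
sampling, 0.5 s zero-force dwell either side, and 50 ms linear engagement
ramps (a choice that avoids step discontinuities while keeping segmentation
testable). Plateau forces come from the calibrated laws; measurement noise
is multiplicative log-normal (default sd 1%) because forces are positive
and instrument error scales with signal — this also keeps the log-space
power-law fit unbiased. Optional isolated spikes (default off; magnitude
10× signal) emulate charge-amplifier glitches and are drawn after the noise
stream so they perturb nothing else. Indentation records draw V uniformly
on a configurable range (default 0.05–0.6 mm³). One seeded
`numpy.random.Generator` drives everything; per-trial streams are spawned
from the experiment seed, so identical inputs give byte-identical CSVs.

What the generator does **not** emulate: drift, vibration/chatter, thermal
effects, tool wear, depth-dependent yield, or any lack of fit between bone
and the model class. Closed-loop tests therefore demonstrate that the
pipeline recovers parameters from data *satisfying the model assumptions*
— they do not validate the model against real bone.

## Problem sizes and tolerances

Tests and the acceptance script use the study-scale problems: 15 replicate
coefficients for the sinusoid fit, n = 1000 indentation records at 1% noise
for power-law recovery (Monte-Carlo standard errors ≈ 0.0005 on α and
≈ 0.1% on C, so the ±0.005 / ±1% checks are many standard errors wide), the
60-trial factorial for closed-loop recovery, and 1000 random series for the
filter-oracle equivalence. Quadrature checks use adaptive `scipy` quadrature
at 1e-9 relative tolerance.

## Known limitations

- No temperature or cutting-speed dependence (the experiments fixed
  100 mm/min precisely to suppress thermal effects); no Johnson–Cook or
  finite-element baseline; no crack/chip morphology modelling.
- The anisotropy model is a single sinusoid over 0°–90° from three angles —
  it interpolates the design angles but is unvalidated between them.
- δ_s, τ_s, E are user-settable scalars; real cortical bone is
  heterogeneous and depth-graded.
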