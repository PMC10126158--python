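# Methods

## Growth-curve quantification

Colony size over time is measured as a normalized log-density: raw pixel
(or OD) readings are log-transformed and scaled so that values lie in
[0, 1], with a detection floor mapping "no colony visible yet" to exactly
0. On that scale each curve is fit with the modified logistic model

    N(t) = A / (1 + exp((4 μm / A)(λ − t) + 2)),

in which `μm` is the slope of the steepest tangent and `λ` is where that
tangent crosses N = 0. Fitting is nonlinear least squares
(`scipy.optimize.curve_fit`, trust-region reflective) with bounds A > 0,
μm > 0, λ ≥ 0 and data-driven starts (A from the maximum value, μm from
the maximum smoothed discrete slope, λ from that tangent's zero-crossing);
tolerances 1e-10, at most ~4000 function evaluations. Failures are
reported (`converged=False` or a raised error), never silently dropped.
On noiseless model curves sampled at 15-min intervals the fit returns the
generating parameters to ~1e-10 relative error.

Time-to-threshold (TTT) is the time the curve first reaches a threshold
density, default 0.8. The default mode returns the sampled time closest
to the crossing (the scan-frame convention); an interpolating mode
recovers the crossing by linear interpolation and matches the closed-form
inverse

    t* = λ + (A / 4 μm) (2 − ln(A/θ − 1))

to ~1e-3 h at fine sampling. At 0.25-h sampling, linear interpolation
carries a curvature sag of up to ~6e-3 h for slow growers — that is a
property of the grid, not of the inversion.

Two derivative-based summaries complement the fit. The *tangent-line*
("manual") rate locates the steepest interior point of the 3-point-smoothed
curve and reports the raw-value secant across ±2 samples (a 1-h window at
15-min sampling). This secant systematically under-reads the true μm —
analytically, a noiseless logistic with μm = 0.5 h⁻¹ gives
expit(1) − expit(−1) ≈ 0.4621 h⁻¹, a 7.6% under-bias — so it is a
cross-check, not the primary estimator. The *instantaneous* rate is
log(x(t)/x(t−Δ))/Δ per interval (natural log by default; the base is a
pure unit choice), with undefined ratios returned as NaN.

## Quality control

Scanner artifacts are handled in a fixed order, each rejection carrying a
reason code:

1. **Final-density outliers** (`final_density_outlier`): within each
   (population, plate) group of ≥ 3 curves, drop curves whose final value
   lies outside mean ± 2 SD of the group's final values. Note a 2 SD rule
   necessarily clips ~5% of honest normal tails, and re-running it on its
   own survivors can clip more (the SD shrinks); strict idempotency holds
   only when final values are tightly clustered. We apply it once, as a
   single pass.
2. **Spike closing**: candidate spikes are samples deviating more than
   0.15 (normalized units) from an 11-point median-filtered reference —
   wide enough to resolve runs up to 5 points. Runs of ≤ 2 points are
   replaced by the average of the flanking samples; wider runs reject the
   curve (`spike_too_wide`).
3. **Plateau check** (`no_plateau`): a curve whose mean smoothed slope
   over the final 2 h exceeds 10% of its maximum smoothed slope is still
   rising when the scan ends and is rejected (its logistic fit would be
   unreliable). The 10% tolerance and 2-h window are configurable.

All thresholds (TTT threshold, SD multiplier, spike width and tolerance,
plateau rule) are keyword arguments and run-config keys.

## Cost statistics

The acquisition cost is mean de novo TTT over mean adapted TTT —
equivalently the mean of per-colony de novo TTTs normalized by the single
adapted mean; both views are reported. Populations are compared with a
two-sided pooled-variance t-test (Welch optional), Bonferroni-multiplied
across plasmids and capped at 1. Colonies are pooled across replicates
before the cost is computed. The within-population lag/growth tradeoff is
summarized by OLS of growth rate on lag time with a t-based 95% CI on the
slope and the Pearson correlation; a panel summary correlates per-plasmid
cost with tradeoff slope across ≥ 3 plasmids.

## Constrained bootstrap

To ask whether an observed growth-vs-TTT slope requires a lag/growth
tradeoff, clone pairs are resampled under two hypotheses. Lags are
lognormal in both, parameterized by method of moments
(shape² = ln(1 + sd²/mean²), location = ln(mean) − shape²/2).
Unconstrained growth is an independent lognormal from the observed growth
moments (lognormal keeps positivity; the choice of family for the growth
draw is ours). Constrained growth is `intercept + slope·lag + N(0, σ)`
with the regression and residual SD taken from the observed data;
the Gaussian residual avoids degenerate per-round regressions. Draws
below 1e-3 (h or h⁻¹) are truncated there and counted. Each round's
clones are converted to TTT by the exact inverse of the logistic model at
A = 1, θ = 0.8 (no curve resampling — exact and fast), growth is
regressed on TTT, and the per-round slopes' 2.5–97.5 percentile interval
is compared with the observed slope's t-based CI (closed-interval
overlap). Defaults are 300 clones × 1000 rounds; the test suite uses
100 × 200, which already separates the hypotheses cleanly.

One measured property worth noting: widening the lag SD *narrows* the
per-round slope CI under both hypotheses, because a wider lag spread
inflates TTT variance and concentrates the OLS slope.

## Clonal competition model

A population is J clones; clone j holds its inoculum exactly until its
lag elapses, then grows logistically against the summed density of all
clones (across competing populations) plus a non-growing parent load P:

    dNj/dt = μj Nj 1[t ≥ λj] (1 − (Σ Ni + P) / K).

Defaults: K = 2×10⁹ cells (a typical saturated CFU for this assay),
P = 0, 24-h horizon, 50 iterations (independent clone-set draws) per
condition. Integration is fixed-step classical RK4 with steps capped at
`dt_max` (default 0.01 h) and aligned exactly to every λj, so pre-lag
sizes are exact and the right-hand side is smooth within each step; the
integrator matches a dt = 1e-4 Euler reference to < 1e-3 relative and the
single-clone closed form to < 1e-6. Populations of more than `j_max`
(default 10⁴) cells are represented by `j_max` clones carrying equal
multiplicity weights, preserving the total inoculum.

The bulk phenotype of a trajectory is read from ln(total). The default
is the classical tangent readout — growth rate = maximum smoothed slope
of ln(total), lag = where that tangent crosses the inoculum level — which
is exact for a single clone. Fitting the logistic model to the rescaled
log curve is also available, mirroring the colony-curve pipeline, but
over the ~17 e-folds between inoculum and carrying capacity the log-space
shape mismatch biases that readout (~+25% on rate, hours on lag), so it
is not the reference.

Density sweeps draw `n_iterations` clone sets per inoculum size with
common random numbers across densities: iteration k reuses one stream, so
a larger inoculum's clone sample extends the smaller one's. Cross-density
contrasts are then paired differences, which cancels the clone-sampling
noise shared between densities. Ratio calibration bisects on the log
initial ratio of two adapted populations until their mean final split is
0.5 ± tol (default 0.02), using common random numbers across bisection
evaluations so the objective is monotone; competitions then run the de
novo counterparts at the calibrated ratio and report the mean final
fraction. Conjugative transfer during the competition window is ignored;
the experimental calibration step this mirrors absorbs such baseline
differences.

## Synthetic data generator

The generator emulates a two-population scanner study: per-colony lags
and growth rates are lognormal (adapted: independent; de novo:
independent, or growth affine in lag when a tradeoff is configured);
curves are the forward model with per-colony asymptote jitter
(N(1, 0.02), truncated), Gaussian measurement noise (default SD 0.01) at
15-min sampling over 24 h, and a detection floor (default 0.05) clipping
pre-emergence samples to 0. Ground-truth TTTs via the closed-form inverse
are stored beside every colony. A `target_cost` convenience solves for
the de novo lag mean whose *expected* TTT ratio equals the target, using
deterministic Gauss–Hermite quadrature of E[TTT] (including the tradeoff
and truncation), so the calibration is seed-independent. Plantable
artifacts (1/2/4-point spikes, never-plateauing ramps, ×3-scaled
colonies) come with a manifest naming which colony got what — the oracle
for QC tests.

What the generator does *not* emulate: pixelation/shadowing noise
structure (noise is i.i.d. Gaussian), colony crowding on the plate,
drift, or conjugation during imaging. Passing tests therefore demonstrate
correctness of the pipeline under the stated generative assumptions, not
performance on arbitrary real scanner data.

### Presets

Three illustrative populations ("low-cost R64drd-like" ≈ 1.1,
"intermediate-cost RP4-like" ≈ 1.5, "high-cost pB10-like" ≈ 1.9 — labels
are synthetic, not measured values) carry both colony-scale settings and
cell-scale simulation parameters. On the cell scale, growth rates sit in
the 0.4–0.7 h⁻¹ range typical of minimal-medium E. coli, with de novo
population cores on one shallow shared lag→rate line
(0.225 + 0.03·lag h⁻¹): with a 24-h window this places the growth-time
optimum μ(λ)(24 − λ) near the intermediate preset's lag, which is exactly
why an intermediate-cost population beats both a shorter-lag/slower and a
longer-lag/faster rival once initial ratios are calibrated on adapted
counterparts — and why, with the tradeoff switched off (rates drawn
independently of lag), the shorter-lag population always wins. Each
population's *within*-clone tradeoff slope is much steeper (0.05 / 0.20 /
0.22 h⁻¹ per h, rising with cost, as per-plasmid regressions do), and the
intermediate preset's lag spread is narrow enough (6.5 ± 1.0 h) that its
fast long-lag clones sit ~3 SD deep: 100-cell inocula essentially never
sample them, 10³–10⁴-cell inocula do, and above ~10⁵ cells saturation
truncates the growth window. That sampling-then-crowding structure
produces the biphasic density response of the tradeoff population (peak
growth rate at interior inoculum sizes) while the no-tradeoff population
is monotone non-increasing. Adapted counterparts are identical across
presets (experimental pairs are chosen for matched adapted growth), so
calibration is exercised honestly but lands near 1:1.

## Problem sizes and numerical choices

The shipped tests and the acceptance script run at desk scale, chosen as
reasonable study sizes: 100 colonies per population for cost recovery,
200 null panels for the type-I rate, 50 replicate studies × 100 clones ×
200 rounds for bootstrap discrimination, 20 iterations for density
sweeps (dt_max 0.1 h there; RK4 error is far below the iteration noise),
12 iterations and j_max = 3000 for competitions (outcomes agree with
j_max = 10⁴ to ~0.001 in final fraction). Truncation floors are 1e-3 h
and 1e-3 h⁻¹; tie-breaks: TTT takes the *first* crossing, the tangent
readout the *first* maximal slope.

## Known limitations

* The 2 SD final-density rule is not strictly idempotent on continuously
  noised data (see above) and clips ~5% of honest tails.
* The tangent-line manual rate has a deterministic secant under-bias; use
  the logistic fit for absolute rates.
* The logistic-fit bulk readout of simulated trajectories is biased by
  log-space shape mismatch; the tangent readout is the reference.
* Competition ignores in-window conjugation, plasmid loss and spatial
  structure; carrying capacity is a single shared scalar.
* Preset parameters are illustrative calibrations that place the system
  in the qualitative regimes described above; they are not fitted to any
  particular organism or plasmid.
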