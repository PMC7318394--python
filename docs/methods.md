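# Methods

## Model and procedure

The package treats a two-arm randomized trial as a dose-response experiment
in time: exposure (months on treatment) produces a response (event-free time
gained), each measurable from the published cumulative-incidence curves
alone, with no proportional-hazards assumption.

All curves live on a regular time grid of step 0.25 months (configurable;
every downstream integral uses the actual step) with incidence on the
percent scale — "per 100 individuals at baseline". The pipeline is:

1. **Ingestion** (`pisa.km`). Digitized coordinates are sorted, duplicate
   times collapsed to the mean, and monotonicity violations repaired:
   decreases below the running maximum larger than a tolerance (default 0.2
   percentage points) are removed as gross digitizer misplacements; smaller
   dips are clipped up to the running maximum. This automates, deterministically
   and with logging, what is usually done by eye. The cleaned curve is
   resampled onto the grid by linear interpolation between the nearest lower
   and upper raw points; extrapolation past the last digitized point is
   refused. Proportion-scale input (max ≤ 1.5) is rescaled to percent with a
   warning — note this heuristic would misread a curve whose true incidence
   never exceeds 1.5%.

2. **Time-Lost / Time-Gain** (`pisa.timegain`). Time-Lost is the running
   trapezoid integral of incidence (exact for piecewise-linear curves, error
   O(step²) otherwise); Time-Gain is control-minus-active, so benefit is
   positive. The through-origin quadratic `a2·t² + a1·t` is fitted by
   ordinary unweighted least squares on all grid points in `[0, t50]`
   (minimum 8 points), where `t50` is the time at which the in-follow-up
   fraction crosses one half — linearly interpolated for continuous profiles,
   first-entry-strictly-below for step-type numbers-at-risk tables, and
   `T/2` when no profile exists (the exact value, e.g. 27.5 for a 55-month
   study, is used internally regardless of display rounding). `a1` is the
   parallel-curves (constant) gain rate; `a2` captures progressive
   divergence of the arms.

3. **Acceptance and extrapolation.** Goodness of fit is the coefficient of
   determination R² = 1 − SS_res/SS_tot with SS_tot about the window mean —
   the conventional reading of an "R² > 0.95" acceptance rule applied to a
   through-origin model. The same statistic evaluated over `[0, T]` reports
   how well the window fit tracks the curve beyond its window. Rejected fits
   (R² ≤ 0.95) block all extrapolation and power fitting downstream. Fitted
   values inside the window are flagged `fitted`, beyond it `extrapolated`;
   the default report horizons are 24 and 72 months.

4. **Indices** (`pisa.pharmaco`). MoT is the running trapezoid integral of
   `100 − incidence` of the active arm. MoT/y⁺ = MoT/(gain/12) and
   NNT/y⁺ = (MoT/t)/(gain/12). Where the gain is ≤ 0 the indices are
   undefined and stored as NaN (masked), never ±∞; NNT/y⁺ is undefined at
   t = 0. Units: with both MoT and gain per 100 baseline individuals the
   normalization cancels in NNT/y⁺, which therefore counts actual patients;
   MoT/y⁺ is months of treatment for the 100-person cohort per event-free
   year. By default the index denominators use the fitted (f50%) gain —
   the observed-gain variants are computed alongside for the "observed"
   report rows.

5. **Power fits.** From the first time the gain reaches 6 months per 100
   (below which the denominator makes the index hopelessly noisy) to the end
   of follow-up, `log(index)` is regressed on `log(t)` by linear least
   squares; `coef = exp(intercept)`, `expo = slope`, R² on the log-log
   scale. This is deterministic and closed-form, and it reproduces the
   exponent-shift identity exactly: an index divided by t refits with the
   same coefficient and exponent lower by exactly 1. (A nonlinear refinement
   on the original scale was considered and rejected: it weights the early,
   noisiest part of the curve most.)

6. **Threshold crossings.** For a decreasing power fit, `a·t^b = level`
   has the unique solution `t = (level/a)^(1/b)`, computed in closed form.
   *Reporting convention:* "reached after" times are rounded **up** to the
   displayed resolution (0.1 month), because the level is only attained
   after the exact crossing; a crossing beyond the report horizon is flagged
   `beyond_horizon`. Exact multiples are kept fixed by a small relative
   guard.

## Synthetic data: what it emulates and what it does not

`pisa.synthetic` generates trials from exponential, Weibull or
piecewise-exponential hazards. `exact_curve` mode samples the true incidence
on the grid — optionally jittered with truncated Gaussian noise (clipped at
±3 SD and to [0, 100], origin kept exact) and then repaired through the same
ingestion path, emulating digitization jitter. The repair used for synthetic
noise is clip-to-running-max only (no point removal), which guarantees the
repaired curve never departs from the noiseless one by more than 3 SD at any
grid point. `simulated_cohort` mode draws per-subject event times (inverse
cumulative-hazard sampling for the piecewise family), applies independent
exponential censoring plus administrative censoring at T (events take
precedence at ties), estimates each arm with the product-limit estimator
(lifelines), and builds the follow-up profile from pooled at-risk counts.
All randomness flows from one seeded generator per run; identical seeds give
identical datasets.

Closed-form oracles back every downstream quantity: for exponential arms,
gain(t) = 100[(1−e^(−λ_a t))/λ_a − (1−e^(−λ_c t))/λ_c] and
MoT(t) = 100(1−e^(−λ_a t))/λ_a; other families use adaptive quadrature at
absolute tolerance 1e−10.

The generator does **not** emulate informative censoring, covariates,
staggered accrual, or the serial correlation of digitizer errors along a
line trace; passing tests therefore demonstrate numerical correctness of the
pipeline under clean-to-moderately-noisy monotone curves, not robustness to
pathological figure extraction.

## Defaults that matter

| parameter | default | unit | rationale |
|---|---|---|---|
| grid step | 0.25 | months | fine enough that trapezoid error is negligible at monthly hazards ≤ 0.02 |
| monotonicity tolerance | 0.2 | % points | clip small digitizer dips, remove gross ones |
| R² acceptance | 0.95 | — | extrapolation only from demonstrably quadratic gain |
| gain threshold for power fits | 6 | months per 100 | index denominator large enough for stable kinetics |
| report horizons | 24, 72 | months | 2- and 6-year comparison points |
| index thresholds | 1000 (MoT/y⁺); 200, 50 (NNT/y⁺) | index units | conventional cost-efficacy levels |
| demo fixture hazards | 0.010 vs 0.008 | per month | event rates and effect size typical of CV-prevention trials |

## Numerical notes and limitations

- Quadratic kinetics are an empirical description, exact only as t → 0
  (where a2 → 50(λ_c − λ_a) for exponential arms). Extrapolation error
  grows with hazard × horizon: at monthly hazards ~0.01 a fit on [0, 30]
  evaluated at 60 months overshoots a true exponential-arm gain by ~15%,
  while in the small-hazard regime (hazard × T ≲ 0.03) the fit tracks the
  closed form within 2% at twice its window. Extrapolated values are always
  flagged; treat them as model projections, not measurements.
- Least-squares problems are solved with `numpy.linalg.lstsq` (SVD);
  through-origin design `[t², t]` is well-conditioned on these windows.
- Degenerate inputs raise typed errors rather than returning NaN: all-zero
  gain (nothing to fit), windows under 8 points, non-positive index values
  inside a power-fit window, gain never reaching the 6-month threshold.
- Observed report values are linear interpolants of the grid curves;
  interpolation outside the defined (positive-gain) region returns
  "unavailable" rather than a value.
- Confidence intervals are out of scope: published curves without
  patient-level data or plotted confidence bands do not determine estimate
  uncertainty.
- Test problem sizes (60-month grids, 5000 subjects per simulated arm, a
  handful of seeds) were chosen as the smallest that exhibit each asymptotic
  property clearly.
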