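# Methods

This note documents the models, conventions, and numerical choices behind
`pmrtox`, and what the synthetic-data generator does and does not emulate.

## Assay model

A PMR recording is 50 s at 16 frames/s (800 frames): background `[0, 30)` s
in the dark, excitatory `[30, 40)` s opened by a 1 s, 18,000 lx white-light
flash, refractory `[40, 50)` s opened by a second identical flash. Phase
windows are half-open, pairwise disjoint, and contiguous; flashes must
coincide with the excitatory and refractory window starts. The ≥ 40 min dark
rest between repeated tests of the same plate is protocol metadata only — the
photoreceptor-recovery kinetics are not modelled.

Plates follow the standard screening design: 96 wells, controls in columns 6
and 12, treatments on column pairs (5, 11) … (1, 7) in increasing
concentration, two replicate plates, hence N = 32 embryos per treatment and
32 controls. The default concentration series is 2.32, 5, 10.7, 23.2 and
50 μg/mL; the 23.2 μg/mL point completes the half-log spacing of the other
four and is a package convention, not a measured design constraint.

## Motion quantification

Activity at frame *t* is the fraction of pixels with
`|I_t − I_{t−1}| > change_threshold` (default 10 intensity units, ~4% of the
8-bit range — enough to suppress sensor noise without any tracking). The
first frame has no predecessor and scores 0. Differences are computed in
signed integers so unsigned wrap-around cannot occur, which also makes the
statistic exactly invariant to constant intensity offsets. Per-second
binning is the arithmetic mean of each second's frames; a partial trailing
second is dropped with a logged warning. Input is TIFF stacks or
pre-extracted trace tables; video container decoding is deliberately out of
scope (codec nondeterminism).

There is no ground-truth equivalence with commercial trackers — only internal
consistency, enforced by the generator round-trip (trace → frames → trace
recovers activity to within half a pixel per frame).

## Phase AUC convention

Per-embryo phase scores are trapezoid integrals of the per-second trace.
Each per-second sample is stamped with the *start* of its second, so a
half-open window `[a, b)` contains samples `a … b−1` plus the boundary
sample at `b`, which belongs to the next phase but closes this phase's
integral; the final phase ends at the last sample. Consequences, both
enforced by tests: the three phase AUCs sum exactly to the whole-trace
trapezoid AUC, and constant activity gives the 30 s background window three
times the excitatory window's area.

Statistics run on per-embryo AUCs (not plate averages) because non-responders
are identified per embryo and the t-test needs within-group replication.

## Filtering

Dead embryos at the 24 hpf viability check are removed first (reason
`dead`). Turbidity-flagged wells are excluded as `untrackable`; treated
groups containing them are labelled `not_evaluable`. Non-responders are
living embryos whose AUC triple is exactly `(0, 0, 0)` *after* scoring; the
default scope removes them from controls only, matching the original
filtering rule. An `all` scope exists, but note that applying it to treated
groups biases hypoactivity estimates upward, since a fully immobilized
treated embryo is indistinguishable from a non-responder. The reported
non-responder rate is all-zero living embryos over living embryos in scope,
computed from statuses so the filter is idempotent.

## Classification

Per concentration and phase, treated AUCs are compared to controls with a
two-tailed t-test at α = 0.05 — Welch's unequal-variance form by default
(toxic effects are typically heteroscedastic), pooled-variance Student
optional. `p < α` with a lower/higher treated mean gives
`hypoactive`/`hyperactive`. No multiple-testing correction is applied by
default, matching the per-phase, per-concentration convention of the
original analysis; callers needing FDR control can correct the returned
p-values. Lowest-effect concentrations are reported per phase; significant
effects existing only above the 50 μg/mL turbidity cutoff report `">50"`,
none at all report `"None"`. Identical or constant groups return p = 1
(`normal`), and groups smaller than two are `not_evaluable`.

## Trimmed Spearman-Karber

Pipeline: Abbott correction `p' = max(0, (p − p0)/(1 − p0))` (control
response of 1 is an explicit failure) → weighted PAVA monotone smoothing
(via `scipy.optimize.isotonic_regression`) → piecewise-linear cdf `F` over
`x = log₁₀ c` → clip to `[trim, 1 − trim]`, renormalize → `LC50 = 10^μ`
with `μ` the mean of `x` under the clipped distribution, accumulated
segment-wise in closed form. Log base 10 is fixed for reproducibility of
intermediates; the estimate itself is base-invariant and exactly
scale-equivariant (`k·c → k·LC50`).

- **Trim**: default `"auto"` picks the smallest of 0, 0.05, 0.10, 0.20 whose
  quantiles are interpolable (`p̃₁ ≤ α` and `p̃_k ≥ 1 − α`); an explicit trim
  must lie in `[0, 0.5)`. Unreachable quantiles raise rather than
  extrapolate.
- **Censoring**: if the smoothed proportions never exceed 0.5 the result is
  `above_highest` (reported `">Cmax"`, matching the convention used for
  low-mortality materials up to 500 μg/mL); never below 0.5 gives
  `below_lowest`; constant 0.5 is uninformative and raises.
- **Uncertainty**: the gradient of `μ` with respect to each observed group
  proportion (control included) is evaluated by central finite differences
  (step 1e-4, one-sided at the [0, 1] boundary) through the full
  correction–smoothing–trimming pipeline with the trim held fixed;
  `Var(μ) = Σ gᵢ² pᵢ(1−pᵢ)/nᵢ` at the raw observed proportions — the same
  variance a within-group resampling bootstrap sees — and the 95% CI is
  `10^(μ ± 2·SE)`. On a fixed five-concentration table the delta SE agrees
  with a 2000-replicate bootstrap within a few percent (tested at 15%), and
  CI coverage of the true LC50 in the recovery simulation is within
  Monte-Carlo error of 95% at n = 32 per group. Saturated groups (p̂ = 0 or
  1) contribute zero variance, consistent with the bootstrap but optimistic
  if the true rate is merely near the boundary.
- **Reporting**: estimates keep full precision internally; reports round to
  two significant figures by default, or fixed decimals on request (the
  ionic-adjusted values use two decimals).

EC50s use the same estimator on malformation tables: a living embryo is
affected if *any* named morphological endpoint is abnormal; all-dead
concentration groups are excluded with a logged note.

The ionic adjustment multiplies every concentration by a material's free-ion
mass fraction (ICP-MS); by scale equivariance this commutes exactly with
estimation, so fitted estimates, CIs and censoring bounds are rescaled
directly, with the fraction's provenance recorded on the result. Printed
free-ion fractions for some materials vary several-fold between measurement
dates; the package takes the fraction (and its date) as explicit input
rather than choosing one.

## Time series

Per-age summaries report mean and SD of each phase AUC over included embryos
(singleton groups report SD 0 with `sd_defined = False`), non-responder
rates computed before exclusion, and the excitatory-vs-background
comparison. That comparison is a *paired* one-tailed t-test — both phases
are measured on the same embryo — on per-second-normalized scores (AUC /
phase duration), because raw AUCs over 30 s and 10 s windows are not
comparable; raw mode is available. All-tied differences report p = 1. The
peak excitatory age is the argmax of mean excitatory AUC, ties broken toward
the earlier age and flagged.

## Synthetic-data generator

The generator defines the study conditions the tests run under:

- Control per-second activity means: background 0.05, excitatory 0.25,
  refractory 0.08 (muted response to the second flash), with an exponential
  post-flash decay (τ = 3 s) inside the flash-opened phases, normalized to
  keep the phase mean fixed.
- Noise: Gaussian per-frame noise (sd 0.02) plus a lognormal per-embryo
  activity multiplier (log-sd 0.25), clipped to [0, 1].
- Dose effects: multiplicative log-logistic scaling of phase means with
  Hill slope 2 — the simplest monotone family whose parameters read as
  behavioral EC50s; mortality is log-logistic
  `p(c) = p0 + (1 − p0)/(1 + (LC50/c)^slope)` with binomial sampling.
- Development: the excitatory magnitude follows a piecewise-linear ramp with
  knots 24 → 0.35, 30 → 0.55, 31 → 1.0, 32 → 0.97 (the response roughly
  doubles from 30 to 31 hpf, then levels off just under the peak); background
  rises linearly over 24–32 hpf; refractory is flat. The knot values are
  generator parameters chosen to reproduce the qualitative developmental
  shape, not measured quantities.
- Non-responders (rate 0.005) and dead embryos both emit all-zero traces but
  distinct statuses, because the analysis filters them by different rules.
  Turbidity above a configurable concentration threshold marks wells
  `untrackable` without altering the trace.
- The developmental cohort generator re-tests the *same* embryos at every
  age (shared per-embryo multiplier, fresh noise), mirroring the design in
  which the same plates are recorded hourly from 24–32 hpf; this pairing is
  what makes the 31 hpf peak recoverable at realistic cohort sizes.
- Toy image stacks toggle exactly `round(a·N)` of the N well pixels between
  two gray levels per frame, so the frame-differencing statistic recovers the
  trace to within half a pixel; `null_stimulus_effect()` provides a
  stimulus-free configuration (equal phase means, flat burst and ramps) for
  calibrating type-I error.

What the generator does **not** emulate: embryo morphology or optics, chorion
effects, nanoparticle aggregation or settling, temporal autocorrelation of
movement bouts, plate-position or batch effects, and any coupling between
behavioral effects and mortality beyond their shared concentration. Passing
tests therefore demonstrate the correctness and calibration of the analysis
under its own statistical assumptions, not tracker-level fidelity to real
video.

## Problem sizes and determinism

Every stochastic operation takes an explicit seed and is bit-reproducible;
plate and cohort simulation spawn per-well child seeds so results do not
depend on iteration order. The calibration suites use 200 replicates for
power/recovery checks and 1000 for type-I error (3-binomial-SE acceptance
bands), a 2000-replicate bootstrap for the CI oracle, and cohorts of 32–64
embryos matching the plate design — sizes chosen to make Monte-Carlo error
small against the tested margins. The pipeline writes byte-identical reports
under a fixed config and seed (timing goes to logs, never into reports).

## Known limitations

- The delta-method SE inherits PAVA's non-smoothness; at tables with many
  tied or saturated groups the finite-difference gradient can understate
  variance. The bootstrap oracle bounds this on tested configurations only.
- Lowest-effect concentrations depend on the tested series; they are not
  interpolated thresholds (no benchmark-dose modelling).
- Probit/logit regression, time-to-event mortality, and mixture toxicity are
  out of scope by design.
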