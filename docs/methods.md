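# Methods

## Population model

The simulator represents an asynchronous population of progenitors as a
non-expanding renewal process. Each cell occupies a position on a cycle of
circumference t_c hours, laid out G1 → S → G2/M with S of length t_s and a
G2+M block of length t_g2m (default 2 h; it affects only mitosis timing in
pulse-chase experiments, never the labeling line). At mitosis the mother is
replaced by one tracked daughter starting at position 0. Under this scheme
the uniform distribution of cycle positions on [0, t_c) is exactly
stationary, which makes the cumulative-labeling law

    f(t) = GF · min((t_s + t) / t_c, 1)

exact rather than asymptotic — so estimator correctness is testable against
a closed form (`analytic_labeled_fraction`). An exponentially growing
population would have a mildly age-biased distribution; that regime is out
of scope here because the estimators being validated assume the linear law.

A fraction GF of cells cycle; the rest are permanently Ki67⁻ and never
incorporate label. EdU label is binary and permanent: daughters inherit it
and no dilution is modeled, which is adequate for exposure windows of ≤ 24 h.

Counting noise mirrors a manual-counting design: per-field totals are
Poisson around `n_cells_per_field` × mixing proportion (defaults: 200 cells,
6 fields, 2 biological replicates), and labeled counts are the realized
per-cell Bernoulli outcomes. Within one simulated run the same cells are
scored at every exposure time (common random numbers), so labeled fractions
are non-decreasing in time exactly, as for a culture followed over time.

## Cycle-length estimation

Fields are pooled within each biological replicate (fractions weighted by
field totals); ordinary least squares of labeled fraction on exposure time
gives the pooled fit, and per-replicate sub-fits provide dispersion. The fit
inverts to t_c = GF/m and t_s = b·t_c/GF. SEM of t_c and t_s is taken across
replicate-level inversions. Estimates carry quality flags (non-positive
replicate slopes, negative intercept, t_s > t_c); a non-positive pooled
slope is an error, not an estimate.

**Growth fraction.** GF must come from outside the line fit: `supplied`
(known/assumed; the default in recovery studies, where the estimator is
given the generating value), `ki67` (a measured Ki67⁺ fraction), or
`plateau` (pooled labeled fraction over the saturated exposure times,
available only when at least two times sit within 2% of the curve maximum).
With cycle lengths near 40 h and S phases near 16 h, a 24 h design barely
reaches saturation, so plateau estimation is deliberately conservative about
declaring saturation.

**Plateau handling.** Any exposure time at or past t = t_c − t_s contributes
a point on the flat part of the curve; including it biases the fitted slope
downward and t_c upward (for a 38.8/16.6 h population measured through 24 h,
by about +8% on t_c — asserted exactly on noise-free curves in the tests).
The `plateau_exclude` fit policy removes this by iterating: fit all points,
invert, drop times with predicted (t_s + t)/t_c ≥ 0.99, refit (at most 5
rounds, keeping at least two times). The default policy fits all points,
because a bench protocol with all times below the plateau needs no
exclusion; the recovery studies and the acceptance script use
`plateau_exclude` because their 2–24 h schedule straddles saturation for
every parameter set studied.

**Condition comparisons** run on the replicate-level t_c (and t_s) values
through the gatekept statistics stage. With two replicates per arm neither
Shapiro–Wilk (needs n ≥ 3) nor Levene (absolute deviations within a pair are
identical, making W degenerate) is evaluable; both are recorded as "not
evaluable, passed" in the decision trail and the equal-variance t test is
used — matching how such small designs are conventionally analyzed.

## Exit index

`compute_exit_index` is the plain ratio count(marker⁺ EdU⁺ Ki67⁻)/count(EdU⁺),
with per-field indices summarized by median and quartiles. Its generative
counterpart models exit as a per-mitosis Bernoulli event with probability
`quit_prob`; Ki67 loss is immediate at exit (a decay lag would only delay
Ki67⁻ conversion; none is applied by default). Cells labeled in S that never
reach mitosis within the chase cannot exit — inherent to a per-mitosis exit
model, and the reason the index increases with chase duration.

`expected_exit_index` is an independent deterministic oracle: it integrates
over the uniform initial-position distribution, counting for each position
the mitoses before S entry (exit there prevents labeling) and the mitoses
between labeling and the endpoint (exit there produces EdU⁺Ki67⁻), using
survival factors (1−q)^k on a 100,000-point midpoint grid (grid error
≪ Monte-Carlo tolerance). Simulator and oracle are two separate
implementations of the same geometry and are cross-checked within 3 SE on a
3×3 (quit probability × chase) grid.

## Flow cytometry model and gating

Synthetic events carry two channels. Reporter intensity is a two-component
log-normal mixture: background (median 100 au, σ_log 0.5) and a
right-shifted positive component (median 3000 au, σ_log 0.5) — separated
enough that threshold gating, not mixture modeling, is the appropriate tool.
Viability-dye intensity is log-normal (σ_log 0.25) with a 10% dead fraction
at 10× the live median. No spectral compensation is modeled (single
reporter).

Positive prevalence follows a saturating conversion trajectory
p(d) = p_max·(1 − exp(−H(d))) with constant hazard switched on after a
reporter-onset delay, a condition scale factor on the hazard (TGFβ
inhibition < 1), an optional forced-exit hazard from a set day (cell-cycle
inhibitor mode, driving exit probability toward 1 so conditions converge),
and a ceiling p_max reflecting the non-reporter lineage share of the
culture. Defaults (hazard 0.079/day, delay 20 d, p_max 0.46) put the control
curve near 15% at day 25 and 40–45% from day 40 on, the regime the gating
stage is meant to operate in.

Gating: dead events are those above 4× the sample median viability
intensity (configurable; with the defaults the live and dead components are
~5σ apart, so the gate is effectively exact). The positivity threshold is
the 99.9th percentile of the matched negative control's reporter channel —
standard practice for a knock-in reporter with a parental-line control — so
the false-positive rate is pinned at ~0.1% by construction. A missing
matched control for any (day, replicate) is an error; there is no silent
fallback to pooled or neighboring-day controls. Timecourses report mean ±
SEM across replicates per (day, condition); missing days are never
interpolated.

## Statistical gatekeeping

Shapiro–Wilk per group and Levene across groups at α = 0.05 (configurable);
both passing → equal-variance t test (two groups) or one-way ANOVA with
Tukey's post-hoc; either failing → Mann–Whitney U or Kruskal–Wallis with
Dunn's post-hoc under Holm adjustment (Dunn implemented here: rank-sum z
statistics with tie correction). Raw and adjusted p values are reported side
by side, and every gatekeeping outcome is recorded in an ordered decision
trail. Under a three-group null simulation the procedure's type-I error is
calibrated at ~5% (checked over 1,000 datasets in the tests).

## Recovery studies and problem sizes

The recovery protocol simulates the bench-scale design — exposure times
2, 4, 8, 16, 24 h; 6 fields × 2 replicates; ~200 cells/field — at the
published kinetics (NKX2.1⁺: 39.98/16.51 h vehicle, 45.65/21.76 h inhibited;
NKX2.1⁻: 38.80/16.60 h vehicle, 40.26/16.11 h inhibited), estimates with
`plateau_exclude` and the generating GF supplied, and averages over 100
repetitions. Growth fractions are not published for these cultures; the
generator uses 0.9 (NKX2.1⁺) and 0.8 (NKX2.1⁻) as plausible values for
progenitor-dense day-22 cultures — recovered t_c/t_s are insensitive to this
choice because the estimator receives the generating value. Oracle-agreement
tests use 3,000–5,000 cells per field so that 3 SE bands are tight enough to
be meaningful while the whole suite stays fast; gating accuracy is checked
at 50,000 events per sample.

## What the simulator does and does not establish

Passing recovery tests show the estimators are correct under the model's own
assumptions: stationary uniform phases, permanent binary label, immediate
Ki67 loss, well-separated fluorescence components, field-level
Poisson/binomial counting noise. Real cultures violate these in known ways —
population growth skews the age distribution young (biasing cumulative
labeling mildly), label detection has a threshold after dilution,
Ki67 persists for hours after exit, fluorescence distributions overlap and
drift between batches, and fields are spatially correlated rather than
independent. None of these are modeled; conclusions about estimator accuracy
on real data therefore extend only as far as those assumptions hold.
A robustness mode with an exponential-growth age distribution and the
configurable Ki67-lag and intensity-model knobs exist precisely so users can
probe sensitivity, but the defaults are the idealized regime.
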