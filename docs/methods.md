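# Methods

## Task model

A design is a point in a 5-dimensional attribute space: three integers in
[1, 100] (length, width, thickness) and two categorical traits with four
options each. Each season has its own fitness landscape mapping designs to
expected calories; landscapes are additive and independent across
attributes and unimodal per continuous attribute, and the displayed score
adds zero-mean Gaussian perception noise (SD 5 calories) before clamping to
the hard range [1, 1000]. Clamping *after* adding noise is the only reading
consistent with a hard printed score range; it is applied in
`perceived_score` and to hunters' displayed scores.

### Contribution function

The exact closed form of the original task's per-attribute contribution is
not public, so the package defaults to a Gaussian bump
`c_i · exp(−(x_i − μ_i)²/(2 w_i²))` — smooth, unimodal, additive — and keeps
the function pluggable (`FitnessLandscape.contribution`) so another form
can be slotted in without touching any other code. Consequently the package
makes **no claim of numeric equivalence** with the original program's
landscape; trajectory-level comparisons are qualitative by design.

### Landscape parameters

`make_landscape` requires per-attribute optima, maximal contributions and
widths, and enforces calibration: continuous maxima must sum to 1000 so the
joint optimum scores the ceiling (an `auto_rescale` flag rescales
proportionally instead). Categorical contributions default to zero — the
simulation ignores the discrete attributes, as in prior simulation work on
this task; experiment-style configurations may assign nonzero values.

The shipped demo seasons use optima (57, 24, 76), (30, 81, 46), (72, 40, 15)
for seasons 1–3, maxima (400, 300, 300) and widths 18 throughout. The
original experiment's optima and widths were never published; these are
package choices, fixed once: distinct optima per season so that designs
carried across a season boundary start well off-optimum, and a width narrow
enough that a Win-Stay cohort climbs visibly within 30 trials without
saturating immediately. Under these defaults a 100-agent asocial cohort
plateaus around 700–850 calories late in a season while a CSI cohort
approaches the ceiling — the qualitative regime of the original cohorts,
not their absolute levels.

## Learning algorithms

**Win-Stay** (asocial): pick one continuous attribute uniformly at random,
move it `L_i = 5` units (the median of empirically observed modification
sizes) in the memorized direction, clamp to [1, 100], hunt. Keep the
direction if the perceived score did not decrease relative to the previous
trial — equality counts as "did not decrease" — else flip it. Exactly one
attribute's direction can change per trial. On the first trial of a season
no previous score exists, so the score is stored without a flip
(bootstrap). Boundary handling: a step absorbed by the bound changes
nothing, the score does not decrease, and the direction is kept; a
`flip_at_wall` variant (off by default) flips it instead, since the
original behavior at bounds is unstated. The agent reacts to the
*perceived* (noisy) score, matching what participants saw.

**CSI** applies all hunters' single-attribute deltas to the reference at
once; by additivity the result dominates every single-delta design except
where clamping binds. **Reverse** applies the negated deltas: it helps
whenever the reversed step does not overshoot the optimum, which is why
Reverse cohorts gain early in a season (designs far from the new optimum)
and lose their edge near it.

## Social information generation

Hunters derive from the learner's previous design ("reference") and its
actually displayed previous score (not re-noised). Per hunter: draw a
magnitude `|N(10, 10²)|`, rounded to integer attribute units (attribute
values are integers; a rounded magnitude of 0 cannot satisfy the strict
inequality and is simply resampled); choose the sign that strictly
increases (positive condition) or reduces (negative) expected fitness —
when both directions qualify, the larger effect wins, ties to “+”; draw a
fresh display noise; accept iff true *and* displayed scores are strictly
better (positive) / worse (negative) than the reference's. Equality
triggers resampling — the fallback clause implies equality is not
acceptance. Both magnitude and noise are redrawn each attempt, up to 10,000
attempts, after which the hunter is an exact copy of the reference with a
`fallback` flag (typical at the landscape optimum in the positive
condition). Rejection sampling is vectorized in fixed-size batches of 512
draws so results are reproducible per seed.

Simulation mode shows 3 hunters, one per continuous attribute; experiment
mode shows 4 — one per attribute plus one on a uniformly random attribute,
guaranteeing full attribute coverage (the original assignment of 4 hunters
to 3 attributes is unstated). Simulation-mode delta magnitudes reuse the
experiment's `|N(10, 10²)|` generator by default; a fixed step can be
configured.

## Simulation engine

Three seasons × 30 trials. Social opportunities arrive once every three
trials in Seasons 2–3 only, at trials 2, 5, …, 29 (the earliest phase
possible, since hunters need a previous design; the phase is a config
knob). On a social trial the CSI/Reverse update *replaces* the Win-Stay
modification — one design change per trial, mirroring one hunt per trial —
the new design is hunted, the previous-score memory is refreshed, and the
direction memory is left untouched (the Win-Stay rule updates a direction
only on Win-Stay trials; documented choice). At season boundaries the
design carries over but the previous-score memory resets, because the
landscape changed. Season 1 is always asocial.

Cohorts give each agent an independent child stream spawned from the master
seed (`numpy.random.SeedSequence`), so runs are reproducible bit-for-bit
and agents independent. Trajectory summaries (mean, SD, SE = SD/√n per
condition × season × trial) are computed on **true fitness**, perception
noise excluded, as cohort trajectories are conventionally plotted.

## Statistics pipeline

Unit of analysis: each participant's mean score over a season's 30 trials
(the default score column is `perceived_score`, the score participants
actually saw; configurable). Welch two-sample t vs the asocial baseline per
social condition per season; Satterthwaite df; two-sided p. Cohen's d uses
the pooled-SD form. The family-wise alpha is Bonferroni-divided by the
number of comparisons (six at the defaults: two conditions × three
seasons). The F-test of variance equality is meant for final-trial scores;
its p is two-sided (`2·min(tail, 1−tail)`). Tail probabilities come from
scipy's t and F distributions; tests cross-check the statistics against
sample-based scipy tests on moment-exact reconstructed samples and against
quadrature of the F density.

Recomputing published-style statistics from *rounded* group summaries
reproduces all printed t and d values to two decimals except three
documented rounding artifacts: a Season-1 positive t of 2.04 (vs 2.05), a
Season-3 negative d of −0.07 (vs −0.08), a questionnaire one-sample t of
2.53 (vs 2.45 from unrounded data), and a Welch df of 77.026 printed
truncated as 77.02; an F of 0.89 (df 39, 39) gives p = 0.718 where 0.728
was computed from the unrounded ratio. These are properties of rounding,
not defects, and are asserted as such in the tests.

## Synthetic datasets (fixtures)

Target mode draws each participant's season mean from a per-condition,
per-season normal target — defaulting to the experiment's published group
summaries (n = 40 per condition) — and fills the 30 trials with a linear
rising trend (span 120 calories) plus trial noise (SD 60 calories),
recentred so the participant's season mean equals the drawn target exactly.
Scores are deliberately *not* clipped to [1, 1000]: clipping would bias the
first two moments the targets specify. Attribute columns are midpoint
placeholders. This emulates the score structure the statistics pipeline
consumes; it does not emulate landscape geometry, attribute trajectories,
within-season autocorrelation beyond the trend, or social-event structure —
so passing statistics tests on fixtures validates the pipeline, not any
behavioral claim. Simulate mode instead runs the full agent engine per
condition.

## Problem sizes and numerical choices

Cohort checks use 100 agents per condition (SE of a cohort trial mean
≈ SD/10, small against the CSI–asocial gaps of 100–300 calories). Parameter
recovery uses 100–150 fixture replicates; the Win-Stay oracle covers all
100 start values of a noise-free 1-D landscape; the hunter post-condition
audit covers 500 generations across random landscapes and both conditions.
Strict inequalities are evaluated in double precision on the smooth
Gaussian landscape, where exact ties between distinct integer designs occur
only at symmetric reflections about an optimum and are handled by the
documented tie rules.

## Known limitations

- The landscape's closed form, per-season optima and widths are package
  choices; absolute trajectory levels are not comparable to the original
  cohorts, only qualitative patterns are.
- Only the CSI and Reverse social algorithms are implemented; the hunter
  API (`HunterObservation` lists with per-attribute deltas) is designed so
  further algorithms can be added without core changes.
- Simulated agents ignore the categorical attributes; experiment-style
  landscapes with nonzero categorical contributions are scored correctly
  but no learning rule explores them.
- Whether the original simulation added an asocial step on social trials,
  or flipped direction at attribute bounds, is unstated; the package's
  choices (replace; keep direction) are documented above and the latter is
  configurable.
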