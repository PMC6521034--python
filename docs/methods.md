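# Methods

This note documents the models, conventions and numerical choices behind
`nutricompile`, and what the synthetic-data tests do and do not establish
about behaviour on real survey data.

## Database compilation

**Adjustments.** Borrowed values are rescaled for compositional differences
between donor and target food. Choline and betaine are treated as
water-soluble, so the default is the dry-matter (moisture) adjustment
`v * (100 - m_tgt) / (100 - m_src)`; the proportional protein adjustment
`v * p_tgt / p_src` is applied only when a match policy explicitly marks
the pair as protein-associated. When the protein adjustment is impossible
(donor protein 0) the policy may fall back to the moisture adjustment,
otherwise the match is rejected. The round trip
`adjust(adjust(v, a→b), b→a) = v` holds exactly for moistures below
100 g/100 g; donors at 100 g/100 g moisture have no dry matter and are a
domain error.

**Confidence rubric.** The A–D grade is fixed here as: A — species,
part/cut and processing all match and no adjustment was needed; B — all
three match but an adjustment was applied, or exactly one criterion
relaxed; C — two relaxed; D — all three relaxed. The rubric is monotone:
relaxing a criterion never improves the grade. This is the package's
codification of the general matching-guideline idea (exact match down to
weak match); the exact published criteria table is not reproduced.

**Recipes.** Composite density is total nutrient mass (raw weight ×
density × retention, summed over ingredients) divided by cooked mass
(yield factor × total raw weight), per 100 g. Retention factors default
to 1 and live in (0, 1]; typical cooking losses for B-group-like
nutrients motivate the 0.7–1.0 range the generator samples. Nested
recipes are resolved by depth-first topological order; self-reference and
longer cycles raise an error naming the cycle. Values are stored
unrounded and rounded only in report output (2 decimals).

**Zero policy.** Foods with no identified value receive choline 0 with
`source=unmatched_zero` and a flag column, keeping "no value found"
distinguishable from a true analytical zero; such zeros do not count as
coverage. Zero-filling a food that already has a value is refused.

**Quality assurance.** Foods are rank-ordered by value; range checks use
per-2-digit-group bounds with a global default; the verification sample
of `round(fraction × n)` ids (default 10%) is drawn without replacement
from a seeded generator, so a seed pins the sample exactly.

## Usual-intake estimation

Person-day intake is modelled as `y_ij = b·z_i + u_i + e_ij` with
person effect variance σ²_b and day-to-day variance σ²_w. The fit is
two-stage: OLS of all person-day intakes on person-level covariates
(default age in years and sex), then a one-way method-of-moments
decomposition of the residuals that handles unbalanced day counts d_i:
σ²_w = SSW/(N − n), σ²_b = (MSB − σ²_w)/c with
c = (N − Σd_i²/N)/(n − 1). Negative moment estimates are truncated at 0.
Usual intake is `b·z_i + λ_{d_i}(ȳ_i − b·z_i)` with
λ_d = σ²_b/(σ²_b + σ²_w/d); one-day respondents get λ₁ (no second day is
imputed). Intakes are untransformed by default — choline is consumed
daily and the synthetic intake model is additive-normal; a log-transform
flag exists as an extension for strongly skewed nutrients but is not the
default. If fewer than two persons report both days, σ²_w is
unidentifiable and estimation raises rather than guessing.

## Survey statistics

- Weighted mean Σwv/Σw; weights must be non-negative with a positive
  total (zeros are allowed so replicate columns can reuse the statistic).
- Jackknife SE over R replicate-weight columns:
  `sqrt((R−1)/R · Σ_g (θ_(g) − θ_full)²)`. A replicate column that is all
  zero over a small group (its deletion group covered the whole group)
  leaves that replicate undefined; the full-sample estimate stands in,
  contributing zero deviation, with a warning. This keeps small domains
  defined at the cost of slightly understating their variance.
- 95% CI is mean ± 2·SE; the conventional 1.96 multiplier is available
  via an argument. Groups without replicate weights fall back to the
  unweighted sd/√n.
- Weighted quartile bounds are the lowest values whose cumulative
  normalised weight reaches 0, .25, .5, .75 and 1, giving contiguous
  lower-bound-inclusive intervals; ties resolve by value order (stable
  sort). Bounds are invariant to rescaling all weights.
- AI attainment: the percentage is the unweighted count ratio (this is
  what published count-based percentages reproduce exactly); the weighted
  population equivalent of attainers is emitted alongside. Respondents
  with no applicable AI band (e.g. below the youngest band) are excluded
  and logged. Pregnancy and lactation bands take precedence over plain
  female age bands, both in AI lookup and in group assignment, so the
  exclusive reporting bands partition the sample.
- Rounding: means, SEs, CI endpoints and percentages to 2 decimals in
  report frames; population equivalents unrounded.

## Food sources and per-group models

Source rankings use day-1 events only (reported consumption, not
shrunken usual intakes): each event's nutrient mass is attributed to the
food group of its code prefix (3-digit default; 2 and 5 available),
weighted by the respondent's population weight. Per-consumer means are
weighted means over respondents with any consumption of the group;
consumer counts are unweighted. Percentages over all groups sum to 100
exactly because every event belongs to exactly one group. Ties in
percent rank by group code ascending.

Per-group regressions are WLS of usual intake (mg/day) on the group's
consumption in 100 g/day units plus energy, activity level, sex, age and
education level. SEs refit the model under every replicate-weight column
and combine as above; p-values use a t distribution with max(R − p, 1)
degrees of freedom (replicate-based, as in survey packages, not n-based);
R² is weighted and reported as a percentage. Collinear designs raise an
error naming the first aliased column. Ranking is by descending R², ties
by group code; configured groups (e.g. infant foods) can be excluded.

## Synthetic data: what it emulates and what it does not

The generators produce every input the pipeline reads, with ground truth
stored alongside:

- Food hierarchy: 20 two-digit groups with realistic labels, log-normal
  within-group densities (σ_log = 0.55) around group medians spanning
  4 mg/100 g (beverages) to 230 mg/100 g (eggs). Donor records invert
  the moisture adjustment so compilation reproduces intended densities
  exactly; recipes have closed-form truth values.
- Survey: ages sampled from national-survey-like band probabilities, a
  linear mean structure (intercept 230 mg/day, +0.9 mg/day per year of
  age, −35 mg/day for females, centring adults near 265 mg/day), person
  effects N(0, 400) and day deviations N(0, 1600) (mg/day)², log-normal
  weights, delete-a-group replicate weights, and a configurable second-day
  fraction (default 0.8). Events back-solve grams through food densities
  so person-day totals are exact; foods are picked with group-popularity
  weights so egg and meat groups top the source rankings as in real data.

Default sizes: "tiny" (60 foods, 150 respondents, 8 replicates) for fast
smoke runs and "paper-like" (400 foods, 2,000 respondents, 30
replicates), chosen so the full pipeline runs in seconds while group
summaries have two-digit cell counts.

What passing tests show: the estimators recover the generating model
(unbiased variance components, exact noiseless regression recovery,
calibrated jackknife SEs) and all bookkeeping invariants hold. What they
do not show: behaviour under real-survey complications absent from the
generator — skewed and episodic intakes, correlated day-to-day reporting
errors, informative weighting, item nonresponse, or food-matching
ambiguity. Published national estimates are therefore reproducible in
structure but not in value without the survey microdata.

## Numerical and testing choices

- All randomness flows through `numpy.random.default_rng` seeded per
  call; identical seeds give byte-identical output files (floats are
  serialised with `repr`).
- The method-of-moments between-person variance has Monte Carlo SD
  ≈ 45 (mg/day)² at n = 2000 with two days per person, so recovery
  checks compare the mean of four independent seeded surveys against
  truth (±10% is then a ~2σ test of calibration rather than a bet on one
  draw); the same averaging is used by the acceptance script.
- The jackknife oracle test centres deviations on the full-sample
  estimate in both the replicate path and the brute-force leave-one-out
  path; for the mean the two conventional centrings coincide exactly.
- Degenerate inputs have explicit contracts: empty groups are omitted
  with a log notice, empty event sets yield empty results, all-single-day
  surveys and saturated-moisture donors raise typed errors.

## Known limitations

- No episodic (two-part) intake model; nutrients not consumed daily
  would need one.
- No recipe disaggregation in source analyses: a composite food's
  nutrient stays in the composite's food group.
- The confidence rubric compresses match quality to three binary
  criteria; real matching judgements are richer.
- Replicate-based degrees of freedom are a convention; with few
  replicate groups p-values are conservative.
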