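# Methods

## Model

Daily physical activity of subject *i* on day *j* is modelled as a
one-way random-effects decomposition

    y_ij = mu + b_i + e_ij,   b_i ~ (0, sigma_b2),   e_ij ~ (0, sigma_w2)

with subject as the only random factor: `sigma_b2` captures stable
between-person differences, `sigma_w2` the day-to-day fluctuation
around each person's habitual level. Days are treated as exchangeable —
no day-of-week, seasonal or reactivity structure. The intraclass
correlation `ICC = sigma_b2 / (sigma_b2 + sigma_w2)` is the share of
total variance that is between-person.

For a protocol measuring *n* subjects on *m* days each, the group mean
has standard error

    SEM(n, m) = sqrt(sigma_b2 / n + sigma_w2 / (m n))

reported also relative to the mean (×100/mean, in percent). Since the
between term is divided only by *n*, `SEM(2n, m) < SEM(n, 2m)` for any
`sigma_b2 > 0` (the difference of squares is `-sigma_b2/(2n)`), which
is the formal content of "recruit subjects before adding days" for
group-level questions. Ranking (reliability) questions use the
Spearman–Brown prophecy `D = ICC_d(1-ICC_o) / (ICC_o(1-ICC_d))`;
individual habitual-level questions use `D = (z * CV_w / D0)^2` with
`CV_w = sqrt(sigma_w2)/mean`.

## Estimation

Variance components come from the unbalanced one-way ANOVA (method of
moments): with *a* subjects, group sizes `m_i`, total `N`,

    MS_b = sum m_i (ybar_i - ybar)^2 / (a-1)
    MS_w = sum (y_ij - ybar_i)^2 / (N-a)
    k0   = (N - sum m_i^2 / N) / (a-1)
    sigma_w2 = MS_w,   sigma_b2 = max(0, (MS_b - MS_w)/k0)

For balanced data `k0 = m` and the estimator reduces to the textbook
one-way ANOVA. A negative raw between-variance is truncated to zero and
flagged (`truncated=True`) rather than raised — the standard behaviour
of this estimator, and it keeps the SEM well defined. Confidence
intervals are not computed; the planners use point estimates only.

The grand mean defaults to the mean over all observations (subjects
with more days weigh more), with `mean_of="subjects"` as the unweighted
alternative; on near-balanced cohorts the two are nearly identical.

## Epoch processing rules

Raw counts (vertical axis, 5-s epochs by default) are summed to 60-s
epochs *before* both non-wear detection and classification, because the
cut-points are stated in counts per minute and the zero-run rule
operates on minutes; a trailing partial minute is dropped. Non-wear is
any maximal run of consecutive zero-cpm minutes **strictly longer than
20 min** — a 20-min zero run is wear, with no spike allowance inside
windows. A day is **valid iff wear > 600 min** (601 passes, 600 does
not). Intensity bands are half-open cpm intervals: sedentary [0, 100),
light [100, 1952), moderate [1952, 5724), vigorous [5724, inf); they
partition wear minutes exactly, and MVPA = moderate + vigorous. Total
daily counts are summed over the whole day (non-wear epochs contribute
zeros by construction). Day boundaries follow the calendar date of the
epoch start; partial first/last days are not special-cased. Subjects
need at least 21 valid days for inclusion; excluded subjects are
reported with their valid-day counts.

"First 7 days" means the first 7 *valid* days, not calendar days:
analysis cohorts contain only valid days, and the 3-of-7 scheme needs 7
usable days to draw from.

## Synthetic data

`generate_daily_cohort` draws subject levels `b_i` and day values
around them, normal by default. The defaults (28 days per subject, 50
subjects in the pipeline recipe, grand mean 60 min/day with
`sigma_b2=100`, `sigma_w2=25`, hence ICC 0.8) mirror a month-long
monitoring cohort of the kind the pipeline targets and match the
worked ICC example; recovery checks use 500–1000 subjects so the
Monte-Carlo error of a variance over ~500 degrees of freedom (~6%
relative) sits inside the stated 10% tolerances. The lognormal option
(for right-skewed outcomes such as vigorous minutes) solves its
log-scale parameters in closed form so the *observed-scale* mean and
both variance components equal the configured targets:
`tau_b2 = log1p(sigma_b2/mu^2)`,
`tau_w2 = log1p(sigma_w2/(mu^2 + sigma_b2))`,
`alpha = log(mu) - (tau_b2 + tau_w2)/2`. Missingness is day-level and
completely at random. Each subject has an independent RNG substream
derived from the master seed, so enlarging a cohort never perturbs
existing subjects. Negative day values under the normal family are
kept by default (they exercise estimator robustness); a
truncate-at-zero option exists.

`generate_epoch_day` turns an explicit bout plan (ordered non-wear /
sedentary / light / moderate / vigorous bouts in whole minutes, summing
to ≤ 1440) into an epoch stream plus its ground-truth daily summary.
Wear-minute cpm values are sampled strictly inside their band (the
open-ended vigorous band is capped at 3× its lower bound) and split
evenly over the minute's epochs with the remainder on the earliest
ones, so re-integration recovers each minute exactly. The ground truth
is computed by minute-level bout arithmetic, independent of the epoch
pipeline it validates: zero minutes occur exactly in non-wear bouts,
and merged zero runs of ≤ 20 min are truthfully counted as zero-cpm
sedentary wear per the strict rule. What these fixtures do *not*
emulate: diurnal rhythms, realistic bout-length distributions,
device-specific count noise, or compliance-driven (informative)
missingness — passing the round-trip suite shows the rules are applied
exactly as stated, not that the generator resembles any particular
population.

## Protocol subsets

Random schemes sample uniformly without replacement using a per-subject
substream keyed by the seed and a CRC-32 of the subject id, then
restore chronological order; removing or adding subjects therefore
never reshuffles the selections of others, and identical seeds
reproduce identical subsets.

## Numerical and design choices

- The headline relative SEM of an unbalanced all-days cohort uses
  `m` = the rounded mean number of valid days per subject, overridable
  (`reference_m`); nothing in the method pins a unique choice for
  unbalanced data.
- Planner outputs `D` are returned as real numbers; `ceil=True` rounds
  up, since a monitoring day is indivisible. Sub-1 Spearman–Brown
  results are reported, not clamped.
- `required_n` inverts the relative-SEM bound in closed form and then
  verifies the integer boundary directly, guarding against
  floating-point edge cases.
- ICC of a decomposition with `sigma_b2 + sigma_w2 = 0` is defined as 0
  inside `anova_decompose` (a degenerate but representable dataset);
  the standalone `icc_from_components` raises instead, since there the
  caller asserted the components.
- Default planning grids: n ∈ {10, 20, …, 500}, m ∈ {1, …, 28}.
- Pipeline artifacts embed a config hash (output path excluded) and the
  seed, and reruns are byte-identical.

## Limitations

- The ANOVA estimator is method-of-moments; REML would differ slightly
  on strongly unbalanced data. No interval estimates.
- One random factor only: no G-theory multi-facet decompositions, no
  day-of-week or seasonal variance sources, no weekday/weekend-balanced
  subsetting.
- Vertical-axis counts only; no vector magnitude, sleep/24-h protocols,
  or non-wear imputation.
- Reproducing a published descriptive table from real monitored data
  requires that data; `scripts/reproduce_table1.py` runs the identical
  pipeline on such a download, and its computation path is itself
  tested on synthetic input with a known answer.
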