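# Methods

## The design

`tweetsurge` implements a case-only analysis of effect modification
between a day-level environmental exposure — a *surge* in a daily count
of suicide-related social-media posts — and time-invariant individual
characteristics of death records.

Daily suicide counts in characteristic stratum *j* are modelled as
Poisson:

    log E[Y_tj] = β0 + β1·Surge(t) + β2_j + β3_j·Surge(t) + Others(t)

where `Surge(t)` is a binary indicator, `β2_j` the main effect of the
characteristic level, `β3_j` the surge × characteristic interaction of
interest, and `Others(t)` collects seasonal terms and any other shared
time-varying risk factors. Summing the expected counts over surge and
non-surge days yields a 2 × J table of deaths whose cross-product ratio
for level *j* against the reference level is exactly `exp(β3_j)`:
every term that is shared across levels — including all of `Others(t)`
— cancels. The interaction is therefore estimable from cases alone, as
the exposure × characteristic odds ratio (binary characteristic,
equivalent to a logistic regression of the characteristic on the surge
indicator among cases) or the relative risk ratio per level against a
base level (multi-level characteristic, equivalent to a multinomial
logistic regression). The key identifying assumption is independence
of the characteristic and the exposure in the base population; the
price is that only the interaction, not the exposure main effect, is
estimable.

## Pipeline

1. **Exposure** (`exposure`): the daily count series is optionally
   detrended by a centered moving median (the upstream noise-reduction
   method used on the original data is not fully specified, so the
   module both provides this simple detrender and accepts an externally
   denoised column); the previous-day ratio `x(t)/x(t−1)` is computed;
   a day is an exposed (surge) day when its ratio is at or above the
   95th percentile of all defined ratios. Percentiles use the
   nearest-rank rule — the smallest observed value such that the
   required fraction of observations is at or below it — everywhere,
   because it is deterministic and tie-safe. The first day and days
   following a zero count have undefined ratios; they are excluded from
   the threshold computation and their exposure is undefined.
2. **Cohort** (`cohort`): records are parsed and validated
   (ICD-10 pattern letter + two digits + optional fourth character;
   age in [0, 130]); causes are selected by ICD-10 range — suicide
   X60–X84, or the sensitivity set of other external-cause deaths
   W00–X59 ∪ Y01–Y59 (taken as stated even though it omits X85–Y00,
   assault); records with missing age, missing occupation, or marital
   status "other" are excluded; age is binarized at 40 or younger
   ("young") vs older ("old"); each record is merged with the exposure
   calendar at `death_date − lag` for each configured lag (default 3
   and 7 days). The lag is a point lag, not a window: exposure is read
   at exactly one date. Records whose lagged date is outside the
   calendar or undefined are dropped and counted.
3. **Estimation** (`caseonly`): exposure × level tables are
   cross-tabulated exactly; the reported estimates are the closed-form
   cross-products with delta-method (sum of reciprocal cells) standard
   errors and Wald 95% CIs on the log scale (z = 1.959964). Each
   estimator can re-fit the corresponding maximum-likelihood model with
   statsmodels — grouped binomial logistic for the OR, multinomial
   logistic (`MNLogit`) for the RRRs, and the saturated Poisson
   log-linear model as an independent oracle — and asserts agreement
   with the closed form to 1e-6 relative. The ML fits are verification,
   never the reported path: the closed forms are exact and have no
   solver dependence. Significance is flagged at two-sided p < .05
   with no multiple-testing adjustment, matching the reporting
   convention of the study design this follows; that absence is a known
   limitation, not an endorsement.

### Zero cells

Surge days are ~5% of the calendar, so sparse strata can produce zero
cells. The estimators fail loudly by default; an explicit
`correction=True` adds 0.5 to every cell and tags the estimate as
corrected. The ML cross-check is skipped for corrected tables, which
have no individual-level counterpart.

## Synthetic data

The study's mortality records and commercial post sample are not
publicly available, so `synthetic` generates both from the model above
with known ground truth:

- **Post series**: `count(t) = round(baseline × lognormal noise ×
  spike multiplier)`, with spikes injected independently per day.
  Defaults: baseline 1920 posts/day (matching the scale of the study
  period's ~2.8M posts over 1461 days), lognormal σ = 0.25 (chosen so
  the 95th percentile of the previous-day ratio is ≈ exp(1.645·σ√2) ≈
  1.79, the threshold reported for the real series), spike probability
  0.02/day with multipliers uniform on [3, 6].
- **Death records**: per-day per-stratum Poisson counts exploded to one
  row per death. Strata are the cross-product of the configured
  characteristics, assumed independent with the stated marginal
  proportions (`log p_j` enters the baseline). `Others(t)` is a single
  sinusoid (amplitude 0.2 on the log scale, period 365.25 d — the
  magnitude is not identified by any published quantity; it only needs
  to be large enough to make confounding-immunity checks meaningful,
  and it is configurable) plus seven weekday offsets. β0 = log 105
  gives ≈ 155k suicide records over 1461 days, the scale of the real
  cohort. ICD-10 codes are uniform within the configured range, since
  only range membership matters downstream.
- **Effect lag**: the analysis reads exposure at `death_date − lag`,
  so the generator applies the surge effect at
  `Surge(t − effect_lag_days)` with `effect_lag_days = 3` by default,
  the first analysis lag. A generator that applied the effect at the
  death date itself could never be recovered by a lagged analysis;
  recovery checks compare the estimate at the matching lag. Estimates
  at non-matching lags are approximately null because surge days are
  nearly independent a few days apart.
- **Sensitivity stream**: optionally, a parallel stream of non-suicide
  external-cause deaths with all β3 = 0 and the same main effects, for
  testing that the sensitivity analysis finds nothing when nothing is
  there. It shares β0 with the suicide stream; only its null
  interactions matter.
- **RNG**: one master seed spawns independent substreams (tweets,
  deaths, sensitivity deaths) so toggling one component never perturbs
  another; identical scenario + seed gives byte-identical outputs.

The default five-characteristic scenario uses level proportions
patterned on published Japanese suicide-decedent composition and
interaction effects of the magnitude the design is meant to detect
(|log OR| ≈ 0.1–0.25, including one protective effect).

What the generator deliberately does **not** emulate: dependence
between characteristics (real age × marital-status structure), secular
trends in the post series, autocorrelated or heavy-tailed posting
noise beyond lognormal, exposure–characteristic dependence in the base
population (the design's failure mode), and reporting delays in death
registration. Passing tests therefore demonstrate that the estimators
recover the generating interaction under the design's own assumptions,
not that those assumptions hold in any real data set.

## Validation experiments and problem sizes

`scripts/acceptance.py --seed N --out results/acceptance.json`
recomputes, from scratch:

- estimator identities on 1,000 random all-positive tables (500 2×2,
  500 2×4): max relative deviation closed form vs ML, and vs the
  saturated Poisson oracle;
- parameter recovery (β3 = log 1.25, one binary characteristic, 1461
  days, ≈150k records, 200 replicates): mean log-OR bias and 95% CI
  coverage;
- type-I error (β3 = 0, 500 replicates) at p < .05;
- confounding immunity: shift of the mean log-OR when the shared
  seasonal amplitude doubles (200 paired replicates);
- sensitivity-stream null: largest absolute mean log estimate across
  all ten characteristic levels (100 replicates of the
  five-characteristic scenario);
- surge classifier: flagged-count exactness on 1,460 distinct ratios
  and mean injected-spike recall over 50 replicates;
- end-to-end ground-truth CI coverage at the effect lag over 100
  replicates of the five-characteristic scenario.

Replicate counts are chosen so each Monte-Carlo standard error is an
order of magnitude below the property band being checked, while the
whole script completes in a few minutes on one CPU. The large
replicate sweeps run with the ML cross-check disabled: the reported
numbers are the closed forms, and the closed-form↔ML identity is
established exhaustively by the table sweeps.

## Numerical notes and edge cases

- Nearest-rank percentile: rank `ceil(p/100 · n)` of the sorted defined
  values; with all-distinct ratios exactly `N − ceil(0.95N) + 1` days
  are flagged; ties can only enlarge the flagged set ("at or above" is
  inclusive).
- The surge classification is invariant to strictly increasing
  transforms of the ratio sequence.
- `MNLogit` is fitted by Newton with tol 1e-10; near machine precision
  the deviance stalls, so convergence is judged by the 1e-6 agreement
  assertion rather than the optimizer's own flag. Saturated fits
  trigger (suppressed) perfect-separation warnings by construction.
- The saturated Poisson oracle agrees with the closed form to the IRLS
  stopping tolerance (~5e-9 in practice).
- Merging is day-granular with naive calendar dates; no time zones.

## Known limitations

- The upstream noise-reduction method applied to the original post
  series is approximated by a centered moving median; users with a
  better denoiser can supply their own denoised column or ratio series.
- Only multiplicative interaction is estimated; additive interaction is
  not identified by a case-only design.
- Characteristic–exposure independence in the base population is
  assumed, not tested.
- No multiple-testing adjustment across characteristics or lags.
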