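# Methods notes

## Data model and deduplication

A FAERS-style load consists of report *versions* (PRIMARYID) grouped
into *cases* (CASEID). Deduplication keeps, per case, the version with
the latest FDA receipt date, breaking date ties by the numerically
largest PRIMARYID, then removes cases named on quarterly deletion
lists. The operation is idempotent, and deletion-list application
commutes with version selection (the list is keyed by CASEID), so it is
applied after version selection for streaming simplicity.

Partial dates are handled by intent of use: an FDA receipt date at
month (YYYYMM) or year (YYYY) precision is completed to the first day
of its period *for ordering only*; event and therapy-start dates below
day precision are treated as missing for onset arithmetic, because
onset quartiles of a single day demand day-resolution subtraction.

Ages are converted to years (decades ×10, months ÷12, weeks ÷52.1429,
days ÷365.25, hours ÷8766); a unit-less value is accepted as years only
when ≤ 150, and negative values become missing with a warning. Drug
names are canonicalized by uppercasing, whitespace collapsing, dosage-
suffix stripping, and a small explicit trade↔generic synonym table —
no fuzzy matching, trading recall for reproducibility. PT→SOC mapping
goes through a pluggable table; the bundled `data/pt_soc.csv` is a
small synthetic stand-in for the licensed MedDRA dictionary with the
same interface. Unmapped PTs are excluded from SOC-level tallies but
retained at PT level and listed in a diagnostics frame, never dropped
silently.

## Disproportionality statistics

Counting is report-level: a report contributes once to a cell however
many times an event (or several PTs of one SOC) appears on it. Within a
stratum, all four cells come from that stratum's reports only, the
standard construction that lets stratum-specific effects surface
(configurable in principle; the global-background variant is a
one-line change in `signal_table`).

The information component and EBGM are computed in their
observed/expected forms, IC = log₂(a/E) and EBGM = a/E with
E = (a+b)(a+c)/N, rather than with full Bayesian (Dirichlet/BCPNN) or
gamma-mixture (DuMouchel) priors. The simplified forms were chosen
because they reproduce the internal relationships visible in published
signal tables of this kind — IC ≈ log₂(EBGM) row by row, and EBGM ≈ the
relative reporting ratio — and they keep the two measures exactly
consistent (IC ≡ log₂ EBGM, shared expected count). The prior-based
versions are natural extension points.

Interval constructions are delta-method on the log scale throughout:
ROR uses √(1/a+1/b+1/c+1/d); PRR and IC use
√(1/a − 1/(a+b) + 1/c − 1/(c+d)) (IC rescaled by 1/ln 2); EBGM05 is the
one-sided 5% bound exp(ln EBGM − 1.645·SE) with the ROR-style SE. χ² is
Pearson's for the 2×2, reported both with and without the Yates
continuity correction; the MHRA flag uses the Yates value, conventional
in the PRR literature.

Zero cells: when any cell is 0 the Haldane–Anscombe 0.5 correction is
added to all four cells for *interval* computation only (logged each
time); point estimates stay on raw counts whenever defined; c = 0
yields an infinite PRR, flagged, without an interval. Empty strata and
an absent target drug raise immediately with diagnostic messages.

No multiple-testing correction is applied — conventional for
hypothesis-generating disproportionality screens — but every output
table carries the number of tests so users can post-filter. Ranking is
a stable sort, ties broken by event name, so repeated runs are
byte-identical.

## Time-to-onset model

Onset is event date minus the *earliest* day-precision start date of
the target drug on the report, in whole days; negative or incomplete
intervals are excluded and tallied as "missing or outlier". Calendar
bins are the closed integer ranges 0–30, 31–60, …, 181–360, > 360 days,
with percentages against both the onset-known and the all-reports
denominators (both conventions circulate; they differ by the known-
onset fraction).

The Weibull fit maximizes the uncensored two-parameter likelihood with
the shape profiled out: β solves Σtᵝ ln t/Σtᵝ − 1/β − mean(ln t) = 0 by
Brent's method (bracket grown geometrically from (10⁻³, 1]; xtol 10⁻¹²)
after scaling the data by its geometric mean for overflow safety, and
α = (mean tᵝ)^{1/β} follows in closed form. 95% CIs come from the
inverse observed information in (ln β, ln α), Hessian by central
differences (step 10⁻⁴), exponentiated back — so intervals respect
positivity. Same-day onsets enter the likelihood at 0.5 day (the
density is singular at 0 for β < 1) while reported values keep 0.
Degenerate inputs (n < 10 or a single distinct value) are rejected.
There is no censoring model: only reports with an observed onset enter.

Failure typing reads the shape CI: entirely below 1 → "early" (declining
hazard), entirely above 1 → "wear-out", spanning 1 → "random".

Known limitation: applying this continuous-density MLE to day-rounded
samples biases the shape upward by roughly +0.014 at n ≈ 1950 and
β = 0.6 (zeros floored at 0.5 day exaggerate the smallest onsets), so
CIs computed on rounded data under-cover the generating shape (~75%
instead of 95% in our replicate study); on un-rounded samples coverage
is nominal. The mean rounded-path estimate stays within ±0.02 of truth.
An interval-censored likelihood would remove the bias and is the
obvious refinement.

The empirical onset summary reports both the quartile-based median/IQR
of the raw day values and the fitted Weibull median α(ln 2)^{1/β};
with heavily zero-inflated onset data these can diverge, which is why
both are surfaced.

## Ω shrinkage for drug–drug interactions

E₁₁ is the two-margin independence product N₁.·N.₁/N with N₁. the
count of reports carrying *both* drugs — i.e. independence of the pair
exposure and the event, not the three-margin interaction baseline of
the original shrinkage-measure literature. The two-margin form is
implemented as stated in the source analysis; swapping in the
three-margin baseline would only change `omega_statistic`'s expected
count. SE(Ω) = 1/(ln 2·√N₁₁), the Poisson delta-method error of a
base-2 log count, which reproduces published CIs of this form exactly
from (Ω, N₁₁) alone. With N₁₁ = 0 the point estimate is still computed
but the CI is undefined and the pair is never significant. The target
drug is matched in the primary-suspect role; the co-drug in any role,
maximizing co-report capture. No minimum N₁₁ is imposed; counts are
always emitted so sparse findings read as exploratory.

## Stratified and indication-restricted analyses

Strata: sex (female, male); age 18–44 (18 ≤ age < 45), 45–64
(45 ≤ age < 65), ≥ 65; reporter type with "healthcare professional"
aggregating physicians and other health-professionals, pharmacists and
consumers standing alone. Unknowns (and lawyers, for reporters;
under-18s, for age) are excluded from strata but never from the overall
analysis. Strata with fewer target-drug cases than a configurable
minimum (default 50) are emitted with a `sparse` flag rather than
suppressed. The indication-restricted sensitivity analysis subsets to
reports carrying the indication PT on any drug entry and repeats the
PT-level analysis, emitting positive-count overlap, per-PT ROR deltas
and onset medians under both analyses.

## Synthetic cohorts

The generator emulates: per-report demographics drawn from realistic
categorical mixes (75.6% female, physician-majority reporters, a
2017–2025 receipt-year profile, US-dominant countries); independent-
marginal drug sets over a small rheumatology formulary with the target
biologic at 15% prevalence; per-(case, event) Bernoulli reactions with
baseline rates 0.01–0.15 multiplied by any applicable injected effects;
Weibull(0.60, 161.14 days) onset times for a 13.06% known-onset
fraction of target reports (plus ~1% negative-interval outliers to
exercise exclusions); indications (80% rheumatoid arthritis);
outcome codes; obsolete duplicate versions (10% of cases, 1–3 extra
versions, 30% of them date-tied to exercise the PRIMARYID tiebreak);
and a 2% deletion list. All sampling flows from one mandatory seed;
identical configurations produce byte-identical files.

What it does *not* emulate — and therefore what passing tests do not
establish about real FAERS data: correlated co-prescription structure,
event–event dependence within a report, reporting-propensity drift over
time, free-text or dose fields, duplicate reports with *different*
CASEIDs, and the real MedDRA hierarchy beyond a PT→SOC lookup. Cases
that draw no reaction are resampled until non-empty (reports must carry
one), which conditions event probabilities on non-emptiness and mildly
attenuates realized reporting ratios relative to the nominal
multiplier; the attenuation is well inside the tolerance bands used in
the recovery tests.

Problem sizes used in the validation suite were chosen as the smallest
that make the assertions statistically meaningful: 8,000–20,000 cases
for signal-recovery runs, 50,000 for the multiplier-calibration check,
1,951 onsets (the reference cohort's known-onset count) × 200
replicates for Weibull recovery, and 100 seeds × 1,500 cases for the
null false-positive ceiling, which is fixed a priori at 10% for the
any-method rule.

## Design choices that were genuinely open

- Stratified backgrounds are stratum-restricted rather than global
  (standard practice; the pooled-masking fixtures demonstrate why).
- Deletion lists are applied after version dedup (result-equivalent,
  simpler to stream).
- The demographic summary keeps empty categories as explicit
  0 (0.00%) rows for a fixed, machine-readable schema.
- "Signals in every SOC" style summaries are derived as ≥ 1 positive PT
  per SOC under the any-method rule; the per-SOC positive-PT count is
  emitted so such tallies can be reproduced.
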