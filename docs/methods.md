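# Methods

This note documents the models implemented in `pvsignal`, the defaults and
why they were chosen, what the synthetic generator emulates, and the
numerical decisions a maintainer would need to know. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Data model and curation

A FAERS-style quarter is a set of `$`-delimited tables (DEMO, DRUG, REAC,
OUTC, THER) keyed by PRIMARYID (one row per report *version*) and CASEID
(one safety *case*), plus an optional deleted-cases list. The dialect has
no quoting: an embedded `$` is rejected at write time; at read time a line
with surplus fields is truncated to the schema width and counted in the
parse report rather than aborting a multi-million-line load.

Curation applies three stages:

1. **Deduplication** (keep-latest): per CASEID retain the version with the
   maximal FDA receipt date FDA_DT; exact ties go to the larger PRIMARYID.
   The id comparison is numeric when the ids parse as integers (they do in
   practice) and lexicographic otherwise. Cases on a deletion list are then
   removed; lists are honoured for every quarter that ships one, since
   applying an existing list can only remove invalidated cases.
   Deduplication is idempotent and never silently loses a case: the output
   CASEID set equals the input set minus the deletion list.
2. **Drug selection**: a case belongs to the target drug if at least one
   role-PS (primary suspect) drug row matches a user pattern after
   normalisation (uppercase, trim, punctuation runs collapsed to single
   spaces; substring match). No fuzzy matching — behaviour stays auditable.
3. **Coding**: each reaction PT maps to exactly one primary SOC through a
   two-column dictionary. Unknown PTs are kept with SOC `UNMAPPED` and
   reported, never dropped. MedDRA is licensed, so the package ships only a
   toy dictionary (~90 PTs) sufficient for tests and demos; real analyses
   supply their own file.

Demographic decoding: FAERS ages arrive as (value, unit) with units YR /
DEC / MON / WK / DY; a missing unit with a plausible year value
(0 < v < 120) is treated as years, which recovers otherwise-lost
demographics and is flagged in the decode path. Age bins are <18, 18–65,
\>65 with both 18 and 65 in the middle bin — published tables label the
bins "18–65" and ">65", leaving 65 ambiguous; inclusive-upper is our
documented choice. Dates keep their precision (day / month / year) instead
of being imputed.

## Contingency tables

Counting unit is the case (presence/absence): a case reporting the same
term twice contributes once, so every table at a level shares the margins
`a+b` (target-case total) and `N` (corpus size). The comparator is the
whole ingested corpus with no drug-class restriction. These are the
dominant conventions in FAERS disproportionality work; both are stated
choices, not database facts.

## Estimators

Closed forms and flags are listed in the README. Non-obvious details:

- **ROR**: Haldane–Anscombe +0.5 on all four cells only when a cell is
  zero, flagged on the result. PRR needs no correction (it uses margin
  totals); the Bayesian estimators regularise themselves.
- **Yates χ²**: Σ(|O−E|−0.5)²/E with the correction clamped at zero when
  |O−E| < 0.5, so degenerate near-null tables report χ² = 0 rather than a
  spurious positive value.
- **BCPNN IC**: hyperparameters α₁=β₁=γ₁₁=1, α=β=2, and the joint-cell
  prior scale γ = γ₁₁(N+α)(N+β)/((a+b+α₁)(a+c+β₁)), which makes the prior
  IC expectation zero. The posterior marginals of (p₁₁, pₓ, p_y) are
  independent Betas; we report the *exact* posterior expectation of
  log₂ p₁₁/(pₓ p_y) via digamma functions and its exact variance via
  trigamma, rather than the older log-of-posterior-means approximation.
  The two agree to O(1/a), but the exact form is what a posterior
  simulation converges to, which is how the tests verify it (a 10⁶-draw
  Monte-Carlo oracle; agreement within 3 MC standard errors over 200
  random tables). IC025 = E(IC) − 2√V(IC), the conventional reported
  lower bound.
- **MGPS**: the mixture hyperparameters are fitted by direct marginal
  maximum likelihood (negative-binomial mixture) over all tables of a
  level, started at the DuMouchel defaults (α₁=0.2, β₁=0.1, α₂=2, β₂=4,
  π=1/3), L-BFGS-B on log/logit-transformed parameters, ftol 1e-6.
  Two numerical guards matter: log-pmf evaluations that come back
  non-finite *or positive* (possible at extreme gamma shapes, where the
  underlying special-function evaluation breaks down) invalidate the
  objective, and the search is bounded to |log θ| ≤ log 1e8. Without the
  first guard the optimiser can "win" with a numerically invalid
  likelihood and return a degenerate spike prior. Optimiser failure falls
  back to the start values with `converged=False`. Fitting requires ≥ 10
  tables; a screen with fewer terms (e.g. SOC level under the toy
  dictionary) uses the DuMouchel default prior, flagged unconverged.
  The fit is unstratified (no age/sex/year strata): stratified expected
  counts are an extension point, not implemented.
- **EBGM05**: the posterior is a two-component gamma mixture; the 5th
  percentile is found by Brent root-finding on the mixture CDF between the
  component quantiles (machine-precision tolerances; verified against an
  adaptive-quadrature oracle to 1e-4 relative). When one component carries
  essentially all posterior weight the bracket degenerates and the
  dominant component's quantile is returned directly.
- **Flag boundaries**: PRR ≥ 2 and χ² ≥ 4 are inclusive; IC025 > 0 and
  EBGM05 > 2 are strict; a ≥ 3 gates the frequentist flags. The composite
  flag defaults to "any method" and is configurable to "all".

## Time-to-onset

Onset = event date − earliest role-PS therapy start, in whole days; day 0
means the event was reported on the day therapy began. The strict default
policy uses only full-precision dates on both ends; month/year-precision,
missing, and negative intervals are excluded with a per-reason tally.
Which date fields define onset is not standardised in this literature; the
event-date-minus-first-PS-start definition is our documented choice.

The Weibull MLE solves the profile shape equation by Newton iteration
(tolerance 1e-10, moment-matched start k₀ = π/(σ_ln x·√6), halving steps
that would leave the positive domain) and recovers the scale in closed
form. Standard errors come from the numerically differentiated observed
information. Zero days have no Weibull density, so a policy applies first:
`shift_half_day` (default — keeps the dominant immediate-onset mass, at
the centre of the day-0 interval) or `drop_zeros`; the policy used is
recorded on every fit.

Two caveats the tests make explicit:

- **Day discretisation bias.** Flooring continuous onset times to whole
  days (as both real reports and the generator do) biases the MLE when the
  scale is only a few days — at shape 0.5 / scale 5 d the shape error from
  discretisation alone exceeds 20%. Parameter-recovery properties are
  therefore stated for the estimator on continuous data (within 10% at
  n = 5,000 across shape {0.5, 1, 1.5, 3} × scale {5, 30} d) and for the
  generator-floored route at month-scale parameters; at day-scale
  parameters the fitted shape should be read as a description of the
  discretised distribution, not an unbiased estimate of a latent
  continuous one. An interval-censored likelihood would remove this bias
  and is a known omission.
- Published onset tables in this field can be internally inconsistent
  (e.g. a day-0 majority alongside a median of 3 days); the binned
  percentages are pure arithmetic and are what the package reproduces.
  Quantiles use linear interpolation (type 7). Both readings of
  "immediate" are available via the zero policy; none is baked in.

## Summaries

Descriptive tables report counts and percentages (half-up to 2 decimals,
the convention of published report tables — note Python's built-in round()
is banker's rounding and would differ). Sex, age, reporter, year and
country use the case total as denominator with missing shown as "Not
specified"; the country table reports the top 5. Outcomes use the *number
of reported outcome codes* as denominator (a case may carry several codes,
each counted once per case) — forced by the printed percentages of the
layout this reproduces, and stated on the table object. The label
"health-professor" is retained verbatim for reporter code HP, matching the
published table it mirrors.

## Synthetic generator

The generator emulates the *structure* that stresses the pipeline:
multi-table quarters keyed by PRIMARYID/CASEID; duplicate case versions
(older version = earlier FDA_DT for half, same FDA_DT with smaller
PRIMARYID for the rest, so the keep-latest rule has unambiguous ground
truth); a deletion list; demographics with explicit missingness emitted as
empty strings; one PS drug row per case plus optional concomitant rows;
reaction rows per sampled event; therapy/event dates yielding onset
intervals with planted missing, partial and negative cases.

The reporting model: each case draws one suspect drug; each configured
event PT occurs independently with probability clip(background ×
rr[drug][pt], 0, 1). rr = 1 everywhere gives a null-calibrated corpus;
an rr > 1 entry plants a signal. Cases sampling no event receive a filler
PT common to all drugs, which keeps at least one reaction per case without
disturbing the configured Bernoulli rates. Defaults mirror the demographic
mix of a bile-acid-sequestrant corpus (62% female, ~70% consumer-reported,
~90% US, 57% age missing; five drugs with uniform shares) and an
early-dominated onset distribution (Weibull shape 0.6, scale 3 d,
continuous draws floored to days), with duplicate rate 0.10, deletion rate
0.02, onset-date missingness 0.30 and a 5% partial-date / 1%
negative-interval admixture to exercise the exclusion paths.

What it does **not** emulate — and hence what passing tests do not show
about real data: drug-name misspellings and ingredient rollup;
reporting-delay dynamics across quarters; correlated event co-reporting
(events are conditionally independent given the drug); demographic
confounding of reporting rates; version-to-version field conflicts beyond
the receipt date; and a realistic PT universe (a dozen terms versus
thousands — empirical-Bayes shrinkage is better identified the more terms
it pools, so real corpora are the *easier* case for the MGPS fit). The
target drug carries ~20% of the synthetic corpus versus a fraction of a
percent in reality; this makes comparator contamination visible (observed
a/E ≈ 2.8 under a planted rate ratio of 5), which the tests treat as the
expected behaviour of a whole-database comparator, not as estimator bias.

## Determinism and reproducibility

A SynthConfig with a fixed seed yields byte-identical files. The pipeline
writes a manifest (input hashes, echoed config, package versions) and its
outputs are reproducible given identical inputs and config. The estimator
stack is deterministic throughout; `scripts/acceptance.py` derives every
stream from its `--seed`. Problem sizes used there (20 corpora of 20,000
cases for recovery, 10 null corpora of 10,000, n = 5,000 onset samples)
are the package's validation conditions and match the property tests.
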