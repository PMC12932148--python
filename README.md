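# pvsignal

Pharmacovigilance signal detection on FAERS-style spontaneous adverse-event
reports.

Spontaneous-report databases such as the FDA Adverse Event Reporting System
(FAERS) collect safety reports for marketed drugs from clinicians, patients
and manufacturers. Because there is no denominator of exposed patients,
post-marketing safety screening asks a proportionality question instead: is
an adverse event reported *disproportionately often* for the drug of
interest, relative to the rest of the database? `pvsignal` implements the
full analysis path used in this literature — quarterly ASCII ingestion,
hierarchical case deduplication, MedDRA PT→SOC coding, 2×2
disproportionality tables, the standard four-estimator battery, and Weibull
time-to-onset modelling — plus a synthetic FAERS-quarter generator with
planted ground truth so every stage can be validated without any download.

It is intended for pharmacoepidemiologists and biostatisticians who want a
tested, scriptable, fully inspectable alternative to one-off SAS/Excel
pipelines for this kind of study.

## The statistics

For each adverse-event term (MedDRA preferred term PT, or system organ
class SOC) a 2×2 table is built at case level against the whole corpus:
`a` target-drug cases with the event, `b` without; `c` other-drug cases
with the event, `d` without; `N = a+b+c+d`, `E = (a+b)(a+c)/N`.

- **ROR** = (a·d)/(b·c), with a Wald 95% CI on the log scale;
  Haldane–Anscombe +0.5 correction when any cell is zero.
  Flag: a ≥ 3 and CI lower bound > 1.
- **PRR** = [a/(a+b)] / [c/(c+d)] with the Yates-corrected χ².
  Flag (MHRA composite): a ≥ 3, PRR ≥ 2, χ² ≥ 4.
- **BCPNN IC** = posterior mean of log₂ p₁₁/(pₓ·p_y) under the Bayesian
  confidence propagation neural network model, computed exactly via
  digamma functions; IC025 = IC − 2·SD(posterior). Flag: IC025 > 0.
- **MGPS EBGM**: DuMouchel's gamma–Poisson shrinker. `a` ~ Poisson(λE)
  with a two-component gamma mixture prior on λ fitted by marginal maximum
  likelihood across all terms; EBGM = 2^{E[log₂ λ | a]}, EBGM05 = 5th
  posterior percentile. Flag: EBGM05 > 2.

Time-to-onset (event date − earliest primary-suspect therapy start, whole
days) is tabulated into the conventional bins (immediate, 1 d, 2 d, 3 d,
4–30 d, monthly to 365 d, >365 d) and modelled as Weibull(k, λ) by Newton
MLE on the profile shape equation; k < 1 indicates an early-failure hazard
(events cluster just after initiation).

Every constant above (1.96, Yates 0.5, BCPNN priors, MGPS starting values,
all flag thresholds) is exposed in configuration objects and printed by
`pvsignal config --show-defaults`.

## Worked example

Generate a synthetic 20,000-case quarter in which cholestyramine reports
"Constipation" at five times its background rate, then screen for signals:

```python
from pvsignal import (SynthConfig, generate_quarter, build_corpus,
                      code_events, load_toy_meddra, build_tables,
                      DisproportionalityModel)
from pvsignal.curation import primary_suspect_caseids

cfg = SynthConfig(n_cases=20_000, seed=42,
                  rr_matrix={"CHOLESTYRAMINE": {"Constipation": 5.0}})
corpus, _ = build_corpus(generate_quarter(cfg))
corpus, _ = code_events(corpus, load_toy_meddra())
target = primary_suspect_caseids(corpus, ["CHOLESTYRAMINE"])
results = DisproportionalityModel(build_tables(corpus, target, "PT")).fit()
print(results.summary())
```

```
Disproportionality screen (PT level)
  terms evaluated : 13
  positive (any-method) : 1

Preferred term (PT)  Case reports        ROR (95% CI)        PRR (95% CI)      IC (IC025) EBGM (EBGM05)
   Drug ineffective          1394 0.585 (0.545-0.629)  0.733 (chi2 211.8) -0.370 (-0.458) 0.775 (0.741)
       Constipation          1209 6.682 (6.084-7.339) 4.934 (chi2 1905.2)   1.461 (1.353) 2.753 (2.625)
...
```

Only the planted pair is flagged (by all four methods): its ROR of 6.68
says the odds of a constipation report are ~6.7× higher under the target
drug than elsewhere in the corpus; IC025 = 1.35 > 0 and EBGM05 = 2.63 > 2
confirm the signal under both Bayesian models. Note EBGM (2.75) sits near
the observed relative reporting ratio a/E ≈ 2.8 rather than the planted
rate ratio 5 — with the target drug at 20% of the corpus its own signal
inflates the event margin, a comparator-contamination effect the shrinker
correctly reflects.

The onset model on the same target cases:

```python
from pvsignal import WeibullOnsetModel, collect_onsets, select_primary_suspect
samples, report = collect_onsets(select_primary_suspect(corpus, ["CHOLESTYRAMINE"]))
print(WeibullOnsetModel(samples).fit().summary())
```

```
Weibull time-to-onset model
  n used          : 2552 (zero policy: shift_half_day)
  shape (k)       : 0.7294 (SE 0.0103)
  scale (days)    : 3.4244 (SE 0.0988)
  median [IQR]    : 1.00 [0.00-5.00] days
```

A shape of 0.73 < 1 is the early-failure pattern: most events occur within
days of starting therapy.

The same flow is available from the shell:

```sh
pvsignal synth --out q1 --n-cases 20000 --seed 42
pvsignal detect q1 --drug CHOLESTYRAMINE --level pt
pvsignal onset  q1 --drug CHOLESTYRAMINE
pvsignal run    run-config.json     # full pipeline with manifest
```

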