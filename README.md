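# stopp-pip

Measurement apparatus for STOPP-criteria decision support in primary
care EMRs: a computable rule engine over coded EMR data, per-clinic
aggregate-only PIP-rate queries, an EMR data-quality probe suite, a
seeded synthetic population generator, and cluster-trial statistics.

## The problem

STOPP (Screening Tool of Older People's Prescriptions) criteria flag
potentially inappropriate prescriptions (PIPs) in patients aged 65 and
over — mostly drug–disease and drug–drug-class conditions. Embedding
them in an EMR as decision support, and then *measuring* whether alerts
changed prescribing, both run on the same substrate: coded medication
lists and coded problem lists. In community practice that substrate is
thin — free-text prescriptions, near-empty problem lists, "active"
patients unseen for years — so both the alerts and the measured rates
are attenuated by data quality before any clinical effect can show.

This package provides that entire chain as tested, reusable code, for
methodologists and EMR researchers who want to study the interplay of
rule logic, data quality, privacy-preserving measurement and
cluster-trial analysis without access to clinic data:

* **`emr_model`** — the four coded-EMR tables (patients, encounters,
  medications, problems), validation, CSV/JSON-lines round-trip.
* **`terminology`** — named ATC/ICD prefix code sets with strict
  validation; bundled fixture.
* **`rules`** — a restricted predicate DSL (no dose, no duration
  conditions — by construction) and a shipped 40-rule STOPP-style
  library in which `fire ⇒ scope` structurally.
* **`measure`** — windowed PIP counting per (patient, rule) pair:
  eligible when the opportunity (scope) condition holds, fired when the
  full condition holds; rate = 100·Σfired/Σeligible.
* **`dq_probes`** — twelve data-quality probes (dq1–dq12): encounter
  recency, demographics completeness, medication coding, problem-list
  usage, drug–diagnosis concordance.
* **`aggregation`** — the distributed-query contract: clinics emit only
  numerator/denominator aggregates; the hub sums them exactly.
* **`synth`** — a seeded multi-clinic generator with per-arm knobs for
  every data-quality pathology and planted PIP prevalences; records
  true vs observable planted counts so measurement attenuation is
  itself measurable.
* **`trial`** — arm rates, difference-in-differences, a clinic-clustered
  GEE interaction test (Mancl–DeRouen bias-corrected sandwich, t(G−2)
  reference), and two-proportion sample-size/power calculations.

## The core model

A rule is a pair of predicates over one patient's coded records in a
16-week window: `scope` (e.g. *age ≥ 65 ∧ on benzodiazepine*) and
`fire = scope ∧ extra` (e.g. *∧ falls history on the problem list*).
Per window, each (patient, rule) pair contributes at most once to

```
rate = 100 · Σ fired / Σ eligible        (missing if Σ eligible = 0)
```

The trial analysis fits the marginal logistic model

```
logit P(fire) = β₀ + β₁·arm + β₂·period + β₃·arm·period
```

on clinic × window binomial aggregates by GEE (exchangeable within
clinic) and tests β₃ — the difference-in-differences on the log-odds
scale — with a bias-corrected sandwich variance and a t reference
suited to a single-digit number of clinics. Atoms over absent data are
*false*: an uncoded prescription or undocumented problem silently
suppresses both alerts and measurement, which is the phenomenon the
synthetic experiments quantify.

## Worked example

The numbered scripts under `analysis/` run the whole study on a
synthetic population whose knobs sit at field-observed values (null
treatment effect), writing outputs under `results/`:

```
python analysis/01_simulate_study.py      # 8 clinics x 2,000 patients
python analysis/02_measure_and_aggregate.py
python analysis/03_data_quality.py
python analysis/04_trial_analysis.py
python analysis/05_calibration.py
```

`04_trial_analysis.py` prints (seed 20150201):

```
control: baseline 18/626 = 2.9%  treatment 14/615 = 2.3%  change -0.6pp
intervention: baseline 83/2713 = 3.1%  treatment 99/2666 = 3.7%  change +0.6pp
difference-in-differences: +1.2pp
GEE interaction: +0.392 log-odds (bias-corrected SE 0.532), t(6) = +0.74, p = 0.49
```

Reading: each arm's PIP rate is fired over eligible (patient, rule)
pairs pooled over clinics; the planted fire prevalences were 2.6%
(control) and 4.0% (intervention) with no treatment effect, and the
test correctly finds nothing (p = 0.49). `03_data_quality.py` shows
*why* rates this low are expected at these data-quality levels — e.g.
only ~36% of flagged-active intervention patients had a recent
encounter, ~82% of prescriptions carried codes, and ~12% of active
patients had any recent problem-list entry — and `01`'s `truth.json`
records how many planted opportunities were invisible to the coded
queries. `05_calibration.py` reports the null type-I error of the GEE
test (0.040 at 300 replicates), its power against a 20% relative
reduction, and the validated sample-size calculation (n = 1,447 per
arm for 20% → 16% at power 0.8).

A thin CLI wraps the same library for shell use — see
`stopp-pip --help` (simulate, measure, probes, respond, hub-collect,
analyze).

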