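# Methods

This package re-creates, end to end, the measurement apparatus needed to
evaluate STOPP (Screening Tool of Older People's Prescriptions) decision
support inside a community primary-care EMR: a computable rule library,
windowed measurement of potentially inappropriate prescriptions (PIPs),
an EMR data-quality probe suite, an aggregate-only distributed-query
contract, a synthetic EMR population generator, and the cluster-trial
statistics. This note records the models, conventions and design
choices, and what the synthetic experiments do and do not demonstrate.

## The rule model

A STOPP-style criterion is two predicates over one patient's *coded*
records in a time window:

* **scope** — the opportunity condition ("aged ≥ 65 and on a
  benzodiazepine"): the patient could trigger the criterion;
* **fire** — the full PIP condition, structurally `ALL_OF(scope, extra)`
  so that firing implies being in scope. The containment is validated
  at load time, which makes `fired ≤ eligible` a theorem rather than a
  hope.

The predicate DSL contains age comparisons, ATC drug-class membership,
ICD problem-group membership, gender, and boolean combinators — and
nothing else. Dose thresholds and prescription-duration conditions are
unrepresentable by construction; criteria that need them are exactly
the ones a simple EMR CDS engine and a coded aggregate query cannot
evaluate, and the loader rejects unknown predicate tags loudly.

**Missing-data semantics.** An atom over absent data is `false`, never
an error: a free-text prescription cannot satisfy `ON_MED`, a missing
date of birth cannot satisfy `AGE_GE`. This single convention is the
mechanism by which poor EMR data quality silently suppresses both
alerts and measured rates, and it is what most of the synthetic
experiments exercise.

The shipped library (`data/stopp40.yaml`) holds 40 enabled rules. The
published STOPP criteria are clinical prose without terminology
bindings, so the library is a faithful-in-kind reconstruction of the
computable subset: each rule pairs an anchor ATC drug class with an
ICD-9 trigger diagnosis group (one rule is additionally
gender-conditioned). The code-set bindings in `data/codesets.yaml` are
conventional mappings; their clinical fidelity is configuration, not
logic, and no test depends on it. Anchor classes are pairwise disjoint
across rules, as are trigger groups — a deliberate simplification that
makes the generator's planting model exact (see below) at the cost of
not modelling criteria that share a drug class.

## Measurement

The counting unit is the (patient, rule) pair within one window:
*eligible* if scope holds, *fired* if fire holds, at most once per pair
per window regardless of how many encounters or prescriptions are
involved. Only patients with ≥ 1 encounter in the window are evaluated.
The PIP rate is `100 · Σ fired / Σ eligible`; a zero denominator gives
a missing rate, not zero. With per-rule opportunity conditions the
denominator lands at a few eligible rules per at-risk patient — the
"possible PIPs" scale a deployment of this kind reports — rather than
40 × patients.

Conventions, fixed once: dates are ISO-8601; intervals are closed and
computed in whole days; "past *N* months" is `ref − ⌊N · 365.25/12⌋`
days; a medication is active in a window under interval overlap
(`start ≤ window_end` and open-ended or `end ≥ window_start`); problem
lists are status registers, so entries count from their documented date
onward, indefinitely.

## Data-quality probes

Twelve aggregate statistics (dq1–dq12) over demographics, medications
and the problem list, the three EMR areas coded PIP queries depend on.
All except dq1 are restricted to *calculated-active* patients (≥ 1
encounter in the past 24 months); dq1 itself measures how far the
EMR's own "active" flag has drifted from that reality. "Invalid date
of birth" (dq3) is defined as present but unusable — unparsable, in
the future, or implying age > 120 — and is disjoint from "no date of
birth" (dq4). The reference date is always an explicit parameter,
never "today". Probe id dq13 is reserved and intentionally
unimplemented.

## Aggregation contract

Clinics compute locally; only `AggregateAnswer` records — clinic id,
measure id, window label, numerator, denominator — cross the clinic
boundary. The type has no slots for patient-level data, so the privacy
contract is enforced by construction, and a leak-scan test additionally
checks that no generated patient identifier or birth date appears in
serialized answers. Hub arm totals are exact sums of clinic answers.
Small-cell suppression (masking numerators 1–4) exists behind a flag
but is off by default: real research networks of this design returned
unsuppressed practice-level aggregates, and the flag is provided for
deployments that need it.

## Synthetic population generator

The generator draws, per clinic: a patient panel with a configurable
elderly fraction; "ghost" patients flagged active with no encounter in
24 months; 1 + Poisson encounters per window for the rest; background
prescriptions (from a drug pool disjoint from all rule classes) with a
configurable coded fraction; recent problem-list entries at the
configured usage rate; and drug–diagnosis concordance pairs for the
three concordance probes. Every knob is a per-arm parameter and each
maps to a probe (ghost ↔ dq1, coded ↔ dq5, no-current-meds ↔ dq6,
usage ↔ dq8, concordance ↔ dq10–12), so parameter recovery is testable
knob by knob.

PIP situations are planted abstractly per (patient, rule) pair:

* the rule's **trigger condition** is chronic: present with probability
  `pip_prevalence`, persisting across both windows, dated more than 24
  months before the reference date (so it never contaminates the
  past-12-month probes). Chronic conditions are what couples a
  clinic's baseline and treatment counts — the within-cluster
  correlation the GEE's working correlation is there for;
* the **anchor prescription** is drawn per window independently with
  probability `scope_prevalence` (prescriptions start and stop), and is
  uncoded with probability `1 − coded_med_frac` like any other
  prescription;
* the **treatment effect** multiplies the probability that a would-fire
  pair is actually prescribed the anchor drug in the intervention arm's
  treatment window — the alert dissuades the prescriber — so the
  measured rate scales by the effect while the denominator barely
  moves.

Corrupting an anchor's code removes the pair from the numerator *and*
the denominator, so the measured rate stays centred on
`pip_prevalence` while the number of visible opportunities attenuates
by the coded fraction; `truth.json` records true and expected
observable counts per clinic and window so the attenuation is itself a
measurable output. This reproduces, mechanistically, the finding that
data quality — not rule logic — limits what coded queries can see.

The background-medication fraction is adjusted analytically so the
marginal no-current-meds fraction equals the dq6 knob despite planted
prescriptions; configurations where that is impossible raise a
validation error.

`paperlike_config()` sets every knob to field-observed values from a
community-EMR deployment of exactly this design: 64–71% ghost-active,
79–82% coded prescriptions, 3.5–12.3% problem-list usage, elderly
fractions of 5% and 19%, fire prevalences of 2.6% and 4.0%, a scope
prevalence tuned so an at-risk patient is eligible for ≈ 5 rules per
window, and a null treatment effect. Default panel size is 2,000
patients per clinic, four clinics per arm, stratified small/large.

**What the generator does not emulate:** realistic longitudinal
prescribing (refill chains, dose changes), free-text content,
per-rule frequency profiles (planting is uniform across rules),
correlations between comorbidities, or drift in data-quality behaviour
over time. Passing recovery tests therefore shows the *pipeline* is
unbiased under the stated model, not that real EMR data would be.

`simulate_trial_counts` is the count-level view of the same model: it
draws the clinic × window (fired, eligible) aggregates directly from
the planting model's margins, including the chronic-condition coupling.
Monte-Carlo calibration of the trial statistics uses it (≈ 10 ms per
replicate instead of ≈ 2 s), and a test pins its margins to the full
record-level pipeline.

## Trial statistics

Rates are exact integer arithmetic up to the final division. Following
the reporting convention of such trials, within-arm changes and the
difference-in-differences are computed on display-rounded rates (one
decimal by default, configurable); full-precision counts are always
carried alongside.

The effect test is a marginal logistic model on the clinic × window
binomial aggregates,
`logit P(fire) = β₀ + β₁·arm + β₂·period + β₃·arm·period`,
fitted by GEE with exchangeable working correlation within clinic.
Fitting on aggregates is score-equivalent to the per-(patient, rule)
Bernoulli rows under this design. With eight clusters the plain
sandwich variance is badly anticonservative (Monte-Carlo type-I ≈ 0.14
with a normal reference), so the returned test uses the Mancl–DeRouen
bias-corrected sandwich — per-cluster residuals inflated by
`(I − H_g)⁻¹` — computed directly on the aggregates, with the Wald
statistic referred to t(G − 2): clusters minus the number of
cluster-level parameters, the usual two-arm cluster-trial reference.
Under the null planting model this combination has Monte-Carlo type-I
error ≈ 0.044 at 2,000 replicates. Requirements and edge cases: ≥ 2
clinics per arm (otherwise the between-cluster variance does not
exist, raised as an error); an all-zero arm × window cell flags the
fit as degenerate.

`sample_size` is the textbook two-proportion normal-approximation
formula with an optional cluster design effect `1 + (m − 1)ρ`. For a
20% rate, 20% relative reduction, α = .05 two-sided and power 0.8 it
returns ≈ 1,447 per arm, which simulation of that design confirms at
0.80 power. A historical figure of ~900 encounters per arm for these
assumptions is not reproduced by any conventional variant of the
formula; the discrepancy is documented rather than reverse-engineered.
Note the difference-in-differences design needs roughly twice the
single-period n for the same power (four cell variances instead of
two); `did_interaction_power` provides the analytic interaction
approximation, validated against simulation in a symmetric design.

## Numerical and testing choices

* All generator randomness flows from one integer seed through
  `numpy.random.SeedSequence.spawn`; identical configs are
  byte-identical on disk.
* Engine evaluation memoises code-to-codeset matching; the test suite's
  independent oracle re-derives everything from raw records per call,
  so engine/oracle agreement is a real cross-check.
* Recovery tests assert agreement within 3 binomial standard errors at
  5,000 patients per clinic; calibration tests use 500 null replicates
  (count-level), with the type-I band [0.03, 0.08] at α = 0.05.
* Problem sizes in tests (panels of 100–5,000 patients, 25–500
  replicates) were chosen to give those assertions adequate resolution
  while keeping the default suite around half a minute.

## Known limitations

* The 40 rules are representative in kind, not a published enumeration;
  drug/diagnosis bindings are conventional, not authoritative.
* Disjoint anchor classes across rules exclude multi-rule drug classes
  (real STOPP re-uses NSAIDs and benzodiazepines across criteria).
* The GEE is specified at clinic level only; per-physician clustering
  within clinics is not modelled.
* `ICD-10` support exists in the data model and code sets, but the
  generator emits ICD-9 problems only.
* Aggregation models the query contract, not a transport: there is no
  networking, authentication, or map-reduce runtime.
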