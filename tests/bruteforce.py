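"""Naive reference evaluator used as an independent oracle.

Deliberately re-derives everything from the raw records on every call —
no code-match caching, no precomputed contexts — so that agreement with
the engine is a meaningful cross-check rather than a tautology.
"""

from __future__ import annotations

from datetime import date

from stopp_pip import emr_model as em
from stopp_pip.rules import (
    AgeGe,
    AgeLt,
    AllOf,
    AnyOf,
    GenderIs,
    HasProblem,
    Not,
    OnMed,
)


def _code_in(code: str | None, cs) -> bool:
    if code is None:
        return False
    c = str(code).strip().upper()
    return bool(c) and any(c.startswith(p) for p in cs.prefixes)


def naive_eval(pred, patient, meds, problems, w_start: date, w_end: date, codesets) -> bool:
    if isinstance(pred, AgeGe):
        a = em.age_at(patient, w_end)
        return a is not None and a >= pred.years
    if isinstance(pred, AgeLt):
        a = em.age_at(patient, w_end)
        return a is not None and a < pred.years
    if isinstance(pred, GenderIs):
        return patient.gender == pred.value
    if isinstance(pred, OnMed):
        cs = codesets[pred.codeset]
        return any(
            m.coded and em.med_active_in(m, w_start, w_end) and cs.system == "ATC" and _code_in(m.drug_code, cs)
            for m in meds
        )
    if isinstance(pred, HasProblem):
        cs = codesets[pred.codeset]
        return any(
            p.documented_date <= w_end and p.code_system == cs.system and _code_in(p.problem_code, cs)
            for p in problems
        )
    if isinstance(pred, AllOf):
        return all(naive_eval(x, patient, meds, problems, w_start, w_end, codesets) for x in pred.items)
    if isinstance(pred, AnyOf):
        return any(naive_eval(x, patient, meds, problems, w_start, w_end, codesets) for x in pred.items)
    if isinstance(pred, Not):
        return not naive_eval(pred.item, patient, meds, problems, w_start, w_end, codesets)
    raise TypeError(pred)


def brute_force_totals(ds, lib, window, codesets):
    """(denominator, numerator, per-rule dict) by looping patients x rules."""
    seen = {
        e.patient_id
        for e in ds.encounters
        if window.start_date <= e.encounter_date <= window.end_date
    }
    meds_by, probs_by = {}, {}
    for m in ds.medications:
        meds_by.setdefault(m.patient_id, []).append(m)
    for p in ds.problems:
        probs_by.setdefault(p.patient_id, []).append(p)
    per_rule = {}
    for rule in lib.enabled_rules:
        eligible = fired = 0
        for patient in ds.patients:
            if patient.patient_id not in seen:
                continue
            meds = meds_by.get(patient.patient_id, [])
            probs = probs_by.get(patient.patient_id, [])
            if naive_eval(rule.scope, patient, meds, probs, window.start_date, window.end_date, codesets):
                eligible += 1
                if naive_eval(rule.fire, patient, meds, probs, window.start_date, window.end_date, codesets):
                    fired += 1
        per_rule[rule.rule_id] = (eligible, fired)
    den = sum(e for e, _ in per_rule.values())
    num = sum(f for _, f in per_rule.values())
    return den, num, per_rule
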