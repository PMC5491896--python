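from __future__ import annotations

from datetime import date

import pytest
import yaml
from hypothesis import given, settings
from hypothesis import strategies as st

from stopp_pip.emr_model import ClinicDataset, EncounterRecord, MedicationRecord, PatientRecord, ProblemRecord
from stopp_pip.rules import (
    AgeGe,
    AllOf,
    HasProblem,
    Not,
    OnMed,
    PatientContext,
    RuleError,
    StoppRule,
    build_contexts,
    evaluate_predicate,
    load_rule_library,
    parse_predicate,
    referenced_codesets,
)

W_START, W_END = date(2015, 2, 2), date(2015, 5, 24)


def ctx(age=70, gender="F", meds=(), problems=()):
    return PatientContext("p", age, gender, frozenset(meds), frozenset(problems))


RULE_YAML = """
version: test
rules:
  - rule_id: r1
    title: benzodiazepine with falls
    scope: &s
      all_of:
        - age_ge: 65
        - on_med: benzodiazepine_anxiolytics
    fire:
      all_of:
        - *s
        - has_problem: falls_history
"""


class TestLoading:
    def test_minimal_library_loads(self, tmp_path, codesets):
        p = tmp_path / "rules.yaml"
        p.write_text(RULE_YAML)
        lib = load_rule_library(p, codesets)
        (rule,) = lib.rules
        assert rule.scope == AllOf((AgeGe(65), OnMed("benzodiazepine_anxiolytics")))
        assert any(c == rule.scope for c in rule.fire.items)

    def test_fire_omitting_scope_rejected(self, tmp_path, codesets):
        bad = yaml.safe_load(RULE_YAML)
        bad["rules"][0]["fire"] = {
            "all_of": [{"age_ge": 65}, {"has_problem": "falls_history"}]
        }
        p = tmp_path / "rules.yaml"
        p.write_text(yaml.safe_dump(bad))
        with pytest.raises(RuleError, match="fire must be ALL_OF"):
            load_rule_library(p, codesets)

    def test_unknown_codeset_rejected(self, tmp_path, codesets):
        text = RULE_YAML.replace("falls_history", "no_such_set")
        p = tmp_path / "rules.yaml"
        p.write_text(text)
        with pytest.raises(RuleError, match="no_such_set"):
            load_rule_library(p, codesets)

    def test_dose_and_duration_predicates_unrepresentable(self):
        with pytest.raises(RuleError, match="dose/duration"):
            parse_predicate({"dose_exceeds_mg": 5})
        with pytest.raises(RuleError):
            parse_predicate({"duration_weeks_ge": 4})

    def test_default_library_structure(self, library, codesets):
        assert len(library.enabled_rules) == 40
        for rule in library.enabled_rules:
            # structurally valid by construction; codesets all resolve
            for name in referenced_codesets(rule.scope) | referenced_codesets(rule.fire):
                assert name in codesets


class TestEvaluation:
    def test_age_gate(self):
        pred = AgeGe(65)
        assert evaluate_predicate(pred, ctx(age=70))
        assert not evaluate_predicate(pred, ctx(age=64))
        assert not evaluate_predicate(pred, ctx(age=None))  # missing -> false

    def test_uncoded_med_cannot_fire_on_med(self, codesets):
        # a patient whose only benzodiazepine prescription is free-text:
        # the coded context contains nothing, so ON_MED is false --
        # the data-quality suppression mechanism in one line.
        ds = ClinicDataset(
            clinic_id="c",
            patients=[PatientRecord("p", "c", birth_date_raw="1940-01-01", gender="F")],
            encounters=[EncounterRecord("p", date(2015, 3, 1))],
            medications=[MedicationRecord("p", None, "diazepam (free text)", date(2015, 1, 1), None)],
        )
        contexts = build_contexts(ds, codesets, W_START, W_END)
        assert not evaluate_predicate(OnMed("benzodiazepine_anxiolytics"), contexts["p"])

    def test_coded_med_fires_on_med(self, codesets):
        ds = ClinicDataset(
            clinic_id="c",
            patients=[PatientRecord("p", "c", birth_date_raw="1940-01-01", gender="F")],
            encounters=[EncounterRecord("p", date(2015, 3, 1))],
            medications=[MedicationRecord("p", "N05BA01", "diazepam", date(2015, 1, 1), None)],
        )
        contexts = build_contexts(ds, codesets, W_START, W_END)
        assert evaluate_predicate(OnMed("benzodiazepine_anxiolytics"), contexts["p"])

    def test_not_on_empty_problem_list_is_vacuously_true(self):
        assert evaluate_predicate(Not(HasProblem("copd_icd9")), ctx(problems=()))

    def test_problems_are_cumulative(self, codesets):
        # documented years before the window still counts at evaluation time
        ds = ClinicDataset(
            clinic_id="c",
            patients=[PatientRecord("p", "c", birth_date_raw="1940-01-01", gender="F")],
            encounters=[EncounterRecord("p", date(2015, 3, 1))],
            problems=[ProblemRecord("p", "E888", "ICD9", date(2009, 1, 1))],
        )
        contexts = build_contexts(ds, codesets, W_START, W_END)
        assert evaluate_predicate(HasProblem("falls_history"), contexts["p"])

    def test_patient_without_encounter_excluded(self, codesets):
        ds = ClinicDataset(
            clinic_id="c",
            patients=[PatientRecord("p", "c", birth_date_raw="1940-01-01")],
            encounters=[EncounterRecord("p", date(2014, 1, 1))],
        )
        assert build_contexts(ds, codesets, W_START, W_END) == {}


class TestProperties:
    @given(st.data())
    @settings(derandomize=True, max_examples=50)
    def test_negation_free_monotonicity(self, codesets, library, data):
        """Adding a coded record can flip a negation-free rule only
        false -> true, never true -> false."""
        rule = data.draw(st.sampled_from(library.enabled_rules))
        base_meds = data.draw(st.sets(st.sampled_from(sorted(
            {n for n, c in codesets.items() if c.system == "ATC"}))))
        base_probs = data.draw(st.sets(st.sampled_from(sorted(
            {n for n, c in codesets.items() if c.system == "ICD9"}))))
        age = data.draw(st.integers(60, 90))
        c1 = ctx(age=age, meds=base_meds, problems=base_probs)
        extra_med = data.draw(st.sampled_from(sorted(
            {n for n, c in codesets.items() if c.system == "ATC"})))
        c2 = ctx(age=age, meds=base_meds | {extra_med}, problems=base_probs)
        for pred in (rule.scope, rule.fire):
            if evaluate_predicate(pred, c1):
                assert evaluate_predicate(pred, c2)

    def test_evaluation_independent_of_record_order(self, codesets, library):
        import random

        from stopp_pip.measure import MeasurementWindow, measure_pips
        from stopp_pip.synth import generate_study

        from conftest import stress_config

        study = generate_study(stress_config(seed=11, patients=100))
        ds = study.clinics[0]
        w = MeasurementWindow(W_START, W_END, "baseline")
        before = measure_pips(ds, library, w, codesets).to_obj()
        rng = random.Random(0)
        for table in (ds.patients, ds.encounters, ds.medications, ds.problems):
            rng.shuffle(table)
        after = measure_pips(ds, library, w, codesets).to_obj()
        assert before == after
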