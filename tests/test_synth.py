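from __future__ import annotations

import numpy as np
import pytest

from stopp_pip.measure import measure_pips
from stopp_pip.synth import (
    ArmParams,
    GeneratorConfig,
    generate_study,
    paperlike_config,
    simulate_trial_counts,
)

from conftest import stress_arm, stress_config


class TestDeterminism:
    def test_same_seed_byte_identical_output(self, tmp_path):
        cfg = stress_config(seed=31, patients=60)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_study(cfg).write(d1)
        generate_study(cfg).write(d2)
        files1 = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        files2 = sorted(p.relative_to(d2) for p in d2.rglob("*") if p.is_file())
        assert files1 == files2
        for rel in files1:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes()

    def test_different_seeds_differ(self):
        a = generate_study(stress_config(seed=1, patients=60))
        b = generate_study(stress_config(seed=2, patients=60))
        assert [p.patient_id for p in a.clinics[0].patients] != [
            p.patient_id for p in b.clinics[0].patients
        ]


class TestStructure:
    def test_arms_and_strata_balanced(self):
        cfg = paperlike_config(seed=4, patients_per_clinic=50)
        study = generate_study(cfg)
        arms = [c.arm for c in study.clinics]
        assert arms.count("control") == arms.count("intervention") == 4
        for arm in ("control", "intervention"):
            strata = [c.size_stratum for c in study.clinics if c.arm == arm]
            assert strata.count("small") == strata.count("large") == 2

    def test_datasets_validate(self, small_study):
        for ds in small_study.clinics:
            ds.validate()

    def test_truth_bookkeeping_tracks_measurement(self, small_study, library, codesets):
        """The engine's observed counts sit near the generator's expected
        observable counts (binomial noise), and never exceed the truth."""
        for ds in small_study.clinics:
            for w in (small_study.baseline, small_study.treatment):
                t = small_study.truth[ds.clinic_id][w.label]
                counts = measure_pips(ds, library, w, codesets)
                assert counts.denominator <= t["true_possible"]
                assert counts.numerator <= t["true_pips"]
                sd = 3 * np.sqrt(max(t["true_possible"], 1))
                assert abs(counts.denominator - t["obs_possible_expected"]) <= sd


class TestDegenerateConfigs:
    def test_zero_pip_prevalence_yields_zero_numerators(self, library, codesets):
        cfg = stress_config(seed=8, patients=150)
        cfg = cfg.model_copy(
            update={
                "control": stress_arm(pip_prevalence=0.0),
                "intervention": stress_arm(pip_prevalence=0.0),
            }
        )
        study = generate_study(cfg)
        for ds in study.clinics:
            for w in (study.baseline, study.treatment):
                assert measure_pips(ds, library, w, codesets).numerator == 0

    def test_impossible_no_meds_config_rejected(self):
        cfg = stress_config(seed=1, patients=10)
        cfg = cfg.model_copy(
            update={"control": stress_arm(no_current_meds_frac=1.0, scope_prevalence=0.5)}
        )
        with pytest.raises(ValueError, match="impossible config"):
            generate_study(cfg)

    def test_proportions_validated(self):
        with pytest.raises(Exception):
            ArmParams(
                frac_age_ge65=1.5,
                ghost_active_frac=0.1,
                coded_med_frac=0.8,
                no_current_meds_frac=0.5,
                problem_list_usage=0.1,
                scope_prevalence=0.1,
                pip_prevalence=0.1,
            )


class TestPlantedPrevalenceRecovery:
    def test_planted_pip_rate_recovered(self, library, codesets):
        """With thousands of eligible pairs, the measured PIP rate sits
        within 3 binomial SEs of the planted fire probability."""
        cfg = paperlike_config(seed=99, patients_per_clinic=5000, n_clinics_per_arm=1)
        study = generate_study(cfg)
        for ds in study.clinics:
            p = cfg.arm(ds.arm).pip_prevalence
            for w in (study.baseline, study.treatment):
                counts = measure_pips(ds, library, w, codesets)
                assert counts.denominator >= 300
                se = np.sqrt(p * (1 - p) / counts.denominator)
                rate = counts.numerator / counts.denominator
                assert abs(rate - p) <= 3 * se, (ds.arm, w.label, rate, p)

    def test_sample_size_assumption_scale(self, library, codesets):
        """A 20% fire probability over ~5,000 eligible pairs is measured
        as 20% within 3 binomial SEs — the planning assumption of a
        cluster trial at this scale."""
        arm = stress_arm(pip_prevalence=0.20, scope_prevalence=0.2, coded_med_frac=0.9,
                         missing_dob_frac=0.0, invalid_dob_frac=0.0, ghost_active_frac=0.1)
        cfg = GeneratorConfig(seed=17, n_clinics_per_arm=1, patients_per_clinic=1200,
                              control=arm, intervention=arm)
        study = generate_study(cfg)
        den = num = 0
        for ds in study.clinics:
            c = measure_pips(ds, library, study.baseline, codesets)
            den += c.denominator
            num += c.numerator
        assert den >= 5000
        se = np.sqrt(0.2 * 0.8 / den)
        assert abs(num / den - 0.20) <= 3 * se

    def test_count_level_simulation_matches_pipeline_means(self, library, codesets):
        """simulate_trial_counts reproduces the margins of the full
        record-level pipeline (same config, independent seeds)."""
        cfg = paperlike_config(seed=55, patients_per_clinic=3000)
        study = generate_study(cfg)
        obs = {("control", "baseline"): [0, 0], ("control", "treatment"): [0, 0],
               ("intervention", "baseline"): [0, 0], ("intervention", "treatment"): [0, 0]}
        for ds in study.clinics:
            for w in (study.baseline, study.treatment):
                c = measure_pips(ds, library, w, codesets)
                obs[(ds.arm, w.label)][0] += c.numerator
                obs[(ds.arm, w.label)][1] += c.denominator
        rng = np.random.default_rng(56)
        reps = [simulate_trial_counts(cfg, rng) for _ in range(30)]
        for (arm, win), (num, den) in obs.items():
            sims_den = np.array([
                r[(r.arm == arm) & (r.window == win)]["eligible"].sum() for r in reps
            ])
            sims_num = np.array([
                r[(r.arm == arm) & (r.window == win)]["fired"].sum() for r in reps
            ])
            # pipeline totals within 4 sim-SDs of the count-level model
            assert abs(den - sims_den.mean()) <= 4 * max(sims_den.std(), 10.0), (arm, win)
            assert abs(num - sims_num.mean()) <= 4 * max(sims_num.std(), 5.0), (arm, win)
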