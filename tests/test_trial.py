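from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from stopp_pip.aggregation import AggregateAnswer, hub_collect
from stopp_pip.synth import paperlike_config, simulate_trial_counts
from stopp_pip.trial import (
    PowerSpec,
    counts_frame,
    did_interaction_power,
    gee_test,
    sample_size,
    summarize,
    two_proportion_power,
)


def hub_from_totals(totals):
    """totals: {(arm, clinic, window): (num, den)}"""
    answers = {}
    arms = {}
    for (arm, clinic, window), (num, den) in totals.items():
        answers.setdefault(clinic, []).append(AggregateAnswer(clinic, "total", window, num, den))
        arms[clinic] = arm
    return hub_collect(answers, arms)


PRINTED = {
    ("control", "c1", "baseline"): (138, 5308),
    ("control", "c1", "treatment"): (157, 5792),
    ("intervention", "i1", "baseline"): (742, 18331),
    ("intervention", "i1", "treatment"): (768, 18668),
}


class TestSummarize:
    def test_reproduces_printed_table(self):
        res = summarize(hub_from_totals(PRINTED))
        assert res.rates["control"] == {"baseline": 2.6, "treatment": 2.7}
        assert res.rates["intervention"] == {"baseline": 4.0, "treatment": 4.1}
        assert res.change == {"control": 0.1, "intervention": 0.1}
        assert res.difference_in_differences == 0.0

    def test_two_decimal_display(self):
        res = summarize(hub_from_totals(PRINTED), decimals={"intervention": 2})
        assert res.rates["intervention"]["treatment"] == 4.11

    def test_missing_window_is_error(self):
        totals = {k: v for k, v in PRINTED.items() if k[2] == "baseline"}
        with pytest.raises(ValueError, match="missing data"):
            summarize(hub_from_totals(totals))


def df_from_counts(rows):
    return pd.DataFrame(rows, columns=["clinic_id", "arm", "window", "fired", "eligible"])


def balanced_null_df(rng, n_per_arm=4, p=0.05, eligible=800):
    rows = []
    for arm in ("control", "intervention"):
        for i in range(n_per_arm):
            for w in ("baseline", "treatment"):
                rows.append((f"{arm}-{i}", arm, w, int(rng.binomial(eligible, p)), eligible))
    return df_from_counts(rows)


class TestGee:
    def test_single_clinic_arm_rejected(self):
        rng = np.random.default_rng(0)
        df = balanced_null_df(rng)
        df = df[df.clinic_id != "control-0"]
        df = df[df.clinic_id != "control-1"]
        df = df[df.clinic_id != "control-2"]
        with pytest.raises(ValueError, match="clinic"):
            gee_test(df)

    def test_all_zero_cell_flagged_degenerate(self):
        rng = np.random.default_rng(0)
        df = balanced_null_df(rng)
        df.loc[(df.arm == "control") & (df.window == "treatment"), "fired"] = 0
        assert gee_test(df).degenerate

    def test_doubling_counts_leaves_estimate_unchanged(self):
        rng = np.random.default_rng(3)
        df = balanced_null_df(rng)
        r1 = gee_test(df)
        df2 = df.copy()
        df2["fired"] *= 2
        df2["eligible"] *= 2
        r2 = gee_test(df2)
        assert r2.estimate == pytest.approx(r1.estimate, abs=1e-8)

    def test_point_estimate_matches_binomial_glm(self):
        """The GEE point estimate on aggregates coincides with the
        independent-GLM estimate for this balanced design."""
        rng = np.random.default_rng(12)
        df = balanced_null_df(rng)
        r = gee_test(df)
        X = pd.DataFrame(
            {
                "arm": (df.arm == "intervention").astype(float),
                "period": (df.window == "treatment").astype(float),
            }
        )
        X["interaction"] = X.arm * X.period
        glm = sm.GLM(
            np.c_[df.fired, df.eligible - df.fired],
            sm.add_constant(X),
            family=sm.families.Binomial(),
        ).fit()
        assert r.estimate == pytest.approx(glm.params["interaction"], abs=1e-4)

    def test_interaction_se_against_cluster_bootstrap(self):
        """Bias-corrected sandwich SE is of the same magnitude as a
        cluster (clinic) bootstrap of the GLM interaction."""
        rng = np.random.default_rng(7)
        df = balanced_null_df(rng, n_per_arm=6, p=0.05, eligible=2000)
        r = gee_test(df)

        def glm_interaction(frame):
            X = pd.DataFrame(
                {
                    "arm": (frame.arm == "intervention").astype(float),
                    "period": (frame.window == "treatment").astype(float),
                }
            )
            X["interaction"] = X.arm * X.period
            fit = sm.GLM(
                np.c_[frame.fired, frame.eligible - frame.fired],
                sm.add_constant(X),
                family=sm.families.Binomial(),
            ).fit()
            return fit.params["interaction"]

        boots = []
        clinics = {arm: sorted(df[df.arm == arm].clinic_id.unique()) for arm in ("control", "intervention")}
        for b in range(200):
            parts = []
            for arm, ids in clinics.items():
                take = rng.choice(ids, size=len(ids), replace=True)
                for k, cid in enumerate(take):
                    part = df[df.clinic_id == cid].copy()
                    part["clinic_id"] = f"{arm}-b{k}"
                    parts.append(part)
            boots.append(glm_interaction(pd.concat(parts)))
        boot_se = np.std(boots, ddof=1)
        assert 0.4 * boot_se <= r.robust_se <= 2.5 * boot_se

    def test_null_interaction_near_zero_on_paperlike_sim(self):
        cfg = paperlike_config(seed=0, patients_per_clinic=4000)
        rng = np.random.default_rng(300)
        ests = [gee_test(simulate_trial_counts(cfg, rng)).estimate for _ in range(40)]
        assert abs(np.mean(ests)) < 0.1

    def test_power_grows_with_effect_size(self):
        cfg = paperlike_config(seed=0, patients_per_clinic=4000)
        rng = np.random.default_rng(8)
        rej = {}
        for effect in (1.0, 0.5):
            c = cfg.model_copy(update={"treatment_effect": effect})
            rej[effect] = np.mean(
                [gee_test(simulate_trial_counts(c, rng)).p_value < 0.05 for _ in range(60)]
            )
        assert rej[0.5] > rej[1.0]

    def test_power_self_consistency_symmetric_design(self):
        """Empirical interaction power tracks the analytic Wald
        approximation in a symmetric two-arm design (coarse check)."""
        cfg = paperlike_config(seed=0, patients_per_clinic=2000)
        sym = cfg.model_copy(update={"control": cfg.intervention, "treatment_effect": 0.6})
        rng = np.random.default_rng(21)
        R = 120
        rejected = 0
        cells = []
        for _ in range(R):
            df = simulate_trial_counts(sym, rng)
            cells.append(df[df.arm == "intervention"].eligible.mean())
            rejected += gee_test(df).p_value < 0.05
        emp = rejected / R
        pairs_per_cell = int(np.mean(cells) * sym.n_clinics_per_arm)
        analytic = did_interaction_power(0.04, 0.6, pairs_per_cell, n_clinics=8)
        assert abs(emp - analytic) <= 0.15, (emp, analytic)


class TestSampleSize:
    def test_two_proportion_baseline_case(self):
        ps = PowerSpec(p_control=0.20, relative_reduction=0.20)
        n = sample_size(ps)["n_per_arm"]
        assert 1400 <= n <= 1450

    def test_simulation_power_at_returned_n(self):
        """At the returned n the simulated two-proportion test achieves
        the requested power within 3 Monte-Carlo SEs."""
        ps = PowerSpec(p_control=0.20, relative_reduction=0.20, power=0.8)
        n = sample_size(ps)["n_per_arm"]
        rng = np.random.default_rng(14)
        R = 800
        rej = 0
        for _ in range(R):
            x1 = rng.binomial(n, ps.p_control)
            x2 = rng.binomial(n, ps.p_intervention)
            p1, p2 = x1 / n, x2 / n
            pbar = (x1 + x2) / (2 * n)
            se = np.sqrt(2 * pbar * (1 - pbar) / n)
            rej += abs(p1 - p2) / se > 1.959963984540054
        emp = rej / R
        mc_se = np.sqrt(0.8 * 0.2 / R)
        assert abs(emp - ps.power) <= 3 * mc_se + 0.01, emp
        assert two_proportion_power(0.20, 0.16, n) == pytest.approx(0.80, abs=0.01)

    def test_monotone_in_power(self):
        lo = sample_size(PowerSpec(0.2, 0.2, power=0.8))["n_per_arm"]
        hi = sample_size(PowerSpec(0.2, 0.2, power=0.9))["n_per_arm"]
        assert lo < hi

    def test_design_effect_scales_linearly(self):
        base = sample_size(PowerSpec(0.2, 0.2))["n_per_arm"]
        doubled = sample_size(PowerSpec(0.2, 0.2, design_effect=2.0))["n_per_arm"]
        assert doubled == pytest.approx(2 * base, abs=1)

    def test_zero_effect_rejected(self):
        with pytest.raises(ValueError, match="relative_reduction"):
            PowerSpec(p_control=0.2, relative_reduction=0.0)

    def test_clinics_per_arm(self):
        out = sample_size(PowerSpec(0.2, 0.2), encounters_per_clinic=120)
        assert out["clinics_per_arm"] == int(np.ceil(out["n_per_arm"] / 120))
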