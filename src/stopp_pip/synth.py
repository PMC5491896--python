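"""Seeded generator of multi-clinic synthetic EMR populations.

The generator emulates a two-arm cluster trial over primary-care
clinics: a baseline window (16 weeks before study start) and a
treatment window (the 16-week study period), a patient panel per clinic
with a configurable elderly fraction, and — critically — the
data-quality pathologies a community EMR exhibits: "ghost" patients
flagged active but unseen for years, free-text (uncoded) prescriptions,
sparse problem-list usage, and incomplete drug–diagnosis concordance.

PIP situations are planted abstractly per (patient, rule) pair:

* each elderly patient seen in a window is given the rule's anchor
  drug-class prescription with probability ``scope_prevalence`` (per
  window, independently — prescriptions start and stop);
* each (patient, rule) pair carries the rule's trigger condition as a
  *chronic* problem-list entry with probability ``pip_prevalence``; the
  condition persists across windows, which is what couples a clinic's
  baseline and treatment counts;
* in the intervention arm's treatment window, ``treatment_effect``
  scales the probability that a would-fire pair is actually prescribed
  the anchor drug (the alert dissuades the prescriber), so the measured
  fire rate scales by the effect while the opportunity denominator is
  nearly unchanged.

Data-quality corruption is applied to the planted records themselves:
an anchor prescription is uncoded with probability
``1 - coded_med_frac``, which removes the pair from *both* the
numerator and the denominator of the measured rate (the opportunity
itself becomes invisible).  The generator therefore records both the
true planted counts and the expected observable counts per clinic and
window (``truth``), so the attenuation of measurement by data quality
is itself measurable; the measured *rate* stays centred on
``pip_prevalence`` because numerator and denominator are thinned by the
same coding process.  Planted trigger conditions are problem-list
entries, which in this EMR model always carry a code, and are dated
well before the baseline window so they never contaminate the
"documented in the past 12 months" probes.

All randomness flows from the single config seed; identical configs
yield byte-identical datasets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from datetime import date, timedelta
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .emr_model import (
    ClinicDataset,
    EncounterRecord,
    MedicationRecord,
    PatientRecord,
    ProblemRecord,
    table_paths,
    write_clinic_dataset,
)
from .measure import DEFAULT_WINDOW_DAYS, MeasurementWindow
from .rules import GenderIs, AllOf, OnMed, RuleLibrary, StoppRule, default_rule_library, referenced_codesets
from .terminology import CodeSet, default_codesets, matches

__all__ = [
    "ArmParams",
    "GeneratorConfig",
    "StudyDataset",
    "generate_study",
    "paperlike_config",
    "simulate_trial_counts",
]

# Background ("therapeutically neutral") drug pool: deliberately disjoint
# from every rule anchor class and from the concordance probe drugs, so
# background prescribing never creates rule opportunities.
BACKGROUND_ATC = ("N02BE01", "A02BC01", "C10AA01", "B03BB01", "A11GA01", "S01XA20", "D02AC")
#: Non-diabetes filler codes for recent problem-list entries; disjoint
#: from every rule trigger set and from the concordance disease sets.
BACKGROUND_ICD9 = ("272.4", "724.2", "461.9", "372.30")
DIABETES_CODE = "250.00"

CONCORDANCE_PAIRS = {
    # probe knob name -> (drug codeset, drug code, disease codeset)
    "tiotropium_copd": ("tiotropium", "R03BB04", "copd_icd9"),
    "levothyroxine_hypothyroidism": ("levothyroxine", "H03AA01", "hypothyroidism_icd9"),
    "anti_gout_gout": ("anti_gout", "M04AA01", "gout_icd9"),
}


class ArmParams(BaseModel):
    """Per-arm knobs; each maps to a probe or to the outcome model."""

    frac_age_ge65: float = Field(ge=0, le=1)
    ghost_active_frac: float = Field(ge=0, le=1)  # 1 - dq1
    encounters_per_patient_per_window: float = Field(default=2.0, gt=0)
    background_meds_mean: float = Field(default=2.0, ge=1)
    coded_med_frac: float = Field(ge=0, le=1)  # dq5
    no_current_meds_frac: float = Field(ge=0, le=1)  # dq6
    problem_list_usage: float = Field(ge=0, le=1)  # dq8
    diabetes_share: float = Field(default=0.3, ge=0, le=1)  # shapes dq9
    missing_gender_frac: float = Field(default=0.0, ge=0, le=1)  # dq2
    missing_dob_frac: float = Field(default=0.0, ge=0, le=1)  # dq4
    invalid_dob_frac: float = Field(default=0.0, ge=0, le=1)  # dq3
    concordance: dict[str, float] = Field(
        default_factory=lambda: {k: 0.5 for k in CONCORDANCE_PAIRS}
    )  # dq10-12
    concordance_drug_frac: float = Field(default=0.01, ge=0, le=1)
    scope_prevalence: float = Field(ge=0, le=1)  # P(anchor drug | elderly, seen), per rule+window
    pip_prevalence: float = Field(ge=0, le=1)  # P(trigger condition | pair)

    @field_validator("concordance")
    @classmethod
    def _known_pairs(cls, v: dict[str, float]) -> dict[str, float]:
        unknown = set(v) - set(CONCORDANCE_PAIRS)
        if unknown:
            raise ValueError(f"unknown concordance pair(s): {sorted(unknown)}")
        for k, p in v.items():
            if not 0 <= p <= 1:
                raise ValueError(f"concordance[{k}] outside [0,1]")
        return v


class GeneratorConfig(BaseModel):
    seed: int = 0
    n_clinics_per_arm: int = Field(default=4, ge=1)
    patients_per_clinic: int = Field(default=2000, ge=1)
    physicians_small: int = Field(default=2, ge=1)
    physicians_large: int = Field(default=5, ge=1)
    study_start: date = date(2015, 2, 2)
    window_days: int = DEFAULT_WINDOW_DAYS
    treatment_effect: float = Field(default=1.0, ge=0)  # multiplies fire rate, intervention x treatment
    control: ArmParams
    intervention: ArmParams

    def arm(self, name: str) -> ArmParams:
        return {"control": self.control, "intervention": self.intervention}[name]

    def windows(self) -> tuple[MeasurementWindow, MeasurementWindow]:
        t0 = self.study_start
        baseline = MeasurementWindow(
            t0 - timedelta(days=self.window_days), t0 - timedelta(days=1), "baseline"
        )
        treatment = MeasurementWindow(t0, t0 + timedelta(days=self.window_days - 1), "treatment")
        return baseline, treatment

    @property
    def ref_date(self) -> date:
        return self.windows()[1].end_date


@dataclass
class StudyDataset:
    clinics: list[ClinicDataset]
    config: GeneratorConfig
    baseline: MeasurementWindow
    treatment: MeasurementWindow
    #: per (clinic, window): true planted counts and expected observable
    #: counts after data-quality corruption.
    truth: dict = dc_field(default_factory=dict)

    @property
    def arms(self) -> dict[str, str]:
        return {c.clinic_id: c.arm for c in self.clinics}

    def write(self, directory: str | Path, fmt: str = "csv") -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        manifest = []
        for c in self.clinics:
            cdir = d / c.clinic_id
            write_clinic_dataset(c, table_paths(cdir, fmt))
            manifest.append(
                {
                    "clinic_id": c.clinic_id,
                    "arm": c.arm,
                    "physician_count": c.physician_count,
                    "size_stratum": c.size_stratum,
                }
            )
        (d / "truth.json").write_text(
            json.dumps(
                {
                    "clinics": manifest,
                    "windows": {
                        "baseline": [self.baseline.start_date.isoformat(), self.baseline.end_date.isoformat()],
                        "treatment": [self.treatment.start_date.isoformat(), self.treatment.end_date.isoformat()],
                    },
                    "ref_date": self.config.ref_date.isoformat(),
                    "planted": self.truth,
                    "config": json.loads(self.config.model_dump_json()),
                },
                indent=1,
            )
        )


def _rule_planting_info(lib: RuleLibrary, codesets: dict[str, CodeSet]):
    """Per enabled rule: anchor drug code to plant, trigger problem code,
    and the gender the scope requires (if any)."""
    info = []
    for rule in lib.enabled_rules:
        anchor_code = trigger_code = None
        gender = None
        for atom_set in (referenced_codesets(rule.scope),):
            for name in sorted(atom_set):
                cs = codesets[name]
                if cs.system == "ATC" and anchor_code is None:
                    anchor_code = _atc_rep(min(cs.prefixes))
        fire_only = referenced_codesets(rule.fire) - referenced_codesets(rule.scope)
        for name in sorted(fire_only):
            cs = codesets[name]
            if cs.system in ("ICD9", "ICD10"):
                trigger_code = (min(cs.prefixes), cs.system)
        gender = _required_gender(rule.scope)
        if anchor_code is None or trigger_code is None:
            raise ValueError(f"{rule.rule_id}: cannot derive planting codes")
        info.append((rule.rule_id, anchor_code, trigger_code, gender))
    return info


def _required_gender(pred) -> Optional[str]:
    if isinstance(pred, GenderIs):
        return pred.value
    if isinstance(pred, AllOf):
        for x in pred.items:
            g = _required_gender(x)
            if g is not None:
                return g
    return None


def _atc_rep(prefix: str) -> str:
    """Extend an ATC class prefix to a full 7-character code."""
    pad = "A00AA01"
    return prefix + pad[len(prefix):]


def _check_disjoint(codesets: dict[str, CodeSet], lib: RuleLibrary) -> None:
    """Background pools must not create rule opportunities or triggers."""
    rule_sets = set()
    for r in lib.enabled_rules:
        rule_sets |= referenced_codesets(r.scope) | referenced_codesets(r.fire)
    for code in BACKGROUND_ATC:
        for name in rule_sets:
            cs = codesets[name]
            if cs.system == "ATC" and matches(code, cs):
                raise ValueError(f"background drug {code} collides with codeset {name}")
        for knob, (dset, dcode, _) in CONCORDANCE_PAIRS.items():
            if matches(code, codesets[dset]):
                raise ValueError(f"background drug {code} collides with probe drug {knob}")
    for code in BACKGROUND_ICD9 + (DIABETES_CODE,):
        for name in rule_sets:
            cs = codesets[name]
            if cs.system == "ICD9" and matches(code, cs):
                raise ValueError(f"background problem {code} collides with codeset {name}")


def _feasible(cfg: GeneratorConfig, arm: ArmParams, n_rules: int) -> float:
    """Fraction of patients given background medications, adjusted so the
    marginal no-current-meds fraction equals the knob despite planted
    anchor prescriptions.  Raises for impossible configurations."""
    s, p, e = arm.scope_prevalence, arm.pip_prevalence, cfg.treatment_effect
    scope_t = s * (1 - p * (1 - min(e, 1.0)))
    pi_t = 1.0 - (1.0 - scope_t) ** n_rules
    denom = 1.0 - arm.frac_age_ge65 * pi_t
    m = 1.0 - arm.no_current_meds_frac / denom
    if m < 0:
        raise ValueError(
            "impossible config: no_current_meds_frac is unattainable once planted "
            "anchor prescriptions are accounted for"
        )
    return m


def _rand_dates(rng: np.random.Generator, start: date, end: date, size: int) -> list[date]:
    span = (end - start).days + 1
    offs = rng.integers(0, span, size=size)
    return [start + timedelta(days=int(o)) for o in offs]


def _birth_date(rng: np.random.Generator, ref: date, age: int) -> date:
    m = int(rng.integers(1, 13))
    d = int(rng.integers(1, 29))
    year = ref.year - age - ((m, d) > (ref.month, ref.day))
    return date(year, m, d)


def _generate_clinic(
    clinic_id: str,
    arm_name: str,
    physicians: int,
    cfg: GeneratorConfig,
    plant_info,
    rng: np.random.Generator,
) -> tuple[ClinicDataset, dict]:
    arm = cfg.arm(arm_name)
    baseline, treatment = cfg.windows()
    ref = cfg.ref_date
    n = cfg.patients_per_clinic
    R = len(plant_info)
    med_frac = _feasible(cfg, arm, R)
    effect = cfg.treatment_effect if arm_name == "intervention" else 1.0

    pids = [f"p{int(v):012x}{i:04d}" for i, v in enumerate(rng.integers(0, 2**48, size=n))]
    elderly = rng.random(n) < arm.frac_age_ge65
    ages = np.where(elderly, rng.integers(66, 96, size=n), rng.integers(0, 65, size=n))
    true_gender = np.where(rng.random(n) < 0.5, "F", "M")

    u = rng.random(n)
    dob_missing = u < arm.missing_dob_frac
    dob_invalid = (~dob_missing) & (u < arm.missing_dob_frac + arm.invalid_dob_frac)
    gender_missing = rng.random(n) < arm.missing_gender_frac
    ghost = rng.random(n) < arm.ghost_active_frac
    medicated = (~ghost) & (rng.random(n) < med_frac)

    patients: list[PatientRecord] = []
    for i in range(n):
        if dob_missing[i]:
            raw = ""
        elif dob_invalid[i]:
            raw = (ref + timedelta(days=int(rng.integers(30, 3650)))).isoformat()
        else:
            raw = _birth_date(rng, ref, int(ages[i])).isoformat()
        patients.append(
            PatientRecord(
                patient_id=pids[i],
                clinic_id=clinic_id,
                birth_date_raw=raw,
                gender=None if gender_missing[i] else str(true_gender[i]),
                active_flag=True,
            )
        )

    encounters: list[EncounterRecord] = []
    for i in np.flatnonzero(ghost):
        d = ref - timedelta(days=int(rng.integers(760, 1460)))
        encounters.append(EncounterRecord(pids[i], d))
    lam = max(arm.encounters_per_patient_per_window - 1.0, 0.0)
    for w in (baseline, treatment):
        idx = np.flatnonzero(~ghost)
        counts = 1 + rng.poisson(lam, size=idx.size)
        for i, k in zip(idx, counts):
            for d in _rand_dates(rng, w.start_date, w.end_date, int(k)):
                encounters.append(EncounterRecord(pids[i], d))

    medications: list[MedicationRecord] = []
    problems: list[ProblemRecord] = []

    def add_med(i: int, code: str, start: date, end: Optional[date], name: str) -> bool:
        coded = bool(rng.random() < arm.coded_med_frac)
        medications.append(
            MedicationRecord(pids[i], code if coded else None, name if coded else "custom prescription", start, end)
        )
        return coded

    # background prescribing
    for i in np.flatnonzero(medicated):
        k = 1 + rng.poisson(max(arm.background_meds_mean - 1.0, 0.0))
        codes = rng.choice(len(BACKGROUND_ATC), size=k)
        for ci in codes:
            start = ref - timedelta(days=int(rng.integers(30, 1000)))
            add_med(int(i), BACKGROUND_ATC[int(ci)], start, None, f"bg-{BACKGROUND_ATC[int(ci)]}")

    # drug-diagnosis concordance pairs (probe targets dq10-12)
    med_idx = np.flatnonzero(medicated)
    for knob, (dset, dcode, pset) in CONCORDANCE_PAIRS.items():
        conc = arm.concordance.get(knob, 0.0)
        take = med_idx[rng.random(med_idx.size) < arm.concordance_drug_frac]
        for i in take:
            start = ref - timedelta(days=int(rng.integers(30, 500)))
            add_med(int(i), dcode, start, None, knob)
            if rng.random() < conc:
                pcode = {"copd_icd9": "491", "hypothyroidism_icd9": "244", "gout_icd9": "274"}[pset]
                doc = ref - timedelta(days=int(rng.integers(760, 1800)))
                problems.append(ProblemRecord(pids[int(i)], pcode, "ICD9", doc))

    # recent problem-list usage (dq8/dq9)
    eligible8 = np.flatnonzero((~ghost) & (ages >= 12))
    take8 = eligible8[rng.random(eligible8.size) < arm.problem_list_usage]
    for i in take8:
        k = 1 + int(rng.random() < 0.3)
        for _ in range(k):
            if rng.random() < arm.diabetes_share:
                code = DIABETES_CODE
            else:
                code = BACKGROUND_ICD9[int(rng.integers(0, len(BACKGROUND_ICD9)))]
            doc = ref - timedelta(days=int(rng.integers(0, 365)))
            problems.append(ProblemRecord(pids[int(i)], code, "ICD9", doc))

    # planted PIP situations per (patient, rule) pair
    truth = {
        w: {"true_possible": 0, "true_pips": 0, "obs_possible_expected": 0.0, "obs_pips_expected": 0.0}
        for w in ("baseline", "treatment")
    }
    dob_ok = ~(dob_missing | dob_invalid)
    s, p = arm.scope_prevalence, arm.pip_prevalence
    for rule_id, anchor_code, (trigger_code, trigger_sys), req_gender in plant_info:
        mask = elderly & ~ghost
        if req_gender is not None:
            mask &= true_gender == req_gender
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        has_cond = rng.random(idx.size) < p
        scope_b = rng.random(idx.size) < s
        # the alert can only avert prescriptions for pairs that would fire
        p_scope_t = np.where(has_cond, s * effect, s)
        scope_t = rng.random(idx.size) < p_scope_t
        for j, i in enumerate(idx):
            i = int(i)
            obs_factor = arm.coded_med_frac * float(dob_ok[i]) * (not gender_missing[i] if req_gender else 1.0)
            if scope_b[j]:
                start = _rand_dates(rng, baseline.start_date, baseline.end_date, 1)[0]
                add_med(i, anchor_code, start, baseline.end_date, f"anchor-{rule_id}")
                truth["baseline"]["true_possible"] += 1
                truth["baseline"]["obs_possible_expected"] += obs_factor
                if has_cond[j]:
                    truth["baseline"]["true_pips"] += 1
                    truth["baseline"]["obs_pips_expected"] += obs_factor
            if scope_t[j]:
                start = _rand_dates(rng, treatment.start_date, treatment.end_date, 1)[0]
                add_med(i, anchor_code, start, None, f"anchor-{rule_id}")
                truth["treatment"]["true_possible"] += 1
                truth["treatment"]["obs_possible_expected"] += obs_factor
                if has_cond[j]:
                    truth["treatment"]["true_pips"] += 1
                    truth["treatment"]["obs_pips_expected"] += obs_factor
            if has_cond[j] and (scope_b[j] or scope_t[j]):
                doc = ref - timedelta(days=int(rng.integers(760, 1825)))
                problems.append(ProblemRecord(pids[i], trigger_code, trigger_sys, doc))

    ds = ClinicDataset(
        clinic_id=clinic_id,
        patients=patients,
        encounters=encounters,
        medications=medications,
        problems=problems,
        arm=arm_name,
        physician_count=physicians,
    )
    return ds, truth


def generate_study(
    cfg: GeneratorConfig,
    lib: Optional[RuleLibrary] = None,
    codesets: Optional[dict[str, CodeSet]] = None,
) -> StudyDataset:
    """Generate the full two-arm study population from one seed."""
    if lib is None:
        lib = default_rule_library()
    if codesets is None:
        codesets = default_codesets()
    _check_disjoint(codesets, lib)
    plant_info = _rule_planting_info(lib, codesets)
    for arm_name in ("control", "intervention"):
        _feasible(cfg, cfg.arm(arm_name), len(plant_info))  # validate early

    baseline, treatment = cfg.windows()
    ss = np.random.SeedSequence(cfg.seed)
    n_half = cfg.n_clinics_per_arm
    clinics: list[ClinicDataset] = []
    truth: dict = {}
    children = ss.spawn(2 * n_half)
    k = 0
    for arm_name in ("control", "intervention"):
        for j in range(n_half):
            # stratified: each arm gets the same mix of small and large clinics
            small = j < (n_half + 1) // 2
            physicians = cfg.physicians_small if small else cfg.physicians_large
            clinic_id = f"{arm_name[:4]}-{j + 1:02d}"
            rng = np.random.default_rng(children[k])
            k += 1
            ds, t = _generate_clinic(clinic_id, arm_name, physicians, cfg, plant_info, rng)
            clinics.append(ds)
            truth[clinic_id] = t
    return StudyDataset(clinics=clinics, config=cfg, baseline=baseline, treatment=treatment, truth=truth)


def paperlike_config(seed: int = 0, patients_per_clinic: int = 2000, **overrides) -> GeneratorConfig:
    """A config whose knobs sit at the observed field values of a
    community-EMR STOPP deployment: heavy ghost-active fractions,
    ~80% coded prescriptions, very low problem-list usage, measured PIP
    rates of a few percent, and a null treatment effect.

    The per-arm scope prevalence is set so that an at-risk patient is
    eligible for about five rules per window — the "possible PIP"
    scale such deployments report.
    """
    base = dict(
        seed=seed,
        patients_per_clinic=patients_per_clinic,
        treatment_effect=1.0,
        control=ArmParams(
            frac_age_ge65=0.05,
            ghost_active_frac=0.714,
            coded_med_frac=0.790,
            no_current_meds_frac=0.846,
            problem_list_usage=0.035,
            diabetes_share=1.0,
            missing_gender_frac=0.005,
            concordance={
                "tiotropium_copd": 0.727,
                "levothyroxine_hypothyroidism": 0.243,
                "anti_gout_gout": 0.122,
            },
            concordance_drug_frac=0.10,
            scope_prevalence=0.155,
            pip_prevalence=0.026,
        ),
        intervention=ArmParams(
            frac_age_ge65=0.19,
            ghost_active_frac=0.643,
            coded_med_frac=0.823,
            no_current_meds_frac=0.699,
            problem_list_usage=0.123,
            diabetes_share=0.43,
            missing_gender_frac=0.003,
            concordance={
                "tiotropium_copd": 0.481,
                "levothyroxine_hypothyroidism": 0.227,
                "anti_gout_gout": 0.084,
            },
            concordance_drug_frac=0.10,
            scope_prevalence=0.156,
            pip_prevalence=0.040,
        ),
    )
    base.update(overrides)
    return GeneratorConfig(**base)


def simulate_trial_counts(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    n_rules: int = 40,
    n_gender_rules: int = 1,
) -> pd.DataFrame:
    """Count-level view of the generator: draw the per-clinic, per-window
    (fired, eligible) aggregates directly from the planting model's
    marginal distribution, without materialising patient records.

    Used for Monte-Carlo calibration of the trial analysis, where only
    the aggregates matter; a full-pipeline test verifies that these
    margins match what :func:`generate_study` + the measurement engine
    produce.
    """
    rows = []
    cid = 0
    for arm_name in ("control", "intervention"):
        arm = cfg.arm(arm_name)
        effect = cfg.treatment_effect if arm_name == "intervention" else 1.0
        sc = arm.scope_prevalence * arm.coded_med_frac * (1 - arm.missing_dob_frac - arm.invalid_dob_frac)
        for _ in range(cfg.n_clinics_per_arm):
            n_eld = rng.binomial(cfg.patients_per_clinic, arm.frac_age_ge65 * (1 - arm.ghost_active_frac))
            n_f = rng.binomial(n_eld, 0.5 * (1 - arm.missing_gender_frac))
            slots = (n_rules - n_gender_rules) * n_eld + n_gender_rules * n_f
            n_cond = rng.binomial(slots, arm.pip_prevalence)
            fired_b = rng.binomial(n_cond, sc)
            elig_b = fired_b + rng.binomial(slots - n_cond, sc)
            fired_t = rng.binomial(n_cond, sc * effect)
            elig_t = fired_t + rng.binomial(slots - n_cond, sc)
            clinic = f"sim-{cid:02d}"
            rows.append((clinic, arm_name, "baseline", fired_b, elig_b))
            rows.append((clinic, arm_name, "treatment", fired_t, elig_t))
            cid += 1
    return pd.DataFrame(rows, columns=["clinic_id", "arm", "window", "fired", "eligible"])
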