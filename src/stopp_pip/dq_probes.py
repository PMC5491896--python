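"""Data-quality probe suite over one clinic's EMR extract.

Twelve aggregate completeness/concordance statistics over demographics,
medications and the problem list — the three EMR areas a coded PIP
query depends on.  Every probe except dq1 is restricted to
*calculated-active* patients: those with at least one encounter in the
24 months before the reference date, regardless of the EMR's own
"active" flag (dq1 itself measures how far that flag has drifted from
reality).

Probe ids:

=====  ====================================================================
dq1    % of flagged-active patients with >=1 encounter in the past 24 months
dq2    % of calculated-active patients with no documented gender
dq3    % of calculated-active patients with an invalid date of birth
dq4    % of calculated-active patients with no date of birth
dq5    % of current medications that are coded
dq6    % of calculated-active patients with no current medications
dq7    % of problems documented in the past 12 months with a diagnostic code
dq8    % of calculated-active patients aged >=12 with >=1 problem documented
       in the past 12 months
dq9    % of calculated-active patients aged >=12 with diabetes on the
       problem list
dq10   % of patients currently on tiotropium with COPD on the problem list
dq11   % of patients currently on levothyroxine with hypothyroidism on the
       problem list
dq12   % of patients currently on anti-gout medication with gout on the
       problem list
=====  ====================================================================

"Invalid date of birth" (dq3) means present but unusable: unparsable,
in the future relative to the reference date, or implying an age over
120 years; dq3 and dq4 are disjoint by construction.  "Current"
medication uses the interval-overlap convention at the reference date.
The id dq13 is reserved and unimplemented.

The reference date is always an explicit parameter (the study-end
date), never "today", so probe output is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Callable, Mapping, Optional

from .emr_model import (
    ClinicDataset,
    PatientRecord,
    age_at,
    med_current,
    past_months,
)
from .terminology import CodeSet, default_codesets, matches

__all__ = ["ProbeResult", "PROBE_IDS", "calculated_active", "run_probe", "run_all_probes"]

PROBE_IDS = tuple(f"dq{i}" for i in range(1, 13))


@dataclass(frozen=True)
class ProbeResult:
    probe_id: str
    clinic_id: str
    numerator: int
    denominator: int

    def __post_init__(self) -> None:
        if not (0 <= self.numerator <= self.denominator):
            raise ValueError(f"{self.probe_id}: numerator outside [0, denominator]")

    @property
    def percentage(self) -> Optional[float]:
        if self.denominator == 0:
            return None
        return 100.0 * self.numerator / self.denominator

    def to_obj(self) -> dict:
        return {
            "probe_id": self.probe_id,
            "clinic_id": self.clinic_id,
            "numerator": self.numerator,
            "denominator": self.denominator,
            "percentage": self.percentage,
        }


def calculated_active(ds: ClinicDataset, ref_date: date) -> set[str]:
    """Patients with >=1 encounter in the closed 24-month lookback."""
    start = past_months(ref_date, 24)
    return {
        e.patient_id for e in ds.encounters if start <= e.encounter_date <= ref_date
    }


def _ratio(ds: ClinicDataset, probe_id: str, num: int, den: int) -> ProbeResult:
    return ProbeResult(probe_id=probe_id, clinic_id=ds.clinic_id, numerator=num, denominator=den)


def _active_patients(ds: ClinicDataset, ref_date: date) -> list[PatientRecord]:
    act = calculated_active(ds, ref_date)
    return [p for p in ds.patients if p.patient_id in act]


def _dq1(ds: ClinicDataset, ref_date: date, cs) -> ProbeResult:
    flagged = [p for p in ds.patients if p.active_flag]
    act = calculated_active(ds, ref_date)
    return _ratio(ds, "dq1", sum(p.patient_id in act for p in flagged), len(flagged))


def _dq2(ds, ref_date, cs):
    pats = _active_patients(ds, ref_date)
    return _ratio(ds, "dq2", sum(p.gender is None for p in pats), len(pats))


def _dq3(ds, ref_date, cs):
    pats = _active_patients(ds, ref_date)
    return _ratio(ds, "dq3", sum(p.dob_invalid(ref_date) for p in pats), len(pats))


def _dq4(ds, ref_date, cs):
    pats = _active_patients(ds, ref_date)
    return _ratio(ds, "dq4", sum(not p.has_dob() for p in pats), len(pats))


def _current_meds(ds: ClinicDataset, ref_date: date):
    act = calculated_active(ds, ref_date)
    return [m for m in ds.medications if m.patient_id in act and med_current(m, ref_date)]


def _dq5(ds, ref_date, cs):
    meds = _current_meds(ds, ref_date)
    return _ratio(ds, "dq5", sum(m.coded for m in meds), len(meds))


def _dq6(ds, ref_date, cs):
    pats = _active_patients(ds, ref_date)
    with_meds = {m.patient_id for m in _current_meds(ds, ref_date)}
    return _ratio(ds, "dq6", sum(p.patient_id not in with_meds for p in pats), len(pats))


def _recent_problems(ds: ClinicDataset, ref_date: date):
    act = calculated_active(ds, ref_date)
    start = past_months(ref_date, 12)
    return [
        p
        for p in ds.problems
        if p.patient_id in act and start <= p.documented_date <= ref_date
    ]


def _dq7(ds, ref_date, cs):
    probs = _recent_problems(ds, ref_date)
    # problem_code is mandatory in this EMR model, so this is 100% whenever
    # the denominator is non-empty; the probe still runs the count honestly.
    return _ratio(ds, "dq7", sum(bool(p.problem_code.strip()) for p in probs), len(probs))


def _aged_12_plus(ds, ref_date):
    return [
        p
        for p in _active_patients(ds, ref_date)
        if (a := age_at(p, ref_date)) is not None and a >= 12
    ]


def _dq8(ds, ref_date, cs):
    pats = _aged_12_plus(ds, ref_date)
    recent = {p.patient_id for p in _recent_problems(ds, ref_date)}
    return _ratio(ds, "dq8", sum(p.patient_id in recent for p in pats), len(pats))


def _has_problem_in(ds, pids: set[str], sets: list[CodeSet]) -> set[str]:
    out = set()
    for p in ds.problems:
        if p.patient_id in pids:
            for cs in sets:
                if cs.system == p.code_system and matches(p.problem_code, cs):
                    out.add(p.patient_id)
                    break
    return out


def _dq9(ds, ref_date, cs):
    pats = _aged_12_plus(ds, ref_date)
    pids = {p.patient_id for p in pats}
    sets = [cs["diabetes_icd9"], cs["diabetes_icd10"]]
    have = _has_problem_in(ds, pids, sets)
    return _ratio(ds, "dq9", sum(pid in have for pid in pids), len(pids))


def _concordance(ds, ref_date, cs, probe_id, drug_set: str, disease_sets: list[str]):
    act = calculated_active(ds, ref_date)
    drug = cs[drug_set]
    on_drug = {
        m.patient_id
        for m in ds.medications
        if m.patient_id in act and med_current(m, ref_date) and matches(m.drug_code, drug)
    }
    have = _has_problem_in(ds, on_drug, [cs[s] for s in disease_sets])
    return _ratio(ds, probe_id, len(have & on_drug), len(on_drug))


def _dq10(ds, ref_date, cs):
    return _concordance(ds, ref_date, cs, "dq10", "tiotropium", ["copd_icd9", "copd_icd10"])


def _dq11(ds, ref_date, cs):
    return _concordance(
        ds, ref_date, cs, "dq11", "levothyroxine", ["hypothyroidism_icd9", "hypothyroidism_icd10"]
    )


def _dq12(ds, ref_date, cs):
    return _concordance(ds, ref_date, cs, "dq12", "anti_gout", ["gout_icd9", "gout_icd10"])


_PROBES: dict[str, Callable] = {
    "dq1": _dq1, "dq2": _dq2, "dq3": _dq3, "dq4": _dq4, "dq5": _dq5, "dq6": _dq6,
    "dq7": _dq7, "dq8": _dq8, "dq9": _dq9, "dq10": _dq10, "dq11": _dq11, "dq12": _dq12,
}


def run_probe(
    probe_id: str,
    ds: ClinicDataset,
    ref_date: date,
    codesets: Optional[Mapping[str, CodeSet]] = None,
) -> ProbeResult:
    if probe_id not in _PROBES:
        raise KeyError(f"unknown probe {probe_id!r}; valid ids: {', '.join(PROBE_IDS)}")
    if codesets is None:
        codesets = default_codesets()
    return _PROBES[probe_id](ds, ref_date, codesets)


def run_all_probes(
    ds: ClinicDataset,
    ref_date: date,
    codesets: Optional[Mapping[str, CodeSet]] = None,
) -> list[ProbeResult]:
    if codesets is None:
        codesets = default_codesets()
    return [run_probe(pid, ds, ref_date, codesets) for pid in PROBE_IDS]


def format_report(results: list[ProbeResult]) -> str:
    """Per-clinic markdown summary of the probe suite."""
    lines = [
        f"# Data-quality summary — clinic {results[0].clinic_id}" if results else "# Data-quality summary",
        "",
        "| probe | numerator | denominator | % |",
        "|-------|-----------|-------------|---|",
    ]
    for r in results:
        pct = "—" if r.percentage is None else f"{r.percentage:.1f}"
        lines.append(f"| {r.probe_id} | {r.numerator} | {r.denominator} | {pct} |")
    return "\n".join(lines)
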