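"""Distributed-query contract: clinics compute locally, only aggregates travel.

Modelled on hQuery-style research networks: each clinic runs the PIP
measurement and the data-quality probes against its own EMR extract and
returns only :class:`AggregateAnswer` records — a numerator and a
denominator per measure and window.  The answer type has *no slots* for
patient identifiers, dates of birth, or any record-level field, so the
privacy contract is enforced by construction rather than by filtering.

Answers travel as flat JSON files (one per clinic); the hub groups and
sums them.  Arm-level totals are exact sums of clinic-level answers
(conservation).  Optional small-cell suppression (masking numerators
1–4) is available but off by default: the upstream network design did
not suppress, and the flag exists for deployments that must.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .dq_probes import run_all_probes
from .emr_model import ClinicDataset
from .measure import MeasurementWindow, measure_pips
from .rules import CodeMatcher, RuleLibrary
from .terminology import CodeSet

__all__ = [
    "AggregateAnswer",
    "HubCollection",
    "clinic_respond",
    "answers_to_json",
    "write_answers",
    "hub_collect",
]


@dataclass(frozen=True)
class AggregateAnswer:
    clinic_id: str
    measure_id: str  # "rule:<rule_id>" | "probe:<probe_id>" | "total"
    window: str  # "baseline" | "treatment" | "at-ref"
    numerator: int
    denominator: int

    def __post_init__(self) -> None:
        if self.numerator < 0 or self.denominator < 0:
            raise ValueError("aggregate counts must be non-negative")

    def masked(self, threshold: int = 5) -> "AggregateAnswer":
        """Small-cell suppression: numerators in [1, threshold) become 0
        and are marked by a negative sentinel-free convention (the count
        is simply suppressed to 0); denominators are left intact."""
        if 0 < self.numerator < threshold:
            return AggregateAnswer(self.clinic_id, self.measure_id, self.window, 0, self.denominator)
        return self


def clinic_respond(
    ds: ClinicDataset,
    lib: RuleLibrary,
    windows: Sequence[MeasurementWindow],
    ref_date: date,
    codesets: Mapping[str, CodeSet],
    suppress_small_cells: bool = False,
    matcher: Optional[CodeMatcher] = None,
) -> list[AggregateAnswer]:
    """Run measurement and probes locally; emit aggregate answers only."""
    answers: list[AggregateAnswer] = []
    for w in windows:
        counts = measure_pips(ds, lib, w, codesets, matcher=matcher)
        for rc in counts.per_rule:
            answers.append(
                AggregateAnswer(ds.clinic_id, f"rule:{rc.rule_id}", w.label, rc.fired, rc.eligible)
            )
        answers.append(
            AggregateAnswer(ds.clinic_id, "total", w.label, counts.numerator, counts.denominator)
        )
    for pr in run_all_probes(ds, ref_date, codesets):
        answers.append(
            AggregateAnswer(ds.clinic_id, f"probe:{pr.probe_id}", "at-ref", pr.numerator, pr.denominator)
        )
    if suppress_small_cells:
        answers = [a.masked() for a in answers]
    return answers


def answers_to_json(answers: Iterable[AggregateAnswer]) -> str:
    return json.dumps(
        [
            {
                "clinic_id": a.clinic_id,
                "measure_id": a.measure_id,
                "window": a.window,
                "numerator": a.numerator,
                "denominator": a.denominator,
            }
            for a in answers
        ],
        indent=1,
    )


def write_answers(answers: Iterable[AggregateAnswer], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(answers_to_json(answers))


def _read_answers(path: str | Path) -> list[AggregateAnswer]:
    raw = json.loads(Path(path).read_text())
    return [
        AggregateAnswer(
            clinic_id=o["clinic_id"],
            measure_id=o["measure_id"],
            window=o["window"],
            numerator=int(o["numerator"]),
            denominator=int(o["denominator"]),
        )
        for o in raw
    ]


@dataclass
class HubCollection:
    study_id: str
    arms: dict[str, str]  # clinic_id -> "control" | "intervention"
    answers: list[AggregateAnswer] = field(default_factory=list)
    rule_library_version: str = "unversioned"

    def clinic_total(self, clinic_id: str, window: str) -> tuple[int, int]:
        for a in self.answers:
            if a.clinic_id == clinic_id and a.measure_id == "total" and a.window == window:
                return a.numerator, a.denominator
        raise KeyError(f"no 'total' answer for clinic {clinic_id!r}, window {window!r}")

    def arm_total(self, arm: str, window: str, measure_id: str = "total") -> tuple[int, int]:
        """Exact sum of clinic answers for one arm and window."""
        num = den = 0
        found = False
        for a in self.answers:
            if (
                self.arms.get(a.clinic_id) == arm
                and a.measure_id == measure_id
                and a.window == window
            ):
                num += a.numerator
                den += a.denominator
                found = True
        if not found:
            raise KeyError(f"no answers for arm {arm!r}, window {window!r}, {measure_id!r}")
        return num, den

    def clinics(self, arm: Optional[str] = None) -> list[str]:
        ids = sorted({a.clinic_id for a in self.answers})
        if arm is None:
            return ids
        return [c for c in ids if self.arms.get(c) == arm]


def hub_collect(
    answer_files: Sequence[str | Path] | Mapping[str, Sequence[AggregateAnswer]],
    arms: Mapping[str, str],
    study_id: str = "study",
    rule_library_version: str = "unversioned",
) -> HubCollection:
    """Collect per-clinic answer files into one hub view.

    Duplicate (clinic, measure, window) triples are an error: a clinic
    cannot answer the same query twice.
    """
    answers: list[AggregateAnswer] = []
    if isinstance(answer_files, Mapping):
        for _, batch in sorted(answer_files.items()):
            answers.extend(batch)
    else:
        for path in answer_files:
            answers.extend(_read_answers(path))
    seen: set[tuple[str, str, str]] = set()
    for a in answers:
        key = (a.clinic_id, a.measure_id, a.window)
        if key in seen:
            raise ValueError(f"duplicate answer for {key}")
        seen.add(key)
    return HubCollection(
        study_id=study_id,
        arms=dict(arms),
        answers=answers,
        rule_library_version=rule_library_version,
    )
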