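"""Windowed PIP measurement: possible PIPs, fired PIPs, rates.

The unit of counting is the (patient, rule) pair within one window:

* a pair is **possible** (eligible) when the rule's *scope* predicate
  holds for that patient's coded records in the window — the patient
  presents the opportunity for this criterion (right age plus the
  anchor drug/disease condition), not merely "aged 65+";
* a pair is a **PIP** (fired) when the full *fire* predicate holds.

A pair contributes at most 1 to each count per window no matter how
many encounters or prescriptions are involved, and only patients with
at least one encounter in the window are evaluated.  The overall PIP
rate is 100 x (sum of fired) / (sum of eligible); with an empty
denominator the rate is *missing*, not zero.

This semantics makes the denominator a few eligible rules per at-risk
patient rather than the full rule count, which is the scale a per-rule
opportunity definition naturally produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping, Optional

from .emr_model import ClinicDataset
from .rules import CodeMatcher, RuleLibrary, build_contexts, evaluate_predicate
from .terminology import CodeSet

__all__ = ["MeasurementWindow", "RuleCount", "PipCounts", "measure_pips", "pip_rate"]

#: Both the baseline and the intervention observation periods span 16 weeks.
DEFAULT_WINDOW_DAYS = 112


@dataclass(frozen=True)
class MeasurementWindow:
    start_date: date
    end_date: date  # inclusive
    label: str = "baseline"  # "baseline" | "treatment"

    def __post_init__(self) -> None:
        if self.end_date < self.start_date:
            raise ValueError("window end before start")

    @classmethod
    def from_start(cls, start: date, label: str, days: int = DEFAULT_WINDOW_DAYS) -> "MeasurementWindow":
        return cls(start, start + timedelta(days=days - 1), label)


@dataclass(frozen=True)
class RuleCount:
    rule_id: str
    eligible: int
    fired: int

    def __post_init__(self) -> None:
        if not (0 <= self.fired <= self.eligible):
            raise ValueError(f"{self.rule_id}: fired must lie in [0, eligible]")


@dataclass
class PipCounts:
    clinic_id: str
    window: str
    per_rule: list[RuleCount] = field(default_factory=list)
    patients_seen: int = 0  # distinct patients with >=1 encounter in window
    patients_at_risk: int = 0  # of those, in scope of >=1 rule

    @property
    def denominator(self) -> int:
        return sum(r.eligible for r in self.per_rule)

    @property
    def numerator(self) -> int:
        return sum(r.fired for r in self.per_rule)

    def to_obj(self) -> dict:
        return {
            "clinic_id": self.clinic_id,
            "window": self.window,
            "per_rule": [
                {"rule_id": r.rule_id, "eligible": r.eligible, "fired": r.fired}
                for r in self.per_rule
            ],
            "totals": {"denominator": self.denominator, "numerator": self.numerator},
            "patients_seen": self.patients_seen,
            "patients_at_risk": self.patients_at_risk,
        }


def measure_pips(
    ds: ClinicDataset,
    lib: RuleLibrary,
    window: MeasurementWindow,
    codesets: Mapping[str, CodeSet],
    matcher: Optional[CodeMatcher] = None,
) -> PipCounts:
    """Count eligible and fired (patient, rule) pairs in one window."""
    contexts = build_contexts(ds, codesets, window.start_date, window.end_date, matcher=matcher)
    at_risk = 0
    rules = lib.enabled_rules
    eligible = {r.rule_id: 0 for r in rules}
    fired = {r.rule_id: 0 for r in rules}
    for ctx in contexts.values():
        in_any = False
        for rule in rules:
            if evaluate_predicate(rule.scope, ctx):
                in_any = True
                eligible[rule.rule_id] += 1
                if evaluate_predicate(rule.fire, ctx):
                    fired[rule.rule_id] += 1
        if in_any:
            at_risk += 1
    return PipCounts(
        clinic_id=ds.clinic_id,
        window=window.label,
        per_rule=[RuleCount(r.rule_id, eligible[r.rule_id], fired[r.rule_id]) for r in rules],
        patients_seen=len(contexts),
        patients_at_risk=at_risk,
    )


def pip_rate(numerator: int | PipCounts, denominator: Optional[int] = None) -> Optional[float]:
    """PIP rate in percent, at full precision; ``None`` when the
    denominator is zero (a rate over nothing is missing, not 0%)."""
    if isinstance(numerator, PipCounts):
        num, den = numerator.numerator, numerator.denominator
    else:
        num, den = numerator, int(denominator)  # type: ignore[arg-type]
    if den == 0:
        return None
    return 100.0 * num / den
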