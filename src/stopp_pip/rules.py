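"""Declarative STOPP rule DSL and the shipped 40-rule library.

A rule is two predicates over one patient's coded records in a time
window:

* ``scope`` — the *opportunity* condition (the patient could trigger
  this criterion at all, e.g. "aged >= 65 and on a benzodiazepine");
* ``fire`` — the full potentially-inappropriate-prescription condition,
  which must be expressed as ``ALL_OF(scope, extra)`` so that firing
  always implies being in scope.  This containment is checked
  structurally at load time.

The predicate language is deliberately restricted: age comparisons,
drug-class membership (ATC prefix sets), problem-list membership (ICD
prefix sets), gender, and boolean combinators.  There is *no* dose
threshold and *no* prescription-duration predicate — criteria that need
them are unrepresentable by construction, mirroring what a simple EMR
CDS engine and a coded aggregate query can actually evaluate.

Missing data always evaluates an atom to ``false``, never to an error:
an uncoded (free-text) prescription cannot satisfy ``ON_MED``, an
absent date of birth cannot satisfy an age test.  Undocumented data
therefore silently suppresses alerts — the central data-quality
mechanism this package exists to expose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import yaml

from .emr_model import ClinicDataset, age_at, med_active_in
from .terminology import CodeSet, default_codesets, matches

__all__ = [
    "AgeGe",
    "AgeLt",
    "OnMed",
    "HasProblem",
    "GenderIs",
    "AllOf",
    "AnyOf",
    "Not",
    "Predicate",
    "StoppRule",
    "RuleLibrary",
    "RuleError",
    "PatientContext",
    "CodeMatcher",
    "parse_predicate",
    "predicate_to_obj",
    "referenced_codesets",
    "evaluate_predicate",
    "build_contexts",
    "load_rule_library",
    "default_rule_library",
]


class RuleError(ValueError):
    pass


@dataclass(frozen=True)
class AgeGe:
    years: int


@dataclass(frozen=True)
class AgeLt:
    years: int


@dataclass(frozen=True)
class OnMed:
    codeset: str


@dataclass(frozen=True)
class HasProblem:
    codeset: str


@dataclass(frozen=True)
class GenderIs:
    value: str


@dataclass(frozen=True)
class AllOf:
    items: tuple["Predicate", ...]


@dataclass(frozen=True)
class AnyOf:
    items: tuple["Predicate", ...]


@dataclass(frozen=True)
class Not:
    item: "Predicate"


Predicate = Union[AgeGe, AgeLt, OnMed, HasProblem, GenderIs, AllOf, AnyOf, Not]

_TAGS = {"age_ge", "age_lt", "on_med", "has_problem", "gender_is", "all_of", "any_of", "not"}


def parse_predicate(obj) -> Predicate:
    """Parse a nested tagged mapping into a predicate tree.

    Unknown tags are rejected loudly; in particular there is nothing to
    parse a dose or duration condition into.
    """
    if not isinstance(obj, Mapping) or len(obj) != 1:
        raise RuleError(f"predicate must be a single-key mapping, got {obj!r}")
    (tag, payload), = obj.items()
    if tag not in _TAGS:
        raise RuleError(f"unknown predicate tag {tag!r} (dose/duration logic is unsupported)")
    if tag == "age_ge":
        return AgeGe(int(payload))
    if tag == "age_lt":
        return AgeLt(int(payload))
    if tag == "on_med":
        return OnMed(str(payload))
    if tag == "has_problem":
        return HasProblem(str(payload))
    if tag == "gender_is":
        return GenderIs(str(payload))
    if tag == "not":
        return Not(parse_predicate(payload))
    items = tuple(parse_predicate(x) for x in payload)
    if not items:
        raise RuleError(f"{tag}: empty combinator")
    return AllOf(items) if tag == "all_of" else AnyOf(items)


def predicate_to_obj(p: Predicate):
    if isinstance(p, AgeGe):
        return {"age_ge": p.years}
    if isinstance(p, AgeLt):
        return {"age_lt": p.years}
    if isinstance(p, OnMed):
        return {"on_med": p.codeset}
    if isinstance(p, HasProblem):
        return {"has_problem": p.codeset}
    if isinstance(p, GenderIs):
        return {"gender_is": p.value}
    if isinstance(p, Not):
        return {"not": predicate_to_obj(p.item)}
    tag = "all_of" if isinstance(p, AllOf) else "any_of"
    return {tag: [predicate_to_obj(x) for x in p.items]}


def referenced_codesets(p: Predicate) -> set[str]:
    if isinstance(p, (OnMed, HasProblem)):
        return {p.codeset}
    if isinstance(p, (AllOf, AnyOf)):
        out: set[str] = set()
        for x in p.items:
            out |= referenced_codesets(x)
        return out
    if isinstance(p, Not):
        return referenced_codesets(p.item)
    return set()


@dataclass(frozen=True)
class StoppRule:
    rule_id: str
    title: str
    scope: Predicate
    fire: Predicate
    enabled: bool = True

    def __post_init__(self) -> None:
        if not (isinstance(self.fire, AllOf) and any(c == self.scope for c in self.fire.items)):
            raise RuleError(
                f"{self.rule_id}: fire must be ALL_OF(scope, ...) containing the scope "
                "predicate verbatim"
            )


@dataclass(frozen=True)
class RuleLibrary:
    rules: tuple[StoppRule, ...]
    version: str = "unversioned"

    def __post_init__(self) -> None:
        ids = [r.rule_id for r in self.rules]
        if len(ids) != len(set(ids)):
            raise RuleError("duplicate rule_id in library")

    @property
    def enabled_rules(self) -> tuple[StoppRule, ...]:
        return tuple(r for r in self.rules if r.enabled)


def load_rule_library(
    path: str | Path, codesets: Optional[Mapping[str, CodeSet]] = None
) -> RuleLibrary:
    """Load a YAML rule file and validate it against the code sets.

    The same file drives both the per-patient engine and the aggregate
    measurement queries, so a library that loads here is the single
    source of truth for both.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if codesets is None:
        codesets = default_codesets()
    if not isinstance(raw, Mapping) or "rules" not in raw:
        raise RuleError("rule file must be a mapping with a 'rules' list")
    rules = []
    for entry in raw["rules"]:
        rule = StoppRule(
            rule_id=str(entry["rule_id"]),
            title=str(entry.get("title", entry["rule_id"])),
            scope=parse_predicate(entry["scope"]),
            fire=parse_predicate(entry["fire"]),
            enabled=bool(entry.get("enabled", True)),
        )
        refs = referenced_codesets(rule.scope) | referenced_codesets(rule.fire)
        unknown = sorted(refs - set(codesets))
        if unknown:
            raise RuleError(f"{rule.rule_id}: unknown codeset(s) {unknown}")
        rules.append(rule)
    return RuleLibrary(rules=tuple(rules), version=str(raw.get("version", "unversioned")))


def default_rule_library() -> RuleLibrary:
    """The shipped 40-rule default library (``stopp40.yaml``)."""
    ref = resources.files("stopp_pip").joinpath("data/stopp40.yaml")
    with resources.as_file(ref) as p:
        return load_rule_library(p)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


class CodeMatcher:
    """Caches which code sets each (system, code) pair belongs to.

    Codes repeat heavily across patients, so memoising the prefix scan
    makes per-patient context construction cheap without changing the
    semantics of :func:`stopp_pip.terminology.matches`.
    """

    def __init__(self, codesets: Mapping[str, CodeSet]):
        self._by_system: dict[str, list[CodeSet]] = {}
        for cs in codesets.values():
            self._by_system.setdefault(cs.system, []).append(cs)
        self._cache: dict[tuple[str, str], frozenset[str]] = {}

    def match(self, system: str, code: Optional[str]) -> frozenset[str]:
        if code is None:
            return frozenset()
        key = (system, code)
        hit = self._cache.get(key)
        if hit is None:
            hit = frozenset(
                cs.name for cs in self._by_system.get(system, []) if matches(code, cs)
            )
            self._cache[key] = hit
        return hit


@dataclass(frozen=True)
class PatientContext:
    """One patient's coded state restricted to an evaluation window."""

    patient_id: str
    age: Optional[int]  # at window end; None when DOB missing/invalid
    gender: Optional[str]
    med_codesets: frozenset[str]  # sets matched by coded meds active in window
    problem_codesets: frozenset[str]  # sets matched by problems documented up to window end


def evaluate_predicate(pred: Predicate, ctx: PatientContext) -> bool:
    """Pure boolean evaluation; atoms over absent data are ``false``."""
    if isinstance(pred, AgeGe):
        return ctx.age is not None and ctx.age >= pred.years
    if isinstance(pred, AgeLt):
        return ctx.age is not None and ctx.age < pred.years
    if isinstance(pred, OnMed):
        return pred.codeset in ctx.med_codesets
    if isinstance(pred, HasProblem):
        return pred.codeset in ctx.problem_codesets
    if isinstance(pred, GenderIs):
        return ctx.gender is not None and ctx.gender == pred.value
    if isinstance(pred, AllOf):
        return all(evaluate_predicate(x, ctx) for x in pred.items)
    if isinstance(pred, AnyOf):
        return any(evaluate_predicate(x, ctx) for x in pred.items)
    if isinstance(pred, Not):
        return not evaluate_predicate(pred.item, ctx)
    raise TypeError(f"not a predicate: {pred!r}")


def build_contexts(
    ds: ClinicDataset,
    codesets: Mapping[str, CodeSet],
    window_start: date,
    window_end: date,
    matcher: Optional[CodeMatcher] = None,
    restrict_to_seen: bool = True,
) -> dict[str, PatientContext]:
    """Build evaluation contexts for patients in a window.

    By default only patients with at least one encounter inside the
    closed window are included (nobody was seen, nobody could have
    triggered an alert).  Medications count when their prescription
    interval overlaps the window and they carry a code; problems count
    cumulatively, i.e. any entry documented on or before window end —
    problem lists are status registers, not events.
    """
    if matcher is None:
        matcher = CodeMatcher(codesets)
    seen: set[str] = set()
    for e in ds.encounters:
        if window_start <= e.encounter_date <= window_end:
            seen.add(e.patient_id)

    meds: dict[str, set[str]] = {}
    for m in ds.medications:
        if m.coded and med_active_in(m, window_start, window_end):
            names = matcher.match("ATC", m.drug_code)
            if names:
                meds.setdefault(m.patient_id, set()).update(names)
    probs: dict[str, set[str]] = {}
    for p in ds.problems:
        if p.documented_date <= window_end:
            names = matcher.match(p.code_system, p.problem_code)
            if names:
                probs.setdefault(p.patient_id, set()).update(names)

    out: dict[str, PatientContext] = {}
    for patient in ds.patients:
        pid = patient.patient_id
        if restrict_to_seen and pid not in seen:
            continue
        out[pid] = PatientContext(
            patient_id=pid,
            age=age_at(patient, window_end),
            gender=patient.gender,
            med_codesets=frozenset(meds.get(pid, ())),
            problem_codesets=frozenset(probs.get(pid, ())),
        )
    return out
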