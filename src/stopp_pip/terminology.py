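"""Code sets and prefix matching for ATC drug classes and ICD diagnosis groups.

STOPP criteria are published as clinical prose, not as terminology-bound
definitions, so every computable deployment has to pick concrete code
lists.  Here a :class:`CodeSet` is a named set of code *prefixes* within
one coding system; a code belongs to the set iff it starts with any of
the prefixes (case-insensitive, surrounding whitespace ignored).  ICD-9
prefixes are matched against the literal stored string, dot included —
a dotted prefix like ``"427.31"`` only matches dotted codes.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional

import yaml

__all__ = ["CodeSet", "CodeSetError", "matches", "load_codesets", "default_codesets"]

SYSTEMS = ("ATC", "ICD9", "ICD10")


class CodeSetError(ValueError):
    pass


@dataclass(frozen=True)
class CodeSet:
    name: str
    system: str  # "ATC" | "ICD9" | "ICD10"
    prefixes: frozenset[str]

    def __post_init__(self) -> None:
        if self.system not in SYSTEMS:
            raise CodeSetError(f"{self.name}: unknown system {self.system!r}")
        if not self.prefixes:
            raise CodeSetError(f"{self.name}: empty prefix set")
        norm = frozenset(p.strip().upper() for p in self.prefixes)
        object.__setattr__(self, "prefixes", norm)
        ps = sorted(norm)
        for i, a in enumerate(ps):
            for b in ps[i + 1 :]:
                if b.startswith(a):
                    raise CodeSetError(
                        f"{self.name}: prefix {a!r} shadows {b!r} (redundant)"
                    )


def matches(code: Optional[str], cs: CodeSet) -> bool:
    """True iff ``code`` starts with any prefix of ``cs``.

    A missing code (``None`` or blank) is *false by contract*: an
    uncoded record can never satisfy a coded criterion.  This never
    raises — it is the mechanism by which poor coding silently
    suppresses rule firing.
    """
    if code is None:
        return False
    c = str(code).strip().upper()
    if not c:
        return False
    return any(c.startswith(p) for p in cs.prefixes)


def load_codesets(path: str | Path) -> dict[str, CodeSet]:
    """Load a YAML/JSON mapping ``name -> {system, prefixes}``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return parse_codesets(raw)


def parse_codesets(raw: Mapping) -> dict[str, CodeSet]:
    if not isinstance(raw, Mapping):
        raise CodeSetError("codeset file must be a mapping of name -> {system, prefixes}")
    out: dict[str, CodeSet] = {}
    for name, spec in raw.items():
        if name in out:
            raise CodeSetError(f"duplicate codeset name {name!r}")
        try:
            cs = CodeSet(name=name, system=spec["system"], prefixes=frozenset(spec["prefixes"]))
        except (KeyError, TypeError) as exc:
            raise CodeSetError(f"{name}: malformed entry ({exc})") from exc
        out[name] = cs
    return out


def default_codesets() -> dict[str, CodeSet]:
    """The bundled code-set fixture used by the shipped rule library and
    the drug–diagnosis concordance probes."""
    ref = resources.files("stopp_pip").joinpath("data/codesets.yaml")
    with resources.as_file(ref) as p:
        return load_codesets(p)
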