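#!/usr/bin/env python
"""Measure PIPs at each clinic and collect aggregate answers at the hub.

Reads the CSV extracts written by 01_simulate_study.py, runs the
40-rule measurement and the 12 data-quality probes *locally per
clinic*, and serializes only numerator/denominator aggregates — the
distributed-query privacy contract.  Writes one answers file per clinic
and the combined hub file under results/.
"""

import json
from datetime import date
from pathlib import Path

from stopp_pip.aggregation import clinic_respond, hub_collect, write_answers
from stopp_pip.emr_model import read_clinic_dataset, table_paths
from stopp_pip.measure import MeasurementWindow
from stopp_pip.rules import default_rule_library
from stopp_pip.terminology import default_codesets

ROOT = Path(__file__).resolve().parent.parent / "results"
STUDY = ROOT / "studydir"


def main() -> None:
    meta = json.loads((STUDY / "truth.json").read_text())
    arms = {c["clinic_id"]: c["arm"] for c in meta["clinics"]}
    wb = MeasurementWindow(*map(date.fromisoformat, meta["windows"]["baseline"]), "baseline")
    wt = MeasurementWindow(*map(date.fromisoformat, meta["windows"]["treatment"]), "treatment")
    ref = date.fromisoformat(meta["ref_date"])

    lib = default_rule_library()
    cs = default_codesets()
    paths = []
    for clinic in meta["clinics"]:
        cid = clinic["clinic_id"]
        ds, issues = read_clinic_dataset(table_paths(STUDY / cid), cid, arm=clinic["arm"])
        assert not issues, f"{cid}: generated data should load cleanly"
        answers = clinic_respond(ds, lib, [wb, wt], ref, cs)
        p = ROOT / "answers" / f"{cid}.json"
        write_answers(answers, p)
        paths.append(p)
        tot = next(a for a in answers if a.measure_id == "total" and a.window == "baseline")
        print(f"{cid} ({clinic['arm']}): baseline PIPs {tot.numerator}/{tot.denominator}")

    hub = hub_collect(paths, arms, rule_library_version=lib.version)
    out = ROOT / "hub.json"
    out.write_text(
        json.dumps(
            {
                "study_id": hub.study_id,
                "arms": hub.arms,
                "rule_library_version": hub.rule_library_version,
                "answers": [a.__dict__ for a in hub.answers],
            },
            indent=1,
        )
    )
    print(f"hub collected {len(hub.answers)} aggregate answers -> {out}")


if __name__ == "__main__":
    main()
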