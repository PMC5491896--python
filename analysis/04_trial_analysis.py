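#!/usr/bin/env python
"""Trial analysis on the hub aggregates: rates, DiD, and the GEE test.

Reads results/hub.json, reports per-arm PIP rates in both windows,
within-arm changes, the difference-in-differences, and the
cluster-robust (bias-corrected) GEE interaction test.  The study was
generated under a null treatment effect, so the expected finding is
"no significant change" — the interest is in the machinery, not the
verdict.  Writes results/trial_result.json.
"""

import json
from pathlib import Path

from stopp_pip.aggregation import AggregateAnswer, HubCollection
from stopp_pip.trial import counts_frame, gee_test, summarize

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    raw = json.loads((ROOT / "hub.json").read_text())
    hub = HubCollection(
        study_id=raw["study_id"],
        arms=raw["arms"],
        answers=[AggregateAnswer(**a) for a in raw["answers"]],
    )
    result = summarize(hub)
    result.gee = gee_test(counts_frame(hub))
    out = ROOT / "trial_result.json"
    out.write_text(json.dumps(result.to_obj(), indent=1))

    for arm in ("control", "intervention"):
        b, t = result.counts[arm]["baseline"], result.counts[arm]["treatment"]
        print(
            f"{arm}: baseline {b[0]}/{b[1]} = {result.rates[arm]['baseline']}%  "
            f"treatment {t[0]}/{t[1]} = {result.rates[arm]['treatment']}%  "
            f"change {result.change[arm]:+.1f}pp"
        )
    print(f"difference-in-differences: {result.difference_in_differences:+.1f}pp")
    g = result.gee
    print(
        f"GEE interaction: {g.estimate:+.3f} log-odds (bias-corrected SE {g.robust_se:.3f}), "
        f"t({g.df}) = {g.statistic:+.2f}, p = {g.p_value:.2f}"
    )
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
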