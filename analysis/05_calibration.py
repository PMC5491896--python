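#!/usr/bin/env python
"""Calibration of the trial statistics by Monte Carlo.

Three checks, all against the count-level view of the generator:

1. type-I error of the GEE interaction test over null replicates at the
   field-observed rates (8 clinics) — should sit near 5%;
2. power against a 20% relative reduction, compared with the analytic
   interaction approximation in a symmetric design;
3. the two-proportion sample-size formula validated by simulating the
   design it models at its own returned n (20% rate, 20% relative
   reduction, alpha .05, power .80).

Writes results/calibration.json.  Replicate counts are kept modest so
the whole script runs in about a minute; the test suite runs the same
checks at higher replication.
"""

import json
import time
from pathlib import Path

import numpy as np

from stopp_pip.synth import paperlike_config, simulate_trial_counts
from stopp_pip.trial import (
    PowerSpec,
    did_interaction_power,
    gee_test,
    sample_size,
    two_proportion_power,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    t0 = time.time()
    out: dict = {}

    cfg = paperlike_config(seed=0)
    rng = np.random.default_rng(42)
    R = 300
    rej = sum(gee_test(simulate_trial_counts(cfg, rng)).p_value < 0.05 for _ in range(R))
    out["null_type_i"] = {"rate": rej / R, "replicates": R}
    print(f"null type-I error: {rej / R:.3f} (target 0.05, {R} replicates)")

    sym = cfg.model_copy(update={"control": cfg.intervention, "treatment_effect": 0.8})
    rng = np.random.default_rng(43)
    R2 = 150
    cells, hits = [], 0
    for _ in range(R2):
        df = simulate_trial_counts(sym, rng)
        cells.append(df[df.arm == "intervention"].eligible.mean())
        hits += gee_test(df).p_value < 0.05
    pairs = int(np.mean(cells) * sym.n_clinics_per_arm)
    analytic = did_interaction_power(0.04, 0.8, pairs, n_clinics=8)
    out["did_power_effect_0.8"] = {
        "empirical": hits / R2,
        "analytic": analytic,
        "pairs_per_cell": pairs,
        "replicates": R2,
    }
    print(f"DiD power at effect 0.8: empirical {hits / R2:.2f} vs analytic {analytic:.2f} "
          f"({pairs} pairs/cell)")

    ps = PowerSpec(p_control=0.20, relative_reduction=0.20)
    n = sample_size(ps)["n_per_arm"]
    rng = np.random.default_rng(44)
    R3 = 1000
    z = 1.959963984540054
    rej3 = 0
    for _ in range(R3):
        x1, x2 = rng.binomial(n, 0.20), rng.binomial(n, 0.16)
        pbar = (x1 + x2) / (2 * n)
        se = np.sqrt(2 * pbar * (1 - pbar) / n)
        rej3 += abs(x1 - x2) / n / se > z
    out["sample_size"] = {
        "n_per_arm": n,
        "simulated_power": rej3 / R3,
        "analytic_power": two_proportion_power(0.20, 0.16, n),
    }
    print(f"sample size: n={n}/arm; simulated power {rej3 / R3:.3f}, "
          f"analytic {out['sample_size']['analytic_power']:.3f} (requested 0.80)")

    ROOT.mkdir(exist_ok=True)
    (ROOT / "calibration.json").write_text(json.dumps(out, indent=1))
    print(f"wrote results/calibration.json in {time.time() - t0:.0f}s")


if __name__ == "__main__":
    main()
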