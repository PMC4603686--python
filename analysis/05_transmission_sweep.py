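#!/usr/bin/env python
"""Coupled-model prevalence across vertical transmission rates.

For each resource level: endophyte prevalence at the observed
transmission rates, sweeps of each transmission rate over [0, 1]
(other rate held at 1, with the observed-value convention as a second
set of curves), and persistence thresholds under both the asymptotic
and the 50-year finite-horizon criterion.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import festuca_demography as fd
from festuca_demography import reference
from festuca_demography.io import write_table

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    sweep_tables, thr_rows, prev_rows = [], [], []
    for resource in ("natural", "F+"):
        S = reference.PRINTED_MATRICES[("S", resource)]
        NS = reference.PRINTED_MATRICES[("NS", resource)]
        obs = reference.TRANSMISSION[resource]

        B = fd.build_coupled(S, NS, obs)
        prev_rows.append({
            "resource": resource,
            "T_A": obs.T_A, "T_S": obs.T_S, "T_seed": obs.T_seed,
            "asymptotic_prevalence_pct":
                100 * fd.asymptotic_prevalence(B),
            "prevalence_50yr_pct": 100 * fd.finite_horizon_prevalence(
                B, np.array([0, 0, 0, 100.0, 0, 0, 0, 100.0]), 50
            ),
        })

        for varied in ("T_A", "T_S"):
            for convention, fixed in (
                ("other=1", None),
                ("other=observed", {"T_A": obs.T_A, "T_S": obs.T_S}),
            ):
                res = fd.transmission_sweep(S, NS, varied, fixed=fixed)
                tab = res.table.copy()
                tab.insert(0, "resource", resource)
                tab.insert(1, "varied", varied)
                tab.insert(2, "convention", convention)
                sweep_tables.append(tab)

            for criterion in ("asymptotic", "finite_horizon"):
                thr = fd.persistence_threshold(S, NS, varied,
                                               criterion=criterion)
                thr_rows.append({
                    "resource": resource, "varied": varied,
                    "criterion": criterion, "threshold": thr.rate,
                    "at_boundary": thr.at_boundary,
                })

    write_table(pd.concat(sweep_tables, ignore_index=True),
                OUT / "transmission_sweeps.tsv", {"analysis": "sweep"})
    prev = pd.DataFrame(prev_rows)
    write_table(prev, OUT / "prevalence_observed.tsv",
                {"analysis": "prevalence"})
    thr = pd.DataFrame(thr_rows)
    write_table(thr, OUT / "persistence_thresholds.tsv",
                {"analysis": "thresholds"})

    print("wrote results/transmission_sweeps.tsv, "
          "results/prevalence_observed.tsv, "
          "results/persistence_thresholds.tsv")
    print(prev.round(1).to_string(index=False))
    print(thr.round(3).to_string(index=False))
    print("note: the model predicts symbiont persistence under both "
          "resource levels at the observed rates, and a LOWER threshold "
          "under F+ (the relative S advantage is larger there); the "
          "published 58%/0% prevalence and higher F+ thresholds are not "
          "reproduced by the deterministic coupled model")


if __name__ == "__main__":
    main()
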