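#!/usr/bin/env python
"""Tone-combination experiments on the passive compartmental ICx model.

Runs the three canonical circuit configurations — AMPA synapses on 5-um
dendrites with high leak, AMPA synapses on thin spines, NMDA synapses on
spines — through the tone / tone-combination protocol, classifies each
V_add-V_stack relation as linear / quadratic / sigmoidal, and tabulates the
matched/mismatched (3-mV rule) structure of the two frequency channels
across ITD.

Expected outcome: dendritic AMPA input combines linearly; spine placement
saturates the combination (quadratic); NMDA's magnesium block adds a lower
plateau (sigmoidal).  Mismatched channel strengths concentrate on side
peaks, where nonlinear combination arises.

Writes results/compartmental_summary.csv and per-configuration response
tables results/compartmental_<name>.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from icxfreq.compartmental import combination_experiment, reference_configurations


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for name, cfg in reference_configurations().items():
        res = combination_experiment(
            cfg["morph"],
            cfg["synapses"],
            cfg["config"],
            n_trials=cfg["n_trials"],
            seed=args.seed,
        )
        res.to_frame().to_csv(
            args.out_dir / f"compartmental_{name}.csv", index=False, float_format="%.4f"
        )
        main_peak = np.abs(res.itds) <= 60
        side = np.abs(res.itds) >= 140
        rows.append(
            {
                "configuration": name,
                "expected": cfg["expected"],
                "classified": res.winner,
                "v_add_max_mv": res.v_add.max(),
                "v_stack_max_mv": res.v_stack_rel.max(),
                "mismatched_frac_main": float(np.mean(~res.matched[main_peak])),
                "mismatched_frac_side": float(np.mean(~res.matched[side])),
            }
        )
        print(
            f"{name:10s}: classified {res.winner:13s} (expected {cfg['expected']}); "
            f"V_add max {res.v_add.max():5.1f} mV; mismatched main/side "
            f"{rows[-1]['mismatched_frac_main']:.2f}/{rows[-1]['mismatched_frac_side']:.2f}"
        )
    df = pd.DataFrame(rows)
    df.to_csv(args.out_dir / "compartmental_summary.csv", index=False, float_format="%.4f")
    print(f"\nwrote {args.out_dir}/compartmental_summary.csv")


if __name__ == "__main__":
    main()
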