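#!/usr/bin/env python
"""Map the power-law subunit parameter space against the in vivo ITD
statistics.

Sweeps the subunit frequency-tuning width (sigma, 0.1-4 kHz), the power-law
exponent (0.1-10, log-spaced) and the spread of subunit center frequencies
(0, 1.25, 2.5 kHz), computes side-peak suppression (SPS) and half-width
(HW) of the model PSP ITD curve for each cell, and z-scores them against
the experimental population statistics (SPS 23.18 +/- 12.27%, HW 75.17 +/-
17.12 us).

Key findings printed at the end: SPS never falls two SDs below the mean
anywhere on the map (suppressive subunits bottom out at SPS ~ 0), whereas
broad integration combined with strongly expansive subunits overshoots the
+2 SPS bound and undershoots the -2 HW bound — expansive nonlinearities are
incompatible with broad frequency integration.

Writes results/subunit_zmap.csv (long format).
"""

import argparse
from pathlib import Path

import numpy as np

from icxfreq.iccl import build_population
from icxfreq.twolayer import map_subunit_space


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    pop = build_population()
    zmap = map_subunit_space(pop)
    df = zmap.to_frame()
    out = args.out_dir / "subunit_zmap.csv"
    df.to_csv(out, index=False, float_format="%.4f")

    defined = ~np.isnan(zmap.sps_z)
    feasible = (
        defined
        & (np.abs(zmap.sps_z) <= 2.0)
        & ~np.isnan(zmap.hw_z)
        & (np.abs(zmap.hw_z) <= 2.0)
    )
    print(f"wrote {out} ({len(df)} cells)")
    print(f"min SPS z-score over the map : {np.nanmin(zmap.sps_z):+.3f} (never < -2)")
    print(f"max SPS z-score over the map : {np.nanmax(zmap.sps_z):+.3f}")
    print(
        "broad+expansive corner (sigma=4, p=10, spread 0): "
        f"SPS z = {zmap.sps_z[0, -1, -1]:+.2f}, HW z = {zmap.hw_z[0, -1, -1]:+.2f}"
    )
    for a, spread in enumerate(zmap.cf_spreads):
        frac = feasible[a].mean()
        print(f"cf spread {spread:4.2f} kHz: {100 * frac:4.1f}% of cells within both +/-2 bounds")


if __name__ == "__main__":
    main()
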