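"""Moment and correlation statistics for the simulated condition ensembles.

Reads the tracks written by 01_simulate_tracks.py and writes, per
condition, the time-ensemble-averaged first/second moments, velocity
auto- and cross-correlations, and the empirical log-derivative beta(t)
under results/stats/<condition>/.  Prints the headline numbers: drift
slope along the gradient, anisotropy of spreading, and decorrelation.

    python analysis/02_trajectory_statistics.py
"""

import argparse
from pathlib import Path

import numpy as np

from tempertrack.io import read_trajectories
from tempertrack.stats import (
    empirical_beta,
    ensemble_moments,
    velocity_autocorrelation,
    velocity_crosscorrelation,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--tracks", type=Path, default=Path("results/tracks"))
    ap.add_argument("--out", type=Path, default=Path("results/stats"))
    args = ap.parse_args()

    for f in sorted(args.tracks.glob("*.csv")):
        cond = f.stem
        paths = read_trajectories(f)
        out = args.out / cond
        out.mkdir(parents=True, exist_ok=True)
        vac0 = {}
        msd_final = {}
        for axis in ("x", "y"):
            mom = ensemble_moments(paths, axis)
            mom.to_frame().to_csv(out / f"moments_{axis}.csv", index=False)
            vac = velocity_autocorrelation(paths, axis)
            vac.to_frame().to_csv(out / f"vacf_{axis}.csv", index=False)
            lags, beta = empirical_beta(mom)
            np.savetxt(
                out / f"beta_{axis}.csv", np.column_stack([lags, beta]),
                delimiter=",", header="lag_min,beta", comments="",
            )
            vac0[axis] = vac.values[0]
            msd_final[axis] = mom.second[-1]
            if axis == "y":
                drift = mom.first[-1] / mom.lags[-1]
        cross = velocity_crosscorrelation(paths)
        cross.to_frame().to_csv(out / "vccf_xy.csv", index=False)
        # couple strength relative to the geometric mean velocity variance
        cross_rel = np.nanmax(np.abs(cross.values[:10])) / np.sqrt(vac0["x"] * vac0["y"])
        print(
            f"{cond:>14}: drift {drift:+.2f} um/min, "
            f"msd_y/msd_x at T = {msd_final['y'] / msd_final['x']:6.1f}, "
            f"|v-cross| < {cross_rel:.3f} of v2"
        )


if __name__ == "__main__":
    main()
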