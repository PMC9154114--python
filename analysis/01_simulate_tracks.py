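"""Simulate synthetic track ensembles for the four murine conditions.

Writes one trajectory CSV per condition under results/tracks/ using the
murine design (361 positions at dt = 5 s): the wildtype condition uses
the published drift-axis estimates, the impaired conditions use the
synthetic stand-ins documented in tempertrack.conditions.

    python analysis/01_simulate_tracks.py --seed 1 --n-paths 60
"""

import argparse
from pathlib import Path

from tempertrack.conditions import MURINE_CONDITIONS_Y, WT_MURINE_X
from tempertrack.io import write_trajectories
from tempertrack.simulate import make_design, simulate_paths


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-paths", type=int, default=60)
    ap.add_argument("--out", type=Path, default=Path("results/tracks"))
    args = ap.parse_args()

    for i, (name, spec_y) in enumerate(MURINE_CONDITIONS_Y.items()):
        design = make_design(
            "murine", WT_MURINE_X, spec_y, n_paths=args.n_paths,
            seed=args.seed + i, label=name,
        )
        paths = simulate_paths(design)
        out = args.out / f"{name.replace('+', '_')}.csv"
        write_trajectories(paths, out)
        drift = paths[0].y[-1] / paths[0].times[-1]
        print(
            f"{name:>11}: {len(paths)} paths x {len(paths[0])} samples -> {out}"
            f"  (model {spec_y.model.value}, first path net drift {drift:.1f} um/min)"
        )


if __name__ == "__main__":
    main()
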