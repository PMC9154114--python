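"""Fit the four motion models to a condition's tracks by nested sampling.

Subsamples the murine acquisition grid to the dt = 10 s analysis grid
(pixelation-bias convention), fits each requested model to the chosen
axis, and writes per-model posterior JSON plus weighted samples under
results/fits/<condition>/.  At the defaults (60 paths, 181 points,
500 live points) a fit takes several minutes per model on one CPU;
--n-paths/--n-live/--extra-subsample trade accuracy for time.

    python analysis/03_fit_models.py --condition WT --axis y --models A,B,C,D
"""

import argparse
import time
from pathlib import Path

from tempertrack.inference import fit_model, subsample_paths
from tempertrack.io import read_trajectories, save_fit


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--tracks", type=Path, default=Path("results/tracks"))
    ap.add_argument("--condition", default="WT")
    ap.add_argument("--axis", choices=["x", "y"], default="y")
    ap.add_argument("--models", default="A,B,C,D")
    ap.add_argument("--n-paths", type=int, default=None, help="cap the ensemble")
    ap.add_argument("--subsample", type=int, default=2, help="5 s -> 10 s analysis grid")
    ap.add_argument("--extra-subsample", type=int, default=1, help="further coarsening for quick runs")
    ap.add_argument("--n-live", type=int, default=500)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/fits"))
    args = ap.parse_args()

    f = args.tracks / f"{args.condition.replace('+', '_')}.csv"
    paths = read_trajectories(f)
    if args.n_paths:
        paths = paths[: args.n_paths]
    paths = subsample_paths(paths, args.subsample * args.extra_subsample)
    print(
        f"fitting {args.condition}/{args.axis}: {len(paths)} paths x "
        f"{len(paths[0])} samples, {args.n_live} live points"
    )
    out = args.out / args.condition.replace("+", "_")
    for m in args.models.split(","):
        t0 = time.perf_counter()
        res = fit_model(paths, m.strip(), axis=args.axis, n_live=args.n_live, seed=args.seed)
        save_fit(res, out / f"fit_{m}_{args.axis}.json", out / f"fit_{m}_{args.axis}.samples.csv")
        line = ", ".join(
            f"{n}={v:.3f}±{s:.3f}" for n, v, s in zip(res.param_names, res.means, res.sds)
        )
        print(
            f"  model {m}: lnZ = {res.log_z:.1f} ± {res.log_z_err:.2f}  [{line}]  "
            f"({time.perf_counter() - t0:.0f}s, {res.n_calls} likelihood calls)"
        )


if __name__ == "__main__":
    main()
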