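"""Turn per-model evidences into model probabilities per condition/axis.

Reads the fit JSONs written by 03_fit_models.py and prints/writes the
evidence-normalized probability table (percentages).  The expected
pattern on synthetic data mirrors the biology: pure fBm (model A) wins
on the wildtype drift axis, tempered models (B/C) win whenever
directional persistence is impaired, and the Ornstein-Uhlenbeck model D
is never competitive.

    python analysis/04_model_comparison.py --condition WT --axis y
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--fits", type=Path, default=Path("results/fits"))
    ap.add_argument("--condition", default="WT")
    ap.add_argument("--axis", choices=["x", "y"], default="y")
    ap.add_argument("--out", type=Path, default=Path("results/model_probabilities.csv"))
    args = ap.parse_args()

    fit_dir = args.fits / args.condition.replace("+", "_")
    rows = []
    for f in sorted(fit_dir.glob(f"fit_*_{args.axis}.json")):
        payload = json.loads(f.read_text())
        rows.append({"model": payload["model"], "log_z": payload["log_z"]})
    if len(rows) < 2:
        raise SystemExit(f"need >=2 fits in {fit_dir}; run 03_fit_models.py first")
    df = pd.DataFrame(rows)
    shifted = df["log_z"] - df["log_z"].max()
    df["probability_percent"] = 100 * np.exp(shifted) / np.exp(shifted).sum()
    df["condition"] = args.condition
    df["axis"] = args.axis
    args.out.parent.mkdir(parents=True, exist_ok=True)
    header = not args.out.exists()
    df.to_csv(args.out, mode="a", header=header, index=False)
    print(df.to_string(index=False, float_format=lambda v: f"{v:.3f}"))


if __name__ == "__main__":
    main()
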