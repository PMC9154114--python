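"""Trajectory tables, result serialization, and run configuration.

The canonical on-disk trajectory format is a tidy CSV with columns
``cell_id, t, x, y`` (minutes and μm), one row per sample; readers
group by cell, sort by time, validate monotonicity and normalize every
path to a common starting point at the origin.  An Excel reader with
the same contract handles supplementary-style sheets.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import ModelComparison, PosteriorResult
from .simulate import Trajectory

__all__ = [
    "REQUIRED_COLUMNS",
    "read_trajectories",
    "write_trajectories",
    "trajectories_to_frame",
    "save_fit",
    "load_fit_summary",
    "save_comparison",
    "RunConfig",
]

REQUIRED_COLUMNS = ("cell_id", "t", "x", "y")


class TrajectoryParseError(ValueError):
    """CSV content violates the trajectory-table contract."""


def _frame_to_trajectories(
    df: pd.DataFrame, normalize: bool, time_scale: float
) -> list[Trajectory]:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryParseError(f"missing required columns: {missing}")
    df = df.copy()
    df["__row"] = np.arange(len(df)) + 2  # 1-based + header
    paths = []
    for cell, g in df.groupby("cell_id", sort=False):
        t = g["t"].to_numpy(dtype=float) * time_scale
        dup = np.flatnonzero(np.diff(t) == 0)
        if dup.size:
            row = int(g["__row"].iloc[dup[0] + 1])
            raise TrajectoryParseError(
                f"cell {cell!r}: duplicate time at row {row}"
            )
        dec = np.flatnonzero(np.diff(t) < 0)
        if dec.size:
            row = int(g["__row"].iloc[dec[0] + 1])
            raise TrajectoryParseError(
                f"cell {cell!r}: decreasing time at row {row}"
            )
        traj = Trajectory(
            str(cell), t, g["x"].to_numpy(dtype=float), g["y"].to_numpy(dtype=float)
        )
        paths.append(traj.normalized() if normalize else traj)
    if not paths:
        raise TrajectoryParseError("file contains no trajectories")
    return paths


def read_trajectories(
    path: str | Path, normalize: bool = True, times_in_seconds: bool = False
) -> list[Trajectory]:
    """Read a trajectory CSV (or supplementary-style Excel file).

    Paths are start-normalized so every cell begins at (t, x, y) =
    (0, 0, 0); pass ``times_in_seconds=True`` to convert a seconds
    time column into the canonical minutes.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    return _frame_to_trajectories(df, normalize, 1.0 / 60.0 if times_in_seconds else 1.0)


def trajectories_to_frame(paths: list[Trajectory]) -> pd.DataFrame:
    return pd.concat(
        [
            pd.DataFrame({"cell_id": p.cell_id, "t": p.times, "x": p.x, "y": p.y})
            for p in paths
        ],
        ignore_index=True,
    )


def write_trajectories(paths: list[Trajectory], out: str | Path) -> Path:
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    trajectories_to_frame(paths).to_csv(out, index=False)
    return out


def save_fit(result: PosteriorResult, out_json: str | Path, samples_csv: str | Path | None = None) -> None:
    """Serialize a fit: JSON summary plus optional weighted-sample CSV."""
    out_json = Path(out_json)
    out_json.parent.mkdir(parents=True, exist_ok=True)
    out_json.write_text(json.dumps(result.summary_dict(), indent=2, sort_keys=True))
    if samples_csv is not None:
        df = pd.DataFrame(result.samples, columns=list(result.param_names))
        df["weight"] = result.weights
        Path(samples_csv).parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(samples_csv, index=False)


def load_fit_summary(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def save_comparison(comparison: ModelComparison, out_json: str | Path) -> None:
    out_json = Path(out_json)
    out_json.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "log_z": {m.value: float(z) for m, z in zip(comparison.models, comparison.log_z)},
        "probability_percent": comparison.as_percent(),
    }
    out_json.write_text(json.dumps(payload, indent=2, sort_keys=True))


@dataclass
class RunConfig:
    """Configuration of one pipeline run; hashed into every output.

    Loadable from a YAML mapping via :meth:`from_yaml`."""

    input: str | None = None
    preset: str | None = None
    axis: str = "y"
    models: tuple[str, ...] = ("A", "B", "C", "D")
    seed: int = 0
    subsample: int = 1
    n_live: int = 500
    n_paths: int | None = None
    out_dir: str = "results"
    prior_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        payload = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(payload, dict):
            raise ValueError(f"{path}: expected a YAML mapping of config keys")
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        if "models" in payload:
            payload["models"] = tuple(payload["models"])
        return cls(**payload)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def stamp(self) -> dict:
        return {"seed": self.seed, "config_hash": self.config_hash()}
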