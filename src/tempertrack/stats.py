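"""Empirical moment and correlation statistics of trajectory ensembles.

Time averages run a sliding window over one path: the first/second
moment of displacement at lag ℓ is the mean (squared) displacement over
all window start points, and velocity auto/cross-correlations apply the
same window to difference-quotient velocities.  Time-ensemble averages
then take the unweighted mean of the per-cell curves; the mean squared
displacement is the NON-central second moment (central moments combined
with time averages misbehave for drifting fractional dynamics).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import Trajectory

__all__ = [
    "MomentCurves",
    "CorrelationCurves",
    "velocities",
    "time_avg_moments",
    "ensemble_moments",
    "velocity_autocorrelation",
    "velocity_crosscorrelation",
    "empirical_beta",
]


@dataclass
class MomentCurves:
    """First/second displacement moments vs lag, per cell and ensemble."""

    lags: np.ndarray                 # min
    first: np.ndarray                # ensemble mean displacement (μm)
    second: np.ndarray               # ensemble mean squared displacement (μm²)
    n_paths: np.ndarray              # paths contributing at each lag
    axis: str
    per_cell_first: np.ndarray | None = None   # (n_cells, n_lags), NaN-padded
    per_cell_second: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lag_min": self.lags,
                f"mean_{self.axis}": self.first,
                f"msd_{self.axis}": self.second,
                "n_paths": self.n_paths,
            }
        )


@dataclass
class CorrelationCurves:
    """Velocity auto- or cross-correlation vs lag (μm²/min²)."""

    lags: np.ndarray
    values: np.ndarray               # ensemble mean
    n_paths: np.ndarray
    axis: str                        # "x", "y" or "xy" for the cross term
    per_cell: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lag_min": self.lags,
                f"vcorr_{self.axis}": self.values,
                "n_paths": self.n_paths,
            }
        )


def _step_count(path: Trajectory, delta: float) -> int:
    """Δ as an integer number of sampling intervals (no interpolation)."""
    dt = path.dt
    steps = delta / dt
    if abs(steps - round(steps)) > 1e-6 or round(steps) < 1:
        raise ValueError(
            f"velocity step {delta} min is not a positive multiple of the "
            f"sampling interval {dt} min"
        )
    return int(round(steps))


def velocities(path: Trajectory, delta: float, axis: str = "x") -> np.ndarray:
    """Difference-quotient velocities v(t) = (x(t+Δ) − x(t))/Δ."""
    j = _step_count(path, delta)
    vals = path.axis(axis)
    if j >= len(path):
        raise ValueError("velocity step exceeds path duration")
    return (vals[j:] - vals[:-j]) / delta


def _sliding_moments(series: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Window means of displacement and squared displacement at all lags."""
    n = series.size
    first = np.empty(n)
    second = np.empty(n)
    first[0] = 0.0
    second[0] = 0.0
    for m in range(1, n):
        d = series[m:] - series[:-m]
        first[m] = d.mean()
        second[m] = (d**2).mean()
    return first, second


def time_avg_moments(path: Trajectory, axis: str = "x") -> MomentCurves:
    """Single-cell time-averaged first and second displacement moments.

    The sliding-window integrals are discretized as means over all
    admissible start indices; lags run over 0 … (n−1)·dt, strictly
    inside the observation window.
    """
    if len(path) < 2:
        raise ValueError("need at least two samples")
    series = path.axis(axis)
    first, second = _sliding_moments(series)
    lags = path.times - path.times[0]
    return MomentCurves(
        lags=lags,
        first=first,
        second=second,
        n_paths=np.ones(len(path), dtype=int),
        axis=axis,
        per_cell_first=first[None, :],
        per_cell_second=second[None, :],
    )


def _stack_ragged(curves: list[np.ndarray], n_lags: int) -> np.ndarray:
    out = np.full((len(curves), n_lags), np.nan)
    for i, c in enumerate(curves):
        out[i, : c.size] = c
    return out


def _check_common_lag_grid(paths: list[Trajectory]) -> np.ndarray:
    """Lag grid of the longest path; all shorter paths must prefix-match."""
    longest = max(paths, key=len)
    lags = longest.times - longest.times[0]
    for p in paths:
        if not np.allclose(p.times - p.times[0], lags[: len(p)], atol=1e-9):
            raise ValueError(
                f"cell {p.cell_id!r}: time grid is not a prefix of the common lag grid"
            )
    return lags


def ensemble_moments(paths: list[Trajectory], axis: str = "x") -> MomentCurves:
    """Time-ensemble-averaged moments over a path ensemble.

    With unequal path lengths (in-vivo data) each lag averages only the
    paths that reach it; the per-lag path count is reported alongside.
    """
    if not paths:
        raise ValueError("empty ensemble")
    lags = _check_common_lag_grid(paths)
    firsts, seconds = [], []
    for p in paths:
        f, s = _sliding_moments(p.axis(axis))
        firsts.append(f)
        seconds.append(s)
    pf = _stack_ragged(firsts, lags.size)
    ps = _stack_ragged(seconds, lags.size)
    n = np.sum(~np.isnan(pf), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        first = np.nanmean(pf, axis=0)
        second = np.nanmean(ps, axis=0)
    return MomentCurves(lags, first, second, n, axis, pf, ps)


def _sliding_corr(va: np.ndarray, vb: np.ndarray) -> np.ndarray:
    n = va.size
    out = np.empty(n)
    out[0] = (va * vb).mean()
    for m in range(1, n):
        out[m] = (va[m:] * vb[:-m]).mean()
    return out


def _correlation(
    paths: list[Trajectory], axis_a: str, axis_b: str, delta: float | None
) -> CorrelationCurves:
    if not paths:
        raise ValueError("empty ensemble")
    delta = paths[0].dt if delta is None else delta
    curves = []
    for p in paths:
        va = velocities(p, delta, axis_a)
        vb = velocities(p, delta, axis_b)
        curves.append(_sliding_corr(va, vb))
    n_lags = max(c.size for c in curves)
    stacked = _stack_ragged(curves, n_lags)
    n = np.sum(~np.isnan(stacked), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stacked, axis=0)
    lags = np.arange(n_lags) * paths[0].dt
    label = axis_a if axis_a == axis_b else axis_a + axis_b
    return CorrelationCurves(lags, mean, n, label, stacked)


def velocity_autocorrelation(
    paths: list[Trajectory], axis: str = "x", delta: float | None = None
) -> CorrelationCurves:
    """Time-ensemble-averaged velocity autocorrelation ⟨v(t+ℓ)v(t)⟩.

    Slow decay signals motion memory; on a drift axis the curve decays
    toward the squared drift velocity v_d² rather than zero.  Δ defaults
    to the path sampling interval.
    """
    return _correlation(paths, axis, axis, delta)


def velocity_crosscorrelation(
    paths: list[Trajectory], delta: float | None = None
) -> CorrelationCurves:
    """x–y velocity cross-correlation; ≈0 justifies axis-decoupled models."""
    return _correlation(paths, "x", "y", delta)


def empirical_beta(curve: MomentCurves) -> tuple[np.ndarray, np.ndarray]:
    """β(t) = d ln msd/d ln t by finite differences on an empirical curve.

    Central differences in log-log space at interior lags, one-sided at
    the ends; lags with non-positive msd are skipped with a warning.
    Returns ``(lags, beta)`` restricted to usable lags.
    """
    mask = (curve.lags > 0) & (curve.second > 0)
    if np.any((curve.lags > 0) & ~(curve.second > 0)):
        warnings.warn("non-positive msd values skipped in beta estimate")
    t = np.log(curve.lags[mask])
    m = np.log(curve.second[mask])
    if t.size < 2:
        raise ValueError("need at least two positive msd values")
    beta = np.gradient(m, t)
    return curve.lags[mask], beta
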