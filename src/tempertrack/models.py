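"""Gaussian stochastic-motion models for chemotactic cell trajectories.

Four overdamped Langevin models for a single coordinate of a migrating
cell, each defined by its stationary velocity (noise) autocorrelation
kernel and the position covariance obtained by integrating that kernel
twice:

* ``A`` — fractional Brownian motion (fBm): power-law kernel
  ``D_H/Γ(2H−1) τ^{2H−2}``; superdiffusive for Hurst exponent H > 1/2.
* ``B`` — exponentially tempered fBm: the fBm kernel multiplied by
  ``exp(−τ/τ*)``; memory is cut off beyond the tempering time τ*.
* ``C`` — power-law tempered fBm: kernel multiplied by
  ``(1 + τ/τ*)^{−μ}``; for μ > 2H−1 ("strong tempering") the process
  becomes normally diffusive at long times.
* ``D`` — Ornstein–Uhlenbeck velocity process: exponential kernel
  ``v_m² exp(−γτ)``, the classic persistent-random-walk reference.

Drift along the chemotactic gradient enters only through the first
moment ``⟨y(t)⟩ = v_d t``; covariances here are always the centered
(drift-free) ones.  All times are in minutes, lengths in μm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable

import numpy as np
from scipy.special import gamma, gammaln, hyp1f1, hyp2f1

__all__ = [
    "Model",
    "ParamVector",
    "ModelSpec",
    "velocity_kernel",
    "position_covariance",
    "covariance_matrix",
    "msd",
    "first_moment",
    "beta_curve",
    "PARAM_NAMES",
]

#: tolerance inside which H is treated as exactly 1/2 (Brownian limit)
H_HALF_EPS = 1e-6


class Model(str, Enum):
    """Model identifiers: A=fBm, B=exp-tempered, C=power-tempered, D=OU."""

    A = "A"
    B = "B"
    C = "C"
    D = "D"


#: free parameters of each model, in canonical (prior/sampler) order
PARAM_NAMES: dict[Model, tuple[str, ...]] = {
    Model.A: ("H", "D_H", "v_d"),
    Model.B: ("H", "D_H", "v_d", "tau_star"),
    Model.C: ("H", "D_H", "v_d", "tau_star", "mu"),
    Model.D: ("gamma", "v_m2", "v_d"),
}


@dataclass(frozen=True)
class ParamVector:
    """Physical parameters; only the fields used by the owning model are set.

    Units: ``H`` dimensionless; ``D_H`` μm²/min^{2H}; ``v_d`` μm/min;
    ``tau_star`` min; ``mu`` dimensionless; ``gamma`` 1/min;
    ``v_m2`` μm²/min².
    """

    H: float | None = None
    D_H: float | None = None
    v_d: float | None = None
    tau_star: float | None = None
    mu: float | None = None
    gamma: float | None = None
    v_m2: float | None = None

    def as_dict(self) -> dict[str, float]:
        return {k: v for k, v in self.__dict__.items() if v is not None}


@dataclass(frozen=True)
class ModelSpec:
    """A model identity plus the parameter vector for one coordinate axis."""

    model: Model
    params: ParamVector
    axis: str = "y"

    def __post_init__(self) -> None:
        model = Model(self.model)
        object.__setattr__(self, "model", model)
        p = self.params
        required = [n for n in PARAM_NAMES[model]]
        for name in required:
            val = getattr(p, name)
            if val is None:
                raise ValueError(f"model {model.value} requires parameter {name!r}")
            if not np.isfinite(val):
                raise ValueError(f"parameter {name!r} must be finite, got {val!r}")
        if model in (Model.A, Model.B, Model.C):
            if not 0.0 < p.H < 1.0:
                raise ValueError(f"Hurst exponent must lie in (0, 1), got {p.H}")
            if p.D_H <= 0:
                raise ValueError(f"D_H must be positive, got {p.D_H}")
        if model in (Model.B, Model.C) and p.tau_star <= 0:
            raise ValueError(f"tau_star must be positive, got {p.tau_star}")
        if model is Model.C and p.mu < 0:
            raise ValueError(f"mu must be non-negative, got {p.mu}")
        if model is Model.D:
            if p.gamma <= 0:
                raise ValueError(f"gamma must be positive, got {p.gamma}")
            if p.v_m2 <= 0:
                raise ValueError(f"v_m2 must be positive, got {p.v_m2}")
        if self.axis not in ("x", "y"):
            raise ValueError(f"axis must be 'x' or 'y', got {self.axis!r}")

    @classmethod
    def from_theta(cls, model: Model | str, theta: Iterable[float], axis: str = "y") -> "ModelSpec":
        """Build a spec from a flat parameter vector in canonical order."""
        model = Model(model)
        names = PARAM_NAMES[model]
        theta = list(theta)
        if len(theta) != len(names):
            raise ValueError(f"model {model.value} expects {len(names)} parameters, got {len(theta)}")
        return cls(model=model, params=ParamVector(**dict(zip(names, theta))), axis=axis)

    def theta(self) -> np.ndarray:
        """Flat parameter vector in canonical order."""
        return np.array([getattr(self.params, n) for n in PARAM_NAMES[self.model]])

    def with_drift(self, v_d: float) -> "ModelSpec":
        return replace(self, params=replace(self.params, v_d=v_d))


def _is_brownian(H: float) -> bool:
    return abs(H - 0.5) < H_HALF_EPS


def velocity_kernel(spec: ModelSpec, tau: float | np.ndarray) -> np.ndarray:
    """Stationary velocity autocorrelation ``⟨v(t)v(t+τ)⟩`` in μm²/min².

    For models A–C the kernel diverges as τ → 0 (and degenerates to a
    delta function at H = 1/2), so τ must be strictly positive there;
    model D is regular at τ = 0.
    """
    tau = np.asarray(tau, dtype=float)
    p = spec.params
    if spec.model is Model.D:
        if np.any(tau < 0):
            raise ValueError("lag time must be non-negative")
        return p.v_m2 * np.exp(-p.gamma * tau)
    if np.any(tau <= 0):
        raise ValueError("lag time must be positive for models A-C")
    if _is_brownian(p.H):
        raise ValueError(
            "velocity kernel is a delta function at H=1/2; use the covariance forms"
        )
    base = p.D_H / gamma(2 * p.H - 1) * tau ** (2 * p.H - 2)
    if spec.model is Model.A:
        return base
    if spec.model is Model.B:
        return base * np.exp(-tau / p.tau_star)
    return base * (1.0 + tau / p.tau_star) ** (-p.mu)


def _hyp1f1_tempered(H: float, z: np.ndarray) -> np.ndarray:
    """₁F₁(2H−1, 2H+1; −z) for z ≥ 0, with an asymptotic fallback.

    scipy's hyp1f1 is accurate for moderate arguments; for very large
    negative arguments we switch to the leading-order asymptotic
    Γ(b)/Γ(b−a) z^{−a}, whose relative error is O(1/z).
    """
    a, b = 2 * H - 1, 2 * H + 1
    z = np.asarray(z, dtype=float)
    out = hyp1f1(a, b, -z)
    # large negative argument or scipy overflow: leading-order asymptote
    bad = (z > 1e4) | ~np.isfinite(out)
    if np.any(bad):
        with np.errstate(divide="ignore", invalid="ignore"):
            asym = np.exp(gammaln(b) - gammaln(b - a)) * np.where(z > 0, z, np.nan) ** (-a)
        out = np.where(bad, asym, out)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("confluent hypergeometric evaluation failed")
    return out


def _hyp2f1_tempered(H: float, mu: float, z: np.ndarray) -> np.ndarray:
    """₂F₁(μ, 2H−1; 2H+1; −z) for z ≥ 0."""
    b, c = 2 * H - 1, 2 * H + 1
    z = np.asarray(z, dtype=float)
    out = hyp2f1(mu, b, c, -z)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("Gaussian hypergeometric evaluation failed")
    return out


def _tempered_power(spec: ModelSpec, s: np.ndarray) -> np.ndarray:
    """The building block |s|^{2H}·F(−|s|/τ*) of the A/B/C covariances."""
    p = spec.params
    s = np.abs(np.asarray(s, dtype=float))
    H = 0.5 if _is_brownian(p.H) else p.H
    pw = s ** (2 * H)
    if spec.model is Model.A or _is_brownian(p.H):
        # ₁F₁(0,2;z) = ₂F₁(μ,0,2;z) = 1: tempering drops out at H = 1/2
        return pw
    with np.errstate(invalid="ignore"):
        z = s / p.tau_star
    if spec.model is Model.B:
        return pw * _hyp1f1_tempered(H, z)
    return pw * _hyp2f1_tempered(H, p.mu, z)


def position_covariance(spec: ModelSpec, t, t2) -> np.ndarray:
    """Centered position covariance ``⟨x(t)x(t′)⟩`` in μm².

    Obtained by double integration of the velocity kernel; the tempered
    variants replace each power ``|s|^{2H}`` with a hypergeometric
    damping.  Drift is excluded (it lives in :func:`first_moment`).
    """
    t = np.asarray(t, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    if np.any(t < 0) or np.any(t2 < 0):
        raise ValueError("times must be non-negative")
    p = spec.params
    if spec.model is Model.D:
        g, vm2 = p.gamma, p.v_m2
        lo = np.minimum(t, t2)
        return (
            vm2
            / g**2
            * (
                2 * g * lo
                - 1.0
                - np.exp(-g * np.abs(t - t2))
                + np.exp(-g * t)
                + np.exp(-g * t2)
            )
        )
    H = 0.5 if _is_brownian(p.H) else p.H
    pref = p.D_H * np.exp(-gammaln(2 * H + 1))
    return pref * (
        _tempered_power(spec, t) + _tempered_power(spec, t2) - _tempered_power(spec, t - t2)
    )


def covariance_matrix(spec: ModelSpec, times: np.ndarray, jitter: float = 1e-8) -> np.ndarray:
    """Dense centered covariance on a strictly increasing time grid.

    A relative jitter of ``jitter * max(diag)`` is added to the diagonal
    so that marginally positive-definite matrices (long grids, extreme
    parameter draws) factorize.  Times must be strictly positive: the
    process is pinned to the origin at t = 0 and that degenerate point
    must not be part of a covariance grid.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if np.any(times <= 0):
        raise ValueError("covariance grid times must be strictly positive")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if spec.model is Model.D:
        C = position_covariance(spec, times[:, None], times[None, :])
    else:
        # the A/B/C covariances depend on times only through g(t), g(t')
        # and g(|t−t'|); evaluating the special functions on the unique
        # lags (≈n values on a uniform grid, not n²) dominates the cost
        p = spec.params
        H = 0.5 if _is_brownian(p.H) else p.H
        pref = p.D_H * np.exp(-gammaln(2 * H + 1))
        lags = np.abs(times[:, None] - times[None, :])
        uniq, inv = np.unique(np.round(lags, 12), return_inverse=True)
        g_lag = _tempered_power(spec, uniq)[inv].reshape(lags.shape)
        g_t = _tempered_power(spec, times)
        C = pref * (g_t[:, None] + g_t[None, :] - g_lag)
    C = 0.5 * (C + C.T)
    if jitter:
        C[np.diag_indices_from(C)] += jitter * float(C.diagonal().max())
    return C


def msd(spec: ModelSpec, t, centered: bool = True) -> np.ndarray:
    """Mean squared displacement at time t (μm²).

    The centered form is the diagonal of the position covariance; the
    non-central form adds the squared drift displacement ``(v_d t)²``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    p = spec.params
    if spec.model is Model.D:
        g = p.gamma
        out = 2 * p.v_m2 / g**2 * (g * t - 1.0 + np.exp(-g * t))
    else:
        H = 0.5 if _is_brownian(p.H) else p.H
        out = 2 * p.D_H * np.exp(-gammaln(2 * H + 1)) * _tempered_power(spec, t)
    if not centered:
        v_d = p.v_d if p.v_d is not None else 0.0
        out = out + (v_d * t) ** 2
    return out


def first_moment(spec: ModelSpec, t) -> np.ndarray:
    """Mean displacement ``v_d t`` (zero on a drift-free axis)."""
    t = np.asarray(t, dtype=float)
    v_d = spec.params.v_d if spec.params.v_d is not None else 0.0
    return v_d * t


def beta_curve(spec: ModelSpec, times: np.ndarray, step_ratio: float = 1.01) -> np.ndarray:
    """Logarithmic msd derivative β(t) = d ln msd / d ln t.

    β = 1 marks normal diffusion, β = 2 ballistic motion; tempering makes
    β(t) decay from ~2H toward 1.  Model A has the closed form β ≡ 2H;
    the other models are differentiated by central differences in
    log-log space with multiplicative step ``step_ratio``.  Uses the
    centered msd, so the drift term never inflates β.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times <= 0):
        raise ValueError("beta is defined for t > 0 only")
    if spec.model is Model.A or (
        spec.model in (Model.B, Model.C) and _is_brownian(spec.params.H)
    ):
        H = 0.5 if _is_brownian(spec.params.H) else spec.params.H
        return np.full_like(times, 2 * H)
    hi = msd(spec, times * step_ratio, centered=True)
    lo = msd(spec, times / step_ratio, centered=True)
    return (np.log(hi) - np.log(lo)) / (2.0 * math.log(step_ratio))
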