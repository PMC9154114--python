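"""Nested sampling for evidence computation and posterior summaries.

A compact implementation of Skilling's classic algorithm: live points
live in the unit hypercube and are mapped to physical parameters by a
prior transform (so any proper prior with an invertible CDF is
supported).  At each iteration the worst live point is recorded with
prior-volume weight ΔX·L and replaced by a constrained random-walk MCMC
chain started from a random surviving point, accepting only proposals
with likelihood above the current threshold.  The run stops when the
maximum possible remaining evidence is a negligible fraction of the
accumulated evidence.

The statistical uncertainty of ln Z is estimated as sqrt(H/n_live)
with H the information (KL divergence posterior‖prior), the standard
nested-sampling error estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["NestedResult", "nested_sample"]


@dataclass
class NestedResult:
    """Weighted posterior samples plus evidence from one nested run."""

    samples: np.ndarray        # (n_samples, ndim) physical parameters
    log_weights: np.ndarray    # normalized: logsumexp == 0
    log_likelihoods: np.ndarray
    log_z: float               # ln evidence
    log_z_err: float           # sqrt(H / n_live)
    information: float         # H, nats
    n_calls: int
    n_iter: int
    seed: int | None = None

    @property
    def weights(self) -> np.ndarray:
        return np.exp(self.log_weights)

    def mean(self) -> np.ndarray:
        return self.weights @ self.samples

    def std(self) -> np.ndarray:
        mu = self.mean()
        var = self.weights @ (self.samples - mu) ** 2
        return np.sqrt(np.maximum(var, 0.0))


def _logsumexp2(a: float, b: float) -> float:
    hi, lo = (a, b) if a >= b else (b, a)
    if hi == -np.inf:
        return -np.inf
    return hi + np.log1p(np.exp(lo - hi))


def _update_information(
    h: float, log_z: float, log_z_new: float, log_zi: float, logl: float
) -> float:
    """Skilling's running update of the information H (KL divergence)."""
    term = np.exp(log_zi - log_z_new) * logl
    if np.isfinite(log_z):
        term += np.exp(log_z - log_z_new) * (h + log_z)
    return float(term - log_z_new)


def _mcmc_replace(
    loglike_u: Callable[[np.ndarray], float],
    start_u: np.ndarray,
    start_logl: float,
    threshold: float,
    scale: float,
    n_steps: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, float, int]:
    """Random walk in the unit cube constrained to L > threshold.

    Proposals reflect off the cube boundary; the step scale is adapted
    toward ~50% acceptance and returned for reuse.
    """
    u = start_u.copy()
    logl = start_logl
    ndim = u.size
    accepted = 0
    calls = 0
    for _ in range(n_steps):
        prop = u + scale * rng.standard_normal(ndim)
        prop = np.abs(prop) % 2.0
        prop = np.where(prop > 1.0, 2.0 - prop, prop)
        cand = loglike_u(prop)
        calls += 1
        if cand > threshold:
            u, logl = prop, cand
            accepted += 1
    frac = accepted / n_steps
    if frac > 0.6:
        scale = min(scale * np.exp(1.0 / max(accepted, 1)), 1.0)
    elif frac < 0.4:
        scale *= np.exp(-1.0 / max(n_steps - accepted, 1))
    scale = max(scale, 1e-5)
    return u, logl, scale, calls


def nested_sample(
    log_likelihood: Callable[[np.ndarray], float],
    prior_transform: Callable[[np.ndarray], np.ndarray],
    ndim: int,
    n_live: int = 500,
    stop_frac: float = 1e-3,
    n_mcmc: int = 25,
    max_iter: int = 200_000,
    seed: int | np.random.SeedSequence | None = None,
) -> NestedResult:
    """Run nested sampling and return evidence plus weighted samples.

    Parameters
    ----------
    log_likelihood
        Maps a physical parameter vector to ln L; may return -inf.
    prior_transform
        Maps a unit-cube point to physical parameters (inverse prior CDF).
    n_live
        Number of live points; evidence error scales as 1/sqrt(n_live).
    stop_frac
        Terminate when max(L_live)·X < stop_frac · Z_accumulated.
    n_mcmc
        Constrained random-walk steps per replacement.
    """
    rng = np.random.default_rng(seed)

    calls = 0

    def loglike_u(u: np.ndarray) -> float:
        nonlocal calls
        calls += 1
        return float(log_likelihood(prior_transform(u)))

    u_live = rng.random((n_live, ndim))
    logl_live = np.array([loglike_u(u) for u in u_live])

    dead_u: list[np.ndarray] = []
    dead_logl: list[float] = []
    dead_logx: list[float] = []

    log_z = -np.inf
    log_x = 0.0                     # current prior volume (log)
    d_log_x = -1.0 / n_live         # mean log shrinkage per iteration
    scale = 0.1
    h = 0.0

    it = 0
    while it < max_iter:
        worst = int(np.argmin(logl_live))
        logl_star = float(logl_live[worst])
        log_x_new = log_x + d_log_x
        # prior-mass element ΔX = X_prev − X_new, in log space
        log_dx = log_x + np.log1p(-np.exp(d_log_x))

        if logl_star > -np.inf:
            log_zi = logl_star + log_dx
            log_z_new = _logsumexp2(log_z, log_zi)
            h = _update_information(h, log_z, log_z_new, log_zi, logl_star)
            log_z = log_z_new
            dead_u.append(u_live[worst].copy())
            dead_logl.append(logl_star)
            dead_logx.append(log_dx)

        # replace the worst point with a constrained draw
        alive = [i for i in range(n_live) if i != worst]
        start = int(rng.choice(alive)) if alive else worst
        u_new, logl_new, scale, _ = _mcmc_replace(
            loglike_u, u_live[start], float(logl_live[start]), logl_star, scale, n_mcmc, rng
        )
        u_live[worst] = u_new
        logl_live[worst] = logl_new
        log_x = log_x_new
        it += 1

        # stopping: remaining evidence bound vs accumulated
        logl_max = float(np.max(logl_live))
        if np.isfinite(log_z) and logl_max + log_x < log_z + np.log(stop_frac):
            break
    else:  # pragma: no cover - budget exhausted
        raise RuntimeError(
            f"nested sampling did not converge within {max_iter} iterations "
            f"(lnZ so far {log_z:.2f})"
        )

    # drain the remaining live points at uniform final volume
    log_x_live = log_x - np.log(n_live)
    order = np.argsort(logl_live)
    for i in order:
        logl_i = float(logl_live[i])
        if logl_i == -np.inf:
            continue
        log_zi = logl_i + log_x_live
        log_z_new = _logsumexp2(log_z, log_zi)
        h = _update_information(h, log_z, log_z_new, log_zi, logl_i)
        log_z = log_z_new
        dead_u.append(u_live[i].copy())
        dead_logl.append(logl_i)
        dead_logx.append(log_x_live)

    dead_logl_arr = np.array(dead_logl)
    log_w = dead_logl_arr + np.array(dead_logx) - log_z
    log_w -= _np_logsumexp(log_w)
    samples = np.array([prior_transform(u) for u in dead_u])
    h = max(h, 0.0)
    return NestedResult(
        samples=samples,
        log_weights=log_w,
        log_likelihoods=dead_logl_arr,
        log_z=float(log_z),
        log_z_err=float(np.sqrt(h / n_live)),
        information=float(h),
        n_calls=calls,
        n_iter=it,
        seed=seed if isinstance(seed, int) else None,
    )


def _np_logsumexp(a: np.ndarray) -> float:
    hi = np.max(a)
    if hi == -np.inf:
        return -np.inf
    return float(hi + np.log(np.sum(np.exp(a - hi))))
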