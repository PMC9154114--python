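"""Exact Gaussian-path likelihoods, priors, and nested-sampling fits.

Each motion model defines a multivariate normal over the sampled
positions of one coordinate: mean v_d·t and the model's centered
position covariance on the path's time grid.  The likelihood of an
ensemble is the product over paths, evaluated from raw positions (never
from fitted msd curves).  Nested sampling returns both the weighted
posterior and the evidence Z; evidences across models turn into model
probabilities P(M) = Z_M / Σ Z.

Murine data are analyzed at dt = 10 s (every second acquired point) to
suppress pixelation bias; zebrafish paths are analyzed on their native
grid.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .models import PARAM_NAMES, Model, ModelSpec, covariance_matrix
from .nested import NestedResult, nested_sample
from .simulate import Trajectory

__all__ = [
    "PriorSpec",
    "PosteriorResult",
    "ModelComparison",
    "path_log_likelihood",
    "ensemble_log_likelihood",
    "EnsembleLikelihood",
    "fit_model",
    "posterior_summary",
    "model_probabilities",
    "subsample_paths",
]

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))

#: smallest admissible tempering time (min); the kernel is undefined at 0
TAU_STAR_FLOOR = 1e-3


@dataclass(frozen=True)
class PriorSpec:
    """Weak priors for the model parameters.

    Uniform: H on [0.01, 0.99], v_d on [−25, 25] μm/min, τ* on
    [~0, 30] min, μ on [0, 4], γ on [0.1, 60] 1/min.  Exponential:
    D_H with mean 50 μm²/min^{2H} and v_m² with mean 100 μm²/min².
    """

    H_range: tuple[float, float] = (0.01, 0.99)
    v_d_range: tuple[float, float] = (-25.0, 25.0)
    tau_star_range: tuple[float, float] = (TAU_STAR_FLOOR, 30.0)
    mu_range: tuple[float, float] = (0.0, 4.0)
    D_H_mean: float = 50.0
    gamma_range: tuple[float, float] = (0.1, 60.0)
    v_m2_mean: float = 100.0

    def transform(self, model: Model) -> Callable[[np.ndarray], np.ndarray]:
        """Inverse-CDF map from the unit cube to physical parameters."""

        def _uniform(u, lo, hi):
            return lo + (hi - lo) * u

        def _expon(u, mean):
            return -mean * np.log1p(-np.minimum(u, 1.0 - 1e-15))

        def t(u: np.ndarray) -> np.ndarray:
            u = np.asarray(u, dtype=float)
            if model is Model.D:
                return np.array(
                    [
                        _uniform(u[0], *self.gamma_range),
                        _expon(u[1], self.v_m2_mean),
                        _uniform(u[2], *self.v_d_range),
                    ]
                )
            out = [
                _uniform(u[0], *self.H_range),
                _expon(u[1], self.D_H_mean),
                _uniform(u[2], *self.v_d_range),
            ]
            if model in (Model.B, Model.C):
                out.append(max(_uniform(u[3], 0.0, self.tau_star_range[1]), self.tau_star_range[0]))
            if model is Model.C:
                out.append(_uniform(u[4], *self.mu_range))
            return np.array(out)

        return t

    def mean(self, model: Model) -> np.ndarray:
        """Analytic prior means, in canonical parameter order."""
        if model is Model.D:
            return np.array(
                [np.mean(self.gamma_range), self.v_m2_mean, np.mean(self.v_d_range)]
            )
        out = [np.mean(self.H_range), self.D_H_mean, np.mean(self.v_d_range)]
        if model in (Model.B, Model.C):
            out.append(np.mean((0.0, self.tau_star_range[1])))
        if model is Model.C:
            out.append(np.mean(self.mu_range))
        return np.array(out)


def _gaussian_logpdf_chol(
    resid: np.ndarray, chol: tuple[np.ndarray, bool]
) -> float:
    """ln N(resid | 0, C) from a precomputed Cholesky factorization."""
    m = resid.size
    alpha = cho_solve(chol, resid)
    logdet = 2.0 * float(np.sum(np.log(np.diag(chol[0]))))
    return -0.5 * (resid @ alpha + logdet + m * _LOG2PI)


def path_log_likelihood(path: Trajectory, spec: ModelSpec, axis: str | None = None) -> float:
    """Exact multivariate-normal log likelihood of one path's positions.

    The t = 0 origin point is deterministic and excluded; the mean is
    v_d·t and the covariance the model's centered position covariance.
    Positive-definiteness failures yield −inf (zero likelihood) rather
    than an exception, so the sampler simply rejects that draw.
    """
    axis = axis or spec.axis
    times = path.times[1:] - path.times[0]
    data = path.axis(axis)[1:] - path.axis(axis)[0]
    return _axis_log_likelihood(times, data, spec)


def _axis_log_likelihood(times: np.ndarray, data: np.ndarray, spec: ModelSpec) -> float:
    if times.size == 0:
        return 0.0
    try:
        C = covariance_matrix(spec, times)
        chol = cho_factor(C, lower=True)
    except (np.linalg.LinAlgError, FloatingPointError, ValueError) as exc:
        logger.debug("PD failure for %s %s: %s", spec.model.value, spec.params.as_dict(), exc)
        return -np.inf
    v_d = spec.params.v_d if spec.params.v_d is not None else 0.0
    return _gaussian_logpdf_chol(data - v_d * times, chol)


class EnsembleLikelihood:
    """Product likelihood over paths with per-grid factorization caching.

    All paths sharing a time grid reuse one covariance build and one
    Cholesky factorization per parameter draw, so an equal-grid ensemble
    costs one O(M³) factorization plus N O(M²) solves.
    ``n_factorizations`` counts covariance factorizations for the cache
    contract.
    """

    def __init__(self, paths: Sequence[Trajectory], model: Model | str, axis: str = "y"):
        self.model = Model(model)
        self.axis = axis
        self.n_factorizations = 0
        self.n_calls = 0
        # group paths by identical (shifted) grid
        self._groups: list[tuple[np.ndarray, np.ndarray]] = []
        buckets: dict[bytes, list[Trajectory]] = {}
        for p in paths:
            t = p.times - p.times[0]
            buckets.setdefault(t.tobytes(), []).append(p)
        for group in buckets.values():
            times = group[0].times - group[0].times[0]
            data = np.stack(
                [p.axis(axis) - p.axis(axis)[0] for p in group], axis=1
            )
            self._groups.append((times[1:], data[1:, :]))
        self.n_paths = len(paths)
        self.fingerprint = self._fingerprint()

    def _fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(self.axis.encode())
        for times, data in self._groups:
            h.update(times.tobytes())
            h.update(data.tobytes())
        return h.hexdigest()[:16]

    def __call__(self, theta: np.ndarray) -> float:
        self.n_calls += 1
        try:
            spec = ModelSpec.from_theta(self.model, theta, axis=self.axis)
        except ValueError:
            return -np.inf
        v_d = spec.params.v_d if spec.params.v_d is not None else 0.0
        total = 0.0
        for times, data in self._groups:
            try:
                C = covariance_matrix(spec, times)
                chol = cho_factor(C, lower=True)
                self.n_factorizations += 1
            except (np.linalg.LinAlgError, FloatingPointError, ValueError):
                return -np.inf
            resid = data - (v_d * times)[:, None]
            alpha = cho_solve(chol, resid)
            logdet = 2.0 * float(np.sum(np.log(np.diag(chol[0]))))
            m, n = resid.shape
            total += -0.5 * (
                float(np.sum(resid * alpha)) + n * (logdet + m * _LOG2PI)
            )
        return total


def ensemble_log_likelihood(
    paths: Sequence[Trajectory], spec: ModelSpec, axis: str | None = None
) -> float:
    """Sum of per-path log likelihoods (log of the product likelihood)."""
    if not paths:
        return 0.0
    like = EnsembleLikelihood(paths, spec.model, axis or spec.axis)
    return like(spec.theta())


@dataclass
class PosteriorResult:
    """Posterior summary of one (model, axis) fit."""

    model: Model
    axis: str
    param_names: tuple[str, ...]
    samples: np.ndarray
    weights: np.ndarray
    log_z: float
    log_z_err: float
    means: np.ndarray
    sds: np.ndarray
    seed: int | None
    n_calls: int
    data_fingerprint: str
    n_paths: int

    def summary_dict(self) -> dict:
        return {
            "model": self.model.value,
            "axis": self.axis,
            "log_z": self.log_z,
            "log_z_err": self.log_z_err,
            "seed": self.seed,
            "n_paths": self.n_paths,
            "n_calls": self.n_calls,
            "params": {
                name: {"mean": float(m), "sd": float(s)}
                for name, m, s in zip(self.param_names, self.means, self.sds)
            },
        }


@dataclass
class ModelComparison:
    """Evidences and normalized model probabilities on shared data."""

    models: list[Model]
    log_z: np.ndarray
    probabilities: np.ndarray  # sums to 1

    def as_percent(self) -> dict[str, float]:
        return {m.value: 100.0 * p for m, p in zip(self.models, self.probabilities)}


def subsample_paths(paths: Sequence[Trajectory], factor: int) -> list[Trajectory]:
    """Keep every ``factor``-th sample (timestamps preserved).

    factor 2 turns the murine dt = 5 s acquisition grid into the
    dt = 10 s analysis grid that suppresses pixelation bias.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("subsampling factor must be a positive integer")
    factor = int(factor)
    out = []
    for p in paths:
        sl = slice(None, None, factor)
        if factor >= len(p):
            warnings.warn(
                f"cell {p.cell_id!r}: subsample factor {factor} >= path length; "
                "only the starting point remains"
            )
        out.append(Trajectory(p.cell_id, p.times[sl], p.x[sl], p.y[sl]))
    return out


def fit_model(
    paths: Sequence[Trajectory],
    model: Model | str,
    axis: str = "y",
    prior: PriorSpec | None = None,
    n_live: int = 500,
    stop_frac: float = 1e-3,
    n_mcmc: int = 25,
    seed: int | None = None,
    log_likelihood: Callable[[np.ndarray], float] | None = None,
) -> PosteriorResult:
    """Nested-sampling posterior and evidence for one model on one axis.

    ``log_likelihood`` may override the ensemble Gaussian likelihood
    (used for analytic validation toys); the prior transform still comes
    from ``prior``.
    """
    model = Model(model)
    prior = prior or PriorSpec()
    like = EnsembleLikelihood(paths, model, axis) if paths else None
    ll = log_likelihood if log_likelihood is not None else like
    if ll is None:
        raise ValueError("either paths or an explicit log_likelihood is required")
    ndim = len(PARAM_NAMES[model])
    res: NestedResult = nested_sample(
        ll,
        prior.transform(model),
        ndim=ndim,
        n_live=n_live,
        stop_frac=stop_frac,
        n_mcmc=n_mcmc,
        seed=seed,
    )
    w = res.weights
    means = w @ res.samples
    sds = np.sqrt(np.maximum(w @ (res.samples - means) ** 2, 0.0))
    return PosteriorResult(
        model=model,
        axis=axis,
        param_names=PARAM_NAMES[model],
        samples=res.samples,
        weights=w,
        log_z=res.log_z,
        log_z_err=res.log_z_err,
        means=means,
        sds=sds,
        seed=seed,
        n_calls=res.n_calls,
        data_fingerprint=like.fingerprint if like is not None else "external",
        n_paths=like.n_paths if like is not None else 0,
    )


def posterior_summary(
    result: PosteriorResult,
    f: Callable[[np.ndarray], np.ndarray],
    max_samples: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted posterior mean and SD of a function of the parameters.

    Evaluates f at every weighted sample (optionally thinned to the
    ``max_samples`` heaviest), so nonlinear functionals such as β(t) or
    msd(t) bands get their true posterior spread rather than f(⟨θ⟩).
    Samples where f fails are dropped and the weights renormalized.
    """
    samples, weights = result.samples, result.weights
    if max_samples is not None and samples.shape[0] > max_samples:
        idx = np.argsort(weights)[::-1][:max_samples]
        samples, weights = samples[idx], weights[idx]
        weights = weights / weights.sum()
    vals, ws = [], []
    for theta, w in zip(samples, weights):
        if w == 0.0:
            continue
        try:
            vals.append(np.asarray(f(theta), dtype=float))
            ws.append(w)
        except Exception:
            warnings.warn("functional failed at a posterior sample; dropped")
    if not vals:
        raise ValueError("functional failed at every posterior sample")
    V = np.stack(vals)
    w = np.asarray(ws)
    w = w / w.sum()
    mean = w @ V
    sd = np.sqrt(np.maximum(w @ (V - mean) ** 2, 0.0))
    return mean, sd


def model_probabilities(results: Sequence[PosteriorResult]) -> ModelComparison:
    """Normalized model probabilities P(M) = Z_M / Σ_M' Z_M'.

    All results must describe the same data (checked by fingerprint);
    the softmax is evaluated in log space.
    """
    if len(results) < 2:
        raise ValueError("need at least two models to compare")
    fps = {r.data_fingerprint for r in results}
    if len(fps) != 1:
        raise ValueError(f"results were fitted on different data: {sorted(fps)}")
    log_z = np.array([r.log_z for r in results])
    shifted = log_z - log_z.max()
    p = np.exp(shifted)
    p /= p.sum()
    return ModelComparison(models=[r.model for r in results], log_z=log_z, probabilities=p)
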