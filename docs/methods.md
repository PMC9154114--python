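# Methods

## The stochastic models

Cell motion is modelled per coordinate as an overdamped Langevin equation
`dx/dt = ζ(t)`, with a constant drift `v_d` added to the mean of the
gradient axis only (`⟨y(t)⟩ = v_d t`, `⟨x(t)⟩ = 0`). The x- and y-axes are
treated as independent processes with their own parameters; this is
justified empirically by vanishing velocity cross-correlations and is an
assumption, not a theorem.

Four stationary noise kernels are supported (units: times min, lengths μm):

- **A — fBm.** `⟨v(t)v(t+τ)⟩ = D_H/Γ(2H−1)·τ^{2H−2}`, Hurst exponent
  H ∈ (0,1), generalized diffusion coefficient D_H (μm²/min^{2H}). The
  centered position covariance is
  `C(t,t′) = D_H/Γ(2H+1)·[t^{2H} + t′^{2H} − |t−t′|^{2H}]`; msd = 2D_H t^{2H}/Γ(2H+1).
- **B — exponentially tempered fBm.** Kernel multiplied by `exp(−τ/τ*)`;
  each power `s^{2H}` in the covariance picks up the confluent
  hypergeometric factor `₁F₁(2H−1, 2H+1; −s/τ*)`. Long-time behaviour is
  normal diffusion with an effective coefficient `D_H τ*^{2H−1}`.
- **C — power-law tempered fBm.** Kernel multiplied by `(1+τ/τ*)^{−μ}`;
  hypergeometric factor `₂F₁(μ, 2H−1; 2H+1; −s/τ*)`. For μ > 2H−1
  ("strong tempering") the process crosses over to normal diffusion.
- **D — Ornstein–Uhlenbeck velocities.** Kernel `v_m² exp(−γτ)`;
  msd `2v_m²/γ²·(γt−1+e^{−γt})` interpolates between ballistic (`t ≪ 1/γ`)
  and normal diffusion (`t ≫ 1/γ`). The printed covariance is the
  `t′ ≤ t` branch; it is evaluated with `t′ → min(t,t′)`, which restores
  symmetry and reproduces the msd on the diagonal.

Nesting: B → A as τ* → ∞; C → A as μ → 0. At H = 1/2 the fBm kernel
degenerates to a delta function; within |H−1/2| < 1e−6 the code switches
to the Brownian closed forms (covariance `2D min(t,t′)`), which is also
the exact limit of the hypergeometric factors (`₁F₁(0,2;z) = ₂F₁(μ,0,2;z) = 1`).
For H < 1/2 the tempered covariances are used as printed; every covariance
is symmetrized and given a relative diagonal jitter of 1e−8·max(diag)
before Cholesky factorization, and a factorization failure is treated as
zero likelihood rather than an abort.

`β(t) = d ln msd / d ln t` is the diagnostic for tempering: flat at 2H for
pure fBm, decaying toward 1 for tempered models. It is always computed
from the **centered** msd — with the non-central form the `(v_d t)²` term
would push the drift axis toward β = 2 regardless of the noise — and
differentiated analytically for model A, else by central differences in
log-log space with multiplicative step 1.01.

## Numerical evaluation

Hypergeometric factors come from scipy (`hyp1f1`, `hyp2f1`); for very
large arguments (z > 1e4) or scipy overflow the ₁F₁ is replaced by its
leading asymptote `Γ(b)/Γ(b−a)·z^{−a}` (relative error O(1/z)). On a
covariance grid only the unique lags are evaluated (≈n values on a uniform
grid instead of n², a ~5× speedup for the tempered models), and the
remaining assembly is outer-sum algebra.

## Empirical statistics

Time averages over a single path discretize the sliding-window integrals
as means over all admissible start indices (the standard TAMSD estimator;
denominator = window count). Velocities are difference quotients
`v(t) = (x(t+Δ)−x(t))/Δ` with Δ an exact multiple of the sampling interval
(no interpolation); auto-/cross-correlations apply the same windows to the
velocity series. Ensemble curves are unweighted means over cells; for
unequal path lengths each lag averages only the cells that reach it and the
per-lag count is reported. The msd is deliberately the **non-central**
second moment (central moments plus time averages misbehave under drift);
model fitting never touches these curves — it uses raw positions.

## Likelihood and inference

A path's axis values on times t₁…t_M (the deterministic t = 0 origin
point excluded) are multivariate normal with mean `v_d·t` and the model
covariance. Log densities are computed via Cholesky solves (never an
explicit inverse); an ensemble is a product over paths, and all paths
sharing a grid reuse one factorization per parameter draw (one O(M³)
factorization + N O(M²) solves — the murine design shares a single grid).

Priors: uniform H ∈ [0.01, 0.99], v_d ∈ [−25, 25] μm/min, τ* ∈ [~0, 30]
min (clipped below at 1e−3 min because the kernel is undefined at τ* = 0),
μ ∈ [0, 4]; exponential D_H with mean 50 μm²/min^{2H}. Model-D priors are
a package choice (none are published): uniform γ ∈ [0.1, 60] 1/min —
covering the reported 1/γ ≈ 0.1–0.2 min time-scale — and exponential v_m²
with mean 100 μm²/min². The τ* upper bound is exposed as a `PriorSpec`
override because in-vivo tempering times (~25 min) sit near it.

Nested sampling is implemented in-package (`tempertrack.nested`; no
sampler library is assumed at run time): Skilling's classic scheme with
live points in the unit cube, inverse-CDF prior transforms, constrained
random-walk replacement (reflecting boundaries, step scale adapted toward
~50% acceptance, 25 steps per replacement), `ΔX` shrinkage `e^{−1/n_live}`
per iteration, termination when the maximum remaining evidence is below
1e−3 of the accumulated evidence, and final draining of the live set. The
ln Z uncertainty is the standard `√(H/n_live)` with H the information;
on a conjugate Gaussian toy the evidence lands within ~2 of these SDs of
the closed form. Posterior summaries are weighted moments of the dead
points; functionals (β(t), msd(t) bands) are averaged **per sample**, not
evaluated at the posterior mean. Model probabilities are a log-space
softmax of ln Z and are reported as point estimates (the evidence
uncertainty is available but not propagated into them).

Murine data are analyzed at dt = 10 s (every second acquired point);
`analysis/06_pixelation_bias.py` demonstrates why: with 1.5 μm pixel
quantization the acquisition-grid fit of H is biased low by many posterior
SDs, while the coarsened grid stays within ~2 SDs of truth. Zebrafish-style
variable-length paths are analyzed on their native grid.

## Synthetic ensembles

The generator draws exact Gaussian paths from the model covariance via
Cholesky (`x = Aη + mean`), one factor per distinct (spec, grid) pair.
Per-path random streams are spawned from a master seed, so enlarging an
ensemble appends paths without reshuffling earlier ones.

Two presets encode the experimental designs the models target: `murine`
(361 positions at dt = 5 s, T = 30 min, default 60 paths) and `zebrafish`
(dt = 17 s, default 108 paths, per-path lengths drawn from a geometric
distribution truncated to [2, 424] samples and calibrated to a ~17.1 min
mean observation time — the length distribution is a synthetic-only
convention; the real acquisition protocol does not specify one). The
generator emulates Gaussianity, stationary increments of the noise, axis
independence and a constant drift; it does **not** emulate cell–cell
interactions, heterogeneous per-cell parameters, localization noise
(except via the optional pixelation operator) or boundary effects — so a
green recovery test establishes self-consistency of the inference on the
stated model family, not correctness on arbitrary real tracks.

Reference condition parameters: the wildtype drift axis uses the published
point estimates (model A, H = 0.76, D_H = 39.01 μm²/min^{2H},
v_d = 7.4 μm/min). The impaired-condition parameter sets in
`tempertrack.conditions` are synthetic stand-ins read qualitatively from
reported trends (drift reduced to ~25% under receptor blockade, tempering
times of order 10–20 min, μ ≈ 1.5–3) because exact values are published
only graphically; they exist for demonstration ensembles and ordering
checks, not as data.

## First passage

The search-efficiency target is a 1-D level crossing on the gradient axis:
the first time y(t) ≥ a. Ensembles are simulated on a 0.5 min grid over
5 h (600 steps; one Cholesky, blockwise matrix products for 10⁴–10⁵
paths), and the crossing time is linearly interpolated between the
bracketing samples; paths that never cross are censored. Against the
closed-form inverse-Gaussian first-passage law of drift–diffusion
(H = 1/2) the simulated distribution agrees to KS distance < 0.02 at 10⁴
paths. Note the exact wildtype model leaves a Φ(−3.5) ≈ 2×10⁻⁴
probability of not reaching 200 μm within 5 h, so "100% arrival" holds at
integer-percent resolution, not literally.

## Scaling choices in the test suite

Production fits (60 paths × 181 points × 500 live points) take several
minutes per model. The automated tests run the same code at reduced scale
— 15–40 paths, grids coarsened to dt = 20–40 s, 100–150 live points,
3 model-ranking replicates — chosen so the whole suite completes in
roughly a quarter hour while leaving the statistical thresholds (3
posterior SDs for recovery; generating model top-ranked in every
replicate) unchanged. `analysis/03_fit_models.py` runs the full-scale
fits.

## Known limitations

- The nested sampler is a single-chain random-walk implementation; highly
  multimodal posteriors (not observed in this family) would need a more
  sophisticated replacement move.
- Evidence uncertainties are not propagated into model probabilities.
- Tempered covariances for H < 1/2 are used as printed and guarded only by
  the positive-definiteness check.
- The likelihood assumes noise-free localization; pixelation is available
  in the generator for robustness studies but not modelled in the
  likelihood.
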