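# tempertrack

Trajectory-based analysis of chemotactic cell migration with tempered
anomalous-diffusion models.

Neutrophils crawling up a chemoattractant gradient do not perform an
uncorrelated random walk: their velocity fluctuations stay correlated over
many minutes, and the strength and lifetime of that "memory" differ along
and across the gradient and depend on receptor signaling. This package fits
a family of Gaussian stochastic-motion models directly to the raw positions
of 2-D cell tracks, selects between the models by Bayesian evidence, and
converts the fitted models into search-efficiency predictions
(first-passage times to a target).

## Models

Each coordinate of a track is an overdamped Langevin process
`dx/dt = ζ(t)` (plus a constant drift `v_d` along the gradient axis, +y),
where the noise `ζ` has one of four stationary autocorrelation kernels:

| model | kernel ⟨v(t)v(t+τ)⟩ | behaviour |
|---|---|---|
| A | `D_H/Γ(2H−1) · τ^{2H−2}` | pure fractional Brownian motion (fBm); msd ∝ t^{2H} |
| B | fBm kernel × `exp(−τ/τ*)` | exponential tempering: memory lost beyond τ* |
| C | fBm kernel × `(1+τ/τ*)^{−μ}` | power-law tempering; normal diffusion at long t when μ > 2H−1 |
| D | `v_m² · exp(−γτ)` | Ornstein–Uhlenbeck (persistent random walk) |

Integrating a kernel twice gives the closed-form position covariance
(hypergeometric ₁F₁/₂F₁ forms for B/C). Because the processes are Gaussian,
the exact likelihood of a path is a multivariate normal with mean `v_d·t`
and that covariance — no msd curve fitting anywhere. Nested sampling
returns posterior parameter summaries and the evidence `Z` per model; model
probabilities are `P(M) = Z_M / Σ Z`. First-passage times are read off
ensembles simulated from the fitted covariance by Cholesky factorization
(`x = Aη`, `C = AAᵀ`).

## Worked example

```sh
tempertrack simulate --preset murine --condition WT --n-paths 15 --seed 1 --out tracks.csv
tempertrack fit tracks.csv --model A --subsample 8 --n-live 150 --seed 2 --out fit_A.json
```

The fit prints (abridged):

```
"model": "A",
"log_z": -2007.06,
"params": {
  "H":   {"mean": 0.740, "sd": 0.025},
  "D_H": {"mean": 32.23, "sd": 3.94},
  "v_d": {"mean": 7.90,  "sd": 0.73}
}
```

i.e. from 15 synthetic wildtype tracks (generated at H = 0.76,
D_H = 39.01 μm²/min^{2H}, v_d = 7.4 μm/min, analyzed on a coarsened grid)
the posterior recovers a superdiffusive Hurst exponent H ≈ 0.74 ± 0.02 and
a drift of ≈ 7.9 ± 0.7 μm/min up the gradient. Fitting model B on the same
tracks and comparing evidences (`analysis/04_model_comparison.py`) gives
P(A) ≈ 82.5% vs P(B) ≈ 17.5% — the data prefer untempered fBm.

The numbered drivers under `analysis/` run the full story — simulate the
four murine conditions, compute moment/correlation statistics, fit and
compare all models, and predict arrival percentages at a 200 μm target
(wildtype: 100% within 5 h, median ≈ 27 min; impaired conditions arrive in
a trickle):

```sh
python analysis/01_simulate_tracks.py --seed 1
python analysis/02_trajectory_statistics.py
python analysis/03_fit_models.py --condition WT --models A,B,C,D
python analysis/04_model_comparison.py --condition WT
python analysis/05_first_passage.py
python analysis/06_pixelation_bias.py
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the pipeline end to end from scratch: it simulates a
wildtype murine-design ensemble, runs the trajectory statistics, fits and
compares the fBm and tempered models by nested sampling, and simulates the
first-passage/arrival predictions, writing the target JSON to `--out` (all
randomness derives from `--seed`).

## Layout

- `src/tempertrack/` — library: `models` (kernels/covariances/msd/β),
  `simulate` (covariance-Cholesky path generation, experimental presets),
  `stats` (time- and ensemble-averaged moments and velocity correlations),
  `nested` + `inference` (likelihoods, priors, nested sampling, model
  probabilities), `fpt` (first-passage), `io` + `cli` (formats, pipeline).
- `analysis/` — numbered narrative drivers writing tables under `results/`.
- `docs/methods.md` — model details, numerical choices, limitations.
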