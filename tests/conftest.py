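import numpy as np
import pytest

from tempertrack.models import Model, ModelSpec, ParamVector
from tempertrack.simulate import Trajectory, make_design, simulate_paths

WT_Y = ModelSpec(Model.A, ParamVector(H=0.76, D_H=39.01, v_d=7.4), axis="y")
WT_X = ModelSpec(Model.A, ParamVector(H=0.76, D_H=39.01, v_d=0.0), axis="x")


@pytest.fixture(scope="session")
def wt_y_spec() -> ModelSpec:
    """Published wildtype drift-axis parameters (model A)."""
    return WT_Y


@pytest.fixture(scope="session")
def wt_x_spec() -> ModelSpec:
    return WT_X


@pytest.fixture(scope="session")
def small_murine_ensemble() -> list[Trajectory]:
    """20 murine-design wildtype paths, coarsened to dt = 40 s."""
    design = make_design("murine", WT_X, WT_Y, n_paths=20, seed=1234)
    paths = simulate_paths(design)
    return [Trajectory(p.cell_id, p.times[::8], p.x[::8], p.y[::8]) for p in paths]


@pytest.fixture()
def tiny_path() -> Trajectory:
    """Hand-sized path for brute-force oracle comparisons."""
    rng = np.random.default_rng(7)
    t = np.arange(8.0)
    return Trajectory("tiny", t, rng.normal(size=8).cumsum(), rng.normal(size=8).cumsum())


def example_specs() -> dict[str, ModelSpec]:
    """One representative valid spec per model."""
    return {
        "A": ModelSpec(Model.A, ParamVector(H=0.76, D_H=39.01, v_d=0.0)),
        "B": ModelSpec(Model.B, ParamVector(H=0.85, D_H=60.0, v_d=0.0, tau_star=4.0)),
        "C": ModelSpec(Model.C, ParamVector(H=0.85, D_H=55.0, v_d=0.0, tau_star=3.0, mu=2.5)),
        "D": ModelSpec(Model.D, ParamVector(gamma=2.0, v_m2=9.0, v_d=0.0)),
    }
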