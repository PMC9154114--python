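"""Reference parameter sets for the experimental conditions.

``WT_MURINE_Y`` carries the published point estimates for wildtype
murine neutrophils along the chemotactic gradient (model A: H = 0.76,
D_H = 39.01 μm²/min^{2H}, v_d = 7.4 μm/min).  The impaired-condition
sets are SYNTHETIC stand-ins: the corresponding point estimates are
published only graphically, so these values are read qualitatively
from the reported trends (drift reduced to ~25% by CXCR2 blockade,
tempering times of order 10–20 min, strong power-law tempering
μ ≈ 1.5–3) and are meant for demonstration ensembles, not as data.
"""

from __future__ import annotations

from .models import Model, ModelSpec, ParamVector

__all__ = ["WT_MURINE_Y", "WT_MURINE_X", "MURINE_CONDITIONS_Y"]

#: published wildtype estimates, drift axis (model A)
WT_MURINE_Y = ModelSpec(
    Model.A, ParamVector(H=0.76, D_H=39.01, v_d=7.4), axis="y"
)

#: wildtype perpendicular axis: same small-time dynamics, no drift,
#: exponentially tempered (synthetic tempering time)
WT_MURINE_X = ModelSpec(
    Model.B, ParamVector(H=0.76, D_H=39.01, v_d=0.0, tau_star=5.0), axis="x"
)

#: drift-axis stand-ins per condition for demonstration simulations;
#: all but "WT" are synthetic approximations of graphical estimates
MURINE_CONDITIONS_Y: dict[str, ModelSpec] = {
    "WT": WT_MURINE_Y,
    "WT+SB": ModelSpec(
        Model.C, ParamVector(H=0.85, D_H=55.0, v_d=1.85, tau_star=3.0, mu=2.5), axis="y"
    ),
    "TRPC6KO": ModelSpec(
        Model.B, ParamVector(H=0.85, D_H=60.0, v_d=1.9, tau_star=20.0), axis="y"
    ),
    "TRPC6KO+SB": ModelSpec(
        Model.C, ParamVector(H=0.85, D_H=45.0, v_d=1.2, tau_star=3.0, mu=2.5), axis="y"
    ),
}
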