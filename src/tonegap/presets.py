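"""The three canonical model variants, parameterized by knee placement.

Every variant follows the same convention: a tone of level ``I_T = 1`` is
the activation threshold in the absence of noise.

* ``model1`` — hysteresis (Region IIIa): knees at I_T = 0.2 and 1.0;
  sustained and inhibitory pathways only.  Noise raises the activation
  threshold (masking) and can drag the deactivation threshold below zero
  (continuity through the gap).
* ``model2`` — bistability (Region IV): knees at I_T = −2 and 2; transient
  pathway only.  Onset kicks activate, offset kicks deactivate; noise masks
  by blunting the acoustic edges.  γ_on = γ_off calibrated so that the
  tone threshold is 1, which also makes masking and continuity thresholds
  coincide.
* ``model3`` — combined (Region IIIb): knees at I_T = 0.2 and 6; all
  pathways.  Activation needs sustained *and* transient input together.

Parameters are stored at full precision (exact knee placement and exact γ
calibration); the one-decimal roundings the variants are conventionally
quoted at are available as :data:`PRINTED` metadata.
"""

from __future__ import annotations

from functools import lru_cache

from .equilibria import solve_knee_placement
from .model import InputParams, ModelConfig, Pathways, PopulationParams

__all__ = ["model1", "model2", "model3", "get_preset", "PRINTED", "KNEE_TARGETS"]

#: knee-placement targets (IT_L, IT_R) that define each variant
KNEE_TARGETS = {"model1": (0.2, 1.0), "model2": (-2.0, 2.0), "model3": (0.2, 6.0)}

#: conventional one-decimal roundings of the preset parameters (metadata only)
PRINTED = {
    "model1": {"a_E": 5.9, "m": 3.6, "a_I": 1.124, "alpha": 0.168},
    "model2": {"a_E": 10.5, "m": 5.2, "beta": 2 / 3, "gamma_on": 5.2, "gamma_off": 5.2},
    "model3": {
        "a_E": 12.7, "m": 9.5, "a_I": 7.0, "alpha": 0.5, "beta": 0.05,
        "gamma_on": 9.6, "gamma_off": 0.88,
    },
}


def _knee_placed_population(variant: str, tau: float) -> PopulationParams:
    a_E, m = solve_knee_placement(*KNEE_TARGETS[variant])
    return PopulationParams(a_E=a_E, m=m, tau=tau)


@lru_cache(maxsize=None)
def _build(variant: str, tau: float) -> ModelConfig:
    # local import: phase_plane depends on equilibria, not on presets
    from .phase_plane import calibrate_gamma_on

    pop = _knee_placed_population(variant, tau)
    if variant == "model1":
        return ModelConfig(
            population=pop,
            inputs=InputParams(alpha=0.168, a_I=1.124),
            pathways=Pathways(sustained=True, transient=False, inhib=True),
            variant="model1",
        )
    if variant == "model2":
        cfg = ModelConfig(
            population=pop,
            inputs=InputParams(beta=2 / 3),
            pathways=Pathways(sustained=False, transient=True, inhib=False),
            variant="model2",
        )
        g = calibrate_gamma_on(cfg)
        return cfg.with_(inputs=InputParams(beta=2 / 3, gamma_on=g, gamma_off=g))
    if variant == "model3":
        cfg = ModelConfig(
            population=pop,
            inputs=InputParams(alpha=0.5, beta=0.05, a_I=7.0, gamma_off=0.88),
            pathways=Pathways(sustained=True, transient=True, inhib=True),
            variant="model3",
        )
        g = calibrate_gamma_on(cfg)
        return cfg.with_(
            inputs=InputParams(alpha=0.5, beta=0.05, a_I=7.0, gamma_on=g, gamma_off=0.88)
        )
    raise ValueError(f"unknown preset {variant!r}")


def model1(tau: float = 0.01) -> ModelConfig:
    """Hysteresis variant (sustained + inhibitory inputs)."""
    return _build("model1", tau)


def model2(tau: float = 0.01) -> ModelConfig:
    """Bistable variant (transient inputs only)."""
    return _build("model2", tau)


def model3(tau: float = 0.01) -> ModelConfig:
    """Combined variant (all input pathways)."""
    return _build("model3", tau)


def get_preset(name: str, tau: float = 0.01) -> ModelConfig:
    if name not in KNEE_TARGETS:
        raise ValueError(f"unknown preset {name!r}; expected one of {sorted(KNEE_TARGETS)}")
    return _build(name, tau)
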