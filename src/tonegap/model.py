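"""Core firing-rate model: parameters, nonlinearity, input components, dynamics.

The model describes the activity ``x(t) ∈ (0, 1)`` of a neural population
tuned to a tone frequency, governed by

    τ x' = −x + f(a_E x + I(t)),      f(u) = 1 / (1 + exp(−(u − m)/k)),

where ``a_E`` is the recurrent-excitation gain and ``I(t)`` is assembled from
up to four sound-driven components:

* a sustained excitatory drive ``I_T·1_tone + α·I_N·1_noise``,
* an excitatory onset transient ``γ_on · s_on`` and an inhibitory offset
  transient ``−γ_off · s_off``, where each transient variable decays as
  ``τ s' = −s`` and is reset at the corresponding acoustic edge,
* a noise-driven inhibition ``a_I·I_N·(1 − x)·1_noise`` with a mutual-
  inhibition factor ``(1 − x)``.

Tones and noise are idealized drive levels (unitless ``I_T``, ``I_N``), not
audio waveforms.  Transient variables carry the raw rectified amplitude
``[I_T − β I_N]_+`` (or ``I_T`` when no noise coincides with the edge); the γ
scaling is applied exactly once, when the drive is assembled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PopulationParams",
    "InputParams",
    "Pathways",
    "ModelConfig",
    "DriveState",
    "sigmoid",
    "sigmoid_prime",
    "rectify",
    "transient_amplitude",
    "sustained_input",
    "inhib_input",
    "total_drive",
    "rhs",
]


@dataclass(frozen=True)
class PopulationParams:
    """Population-level parameters of the firing-rate equation.

    Attributes
    ----------
    a_E : float
        Recurrent excitation strength (unitless, > 0).  Values above 4 give
        an S-shaped equilibrium curve with two saddle-node knees.
    m : float
        Half-maximum of the sigmoid nonlinearity (unitless).
    k : float
        Sigmoid slope scale.  Fixed at 1 in all preset
        configurations; changing it rescales every unitless level.
    tau : float
        Time constant of the rate (and transient) dynamics, in seconds.
    """

    a_E: float
    m: float
    k: float = 1.0
    tau: float = 0.01

    def __post_init__(self) -> None:
        if self.a_E <= 0:
            raise ValueError(f"a_E must be positive, got {self.a_E}")
        if self.k <= 0:
            raise ValueError(f"k must be positive, got {self.k}")
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")


@dataclass(frozen=True)
class InputParams:
    """Weights of the four input pathways and the level caps.

    ``alpha`` scales the noise contribution to the sustained excitatory
    drive, ``beta`` the noise suppression of transient amplitudes, ``a_I``
    the noise-driven inhibition, and ``gamma_on``/``gamma_off`` the onset and
    offset transients.  ``I_T_max``/``I_N_max`` cap the admissible tone and
    noise levels.
    """

    alpha: float = 0.0
    beta: float = 0.0
    a_I: float = 0.0
    gamma_on: float = 0.0
    gamma_off: float = 0.0
    I_T_max: float = 5.0
    I_N_max: float = 10.0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "a_I", "gamma_on", "gamma_off"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.I_T_max <= 1:
            raise ValueError("I_T_max must exceed 1 (the activation threshold)")
        if self.I_N_max <= 0:
            raise ValueError("I_N_max must be positive")


@dataclass(frozen=True)
class Pathways:
    """Which input components enter the drive."""

    sustained: bool = True
    transient: bool = True
    inhib: bool = True


@dataclass(frozen=True)
class ModelConfig:
    """Full parameterization of one model variant."""

    population: PopulationParams
    inputs: InputParams
    pathways: Pathways
    variant: str = "custom"

    def with_(self, **kwargs) -> "ModelConfig":
        """Return a copy with replaced top-level fields."""
        return replace(self, **kwargs)


@dataclass
class DriveState:
    """Instantaneous dynamical state: rate plus the two transient variables.

    ``s_on`` and ``s_off`` are nonnegative; the offset transient enters the
    drive with a negative sign.
    """

    x: float
    s_on: float = 0.0
    s_off: float = 0.0


def sigmoid(u, pop: PopulationParams):
    """Sigmoidal input-output function f(u); strictly increasing onto (0, 1)."""
    return 1.0 / (1.0 + np.exp(-(np.asarray(u, dtype=float) - pop.m) / pop.k))


def sigmoid_prime(u, pop: PopulationParams):
    """Derivative f'(u) = f(u)(1 − f(u))/k."""
    f = sigmoid(u, pop)
    return f * (1.0 - f) / pop.k


def rectify(u):
    """Half-wave rectifier [u]_+ = max(0, u)."""
    return np.maximum(0.0, u)


def transient_amplitude(
    I_T: float, I_N: float, noise_coincident: bool, params: InputParams
) -> float:
    """Initial magnitude of a transient variable at a tone edge.

    Returns ``I_T`` when no noise coincides with the edge and the rectified
    ``[I_T − β I_N]_+`` otherwise: noise obscures the acoustic edge.  The γ
    scaling is *not* applied here — it enters once, in :func:`total_drive`.
    """
    if I_T < 0 or I_N < 0:
        raise ValueError("levels must be nonnegative")
    if I_T > params.I_T_max or I_N > params.I_N_max:
        raise ValueError("levels exceed the configured caps")
    if not noise_coincident:
        return float(I_T)
    return float(rectify(I_T - params.beta * I_N))


def sustained_input(
    tone_on: bool, noise_on: bool, I_T: float, I_N: float, params: InputParams
) -> float:
    """Piecewise-constant excitatory drive: I_T while the tone is on plus
    the partial noise contribution α·I_N while noise is on."""
    return float(I_T * bool(tone_on) + params.alpha * I_N * bool(noise_on))


def inhib_input(
    x: float, noise_on: bool, I_N: float, params: InputParams
) -> float:
    """Noise-driven inhibition a_I·I_N·(1 − x), gated by the noise indicator.

    The (1 − x) factor implements mutual inhibition between the tone-driven
    and noise-driven populations: a fully active tone population silences
    its inhibitor.
    """
    if not noise_on:
        return 0.0
    return float(params.a_I * I_N * (1.0 - x))


def total_drive(
    state: DriveState,
    tone_on: bool,
    noise_on: bool,
    I_T: float,
    I_N: float,
    config: ModelConfig,
) -> float:
    """Instantaneous argument of the sigmoid: recurrent plus enabled inputs."""
    p = config.inputs
    u = config.population.a_E * state.x
    if config.pathways.sustained:
        u += sustained_input(tone_on, noise_on, I_T, I_N, p)
    if config.pathways.transient:
        u += p.gamma_on * state.s_on - p.gamma_off * state.s_off
    if config.pathways.inhib:
        u -= inhib_input(state.x, noise_on, I_N, p)
    return float(u)


def rhs(
    state: DriveState,
    tone_on: bool,
    noise_on: bool,
    I_T: float,
    I_N: float,
    config: ModelConfig,
) -> tuple[float, float, float]:
    """Time derivatives (x', s_on', s_off') of the smooth flow between events."""
    tau = config.population.tau
    u = total_drive(state, tone_on, noise_on, I_T, I_N, config)
    dx = (-state.x + float(sigmoid(u, config.population))) / tau
    return dx, -state.s_on / tau, -state.s_off / tau
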