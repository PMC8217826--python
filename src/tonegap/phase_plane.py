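"""Phase-plane analysis of the (x, s) system around the saddle.

Between acoustic edges the model is the planar system

    τ x' = −x + f(a_E x + I_const + γ s),     τ s' = −s,

whose basins of inactive and active attraction are divided by the stable
manifold of the saddle.  Because rate and transient share the time constant
τ, the stable eigenvector yields the exact linear approximation

    S(x) = (a_E + a_I I_N) / γ · (x_S − x)

(the a_I term present only when noise-driven inhibition is active).  An
onset kick activates the population iff it lifts s above S(x) at the current
rate; an offset kick deactivates iff it pushes s below S(x).  γ_on is
calibrated so that S(x_I) = 1, pinning the tone threshold at I_T = 1.

The numerically integrated stable manifold (reversed-time integration from
the saddle) is provided as an oracle for the linear approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .equilibria import find_equilibria
from .model import ModelConfig, DriveState, sigmoid, sigmoid_prime, total_drive

__all__ = [
    "MonostableError",
    "LinearSeparatrix",
    "SeparatrixCurve",
    "jacobian",
    "linear_separatrix",
    "numeric_separatrix",
    "calibrate_gamma_on",
    "crosses_separatrix",
    "saddle_and_neighbors",
]


class MonostableError(ValueError):
    """No saddle exists for the given constant inputs (monostable regime)."""


@dataclass(frozen=True)
class LinearSeparatrix:
    """S(x) = slope_scale · (x_S − x); positive s side is the onset side."""

    x_S: float
    slope_scale: float
    I_T: float
    I_N: float
    gamma: float

    def __call__(self, x):
        return self.slope_scale * (self.x_S - np.asarray(x, dtype=float))


@dataclass
class SeparatrixCurve:
    """Sampled stable manifold of the saddle, ordered by x."""

    x: np.ndarray
    s: np.ndarray

    def __call__(self, x):
        return np.interp(np.asarray(x, dtype=float), self.x, self.s)


def _drive(config, x, s, gamma, tone_on, noise_on, I_T, I_N):
    """Drive with a single transient variable s scaled by gamma."""
    pop, inp, path = config.population, config.inputs, config.pathways
    u = pop.a_E * x + gamma * s
    if path.sustained:
        u += I_T * bool(tone_on) + inp.alpha * I_N * bool(noise_on)
    if path.inhib and noise_on:
        u -= inp.a_I * I_N * (1.0 - x)
    return u


def jacobian(
    config: ModelConfig,
    x: float,
    s: float,
    gamma: float,
    tone_on: bool = False,
    noise_on: bool = False,
    I_T: float = 0.0,
    I_N: float = 0.0,
) -> np.ndarray:
    """Jacobian of the planar (x, s) flow at the given state."""
    pop, inp, path = config.population, config.inputs, config.pathways
    tau = pop.tau
    u = _drive(config, x, s, gamma, tone_on, noise_on, I_T, I_N)
    fp = float(sigmoid_prime(u, pop))
    gain = pop.a_E + (inp.a_I * I_N if (path.inhib and noise_on) else 0.0)
    return np.array(
        [[(-1.0 + gain * fp) / tau, gamma * fp / tau], [0.0, -1.0 / tau]]
    )


def saddle_and_neighbors(
    config: ModelConfig,
    tone_on: bool = False,
    noise_on: bool = False,
    I_T: float = 0.0,
    I_N: float = 0.0,
):
    """(x_I, x_S, x_A) of the constant-input system, or raise MonostableError."""
    fps = find_equilibria(config, tone_on, noise_on, I_T, I_N)
    if len(fps) != 3:
        raise MonostableError(
            f"system has {len(fps)} fixed point(s) at I_T={I_T}, I_N={I_N}: no saddle"
        )
    return fps[0].x, fps[1].x, fps[2].x


def linear_separatrix(
    config: ModelConfig,
    I_T: float = 0.0,
    I_N: float = 0.0,
    gamma: float | None = None,
    tone_on: bool = False,
    noise_on: bool = False,
) -> LinearSeparatrix:
    """Linear separatrix through the saddle of the constant-input system.

    ``gamma`` defaults to the configuration's γ_on.  The slope equals the
    stable-eigenvector construction exactly because rate and transient share
    the same time constant.
    """
    if gamma is None:
        gamma = config.inputs.gamma_on
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    _, x_S, _ = saddle_and_neighbors(config, tone_on, noise_on, I_T, I_N)
    inp, path = config.inputs, config.pathways
    gain = config.population.a_E + (
        inp.a_I * I_N if (path.inhib and noise_on) else 0.0
    )
    return LinearSeparatrix(
        x_S=x_S, slope_scale=gain / gamma, I_T=I_T, I_N=I_N, gamma=gamma
    )


def numeric_separatrix(
    config: ModelConfig,
    I_T: float = 0.0,
    I_N: float = 0.0,
    gamma: float | None = None,
    tone_on: bool = False,
    noise_on: bool = False,
    eps: float = 1e-6,
    x_bounds: tuple[float, float] = (0.001, 0.999),
) -> SeparatrixCurve:
    """Stable manifold of the saddle by reversed-time integration.

    Both branches are launched a distance ``eps`` along the stable
    eigenvector and integrated backward until x leaves ``x_bounds``.
    """
    if gamma is None:
        gamma = config.inputs.gamma_on
    lin = linear_separatrix(config, I_T, I_N, gamma, tone_on, noise_on)
    x_S = lin.x_S
    tau = config.population.tau
    pop = config.population

    v = np.array([1.0, -lin.slope_scale])
    v /= np.linalg.norm(v)

    def back_rhs(t, y):
        x, s = y
        u = _drive(config, x, s, gamma, tone_on, noise_on, I_T, I_N)
        dx = (-x + float(sigmoid(u, pop))) / tau
        return [-dx, s / tau]

    s_max = 10.0 * lin.slope_scale + 10.0

    def leave(t, y):
        x, s = y
        return min(x - x_bounds[0], x_bounds[1] - x, s_max - abs(s))

    leave.terminal = True
    xs, ss = [x_S], [0.0]
    for sign in (+1.0, -1.0):
        y0 = np.array([x_S, 0.0]) + sign * eps * v
        sol = solve_ivp(
            back_rhs, (0.0, 200.0 * tau), y0, events=leave,
            rtol=1e-9, atol=1e-11, max_step=tau / 4, dense_output=False,
        )
        xs.extend(sol.y[0])
        ss.extend(sol.y[1])
    order = np.argsort(xs)
    return SeparatrixCurve(x=np.asarray(xs)[order], s=np.asarray(ss)[order])


def calibrate_gamma_on(config: ModelConfig) -> float:
    """Onset scaling that places the tone-only activation threshold at I_T = 1.

    For a configuration bistable at rest the separatrix above the inactive
    state must sit at s = 1, giving γ_on = a_E (x_S − x_I).  When rest is
    monostable but a sustained tone of I_T = 1 creates the saddle (combined
    variant), the calibration uses γ_on = a_E [x_S(1, 0) − x_I(0, 0)].
    """
    a_E = config.population.a_E
    rest = find_equilibria(config)
    try:
        x_I, x_S, _ = saddle_and_neighbors(config)
        return float(a_E * (x_S - x_I))
    except MonostableError:
        pass
    if not config.pathways.sustained:
        raise MonostableError(
            "rest is monostable and no sustained pathway exists: cannot calibrate"
        )
    x_I0 = rest[0].x
    _, x_S1, _ = saddle_and_neighbors(config, tone_on=True, I_T=1.0)
    return float(a_E * (x_S1 - x_I0))


def crosses_separatrix(
    x0: float,
    s0: float,
    separatrix: LinearSeparatrix,
    direction: str = "up",
    atol: float = 1e-9,
) -> str:
    """Does the kick (x0, s0) cross the separatrix?

    "up": activation (s above S(x)); "down": deactivation (s below S(x)).
    Returns "crosses", "stays", or "at-threshold".
    """
    gap = s0 - float(separatrix(x0))
    if abs(gap) <= atol:
        return "at-threshold"
    if direction == "up":
        return "crosses" if gap > 0 else "stays"
    if direction == "down":
        return "crosses" if gap < 0 else "stays"
    raise ValueError("direction must be 'up' or 'down'")
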