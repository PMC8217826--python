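"""Equilibrium structure of the firing-rate model.

The tone-only equilibrium relation inverts the fixed-point condition
``x = f(a_E x + I_T)`` into the closed form

    I_T(x) = m − ln(1/x − 1) − a_E x,

and with noise-driven terms (sustained fraction α, inhibition a_I)

    I_T(x, I_N) = m − ln(1/x − 1) − a_E x + a_I I_N (1 − x) − α I_N.

The S-shaped curve's fold points ("knees") are saddle-node bifurcations at

    x_{L,R}(I_N) = (1 ± sqrt(1 − 4/(a_E + a_I I_N))) / 2,

so knees exist iff ``a_E + a_I I_N ≥ 4``.  The right knee's tone level is the
activation threshold, the left knee's the deactivation threshold; their
mismatch is the hysteresis that lets noise sustain activity through a gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model import ModelConfig, DriveState, InputParams, PopulationParams, sigmoid, sigmoid_prime, total_drive

__all__ = [
    "NoKneesError",
    "KneePair",
    "FixedPoint",
    "equilibrium_IT",
    "knee_x",
    "knee_IT",
    "classify_region",
    "solve_knee_placement",
    "find_equilibria",
    "equilibrium_branch",
]

# Root-search abscissae: uniform in logit space so that equilibria pinned
# arbitrarily close to 0 or 1 (strong inhibition pushes x_I below 1e-20)
# are still bracketed, while mid-range spacing stays ~4e-3.
_LOGIT_GRID = 1.0 / (1.0 + np.exp(-np.linspace(-80.0, 80.0, 6001)))

#: derivative magnitudes below this are reported as marginal stability
MARGINAL_TOL = 1e-10


class NoKneesError(ValueError):
    """The equilibrium curve is not S-shaped (a_E + a_I·I_N < 4): no knees."""


@dataclass(frozen=True)
class KneePair:
    """Firing rates and tone levels at the two saddle-node knees.

    ``x_L + x_R = 1`` exactly; ``IT_L < IT_R`` whenever the knees are
    distinct (hysteresis ordering).
    """

    x_L: float
    x_R: float
    IT_L: float
    IT_R: float


@dataclass(frozen=True)
class FixedPoint:
    x: float
    stability: str  # "stable" | "unstable" | "marginal"


def equilibrium_IT(
    x: float | np.ndarray,
    I_N: float,
    pop: PopulationParams,
    inputs: InputParams,
    *,
    include_alpha: bool = True,
    include_inhib: bool = True,
) -> float | np.ndarray:
    """Tone level at which ``x`` is an equilibrium, given gap/overlap noise I_N.

    The α and a_I terms can be switched off to match configurations whose
    sustained or inhibitory pathway is disabled.
    """
    x = np.asarray(x, dtype=float)
    if np.any((x <= 0) | (x >= 1)):
        raise ValueError("x must lie strictly inside (0, 1)")
    out = pop.m * pop.k - pop.k * np.log(1.0 / x - 1.0) - pop.a_E * x
    if include_inhib:
        out = out + inputs.a_I * I_N * (1.0 - x)
    if include_alpha:
        out = out - inputs.alpha * I_N
    return float(out) if out.ndim == 0 else out


def knee_x(a_E: float, a_I: float = 0.0, I_N: float = 0.0) -> tuple[float, float]:
    """Firing rates (x_L, x_R) at the knees; degenerate (0.5, 0.5) at the fold.

    Raises :class:`NoKneesError` when ``a_E + a_I·I_N < 4``.
    """
    gain = a_E + a_I * I_N
    if gain < 4.0:
        raise NoKneesError(
            f"effective gain a_E + a_I*I_N = {gain:.6g} < 4: equilibrium curve not S-shaped"
        )
    d = np.sqrt(1.0 - 4.0 / gain)
    return 0.5 * (1.0 + d), 0.5 * (1.0 - d)


def knee_IT(pop: PopulationParams, inputs: InputParams, I_N: float = 0.0, **kw) -> KneePair:
    """Tone levels at the knees: IT_R is the activation threshold, IT_L the
    deactivation threshold."""
    x_L, x_R = knee_x(pop.a_E, inputs.a_I if kw.get("include_inhib", True) else 0.0, I_N)
    IT_L = equilibrium_IT(x_L, I_N, pop, inputs, **kw)
    IT_R = equilibrium_IT(x_R, I_N, pop, inputs, **kw)
    return KneePair(x_L=x_L, x_R=x_R, IT_L=IT_L, IT_R=IT_R)


def classify_region(a_E: float, m: float, I_T_max: float = 5.0) -> str:
    """Classify (a_E, m) by knee positions of the tone-only equilibrium curve.

    I: no knees (a_E < 4).  II: both knees above I_T_max.  IIIa: both knees
    inside (0, I_T_max).  IIIb: left knee inside, right knee above I_T_max.
    IV: left knee negative, right knee positive (bistable at rest).  V: both
    knees negative (active without input).  Boundary cases take the first
    matching label in this order.
    """
    if a_E <= 0:
        raise ValueError("a_E must be positive")
    pop = PopulationParams(a_E=a_E, m=m)
    try:
        knees = knee_IT(pop, InputParams())
    except NoKneesError:
        return "I"
    IT_L, IT_R = knees.IT_L, knees.IT_R
    if IT_L >= I_T_max and IT_R >= I_T_max:
        return "II"
    if 0 <= IT_L and IT_R <= I_T_max:
        return "IIIa"
    if 0 <= IT_L < I_T_max < IT_R:
        return "IIIb"
    if IT_L < 0 < IT_R:
        return "IV"
    return "V"


def solve_knee_placement(IT_L_target: float, IT_R_target: float) -> tuple[float, float]:
    """Solve for (a_E, m) that place the tone-only knees at the given levels.

    Uses the exact reduction of the 2×2 system: with d = sqrt(1 − 4/a_E)
    and x_{L,R} = (1 ± d)/2,

        IT_R − IT_L = a_E d − 2 ln(x_L / x_R),

    which is strictly increasing in a_E on (4, ∞), so a_E follows from 1-D
    bracketed root finding; then m = (IT_L + IT_R + a_E)/2.
    """
    if not IT_L_target < IT_R_target:
        raise ValueError("left knee must be below right knee")
    span = IT_R_target - IT_L_target

    def gap(a_E: float) -> float:
        d = np.sqrt(1.0 - 4.0 / a_E)
        x_L, x_R = 0.5 * (1 + d), 0.5 * (1 - d)
        return a_E * d - 2.0 * np.log(x_L / x_R) - span

    hi = 8.0
    while gap(hi) < 0:
        hi *= 2.0
        if hi > 1e6:  # pragma: no cover - unreachable for finite targets
            raise RuntimeError("no bracket for a_E")
    a_E = brentq(gap, 4.0 + 1e-12, hi, xtol=1e-12, rtol=8.9e-16)
    m = 0.5 * (IT_L_target + IT_R_target + a_E)
    return float(a_E), float(m)


def _drift(config: ModelConfig, x, tone_on, noise_on, I_T, I_N):
    """Vectorized −x + f(drive(x)) for constant inputs with transients at 0."""
    x = np.asarray(x, dtype=float)
    pop, inp, path = config.population, config.inputs, config.pathways
    u = pop.a_E * x
    if path.sustained:
        u = u + I_T * bool(tone_on) + inp.alpha * I_N * bool(noise_on)
    if path.inhib and noise_on:
        u = u - inp.a_I * I_N * (1.0 - x)
    return -x + sigmoid(u, pop)


def find_equilibria(
    config: ModelConfig,
    tone_on: bool = False,
    noise_on: bool = False,
    I_T: float = 0.0,
    I_N: float = 0.0,
) -> list[FixedPoint]:
    """Fixed points of the constant-input system (transients at zero).

    Sign-change bracketing on a logit-spaced grid followed by Brent
    polishing; stability from the sign of d/dx[−x + f(drive(x))].  Returns
    1–3 points ordered by x.
    """
    g = lambda x: float(_drift(config, x, tone_on, noise_on, I_T, I_N))
    vals = np.asarray(_drift(config, _LOGIT_GRID, tone_on, noise_on, I_T, I_N))
    roots: list[float] = []
    for i in range(len(_LOGIT_GRID) - 1):
        if vals[i] == 0.0:
            roots.append(float(_LOGIT_GRID[i]))
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(g, _LOGIT_GRID[i], _LOGIT_GRID[i + 1], xtol=2e-16))
    if vals[-1] == 0.0:
        roots.append(float(_LOGIT_GRID[-1]))

    pop, inp, path = config.population, config.inputs, config.pathways
    out = []
    for x in roots:
        state = DriveState(x=x)
        u = total_drive(state, tone_on, noise_on, I_T, I_N, config)
        gain = pop.a_E + (inp.a_I * I_N if (path.inhib and noise_on) else 0.0)
        slope = -1.0 + gain * float(sigmoid_prime(u, pop))
        if abs(slope) < MARGINAL_TOL:
            stability = "marginal"
        else:
            stability = "stable" if slope < 0 else "unstable"
        out.append(FixedPoint(x=x, stability=stability))
    return out


def equilibrium_branch(
    config: ModelConfig,
    I_N: float = 0.0,
    n: int = 801,
    x_lo: float = 1e-4,
    x_hi: float = 1 - 1e-4,
) -> pd.DataFrame:
    """Sample the equilibrium curve I_T(x, I_N) for export/plotting.

    Columns: x, I_T, stability.  Stability along the curve follows the knee
    structure: the middle branch (between the knees' firing rates) is
    unstable, the outer branches stable.
    """
    xs = np.linspace(x_lo, x_hi, n)
    path = config.pathways
    its = equilibrium_IT(
        xs, I_N, config.population, config.inputs,
        include_alpha=path.sustained, include_inhib=path.inhib,
    )
    try:
        x_L, x_R = knee_x(
            config.population.a_E, config.inputs.a_I if path.inhib else 0.0, I_N
        )
        stab = np.where((xs > x_R) & (xs < x_L), "unstable", "stable")
    except NoKneesError:
        stab = np.full(xs.shape, "stable", dtype=object)
    return pd.DataFrame({"x": xs, "I_T": its, "stability": stab})
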