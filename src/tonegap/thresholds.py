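"""Analytic masking and continuity threshold curves for all model variants.

Both thresholds are reported as the minimum noise level, as a function of
tone level ``I_T ∈ (1, I_T_max]``:

* masking threshold M(I_T): smallest noise that prevents a simultaneous
  tone from activating the population;
* continuity threshold C(I_T): smallest gap noise for which the population
  stays active through a noise-filled interruption between two tones.

Variant dispatch follows the enabled pathways:

* sustained-only (hysteresis): M solves I_T = I_T(x_R(I_N), I_N); C solves
  I_T(x_L(I_N), I_N) = 0 and is exactly constant in tone level (no tone is
  present during the gap).
* transient-only (bistable): closed forms M = (I_T − 1)/β and
  C = (I_T − a_E (x_A − x_S)/γ_off)/β; the symmetric calibration
  γ_off = γ_on makes them identical.
* combined: both thresholds solve separatrix-crossing equations; the onset
  must clear S(x_I(0,0); I_T, I_N), and continuity additionally requires
  the gap noise to preserve the saddle and active state.  The offset
  comparison uses the pre-offset rate (the active equilibrium under the
  tone) against the gap system's separatrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .equilibria import NoKneesError, equilibrium_IT, find_equilibria, knee_x
from .model import ModelConfig
from .phase_plane import MonostableError, saddle_and_neighbors

__all__ = [
    "ThresholdCurve",
    "masking_threshold",
    "continuity_threshold",
    "model1_masking_slope_approx",
    "feasibility_report",
    "sweep_aI_alpha",
    "sweep_gamma_off",
    "threshold_curve",
]

_ROOT_TOL = 1e-9
_SCAN_STEP = 0.05


@dataclass(frozen=True)
class ThresholdCurve:
    """Tabulated threshold noise level per tone level (NaN where absent)."""

    tone_levels: np.ndarray
    noise_thresholds: np.ndarray
    kind: str  # "masking" | "continuity"
    method: str  # "analytic" | "bisection"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "I_T": self.tone_levels,
                "I_N_threshold": self.noise_thresholds,
                "kind": self.kind,
                "method": self.method,
            }
        )


def _check_IT(config: ModelConfig, I_T: float) -> None:
    if I_T <= 1.0:
        raise ValueError("tone level must exceed the activation threshold I_T = 1")
    if I_T > config.inputs.I_T_max:
        raise ValueError(f"tone level {I_T} exceeds I_T_max={config.inputs.I_T_max}")


def _variant_kind(config: ModelConfig) -> str:
    s, t = config.pathways.sustained, config.pathways.transient
    if s and t:
        return "combined"
    if s:
        return "sustained"
    if t:
        return "transient"
    raise ValueError("no input pathway enabled: thresholds undefined")


def _scan_root(h, lo: float, hi: float, step: float = _SCAN_STEP) -> float | None:
    """First sign change of h (may be ±inf on part of the range) by scan +
    bisection; None when h never changes sign on [lo, hi]."""
    grid = np.arange(lo, hi + step / 2, step)
    prev_t, prev_v = None, None
    for t in grid:
        v = h(t)
        if prev_v is not None and np.isfinite(prev_v) and np.isfinite(v) and prev_v * v < 0:
            return brentq(h, prev_t, t, xtol=_ROOT_TOL)
        if prev_v is not None and np.sign(prev_v) != np.sign(v):
            a, b = prev_t, t  # discontinuous flip: plain bisection
            for _ in range(60):
                mid = 0.5 * (a + b)
                if np.sign(h(mid)) == np.sign(prev_v):
                    a = mid
                else:
                    b = mid
                if b - a < _ROOT_TOL:
                    break
            return 0.5 * (a + b)
        prev_t, prev_v = t, v
    return None


def masking_threshold(config: ModelConfig, I_T: float) -> float | None:
    """Minimum simultaneous noise level that prevents activation by the tone.

    Returns None when no admissible noise level (≤ I_N_max) masks the tone.
    """
    _check_IT(config, I_T)
    pop, inp = config.population, config.inputs
    kind = _variant_kind(config)

    if kind == "transient":
        return (I_T - 1.0) / inp.beta if inp.beta > 0 else None

    if kind == "sustained":
        if not config.pathways.inhib:
            return None  # noise only excites: masking impossible

        def h(I_N):
            _, x_R = knee_x(pop.a_E, inp.a_I, I_N)
            return equilibrium_IT(x_R, I_N, pop, inp) - I_T

        root = _scan_root(h, 0.0, inp.I_N_max)
        return root

    # combined: onset amplitude vs separatrix at the resting rate
    x_I0 = find_equilibria(config)[0].x

    def h(I_N):
        try:
            _, x_S, _ = saddle_and_neighbors(
                config, tone_on=True, noise_on=I_N > 0, I_T=I_T, I_N=I_N
            )
        except MonostableError:
            return -np.inf  # no active state to reach: masked
        sep = (pop.a_E + inp.a_I * I_N) / inp.gamma_on * (x_S - x_I0)
        return max(I_T - inp.beta * I_N, 0.0) - sep

    return _scan_root(h, 0.0, inp.I_N_max)


def continuity_threshold(config: ModelConfig, I_T: float) -> float | None:
    """Minimum gap noise for which activity persists between the two tones.

    Returns None when no admissible noise level (≤ I_N_max) yields
    continuity.
    """
    _check_IT(config, I_T)
    pop, inp = config.population, config.inputs
    kind = _variant_kind(config)

    if kind == "transient":
        try:
            _, x_S, x_A = saddle_and_neighbors(config)
        except MonostableError:
            raise MonostableError(
                "transient-only continuity requires bistability at rest"
            ) from None
        if inp.beta <= 0 or inp.gamma_off <= 0:
            return None
        c = (I_T - pop.a_E * (x_A - x_S) / inp.gamma_off) / inp.beta
        return max(c, 0.0)

    if kind == "sustained":
        # no tone during the gap: threshold is the noise that drags the
        # deactivation knee below zero, independent of tone level
        def h(I_N):
            try:
                x_L, _ = knee_x(pop.a_E, inp.a_I if config.pathways.inhib else 0.0, I_N)
            except NoKneesError:
                return np.inf
            return equilibrium_IT(
                x_L, I_N, pop, inp, include_inhib=config.pathways.inhib
            )

        return _scan_root(h, 0.0, inp.I_N_max)

    # combined: offset kick from the tone-driven active state against the
    # gap system's separatrix; the gap noise must also preserve the saddle
    try:
        _, _, x_A_pre = saddle_and_neighbors(config, tone_on=True, I_T=I_T)
    except MonostableError:
        return None
    if inp.gamma_off <= 0:
        # pure hysteresis limit: saddle preservation alone decides
        def h0(I_N):
            try:
                _, x_S, _ = saddle_and_neighbors(config, noise_on=True, I_N=I_N)
                return -1.0
            except MonostableError:
                return 1.0

        return _scan_root(h0, 0.0, inp.I_N_max)

    def h(I_N):
        try:
            _, x_S, _ = saddle_and_neighbors(config, noise_on=I_N > 0, I_N=I_N)
        except MonostableError:
            return np.inf  # active state lost in the gap: no continuity
        sep = (pop.a_E + inp.a_I * I_N) / inp.gamma_off * (x_A_pre - x_S)
        return max(I_T - inp.beta * I_N, 0.0) - sep

    return _scan_root(h, 0.0, inp.I_N_max)


def model1_masking_slope_approx(a_I: float, alpha: float, x_R0: float) -> float:
    """Approximate slope dI_N/dI_T of the hysteresis-variant masking curve.

    Valid when a_I (1 − x_R0) > α; otherwise noise excitation dominates and
    masking is impossible.
    """
    denom = a_I * (1.0 - x_R0) - alpha
    if denom <= 0:
        raise ValueError(
            "masking impossible: alpha must be below a_I * (1 - x_R(0))"
        )
    return 1.0 / denom


def feasibility_report(config: ModelConfig, tone_grid=None) -> dict:
    """Named pass/fail checks on the parameterization (reports, never raises).

    i.   α < a_I (1 − x_R(0)) so noise can mask (sustained + inhib only);
    ii.  C(I_T) ≥ M(I_T) wherever both are defined (continuity compensates
         masking, never precedes it);
    iii. M and C at I_T_max do not exceed I_N_max;
    iv.  γ_off ≥ γ_on for configurations bistable at rest (otherwise a tone
         could activate the population in perpetuity).
    """
    pop, inp = config.population, config.inputs
    checks: dict[str, dict] = {}

    applies_alpha = config.pathways.sustained and config.pathways.inhib
    if applies_alpha:
        try:
            _, x_R0 = knee_x(pop.a_E)
            bound = inp.a_I * (1.0 - x_R0)
            checks["alpha_constraint"] = {
                "applies": True,
                "passed": inp.alpha < bound,
                "detail": f"alpha={inp.alpha:.4g} vs a_I*(1-x_R(0))={bound:.4g}",
            }
        except NoKneesError:
            checks["alpha_constraint"] = {
                "applies": True, "passed": False, "detail": "no knees (a_E < 4)",
            }
    else:
        checks["alpha_constraint"] = {"applies": False, "passed": True, "detail": "pathway off"}

    if tone_grid is None:
        tone_grid = np.arange(1.05, inp.I_T_max + 1e-9, 0.25)
    pairs = []
    for it in tone_grid:
        try:
            m = masking_threshold(config, it)
            c = continuity_threshold(config, it)
        except (ValueError, MonostableError):
            continue
        if m is not None and c is not None:
            pairs.append((it, m, c))
    ordered = all(c >= m - 1e-9 for _, m, c in pairs)
    checks["continuity_at_or_above_masking"] = {
        "applies": bool(pairs),
        "passed": ordered if pairs else True,
        "detail": f"{len(pairs)} tone levels compared",
    }

    try:
        m_max = masking_threshold(config, inp.I_T_max)
        c_max = continuity_threshold(config, inp.I_T_max)
        within = (m_max is not None and m_max <= inp.I_N_max) and (
            c_max is not None and c_max <= inp.I_N_max
        )
        detail = f"M(I_T_max)={m_max}, C(I_T_max)={c_max}, cap={inp.I_N_max}"
    except (ValueError, MonostableError) as e:
        within, detail = False, str(e)
    checks["thresholds_within_noise_cap"] = {
        "applies": True, "passed": within, "detail": detail,
    }

    rest_bistable = len(find_equilibria(config)) == 3
    applies_gamma = config.pathways.transient and rest_bistable
    checks["gamma_off_at_least_gamma_on"] = {
        "applies": applies_gamma,
        "passed": (inp.gamma_off >= inp.gamma_on) if applies_gamma else True,
        "detail": f"gamma_on={inp.gamma_on:.4g}, gamma_off={inp.gamma_off:.4g}",
    }

    checks["all_passed"] = all(
        c["passed"] for k, c in checks.items() if isinstance(c, dict) and c["applies"]
    )
    return checks


def sweep_aI_alpha(config: ModelConfig, a_I_grid, alpha_grid) -> pd.DataFrame:
    """Masking/continuity thresholds at I_T_max across the (a_I, α) plane.

    One row per cell with M(I_T_max), C (tone-independent for the
    hysteresis variant), and a feasibility flag.  NaN where a threshold is
    absent.
    """
    from dataclasses import replace

    rows = []
    I_T_max = config.inputs.I_T_max
    for a_I in a_I_grid:
        for alpha in alpha_grid:
            if a_I <= 0 or alpha < 0:
                raise ValueError("grids must be positive")
            cfg = config.with_(inputs=replace(config.inputs, a_I=a_I, alpha=alpha))
            try:
                m = masking_threshold(cfg, I_T_max)
            except ValueError:
                m = None
            try:
                c = continuity_threshold(cfg, I_T_max)
            except (ValueError, MonostableError):
                c = None
            rep = feasibility_report(cfg, tone_grid=[I_T_max])
            rows.append(
                {
                    "a_I": a_I,
                    "alpha": alpha,
                    "M_at_IT_max": np.nan if m is None else m,
                    "C_at_IT_max": np.nan if c is None else c,
                    "feasible": bool(rep["all_passed"]),
                }
            )
    return pd.DataFrame(rows)


def sweep_gamma_off(config: ModelConfig, gamma_off_grid, tone_grid) -> pd.DataFrame:
    """Continuity-threshold family across offset strengths γ_off.

    Long-format frame (gamma_off, I_T, C).  Small γ_off approaches the
    hysteresis limit (flat in tone level); larger γ_off steepens the
    dependence on I_T.
    """
    from dataclasses import replace

    rows = []
    for g in gamma_off_grid:
        if g < 0:
            raise ValueError("gamma_off grid must be nonnegative")
        cfg = config.with_(inputs=replace(config.inputs, gamma_off=g))
        for it in tone_grid:
            try:
                c = continuity_threshold(cfg, it)
            except (ValueError, MonostableError):
                c = None
            rows.append({"gamma_off": g, "I_T": it, "C": np.nan if c is None else c})
    return pd.DataFrame(rows)


def threshold_curve(
    config: ModelConfig,
    kind: str,
    tone_grid=None,
    method: str = "analytic",
    **bisect_kw,
) -> ThresholdCurve:
    """Tabulate M or C over a tone-level grid, analytically or by simulation."""
    if kind not in ("masking", "continuity"):
        raise ValueError("kind must be 'masking' or 'continuity'")
    if tone_grid is None:
        tone_grid = np.arange(1.05, config.inputs.I_T_max + 1e-9, 0.05)
    tone_grid = np.asarray(tone_grid, dtype=float)
    fn = masking_threshold if kind == "masking" else continuity_threshold

    vals = []
    for it in tone_grid:
        if method == "analytic":
            try:
                v = fn(config, it)
            except (ValueError, MonostableError):
                v = None
        elif method == "bisection":
            from .simulate import threshold_by_bisection

            try:
                v = threshold_by_bisection(config, kind, vary="I_N", fixed_level=it, **bisect_kw)
            except ValueError:
                v = None
        else:
            raise ValueError("method must be 'analytic' or 'bisection'")
        vals.append(np.nan if v is None else v)
    return ThresholdCurve(
        tone_levels=tone_grid,
        noise_thresholds=np.asarray(vals, dtype=float),
        kind=kind,
        method=method,
    )
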