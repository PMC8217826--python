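"""Event-driven integration of the full model and response classification.

The stimulus is piecewise constant, so the flow is smooth between acoustic
edges: integration proceeds segment by segment with an adaptive solver, and
at each tone edge the corresponding transient variable is reset to its
rectified amplitude.  The firing-rate trajectory is continuous; only the
transients jump.

A response is classified by probing x shortly before the end of each
stimulus epoch: the population counts as active when x exceeds the basin
midpoint (0.5 by default — the saddle lies well inside (0.2, 0.8) for every
preset regime).  Thresholds are then measured by bisection on a stimulus
level against the scenario's defining predicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .equilibria import find_equilibria
from .model import ModelConfig, DriveState, sigmoid, sustained_input, inhib_input, transient_amplitude
from .stimulus import Stimulus, build_scenario, edge_events, indicators

__all__ = [
    "SimulationResult",
    "ResponseLabel",
    "integrate",
    "classify_response",
    "threshold_by_bisection",
]


@dataclass
class SimulationResult:
    times: np.ndarray
    x: np.ndarray
    s_on: np.ndarray
    s_off: np.ndarray
    I_sustain: np.ndarray
    I_onset: np.ndarray
    I_offset: np.ndarray
    I_inhib: np.ndarray
    stimulus: Stimulus
    config: ModelConfig

    def x_at(self, t) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float), self.times, self.x)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.times,
                "x": self.x,
                "s_on": self.s_on,
                "s_off": self.s_off,
                "I_sustain": self.I_sustain,
                "I_onset": self.I_onset,
                "I_offset": self.I_offset,
                "I_inhib": self.I_inhib,
            }
        )


@dataclass(frozen=True)
class ResponseLabel:
    """Per-probe activity flags and the scenario-level verdict."""

    verdict: str
    probes: dict = field(default_factory=dict)


def _segments(stim: Stimulus) -> list[tuple[float, float]]:
    cuts = {0.0, stim.total_duration}
    for iv in stim.tone_intervals + stim.noise_intervals:
        cuts.update((iv.start, iv.end))
    cuts = sorted(cuts)
    return [(a, b) for a, b in zip(cuts, cuts[1:]) if b - a > 1e-12]


def integrate(
    config: ModelConfig,
    stim: Stimulus,
    x0: float | None = None,
    rtol: float = 1e-7,
    atol: float = 1e-9,
    dt: float = 1e-3,
    enforce_caps: bool = True,
) -> SimulationResult:
    """Integrate the model over the stimulus.

    ``x0`` defaults to the inactive fixed point of the input-free system.
    Sampling is on a uniform grid of spacing ``dt`` augmented with every
    segment boundary.
    """
    inp = config.inputs
    if enforce_caps and (stim.I_T > inp.I_T_max or stim.I_N > inp.I_N_max):
        raise ValueError(
            f"stimulus levels (I_T={stim.I_T}, I_N={stim.I_N}) exceed caps "
            f"({inp.I_T_max}, {inp.I_N_max})"
        )
    if x0 is None:
        x0 = find_equilibria(config)[0].x
    if not 0 < x0 < 1:
        raise ValueError("x0 must lie in (0, 1)")

    tau = config.population.tau
    pop = config.population
    resets = {
        (e.time, e.kind): transient_amplitude(stim.I_T, stim.I_N, e.noise_coincident, inp)
        for e in edge_events(stim)
    }

    times, xs, sons, soffs = [], [], [], []
    flags = []  # (tone_on, noise_on) per sample
    y = np.array([float(x0), 0.0, 0.0])
    for (t0, t1) in _segments(stim):
        if config.pathways.transient:
            if (t0, "onset") in resets:
                y[1] = resets[(t0, "onset")]
            if (t0, "offset") in resets:
                y[2] = resets[(t0, "offset")]
        tone_on, noise_on = indicators(stim, 0.5 * (t0 + t1))

        def seg_rhs(t, yv):
            state = DriveState(x=yv[0], s_on=yv[1], s_off=yv[2])
            u = pop.a_E * yv[0]
            if config.pathways.sustained:
                u += sustained_input(tone_on, noise_on, stim.I_T, stim.I_N, inp)
            if config.pathways.transient:
                u += inp.gamma_on * yv[1] - inp.gamma_off * yv[2]
            if config.pathways.inhib:
                u -= inhib_input(yv[0], noise_on, stim.I_N, inp)
            return [
                (-yv[0] + float(sigmoid(u, pop))) / tau,
                -yv[1] / tau,
                -yv[2] / tau,
            ]

        grid = np.arange(t0, t1, dt)
        grid = np.unique(np.concatenate([grid, [t1]]))
        sol = solve_ivp(
            seg_rhs, (t0, t1), y, t_eval=grid, rtol=rtol, atol=atol, method="LSODA"
        )
        if not sol.success:  # pragma: no cover - solver failure is exceptional
            raise RuntimeError(f"integration failed on [{t0}, {t1}]: {sol.message}")
        times.append(sol.t)
        xs.append(sol.y[0])
        sons.append(sol.y[1])
        soffs.append(sol.y[2])
        flags.extend([(tone_on, noise_on)] * len(sol.t))
        y = sol.y[:, -1].copy()

    t = np.concatenate(times)
    x = np.concatenate(xs)
    # transients are exactly nonnegative; clamp solver undershoot at 0
    s_on = np.maximum(np.concatenate(sons), 0.0)
    s_off = np.maximum(np.concatenate(soffs), 0.0)
    tone_f = np.array([f[0] for f in flags], dtype=bool)
    noise_f = np.array([f[1] for f in flags], dtype=bool)

    zero = np.zeros_like(x)
    I_sus = np.where(
        True,
        (stim.I_T * tone_f + inp.alpha * stim.I_N * noise_f)
        if config.pathways.sustained
        else zero,
        zero,
    )
    I_on = inp.gamma_on * s_on if config.pathways.transient else zero
    I_off = inp.gamma_off * s_off if config.pathways.transient else zero
    I_inh = (
        inp.a_I * stim.I_N * (1.0 - x) * noise_f if config.pathways.inhib else zero
    )
    return SimulationResult(
        times=t, x=x, s_on=s_on, s_off=s_off,
        I_sustain=np.asarray(I_sus, dtype=float), I_onset=I_on, I_offset=I_off,
        I_inhib=np.asarray(I_inh, dtype=float), stimulus=stim, config=config,
    )


def classify_response(
    result: SimulationResult,
    active_threshold: float = 0.5,
    delta: float = 1e-3,
) -> ResponseLabel:
    """Scenario verdict from probes taken ``delta`` before each epoch end.

    tone_only / masking: probe the tone end — "activated" / "inactive", and
    for masking "masked" when the tone fails to activate.  continuity:
    probe first-tone end, gap end, and second-tone end — "continuous" when
    all three are active, "discontinuous" when the first tone activates but
    the gap deactivates, "inactive" when the first tone never activates.
    """
    stim = result.stimulus
    active = lambda t: float(result.x_at(t - delta)) > active_threshold

    if stim.kind in ("tone_only", "masking"):
        tone = stim.tone_intervals[0]
        on = active(tone.end)
        probes = {"tone_end": on}
        if stim.kind == "masking":
            verdict = "activated" if on else "masked"
        else:
            verdict = "activated" if on else "inactive"
        return ResponseLabel(verdict=verdict, probes=probes)

    if stim.kind == "continuity":
        t1, t2 = stim.tone_intervals
        gap_end = stim.noise_intervals[0].end if stim.noise_intervals else t2.start
        p = {
            "tone1_end": active(t1.end),
            "gap_end": active(gap_end),
            "tone2_end": active(t2.end),
        }
        if p["tone1_end"] and p["gap_end"] and p["tone2_end"]:
            verdict = "continuous"
        elif p["tone1_end"] and not p["gap_end"]:
            verdict = "discontinuous"
        elif not p["tone1_end"]:
            verdict = "inactive"
        else:  # pragma: no cover - active gap but silent tone 2 end
            verdict = "discontinuous"
        return ResponseLabel(verdict=verdict, probes=p)

    raise ValueError(f"cannot classify scenario kind {stim.kind!r}")


_PREDICATES = {
    "tone_only": lambda lbl: lbl.verdict == "activated",
    "masking": lambda lbl: lbl.verdict == "activated",
    "continuity": lambda lbl: lbl.verdict == "continuous",
}


def threshold_by_bisection(
    config: ModelConfig,
    kind: str,
    vary: str = "I_N",
    fixed_level: float = 0.0,
    lo: float = 0.0,
    hi: float | None = None,
    tol: float = 1e-3,
    **sim_kw,
) -> float:
    """Threshold stimulus level by bisection on a monotone response predicate.

    ``vary`` selects the swept level ("I_T" or "I_N"); ``fixed_level`` is
    the other one.  The predicate must differ at the bracket ends, otherwise
    a ValueError("no threshold in range") is raised.  Returns the midpoint
    of the final bracket (absolute tolerance ``tol``).
    """
    if vary not in ("I_T", "I_N"):
        raise ValueError("vary must be 'I_T' or 'I_N'")
    if hi is None:
        hi = config.inputs.I_T_max if vary == "I_T" else config.inputs.I_N_max
    pred = _PREDICATES[kind]

    def holds(level: float) -> bool:
        kw = {"I_T": level, "I_N": fixed_level} if vary == "I_T" else {
            "I_T": fixed_level, "I_N": level}
        stim = build_scenario(kind, **kw)
        return pred(classify_response(integrate(config, stim, **sim_kw)))

    p_lo, p_hi = holds(lo), holds(hi)
    if p_lo == p_hi:
        raise ValueError(f"no threshold in range [{lo}, {hi}] (predicate constant)")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if holds(mid) == p_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
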