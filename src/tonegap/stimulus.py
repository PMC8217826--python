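"""Idealized stimulus scenarios: tone-only, masking, and continuity.

A stimulus is a set of tone and noise intervals with constant levels
``I_T`` and ``I_N``.  Indicator functions gate the sustained drives, and the
ordered list of tone-edge events (with noise-coincidence flags) drives the
transient resets during simulation.

Boundary convention: interval membership is half-open ``[start, end)``, but
noise that exactly abuts a tone edge counts as "on" at that edge — in the
continuity scenario the gap noise starts at the first tone's offset and ends
at the second tone's onset, and both gap-adjacent transients are suppressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["Interval", "Stimulus", "EdgeEvent", "build_scenario", "indicators", "edge_events"]

SCENARIOS = ("tone_only", "masking", "continuity")


@dataclass(frozen=True)
class Interval:
    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"interval start must precede end: {self}")

    def contains(self, t: float) -> bool:
        """Half-open membership [start, end)."""
        return self.start <= t < self.end

    def touches(self, t: float) -> bool:
        """Closed membership [start, end] — used for edge coincidence."""
        return self.start <= t <= self.end


@dataclass(frozen=True)
class EdgeEvent:
    """A tone onset or offset, flagged when noise is on (or abuts) at that time."""

    time: float
    kind: str  # "onset" | "offset"
    noise_coincident: bool


@dataclass(frozen=True)
class Stimulus:
    tone_intervals: tuple[Interval, ...]
    noise_intervals: tuple[Interval, ...]
    I_T: float
    I_N: float
    total_duration: float
    kind: str = "custom"

    def __post_init__(self) -> None:
        if self.I_T < 0 or self.I_N < 0:
            raise ValueError("levels must be nonnegative")
        for ivs in (self.tone_intervals, self.noise_intervals):
            for iv in ivs:
                if iv.start < 0 or iv.end > self.total_duration:
                    raise ValueError(f"interval {iv} outside [0, {self.total_duration}]")
            for a, b in zip(ivs, ivs[1:]):
                if b.start < a.end:
                    raise ValueError("intervals must be disjoint and ordered")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "I_T": self.I_T,
            "I_N": self.I_N,
            "total_duration": self.total_duration,
            "tone_intervals": [[iv.start, iv.end] for iv in self.tone_intervals],
            "noise_intervals": [[iv.start, iv.end] for iv in self.noise_intervals],
        }


def build_scenario(
    kind: str,
    I_T: float,
    I_N: float = 0.0,
    *,
    tone_duration: float = 1.0,
    gap_duration: float = 0.5,
    lead: float = 0.5,
    trail: float = 0.5,
) -> Stimulus:
    """Construct one of the three canonical scenarios.

    tone_only : a single tone of ``tone_duration`` (noise forced to 0).
    masking   : tone and noise presented together over the same interval.
    continuity: two tones separated by a noise-filled gap of
                ``gap_duration``; noise exactly fills the gap.

    Lead/trail silences let trajectories start and end at rest; they do not
    affect thresholds.
    """
    if kind not in SCENARIOS:
        raise ValueError(f"unknown scenario {kind!r}; expected one of {SCENARIOS}")
    if min(tone_duration, gap_duration, lead, trail) < 0 or tone_duration == 0:
        raise ValueError("durations must be positive (lead/trail may be zero)")
    if I_T < 0 or I_N < 0:
        raise ValueError("levels must be nonnegative")

    t0 = lead
    t1 = lead + tone_duration
    if kind == "tone_only":
        return Stimulus((Interval(t0, t1),), (), I_T, 0.0, t1 + trail, kind)
    if kind == "masking":
        return Stimulus((Interval(t0, t1),), (Interval(t0, t1),), I_T, I_N, t1 + trail, kind)
    g1 = t1 + gap_duration
    t2 = g1 + tone_duration
    return Stimulus(
        (Interval(t0, t1), Interval(g1, t2)),
        (Interval(t1, g1),),
        I_T,
        I_N,
        t2 + trail,
        kind,
    )


def indicators(stim: Stimulus, t: float) -> tuple[bool, bool]:
    """(tone_on, noise_on) at time t, half-open convention."""
    if not 0 <= t <= stim.total_duration:
        raise ValueError(f"t={t} outside the stimulus window")
    tone_on = any(iv.contains(t) for iv in stim.tone_intervals)
    noise_on = any(iv.contains(t) for iv in stim.noise_intervals)
    return tone_on, noise_on


def edge_events(stim: Stimulus) -> list[EdgeEvent]:
    """Ordered tone onset/offset events with noise-coincidence flags.

    Coincidence uses closed-interval membership so that noise exactly
    abutting a tone edge suppresses the corresponding transient.
    """
    events = []
    for iv in stim.tone_intervals:
        for t, kind in ((iv.start, "onset"), (iv.end, "offset")):
            coincident = any(niv.touches(t) for niv in stim.noise_intervals)
            events.append(EdgeEvent(t, kind, coincident))
    events.sort(key=lambda e: e.time)
    return events
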