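"""Time-dependent parameter schedules.

Gastric emptying is represented here as a smooth transition of a plug's
absorption rate constant from its value in the stomach (zero, by the usual
assumption that the stomach absorbs negligibly) to its value in the small
intestine.  The same machinery serves any other time-dependent scalar
parameter of the model (plug volume, solubility): a :class:`ParameterSchedule`
is a baseline value followed by an ordered chain of sigmoidal
:class:`TransitionSegment` pieces.  Chaining segments through common end
points yields an arbitrary continuous piecewise profile, evaluated afresh at
every integrator sub-step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = [
    "TransitionSegment",
    "ParameterSchedule",
    "ScheduleError",
    "sigmoid_transition",
    "step_transition",
    "evaluate_schedule",
]


class ScheduleError(ValueError):
    """Raised for ill-formed transition segments or schedules."""


@dataclass(frozen=True)
class TransitionSegment:
    """One smooth transition, anchored exactly at two (time, value) points.

    Parameters
    ----------
    t_start, t_end
        Times (min) at which the transition begins and completes.
    v_start, v_end
        Parameter values at and before ``t_start``, and at and after
        ``t_end``.  For an absorption rate constant these are the gastric
        and intestinal values (min^-1).
    """

    t_start: float
    t_end: float
    v_start: float
    v_end: float

    def __post_init__(self) -> None:
        if not (self.t_end > self.t_start):
            raise ScheduleError(
                f"transition must have t_end > t_start, got [{self.t_start}, {self.t_end}]"
            )
        if self.v_start < 0 or self.v_end < 0:
            raise ScheduleError("transition values must be non-negative")


def sigmoid_transition(t: float, seg: TransitionSegment) -> float:
    """Smooth (cosine smoothstep) value of *seg* at time *t*.

    Exactly ``v_start`` for ``t <= t_start`` and exactly ``v_end`` for
    ``t >= t_end``; continuously differentiable in between and monotone
    between the two anchor values.
    """
    if t <= seg.t_start:
        return seg.v_start
    if t >= seg.t_end:
        return seg.v_end
    x = (t - seg.t_start) / (seg.t_end - seg.t_start)
    return seg.v_start + (seg.v_end - seg.v_start) * 0.5 * (1.0 - math.cos(math.pi * x))


def step_transition(t: float, seg: TransitionSegment) -> float:
    """Abrupt variant: switches from ``v_start`` to ``v_end`` at the window
    midpoint ``(t_start + t_end) / 2``.

    Switching at the midpoint preserves the time centroid of the transition
    (the cosine smoothstep is symmetric about it), so an abrupt run is
    directly comparable to a smooth one; switching at ``t_start`` would turn
    absorption on earlier by half the transition window on average.  Used to
    demonstrate that smooth and immediate emptying transitions produce
    essentially the same plasma profile; smooth transitions are the default
    because discontinuous coefficients can destabilise fixed-step
    integration.
    """
    return seg.v_end if t >= 0.5 * (seg.t_start + seg.t_end) else seg.v_start


@dataclass(frozen=True)
class ParameterSchedule:
    """Baseline value plus an ordered, non-overlapping chain of transitions.

    Segments may share end points (segment *k*'s ``t_end`` equal to segment
    *k+1*'s ``t_start``), which is how multi-leg profiles are built; the
    evaluated schedule is then continuous provided the shared point carries
    the same value on both sides.
    """

    baseline: float
    segments: tuple[TransitionSegment, ...] = ()

    def __post_init__(self) -> None:
        segs = tuple(self.segments)
        object.__setattr__(self, "segments", segs)
        for a, b in zip(segs, segs[1:]):
            if b.t_start < a.t_end:
                raise ScheduleError(
                    f"overlapping segments: [{a.t_start}, {a.t_end}] and "
                    f"[{b.t_start}, {b.t_end}]"
                )

    @classmethod
    def constant(cls, value: float) -> "ParameterSchedule":
        return cls(baseline=float(value))

    def evaluate(self, t: float, mode: str = "smooth") -> float:
        """Schedule value at time *t*.

        Returns the baseline before the first segment, the active segment's
        sigmoid (or step) value inside a segment, and the most recently
        completed segment's ``v_end`` between and after segments.
        """
        if mode not in ("smooth", "step"):
            raise ScheduleError(f"unknown transition mode {mode!r}")
        val = self.baseline
        for seg in self.segments:
            if t < seg.t_start:
                break
            if t < seg.t_end:
                if mode == "smooth":
                    return sigmoid_transition(t, seg)
                return step_transition(t, seg)
            val = seg.v_end
        return val

    __call__ = evaluate

    @property
    def final_value(self) -> float:
        return self.segments[-1].v_end if self.segments else self.baseline

    def to_arrays(self) -> tuple[float, np.ndarray]:
        """Encode as (baseline, (m, 4) array of t_start/t_end/v_start/v_end).

        This flat encoding is what the compiled integration kernel consumes.
        """
        arr = np.array(
            [[s.t_start, s.t_end, s.v_start, s.v_end] for s in self.segments],
            dtype=np.float64,
        ).reshape(len(self.segments), 4)
        return float(self.baseline), arr


def evaluate_schedule(schedule: ParameterSchedule, t: float, mode: str = "smooth") -> float:
    """Functional alias for :meth:`ParameterSchedule.evaluate`."""
    return schedule.evaluate(t, mode=mode)


def as_schedule(value: "float | ParameterSchedule") -> ParameterSchedule:
    """Coerce a plain number to a constant schedule."""
    if isinstance(value, ParameterSchedule):
        return value
    return ParameterSchedule.constant(float(value))
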