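"""Piecewise-constant drug schedules C(t)."""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["DrugSchedule", "drug_concentration", "constant_schedule"]


@dataclass(frozen=True)
class DrugSchedule:
    """Piecewise-constant drug concentration over a simulation horizon.

    ``intervals`` is a tuple of ``(t_on, t_off, dose_nM)`` with right-open
    administration windows ``[t_on, t_off)``; outside every window the
    concentration is zero.  Intervals must be non-overlapping and contained
    in ``[0, horizon]``.
    """

    intervals: tuple[tuple[float, float, float], ...] = ()
    horizon: float = 96.0

    def __post_init__(self) -> None:
        if self.horizon < 0:
            raise ValueError("horizon must be >= 0")
        ivs = tuple(
            (float(a), float(b), float(d)) for a, b, d in self.intervals
        )
        object.__setattr__(self, "intervals", ivs)
        last_end = None
        for t_on, t_off, dose in sorted(ivs):
            if not 0.0 <= t_on < t_off <= self.horizon:
                raise ValueError(
                    f"interval [{t_on}, {t_off}) must lie within [0, {self.horizon}]"
                )
            if dose < 0:
                raise ValueError(f"dose must be >= 0, got {dose}")
            if last_end is not None and t_on < last_end:
                raise ValueError("schedule intervals overlap")
            last_end = t_off

    def concentration(self, t: float) -> float:
        """Drug concentration (nM) at time ``t``; domain error outside the horizon."""
        if not 0.0 <= t <= self.horizon:
            raise ValueError(f"t={t} outside schedule domain [0, {self.horizon}]")
        for t_on, t_off, dose in self.intervals:
            if t_on <= t < t_off:
                return dose
        return 0.0

    def switch_times(self) -> list[float]:
        """All on/off breakpoints, sorted (useful for exact time stepping)."""
        pts = {t for iv in self.intervals for t in iv[:2]}
        return sorted(pts)

    def total_on_time(self) -> float:
        """Total hours with a nonzero dose."""
        return sum(t_off - t_on for t_on, t_off, dose in self.intervals if dose > 0)


def drug_concentration(schedule: DrugSchedule, t: float) -> float:
    """Functional form of :meth:`DrugSchedule.concentration`."""
    return schedule.concentration(t)


def constant_schedule(dose: float, horizon: float) -> DrugSchedule:
    """Constant dose over ``[0, horizon)`` (no drug if ``dose == 0``)."""
    if dose <= 0 or horizon <= 0:
        return DrugSchedule(intervals=(), horizon=horizon)
    return DrugSchedule(intervals=((0.0, horizon, dose),), horizon=horizon)
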