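"""Sampling designs for circadian time courses.

A :class:`TimeCourseDesign` records when samples were taken (hours since the
first sample) and under which light regime: constant light (LL, free-running)
or a light--dark cycle (LD, entrained).  The default design is 24 samples
taken every 2 h over 2 days (t = 0, 2, ..., 46 h), which covers exactly two
24-h cycles and therefore makes full-cycle trigonometric sums exact
(sum cos = 0, sum cos^2 = n/2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, Tuple

import numpy as np

__all__ = ["TimeCourseDesign", "default_design"]

_CONDITIONS = ("LL", "LD")


@dataclass(frozen=True)
class TimeCourseDesign:
    """When and under which light regime samples were taken.

    Parameters
    ----------
    sample_times
        Hours since the first sample, strictly increasing, at least 4 values.
    condition_label
        ``"LL"`` (constant light) or ``"LD"`` (light--dark cycle).
    photoperiod_hours
        Light hours per 24-h cycle.  Must be 24 for LL and in (0, 24) for LD.
    lights_on_time
        Hour-of-cycle in [0, 24) at which light turns on (meaningful for LD).
    entrainment_photoperiod_hours
        Photoperiod of the entrainment regime that preceded a free run.  Used
        only to shade "subjective night" on LL profile plots; LD designs use
        their own photoperiod.
    """

    sample_times: Tuple[float, ...]
    condition_label: str = "LL"
    photoperiod_hours: float = 24.0
    lights_on_time: float = 0.0
    entrainment_photoperiod_hours: float = 12.0

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.sample_times)
        object.__setattr__(self, "sample_times", times)
        if len(times) < 4:
            raise ValueError("sample_times: need at least 4 samples")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("sample_times: must be strictly increasing")
        if self.condition_label not in _CONDITIONS:
            raise ValueError(
                f"condition_label: must be one of {_CONDITIONS}, "
                f"got {self.condition_label!r}"
            )
        if not (0.0 < self.photoperiod_hours <= 24.0):
            raise ValueError("photoperiod_hours: must lie in (0, 24]")
        is_ll = self.photoperiod_hours == 24.0
        if is_ll != (self.condition_label == "LL"):
            raise ValueError(
                "condition_label: LL requires photoperiod_hours == 24 "
                "and LD requires photoperiod_hours < 24"
            )
        if not (0.0 <= self.lights_on_time < 24.0):
            raise ValueError("lights_on_time: must lie in [0, 24)")

    # ------------------------------------------------------------------
    @property
    def times(self) -> np.ndarray:
        """Sample times as a float array (hours)."""
        return np.asarray(self.sample_times, dtype=float)

    @property
    def n_samples(self) -> int:
        return len(self.sample_times)

    @property
    def is_ll(self) -> bool:
        return self.condition_label == "LL"

    def is_uniform_full_cycle(self, period_hours: float = 24.0,
                              rtol: float = 1e-9) -> bool:
        """True if samples are evenly spaced and span a whole number of periods.

        Under this condition the discrete sums of sin/cos over the samples
        vanish exactly, which is what makes the closed-form phase estimator
        the exact maximiser of the cosine-bank correlation.
        """
        t = self.times
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=rtol, atol=1e-9):
            return False
        span = t[-1] - t[0] + dt[0]  # one period ends one step after last sample
        cycles = span / period_hours
        return bool(np.isclose(cycles, np.round(cycles), atol=1e-9)
                    and np.round(cycles) >= 1)

    def light_transitions(self, pad_hours: float = 0.0) -> np.ndarray:
        """Times (h, same axis as sample_times) of lights-on/off events.

        Returns an empty array for LL designs (no transitions).  Events are
        enumerated from ``-pad_hours`` before the first sample to the last
        sample, so transients from a transition shortly before sampling began
        can be represented.
        """
        if self.is_ll:
            return np.array([], dtype=float)
        t_lo = self.times[0] - pad_hours
        t_hi = self.times[-1]
        events = []
        k0 = int(np.floor((t_lo - 24.0) / 24.0))
        k1 = int(np.ceil((t_hi + 24.0) / 24.0))
        for k in range(k0, k1 + 1):
            on = self.lights_on_time + 24.0 * k
            off = on + self.photoperiod_hours
            for ev in (on, off):
                if t_lo <= ev <= t_hi:
                    events.append(ev)
        return np.array(sorted(events), dtype=float)

    def night_interval(self) -> Tuple[float, float]:
        """Dark (LD) or subjective-night (LL) span as hours-of-cycle.

        Returns ``(start, end)`` with ``start`` in [0, 24) and ``end`` possibly
        exceeding 24 (wrap-around interval).
        """
        photoperiod = (self.entrainment_photoperiod_hours if self.is_ll
                       else self.photoperiod_hours)
        start = (self.lights_on_time + photoperiod) % 24.0
        return start, start + (24.0 - photoperiod)

    def time_axis_label(self) -> str:
        """CT (circadian time) for free-run, ZT (zeitgeber time) for LD."""
        return "CT" if self.is_ll else "ZT"


def default_design(condition: str = "LL", n_samples: int = 24,
                   interval_hours: float = 2.0,
                   lights_on_time: float = 0.0) -> TimeCourseDesign:
    """The standard 2-day, 2-hourly design (24 samples at t = 0..46 h).

    ``n_samples=25`` gives the variant that includes the closing t = 48 h
    sample.  LD designs default to a 12L:12D cycle with lights on at t = 0.
    """
    times = tuple(interval_hours * i for i in range(n_samples))
    if condition == "LL":
        return TimeCourseDesign(times, "LL", 24.0, lights_on_time)
    return TimeCourseDesign(times, "LD", 12.0, lights_on_time)
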