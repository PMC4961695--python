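"""Measurement noise of oscillating-contig expression profiles.

For each detected oscillator the model predicts a unit-variance cosine on the
z-normalised scale: ``sqrt(2) * cos(2*pi*(t - peak_time)/period)``.  The
``sqrt(2)`` half-amplitude is the unique value for which a noiseless
z-normalised cosine (population-SD convention, whole sampled cycles) is an
exact fit.  Measurement noise at sample time ``t_j`` is the population SD,
across the selected oscillating contigs, of the residual between observed
normalised expression and this model curve, reported as a percentage of the
unit-variance scale.  The profile is summarised by its range and
mean +- SD across sample times.

A per-contig least-squares amplitude refit is available
(``refit_amplitude=True``) but off by default: the timetable model curve is
the fixed unit-variance cosine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import TimeCourseDesign
from .io import NormalizedMatrix

__all__ = ["NoiseProfile", "estimated_profile", "measurement_noise"]


@dataclass(frozen=True)
class NoiseProfile:
    """Per-sample-time residual SD (percent) with range/mean/SD summary."""

    sample_times: np.ndarray
    per_sample_noise: np.ndarray   # percent
    range_min: float
    range_max: float
    mean_noise: float
    sd_noise: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_time_h": self.sample_times,
                             "noise_percent": self.per_sample_noise})

    def summary_dict(self) -> dict:
        return {"range_min": self.range_min, "range_max": self.range_max,
                "mean": self.mean_noise, "sd": self.sd_noise}

    def __str__(self) -> str:
        return (f"measurement noise {self.range_min:.0f}-{self.range_max:.0f}% "
                f"({self.mean_noise:.0f} +- {self.sd_noise:.0f}%)")


def estimated_profile(peak_time: float, design: TimeCourseDesign,
                      period_hours: float = 24.0) -> np.ndarray:
    """Model curve on the normalised scale: sqrt(2)*cos(2pi(t - peak)/P)."""
    t = design.times
    return np.sqrt(2.0) * np.cos(2.0 * np.pi * (t - peak_time) / period_hours)


def measurement_noise(nm: NormalizedMatrix, stats: pd.DataFrame,
                      period_hours: float = 24.0,
                      refit_amplitude: bool = False) -> NoiseProfile:
    """Residual SD per sample time over the selected oscillating contigs.

    ``stats`` is a detection table restricted to the contigs of interest
    (normally the passing set) with ``contig_id`` and ``peak_time_h``
    columns; every contig must be present in ``nm``.  At least two contigs
    are required for the SD to be defined.
    """
    if len(stats) < 2:
        raise ValueError("measurement noise needs >= 2 selected contigs")
    sub = nm.subset(list(stats["contig_id"]))
    t = nm.design.times
    peaks = np.asarray(stats["peak_time_h"], dtype=float)
    model = np.sqrt(2.0) * np.cos(
        2.0 * np.pi * (t[None, :] - peaks[:, None]) / period_hours)
    if refit_amplitude:
        # per-contig least-squares scale of the unit cosine shape
        shape = model / np.sqrt(2.0)
        denom = np.sum(shape * shape, axis=1)
        coef = np.sum(sub.z_values * shape, axis=1) / denom
        model = coef[:, None] * shape
    residual = sub.z_values - model
    per_sample = 100.0 * residual.std(axis=0, ddof=0)
    return NoiseProfile(
        sample_times=t.copy(),
        per_sample_noise=per_sample,
        range_min=float(per_sample.min()),
        range_max=float(per_sample.max()),
        mean_noise=float(per_sample.mean()),
        sd_noise=float(per_sample.std(ddof=0)),
    )
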