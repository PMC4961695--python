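"""Cosine-bank rhythm detection (the molecular timetable method's core).

For each contig the method computes

* an amplitude statistic ``a`` = population SD / mean of the expression row
  (a dimensionless relative amplitude), and
* the best Pearson correlation ``r`` between the row and a bank of test
  cosine curves ``cos(2*pi*(t - phi)/period)`` whose peak times ``phi`` tile
  [0, period) — at the defaults, 1440 curves with period 24 h at 1-min steps.

The peak time of the best-fitting curve is the contig's *molecular peak
time*.  A contig is called oscillating when ``a >= a_cutoff`` and
``r >= r_cutoff`` (defaults 0.15 and 0.8).  Because the bank covers every
phase, the antiphase curve at ``phi + 12`` realises ``-r`` as ``+r``, so the
one-sided maximum is equivalent to testing ``|r|``.

``closed_form_peak`` is the analytic counterpart of the grid search: on an
evenly spaced design covering a whole number of periods the correlation
maximiser over continuous phase is ``(P/2pi) * atan2(sum x~ sin, sum x~ cos)``
(first-harmonic phase of the centred row).  It exists to cross-check the grid
search and is valid only under that design condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Tuple

import numpy as np
import pandas as pd

from .design import TimeCourseDesign
from .io import ExpressionMatrix

__all__ = [
    "CosinePhaseGrid",
    "DetectionConfig",
    "DetectionResult",
    "amplitude_stat",
    "cosine_bank",
    "best_cosine_fit",
    "closed_form_peak",
    "detect_oscillating",
]

logger = logging.getLogger(__name__)

EXCLUDE_CONSTANT = "zero-variance row"
EXCLUDE_NONPOSITIVE_MEAN = "non-positive mean"


@dataclass(frozen=True)
class CosinePhaseGrid:
    """The bank of candidate peak times: 0, step, 2*step, ... < period.

    At the defaults (24-h period, 1-min step) the bank holds 1440 curves;
    peak times live on the half-open interval [0, period) since a peak at
    the full period is identical to one at 0.
    """

    period_hours: float = 24.0
    phase_step_minutes: float = 1.0

    def __post_init__(self) -> None:
        if self.period_hours <= 0:
            raise ValueError("period_hours: must be positive")
        if self.phase_step_minutes <= 0:
            raise ValueError("phase_step_minutes: must be positive")
        n = self.period_hours * 60.0 / self.phase_step_minutes
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                "phase_step_minutes: must divide the period evenly")

    @property
    def n_curves(self) -> int:
        return int(round(self.period_hours * 60.0 / self.phase_step_minutes))

    @property
    def peak_times(self) -> np.ndarray:
        """Candidate peak times in hours, on [0, period)."""
        step_h = self.phase_step_minutes / 60.0
        return np.arange(self.n_curves) * step_h


@dataclass(frozen=True)
class DetectionConfig:
    """Cutoffs and phase grid for oscillator detection."""

    a_cutoff: float = 0.15
    r_cutoff: float = 0.8
    grid: CosinePhaseGrid = field(default_factory=CosinePhaseGrid)

    def __post_init__(self) -> None:
        if self.a_cutoff < 0:
            raise ValueError("a_cutoff: must be >= 0")
        if not (0 < self.r_cutoff <= 1):
            raise ValueError("r_cutoff: must lie in (0, 1]")


def amplitude_stat(row: np.ndarray) -> float:
    """Relative amplitude: population SD divided by the mean.

    Undefined (raises) for rows with non-positive mean.
    """
    row = np.asarray(row, dtype=float)
    mean = row.mean()
    if mean <= 0:
        raise ValueError("amplitude statistic undefined for mean <= 0")
    return float(row.std(ddof=0) / mean)


def cosine_bank(grid: CosinePhaseGrid,
                sample_times: np.ndarray) -> np.ndarray:
    """Test curves evaluated at the sample times: shape (n_curves, n_times)."""
    t = np.asarray(sample_times, dtype=float)
    phi = grid.peak_times
    return np.cos(2.0 * np.pi * (t[None, :] - phi[:, None])
                  / grid.period_hours)


def _standardize(x: np.ndarray) -> np.ndarray:
    """Centre rows and scale to unit population SD; rows must be non-constant."""
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    if (sd == 0).any():
        raise ValueError("zero-variance row: must be excluded before fitting")
    return (x - mean) / sd


def _correlation_matrix(rows: np.ndarray, bank_z: np.ndarray) -> np.ndarray:
    """Pearson correlations of standardized rows against a standardized bank."""
    n = rows.shape[1]
    return rows @ bank_z.T / n


def best_cosine_fit(row: np.ndarray, design: TimeCourseDesign,
                    grid: CosinePhaseGrid | None = None,
                    ) -> Tuple[float, float]:
    """Best Pearson correlation over the cosine bank and its peak time.

    Ties are broken toward the smallest peak time (argmax returns the first
    maximum on the ascending grid), which only matters for degenerate rows.
    """
    grid = grid or CosinePhaseGrid()
    row = np.asarray(row, dtype=float)[None, :]
    bank_z = _standardize(cosine_bank(grid, design.times))
    r = _correlation_matrix(_standardize(row), bank_z)[0]
    best = int(np.argmax(r))
    return float(r[best]), float(grid.peak_times[best])


def closed_form_peak(row: np.ndarray, design: TimeCourseDesign,
                     period_hours: float = 24.0) -> float:
    """Analytic continuous-phase correlation maximiser (first-harmonic phase).

    Valid only for evenly spaced designs covering an integer number of
    periods, where the discrete orthogonality of sin/cos makes this the exact
    maximiser; refuses other designs.
    """
    if not design.is_uniform_full_cycle(period_hours):
        raise ValueError(
            "closed_form_peak requires a uniformly spaced design covering "
            "an integer number of periods")
    row = np.asarray(row, dtype=float)
    if row.std(ddof=0) == 0:
        raise ValueError("zero-variance row")
    t = design.times
    x = row - row.mean()
    omega = 2.0 * np.pi / period_hours
    s = float(np.sum(x * np.sin(omega * t)))
    c = float(np.sum(x * np.cos(omega * t)))
    peak = (period_hours / (2.0 * np.pi)) * np.arctan2(s, c)
    return float(peak % period_hours)


@dataclass(frozen=True)
class DetectionResult:
    """Per-contig rhythm statistics plus excluded-contig accounting."""

    stats: pd.DataFrame        # contig_id, amplitude, best_r, peak_time_h, passes
    excluded: pd.DataFrame     # contig_id, reason
    config: DetectionConfig

    @property
    def passing(self) -> pd.DataFrame:
        return self.stats[self.stats["passes"]]

    @property
    def n_detected(self) -> int:
        return int(self.stats["passes"].sum())

    def passing_ids(self) -> set:
        return set(self.passing["contig_id"])


def detect_oscillating(em: ExpressionMatrix,
                       cfg: DetectionConfig | None = None,
                       block_size: int | None = None) -> DetectionResult:
    """Run amplitude + cosine-bank detection over every contig.

    Contigs with zero variance or non-positive mean are excluded (with
    reasons) rather than scored.  Results are independent of ``block_size``,
    which only bounds the working-set size of the vectorised correlation.
    """
    cfg = cfg or DetectionConfig()
    if em.n_contigs == 0:
        raise ValueError("empty expression matrix")
    x = em.values
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=0)
    constant = sd == 0
    nonpos = (~constant) & (mean <= 0)
    keep = ~(constant | nonpos)

    reasons = np.where(constant, EXCLUDE_CONSTANT, EXCLUDE_NONPOSITIVE_MEAN)
    excluded = pd.DataFrame({
        "contig_id": em.contig_ids[~keep],
        "reason": reasons[~keep],
    })
    if len(excluded):
        counts = excluded["reason"].value_counts().to_dict()
        logger.info("detect_oscillating: excluded %d contig(s): %s",
                    len(excluded), counts)

    ids = em.contig_ids[keep]
    xk = x[keep]
    amp = sd[keep] / mean[keep]

    bank_z = _standardize(cosine_bank(cfg.grid, em.design.times))
    peak_times = cfg.grid.peak_times
    n_rows = xk.shape[0]
    step = block_size or n_rows or 1
    best_r = np.empty(n_rows)
    best_phi = np.empty(n_rows)
    for lo in range(0, n_rows, step):
        hi = min(lo + step, n_rows)
        r = _correlation_matrix(_standardize(xk[lo:hi]), bank_z)
        idx = np.argmax(r, axis=1)  # first max -> smallest peak time
        best_r[lo:hi] = r[np.arange(hi - lo), idx]
        best_phi[lo:hi] = peak_times[idx]

    stats = pd.DataFrame({
        "contig_id": ids,
        "amplitude": amp,
        "best_r": best_r,
        "peak_time_h": best_phi,
        "passes": (amp >= cfg.a_cutoff) & (best_r >= cfg.r_cutoff),
    })
    return DetectionResult(stats=stats.reset_index(drop=True),
                           excluded=excluded.reset_index(drop=True),
                           config=cfg)


def write_stats_table(result: DetectionResult, path) -> None:
    """Tab-separated detection table, sorted by peak time then contig ID."""
    out = result.stats.sort_values(["peak_time_h", "contig_id"],
                                   kind="mergesort")
    out = out.rename(columns={"amplitude": "a", "best_r": "r"})
    out.to_csv(path, sep="\t", index=False,
               columns=["contig_id", "a", "r", "peak_time_h", "passes"])
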