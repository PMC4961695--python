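"""Model/Results interface to the molecular timetable analysis.

:class:`MolecularTimetable` wraps an expression matrix plus its sampling
design; :meth:`~MolecularTimetable.fit` screens every contig against the
cosine bank and returns a :class:`TimetableResults` holding the per-contig
amplitude, best correlation, molecular peak time and pass flag, along with
the z-normalised matrix, excluded-contig accounting, and methods for the
downstream analyses (measurement noise, phase profiles, plots).

Example
-------
>>> from moltimetable import MolecularTimetable, default_design
>>> from moltimetable.synthetic import SyntheticParams, generate_timecourse
>>> em, truth = generate_timecourse(SyntheticParams(seed=7), default_design())
>>> res = MolecularTimetable(em).fit()
>>> res.n_detected == len(res.oscillator_set())
True
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .compare import OscillatorSet
from .core import (DetectionConfig, DetectionResult, detect_oscillating,
                   write_stats_table)
from .design import TimeCourseDesign
from .io import (CountMatrix, ExpressionMatrix, NormalizedMatrix,
                 rpkm_normalize, zscore_rows)
from .noise import NoiseProfile, measurement_noise
from .profile import PhaseProfile, build_profile, render_profile

__all__ = ["MolecularTimetable", "TimetableResults"]


class MolecularTimetable:
    """Cosine-bank rhythm screen for a time-course expression matrix.

    Parameters
    ----------
    data
        An :class:`ExpressionMatrix`, or a contig x sample DataFrame
        (index = contig IDs, columns = sample times in hours) together with
        ``design``.
    design
        Required when ``data`` is a DataFrame; ignored otherwise.
    """

    def __init__(self, data, design: Optional[TimeCourseDesign] = None):
        if isinstance(data, ExpressionMatrix):
            self.data = data
        elif isinstance(data, pd.DataFrame):
            if design is None:
                raise ValueError("design is required with DataFrame input")
            self.data = ExpressionMatrix(
                np.asarray(data.index, dtype=object),
                data.to_numpy(dtype=float), design)
        else:
            raise TypeError("data must be an ExpressionMatrix or DataFrame")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       design: TimeCourseDesign) -> "MolecularTimetable":
        return cls(df, design)

    @classmethod
    def from_counts(cls, cm: CountMatrix) -> "MolecularTimetable":
        """Build the model from raw counts via RPKM normalisation."""
        return cls(rpkm_normalize(cm))

    @property
    def design(self) -> TimeCourseDesign:
        return self.data.design

    def fit(self, config: Optional[DetectionConfig] = None,
            block_size: Optional[int] = None) -> "TimetableResults":
        """Screen all contigs and return the results object."""
        config = config or DetectionConfig()
        detection = detect_oscillating(self.data, config,
                                       block_size=block_size)
        normalized, z_excluded = zscore_rows(self.data)
        return TimetableResults(self, detection, normalized)


class TimetableResults:
    """Fitted rhythm screen: per-contig statistics and derived analyses.

    Attributes
    ----------
    stats : DataFrame
        Columns ``contig_id``, ``amplitude`` (population SD / mean),
        ``best_r`` (best cosine-bank Pearson correlation), ``peak_time_h``
        (molecular peak time) and ``passes``.
    excluded : DataFrame
        Contigs that could not be scored, with reasons.
    normalized : NormalizedMatrix
        Per-contig z-normalised expression of all scoreable contigs.
    """

    def __init__(self, model: MolecularTimetable,
                 detection: DetectionResult,
                 normalized: NormalizedMatrix):
        self.model = model
        self.config = detection.config
        self.detection = detection
        self.stats = detection.stats
        self.excluded = detection.excluded
        self.normalized = normalized

    # -- basic accessors ------------------------------------------------
    @property
    def design(self) -> TimeCourseDesign:
        return self.model.design

    @property
    def n_detected(self) -> int:
        return self.detection.n_detected

    @property
    def passing(self) -> pd.DataFrame:
        return self.detection.passing

    def oscillator_set(self) -> OscillatorSet:
        return OscillatorSet(self.design.condition_label,
                             frozenset(self.detection.passing_ids()))

    # -- downstream analyses --------------------------------------------
    def measurement_noise(self, period_hours: float = 24.0,
                          refit_amplitude: bool = False) -> NoiseProfile:
        """Noise profile over the passing contigs (see :mod:`.noise`)."""
        return measurement_noise(self.normalized, self.passing,
                                 period_hours=period_hours,
                                 refit_amplitude=refit_amplitude)

    def phase_profile(self) -> PhaseProfile:
        """Phase-ordered expression profile of the passing contigs."""
        return build_profile(self.normalized, self.passing, self.design)

    def plot_profile(self, out_path, **kwargs):
        """Render the panel-per-sample-time profile figure to ``out_path``."""
        return render_profile(self.phase_profile(), out_path, **kwargs)

    def to_table(self, path) -> None:
        """Write the detection table (TSV, sorted by peak time then ID)."""
        write_stats_table(self.detection, path)

    # -- summary ---------------------------------------------------------
    def summary(self) -> str:
        """Human-readable account of the screen, statsmodels-style."""
        s = self.stats
        d = self.design
        lines = [
            "Molecular Timetable Detection Results",
            "=" * 53,
            f"Condition:            {d.condition_label}"
            f" ({d.photoperiod_hours:g} h photoperiod)",
            f"Samples:              {d.n_samples}"
            f" (t = {d.times[0]:g}..{d.times[-1]:g} h)",
            f"Cosine bank:          {self.config.grid.n_curves} curves,"
            f" period {self.config.grid.period_hours:g} h,"
            f" step {self.config.grid.phase_step_minutes:g} min",
            f"Cutoffs:              a >= {self.config.a_cutoff:g},"
            f" r >= {self.config.r_cutoff:g}",
            "-" * 53,
            f"Contigs scored:       {len(s)}",
            f"Contigs excluded:     {len(self.excluded)}",
            f"Oscillating contigs:  {self.n_detected}",
        ]
        if self.n_detected:
            p = self.passing
            lines += [
                f"  amplitude a:        median {p['amplitude'].median():.3f}"
                f"  (range {p['amplitude'].min():.3f}-"
                f"{p['amplitude'].max():.3f})",
                f"  best r:             median {p['best_r'].median():.3f}"
                f"  (min {p['best_r'].min():.3f})",
            ]
        lines.append("=" * 53)
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<TimetableResults: {self.n_detected} oscillating of "
                f"{len(self.stats)} scored contigs "
                f"({self.design.condition_label})>")
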