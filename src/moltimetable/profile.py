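"""Phase-ordered expression profiles (the timetable's collective view).

At each sample time, every passing contig contributes one point: its
molecular peak time on the x-axis against its normalised expression on the
y-axis.  For rhythmic data the cloud traces the cosine
``sqrt(2) * cos(2*pi*(t - phi)/period)`` as a function of peak time ``phi``,
sweeping left as sampling time advances — the collective behaviour of the
oscillating contigs.  Time is labelled CT (circadian time) for free-running
designs and ZT (zeitgeber time) for entrained ones, zero anchored at the
first sampling point.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import TimeCourseDesign
from .io import NormalizedMatrix

__all__ = ["PhaseProfile", "build_profile", "render_profile"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhaseProfile:
    """Long-format profile: one row per (sample time, passing contig)."""

    table: pd.DataFrame   # sample_time_h, contig_id, peak_time_h, z
    time_axis_label: str  # "CT" or "ZT"
    design: TimeCourseDesign

    @property
    def n_contigs(self) -> int:
        return self.table["contig_id"].nunique()

    def at_time(self, sample_time_h: float) -> pd.DataFrame:
        t = self.table
        return t[t["sample_time_h"] == sample_time_h]

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def build_profile(nm: NormalizedMatrix, stats: pd.DataFrame,
                  design: TimeCourseDesign) -> PhaseProfile:
    """Tabulate normalised expression against molecular peak time.

    ``stats`` carries the passing contigs (``contig_id``, ``peak_time_h``);
    rows are sorted by peak time then contig ID, deterministically.  An empty
    passing set yields an empty profile with a warning.
    """
    label = design.time_axis_label()
    if len(stats) == 0:
        logger.warning("build_profile: empty passing set, empty profile")
        empty = pd.DataFrame(columns=["sample_time_h", "contig_id",
                                      "peak_time_h", "z"])
        return PhaseProfile(empty, label, design)
    order = stats.sort_values(["peak_time_h", "contig_id"],
                              kind="mergesort")
    sub = nm.subset(list(order["contig_id"]))
    t = design.times
    peaks = np.asarray(order["peak_time_h"], dtype=float)
    frames = []
    for j, tj in enumerate(t):
        frames.append(pd.DataFrame({
            "sample_time_h": tj,
            "contig_id": sub.contig_ids,
            "peak_time_h": peaks,
            "z": sub.z_values[:, j],
        }))
    table = pd.concat(frames, ignore_index=True)
    return PhaseProfile(table, label, design)


def render_profile(profile: PhaseProfile, out_path,
                   n_cols: int = 6, period_hours: float = 24.0):
    """One panel per sample time: peak time (x) vs normalised expression (y).

    Night-time (LD) or subjective night (LL, from the entrainment
    photoperiod) is shaded on the peak-time axis.  The format follows the
    output path's extension.  Empty profiles write nothing and warn.
    """
    if len(profile.table) == 0:
        logger.warning("render_profile: empty profile, no plot written")
        return None
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    design = profile.design
    times = design.times
    n_panels = len(times)
    n_rows = math.ceil(n_panels / n_cols)
    fig, axes = plt.subplots(n_rows, n_cols,
                             figsize=(2.2 * n_cols, 1.9 * n_rows),
                             sharex=True, sharey=True, squeeze=False)
    night_start, night_end = design.night_interval()
    label = profile.time_axis_label
    for k, tj in enumerate(times):
        ax = axes[k // n_cols][k % n_cols]
        sub = profile.at_time(tj)
        _shade_night(ax, night_start, night_end, period_hours)
        ax.scatter(sub["peak_time_h"], sub["z"], s=4, alpha=0.5,
                   color="tab:blue", linewidths=0)
        ax.set_xlim(0, period_hours)
        ax.set_title(f"{label}{tj:g}", fontsize=8)
    for k in range(n_panels, n_rows * n_cols):
        axes[k // n_cols][k % n_cols].axis("off")
    fig.supxlabel("molecular peak time (h)")
    fig.supylabel("normalized expression")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path


def _shade_night(ax, start: float, end: float, period: float) -> None:
    # wrap-around interval on the peak-time axis
    if end <= period:
        ax.axvspan(start, end, color="0.85", zorder=0)
    else:
        ax.axvspan(start, period, color="0.85", zorder=0)
        ax.axvspan(0.0, end - period, color="0.85", zorder=0)
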