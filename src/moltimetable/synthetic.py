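"""Synthetic time-course expression matrices with planted rhythms.

The generator plants a known fraction of 24-h cosine oscillators among flat
contigs so that every downstream stage (normalisation, detection, set
comparison, noise estimation) has a ground truth to be checked against.

An oscillator row is

    baseline * (1 + sqrt(2) * a_true * cos(2*pi*(t - phi)/period)) + noise

with additive Gaussian noise of SD ``noise_cv * baseline``, clamped at zero.
The ``sqrt(2)`` factor makes the planted relative amplitude directly
comparable to the detection statistic: over whole sampled cycles a cosine's
population SD is 1/sqrt(2) of its half-amplitude, so the row's SD/mean equals
``a_true`` exactly in the noiseless limit.

For LD designs, square-wave light-transition artifacts can be layered on:
each lights-on/lights-off event adds an exponentially decaying transient of
size ``magnitude * baseline`` with a per-contig random sign.  This emulates
the acute transcriptional response to abrupt light steps that degrades cosine
fits under entrained conditions relative to free run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Tuple

import numpy as np
import pandas as pd
import yaml

from .design import TimeCourseDesign
from .io import ExpressionMatrix

__all__ = [
    "SyntheticParams",
    "SyntheticTruth",
    "generate_timecourse",
    "apply_light_artifact",
]


@dataclass(frozen=True)
class SyntheticParams:
    """Knobs of the generator.

    Defaults emulate a bulk time-course transcriptome: a couple of thousand
    contigs of which a minority oscillate with assorted phases and relative
    amplitudes, log-normal baselines around 10 RPKM, and 5% multiplicative
    measurement noise.
    """

    n_contigs: int = 2000
    frac_oscillating: float = 0.25
    period_hours: float = 24.0
    relative_amplitude_range: Tuple[float, float] = (0.1, 0.6)
    baseline_log_mean: float = float(np.log(10.0))  # ln RPKM
    baseline_log_sd: float = 1.0
    noise_cv: float = 0.05
    ld_artifact_magnitude: float = 0.0
    ld_artifact_decay_hours: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_contigs < 1:
            raise ValueError("n_contigs: must be >= 1")
        if not (0.0 <= self.frac_oscillating <= 1.0):
            raise ValueError("frac_oscillating: must lie in [0, 1]")
        if self.period_hours <= 0:
            raise ValueError("period_hours: must be positive")
        lo, hi = self.relative_amplitude_range
        if not (0.0 <= lo <= hi):
            raise ValueError("relative_amplitude_range: need 0 <= lo <= hi")
        if self.baseline_log_sd < 0:
            raise ValueError("baseline_log_sd: must be >= 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv: must be >= 0")
        if self.ld_artifact_magnitude < 0:
            raise ValueError("ld_artifact_magnitude: must be >= 0")
        if self.ld_artifact_decay_hours <= 0:
            raise ValueError("ld_artifact_decay_hours: must be positive")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "relative_amplitude_range" in raw:
            raw["relative_amplitude_range"] = tuple(
                raw["relative_amplitude_range"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        raw["relative_amplitude_range"] = list(raw["relative_amplitude_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth, one record per contig (as a DataFrame).

    Columns: contig_id, is_oscillator, true_peak_time (NaN for
    non-oscillators), true_relative_amplitude (NaN likewise), baseline_mean.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"contig_id", "is_oscillator", "true_peak_time",
                    "true_relative_amplitude", "baseline_mean"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"truth table missing columns: {sorted(missing)}")

    @property
    def oscillator_ids(self) -> set:
        t = self.table
        return set(t.loc[t["is_oscillator"], "contig_id"])

    @property
    def n_oscillators(self) -> int:
        return int(self.table["is_oscillator"].sum())

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "SyntheticTruth":
        t = pd.read_csv(path, sep="\t")
        t["is_oscillator"] = t["is_oscillator"].astype(bool)
        return cls(t)


def generate_timecourse(params: SyntheticParams, design: TimeCourseDesign,
                        ) -> Tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate a matrix with exactly round(n * frac) planted oscillators.

    Deterministic: identical (params, design) — the seed lives in params —
    reproduce the matrix bit for bit.  If the design is LD and
    ``ld_artifact_magnitude > 0``, light-transition artifacts are applied to
    the finished matrix with a seed derived from ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_contigs
    t = design.times

    ids = np.array([f"contig_{i:06d}" for i in range(n)], dtype=object)
    n_osc = int(round(n * params.frac_oscillating))
    osc_idx = rng.choice(n, size=n_osc, replace=False)
    is_osc = np.zeros(n, dtype=bool)
    is_osc[osc_idx] = True

    baseline = np.exp(rng.normal(params.baseline_log_mean,
                                 params.baseline_log_sd, size=n))
    phases = np.full(n, np.nan)
    amps = np.full(n, np.nan)
    phases[is_osc] = rng.uniform(0.0, params.period_hours, size=n_osc)
    lo, hi = params.relative_amplitude_range
    amps[is_osc] = rng.uniform(lo, hi, size=n_osc)

    values = np.repeat(baseline[:, None], len(t), axis=1)
    if n_osc:
        cosine = np.cos(2.0 * np.pi * (t[None, :] - phases[is_osc, None])
                        / params.period_hours)
        values[is_osc] = baseline[is_osc, None] * (
            1.0 + np.sqrt(2.0) * amps[is_osc, None] * cosine)
    if params.noise_cv > 0:
        noise = rng.normal(0.0, 1.0, size=values.shape)
        values = values + noise * (params.noise_cv * baseline)[:, None]
    values = np.clip(values, 0.0, None)

    em = ExpressionMatrix(ids, values, design)
    if params.ld_artifact_magnitude > 0 and not design.is_ll:
        em = apply_light_artifact(em, design, params.ld_artifact_magnitude,
                                  params.ld_artifact_decay_hours,
                                  seed=_artifact_seed(params.seed))

    truth = SyntheticTruth(pd.DataFrame({
        "contig_id": ids,
        "is_oscillator": is_osc,
        "true_peak_time": phases,
        "true_relative_amplitude": amps,
        "baseline_mean": baseline,
    }))
    return em, truth


def _artifact_seed(seed: int) -> int:
    # independent substream for the artifact stage, kept below 2**31
    return int(np.random.SeedSequence([seed, 0x1D]).generate_state(1)[0]
               % (2 ** 31))


def apply_light_artifact(matrix: ExpressionMatrix, design: TimeCourseDesign,
                         magnitude: float, decay_hours: float,
                         seed: int, affected_fraction: float = 1.0,
                         ) -> ExpressionMatrix:
    """Add decaying transients at each light transition of an LD design.

    Every affected contig receives, at each lights-on/lights-off event ``e``,
    a bump ``sign_i * magnitude * baseline_i * exp(-(t - e)/decay_hours)``
    for ``t >= e``, where ``baseline_i`` is the row mean and ``sign_i`` a
    per-contig random sign.  LL designs and ``magnitude = 0`` return the
    input unchanged.  Transitions up to ``5 * decay_hours`` before the first
    sample are included so that pre-sampling events can still leave a tail.
    """
    if design.is_ll or magnitude == 0:
        return matrix
    if decay_hours <= 0:
        raise ValueError("decay_hours: must be positive")
    rng = np.random.default_rng(seed)
    n = matrix.n_contigs
    signs = rng.choice([-1.0, 1.0], size=n)
    affected = rng.random(n) < affected_fraction

    t = design.times
    events = design.light_transitions(pad_hours=5.0 * decay_hours)
    bump = np.zeros(len(t))
    for ev in events:
        dt = t - ev
        bump += np.where(dt >= 0, np.exp(-dt / decay_hours), 0.0)

    baseline = matrix.values.mean(axis=1)
    delta = (signs * affected * magnitude * baseline)[:, None] * bump[None, :]
    values = np.clip(matrix.values + delta, 0.0, None)
    return ExpressionMatrix(matrix.contig_ids.copy(), values, matrix.design)
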