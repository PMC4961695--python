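"""Set algebra between oscillator sets from two light conditions.

Detection is run per condition; the contigs passing in both are the
candidate circadian set ("shared"), those passing in exactly one are
condition-specific ("unique").  A circular peak-time shift between
conditions supports phase-comparison of the shared contigs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Set

import pandas as pd

__all__ = [
    "OscillatorSet",
    "ConditionPartition",
    "intersect_conditions",
    "peak_time_shift",
    "circular_shift_hours",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OscillatorSet:
    """IDs of contigs that pass detection under one condition."""

    condition_label: str
    contig_ids: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "contig_ids", frozenset(self.contig_ids))

    def __len__(self) -> int:
        return len(self.contig_ids)


@dataclass(frozen=True)
class ConditionPartition:
    """Disjoint unique/unique/shared partition of two oscillator sets."""

    unique_first: frozenset
    unique_second: frozenset
    shared: frozenset

    def sizes(self) -> tuple:
        return len(self.unique_first), len(self.unique_second), len(self.shared)

    def summary(self) -> str:
        n1, n2, ns = self.sizes()
        return f"unique_a/unique_b/shared = {n1}/{n2}/{ns}"


def intersect_conditions(set_a: OscillatorSet,
                         set_b: OscillatorSet) -> ConditionPartition:
    """Partition two oscillator sets into unique-A, unique-B and shared IDs."""
    a, b = set_a.contig_ids, set_b.contig_ids
    part = ConditionPartition(unique_first=frozenset(a - b),
                              unique_second=frozenset(b - a),
                              shared=frozenset(a & b))
    logger.info("intersect_conditions(%s, %s): %s", set_a.condition_label,
                set_b.condition_label, part.summary())
    return part


def circular_shift_hours(peak_a: float, peak_b: float,
                         period_hours: float = 24.0) -> float:
    """Signed circular difference peak_b - peak_a, mapped to [-P/2, P/2)."""
    half = period_hours / 2.0
    return ((peak_b - peak_a + half) % period_hours) - half


def peak_time_shift(stats_a: pd.DataFrame, stats_b: pd.DataFrame,
                    shared_ids: Iterable[str],
                    period_hours: float = 24.0) -> pd.DataFrame:
    """Per-contig circular peak-time shift (condition B minus condition A).

    ``stats_a``/``stats_b`` are detection tables with ``contig_id`` and
    ``peak_time_h`` columns.  Shifts live on [-12, 12) hours at the default
    period; a contig missing from either table raises, naming it.
    """
    shared = list(shared_ids)
    maps = []
    for name, stats in (("first", stats_a), ("second", stats_b)):
        lookup = dict(zip(stats["contig_id"], stats["peak_time_h"]))
        missing = [c for c in shared if c not in lookup]
        if missing:
            raise KeyError(
                f"contig {missing[0]!r} missing from {name} stats table")
        maps.append(lookup)
    rows = [{
        "contig_id": cid,
        "peak_a_h": maps[0][cid],
        "peak_b_h": maps[1][cid],
        "shift_h": circular_shift_hours(maps[0][cid], maps[1][cid],
                                        period_hours),
    } for cid in shared]
    return pd.DataFrame(rows, columns=["contig_id", "peak_a_h", "peak_b_h",
                                       "shift_h"])


def write_id_list(ids: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for cid in sorted(ids):
            fh.write(f"{cid}\n")
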