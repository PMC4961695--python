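"""Expression-matrix containers, normalisation and tab-separated I/O.

Two normalisations are provided:

* RPKM (reads per kilobase per million mapped reads) from raw counts:
  ``rpkm[i, j] = counts[i, j] * 1e9 / (length_bp[i] * library_size[j])``.
* Per-contig z-normalisation: ``z = (x - mean(x)) / sd(x)`` with the
  *population* standard deviation (ddof = 0).  The population convention is
  used for every SD in this package so that a noiseless cosine time course
  sampled over whole cycles z-normalises exactly to ``sqrt(2) * cos``.

Constant rows (population SD 0, including all-zero rows) cannot be
z-normalised and are excluded, not errored: real matrices contain unexpressed
contigs and downstream detection could never retain them anyway.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .design import TimeCourseDesign

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "NormalizedMatrix",
    "MatrixParseError",
    "rpkm_normalize",
    "zscore_rows",
    "read_matrix",
    "write_matrix",
]

logger = logging.getLogger(__name__)


class MatrixParseError(ValueError):
    """Malformed matrix file (carries a 1-based line number when known)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


def _check_ids(contig_ids: Sequence[str]) -> np.ndarray:
    ids = np.asarray(contig_ids, dtype=object)
    if ids.ndim != 1 or ids.size == 0:
        raise ValueError("contig_ids: need a non-empty 1-D sequence")
    uniq, counts = np.unique(ids.astype(str), return_counts=True)
    if (counts > 1).any():
        dup = uniq[counts > 1][0]
        raise ValueError(f"contig_ids: duplicate contig ID {dup!r}")
    return ids.astype(str)


@dataclass(frozen=True)
class CountMatrix:
    """Raw mapped-read counts with the metadata RPKM needs."""

    contig_ids: np.ndarray
    counts: np.ndarray           # contig x sample, non-negative
    contig_lengths: np.ndarray   # bp per contig
    library_sizes: np.ndarray    # total mapped reads per sample
    design: TimeCourseDesign

    def __post_init__(self) -> None:
        ids = _check_ids(self.contig_ids)
        counts = np.asarray(self.counts, dtype=float)
        lengths = np.asarray(self.contig_lengths, dtype=float)
        libs = np.asarray(self.library_sizes, dtype=float)
        if counts.ndim != 2:
            raise ValueError("counts: must be 2-D (contig x sample)")
        n, m = counts.shape
        if ids.size != n:
            raise ValueError("contig_ids: length mismatch with counts rows")
        if m != self.design.n_samples:
            raise ValueError("counts: one column per design sample required")
        if lengths.shape != (n,):
            raise ValueError("contig_lengths: one value per contig required")
        if libs.shape != (m,):
            raise ValueError("library_sizes: one value per sample required")
        if (counts < 0).any():
            raise ValueError("counts: negative values not allowed")
        if (lengths < 1).any():
            raise ValueError("contig_lengths: must be >= 1 bp")
        if (libs < 1).any():
            raise ValueError("library_sizes: must be >= 1 read")
        object.__setattr__(self, "contig_ids", ids)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "contig_lengths", lengths)
        object.__setattr__(self, "library_sizes", libs)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Contig x time-point expression values (RPKM scale) plus the design."""

    contig_ids: np.ndarray
    values: np.ndarray
    design: TimeCourseDesign

    def __post_init__(self) -> None:
        ids = _check_ids(self.contig_ids)
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values: must be 2-D (contig x sample)")
        if ids.size != values.shape[0]:
            raise ValueError("contig_ids: length mismatch with values rows")
        if values.shape[1] != self.design.n_samples:
            raise ValueError("values: one column per design sample required")
        if not np.isfinite(values).all():
            raise ValueError("values: non-finite values not allowed")
        if (values < 0).any():
            raise ValueError("values: negative values not allowed")
        object.__setattr__(self, "contig_ids", ids)
        object.__setattr__(self, "values", values)

    @property
    def n_contigs(self) -> int:
        return int(self.values.shape[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.contig_ids,
                                                        name="contig_id"),
                            columns=list(self.design.times))

    def row(self, contig_id: str) -> np.ndarray:
        idx = np.flatnonzero(self.contig_ids == contig_id)
        if idx.size == 0:
            raise KeyError(f"contig {contig_id!r} not in matrix")
        return self.values[idx[0]]


@dataclass(frozen=True)
class NormalizedMatrix:
    """Per-contig z-normalised expression (rows have mean 0, population SD 1)."""

    contig_ids: np.ndarray
    z_values: np.ndarray
    design: TimeCourseDesign

    def __post_init__(self) -> None:
        ids = _check_ids(self.contig_ids)
        z = np.asarray(self.z_values, dtype=float)
        if z.ndim != 2 or ids.size != z.shape[0]:
            raise ValueError("z_values: must be 2-D with one row per contig")
        if z.shape[1] != self.design.n_samples:
            raise ValueError("z_values: one column per design sample required")
        object.__setattr__(self, "contig_ids", ids)
        object.__setattr__(self, "z_values", z)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.z_values,
                            index=pd.Index(self.contig_ids, name="contig_id"),
                            columns=list(self.design.times))

    def subset(self, contig_ids: Sequence[str]) -> "NormalizedMatrix":
        wanted = list(contig_ids)
        pos = {c: i for i, c in enumerate(self.contig_ids)}
        missing = [c for c in wanted if c not in pos]
        if missing:
            raise KeyError(f"contigs not in normalized matrix: {missing[:5]}")
        idx = np.array([pos[c] for c in wanted], dtype=int)
        return NormalizedMatrix(self.contig_ids[idx], self.z_values[idx],
                                self.design)


# ----------------------------------------------------------------------
# normalisation


def rpkm_normalize(cm: CountMatrix) -> ExpressionMatrix:
    """Counts -> RPKM: ``counts * 1e9 / (length_bp * library_size)``."""
    values = cm.counts * 1.0e9 / (cm.contig_lengths[:, None]
                                  * cm.library_sizes[None, :])
    return ExpressionMatrix(cm.contig_ids, values, cm.design)


def zscore_rows(em: ExpressionMatrix) -> Tuple[NormalizedMatrix, List[str]]:
    """Z-normalise each row with the population SD.

    Rows with zero population SD (constant, including all-zero) cannot be
    normalised; they are excluded and their IDs returned.
    """
    x = em.values
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    keep = (sd[:, 0] > 0.0)
    excluded = [str(c) for c in em.contig_ids[~keep]]
    if excluded:
        logger.info("zscore_rows: excluded %d constant row(s)", len(excluded))
    z = (x[keep] - mean[keep]) / sd[keep]
    nm = NormalizedMatrix(em.contig_ids[keep], z, em.design)
    return nm, excluded


# ----------------------------------------------------------------------
# tab-separated matrix I/O
#
# Format: header line "contig_id<TAB>t0<TAB>t1...", times in hours; one row
# per contig.  Deterministic, row order preserved.


def write_matrix(em: ExpressionMatrix, path) -> None:
    with open(path, "w") as fh:
        times = "\t".join(format(t, ".6g") for t in em.design.times)
        fh.write(f"contig_id\t{times}\n")
        for cid, row in zip(em.contig_ids, em.values):
            vals = "\t".join(repr(float(v)) for v in row)
            fh.write(f"{cid}\t{vals}\n")


def read_matrix(path, condition: str = "LL", photoperiod_hours: float | None = None,
                lights_on_time: float = 0.0) -> ExpressionMatrix:
    """Read a tab-separated expression matrix.

    The file stores only IDs, sample times and values; the light regime is
    supplied by the caller (default LL).
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise MatrixParseError("empty file", line=1)
        cols = header.split("\t")
        if len(cols) < 2:
            raise MatrixParseError("header must have contig_id plus sample times",
                                   line=1)
        try:
            times = tuple(float(c) for c in cols[1:])
        except ValueError as exc:
            raise MatrixParseError(f"non-numeric sample time in header: {exc}",
                                   line=1) from None
        n_cols = len(times)
        ids: List[str] = []
        rows: List[List[float]] = []
        seen = set()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != n_cols + 1:
                raise MatrixParseError(
                    f"expected {n_cols + 1} columns, found {len(parts)}",
                    line=lineno)
            cid = parts[0]
            if cid in seen:
                raise MatrixParseError(f"duplicate contig ID {cid!r}",
                                       line=lineno)
            seen.add(cid)
            try:
                vals = [float(p) for p in parts[1:]]
            except ValueError:
                bad = next(p for p in parts[1:]
                           if not _is_float(p))
                raise MatrixParseError(
                    f"non-numeric cell {bad!r} for contig {cid!r}",
                    line=lineno) from None
            ids.append(cid)
            rows.append(vals)
    if not ids:
        raise MatrixParseError("no data rows", line=2)
    if photoperiod_hours is None:
        photoperiod_hours = 24.0 if condition == "LL" else 12.0
    design = TimeCourseDesign(times, condition, photoperiod_hours,
                              lights_on_time)
    return ExpressionMatrix(np.array(ids, dtype=object),
                            np.array(rows, dtype=float), design)


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False
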