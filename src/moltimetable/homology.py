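"""Two-stage homology filter over precomputed tabular BLAST results.

Candidate contigs are first screened against BLASTn hits; contigs without a
qualifying nucleotide hit are then screened against BLASTx hits.  A hit
qualifies when, simultaneously, E-value <= 1e-20, percent identity >= 60 and
query coverage >= 60 (defaults; all thresholds inclusive at the boundary).
Any single qualifying hit retains the contig — the filter tests for the
existence of homology, not for best-hit quality.

Input is BLAST's 12-column tabular format (outfmt 6):

    qseqid sseqid pident length mismatch gapopen qstart qend sstart send
    evalue bitscore

optionally followed by a 13th query-coverage column (``qcovs``).  When the
coverage column is absent, coverage is computed as
``100 * alignment_length / query_length`` from a caller-supplied
query-length table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

__all__ = [
    "BlastHit",
    "HomologyFilterConfig",
    "BlastParseError",
    "parse_blast_tab",
    "read_query_lengths",
    "two_stage_filter",
]

_PROGRAMS = ("blastn", "blastx")


class BlastParseError(ValueError):
    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class BlastHit:
    query_id: str
    subject_id: str
    percent_identity: float
    evalue: float
    query_coverage_percent: float
    program: str

    def __post_init__(self) -> None:
        if self.program not in _PROGRAMS:
            raise ValueError(f"program: must be one of {_PROGRAMS}")
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError("percent_identity: must lie in [0, 100]")
        if not (0.0 <= self.query_coverage_percent <= 100.0):
            raise ValueError("query_coverage_percent: must lie in [0, 100]")
        if self.evalue < 0:
            raise ValueError("evalue: must be >= 0")


@dataclass(frozen=True)
class HomologyFilterConfig:
    max_evalue: float = 1e-20
    min_identity_percent: float = 60.0
    min_query_cover_percent: float = 60.0

    def __post_init__(self) -> None:
        if self.max_evalue < 0:
            raise ValueError("max_evalue: must be >= 0")
        for name in ("min_identity_percent", "min_query_cover_percent"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name}: must lie in [0, 100]")

    def qualifies(self, hit: BlastHit) -> bool:
        """Inclusive thresholds: boundary hits (e.g. exactly 60%) pass."""
        return (hit.evalue <= self.max_evalue
                and hit.percent_identity >= self.min_identity_percent
                and hit.query_coverage_percent >= self.min_query_cover_percent)


def read_query_lengths(path) -> Dict[str, int]:
    """Two-column tab-separated table: query_id, length_bp."""
    lengths: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise BlastParseError("expected 2 columns (id, length)",
                                      line=lineno)
            try:
                lengths[parts[0]] = int(parts[1])
            except ValueError:
                raise BlastParseError(
                    f"non-integer length {parts[1]!r}", line=lineno) from None
    return lengths


def parse_blast_tab(path, program: str,
                    query_lengths: Mapping[str, int] | None = None,
                    ) -> List[BlastHit]:
    """Parse outfmt-6 tabular BLAST output into :class:`BlastHit` records.

    With exactly 12 columns, coverage is derived from the alignment length
    and ``query_lengths`` (required in that case); a 13th column is read as
    percent query coverage directly.  Comment lines (``#``) are skipped.
    """
    if program not in _PROGRAMS:
        raise ValueError(f"program: must be one of {_PROGRAMS}")
    hits: List[BlastHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise BlastParseError(
                    f"expected >= 12 tab-separated columns, found {len(parts)}",
                    line=lineno)
            qid = parts[0]
            try:
                pident = float(parts[2])
                aln_len = float(parts[3])
                evalue = float(parts[10])
            except ValueError as exc:
                raise BlastParseError(f"malformed numeric field: {exc}",
                                      line=lineno) from None
            if len(parts) >= 13:
                try:
                    cover = float(parts[12])
                except ValueError:
                    raise BlastParseError(
                        f"malformed coverage field {parts[12]!r}",
                        line=lineno) from None
            else:
                if query_lengths is None:
                    raise BlastParseError(
                        "no coverage column and no query-length table "
                        "supplied", line=lineno)
                if qid not in query_lengths:
                    raise BlastParseError(
                        f"query {qid!r} missing from query-length table",
                        line=lineno)
                cover = 100.0 * aln_len / float(query_lengths[qid])
            hits.append(BlastHit(
                query_id=qid,
                subject_id=parts[1],
                percent_identity=pident,
                evalue=evalue,
                query_coverage_percent=min(cover, 100.0),
                program=program,
            ))
    return hits


def two_stage_filter(candidate_ids: Iterable[str],
                     blastn_hits: Sequence[BlastHit],
                     blastx_hits: Sequence[BlastHit],
                     cfg: HomologyFilterConfig | None = None,
                     ) -> Tuple[List[str], Dict[str, str]]:
    """Retain candidates with a qualifying BLASTn hit, else a BLASTx hit.

    Returns the retained IDs (input order preserved, duplicates dropped) and
    a map from each retained ID to the stage (``"blastn"``/``"blastx"``)
    that retained it.  Hits whose query is not a candidate are ignored; the
    result is independent of hit order and idempotent.
    """
    cfg = cfg or HomologyFilterConfig()
    candidates: List[str] = list(dict.fromkeys(candidate_ids))
    cand_set = set(candidates)

    def qualifying_queries(hits: Sequence[BlastHit]) -> set:
        return {h.query_id for h in hits
                if h.query_id in cand_set and cfg.qualifies(h)}

    stage1 = qualifying_queries(blastn_hits)
    remaining = cand_set - stage1
    stage2 = {q for q in qualifying_queries(blastx_hits) if q in remaining}

    stage_of: Dict[str, str] = {}
    retained: List[str] = []
    for cid in candidates:
        if cid in stage1:
            stage_of[cid] = "blastn"
            retained.append(cid)
        elif cid in stage2:
            stage_of[cid] = "blastx"
            retained.append(cid)
    return retained, stage_of
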