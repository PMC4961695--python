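"""End-to-end pipeline: simulate/load -> detect -> intersect -> filter -> noise.

The pipeline mirrors the analysis flow for a two-condition (LL and LD)
circadian screen: obtain a matrix per condition (synthetic or from disk),
run cosine-bank detection, partition the passing sets into unique/shared,
optionally apply the two-stage homology filter to the shared set, compute
measurement-noise profiles, and write phase-profile tables.  A JSON manifest
records input hashes, parameters and the contig counts at every stage, so a
rerun with the same configuration is byte-identical except for its
timestamp.

All outputs are written atomically (temp file + rename).  Stage failures
raise :class:`StageError` naming the stage; partial outputs are removed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import yaml

from . import __version__
from .compare import intersect_conditions, write_id_list
from .core import CosinePhaseGrid, DetectionConfig
from .design import TimeCourseDesign, default_design
from .homology import (HomologyFilterConfig, parse_blast_tab,
                       read_query_lengths, two_stage_filter)
from .io import read_matrix, write_matrix
from .model import MolecularTimetable
from .synthetic import SyntheticParams, generate_timecourse

__all__ = ["RunConfig", "StageError", "run_pipeline"]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class ConditionSpec:
    """One condition's input: a matrix path or synthetic parameters."""

    label: str                       # "LL" or "LD"
    matrix_path: Optional[str] = None
    synthetic: Optional[dict] = None  # SyntheticParams overrides
    n_samples: int = 24
    interval_hours: float = 2.0
    lights_on_time: float = 0.0


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    conditions: Dict[str, ConditionSpec] = field(default_factory=dict)
    a_cutoff: float = 0.15
    r_cutoff: float = 0.8
    period_hours: float = 24.0
    phase_step_minutes: float = 1.0
    blastn_path: Optional[str] = None
    blastx_path: Optional[str] = None
    query_lengths_path: Optional[str] = None
    max_evalue: float = 1e-20
    min_identity_percent: float = 60.0
    min_query_cover_percent: float = 60.0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        conds = {}
        for label, spec in (raw.pop("conditions", {}) or {}).items():
            conds[label] = ConditionSpec(label=label, **(spec or {}))
        return cls(conditions=conds, **raw)

    def detection_config(self) -> DetectionConfig:
        grid = CosinePhaseGrid(self.period_hours, self.phase_step_minutes)
        return DetectionConfig(self.a_cutoff, self.r_cutoff, grid)

    def homology_config(self) -> HomologyFilterConfig:
        return HomologyFilterConfig(self.max_evalue,
                                    self.min_identity_percent,
                                    self.min_query_cover_percent)


def _atomic_write_text(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _condition_seed(master: int, label: str) -> int:
    digest = int.from_bytes(hashlib.sha256(label.encode()).digest()[:4], "big")
    return int(np.random.SeedSequence([master, digest]).generate_state(1)[0]
               % (2 ** 31))


def _obtain_matrix(spec: ConditionSpec, cfg: RunConfig, outdir: Path):
    if spec.matrix_path:
        photoperiod = 24.0 if spec.label == "LL" else 12.0
        return read_matrix(spec.matrix_path, condition=spec.label,
                           photoperiod_hours=photoperiod,
                           lights_on_time=spec.lights_on_time), None
    design = default_design(spec.label, spec.n_samples, spec.interval_hours,
                            spec.lights_on_time)
    overrides = dict(spec.synthetic or {})
    if "relative_amplitude_range" in overrides:
        overrides["relative_amplitude_range"] = tuple(
            overrides["relative_amplitude_range"])
    overrides.setdefault("seed", _condition_seed(cfg.seed, spec.label))
    params = SyntheticParams(**overrides)
    em, truth = generate_timecourse(params, design)
    write_matrix(em, outdir / f"matrix_{spec.label}.tsv")
    truth.write(outdir / f"truth_{spec.label}.tsv")
    return em, truth


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages and return (and write) the run manifest."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), 20))
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            "a_cutoff": cfg.a_cutoff, "r_cutoff": cfg.r_cutoff,
            "period_hours": cfg.period_hours,
            "phase_step_minutes": cfg.phase_step_minutes,
        },
        "inputs": {},
        "counts": {},
        "stages": [],
    }
    results = {}
    det_cfg = cfg.detection_config()
    for label, spec in cfg.conditions.items():
        try:
            if spec.matrix_path:
                manifest["inputs"][str(spec.matrix_path)] = _sha256(
                    Path(spec.matrix_path))
            em, truth = _obtain_matrix(spec, cfg, outdir)
            res = MolecularTimetable(em).fit(det_cfg)
            res.to_table(outdir / f"stats_{label}.tsv")
            results[label] = res
            manifest["counts"][f"detected_{label}"] = res.n_detected
            manifest["counts"][f"excluded_{label}"] = len(res.excluded)
            manifest["stages"].append({"stage": f"detect_{label}",
                                       "n_scored": len(res.stats)})
            if res.n_detected >= 2:
                noise = res.measurement_noise()
                _atomic_write_text(outdir / f"noise_{label}.json",
                                   json.dumps(noise.summary_dict(),
                                              indent=2) + "\n")
                noise.to_frame().to_csv(outdir / f"noise_{label}.tsv",
                                        sep="\t", index=False)
            profile = res.phase_profile()
            profile.write(outdir / f"profile_{label}.tsv")
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"detect_{label}", exc) from exc

    labels = list(cfg.conditions)
    shared_ids = None
    if len(labels) >= 2:
        try:
            a, b = results[labels[0]], results[labels[1]]
            part = intersect_conditions(a.oscillator_set(),
                                        b.oscillator_set())
            write_id_list(part.unique_first,
                          outdir / f"unique_{labels[0]}.txt")
            write_id_list(part.unique_second,
                          outdir / f"unique_{labels[1]}.txt")
            write_id_list(part.shared, outdir / "shared.txt")
            manifest["counts"][f"unique_{labels[0]}"] = len(part.unique_first)
            manifest["counts"][f"unique_{labels[1]}"] = len(part.unique_second)
            manifest["counts"]["shared"] = len(part.shared)
            manifest["stages"].append({"stage": "intersect",
                                       "summary": part.summary()})
            shared_ids = sorted(part.shared)
        except Exception as exc:
            raise StageError("intersect", exc) from exc

    if shared_ids is not None and cfg.blastn_path and cfg.blastx_path:
        try:
            for p in (cfg.blastn_path, cfg.blastx_path,
                      cfg.query_lengths_path):
                if p:
                    manifest["inputs"][str(p)] = _sha256(Path(p))
            qlen = (read_query_lengths(cfg.query_lengths_path)
                    if cfg.query_lengths_path else None)
            blastn = parse_blast_tab(cfg.blastn_path, "blastn", qlen)
            blastx = parse_blast_tab(cfg.blastx_path, "blastx", qlen)
            retained, stage_of = two_stage_filter(shared_ids, blastn, blastx,
                                                  cfg.homology_config())
            write_id_list(retained, outdir / "retained.txt")
            _atomic_write_text(
                outdir / "retained_stages.tsv",
                "".join(f"{cid}\t{stage_of[cid]}\n" for cid in retained))
            manifest["counts"]["retained"] = len(retained)
            manifest["stages"].append({"stage": "blast_filter",
                                       "n_retained": len(retained)})
        except Exception as exc:
            raise StageError("blast_filter", exc) from exc

    _atomic_write_text(outdir / "manifest.json",
                       json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
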