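"""Readers, writers, configuration and the end-to-end pipeline.

SAM/BAM ingestion goes through pysam; cohort tables are TSV (tab
separated, UTF-8, ``.`` for missing values). The pipeline command chains
simulate -> quantify -> stats -> classify and writes a run manifest with
per-output checksums so identical (config, seed) runs are verifiable as
identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import sys
import time
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
import pysam
import yaml

from .quant import AlignmentRecord

logger = logging.getLogger("cfmito")

MISSING = "."
MANDATORY_COHORT_COLUMNS = ("sample_id", "center", "status")
STATUS_VOCAB = ("healthy", "cancer")

__version__ = "0.1.0"


def configure_logging(level: str = "INFO") -> None:
    """Log to stderr; results go only to files or stdout."""
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, level.upper()),
        format="%(levelname)s %(name)s: %(message)s",
    )


# ---------------------------------------------------------------------------
# Alignment I/O
# ---------------------------------------------------------------------------

def read_alignments(path: str) -> Iterator[AlignmentRecord]:
    """Lazily yield alignment records from SAM or BAM, flags decoded.

    Ground-truth tags (and any other string tags) are preserved on the
    records. Malformed input raises with the offending position.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        fh = pysam.AlignmentFile(path, check_sq=False)
    except ValueError as exc:
        raise ValueError(f"{path}: unrecognized alignment format: {exc}") from exc
    with fh:
        for i, seg in enumerate(fh):
            try:
                yield AlignmentRecord(
                    qname=seg.query_name or "",
                    flag=seg.flag,
                    contig=None if seg.is_unmapped else seg.reference_name,
                    pos=0 if seg.is_unmapped else seg.reference_start + 1,
                    mapq=seg.mapping_quality,
                    tlen=seg.template_length,
                    tags={k: str(v) for k, v in seg.get_tags()},
                )
            except Exception as exc:  # pragma: no cover - defensive
                raise ValueError(f"{path}: malformed record #{i + 1}: {exc}") from exc


def write_alignments(path: str, records, contigs: dict[str, int]) -> None:
    """Write records to SAM (used by tests and small fixtures)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": l} for n, l in contigs.items()],
    }
    with pysam.AlignmentFile(path, "w", header=header) as out:
        hdr = out.header
        for rec in records:
            seg = pysam.AlignedSegment(hdr)
            seg.query_name = rec.qname
            seg.flag = rec.flag
            if rec.contig is not None:
                seg.reference_id = hdr.get_tid(rec.contig)
                seg.reference_start = rec.pos - 1
            seg.mapping_quality = rec.mapq
            seg.template_length = rec.tlen
            seg.cigarstring = None if rec.flag & 0x4 else "50M"
            seg.set_tags([(k, v, "Z") for k, v in rec.tags.items()])
            out.write(seg)


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

def read_cohort(path: str) -> pd.DataFrame:
    """Read a cohort TSV with typed columns and explicit missing values.

    Mandatory columns: sample_id, center, status; unknown columns are
    preserved. Missing values are ``.`` or empty, never silently zero.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[MISSING, ""],
                     keep_default_na=True)
    missing = [c for c in MANDATORY_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: cohort table missing mandatory columns {missing}")
    bad = df[~df["status"].isin(STATUS_VOCAB)]
    if len(bad):
        row = bad.index[0] + 2  # 1-based, counting the header
        raise ValueError(
            f"{path} line {row}: status {bad['status'].iloc[0]!r} not in "
            f"{list(STATUS_VOCAB)}"
        )
    for col in ("tf_ichor", "maf", "p_mtdna", "d_metric", "pci"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col])
    return df


def write_cohort(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    out_dir: str
    stages: list[str]
    seed: int = 0
    feature_only: bool = True
    cohort_path: str | None = None  # existing cohort table (skip simulate)
    read_cohort_scale: bool = True  # use the scaled read-mode default config
    n_iter: int = 12
    n_trees: int = 200
    log_level: str = "INFO"

    @staticmethod
    def from_yaml(path: str) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return PipelineConfig(**payload)

    def validate(self) -> None:
        if not self.stages:
            raise ValueError("pipeline config lists no stages")
        if self.seed < 0:
            raise ValueError("seed must be a non-negative integer")
        known = {"simulate", "quantify", "stats", "classify"}
        unknown = set(self.stages) - known
        if unknown:
            raise ValueError(f"unknown pipeline stages: {sorted(unknown)}")
        if self.cohort_path is not None and not os.path.exists(self.cohort_path):
            raise FileNotFoundError(self.cohort_path)


@dataclass
class RunManifest:
    version: str
    config: dict
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    started: float = 0.0
    finished: float = 0.0

    def add(self, path: str) -> None:
        h = hashlib.sha256()
        with open(path, "rb") as fh:
            for chunk in iter(lambda: fh.read(1 << 20), b""):
                h.update(chunk)
        self.outputs[os.path.basename(path)] = h.hexdigest()

    def write(self, path: str) -> None:
        with open(path, "wt") as fh:
            json.dump(
                {
                    "version": self.version,
                    "config": self.config,
                    "outputs": self.outputs,
                    "started": self.started,
                    "finished": self.finished,
                },
                fh,
                indent=1,
            )


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute configured stages in order and write a run manifest.

    Each stage's outputs are written before the next starts; a stage
    failure aborts with the stage named, leaving prior outputs on disk.
    """
    from . import classify as _classify
    from . import stats as _stats
    from . import synth as _synth
    from .quant import quantify_file

    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    manifest = RunManifest(__version__, config.__dict__.copy(), started=time.time())
    cohort: pd.DataFrame | None = None
    sam_paths: dict[str, str] | None = None
    cohort_path = os.path.join(config.out_dir, "cohort.tsv")

    for stage in config.stages:
        logger.info("pipeline stage: %s", stage)
        try:
            if stage == "simulate":
                cfg = (
                    _synth.default_cohort_config(config.seed)
                    if config.feature_only or not config.read_cohort_scale
                    else _synth.default_read_cohort_config(config.seed)
                )
                cohort, _, sam_paths = _synth.simulate_cohort(
                    cfg, config.out_dir, feature_only=config.feature_only
                )
                manifest.add(cohort_path)
            elif stage == "quantify":
                if cohort is None:
                    if config.cohort_path is None:
                        raise ValueError("quantify needs a simulate stage or cohort_path")
                    cohort = read_cohort(config.cohort_path)
                if sam_paths:
                    estimates = {}
                    for sample_id, sam in sam_paths.items():
                        profile = quantify_file(sam, sample_id)
                        estimates[sample_id] = profile.p_mtdna
                    cohort["p_mtdna"] = cohort["sample_id"].map(estimates)
                write_cohort(cohort, cohort_path)
                manifest.add(cohort_path)
            elif stage == "stats":
                if cohort is None:
                    cohort = read_cohort(config.cohort_path or cohort_path)
                report = _stats.run_group_analyses(cohort)
                out = os.path.join(config.out_dir, "group_stats.tsv")
                report.to_csv(out, sep="\t", index=False, na_rep=MISSING)
                manifest.add(out)
            elif stage == "classify":
                if cohort is None:
                    cohort = read_cohort(config.cohort_path or cohort_path)
                corrected = _classify.apply_batch_correction(cohort)
                evals, pairwise = _classify.evaluate_feature_sets(
                    corrected, n_iter=config.n_iter, seed=config.seed,
                    n_trees=config.n_trees,
                )
                summary = {
                    "evaluations": [e.summary() for e in evals],
                    "pairwise": pairwise.to_dict(orient="records"),
                }
                out = os.path.join(config.out_dir, "classifier_summary.json")
                with open(out, "wt") as fh:
                    json.dump(summary, fh, indent=1)
                iters = pd.concat(
                    [e.iterations.assign(feature_set=e.feature_set) for e in evals]
                )
                iters_path = os.path.join(config.out_dir, "classifier_iterations.tsv")
                iters.to_csv(iters_path, sep="\t", index=False)
                manifest.add(out)
                manifest.add(iters_path)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest.finished = time.time()
    manifest.write(os.path.join(config.out_dir, "run_manifest.json"))
    return manifest
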