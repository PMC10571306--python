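"""Xenograft read-of-origin analysis.

Plasma from tumor-bearing mice is a two-species read mixture: human reads
are tumor-derived, mouse reads come from the host (normal). This module
partitions filter-passing reads by species, tabulates mitochondrial vs
nuclear counts per animal, pools mitochondrial reads across animals for
fragment-size comparison (tumor mtDNA is much rarer than host mtDNA, so
per-animal profiles are too sparse), and correlates tumor-derived counts
with the peritoneal cancer index (PCI), an ordinal tumor-load score.

Species assignment models a best-alignment-score splitter: a ground-truth
tag wins when present; otherwise the higher score wins and exact ties are
called ambiguous and excluded downstream. This is an analog of
alignment-based read splitting, not a reimplementation of it.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .quant import (
    AlignmentRecord,
    MAX_FRAGMENT_BP,
    compare_profiles,
    passes_filters,
    summarize_profile,
)
from .synth import HUMAN_MITO, MOUSE_MITO, TAG_SPECIES


@dataclass
class SpeciesAssignment:
    read_id: str
    call: str  # "human" | "mouse" | "ambiguous"
    basis: str  # "truth-tag" | "score-compare"


@dataclass
class XenograftSummary:
    """Per-animal 2x2 filter-passing read counts by (species, contig class)."""

    animal_id: str
    pci: float
    tumor_mt_reads: int = 0
    normal_mt_reads: int = 0
    tumor_nuclear_reads: int = 0
    normal_nuclear_reads: int = 0

    def as_row(self) -> dict:
        return {
            "animal_id": self.animal_id,
            "pci": self.pci,
            "tumor_mt_reads": self.tumor_mt_reads,
            "normal_mt_reads": self.normal_mt_reads,
            "tumor_nuclear_reads": self.tumor_nuclear_reads,
            "normal_nuclear_reads": self.normal_nuclear_reads,
        }


def assign_species(
    read_id: str,
    truth_tag: str | None = None,
    human_score: float | None = None,
    mouse_score: float | None = None,
) -> SpeciesAssignment:
    """Call a read human or mouse.

    A ground-truth tag takes precedence; otherwise the higher alignment
    score wins and an exact tie is ambiguous (excluded downstream).
    """
    if truth_tag is not None:
        if truth_tag not in ("human", "mouse"):
            raise ValueError(f"unknown species truth tag {truth_tag!r}")
        return SpeciesAssignment(read_id, truth_tag, "truth-tag")
    if human_score is None or mouse_score is None:
        raise ValueError("need a truth tag or both alignment scores")
    if human_score > mouse_score:
        call = "human"
    elif mouse_score > human_score:
        call = "mouse"
    else:
        call = "ambiguous"
    return SpeciesAssignment(read_id, call, "score-compare")


MITO_CONTIGS = frozenset({HUMAN_MITO, MOUSE_MITO})


def _record_species(rec: AlignmentRecord) -> str | None:
    tag = rec.tags.get(TAG_SPECIES)
    if tag in ("human", "mouse"):
        return tag
    return None


def summarize_animal(
    records: Iterable[AlignmentRecord],
    pci: float,
    animal_id: str = "animal",
    mito_contigs: frozenset[str] = MITO_CONTIGS,
) -> XenograftSummary:
    """Count filter-passing reads in the (species, mt/nuclear) 2x2 table.

    Human reads count as tumor, mouse reads as normal; reads without a
    species call (ambiguous) are excluded from all four cells.
    """
    s = XenograftSummary(animal_id, pci)
    for rec in records:
        if not passes_filters(rec):
            continue
        species = _record_species(rec)
        if species is None:
            continue
        is_mt = rec.contig in mito_contigs
        if species == "human":
            if is_mt:
                s.tumor_mt_reads += 1
            else:
                s.tumor_nuclear_reads += 1
        else:
            if is_mt:
                s.normal_mt_reads += 1
            else:
                s.normal_nuclear_reads += 1
    return s


def summarize_animal_sam(
    sam_path: str, pci: float, animal_id: str = "animal"
) -> XenograftSummary:
    """Vectorized per-animal summary for generator-produced SAM files."""
    from .quant import _read_sam_columns, _vector_pass_mask

    df = _read_sam_columns(sam_path, usecols=[1, 2, 4, 11])
    if df is None:
        from .io import read_alignments

        return summarize_animal(read_alignments(sam_path), pci, animal_id)
    if len(df) == 0:
        return XenograftSummary(animal_id, pci)
    flag = df[1].to_numpy(np.int64)
    mapq = df[4].to_numpy(np.int64)
    contig = df[2].to_numpy()
    species = df[11].astype(str).str.removeprefix("XS:Z:").to_numpy()
    ok = _vector_pass_mask(flag, mapq)
    is_mt = np.isin(contig, list(MITO_CONTIGS))
    human = species == "human"
    mouse = species == "mouse"
    return XenograftSummary(
        animal_id,
        pci,
        tumor_mt_reads=int((ok & human & is_mt).sum()),
        normal_mt_reads=int((ok & mouse & is_mt).sum()),
        tumor_nuclear_reads=int((ok & human & ~is_mt).sum()),
        normal_nuclear_reads=int((ok & mouse & ~is_mt).sum()),
    )


def _mt_histograms(records: Iterable[AlignmentRecord]) -> dict[str, Counter]:
    """Tumor/normal mitochondrial size histograms from one record stream."""
    hists = {"tumor": Counter(), "normal": Counter()}
    for rec in records:
        if not passes_filters(rec):
            continue
        if rec.contig not in MITO_CONTIGS:
            continue
        if rec.is_paired and not rec.is_first_in_pair:
            continue
        species = _record_species(rec)
        if species is None:
            continue
        length = abs(rec.tlen)
        if not 1 <= length <= MAX_FRAGMENT_BP:
            continue
        hists["tumor" if species == "human" else "normal"][length] += 1
    return hists


def pooled_size_comparison(per_animal_records: Sequence[Iterable[AlignmentRecord]]):
    """Pool mitochondrial reads across animals and compare size profiles.

    Returns ``(tumor_hist, normal_hist, comparison)`` where the histograms
    are per-length sums over animals and the comparison holds the KS and
    Mann-Whitney results for tumor vs normal fragment lengths.
    """
    if not per_animal_records:
        raise ValueError("need at least one animal")
    tumor: Counter = Counter()
    normal: Counter = Counter()
    for records in per_animal_records:
        h = _mt_histograms(records)
        tumor.update(h["tumor"])
        normal.update(h["normal"])
    for name, hist in (("tumor", tumor), ("normal", normal)):
        if not hist:
            raise ValueError(f"no mitochondrial reads in the {name} compartment")
    result = compare_profiles(tumor, normal)
    result["tumor_summary"] = summarize_profile(tumor)
    result["normal_summary"] = summarize_profile(normal)
    return dict(tumor), dict(normal), result


def pooled_size_comparison_sam(sam_paths: Sequence[str]):
    """File-path convenience wrapper around :func:`pooled_size_comparison`."""
    from .io import read_alignments

    if not sam_paths:
        raise ValueError("need at least one animal")
    return pooled_size_comparison([list(read_alignments(p)) for p in sam_paths])


def tumor_load_correlations(
    summaries: Sequence[XenograftSummary] | pd.DataFrame,
) -> dict[str, float]:
    """Pearson correlations of tumor mtDNA reads vs PCI and vs tumor
    nuclear reads, with two-sided t-based p values."""
    if isinstance(summaries, pd.DataFrame):
        df = summaries
    else:
        df = pd.DataFrame([s.as_row() for s in summaries])
    if len(df) < 3:
        raise ValueError("need at least 3 animals")
    for col in ("pci", "tumor_mt_reads", "tumor_nuclear_reads"):
        if df[col].nunique() < 2:
            raise ValueError(f"correlation undefined: {col} is constant")
    r1, p1 = sps.pearsonr(df["tumor_mt_reads"], df["pci"])
    r2, p2 = sps.pearsonr(df["tumor_mt_reads"], df["tumor_nuclear_reads"])
    return {
        "r_mt_vs_pci": float(r1),
        "p_mt_vs_pci": float(p1),
        "r_mt_vs_nuclear": float(r2),
        "p_mt_vs_nuclear": float(p2),
    }
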