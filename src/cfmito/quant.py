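"""Mitochondrial DNA quantification from WGS alignments.

Computes the plasma mtDNA fraction

    P_mtDNA [%] = reads_chrM / reads_aligned * 100

where both counts refer to alignment records that survive the standard
quality filters (mapped, primary, non-supplementary, non-duplicate,
MAPQ >= 30), and extracts mitochondrial fragment-size profiles from
template lengths with summary statistics and two-sample comparisons.

"Reads" in the fraction are counted as records (matching samtools-style
counting); fragment-size profiles count templates once, via the
first-in-pair record.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger("cfmito")

# SAM FLAG bits
FLAG_PAIRED = 0x1
FLAG_PROPER_PAIR = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_FIRST_IN_PAIR = 0x40
FLAG_SECOND_IN_PAIR = 0x80
FLAG_SECONDARY = 0x100
FLAG_QC_FAIL = 0x200
FLAG_DUPLICATE = 0x400
FLAG_SUPPLEMENTARY = 0x800

#: minimum mapping quality retained by the standard filter set
MAPQ_THRESHOLD = 30

#: default mitochondrial contig name, with resolvable aliases
DEFAULT_MITO_CONTIG = "chrM"
MITO_ALIASES = {"chrM": "chrM", "MT": "chrM", "chrMT": "chrM", "M": "chrM"}

#: fragment-length histogram support (Picard-style HISTOGRAM_WIDTH bound)
MAX_FRAGMENT_BP = 1000

#: exclusion-reason precedence: a record is charged to the first matching
#: reason only, so the reasons partition the excluded records.
EXCLUSION_PRECEDENCE = ("unmapped", "secondary", "supplementary", "duplicate", "low_mapq")


class UndefinedFractionError(ZeroDivisionError):
    """Raised when the mtDNA fraction denominator is zero."""


@dataclass
class AlignmentRecord:
    """One aligned read with the fields the analysis consumes."""

    qname: str
    flag: int
    contig: str | None
    pos: int  # 1-based leftmost coordinate; 0 when unmapped
    mapq: int
    tlen: int
    tags: dict[str, str] = field(default_factory=dict)

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FLAG_UNMAPPED)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flag & FLAG_SECONDARY)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flag & FLAG_SUPPLEMENTARY)

    @property
    def is_duplicate(self) -> bool:
        return bool(self.flag & FLAG_DUPLICATE)

    @property
    def is_first_in_pair(self) -> bool:
        return bool(self.flag & FLAG_FIRST_IN_PAIR)

    @property
    def is_paired(self) -> bool:
        return bool(self.flag & FLAG_PAIRED)


@dataclass
class FilterCounts:
    """Single-pass filter bookkeeping for one alignment file."""

    total_records: int = 0
    excluded_by_reason: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in EXCLUSION_PRECEDENCE}
    )
    reads_aligned: int = 0
    reads_chrM: int = 0

    def __add__(self, other: "FilterCounts") -> "FilterCounts":
        merged = {
            r: self.excluded_by_reason.get(r, 0) + other.excluded_by_reason.get(r, 0)
            for r in EXCLUSION_PRECEDENCE
        }
        return FilterCounts(
            total_records=self.total_records + other.total_records,
            excluded_by_reason=merged,
            reads_aligned=self.reads_aligned + other.reads_aligned,
            reads_chrM=self.reads_chrM + other.reads_chrM,
        )


@dataclass
class SampleProfile:
    """Per-sample quantification result."""

    sample_id: str
    filter_counts: FilterCounts
    p_mtdna: float | None  # percent; None when no aligned reads
    size_histogram: dict[int, int]
    size_summary: dict[str, float] | None

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "total_records": self.filter_counts.total_records,
            "excluded_by_reason": dict(self.filter_counts.excluded_by_reason),
            "reads_aligned": self.filter_counts.reads_aligned,
            "reads_chrM": self.filter_counts.reads_chrM,
            "p_mtdna": self.p_mtdna,
            "size_histogram": {str(k): v for k, v in sorted(self.size_histogram.items())},
            "size_summary": self.size_summary,
        }


def resolve_mito_contig(name: str) -> str:
    """Map mitochondrial contig aliases (MT, chrMT) onto a canonical name."""
    return MITO_ALIASES.get(name, name)


def exclusion_reason(record: AlignmentRecord) -> str | None:
    """Reason a record fails the filters, or None if it passes.

    Precedence is fixed (unmapped > secondary > supplementary > duplicate >
    low_mapq) so the reasons partition the excluded records.
    """
    if record.is_unmapped:
        return "unmapped"
    if record.is_secondary:
        return "secondary"
    if record.is_supplementary:
        return "supplementary"
    if record.is_duplicate:
        return "duplicate"
    if record.mapq < MAPQ_THRESHOLD:
        return "low_mapq"
    return None


def passes_filters(record: AlignmentRecord) -> bool:
    """True iff mapped, primary, non-supplementary, non-duplicate, MAPQ >= 30."""
    return exclusion_reason(record) is None


def count_reads(
    records: Iterable[AlignmentRecord], mito_contig: str = DEFAULT_MITO_CONTIG
) -> FilterCounts:
    """Count filter-passing records overall and on the mitochondrial contig.

    Each record is charged to exactly one exclusion reason or counted as
    aligned; the chrM subset is selected by exact contig-name match.
    """
    counts = FilterCounts()
    for rec in records:
        counts.total_records += 1
        reason = exclusion_reason(rec)
        if reason is not None:
            counts.excluded_by_reason[reason] += 1
        else:
            counts.reads_aligned += 1
            if rec.contig == mito_contig:
                counts.reads_chrM += 1
    return counts


def mtdna_fraction(counts: FilterCounts) -> float:
    """mtDNA fraction in percent: 100 * reads_chrM / reads_aligned.

    Raises UndefinedFractionError when no reads pass the filters — an
    undefined fraction is distinct from a measured zero.
    """
    if counts.reads_aligned == 0:
        raise UndefinedFractionError(
            "mtDNA fraction undefined: zero filter-passing aligned reads"
        )
    return 100.0 * counts.reads_chrM / counts.reads_aligned


def size_profile(
    records: Iterable[AlignmentRecord], contig: str = DEFAULT_MITO_CONTIG
) -> dict[int, int]:
    """Fragment-length histogram {bp: template count} for one contig.

    Counts |template_length| once per template via the first-in-pair record
    (unpaired records are counted directly), restricted to 1..1000 bp.
    Records are expected to be filter-passing already. Zero-length
    templates are skipped and logged.
    """
    hist: Counter[int] = Counter()
    skipped_zero = 0
    for rec in records:
        if rec.contig != contig:
            continue
        if rec.is_paired and not rec.is_first_in_pair:
            continue
        length = abs(rec.tlen)
        if length == 0:
            skipped_zero += 1
            continue
        if length <= MAX_FRAGMENT_BP:
            hist[length] += 1
    if skipped_zero:
        logger.info("size_profile: skipped %d zero-length templates", skipped_zero)
    return dict(hist)


def summarize_profile(hist: Mapping[int, int]) -> dict[str, float]:
    """n, median and mode of a fragment-length histogram.

    Median is the weighted median (lower of the two central values at even
    n); mode is the most frequent length, smallest length on ties.
    """
    if not hist or sum(hist.values()) == 0:
        raise ValueError("cannot summarize an empty size histogram")
    lengths = np.array(sorted(hist.keys()), dtype=np.int64)
    counts = np.array([hist[int(l)] for l in lengths], dtype=np.int64)
    n = int(counts.sum())
    cum = np.cumsum(counts)
    # lower central value: first length whose cumulative count reaches
    # ceil(n/2); at even n this is the lower of the two central values
    median = int(lengths[np.searchsorted(cum, (n + 1) // 2)])
    mode = int(lengths[np.argmax(counts)])  # argmax takes the first (= smallest) tie
    return {"n": n, "median_bp": median, "mode_bp": mode}


def _expand(hist: Mapping[int, int]) -> np.ndarray:
    lengths = np.array(sorted(hist.keys()), dtype=np.int64)
    counts = np.array([hist[int(l)] for l in lengths], dtype=np.int64)
    return np.repeat(lengths, counts)


def compare_profiles(
    hist_a: Mapping[int, int], hist_b: Mapping[int, int]
) -> dict[str, float]:
    """Two-sample KS and Mann-Whitney comparison of two size histograms.

    Both tests run on the expanded samples; the Mann-Whitney U uses
    midranks for ties with the asymptotic two-sided p value.
    """
    if not hist_a or not hist_b:
        raise ValueError("compare_profiles requires two non-empty histograms")
    a, b = _expand(hist_a), _expand(hist_b)
    ks = sps.ks_2samp(a, b, method="asymp")
    mw = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return {
        "ks_D": float(ks.statistic),
        "ks_p": float(ks.pvalue),
        "mw_U": float(mw.statistic),
        "mw_p": float(mw.pvalue),
    }


# ---------------------------------------------------------------------------
# Vectorized fast path over generator-produced SAM (fixed column count).
# The streaming path above is the reference; the two are tested for exact
# agreement. BAM and ragged SAM inputs go through cfmito.io.read_alignments.
# ---------------------------------------------------------------------------

def _sam_header_lines(path: str) -> int:
    n = 0
    with open(path, "rt") as fh:
        for line in fh:
            if line.startswith("@"):
                n += 1
            else:
                break
    return n


def _read_sam_columns(path: str, usecols: list[int]) -> pd.DataFrame | None:
    """Read selected SAM columns with the pandas C engine.

    Returns None when the file is ragged (variable column count), in which
    case callers fall back to the streaming path.
    """
    skip = _sam_header_lines(path)
    with open(path, "rt") as fh:
        for _ in range(skip):
            fh.readline()
        first = fh.readline()
    if not first:
        return pd.DataFrame({c: [] for c in usecols})
    ncol = first.count("\t") + 1
    try:
        return pd.read_csv(
            path,
            sep="\t",
            header=None,
            skiprows=skip,
            names=list(range(ncol)),
            usecols=usecols,
            quoting=3,
            dtype={1: np.int64, 4: np.int64, 8: np.int64},
        )
    except (pd.errors.ParserError, ValueError):
        return None


def _vector_pass_mask(flag: np.ndarray, mapq: np.ndarray) -> np.ndarray:
    bad_bits = FLAG_UNMAPPED | FLAG_SECONDARY | FLAG_SUPPLEMENTARY | FLAG_DUPLICATE
    return ((flag & bad_bits) == 0) & (mapq >= MAPQ_THRESHOLD)


def count_sam_file(path: str, mito_contig: str = DEFAULT_MITO_CONTIG) -> FilterCounts:
    """FilterCounts for a SAM file via the vectorized fast path.

    Falls back to the record-streaming path for ragged files.
    """
    df = _read_sam_columns(path, usecols=[1, 2, 4])
    if df is None:
        from .io import read_alignments

        return count_reads(read_alignments(path), mito_contig)
    flag = df[1].to_numpy(np.int64)
    mapq = df[4].to_numpy(np.int64)
    contig = df[2].to_numpy()
    passing = _vector_pass_mask(flag, mapq)
    reasons = {
        "unmapped": (flag & FLAG_UNMAPPED) != 0,
        "secondary": (flag & FLAG_SECONDARY) != 0,
        "supplementary": (flag & FLAG_SUPPLEMENTARY) != 0,
        "duplicate": (flag & FLAG_DUPLICATE) != 0,
        "low_mapq": mapq < MAPQ_THRESHOLD,
    }
    excluded = {}
    claimed = np.zeros(len(df), dtype=bool)
    for reason in EXCLUSION_PRECEDENCE:
        mask = reasons[reason] & ~claimed
        excluded[reason] = int(mask.sum())
        claimed |= mask
    return FilterCounts(
        total_records=len(df),
        excluded_by_reason=excluded,
        reads_aligned=int(passing.sum()),
        reads_chrM=int((passing & (contig == mito_contig)).sum()),
    )


def profile_sam_file(path: str, mito_contig: str = DEFAULT_MITO_CONTIG) -> dict[int, int]:
    """Filter-passing mitochondrial fragment-size histogram for a SAM file."""
    df = _read_sam_columns(path, usecols=[1, 2, 4, 8])
    if df is None:
        from .io import read_alignments

        recs = (r for r in read_alignments(path) if passes_filters(r))
        return size_profile(recs, mito_contig)
    flag = df[1].to_numpy(np.int64)
    mapq = df[4].to_numpy(np.int64)
    contig = df[2].to_numpy()
    tlen = np.abs(df[8].to_numpy(np.int64))
    first = ((flag & FLAG_PAIRED) == 0) | ((flag & FLAG_FIRST_IN_PAIR) != 0)
    keep = (
        _vector_pass_mask(flag, mapq)
        & (contig == mito_contig)
        & first
        & (tlen >= 1)
        & (tlen <= MAX_FRAGMENT_BP)
    )
    lengths, counts = np.unique(tlen[keep], return_counts=True)
    return {int(l): int(c) for l, c in zip(lengths, counts)}


def quantify_file(
    path: str, sample_id: str, mito_contig: str = DEFAULT_MITO_CONTIG
) -> SampleProfile:
    """Full per-sample quantification: filters, mtDNA fraction, size profile.

    SAM inputs use the vectorized path; BAM inputs stream through pysam.
    """
    mito_contig = resolve_mito_contig(mito_contig)
    if str(path).endswith(".sam"):
        counts = count_sam_file(path, mito_contig)
        hist = profile_sam_file(path, mito_contig)
    else:
        from .io import read_alignments

        counts = FilterCounts()
        hist_counter: Counter[int] = Counter()
        for rec in read_alignments(path):
            counts.total_records += 1
            reason = exclusion_reason(rec)
            if reason is not None:
                counts.excluded_by_reason[reason] += 1
                continue
            counts.reads_aligned += 1
            if rec.contig == mito_contig:
                counts.reads_chrM += 1
                if not rec.is_paired or rec.is_first_in_pair:
                    length = abs(rec.tlen)
                    if 1 <= length <= MAX_FRAGMENT_BP:
                        hist_counter[length] += 1
        hist = dict(hist_counter)
    p = mtdna_fraction(counts) if counts.reads_aligned > 0 else None
    summary = summarize_profile(hist) if hist else None
    return SampleProfile(sample_id, counts, p, hist, summary)
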