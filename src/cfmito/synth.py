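"""Synthetic references, alignments and cohorts for plasma mtDNA analysis.

Generates the inputs the downstream analysis assumes, with ground-truth
manifests so every stage can be tested by round-trip recovery:

* seeded random FASTA references (human-like nuclear contig + the 16,569 bp
  mitochondrial contig, optionally a second-species copy of both),
* per-sample paired-end alignment files (SAM) in which the compartment of
  each template (tumor/normal x mitochondrial/nuclear, human/mouse) is
  drawn from configured fractions and carried as ground-truth tags,
* cohort metadata tables with center-specific batch shifts, a tumor-fraction
  signal correlated with cancer status, and an mtDNA-fraction distribution
  calibrated so its marginal median matches the 0.0032% observed in plasma,
* a 13-animal xenograft cohort in which human (tumor) read counts scale
  with the peritoneal cancer index while mouse (normal) counts do not.

Everything is a pure function of (config, seed); fragment lengths are
encoded in the template-length field, the mitochondrial contig is
linearized and fragments never span the circular origin.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.stats import norm

DEFAULT_MITO_LENGTH = 16_569  # bp, human mitochondrial genome
MOUSE_MITO_LENGTH = 16_299  # bp, mouse mitochondrial genome
DEFAULT_NUCLEAR_LENGTH = 1_000_000
READ_LENGTH = 150  # bp, paired-end read length used for emitted records

HUMAN_NUCLEAR = "chr1"
HUMAN_MITO = "chrM"
MOUSE_NUCLEAR = "chr1_mm"
MOUSE_MITO = "chrM_mm"

COMPARTMENTS = ("mt_tumor", "mt_normal", "nuclear_tumor", "nuclear_normal")

#: ground-truth SAM tags carried on every emitted record
TAG_SPECIES = "XS"
TAG_COMPARTMENT = "XC"


class SimulationConfigError(ValueError):
    """Invalid generator configuration."""


# ---------------------------------------------------------------------------
# References
# ---------------------------------------------------------------------------

@dataclass
class ReferenceSet:
    """Named contigs and their lengths; content is seeded-random A/C/G/T."""

    contigs: dict[str, int]
    nuclear_contig_name: str = HUMAN_NUCLEAR
    mito_contig_name: str = HUMAN_MITO
    fasta_path: str | None = None

    def __post_init__(self) -> None:
        if len(set(self.contigs)) != len(self.contigs):
            raise SimulationConfigError("contig names must be unique")
        for name, length in self.contigs.items():
            if length <= 0:
                raise SimulationConfigError(f"contig {name!r} has non-positive length")


def make_references(
    out_fasta: str,
    nuclear_length: int = DEFAULT_NUCLEAR_LENGTH,
    mito_length: int = DEFAULT_MITO_LENGTH,
    nuclear_name: str = HUMAN_NUCLEAR,
    mito_name: str = HUMAN_MITO,
    second_species: bool = False,
    seed: int = 0,
) -> ReferenceSet:
    """Write a FASTA reference set and return its description.

    Only names and lengths matter downstream; sequence content is random.
    """
    contigs = {nuclear_name: int(nuclear_length), mito_name: int(mito_length)}
    if second_species:
        contigs[MOUSE_NUCLEAR] = int(nuclear_length)
        contigs[MOUSE_MITO] = MOUSE_MITO_LENGTH
    if nuclear_name == mito_name:
        raise SimulationConfigError("contig names must be unique")
    ref = ReferenceSet(contigs, nuclear_name, mito_name, out_fasta)
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    with open(out_fasta, "wt") as fh:
        for name, length in contigs.items():
            fh.write(f">{name}\n")
            seq = rng.choice(bases, size=length)
            for start in range(0, length, 80):
                fh.write(seq[start : start + 80].tobytes().decode())
                fh.write("\n")
    return ref


# ---------------------------------------------------------------------------
# Fragment-size distributions
# ---------------------------------------------------------------------------

@dataclass
class SizeDistributionSpec:
    """Named generative fragment-length distribution.

    Families: ``lognormal`` (params mu, sigma of log length),
    ``mixture_lognormal`` (params components = [(weight, mu, sigma), ...])
    and ``empirical`` (params lengths, weights). Sampling always returns
    integer lengths inside ``support``.
    """

    name: str
    family: str
    params: dict
    support: tuple[int, int] = (1, 1000)

    def __post_init__(self) -> None:
        lo, hi = self.support
        if not (1 <= lo <= hi <= 1000):
            raise SimulationConfigError(f"invalid support {self.support}")
        if self.family not in ("lognormal", "mixture_lognormal", "empirical"):
            raise SimulationConfigError(f"unknown family {self.family!r}")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n integer fragment lengths within the support."""
        if n < 0:
            raise SimulationConfigError("n must be >= 0")
        if n == 0:
            return np.zeros(0, dtype=np.int64)
        lo, hi = self.support
        if self.family == "empirical":
            lengths = np.asarray(self.params["lengths"], dtype=np.int64)
            weights = np.asarray(self.params["weights"], dtype=float)
            weights = weights / weights.sum()
            return rng.choice(lengths, size=n, p=weights)
        if self.family == "lognormal":
            comps = [(1.0, self.params["mu"], self.params["sigma"])]
        else:
            comps = self.params["components"]
        weights = np.array([c[0] for c in comps], dtype=float)
        weights /= weights.sum()
        which = rng.choice(len(comps), size=n, p=weights)
        mu = np.array([c[1] for c in comps])[which]
        sigma = np.array([c[2] for c in comps])[which]
        out = np.rint(np.exp(rng.normal(mu, sigma))).astype(np.int64)
        bad = (out < lo) | (out > hi)
        while bad.any():  # rejection keeps samples inside the support
            k = int(bad.sum())
            redraw = np.rint(np.exp(rng.normal(mu[bad], sigma[bad]))).astype(np.int64)
            out[bad] = redraw
            bad = (out < lo) | (out > hi)
        return out


def _peaked_empirical(name: str, mode: int, tau_left: float = 9.0,
                      tau_right: float = 18.0, support: tuple[int, int] = (30, 340),
                      broad_weight: float = 0.15) -> SizeDistributionSpec:
    """Short-fragment profile with a sharp, recoverable mode.

    A two-sided exponential peak blended with a broad lognormal base,
    mimicking the short, sub-nucleosomal mtDNA fragment profile seen in
    plasma while keeping the mode decisively identifiable at desk-scale n.
    """
    lengths = np.arange(support[0], support[1] + 1)
    peak = np.where(
        lengths <= mode,
        np.exp(-(mode - lengths) / tau_left),
        np.exp(-(lengths - mode) / tau_right),
    )
    broad = np.exp(-((np.log(lengths) - math.log(120.0)) ** 2) / (2 * 0.45**2)) / lengths
    w = (1 - broad_weight) * peak / peak.sum() + broad_weight * broad / broad.sum()
    return SizeDistributionSpec(
        name, "empirical", {"lengths": lengths, "weights": w}, support
    )


#: packaged presets; medians/modes match the profiles the analysis targets
PRESETS: dict[str, SizeDistributionSpec] = {
    # xenograft: tumor-derived mtDNA is markedly shorter than host mtDNA
    "xeno_tumor_mt": SizeDistributionSpec(
        "xeno_tumor_mt", "lognormal", {"mu": math.log(57.0), "sigma": 0.35}
    ),
    "xeno_normal_mt": SizeDistributionSpec(
        "xeno_normal_mt", "lognormal", {"mu": math.log(155.0), "sigma": 0.25}
    ),
    # human plasma mtDNA: modal lengths 84 bp (cancer) / 86 bp (healthy)
    "human_cancer_mt": _peaked_empirical("human_cancer_mt", 84),
    "human_healthy_mt": _peaked_empirical("human_healthy_mt", 86),
    # nucleosome-protected nuclear cfDNA, ~166 bp
    "nuclear_cf": SizeDistributionSpec(
        "nuclear_cf", "lognormal", {"mu": math.log(166.0), "sigma": 0.18}
    ),
}


def get_preset(name: str) -> SizeDistributionSpec:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown size preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def sample_fragment_lengths(
    spec: SizeDistributionSpec | str, n: int, seed: int
) -> np.ndarray:
    """Seeded fragment-length sample from a spec or packaged preset name."""
    if isinstance(spec, str):
        spec = get_preset(spec)
    return spec.sample(n, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# Per-sample alignment simulation
# ---------------------------------------------------------------------------

@dataclass
class SampleSimConfig:
    sample_id: str = "sample"
    n_templates: int = 2_000_000
    mtdna_fraction_true: float = 0.0032  # percent of filter-passing reads
    tumor_fraction_true: float = 0.0  # proportion of templates tumor-derived
    size_spec_mt_tumor: str = "human_cancer_mt"
    size_spec_mt_normal: str = "human_healthy_mt"
    size_spec_nuclear: str = "nuclear_cf"
    duplicate_rate: float = 0.0
    low_mapq_rate: float = 0.0
    secondary_rate: float = 0.0
    unmapped_rate: float = 0.0
    species_mix: float = 0.0  # proportion of second-species (mouse) templates
    seed: int = 0

    def validate(self) -> None:
        if self.n_templates <= 0:
            raise SimulationConfigError("n_templates must be > 0")
        if not 0 <= self.mtdna_fraction_true <= 100:
            raise SimulationConfigError("mtdna_fraction_true must be in [0, 100] percent")
        for attr in ("tumor_fraction_true", "duplicate_rate", "low_mapq_rate",
                     "secondary_rate", "unmapped_rate", "species_mix"):
            v = getattr(self, attr)
            if not 0 <= v <= 1:
                raise SimulationConfigError(f"{attr} must be in [0, 1], got {v}")


@dataclass
class SampleTruth:
    """Ground truth written alongside each simulated alignment file.

    ``template_counts`` maps (species, compartment) to clean template
    counts; filter-passing read counts are exactly twice these.
    """

    sample_id: str
    template_counts: dict[tuple[str, str], int]
    n_templates: int
    true_mtdna_fraction: float  # percent, refers to filter-passing reads
    true_tumor_fraction: float
    seed: int

    def __post_init__(self) -> None:
        assert sum(self.template_counts.values()) == self.n_templates

    def to_json(self, path: str) -> None:
        payload = {
            "sample_id": self.sample_id,
            "template_counts": {
                f"{sp}:{comp}": n for (sp, comp), n in self.template_counts.items()
            },
            "n_templates": self.n_templates,
            "true_mtdna_fraction": self.true_mtdna_fraction,
            "true_tumor_fraction": self.true_tumor_fraction,
            "seed": self.seed,
        }
        with open(path, "wt") as fh:
            json.dump(payload, fh, indent=1)

    @staticmethod
    def from_json(path: str) -> "SampleTruth":
        with open(path) as fh:
            payload = json.load(fh)
        counts = {
            tuple(k.split(":")): v for k, v in payload["template_counts"].items()
        }
        return SampleTruth(
            payload["sample_id"], counts, payload["n_templates"],
            payload["true_mtdna_fraction"], payload["true_tumor_fraction"],
            payload["seed"],
        )


def _sam_header(ref: ReferenceSet) -> str:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for name, length in ref.contigs.items():
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    return "\n".join(lines) + "\n"


def _render_block(out, qbase: str, start_id: int, contig: str, positions, lengths,
                  species: str, compartment: str, mapq: int = 60,
                  chunk: int = 250_000) -> None:
    """Render paired records (flags 99/147) for one compartment block."""
    lines: list[str] = []
    tag = f"XS:Z:{species}\tXC:Z:{compartment}"
    for i, (p, L) in enumerate(zip(positions.tolist(), lengths.tolist())):
        rl = L if L < READ_LENGTH else READ_LENGTH
        p2 = p + L - rl
        q = f"{qbase}:{start_id + i}"
        lines.append(f"{q}\t99\t{contig}\t{p}\t{mapq}\t{rl}M\t=\t{p2}\t{L}\t*\t*\t{tag}")
        lines.append(f"{q}\t147\t{contig}\t{p2}\t{mapq}\t{rl}M\t=\t{p}\t{-L}\t*\t*\t{tag}")
        if len(lines) >= chunk:
            out.write("\n".join(lines) + "\n")
            lines.clear()
    if lines:
        out.write("\n".join(lines) + "\n")


def _compartment_blocks(cfg: SampleSimConfig, ref: ReferenceSet):
    """(species, compartment, contig) cells and their template probabilities."""
    pm = cfg.mtdna_fraction_true / 100.0
    tf = cfg.tumor_fraction_true
    mix = cfg.species_mix
    cells = [
        ("human", "mt_tumor", ref.mito_contig_name, (1 - mix) * pm * tf),
        ("human", "mt_normal", ref.mito_contig_name, (1 - mix) * pm * (1 - tf)),
        ("human", "nuclear_tumor", ref.nuclear_contig_name, (1 - mix) * (1 - pm) * tf),
        ("human", "nuclear_normal", ref.nuclear_contig_name, (1 - mix) * (1 - pm) * (1 - tf)),
        ("mouse", "mt_normal", MOUSE_MITO, mix * pm),
        ("mouse", "nuclear_normal", MOUSE_NUCLEAR, mix * (1 - pm)),
    ]
    if mix > 0 and MOUSE_MITO not in ref.contigs:
        raise SimulationConfigError(
            "species_mix > 0 requires references generated with second_species=True"
        )
    return cells


def simulate_sample(
    cfg: SampleSimConfig, ref: ReferenceSet, out_dir: str
) -> tuple[str, SampleTruth]:
    """Emit one sample's paired-end SAM plus its ground-truth manifest.

    The configured mtDNA fraction refers to filter-passing reads: noise
    records (duplicates, secondary, low-MAPQ, unmapped) are injected on
    top of the clean template set and are all rejected by the filters.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    cells = _compartment_blocks(cfg, ref)
    probs = np.array([c[3] for c in cells])
    counts = rng.multinomial(cfg.n_templates, probs / probs.sum())

    spec_for = {
        "mt_tumor": get_preset(cfg.size_spec_mt_tumor),
        "mt_normal": get_preset(cfg.size_spec_mt_normal),
        "nuclear_tumor": get_preset(cfg.size_spec_nuclear),
        "nuclear_normal": get_preset(cfg.size_spec_nuclear),
    }

    sam_path = os.path.join(out_dir, f"{cfg.sample_id}.sam")
    truth_counts: dict[tuple[str, str], int] = {}
    clean_records = 0
    # remember a few positions to source duplicate/secondary copies from
    copy_sources: list[str] = []
    with open(sam_path, "wt") as out:
        out.write(_sam_header(ref))
        qid = 0
        for (species, comp, contig, _), n in zip(cells, counts):
            truth_counts[(species, comp)] = int(n)
            if n == 0:
                continue
            clen = ref.contigs[contig]
            lengths = spec_for[comp].sample(int(n), rng)
            lengths = np.minimum(lengths, clen)  # fragments fit the contig
            positions = rng.integers(1, clen - lengths + 2)
            _render_block(out, cfg.sample_id, qid, contig, positions, lengths,
                          species, comp)
            rl = min(int(lengths[0]), READ_LENGTH)
            p, L = int(positions[0]), int(lengths[0])
            copy_sources.append(
                f"{cfg.sample_id}:{qid}\t{{flag}}\t{contig}\t{p}\t60\t{rl}M\t=\t"
                f"{p + L - rl}\t{L}\t*\t*\tXS:Z:{species}\tXC:Z:{comp}"
            )
            qid += int(n)
            clean_records += 2 * int(n)

        _inject_noise(out, cfg, ref, rng, clean_records, copy_sources)

    truth = SampleTruth(
        cfg.sample_id, truth_counts, cfg.n_templates,
        cfg.mtdna_fraction_true, cfg.tumor_fraction_true, cfg.seed,
    )
    truth.to_json(os.path.join(out_dir, f"{cfg.sample_id}.truth.json"))
    return sam_path, truth


def _inject_noise(out, cfg: SampleSimConfig, ref: ReferenceSet,
                  rng: np.random.Generator, clean_records: int,
                  copy_sources: list[str]) -> None:
    """Append filter-failing records at the configured rates."""
    n_dup = int(round(cfg.duplicate_rate * clean_records))
    n_sec = int(round(cfg.secondary_rate * clean_records))
    n_low = int(round(cfg.low_mapq_rate * clean_records))
    n_unm = int(round(cfg.unmapped_rate * clean_records))
    lines: list[str] = []
    if copy_sources:
        for i in range(n_dup):  # copies of existing records, duplicate bit set
            src = copy_sources[int(rng.integers(len(copy_sources)))]
            lines.append(src.format(flag=99 | 0x400))
        for i in range(n_sec):
            src = copy_sources[int(rng.integers(len(copy_sources)))]
            lines.append(src.format(flag=99 | 0x100))
    contig = ref.nuclear_contig_name
    clen = ref.contigs[contig]
    if n_low:
        mapqs = rng.integers(0, 30, n_low)  # uniform on 0..29
        poss = rng.integers(1, clen - READ_LENGTH, n_low)
        for i in range(n_low):
            lines.append(
                f"lowq:{i}\t99\t{contig}\t{poss[i]}\t{mapqs[i]}\t{READ_LENGTH}M\t=\t"
                f"{poss[i]}\t{READ_LENGTH}\t*\t*\tXS:Z:none\tXC:Z:noise"
            )
    for i in range(n_unm):
        lines.append(f"unm:{i}\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\tXS:Z:none\tXC:Z:noise")
    if lines:
        out.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

#: cancer types whose plasma mtDNA fraction is elevated in the generator
ELEVATED_TYPES = frozenset(
    {"cholangiocarcinoma", "colorectal", "liver", "pancreatic", "prostate"}
)
CANCER_TYPES = (
    "breast", "cholangiocarcinoma", "colorectal", "glioblastoma", "liver",
    "lung", "melanoma", "ovarian", "pancreatic", "prostate", "renal",
)
STAGES = ("I", "II", "III", "IV")


@dataclass
class CenterBlock:
    """One collection center's composition and batch shifts."""

    label: str
    n_healthy: int
    n_cancer: dict[str, int]
    mt_batch_factor: float = 1.0  # multiplicative on measured mtDNA fraction
    tf_batch_shift: float = 0.0  # additive on measured tumor fraction


@dataclass
class CohortSimConfig:
    centers: list[CenterBlock]
    mt_median_overall: float = 0.0032  # percent; marginal calibration anchor
    mt_log_sigma: float = 0.35  # inter-individual spread of log mtDNA fraction
    mt_elevated_multiplier: float = 2.0
    mt_other_cancer_multiplier: float = 1.1
    tf_cancer_median: float = 0.02
    tf_log_sigma: float = 1.0
    tf_healthy_scale: float = 0.012  # half-normal noise floor; healthy TF ~ 0
    mt_tf_rho: float = 0.4  # copula correlation linking TF and mtDNA in cancer
    maf_rate: float = 0.7  # fraction of cancer samples with a MAF assay
    maf_log_sd: float = 0.3
    measurement_log_sigma: float = 0.09  # feature-only stand-in for counting noise
    n_templates: int = 2_000_000  # per-sample templates in read mode
    seed: int = 0

    def type_multiplier(self, cancer_type: str | None) -> float:
        if cancer_type is None:
            return 1.0
        if cancer_type in ELEVATED_TYPES:
            return self.mt_elevated_multiplier
        return self.mt_other_cancer_multiplier


def default_cohort_config(seed: int = 0) -> CohortSimConfig:
    """855-sample three-center cohort (200 healthy, 655 cancer)."""
    centers = [
        CenterBlock("A", 60, {"breast": 80, "melanoma": 40},
                    mt_batch_factor=1.3, tf_batch_shift=0.002),
        CenterBlock("U", 100, {
            "cholangiocarcinoma": 40, "colorectal": 50, "liver": 30,
            "pancreatic": 35, "prostate": 40, "breast": 50, "lung": 45,
            "ovarian": 45, "melanoma": 40, "renal": 30, "glioblastoma": 30,
        }),
        CenterBlock("N", 40, {"lung": 100},
                    mt_batch_factor=0.8, tf_batch_shift=0.0),
    ]
    return CohortSimConfig(centers=centers, seed=seed)


def default_read_cohort_config(seed: int = 0, n_templates: int = 400_000) -> CohortSimConfig:
    """Scaled-down cohort for read-mode (alignment-emitting) runs."""
    centers = [
        CenterBlock("A", 4, {"breast": 5, "melanoma": 5},
                    mt_batch_factor=1.3, tf_batch_shift=0.002),
        CenterBlock("U", 7, {
            "cholangiocarcinoma": 3, "colorectal": 5, "liver": 3,
            "pancreatic": 3, "prostate": 3, "breast": 4, "lung": 3,
            "ovarian": 3, "melanoma": 3, "renal": 2, "glioblastoma": 2,
        }),
        CenterBlock("N", 3, {"lung": 7}, mt_batch_factor=0.8),
    ]
    return CohortSimConfig(centers=centers, seed=seed, n_templates=n_templates)


def _calibrate_base_median(cfg: CohortSimConfig) -> float:
    """Solve for the healthy-sample median so the marginal median of the
    measured mtDNA fraction equals ``mt_median_overall``.

    The marginal is a mixture of lognormal components, one per
    (center, group); each component's median is base x type multiplier x
    center batch factor."""
    comps: list[tuple[float, float]] = []  # (weight, log multiplier)
    for c in cfg.centers:
        comps.append((c.n_healthy, math.log(c.mt_batch_factor)))
        for t, n in c.n_cancer.items():
            comps.append((n, math.log(cfg.type_multiplier(t) * c.mt_batch_factor)))
    total = sum(w for w, _ in comps)
    sigma = math.hypot(cfg.mt_log_sigma, cfg.measurement_log_sigma)
    target = math.log(cfg.mt_median_overall)

    def mixture_cdf_minus_half(log_base: float) -> float:
        acc = sum(
            w * norm.cdf((target - (log_base + lm)) / sigma) for w, lm in comps
        )
        return acc / total - 0.5

    log_base = optimize.brentq(mixture_cdf_minus_half, target - 5, target + 5)
    return math.exp(log_base)


def simulate_cohort(
    cfg: CohortSimConfig,
    out_dir: str,
    feature_only: bool = True,
    references: ReferenceSet | None = None,
):
    """Generate a cohort table (+ per-sample alignments in read mode).

    Returns ``(cohort_df, truth_df, sam_paths)``; ``sam_paths`` is None in
    feature-only mode. In feature-only mode the ``p_mtdna`` column holds
    truth-plus-noise measurements; in read mode it is left missing and is
    filled by the quantification stage from the emitted alignments.

    Per-sample seeds are spawned as ``cfg.seed + sample index``.
    """
    import pandas as pd

    if not cfg.centers or all(
        c.n_healthy == 0 and sum(c.n_cancer.values()) == 0 for c in cfg.centers
    ):
        raise SimulationConfigError("empty cohort")
    os.makedirs(out_dir, exist_ok=True)
    base = _calibrate_base_median(cfg)
    rng = np.random.default_rng(cfg.seed)
    rows, truth_rows = [], []
    sam_paths: dict[str, str] | None = None if feature_only else {}
    if not feature_only:
        if references is None:
            references = make_references(
                os.path.join(out_dir, "reference.fa"),
                nuclear_length=10_000, seed=cfg.seed,
            )
        os.makedirs(os.path.join(out_dir, "alignments"), exist_ok=True)

    idx = 0
    for center in cfg.centers:
        groups = [(None, center.n_healthy)] + sorted(center.n_cancer.items())
        for cancer_type, n in groups:
            for _ in range(n):
                sample_id = f"{center.label}{idx:04d}"
                sample_seed = int((cfg.seed + idx) % (2**31))
                is_cancer = cancer_type is not None
                z1, z2 = rng.standard_normal(2)
                mt_true = base * cfg.type_multiplier(cancer_type) * math.exp(
                    cfg.mt_log_sigma * z1
                )
                if is_cancer:
                    # Gaussian copula links log TF to log mtDNA fraction
                    z_tf = cfg.mt_tf_rho * z1 + math.sqrt(1 - cfg.mt_tf_rho**2) * z2
                    tf = min(cfg.tf_cancer_median * math.exp(cfg.tf_log_sigma * z_tf), 1.0)
                    stage = STAGES[int(rng.integers(len(STAGES)))]
                else:
                    tf = abs(rng.normal(0.0, cfg.tf_healthy_scale))
                    stage = None
                tf_obs = min(max(tf + center.tf_batch_shift, 0.0), 1.0)
                if is_cancer and rng.random() < cfg.maf_rate:
                    maf = min(tf * math.exp(rng.normal(0.0, cfg.maf_log_sd)), 1.0)
                else:
                    maf = np.nan
                mt_apparent = mt_true * center.mt_batch_factor
                row = {
                    "sample_id": sample_id,
                    "center": center.label,
                    "status": "cancer" if is_cancer else "healthy",
                    "cancer_type": cancer_type,
                    "tnm_stage": stage,
                    "tf_ichor": tf_obs,
                    "maf": maf,
                }
                if feature_only:
                    row["p_mtdna"] = mt_apparent * math.exp(
                        rng.normal(0.0, cfg.measurement_log_sigma)
                    )
                else:
                    row["p_mtdna"] = np.nan
                    scfg = SampleSimConfig(
                        sample_id=sample_id,
                        n_templates=cfg.n_templates,
                        mtdna_fraction_true=mt_apparent,
                        tumor_fraction_true=tf if is_cancer else 0.0,
                        seed=sample_seed,
                    )
                    path, _ = simulate_sample(
                        scfg, references, os.path.join(out_dir, "alignments")
                    )
                    sam_paths[sample_id] = path
                rows.append(row)
                truth_rows.append({
                    "sample_id": sample_id,
                    "true_mtdna_fraction": mt_true,
                    "apparent_mtdna_fraction": mt_apparent,
                    "true_tf": tf,
                    "seed": sample_seed,
                })
                idx += 1

    cohort = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    os.makedirs(out_dir, exist_ok=True)
    from .io import write_cohort

    write_cohort(cohort, os.path.join(out_dir, "cohort.tsv"))
    truth.to_csv(os.path.join(out_dir, "cohort.truth.tsv"), sep="\t", index=False)
    return cohort, truth, sam_paths


# ---------------------------------------------------------------------------
# Xenograft simulation
# ---------------------------------------------------------------------------

#: default peritoneal cancer index values for the 13-animal cohort
DEFAULT_PCI = (3, 5, 6, 8, 9, 11, 13, 15, 18, 21, 24, 28, 33)

#: tumor mtDNA read-count model: mean reads = floor + slope * PCI, with a
#: gamma latent factor shared with nuclear reads (overdispersion + the
#: strong mt/nuclear coupling seen across animals)
XENO_MT_FLOOR = 21.0
XENO_MT_SLOPE = 8.4
XENO_LATENT_SHAPE = 8.0
XENO_NORMAL_MT_MEAN = 2717.0
XENO_NORMAL_MT_SHAPE = 15.0
XENO_NUCLEAR_RATIO = 40.0  # tumor nuclear reads per tumor mtDNA read
XENO_MOUSE_NUCLEAR_MEAN = 50_000.0


def simulate_xenograft_cohort(
    out_dir: str,
    n_animals: int = 13,
    pci_values: Sequence[float] | None = None,
    seed: int = 0,
    mt_floor: float = XENO_MT_FLOOR,
    mt_slope: float = XENO_MT_SLOPE,
    latent_shape: float = XENO_LATENT_SHAPE,
    normal_mt_mean: float = XENO_NORMAL_MT_MEAN,
    normal_mt_shape: float = XENO_NORMAL_MT_SHAPE,
    nuclear_ratio: float = XENO_NUCLEAR_RATIO,
    mouse_nuclear_mean: float = XENO_MOUSE_NUCLEAR_MEAN,
):
    """Simulate a mixed-species xenograft plasma cohort.

    Human (tumor) read counts increase stochastically with the peritoneal
    cancer index; mouse (normal) counts are PCI-independent. Tumor mtDNA
    fragments use the ``xeno_tumor_mt`` preset, host mtDNA the
    ``xeno_normal_mt`` preset. Returns (manifest_df, truth_df, sam_paths);
    truth counts are filter-passing reads per (species, compartment).
    """
    import pandas as pd

    if n_animals <= 0:
        raise SimulationConfigError("n_animals must be > 0")
    if pci_values is None:
        pci_values = DEFAULT_PCI[:n_animals] if n_animals <= len(DEFAULT_PCI) else None
    if pci_values is None or len(pci_values) != n_animals:
        raise SimulationConfigError("pci_values length must equal n_animals")
    if any(p < 0 for p in pci_values):
        raise SimulationConfigError("PCI values must be >= 0")

    os.makedirs(out_dir, exist_ok=True)
    ref = make_references(
        os.path.join(out_dir, "reference.fa"),
        nuclear_length=100_000, second_species=True, seed=seed,
    )
    rng = np.random.default_rng(seed)
    spec_tumor_mt = get_preset("xeno_tumor_mt")
    spec_normal_mt = get_preset("xeno_normal_mt")
    spec_nuclear = get_preset("nuclear_cf")

    manifest_rows, truth_rows, sam_paths = [], [], {}
    for a, pci in enumerate(pci_values):
        animal_id = f"xeno{a:02d}"
        mean_reads = mt_floor + mt_slope * float(pci)
        latent = rng.gamma(latent_shape, 1.0 / latent_shape)
        # template counts; reads = 2 x templates (paired-end emission)
        t_mt = int(rng.poisson(latent * mean_reads / 2.0))
        t_nuc = int(rng.poisson(latent * mean_reads * nuclear_ratio / 2.0))
        host_latent = rng.gamma(normal_mt_shape, 1.0 / normal_mt_shape)
        n_mt = int(rng.poisson(host_latent * normal_mt_mean / 2.0))
        n_nuc = int(rng.poisson(mouse_nuclear_mean / 2.0))

        sam_path = os.path.join(out_dir, f"{animal_id}.sam")
        with open(sam_path, "wt") as out:
            out.write(_sam_header(ref))
            qid = 0
            for species, comp, contig, spec, n in [
                ("human", "mt_tumor", HUMAN_MITO, spec_tumor_mt, t_mt),
                ("human", "nuclear_tumor", HUMAN_NUCLEAR, spec_nuclear, t_nuc),
                ("mouse", "mt_normal", MOUSE_MITO, spec_normal_mt, n_mt),
                ("mouse", "nuclear_normal", MOUSE_NUCLEAR, spec_nuclear, n_nuc),
            ]:
                if n == 0:
                    continue
                clen = ref.contigs[contig]
                lengths = np.minimum(spec.sample(n, rng), clen)
                positions = rng.integers(1, clen - lengths + 2)
                _render_block(out, animal_id, qid, contig, positions, lengths,
                              species, comp)
                qid += n
        sam_paths[animal_id] = sam_path
        manifest_rows.append({"animal_id": animal_id, "pci": float(pci)})
        truth_rows.append({
            "animal_id": animal_id, "pci": float(pci),
            "tumor_mt_reads": 2 * t_mt, "normal_mt_reads": 2 * n_mt,
            "tumor_nuclear_reads": 2 * t_nuc, "normal_nuclear_reads": 2 * n_nuc,
        })

    manifest = pd.DataFrame(manifest_rows)
    truth = pd.DataFrame(truth_rows)
    manifest.to_csv(os.path.join(out_dir, "animals.tsv"), sep="\t", index=False)
    truth.to_csv(os.path.join(out_dir, "animals.truth.tsv"), sep="\t", index=False)
    return manifest, truth, sam_paths
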