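# Methods

`cfmito` implements a plasma mitochondrial-DNA (mtDNA) liquid-biopsy
analysis: quantification of the mtDNA fraction of cell-free DNA (cfDNA)
from whole-genome-sequencing alignments, mitochondrial fragmentomics, a
xenograft tumor-vs-host read split, cohort-level group statistics, and
integration of the mtDNA fraction with a copy-number-derived tumor
fraction for cancer detection. Because the real cohorts behind this kind
of analysis are controlled-access, the package ships a first-class
synthetic-data generator that emulates the statistical structure the
analysis assumes; every stage is validated by round-trip recovery against
generated ground truth.

## mtDNA fraction

A record passes the quality filters iff it is mapped, primary,
non-supplementary, not a PCR duplicate, and has MAPQ >= 30. The mtDNA
fraction of a sample is

    P_mtDNA [%] = reads_chrM / reads_aligned x 100

with both counts taken over filter-passing records (samtools-style read
counting; the denominator includes the chrM reads themselves). A zero
denominator is an error, not a zero: an undefined fraction must not be
confused with a measured absence of mtDNA. Counting charges each excluded
record to exactly one reason under a fixed precedence (unmapped >
secondary > supplementary > duplicate > low-MAPQ) so that the exclusion
counts plus the aligned count partition the file; the precedence is a
package convention, since the filters themselves do not imply one.

Fragment sizes are read from the template-length (TLEN) field, counted
once per template via the first-in-pair record, and restricted to
1–1000 bp (the conventional insert-size histogram width). Summary
conventions are fixed and documented: the median is the weighted median
with the lower central value taken at even n; the mode is the most
frequent length with ties broken toward the smaller length. Two-sample
profile comparisons use the two-sample Kolmogorov–Smirnov statistic and
the two-sided Mann–Whitney U with midrank tie handling, both computed on
the expanded samples.

Two equivalent quantification paths exist: a record-streaming path
(pysam, works for SAM and BAM) and a vectorized path over the fixed
column layout the generator emits. They are tested for exact agreement;
the vectorized path exists because desk-scale validation pushes tens of
millions of records through the quantifier.

## Synthetic data generator

The generator is the package's stand-in for the wet lab and the aligner:
it emits already-aligned paired-end records whose compartment
(mitochondrial/nuclear x tumor/normal x human/mouse) is drawn from
configured fractions and carried as per-read tags (`XS` species, `XC`
compartment), so the quantifier can be tested blind or unblinded.

Key conventions:

* References are seeded-random A/C/G/T; only names and lengths matter.
  The mitochondrial contig is 16,569 bp (the human mitochondrial genome),
  emitted linearized; fragments never span the circular origin. The mouse
  mitochondrial contig is 16,299 bp. The default nuclear contig is 1 Mbp
  — a length proxy, since no positional feature of the nuclear genome is
  used downstream.
* Fragment lengths come from named size distributions. Packaged presets:
  `xeno_tumor_mt` (lognormal, median 57 bp, log-sd 0.35) and
  `xeno_normal_mt` (lognormal, median 155 bp, log-sd 0.25) for the
  xenograft compartments; `human_cancer_mt` (mode 84 bp) and
  `human_healthy_mt` (mode 86 bp) for human plasma mtDNA, built as a
  two-sided exponential peak (decay 9 bp left / 18 bp right) blended with
  a broad lognormal base — sharply peaked enough that the sample mode at
  n = 50,000 is within 1 bp of the configured mode, while keeping a
  plausible short-fragment profile; `nuclear_cf` (lognormal, median
  166 bp, log-sd 0.18) for nucleosome-protected nuclear cfDNA. Sampling
  is integer-valued, seeded, and rejection-bounded to each preset's
  support.
* The configured mtDNA fraction refers to filter-passing reads. Noise
  records — duplicate copies (flag 0x400), secondary copies (0x100),
  fresh low-MAPQ records (MAPQ uniform on 0–29) and unmapped records —
  are injected on top of the clean template set at configured rates, so
  filters must reject all of them to recover the truth. Because both
  mates of a template share its compartment, the estimated fraction is
  exactly binomial in the number of templates, which gives the recovery
  tests a closed-form error model: the estimate should sit within
  3·sqrt(p(1−p)/n_templates) of truth in ≈99.7% of replicates.
* Determinism: every output is a pure function of (config, seed);
  per-sample seeds are spawned as global seed + sample index.

### Cohort model

A cohort is defined per collection center (labels A, U, N) with healthy
and per-cancer-type sample counts; the default cohort has 855 samples
(200 healthy, 655 cancer over 11 types across the three centers, center N
lung-only). Per-sample quantities:

* True mtDNA fraction: lognormal. Cancer types known to show elevated
  plasma mtDNA (cholangiocarcinoma, colorectal, liver, pancreatic,
  prostate) get a x2.0 median multiplier; other types x1.1; healthy x1.0.
  The base median is solved numerically (mixture-CDF root) so that the
  marginal median of the measured fraction equals the calibration anchor
  of 0.0032%. The inter-individual log-sd defaults to 0.35, a modeling
  choice: no generative model of inter-individual mtDNA variability is
  available to copy, and the published summary ("median 0.0032%, range
  0.0017–0.0047%") is ambiguous about what the range covers; 0.35 gives a
  cohort spread between the min–max and IQR readings of that summary.
* Tumor fraction (TF): healthy samples have true TF 0 plus a half-normal
  noise floor (scale 0.012) emulating the uncertainty floor of
  copy-number-based TF estimation; cancer TF is lognormal (median 0.02,
  log-sd 1.0), leaving a substantial sub-3% "undetectable" mass. Within
  cancer samples, log TF and log mtDNA fraction are linked by a Gaussian
  copula (rho 0.4): correlated, but each carrying independent signal.
  These scales place the single-feature and combined detection
  performance in the regime the analysis is designed for (TF-only AUC
  ≈ 0.72, mtDNA-only ≈ 0.62, combined ≈ 0.75).
* Batch effects: per center, a multiplicative factor on the measured
  mtDNA fraction (defaults 1.3 / 1.0 / 0.8 for A / U / N) and a small
  additive shift on TF. TNM stage is assigned independently of the mtDNA
  fraction (matching the observation that plasma mtDNA largely does not
  track stage). MAF is present for 70% of cancer samples as TF times
  lognormal noise.
* Modes: feature-only mode writes truth-plus-noise measurements directly
  (log-sd 0.09, the counting noise of a ~2M-template sample) and is used
  for classifier-scale work; read mode emits per-sample alignments and
  leaves `p_mtdna` to be filled by the quantifier. The default read-mode
  cohort is 65 samples x 400,000 templates — chosen so that a full
  simulate-and-quantify round trip runs in a couple of minutes while the
  cohort-median recovery stays well inside the +-15% validation band.

### Xenograft model

13 animals with peritoneal cancer index (PCI) values 3–33. Tumor (human)
mitochondrial read counts are Poisson draws around a gamma latent factor
(shape 8) times a linear tumor-load mean, floor 21 + 8.4 reads per PCI
unit; tumor nuclear counts share the same latent factor (ratio 40), which
produces the strong tumor-nuclear/tumor-mtDNA coupling and a positive but
noisy PCI correlation. Host (mouse) mitochondrial counts are
PCI-independent negative-binomial draws with mean 2717 reads (shape 15);
host nuclear counts default to 50,000 reads. The floor/slope/dispersion
were set so the across-animal median counts sit at the calibration
anchors (124 tumor, 2717 host mitochondrial reads). With 13 animals the
median of the tumor counts is itself noisy (sd ≈ 21 reads), so
calibration checks average the median over replicate simulated cohorts
rather than trusting a single draw. A stronger dispersion would push the
PCI correlation down toward the weak-correlation regime seen in small
animal cohorts, but at the cost of making the median anchors meaningless
at n = 13; the package prioritizes the count anchors.

What the generator does **not** model: sequence content (no error model,
GC bias, mappability), the alignment step itself, NUMT (nuclear-
mitochondrial) segments, read trimming, or within-animal fragment-length
heterogeneity. Passing round-trip tests therefore demonstrates the
correctness of the analysis code under the stated statistical
assumptions, not robustness to alignment artifacts in real data.

## Xenograft analysis

Species assignment prefers ground-truth tags; without tags it compares
per-species alignment scores, with exact ties called ambiguous and
excluded from every count — an analog of best-alignment read splitting,
not a clone of any aligner. Per-animal summaries are 2x2 filter-passing
read counts by (species, mitochondrial/nuclear). Mitochondrial reads are
pooled across animals before fragmentation analysis (tumor mtDNA is too
sparse per animal), with pooled counts equal to per-length sums.
Correlations of tumor mtDNA counts with PCI and with tumor nuclear counts
are Pearson r with two-sided t-based p.

## Cohort statistics

Pairwise group comparisons default to the two-sided Wilcoxon rank-sum
test; across-group comparisons (stages, types) use Kruskal–Wallis with
tie correction. For small comparisons (both groups <= 10) the rank-sum p
is computed by exhaustive enumeration over all group assignments using
midranks, which handles ties exactly and makes identical groups give
p = 1; larger comparisons use the tie-corrected asymptotic p. Star labels
are inclusive: **** p <= 1e-4, *** p <= 1e-3, ** p <= 0.01, * p <= 0.05,
else ns. Raw p values are reported (a Benjamini–Hochberg toggle exists,
default off). TF detectability uses the strict < 3% convention for
"undetectable", so TF = 0.03 is detectable. Missing TF/MAF are excluded
pairwise per analysis, never imputed as zero. The analysis plan emits a
tidy table; analyses that cannot run on a given cohort (no healthy
samples in a center, all-missing feature) emit a row with a reason rather
than failing the report.

## Batch metric and detection

The batch-effect–negated metric maps each sample's feature point
(default coordinates: mtDNA fraction, ichorCNA TF) to

    d = ||x − m_cancer|| / ||x − m_healthy||

where m_cancer and m_healthy are the coordinate-wise medians of that
sample's collection center's cancer and healthy samples (an explicit
designated-sample mode is the alternative). Features are z-scored within
center before the distance (raw mode available): the two coordinates
differ by orders of magnitude, and z-scoring makes d invariant to
per-center multiplicative batch effects. d < 1 means closer to the cancer
control; a point equal to the healthy control maps to +inf (logged);
coincident controls are an error. d is invariant to joint translation and
joint positive rescaling of point and controls, and the d = 1 locus is
the perpendicular bisector hyperplane of the two controls — all tested to
1e-12.

Detection evaluation: per iteration (default 50), the cohort is randomly
balanced (majority class down-sampled to the minority size — balancing is
re-drawn per iteration with derived seeds so the confidence intervals
reflect balancing variability; a balance-once mode exists), split into a
stratified 80/20 train/test partition, and a random forest (500 trees,
sqrt feature candidates, unbounded depth, seeded) is trained. Accuracy
uses the 0.5 probability threshold; AUC is the rank-based (Mann–Whitney)
statistic with ties counted half, which equals pair-enumeration exactly.
Summaries are the mean and the empirical 2.5–97.5 percentile interval
over iterations; feature sets ({d}, {TF}, {d, TF}) are compared pairwise
by rank-sum on the iteration-level metric distributions. The
mtDNA-feature model uses d in place of the raw fraction (configurable);
note d is computed from both coordinates, so the "mtDNA" model is more
precisely "batch-corrected mtDNA-anchored". Leave-one-cancer-out mode
excludes one cancer type from the training pool at a time and reports
both the held-in test performance and the excluded type scored against
held-out healthy samples; types with fewer than 2 samples are skipped
with a log entry.

## Numerical and degenerate-input conventions

* Fractions are carried at full floating precision; rounding only at
  display.
* Empty histograms, empty groups, constant correlation inputs, cohorts
  missing a class, and zero aligned reads are errors with named causes,
  not silent zeros.
* Validation problem sizes (20 recovery seeds at 2M templates, 65-sample
  read-mode cohort, 8–12 replicate xenograft cohorts, 10 classifier
  seeds x 25 iterations) were chosen as the package's own desk-scale
  defaults: large enough that each check's Monte-Carlo error is small
  against its tolerance.

## Known limitations

* Real-cohort headline numbers (per-type effect sizes, cohort AUCs)
  depend on controlled-access data and are not reproduced here; the
  synthetic cohort reproduces the structure, not the exact effect sizes.
* No NUMT masking: reads from nuclear-mitochondrial segments would
  inflate P_mtDNA on real data; the generator does not emit them.
* The score-compare species split is a simplified stand-in for two-genome
  competitive alignment; its ambiguity handling (exclusion) is a
  convention.
* The xenograft PCI correlation regime is stronger than in small real
  cohorts (see above); treat the simulated correlation magnitude as a
  property of the generator, not a prediction.
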