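# cfmito

Analysis of circulating mitochondrial DNA (mtDNA) in plasma
whole-genome-sequencing (WGS) liquid biopsies.

Cell-free DNA (cfDNA) in plasma contains a small mitochondrial component
— on the order of 0.003% of aligned reads — whose abundance and
fragmentation carry information about the presence of cancer. `cfmito`
is a toolkit for researchers working with such data. It provides:

* **Quantification** — apply the standard read filters (mapped, primary,
  non-supplementary, non-duplicate, MAPQ >= 30) and compute the mtDNA
  fraction

      P_mtDNA [%] = reads_chrM / reads_aligned x 100

  together with the mitochondrial fragment-size histogram from template
  lengths (1–1000 bp, counted once per template), summary statistics
  (weighted median / mode with fixed tie conventions) and two-sample
  profile comparisons (Kolmogorov–Smirnov, Mann–Whitney).
* **Xenograft split** — partition reads of a human-tumor-in-mouse plasma
  sample by species of origin, tabulate tumor (human) vs normal (mouse)
  mitochondrial and nuclear read counts per animal, pool mitochondrial
  reads across animals for fragmentation analysis, and correlate tumor
  mtDNA with tumor load (peritoneal cancer index).
* **Cohort statistics** — Wilcoxon rank-sum / Kruskal–Wallis comparisons
  of the mtDNA fraction by cancer status, stage and type with the usual
  star conventions, Pearson correlation with the copy-number tumor
  fraction (TF) and mutant allele fraction, and the TF >= 3%
  detectability partition.
* **Batch metric + detection** — a per-center distance-ratio metric
  d = dist(x, median cancer) / dist(x, median healthy) that negates
  center batch effects, and a repeated (default 50x) balanced,
  stratified-80/20, random-forest evaluation of the feature sets
  {mtDNA metric}, {TF} and {combined}, reporting accuracy and rank-based
  AUC with empirical 95% confidence intervals.
* **Synthetic data** — seeded generators for references (16,569 bp
  mitochondrial contig), per-sample paired-end alignments with
  ground-truth species/compartment tags and configurable noise
  (duplicates, secondary, low-MAPQ, unmapped), multi-center cohort
  tables with batch effects, and a 13-animal xenograft cohort. Every
  analysis stage is validated by round-trip recovery against generated
  truth; see `docs/methods.md` for the generative models and their
  limitations.

## Worked example

Simulate a plasma sample at the typical mtDNA abundance and quantify it:

```python
import tempfile, os
from cfmito import (SampleSimConfig, make_references, simulate_sample,
                    quantify_file)

d = tempfile.mkdtemp()
ref = make_references(os.path.join(d, "ref.fa"), seed=0)   # chr1 + 16,569 bp chrM
cfg = SampleSimConfig(sample_id="demo", n_templates=2_000_000,
                      mtdna_fraction_true=0.0032, seed=0)
sam, truth = simulate_sample(cfg, ref, d)

profile = quantify_file(sam, "demo")
print(f"reads_aligned={profile.filter_counts.reads_aligned}",
      f"reads_chrM={profile.filter_counts.reads_chrM}",
      f"p_mtdna={profile.p_mtdna:.5f}%")
print("fragment sizes:", profile.size_summary)
```

prints

```
reads_aligned=4000000 reads_chrM=124 p_mtdna=0.00310%
fragment sizes: {'n': 62, 'median_bp': 94, 'mode_bp': 83}
```

— 62 of 2,000,000 templates landed on chrM, so the estimated fraction
0.00310% sits within binomial counting error of the configured 0.0032%
(1 SD here is 0.00040 percentage points), and the mitochondrial
fragments are short (median 94 bp) as expected for plasma mtDNA.

Cohort-level detection on a synthetic 855-sample, three-center cohort:

```python
from cfmito import (default_cohort_config, simulate_cohort,
                    apply_batch_correction, evaluate_feature_sets)

cohort, truth, _ = simulate_cohort(default_cohort_config(seed=1), d)
corrected = apply_batch_correction(cohort)          # adds the d metric
evals, pairwise = evaluate_feature_sets(corrected, n_iter=50, seed=1)
for e in evals:
    print(e.feature_set, round(e.mean_auc, 3),
          [round(v, 3) for v in e.ci_auc])
```

prints

```
mtDNA 0.633 [0.54, 0.757]
ichorCNA 0.736 [0.643, 0.819]
combined 0.767 [0.675, 0.852]
```

— the combined model outperforms either single feature because the
simulated mtDNA signal is partly independent of the tumor fraction
(some cancers shed mtDNA without detectable copy-number signal).

A CLI mirrors the library: `cfmito simulate|quantify|xeno|stats|classify|run`
(see `cfmito --help`). Cohort tables are TSV (UTF-8, `.` for missing);
alignments are SAM/BAM with standard FLAG semantics.

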