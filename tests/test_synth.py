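"""Synthetic-data generator: references, size presets, samples, cohorts."""

import math
import os

import numpy as np
import pytest
from Bio import SeqIO

from cfmito.quant import count_sam_file, mtdna_fraction
from cfmito.synth import (
    CenterBlock,
    CohortSimConfig,
    SampleSimConfig,
    SampleTruth,
    SimulationConfigError,
    SizeDistributionSpec,
    default_cohort_config,
    default_read_cohort_config,
    get_preset,
    make_references,
    sample_fragment_lengths,
    simulate_cohort,
    simulate_sample,
    simulate_xenograft_cohort,
)


class TestReferences:
    def test_default_mito_length(self, tmp_path):
        ref = make_references(str(tmp_path / "r.fa"), seed=1)
        assert ref.contigs["chrM"] == 16_569
        rec = {r.id: r for r in SeqIO.parse(str(tmp_path / "r.fa"), "fasta")}
        assert len(rec["chrM"].seq) == 16_569

    def test_nuclear_length_roundtrip(self, tmp_path):
        make_references(str(tmp_path / "r.fa"), nuclear_length=10_000, seed=1)
        rec = {r.id: r for r in SeqIO.parse(str(tmp_path / "r.fa"), "fasta")}
        assert len(rec["chr1"].seq) == 10_000

    def test_duplicate_contig_names_rejected(self, tmp_path):
        with pytest.raises(SimulationConfigError):
            make_references(str(tmp_path / "r.fa"), nuclear_name="chrM")

    def test_nonpositive_length_rejected(self, tmp_path):
        with pytest.raises(SimulationConfigError):
            make_references(str(tmp_path / "r.fa"), nuclear_length=0)


class TestFragmentSampling:
    def test_n_zero_is_empty(self):
        assert len(sample_fragment_lengths("xeno_tumor_mt", 0, 1)) == 0

    def test_unknown_preset_lists_available(self):
        with pytest.raises(KeyError, match="xeno_tumor_mt"):
            sample_fragment_lengths("no_such_preset", 10, 1)

    def test_determinism(self):
        a = sample_fragment_lengths("human_cancer_mt", 1000, 42)
        b = sample_fragment_lengths("human_cancer_mt", 1000, 42)
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("name", ["xeno_tumor_mt", "xeno_normal_mt",
                                      "human_cancer_mt", "human_healthy_mt",
                                      "nuclear_cf"])
    def test_support_respected(self, name):
        spec = get_preset(name)
        x = sample_fragment_lengths(name, 5_000, 2)
        lo, hi = spec.support
        assert x.min() >= lo and x.max() <= hi
        assert x.dtype.kind == "i"

    def test_monte_carlo_median(self):
        x = sample_fragment_lengths("xeno_tumor_mt", 50_000, 1)
        assert abs(np.median(x) - 57) <= 2

    def test_mixture_family(self):
        spec = SizeDistributionSpec(
            "mix", "mixture_lognormal",
            {"components": [(0.5, math.log(60), 0.1), (0.5, math.log(200), 0.1)]},
        )
        x = spec.sample(5_000, np.random.default_rng(0))
        # clearly bimodal: mass near both component medians
        assert ((x > 45) & (x < 80)).mean() > 0.3
        assert ((x > 150) & (x < 260)).mean() > 0.3

    def test_invalid_support_rejected(self):
        with pytest.raises(SimulationConfigError):
            SizeDistributionSpec("bad", "lognormal", {"mu": 4, "sigma": 0.3},
                                 support=(0, 100))


class TestSimulateSample:
    def test_truth_conservation_and_tags(self, references, tmp_path):
        cfg = SampleSimConfig(sample_id="t", n_templates=10_000,
                              mtdna_fraction_true=1.0, tumor_fraction_true=0.4,
                              species_mix=0.25, seed=5)
        sam, truth = simulate_sample(cfg, references, str(tmp_path))
        assert sum(truth.template_counts.values()) == 10_000
        reloaded = SampleTruth.from_json(str(tmp_path / "t.truth.json"))
        assert reloaded.template_counts == truth.template_counts

    def test_zero_fraction_means_zero_chrm(self, references, tmp_path):
        cfg = SampleSimConfig(sample_id="z", n_templates=5_000,
                              mtdna_fraction_true=0.0, seed=1)
        sam, _ = simulate_sample(cfg, references, str(tmp_path))
        assert count_sam_file(sam).reads_chrM == 0

    def test_pure_mouse_mixture(self, references, tmp_path):
        cfg = SampleSimConfig(sample_id="m", n_templates=2_000,
                              mtdna_fraction_true=1.0, species_mix=1.0, seed=1)
        _, truth = simulate_sample(cfg, references, str(tmp_path))
        human = sum(n for (sp, _), n in truth.template_counts.items() if sp == "human")
        assert human == 0

    def test_mouse_mix_requires_second_species(self, tmp_path):
        ref = make_references(str(tmp_path / "h.fa"), nuclear_length=10_000, seed=1)
        cfg = SampleSimConfig(species_mix=0.5, n_templates=100)
        with pytest.raises(SimulationConfigError):
            simulate_sample(cfg, ref, str(tmp_path))

    @pytest.mark.parametrize("field,value", [
        ("n_templates", 0), ("mtdna_fraction_true", 101.0),
        ("tumor_fraction_true", -0.1), ("duplicate_rate", 1.5),
    ])
    def test_config_validation(self, field, value):
        cfg = SampleSimConfig(**{field: value})
        with pytest.raises(SimulationConfigError):
            cfg.validate()

    def test_recovery_within_three_binomial_sd(self, references, tmp_path):
        """Quantifier recovers the configured fraction within 3 binomial
        SDs in at least 19 of 20 seeded replicates (clean rates)."""
        p_pct, n = 0.1, 200_000
        sd_pct = 100 * math.sqrt((p_pct / 100) * (1 - p_pct / 100) / n)
        misses = 0
        for seed in range(20):
            cfg = SampleSimConfig(sample_id=f"r{seed}", n_templates=n,
                                  mtdna_fraction_true=p_pct, seed=seed)
            sam, _ = simulate_sample(cfg, references, str(tmp_path))
            est = mtdna_fraction(count_sam_file(sam))
            if abs(est - p_pct) > 3 * sd_pct:
                misses += 1
            os.unlink(sam)
        assert misses <= 1


class TestSimulateCohort:
    def test_default_cohort_shape(self, tmp_path):
        cohort, truth, paths = simulate_cohort(
            default_cohort_config(seed=3), str(tmp_path), feature_only=True
        )
        assert len(cohort) == 855
        counts = cohort.groupby("status").size()
        assert counts["healthy"] == 200 and counts["cancer"] == 655
        assert paths is None
        # healthy rows carry no type or stage
        healthy = cohort[cohort["status"] == "healthy"]
        assert healthy["cancer_type"].isna().all()
        assert healthy["tnm_stage"].isna().all()

    def test_feature_only_determinism(self, tmp_path):
        c1, _, _ = simulate_cohort(default_cohort_config(seed=5),
                                   str(tmp_path / "a"), feature_only=True)
        c2, _, _ = simulate_cohort(default_cohort_config(seed=5),
                                   str(tmp_path / "b"), feature_only=True)
        assert c1.equals(c2)

    def test_marginal_median_calibration(self, tmp_path):
        cohort, _, _ = simulate_cohort(default_cohort_config(seed=17),
                                       str(tmp_path), feature_only=True)
        # 855 samples: Monte-Carlo error on the median is a few percent
        assert cohort["p_mtdna"].median() == pytest.approx(0.0032, rel=0.10)

    def test_empty_cohort_rejected(self, tmp_path):
        cfg = CohortSimConfig(centers=[CenterBlock("X", 0, {})])
        with pytest.raises(SimulationConfigError):
            simulate_cohort(cfg, str(tmp_path))

    def test_healthy_tf_near_zero(self, tmp_path):
        cohort, _, _ = simulate_cohort(default_cohort_config(seed=2),
                                       str(tmp_path), feature_only=True)
        healthy_tf = cohort.loc[cohort["status"] == "healthy", "tf_ichor"]
        assert (healthy_tf < 0.08).all()


class TestXenograftCohort:
    def test_argument_validation(self, tmp_path):
        with pytest.raises(SimulationConfigError):
            simulate_xenograft_cohort(str(tmp_path), n_animals=0)
        with pytest.raises(SimulationConfigError):
            simulate_xenograft_cohort(str(tmp_path), n_animals=3, pci_values=[1, 2])
        with pytest.raises(SimulationConfigError):
            simulate_xenograft_cohort(str(tmp_path), n_animals=2, pci_values=[1, -2])

    def test_truth_counts_and_files(self, tmp_path):
        manifest, truth, paths = simulate_xenograft_cohort(
            str(tmp_path), n_animals=3, pci_values=[2, 10, 30], seed=4,
            mouse_nuclear_mean=2_000, nuclear_ratio=5.0,
        )
        assert len(manifest) == 3 and set(paths) == set(manifest["animal_id"])
        assert (truth[["tumor_mt_reads", "normal_mt_reads"]] >= 0).all().all()
        # read counts are even: paired-end emission
        assert (truth["tumor_mt_reads"] % 2 == 0).all()

    def test_tumor_counts_track_pci(self, tmp_path):
        """Expected tumor mtDNA counts increase with PCI: positive Pearson
        correlation in >= 19/20 seeded replicates (small fast cohorts)."""
        from scipy.stats import pearsonr

        positives = 0
        for seed in range(20):
            _, truth, _ = simulate_xenograft_cohort(
                str(tmp_path / f"s{seed}"), seed=seed,
                mouse_nuclear_mean=200.0, nuclear_ratio=0.5, normal_mt_mean=200.0,
            )
            r, _ = pearsonr(truth["pci"], truth["tumor_mt_reads"])
            positives += r > 0
        assert positives >= 19
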