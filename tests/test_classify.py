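"""Distance-ratio batch metric and random-forest detection evaluation."""

import math

import numpy as np
import pandas as pd
import pytest

from cfmito.classify import (
    CenterControls,
    DegenerateControlsError,
    FeaturePoint,
    apply_batch_correction,
    auc_rank,
    balance_cohort,
    batch_metric,
    center_controls,
    evaluate_feature_sets,
    leave_one_cancer_out,
    run_iteration,
)


def controls(cancer, healthy):
    names = tuple(f"f{i}" for i in range(len(cancer)))
    return CenterControls("X", FeaturePoint(names, np.array(cancer, float)),
                          FeaturePoint(names, np.array(healthy, float)))


class TestBatchMetric:
    def test_equidistant_point(self):
        assert batch_metric(np.array([0.0, 1.0]), controls([-1, 0], [1, 0])) == 1.0

    def test_point_at_cancer_control(self):
        assert batch_metric(np.array([2.0, 3.0]), controls([2, 3], [0, 0])) == 0.0

    def test_three_four_five_triangle(self):
        # point (3,4): distance 5 to (0,0), distance 4 to (3,0)
        assert batch_metric(np.array([3.0, 4.0]), controls([0, 0], [3, 0])) == 1.25

    def test_point_at_healthy_control_is_infinite(self):
        assert batch_metric(np.array([1.0, 1.0]), controls([0, 0], [1, 1])) == math.inf

    def test_coincident_controls_rejected(self):
        with pytest.raises(DegenerateControlsError):
            controls([1, 1], [1, 1])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            batch_metric(np.array([1.0]), controls([0, 0], [1, 1]))

    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p, c, h, shift = rng.normal(size=(4, 2))
            d0 = batch_metric(p, controls(c, h))
            d1 = batch_metric(p + shift, controls(c + shift, h + shift))
            assert d1 == pytest.approx(d0, rel=1e-12)

    def test_joint_scaling_invariance(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            p, c, h = rng.normal(size=(3, 2))
            s = float(rng.uniform(0.1, 50))
            d0 = batch_metric(p, controls(c, h))
            d1 = batch_metric(s * p, controls(s * c, s * h))
            assert d1 == pytest.approx(d0, rel=1e-12)

    def test_unit_locus_is_perpendicular_bisector(self):
        c, h = np.array([1.0, 0.0]), np.array([-1.0, 0.0])
        for y in (-3.0, 0.0, 7.0):
            assert batch_metric(np.array([0.0, y]), controls(c, h)) == pytest.approx(1.0)


class TestCenterControls:
    def _cohort(self, cancer_vals, healthy_vals):
        rows = [{"sample_id": f"c{i}", "center": "A", "status": "cancer",
                 "p_mtdna": v, "tf_ichor": 0.1} for i, v in enumerate(cancer_vals)]
        rows += [{"sample_id": f"h{i}", "center": "A", "status": "healthy",
                  "p_mtdna": v, "tf_ichor": 0.0} for i, v in enumerate(healthy_vals)]
        return pd.DataFrame(rows)

    def test_singleton_controls_equal_samples(self):
        cc = center_controls(self._cohort([4.0], [1.0]), "A")
        assert cc.cancer_control.values[0] == 4.0
        assert cc.healthy_control.values[0] == 1.0

    def test_odd_n_median(self):
        cc = center_controls(self._cohort([1.0, 2.0, 9.0], [0.0]), "A")
        assert cc.cancer_control.values[0] == 2.0

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError, match="healthy"):
            center_controls(self._cohort([1.0], []), "A")


class TestApplyBatchCorrection:
    def _two_center_cohort(self, rng, factor_b=1.0):
        rows = []
        for center, factor in (("A", 1.0), ("B", factor_b)):
            for i in range(30):
                mt = rng.lognormal(0, 0.3) * (3.0 if i < 15 else 1.0) * factor
                rows.append({
                    "sample_id": f"{center}{i}", "center": center,
                    "status": "cancer" if i < 15 else "healthy",
                    "p_mtdna": mt, "tf_ichor": (0.1 if i < 15 else 0.01)
                    + rng.normal(0, 0.005),
                })
        return pd.DataFrame(rows)

    def test_scale_invariance_under_zscoring(self):
        """Multiplying one center's mtDNA fraction by 10 leaves that
        center's d_metric unchanged when features are z-scored."""
        rng = np.random.default_rng(3)
        base = self._two_center_cohort(rng)
        scaled = base.copy()
        scaled.loc[scaled["center"] == "B", "p_mtdna"] *= 10
        d0 = apply_batch_correction(base)["d_metric"]
        d1 = apply_batch_correction(scaled)["d_metric"]
        assert np.allclose(d0, d1, rtol=1e-9, equal_nan=True)

    def test_separated_clusters_order_medians(self):
        rng = np.random.default_rng(4)
        df = apply_batch_correction(self._two_center_cohort(rng))
        med = df.groupby("status")["d_metric"].median()
        assert med["healthy"] > med["cancer"]

    def test_missing_features_leave_missing_metric(self):
        rng = np.random.default_rng(5)
        df = self._two_center_cohort(rng)
        df.loc[df.index[0], "tf_ichor"] = np.nan
        out = apply_batch_correction(df)
        assert np.isnan(out["d_metric"].iloc[0])
        assert out["d_metric"].iloc[1:].notna().all()

    def test_unknown_scaling_rejected(self):
        with pytest.raises(ValueError):
            apply_batch_correction(pd.DataFrame(), scaling="quantile")


class TestBalanceCohort:
    def _cohort(self, n_cancer, n_healthy):
        return pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n_cancer + n_healthy)],
            "status": ["cancer"] * n_cancer + ["healthy"] * n_healthy,
        })

    def test_downsampled_to_minority(self):
        out = balance_cohort(self._cohort(655, 200), seed=1)
        assert len(out) == 400
        assert (out.groupby("status").size() == 200).all()

    def test_already_balanced_unchanged_membership(self):
        df = self._cohort(5, 5)
        out = balance_cohort(df, seed=2)
        assert sorted(out["sample_id"]) == sorted(df["sample_id"])

    def test_seed_determinism(self):
        df = self._cohort(30, 10)
        a = balance_cohort(df, seed=7)
        b = balance_cohort(df, seed=7)
        assert a.equals(b)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            balance_cohort(self._cohort(5, 0), seed=1)


def brute_force_auc(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAucRank:
    def test_single_dominated_pair(self):
        assert auc_rank([0.9, 0.1], [1, 0]) == 1.0

    def test_all_ties(self):
        assert auc_rank([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    @pytest.mark.parametrize("scores,labels", [
        ([0.9, 0.8, 0.3, 0.7, 0.2, 0.1], [1, 1, 1, 0, 0, 0]),
        ([0.5, 0.5, 0.4, 0.5, 0.6, 0.4], [1, 1, 1, 0, 0, 0]),
        ([0.1, 0.9, 0.2, 0.8], [1, 1, 0, 0]),
    ])
    def test_matches_pair_enumeration(self, scores, labels):
        assert auc_rank(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels)
        )

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            auc_rank([0.1, 0.2], [1, 1])


def _informative_cohort(rng, n=120, separable=False):
    rows = []
    for i in range(n):
        cancer = i < n // 2
        if separable:
            x = rng.uniform(10, 20) if cancer else rng.uniform(0, 5)
        else:
            x = rng.normal(1.0 if cancer else 0.0, 1.0)
        rows.append({"sample_id": f"s{i}", "center": "A",
                     "status": "cancer" if cancer else "healthy",
                     "cancer_type": ("liver" if i % 2 else "lung") if cancer else None,
                     "x": float(x),
                     "y": float(rng.normal(0.5 if cancer else 0.0, 1.0))})
    return pd.DataFrame(rows)


class TestRunIteration:
    def test_perfectly_separable(self):
        rng = np.random.default_rng(0)
        df = _informative_cohort(rng, separable=True)
        out = run_iteration(df[["x"]].to_numpy(),
                            (df["status"] == "cancer").to_numpy(int), seed=1,
                            n_trees=50)
        assert out["auc"] == 1.0 and out["accuracy"] == 1.0

    def test_too_few_per_class_rejected(self):
        with pytest.raises(ValueError):
            run_iteration(np.zeros((3, 1)), np.array([1, 0, 0]), seed=1)


class TestEvaluateFeatureSets:
    def test_determinism_and_ci_collapse(self):
        rng = np.random.default_rng(2)
        df = _informative_cohort(rng)
        sets = (("x", ("x",)),)
        e1, _ = evaluate_feature_sets(df, sets, n_iter=1, seed=9, n_trees=30)
        e2, _ = evaluate_feature_sets(df, sets, n_iter=1, seed=9, n_trees=30)
        assert e1[0].iterations.equals(e2[0].iterations)
        # a single iteration collapses the empirical CI to the value
        assert e1[0].ci_auc[0] == e1[0].ci_auc[1] == e1[0].mean_auc

    def test_pairwise_table_shape(self):
        rng = np.random.default_rng(3)
        df = _informative_cohort(rng)
        sets = (("x", ("x",)), ("y", ("y",)), ("xy", ("x", "y")))
        evals, pairwise = evaluate_feature_sets(df, sets, n_iter=4, seed=0,
                                                n_trees=30)
        assert len(evals) == 3
        assert len(pairwise) == 3 * 2  # 3 set pairs x 2 metrics
        assert set(pairwise["metric"]) == {"accuracy", "auc"}


class TestLeaveOneCancerOut:
    def test_small_run_and_single_sample_type_skipped(self):
        rng = np.random.default_rng(4)
        df = _informative_cohort(rng)
        # add a cancer type with a single sample: must be skipped
        extra = df.iloc[[0]].copy()
        extra["sample_id"] = "solo"
        extra["status"] = "cancer"
        extra["cancer_type"] = "renal"
        df = pd.concat([df, extra], ignore_index=True)
        table = leave_one_cancer_out(df, (("x", ("x",)),), n_iter=2, seed=1,
                                     n_trees=20)
        assert set(table["excluded_type"]) == {"liver", "lung"}
        assert table["mean_auc_held_in"].notna().all()

    def test_fewer_than_two_types_rejected(self):
        rng = np.random.default_rng(5)
        df = _informative_cohort(rng)
        df["cancer_type"] = df["cancer_type"].where(df["status"] != "cancer", "liver")
        with pytest.raises(ValueError):
            leave_one_cancer_out(df, (("x", ("x",)),), n_iter=1, seed=1)
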