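"""Batch-effect negation and supervised cancer detection.

The batch metric maps each sample's feature point (by default the mtDNA
fraction and the ichorCNA tumor fraction) to the ratio

    d = ||x - cancer_control|| / ||x - healthy_control||

where the controls are per-collection-center coordinate-wise medians of
the cancer and healthy samples (features are z-scored within center
first, since the two coordinates differ by orders of magnitude). d < 1
means a sample lies closer to its center's cancer control than to its
healthy control, on a scale comparable across centers.

Detection performance is evaluated by repeatedly (default 50 iterations)
class-balancing the cohort, drawing a stratified 80/20 train/test split,
training a random forest, and scoring accuracy and the rank-based
(Mann-Whitney) AUC on the held-out 20%, for the feature sets {d_metric},
{tf_ichor} and {d_metric, tf_ichor}; iteration distributions are compared
pairwise with the rank-sum test. A leave-one-cancer-out mode retrains
with each cancer type excluded from the training pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .stats import wilcoxon_rank_sum

DEFAULT_FEATURES = ("p_mtdna", "tf_ichor")
DEFAULT_FEATURE_SETS = (
    ("mtDNA", ("d_metric",)),
    ("ichorCNA", ("tf_ichor",)),
    ("combined", ("d_metric", "tf_ichor")),
)
DEFAULT_N_ITER = 50
DEFAULT_N_TREES = 500
DEFAULT_TRAIN_FRACTION = 0.8


class DegenerateControlsError(ValueError):
    """Cancer and healthy controls coincide; the distance ratio is undefined."""


@dataclass
class FeaturePoint:
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("feature coordinates must be finite")
        if len(self.names) != len(self.values):
            raise ValueError("names and values must align")


@dataclass
class CenterControls:
    center: str
    cancer_control: FeaturePoint
    healthy_control: FeaturePoint
    derivation: str = "per-center coordinate-wise median"

    def __post_init__(self) -> None:
        if np.allclose(self.cancer_control.values, self.healthy_control.values):
            raise DegenerateControlsError(
                f"center {self.center!r}: cancer and healthy controls coincide"
            )


@dataclass
class ClassifierEvaluation:
    feature_set: str
    features: tuple[str, ...]
    iterations: pd.DataFrame  # columns: iteration, seed, accuracy, auc
    mean_accuracy: float = field(init=False)
    mean_auc: float = field(init=False)
    ci_accuracy: tuple[float, float] = field(init=False)
    ci_auc: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        acc = self.iterations["accuracy"].to_numpy()
        auc = self.iterations["auc"].to_numpy()
        self.mean_accuracy = float(acc.mean())
        self.mean_auc = float(auc.mean())
        # empirical 95% CI over iterations
        self.ci_accuracy = tuple(float(v) for v in np.percentile(acc, [2.5, 97.5]))
        self.ci_auc = tuple(float(v) for v in np.percentile(auc, [2.5, 97.5]))

    def summary(self) -> dict:
        return {
            "feature_set": self.feature_set,
            "features": list(self.features),
            "n_iterations": len(self.iterations),
            "mean_accuracy": self.mean_accuracy,
            "ci95_accuracy": list(self.ci_accuracy),
            "mean_auc": self.mean_auc,
            "ci95_auc": list(self.ci_auc),
        }


# ---------------------------------------------------------------------------
# Batch metric
# ---------------------------------------------------------------------------

def center_controls(
    cohort: pd.DataFrame, center: str, features: Sequence[str] = DEFAULT_FEATURES
) -> CenterControls:
    """Coordinate-wise median cancer and healthy control points for a center."""
    cdf = cohort[cohort["center"] == center].dropna(subset=list(features))
    points = {}
    for status in ("cancer", "healthy"):
        sub = cdf[cdf["status"] == status]
        if len(sub) == 0:
            raise ValueError(
                f"center {center!r} has no {status} samples with complete features"
            )
        points[status] = FeaturePoint(
            tuple(features), sub[list(features)].median().to_numpy()
        )
    return CenterControls(center, points["cancer"], points["healthy"])


def batch_metric(point: FeaturePoint | np.ndarray, controls: CenterControls) -> float:
    """Euclidean distance-ratio d of a point to the two center controls.

    d = dist(point, cancer control) / dist(point, healthy control),
    generalized to any dimensionality. A point equal to the healthy
    control gets a +inf sentinel; a point equal to both controls at once
    is an error (the controls coincide, the ratio is undefined).
    """
    x = point.values if isinstance(point, FeaturePoint) else np.asarray(point, float)
    if x.shape != controls.cancer_control.values.shape:
        raise ValueError("point and controls have mismatched dimensions")
    num = float(np.linalg.norm(x - controls.cancer_control.values))
    den = float(np.linalg.norm(x - controls.healthy_control.values))
    if den == 0.0:
        if num == 0.0:
            raise DegenerateControlsError("point coincides with both controls")
        import logging

        logging.getLogger("cfmito").info(
            "batch_metric: point equals healthy control; returning +inf"
        )
        return math.inf
    return num / den


def apply_batch_correction(
    cohort: pd.DataFrame,
    features: Sequence[str] = DEFAULT_FEATURES,
    scaling: str = "zscore",
) -> pd.DataFrame:
    """Add a ``d_metric`` column: per-center distance-ratio batch metric.

    ``scaling='zscore'`` (default) z-scores each feature within center
    before computing distances; ``scaling='raw'`` uses raw coordinates.
    Samples with missing features keep a missing d_metric.
    """
    if scaling not in ("zscore", "raw"):
        raise ValueError(f"unknown scaling mode {scaling!r}")
    out = cohort.copy()
    out["d_metric"] = np.nan
    for center in out["center"].unique():
        mask = (out["center"] == center) & out[list(features)].notna().all(axis=1)
        sub = out.loc[mask]
        if not len(sub):
            continue
        coords = sub[list(features)].to_numpy(dtype=float)
        if scaling == "zscore":
            mu = coords.mean(axis=0)
            sd = coords.std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            coords = (coords - mu) / sd
        scaled = pd.DataFrame(coords, columns=list(features), index=sub.index)
        scaled["status"] = sub["status"].to_numpy()
        scaled["center"] = center
        try:
            controls = center_controls(scaled, center, features)
        except ValueError:
            continue  # a class absent in this center: d_metric stays missing
        d = np.array([batch_metric(row, controls) for row in coords])
        out.loc[mask, "d_metric"] = d
    return out


# ---------------------------------------------------------------------------
# Classifier evaluation
# ---------------------------------------------------------------------------

def balance_cohort(cohort: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Randomly down-sample the majority class to the minority size."""
    classes = cohort.groupby("status").size()
    if len(classes) < 2 or (classes == 0).any():
        raise ValueError("both classes must be present to balance")
    n_min = int(classes.min())
    rng = np.random.default_rng(seed)
    parts = []
    for status, sub in cohort.groupby("status", sort=True):
        if len(sub) > n_min:
            idx = rng.choice(len(sub), size=n_min, replace=False)
            sub = sub.iloc[np.sort(idx)]
        parts.append(sub)
    return pd.concat(parts).reset_index(drop=True)


def auc_rank(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based (Mann-Whitney) AUC: fraction of positive-negative pairs
    with the positive scored higher, ties counted half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC requires both classes")
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def run_iteration(
    features: np.ndarray,
    labels: np.ndarray,
    seed: int,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    n_trees: int = DEFAULT_N_TREES,
    _retry: bool = True,
) -> dict[str, float]:
    """One stratified 80/20 split + random-forest fit + test-set scoring.

    Accuracy uses the 0.5 probability threshold; AUC is the rank-based
    statistic on predicted cancer probabilities. If the test split lacks a
    class (possible only at tiny n), the split is redrawn once with a
    derived seed.
    """
    labels = np.asarray(labels)
    if min((labels == 0).sum(), (labels == 1).sum()) < 2:
        raise ValueError("need at least 2 samples per class")
    x_tr, x_te, y_tr, y_te = train_test_split(
        features, labels, train_size=train_fraction, stratify=labels,
        random_state=seed % (2**31),
    )
    if len(np.unique(y_te)) < 2 or len(np.unique(y_tr)) < 2:
        if _retry:
            return run_iteration(features, labels, seed + 10_007,
                                 train_fraction, n_trees, _retry=False)
        raise ValueError("test split is missing a class")
    clf = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed % (2**31),
        n_jobs=1,
    )
    clf.fit(x_tr, y_tr)
    prob = clf.predict_proba(x_te)[:, list(clf.classes_).index(1)]
    accuracy = float(((prob >= 0.5).astype(int) == y_te).mean())
    return {"accuracy": accuracy, "auc": auc_rank(prob, y_te)}


def _prepare(cohort: pd.DataFrame, features: Sequence[str]):
    sub = cohort.dropna(subset=list(features))
    sub = sub[np.isfinite(sub[list(features)]).all(axis=1)]
    return sub


def evaluate_feature_sets(
    cohort: pd.DataFrame,
    feature_sets: Sequence[tuple[str, Sequence[str]]] = DEFAULT_FEATURE_SETS,
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
    balance_once: bool = False,
) -> tuple[list[ClassifierEvaluation], pd.DataFrame]:
    """Repeated balanced holdout evaluation for each feature set.

    Balancing is redrawn per iteration with a derived seed (so the CIs
    reflect balancing variability); ``balance_once=True`` balances a single
    time up front. Returns the per-set evaluations and a table of pairwise
    rank-sum comparisons of the iteration-level accuracy and AUC
    distributions.
    """
    evaluations: list[ClassifierEvaluation] = []
    for set_idx, (name, feats) in enumerate(feature_sets):
        sub = _prepare(cohort, feats)
        if sub.empty:
            raise ValueError(f"feature set {name!r}: no samples with complete features")
        feats = tuple(feats)
        rows = []
        balanced = balance_cohort(sub, seed) if balance_once else None
        for it in range(n_iter):
            it_seed = (seed + 1_000_003 * (set_idx + 1) + 97 * it) % (2**31)
            pool = balanced if balanced is not None else balance_cohort(sub, it_seed)
            x = pool[list(feats)].to_numpy(dtype=float)
            y = (pool["status"] == "cancer").astype(int).to_numpy()
            scores = run_iteration(x, y, it_seed, n_trees=n_trees)
            rows.append({"iteration": it, "seed": it_seed, **scores})
        evaluations.append(
            ClassifierEvaluation(name, feats, pd.DataFrame(rows))
        )

    pairwise_rows = []
    for i in range(len(evaluations)):
        for j in range(i + 1, len(evaluations)):
            for metric in ("accuracy", "auc"):
                res = wilcoxon_rank_sum(
                    evaluations[i].iterations[metric],
                    evaluations[j].iterations[metric],
                )
                pairwise_rows.append({
                    "set_a": evaluations[i].feature_set,
                    "set_b": evaluations[j].feature_set,
                    "metric": metric,
                    "statistic": res.statistic,
                    "p": res.p,
                    "stars": res.stars,
                })
    return evaluations, pd.DataFrame(pairwise_rows)


def leave_one_cancer_out(
    cohort: pd.DataFrame,
    feature_sets: Sequence[tuple[str, Sequence[str]]] = DEFAULT_FEATURE_SETS,
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
) -> pd.DataFrame:
    """Retrain with each cancer type excluded from the training pool.

    For every cancer type t (with >= 2 samples; smaller types are skipped
    and logged) and every feature set: the pool excludes type-t cancer
    samples; per iteration the pool is balanced, split 80/20 and a forest
    trained. Two evaluations are reported per iteration: the held-in test
    split, and the excluded type-t samples scored against the test split's
    healthy samples. Returns a tidy table of per-type summaries.
    """
    import logging

    logger = logging.getLogger("cfmito")
    types = [
        t for t in sorted(cohort.loc[cohort["status"] == "cancer", "cancer_type"]
                          .dropna().unique())
    ]
    if len(types) < 2:
        raise ValueError("leave-one-cancer-out needs >= 2 cancer types")
    rows = []
    for t_idx, ctype in enumerate(types):
        type_mask = (cohort["status"] == "cancer") & (cohort["cancer_type"] == ctype)
        if int(type_mask.sum()) < 2:
            logger.info("leave_one_cancer_out: skipping %r (< 2 samples)", ctype)
            continue
        pool_all = cohort[~type_mask]
        for set_idx, (name, feats) in enumerate(feature_sets):
            feats = tuple(feats)
            sub = _prepare(pool_all, feats)
            held_out = _prepare(cohort[type_mask], feats)
            held_in_scores, held_out_aucs = [], []
            for it in range(n_iter):
                it_seed = (seed + 7_919 * (t_idx + 1) + 1_000_003 * (set_idx + 1)
                           + 97 * it) % (2**31)
                pool = balance_cohort(sub, it_seed)
                x = pool[list(feats)].to_numpy(dtype=float)
                y = (pool["status"] == "cancer").astype(int).to_numpy()
                x_tr, x_te, y_tr, y_te = train_test_split(
                    x, y, train_size=DEFAULT_TRAIN_FRACTION, stratify=y,
                    random_state=it_seed % (2**31),
                )
                clf = RandomForestClassifier(
                    n_estimators=n_trees, max_features="sqrt",
                    random_state=it_seed % (2**31), n_jobs=1,
                )
                clf.fit(x_tr, y_tr)
                pos_col = list(clf.classes_).index(1)
                prob_te = clf.predict_proba(x_te)[:, pos_col]
                held_in_scores.append({
                    "accuracy": float(((prob_te >= 0.5).astype(int) == y_te).mean()),
                    "auc": auc_rank(prob_te, y_te),
                })
                if len(held_out) and (y_te == 0).sum():
                    prob_t = clf.predict_proba(
                        held_out[list(feats)].to_numpy(dtype=float)
                    )[:, pos_col]
                    prob_h = prob_te[y_te == 0]
                    scores = np.concatenate([prob_t, prob_h])
                    lab = np.concatenate([
                        np.ones(len(prob_t), int), np.zeros(len(prob_h), int)
                    ])
                    held_out_aucs.append(auc_rank(scores, lab))
            hi = pd.DataFrame(held_in_scores)
            rows.append({
                "excluded_type": ctype,
                "feature_set": name,
                "n_excluded": int(type_mask.sum()),
                "mean_accuracy_held_in": float(hi["accuracy"].mean()),
                "mean_auc_held_in": float(hi["auc"].mean()),
                "mean_auc_excluded_type": (
                    float(np.mean(held_out_aucs)) if held_out_aucs else np.nan
                ),
            })
    return pd.DataFrame(rows)
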