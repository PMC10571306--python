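"""Cohort-level group comparisons and correlations.

Non-parametric comparisons of the plasma mtDNA fraction by cancer status,
TNM stage and cancer type (with the usual star conventions for p values),
Pearson correlations of the mtDNA fraction against copy-number-derived
tumor fraction (TF) and mutant allele fraction (MAF), and the partition of
cancer samples into TF-detectable (TF >= 3%) vs undetectable.

Rank-sum p values are computed by exhaustive enumeration over all group
assignments (midrank ties) when both groups are small, and by the
tie-corrected normal approximation otherwise. Raw p values are reported;
an optional Benjamini-Hochberg adjustment is off by default.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

#: p-value star conventions (inclusive thresholds)
STAR_LEVELS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*"))

#: ichorCNA detectability threshold: TF < 3% is undetectable
TF_DETECTABLE_THRESHOLD = 0.03

#: largest total sample size for exact rank-sum enumeration
EXACT_ENUM_LIMIT = 22


@dataclass
class StatResult:
    test: str
    statistic: float
    p: float
    n_per_group: tuple[int, ...]
    stars: str

    def as_row(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "p": self.p,
            "n": "/".join(str(n) for n in self.n_per_group),
            "stars": self.stars,
        }


def stars(p: float) -> str:
    """Star label for a p value: ``****`` <= 1e-4 ... ``*`` <= 0.05, else ``ns``."""
    if not 0 <= p <= 1:
        raise ValueError(f"p value outside [0, 1]: {p}")
    for threshold, label in STAR_LEVELS:
        if p <= threshold:
            return label
    return "ns"


def tf_detectable(tf: float) -> bool | None:
    """True iff the tumor fraction is callable (TF >= 3%); None if missing."""
    if tf is None or (isinstance(tf, float) and math.isnan(tf)):
        return None
    return tf >= TF_DETECTABLE_THRESHOLD


def _rank_sum_u(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U of group a (midranks for ties)."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r_a = ranks[: len(a)].sum()
    return r_a - len(a) * (len(a) + 1) / 2.0


def _exact_rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact p by enumeration of all C(n_a+n_b, n_a) splits.

    Works with ties: ranks are midranks of the pooled sample, and the
    distribution of U is tabulated over every assignment of pooled values
    to the two groups."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n_a, n = len(a), len(pooled)
    mu = n_a * (n - n_a) / 2.0
    u_obs = _rank_sum_u(a, b)
    dev_obs = abs(u_obs - mu)
    hits = total = 0
    const = n_a * (n_a + 1) / 2.0
    for combo in itertools.combinations(range(n), n_a):
        u = ranks[list(combo)].sum() - const
        total += 1
        if abs(u - mu) >= dev_obs - 1e-12:
            hits += 1
    return hits / total


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> StatResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when both groups have <= 10 values (and the total is
    small enough to enumerate); otherwise the tie-corrected asymptotic p.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    u = _rank_sum_u(a, b)
    if len(a) <= 10 and len(b) <= 10 and len(a) + len(b) <= EXACT_ENUM_LIMIT:
        p = _exact_rank_sum_p(a, b)
        test = "wilcoxon_rank_sum_exact"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        u, p = float(res.statistic), float(res.pvalue)
        test = "wilcoxon_rank_sum"
    return StatResult(test, float(u), float(p), (len(a), len(b)), stars(p))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> StatResult:
    """Kruskal-Wallis H test with tie correction, chi-squared p (k-1 df)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in arrays):
        raise ValueError("all groups must be non-empty")
    if all(np.all(g == arrays[0][0]) for g in arrays):
        # all values identical: H = 0 by definition, p = 1
        return StatResult("kruskal_wallis", 0.0, 1.0,
                          tuple(len(g) for g in arrays), "ns")
    h, p = sps.kruskal(*arrays)
    return StatResult(
        "kruskal_wallis", float(h), float(p), tuple(len(g) for g in arrays), stars(p)
    )


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Pearson correlation with two-sided t-distribution p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired vectors of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = sps.pearsonr(x, y)
    return StatResult("pearson", float(r), float(p), (len(x),), stars(p))


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH-adjusted p values (optional; group analyses default to raw p)."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for i in range(n - 1, -1, -1):
        rank = i + 1
        running = min(running, p[order[i]] * n / rank)
        adj[order[i]] = running
    return adj


# ---------------------------------------------------------------------------
# Cohort-level analysis plan
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = ("sample_id", "center", "status", "p_mtdna")

DEFAULT_PLAN = (
    "status_by_center",
    "stage_by_center",
    "type_vs_healthy",
    "types_overall",
    "tf_correlations",
    "maf_correlations",
    "tf_partition",
)


def _vals(df: pd.DataFrame, col: str = "p_mtdna") -> np.ndarray:
    return df[col].dropna().to_numpy(dtype=float)


def run_group_analyses(
    cohort: pd.DataFrame,
    plan: Sequence[str] = DEFAULT_PLAN,
    adjust: bool = False,
) -> pd.DataFrame:
    """Run the configured cohort analyses and return a tidy results table.

    Columns: analysis, center, group, test, statistic, p, stars, n, note.
    Pairwise comparisons default to the rank-sum test with the star legend
    applied; analyses that cannot run (missing data, degenerate groups)
    emit a row with a ``note`` instead of failing the whole report.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing required columns: {missing}")
    rows: list[dict] = []

    def emit(analysis: str, center: str, group: str,
             result: StatResult | None, note: str = "") -> None:
        row = {"analysis": analysis, "center": center, "group": group,
               "test": "", "statistic": np.nan, "p": np.nan, "stars": "",
               "n": "", "note": note}
        if result is not None:
            row.update(result.as_row())
        rows.append(row)

    for center, cdf in cohort.groupby("center", sort=True):
        healthy = _vals(cdf[cdf["status"] == "healthy"])
        cancer_df = cdf[cdf["status"] == "cancer"]
        cancer = _vals(cancer_df)

        if "status_by_center" in plan:
            if len(healthy) and len(cancer):
                emit("status_by_center", center, "cancer_vs_healthy",
                     wilcoxon_rank_sum(cancer, healthy))
            else:
                emit("status_by_center", center, "cancer_vs_healthy", None,
                     "skipped: a status group is empty")

        if "stage_by_center" in plan:
            staged = cancer_df.dropna(subset=["tnm_stage"]) if "tnm_stage" in cdf else cancer_df.iloc[0:0]
            stage_groups = [
                _vals(g) for _, g in staged.groupby("tnm_stage", sort=True)
            ]
            stage_groups = [g for g in stage_groups if len(g)]
            if len(stage_groups) >= 2:
                emit("stage_by_center", center, "across_stages",
                     kruskal_wallis(stage_groups))
            else:
                emit("stage_by_center", center, "across_stages", None,
                     "skipped: fewer than 2 staged groups")
            if len(healthy):
                for stage, g in staged.groupby("tnm_stage", sort=True):
                    v = _vals(g)
                    if len(v):
                        emit("stage_by_center", center, f"stage_{stage}_vs_healthy",
                             wilcoxon_rank_sum(v, healthy))

        if "type_vs_healthy" in plan and "cancer_type" in cdf.columns:
            for ctype, g in cancer_df.groupby("cancer_type", sort=True):
                v = _vals(g)
                if len(v) and len(healthy):
                    emit("type_vs_healthy", center, str(ctype),
                         wilcoxon_rank_sum(v, healthy))

        if "tf_partition" in plan and "tf_ichor" in cdf.columns:
            tf = cancer_df["tf_ichor"]
            detectable = _vals(cancer_df[tf >= TF_DETECTABLE_THRESHOLD])
            undetectable = _vals(cancer_df[tf < TF_DETECTABLE_THRESHOLD])
            for label, vals in (("detectable_vs_healthy", detectable),
                                ("undetectable_vs_healthy", undetectable)):
                if len(vals) and len(healthy):
                    emit("tf_partition", center, label,
                         wilcoxon_rank_sum(vals, healthy))
                else:
                    emit("tf_partition", center, label, None,
                         "skipped: empty partition or no healthy samples")

        for feature, analysis in (("tf_ichor", "tf_correlations"),
                                  ("maf", "maf_correlations")):
            if analysis not in plan or feature not in cdf.columns:
                continue
            for ctype, g in cancer_df.groupby("cancer_type", sort=True):
                sub = g.dropna(subset=["p_mtdna", feature])
                if len(sub) >= 3 and sub[feature].nunique() > 1 \
                        and sub["p_mtdna"].nunique() > 1:
                    emit(analysis, center, str(ctype),
                         pearson_with_p(sub["p_mtdna"], sub[feature]))
                else:
                    emit(analysis, center, str(ctype), None,
                         "skipped: insufficient paired data")

    if "types_overall" in plan and "cancer_type" in cohort.columns:
        cancer_all = cohort[cohort["status"] == "cancer"]
        type_groups = [
            _vals(g) for _, g in cancer_all.groupby("cancer_type", sort=True)
        ]
        type_groups = [g for g in type_groups if len(g)]
        if len(type_groups) >= 2:
            emit("types_overall", "all", "across_types", kruskal_wallis(type_groups))
        else:
            emit("types_overall", "all", "across_types", None,
                 "skipped: fewer than 2 cancer types")

    out = pd.DataFrame(rows)
    if adjust and len(out):
        tested = out["p"].notna()
        out.loc[tested, "p_adjusted"] = benjamini_hochberg(out.loc[tested, "p"])
    return out
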