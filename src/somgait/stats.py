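"""Group comparison battery for the recovered gait-pattern clusters.

For each of the 13 directional gait variable scores, the clusters are
compared with a Levene test of homogeneity of variance (Brown-Forsythe,
median-centered), per-group Shapiro-Wilk normality tests, a one-way ANOVA,
and two-sided Welch pairwise comparisons flagged against a Bonferroni
threshold of 0.05 divided by the number of clusters (0.008 at three
decimals for six clusters).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .scores import GVS_NAMES, GVSVector, gvs_matrix


def levene_test(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Brown-Forsythe (median-centered) test of equal variances."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least 2 values")
    stat, p = sps.levene(*groups, center="median")
    return float(stat), float(p)


def normality_test(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk normality test for samples of size 3..5000."""
    values = np.asarray(values, dtype=float)
    if values.size < 3 or values.size > 5000:
        raise ValueError("Shapiro-Wilk requires 3..5000 values")
    stat, p = sps.shapiro(values)
    return float(stat), float(p)


def anova_per_gvs(
    gvs_by_group: Mapping[str, Iterable[GVSVector]]
) -> dict[str, tuple[float, float]]:
    """One-way fixed-effects ANOVA per directional score across groups."""
    mats = {g: gvs_matrix(list(v)) for g, v in gvs_by_group.items()}
    if len(mats) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    out = {}
    for i, name in enumerate(GVS_NAMES):
        f, p = sps.f_oneway(*[m[:, i] for m in mats.values()])
        out[name] = (float(f), float(p))
    return out


def bonferroni_threshold(n_clusters: int) -> float:
    """alpha = 0.05 divided by the number of clusters."""
    if n_clusters < 1:
        raise ValueError("need at least one cluster")
    return 0.05 / n_clusters


def pairwise_bonferroni(
    gvs_by_group: Mapping[str, Iterable[GVSVector]], n_clusters: int
) -> dict[str, dict]:
    """All-pairs Welch t-tests per score, flagged at 0.05/n_clusters.

    Returns, per score, a symmetric p-value matrix (unit diagonal), the
    significance flags, the group order, and the threshold used.
    """
    names = list(gvs_by_group)
    mats = {g: gvs_matrix(list(v)) for g, v in gvs_by_group.items()}
    alpha = bonferroni_threshold(n_clusters)
    out = {}
    for i, score in enumerate(GVS_NAMES):
        g = len(names)
        p = np.eye(g)  # diagonal convention p = 1
        np.fill_diagonal(p, 1.0)
        for a in range(g):
            for b in range(a + 1, g):
                _, pv = sps.ttest_ind(
                    mats[names[a]][:, i], mats[names[b]][:, i], equal_var=False
                )
                p[a, b] = p[b, a] = float(pv)
        out[score] = {
            "groups": names,
            "p_matrix": p,
            "significant": p < alpha,
            "alpha_bonferroni": alpha,
        }
    return out


def boxplot_summary(values: Sequence[float]) -> dict:
    """Quartiles, mean, 10th/90th percentiles and outliers beyond them.

    Percentiles use linear interpolation between order statistics, matching
    the whisker convention of the group box plots (whiskers at p10/p90,
    points outside them drawn as outliers).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    q25, med, q75 = np.percentile(v, [25, 50, 75], method="linear")
    p10, p90 = np.percentile(v, [10, 90], method="linear")
    outliers = v[(v < p10) | (v > p90)]
    return {
        "q25": float(q25),
        "median": float(med),
        "mean": float(v.mean()),
        "q75": float(q75),
        "p10": float(p10),
        "p90": float(p90),
        "outliers": outliers.tolist(),
    }


def stats_report(gvs_by_group: Mapping[str, Iterable[GVSVector]]) -> dict:
    """The full battery as one JSON-serializable report."""
    groups = {g: list(v) for g, v in gvs_by_group.items()}
    n_clusters = len(groups)
    mats = {g: gvs_matrix(v) for g, v in groups.items()}
    anova = anova_per_gvs(groups)
    pairwise = pairwise_bonferroni(groups, n_clusters)
    report: dict = {
        "n_clusters": n_clusters,
        "alpha_bonferroni": bonferroni_threshold(n_clusters),
        "scores": {},
    }
    for i, score in enumerate(GVS_NAMES):
        cols = {g: m[:, i] for g, m in mats.items()}
        lev_stat, lev_p = levene_test(list(cols.values()))
        normality = {}
        for g, col in cols.items():
            if 3 <= col.size <= 5000 and np.ptp(col) > 0:
                _, np_p = normality_test(col)
            else:
                np_p = None
            normality[g] = np_p
        pw = pairwise[score]
        report["scores"][score] = {
            "levene": {"statistic": lev_stat, "p": lev_p},
            "normality_p": normality,
            "anova": {"F": anova[score][0], "p": anova[score][1]},
            "pairwise_p": pw["p_matrix"].tolist(),
            "pairwise_significant": pw["significant"].tolist(),
            "group_order": pw["groups"],
            "box_summaries": {g: boxplot_summary(col) for g, col in cols.items()},
        }
    return report
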