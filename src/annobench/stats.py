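"""Statistical comparison of annotation tools and feature-accuracy correlation.

The workflow mirrors standard non-parametric benchmarking practice:
Shapiro-Wilk normality screening per group, a Kruskal-Wallis omnibus test
per metric across tools, then pairwise Mann-Whitney U tests; and
Spearman/Pearson correlation of per-genome accuracy metrics against genome
features (assembly size, contig count, GC%, repeat content).

The metric table is a tidy pandas DataFrame: one row per genome per tool,
with numeric metric/feature columns (missing values allowed) and optional
categorical grouping columns such as tool or angiosperm class.

Mann-Whitney p-values use exact enumeration for group sizes <= 8 and the
normal approximation with tie correction otherwise. Raw p-values are always
reported; Benjamini-Hochberg adjustment is opt-in and flagged in the output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationResult",
    "ComparisonResult",
    "correlate_features",
    "compare_tools",
    "mannwhitney_pvalue",
]

EXACT_MAX_N = 8


@dataclass(frozen=True)
class CorrelationResult:
    feature: str
    metric: str
    method: str  # "spearman" | "pearson"
    coefficient: float | None
    p_value: float | None
    n: int
    most_affected: bool = False  # largest |coefficient| for this feature

    @property
    def computable(self) -> bool:
        return self.coefficient is not None


@dataclass(frozen=True)
class PairwiseTest:
    group_a: str
    group_b: str
    statistic: float
    p_value: float
    p_adjusted: float | None = None


@dataclass
class ComparisonResult:
    metric: str
    groups: tuple[str, ...]
    shapiro_p: dict[str, float]
    kruskal_p: float | None
    pairwise: list[PairwiseTest]
    excluded_groups: list[str] = field(default_factory=list)
    adjusted: bool = False
    alpha: float = 0.05


def correlate_features(
    table: pd.DataFrame,
    features: Sequence[str],
    metrics: Sequence[str],
    method: str = "spearman",
) -> list[CorrelationResult]:
    """Correlate each genome feature with each accuracy metric.

    Rows with a missing value in either column are dropped pairwise. A
    combination with fewer than 3 complete pairs is reported as
    not-computable (coefficient/p None), never raised. Per feature, the
    metric with the largest absolute coefficient is flagged.
    """
    if method not in {"spearman", "pearson"}:
        raise ValueError(f"method must be spearman|pearson, got {method!r}")
    corr_fn = sps.spearmanr if method == "spearman" else sps.pearsonr
    results: list[CorrelationResult] = []
    for feature in features:
        per_feature: list[CorrelationResult] = []
        for metric in metrics:
            pair = table[[feature, metric]].dropna()
            n = len(pair)
            if n < 3:
                per_feature.append(
                    CorrelationResult(feature, metric, method, None, None, n)
                )
                continue
            res = corr_fn(pair[feature].to_numpy(), pair[metric].to_numpy())
            coef, p = float(res.statistic), float(res.pvalue)
            if np.isnan(coef):  # constant input
                per_feature.append(
                    CorrelationResult(feature, metric, method, None, None, n)
                )
            else:
                per_feature.append(
                    CorrelationResult(feature, metric, method, coef, p, n)
                )
        computable = [r for r in per_feature if r.computable]
        if computable:
            best = max(computable, key=lambda r: abs(r.coefficient))
            per_feature = [
                CorrelationResult(
                    r.feature, r.metric, r.method, r.coefficient, r.p_value, r.n,
                    most_affected=(r is best),
                )
                for r in per_feature
            ]
        results.extend(per_feature)
    return results


def mannwhitney_pvalue(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: (U statistic, p).

    Exact null distribution when both groups have <= 8 observations,
    normal approximation with tie correction otherwise.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    method = "exact" if max(len(a), len(b)) <= EXACT_MAX_N else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_tools(
    table: pd.DataFrame,
    group_column: str,
    metrics: Sequence[str],
    bh_adjust: bool = False,
    alpha: float = 0.05,
    min_group_size: int = 3,
) -> list[ComparisonResult]:
    """Per metric: Shapiro-Wilk per group, Kruskal-Wallis omnibus, pairwise
    Mann-Whitney U. Groups with fewer than ``min_group_size`` non-missing
    observations are excluded with a warning record.
    """
    if group_column not in table.columns:
        raise ValueError(f"group column {group_column!r} not in table")
    results: list[ComparisonResult] = []
    for metric in metrics:
        samples: dict[str, np.ndarray] = {}
        excluded: list[str] = []
        for name, sub in table.groupby(group_column, observed=True, sort=True):
            vals = sub[metric].dropna().to_numpy(float)
            if len(vals) < min_group_size:
                excluded.append(str(name))
                warnings.warn(
                    f"metric {metric!r}: group {name!r} has {len(vals)} "
                    f"observations (<{min_group_size}); excluded",
                    stacklevel=2,
                )
            else:
                samples[str(name)] = vals
        if len(samples) < 2:
            raise ValueError(
                f"metric {metric!r}: need >=2 groups with "
                f">={min_group_size} observations, have {len(samples)}"
            )
        shapiro_p = {}
        for name, vals in samples.items():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # small-n / identical-value notes
                try:
                    shapiro_p[name] = float(sps.shapiro(vals).pvalue)
                except ValueError:
                    shapiro_p[name] = float("nan")
        try:
            kruskal_p = float(sps.kruskal(*samples.values()).pvalue)
        except ValueError:  # all values identical across groups
            kruskal_p = None
        names = sorted(samples)
        pairwise = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                u, p = mannwhitney_pvalue(samples[names[i]], samples[names[j]])
                pairwise.append(PairwiseTest(names[i], names[j], u, p))
        if bh_adjust and pairwise:
            raw = [t.p_value for t in pairwise]
            adjusted = multipletests(raw, alpha=alpha, method="fdr_bh")[1]
            pairwise = [
                PairwiseTest(t.group_a, t.group_b, t.statistic, t.p_value, float(q))
                for t, q in zip(pairwise, adjusted)
            ]
        results.append(
            ComparisonResult(
                metric=metric,
                groups=tuple(names),
                shapiro_p=shapiro_p,
                kruskal_p=kruskal_p,
                pairwise=pairwise,
                excluded_groups=excluded,
                adjusted=bh_adjust,
                alpha=alpha,
            )
        )
    return results
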