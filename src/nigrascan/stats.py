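"""Group comparisons, prodromal-score correlations, and FDR control.

Per-feature one-way ANOVA compares groups (for two groups this is the
squared-t two-sample test); Pearson correlation relates imaging features to
the prodromal likelihood-ratio (LR) score; the Benjamini-Hochberg step-up
procedure controls the false discovery rate over the correlation family at
q = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["ComparisonResult", "CorrelationResult", "compare_groups",
           "correlate_with_lr", "bh_fdr", "LR_CUTOFF"]

LR_CUTOFF = 50.0  # LR above this marks increased prodromal risk


@dataclass(frozen=True)
class ComparisonResult:
    feature: str
    group_means: dict  # group -> mean
    group_sds: dict  # group -> sd
    statistic: float  # one-way ANOVA F
    p_value: float
    degenerate: bool = False  # constant feature within all groups


@dataclass(frozen=True)
class CorrelationResult:
    feature: str
    r: float
    p_value: float
    n: int
    degenerate: bool = False
    fdr_significant: bool = False


def compare_groups(table: pd.DataFrame, grouping: str | np.ndarray,
                   features: list[str]) -> list[ComparisonResult]:
    """One-way ANOVA per feature across groups.

    Parameters
    ----------
    table : DataFrame
        Subjects x features (plus metadata).
    grouping : column name or array of labels
        Group membership per row; at least two groups with >= 2 subjects.
    features : list of str
        Feature columns to test.
    """
    labels = table[grouping].to_numpy() if isinstance(grouping, str) else np.asarray(grouping)
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("at least two groups are required")
    group_rows = {g: labels == g for g in uniq}
    if any(m.sum() < 2 for m in group_rows.values()):
        raise ValueError("each group needs at least two subjects")

    results = []
    for feat in features:
        x = table[feat].to_numpy(dtype=float)
        samples = [x[m] for m in group_rows.values()]
        means = {g: float(x[m].mean()) for g, m in group_rows.items()}
        sds = {g: float(x[m].std(ddof=1)) for g, m in group_rows.items()}
        if np.ptp(x) == 0:
            results.append(ComparisonResult(feat, means, sds, float("nan"),
                                            float("nan"), degenerate=True))
            continue
        f, p = sps.f_oneway(*samples)
        results.append(ComparisonResult(feat, means, sds, float(f), float(p)))
    return results


def correlate_with_lr(table: pd.DataFrame, lr: str | np.ndarray,
                      features: list[str] | None = None,
                      q: float = 0.05) -> list[CorrelationResult]:
    """Pearson correlation of each feature with the LR score, BH-corrected.

    Zero-variance features are flagged degenerate and excluded from the FDR
    family; the remaining p-values enter a Benjamini-Hochberg step-up at
    rate ``q``.
    """
    scores = table[lr].to_numpy(dtype=float) if isinstance(lr, str) else np.asarray(lr, dtype=float)
    if features is None:
        features = [c for c in table.columns if c != lr]
    keep = np.isfinite(scores)
    if keep.sum() < 3:
        raise ValueError("Pearson correlation requires n >= 3 finite LR scores")
    if np.ptp(scores[keep]) == 0:
        raise ValueError("LR scores have zero variance")

    results = []
    for feat in features:
        x = table[feat].to_numpy(dtype=float)[keep]
        y = scores[keep]
        if np.ptp(x) == 0:
            results.append(CorrelationResult(feat, float("nan"), float("nan"),
                                             int(keep.sum()), degenerate=True))
            continue
        r, p = sps.pearsonr(x, y)
        results.append(CorrelationResult(feat, float(r), float(p), int(keep.sum())))

    testable = [i for i, res in enumerate(results) if not res.degenerate]
    if testable:
        flags = bh_fdr([results[i].p_value for i in testable], q=q)
        for i, flag in zip(testable, flags):
            res = results[i]
            results[i] = CorrelationResult(res.feature, res.r, res.p_value,
                                           res.n, fdr_significant=bool(flag))
    return results


def bh_fdr(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up: reject the largest prefix of sorted
    p-values with ``p(i) <= i*q/m``. Flags are returned in input order."""
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject
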