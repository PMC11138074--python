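"""Downstream statistics on variant score maps.

Correlation with orthogonal electrophysiology measurements, ROC
performance against presumed benign/pathogenic labels (low score =
deleterious), rank-sum group contrasts, trafficking-by-function
category independence, per-residue intolerance summaries, and splice
predictor threshold flags.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

INTOLERANT_FRACTION = 0.70
TOLERANT_FRACTION = 0.50
SPLICE_RECOMMENDED = 0.5
SPLICE_HIGH_RECALL = 0.2


def rank_correlation(scores, external) -> tuple[float, float, int]:
    """Spearman rank correlation on paired observations (ties averaged)."""
    x = np.asarray(scores, dtype=float)
    y = np.asarray(external, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        raise ValueError("need at least 3 paired observations")
    rho, p = stats.spearmanr(x[ok], y[ok])
    return float(rho), float(p), int(ok.sum())


def roc(labels, scores) -> tuple[pd.DataFrame, float]:
    """ROC curve and trapezoidal AUC; lower score = positive (deleterious).

    ``labels`` are boolean/0-1 with 1 = pathogenic.  Returns a curve
    table (threshold, tpr, fpr) over all observed thresholds plus the
    AUC.
    """
    y = np.asarray(labels).astype(bool)
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ValueError("need both classes for a ROC curve")
    thresholds = np.concatenate(([-np.inf], np.unique(s), [np.inf]))
    tpr = [(s[y] < t).mean() for t in thresholds]
    fpr = [(s[~y] < t).mean() for t in thresholds]
    curve = pd.DataFrame({"threshold": thresholds, "tpr": tpr, "fpr": fpr})
    auc = float(np.trapezoid(curve["tpr"], curve["fpr"]))
    return curve, auc


def operating_point(labels, scores, cutoff: float) -> tuple[float, float]:
    """(sensitivity, specificity) of the rule ``score < cutoff`` => positive."""
    y = np.asarray(labels).astype(bool)
    s = np.asarray(scores, dtype=float)
    sensitivity = float((s[y] < cutoff).mean())
    specificity = float((s[~y] >= cutoff).mean())
    return sensitivity, specificity


def group_contrast(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test between two score groups.

    Exact null for small groups (both n <= 10), normal approximation
    with continuity correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    method = "exact" if max(a.size, b.size) <= 10 else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def crosstab_independence(table: pd.DataFrame) -> tuple[float, float]:
    """Pearson chi-square test of independence (no continuity correction)."""
    arr = np.asarray(table, dtype=float)
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("degenerate margins")
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return float(chi2), float(p)


def residue_intolerance(
    categories: pd.Series, variants: pd.DataFrame
) -> pd.DataFrame:
    """Per-residue missense intolerance summary.

    A residue is *intolerant* when strictly more than 70% of its scored
    missense variants are loss or partial loss, and *tolerant* when
    strictly more than 50% are category normal.  ``variants`` supplies
    ``position`` and ``vclass`` for the scored names.
    """
    joined = variants.join(categories.rename("category"), how="inner")
    mis = joined[joined["vclass"] == "missense"]
    rows = []
    for residue, grp in mis.groupby("position"):
        n = len(grp)
        lof = grp["category"].isin(["loss", "partial_loss"]).mean()
        wt = (grp["category"] == "normal").mean()
        rows.append(
            {
                "position": int(residue),
                "n_missense": n,
                "fraction_lof": lof,
                "fraction_normal": wt,
                "intolerant": lof > INTOLERANT_FRACTION,
                "tolerant": wt > TOLERANT_FRACTION,
            }
        )
    return pd.DataFrame(rows).set_index("position")


def splice_flags(delta_scores) -> pd.Series:
    """Flag precomputed splice delta scores at the 0.5/0.2 thresholds."""
    s = pd.Series(delta_scores, dtype=float)
    if ((s < 0) | (s > 1)).any():
        raise ValueError("splice scores must lie in [0, 1]")
    flags = pd.Series("none", index=s.index, name="splice_flag")
    flags[s > SPLICE_HIGH_RECALL] = "high_recall"
    flags[s > SPLICE_RECOMMENDED] = "recommended"
    return flags
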