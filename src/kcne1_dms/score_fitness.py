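"""Functional scores from depletion over a day-0/8/20 time course.

Cells whose variant supports normal channel activity are selected
against, so their barcodes deplete from the pool.  The raw statistic is
the ordinary-least-squares slope of log2 barcode frequency against day;
normalization maps the median synonymous slope to 1 and the median
early-nonsense slope to 0, so 1 = WT-like (depletes) and 0 =
nonfunctional (persists).  Confidence intervals use the same
hierarchical bootstrap as the sort-seq scorer.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import parse_sample_columns
from .score_sortseq import (  # shared implementation
    PSEUDOCOUNT,
    aggregate_variant_scores,
    normalize_scores,
    score_ci,
    score_table,
)

__all__ = [
    "depletion_slope",
    "barcode_slopes",
    "aggregate_variant_scores",
    "normalize_scores",
    "score_ci",
    "score_table",
]


def depletion_slope(frequencies: np.ndarray, days: np.ndarray) -> float | np.ndarray:
    """OLS slope of log2 frequency against day.

    ``frequencies`` may be a vector (one series) or a matrix with one
    row per entity and one column per day.  Frequencies must already be
    pseudocounted/nonzero; fewer than two time points is an error.
    """
    days = np.asarray(days, dtype=float)
    if days.size < 2:
        raise ValueError("need at least two time points")
    f = np.asarray(frequencies, dtype=float)
    single = f.ndim == 1
    f = np.atleast_2d(f)
    if f.shape[1] != days.size:
        raise ValueError("frequency columns must match days")
    if (f <= 0).any():
        raise ValueError("frequencies must be positive (apply a pseudocount)")
    y = np.log2(f)
    x = days - days.mean()
    slope = (y * x).sum(axis=1) / (x * x).sum()
    return float(slope[0]) if single else slope


def barcode_slopes(
    counts: pd.DataFrame, pseudocount: float = PSEUDOCOUNT
) -> pd.DataFrame:
    """Raw per-barcode depletion slopes, one column per replicate.

    Counts plus pseudocount are converted to within-sample frequencies
    (so the slope is invariant to per-day depth) before the log2-vs-day
    regression.  Barcodes with zero reads at every day of a replicate
    are dropped from that replicate.
    """
    roles = parse_sample_columns(list(counts.columns))
    if set(roles["role"]) != {"day"}:
        raise ValueError("expected day-role sample columns")
    cols = {}
    for rep, grp in roles.groupby("replicate"):
        grp = grp.sort_values("index")
        days = grp["index"].to_numpy(dtype=float)
        sub = counts[grp["column"]].astype(float)
        sub = sub[sub.sum(axis=1) > 0] + pseudocount
        freqs = (sub / sub.sum(axis=0)).to_numpy()
        cols[rep] = pd.Series(depletion_slope(freqs, days), index=sub.index)
    return pd.DataFrame(cols)
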