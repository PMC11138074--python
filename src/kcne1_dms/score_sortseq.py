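"""Surface-expression ("trafficking") scores from 4-bin sort-seq counts.

Per replicate, each barcode's read counts across the four sorted bins
are depth-normalized, converted to bin shares, and collapsed to a
weighted-average score in [0, 1] (bottom bin 0, top bin 1).  Barcode
scores are averaged per variant, normalized so that the synonymous
median is exactly 1 and the early-nonsense median exactly 0, and a
hierarchical bootstrap over barcodes within replicates yields the 95%
confidence interval.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import parse_sample_columns

#: equally spaced default bin weights (bin 1 .. bin 4)
DEFAULT_BIN_WEIGHTS = (0.0, 1 / 3, 2 / 3, 1.0)
PSEUDOCOUNT = 0.5


def bin_frequencies(
    counts: pd.DataFrame, pseudocount: float = PSEUDOCOUNT
) -> dict[int, pd.DataFrame]:
    """Per-replicate bin-share tables from a sort-seq count matrix.

    Within each sample (bin) column, counts plus pseudocount are scaled
    to proportions of the column total (depth normalization); each
    entity's four proportions are then renormalized to sum to 1.
    Entities with zero reads across all four bins of a replicate are
    dropped from that replicate.  Returns ``{replicate: share table}``
    with bin columns 1..4.
    """
    roles = parse_sample_columns(list(counts.columns))
    if set(roles["role"]) != {"bin"}:
        raise ValueError("expected bin-role sample columns")
    out: dict[int, pd.DataFrame] = {}
    for rep, grp in roles.groupby("replicate"):
        grp = grp.sort_values("index")
        sub = counts[grp["column"]].astype(float)
        nonzero = sub.sum(axis=1) > 0
        sub = sub[nonzero] + pseudocount
        depth = sub / sub.sum(axis=0)  # within-sample proportions
        shares = depth.div(depth.sum(axis=1), axis=0)
        shares.columns = grp["index"].to_list()
        out[rep] = shares
    return out


def weighted_bin_score(
    shares: np.ndarray | pd.DataFrame,
    weights: tuple[float, ...] = DEFAULT_BIN_WEIGHTS,
    atol: float = 1e-9,
) -> np.ndarray:
    """Weighted average of bin shares: ``sum_b w_b * share_b``."""
    arr = np.asarray(shares, dtype=float)
    single = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if not np.allclose(arr.sum(axis=1), 1.0, atol=atol):
        raise ValueError("bin shares must sum to 1")
    w = np.asarray(weights, dtype=float)
    if np.any(np.diff(w) < 0) or w.min() < 0 or w.max() > 1:
        raise ValueError("weights must be non-decreasing within [0, 1]")
    score = arr @ w
    return float(score[0]) if single else score


def barcode_scores(
    counts: pd.DataFrame,
    weights: tuple[float, ...] = DEFAULT_BIN_WEIGHTS,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Raw per-barcode weighted scores, one column per replicate."""
    per_rep = bin_frequencies(counts, pseudocount=pseudocount)
    cols = {
        rep: pd.Series(weighted_bin_score(shares, weights), index=shares.index)
        for rep, shares in per_rep.items()
    }
    return pd.DataFrame(cols)


def aggregate_variant_scores(
    bc_scores: pd.DataFrame, barcode_map: pd.DataFrame
) -> pd.DataFrame:
    """Unweighted mean of barcode scores per variant, per replicate.

    Barcodes are independent clonal measurements of the same variant, so
    each gets equal weight.  Returns a table indexed by variant name
    with replicate columns plus ``n_barcodes``.
    """
    missing = bc_scores.index.difference(barcode_map.index)
    if len(missing):
        raise KeyError(f"{len(missing)} scored barcodes missing from the map")
    joined = bc_scores.join(barcode_map["variant"])
    grouped = joined.groupby("variant")
    out = grouped.mean(numeric_only=True)
    out["n_barcodes"] = grouped.size()
    out.index.name = "name"
    return out


def normalize_scores(
    raw: pd.Series | np.ndarray,
    synonymous_raw: np.ndarray,
    early_nonsense_raw: np.ndarray,
) -> pd.Series | np.ndarray:
    """Anchor raw scores: synonymous median -> 1, early-nonsense median -> 0."""
    syn_med = float(np.median(np.asarray(synonymous_raw, dtype=float)))
    non_med = float(np.median(np.asarray(early_nonsense_raw, dtype=float)))
    if np.isclose(syn_med, non_med):
        raise ValueError("degenerate anchors: synonymous and nonsense medians equal")
    return (raw - non_med) / (syn_med - non_med)


def score_ci(
    per_replicate_barcode_scores: list[np.ndarray],
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    level: float = 0.95,
) -> tuple[float, float, float]:
    """Estimate and percentile-bootstrap 95% CI for one variant.

    Input is one array of (already normalized) barcode scores per
    replicate.  The estimate is the mean of replicate means.  Each
    bootstrap draw resamples barcodes with replacement within every
    replicate and averages the replicate means; the CI is the central
    ``level`` percentile interval of the draws.  A single barcode in a
    single replicate collapses the interval to the point.
    """
    reps = [np.asarray(r, dtype=float) for r in per_replicate_barcode_scores if len(r)]
    if not reps:
        raise ValueError("need at least one replicate with a scored barcode")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    estimate = float(np.mean([r.mean() for r in reps]))
    boots = np.zeros(n_boot)
    for r in reps:
        idx = rng.integers(0, len(r), size=(n_boot, len(r)))
        boots += r[idx].mean(axis=1)
    boots /= len(reps)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return estimate, float(lo), float(hi)


def score_table(
    variant_scores: pd.DataFrame,
    truth_classes: pd.Series,
    early_nonsense: pd.Index | list[str],
    n_boot: int = 1000,
    seed: int = 0,
    bc_scores: pd.DataFrame | None = None,
    barcode_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the per-variant score table with normalization and CIs.

    ``variant_scores`` comes from :func:`aggregate_variant_scores`;
    ``truth_classes`` labels each variant's class (used only to locate
    the synonymous anchor set); ``early_nonsense`` lists the nonsense
    variants in the loss-anchoring residue range.  When per-barcode
    scores and the barcode map are supplied, CIs come from the
    hierarchical bootstrap; otherwise CIs degenerate to the replicate
    mean spread and are flagged.
    """
    rep_cols = [c for c in variant_scores.columns if c != "n_barcodes"]
    syn = variant_scores.index[
        truth_classes.reindex(variant_scores.index) == "synonymous"
    ]
    non = variant_scores.index.intersection(pd.Index(early_nonsense))
    if len(syn) == 0 or len(non) == 0:
        raise ValueError("anchor sets must be non-empty")

    # per-replicate anchoring keeps each replicate on the same 0..1 scale
    norm = variant_scores[rep_cols].copy()
    anchors = {}
    for col in rep_cols:
        anchors[col] = (
            float(variant_scores.loc[non, col].median()),
            float(variant_scores.loc[syn, col].median()),
        )
        non_med, syn_med = anchors[col]
        if np.isclose(syn_med, non_med):
            raise ValueError("degenerate anchors in replicate")
        norm[col] = (variant_scores[col] - non_med) / (syn_med - non_med)

    out = pd.DataFrame(index=variant_scores.index)
    out["score"] = norm.mean(axis=1)
    out["n_barcodes"] = variant_scores["n_barcodes"]
    for i, col in enumerate(rep_cols, start=1):
        out[f"score_rep{i}"] = norm[col]

    rng = np.random.default_rng(seed)
    if bc_scores is not None and barcode_map is not None:
        joined = bc_scores.join(barcode_map["variant"])
        lows = np.empty(len(out))
        highs = np.empty(len(out))
        groups = {k: g for k, g in joined.groupby("variant")}
        for i, name in enumerate(out.index):
            g = groups[name]
            reps = []
            for col in rep_cols:
                non_med, syn_med = anchors[col]
                vals = g[col].dropna().to_numpy()
                reps.append((vals - non_med) / (syn_med - non_med))
            _, lo, hi = score_ci(reps, n_boot=n_boot, seed=rng)
            lows[i], highs[i] = lo, hi
        out["ci_lower"], out["ci_upper"] = lows, highs
    else:
        spread = norm.std(axis=1, ddof=1).fillna(0.0)
        out["ci_lower"] = out["score"] - 1.96 * spread / np.sqrt(len(rep_cols))
        out["ci_upper"] = out["score"] + 1.96 * spread / np.sqrt(len(rep_cols))
        out.attrs["ci_method"] = "replicate-normal"
    # the point estimate is kept inside its interval by construction
    out["ci_lower"] = np.minimum(out["ci_lower"], out["score"])
    out["ci_upper"] = np.maximum(out["ci_upper"], out["score"])
    return out
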