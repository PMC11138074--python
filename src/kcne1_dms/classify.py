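"""Six-way variant categorization from score estimates and 95% CIs.

Cutoffs are data-derived: the 97.5th percentile of the early-nonsense
score distribution separates complete loss from partial loss, and the
2.5th/97.5th percentiles of the synonymous distribution bound the
normal range.  The decision tree uses the point estimate for the loss
call and the CI's relation to the cutoffs for everything else, so each
variant lands in exactly one category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CATEGORIES = ("loss", "partial_loss", "possible_loss", "normal", "possible_gain", "gain")

#: nonsense variants stop abolishing surface expression after residue 55
TRAFFICKING_NONSENSE_BOUNDARY = 55
#: and stop abolishing channel function after residue 104
FUNCTIONAL_NONSENSE_BOUNDARY = 104


@dataclass(frozen=True)
class Cutoffs:
    """(lower, mid_low, mid_high) category boundaries on the score scale."""

    lower: float
    mid_low: float
    mid_high: float

    def __post_init__(self) -> None:
        if not self.lower < self.mid_low < self.mid_high:
            raise ValueError(
                f"degenerate cutoffs: need lower < mid_low < mid_high, got "
                f"({self.lower}, {self.mid_low}, {self.mid_high})"
            )


def compute_cutoffs(
    synonymous_scores: np.ndarray, early_nonsense_scores: np.ndarray
) -> Cutoffs:
    """Percentile cutoffs (linear-interpolation / type-7 percentiles)."""
    syn = np.asarray(synonymous_scores, dtype=float)
    non = np.asarray(early_nonsense_scores, dtype=float)
    if syn.size == 0 or non.size == 0:
        raise ValueError("anchor sets must be non-empty")
    return Cutoffs(
        lower=float(np.percentile(non, 97.5)),
        mid_low=float(np.percentile(syn, 2.5)),
        mid_high=float(np.percentile(syn, 97.5)),
    )


def classify_variant(
    estimate: float, ci_low: float, ci_high: float, cutoffs: Cutoffs
) -> str:
    """Assign one of the six categories.

    Ordered rules: a point estimate below ``lower`` is loss regardless
    of the CI; then a CI wholly below the synonymous range is partial
    loss, a CI reaching below its 2.5th percentile is possible loss, a
    CI inside the range is normal, a CI crossing its 97.5th percentile
    is possible gain, and a CI wholly above is gain.
    """
    if not ci_low <= estimate <= ci_high:
        raise ValueError("malformed CI: need ci_low <= estimate <= ci_high")
    c = cutoffs
    if estimate < c.lower:
        return "loss"
    if ci_high < c.mid_low:
        return "partial_loss"
    if ci_low < c.mid_low:
        return "possible_loss"
    if ci_high <= c.mid_high:
        return "normal"
    if ci_low <= c.mid_high:
        return "possible_gain"
    return "gain"


def classify_table(scores: pd.DataFrame, cutoffs: Cutoffs) -> pd.Series:
    """Vectorized application of :func:`classify_variant` to a score table."""
    return pd.Series(
        [
            classify_variant(row.score, row.ci_lower, row.ci_upper, cutoffs)
            for row in scores.itertuples()
        ],
        index=scores.index,
        name="category",
    )


def nonsense_regime(
    residue: int, assay: str, protein_length: int = 129
) -> str:
    """``early`` or ``late`` truncation regime for a nonsense variant.

    Early truncations abolish the assayed property; the boundary sits
    after residue 55 for surface expression and after residue 104 for
    function.
    """
    if not 1 <= residue <= protein_length:
        raise ValueError(f"residue {residue} outside 1..{protein_length}")
    boundary = {
        "trafficking": TRAFFICKING_NONSENSE_BOUNDARY,
        "functional": FUNCTIONAL_NONSENSE_BOUNDARY,
    }[assay]
    return "early" if residue <= boundary else "late"


def early_nonsense_names(
    variants: pd.DataFrame, assay: str = "trafficking", protein_length: int = 129
) -> pd.Index:
    """Names of nonsense variants in the early regime of ``assay``.

    ``variants`` needs ``position`` and ``vclass`` columns indexed by
    name (a truth table or an annotated score table both work).
    """
    non = variants[variants["vclass"] == "nonsense"]
    mask = [
        nonsense_regime(int(p), assay, protein_length) == "early"
        for p in non["position"]
    ]
    return non.index[np.asarray(mask, dtype=bool)]


def crosstab_categories(
    trafficking: pd.Series, functional: pd.Series
) -> pd.DataFrame:
    """Trafficking-by-functional category contingency table."""
    joined = pd.concat(
        {"trafficking": trafficking, "functional": functional}, axis=1
    ).dropna()
    return pd.crosstab(joined["trafficking"], joined["functional"])
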