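"""ACMG/AMP functional-evidence calibration via OddsPath.

Following the ClinGen sequence-variant-interpretation framework, the
assay is benchmarked on presumed pathogenic and presumed benign control
variants.  Each control's score is reduced to an assay readout
(abnormal low / abnormal high / normal / indeterminate); the likelihood
ratio of pathogenicity attached to a readout class is

    OddsPath = [P2 * (1 - P1)] / [(1 - P2) * P1]

where P1 is the prior proportion pathogenic among determinate controls
and P2 the posterior proportion pathogenic within the readout class.
A perfectly concordant readout class would give an infinite ratio, so
one hypothetical discordant control is added to any zero cell before
computing that class's P2.  The resulting ratios map onto PS3/BS3
evidence strengths on the ClinGen scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# synonymous-distribution cutoffs used for calibration readouts
DEFAULT_LO_CUTOFF = 0.44
DEFAULT_HI_CUTOFF = 1.43

# ClinGen evidence-strength thresholds on the OddsPath scale
PS3_THRESHOLDS = (
    (350.0, "PS3_very_strong"),
    (18.7, "PS3_strong"),
    (4.3, "PS3_moderate"),
    (2.1, "PS3_supporting"),
)
BS3_THRESHOLDS = (
    (0.0029, "BS3_very_strong"),
    (0.053, "BS3_strong"),
    (0.23, "BS3_moderate"),
    (0.48, "BS3_supporting"),
)

PATHOGENIC_AF_MAX = 2.5e-5
BENIGN_AF_MIN = 3e-5
PENETRANCE_MAX = 0.10


def estimate_penetrance(
    n_cases: int, n_carriers_literature: int, gnomad_ac: int
) -> float:
    """Cases over total carriers (literature carriers + gnomAD alleles)."""
    denom = n_carriers_literature + gnomad_ac
    if denom <= 0:
        raise ValueError("penetrance denominator must be positive")
    if n_cases < 0:
        raise ValueError("case count must be non-negative")
    return n_cases / denom


def curate_controls(controls: pd.DataFrame) -> pd.DataFrame:
    """Label controls presumed pathogenic / benign / excluded.

    Expects columns ``clinvar`` (``P/LP``, ``B/LB``, or other/blank),
    ``n_cases``, ``n_carriers``, ``gnomad_ac``, ``gnomad_af``.  ClinVar
    classifications win outright; otherwise literature case counts at
    rare allele frequency (< 2.5e-5) imply pathogenic, and low estimated
    penetrance (< 10%) at population frequency (> 3e-5) implies benign.
    Everything else — including rare high-penetrance population
    variants — is excluded.
    """
    out = controls.copy()
    labels = []
    penetrances = []
    for row in out.itertuples():
        clinvar = str(getattr(row, "clinvar", "") or "")
        af = float(getattr(row, "gnomad_af", 0.0) or 0.0)
        cases = int(getattr(row, "n_cases", 0) or 0)
        carriers = int(getattr(row, "n_carriers", 0) or 0)
        ac = int(getattr(row, "gnomad_ac", 0) or 0)
        try:
            pen = estimate_penetrance(cases, carriers, ac)
        except ValueError:
            pen = np.nan
        penetrances.append(pen)
        if clinvar == "P/LP":
            labels.append("pathogenic")
        elif clinvar == "B/LB":
            labels.append("benign")
        elif cases >= 1 and af < PATHOGENIC_AF_MAX:
            labels.append("pathogenic")
        elif af > BENIGN_AF_MIN and not np.isnan(pen) and pen < PENETRANCE_MAX:
            labels.append("benign")
        else:
            labels.append("excluded")
    out["penetrance"] = penetrances
    out["presumed_label"] = labels
    return out


def assay_readout(
    estimate: float,
    ci_low: float,
    ci_high: float,
    lo_cutoff: float = DEFAULT_LO_CUTOFF,
    hi_cutoff: float = DEFAULT_HI_CUTOFF,
) -> str:
    """Readout class from a score estimate and its 95% CI.

    Abnormal requires the estimate and the whole interval beyond a
    cutoff; normal requires both inside; intervals overlapping a cutoff
    are indeterminate.
    """
    if not ci_low <= estimate <= ci_high:
        raise ValueError("malformed CI")
    if ci_high < lo_cutoff:
        return "abnormal_low"
    if ci_low > hi_cutoff:
        return "abnormal_high"
    if ci_low >= lo_cutoff and ci_high <= hi_cutoff:
        return "normal"
    return "indeterminate"


@dataclass
class OddsPathReport:
    """Calibration summary: prior, posteriors, likelihood ratios, strengths."""

    p1: float
    p2_abnormal: float
    p2_normal: float
    oddspath_pathogenic: float
    oddspath_benign: float
    n_pathogenic: int
    n_benign: int
    n_indeterminate: int
    corrections_applied: list[str] = field(default_factory=list)
    strengths: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "P1": self.p1,
            "P2_abnormal": self.p2_abnormal,
            "P2_normal": self.p2_normal,
            "oddspath_pathogenic": self.oddspath_pathogenic,
            "oddspath_benign": self.oddspath_benign,
            "n_pathogenic": self.n_pathogenic,
            "n_benign": self.n_benign,
            "n_indeterminate": self.n_indeterminate,
            "corrections_applied": self.corrections_applied,
            "strengths": self.strengths,
        }


def _oddspath(p1: float, p2: float) -> float:
    return (p2 * (1.0 - p1)) / ((1.0 - p2) * p1)


def oddspath(labels: pd.Series, readouts: pd.Series) -> OddsPathReport:
    """OddsPath ratios from control labels and assay readouts.

    ``labels`` take values ``pathogenic``/``benign`` (others ignored),
    ``readouts`` come from :func:`assay_readout`.  Indeterminate
    readouts are excluded from every denominator.  Zero discordant
    cells receive one hypothetical discordant control when computing
    that readout class's P2 only; the prior P1 is computed without
    hypothetical controls.
    """
    df = pd.concat({"label": labels, "readout": readouts}, axis=1).dropna()
    df = df[df["label"].isin(["pathogenic", "benign"])]
    determinate = df[df["readout"] != "indeterminate"]
    n_path = int((determinate["label"] == "pathogenic").sum())
    n_ben = int((determinate["label"] == "benign").sum())
    if n_path == 0 or n_ben == 0:
        raise ValueError("need determinate controls on both sides")
    p1 = n_path / (n_path + n_ben)

    abnormal = determinate[determinate["readout"].str.startswith("abnormal")]
    normal = determinate[determinate["readout"] == "normal"]
    corrections: list[str] = []

    ab_path = int((abnormal["label"] == "pathogenic").sum())
    ab_ben = int((abnormal["label"] == "benign").sum())
    if ab_path == 0 or ab_ben == 0:
        # one hypothetical control fills each empty cell of the class,
        # keeping the posterior away from the degenerate 0/1 endpoints
        ab_path, ab_ben = max(ab_path, 1), max(ab_ben, 1)
        corrections.append("abnormal_zero_cell")
    p2_abnormal = ab_path / (ab_path + ab_ben)

    no_path = int((normal["label"] == "pathogenic").sum())
    no_ben = int((normal["label"] == "benign").sum())
    if no_path == 0 or no_ben == 0:
        no_path, no_ben = max(no_path, 1), max(no_ben, 1)
        corrections.append("normal_zero_cell")
    p2_normal = no_path / (no_path + no_ben)

    report = OddsPathReport(
        p1=p1,
        p2_abnormal=p2_abnormal,
        p2_normal=p2_normal,
        oddspath_pathogenic=_oddspath(p1, p2_abnormal),
        oddspath_benign=_oddspath(p1, p2_normal),
        n_pathogenic=n_path,
        n_benign=n_ben,
        n_indeterminate=int((df["readout"] == "indeterminate").sum()),
        corrections_applied=corrections,
    )
    report.strengths = evidence_strength(report)
    return report


def evidence_strength(report: OddsPathReport) -> dict[str, str]:
    """Map OddsPath ratios to PS3/BS3 levels on the ClinGen scale."""
    ps3 = "none"
    for threshold, level in PS3_THRESHOLDS:
        if report.oddspath_pathogenic > threshold:
            ps3 = level
            break
    bs3 = "none"
    for threshold, level in BS3_THRESHOLDS:
        if report.oddspath_benign < threshold:
            bs3 = level
            break
    return {"PS3": ps3, "BS3": bs3}
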