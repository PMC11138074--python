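"""Control curation, assay readouts, OddsPath, evidence strengths."""

import itertools

import numpy as np
import pandas as pd
import pytest

from kcne1_dms.calibrate import (
    OddsPathReport,
    assay_readout,
    curate_controls,
    estimate_penetrance,
    evidence_strength,
    oddspath,
)


def _contingency(path_abnormal, path_normal, ben_abnormal, ben_normal):
    labels = (
        ["pathogenic"] * (path_abnormal + path_normal)
        + ["benign"] * (ben_abnormal + ben_normal)
    )
    readouts = (
        ["abnormal_low"] * path_abnormal
        + ["normal"] * path_normal
        + ["abnormal_low"] * ben_abnormal
        + ["normal"] * ben_normal
    )
    idx = [f"v{i}" for i in range(len(labels))]
    return pd.Series(labels, index=idx), pd.Series(readouts, index=idx)


def _oracle_posterior_odds(path_abnormal, path_normal, ben_abnormal, ben_normal):
    """Independent check: OddsPath as the ratio of posterior to prior
    odds of pathogenicity, with the same zero-cell convention."""
    n_path, n_ben = path_abnormal + path_normal, ben_abnormal + ben_normal
    prior_odds = n_path / n_ben
    if path_abnormal == 0 or ben_abnormal == 0:
        path_abnormal, ben_abnormal = max(path_abnormal, 1), max(ben_abnormal, 1)
    if path_normal == 0 or ben_normal == 0:
        path_normal, ben_normal = max(path_normal, 1), max(ben_normal, 1)
    posterior_odds_abnormal = path_abnormal / ben_abnormal
    posterior_odds_normal = path_normal / ben_normal
    return (
        posterior_odds_abnormal / prior_odds,
        posterior_odds_normal / prior_odds,
    )


class TestPenetrance:
    def test_zero_cases_gives_zero(self):
        assert estimate_penetrance(0, 12, 30) == 0.0

    def test_direct_ratio(self):
        assert estimate_penetrance(2, 5, 45) == pytest.approx(0.04)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            estimate_penetrance(1, 0, 0)


class TestCuration:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(
            rows,
            columns=["variant", "clinvar", "n_cases", "n_carriers", "gnomad_ac", "gnomad_af"],
        ).set_index("variant")

    def test_clinvar_benign_wins_regardless_of_frequency(self):
        out = curate_controls(self._table([("V1", "B/LB", 3, 4, 10, 1e-6)]))
        assert out.loc["V1", "presumed_label"] == "benign"

    def test_rare_literature_case_is_presumed_pathogenic(self):
        out = curate_controls(self._table([("V2", "", 1, 1, 2, 1e-6)]))
        assert out.loc["V2", "presumed_label"] == "pathogenic"

    def test_common_low_penetrance_is_presumed_benign(self):
        # 2 cases over 5 literature + 45 gnomAD carriers: penetrance 4%
        out = curate_controls(self._table([("V3", "", 2, 5, 45, 1e-4)]))
        assert out.loc["V3", "presumed_label"] == "benign"
        assert out.loc["V3", "penetrance"] == pytest.approx(0.04)

    def test_common_high_penetrance_is_excluded(self):
        # the G55S-style rule: frequent yet penetrant -> dropped
        out = curate_controls(self._table([("V4", "", 6, 10, 10, 1e-4)]))
        assert out.loc["V4", "presumed_label"] == "excluded"

    def test_rare_caseless_variant_is_excluded(self):
        out = curate_controls(self._table([("V5", "", 0, 2, 3, 1e-6)]))
        assert out.loc["V5", "presumed_label"] == "excluded"


class TestAssayReadout:
    @pytest.mark.parametrize(
        "estimate,lo,hi,expected",
        [
            (0.2, 0.1, 0.3, "abnormal_low"),
            (1.0, 0.8, 1.2, "normal"),
            (0.5, 0.40, 0.60, "indeterminate"),
            (1.6, 1.5, 1.7, "abnormal_high"),
            (1.3, 1.2, 1.5, "indeterminate"),
        ],
    )
    def test_readout_classes(self, estimate, lo, hi, expected):
        assert assay_readout(estimate, lo, hi) == expected

    def test_malformed_ci_rejected(self):
        with pytest.raises(ValueError):
            assay_readout(0.5, 0.6, 0.7)


class TestOddsPath:
    def test_clinvar_contingency_reproduces_printed_ratios(self):
        labels, readouts = _contingency(3, 1, 0, 7)
        report = oddspath(labels, readouts)
        assert report.p1 == pytest.approx(4 / 11)
        assert report.oddspath_pathogenic == pytest.approx(5.25)
        assert report.oddspath_benign == pytest.approx(0.25)
        assert report.corrections_applied == ["abnormal_zero_cell"]
        assert report.strengths == {"PS3": "PS3_moderate", "BS3": "BS3_supporting"}

    def test_expanded_contingency(self):
        labels, readouts = _contingency(14, 3, 1, 16)
        report = oddspath(labels, readouts)
        assert report.oddspath_pathogenic == pytest.approx(14.0)
        assert report.oddspath_benign == pytest.approx(0.1875)
        assert report.strengths == {"PS3": "PS3_moderate", "BS3": "BS3_moderate"}

    def test_uninformative_assay_gives_unit_ratio(self):
        labels, readouts = _contingency(5, 5, 5, 5)
        report = oddspath(labels, readouts)
        assert report.oddspath_pathogenic == pytest.approx(1.0)
        assert report.oddspath_benign == pytest.approx(1.0)

    def test_indeterminate_controls_excluded_everywhere(self):
        labels, readouts = _contingency(3, 1, 0, 7)
        labels["extra"] = "pathogenic"
        readouts["extra"] = "indeterminate"
        report = oddspath(labels, readouts)
        assert report.p1 == pytest.approx(4 / 11)
        assert report.n_indeterminate == 1

    def test_one_sided_controls_rejected(self):
        labels = pd.Series(["pathogenic", "pathogenic"])
        readouts = pd.Series(["abnormal_low", "normal"])
        with pytest.raises(ValueError):
            oddspath(labels, readouts)

    def test_matches_posterior_odds_oracle_on_small_tables(self):
        cells = range(0, 7)
        for pa, pn, ba, bn in itertools.product(cells, repeat=4):
            if pa + pn == 0 or ba + bn == 0 or pa + ba == 0 or pn + bn == 0:
                continue
            labels, readouts = _contingency(pa, pn, ba, bn)
            report = oddspath(labels, readouts)
            want_path, want_ben = _oracle_posterior_odds(pa, pn, ba, bn)
            assert report.oddspath_pathogenic == pytest.approx(want_path)
            assert report.oddspath_benign == pytest.approx(want_ben)

    def test_adding_pathogenic_abnormal_never_decreases_oddspath(self, rng):
        for _ in range(50):
            pa, pn, ba, bn = rng.integers(1, 15, size=4)
            labels, readouts = _contingency(pa, pn, ba, bn)
            base = oddspath(labels, readouts).oddspath_pathogenic
            labels2, readouts2 = _contingency(pa + 1, pn, ba, bn)
            grown = oddspath(labels2, readouts2).oddspath_pathogenic
            assert grown >= base - 1e-12


class TestEvidenceStrength:
    @pytest.mark.parametrize(
        "path_ratio,benign_ratio,ps3,bs3",
        [
            (5.25, 0.25, "PS3_moderate", "BS3_supporting"),
            (14.0, 0.188, "PS3_moderate", "BS3_moderate"),
            (400.0, 0.001, "PS3_very_strong", "BS3_very_strong"),
            (20.0, 0.04, "PS3_strong", "BS3_strong"),
            (2.5, 0.47, "PS3_supporting", "BS3_supporting"),
            (1.5, 0.9, "none", "none"),
        ],
    )
    def test_clingen_scale_mapping(self, path_ratio, benign_ratio, ps3, bs3):
        report = OddsPathReport(
            p1=0.5, p2_abnormal=0.5, p2_normal=0.5,
            oddspath_pathogenic=path_ratio, oddspath_benign=benign_ratio,
            n_pathogenic=1, n_benign=1, n_indeterminate=0,
        )
        assert evidence_strength(report) == {"PS3": ps3, "BS3": bs3}
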