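"""Trend classification, hypothesis grading, and the assembled pipeline."""

import itertools

import numpy as np
import pandas as pd
import pytest

from vpdtraits import harness
from vpdtraits.harness import classify_trend, grade_trend, grade_verdicts
from vpdtraits.stats import SMAFit

PLOTS = ["A1", "A2", "B1", "B2", "K1", "K2", "K3"]
SITE_OF = {"A1": "A", "A2": "A", "B1": "B", "B2": "B",
           "K1": "K", "K2": "K", "K3": "K"}


def series(values):
    return pd.Series(values, index=PLOTS, dtype=float)


def letters_all_distinct():
    return {p: l for p, l in zip(PLOTS, "abcdefg")}


def letters_all_shared():
    return {p: "a" for p in PLOTS}


class TestClassifyTrend:
    def test_monotone_disjoint_letters_increase(self):
        cls = classify_trend(series([1, 2, 3, 4, 5, 6, 7]),
                             letters_all_distinct(), SITE_OF, "A", "K")
        assert cls.label == "increase" and cls.significant

    def test_monotone_decrease(self):
        cls = classify_trend(series([7, 6, 5, 4, 3, 2, 1]),
                             letters_all_distinct(), SITE_OF, "A", "K")
        assert cls.label == "decrease"

    def test_one_violating_plot_slight(self):
        cls = classify_trend(series([1, 2, 3, 2.5, 5, 6, 7]).rename(None),
                             letters_all_distinct(), SITE_OF, "A", "K")
        # one plot breaks the ordering but endpoints separate cleanly
        assert cls.label in ("increase", "slight increase")
        cls2 = classify_trend(series([1, 4.5, 3, 3.5, 5, 6, 7]),
                              letters_all_distinct(), SITE_OF, "A", "K")
        assert cls2.n_violations == 1
        assert cls2.label == "slight increase"

    def test_shared_letters_no_trend(self):
        cls = classify_trend(series([1, 2, 3, 4, 5, 6, 7]),
                             letters_all_shared(), SITE_OF, "A", "K")
        assert cls.label == "no trend" and not cls.significant

    def test_mid_site_outside_range_no_trend(self):
        # B plots above both endpoints: no recognized gradient response
        cls = classify_trend(series([1, 2, 9, 9, 5, 6, 7]),
                             letters_all_distinct(), SITE_OF, "A", "K")
        assert cls.label == "no trend"

    def test_non_inferential_classified_on_ordering(self):
        cls = classify_trend(series([7, 6, 5, 4, 3, 2, 1]), None,
                             SITE_OF, "A", "K")
        assert cls.label == "decrease"
        assert cls.significant is None
        assert "non_inferential" in cls.flags

    def test_letter_rule_any_pair(self):
        # one dry plot separated from one wet plot suffices
        letters = {"A1": "a", "A2": "ab", "B1": "b", "B2": "bc",
                   "K1": "bc", "K2": "c", "K3": "c"}
        cls = classify_trend(series([1, 2, 3, 4, 5, 6, 7]), letters,
                             SITE_OF, "A", "K")
        assert cls.significant


class TestGrades:
    def test_exhaustive_label_direction_grid(self):
        labels = ["increase", "decrease", "slight increase",
                  "slight decrease", "no trend"]
        for expected, label in itertools.product("+-", labels):
            grade = grade_trend(expected, label)
            want = "increase" if expected == "+" else "decrease"
            if label == want:
                assert grade == "consistent"
            elif label == f"slight {want}":
                assert grade == "weakly consistent"
            else:
                assert grade == "inconsistent"

    def test_correlation_grading(self):
        neg_sig = SMAFit(-1.0, 0.0, -0.8, 0.001, 30)
        neg_ns = SMAFit(-1.0, 0.0, -0.2, 0.4, 30)
        pos_sig = SMAFit(1.0, 0.0, 0.8, 0.001, 30)
        assert harness.grade_correlation(neg_sig, "-") == "consistent"
        assert harness.grade_correlation(neg_ns, "-") == "weakly consistent"
        assert harness.grade_correlation(pos_sig, "-") == "inconsistent"

    def test_unknown_trait_rejected(self):
        cls = classify_trend(series([1, 2, 3, 4, 5, 6, 7]),
                             letters_all_distinct(), SITE_OF, "A", "K",
                             trait_name="mystery")
        with pytest.raises(ValueError):
            grade_verdicts({"mystery": cls})


class TestPipeline:
    def test_all_fourteen_hypotheses_scored(self, default_study):
        _, _, result = default_study
        assert len(result.verdicts) == 14
        assert sum(result.verdict_counts.values()) == 14

    def test_grades_match_imposed_truth(self, default_study):
        """The generator imposes the observed directions (including the Kp
        increase that contradicts safety-efficiency); the harness recovers
        at least 12 of the 14 imposed outcomes."""
        _, truth, result = default_study
        cfg_end = truth["plot_means"].pivot(index="trait", columns="plot_id",
                                            values="value")
        grades = {v.trait_name: v.grade for v in result.verdicts}
        expected_grade = {}
        directions = harness.expected_directions()
        for trait, want in directions.items():
            if trait == "kp_huber_correlation":
                expected_grade[trait] = "inconsistent"  # imposed positive corr
                continue
            if trait == "vessel_diameter":
                continue  # emergent trait: direction not directly imposed
            wet, dry = cfg_end.loc[trait, "ANK01"], cfg_end.loc[trait, "KOG05"]
            imposed = "+" if dry > wet else "-"
            expected_grade[trait] = (
                "consistent" if imposed == want else "inconsistent")
        matches = sum(grades[t] == g for t, g in expected_grade.items())
        assert matches >= 12

    def test_kp_graded_inconsistent_under_imposed_increase(self, default_study):
        _, _, result = default_study
        grades = {v.trait_name: v.grade for v in result.verdicts}
        assert grades["kp"] == "inconsistent"
        assert result.classifications["kp"].label in ("increase",
                                                      "slight increase")

    def test_hmax_has_no_letters(self, default_study):
        _, _, result = default_study
        sub = result.cwm[result.cwm["trait_name"] == "hmax"]
        assert (sub["tukey_letter"] == "").all()
        assert "non_inferential" in result.classifications["hmax"].flags

    def test_varpart_interspecific_dominates_unique_plot(self, default_study):
        _, _, result = default_study
        vp = result.varpart.set_index("trait_name")
        for trait in vp.index:
            assert vp.loc[trait, "frac_b"] >= 0.0
        # species-composition component exceeds the plot-unique component
        assert (vp["frac_b"] > vp["frac_a"]).sum() >= 2

    def test_pca_present_with_four_traits(self, default_study):
        _, _, result = default_study
        assert result.pca is not None
        assert set(result.pca.loadings.index) == {"huber", "chi", "vcmax25", "kp"}

    def test_cwm_table_shape(self, default_study):
        _, _, result = default_study
        counts = result.cwm.groupby("trait_name")["plot_id"].count()
        assert (counts == 7).all()

    def test_site_scale_capacities_flagged(self, default_study):
        _, _, result = default_study
        assert "site_scale" in result.classifications["vcmax25"].flags
        assert len(result.classifications["vcmax25"].plot_cwm) == 3
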