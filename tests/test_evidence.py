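"""DerSimonian-Laird pooling, decision rules, and back-calculation.

The two-study DL example is checked against a hand computation of the
formulas done independently beforehand:

    w = (100, 50); theta_FE = 40/150 = 0.2666...;
    Q = 100(0.2-4/15)^2 + 50(0.4-4/15)^2 = 4/3;
    C = 150 - 12500/150 = 200/3; tau2 = (4/3 - 1)/(200/3) = 0.005;
    w_RE = (1/0.015, 1/0.025) = (200/3, 40);
    pooled = (200/3*0.2 + 40*0.4)/(200/3 + 40) = 0.275;
    I2 = (4/3 - 1)/(4/3) * 100 = 25%.
"""

import math

import pytest

from copdad.evidence import (
    ConfigurationError,
    InputError,
    ParameterEstimate,
    StudyEffect,
    back_calculate_complement,
    choose_estimate,
    forest_data,
    pool_dl,
    read_study_table,
)


TWO_STUDIES = [
    StudyEffect("s1", 0.2, 0.01),
    StudyEffect("s2", 0.4, 0.02),
]


class TestPoolDL:
    def test_two_study_hand_computation(self):
        res = pool_dl(TWO_STUDIES)
        assert res.pooled_fe == pytest.approx(4 / 15, abs=1e-6)
        assert res.Q == pytest.approx(4 / 3, abs=1e-6)
        assert res.tau2 == pytest.approx(0.005, abs=1e-6)
        assert res.pooled == pytest.approx(0.275, abs=1e-6)
        assert res.i2 == pytest.approx(25.0, abs=1e-6)
        assert res.k == 2

    def test_homogeneous_degenerate_case(self):
        res = pool_dl([StudyEffect(f"s{i}", 0.3, 0.01) for i in range(3)])
        assert res.pooled == pytest.approx(0.3)
        assert res.Q == pytest.approx(0.0, abs=1e-12)
        assert res.tau2 == 0.0
        assert res.i2 == 0.0
        assert res.homogeneous

    def test_q_below_df_truncates_tau2_to_fixed_effect(self):
        studies = [StudyEffect("a", 0.30, 0.01), StudyEffect("b", 0.32, 0.02)]
        res = pool_dl(studies)
        assert res.Q < 1
        assert res.tau2 == 0.0
        assert res.pooled == pytest.approx(res.pooled_fe, abs=1e-12)

    def test_equal_variances_give_unweighted_mean_when_tau2_zero(self):
        estimates = [0.28, 0.30, 0.31]
        studies = [StudyEffect(f"s{i}", e, 0.05) for i, e in enumerate(estimates)]
        res = pool_dl(studies)
        assert res.tau2 == 0.0
        assert res.pooled == pytest.approx(sum(estimates) / 3, abs=1e-12)

    def test_variance_scaling_leaves_pooled_point_unchanged(self):
        # scaling all variances up keeps Q <= k-1, so tau2 stays 0 and
        # the inverse-variance weights renormalize identically
        base = pool_dl([StudyEffect("a", 0.30, 0.01), StudyEffect("b", 0.32, 0.02)])
        scaled = pool_dl([StudyEffect("a", 0.30, 0.04), StudyEffect("b", 0.32, 0.08)])
        assert base.tau2 == scaled.tau2 == 0.0
        assert scaled.pooled == pytest.approx(base.pooled, abs=1e-12)

    def test_q_pvalue_monotone_decreasing_in_q(self):
        mild = pool_dl([StudyEffect("a", 0.30, 0.01), StudyEffect("b", 0.35, 0.01)])
        strong = pool_dl([StudyEffect("a", 0.10, 0.01), StudyEffect("b", 0.90, 0.01)])
        assert strong.Q > mild.Q
        assert strong.q_pvalue < mild.q_pvalue

    def test_requires_two_studies(self):
        with pytest.raises(InputError, match="2"):
            pool_dl([StudyEffect("solo", 0.3, 0.01)])

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(InputError, match="variance"):
            StudyEffect("bad", 0.3, 0.0)


class TestChooseEstimate:
    def test_homogeneous_trio_pools(self):
        est = choose_estimate("p", [StudyEffect(f"s{i}", 0.3, 0.01) for i in range(3)])
        assert est.provenance == "pooled"
        assert est.point == pytest.approx(0.3)
        assert est.low < 0.3 < est.high

    def test_heterogeneous_studies_fall_back_to_median(self):
        studies = [
            StudyEffect("a", 0.1, 1e-4),
            StudyEffect("b", 0.5, 1e-4),
            StudyEffect("c", 0.9, 1e-4),
        ]
        assert not pool_dl(studies).homogeneous  # heterogeneity per the Q oracle
        est = choose_estimate("p", studies)
        assert est.provenance == "median"
        assert est.point == pytest.approx(0.5)
        # range spans the outermost per-study CI bounds
        assert est.low == pytest.approx(0.1 - 1.959963984540054 * 0.01, abs=1e-9)
        assert est.high == pytest.approx(0.9 + 1.959963984540054 * 0.01, abs=1e-9)

    def test_even_study_count_median_is_midpoint(self):
        studies = [
            StudyEffect("a", 0.1, 1e-6),
            StudyEffect("b", 0.2, 1e-6),
            StudyEffect("c", 0.6, 1e-6),
            StudyEffect("d", 0.9, 1e-6),
        ]
        est = choose_estimate("p", studies)
        assert est.provenance == "median"
        assert est.point == pytest.approx(0.4)

    def test_expert_only_passes_through(self):
        est = choose_estimate("p", expert_value=0.2, expert_range=(0.05, 0.6))
        assert (est.provenance, est.point, est.low, est.high) == ("expert", 0.2, 0.05, 0.6)

    def test_single_study_uses_its_own_ci(self):
        est = choose_estimate("p", [StudyEffect("only", 0.3, 0.0025)])
        assert est.point == pytest.approx(0.3)
        assert est.low == pytest.approx(0.3 - 1.959963984540054 * 0.05, abs=1e-9)

    def test_probability_clamping(self):
        est = choose_estimate(
            "p", [StudyEffect("only", 0.02, 0.01)], clamp_probability=True
        )
        assert est.low == 0.0

    def test_no_inputs_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            choose_estimate("p")


class TestBackCalculation:
    def _pe(self, name, point, low, high):
        return ParameterEstimate(name, point, low, high, "median")

    def test_two_siblings(self):
        comp = back_calculate_complement(
            [self._pe("a", 0.3, 0.3, 0.3), self._pe("b", 0.5, 0.5, 0.5)]
        )
        assert comp.point == pytest.approx(0.2)
        assert comp.provenance == "back-calculated"

    def test_single_zero_sibling_gives_identity(self):
        comp = back_calculate_complement([self._pe("a", 0.0, 0.0, 0.0)])
        assert comp.point == 1.0

    def test_interval_arithmetic_range(self):
        comp = back_calculate_complement(
            [self._pe("a", 0.3, 0.25, 0.35), self._pe("b", 0.5, 0.45, 0.55)]
        )
        assert comp.point == pytest.approx(0.2)
        assert comp.low == pytest.approx(0.1)
        assert comp.high == pytest.approx(0.3)

    def test_oversubscribed_siblings_rejected(self):
        with pytest.raises(InputError, match="sum"):
            back_calculate_complement(
                [self._pe("a", 0.7, 0.7, 0.7), self._pe("b", 0.5, 0.5, 0.5)]
            )


class TestStudyTables:
    def test_events_conversion_matches_binomial_variance(self):
        s = StudyEffect.from_events("s", 30, 100)
        assert s.estimate == pytest.approx(0.3)
        assert s.variance == pytest.approx(0.3 * 0.7 / 100)

    def test_zero_cell_continuity_correction(self):
        s = StudyEffect.from_events("s", 0, 20)
        assert s.estimate == pytest.approx(0.5 / 21)
        assert s.variance > 0

    @pytest.mark.parametrize("columns", ["estimate", "events"])
    def test_read_study_table(self, tmp_path, columns):
        path = tmp_path / "studies.csv"
        if columns == "estimate":
            path.write_text("study_id,estimate,variance\na,0.2,0.01\nb,0.4,0.02\n")
        else:
            path.write_text("study_id,events,n\na,20,100\nb,40,100\n")
        studies = read_study_table(str(path))
        assert [s.study_id for s in studies] == ["a", "b"]
        assert studies[0].estimate == pytest.approx(0.2)

    def test_forest_data_has_pooled_row(self):
        res = pool_dl(TWO_STUDIES)
        df = forest_data(TWO_STUDIES, res)
        assert list(df.study_id) == ["s1", "s2", "pooled (RE)"]
        assert df.iloc[-1].estimate == pytest.approx(res.pooled)


class TestParameterEstimate:
    def test_ordering_invariant_enforced(self):
        with pytest.raises(InputError, match="low <= point <= high"):
            ParameterEstimate("p", 0.5, 0.6, 0.9, "expert")

    def test_clamped_respects_bounds(self):
        est = ParameterEstimate("p", 0.5, -0.2, 1.4, "expert").clamped()
        assert (est.low, est.high) == (0.0, 1.0)
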