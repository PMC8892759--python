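"""Inferential layer: ANOVA, pooled t, Pearson, and the full report."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rmetnet import (
    AnswerKey,
    DegenerateDataError,
    ItemSpec,
    ValidationError,
    build_response_network,
    compare_groups,
    one_way_anova,
    pearson_r,
    two_sample_t,
)

from conftest import make_records

floats = st.floats(min_value=-50, max_value=50, allow_nan=False, width=32)
samples = st.lists(floats, min_size=2, max_size=30)


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        res = one_way_anova([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.value == pytest.approx(0.0)

    def test_study_shaped_df(self):
        rng = np.random.default_rng(0)
        res = one_way_anova(rng.normal(size=30), rng.normal(size=30))
        assert res.df == (1, 58)

    def test_hand_computed_small_fixture(self):
        # a=(1,2,3), b=(2,4,6): SSB=6, SSW=10, df=(1,4), F = 6/(10/4) = 2.4
        res = one_way_anova([1, 2, 3], [2, 4, 6])
        assert res.df == (1, 4)
        assert res.value == pytest.approx(2.4)

    def test_all_constant_input_degenerates_to_zero(self):
        res = one_way_anova([5.0, 5.0], [5.0, 5.0])
        assert res.value == 0.0 and res.p_value == 1.0

    def test_too_few_values_rejected(self):
        with pytest.raises(ValidationError):
            one_way_anova([1.0], [2.0, 3.0])

    @given(samples, samples)
    def test_f_equals_t_squared_for_two_groups(self, a, b):
        from hypothesis import assume

        t = two_sample_t(a, b)
        f = one_way_anova(a, b)
        # near-zero pooled variance overflows t**2 before F does
        assume(math.isfinite(t.value) and abs(t.value) < 1e6)
        assert f.value == pytest.approx(t.value**2, abs=1e-9, rel=1e-9)


class TestTwoSampleT:
    def test_equal_samples_give_zero_t(self):
        res = two_sample_t([1.0, 2.0], [1.0, 2.0])
        assert res.value == pytest.approx(0.0) and res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("n,df", [(43, 84), (19, 36), (15, 28), (9, 16)])
    def test_pooled_df_is_n1_plus_n2_minus_2(self, n, df):
        rng = np.random.default_rng(n)
        res = two_sample_t(rng.integers(1, 6, n).astype(float), rng.integers(1, 6, n).astype(float))
        assert res.df == df

    def test_zero_variance_unequal_means_gives_infinite_sentinel(self):
        res = two_sample_t([2.0, 2.0], [5.0, 5.0])
        assert math.isinf(res.value) and res.value < 0 and res.p_value == 0.0

    @given(samples, samples)
    def test_matches_direct_pooled_formula(self, a, b):
        a, b = np.asarray(a), np.asarray(b)
        res = two_sample_t(a, b)
        n1, n2 = len(a), len(b)
        sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
        if sp2 == 0:
            return
        expected = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
        assert res.value == pytest.approx(expected, abs=1e-9, rel=1e-9)

    @given(samples, samples)
    def test_label_swap_flips_sign_only(self, a, b):
        r1 = two_sample_t(a, b)
        r2 = two_sample_t(b, a)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)
        assert r1.value == pytest.approx(-r2.value, abs=1e-12)

    def test_welch_df_differs_under_unequal_variances(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 20), rng.normal(0, 5, 20)
        assert two_sample_t(a, b, welch=True).df != two_sample_t(a, b).df


class TestPearson:
    def test_perfect_positive_and_negative(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_r(x, x).value == pytest.approx(1.0)
        assert pearson_r(x, [-v for v in x]).value == pytest.approx(-1.0)

    def test_five_pair_fixture_matches_hand_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        # independent oracle: covariance over product of SDs
        expected = ((x - x.mean()) * (y - y.mean())).sum() / math.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        res = pearson_r(x, y)
        assert res.value == pytest.approx(expected, abs=1e-12)
        assert res.df == 3

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateDataError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            pearson_r([1.0, 2.0], [2.0, 1.0])


class TestCompareGroups:
    @staticmethod
    def _duplicated_cohort(tiny_key):
        recs_a = make_records(
            {"p1": {1: "calm", 2: "sad"}, "p2": {1: "sad", 2: "happy"}},
            tiny_key,
            group="A",
        )
        recs_b = make_records(
            {"q1": {1: "calm", 2: "sad"}, "q2": {1: "sad", 2: "happy"}},
            tiny_key,
            group="B",
        )
        return recs_a, recs_b

    def test_identical_cohorts_null_effects(self, tiny_key):
        recs_a, recs_b = self._duplicated_cohort(tiny_key)
        net_a = build_response_network(recs_a, tiny_key, "A")
        net_b = build_response_network(recs_b, tiny_key, "B")
        report = compare_groups(net_a, net_b, tiny_key, recs_a, recs_b)
        t_rows = report.network[report.network["statistic"] == "t"]
        assert (t_rows["value"].abs() < 1e-12).all()
        dens = report.network[report.network["row"] == "network_density"]
        assert dens["A"].iloc[0] == dens["B"].iloc[0]

    def test_study_shaped_report_has_expected_df_structure(self, study_cohort):
        responses, key, traits = study_cohort
        recs_a = [r for r in responses if r.group == "A"]
        recs_b = [r for r in responses if r.group == "B"]
        net_a = build_response_network(responses, key, "A")
        net_b = build_response_network(responses, key, "B")
        report = compare_groups(net_a, net_b, key, recs_a, recs_b, traits=traits)
        assert set(report.behavioral["df"]) == {"(1, 58)"}
        df_by_row = dict(zip(report.network["row"], report.network["df"]))
        assert df_by_row["in_degree_all"] == "84"
        assert df_by_row["in_degree_negative"] == "36"
        assert df_by_row["in_degree_neutral"] == "28"
        assert df_by_row["in_degree_positive"] == "16"
        assert set(report.correlations["df"]) == {28}

    def test_correlation_block_has_negative_trait_associations(self, study_cohort):
        responses, key, traits = study_cohort
        recs_a = [r for r in responses if r.group == "A"]
        recs_b = [r for r in responses if r.group == "B"]
        net_a = build_response_network(responses, key, "A")
        net_b = build_response_network(responses, key, "B")
        report = compare_groups(net_a, net_b, key, recs_a, recs_b, traits=traits)
        # generator calibrates accuracy-trait correlations to be negative
        adir = report.correlations[
            report.correlations["y"] == "adir_socio_emotional_reciprocity"
        ]
        assert set(adir["group"]) == {"A"}
        assert (report.correlations["r"] < 0.1).all()

    def test_single_valence_key_reports_single_stratum(self):
        key = AnswerKey(
            items=tuple(
                ItemSpec(i, f"t{i}", (f"a{i}", f"b{i}", f"c{i}"), "negative")
                for i in range(1, 4)
            )
        )
        recs_a = make_records(
            {"p1": {1: "t1", 2: "a2", 3: "t3"}, "p2": {1: "b1", 2: "t2", 3: "t3"}},
            key,
            group="A",
        )
        recs_b = make_records(
            {"q1": {1: "t1", 2: "t2", 3: "c3"}, "q2": {1: "t1", 2: "t2", 3: "t3"}},
            key,
            group="B",
        )
        net_a = build_response_network(recs_a, key, "A")
        net_b = build_response_network(recs_b, key, "B")
        report = compare_groups(net_a, net_b, key, recs_a, recs_b)
        strata = [r for r in report.network["row"] if r.startswith("in_degree_") and r != "in_degree_all"]
        assert strata == ["in_degree_negative"]

    def test_missing_traits_noted(self, tiny_key):
        recs_a, recs_b = self._duplicated_cohort(tiny_key)
        net_a = build_response_network(recs_a, tiny_key, "A")
        net_b = build_response_network(recs_b, tiny_key, "B")
        report = compare_groups(net_a, net_b, tiny_key, recs_a, recs_b, traits=None)
        assert len(report.correlations) == 0
        assert any("trait" in n for n in report.notes)

    def test_bonferroni_scales_stratified_p_only(self, study_cohort):
        responses, key, _ = study_cohort
        recs_a = [r for r in responses if r.group == "A"]
        recs_b = [r for r in responses if r.group == "B"]
        net_a = build_response_network(responses, key, "A")
        net_b = build_response_network(responses, key, "B")
        plain = compare_groups(net_a, net_b, key, recs_a, recs_b)
        corr = compare_groups(net_a, net_b, key, recs_a, recs_b, bonferroni=True)
        p_plain = dict(zip(plain.network["row"], plain.network["p_value"]))
        p_corr = dict(zip(corr.network["row"], corr.network["p_value"]))
        assert p_corr["in_degree_all"] == pytest.approx(p_plain["in_degree_all"])
        for stratum in ("negative", "neutral", "positive"):
            row = f"in_degree_{stratum}"
            assert p_corr[row] == pytest.approx(min(1.0, 3 * p_plain[row]))

    def test_same_group_rejected(self, tiny_key):
        recs_a, _ = self._duplicated_cohort(tiny_key)
        net_a = build_response_network(recs_a, tiny_key, "A")
        with pytest.raises(ValidationError):
            compare_groups(net_a, net_a, tiny_key, recs_a, recs_a)
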