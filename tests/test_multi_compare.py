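import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pvcomp import (
    ResultMatrix,
    ThresholdConfig,
    build_multi_table,
    color_for_cell,
    common_significant,
    fisher_combine,
)
from pvcomp.core_model import ResultMatrixError

from conftest import random_matrix


def chi2_sf_even_df(x: float, k: int) -> float:
    """Closed-form chi-square survival function for df = 2k:
    exp(-x/2) * sum_{i<k} (x/2)^i / i! — independent oracle."""
    t = x / 2.0
    term, total = 1.0, 1.0
    for i in range(1, k):
        term *= t / i
        total += term
    return math.exp(-t) * total


class TestFisherCombine:
    @pytest.mark.parametrize("p", [1e-8, 0.001, 0.05, 0.3, 0.777, 1.0])
    def test_single_p_identity_exact(self, p):
        assert fisher_combine([p]).combined_p == p

    def test_all_ones_boundary(self):
        res = fisher_combine([1.0, 1.0])
        assert res.statistic == 0.0
        assert res.df == 4
        assert res.combined_p == pytest.approx(1.0)

    def test_two_nominal_pvalues_closed_form(self):
        # oracle: X^2 = -4 ln 0.05 = 11.9829..., df 4 tail = e^{-x/2}(1 + x/2)
        x2 = -4.0 * math.log(0.05)
        expected = math.exp(-x2 / 2.0) * (1.0 + x2 / 2.0)
        assert expected == pytest.approx(0.0175, abs=5e-5)
        res = fisher_combine([0.05, 0.05])
        assert res.statistic == pytest.approx(x2, abs=1e-12)
        assert res.df == 4
        assert res.combined_p == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_matches_closed_form_grid(self, k):
        for p in np.logspace(-8, 0, 9):
            ps = [float(p)] * k
            res = fisher_combine(ps)
            assert res.combined_p == pytest.approx(
                chi2_sf_even_df(res.statistic, k), abs=1e-10
            )

    def test_missing_dropped_with_df_adjusted(self):
        res = fisher_combine([0.05, math.nan, 0.05])
        assert res.df == 4
        assert res.combined_p == fisher_combine([0.05, 0.05]).combined_p

    def test_zero_clamped(self):
        res = fisher_combine([0.0, 0.5])
        assert math.isfinite(res.statistic)
        assert 0.0 <= res.combined_p <= 1.0

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            fisher_combine([])
        with pytest.raises(ValueError):
            fisher_combine([math.nan])

    def test_out_of_range_is_error(self):
        with pytest.raises(ValueError):
            fisher_combine([0.5, 1.5])

    def test_independence_warning_flag(self):
        assert fisher_combine([0.1, 0.2], independence_warning=True).independence_warning
        assert not fisher_combine([0.1, 0.2]).independence_warning

    @given(st.lists(st.floats(min_value=1e-10, max_value=1.0), min_size=2, max_size=6))
    @settings(max_examples=80, deadline=None)
    def test_exchangeable(self, ps):
        forward = fisher_combine(ps)
        backward = fisher_combine(list(reversed(ps)))
        assert forward.combined_p == pytest.approx(backward.combined_p, rel=1e-12)
        assert forward.df == backward.df

    def test_strictly_increasing_in_each_argument(self):
        base = [0.01, 0.2, 0.4]
        for i in range(3):
            bumped = list(base)
            bumped[i] *= 1.5
            assert fisher_combine(bumped).combined_p > fisher_combine(base).combined_p

    @pytest.mark.parametrize("p,k", [(0.05, 2), (0.05, 3), (0.01, 4), (0.1, 3)])
    def test_replicated_small_p_strengthens(self, p, k):
        assert fisher_combine([p] * k).combined_p < p

    def test_replicated_weak_p_can_weaken(self):
        # combining copies of a weak p-value need not strengthen it:
        # X^2 = -4 ln 0.3 = 4.816 has a df-4 tail of ~0.307 > 0.3
        assert fisher_combine([0.3, 0.3]).combined_p > 0.3

    def test_null_combined_p_is_uniform(self):
        # Monte-Carlo oracle: combining k=3 Uniform(0,1) nulls must give a
        # Uniform(0,1) combined p
        rng = np.random.default_rng(2024)
        ps = rng.random((5000, 3))
        x2 = -2.0 * np.log(ps).sum(axis=1)
        combined = stats.chi2.sf(x2, 6)
        sample = [fisher_combine(row).combined_p for row in ps[:200]]
        assert np.allclose(sample, combined[:200], atol=1e-12)
        assert stats.kstest(combined, "uniform").pvalue > 0.01


class TestColorForCell:
    def test_boundary_alpha_red_zero(self):
        c = color_for_cell(0.05, 0.05)
        assert c.hue == "red"
        assert c.intensity == pytest.approx(0.0, abs=1e-12)

    def test_saturation_cap(self):
        c = color_for_cell(1e-12, 0.05, saturation_p=1e-10)
        assert c.hue == "red"
        assert c.intensity == 1.0

    def test_geometric_midpoint_half_intensity(self):
        # oracle: log10(a/sqrt(a*s)) / log10(a/s) = 0.5 exactly
        alpha, sat = 0.05, 1e-10
        p = math.sqrt(alpha * sat)
        c = color_for_cell(p, alpha, saturation_p=sat)
        assert c.hue == "red"
        assert c.intensity == pytest.approx(0.5, abs=1e-12)

    def test_p_one_green_zero(self):
        c = color_for_cell(1.0, 0.05)
        assert c.hue == "green"
        assert c.intensity == 0.0

    def test_green_above_half_is_zero(self):
        assert color_for_cell(0.6, 0.05).intensity == 0.0
        assert color_for_cell(0.5, 0.05).intensity == 0.0

    def test_green_grows_toward_alpha(self):
        a = color_for_cell(0.4, 0.05).intensity
        b = color_for_cell(0.1, 0.05).intensity
        assert 0.0 < a < b <= 1.0

    def test_monotone_within_each_hue(self):
        alpha = 0.05
        reds = [color_for_cell(p, alpha).intensity
                for p in np.logspace(-12, math.log10(alpha), 50)]
        assert all(x >= y - 1e-12 for x, y in zip(reds, reds[1:]))
        greens = [color_for_cell(p, alpha).intensity
                  for p in np.linspace(alpha + 1e-6, 1.0, 50)]
        assert all(x >= y - 1e-12 for x, y in zip(greens, greens[1:]))

    def test_hue_rule(self):
        assert color_for_cell(0.049, 0.05).hue == "red"
        assert color_for_cell(0.051, 0.05).hue == "green"

    def test_css_rendering(self):
        assert color_for_cell(1.0, 0.05).css() == "rgb(255,255,255)"
        assert color_for_cell(1e-300, 0.05).css() == "rgb(255,0,0)"

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            color_for_cell(1.5, 0.05)
        with pytest.raises(ValueError):
            color_for_cell(0.5, 0.0)
        with pytest.raises(ValueError):
            color_for_cell(0.5, 0.05, saturation_p=0.1)


class TestBuildMultiTable:
    def test_spec_example(self):
        m = ResultMatrix.from_arrays(
            ["m1", "m2"], ["A", "B"],
            [[0.01, 0.2], [0.5, 0.6]],
        )
        t = build_multi_table(m, alpha=0.05)
        assert t.marker_ids == ["m1", "m2"]  # ranked by average p
        assert bool(t.significant.loc["m1", "A"]) is True
        assert bool(t.significant.loc["m1", "B"]) is False
        assert t.colors.loc["m1", "A"].hue == "red"
        assert t.colors.loc["m1", "B"].hue == "green"
        assert t.colors.loc["m2", "A"].hue == "green"

    def test_all_ones_all_green_zero_intensity(self):
        m = ResultMatrix.from_arrays(
            ["a", "b"], ["A", "B"], [[1.0, 1.0], [1.0, 1.0]]
        )
        t = build_multi_table(m, alpha=0.05)
        for marker in t.marker_ids:
            for name in t.selected_methods:
                color = t.colors.loc[marker, name]
                assert color.hue == "green"
                assert color.intensity == 0.0

    def test_flags_match_brute_force(self):
        rng = np.random.default_rng(33)
        m = random_matrix(rng, 300, 4, missing_rate=0.05)
        alphas = {"meth0": 0.05, "meth1": 0.01, "meth2": 0.1, "meth3": 0.001}
        t = build_multi_table(m, thresholds=ThresholdConfig(alphas))
        for marker in t.marker_ids:
            for name in t.selected_methods:
                p = m.data.loc[marker, name]
                expected = bool((not math.isnan(p)) and p <= alphas[name])
                assert bool(t.significant.loc[marker, name]) is expected

    def test_rows_sorted_by_average_p(self):
        rng = np.random.default_rng(4)
        m = random_matrix(rng, 100, 3)
        t = build_multi_table(m)
        avgs = t.average_p.to_numpy()
        assert np.all(np.diff(avgs) >= -1e-15)

    def test_combined_column_only_when_requested(self):
        rng = np.random.default_rng(8)
        m = random_matrix(rng, 20, 3)
        assert build_multi_table(m).combined_p is None
        t = build_multi_table(m, with_combined=True)
        assert t.combined_p is not None
        assert len(t.combined_p) == 20

    def test_method_without_threshold_is_error(self, tiny_matrix):
        with pytest.raises(ResultMatrixError, match="threshold"):
            build_multi_table(tiny_matrix, thresholds=ThresholdConfig({"T": 0.05}))

    def test_fewer_than_two_methods_is_error(self, tiny_matrix):
        with pytest.raises(ResultMatrixError, match="at least 2"):
            build_multi_table(tiny_matrix, methods=["T"])

    def test_ranking_uses_selected_subset_only(self):
        m = ResultMatrix.from_arrays(
            ["x", "y"], ["A", "B", "C"],
            [[0.4, 0.4, 0.001], [0.3, 0.3, 0.9]],
        )
        t = build_multi_table(m, methods=["A", "B"], alpha=0.05)
        assert t.marker_ids == ["y", "x"]


class TestCommonSignificant:
    def test_spec_example(self):
        m = ResultMatrix.from_arrays(
            ["m1", "m2"], ["A", "B"],
            [[0.01, 0.01], [0.01, 0.9]],
        )
        assert common_significant(m, alpha=0.05) == ["m1"]

    def test_saturation_thresholds(self):
        rng = np.random.default_rng(6)
        m = random_matrix(rng, 50, 3)
        got = common_significant(m, thresholds=ThresholdConfig.uniform(m.method_names, 0.999999))
        assert sorted(got) == sorted(m.marker_ids)

    def test_matches_brute_force_intersection(self):
        rng = np.random.default_rng(77)
        m = random_matrix(rng, 1000, 4, missing_rate=0.02)
        got = common_significant(m, alpha=0.05)
        sets = []
        for k, name in enumerate(m.method_names):
            col = m.pvalues[:, k]
            sets.append({m.marker_ids[i] for i in range(1000)
                         if not math.isnan(col[i]) and col[i] <= 0.05})
        expected = set.intersection(*sets)
        assert set(got) == expected

    def test_anti_monotone_in_method_set(self):
        rng = np.random.default_rng(13)
        m = random_matrix(rng, 400, 4)
        full = set(common_significant(m, alpha=0.2))
        for subset in (["meth0", "meth1"], ["meth0", "meth2", "meth3"]):
            assert full <= set(common_significant(m, subset, alpha=0.2))

    def test_result_ranked_by_average_p(self):
        rng = np.random.default_rng(21)
        m = random_matrix(rng, 200, 3)
        got = common_significant(m, alpha=0.3)
        means = m.data.mean(axis=1)
        assert got == sorted(got, key=lambda mk: means.loc[mk])


class TestThresholdConfig:
    def test_alpha_range_validated(self):
        with pytest.raises(ValueError):
            ThresholdConfig({"A": 0.0})
        with pytest.raises(ValueError):
            ThresholdConfig({"A": 1.0})

    def test_uniform(self):
        cfg = ThresholdConfig.uniform(["A", "B"], 0.01)
        assert cfg.alpha_for("A") == 0.01
        assert cfg.alpha_for("B") == 0.01

    def test_missing_method_error(self):
        cfg = ThresholdConfig({"A": 0.05})
        with pytest.raises(ResultMatrixError):
            cfg.alpha_for("B")
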