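"""Predicted/realized gains, percentages, better-parent comparisons."""

import numpy as np
import pandas as pd
import pytest

from selgain.anova import ComponentSet
from selgain.calibration import parent_means
from selgain.errors import SchemaError, UndefinedStatisticError
from selgain.gains import (better_parent_percent, direct_gain_from_heritability,
                           gain_percent, predicted_gain_direct,
                           predicted_gain_index, predicted_realized_correlation,
                           realized_gain, selection_differential)
from selgain.index import DIRECT, SMITH_HAZEL, IndexDefinition, smith_hazel_weights
from selgain.io_model import ParentTable
from selgain._util import round_half_up


def _components(G, E, traits, f=20, r=3):
    G, E = np.asarray(G, float), np.asarray(E, float)
    return ComponentSet(generation="F3", traits=traits, G=G, E=E, P=G + E,
                        f=f, r=r)


class TestSelectionDifferential:
    def test_selecting_everyone_gives_zero_differential(self):
        means = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        x_s, sd, k = selection_differential(list("abc"), means,
                                            means.mean(), 1.0)
        assert sd == pytest.approx(0.0)

    def test_reported_lint_yield_differential(self):
        # selected-group mean 40.84 against an F2 mean of 19.55
        means = pd.Series([40.84], index=["sel"])
        x_s, sd, _ = selection_differential(["sel"], means, 19.55, 1.0)
        assert round_half_up(sd) == pytest.approx(21.29)

    def test_subset_mean_matches_brute_force(self):
        rng = np.random.default_rng(2)
        means = pd.Series(rng.uniform(5, 20, 12),
                          index=[f"f{i}" for i in range(12)])
        sel = ["f1", "f4", "f9"]
        x_s, sd, k = selection_differential(sel, means, means.mean(), 2.0)
        assert x_s == pytest.approx(np.mean([means[s] for s in sel]))
        assert k == pytest.approx(sd / 2.0)

    def test_zero_sigma_is_undefined(self):
        means = pd.Series([1.0, 2.0], index=list("ab"))
        with pytest.raises(UndefinedStatisticError):
            selection_differential(["a"], means, 1.5, 0.0)


class TestDirectGain:
    @pytest.mark.parametrize("h2,x_s,mean,expected", [
        (60.84, 40.84, 19.55, 12.95),   # lint yield, F2
        (52.74, 31.13, 16.41, 7.76),    # bolls/plant, F2
        (84.31, 16.96, 11.29, 4.78),    # bolls/plant, F3
        (86.50, 41.46, 37.30, 3.60),    # lint percentage, F2
        (89.11, 17.50, 16.65, 0.76),    # lint yield, F4 after Ped.2
    ])
    def test_reported_direct_gain_cells(self, h2, x_s, mean, expected):
        gain = direct_gain_from_heritability(h2, x_s, mean)
        assert round_half_up(gain) == pytest.approx(expected)

    def test_no_genetic_covariance_means_no_response(self):
        assert predicted_gain_direct(2.0, 0.0, 1.5) == 0.0

    def test_own_trait_form_equals_h2_times_differential(self):
        var_g, var_e = 3.0, 2.0
        sigma_p = np.sqrt(var_g + var_e)
        sd_raw = 1.7
        gain = predicted_gain_direct(sd_raw / sigma_p, var_g, sigma_p)
        assert gain == pytest.approx(var_g / (var_g + var_e) * sd_raw)

    def test_nonpositive_sigma_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            predicted_gain_direct(1.0, 1.0, 0.0)


class TestIndexGain:
    def test_single_trait_standard_mode_degenerates_to_direct(self):
        comps = _components([[3.0]], [[1.0]], ("LY/P",))
        w = smith_hazel_weights(comps,
                                IndexDefinition("Ped.1", ("LY/P",), DIRECT))
        sd_raw = 2.0                       # trait-scale differential
        sd_index = w.b[0] * sd_raw         # index-scale differential
        got = predicted_gain_index(w, sd_index, comps, "LY/P")
        sigma_p = np.sqrt(4.0)
        expected = predicted_gain_direct(sd_raw / sigma_p, 3.0, sigma_p)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_zero_weights_give_zero_gain_in_both_modes(self):
        comps = _components(np.zeros((2, 2)), np.eye(2), ("LY/P", "B/P"))
        d = IndexDefinition("I.x", ("LY/P", "B/P"), SMITH_HAZEL)
        w = smith_hazel_weights(comps, d)   # G = 0 -> b = 0
        np.testing.assert_allclose(w.b, 0.0, atol=1e-14)
        assert predicted_gain_index(w, 1.0, comps, "LY/P") == 0.0
        assert predicted_gain_index(w, 1.0, comps, "LY/P",
                                    mode="as_printed") == pytest.approx(0.0,
                                                                        abs=1e-7)

    def test_two_trait_standard_mode_matches_matrix_arithmetic(self):
        G = np.array([[2.0, 0.5], [0.5, 1.0]])
        E = np.array([[2.0, 0.5], [0.5, 1.0]])
        comps = _components(G, E, ("LY/P", "B/P"))
        d = IndexDefinition("I.x", ("LY/P", "B/P"), SMITH_HAZEL)
        w = smith_hazel_weights(comps, d)
        sd_index = 1.3
        got = predicted_gain_index(w, sd_index, comps, "LY/P")
        g_w = G[:, 0]
        expected = sd_index * (w.b @ g_w) / (w.b @ (G + E) @ w.b)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_standard_mode_invariant_to_rescaling_b(self):
        G = np.array([[2.0, 0.5], [0.5, 1.0]])
        E = np.eye(2)
        comps = _components(G, E, ("LY/P", "B/P"))
        w = smith_hazel_weights(
            comps, IndexDefinition("I.x", ("LY/P", "B/P"), SMITH_HAZEL))
        base = predicted_gain_index(w, 1.0, comps, "B/P")
        w2 = smith_hazel_weights(
            comps, IndexDefinition("I.x", ("LY/P", "B/P"), SMITH_HAZEL))
        w2.b = 5.0 * w2.b
        # the index-scale differential rescales with b; the response must not
        assert predicted_gain_index(w2, 5.0 * 1.0, comps, "B/P") == \
            pytest.approx(base, rel=1e-12)

    def test_as_printed_mode_square_root_form(self):
        G = np.array([[2.0, 0.5], [0.5, 1.0]])
        comps = _components(G, np.eye(2), ("LY/P", "B/P"))
        w = smith_hazel_weights(
            comps, IndexDefinition("I.x", ("LY/P", "B/P"), SMITH_HAZEL))
        K = 1.76
        got = predicted_gain_index(w, K, comps, "LY/P", mode="as_printed")
        assert got == pytest.approx(K * np.sqrt(w.b @ G[:, 0]), rel=1e-12)

    def test_as_printed_negative_bracket_warns_nan(self):
        G = np.array([[1.0, -0.9], [-0.9, 1.0]])
        comps = _components(G, np.eye(2), ("LY/P", "B/P"))
        w = smith_hazel_weights(
            comps, IndexDefinition("I.x", ("LY/P",), DIRECT))
        w.b = np.array([-1.0])   # forced negative bracket
        with pytest.warns(UserWarning, match="negative bracket"):
            assert np.isnan(predicted_gain_index(w, 1.0, comps, "LY/P",
                                                 mode="as_printed"))


class TestRealizedAndPercent:
    def test_reported_realized_gain_cell(self):
        assert realized_gain(18.50, 16.65) == pytest.approx(1.85)

    def test_equal_means_give_zero(self):
        assert realized_gain(4.0, 4.0) == 0.0

    @pytest.mark.parametrize("g,mean,expected", [
        (12.95, 19.55, 66.24),
        (0.0, 19.55, 0.0),
        (19.55, 19.55, 100.0),
    ])
    def test_gain_percent_cells(self, g, mean, expected):
        assert round_half_up(gain_percent(g, mean)) == pytest.approx(expected)

    def test_percent_rounds_gain_before_dividing(self):
        # 12.9528 -> 12.95 first, then the percentage
        assert gain_percent(12.9528, 19.55) == pytest.approx(
            100 * 12.95 / 19.55)

    def test_nonpositive_mean_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            gain_percent(1.0, 0.0)


class TestBetterParent:
    def test_reported_family_cell(self):
        assert better_parent_percent(18.85, 13.0) == pytest.approx(145.00)

    def test_family_equal_to_parent_is_100(self):
        assert better_parent_percent(6.31, 6.31) == pytest.approx(100.0)

    def test_micronaire_better_parent_is_the_smaller_value(self):
        pt = ParentTable(means=parent_means())
        assert pt.better_parent("MR") == pytest.approx(4.13)
        assert pt.better_parent("LY/P") == pytest.approx(13.0)

    def test_nonpositive_parent_value_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            better_parent_percent(5.0, 0.0)


class TestPredictedRealizedCorrelation:
    def test_identical_lists_give_one(self):
        g = [1.0, 2.0, 3.0, 4.0]
        assert predicted_realized_correlation(g, g) == pytest.approx(1.0)

    def test_negated_lists_give_minus_one(self):
        g = np.array([1.0, 2.0, 3.5])
        assert predicted_realized_correlation(g, -g) == pytest.approx(-1.0)

    def test_matches_textbook_formula_on_random_lists(self):
        rng = np.random.default_rng(23)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        num = ((x - x.mean()) * (y - y.mean())).sum()
        den = np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert predicted_realized_correlation(x, y) == pytest.approx(
            num / den, rel=1e-12)

    def test_constant_list_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            predicted_realized_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(SchemaError):
            predicted_realized_correlation([1.0, 2.0], [1.0, 2.0, 3.0])
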