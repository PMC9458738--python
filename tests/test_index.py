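"""Selection procedures: Smith-Hazel weights, multiplicative index,
truncation selection."""

import numpy as np
import pandas as pd
import pytest

from selgain.anova import ComponentSet
from selgain.errors import (IndexConstructionError, SchemaError,
                            UndefinedStatisticError)
from selgain.index import (DIRECT, MULTIPLICATIVE, SMITH_HAZEL,
                           IndexDefinition, index_scores,
                           multiplicative_scores, smith_hazel_weights,
                           standard_procedures, truncate_select,
                           union_selected)


def _components(G, E, traits, f=20, r=3):
    G, E = np.asarray(G, float), np.asarray(E, float)
    return ComponentSet(generation="F3", traits=traits, G=G, E=E, P=G + E,
                        f=f, r=r)


class TestSmithHazelWeights:
    def test_p_equal_g_returns_economic_weights(self):
        P = np.array([[2.0, 0.5], [0.5, 1.5]])
        comps = _components(P, np.zeros((2, 2)), ("LY/P", "B/P"))
        d = IndexDefinition("I.x", ("LY/P", "B/P"), SMITH_HAZEL)
        w = smith_hazel_weights(comps, d)
        np.testing.assert_allclose(w.b, [1.0, 1.0], atol=1e-12)

    def test_single_trait_weight_is_heritability_fraction(self):
        comps = _components([[3.0]], [[1.0]], ("LY/P",))
        d = IndexDefinition("Ped.1", ("LY/P",), DIRECT)
        w = smith_hazel_weights(comps, d)
        assert w.b[0] == pytest.approx(0.75)

    def test_two_trait_case_matches_hand_inverted_system(self):
        # P = [[4,1],[1,2]], G = [[2,.5],[.5,1]], a = (1,1)
        # P^-1 = 1/7 [[2,-1],[-1,4]]; G a = (2.5, 1.5); b = (0.5, 0.5)
        comps = _components([[2.0, 0.5], [0.5, 1.0]],
                            [[2.0, 0.5], [0.5, 1.0]], ("LY/P", "B/P"))
        d = IndexDefinition("I.x", ("LY/P", "B/P"), SMITH_HAZEL)
        w = smith_hazel_weights(comps, d)
        np.testing.assert_allclose(w.b, [0.5, 0.5], rtol=1e-12)

    def test_normal_equations_residual_is_tiny_on_random_systems(self):
        rng = np.random.default_rng(13)
        traits = ("LY/P", "B/P", "BW", "SI")
        for _ in range(50):
            a = rng.normal(size=(4, 4))
            G = a @ a.T
            b_ = rng.normal(size=(4, 4))
            E = b_ @ b_.T + 0.5 * np.eye(4)
            comps = _components(G, E, traits)
            d = IndexDefinition("I.x", traits, SMITH_HAZEL)
            w = smith_hazel_weights(comps, d)
            rhs = w.G_sub @ w.a
            resid = np.linalg.norm(w.P_sub @ w.b - rhs)
            assert resid <= 1e-8 * np.linalg.norm(rhs)

    def test_ill_conditioned_p_names_traits(self):
        P = np.array([[1.0, 1.0], [1.0, 1.0 + 1e-15]])
        comps = _components(P * 0.5, P * 0.5, ("LY/P", "B/P"))
        d = IndexDefinition("I.x", ("LY/P", "B/P"), SMITH_HAZEL)
        with pytest.raises(IndexConstructionError, match="LY/P"):
            smith_hazel_weights(comps, d)


class TestScores:
    def _means(self, rng, traits, n=5):
        return pd.DataFrame(rng.uniform(1, 10, size=(n, len(traits))),
                            index=[f"fam{i}" for i in range(n)],
                            columns=traits)

    def test_unit_weight_on_first_trait_reproduces_its_means(self):
        comps = _components(np.diag([1.0, 1.0]), np.zeros((2, 2)),
                            ("LY/P", "B/P"))
        d = IndexDefinition("I.x", ("LY/P", "B/P"), SMITH_HAZEL,
                            weights={"LY/P": 1.0, "B/P": 0.0})
        w = smith_hazel_weights(comps, d)
        means = self._means(np.random.default_rng(2), ["LY/P", "B/P"])
        np.testing.assert_allclose(index_scores(w, means), means["LY/P"])

    def test_scores_equal_brute_force_dot_product(self):
        rng = np.random.default_rng(4)
        traits = ("LY/P", "B/P", "BW")
        comps = _components(np.eye(3) * 2, np.eye(3), traits)
        d = IndexDefinition("I.x", traits, SMITH_HAZEL)
        w = smith_hazel_weights(comps, d)
        means = self._means(rng, list(traits))
        scores = index_scores(w, means)
        for fam in means.index:
            expected = sum(w.b[k] * means.loc[fam, t]
                           for k, t in enumerate(traits))
            assert scores[fam] == pytest.approx(expected, rel=1e-12)

    def test_missing_trait_mean_is_an_input_error(self):
        comps = _components([[1.0]], [[1.0]], ("LY/P",))
        w = smith_hazel_weights(comps,
                                IndexDefinition("Ped.1", ("LY/P",), DIRECT))
        with pytest.raises(SchemaError, match="LY/P"):
            index_scores(w, pd.DataFrame({"B/P": [1.0, 2.0]}))

    def test_single_trait_index_preserves_trait_ranking(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            var_g = float(rng.uniform(0.1, 5))
            var_e = float(rng.uniform(0.1, 5))
            comps = _components([[var_g]], [[var_e]], ("LY/P",))
            w = smith_hazel_weights(
                comps, IndexDefinition("Ped.1", ("LY/P",), DIRECT))
            means = self._means(rng, ["LY/P"], n=8)
            scores = index_scores(w, means)
            assert list(scores.sort_values(ascending=False).index) == \
                list(means["LY/P"].sort_values(ascending=False).index)


class TestMultiplicative:
    def test_dominating_family_scores_highest(self):
        means = pd.DataFrame({"LY/P": [10.0, 5.0], "BW": [4.0, 3.0]},
                             index=["best", "other"])
        s = multiplicative_scores(means)
        assert s["best"] > s["other"]

    def test_constant_trait_does_not_change_ranking(self):
        rng = np.random.default_rng(6)
        means = pd.DataFrame({"LY/P": rng.uniform(5, 15, 6)},
                             index=[f"f{i}" for i in range(6)])
        with_const = means.assign(BW=3.2)
        s1 = multiplicative_scores(means)
        s2 = multiplicative_scores(with_const)
        assert list(s1.rank()) == list(s2.rank())

    def test_scores_equal_brute_force_product(self):
        rng = np.random.default_rng(10)
        means = pd.DataFrame(rng.uniform(1, 9, size=(4, 3)),
                             index=list("abcd"),
                             columns=["LY/P", "B/P", "BW"])
        s = multiplicative_scores(means)
        z = means.to_numpy()
        lo, hi = z.min(axis=0), z.max(axis=0)
        k = lo - 0.01 * (hi - lo)
        expected = (z - k).prod(axis=1)
        np.testing.assert_allclose(s.to_numpy(), expected, rtol=1e-12)

    def test_ranking_invariant_to_positive_affine_rescaling(self):
        rng = np.random.default_rng(12)
        means = pd.DataFrame(rng.uniform(1, 9, size=(6, 2)),
                             index=[f"f{i}" for i in range(6)],
                             columns=["LY/P", "BW"])
        scaled = means * [2.5, 0.3] + [7.0, 1.0]
        s1 = multiplicative_scores(means)
        s2 = multiplicative_scores(scaled)
        assert list(s1.rank()) == list(s2.rank())

    def test_direction_flips_micronaire_preference(self):
        means = pd.DataFrame({"MR": [4.5, 3.9]}, index=["hi", "lo"])
        s = multiplicative_scores(means)
        assert s["lo"] > s["hi"]

    def test_single_family_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            multiplicative_scores(pd.DataFrame({"LY/P": [1.0]}, index=["a"]))


class TestTruncateSelect:
    def test_reported_trial_dimensions_select_eight_of_76(self):
        scores = pd.Series(np.arange(76, dtype=float),
                           index=[f"fam{i}" for i in range(76)])
        out = truncate_select(scores, intensity=0.10)
        assert out.n_selected == 8

    def test_full_intensity_selects_everyone(self):
        scores = pd.Series([3.0, 1.0, 2.0], index=list("abc"))
        out = truncate_select(scores, intensity=1.0)
        assert set(out.selected) == {"a", "b", "c"}

    def test_ties_at_cut_break_by_listing_order(self):
        scores = pd.Series([3.0, 2.0, 2.0, 1.0], index=list("abcd"))
        out = truncate_select(scores, n_selected=2)
        assert out.selected == ("a", "b")

    def test_intensity_and_explicit_count_agree(self):
        rng = np.random.default_rng(3)
        scores = pd.Series(rng.normal(size=40),
                           index=[f"f{i}" for i in range(40)])
        by_frac = truncate_select(scores, intensity=6 / 40)
        by_count = truncate_select(scores, n_selected=6)
        assert by_frac.selected == by_count.selected

    def test_minimum_one_family(self):
        scores = pd.Series([1.0, 2.0], index=list("ab"))
        assert truncate_select(scores, intensity=0.01).n_selected == 1

    def test_nonfinite_scores_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            truncate_select(pd.Series([1.0, np.nan]), intensity=0.5)


class TestUnion:
    def _outcome(self, name, fams):
        scores = pd.Series(np.zeros(len(fams)), index=fams)
        return truncate_select(scores, n_selected=len(fams), procedure=name)

    def test_disjoint_selections_concatenate(self):
        a = self._outcome("Ped.1", [f"x{i}" for i in range(8)])
        b = self._outcome("Ped.2", [f"y{i}" for i in range(8)])
        assert len(union_selected([a, b])) == 16

    def test_identical_selections_deduplicate(self):
        fams = [f"x{i}" for i in range(8)]
        u = union_selected([self._outcome("Ped.1", fams),
                            self._outcome("Ped.2", fams)])
        assert len(u) == 8
        assert u["x0"] == ("Ped.1", "Ped.2")

    def test_random_overlap_matches_set_oracle(self):
        rng = np.random.default_rng(17)
        pool = [f"f{i}" for i in range(30)]
        outs, expected = [], set()
        for k in range(5):
            fams = list(rng.choice(pool, size=8, replace=False))
            outs.append(self._outcome(f"P{k}", fams))
            expected |= set(fams)
        assert set(union_selected(outs)) == expected


class TestStandardProcedures:
    def test_all_eight_with_full_trait_list(self):
        procs = standard_procedures()
        assert [p.name for p in procs] == [
            "Ped.1", "Ped.2", "Ped.3", "I.1", "I.2", "I.3", "I.4", "I.5"]
        kinds = {p.name: p.kind for p in procs}
        assert kinds["I.4"] == SMITH_HAZEL and kinds["I.5"] == MULTIPLICATIVE
        assert len(procs[3].traits) == 7          # yield and components

    def test_f2_trait_set_keeps_only_yield_procedures(self):
        from selgain.traits import F2_TRAITS
        names = [p.name for p in standard_procedures(available=F2_TRAITS)]
        assert names == ["Ped.1", "Ped.2", "Ped.3", "I.1"]

    def test_direct_procedure_must_be_single_trait(self):
        with pytest.raises(SchemaError):
            IndexDefinition("bad", ("LY/P", "B/P"), DIRECT)
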