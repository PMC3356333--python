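"""Community-weighted means and Rao quadratic diversity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import traitbef as tb


def comp(p, plot_id="plot"):
    p = np.asarray(p, dtype=float)
    species = [f"s{i}" for i in range(len(p))]
    return tb.CommunityComposition(plot_id=plot_id, species_ids=species, biomass=p)


def brute_force_rao(p, Z, w=None):
    """Independent oracle: explicit double sum over the pairwise distances."""
    p = np.asarray(p, float)
    Z = np.atleast_2d(np.asarray(Z, float).T).T  # (S, K)
    w = np.ones(Z.shape[1]) if w is None else np.asarray(w, float)
    total = 0.0
    for i in range(len(p)):
        for j in range(len(p)):
            d_ij = float(w @ (Z[i] - Z[j]) ** 2)
            total += p[i] * p[j] * d_ij
    return total


class TestCwm:
    @pytest.mark.parametrize(
        "p, t, expected",
        [
            ([1.0], [5.2], 5.2),
            ([0.5, 0.5], [2.0, 4.0], 3.0),
            ([0.25, 0.75], [2.0, 4.0], 3.5),
        ],
    )
    def test_weighted_mean(self, p, t, expected):
        assert tb.cwm(comp(p), t) == pytest.approx(expected)

    def test_missing_species_trait_rejected(self):
        c = comp([0.5, 0.5])
        with pytest.raises(ValueError, match="without trait value"):
            tb.cwm(c, pd.Series({"s0": 1.0}))

    @given(
        st.lists(st.floats(0.01, 100.0), min_size=2, max_size=8),
        st.data(),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_cwm_within_convex_hull(self, biomass, data):
        t = data.draw(
            st.lists(
                st.floats(-50, 50), min_size=len(biomass), max_size=len(biomass)
            )
        )
        c = comp(biomass)
        value = tb.cwm(c, t)
        present = [ti for ti, pi in zip(t, c.p) if pi > 0]
        assert min(present) - 1e-9 <= value <= max(present) + 1e-9


class TestRaoSingle:
    def test_monoculture_is_zero(self):
        assert tb.rao_q_single(comp([1.0]), [3.3]) == 0.0

    def test_two_species_hand_value(self):
        # 2 * 0.25 * (1 - (-1))^2 = 2
        assert tb.rao_q_single(comp([0.5, 0.5]), [-1.0, 1.0]) == pytest.approx(2.0)

    def test_three_species_hand_value(self):
        q = tb.rao_q_single(comp([1, 1, 1]), [-1.0, 0.0, 1.0])
        assert q == pytest.approx(4.0 / 3.0)

    def test_matches_brute_force_double_sum(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            s = rng.integers(2, 9)
            p = rng.dirichlet(np.ones(s))
            z = rng.normal(size=s)
            got = tb.rao_q_single(comp(p), z)
            assert got == pytest.approx(brute_force_rao(p, z), abs=1e-12)

    def test_unstandardized_declaration_rejected(self):
        with pytest.raises(ValueError, match="standardized"):
            tb.rao_q_single(comp([0.5, 0.5]), [1.0, 2.0], standardized=False)

    def test_species_order_invariance(self):
        rng = np.random.default_rng(1)
        b = rng.gamma(2, 10, 6)
        z = rng.normal(size=6)
        perm = rng.permutation(6)
        assert tb.rao_q_single(comp(b), z) == pytest.approx(
            tb.rao_q_single(comp(b[perm]), z[perm]), abs=1e-12
        )
        assert tb.cwm(comp(b), z) == pytest.approx(tb.cwm(comp(b[perm]), z[perm]))

    def test_maximal_at_even_split_for_two_species(self):
        z = np.array([-0.8, 1.7])
        grid = np.linspace(0.01, 0.99, 99)
        vals = [tb.rao_q_single(comp([a, 1 - a]), z) for a in grid]
        assert grid[int(np.argmax(vals))] == pytest.approx(0.5, abs=0.011)


class TestRaoWeighted:
    @pytest.fixture(scope="class")
    def std_table(self, dataset):
        return tb.standardize_traits(tb.transform_traits(dataset.traits))

    def test_zero_weights(self, std_table):
        c = tb.CommunityComposition(
            "p", std_table.species_ids[:4], np.array([1.0, 2.0, 3.0, 4.0])
        )
        assert tb.rao_q_weighted(c, std_table, np.zeros(18)) == 0.0

    def test_unit_weights_sum_singles(self, std_table):
        c = tb.CommunityComposition(
            "p", std_table.species_ids[:5], np.array([5.0, 1.0, 2.0, 3.0, 4.0])
        )
        singles = sum(
            tb.rao_q_single(c, std_table.values[a]) for a in std_table.trait_abbrevs
        )
        assert tb.rao_q_weighted(c, std_table, np.ones(18)) == pytest.approx(singles)

    def test_additivity_matches_multitrait_brute_force(self, std_table):
        rng = np.random.default_rng(11)
        for _ in range(100):
            idx = rng.choice(60, size=5, replace=False)
            species = [std_table.species_ids[i] for i in idx]
            c = tb.CommunityComposition("p", species, rng.gamma(2, 10, 5))
            w = rng.uniform(0, 2, 18)
            got = tb.rao_q_weighted(c, std_table, w)
            Z = std_table.values.loc[species].to_numpy()
            assert got == pytest.approx(brute_force_rao(c.p, Z, w), abs=1e-10)

    def test_negative_weight_rejected(self, std_table):
        c = tb.CommunityComposition("p", std_table.species_ids[:2], np.array([1.0, 1.0]))
        w = np.ones(18)
        w[3] = -0.1
        with pytest.raises(ValueError, match="negative weight"):
            tb.rao_q_weighted(c, std_table, w)

    def test_unstandardized_table_rejected(self, dataset):
        table = tb.transform_traits(dataset.traits)
        c = tb.CommunityComposition("p", table.species_ids[:2], np.array([1.0, 1.0]))
        with pytest.raises(ValueError, match="standardized"):
            tb.rao_q_weighted(c, table, np.ones(18))


class TestPredictorMatrix:
    def test_full_design_shape(self, predictor_matrix):
        assert predictor_matrix.cwm.shape == (66, 18)
        assert predictor_matrix.fd.shape == (66, 18)
        assert (predictor_matrix.fd.to_numpy() >= 0).all()

    def test_monocultures_have_zero_fd(self, dataset):
        table = tb.transform_traits(dataset.traits)
        comps = [
            c
            for c in tb.compositions_from_table(dataset.mixture)
            if len(c.species_ids) == 1
        ]
        pm = tb.build_predictor_matrix(comps, table)
        assert np.allclose(pm.fd.to_numpy(), 0.0)

    def test_plot_permutation_permutes_rows_only(self, dataset):
        table = tb.transform_traits(dataset.traits)
        comps = [
            c
            for c in tb.compositions_from_table(dataset.mixture)
            if len(c.species_ids) >= 2
        ]
        pm = tb.build_predictor_matrix(comps, table)
        pm_rev = tb.build_predictor_matrix(list(reversed(comps)), table)
        pd.testing.assert_frame_equal(pm.cwm, pm_rev.cwm.iloc[::-1])
        pd.testing.assert_frame_equal(pm.fd, pm_rev.fd.iloc[::-1])

    def test_zero_biomass_plot_excluded(self, dataset):
        table = tb.transform_traits(dataset.traits)
        comps = tb.compositions_from_table(dataset.mixture)[:5]
        dead = tb.CommunityComposition(
            "dead", dataset.pool.species_ids[:3], np.zeros(3)
        )
        pm = tb.build_predictor_matrix(comps + [dead], table)
        assert pm.excluded_plots == ["dead"]
        assert "dead" not in pm.plot_ids

    def test_untransformed_table_rejected(self, dataset):
        comps = tb.compositions_from_table(dataset.mixture)[:2]
        with pytest.raises(ValueError, match="transformed"):
            tb.build_predictor_matrix(comps, dataset.traits)
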