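"""Unit and property tests for the four stability statistics.

Published-table cells are asserted at the printed 2-decimal precision;
algorithmic correctness is checked against independent loop-based oracles on
tiny matrices, and the pairwise-cancellation invariances are exercised with
hypothesis.
"""

import itertools
import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import refstab as rs
from conftest import make_table


def matrices(min_n=3, max_n=6, min_g=3, max_g=5):
    """Random small Ct matrices in a plausible range."""

    @st.composite
    def build(draw):
        n = draw(st.integers(min_n, max_n))
        g = draw(st.integers(min_g, max_g))
        cells = draw(
            st.lists(
                st.floats(10.0, 35.0, allow_nan=False, width=32),
                min_size=n * g,
                max_size=n * g,
            )
        )
        return np.array(cells, dtype=float).reshape(n, g)

    return build()


class TestDescriptives:
    def test_published_means_and_sds(self, asc):
        d = rs.descriptives(asc).round(2)
        assert d.loc["RPLP0", "mean"] == 19.20 and d.loc["RPLP0", "sd"] == 0.53
        assert d.loc["HPRT1", "mean"] == 27.11 and d.loc["HPRT1", "sd"] == 0.71
        assert d.loc["B2M", "sd"] == 0.44
        assert d.loc["ACTB", "range"] == 3.54
        assert d.loc["B2M", "range"] == 1.53

    def test_constant_gene_has_zero_spread(self):
        table = make_table([[20.0, 21.0], [20.0, 22.0], [20.0, 23.0]])
        d = rs.descriptives(table)
        assert d.loc["G1", "sd"] == 0.0 and d.loc["G1", "range"] == 0.0

    def test_range_consistency(self, asc):
        d = rs.descriptives(asc)
        assert ((d["min"] <= d["mean"]) & (d["mean"] <= d["max"])).all()
        np.testing.assert_allclose(d["range"], d["max"] - d["min"])


class TestDeltaCt:
    @pytest.mark.parametrize(
        "condition,gene,expected",
        [("F", "HPRT1", 0.14), ("F", "B2M", 0.14), ("F", "ACTB", 0.16), ("S", "B2M", 0.16)],
    )
    def test_published_cells(self, asc, condition, gene, expected):
        res = rs.delta_ct_stability(asc.select_conditions(condition))
        assert round(res.values[gene], 2) == expected

    def test_constant_offset_pair_has_zero_mutual_term(self):
        # two genes differing by a constant: their mutual dCt SD is 0, so each
        # one's stability equals half the mean SD against the noisy third gene
        table = make_table(
            [[20.0, 22.0, 25.0], [21.0, 23.0, 24.1], [20.5, 22.5, 26.3]]
        )
        res = rs.delta_ct_stability(table)
        sd_13 = statistics.stdev(
            a - b for a, b in zip(table.ct["G1"], table.ct["G3"])
        )
        assert res.values["G1"] == pytest.approx(sd_13 / 2)
        assert res.values["G1"] == pytest.approx(res.values["G2"])

    def test_requires_three_samples(self):
        with pytest.raises(rs.ValidationError):
            rs.delta_ct_stability(make_table([[20.0, 21.0], [20.5, 21.5]]))

    def test_loop_oracle(self, toy_table):
        res = rs.delta_ct_stability(toy_table)
        X = toy_table.matrix()
        for i, gene in enumerate(toy_table.genes):
            sds = [
                statistics.stdev(X[:, i] - X[:, j])
                for j in range(X.shape[1])
                if j != i
            ]
            assert res.values[gene] == pytest.approx(sum(sds) / len(sds), abs=1e-12)


class TestBestKeeper:
    @pytest.mark.parametrize(
        "condition,gene,expected",
        [
            ("F", "RPLP0", 0.16),
            ("F", "B2M", 0.26),
            ("F", "ACTB", 0.35),
            ("F", "GAPDH", 0.40),
            ("S", "RPLP0", 0.14),
        ],
    )
    def test_published_cells(self, asc, condition, gene, expected):
        res = rs.bestkeeper(asc.select_conditions(condition))
        assert round(res.values[gene], 2) == expected

    def test_full_precision_orders_hprt1_below_b2m_in_f(self, asc_f):
        res = rs.bestkeeper(asc_f)
        assert res.values["HPRT1"] < res.values["B2M"]  # both print as 0.26

    def test_constant_gene_mad_zero_and_correlation_missing(self):
        table = make_table([[20.0, 21.0, 25.0], [20.0, 22.0, 24.0], [20.0, 23.0, 26.0]])
        res = rs.bestkeeper(table)
        assert res.values["G1"] == 0.0
        assert np.isnan(res.extras["index_correlation"]["G1"])

    def test_index_is_per_sample_mean(self, toy_table):
        res = rs.bestkeeper(toy_table)
        np.testing.assert_allclose(
            res.extras["index"].to_numpy(), toy_table.matrix().mean(axis=1)
        )

    def test_geometric_center_close_at_typical_ct(self, asc_f):
        arith = rs.bestkeeper(asc_f).values
        geom = rs.bestkeeper(asc_f, center="geometric").values
        assert (arith - geom).abs().max() < 0.01


class TestNormFinder:
    def test_f_condition_top_pair(self, asc_f):
        res = rs.normfinder(asc_f)
        ordered = res.values.sort_values()
        assert set(ordered.index[:2]) == {"B2M", "HPRT1"}

    def test_zero_residual_gene_scores_zero(self):
        # G2 = G1 + 1 and G3 = G1 - 2 leave no interaction residual anywhere
        base = np.array([20.0, 21.0, 20.4, 22.0])
        table = make_table(np.column_stack([base, base + 1, base - 2]))
        res = rs.normfinder(table)
        np.testing.assert_allclose(res.values.to_numpy(), 0.0, atol=1e-12)

    def test_literal_oracle_4x6(self):
        # step-by-step transcription of the ungrouped model's algebra:
        # double-centre, per-gene residual mean square, bias correction
        rng = np.random.default_rng(42)
        X = rng.normal(22.0, 1.0, size=(6, 4))
        table = make_table(X)
        res = rs.normfinder(table)
        n, g = X.shape
        grand = X.mean()
        expected = []
        for i in range(g):
            total_u = 0.0
            for k in range(g):
                sq = 0.0
                for s in range(n):
                    z = X[s, k] - X[:, k].mean() - X[s, :].mean() + grand
                    sq += z * z
                total_u += sq / (n - 1)
                if k == i:
                    u_i = sq / (n - 1)
            t_hat = g / (g - 1) * total_u
            var_i = g / (g - 2) * (u_i - t_hat / g**2)
            expected.append(np.sqrt(max(var_i, 0.0)))
        np.testing.assert_allclose(res.values.to_numpy(), expected, atol=1e-12)

    def test_grouped_variant_penalizes_condition_shift(self):
        # G3 shifts by +2 between the groups; grouped NormFinder must rank it
        # last, and the stable genes first
        rng = np.random.default_rng(3)
        base = rng.normal(0.0, 0.05, size=(8, 4))
        X = base + np.array([20.0, 21.0, 23.0, 26.0])
        X[4:, 2] += 2.0
        table = make_table(X, conditions=["F"] * 4 + ["S"] * 4)
        res = rs.normfinder(table, groups=table.conditions)
        assert res.values.idxmax() == "G3"

    def test_single_sample_group_rejected(self):
        table = make_table(
            np.full((3, 3), 20.0) + np.eye(3) * 0.1,
            conditions=["F", "F", "S"],
        )
        with pytest.raises(rs.ValidationError, match="fewer than 2"):
            rs.normfinder(table, groups=table.conditions)


class TestGeNorm:
    @pytest.mark.parametrize(
        "condition,pair,m",
        [
            ("F", ("B2M", "HPRT1"), 0.07),
            ("S", ("GAPDH", "RPLP0"), 0.07),
        ],
    )
    def test_published_final_pairs(self, asc, condition, pair, m):
        res = rs.genorm(asc.select_conditions(condition))
        assert res.genorm_pair == pair
        assert round(res.values[pair[0]], 2) == m
        assert res.values[pair[0]] == res.values[pair[1]]

    def test_identical_profiles_survive_with_m_zero(self):
        rng = np.random.default_rng(0)
        g1 = rng.normal(20, 0.5, 5)
        X = np.column_stack([g1, g1 + 1.0, rng.normal(24, 0.5, 5), rng.normal(26, 0.8, 5)])
        res = rs.genorm(make_table(X))
        assert res.genorm_pair == ("G1", "G2")
        assert res.values["G1"] == pytest.approx(0.0, abs=1e-12)

    def test_pair_rank_rule(self, asc_f):
        res = rs.genorm(asc_f)
        assert sorted(res.ranks.to_numpy()) == [1.0, 1.0, 3.0, 4.0, 5.0]

    def test_population_denominator_option(self, asc_f):
        sample = rs.genorm(asc_f, sd_denominator="sample")
        pop = rs.genorm(asc_f, sd_denominator="population")
        assert pop.genorm_pair == sample.genorm_pair
        # n-1 vs n denominator scales every SD up
        assert (pop.values <= sample.values).all()

    def test_two_gene_table_equals_delta_ct(self):
        X = np.array([[20.0, 22.1], [20.6, 22.4], [19.9, 22.9], [20.3, 21.8]])
        table = make_table(X)
        g = rs.genorm(table)
        d = rs.delta_ct_stability(table)
        assert g.values["G1"] == pytest.approx(d.values["G1"], abs=1e-12)
        assert g.values["G2"] == pytest.approx(d.values["G2"], abs=1e-12)


class TestInvariances:
    """Pairwise/centring cancellation properties shared by the methods."""

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(matrices())
    def test_sample_shift_invariance(self, X):
        shifts = np.linspace(-1.0, 1.0, X.shape[0])[:, None]
        a, b = make_table(X), make_table(X + shifts)
        for fn in (rs.delta_ct_stability, rs.genorm, rs.normfinder):
            np.testing.assert_allclose(
                fn(a).values.to_numpy(), fn(b).values.to_numpy(), atol=1e-8
            )

    def test_bestkeeper_is_not_sample_shift_invariant(self, toy_table):
        shifts = np.array([0.0, 1.0, -1.0, 0.5])[:, None]
        shifted = make_table(toy_table.matrix() + shifts)
        assert not np.allclose(
            rs.bestkeeper(toy_table).values.to_numpy(),
            rs.bestkeeper(shifted).values.to_numpy(),
        )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(matrices())
    def test_gene_shift_invariance(self, X):
        shifts = np.linspace(-2.0, 2.0, X.shape[1])[None, :]
        a, b = make_table(X), make_table(X + shifts)
        for fn in (rs.delta_ct_stability, rs.bestkeeper, rs.genorm, rs.normfinder):
            np.testing.assert_allclose(
                fn(a).values.to_numpy(), fn(b).values.to_numpy(), atol=1e-8
            )

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(matrices(), st.randoms(use_true_random=False))
    def test_order_invariance(self, X, rnd):
        n, g = X.shape
        rows = list(range(n))
        cols = list(range(g))
        rnd.shuffle(rows)
        rnd.shuffle(cols)
        a = make_table(X)
        b_raw = X[np.ix_(rows, cols)]
        genes_b = [f"G{j + 1}" for j in cols]
        b = make_table(b_raw, genes=genes_b)
        for fn in (rs.delta_ct_stability, rs.bestkeeper, rs.genorm, rs.normfinder):
            va, vb = fn(a).values, fn(b).values
            for gene in va.index:
                assert va[gene] == pytest.approx(vb[gene], abs=1e-8)

    def test_brute_force_pairwise_sd_oracle(self):
        # <=4x4: every pairwise SD via explicit loops matches the vectorized
        # implementations to 1e-12
        rng = np.random.default_rng(11)
        X = rng.normal(22, 1.2, size=(4, 4))
        table = make_table(X)
        d = rs.delta_ct_stability(table)
        g = rs.genorm(table)
        n, ng = X.shape
        pair_sd = {}
        for i, j in itertools.permutations(range(ng), 2):
            diffs = [X[s, i] - X[s, j] for s in range(n)]
            pair_sd[(i, j)] = statistics.stdev(diffs)
        for i, gene in enumerate(table.genes):
            expected = statistics.mean(
                pair_sd[(i, j)] for j in range(ng) if j != i
            )
            assert d.values[gene] == pytest.approx(expected, abs=1e-12)
        # geNorm's first exclusion is the gene with the highest mean pair SD
        worst = max(
            range(ng),
            key=lambda i: statistics.mean(
                pair_sd[(i, j)] for j in range(ng) if j != i
            ),
        )
        assert g.extras["exclusion_order"][0] == table.genes[worst]
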