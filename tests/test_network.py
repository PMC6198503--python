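"""Feature-network machinery: correlation oracle, the scaled-mean filter,
gap-statistic k selection, bootstrap consensus, and Louvain consensus
module detection with versatility diagnostics."""

import numpy as np
import pandas as pd
import pytest

from xyyphen.cohort import generate_cohort
from xyyphen.network import (
    ConsensusMatrix,
    bootstrap_cocluster,
    cluster_variables,
    export_network,
    filter_variables,
    gap_statistic_k,
    louvain_consensus,
    pairwise_correlations,
    versatility_curve,
)

from conftest import planted_config


def _block_consensus(sizes, within=1.0, between=0.0):
    names = [f"m{i}_{j}" for i, s in enumerate(sizes) for j in range(s)]
    blocks = np.repeat(np.arange(len(sizes)), sizes)
    c = np.where(blocks[:, None] == blocks[None, :], within, between)
    np.fill_diagonal(c, 1.0)
    cdf = pd.DataFrame(c, index=names, columns=names)
    return ConsensusMatrix(cdf, cdf * 0 + 1, 1)


class TestCorrelations:
    def test_self_correlation_unity_and_negation(self, rng):
        x = rng.normal(size=50)
        df = pd.DataFrame({"x": x, "y": -x, "z": rng.normal(size=50)})
        cm = pairwise_correlations(df)
        assert cm.r.loc["x", "x"] == 1.0
        assert abs(cm.r.loc["x", "y"] + 1.0) < 1e-12

    def test_matches_textbook_formula(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 5)), columns=list("abcde"))
        cm = pairwise_correlations(df)
        x = df.to_numpy()
        xc = x - x.mean(axis=0)
        cov = xc.T @ xc / (len(df) - 1)
        d = np.sqrt(np.diag(cov))
        ref = cov / np.outer(d, d)
        assert np.allclose(cm.r.to_numpy(), ref, atol=1e-12)

    def test_row_order_invariance(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        shuffled = df.sample(frac=1, random_state=1).reset_index(drop=True)
        assert np.allclose(
            pairwise_correlations(df).r, pairwise_correlations(shuffled).r, atol=1e-12
        )

    def test_per_pair_n_with_missingness(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=20), "b": rng.normal(size=20)})
        df.loc[:4, "a"] = np.nan
        cm = pairwise_correlations(df)
        assert cm.n_eff.loc["a", "b"] == 15
        assert cm.n_eff.loc["b", "b"] == 20

    def test_constant_variable_flagged(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=10), "c": np.ones(10),
                           "b": rng.normal(size=10)})
        cm = pairwise_correlations(df)
        assert cm.undefined == ("c",)
        assert np.isnan(cm.r.loc["c", "a"])


class TestFilter:
    def _corr_with_outlier(self, rng, n=400):
        z = rng.normal(size=(n, 1))
        block = 0.9 * z + 0.45 * rng.normal(size=(n, 9))
        anti = -0.6 * z + 0.8 * rng.normal(size=(n, 1))
        df = pd.DataFrame(np.hstack([block, anti]),
                          columns=[f"g{i}" for i in range(9)] + ["anti"])
        return pairwise_correlations(df)

    def test_anticorrelated_variable_removed(self, rng):
        report = filter_variables(self._corr_with_outlier(rng), tau=-2.0)
        assert report.removed == ["anti"]

    def test_all_equal_mean_correlations_remove_nothing(self):
        n = 5
        c = np.full((n, n), 0.4)
        np.fill_diagonal(c, 1.0)
        names = list("abcde")
        df = pd.DataFrame(c, index=names, columns=names)
        from xyyphen.network import CorrelationMatrix

        corr = CorrelationMatrix(df, df * 0 + 10)
        with pytest.warns(UserWarning, match="equal"):
            report = filter_variables(corr)
        assert report.removed == []

    def test_threshold_monotonicity(self, rng):
        corr = self._corr_with_outlier(rng)
        none_removed = filter_variables(corr, tau=-np.inf)
        assert none_removed.removed == []
        cols = ["variable", "mean_r", "scaled"]
        pd.testing.assert_frame_equal(
            none_removed.table[cols], filter_variables(corr, tau=-2.0).table[cols]
        )

    def test_variable_order_invariance(self, rng):
        corr = self._corr_with_outlier(rng)
        perm = list(np.random.default_rng(3).permutation(corr.variables))
        from xyyphen.network import CorrelationMatrix

        corr_perm = CorrelationMatrix(
            corr.r.loc[perm, perm], corr.n_eff.loc[perm, perm], corr.undefined
        )
        a = filter_variables(corr).table.set_index("variable").sort_index()
        b = filter_variables(corr_perm).table.set_index("variable").sort_index()
        pd.testing.assert_frame_equal(a, b)


class TestGapStatistic:
    def _block_corr(self, rng, r_in=0.8, n=300):
        z1, z2 = rng.normal(size=(n, 1)), rng.normal(size=(n, 1))
        lam = np.sqrt(r_in)
        e = np.sqrt(1 - r_in)
        x = np.hstack([lam * z1 + e * rng.normal(size=(n, 4)),
                       lam * z2 + e * rng.normal(size=(n, 4))])
        return pairwise_correlations(pd.DataFrame(x, columns=[f"v{i}" for i in range(8)]))

    def test_two_planted_blocks_selected(self, rng):
        hits = 0
        for s in range(100):
            corr = self._block_corr(rng)
            k, _ = gap_statistic_k(corr, k_max=5, seed=s)
            hits += k == 2
        assert hits >= 95

    def test_structureless_data_prefers_one_cluster(self, rng):
        hits = 0
        for s in range(50):
            df = pd.DataFrame(rng.normal(size=(100, 8)),
                              columns=[f"v{i}" for i in range(8)])
            k, _ = gap_statistic_k(pairwise_correlations(df), k_max=5, seed=s)
            hits += k == 1
        assert hits > 25

    def test_deterministic_for_seed(self, rng):
        corr = self._block_corr(rng)
        k1, c1 = gap_statistic_k(corr, k_max=6, seed=11)
        k2, c2 = gap_statistic_k(corr, k_max=6, seed=11)
        assert k1 == k2
        pd.testing.assert_frame_equal(c1, c2)

    def test_k_max_clipped_with_warning(self, rng):
        corr = self._block_corr(rng)
        with pytest.warns(UserWarning, match="clipped"):
            gap_statistic_k(corr, k_max=50, seed=0)


class TestClusterVariables:
    def test_k_one_single_cluster(self, rng):
        corr = pairwise_correlations(
            pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        )
        assert cluster_variables(corr, 1).nunique() == 1

    def test_k_equals_p_singletons(self, rng):
        corr = pairwise_correlations(
            pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        )
        assert cluster_variables(corr, 4).nunique() == 4

    def test_perfect_blocks_recovered(self):
        cm = _block_consensus([3, 3])  # use as a correlation matrix
        from xyyphen.network import CorrelationMatrix

        corr = CorrelationMatrix(cm.c.replace(0.0, 0.0), cm.n_valid)
        labels = cluster_variables(corr, 2)
        a = {labels[f"m0_{j}"] for j in range(3)}
        b = {labels[f"m1_{j}"] for j in range(3)}
        assert len(a) == 1 and len(b) == 1 and a != b


class TestBootstrapConsensus:
    def test_single_draw_consensus_is_binary(self, planted_cohort):
        table, _ = planted_cohort
        _, cons = bootstrap_cocluster(table.phenotypes(), n_boot=1, seed=0)
        vals = cons.c.to_numpy()
        assert set(np.unique(vals)) <= {0.0, 1.0}

    def test_planted_modules_separate_in_consensus(self, planted_cohort):
        table, truth = planted_cohort
        _, cons = bootstrap_cocluster(table.phenotypes(), n_boot=200, seed=1)
        names = cons.variables
        part = truth.true_partition
        within, between = [], []
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                (within if part[a] == part[b] else between).append(cons.c.loc[a, b])
        assert np.mean(within) >= 0.9
        assert np.mean(between) <= 0.2

    def test_reproducible_and_symmetric(self, planted_cohort):
        table, _ = planted_cohort
        _, c1 = bootstrap_cocluster(table.phenotypes(), n_boot=25, seed=9)
        _, c2 = bootstrap_cocluster(table.phenotypes(), n_boot=25, seed=9)
        pd.testing.assert_frame_equal(c1.c, c2.c)
        a = c1.c.to_numpy()
        assert np.allclose(a, a.T)
        assert a.min() >= 0 and a.max() <= 1
        assert np.allclose(np.diag(a), 1.0)

    def test_extending_draws_preserves_earlier_ones(self, planted_cohort):
        """Counter-derived sub-seeds: the first draws of a longer run equal
        the draws of a shorter run."""
        table, _ = planted_cohort
        p1, _ = bootstrap_cocluster(table.phenotypes(), n_boot=5, seed=4)
        p2, _ = bootstrap_cocluster(table.phenotypes(), n_boot=10, seed=4)
        assert np.array_equal(p1.resample_indices, p2.resample_indices[:5])
        pd.testing.assert_frame_equal(p1.partitions, p2.partitions.iloc[:5])


class TestLouvainConsensus:
    def test_two_disconnected_cliques(self):
        cons = _block_consensus([4, 4], within=1.0, between=0.0)
        part = louvain_consensus(cons, gamma=1.2, n_runs=50, seed=0)
        assert part.n_modules == 2
        assert (part.versatility == 0).all()
        assert part.n_consensus_iterations == 1

    def test_uniform_complete_graph_low_gamma_one_module(self):
        n = 6
        c = np.full((n, n), 0.8)
        np.fill_diagonal(c, 1.0)
        names = [f"v{i}" for i in range(n)]
        cdf = pd.DataFrame(c, index=names, columns=names)
        cons = ConsensusMatrix(cdf, cdf * 0 + 1, 1)
        part = louvain_consensus(cons, gamma=0.9, n_runs=50, seed=0)
        assert part.n_modules == 1

    def test_three_block_consensus_recovered_exactly(self, planted_cohort):
        _, truth = planted_cohort
        cons = _block_consensus([4, 4, 4])
        part = louvain_consensus(cons, gamma=1.2, n_runs=100, seed=2)
        assert part.n_modules == 3
        blocks = {n.split("_")[0] for n in part.labels.index}
        for b in blocks:
            members = [n for n in part.labels.index if n.startswith(b)]
            assert part.labels[members].nunique() == 1

    def test_labels_contiguous_from_one(self, planted_cohort):
        table, _ = planted_cohort
        _, cons = bootstrap_cocluster(table.phenotypes(), n_boot=40, seed=3)
        part = louvain_consensus(cons, gamma=1.2, n_runs=100, seed=3)
        assert sorted(part.labels.unique()) == list(range(1, part.n_modules + 1))

    def test_gamma_must_be_positive(self):
        cons = _block_consensus([3, 3])
        with pytest.raises(ValueError, match="gamma"):
            louvain_consensus(cons, gamma=0.0)


class TestVersatility:
    def test_curve_bounded_and_zero_under_stable_partitions(self):
        import warnings

        cons = _block_consensus([4, 4])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # flat curve expected here
            curve, gamma_star = versatility_curve(
                cons, np.arange(0.8, 1.7, 0.1), n_runs=30, seed=0
            )
        assert ((curve["mean_versatility"] >= 0) & (curve["mean_versatility"] <= 1)).all()

    def test_flat_curve_returns_midpoint_with_warning(self):
        cons = _block_consensus([3, 3])
        grid = np.array([1.0, 1.1, 1.2])
        with pytest.warns(UserWarning, match="flat"):
            _, gamma_star = versatility_curve(cons, grid, n_runs=20, seed=0)
        assert gamma_star == 1.1

    def test_grid_validation(self):
        cons = _block_consensus([3, 3])
        with pytest.raises(ValueError):
            versatility_curve(cons, np.array([1.0, 0.9, 1.2]), n_runs=10)


class TestExport:
    def test_round_trip_and_attributes(self, planted_cohort, tmp_path):
        import networkx as nx

        table, _ = planted_cohort
        X = table.phenotypes()
        corr = pairwise_correlations(X)
        _, cons = bootstrap_cocluster(X, n_boot=30, seed=6)
        part = louvain_consensus(cons, gamma=1.2, n_runs=50, seed=6, corr=corr)
        g = export_network(cons, part, tmp_path, edge_threshold=0.1, layout_seed=1)

        # edge count matches the threshold rule
        c = cons.c.to_numpy()
        iu = np.triu_indices_from(c, k=1)
        assert g.number_of_edges() == int((c[iu] > 0.1).sum())

        # GraphML round-trips the adjacency
        g2 = nx.read_graphml(tmp_path / "network.graphml")
        for u, v, d in g.edges(data=True):
            assert abs(g2[u][v]["weight"] - d["weight"]) < 1e-9

        # node strength equals the mean off-diagonal correlation
        r = corr.r.to_numpy().copy()
        np.fill_diagonal(r, np.nan)
        for i, name in enumerate(cons.variables):
            assert abs(g.nodes[name]["strength"] - np.nanmean(r[i])) < 1e-12

        # text outputs exist
        assert (tmp_path / "edges.tsv").exists()
        assert (tmp_path / "nodes.csv").exists()
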