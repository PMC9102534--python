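"""CoI rule, correlation, DBSCAN oracle equivalence, municipality mapping."""

import numpy as np
import pandas as pd
import pytest

from ptbstrat.consensus import (
    DBSCANParams,
    centroid_correlation,
    cluster_pmr_stats,
    dbscan_consensus,
    final_cluster_types,
    map_municipalities,
    reduce_correlation,
    run_consensus,
    select_coi,
)


def brute_force_dbscan(X, eps, min_points):
    """Reachability-closure oracle: O(n^2) neighbourhood graph, core points,
    connected core components, then border attachment."""
    n = len(X)
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    neigh = d <= eps
    core = neigh.sum(axis=1) >= min_points  # self included
    labels = np.full(n, -1)
    cur = 0
    for s in range(n):
        if not core[s] or labels[s] != -1:
            continue
        stack, labels[s] = [s], cur
        while stack:
            u = stack.pop()
            for v in np.where(neigh[u])[0]:
                if labels[v] == -1:
                    labels[v] = cur
                    if core[v]:
                        stack.append(v)
        cur += 1
    return labels


def _tagged(rows, h=4, seed=0):
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(rng.random((rows, h)), columns=[f"f{i+1}" for i in range(h)])
    frame.insert(0, "cluster_index", np.arange(rows) % 5)
    frame.insert(0, "model_index", np.arange(rows) // 5 + 1)
    return frame


class TestClusterStats:
    def _assignments(self):
        return pd.DataFrame(
            {
                "municipality_code": ["A", "B", "C", "D"],
                "PMR": [1e-4, 3e-4, 1.15e-4, 0.9e-4],
                "m0001": [0, 0, 1, 1],
            }
        )

    def test_mean_is_plain_average(self):
        stats = cluster_pmr_stats(self._assignments(), 1e-4)
        c0 = stats[stats["cluster_index"] == 0].iloc[0]
        assert c0["mean_pmr"] == pytest.approx(2e-4)
        assert c0["B"] == 2

    def test_ten_percent_rule_boundary_inclusive(self):
        assignments = pd.DataFrame(
            {
                "municipality_code": list("ABC"),
                "PMR": [1.15e-4, 1.10e-4, 0.90e-4],
                "m0001": [0, 1, 2],
            }
        )
        stats = cluster_pmr_stats(assignments, 1.0e-4).set_index("cluster_index")
        assert stats.loc[0, "coi_flag"] == "high"   # +15%
        assert stats.loc[1, "coi_flag"] == "high"   # exactly +10% qualifies
        assert stats.loc[2, "coi_flag"] == "low"    # exactly -10% qualifies

    def test_empty_cluster_forced_none(self):
        centroids = pd.DataFrame(
            {"model_index": [1, 1, 1], "cluster_index": [0, 1, 2], "f1": [0.0, 1.0, 2.0]}
        )
        stats = cluster_pmr_stats(self._assignments(), 1e-4, centroids)
        empty = stats[stats["cluster_index"] == 2].iloc[0]
        assert empty["B"] == 0 and empty["coi_flag"] == "none"

    def test_nonpositive_national_rejected(self):
        with pytest.raises(ValueError):
            cluster_pmr_stats(self._assignments(), 0.0)

    def test_full_ensemble_matches_reaggregation_oracle(self, fitted):
        stats = fitted.consensus.stats
        ac = fitted.mkm.assignments
        rng = np.random.default_rng(1)
        for col in rng.choice(
            [c for c in ac.columns if c[0] == "m" and c[1:].isdigit()], 3, replace=False
        ):
            i = int(col[1:])
            expect = ac.groupby(col)["PMR"].agg(["size", "mean"])
            got = stats[stats["model_index"] == i].set_index("cluster_index")
            for cl, row in expect.iterrows():
                assert got.loc[cl, "B"] == row["size"]
                assert got.loc[cl, "mean_pmr"] == pytest.approx(row["mean"])


class TestSelectCoi:
    def _stats(self, flags):
        return pd.DataFrame(
            {
                "model_index": [1] * len(flags),
                "cluster_index": range(len(flags)),
                "coi_flag": flags,
            }
        )

    def test_none_all_high_and_mixed(self):
        c0 = pd.DataFrame(
            {"model_index": [1] * 4, "cluster_index": range(4), "f1": range(4)}
        )
        assert select_coi(self._stats(["none"] * 4), c0).empty
        all_high = select_coi(self._stats(["high"] * 4), c0)
        pd.testing.assert_frame_equal(all_high, c0)
        mixed = select_coi(self._stats(["high", "none", "low", "none"]), c0)
        assert len(mixed) == 2
        assert set(mixed["cluster_index"]) == {0, 2}

    def test_coi_count_matches_flag_count(self, fitted):
        stats = fitted.consensus.stats
        cci = select_coi(stats, fitted.mkm.centroids)
        assert len(cci) == (stats["coi_flag"] != "none").sum()


class TestCorrelation:
    def test_identical_and_antiparallel(self):
        base = np.array([0.1, 0.5, 0.9, 0.3])
        cci = pd.DataFrame(
            np.vstack([base, base, 1.0 - base]),
            columns=[f"f{i+1}" for i in range(4)],
        )
        cci.insert(0, "cluster_index", [0, 1, 2])
        cci.insert(0, "model_index", [1, 1, 1])
        c1 = centroid_correlation(cci)
        arr = c1.to_numpy()
        assert arr[0, 1] == pytest.approx(1.0)
        assert arr[0, 2] == pytest.approx(-1.0)
        np.testing.assert_allclose(arr, arr.T)
        np.testing.assert_allclose(np.diag(arr), 1.0)

    def test_matches_definitional_oracle(self):
        cci = _tagged(20, h=5, seed=2)
        c1 = centroid_correlation(cci).to_numpy()
        X = cci[[f"f{i+1}" for i in range(5)]].to_numpy()
        for a in range(20):
            for b in range(20):
                xa, xb = X[a] - X[a].mean(), X[b] - X[b].mean()
                rho = (xa @ xb) / np.sqrt((xa @ xa) * (xb @ xb))
                assert abs(c1[a, b] - rho) < 1e-10

    def test_constant_vector_error_names_tag(self):
        cci = _tagged(3, h=4, seed=3)
        cci.loc[1, ["f1", "f2", "f3", "f4"]] = 0.7
        with pytest.raises(ValueError, match=r"\(1, 1\)"):
            centroid_correlation(cci)

    def test_single_centroid_refused(self):
        with pytest.raises(ValueError, match="at least 2"):
            centroid_correlation(_tagged(1))


class TestReduceCorrelation:
    def test_rank_two_keeps_two_columns(self):
        rng = np.random.default_rng(4)
        basis = rng.random((2, 12))
        coords = rng.random((30, 2))
        c1 = pd.DataFrame(coords @ basis)
        crn = reduce_correlation(c1, 0.999)
        assert crn.shape[1] == 2

    def test_minmax_contract(self, fitted):
        crn = reduce_correlation(
            centroid_correlation(
                select_coi(fitted.consensus.stats, fitted.mkm.centroids)
            ),
            0.99,
        )
        arr = crn.to_numpy()
        np.testing.assert_allclose(arr.min(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(arr.max(axis=0), 1, atol=1e-12)


class TestDbscan:
    def _frame(self, X):
        idx = pd.MultiIndex.from_arrays(
            [np.ones(len(X), int), np.arange(len(X))],
            names=["model_index", "cluster_index"],
        )
        return pd.DataFrame(X, index=idx)

    def test_two_dense_blobs(self):
        rng = np.random.default_rng(5)
        X = np.vstack(
            [rng.normal(0.1, 0.005, (60, 3)), rng.normal(0.9, 0.005, (60, 3))]
        )
        labels = dbscan_consensus(self._frame(X), DBSCANParams(0.06, 50))
        assert set(labels[:60]) == {0} and set(labels[60:]) == {1}

    def test_isolated_point_is_noise(self):
        rng = np.random.default_rng(6)
        X = np.vstack([rng.normal(0.5, 0.004, (60, 2)), [[0.0, 0.0]]])
        labels = dbscan_consensus(self._frame(X), DBSCANParams(0.06, 50))
        assert labels.iloc[-1] == -1

    def test_matches_reachability_closure_oracle(self):
        rng = np.random.default_rng(7)
        X = np.vstack(
            [
                rng.normal(0.2, 0.02, (80, 2)),
                rng.normal(0.8, 0.02, (70, 2)),
                rng.random((50, 2)),
            ]
        )
        params = DBSCANParams(eps=0.07, min_points=10)
        got = dbscan_consensus(self._frame(X), params).to_numpy()
        oracle = brute_force_dbscan(X, params.eps, params.min_points)
        # same noise set and same partition up to relabelling
        assert ((got == -1) == (oracle == -1)).all()
        from sklearn.metrics import adjusted_rand_score

        mask = got != -1
        if mask.any():
            assert adjusted_rand_score(got[mask], oracle[mask]) == 1.0

    def test_degenerate_eps_limits(self):
        rng = np.random.default_rng(8)
        X = rng.random((40, 2))
        tiny = dbscan_consensus(self._frame(X), DBSCANParams(1e-9, 2))
        assert (tiny == -1).all()
        huge = dbscan_consensus(self._frame(X), DBSCANParams(1e3, 1))
        assert (huge == 0).all()


class TestMapping:
    def _setup(self):
        assignments = pd.DataFrame(
            {
                "municipality_code": ["A", "B", "C"],
                "PMR": [2e-4, 1e-4, 1.5e-4],
                # model i cluster labels
                "m0001": [0, 1, 1],
                "m0002": [0, 1, 0],
                "m0003": [0, 0, 1],
            }
        )
        tags = pd.MultiIndex.from_tuples(
            [(1, 0), (1, 1), (2, 0), (2, 1), (3, 0), (3, 1)],
            names=["model_index", "cluster_index"],
        )
        # final clusters: 0 (high) from models 1&2 cluster 0; 1 (low) from
        # model 1&2 cluster 1; model 3's clusters are noise
        labels = pd.Series([0, 1, 0, 1, -1, -1], index=tags)
        types = {0: "high", 1: "low"}
        stats = pd.DataFrame(
            {
                "model_index": [t[0] for t in tags],
                "cluster_index": [t[1] for t in tags],
                "B": 1,
                "mean_pmr": [2e-4, 1e-4] * 3,
                "coi_flag": ["high", "low"] * 3,
            }
        )
        return assignments, stats, labels, types

    def test_counts_dominant_type_intensity(self):
        assignments, stats, labels, types = self._setup()
        out = map_municipalities(assignments, stats, labels, types).set_index(
            "municipality_code"
        )
        # A: cluster 0 twice (models 1,2), model 3 noise -> dominant 0, high
        assert out.loc["A", "count_0"] == 2 and out.loc["A", "count_1"] == 0
        assert out.loc["A", "dominant_cluster"] == 0
        assert out.loc["A", "type"] == "high"
        assert out.loc["A", "intensity"] == 2
        # B: cluster 1 twice -> low, intensity -2
        assert out.loc["B", "dominant_cluster"] == 1
        assert out.loc["B", "intensity"] == -2
        # C: one high and one low membership -> tie falls to dominant (lowest label)
        assert out.loc["C", "count_0"] == 1 and out.loc["C", "count_1"] == 1
        assert out.loc["C", "dominant_cluster"] == 0
        assert out.loc["C", "type"] == "high"
        assert out.loc["C", "intensity"] == 0

    def test_never_in_coi_is_unclassified(self):
        assignments, stats, labels, types = self._setup()
        labels[:] = -1  # everything noise
        out = map_municipalities(assignments, stats, labels, types)
        assert (out["type"] == "unclassified").all()
        assert (out["dominant_cluster"] == -1).all()

    def test_intensity_subtraction_rule(self):
        # 7 high-cluster memberships vs 3 low -> +4, type high
        assignments = pd.DataFrame(
            {
                "municipality_code": ["X"],
                "PMR": [1e-4],
                **{f"m{i:04d}": [0] for i in range(1, 8)},
                **{f"m{i:04d}": [1] for i in range(8, 11)},
            }
        )
        tags = []
        for i in range(1, 8):
            tags.append((i, 0))
        for i in range(8, 11):
            tags.append((i, 1))
        idx = pd.MultiIndex.from_tuples(tags, names=["model_index", "cluster_index"])
        labels = pd.Series([0] * 7 + [1] * 3, index=idx)
        stats = pd.DataFrame(
            {
                "model_index": [t[0] for t in tags],
                "cluster_index": [t[1] for t in tags],
                "B": 1,
                "mean_pmr": [2e-4] * 7 + [1e-4] * 3,
                "coi_flag": ["high"] * 7 + ["low"] * 3,
            }
        )
        out = map_municipalities(assignments, stats, labels, {0: "high", 1: "low"})
        assert out.loc[0, "intensity"] == 4
        assert out.loc[0, "type"] == "high"


class TestEndToEnd:
    def test_partition_property(self, fitted):
        cons = fitted.consensus
        n_cci = (cons.stats["coi_flag"] != "none").sum()
        sizes = cons.coi_labels.value_counts()
        assert sizes.sum() == n_cci  # every CoI centroid: one cluster or noise
        assert len(cons.coi_labels) == n_cci

    def test_cluster_types_cover_all_final_clusters(self, fitted):
        cons = fitted.consensus
        finals = set(cons.coi_labels[cons.coi_labels >= 0])
        assert finals == set(cons.cluster_types)
        assert set(cons.cluster_types.values()) <= {"high", "low"}

    def test_no_coi_is_explicit_error(self, bench_a0):
        from ptbstrat import EnsembleConfig, PTBStratification

        a0, _ = bench_a0
        model = PTBStratification(
            a0,
            ensemble=EnsembleConfig(nc_values=(2, 3), reps_per_nc=1, seed=0),
            coi_threshold=50.0,  # nothing can deviate 5000%
        )
        with pytest.raises(ValueError, match="no clusters of interest"):
            model.fit()
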