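"""Correlation clustering and mutual-information representatives."""

import numpy as np
import pandas as pd
import pytest

from oracles import bf_mutual_information, bf_spearman
from peradiomics.redundancy import (
    cluster_features,
    mutual_information_binary,
    reduce_features,
    spearman_abs_matrix,
)


def _table(n=60, seed=0):
    rng = np.random.default_rng(seed)
    base = rng.normal(0, 1, n)
    return pd.DataFrame({
        "a": base,
        "b": base * 2.0 + rng.normal(0, 0.1, n),   # tightly correlated with a
        "c": np.exp(base) + rng.normal(0, 0.05, n),  # monotone transform of a
        "d": rng.normal(0, 1, n),                   # independent
    })


class TestSpearman:
    def test_self_correlation_is_one(self):
        sim = spearman_abs_matrix(_table())
        assert np.allclose(np.diag(sim), 1.0)

    def test_monotone_transform_pair_is_one(self):
        t = _table()
        t["mono"] = t["a"] ** 3
        sim = spearman_abs_matrix(t)
        assert sim.loc["a", "mono"] == pytest.approx(1.0)

    def test_tied_vectors_match_rank_arithmetic_oracle(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 6.0, 5.0]
        t = pd.DataFrame({"x": x, "y": y, "z": np.arange(6.0)})
        sim = spearman_abs_matrix(t)
        assert sim.loc["x", "y"] == pytest.approx(abs(bf_spearman(x, y)))

    def test_requires_three_patients(self):
        with pytest.raises(ValueError):
            spearman_abs_matrix(_table(n=2))


class TestMutualInformation:
    def test_independent_feature_low_mi(self):
        rng = np.random.default_rng(0)
        y = (rng.random(5000) < 0.5).astype(int)
        x = rng.normal(0, 1, 5000)
        assert mutual_information_binary(x, y) < 0.01

    def test_feature_equals_label_one_bit(self):
        y = np.array([0, 1] * 50)
        assert mutual_information_binary(y.astype(float), y) == pytest.approx(1.0)

    def test_toy_table_matches_contingency_oracle(self):
        x = np.array([0.1, 0.2, 0.3, 0.4, 1.1, 1.2, 1.3, 1.4, 2.1, 2.2, 2.3, 2.4])
        y = np.array([0, 0, 0, 1, 0, 1, 1, 1, 0, 0, 1, 1])
        got = mutual_information_binary(x, y, n_bins=3)
        cells = np.zeros((3, 2))
        for xi, yi in zip(np.repeat([0, 1, 2], 4), y):
            cells[xi, yi] += 1
        assert got == pytest.approx(bf_mutual_information(cells))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            mutual_information_binary(np.arange(10.0), np.zeros(10))


class TestClustering:
    def test_identity_similarity_every_feature_own_cluster(self):
        names = ["f1", "f2", "f3"]
        sim = pd.DataFrame(np.eye(3), index=names, columns=names)
        rng = np.random.default_rng(0)
        table = pd.DataFrame(rng.normal(0, 1, (40, 3)), columns=names)
        labels = (rng.random(40) < 0.5).astype(int)
        out = cluster_features(sim, labels, table)
        assert out.table["cluster"].nunique() == 3
        assert out.table["representative"].all()

    def test_block_matrix_two_clusters(self):
        names = ["a1", "a2", "b1", "b2"]
        sim = pd.DataFrame([
            [1.0, 0.9, 0.1, 0.1],
            [0.9, 1.0, 0.1, 0.1],
            [0.1, 0.1, 1.0, 0.9],
            [0.1, 0.1, 0.9, 1.0],
        ], index=names, columns=names)
        rng = np.random.default_rng(1)
        table = pd.DataFrame(rng.normal(0, 1, (40, 4)), columns=names)
        labels = (rng.random(40) < 0.5).astype(int)
        out = cluster_features(sim, labels, table)
        assert out.table["cluster"].nunique() == 2
        assert out.table.loc["a1", "cluster"] == out.table.loc["a2", "cluster"]

    def test_average_linkage_three_feature_case(self):
        # rho: (f1,f2)=0.85, (f1,f3)=0.85, (f2,f3)=0.6
        # merge f1+f2 at d=0.15; cluster-to-f3 average distance
        # (0.15 + 0.4)/2 = 0.275 > 0.2 -> two clusters
        names = ["f1", "f2", "f3"]
        sim = pd.DataFrame([
            [1.0, 0.85, 0.85],
            [0.85, 1.0, 0.6],
            [0.85, 0.6, 1.0],
        ], index=names, columns=names)
        rng = np.random.default_rng(2)
        table = pd.DataFrame(rng.normal(0, 1, (40, 3)), columns=names)
        labels = (rng.random(40) < 0.5).astype(int)
        out = cluster_features(sim, labels, table)
        assert out.table["cluster"].nunique() == 2

    def test_representative_has_max_mi_in_cluster(self):
        rng = np.random.default_rng(3)
        n = 200
        y = (rng.random(n) < 0.4).astype(int)
        base = y + rng.normal(0, 1.0, n)
        table = pd.DataFrame({
            "weak": base + rng.normal(0, 1.0, n),
            "strong": base + rng.normal(0, 0.1, n),
            "noise": rng.normal(0, 1, n),
        })
        reduced, assignment = reduce_features(table, y)
        tab = assignment.table
        for cid in tab["cluster"].unique():
            members = tab[tab["cluster"] == cid]
            rep_mi = members.loc[members["representative"], "mi"].iloc[0]
            assert rep_mi == members["mi"].max()

    def test_cluster_count_non_increasing_in_threshold(self):
        table = _table(n=80, seed=4)
        rng = np.random.default_rng(4)
        labels = (rng.random(80) < 0.5).astype(int)
        sim = spearman_abs_matrix(table)
        n_loose = cluster_features(sim, labels, table, threshold=0.5).table["cluster"].nunique()
        n_strict = cluster_features(sim, labels, table, threshold=0.95).table["cluster"].nunique()
        assert n_loose <= n_strict

    def test_zero_variance_feature_passed_through_unclustered(self):
        table = _table()
        table["flat"] = 1.0
        labels = (np.random.default_rng(0).random(len(table)) < 0.5).astype(int)
        with pytest.warns(UserWarning, match="unclustered"):
            reduced, assignment = reduce_features(table, labels)
        assert assignment.unclustered == ["flat"]
        assert "flat" not in reduced.columns
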