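"""Descriptor similarity clustering, VIF, and admissible predictor sets."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.outliers_influence import variance_inflation_factor

from biomimqsar.clustering import admissible_sets, variable_cluster, vif
from biomimqsar.errors import DomainError
from conftest import exact_corr_columns


def panel_with_corr(corr, names, n=12, seed=0):
    return pd.DataFrame(exact_corr_columns(n, np.asarray(corr), seed=seed), columns=names)


class TestVariableCluster:
    def test_perfectly_correlated_pair_merges_at_100(self):
        x = np.arange(10.0)
        frame = pd.DataFrame({"A": x, "B": 2 * x + 3})
        tree = variable_cluster(frame, ["A", "B"])
        assert tree.merges[0][2] == pytest.approx(100.0, abs=1e-9)

    def test_orthogonal_pair_merges_at_0(self):
        frame = panel_with_corr(np.eye(2), ["A", "B"])
        tree = variable_cluster(frame, ["A", "B"])
        assert tree.merges[0][2] == pytest.approx(0.0, abs=1e-9)

    def test_average_linkage_hand_computed(self):
        """|r| = {AB: .9, AC: .2, BC: .3}: merges at 90% then 100*(1-mean(.8,.7)) = 25%."""
        corr = np.array([[1.0, 0.9, 0.2], [0.9, 1.0, 0.3], [0.2, 0.3, 1.0]])
        tree = variable_cluster(panel_with_corr(corr, list("ABC")), list("ABC"))
        sims = [m[2] for m in tree.merges]
        assert sims[0] == pytest.approx(90.0, abs=1e-8)
        assert sims[1] == pytest.approx(25.0, abs=1e-8)
        assert sims == sorted(sims, reverse=True)

    def test_affine_rescaling_invariance(self):
        corr = np.array([[1.0, 0.7, 0.1], [0.7, 1.0, 0.2], [0.1, 0.2, 1.0]])
        frame = panel_with_corr(corr, list("ABC"))
        scaled = frame.copy()
        scaled["A"] = -3.0 * scaled["A"] + 7.0
        scaled["C"] = 0.01 * scaled["C"] - 1.0
        t1 = variable_cluster(frame, list("ABC"))
        t2 = variable_cluster(scaled, list("ABC"))
        for (a1, b1, s1), (a2, b2, s2) in zip(t1.merges, t2.merges):
            assert (a1, b1) == (a2, b2)
            assert s1 == pytest.approx(s2, abs=1e-8)

    def test_constant_variable_named_in_error(self):
        frame = pd.DataFrame({"A": [1.0, 2.0, 3.0], "B": [5.0, 5.0, 5.0]})
        with pytest.raises(DomainError, match="B"):
            variable_cluster(frame, ["A", "B"])

    def test_default_panel_splits_into_electronic_and_structural(self, panel29):
        panel, _ = panel29
        tree = variable_cluster(panel, ["MW", "TPSA", "alpha", "HBD_HBA", "NRB"])
        clusters = tree.flat_clusters(50.0)
        assert clusters == [["HBD_HBA", "TPSA"], ["MW", "NRB", "alpha"]]

    def test_newick_contains_all_leaves(self, panel29):
        panel, _ = panel29
        tree = variable_cluster(panel, ["MW", "TPSA", "alpha", "HBD_HBA", "NRB"])
        nwk = tree.to_newick()
        assert nwk.endswith(";")
        for leaf in tree.leaves:
            assert leaf in nwk


class TestVif:
    def test_orthogonal_variables_have_unit_vif(self):
        frame = panel_with_corr(np.eye(2), ["A", "B"])
        report = vif(frame, ["A", "B"])
        assert report.vif["A"] == pytest.approx(1.0, abs=1e-9)
        assert report.vif["B"] == pytest.approx(1.0, abs=1e-9)
        assert report.flagged == []

    def test_perfect_collinearity_flagged_infinite(self):
        x = np.arange(8.0)
        frame = pd.DataFrame({"x1": x, "x2": 2 * x, "z": np.arange(8.0) ** 2})
        report = vif(frame, ["x1", "x2", "z"])
        assert np.isinf(report.vif["x1"]) and np.isinf(report.vif["x2"])
        assert set(report.flagged) == {"x1", "x2"}

    def test_matches_statsmodels_oracle(self):
        rng = np.random.default_rng(2)
        frame = pd.DataFrame(rng.normal(size=(15, 3)), columns=list("ABC"))
        frame["B"] += 0.8 * frame["A"]
        report = vif(frame, list("ABC"))
        X = frame.to_numpy()
        Xc = np.column_stack([X, np.ones(len(X))])  # statsmodels wants the constant inline
        for j, name in enumerate("ABC"):
            assert report.vif[name] == pytest.approx(
                variance_inflation_factor(Xc, j), rel=1e-8
            )

    def test_correlation_matrix_symmetric_unit_diagonal(self, panel29):
        panel, _ = panel29
        report = vif(panel, ["MW", "alpha", "NRB"])
        c = report.correlation.to_numpy()
        assert np.allclose(c, c.T)
        assert np.allclose(np.diag(c), 1.0)

    def test_requires_more_compounds_than_variables(self):
        frame = pd.DataFrame(np.random.default_rng(0).normal(size=(4, 3)), columns=list("ABC"))
        with pytest.raises(DomainError):
            vif(frame, list("ABC"))


class TestAdmissibleSets:
    @pytest.fixture
    def two_cluster_tree(self):
        # {A,B} tightly correlated, {C,D,E} tightly correlated, blocks orthogonal
        corr = np.eye(5)
        corr[0, 1] = corr[1, 0] = 0.9
        for i in range(2, 5):
            for j in range(2, 5):
                if i != j:
                    corr[i, j] = 0.8
        frame = panel_with_corr(corr, list("ABCDE"), n=20)
        return variable_cluster(frame, list("ABCDE"))

    def test_exhaustive_counts(self, two_cluster_tree):
        sets = admissible_sets(two_cluster_tree, 50.0, ["L1", "L2"], 3)
        by_size = {k: sum(1 for s in sets if len(s) == k) for k in (1, 2, 3)}
        assert by_size == {1: 2, 2: 10, 3: 12}
        assert len(sets) == 24
        assert len(set(map(tuple, sets))) == 24  # no duplicates

    def test_never_two_members_of_one_cluster(self, two_cluster_tree):
        clusters = [set(c) for c in two_cluster_tree.flat_clusters(50.0)]
        for s in admissible_sets(two_cluster_tree, 50.0, ["L1", "L2"], 3):
            for cl in clusters:
                assert len(cl & set(s)) <= 1

    def test_exactly_one_lipophilicity_member(self, two_cluster_tree):
        for s in admissible_sets(two_cluster_tree, 50.0, ["L1", "L2"], 3):
            assert len({"L1", "L2"} & set(s)) == 1

    def test_deterministic_order(self, two_cluster_tree):
        a = admissible_sets(two_cluster_tree, 50.0, ["L2", "L1"], 3)
        b = admissible_sets(two_cluster_tree, 50.0, ["L1", "L2"], 3)
        assert a == b == sorted(b, key=lambda s: (len(s), s))

    def test_single_variable_cluster(self):
        frame = panel_with_corr(np.eye(2), ["V1", "V2"])
        tree = variable_cluster(frame, ["V1", "V2"])
        sets = admissible_sets(tree, 50.0, ["L1"], 2)
        assert sets == [("L1",), ("L1", "V1"), ("L1", "V2")]

    def test_all_one_cluster_caps_set_size(self):
        # threshold below every merge similarity -> a single flat cluster
        corr = np.full((4, 4), 0.4)
        np.fill_diagonal(corr, 1.0)
        frame = panel_with_corr(corr, list("ABCD"), n=20)
        tree = variable_cluster(frame, list("ABCD"))
        sets = admissible_sets(tree, 10.0, ["L1"], 3)
        assert tree.flat_clusters(10.0) == [["A", "B", "C", "D"]]
        assert max(len(s) for s in sets) <= 2

    def test_empty_lipophilicity_errors(self, two_cluster_tree):
        with pytest.raises(DomainError):
            admissible_sets(two_cluster_tree, 50.0, [], 3)
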