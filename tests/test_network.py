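"""Co-abundance networks: correlation math, the edge rule, hubs, trends."""

import itertools

import numpy as np
import pandas as pd
import pytest

import odorbalance as ob
from odorbalance.exceptions import InsufficientDataError


def pearson_closed_form(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())


def brute_force_edges(data, threshold=0.6, include_negative=True):
    edges = set()
    cols = list(data.columns)
    for a, b in itertools.combinations(cols, 2):
        r = pearson_closed_form(data[a], data[b])
        if (abs(r) if include_negative else r) > threshold:
            edges.add(frozenset((a, b)))
    return edges


class TestPearsonMatrix:
    def test_perfect_linearity(self):
        x = np.arange(5, dtype=float)
        data = pd.DataFrame({"x": x, "y": 2 * x})
        r, p = ob.pearson_matrix(data)
        assert r.loc["x", "y"] == pytest.approx(1.0)
        assert p.loc["x", "y"] == 0.0

    def test_anticorrelation_sign(self):
        x = np.arange(5, dtype=float)
        r, _ = ob.pearson_matrix(pd.DataFrame({"x": x, "y": -x}))
        assert r.loc["x", "y"] == pytest.approx(-1.0)

    def test_five_point_toy_matches_closed_form(self):
        data = pd.DataFrame({"x": [1.0, 2, 4, 5, 8], "y": [3.0, 1, 5, 7, 9]})
        r, p = ob.pearson_matrix(data)
        assert r.loc["x", "y"] == pytest.approx(pearson_closed_form(data["x"], data["y"]))
        from scipy.stats import pearsonr

        assert p.loc["x", "y"] == pytest.approx(pearsonr(data["x"], data["y"]).pvalue)

    def test_constant_column_gives_nan(self):
        data = pd.DataFrame({"x": [1.0, 2, 3], "y": [5.0, 5, 5]})
        r, _ = ob.pearson_matrix(data)
        assert np.isnan(r.loc["x", "y"])

    def test_too_few_samples_rejected(self):
        with pytest.raises(InsufficientDataError):
            ob.pearson_matrix(pd.DataFrame({"x": [1.0, 2], "y": [3.0, 4]}))


class TestBuildNetwork:
    def _r(self, val):
        return pd.DataFrame(
            [[1.0, val], [val, 1.0]], index=["A", "B"], columns=["A", "B"]
        )

    def test_edge_just_above_threshold(self):
        net = ob.build_network(self._r(0.61))
        assert net.has_edge("A", "B")

    def test_no_edge_just_below_threshold(self):
        net = ob.build_network(self._r(0.59), drop_isolated=False)
        assert net.number_of_edges() == 0

    def test_negative_edge_kept_and_signed(self):
        net = ob.build_network(self._r(-0.70))
        assert net.edges["A", "B"]["sign"] == "neg"

    def test_negative_edge_excluded_when_positive_only(self):
        net = ob.build_network(self._r(-0.70), include_negative=False, drop_isolated=False)
        assert net.number_of_edges() == 0

    def test_edge_set_equals_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for trial in range(50):
            n, p = rng.integers(5, 20), rng.integers(3, 8)
            data = pd.DataFrame(
                rng.normal(size=(n, p)), columns=[f"v{j}" for j in range(p)]
            )
            r, _ = ob.pearson_matrix(data)
            net = ob.build_network(r, threshold=0.6)
            got = {frozenset(e) for e in net.edges}
            assert got == brute_force_edges(data)

    def test_raising_threshold_never_adds_edges(self):
        rng = np.random.default_rng(1)
        data = pd.DataFrame(rng.normal(size=(15, 6)))
        data.columns = [f"v{j}" for j in range(6)]
        r, _ = ob.pearson_matrix(data)
        prev = None
        for thr in (0.2, 0.4, 0.6, 0.8):
            edges = {frozenset(e) for e in ob.build_network(r, threshold=thr).edges}
            if prev is not None:
                assert edges <= prev
            prev = edges


class TestHubsAndGroups:
    def test_star_graph_center_degree(self):
        rng = np.random.default_rng(2)
        hub = rng.normal(size=40)
        data = pd.DataFrame({"hub": hub})
        for i in range(4):
            data[f"leaf{i}"] = hub + rng.normal(0, 0.3, size=40)
        r, _ = ob.pearson_matrix(data)
        # keep only hub-leaf edges for a clean star
        for a in [c for c in data if c != "hub"]:
            for b in [c for c in data if c != "hub"]:
                if a != b:
                    r.loc[a, b] = 0.0
        net = ob.build_network(r, threshold=0.6)
        assert ob.hub_degrees(net).iloc[0] == 4
        assert ob.hub_degrees(net).index[0] == "hub"

    def test_compare_groups_degree_difference(self):
        import networkx as nx

        a = nx.Graph([("x", "y"), ("x", "z")])
        b = nx.Graph([("x", "y")])
        out = ob.compare_groups(a, b).set_index("node")
        assert out.loc["x", "degree_diff"] == 1
        assert out.loc["z", "degree_b"] == 0

    def test_group_networks_independent_of_other_group(self, cohort_labels):
        rng = np.random.default_rng(3)
        data = pd.DataFrame(
            np.abs(rng.normal(10, 2, size=(66, 6))), index=cohort_labels.index,
            columns=[f"c{j}" for j in range(6)],
        )
        nets = ob.group_networks(data, cohort_labels)
        perturbed = data.copy()
        perturbed.loc[cohort_labels == "RP"] *= 7.0
        nets2 = ob.group_networks(perturbed, cohort_labels)
        assert set(nets["RG"].edges) == set(nets2["RG"].edges)


class TestPairwiseTrend:
    def test_collinear_pair_r_one(self, cohort_labels):
        x = np.linspace(1, 10, 66)
        data = pd.DataFrame({"a": x, "b": 3 * x + 1}, index=cohort_labels.index)
        trends = ob.pairwise_trend(data, "a", "b", cohort_labels)
        for res in trends.values():
            assert res.r == pytest.approx(1.0)
            assert res.p < 1e-10
            assert res.slope == pytest.approx(3.0)

    def test_group_specific_correlation_ordering(self, cohort_labels):
        rng = np.random.default_rng(4)
        a = rng.normal(size=66)
        b = rng.normal(size=66)
        rg = (cohort_labels == "RG").to_numpy()
        b[rg] = 0.9 * a[rg] + np.sqrt(1 - 0.81) * rng.normal(size=rg.sum())
        data = pd.DataFrame({"a": a, "b": b}, index=cohort_labels.index)
        trends = ob.pairwise_trend(data, "a", "b", cohort_labels)
        assert trends["RG"].r > trends["RP"].r

    def test_symmetric_in_r(self, cohort_labels):
        rng = np.random.default_rng(5)
        data = pd.DataFrame(
            rng.normal(size=(66, 2)), index=cohort_labels.index, columns=["a", "b"]
        )
        ab = ob.pairwise_trend(data, "a", "b", cohort_labels)
        ba = ob.pairwise_trend(data, "b", "a", cohort_labels)
        for g in ab:
            assert ab[g].r == pytest.approx(ba[g].r)

    def test_constant_variable_gives_missing(self, cohort_labels):
        data = pd.DataFrame(
            {"a": np.ones(66), "b": np.arange(66, dtype=float)}, index=cohort_labels.index
        )
        trends = ob.pairwise_trend(data, "a", "b", cohort_labels)
        assert all(v is None for v in trends.values())
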