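import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cryocomm.core_io import CountTable, ValidationError
from cryocomm.network_ecology import (CohesionResult, classify_keystones,
                                      classify_role, cohesion, detect_modules,
                                      focal_association, removal_stability,
                                      zi_pi, ROLE_CONNECTOR, ROLE_MODULE_HUB,
                                      ROLE_NETWORK_HUB, ROLE_PERIPHERAL)
from cryocomm.sparcc_network import CorrelationNetwork, CorrelationResult
from conftest import make_taxonomy


def corr_from(ids, entries):
    n = len(ids)
    rho = np.eye(n)
    for (i, j), v in entries.items():
        rho[i, j] = rho[j, i] = v
    return CorrelationResult(tuple(ids), pd.DataFrame(rho, index=ids, columns=ids),
                             None, 0, {})


def net_from_graph(g):
    return CorrelationNetwork(g, 0.6, 0.05)


class TestDetectModules:
    def test_two_cliques_recovered(self):
        g = nx.Graph()
        for grp in (["a1", "a2", "a3", "a4"], ["b1", "b2", "b3", "b4"]):
            for i, u in enumerate(grp):
                for v in grp[i + 1:]:
                    g.add_edge(u, v, weight=0.9)
        g.add_edge("a1", "b1", weight=0.9)
        part = detect_modules(net_from_graph(g))
        mods_a = {part.assignment[n] for n in ("a1", "a2", "a3", "a4")}
        mods_b = {part.assignment[n] for n in ("b1", "b2", "b3", "b4")}
        assert len(mods_a) == 1 and len(mods_b) == 1 and mods_a != mods_b

    def test_complete_graph_single_module_and_determinism(self):
        g = nx.complete_graph(5)
        part1 = detect_modules(net_from_graph(nx.relabel_nodes(g, str)))
        part2 = detect_modules(net_from_graph(nx.relabel_nodes(g, str)))
        assert len(set(part1.assignment.values())) == 1
        assert part1.assignment == part2.assignment


class TestZiPi:
    def test_pi_zero_when_all_edges_internal(self):
        g = nx.complete_graph(4)
        net = net_from_graph(nx.relabel_nodes(g, str))
        part = detect_modules(net)
        df = zi_pi(net, part)
        assert (df["pi"] == 0.0).all()
        # equal within-module degrees -> zi all zero by the sd-0 convention
        assert (df["zi"] == 0.0).all()

    def test_pi_half_for_even_split(self):
        g = nx.Graph([("x", "a"), ("x", "b")])
        net = net_from_graph(g)
        from cryocomm.network_ecology import ModulePartition
        part = ModulePartition({"x": 0, "a": 0, "b": 1}, 0.0)
        df = zi_pi(net, part)
        assert df.loc["x", "pi"] == pytest.approx(0.5)
        assert df.loc["a", "pi"] == pytest.approx(0.0)


class TestKeystoneClassification:
    @pytest.mark.parametrize("zi, pi, role", [
        (2.6, 0.5, ROLE_MODULE_HUB),
        (1.0, 0.7, ROLE_CONNECTOR),
        (2.5, 0.62, ROLE_NETWORK_HUB),   # boundary inclusive
        (2.49999, 0.61999, ROLE_PERIPHERAL),
        (2.5, 0.0, ROLE_MODULE_HUB),
        (-1.0, 1.0, ROLE_CONNECTOR),
    ])
    def test_threshold_rules(self, zi, pi, role):
        assert classify_role(zi, pi) == role

    @given(st.floats(-5, 5, allow_nan=False), st.floats(0, 1, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_exhaustive_coverage_no_gaps(self, zi, pi):
        role = classify_role(zi, pi)
        expected = {(False, False): ROLE_PERIPHERAL,
                    (True, False): ROLE_MODULE_HUB,
                    (False, True): ROLE_CONNECTOR,
                    (True, True): ROLE_NETWORK_HUB}[(zi >= 2.5, pi >= 0.62)]
        assert role == expected

    def test_frame_classification_marks_keystones(self):
        df = pd.DataFrame({"zi": [3.0, 0.0], "pi": [0.1, 0.9],
                           "module": [0, 0], "degree": [3, 3]},
                          index=["a", "b"])
        out = classify_keystones(df)
        assert out["keystone"].all()


@pytest.fixture
def cohesion_setup():
    ids = ["t1", "t2", "t3"]
    corr = corr_from(ids, {(0, 1): 0.5, (0, 2): -0.4})
    rel = CountTable(data=pd.DataFrame({"s1": [0.5, 0.3, 0.2]}, index=ids),
                     unit="relative_fraction")
    return rel, corr


class TestCohesion:
    def test_hand_worked_example(self, cohesion_setup):
        rel, corr = cohesion_setup
        res = cohesion(rel, corr, qualify="all")
        assert res.positive["s1"] == pytest.approx(0.40)
        assert res.negative["s1"] == pytest.approx(-0.28)

    def test_zero_correlations_give_zero_cohesion(self):
        ids = ["t1", "t2", "t3"]
        corr = corr_from(ids, {})
        rel = CountTable(data=pd.DataFrame({"s1": [0.5, 0.3, 0.2]}, index=ids),
                         unit="relative_fraction")
        res = cohesion(rel, corr, qualify="all")
        assert res.positive["s1"] == 0.0 and res.negative["s1"] == 0.0

    def test_linearity_in_relative_abundance(self, cohesion_setup):
        rel, corr = cohesion_setup
        p1 = np.array([0.5, 0.3, 0.2])
        p2 = np.array([0.1, 0.1, 0.8])
        alpha = 0.3
        mix = alpha * p1 + (1 - alpha) * p2
        def c_of(p):
            t = CountTable(data=pd.DataFrame({"s": p}, index=rel.taxon_ids),
                           unit="relative_fraction")
            r = cohesion(t, corr, qualify="all")
            return r.positive["s"], r.negative["s"]
        cp1, cn1 = c_of(p1)
        cp2, cn2 = c_of(p2)
        cpm, cnm = c_of(mix)
        assert cpm == pytest.approx(alpha * cp1 + (1 - alpha) * cp2, abs=1e-12)
        assert cnm == pytest.approx(alpha * cn1 + (1 - alpha) * cn2, abs=1e-12)

    def test_pearson_null_variant_runs_without_sparcc_result(self):
        rng = np.random.default_rng(12)
        data = rng.dirichlet(np.ones(6), size=8).T
        rel = CountTable(data=pd.DataFrame(data, index=[f"t{i}" for i in range(6)],
                                           columns=[f"s{i}" for i in range(8)]),
                         unit="relative_fraction")
        res = cohesion(rel, None, qualify="pearson_null", n_null=49, seed=1)
        assert (res.positive >= 0).all() and (res.negative <= 0).all()
        res2 = cohesion(rel, None, qualify="pearson_null", n_null=49, seed=1)
        pd.testing.assert_series_equal(res.positive, res2.positive)

    def test_unit_mismatch_rejected(self, cohesion_setup):
        rel, corr = cohesion_setup
        reads = CountTable(data=rel.data * 100, unit="reads")
        with pytest.raises(ValidationError):
            cohesion(reads, corr)


@pytest.fixture
def removal_setup():
    ids = [f"t{i}" for i in range(6)]
    # dense positive correlations within the first 3 taxa (phylum A)
    entries = {(0, 1): 0.8, (0, 2): 0.8, (1, 2): 0.8, (3, 4): 0.3}
    corr = corr_from(ids, entries)
    rel = CountTable(data=pd.DataFrame(
        {"s1": [0.3, 0.2, 0.1, 0.2, 0.1, 0.1],
         "s2": [0.25, 0.25, 0.1, 0.1, 0.2, 0.1]}, index=ids),
        unit="relative_fraction")
    tax = make_taxonomy({t: ("A" if i < 3 else "B") for i, t in enumerate(ids)})
    return rel, corr, tax


class TestRemovalStability:
    def test_fraction_zero_reproduces_unperturbed_cohesion(self, removal_setup):
        rel, corr, tax = removal_setup
        traj = removal_stability(rel, corr, tax, "A", fractions=[0.0],
                                 n_reps=3, seed=0, qualify="all")
        base = cohesion(rel, corr, qualify="all")
        assert traj.mean_positive[0] == pytest.approx(float(base.positive.mean()))
        assert traj.mean_negative[0] == pytest.approx(float(base.negative.mean()))

    def test_fraction_one_equals_phylum_absent_recomputation(self, removal_setup):
        rel, corr, tax = removal_setup
        traj = removal_stability(rel, corr, tax, "A", fractions=[1.0],
                                 n_reps=3, seed=0, qualify="all")
        keep = [t for t in rel.taxon_ids if tax.rank_of(t, "phylum") != "A"]
        sub = rel.data.loc[keep]
        rel2 = CountTable(data=sub / sub.sum(axis=0), unit="relative_fraction")
        corr2 = corr_from(keep, {(0, 1): 0.3})
        base = cohesion(rel2, corr2, qualify="all")
        assert traj.mean_positive[0] == pytest.approx(float(base.positive.mean()))

    def test_removing_correlated_phylum_gives_negative_slope(self, removal_setup):
        rel, corr, tax = removal_setup
        traj_a = removal_stability(rel, corr, tax, "A",
                                   fractions=[0, 0.5, 1.0], n_reps=30, seed=1,
                                   qualify="all")
        assert traj_a.positive_slope < 0

    def test_unknown_phylum_errors(self, removal_setup):
        rel, corr, tax = removal_setup
        with pytest.raises(ValidationError):
            removal_stability(rel, corr, tax, "Z", n_reps=2)


class TestFocalAssociation:
    @pytest.fixture
    def setup(self):
        ids = ["f1", "f2", "x", "y", "z"]
        g = nx.Graph()
        g.add_edge("x", "f1", weight=0.7)
        g.add_edge("y", "f1", weight=0.7)
        g.add_edge("y", "f2", weight=-0.65)
        g.add_edge("z", "x", weight=0.9)  # no focal edge for z
        net = net_from_graph(g)
        corr = corr_from(ids, {})
        abs_t = CountTable(data=pd.DataFrame(
            {"s1": [10.0, 10.0, 30.0, 20.0, 30.0]}, index=ids),
            unit="copies_per_ml")
        return net, corr, abs_t

    def test_single_edge_and_sum_rule(self, setup):
        net, corr, abs_t = setup
        res = focal_association(net, corr, ["f1", "f2"], abs_t)
        assert res.node_class["x"] == "positive"
        # y: +0.7 - 0.65 = +0.05 -> positive by the sum rule
        assert res.node_class["y"] == "positive"
        assert res.node_class["z"] == "none"

    def test_fractions_partition_total_abundance(self, setup):
        net, corr, abs_t = setup
        res = focal_association(net, corr, ["f1", "f2"], abs_t)
        row = res.fractions.loc["all"]
        assert row.sum() == pytest.approx(1.0)
        assert row["focal"] == pytest.approx(0.2)
        assert row["positive"] == pytest.approx(0.5)
        assert row["none"] == pytest.approx(0.3)

    def test_unconnected_focal_set_gives_all_none(self):
        ids = ["f1", "a", "b"]
        net = net_from_graph(nx.Graph([("a", "b")]))
        net.graph["a"]["b"]["weight"] = 0.9
        abs_t = CountTable(data=pd.DataFrame({"s1": [25.0, 50.0, 25.0]},
                                             index=ids), unit="copies_per_ml")
        res = focal_association(net, corr_from(ids, {}), ["f1"], abs_t)
        assert res.fractions.loc["all", "none"] == pytest.approx(0.75)
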