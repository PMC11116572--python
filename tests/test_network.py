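import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from soilconet.datatypes import AbundanceTable, ValidationError
from soilconet.network import (
    ROLE_CONNECTOR,
    ROLE_MODULE_HUB,
    ROLE_NETWORK_HUB,
    ROLE_PERIPHERAL,
    analyze_network,
    build_network,
    classify_roles,
    detect_modules,
    partition_modularity,
    topology,
    zi_pi,
)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def zi_pi_oracle(g, modules):
    """Per-definition Zi/Pi computed with plain loops."""
    out = {}
    members = {}
    for node, mod in modules.items():
        members.setdefault(mod, []).append(node)
    for node in g.nodes:
        own = modules[node]
        k_to = {}
        for nbr in g.neighbors(node):
            k_to[modules[nbr]] = k_to.get(modules[nbr], 0) + 1
        ks = [
            sum(1 for nbr in g.neighbors(m) if modules[nbr] == own)
            for m in members[own]
        ]
        mean, sd = np.mean(ks), np.std(ks)
        zi = 0.0 if sd == 0 else (k_to.get(own, 0) - mean) / sd
        k = g.degree(node)
        pi = 0.0 if k == 0 else 1 - sum((v / k) ** 2 for v in k_to.values())
        out[node] = (zi, pi)
    return out


def modularity_oracle(g, modules):
    """Q = sum_c [L_c/E - (d_c/2E)^2]."""
    e = g.number_of_edges()
    groups = {}
    for node, mod in modules.items():
        groups.setdefault(mod, set()).add(node)
    q = 0.0
    for nodes in groups.values():
        l_c = sum(1 for u, v in g.edges if u in nodes and v in nodes)
        d_c = sum(g.degree(n) for n in nodes)
        q += l_c / e - (d_c / (2 * e)) ** 2
    return q


def triangles_oracle(g, node):
    nbrs = list(g.neighbors(node))
    return sum(
        1 for a, b in itertools.combinations(nbrs, 2) if g.has_edge(a, b)
    )


# ---------------------------------------------------------------------------
# build_network
# ---------------------------------------------------------------------------

def _table(counts, domain="bacteria"):
    return AbundanceTable(pd.DataFrame(counts), domain)


class TestBuildNetwork:
    def test_two_covarying_taxa_one_edge(self, rng):
        base = np.arange(1, 11)
        counts = pd.DataFrame(
            {
                "T1": base * 3,
                "T2": base * 5,
                "T3": rng.integers(1, 50, size=10),
            }
        )
        g = build_network(_table(counts), r_threshold=0.7, alpha=0.05,
                          min_prevalence=0.0)
        assert g.has_edge("T1", "T2")
        assert g.edges["T1", "T2"]["rho"] == pytest.approx(1.0)
        assert g.edges["T1", "T2"]["sign"] == "+"

    def test_every_edge_satisfies_both_thresholds(self, default_bundle):
        _, _, bact, fungi, _ = default_bundle
        g = build_network(bact, fungi, r_threshold=0.6, alpha=0.05)
        assert g.number_of_nodes() > 0
        for _, _, d in g.edges(data=True):
            assert abs(d["rho"]) > 0.6
            assert d["q"] < 0.05
            assert d["sign"] == ("+" if d["rho"] > 0 else "-")

    def test_no_self_loops_and_no_isolates(self, default_bundle):
        _, _, bact, fungi, _ = default_bundle
        g = build_network(bact, fungi, r_threshold=0.6, alpha=0.05)
        assert nx.number_of_selfloops(g) == 0
        assert all(g.degree(n) > 0 for n in g.nodes)

    def test_too_few_samples_rejected(self, rng):
        counts = pd.DataFrame(rng.integers(0, 10, size=(4, 6)))
        with pytest.raises(ValidationError):
            build_network(_table(counts))

    def test_node_attributes_carry_domain(self, default_bundle):
        _, _, bact, fungi, _ = default_bundle
        g = build_network(bact, fungi, r_threshold=0.6, alpha=0.05)
        domains = {d["domain"] for _, d in g.nodes(data=True)}
        assert domains <= {"bacteria", "fungi"}


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

class TestTopology:
    def test_complete_graph_closed_forms(self):
        g = nx.complete_graph(4)
        nx.set_node_attributes(g, "bacteria", "domain")
        s = topology(g)
        assert s.density == pytest.approx(1.0)
        assert s.average_clustering == pytest.approx(1.0)
        assert s.average_degree == pytest.approx(3.0)

    def test_path_graph_zero_clustering(self):
        g = nx.path_graph(3)
        s = topology(g)
        assert s.average_clustering == 0.0

    def test_triangle_counts_match_bruteforce(self, rng):
        g = nx.gnp_random_graph(15, 0.4, seed=7)
        for node in g.nodes:
            deg = g.degree(node)
            expected = (
                0.0
                if deg < 2
                else 2 * triangles_oracle(g, node) / (deg * (deg - 1))
            )
            assert nx.clustering(g, node) == pytest.approx(expected, abs=1e-12)

    def test_empty_graph_warns_all_zero(self):
        with pytest.warns(UserWarning):
            s = topology(nx.Graph())
        assert s.n_nodes == 0 and s.average_degree == 0.0

    def test_fraction_partition(self, default_bundle):
        _, _, bact, fungi, _ = default_bundle
        g = build_network(bact, fungi, r_threshold=0.6, alpha=0.05)
        s = topology(g)
        assert s.bacterial_fraction + s.fungal_fraction == pytest.approx(1.0)
        assert s.positive_edge_fraction + s.negative_edge_fraction == pytest.approx(1.0)
        assert s.average_degree == pytest.approx(2 * s.n_edges / s.n_nodes)


# ---------------------------------------------------------------------------
# module detection
# ---------------------------------------------------------------------------

class TestDetectModules:
    def test_two_disjoint_cliques(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        modules, q = detect_modules(g)
        comms = {}
        for node, mod in modules.items():
            comms.setdefault(mod, set()).add(node)
        assert sorted(len(c) for c in comms.values()) == [5, 5]
        assert q == pytest.approx(modularity_oracle(g, modules), abs=1e-12)
        assert q == pytest.approx(0.5)

    def test_single_clique_one_module(self):
        g = nx.complete_graph(6)
        modules, _ = detect_modules(g)
        assert len(set(modules.values())) == 1

    def test_edgeless_graph_singletons(self):
        g = nx.empty_graph(4)
        modules, q = detect_modules(g)
        assert len(set(modules.values())) == 4
        assert q == 0.0

    def test_q_matches_oracle_on_random_graph(self, rng):
        g = nx.gnp_random_graph(20, 0.3, seed=11)
        modules, q = detect_modules(g)
        assert q == pytest.approx(modularity_oracle(g, modules), abs=1e-12)

    def test_deterministic(self):
        g = nx.gnp_random_graph(30, 0.2, seed=5)
        m1, q1 = detect_modules(g, seed=1)
        m2, q2 = detect_modules(g, seed=2)
        assert m1 == m2 and q1 == q2

    def test_partition_modularity_matches_networkx(self, rng):
        g = nx.gnp_random_graph(12, 0.5, seed=3)
        modules = {n: n % 3 for n in g.nodes}
        assert partition_modularity(g, modules) == pytest.approx(
            modularity_oracle(g, modules), abs=1e-12
        )


# ---------------------------------------------------------------------------
# Zi / Pi
# ---------------------------------------------------------------------------

class TestZiPi:
    def test_all_edges_inside_module_pi_zero(self):
        g = nx.complete_graph(5)
        modules = {n: 0 for n in g.nodes}
        zp = zi_pi(g, modules)
        assert (zp["Pi"] == 0).all()

    def test_even_split_pi_closed_form(self):
        # star center with one leaf in each of m foreign modules
        for m in (2, 3, 4):
            g = nx.star_graph(m)
            modules = {0: 99}
            for leaf in range(1, m + 1):
                modules[leaf] = leaf
            zp = zi_pi(g, modules)
            assert zp.at[0, "Pi"] == pytest.approx(1 - 1 / m)

    def test_star_center_max_zi(self):
        g = nx.star_graph(6)
        g.add_edge(1, 2)  # some leaf structure
        modules = {n: 0 for n in g.nodes}
        zp = zi_pi(g, modules)
        assert zp["Zi"].idxmax() == 0
        oracle = zi_pi_oracle(g, modules)
        for node, (zi, pi) in oracle.items():
            assert zp.at[node, "Zi"] == pytest.approx(zi, abs=1e-12)
            assert zp.at[node, "Pi"] == pytest.approx(pi, abs=1e-12)

    def test_matches_oracle_on_random_graphs(self, rng):
        for trial in range(20):
            g = nx.gnp_random_graph(12, 0.35, seed=trial)
            modules = {n: int(rng.integers(0, 3)) for n in g.nodes}
            zp = zi_pi(g, modules)
            oracle = zi_pi_oracle(g, modules)
            for node, (zi, pi) in oracle.items():
                assert zp.at[node, "Zi"] == pytest.approx(zi, abs=1e-10)
                assert zp.at[node, "Pi"] == pytest.approx(pi, abs=1e-10)

    def test_zi_zero_mean_within_module(self, rng):
        g = nx.gnp_random_graph(20, 0.4, seed=2)
        modules, _ = detect_modules(g)
        zp = zi_pi(g, modules)
        for mod, sub in zp.groupby("module"):
            if sub["Zi"].abs().sum() > 0:
                assert sub["Zi"].mean() == pytest.approx(0.0, abs=1e-10)

    def test_pi_bounded(self, rng):
        g = nx.gnp_random_graph(25, 0.3, seed=9)
        modules = {n: int(rng.integers(0, 4)) for n in g.nodes}
        zp = zi_pi(g, modules)
        n_modules = len(set(modules.values()))
        assert (zp["Pi"] >= -1e-12).all()
        assert (zp["Pi"] <= 1 - 1 / n_modules + 1e-12).all()

    def test_missing_module_rejected(self):
        g = nx.complete_graph(3)
        with pytest.raises(ValidationError):
            zi_pi(g, {0: 0, 1: 0})


class TestClassifyRoles:
    @pytest.mark.parametrize(
        "zi,pi,role",
        [
            (3.0, 0.5, ROLE_MODULE_HUB),
            (1.0, 0.7, ROLE_CONNECTOR),
            (3.0, 0.7, ROLE_NETWORK_HUB),
            (1.0, 0.5, ROLE_PERIPHERAL),
            (2.5, 0.62, ROLE_PERIPHERAL),  # thresholds are strict
            (2.51, 0.62, ROLE_MODULE_HUB),
            (2.5, 0.63, ROLE_CONNECTOR),
        ],
    )
    def test_threshold_rules(self, zi, pi, role):
        zp = pd.DataFrame({"Zi": [zi], "Pi": [pi]}, index=["t"])
        out = classify_roles(zp)
        assert out.at["t", "role"] == role
        assert out.at["t", "keystone"] == (role != ROLE_PERIPHERAL)

    def test_keystone_counted_once(self):
        zp = pd.DataFrame({"Zi": [3.0], "Pi": [0.7]}, index=["t"])
        out = classify_roles(zp)
        assert int(out["keystone"].sum()) == 1


class TestAnalyzeNetwork:
    def test_annotates_graph(self, default_bundle):
        _, _, bact, fungi, _ = default_bundle
        g = build_network(bact, fungi, r_threshold=0.6, alpha=0.05)
        nodes, summary = analyze_network(g)
        assert set(nodes.columns) >= {"module", "Zi", "Pi", "role", "keystone"}
        for node in g.nodes:
            assert g.nodes[node]["role"] in {
                ROLE_PERIPHERAL,
                ROLE_MODULE_HUB,
                ROLE_CONNECTOR,
                ROLE_NETWORK_HUB,
            }
        assert summary.n_nodes == g.number_of_nodes()
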