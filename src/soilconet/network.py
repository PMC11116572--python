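"""Cross-domain co-occurrence networks: construction, topology, module
detection, Zi-Pi connectivity, and keystone-role classification.

Edges are taxon pairs whose Spearman correlation satisfies |rho| > r
AND BH-adjusted q < alpha, with one BH family per network build (all tested
pairs, within- plus cross-domain). Isolated taxa never enter the graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .association import bh_adjust, spearman_matrix
from .datatypes import AbundanceTable, ValidationError

ROLE_PERIPHERAL = "peripheral"
ROLE_MODULE_HUB = "module hub"
ROLE_CONNECTOR = "connector"
ROLE_NETWORK_HUB = "network hub"


def prevalence_filter(table: AbundanceTable, min_prevalence: float) -> AbundanceTable:
    """Keep taxa present (count > 0) in at least ``min_prevalence`` of samples."""
    frac = (table.counts > 0).mean(axis=0)
    keep = frac.index[frac >= min_prevalence]
    return AbundanceTable(table.counts[list(keep)], table.domain, table.lineage)


def build_network(
    bact: AbundanceTable,
    fungi: AbundanceTable | None = None,
    r_threshold: float = 0.7,
    alpha: float = 0.05,
    min_prevalence: float = 1 / 3,
) -> nx.Graph:
    """Build the co-occurrence graph over bacterial (and optionally fungal) taxa.

    All prevalence-passing taxa are tested all-vs-all with Spearman on
    counts; BH runs over every tested pair; an edge is kept iff
    |rho| > ``r_threshold`` and q < ``alpha``. Nodes without a surviving
    edge are dropped.
    """
    tables = [bact] if fungi is None else [bact, fungi]
    samples = tables[0].sample_ids
    for t in tables[1:]:
        if list(t.sample_ids) != list(samples):
            raise ValidationError("tables must share an identical sample set")
    if len(samples) < 5:
        raise ValidationError(
            "co-occurrence networks need at least 5 samples (rank correlation degenerates)"
        )

    filtered = [prevalence_filter(t, min_prevalence) for t in tables]
    frames, domains, lineages = [], {}, {}
    for t in filtered:
        frames.append(t.counts.astype(float))
        for taxon in t.taxon_ids:
            domains[taxon] = t.domain
            lineages[taxon] = t.lineage.loc[taxon].to_dict()
    merged = pd.concat(frames, axis=1)
    if merged.columns.has_duplicates:
        raise ValidationError("taxon ids collide across domains")

    rho, p = spearman_matrix(merged)
    taxa = list(merged.columns)
    k = len(taxa)
    iu = np.triu_indices(k, k=1)
    rho_flat = rho.to_numpy()[iu]
    q_flat = bh_adjust(p.to_numpy()[iu])

    g = nx.Graph(
        r_threshold=float(r_threshold),
        alpha=float(alpha),
        min_prevalence=float(min_prevalence),
        n_samples=len(samples),
        n_taxa_tested=k,
        n_pairs_tested=len(rho_flat),
    )
    keep = (np.abs(rho_flat) > r_threshold) & (q_flat < alpha)
    for idx in np.flatnonzero(keep):
        a, b = taxa[iu[0][idx]], taxa[iu[1][idx]]
        r = float(rho_flat[idx])
        for node in (a, b):
            if node not in g:
                g.add_node(node, domain=domains[node], **lineages[node])
        g.add_edge(a, b, rho=r, q=float(q_flat[idx]), sign="+" if r > 0 else "-")
    return g


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

@dataclass
class TopologySummary:
    """Network-level properties mirroring a co-occurrence topology table."""

    n_nodes: int
    n_edges: int
    bacterial_fraction: float
    fungal_fraction: float
    positive_edge_fraction: float
    negative_edge_fraction: float
    average_degree: float
    average_clustering: float
    density: float
    modularity: float

    def to_series(self) -> pd.Series:
        return pd.Series(self.__dict__)


def topology(g: nx.Graph, modules: dict | None = None) -> TopologySummary:
    """Average degree, clustering, density and modularity of ``g``.

    ``modules`` may supply a precomputed partition; otherwise one is
    detected. An empty graph reports all-zero metrics with a warning.
    """
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        warnings.warn("empty graph: topology metrics are all zero", stacklevel=2)
        return TopologySummary(0, 0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    domains = nx.get_node_attributes(g, "domain")
    n_bact = sum(1 for d in domains.values() if d == "bacteria")
    n_fungi = sum(1 for d in domains.values() if d == "fungi")
    signs = [d.get("sign", "+") for _, _, d in g.edges(data=True)]
    n_pos = sum(1 for s in signs if s == "+")
    if modules is None:
        modules, q = detect_modules(g)
    else:
        q = partition_modularity(g, modules)
    return TopologySummary(
        n_nodes=n,
        n_edges=e,
        bacterial_fraction=n_bact / n,
        fungal_fraction=n_fungi / n,
        positive_edge_fraction=(n_pos / e) if e else 0.0,
        negative_edge_fraction=((e - n_pos) / e) if e else 0.0,
        average_degree=2.0 * e / n,
        average_clustering=float(np.mean(list(nx.clustering(g).values()))),
        density=2.0 * e / (n * (n - 1)) if n > 1 else 0.0,
        modularity=q,
    )


def partition_modularity(g: nx.Graph, modules: dict) -> float:
    """Newman modularity Q of a node -> module-id partition (unweighted)."""
    if g.number_of_edges() == 0:
        return 0.0
    groups: dict[object, set] = {}
    for node, mod in modules.items():
        groups.setdefault(mod, set()).add(node)
    return float(nx.community.modularity(g, groups.values(), weight=None))


def detect_modules(g: nx.Graph, seed: int | None = None) -> tuple[dict, float]:
    """Greedy modularity maximisation on the unweighted, sign-blind graph.

    Returns ``(module_of, Q)``. An edgeless graph yields singleton modules
    with Q = 0. Node order is fixed before detection so results are
    deterministic; ``seed`` is accepted for interface stability.
    """
    if g.number_of_edges() == 0:
        return {node: i for i, node in enumerate(sorted(g.nodes))}, 0.0
    h = nx.Graph()
    h.add_nodes_from(sorted(g.nodes))
    h.add_edges_from(sorted((min(u, v), max(u, v)) for u, v in g.edges))
    communities = nx.community.greedy_modularity_communities(h, weight=None)
    module_of = {}
    for i, comm in enumerate(sorted(communities, key=lambda c: sorted(c)[0])):
        for node in comm:
            module_of[node] = i
    q = partition_modularity(g, module_of)
    return module_of, q


# ---------------------------------------------------------------------------
# Zi-Pi and keystone roles
# ---------------------------------------------------------------------------

def zi_pi(g: nx.Graph, modules: dict) -> pd.DataFrame:
    """Within-module (Zi) and among-module (Pi) connectivity per node.

    Zi = (k_is - mean_s) / sd_s, where k_is counts node i's edges into its
    own module s and mean/sd run over the members of s (population sd;
    Zi = 0 when sd is 0). Pi = 1 - sum_t (k_it / k_i)^2 over all modules t.
    """
    missing = [node for node in g.nodes if node not in modules]
    if missing:
        raise ValidationError(f"nodes without a module assignment: {missing[:5]}")

    within_degree = {}
    module_links: dict[object, dict] = {}
    for node in g.nodes:
        own = modules[node]
        links: dict[object, int] = {}
        for nbr in g.neighbors(node):
            links[modules[nbr]] = links.get(modules[nbr], 0) + 1
        module_links[node] = links
        within_degree[node] = links.get(own, 0)

    members: dict[object, list] = {}
    for node in g.nodes:
        members.setdefault(modules[node], []).append(node)

    stats_by_module = {}
    for mod, nodes in members.items():
        ks = np.array([within_degree[n] for n in nodes], dtype=float)
        stats_by_module[mod] = (ks.mean(), ks.std(ddof=0))

    rows = {}
    for node in g.nodes:
        mean_s, sd_s = stats_by_module[modules[node]]
        zi = 0.0 if sd_s == 0 else (within_degree[node] - mean_s) / sd_s
        k_i = g.degree(node)
        if k_i == 0:
            pi = 0.0
        else:
            pi = 1.0 - sum((k / k_i) ** 2 for k in module_links[node].values())
        rows[node] = {"module": modules[node], "Zi": zi, "Pi": pi, "degree": k_i}
    return pd.DataFrame.from_dict(rows, orient="index")


def classify_roles(
    zipi: pd.DataFrame, zi_threshold: float = 2.5, pi_threshold: float = 0.62
) -> pd.DataFrame:
    """Assign Zi-Pi roles; the keystone set is every non-peripheral node."""
    out = zipi.copy()
    hub = out["Zi"] > zi_threshold
    conn = out["Pi"] > pi_threshold
    role = np.where(
        hub & conn,
        ROLE_NETWORK_HUB,
        np.where(hub, ROLE_MODULE_HUB, np.where(conn, ROLE_CONNECTOR, ROLE_PERIPHERAL)),
    )
    out["role"] = role
    out["keystone"] = out["role"] != ROLE_PERIPHERAL
    return out


def analyze_network(g: nx.Graph, seed: int | None = None):
    """Detect modules, compute Zi-Pi roles, annotate ``g`` in place.

    Returns ``(node_table, topology_summary)``; node attributes ``module``,
    ``Zi``, ``Pi``, ``role`` are written onto the graph for export.
    """
    modules, _ = detect_modules(g, seed=seed)
    nodes = classify_roles(zi_pi(g, modules)) if g.number_of_nodes() else pd.DataFrame(
        columns=["module", "Zi", "Pi", "degree", "role", "keystone"]
    )
    summary = topology(g, modules=modules)
    for node in g.nodes:
        g.nodes[node]["module"] = int(nodes.at[node, "module"])
        g.nodes[node]["Zi"] = float(nodes.at[node, "Zi"])
        g.nodes[node]["Pi"] = float(nodes.at[node, "Pi"])
        g.nodes[node]["role"] = str(nodes.at[node, "role"])
    return nodes, summary
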