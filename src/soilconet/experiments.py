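"""Recovery and calibration experiments on synthetic communities.

These are the benchmark runs the test suite and the acceptance report both
execute: planted-structure recovery (modules, hubs, connectors), FDR null
calibration of network construction, density contrast between
contaminated-like and uncontaminated-like configurations, metal-responder
detection power, and permutation-test null uniformity.
"""

from __future__ import annotations

from math import comb

import numpy as np
import pandas as pd

from . import association, community, network
from .synthetic import SyntheticConfig, simulate

# Recovery experiment thresholds. Module recovery uses a stringent
# correlation + FDR rule; hub Zi is evaluated on a graph thresholded
# between the expected member-member and hub-member rank correlations;
# connector Pi on a permissive correlation-only graph (a planted
# connector's attainable correlation to three near-orthogonal modules is
# bounded by ~sqrt(rho_within / 3) + shared-factor terms, below the
# stringent threshold).
RECOVERY_R_MODULES = 0.75
RECOVERY_R_HUB = 0.86
RECOVERY_R_CONNECTOR = 0.45


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Adjusted Rand index between two partitions of the same items."""
    a = pd.Series(list(labels_a))
    b = pd.Series(list(labels_b))
    if len(a) != len(b):
        raise ValueError("partitions must label the same items")
    n = len(a)
    if n < 2:
        return 1.0
    contingency = pd.crosstab(a, b).to_numpy()
    sum_cells = sum(comb(int(x), 2) for x in contingency.ravel())
    sum_a = sum(comb(int(x), 2) for x in contingency.sum(axis=1))
    sum_b = sum(comb(int(x), 2) for x in contingency.sum(axis=0))
    expected = sum_a * sum_b / comb(n, 2)
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return float((sum_cells - expected) / (max_index - expected))


def recovery_config(seed: int) -> SyntheticConfig:
    """The planted-structure configuration: 3 modules of 16 taxa at
    rho_within 0.9, one hub each, one connector, 30 samples."""
    return SyntheticConfig(
        n_samples_per_group={"contaminated": 30},
        n_taxa_bact=160,
        n_taxa_fungi=80,
        n_modules=3,
        module_sizes=[16, 16, 16],
        rho_within=0.9,
        rho_between=0.45,
        hub_boost=0.1,
        n_hubs_per_module=1,
        n_connectors=1,
        n_metal_responders=0,
        depth=50_000,
        seed=seed,
    )


def planted_recovery(n_seeds: int = 20, base_seed: int = 0) -> dict:
    """Module / hub / connector recovery rates over ``n_seeds`` replicates.

    Returns per-seed ARI pass rate (ARI >= 0.8 against planted modules),
    the fraction of planted hubs attaining top-decile Zi, and the fraction
    of planted connectors attaining Pi > 0.62.
    """
    ari_pass = 0
    hub_pass = 0
    hub_trials = 0
    conn_pass = 0
    conn_trials = 0
    aris = []
    for seed in range(base_seed, base_seed + n_seeds):
        cfg = recovery_config(seed)
        _, bact, fungi, truth = simulate(cfg)

        g_mod = network.build_network(
            bact, fungi, r_threshold=RECOVERY_R_MODULES, alpha=0.05, min_prevalence=0.0
        )
        modules, _ = network.detect_modules(g_mod)
        planted = [t for t, m in truth.module_of.items() if m is not None]
        recovered = [t for t in planted if t in modules]
        if len(recovered) >= 2 * len(planted) // 3:
            ari = adjusted_rand_index(
                [truth.module_of[t] for t in recovered],
                [modules[t] for t in recovered],
            )
        else:
            ari = 0.0
        aris.append(ari)
        ari_pass += ari >= 0.8

        def modules_extended(g, base=modules):
            out = dict(base)
            nxt = max(base.values(), default=-1) + 1
            for node in g.nodes:
                if node not in out:
                    out[node] = nxt
                    nxt += 1
            return out

        g_hub = network.build_network(
            bact, fungi, r_threshold=RECOVERY_R_HUB, alpha=1.01, min_prevalence=0.0
        )
        zp_hub = network.zi_pi(g_hub, modules_extended(g_hub))
        zi_q90 = zp_hub["Zi"].quantile(0.9) if len(zp_hub) else 0.0
        for hub in truth.hub_taxa:
            hub_trials += 1
            hub_pass += hub in zp_hub.index and zp_hub.at[hub, "Zi"] >= zi_q90 - 1e-12

        g_conn = network.build_network(
            bact, fungi, r_threshold=RECOVERY_R_CONNECTOR, alpha=1.01, min_prevalence=0.0
        )
        zp_conn = network.zi_pi(g_conn, modules_extended(g_conn))
        for conn in truth.connector_taxa:
            conn_trials += 1
            conn_pass += conn in zp_conn.index and zp_conn.at[conn, "Pi"] > 0.62

    return {
        "n_seeds": n_seeds,
        "mean_ari": float(np.mean(aris)),
        "ari_pass_rate": ari_pass / n_seeds,
        "hub_top_decile_rate": hub_pass / hub_trials,
        "connector_pi_rate": conn_pass / conn_trials,
    }


def fdr_null(
    n_reps: int = 100,
    base_seed: int = 0,
    n_taxa: int = 200,
    n_samples: int = 16,
    r_threshold: float = 0.7,
    alpha: float = 0.05,
) -> dict:
    """Edge rate of network construction on fully independent taxa.

    Every taxon is latent-independent; any surviving edge is a false
    discovery. Returns the mean fraction of tested pairs declared edges and
    the mean edge count per replicate.
    """
    edge_fracs = []
    edge_counts = []
    for rep in range(n_reps):
        cfg = SyntheticConfig(
            n_samples_per_group={"contaminated": n_samples},
            n_taxa_bact=n_taxa * 2 // 3,
            n_taxa_fungi=n_taxa - n_taxa * 2 // 3,
            n_modules=0,
            module_sizes=[],
            rho_within=0.0,
            n_connectors=0,
            n_metal_responders=0,
            effect_size_metal=0.0,
            depth=10_000,
            seed=base_seed + rep,
        )
        _, bact, fungi, _ = simulate(cfg)
        g = network.build_network(
            bact, fungi, r_threshold=r_threshold, alpha=alpha, min_prevalence=0.0
        )
        n_pairs = g.graph["n_pairs_tested"]
        edge_counts.append(g.number_of_edges())
        edge_fracs.append(g.number_of_edges() / n_pairs)
    return {
        "n_reps": n_reps,
        "mean_edge_fraction": float(np.mean(edge_fracs)),
        "mean_edge_count": float(np.mean(edge_counts)),
    }


def density_contrast(seed: int = 0, n_samples: int = 24) -> dict:
    """Contaminated-like (dense planted correlation) vs uncontaminated-like
    (sparse) networks built with the default thresholds.

    The dense configuration plants three large strongly-correlated modules;
    the sparse one plants a single smaller, weaker module. All planted
    correlations are positive.
    """
    dense_cfg = SyntheticConfig(
        n_samples_per_group={"contaminated": n_samples},
        n_taxa_bact=120,
        n_taxa_fungi=60,
        n_modules=3,
        module_sizes=[16, 16, 16],
        rho_within=0.9,
        rho_between=0.3,
        n_connectors=1,
        n_metal_responders=0,
        depth=30_000,
        seed=seed,
    )
    sparse_cfg = SyntheticConfig(
        n_samples_per_group={"uncontaminated": n_samples},
        n_taxa_bact=120,
        n_taxa_fungi=60,
        n_modules=1,
        module_sizes=[12],
        rho_within=0.9,
        rho_between=0.0,
        n_connectors=0,
        n_metal_responders=0,
        depth=30_000,
        seed=seed + 1,
    )
    out = {}
    for name, cfg in (("dense", dense_cfg), ("sparse", sparse_cfg)):
        _, bact, fungi, _ = simulate(cfg)
        g = network.build_network(bact, fungi, min_prevalence=0.0)
        summary = network.topology(g)
        out[name] = {
            "edges": summary.n_edges,
            "nodes": summary.n_nodes,
            "average_degree": summary.average_degree,
            "positive_edge_fraction": summary.positive_edge_fraction,
        }
    return out


def responder_power(
    n_seeds: int = 10, base_seed: int = 0, q_threshold: float = 0.05
) -> dict:
    """Detection of planted metal responders in the env-taxon heatmap.

    Power = fraction of planted (responder, own metal) pairs significant
    with the correct sign. False positives are measured two ways: the
    false-positive taxon rate (distinct non-responder taxa with any
    significant pair, over all non-responder taxa) and the per-pair
    false-discovery proportion (significant non-responder pairs among all
    significant pairs; heavy-tailed because discoveries clump across the
    mutually correlated metals).
    """
    hits = 0
    trials = 0
    fdps = []
    false_taxon_rates = []
    for seed in range(base_seed, base_seed + n_seeds):
        # deeper sequencing keeps compositional ripples from the planted
        # responders below the significance threshold for null taxa
        cfg = SyntheticConfig(seed=seed, depth=30_000)
        meta, bact, fungi, truth = simulate(cfg)
        frames = []
        for table in (bact, fungi):
            heat = association.env_taxon_heatmap(table, meta, rank="genus")
            frames.append(heat)
        responders_by_genus = {
            f"g__{taxon}": (metal, slope)
            for taxon, (metal, slope) in truth.metal_responders.items()
        }
        n_sig_false = 0
        n_sig = 0
        false_taxa = 0
        null_taxa = 0
        for heat in frames:
            sig = heat[heat["q"] < q_threshold]
            n_sig += len(sig)
            n_sig_false += int(
                (~sig["taxon"].isin(responders_by_genus)).sum()
            )
            taxa = heat["taxon"].unique()
            null = [t for t in taxa if t not in responders_by_genus]
            flagged = sig["taxon"].unique()
            false_taxa += sum(1 for t in null if t in set(flagged))
            null_taxa += len(null)
            for genus, (metal, slope) in responders_by_genus.items():
                row = heat[(heat["taxon"] == genus) & (heat["env"] == metal)]
                if len(row) == 0:
                    continue
                trials += 1
                row = row.iloc[0]
                hits += row["q"] < q_threshold and np.sign(row["rho"]) == np.sign(slope)
        fdps.append(n_sig_false / n_sig if n_sig else 0.0)
        false_taxon_rates.append(false_taxa / null_taxa if null_taxa else 0.0)
    fdps = np.asarray(fdps)
    return {
        "n_seeds": n_seeds,
        "power": hits / trials if trials else 0.0,
        "mean_false_taxon_rate": float(np.mean(false_taxon_rates)),
        "mean_false_discovery_proportion": float(fdps.mean()),
        "fdp_standard_error": float(fdps.std(ddof=1) / np.sqrt(len(fdps))),
    }


def _ks_uniform(pvalues: np.ndarray) -> float:
    """Kolmogorov-Smirnov distance of p-values from U(0,1)."""
    p = np.sort(np.asarray(pvalues, dtype=float))
    n = len(p)
    grid = np.arange(1, n + 1) / n
    return float(max(np.max(np.abs(grid - p)), np.max(np.abs(p - (grid - 1 / n)))))


def permutation_null_uniformity(
    n_reps: int = 200, base_seed: int = 0, n_samples: int = 12, n_perm: int = 199
) -> dict:
    """KS distance from uniformity of ANOSIM and Mantel p-values under the
    null (random distance matrices / labels)."""
    rng = np.random.default_rng(base_seed)
    ids = [f"S{i}" for i in range(n_samples)]
    labels = pd.Series(
        ["a"] * (n_samples // 2) + ["b"] * (n_samples - n_samples // 2), index=ids
    )

    def random_dm() -> pd.DataFrame:
        m = np.zeros((n_samples, n_samples))
        iu = np.triu_indices(n_samples, k=1)
        m[iu] = rng.random(len(iu[0]))
        return pd.DataFrame(m + m.T, index=ids, columns=ids)

    anosim_p = []
    mantel_p = []
    for rep in range(n_reps):
        d = random_dm()
        _, p = community.anosim(d, labels, n_perm=n_perm, seed=base_seed + rep)
        anosim_p.append(p)
        _, p = association.mantel(
            d, random_dm(), n_perm=n_perm, seed=base_seed + rep
        )
        mantel_p.append(p)
    return {
        "anosim_ks": _ks_uniform(np.array(anosim_p)),
        "mantel_ks": _ks_uniform(np.array(mantel_p)),
    }
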