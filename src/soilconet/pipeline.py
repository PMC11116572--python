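"""End-to-end orchestration: simulate/load -> pollution -> diversity ->
association -> per-group networks, with a checksum manifest for
reproducibility."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from . import association, community, network, pollution, tabular_io
from .datatypes import AbundanceTable, SampleFrame
from .synthetic import SyntheticConfig, simulate

log = logging.getLogger("soilconet")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "soilconet_out"
    seed: int = 0
    # either simulate (dict of SyntheticConfig overrides) or explicit inputs
    simulate: dict | None = None
    bacteria_path: str | None = None
    fungi_path: str | None = None
    taxonomy_path: str | None = None
    metadata_path: str | None = None
    background_path: str | None = None
    r_threshold: float = 0.7
    alpha: float = 0.05
    min_prevalence: float = 1 / 3
    genus_threshold: float = 0.10
    heatmap_rank: str = "phylum"
    n_perm: int = 999
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.r_threshold <= 1:
            raise ValueError("r_threshold must lie in (0, 1]")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")
        if not 0 <= self.min_prevalence <= 1:
            raise ValueError("min_prevalence must lie in [0, 1]")
        if self.simulate is None and not (
            self.bacteria_path and self.fungi_path and self.metadata_path
        ):
            raise ValueError(
                "provide either a 'simulate' section or input table paths"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in payload.items() if k in known}
        kwargs["extra"] = {k: v for k, v in payload.items() if k not in known}
        return cls(**kwargs)


def _load_inputs(cfg: RunConfig):
    if cfg.simulate is not None:
        overrides = dict(cfg.simulate)
        overrides.setdefault("seed", cfg.seed)
        sim_cfg = SyntheticConfig(**overrides)
        meta, bact, fungi, truth = simulate(sim_cfg)
        background = sim_cfg.background_values
        return meta, bact, fungi, background, truth
    bact = tabular_io.read_abundance(cfg.bacteria_path, cfg.taxonomy_path, "bacteria")
    fungi = tabular_io.read_abundance(cfg.fungi_path, cfg.taxonomy_path, "fungi")
    meta = tabular_io.read_metadata(cfg.metadata_path)
    background = (
        tabular_io.read_background(cfg.background_path)
        if cfg.background_path
        else None
    )
    return meta, bact, fungi, background, None


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(cfg: RunConfig) -> dict:
    """Run every stage and return the manifest (also written as JSON)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        meta, bact, fungi, background, truth = _load_inputs(cfg)
        written: dict[str, Path] = {}

        def save(name: str, frame, **kwargs) -> None:
            path = out / name
            frame.to_csv(path, sep="\t", **kwargs)
            written[name] = path

        stage = "inputs"
        tabular_io.write_abundance(bact, out / "bacteria_counts.tsv")
        tabular_io.write_abundance(fungi, out / "fungi_counts.tsv")
        tabular_io.write_metadata(meta, out / "metadata.tsv")
        written["bacteria_counts.tsv"] = out / "bacteria_counts.tsv"
        written["fungi_counts.tsv"] = out / "fungi_counts.tsv"
        written["metadata.tsv"] = out / "metadata.tsv"
        if truth is not None:
            truth.to_frame().to_csv(out / "truth.tsv", sep="\t")
            written["truth.tsv"] = out / "truth.tsv"

        stage = "pollution"
        results: dict = {}
        if background is not None:
            report = pollution.pollution_report(meta, background)
            save("pollution_cf.tsv", report.cf)
            save("pollution_pli.tsv", pd.DataFrame({"PLI": report.pli, "class": report.pli_class}))
            results["group_pli"] = report.group_pli.to_dict()
            pli_u, pli_p = community.group_compare(report.pli, meta.groups)
            results["pli_wilcoxon"] = {"U": pli_u, "p": pli_p}
            log.info("pollution: group PLI %s", results["group_pli"])

        stage = "diversity"
        for name, table in (("bacteria", bact), ("fungi", fungi)):
            div = community.alpha_diversity(table)
            save(f"diversity_{name}.tsv", div)
            dm = community.bray_curtis(table)
            save(f"braycurtis_{name}.tsv", dm)
            coords, explained = community.pcoa(dm)
            save(f"pcoa_{name}.tsv", coords)
            r, p = community.anosim(dm, meta.groups, n_perm=cfg.n_perm, seed=cfg.seed)
            results[f"anosim_{name}"] = {"R": r, "p": p}
            results[f"pcoa_{name}_explained"] = [float(x) for x in explained[:2]]
            log.info("%s ANOSIM R=%.4f p=%.4f", name, r, p)

        stage = "association"
        for name, table in (("bacteria", bact), ("fungi", fungi)):
            heat = association.env_taxon_heatmap(table, meta, rank=cfg.heatmap_rank)
            save(f"env_taxon_{name}.tsv", heat, index=False)
        cross = association.genus_cross_domain(bact, fungi, threshold=cfg.genus_threshold)
        save("genus_cross_domain.tsv", cross, index=False)
        log_metals = np.log(meta.metals + 1e-12)
        z_metals = (log_metals - log_metals.mean()) / log_metals.std().replace(0, 1.0)
        metal_dist = pd.DataFrame(
            squareform(pdist(z_metals, metric="euclidean")),
            index=meta.sample_ids,
            columns=meta.sample_ids,
        )
        for name, table in (("bacteria", bact), ("fungi", fungi)):
            dm = community.bray_curtis(table)
            r, p = association.mantel(dm, metal_dist, n_perm=cfg.n_perm, seed=cfg.seed)
            results[f"mantel_{name}_metals"] = {"r": r, "p": p}

        stage = "network"
        for group in sorted(meta.groups.unique()):
            samples = [s for s, g in meta.groups.items() if g == group]
            if len(samples) < 5:
                log.warning("group %s has <5 samples; skipping network", group)
                continue
            g = network.build_network(
                bact.subset_samples(samples),
                fungi.subset_samples(samples),
                r_threshold=cfg.r_threshold,
                alpha=cfg.alpha,
                min_prevalence=cfg.min_prevalence,
            )
            nodes, summary = network.analyze_network(g, seed=cfg.seed)
            tabular_io.write_graph(g, out / f"network_{group}.graphml", "graphml")
            tabular_io.write_graph(g, out / f"network_{group}_edges.tsv", "edgelist-tsv")
            written[f"network_{group}.graphml"] = out / f"network_{group}.graphml"
            written[f"network_{group}_edges.tsv"] = out / f"network_{group}_edges.tsv"
            save(f"network_{group}_nodes.tsv", nodes)
            save(f"topology_{group}.tsv", summary.to_series().rename(group).to_frame())
            keystones = nodes[nodes["keystone"]]
            save(f"keystone_{group}.tsv", keystones)
            results[f"network_{group}"] = {
                "nodes": summary.n_nodes,
                "edges": summary.n_edges,
                "average_degree": summary.average_degree,
                "modularity": summary.modularity,
                "keystones": int(keystones.shape[0]),
            }
            log.info(
                "network[%s]: %d nodes, %d edges, %d keystones",
                group, summary.n_nodes, summary.n_edges, keystones.shape[0],
            )
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "seed": cfg.seed,
        "thresholds": {
            "r_threshold": cfg.r_threshold,
            "alpha": cfg.alpha,
            "min_prevalence": cfg.min_prevalence,
            "genus_threshold": cfg.genus_threshold,
        },
        "n_perm": cfg.n_perm,
        "results": results,
        "outputs": {name: _sha256(path) for name, path in sorted(written.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
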