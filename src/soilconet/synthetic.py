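"""Synthetic paired bacterial/fungal communities with known ground truth.

The generator plants the statistical structure the downstream analysis is
meant to recover: block-correlated taxon modules (spanning both domains),
hub taxa with elevated within-module correlation, connector taxa correlated
with every module, taxa whose latent abundance tracks a metal gradient, and
two sample groups with log-normal, mutually correlated metal concentrations.

Latent model
------------
Each taxon's latent log-abundance is a unit-variance Gaussian built from a
global factor ``G``, one factor per module ``F_m``, and an idiosyncratic
residual:

* module member:  sqrt(rho_b)*G + sqrt(rho_w - rho_b)*F_m + sqrt(1-rho_w)*e
* hub:            same, with rho_w replaced by min(rho_w + hub_boost, 0.99)
* connector:      sqrt(rho_b)*G + sum_m a*F_m + residual, with
                  a = sqrt(connector_strength*(1-rho_b)/M)
* metal responder: e + effect_size_metal * z(log metal)
* free taxon:     e

Because every latent is an explicit factor combination, the implied
covariance is positive semi-definite by construction; the residual-variance
check at configuration time is exactly the PSD condition.

Counts are multinomial draws (one per domain per sample, ``depth`` reads)
from softmax-style relative abundances exp(mu_i + Z_i), which induces the
compositionality real amplicon tables have.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import METALS, PHYSCHEM, RANKS, AbundanceTable, SampleFrame

# -- defaults anchored to the study design this emulates ----------------------

#: Geochemical background values, mg/kg.
DEFAULT_BACKGROUND = {
    "Mo": 1.4, "Cd": 0.116, "Sb": 1.01, "Cu": 24.1,
    "Zn": 68.4, "Hg": 0.02, "Pb": 20.0,
}

#: Target group-mean contamination factors (mean concentration / background).
#: The contaminated group reproduces the headline CF profile
#: (Cd 30.35, Hg 11.26, Pb 5.46, Zn 5.19, Cu 2.46) with trace Mo and Sb;
#: the uncontaminated profile keeps every CF below 1.
DEFAULT_CF_TARGETS = {
    "contaminated": {
        "Mo": 0.005, "Cd": 30.35, "Sb": 0.0124, "Cu": 2.46,
        "Zn": 5.19, "Hg": 11.26, "Pb": 5.46,
    },
    "uncontaminated": {
        "Mo": 0.002, "Cd": 0.9, "Sb": 0.0032, "Cu": 0.8,
        "Zn": 0.6, "Hg": 0.8, "Pb": 0.7,
    },
}

#: Physicochemical (mean_contaminated, mean_uncontaminated, sd); the
#: direction of each contrast (e.g. lower MBC under contamination) follows
#: the field study this generator emulates.
DEFAULT_PHYSCHEM = {
    "MBC": (115.58, 174.16, 30.0),
    "MBN": (15.85, 20.73, 4.0),
    "MBP": (8.10, 8.08, 3.0),
    "WC": (14.42, 14.94, 2.0),
    "TP": (0.50, 0.35, 0.15),
    "AP": (70.73, 45.73, 25.0),
    "TN": (0.93, 1.40, 0.30),
    "OC": (13.58, 18.93, 4.0),
    "AMN": (0.79, 1.37, 0.50),
    "NN": (2.11, 4.66, 1.50),
}

BACT_PHYLA = (
    "Proteobacteria", "Actinobacteria", "Acidobacteria", "Chloroflexi",
    "Gemmatimonadetes", "Planctomycetes", "Armatimonadetes", "Firmicutes",
    "Bacteroidetes", "Verrucomicrobia",
)
FUNGI_PHYLA = (
    "Ascomycota", "Basidiomycota", "Mortierellomycota",
    "Chytridiomycota", "Zoopagomycota",
)

MAX_FACTOR_CORR = 0.99


class ConfigError(ValueError):
    """Raised when a synthetic configuration is internally inconsistent."""


@dataclass
class SyntheticConfig:
    """Parameters of the community generator; defaults give a small,
    fast two-group dataset with three planted cross-domain modules."""

    n_samples_per_group: dict[str, int] = field(
        default_factory=lambda: {"contaminated": 9, "uncontaminated": 7}
    )
    n_taxa_bact: int = 80
    n_taxa_fungi: int = 40
    n_modules: int = 3
    module_sizes: list[int] | None = None
    rho_within: float = 0.85
    rho_between: float = 0.0
    hub_boost: float = 0.10
    n_hubs_per_module: int = 1
    n_connectors: int = 1
    connector_strength: float = 1.0
    n_metal_responders: int = 5
    effect_size_metal: float = 2.5
    depth: int = 10_000
    latent_scale: float = 1.0
    base_abundance_sd: float = 1.0
    role_abundance_floor: float = 1.0
    responder_abundance_offset: float = -3.0
    metal_group_means: dict[str, dict[str, float]] | None = None
    metal_group_cv: float | dict[str, float] = 0.3
    metal_corr: float = 0.6
    background_values: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BACKGROUND)
    )
    physchem_params: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PHYSCHEM)
    )
    zero_inflation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.module_sizes is None:
            self.module_sizes = [10] * self.n_modules
        if len(self.module_sizes) != self.n_modules:
            raise ConfigError(
                f"module_sizes has {len(self.module_sizes)} entries "
                f"but n_modules is {self.n_modules}"
            )
        if any(s < 2 for s in self.module_sizes):
            raise ConfigError("every module needs at least 2 taxa")
        n_taxa = self.n_taxa_bact + self.n_taxa_fungi
        n_planted = sum(self.module_sizes) + self.n_connectors + self.n_metal_responders
        if n_planted > n_taxa:
            raise ConfigError(
                f"planted taxa ({n_planted}) exceed total taxa ({n_taxa})"
            )
        if not 0.0 <= self.rho_within < 1.0:
            raise ConfigError("rho_within must lie in [0, 1)")
        if not 0.0 <= self.rho_between <= self.rho_within:
            raise ConfigError(
                "latent covariance is not positive semi-definite: "
                "rho_between must lie in [0, rho_within]"
            )
        if not 0.0 < self.connector_strength <= 1.0:
            raise ConfigError("connector_strength must lie in (0, 1]")
        if self.depth <= 0:
            raise ConfigError("depth must be positive")
        if any(v <= 0 for v in self.background_values.values()):
            raise ConfigError("background values must be positive")
        missing = [m for m in METALS if m not in self.background_values]
        if missing:
            raise ConfigError(f"background values missing metals: {missing}")
        if self.metal_group_means is None:
            self.metal_group_means = {
                group: {
                    m: self.background_values[m] * DEFAULT_CF_TARGETS[group][m]
                    for m in METALS
                }
                for group in self.n_samples_per_group
                if group in DEFAULT_CF_TARGETS
            }
            if set(self.metal_group_means) != set(self.n_samples_per_group):
                raise ConfigError(
                    "metal_group_means must be given explicitly for custom group names"
                )
        if not 0.0 <= self.metal_corr <= 1.0:
            raise ConfigError("metal_corr must lie in [0, 1]")
        # PSD condition of the factor model: residual variances must be
        # non-negative for every planted role.
        rho_hub = min(self.rho_within + self.hub_boost, MAX_FACTOR_CORR)
        for label, resid in (
            ("module member", 1.0 - self.rho_within),
            ("hub", 1.0 - rho_hub),
            (
                "connector",
                (1.0 - self.rho_between) * (1.0 - self.connector_strength),
            ),
        ):
            if resid < -1e-12:
                raise ConfigError(
                    f"latent covariance is not positive semi-definite ({label})"
                )

    def cv_for(self, group: str) -> float:
        if isinstance(self.metal_group_cv, dict):
            return float(self.metal_group_cv[group])
        return float(self.metal_group_cv)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=list)


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a synthetic dataset."""

    module_of: dict[str, int | None]
    hub_taxa: set[str]
    connector_taxa: set[str]
    metal_responders: dict[str, tuple[str, float]]
    group_of: dict[str, str]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for taxon, mod in self.module_of.items():
            rows.append(
                {
                    "taxon": taxon,
                    "module": -1 if mod is None else mod,
                    "is_hub": taxon in self.hub_taxa,
                    "is_connector": taxon in self.connector_taxa,
                    "responder_metal": self.metal_responders.get(taxon, ("", 0.0))[0],
                    "responder_slope": self.metal_responders.get(taxon, ("", 0.0))[1],
                }
            )
        return pd.DataFrame(rows).set_index("taxon")


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------

def _sample_ids(cfg: SyntheticConfig) -> tuple[list[str], list[str]]:
    ids, groups = [], []
    for gi, (group, n) in enumerate(sorted(cfg.n_samples_per_group.items())):
        prefix = group[:1].upper() or "G"
        for i in range(n):
            ids.append(f"{prefix}{gi}{i + 1:02d}")
            groups.append(group)
    return ids, groups


def generate_metadata(cfg: SyntheticConfig) -> SampleFrame:
    """Draw per-sample metals (correlated log-normals) and physicochemistry.

    Within each group, log-concentrations share a latent sample factor with
    weight ``metal_corr``, making pairwise metal rank correlations positive
    in expectation. ``metal_group_cv = 0`` returns the group means exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    ids, groups = _sample_ids(cfg)
    rows = []
    for sample, group in zip(ids, groups):
        cv = cfg.cv_for(group)
        sigma = float(np.sqrt(np.log1p(cv * cv)))
        shared = rng.standard_normal()
        row = {"group": group}
        for metal in METALS:
            mean = cfg.metal_group_means[group][metal]
            noise = rng.standard_normal()
            z = np.sqrt(cfg.metal_corr) * shared + np.sqrt(1 - cfg.metal_corr) * noise
            row[metal] = float(mean * np.exp(sigma * z - 0.5 * sigma * sigma))
        for var in PHYSCHEM:
            mean_c, mean_u, sd = cfg.physchem_params[var]
            mean = mean_c if group == "contaminated" else mean_u
            row[var] = float(max(mean + sd * rng.standard_normal(), 0.0))
        rows.append(row)
    data = pd.DataFrame(rows, index=pd.Index(ids, name="sample"))
    return SampleFrame(data)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _assign_taxa(cfg: SyntheticConfig):
    """Lay out taxon ids, domains, and planted roles.

    Module members alternate two bacteria : one fungus so every module spans
    both domains; connectors and responders likewise alternate.
    """
    bact_ids = [f"B{i + 1:04d}" for i in range(cfg.n_taxa_bact)]
    fungi_ids = [f"F{i + 1:04d}" for i in range(cfg.n_taxa_fungi)]
    pools = {"bacteria": list(bact_ids), "fungi": list(fungi_ids)}

    def take(domain: str) -> str:
        # fall back to the other pool when one runs dry
        if not pools[domain]:
            domain = "fungi" if domain == "bacteria" else "bacteria"
        return pools[domain].pop(0)

    module_members: list[list[str]] = []
    for size in cfg.module_sizes:
        members = [
            take("bacteria" if j % 3 != 2 else "fungi") for j in range(size)
        ]
        module_members.append(members)
    connectors = [
        take("bacteria" if j % 2 == 0 else "fungi") for j in range(cfg.n_connectors)
    ]
    responders = [
        take("bacteria" if j % 2 == 0 else "fungi")
        for j in range(cfg.n_metal_responders)
    ]
    return bact_ids, fungi_ids, module_members, connectors, responders


def _lineage_for(taxon_ids: list[str], phyla: tuple[str, ...]) -> pd.DataFrame:
    rows = {}
    for i, taxon in enumerate(taxon_ids):
        phylum = phyla[i % len(phyla)]
        rows[taxon] = {
            "phylum": phylum,
            "class": f"c__{phylum[:4]}{i % 7}",
            "order": f"o__{phylum[:4]}{i % 11}",
            "family": f"f__{phylum[:4]}{i % 13}",
            "genus": f"g__{taxon}",
        }
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))


def generate_counts(
    cfg: SyntheticConfig, meta: SampleFrame
) -> tuple[AbundanceTable, AbundanceTable, SyntheticTruth]:
    """Draw paired count tables plus the generator's ground truth."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    bact_ids, fungi_ids, module_members, connectors, responders = _assign_taxa(cfg)
    all_ids = bact_ids + fungi_ids
    col = {t: i for i, t in enumerate(all_ids)}
    n_samples = len(meta.sample_ids)
    n_taxa = len(all_ids)

    rho_w, rho_b = cfg.rho_within, cfg.rho_between
    rho_hub = min(rho_w + cfg.hub_boost, MAX_FACTOR_CORR)

    g_factor = rng.standard_normal(n_samples)
    f_factors = rng.standard_normal((n_samples, cfg.n_modules))
    eps = rng.standard_normal((n_samples, n_taxa))

    z = np.array(eps)  # free taxa keep pure noise
    module_of: dict[str, int | None] = {t: None for t in all_ids}
    hub_taxa: set[str] = set()

    for m, members in enumerate(module_members):
        for j, taxon in enumerate(members):
            module_of[taxon] = m
            rho = rho_hub if j < cfg.n_hubs_per_module else rho_w
            if j < cfg.n_hubs_per_module:
                hub_taxa.add(taxon)
            z[:, col[taxon]] = (
                np.sqrt(rho_b) * g_factor
                + np.sqrt(rho - rho_b) * f_factors[:, m]
                + np.sqrt(1.0 - rho) * eps[:, col[taxon]]
            )

    a = (
        np.sqrt(cfg.connector_strength * (1.0 - rho_b) / cfg.n_modules)
        if cfg.n_modules
        else 0.0
    )
    resid_conn = np.sqrt((1.0 - rho_b) * (1.0 - cfg.connector_strength))
    for taxon in connectors:
        z[:, col[taxon]] = (
            np.sqrt(rho_b) * g_factor
            + a * f_factors.sum(axis=1)
            + resid_conn * eps[:, col[taxon]]
        )

    metal_responders: dict[str, tuple[str, float]] = {}
    log_metals = np.log(meta.metals.to_numpy(dtype=float) + 1e-12)
    z_metals = (log_metals - log_metals.mean(axis=0)) / np.where(
        log_metals.std(axis=0) > 0, log_metals.std(axis=0), 1.0
    )
    # slopes alternate in sign so the responders' compositional footprints
    # roughly cancel instead of compounding within a sample group
    for j, taxon in enumerate(responders):
        metal = METALS[j % len(METALS)]
        slope = cfg.effect_size_metal * (1 if j % 2 == 0 else -1)
        z[:, col[taxon]] = eps[:, col[taxon]] + slope * z_metals[:, METALS.index(metal)]
        metal_responders[taxon] = (metal, slope)

    mu = cfg.base_abundance_sd * rng.standard_normal(n_taxa)
    # planted-role taxa get a baseline-abundance floor so their rank
    # correlations are not drowned by count noise at realistic depths
    for taxon in list(hub_taxa) + connectors:
        mu[col[taxon]] = max(mu[col[taxon]], cfg.role_abundance_floor)
    # responders start rare so their metal-driven swings stay a small share
    # of the community (limits compositional ripple onto null taxa)
    for taxon in responders:
        mu[col[taxon]] = min(mu[col[taxon]], 0.0) + cfg.responder_abundance_offset
    log_weights = mu[None, :] + cfg.latent_scale * z
    weights = np.exp(log_weights - log_weights.max(axis=1, keepdims=True))
    if cfg.zero_inflation > 0:
        mask = rng.random((n_samples, n_taxa)) >= cfg.zero_inflation
        weights = weights * mask

    counts = np.zeros((n_samples, n_taxa), dtype=np.int64)
    for domain_ids in (bact_ids, fungi_ids):
        idx = [col[t] for t in domain_ids]
        w = weights[:, idx]
        w_sum = w.sum(axis=1, keepdims=True)
        w_sum[w_sum == 0] = 1.0
        probs = w / w_sum
        for s in range(n_samples):
            counts[s, idx] = rng.multinomial(cfg.depth, probs[s])

    frame = pd.DataFrame(
        counts, index=pd.Index(meta.sample_ids, name="sample"), columns=all_ids
    )
    bact = AbundanceTable(
        frame[bact_ids], "bacteria", _lineage_for(bact_ids, BACT_PHYLA)
    )
    fungi = AbundanceTable(
        frame[fungi_ids], "fungi", _lineage_for(fungi_ids, FUNGI_PHYLA)
    )
    truth = SyntheticTruth(
        module_of=module_of,
        hub_taxa=hub_taxa,
        connector_taxa=set(connectors),
        metal_responders=metal_responders,
        group_of=dict(zip(meta.sample_ids, meta.groups)),
    )
    return bact, fungi, truth


def simulate(cfg: SyntheticConfig):
    """Full bundle: ``(metadata, bacteria, fungi, truth)`` for one config."""
    meta = generate_metadata(cfg)
    bact, fungi, truth = generate_counts(cfg, meta)
    return meta, bact, fungi, truth


def write_bundle(cfg: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Simulate and write every table as TSV (+ a JSON config echo)."""
    from . import tabular_io as tio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta, bact, fungi, truth = simulate(cfg)
    paths = {
        "bacteria": out / "bacteria_counts.tsv",
        "fungi": out / "fungi_counts.tsv",
        "taxonomy": out / "taxonomy.tsv",
        "metadata": out / "metadata.tsv",
        "background": out / "background_values.tsv",
        "truth": out / "truth.tsv",
        "config": out / "config.json",
    }
    tio.write_abundance(bact, paths["bacteria"])
    tio.write_abundance(fungi, paths["fungi"])
    tio.write_taxonomy({"bacteria": bact, "fungi": fungi}, paths["taxonomy"])
    tio.write_metadata(meta, paths["metadata"])
    tio.write_background(cfg.background_values, paths["background"])
    truth.to_frame().to_csv(paths["truth"], sep="\t")
    paths["config"].write_text(cfg.to_json())
    return paths
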