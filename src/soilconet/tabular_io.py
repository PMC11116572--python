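"""Readers and writers for every on-disk artifact.

Canonical dialect: tab-separated UTF-8 with '.' decimals. Abundance tables
are written taxa-as-rows (first header token ``taxon_id``) but read in
either orientation, detected from that token. Metal units are normalised to
mg/kg exactly once at read time, driven by a ``# metal_units:`` header line.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .datatypes import (
    METALS,
    RANKS,
    AbundanceTable,
    SampleFrame,
    ValidationError,
)

TAXON_TOKEN = "taxon_id"
SAMPLE_TOKEN = "sample"

#: factors converting declared units to mg/kg
_UNIT_TO_MG_PER_KG = {"mg_per_kg": 1.0, "ng_per_g": 1e-3, "ug_per_kg": 1e-3}


# ---------------------------------------------------------------------------
# abundance + taxonomy
# ---------------------------------------------------------------------------

def write_abundance(table: AbundanceTable, path: str | Path) -> None:
    """Write counts taxa-as-rows with a ``taxon_id`` header token."""
    out = table.counts.T.rename_axis(index=TAXON_TOKEN, columns=None)
    out.to_csv(path, sep="\t")


def read_abundance(
    path: str | Path,
    taxonomy_path: str | Path | None = None,
    domain: str = "bacteria",
) -> AbundanceTable:
    """Read a count TSV (either orientation) plus optional taxonomy TSV."""
    raw = pd.read_csv(path, sep="\t", index_col=0)
    token = (raw.index.name or "").strip().lower()
    if token == TAXON_TOKEN:
        counts = raw.T
    elif token == SAMPLE_TOKEN:
        counts = raw
    else:
        raise ValidationError(
            f"{path}: first header cell must be {TAXON_TOKEN!r} or "
            f"{SAMPLE_TOKEN!r}, got {raw.index.name!r}"
        )
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    lineage = None
    if taxonomy_path is not None:
        lineage = read_taxonomy(taxonomy_path, domain=domain)
    return AbundanceTable(counts, domain, lineage)


def write_taxonomy(tables: dict[str, AbundanceTable], path: str | Path) -> None:
    """One taxonomy TSV covering several domains (``domain`` column added)."""
    frames = []
    for domain, table in tables.items():
        frame = table.lineage.copy()
        frame.insert(0, "domain", domain)
        frames.append(frame)
    out = pd.concat(frames)
    out.index.name = TAXON_TOKEN
    out.to_csv(path, sep="\t")


def read_taxonomy(path: str | Path, domain: str | None = None) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    if domain is not None and "domain" in frame.columns:
        frame = frame[frame["domain"] == domain]
    missing = [r for r in RANKS if r not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: taxonomy missing rank columns {missing}")
    return frame[list(RANKS)]


# ---------------------------------------------------------------------------
# metadata + background values
# ---------------------------------------------------------------------------

def write_metadata(
    meta: SampleFrame, path: str | Path, metal_units: str = "mg_per_kg"
) -> None:
    if metal_units != "mg_per_kg":
        raise ValueError("metadata is stored in mg_per_kg")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# metal_units: {metal_units}\n")
        meta.data.to_csv(fh, sep="\t", index_label=SAMPLE_TOKEN)


def read_metadata(path: str | Path) -> SampleFrame:
    """Read sample metadata; metal columns are converted to mg/kg once,
    according to the ``# metal_units:`` header (default mg_per_kg)."""
    units = "mg_per_kg"
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("# metal_units:"):
            units = first.split(":", 1)[1].strip()
            data = pd.read_csv(fh, sep="\t", index_col=0)
        else:
            fh.seek(0)
            data = pd.read_csv(fh, sep="\t", index_col=0)
    if units not in _UNIT_TO_MG_PER_KG:
        raise ValidationError(f"{path}: unknown metal unit {units!r}")
    factor = _UNIT_TO_MG_PER_KG[units]
    if factor != 1.0:
        for metal in METALS:
            if metal in data.columns:
                data[metal] = data[metal].astype(float) * factor
    data.index = data.index.astype(str)
    return SampleFrame(data)


def write_background(background: dict[str, float], path: str | Path) -> None:
    out = pd.Series(background, name="background_mg_per_kg")
    out.index.name = "metal"
    out.to_csv(path, sep="\t")


def read_background(path: str | Path) -> dict[str, float]:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    values = frame.iloc[:, 0].astype(float)
    bad = values.index[values <= 0].tolist()
    if bad:
        raise ValidationError(f"{path}: non-positive background for {bad}")
    return values.to_dict()


# ---------------------------------------------------------------------------
# graphs
# ---------------------------------------------------------------------------

GRAPH_FORMATS = ("graphml", "edgelist-tsv")


def write_graph(g: nx.Graph, path: str | Path, format: str = "graphml") -> None:
    """Export a co-occurrence graph with node and edge attributes.

    ``graphml`` round-trips all attributes; ``edgelist-tsv`` writes
    source / target / rho / q / sign rows.
    """
    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "edgelist-tsv":
        rows = [
            {
                "source": u,
                "target": v,
                "rho": d.get("rho"),
                "q": d.get("q"),
                "sign": d.get("sign"),
            }
            for u, v, d in g.edges(data=True)
        ]
        frame = pd.DataFrame(rows, columns=["source", "target", "rho", "q", "sign"])
        frame.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown graph format {format!r}; use one of {GRAPH_FORMATS}")


def read_graph(path: str | Path) -> nx.Graph:
    """Read a GraphML export back into a graph."""
    return nx.read_graphml(path)
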