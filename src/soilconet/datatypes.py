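"""Core table types shared by every analysis stage.

Two containers move through the pipeline: :class:`AbundanceTable` (counts of
amplicon sequence variants per sample, plus taxonomy) and
:class:`SampleFrame` (per-sample group label, metal concentrations and
physicochemical measurements). Both validate on construction so that
downstream stages can assume clean input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Heavy metals measured per sample, concentrations in mg/kg.
METALS = ("Mo", "Cd", "Sb", "Cu", "Zn", "Hg", "Pb")

#: Physicochemical variables measured per sample.
PHYSCHEM = ("MBC", "MBN", "MBP", "WC", "TP", "AP", "TN", "OC", "AMN", "NN")

#: Taxonomic ranks carried for every taxon, coarsest first.
RANKS = ("phylum", "class", "order", "family", "genus")

#: Placeholder for an unassigned rank.
UNKNOWN_RANK = "unclassified"

VALID_DOMAINS = ("bacteria", "fungi")


class ValidationError(ValueError):
    """Raised when a table violates its schema."""


@dataclass
class AbundanceTable:
    """Samples x taxa count matrix with a domain tag and per-taxon lineage.

    Parameters
    ----------
    counts
        DataFrame indexed by sample id, columns are taxon ids, values are
        non-negative integers.
    domain
        Either ``"bacteria"`` or ``"fungi"``.
    lineage
        DataFrame indexed by taxon id with the columns in :data:`RANKS`.
        Missing taxa are filled with :data:`UNKNOWN_RANK` at construction.
    """

    counts: pd.DataFrame
    domain: str
    lineage: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.domain not in VALID_DOMAINS:
            raise ValidationError(
                f"domain must be one of {VALID_DOMAINS}, got {self.domain!r}"
            )
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        if self.counts.columns.has_duplicates:
            dupes = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate taxon ids: {dupes}")
        values = self.counts.to_numpy()
        if values.size:
            bad = ~np.isfinite(values.astype(float))
            if bad.any():
                r, c = np.argwhere(bad)[0]
                raise ValidationError(
                    "non-finite count at sample "
                    f"{self.counts.index[r]!r}, taxon {self.counts.columns[c]!r}"
                )
            if (values < 0).any():
                r, c = np.argwhere(values < 0)[0]
                raise ValidationError(
                    "negative count at sample "
                    f"{self.counts.index[r]!r}, taxon {self.counts.columns[c]!r}"
                )
            frac = values.astype(float) % 1
            if (frac != 0).any():
                r, c = np.argwhere(frac != 0)[0]
                raise ValidationError(
                    "non-integer count at sample "
                    f"{self.counts.index[r]!r}, taxon {self.counts.columns[c]!r}"
                )
        self.counts = self.counts.astype(np.int64)
        self.counts.index.name = "sample"
        self.counts.columns.name = None
        if self.lineage is None:
            self.lineage = pd.DataFrame(
                UNKNOWN_RANK, index=self.counts.columns, columns=list(RANKS)
            )
        else:
            lineage = self.lineage.reindex(
                index=self.counts.columns, columns=list(RANKS)
            )
            self.lineage = lineage.fillna(UNKNOWN_RANK).astype(str)

    # -- convenience accessors -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def relative_abundance(self) -> pd.DataFrame:
        """Counts divided by per-sample totals. Errors on an empty sample."""
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            empty = totals.index[totals == 0].tolist()
            raise ValidationError(f"samples with zero total count: {empty}")
        return self.counts.div(totals, axis=0)

    def aggregate(self, rank: str) -> pd.DataFrame:
        """Sum counts over taxa sharing the same name at ``rank``."""
        if rank in (None, "asv"):
            return self.counts.copy()
        if rank not in RANKS:
            raise ValidationError(f"unknown rank {rank!r}; expected one of {RANKS}")
        labels = self.lineage[rank]
        return self.counts.T.groupby(labels).sum().T

    def subset_samples(self, sample_ids) -> "AbundanceTable":
        missing = [s for s in sample_ids if s not in self.counts.index]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing}")
        return AbundanceTable(
            self.counts.loc[list(sample_ids)], self.domain, self.lineage
        )


@dataclass
class SampleFrame:
    """Per-sample metadata: group label, metals (mg/kg) and physicochemistry."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        if "group" not in self.data.columns:
            raise ValidationError("metadata must contain a 'group' column")
        missing = [m for m in METALS if m not in self.data.columns]
        if missing:
            raise ValidationError(f"metadata missing metal columns: {missing}")
        metals = self.data[list(METALS)].to_numpy(dtype=float)
        if not np.isfinite(metals).all():
            raise ValidationError("non-finite metal concentration in metadata")
        if (metals < 0).any():
            raise ValidationError("negative metal concentration in metadata")
        self.data.index.name = "sample"

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def groups(self) -> pd.Series:
        return self.data["group"]

    @property
    def metals(self) -> pd.DataFrame:
        return self.data[list(METALS)].astype(float)

    @property
    def physchem(self) -> pd.DataFrame:
        cols = [c for c in PHYSCHEM if c in self.data.columns]
        return self.data[cols].astype(float)

    def environment(self) -> pd.DataFrame:
        """Metals plus physicochemical variables, one column per factor."""
        return pd.concat([self.metals, self.physchem], axis=1)

    def subset(self, sample_ids) -> "SampleFrame":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing}")
        return SampleFrame(self.data.loc[list(sample_ids)].copy())
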