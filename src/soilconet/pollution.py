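"""Contamination factors, pollution load index, and pollution classes.

CF is the ratio of a measured metal concentration to its geochemical
background value; the pollution load index (PLI) of a sample is the
geometric mean of its CFs. Class boundaries follow the conventional strict
inequalities: boundary values fall in the lower class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import METALS, SampleFrame

#: (upper bound, label) for CF classes; scanned in order, strict inequalities.
CF_CLASSES = (
    (1.0, "none"),
    (3.0, "moderate"),
    (6.0, "considerable"),
    (np.inf, "highest"),
)


def contamination_factor(measured: float, background: float) -> float:
    """CF = measured / background.

    ``background`` must be positive and ``measured`` non-negative.
    """
    if background <= 0:
        raise ValueError(f"background value must be > 0, got {background}")
    if measured < 0:
        raise ValueError(f"measured concentration must be >= 0, got {measured}")
    return float(measured) / float(background)


def pollution_load_index(cfs) -> float:
    """Geometric mean of contamination factors.

    Computed in log space when all CFs are positive; a single zero CF makes
    the product, and thus the PLI, exactly zero.
    """
    cfs = np.asarray(cfs, dtype=float)
    if cfs.size == 0:
        raise ValueError("PLI requires at least one contamination factor")
    if (cfs < 0).any():
        raise ValueError("contamination factors must be >= 0")
    if (cfs == 0).any():
        return 0.0
    return float(np.exp(np.mean(np.log(cfs))))


def classify_cf(cf: float, boundaries=CF_CLASSES) -> str:
    """Map a CF to its pollution class (boundary values -> lower class)."""
    if cf < 0:
        raise ValueError("CF must be >= 0")
    for upper, label in boundaries[:-1]:
        if cf <= upper:
            return label
    return boundaries[-1][1]


def classify_pli(pli: float, threshold: float = 1.0) -> str:
    """PLI strictly above ``threshold`` marks a contaminated area."""
    if pli < 0:
        raise ValueError("PLI must be >= 0")
    return "contaminated" if pli > threshold else "uncontaminated"


def classify(value: float, kind: str) -> str:
    """Dispatch on ``kind`` in {'cf', 'pli'}."""
    if kind == "cf":
        return classify_cf(value)
    if kind == "pli":
        return classify_pli(value)
    raise ValueError(f"unknown classification kind {kind!r}")


@dataclass
class PollutionReport:
    """Per-sample CF matrix plus PLI summaries.

    Attributes
    ----------
    cf : pd.DataFrame
        Samples x metals contamination factors.
    cf_class : pd.DataFrame
        Pollution class label per sample and metal.
    pli : pd.Series
        Per-sample pollution load index over ``n_metals`` metals.
    pli_class : pd.Series
        Per-sample contamination label.
    group_pli : pd.Series
        Arithmetic mean of per-sample PLIs within each group.
    n_metals : int
        Number of metals entering each PLI.
    """

    cf: pd.DataFrame
    cf_class: pd.DataFrame
    pli: pd.Series
    pli_class: pd.Series
    group_pli: pd.Series
    n_metals: int


def pollution_report(
    meta: SampleFrame, background: dict[str, float] | pd.Series
) -> PollutionReport:
    """Compute CFs, PLIs and class labels for every sample in ``meta``."""
    background = pd.Series(background, dtype=float)
    missing = [m for m in METALS if m not in background.index]
    if missing:
        raise ValueError(f"background values missing for metals: {missing}")
    if (background[list(METALS)] <= 0).any():
        bad = background.index[background <= 0].tolist()
        raise ValueError(f"background values must be > 0: {bad}")

    cf = meta.metals.div(background[list(METALS)], axis=1)
    cf_class = cf.map(classify_cf)
    pli = cf.apply(lambda row: pollution_load_index(row.to_numpy()), axis=1)
    pli.name = "PLI"
    pli_class = pli.map(classify_pli)
    pli_class.name = "class"
    group_pli = pli.groupby(meta.groups).mean()
    return PollutionReport(
        cf=cf,
        cf_class=cf_class,
        pli=pli,
        pli_class=pli_class,
        group_pli=group_pli,
        n_metals=len(METALS),
    )
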