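"""Spearman correlation surfaces: environment-taxon heatmaps, Mantel tests,
and cross-domain genus correlations, with Benjamini-Hochberg adjustment.

Each analysis surface (one heatmap, one cross-domain matrix, one network
build) forms its own BH family; q-values are never pooled across surfaces.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AbundanceTable, SampleFrame, ValidationError


# ---------------------------------------------------------------------------
# Spearman primitives
# ---------------------------------------------------------------------------

def _spearman_p(rho: float, n: int) -> float:
    """Two-sided p from the t approximation with n-2 degrees of freedom."""
    if n < 3 or abs(rho) >= 1.0:
        return 0.0 if abs(rho) >= 1.0 and n >= 3 else 1.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def spearman(x, y, mode: str = "approx") -> tuple[float, float]:
    """Spearman rank correlation: Pearson correlation of average ranks.

    Returns ``(rho, p)``. Constant input gives ``(0.0, 1.0)``. ``mode``
    selects the p-value: ``"approx"`` (t with n-2 df, the default) or
    ``"exact"`` (full permutation enumeration, small n only).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 1 or len(x) < 4:
        raise ValidationError("spearman needs 1-d vectors of length >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("spearman requires finite values")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return 0.0, 1.0
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if mode == "approx":
        return rho, _spearman_p(rho, len(x))
    if mode == "exact":
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, perm)[0, 1]
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        return rho, count / total
    raise ValueError(f"unknown p-value mode {mode!r}")


def spearman_matrix(
    x: pd.DataFrame, y: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman between columns of ``x`` and ``y`` (or within ``x``).

    Vectorised: columns are ranked once and correlated with a single matrix
    product. Constant columns yield rho 0 / p 1. Returns ``(rho, p)`` frames
    with x-columns as rows and y-columns as columns.
    """
    same = y is None
    if same:
        y = x
    if len(x) != len(y):
        raise ValidationError("x and y must share samples")
    n = len(x)
    if n < 4:
        raise ValidationError("spearman needs at least 4 samples")

    def _ranked(frame: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        ranks = stats.rankdata(frame.to_numpy(dtype=float), axis=0)
        sd = ranks.std(axis=0, ddof=0)
        constant = sd == 0
        z = np.zeros_like(ranks)
        ok = ~constant
        z[:, ok] = (ranks[:, ok] - ranks[:, ok].mean(axis=0)) / sd[ok]
        return z, constant

    zx, const_x = _ranked(x)
    zy, const_y = (zx, const_x) if same else _ranked(y)
    rho = zx.T @ zy / n
    rho = np.clip(rho, -1.0, 1.0)
    rho[const_x, :] = 0.0
    rho[:, const_y] = 0.0

    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(rho) >= 1.0] = 0.0
    p[const_x, :] = 1.0
    p[:, const_y] = 1.0
    if same:
        np.fill_diagonal(rho, 1.0)
        np.fill_diagonal(p, 0.0)
    return (
        pd.DataFrame(rho, index=x.columns, columns=y.columns),
        pd.DataFrame(p, index=x.columns, columns=y.columns),
    )


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} (m * p_(j) / j), capped at 1; order preserving.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def significance_star(p: float) -> str:
    """Two-tier star annotation: ** for p < 0.01, * for p < 0.05."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# analysis surfaces
# ---------------------------------------------------------------------------

def _tidy_pairs(rho: pd.DataFrame, p: pd.DataFrame, family: str) -> pd.DataFrame:
    rows = []
    for a in rho.index:
        for b in rho.columns:
            rows.append((a, b, rho.at[a, b], p.at[a, b]))
    out = pd.DataFrame(rows, columns=["a", "b", "rho", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    out["star"] = out["p"].map(significance_star)
    out["family"] = family
    out["n"] = len(rho.columns) and None  # filled by callers that know n
    return out.drop(columns=["n"])


def env_taxon_heatmap(
    table: AbundanceTable, meta: SampleFrame, rank: str = "phylum"
) -> pd.DataFrame:
    """Spearman correlations between rank-aggregated relative abundances and
    every environmental variable, BH-adjusted within this heatmap."""
    agg = table.aggregate(rank)
    totals = agg.sum(axis=1)
    if (totals == 0).any():
        raise ValidationError("samples with zero counts cannot be normalised")
    rel = agg.div(totals, axis=0)
    env = meta.environment().reindex(rel.index)
    if env.isna().any().any():
        raise ValidationError("metadata does not cover all samples")
    rho, p = spearman_matrix(rel, env)
    out = _tidy_pairs(rho, p, family=f"env_taxon:{rank}")
    out = out.rename(columns={"a": "taxon", "b": "env"})
    out["n"] = len(rel)
    return out


def metal_correlations(meta: SampleFrame, group: str | None = None) -> pd.DataFrame:
    """Pairwise Spearman among metal concentrations (optionally one group)."""
    metals = meta.metals
    if group is not None:
        metals = metals[meta.groups == group]
    rho, p = spearman_matrix(metals)
    pairs = []
    for i, a in enumerate(metals.columns):
        for b in metals.columns[i + 1:]:
            pairs.append((a, b, rho.at[a, b], p.at[a, b]))
    out = pd.DataFrame(pairs, columns=["a", "b", "rho", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    out["n"] = len(metals)
    return out


def mantel(
    d1: pd.DataFrame,
    d2: pd.DataFrame,
    n_perm: int | str = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mantel test: Spearman correlation of lower-triangle entries, with the
    p-value from jointly permuting rows and columns of ``d2``.

    ``n_perm="all"`` enumerates every sample permutation for an exact
    p-value #(r_perm >= r_obs)/total; otherwise p = (1 + b) / (1 + n_perm).
    """
    a1 = np.asarray(d1, dtype=float)
    a2 = np.asarray(d2, dtype=float)
    if a1.shape != a2.shape or a1.ndim != 2 or a1.shape[0] != a1.shape[1]:
        raise ValidationError("distance matrices must be square with equal shape")
    for a in (a1, a2):
        if not np.allclose(a, a.T, atol=1e-12):
            raise ValidationError("distance matrices must be symmetric")
    n = a1.shape[0]
    if n < 3:
        raise ValidationError("mantel needs at least 3 samples")
    il = np.tril_indices(n, k=-1)

    # ranks are invariant under relabeling, so rank the full symmetric matrix
    # once and re-index per permutation
    def _rank_matrix(a: np.ndarray) -> np.ndarray:
        r = np.zeros_like(a)
        r[il] = stats.rankdata(a[il])
        return r + r.T

    r1 = _rank_matrix(a1)[il]
    r2_full = _rank_matrix(a2)

    def _corr(v1: np.ndarray, v2: np.ndarray) -> float:
        if np.ptp(v1) == 0 or np.ptp(v2) == 0:
            return 0.0
        return float(np.corrcoef(v1, v2)[0, 1])

    r_obs = _corr(r1, r2_full[il])

    if n_perm == "all":
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            p_idx = np.asarray(perm)
            r_perm = _corr(r1, r2_full[np.ix_(p_idx, p_idx)][il])
            if r_perm >= r_obs - 1e-12:
                count += 1
            total += 1
        return r_obs, count / total

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(int(n_perm)):
        p_idx = rng.permutation(n)
        r_perm = _corr(r1, r2_full[np.ix_(p_idx, p_idx)][il])
        if r_perm >= r_obs - 1e-12:
            exceed += 1
    return r_obs, (1 + exceed) / (1 + int(n_perm))


def genus_cross_domain(
    bact: AbundanceTable,
    fungi: AbundanceTable,
    threshold: float = 0.10,
    mode: str = "mean",
) -> pd.DataFrame:
    """Spearman between abundant bacterial and fungal genera.

    A genus is retained when its relative abundance within its own domain
    exceeds ``threshold`` — averaged across samples (``mode="mean"``) or in
    at least one sample (``mode="max"``). BH family = this matrix.
    """
    if list(bact.sample_ids) != list(fungi.sample_ids):
        raise ValidationError("bacterial and fungal tables must share samples")
    if mode not in ("mean", "max"):
        raise ValueError(f"unknown abundance mode {mode!r}")

    def _abundant(table: AbundanceTable) -> pd.DataFrame:
        agg = table.aggregate("genus")
        rel = agg.div(agg.sum(axis=1), axis=0)
        stat = rel.mean(axis=0) if mode == "mean" else rel.max(axis=0)
        return rel.loc[:, stat > threshold]

    rel_b = _abundant(bact)
    rel_f = _abundant(fungi)
    if rel_b.shape[1] == 0 or rel_f.shape[1] == 0:
        warnings.warn("no genus passes the abundance threshold", stacklevel=2)
        return pd.DataFrame(
            columns=["bacteria_genus", "fungi_genus", "rho", "p", "q", "star", "family", "n"]
        )
    rho, p = spearman_matrix(rel_b, rel_f)
    out = _tidy_pairs(rho, p, family="genus_cross_domain")
    out = out.rename(columns={"a": "bacteria_genus", "b": "fungi_genus"})
    out["n"] = len(rel_b)
    return out
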