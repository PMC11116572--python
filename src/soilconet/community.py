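"""Alpha diversity, Bray-Curtis ordination, ANOSIM, and group tests."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .datatypes import AbundanceTable, ValidationError


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def goods_coverage(counts: np.ndarray) -> float:
    """Good's coverage 1 - F1/N (F1 = singleton count, N = total reads)."""
    counts = np.asarray(counts)
    n = counts.sum()
    if n <= 0:
        raise ValidationError("coverage undefined for an empty sample")
    f1 = int((counts == 1).sum())
    return 1.0 - f1 / n


def chao1(counts: np.ndarray) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1) / (2(F2+1))."""
    counts = np.asarray(counts)
    if counts.sum() <= 0:
        raise ValidationError("chao1 undefined for an empty sample")
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def gini_simpson(counts: np.ndarray) -> float:
    """Gini-Simpson diversity 1 - sum(p_i^2)."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n <= 0:
        raise ValidationError("simpson undefined for an empty sample")
    p = counts / n
    return 1.0 - float(np.sum(p * p))


def alpha_diversity(table: AbundanceTable, simpson_form: str = "gini") -> pd.DataFrame:
    """Per-sample coverage, Chao1, and Simpson index.

    ``simpson_form`` selects how the Simpson concentration D = sum(p^2) is
    reported: ``"gini"`` (1 - D, the default), ``"dominance"`` (D), or
    ``"inverse"`` (1/D).
    """
    rows = {}
    for sample in table.sample_ids:
        counts = table.counts.loc[sample].to_numpy()
        d = 1.0 - gini_simpson(counts)
        if simpson_form == "gini":
            simpson = 1.0 - d
        elif simpson_form == "dominance":
            simpson = d
        elif simpson_form == "inverse":
            simpson = math.inf if d == 0 else 1.0 / d
        else:
            raise ValueError(f"unknown simpson_form {simpson_form!r}")
        rows[sample] = {
            "coverage": goods_coverage(counts),
            "chao1": chao1(counts),
            "simpson": simpson,
            "observed_richness": int((counts > 0).sum()),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

def bray_curtis(table: AbundanceTable) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity on relative abundances."""
    if table.n_samples < 2:
        raise ValidationError("Bray-Curtis needs at least two samples")
    rel = table.relative_abundance().to_numpy()
    dm = squareform(pdist(rel, metric="braycurtis"))
    return pd.DataFrame(dm, index=table.sample_ids, columns=table.sample_ids)


def _check_distance_matrix(d: pd.DataFrame) -> np.ndarray:
    arr = np.asarray(d, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(arr, arr.T, atol=1e-12):
        raise ValidationError("distance matrix must be symmetric")
    if not np.allclose(np.diag(arr), 0.0, atol=1e-12):
        raise ValidationError("distance matrix must have a zero diagonal")
    return arr


def pcoa(d: pd.DataFrame, n_axes: int | None = None):
    """Principal-coordinate embedding of a distance matrix.

    Returns ``(coordinates, explained)`` where coordinates are ordered by
    eigenvalue and ``explained[k]`` is eigenvalue k divided by the sum of
    positive eigenvalues. Axes with non-positive eigenvalues are dropped.
    """
    arr = _check_distance_matrix(d)
    n = arr.shape[0]
    # Gower double centering of -D^2/2
    a = -0.5 * arr**2
    centerer = np.eye(n) - np.ones((n, n)) / n
    b = centerer @ a @ centerer
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    positive = eigvals > 1e-10
    eigvals, eigvecs = eigvals[positive], eigvecs[:, positive]
    if n_axes is not None:
        eigvals, eigvecs = eigvals[:n_axes], eigvecs[:, :n_axes]
    coords = eigvecs * np.sqrt(eigvals)
    explained = eigvals / eigvals.sum() if eigvals.size else eigvals
    index = d.index if isinstance(d, pd.DataFrame) else pd.RangeIndex(n)
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=index, columns=cols), explained


def pca_abundance(table: AbundanceTable, n_axes: int | None = None):
    """Covariance PCA on relative abundances (alternative ordination mode)."""
    rel = table.relative_abundance().to_numpy()
    centered = rel - rel.mean(axis=0)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    var = s**2
    keep = var > 1e-12 * var.max() if var.size else slice(None)
    u, s, var = u[:, keep], s[keep], var[keep]
    if n_axes is not None:
        u, s, var = u[:, :n_axes], s[:n_axes], var[:n_axes]
    coords = u * s
    explained = var / (s**2).sum() if s.size else var
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=table.sample_ids, columns=cols), explained


def ordinate(d: pd.DataFrame, method: str = "pcoa", n_axes: int | None = None):
    """Ordinate a distance matrix (``pcoa``) — see :func:`pca_abundance`
    for the covariance-PCA alternative that starts from abundances."""
    if method != "pcoa":
        raise ValueError(f"unknown ordination method {method!r}")
    return pcoa(d, n_axes=n_axes)


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

def _anosim_r(rank_matrix: np.ndarray, labels: np.ndarray) -> float:
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    within = labels[iu[0]] == labels[iu[1]]
    ranks = rank_matrix[iu]
    r_w = ranks[within].mean()
    r_b = ranks[~within].mean()
    m = n * (n - 1) / 2
    return (r_b - r_w) / (m / 2.0)


def anosim(
    d: pd.DataFrame,
    groups,
    n_perm: int | str = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """ANOSIM R statistic and permutation p-value.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2 dissimilarities ranked across the whole matrix.
    ``n_perm="all"`` enumerates every distinct label permutation and returns
    the exact p-value #(R_perm >= R_obs)/total (identity included);
    otherwise p = (1 + #exceedances) / (1 + n_perm) over random permutations.
    """
    arr = _check_distance_matrix(d)
    labels = np.asarray(pd.Series(groups).reindex(d.index))
    if pd.isna(labels).any():
        raise ValidationError("every sample needs a group label")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("ANOSIM needs at least two groups")
    if (counts < 2).any():
        small = uniq[counts < 2].tolist()
        raise ValidationError(f"groups with fewer than 2 samples: {small}")

    n = arr.shape[0]
    iu = np.triu_indices(n, k=1)
    rank_matrix = np.zeros_like(arr)
    ranks = stats.rankdata(arr[iu])
    rank_matrix[iu] = ranks
    rank_matrix = rank_matrix + rank_matrix.T

    r_obs = _anosim_r(rank_matrix, labels)

    if n_perm == "all":
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            perm_labels = labels[list(perm)]
            if _anosim_r(rank_matrix, perm_labels) >= r_obs - 1e-12:
                count += 1
            total += 1
        return r_obs, count / total

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(int(n_perm)):
        perm_labels = rng.permutation(labels)
        if _anosim_r(rank_matrix, perm_labels) >= r_obs - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + int(n_perm))
    return r_obs, p


# ---------------------------------------------------------------------------
# two-group comparison
# ---------------------------------------------------------------------------

def group_compare(values, groups) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test between exactly two groups.

    Uses exact enumeration when both groups have at most 8 observations and
    no ties span the groups; otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    values = pd.Series(values)
    labels = pd.Series(groups, index=values.index)
    uniq = labels.unique()
    if len(uniq) != 2:
        raise ValidationError(f"expected exactly two groups, got {list(uniq)}")
    x = values[labels == uniq[0]].to_numpy(dtype=float)
    y = values[labels == uniq[1]].to_numpy(dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
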