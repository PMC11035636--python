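"""Multivariate and univariate statistics for lipidome composition.

* Hellinger transform (row-wise square root of proportions; makes
  Euclidean distance between samples equal the Hellinger distance and
  tames double-zero bias) followed by mean-centered PCA without unit
  variance scaling — the transform already equalizes scale.
* Row-wise Z-scoring of class abundances plus agglomerative clustering
  of rows and columns (Euclidean / average linkage by default).
* One-way Tukey HSD on the studentized-range distribution with a
  compact letter display (CLD): groups sharing a letter do not differ
  at the chosen alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy import stats as _sps
from sklearn.decomposition import PCA as _SkPCA

from .io import ValidationError

__all__ = [
    "OrdinationResult",
    "TukeyResult",
    "hellinger",
    "pca",
    "zscore_cluster",
    "tukey_hsd",
]


@dataclass
class OrdinationResult:
    scores: pd.DataFrame                 # samples × components
    loadings: pd.DataFrame               # features × components
    explained_variance_ratio: np.ndarray  # per component, non-increasing
    zero_variance: bool = False


@dataclass
class TukeyResult:
    pairwise: pd.DataFrame  # group_a, group_b, mean_diff, p_value
    letters: dict[str, str]
    alpha: float = 0.05


def hellinger(profile: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Hellinger transform of a samples × features abundance matrix.

    Each row is closed to proportions and square-rooted, so every output
    row has unit sum of squares.  All-zero rows are an error.
    """
    values = np.asarray(profile, dtype=float)
    if values.ndim != 2:
        raise ValidationError("hellinger expects a 2-D samples × features matrix")
    if np.any(values < 0):
        raise ValidationError("hellinger requires non-negative abundances")
    totals = values.sum(axis=1)
    if np.any(totals == 0):
        bad = np.where(totals == 0)[0].tolist()
        raise ValidationError(f"all-zero rows at positions {bad}")
    out = np.sqrt(values / totals[:, None])
    if isinstance(profile, pd.DataFrame):
        return pd.DataFrame(out, index=profile.index, columns=profile.columns)
    return out


def pca(X: pd.DataFrame | np.ndarray, n_components: int | None = None) -> OrdinationResult:
    """Column-mean-centered PCA (no variance scaling).

    Keeps all ``min(n_samples - 1, n_features)`` components by default,
    so the explained-variance ratios sum to 1 for data of full rank.
    The sign of each component is fixed by forcing its
    largest-magnitude loading positive.  Degenerate input (all samples
    identical) is flagged via ``zero_variance`` with zero ratios.
    """
    if isinstance(X, pd.DataFrame):
        index, columns, values = X.index, X.columns, X.to_numpy(dtype=float)
    else:
        values = np.asarray(X, dtype=float)
        index = pd.RangeIndex(values.shape[0])
        columns = pd.RangeIndex(values.shape[1])
    n, p = values.shape
    if n < 2:
        raise ValidationError("PCA requires at least 2 samples")
    max_comp = min(n - 1, p)
    k = max_comp if n_components is None else min(n_components, max_comp)

    centered = values - values.mean(axis=0)
    total_var = centered.var(axis=0, ddof=1).sum()
    comp_names = [f"PC{i + 1}" for i in range(k)]
    if total_var == 0:
        return OrdinationResult(
            scores=pd.DataFrame(0.0, index=index, columns=comp_names),
            loadings=pd.DataFrame(0.0, index=columns, columns=comp_names),
            explained_variance_ratio=np.zeros(k),
            zero_variance=True,
        )

    model = _SkPCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(values)
    loadings = model.components_.T  # features × components
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(k):
        col = loadings[:, j]
        pivot = np.argmax(np.abs(col))
        if col[pivot] < 0:
            loadings[:, j] = -col
            scores[:, j] = -scores[:, j]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=columns, columns=comp_names),
        explained_variance_ratio=model.explained_variance_ratio_.copy(),
    )


def zscore_cluster(
    class_abundance: pd.DataFrame,
    metric: str = "euclidean",
    method: str = "average",
    clip: float = 3.0,
) -> dict:
    """Row-wise Z-scores of a classes × samples matrix plus 2-way clustering.

    Z-scoring uses the sample (n−1) standard deviation.  Zero-variance
    rows get Z = 0 with a warning.  Returns the unclipped Z matrix used
    for clustering, a ±``clip`` display copy, row/column orders and the
    scipy linkage matrices.
    """
    X = class_abundance.astype(float)
    if X.shape[1] < 2:
        raise ValidationError("Z-scoring needs at least 2 samples")
    mean = X.mean(axis=1)
    sd = X.std(axis=1, ddof=1)
    flat = sd[sd == 0].index.tolist()
    if flat:
        warnings.warn(f"zero-variance rows set to Z=0: {flat}", stacklevel=2)
    Z = X.sub(mean, axis=0).divide(sd.replace(0.0, np.nan), axis=0).fillna(0.0)

    def _order(matrix: np.ndarray):
        if matrix.shape[0] < 2:
            return np.arange(matrix.shape[0]), None
        link = hierarchy.linkage(pdist(matrix, metric=metric), method=method)
        return hierarchy.leaves_list(link), link

    row_order, row_link = _order(Z.to_numpy())
    col_order, col_link = _order(Z.to_numpy().T)
    return {
        "Z": Z,
        "Z_display": Z.clip(-clip, clip),
        "row_order": list(Z.index[row_order]),
        "col_order": list(Z.columns[col_order]),
        "row_linkage": row_link,
        "col_linkage": col_link,
    }


def _compact_letter_display(
    groups: Sequence[str], significant: set[tuple[str, str]]
) -> dict[str, str]:
    """Insert-and-absorb CLD: groups sharing a letter are not significantly
    different; every significant pair shares no letter."""
    columns: list[set[str]] = [set(groups)]
    for a, b in sorted(significant):
        for col in list(columns):
            if a in col and b in col:
                columns.remove(col)
                columns.append(col - {a})
                columns.append(col - {b})
        # absorb columns contained in another
        columns = [
            col
            for col in columns
            if col and not any(col < other for other in columns if other is not col)
        ]
        # deduplicate while keeping order
        seen: list[set[str]] = []
        for col in columns:
            if col not in seen:
                seen.append(col)
        columns = seen
    columns.sort(key=lambda col: sorted(col)[0])
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for i, col in enumerate(columns):
        for g in sorted(col):
            letters[g] += alphabet[i % len(alphabet)]
    return letters


def tukey_hsd(
    values: Sequence[float] | pd.Series,
    groups: Sequence[str],
    alpha: float = 0.05,
    one_sided: bool = False,
) -> TukeyResult:
    """Tukey's Honest Significant Difference over a one-way layout.

    Pairwise p-values come from the studentized-range distribution
    (scipy).  ``one_sided=True`` halves the p-value of each pair in the
    direction of the observed difference — a pragmatic reading of
    one-sided multiple comparison; the standard two-sided test is the
    default.  Letters follow the insert-and-absorb CLD.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray([str(g) for g in groups])
    if values.shape[0] != labels.shape[0]:
        raise ValidationError("values and groups differ in length")
    names = sorted(set(labels))
    if len(names) < 2:
        raise ValidationError("Tukey HSD needs at least 2 groups")
    arrays = [values[labels == g] for g in names]
    for g, arr in zip(names, arrays):
        if arr.shape[0] < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 replicates")

    with np.errstate(divide="ignore", invalid="ignore"):
        res = _sps.tukey_hsd(*arrays)
    rows = []
    significant: set[tuple[str, str]] = set()
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            diff = float(np.mean(arrays[i]) - np.mean(arrays[j]))
            p = float(res.pvalue[i, j])
            if one_sided:
                p = min(1.0, p / 2.0)
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "mean_diff": diff,
                    "p_value": p,
                }
            )
            if p < alpha:
                significant.add((names[i], names[j]))
    letters = _compact_letter_display(names, significant)
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "mean_diff", "p_value"])
    return TukeyResult(pairwise=pairwise, letters=letters, alpha=alpha)
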