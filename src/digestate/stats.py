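"""Survey-level statistics: scaling, Ward clustering, PCA, Pearson scans.

Operates on a plant-by-parameter feature table (a pandas DataFrame with
plant/digester identifiers as the index).  The workflow mirrors common
practice for small process surveys: drop parameters with any missing
value, z-score the rest, cluster plants with Ward's minimum-variance
method, summarize with PCA, and scan selected parameter pairs for Pearson
correlations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy import stats as sps

log = logging.getLogger(__name__)


@dataclass
class PcaResult:
    """Principal component analysis of a scaled feature matrix.

    ``explained_variance_fraction`` covers *all* components of the
    decomposition (it sums to 1) even when ``scores``/``loadings`` are
    truncated to the requested number of components.  The sign of each
    component is fixed so that its largest-magnitude loading is positive.
    """

    scores: pd.DataFrame       # rows x components
    loadings: pd.DataFrame     # variables x components
    explained_variance_fraction: np.ndarray


def scale_features(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-score every column to mean 0, sd 1 (sample sd, ddof=1).

    Constant columns cannot be scaled and are dropped with a warning.
    """
    numeric = matrix.astype(float)
    sd = numeric.std(ddof=1)
    constant = sd.index[(sd == 0) | sd.isna()]
    if len(constant):
        log.warning("dropping constant columns before scaling: %s", list(constant))
        numeric = numeric.drop(columns=constant)
        sd = sd.drop(constant)
    return (numeric - numeric.mean()) / sd


def drop_incomplete(matrix: pd.DataFrame) -> pd.DataFrame:
    """Remove every column with at least one missing value."""
    incomplete = matrix.columns[matrix.isna().any()]
    if len(incomplete):
        log.warning("dropping incomplete columns: %s", list(incomplete))
    out = matrix.drop(columns=incomplete)
    if out.shape[1] == 0:
        raise ValueError("no complete columns remain after dropping missing data")
    return out


def ward_cluster(matrix: pd.DataFrame) -> np.ndarray:
    """Agglomerative Ward clustering of the rows.

    Returns a SciPy linkage matrix: each row ``[i, j, height, size]``
    merges clusters ``i`` and ``j``; heights are the Ward distances
    ``sqrt(2 * increase in within-cluster sum of squares)`` and are
    monotonically non-decreasing.  Ties resolve to the lowest cluster
    indices (as produced by the nearest-neighbor-chain algorithm).
    """
    values = np.asarray(matrix, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("ward_cluster requires a 2-D matrix with >= 2 rows")
    if np.isnan(values).any():
        raise ValueError("ward_cluster requires complete data (no NaN)")
    return linkage(values, method="ward")


def pca(matrix: pd.DataFrame, n_components: int | None = None) -> PcaResult:
    """PCA of a scaled, centred, complete feature matrix via SVD.

    Components are ordered by decreasing explained variance.  When the
    matrix is rank-deficient the decomposition is truncated to the rank
    with a warning.
    """
    x = np.asarray(matrix, dtype=float)
    if np.isnan(x).any():
        raise ValueError("pca requires complete data (no NaN)")
    n, p = x.shape
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    tol = max(n, p) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int((s > tol).sum())
    if rank < min(n - 1, p):
        warnings.warn(
            f"rank-deficient matrix: truncating to {rank} components",
            stacklevel=2,
        )
    u, s, vt = u[:, :rank], s[:rank], vt[:rank]
    var = s**2 / (n - 1)
    explained = var / var.sum()
    # deterministic sign: largest-magnitude loading of each PC is positive
    for k in range(rank):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    keep = rank if n_components is None else min(n_components, rank)
    comp_names = [f"PC{i + 1}" for i in range(keep)]
    scores = pd.DataFrame(
        u[:, :keep] * s[:keep], index=matrix.index, columns=comp_names
    )
    loadings = pd.DataFrame(vt[:keep].T, index=matrix.columns, columns=comp_names)
    return PcaResult(
        scores=scores, loadings=loadings, explained_variance_fraction=explained
    )


def pearson_scan(
    matrix: pd.DataFrame, pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Pearson r and two-sided p-value for selected parameter pairs.

    Uses pairwise-complete observations.  Pairs with fewer than 3
    complete observations or zero variance yield NaN.  A Benjamini-
    Hochberg adjusted p-value column (``p_bh``) is added as an extension
    beyond the plain per-pair p-values.
    """
    rows = []
    for a, b in pairs:
        sub = matrix[[a, b]].dropna()
        n = len(sub)
        if n < 3 or sub[a].nunique() < 2 or sub[b].nunique() < 2:
            if n >= 3:
                log.warning("zero variance for pair (%s, %s); r undefined", a, b)
            rows.append((a, b, n, np.nan, np.nan))
            continue
        r, p = sps.pearsonr(sub[a], sub[b])
        rows.append((a, b, n, float(r), float(p)))
    out = pd.DataFrame(rows, columns=["x", "y", "n", "r", "p"])
    out["p_bh"] = _benjamini_hochberg(out["p"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values; NaNs pass through."""
    adj = np.full_like(p, np.nan, dtype=float)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return adj
    order = np.argsort(pv)
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    vals = np.empty(m)
    vals[order] = np.minimum(ranked, 1.0)
    adj[ok] = vals
    return adj


def normalize_enzyme_activity(values: list[float]) -> list[float]:
    """Scale enzyme activities to the highest observed value (max -> 1)."""
    if not values:
        raise ValueError("normalize_enzyme_activity requires at least one value")
    top = max(values)
    if top <= 0:
        raise ValueError("all activities are zero or negative; cannot normalize")
    return [v / top for v in values]
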