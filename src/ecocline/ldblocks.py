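"""Linkage disequilibrium: pairwise R^2, decay curves, and block clustering.

For binary variant columns i and j with 1-frequencies f_i, f_j and joint
(1,1) frequency f_ij,

    R^2 = (f_ij - f_i f_j)^2 / (f_i (1 - f_i) f_j (1 - f_j)),

which is algebraically the squared Pearson correlation of the two columns.
Decay curves average R^2 over pairs binned by bp distance up to a maximum
marker distance; the high-loading variant analysis computes the full R^2
matrix among variants whose squared PC1 loading exceeds a cutoff and
partitions it into blocks by agglomerative clustering on 1 - R^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .snpmatrix import SNPMatrix

__all__ = [
    "LDSummary",
    "LDUndefinedError",
    "r2_pair",
    "r2_matrix",
    "ld_decay",
    "high_loading_ld",
    "cluster_blocks",
]


class LDUndefinedError(ValueError):
    """R^2 is undefined (a column is monomorphic over the shared strains)."""


@dataclass
class LDSummary:
    r2_matrix: np.ndarray  # variants x variants, unit diagonal
    positions: np.ndarray  # bp coordinate of each included variant
    decay_bins: pd.DataFrame | None = None  # bin_bp, mean_r2, n_pairs
    blocks: np.ndarray | None = None  # per-variant block label (1-based)
    high_loading_cutoff: float | None = None


def r2_pair(col_i, col_j) -> float:
    """R^2 between two binary columns via the joint-frequency formula."""
    x = np.asarray(col_i, dtype=np.float64)
    y = np.asarray(col_j, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("columns must have equal length")
    fi, fj = x.mean(), y.mean()
    if fi in (0.0, 1.0) or fj in (0.0, 1.0):
        raise LDUndefinedError("R^2 undefined for a monomorphic column")
    fij = (x * y).mean()
    return float((fij - fi * fj) ** 2 / (fi * (1 - fi) * fj * (1 - fj)))


def r2_matrix(m: SNPMatrix) -> np.ndarray:
    """Full pairwise R^2 matrix (vectorised joint-frequency formula)."""
    x = m.imputed()
    n = x.shape[0]
    f = x.mean(axis=0)
    if np.any((f == 0) | (f == 1)):
        raise LDUndefinedError("matrix contains monomorphic columns")
    fij = (x.T @ x) / n
    num = (fij - np.outer(f, f)) ** 2
    den = np.outer(f * (1 - f), f * (1 - f))
    r2 = num / den
    np.fill_diagonal(r2, 1.0)
    return np.clip(r2, 0.0, 1.0)


def ld_decay(m: SNPMatrix, max_dist: int = 30_000, bin_size: int = 10) -> pd.DataFrame:
    """Mean R^2 per distance bin over all pairs within ``max_dist`` bp.

    Returns the populated bins only, with columns ``bin_bp`` (bin midpoint),
    ``mean_r2`` and ``n_pairs``; pair distance is binned in ``bin_size`` bp
    steps.
    """
    if max_dist <= 0 or bin_size <= 0:
        raise ValueError("max_dist and bin_size must be positive")
    pos = m.positions
    x = m.imputed()
    n = x.shape[0]
    f = x.mean(axis=0)
    var = f * (1 - f)
    if np.any(var == 0):
        raise LDUndefinedError("matrix contains monomorphic columns")
    n_bins = max_dist // bin_size + 1
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for i in range(m.n_sites - 1):
        hi = np.searchsorted(pos, pos[i] + max_dist, side="right")
        if hi <= i + 1:
            continue
        js = np.arange(i + 1, hi)
        fij = (x[:, i] @ x[:, js]) / n
        r2 = (fij - f[i] * f[js]) ** 2 / (var[i] * var[js])
        bins = (pos[js] - pos[i]) // bin_size
        np.add.at(sums, bins, r2)
        np.add.at(counts, bins, 1)
    keep = counts > 0
    return pd.DataFrame(
        {
            "bin_bp": (np.arange(n_bins)[keep] + 0.5) * bin_size,
            "mean_r2": sums[keep] / counts[keep],
            "n_pairs": counts[keep],
        }
    )


def high_loading_ld(
    m: SNPMatrix, squared_loadings, cutoff: float = 300.0
) -> LDSummary:
    """Full R^2 matrix among variants whose squared PC1 loading exceeds
    ``cutoff`` (no distance cap: high-loading blocks span the genome)."""
    squared_loadings = np.asarray(squared_loadings, dtype=np.float64)
    if squared_loadings.shape != (m.n_sites,):
        raise ValueError("need one squared loading per site")
    idx = np.flatnonzero(squared_loadings > cutoff)
    if idx.size < 2:
        raise ValueError(
            f"fewer than 2 variants exceed the squared-loading cutoff {cutoff}"
        )
    sub = m.take_sites(idx)
    return LDSummary(
        r2_matrix=r2_matrix(sub),
        positions=sub.positions,
        high_loading_cutoff=float(cutoff),
    )


def cluster_blocks(r2: np.ndarray, n_blocks: int, loadings=None) -> np.ndarray:
    """Agglomerative block assignment on the LD matrix.

    Complete-linkage hierarchical clustering on the distance 1 - R^2, with
    the tree cut to ``n_blocks`` labels. Labels are 1-based and ordered by
    descending within-block mean of ``loadings`` when given (block 1 = top
    loading block), otherwise by descending block size with ties broken by
    first member index.
    """
    r2 = np.asarray(r2, dtype=np.float64)
    nv = r2.shape[0]
    if r2.shape != (nv, nv):
        raise ValueError("r2 must be square")
    if not (1 <= n_blocks <= nv):
        raise ValueError("n_blocks must lie in [1, n_variants]")
    if nv == 1 or n_blocks == 1:
        return np.ones(nv, dtype=np.int64)
    d = 1.0 - np.clip((r2 + r2.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="complete")
    raw = fcluster(z, t=n_blocks, criterion="maxclust")
    labels = np.unique(raw)
    if loadings is not None:
        loadings = np.asarray(loadings, dtype=np.float64)
        key = [-loadings[raw == lab].mean() for lab in labels]
    else:
        key = [(-(raw == lab).sum(), int(np.flatnonzero(raw == lab)[0])) for lab in labels]
    order = sorted(range(len(labels)), key=lambda i: key[i])
    remap = {labels[i]: rank + 1 for rank, i in enumerate(order)}
    return np.array([remap[lab] for lab in raw], dtype=np.int64)
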