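"""PCA on binary variant matrices: strain loadings, per-variant loadings,
variance explained, and cross-group projection.

Strain loadings are the left singular vectors of the (column-centred)
matrix scaled by the square root of the covariance eigenvalues, i.e. the
standard loading definition (a scaled principal-component score). Per-variant
loadings are obtained by multiplying the strain-loading matrix into the
MAF-filtered binary matrix, one value per site and component — this puts
loading values on sites that were pruned away before the decomposition, and
its squared PC1 column is the genome scan used to locate loading peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .snpmatrix import SNPMatrix

__all__ = ["PCAResult", "VariantLoadings", "run_pca", "variant_loadings", "project"]


@dataclass
class PCAResult:
    eigenvalues: np.ndarray  # top-k covariance eigenvalues
    pve: np.ndarray  # proportion of variance explained, per component
    strain_loadings: np.ndarray  # strains x k
    strain_ids: list[str]
    scaling: str  # "sqrt" (default) or "eigenvalue"
    total_variance: float
    variants: "VariantLoadings | None" = None


@dataclass
class VariantLoadings:
    positions: np.ndarray  # sites (MAF-filtered set)
    loadings: np.ndarray  # sites x k
    squared: np.ndarray = field(default=None)
    abs: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.squared is None:
            self.squared = self.loadings**2
        if self.abs is None:
            self.abs = np.abs(self.loadings)

    def to_frame(self, component: int = 0) -> pd.DataFrame:
        c = component
        return pd.DataFrame(
            {
                "position": self.positions,
                "loading": self.loadings[:, c],
                "squared": self.squared[:, c],
                "abs": self.abs[:, c],
            }
        )


def _fix_signs(u: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: in each column the entry of largest
    magnitude is positive (component signs are arbitrary otherwise)."""
    idx = np.argmax(np.abs(u), axis=0)
    signs = np.sign(u[idx, np.arange(u.shape[1])])
    signs[signs == 0] = 1.0
    return u * signs[None, :]


def run_pca(
    m: SNPMatrix,
    k: int = 20,
    scaling: str = "sqrt",
    standardize: bool = False,
) -> PCAResult:
    """PCA of a (typically LD-pruned) binary matrix.

    Columns are mean-centred (optionally variance-standardized, matching
    genotype-PCA tools); the strain-by-strain covariance spectrum comes from
    an SVD. ``scaling="sqrt"`` multiplies eigenvectors by the square root of
    the eigenvalues (the loading definition used throughout); the
    ``"eigenvalue"`` variant (no square root) is available for replication
    experiments. Proportions of variance explained are eigenvalues over the
    full-spectrum total.
    """
    if scaling not in ("sqrt", "eigenvalue"):
        raise ValueError("scaling must be 'sqrt' or 'eigenvalue'")
    n, p = m.n_strains, m.n_sites
    kmax = min(n - 1, p)
    if not (1 <= k <= kmax):
        raise ValueError(f"k must lie in [1, {kmax}] for a {n}x{p} matrix")
    x = m.imputed()
    x = x - x.mean(axis=0)
    if standardize:
        sd = x.std(axis=0)
        if np.any(sd == 0):
            raise ValueError("standardize=True requires no constant columns")
        x = x / sd
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    eig = s**2 / (n - 1)
    total = float(eig.sum())
    if total <= 0:
        raise ValueError("matrix is constant: no variance to decompose")
    u = _fix_signs(u[:, :k])
    eig_k = eig[:k]
    scale = np.sqrt(eig_k) if scaling == "sqrt" else eig_k
    return PCAResult(
        eigenvalues=eig_k,
        pve=eig_k / total,
        strain_loadings=u * scale[None, :],
        strain_ids=list(m.strain_ids),
        scaling=scaling,
        total_variance=total,
    )


def variant_loadings(res: PCAResult, maf_matrix: SNPMatrix) -> VariantLoadings:
    """Per-variant loadings: strain loadings multiplied into the MAF-filtered
    (not pruned) binary matrix over the same strains, one row per site.

    Because strain-loading columns have zero mean, using the raw binary
    matrix or its centred version gives identical values.
    """
    if maf_matrix.n_strains != res.strain_loadings.shape[0]:
        raise ValueError("matrix strains do not match the PCA result")
    if list(maf_matrix.strain_ids) != list(res.strain_ids):
        raise ValueError("strain ids do not match the PCA result")
    x = maf_matrix.imputed()
    vl = VariantLoadings(
        positions=maf_matrix.positions.copy(),
        loadings=x.T @ res.strain_loadings,
    )
    res.variants = vl
    return vl


def project(m2: SNPMatrix, vl: VariantLoadings) -> np.ndarray:
    """Map a second strain set onto components defined elsewhere.

    ``m2`` is inner-joined on position with the loading site set and the
    binary matrix multiplied into the loading vectors; the result is one
    score per strain and component, intended for correlation (the scale is
    unconstrained).
    """
    common, i2, iv = np.intersect1d(
        m2.positions, vl.positions, assume_unique=True, return_indices=True
    )
    del common
    x = m2.imputed()[:, i2]
    return x @ vl.loadings[iv]
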