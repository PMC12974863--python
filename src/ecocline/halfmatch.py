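"""Reproducibility tests for PC1.

A principal component that reflects a real axis of population differentiation
should be recoverable from non-overlapping slices of the data. Three tests
operationalize this:

* half-strain matching — split the strains in two, define PC1 on one half,
  map the other half onto it via per-variant loadings, and correlate the
  mapped scores with that half's own PC1 (both directions);
* half-genome matching — run independent prune+PCA on the two halves of the
  chromosome and correlate the resulting PC1 strain scores;
* partial-variants matching — classify sites into low/medium/high by the
  windowed maximum of squared PC1 loadings, run independent prune+PCA on the
  low and high sets, and correlate their PC1s (medium sites are ignored).

Correlations are reported as |Pearson r| (component signs are arbitrary) and
significance is assessed against a strain-permutation null (200 permutations,
alpha = 0.01 by default), since a stated test does not accompany the
correlations themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .pca import run_pca, variant_loadings, project
from .snpmatrix import SNPMatrix, ld_prune

__all__ = [
    "HalfMatchReport",
    "half_strain_test",
    "half_genome_test",
    "window_max_loading",
    "partial_variants_test",
]


@dataclass
class HalfMatchReport:
    test_name: str  # half_strain | half_genome | partial_variants
    r_forward: float
    p_forward: float
    null_q99_forward: float
    r_reverse: float | None = None
    p_reverse: float | None = None
    null_q99_reverse: float | None = None
    group_assignments: np.ndarray | None = None  # per-strain or per-site labels
    category_thresholds: tuple[float, float] | None = None
    alpha: float = 0.01

    @property
    def significant(self) -> bool:
        """True when every reported correlation beats the permutation null."""
        ok = self.p_forward <= self.alpha
        if self.p_reverse is not None:
            ok = ok and self.p_reverse <= self.alpha
        return bool(ok)


def _abs_pearson(a, b) -> float:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(abs(stats.pearsonr(a, b)[0]))


def _perm_null(a, b, rng, n_perm: int = 200):
    """|r| observed, permutation p-value and null 99th percentile."""
    obs = _abs_pearson(a, b)
    a = np.asarray(a, dtype=np.float64)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = _abs_pearson(rng.permutation(a), b)
    p = (1.0 + np.sum(null >= obs)) / (n_perm + 1.0)
    return obs, float(p), float(np.quantile(null, 0.99))


def _prune_pca(m: SNPMatrix, window: int, r2_max: float):
    """Restrict to polymorphic sites, prune, and return PCA (k=2)."""
    poly = m.polymorphic()
    if poly.n_sites < 2:
        raise ValueError("fewer than 2 polymorphic sites in subset")
    pruned = ld_prune(poly, window=window, r2_max=r2_max)
    if pruned.n_sites < 2:
        raise ValueError("fewer than 2 sites survive LD pruning in subset")
    k = min(2, pruned.n_strains - 1, pruned.n_sites)
    return poly, run_pca(pruned, k=k)


def half_strain_test(
    m: SNPMatrix,
    partition,
    window: int = 50_000,
    r2_max: float = 0.1,
    n_perm: int = 200,
    alpha: float = 0.01,
    rng: np.random.Generator | None = None,
) -> HalfMatchReport:
    """Half-strain matching on a MAF-filtered matrix.

    ``partition`` is a per-strain binary label vector (e.g. the two sides of
    the tree backbone, or the sign of a preliminary full-data PC1). For each
    direction: prune+PCA on the defining group, per-variant loadings on the
    group's rows of the full MAF-filtered site set, projection of the other
    group, and |Pearson r| between projected PC1 and that group's own PC1.
    """
    rng = rng or np.random.default_rng(0)
    labels = np.asarray(partition).astype(int)
    if labels.shape != (m.n_strains,) or set(np.unique(labels)) - {0, 1}:
        raise ValueError("partition must be a binary label per strain")
    g1 = np.flatnonzero(labels == 0)
    g2 = np.flatnonzero(labels == 1)
    if g1.size < 3 or g2.size < 3:
        raise ValueError("both strain groups must contain at least 3 strains")

    def one_direction(defining, other):
        m_def = m.take_strains(defining)
        _, res = _prune_pca(m_def, window, r2_max)
        vl = variant_loadings(res, m_def)
        m_oth = m.take_strains(other)
        projected = project(m_oth, vl)[:, 0]
        _, own = _prune_pca(m_oth, window, r2_max)
        return _perm_null(projected, own.strain_loadings[:, 0], rng, n_perm)

    r_f, p_f, q_f = one_direction(g1, g2)
    r_r, p_r, q_r = one_direction(g2, g1)
    return HalfMatchReport(
        test_name="half_strain",
        r_forward=r_f,
        p_forward=p_f,
        null_q99_forward=q_f,
        r_reverse=r_r,
        p_reverse=p_r,
        null_q99_reverse=q_r,
        group_assignments=labels,
        alpha=alpha,
    )


def half_genome_test(
    m: SNPMatrix,
    split: int,
    window: int = 50_000,
    r2_max: float = 0.1,
    n_perm: int = 200,
    alpha: float = 0.01,
    rng: np.random.Generator | None = None,
) -> HalfMatchReport:
    """Half-genome matching: independent prune+PCA on the sites before and
    after ``split`` bp, then |Pearson r| between the two PC1 score vectors."""
    rng = rng or np.random.default_rng(0)
    first = np.flatnonzero(m.positions < split)
    second = np.flatnonzero(m.positions >= split)
    if first.size < 2 or second.size < 2:
        raise ValueError("both genome fragments need at least 2 polymorphic sites")
    _, res1 = _prune_pca(m.take_sites(first), window, r2_max)
    _, res2 = _prune_pca(m.take_sites(second), window, r2_max)
    r, p, q = _perm_null(
        res1.strain_loadings[:, 0], res2.strain_loadings[:, 0], rng, n_perm
    )
    side = (m.positions >= split).astype(int)
    return HalfMatchReport(
        test_name="half_genome",
        r_forward=r,
        p_forward=p,
        null_q99_forward=q,
        group_assignments=side,
        alpha=alpha,
    )


def window_max_loading(loadings, positions, window: int) -> np.ndarray:
    """Windowed maximum of per-site (squared) loadings.

    The value at site s is the maximum loading among sites within
    +- window/2 bp of s, i.e. the peak height of the site's vicinity.
    """
    loadings = np.asarray(loadings, dtype=np.float64)
    positions = np.asarray(positions, dtype=np.int64)
    if loadings.shape != positions.shape:
        raise ValueError("loadings and positions must align")
    if positions.size > 1 and np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted")
    half = window / 2.0
    out = np.empty_like(loadings)
    for i, p in enumerate(positions):
        lo = np.searchsorted(positions, p - half, side="left")
        hi = np.searchsorted(positions, p + half, side="right")
        out[i] = loadings[lo:hi].max()
    return out


def partial_variants_test(
    m: SNPMatrix,
    low_q: float = 1 / 3,
    high_q: float = 0.9,
    window: int = 50_000,
    r2_max: float = 0.1,
    n_perm: int = 200,
    alpha: float = 0.01,
    rng: np.random.Generator | None = None,
) -> HalfMatchReport:
    """Partial-variants matching on a MAF-filtered matrix.

    Squared PC1 loadings from a full prune+PCA pass are spread into windowed
    maxima; sites below the ``low_q`` quantile of that distribution form the
    low-loading set and sites above the ``high_q`` quantile the high-loading
    set (intermediate sites are ignored). Independent prune+PCA on the two
    sets gives the correlated PC1 pair.
    """
    rng = rng or np.random.default_rng(0)
    if not (0 < low_q < high_q < 1):
        raise ValueError("need 0 < low_q < high_q < 1")
    _, res = _prune_pca(m, window, r2_max)
    vl = variant_loadings(res, m)
    wmax = window_max_loading(vl.squared[:, 0], m.positions, window)
    lo_thr = float(np.quantile(wmax, low_q))
    hi_thr = float(np.quantile(wmax, high_q))
    low = np.flatnonzero(wmax <= lo_thr)
    high = np.flatnonzero(wmax >= hi_thr)
    if lo_thr >= hi_thr or low.size < 2 or high.size < 2:
        raise ValueError(
            "loading distribution does not separate low and high categories"
        )
    _, res_hi = _prune_pca(m.take_sites(high), window, r2_max)
    _, res_lo = _prune_pca(m.take_sites(low), window, r2_max)
    r, p, q = _perm_null(
        res_hi.strain_loadings[:, 0], res_lo.strain_loadings[:, 0], rng, n_perm
    )
    cats = np.ones(m.n_sites, dtype=np.int64)  # 0=low, 1=medium, 2=high
    cats[low] = 0
    cats[high] = 2
    return HalfMatchReport(
        test_name="partial_variants",
        r_forward=r,
        p_forward=p,
        null_q99_forward=q,
        group_assignments=cats,
        category_thresholds=(lo_thr, hi_thr),
        alpha=alpha,
    )
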