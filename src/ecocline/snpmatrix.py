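"""Binary minor-allele strain x site matrices and the filtering rules.

Polymorphic sites are encoded so that the minor allele (the second most
frequent state at the site, counting the ancestral no-mutation state as an
allele) is 1 and every other state - including third- and fourth-ranked
alleles at multi-allelic sites - is 0. Frequency ties are broken
deterministically towards the smaller internal allele identifier
(ancestral < m1 < m2, or REF < ALT1 < ALT2 for imported VCF records).

The module also implements minor-allele-frequency filtering, greedy windowed
LD pruning, raw Hamming distances and the non-redundant strain selection
used before tree building.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import Genome

__all__ = [
    "SNPMatrix",
    "encode_binary",
    "encode_allele_matrix",
    "maf_filter",
    "ld_prune",
    "nonredundant_select",
    "pairwise_distance",
    "from_tsv",
    "from_vcf",
]

MISSING = -1  # only arises in imported call sets


@dataclass
class SNPMatrix:
    """Strains x polymorphic-sites binary minor-allele matrix.

    ``values`` entries are {0, 1} (−1 marks missing calls in imported data);
    ``positions`` are strictly increasing bp coordinates; ``minor_freqs`` is
    the per-site frequency of the 1-coded allele among non-missing calls.
    """

    values: np.ndarray
    positions: np.ndarray
    strain_ids: list[str]
    minor_freqs: np.ndarray = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D strains x sites array")
        if self.values.shape != (len(self.strain_ids), self.positions.size):
            raise ValueError("values shape must be (n_strains, n_sites)")
        if self.positions.size > 1 and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.minor_freqs is None:
            self.minor_freqs = self._column_freqs()
        else:
            self.minor_freqs = np.asarray(self.minor_freqs, dtype=np.float64)

    def _column_freqs(self) -> np.ndarray:
        v = self.values
        obs = v != MISSING
        with np.errstate(invalid="ignore"):
            return np.where(obs.any(axis=0), (v == 1).sum(axis=0) / obs.sum(axis=0), np.nan)

    @property
    def n_strains(self) -> int:
        return self.values.shape[0]

    @property
    def n_sites(self) -> int:
        return self.values.shape[1]

    def take_sites(self, index) -> "SNPMatrix":
        """Submatrix over a site index/mask (site order preserved)."""
        index = np.asarray(index)
        index = np.flatnonzero(index) if index.dtype == bool else index.astype(int)
        return SNPMatrix(
            self.values[:, index], self.positions[index], list(self.strain_ids)
        )

    def take_strains(self, index) -> "SNPMatrix":
        """Submatrix over strains; site set unchanged (columns may become
        monomorphic within the subset — use :meth:`polymorphic` after)."""
        index = np.asarray(index)
        index = np.flatnonzero(index) if index.dtype == bool else index.astype(int)
        ids = [self.strain_ids[i] for i in index]
        return SNPMatrix(self.values[index], self.positions.copy(), ids)

    def polymorphic(self) -> "SNPMatrix":
        """Drop sites that are monomorphic among the current strains."""
        v = np.where(self.values == MISSING, np.nan, self.values.astype(float))
        with np.errstate(invalid="ignore"):
            f = np.nanmean(v, axis=0)
        keep = (f > 0) & (f < 1)
        return self.take_sites(np.flatnonzero(keep))

    def imputed(self) -> np.ndarray:
        """Float matrix with missing calls replaced by the column mean."""
        x = self.values.astype(np.float64)
        miss = self.values == MISSING
        if miss.any():
            x[miss] = np.nan
            col_mean = np.nanmean(x, axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            idx = np.where(miss)
            x[idx] = col_mean[idx[1]]
        return x

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            self.values, index=self.strain_ids, columns=self.positions
        )
        df.index.name = "strain"
        df.to_csv(path, sep="\t")


def encode_binary(pop_or_calls, genome_length: int | None = None) -> SNPMatrix:
    """Binary minor-allele matrix from a simulated population.

    Accepts a list of :class:`~ecocline.simulate.Genome`. The ancestral
    (no-mutation) state is an allele like any other; m1 and m2 at one site
    are distinct alleles. Monomorphic sites are dropped; at each retained
    site the second most frequent allele is coded 1 (ties towards the
    smaller allele id).
    """
    genomes = list(pop_or_calls)
    if len(genomes) < 2:
        raise ValueError("need at least 2 strains to encode a SNP matrix")
    if not all(isinstance(g, Genome) for g in genomes):
        raise TypeError("encode_binary expects Genome objects; use encode_allele_matrix for call sets")
    all_pos = np.unique(np.concatenate([g.positions for g in genomes] or [np.empty(0, np.int64)]))
    alleles = np.zeros((len(genomes), all_pos.size), dtype=np.int8)
    for i, g in enumerate(genomes):
        idx = np.searchsorted(all_pos, g.positions)
        alleles[i, idx] = g.types
    ids = [f"strain_{i}" for i in range(len(genomes))]
    return encode_allele_matrix(alleles, all_pos, ids)


def encode_allele_matrix(alleles, positions, strain_ids) -> SNPMatrix:
    """Binary-encode a strains x sites matrix of small integer allele codes.

    Allele code −1 marks a missing call; monomorphic sites (one allele among
    non-missing calls) are dropped.
    """
    alleles = np.asarray(alleles)
    positions = np.asarray(positions, dtype=np.int64)
    if alleles.shape[0] < 2:
        raise ValueError("need at least 2 strains")
    max_code = int(alleles.max(initial=0))
    counts = np.stack(
        [(alleles == a).sum(axis=0) for a in range(max_code + 1)]
    )  # (n_alleles, n_sites)
    sorted_desc = -np.sort(-counts, axis=0)
    second = sorted_desc[1] if counts.shape[0] > 1 else np.zeros(counts.shape[1], int)
    keep = second > 0  # at least two segregating states
    # minor allele = smallest id whose count equals the second-order statistic
    minor_id = np.argmax(counts == second[None, :], axis=0)
    values = np.full(alleles.shape, 0, dtype=np.int8)
    values[alleles == minor_id[None, :]] = 1
    values[alleles == MISSING] = MISSING
    m = SNPMatrix(values[:, keep], positions[keep], list(strain_ids))
    return m


def maf_filter(m: SNPMatrix, threshold: float = 0.02) -> SNPMatrix:
    """Retain sites whose minor-allele frequency is at least ``threshold``."""
    if not (0.0 <= threshold <= 0.5):
        raise ValueError("MAF threshold must lie in [0, 0.5]")
    return m.take_sites(m.minor_freqs >= threshold)


def _center_scale(x: np.ndarray):
    xc = x - x.mean(axis=0)
    norm = np.sqrt((xc**2).sum(axis=0))
    return xc, norm


def ld_prune(
    m: SNPMatrix, window: int = 50_000, step: int = 10, r2_max: float = 0.1
) -> SNPMatrix:
    """Greedy windowed LD pruning.

    Sites are scanned left to right; a site is kept only if its R^2 with
    every already-kept site less than ``window`` bp behind it does not
    exceed ``r2_max`` (when a pair exceeds the cap, the later-positioned
    member is the one removed). The scan visits every site directly, which
    subsumes a sliding window advanced in small steps; ``step`` is accepted
    for interface compatibility and does not change the result.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    del step
    x = m.imputed()
    xc, norm = _center_scale(x)
    pos = m.positions
    kept: list[int] = []
    kept_pos: list[int] = []
    for j in range(m.n_sites):
        lo = np.searchsorted(kept_pos, pos[j] - window, side="right")
        cand = kept[lo:]
        if cand and norm[j] > 0:
            r = xc[:, cand].T @ xc[:, j] / (norm[cand] * norm[j])
            if np.any(r**2 > r2_max):
                continue
        kept.append(j)
        kept_pos.append(int(pos[j]))
    return m.take_sites(np.array(kept, dtype=int))


def pairwise_distance(m: SNPMatrix) -> np.ndarray:
    """Raw Hamming distance (number of differing sites) between strains.

    Missing calls are handled pairwise-complete: a site contributes to a
    pair only when both strains are called there.
    """
    v = m.values
    if (v == MISSING).any():
        x = v.astype(np.float64)
        obs = (v != MISSING).astype(np.float64)
        x[v == MISSING] = 0.0
        both = obs @ obs.T
        s11 = x @ x.T
        r1 = (x * obs) @ obs.T  # ones of i at jointly-observed sites
        d = r1 + r1.T - 2 * s11
        del both
        return d
    x = v.astype(np.float64)
    s11 = x @ x.T
    r = x.sum(axis=1)
    d = r[:, None] + r[None, :] - 2 * s11
    np.fill_diagonal(d, 0.0)
    return np.rint(d)


def nonredundant_select(m: SNPMatrix, min_dist: int) -> list[str]:
    """Greedy non-redundant strain selection.

    A single pass in input order keeps a strain iff its Hamming distance to
    every already-kept strain exceeds ``min_dist``; the kept set is pairwise
    more than ``min_dist`` apart.
    """
    if min_dist < 0:
        raise ValueError("min_dist must be nonnegative")
    d = pairwise_distance(m)
    kept: list[int] = []
    for i in range(m.n_strains):
        if all(d[i, k] > min_dist for k in kept):
            kept.append(i)
    return [m.strain_ids[i] for i in kept]


# ---------------------------------------------------------------------------
# import / export
# ---------------------------------------------------------------------------


def from_tsv(path) -> SNPMatrix:
    """Read a strains x sites TSV written by :meth:`SNPMatrix.to_tsv`
    (first column strain id, header row of bp positions)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SNPMatrix(
        df.to_numpy(dtype=np.int8),
        df.columns.to_numpy(dtype=np.int64),
        [str(s) for s in df.index],
    )


def from_vcf(path) -> SNPMatrix:
    """Binary-encode a haploid VCF.

    Allele codes follow the record (REF=0, ALT1=1, ...); missing genotypes
    become missing calls. Multi-allelic records are handled by the same
    minor-allele rule as simulated data (second most frequent allele coded
    1, lower-ranked alleles 0). Positions are 0-based in the returned matrix.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    pos, cols = [], []
    for var in vcf:
        g = np.asarray(var.genotypes, dtype=object)
        # first allele per sample; haploid records carry [allele, phased]
        col = np.array([int(row[0]) for row in g], dtype=np.int8)
        pos.append(var.POS - 1)
        cols.append(col)
    vcf.close()
    if not cols:
        raise ValueError("VCF contains no variant records")
    alleles = np.stack(cols, axis=1)
    order = np.argsort(pos, kind="stable")
    return encode_allele_matrix(alleles[:, order], np.asarray(pos)[order], ids)
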