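"""End-to-end scenario pipelines: simulate, encode, filter, diagnose, report.

`run_pipeline` drives one scenario through the full diagnostic stack —
binary encoding, MAF filtering, LD pruning, PCA and per-variant loadings,
the half-matching trio, LD decay and block clustering, neighbor-joining
tree and backbone score — and writes both the exchange TSVs and a single
machine-readable JSON report. Reports are deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .halfmatch import half_genome_test, half_strain_test, partial_variants_test, window_max_loading
from .ldblocks import cluster_blocks, high_loading_ld, ld_decay
from .pca import run_pca, variant_loadings
from .simulate import ScenarioSpec, SimOutput, run_scenario, write_outputs
from .snpmatrix import (
    SNPMatrix,
    encode_binary,
    ld_prune,
    maf_filter,
    nonredundant_select,
    pairwise_distance,
)
from .treekit import backbone_score, nj_tree, write_newick

__all__ = ["PipelineConfig", "DiagnosticParams", "run_pipeline", "compare_runs", "load_report"]

REPORT_VERSION = 1


@dataclass
class DiagnosticParams:
    """Diagnostic-stage knobs; defaults scale with the preset."""

    maf: float = 0.02
    prune_window: int = 50_000
    r2_max: float = 0.1
    decay_max_dist: int = 30_000
    decay_bin: int = 10
    halfmatch_window: int = 50_000
    n_perm: int = 200
    alpha: float = 0.01
    n_blocks: int = 8
    high_loading_quantile: float = 0.995
    tree_max_strains: int = 150
    #: clonal-relative removal before half-matching: greedy selection of
    #: strains with pairwise Hamming distance above this many SNPs; set to
    #: half the expected pairwise diversity, N x u_genome
    nonredundant_min_dist: int = 2_000

    @classmethod
    def for_preset(cls, preset: str, spec: ScenarioSpec) -> "DiagnosticParams":
        min_dist = max(
            1, int(spec.pop_size * spec.mutation_rate * spec.genome_length)
        )
        if preset == "paper":
            return cls(nonredundant_min_dist=min_dist)
        # desk preset: shrink bp windows by the genome-length ratio so that
        # window/genome proportions match the full-scale analysis
        ratio = spec.genome_length / 1_000_000
        return cls(
            prune_window=max(200, int(50_000 * ratio)),
            decay_max_dist=max(100, int(30_000 * ratio)),
            halfmatch_window=max(200, int(50_000 * ratio)),
            nonredundant_min_dist=min_dist,
        )


@dataclass
class PipelineConfig:
    spec: ScenarioSpec
    out_dir: Path | str = "ecocline_run"
    preset: str = "desk"
    run_pca: bool = True
    run_halfmatch: bool = True
    run_ld: bool = True
    run_tree: bool = True
    diagnostics: DiagnosticParams | None = None

    def __post_init__(self):
        if self.preset not in ("desk", "paper"):
            raise ValueError("preset must be 'desk' or 'paper'")
        if self.diagnostics is None:
            self.diagnostics = DiagnosticParams.for_preset(self.preset, self.spec)


def _spec_hash(spec: ScenarioSpec) -> str:
    blob = json.dumps(spec.asdict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _diagnose(sim: SimOutput, cfg: PipelineConfig, out_dir: Path) -> dict:
    d = cfg.diagnostics
    spec = sim.spec
    report: dict = {}

    full = encode_binary(sim.final_population)
    report["n_strains_total"] = int(full.n_strains)
    traits = sim.trait_values
    maf = maf_filter(full, d.maf)
    report["n_sites_polymorphic"] = int(full.n_sites)
    report["n_sites_maf"] = int(maf.n_sites)
    maf.to_tsv(out_dir / "matrix_maf.tsv")

    pruned = ld_prune(maf, window=d.prune_window, r2_max=d.r2_max)
    report["n_sites_pruned"] = int(pruned.n_sites)

    res = None
    if cfg.run_pca:
        k = min(20, pruned.n_strains - 1, pruned.n_sites)
        res = run_pca(pruned, k=k)
        vl = variant_loadings(res, maf)
        report["pve1"] = float(res.pve[0])
        pc1 = res.strain_loadings[:, 0]
        report["pc1_trait_abs_r"] = (
            float(abs(stats.pearsonr(pc1, traits)[0]))
            if np.std(traits) > 0 and np.std(pc1) > 0
            else 0.0
        )
        sq1 = vl.squared[:, 0]
        report["loading_excess_kurtosis"] = float(stats.kurtosis(vl.loadings[:, 0]))
        wmax = window_max_loading(sq1, maf.positions, d.halfmatch_window)
        report["top_loading_position"] = int(maf.positions[int(np.argmax(sq1))])
        report["top_effect_position"] = int(np.argmax(sim.effects.coefficients))
        pd.DataFrame(
            {
                "strain": res.strain_ids,
                **{f"PC{i+1}": res.strain_loadings[:, i] for i in range(res.strain_loadings.shape[1])},
            }
        ).to_csv(out_dir / "strain_loadings.tsv", sep="\t", index=False)
        vl.to_frame(0).to_csv(out_dir / "variant_loadings_pc1.tsv", sep="\t", index=False)
        pd.DataFrame({"component": np.arange(1, res.pve.size + 1), "pve": res.pve}).to_csv(
            out_dir / "scree.tsv", sep="\t", index=False
        )

    if cfg.run_halfmatch and res is not None:
        rng = np.random.default_rng(spec.seed + 10_000)
        # clonal-relative removal before half-matching, as in the neutral
        # clonal-model protocol (SNP distance above the redundancy cutoff);
        # under the selective scenarios the population is organised into a
        # few internally clonal trait clusters, and distance deduplication
        # would remove the structure under study, so it is skipped there
        hm = maf
        if (
            d.nonredundant_min_dist > 0
            and spec.scenario not in ("selective_uniform", "selective_gamma")
        ):
            kept_ids = nonredundant_select(full, d.nonredundant_min_dist)
            idx = np.array([full.strain_ids.index(s) for s in kept_ids])
            hm = maf_filter(full.take_strains(idx).polymorphic(), d.maf)
        report["n_strains_halfmatch"] = int(hm.n_strains)
        if hm.n_strains < 6 or hm.n_sites < 4:
            report["halfmatch_error"] = (
                "too few non-redundant strains or sites for half-matching"
            )
            report["n_halfmatch_significant"] = 0
            hm = None
    if cfg.run_halfmatch and res is not None and hm is not None:
        hm_res = run_pca(
            ld_prune(hm, window=d.prune_window, r2_max=d.r2_max),
            k=min(2, hm.n_strains - 1),
        )
        # partition by the sign of a preliminary full-data PC1 (stands in
        # for the tree-backbone split used on real data); fall back to a
        # median split if one side is too small
        pc1_hm = hm_res.strain_loadings[:, 0]
        partition = (pc1_hm >= 0).astype(int)
        if min(partition.sum(), (1 - partition).sum()) < 3:
            partition = (pc1_hm >= np.median(pc1_hm)).astype(int)
        hm_kw = dict(
            window=d.halfmatch_window, r2_max=d.r2_max, n_perm=d.n_perm, alpha=d.alpha
        )
        trio = {}
        try:
            hs = half_strain_test(hm, partition, rng=rng, **hm_kw)
            trio["half_strain"] = hs
        except ValueError as err:
            report["half_strain_error"] = str(err)
        try:
            hg = half_genome_test(hm, split=spec.genome_length // 2, rng=rng, **hm_kw)
            trio["half_genome"] = hg
        except ValueError as err:
            report["half_genome_error"] = str(err)
        try:
            pv = partial_variants_test(hm, rng=rng, **hm_kw)
            trio["partial_variants"] = pv
        except ValueError as err:
            report["partial_variants_error"] = str(err)
        for name, rep in trio.items():
            report[f"r_{name}"] = rep.r_forward
            report[f"p_{name}"] = rep.p_forward
            if rep.r_reverse is not None:
                report[f"r_{name}_reverse"] = rep.r_reverse
                report[f"p_{name}_reverse"] = rep.p_reverse
            report[f"significant_{name}"] = rep.significant
        report["n_halfmatch_significant"] = int(
            sum(rep.significant for rep in trio.values())
        )

    if cfg.run_ld:
        decay = ld_decay(maf, max_dist=d.decay_max_dist, bin_size=d.decay_bin)
        decay.to_csv(out_dir / "ld_decay.tsv", sep="\t", index=False)
        report["ld_mean_r2"] = float(
            (decay["mean_r2"] * decay["n_pairs"]).sum() / decay["n_pairs"].sum()
        ) if len(decay) else float("nan")
        if res is not None:
            sq1 = res.variants.squared[:, 0]
            cutoff = float(np.quantile(sq1, d.high_loading_quantile))
            try:
                summary = high_loading_ld(maf, sq1, cutoff=cutoff)
                nb = min(d.n_blocks, summary.r2_matrix.shape[0])
                summary.blocks = cluster_blocks(
                    summary.r2_matrix, nb, loadings=sq1[sq1 > cutoff]
                )
                pd.DataFrame(
                    {"position": summary.positions, "block": summary.blocks}
                ).to_csv(out_dir / "ld_blocks.tsv", sep="\t", index=False)
                report["n_high_loading_variants"] = int(summary.positions.size)
                report["n_ld_blocks"] = int(np.unique(summary.blocks).size)
            except ValueError as err:
                report["ld_blocks_error"] = str(err)

    if cfg.run_tree:
        stride = max(1, full.n_strains // d.tree_max_strains)
        sub = full.take_strains(np.arange(0, full.n_strains, stride)).polymorphic()
        dist = pairwise_distance(sub)
        tree = nj_tree(dist, ids=sub.strain_ids)
        write_newick(tree, out_dir / "tree.nwk")
        report["backbone_score"] = float(backbone_score(tree))
        report["n_tree_strains"] = int(sub.n_strains)

    return report


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run one configured scenario end to end; returns the run directory.

    The directory holds the simulator exchange TSVs, diagnostic TSVs, a
    Newick tree and ``report.json``. Identical configurations (including
    the scenario seed) produce byte-identical reports.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        sim = run_scenario(cfg.spec)
        write_outputs(sim, out_dir)
        stage = "diagnose"
        report = _diagnose(sim, cfg, out_dir)
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err
    report.update(
        {
            "report_version": REPORT_VERSION,
            "package_version": __version__,
            "scenario": cfg.spec.scenario,
            "preset": cfg.preset,
            "seed": cfg.spec.seed,
            "spec_hash": _spec_hash(cfg.spec),
            "spec": cfg.spec.asdict(),
        }
    )
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return out_dir


def load_report(run_dir) -> dict:
    return json.loads((Path(run_dir) / "report.json").read_text())


COMPARE_FIELDS = [
    "scenario",
    "seed",
    "pve1",
    "backbone_score",
    "r_half_strain",
    "r_half_genome",
    "r_partial_variants",
    "n_halfmatch_significant",
    "pc1_trait_abs_r",
    "loading_excess_kurtosis",
]


def compare_runs(reports: list[dict]) -> pd.DataFrame:
    """Tabulate the headline diagnostics of two or more run reports."""
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to compare")
    versions = {r.get("report_version") for r in reports}
    if len(versions) != 1:
        raise ValueError("reports have mismatching schema versions")
    rows = [{f: r.get(f) for f in COMPARE_FIELDS} for r in reports]
    return pd.DataFrame(rows)
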