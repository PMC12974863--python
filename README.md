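# ecocline

Forward-time simulation and population-genomic diagnostics for
**selection-driven clines in recombining bacterial populations**.

Phylogenies of globally sampled *Klebsiella pneumoniae* (and some other
bacteria) show a *backbone*: a single connected path of branches carrying a
large fraction of the tree's internal branch length, mirrored by a first
principal component (PC1) that explains an outsized share of genetic
variation. `ecocline` is a toolkit for asking what evolutionary forces can
generate that pattern. It provides:

* a **non-Wright–Fisher forward simulator** of haploid genomes with
  per-generation horizontal gene transfer (HGT) of fixed-length tracts,
  under six scenarios: neutral panmixia, a linear stepping-stone chain,
  recombination hotspots, strain-level mutation-rate heterogeneity, and
  diversifying selection on an additive polygenic trait with uniform or
  Gamma-distributed per-site effects — the trait score is
  `sum(c_i over m1) - sum(c_j over m2)` and fitness is
  `2 + A·|score-mu|^k / (max|score-mu|^k + 1e-6)`, favouring both tails;
* the **diagnostic stack** used to interrogate real or simulated data:
  binary minor-allele SNP matrices with MAF filtering and windowed LD
  pruning, PCA with strain loadings (eigenvectors scaled by sqrt
  eigenvalues) and per-variant loadings (strain loadings multiplied into
  the MAF-filtered matrix), three half-matching reproducibility tests for
  PC1, LD decay curves and R² block clustering of high-loading variants,
  and neighbor-joining trees with a quantitative **backbone score** (the
  best single path's share of total internal branch length).

It is aimed at microbial population geneticists who want to reproduce the
ecocline argument end to end at desk scale, or to run the same diagnostics
on their own strain × SNP matrices (TSV or haploid VCF import).

## Worked example

Run the desk-scale preset (N = 500, 100 kb genome, 2,000 generations,
selection from generation 1,001) for a neutral and a selective scenario and
compare them:

```bash
ecocline pipeline --scenario neutral           --seed 103 --out runs/neutral
ecocline pipeline --scenario selective_uniform --seed 103 --out runs/selective
ecocline compare runs/neutral runs/selective --out runs/comparison.tsv
```

The two pipeline invocations print

```
pve1=0.0810 backbone=0.0794 halfmatch_significant=1/3
pve1=0.1324 backbone=0.1245 halfmatch_significant=3/3
```

Read: under neutrality PC1 explains 8.1% of variation, the best internal
path carries 7.9% of internal branch length, and only one of the three PC1
reproducibility tests (half-strain, half-genome, partial-variants) beats
its permutation null. Under diversifying selection on the same per-genome
mutation and recombination rates, PC1's share grows, the backbone
strengthens, all three half-matching tests become significant — and in
`runs/selective/report.json` the correlation between PC1 and the true
simulated trait is `pc1_trait_abs_r = 0.972`, versus `0.300` for the
neutral run. Each run directory also holds the binary SNP matrix, trait and
effect tables, per-variant PC1 loadings, LD decay curve and block
assignments, and a Newick tree.

The same diagnostics run on imported data:

```bash
ecocline diagnose --matrix strains.vcf --out diag/
ecocline halfmatch --matrix matrix.tsv --test genome --split 2600000 --out hm.tsv
```

Python API mirroring the CLI:

```python
from ecocline import desk_spec, run_scenario, encode_binary, maf_filter, ld_prune, run_pca

sim = run_scenario(desk_spec("selective_gamma", seed=1))
m = ld_prune(maf_filter(encode_binary(sim.final_population), 0.02), window=5_000)
res = run_pca(m, k=10)
print(res.pve[0])
```

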