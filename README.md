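# orthotraits

Comparative-genomics statistics for true bugs (Heteroptera) — and for any
clade where you want to ask the same questions: how trustworthy are your
predicted gene models, are expanded gene families arranged in tandem
arrays, which orthogroups form a shared "toolkit" across trait groups, how
do chromosomes map between assemblies, and does a continuous trait such as
genome size track diet once phylogeny is accounted for.

The package grew out of the analysis needs of an insect-pest genome
project (the cotton seed bug, a lygaeid pest of cotton), where each of
these questions had to be answered with small bespoke computations around
standard tools (DIAMOND, OrthoFinder, BUSCO, CAFE). `orthotraits` turns
those computations into a tested, reusable library with a CLI.

## What it computes

**Gene-model tiers.** Predicted proteins (length-bounded to 100–6,000 aa)
are classified by homology evidence into *gold* (query ≥ 150 aa, a
single-HSP hit to a subject ≥ 150 aa with ≥ 75% positive residues covering
≥ 90% of the subject), *silver* (query ≥ 100 aa, hit covering ≥ 75% of a
subject ≥ 100 aa), *bronze* (any hit covering ≥ 30% of its subject), or
*non-podium*. Coverage is the subject-aligned span over the subject
length.

**Gene clusters.** Genes within 35 kbp of a neighbour on the same sequence
(bedtools `merge -d` semantics, transitive chains) form clusters — a proxy
for tandem duplication. Summaries report #single / #clustered and cluster
sizes, per pooled expanded-orthogroup sets or per gene family.

**Orthogroup sets.** Core sets ("present in every member of a group"),
their 4-set Venn decomposition, and focal-taxon combination tallies.

**Synteny links.** BUSCOs complete and single-copy in two assemblies,
joined on id, with chromosome-level contingency counts.

**Phylogenetic comparative battery.** For a trait *x* on a rooted tree
with shared-path covariance **C** (tips are multivariate normal with
covariance σ²**C** under Brownian motion):

- Blomberg's *K* = (MSE₀/MSE) / E₀[MSE₀/MSE], permutation *p*;
- Pagel's λ by ML over **C**(λ) (off-diagonal scaling), LR test vs λ = 0;
- BM1 and single-optimum OU1 fits by ML (σ², z₀ or θ, α), compared by
  AIC = 2k − 2 ln L;
- PGLS: β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹x with V = **C**(λ̂), λ̂ by ML;
- simulation-based phylogenetic ANOVA (observed F referred to a BM null);
- Grafen branch lengths for topology-only trees;
- plain pooled/Welch t and Wilcoxon rank-sum baselines.

A seeded synthetic-data module generates every input dialect with planted
ground truth (tandem arrays, tier-exact hit tables, core/exclusive
orthogroup structure, BM/OU traits on random ultrametric trees), so the
whole pipeline is testable end to end without any external download.

## Worked example

Generate a synthetic dataset and run the phylogenetic battery on it:

```sh
orthotraits simulate --out-dir demo --seed 42
orthotraits physig   --tree demo/tree.nwk --traits demo/traits.tsv \
                     --n-perm 999 --seed 42 --out demo/sig.json
orthotraits fitmodels --tree demo/tree.nwk --traits demo/traits.tsv \
                      --out demo/models.json
orthotraits clusters --genes demo/genes.bed --out demo/clusters.bed \
                     --summary demo/summary.tsv
```

`demo/sig.json` (trait simulated under Brownian motion on a 128-tip tree,
rescaled to genome-size units):

```json
{
  "K": 1.0860888982455166,
  "p_K": 0.001,
  "lambda": 0.9997556691706635,
  "p_lambda": 2.3122666625705112e-24
}
```

*K* ≈ 1 and λ ≈ 1 say exactly what they should for BM data: relatives
resemble each other as much as Brownian evolution predicts, and the
permutation/LR tests reject the no-signal null. `demo/models.json` shows
the AIC comparison preferring the generating model (BM1 5007.35 vs OU1
5009.35 — the OU fit collapses to α ≈ 0 and pays a parameter penalty), and
`demo/summary.tsv`

```
n_single  n_clustered  ratio   largest_cluster_size  average_cluster_size
20        20           1.0000  10                    5.00
```

recovers the planted layout: 20 singleton genes and 20 genes inside the
four planted arrays (sizes 2, 3, 5, 10), every gap inside an array below
35 kbp and every gap between units above it.

The same subcommands run on real data: `podium` on a DIAMOND tabular file
plus a protein-length table, `clusters` on a BED/GFF3 gene table,
`orthosets` on an OrthoFinder `Orthogroups.tsv`, `synteny` on two BUSCO
`full_table.tsv` files, and `physig`/`pgls`/`phyloanova`/`fitmodels` on a
Newick tree plus a taxon–trait TSV.

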