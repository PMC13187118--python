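# Methods notes

This note documents the models and procedures implemented in
`orthotraits`, the defaults and why they were chosen, what the synthetic
data do and do not emulate, and the numerical choices that matter for
reproducibility.

## Coordinate and format conventions

All gene intervals are held 0-based half-open (BED convention) regardless
of source dialect; GFF3 and 1-based TSV tables are converted on read and
back-converted on GFF3 write. This makes the inter-gene gap used by the
clustering rule an exact integer subtraction (`next.start − max_end`) with
no off-by-one ambiguity. Protein alignment coordinates stay 1-based
inclusive, as emitted by BLAST/DIAMOND; subject coverage is
`(send − sstart + 1) / slen`. Strand is parsed and carried but used by no
computation — every procedure here is strand-agnostic.

Hit tables must supply query/subject lengths and percent-positives
(`qlen`, `slen`, `ppos`), which are not part of the default BLAST outfmt-6
column set; the column layout is therefore explicit configuration with a
documented default order (`qseqid sseqid qlen slen length ppos sstart
send`). No e-value filter is applied by default: tiering is driven by
coverage and positives, and any pre-filtering is left to the search tool.

## Gene-model tiering

A gene's tier is the best tier earned by any *single* hit, with hits from
all reference databases pooled. Two readings of the published rules had to
be fixed:

- "single high-scoring segment pair" is taken literally: the qualifying
  query–subject pair must have exactly one HSP in the table
  (`n_hsps_for_pair == 1`). Multi-HSP pairs can assemble inflated
  coverage from fragments, which is precisely what the gold tier is meant
  to exclude.
- the "hit length to subject length ratio" uses the subject-aligned span,
  not alignment columns; gapped columns would overcount coverage.

The supporting subject is deterministic: highest subject coverage among
qualifying hits, ties broken lexicographically on subject id. The tier
assignment is provably monotone — improving any single attribute of a hit
(positives, coverage, subject length at fixed coverage, collapsing a
multi-HSP pair) can never demote a gene — and this is exercised as a
property test with 10,000 random perturbations.

The published silver-tranche percentage is a truncation of the exact
fraction (12,468/75,783 = 16.452%, printed as 16.4); the report code
rounds, and the tests assert the exact fraction.

## Gene clusters

Clustering follows bedtools `merge -d` semantics: per sequence, sort by
start, keep a running maximum end, and open a new cluster when the gap to
the next start exceeds `max_gap` (35,000 bp by default, the conventional
window for tandem arrays in hemipteran comparative work). The rule is
transitive — chains merge even when their ends are far apart — and
overlap counts as gap ≤ 0. Equivalence with an O(n²)
connected-components oracle over the interval-proximity graph is asserted
on 1,000 random tables.

`ratio` is singleton genes over genes inside size-≥2 clusters and
`average_cluster_size` averages only size-≥2 clusters: published per-taxon
minima of the average (≈ 2.4) are only possible under that convention.
Two modes are exposed because the two published analyses differ: the
expanded-orthogroup analysis pools genes across orthogroups before
clustering, whereas gene-family reports cluster each family independently.

## Orthogroup set analysis

"Present" means ≥ 1 gene copy; no higher floor is used anywhere. Group
cores are intersections over member taxa ("at least one sequence from each
taxon of the group"), so adding a taxon to a group can only shrink its
core (antitone; property-tested). Exclusive regions come solely from the
4-set Venn decomposition of the cores. Taxa with omnivorous or
hematophagous diets are excluded from diet groups but retained in
infraorder groups.

## Synteny links

"Single-copy" is operationalised as BUSCO status `Complete` with exactly
one record: `Duplicated` ids (which appear as multiple rows) are excluded
in either assembly, as are `Fragmented` and `Missing`. The tested artifact
is the link table and its chromosome contingency matrix; ribbon-plot
rendering is display-side and deliberately out of contract.

## Phylogenetic comparative methods

All methods run on the shared-path covariance **C** (C_ij = depth of the
MRCA of tips i and j), assembled in one postorder pass. Zero-length
terminal branches make **C** singular; they are nudged by 10⁻⁹ × tree
height with a warning rather than rejected, since they are almost always
polytomy artifacts.

- **BM1**: ẑ₀ is the GLS mean, σ̂² = rᵀC⁻¹r/n, both analytic; k = 2.
- **OU1**: covariance V_ij = σ²/(2α) · e^(−2α(T−C_ij)) · (1 − e^(−2αC_ij))
  — the single-optimum model with the root at the optimum and
  non-stationary variance, matching the "OU1" model of standard
  trait-evolution software. A stationary-root variant sits behind a flag.
  θ and σ² are profiled analytically; α is optimised on the log scale by
  bounded Brent over [10⁻⁸/T, 100/T] (xatol 10⁻¹⁰), with boundary
  candidates checked explicitly and a warning flag when α̂ hits the upper
  bound. The tree must be ultrametric for this covariance; as α → 0 the
  profiled likelihood converges to BM (checked to < 10⁻⁴ at α = 10⁻⁸).
- **Blomberg's K** uses the MSE₀/MSE ratio against its BM expectation;
  the permutation test shuffles tip values and counts permutations with
  corrected MSE ≤ observed, p = (1 + count)/(1 + n_perm). Permutation
  count defaults to 999 with a mandatory seed; results are bit-identical
  for a given seed.
- **Pagel's λ** scales the off-diagonal of **C**; the search is bounded to
  [0, 1] (golden/Brent, xatol 10⁻⁸) because the input trees are
  ultrametric, where λ > 1 risks losing positive definiteness. Reference
  implementations allow λ slightly above 1; on interior optima the two
  agree (cross-checked against an independent R implementation to ~10⁻⁶
  in the suite). p comes from χ²₁ on the LR against λ = 0.
- **PGLS** estimates λ jointly by ML, then reports coefficient t-tests at
  df = n − p with σ̂² = RSS/(n − p). R² is the GLS-residual version
  relative to an intercept-only GLS fit under the same V — reference
  packages do not print their definition, so this is a documented
  convention choice, and the model p-value is the matching F test.
  Categorical predictors are dummy-coded against the alphabetically first
  level.
- **Phylogenetic ANOVA** refers the ordinary one-way F statistic to a null
  built by simulating BM on the tree with (ẑ₀, σ̂²) estimated from the
  data; p = (1 + #{F_sim ≥ F_obs})/(1 + n_sim), n_sim = 1000 by default,
  seed mandatory. On a star tree this reproduces the parametric ANOVA p;
  on clade-aligned groups the parametric test is anticonservative relative
  to it (both property-tested).
- No multiple-testing correction is applied anywhere, matching how these
  batteries are conventionally reported.

## Synthetic data: what it emulates, what it does not

Generators are deterministic under a seed (NumPy PCG64 seeded with
`(seed, salt)` tuples, one salt per generator) and write truth sidecars in
JSON next to every emitted file.

- *Gene tables* plant arrays with intra-array gaps drawn ≤ 35 kbp and
  inter-unit gaps > 35 kbp, so the planted partition is exactly the
  clustering answer. Real genomes have no such guarantee band around the
  threshold; passing recovery tests show correctness of the rule, not
  robustness of the 35-kbp choice.
- *Hit tables* are engineered per gene to satisfy its target tier and fail
  every higher tier through one randomly chosen violated condition. All
  query lengths are ≥ 100 aa because the length filter precedes tiering in
  the real pipeline. Real hit tables carry e-values, taxonomy and multiple
  subjects per query in ways not modelled here.
- *Orthogroup matrices* use four **disjoint** taxon groups so that every
  Venn region is feasible and exactly recoverable. The real study's diet
  and infraorder groups overlap in taxa, which constrains which regions
  can be non-empty; the set operations themselves are unaffected.
- *Trees* come from random sequential coalescence scaled to a fixed
  height — shape-agnostic by intent, since the study's trees come from
  inference, not from a birth–death process. Traits evolve by exact BM or
  OU transition densities (no Euler discretisation), so estimator-recovery
  tests carry no simulation bias. Emitted genome spans are an affine map
  of the simulated trait onto a realistic ~1.5 Gbp scale; BM/OU are closed
  under affine maps, so signal statistics are unchanged and σ² scales by
  the squared factor.

## Problem sizes and runtime

The Monte-Carlo recovery suite runs 200 replicates on a 128-tip height-1
tree for BM (K, λ, σ², AIC preference) and OU (α recovery, AIC
preference), a size at which the estimators' sampling error is well inside
the asserted bands; the full suite plus the acceptance script completes in
well under a minute on a single CPU.

## Known limitations

- OU fitting assumes ultrametry; non-ultrametric trees are rejected rather
  than approximated.
- Single-optimum OU only; multi-regime (OUM-style) models are out of
  scope, as are divergence-time estimation and tree inference.
- The λ search cap at 1 means traits with genuinely super-λ structure
  (rare, and impossible under the generating models used here) report
  λ̂ = 1.
- The permutation and simulation p-values are Monte-Carlo estimates with
  the usual (1+count)/(1+n) granularity; raise `n_perm`/`n_sim` for finer
  resolution.
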