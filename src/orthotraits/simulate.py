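"""Seeded generators for every input the pipeline consumes.

Each generator plants known structure — tandem gene arrays separated by sub-
and supra-threshold gaps, hit tables engineered to land in an exact quality
tier, orthogroup matrices with known core/exclusive membership, ultrametric
trees with traits evolved under BM or OU — and returns the ground truth next
to the data, so recovery tests can assert exact agreement.

All generators are deterministic given a seed (NumPy PCG64 integer-state
contract) and all emulate the file dialects of real annotation pipelines.
OU traits use the exact transition density (no Euler discretisation), so
estimator-recovery checks carry no simulation bias.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .tree import Phylogeny
from .types import BuscoRecord, GeneInterval, HitRecord, OrthoMatrix

import pandas as pd

DEFAULT_TIER_MIX = {
    "gold": 100,
    "silver": 100,
    "bronze": 100,
    "non_podium_hit": 50,
    "non_podium_nohit": 50,
}


@dataclass
class SynthSpec:
    """Parameters of the synthetic study conditions.

    Defaults mirror the kind of data the pipeline was designed around: gene
    arrays well inside / well outside the 35-kbp clustering window, a
    hit-table mix covering every tier and both non-podium cases, a modest
    orthogroup universe with all Venn regions populated, and a 128-tip
    height-1 ultrametric tree with unit-rate BM (or OU with pull 2).
    """

    seed: int = 0
    # gene tables
    n_chromosomes: int = 3
    chromosome_length: int = 5_000_000
    n_singletons: int = 20
    cluster_sizes: tuple[int, ...] = (2, 3, 5, 10)
    intra_gap: int = 10_000
    inter_gap: int = 100_000
    gene_length: int = 2_000
    # hit tables
    tier_mix: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_TIER_MIX))
    # orthogroup matrices
    taxa_per_group: int = 2
    ogs_per_region: int = 3
    ogs_outside: int = 5
    # tree and traits
    n_tips: int = 128
    tree_height: float = 1.0
    trait_model: str = "BM"  # "BM" or "OU"
    sigma2: float = 1.0
    alpha: float = 2.0
    theta: float = 0.0
    z0: float = 0.0
    group_offset: float = 0.0
    # affine map applied when emitting the trait as a genome span in bp
    # (heteropteran assemblies are of order 1 Gbp); BM/OU are closed under
    # affine maps, so signal statistics are unchanged and sigma^2 scales
    # by trait_scale^2
    trait_scale: float = 1e8
    trait_offset: float = 1.5e9

    def __post_init__(self):
        if self.intra_gap > 35_000 or self.inter_gap <= 35_000:
            raise ValidationError(
                "planted layout needs intra_gap <= 35000 < inter_gap"
            )
        if min(self.cluster_sizes, default=2) < 2:
            raise ValidationError("planted clusters must have size >= 2")
        if self.trait_model not in ("BM", "OU"):
            raise ValidationError("trait_model must be BM or OU")
        if self.sigma2 < 0 or self.alpha <= 0 or self.n_tips < 2:
            raise ValidationError("bad trait-model parameters")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))


# ----------------------------------------------------------------- gene table
def gen_gene_table(spec: SynthSpec) -> tuple[list[GeneInterval], list[list[str]]]:
    """Genes laid out so clustering at 35 kbp recovers the planted arrays.

    Returns (genes, truth) where truth lists the member gene ids of every
    planted unit (arrays and singletons; singletons are 1-element lists).
    """
    rng = spec.rng(1)
    units: list[int] = list(spec.cluster_sizes) + [1] * spec.n_singletons
    order = rng.permutation(len(units))
    cursors = [0] * spec.n_chromosomes
    genes: list[GeneInterval] = []
    truth: list[list[str]] = []
    gid = 0
    for k, unit_idx in enumerate(order):
        size = units[unit_idx]
        chrom = k % spec.n_chromosomes
        pos = cursors[chrom]
        members = []
        for j in range(size):
            start = pos
            end = start + spec.gene_length
            name = f"g{gid:05d}"
            gid += 1
            genes.append(GeneInterval(name, f"chr{chrom + 1}", start, end))
            members.append(name)
            pos = end + (int(rng.integers(1, spec.intra_gap + 1)) if j < size - 1 else 0)
        cursors[chrom] = pos + spec.inter_gap
        if cursors[chrom] > spec.chromosome_length:
            raise ValidationError(
                "infeasible layout: chromosome too short for the planted units"
            )
        truth.append(members)
    return genes, truth


# ------------------------------------------------------------------ hit table
def _span_for_coverage(
    rng: np.random.Generator, slen: int, lo: float, hi: float
) -> tuple[int, int]:
    """An integer subject span whose coverage lies in [lo, hi]."""
    span_min = max(1, math.ceil(lo * slen))
    span_max = min(slen, math.floor(hi * slen))
    if span_min > span_max:
        raise ValidationError(f"no integer span with coverage in [{lo}, {hi}] for slen={slen}")
    span = int(rng.integers(span_min, span_max + 1))
    start = int(rng.integers(1, slen - span + 2))
    return start, start + span - 1


def gen_hit_table(
    spec: SynthSpec,
) -> tuple[list[HitRecord], dict[str, int], dict[str, str]]:
    """Hit tables engineered so classification reproduces the planted tiers.

    For every gene the hits satisfy exactly the target tier and provably
    fail all higher tiers (silver genes fail gold through a randomly chosen
    single violated condition, and so on).  Returns
    (hits, query lengths, truth tier per gene).
    """
    rng = spec.rng(2)
    hits: list[HitRecord] = []
    lengths: dict[str, int] = {}
    truth: dict[str, str] = {}
    dbs = ("nr", "sprot", "trembl")
    gid = 0
    for tier, count in spec.tier_mix.items():
        for _ in range(count):
            gene = f"q{gid:05d}"
            gid += 1
            db = dbs[int(rng.integers(0, len(dbs)))]
            if tier == "gold":
                qlen = int(rng.integers(150, 1001))
                slen = int(rng.integers(150, 1001))
                ppos = float(rng.uniform(75.0, 99.9))
                s, e = _span_for_coverage(rng, slen, 0.90, 1.0)
                hits.append(
                    HitRecord(gene, f"ref_{gene}", qlen, slen, e - s + 1, round(ppos, 1), s, e, 1, db)
                )
                truth[gene] = "gold"
            elif tier == "silver":
                # pass silver, fail gold by exactly one randomly chosen condition
                mode = ("short_query", "short_subject", "low_ppos", "low_coverage", "two_hsps")[
                    int(rng.integers(0, 5))
                ]
                qlen = int(rng.integers(100, 150) if mode == "short_query" else rng.integers(150, 1001))
                slen = int(rng.integers(100, 150) if mode == "short_subject" else rng.integers(150, 1001))
                ppos = float(rng.uniform(20.0, 74.9) if mode == "low_ppos" else rng.uniform(75.0, 99.9))
                cov_hi = 0.89 if mode == "low_coverage" else 1.0
                s, e = _span_for_coverage(rng, slen, 0.75, cov_hi)
                if mode == "low_coverage" and (e - s + 1) / slen >= 0.90:
                    e = s + math.floor(0.89 * slen) - 1  # guard integer rounding
                n_hsps = 2 if mode == "two_hsps" else 1
                rec = HitRecord(
                    gene, f"ref_{gene}", qlen, slen, e - s + 1, round(ppos, 1), s, e, n_hsps, db
                )
                hits.append(rec)
                if mode == "two_hsps":
                    # second, much weaker HSP of the same pair
                    s2, e2 = _span_for_coverage(rng, slen, 0.05, 0.25)
                    hits.append(
                        HitRecord(gene, f"ref_{gene}", qlen, slen, e2 - s2 + 1, round(ppos, 1), s2, e2, 2, db)
                    )
                truth[gene] = "silver"
            elif tier == "bronze":
                # queries kept >= 100 aa (the length filter runs first in the
                # pipeline), so bronze fails silver through coverage alone
                qlen = int(rng.integers(100, 1001))
                slen = int(rng.integers(100, 1001))
                s, e = _span_for_coverage(rng, slen, 0.30, 0.74)
                if (e - s + 1) / slen >= 0.75:
                    e = s + math.floor(0.74 * slen) - 1
                ppos = float(rng.uniform(20.0, 99.9))
                hits.append(
                    HitRecord(gene, f"ref_{gene}", qlen, slen, e - s + 1, round(ppos, 1), s, e, 1, db)
                )
                truth[gene] = "bronze"
            elif tier == "non_podium_hit":
                qlen = int(rng.integers(100, 1001))
                slen = int(rng.integers(200, 1001))
                s, e = _span_for_coverage(rng, slen, 0.05, 0.29)
                if (e - s + 1) / slen >= 0.30:
                    e = s + math.floor(0.29 * slen) - 1
                ppos = float(rng.uniform(20.0, 99.9))
                hits.append(
                    HitRecord(gene, f"ref_{gene}", qlen, slen, e - s + 1, round(ppos, 1), s, e, 1, db)
                )
                truth[gene] = "non_podium"
            elif tier == "non_podium_nohit":
                qlen = int(rng.integers(100, 1001))
                truth[gene] = "non_podium"
            else:
                raise ValidationError(f"unknown tier_mix key {tier!r}")
            lengths[gene] = qlen
    return hits, lengths, truth


# ------------------------------------------------------------- ortho matrices
def gen_orthomatrix(
    spec: SynthSpec,
) -> tuple[OrthoMatrix, dict[str, list[str]], dict[str, frozenset[str]]]:
    """Orthogroup counts with planted core membership in four taxon groups.

    Four disjoint groups of ``taxa_per_group`` taxa each; for every nonempty
    subset of groups, ``ogs_per_region`` orthogroups are planted whose core
    membership is exactly that subset (present in all taxa of in-groups,
    absent from at least one taxon of each out-group), plus ``ogs_outside``
    orthogroups in no core at all.  Returns
    (matrix, group definitions, truth region per orthogroup).
    """
    rng = spec.rng(3)
    group_names = ["predator", "herbivore", "pentatomomorpha", "cimicomorpha"]
    groups = {
        name: [f"{name[:4].upper()}{i + 1}" for i in range(spec.taxa_per_group)]
        for name in group_names
    }
    taxa = [t for members in groups.values() for t in members]
    rows: dict[str, list[int]] = {}
    truth: dict[str, frozenset[str]] = {}
    og_idx = 0
    from itertools import combinations

    regions = [
        frozenset(combo)
        for r in range(1, len(group_names) + 1)
        for combo in combinations(group_names, r)
    ]
    for region in regions:
        for _ in range(spec.ogs_per_region):
            og = f"OG{og_idx:05d}"
            og_idx += 1
            counts = []
            for name in group_names:
                if name in region:
                    counts.extend(int(rng.integers(1, 4)) for _ in groups[name])
                else:
                    # absent from at least one member taxon breaks the core
                    absent = int(rng.integers(0, spec.taxa_per_group))
                    counts.extend(
                        0 if i == absent else int(rng.integers(0, 3))
                        for i in range(spec.taxa_per_group)
                    )
            rows[og] = counts
            truth[og] = region
    for _ in range(spec.ogs_outside):
        og = f"OG{og_idx:05d}"
        og_idx += 1
        counts = []
        first_absent = None
        for gi, name in enumerate(group_names):
            absent = int(rng.integers(0, spec.taxa_per_group))
            if gi == 0:
                first_absent = absent
            counts.extend(
                0 if i == absent else int(rng.integers(0, 3))
                for i in range(spec.taxa_per_group)
            )
        if sum(counts) == 0:
            # keep the row non-empty without completing any group's core:
            # fill one non-designated taxon of the first group
            present = (first_absent + 1) % spec.taxa_per_group
            counts[present] = 1
        rows[og] = counts
        truth[og] = frozenset()
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=taxa).astype(int)
    matrix = OrthoMatrix(frame)
    return matrix, groups, truth


# ---------------------------------------------------------------- tree/traits
def gen_tree(spec: SynthSpec) -> Phylogeny:
    """Random ultrametric tree by sequential pairwise coalescence to a fixed
    height (shape-agnostic: no birth–death model is claimed)."""
    rng = spec.rng(4)
    n = spec.n_tips
    times = np.sort(rng.uniform(0.0, 1.0, size=n - 1))
    times = times / times[-1] * spec.tree_height  # root exactly at tree_height
    # active lineages: (builder node id); heights tracked per builder node
    next_id = 0
    heights: dict[int, float] = {}
    children: dict[int, list[int]] = {}
    labels: dict[int, str | None] = {}
    active: list[int] = []
    for i in range(n):
        heights[next_id] = 0.0
        children[next_id] = []
        labels[next_id] = f"t{i + 1}"
        active.append(next_id)
        next_id += 1
    for t in times:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        heights[next_id] = float(t)
        children[next_id] = [a, b]
        labels[next_id] = None
        active.pop(j)
        active.pop(i)
        active.append(next_id)
        next_id += 1
    root = active[0]
    # flatten to preorder arrays
    order: list[int] = []
    stack = [root]
    while stack:
        node = stack.pop()
        order.append(node)
        stack.extend(reversed(children[node]))
    index = {node: i for i, node in enumerate(order)}
    parent = [-1] * len(order)
    length = [0.0] * len(order)
    labs: list[str | None] = [None] * len(order)
    for node in order:
        labs[index[node]] = labels[node]
        for ch in children[node]:
            parent[index[ch]] = index[node]
            length[index[ch]] = heights[node] - heights[ch]
    return Phylogeny(parent, length, labs)


def simulate_trait(
    tree: Phylogeny, spec: SynthSpec, rng: np.random.Generator | None = None
) -> dict[str, float]:
    """Evolve a trait along the tree under BM or OU (exact transitions)."""
    if rng is None:
        rng = spec.rng(5)
    values = np.zeros(tree.n_nodes)
    values[0] = spec.z0 if spec.trait_model == "BM" else spec.theta
    sigma = math.sqrt(spec.sigma2)
    for i in range(1, tree.n_nodes):
        t = tree.length[i]
        parent_val = values[tree.parent[i]]
        if spec.trait_model == "BM":
            values[i] = parent_val + sigma * math.sqrt(t) * rng.standard_normal()
        else:
            decay = math.exp(-spec.alpha * t)
            mean = spec.theta + (parent_val - spec.theta) * decay
            var = spec.sigma2 * (1.0 - decay * decay) / (2.0 * spec.alpha)
            values[i] = mean + math.sqrt(var) * rng.standard_normal()
    return {tree.labels[i]: float(values[i]) for i in tree.tip_indices}


def gen_tree_and_traits(
    spec: SynthSpec,
) -> tuple[Phylogeny, dict[str, float], dict[str, str], dict]:
    """Tree, trait values, a two-level diet grouping and the truth parameters.

    The "predator" group is the clade whose tip count is closest to half the
    tips; its tip values are shifted by ``group_offset``.
    """
    tree = gen_tree(spec)
    traits = simulate_trait(tree, spec)
    target = tree.n_tips / 2
    best_node, best_dist = None, math.inf
    for i in range(1, tree.n_nodes):
        if tree.is_tip[i]:
            continue
        k = len(tree.clade_tips(i))
        if abs(k - target) < best_dist and k < tree.n_tips:
            best_node, best_dist = i, abs(k - target)
    clade = set(tree.clade_tips(best_node)) if best_node is not None else set()
    groups = {t: ("predator" if t in clade else "herbivore") for t in tree.tip_labels}
    if spec.group_offset:
        traits = {
            t: v + (spec.group_offset if t in clade else 0.0) for t, v in traits.items()
        }
    truth = {
        "model": spec.trait_model,
        "sigma2": spec.sigma2,
        "alpha": spec.alpha if spec.trait_model == "OU" else None,
        "theta": spec.theta if spec.trait_model == "OU" else None,
        "z0": spec.z0 if spec.trait_model == "BM" else None,
        "group_offset": spec.group_offset,
        "offset_group": "predator",
    }
    return tree, traits, groups, truth


# ---------------------------------------------------------------- BUSCO pairs
def gen_busco_pair(
    spec: SynthSpec, n_links: int = 60, split_ways: int = 2
) -> tuple[list[BuscoRecord], list[BuscoRecord], dict]:
    """Two BUSCO tables with a planted chromosome mapping.

    Links from each chromosome of assembly A are split across ``split_ways``
    chromosomes of assembly B; a few Fragmented/Missing/Duplicated entries
    are mixed in, which must not survive the linking step.
    """
    rng = spec.rng(6)
    table_a: list[BuscoRecord] = []
    table_b: list[BuscoRecord] = []
    mapping: dict[str, set[str]] = {}
    for k in range(n_links):
        bid = f"busco{k:04d}"
        chrom_a = f"A{k % spec.n_chromosomes + 1}"
        chrom_b = f"B{(k % spec.n_chromosomes) * split_ways + k % split_ways + 1}"
        sa = int(rng.integers(0, 1_000_000))
        sb = int(rng.integers(0, 1_000_000))
        table_a.append(BuscoRecord(bid, "Complete", chrom_a, sa, sa + 1000))
        table_b.append(BuscoRecord(bid, "Complete", chrom_b, sb, sb + 1000))
        mapping.setdefault(chrom_a, set()).add(chrom_b)
    # records that must be dropped by the single-copy filter
    table_a.append(BuscoRecord("busco_frag", "Fragmented", "A1", 10, 500))
    table_b.append(BuscoRecord("busco_frag", "Complete", "B1", 10, 1000))
    table_a.append(BuscoRecord("busco_dup", "Duplicated", "A1", 100, 1100))
    table_a.append(BuscoRecord("busco_dup", "Duplicated", "A2", 200, 1200))
    table_b.append(BuscoRecord("busco_dup", "Complete", "B1", 300, 1300))
    table_a.append(BuscoRecord("busco_miss", "Missing"))
    table_b.append(BuscoRecord("busco_miss", "Complete", "B2", 400, 1400))
    truth = {
        "n_links": n_links,
        "partners_per_chromosome": {c: sorted(p) for c, p in mapping.items()},
        "split_ways": split_ways,
    }
    return table_a, table_b, truth


# -------------------------------------------------------------------- emitter
def emit_fixtures(spec: SynthSpec, out_dir) -> dict[str, str]:
    """Write every synthetic input plus a truth sidecar JSON per dataset."""
    from . import io as fio

    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}

    genes, gene_truth = gen_gene_table(spec)
    paths["genes"] = os.path.join(out_dir, "genes.bed")
    fio.write_gene_table(genes, paths["genes"], format="bed")
    _dump_json(os.path.join(out_dir, "genes.truth.json"), {"clusters": gene_truth})

    hits, lengths, tier_truth = gen_hit_table(spec)
    paths["hits"] = os.path.join(out_dir, "hits.tsv")
    lines = [
        "\t".join(
            str(v)
            for v in (
                h.query_id, h.subject_id, h.query_len, h.subject_len,
                h.aln_len, h.pct_positives, h.subject_start, h.subject_end,
            )
        )
        for h in hits
    ]
    fio.atomic_write(paths["hits"], "\n".join(lines) + "\n")
    paths["lengths"] = os.path.join(out_dir, "lengths.tsv")
    fio.atomic_write(
        paths["lengths"],
        "\n".join(f"{g}\t{n}" for g, n in lengths.items()) + "\n",
    )
    _dump_json(os.path.join(out_dir, "hits.truth.json"), {"tiers": tier_truth})

    matrix, groups, og_truth = gen_orthomatrix(spec)
    paths["orthogroups"] = os.path.join(out_dir, "Orthogroups.tsv")
    fio.write_orthogroups(matrix, paths["orthogroups"])
    _dump_json(
        os.path.join(out_dir, "orthogroups.truth.json"),
        {
            "groups": groups,
            "regions": {og: sorted(region) for og, region in og_truth.items()},
        },
    )

    tree, traits, diet, trait_truth = gen_tree_and_traits(spec)
    paths["tree"] = os.path.join(out_dir, "tree.nwk")
    fio.write_newick(tree, paths["tree"])
    paths["traits"] = os.path.join(out_dir, "traits.tsv")
    rows = ["taxon\tdiet\tgenome_span"]
    for t in tree.tip_labels:
        span = spec.trait_offset + spec.trait_scale * traits[t]
        if span <= 0:
            raise ValidationError(
                "trait_offset/trait_scale produced a non-positive genome span"
            )
        rows.append(f"{t}\t{diet[t]}\t{span:.10g}")
    fio.atomic_write(paths["traits"], "\n".join(rows) + "\n")
    trait_truth = dict(
        trait_truth, trait_scale=spec.trait_scale, trait_offset=spec.trait_offset
    )
    _dump_json(os.path.join(out_dir, "traits.truth.json"), trait_truth)

    table_a, table_b, busco_truth = gen_busco_pair(spec)
    for tag, table in (("a", table_a), ("b", table_b)):
        paths[f"busco_{tag}"] = os.path.join(out_dir, f"full_table_{tag}.tsv")
        lines = ["# Busco id\tStatus\tSequence\tGene Start\tGene End"]
        for r in table:
            if r.status == "Missing":
                lines.append(f"{r.busco_id}\t{r.status}")
            else:
                lines.append(f"{r.busco_id}\t{r.status}\t{r.seq_id}\t{r.start}\t{r.end}")
        fio.atomic_write(paths[f"busco_{tag}"], "\n".join(lines) + "\n")
    _dump_json(os.path.join(out_dir, "busco.truth.json"), busco_truth)
    return paths


def _dump_json(path, obj) -> None:
    from .io import atomic_write

    atomic_write(path, json.dumps(obj, indent=2, sort_keys=True) + "\n")
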