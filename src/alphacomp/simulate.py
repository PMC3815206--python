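"""Genome-evolution simulator with known ground truth.

Generates a pure-birth species tree and evolves genomes along it: gene
gain/loss/duplication (Poisson per gene per unit branch length), genome
rearrangement (segment inversions and translocations), and amino-acid
sequence divergence whose replacement-target frequencies shift with a
per-lineage GC-bias parameter.  Negative ``gc_bias`` makes substitutions
preferentially leave the GC-rich amino-acid set {G, A, R, P} — the
protein-level footprint of an AT mutation pressure — while positive values
push into it.  Proteins are simulated directly as amino-acid strings; the
compositional statistic downstream is amino-acid-level, so a codon layer
would add nothing testable.

Every dataset is a pure function of :class:`SimulationConfig`, including the
seed: the same config yields byte-identical files from
:func:`write_dataset`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import dendropy
import numpy as np
import yaml

from alphacomp.io_formats import (
    ClusterSet,
    GeneRecord,
    GenomeAnnotation,
    Replicon,
    TaxonomyTable,
    write_clusters,
    write_fasta,
    write_gene_table,
    write_newick,
    write_taxonomy,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
GC_RICH_SET = "GARP"  # codon families GGN, GCN, CGN, CCN
_GC_IDX = np.array([_AA_INDEX[a] for a in GC_RICH_SET])


@dataclass(frozen=True)
class LineageOverride:
    """Per-lineage deviation from the global regime.

    Applied to every branch whose descendant leaves all carry this same
    override — so flagging a whole clade biases its internal edges too,
    while a single flagged taxon biases only its terminal branch.
    """

    gc_bias: float = 0.0
    rate_scale: float = 1.0


@dataclass
class SimulationConfig:
    n_taxa: int = 12
    birth_rate: float = 1.0
    root_gene_count: int = 250
    gain_rate: float = 0.06      # per gene per unit branch length
    loss_rate: float = 0.12
    dup_rate: float = 0.01
    inversion_rate: float = 6.0  # per genome per unit branch length
    translocation_rate: float = 2.0
    subst_rate: float = 0.35     # per-site replacement probability scale
    gc_bias: float = 0.0         # in [-1, 1]; negative = AT-biased
    protein_length_mean: float = 120.0
    protein_length_sd: float = 30.0
    circular: bool = True
    second_replicon: bool = False   # adds a small linear replicon
    seed: int = 0
    lineage_overrides: dict[str, LineageOverride] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            "birth_rate",
            "gain_rate",
            "loss_rate",
            "dup_rate",
            "inversion_rate",
            "translocation_rate",
            "subst_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_taxa < 3:
            raise ValueError("n_taxa must be >= 3")
        if not -1.0 <= self.gc_bias <= 1.0:
            raise ValueError("gc_bias must be in [-1, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        overrides = {
            taxon: LineageOverride(**vals)
            for taxon, vals in (raw.pop("lineage_overrides", {}) or {}).items()
        }
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(lineage_overrides=overrides, **raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["lineage_overrides"] = {
            t: dataclasses.asdict(o) for t, o in self.lineage_overrides.items()
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


@dataclass(frozen=True)
class SimEvent:
    branch: str          # label of the child node the branch leads to
    kind: str            # gain | loss | duplication | inversion | translocation
    detail: tuple


@dataclass
class GroundTruth:
    species_tree: dendropy.Tree
    clusters: ClusterSet
    event_log: list[SimEvent]
    lineage_gc_bias: dict[str, float]


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    annotations: dict[str, GenomeAnnotation]
    proteomes: dict[str, dict[str, str]]       # taxon -> {gene_id: sequence}
    orders: dict[str, list[str]]               # taxon -> gene_ids in genome order
    truth: GroundTruth


# ---------------------------------------------------------------------------
# Species tree (pure-birth / Yule)
# ---------------------------------------------------------------------------

def simulate_species_tree(
    n_taxa: int, birth_rate: float, seed: int
) -> dendropy.Tree:
    """Sample an ultrametric pure-birth tree with ``n_taxa`` leaves.

    The root is the first bifurcation: starting from two lineages, each of
    the k extant lineages splits at rate ``birth_rate``; after the n-th
    lineage appears the process runs for one further exponential waiting
    time so terminal branches are positive.  Expected root-to-tip depth is
    sum_{k=2..n} 1/(k * birth_rate).
    """
    if n_taxa < 3:
        raise ValueError("n_taxa must be >= 3")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7ee]))

    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.is_rooted = True
    # each active node carries its birth time in .birth_time
    active = []
    for _ in range(2):
        child = dendropy.Node()
        child.birth_time = 0.0
        tree.seed_node.add_child(child)
        active.append(child)
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        idx = int(rng.integers(len(active)))
        parent = active.pop(idx)
        parent.edge.length = t - parent.birth_time
        for _ in range(2):
            child = dendropy.Node()
            child.birth_time = t
            parent.add_child(child)
            active.append(child)
    t += rng.exponential(1.0 / (birth_rate * n_taxa))
    width = len(str(n_taxa))
    # deterministic leaf naming in traversal order
    leaves = sorted(active, key=lambda nd: _preorder_index(tree, nd))
    for i, leaf in enumerate(leaves, 1):
        leaf.edge.length = t - leaf.birth_time
        leaf.taxon = taxon_ns.new_taxon(f"t{i:0{width}d}")
    tree.seed_node.edge.length = None
    _label_internal_nodes(tree)
    return tree


def _preorder_index(tree: dendropy.Tree, node: dendropy.Node) -> int:
    for i, nd in enumerate(tree.preorder_node_iter()):
        if nd is node:
            return i
    raise ValueError("node not in tree")


def _label_internal_nodes(tree: dendropy.Tree) -> None:
    k = 0
    for nd in tree.preorder_node_iter():
        if nd.is_internal() and nd.label is None:
            nd.label = f"n{k:03d}"
            k += 1


# ---------------------------------------------------------------------------
# Evolution engine
# ---------------------------------------------------------------------------

class _Gene:
    __slots__ = ("uid", "cluster", "seq")

    def __init__(self, uid: int, cluster: str, seq: np.ndarray):
        self.uid = uid
        self.cluster = cluster
        self.seq = seq

    def copy(self) -> "_Gene":
        return _Gene(self.uid, self.cluster, self.seq.copy())


def _target_weights(gc_bias: float) -> np.ndarray:
    w = np.ones(len(AMINO_ACIDS))
    w[_GC_IDX] *= 1.0 + gc_bias
    return w / w.sum()


def _branch_override(
    node: dendropy.Node,
    overrides: dict[str, LineageOverride],
) -> LineageOverride | None:
    leaves = [lf.taxon.label for lf in node.leaf_iter()]
    vals = {overrides.get(name) for name in leaves}
    if len(vals) == 1 and None not in vals:
        return vals.pop()
    return None


def _sample_length(cfg: SimulationConfig, rng: np.random.Generator) -> int:
    return max(30, int(round(rng.normal(cfg.protein_length_mean, cfg.protein_length_sd))))


def _random_seq(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, len(AMINO_ACIDS), size=length)


def simulate_dataset(
    config: SimulationConfig, tree: dendropy.Tree | None = None
) -> SimulatedDataset:
    """Run the full simulation: tree, content, order, sequences, files-ready."""
    if tree is None:
        tree = simulate_species_tree(config.n_taxa, config.birth_rate, config.seed)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xe7]))
    counter = [0]
    next_cluster = [0]
    events: list[SimEvent] = []

    def new_gene(rng: np.random.Generator, cluster: str | None = None) -> _Gene:
        uid = counter[0]
        counter[0] += 1
        if cluster is None:
            cluster = f"OG{next_cluster[0]:05d}"
            next_cluster[0] += 1
        return _Gene(uid, cluster, _random_seq(_sample_length(config, rng), rng))

    root_genome = [new_gene(rng) for _ in range(config.root_gene_count)]

    leaf_genomes: dict[str, list[_Gene]] = {}
    realized_bias: dict[str, float] = {}

    def evolve_branch(
        genome: list[_Gene], node: dendropy.Node
    ) -> list[_Gene]:
        t = node.edge.length or 0.0
        label = node.taxon.label if node.is_leaf() else node.label
        ov = _branch_override(node, config.lineage_overrides)
        scale = ov.rate_scale if ov else 1.0
        gc_bias = ov.gc_bias if ov else config.gc_bias
        t_eff = t * scale
        genome = [g.copy() for g in genome]

        # losses: each gene survives with prob exp(-loss_rate * t)
        p_loss = 1.0 - np.exp(-config.loss_rate * t_eff)
        if p_loss > 0 and genome:
            keep = rng.random(len(genome)) >= p_loss
            for g, k in zip(genome, keep):
                if not k:
                    events.append(SimEvent(label, "loss", (g.uid, g.cluster)))
            genome = [g for g, k in zip(genome, keep) if k]

        # duplications: tandem copy next to the template, same cluster
        p_dup = 1.0 - np.exp(-config.dup_rate * t_eff)
        if p_dup > 0 and genome:
            dup_flags = rng.random(len(genome)) < p_dup
            out: list[_Gene] = []
            for g, d in zip(genome, dup_flags):
                out.append(g)
                if d:
                    twin = _Gene(counter[0], g.cluster, g.seq.copy())
                    counter[0] += 1
                    out.append(twin)
                    events.append(SimEvent(label, "duplication", (g.uid, twin.uid)))
            genome = out

        # gains: new clusters at random positions
        n_gain = rng.poisson(config.gain_rate * t_eff * max(len(genome), 1))
        for _ in range(n_gain):
            g = new_gene(rng)
            pos = int(rng.integers(len(genome) + 1))
            genome.insert(pos, g)
            events.append(SimEvent(label, "gain", (g.uid, g.cluster)))

        # rearrangements
        n_inv = rng.poisson(config.inversion_rate * t_eff)
        for _ in range(n_inv):
            if len(genome) < 2:
                break
            i, j = sorted(rng.integers(0, len(genome), size=2))
            genome[i : j + 1] = genome[i : j + 1][::-1]
            events.append(SimEvent(label, "inversion", (int(i), int(j))))
        n_tr = rng.poisson(config.translocation_rate * t_eff)
        for _ in range(n_tr):
            if len(genome) < 3:
                break
            i, j = sorted(rng.integers(0, len(genome), size=2))
            seg = genome[i : j + 1]
            rest = genome[:i] + genome[j + 1 :]
            k = int(rng.integers(len(rest) + 1))
            genome = rest[:k] + seg + rest[k:]
            events.append(SimEvent(label, "translocation", (int(i), int(j), k)))

        # substitutions with GC-bias on replacement targets
        p_sub = 1.0 - np.exp(-config.subst_rate * t_eff)
        if p_sub > 0:
            target = _target_weights(gc_bias)
            for g in genome:
                hits = rng.random(g.seq.size) < p_sub
                n = int(hits.sum())
                if n:
                    g.seq[hits] = rng.choice(len(AMINO_ACIDS), size=n, p=target)
        return genome

    def walk(node: dendropy.Node, genome: list[_Gene]) -> None:
        for child in node.child_nodes():
            child_genome = evolve_branch(genome, child)
            if child.is_leaf():
                name = child.taxon.label
                leaf_genomes[name] = child_genome
                ov = config.lineage_overrides.get(name)
                realized_bias[name] = ov.gc_bias if ov else config.gc_bias
            else:
                walk(child, child_genome)

    walk(tree.seed_node, root_genome)

    # assemble outputs
    orders: dict[str, list[str]] = {}
    proteomes: dict[str, dict[str, str]] = {}
    annotations: dict[str, GenomeAnnotation] = {}
    cluster_members: dict[str, list[tuple[str, str]]] = {}
    for taxon in sorted(leaf_genomes):
        genome = leaf_genomes[taxon]
        gene_ids = [f"{taxon}|g{g.uid:05d}" for g in genome]
        orders[taxon] = gene_ids
        proteomes[taxon] = {
            gid: "".join(AMINO_ACIDS[i] for i in g.seq)
            for gid, g in zip(gene_ids, genome)
        }
        for gid, g in zip(gene_ids, genome):
            cluster_members.setdefault(g.cluster, []).append((taxon, gid))
        annotations[taxon] = _layout_annotation(
            taxon, genome, gene_ids, config, rng
        )
    clusters = ClusterSet(
        {cid: cluster_members[cid] for cid in sorted(cluster_members)},
        frozenset(leaf_genomes),
    )
    truth = GroundTruth(tree, clusters, events, realized_bias)
    return SimulatedDataset(config, annotations, proteomes, orders, truth)


def _layout_annotation(
    taxon: str,
    genome: list[_Gene],
    gene_ids: list[str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> GenomeAnnotation:
    """Lay genes consecutively on one (optionally two) replicons."""
    ann = GenomeAnnotation(taxon)
    split = len(genome) if not config.second_replicon else max(1, len(genome) * 4 // 5)
    chunks = [("chr", genome[:split], gene_ids[:split], config.circular)]
    if config.second_replicon:
        chunks.append(("plasmid", genome[split:], gene_ids[split:], False))
    for rep_id, genes, ids, circ in chunks:
        pos = 0
        records = []
        for g, gid in zip(genes, ids):
            length_nt = 3 * g.seq.size + 3
            strand = "+" if rng.random() < 0.5 else "-"
            records.append(
                GeneRecord(
                    genome_id=taxon,
                    replicon_id=rep_id,
                    gene_id=gid,
                    start=pos,
                    end=pos + length_nt,
                    strand=strand,
                    feature_type="CDS",
                    product="simulated protein",
                )
            )
            pos += length_nt + 50
        rep = Replicon(rep_id, length_bp=pos + 50, circular=circ, genes=records)
        ann.replicons[rep_id] = rep
    return ann.finalize()


# ---------------------------------------------------------------------------
# Spec-level operations (views over the engine)
# ---------------------------------------------------------------------------

def evolve_gene_content(
    tree: dendropy.Tree | None, config: SimulationConfig
) -> tuple[dict[str, list[str]], ClusterSet]:
    """Per-taxon gene inventories (in genome order) and the true clusters."""
    ds = simulate_dataset(config, tree=tree)
    return ds.orders, ds.truth.clusters


def evolve_gene_order(
    tree: dendropy.Tree | None, config: SimulationConfig
) -> dict[str, list[str]]:
    ds = simulate_dataset(config, tree=tree)
    return ds.orders


def evolve_sequences(
    tree: dendropy.Tree | None, config: SimulationConfig
) -> dict[str, dict[str, str]]:
    ds = simulate_dataset(config, tree=tree)
    return ds.proteomes


# ---------------------------------------------------------------------------
# Taxonomy from tree cuts
# ---------------------------------------------------------------------------

def taxonomy_from_tree(
    tree: dendropy.Tree,
    fractions: tuple[float, float, float] = (0.25, 0.5, 0.75),
) -> TaxonomyTable:
    """Derive (order, family, genus) strata by cutting the tree at three
    fixed depth fractions of the maximum root-to-tip distance.

    Each leaf's group at a cut is the lineage (branch) crossing that depth on
    its root path; shallower cuts give coarser strata.
    """
    depths: dict[dendropy.Node, float] = {tree.seed_node: 0.0}
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        depths[nd] = depths[nd.parent_node] + (nd.edge.length or 0.0)
    max_depth = max(depths[lf] for lf in tree.leaf_node_iter())
    cuts = [f * max_depth for f in fractions]  # order, family, genus
    prefixes = ["O", "F", "G"]

    group_ids: dict[tuple[int, int], str] = {}
    table: dict[str, tuple[str, str, str]] = {}
    node_index = {nd: i for i, nd in enumerate(tree.preorder_node_iter())}
    for leaf in tree.leaf_node_iter():
        labels = []
        for level, cut in enumerate(cuts):
            nd = leaf
            while nd.parent_node is not None and depths[nd.parent_node] > cut:
                nd = nd.parent_node
            key = (level, node_index[nd])
            if key not in group_ids:
                group_ids[key] = f"{prefixes[level]}{len([k for k in group_ids if k[0] == level]) + 1:02d}"
            labels.append(group_ids[key])
        order, family, genus = labels
        table[leaf.taxon.label] = (genus, family, order)
    return TaxonomyTable(table)


# ---------------------------------------------------------------------------
# Dataset export
# ---------------------------------------------------------------------------

def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> Path:
    """Write FASTA proteomes, TSV gene tables, the TRUE groups file, the
    species tree, the config, and a tree-cut taxonomy under ``outdir``."""
    out = Path(outdir)
    (out / "proteomes").mkdir(parents=True, exist_ok=True)
    for taxon in sorted(dataset.proteomes):
        write_fasta(dataset.proteomes[taxon], out / "proteomes" / f"{taxon}.faa")
    write_gene_table(
        [dataset.annotations[t] for t in sorted(dataset.annotations)],
        out / "gene_tables.tsv",
    )
    write_clusters(dataset.truth.clusters, out / "clusters.groups")
    write_newick(dataset.truth.species_tree, out / "species_tree.nwk")
    write_taxonomy(
        taxonomy_from_tree(dataset.truth.species_tree), out / "taxonomy.tsv"
    )
    dataset.config.to_yaml(out / "config.yaml")
    return out


# ---------------------------------------------------------------------------
# Rogue-lineage preset
# ---------------------------------------------------------------------------

@dataclass
class RoguePreset:
    """A fast-evolving AT-biased taxon outside a convergently biased clade.

    Emulates the central confound at desk scale: a compositionally
    convergent rogue lineage that shares an AT-biased, fast-evolving profile
    with an unrelated clade.  Gene-content and synteny metrics should NOT
    group the rogue with the clade, while the clade's true members remain
    each other's nearest neighbours.
    """

    config: SimulationConfig
    focal_clade: tuple[str, ...]
    rogue_taxon: str


def rogue_lineage_preset(
    seed: int,
    n_taxa: int = 12,
    **config_kwargs,
) -> RoguePreset:
    base = SimulationConfig(n_taxa=n_taxa, seed=seed, **config_kwargs)
    tree = simulate_species_tree(n_taxa, base.birth_rate, seed)

    # focal clade: internal node with leaf count closest to 5 (but a proper
    # sub-clade), deterministic preorder tie-break
    best = None
    for nd in tree.preorder_internal_node_iter():
        if nd is tree.seed_node:
            continue
        count = sum(1 for _ in nd.leaf_iter())
        if count < 3 or count > n_taxa - 2:
            continue
        score = abs(count - 5)
        if best is None or score < best[0]:
            best = (score, nd)
    if best is None:
        raise ValueError("tree has no suitable clade; increase n_taxa")
    clade_node = best[1]
    clade = tuple(sorted(lf.taxon.label for lf in clade_node.leaf_iter()))

    # rogue: the non-clade leaf farthest (patristically) from the clade MRCA
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    def dist_to_clade(name: str) -> float:
        return min(pdm.patristic_distance(taxa[name], taxa[c]) for c in clade)
    candidates = sorted(set(taxa) - set(clade))
    rogue = max(candidates, key=lambda n: (dist_to_clade(n), n))

    overrides = {name: LineageOverride(gc_bias=-0.8) for name in clade}
    overrides[rogue] = LineageOverride(gc_bias=-0.8, rate_scale=3.0)
    config = dataclasses.replace(base, lineage_overrides=overrides)
    return RoguePreset(config=config, focal_clade=clade, rogue_taxon=rogue)
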