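"""Ortholog-cluster curation.

Implements the standard curation ladder applied to orthoMCL-style clusters
before phylogenomic use: threshold filtering (taxon coverage, per-genome
copy number, cluster size), pan-ortholog selection (exactly one copy per
genome), gene-tree-based paralog resolution, and discordance flagging
against a species tree.  A reciprocal-best-hit clusterer is provided as
plumbing so simulated datasets need no external clustering program.

Paralog resolution follows four rules.  Within a gene tree, when one
genome's paralogs form a clade containing no other genome's leaves
("clustered together"), the copy with the shortest terminal branch is
retained.  Ingroup copies placed inside the outgroup clade are removed.
Paralogs of one genome at genuinely different tree positions invalidate the
whole cluster.  Outgroup species whose copies sit at different positions
lose all their copies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import dendropy
import networkx as nx

from alphacomp.io_formats import ClusterSet


@dataclass(frozen=True)
class ClusterFilterParams:
    min_taxa: int
    max_copies_per_genome: int
    max_genes: int

    def validate(self, n_taxa: int) -> None:
        if self.min_taxa > n_taxa:
            raise ValueError(
                f"min_taxa={self.min_taxa} exceeds universe size {n_taxa}"
            )
        if self.max_copies_per_genome < 1:
            raise ValueError("max_copies_per_genome must be >= 1")
        if self.max_genes < self.min_taxa:
            raise ValueError("max_genes must be >= min_taxa")


@dataclass(frozen=True)
class ParalogDecision:
    cluster_id: str
    action: str  # keep_shortest_branch | remove_outgroup_copy | remove_cluster | remove_all_copies
    affected: tuple[str, ...]  # gene_ids removed (or the whole cluster's)
    rationale: str


# ---------------------------------------------------------------------------
# Threshold filtering and pan-orthologs
# ---------------------------------------------------------------------------

def filter_clusters(
    clusters: ClusterSet, params: ClusterFilterParams
) -> tuple[ClusterSet, dict[str, int]]:
    """Keep clusters meeting all three predicates; report rejections each.

    Predicates: present in >= min_taxa genomes; <= max_copies_per_genome
    copies in every genome; <= max_genes members overall.  A cluster failing
    several predicates is counted under each.
    """
    params.validate(len(clusters.taxa))
    report = {"taxa": 0, "copies": 0, "size": 0, "kept": 0, "total": 0}
    kept: list[str] = []
    for cid in clusters.clusters:
        report["total"] += 1
        counts = clusters.copy_counts(cid)
        ok = True
        if len(counts) < params.min_taxa:
            report["taxa"] += 1
            ok = False
        if max(counts.values()) > params.max_copies_per_genome:
            report["copies"] += 1
            ok = False
        if sum(counts.values()) > params.max_genes:
            report["size"] += 1
            ok = False
        if ok:
            kept.append(cid)
            report["kept"] += 1
    return clusters.subset(kept), report


def find_pan_orthologs(clusters: ClusterSet) -> ClusterSet:
    """Clusters with exactly one member in every genome of the universe."""
    n = len(clusters.taxa)
    kept = [
        cid
        for cid in clusters.clusters
        if (counts := clusters.copy_counts(cid))
        and len(counts) == n
        and all(v == 1 for v in counts.values())
    ]
    return clusters.subset(kept)


# ---------------------------------------------------------------------------
# Tree utilities (splits on leaf-name sets)
# ---------------------------------------------------------------------------

def _leaf_name(node: dendropy.Node) -> str:
    return node.taxon.label if node.taxon else node.label


def _tree_sides(tree: dendropy.Tree) -> list[frozenset[str]]:
    """One leafset per edge (the subtree side), trivial edges included."""
    sides = []
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        sides.append(frozenset(_leaf_name(lf) for lf in nd.leaf_iter()))
    return sides


def _all_leaves(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(_leaf_name(lf) for lf in tree.leaf_node_iter())


def is_clade(tree: dendropy.Tree, names: set[str], within: set[str] | None = None) -> bool:
    """True if ``names`` is separated from the rest by some edge, judged
    after (virtually) pruning to ``within`` when given — unrooted monophyly."""
    universe = _all_leaves(tree) if within is None else frozenset(within)
    target = frozenset(names)
    if not target or not target <= universe:
        return False
    if target == universe:
        return True
    for side in _tree_sides(tree):
        restricted = side & universe
        if restricted == target or universe - restricted == target:
            return True
    return False


def _terminal_branch_lengths(tree: dendropy.Tree) -> dict[str, float]:
    return {
        _leaf_name(lf): (lf.edge.length if lf.edge.length is not None else 0.0)
        for lf in tree.leaf_node_iter()
    }


# ---------------------------------------------------------------------------
# Paralog resolution
# ---------------------------------------------------------------------------

def resolve_paralogs(
    cluster_id: str,
    members: Sequence[tuple[str, str]],
    gene_tree: dendropy.Tree,
    ingroup: set[str],
    outgroup: set[str] | None = None,
) -> tuple[list[ParalogDecision], list[tuple[str, str]]]:
    """Apply the four paralog rules; return decisions and the pruned members.

    Gene-tree leaves are gene_ids (``genome|locus``) and must all belong to
    the cluster.  With an outgroup, the tree is conceptually rooted on the
    edge above the outgroup's minimal subtree; ingroup copies falling inside
    that subtree are removed, provided their genome retains a copy elsewhere
    — otherwise the outgroup is declared non-monophyletic.
    """
    outgroup = outgroup or set()
    member_ids = {gid for _, gid in members}
    genome_of = {gid: genome for genome, gid in members}
    leaves = _all_leaves(gene_tree)
    stray = leaves - member_ids
    if stray:
        raise ValueError(f"gene-tree leaves not in cluster {cluster_id}: {sorted(stray)}")

    decisions: list[ParalogDecision] = []
    removed: set[str] = set()
    term_len = _terminal_branch_lengths(gene_tree)

    def copies(genome: str) -> list[str]:
        return sorted(
            gid for gid in leaves - removed if genome_of[gid] == genome
        )

    # --- outgroup species with multiple copies (before rooting: a
    # scattered outgroup species is what breaks outgroup monophyly) ---
    for genome in sorted(outgroup):
        cps = copies(genome)
        if len(cps) < 2:
            continue
        if is_clade(gene_tree, set(cps), within=leaves - removed):
            keep = min(cps, key=lambda g: (term_len[g], g))
            drop = tuple(g for g in cps if g != keep)
            removed.update(drop)
            decisions.append(
                ParalogDecision(
                    cluster_id, "keep_shortest_branch", drop,
                    f"outgroup paralogs of {genome} monophyletic; kept {keep}",
                )
            )
        else:
            removed.update(cps)
            decisions.append(
                ParalogDecision(
                    cluster_id, "remove_all_copies", tuple(cps),
                    f"outgroup copies of {genome} at different positions",
                )
            )

    # --- outgroup side (rooting on the edge above the remaining outgroup) ---
    remaining = leaves - removed
    og_leaves = {gid for gid in remaining if genome_of[gid] in outgroup}
    if og_leaves:
        best = None
        for side in _tree_sides(gene_tree) + [leaves]:
            for cand in (side & remaining, remaining - side):
                if og_leaves <= cand and (best is None or len(cand) < len(best)):
                    best = cand
        og_side = frozenset(best or ())
        inside_ingroup = {gid for gid in og_side if genome_of[gid] in ingroup}
        for gid in sorted(inside_ingroup):
            genome = genome_of[gid]
            others = [
                g
                for g in remaining
                if genome_of[g] == genome and g not in og_side and g not in removed
            ]
            if not others:
                raise ValueError(
                    f"cluster {cluster_id}: outgroup not monophyletic "
                    f"(single-copy ingroup leaf {gid} inside outgroup side)"
                )
            removed.add(gid)
            decisions.append(
                ParalogDecision(
                    cluster_id, "remove_outgroup_copy", (gid,),
                    "ingroup copy placed within the outgroup",
                )
            )

    # --- ingroup paralogs ---
    for genome in sorted(ingroup):
        cps = copies(genome)
        if len(cps) < 2:
            continue
        if is_clade(gene_tree, set(cps), within=leaves - removed):
            keep = min(cps, key=lambda g: (term_len[g], g))
            drop = tuple(g for g in cps if g != keep)
            removed.update(drop)
            decisions.append(
                ParalogDecision(
                    cluster_id, "keep_shortest_branch", drop,
                    f"paralogs of {genome} clustered together; kept {keep}",
                )
            )
        else:
            decisions.append(
                ParalogDecision(
                    cluster_id, "remove_cluster", tuple(sorted(member_ids)),
                    f"paralogs of {genome} at different positions in the tree",
                )
            )
            return decisions, []

    pruned = [(g, gid) for g, gid in members if gid not in removed]
    return decisions, pruned


# ---------------------------------------------------------------------------
# Discordance flagging
# ---------------------------------------------------------------------------

def _support_of(node: dendropy.Node, scale_hint: list[float]) -> float | None:
    label = node.label
    if label is None:
        return None
    try:
        v = float(label)
    except ValueError:
        return None
    scale_hint.append(v)
    return v


def _splits_with_support(
    tree: dendropy.Tree, universe: frozenset[str]
) -> list[tuple[frozenset[str], float | None]]:
    out = []
    scale: list[float] = []
    raw = []
    for nd in tree.preorder_internal_node_iter():
        if nd is tree.seed_node:
            continue
        side = frozenset(_leaf_name(lf) for lf in nd.leaf_iter()) & universe
        if len(side) < 2 or len(universe - side) < 2:
            continue
        raw.append((side, _support_of(nd, scale)))
    # supports on 0-100 scale are normalized to [0, 1]
    factor = 100.0 if any(v > 1.0 for v in scale) else 1.0
    for side, sup in raw:
        out.append((side, None if sup is None else sup / factor))
    return out


def _compatible(a: frozenset[str], b: frozenset[str], universe: frozenset[str]) -> bool:
    ac, bc = universe - a, universe - b
    return not (a & b) or not (a & bc) or not (ac & b) or not (ac & bc)


def discordance_flag(
    cluster_tree: dendropy.Tree,
    species_tree: dendropy.Tree,
    support_threshold: float = 0.9,
) -> str:
    """``"discordant"`` iff the cluster tree holds a bipartition with support
    >= threshold that is incompatible with the species tree (on the shared
    leaf set), else ``"concordant"``.  Unannotated edges count as fully
    supported.  Used to drop putative horizontal transfers.
    """
    shared = _all_leaves(cluster_tree) & _all_leaves(species_tree)
    if len(shared) < 4:
        return "concordant"
    species_splits = [s for s, _ in _splits_with_support(species_tree, shared)]
    for side, support in _splits_with_support(cluster_tree, shared):
        sup = 1.0 if support is None else support
        if sup < support_threshold:
            continue
        for sp in species_splits:
            if not _compatible(side, sp, shared):
                return "discordant"
    return "concordant"


# ---------------------------------------------------------------------------
# Reciprocal-best-hit fallback clustering
# ---------------------------------------------------------------------------

def _kmer_index(seqs: dict[str, str], k: int = 3) -> dict[str, set[str]]:
    index: dict[str, set[str]] = {}
    for gid, seq in seqs.items():
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], set()).add(gid)
    return index


def _best_hits(
    query: dict[str, str],
    subject: dict[str, str],
    score_fn: Callable[[str, str], float],
    n_candidates: int = 5,
) -> dict[str, str]:
    """Best subject gene per query gene, with a shared-3-mer prefilter."""
    index = _kmer_index(subject)
    best: dict[str, str] = {}
    for qid in sorted(query):
        qseq = query[qid]
        shared: dict[str, int] = {}
        for i in range(len(qseq) - 2):
            for sid in index.get(qseq[i : i + 3], ()):
                shared[sid] = shared.get(sid, 0) + 1
        if not shared:
            continue
        cands = sorted(shared, key=lambda s: (-shared[s], s))[:n_candidates]
        scored = [(score_fn(qseq, subject[s]), s) for s in cands]
        top_score = max(sc for sc, _ in scored)
        if top_score > 0:
            best[qid] = min(s for sc, s in scored if sc == top_score)
    return best


def rbh_cluster(
    proteomes: dict[str, dict[str, str]],
    score_fn: Callable[[str, str], float] | None = None,
) -> ClusterSet:
    """Reciprocal-best-hit graph across all genome pairs; connected
    components become clusters.  Genes without any reciprocal hit are left
    unclustered (no singleton clusters)."""
    if score_fn is None:
        from alphacomp.synteny_identity import sw_score
        score_fn = sw_score
    graph = nx.Graph()
    genomes = sorted(proteomes)
    for gi in genomes:
        for gid in proteomes[gi]:
            graph.add_node((gi, gid))
    for i, ga in enumerate(genomes):
        for gb in genomes[i + 1 :]:
            fwd = _best_hits(proteomes[ga], proteomes[gb], score_fn)
            rev = _best_hits(proteomes[gb], proteomes[ga], score_fn)
            for qid, sid in fwd.items():
                if rev.get(sid) == qid:
                    graph.add_edge((ga, qid), (gb, sid))
    components = [
        sorted(c) for c in nx.connected_components(graph) if len(c) > 1
    ]
    components.sort(key=lambda c: c[0])
    clusters = {
        f"RBH{i:05d}": [(g, gid) for g, gid in comp]
        for i, comp in enumerate(components, 1)
    }
    return ClusterSet(clusters, frozenset(genomes))
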