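"""Gene-order synteny versus protein identity for genome pairs.

For each genome pair the module computes two numbers: the average
normalized bit score over shared protein-coding genes (a proxy for protein
identity) and the synteny fraction — the fraction of shared genes that keep
at least one conserved adjacent shared gene ("same nearest neighbour")
after both gene orders are restricted to the shared genes.  Pairs are
stratified by taxonomic rank (within genus / family / order, between
orders) so a focal genome's similarity to a candidate clade can be read
against the background of unrelated pairs at the same divergence.

Shared genes come either from single-copy co-membership in ortholog
clusters or from reciprocal best hits.  The internal pairwise scorer is
Smith-Waterman (BLOSUM62, gap open 11 / extend 1) with bit scores from the
Karlin-Altschul conversion at fixed constants lambda = 0.267, K = 0.041, so
results are deterministic without an external aligner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from alphacomp.io_formats import ClusterSet, GenomeAnnotation, TaxonomyTable

KA_LAMBDA = 0.267
KA_K = 0.041

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

_aligner = Align.PairwiseAligner()
_aligner.mode = "local"
_aligner.substitution_matrix = _BLOSUM62
_aligner.open_gap_score = -11.0
_aligner.extend_gap_score = -1.0


def sw_score(a: str, b: str) -> float:
    """Raw Smith-Waterman score (BLOSUM62, 11/1)."""
    if not a or not b:
        return 0.0
    return float(_aligner.score(a, b))


def self_score(seq: str) -> float:
    """Raw score of a sequence against itself: the BLOSUM62 diagonal sum."""
    return float(sum(_BLOSUM62[c, c] for c in seq))


def karlin_altschul_bits(raw_score: float) -> float:
    return (KA_LAMBDA * raw_score - math.log(KA_K)) / math.log(2.0)


def normalized_bitscore(
    bitscore_ab: float, selfscore_a: float, selfscore_b: float
) -> float:
    """bitscore_AB / min(self scores), clipped to [0, 1]."""
    denom = min(selfscore_a, selfscore_b)
    if denom <= 0:
        raise ValueError("self bit scores must be positive")
    return min(max(bitscore_ab / denom, 0.0), 1.0)


# ---------------------------------------------------------------------------
# Ortholog pair maps
# ---------------------------------------------------------------------------

@dataclass
class OrthologPairMap:
    genome_a: str
    genome_b: str
    # (gene_a, gene_b, bitscore_ab, selfscore_a, selfscore_b)
    pairs: list[tuple[str, str, float, float, float]]
    method: str = "rbh_internal"

    def __post_init__(self) -> None:
        seen_a = {p[0] for p in self.pairs}
        seen_b = {p[1] for p in self.pairs}
        if len(seen_a) != len(self.pairs) or len(seen_b) != len(self.pairs):
            raise ValueError("pair map is not one-to-one")

    @property
    def mapping(self) -> dict[str, str]:
        return {a: b for a, b, *_ in self.pairs}


def pair_map_from_clusters(
    clusters: ClusterSet,
    proteomes: Mapping[str, Mapping[str, str]],
    genome_a: str,
    genome_b: str,
) -> OrthologPairMap:
    """Shared genes = clusters with exactly one member in each genome."""
    pairs: list[tuple[str, str, float, float, float]] = []
    for cid in sorted(clusters.clusters):
        in_a = [gid for g, gid in clusters.clusters[cid] if g == genome_a]
        in_b = [gid for g, gid in clusters.clusters[cid] if g == genome_b]
        if len(in_a) == 1 and len(in_b) == 1:
            sa, sb = proteomes[genome_a][in_a[0]], proteomes[genome_b][in_b[0]]
            pairs.append(
                (
                    in_a[0],
                    in_b[0],
                    karlin_altschul_bits(sw_score(sa, sb)),
                    karlin_altschul_bits(self_score(sa)),
                    karlin_altschul_bits(self_score(sb)),
                )
            )
    return OrthologPairMap(genome_a, genome_b, pairs, method="clusters")


def pair_map_rbh(
    proteomes: Mapping[str, Mapping[str, str]],
    genome_a: str,
    genome_b: str,
) -> OrthologPairMap:
    """Shared genes = reciprocal best hits under the internal scorer."""
    from alphacomp.clustering import _best_hits

    fwd = _best_hits(dict(proteomes[genome_a]), dict(proteomes[genome_b]), sw_score)
    rev = _best_hits(dict(proteomes[genome_b]), dict(proteomes[genome_a]), sw_score)
    pairs = []
    for qid in sorted(fwd):
        sid = fwd[qid]
        if rev.get(sid) == qid:
            sa, sb = proteomes[genome_a][qid], proteomes[genome_b][sid]
            pairs.append(
                (
                    qid,
                    sid,
                    karlin_altschul_bits(sw_score(sa, sb)),
                    karlin_altschul_bits(self_score(sa)),
                    karlin_altschul_bits(self_score(sb)),
                )
            )
    return OrthologPairMap(genome_a, genome_b, pairs, method="rbh_internal")


def pair_identity(pair_map: OrthologPairMap) -> float:
    """Average normalized bit score over shared genes."""
    if not pair_map.pairs:
        raise ValueError("no shared genes")
    return float(
        np.mean(
            [normalized_bitscore(ab, sa, sb) for _, _, ab, sa, sb in pair_map.pairs]
        )
    )


# ---------------------------------------------------------------------------
# Synteny
# ---------------------------------------------------------------------------

def _adjacency_set(
    replicon_orders: Iterable[tuple[Sequence[str], bool]],
    shared: set[str],
) -> set[frozenset[str]]:
    """Unordered adjacent pairs after restricting each replicon's gene order
    to the shared genes; circular replicons close the ring."""
    adj: set[frozenset[str]] = set()
    for order, circular in replicon_orders:
        restricted = [g for g in order if g in shared]
        for x, y in zip(restricted, restricted[1:]):
            adj.add(frozenset((x, y)))
        if circular and len(restricted) > 2:
            adj.add(frozenset((restricted[0], restricted[-1])))
    return adj


def synteny_fraction(
    order_a: Sequence[str] | Iterable[tuple[Sequence[str], bool]],
    order_b: Sequence[str] | Iterable[tuple[Sequence[str], bool]],
    mapping: Mapping[str, str],
    circular_a: bool = False,
    circular_b: bool = False,
    require_both: bool = False,
) -> float:
    """Fraction of shared genes with a conserved adjacent shared gene.

    ``mapping`` sends gene ids of A to their orthologs in B (one-to-one).
    Orders are flat gene-id lists (with a circular flag) or iterables of
    ``(order, circular)`` replicon tuples.  Adjacency is orientation- and
    strand-free: a reversed gene order is fully syntenic.  With
    ``require_both`` a gene counts only if every adjacent shared gene is
    conserved, instead of at least one.
    """
    reps_a = _as_replicons(order_a, circular_a)
    reps_b = _as_replicons(order_b, circular_b)
    shared_a = set(mapping)
    shared_b = set(mapping.values())
    if len(shared_a) != len(shared_b):
        raise ValueError("mapping is not one-to-one")
    n_shared = len(shared_a)
    if n_shared == 0:
        raise ValueError("no shared genes")
    adj_b = _adjacency_set(reps_b, shared_b)

    # neighbours of each shared gene in A's restricted orders
    neighbours: dict[str, set[str]] = {g: set() for g in shared_a}
    for pair in _adjacency_set(reps_a, shared_a):
        x, y = tuple(pair)
        neighbours[x].add(y)
        neighbours[y].add(x)

    count = 0
    for g in shared_a:
        nb = neighbours[g]
        if not nb:
            continue
        conserved = [
            frozenset((mapping[g], mapping[n])) in adj_b for n in nb
        ]
        if (all(conserved) if require_both else any(conserved)):
            count += 1
    return count / n_shared


def _as_replicons(
    order, circular: bool
) -> list[tuple[list[str], bool]]:
    order = list(order)
    if order and isinstance(order[0], str):
        return [(order, circular)]
    return [(list(genes), bool(circ)) for genes, circ in order]


def annotation_replicons(ann: GenomeAnnotation) -> list[tuple[list[str], bool]]:
    return [
        (ann.gene_order(rep_id), ann.replicons[rep_id].circular)
        for rep_id in sorted(ann.replicons)
    ]


# ---------------------------------------------------------------------------
# Taxonomic pair classes and the all-pairs scan
# ---------------------------------------------------------------------------

CATEGORIES = ("within_genus", "within_family", "within_order", "between_orders")


def classify_pair(
    genome_a: str, genome_b: str, taxonomy: TaxonomyTable
) -> str:
    ga, fa, oa = taxonomy[genome_a]
    gb, fb, ob = taxonomy[genome_b]
    if ga == gb:
        return "within_genus"
    if fa == fb:
        return "within_family"
    if oa == ob:
        return "within_order"
    return "between_orders"


@dataclass(frozen=True)
class PairRecord:
    genome_a: str
    genome_b: str
    category: str
    n_shared: int
    avg_norm_bitscore: float
    synteny_fraction: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.avg_norm_bitscore <= 1.0):
            raise ValueError("avg_norm_bitscore out of [0, 1]")
        if not (0.0 <= self.synteny_fraction <= 1.0):
            raise ValueError("synteny_fraction out of [0, 1]")


def pair_scan(
    annotations: Mapping[str, GenomeAnnotation],
    proteomes: Mapping[str, Mapping[str, str]],
    clusters: ClusterSet | None,
    taxonomy: TaxonomyTable,
    mode: str = "clusters",
    compute_identity: bool = True,
) -> list[PairRecord]:
    """One PairRecord per unordered genome pair.

    ``mode="clusters"`` takes shared genes from single-copy cluster
    co-membership; ``mode="rbh"`` recomputes reciprocal best hits with the
    internal scorer.  ``compute_identity=False`` skips the alignment step
    (identity reported as 0.0) for synteny-only scans.
    """
    genomes = sorted(annotations)
    records: list[PairRecord] = []
    for i, ga in enumerate(genomes):
        for gb in genomes[i + 1 :]:
            if mode == "clusters":
                if clusters is None:
                    raise ValueError("clusters mode needs a ClusterSet")
                pm = pair_map_from_clusters(clusters, proteomes, ga, gb)
            elif mode == "rbh":
                pm = pair_map_rbh(proteomes, ga, gb)
            else:
                raise ValueError(f"unknown mode {mode!r}")
            if not pm.pairs:
                continue
            ident = pair_identity(pm) if compute_identity else 0.0
            synt = synteny_fraction(
                annotation_replicons(annotations[ga]),
                annotation_replicons(annotations[gb]),
                pm.mapping,
            )
            records.append(
                PairRecord(
                    ga, gb, classify_pair(ga, gb, taxonomy), len(pm.pairs), ident, synt
                )
            )
    return records


def records_to_frame(records: Sequence[PairRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "genome_a": r.genome_a,
                "genome_b": r.genome_b,
                "category": r.category,
                "n_shared": r.n_shared,
                "avg_norm_bitscore": r.avg_norm_bitscore,
                "synteny_fraction": r.synteny_fraction,
            }
            for r in records
        ]
    )


def flag_outliers(
    records: Sequence[PairRecord],
) -> list[PairRecord]:
    """Within-category robust outliers: pairs strictly outside the 1.5 x IQR
    fence on either axis (identity or synteny)."""
    by_cat: dict[str, list[PairRecord]] = {}
    for r in records:
        by_cat.setdefault(r.category, []).append(r)
    flagged: list[PairRecord] = []
    for cat in sorted(by_cat):
        recs = by_cat[cat]
        if len(recs) < 4:
            continue
        for axis in ("avg_norm_bitscore", "synteny_fraction"):
            vals = np.array([getattr(r, axis) for r in recs])
            q1, q3 = np.percentile(vals, [25, 75])
            iqr = q3 - q1
            lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
            for r, v in zip(recs, vals):
                if (v < lo or v > hi) and r not in flagged:
                    flagged.append(r)
    return flagged


def scatter_plot(
    records: Sequence[PairRecord],
    path,
    focal_genome: str | None = None,
) -> None:
    """Synteny against identity, coloured by taxonomic pair class; pairs
    involving the focal genome are drawn on top in orange."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {
        "within_genus": "#1b9e77",
        "within_family": "#7570b3",
        "within_order": "#66a61e",
        "between_orders": "#666666",
    }
    fig, ax = plt.subplots(figsize=(6, 5))
    for cat in CATEGORIES:
        xs = [r.avg_norm_bitscore for r in records if r.category == cat]
        ys = [r.synteny_fraction for r in records if r.category == cat]
        if xs:
            ax.scatter(xs, ys, s=14, c=colors[cat], label=cat, alpha=0.7)
    if focal_genome:
        xs = [
            r.avg_norm_bitscore
            for r in records
            if focal_genome in (r.genome_a, r.genome_b)
        ]
        ys = [
            r.synteny_fraction
            for r in records
            if focal_genome in (r.genome_a, r.genome_b)
        ]
        ax.scatter(xs, ys, s=26, c="orange", label=focal_genome, zorder=3)
    ax.set_xlabel("average normalized bit score")
    ax.set_ylabel("synteny fraction")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
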