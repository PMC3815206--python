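"""Readers and writers for every external format the pipeline touches.

All genomic intervals are stored 0-based half-open internally.  GFF3 input
(1-based inclusive) is converted at the boundary, so the conversion is a
bijection on valid intervals.  Gene identifiers are namespaced as
``genome_id|locus_tag`` to match the orthoMCL "groups" dialect, which makes
cluster files the join key between annotations, proteomes and clusters.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """Raised for malformed input files or inconsistent records."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

FEATURE_TYPES = ("CDS", "tRNA", "rRNA", "other")


@dataclass(frozen=True)
class GeneRecord:
    """One gene on one replicon; coordinates 0-based half-open."""

    genome_id: str
    replicon_id: str
    gene_id: str
    start: int
    end: int
    strand: str
    feature_type: str = "CDS"
    product: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid interval [{self.start}, {self.end}) for {self.gene_id}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"unknown strand {self.strand!r} for {self.gene_id}")
        if self.feature_type not in FEATURE_TYPES:
            raise FormatError(f"unknown feature type {self.feature_type!r}")

    @property
    def sort_key(self) -> tuple[int, int, str]:
        return (self.start, self.end, self.gene_id)


@dataclass
class Replicon:
    replicon_id: str
    length_bp: int | None = None
    circular: bool = False
    genes: list[GeneRecord] = field(default_factory=list)
    sequence: str | None = None

    def sort(self) -> None:
        self.genes.sort(key=lambda g: g.sort_key)


@dataclass
class GenomeAnnotation:
    """Ordered gene records per replicon for one genome."""

    genome_id: str
    replicons: dict[str, Replicon] = field(default_factory=dict)

    def add(self, rec: GeneRecord) -> None:
        rep = self.replicons.setdefault(rec.replicon_id, Replicon(rec.replicon_id))
        rep.genes.append(rec)

    def finalize(self) -> "GenomeAnnotation":
        seen: set[str] = set()
        for rep in self.replicons.values():
            rep.sort()
            for g in rep.genes:
                if g.gene_id in seen:
                    raise FormatError(f"duplicate gene_id {g.gene_id}")
                seen.add(g.gene_id)
                if rep.length_bp is not None and g.end > rep.length_bp:
                    raise FormatError(
                        f"{g.gene_id} ends at {g.end} beyond replicon "
                        f"{rep.replicon_id} length {rep.length_bp}"
                    )
        return self

    def all_genes(self) -> list[GeneRecord]:
        out: list[GeneRecord] = []
        for rep in self.replicons.values():
            out.extend(rep.genes)
        return out

    def gene_order(self, replicon_id: str) -> list[str]:
        return [g.gene_id for g in self.replicons[replicon_id].genes]


@dataclass
class ClusterSet:
    """Ortholog clusters: cluster_id -> [(genome_id, gene_id), ...].

    ``taxa`` is the full genome universe; it matters because absence of a
    genome from a cluster is meaningful for gene-content comparisons.
    """

    clusters: dict[str, list[tuple[str, str]]]
    taxa: frozenset[str]

    def __post_init__(self) -> None:
        self.taxa = frozenset(self.taxa)
        seen: set[tuple[str, str]] = set()
        for cid, members in self.clusters.items():
            for m in members:
                if m in seen:
                    raise FormatError(f"member {m[0]}|{m[1]} appears in two clusters")
                seen.add(m)
                if m[0] not in self.taxa:
                    raise FormatError(f"genome {m[0]} (cluster {cid}) not in taxa universe")

    def copy_counts(self, cluster_id: str) -> dict[str, int]:
        counts: dict[str, int] = {}
        for genome, _ in self.clusters[cluster_id]:
            counts[genome] = counts.get(genome, 0) + 1
        return counts

    def genomes_of(self, cluster_id: str) -> set[str]:
        return {g for g, _ in self.clusters[cluster_id]}

    def clusters_of_genome(self, genome_id: str) -> set[str]:
        return {
            cid
            for cid, members in self.clusters.items()
            if any(g == genome_id for g, _ in members)
        }

    def n_genes(self) -> int:
        return sum(len(m) for m in self.clusters.values())

    def subset(self, cluster_ids: Iterable[str]) -> "ClusterSet":
        wanted = set(cluster_ids)
        return ClusterSet(
            {cid: list(m) for cid, m in self.clusters.items() if cid in wanted},
            self.taxa,
        )


@dataclass
class TaxonomyTable:
    """genome_id -> (genus, family, order)."""

    table: dict[str, tuple[str, str, str]]

    def __post_init__(self) -> None:
        for gid, (genus, family, order) in self.table.items():
            if not (genus and family and order):
                raise FormatError(f"empty taxonomy field for {gid}")

    def __getitem__(self, genome_id: str) -> tuple[str, str, str]:
        return self.table[genome_id]

    def __contains__(self, genome_id: str) -> bool:
        return genome_id in self.table

    def genomes(self) -> list[str]:
        return sorted(self.table)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` map.

    Ids are preserved verbatim up to the first whitespace.  Duplicate ids and
    empty files are errors.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq)
    if not seqs:
        raise FormatError(f"no FASTA records in {path}")
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Gene tables (GFF3 and the internal TSV dialect)
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "genome_id",
    "replicon_id",
    "gene_id",
    "start0",
    "end0",
    "strand",
    "feature_type",
    "product",
]

_GFF_ATTR = re.compile(r"([^=;]+)=([^;]*)")


def _classify_feature(ftype: str) -> str:
    if ftype in FEATURE_TYPES:
        return ftype
    return "other"


def _parse_gff3(path: str | Path, genome_id: str) -> list[GeneRecord]:
    records: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype in ("region", "gene"):
                continue
            attr = dict(_GFF_ATTR.findall(attrs))
            locus = attr.get("locus_tag") or attr.get("ID")
            if not locus:
                raise FormatError(f"{path}:{lineno}: no ID/locus_tag attribute")
            start0 = int(start) - 1  # GFF3 is 1-based inclusive
            end0 = int(end)
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
            if end0 <= start0:
                raise FormatError(f"{path}:{lineno}: end <= start after conversion")
            records.append(
                GeneRecord(
                    genome_id=genome_id,
                    replicon_id=seqid,
                    gene_id=f"{genome_id}|{locus}",
                    start=start0,
                    end=end0,
                    strand=strand,
                    feature_type=_classify_feature(ftype),
                    product=attr.get("product", ""),
                )
            )
    return records


def _parse_tsv(path: str | Path) -> tuple[list[GeneRecord], dict]:
    """Parse the TSV gene-table dialect (0-based half-open coordinates).

    ``#replicon <genome> <replicon> <length|-> <circular:0/1>`` header comments
    carry replicon metadata through round trips.
    """
    records: list[GeneRecord] = []
    replicon_meta: dict[tuple[str, str], tuple[int | None, bool]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#replicon"):
                _, genome, rep, length, circ = line.split("\t")
                replicon_meta[(genome, rep)] = (
                    None if length == "-" else int(length),
                    circ == "1",
                )
                continue
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            if cols[: len(_TSV_COLUMNS)] == _TSV_COLUMNS:
                continue  # header row
            if len(cols) < 7:
                raise FormatError(f"{path}:{lineno}: expected ≥7 TSV columns")
            genome, rep, gene, start0, end0, strand, ftype = cols[:7]
            product = cols[7] if len(cols) > 7 else ""
            start, end = int(start0), int(end0)
            if end <= start:
                raise FormatError(f"{path}:{lineno}: end0 <= start0")
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
            records.append(
                GeneRecord(
                    genome_id=genome,
                    replicon_id=rep,
                    gene_id=gene,
                    start=start,
                    end=end,
                    strand=strand,
                    feature_type=_classify_feature(ftype),
                    product=product,
                )
            )
    return records, replicon_meta


def read_gene_table(
    path: str | Path,
    dialect: str = "tsv",
    genome_id: str | None = None,
) -> GenomeAnnotation:
    """Read a single genome's gene table (GFF3 or TSV dialect).

    For GFF3, ``genome_id`` defaults to the file stem (GFF3 carries no genome
    identifier).  Raises if the table mixes more than one genome; use
    :func:`read_gene_tables` for multi-genome TSVs.
    """
    annotations = read_gene_tables(path, dialect=dialect, genome_id=genome_id)
    if len(annotations) != 1:
        raise FormatError(
            f"{path} contains {len(annotations)} genomes; expected exactly one"
        )
    return next(iter(annotations.values()))


def read_gene_tables(
    path: str | Path,
    dialect: str = "tsv",
    genome_id: str | None = None,
) -> dict[str, GenomeAnnotation]:
    if dialect == "gff3":
        gid = genome_id or Path(path).stem
        records = _parse_gff3(path, gid)
        meta: dict = {}
    elif dialect == "tsv":
        records, meta = _parse_tsv(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    annotations: dict[str, GenomeAnnotation] = {}
    for rec in records:
        ann = annotations.setdefault(rec.genome_id, GenomeAnnotation(rec.genome_id))
        ann.add(rec)
    for (genome, rep), (length, circ) in meta.items():
        ann = annotations.setdefault(genome, GenomeAnnotation(genome))
        replicon = ann.replicons.setdefault(rep, Replicon(rep))
        replicon.length_bp = length
        replicon.circular = circ
    for ann in annotations.values():
        ann.finalize()
    return annotations


def write_gene_table(
    annotations: GenomeAnnotation | Iterable[GenomeAnnotation],
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    """Write annotations in the TSV dialect (0-based half-open)."""
    if isinstance(annotations, GenomeAnnotation):
        annotations = [annotations]
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for ann in annotations:
            for rep_id in sorted(ann.replicons):
                rep = ann.replicons[rep_id]
                length = "-" if rep.length_bp is None else str(rep.length_bp)
                circ = "1" if rep.circular else "0"
                fh.write(f"#replicon\t{ann.genome_id}\t{rep_id}\t{length}\t{circ}\n")
                for g in rep.genes:
                    fh.write(
                        "\t".join(
                            [
                                g.genome_id,
                                g.replicon_id,
                                g.gene_id,
                                str(g.start),
                                str(g.end),
                                g.strand,
                                g.feature_type,
                                g.product,
                            ]
                        )
                        + "\n"
                    )


# ---------------------------------------------------------------------------
# orthoMCL "groups" dialect
# ---------------------------------------------------------------------------

def read_clusters(path: str | Path, taxa: Iterable[str] | None = None) -> ClusterSet:
    """Read an orthoMCL-style groups file: ``OG0001: gnmA|g1 gnmB|g2 ...``.

    ``taxa`` fixes the genome universe; by default it is the set of genomes
    observed in the file.
    """
    clusters: dict[str, list[tuple[str, str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise FormatError(f"{path}:{lineno}: missing ':' separator")
            cid, _, rest = line.partition(":")
            cid = cid.strip()
            if cid in clusters:
                raise FormatError(f"{path}:{lineno}: duplicate cluster id {cid}")
            members: list[tuple[str, str]] = []
            for token in rest.split():
                if token.count("|") != 1:
                    raise FormatError(
                        f"{path}:{lineno}: member {token!r} must contain exactly one '|'"
                    )
                genome, _, locus = token.partition("|")
                members.append((genome, token))
            clusters[cid] = members
    universe = frozenset(taxa) if taxa is not None else frozenset(
        g for members in clusters.values() for g, _ in members
    )
    return ClusterSet(clusters, universe)


def write_clusters(cluster_set: ClusterSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for cid in sorted(cluster_set.clusters):
            members = " ".join(gene for _, gene in cluster_set.clusters[cid])
            fh.write(f"{cid}: {members}\n")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def read_newick(path_or_string: str | Path) -> dendropy.Tree:
    """Read one Newick tree from a file path or a literal Newick string."""
    text: str
    p = Path(str(path_or_string))
    if "(" in str(path_or_string):
        text = str(path_or_string)
    else:
        text = p.read_text()
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"cannot parse Newick: {exc}") from exc
    names = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    if len(names) != len(set(names)):
        raise FormatError("duplicate leaf names in tree")
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(newick_string(tree))


def newick_string(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".6f",
        unquoted_underscores=True,
    )


# ---------------------------------------------------------------------------
# Taxonomy TSV
# ---------------------------------------------------------------------------

def read_taxonomy(path: str | Path) -> TaxonomyTable:
    table: dict[str, tuple[str, str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if cols[0] == "genome_id":
                continue
            if len(cols) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            genome, genus, family, order = cols
            if genome in table:
                raise FormatError(f"{path}:{lineno}: duplicate genome {genome}")
            table[genome] = (genus, family, order)
    return TaxonomyTable(table)


def write_taxonomy(tax: TaxonomyTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tgenus\tfamily\torder\n")
        for genome in sorted(tax.table):
            genus, family, order = tax.table[genome]
            fh.write(f"{genome}\t{genus}\t{family}\t{order}\n")
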