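"""Amino-acid compositional bias (aminoGC) and nucleotide GC content.

aminoGC is the fraction of residues belonging to amino acids encoded by
codon families with G or C in both of the first two codon positions:
glycine (GGN), alanine (GCN), arginine (CGN) and proline (CCN).  Genomes
under AT mutation pressure are depleted in these residues, so a low aminoGC
signals the protein-level footprint of nucleotide composition bias — the
kind of signal that can draw unrelated AT-rich lineages together in
phylogenies.  Arginine also has AGR codons; an Arg-free variant of the set
is available via the ``gc_set`` argument for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

GC_SET = frozenset("GARP")
GC_SET_NO_ARG = frozenset("GAP")

# gaps and ambiguity codes leave both numerator and denominator
_EXCLUDED = set("-.*BZXJUO")
_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


def amino_gc(sequence: str, gc_set: frozenset[str] = GC_SET) -> float:
    """Fraction of counted residues in the GC-rich amino-acid set."""
    seq = sequence.upper()
    counted = [c for c in seq if c in _ALPHABET]
    if not counted:
        raise ValueError("no countable residues after removing gaps/ambiguities")
    hits = sum(1 for c in counted if c in gc_set)
    return hits / len(counted)


def gc_content(sequence: str) -> float:
    """G+C fraction of a nucleotide sequence (N's excluded)."""
    seq = sequence.upper()
    counted = [c for c in seq if c in "ACGT"]
    if not counted:
        raise ValueError("no countable bases")
    return sum(1 for c in counted if c in "GC") / len(counted)


@dataclass(frozen=True)
class AminoGCReport:
    unit_id: str
    n_residues: int
    amino_gc: float


@dataclass(frozen=True)
class BoxStats:
    """Tukey box-plot summary of a per-gene aminoGC distribution."""

    median: float
    q1: float
    q3: float
    lower_whisker: float
    upper_whisker: float
    n: int


def alignment_amino_gc(
    alignments: Mapping[str, Mapping[str, str]],
    gc_set: frozenset[str] = GC_SET,
) -> tuple[list[AminoGCReport], BoxStats]:
    """One aminoGC value per gene (all taxa's residues pooled), plus the
    Tukey box-plot summary across genes.

    ``alignments`` maps gene id -> {taxon: aligned sequence}.
    """
    reports: list[AminoGCReport] = []
    for gene_id in sorted(alignments):
        pooled = "".join(alignments[gene_id][t] for t in sorted(alignments[gene_id]))
        counted = sum(1 for c in pooled.upper() if c in _ALPHABET)
        reports.append(AminoGCReport(gene_id, counted, amino_gc(pooled, gc_set)))
    values = np.array([r.amino_gc for r in reports])
    return reports, tukey_box_stats(values)


def tukey_box_stats(values: Iterable[float]) -> BoxStats:
    v = np.sort(np.asarray(list(values), dtype=float))
    if v.size == 0:
        raise ValueError("empty distribution")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo = v[v >= q1 - 1.5 * iqr]
    hi = v[v <= q3 + 1.5 * iqr]
    return BoxStats(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        lower_whisker=float(lo[0]),
        upper_whisker=float(hi[-1]),
        n=int(v.size),
    )
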