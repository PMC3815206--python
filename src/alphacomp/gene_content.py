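"""Gene-content similarity over ortholog clusters.

The similarity of two genomes is the number of shared orthologous clusters
divided by the number of clusters in the genome represented in fewer
clusters: S(A, B) = |A ∩ B| / min(|A|, |B|), where A and B are the sets of
clusters each genome has at least one member in (copy number is ignored —
the index is defined over clusters, not genes).  Singleton clusters count
toward their genome's total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from alphacomp.io_formats import ClusterSet


def content_similarity(clusters_a: set[str], clusters_b: set[str]) -> float:
    """|A ∩ B| / min(|A|, |B|); symmetric, in [0, 1]."""
    if not clusters_a or not clusters_b:
        raise ValueError("a genome with an empty cluster set has no similarity")
    return len(clusters_a & clusters_b) / min(len(clusters_a), len(clusters_b))


@dataclass
class ContentSimilarityMatrix:
    genomes: list[str]
    values: pd.DataFrame           # square, symmetric, diagonal 1
    cluster_counts: dict[str, int]

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.values.loc[a, b])

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            self.values.to_csv(fh, sep="\t", float_format="%.6f")


def similarity_matrix(cluster_set: ClusterSet) -> ContentSimilarityMatrix:
    """All-pairs content similarity; genomes with zero clusters are excluded
    with a warning."""
    import warnings

    membership: dict[str, set[str]] = {g: set() for g in cluster_set.taxa}
    for cid, members in cluster_set.clusters.items():
        for genome, _ in members:
            membership[genome].add(cid)
    empty = sorted(g for g, s in membership.items() if not s)
    if empty:
        warnings.warn(f"genomes with zero clusters excluded: {empty}")
        for g in empty:
            del membership[g]
    genomes = sorted(membership)
    n = len(genomes)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            s = content_similarity(membership[genomes[i]], membership[genomes[j]])
            mat[i, j] = mat[j, i] = s
    values = pd.DataFrame(mat, index=genomes, columns=genomes)
    counts = {g: len(membership[g]) for g in genomes}
    return ContentSimilarityMatrix(genomes, values, counts)


def rank_neighbors(
    matrix: ContentSimilarityMatrix, focal_genome: str
) -> list[tuple[str, float, int]]:
    """Genomes ranked by similarity to the focal genome, descending.

    Ties share the smallest rank (competition ranking) and are listed in
    lexicographic genome order; the focal genome is excluded.
    """
    if focal_genome not in matrix.genomes:
        raise KeyError(focal_genome)
    sims = [
        (g, matrix[focal_genome, g]) for g in matrix.genomes if g != focal_genome
    ]
    sims.sort(key=lambda t: (-t[1], t[0]))
    out: list[tuple[str, float, int]] = []
    for i, (g, s) in enumerate(sims):
        rank = out[i - 1][2] if i and s == out[i - 1][1] else i + 1
        out.append((g, s, rank))
    return out
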