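"""Hypervariable-region extraction and translated comparison.

Hypervariable regions are located by their flanking features (e.g. between
the 23S and 5S rRNA genes, or between a tRNA-Ser and a tRNA-Ala), expanded
by a fixed flank on either side, and compared across genomes with an
internal translated similarity search: all six reading frames of both
regions are translated and scanned for seeded, ungapped, X-drop-extended
local alignments under BLOSUM62 — a deterministic miniature of a
tblastx-style comparison with fixed Karlin-Altschul constants
(lambda = 0.267, K = 0.041).  Hits below an E-value threshold are reported
and can be written as ACT-compatible crunch comparison files for stacked
visual comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq
from Bio.Align import substitution_matrices

from alphacomp.io_formats import GenomeAnnotation

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_B62 = {
    (a, b): int(_BLOSUM62[a, b])
    for a in _BLOSUM62.alphabet
    for b in _BLOSUM62.alphabet
}

FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass(frozen=True)
class Region:
    """A chromosomal interval, 0-based half-open in replicon coordinates.

    ``wrapped`` marks a region that crosses the origin of a circular
    replicon; its coordinates then satisfy end > replicon length and the
    sequence is read modulo the length.
    """

    genome_id: str
    replicon_id: str
    start: int
    end: int
    anchor: str = ""
    flank_bp: int = 0
    wrapped: bool = False

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid region [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SearchParams:
    word_size: int = 3
    xdrop: float = 20.0
    evalue_threshold: float = 1e-10
    ka_lambda: float = 0.267
    ka_k: float = 0.041


@dataclass(frozen=True)
class TranslatedHit:
    query_frame: int
    subject_frame: int
    q_start: int   # nucleotide coords within the query region, forward strand
    q_end: int
    s_start: int
    s_end: int
    raw_score: int
    bits: float
    evalue: float
    pct_id: float

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ValueError("E-value must be > 0")


# ---------------------------------------------------------------------------
# Region location and expansion
# ---------------------------------------------------------------------------

def locate_between_features(
    annotation: GenomeAnnotation,
    left_query: str,
    right_query: str,
) -> Region:
    """Region between two uniquely matched features (end of left feature to
    start of right feature).

    Queries match case-insensitively against the product text or feature
    type of each gene record.  Exactly one match per query is required, both
    on the same replicon, left upstream of right (a circular replicon may
    wrap instead).
    """

    def matches(query: str):
        q = query.lower()
        return [
            g
            for g in annotation.all_genes()
            if q in g.product.lower() or q == g.feature_type.lower()
        ]

    hits_l, hits_r = matches(left_query), matches(right_query)
    for query, hits in ((left_query, hits_l), (right_query, hits_r)):
        if len(hits) != 1:
            found = ", ".join(g.gene_id for g in hits) or "none"
            raise ValueError(
                f"query {query!r} matched {len(hits)} features ({found}); need exactly 1"
            )
    left, right = hits_l[0], hits_r[0]
    if left.replicon_id != right.replicon_id:
        raise ValueError(
            f"flanking features on different replicons: "
            f"{left.replicon_id} vs {right.replicon_id}"
        )
    rep = annotation.replicons[left.replicon_id]
    anchor = f"{left.gene_id}..{right.gene_id}"
    if left.end <= right.start:
        return Region(annotation.genome_id, rep.replicon_id, left.end, right.start, anchor)
    if rep.circular and rep.length_bp:
        return Region(
            annotation.genome_id,
            rep.replicon_id,
            left.end,
            right.start + rep.length_bp,
            anchor,
            wrapped=True,
        )
    raise ValueError(
        f"left feature {left.gene_id} not upstream of {right.gene_id} on a linear replicon"
    )


def expand_region(
    region: Region,
    flank_bp: int,
    replicon_length: int,
    circular: bool,
) -> Region:
    """Add ``flank_bp`` on either side; clamp on linear replicons, wrap on
    circular ones (collapsing to the full replicon when flanks meet)."""
    if flank_bp == 0:
        return region
    if not circular:
        return Region(
            region.genome_id,
            region.replicon_id,
            max(0, region.start - flank_bp),
            min(replicon_length, region.end + flank_bp),
            region.anchor,
            flank_bp=flank_bp,
        )
    span = region.length + 2 * flank_bp
    if span >= replicon_length:
        return Region(
            region.genome_id,
            region.replicon_id,
            0,
            replicon_length,
            region.anchor,
            flank_bp=flank_bp,
            wrapped=True,
        )
    start = (region.start - flank_bp) % replicon_length
    return Region(
        region.genome_id,
        region.replicon_id,
        start,
        start + span,
        region.anchor,
        flank_bp=flank_bp,
        wrapped=start + span > replicon_length,
    )


def region_sequence(region: Region, replicon_seq: str) -> str:
    L = len(replicon_seq)
    if region.end <= L:
        return replicon_seq[region.start : region.end]
    return replicon_seq[region.start :] + replicon_seq[: region.end - L]


# ---------------------------------------------------------------------------
# Six-frame translated search
# ---------------------------------------------------------------------------

def _translations(seq: str) -> dict[int, str]:
    """Protein translation for each of the six frames (stops kept as '*')."""
    out: dict[int, str] = {}
    rc = str(Seq(seq).reverse_complement())
    for frame in FRAMES:
        src = seq if frame > 0 else rc
        off = abs(frame) - 1
        sub = src[off : off + 3 * ((len(src) - off) // 3)]
        out[frame] = str(Seq(sub).translate())
    return out


def _aa_to_nt(frame: int, aa_start: int, aa_end: int, nt_len: int) -> tuple[int, int]:
    """Map an aa interval in a frame to forward-strand nt coords."""
    off = abs(frame) - 1
    s, e = off + 3 * aa_start, off + 3 * aa_end
    if frame > 0:
        return s, e
    return nt_len - e, nt_len - s


def _extend(q: str, s: str, qi: int, si: int, w: int, xdrop: float) -> tuple[int, int, int]:
    """Ungapped X-drop extension of a word hit; returns (qstart, qend, score)
    as aa coordinates on the query (subject follows the same diagonal)."""
    score = sum(_B62[q[qi + k], s[si + k]] for k in range(w))
    best = score
    left = 0
    run, best_run, cut = score, score, 0
    i = 1
    while qi - i >= 0 and si - i >= 0:
        run += _B62[q[qi - i], s[si - i]]
        if run > best_run:
            best_run, cut = run, i
        if best_run - run > xdrop:
            break
        i += 1
    left = cut
    score = best_run
    run, best_run, cut = score, score, 0
    j = 0
    while qi + w + j < len(q) and si + w + j < len(s):
        run += _B62[q[qi + w + j], s[si + w + j]]
        if run > best_run:
            best_run, cut = run, j + 1
        if best_run - run > xdrop:
            break
        j += 1
    right = cut
    return qi - left, qi + w + right, best_run


def translated_search(
    seq_a: str,
    seq_b: str,
    params: SearchParams = SearchParams(),
) -> list[TranslatedHit]:
    """All significant translated local alignments between two nucleotide
    regions, sorted by score descending.

    The search space for E-values is the sum over all 36 frame pairs of the
    product of translated lengths: E = K * N * exp(-lambda * S).
    """
    w = params.word_size
    if min(len(seq_a), len(seq_b)) < 3 * w:
        raise ValueError(f"region shorter than {3 * w} nt")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    trans_a, trans_b = _translations(seq_a), _translations(seq_b)
    space = sum(
        len(trans_a[fa]) * len(trans_b[fb]) for fa in FRAMES for fb in FRAMES
    )
    bad = set("*X")
    hits: list[TranslatedHit] = []
    for fa in FRAMES:
        q = trans_a[fa]
        for fb in FRAMES:
            s = trans_b[fb]
            index: dict[str, list[int]] = {}
            for i in range(len(s) - w + 1):
                word = s[i : i + w]
                if not bad & set(word):
                    index.setdefault(word, []).append(i)
            covered: dict[int, int] = {}  # diagonal -> q end already extended
            seen: set[tuple[int, int, int, int]] = set()
            for qi in range(len(q) - w + 1):
                word = q[qi : qi + w]
                if bad & set(word):
                    continue
                for si in index.get(word, ()):
                    diag = qi - si
                    if covered.get(diag, -1) >= qi + w:
                        continue
                    qs, qe, raw = _extend(q, s, qi, si, w, params.xdrop)
                    covered[diag] = qe
                    # clamp against float underflow at very large scores
                    evalue = max(
                        params.ka_k * space * math.exp(-params.ka_lambda * raw),
                        1e-300,
                    )
                    if evalue >= params.evalue_threshold:
                        continue
                    ss, se = qs - diag, qe - diag
                    key = (qs, qe, ss, se)
                    if key in seen:
                        continue
                    seen.add(key)
                    ident = sum(1 for k in range(qe - qs) if q[qs + k] == s[ss + k])
                    qn = _aa_to_nt(fa, qs, qe, len(seq_a))
                    sn = _aa_to_nt(fb, ss, se, len(seq_b))
                    hits.append(
                        TranslatedHit(
                            query_frame=fa,
                            subject_frame=fb,
                            q_start=qn[0],
                            q_end=qn[1],
                            s_start=sn[0],
                            s_end=sn[1],
                            raw_score=raw,
                            bits=(params.ka_lambda * raw - math.log(params.ka_k))
                            / math.log(2.0),
                            evalue=evalue,
                            pct_id=100.0 * ident / (qe - qs),
                        )
                    )
    hits.sort(key=lambda h: (-h.raw_score, h.q_start, h.s_start, h.query_frame))
    return hits


# ---------------------------------------------------------------------------
# Multi-region comparison (ACT-style stack)
# ---------------------------------------------------------------------------

def write_crunch(hits: Iterable[TranslatedHit], path: str | Path) -> None:
    """Crunch dialect: ``score qstart qend sstart send pct_id`` per line
    (scores as integer bits), consumable by the Artemis Comparison Tool."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{int(round(h.bits))} {h.q_start} {h.q_end} "
                f"{h.s_start} {h.s_end} {h.pct_id:.1f}\n"
            )


def region_comparison_matrix(
    regions: Sequence[tuple[str, str]],
    params: SearchParams = SearchParams(),
    outdir: str | Path | None = None,
) -> dict[tuple[str, str], list[TranslatedHit]]:
    """Compare regions pairwise; ``regions`` is an ordered list of
    ``(region_id, nucleotide_sequence)`` as in an ACT stack.

    Returns hits for every unordered pair (keyed in chain order); when
    ``outdir`` is given, writes one crunch file per *adjacent* pair.
    """
    results: dict[tuple[str, str], list[TranslatedHit]] = {}
    ids = [rid for rid, _ in regions]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate region ids")
    for i, (id_a, seq_a) in enumerate(regions):
        for id_b, seq_b in regions[i + 1 :]:
            results[(id_a, id_b)] = translated_search(seq_a, seq_b, params)
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for (id_a, _), (id_b, _) in zip(regions, regions[1:]):
            write_crunch(results[(id_a, id_b)], out / f"{id_a}__{id_b}.crunch")
    return results
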