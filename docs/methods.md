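# Methods

`alphacomp` computes the comparative-genomic similarity measures used to
decide whether a divergent genome belongs with a candidate clade — the
question that arises, for example, for the marine alphaproteobacterium
HIMB59 and the SAR11 (Pelagibacterales) clade, where AT mutation pressure
and fast sequence evolution can make unrelated lineages look alike.  The
package separates four independent lines of evidence (gene content, gene
order, protein-level composition, and hypervariable-region homology) and
pairs them with a genome-evolution simulator so every statistic can be
validated against known ground truth.

## Statistics

**Gene-content similarity.**  For genomes A and B with cluster repertoires
C_A and C_B (the ortholog clusters each genome has at least one member in),

    S(A, B) = |C_A ∩ C_B| / min(|C_A|, |C_B|)

Copy number is ignored (the index is defined over clusters, not genes) and
singleton clusters count toward their genome's repertoire.  The min
denominator makes the index insensitive to genome-size asymmetry but also
means a genome with a very small repertoire can look similar to everything;
rankings should therefore be read jointly with the synteny and composition
measures.  An open question in the definition is whether "smallest genome"
means fewest clusters or fewest base pairs; we use cluster count, which is
the quantity the formula itself is defined over.

**Synteny fraction.**  Both genomes' gene orders are first restricted to
the shared genes (one-to-one ortholog pairs from single-copy cluster
co-membership, or reciprocal best hits).  A shared gene is syntenic when at
least one of its adjacent shared genes in A maps to a gene adjacent to its
own image in B.  Adjacency is orientation- and strand-free (a fully
reversed order scores 1.0) and circular replicons close the adjacency
ring.  The fraction of syntenic shared genes is reported.  Config flags
switch to a stricter both-neighbours rule; the one-sided rule is the
default because it is the weakest symmetric reading of "same nearest
neighbour".  The expected value for a random permutation of n shared genes
is small (≈ 0.08 at n = 50) and decreases with n.

**Normalized bit score.**  Protein identity for a genome pair is the mean
over shared genes of bit(A vs B) / min(bit(A vs A), bit(B vs B)), clipped
to [0, 1].  Raw scores are Smith-Waterman local alignments under BLOSUM62
with gap open 11 / extend 1 (Biopython's PairwiseAligner); bits follow the
Karlin-Altschul conversion (λ = 0.267, K = 0.041), the standard gapped
constants for this scoring system.  Fixed constants keep results
deterministic and independent of any external aligner.  The min-self
denominator keeps the measure symmetric.

**Taxonomic pair classes.**  Each genome pair is assigned the most specific
shared rank (within genus / family / order, between orders) from a
taxonomy table, so a focal pair's (identity, synteny) point can be read
against the background cloud of its divergence class.  Outlier flagging is
a per-class Tukey fence: a pair strictly outside median ± 1.5×IQR limits on
either axis.

**aminoGC.**  The fraction of residues belonging to G, A, R, P — the amino
acids whose codon families (GGN, GCN, CGN, CCN) carry G/C in the first two
codon positions.  Low aminoGC is the protein-level footprint of AT
mutation pressure; gene sets with heterogeneous aminoGC across lineages
are the ones prone to compositional attraction artifacts in phylogenies.
Gaps and ambiguity codes (B, Z, X, J, U, O) are excluded from numerator
and denominator so alignment columns with missing data do not dilute the
statistic.  Arginine also has AGR codons; an Arg-free set {G, A, P} is
available for sensitivity analysis (`gc_set` argument / `--exclude-arg`).

**Hypervariable-region comparison.**  A region is located between two
uniquely matched flanking features (e.g. 23S rRNA → 5S rRNA, or
tRNA-Ser → tRNA-Ala), optionally expanded by a fixed flank (default
20 kb) with clamping on linear and wrap-around on circular replicons, and
compared by an internal translated search: all 6×6 frame pairs are scanned
for exact 3-mer seeds extended ungapped with an X-drop of 20.  E-values use
E = K·N·exp(−λS) with the search space N summed over frame pairs; the
default reporting threshold is E < 1e-10.  The engine is deterministic and
ungapped — it is a screening tool for presence/absence of translated
similarity, not a substitute for a full gapped tblastx when alignment
details matter; an empty hit list at this threshold is the operative
negative result.

## Cluster curation

Threshold filtering keeps clusters with ≥ min_taxa genomes, ≤ max copies
per genome and ≤ max_genes members (the classic pre-phylogenomics ladder;
a 135-genome study would use e.g. 130 / 3 / 142).  Pan-orthologs are the
clusters with exactly one copy in every genome.  Paralog resolution uses
the cluster's gene tree: paralogs of one genome forming a clean clade keep
the copy with the shortest terminal branch (ties: lexicographically
smallest gene id); ingroup copies inside the outgroup's subtree are
removed; paralogs at genuinely different positions invalidate the whole
cluster; outgroup species with scattered copies lose all of them.
"Clustered together" is operationalized as monophyly of that genome's
leaves — the weakest reading consistent with the rule.  The outgroup
subtree is the bipartition side containing all outgroup leaves with the
fewest extras; the scattered-outgroup rule is applied before rooting,
because a scattered outgroup species is exactly what breaks outgroup
monophyly.  Discordance flagging marks a cluster discordant when its tree
contains a bipartition with support ≥ 0.9 (configurable; 0–100 scales are
normalized, unannotated edges count as fully supported) that is
incompatible with the species tree on the shared leaf set.  This is the
standard realization of "discordance filtering"; published pipelines vary
and the threshold is exposed rather than claimed.

## The simulator

`SimulationConfig` defines the study conditions; the whole dataset is a
pure function of the config, including the seed.

- **Species tree**: pure-birth (Yule), `birth_rate` 1.0, `n_taxa` 12 by
  default; the root is the first bifurcation and one extra exponential
  waiting time after the n-th lineage keeps terminal branches positive.
  Expected root-to-tip depth is Σ_{k=2..n} 1/(k·b).
- **Gene content**: per gene and unit branch length, loss 0.12, gain 0.06,
  duplication 0.01 (tandem, same cluster).  From a root complement of 250
  genes over a depth-~2.4 tree this yields pairwise content similarities of
  roughly 0.55 (between distant taxa) to 0.95 (sister taxa) — the realistic
  range for a single bacterial class with genome streamlining.
- **Gene order**: one circular replicon (a flag adds a second, linear one);
  per genome and unit branch length, 6 segment inversions and 2
  translocations, giving synteny ≈ 0.95 within recent clades down to
  ≈ 0.5–0.7 between distant taxa.
- **Sequences**: proteins are simulated directly as amino-acid strings
  (length ~ N(120, 30²), floor 30) with per-site replacement probability
  1 − exp(−subst_rate·t), subst_rate 0.35.  Replacement targets follow a
  frequency vector in which the weight of {G, A, R, P} is multiplied by
  (1 + gc_bias): gc_bias −0.8 drives equilibrium aminoGC to ≈ 0.05 versus
  0.20 unbiased.  There is no codon layer — the downstream composition
  statistic is amino-acid-level, so a nucleotide layer would add nothing
  testable — and no indels.
- **Lineage overrides** (gc_bias, rate multiplier) attach to taxa and apply
  to every branch whose descendant leaves all carry the same override: a
  flagged clade is biased including its internal edges, a single flagged
  taxon only on its terminal branch.
- **Rogue preset** (`rogue_lineage_preset`, CLI `--preset himb59-like`):
  one clade of ~5 taxa gets gc_bias −0.8; one maximally distant outside
  taxon gets gc_bias −0.8 plus a 3× rate multiplier.  This reproduces the
  central confound at desk scale — a fast-evolving, compositionally
  convergent rogue — and the content/synteny metrics should *not* group the
  rogue with the clade even though composition does.

What the simulator does not emulate: horizontal transfer, indels,
intergenic architecture, rate variation across sites and genes, codon-level
composition.  Passing tests therefore demonstrate the statistics' internal
correctness and their behavior under gain/loss/rearrangement/composition
regimes, not performance on real annotation noise (missed genes,
frame-shifts, chimeric clusters).

## Numerical and design choices

- Coordinates are 0-based half-open everywhere; GFF3 (1-based inclusive)
  is converted at the boundary, a tested bijection.  Gene order is the
  sort by (start, end, gene_id); overlapping genes are allowed.
- Gene ids are namespaced `genome|locus` to match the orthoMCL groups
  dialect, which is the join key across files.
- RBH clustering prefilters candidate hits by shared 3-mer counts (top 5
  candidates) before Smith-Waterman, then links mutual best hits and takes
  connected components; ties are broken toward the lexicographically
  smallest id.  At zero divergence this recovers the true clusters exactly;
  at 15% per-site divergence it recovers ≥ 95% of them.
- E-values below 1e-300 are clamped to keep them positive under float
  underflow at very large self-alignment scores.
- The rank test used to ask whether the rogue's synteny to the focal clade
  is elevated treats pairs as independent; they are not (rearrangement
  counts are shared along internal branches), so its p-value is
  anti-conservative across random tree draws.  At the fixed preset seed the
  qualitative conclusion is stable; across arbitrary seeds clade-level
  Poisson noise in rearrangement counts can nominally tip it either way.
  This pseudo-replication is intrinsic to the pairwise design, in real
  data as much as in simulation.

## Problem sizes

Default test and acceptance runs use 6–12 taxa, 30–250 genes per genome,
and proteins of ~50–120 residues; Monte-Carlo checks use 50–1000
replicates.  These sizes were chosen so the full validation cycle completes
in well under a minute while keeping every statistic's sampling noise far
below the asserted effect sizes.
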