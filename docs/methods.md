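# Methods

This note records the models, conventions and numerical choices behind
`mitocomp`, in the order the pipeline applies them.

## Coordinates and circular genomes

Feature files use 1-based inclusive coordinates (the GenBank/annotation
convention); all internal arithmetic is done on 0-based half-open
segments, which makes length accounting unambiguous. An origin-spanning
feature of a circular genome is encoded as a single row with
`start > end` and means `start..L` followed by `1..end`; internally it is
split into two linear segments. Annotation tools do not report
origin-spanning features uniformly, so this convention is a package
choice, not an ecosystem standard — it round-trips losslessly through
both supported dialects (the five-column TSV and the GFF3 subset, whose
extra attributes are preserved opaquely).

All coverage accounting is **strand-blind**: both strands project onto a
single axis before overlap removal. The genic length of a genome is the
length of the union of all feature intervals; the intergenic length is
the genome length minus that union, so the two always sum exactly to the
genome length, on both topologies and under any rotation of a circular
genome's origin. GC content is computed over non-N bases only (N bases
excluded from the denominator), so gappy sequences do not deflate GC.

Two overlap statistics are computed between feature categories because
both are scientifically meaningful and genuinely different:

- *within*: the fraction of A features fully contained in the union of
  B (a wrapped feature must have both of its segments contained);
- *overlap*: the fraction of A features sharing at least 1 bp with the
  union of B.

Each A feature is counted once per mode regardless of how many B
features it touches, and dataset-level fractions pool the **counts**
across genomes (not the per-genome fractions), so large genomes weigh in
proportion to their feature load.

## Feature triage

Categories are assigned by a fixed precedence: annotated name (core
gene, rRNA, *rps3*, tRNA by `trn`/`tRNA` prefix, intron with its class
parsed from the name) → nucleotide identity to a reference panel
strictly above 0.80 (HEG/*dpo*/*rpo*; the highest identity wins, ties
across classes demote to `other` with a warning) → protein-domain hit of
a HEG family (LAGLIDADG, GIY-YIG, H-N-H) → any other domain hit
(`domain_orf`) → `uORF`. Identity thresholds are strict inequalities
("above 50%", "above 80%"). Domain hits are accepted at e-value ≤ 0.01
by default (configurable; no canonical cut-off exists for this step).

Core-gene presence (16 columns: 14 protein-coding genes + *rns* +
*rnl*, in a fixed documented order) is name-based, with a similarity
rescue: an unannotated gene counts as present when a local alignment to
any reference sequence of that gene exceeds 0.50 identity **and** covers
at least half the reference length. The coverage requirement is an
extension: without it, a 20 bp high-identity fragment would "rescue" a
gene, which cannot be the intent of a presence call. Setting the
identity threshold above 1 disables the rescue and degenerates to
name-only presence.

## Alignment

Scoring defaults are BLASTn-like analog knobs: match +1, mismatch −2,
and an affine gap of length L costing 5 + 2L. Pairs where both
sequences are ≤ 2,000 bp are aligned by exact affine-gap Smith–Waterman
(delegated to Biopython's C aligner; an independent C engine,
scikit-bio's, verifies optimality in the test suite). Longer pairs use
a seed-and-extend path: exact 11-mer seeds (vectorized 2-bit hashing;
words occurring > 40 times are skipped), grouping into diagonal bands
(width 48, split at positional gaps > 3 kbp), and then either a small
exact DP on the enclosing window (spans ≤ 500 bp) or collinear anchor
chaining. The chain is a windowed dynamic program maximizing anchored
length with a penalty of 0.5 per diagonal unit jumped — this is what
stops an isolated spurious seed that happens to lie in the same band
from hijacking the chain. Inter-anchor gaps are closed by exact global
alignment (single-column gaps in closed form); gaps larger than 500 bp
split the alignment into separate HSPs; ends are extended ungapped with
an X-drop of 20.

Two identity definitions coexist and are never conflated:

- `hsp_identity` = identical columns / alignment columns of one
  continuous local alignment (HSP);
- `clustering_identity` = identical columns of the best local alignment
  / length of the shorter sequence, capped at 1 — the global-identity
  convention of greedy incremental clusterers, which makes an exact
  substring score 1.0 against its parent.

Both strands are always searched (reverse complement of the second
sequence), since database deposits have arbitrary strand and origin.

## Redundancy clustering

Greedy incremental clustering in CD-HIT's semantics: genomes sorted by
length descending (ties by id), each compared only against existing
**representatives** in creation order, joining the first one at
`clustering_identity ≥ t` (default t = 0.90), else founding a new
cluster. Representatives form the non-redundant set used by every
downstream stage. Because members are compared only to representatives,
a chain of pairwise-similar genomes can split across clusters — the
standard, documented divergence from exhaustive clustering. A cheap
shared-11-mer prescreen (both strands) skips alignments for pairs whose
shared-word fraction is below 1% — far below what any pair near a usable
threshold can show (uniform divergence at 70% identity still preserves
≈ 2% of words, while unrelated multi-kbp genomes share ≈ 0.3–0.7% by
chance); it applies only above the exact-alignment size limit and can be
disabled.

## Similarity network

For every unordered pair of genomes, all HSPs over both strands are
collected and exactly one edge is drawn, carrying the identity of the
**length-maximal** HSP (ties: more matches, then smaller start). This is
deliberate: when a pair aligns in several segments, the longest
continuous alignment defines the pair's similarity index even if a
shorter segment aligns at higher identity. A score-maximal variant is
available as a configuration toggle (`rule="best_score"`), since
"longest" and "best-scoring" differ precisely in those multi-segment
cases. Edge filters (minimum identity, minimum HSP length) default to
off; network-level summaries use connected components.

## Statistics

- **Pearson correlation**: product-moment r with the two-sided p-value
  from t = r·√((n−2)/(1−r²)) against Student-t with n−2 df (computed via
  scipy; the test suite checks the closed form to 1e−12). Correlations
  involving uORF lengths support a log10 transform, since uORF loads are
  heavy-tailed; genomes with a zero value are dropped under the
  transform (they have no such element to measure).
- **Wilcoxon rank-sum**: statistic is the rank sum of the first sample
  with midranks for ties. When n₁+n₂ ≤ 12 and there are no ties, the
  two-sided p is exact by enumeration of all rank assignments; otherwise
  a normal approximation with the midrank tie correction and a 0.5
  continuity correction. All tests are two-sided.
- **Patristic distances**: leaf-pair path-length sums on a Newick tree
  with branch lengths (via dendropy); a missing branch length or a
  duplicate leaf label is an error, and the matrix is invariant to the
  rotation of children.

Group summaries report mean ± SD per phylum.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical regimes the analysis assumes,
at a ten-fold length scale-down so exhaustive per-base and DP oracles
stay fast. Defaults (the study conditions):

| parameter | default | rationale |
|---|---|---|
| genome length | lognormal, median 6.4 kbp, σ = 0.5, clipped to 4–27.2 kbp | 10× scale-down of the tens-of-kbp regime; the floor is raised so the full core complement always fits, and a genome in the low tail is expanded just enough to keep ≥ 5% intergenic space |
| topology | 94.8% circular | linear mitogenomes are a small minority (≈ 5%) |
| genetic codes | 4: 62%, 1: 22%, 3: 10%, 16: 6% | code 4 dominates fungal mitochondria; the remainder split is a plausible choice |
| GC | Normal(0.25, 0.05), clipped 0.10–0.60 | fungal mtDNA is AT-rich (≈ 25% GC) with rare extreme outliers |
| core dropout | 0.0317 per gene | yields ≈ 36% of genomes missing ≥ 1 core gene |
| *rps3* presence | 0.8 | present in most but not all taxa |
| introns / HEGs / uORFs | Poisson means 8.0 / 8.0 / 8.2 per genome | the per-genome averages of the emulated regime |
| HEG embedding | 0.4346 | the share of HEGs lying inside introns |
| HEG families | LAGLIDADG 77.8%, GIY-YIG 21.9%, H-N-H 0.3% | LAGLIDADG dominates; H-N-H is rare |
| intron classes | IB 45%, II 20%, IA 15%, ID 10%, IC2 6%, IC1 4% | IB most common, IC1 least; per-intron frequencies chosen once |
| dpo / rpo | Poisson 0.4 / 0.15 | occasional plasmid-derived genes |
| coupling | 0.5 | accessory means scale as (L/median)^(2·coupling), producing the positive length-load correlations |

Layout is constructive, not rejection-sampled: present core genes, tRNAs
and free-standing elements are placed left-to-right with
Dirichlet-split intergenic gaps (so placement always succeeds and is
exactly reproducible under the seed); introns sit inside host genes,
embedded HEGs inside their own introns; circular genomes are then
rotated by a random offset, which is what exercises origin-wrapping
features downstream. Feature sequences are random DNA with planted
start/stop codons (ATG…TAA; TAA is a stop under all four supported
codes) — classification is name- and hit-driven, so sequence-level
homology realism is unnecessary, and the generator makes no attempt at
it. Consequences for interpretation: passing tests demonstrate the
correctness of the accounting, triage, clustering and network machinery
on data with the right statistical shape; they say nothing about
annotation quality, real codon usage, phylogenetic signal, or repeat
content, none of which the generator models.

`mutate_copy` diverges a genome toward a target identity by spending the
divergence budget 90% on substitutions and 10% on indels (geometric
block lengths, mean 3 bp, insertions and deletions equally likely); the
realized clustering identity tracks the target within a few percent at
a few kbp. `plant_families` builds one ancestor per family plus mutated
copies; a copy is redrawn (bounded retries) if it ends up at least as
long as the ancestor, so the ancestor is deterministically the longest
member — and therefore the greedy representative, which makes member
identities to the representative equal the family's target rather than
the square of it.

## Pipeline

Stage order: load → QC → redundancy filter → triage → presence →
accounting/overlaps → correlations → network. The redundancy filter
runs **before** all statistics, so every number downstream describes the
non-redundant set. QC excludes genomes with > 20% N bases or shorter
than 2 kbp, each with a logged reason. Any stage failure aborts with
the stage name and leaves a `RUN.partial` marker next to whatever
outputs were already written; a completed run removes the marker and
writes a manifest (versions, seed, parameter echo, per-stage record
counts and timings). Reruns with the same inputs and seed are
byte-identical except for the manifest's timings.

The acceptance script runs this pipeline on 64 generated genomes plus 8
near-duplicates (95% identity, removed by the filter) and 3 divergent
relatives (80% identity, retained and connected by the network) — sizes
chosen to exercise every stage while keeping a full from-scratch run in
the minutes range on one CPU.

## Known limitations

- The seed-and-extend path guarantees optimality only where the exact
  path runs (both sequences ≤ 2 kbp); above that, scores are heuristic,
  though calibrated (family-identity tests) and chain-protected against
  seed hijacking.
- Clustering identity between co-optimal alignments is tie-dependent at
  the level of a column or two; symmetry holds only up to tie-breaking.
- E-value statistics for HSPs are out of scope; network sparsification
  relies on explicit identity/length filters instead.
- The GFF3 reader handles the subset the pipeline emits (single-line
  features, `Name`/`ID` attributes, origin wrap as `start > end`); it is
  not a general GFF3 parser and does not interpret multi-segment
  (joined) locations.
- Intron classes are taken from annotation names; no secondary-structure
  classification is attempted.
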