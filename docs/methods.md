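# Methods

`plastevo` re-implements, as a tested pipeline, the comparative analyses used to study
structural degradation of plastid genomes in lineages that abandon photosynthesis
(mycoheterotrophic orchids being the motivating system): quadripartite/IR structure,
gene and pseudogene content over a fixed reference catalogue, staged gene loss, minimal
retained gene sets, gene-order rearrangement blocks, and Dollo-parsimony loss mapping
on a fixed phylogeny. This note records the models, the tunable parameters, and the
choices made where the procedure was genuinely open.

## The reference gene catalogue

A canonical angiosperm plastome carries 113 distinct genes: 6 *atp*, 11 *ndh*, 6 *pet*,
9 *rpl*, 4 *rpo*, 12 *rps*, 4 *rrn*, 5 *psa*, 15 *psb*, 30 *trn* and 11 ungrouped genes
(*accD*, *ccsA*, *cemA*, *clpP*, *infA*, *matK*, *rbcL*, *ycf1*–*ycf4*). Published
class sizes fix the totals but not the full roster; the packaged roster
(`plastevo/data/reference_genes.tsv`) follows the canonical tobacco-like gene list that
satisfies those sizes and is user-overridable (`ReferenceGeneSet.from_table`). The
intron catalogue comprises the 16 one-intron genes (*atpF*, *ndhA*, *ndhB*, *petB*,
*petD*, *rpl2*, *rpl16*, *rpoC1*, *rps12*, *rps16*, *trnA-UGC*, *trnG-UCC*,
*trnI-GAU*, *trnK-UUU*, *trnL-UAA*, *trnV-UAC*) plus *clpP* and *ycf3* with two each —
20 introns. *rps12* is stored as one gene; its trans-spliced structure is exempt from
the exon-contiguity invariant. The *trnC* anticodon appears in print both as GCA and
GGA; the catalogue uses trnC-GCA and the name normalizer maps the GGA variant to it.

## Inverted-repeat detection

`detect_inverted_repeat` finds the maximal pair of disjoint segments of a circular
sequence that are reverse complements of each other. Exact k-mer seeds (k = min(31,
min_len)) of the reverse complement are collected on the doubled sequence and grouped
by the antidiagonal a+b, which is invariant along a reverse-complement match; maximal
runs of consecutive seeds give maximal exact matches. A self-overlapping match is a
self-reverse-complementary region (two IR copies head-to-head with no SSC); the usable
disjoint pair is derived by trimming (length = floor((t−s+M)/2)). Ties are broken
toward the pair with the smallest single-copy arc (most SSC-like), then by position —
deterministic, and invariant under rotation of the origin and reverse complementation
of the genome.

Classes: best pair < `min_len` → `single_copy_only` (IR-less genomes); one empty arc →
`no_SSC_tripartite` (head-to-head IRs); otherwise `quadripartite`, the longer arc being
the LSC. `min_len` defaults to 100 bp — small enough to admit a residual 261 bp IR,
large enough to reject incidental repeats. `max_mismatch_rate` (default 0.0; 0.01
suggested for real records) enables greedy outward extension of the best exact pair.
The two flanks are extended in alternation and a flank stops at a local mismatch
cluster (two mismatches within 20 steps) or when the global mismatch fraction would
exceed the rate; the local rule prevents one noisy flank from consuming the budget
that the other flank's true repeat needs. The recovered length under mismatches is
approximate by nature (± a few tens of bp of overshoot into flanking sequence); exact
inputs are recovered exactly.

Junctions JLB, JSB, JSA, JLA are the four region boundaries, reported as the 1-based
position of the first base of the downstream region. A junction lies between two
bases; a feature containing either abutting base overlaps it (offset 0). Otherwise the
offset is the circular distance to the nearest feature boundary, signed toward the IR
(negative = single-copy side), following the convention of IR-junction survey figures.

## Gene and pseudogene status

For protein-coding genes the spliced sequence in reading orientation is examined:

- **present** — valid start (ATG, or the alternative starts ACG/TTG known from plastid
  transcripts, recorded as `alt_start` evidence), length ≡ 0 mod 3, and no internal
  stops; or 1–5 internal stops, every one an "editable" UGA. Plastid C→U editing at
  the first position of an arginine CGA codon routinely produces internal UGA at the
  RNA level in functional genes, so a genomic TGA may be an edited codon; TAA/TAG have
  no such single-edit origin and are treated as real stops. This is one defensible
  formalization of "gene sequences with few internal stop codons for which RNA editing
  was possible"; no editing database is consulted.
- **pseudogene** — more than five internal stops; a frame length not divisible by
  three (an uncompensated frameshift — compensating indel pairs restore the length and
  are then judged by the stop-codon rule); a length deviating from the reference by
  more than `large_indel_bp` (default 30 bp, config-exposed); a missing start; or an
  explicit `/pseudo` annotation.
- **absent** — no feature.

The terminal codon is never counted as internal; selenocysteine/readthrough are not
modeled. tRNA/rRNA genes are called by length against the catalogue (within 20%).
Genes present only as IR duplicates count once per genome; when the two copies
disagree the better-supported status wins (present > pseudogene).

## Degradation stages

Plastome degradation proceeds in stages rather than on a continuum: first the 11-gene
*ndh* class; then the photosynthesis light-reaction machinery (*pet*, *psa*, *psb*)
together with the plastid-encoded polymerase (*rpo*); finally the housekeeping
apparatus (*rpl*, *rps*, *trn*, …), leaving a ~27–33 gene core. The empirical count
clusters — at least 55 functional genes in stage 2, at most 33 in stage 3 — set the
default thresholds (`StageThresholds`, all config-exposed). Pseudogenes count as
nonfunctional throughout.

Rules are applied in order so every one of the 3^113 possible rows resolves:

1. `stage3_housekeeping` — ≤ 33 functional genes;
2. `stage1_ndh` — ≥ 4 of 11 *ndh* nonfunctional with ≤ 3 non-*ndh* losses. This is
   checked before the photosynthesis rule because the stage-1 pattern explicitly
   includes "all 11 *ndh* plus one or two other genes"; a genome losing *ndh* plus a
   single *psbD* is an *ndh*-stage genome, not a stage-2 one;
3. `intermediate` — ≥ 3 nonfunctional housekeeping genes (rpl/rps/trn/rrn) together
   with photosynthesis losses, above the stage-3 count. Housekeeping erosion overrides
   the ≥ 55 count threshold: a genome with 66 functional genes but several rpl/rps/trn
   losses sits between stages 2 and 3, while a stage-2 genome with a single incidental
   *rpl* loss stays stage 2;
4. `stage2_photo` — any *pet*/*psa*/*psb*/*rpo* loss with ≥ 55 functional genes (or,
   between the clusters without housekeeping erosion, `intermediate`);
5. `near_full` — 1–3 nonfunctional genes; `full` — otherwise.

`minimal_common_genes` is the intersection of present-status genes over a taxon subset
(pseudogene ≠ present); it is monotone non-increasing under subset growth.
Correlation summaries report squared Pearson correlations per metadata-defined group;
groups under three members are skipped with a warning and zero-variance pairs are
reported as undefined rather than 0 or 1. The published mycoheterotroph subset is not
enumerated in print, so those r² values are reproduced qualitatively (strong LSC
correlation exceeding the IR correlation), not as an exact gate.

## Gene-order blocks

Rearrangements are assessed at gene granularity: each genome reduces to a circular
signed gene order (sign = strand; IR duplicates collapsed to the IRb copy; order
starting at JLA). A block is a maximal run of reference genes contiguous and
consistently oriented in every taxon carrying all of its genes; taxa missing a member
gene are not-applicable; a block is constant when all applicable orientations agree.
Blocks are built greedily left-to-right along the reference order, which anchors the
segmentation (deterministic); the other orders are treated as fully circular, so their
rotation is irrelevant. Genomes missing more than 60% of reference genes are excluded
(config-exposed), mirroring the exclusion of extremely reduced genomes from
whole-genome alignment studies. Nucleotide-level aligner block counts depend on
aligner parameters and full sequences; gene-granularity counts are not expected to
match them and are not used as acceptance gates.

## Dollo loss mapping

Each gene is ancestrally present (root state functional) and can only be lost — no
regain. The unique minimum-loss reconstruction places one event on the edge subtending
every maximal all-nonfunctional clade; if all tips are nonfunctional the single event
sits on the root edge. Pseudogene and absent collapse to nonfunctional by default
(non-functionalization is the plotted character); an optional ordered three-state mode
additionally maps the pseudogene → absent transition as a second no-regain character.
Polytomies are handled natively. Edges are named by the smallest tip label of their
child clade. The mapper is verified against an exhaustive oracle (all minimum edge
subsets realizing the tip states) on all 4- and 5-tip rooted binary trees and seeded
6-tip trees, over every state vector. Robinson–Foulds comparison of two trees restricts
both to their shared tips (≥ 4) and counts bipartitions present in exactly one tree;
"conflicting tips" are found greedily by removing the tip whose removal most reduces
the distance.

## The synthetic-genome generator

`simulate_plastome` states a typical photosynthetic-orchid plastome: 150 kb genome,
26.5 kb IR containing the rrn block, 18 kb SSC, 37% GC — the central values of the
published accession tables. The 113 genes are laid out in a canonical order with psbA
near JLA, ndhF opening the SSC flush at JSB and ycf1 closing it flush at JSA, so
junction analyses mirror real genomes. Gene sequences are synthetic ORFs (random sense
codons, valid start, terminal stop) — status calling depends only on frame properties,
so homology-level realism is deliberately not simulated. Stage presets state the
published degradation patterns down to a ~36 kb, IR-less, 28-gene stage-3 genome with
AT-shifted composition (GC 30%).

Degenerate geometries follow the real mechanisms: an IR too small for its genes pushes
them into the LSC (residual-IR genomes); an SSC too small for its genes is engulfed by
the IR (SSC contraction by IR expansion); `ir_length: 0` produces a single-copy
genome. The four bases flanking the IR copies are pinned to non-complementary values
so the planted repeat cannot extend by chance — planted IR lengths are therefore
recovered *exactly*, which the tests rely on. Pseudogenization modes: `stops_k`
(k premature TAA stops), `frameshift` (1 bp deletion), `large_indel` (in-frame ≥ 33 bp
deletion). Inversions reverse-complement a gene-range segment and flip the contained
features. Every record carries a ground-truth sidecar; the same seed yields
byte-identical output.

What a green synthetic test does **not** establish: performance on real annotation
dialects beyond the synonym table, IRs with internal duplications or gene conversion
tracts, trans-splicing, transcript-level evidence for pseudogene rescue, or
nucleotide-level rearrangement breakpoints inside genes.

## Packaged published tables

Three printed tables ship as TSV fixtures: per-accession features of the 129 study
genomes (124 orchids + 5 outgroups), the 24 newly sequenced genome lengths, and the
minimal-gene table (seven extremely degraded plastomes × 20 genes, plus each gene's
presence count over the other 117 orchids with the exception taxa named). For
set-intersection purposes the 117 are represented exactly by those named exception
taxa plus one representative row — a gene is shared by all 124 iff it is present in
the seven and its count is 117/117. Two in-print inconsistencies are resolved in favor
of the tables: the text's 890 bp SSC for the smallest genome (table prints 8,907) and
the discussion's *rpl26*/*trnC-GGA* spellings of the 15-gene list (*rpl36*/*trnC-GCA*
per the table).

## Known limitations

- The status caller sees only the annotated sequence; genes absent from the annotation
  but present in the sequence are called absent (annotation quality is the ceiling).
- Mismatch-tolerant IR boundaries are approximate (greedy extension); only exact
  repeats have exact boundaries.
- The large-indel rule needs a reference length; without one, only frame and stop
  evidence applies.
- Real-accession IR values require downloading the records; offline, the same
  geometries are verified on planted synthetic genomes instead.
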