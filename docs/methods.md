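# Methods

## Gene-structure annotation

Each amplicon is annotated by projection from a single annotated
reference copy.  The query is aligned to the reference globally
(affine gaps; match +2, mismatch −3, gap open −5, gap extend −2, where
a gap of length *k* costs `open + (k−1)·extend`; the aligner's first
reported optimum is taken, which is deterministic for fixed inputs).
Every reference exon/intron boundary is mapped through the alignment as
the leftmost query residue aligned at or after the boundary, then each
intron boundary is snapped to the nearest position within
`snap_window = 6` bp at which the intron starts `GT` and ends `AG`.  A
boundary with no canonical dinucleotide in the window is kept at its
projected position and flagged as a warning, never a failure — clean
sequences should not reach that path, and degraded ones deserve human
eyes rather than a guess.

An intron whose projected span falls below `min_intron_len = 20` bp is
recorded as *lost*: the segment collapses to the point where the
downstream exon resumes (the projection of the intron's 3′ boundary),
residual bases between the two boundary projections are absorbed by the
upstream exon, and the intron reports length 0.  Collapsing to the 3′
projection, rather than the 5′ one, keeps the total exonic length exact
under gap-placement ambiguity in the pairwise alignment, which matters
because the frameshift test below is a statement about exonic length.
Queries covering less than 50% of the reference are rejected.

The 20 bp floor separates true intron loss from short alleles: the
shortest spliceosomal introns known are ~20–30 bp, so anything smaller
cannot be a functional intron.

## Pseudogene detection

The concatenated exons are translated in the reference reading frame
(`frame_offset` = bases to skip before the first complete codon; the
built-in reference uses 0).  Any stop codon is internal, since the
amplicon is interior to the gene.  A frameshift is declared when the
exonic length differs from the reference's by a non-multiple of three.
IUPAC ambiguity codes translate as `X` and never count as stops.
Sequences with fewer than three exonic bases are reported
*undetermined*.  Frameshifted sequences skip the orthology screen —
amino-acid identity is meaningless downstream of a frameshift — and
keep their structural variant label, as is conventional for typed
pseudogenes.

## Structural variant typing

The primary rule is an absolute intron-4 length threshold:

| parameter | default | meaning |
|---|---|---|
| `tau4` | 300 bp | intron 4 shorter than this ⇒ "short" (1b/1c) |
| `intron5_lost_max` | 20 bp | intron 5 at or below this ⇒ lost (1c) |
| `deficit_min` | 260 bp | corroborating shortfall vs the reference intron 4 |

Observed intron-4 length ranges of the long form (403–484 bp) and the
short form (191–249 bp) are disjoint; 300 bp sits in the gap between
them.  The often-quoted "at least 260 bp shorter" phrasing is retained
only as a cross-check (`deficit_min`), because the printed ranges imply
a minimum observed deficit of 154 bp — the absolute-length rule is the
one that reproduces the published classes.  A long intron 4 with a
lost intron 5 matches no described form and is labelled
`unclassified`.  Typing is a pure function of intron lengths.

## Alignment statistics and distances

Gaps (`-`, `?`) and ambiguity codes are missing data throughout.  A
column is *variable* iff at least two distinct unambiguous bases occur,
and *parsimony-informative* iff at least two distinct bases each occur
in at least two sequences.  Percentages are reported to two decimals.

Uncorrected-P distance = mismatches / compared sites, compared sites
being those unambiguous in both rows (*pairwise deletion*) or in all
rows (*complete deletion*, matrix-wide).  A pair with zero comparable
sites is an error, not a distance of zero.

For tree building the pipeline defaults to **complete deletion**, and
for a substantive reason: this locus combines strong site-rate
heterogeneity (conserved exons, fast introns) with a large
structurally missing block (the intron-4 deletion that defines the
short gene form).  Under pairwise deletion, any taxon compared against
a short-form sequence loses exactly the fastest-evolving block from
its compared sites, so such distances are systematically compressed —
in simulation the outgroup appears ~0.01–0.04 closer to the short-form
clade than to the long-form clade purely through this artifact, enough
to drag its attachment inside the short-form clade in a large fraction
of bootstrap replicates and erode that clade's support.  Complete
deletion compares every pair on the same column set and removes the
asymmetry.  Pairwise deletion remains available (`--deletion
pairwise`) and is the default for standalone distance matrices, where
no cross-taxon comparability is implied.

The orthology screen translates query and reference exons, aligns the
proteins globally, and passes the query iff identity over aligned
non-gap columns is ≥ `identity_min = 0.90` across ≥ `min_aligned_aa =
100` residues.  No E-value is computed: the E-value of the original
database search belongs to the search engine, and identity is the
reproducible criterion.

## Neighbor joining and bootstrap

Standard Saitou–Nei agglomeration on the Q-criterion
`Q_ij = (m−2)·d_ij − r_i − r_j`.  Tie-breaking is lowest index pair,
applied over *mathematical* ties detected with a relative tolerance of
10⁻⁹ rather than exact float equality — necessary because at the
four-cluster stage complementary pairs always share the same Q
analytically, differing only in rounding, and exact-equality
tie-breaking would make the output depend on summation order.  Negative
branch-length estimates are clamped to zero with the deficit
transferred to the sister edge (the joined pair's distance is
preserved); reduced distances are internal bookkeeping and are not
clamped.  The final three clusters get closed-form pendant lengths,
clamped at zero.

Bootstrap: alignment columns are resampled with replacement; each
replicate's p-distance matrix feeds a fresh NJ tree; an internal
edge's support is the percentage of successful replicates containing
the same bipartition.  Replicates in which some pair loses all
comparable sites are skipped and counted, with a warning when more
than 5% are skipped.  Rows are put in a canonical (sorted-id) order
first, so supports are exactly invariant to the input leaf order.
Supports live on internal-node labels in [0, 100], the same place
Newick I/O reads and writes them.

Rooting on an outgroup requires the outgroup to form one side of an
edge of the unrooted tree.  Because rerooting rotates the node–edge
relationship, supports are re-attached afterwards by matching
bipartitions, which are rooting-invariant.  Without an outgroup the
pipeline midpoint-roots.

## Origin inference

Given a rooted support-annotated tree, major clades are defined by
exemplar sequences (by default, the diploid carriers of each variant
class: 1a-diploids anchor clade I, 1b/1c-diploids clade II).  A
sequence belongs to clade K iff it descends from the MRCA of K's
exemplars and from no other clade's MRCA; nested or ambiguous MRCAs
leave it unassigned.

Per individual:

* single recovered copy → `uninformative`;
* copies monophyletic (their MRCA subtends exactly them) →
  `autopolyploid_pattern`;
* copies non-monophyletic **and** assigned to ≥ 2 distinct major
  clades whose separation is well supported → `allopolyploid_pattern`;
* anything else → `uninformative`, with the reason recorded.

The support gate: for each involved major clade, the *separating
support* is the highest bootstrap value among edges whose clade
contains that clade's copies together with its exemplars while
excluding the individual's copies assigned elsewhere.  This is the
support of the claim "this copy is resolved inside this major clade,
apart from the individual's other copies".  It is deliberately not the
support of the exemplar-MRCA edge alone: when other lineages attach
basally within a major clade, that single interior edge can be weak
even though the copy separation itself is maximally supported.  The
call requires the minimum separating support across the involved
clades to reach `support_min = 70` — a conventional floor for
"well-supported", below the 84–100% range typically quoted for such
clades but above the noise zone.  An imported tree without support
values disables the gate (flagged in the report).

A diploid whose two copies satisfy the allopolyploid pattern is
reported as `hybrid_pattern`: the same phylogenetic signal, but the
biological reading is interspecific hybridity rather than polyploidy.

## The simulator

`simulate_dataset` emulates the assumed history: an ancestral amplicon
(the built-in reference: 1325 bp; exon stubs of 7 bp at both ends,
four complete exons, introns of 90/440/85/95/90 bp, exonic total a
multiple of three) evolves along an ultrametric genealogy.

* Two diploid pools split at `stem_depth = 0.08` substitutions/site,
  so expected between-pool divergence is 0.16; within-pool
  coalescences are randomly paired with merge times spaced
  quadratically down to `crown_depth = 0.02` — dense near the present,
  long basal internides, as in real species-level clades (even spacing
  would leave basal crown edges far below deep-branch sampling noise).
* Pool B's stem carries a structural deletion of
  `intron4_deletion_bp = 280` from intron 4 (440 → 160 bp: the short
  form); designated B lineages additionally lose intron 5 entirely
  (the intron-lost form).  Structural events sit on zero-length event
  nodes so that polyploid lineages spliced below them inherit the
  structure.
* A pair of outgroup sequences diverges at `2·stem_depth`, coalescing
  midway between that and the pool split.  A pair, not a single tip:
  one outgroup at equal distance from both pools creates a degenerate
  polytomy at the pool split whose random resolution halves the
  bootstrap support of one pool clade; the pair's stem makes the
  rooting edge real.
* Substitutions are JC69 with exact per-branch transition
  probabilities.  Introns evolve at the nominal rate; exons at
  `exon_rate_scale = 0.10` of it, with substitutions creating in-frame
  stops reverted, and the splice-site `GT`/`AG` dinucleotides exempt —
  purifying selection on a strongly conserved enzyme and on splicing.
  At the default depths this keeps true orthologs near ~96% amino-acid
  identity, safely above the 90% screen, while a single
  whole-amplicon neutral rate would push them to ~70% and make the
  screen reject every true ortholog.
* Intron indels occur at `intron_indel_rate = 0.3` expected events per
  intron per root-to-tip lineage (Poisson per branch, proportional to
  branch length), geometric lengths with mean 8 bp, placed ≥ 2 bp from
  intron ends; insertions open new alignment columns.  Pseudogenes
  arise as terminal 1–2 bp exonic indels at `pseudogene_rate = 0.03`
  per sequence.
* An allotetraploid draws one contemporary pool-A lineage and one
  pool-B lineage; an autotetraploid duplicates a single lineage.  Each
  copy diverges from its source *lineage* at `polyploid_split_depth =
  0.015` — ascending past any more recent coalescences of the sampled
  diploid, since the polyploid's parental population need not be the
  sampled individual's closest relative — and the two copies of an
  autotetraploid coalesce at `polyploid_age = 0.002`, the recent
  moment of genome doubling at which they were a single allele.

The true multiple alignment is maintained through a global column
registry (every insertion opens a column labelled with its gene
segment), so alignment-consuming stages are tested without an external
aligner.  Ground truth records each sequence's source pool, structural
lineage, pseudogene status and the generating tree; identical
configurations (including the seed) give byte-identical output.

### What the simulator does not emulate

No within-species polymorphism or coalescent structure, no
recombination, no alignment error (the truth alignment is exact — real
pipelines inherit aligner artifacts), no rate heterogeneity beyond the
exon/intron dichotomy, no unreduced-gamete routes to higher ploidies,
and no paralogous locus (the orthology screen is exercised only by
frameshift mutants and synthetic divergence, not by a true paralog).
Passing tests therefore demonstrate correctness of the algorithms
under the stated model, not robustness to aligner noise or deep
coalescence.

## Problem sizes and numerical checks

The test suite and the acceptance script use: typing fidelity on a
default simulation with indels disabled (~60 ingroup sequences);
origin recovery on 25 allo- + 25 autotetraploids over 12 + 12 diploids
(126 sequences, 100 bootstrap replicates; the pipeline default is 1000
replicates — 100 keeps this experiment proportionate to its size);
neighbor joining on 100 random additive matrices (n ≤ 12, recovery
must be exact in topology and path lengths to 10⁻⁹) and 50 random
non-additive matrices against an independently written plain NJ; site
classification against exhaustive counting on 200 random alignments
with gaps and ambiguity codes; pseudogene detection on 17 constructed
mutants; and the JC69 closed form `3/4·(1 − e^(−8·stem/3))` for mean
between-pool p-distance at neutral intron sites over 30 replicate
simulations, required to sit within 3 Monte-Carlo standard errors.
The JC check excludes each intron's terminal two positions: those hold
the conserved splice dinucleotides, which do not evolve and would bias
the neutral-site distance downward by ~2.5%.

## Known limitations

* Boundary projection trusts a single reference; a query whose true
  structure differs from the reference's beyond intron presence/length
  (e.g. a novel intron) will be mis-tiled rather than rejected.
* The typing thresholds are calibrated to this locus's bimodal
  intron-4 length distribution; other loci need their own
  `TypingConfig`.
* Clade assignment by exemplar MRCA is sensitive to rogue exemplars: a
  single mis-typed diploid can widen a clade's MRCA to the whole tree
  and void assignments.  Exemplars can be supplied explicitly to guard
  against this.
* NJ is used for its speed and determinism; for publication-grade
  trees an external ML/Bayesian tree can be imported (`--tree`), and
  inference then runs on it unchanged.
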