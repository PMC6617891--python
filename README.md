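# waxyphylo

Homoeolog typing of low-copy nuclear gene amplicons and gene-tree
inference of allo- vs autopolyploid origin.

## The problem

Polyploid plant species carry multiple copies of every nuclear gene.
When a polyploid arose by hybridization between two species followed by
genome doubling (**allopolyploidy**), its gene copies — *homoeologs* —
were contributed by different parental lineages; when it arose by
doubling within one species (**autopolyploidy**), the copies are recent
duplicates of a single lineage.  A single-copy nuclear gene sequenced
from many diploid and polyploid individuals lets you tell these
histories apart: in a gene tree, the copies of an autopolyploid should
be each other's closest relatives, while the homoeologs of an
allopolyploid fall in different major clades, often closer to copies
from *other* species than to each other.

`waxyphylo` implements this analysis for amplicons of the granule-bound
starch synthase I gene (*GBSSI*, the "waxy" gene), as used to resolve
polyploid origins in brambles (*Rubus*), where the *GBSSI-1* locus
occurs in structurally distinct forms:

* **1a** — long fourth intron, fifth intron present;
* **1b** — fourth intron several hundred bp shorter;
* **1c** — short fourth intron **and** loss of the fifth intron.

The pipeline:

1. **annotate** — project exon/intron boundaries from an annotated
   reference onto each amplicon by global alignment, snapping each
   boundary to the canonical `GT…AG` splice dinucleotides;
2. **screen** — amino-acid identity filter (≥ 90% to the reference
   protein) to exclude paralogous amplification products;
3. **type** — classify each sequence into 1a/1b/1c from its intron-4
   length and intron-5 presence, and flag pseudogenes (exonic
   frameshifts, internal stop codons);
4. **stats** — variable and parsimony-informative site tallies,
   gaps treated as missing data;
5. **tree** — neighbor-joining on uncorrected-P distances (pairwise
   deletion) with nonparametric bootstrap supports, rooted on an
   outgroup;
6. **infer** — per-individual origin call
   (`allopolyploid_pattern` / `autopolyploid_pattern` /
   `uninformative`) from copy monophyly and major-clade placement,
   gated on bootstrap support.

A first-class simulator (`waxyphylo.synthetic_data`) generates datasets
with this exact structure — two diverged diploid gene pools with
distinct intron architectures, allo- and autotetraploids, intron
indels, intron losses, pseudogenes — together with the true alignment
and full ground truth, so every stage is testable without downloads.

## Worked example

Simulate a small cohort (24 diploids from two gene pools, 3
allotetraploids, 3 autotetraploids, 2 outgroup sequences) and run the
full pipeline on its true alignment:

```bash
waxyphylo simulate --seed 11 --n-allo 3 --n-auto 3 --out-dir demo
waxyphylo run \
    --sequences demo/truth_alignment.fasta --aligned \
    --metadata demo/metadata.csv \
    --reference demo/reference.fasta \
    --reference-segments demo/reference_segments.csv \
    --bootstrap 200 --seed 7 \
    --outgroup OG01_1 --outgroup OG02_1 \
    --out-dir demo/out
```

The origin-call table printed at the end contains, among the diploids
(all single-copy, hence uninformative for polyploidy):

```
individual_id  ploidy  n_copies labels  clades        monophyly  min_separating_support               verdict
          T01       4         2  1a+1b    I+II non_monophyletic                   100.0 allopolyploid_pattern
          T02       4         2  1a+1b    I+II non_monophyletic                   100.0 allopolyploid_pattern
          T03       4         2  1a+1b    I+II non_monophyletic                   100.0 allopolyploid_pattern
          U01       4         2     1a       I     monophyletic                     NaN autopolyploid_pattern
          U02       4         2     1b      II     monophyletic                     NaN autopolyploid_pattern
          U03       4         2     1a       I     monophyletic                     NaN autopolyploid_pattern
```

Every allotetraploid carries one 1a and one 1b homoeolog resolved in
the two major clades (I and II) with 100% bootstrap separation — the
allopolyploid pattern.  Every autotetraploid's two copies are sister
leaves — the autopolyploid pattern.  `demo/out/` also contains the
per-region variation table (`seqstats.csv`):

```
region,n_sequences,aligned_length,length_min,length_max,variable_sites,variable_pct,informative_sites,informative_pct
all,38,1359,1044,1316,421,30.98,228,16.78
1a,21,1332,1299,1316,363,27.25,164,12.31
1b,17,1052,1044,1052,73,6.94,33,3.14
```

(the 1b group is ~300 bp shorter — the structural intron-4 deletion),
plus the bootstrapped tree (`tree.nwk`), the per-sequence typing table,
the section × ploidy × genotype cross-tabulation and a provenance block
recording the seed and settings.

For real data, supply your own aligned FASTA, a metadata table
(`individual_id, taxon_name, section, subsection, ploidy, accessions`)
and an annotated reference (FASTA plus a segment table with `kind,
index, start, end` in 0-based half-open coordinates).  An externally
computed tree (e.g. maximum likelihood) can be passed with `--tree` to
drive inference instead of the built-in neighbor joining.

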