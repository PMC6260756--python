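# Methods

## The curation model

`txcurate` treats catalog curation as three evidence questions applied to a
merged multi-sample assembly: *is the transcript reproducible* (assembled
independently in many samples at non-trivial abundance), *is it conserved*
(its ORF aligns well to known proteins), and *is it explainable as an
artifact* (pre-mRNA, pseudogene mis-alignment, repeat-driven transcription,
assembly read-through)? Transcripts failing all three are treated as
transcriptional noise and removed.

The unit of identity throughout is the **intron chain**: two spliced
transcripts are the same iff their intron coordinates match exactly, on the
same sequence and strand; terminal exon ends are ignored because assembled
ends are coverage artifacts far more often than real TSS/polyA variation.
Gene counting uses **loci**: maximal clusters of transcripts linked
transitively by ≥ 1 bp of same-strand exonic overlap. Exonic (not span)
overlap is used so that antisense and intron-nested genes stay separate
loci; the flag `stranded=False` merges across strands for sensitivity
analyses. Locus counts are moderately sensitive to this choice: span
clustering would merge loci that interleave without sharing exonic bases.

Coordinates are 1-based inclusive everywhere (GTF convention); BED input is
converted at the parser boundary and nowhere else. Abutting exons
(zero-length gap) are merged with a logged warning, since a zero-length
intron is not a splicing event.

## Merging

Per-sample catalogs are merged in two stages — within each tissue, then
across tissue-level results — mirroring how very large collections are
processed in practice. Within a merge pass:

1. transcripts with identical intron chains collapse to one representative
   whose extent is the union of member extents (union maximizes evidence
   retention; per-member provenance is kept in `source_ids`);
2. a spliced transcript whose chain is a contiguous sub-chain of a
   co-located longer transcript, with its terminal exons inside the
   container's corresponding exons, is absorbed into the container
   (fragmented assemblies are the rule at low coverage);
3. single-exon transcripts merge only with other single-exon transcripts,
   by transitive reciprocal exonic overlap on the same strand. Empty intron
   chains are never "equal", so chain identity is undefined for them by
   construction.

Support counts the distinct contributing samples — a sample contributes at
most 1 per merged transcript — and `tissue_support` carries the per-tissue
breakdown. The merge is idempotent: re-merging its own output is a no-op.

## Overlap classification

`classify_overlap(q, r)` returns one code per ordered pair, by priority:
`chain_match > contained > container > junction_share > exon_overlap >
intronic > antisense_exonic > none`. "Contained" requires both the
sub-chain condition and the terminal exons to fall inside the container's
matched exons. `antisense_exonic` requires two explicit, different strands
plus exonic overlap; unstranded features are treated as strand-compatible.
In streaming comparison, ties among references with the same class go to
the longest exonic overlap, then lexicographic id — fully deterministic.
When a query chain-matches a reference with experimentally supported ends
(e.g. CAGE-derived 5′ ends), `adjust_ends_to_reference` replaces only the
terminal exon outer coordinates, never the internal structure.

## Thresholds (CurationConfig)

| parameter | default | role |
|---|---|---|
| `min_samples` | 10 | minimum samples a noncoding transcript must be assembled in |
| `min_avg_tpm` | 1.0 (TPM) | mean abundance floor (noncoding, ≥); per-tissue floor (coding, strict >) |
| `outlier_tpm` | 13.87 (TPM) | single-exon / low-support escape hatch, strict > |
| `min_orf_aa` | 60 aa | minimum ORF length for coding candidacy and lncRNA rescue |
| `max_evalue` | 1e−15 | best-protein-hit e-value ceiling ("or smaller", so ≤) |
| `min_orf_fraction` | 0.75 | ORF length relative to the matched protein (≥; truncation marks pseudogenes) |
| `pseudo_identity` | 98.0 % | nucleotide identity to a known transcript that marks a pseudogene copy (≥) |
| `pseudo_coverage` | 0.90 | fraction of the novel transcript covered by that alignment (≥) |
| `top_n_per_locus` | 10 | abundance cap on novel isoforms per locus |
| `domain_max_evalue` | 1e−5 | Pfam/CDD hit ceiling for waiving the Alu/SVA screen |

Comparisons are strict (">") exactly where the source thresholds are stated
as strict and inclusive where stated as "at least" — boundary cases
(TPM = 13.87, ORF = 75 % exactly, e = 1e−15) are covered by tests.
`outlier_tpm` is a supplied constant: it is the upper outlier fence of a
reference expression distribution that this package does not ship.
`outlier_fence()` implements the standard boxplot estimator
(Q3 + 1.5·IQR) for users who want to derive the value from their own known
transcript TPM distribution; no claim is made that it reproduces 13.87 on
any particular data set.

`mean_tpm` averages over the samples in which a transcript was assembled
(TPM > 0), not over all samples; the alternative reading is available as
`mean_over="all"`. Averaging over all samples makes the mean gate far
stricter for tissue-specific transcripts, which is why "assembled" is the
default.

## Cascade order and its consequences

Filters run in the listed order and the report records every decision, so
order effects are measurable. One consequence worth knowing: the per-locus
abundance cap (keep the `top_n` most abundant) is rank-based, so the
cascade is *not* pointwise monotone in the upstream thresholds — tightening
the support gate can remove a top-10 isoform and thereby promote the 11th
into the cap. The kept *count* never grows under tightening, and
idempotence holds throughout; the tests assert exactly these properties.

The retained-intron rule is deliberately conservative: an exon flags a
retained intron only if it fully contains a reference intron **and**
reaches ≥ 1 bp into both flanking reference exon territories. Requiring
both overhangs keeps legitimate alternative first/last exons that end at an
intron boundary from being discarded; the operational definition is ours,
as the source procedure names the filter without formalizing it.

Other operational choices made where the procedure was underspecified:

* "overlaps multiple known genes" = same-strand exonic overlap with ≥ 2
  distinct reference gene ids; the opposite-strand check in the same filter
  is taken against the reference annotation, not the post-merge catalog.
* "conflicting loci" in the coding cascade = opposite-strand span overlap
  among cascade survivors; each conflicted transcript is kept only if its
  best protein hit has a named function.
* read-through exclusion during lncRNA rescue = same-strand exonic overlap
  with ≥ 2 reference gene loci. This is an assumed definition, exposed as
  its own reported stage so it can be audited or ablated.
* unknown-function names: substring matching (case-insensitive) for
  "hypothetical", "unnamed protein product", "uncharacterized protein",
  "unknown", "pseudogene", "open reading frame"; token-level matching for
  `LOC`, `PRO`, `ORF` — a token matches if it equals the keyword or is the
  keyword followed by digits (`LOC101927562`), which avoids false hits
  inside words like "prolactin" while catching the identifier forms these
  keywords actually take; `hCG` is a case-sensitive prefix test on the
  first token.
* ORF search is sense-strand only (transcripts are stranded); codons
  containing N translate to X and never terminate a frame; ties between
  equally long ORFs go to the 5′-most start.
* biotype precedence when sources disagree: first reference type, then
  second reference type, then the cascade's own call (protein-coding if
  accepted by the coding cascade; otherwise antisense if opposite-strand
  overlapping a reference transcript, else lncRNA).

## Synthetic study conditions

The generator (`txcurate.simulate`) emulates the statistical structure the
cascades assume, not sequencing itself. The default spec plants, on one
abstract 3 Mb chromosome: 10 genuine spliced noncoding transcripts; one
noise transcript per noncoding filter (low support, single-exon, rRNA
overlap, retained intron, pseudogene copy, antisense, multi-gene
read-through, excess isoform at a 11-isoform locus whose 10 keepers count
as genuine, Ig/TCR overlap); 5 coding candidates satisfying every coding
gate plus one Alu-embedded ORF that fails only the repeat screen; and 2
rescueable lncRNAs. Expression is drawn per supporting sample from
log-normal TPM models (genuine: ln-location 1.2, ln-scale 0.5, i.e. median
≈ 3.3 TPM; noise: −1.0/0.6, median ≈ 0.37 TPM) over 30 samples in 3
tissues, with genuine support of ≥ 12 samples and low-support plants at 3.
Where a draw would violate a plant's defining constraint (e.g. a genuine
mean drifting below 1 TPM), the vector is rescaled and the generator
verifies every plant against its own gate at generation time. Assembled
per-sample fragments are 5′-truncated by up to 30 bp in all but the first
supporting sample, so merging must reconstruct the union extent.

Coding-plant sequences embed the ORF between A-free flanks, guaranteeing
the planted frame is the unique longest one; pseudogene-copy similarity is
computed by actually aligning the mutated copy to its source (edlib global
alignment), not asserted. Homology and domain evidence are synthesized
tables with values chosen to clear or miss the gates — conservation is an
input here, as the package consumes alignment evidence rather than running
the aligners.

What passing these fixtures shows: the cascades implement their
definitions exactly — each artifact class is removed at its designated
stage, with nothing else caught in the crossfire. What it does not show:
performance on real data, where noise violates several filters at once,
expression is correlated across isoforms, repeat annotations are
incomplete, and genuine transcripts sometimes look like artifacts. The
fixture's separability is a design property, not an empirical claim about
recall on real catalogs.

## Numerical and reporting conventions

Report-style ratios round half-up to one decimal (so 13.087 prints as
13.1); raw ratios are carried alongside. Venn identity keys always include
the strand — identical coordinates on opposite strands are distinct
introns/exons/chains. Single-exon transcripts are excluded from the
chain-level comparison (an empty chain has no identity) and are counted
separately in catalog tallies. Exon-level comparison uses exact outer
coordinates including terminal exons, which is expected to depress
agreement relative to the intron level. The functional-activity share is
the summed TPM of retained transcripts over the summed TPM of all
transcripts, with per-transcript totals summed across all samples.

## Problem sizes

The shipped tests and the acceptance script run the pipeline at desk scale:
35-transcript candidate catalogs over 30 samples for cascade checks, and
1,000 random queries against 250 references for the oracle-equivalence
checks. All operations are streaming or interval-tree indexed and have been
written to scale linearly in catalog size, but headline catalog counts from
population-scale collections are not reproducible here: they require the
underlying controlled-access samples and specific reference releases.

## Known limitations

* No CDS phase bookkeeping beyond ORF coordinates, and no genome-level
  operations (alignment, assembly, quantification) — upstream tools own
  those.
* The similarity filter consumes alignment evidence as a table; the
  packaged aligner wrapper exists for fixture construction, not as a
  replacement for a real all-vs-all nucleotide search.
* `support_check` requires same-strand exon overlap; unstranded assemblies
  will under-report support for stranded references.
* The 13.87 TPM outlier constant and the keyword list are modeling inputs;
  both are exposed in configuration rather than derived from data.
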