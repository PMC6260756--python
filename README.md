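# txcurate

Curation toolkit for building a transcript catalog from many individually
assembled RNA-seq samples — and for separating the transcripts worth keeping
from the pervasive transcriptional noise that deep sequencing reveals.

When thousands of samples are aligned and assembled independently, the union
of their transcript models is enormous: tens of millions of distinct
structures, most of them produced by nonspecific polymerase and splicing
activity rather than by functional genes. `txcurate` implements the
catalog-construction workflow around that problem:

* **merging** — per-sample catalogs are merged tissue-by-tissue and then
  globally. Two spliced transcripts are *the same* iff their intron chains
  match coordinate-for-coordinate (terminal exon ends are ignored);
  fragments whose chain is strictly contained in a co-located longer
  transcript are absorbed into it. Merged transcripts carry sample and
  tissue support counts.
* **protein-coding cascade** — expression (TPM > 1 in some tissue, or
  outlier-level expression for single-exon candidates), containment,
  a ≥ 60 aa ORF, LINE/LTR/rRNA exclusions, protein homology (best BLAST
  e-value ≤ 1e−15 and ORF ≥ 75 % of the matching protein's length),
  a named-function requirement at conflicting opposite-strand loci, and an
  Alu/SVA screen waived only by Pfam/CDD domain support.
* **noncoding cascade** — reproducibility (assembled in ≥ 10 samples with
  mean TPM ≥ 1, or TPM > 13.87), single-exon and rRNA exclusion,
  retained-intron and pseudogene-copy screens (≥ 98 % identity over ≥ 90 %
  of the length of a known transcript), antisense/multi-gene exclusions, a
  10-isoforms-per-locus abundance cap, and processed-pseudogene / Ig-TCR
  locus masks.
* **lncRNA rescue** — annotated lncRNAs that carry a qualifying ORF whose
  best hit is a protein with a *named* function (not "hypothetical",
  "uncharacterized", LOC/ORF identifiers, hCG predictions) are re-typed as
  protein-coding.
* **catalog comparison** — three-way share structure of distinct introns,
  exons, and intron chains across annotation databases, plus per-biotype
  accounting (genes, transcripts, isoforms per coding gene, and the share
  of total transcriptional activity carried by retained transcripts).

Every cascade decision is logged in a `FilterReport`
(transcript, stage, kept/removed, reason), so catalog-level numbers are
auditable transcript by transcript.

Because the large RNA-seq collections this workflow targets are
access-controlled, the package ships a deterministic synthetic-fixture
generator (`txcurate.simulate`) that emulates multi-sample catalogs with
planted noise of every category the cascades address, each labelled with
the stage that must remove it.

## Worked example

```python
from txcurate import (FixtureSpec, generate, merge_catalogs,
                      noncoding_cascade, coding_cascade, truth_eval)

bundle = generate(FixtureSpec(seed=1))          # 35 candidates, 30 samples
merged = merge_catalogs(bundle.samples)

summaries = bundle.expression_summaries()
kept, report = noncoding_cascade(
    bundle.noncoding_candidates, summaries, [bundle.reference],
    bundle.similarities, bundle.repeats)
coding, _ = coding_cascade(bundle.candidates, summaries, bundle.sequences,
                           bundle.homology, bundle.domains, bundle.repeats)
print(f"noncoding cascade: kept {len(kept)} of {len(bundle.noncoding_candidates)}")
print(f"coding cascade: accepted {len(coding)} of {len(bundle.candidates)}")
print(truth_eval(report, bundle.truth[bundle.truth.cascade == "noncoding"])
      .to_string(index=False))
```

prints

```
noncoding cascade: kept 20 of 29
coding cascade: accepted 5 of 35
               stage  n_removed  n_truth  tp  precision  recall
  expression_support          1        1   1        1.0     1.0
         single_exon          1        1   1        1.0     1.0
        rrna_overlap          1        1   1        1.0     1.0
     retained_intron          1        1   1        1.0     1.0
    known_similarity          1        1   1        1.0     1.0
antisense_multi_gene          2        2   2        1.0     1.0
     locus_abundance          1        1   1        1.0     1.0
pseudogene_igtr_loci          1        1   1        1.0     1.0
```

The 9 planted noise transcripts are each removed at exactly the stage
designed to catch them (the `antisense_multi_gene` stage removes both the
antisense artifact and the multi-gene read-through); all 20 genuine
transcripts survive, and the coding cascade accepts exactly the 5 planted
coding candidates while rejecting the repeat-embedded ORF at the Alu/SVA
screen.

The same pipeline is available from the shell:

```sh
txcurate simulate -o fixtures/ --seed 1
txcurate merge --tissue-map fixtures/tissue_map.tsv -o merged.gtf fixtures/samples/*.gtf
txcurate curate --assembled merged.gtf --refseq fixtures/reference.gtf \
    --expr fixtures/expression.tsv --tissue-map fixtures/tissue_map.tsv \
    --blast fixtures/homology.tsv --domains fixtures/domains.tsv \
    --similarity fixtures/similarity.tsv --repeats fixtures/repeats.bed \
    --seqs fixtures/transcripts.fa -o curated.gtf --report report.tsv
txcurate venn --level intron a.gtf b.gtf c.gtf
```

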