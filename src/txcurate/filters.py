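"""The curation filter cascades.

Two ordered cascades separate functional transcripts from transcriptional
noise in a merged multi-sample catalog:

* the **protein-coding cascade** — expression and containment gates, a
  minimum ORF length, repeat/rRNA exclusions, protein-homology evidence,
  a named-function requirement at conflicting (opposite-strand) loci, and
  a final Alu/SVA screen waived only by Pfam/CDD domain support;
* the **noncoding cascade** — reproducibility and abundance gates,
  single-exon and rRNA exclusions, retained-intron and pseudogene-copy
  screens, antisense/multi-gene exclusions, a per-locus abundance cap,
  and processed-pseudogene / immunoglobulin–T-cell-receptor locus masks.

Every decision is logged in a FilterReport so catalog-level accounting is
auditable transcript by transcript.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from intervaltree import IntervalTree

from .model import (
    AnnotationSet,
    GenomicInterval,
    Transcript,
    cluster_loci,
    introns_of,
    normalize_biotype,
    parse_bed,
    project_to_genome,
    strands_compatible,
)
from .orf import (
    DomainHit,
    HomologyHit,
    OrfRecord,
    has_domain_support,
    has_named_function,
    longest_orf,
    passes_homology_gate,
)
from .overlap import OverlapClass, classify_overlap

log = logging.getLogger(__name__)

REPEAT_CLASSES = ("LINE", "LTR", "Alu", "SVA", "rRNA", "processed_pseudogene", "IG_TR")


@dataclass(frozen=True)
class ExpressionSummary:
    """Per-transcript sample support and TPM statistics."""

    transcript_id: str
    n_samples: int
    mean_tpm: float
    max_tpm: float
    per_tissue_max: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        # small epsilon absorbs float summation error when all samples are equal
        if self.n_samples > 0 and not (self.max_tpm >= self.mean_tpm - 1e-9 and self.mean_tpm >= 0):
            raise ValueError(f"{self.transcript_id}: require max_tpm >= mean_tpm >= 0")


@dataclass(frozen=True)
class SimilarityRecord:
    """Nucleotide similarity of a novel transcript to a known one."""

    novel_id: str
    known_id: str
    percent_identity: float
    coverage_fraction: float

    def __post_init__(self) -> None:
        if not 0 <= self.percent_identity <= 100:
            raise ValueError("percent_identity outside [0, 100]")
        if not 0 <= self.coverage_fraction <= 1:
            raise ValueError("coverage_fraction outside [0, 1]")


@dataclass(frozen=True)
class RepeatFeature:
    interval: GenomicInterval
    repeat_class: str

    def __post_init__(self) -> None:
        if self.repeat_class not in REPEAT_CLASSES:
            raise ValueError(f"repeat class {self.repeat_class!r} not in {REPEAT_CLASSES}")


class RepeatIndex:
    """Positional index over classed repeat/mask features."""

    def __init__(self, features: Iterable[RepeatFeature]) -> None:
        self.features = list(features)
        self._trees: dict[str, IntervalTree] = {}
        for f in self.features:
            iv = f.interval
            self._trees.setdefault(iv.seqid, IntervalTree()).addi(iv.start, iv.end + 1, f)

    def overlapping(self, interval: GenomicInterval, classes: Sequence[str] | None = None) -> list[RepeatFeature]:
        tree = self._trees.get(interval.seqid)
        if tree is None:
            return []
        hits = [h.data for h in tree.overlap(interval.start, interval.end + 1)]
        if classes is not None:
            hits = [f for f in hits if f.repeat_class in classes]
        return hits

    def exon_hit(self, t: Transcript, classes: Sequence[str]) -> bool:
        """True if any exon of t overlaps a feature of the given classes."""
        return any(
            f.interval.overlaps(e)
            for e in t.exons
            for f in self.overlapping(e, classes)
        )


def load_repeats(source) -> RepeatIndex:
    """Read a repeat/mask BED whose name column carries the repeat class."""
    feats = []
    for interval, name in parse_bed(source):
        cls = name.split("|")[0]
        if cls not in REPEAT_CLASSES:
            log.warning("repeat class %r not recognised; feature skipped", name)
            continue
        feats.append(RepeatFeature(interval, cls))
    return RepeatIndex(feats)


class FilterReport:
    """Ordered audit trail of keep/remove decisions per cascade stage."""

    def __init__(self) -> None:
        self.records: list[tuple[str, str, str, str]] = []

    def record(self, transcript_id: str, stage: str, kept: bool, reason: str = "") -> None:
        self.records.append((transcript_id, stage, "kept" if kept else "removed", reason))

    @property
    def stages(self) -> list[str]:
        seen: list[str] = []
        for _, stage, _, _ in self.records:
            if stage not in seen:
                seen.append(stage)
        return seen

    def removed_at(self, stage: str) -> set[str]:
        return {tid for tid, s, d, _ in self.records if s == stage and d == "removed"}

    def removed_ids(self) -> set[str]:
        return {tid for tid, _, d, _ in self.records if d == "removed"}

    def removal_stage(self) -> dict[str, str]:
        return {tid: s for tid, s, d, _ in self.records if d == "removed"}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["transcript_id", "stage", "decision", "reason"])

    def write_tsv(self, dest) -> None:
        self.to_frame().to_csv(dest, sep="\t", index=False)


@dataclass
class CurationConfig:
    """Thresholds of both cascades, with the published defaults.

    ``outlier_tpm`` is the upper outlier fence of the known-transcript TPM
    distribution (a supplied constant here; see :func:`outlier_fence` for
    the boxplot estimator). ``mean_over`` selects whether mean TPM averages
    over the samples in which a transcript was assembled or over all
    samples.
    """

    min_samples: int = 10
    min_avg_tpm: float = 1.0
    outlier_tpm: float = 13.87
    min_orf_aa: int = 60
    max_evalue: float = 1e-15
    min_orf_fraction: float = 0.75
    pseudo_identity: float = 98.0
    pseudo_coverage: float = 0.90
    top_n_per_locus: int = 10
    domain_max_evalue: float = 1e-5
    mean_over: str = "assembled"  # or "all"

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "mean_over":
                continue
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")
        for name in ("min_orf_fraction", "pseudo_coverage"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.mean_over not in ("assembled", "all"):
            raise ValueError("mean_over must be 'assembled' or 'all'")

    @classmethod
    def from_yaml(cls, source) -> "CurationConfig":
        fh = open(source) if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__") else source
        data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, dest) -> None:
        with open(dest, "w") as fh:
            yaml.safe_dump({f.name: getattr(self, f.name) for f in fields(self)}, fh)


def outlier_fence(tpms: Sequence[float]) -> float:
    """Boxplot upper fence (Q3 + 1.5 IQR) of a TPM sample.

    Offered as an estimator for the single-exon outlier threshold; the
    shipped default (13.87) is a supplied constant, not a claim that this
    estimator reproduces it on any particular expression set.
    """
    arr = np.asarray(tpms, dtype=float)
    q1, q3 = np.percentile(arr, [25, 75])
    return float(q3 + 1.5 * (q3 - q1))


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------


def read_expression_table(source) -> pd.DataFrame:
    """Read a transcript-by-sample TPM matrix (TSV, first column = id)."""
    return pd.read_csv(source, sep="\t", index_col=0)


def read_tissue_map(source) -> dict[str, str]:
    """Read a two-column sample -> tissue TSV (no header required)."""
    df = pd.read_csv(source, sep="\t", header=None, names=["sample", "tissue"], comment="#")
    if df.iloc[0, 0] in ("sample", "sample_id"):
        df = df.iloc[1:]
    return dict(zip(df["sample"].astype(str), df["tissue"].astype(str)))


def summarize_expression(
    expr: pd.DataFrame, tissue_map: Mapping[str, str], *, mean_over: str = "assembled"
) -> dict[str, ExpressionSummary]:
    """Collapse a TPM matrix into per-transcript ExpressionSummary records.

    A transcript counts as assembled in a sample when its TPM is > 0 there.
    """
    missing = [s for s in expr.columns if s not in tissue_map]
    if missing:
        raise ValueError(f"samples missing from tissue map: {missing[:5]}")
    tissues = np.array([tissue_map[s] for s in expr.columns])
    vals = expr.to_numpy(dtype=float)
    out: dict[str, ExpressionSummary] = {}
    for i, tid in enumerate(expr.index.astype(str)):
        row = vals[i]
        present = row > 0
        n = int(present.sum())
        if n == 0:
            out[tid] = ExpressionSummary(tid, 0, 0.0, 0.0, {})
            continue
        mean = float(row[present].mean() if mean_over == "assembled" else row.mean())
        per_tissue = {}
        for tis in np.unique(tissues[present]):
            per_tissue[str(tis)] = float(row[tissues == tis].max())
        out[tid] = ExpressionSummary(tid, n, mean, float(row.max()), per_tissue)
    return out


def read_similarity_table(source) -> list[SimilarityRecord]:
    """Read (novel_id, known_id, percent_identity, coverage_fraction) TSV."""
    df = pd.read_csv(source, sep="\t", comment="#", header=None,
                     names=["novel_id", "known_id", "percent_identity", "coverage_fraction"])
    return [
        SimilarityRecord(str(r.novel_id), str(r.known_id),
                         float(r.percent_identity), float(r.coverage_fraction))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Individual gates
# ---------------------------------------------------------------------------


def find_novel(
    assembled: AnnotationSet, references: Sequence[AnnotationSet], name: str = "novel"
) -> tuple[AnnotationSet, FilterReport]:
    """Transcripts with no exonic overlap (either strand) with any reference gene.

    References are expected to include pseudogene records, so novelty means
    clear of coding genes, noncoding genes and pseudogenes alike.
    """
    report = FilterReport()
    kept = []
    for t in assembled:
        hit = None
        for ref in references:
            for r in ref.overlapping(t.interval):
                if t.exonic_overlap(r, stranded=False):
                    hit = (ref.name, r.transcript_id)
                    break
            if hit:
                break
        if hit:
            report.record(t.transcript_id, "novelty", False,
                          f"exonic overlap with {hit[0]}:{hit[1]}")
        else:
            report.record(t.transcript_id, "novelty", True)
            kept.append(t)
    return AnnotationSet.from_transcripts(name, kept), report


def coding_expression_gate(
    t: Transcript, e: ExpressionSummary | None, cfg: CurationConfig
) -> bool:
    """Spliced: TPM > 1 in at least one tissue. Single-exon: expression at
    least as high as the known-transcript outliers (TPM > outlier_tpm)."""
    if e is None:
        return False
    if t.is_spliced:
        return any(v > cfg.min_avg_tpm for v in e.per_tissue_max.values())
    return e.max_tpm > cfg.outlier_tpm


def containment_gate(
    t: Transcript,
    catalog: AnnotationSet,
    support: Mapping[str, ExpressionSummary],
    cfg: CurationConfig | None = None,
) -> bool:
    """Not contained in another transcript, unless expressed in more samples
    than every containing transcript."""
    containers = [
        o for o in catalog.overlapping(t.interval)
        if o.transcript_id != t.transcript_id
        and classify_overlap(t, o) is OverlapClass.contained
    ]
    if not containers:
        return True
    own = support[t.transcript_id].n_samples if t.transcript_id in support else 0
    most = max(
        (support[o.transcript_id].n_samples if o.transcript_id in support else 0)
        for o in containers
    )
    return own > most


def retained_intron(t: Transcript, ref_introns: Iterable[GenomicInterval]) -> bool:
    """True iff some exon of t fully contains a reference intron and reaches
    at least 1 bp into both flanking reference exon territories.

    The flanking requirement keeps legitimate alternative terminal exons
    from being flagged: an exon ending exactly at an intron boundary is not
    a retained intron.
    """
    for e in t.exons:
        for i in ref_introns:
            if (e.seqid == i.seqid and strands_compatible(e.strand, i.strand)
                    and e.start < i.start and e.end > i.end):
                return True
    return False


def reference_introns(references: Sequence[AnnotationSet]) -> list[GenomicInterval]:
    """Distinct introns of all spliced reference transcripts."""
    seen = set()
    out = []
    for ref in references:
        for t in ref:
            for i in introns_of(t):
                key = (i.seqid, i.start, i.end, i.strand)
                if key not in seen:
                    seen.add(key)
                    out.append(i)
    return out


def _ref_exonic_hits(
    t: Transcript, references: Sequence[AnnotationSet], *, same_strand: bool
) -> list[Transcript]:
    hits = []
    for ref in references:
        for r in ref.overlapping(t.interval):
            if not t.exonic_overlap(r, stranded=False):
                continue
            opposite = t.strand != r.strand and t.strand in "+-" and r.strand in "+-"
            if same_strand and not opposite:
                hits.append(r)
            elif not same_strand and opposite:
                hits.append(r)
    return hits


def support_check(refs: AnnotationSet, assembled: AnnotationSet) -> list[str]:
    """Reference genes with no exon overlapped by any assembled transcript.

    A gene counts as supported if any assembled exon overlaps any exon of
    any of its transcripts on the same strand; the precise exon-intron
    structure is not required to match.
    """
    genes: dict[str, list[Transcript]] = {}
    for t in refs:
        genes.setdefault(t.gene_id, []).append(t)
    unsupported = []
    for gid in sorted(genes):
        supported = False
        for t in genes[gid]:
            for a in assembled.overlapping(t.interval):
                if t.exonic_overlap(a, stranded=True):
                    supported = True
                    break
            if supported:
                break
        if not supported:
            unsupported.append(gid)
    return unsupported


def assign_biotype(
    t: Transcript,
    refseq_type: str | None = None,
    gencode_type: str | None = None,
    *,
    coding_accepted: bool = False,
    references: Sequence[AnnotationSet] = (),
) -> str:
    """Biotype precedence: RefSeq type, then GENCODE type, then the
    cascade's own call (coding if accepted, else antisense/lncRNA by
    position)."""
    if refseq_type:
        return normalize_biotype(refseq_type)
    if gencode_type:
        return normalize_biotype(gencode_type)
    if coding_accepted:
        return "protein_coding"
    for ref in references:
        for r in ref.overlapping(t.interval):
            if t.strand in "+-" and r.strand in "+-" and t.strand != r.strand:
                return "antisense"
    return "lncRNA"


# ---------------------------------------------------------------------------
# Cascades
# ---------------------------------------------------------------------------


def _run_stage(survivors, report, stage, fail_reason, predicate):
    """Apply one keep/remove stage to the ordered survivor list."""
    out = []
    for t in survivors:
        ok, reason = predicate(t)
        report.record(t.transcript_id, stage, ok, reason if not ok else "")
        if ok:
            out.append(t)
    return out


def coding_cascade(
    novel: AnnotationSet,
    expression: Mapping[str, ExpressionSummary],
    sequences: Mapping[str, str],
    homology: Sequence[HomologyHit],
    domains: Sequence[DomainHit],
    repeats: RepeatIndex,
    cfg: CurationConfig | None = None,
) -> tuple[AnnotationSet, FilterReport]:
    """Protein-coding candidate cascade with an audit trail.

    Stages, in order: expression gate; containment gate; minimum ORF
    length; LINE/LTR and rRNA exclusion of the ORF footprint / transcript;
    protein-homology gate; named-function requirement at conflicting
    opposite-strand loci; Alu/SVA screen waived by Pfam/CDD support.
    Accepted transcripts are returned re-biotyped as protein_coding.
    """
    cfg = cfg or CurationConfig()
    report = FilterReport()
    hits_by_query: dict[str, list[HomologyHit]] = {}
    for h in homology:
        hits_by_query.setdefault(h.query_id, []).append(h)

    survivors = sorted(novel, key=lambda t: (t.seqid, t.interval.start, t.transcript_id))

    def expr_gate(t):
        e = expression.get(t.transcript_id)
        if e is None:
            return False, "no expression evidence"
        ok = coding_expression_gate(t, e, cfg)
        return ok, "" if ok else "below expression thresholds"

    survivors = _run_stage(survivors, report, "expression", "", expr_gate)

    def contain_gate(t):
        ok = containment_gate(t, novel, expression, cfg)
        return ok, "" if ok else "contained in a better-supported transcript"

    survivors = _run_stage(survivors, report, "containment", "", contain_gate)

    orfs: dict[str, OrfRecord] = {}

    def orf_gate(t):
        seq = sequences.get(t.transcript_id)
        orf = longest_orf(seq, t.transcript_id) if seq else None
        if orf is None or orf.length_aa < cfg.min_orf_aa:
            return False, f"no ORF of >= {cfg.min_orf_aa} aa"
        orfs[t.transcript_id] = orf
        return True, ""

    survivors = _run_stage(survivors, report, "orf_length", "", orf_gate)

    def repeat_gate(t):
        orf = orfs[t.transcript_id]
        footprint = project_to_genome(t, orf.start, orf.end)
        for piece in footprint:
            if repeats.overlapping(piece, ("LINE", "LTR")):
                return False, "ORF overlaps LINE/LTR repeat"
        if repeats.exon_hit(t, ("rRNA",)):
            return False, "overlaps ribosomal RNA gene"
        return True, ""

    survivors = _run_stage(survivors, report, "repeat_rrna", "", repeat_gate)

    best_hits: dict[str, HomologyHit] = {}

    def homology_gate(t):
        orf = orfs[t.transcript_id]
        ok, best = passes_homology_gate(
            orf, hits_by_query.get(t.transcript_id, ()), cfg.max_evalue, cfg.min_orf_fraction
        )
        if ok:
            best_hits[t.transcript_id] = best
            return True, ""
        return False, "no qualifying protein homology"

    survivors = _run_stage(survivors, report, "homology", "", homology_gate)

    conflicted = set()
    for i, a in enumerate(survivors):
        for b in survivors[i + 1:]:
            if (a.seqid == b.seqid and a.strand in "+-" and b.strand in "+-"
                    and a.strand != b.strand and a.interval.overlaps(b.interval)):
                conflicted.add(a.transcript_id)
                conflicted.add(b.transcript_id)

    def conflict_gate(t):
        if t.transcript_id not in conflicted:
            return True, ""
        if has_named_function(best_hits[t.transcript_id].subject_description):
            return True, ""
        return False, "conflicting locus and best hit lacks a named function"

    survivors = _run_stage(survivors, report, "conflict_named_function", "", conflict_gate)

    def alu_sva_gate(t):
        if not repeats.exon_hit(t, ("Alu", "SVA")):
            return True, ""
        if has_domain_support(t.transcript_id, domains, cfg.domain_max_evalue):
            return True, ""
        return False, "overlaps Alu/SVA repeat without Pfam/CDD support"

    survivors = _run_stage(survivors, report, "alu_sva_screen", "", alu_sva_gate)

    accepted = AnnotationSet.from_transcripts(
        f"{novel.name}.coding",
        (replace_biotype(t, "protein_coding") for t in survivors),
    )
    return accepted, report


def replace_biotype(t: Transcript, biotype: str) -> Transcript:
    return replace(t, biotype=biotype)


def lncrna_rescue(
    lncrnas: AnnotationSet,
    sequences: Mapping[str, str],
    homology: Sequence[HomologyHit],
    cfg: CurationConfig | None = None,
    references: Sequence[AnnotationSet] = (),
) -> tuple[AnnotationSet, FilterReport]:
    """Recover mis-annotated protein-coding genes from an lncRNA catalog.

    An lncRNA is rescued when it carries an ORF of at least 180 bp (60 aa)
    whose best mammalian-protein hit passes the homology gate *and* has a
    named function, and the transcript is not a read-through (exonic
    overlap with >= 2 distinct reference gene loci on its strand — an
    assumed operational definition, exposed for override).
    """
    cfg = cfg or CurationConfig()
    report = FilterReport()
    hits_by_query: dict[str, list[HomologyHit]] = {}
    for h in homology:
        hits_by_query.setdefault(h.query_id, []).append(h)
    survivors = sorted(lncrnas, key=lambda t: (t.seqid, t.interval.start, t.transcript_id))

    orfs: dict[str, OrfRecord] = {}

    def orf_gate(t):
        seq = sequences.get(t.transcript_id)
        orf = longest_orf(seq, t.transcript_id) if seq else None
        if orf is None or orf.length_aa < cfg.min_orf_aa:
            return False, f"no ORF of >= {cfg.min_orf_aa} aa"
        orfs[t.transcript_id] = orf
        return True, ""

    survivors = _run_stage(survivors, report, "orf_length", "", orf_gate)

    def homology_named_gate(t):
        ok, best = passes_homology_gate(
            orfs[t.transcript_id], hits_by_query.get(t.transcript_id, ()),
            cfg.max_evalue, cfg.min_orf_fraction,
        )
        if not ok:
            return False, "no qualifying protein homology"
        if not has_named_function(best.subject_description):
            return False, "best hit lacks a named function"
        return True, ""

    survivors = _run_stage(survivors, report, "homology_named_function", "", homology_named_gate)

    def read_through_gate(t):
        gene_ids = {r.gene_id for r in _ref_exonic_hits(t, references, same_strand=True)}
        if len(gene_ids) >= 2:
            return False, f"read-through across {len(gene_ids)} reference genes"
        return True, ""

    survivors = _run_stage(survivors, report, "read_through", "", read_through_gate)

    rescued = AnnotationSet.from_transcripts(
        f"{lncrnas.name}.rescued",
        (replace_biotype(t, "protein_coding") for t in survivors),
    )
    return rescued, report


def noncoding_cascade(
    novel: AnnotationSet,
    expression: Mapping[str, ExpressionSummary],
    references: Sequence[AnnotationSet],
    similarities: Sequence[SimilarityRecord],
    repeats: RepeatIndex,
    cfg: CurationConfig | None = None,
) -> tuple[AnnotationSet, FilterReport]:
    """Noncoding noise-filter cascade with an audit trail.

    Stages, in the published order: (1) assembled in >= min_samples samples
    with mean TPM >= 1, or outlier-level expression; (2) no single-exon
    transcripts; (3) no rRNA overlap; (4) no retained introns relative to
    the reference intron annotation; (5) no near-identical copy of a known
    transcript (pseudogene signature); (6) no exonic overlap with reference
    exons on the opposite strand, and no spanning of multiple known genes;
    (7) at most the top_n most abundant novel transcripts per locus;
    (8) no processed-pseudogene or immunoglobulin/T-cell-receptor loci.
    """
    cfg = cfg or CurationConfig()
    report = FilterReport()
    survivors = sorted(novel, key=lambda t: (t.seqid, t.interval.start, t.transcript_id))

    def expr_gate(t):
        e = expression.get(t.transcript_id)
        if e is None:
            return False, "no expression evidence"
        if e.n_samples >= cfg.min_samples and e.mean_tpm >= cfg.min_avg_tpm:
            return True, ""
        if e.max_tpm > cfg.outlier_tpm:
            return True, ""
        return False, (f"assembled in {e.n_samples} samples, mean TPM {e.mean_tpm:.3g}")

    survivors = _run_stage(survivors, report, "expression_support", "", expr_gate)

    survivors = _run_stage(
        survivors, report, "single_exon", "",
        lambda t: (t.is_spliced, "single-exon noncoding transcript"),
    )

    ref_rrna = [
        AnnotationSet.from_transcripts(f"{ref.name}.rrna",
                                       [t for t in ref if t.biotype == "rRNA"])
        for ref in references
    ]

    def rrna_gate(t):
        if repeats.exon_hit(t, ("rRNA",)):
            return False, "overlaps ribosomal RNA gene"
        for ref in ref_rrna:
            for r in ref.overlapping(t.interval):
                if t.exonic_overlap(r, stranded=False):
                    return False, "overlaps ribosomal RNA gene"
        return True, ""

    survivors = _run_stage(survivors, report, "rrna_overlap", "", rrna_gate)

    ref_introns = reference_introns(references)

    survivors = _run_stage(
        survivors, report, "retained_intron", "",
        lambda t: (not retained_intron(t, ref_introns), "retained intron (pre-mRNA signature)"),
    )

    sim_by_novel: dict[str, list[SimilarityRecord]] = {}
    for s in similarities:
        sim_by_novel.setdefault(s.novel_id, []).append(s)

    def similarity_gate(t):
        for s in sim_by_novel.get(t.transcript_id, ()):
            if s.percent_identity >= cfg.pseudo_identity and s.coverage_fraction >= cfg.pseudo_coverage:
                return False, f"{s.percent_identity:.1f}% identical to {s.known_id} (pseudogene copy)"
        return True, ""

    survivors = _run_stage(survivors, report, "known_similarity", "", similarity_gate)

    def antisense_multi_gate(t):
        if _ref_exonic_hits(t, references, same_strand=False):
            return False, "exonic overlap with annotated transcript on opposite strand"
        gene_ids = {r.gene_id for r in _ref_exonic_hits(t, references, same_strand=True)}
        if len(gene_ids) >= 2:
            return False, f"overlaps {len(gene_ids)} known genes"
        return True, ""

    survivors = _run_stage(survivors, report, "antisense_multi_gene", "", antisense_multi_gate)

    # per-locus abundance cap: rank by mean TPM, ties by max TPM then id
    keep_ids = set()
    for locus in cluster_loci(survivors, stranded=True):
        ranked = sorted(
            locus.transcripts,
            key=lambda t: (
                -(expression[t.transcript_id].mean_tpm if t.transcript_id in expression else 0.0),
                -(expression[t.transcript_id].max_tpm if t.transcript_id in expression else 0.0),
                t.transcript_id,
            ),
        )
        keep_ids.update(t.transcript_id for t in ranked[:cfg.top_n_per_locus])

    survivors = _run_stage(
        survivors, report, "locus_abundance", "",
        lambda t: (t.transcript_id in keep_ids,
                   f"beyond the {cfg.top_n_per_locus} most abundant at its locus"),
    )

    survivors = _run_stage(
        survivors, report, "pseudogene_igtr_loci", "",
        lambda t: (not repeats.exon_hit(t, ("processed_pseudogene", "IG_TR")),
                   "processed pseudogene or Ig/TCR locus"),
    )

    accepted = AnnotationSet.from_transcripts(f"{novel.name}.noncoding", survivors)
    return accepted, report
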