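"""Three-way catalog comparison and summary reporting.

Annotation catalogs are compared at three resolutions: distinct introns
(exact coordinate identity), distinct exons, and intron chains ("same
transcript" = exactly the same introns, terminal ends ignored). Strand is
part of every identity key: identical coordinates on opposite strands are
distinct splicing events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Iterable, Mapping, Sequence

from .model import AnnotationSet, Transcript, introns_of

#: the seven non-empty regions of a three-set Venn diagram
VENN_REGIONS = ("A", "B", "C", "AB", "AC", "BC", "ABC")


@dataclass(frozen=True)
class VennPartition:
    """Counts over the 7 regions of three sets, plus the union size."""

    labels: tuple[str, str, str]
    counts: dict
    union_size: int

    def __post_init__(self) -> None:
        if set(self.counts) != set(VENN_REGIONS):
            raise ValueError(f"counts must cover exactly the regions {VENN_REGIONS}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative region count")
        if sum(self.counts.values()) != self.union_size:
            raise ValueError("region counts must sum to the union size")

    def __getitem__(self, region: str) -> int:
        return self.counts[region]

    def shared_by_all(self) -> int:
        return self.counts["ABC"]


def venn_partition(a: set, b: set, c: set, labels: tuple[str, str, str]) -> VennPartition:
    """Partition three key sets into the 7 Venn regions."""
    counts = {
        "A": len(a - b - c),
        "B": len(b - a - c),
        "C": len(c - a - b),
        "AB": len((a & b) - c),
        "AC": len((a & c) - b),
        "BC": len((b & c) - a),
        "ABC": len(a & b & c),
    }
    return VennPartition(labels, counts, len(a | b | c))


def _intron_keys(aset: AnnotationSet) -> set:
    return {
        (i.seqid, i.start, i.end, i.strand)
        for t in aset if t.is_spliced
        for i in introns_of(t)
    }


def _exon_keys(aset: AnnotationSet) -> set:
    return {(e.seqid, e.start, e.end, e.strand) for t in aset for e in t.exons}


def _chain_keys(aset: AnnotationSet) -> set:
    # single-exon transcripts have no intron chain and are excluded here;
    # they are counted separately by the callers that need them
    return {
        (t.seqid, t.strand, tuple((i.start, i.end) for i in introns_of(t)))
        for t in aset if t.is_spliced
    }


def intron_venn(a: AnnotationSet, b: AnnotationSet, c: AnnotationSet) -> VennPartition:
    """Share structure of distinct introns; identity = exact start/end
    coordinates (plus seqid and strand)."""
    return venn_partition(_intron_keys(a), _intron_keys(b), _intron_keys(c),
                          (a.name, b.name, c.name))


def exon_venn(a: AnnotationSet, b: AnnotationSet, c: AnnotationSet) -> VennPartition:
    """Share structure of distinct exons by exact outer coordinates
    (terminal exons included, which depresses agreement relative to
    introns)."""
    return venn_partition(_exon_keys(a), _exon_keys(b), _exon_keys(c),
                          (a.name, b.name, c.name))


def transcript_venn(a: AnnotationSet, b: AnnotationSet, c: AnnotationSet) -> VennPartition:
    """Share structure of spliced transcripts keyed by full intron chain."""
    return venn_partition(_chain_keys(a), _chain_keys(b), _chain_keys(c),
                          (a.name, b.name, c.name))


def round_ratio(numerator: float, denominator: float, places: int = 1) -> float:
    """Ratio rounded half-up to the given decimal places (report style)."""
    if denominator == 0:
        raise ZeroDivisionError("ratio denominator is zero")
    q = Decimal(numerator) / Decimal(denominator)
    return float(q.quantize(Decimal(1).scaleb(-places), rounding=ROUND_HALF_UP))


@dataclass
class CatalogSummary:
    """Per-biotype accounting of a catalog plus headline ratios."""

    name: str
    genes: dict = field(default_factory=dict)        # biotype -> gene count
    transcripts: dict = field(default_factory=dict)  # biotype -> transcript count
    isoforms_per_coding_gene: float | None = None
    isoforms_per_coding_gene_raw: float | None = None
    functional_activity_share: float | None = None

    @property
    def total_genes(self) -> int:
        return sum(self.genes.values())

    @property
    def total_transcripts(self) -> int:
        return sum(self.transcripts.values())

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "genes": dict(self.genes),
            "transcripts": dict(self.transcripts),
            "total_genes": self.total_genes,
            "total_transcripts": self.total_transcripts,
            "isoforms_per_coding_gene": self.isoforms_per_coding_gene,
            "isoforms_per_coding_gene_raw": self.isoforms_per_coding_gene_raw,
            "functional_activity_share": self.functional_activity_share,
        }


_BIOTYPE_PRIORITY = ("protein_coding", "lncRNA", "antisense", "miscRNA", "pseudogene", "rRNA", "other")


def summarize(
    catalog: AnnotationSet,
    expression: Mapping[str, object] | None = None,
    kept_ids: Iterable[str] | None = None,
    *,
    total_tpm: Callable[[object], float] | None = None,
) -> CatalogSummary:
    """Tally genes and transcripts per biotype and compute headline ratios.

    A gene's biotype is the highest-priority biotype among its transcripts
    (protein_coding first). When ``expression`` and ``kept_ids`` are given,
    the functional-activity share is the summed TPM of kept transcripts
    over the summed TPM of all transcripts — the fraction of transcriptional
    activity devoted to retained (functional) transcripts.
    """
    gene_bt: dict[str, str] = {}
    tx_counts: dict[str, int] = {}
    for t in catalog:
        tx_counts[t.biotype] = tx_counts.get(t.biotype, 0) + 1
        cur = gene_bt.get(t.gene_id)
        if cur is None or _BIOTYPE_PRIORITY.index(t.biotype) < _BIOTYPE_PRIORITY.index(cur):
            gene_bt[t.gene_id] = t.biotype
    gene_counts: dict[str, int] = {}
    for bt in gene_bt.values():
        gene_counts[bt] = gene_counts.get(bt, 0) + 1

    summary = CatalogSummary(catalog.name, gene_counts, tx_counts)
    n_cg = gene_counts.get("protein_coding", 0)
    n_ct = tx_counts.get("protein_coding", 0)
    if n_cg:
        summary.isoforms_per_coding_gene_raw = n_ct / n_cg
        summary.isoforms_per_coding_gene = round_ratio(n_ct, n_cg)

    if expression is not None and kept_ids is not None:
        get_total = total_tpm or (lambda e: getattr(e, "mean_tpm") * getattr(e, "n_samples"))
        kept = set(kept_ids)
        tot = kept_tot = 0.0
        for t in catalog:
            e = expression.get(t.transcript_id)
            if e is None:
                continue
            v = float(get_total(e))
            tot += v
            if t.transcript_id in kept:
                kept_tot += v
        summary.functional_activity_share = (kept_tot / tot) if tot > 0 else None
    return summary


def activity_share(
    total_tpm_by_transcript: Mapping[str, float], kept_ids: Iterable[str]
) -> float:
    """Fraction of summed transcriptional activity in the kept transcripts."""
    kept = set(kept_ids)
    tot = sum(total_tpm_by_transcript.values())
    if tot <= 0:
        raise ValueError("no transcriptional activity")
    return sum(v for k, v in total_tpm_by_transcript.items() if k in kept) / tot
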