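"""Genomic annotation data model and I/O.

Coordinates are 1-based inclusive throughout (GTF convention). BED input is
converted from 0-based half-open at the parser boundary. The model is
deliberately small: transcripts are exon chains on one strand of one
sequence, loci are transitive-closure clusters of exonic overlap, and an
annotation set is a named collection of transcripts with a positional index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

from gffutils.feature import feature_from_line
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

#: Fixed biotype vocabulary; unknown biotypes map to "other" with a warning.
BIOTYPES = ("protein_coding", "lncRNA", "antisense", "miscRNA", "pseudogene", "rRNA", "other")

_BIOTYPE_ALIASES = {
    "protein_coding": "protein_coding",
    "mrna": "protein_coding",
    "lncrna": "lncRNA",
    "lincrna": "lncRNA",
    "lnc_rna": "lncRNA",
    "antisense": "antisense",
    "antisense_rna": "antisense",
    "miscrna": "miscRNA",
    "misc_rna": "miscRNA",
    "rrna": "rRNA",
}


def normalize_biotype(raw: str | None) -> str:
    """Map a free-form biotype string onto the fixed vocabulary."""
    if not raw:
        return "other"
    key = raw.strip().lower()
    if key in _BIOTYPE_ALIASES:
        return _BIOTYPE_ALIASES[key]
    if "pseudogene" in key:
        return "pseudogene"
    if raw in BIOTYPES:
        return raw
    log.warning("unknown biotype %r mapped to 'other'", raw)
    return "other"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed 1-based interval on one sequence.

    ``strand`` is '+', '-' or '.' (unstranded).
    """

    seqid: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end < start: {self.end} < {self.start}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        """1-bp overlap on the same sequence; strand is ignored here."""
        return self.seqid == other.seqid and self.start <= other.end and other.start <= self.end

    def contains(self, other: "GenomicInterval") -> bool:
        return self.seqid == other.seqid and self.start <= other.start and other.end <= self.end


def strands_compatible(a: str, b: str) -> bool:
    """True unless both strands are explicit and different."""
    return a == "." or b == "." or a == b


class IntronChain(tuple):
    """Ordered introns of a spliced transcript (empty for single-exon).

    Each intron is the gap between consecutive exons: donor = previous exon
    end + 1, acceptor = next exon start - 1, stored as a GenomicInterval.
    """

    __slots__ = ()

    def key(self) -> tuple:
        """Hashable identity key: (seqid, strand, ((s, e), ...))."""
        if not self:
            raise ValueError("empty intron chain has no identity key")
        return (self[0].seqid, self[0].strand, tuple((i.start, i.end) for i in self))


@dataclass
class Transcript:
    """An exon chain with identity and classification.

    Exons are sorted, non-overlapping, all on the same seqid/strand.
    Abutting exons (zero-length gap) are merged on construction.
    """

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    biotype: str = "other"
    source: str = ""
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        exons = sorted(self.exons, key=lambda e: (e.start, e.end))
        if not exons:
            raise ValueError(f"transcript {self.transcript_id}: no exons")
        seqids = {e.seqid for e in exons}
        strands = {e.strand for e in exons}
        if len(seqids) > 1 or len(strands) > 1:
            raise ValueError(f"transcript {self.transcript_id}: exons span seqids/strands")
        merged: list[GenomicInterval] = [exons[0]]
        for e in exons[1:]:
            prev = merged[-1]
            if e.start <= prev.end + 1:
                if e.start <= prev.end:
                    raise ValueError(
                        f"transcript {self.transcript_id}: overlapping exons "
                        f"{prev.start}-{prev.end} and {e.start}-{e.end}"
                    )
                log.warning(
                    "transcript %s: abutting exons %d-%d|%d-%d merged",
                    self.transcript_id, prev.start, prev.end, e.start, e.end,
                )
                merged[-1] = replace(prev, end=e.end)
            else:
                merged.append(e)
        self.exons = tuple(merged)
        if self.biotype not in BIOTYPES:
            self.biotype = normalize_biotype(self.biotype)

    @property
    def seqid(self) -> str:
        return self.exons[0].seqid

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.seqid, self.exons[0].start, self.exons[-1].end, self.strand)

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def is_spliced(self) -> bool:
        return len(self.exons) >= 2

    @property
    def exonic_length(self) -> int:
        return sum(e.length for e in self.exons)

    def exonic_overlap(self, other: "Transcript", *, stranded: bool = True) -> bool:
        """True if any exon of self shares >= 1 bp with any exon of other."""
        if self.seqid != other.seqid:
            return False
        if stranded and not strands_compatible(self.strand, other.strand):
            return False
        i = j = 0
        a, b = self.exons, other.exons
        while i < len(a) and j < len(b):
            if a[i].end < b[j].start:
                i += 1
            elif b[j].end < a[i].start:
                j += 1
            else:
                return True
        return False


def introns_of(t: Transcript) -> IntronChain:
    """Derive the intron chain of a transcript (empty for single-exon)."""
    introns = []
    for prev, nxt in zip(t.exons, t.exons[1:]):
        introns.append(GenomicInterval(t.seqid, prev.end + 1, nxt.start - 1, t.strand))
    return IntronChain(introns)


def project_to_genome(t: Transcript, tstart: int, tend: int) -> list[GenomicInterval]:
    """Map a 1-based transcript-coordinate span onto genomic intervals.

    Transcript position 1 is the 5' end: the first exon start on '+', the
    last exon end on '-'. The result is a list of exonic genomic intervals
    covering the span, in genomic order.
    """
    if not 1 <= tstart <= tend <= t.exonic_length:
        raise ValueError(f"span {tstart}-{tend} outside transcript of length {t.exonic_length}")
    exons = t.exons if t.strand != "-" else tuple(reversed(t.exons))
    out = []
    offset = 0
    for e in exons:
        lo, hi = offset + 1, offset + e.length
        if hi >= tstart and lo <= tend:
            a, b = max(tstart, lo) - lo, min(tend, hi) - lo  # within-exon offsets, 5'->3'
            if t.strand != "-":
                out.append(GenomicInterval(e.seqid, e.start + a, e.start + b, t.strand))
            else:
                out.append(GenomicInterval(e.seqid, e.end - b, e.end - a, t.strand))
        offset = hi
    out.sort(key=lambda g: g.start)
    return out


def chain_key(t: Transcript) -> tuple:
    """Intron-chain identity key of a spliced transcript."""
    chain = introns_of(t)
    if not chain:
        raise ValueError(f"transcript {t.transcript_id} is unspliced; chain key undefined")
    return chain.key()


@dataclass
class Locus:
    locus_id: str
    interval: GenomicInterval
    transcripts: list[Transcript]


@dataclass
class AnnotationSet:
    """A named transcript catalog with a positional index over spans."""

    name: str
    _transcripts: dict[str, Transcript] = field(default_factory=dict)
    _index: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    @classmethod
    def from_transcripts(cls, name: str, transcripts: Iterable[Transcript]) -> "AnnotationSet":
        aset = cls(name)
        for t in transcripts:
            aset.add(t)
        return aset

    def add(self, t: Transcript) -> None:
        if t.transcript_id in self._transcripts:
            raise ValueError(f"duplicate transcript_id {t.transcript_id!r} in set {self.name!r}")
        self._transcripts[t.transcript_id] = t
        iv = t.interval
        # IntervalTree is half-open; store [start, end+1)
        self._index.setdefault(iv.seqid, IntervalTree()).addi(iv.start, iv.end + 1, t)

    def __len__(self) -> int:
        return len(self._transcripts)

    def __iter__(self) -> Iterator[Transcript]:
        return iter(self._transcripts.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._transcripts

    def __getitem__(self, transcript_id: str) -> Transcript:
        return self._transcripts[transcript_id]

    @property
    def transcripts(self) -> Sequence[Transcript]:
        return list(self._transcripts.values())

    def overlapping(self, interval: GenomicInterval) -> list[Transcript]:
        """Transcripts whose span overlaps the interval (strand ignored)."""
        tree = self._index.get(interval.seqid)
        if tree is None:
            return []
        hits = [h.data for h in tree.overlap(interval.start, interval.end + 1)]
        hits.sort(key=lambda t: (t.interval.start, t.interval.end, t.transcript_id))
        return hits

    def loci(self, *, stranded: bool = True) -> list[Locus]:
        return cluster_loci(self.transcripts, stranded=stranded)

    def biotype_tally(self) -> dict[str, dict[str, int]]:
        """Per-biotype gene and transcript counts."""
        genes: dict[str, set] = {}
        txs: dict[str, int] = {}
        for t in self:
            genes.setdefault(t.biotype, set()).add(t.gene_id)
            txs[t.biotype] = txs.get(t.biotype, 0) + 1
        return {
            bt: {"genes": len(genes.get(bt, ())), "transcripts": txs.get(bt, 0)}
            for bt in sorted(set(genes) | set(txs))
        }


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def cluster_loci(
    transcripts: Sequence[Transcript], *, stranded: bool = True, id_prefix: str = "LOC"
) -> list[Locus]:
    """Partition transcripts into loci by transitive exonic overlap.

    With ``stranded=True`` (default) only same-strand exon overlap links two
    transcripts; unstranded transcripts link to either strand. Locus ids are
    deterministic, ordered by genomic position.
    """
    ts = list(transcripts)
    if not ts:
        return []
    uf = _UnionFind(len(ts))
    groups: dict[tuple, list[tuple[int, int, int]]] = {}
    for idx, t in enumerate(ts):
        strands = [t.strand] if (stranded and t.strand != ".") else (["+", "-"] if stranded else ["."])
        for s in strands:
            key = (t.seqid, s) if stranded else (t.seqid,)
            for e in t.exons:
                groups.setdefault(key, []).append((e.start, e.end, idx))
    # sweep: an exon starting at or before the running max end overlaps the
    # exon holding that max end, so union with the run representative
    for exons in groups.values():
        exons.sort()
        run_rep, run_end = None, -1
        for start, end, idx in exons:
            if run_rep is not None and start <= run_end:
                uf.union(run_rep, idx)
                run_end = max(run_end, end)
            else:
                run_rep, run_end = idx, end
    members: dict[int, list[Transcript]] = {}
    for idx, t in enumerate(ts):
        members.setdefault(uf.find(idx), []).append(t)
    loci = []
    for txs in members.values():
        txs.sort(key=lambda t: (t.interval.start, t.interval.end, t.transcript_id))
        seqid = txs[0].seqid
        start = min(t.interval.start for t in txs)
        end = max(t.interval.end for t in txs)
        strand = txs[0].strand if len({t.strand for t in txs}) == 1 else "."
        loci.append((seqid, start, end, strand, txs))
    loci.sort(key=lambda l: (l[0], l[1], l[2], l[3]))
    width = max(6, len(str(len(loci))))
    return [
        Locus(f"{id_prefix}{i + 1:0{width}d}", GenomicInterval(s, a, b, st), txs)
        for i, (s, a, b, st, txs) in enumerate(loci)
    ]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_TX_FEATURE_TYPES = {
    "transcript", "mRNA", "lnc_RNA", "lncRNA", "ncRNA", "antisense_RNA",
    "misc_RNA", "rRNA", "pseudogenic_transcript", "primary_transcript",
}

_BIOTYPE_ATTR_KEYS = ("transcript_biotype", "transcript_type", "gene_biotype", "gene_type", "biotype")


def _open(source):
    """Accept a filesystem path or an open text stream."""
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        return open(source, "rt"), True
    return source, False


def parse_gtf(source, name: str = "catalog") -> AnnotationSet:
    """Parse GTF2.2 exon features into an AnnotationSet.

    ``source`` is a path or a text stream. One Transcript is built per
    distinct transcript_id, with exons sorted; biotype is read from the
    usual attribute keys when present, else "other". Records with end <
    start are rejected with a diagnostic; an exon without a transcript_id
    is a hard error naming the line number.
    """
    fh, close = _open(source)
    try:
        return _parse_annotation(fh, name, dialect="gtf")
    finally:
        if close:
            fh.close()


def parse_gff3(source, name: str = "catalog") -> AnnotationSet:
    """Parse GFF3 (exon features with Parent attributes) into an AnnotationSet."""
    fh, close = _open(source)
    try:
        return _parse_annotation(fh, name, dialect="gff3")
    finally:
        if close:
            fh.close()


def _parse_annotation(fh, name: str, dialect: str) -> AnnotationSet:
    exons: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, dict] = {}
    tx_parent: dict[str, str] = {}  # gff3: transcript id -> gene id
    tx_biotype: dict[str, str] = {}
    for lineno, line in enumerate(fh, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        try:
            feat = feature_from_line(line)
        except Exception as exc:  # malformed line
            log.warning("line %d rejected: %s", lineno, exc)
            continue
        if feat.end < feat.start:
            log.warning("line %d rejected: end < start (%d < %d)", lineno, feat.end, feat.start)
            continue
        ftype = feat.featuretype
        attrs = {k: v[0] for k, v in feat.attributes.items() if v}
        if dialect == "gff3" and ftype in _TX_FEATURE_TYPES:
            tid = attrs.get("ID")
            if tid:
                tx_parent[tid] = attrs.get("Parent", attrs.get("geneID", tid))
                bt = next((attrs[k] for k in _BIOTYPE_ATTR_KEYS if k in attrs), None)
                tx_biotype[tid] = normalize_biotype(bt if bt else ftype)
            continue
        if ftype != "exon":
            continue
        if dialect == "gtf":
            tid = attrs.get("transcript_id")
            gid = attrs.get("gene_id", tid)
        else:
            tid = attrs.get("Parent") or attrs.get("transcript_id")
            gid = None
        if not tid:
            raise ValueError(f"line {lineno}: exon feature lacks a transcript identifier")
        exons.setdefault(tid, []).append(
            GenomicInterval(feat.seqid, feat.start, feat.end, feat.strand if feat.strand in "+-" else ".")
        )
        if tid not in meta:
            bt = next((attrs[k] for k in _BIOTYPE_ATTR_KEYS if k in attrs), None)
            meta[tid] = {
                "gene_id": gid,
                "biotype": normalize_biotype(bt) if bt else None,
                "attributes": {
                    k: v for k, v in attrs.items()
                    if k not in ("transcript_id", "gene_id", "Parent", "ID")
                },
            }
    aset = AnnotationSet(name)
    for tid, exon_list in exons.items():
        m = meta[tid]
        gid = m["gene_id"] or tx_parent.get(tid, tid)
        bt = m["biotype"] or tx_biotype.get(tid) or "other"
        aset.add(Transcript(tid, gid, tuple(exon_list), biotype=bt, source=name,
                            attributes=m["attributes"]))
    return aset


def write_gtf(aset: AnnotationSet, dest) -> None:
    """Write an AnnotationSet as GTF (transcript + exon features)."""
    fh, close = (open(dest, "wt"), True) if isinstance(dest, (str, bytes)) or hasattr(dest, "__fspath__") else (dest, False)
    try:
        for t in sorted(aset, key=lambda t: (t.seqid, t.interval.start, t.interval.end, t.transcript_id)):
            base = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; biotype "{t.biotype}";'
            extra = "".join(f' {k} "{v}";' for k, v in t.attributes.items())
            iv = t.interval
            fh.write(f"{iv.seqid}\t{t.source or aset.name}\ttranscript\t{iv.start}\t{iv.end}\t.\t{t.strand}\t.\t{base}{extra}\n")
            for e in t.exons:
                fh.write(f"{e.seqid}\t{t.source or aset.name}\texon\t{e.start}\t{e.end}\t.\t{t.strand}\t.\t{base}\n")
    finally:
        if close:
            fh.close()


def parse_bed(source) -> list[tuple[GenomicInterval, str]]:
    """Read BED (>= 4 columns) into 1-based inclusive intervals plus the name column.

    BED is 0-based half-open; conversion happens here and nowhere else.
    """
    fh, close = _open(source)
    out = []
    try:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                log.warning("BED line %d rejected: fewer than 3 columns", lineno)
                continue
            seqid, start0, end0 = cols[0], int(cols[1]), int(cols[2])
            if end0 <= start0:
                log.warning("BED line %d rejected: empty interval", lineno)
                continue
            name = cols[3] if len(cols) > 3 else ""
            strand = cols[5] if len(cols) > 5 and cols[5] in "+-" else "."
            out.append((GenomicInterval(seqid, start0 + 1, end0, strand), name))
    finally:
        if close:
            fh.close()
    return out


def read_fasta(source) -> dict[str, str]:
    """Read a (small) FASTA file into an id -> sequence dict."""
    from Bio import SeqIO

    fh, close = _open(source)
    try:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
    finally:
        if close:
            fh.close()


def write_fasta(seqs: Mapping[str, str], dest, width: int = 70) -> None:
    fh, close = (open(dest, "wt"), True) if isinstance(dest, (str, bytes)) or hasattr(dest, "__fspath__") else (dest, False)
    try:
        for sid in seqs:
            fh.write(f">{sid}\n")
            s = seqs[sid]
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")
    finally:
        if close:
            fh.close()
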