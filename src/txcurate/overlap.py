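"""Pairwise transcript comparison and multi-sample catalog merging.

Overlap classification follows gffcompare-style conventions: a single code
per ordered (query, reference) pair, chosen by a fixed priority. Intron-chain
identity is the notion of "same transcript" used throughout — two spliced
transcripts are the same iff their intron coordinates match exactly,
regardless of terminal exon ends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import (
    AnnotationSet,
    GenomicInterval,
    Transcript,
    introns_of,
    strands_compatible,
)

log = logging.getLogger(__name__)


class OverlapClass(str, Enum):
    """Classification of a (query, reference) transcript pair, best first."""

    chain_match = "chain_match"
    contained = "contained"
    container = "container"
    junction_share = "junction_share"
    exon_overlap = "exon_overlap"
    intronic = "intronic"
    antisense_exonic = "antisense_exonic"
    none = "none"


_PRIORITY = {c: i for i, c in enumerate(OverlapClass)}


def intron_chain_equal(a: Transcript, b: Transcript) -> bool:
    """True iff both transcripts have the identical intron chain.

    Terminal exon end coordinates are ignored; same seqid and strand are
    required. Undefined (raises) when both transcripts are unspliced.
    """
    if not a.is_spliced and not b.is_spliced:
        raise ValueError("intron chain identity is undefined for two unspliced transcripts")
    if not (a.is_spliced and b.is_spliced):
        return False
    if a.seqid != b.seqid or not strands_compatible(a.strand, b.strand):
        return False
    ia, ib = introns_of(a), introns_of(b)
    return [(i.start, i.end) for i in ia] == [(i.start, i.end) for i in ib]


def _sub_chain_offset(q: Transcript, r: Transcript) -> int | None:
    """Offset at which q's intron chain occurs contiguously in r's, else None.

    For a single-exon q, returns the index of the r exon containing it.
    """
    if not q.is_spliced:
        for k, e in enumerate(r.exons):
            if e.contains(q.exons[0]):
                return k
        return None
    qi = [(i.start, i.end) for i in introns_of(q)]
    ri = [(i.start, i.end) for i in introns_of(r)]
    n, m = len(qi), len(ri)
    for k in range(m - n + 1):
        if ri[k:k + n] == qi:
            return k
    return None


def _is_contained(q: Transcript, r: Transcript) -> bool:
    """q's exons all fall within r's exons and q's chain is a contiguous
    sub-chain of r's (trivially so for single-exon q)."""
    if q.seqid != r.seqid or not strands_compatible(q.strand, r.strand):
        return False
    if q.is_spliced and not r.is_spliced:
        return False
    k = _sub_chain_offset(q, r)
    if k is None:
        return False
    if not q.is_spliced:
        return True
    # internal exons are pinned by the matched introns; check the terminals
    return (r.exons[k].contains(q.exons[0])
            and r.exons[k + len(q.exons) - 1].contains(q.exons[-1]))


def classify_overlap(q: Transcript, r: Transcript) -> OverlapClass:
    """Single best classification of query q against reference r."""
    same_seq = q.seqid == r.seqid
    if not same_seq:
        return OverlapClass.none
    compat = strands_compatible(q.strand, r.strand)
    if compat and q.is_spliced and r.is_spliced and intron_chain_equal(q, r):
        return OverlapClass.chain_match
    if _is_contained(q, r):
        return OverlapClass.contained
    if _is_contained(r, q):
        return OverlapClass.container
    if compat and q.is_spliced and r.is_spliced:
        qi = {(i.start, i.end) for i in introns_of(q)}
        ri = {(i.start, i.end) for i in introns_of(r)}
        if qi & ri:
            return OverlapClass.junction_share
    exon_hit = q.exonic_overlap(r, stranded=False)
    if compat and exon_hit:
        return OverlapClass.exon_overlap
    if compat and q.interval.overlaps(r.interval) and not exon_hit:
        for intron in introns_of(r):
            if intron.contains(q.interval):
                return OverlapClass.intronic
    if not compat and exon_hit:
        return OverlapClass.antisense_exonic
    return OverlapClass.none


def _exonic_overlap_bp(a: Transcript, b: Transcript) -> int:
    if a.seqid != b.seqid:
        return 0
    total, i, j = 0, 0, 0
    while i < len(a.exons) and j < len(b.exons):
        ea, eb = a.exons[i], b.exons[j]
        lo, hi = max(ea.start, eb.start), min(ea.end, eb.end)
        if lo <= hi:
            total += hi - lo + 1
        if ea.end < eb.end:
            i += 1
        else:
            j += 1
    return total


def best_reference(q: Transcript, refs: Sequence[Transcript]) -> tuple[OverlapClass, Transcript | None]:
    """Best class of q over candidate references, with the winning reference.

    Ties on class are broken by longest exonic overlap, then transcript id.
    """
    best_cls, best_ref, best_key = OverlapClass.none, None, None
    for r in refs:
        cls = classify_overlap(q, r)
        if cls is OverlapClass.none:
            continue
        key = (_PRIORITY[cls], -_exonic_overlap_bp(q, r), r.transcript_id)
        if best_key is None or key < best_key:
            best_cls, best_ref, best_key = cls, r, key
    return best_cls, best_ref


def stream_compare(queries, reference: AnnotationSet) -> pd.DataFrame:
    """Classify every query against an indexed reference catalog.

    ``queries`` is an AnnotationSet or an iterable of transcripts; an
    unsorted stream is sorted internally with a logged warning. Returns a
    DataFrame with columns query_id, overlap_class, best_reference_id.
    """
    qs = list(queries)
    order = [(t.seqid, t.interval.start, t.interval.end) for t in qs]
    if order != sorted(order):
        log.warning("query stream not position-sorted; sorting internally")
        qs.sort(key=lambda t: (t.seqid, t.interval.start, t.interval.end, t.transcript_id))
    rows = []
    for q in qs:
        cands = reference.overlapping(q.interval)
        cls, ref = best_reference(q, cands)
        rows.append((q.transcript_id, cls.value, ref.transcript_id if ref else ""))
    return pd.DataFrame(rows, columns=["query_id", "overlap_class", "best_reference_id"])


def adjust_ends_to_reference(q: Transcript, r: Transcript) -> Transcript:
    """Replace q's terminal exon outer coordinates with r's.

    Only valid for a chain-matched pair (experimentally supported reference
    ends, e.g. CAGE-defined 5' ends, override assembled ends); the internal
    structure is untouched.
    """
    if classify_overlap(q, r) is not OverlapClass.chain_match:
        raise ValueError(
            f"end adjustment requires a chain match: {q.transcript_id} vs {r.transcript_id}"
        )
    exons = list(q.exons)
    first, last = exons[0], exons[-1]
    exons[0] = GenomicInterval(first.seqid, r.exons[0].start, first.end, first.strand)
    exons[-1] = GenomicInterval(last.seqid, exons[-1].start, r.exons[-1].end, last.strand)
    return Transcript(q.transcript_id, q.gene_id, tuple(exons), biotype=q.biotype,
                      source=q.source, attributes=dict(q.attributes))


# ---------------------------------------------------------------------------
# Multi-sample merging
# ---------------------------------------------------------------------------


@dataclass
class MergedTranscript(Transcript):
    """A representative transcript with sample/tissue provenance.

    support = number of distinct source samples; a sample contributes at
    most once per merged transcript.
    """

    sample_ids: frozenset = frozenset()
    tissue_support: dict = field(default_factory=dict)
    source_ids: list = field(default_factory=list)

    @property
    def support(self) -> int:
        return len(self.sample_ids)


def _as_merged(t: Transcript, sample: str, tissue: str | None) -> MergedTranscript:
    if isinstance(t, MergedTranscript):
        return t
    return MergedTranscript(
        t.transcript_id, t.gene_id, t.exons, biotype=t.biotype, source=t.source,
        attributes=dict(t.attributes), sample_ids=frozenset([sample]),
        tissue_support={tissue: 1} if tissue else {}, source_ids=[f"{sample}:{t.transcript_id}"],
    )


def _combine(rep: MergedTranscript, members: Sequence[MergedTranscript],
             exons: tuple[GenomicInterval, ...]) -> MergedTranscript:
    samples = frozenset().union(*(m.sample_ids for m in members))
    tissues: dict[str, int] = {}
    for m in members:
        for k, v in m.tissue_support.items():
            tissues[k] = tissues.get(k, 0) + v
    source_ids = sorted(set(sid for m in members for sid in m.source_ids))
    return MergedTranscript(
        rep.transcript_id, rep.gene_id, exons, biotype=rep.biotype, source=rep.source,
        attributes=dict(rep.attributes), sample_ids=samples, tissue_support=tissues,
        source_ids=source_ids,
    )


def _exons_from_chain(chain: Sequence[tuple[int, int]], start: int, end: int,
                      seqid: str, strand: str) -> tuple[GenomicInterval, ...]:
    bounds = [start]
    for s, e in chain:
        bounds.extend([s - 1, e + 1])
    bounds.append(end)
    return tuple(
        GenomicInterval(seqid, bounds[i], bounds[i + 1], strand)
        for i in range(0, len(bounds), 2)
    )


def _merge_members(members: list[MergedTranscript]) -> list[MergedTranscript]:
    """One merge pass: chain-identity collapse, then containment absorption."""
    spliced = [m for m in members if m.is_spliced]
    mono = [m for m in members if not m.is_spliced]

    # 1) collapse identical intron chains, extent = union of member extents
    by_chain: dict[tuple, list[MergedTranscript]] = {}
    for m in spliced:
        key = (m.seqid, m.strand, tuple((i.start, i.end) for i in introns_of(m)))
        by_chain.setdefault(key, []).append(m)
    collapsed: list[MergedTranscript] = []
    for (seqid, strand, chain), group in by_chain.items():
        group.sort(key=lambda m: m.transcript_id)
        start = min(m.interval.start for m in group)
        end = max(m.interval.end for m in group)
        exons = _exons_from_chain(chain, start, end, seqid, strand)
        collapsed.append(_combine(group[0], group, exons))

    # 2) absorb transcripts whose chain is strictly contained in a kept one
    collapsed.sort(key=lambda m: (-len(m.exons), -(m.interval.length), m.transcript_id))
    kept: list[MergedTranscript] = []
    for cand in collapsed:
        container = None
        for k in kept:
            if k.seqid == cand.seqid and k.interval.overlaps(cand.interval) and _is_contained(cand, k):
                container = k
                break
        if container is None:
            kept.append(cand)
        else:
            kept[kept.index(container)] = _combine(container, [container, cand], container.exons)

    # 3) single-exon transcripts merge by reciprocal exonic overlap (same strand)
    groups: dict[tuple, list[MergedTranscript]] = {}
    for m in mono:
        groups.setdefault((m.seqid, m.strand), []).append(m)
    for group in groups.values():
        group.sort(key=lambda m: (m.interval.start, m.interval.end, m.transcript_id))
        run: list[MergedTranscript] = []
        run_end = -1
        for m in group:
            if run and m.interval.start <= run_end:
                run.append(m)
                run_end = max(run_end, m.interval.end)
            else:
                if run:
                    kept.append(_fuse_mono(run))
                run, run_end = [m], m.interval.end
        if run:
            kept.append(_fuse_mono(run))

    kept.sort(key=lambda m: (m.seqid, m.interval.start, m.interval.end, m.transcript_id))
    return kept


def _fuse_mono(run: list[MergedTranscript]) -> MergedTranscript:
    rep = min(run, key=lambda m: m.transcript_id)
    seqid, strand = rep.seqid, rep.strand
    start = min(m.interval.start for m in run)
    end = max(m.interval.end for m in run)
    return _combine(rep, run, (GenomicInterval(seqid, start, end, strand),))


def merge_catalogs(groups: Mapping[str, Sequence[AnnotationSet]], name: str = "merged") -> AnnotationSet:
    """Two-stage merge of per-sample catalogs grouped by tissue.

    Samples are merged within each tissue first, then the per-tissue results
    are merged globally — the strategy used to build a single consistent
    transcript set from thousands of individually assembled samples.
    Transcripts with identical intron chains collapse to one representative
    with union extent; spliced transcripts strictly contained (sub-chain) in
    a co-located longer transcript collapse into it; support counts the
    distinct contributing samples.
    """
    seen_samples: set[str] = set()
    tissue_results: list[list[MergedTranscript]] = []
    for tissue in sorted(groups):
        members: list[MergedTranscript] = []
        for sample_set in groups[tissue]:
            if sample_set.name in seen_samples:
                raise ValueError(f"duplicate sample name {sample_set.name!r} across groups")
            seen_samples.add(sample_set.name)
            for t in sample_set:
                members.append(_as_merged(t, sample_set.name, tissue))
        tissue_results.append(_merge_members(members))
    merged = _merge_members([m for res in tissue_results for m in res])

    out = AnnotationSet(name)
    used_ids: set[str] = set()
    for m in merged:
        tid = m.transcript_id
        n = 1
        while tid in used_ids:
            tid = f"{m.transcript_id}.{n}"
            n += 1
        used_ids.add(tid)
        if tid != m.transcript_id:
            m = _combine(m, [m], m.exons)
            m.transcript_id = tid
        m.attributes = dict(m.attributes)
        m.attributes["num_samples"] = str(m.support)
        m.attributes["tissues"] = ",".join(sorted(m.tissue_support))
        out.add(m)
    return out
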