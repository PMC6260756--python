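"""Pairwise classification, streaming comparison, and catalog merging."""

import numpy as np
import pytest

from txcurate.model import AnnotationSet, GenomicInterval, Transcript, introns_of
from txcurate.overlap import (
    OverlapClass,
    adjust_ends_to_reference,
    best_reference,
    classify_overlap,
    intron_chain_equal,
    merge_catalogs,
    stream_compare,
)
from txcurate.simulate import random_transcripts

from conftest import make_tx


FOUR_EXON = [(100, 200), (300, 400), (500, 600), (700, 800)]


class TestChainIdentity:
    def test_self_identity(self):
        t = make_tx("t", FOUR_EXON)
        assert intron_chain_equal(t, t)

    def test_terminal_extension_is_same_transcript(self):
        a = make_tx("a", FOUR_EXON)
        b = make_tx("b", [(50, 200)] + FOUR_EXON[1:])  # 5' end extended 50 bp
        assert intron_chain_equal(a, b)

    def test_one_shifted_intron_differs(self):
        a = make_tx("a", FOUR_EXON)
        b = make_tx("b", [(100, 201)] + FOUR_EXON[1:])  # donor moved by 1 bp
        set_a = {(i.start, i.end) for i in introns_of(a)}
        set_b = {(i.start, i.end) for i in introns_of(b)}
        assert not intron_chain_equal(a, b)
        assert set_a != set_b  # brute-force set comparison agrees

    def test_undefined_for_two_unspliced(self):
        a, b = make_tx("a", [(1, 50)]), make_tx("b", [(10, 60)])
        with pytest.raises(ValueError, match="unspliced"):
            intron_chain_equal(a, b)

    def test_spliced_vs_unspliced_is_false(self):
        assert not intron_chain_equal(make_tx("a", FOUR_EXON), make_tx("b", [(100, 800)]))


class TestClassifyOverlap:
    def test_identical_is_chain_match(self):
        t = make_tx("t", FOUR_EXON)
        assert classify_overlap(t, t) is OverlapClass.chain_match

    def test_internal_sub_chain_is_contained(self):
        r = make_tx("r", FOUR_EXON)
        q = make_tx("q", [(300, 400), (500, 600)])
        assert classify_overlap(q, r) is OverlapClass.contained
        assert classify_overlap(r, q) is OverlapClass.container

    def test_terminal_exon_outside_container_breaks_containment(self):
        r = make_tx("r", FOUR_EXON)
        q = make_tx("q", [(250, 400), (500, 600)])  # 5' end reaches into r's intron
        assert classify_overlap(q, r) is OverlapClass.junction_share

    def test_antisense_exonic(self):
        r = make_tx("r", FOUR_EXON, strand="+")
        q = make_tx("q", [(150, 350)], strand="-")
        assert classify_overlap(q, r) is OverlapClass.antisense_exonic

    def test_intronic(self):
        r = make_tx("r", FOUR_EXON)
        q = make_tx("q", [(420, 480)])
        assert classify_overlap(q, r) is OverlapClass.intronic

    def test_chain_match_is_symmetric_and_containment_inverse(self, rng):
        ts = random_transcripts(rng, 120, region=8_000, max_exons=4)
        for i in range(len(ts)):
            for j in range(i + 1, len(ts)):
                ab = classify_overlap(ts[i], ts[j])
                ba = classify_overlap(ts[j], ts[i])
                assert (ab is OverlapClass.chain_match) == (ba is OverlapClass.chain_match)
                assert (ab is OverlapClass.contained) == (ba is OverlapClass.container)
                assert (ab is OverlapClass.antisense_exonic) == (ba is OverlapClass.antisense_exonic)


class TestStreamCompare:
    def test_no_overlap_is_none_and_exact_match_is_chain_match(self):
        ref = AnnotationSet.from_transcripts("r", [make_tx("R1", FOUR_EXON)])
        far = make_tx("q1", [(10_000, 10_100)])
        same = make_tx("q2", FOUR_EXON)
        table = stream_compare([far, same], ref).set_index("query_id")
        assert table.loc["q1", "overlap_class"] == "none"
        assert table.loc["q2", "overlap_class"] == "chain_match"
        assert table.loc["q2", "best_reference_id"] == "R1"

    def test_matches_exhaustive_pairwise_oracle(self, rng):
        queries = random_transcripts(rng, 500, region=40_000, prefix="Q")
        refs = random_transcripts(rng, 200, region=40_000, prefix="T")
        ref_set = AnnotationSet.from_transcripts("r", refs)
        table = stream_compare(queries, ref_set).set_index("query_id")
        for q in queries:
            cls, ref = best_reference(q, refs)  # quadratic: every reference
            assert table.loc[q.transcript_id, "overlap_class"] == cls.value
            assert table.loc[q.transcript_id, "best_reference_id"] == (
                ref.transcript_id if ref else ""
            )

    def test_unsorted_stream_warns(self, caplog):
        ref = AnnotationSet.from_transcripts("r", [])
        qs = [make_tx("b", [(500, 600)]), make_tx("a", [(100, 200)])]
        with caplog.at_level("WARNING"):
            stream_compare(qs, ref)
        assert any("sorting internally" in r.message for r in caplog.records)


class TestAdjustEnds:
    def test_reference_ends_replace_query_ends(self):
        q = make_tx("q", FOUR_EXON)
        r = make_tx("r", [(40, 200)] + FOUR_EXON[1:-1] + [(700, 950)])
        adj = adjust_ends_to_reference(q, r)
        assert (adj.interval.start, adj.interval.end) == (40, 950)
        assert intron_chain_equal(adj, q) and intron_chain_equal(adj, r)

    def test_identical_pair_unchanged(self):
        q = make_tx("q", FOUR_EXON)
        adj = adjust_ends_to_reference(q, make_tx("r", FOUR_EXON))
        assert [(e.start, e.end) for e in adj.exons] == FOUR_EXON

    def test_requires_chain_match(self):
        q = make_tx("q", FOUR_EXON)
        r = make_tx("r", [(100, 201), (300, 400)])
        with pytest.raises(ValueError, match="chain match"):
            adjust_ends_to_reference(q, r)

    def test_chain_preserved_on_random_matched_pairs(self, rng):
        for _ in range(50):
            base = random_transcripts(rng, 1, max_exons=5)[0]
            if not base.is_spliced:
                continue
            d5 = int(rng.integers(0, base.exons[0].length))
            d3 = int(rng.integers(0, 200))
            exons = ((GenomicInterval(base.seqid, base.exons[0].start + d5,
                                      base.exons[0].end, base.strand),)
                     + base.exons[1:-1]
                     + (GenomicInterval(base.seqid, base.exons[-1].start,
                                        base.exons[-1].end + d3, base.strand),))
            other = Transcript("other", "g", exons)
            adj = adjust_ends_to_reference(base, other)
            assert intron_chain_equal(adj, base) and intron_chain_equal(adj, other)


def _sets(named_exon_lists, strand="+"):
    return AnnotationSet.from_transcripts(
        named_exon_lists[0],
        [make_tx(tid, exons, strand=strand) for tid, exons in named_exon_lists[1]],
    )


class TestMerge:
    def test_same_chain_two_samples_collapse_with_union_extent(self):
        s1 = _sets(("s1", [("t", FOUR_EXON)]))
        s2 = _sets(("s2", [("t", [(200, 200)] + FOUR_EXON[1:])]))  # 5' differs by 100
        merged = merge_catalogs({"liver": [s1, s2]})
        assert len(merged) == 1
        m = next(iter(merged))
        assert m.support == 2
        assert (m.interval.start, m.interval.end) == (100, 800)
        assert m.tissue_support == {"liver": 2}

    def test_single_sample_count_unchanged(self, rng):
        ts = random_transcripts(rng, 40, region=500_000)
        # spread transcripts out so none merge by construction
        s = AnnotationSet.from_transcripts("s1", ts)
        pre = len(merge_catalogs({"a": [s]}))
        assert pre <= 40
        again = merge_catalogs({"a": [merge_catalogs({"a": [s]}, name="m1")]})
        assert len(again) == pre

    def test_contained_sub_chain_absorbed(self):
        s1 = _sets(("s1", [("long", FOUR_EXON)]))
        s2 = _sets(("s2", [("frag", [(310, 400), (500, 590)])]))
        merged = merge_catalogs({"a": [s1, s2]})
        assert len(merged) == 1
        m = next(iter(merged))
        assert m.transcript_id == "long" and m.support == 2

    def test_merge_is_idempotent_on_random_catalogs(self, rng):
        samples = {
            f"tis{k}": [
                AnnotationSet.from_transcripts(
                    f"s{k}_{i}", random_transcripts(rng, 30, region=20_000, prefix=f"P{k}{i}")
                )
                for i in range(2)
            ]
            for k in range(2)
        }
        once = merge_catalogs(samples)
        twice = merge_catalogs({"all": [once]})
        key = lambda s: sorted(
            (tuple((e.start, e.end) for e in t.exons), t.strand) for t in s
        )
        assert key(once) == key(twice)

    def test_merge_never_invents_chains(self, rng):
        ts = random_transcripts(rng, 60, region=15_000)
        s = AnnotationSet.from_transcripts("s", ts)
        merged = merge_catalogs({"a": [s]})
        input_chains = {
            (t.seqid, t.strand, tuple((i.start, i.end) for i in introns_of(t)))
            for t in ts if t.is_spliced
        }
        for m in merged:
            if m.is_spliced:
                chain = (m.seqid, m.strand, tuple((i.start, i.end) for i in introns_of(m)))
                assert chain in input_chains

    def test_duplicate_sample_names_rejected(self):
        s = _sets(("dup", [("t", FOUR_EXON)]))
        s2 = _sets(("dup", [("t", FOUR_EXON)]))
        with pytest.raises(ValueError, match="duplicate sample name"):
            merge_catalogs({"a": [s], "b": [s2]})

    def test_fixture_merge_recovers_support_counts(self, bundle):
        merged = merge_catalogs(bundle.samples)
        summaries = bundle.expression_summaries()
        assert len(merged) == len(bundle.candidates)
        for m in merged:
            assert m.support == summaries[m.transcript_id].n_samples
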