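"""Filter cascades, individual gates, and the audit trail."""

import dataclasses

import numpy as np
import pytest

from txcurate.filters import (
    CurationConfig,
    ExpressionSummary,
    RepeatFeature,
    RepeatIndex,
    SimilarityRecord,
    assign_biotype,
    coding_cascade,
    coding_expression_gate,
    containment_gate,
    find_novel,
    lncrna_rescue,
    noncoding_cascade,
    outlier_fence,
    retained_intron,
    support_check,
)
from txcurate.model import AnnotationSet, GenomicInterval, introns_of
from txcurate.simulate import random_transcripts

from conftest import make_tx


def _expr(tid, n=12, mean=2.0, mx=None, tissues=None):
    mx = mx if mx is not None else mean * 2
    return ExpressionSummary(tid, n, mean, mx, tissues or {"liver": mx})


class TestCodingExpressionGate:
    def test_spliced_passes_on_one_tissue_above_one(self, cfg):
        t = make_tx("t", [(100, 200), (300, 400)])
        assert coding_expression_gate(t, _expr("t", tissues={"liver": 1.2}), cfg)

    def test_spliced_fails_when_all_tissues_at_or_below_one(self, cfg):
        t = make_tx("t", [(100, 200), (300, 400)])
        e = _expr("t", tissues={"liver": 1.0, "lung": 0.4})
        assert not coding_expression_gate(t, e, cfg)

    @pytest.mark.parametrize("mx,expected", [(14.0, True), (13.87, False)])
    def test_single_exon_needs_outlier_expression_strictly(self, cfg, mx, expected):
        t = make_tx("t", [(100, 900)])
        e = ExpressionSummary("t", 5, 5.0, mx, {"liver": mx})
        assert coding_expression_gate(t, e, cfg) is expected

    def test_missing_expression_fails(self, cfg):
        assert not coding_expression_gate(make_tx("t", [(1, 50)]), None, cfg)


class TestContainmentGate:
    def _catalog(self):
        big = make_tx("big", [(100, 200), (300, 400), (500, 600)])
        frag = make_tx("frag", [(310, 400), (500, 590)])
        lone = make_tx("lone", [(5000, 5100), (5300, 5400)])
        return AnnotationSet.from_transcripts("c", [big, frag, lone]), big, frag, lone

    def test_no_container_passes(self, cfg):
        cat, big, frag, lone = self._catalog()
        assert containment_gate(lone, cat, {}, cfg)

    def test_more_samples_than_container_passes(self, cfg):
        cat, big, frag, lone = self._catalog()
        support = {"big": _expr("big", n=5), "frag": _expr("frag", n=8)}
        assert containment_gate(frag, cat, support, cfg)

    def test_tie_with_any_container_fails(self, cfg):
        # strictly greater than ALL containers is required
        cat, big, frag, lone = self._catalog()
        support = {"big": _expr("big", n=8), "frag": _expr("frag", n=8)}
        assert not containment_gate(frag, cat, support, cfg)


class TestRetainedIntron:
    REF = [(1000, 1199), (1500, 1699), (2000, 2199)]

    def _ref_introns(self):
        return list(introns_of(make_tx("ref", self.REF)))

    def test_exon_spanning_intron_with_flanks(self):
        t = make_tx("t", [(1180, 1520), (2500, 2600)])
        assert retained_intron(t, self._ref_introns())

    def test_exon_identical_to_reference_exon(self):
        t = make_tx("t", [(1000, 1199), (1500, 1699)])
        assert not retained_intron(t, self._ref_introns())

    def test_exon_ending_at_intron_boundary_not_flagged(self):
        # contains the intron but does not reach into the downstream exon
        t = make_tx("t", [(1150, 1499), (2500, 2600)])
        assert not retained_intron(t, self._ref_introns())

    def test_opposite_strand_not_flagged(self):
        t = make_tx("t", [(1180, 1520), (2500, 2600)], strand="-")
        assert not retained_intron(t, self._ref_introns())


class TestFindNovel:
    def test_reference_overlap_removed_and_free_region_kept(self):
        ref = AnnotationSet.from_transcripts("ref", [make_tx("r", [(100, 200)])])
        hit = make_tx("hit", [(150, 250)], strand="-")  # either strand counts
        free = make_tx("free", [(5000, 5100)])
        novel, report = find_novel(
            AnnotationSet.from_transcripts("a", [hit, free]), [ref])
        assert {t.transcript_id for t in novel} == {"free"}
        assert report.removal_stage() == {"hit": "novelty"}

    def test_matches_quadratic_overlap_oracle(self, rng):
        assembled = random_transcripts(rng, 150, region=30_000, prefix="A")
        refs = random_transcripts(rng, 60, region=30_000, prefix="B")
        ref_set = AnnotationSet.from_transcripts("ref", refs)
        novel, _ = find_novel(AnnotationSet.from_transcripts("a", assembled), [ref_set])
        expected = {
            t.transcript_id for t in assembled
            if not any(t.exonic_overlap(r, stranded=False) for r in refs)
        }
        assert {t.transcript_id for t in novel} == expected


class TestSupportCheck:
    def test_exon_overlap_supports_gene(self):
        refs = AnnotationSet.from_transcripts("r", [make_tx("r1", [(100, 200)], gene="G1")])
        asm = AnnotationSet.from_transcripts("a", [make_tx("a1", [(150, 300)])])
        assert support_check(refs, asm) == []

    def test_assembly_free_gene_unsupported(self):
        refs = AnnotationSet.from_transcripts("r", [make_tx("r1", [(100, 200)], gene="G1")])
        asm = AnnotationSet.from_transcripts("a", [make_tx("a1", [(5000, 5100)])])
        assert support_check(refs, asm) == ["G1"]

    def test_matches_exhaustive_exon_overlap_oracle(self, rng):
        refs = random_transcripts(rng, 80, region=25_000, prefix="R")
        asm = random_transcripts(rng, 80, region=25_000, prefix="A")
        ref_set = AnnotationSet.from_transcripts("r", refs)
        asm_set = AnnotationSet.from_transcripts("a", asm)
        expected = sorted(
            t.gene_id for t in refs
            if not any(t.exonic_overlap(a, stranded=True) for a in asm)
        )
        assert support_check(ref_set, asm_set) == expected


class TestAssignBiotype:
    def test_refseq_type_wins(self):
        t = make_tx("t", [(1, 100)])
        assert assign_biotype(t, "lncRNA", "protein_coding") == "lncRNA"

    def test_gencode_fallback(self):
        assert assign_biotype(make_tx("t", [(1, 100)]), None, "protein_coding") == "protein_coding"

    def test_cascade_call_fallback(self):
        t = make_tx("t", [(1, 100)])
        assert assign_biotype(t, coding_accepted=True) == "protein_coding"
        assert assign_biotype(t) == "lncRNA"
        anti_ref = AnnotationSet.from_transcripts(
            "r", [make_tx("r", [(50, 150)], strand="-")])
        assert assign_biotype(t, references=[anti_ref]) == "antisense"


class TestCascades:
    def test_noncoding_cascade_keeps_exactly_genuine(self, bundle, cfg):
        """Every planted artifact is removed at its designated stage; every
        genuine transcript survives (ground-truth recovery)."""
        summaries = bundle.expression_summaries(cfg)
        kept, report = noncoding_cascade(
            bundle.noncoding_candidates, summaries, [bundle.reference],
            bundle.similarities, bundle.repeats, cfg)
        labels = bundle.truth[bundle.truth.cascade == "noncoding"]
        genuine = set(labels[labels.expected_stage == "kept"].transcript_id)
        assert {t.transcript_id for t in kept} == genuine
        stage_of = report.removal_stage()
        for row in labels.itertuples():
            if row.expected_stage != "kept":
                assert stage_of[row.transcript_id] == row.expected_stage

    def test_coding_cascade_accepts_exactly_planted_candidates(self, bundle, cfg):
        summaries = bundle.expression_summaries(cfg)
        kept, report = coding_cascade(
            bundle.candidates, summaries, bundle.sequences, bundle.homology,
            bundle.domains, bundle.repeats, cfg)
        expected = set(
            bundle.truth[(bundle.truth.cascade == "coding")
                         & (bundle.truth.expected_stage == "kept")].transcript_id)
        assert {t.transcript_id for t in kept} == expected
        assert all(t.biotype == "protein_coding" for t in kept)
        repeat_plants = bundle.truth[bundle.truth.category == "repeat_embedded_orf"]
        for tid in repeat_plants.transcript_id:
            assert report.removal_stage()[tid] == "alu_sva_screen"

    def test_short_orf_removed_at_orf_stage(self, bundle, cfg):
        tid = next(iter(bundle.coding_candidates)).transcript_id
        seqs = dict(bundle.sequences)
        seqs[tid] = "ATG" + "GCA" * 58 + "TAA"  # 59 aa, below the 60 aa floor
        _, report = coding_cascade(
            bundle.coding_candidates, bundle.expression_summaries(cfg), seqs,
            bundle.homology, bundle.domains, bundle.repeats, cfg)
        assert report.removal_stage()[tid] == "orf_length"

    def test_conflicting_loci_keep_only_named_function(self, cfg):
        plus = make_tx("plus", [(1000, 1200), (2000, 2200)], strand="+")
        minus = make_tx("minus", [(1100, 1300), (2100, 2300)], strand="-")
        catalog = AnnotationSet.from_transcripts("c", [plus, minus])
        seqs = {t.transcript_id: "CGC" * 20 + "ATG" + "GCA" * 70 + "TAA" + "CGC" * 20
                for t in catalog}
        from txcurate.orf import HomologyHit

        hits = [
            HomologyHit("plus", "a1", "cytochrome oxidase subunit", 1e-20, 90, 80, 71),
            HomologyHit("minus", "a2", "uncharacterized protein", 1e-20, 90, 80, 71),
        ]
        expr = {t.transcript_id: _expr(t.transcript_id) for t in catalog}
        kept, report = coding_cascade(catalog, expr, seqs, hits, [], RepeatIndex([]), cfg)
        assert {t.transcript_id for t in kept} == {"plus"}
        assert report.removal_stage()["minus"] == "conflict_named_function"

    def test_locus_abundance_cap_keeps_ten_most_abundant(self, cfg):
        txs, expr = [], {}
        for j in range(12):
            mid = 2000 + 50 * j
            t = make_tx(f"iso{j:02d}", [(1000, 1199), (mid, mid + 120), (4000, 4200)])
            txs.append(t)
            expr[t.transcript_id] = _expr(t.transcript_id, n=15, mean=10.0 - 0.5 * j)
        kept, report = noncoding_cascade(
            AnnotationSet.from_transcripts("c", txs), expr, [], [], RepeatIndex([]), cfg)
        assert {t.transcript_id for t in kept} == {f"iso{j:02d}" for j in range(10)}
        assert report.removed_at("locus_abundance") == {"iso10", "iso11"}

    def test_lncrna_rescue_requires_named_function_and_orf(self, bundle, cfg):
        rescued, _ = lncrna_rescue(
            bundle.lncrnas, bundle.sequences, bundle.homology, cfg, [bundle.reference])
        assert {t.transcript_id for t in rescued} == set(
            bundle.truth[bundle.truth.cascade == "rescue"].transcript_id)
        assert all(t.biotype == "protein_coding" for t in rescued)
        # flip the best hit to a placeholder name: nothing is rescued
        from txcurate.orf import HomologyHit

        anon = [
            HomologyHit(h.query_id, h.subject_accession, "uncharacterized protein",
                        h.e_value, h.percent_identity, h.subject_length_aa,
                        h.query_orf_length_aa)
            for h in bundle.homology
        ]
        none, report = lncrna_rescue(bundle.lncrnas, bundle.sequences, anon, cfg)
        assert len(none) == 0
        assert all(s == "homology_named_function" for s in report.removal_stage().values())

    def test_cascades_are_idempotent(self, bundle, cfg):
        summaries = bundle.expression_summaries(cfg)
        kept1, _ = noncoding_cascade(
            bundle.noncoding_candidates, summaries, [bundle.reference],
            bundle.similarities, bundle.repeats, cfg)
        kept2, _ = noncoding_cascade(
            kept1, summaries, [bundle.reference], bundle.similarities, bundle.repeats, cfg)
        assert {t.transcript_id for t in kept1} == {t.transcript_id for t in kept2}
        c1, _ = coding_cascade(bundle.candidates, summaries, bundle.sequences,
                               bundle.homology, bundle.domains, bundle.repeats, cfg)
        c2, _ = coding_cascade(c1, summaries, bundle.sequences,
                               bundle.homology, bundle.domains, bundle.repeats, cfg)
        assert {t.transcript_id for t in c1} == {t.transcript_id for t in c2}

    def test_tightening_thresholds_never_grows_kept_set(self, bundle, cfg):
        """Tightening any threshold never grows the kept set. Note the
        rank-based per-locus cap means this holds for the kept *count*, not
        pointwise: removing a top-10 isoform upstream can promote the 11th."""
        summaries = bundle.expression_summaries(cfg)
        base, _ = noncoding_cascade(
            bundle.noncoding_candidates, summaries, [bundle.reference],
            bundle.similarities, bundle.repeats, cfg)
        for stricter in (
            dataclasses.replace(cfg, min_samples=15),
            dataclasses.replace(cfg, min_avg_tpm=2.5),
            dataclasses.replace(cfg, top_n_per_locus=5),
            dataclasses.replace(cfg, min_samples=20, min_avg_tpm=4.0),
        ):
            kept, _ = noncoding_cascade(
                bundle.noncoding_candidates,
                bundle.expression_summaries(stricter),
                [bundle.reference], bundle.similarities, bundle.repeats, stricter)
            assert len(kept) <= len(base)
            # pointwise monotonicity does hold away from the rank stage
            crowd = {t.transcript_id for t in bundle.noncoding_candidates
                     if t.gene_id == "CRWLOC"}
            assert ({t.transcript_id for t in kept} - crowd
                    <= {t.transcript_id for t in base} - crowd)

    def test_report_is_exhaustive_and_exclusive(self, bundle, cfg):
        summaries = bundle.expression_summaries(cfg)
        _, report = noncoding_cascade(
            bundle.noncoding_candidates, summaries, [bundle.reference],
            bundle.similarities, bundle.repeats, cfg)
        frame = report.to_frame()
        all_ids = {t.transcript_id for t in bundle.noncoding_candidates}
        assert set(frame.transcript_id) == all_ids
        survivors = set(all_ids)
        for stage in report.stages:
            sub = frame[frame.stage == stage]
            # every current survivor gets exactly one record per stage
            assert set(sub.transcript_id) == survivors
            assert len(sub) == len(survivors)
            survivors -= set(sub[sub.decision == "removed"].transcript_id)
        removed = report.removal_stage()
        for tid, stage in removed.items():
            later = frame[(frame.transcript_id == tid)
                          & (frame.stage.map(report.stages.index) > report.stages.index(stage))]
            assert later.empty


class TestConfig:
    def test_defaults_match_published_thresholds(self, cfg):
        assert (cfg.min_samples, cfg.min_avg_tpm, cfg.outlier_tpm) == (10, 1.0, 13.87)
        assert (cfg.min_orf_aa, cfg.max_evalue, cfg.min_orf_fraction) == (60, 1e-15, 0.75)
        assert (cfg.pseudo_identity, cfg.pseudo_coverage, cfg.top_n_per_locus) == (98.0, 0.90, 10)

    def test_yaml_round_trip(self, tmp_path, cfg):
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert CurationConfig.from_yaml(path) == cfg

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            CurationConfig(min_samples=0)
        with pytest.raises(ValueError):
            CurationConfig(pseudo_coverage=1.5)

    def test_outlier_fence_is_q3_plus_iqr(self):
        vals = [1, 2, 3, 4, 5, 6, 7, 8]
        q1, q3 = np.percentile(vals, [25, 75])
        assert outlier_fence(vals) == pytest.approx(q3 + 1.5 * (q3 - q1))
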