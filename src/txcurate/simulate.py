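"""Deterministic synthetic fixture generator with planted ground truth.

Real multi-sample transcript catalogs cannot ship with the package (the
underlying RNA-seq collections are access-controlled), so every cascade and
comparison operation is exercised on generated catalogs instead: a small
reference annotation, per-sample assembled catalogs with jittered transcript
ends, an expression matrix, homology/domain/similarity evidence tables and a
repeat mask. Each planted artifact violates exactly one cascade filter and
carries a truth label naming the stage that must remove it; each genuine
transcript satisfies every gate. Identical specs (including the seed) yield
byte-identical output files.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .filters import (
    CurationConfig,
    RepeatFeature,
    RepeatIndex,
    SimilarityRecord,
    coding_expression_gate,
    retained_intron,
    summarize_expression,
)
from .model import (
    AnnotationSet,
    GenomicInterval,
    Transcript,
    introns_of,
    write_fasta,
    write_gtf,
)
from .orf import DomainHit, HomologyHit, longest_orf
from .filters import FilterReport

CHROM = "chrS1"
_SLOT = 20_000
_NON_STOP_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
)

#: truth-label categories and the cascade stage expected to act on them
CATEGORY_STAGE = {
    "genuine": ("noncoding", "kept"),
    "low_support": ("noncoding", "expression_support"),
    "single_exon_noise": ("noncoding", "single_exon"),
    "rrna_overlap": ("noncoding", "rrna_overlap"),
    "retained_intron": ("noncoding", "retained_intron"),
    "pseudogene_copy": ("noncoding", "known_similarity"),
    "antisense_artifact": ("noncoding", "antisense_multi_gene"),
    "multi_gene_spanning": ("noncoding", "antisense_multi_gene"),
    "excess_isoform": ("noncoding", "locus_abundance"),
    "igtr_overlap": ("noncoding", "pseudogene_igtr_loci"),
    "coding_candidate": ("coding", "kept"),
    "repeat_embedded_orf": ("coding", "alu_sva_screen"),
    "rescueable_lncRNA": ("rescue", "rescued"),
}


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions of one synthetic catalog.

    Counts are planted transcripts per category; expression parameters are
    ln-space location/scale of per-sample TPM draws.
    """

    seed: int = 1
    n_genuine: int = 10
    n_single_exon_noise: int = 1
    n_low_support: int = 1
    n_rrna_overlap: int = 1
    n_retained_intron: int = 1
    n_pseudogene_copy: int = 1
    n_antisense_artifact: int = 1
    n_multi_gene_spanning: int = 1
    n_excess_isoform: int = 1
    n_igtr_overlap: int = 1
    n_coding_candidate: int = 5
    n_repeat_embedded_orf: int = 1
    n_rescueable_lncrna: int = 2
    n_samples: int = 30
    n_tissues: int = 3
    genuine_tpm_mu: float = 1.2
    genuine_tpm_sigma: float = 0.5
    noise_tpm_mu: float = -1.0
    noise_tpm_sigma: float = 0.6
    chrom_length: int = 3_000_000

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name.startswith("n_") and getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")
        if self.n_samples < 12:
            raise ValueError("need at least 12 samples so genuine support can exceed the gate")
        if self.n_tissues < 1 or self.n_tissues > self.n_samples:
            raise ValueError("n_tissues must be in [1, n_samples]")

    @classmethod
    def from_yaml(cls, source) -> "FixtureSpec":
        fh = open(source) if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__") else source
        return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class FixtureBundle:
    """All generated inputs plus the planted truth labels."""

    spec: FixtureSpec
    reference: AnnotationSet
    candidates: AnnotationSet            # everything the cascades judge
    noncoding_candidates: AnnotationSet  # genuine + noncoding plants
    coding_candidates: AnnotationSet     # coding plants only
    lncrnas: AnnotationSet               # rescue candidates
    samples: dict                        # tissue -> [per-sample AnnotationSet]
    expression: pd.DataFrame             # transcript x sample TPM
    tissue_map: dict
    sequences: dict
    homology: list
    domains: list
    similarities: list
    repeats: RepeatIndex
    truth: pd.DataFrame                  # transcript_id, category, cascade, expected_stage

    def expression_summaries(self, cfg: CurationConfig | None = None):
        cfg = cfg or CurationConfig()
        return summarize_expression(self.expression, self.tissue_map, mean_over=cfg.mean_over)

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_gtf(self.reference, out / "reference.gtf")
        write_gtf(self.candidates, out / "candidates.gtf")
        write_gtf(self.lncrnas, out / "lncrna.gtf")
        sample_dir = out / "samples"
        sample_dir.mkdir(exist_ok=True)
        for tissue in sorted(self.samples):
            for aset in self.samples[tissue]:
                write_gtf(aset, sample_dir / f"{aset.name}.gtf")
        self.expression.to_csv(out / "expression.tsv", sep="\t")
        with open(out / "tissue_map.tsv", "w") as fh:
            for s in sorted(self.tissue_map):
                fh.write(f"{s}\t{self.tissue_map[s]}\n")
        with open(out / "homology.tsv", "w") as fh:
            for h in self.homology:
                fh.write("\t".join(map(str, [
                    h.query_id, h.subject_accession, h.percent_identity, h.query_orf_length_aa,
                    0, 0, 1, h.query_orf_length_aa, 1, h.subject_length_aa,
                    h.e_value, 200.0, h.subject_length_aa, h.query_orf_length_aa,
                    h.subject_description,
                ])) + "\n")
        with open(out / "domains.tsv", "w") as fh:
            for d in self.domains:
                fh.write(f"{d.query_id}\t{d.database}\t{d.accession}\t{d.e_value}\n")
        with open(out / "similarity.tsv", "w") as fh:
            for s in self.similarities:
                fh.write(f"{s.novel_id}\t{s.known_id}\t{s.percent_identity}\t{s.coverage_fraction}\n")
        with open(out / "repeats.bed", "w") as fh:
            for f in self.repeats.features:
                iv = f.interval
                fh.write(f"{iv.seqid}\t{iv.start - 1}\t{iv.end}\t{f.repeat_class}\t0\t{iv.strand}\n")
        write_fasta(self.sequences, out / "transcripts.fa")
        self.truth.to_csv(out / "truth_labels.tsv", sep="\t", index=False)
        with open(out / "spec.yaml", "w") as fh:
            yaml.safe_dump(asdict(self.spec), fh)


class _Layout:
    """Sequential slot allocator on the synthetic chromosome."""

    def __init__(self, chrom_length: int) -> None:
        self.next = 1
        self.limit = chrom_length

    def slot(self) -> int:
        base = self.next
        self.next += _SLOT
        if self.next > self.limit:
            raise ValueError(
                f"genome too small: need > {self.next} bp, chrom_length is {self.limit}"
            )
        return base


def _spliced(tid, gid, start, exon_lens, intron_lens, strand="+", biotype="other"):
    exons, pos = [], start
    for i, L in enumerate(exon_lens):
        exons.append(GenomicInterval(CHROM, pos, pos + L - 1, strand))
        pos += L + (intron_lens[i] if i < len(intron_lens) else 0)
    return Transcript(tid, gid, tuple(exons), biotype=biotype)


def _random_seq(rng, n, alphabet="ACGT"):
    return "".join(np.asarray(list(alphabet))[rng.integers(0, len(alphabet), n)])


def _coding_seq(rng, total_len: int, orf_aa: int) -> str:
    """Sequence whose unique ORF is the planted one (flanks lack A, hence
    hold neither ATG nor stop codons)."""
    orf_bp = 3 * orf_aa + 6  # ATG + orf_aa codons + stop
    if orf_bp > total_len:
        raise ValueError("transcript too short for the requested ORF")
    lead = (total_len - orf_bp) // 2
    codons = [_NON_STOP_CODONS[i] for i in rng.integers(0, len(_NON_STOP_CODONS), orf_aa)]
    orf = "ATG" + "".join(codons) + "TAA"
    return _random_seq(rng, lead, "CGT") + orf + _random_seq(rng, total_len - lead - orf_bp, "CGT")


def nucleotide_similarity(novel_seq: str, known_seq: str) -> tuple[float, float]:
    """(percent identity, coverage fraction) of a global novel-vs-known
    alignment; used only to derive fixture similarity evidence."""
    import edlib

    res = edlib.align(novel_seq, known_seq, mode="NW", task="distance")
    span = max(len(novel_seq), len(known_seq))
    identity = 100.0 * (1 - res["editDistance"] / span)
    return identity, 1.0


def generate(spec: FixtureSpec) -> FixtureBundle:
    """Build the full fixture bundle for a spec (pure function of the spec)."""
    rng = np.random.default_rng(spec.seed)
    layout = _Layout(spec.chrom_length)
    cfg = CurationConfig()

    reference: list[Transcript] = []
    noncoding: list[Transcript] = []
    coding: list[Transcript] = []
    lncrnas: list[Transcript] = []
    repeats: list[RepeatFeature] = []
    similarities: list[SimilarityRecord] = []
    homology: list[HomologyHit] = []
    domains: list[DomainHit] = []
    sequences: dict[str, str] = {}
    truth_rows: list[tuple[str, str, str, str]] = []
    # expression plan: tid -> (kind, params) consumed after placement
    expr_plan: dict[str, dict] = {}

    def label(tid: str, category: str) -> None:
        cascade, stage = CATEGORY_STAGE[category]
        truth_rows.append((tid, category, cascade, stage))

    def plan(tid: str, kind: str, **kw) -> None:
        expr_plan[tid] = {"kind": kind, **kw}

    # --- genuine multi-exon noncoding transcripts in reference-free slots
    for i in range(spec.n_genuine):
        b = layout.slot()
        lens = [int(rng.integers(150, 320)) for _ in range(3)]
        gaps = [int(rng.integers(300, 1200)) for _ in range(2)]
        t = _spliced(f"GEN{i:03d}.1", f"GEN{i:03d}", b + 1000, lens, gaps)
        noncoding.append(t)
        label(t.transcript_id, "genuine")
        plan(t.transcript_id, "genuine")

    # --- noncoding noise plants, one filter each
    for i in range(spec.n_low_support):
        b = layout.slot()
        t = _spliced(f"LOW{i:03d}.1", f"LOW{i:03d}", b + 1000, [200, 250], [600])
        noncoding.append(t)
        label(t.transcript_id, "low_support")
        plan(t.transcript_id, "low_support")

    for i in range(spec.n_single_exon_noise):
        b = layout.slot()
        t = Transcript(f"SE{i:03d}.1", f"SE{i:03d}",
                       (GenomicInterval(CHROM, b + 1000, b + 1900, "+"),))
        noncoding.append(t)
        label(t.transcript_id, "single_exon_noise")
        plan(t.transcript_id, "mid_band")

    for i in range(spec.n_rrna_overlap):
        b = layout.slot()
        t = _spliced(f"RRN{i:03d}.1", f"RRN{i:03d}", b + 1000, [250, 250], [700])
        noncoding.append(t)
        repeats.append(RepeatFeature(GenomicInterval(CHROM, b + 1100, b + 1600, "."), "rRNA"))
        label(t.transcript_id, "rrna_overlap")
        plan(t.transcript_id, "genuine")

    for i in range(spec.n_retained_intron):
        b = layout.slot()
        ref = _spliced(f"REFRI{i:03d}.1", f"REFRI{i:03d}", b + 1000,
                       [200, 200, 200], [300, 300], biotype="protein_coding")
        reference.append(ref)
        # exon spans the first reference intron plus flanks on both sides
        t = Transcript(f"RI{i:03d}.1", f"RI{i:03d}", (
            GenomicInterval(CHROM, b + 1100, b + 1750, "+"),
            GenomicInterval(CHROM, b + 2500, b + 2700, "+"),
        ))
        noncoding.append(t)
        label(t.transcript_id, "retained_intron")
        plan(t.transcript_id, "genuine")

    for i in range(spec.n_pseudogene_copy):
        b = layout.slot()
        known = _spliced(f"REFPS{i:03d}.1", f"REFPS{i:03d}", b + 1000,
                         [200, 200], [400], biotype="protein_coding")
        reference.append(known)
        b2 = layout.slot()
        t = _spliced(f"PS{i:03d}.1", f"PS{i:03d}", b2 + 1000, [200, 200], [400])
        noncoding.append(t)
        known_seq = _random_seq(rng, known.exonic_length)
        copy = list(known_seq)
        for pos in rng.choice(len(copy), size=max(1, len(copy) // 100), replace=False):
            copy[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[copy[pos]]
        ident, cov = nucleotide_similarity("".join(copy), known_seq)
        similarities.append(SimilarityRecord(t.transcript_id, known.transcript_id, ident, cov))
        sequences[known.transcript_id] = known_seq
        sequences[t.transcript_id] = "".join(copy)
        label(t.transcript_id, "pseudogene_copy")
        plan(t.transcript_id, "genuine")

    for i in range(spec.n_antisense_artifact):
        b = layout.slot()
        ref = _spliced(f"REFAS{i:03d}.1", f"REFAS{i:03d}", b + 1000,
                       [400, 400], [400], biotype="protein_coding")
        reference.append(ref)
        t = Transcript(f"AS{i:03d}.1", f"AS{i:03d}", (
            GenomicInterval(CHROM, b + 1100, b + 1300, "-"),
            GenomicInterval(CHROM, b + 1900, b + 2100, "-"),
        ))
        noncoding.append(t)
        label(t.transcript_id, "antisense_artifact")
        plan(t.transcript_id, "genuine")

    for i in range(spec.n_multi_gene_spanning):
        b = layout.slot()
        ga = _spliced(f"REFMGA{i:03d}.1", f"REFMGA{i:03d}", b + 1000,
                      [300, 300], [400], biotype="protein_coding")
        gb = _spliced(f"REFMGB{i:03d}.1", f"REFMGB{i:03d}", b + 4000,
                      [300, 300], [400], biotype="protein_coding")
        reference.extend([ga, gb])
        t = Transcript(f"MG{i:03d}.1", f"MG{i:03d}", (
            GenomicInterval(CHROM, b + 1900, b + 2100, "+"),
            GenomicInterval(CHROM, b + 4100, b + 4250, "+"),
        ))
        noncoding.append(t)
        label(t.transcript_id, "multi_gene_spanning")
        plan(t.transcript_id, "genuine")

    # --- crowded locus: top_n keepers + excess low-abundance isoforms
    if spec.n_excess_isoform:
        b = layout.slot()
        n_keep = cfg.top_n_per_locus
        for j in range(n_keep + spec.n_excess_isoform):
            mid = b + 1600 + 40 * j
            t = Transcript(f"CRW{j:03d}.1", "CRWLOC", (
                GenomicInterval(CHROM, b + 1000, b + 1199, "+"),
                GenomicInterval(CHROM, mid, mid + 150, "+"),
                GenomicInterval(CHROM, b + 4000, b + 4299, "+"),
            ))
            noncoding.append(t)
            if j < n_keep:
                label(t.transcript_id, "genuine")
                plan(t.transcript_id, "constant", value=4.0 + 0.5 * (n_keep - j))
            else:
                label(t.transcript_id, "excess_isoform")
                plan(t.transcript_id, "constant", value=1.05 + 0.01 * j)

    for i in range(spec.n_igtr_overlap):
        b = layout.slot()
        t = _spliced(f"IGT{i:03d}.1", f"IGT{i:03d}", b + 1000, [250, 250], [600])
        noncoding.append(t)
        repeats.append(RepeatFeature(GenomicInterval(CHROM, b + 1050, b + 1500, "."), "IG_TR"))
        label(t.transcript_id, "igtr_overlap")
        plan(t.transcript_id, "genuine")

    # --- coding cascade plants
    named_descriptions = (
        "ATP-dependent RNA helicase",
        "serine/threonine kinase receptor",
        "zinc finger transcription factor",
        "solute carrier family member",
        "E3 ubiquitin ligase",
    )
    for i in range(spec.n_coding_candidate):
        b = layout.slot()
        t = _spliced(f"COD{i:03d}.1", f"COD{i:03d}", b + 1000, [180, 180], [800])
        coding.append(t)
        seq = _coding_seq(rng, t.exonic_length, 80)
        sequences[t.transcript_id] = seq
        orf = longest_orf(seq, t.transcript_id)
        homology.append(HomologyHit(
            t.transcript_id, f"XP_{900000 + i}", named_descriptions[i % len(named_descriptions)],
            1e-30, 92.0, int(orf.length_aa / 0.8), orf.length_aa,
        ))
        if i == 0:
            domains.append(DomainHit(t.transcript_id, "Pfam", "PF00270", 1e-8))
        label(t.transcript_id, "coding_candidate")
        plan(t.transcript_id, "genuine")

    for i in range(spec.n_repeat_embedded_orf):
        b = layout.slot()
        t = _spliced(f"REP{i:03d}.1", f"REP{i:03d}", b + 1000, [180, 180], [800])
        coding.append(t)
        seq = _coding_seq(rng, t.exonic_length, 80)
        sequences[t.transcript_id] = seq
        orf = longest_orf(seq, t.transcript_id)
        homology.append(HomologyHit(
            t.transcript_id, f"XP_{950000 + i}", "DNA repair protein homolog",
            1e-25, 88.0, int(orf.length_aa / 0.8), orf.length_aa,
        ))
        # Alu under the first exon; no domain support, so the screen removes it
        repeats.append(RepeatFeature(GenomicInterval(CHROM, b + 1020, b + 1120, "."), "Alu"))
        label(t.transcript_id, "repeat_embedded_orf")
        plan(t.transcript_id, "genuine")

    # --- rescueable lncRNAs (separate catalog, free regions)
    for i in range(spec.n_rescueable_lncrna):
        b = layout.slot()
        t = _spliced(f"LNC{i:03d}.1", f"LNC{i:03d}", b + 1000, [200, 200], [700],
                     biotype="lncRNA")
        lncrnas.append(t)
        seq = _coding_seq(rng, t.exonic_length, 75)
        sequences[t.transcript_id] = seq
        orf = longest_orf(seq, t.transcript_id)
        homology.append(HomologyHit(
            t.transcript_id, f"NP_{800000 + i}", "homeobox domain transcription factor",
            1e-22, 85.0, int(orf.length_aa / 0.8), orf.length_aa,
        ))
        label(t.transcript_id, "rescueable_lncRNA")

    # a reference pseudogene record, so novelty screens see one
    b = layout.slot()
    reference.append(_spliced("REFPG000.1", "REFPG000", b + 1000, [300, 300], [500],
                              biotype="pseudogene"))

    candidates = noncoding + coding
    for t in candidates:
        sequences.setdefault(t.transcript_id, _random_seq(rng, t.exonic_length))

    # --- expression matrix and per-sample catalogs
    sample_names = [f"S{i:02d}" for i in range(spec.n_samples)]
    tissue_map = {s: f"tissue{i % spec.n_tissues}" for i, s in enumerate(sample_names)}
    expr = pd.DataFrame(
        0.0, index=[t.transcript_id for t in candidates], columns=sample_names
    )
    membership: dict[str, list[str]] = {s: [] for s in sample_names}

    for t in candidates:
        p = expr_plan[t.transcript_id]
        kind = p["kind"]
        if kind == "low_support":
            k = 3
            vals = np.minimum(rng.lognormal(spec.noise_tpm_mu, spec.noise_tpm_sigma, k), 13.0)
        elif kind == "mid_band":
            k = int(rng.integers(cfg.min_samples + 2, spec.n_samples + 1))
            vals = rng.uniform(1.5, 5.0, k)
        elif kind == "constant":
            k = int(rng.integers(cfg.min_samples + 2, spec.n_samples + 1))
            vals = np.full(k, p["value"])
        else:  # genuine-quality expression
            k = int(rng.integers(cfg.min_samples + 2, spec.n_samples + 1))
            vals = rng.lognormal(spec.genuine_tpm_mu, spec.genuine_tpm_sigma, k)
            if vals.mean() < cfg.min_avg_tpm:
                vals *= 1.05 * cfg.min_avg_tpm / vals.mean()
            if vals.max() <= cfg.min_avg_tpm:
                vals[0] = cfg.min_avg_tpm * 1.5
        chosen = sorted(rng.choice(spec.n_samples, size=k, replace=False).tolist())
        for idx, v in zip(chosen, vals):
            expr.loc[t.transcript_id, sample_names[idx]] = round(float(v), 4)
            membership[sample_names[idx]].append(t.transcript_id)

    by_id = {t.transcript_id: t for t in candidates}
    samples: dict[str, list[AnnotationSet]] = {}
    for s in sample_names:
        txs = []
        first_seen = {tid: min(
            (i for i, sn in enumerate(sample_names) if expr.loc[tid, sn] > 0), default=0
        ) for tid in membership[s]}
        for tid in membership[s]:
            t = by_id[tid]
            # 5'-truncate assembled fragments in all but the first supporting
            # sample, so merging must restore the union extent
            if t.is_spliced and sample_names.index(s) != first_seen[tid]:
                jit = int(rng.integers(0, min(30, t.exons[0].length - 1) + 1))
            else:
                jit = 0
            exons = (GenomicInterval(t.seqid, t.exons[0].start + jit, t.exons[0].end, t.strand),) + t.exons[1:]
            txs.append(Transcript(tid, t.gene_id, exons, biotype=t.biotype))
        samples.setdefault(tissue_map[s], []).append(
            AnnotationSet.from_transcripts(s, txs)
        )

    repeat_index = RepeatIndex(repeats)
    bundle = FixtureBundle(
        spec=spec,
        reference=AnnotationSet.from_transcripts("reference", reference),
        candidates=AnnotationSet.from_transcripts("candidates", candidates),
        noncoding_candidates=AnnotationSet.from_transcripts("noncoding_candidates", noncoding),
        coding_candidates=AnnotationSet.from_transcripts("coding_candidates", coding),
        lncrnas=AnnotationSet.from_transcripts("lncrnas", lncrnas),
        samples=samples,
        expression=expr,
        tissue_map=tissue_map,
        sequences=sequences,
        homology=homology,
        domains=domains,
        similarities=similarities,
        repeats=repeat_index,
        truth=pd.DataFrame(truth_rows, columns=["transcript_id", "category", "cascade", "expected_stage"]),
    )
    _verify_separability(bundle, cfg)
    return bundle


def _verify_separability(bundle: FixtureBundle, cfg: CurationConfig) -> None:
    """Construction-time check: every plant violates (exactly) its filter,
    every genuine transcript passes the gates it will face."""
    summaries = bundle.expression_summaries(cfg)
    ref_introns = [i for t in bundle.reference if t.is_spliced for i in introns_of(t)]
    for row in bundle.truth.itertuples():
        t = (bundle.candidates[row.transcript_id]
             if row.transcript_id in bundle.candidates else bundle.lncrnas[row.transcript_id])
        e = summaries.get(row.transcript_id)
        if row.category == "genuine":
            ok = (e.n_samples >= cfg.min_samples and e.mean_tpm >= cfg.min_avg_tpm
                  and t.is_spliced and not retained_intron(t, ref_introns))
            if not ok:
                raise RuntimeError(f"genuine plant {row.transcript_id} violates a gate")
        elif row.category == "low_support":
            if e.n_samples >= cfg.min_samples or e.max_tpm > cfg.outlier_tpm:
                raise RuntimeError(f"{row.transcript_id}: low-support plant is too well supported")
        elif row.category == "single_exon_noise":
            if t.is_spliced or e.n_samples < cfg.min_samples or e.max_tpm > cfg.outlier_tpm:
                raise RuntimeError(f"{row.transcript_id}: single-exon plant malformed")
        elif row.category == "retained_intron":
            if not retained_intron(t, ref_introns):
                raise RuntimeError(f"{row.transcript_id}: retained-intron plant does not retain")
        elif row.category in ("coding_candidate", "repeat_embedded_orf", "rescueable_lncRNA"):
            orf = longest_orf(bundle.sequences[row.transcript_id], row.transcript_id)
            if orf is None or orf.length_aa < cfg.min_orf_aa:
                raise RuntimeError(f"{row.transcript_id}: planted ORF below threshold")
            if row.category != "rescueable_lncRNA" and not coding_expression_gate(t, e, cfg):
                raise RuntimeError(f"{row.transcript_id}: coding plant fails expression gate")


def random_transcripts(
    rng: np.random.Generator,
    n: int,
    *,
    seqid: str = "chrR",
    region: int = 60_000,
    max_exons: int = 6,
    prefix: str = "R",
) -> list[Transcript]:
    """Small random transcripts for property tests and oracle comparisons.

    Structures are unconstrained (any strand, 1..max_exons exons, arbitrary
    overlaps between transcripts), which is exactly what the brute-force
    oracles need to explore.
    """
    out = []
    for i in range(n):
        n_exons = int(rng.integers(1, max_exons + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        pos = int(rng.integers(1, region))
        exons = []
        for _ in range(n_exons):
            length = int(rng.integers(30, 400))
            exons.append(GenomicInterval(seqid, pos, pos + length - 1, strand))
            pos += length + int(rng.integers(2, 800))
        out.append(Transcript(f"{prefix}{i:04d}", f"{prefix}G{i:04d}", tuple(exons)))
    return out


def truth_eval(report: FilterReport, labels: pd.DataFrame) -> pd.DataFrame:
    """Per-stage precision/recall of a cascade's removals against truth.

    Only transcripts present in ``labels`` are scored, so a report from a
    cascade run on a wider input can be evaluated against the subset of
    transcripts whose truth labels concern that cascade.
    """
    labeled = set(labels["transcript_id"])
    expected = {
        r.transcript_id: r.expected_stage
        for r in labels.itertuples()
        if r.expected_stage not in ("kept", "rescued")
    }
    stages = list(dict.fromkeys(
        report.stages + [s for s in expected.values() if s not in report.stages]
    ))
    rows = []
    for stage in stages:
        removed = report.removed_at(stage) & labeled
        truth = {tid for tid, s in expected.items() if s == stage}
        tp = len(removed & truth)
        rows.append({
            "stage": stage,
            "n_removed": len(removed),
            "n_truth": len(truth),
            "tp": tp,
            "precision": tp / len(removed) if removed else float("nan"),
            "recall": tp / len(truth) if truth else float("nan"),
        })
    return pd.DataFrame(rows)
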