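"""ORF discovery and conservation-evidence gating.

Coding potential of a novel transcript rests on three kinds of evidence:
the longest sense-strand open reading frame, protein homology (BLAST-style
tabular hits against a mammalian protein set), and protein-domain support
(Pfam/CDD tabular hits). A name-based classifier separates proteins with
known functions from computational placeholders ("hypothetical protein",
LOC/ORF identifiers, hCG predictions).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from Bio.Seq import Seq

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class OrfRecord:
    """An ATG-initiated, stop-terminated reading frame in transcript coordinates.

    ``start``/``end`` are 1-based and include the stop codon; ``length_aa``
    excludes the stop.
    """

    transcript_id: str
    start: int
    end: int
    length_aa: int
    protein: str

    def __post_init__(self) -> None:
        if (self.end - self.start + 1 - 3) % 3 != 0:
            raise ValueError("ORF span minus stop codon must be divisible by 3")
        if self.length_aa != (self.end - self.start + 1 - 3) // 3:
            raise ValueError("length_aa inconsistent with coordinates")


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_accession: str
    subject_description: str
    e_value: float
    percent_identity: float
    subject_length_aa: int
    query_orf_length_aa: int

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")
        if not 0 <= self.percent_identity <= 100:
            raise ValueError("percent_identity outside [0, 100]")


@dataclass(frozen=True)
class DomainHit:
    query_id: str
    database: str  # Pfam or CDD
    accession: str
    e_value: float

    def __post_init__(self) -> None:
        if self.database not in ("Pfam", "CDD"):
            raise ValueError(f"domain database must be Pfam or CDD, got {self.database!r}")


def _is_stop(codon: str) -> bool:
    # codons containing N are ambiguous: they translate to X and never
    # terminate a frame
    return codon in STOP_CODONS


def longest_orf(seq: str, transcript_id: str = "") -> OrfRecord | None:
    """Longest ATG-initiated, stop-terminated ORF on the sense strand.

    Transcripts are already stranded, so only the given sequence is
    scanned, in all three frames. Ties go to the 5'-most start. Returns
    None when no ATG...stop span exists.
    """
    seq = seq.upper()
    n = len(seq)
    best: tuple[int, int] | None = None  # (-length, start) minimisation key
    best_span: tuple[int, int] | None = None
    for frame in range(3):
        open_start: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos:pos + 3]
            if open_start is None:
                if codon == "ATG":
                    open_start = pos
            elif _is_stop(codon):
                length = pos - open_start  # coding bp, stop excluded
                key = (-length, open_start)
                if best is None or key < best:
                    best = key
                    best_span = (open_start, pos + 3)
                open_start = None
    if best_span is None:
        return None
    s0, e0 = best_span
    coding = seq[s0:e0 - 3]
    # the scanned span holds no true stop codons; ambiguous codons become X
    protein = str(Seq(coding).translate()) if coding else ""
    return OrfRecord(transcript_id, s0 + 1, e0, (e0 - s0 - 3) // 3, protein)


def passes_homology_gate(
    orf: OrfRecord,
    hits: Sequence[HomologyHit],
    max_e: float = 1e-15,
    min_frac: float = 0.75,
) -> tuple[bool, HomologyHit | None]:
    """Conservation gate for a candidate coding ORF.

    Passes iff some hit has e_value <= max_e and the ORF is at least
    ``min_frac`` of the matching protein's length (truncated matches are
    the signature of pseudogenes). Returns the flag and the best
    qualifying hit (smallest e-value).
    """
    qualifying = [
        h for h in hits
        if h.e_value <= max_e and h.query_orf_length_aa >= min_frac * h.subject_length_aa
    ]
    if not qualifying:
        return False, None
    best = min(qualifying, key=lambda h: (h.e_value, -h.percent_identity, h.subject_accession))
    return True, best


#: substring keywords (case-insensitive) marking an unknown-function name
_UNKNOWN_SUBSTRINGS = (
    "hypothetical",
    "unnamed protein product",
    "uncharacterized protein",
    "unknown",
    "pseudogene",
    "open reading frame",
)
#: token keywords: a token equal to the keyword, or keyword + digits
#: (LOC101927562-style identifiers), marks an unknown-function name
_UNKNOWN_TOKENS = ("loc", "pro", "orf")
_TOKEN_RE = re.compile(r"[A-Za-z]+\d*")


def has_named_function(description: str) -> bool:
    """True iff the subject protein name denotes a known function.

    Placeholder names ("hypothetical ...", LOC/ORF identifiers, hCG de novo
    predictions) return False. Matching is case-insensitive except for the
    hCG prefix; token matching avoids false hits inside words such as
    "prolactin".
    """
    text = description.strip()
    if not text:
        return False
    low = text.lower()
    if any(kw in low for kw in _UNKNOWN_SUBSTRINGS):
        return False
    for raw_tok in text.split():
        m = _TOKEN_RE.fullmatch(raw_tok.strip(".,;:()[]"))
        if not m:
            continue
        tok = m.group(0).lower()
        for kw in _UNKNOWN_TOKENS:
            if tok == kw or (tok.startswith(kw) and tok[len(kw):].isdigit()):
                return False
    first = text.split()[0]
    if first.startswith("hCG"):
        return False
    return True


def has_domain_support(
    transcript_id: str, domains: Iterable[DomainHit], max_e: float = 1e-5
) -> bool:
    """True iff >= 1 Pfam or CDD hit for this transcript at e_value <= max_e."""
    return any(d.query_id == transcript_id and d.e_value <= max_e for d in domains)


# ---------------------------------------------------------------------------
# Tabular evidence I/O
# ---------------------------------------------------------------------------

HOMOLOGY_COLUMNS = [
    "query_id", "subject_accession", "percent_identity", "alignment_length",
    "mismatches", "gap_opens", "q_start", "q_end", "s_start", "s_end",
    "e_value", "bit_score", "subject_length_aa", "query_orf_length_aa",
    "subject_description",
]


def read_homology_table(source) -> list[HomologyHit]:
    """Read BLAST outfmt-6-with-extras tabular hits.

    Columns are the 12 standard BLAST tabular fields followed by
    subject_length_aa, query_orf_length_aa and subject_description
    (tab-separated, no header or a '#'-prefixed header).
    """
    df = pd.read_csv(source, sep="\t", comment="#", header=None, names=HOMOLOGY_COLUMNS)
    return [
        HomologyHit(
            query_id=str(r.query_id),
            subject_accession=str(r.subject_accession),
            subject_description=str(r.subject_description),
            e_value=float(r.e_value),
            percent_identity=float(r.percent_identity),
            subject_length_aa=int(r.subject_length_aa),
            query_orf_length_aa=int(r.query_orf_length_aa),
        )
        for r in df.itertuples()
    ]


def read_domain_table(source) -> list[DomainHit]:
    """Read (query_id, database, accession, e_value) TSV of Pfam/CDD hits."""
    df = pd.read_csv(source, sep="\t", comment="#", header=None,
                     names=["query_id", "database", "accession", "e_value"])
    return [
        DomainHit(str(r.query_id), str(r.database), str(r.accession), float(r.e_value))
        for r in df.itertuples()
    ]
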