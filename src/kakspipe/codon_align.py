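"""From a homologue pair to a clean in-frame codon alignment.

Stages: trim both sequences to the overlapping hit region (snapped to
codon boundaries of the hit frame), translate, align the proteins
globally, thread the source codons through the protein alignment
(PAL2NAL-style), delete stop/nonsense columns, and apply the minimum
alignment-length filter (default 150 bp = 50 codons of comparable
sequence).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .core_formats import (
    GeneticCode,
    NucleotideSequence,
    ProteinSequence,
    STANDARD_CODE,
    STOP_CODONS,
    reverse_complement,
    translate_cds,
)
from .homology import HomologPair, _make_aligner, default_protein_scoring

MIN_ALIGNMENT_BP = 150

GAP_CODON = "---"


class PairDiscarded(Exception):
    """A pair failed a filter; `reason` is a stable reason code."""

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


class ThreadingError(ValueError):
    """Protein row inconsistent with its CDS — an upstream bug."""


@dataclass(frozen=True)
class TrimmedPair:
    """In-frame CDS fragments cut from the hit's overlapping region."""

    pair_id: str
    cds_a: str
    cds_b: str
    frame_a: int
    frame_b: int
    # 1-based inclusive coordinates of the fragments on the original sequences
    span_a: tuple[int, int] = (0, 0)
    span_b: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        for name, cds in (("cds_a", self.cds_a), ("cds_b", self.cds_b)):
            if len(cds) % 3 or len(cds) < 3:
                raise ValueError(f"{self.pair_id}.{name}: length {len(cds)} not a positive codon multiple")


def _extract_in_frame(seq: NucleotideSequence, start1: int, end1: int,
                      frame: int) -> tuple[str, tuple[int, int]]:
    """Cut [start1, end1] (1-based inclusive, original coordinates),
    orient to the frame's strand, and snap to that frame's codon grid:
    the start advances, the end recedes — the fragment never extends
    beyond the hit."""
    L = len(seq)
    if not (1 <= start1 <= end1 <= L):
        raise ValueError(f"{seq.id}: hit region {start1}..{end1} outside 1..{L}")
    strand = seq.bases if frame > 0 else reverse_complement(seq).bases
    if frame > 0:
        s0, e0 = start1 - 1, end1  # half-open on the plus strand
    else:
        s0, e0 = L - end1, L - start1 + 1  # half-open on the reverse complement
    offset = abs(frame) - 1
    # advance start to the frame's codon grid
    shift = (offset - s0) % 3
    s0 += shift
    e0 = s0 + 3 * ((e0 - s0) // 3)
    if e0 - s0 < 3:
        raise PairDiscarded("region_too_short",
                            f"{seq.id}: <1 codon after boundary snapping")
    fragment = strand[s0:e0]
    if frame > 0:
        span = (s0 + 1, e0)
    else:
        span = (L - e0 + 1, L - s0)
    return fragment, span


def trim_to_overlap(pair: HomologPair) -> TrimmedPair:
    """Trim both sequences of a pair to hit_ab's overlapping region.

    Raises :class:`PairDiscarded` (reason ``region_too_short``) when a
    side is shorter than one codon after snapping.
    """
    if pair.seq_a is None or pair.seq_b is None:
        raise ValueError(f"{pair.pair_id}: sequences not attached")
    hit = pair.hit_ab
    cds_a, span_a = _extract_in_frame(pair.seq_a, hit.qstart, hit.qend, hit.qframe)
    cds_b, span_b = _extract_in_frame(pair.seq_b, hit.sstart, hit.send, hit.sframe)
    return TrimmedPair(pair.pair_id, cds_a, cds_b, hit.qframe, hit.sframe,
                       span_a, span_b)


def protein_align_global(p1: ProteinSequence, p2: ProteinSequence,
                         matrix=None) -> tuple[str, str]:
    """Needleman-Wunsch global alignment under affine gaps.

    Returns two equal-length gapped strings whose ungapped content
    equals the inputs.
    """
    if not p1.residues or not p2.residues:
        raise ValueError("global alignment requires non-empty sequences")
    aligner = _make_aligner("global", matrix)
    aln = next(iter(aligner.align(p1.residues, p2.residues)))
    row_a, row_b = str(aln[0]), str(aln[1])
    return row_a, row_b


@dataclass(frozen=True)
class CodonAlignment:
    """Two gapped codon rows; each column is a codon or '---'."""

    pair_id: str
    row_a: tuple[str, ...]
    row_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.row_a) != len(self.row_b):
            raise ValueError("codon rows differ in column count")
        for ca, cb in zip(self.row_a, self.row_b):
            if len(ca) != 3 or len(cb) != 3:
                raise ValueError("every column entry must be 3 characters")
            if ca == GAP_CODON and cb == GAP_CODON:
                raise ValueError("column gapped in both rows")

    @property
    def n_columns(self) -> int:
        return len(self.row_a)

    @property
    def n_ungapped(self) -> int:
        return sum(1 for a, b in zip(self.row_a, self.row_b)
                   if a != GAP_CODON and b != GAP_CODON)

    @property
    def aln_len_bp(self) -> int:
        return 3 * self.n_ungapped

    def ungapped_pairs(self) -> list[tuple[str, str]]:
        return [(a, b) for a, b in zip(self.row_a, self.row_b)
                if a != GAP_CODON and b != GAP_CODON]

    def ungapped_row(self, which: str) -> str:
        row = self.row_a if which == "a" else self.row_b
        return "".join(c for c in row if c != GAP_CODON)


def thread_codons(protein_aln: tuple[str, str], trimmed: TrimmedPair,
                  code: GeneticCode = STANDARD_CODE) -> CodonAlignment:
    """Back-thread codons through a protein alignment.

    Each residue column is replaced by its source codon; gap residues
    become '---'.  The ungapped protein rows must equal the CDS
    translations or a :class:`ThreadingError` is raised.
    """
    row_pa, row_pb = protein_aln
    if len(row_pa) != len(row_pb):
        raise ThreadingError("protein rows differ in length")
    if row_pa.replace("-", "") != translate_cds(trimmed.cds_a, code):
        raise ThreadingError(f"{trimmed.pair_id}: row A does not translate cds_a")
    if row_pb.replace("-", "") != translate_cds(trimmed.cds_b, code):
        raise ThreadingError(f"{trimmed.pair_id}: row B does not translate cds_b")
    codons_a: list[str] = []
    codons_b: list[str] = []
    ia = ib = 0
    for res_a, res_b in zip(row_pa, row_pb):
        if res_a == "-":
            codons_a.append(GAP_CODON)
        else:
            codons_a.append(trimmed.cds_a[3 * ia:3 * ia + 3])
            ia += 1
        if res_b == "-":
            codons_b.append(GAP_CODON)
        else:
            codons_b.append(trimmed.cds_b[3 * ib:3 * ib + 3])
            ib += 1
    return CodonAlignment(trimmed.pair_id, tuple(codons_a), tuple(codons_b))


def _is_clean(codon: str) -> bool:
    return codon == GAP_CODON or (codon not in STOP_CODONS
                                  and all(b in "ACGT" for b in codon))


def remove_stop_and_nonsense(aln: CodonAlignment) -> CodonAlignment:
    """Delete every column where either row holds a stop codon or a
    codon containing non-ACGT characters.  Idempotent; may return an
    empty alignment."""
    kept = [(a, b) for a, b in zip(aln.row_a, aln.row_b)
            if _is_clean(a) and _is_clean(b)]
    rows = tuple(zip(*kept)) if kept else ((), ())
    return CodonAlignment(aln.pair_id, tuple(rows[0]), tuple(rows[1]))


def filter_min_length(aln: CodonAlignment,
                      min_bp: int = MIN_ALIGNMENT_BP) -> tuple[bool, Optional[str]]:
    """Keep iff the alignment carries at least `min_bp` of comparable
    (ungapped, stop-free) sequence."""
    if aln.aln_len_bp >= min_bp:
        return True, None
    return False, f"alignment_below_{min_bp}bp"


@dataclass
class CodonAlignmentResult:
    """Outcome of the full threading chain for one pair."""

    pair_id: str
    alignment: Optional[CodonAlignment] = None
    discard_reason: Optional[str] = None


def build_codon_alignment(pair: HomologPair,
                          min_bp: int = MIN_ALIGNMENT_BP,
                          matrix=None,
                          code: GeneticCode = STANDARD_CODE) -> CodonAlignmentResult:
    """Run trim -> translate -> global align -> thread -> clean -> filter."""
    if matrix is None:
        matrix = default_protein_scoring()
    try:
        trimmed = trim_to_overlap(pair)
    except PairDiscarded as exc:
        return CodonAlignmentResult(pair.pair_id, discard_reason=exc.reason)
    prot_a = ProteinSequence(pair.id_a, translate_cds(trimmed.cds_a, code))
    prot_b = ProteinSequence(pair.id_b, translate_cds(trimmed.cds_b, code))
    rows = protein_align_global(prot_a, prot_b, matrix)
    aln = thread_codons(rows, trimmed, code)
    aln = remove_stop_and_nonsense(aln)
    keep, reason = filter_min_length(aln, min_bp)
    if not keep:
        return CodonAlignmentResult(pair.pair_id, discard_reason=reason)
    return CodonAlignmentResult(pair.pair_id, alignment=aln)


def write_codon_alignment_fasta(aln: CodonAlignment, id_a: str, id_b: str,
                                path) -> None:
    """Write the two gapped rows as aligned FASTA (3-character codon
    granularity)."""
    with open(path, "w") as handle:
        for rec_id, row in ((id_a, aln.row_a), (id_b, aln.row_b)):
            handle.write(f">{rec_id}\n")
            seq = "".join(row)
            for i in range(0, len(seq), 60):
                handle.write(seq[i:i + 60] + "\n")
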