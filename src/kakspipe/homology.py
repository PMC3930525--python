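"""Translated homology search and reciprocal-best-hit pairing.

A desk-scale stand-in for a translated BLAST (tBLASTx-style) step:
every query/subject pair is evaluated over all 36 reading-frame
combinations with Smith-Waterman local alignment in protein space
(BLOSUM62, affine gaps), and the single best HSP per pair is kept.
Externally produced tabular hits (BLAST outfmt 6) can be ingested
instead, so the pairing logic is independent of the search engine.

E-values use the Karlin-Altschul form E = K*m*n*exp(-lambda*S) with the
gapped BLOSUM62 constants K = 0.041, lambda = 0.267; m and n are the
protein frame lengths summed over the six frames.  This is an explicit
approximation — a raw-score threshold is accepted as an alternative.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

from Bio.Align import PairwiseAligner, substitution_matrices

from .core_formats import (
    FRAMES,
    NucleotideSequence,
    ProteinSequence,
    STANDARD_CODE,
    translate_frame,
)

logger = logging.getLogger(__name__)

KARLIN_K = 0.041
KARLIN_LAMBDA = 0.267

#: BLAST-style affine gap cost: a gap of length k costs open + k * extend.
GAP_OPEN = 11
GAP_EXTEND = 1


#: Score for any column involving a stop.  Strong enough that a local
#: hit never pays to extend across a stop codon, so the best HSP stays
#: inside one open reading frame (a mild -4 lets long flanks absorb the
#: cost and off-frame self-hits can outscore the true frame).
STOP_SCORE = -100.0


def default_protein_scoring():
    """BLOSUM62 with '*' alignment-blocking and 'X' neutral (0).

    Stops are frame artefacts here: penalising them hard keeps HSPs
    within a single reading frame.  Untranslatable codons ('X') are
    scored 0 against everything except stops.
    """
    matrix = substitution_matrices.load("BLOSUM62")
    alphabet = matrix.alphabet
    star = alphabet.index("*")
    x = alphabet.index("X")
    for i in range(len(alphabet)):
        matrix[star, i] = matrix[i, star] = STOP_SCORE
    for i in range(len(alphabet)):
        if i != star:
            matrix[x, i] = matrix[i, x] = 0.0
    return matrix


def _make_aligner(mode: str, matrix=None) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = matrix if matrix is not None else default_protein_scoring()
    aligner.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


@dataclass(frozen=True)
class ProteinLocalAlignment:
    """Best local alignment between two protein sequences."""

    aligned_a: str
    aligned_b: str
    raw_score: float
    a_start: int  # 0-based half-open residue coordinates on the inputs
    a_end: int
    b_start: int
    b_end: int

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)

    @property
    def n_identical(self) -> int:
        return sum(1 for x, y in zip(self.aligned_a, self.aligned_b) if x == y and x != "-")


def local_align_protein(p1: ProteinSequence, p2: ProteinSequence,
                        matrix=None) -> ProteinLocalAlignment:
    """Smith-Waterman optimum under affine gaps.

    Raises a ``ValueError`` if a residue is missing from the scoring
    matrix.  A score-0 empty alignment is a legal result (all pair
    scores negative).
    """
    if not p1.residues or not p2.residues:
        raise ValueError("local alignment requires non-empty sequences")
    aligner = _make_aligner("local", matrix)
    alphabet = set(aligner.substitution_matrix.alphabet)
    missing = (set(p1.residues) | set(p2.residues)) - alphabet
    if missing:
        raise ValueError(f"residues absent from scoring matrix: {sorted(missing)}")
    score = aligner.score(p1.residues, p2.residues)
    if score <= 0:
        return ProteinLocalAlignment("", "", 0.0, 0, 0, 0, 0)
    aln = next(iter(aligner.align(p1.residues, p2.residues)))
    seg_a, seg_b = aln.aligned
    a0, a1 = int(seg_a[0][0]), int(seg_a[-1][1])
    b0, b1 = int(seg_b[0][0]), int(seg_b[-1][1])
    row_a, row_b = _gapped_rows(p1.residues, p2.residues, seg_a, seg_b)
    return ProteinLocalAlignment(
        aligned_a=row_a,
        aligned_b=row_b,
        raw_score=float(score),
        a_start=a0,
        a_end=a1,
        b_start=b0,
        b_end=b1,
    )


def _gapped_rows(seq_a: str, seq_b: str, seg_a, seg_b) -> tuple[str, str]:
    """Reconstruct gapped row strings for the aligned region from the
    aligned-block coordinates."""
    row_a: list[str] = []
    row_b: list[str] = []
    for i in range(len(seg_a)):
        if i > 0:
            gap_a = seg_a[i][0] - seg_a[i - 1][1]
            gap_b = seg_b[i][0] - seg_b[i - 1][1]
            row_a.append(seq_a[seg_a[i - 1][1]:seg_a[i][0]] + "-" * gap_b)
            row_b.append("-" * gap_a + seq_b[seg_b[i - 1][1]:seg_b[i][0]])
        row_a.append(seq_a[seg_a[i][0]:seg_a[i][1]])
        row_b.append(seq_b[seg_b[i][0]:seg_b[i][1]])
    return "".join(row_a), "".join(row_b)


@dataclass(frozen=True)
class AlignmentHit:
    """One translated-search HSP with 1-based nucleotide coordinates.

    Coordinates always refer to the original (unreversed) sequences;
    minus-strand hits are flagged by a negative frame.
    """

    query_id: str
    subject_id: str
    qframe: int
    sframe: int
    qstart: int
    qend: int
    sstart: int
    send: int
    raw_score: float
    bitscore: float
    evalue: float
    aln_len_aa: int
    pident: float

    def __post_init__(self) -> None:
        if not (1 <= self.qstart <= self.qend):
            raise ValueError(f"bad query coordinates {self.qstart}..{self.qend}")
        if not (1 <= self.sstart <= self.send):
            raise ValueError(f"bad subject coordinates {self.sstart}..{self.send}")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if self.aln_len_aa < 1:
            raise ValueError("aln_len_aa must be >= 1")


@dataclass(frozen=True)
class SearchThreshold:
    """Report a hit if evalue <= evalue bound, or raw_score >= score bound."""

    evalue: Optional[float] = 1e-5
    score: Optional[float] = None

    def passes(self, hit: AlignmentHit) -> bool:
        if self.score is not None:
            return hit.raw_score >= self.score
        if self.evalue is not None:
            return hit.evalue <= self.evalue
        return True


def _frame_to_original(frame: int, res_start: int, res_end: int, seq_len: int) -> tuple[int, int]:
    """Map half-open residue coords on a frame translation to 1-based
    inclusive nucleotide coords on the original strand."""
    offset = abs(frame) - 1
    nt_start0 = offset + 3 * res_start
    nt_end0 = offset + 3 * res_end  # half-open
    if frame > 0:
        return nt_start0 + 1, nt_end0
    return seq_len - nt_end0 + 1, seq_len - nt_start0


def _frame_translations(seq: NucleotideSequence, code) -> dict[int, ProteinSequence]:
    out = {}
    for frame in FRAMES:
        if abs(frame) - 1 < len(seq):
            prot = translate_frame(seq, frame, code)
            if len(prot):
                out[frame] = prot
    return out


def translated_search(query: NucleotideSequence,
                      subjects: Sequence[NucleotideSequence],
                      matrix=None,
                      threshold: SearchThreshold = SearchThreshold(),
                      code=STANDARD_CODE) -> list[AlignmentHit]:
    """Six-frame by six-frame local search of `query` against `subjects`.

    Only the single best HSP per query/subject pair is retained (the
    downstream trim uses one overlapping region).  Hits are sorted by
    descending raw score with (subject_id, qframe, sframe) as the tie
    order.
    """
    if matrix is None:
        matrix = default_protein_scoring()
    q_frames = _frame_translations(query, code)
    m = sum(len(p) for p in q_frames.values())
    hits: list[AlignmentHit] = []
    for subject in subjects:
        s_frames = _frame_translations(subject, code)
        n = sum(len(p) for p in s_frames.values())
        best: Optional[AlignmentHit] = None
        for qf in FRAMES:
            if qf not in q_frames:
                continue
            for sf in FRAMES:
                if sf not in s_frames:
                    continue
                aln = local_align_protein(q_frames[qf], s_frames[sf], matrix)
                if aln.raw_score <= 0:
                    continue
                qstart, qend = _frame_to_original(qf, aln.a_start, aln.a_end, len(query))
                sstart, send = _frame_to_original(sf, aln.b_start, aln.b_end, len(subject))
                evalue = KARLIN_K * m * n * math.exp(-KARLIN_LAMBDA * aln.raw_score)
                bitscore = (KARLIN_LAMBDA * aln.raw_score - math.log(KARLIN_K)) / math.log(2)
                hit = AlignmentHit(
                    query_id=query.id, subject_id=subject.id,
                    qframe=qf, sframe=sf,
                    qstart=qstart, qend=qend, sstart=sstart, send=send,
                    raw_score=aln.raw_score, bitscore=bitscore, evalue=evalue,
                    aln_len_aa=aln.n_columns,
                    pident=100.0 * aln.n_identical / aln.n_columns,
                )
                if best is None or hit.raw_score > best.raw_score:
                    best = hit
        if best is not None and threshold.passes(best):
            hits.append(best)
    hits.sort(key=lambda h: (-h.raw_score, h.subject_id, h.qframe, h.sframe))
    return hits


def search_all(queries: Sequence[NucleotideSequence],
               subjects: Sequence[NucleotideSequence],
               matrix=None,
               threshold: SearchThreshold = SearchThreshold(),
               code=STANDARD_CODE) -> list[AlignmentHit]:
    """translated_search for every query, concatenated."""
    if matrix is None:
        matrix = default_protein_scoring()
    hits: list[AlignmentHit] = []
    for query in queries:
        hits.extend(translated_search(query, subjects, matrix, threshold, code))
    return hits


@dataclass(frozen=True)
class HomologPair:
    """A reciprocally best-matched pair of transcripts."""

    pair_id: str
    hit_ab: AlignmentHit
    hit_ba: AlignmentHit
    seq_a: Optional[NucleotideSequence] = None
    seq_b: Optional[NucleotideSequence] = None

    def __post_init__(self) -> None:
        if self.hit_ab.query_id != self.hit_ba.subject_id or \
           self.hit_ab.subject_id != self.hit_ba.query_id:
            raise ValueError("hit_ab and hit_ba do not describe the same pair")
        if self.seq_a is not None and self.seq_a.id != self.hit_ab.query_id:
            raise ValueError("seq_a id does not match hit_ab.query_id")
        if self.seq_b is not None and self.seq_b.id != self.hit_ab.subject_id:
            raise ValueError("seq_b id does not match hit_ab.subject_id")

    @property
    def id_a(self) -> str:
        return self.hit_ab.query_id

    @property
    def id_b(self) -> str:
        return self.hit_ab.subject_id


def _best_per_query(hits: Sequence[AlignmentHit]) -> dict[str, Optional[AlignmentHit]]:
    """Single best subject per query; an exact score tie between distinct
    subjects marks the query ambiguous (None)."""
    best: dict[str, AlignmentHit] = {}
    ambiguous: set[str] = set()
    for hit in hits:
        cur = best.get(hit.query_id)
        if cur is None or hit.raw_score > cur.raw_score:
            best[hit.query_id] = hit
            ambiguous.discard(hit.query_id)
        elif hit.raw_score == cur.raw_score and hit.subject_id != cur.subject_id:
            ambiguous.add(hit.query_id)
    out: dict[str, Optional[AlignmentHit]] = dict(best)
    for qid in ambiguous:
        logger.warning("query %s has a best-score tie between subjects; left unpaired", qid)
        out[qid] = None
    return out


def reciprocal_best_hits(hits_ab: Sequence[AlignmentHit],
                         hits_ba: Sequence[AlignmentHit],
                         threshold: SearchThreshold = SearchThreshold()) -> list[HomologPair]:
    """Pair (a, b) iff b is a's single best subject and a is b's, both
    passing the threshold.  The output is a matching: each id occurs in
    at most one pair."""
    best_ab = _best_per_query(hits_ab)
    best_ba = _best_per_query(hits_ba)
    pairs: list[HomologPair] = []
    for a_id in sorted(best_ab):
        hit_ab = best_ab[a_id]
        if hit_ab is None or not threshold.passes(hit_ab):
            continue
        hit_ba = best_ba.get(hit_ab.subject_id)
        if hit_ba is None or hit_ba.subject_id != a_id or not threshold.passes(hit_ba):
            continue
        pairs.append(HomologPair(
            pair_id=f"pair{len(pairs) + 1:05d}", hit_ab=hit_ab, hit_ba=hit_ba))
    return pairs


def attach_sequences(pairs: Sequence[HomologPair],
                     seqs_a: Sequence[NucleotideSequence],
                     seqs_b: Sequence[NucleotideSequence]) -> list[HomologPair]:
    """Resolve sequence references for pairs built from tabular hits."""
    by_a = {s.id: s for s in seqs_a}
    by_b = {s.id: s for s in seqs_b}
    out = []
    for pair in pairs:
        try:
            out.append(HomologPair(pair.pair_id, pair.hit_ab, pair.hit_ba,
                                   seq_a=by_a[pair.id_a], seq_b=by_b[pair.id_b]))
        except KeyError as exc:
            raise ValueError(f"pair {pair.pair_id}: sequence {exc} not found") from exc
    return out


# ---------------------------------------------------------------------------
# BLAST outfmt-6 interop

class TabularHitParseError(ValueError):
    pass


def read_tabular_hits(path: Union[str, Path]) -> list[AlignmentHit]:
    """Parse a 12-column BLAST outfmt-6 TSV, with two optional trailing
    qframe/sframe columns.

    When frame columns are missing, orientation is inferred from
    coordinate order (start > end => minus strand, recorded as frame
    -1; plus strand as +1 — the frame index is unknown) and coordinates
    are normalized to start <= end.
    """
    hits: list[AlignmentHit] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (12, 14):
                raise TabularHitParseError(
                    f"line {lineno}: expected 12 or 14 columns, got {len(fields)}")
            try:
                (qseqid, sseqid, pident, length, _mismatch, _gapopen,
                 qstart, qend, sstart, send, evalue, bitscore) = fields[:12]
                qstart, qend, sstart, send = map(int, (qstart, qend, sstart, send))
                pident, evalue, bitscore = float(pident), float(evalue), float(bitscore)
                length = int(length)
            except ValueError as exc:
                raise TabularHitParseError(f"line {lineno}: {exc}") from exc
            if len(fields) == 14:
                qframe, sframe = int(fields[12]), int(fields[13])
            else:
                qframe = 1 if qstart <= qend else -1
                sframe = 1 if sstart <= send else -1
            if qstart > qend:
                qstart, qend = qend, qstart
            if sstart > send:
                sstart, send = send, sstart
            hits.append(AlignmentHit(
                query_id=qseqid, subject_id=sseqid, qframe=qframe, sframe=sframe,
                qstart=qstart, qend=qend, sstart=sstart, send=send,
                raw_score=bitscore, bitscore=bitscore, evalue=evalue,
                aln_len_aa=length, pident=pident))
    return hits


def write_tabular_hits(hits: Sequence[AlignmentHit], path: Union[str, Path]) -> None:
    """Write hits as 14-column outfmt-6-plus-frames TSV."""
    with open(path, "w") as handle:
        for h in hits:
            handle.write("\t".join(str(v) for v in (
                h.query_id, h.subject_id, f"{h.pident:.2f}", h.aln_len_aa, 0, 0,
                h.qstart, h.qend, h.sstart, h.send,
                f"{h.evalue:.3g}", f"{h.bitscore:.1f}", h.qframe, h.sframe)) + "\n")
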