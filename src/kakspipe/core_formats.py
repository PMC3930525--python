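"""Sequence and table primitives shared by every pipeline stage.

DNA FASTA in, frame-aware translation out.  Coordinates are 0-based
half-open internally; every external report uses 1-based inclusive
coordinates, matching the tabular-hit convention of translated-search
tools.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

from Bio.Data import CodonTable

DNA_ALPHABET = frozenset("ACGTN")
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
FRAMES = (1, 2, 3, -1, -2, -3)

FASTA_LINE_WIDTH = 80


class FastaParseError(ValueError):
    """Malformed FASTA input; message carries the offending line number."""


@dataclass(frozen=True)
class NucleotideSequence:
    """An uppercase DNA sequence over {A,C,G,T,N} with a non-empty id."""

    id: str
    bases: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"sequence id must be non-empty and whitespace-free: {self.id!r}")
        object.__setattr__(self, "bases", self.bases.upper())
        if len(self.bases) < 1:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.bases) - DNA_ALPHABET
        if bad:
            raise ValueError(f"{self.id}: illegal characters {sorted(bad)} (U/RNA not accepted)")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class ProteinSequence:
    """A translation product: 20 amino acids plus '*' (stop) and 'X' (untranslatable)."""

    id: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


def _standard_code_table() -> dict[str, str]:
    table = dict(CodonTable.unambiguous_dna_by_id[1].forward_table)
    for stop in STOP_CODONS:
        table[stop] = "*"
    return table


@dataclass(frozen=True)
class GeneticCode:
    """Codon -> amino-acid map.  Default is the standard nuclear code."""

    id: str = "standard"
    table: dict[str, str] = field(default_factory=_standard_code_table)

    def __post_init__(self) -> None:
        if len(self.table) != 64:
            raise ValueError(f"genetic code must map all 64 codons, got {len(self.table)}")

    def translate_codon(self, codon: str) -> str:
        """Translate one codon; codons containing N (or anything non-ACGT) give 'X'."""
        return self.table.get(codon, "X")

    def is_stop(self, codon: str) -> bool:
        return self.table.get(codon) == "*"

    @property
    def sense_codons(self) -> list[str]:
        return sorted(c for c, aa in self.table.items() if aa != "*")


STANDARD_CODE = GeneticCode()


# ---------------------------------------------------------------------------
# FASTA IO

def read_fasta(source: Union[str, Path, io.TextIOBase]) -> list[NucleotideSequence]:
    """Read a multi-record DNA FASTA file.

    Sequence lines are concatenated and uppercased; record order is
    preserved.  Malformed headers, empty records or illegal characters
    raise :class:`FastaParseError` naming the line number.
    """
    if isinstance(source, (str, Path)):
        with open(source) as handle:
            return _parse_fasta(handle)
    return _parse_fasta(source)


def _parse_fasta(handle: Iterable[str]) -> list[NucleotideSequence]:
    records: list[NucleotideSequence] = []
    current_id: str | None = None
    chunks: list[str] = []
    header_line = 0

    def flush() -> None:
        if current_id is None:
            return
        seq = "".join(chunks)
        try:
            records.append(NucleotideSequence(current_id, seq))
        except ValueError as exc:
            raise FastaParseError(f"line {header_line}: {exc}") from exc

    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith(">"):
            flush()
            current_id = line[1:].split()[0] if line[1:].strip() else ""
            if not current_id:
                raise FastaParseError(f"line {lineno}: empty FASTA header")
            chunks = []
            header_line = lineno
        else:
            if current_id is None:
                raise FastaParseError(f"line {lineno}: sequence data before any header")
            chunks.append(line.strip())
    flush()
    return records


def write_fasta(records: Iterable[Union[NucleotideSequence, ProteinSequence]],
                dest: Union[str, Path, io.TextIOBase],
                line_width: int = FASTA_LINE_WIDTH) -> None:
    """Write records as FASTA, wrapped at `line_width` columns."""
    def _emit(handle: io.TextIOBase) -> None:
        for rec in records:
            seq = rec.bases if isinstance(rec, NucleotideSequence) else rec.residues
            handle.write(f">{rec.id}\n")
            for i in range(0, len(seq), line_width):
                handle.write(seq[i:i + line_width] + "\n")

    if isinstance(dest, (str, Path)):
        with open(dest, "w") as handle:
            _emit(handle)
    else:
        _emit(dest)


# ---------------------------------------------------------------------------
# Strand and frame operations

def reverse_complement(seq: NucleotideSequence) -> NucleotideSequence:
    """Watson-Crick complement, reversed.  N maps to N; an involution."""
    return NucleotideSequence(seq.id, seq.bases.translate(COMPLEMENT)[::-1])


def translate_frame(seq: NucleotideSequence, frame: int,
                    code: GeneticCode = STANDARD_CODE) -> ProteinSequence:
    """Translate one of the six reading frames.

    Minus frames translate the reverse complement.  The leading
    ``|frame| - 1`` bases are skipped and any trailing partial codon is
    dropped, so the product has ``floor((len - (|frame| - 1)) / 3)``
    residues.  Stops render as '*', codons containing N as 'X'.
    """
    if frame not in FRAMES:
        raise ValueError(f"frame must be one of {FRAMES}, got {frame}")
    bases = seq.bases if frame > 0 else reverse_complement(seq).bases
    offset = abs(frame) - 1
    if offset >= len(bases):
        raise ValueError(f"{seq.id}: frame {frame} needs at least {offset + 1} bases")
    usable = bases[offset:]
    residues = "".join(code.translate_codon(usable[i:i + 3])
                       for i in range(0, len(usable) - len(usable) % 3, 3))
    return ProteinSequence(f"{seq.id}|frame{frame:+d}", residues)


def translate_cds(bases: str, code: GeneticCode = STANDARD_CODE) -> str:
    """Translate an in-frame CDS string (length divisible by 3)."""
    if len(bases) % 3:
        raise ValueError(f"CDS length {len(bases)} not divisible by 3")
    return "".join(code.translate_codon(bases[i:i + 3]) for i in range(0, len(bases), 3))
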