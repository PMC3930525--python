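"""Tiered SNP discovery from per-position base-count pileups.

Implements the depth/MAF stringency tiers used for 454 transcriptome
assemblies (strict inequalities throughout), the 50 bp flanking rule,
and the homopolymer exclusion (no call inside a mononucleotide run
longer than two in the contig reference — the dominant 454 error mode).
Tier thresholds default to: low depth > 8 and MAF > 15%; medium
depth > 12 and MAF > 20%; high depth > 15 and MAF > 25%.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .core_formats import NucleotideSequence

BASES = ("A", "C", "G", "T")

FLANK_BP = 50
MAX_HOMOPOLYMER = 2


@dataclass(frozen=True)
class PileupColumn:
    """Base counts at one 1-based contig position."""

    contig_id: str
    position: int
    count_a: int
    count_c: int
    count_g: int
    count_t: int

    @property
    def counts(self) -> dict[str, int]:
        return {"A": self.count_a, "C": self.count_c,
                "G": self.count_g, "T": self.count_t}

    @property
    def depth(self) -> int:
        return self.count_a + self.count_c + self.count_g + self.count_t


@dataclass(frozen=True)
class TierThresholds:
    """Strict lower bounds: a call needs depth > min_depth and
    MAF > min_maf."""

    name: str
    min_depth: int
    min_maf: float


DEFAULT_TIERS = (
    TierThresholds("low", 8, 0.15),
    TierThresholds("medium", 12, 0.20),
    TierThresholds("high", 15, 0.25),
)

TRANSITIONS = frozenset({frozenset("AG"), frozenset("CT")})


def classify_substitution(major: str, minor: str) -> str:
    """A<->G and C<->T are transitions; every other pair a transversion."""
    if major == minor:
        raise ValueError("major and minor allele must differ")
    return "transition" if frozenset((major, minor)) in TRANSITIONS else "transversion"


@dataclass(frozen=True)
class SnpCall:
    contig_id: str
    position: int
    major_base: str
    minor_base: str
    maf: float
    depth: int
    tiers: frozenset[str]
    substitution_class: str


def max_homopolymer_run(reference: str, position: int) -> int:
    """Length of the maximal mononucleotide run containing the 1-based
    `position` in the reference sequence."""
    i = position - 1
    base = reference[i]
    left = i
    while left > 0 and reference[left - 1] == base:
        left -= 1
    right = i
    while right + 1 < len(reference) and reference[right + 1] == base:
        right += 1
    return right - left + 1


def _third_allele_ceiling(depth: int) -> float:
    return max(1.0, 0.01 * depth)


def call_snps(pileups: Iterable[PileupColumn],
              contigs: Sequence[NucleotideSequence],
              tiers: Sequence[TierThresholds] = DEFAULT_TIERS,
              flank_bp: int = FLANK_BP,
              max_homopolymer: int = MAX_HOMOPOLYMER,
              third_allele_ceiling=_third_allele_ceiling) -> list[SnpCall]:
    """Scan pileup columns and emit tiered SNP calls.

    A column is called when: exactly one credible minor allele exists
    (columns whose 3rd-most-frequent base exceeds the noise ceiling are
    rejected as multi-allelic); depth and MAF strictly exceed at least
    one tier's thresholds; the position has >= `flank_bp` bases of
    contig sequence on both sides; and the reference run containing it
    is no longer than `max_homopolymer`.
    """
    by_contig = {c.id: c for c in contigs}
    calls: list[SnpCall] = []
    for col in pileups:
        contig = by_contig.get(col.contig_id)
        if contig is None:
            raise ValueError(f"pileup references unknown contig {col.contig_id!r}")
        if not (1 <= col.position <= len(contig)):
            raise ValueError(
                f"{col.contig_id}:{col.position} outside contig length {len(contig)}")
        ranked = sorted(col.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        (major, major_n), (minor, minor_n), (_, third_n) = ranked[0], ranked[1], ranked[2]
        depth = col.depth
        if minor_n == 0 or depth == 0:
            continue
        if third_n > third_allele_ceiling(depth):
            continue
        maf = minor_n / depth
        passed = frozenset(t.name for t in tiers
                           if depth > t.min_depth and maf > t.min_maf)
        if not passed:
            continue
        if col.position - 1 < flank_bp or len(contig) - col.position < flank_bp:
            continue
        if max_homopolymer_run(contig.bases, col.position) > max_homopolymer:
            continue
        calls.append(SnpCall(
            contig_id=col.contig_id, position=col.position,
            major_base=major, minor_base=minor, maf=maf, depth=depth,
            tiers=passed,
            substitution_class=classify_substitution(major, minor)))
    return calls


@dataclass(frozen=True)
class TierSummary:
    tier: str
    n_snps: int
    n_contigs: int
    n_transversions: int
    n_transitions: int


def summarize_snps(calls: Sequence[SnpCall],
                   tiers: Sequence[TierThresholds] = DEFAULT_TIERS) -> list[TierSummary]:
    """Per-tier totals: SNPs, contigs with at least one SNP,
    transversions and transitions (Ts + Tv = total within each tier)."""
    out = []
    for tier in tiers:
        subset = [c for c in calls if tier.name in c.tiers]
        ts = sum(1 for c in subset if c.substitution_class == "transition")
        tv = len(subset) - ts
        out.append(TierSummary(tier.name, len(subset),
                               len({c.contig_id for c in subset}), tv, ts))
    return out


# ---------------------------------------------------------------------------
# IO

def read_pileup_tsv(path: Union[str, Path]) -> list[PileupColumn]:
    """Read a pileup TSV: contig, pos (1-based), countA, countC, countG,
    countT, with a header row."""
    cols: list[PileupColumn] = []
    with open(path) as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        required = {"contig", "pos", "countA", "countC", "countG", "countT"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"pileup TSV must have columns {sorted(required)}")
        for row in reader:
            cols.append(PileupColumn(
                row["contig"], int(row["pos"]),
                int(row["countA"]), int(row["countC"]),
                int(row["countG"]), int(row["countT"])))
    return cols


def write_pileup_tsv(cols: Iterable[PileupColumn], path: Union[str, Path]) -> None:
    with open(path, "w") as handle:
        handle.write("contig\tpos\tcountA\tcountC\tcountG\tcountT\n")
        for c in cols:
            handle.write(f"{c.contig_id}\t{c.position}\t{c.count_a}\t"
                         f"{c.count_c}\t{c.count_g}\t{c.count_t}\n")


def write_snp_tsv(calls: Sequence[SnpCall], path: Union[str, Path]) -> None:
    with open(path, "w") as handle:
        handle.write("contig\tpos\tmajor\tminor\tmaf\tdepth\ttiers\tsubstitution_class\n")
        for c in sorted(calls, key=lambda c: (c.contig_id, c.position)):
            tier_str = ",".join(t for t in ("low", "medium", "high") if t in c.tiers)
            handle.write(f"{c.contig_id}\t{c.position}\t{c.major_base}\t{c.minor_base}\t"
                         f"{c.maf:.6g}\t{c.depth}\t{tier_str}\t{c.substitution_class}\n")


def write_snp_vcf(calls: Sequence[SnpCall], path: Union[str, Path]) -> None:
    """Minimal VCF v4.2: REF = major allele, ALT = minor, INFO DP and
    AF, FILTER carries the tier labels."""
    with open(path, "w") as handle:
        handle.write("##fileformat=VCFv4.2\n")
        handle.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        handle.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Minor allele frequency">\n')
        for tier in ("low", "medium", "high"):
            handle.write(f'##FILTER=<ID={tier},Description="Passes {tier}-stringency thresholds">\n')
        handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(calls, key=lambda c: (c.contig_id, c.position)):
            tier_str = ";".join(t for t in ("low", "medium", "high") if t in c.tiers)
            handle.write(f"{c.contig_id}\t{c.position}\t.\t{c.major_base}\t{c.minor_base}\t.\t"
                         f"{tier_str}\tDP={c.depth};AF={c.maf:.6g}\n")


def pileup_from_sam(sam_path: Union[str, Path],
                    contigs: Sequence[NucleotideSequence]) -> list[PileupColumn]:
    """Reduce a SAM file to pileup columns, counting only aligned
    match/mismatch bases (indels and clips ignored)."""
    import pysam

    lengths = {c.id: len(c) for c in contigs}
    counts: dict[tuple[str, int], dict[str, int]] = {}
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for read in sam.fetch(until_eof=True):
            if read.is_unmapped or read.query_sequence is None:
                continue
            contig = read.reference_name
            if contig not in lengths:
                raise ValueError(f"SAM read maps to unknown contig {contig!r}")
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                base = read.query_sequence[qpos].upper()
                if base not in BASES:
                    continue
                key = (contig, rpos + 1)
                counts.setdefault(key, {b: 0 for b in BASES})[base] += 1
    return [PileupColumn(contig, pos, c["A"], c["C"], c["G"], c["T"])
            for (contig, pos), c in sorted(counts.items())]
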