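"""Nei-Gojobori (1986) Ka/Ks estimation on codon alignments.

The estimator counts, for each codon, the fractional number of
synonymous (s) and nonsynonymous (n) sites — a site's synonymous
fraction is the share of its three possible single-nucleotide changes
that preserve the amino acid, changes to stop codons counting as
nonsynonymous.  Differences between a codon pair are partitioned by
averaging over all orderings of the single-nucleotide steps connecting
them (pathways through stop codons excluded, with an include-all
fallback when every pathway is blocked).  Proportions pS = Sd/S and
pN = Nd/N are corrected for multiple hits with the Jukes-Cantor
formula d = -(3/4) ln(1 - (4/3) p), and the ratio Ka/Ks classifies
selection: > 1 positive, < 1 purifying, = 1 neutral.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from typing import Optional

from .core_formats import GeneticCode, STANDARD_CODE
from .codon_align import CodonAlignment


@dataclass(frozen=True)
class CodonSiteCounts:
    """Fractional synonymous/nonsynonymous site counts for one codon;
    s + n = 3 exactly."""

    s: float
    n: float


def synonymous_sites(codon: str, code: GeneticCode = STANDARD_CODE) -> CodonSiteCounts:
    """Per-codon fractional site counts.

    Each of the 3 positions contributes (synonymous single-nucleotide
    changes at that position) / 3 to s.  Changes producing a stop codon
    are nonsynonymous.  Stop-codon input is an error.
    """
    return _site_counts_impl(codon, tuple(sorted(code.table.items())))


@lru_cache(maxsize=None)
def _site_counts_impl(codon: str, table_items: tuple) -> CodonSiteCounts:
    table = dict(table_items)
    aa = table.get(codon)
    if aa is None:
        raise ValueError(f"codon {codon!r} contains non-ACGT characters")
    if aa == "*":
        raise ValueError(f"stop codon {codon} has no site counts")
    s = 0.0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            if table[mutant] == aa:  # stop mutants have aa '*', never equal
                s += 1.0 / 3.0
    return CodonSiteCounts(s=s, n=3.0 - s)


def pathway_diffs(codon1: str, codon2: str,
                  code: GeneticCode = STANDARD_CODE) -> tuple[float, float]:
    """Pathway-averaged (sd, nd) between two sense codons.

    For codons differing at k positions, the k! orderings of single
    changes are averaged; orderings passing through a stop codon are
    excluded (falling back to all orderings when every one is blocked).
    sd + nd = k exactly, and the function is symmetric.
    """
    return _pathway_impl(codon1, codon2, tuple(sorted(code.table.items())))


@lru_cache(maxsize=None)
def _pathway_impl(codon1: str, codon2: str, table_items: tuple) -> tuple[float, float]:
    table = dict(table_items)
    for codon in (codon1, codon2):
        aa = table.get(codon)
        if aa is None:
            raise ValueError(f"codon {codon!r} contains non-ACGT characters")
        if aa == "*":
            raise ValueError(f"stop codon {codon} not allowed in pathway counting")
    diff_positions = [i for i in range(3) if codon1[i] != codon2[i]]
    k = len(diff_positions)
    if k == 0:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stops: bool) -> Optional[tuple[float, float]]:
        sd = nd = 0.0
        current = codon1
        for pos in order:
            nxt = current[:pos] + codon2[pos] + current[pos + 1:]
            aa_from, aa_to = table[current], table[nxt]
            if aa_to == "*" and nxt != codon2 and not allow_stops:
                return None
            if aa_from == aa_to:
                sd += 1.0
            else:
                nd += 1.0
            current = nxt
        return sd, nd

    orders = list(permutations(diff_positions))
    results = [r for r in (walk(o, allow_stops=False) for o in orders) if r is not None]
    if not results:
        results = [walk(o, allow_stops=True) for o in orders]
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


def jukes_cantor(p: float) -> Optional[float]:
    """Jukes-Cantor distance d = -(3/4) ln(1 - (4/3) p).

    Returns None at saturation (p >= 3/4); d(0) = 0; strictly
    increasing on [0, 3/4).
    """
    if p < 0:
        raise ValueError(f"proportion must be non-negative, got {p}")
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


STATUS_OK = "ok"
STATUS_KS_ZERO = "ks_zero"
STATUS_SATURATED_S = "saturated_s"
STATUS_SATURATED_N = "saturated_n"
STATUS_EMPTY = "empty"


@dataclass(frozen=True)
class KaKsEstimate:
    """NG86 summary for one codon alignment.

    S + N = 3 * n_ungapped exactly; `ratio` is None whenever the
    estimate is undefined (saturation, empty alignment, or Ks = 0 —
    the latter reported as NA rather than infinity).
    """

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: Optional[float]
    Ka: Optional[float]
    ratio: Optional[float]
    status: str
    n_ungapped: int = 0


def kaks(aln: CodonAlignment, code: GeneticCode = STANDARD_CODE) -> KaKsEstimate:
    """NG86 estimate over the ungapped columns of a cleaned alignment.

    Site totals S, N are the mean of the two rows' per-codon sums;
    Sd, Nd accumulate pathway-averaged differences.  Gapped columns
    contribute to neither sites nor differences.
    """
    pairs = aln.ungapped_pairs()
    if not pairs:
        return KaKsEstimate(0, 0, 0, 0, 0, 0, None, None, None, STATUS_EMPTY, 0)
    s_a = s_b = 0.0
    sd = nd = 0.0
    for ca, cb in pairs:
        s_a += synonymous_sites(ca, code).s
        s_b += synonymous_sites(cb, code).s
        d = pathway_diffs(ca, cb, code)
        sd += d[0]
        nd += d[1]
    n_cols = len(pairs)
    S = (s_a + s_b) / 2.0
    N = 3.0 * n_cols - S
    pS = sd / S if S > 0 else 0.0
    pN = nd / N if N > 0 else 0.0
    Ks = jukes_cantor(pS)
    Ka = jukes_cantor(pN)
    if Ks is None:
        return KaKsEstimate(S, N, sd, nd, pS, pN, None, Ka, None, STATUS_SATURATED_S, n_cols)
    if Ka is None:
        return KaKsEstimate(S, N, sd, nd, pS, pN, Ks, None, None, STATUS_SATURATED_N, n_cols)
    if Ks == 0.0:
        # ratio undefined whether or not Ka > 0; reported as NA
        return KaKsEstimate(S, N, sd, nd, pS, pN, Ks, Ka, None, STATUS_KS_ZERO, n_cols)
    return KaKsEstimate(S, N, sd, nd, pS, pN, Ks, Ka, Ka / Ks, STATUS_OK, n_cols)


SELECTION_POSITIVE = "positive"
SELECTION_PURIFYING = "purifying"
SELECTION_NEUTRAL = "neutral"
SELECTION_UNDETERMINED = "undetermined"


def classify_selection(est: KaKsEstimate) -> str:
    """Ka/Ks > 1 positive, < 1 purifying, = 1 neutral; undefined ratios
    are undetermined."""
    if est.status != STATUS_OK or est.ratio is None:
        return SELECTION_UNDETERMINED
    if est.ratio > 1.0:
        return SELECTION_POSITIVE
    if est.ratio < 1.0:
        return SELECTION_PURIFYING
    return SELECTION_NEUTRAL
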