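"""Synthetic-data generators with known ground truth.

Three generative twins of the pipeline's inputs: coding-sequence pairs
diverged from a common ancestor under a chosen dN/dS ratio omega (an
accept/reject point-substitution process with acceptance probabilities
calibrated so the realized dN/dS over the estimator's site counts
equals omega; divergence split equally between lineages);
expression tables whose log(Ka/Ks) is a linear function of the
decoupling covariates plus Gaussian noise; and pileups with planted
SNPs of known depth and minor-allele frequency.

Every generator is bit-reproducible for a fixed seed and returns a
truth record alongside its data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core_formats import NucleotideSequence, STANDARD_CODE, translate_cds
from .snp import (DEFAULT_TIERS, FLANK_BP, MAX_HOMOPOLYMER, PileupColumn,
                  TierThresholds, max_homopolymer_run)

SENSE_CODONS = STANDARD_CODE.sense_codons


def simulate_cds(n_codons: int, seed: int) -> NucleotideSequence:
    """A stop-free CDS: ATG followed by uniform random sense codons."""
    if n_codons < 2:
        raise ValueError("need at least 2 codons")
    rng = np.random.default_rng(seed)
    codons = ["ATG"] + [SENSE_CODONS[i]
                        for i in rng.integers(0, len(SENSE_CODONS), size=n_codons - 1)]
    return NucleotideSequence(f"cds_n{n_codons}_s{seed}", "".join(codons))


@dataclass(frozen=True)
class EvolutionTruth:
    """Realized substitution record for one simulated pair."""

    omega: float
    divergence: float
    seed: int
    n_synonymous: int
    n_nonsynonymous: int


def _stop_mutability(bases: str) -> float:
    """Fraction of the sequence's nonsynonymous single-nucleotide
    changes that do not create a stop codon.

    The selection estimator counts changes-to-stop as nonsynonymous
    sites, but the substitution process structurally forbids them; a
    generator that simply rejects them realises a dN/dS below the
    target.  Scaling the synonymous acceptance by this factor
    calibrates the process so omega = 1 is exactly neutral over the
    estimator's site counts.
    """
    code = STANDARD_CODE
    n_nonsyn = n_nonsyn_mutable = 0
    for start in range(0, len(bases), 3):
        codon = bases[start:start + 3]
        aa = code.translate_codon(codon)
        for pos in range(3):
            for alt in "ACGT":
                if alt == codon[pos]:
                    continue
                mutant = codon[:pos] + alt + codon[pos + 1:]
                if code.translate_codon(mutant) == aa:
                    continue
                n_nonsyn += 1
                if not code.is_stop(mutant):
                    n_nonsyn_mutable += 1
    return n_nonsyn_mutable / n_nonsyn if n_nonsyn else 1.0


def _evolve_lineage(bases: str, n_proposals: int, omega: float, phi: float,
                    rng: np.random.Generator) -> tuple[str, int, int]:
    seq = list(bases)
    n_syn = n_nonsyn = 0
    code = STANDARD_CODE
    if omega <= 1.0:
        p_syn, p_nonsyn = phi, omega
    else:
        p_syn, p_nonsyn = phi / omega, 1.0
    for _ in range(n_proposals):
        site = int(rng.integers(0, len(seq)))
        old = seq[site]
        new = "ACGT".replace(old, "")[int(rng.integers(0, 3))]
        codon_start = site - site % 3
        old_codon = "".join(seq[codon_start:codon_start + 3])
        new_codon = old_codon[:site % 3] + new + old_codon[site % 3 + 1:]
        if code.is_stop(new_codon):
            continue
        synonymous = code.translate_codon(old_codon) == code.translate_codon(new_codon)
        if rng.random() >= (p_syn if synonymous else p_nonsyn):
            continue
        seq[site] = new
        if synonymous:
            n_syn += 1
        else:
            n_nonsyn += 1
    return "".join(seq), n_syn, n_nonsyn


def evolve_pair(ancestor: NucleotideSequence, omega: float, divergence: float,
                seed: int) -> tuple[NucleotideSequence, NucleotideSequence, EvolutionTruth]:
    """Evolve two descendants from `ancestor` at the given expected
    divergence (substitutions/site, split equally between lineages)
    under dN/dS ratio `omega`.

    Proposals creating a stop codon are rejected outright.  Acceptance
    probabilities are calibrated by the ancestor's stop-mutability
    factor so that the realized dN/dS over the estimator's site counts
    equals `omega` (see :func:`_stop_mutability`).
    """
    if omega < 0:
        raise ValueError("omega must be >= 0")
    if divergence < 0:
        raise ValueError("divergence must be >= 0")
    if len(ancestor) % 3:
        raise ValueError("ancestor length must be a codon multiple")
    rng = np.random.default_rng(seed)
    L = len(ancestor)
    phi = _stop_mutability(ancestor.bases)
    n_syn = n_nonsyn = 0
    descendants = []
    for i in (1, 2):
        n_prop = int(rng.poisson(divergence * L / 2.0))
        bases, s, n = _evolve_lineage(ancestor.bases, n_prop, omega, phi, rng)
        n_syn += s
        n_nonsyn += n
        descendants.append(NucleotideSequence(f"{ancestor.id}_d{i}", bases))
    truth = EvolutionTruth(omega=omega, divergence=divergence, seed=seed,
                           n_synonymous=n_syn, n_nonsynonymous=n_nonsyn)
    return descendants[0], descendants[1], truth


def simulate_homolog_set(n_pairs: int,
                         omega_spec: Union[float, Sequence[float]],
                         divergence: float,
                         seed: int,
                         n_codons: int = 300
                         ) -> tuple[list[NucleotideSequence], list[NucleotideSequence], pd.DataFrame]:
    """Independent ancestors evolved into two species files.

    Returns (species A records, species B records, truth table); the
    truth lists the intended pairing, the per-pair omega and the
    realized substitution counts.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    omegas = ([float(omega_spec)] * n_pairs if np.isscalar(omega_spec)
              else [float(w) for w in omega_spec])
    if len(omegas) != n_pairs:
        raise ValueError("omega_spec list length must equal n_pairs")
    rng = np.random.default_rng(seed)
    seqs_a, seqs_b, rows = [], [], []
    for i in range(n_pairs):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        ancestor = simulate_cds(n_codons, sub_seed)
        d1, d2, truth = evolve_pair(ancestor, omegas[i], divergence, sub_seed + 1)
        id_a, id_b = f"spA_{i + 1:04d}", f"spB_{i + 1:04d}"
        seqs_a.append(NucleotideSequence(id_a, d1.bases))
        seqs_b.append(NucleotideSequence(id_b, d2.bases))
        rows.append({"id_a": id_a, "id_b": id_b, "omega": omegas[i],
                     "n_synonymous": truth.n_synonymous,
                     "n_nonsynonymous": truth.n_nonsynonymous})
    return seqs_a, seqs_b, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Expression tables

#: Default true coefficients: the published decoupling-model estimates
#: for the congeneric comparison (morph-bias 0.230 etc.).
DEFAULT_COEFFICIENTS = {
    "intercept": -2.5,
    "overall_expression": -0.013,
    "alignment_length": -0.0008,
    "sequence_length": -0.0002,
    "n_tissues": 0.0192,
    "sex_bias": 0.201,
    "morph_bias": 0.230,
    "morph_x_sex": 0.0917,
}

#: Residual noise calibrated so the fitted model's adjusted r-squared
#: is near 0.105 under the default coefficients and covariate
#: distributions — the modest explained variance the decoupling model
#: shows on real data.
DEFAULT_NOISE_SD = 2.0


def simulate_expression_table(n_genes: int,
                              coefficients: Optional[dict[str, float]] = None,
                              noise_sd: float = DEFAULT_NOISE_SD,
                              seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene covariates with log(Ka/Ks) linear in them plus noise.

    Covariates: log-normal biases and overall expression, 1-11 tissues,
    uniform lengths 150-3000 nt.  Returns (records, truth); the
    records frame has the decoupling-stats input schema plus the
    observed `ratio` column, truth carries the noiseless linear
    predictor.
    """
    beta = dict(DEFAULT_COEFFICIENTS)
    if coefficients:
        unknown = set(coefficients) - set(beta)
        if unknown:
            raise ValueError(f"unknown coefficient names: {sorted(unknown)}")
        beta.update(coefficients)
    if n_genes <= len(beta) + 10:
        raise ValueError(f"n_genes must exceed {len(beta) + 10}")
    rng = np.random.default_rng(seed)
    overall = rng.lognormal(mean=2.0, sigma=0.7, size=n_genes)
    sex_bias = rng.lognormal(mean=0.0, sigma=0.5, size=n_genes)
    morph_bias = rng.lognormal(mean=0.0, sigma=0.5, size=n_genes)
    n_tissues = rng.integers(1, 12, size=n_genes)
    seq_len = rng.integers(150, 3001, size=n_genes)
    aln_len = np.minimum(seq_len, rng.integers(150, 3001, size=n_genes))
    log_sex, log_morph = np.log(sex_bias), np.log(morph_bias)
    lp = (beta["intercept"]
          + beta["overall_expression"] * np.log(overall)
          + beta["alignment_length"] * aln_len
          + beta["sequence_length"] * seq_len
          + beta["n_tissues"] * n_tissues
          + beta["sex_bias"] * log_sex
          + beta["morph_bias"] * log_morph
          + beta["morph_x_sex"] * log_morph * log_sex)
    log_ratio = lp + rng.normal(0.0, noise_sd, size=n_genes)
    records = pd.DataFrame({
        "gene_id": [f"gene_{i + 1:05d}" for i in range(n_genes)],
        "overall_expression": overall,
        "sex_bias": sex_bias,
        "morph_bias": morph_bias,
        "n_tissues": n_tissues,
        "sequence_length": seq_len,
        "alignment_length": aln_len,
        "ratio": np.exp(log_ratio),
        "horn_biased": False,
    })
    truth = pd.DataFrame({"gene_id": records["gene_id"],
                          "true_log_ratio": lp,
                          "noise_sd": noise_sd})
    return records, truth


# ---------------------------------------------------------------------------
# Pileups

@dataclass(frozen=True)
class PlantedSnp:
    position: int
    minor_base: str
    target_maf: float


def simulate_pileup(contig: NucleotideSequence,
                    planted: Sequence[PlantedSnp],
                    depth: int,
                    error_rate: float = 0.0,
                    seed: int = 0,
                    tiers: Sequence[TierThresholds] = DEFAULT_TIERS,
                    flank_bp: int = FLANK_BP,
                    max_homopolymer: int = MAX_HOMOPOLYMER
                    ) -> tuple[list[PileupColumn], pd.DataFrame]:
    """Per-position base counts with planted SNPs.

    At error_rate 0 the planted minor count is exactly
    round(depth * target_maf); otherwise it is binomial and uniform
    miscalls are sprinkled elsewhere.  The truth table records, for
    each plant, which tiers it should pass given the thresholds, the
    flanking rule and the reference homopolymer context (plants inside
    long runs are allowed, flagged `expected_excluded`).
    """
    positions = [p.position for p in planted]
    if len(set(positions)) != len(positions):
        raise ValueError("planted positions must be distinct")
    for p in planted:
        if not (1 <= p.position <= len(contig)):
            raise ValueError(f"planted position {p.position} outside contig")
        if p.minor_base == contig.bases[p.position - 1]:
            raise ValueError(f"planted minor base equals reference at {p.position}")
    rng = np.random.default_rng(seed)
    by_pos = {p.position: p for p in planted}
    columns: list[PileupColumn] = []
    truth_rows = []
    for pos in range(1, len(contig) + 1):
        ref = contig.bases[pos - 1]
        counts = {b: 0 for b in "ACGT"}
        plant = by_pos.get(pos)
        if ref not in counts:  # N in reference: no coverage
            columns.append(PileupColumn(contig.id, pos, 0, 0, 0, 0))
            continue
        if plant is not None:
            minor_n = (int(round(depth * plant.target_maf)) if error_rate == 0
                       else int(rng.binomial(depth, plant.target_maf)))
            counts[plant.minor_base] = minor_n
            counts[ref] = depth - minor_n
        else:
            counts[ref] = depth
            if error_rate > 0:
                n_err = int(rng.binomial(depth, error_rate))
                counts[ref] -= n_err
                for _ in range(n_err):
                    counts["ACGT".replace(ref, "")[int(rng.integers(0, 3))]] += 1
        columns.append(PileupColumn(contig.id, pos,
                                    counts["A"], counts["C"], counts["G"], counts["T"]))
        if plant is not None:
            maf = counts[plant.minor_base] / depth
            in_homopolymer = max_homopolymer_run(contig.bases, pos) > max_homopolymer
            flank_ok = pos - 1 >= flank_bp and len(contig) - pos >= flank_bp
            tiers_passed = [t.name for t in tiers
                            if depth > t.min_depth and maf > t.min_maf
                            and flank_ok and not in_homopolymer]
            truth_rows.append({
                "contig": contig.id, "position": pos,
                "minor_base": plant.minor_base, "target_maf": plant.target_maf,
                "realized_maf": maf, "depth": depth,
                "expected_excluded": in_homopolymer or not flank_ok,
                "expected_tiers": ",".join(tiers_passed),
            })
    return columns, pd.DataFrame(truth_rows)
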