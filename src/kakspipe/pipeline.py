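"""Orchestration: configuration, staged runners and the run manifest.

Each runner consumes a :class:`RunConfig`, executes its stages in
order, and writes a deterministic output directory plus a manifest
whose record counts reconcile (pairs in = pairs kept + pairs discarded
by reason).  Config files are flat key=value text, echoed verbatim
into the manifest for provenance.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import codon_align, decoupling, homology, ng86, snp
from .core_formats import read_fasta

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_INVALID_INPUT = 2
EXIT_EMPTY_RESULT = 3


class ConfigError(ValueError):
    """Invalid configuration or input (exit code 2)."""


class EmptyResultError(RuntimeError):
    """The run was valid but produced no records (exit code 3)."""


@dataclass
class RunConfig:
    """Inputs and thresholds for a pipeline run."""

    fasta_a: Optional[str] = None
    fasta_b: Optional[str] = None
    expression_table: Optional[str] = None
    pileup: Optional[str] = None
    contigs: Optional[str] = None
    hits_ab: Optional[str] = None
    hits_ba: Optional[str] = None
    evalue: float = 1e-5
    score: Optional[float] = None
    min_aln_bp: int = 150
    low_depth: int = 8
    low_maf: float = 0.15
    medium_depth: int = 12
    medium_maf: float = 0.20
    high_depth: int = 15
    high_maf: float = 0.25
    flank_bp: int = 50
    max_homopolymer: int = 2
    transform_profile: str = "log-biases"
    seed: int = 0
    out_dir: str = "kakspipe_out"

    _FLOAT_KEYS = {"evalue", "score", "low_maf", "medium_maf", "high_maf"}
    _INT_KEYS = {"min_aln_bp", "low_depth", "medium_depth", "high_depth",
                 "flank_bp", "max_homopolymer", "seed"}

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "RunConfig":
        """Parse a flat key=value config file; unknown keys are
        rejected."""
        known = {f.name for f in dc_fields(cls) if not f.name.startswith("_")}
        values: dict = {}
        with open(path) as handle:
            for lineno, raw in enumerate(handle, start=1):
                line = raw.split("#")[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ConfigError(f"line {lineno}: expected key=value, got {line!r}")
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key not in known:
                    raise ConfigError(f"line {lineno}: unknown config key {key!r}")
                if key in cls._INT_KEYS:
                    values[key] = int(value)
                elif key in cls._FLOAT_KEYS:
                    values[key] = float(value)
                else:
                    values[key] = value
        return cls(**values)

    def validate_paths(self, *keys: str) -> None:
        for key in keys:
            value = getattr(self, key)
            if value is None:
                raise ConfigError(f"config key {key!r} is required for this stage")
            if not Path(value).exists():
                raise ConfigError(f"{key}: path {value!r} does not exist")

    def tier_thresholds(self) -> tuple[snp.TierThresholds, ...]:
        return (snp.TierThresholds("low", self.low_depth, self.low_maf),
                snp.TierThresholds("medium", self.medium_depth, self.medium_maf),
                snp.TierThresholds("high", self.high_depth, self.high_maf))

    def search_threshold(self) -> homology.SearchThreshold:
        if self.score is not None:
            return homology.SearchThreshold(evalue=None, score=self.score)
        return homology.SearchThreshold(evalue=self.evalue)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)
                if not f.name.startswith("_")}


def _write_manifest(out_dir: Path, config: RunConfig, stage_counts: dict,
                    stage_seconds: dict) -> None:
    manifest = {
        "tool": "kakspipe 0.1.0",
        "config": config.as_dict(),
        "counts": stage_counts,
        "stage_seconds": {k: round(v, 3) for k, v in stage_seconds.items()},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def kaks_table(pairs, results, estimates) -> pd.DataFrame:
    """Assemble the Ka/Ks results table (one row per surviving pair)."""
    rows = []
    by_id = {r.pair_id: r for r in results}
    for pair in pairs:
        res = by_id.get(pair.pair_id)
        if res is None or res.alignment is None:
            continue
        est = estimates[pair.pair_id]
        rows.append({
            "pair_id": pair.pair_id, "id_a": pair.id_a, "id_b": pair.id_b,
            "aln_len_bp": res.alignment.aln_len_bp,
            "S": est.S, "N": est.N, "Sd": est.Sd, "Nd": est.Nd,
            "pS": est.pS, "pN": est.pN, "Ka": est.Ka, "Ks": est.Ks,
            "ratio": est.ratio, "status": est.status,
            "selection_class": ng86.classify_selection(est),
        })
    return pd.DataFrame(rows)


def run_kaks_pipeline(config: RunConfig) -> Path:
    """search -> RBH -> trim -> align -> thread -> clean -> filter ->
    NG86 -> classify.  Returns the output directory."""
    config.validate_paths("fasta_a", "fasta_b")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "alignments").mkdir(exist_ok=True)
    counts: dict = {}
    seconds: dict = {}

    t0 = time.perf_counter()
    seqs_a = read_fasta(config.fasta_a)
    seqs_b = read_fasta(config.fasta_b)
    if not seqs_a or not seqs_b:
        raise ConfigError("empty FASTA input")
    counts["sequences_a"] = len(seqs_a)
    counts["sequences_b"] = len(seqs_b)
    threshold = config.search_threshold()

    if config.hits_ab and config.hits_ba:
        hits_ab = homology.read_tabular_hits(config.hits_ab)
        hits_ba = homology.read_tabular_hits(config.hits_ba)
    else:
        matrix = homology.default_protein_scoring()
        hits_ab = homology.search_all(seqs_a, seqs_b, matrix, threshold)
        hits_ba = homology.search_all(seqs_b, seqs_a, matrix, threshold)
    counts["hits_ab"] = len(hits_ab)
    counts["hits_ba"] = len(hits_ba)
    seconds["search"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    pairs = homology.reciprocal_best_hits(hits_ab, hits_ba, threshold)
    pairs = homology.attach_sequences(pairs, seqs_a, seqs_b)
    counts["pairs_in"] = len(pairs)
    homology.write_tabular_hits([p.hit_ab for p in pairs], out_dir / "pairs.tsv")
    seconds["rbh"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    results = []
    discard_reasons: dict[str, int] = {}
    estimates = {}
    discard_log = []
    for pair in pairs:
        res = codon_align.build_codon_alignment(pair, min_bp=config.min_aln_bp)
        results.append(res)
        if res.alignment is None:
            discard_reasons[res.discard_reason] = discard_reasons.get(res.discard_reason, 0) + 1
            discard_log.append((pair.pair_id, pair.id_a, pair.id_b, res.discard_reason))
            continue
        codon_align.write_codon_alignment_fasta(
            res.alignment, pair.id_a, pair.id_b,
            out_dir / "alignments" / f"{pair.pair_id}.fasta")
        estimates[pair.pair_id] = ng86.kaks(res.alignment)
    counts["pairs_kept"] = len(estimates)
    counts["pairs_discarded_by_reason"] = discard_reasons
    with open(out_dir / "discards.tsv", "w") as handle:
        handle.write("pair_id\tid_a\tid_b\treason\n")
        for row in discard_log:
            handle.write("\t".join(row) + "\n")
    seconds["codon_alignment"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    table = kaks_table(pairs, results, estimates)
    table.to_csv(out_dir / "kaks.tsv", sep="\t", index=False, na_rep="NA")
    if len(table):
        status_counts = table["status"].value_counts().to_dict()
        class_counts = table["selection_class"].value_counts().to_dict()
    else:
        status_counts, class_counts = {}, {}
    counts["estimates_by_status"] = status_counts
    counts["estimates_by_selection_class"] = class_counts
    seconds["ng86"] = time.perf_counter() - t0

    _write_manifest(out_dir, config, counts, seconds)
    if not len(table):
        raise EmptyResultError("no homologue pair survived the filters")
    return out_dir


def run_snp_pipeline(config: RunConfig) -> Path:
    """Pileup + contigs -> tiered SNP calls, VCF and tier summary."""
    config.validate_paths("pileup", "contigs")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts: dict = {}
    seconds: dict = {}

    t0 = time.perf_counter()
    contigs = read_fasta(config.contigs)
    pileups = snp.read_pileup_tsv(config.pileup)
    tiers = config.tier_thresholds()
    try:
        calls = snp.call_snps(pileups, contigs, tiers,
                              flank_bp=config.flank_bp,
                              max_homopolymer=config.max_homopolymer)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    seconds["snp_calling"] = time.perf_counter() - t0

    snp.write_snp_tsv(calls, out_dir / "snps.tsv")
    snp.write_snp_vcf(calls, out_dir / "snps.vcf")
    summaries = snp.summarize_snps(calls, tiers)
    with open(out_dir / "tier_summary.tsv", "w") as handle:
        handle.write("tier\tn_snps\tn_contigs\tn_transversions\tn_transitions\n")
        for s in summaries:
            handle.write(f"{s.tier}\t{s.n_snps}\t{s.n_contigs}\t"
                         f"{s.n_transversions}\t{s.n_transitions}\n")
    counts["pileup_columns"] = len(pileups)
    counts["snps_by_tier"] = {s.tier: s.n_snps for s in summaries}
    _write_manifest(out_dir, config, counts, seconds)
    return out_dir


def run_decoupling_analysis(config: RunConfig, kaks_tsv: Union[str, Path]) -> Path:
    """Join Ka/Ks estimates with the expression table and produce the
    descriptive-statistics and GLM reports."""
    config.validate_paths("expression_table")
    if not Path(kaks_tsv).exists():
        raise ConfigError(f"Ka/Ks table {kaks_tsv!r} does not exist")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts: dict = {}
    seconds: dict = {}

    t0 = time.perf_counter()
    kaks_df = pd.read_csv(kaks_tsv, sep="\t", na_values=["NA"])
    expr = pd.read_csv(config.expression_table, sep="\t")
    joined = kaks_df.merge(expr, left_on="id_a", right_on="gene_id", how="inner")
    counts["kaks_rows"] = len(kaks_df)
    counts["expression_rows"] = len(expr)
    counts["joined_rows"] = len(joined)
    if len(joined) < 20:
        raise EmptyResultError(f"join produced only {len(joined)} rows (< 20)")
    if joined["ratio"].notna().sum() == 0:
        raise EmptyResultError("no defined Ka/Ks ratio in the joined table")

    horn_ids = set(expr.loc[expr.get("horn_biased", False) == True, "gene_id"])  # noqa: E712
    comparison = decoupling.stratified_kaks_compare(joined, horn_ids)
    with open(out_dir / "descriptives.tsv", "w") as handle:
        handle.write("stratum\tn\tmean\tsd\tmedian\tq1\tq3\tn_positive\tfrac_positive\n")
        groups = [comparison.background] + ([comparison.focal] if comparison.focal else [])
        for g in groups:
            handle.write(f"{g.label}\t{g.n}\t{g.mean:.6g}\t{g.sd:.6g}\t{g.median:.6g}\t"
                         f"{g.q1:.6g}\t{g.q3:.6g}\t{g.n_positive}\t{g.frac_positive:.4f}\n")
        if comparison.test is not None:
            handle.write(f"# Mann-Whitney W={comparison.test.w:.6g} "
                         f"p={comparison.test.p_two_sided:.4g} ({comparison.test.method})\n")

    glm_input = joined.rename(columns={"aln_len_bp": "alignment_length"})
    fit = decoupling.fit_decoupling_glm(glm_input, config.transform_profile)
    report = decoupling.glm_report(fit)
    report.to_csv(out_dir / "glm.tsv", sep="\t", index=False)
    counts["glm_n"] = fit.n
    counts["glm_residual_df"] = fit.residual_df
    counts["glm_excluded"] = fit.n_excluded
    seconds["decoupling"] = time.perf_counter() - t0
    _write_manifest(out_dir, config, counts, seconds)
    return out_dir
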