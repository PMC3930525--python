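"""Tiered SNP calling: thresholds, flanks, homopolymers, summaries."""

import pytest

from kakspipe.core_formats import NucleotideSequence
from kakspipe.snp import (
    DEFAULT_TIERS,
    PileupColumn,
    TierThresholds,
    call_snps,
    classify_substitution,
    max_homopolymer_run,
    pileup_from_sam,
    read_pileup_tsv,
    summarize_snps,
    write_pileup_tsv,
    write_snp_vcf,
)
from kakspipe.simulate import PlantedSnp, simulate_cds, simulate_pileup


def _contig(seed=1, n_codons=100, cid="ctg1"):
    return NucleotideSequence(cid, simulate_cds(n_codons, seed).bases)


def _col(contig_id, pos, ref, minor, minor_n, depth):
    counts = {b: 0 for b in "ACGT"}
    counts[ref] = depth - minor_n
    counts[minor] = counts.get(minor, 0) + minor_n
    return PileupColumn(contig_id, pos, counts["A"], counts["C"], counts["G"], counts["T"])


def _safe_pos(contig, pos=150):
    """A position away from homopolymers with both flanks >= 50."""
    for p in range(pos, len(contig) - 51):
        if max_homopolymer_run(contig.bases, p) <= 2:
            return p
    raise AssertionError("no safe position found")


class TestClassifySubstitution:
    @pytest.mark.parametrize("a,b,expected", [
        ("A", "G", "transition"),
        ("G", "A", "transition"),
        ("C", "T", "transition"),
        ("A", "C", "transversion"),
        ("G", "T", "transversion"),
    ])
    def test_classes(self, a, b, expected):
        assert classify_substitution(a, b) == expected

    def test_identical_bases_rejected(self):
        with pytest.raises(ValueError):
            classify_substitution("A", "A")


class TestCallSnps:
    def test_strict_inequality_at_tier_boundary(self):
        """depth 20, MAF exactly 0.20 passes low (> 0.15) but not
        medium (not > 0.20)."""
        contig = _contig()
        pos = _safe_pos(contig)
        ref = contig.bases[pos - 1]
        minor = "A" if ref != "A" else "C"
        calls = call_snps([_col("ctg1", pos, ref, minor, 4, 20)], [contig])
        assert len(calls) == 1
        assert calls[0].tiers == frozenset({"low"})

    def test_high_depth_high_maf_passes_all_tiers(self):
        contig = _contig()
        pos = _safe_pos(contig)
        ref = contig.bases[pos - 1]
        minor = "A" if ref != "A" else "C"
        calls = call_snps([_col("ctg1", pos, ref, minor, 12, 40)], [contig])
        assert calls[0].tiers == frozenset({"low", "medium", "high"})
        assert calls[0].maf == pytest.approx(0.3)

    def test_homopolymer_run_blocks_call(self):
        bases = "ACGT" * 30 + "AAA" + "CGTA" * 30
        contig = NucleotideSequence("ctg1", bases)
        pos = 122  # middle of the AAA run
        assert contig.bases[pos - 1] == "A"
        assert max_homopolymer_run(bases, pos) == 3
        calls = call_snps([_col("ctg1", pos, "A", "G", 12, 40)], [contig])
        assert calls == []

    def test_left_flank_shorter_than_50_blocks_call(self):
        contig = _contig()
        pos = 30
        ref = contig.bases[pos - 1]
        minor = "A" if ref != "A" else "C"
        calls = call_snps([_col("ctg1", pos, ref, minor, 12, 40)], [contig])
        assert calls == []

    def test_right_flank_boundary(self):
        contig = _contig(n_codons=100)  # 300 nt
        pos = len(contig) - 50  # exactly 50 bases to the right
        if max_homopolymer_run(contig.bases, pos) > 2:
            pytest.skip("fixture position falls in a homopolymer")
        ref = contig.bases[pos - 1]
        minor = "A" if ref != "A" else "C"
        calls = call_snps([_col("ctg1", pos, ref, minor, 12, 40)], [contig])
        assert len(calls) == 1

    def test_multiallelic_column_rejected(self):
        contig = _contig()
        pos = _safe_pos(contig)
        ref = contig.bases[pos - 1]
        others = [b for b in "ACGT" if b != ref]
        counts = {b: 0 for b in "ACGT"}
        counts[ref] = 26
        counts[others[0]] = 10
        counts[others[1]] = 4  # third allele well above noise
        col = PileupColumn("ctg1", pos, counts["A"], counts["C"], counts["G"], counts["T"])
        assert call_snps([col], [contig]) == []

    def test_unknown_contig_is_input_error(self):
        with pytest.raises(ValueError, match="unknown contig"):
            call_snps([_col("nope", 10, "A", "C", 5, 20)], [_contig()])

    def test_tier_nesting(self):
        """Every high call is also medium and low."""
        contig = _contig(seed=3, n_codons=200)
        plants = [PlantedSnp(_safe_pos(contig, p), "T" if contig.bases[_safe_pos(contig, p) - 1] != "T" else "G", maf)
                  for p, maf in ((100, 0.18), (200, 0.22), (300, 0.35))]
        cols, _ = simulate_pileup(contig, plants, depth=40, seed=1)
        calls = call_snps(cols, [contig])
        for call in calls:
            if "high" in call.tiers:
                assert {"medium", "low"} <= call.tiers
            if "medium" in call.tiers:
                assert "low" in call.tiers

    def test_threshold_monotonicity(self):
        """Raising any threshold never increases the call count."""
        contig = _contig(seed=4, n_codons=200)
        plants = [PlantedSnp(_safe_pos(contig, p), "T" if contig.bases[_safe_pos(contig, p) - 1] != "T" else "G", maf)
                  for p, maf in ((100, 0.17), (250, 0.28), (400, 0.40))]
        cols, _ = simulate_pileup(contig, plants, depth=30, seed=2)
        base = [TierThresholds("low", 8, 0.15)]
        n_base = len(call_snps(cols, [contig], base))
        for depth, maf in ((12, 0.15), (8, 0.25), (20, 0.35)):
            n = len(call_snps(cols, [contig], [TierThresholds("low", depth, maf)]))
            assert n <= n_base


class TestPlantedTruthRecovery:
    def test_deterministic_pileup_calls_equal_truth(self):
        """With zero sequencing error, calls match planted truth
        exactly, tier by tier."""
        contig = _contig(seed=7, n_codons=150)
        plants = []
        for p, maf in ((80, 0.18), (160, 0.22), (240, 0.30), (320, 0.45)):
            pos = _safe_pos(contig, p)
            if any(pl.position == pos for pl in plants):
                continue
            ref = contig.bases[pos - 1]
            plants.append(PlantedSnp(pos, "T" if ref != "T" else "G", maf))
        cols, truth = simulate_pileup(contig, plants, depth=40, error_rate=0.0, seed=3)
        calls = call_snps(cols, [contig])
        called = {c.position: c for c in calls}
        for row in truth.itertuples():
            expected = set(row.expected_tiers.split(",")) - {""}
            if expected:
                assert row.position in called
                assert set(called[row.position].tiers) == expected
            else:
                assert row.position not in called
        assert set(called) <= set(truth["position"])

    def test_planted_inside_homopolymer_is_excluded(self):
        bases = "ACGT" * 40 + "AAAA" + "CGTA" * 40
        contig = NucleotideSequence("ctg1", bases)
        pos = 162
        assert contig.bases[pos - 1] == "A"
        cols, truth = simulate_pileup(contig, [PlantedSnp(pos, "G", 0.3)],
                                      depth=40, seed=4)
        assert truth.iloc[0]["expected_excluded"]
        assert call_snps(cols, [contig]) == []


class TestSummaries:
    def test_empty_calls_give_zero_rows(self):
        for row in summarize_snps([]):
            assert row.n_snps == row.n_contigs == 0
            assert row.n_transitions == row.n_transversions == 0

    def test_counts_on_planted_fixture(self):
        """3 planted passing SNPs on 2 contigs -> (3, 2) with
        Ts + Tv = 3."""
        c1 = _contig(seed=8, n_codons=120, cid="c1")
        c2 = _contig(seed=9, n_codons=120, cid="c2")
        def plant(contig, approx):
            pos = _safe_pos(contig, approx)
            ref = contig.bases[pos - 1]
            return PlantedSnp(pos, "T" if ref != "T" else "G", 0.3)
        cols1, _ = simulate_pileup(c1, [plant(c1, 100), plant(c1, 200)], depth=40, seed=5)
        cols2, _ = simulate_pileup(c2, [plant(c2, 150)], depth=40, seed=6)
        calls = call_snps(cols1 + cols2, [c1, c2])
        low = next(s for s in summarize_snps(calls) if s.tier == "low")
        assert (low.n_snps, low.n_contigs) == (3, 2)
        assert low.n_transitions + low.n_transversions == 3

    def test_ts_tv_identity_on_every_tier(self):
        contig = _contig(seed=10, n_codons=200)
        plants = [PlantedSnp(_safe_pos(contig, p), "T" if contig.bases[_safe_pos(contig, p) - 1] != "T" else "G", m)
                  for p, m in ((100, 0.2), (200, 0.3), (350, 0.4))]
        cols, _ = simulate_pileup(contig, plants, depth=40, seed=7)
        for row in summarize_snps(call_snps(cols, [contig])):
            assert row.n_transitions + row.n_transversions == row.n_snps


class TestIO:
    def test_pileup_tsv_roundtrip(self, tmp_path):
        cols = [PileupColumn("c1", 1, 10, 0, 0, 0), PileupColumn("c1", 2, 0, 5, 5, 0)]
        path = tmp_path / "pileup.tsv"
        write_pileup_tsv(cols, path)
        assert read_pileup_tsv(path) == cols

    def test_vcf_has_required_columns(self, tmp_path):
        contig = _contig()
        pos = _safe_pos(contig)
        ref = contig.bases[pos - 1]
        minor = "A" if ref != "A" else "C"
        calls = call_snps([_col("ctg1", pos, ref, minor, 12, 40)], [contig])
        path = tmp_path / "out.vcf"
        write_snp_vcf(calls, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "##fileformat=VCFv4.2"
        data = [l for l in lines if not l.startswith("#")]
        assert len(data) == 1
        fields = data[0].split("\t")
        assert fields[0] == "ctg1" and int(fields[1]) == pos
        assert fields[3] == ref and fields[4] == minor
        assert "DP=40" in fields[7]

    def test_sam_reduction_counts_matches(self, tmp_path):
        contig = NucleotideSequence("c1", "ACGTACGTACGT")
        sam = tmp_path / "reads.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:unsorted\n"
            "@SQ\tSN:c1\tLN:12\n"
            "r1\t0\tc1\t1\t60\t4M\t*\t0\t0\tACGT\t*\n"
            "r2\t0\tc1\t1\t60\t4M\t*\t0\t0\tACTT\t*\n")
        cols = pileup_from_sam(sam, [contig])
        by_pos = {c.position: c for c in cols}
        assert by_pos[1].count_a == 2
        assert by_pos[3].count_g == 1 and by_pos[3].count_t == 1
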