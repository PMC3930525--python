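# Methods

This note documents the models and procedures kakspipe implements, the
defaults and why they were chosen, what the synthetic-data generators
do and do not emulate, and the numerical corner cases.

## Translated homology search and RBH pairing

The search is a desk-scale stand-in for a translated BLAST step: every
query/subject pair is scored over all 36 combinations of the six query
and six subject reading frames with Smith–Waterman local alignment in
protein space, and only the single best HSP per pair is retained (the
downstream trim uses one overlapping region per pair). Residue
coordinates are mapped back to 1-based nucleotide coordinates on the
original, unreversed sequences; minus-strand hits carry a negative
frame.

**Scoring.** BLOSUM62 with affine gaps; a gap of length k costs
11 + k (open 11, extend 1, the BLAST convention — the open penalty is
charged together with the first extension). Two residue classes get
special treatment:

- `X` (untranslatable codon, e.g. containing N) scores 0 against
  everything: no evidence either way.
- `*` (stop) scores −100 against everything, i.e. it is effectively
  alignment-blocking. A mild stop penalty lets long high-identity
  flanks absorb the cost of crossing several stop columns, and an
  off-frame self-hit can then outscore the true-frame hit (observed:
  frame 2/2 self-alignment of a random 100-codon CDS scored 517
  across four stops versus 507 for frame 1/1). Because the trim stage
  inherits the hit's frame, hits must stay within one open reading
  frame; blocking stops guarantees that for any realistic coding
  sequence.

**E-values** use the Karlin–Altschul form E = K·m·n·e^(−λS) with the
gapped-BLOSUM62 constants K = 0.041, λ = 0.267, where m and n are the
query and subject translation lengths summed over the six frames.
This is an explicit approximation (no composition-based adjustment,
no sum statistics); a raw-score threshold can be used instead. The
default reporting threshold is E ≤ 1e−5.

**RBH matching.** A pair (a, b) is emitted iff b is a's single best
subject and a is b's single best subject, both passing the threshold.
An exact raw-score tie between distinct subjects makes the query
ambiguous: it is left unpaired and a warning logged. This is a
documented choice — tie handling is not prescribed by the procedure
the pipeline emulates — and it is conservative: ties at desk scale
almost always mean duplicated or chimeric input.

## Codon alignment

Each side of a pair is cut to the hit's overlapping region and
re-oriented to the hit frame's strand; the start is then advanced and
the end receded to the frame's codon grid (never extended — trimming
must not fabricate aligned sequence). Fragments shorter than one
codon discard the pair with reason code `region_too_short`.

The two in-frame fragments are translated and globally aligned
(Needleman–Wunsch, same scoring), and codons are threaded back
through the protein alignment: residue columns become their source
codons, gap residues become `---`. Pairwise global alignment replaces
a multiple-aligner step because only two sequences are ever aligned
per pair; externally aligned protein FASTA is accepted for exact
replication attempts.

Cleaning removes every column in which either row holds a stop codon
(TAA/TAG/TGA) or a codon containing a non-ACGT character. "Nonsense
codon" is read broadly as any codon not translatable to one of the 20
amino acids; each removed column is logged. The minimum-length filter
keeps an alignment iff it has at least 150 bp = 50 codons of
comparable sequence, counting only columns where neither row is
gapped — gap columns carry no distance information, so counting them
would let uninformative alignments pass.

## The NG86 estimator

For each sense codon, each of the three positions contributes
(synonymous single-nucleotide changes at that position)/3 to the
synonymous site count s; changes producing a stop codon count as
nonsynonymous, so s + n = 3 exactly. Between two codons differing at
k positions, the k! orderings of single changes are enumerated;
orderings passing through a stop codon are excluded (if every
ordering is blocked, all are included as a fallback), and the
synonymous/nonsynonymous step classifications are averaged, giving
sd + nd = k exactly. Site totals S, N are the mean of the two rows'
per-codon sums over ungapped columns; gapped columns contribute
neither sites nor differences.

Proportions pS = Sd/S and pN = Nd/N are corrected with Jukes–Cantor;
p ≥ 3/4 is reported as saturation (`saturated_s` / `saturated_n`)
rather than an exception. Ks = 0 with any Ka makes the ratio
undefined and is reported as NA (`ks_zero`), not infinity — matching
how such cells appear in published tables. Ka = 0 with Ks > 0 gives
ratio 0 (purifying). Classification: ω > 1 positive, ω < 1 purifying,
ω = 1 neutral, anything undefined undetermined.

The per-codon site table and the 61×61 pathway table are verified in
the test suite against an independent oracle that enumerates
permutations literally.

## SNP tiers

Input is a per-position base-count pileup (TSV: contig, 1-based pos,
countA..countT; a SAM reducer that counts aligned match/mismatch
bases is provided). A column yields a call iff:

1. it has exactly one credible minor allele — columns whose
   third-most-frequent base exceeds max(1, 1% of depth) are rejected
   as multi-allelic/noisy (configurable);
2. depth and minor-allele frequency *strictly* exceed at least one
   tier's thresholds — defaults low (8, 15%), medium (12, 20%),
   high (15, 25%). The sources for the high tier disagree (>16, >15
   and >12 appear in different places); the procedural-methods value
   15 is the default and all six numbers are configurable;
3. at least 50 bp of contig sequence flank the position on each side
   (measured from the contig ends);
4. the maximal mononucleotide run containing the position in the
   contig reference is ≤ 2 — homopolymer runs are the dominant
   454-sequencing error mode and the rule is evaluated on the
   reference context, where the error arises.

Each call carries every tier it passes, so tiers are nested by
construction. A↔G and C↔T are transitions, all other pairs
transversions; within each tier transitions + transversions = total
calls, asserted on every summary. MAF is computed over the full
column depth (whether the original mapper-based counts used full
depth is unstated; this choice is recorded here).

## Decoupling statistics

**Mann–Whitney.** W is reported as the first-sample U statistic — the
number of (xᵢ, yⱼ) pairs with xᵢ > yⱼ, ties counting ½ — the
convention of the statistical environment in which such W values are
commonly printed (e.g. W = 2102 for group sizes 11 vs 238 lies in
[0, 2618] = [0, n₁n₂]). The p-value is exact by full enumeration when
n₁·n₂ ≤ 400 and there are no ties; otherwise a normal approximation
with midranks, tie-corrected variance and continuity correction.

**The GLM.** Ordinary least squares of log(Ka/Ks) on
log(overall expression), alignment length, sequence length, number of
tissues, log(sex bias), log(morph bias) and the product of the two
log-biases, plus intercept — 8 parameters, residual df = n − 8. Two
transform profiles are first-class because the source descriptions
conflict: the default (`log-biases`) logs only ratio, overall
expression and the two biases; `log-lengths` additionally logs
sequence and alignment length. Per-term partial r² = t²/(t² + residual df),
which equals the relative SSE drop when exactly that term is removed
(verified against a refit oracle). Rows whose ratio is 0 cannot be
log-transformed and are excluded and counted by default; an optional
floor mode substitutes half the smallest positive ratio. Exact
collinearity raises a singular-fit error naming the offending terms.

## Synthetic-data generators

All generators are bit-reproducible given a seed and return a truth
record with their data.

**CDS evolution.** An ancestor (ATG + uniform sense codons) is
evolved along two lineages, each receiving
Poisson(divergence·L/2) proposed point mutations at uniform sites and
alternative bases; divergence is split equally because branch
asymmetry of a species pair is unknowable and symmetry is the neutral
default. Proposals creating stops are rejected. Acceptance
probabilities encode the target dN/dS ω with a stop-mutability
calibration: the estimator counts changes-to-stop as nonsynonymous
sites, but the process forbids them, so a naive "accept synonymous
always, nonsynonymous with probability ω" realizes only ≈ 0.95ω over
the estimator's site counts. Synonymous acceptance is therefore
scaled by φ = (non-stop nonsynonymous single-nt changes)/(all
nonsynonymous single-nt changes), computed on the ancestor, making
ω = 1 exactly neutral over NG86 sites. This is a simple accept/reject
point process, not a continuous-time codon model: no
transition/transversion bias, no codon-frequency structure, no
indels. Passing ω-recovery tests therefore show the estimator is
calibrated under its own site-counting assumptions, not that it is
robust to the mutational biases of real 454 transcriptomes.

When recovery is summarized over replicates, the pooled ratio
mean(Ka)/mean(Ks) is used rather than the mean of per-pair ratios:
with ~40 synonymous substitutions per pair, E[Ka/Ks] ≈ 1.02ω from
Var(Ks) alone, and the mean-of-ratios comparison would fail a 2-SE
check on roughly half of seed sets for reasons unrelated to
estimator quality. The pooled ratio is consistent for a shared ω;
its standard error is taken by jackknife.

**Expression tables.** Covariates are log-normal (biases σ = 0.5,
overall expression σ = 0.7), uniform-integer tissues 1–11 and uniform
lengths 150–3000 nt; true log(Ka/Ks) is the linear predictor under
the supplied coefficients plus Gaussian noise. Default coefficients
are the published congeneric-comparison estimates and the default
noise (σ = 2.0) is calibrated once so the fitted model's adjusted r²
is near 0.105 — the modest explained variance such models show on
real data. Real covariate distributions are only available by
download, so these are documented defaults, all overridable.

**Pileups.** Every position receives `depth` observations; planted
positions get exactly round(depth·MAF) minor reads at error rate 0
(binomial otherwise, with uniform miscalls sprinkled elsewhere).
Truth records which tiers each plant should pass given the thresholds
and the contig's flank/homopolymer context; plants inside homopolymer
runs are allowed and flagged, to exercise the exclusion rule.

## Orchestration

Config files are flat key=value text with unknown keys rejected;
every run echoes its config into `manifest.json` along with per-stage
record counts that must reconcile (pairs in = kept + Σ discarded by
reason) and wall-clock per stage. Reruns with the same config and
seed are byte-identical apart from the manifest timings. Exit codes:
0 success, 2 invalid input/config, 3 valid-but-empty result.

## Known limitations

- The search has no composition-adjusted statistics and no multi-HSP
  chaining; E-values are approximate and meant for thresholding, not
  reporting.
- NG86 only: no transition/transversion weighting, no
  maximum-likelihood estimators, no codon-frequency corrections.
  Published per-pair values computed with other NG86 implementations
  may differ in the 2nd–3rd decimal if their stop-pathway convention
  differs; that convention is not documented for the tool the
  original analysis used.
- SNP calling has no genotype likelihoods and ignores indels; the
  flanking rule measures from contig ends, not assembly gaps.
- The GLM assumes independent observations; no phylogenetic or
  mixed-model correction, and no quadratic terms (they are reported
  not to improve such fits).
- No multiple-testing control across genes, matching the procedure
  the pipeline reproduces.
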