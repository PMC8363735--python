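# Methods

This note documents the models, parameter choices and numerical
decisions behind each stage, what the synthetic scenario does and does
not emulate, and the known limitations.

## Synthetic scenario

One `ScenarioConfig` determines every input. Replicate numbers follow
the study design the package targets: 3/group for count assays, 4/group
for metabolites, 5/group for bisulfite amplicons, 2/group for ribosome
profiling.

**tRNA reference.** 162 isodecoders on a 76-nt cloverleaf-length
scaffold (random bases, anticodon at positions 34–36; some isodecoders
pad the variable loop to 82/88 nt, inserted after position 60 so
annotated coordinates stay canonical). Ten isodecoders are glycine
family (4 GCC, 3 CCC, 3 TCC) and carry four Nsun2-regulated cytosines
(C39, C46–C48) plus the Dnmt2 site C37; Asp-GTC carries Dnmt2 C38;
every other family carries at most three Nsun2 sites (C46–C48).
Canonical labels come only from the annotation table, never inferred
from sequence numbering. Real tRNA secondary structure is irrelevant to
every statistic tested and is not modelled.

**Bisulfite reads.** Each read is a full-length amplicon copy; annotated
cytosines retain C with their site's methylation probability, other
cytosines convert to T with efficiency 0.99 (configurable — incomplete
conversion appears as background methylation; the assay's conversion
control gives no published number, so 0.99 represents a well-behaved
library). Baselines: C46–C48 0.90, C39 0.15 (a moderately methylated
site in the 10–20% band), C37/C38 0.90. Knockout: Nsun2 sites at
0.05–0.08 residual; Dnmt2 sites unchanged. The knockout residual is not
published per site; these values realize a >50% *relative* deficit at
every Nsun2 site, which is the only reading under which C39 (15%
baseline) can satisfy the >50% deficit pattern — in percentage points
its drop is ~10.

**Counts.** Per-isodecoder baseline means are log-normal (median 300,
σ=1, so the CPM ≥ 20 filter is almost always passed); counts are
negative binomial with common dispersion φ = 0.1 (var = μ(1+φμ)).
Knockout fold changes: 0.4 on seven Gly isodecoders (all GCC, two CCC,
one TCC), 0.85 on the remaining three, 0.5 on two non-Gly isodecoders,
1.8 on Asn-GTT-1 and Met-CAT-1. Note a power consequence of φ = 0.1 at
n = 3: the sampling sd of a log₂ fold-change estimate is ≈ 0.37, so a
2.5× depletion is detected at raw p < 0.05 with ~0.92 probability but at
BKY q < 0.05 over 162 features with only ~0.5–0.6 — the significant-call
count among the seven strong depletions is typically 3–6, and one of the
three weak (0.85×) isodecoders flips to a positive logFC estimate in a
sizeable fraction of cohorts. This matches what edgeR's exact test
produces on the same matrices; it is a property of the stated
conditions, not of the test implementation.

**Fragments.** Each isodecoder emits ~3 fragment species with end
(5′/3′) and lengths uniform within the class windows; Gly 5′ fragments
are depleted 0.4× in KO. Window rules: 3′ 17–22 nt → tRF-3; 5′ 33–35 →
tiRNA; 5′ 28–32 → tRF-5c (a subclass counted inside tRF-5); 5′ 14–32 →
tRF-5. A fragment with CPM 0 in any sample is excluded from family
tests.

**CDS set and ribosomes.** 300 random CDSs (100–300 codons, ATG…TAA, no
internal stops) with gene-level glycine codon fraction ~N(0.065, 0.03)
clipped to [0.005, 0.2]; glycine codon usage is GGA-biased
(0.40/0.30/0.15/0.15 over GGA/GGC/GGG/GGT). Transcripts get fixed 30-nt
UTRs. Footprints are placed with per-codon rate ∝ transcript abundance ×
A-site stall multiplier (GGA ×3 in KO only), an 8× initiation
enrichment at the first coding A-site (which creates the metagene peak
offset inference needs, and is excluded from dwell time anyway), read
lengths 27–31 nt with fixed true offsets {27:11, 28:12, 29:12, 30:13,
31:13}, all inside the standard 10–15 window.

**Omics tables.** RNA log₂FC ~ N(0, 0.3); protein log₂FC = RNA log₂FC +
slope × (gene glycine codon fraction − cohort mean) + N(0, 0.25) with
slope −4 per unit fraction; per-sample measurement noise 0.1 (log₂).
Metabolites: 19 amino acids (no cysteine — unquantifiable by the assay),
log-normal areas with CV 0.15, glycine KO mean 2.46× WT, heavy-standard
areas constant per amino acid ± CV 0.05, tissue weights U(10, 20) mg.
With n = 4/group the single-cohort glycine fold-change estimate carries
≈ 11% relative sampling error (sd of a difference of two 4-sample
log-means at CV 0.15), so any single cohort can land outside ±10% of
2.46; cohort-averaged estimates converge to the injected value.

**Proteome table.** A discrete stratum truth at published scale: 5820
proteins, 635 decreased (−0.8 log₂), 853 increased (+0.8), noise sd
0.25, n = 5/group; glycine content ~N(6.63, 2.2)% with +0.53 pp on the
decreased and −0.2 pp on the increased stratum.

**What the generator does not emulate:** sequencing error and quality
profiles, adapter contamination, PCR bias beyond the UMI toy model,
multi-mapping ambiguity between near-identical isodecoders,
mitochondrial tRNAs, batch structure, and missing values in proteomics.
Tests passing on this scenario therefore demonstrate correct statistics
and end-to-end plumbing under the stated effect/noise model — not
robustness to real-library artefacts.

## Statistical machinery

**Mann–Whitney.** U = min(U₁, U₂); at n₁+n₂ ≤ 20 with no ties the U
distribution is built by the Gaussian-binomial recursion and the
two-sided p doubles the smaller tail (capped at 1). Ties or larger
samples fall back to the normal approximation with tie correction and
continuity correction, flagged in the result's `method`.

**BKY two-stage FDR.** Stage 1 runs the linear step-up at q/(1+q) and
estimates m₀ = max(m − r₁, 1); stage 2 re-runs the step-up with m₀ in
the numerator. Adjusted values are the monotone step-up of p·m₀/rank,
comparable to q directly; a single p-value is returned unchanged and the
procedure never exceeds plain BH. The variant that additionally inflates
stage 2 by (1+q) is not applied — the difference is a ≤5% relative
threshold shift, on the conservative side.

**Grubbs.** G = max|xᵢ−x̄|/s against the t-based critical value
((n−1)/√n)·√(t²/(n−2+t²)) at two-sided α; the p-value inverts G to a t
quantile with the 2n Bonferroni factor. Constant samples are a
degenerate-input error.

**NB exact test.** Conditional on the feature total with common
dispersion φ (counts first scaled to the geometric-mean library size and
rounded); weights computed in log-gamma space; two-sided p = doubled
smaller tail. φ = 0 switches to the exact binomial conditional. The
default φ is a method-of-moments median across retained features —
common rather than tagwise, since the scenario generates a shared
dispersion.

**MI + permutation.** Equal-frequency binning (default 5 bins) keeps MI
invariant to monotone transforms and robust to heavy tails; the
permutation p uses the (1 + #{null ≥ obs})/(1 + N) correction so it is
never zero. Per-bin hypergeometric tests report the smaller of the
enrichment/depletion tails with its Bonferroni factor over bins.

**Loess.** Hand-written tricube local-linear smoother over the
ceil(span·n) nearest neighbours with two bisquare robustness passes
(zero weight beyond six MADs). The robustness passes matter: they keep
an isolated stall spike from inflating its own prediction, which is what
the excess-capping correction relies on. Fitted values are floored at
1e-6 so excess ratios stay finite.

## Stage-specific choices

**Bisulfite alignment.** Reads and references are compared in
three-letter space (C→T both sides) so conversion status cannot bias
placement; ungapped scan over all offsets of every reference; a hit is
kept if mismatches ≤ 2 and it beats the runner-up by ≥ 2 mismatches
(both CLI-configurable; sensible for 60–100-nt amplicons). Reverse
complements and reads < 40 nt are rejected. Sites with coverage < 100
reads are masked. Methylation deltas are reported in percentage points,
100×(WT−KO); the relative deficit 100×(WT−KO)/WT is derived from the
same means where the baseline varies across sites.

**UMI dedup.** The two 4-nt UMIs sit immediately 3′ of the
GATC-terminated 5′-linker prefix and immediately 3′ of GTATCCAGT in the
3′ linker; molecules are distinct (insert, UMI-pair) combinations.
Reads missing either pattern are dropped and counted.

**Differential expression.** Retention: mean CPM ≥ 20 in at least one
group. Fold change on CPM + 0.5 pseudo-counted group means; calls need
BKY q < 0.05 and |FC| ≥ 1.5. Multi-mapping correction (fractional 1/k
assignment) applies when alignment multiplicity is known; the synthetic
counts are already unique-feature.

**Ribosome stage.** Offsets: per read length, argmax of the
cds_start − 5′-end histogram inside 10–15 nt, accepted only when the
peak at least doubles the runner-up slot; otherwise the global default
12 with a low-confidence flag (also used below 500 footprints per
length class). A-site = P-site + 3 nt. Codon index = floor(nt/3) on
0-based half-open CDS coordinates. Excess capping: observed/loess > 5
is capped to 5× the prediction on transcripts with ≥ 50 codons and
≥ 100 counts (smaller transcripts pass through flagged). Dwell time
excludes the first/last 5 codons (initiation/termination bias), pools
replicates within group, normalizes per transcript to the interior mean,
and takes a 5% trimmed mean per codon; codons with < 20 instances are
masked. Per-codon significance is a Mann–Whitney across per-transcript
mean densities — a deliberately simple substitute for unpublished
dwell-time inference internals, so its p-values are comparative, not a
reproduction target.

**Proteome.** Welch t-test + BKY at q < 0.05 replaces the
permutation-based FDR t-test of the original desktop software (whose s0
procedure is not published); the threshold matches the reported
significant-protein counts' caption. Proteins missing a full group are
reported `ns` and flagged rather than imputed.

**Metabolomics.** Normalization factor per sample = mean over amino
acids of heavy/pooled-heavy; then division by tissue weight relative to
the first sample. Calibration searches contiguous ladder subsets of ≥ 5
points and keeps the best r² with positive slope (ties prefer more
points), which drops saturated or below-range ladder ends; the default
ladder matches the 1.10–41.66 pmol range. Genotype tests are Welch
(no common-SD assumption) with BKY at the q = 1% stage parameter; the
19-element fold-change vector is screened by Grubbs at α = 0.001. Fold
change is computed on group means of normalized levels.

**Pipeline.** Stages communicate only through files in write-once
per-stage directories; all randomness derives from the root seed by
CRC32 stage-name hashing, so results are independent of stage order;
the manifest holds SHA-256 digests of every output.

## Problem sizes

Defaults were chosen so a full pipeline run completes in seconds and the
test suite in about a minute: 162 isodecoders × 3/group; 6 amplicons ×
2000 reads × 5/group; 300 genes; 50 ribosome transcripts × ~2000
footprints × 2/group; 5820 proteins × 5/group; 19 amino acids × 4/group.
Null-calibration checks aggregate ≥ 1000 tests per stage across seeds,
with per-seed sizes reduced (200-read amplicons, 12-transcript ribosome
runs) since calibration depends on the test, not the depth.

## Limitations

- The aligner is ungapped and amplicon-oriented; it is not a general
  small-RNA mapper and does not handle indels or clipped bases.
- Common (not tagwise) dispersion; no empirical-Bayes shrinkage or GLMs.
- The dwell-time significance method is a documented substitute (see
  above); relative DT magnitudes are the meaningful output.
- The MI enrichment scans one gene set (or content-ranked clusters), not
  a pathway database.
- Calibration consumes one consolidated ladder and does not model
  dilution provenance.
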