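# Methods

`exlnc` implements an integrative analysis of long non-coding RNA (lncRNA)
responses to endurance training: differential-lncRNA set construction from
per-contrast effect tables, sex-stratified p-value combination for
chromatin accessibility, and lncRNA–ATAC-peak–gene "triad" scoring that
prioritizes candidate cis-regulatory lncRNAs. This note documents the
model, the parameters, the synthetic study design the package is validated
on, and the numerical choices made where the design was open.

## Study design and inputs

The analysis assumes a multi-tissue training time course: male and female
animals trained for 1, 2, 4 or 8 weeks, with every contrast expressed as a
log2 fold-change (log2FC) versus sex-matched sedentary controls. The
package consumes the *results* of upstream differential modeling — one row
per (feature, tissue, sex, week) with log2FC, raw p and mean FPKM — not
read-level data. Alignment, quantification, negative-binomial model
fitting, and ATAC peak calling are out of scope; gene models (GTF), peaks
(BED/narrowPeak), peak-by-sample counts (TSV) and transcript sequences
(FASTA) are inputs.

All internal coordinates are 0-based half-open. GTF's 1-based closed
coordinates are converted on read; BED passes through. A single convention
prevents off-by-one drift between the pairing, summit and TSS arithmetic.

## Differential lncRNA sets

Features first pass an expression gate, mean FPKM >= 1 (inclusive). Two
complementary schemes then define differential lncRNAs (DELncs):

* **primary** — raw p <= 0.01 and |log2FC| >= 1. Sensitive to
  low-abundance, high-variance lncRNAs.
* **stringent** — Benjamini–Hochberg q <= 0.10 and |log2FC| >= 0.5, with
  BH applied within tissue.

All boundaries are inclusive; strict variants (`strict=True`) are
available because reported thresholds are often written either way.
A DELnc *cell* is one (feature, sex, week) triple passing the gates; the
unique-feature set is its projection. Sex sharing is summarized as
100·|M ∩ F| / |M ∪ F| — the union denominator keeps the quantity symmetric
and bounded in [0, 100]; per-sex denominators can be derived from the
male_only/female_only counts also reported.

Z-score trajectory summaries standardize each feature's log2FC vector to
mean 0, sd 1 across all eight (sex, week) cells of a tissue — the
heatmap-style per-feature axis — then report the grand mean Z and the
week-8 minus week-1 column-mean difference per sex, over the differential
set only.

## Sex-combined peak significance

ATAC peaks enter as per-condition peak sets, are trimmed to 200 bp around
their summits (100 bp each side; clamped at position 0 with a warning) and
merged — overlapping or book-ended intervals collapse, and the merged
peak's summit is defined as the merged midpoint (a deterministic,
symmetric choice). The merge is idempotent: re-merging a master list
returns it unchanged. Peaks must then show >= 10 reads in >= 4 samples and
lie on standard chromosomes (autosomes, X, Y — a configurable allow-list,
so the rule is species-agnostic).

Per-sex p-values for the training response are combined with Fisher's
sum-of-logs, X² = −2(ln p_M + ln p_F) ~ χ²(4) under the joint null.
Inputs are floored at 1e-300 before logs so underflowed p-values cannot
produce infinite statistics. The combined "training p-value" is adjusted
by BH *within tissue strata* (`bh_by_tissue`, stamped on all outputs).
Covariate-weighted FDR procedures that learn tissue weights are
deliberately not reimplemented; stratified BH preserves per-tissue
calibration and is fully specifiable, which the exact-equality tests
require. Training-significant peaks are those with q <= 0.05.

## lncRNA–chromatin linking

For each differential lncRNA, every training-significant peak on the same
chromosome whose interval midpoint lies within +/-500 kb (inclusive at
exactly 500,000 bp) of the lncRNA's midpoint forms a *local pair*. The
training trajectories of the two members — log2FC on the fixed 8-point
grid, male weeks 1/2/4/8 then female weeks 1/2/4/8 — are compared by
sample Pearson correlation. Using the concatenated two-sex vector matches
the sex-combined significance call and uses all available contrasts;
per-sex 4-vectors would leave only 2 residual degrees of freedom per
correlation. Zero-variance trajectories are excluded with a logged
warning, never silently scored.

Each retained pair (r >= 0.5) is scored against the nearest
protein-coding transcription start site (TSS; for minus-strand genes, the
locus 3′ genomic end):

    activity_score = r / (tss_distance + 1)

where `tss_distance` is |peak summit − TSS| in bp. Note the two distances
are deliberately different quantities: pairing uses interval midpoints,
scoring uses the summit. The score inherits r's sign, satisfies
|score| <= |r| with equality only at distance 0, and decays strictly with
distance — it concentrates on high-correlation pairs whose accessibility
change sits at a promoter. When several triads map to the same coding
gene, only the maximum-score triad is retained; ties break by smaller TSS
distance, then lexicographic lncRNA id, so outputs are reproducible.
Nearest-TSS ties break lexicographically for the same reason. Genes are
labelled up/down/ns from the differential coding-gene sets (direction by
the sign of the mean log2FC over the gene's differential cells).

## Sequence features and smORFs

GC content is computed over unambiguous bases only (N and other ambiguity
codes are excluded from numerator and denominator; U reads as T). Small
open reading frames run from an ATG to the first in-frame stop codon,
inclusive, with a 30-nt minimum (hence >= 9-aa peptides); every ATG opens
a candidate, including ATGs nested inside reported ORFs, and ORFs lacking
an in-frame stop are not reported. The microprotein search database
translates all smORFs in the three sense frames (a 6-frame mode exists),
deduplicated per source sequence by peptide. Transcript length and GC are
compared between classes with the two-sided Mann–Whitney U test (exact
enumeration for tie-free samples with n·m <= 400, otherwise the
tie-corrected normal approximation); minimum-free-energy distributions,
when provided precomputed, use the two-sample Kolmogorov–Smirnov test.
Secondary-structure prediction itself is out of scope.

## Synthetic data generator

The generator emulates the study design — 2 sexes x 4 weeks x N tissues —
with three planted truths, all deterministic under a single seed (one
`SeedSequence`, spawned child streams per stage):

* **Differential features.** A fraction `frac_diff` (default 0.15) of
  each biotype carries true |log2FC| = `effect_size` (default 2.0) in a
  random non-empty subset of the 8 cells (each active with probability
  0.6). Observed log2FC adds N(0, `noise_sd`) noise (default 0.1) and the
  p-value follows the two-sided z-model p = 2Φ(−|log2FC|/noise_sd). With
  `guarantee_separation` (default on), planted cells are rejection-sampled
  to p < 1e-4 with |log2FC| >= 1 and null cells to p > 0.1, so the
  threshold filters can be compared to truth *exactly*; planted features
  also draw mean FPKM conditioned >= 1 so truth survives the expression
  gate. P-values are generated analytically rather than by simulating and
  refitting counts, because the differential model itself is an upstream
  input, not part of this package.
* **Couplings.** A fraction `frac_coupled` (default 0.1) of lncRNAs get a
  partner peak within 50 kb. Both members' 8-point trajectories share a
  latent signal of per-point amplitude a = noise_sd·sqrt(r/(1−r)) plus
  independent N(0, noise_sd) noise, which makes the expected sample
  correlation equal the target `coupling_r` (default 0.95); at
  noise_sd = 0 the coupling is exactly r = 1. Uncoupled trajectories are
  i.i.d. normal with the matching marginal sd.
* **Significant peaks.** Coupled peaks (and a 5% background fraction)
  receive per-sex p-values of 1e-12–1e-5; the rest are uniform.

Peak statistics are keyed on the master peak list the pipeline itself
reconstructs from the emitted raw peak file, so file round-trips are
exact. Counts are Poisson with per-peak rates of 20–200 reads (coupled
peaks always high-coverage); 5% of peaks draw rates of 0.2–3 to exercise
the count gate. Default problem size (200 lncRNAs, 400 coding genes,
1,000 peaks, two 50-Mb chromosomes, 2 tissues) keeps a full run under a
minute; validation experiments scale to 500 lncRNAs x 2,000 peaks
(~10,000 local pairs) where the windowed sweep is checked against the
all-pairs scan.

What the generator does *not* emulate: count-level noise and dispersion
(p-values come from the z-model, not a negative-binomial refit),
tissue-specific biology and correlated effects across tissues, realistic
codon/GC structure of transcripts (i.i.d. bases), and chromatin-domain
structure around peaks. Passing tests therefore demonstrate that the
*decision logic* — gates, combination, pairing, scoring, deduplication —
is correct and calibrated under the stated model, not that upstream
models of real sequencing data are.

## Pair-filter operating characteristics

With 8-point trajectories, the null distribution of the sample Pearson r
between two independent Gaussian vectors has density ∝ (1−r²)², giving
P(r >= 0.5) ≈ 10.35%. The r gate alone therefore cannot suppress
background pairs below that rate at this grid length — the filter's
specificity comes from requiring the peak to be training-significant
*first*, exactly as the pipeline applies it. Under the default background
conditions (5% of uncoupled peaks training-responsive) the full-filter
background pass rate is ≈ 0.5–1% while sensitivity for planted r = 0.95
couplings exceeds 99% (Fisher-z: P(sample r < 0.5 | true 0.95, n = 8)
≈ 0.002). Both the full-filter and the r-only background rates are
reported by the validation experiments.

## Numerical and degenerate-input choices

* BH is the literal step-up: q_(i) = min_{j>=i} p_(j)·m/j clipped at 1,
  vectorized with a reversed cumulative minimum; verified bit-exact
  against a brute-force double loop and cross-checked against
  statsmodels.
* The chi-square(4) tail used in tests is the independent closed form
  exp(−x/2)(1 + x/2), not the implementation's own `scipy` call.
* Peak trimming at chromosome start clamps to 0 (with a warning), the
  only case where a pre-merge trimmed interval is shorter than 200 bp.
  With the even default width the summit-centering question (left vs
  right half for odd widths) does not arise; odd widths place the extra
  base on the right.
* Empty inputs: empty p-vectors return empty; an empty differential set
  makes the trajectory summary an error (a mean over nothing), not a 0.
* All output tables use fixed float formatting (`%.10g`) and sorted JSON
  keys; two runs of the same configuration are byte-identical, with
  timestamps confined to the log.

## Known limitations

* Stratified BH is not a reweighted FDR procedure; with strongly
  informative covariates it is conservative relative to weighting.
* Nearest-TSS assignment ignores topological domains and loops; a peak's
  true target may not be the linearly nearest promoter.
* The activity score's 1/(d+1) decay is a prioritization heuristic, not a
  calibrated contact probability; scores are comparable within, not
  across, tissues.
* The 8-point correlation is noisy (see operating characteristics above);
  r >= 0.5 on this grid is a screen, not an inference with controlled
  per-pair error.
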