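# Methods

## The signal model

A bulk tumor sample is a mixture of normal cells and a tumor clone at
purity ρ ∈ (0, 1]. At a germline-heterozygous SNP, normal cells contribute
one B allele of two; a fraction f ∈ (0, 1] of tumor cells (the event's
clonal fraction) carries an aberrant genotype with `c_t` total and `b_t`
B-allele copies, the remaining tumor cells staying diploid heterozygous.
The expected B-allele frequency and log R ratio are

    BAF = ((1−ρ) + ρ[(1−f) + f·b_t]) / D,   D = 2(1−ρ) + ρ[2(1−f) + f·c_t]
    LRR = α · log2(D / 2)

with α the array attenuation factor (default 0.55): genotyping arrays
compress the log copy ratio, so a clonal single-copy gain at full purity
reads ≈ 0.32 rather than log2(3/2) ≈ 0.58. LRR is floored at −5 for the
zero-DNA regime. The derived quantities follow by inversion: purity
from the strongest copy-neutral AI segment (clonal cn-LOH has mirrored-BAF
deviation Δ = ρ/2, hence ρ̂ = 2Δ_max), and per-segment clonality from the
purity-corrected BAF — f̂ = 2Δ/ρ under the cn-LOH model (|LRR| ≤ 0.10) or
f̂ = (1 − 2B̂)/(ρ(1 − B̂)) with B̂ = 0.5 − Δ under the one-copy-deletion
model. Estimates above 1.1 are flagged rather than clipped.

Event classes map to copies as: one-copy loss (1, 0), cn-LOH (2, 0), gain
(3, 2), homozygous deletion (0, 0). "Loss" throughout includes cn-LOH,
because selection against an allele can act through either route; the two
are separated only by LRR, not by AI itself.

## Segmentation

Changepoints are found on the mirrored BAF m = |BAF − 0.5| per chromosome
by binary segmentation minimizing within-segment sum of squares, with a
BIC-style penalty `2·σ̂²·log n` per accepted split; σ̂ is the robust
successive-difference estimate `1.4826·median|Δm|/√2`, insensitive to the
step changes themselves. Minimum 5 probes per changepoint segment,
20 probes per analyzed chromosome. A segment is AI when its mean m ≥ 0.07
(approximating the sensitivity of standard BAF segmentation tools at
typical array noise); AI segments are classified by mean LRR (gain above
+0.10), same-class neighbors closer than 1 Mb are merged, and only merged
segments with ≥ 10 probes are kept. Merging precedes the probe-count
filter deliberately: a spurious split near a true boundary otherwise sheds
a small fragment whose deletion would shift the called boundary by its
width. Homozygous deletions are maximal runs of ≥ 5 probes with
LRR < −1.0; at default noise this calls only reasonably pure clonal
events (|LRR| of a clonal homozygous deletion reaches −1 only for
ρ ≳ 0.72), which matches how rare and clonal such calls are in practice.

## Count tracks, peaks, prominence

For each class, the cohort count track assigns to every inter-breakpoint
interval the number of distinct tumors with a covering segment of that
class (a tumor's overlapping segments are unioned first). The track is
smoothed with a running maximum over w = 10 consecutive intervals —
centered by default (intervals i−4 … i+5; a trailing window is available,
since either alignment is consistent with a "10 consecutive breakpoints"
window), clipped at chromosome ends. Peaks are maximal equal-value runs of
the smoothed track strictly above both neighbors (end runs need only beat
their single inner neighbor; an all-constant nonzero chromosome yields one
flagged chromosome-spanning apex). Prominence is computed on the
*unsmoothed* track: from the apex, walk outward on each side recording the
running minimum until an interval exceeds the apex height; the prominence
is the height minus the highest such col, or the full height if neither
side reaches higher terrain — sea level is zero at both chromosome ends,
which forces the chromosome's highest peak to have prominence equal to its
height. A flood-fill reference implementation of the same contour
definition (`prominence_oracle`) exists purely for testing; the two are
checked equivalent on all tracks of length ≤ 6 with values 0–3 and on
1000 random tracks. Peaks with prominence ≥ 15 tumors are reported, ranked
by prominence (ties: height, then genomic order). Gene assignment uses the
smoothed apex plateau; an apex containing no gene receives its two
flanking genes.

## Isochromosome rule and co-occurrence scan

A sample is isochromosome-like on a chromosome if ≥ 80% of either arm (bp
fraction of the union of its AI segments of any class intersected with the
arm) is in AI *and* mean probe LRR on the p-arm is at least 0.2 below the
q-arm. That is the i(q) form of the rule; the mirrored inequality is
reported as i(p) and flagged by the direction field. The scan of coupled
lesions computes, on a 1 Mb grid, the 2×2 table of samples by (gain covers
x) × (loss covers y) and its log2 odds ratio, with the Haldane–Anscombe
0.5 correction when a cell is zero; pairs where either locus has zero or
universal coverage carry no co-occurrence information and are NaN. The
two-sided Fisher exact test is applied to the uncorrected argmax table.

## Mutation density and the per-copy rate

Somatic SNVs are counted per segment within a callable mask; segments with
under 0.5 callable Mb are excluded. Density curves use raw segment LRR as
the x-axis (faithful to how such data are usually displayed), with robust
lowess (tricube weights, frac 0.3, 2 iterations) as a visual guide. For a
testable recovery target the copy number is additionally inverted from
LRR, `ĉ = (2·2^(LRR/α) − 2(1−ρ))/ρ` clipped at 0, and the per-copy rate μ
is fitted by identity-link Poisson regression of counts on the exposure
`ĉ × callable Mb` with no intercept — whose MLE is the closed form
`μ̂ = Σ counts / Σ(ĉ·Mb)` — with the exact chi-square (gamma) profile
interval for a Poisson rate at fixed exposure. A test cross-checks the
closed form against the statsmodels GLM fit.

## Association statistics

2×2 contingency analyses report integer row percentages, the odds ratio
(Haldane-corrected when a cell is zero) and the two-sided Fisher p. The
hypergeometric upper tail is evaluated exactly in log space (gammaln +
logsumexp). Peak–peak association uses logistic regression of the AI
indicator at one peak on the indicator at the other, controlling for the
sample's AI basepairs on chromosomes other than *both* peaks' chromosomes
(the natural extension of the single-peak burden control); peak–phenotype
tests control for burden outside the peak's chromosome, with Bonferroni
across tested loci as the genome-wide correction. Complete or
quasi-separation — likely at desk-scale cohort sizes — is detected and the
fit redone with Firth's Jeffreys-prior penalization, which keeps
coefficients finite. Expression–dosage tests are per-gene OLS of
expression on gene-level LRR plus purity, Wald test on the LRR slope,
Benjamini–Hochberg across genes at 10% FDR. Per-tumor event counts over
curated peaks count gain segments at gain peaks and loss segments at loss
peaks only, once per peak; strata are compared with the two-sided
Mann–Whitney test (normal approximation with tie correction).

## The synthetic cohort generator

The generator emulates an array cohort at desk scale: 5 chromosomes of
100 Mb (centromere at 40 Mb), 100 heterozygous SNPs/Mb, purity
ρ ~ Beta(5, 3) (mean 0.625, most mass 0.4–0.85, typical of surgical
specimens), 15% MSI samples. Background chromosomal instability plants
whole-arm events (uniform over arms; class uniform over one-copy loss /
cn-LOH / gain; clonal fraction uniform on 0.3–1.0) at Poisson rates of 6
per MSS and 1.5 per MSI sample — a 4-fold design ratio chosen to
reproduce the several-fold MSS excess of AI basepairs reported for real
cohorts. Six planted drivers (recurrence 10–60%, clonal, extent 5–30 Mb
per side around the locus, clipped to the arm) create recoverable peaks.
Isochromosome events (probability 0.2 on a designated chromosome) couple a
clonal p-arm loss (minus a 1 Mb retained terminal stub) with a q-arm gain.
Fragile-site deletions are 0.1–1 Mb focal losses at fixed loci with
probability 0.05 (MSS) vs 0.25 (MSI). Rare clonal homozygous deletions
(probability 0.02) occupy 0.2–0.5 Mb. A binary instability marker
("TP53-like", prevalence 0.55) doubles the background event rate of its
carriers, creating the expected contrast in per-tumor event counts between
strata. Noise: σ_BAF = 0.03 (truncated to [0, 1]), σ_LRR = 0.15 — chosen
as plausible array noise; the real platform's compression and noise are
not modeled explicitly, which is why α and both σ are configurable.

Somatic SNVs accrue per truth segment as Poisson(μ · c_t · callable Mb)
with μ = 0.05/Mb/copy, multiplicity fixed at 1 (each mutation on a single
copy; a mutation-timing mode that would yield multiplicity > 1 for
pre-gain mutations is deliberately omitted for simplicity). Sequencing
depth is negative binomial with mean proportional to the local total copy
ratio (mean 40 at diploid, dispersion parameter 10), as shotgun coverage
is; alt reads are Binomial(depth, VAF) with
VAF = ρ·f·m / (2(1−ρ) + ρ·c̄), c̄ = 2(1−f) + f·c_t. This reproduces the
neutral-model signature: SNV density per callable Mb rises linearly with
copy number while the expected mutated-read count per SNV (haploid
coverage × multiplicity) stays flat. Expression for driver genes is
β·LRR + γ·purity + noise (β = 1, γ = 0.5, σ = 0.5); background genes have
no dosage term. The callable mask is the first 80% of every 1 Mb block.

What the generator does **not** emulate: GC/wave artifacts, probe-specific
biases, germline genotype structure, read-level sequences, subclonal
phylogenies beyond a single clonal fraction per event, and mutation
timing. Passing recovery tests therefore demonstrates correctness of the
algorithms under the stated mixture model, not robustness to platform
artifacts of any particular array.

## Validation scenarios and their sizes

- **Planted-peak recovery**: 300 samples, the 6-driver catalog, default
  noise, sparse background (0.25 arm events/sample, no isochromosome /
  fragile / homozygous events). Two of three background classes land on
  the loss track, so expected per-arm background loss coverage is
  300·(0.25/10)·(2/3) ≈ 5 tumors — far below the 15-tumor reporting
  threshold — so every reported peak must be a planted locus. The full
  default background (6 events/sample) is not used here by design: with
  whole-arm instability at that rate, arm-level plateaus legitimately
  clear the threshold (a chromosome's highest peak has prominence equal to
  its height), which is a property of the method, not a detection error.
- **Isochromosome**: 50 planted samples (probability 1) and 50 null
  samples whose designated chromosome carries no background events while
  all other chromosomes keep the default rate. Isolated whole-arm losses
  *satisfy* the calling rule — they are its intrinsic confounder — so
  the specificity arm isolates robustness to measurement noise, which is
  what a caller can actually control.
- **Mutation rate**: 200 samples (≈ 2400 truth segments, ≈ 6000 SNVs);
  μ̂ recovers 0.05 within ~1%. The flatness check uses ρ = 1 chromosomes
  at c_t = 1–4 over 30 replicates.
- **Segmentation/clonality**: a 10 Mb clonal cn-LOH event at
  ρ ∈ {0.4, 0.6, 0.8}, 10 replicates each; boundary error ≤ 5 probe
  spacings, clonality bias well under 0.05.
- **Calibration**: 200 null logistic replicates at n = 500
  (Kolmogorov–Smirnov uniformity at the 1% level — a test that by
  construction fails on ~1% of seeds); 500 simulated genes (100 with a
  true dosage slope) for the empirical FDR of the BH procedure.

Problem sizes were chosen so the entire validation battery runs in tens of
seconds while keeping every recovery target comfortably identified.

## Conventions and numerical choices

All coordinates are 0-based half-open, internally and in the BED-like
files; VCF positions are converted on read/write. All randomness flows
from explicit `numpy` generators; cohorts are generated per-sample from
spawned seed sequences so streaming and in-memory paths produce identical
results. Segment boundaries are placed at the first/last probe of the
changepoint segment. Ranking ties break deterministically (height, then
genomic order). Degenerate inputs (empty probe files, zero-depth SNVs,
all-zero tracks, single-class phenotypes, zero-variance regressors) are
rejected or flagged rather than silently propagated.

## Known limitations

- The purity heuristic ρ̂ = 2Δ_max assumes at least one clonal
  copy-neutral LOH segment; cohorts without one need metadata purity.
- No ploidy estimation: whole-genome duplication would shift the LRR
  baseline and bias the copy-number inversion.
- The isochromosome rule cannot distinguish a genuine isochromosome from
  independent co-occurring arm loss and arm gain; the rule is a
  pattern detector, not a mechanism caller.
- Binary segmentation is greedy; pathological changepoint configurations
  (nested short events at low Δ) can be merged or missed where exact
  dynamic programming would resolve them.
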