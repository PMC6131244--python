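# aiscape

Allelic-imbalance (AI) landscape analysis for tumor SNP-array cohorts.

In bulk tumor DNA, the two parental alleles at a germline-heterozygous SNP
act as an internal control: any somatic copy-number change — one-copy loss,
gain, or copy-neutral loss of heterozygosity (cn-LOH) — unbalances the
B-allele frequency (BAF) away from 0.5, even when the total copy number
(log R ratio, LRR) barely moves. Counting, across a cohort, how many tumors
carry AI at every locus turns recurrent selection into narrow peaks whose
apexes pinpoint candidate driver genes at gene-level resolution.

`aiscape` implements that analysis end to end:

- **Segmentation** — penalized least-squares changepoint detection on the
  mirrored BAF `m = |BAF − 0.5|` per chromosome; segments with mean
  `m ≥ 0.07` are called AI and classified **gain** (mean LRR > 0.10) or
  **loss** (everything else, explicitly including cn-LOH). Deep-loss probe
  runs (LRR < −1) are reported as homozygous deletions.
- **Recurrence peaks** — per-class tumor-count tracks over breakpoint
  intervals, smoothed with a max filter over 10 consecutive intervals;
  local maxima are peaks, ranked by **topographic prominence** (the height
  of a peak above the lowest contour line that surrounds it and does not
  contain a higher peak, computed on the unsmoothed track; a chromosome's
  highest peak has prominence equal to its height). Peaks with prominence
  ≥ 15 tumors are reported, with overlapping genes or, for gene-free
  apexes, the two flanking genes.
- **Isochromosome calls** — a tumor is called isochromosome-like on a
  chromosome when ≥ 80% of an arm is in AI and the p-arm mean LRR is at
  least 0.2 below the q-arm (direction i(q); the mirrored condition is
  reported as i(p)). A grid scan of log2 odds ratios localizes coupled
  gain/loss pairs within a chromosome.
- **Purity and clonality** — the two-population mixture model
  `BAF = ((1−ρ) + ρ[(1−f) + f·b_t]) / (2(1−ρ) + ρ[2(1−f) + f·c_t])`
  is inverted to estimate tumor purity ρ (from the strongest copy-neutral
  segment, `ρ̂ = 2Δ_max`) and per-segment clonal fraction f (purity-corrected
  BAF, `f̂ = 2Δ/ρ` for cn-LOH).
- **Mutation density** — somatic SNV counts per strictly-callable megabase
  versus segment LRR, variant-allele statistics, lowess summaries, and a
  Poisson fit of the per-copy mutation rate μ (SNVs per Mb per chromosomal
  copy) under the neutral model in which every copy mutates independently.
- **Association statistics** — Fisher 2×2 contingency, exact hypergeometric
  overlap enrichment, AI-burden-controlled logistic regression for
  peak–peak and peak–phenotype association (with a Firth fallback under
  separation), per-tumor event counts over curated peaks, expression–dosage
  Wald tests with Benjamini–Hochberg correction.
- **Synthetic cohorts** — a generator with full ground truth: purity
  mixtures, arm-level events, planted recurrent drivers, isochromosomes,
  MSI-enriched fragile-site deletions, homozygous deletions, per-copy SNV
  accrual with coverage tracking copy number, and dosage-responsive
  expression.

## Worked example

```python
import aiscape as ai

cfg = ai.SimulationConfig(n_samples=40)
cohort = ai.simulate_cohort(cfg, seed=7)
segments = ai.segment_cohort(cohort.probes)
peaks = ai.call_all_peaks(segments, cfg.genome, genes=cohort.genes)
print(f"{len(segments)} AI segments in {cfg.n_samples} tumors")
for p in peaks:
    print(f"rank {p.rank}: {p.chrom} {p.klass} peak, apex "
          f"{p.apex_start/1e6:.1f}-{p.apex_end/1e6:.1f} Mb, height {p.height}, "
          f"prominence {p.prominence}, genes {','.join(p.genes)}")
```

prints

```
217 AI segments in 40 tumors
rank 1: chr1 loss peak, apex 10.9-28.8 Mb, height 29, prominence 29, genes DRV1,BG_chr1_1
rank 2: chr1 gain peak, apex 56.4-80.6 Mb, height 26, prominence 26, genes BG_chr1_3,DRV2,BG_chr1_4
rank 3: chr3 loss peak, apex 2.6-36.2 Mb, height 25, prominence 25, genes BG_chr3_1,DRV3
rank 4: chr4 loss peak, apex 14.3-39.6 Mb, height 22, prominence 22, genes BG_chr4_1,DRV5
rank 5: chr2 loss peak, apex 1.0-40.0 Mb, height 21, prominence 21, genes BG_chr2_1
```

The four planted drivers recurrent enough to clear the 15-tumor prominence
threshold in a 40-tumor cohort are recovered with their genes inside the
apex (DRV1, DRV2, DRV3, DRV5). The rank-5 peak is real too: it is the
p-arm loss plateau of the isochromosome events planted on chr2 — the
coupled arm-loss/arm-gain pattern the isochromosome caller then resolves:

```python
iso = ai.call_isochromosomes_cohort(segments, cohort.probes, cfg.genome, "chr2")
print(f"isochromosome i(q) calls on chr2: {int(iso['called'].sum())}/{len(iso)} tumors")
# isochromosome i(q) calls on chr2: 13/40 tumors
```

The same stages are available from the shell:

```bash
aiscape simulate --seed 7 --out-dir out/
aiscape segment --probes out/probes.tsv --out out/segments.tsv
aiscape peaks --segments out/segments.tsv --genome out/genome.tsv \
    --genes out/genes.bed --out out/peaks.tsv
aiscape run-all --seed 7 --out-dir out/     # everything, chained
```

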