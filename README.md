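# lcimpute

Dual-phase genotype imputation for ultra-low-coverage whole-genome
sequencing (ulcWGS), with a genomic-selection evaluation stack.

## The problem

Sequencing a population at 0.001–0.5× coverage leaves most SNP sites with
zero or one read per sample, so genotypes cannot be called directly.  With
a phased reference haplotype panel, linkage disequilibrium lets a
haplotype-copying model recover the missing genotypes — but at ultra-low
depth, a single likelihood-based pass leaves many sites uncalled whenever
no read covers them in any sample.  `lcimpute` implements a two-round
strategy for exactly this regime:

1. **Round 1** — a Li–Stephens diploid copying HMM is run over per-site
   genotype likelihoods against the reference panel, in 2 Mb windows with
   200 kb buffers that are ligated back together.  The hidden state is the
   ordered pair of reference haplotypes being copied; transitions follow
   ρ = 1 − exp(−4·Ne·c·d/K) per interval, and each copied allele is
   miscopied with probability λ.  Calls with posterior ≥ τ form the
   *typed* set: sparse but accurate.
2. **Round 2** — the panel is first self-imputed (haploid copying,
   leave-one-out) so it has no missing entries.  Each sample's typed
   genotypes are phased into two query haplotypes, the reference
   haplotypes sharing the longest identical-by-state segments at the typed
   sites are selected as conditioning states (the positional
   Burrows–Wheeler transform is the indexing structure for such queries),
   a copying HMM is run over the typed sites only, and the state posterior
   is interpolated in physical distance to every untyped panel site.
   Recovery is 100 % of panel sites by construction.

Accuracy is measured by genotype concordance (total: missing counts as
discordant; called: over called cells only), per-site genotypic
r² = Cov(X,Y)²/(Var X·Var Y) between imputed dosage X and true genotype Y,
and SNP recovery, all aggregated by minor-allele-frequency bin.

For downstream genomic selection the package simulates quantitative traits
(P = μ + sTBV + e, QTL effects |β| ~ gamma(0.4, 1.66) with random sign,
sTBV scaled so Var(sTBV) = σe²·h²/(1−h²)), fits kinship-parameterised
GBLUP/rrBLUP (K = WWᵀ/S over standardised dosages, variance components by
REML), and scores ranking stability with the Jaccard index of top-α%
selections between prediction rounds.

Everything runs on synthetic data from the built-in simulators: a
mosaic-copying haplotype panel generator with LD, diploid offspring
sampling, Poisson read coverage with base error, and binomial coverage
thinning for replicate down-sampling experiments.

## Worked example

```sh
lcimpute simulate-panel --n-hap 80 --n-sites 400 --region-len 200000 \
    --seed 5 --out panel.vcf
lcimpute simulate-reads --panel panel.vcf --n-ind 4 --depth 0.2 --seed 6 \
    --out reads.vcf --truth-out truth.vcf
lcimpute impute --panel panel.vcf --reads reads.vcf --out-dir run/
lcimpute evaluate --imputed run/imputed.vcf.gz --truth truth.vcf \
    --panel panel.vcf --out report.tsv
```

which prints, in order:

```
wrote 80 haplotypes x 400 sites to panel.vcf
wrote 4 samples at 0.2x to reads.vcf
imputation complete; artifacts under run
total concordance 0.8931; report at report.tsv
```

The final line means that after both rounds, 89.31 % of the 4 × 400
genotype cells match the simulated truth (at 0.2× coverage only ~18 % of
cells had any read at all); `report.tsv` breaks concordance, mean r² and
recovery down by panel-MAF bin, with a `total` row at the bottom.  The
same flow is available programmatically via `lcimpute.pipeline`.

Or in Python:

```python
from lcimpute import pipeline, seqsim
panel, _, truth = pipeline.simulate_population(seed=1)
counts = seqsim.simulate_reads(truth, depth=0.1, seed=3)
r1, r2 = pipeline.run_dual_phase(panel, counts, sample_ids=truth.sample_ids)
reports = pipeline.evaluate_rounds(r1, r2, truth, panel)
print(reports["round1"].total_concordance)   # 0.6018 (confident sites only)
print(reports["round2"].total_concordance)   # 0.9476 (all panel sites)
```

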