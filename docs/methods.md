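# Methods

## Scope and model

`lcimpute` implements dual-phase genotype imputation for ultra-low-coverage
sequencing against a phased reference haplotype panel, plus the simulation
and genomic-selection machinery needed to evaluate it without any external
data.  Everything operates on biallelic SNPs on a single diploid
chromosome; positions are 1-based base pairs matching VCF.

### Round 1: copying HMM over genotype likelihoods

Per sample, read evidence at each site is summarised as a genotype
likelihood triplet P(reads | g), g ∈ {0,1,2}, from an independent-reads
binomial model with per-base error ε: a read reports the alternate allele
with probability p_g = (g/2)(1−ε) + (1−g/2)ε.  Sites with no reads carry
the flat triplet (1,1,1) and contribute nothing to the HMM.

The hidden state is the ordered pair of reference haplotypes the sample's
two chromosomes are copying.  K conditioning haplotypes are chosen per
sample by an agreement score: the summed likelihood, over read-covered
sites, of the homozygote matching each haplotype's allele (ties to the
lower index; K = H when the panel is small).  Transitions factorise per
haplotype with switch probability ρ = 1 − exp(−4·Ne·c·d/K) over an
interval of d bp, a switch landing uniformly on the K haplotypes.
Emissions allow each copied allele to flip independently with miscopy
probability λ, so P(data | state) depends only on the copied allele sum;
the forward–backward recursion exploits this, and the genotype posterior
at a site is the class-mass average of P(g | class)·GL(g) renormalised
within class.  All recursions are scaled per site.

Long chromosomes are processed in windows (default 2,000,000 bp) with
buffers (default 200,000 bp); adjacent windows overlap by two buffers, and
at ligation each site is taken from the window in which it lies furthest
from a window edge, so buffer-edge artifacts never reach the output.  A
coverage gap between windows is a hard error.

A call is *typed* ("successfully imputed") when its posterior maximum
reaches τ (default 0.90); sites with no read in any sample are excluded
from every sample's typed set regardless of posterior, because such calls
are pure prior.  τ is deliberately exposed: the boundary between a
trustworthy round-1 call and one to re-estimate in round 2 is a policy
choice, not something the model determines.

### Panel self-imputation

Round 2 needs a complete panel.  Each panel haplotype with missing entries
is run as a haploid copying query against all other haplotypes
(leave-one-out, always against the original panel so the result is
independent of processing order); missing alleles are set to the
posterior-argmax copied allele.  Observed alleles are never altered, a
complete panel passes through untouched, and a site missing in every
haplotype is an error.

### Round 2: IBS-conditioned refinement

Per sample, the typed hard calls are phased into two query haplotypes:
homozygotes trivially, heterozygotes by the alleles of the round-1
argmax copied pair cached during ligation; when the cached pair cannot
resolve the phase (both copied alleles equal), the alternate allele goes
deterministically to the second query haplotype.  Caching the argmax pair
rather than the full K×K state posterior keeps memory linear in sites.

For each query haplotype, the reference haplotypes with the longest
contiguous identical-by-state run at the typed sites are selected
(top L = 16 per query, union over the two queries, ties to the lower
index).  The PBWT prefix/divergence index over the typed sites — the
standard sublinear structure for set-maximal match queries — is provided
and tested (`build_pbwt`); the match search itself is a vectorised
run-length scan, which returns the identical top-L set at this scale with
far less bookkeeping.

A diploid copying HMM then runs over the typed sites only, emitting the
observed hard call with symmetric genotype error η (default 1e-3).  At
each untyped panel site the state posterior is interpolated linearly in
physical distance between the flanking typed sites (nearest posterior
beyond the ends) and converted to a genotype posterior through the
miscopy model with no data term.  Physical distance is used because the
pipeline's inputs carry no genetic map.  Typed sites keep their round-1
posteriors — the round-1 calls are the trusted anchor — and every panel
site receives a call, so recovery is 100 % by construction.

## Evaluation metrics

Concordance comes in two flavours: *total* divides matching calls by all
truth cells (a missing call counts as discordant), *called* by called
cells only.  Genotypic r² per site is Cov(X,Y)²/(Var X · Var Y) across
samples between imputed dosage X and true genotype Y; sites where either
variance is zero are excluded from the mean and counted.  Reports
aggregate by panel-MAF bin (left-open, right-closed; default edges 0,
0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5), plus a total row; bin-weighted
concordance recombines exactly to the total because the bins partition
the polymorphic sites.  Both concordance flavours are always reported.

## Genomic-selection stack

Traits follow P_i = μ + sTBV_i + e_i.  QTL positions are drawn uniformly
without replacement; effect magnitudes from gamma(shape 0.4, scale 1.66)
— the 1.66 is read as a scale parameter, following the livestock-genetics
convention for this effect-size distribution — with sign ± at probability
0.5.  Raw breeding values (Σ effect × dosage) are rescaled so their
variance equals σg² = σe²·h²/(1−h²), pinning the realized heritability at
h² exactly; residuals are N(0, σe²) with σe² = 1 and μ = 0 by default
(both configurable — only the ratio matters to any scale-free result).
A QTL draw with zero TBV variance is resampled.

Kinship is K = WWᵀ/S over per-site standardised dosages
w = (x − 2p)/√(2p(1−p)); fixed sites (p ∈ {0,1}) are excluded.  GBLUP is
the intercept-only mixed model y = μ + g + e, g ~ N(0, σg²K), solved on
the spectrum of K: the variance ratio δ = σe²/σg² by exact restricted
maximum likelihood (1-D bounded minimisation in log δ, intercept and σg²
profiled out), then ĝ = K(K + δI)⁻¹(y − μ̂) and predictions
ŷ = μ̂ + K_cross·α with α = (K + δI)⁻¹(y − μ̂).  At fixed δ this equals
the dense ridge solution to 1e-8, which the tests verify.

Ranking stability between prediction rounds uses the Jaccard index of the
top-α% sample sets, with set size β = ⌈n·α/100⌉ and ties broken by sample
index.  The GWAS scan is a plain single-marker linear-regression score
test (two-sided t on the correlation), a deliberate simplification of a
mixed-model scan: it serves the SNP-subsetting workflow, not population
structure correction.  Monomorphic SNPs report p = 1; selection is a
strict inequality against the threshold (default 1e-12).

## Synthetic data generator

The panel generator is a mosaic-copying model, not a coalescent: founder
haplotypes (default 20) are drawn site-wise from a 1/f allele-frequency
spectrum truncated to [0.01, 0.99] (inverse-CDF sampling), and each later
haplotype copies a previously generated one, switching template between
adjacent sites with probability 1 − exp(−r·d) and flipping each site with
the mutation rate.  Monomorphic sites are resampled at the founders and
re-propagated through the recorded copying structure.  This produces the
block-wise LD that copying-model imputation exploits — which is what the
tests need — but no demographic realism: no coalescent genealogy, no
recombination hotspots, no allele-frequency drift between panel and test
samples, no indels or SVs, and read simulation has no mapping bias,
GC bias or amplification artifacts.  Passing tests therefore demonstrate
the machinery is correct under its own model assumptions, not that
real-data accuracy figures transfer.

Test individuals are pairs of independent panel-haplotype mosaics, so the
panel genuinely contains the LD structure of the test genomes.  Reads per
(sample, site) are Poisson(depth) with the binomial allele model above;
coverage down-sampling is binomial thinning, which maps Poisson(d) exactly
to Poisson(d′) — the property the repeated down-sampling consistency
protocol relies on.  Panel missingness is i.i.d. per entry, with site
masks resampled to keep at least two observed alleles per site.

All randomness derives from one integer seed through named substreams
(panel, offspring, reads, thinning, trait), so fixing the seed reproduces
any artifact bit for bit and stages cannot perturb each other.

## Benchmark scale and defaults

The standing synthetic benchmark is a 2 Mb region with 200 reference
haplotypes over 4,000 SNPs and 20 test individuals at ε = 0.001 — sized so
a full dual-phase run completes in seconds and whole test batteries
(10-seed comparisons, 4-depth × 5-seed ladders, 5-replicate thinning
protocols) remain desk-scale.  HMM defaults: K = 48, Ne = 10,000,
c = 1e-8/bp, λ = 1e-3, η = 1e-3, τ = 0.90, L = 48.  K and L sit on the
benchmark's accuracy/runtime frontier: smaller values cost several points
of 0.1× concordance, while doubling K again roughly doubles the runtime
for a marginal gain — with a 200-haplotype panel, K = 48 conditions on a
quarter of it.  For much larger panels these defaults are conservative
(K stays well below H).
Window/buffer defaults are 2 Mb / 200 kb; the benchmark region occupies a
single window, and the window machinery is exercised separately with
smaller windows.  Ne, c and λ are conventional copying-model values, not
claimed to match any external tool's internals; all are config-exposed.

## Numerical choices and degenerate inputs

The diploid forward–backward scan is compiled with numba (the per-site
K² update is the pipeline's hot loop); the posterior extraction exploits
that emissions depend on a state pair only through its copied-allele sum,
so per-site class masses are three quadratic forms evaluated with BLAS.
Forward–backward is scaled per site; likelihood triplets are computed in
log space and floored at 1e-300, so ε = 0 and deep coverage cannot
underflow.  Hard-call ties break toward the smaller dosage.  Posterior
triplets are renormalised before dosage extraction; the VCF writer
enforces triplet sums within 1e-6 and emits DS/GP at 3 decimals (read-back
agreement to 5e-4).  REML's δ is searched in log space on [e^-10, e^10];
a constant phenotype yields zero residuals, μ̂ equal to the constant and
zero BLUPs.  A sample with no covered site falls back to the first K
conditioning haplotypes (warned); a sample with no typed sites keeps its
round-1 posteriors (warned); an empty typed set fails PBWT construction.

## Known limitations

Round 1 is a single deterministic forward–backward per sample — no
iterative phasing refinement across samples, so it will trail samplers
that share haplotype information between test individuals at very low
depth.  Round-2 phasing inherits switch errors from the per-site argmax
cache.  Interpolation in bp ignores recombination-rate variation.  The
GWAS scan ignores relatedness.  No sex chromosomes, no ploidy other
than 2, no multiallelic sites, no structural variants.
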