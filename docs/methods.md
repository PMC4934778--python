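# Methods

This note records the statistical models implemented in `msatland`, the
defaults and why they were chosen, the numerical choices that matter,
what the synthetic data generator does and does not emulate, and the
known limitations.

## Data model

Genotypes are unordered diploid allele-size pairs (base pairs), stored
sorted with a dedicated missing sentinel (never 0, so GenePop "00"
codes cannot collide with data). Coordinates are planar kilometres
(x = east, y = north), assumed already projected; the package performs
no geodesy, matching field designs where each sample is placed at the
centroid of its management/hunting district. Allele sizes are kept in
base pairs everywhere; conversion to repeat units happens only inside
the Garza–Williamson statistic, via each locus's motif length.

## Diversity and differentiation

* Expected heterozygosity is Nei's unbiased estimator
  Hₑ = n/(n−1)·(1−Σpᵢ²) with n = gene copies; Hₒ is the heterozygous
  fraction of typed individuals. Across-loci means are unweighted.
* Allelic richness uses hypergeometric rarefaction to g gene copies,
  A_R = Σᵢ[1 − C(n−nᵢ, g)/C(n, g)]; g defaults to the smallest
  per-unit gene-copy count (the FSTAT convention), so A_R(g=n) = N_A.
* θ (FST) and the grouped F_IS use the Weir & Cockerham (1984) a/b/c
  variance components accumulated as ratios of sums over alleles and
  loci (the ARLEQUIN/FSTAT convention), never averages of per-locus
  ratios. For a single unit (no grouping) W&C components are undefined,
  so the whole-sample F_IS is the ratio-of-sums estimator
  1 − ΣHₒ/ΣHₑ over polymorphic loci.
* Pairwise-θ p-values come from label permutations (add-one corrected);
  the Hardy–Weinberg exact test shuffles alleles among individuals
  within a locus and ranks the Levene conditional probability of the
  genotype configuration (probability-ordering criterion), with
  one-sided heterozygote excess/deficit companions (both are reported
  because group-level deviations are often directional); the global
  test combines per-locus p by Fisher's method. The LD test permutes
  one locus's genotype column and uses the G statistic on the genotype
  contingency table, Bonferroni threshold α/C(L,2).

## Bottleneck inference

A recently bottlenecked population transiently shows *heterozygosity
excess*: Hₑ computed from allele frequencies exceeds the equilibrium
value expected for the number of alleles that survived. For each locus
the equilibrium distribution Heq | (k alleles, n copies) is simulated
from the neutral coalescent: the backward event chain (with j lineages
the most recent event is a mutation with probability θ/(θ+j−1), else a
coalescence) needs no event times; stepwise mutations accumulate signed
steps down the genealogy, while IAM uses the exact Hoppe-urn
construction. Conditioning on exactly k alleles is by rejection with a
multiplicative θ adaptation between attempts (the conditioning strategy
of the classical heterozygosity-excess software). Heq and the observed
Hₑ use the same unbiased estimator, so the excess comparison is
like-for-like.

TPM mixes single steps (probability `tpm_p_smm`) with geometric
multi-step jumps whose variance is configurable (defaults: variance 36,
p_smm = 0 — the settings used in the study this package's defaults
mirror; the proportion is left as a free parameter because a 0% SMM
share inside a "two-phase" model is unusual and users may prefer the
common 70–95% range). At equal k, equilibrium Heq orders
IAM < TPM < SMM: stepwise homoplasy needs more mutation to maintain k
alleles, which evens the frequencies. This is why empirical wolf data
can reject equilibrium under IAM yet not under SMM.

The sign test calls a locus *excess* when observed Hₑ exceeds its mean
simulated Heq; the expected excess count is Σ P(excess|null) from the
simulations, and the p-value is the exact Poisson-binomial tail in the
observed direction (one-tailed, the conventional report; a doubled-tail
two-sided value is also returned). The mode-shift test bins pooled
allele frequencies into ten classes and calls "L-shaped" iff the lowest
class is strictly modal. Garza–Williamson M = k/(r+1) with the range r
in repeat units (the +1 convention of ARLEQUIN; a flag exposes the
literal k/r variant), mean below 0.68 flagged as a historical
bottleneck.

## LD effective population size

Burrows' composite disequilibrium is computed for every allele pair at
every locus pair from unphased genotypes,
Δ̂ = S/(S−1)·[ΣXY/(2S) − 2p̂_A p̂_B], r² = Δ̂²/(p_A q_A p_B q_B), with
alleles under the frequency cutoff (default 0.02) screened out and
missing data handled pairwise. The drift component is
r²′ = mean r² − E[r²|S] with the Waples (2006) second-order sampling
expectation at the harmonic-mean S, inverted through the Waples & Do
(2008) drift equations for random mating or lifetime monogamy
(monogamy ≈ doubles the estimate). r²′ ≤ 0 yields an infinite estimate
with a finite lower bound. The parametric CI is chi-square with
df = Σ(k₁−1)(k₂−1) independent comparisons; the jackknife CI deletes
one *locus* at a time (pairs sharing a locus are dependent, and a
pair-level jackknife understates the variance — in the package's own
recovery harness at true Ne = 50 the locus jackknife covers the truth
in ≈95% of replicates versus ≈65% for the pair version).

## Exclusion of immigrants

Each individual's multilocus genotype is scored by the Rannala–Mountain
posterior-predictive likelihood under a Dirichlet(1/k) prior on the
reference frequencies (no genotype has zero probability), with the
focal individual's own alleles removed from the counts first. The
Monte-Carlo p is the add-one rank of that score among genotypes
simulated from the reference frequencies under HWE and linkage
equilibrium. On reference members the p-values are uniform (KS-checked
in the tests). Power to exclude immigrants is moderate at typical panel
sizes — with 15 loci and a source population at F_ST ≈ 0.2 roughly half
of single immigrants fall below p = 0.05 — which matches the method's
behaviour in practice and is why only a couple of "ghost" immigrants
are typically flagged in real datasets.

## Clustering post-processing

The admixture MCMC itself is out of scope; the module consumes Q
matrices and log-likelihood tables (plain CSV or the native
results-file layout). ΔK = |L(K+1) − 2L(K) + L(K−1)|/sd(L(K)); zero sd
leaves ΔK undefined at that K. Hybrid filtering removes individuals
with focal-cluster membership below the threshold (default 0.98, the
conservative canid purity cutoff) and summarises kept members' q with a
*percentile* 90% interval (the interval construction is not specified
in the source literature; percentile is labelled as such). PCA uses
per-individual allele dosages divided by 2, column-centred and not
scaled, constant columns dropped, missing genotypes mean-imputed.

## DResD and kriged surfaces

Nei's standard D is applied to individuals as populations of one
(per-locus frequencies 0/0.5/1; J-terms summed over shared-typed loci;
pairs sharing no allele anywhere are capped at a configurable value,
default 10). The global IBD model is OLS of raw D on raw Euclidean km
over *all* pairs — the minimal model, with a log-distance option — and
the neighbour band (default 17–33 km) is applied *after* the global
fit, so residuals measure deviation from the population-wide IBD
expectation. Residuals sit at pair midpoints and are interpolated by
universal kriging: first-order planar trend plus an exponential
variogram fitted to the binned empirical semivariogram by weighted
least squares (bin counts as weights; automatic linear fallback). With
zero nugget the predictor is exact at the support points (tested to
1e-6); a 1e-10 diagonal jitter stabilises the solve. The grid defaults
to 2 km cells over the sample bounding box padded by 10 km, with
no-data beyond 40 km from any sample.

Significance is Monte-Carlo: the default scheme permutes whole
*individuals* across the sampled locations, rebuilding all pairwise
genetic distances, refitting the IBD regression and re-kriging each
replicate (the kriging operator depends only on geography, so each
replicate costs one triangular solve). Permuting individuals rather
than single residuals preserves the dependence created by each
individual entering many pairs; on spatially random and pure-IBD
synthetic landscapes the masks then cover ≈1–5% of cells at α = 0.05,
whereas residual-level permutation (available as an option, along with
point resampling) is badly anti-conservative. Per cell the two-sided
p = 2·min(tail fractions) is stored and the mask splits into
significantly-low cells (population cores: neighbours more similar than
IBD predicts) and significantly-high cells (contact/transition zones),
judged against the retained-pair median residual (configurable to the
raw IBD prediction, i.e. zero).

Bounded scalars (proportion of heterozygous loci, membership
coefficients) are logit-transformed before kriging (0/1 clamped to
1/(2m) for an m-locus proportion), tested against the global median
(heterozygosity) or mean (membership) on the link scale, and
back-transformed for display. Default replicate counts follow the
study design the package mirrors: 499 for residual and heterozygosity
surfaces, 199 for membership surfaces.

Pair non-independence beyond the permutation scheme is deliberately not
corrected — the published method does not — and significant areas
should be read as descriptive mapping, not field-wise tests.

## Synthetic data generator

`generate_dataset` emulates the study design end-to-end: ~168
individuals at 15 dinucleotide loci (8-allele stepwise ladder), four
genetic groups drawn by Balding–Nichols from a shared ancestral
frequency set, group spatial centres on a 250 × 150 km landscape with
Gaussian dispersal, an island block whose group descends from a small
founder pool, and optional hybrids mixing a wolf group with a divergent
"dog" frequency set. Defaults, chosen once: ancestral frequencies
Dirichlet(0.6) (mean Hₑ ≈ 0.68, ≈6.3 observed alleles per locus — a
moderately diverse wolf panel); group F = (0.05, 0.08, 0.10, 0.12), so
realized pairwise θ spans ≈0.06–0.12; founder pool of **one breeding
pair**, matching an island recolonised by a single pack and producing
the pronounced heterozygosity deficit such populations show.
Hybrids carry wolf-side ancestry uniform on (0.6, 0.9). True labels,
frequencies, founder pools and hybrid identities travel only through
the explicit truth channel, never inside the emitted genotype matrix.

What the generator does **not** emulate: pedigree/pack structure on the
mainland, dispersal kernels, genotyping error, null alleles and allele
binning artefacts, missing data patterns, and temporal change. Passing
tests therefore demonstrate statistical correctness of the methods
under a clean spatial mixture model, not robustness to those real-data
complications.

`forward_bottleneck` is a diploid pedigree Wright–Fisher simulator
(offspring draw two parents; unlinked loci are co-inherited, which is
what creates the drift LD that the Ne estimator measures) with
IAM/SMM/TPM mutation, an Ne schedule for crashes, and either a
mutation-drift burn-in or initialisation from supplied allele
frequencies for short-horizon drift experiments.

## Problem sizes used in tests and acceptance

All stochastic checks run at desk scale, chosen as the package's test
design: θ recovery 20 replicates of 2×50 individuals; sign-test type-I
80 equilibrium replicates (120 conditioned draws per locus); bottleneck
power 6 replicates of a 95% crash; Ne CI coverage 20 replicates at true
Ne = 50; DResD null calibration 20 IBD-only landscapes at 8 km cells
with 99 permutations; island detection 10 landscape replicates at 6 km
cells with 199 permutations; exclusion calibration 500 individuals with
2000–5000 simulated genotypes. `scripts/acceptance.py` uses the full
study-scale defaults (2 km grid, 499/199 replicates, 2000 conditioned
draws per locus) where the cost is one run rather than many.

## Known limitations

* The HWE/LD Monte-Carlo tests are plain permutation tests, not the
  dememorised Markov chain of the classical software; p-values agree in
  distribution but not draw-for-draw.
* LD-Ne assumes a closed, unstructured population sampled in one
  cohort; structure or admixture biases it downward (the pooled
  landscape sample illustrates this in the worked example).
* The exclusion test's power depends on rare-allele contrast, not just
  F_ST; concentrated but overlapping source frequencies can even score
  *above* the reference average.
* Kriging fixes the variogram fitted to the observed surface for all
  permutation replicates; this makes the test a permutation test of a
  fixed linear smoother, which is exact under exchangeability but does
  not propagate variogram-estimation uncertainty.
* Nei's D between individuals saturates for non-overlapping genotypes
  (capped); the cap value only affects pairs with zero allele sharing
  across all loci, which are absent at realistic diversity.
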