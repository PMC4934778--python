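# msatland

Spatial population genetics for microsatellite data: diversity and
differentiation statistics, bottleneck and effective-population-size
inference, hybrid and migrant filtering, and spatially explicit
isolation-by-distance residual (DResD) surfaces with kriged bootstrap
significance.

The package is aimed at wildlife geneticists analysing diploid
microsatellite panels with sample coordinates — the classic design of a
carnivore monitoring study: a few hundred individuals, 10–20 loci, an
admixture Q matrix from an external clustering program, and questions
such as *is the population bottlenecked*, *what is Ne*, *are there
hybrids or immigrants*, and *where on the landscape do neighbours look
genetically unusual*.

## What it computes

* **Diversity** (`msatland.diversity`): observed and Nei's unbiased
  expected heterozygosity (Hₑ = n/(n−1)·(1−Σpᵢ²), n = gene copies),
  allele counts, rarefied allelic richness, Weir–Cockerham (1984)
  F-statistics as ratios of variance-component sums across alleles and
  loci, exact Hardy–Weinberg and genotypic linkage-disequilibrium tests
  by Monte-Carlo permutation.
* **Bottleneck** (`msatland.bottleneck`): heterozygosity-excess sign
  tests under IAM / SMM / TPM with coalescent Heq distributions
  conditioned on the observed allele count, the allele-frequency
  mode-shift test, and the Garza–Williamson M = k/(r+1) in repeat units.
* **Effective size** (`msatland.ne_ld`): single-sample LD Ne from
  Burrows' composite r², with the Waples (2006) sampling correction
  E[r²|S] and the monogamy/random-mating drift equations (Waples & Do
  2008), chi-square parametric and delete-one-locus jackknife CIs.
* **Assignment** (`msatland.assignment`): Rannala–Mountain
  posterior-predictive genotype likelihood with Monte-Carlo exclusion
  p-values (simulated reference genotypes, leave-one-out frequencies).
* **Clustering post-processing** (`msatland.structure_post`): Evanno
  ΔK, hybrid filtering by membership threshold (default q < 0.98),
  hard group assignment, PCA on centred (unscaled) allele dosages.
* **DResD** (`msatland.dresd`): individual-level Nei's D, a global OLS
  isolation-by-distance model, residuals of neighbour pairs
  (17–33 km band by default) kriged onto a grid with universal kriging
  (planar trend + fitted exponential variogram), and per-cell
  Monte-Carlo significance; the same engine maps individual
  heterozygosity and membership coefficients through a logit link.
* **Simulator** (`msatland.synthetic`): a spatially explicit landscape
  generator with known truth (Balding–Nichols group divergence, island
  founder effect, hybrids, IBD clines) and a pedigree Wright–Fisher
  forward simulator with IAM/SMM/TPM mutation — every stochastic method
  in the package is tested against it.

## Worked example

```python
import msatland as m

# a synthetic 168-wolf landscape: 16 loci, one dropped downstream
gm16, q_true, truth = m.generate_dataset(m.SimConfig(n_loci=16, seed=1))
gm = m.exclude_loci(gm16, ["L16"])

print(m.summary_stats(gm, groups=truth.group_labels).means.round(3))
est = m.ldne(gm, min_freq=0.02, mating="monogamy")
st  = m.sign_test(gm, "SMM", reps=500, seed=2)
surf = m.dresd_surface(gm, 17, 33, n_boot=499, cell_km=2.0, seed=3)
```

prints

```
        N_A    A_R    H_O    H_E   F_IS
unit
ALL   6.600  6.600  0.586  0.653  0.102
G1    2.533  2.533  0.469  0.483  0.029
G2    5.800  5.800  0.644  0.665  0.032
G3    5.133  5.133  0.583  0.576 -0.012
G4    4.867  4.867  0.609  0.603 -0.011

Ne = 56.5  parametric CI (50.9, 62.7)  jackknife CI (39.2, 81.0)
SMM sign test: 8 excess / 7 deficiency loci, expected 8.8, p = 0.429
Garza-Williamson mean M = 0.892
DResD: 1217 pairs in 17-33 km, median residual -0.057,
       3959 low / 599 high significant cells
```

Reading the numbers: the island group G1 carries the founder-effect
signature (2.5 alleles per locus and Hₑ = 0.48 against 0.58–0.67 on the
mainland); the pooled Fᵢₛ = 0.10 is a Wahlund effect of analysing four
groups together. The LD-Ne point estimate sits inside both intervals;
the equilibrium SMM sign test finds 8 excess loci where 8.8 are expected
by chance (p = 0.43, no bottleneck signal — this panel was simulated at
equilibrium). The DResD low-residual cells mark the island core and the
group interiors, where neighbouring individuals are more similar than
the global isolation-by-distance regression predicts; high cells mark
the inter-group contact zones.

The same analyses run from the shell:

```bash
msatland simulate --n 168 --seed 1 --out sim/
msatland diversity sim/genotypes.gen
msatland ne sim/genotypes.gen --mating monogamy
msatland dresd sim/genotypes.csv --table --band 17 33 --boot 499
msatland run --config pipeline.yaml     # the full orchestrated pipeline
```

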