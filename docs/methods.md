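# Methods

`equimpute` re-implements, at desk scale, an evaluation pipeline for genotype
imputation in structured livestock populations: how well can array genotypes
of a target breed cluster be imputed to sequence level from a multi-breed
whole-genome reference panel, how should that panel be composed, how much
information do array, imputed and sequence panels share, and when can a
missing-homozygosity scan prove that a HIGH-impact variant is a recessive
lethal.  This note records the models, the defaults and why, the numerical
choices, and what the synthetic data do and do not show.

## Synthetic population model

Real multi-breed sequence panels are replaced by a generator with the
statistical structure the downstream analyses rely on.

**Allele frequencies.** Ancestral frequencies are drawn from a
Beta(0.5, 0.5) site-frequency spectrum (clipped to [0.02, 0.98] so sites are
rarely monomorphic everywhere), giving the U-shaped folded spectrum typical
of sequence data.  Each breed's frequencies follow the Balding-Nichols
model: `p_b ~ Beta(p(1-F)/F, (1-p)(1-F)/F)`, with divergence `F` increasing
over three relationship tiers around the target cluster (defaults 0.02 /
0.12 / 0.30 for tiers 1 / 2 / 3).  No quantitative between-breed divergence
was available to match, so the tier values were chosen once to produce clear
but not caricatured separation: tier 1 resembles closely related warmblood
lines, tier 3 clearly distinct breeds.

**Linkage disequilibrium.** Haplotypes are mosaics of 20 breed-founder
haplotypes: segment lengths are exponential with mean `1 Mb / recomb_rate`,
founder choice is uniform per segment, and a 0.2% per-site mutation flip is
applied.  Shared founder segments give within-breed LD and the haplotype
sharing the copying model needs; across breeds only frequencies are shared.
A consequence worth knowing: founder sampling adds drift of order
`1/(2*20)` on top of `F`, so realized FST in mosaic mode exceeds the nominal
`F`.  The generator therefore also offers `ld_mode="independent"`
(site-independent draws), which realizes the Balding-Nichols FST exactly and
is what the calibration tests use; everything involving imputation uses the
mosaic mode.

**Default profile.** 2 chromosomes x 10 Mb, 20,000 polymorphic sites, 120
samples: 65 target-cluster animals (five cross-validation folds of 13), 30
related, 25 distant.  Marker panels are drawn MAF-weighted without
replacement: 3,600 high-density sites and a nested 400-site medium panel
(the ~1:9 density ratio of the emulated 670K and 60K arrays), excluding a
1-Mb array coverage gap on chromosome 1 (arrays have such gaps in reality).
A fraction of sites (default 0.1%) is labelled HIGH impact.

**Planted lethal.** A recessive lethal with zero alternate homozygotes is
planted by conditional sampling: each in-scope individual is a heterozygous
carrier with probability `2q`, redrawn (bounded retries) until the realized
frequency is within 10% of the target.  Naive rejection of random genotype
columns is astronomically unlikely to produce zero homozygotes at, say,
q = 0.3 in 2,000 animals, which is exactly the regime the detection test
needs.  Frequencies above 0.5 are infeasible (zero homozygotes caps the
allele frequency at 0.5) and raise a configuration error.

All randomness flows from one seed through named substreams
(CRC32-hashed stream names in the SeedSequence spawn key), so outputs are
byte-identical across runs and insensitive to reordering of stages.

## Relationship tiers and reference panels

Pairwise distance is `1 - IBS` on the medium-density markers,
`D = 1 - mean((2 - |g_a - g_b|)/2)` over sites called in both samples —
the same quantity PLINK's MDS consumes.  Classical (Torgerson) scaling
double-centers `-D^2/2` and takes the top-k eigenpairs; negative eigenvalues
(expected for IBS matrices, which need not be Euclidean) become zero-width
dimensions rather than errors.  The original study assigned tiers visually
from the MDS plot; here that step is reproducible: tiers are centroid-radius
shells around the target cluster in the first two dimensions, with inclusive
boundaries and defaults `t1 = 1.1 x` the maximum target-to-centroid distance
and `t2 = 3 t1`.  The dimensions and radii are declared choices, not values
inferred from data.  RP1 = tier 1, RP2 = tiers 1-2, RP3 = all samples, so
the nesting RP1 ⊆ RP2 ⊆ RP3 holds by construction.

## Haplotype-copying imputation

The imputer is a diploid Li-Stephens HMM over ordered pairs of the K
reference haplotypes.  Per chromosome copy and per interval of genetic
length `d` Morgans (constant map, default 1 cM/Mb), the copy switches to a
uniformly chosen haplotype (including itself) with probability
`theta = 1 - exp(-4 Ne d / K)`; `Ne` defaults to 1000, the value the
original analyses passed to their imputation software.  At a typed site each
copied allele is read through an error channel with mismatch probability
`err = 1e-3`, and the observed unphased genotype is the sum of the two read
alleles; untyped or missing sites emit nothing.  Posterior dosages
`E[a1 + a2 | data]` and variances come from forward-backward.

Numerical structure: the per-copy transition is `(1-theta) I + (theta/K) J`,
so a pair-state update is `c^2 F + cd(r 1' + 1 s') + d^2 S` — O(K^2), not
O(K^4) — and these operators compose exactly across unobserved sites, so the
chain is run over typed sites only and posteriors at untyped sites are
bridged by propagating the flanking forward/backward matrices.  `theta` is
clipped to `(min_switch, 1 - 1e-12)`: the floor keeps coincident positions
from freezing the chain, the cap keeps the log-survival bridging finite when
`Ne * d` is huge.  Dosages are clipped to [0, 2] against floating-point
overshoot.  Targets are imputed independently given the reference, so
results cannot depend on target processing order.

This is a deliberate simplification of production imputation software (no
haplotype clustering, no pre-phasing stage, fixed `err`), adequate as a
reference implementation whose exactness is provable: forward-backward
dosages are checked against exhaustive enumeration of all haplotype-pair
copying paths for K <= 4, M <= 6 over 50 random instances at 1e-8.

**DR2.** Per variant, `DR2 = Var(ds) / (Var(ds) + mean(post_var))` across
samples, clamped to [0, 1], with 0/0 defined as 0 — the estimated-over-total
dosage variance ratio.  Production imputers compute version-dependent
variants of this quantity; the ratio form is the documented contract here.

## Cross-validation scenarios and accuracy

The target cluster is split into five folds by a seeded permutation cut into
contiguous blocks (65 animals -> five folds of 13).  Scenario knobs follow
the study design: reference = the cyclically following 2, 3 or 4 folds of
the target cluster, or all remaining folds plus the tier-2 (RP2) or
tier-2+3 (RP3) samples; target genotypes masked to the medium or high
panel; a two-step variant imputes medium -> high using the previous two
folds as high-density reference, optionally drops step-one sites with
DR2 < 0.4, rounds step-one dosages to best-guess genotypes (the HMM consumes
hard genotypes; dosage-aware emission would be an extension), and imputes
high -> sequence using the following two folds.

Accuracy `r` per variant is the Pearson correlation between true genotypes
and dosages pooled over validation samples; exclusions are evaluated per
validation fold: multiallelic sites, and sites where the truth or the
dosages are constant within any single fold (`no_variation_obs` /
`no_variation_dosage`, checked in that order).  MAF is computed from the
RP1 sequence genotypes only.  Aggregation reports unweighted means of
included `r` overall, per chromosome, per 1-Mb window and per half-open MAF
bin (x, y], plus an OLS of mean window accuracy on window marker density
(slope, intercept, adjusted R^2); windows without included variants are
omitted.

**Problem sizes.** The trend checks in the test suite run a reduced profile
— 2 x 5 Mb, 6,000 sites, 80 samples (40-animal target cluster, folds of 8),
one validation fold, three seeds — chosen as the package's test-scale
configuration; the trends it asserts (accuracy non-decreasing in reference
fold count, high > medium density, accuracy increasing with MAF, distant
reference not helping) are qualitative and hold on every seed.  Absolute
accuracies at this scale (~0.6-0.95 depending on density) are not comparable
to any real-data figure: marker densities, LD extent and panel sizes all
differ by orders of magnitude.

## Information content (MC-ANOVA)

The proportion of variation in panel A explained by panel B is estimated by
Monte Carlo: draw a focal variant uniformly from A's polymorphic sites,
regress its centered genotype vector on the centered B genotypes within
±0.5 Mb (same chromosome), record adjusted
`R^2 = 1 - (1 - R^2)(n-1)/(n-p-1)` floored at 0 and capped at 1, and average
over 300 replicates with a Monte Carlo standard error.  When the local
window holds more than `n - 2` predictors they are screened to the `n - 2`
most correlated with the focal variant; an empty window contributes 0; exact
fits (residual below `1e-10` of the total sum of squares) snap to exactly 1,
which makes self-explanation and subset-explanation exactly 1.0 rather than
1-minus-roundoff.  The focal variant, when present in B, is its own
predictor — that is what "B contains A's variation" means here.  Adjusted
R^2 is near-unbiased at zero under independence, so unlinked panels score
~0 (flooring at 0 leaves a small positive bias, bounded in the tests at
0.1 with n = 100).  The cited source for the idea gives no procedural
detail, so window width, screening cap and adjustment are this module's
declared choices; real-data percentages are not claimed reproducible.

## Missing-homozygosity scan

For each biallelic HIGH-impact variant, the cohort minor allele frequency
`q` is estimated from the same cohort's allele counts (a documented
circularity: carriers contribute to `q`), and the observed count `k` of
minor-allele homozygotes among `n` genotyped animals is tested one-sided
against Binomial(n, q^2) — `p = P(X <= k)`, with the exact closed form
`(1 - q^2)^n` at `k = 0`.  Bonferroni correction multiplies by the number of
tested variants (each variant once, regardless of how many genes it
annotates to) and clamps at 1.  The scan also reports the largest `q` among
zero-homozygote variants, the quantity that says how close the cohort came
to a provable lethal.

The design calculators invert the `k = 0` closed form: the smallest `n` with
`(1 - q^2)^n <= alpha/m` (boundary verified by stepping both ways across the
analytic solution) and the smallest detectable `q* = sqrt(1 - (alpha/m)^(1/n))`.
At the study's printed inputs (n = 317, m = 23,148, alpha = 0.05) these give
q* = 0.2008 and, at q = 0.1, n = 1299 — the two headline numbers
`scripts/acceptance.py` recomputes.  A degenerate level `alpha/m >= 1`
returns 0 by convention.  The one-sided "deficit" alternative is a declared
choice (the source does not state sidedness); it is the alternative that
reproduces the printed sample-size figure exactly.

## Known limitations

- The generator has no demographic realism (no migration, bottlenecks,
  admixture), no array genotyping error, and no sequencing error; passing
  trend tests show the pipeline's internal consistency, not real-data
  accuracy levels.
- The imputer is a single simplified model; contrasts between production
  tools (Beagle vs Impute vs Minimac) are out of reach by construction.
- VCF support covers GT/DS/INFO-level round-trips of biallelic-centric
  matrices; multiallelic genotypes are retained and flagged but written
  back with first-alternate coding only; no BCF, no genotype likelihoods.
- The MC-ANOVA variant is one reasonable member of a family; its absolute
  percentages depend on window width and screening choices.
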