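# Methods

This note records the models, defaults and numerical choices behind the
pipeline, what the synthetic cohort does and does not emulate, and the
known limitations.

## Data model and QC

Genotypes are alternate-allele dosages in [0, 2] (imputed dosages pass
through unrounded; VCF `DS` preferred over `GT` counts).  Coordinates
are 1-based throughout; readers reject coordinate 0.  Variant QC keeps
variants with MAF ≥ 0.01, Hardy–Weinberg 1-df χ² p ≥ 10⁻⁶ (computed on
hard calls — dosages rounded to the nearest integer for this test
only), and imputation R² ≥ 0.5 where the field exists; all boundaries
are inclusive on the "keep" side.  The GRM is VanRaden method 1 with
allele frequencies estimated from the input panel — `G = ZZ′ / 2Σp(1−p)`
with dosages centered by 2p — and the same construction serves as the
relationship matrix of the BayesR polygenic remainder (no pedigree is
available to the pipeline).  LD pruning is greedy within sliding
windows (defaults 5000 variants, step 500, r² > 0.95): the highest-r²
pair is resolved by dropping the smaller-MAF member (tie: the later
position), iterating until no in-window pair exceeds the threshold.
The dropped-member rule is our fixed convention; pruning never reorders
retained variants.

## Mixed-model machinery

All three mixed-model stages (heritability, LOCO scan, GSOR) share one
routine: eigendecompose the relationship matrix once, rotate y and the
fixed-effect design, and profile the restricted likelihood down to the
heritability ratio h² = σ²g/(σ²g+σ²e), which is maximized by bounded
scalar search on [10⁻⁸, 1−10⁻⁸] (tolerance 10⁻⁹) with an explicit
endpoint check.  Non-negativity is enforced by the bound itself.
se(h²) uses the numeric Hessian of the unprofiled restricted likelihood
in (σ²g, σ²e) (central differences, step 10⁻⁴ of the total variance)
and the delta method; a singular information matrix yields NaN rather
than an arbitrary number.  Fixed effects and per-variant substitution
effects come from GLS in the rotated basis; association p-values are
Wald 1-df χ² — cheaper than likelihood ratios and asymptotically
equivalent, at the price of mild anticonservativeness at small n (at
n = 150 the null rejection rate at 0.05 is ≈ 0.06; see the calibration
tests).  Variance components are re-estimated for every
leave-one-chromosome-out GRM, and missing phenotypes are handled
complete-case per trait.  Outlier removal is single-pass: mean and SD
(n−1 denominator) are computed once over non-missing records and values
beyond k·SD (default k = 4) are set missing — survivors are not
re-screened.

Genomic inflation transforms p-values to 1-df χ² quantiles and divides
the observed median by 0.4549364 (the exact null median).  FDR control
is Benjamini–Hochberg step-up via statsmodels, applied per trait.

## Meta-analysis

The trait correlation **V** is the Pearson correlation of signed
t-values over **all** variants, not a null-restricted subset — the
faithful choice given how the statistic is defined; with strong shared
signal this slightly deflates the statistic.  Variants missing in any
trait are dropped (the quadratic form needs a complete vector).  An
optional ridge (off by default) renormalizes **V** after adding λI;
with ridge 0 a condition number above 10¹⁰ is an error rather than a
silent near-singular solve.

## BayesR

The reference single-site Gibbs scheme: mixture variances
(0, 10⁻⁴, 10⁻³, 10⁻²) × σ²g where σ²g is the *current sampled* genetic
variance, starting proportions (0.994, 0.0055, 0.00049, 0.00001),
Dirichlet(counts + 1) proportion updates, scaled inverse-χ² draws for
σ²g, σ²e and the polygenic σ²a (prior df 4; prior scales 0.5, 0.5 and
0.1 × phenotypic variance), polygenic values sampled through the
eigendecomposition of the relationship matrix, and flat-prior Gaussian
fixed effects.  The σ²g prior scale matters: anchored too low, the
chain can freeze in an all-null state where the mixture variances are
too small for a true effect to re-enter; 0.5 × var(y) keeps the
non-null components on a usable scale while the mixture still shrinks
null SNPs.  Under a null trait the mixture labels are unidentifiable —
σ²g collapses, every component is a near-point-mass at zero and the
proportions wander over the simplex — so null behavior should be read
from the effects (all ≈ 0), not from the null-component proportion.
Desk-scale default chains are 5000 iterations / 2500 burn-in
(50,000/25,000 available via config; the pipeline drivers use
2000/800, which recovers planted architecture on the fixture).  The
per-SNP sweep is numba-compiled; chains are reproducible under the
spec seed.

Local GEBVs sum dosage × posterior-mean effect over SNPs within ±1 Mb
of the gene's TSS (strand-aware: start on +, end on −, start when
unknown; both window ends inclusive).  Genes with no in-window SNP are
flagged and excluded from downstream testing and from the background
count.

## GSOR

Per gene and trait a full mixed model is refit (response local GEBV;
fixed effects intercept, expression, cohort covariates; polygenic
effect on the expression cohort's GRM), rather than sharing a variance
ratio across genes — the model is per-gene by definition.  Hits are
genes at per-trait BH FDR ≤ 0.01.  Genes with constant expression or
failed REML are dropped from the tested set.  Expression rescaling
changes b₁ inversely but not its p-value.

## Windows, overlap and enrichment

Windows are 1-based inclusive [1, W], [W+1, 2W], …; the final partial
window is kept; a coordinate exactly at a multiple of W belongs to the
earlier window.  Genes are assigned by their start coordinate.  The
overlap table is (hit vs non-hit tested gene) × (inside vs outside
marked windows); the enrichment table compares hits-inside-marked
against **all** tested genes (hits are not removed from the
background — the published margins overlap, and we reproduce that
convention).  Fisher's exact test uses the minimum-likelihood two-sided
convention (sum of same-margin table probabilities ≤ the observed
point probability).  Two odds ratios are emitted: the cross-product
ad/bc (∞ when bc = 0 with ad > 0, NaN for 0/0) and the conditional-MLE
OR; the two-decimal headline display truncates the conditional-MLE OR,
the rule that reproduces all four published worked-example values.

## Synthetic cohort

The generator emulates the study design at desk scale: a GWAS cohort
(default 400) and a disjoint expression cohort (default 150) drawn from
one founder pool; 3 chromosomes × 2000 variants (the analysis drivers
use 1200) as mosaics of 12 founder haplotypes with breakpoint rate
5 × 10⁻⁶/bp, giving block LD that decays over roughly 200 kb; 60 genes
of which 5 are mediating — each has a cis variant within ±1 Mb of its
TSS driving expression (effect magnitude ≈ 1 SD, random sign) and
trait effects through the genetic part of expression; 3 direct QTLs;
a diffuse polygenic term (300 variants, effect SD 0.02); a batch-year
factor with 9 levels (effect SD 0.5) in the GWAS cohort and an
experiment factor (5 levels) plus days-in-milk in the expression
cohort.  Environmental noise is rescaled so the realized variance-ratio
heritability equals the target exactly; default targets span 0.07–0.7.
One non-mediating gene per confounding pair is placed **adjacent** to a
mediating gene with expression correlated 0.5 — reproducing the
coexpression/shared-window false-hit mode of expression-based
prioritization, which the test suite asserts occurs in a nontrivial
fraction of seeds rather than hiding it.  A synthetic
"lipid_metabolism" term contains every mediating gene plus 15% of the
rest.

What the generator does **not** emulate: realistic cattle demography or
mutation/recombination maps, sequence-scale variant density (14M
variants), trans-eQTLs, expression count noise, or 56-trait phenotype
panels (supported via config, defaults are 3–6 traits).  Passing tests
therefore demonstrate correctness and calibration of the machinery on
mediated architectures with block LD — not performance claims at
genome scale.

## Problem sizes and determinism

Test and driver problem sizes are chosen so the full suite and the
acceptance script each complete in minutes on one CPU: cohorts of
150–500 samples, 3000–10,000 variants, chains of 2000–5000 iterations
(30,000 for the ridge-equivalence check, where the autocorrelated
chain's Monte Carlo error otherwise dominates).  Every stochastic
component draws from an explicit seed; the pipeline splits one master
seed per stage, and rerunning with the same seed reproduces reports
bit-identically.

## Known limitations

- Wald tests are mildly anticonservative at small cohort sizes (see
  calibration above); likelihood-ratio or exact tests are not offered.
- The BayesR genetic variance follows a heavy random walk when the
  data carry little signal; only effect summaries are meaningful there.
- The LD-pruning tie-break and the greedy window order are fixed
  conventions; other tools' retained sets can differ on ties.
- Single-tissue, cis-only: trans effects and multi-tissue joint models
  are out of scope.
- The enrichment stage takes a user-supplied gene→term table; no
  ontology-graph propagation or multi-term correction is performed.
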