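# Methods

`riskloci` integrates case/control GWAS summary statistics with expression
and methylation evidence to nominate risk loci and their target genes.  It
consumes only summary-level GWAS data plus a genotype reference panel for
linkage disequilibrium (LD), and ships a synthetic-cohort module so that
every stage can be validated against known ground truth.

## Risk-locus construction

GWAS summary lines carry an odds ratio (OR) and a p-value per SNP.  ORs are
folded onto the risk scale, `OR* = max(OR, 1/OR)`, so risk and protective
alleles are comparable in magnitude; a signed z-score is reconstructed as
`|z| = Phi^-1(1 - p/2)`, `sign(z) = sign(ln OR)`.  The GWAS input states
direction only through the OR, so this z is a reconstruction: any
monotone-consistent signing would give the same region statistic (which
uses z^2) and the same SMR magnitudes.

Subthreshold SNPs (`p < 1e-3`) anchor candidate loci: a SNP is an **index
SNP** if its folded OR is maximal among subthreshold SNPs within ±100 kb on
its chromosome, and its locus spans the index position ±100 kb (1-based
inclusive; 200,001 bp wide).  Ties on the folded OR break to the smaller p,
then the smaller position, making the construction deterministic.
Overlapping loci are expected and retained; only exactly identical
intervals are de-duplicated.  Windows are not clipped at chromosome ends
unless a chromosome-length table is supplied (synthetic coordinates never
need it).  Loci are flagged as previously reported when their interval
expanded by 500 kb intersects a known-locus interval, and genes
(protein-coding only) are attached by interval overlap.

## Region association statistic

For a locus with member z-scores `z_1..z_m` and LD matrix `R` (Pearson
correlation of reference-panel dosages, ridge 1e-6 on the diagonal), the
region statistic is the SNP-wise sum of chi-squares

    S = sum_i z_i^2 ,   null:  z ~ MVN(0, R)  =>  S ~ sum_i lambda_i chi2_1

with `lambda_i` the (zero-floored) eigenvalues of `R`.  This is the
"snp-wise mean" family of multi-marker region models; the model name is
recorded in the scan metadata.

The tail probability `P(sum lambda_i chi2_1 >= S)` is computed by:

- an **exact scaled chi-square** when all positive eigenvalues are equal
  (identity LD reduces exactly to the central chi2_m tail);
- **Imhof characteristic-function quadrature** otherwise, which is
  essentially exact and monotone in S down to ~1e-10;
- the **Lugannani–Rice saddlepoint** beyond that, capped at the hand-off
  level so the p-value remains nonincreasing in S.  The saddlepoint keeps
  relative error within a few percent arbitrarily far into the tail.

A Liu three-moment match (`method="moment"`) is retained for fast
approximate scoring.  Three-moment fits are accurate in the body of the
distribution but can understate weighted-chi-square tails several-fold at
p ~ 1e-6 when the eigenvalue spectrum is skewed (for nonnegative weights
the skewness-matching branch always engages, by Cauchy–Schwarz), which is
why the default route switches to quadrature/saddlepoint; the accuracy
tests pin both analytic routes to within 10% of the quadrature oracle for
p >= 1e-6.  P-values are clamped to (1e-320, 1].  Loci whose members are
all absent from the panel are excluded with a warning; partial absences
are counted per locus.

## Summary-based Mendelian randomization (SMR)

At a SNP shared between the GWAS and an eQTL study, the single-SNP
statistic is

    T_SMR = z_gwas^2 z_eqtl^2 / (z_gwas^2 + z_eqtl^2) ,  p from chi2_1,

bounded by the weaker of the two signals, with the ratio estimate
`b_xy = b_gwas / b_eqtl` of the effect of expression on the trait.
Candidate genes lie within 1 Mb of a locus.  The multi-SNP statistic sums
T_SMR over all eQTL SNPs with `p_eqtl < 1e-3`, greedily LD-pruned at
`r^2 <= 0.9` in ascending-p order.

Its p-value is a seeded Monte Carlo under the strong-instrument null: with
a genuine eQTL and no mediated GWAS effect, each per-SNP T_SMR is
asymptotically the GWAS chi-square, so null replicates draw
`z ~ MVN(0, R_set)` once per replicate and use `t_null = sum z_i^2`,
preserving the LD correlation between per-SNP statistics;
`p = (1 + #{t_null >= t_obs}) / (n_null + 1)` with `n_null = 10,000` by
default (Monte Carlo floor ~1e-4).  A paired null that also redraws the
eQTL z-scores was considered and rejected: it makes T_SMR stochastically
smaller than chi2_1, is anticonservative under the realistic null, and
breaks the exact single-SNP reduction to the closed form.  No
HEIDI-style heterogeneity filter is applied.

Multi-SNP p-values are Bonferroni-adjusted; the multiplier defaults to the
number of (locus, gene) pairs with a finite p in the run (an explicit
override is accepted), and genes with adjusted p < 0.05 are the target
susceptibility genes.  Genes with no eQTL SNP below threshold are skipped
with a reason code rather than penalizing the multiplier.

eQTL mapping itself is ordinary least squares of expression on dosage with
covariates (both sides residualized on the covariate design;
Frisch–Waugh–Lovell), p-values from the t reference with residual degrees
of freedom; `z_eqtl = slope/se` regardless.

## Corroborating evidence

**Differential-expression meta-analysis.**  Per-study effects are Hedges g
(standardized mean difference with small-sample correction
`J = 1 - 3/(4(n1+n2-2)-1)`) with variance
`v = (n1+n2)/(n1 n2) + g^2/(2(n1+n2))`; pooling is DerSimonian–Laird:
`Q` from inverse-variance fixed weights,
`tau2 = max(0, (Q-(k-1))/(sum w - sum w^2/sum w))`, random weights
`1/(v+tau2)`, normal reference for the pooled p (no t correction), and
`ci95 = pooled ± 1.96 se`.  The pooling code is scale-agnostic given
(effect, variance) pairs; Hedges g is the pinned scale for the synthetic
studies because heterogeneous published differential-expression outputs
have no common reported scale.

**Methylation screen.**  Each probe's beta value is regressed on the
binary group plus covariates (sex, race in the synthetic data); the group
coefficient's two-sided t-based p is screened at 1e-6.  Methylation stays
on the beta scale by default with an optional logit (M-value) transform.
Constant probes yield p = NA and are excluded from the screen with a
count.

**Co-expression.**  Pearson correlation over shared samples with the
t-transform p on n-2 df, and an optional `log2(x+1)` pre-transform for
count-scale input.

## Synthetic cohorts

The generators are pure functions of (parameters, seed); a single pipeline
seed fans out to per-stage child seeds by fixed offsets.

- **LD panel** — haplotypes from a latent Gaussian AR(1) process
  (adjacent-SNP correlation `rho`, default 0.8), thresholded at a MAF
  drawn uniformly from (0.05, 0.5); two haplotypes sum to a dosage.
  Positions take exponential gaps (mean 5 kb).  This reproduces the
  block-correlation structure the statistics consume; it does not model
  recombination hotspots, demography or imputation error, so passing
  tests certify the statistics' behavior under block LD, not under any
  particular human LD landscape.  Monomorphic draws are rejected and
  redrawn (bounded retries) so panels never carry constant columns.
- **GWAS summary statistics** — `z ~ MVN(R lam, R)` at the z level with
  `lam` loaded on causal SNPs, ORs reconstructed as `exp(z * se_nominal)`
  (nominal se 0.05, a typical per-allele standard error for a
  several-ten-thousand-sample case/control study) so fold/quantile round
  trips hold.  Individual-level case/control sampling is deliberately
  skipped: the pipeline consumes only summary statistics and this is the
  standard null/alternative for LD-aware region tests.
- **eQTL cohort** — expression = slope·dosage + covariates + Gaussian
  noise scaled so the causal SNP explains `h2_like` of the variance
  (default 0.1, a strong brain cis-eQTL); covariates are age, post-mortem
  interval and sex.  The panel samples double as the cohort genotypes, so
  one simulated cohort serves as both LD reference and eQTL study.
- **Scenarios** — `pleiotropy` shares the causal SNP between GWAS and the
  eQTL gene G1; `linkage` places the eQTL at a distinct SNP chosen to
  have empirical LD closest to a target r (default 0.4); `null` has no
  eQTL gene.  Remaining genes are expression noise; gene spans scatter
  within 1 Mb of the causal position so they are candidates of the
  resulting locus.
- **Expression studies** — study i draws its true effect from
  `Normal(true_smd, tau^2)` and case/control samples from unit normals
  separated by it (defaults: 9 studies, ~32 cases/38 controls each,
  matching the scale of a typical published brain cohort collection).
- **Methylation** — latent Gaussian M-like values mapped through the
  logistic into (0,1); designated probes carry the case shift; an
  optional confounder ("race") tracks the group label and shifts every
  probe, so adjusted and unadjusted scans can be contrasted.

## Pipeline

`run_pipeline` executes simulate → build-loci → region-test → eqtl → smr →
meta → dmp → enrich from a strictly validated YAML/pydantic config
(unknown keys rejected; thresholds range-checked before any compute).  All
thresholds default to the analysis conventions above (subthreshold 1e-3,
radius 100 kb, region alpha 5e-8, eQTL threshold 1e-3, pruning r^2 0.9,
known-locus margin 500 kb, gene window 1 Mb, target alpha 0.05, DMP screen
1e-6).  SMR runs over all built loci by default (`smr_scope: all`):
prioritization is already Bonferroni-gated by the SMR stage, and gating on
region significance would make target recovery hinge on the region test's
power at the configured alpha; `smr_scope: significant` restores the
stricter behavior.  The run directory receives per-stage TSV/BED outputs,
a `report.json` validated against the shipped schema, and a log with
seeds, thresholds and stage timers.  Re-running an identical config and
seed reproduces the outputs byte-identically (timestamps live only in the
log).  "Colocalized" SNPs are a threshold overlap flag (GWAS p < 5e-8 and
eQTL p < 1e-3), not a colocalization posterior.

## Numerical choices and degenerate inputs

- p = 0 on input is clamped to 1e-300 with a warning (the quantile must be
  finite); region p-values clamp to (1e-320, 1].
- Duplicate SNP ids keep the smallest-p record (deterministic, favors the
  strongest signal).
- Allele harmonization flips the eQTL slope sign for swapped allele pairs,
  drops strand-ambiguous (A/T, C/G) and non-single-base records with
  counts, and is involution-safe.
- LD ridge 1e-6 with eigenvalue flooring handles rank-deficient panels;
  matrices built from an explicit correlation matrix take no ridge, so
  exact reductions stay exact.
- Rank-deficient covariate designs and constant dosage columns raise
  errors naming the offending columns/SNPs.

## Problem sizes used in validation

The shipped checks use panels of 100–500 samples and 5–60 SNPs, 2000-draw
null calibrations, 10,000-draw Monte Carlo SMR nulls, 20-replicate
recovery and family-wise-error runs, and 5000-probe methylation nulls —
sizes at which every oracle (quadratic brute force, full hypergeometric
enumeration, characteristic-function quadrature, textbook
DerSimonian–Laird) is itself cheap to evaluate exactly.

## Known limitations

- The region model is the sum-of-chi-squares member of the multi-marker
  family; principal-components regression variants and conditional/joint
  analysis are out of scope.
- No genotype imputation, build liftover, allele-frequency-based strand
  resolution, LD clumping by r^2, or multi-tissue eQTL meta-analysis.
- The Monte Carlo SMR p has a floor of 1/(n_null+1); Bonferroni-adjusted
  values inherit it.
- Counts and p-values reported by the original consortium-scale analyses
  depend on restricted-access data and are not reproduction targets of
  the synthetic validation.
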