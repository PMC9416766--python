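# Methods

## The analysis in one paragraph

The package re-creates, on synthetic populations, the complete quantitative
genetics workflow of a national dairy evaluation: construct derived traits
(conception status, herd-life) and contemporary-group keys from raw
records; predict breeding values with a multi-trait individual animal model
(BLUP) over the pedigree relationship matrix; estimate the genetic (G) and
environmental (E) covariance matrices among traits by REML; translate an
economic index into expected genetic change per trait through
selection-index theory and compare against the realized trends estimated by
regressing cow EBVs on birth dates; and test per-marker effects on sire
evaluations with a mixed-model (EMMAX-style) association scan.  The shipped
reference parameter set is the published Israeli-Holstein first-parity
estimate for cows born 2008–2016 (`herdtrend.tables`).

## Pedigree algebra (`pedigree`)

Inbreeding is computed by the Meuwissen–Luo device (accumulating the L-row
of A = LDL' per animal), the dense relationship matrix by the tabular
method (kept as an exact oracle, refused above 2,000 animals), and the
sparse A-inverse by Henderson's rules with Mendelian-sampling variance
d_i = 1/2 − (F_s + F_d)/4 (3/4 − F/4 with one parent unknown, 1 with both
unknown).  Unknown-parent groups follow the Westell/Quaas–Pollak
construction: a group column substitutes for the missing parent in the
±α/2, α/4 contribution pattern while d_i keeps its unknown-parent value,
because groups are population means rather than sampled individuals; group
inbreeding is fixed at 0.  The grouped matrix is singular on its own (rows
sum to zero); data in the mixed-model equations restores solvability, and
the direct solver falls back to a least-squares solution when groups remain
confounded with other fixed effects.  Relationship blocks among arbitrary
animal subsets are obtained by solving A⁻¹X = E_subset with a sparse LU
factorization, which scales far beyond the dense limit.

## Derived traits (`traits`)

* **Conception status**: CS = 100 / (number of services to conception).
  Cows censored before conception get CS = 100 / (observed services + 1/p)
  with p the herd's empirical per-service conception rate (global rate as
  fallback) — the geometric-expectation model is the minimal process
  consistent with a per-service rate; national imputation factors are not
  public.
* **Herd-life**: days from first calving to culling; live cows receive the
  observed days plus the Kaplan–Meier restricted-mean residual life fitted
  (via lifelines) to the culled cows in the same data set.
* **Herd-year-season**: April–September is season 1 of the calendar year;
  October–March is season 2 *of the year containing the October*, so each
  class is one contiguous six-month block.  The January–March convention is
  a package choice; the alternative (assigning them to their own year)
  would merely relabel classes.
* **Pre-adjustment** removes covariate-class effects (calving/birth month,
  days open) by joint least squares on class indicator dummies, pooling
  classes under 5 records into their sort-order neighbor and recentering to
  preserve the overall mean; national adjustment factors are unpublished,
  so within-data estimation stands in for them.

## BLUP (`blup`)

Henderson's mixed-model equations are assembled sparsely: one-hot fixed
effects (the first effect keeps all levels, later effects drop their
reference level), per-record residual precision equal to the inverse of the
observed submatrix of E (the exact treatment of missing traits), and
A⁻¹ ⊗ G⁻¹ on the genetic block with group columns appended.  Solvers:
sparse LU (with an lsmr least-squares fallback for singular grouped
systems) and Jacobi-preconditioned conjugate gradients.  Reliabilities are
exact, r² = 1 − PEV/G_tt with PEV from the dense inverse of the coefficient
matrix, deliberately restricted to desk-scale systems instead of a
large-scale approximation.  Parity evaluations combine with normalized
non-negative weights (default 0.5/0.3/0.2 for parities 1–3, a configurable
stand-in for the unpublished national weights).  Realized genetic trends
are ordinary least-squares slopes of EBV on birth date, converted to
per-year units, with their standard errors.  A dense GLS implementation of
the same model ships alongside purely as a validation oracle.

## REML (`reml`)

The engine works in the eigenspace of the relationship matrix among
recorded animals: with A = UΛU′, rotated records are independent with
per-record covariance V_k = λ_k G + E, making the restricted likelihood and
its derivatives O(n·t³) per iteration after a single eigendecomposition
(reusable across simulation replicates).  This rotation requires complete
multi-trait records per animal, matching the complete-case edit used for
the nine-trait national analysis; partial records are dropped by the
table-level wrapper.  Updates:

* **EM** — the classical EM-REML step, provably non-decreasing in the
  restricted likelihood (asserted to 1e−8 in tests);
* **AI** — average-information quasi-Newton on the vech(G), vech(E)
  parameters with step halving back to an EM step on failure; approximate
  standard errors come from the inverse AI matrix at convergence;
* default **em-then-ai** runs 10 EM warm-up iterations first, the standard
  remedy for AI divergence far from the optimum.

G and E are floored to positive semi-definite after every update
(eigenvalue clipping at 1e−8 × trace), so heritabilities stay in [0, 1] and
derived correlations in [−1, 1].  Convergence is declared when the maximum
relative parameter change drops below the tolerance (1e−6 default).

Derived parameters: h² = G_tt/(G_tt + E_tt); r_g = G_ab/√(G_aa G_bb);
phenotypic correlations from P = G + E.  The parameter-table writer places
heritabilities on the diagonal, genetic correlations above and — by default
— phenotypic correlations below, because the published sub-diagonal values
labelled environmental reconcile numerically with phenotypic correlations
(milk–protein: 0.90 phenotypic vs 0.96 environmental-only); both are
available.

## Selection index (`index`)

Fractions, expected gains, the total gain and the intensity calibration are
the closed-form expressions given in the README.  Expected gains are
interpreted over the same horizon as the realized trends they are compared
with (a decade for the shipped parameter set); the intensity is never
hard-coded — 3.02 is stored as the published calibration and can be
re-derived from the realized total gain.  Traits with zero weight stay in
every vector because correlated response is exactly the point of the milk
row.  The standardized discrepancy d_j = s_j(realized_j − Φ_j)/g_j flips
sign (s_j = −1) for traits where lower is better, so positive always means
"realized beat expectation in the desired direction".

## GWAS (`gwas`)

Call-rate QC (> 0.90), IBS kinship K_ij = mean(1 − |d_i − d_j|/2) with
pairwise-complete SNPs, single-component genomic REML on the eigenspectrum
of K (grid plus bounded refinement over log δ; pseudo-heritability
1/(1+δ)), and a two-stage scan: variance components fixed at the null fit,
per-SNP generalized least squares in the rotated space with per-SNP
mean-imputed missing dosages and t-distributed p-values on n−2 degrees of
freedom.  The response is the sire evaluation itself (no deregression or
reliability weighting), mirroring how the bull cohorts are analyzed;
monomorphic SNPs are flagged and excluded from the p-value set; Bonferroni
controls the experiment-wise level.  The cross-trait comparison regresses
allele-substitution effects of one trait on another over SNPs with
MAF > 0.10 (optionally the top-k by significance), the marker-level
counterpart of a genetic correlation.

## Synthetic populations (`simdata`)

The generator emulates the data structures the analyses assume, at the
published parameter values:

* **Pedigree**: discrete generations, hierarchical matings (each sire with
  `dams_per_sire` dams, `progeny_per_dam` offspring each), random 50/50
  sex, herds assigned to females, birth years spread over the configured
  span; optionally a fraction of non-founders has sire, dam or both
  blanked.
* **Breeding values**: gene-dropped with founder covariance G and
  Mendelian-sampling covariance (1/2 − (F_s+F_d)/4)·G; unknown parents are
  drawn as phantom founders, consistent with the genetic-group model
  downstream.
* **Phenotypes**: parity shift + herd-year-season effect (per-trait SD
  defaulting to 10% of the phenotypic SD) + breeding value + residual with
  covariance E; cows survive to the next parity with probability
  1 − cull_hazard (default 0.3), so missingness is monotone by
  construction.  Freshening is ~2 years after birth with a ~13-month
  calving interval.
* **Inseminations**: per-service Bernoulli conception with probability
  logistic(logit(0.5) + k·u_CS + herd effect); the slope k is calibrated by
  Gauss–Hermite quadrature so the population SD of each cow's expected CS
  equals the genetic SD of CS (√62.1 for the reference set), because the
  trait-scale variance, not the service-level process, is what is
  published.  Sequences stop at conception or are censored at
  `max_services` (8); culling acts between parities, not within an
  insemination sequence.
* **Genotypes**: founder frequencies uniform on `maf_range`, Mendelian
  allele transmission, and `n_causal` SNPs whose effect pairs are rescaled
  so the expected causal covariance under founder Hardy–Weinberg equals the
  protein/CS G-submatrix.

All randomness derives from one integer seed through named, order-stable
streams, so each stage is independently reproducible and full runs are
bit-identical.

What the generator does **not** emulate: selection of parents on the index
(matings are random, so simulated populations have no genetic trend unless
one is injected), age structure within herds, heterogeneous variances
across herds, genotype platform mixtures, and within-parity culling.
Passing tests therefore demonstrate correctness of the estimators under the
stated model, not robustness to the selection and heterogeneity present in
real national data.

## Problem sizes used in the test suite

Oracle-equivalence checks run on random instances up to 300 equations or
300 animals, where dense linear algebra is exact and cheap.  Estimator
calibration uses populations the package simulates in seconds: REML
recovery uses ~3,000 first-parity cows on a three-cohort pedigree
(recorded dams and granddaughters, so parent–offspring covariance and
half-sib structure jointly identify the low-heritability CS components)
over 30 replicates with a shared relationship eigendecomposition; GWAS
calibration uses ~1,000 pedigreed individuals with 1,500–2,000 gene-dropped
SNPs.  Nine-trait REML is supported, but calibration experiments use the
2-trait protein/CS pair, whose parameters (h² 0.45 and 0.05, r_g −0.38) are
the scientifically interesting corner.

## Known limitations

* The REML engine's rotation requires a single genetic effect and complete
  records; models with trait-specific fixed structures or missing-trait
  patterns need the (slower) MME route via the BLUP module.
* Exact reliabilities and GWAS eigendecompositions are O(n³) and intended
  for desk-scale cohorts (thousands, not millions).
* Dystocia and stillbirth are treated as ordinary linear traits; threshold
  (liability-scale) models are out of scope, consistent with how the
  covariance components are published.
* Censored-CS imputation conditions only on the herd-year rate, not on
  parity or cow covariates.
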