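# Methods

This note documents the statistical model behind `polygbs`, the choices we
made where the design was genuinely open, the synthetic-data generator, and
the numerical conventions. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Continuous genotypes and marker filtering

GBS for a hexaploid without a reference genome yields reference/alternate
read depths per SNP but no trustworthy integer dosage. We therefore work
with the per-individual reference-allele frequency `f_ij = R_A/(R_A+R_B)`,
missing when both depths are zero. Repeated samples of the same individual
are merged *before* filtering — frequencies by averaging over the
non-missing replicates, read counts by summation — so per-marker
statistics describe the merged individual-level matrix, and the
overdispersion likelihood (below) sees each individual's full read support.

Markers are filtered conjunctively on minor allele frequency of the mean
frequency (`min(f̄, 1−f̄) ≥ maf_min`, computed before imputation so that
imputation cannot alter selection), on the per-marker mean total depth
lying in `[depth_min, depth_max]`, and on call rate (fraction of
individuals with at least one read). Defaults are MAF ≥ 0.05, depth in
[10, 200], call rate ≥ 0.7. The mean depth is averaged over individuals
with at least one read; averaging over all individuals (zeros included) is
an equally defensible convention and the two differ exactly by the call
rate factor — we expose only the non-missing mean and note the ambiguity
here. Missing entries of surviving markers are imputed by the marker mean
of the observed entries, which preserves per-marker means exactly.

## Relationship matrices and the Beta-Binomial scaling

All three scalings share `G = (F − 1 f̄′)(F − 1 f̄′)′/h`; the centering
vector is recomputed from the post-imputation matrix so every row of G sums
to zero exactly (which also makes G rank-deficient by construction; see
Numerical choices). The naive scaling `h = (1/k) Σ f̄_j(1−f̄_j)` treats
reads as error-free draws of a Binomial in the ploidy `k`. The de-biased
variant multiplies each diagonal element of the naive-scaled G by
`1 − w_i`, `w_i = (k−1)/(R̄_Ti+k−1)`, leaving off-diagonals untouched —
this deliberately breaks the zero-row-sum property.

The Beta-Binomial scaling models the latent allele-sampling probability
per individual and marker as `p_ij ~ Beta(μ_j, τ_j)` in the
mean/dispersion parameterization (`Var[p] = μ(1−μ)τ`), which yields
`Var[f_ij] = μ_j(1−μ_j)·ω_j` with `ω_j = [1+(R̄_Tj−1)τ_j]/R̄_Tj`, and hence
`h = Σ f̄_j(1−f̄_j) ω_j`. The dispersion τ_j is estimated per marker by
maximizing the Beta-Binomial log-likelihood over `τ ∈ [1e-6, 1−1e-6]`
(bounded Brent; a dense 10⁻³ grid search is the fallback and the test
oracle), with the location fixed at the observed mean frequency f̄_j
rather than estimated jointly. Entries with zero reads are excluded from
the likelihood — imputed values carry no read evidence.

Interpretation note: τ̂ absorbs **all** individual-level variation of
`p_ij` at a marker, i.e. true genotypic differences between individuals as
well as sequencing overdispersion. That is intentional — it is exactly the
variance that the scaling must account for — but it means τ̂ on a
segregating population is far above zero even with perfectly Binomial
reads. Tests that check recovery of a known τ therefore simulate directly
from the hierarchy with a common per-marker location.

## GBLUP and EM-REML

The trait model is `y = Xb + Z_m m + Z_c c + e` with trial-by-year fixed
effects (cell-means coding: one parameter per level and trait, which for a
single factor is equivalent to intercept-plus-reference-level coding and
needs no rank bookkeeping), mother genetic effects `m ~ N(0, V_M ⊗ G)`,
progeny-within-trial permanent-environment effects `c ~ N(0, V_C ⊗ I)` and
residuals coupled across traits within a record by `V_E`. All mothers with
records must be genotyped; genotyped mothers without records are carried in
the equations and receive GEBV through G. Multi-trait fits handle per-trait
missingness by building the residual precision per record from the observed
trait subset (equivalent to zero-weighting the missing traits).

The mixed-model equations are assembled sparsely and solved densely — the
package targets desk-scale problems (up to a few thousand mothers and
some tens of thousands of records), where exact dense solves and exact
trace terms are affordable.

Variance components are estimated by deterministic EM-REML: each round
solves the MME at the current components and updates

* `V_M[j,k] ← (m̂_j′G⁻¹m̂_k + tr(G⁻¹ C^{mm}_{jk}))/q`
* `V_C[j,k] ← (ĉ_j′ĉ_k + tr(C^{cc}_{jk}))/p`
* `V_E ← (Σ_r ê_r ê_r′ + W_r C⁻¹ W_r′)/N`

with `C⁻¹` the inverse coefficient matrix. A Monte-Carlo variant of these
expectations is what large-scale evaluation software uses; at desk scale
the exact traces are feasible and make the estimator deterministic and
testable (the restricted likelihood is then provably non-decreasing, which
the tests assert on every replicate). Multi-trait EM uses records complete
for the selected traits (incomplete records are dropped with a warning);
this keeps the conditional expectations exact. V_C and V_E are only
separable when some progeny-within-trial levels have repeated records; a
warning is raised otherwise. Standard errors of the REML estimates are not
computed; reports print `NA`.

The user-facing convergence tolerance is the maximum relative
round-to-round change in any component (default `1e-6`, cap 200 rounds).
EM converges slowly near the optimum; for the bundled parameter-recovery
experiments we run to `1e-5` with a 300-round cap, which the trajectories
show is past the point where estimates move by more than a fraction of
their Monte-Carlo spread.

## Derived parameters

The mother variance is a half-sib family variance, so `σ²_A = 4σ²_M`, and
because mean diag(G) is not standardized to 1 it multiplies the additive
variance: `h² = diaḡ(G)σ²_A/(σ²_M diaḡ(G) + σ²_C + σ²_e)` and
`c²` adds `σ²_C` to the numerator. `h²` is **not** clamped to [0, 1]; with
small σ²_C + σ²_e the ratio exceeds 1 (numerator uses 4σ²_M against σ²_M
in the denominator) and we report the formula value. `c² − h² =
σ²_C/denominator ≥ 0` holds exactly. Genetic correlations are the
correlations of `V_A = 4V_M` (the factor cancels); phenotypic correlations
those of `V_P = V_M + V_C + V_E`. The API accepts either mother-scale or
additive-scale inputs behind an explicit flag, because published tables
mix additive variances with mother-level covariances and an implicit
convention is an easy source of a hidden factor of 4. Report tables round
half-up to two decimals.

## Validation

Family cross-validation removes the progeny records of all mothers of one
half-sib family (one split per family with at least 50 mothers, by
default); forward prediction removes all records from a cutoff year on.
Genomic data always stays complete — only phenotypes are withheld.
Predictive ability is the correlation between GEBV from the reduced fit
and mean progeny performance adjusted for fixed and permanent-environment
effects. The adjustment uses estimates from the full-data fit (default):
reduced-fit estimates cannot cover trial-year levels that exist only in
the validation period. The Legarra–Reverter statistics are computed over
the validation mothers, regressing full-data GEBV on reduced-data GEBV
(slope < 1 = over-prediction, > 1 = under-prediction, R² = squared
correlation); note the original method regresses the other way round — we
follow the convention of the evaluation design we target.

## The synthetic-data generator

The generator emulates the structure of a Nordic forage-grass breeding
program:

* **Population** — hexaploid dosages; per-marker true frequencies from a
  Beta(2.6, 0.8) prior (mean ≈ 0.77, SD ≈ 0.2, matching the skew of
  reference-allele frequencies in such data). Half-sib families share one
  simulated parent: an individual draws k/2 alleles from the family
  parent's allele pool and k/2 from the population, so expected dosage is
  preserved while within-family relationships exceed between-family ones.
  The crossing design linking mothers to progeny is not modelled
  (top-/poly-cross pollination details are unavailable); progeny records
  per mother is a free parameter instead.
* **Reads** — total depth per sample and marker is negative-binomial with
  mean 37.88 and shape 1.36 (chosen to reproduce a right-skewed depth
  histogram with SD ≈ 33; a Poisson cannot), optionally zero-inflated;
  zero depth is the only missingness mechanism. Given depth, reference
  reads are Beta-Binomial with location dosage/k and per-marker τ drawn
  from Beta(1.7, 4.8) (mean 0.26, SD 0.16) unless fixed. Boundary
  locations (dosage 0 or k) skip the Beta draw. 107 mothers receive a
  second, independently sequenced sample by default.
* **Phenotypes** — six traits (three yield cuts, winter damage, two
  digestibility values) with mother/permanent-environment/residual
  covariance matrices reconstructed from published magnitudes: mother
  variances are additive variances over 4; mother covariances come from
  the genetic correlations; V_C is diagonal; residual covariances complete
  the published phenotypic correlations. Two-decimal correlations need not
  form a PSD matrix, so each matrix is projected to the nearest PSD
  (eigenvalue clipping). Defaults: 1764 mothers, 18 families, 23 trial
  years — the magnitudes of the target program; tests pass smaller sizes
  explicitly and the bundled demo runs at 80 mothers × 400 markers.

What the generator does **not** emulate: linkage and LD, selection and
drift across generations, genotype-by-environment interaction, sequencing
error/allelic bias/outliers, and non-Gaussian trait distributions.
Passing tests therefore demonstrate correctness of the estimators under
the stated generative model, not robustness to those real-data features.

## Numerical choices

* The centered G is singular by construction (zero row sums); wherever an
  inverse is needed a ridge of `1e-6 × mean(diag)` is added and logged.
  The ridge is proportional to the matrix scale, which preserves the exact
  scalar equivalence between naive- and Beta-Binomial-scaled analyses.
  A Cholesky that "succeeds" on a rank-deficient matrix through roundoff
  is caught by a pivot-ratio check (`min/max diag(L) < 1e-6`).
* Beta-Binomial log-likelihood: for τ below 1e-10 the Binomial limit is
  evaluated directly; τ estimates are clipped to `[1e-6, 1−1e-6]`.
* Zero genetic variance is handled as the limit (GEBV pinned at zero via a
  large precision) rather than by inverting a zero matrix; zero V_C drops
  the permanent-environment terms from the equations.
* Ties/degenerate inputs: markers fixed in frequency are rejected by the
  scaling functions (they must be removed by the MAF filter); predictive
  ability and LR statistics report NaN with an explanation when a GEBV
  vector has zero variance; identical full/reduced GEBV short-circuit to
  exact (1, 1, 1).

## Problem sizes used in the bundled experiments

Parameter-recovery and validation experiments in the test suite run at
300 mothers (15 or 6 families) × 200–300 markers with 2–3 records per
progeny, 20 replicates; overdispersion recovery at 500 individuals × 200
markers and mean depth 40. These sizes give Monte-Carlo standard errors
small enough for the stated acceptance bands while keeping the suite
comfortably runnable on a laptop.

## Known limitations

* Ungenotyped mothers with records are rejected rather than handled by
  pedigree augmentation.
* EM-REML is first-order and slow near the optimum; no acceleration (e.g.
  Aitken) is implemented.
* The multi-trait EM drops records incomplete for the selected traits.
* Broad-sense heritability, dominance/epistasis, spatial field-trial
  pre-correction and reaction-norm G×E models are out of scope.
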