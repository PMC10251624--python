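# Methods

## Model and assumptions

The evaluation model is a univariate animal model `y = Xb + Wu + e`, one
additive genetic effect per pedigree animal, homogeneous residual variance,
and known variance components entering only through `λ = σ²_e/σ²_u`.  The
additive covariance is the single-step matrix `H`: pedigree relationships
`A` everywhere, with the genotyped block replaced by
`G_C = ZBZ' + C`.  Throughout the package `C = wA_gg` (residual polygenic
form) is the default; `C = εI` is supported for the genomic-factor algebra.
With `C = wA_gg`, the proportion `1 − w` of additive variance is assigned
to the markers via `B = ((1−w)/k)I`, `k = 2Σp(1−p)` (VanRaden method 1),
and the remaining proportion `w` flows through the pedigree — the residual
polygenic (RPG) effect.

Multi-trait models, maternal effects, genetic groups/metafounders and
heterogeneous residual variances are out of scope.

## Equivalent formulations

Both mixed-model-equation operators share the fixed-effect and animal
blocks and the right-hand side `(X'y, W'y, 0)`:

* breeding-value form: pedigree MME plus `(G_C⁻¹ − A_gg⁻¹)λ` on the
  genotyped block; `G_C⁻¹v` via the Woodbury identity, either component-wise
  (two triangular solves against the Cholesky factor `L` of
  `K = Z'C⁻¹Z + B⁻¹` per product) or as `(C⁻¹ − T'T)v` with a cached
  `T = L⁻¹Z'C⁻¹` (8nm bytes; the memory-heavy variant);
* marker-equation form: `(C⁻¹ − A_gg⁻¹)λ` on the genotyped block, coupling
  blocks `−C⁻¹Zλ`/`−Z'C⁻¹λ`, and `Kλ` on the SNP block applied as
  `Z'(C⁻¹(Zv)) + B⁻¹v` so `K` itself is needed only for its diagonal.

`K⁻¹x` is always evaluated as a forward solve with `L` followed by a
backward solve with `L'` (`K = LL'`); a transposed ordering of the two
solves is algebraically wrong and is not offered.  Direct dense solves of
both systems agree on the shared blocks to 1e−6 on random instances, and
the SNP block of the extended solution satisfies `ĝ = K⁻¹Z'C⁻¹û_g` — this
equivalence is asserted in the test suite with an independently assembled
dense oracle on each side.

Solves against `A_gg` use a cached dense Cholesky factor of the submatrix
`A[g, g]`; `A_gg⁻¹` is never formed.  `A⁻¹` is built sparsely by
Henderson's rules with inbreeding (Meuwissen–Luo recursion for `F`), and
`A·v` products use Colleau's O(N) gene-flow factorisation `A = TDT'`.

## Solver

PCG from a zero start vector (reproducibility; no warm starts), with a
block preconditioner: dense Cholesky solve with
`P_ff = X'X + diag(X'X)·10⁻⁴` on the fixed block — the inflation keeps
`P_ff` positive definite when fixed effects are confounded — and Jacobi
on all random equations.  The random-block diagonal is exact by default,
including the rank-m part of the genotyped-block correction (computed from
`T` column norms); an `omit_correction_diag` switch reproduces production
solvers that never form `T` and therefore keep only the
`(1/w − 1)diag(A_gg⁻¹)` part.  The SNP-block diagonal can use `diag(K)`
exactly (default; `K` exists anyway at these sizes) or the per-marker
approximation `2p(1−p)n` scaled by the `C⁻¹` magnitude.

Convergence is declared at `C_r = ‖C_MME s − r_MME‖₂/‖r_MME‖₂ < 10⁻⁷`
(checked every iteration; the recurrence residual is used, whose drift
from the true residual is orders of magnitude below the tolerance at desk
scale).  The PCG α/β scalars form a Lanczos tridiagonal whose extreme
eigenvalues are reported as estimates of the preconditioned system's
effective spectrum — a diagnostic only; the estimator is accurate for the
extremes reached within the iteration count but is not unique, so values
from other software need not match.

## Indirect prediction

A candidate's GEBV decomposes as `u_c = −μ + Z_c g + d_c`.  The package
computes, from a previous evaluation's solutions:

* `ĝ = K⁻¹Z'C⁻¹û_g` (backsolve; equals `BZ'G_C⁻¹û_g`),
* `d̂_g = û_g − Zĝ` (equals `wA_gg G_C⁻¹û_g`),
* `d̂_c = A_cg A_gg⁻¹ d̂_g`, exact, via two routes that agree to 1e−8: a
  dense `A_gg` solve plus one Colleau product, or a sparse solve for the
  non-genotyped ancestors of the reference animals followed by
  parent-average propagation (valid because an animal that is no ancestor
  of any genotyped animal has a relationship row to the reference equal to
  its parents' average).

Predictors: PA (parent average of GEBV; an unknown parent contributes 0 —
no rule is standard, the base value is the neutral choice), DGV (`Z_cĝ`
only), REG (`d̂_c` replaced by a parent average using a linear regression
`d̂_g = â + b̂û_g` for non-genotyped parents; unknown ancestors contribute
0; a degenerate regression falls back to `â = mean(d̂_g), b̂ = 0` with a
warning), and GRV (all components exact).  For a candidate with both
parents genotyped REG and GRV coincide identically.  Candidate genotypes
are centred with the *previous evaluation's* allele frequencies, the scale
on which `ĝ` lives.

A useful exactness property, exercised in the tests: a genotyped animal
with no records, no progeny and both parents genotyped is conditionally
independent of all other animals given its parents, so removing its
genotype (keeping centring frequencies fixed) changes no other solution,
and GRV from the reduced solutions reproduces its full-evaluation GEBV to
solver precision.  Without the both-parents-genotyped condition this is
only approximate — a held-out genotype still informs the imputation of
non-genotyped relatives.

## Synthetic study

The generator emulates the statistical structure the method assumes, not
any particular population: discrete non-overlapping generations with
random pairing (default 500 founders, 6 generations, 2 offspring per
mating → 3,000 animals); unlinked biallelic markers gene-dropped from
founder frequencies drawn uniformly on (0.05, 0.95) (default m = 1,000);
true breeding values `u = Za + d` with i.i.d. marker effects of total
variance `(1−w)σ²_u` (Z centred at founder frequencies) and an
infinitesimal RPG part `d` gene-dropped with inbreeding-adjusted Mendelian
sampling variance (`w = 0.20`); single phenotype records
`y = μ₀ + u + e` at `h² = 0.3` for non-candidate animals from the third
generation on; `σ²_u = 1` so biases read directly in genetic-SD units.
The final generation (500 animals, no records, no progeny) are the
selection candidates; all are genotyped, and non-candidate phenotyped
animals are genotyped at rate 0.7, which makes all three candidate
parent-status groups (GG/NG/NN) non-empty.  The reduced dataset removes
exactly the candidates' genotypes; full and reduced evaluations recompute
allele frequencies from their own genotype sets, as consecutive real
evaluations would.

A pedigree-versus-genomic base difference — what the J-factor covariate
absorbs — is induced by giving a designated half of the founders a mean of
`jfactor_shift·σ_u` (default 0.3) in their RPG values; the shift then
propagates by parent average, which keeps the construction consistent with
the additive model (a hard shift for every descendant would not be).

What the generator does *not* emulate: linkage and LD beyond
pedigree-induced structure, selection, overlapping generations, repeated
or maternally affected records, genotyping error and missingness, and
multi-breed structure.  Tests passing on these data therefore certify the
algebra and the solver, and the qualitative behaviour of the predictors,
not field-scale accuracy levels.

## Problem sizes and what desk scale can and cannot show

End-to-end checks run the default study (3,000 animals, ~1,550 genotypes,
1,000 markers), solving to `C_r < 10⁻⁷` in seconds per system.  At this
scale the formulation equivalence is reproduced essentially exactly
(GEBV correlation ≈ 1.000, slope ≈ 1.000), and reference-animal GEBV agree
between the full and reduced evaluations at r ≈ 0.998.  Quantities that
depend on the *size of the genotyped reference* sit lower than they would
with millions of reference genotypes: each candidate's own genotype
carries substantial marginal information against a ~1,000-animal
reference, so the all-animal reduced-versus-full correlation is ≈ 0.97 and
the GRV indirect accuracy ≈ 0.98 overall (≈ 0.95–0.96 averaged over
parent-status groups), with the exact predictor's level bias wandering by
a few hundredths of a genetic SD because the two evaluations' genomic
bases (allele frequencies, J-factor solutions) differ slightly.  For the
same reason the regression predictor, which borrows phenotype information
of non-genotyped parents that the exact reduced-system decomposition does
not use, can edge past GRV in accuracy at this scale.  These are
information effects of small references, not algebraic error: the exact
identities behind GRV hold to 1e−7–1e−8 on every fixture.

## Numerical choices

* Class fixed-effect levels are indexed in sorted label order; equation
  numbering is deterministic, so solution files are byte-reproducible.
* An intercept is included only when the model has no class fixed term
  (a class term spans the mean; this keeps the fixed block full rank).
* Missing genotypes: `mean_impute` (per-marker mean, rounded, with a
  warning) or `fail`.  Monomorphic markers are dropped at read time.
* Genotype counts are held as a dense int8 array; at desk scale the packed
  2-bit form saves nothing worth the decode cost.
* `dense_gc` / `dense_reference` refuse more than 2,000 animals / 5,000
  equations — they exist as oracles, not as a solve path.
* PCG aborts with the iteration index on a NaN or non-positive curvature;
  `maxit` exhaustion returns the current solutions flagged unconverged.

## Known limitations

Univariate only; no genetic groups; the RPG-form regularisation is
required for the REG/GRV predictors (`C = εI` evaluations can use PA and
DGV); the second-level SNP preconditioner and closed-form random-J-factor
mean are not implemented; indirect predictions come without reliability
approximations.
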