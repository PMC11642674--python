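# Methods

## The model chain

`pathblup` estimates genetic parameters of repeated-record semen traits
and compares four genomic prediction models that differ in how they
represent genetic covariance between boars.

### Repeatability animal model

Each ejaculate record of boar *i* is modelled as

    y = Xb + Age·β_age + Int·β_int + Z u + E p + e

with fixed herd-year-season classes (dummy-coded, first level absorbed
into the intercept), age in months and collection interval in days as
centered linear covariates, additive genetic values
u ~ N(0, A σᵤ²) over the whole pedigree (A from the tabular recursion,
unknown parents contributing zero), permanent-environment effects
p ~ N(0, I σₚₑ²) for boars with records, and i.i.d. residuals.
Age and interval enter linearly because nothing in the data model
suggests a basis expansion; the covariate columns are rank-checked and
confounded columns are dropped with a warning (a generalized-inverse
fit in effect).

REML maximizes −½[log|V| + log|X′V⁻¹X| + y′Py]. Both the likelihood
and its derivatives are evaluated through the mixed-model equations
using log|V| + log|X′V⁻¹X| = log|R| + log|G| + log|C/σₑ²| (Schur
determinant identity), so the per-iteration cost is a Cholesky factor
and inverse of the (p + n_pedigree + n_boars)-dimensional coefficient
matrix rather than anything scaling with the record count. Updates are
average-information (AI) Newton steps with step-halving; a step is
accepted only if it improves the restricted likelihood, otherwise the
classic EM-REML update is taken. Components pinned at the floor
(10⁻¹⁰·Var(y)) with a negative gradient are excluded from the Newton
solve (active-set step). Convergence requires a relative parameter
change or likelihood change below 10⁻⁸; non-convergence after 200
iterations raises an error carrying the iteration trajectory.
Asymptotic standard errors come from the inverse AI matrix at the
optimum. EBVs are the MME solutions; PEV is read off the inverse
coefficient matrix; reliability is 1 − PEV/σᵤ², clipped to [0, 1].

With unrelated boars (A = I) the additive and permanent-environment
components are identified only through their sum; the solver converges
on the likelihood ridge and the test suite checks the identified
quantities (their sum against the one-way ANOVA between-boar estimator).

### Ratios, correlations, deregression

h² = σᵤ²/(σᵤ²+σₚₑ²+σₑ²) and r² = (σᵤ²+σₚₑ²)/(σᵤ²+σₚₑ²+σₑ²), reported
at 3 decimals. Genetic correlations come from a bivariate repeatability
model fitted by EM-REML over three unstructured 2×2 covariance matrices
(genetic, permanent-environment, residual; complete records assumed, so
R⁻¹ = Σe⁻¹ ⊗ I). The E-step residual update uses the expectation form
(ê′ê plus the per-record prediction-error covariance from the MME
inverse)/n. Because EM creeps near the optimum, every third iteration
an extrapolated jump along the EM direction (step factors 32…2, each
matrix projected back to PSD) is attempted and accepted only when the
restricted likelihood improves; starting values are the univariate fits
with the boar-mean cross-correlation seeding the covariances. The
four-trait analysis is composed of univariate fits plus the six
pairwise bivariate fits, which have the same expectations for every
reported quantity at far lower solver complexity than a joint
four-trait REML.

De-regressed proofs use the individual-only variant (no parent-average
removal — appropriate when proofs derive from deep own-performance
records rather than progeny): drpᵢ = ebvᵢ/relᵢ, weight
wᵢ = (1−h²)/[(c + (1−relᵢ)/relᵢ)h²] with c = 0.5 (the fraction of
genetic variance assumed uncaptured by markers), and individuals with
reliability ≤ 0.10 dropped.

### Kernels

The genomic relationship matrix follows VanRaden:
G = MM′/(2Σⱼpⱼ(1−pⱼ)) with M the dosage matrix centered by twice the
counted-allele frequency, recomputed from the analyzed individuals
(no external base-population frequencies exist for synthetic data).
Centering by the counted-allele frequency (not the folded MAF) is what
makes the columns of M mean-zero, which the partition-additivity
property of G requires. Monomorphic SNPs are dropped with a log entry.
Gaussian kernels exp(−‖Mᵢ−Mᵢ′‖²/h) use the same centered coordinates,
with the diagonal set to 1 exactly. Bandwidth candidates are
h = median pairwise squared distance / {0.05, 0.1, 0.5, 1, 2, 4}
(the division reading of the family; the divisor is a logged config
value so the multiplicative reading is also runnable), the median exact
up to 2000 individuals and estimated from 10⁶ seeded pair samples
beyond. Matrices whose smallest eigenvalue falls below −10⁻⁸ of the
largest receive 10⁻⁶ diagonal jitter (logged) so REML V stays
invertible.

Reference-panel selection ("who to sequence") is greedy: the first
pick maximizes average kinship with the rest; each later pick maximizes
the gain in rep(S) = mean over unselected i of
max_{s∈S} G_is/√(G_ii G_ss), clipped to [0,1], until 70% coverage.
This coverage score is this package's operational definition of
"genome representativity" and is flagged as such in output metadata.

### Pathway models

Genes are extended 5 kb on both ends (strand-agnostic: extending
upstream of the TSS and downstream of the TTS is the same symmetric
extension for either strand), clamped at coordinate 1; SNPs map to
genes by closed-interval, 1-based overlap; a pathway's SNP set is the
union over its genes; pathways with fewer than 10 represented genes
(≥1 mapped SNP) are pruned. A SNP may serve several pathways and is
counted once within each.

The four prediction models on DRPs: GBLUP (G), RKHS (Gaussian K, all
SNPs), GFBLUP (G + pathway Gₚ), biBLUP (G + pathway Gaussian Kₚ).
One-kernel fits use profiled REML on the variance ratio via a single
eigendecomposition and a bounded 1-D search (tolerance 1e−8 on the
ratio — the profiled and generic AI paths agree to 1e−6 by test).
Two-kernel fits use the same AI-with-EM-fallback scheme as the
repeatability solver on the dense training-subset covariance; when a
kernel variance collapses to the boundary the remaining one-kernel
problem is solved exactly by the profiled path. Validation individuals
stay inside the kernels with their DRPs masked from y, so the BLUP
back-solve ĝ = σ̂² K[:, train] Py prices every individual in one pass —
equivalent to the projection formula K_vt K_tt⁻¹ ĝ_train and much
cheaper than per-fold kernel rebuilds. DRP weights (off by default,
since predictive ability is defined on unweighted DRPs) scale the
residual variance per record. Bandwidth divisors are selected per
training fold by restricted likelihood over the six candidates;
variance components are re-estimated within every fold (no leakage).

### Cross-validation and screening

Predictive ability is the Pearson correlation between predicted total
genetic values (ĝ + î) and validation DRPs under repeated random
k-fold cross-validation (default 20 repetitions × 5 folds). One fold
set per (dataset, seed) is shared across models and pathways, so all
comparisons are paired. The reported SE is the standard error over all
fold-level correlations (the fold/repetition-mean distinction is not
resolvable from published tables; the definition is switchable).
Relative improvement is 100·(a−b)/b at 2 decimals, computed in decimal
arithmetic (string-constructed `Decimal`) because binary floats
misround printed half-way cases such as (0.370−0.320)/0.320.

## The synthetic-data generator

The generator emulates a boar-stud dataset: founders with allele
frequencies ~ U(0.05, 0.5), gene-drop inheritance (one allele per
parent per SNP, linkage-free; an optional block-copy founder mode
creates within-block LD for prune testing), non-overlapping genes tiled
over the chromosomes, random pathway membership, and four correlated
traits by default whose heritabilities (0.221, 0.227, 0.164, 0.432),
repeatabilities (0.422, 0.363, 0.322, 0.587), residual scales and means
follow the Duroc semen-trait estimates, with 111 records per boar on
average (shifted Poisson, minimum 1) and herd-year-season/age/interval
fixed effects of documented arbitrary magnitude (0.5, 0.01 and 0.02 of
the trait SD respectively — no generative model for these exists to
copy). The default genetic-correlation matrix follows the reported
sign pattern among the four traits but that matrix is slightly
indefinite, so its nearest-PSD projection is used — a fixture, not a
claim. Additive values come from a causal SNP subset (default 20% of
SNPs) with effects drawn under the trait correlation matrix and
rescaled so the realized variance over phenotyped boars hits the target
exactly; additive×additive epistasis is a sum over centered-dosage
products of SNP pairs sampled within one causal pathway — the simplest
architecture a Gaussian kernel should capture and an additive GRM
should not. Truth tables (per-individual u, epistatic value, pe, and
realized variance fractions) let every estimator be scored by recovery
error; everything is bit-reproducible from the scenario seed.

What the generator does **not** emulate: linkage maps and realistic LD
decay, selection, mutation, genotyping error, the real population's
allele-frequency spectrum, or non-Gaussian trait distributions
(proportions are simulated as Gaussians around their means and may exit
[0,1]). Passing recovery tests therefore demonstrates estimator
correctness under the stated generative model, not robustness to real
data pathologies.

## Validation scenario sizes

Tests and the acceptance script run at desk scale, chosen to keep the
full suite in the tens of minutes while leaving each check adequately
powered:

- Heritability/repeatability recovery: 400 phenotyped boars × ~20
  records (two generations from 100 founders), 600 SNPs, five seeds per
  (h², r²) cell over the seven generable cells of
  {0.16, 0.22, 0.43} × {0.32, 0.42, 0.59} (cells with r² < h² imply
  negative permanent-environment variance and cannot exist). Mean
  absolute error ≤ 0.05 on both ratios.
- Genetic-correlation recovery: the same population with two traits at
  r_g = 0.5 and all SNPs causal — with a sparse causal subset, the
  marker-realized relationship deviates from pedigree A and the
  deviation loads into the permanent-environment covariance, biasing
  r̂_g toward zero; an all-causal genome matches the pedigree-REML
  assumptions and recovers 0.5 within ±0.1 over five seeds.
- Model ordering: strong within-pathway epistasis (h²_add = 0.2,
  h²_epi = 0.45) in a sib-dense population (40 founders, two
  generations, five offspring per mating → 250 boars) with
  high-reliability pseudo-proofs (noise SD 0.15). Family structure is
  what makes epistatic values predictable at all — the
  additive×additive relationship is approximately the Hadamard square
  of Gₚ, which vanishes between unrelated individuals — and boar studs
  are in fact sib-dense. Under these conditions biBLUP beats GFBLUP on
  the causal pathway in ≥70% of 20 seeds, while on purely additive
  data the four models are statistically indistinguishable (paired
  tests over 20 seeds at family-wise α = 0.05).

## Numerical choices and edge cases

- Variance components are clamped at 10⁻¹⁰·Var(y); boundary components
  are handled by active-set Newton steps and, for kernel models, exact
  reduced-model solves.
- LD pruning is windowed greedy (window 50 SNPs, step 5, repeated to a
  fixed point): within a window, the lower-MAF member of any pair with
  r² ≥ 0.9 is removed, ties broken against the later position. MAF and
  call-rate filtering runs before LD pruning; the order is logged.
- Filter boundaries use the complementary closed inequalities of the
  stated removal rules: records kept at VOL ≥ 20 mL, DEN ≤ 20×10⁹/mL,
  MOT ≥ 0.5, ABN ≤ 0.6; SNPs kept at MAF > 0.01 and call rate > 0.90;
  boars kept at ≥ 10 surviving records (records filtered first).
- Missing genotypes are mean-imputed (2p̄) before any kernel is built;
  haplotype-reference imputation is out of scope.
- Unit normalization on load is heuristic and idempotent: a volume
  column topping out below 20 is treated as liters (×1000); motility or
  abnormality columns exceeding 1.5 are treated as percentages (÷100).
- Coordinates are 1-based inclusive everywhere (GFF3 convention); VCF
  POS is used as-is; BED-like inputs are converted on load.
- Pedigrees may list parents that lack their own rows; these become
  founders. Cycles raise an error naming the cycle.

## Known limitations

- The bivariate EM-REML reports no standard errors for the correlation
  estimates; only the univariate AI solver provides asymptotic SEs.
- The greedy representativity score for sequencing-panel selection is
  one reasonable operationalization among several; rankings beyond the
  first pick depend on it.
- Single-pathway models only (as in the model suite it implements);
  no joint multi-pathway fits, dominance kernels, or single-step
  (H-matrix) evaluation.
- The CLI covers the standard pipeline paths; unusual compositions
  (e.g., weighted screening with custom divisor families) are
  library-only.
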