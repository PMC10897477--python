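# Methods

## The generative model

Each family consists of a mother, a father and one child, observed on `p = 11`
standardized psychiatric polygenic scores. The latent layer has `k` additive
genetic factors per person.

**Couples.** Mother/father factor vectors are drawn jointly,

    (F_m, F_f) ~ N( (α_m, α_f), [[Ψ, Γ], [Γᵀ, Ψ]] ),

where Ψ is the population factor covariance (identity by default: an
orthogonal bifactor structure), Γ holds cross-partner covariances — its
diagonal entries are the per-factor assortative-mating parameters — and
α_m, α_f are latent mean shifts of the *participating* parents relative to a
population mean of zero (participation selection). Trait-specific genetic
components `U ~ N(0, Θ)` are independent across partners: assortment acts on
the latent factors, and the observed-scale partner covariance follows as
ΛΓΛᵀ.

**Meiosis.** The child's factors are midparent plus a segregation deviation,

    F_c = ½F_m + ½F_f + S,   S ~ N(0, ½Ψ),

so segregation carries half the population additive variance and, under
random mating and no selection, `Var(child) = Var(parent)`. By default the
trait-specific components follow the same ½/½/½Θ rule (`transmit_unique`),
because PGS residual variance is itself genetic; a config switch draws the
child's unique part independently instead, and both modes exist in the
fitted model as well, since published trio models rarely state which is
intended.

**Observation.** `Y = ΛF + U` per person. The packaged calibrated loadings
come in two forms: a dense five-factor exploratory matrix (general factor,
neurodevelopmental, psychotic, constraint, and a depression "residual"
factor, with tabulated residual variances) and the four-factor confirmatory
simple structure derived from it, where unique variances are set to
`1 − Σλ²` so every trait has exactly unit population variance (the
tabulated errors belong to the five-factor solution; reusing them after
dropping the residual factor would leave the depression score with variance
0.60).

Selection can alternatively be generated by a probit threshold model
(`selection_mode="threshold"`): couples are drawn from the unshifted
population and retained when both partners pass a liability cut calibrated
to a participation rate (default 0.41, a typical pregnancy-cohort consent
rate). The mean-shift mode is the default because it generates exactly what
the confirmatory model estimates.

**What the generator does not emulate.** No genotypes, linkage
disequilibrium or SNP weights — simulation is at the polygenic-score level;
no sibling structure, dynastic effects, gene–environment correlation, or
non-Gaussian tails. Passing recovery tests therefore demonstrates
correctness of the estimators under the stated model, not robustness of the
design to processes outside it.

## The trio structural model

Observations are stacked mother (11), father (11), child (11). One loading
matrix Λ, residual diagonal Θ and scaling are shared by all three family
members (sexes tied); transmission paths from each parental factor to the
child factor are fixed at 0.5 and never free. With diagonal parental factor
variances ψ, diagonal partner covariances γ and fixed within-family
(segregation) variance ψ_w, the implied covariance blocks are

    Σ_mm = Σ_ff = Λ diag(ψ) Λᵀ + Θ
    Σ_mf         = Λ diag(γ) Λᵀ
    Σ_mc = Σ_fc  = Λ diag(½(ψ+γ)) Λᵀ  [+ ½Θ if uniques transmit]
    Σ_cc         = Λ diag(½(ψ+γ) + ψ_w) Λᵀ + Θ

and the implied means, when latent means are modelled, are `μ_m = Λα_m`,
`μ_f = Λα_f`, `μ_c = ½Λ(α_m + α_f)`.

**Identification.** The fixed ψ_w sets the latent scale.

* *Assortment model*: ψ_w = 1, ψ and γ free; the reported partner
  correlation is the standardized covariance `b_j = γ_j / ψ_j`, which is
  invariant to the scale convention.
* *Selection-means model*: ψ_w = 0.5 and within-family mean 0, so ψ ≈ 1 on
  the population scale and latent means are in population-SD units. The
  observed intercepts are **fixed at 0** (and scalings at 1): scores enter
  on their population-standardized scale and are not re-centered. This is
  not optional — with free intercepts the mean structure is unidentified
  (a common shift d of both parents' latent means is absorbed by
  ν ← ν − Λd with no change in any implied mean), and re-centering per sex
  would subtract exactly the estimand.

**A local identification subtlety.** With transmitted uniques, the moment
map loses rank *exactly on* the random-mating equilibrium manifold
(γ = 0 and ψ = 2ψ_w) for factors with only two indicators: there the
parent–child residual covariance ½Θ is locally exchangeable with the factor
path, so the loading²/uniqueness split of such a factor is flat.
Structural identification holds off this measure-zero set, so the
pre-optimization identification check evaluates the Jacobian rank at a
generic admissible point. Consequences at finite n: estimates are fine
(sampled moments never sit exactly on the manifold), but the observed
information can be near-singular; in that case parameter covariances use a
pseudo-inverse and standard errors along flat directions are reported as
infinite rather than silently wrong.

**Estimation.** Full-information Gaussian ML through sufficient statistics
(mean and covariance of the 33-vector), so cost is independent of the
number of trios; implied covariances are Cholesky-factorized, and a
singular Σ returns a large finite penalty, never NaN. Variances are
optimized on the log scale (no Heywood crashes). L-BFGS with gradient
tolerance 1e-6, up to 2,000 iterations; multi-start with the first start at
the deterministic initial point (pattern values rescaled to the latent
scale implied by ψ_w) and subsequent starts jittering loadings with random
sign flips, since factor signs are only locally identified. After fitting,
each factor's sign is canonicalized (sum of pattern-signed loadings made
positive, flipping α with it) so that replicate averages of signed
quantities are meaningful. Standard errors come from the central
finite-difference Hessian of the negative log-likelihood at the optimum;
confidence intervals are Wald, and partner correlations b use the delta
method. Default 10 starts; the replicate-heavy acceptance runs use 3
(1 deterministic + 2 jittered), which is ample for the well-conditioned
packaged pattern and keeps a 160-fit study at 25,293 trios in the
ten-minute range.

Only complete trios are analysed; there is no FIML for partial families.

## Exploratory stage

The between-family covariance is the pooled parental covariance (2n
person-level observations); the within-family covariance is that of
child-minus-midparent deviations rescaled by 2 to the population metric
(mirroring the fixed ½ within-family variance). Extraction is ML via the
classical profile method — for fixed uniquenesses the optimal loadings are
an eigen-solution, leaving a p-dimensional optimization over
log-uniquenesses with the analytic gradient `diag(Σ⁻¹(Σ−S)Σ⁻¹)`.
Uniquenesses are bounded below at 1e-4 of the observed variance (Heywood
protection, warned). Two deterministic starts (the `1/diag(S⁻¹)` heuristic
and the full-uniqueness point) guard against boundary optima; exact ties
are broken toward the maximal-uniqueness solution, which also makes the
degenerate diagonal-covariance case return the canonical zero-loading
answer.

The dimensionality search walks, for k = 1, 2, ...: one extra between
factor, one extra within factor, then the metric-equality constraint
(loadings tied across levels, echelon-identified; residual variances stay
level-specific), starting from a 0-factor baseline. BIC uses
`N = 3n` person-level observations. Models that fail to converge are
recorded but excluded from selection.

Rotation of the best model is bi-factor geomin: the geomin complexity
`Σ_i (Π_j (λ_ij² + ε))^(1/q)` applied to the specific columns only, with
the first column the unpenalized general factor, minimized over the
orthogonal group (subfactors uncorrelated with the general factor and each
other, matching the confirmatory structure); plain geomin over oblique
rotations is also provided. Both use gradient projection with monotone
backtracking, ε = 0.01 (Browne's convention), and 30 random orthonormal
starts by default — geomin objectives have genuine local minima, and
recovery comparisons always align columns by Hungarian matching on absolute
congruence with sign freedom.

A caveat the package makes explicit: in a *single-level* EFA a two-indicator
specific factor's loading²/uniqueness split is not identified (only its
off-diagonal contribution is), and a quasi-single-indicator factor (the
depression residual factor) is nearly so. The exploratory stage is
therefore validated on off-diagonal common covariance and on rotated
loadings after alignment; the trio model itself, which ties the layers
together, does not share this indeterminacy.

## Numerical and design choices

* BIC = `n_params·log(n) − 2·loglik`; for covariance-only trio models the
  saturated means are profiled out and not counted (constant across
  compared models).
* The assortment CFA estimates all factors' partner covariances jointly
  (diagonal Γ); the selection-means model also frees Γ by default, since
  the two processes co-occur.
* The depression residual factor is reproduced in the exploratory stage but
  excluded from the confirmatory pattern by default; the packaged
  confirmatory pattern can be replaced by any signed pattern TSV, or
  derived automatically by thresholding |λ| (default cutoff 0.1).
* Standardization defaults: z-scoring against the pooled parent generation
  (configurable); covariate adjustment (genetic PCs, batch) is pooled OLS
  residualization before scaling.
* Model comparison uses raw BIC differences, no weights.
* Simulation sizes in the test suite are scaled (thousands of trios,
  3–5 replicates) relative to the acceptance study (25,293 trios,
  40 replicates), with tolerances tied to the empirical Monte-Carlo
  standard error of each replicate mean in both cases.

## Known limitations

* Wald intervals from observed information; a different estimator (e.g.
  robust ML) would give slightly different CIs. Exploratory-stage loading
  SEs are not provided (confirmatory SEs are).
* Trios only: no siblings, twins or extended pedigrees; no categorical
  indicators; no Bayesian estimation.
* Partner correlations on weak subfactors (few, small loadings) are
  intrinsically noisy — at 25,293 trios the constraint subfactor's partner
  correlation has a sampling SD near 0.09 — so single-cohort estimates of
  such parameters should be read with their intervals, not their point
  values.
* The sequential search's model numbering follows its own ladder; published
  supplementary model tables may count models differently even when the
  selected structure agrees.
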