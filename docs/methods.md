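# Methods

## The geometric model

An absorptive root is modelled as a cylinder of two concentric tissues:
a stele of radius `SR` (lignified vascular tissue) wrapped in the
tissues outside the stele (`tToS`, the epidermis + exodermis + cortex),
so `SR + tToS = x/2` for diameter `x`.  Across species the outer tissue
follows the linear allometry `tToS = k·x + c` with `0 < k < 0.5` (the
implied stele slope `0.5 − k` must stay positive) and an intercept `c`
of either sign.  The stele's share of the cross-section is

    PRS(x) = (2·SR/x)² = (1 − 2k − 2c/x)².

The inner term must lie in `[0, 1]`; values outside are *flagged* as
out-of-domain and excluded from downstream fits, never clipped —
clipping would fabricate curvature at exactly the diameters where the
curve is steepest.

Tissue-level traits combine by cross-sectional area:
`trait(x) = PRS·v_stele + (1 − PRS)·v_outer`.  With a denser,
nitrogen-poorer stele (`ρ_s > ρ_c`, `ν_s < ν_c`) this yields the
allometry-form trait curves `y = (a + b/x)² + d`, decreasing in `x` for
RTD and increasing for RN whenever `c < 0`, and the reverse for
`c > 0`.

Two closed-form consequences used by the package:

* **SRL identity.**  For a cylinder, specific root length is
  `SRL = 4/(π·RTD·x²)` (diameter converted to cm internally; default
  output m g⁻¹).
* **Dry-mass monotonicity.**  Mass per length is
  `m(x) = π(x/2)²·RTD(x)`.  Substituting the mixture and the model PRS
  gives `x²·PRS(x) = ((1−2k)x − 2c)²`, so

      m(x) = (π/4)·[ρ_c·x² + (ρ_s − ρ_c)·((1−2k)x − 2c)²].

  For `c < 0` both summands increase on the whole positive axis; for
  `c > 0` the second term decreases only where `x < 2c/(1−2k)`, which
  is precisely the out-of-domain region (inner term negative).  Hence
  on the valid domain `m` is strictly increasing for *every* admissible
  mixture: falling tissue density can never beat the quadratic volume
  term.  `dry_mass_monotonicity` still evaluates and reports rather
  than asserts — it flags out-of-domain grid points and returns the
  minimum finite-difference slope — but a non-monotone report cannot
  arise from admissible parameters.

## Regression machinery

**OLS** is closed-form, with the usual t-based two-sided p-value on the
slope.  **SMA** uses `slope = sign(r)·sd(y)/sd(x)` and the standard
likelihood interval `slope·(√(B+1) ± √B)`,
`B = F(1−α; 1, n−2)(1−r²)/(n−2)`.  The **common-slope test** minimizes
`Σᵢ −(nᵢ − 2.5)·log(1 − rᵢ²(b))` over candidate slopes `b`, where
`rᵢ(b)` is the within-group correlation between the SMA residual axis
`y − b·x` and fitted axis `y + b·x` (uncorrelated in every group under a
shared slope; the `n − 2.5` factor is the usual Bartlett-type
correction).  The minimized statistic is referred to χ² with
`groups − 1` df; simulation puts its size at ≈0.035 for nominal 0.05
with two groups of 60.  When any group has fewer than 20 points the
p-value comes instead from shuffling group labels (seeded, default 999
permutations).

**Allometry-form NLS** fits `y = (a + b/x)² + d` by Levenberg–Marquardt
with the analytic Jacobian, from a grid of 8 starts spanning both signs
and two magnitudes of `b` and two offsets `d`, tolerance 1e-10 on the
relative SS change, at most 500 evaluations per start.  The sign
symmetry `(a, b) ↔ (−a, −b)` is resolved by reporting `a ≥ 0`, so the
sign of `b` carries the biological direction (it mirrors the sign of
`c`).  Two structural facts shape the implementation:

* The family expands exactly to `c₀ + c₁/x + c₂/x²` under the single
  constraint `c₂ = b² ≥ 0`.  The unconstrained linear fit on
  `{1, 1/x, 1/x²}` therefore provides a strict lower bound on the
  attainable residual SS, and when its `ĉ₂ > 0` it *is* the global
  optimum, used as an additional start.  A fit is declared converged
  when the solver reports success or when its SS sits within 1e-4
  (relative) of that bound — a global-optimality certificate.
* When `ĉ₂ < 0` the in-family infimum lies on the `b → 0` boundary and
  is approached (`a → ∞`, `2ab` fixed) but never attained.  Such fits
  are flagged `degenerate`: the curve is effectively `c₀ + c₁/x` and
  `(a, d)` are not separately identifiable.  This is common for weak,
  noisy trait relationships and is reported, not hidden.

A `fix_b` mode freezes `b` (chiefly `b = 0`, where the optimum is the
response mean), used by the invariant tests.

## Phylogenetic statistics

All statistics operate on the Brownian covariance `C[i,j] =` shared
root-to-MRCA path length (diagonal = tip depths).  Zero-length branches
(e.g. inserted by polytomy resolution, which is seeded and adds
length-0 edges so path lengths are conserved) are floored at 1e-8 when
`C` is built, keeping it invertible without measurably moving paths.

* **PIC** is the standard pruning pass; contrasts are standardized by
  `√(b₁+b₂)` with the `b₁b₂/(b₁+b₂)` parent-branch extension.  The PIC
  regression is through the origin with each pair oriented to a
  positive x-contrast; its slope equals the Brownian PGLS slope (tested
  to 1e-8 on random trees).
* **Blomberg's K** uses the GLS (phylogenetic) mean, the ratio
  `MSE₀/MSE`, and the Brownian expectation
  `(tr C − n/(1ᵀC⁻¹1))/(n−1)`; significance is the proportion of
  trait-shuffles with K at least as large (seeded, default 999;
  `(1+m)/(1+nperm)` so p ∈ (0,1]).
* **Pagel's λ** multiplies only the off-diagonal of `C` (the diagonal
  is untouched — stated explicitly since definitions vary).  The mean
  and rate are profiled analytically; the remaining 1-D likelihood is
  maximized on `[0, 1]` to 1e-6, with both endpoints checked.  The
  p-value is a χ²(1) likelihood-ratio test against λ = 0.  Star trees
  are rejected as unidentifiable.
* **PGLS** is `(XᵀV⁻¹X)⁻¹XᵀV⁻¹y` with `V = C` (Brownian) or `C(λ̂)`
  with λ estimated by ML jointly with the coefficients; interaction
  columns are ordinary design columns, and rank-deficient designs are
  rejected with the collinear columns named.

K, λ, PIC correlations and PGLS slopes are invariant to tip order and
to uniform branch rescaling (tested).  Trees are simulated as Yule
(pure-birth, rate 1) processes; because the simulator stops at the
n-th birth, all pendant edges are extended by the exponential waiting
time to the next (unrealized) event, so branch lengths are strictly
positive and the scale-invariance above holds exactly.

λ-transformed Brownian traits are drawn in O(n) via the exact
decomposition `C(λ) = λ(C − diag C) + diag C`:
`√λ · (edge-wise BM) + √(1−λ) · independent tip noise` with variance
equal to each tip's depth, which has distribution `N(root, σ²C(λ))`
without any dense factorization.

## The synthetic generator

The generator defines the study conditions; its defaults are fixed and
the tests run against them.

| parameter | default | basis |
| --- | --- | --- |
| group sizes | 505 woody / 361 non-woody | published data-collection counts |
| woody mycorrhizal counts | AM 376, EM 89, ERM 13, NM 3, AM+EM 17, unknown 7 | published counts |
| anatomy subsample | 158 woody / 13 non-woody species | published counts |
| woody tToS line | k = 0.43, c = −0.016 mm | published regression |
| woody SR line (independent mode) | k_SR = 0.068, c_SR = 0.016 mm, σ_s = 0.01 mm | published slope; intercept = complement value; noise choice below |
| non-woody tToS line | k = 0.32, c = 0.011 mm; SR by exact complement | published regression |
| diameters | lognormal, median 0.35 mm (log-sd 0.4, clipped 0.1–1.2) woody; median 0.25 mm (log-sd 0.35, clipped 0.1–2.0) non-woody | chosen to span the diameter ranges the analysis must cover; not published values |
| tToS noise σ_t | 0.02 mm woody, 0.006 mm non-woody | 0.02 mm is the reference noise level for the recovery analyses; on non-woody roots (tToS ≈ 0.09 mm) it would exceed 20% relative error and push >1% of stele radii negative, so the non-woody default is scaled to a comparable ~7% relative error |
| mixture | ρ_s = 0.45, ρ_c = 0.12 g cm⁻³; ν_s = 6, ν_c = 14 mg g⁻¹ | placed so mixture outputs fall in realistic trait ranges; generator conveniences, not estimates |
| trait noise | σ_RTD = 0.05 g cm⁻³, σ_RN = 2 mg g⁻¹ | free parameters, documented defaults |
| diameter evolution | Brownian with λ = 0.8, σ² = 1 on the Yule tree, standardized within growth form and mapped through the lognormal | produces phylogenetically structured diameters |
| data-source split | 53% vs 17% thin/high-RTD quota | published frequency contrast |

Every random draw flows from one master seed through named substreams
(`zlib.crc32` of the stage name), so a config reproduces its CSV
byte-for-byte.  A truth sidecar records all generating parameters for
exact recovery assertions.

**Out-of-domain policy.**  Records whose anatomy implies PRS outside
`[0, 1]` (almost always a noise-driven negative stele radius at small
diameters) carry NaN PRS and a False flag; RTD/RN are not generated for
them.  If more than 1% of records are flagged the generator raises and
names the parameters to change; `out_of_domain_policy="flag"` downgrades
the error for runs — such as the SR-noise-0.02 recovery analyses —
whose target quantity (an OLS line on raw tToS or SR) never passes
through the PRS domain.

**Data-source classes.**  A record is "thin/high-RTD" when its RTD
exceeds the table mean (the rule separating low- from high-RTD roots)
*and* its diameter is below the median.  Class sizes are solved so the
correlated class contains exactly the requested 53% of such records and
the uncorrelated class 17%, then membership is sampled without
replacement (seeded).  Selecting jointly on density and thinness is
what splits the curve's steep and flat regions; the split is infeasible
— and raises — when the table's overall frequency lies outside the two
quotas.  The downstream frequency comparison reports the RTD-only
frequency above the mean-RTD threshold, so the reported gap is positive
but smaller than the 36-point assignment quota.

**Outlier rule.**  The two by-hand exclusions of the original analysis
(one extreme RN, one extreme PRS) are emulated by a reproducible rule:
drop records more than 4 interquartile ranges from the median of RN or
PRS, applied only at the PRS-relationship stage and always logged.  On
strongly right-skewed traits this rule can flag genuine tail records —
an inherent property of IQR rules, visible in the generator's skewed
PRS distribution — which is why exclusions are logged with species and
values rather than silently dropped.

## Pipeline and substitutions

The analysis report runs anatomy allometry → SMA slope comparisons →
PRS relationships (with outlier exclusion) → nonlinear trait fits
(overall, by growth form, woody by mycorrhizal type restricted to the
three main types with ≥10 species, woody by root-order class) →
phylogenetic statistics (K, λ, PIC regressions per subset; PGLS with
diameter × growth-form interactions) → data-source analysis.  Stage
reports carry row counts in/out; every pipeline stage asserts
`rows_in = rows_out + rows_excluded`.

The published interaction analysis used a REML linear mixed model with
study nested in data source.  Here it is an OLS ANCOVA F-test
(`y ~ x + factor` vs `y ~ x × factor`, optional fixed covariates); only
the interaction p-values feed any downstream decision, and every report
names the substitution in a `method` field.  Satterthwaite degrees of
freedom and meta-analytic study weighting are out of scope.

The non-woody PRS–RN regression is skipped (and logged) below 15
species, mirroring the small-sample skip in the original analysis
(13 species).

## Problem sizes

The test suite exercises the estimators at the scales the statistics
need, not larger: recovery runs use 2000 roots (5000 for intercepts,
where the tolerance is tighter), Blomberg-K calibration uses 200
simulations on 100-tip trees, λ recovery 100 replicates per value on
300-tip trees, and the PIC–PGLS equivalence 100 trees of up to 64 tips.
These sizes give Monte-Carlo error comfortably inside each stated
tolerance.

## What passing tests do and do not show

The generator reproduces the *mechanistic* structure the analysis
assumes: exact two-tissue geometry plus independent Gaussian noise,
single-tree phylogenetic structure, clean category labels.  Real
compilations add between-study measurement heterogeneity, non-Gaussian
and heteroscedastic errors, correlated trait noise, phylogenetic error
in the tree itself, and mycorrhiza-linked tissue differences that the
single shared mixture does not encode.  Passing recovery tests
therefore demonstrate the correctness and calibration of the
estimators, not that real root-trait data satisfy the model.  Known
limitations: no Ornstein–Uhlenbeck or other non-Brownian models; no
SMA elevation/shift tests; no REML mixed models; the λ transform and K
are computed on species means without within-species error.
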