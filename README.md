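# rootallometry

Allometry-based nonlinear analysis of absorptive-root traits, with
phylogenetic comparative statistics and a synthetic global-dataset
generator.

## The problem

Fine "absorptive" roots — the most distal, ephemeral root orders — are
often interpreted through the root economics spectrum (RES), which
predicts a positive correlation of root tissue density (RTD, g cm⁻³)
with root diameter and a negative one for root nitrogen concentration
(RN, mg g⁻¹).  Global compilations report conflicting signs for these
relationships.  A geometric model explains why: an absorptive root is a
cylinder of two concentric tissues, a dense, nitrogen-poor stele of
radius SR inside the tissues outside the stele (tToS = epidermis +
exodermis + cortex), with

```
tToS = k·x + c                      (x = root diameter, mm)
PRS  = (2·SR/x)² = (1 − 2k − 2c/x)²
```

where PRS is the proportion of the cross-section occupied by the stele.
An area-weighted two-tissue mixture then makes RTD and RN *nonlinear*
functions of diameter of the form `y = (a + b/x)² + d`.  The sign of the
intercept `c` decides the direction: `c < 0` (woody species) makes PRS —
and with it RTD — fall steeply at small diameters and flatten for thick
roots; `c > 0` (non-woody) reverses the curve.  Studies that sample only
the flat region of such a curve see "no relationship"; studies sampling
the steep thin-root end see strong ones.  The package implements this
model, the regressions around it, and the sampling-bias analysis that
reconciles the conflicting reports.

Because the underlying global trait compilation is not redistributable,
the package ships a first-class synthetic generator
(`rootallometry.synthetic`) that emulates its statistical structure —
505 woody and 361 non-woody species, lognormal diameters, the published
allometry lines as generating truth, Brownian trait evolution with a
Pagel λ transform on a pure-birth phylogeny, mycorrhizal/growth-form/
root-order/climate grouping factors — so every analysis stage runs and
is testable offline, with exact truth values for parameter-recovery
checks.

## What is inside

| module | contents |
| --- | --- |
| `allometry` | the geometric model: PRS from diameter or anatomy, two-tissue mixtures, SRL = 4/(π·RTD·x²), dry-mass-per-length and its monotonicity report |
| `regression` | sklearn-style estimators: `LinearOLS`, `AllometricCurve` (multi-start Levenberg–Marquardt NLS for `y=(a+b/x)²+d` with a global-optimality certificate), `StandardizedMajorAxis`, plus an SMA common-slope likelihood-ratio test |
| `phylo` | Newick I/O, seeded polytomy resolution and Yule simulation (via dendropy); from-scratch PIC, Blomberg's K (permutation test), ML Pagel's λ, and PGLS on the Brownian covariance |
| `synthetic` | the dataset/tree generator, data-source class assignment, outlier injection, species-mean aggregation |
| `groups` | per-group nonlinear fits, ANCOVA interaction tests, data-source split analysis with the high-RTD frequency comparison, the 4-IQR outlier rule |
| `pipeline` / `cli` | end-to-end orchestration, flat key=value configs, JSON reports with a shipped schema, reproducibility manifests; `rootallometry simulate / analyze / recover / report` |

## Worked example

```python
from rootallometry import (GeneratorConfig, generate_dataset, ols_fit,
                           blomberg_k, pagel_lambda_ml)
from rootallometry.regression import nls_allometric_fit

table, tree, truth = generate_dataset(GeneratorConfig(seed=11))

woody = table[table.growth_form == "woody"].dropna(subset=["tToS"])
fit = ols_fit(woody["diameter"], woody["tToS"])
# woody tToS ~ diameter: slope=0.448  intercept=-0.0244  R^2=0.91  n=158

w_rtd = table[table.growth_form == "woody"].dropna(subset=["RTD"])
curve = nls_allometric_fit(w_rtd["diameter"], w_rtd["RTD"])
# woody RTD ~ diameter: RTD = (0.054 - 0.0407/x)^2 + 0.132   R^2=0.060

diam = table.set_index("species")["diameter"]
k = blomberg_k(tree, diam, n_permutations=199, seed=0)
lam = pagel_lambda_ml(tree, diam)
# diameter signal: K=0.066 (p=0.005)  lambda=0.60 (p=3.2e-92)
```

The anatomy regression recovers the generating truth (slope 0.43,
intercept −0.016) within its standard errors from the 158-species
anatomy subsample; the negative fitted `b` confirms the falling woody
RTD curve; and the phylogenetic signal estimates show the typical
pattern of a strongly structured diameter (λ well above 0) whose K is
nonetheless far below 1, because the lognormal trait mapping and the
λ < 1 simulation both dilute pure-Brownian resemblance.

The same flow is available from the shell:

```
rootallometry simulate --seed 11 --out run/
rootallometry analyze --traits run/traits.csv --tree run/tree.nwk \
    --out run/analysis --truth run/truth.json
rootallometry recover --seed 11 --n-reps 50
```

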