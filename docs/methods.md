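# Methods

This note documents the models, estimators, numerical choices and known
limitations of the phenosync pipeline, and what its synthetic data do and
do not establish about real multi-site datasets.

## Seasonal curve families

Two parametric families describe a normalized seasonal series on a
1-based, 365-day day-of-year axis (no leap days; sub-day effects are far
below the method's resolution):

- **Skew-normal:** `A/(ω√2π) · exp(−½((t−ξ)/ω)²) · (1 + erf(α(t−ξ)/(ω√2)))`.
  The exponent is negative — the only sign under which the expression is a
  unimodal density; the curve is otherwise divergent and could not describe
  a seasonal peak. The free amplitude `A` is required because the density's
  maximum is far below 1 while the data are min–max normalized to [0, 1];
  `A` rescales the height only and leaves every timing statistic unchanged.
  `1 + erf(u)` is evaluated as `erfc(−u)` so the thin tail does not round
  to exactly zero.
- **V-type exponential:** `Ymax·μ^((t−Xmax)²)`. Differentiating shows the
  curvature is governed by `ln μ`, so the curve has a maximum iff μ < 1 and
  a minimum iff μ > 1 (Xmax plays no role in the classification), and
  degenerates to the line `y = Ymax` at μ = 1. Internally the family is
  parameterized by the log-rate λ = ln μ, which makes very shallow wide
  dips (|λ| ~ 1e-4, typical for monthly NSC series) numerically reachable;
  the exponent is clamped at 50 during fitting so a wild trial step cannot
  overflow the residuals.

Search windows for extrema and crossings are ξ ± 6ω (skew-normal) and
Xmax ± 6/√(−ln μ̃) with μ̃ = min(μ, 1/μ) (V-exponential): beyond six
Gaussian-equivalent half-widths the curve mass is negligible.

## Phenometrics

Percentile timing is an **amplitude threshold**, not a cumulative-area
quantile: the time at level q on a limb is the unique crossing of
q × (peak value), found by bisection to 1e-6 days between the limb's outer
window bound and the extremum (located by bounded scalar minimization to
1e-6 days; the V-exponential extremum is at Xmax exactly). The two
interpretations coincide at the peak; the amplitude reading is the one
under which a "period of maximum activity" is an interval around the peak
bounded by the 75%-of-peak crossings, which is how the activity bars are
used downstream.

For minimum-type curves (soluble sugars) on 0–1 normalized data, the level
q targets `v_min + (1−q)·(v_max_window − v_min)`, so q = 1 is the minimum
itself for both curve types and larger q always means closer to the
extremum. The maximum-activity period of a minimum is the interval where
the curve sits at or below the 25%-amplitude level
(`v_min + 0.25 · range`) — the exact mirror of the maxima rule under curve
inversion. Limbs are defined on the time axis (ascending = before the
extremum) for maxima and minima alike.

Areas are adaptive quadrature (relative tolerance 1e-8): the total area
over the search window and the area over the maximum-activity interval.

Event sequences sort the biome's peak (or minimum) times ascending; exact
ties are broken by a fixed canonical process order so output is
deterministic. The growing-season span is the difference between the
latest and earliest event times of a biome — with the default timing
structure this arithmetic reproduces spans of 60, 73 and 170 days for the
boreal, temperate and Mediterranean biome on noise-free data.

## Curve fitting

Series are min–max normalized (an affine map: fits of rescaled raw data
are identical), monthly axes converted to mid-month day of year
(Jan→15 … Dec→349). Estimation is trust-region-reflective least squares
(analytic Jacobians) from a fixed, data-derived multistart grid: ξ (or
Xmax) at the 25/50/75% quantiles of the observed times; ω at range/10 and
range/4; α ∈ {−5, 0, +5}; A at max(y)·ω√(2π)/2; μ ∈ {0.9, 0.99, 1.01, 1.1}
plus two data-scaled shallow-rate starts λ = ±ln 20/(halfspan²). The grid
is deterministic, so fits are bit-for-bit reproducible; convergence
tolerance is 1e-10 on the relative SSE change with at most 500 function
evaluations per start, and the best converged start by SSE wins.

Significance of a nonlinear fit is an F-test against the intercept-only
model, `F = ((SSE₀ − SSE)/(k−1)) / (SSE/(n−k))`; residual standard error
is `√(SSE/(n−k))` with k = 4 (skew-normal) or 3 (V-exponential) free
parameters. Family selection fits the skew-normal first and accepts it if
it converged with its extremum inside the observed window ± 30 days,
falling back to the V-exponential (which covers concave/linear-like
shapes) otherwise. Soluble-sugar series are dispatched to the
V-exponential directly: a positive-amplitude skew-normal cannot represent
a concentration dip.

**Pooled fits.** Biome-level curves are fitted to the grid-mean of the
individual normalized series. With equal observation counts per grid time
this gives exactly the least-squares parameters of the joint fit to all
points at a fraction of the cost; the RSE and F-test are then recomputed
against all pooled points (on the mean curve's scale) so the reported
residual spread reflects between-site variability, not the smoothness of
an average. Fitted curves whose extremum falls outside the sampled window
± 30 days are excluded from phenometrics with a warning: such fits are
monotone-limb degeneracies (possible for wide shallow dips sampled
monthly) whose timing statistics would be meaningless.

## SMA scaling and cross-biome tests

The SMA slope is `sign(r)·sd(y)/sd(x)` with intercept through the means;
the 95% CI follows the F-construction on the correlation
(`B = F₀.₉₅;₁,ₙ₋₂·(1−r²)/(n−2)`, CI = `b(√(B+1) ∓ √B)`; Warton et al.
2006). Constraining the SMA slope to b is equivalent to constraining
`corr(y − bx, y + bx) = 0`, so the common-slope likelihood-ratio statistic
is `LR(b) = −Σ (nᵢ − 2.5)·ln(1 − rᵢ(b)²)` minimized over b (bounded search
on log|b|; groups must agree in slope sign), compared to χ² with g−1 df;
the (nᵢ − 2.5) small-sample weight keeps the empirical type-I error at
≈ 0.044 for n = 30 per group. When homogeneity is not rejected (p ≥ 0.05)
elevations are compared with a Wald χ² on the residual means
`ȳᵢ − b·x̄ᵢ`, with the common-slope variance (from the curvature of the LR
profile) propagated into their covariance; the test is invariant under a
common translation of y.

## Bioclimatic classification

Variables are greedily decollinearized: while any pair exceeds |r| = 0.7,
the member of the worst pair with the larger mean absolute correlation to
the other retained variables is dropped (name order breaks ties). PAM is
implemented directly (BUILD + SWAP on an arbitrary dissimilarity; the
steepest-descent SWAP strictly decreases cost). Because single-restart
SWAP can stall in a local optimum, the search restarts from the BUILD
solution, a farthest-first seeding and six reproducible random seedings,
keeping the best — on all tiny instances tested this matches exhaustive
medoid enumeration. The cluster count is chosen by running PAM on squared
Euclidean distances between standardized variables (so the cost *is* the
within-sum-of-squares about medoids), warm-starting each k from the
previous k's medoids so the WSS curve is non-increasing, and selecting the
smallest k whose relative WSS drop to k+1 falls below 10%. PCA operates on
standardized variables; all components are returned so the explained
variance sums to one.

## Predictor importance

A random-forest regression (500 trees by default) of peak day of year on
one-hot-encoded biome, site, species and year. %IncMSE is computed per
tree on its out-of-bag samples by permuting **all columns of a predictor
jointly** — "site" stays one predictor despite its many levels — and
averaging the percent MSE increase across trees; aggregate out-of-bag
predictions give the percent variance explained. Quality is reported as
R² on an 80/20 split and five-fold, five-repeat cross-validated RMSE/R² on
the training split. Predictors with fewer than two observed levels are
dropped with a warning (e.g. species for ecosystem-flux records).

## The synthetic generator

The generator emulates the *structure* of a restricted multi-site
compilation: 27 sites per biome (81 total; 19 per biome with NSC
sampling, 57 total), two seasons, daily fluxes, weekly wood-phase counts,
monthly NSC concentrations. Timing is configured as per-process lags
relative to each biome's GPP peak — cambial activity −30/−45/−60 days
(boreal/temperate/Mediterranean), cell enlargement −13, wall thickening
+9, NEE −32, RECO +12, starch peaks about a week after the cambial peak,
sugar minima closing the season (latest in Mediterranean roots) — so all
pairwise lags are consistent by construction and the configured biome
event spans are 60, 73 and 170 days. GPP peaks at day 170/166/155 with
curve scales of 20/28/45 days (sharp short boreal seasons, long flat
Mediterranean ones) and right skew α = 2.

Site-level structure: a shared site shift (sd 6 days) moves all of a
site's processes together, a process-specific shift (sd 3 days) partially
decorrelates them (giving cross-site SMA scatter), year effects (sd 2
days) are common to all sites within a year, and species effects (sd 4
days) apply to wood phases only — an importance hierarchy
biome ≫ site ≫ year by construction. Observations are unit-peak curves
plus Gaussian noise (sd 0.05 on the normalized scale), floored at zero;
wood counts are continuous by default (normalization removes the integer
scale; rounding is an optional toggle). Sugar dips are exact
V-exponentials whose shoulder is reached at the farthest sampled month,
so the fitted family matches the generating family over the whole window.

Bioclimatic covariates: four planted clusters whose rank-3 separation is
carried by three "signal" variables with mutually orthogonal sign
patterns (±6 against within-cluster sd 1), seven uninformative variables,
and three near-duplicates (r ≈ 0.95) that exercise the collinearity
filter; cluster membership is balanced round-robin across sites — climate
clusters cross biome boundaries, as in real compilations.

**What passing tests show — and don't.** The generator's series are exact
members of the fitted families plus white noise; real series carry
autocorrelated weather signal, irregular and missing sampling, bimodal
Mediterranean seasons, count discreteness, and organ-specific NSC
baselines. Recovery of lags to ≈ 2 days at these settings therefore
validates the estimation machinery, not the adequacy of single-peak
parametric curves for any particular field dataset.

## Problem sizes and runtime choices

Acceptance checks run at: 200 replicates for peak-timing recovery (26
weekly points, noise sd 0.05); 20 seeds of the full biome-level pipeline
for lag recovery; 1000 replicates for the LR test's type-I error and 200
for Wald power; 25 random instances per n ∈ 4..8 against exhaustive medoid
search; 20 seeded importance runs on generator-truth peak records (using
truth records isolates the importance machinery from fitting noise, whose
~1-day scatter is negligible against the configured effects). The
delta-recovery analyses fit biome-pooled curves only; site and site-year
fits are run where the scaling and importance analyses need them.

## Known limitations

- Min–max normalization makes a V-exponential dip only approximately
  in-family (the affine shift has no offset parameter), biasing dip
  timing by well under a day at the generator's settings.
- Biome-pooled curves of jittered skewed series acquire a small
  convolution bias in the mode (≈ 1–2 days at jitter sd ≈ 7), which
  partially cancels in flux–wood deltas.
- The elbow rule's 10% threshold assumes cluster sizes are roughly
  balanced; strongly unbalanced planted clusters can make k-medoid
  overfitting gains straddle the threshold.
- The Wald intercept test treats the common slope as asymptotically
  normal; for very small groups (n < ~10) its nominal level is
  approximate.
- Mediterranean soluble-sugar minima fall late in the year where monthly
  sampling carries little right-limb information; such fits can
  degenerate to a monotone limb and are then excluded from event
  sequences, which shortens the recovered Mediterranean season relative
  to its configured 170-day span under noise.
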