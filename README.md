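# phenosync

Intra-annual synchrony of forest carbon sources and sinks: a tested,
reproducible pipeline for comparing the seasonal timing of ecosystem carbon
fluxes, non-structural carbohydrates (NSC) and wood formation across
boreal, temperate and Mediterranean conifer sites.

Forests assimilate carbon (gross primary production, GPP) on a schedule
that need not match the schedule on which that carbon is committed to wood
(cambial cell division, cell enlargement, cell wall thickening and
lignification), with starch and soluble sugars buffering between the two.
Quantifying *when* each process peaks, how long its high-activity window
lasts, and how the timing of sink processes scales with the timing of the
source across sites is the core of this analysis. The package is aimed at
forest ecophysiologists and flux/xylogenesis data analysts; because raw
multi-site wood-formation datasets are typically restricted, it ships a
synthetic multi-biome generator with known ground truth so every stage of
the pipeline is testable end to end.

## The model

Each normalized seasonal series (values min–max scaled to [0, 1] on a
day-of-year axis *t*) is fitted by multi-start nonlinear least squares with
one of two closed-form families:

- **skew-normal curve** — unimodal, possibly asymmetric peak:

  `f(t) = A · 1/(ω√(2π)) · exp(−z²/2) · (1 + erf(αz/√2))`, `z = (t−ξ)/ω`

  with location ξ (days), scale ω > 0 (days), shape α (α = 0 gives a scaled
  Gaussian) and amplitude A > 0;

- **V-type exponential** — symmetric fallback for concave/linear-like or
  dip-shaped series (soluble-sugar minima):

  `f(t) = Ymax · μ^((t−Xmax)²)`

  with a maximum at Xmax when μ < 1, a minimum when μ > 1, and the
  horizontal line f = Ymax at μ = 1.

From each significant fitted curve (F-test against the constant-mean model,
p < 0.05) the pipeline derives phenometrics: the extremum time, the
10/25/50/75/90% amplitude-percentile crossing times on the ascending and
descending limbs, the maximum-activity interval (75%-of-peak threshold;
mirrored 25%-amplitude level for minima) and definite-integral areas under
the curve. Downstream analyses are:

- **timing deltas** between each carbon flux (NEE, GPP, RECO) and each
  wood-formation phase at matched percentile levels (negative = flux
  earlier);
- **standardized major axis (SMA) scaling** of wood-phase peak day on GPP
  peak day across sites (slope = sign(r)·sd(y)/sd(x)), with a
  likelihood-ratio test for a common slope across biomes and a Wald test
  for intercept (elevation) differences;
- **bioclimatic clustering** of sites: collinearity filter (|r| > 0.7),
  PAM (k-medoids, BUILD + SWAP) with the cluster count chosen by the
  within-sum-of-squares elbow, and PCA ordination;
- **predictor importance**: random-forest regression of peak timing on
  biome, site, species and study year with out-of-bag permutation
  importance (%IncMSE).

## Usage

The numbered scripts under `analysis/` run the stages in order on the
default configuration (optionally pass a seed):

```bash
python analysis/01_simulate.py 1
python analysis/02_fit_curves.py 1
python analysis/03_phenometrics.py 1
python analysis/04_timing_deltas.py 1
python analysis/05_sma_scaling.py 1
python analysis/06_bioclim_clusters.py 1
python analysis/07_predictor_importance.py 1
```

The same stages are exposed as a CLI (`phenosync simulate|fit|phenology|
deltas|sma|cluster|importance|all --config cfg.yaml --out DIR --seed N`)
and as a library (`phenosync.pipeline.run_pipeline`). All stage outputs
are CSV files plus a JSON manifest with the configuration hash and a
SHA-256 per output, so a rerun with the same seed is verifiably identical.

### Worked example

`python analysis/04_timing_deltas.py 1` prints the peak-level deltas
(days, flux time − wood time) recovered from a full simulate→fit→
phenology→deltas run at seed 1:

```
flux_process                                  GPP   NEE  RECO
biome         wood_phase
boreal        cambial_activity               30.5  -2.0  43.1
              cell_enlargement               10.9 -21.5  23.6
              wall_thickening_lignification  -9.2 -41.6   3.5
temperate     cambial_activity               45.3  11.9  55.8
mediterranean cambial_activity               59.6  27.8  71.5
...
|GPP - cell enlargement| by level (narrows toward the peak):
0.10    16.4
0.50    12.7
1.00    11.6
```

Reading: cambial activity peaks 30.5 / 45.3 / 59.6 days before GPP in the
boreal / temperate / Mediterranean biome (the generator's configured lags
are 30 / 45 / 60 days); cell enlargement leads GPP by ~11–13 days and wall
thickening trails it by ~9; the flux–wood gap shrinks monotonically as the
percentile level approaches the peak — sources and sinks are coupled at
their peaks and decoupled at the season edges.

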