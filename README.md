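# ricelai

Whole-season rice leaf area index (LAI) estimation from multispectral UAV
imagery, for crop phenotyping and breeding-nursery workflows where dozens of
cultivars with different heading dates share one field and destructive
sampling of every plot every week is not an option.

## The problem and the model

Vegetation indices (VI) computed from canopy reflectance track LAI well while
rice is vegetative, but the relationship breaks after heading: exserted and
ripening panicles raise visible reflectance and disturb NIR reflectance, so at
equal LAI every NIR/visible index reads systematically lower post-heading
than pre-heading. Pooling both stages, LAI vs. VI becomes a two-branch cloud
(**hysteresis**) and a single linear model over-estimates LAI before heading
and under-estimates it after.

Canopy height H (from differencing the crop surface model against the
pre-transplant bare-soil surface, H = DSM − DSM_soil) shows the *opposite*
hysteresis — at equal LAI the canopy is taller post-heading — so the product
of the two signals cancels the phenology effect. The package builds and
evaluates three univariate ordinary-least-squares models per index:

    LAI = a · VI + b
    LAI = a · H·VI + b
    LAI = a · H·ln(VI + 1) + b

over eight indices (NDVI, EVI2, WDRVI with α = 0.2, CI_green, CI_rededge,
NDRE, MTCI, OSAVI), evaluated by 10-fold cross-validation with per-fold
RMSE, CV = RMSE / mean(measured LAI), and bias averaged across folds.
Upstream of the models the package implements the full measurement chain:

- **empirical-line calibration** — per band, reflectance = DN·Gain + Offset
  fitted by OLS over eight grey canvases (reflectance 0.03–0.80);
- **quality filters** — a pixel is *bad* if its DN exceeds 250 in all 12
  bands (water specular saturation); a plot is invalid if its ROI holds more
  than 100 bad pixels;
- **plot aggregation** — ROI-mean reflectance and height, destructive
  LAI = LA/n × ρ (n = 3 bundles, ρ = 22.5 bundles/m²);
- **a synthetic campaign generator** — a seedable 48-cultivar × 13-date
  study (heading 59–73 days after transplanting, peak LAI 2.76–8.53, final
  height 0.82–1.13 m, 12 bands at 490–950 nm, water contamination on the
  first flight) with the spectral hysteresis built in, so the whole pipeline
  is testable without field data.

## Worked example

The four analysis drivers reproduce the study end to end on synthetic data:

```bash
python analysis/01_simulate_campaign.py     # scenes -> scratch/campaign/
python analysis/02_extract_observations.py  # -> results/observations.csv
python analysis/03_fit_models.py            # R² table + fitted equations
python analysis/04_cross_validate.py        # 10-fold CV + stage analysis
```

The extraction step reports the quality filter at work — the flooded first
flight keeps only half the plots:

```
valid plots per date: {17: 24, 23: 48, 27: 48, ..., 86: 48}
first flight retained 24 of 48 plots (water specular contamination)
```

and the model comparison shows the hysteresis and its removal (seed 11):

```
whole-season R² by predictor:
              VI   H*VI  H*ln(VI+1)
NDVI       0.262  0.576       0.552
EVI2       0.487  0.597       0.584
WDRVI      0.307  0.392       0.354
CIgreen    0.183  0.492       0.533
...
VI-only stage bias:   CIgreen  +0.47 pre-heading, -1.00 post-heading
H x ln(VI+1) lowers the CV for 8 of 8 indices; mean reduction 8.7 points
```

Read: with VI alone, whole-season R² stays below 0.5 for every index and the
sign pattern of the stage biases (over-estimate pre-heading, under-estimate
post-heading) is exactly the phenology hysteresis; multiplying by canopy
height roughly doubles the explained variance and cuts the cross-validated
CV by ~9 points on average.

The same pipeline is scriptable via the CLI
(`ricelai simulate|calibrate|extract|fit|report`), configured by YAML for the
`report` subcommand.

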