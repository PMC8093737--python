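# shrubmass

Two-component allometric biomass estimation for tall shrubs, with
Monte-Carlo propagation of prediction error to plot-level 95% intervals
and a decision rule for choosing the measurement threshold `D_max`.

## The problem

Tall shrubs (diameter at root collar, DRC ≥ 2.5 cm) are spreading across
arctic, boreal, alpine and dryland ecosystems, and their biomass is
usually estimated from a single stem diameter through a power-function
allometry

    M = a · D^b,    fitted as   ln M = b ln D + ln a + ε,   ε ~ N(0, σ²).

Because the residuals are multiplicative, the back-transformed 95%
prediction interval (PI) widens roughly as `D^p` with `p > 2`: a few
large shrubs dominate the uncertainty of a whole field plot. Shrub
architecture, however, is approximately self-similar — an aerial tip
(any stem with diameter ≤ `D_max`) follows the same allometry as a whole
small shrub. So a large shrub can be measured as **two components**:

* **stem internodes** with diameter > `D_max`, treated as conic frustra
  of volume `V = πL(D1² + D1·D2 + D2²)/12` and converted to mass through
  a calibrated wet density (kg/L);
* **aerial tips** with diameter ≤ `D_max`, put through the ordinary tip
  allometry.

Internodes are nearly deterministic (volume × density), so replacing the
single `M = a·DRC^b` prediction of a big shrub by frustra + tips cuts
its prediction error substantially. Per-component uncertainty is
propagated to the plot as a Monte-Carlo sum of lognormals: each
component's mass is drawn from `Lognormal(μ − s²/2, s)` (mean-preserving,
so the expected draw equals the allometric point estimate `exp(μ)`), the
draws are summed per replicate, and the middle 95% of replicate totals
is the plot interval. "Uncertainty" throughout is the interval range
`upr − lwr`.

Choosing `D_max` is a benefit/cost problem. With a prediction-error law
`PE = k·D^p` and a kernel density `pdf(D)` of stem diameters,

    E[PE1] = Σ pdf(x_i) · k x_i^p · Δx            (single-component)
    E[PE2] = Σ_{x_i ≤ D_max} pdf(x_i) · k x_i^p · Δx   (two-component)

and with per-measure times `t1` (single) and `t2` (extra frustrum work),
a candidate `D_max` is worth adopting when

    E[PE1]/E[PE2]  ≥  (t2 · P(D > D_max) + t1) / t1.

## Worked example

Everything below is computed on simulated data (`shrubmass.simulate`
generates shrubs with self-similar architecture, power-law tip masses
and density-based internode masses — no field data needed):

```python
import numpy as np
from shrubmass import *
from shrubmass.geometry import InternodeSample

cfg = SimConfig()                                   # a = 0.07, b = 2.437, ...
calib, internodes = gen_destructive(cfg, 200, seed=11)

tips = calib[(calib.role == "aerial_tip") |
             ((calib.role == "whole_shrub") & (calib.diameter_cm <= 7.5))]
tip_fit = LogLogAllometry().fit(tips.diameter_cm, tips.mass_kg)
whole = calib[calib.role == "whole_shrub"]
whole_fit = LogLogAllometry().fit(whole.diameter_cm, whole.mass_kg)
internode_fit = fit_density_loglog(
    [InternodeSample(r.d1_cm, r.d2_cm, r.length_cm, r.mass_kg)
     for r in internodes.itertuples()])

print(band_overlap(tip_fit.band(2.5, 7.5), whole_fit.band(2.5, 7.5)))
```

prints a tip/whole PI-band overlap of `0.93` — the self-similarity that
justifies one shared tip allometry — and the internode log-log fit has
slope `0.9897` (se `0.0172`, i.e. proportional to volume) with a wet
density CI of `(0.86, 0.97)` kg/L around the true 0.9.

Propagating a 20-shrub plot (true total 132 kg) both ways:

```text
single: point = 137 kg, 95% interval [106, 180], uncertainty 74 kg
two:    point = 130 kg, 95% interval [112, 152], uncertainty 40 kg
ratio  = 1.88
```

The two-component interval is ~half as wide and covers the truth. The
`D_max` scan (prediction-error model fitted from the whole-shrub band,
timing regression from 14 simulated plots):

```text
D_max= 5.0: pe_ratio=17.18  time_ratio=3.59  acceptable=True
D_max= 7.5: pe_ratio= 5.19  time_ratio=2.78  acceptable=True
D_max=10.0: pe_ratio= 2.35  time_ratio=1.75  acceptable=True
```

Every candidate passes here because the simulated stands hold many large
shrubs; the ratios shrink toward 1 as `D_max` approaches the largest
stem, exactly as the decision rule predicts.

The same pipeline from the shell:

```bash
shrubmass simulate --seed 7 --out data/
shrubmass fit --seed 7 --calibration data/calibration.csv \
    --internodes data/internodes.csv --out models.json
shrubmass estimate --seed 7 --models models.json \
    --inventory data/inventory.csv --shrubs data/shrubs.csv --out plots.csv
shrubmass dmax --seed 7 --diameters data/diameters.csv \
    --timing data/timing.csv --k 0.1327 --p 2.41 \
    --candidates 5,7.5,10 --out dmax.json
```

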