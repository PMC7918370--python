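# tsgc — comparing groups of time series

`tsgc` answers a question that comes up constantly in longitudinal
experiments: **at which timepoints do the mean curves of two groups of time
series actually differ?** The motivating data are plant-phenotyping panels
— chlorophyll-fluorescence de-etiolation curves of *Arabidopsis* genotypes,
27 seedlings sampled every 2 minutes for 4 hours — but any complete,
equally spaced panel with a group label per series fits.

Naively running a t-test (or ANOVA) at each timepoint is wrong for such
data: within one series the measurements are serially correlated, and a
trend model's residuals inherit that autocorrelation, biasing per-timepoint
comparisons toward false positives and false negatives. `tsgc` implements a
two-stage remedy:

1. **Mixed-model trend.** One linear mixed model for the whole panel,

   y<sub>ij</sub> = b₀ + b₁t + b₂t² + Σ<sub>g</sub> b<sub>g</sub>·1[group(j)=g]
   + u₀ⱼ + u₁ⱼt + u₂ⱼt² + ε<sub>ij</sub>,

   with subject-specific intercept/slope/curvature (u₀ⱼ, u₁ⱼ, u₂ⱼ) drawn
   from an unstructured 3×3 covariance, fitted by maximum likelihood
   (statsmodels `MixedLM`); mean structures are compared by AIC.
2. **Per-subject ARIMA residual models.** Each subject's residual series
   ε<sub>j</sub> gets its own ARIMA(p,d,q): d from KPSS tests (with an
   enforceable floor, default d ≥ 1), (p,q) by a stepwise AICc search in
   the Hyndman–Khandakar style. ACF diagnostics with ±1.96/√n bands verify
   the whitened remainder r<sub>ij</sub> = ε<sub>ij</sub> − ε̂<sub>ij</sub>
   is serially flat.
3. **Per-timepoint tests and windows.** At every timepoint, each group
   pair is compared by a two-sample t-test on the subjects' final fitted
   values, Bonferroni-corrected across pairs (α/3 = 0.01667 for three
   groups); maximal runs of significant timepoints become significance
   windows in minutes. A *naive* mode (skip stage 2) is built in so the
   cost of ignoring autocorrelation can be demonstrated on your own data.

A seeded synthetic-data module generates panels with exactly this structure
(known fixed effects, unstructured random-effect covariance, AR/ARMA noise,
optional localized group differences with ground truth), powering
simulation studies of type-I control, power and window recovery.

## Worked example

Simulate 18 series in 3 groups (36 timepoints at 2-minute steps) with
AR(1) noise and a +0.18 offset injected into group G2 between minutes 20
and 60, then run the corrected pipeline:

```python
import numpy as np
from tsgc import (SimConfig, LocalizedEffect, generate_panel, fit_trend,
                  whiteness_report, fit_all_residuals, ARIMASettings,
                  combine, pairwise_windows)
from tsgc.simulate import default_random_cov

cfg = SimConfig(
    n_groups=3, n_experiments=3, replicas_per_experiment=2, n_timepoints=36,
    group_offsets=(0.0, 0.0, 0.0),
    random_cov=default_random_cov() * 0.3**2,
    localized_effect=LocalizedEffect("G2", start_minutes=20,
                                     end_minutes=60, magnitude=0.18),
    seed=7,
)
panel, truth = generate_panel(cfg)
trend = fit_trend(panel)
white = whiteness_report(trend.residual_series())
models = fit_all_residuals(trend, ARIMASettings(min_d=1, p_max=2, q_max=2))
report = pairwise_windows(combine(trend, models, "corrected"), alpha=0.05)
print(report.windows_frame().to_string(index=False))
```

Output (abridged):

```
initial residuals: mean significant-lag fraction 0.16 -> autocorrelated
after per-subject ARIMA: 0.01
corrected threshold: 0.01667 (3 pairs)
group_a group_b  start_index  end_index  start_minutes  end_minutes  n_timepoints
     G1      G2           12         32           22.0         62.0            21
     G2      G3           12         32           22.0         62.0            21
```

Reading it: the trend model's residuals were autocorrelated (16% of ACF
lags significant; the white-noise bar is 10%), the per-subject ARIMA stage
whitened them (1%), and the G1–G2 and G2–G3 comparisons recover the
injected 20–60 min difference window to within one 2-minute sampling step
(22–62; the one-step ARIMA predictions trail a sharp onset by one step).
G1–G3, identical by construction, gets no window.

The same pipeline is available from the shell:

```sh
tsgc simulate --seed 7 --out panel.csv
tsgc run --data panel.csv --mode both --out results/
tsgc diagnose --data panel.csv
```

`tsgc run` writes the fit summary, the per-subject ARIMA model list, ACF
grids before/after correction, comparison tables, window summaries, a
window plot (solid lines: corrected; dashed: naive) and a JSON manifest.

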