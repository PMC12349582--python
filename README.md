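# laidrivers

Attention-based attribution of leaf-area-index (LAI) dynamics to soil
moisture and temperature.

## What this is for

In water-limited regions, vegetation growth is squeezed between two
controls: soil-water availability and temperature. Remote-sensing LAI
(m²/m², 8-day composites) makes the outcome observable, but standard
deep-learning regressors that predict LAI from climate forcings say nothing
about *which* forcing mattered, where, or when. This package implements a
pipeline for that attribution question, aimed at land-surface and vegetation
ecologists:

1. **simulate** gridded soil-moisture / temperature / LAI series with a
   known, controllable driver dominance (so attribution can be validated),
2. **preprocess** them into sliding-window samples (7 composites = 56 days
   of forcing history per sample, fixed-range min–max normalization,
   chronological 70/10/20 splits),
3. **train** three model families — an ANN baseline, an LSTM, and an
   interpretable multivariable LSTM (IMV-LSTM) — with Adam, min-validation-
   loss model selection, and pooled pretraining + per-grid fine-tuning,
4. **evaluate** with R², RMSE and MAE per grid and per vegetation class, and
5. **interpret** the IMV-LSTM's attention to map driver dominance in space,
   by season, by vegetation type, and along the LAI and driver axes.

## The model at the core

The IMV-LSTM keeps a separate hidden-state block per input variable. For
variable *n* with hidden state $h^n_t \in \mathbb{R}^d$ and scalar input
$x^n_t$:

$$j^n_t = \tanh(W_j^n h^n_{t-1} + U_j^n x^n_t + b_j^n),$$

with input/forget/output gates $i^n_t, f^n_t, o^n_t$ defined analogously
(sigmoid), cell update $c^n_t = f^n_t \odot c^n_{t-1} + i^n_t \odot j^n_t$
and $h^n_t = o^n_t \odot \tanh(c^n_t)$ — no term ever mixes variables.
Temporal attention summarizes each variable's sequence,
$\alpha^n_t = \mathrm{softmax}_t f_n(h^n_t)$, $g_n = \sum_t \alpha^n_t h^n_t$,
and a variable-attention stage produces mixture weights
$\Pr(z = n \mid h_T^1 \oplus g_1, \dots)$ over the per-variable heads
$\mu_n$; the prediction is $\sum_n \Pr(z=n)\,\mu_n$. The weight
$\Pr(z=\text{soil moisture}) \in [0,1]$ is the **soil-moisture importance**
of that prediction; temperature importance is its complement. A grid whose
period-mean importance exceeds 0.5 is moisture-dominant, otherwise
temperature-dominant.

The synthetic generator plants the ground truth these weights must recover:
LAI responds (through a saturating logistic and vegetation-class envelopes)
to a latent growth signal
$G_t = \lambda \tilde S_t + (1-\lambda) \tilde T_t$, a $\lambda$-weighted
blend of lagged soil-moisture and temperature histories. Recovering
$\lambda$'s direction from the attention weights is the package's headline
validation.

All three networks (and their training loop) run on a small reverse-mode
autodiff engine over numpy included in the package — no deep-learning
framework required.

## Worked example

```python
import numpy as np
from laidrivers import run_experiment

# 4x4 grid, 6 years, strongly moisture-driven vegetation (lambda = 0.9);
# pretrain on the pooled grids, fine-tune per grid, extract attention.
er = run_experiment(seed=1, dominance_lambda=0.9, families=("imv",))

print(er.vegetation_summary("imv")[["vegetation", "r2_mean", "rmse_mean"]])
print("mean soil-moisture importance:", round(er.mean_sm_importance(), 3))
```

prints

```
    vegetation   r2_mean  rmse_mean
0  crop_double  0.260880   0.867944
1  crop_single  0.886826   0.282549
2       forest  0.792938   0.447165
3    grassland  0.856584   0.195397
mean soil-moisture importance: 0.542
```

The unimodal classes are fitted well (R² 0.79–0.89 on the held-out years);
the double-cropping class is harder (bimodal trajectory, calendar-gated
harvest dip). The mean attention weight on soil moisture lands above 0.5 —
the model attributes LAI variability mostly to moisture, matching the
generator's λ = 0.9 ground truth; rerunning with `dominance_lambda=0.1`
drives it below 0.5 (e.g. 0.228 for seed 1).

Each `run_experiment` family entry holds statsmodels-style results objects
(`.summary()`, `.predict()`, and for the IMV-LSTM `.attention()`); the
`laidrivers` CLI (`simulate` / `preprocess` / `train` / `interpret`) drives
the same stages from the shell and writes NetCDF, checkpoint and CSV
artifacts.

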