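# kmmae — Koopman multi-modal auto-encoder

`kmmae` learns a **single shared linear latent dynamics** that explains
several nonlinear observation streams ("modalities") of one underlying
dynamical system — the situation of multi-modal physiological monitoring,
where heart rate, electrodermal activity, EEG or EMG all reflect the same
latent state through different, noisy, possibly time-delayed observation
functions.

The model is a multi-modal auto-encoder built on Koopman operator theory.
For a latent system ẏ = h(y) observed through modality maps
x_l(t) = g_l(y(t)), each modality gets an encoder φ_l (a learned
inverse-observation function) mapping its delay-embedded input
[x_l(k), x_l(k−τ), …, x_l(k−(d−1)τ)] into a joint latent space, and a
decoder φ_l⁻¹ mapping back. The per-modality encodings are fused by the
arithmetic mean over non-missing modalities,

  ŷ(k) = mean over non-missing l of ŷ_l(k),

and a single bias-free, activation-free p×p matrix **A** — a finite
approximation of the Koopman operator — advances the fused state:
ŷ(k+1) = A ŷ(k). Training minimizes

  Loss = λ_recon (L_recon + L_predict) + λ_linear L_linear
       + λ_modality L_modality + λ_reg ‖W‖²,

where L_recon is the per-modality reconstruction error, L_predict decodes
A^j ŷ(k) against the true x_l(k+j) for j = 1..m, L_linear requires each
modality's own latent trajectory to follow A, and L_modality is a center
loss pulling the encodings toward their mean. Inputs get Gaussian noise at
a configurable SNR and random whole-modality masking (sentinel −1) during
training, so the fitted model denoises, **restores missing modalities from
the others**, predicts multiple steps ahead through powers of A, and
exposes an interpretable spectrum via `koopman_spectrum`. A loss-spike
detector turns the model into an event detector: when the dynamics change,
reconstruction and prediction losses jump, and the reaction time is the
first post-stimulus step where both exceed a ratio of their pre-stimulus
baselines for a required run of consecutive steps.

Who it is for: anyone with aligned multi-variate time series from several
sensors of one system who wants a linear (hence analyzable and predictive)
latent model plus robustness to noise and missing channels.

## Worked example

Recover the spectrum of a known linear system seen through a single
identity modality:

```python
import numpy as np, kmmae as K
from kmmae.benchmarks import linear_dmd_benchmark

r = linear_dmd_benchmark(seed=0)
print("eigenvalues:", r["eigenvalues"].round(3))
print("one-step prediction RMSE:", f"{r['model_rmse']:.2e}")
print("exact DMD residual:      ", f"{r['dmd_rmse']:.2e}")
```

prints

```
eigenvalues: [0.9 0.5]
one-step prediction RMSE: 9.96e-08
exact DMD residual:       3.70e-02
```

The data are 500 noiseless samples of x(k+1) = diag(0.9, 0.5) x(k). The
learned propagator's eigenvalues match the true ones to seven decimal
places,
and one-step prediction error reaches the numerical floor — the network
has found the exact linear model that dynamic mode decomposition (DMD)
computes in closed form. On nonlinear systems (see
`kmmae.benchmarks.slow_manifold_spectrum_benchmark`) the same pipeline
recovers the analytic Koopman eigenvalues {e^{μΔt}, e^{λΔt}, e^{2μΔt}} of
the slow-manifold system through nonlinear observation maps.

There is also a CLI for the end-to-end pipeline:

```sh
kmmae simulate --spec system.yaml --out data/ --seed 7
kmmae train    --config train.yaml --data data/modalities.csv --out run/
kmmae evaluate --model run/model.h5 --data data/modalities.csv --report report.json
kmmae spectrum --model run/model.h5
kmmae detect   --model run/model.h5 --segments seg.csv --stimulus 200 \
               --ratio 1.5 --consec 3 --out reactions.csv
```

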