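# Methods

## Model

The package assumes one latent dynamical system ẏ = h(y) observed through
L modality-specific maps x_l = g_l(y), possibly with per-modality sampling
delays and additive white Gaussian sensor noise. Koopman operator theory
says that measurement functions of the state evolve *linearly* under the
(infinite-dimensional) Koopman operator; the model approximates a p
dimensional invariant subspace of that operator with learned coordinates.

Each modality l has an encoder φ_l: R^{d·C} → R^p and a mirror decoder
φ_l⁻¹. Encoders see the standardized, delay-embedded input
x̂_l(k) = [x_l(k), x_l(k−τ), …, x_l(k−(d−1)τ)] (most-recent-first; the
Hankel/Takens unfolding that exposes dynamics hidden by partial
observation). The fused latent state is the arithmetic mean of the
per-modality encodings over **non-missing** modalities, and one bias-free
linear layer A (p×p) is the finite Koopman approximation:
ŷ(k+1) = A ŷ(k). The spectrum of A is directly interpretable: its
eigenvalues are discrete-time growth/oscillation rates of the latent
dynamics.

Architecture: per-modality encoders with two ReLU hidden layers (20 then
15 nodes by default) followed by a *linear* projection into the joint
layer (p = 20 by default); decoders mirror this (15 then 20, ReLU) with a
linear output layer. The projection and output layers carry no ReLU
deliberately: a rectified joint layer could not represent negative latent
coordinates, which linear dynamics with oscillatory or sign-changing
eigenvalues (and standardized, signed signals) require. An `identity`
activation option makes the whole network linear, which is the regime
where exact least-squares baselines exist.

## Losses

All four data terms use squared L2 norms and are means over the batch (so
the weights λ are batch-size independent):

* **Reconstruction** — mean over non-missing modalities of
  ‖x̂_l(k) − φ_l⁻¹(φ_l(x̂_l(k)))‖².
* **Prediction** — (1/m) Σ_l Σ_{j=1..m} ‖x̂_l(k+j) − φ_l⁻¹(A^j ŷ(k))‖²,
  where ŷ(k) is the *fused* state and the sum over l covers **all**
  modalities, including a masked one. This is the term that teaches a
  masked modality's decoder to work from the fused state of the others —
  the mechanism behind missing-modality restoration.
* **Linearity** — (1/m) Σ_l Σ_j ‖φ_l(x̂_l(k+j)) − A^j φ_l(x̂_l(k))‖² per
  modality, forcing each modality's own latent trajectory to follow A.
* **Modality (center) loss** — mean over non-missing modalities of
  ‖ŷ(k) − ŷ_l(k)‖², pulling encodings toward one shared trajectory.

Total: λ_recon (L_recon + λ_predict·L_predict) + λ_linear L_linear +
λ_modality L_modality + λ_reg ‖W‖², with all λ = 1 and λ_reg = 1e−8 by
default; λ_predict is an optional extra multiplier (default 1) so the
prediction term can be rebalanced without detaching it from λ_recon. The
regularizer sums squared entries of weight matrices (including A) and
excludes biases. Squared norms are used uniformly — including for the
prediction/linearity terms — because they give smooth gradients and keep
the four terms commensurate under a single reconstruction weight.

A masked modality is excluded from fusion and from the reconstruction,
linearity and center sums; its sentinel-filled values never enter an
encoder. Fusion divides by the count of non-missing modalities (a proper
mean), so the shared state keeps its scale when modalities drop out.

## Embedding parameter estimation

* Delay τ: first local minimum of the auto mutual information, estimated
  with an equal-width 2-D histogram (16 bins per axis by default). The
  first lag ℓ with MI(ℓ) < MI(ℓ−1) and MI(ℓ) ≤ MI(ℓ+1) is returned;
  if the curve has no interior minimum the maximum lag is returned with a
  warning.
* Dimension d: false nearest neighbors. For each d, embed, find each
  point's nearest neighbor, and call it false when the coordinate revealed
  at dimension d+1 changes the pair's distance by more than rtol (= 10)
  times; the smallest d with a false fraction below 1% wins. Coincident
  embedded points whose next coordinate also coincides are counted as true
  neighbors, which keeps the criterion sane on (near-)periodic signals.
* τ = 0 is accepted and interpreted as consecutive-sample (Hankel)
  stacking, i.e. τ = 1, with a warning: a literal zero lag would make all
  d copies identical and carry no information, while consecutive stacking
  is the only reading under which a large d remains meaningful.
* Standardization uses per-channel mean and population standard deviation
  fitted on the **training split only**; embedding-parameter estimation is
  likewise a training-split operation. Estimation is per modality by
  default (each modality may need its own unfolding).

## Training

Adam (lr 1e−3), Xavier-initialized weights, zero biases. A is initialized
to the **identity**, not Xavier: the initial latent dynamics is then
stable and norm-preserving, and training bends its spectrum toward the
system's instead of first recovering from a random unstable propagator.
Each step draws a window batch, adds fresh Gaussian noise at the
configured SNR (denoising augmentation: inputs are noisy, targets clean),
and with probability 0.5 masks one uniformly chosen whole modality with
the sentinel (−1), applied after standardization since the network sees
standardized inputs. Gradients are clipped at global norm 10, which
protects the A^m rollout terms early in training. The best-validation
checkpoint is returned; the default budget is 1000 epochs with early
stopping at patience 50. Splits are either random over sessions
(0.8/0.1/0.1, optionally stratified by condition label) or temporal
within a recording (0.70/0.10/0.20).

Gradients come from a small reverse-mode autodiff engine inside the
package (`kmmae.autodiff`), verified elementwise against central finite
differences in the test suite; the networks involved are tiny, so dense
numpy tapes are fast and exact.

## Event detection

`loss_trace` produces two per-step series on a common time base: loss1,
the squared reconstruction error at step k, and loss2, the squared error
of the one-step-ahead prediction landing at k (a horizon flag generalizes
this). For reaction-time analysis each signal is traced through its own
encode/decode path, mirroring the per-signal models used in practice.
`detect_reaction_time` computes **separate baselines per loss series**
(the two losses live on different scales) as strictly pre-stimulus means,
then reports the first step t at or after the stimulus where *both*
losses exceed ratio × their own baseline for `consec_len` consecutive
steps; the start of the qualifying window is the reaction index.
Exceedances beginning before the stimulus are flagged as a data-quality
warning rather than reported.

## Synthetic data

The generator emulates the structure of multi-modal physiological
recordings: a shared low-dimensional latent dynamics (discrete linear
systems advanced exactly; smooth ODEs, including the canonical
slow-manifold pair ẋ1 = μx1, ẋ2 = λ(x2 − x1²), integrated with fixed-step
classical Runge-Kutta at the sampling step — deterministic and adequate
for these smooth systems), modality-specific pointwise observation maps
(identity, polynomial, sinusoidal, affine, tabulated), per-modality
observation delays with all series truncated to one aligned time base,
white Gaussian noise at a stated SNR (signal power measured after
per-channel mean removal, the conventional AWGN definition), and
whole-modality sentinel masking. Everything is a pure function of its
arguments and a seed.

For stimulus datasets the latent dynamics switches at a given step with a
continuous state handoff, and each modality's ground-truth change onset
(stimulus step shifted by that modality's delay) is recorded. One
deliberate deviation from the plain noise operator: inside the stimulus
generator, noise sigma is calibrated on the **pre-onset** portion of each
modality. Sensor noise is a property of the sensor; calibrating on the
whole series would let a large post-stimulus excursion inflate the noise
and drown the pre-stimulus baseline the detector depends on.

What the generator does *not* emulate: the spectral content, artifacts and
non-stationarities of real EEG/EMG/EDA. Passing benchmarks therefore
demonstrates the mechanics of the method — joint linearization, denoising,
restoration, spectral recovery, event detection — under its structural
assumptions, not clinical performance on real recordings.

## Benchmark studies and problem sizes

All in `kmmae.benchmarks`, seeded end to end; sizes chosen so each study
trains to convergence in seconds-to-a-minute on one CPU.

* **Linear/DMD** — 500 noiseless samples of x(k+1) = diag(0.9, 0.5) x(k),
  identity observation, fully linear encoders, p = 2, 1000 epochs. The
  learned one-step prediction must stay within 2× the exact least-squares
  (DMD) residual, and A's eigenvalues must match {0.9, 0.5}. p equals the
  true state dimension here so the spectrum of A is exactly the system's;
  a wider identity-initialized A would retain spurious unit eigenvalues
  in directions the data never excites.
* **Slow-manifold spectrum** — 4000 samples at dt = 0.01 (μ = −0.05,
  λ = −1) observed through identity and square maps, p = 3, ReLU
  encoders. The analytic discrete spectrum is {e^{μdt}, e^{λdt},
  e^{2μdt}}; EDMD with the exact dictionary {x1, x2, x1²} is the
  independent oracle.
* **Restoration** — 2200 samples of a 2-D latent rotation (0.2 rad/step)
  observed through identity/square/sine/affine maps at 10 dB SNR, random
  whole-modality masking during training. Every modality observes both
  latent channels so that any masked *pair* remains identifiable from the
  remaining two. Held-out restoration RMSE of any single or pair of
  masked modalities must stay within 3× that modality's full-observation
  reconstruction RMSE.
* **Reaction time** — latent rotation 0.15 rad/step switching to 0.9
  rad/step mid-segment; two identity modalities at 30 dB SNR with delays
  {0, 5}. A model trained on pre-stimulus dynamics only; the detector
  (ratio 1.5, 3 consecutive steps) must recover the 5-step lag and its
  ordering across 20 seeded replicates.
* **SNR sweep** — identical system, seed and epoch budget; training SNR
  swept over {∞, 20, 10, 0} dB; held-out prediction RMSE against the
  clean signal must not improve as SNR drops (5% slack for run-to-run
  noise).

## Numerical choices and limitations

* Population (ddof = 0) standardization; constant channels are an error.
* Eigenvalues sorted by modulus, stable sort, for reproducible reports.
* Checkpoints are HDF5 written without timestamps, so identical runs give
  byte-identical files; loading is a bit-exact round trip.
* The engine builds one tape per batch; very deep rollout horizons (m in
  the hundreds) would make tapes long — m ≤ 10 is the intended regime.
* Masking granularity is whole-modality per training batch; per-variable
  masking is representable through the same sentinel mechanism but is not
  the default, since restoring an entire missing channel is the use case
  the fusion design targets.
* No control inputs, switched dynamics or classification heads; the model
  assumes one time-invariant latent dynamics per trained model.
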