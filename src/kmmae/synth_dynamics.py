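"""Synthetic multi-modal observations of a shared latent dynamical system.

Emulates the structure of multi-modal physiological recordings: one
low-dimensional latent dynamics observed through several modality-specific
nonlinear observation functions, with per-modality time delays, additive
white Gaussian noise at a stated SNR, masked (missing) modalities marked by
a sentinel value, and optional mid-series stimulus events that switch the
latent dynamics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "LatentSystemSpec",
    "ModalityObservation",
    "ObservationSpec",
    "ModalSeries",
    "StimulusMetadata",
    "simulate_latent",
    "observe_modalities",
    "add_noise_snr",
    "mask_modality",
    "make_stimulus_dataset",
    "slow_manifold_spec",
    "rotation_matrix",
]

_KINDS = ("linear_discrete", "slow_manifold", "custom_ode")


class DivergenceError(RuntimeError):
    """Raised when numerical integration produces a non-finite state."""


@dataclass(frozen=True)
class LatentSystemSpec:
    """Latent system y' = h(y) (continuous) or x(k+1) = M x(k) (discrete).

    kind:
        ``linear_discrete`` — parameters must contain matrix ``M`` (p x p);
        ``slow_manifold``   — the canonical pair dx1/dt = mu*x1,
                              dx2/dt = lam*(x2 - x1^2); parameters ``mu``,
                              ``lam`` per unit time;
        ``custom_ode``      — parameters contain ``rhs``: callable y -> dy/dt.
    dt: seconds per sample step.
    x0: initial state.
    """

    kind: str
    parameters: dict
    dt: float
    x0: np.ndarray

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown system kind {self.kind!r}; choose from {_KINDS}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        object.__setattr__(self, "x0", np.atleast_1d(np.asarray(self.x0, dtype=float)))
        p = self.x0.size
        if self.kind == "linear_discrete":
            M = np.asarray(self.parameters["M"], dtype=float)
            if M.shape != (p, p):
                raise ValueError(f"M has shape {M.shape}, expected ({p}, {p})")
        elif self.kind == "slow_manifold":
            if p != 2:
                raise ValueError("slow_manifold is a 2-dimensional system")
            for name in ("mu", "lam"):
                if name not in self.parameters:
                    raise ValueError(f"slow_manifold requires parameter {name!r}")
        elif self.kind == "custom_ode":
            if not callable(self.parameters.get("rhs")):
                raise ValueError("custom_ode requires a callable 'rhs' parameter")

    @property
    def dim(self) -> int:
        return self.x0.size

    def rhs(self) -> Callable[[np.ndarray], np.ndarray]:
        if self.kind == "slow_manifold":
            mu = float(self.parameters["mu"])
            lam = float(self.parameters["lam"])

            def f(y):
                return np.array([mu * y[0], lam * (y[1] - y[0] ** 2)])

            return f
        if self.kind == "custom_ode":
            return self.parameters["rhs"]
        raise ValueError("discrete systems have no continuous right-hand side")


def slow_manifold_spec(mu: float = -0.05, lam: float = -1.0, dt: float = 0.01,
                       x0=(1.0, 1.0)) -> LatentSystemSpec:
    """The standard nonlinear benchmark admitting an exact 3-D linear
    (Koopman) embedding spanned by {x1, x2, x1^2}."""
    return LatentSystemSpec("slow_manifold", {"mu": mu, "lam": lam}, dt, np.asarray(x0))


def rotation_matrix(theta: float, decay: float = 1.0) -> np.ndarray:
    """2-D rotation by `theta` radians per step, scaled by `decay`."""
    c, s = np.cos(theta), np.sin(theta)
    return decay * np.array([[c, -s], [s, c]])


@dataclass(frozen=True)
class ModalityObservation:
    """One modality's pointwise observation map of the latent state.

    map_kind: identity | polynomial | sinusoidal | affine | tabulated
    map_params: polynomial -> {"coeffs": [c0, c1, c2, ...]} (c0 + c1*y + ...);
        sinusoidal -> {"amplitude", "frequency", "phase"};
        affine -> {"scale", "offset"};
        tabulated -> {"x", "y"} lookup nodes, linearly interpolated.
    channels: number of latent components observed (first `channels` of p).
    delay_steps: this modality lags the latent state by this many samples.
    noise_snr_db: additive white Gaussian noise level, or None for noiseless.
    """

    modality_id: str
    map_kind: str = "identity"
    map_params: dict = field(default_factory=dict)
    channels: int = 1
    delay_steps: int = 0
    noise_snr_db: float | None = None

    def __post_init__(self):
        if self.channels < 1:
            raise ValueError("channels must be >= 1")
        if self.delay_steps < 0:
            raise ValueError("delay_steps must be >= 0")

    def apply(self, y: np.ndarray) -> np.ndarray:
        """Apply the pointwise map to latent rows y (n x p) -> (n x channels)."""
        if y.shape[1] < self.channels:
            raise ValueError(
                f"modality {self.modality_id!r} observes {self.channels} channels "
                f"but the latent state has only {y.shape[1]} components")
        z = y[:, : self.channels]
        k = self.map_kind
        if k == "identity":
            return z.copy()
        if k == "polynomial":
            coeffs = np.asarray(self.map_params["coeffs"], dtype=float)
            # numpy's polyval wants highest degree first
            return np.polyval(coeffs[::-1], z)
        if k == "sinusoidal":
            a = self.map_params.get("amplitude", 1.0)
            w = self.map_params.get("frequency", 1.0)
            ph = self.map_params.get("phase", 0.0)
            return a * np.sin(w * z + ph)
        if k == "affine":
            return self.map_params.get("scale", 1.0) * z + self.map_params.get("offset", 0.0)
        if k == "tabulated":
            xs = np.asarray(self.map_params["x"], dtype=float)
            ys = np.asarray(self.map_params["y"], dtype=float)
            return np.interp(z, xs, ys)
        raise ValueError(f"unknown map kind {k!r}")


@dataclass(frozen=True)
class ObservationSpec:
    """The collection of modality observation functions g_l."""

    modalities: tuple

    def __post_init__(self):
        ids = [m.modality_id for m in self.modalities]
        if len(set(ids)) != len(ids):
            raise ValueError("modality ids must be unique")
        object.__setattr__(self, "modalities", tuple(self.modalities))

    @property
    def max_delay(self) -> int:
        return max(m.delay_steps for m in self.modalities)

    def __iter__(self):
        return iter(self.modalities)


@dataclass
class ModalSeries:
    """A uniformly sampled multi-channel time series for one modality."""

    modality_id: str
    sample_rate: float
    values: np.ndarray  # (T, C), time-major
    missing_mask: np.ndarray | None = None  # (T,) bool, True where masked
    sentinel: float = -1.0

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        self.values = v.reshape(-1, 1) if v.ndim == 1 else v
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        T = self.values.shape[0]
        if self.missing_mask is None:
            self.missing_mask = np.zeros(T, dtype=bool)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != (T,):
                raise ValueError("missing_mask must have one entry per time step")
        if not np.all(np.isfinite(self.values[~self.missing_mask])):
            raise ValueError("non-finite values outside the missing mask")

    @classmethod
    def from_column(cls, modality_id: str, x, sample_rate: float = 1.0, **kw) -> "ModalSeries":
        return cls(modality_id, sample_rate, np.asarray(x, dtype=float).reshape(-1, 1), **kw)

    @property
    def n_steps(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def all_missing(self) -> bool:
        return bool(self.missing_mask.all())

    def copy(self) -> "ModalSeries":
        return ModalSeries(self.modality_id, self.sample_rate, self.values.copy(),
                           self.missing_mask.copy(), self.sentinel)


@dataclass(frozen=True)
class StimulusMetadata:
    """Ground truth for a stimulus (dynamics-change) dataset."""

    stimulus_step: int                 # latent index of the first post-stimulus step
    observed_onsets: dict              # modality_id -> index in the returned series
    delay_steps: dict                  # modality_id -> delay
    truncated_prefix: int              # latent samples dropped for delay alignment


def _rk4_step(f: Callable, y: np.ndarray, dt: float) -> np.ndarray:
    k1 = f(y)
    k2 = f(y + 0.5 * dt * k1)
    k3 = f(y + 0.5 * dt * k2)
    k4 = f(y + dt * k3)
    return y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)


def simulate_latent(spec: LatentSystemSpec, n_steps: int, seed: int = 0) -> np.ndarray:
    """Simulate the latent trajectory for `n_steps` samples (row 0 is x0).

    Discrete linear systems advance exactly; continuous systems use
    fixed-step classical Runge-Kutta at step dt, which is deterministic.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    p = spec.dim
    out = np.empty((n_steps, p))
    out[0] = spec.x0
    if spec.kind == "linear_discrete":
        M = np.asarray(spec.parameters["M"], dtype=float)
        for k in range(1, n_steps):
            out[k] = M @ out[k - 1]
            if not np.all(np.isfinite(out[k])):
                raise DivergenceError(f"non-finite state at step {k}")
    else:
        f = spec.rhs()
        for k in range(1, n_steps):
            out[k] = _rk4_step(f, out[k - 1], spec.dt)
            if not np.all(np.isfinite(out[k])):
                raise DivergenceError(f"non-finite state at step {k}")
    return out


def observe_modalities(latent: np.ndarray, obs: ObservationSpec, seed: int = 0,
                       sample_rate: float = 1.0) -> list[ModalSeries]:
    """Observe a latent trajectory through each modality's map and delay.

    Modality l at output step i reports map_l(latent[max_delay + i - delay_l]);
    all returned series share length T - max_delay so they are aligned on a
    common time base.  Noise, when configured, is drawn from a per-modality
    substream of `seed`.
    """
    latent = np.atleast_2d(np.asarray(latent, dtype=float))
    T = latent.shape[0]
    maxd = obs.max_delay
    if maxd >= T:
        raise ValueError(f"max delay {maxd} >= series length {T}")
    n_out = T - maxd
    root = np.random.SeedSequence(seed)
    streams = root.spawn(len(obs.modalities))
    series = []
    for m, ss in zip(obs.modalities, streams):
        start = maxd - m.delay_steps
        vals = m.apply(latent[start:start + n_out])
        s = ModalSeries(m.modality_id, sample_rate, vals)
        if m.noise_snr_db is not None and np.isfinite(m.noise_snr_db):
            s = add_noise_snr(s, m.noise_snr_db, rng=np.random.default_rng(ss))
        series.append(s)
    return series


def add_noise_snr(series: ModalSeries, snr_db: float, seed: int | None = None,
                  rng: np.random.Generator | None = None) -> ModalSeries:
    """Add white Gaussian noise at the requested SNR (dB) per channel.

    Signal power is the per-channel mean of squared mean-removed samples;
    noise variance is signal_power / 10^(snr_db/10).  An infinite SNR is a
    passthrough.  A zero-variance channel has no defined SNR and is an error.
    """
    if snr_db is None or np.isinf(snr_db):
        return series.copy()
    if rng is None:
        rng = np.random.default_rng(seed)
    x = series.values
    power = np.mean((x - x.mean(axis=0)) ** 2, axis=0)
    if np.any(power <= 0):
        bad = np.nonzero(power <= 0)[0].tolist()
        raise ValueError(f"zero-variance channel(s) {bad}: SNR undefined")
    sigma = np.sqrt(power / 10.0 ** (snr_db / 10.0))
    noisy = x + rng.standard_normal(x.shape) * sigma
    return ModalSeries(series.modality_id, series.sample_rate, noisy,
                       series.missing_mask.copy(), series.sentinel)


def mask_modality(batch: list[ModalSeries], modality_id: str,
                  sentinel: float = -1.0) -> list[ModalSeries]:
    """Replace the named modality's values by `sentinel` and flag it missing.

    Other modalities are returned as untouched copies; masking is idempotent.
    """
    ids = [s.modality_id for s in batch]
    if modality_id not in ids:
        raise KeyError(f"unknown modality {modality_id!r}; have {ids}")
    out = []
    for s in batch:
        s = s.copy()
        if s.modality_id == modality_id:
            s.values[:] = sentinel
            s.missing_mask[:] = True
            s.sentinel = sentinel
        out.append(s)
    return out


def make_stimulus_dataset(pre_spec: LatentSystemSpec, post_spec: LatentSystemSpec,
                          obs: ObservationSpec, stimulus_step: int, n_steps: int,
                          seed: int = 0, sample_rate: float = 1.0
                          ) -> tuple[list[ModalSeries], StimulusMetadata]:
    """Simulate a latent trajectory that switches dynamics at `stimulus_step`.

    The latent state hands off continuously: the post-stimulus system starts
    from the last pre-stimulus state.  Each modality's observed change onset
    is the stimulus step shifted by that modality's delay, recorded as ground
    truth in the metadata (indices refer to the returned, aligned series).
    """
    if not (0 < stimulus_step < n_steps):
        raise ValueError("stimulus_step must lie strictly inside the series")
    if pre_spec.dim != post_spec.dim:
        raise ValueError("pre and post systems have incompatible state dimensions")
    pre = simulate_latent(pre_spec, stimulus_step + 1, seed)
    post_spec = dataclasses.replace(post_spec, x0=pre[-1])
    post = simulate_latent(post_spec, n_steps - stimulus_step, seed)
    latent = np.vstack([pre[:-1], post])
    maxd = obs.max_delay
    # Observe noiselessly first, then add sensor noise calibrated on the
    # pre-stimulus portion of each modality: noise level is a property of
    # the sensor, and must not scale with the post-stimulus excursion.
    quiet = ObservationSpec(tuple(dataclasses.replace(m, noise_snr_db=None)
                                  for m in obs))
    series = observe_modalities(latent, quiet, seed, sample_rate)
    streams = np.random.SeedSequence(seed).spawn(len(obs.modalities))
    noisy = []
    for s, m, ss in zip(series, obs.modalities, streams):
        if m.noise_snr_db is None or np.isinf(m.noise_snr_db):
            noisy.append(s)
            continue
        onset = stimulus_step - maxd + m.delay_steps
        rng = np.random.default_rng(ss)
        x = s.values
        power = np.mean((x[:onset] - x[:onset].mean(axis=0)) ** 2, axis=0)
        if np.any(power <= 0):
            raise ValueError("zero-variance pre-stimulus channel: SNR undefined")
        sigma = np.sqrt(power / 10.0 ** (m.noise_snr_db / 10.0))
        noisy.append(ModalSeries(s.modality_id, sample_rate,
                                 x + rng.standard_normal(x.shape) * sigma))
    series = noisy
    onsets = {m.modality_id: stimulus_step - maxd + m.delay_steps for m in obs}
    delays = {m.modality_id: m.delay_steps for m in obs}
    meta = StimulusMetadata(stimulus_step, onsets, delays, maxd)
    return series, meta
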