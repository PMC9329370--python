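"""Standardization and time-delay (Hankel) embedding.

A partially observed dynamical system can be unfolded by augmenting each
sample with d-1 lagged copies at spacing tau.  The embedded vector at time k
is [x(k), x(k-tau), ..., x(k-(d-1)tau)], most-recent-first.  The embedding
dimension d is estimated with the false-nearest-neighbor (FNN) criterion and
the delay tau as the first local minimum of the time-lagged mutual
information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .synth_dynamics import ModalSeries

__all__ = [
    "StandardizationParams",
    "DelayEmbeddedSeries",
    "fit_standardizer",
    "apply_standardizer",
    "invert_standardizer",
    "delay_embed",
    "lagged_mutual_information",
    "estimate_delay_ami",
    "fnn_fractions",
    "estimate_dim_fnn",
]


@dataclass(frozen=True)
class StandardizationParams:
    """Per-channel mean and (population) standard deviation of the fit data."""

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "std", np.asarray(self.std, dtype=float))


@dataclass(frozen=True)
class DelayEmbeddedSeries:
    """Delay-embedded view of a modality.

    vectors: K x (d*C); row for source index k is
        [x(k) channels | x(k-tau) channels | ... | x(k-(d-1)tau) channels].
    origin_index: the first source index represented (= (d-1)*tau_eff).
    """

    modality_id: str
    d: int
    tau: int
    vectors: np.ndarray
    origin_index: int

    @property
    def n_vectors(self) -> int:
        return self.vectors.shape[0]

    def current_block(self, n_channels: int) -> np.ndarray:
        """The lag-0 block: columns holding x(k) itself."""
        return self.vectors[:, :n_channels]


def _values(series) -> np.ndarray:
    if isinstance(series, ModalSeries):
        return series.values
    v = np.asarray(series, dtype=float)
    return v.reshape(-1, 1) if v.ndim == 1 else v


def fit_standardizer(series) -> StandardizationParams:
    """Fit per-channel mean/std (population convention) on training data."""
    x = _values(series)
    if x.shape[0] < 2:
        raise ValueError("need at least two samples per channel to standardize")
    mean = x.mean(axis=0)
    std = x.std(axis=0)  # ddof=0
    if np.any(std <= 0):
        bad = np.nonzero(std <= 0)[0].tolist()
        raise ValueError(f"constant channel(s) {bad}: cannot standardize")
    return StandardizationParams(mean, std)


def apply_standardizer(series, params: StandardizationParams):
    x = _values(series)
    z = (x - params.mean) / params.std
    if isinstance(series, ModalSeries):
        return ModalSeries(series.modality_id, series.sample_rate, z,
                           series.missing_mask.copy(), series.sentinel)
    return z


def invert_standardizer(values, params: StandardizationParams) -> np.ndarray:
    return np.asarray(values) * params.std + params.mean


def effective_tau(tau: int) -> int:
    """tau = 0 is accepted as a request for consecutive-sample (Hankel)
    stacking, i.e. equivalent to tau = 1; a literal zero lag would make all
    d copies identical and carry no dynamical information."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if tau == 0:
        warnings.warn("tau=0 interpreted as consecutive-sample stacking (tau=1)",
                      stacklevel=3)
        return 1
    return tau


def delay_embed(series, d: int, tau: int, modality_id: str | None = None
                ) -> DelayEmbeddedSeries:
    """Delay-embed a series: row k is [x(k), x(k-tau), ..., x(k-(d-1)tau)].

    Multi-channel series are embedded per channel and concatenated
    channel-major within each lag block.  K = T - (d-1)*tau rows.
    """
    x = _values(series)
    if modality_id is None:
        modality_id = series.modality_id if isinstance(series, ModalSeries) else ""
    if d < 1:
        raise ValueError("embedding dimension d must be >= 1")
    t_eff = effective_tau(tau) if d > 1 else max(tau, 1)
    T = x.shape[0]
    span = (d - 1) * t_eff
    if T < span + 1:
        raise ValueError(f"series length {T} < minimum {(d - 1) * t_eff + 1} "
                         f"for d={d}, tau={tau}")
    K = T - span
    blocks = [x[span - j * t_eff: span - j * t_eff + K] for j in range(d)]
    vectors = np.hstack(blocks)
    return DelayEmbeddedSeries(modality_id, d, tau, vectors, span)


def _hist_mi(x: np.ndarray, y: np.ndarray, n_bins: int) -> float:
    """Mutual information (nats) via an equal-width 2-D histogram."""
    joint, _, _ = np.histogram2d(x, y, bins=n_bins)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float(np.sum(pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])))


def lagged_mutual_information(x: np.ndarray, max_lag: int, n_bins: int = 16
                              ) -> np.ndarray:
    """MI between x(t) and x(t+lag) for lags 0..max_lag."""
    x = np.asarray(x, dtype=float).ravel()
    return np.array([_hist_mi(x[: len(x) - ell] if ell else x,
                              x[ell:], n_bins) for ell in range(max_lag + 1)])


def estimate_delay_ami(series, max_lag: int = 40, n_bins: int = 16) -> int:
    """Embedding delay: first local minimum of the auto mutual information.

    Returns the smallest lag ell in [1, max_lag-1] with MI(ell) < MI(ell-1)
    and MI(ell) <= MI(ell+1); falls back to max_lag with a warning when the
    MI curve has no local minimum in range.
    """
    x = _values(series)[:, 0]
    if np.std(x) == 0:
        raise ValueError("constant series: mutual information undefined")
    if len(x) < 4 * max_lag:
        raise ValueError(f"series too short for max_lag={max_lag}")
    mi = lagged_mutual_information(x, max_lag, n_bins)
    for ell in range(1, max_lag):
        if mi[ell] < mi[ell - 1] and mi[ell] <= mi[ell + 1]:
            return ell
    warnings.warn("no local MI minimum found; returning max_lag")
    return max_lag


def fnn_fractions(x: np.ndarray, tau: int, max_d: int, rtol: float = 10.0
                  ) -> np.ndarray:
    """False-nearest-neighbor fraction for each embedding dimension 1..max_d.

    For each d, embed at (d, tau), find each point's nearest neighbor in the
    d-dimensional embedding, and mark the pair false if the extra coordinate
    revealed at dimension d+1 changes their distance by more than `rtol`
    times the d-dimensional distance.
    """
    x = np.asarray(x, dtype=float).ravel()
    fracs = np.empty(max_d)
    for d in range(1, max_d + 1):
        emb_d = delay_embed(x, d, tau).vectors
        emb_d1 = delay_embed(x, d + 1, tau).vectors
        n = emb_d1.shape[0]
        # align: the last n rows of emb_d correspond to emb_d1's rows
        pts = emb_d[-n:]
        tree = cKDTree(pts)
        dist, idx = tree.query(pts, k=2)
        dist, idx = dist[:, 1], idx[:, 1]
        extra = np.abs(emb_d1[np.arange(n), -1] - emb_d1[idx, -1])
        with np.errstate(divide="ignore", invalid="ignore"):
            # coincident points whose extra coordinate also coincides are
            # true neighbors, not false ones
            ratio = np.where(dist > 0, extra / dist,
                             np.where(extra > 0, np.inf, 0.0))
        fracs[d - 1] = np.mean(ratio > rtol)
    return fracs


def estimate_dim_fnn(series, tau: int, max_d: int = 10, rtol: float = 10.0,
                     fnn_threshold: float = 0.01) -> int:
    """Embedding dimension: smallest d with false-neighbor fraction below
    `fnn_threshold`; max_d with a warning if none qualifies."""
    if tau < 1:
        raise ValueError("tau must be >= 1 for FNN estimation")
    x = _values(series)[:, 0]
    if len(x) < 50 * max_d:
        raise ValueError(f"series too short for max_d={max_d}")
    fracs = fnn_fractions(x, tau, max_d, rtol)
    below = np.nonzero(fracs < fnn_threshold)[0]
    if below.size:
        return int(below[0]) + 1
    warnings.warn("FNN fraction never fell below threshold; returning max_d")
    return max_d
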