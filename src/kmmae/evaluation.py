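"""Metrics and analyses: RMSE, missing-modality restoration, multi-step
rollout prediction, per-step loss traces and the loss-spike reaction-time
detector.

The reaction-time rule follows the physiological use case: once the latent
dynamics has been learned on ordinary (pre-stimulus) data, an unexpected
event makes the reconstruction and prediction losses spike.  The reaction
time is the first post-stimulus step at which both losses stay above a
ratio of their pre-stimulus baselines for a required number of consecutive
steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .embedding import invert_standardizer
from .model import KoopmanModel, decode, encode, fuse, step_linear

__all__ = ["EventTrace", "rmse", "restore_missing", "rollout_predict",
           "loss_trace", "detect_reaction_time", "dmd_fit"]


def dmd_fit(states: np.ndarray) -> np.ndarray:
    """Least-squares linear propagator (dynamic mode decomposition).

    Given a trajectory of (possibly dictionary-lifted) observables, rows
    k = 0..T-1, returns the matrix A minimizing ||X(k+1) - A X(k)||_F —
    the exact solution of the problem the learned Koopman layer
    approximates, used as an independent cross-check in the linear limit.
    """
    states = np.atleast_2d(np.asarray(states, dtype=float))
    X, Y = states[:-1], states[1:]
    A, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return A.T


@dataclass
class EventTrace:
    """Per-time-step reconstruction (loss1) and one-step prediction (loss2)
    losses around a stimulus, on a common time base."""

    loss1: np.ndarray
    loss2: np.ndarray
    stimulus_index: int
    ratio: float = 1.5
    consec_len: int = 3
    time_base: np.ndarray | None = None   # source indices of each trace step
    reaction_index: int | None = None
    baseline1: float = np.nan
    baseline2: float = np.nan
    prestimulus_warning: bool = False


def rmse(truth, estimate) -> float:
    """Root mean squared error over all channels and time steps."""
    truth = np.asarray(truth, dtype=float)
    estimate = np.asarray(estimate, dtype=float)
    if truth.shape != estimate.shape:
        raise ValueError(f"shape mismatch {truth.shape} vs {estimate.shape}")
    return float(np.sqrt(np.mean((truth - estimate) ** 2)))


def restore_missing(model: KoopmanModel, observed: dict, missing: list,
                    destandardize: bool = True) -> dict:
    """Restore missing modalities from the others via the shared latent state.

    observed: modality -> (K, width) standardized embedded rows of the
    modalities that are available (sentinel-filled inputs must not be
    passed: a masked modality simply does not appear here).  Each missing
    modality is decoded from the fused encoding of the observed ones; the
    lag-0 block is mapped back to original units when standardizers are
    attached and `destandardize` is set.

    Returns: modality -> dict with 'embedded' (K, width) and, when
    available, 'values' (K, C) in original units.
    """
    observed = {mid: np.atleast_2d(np.asarray(v, dtype=float))
                for mid, v in observed.items() if mid not in missing}
    if not observed:
        raise ValueError("no observed modalities to restore from")
    enc = {mid: encode(model, mid, v) for mid, v in observed.items()}
    fused = fuse(enc)
    out = {}
    for mid in missing:
        emb = decode(model, mid, fused)
        entry = {"embedded": emb}
        if destandardize and mid in model.standardizers:
            sp = model.standardizers[mid]
            n_ch = sp.mean.size
            entry["values"] = invert_standardizer(emb[:, :n_ch], sp)
        out[mid] = entry
    return out


def rollout_predict(model: KoopmanModel, initial: dict, horizon: int) -> dict:
    """Open-loop prediction: fuse the encodings at time k, advance the latent
    state with A one step at a time, and decode every modality at each step.
    Predictions are never re-encoded.

    initial: modality -> (width,) or (B, width) embedded rows at time k.
    Returns: modality -> (horizon, ...) predicted embedded rows for steps
    k+1 .. k+horizon.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    enc = {mid: encode(model, mid, np.asarray(v, dtype=float))
           for mid, v in initial.items()}
    y = fuse(enc)
    preds = {mid: [] for mid in initial}
    for _ in range(horizon):
        y = step_linear(model, y, 1)
        for mid in initial:
            preds[mid].append(decode(model, mid, y))
    return {mid: np.stack(v) for mid, v in preds.items()}


def loss_trace(model: KoopmanModel, segment: dict, modality_id: str | None = None,
               stimulus_index: int = 0, horizon: int = 1) -> EventTrace:
    """Per-step reconstruction (loss1) and prediction (loss2) losses.

    segment: modality -> (K, width) standardized embedded rows on a common
    time base.  loss1(k) is the squared reconstruction error at step k;
    loss2(k) is the squared error of the `horizon`-step-ahead prediction
    landing at step k (so both traces are aligned on the same steps,
    starting at step `horizon`).  With `modality_id` set, both losses use
    that modality's own encode/decode path — the per-signal configuration
    used for event detection; otherwise losses are summed over modalities
    with fused encodings.
    """
    mids = [modality_id] if modality_id else list(segment)
    seg = {mid: np.atleast_2d(np.asarray(segment[mid], dtype=float)) for mid in mids}
    K = next(iter(seg.values())).shape[0]
    if K <= horizon:
        raise ValueError(f"segment length {K} too short for horizon {horizon}")
    enc = {mid: encode(model, mid, seg[mid]) for mid in mids}
    fused = fuse(enc) if modality_id is None else enc[modality_id]

    recon_err = np.zeros(K)
    pred_err = np.zeros(K)
    y_prop = step_linear(model, fused, horizon)     # rows k -> prediction at k+horizon
    for mid in mids:
        rec = decode(model, mid, enc[mid] if modality_id else fused)
        recon_err += np.sum((seg[mid] - rec) ** 2, axis=1)
        pred = decode(model, mid, y_prop)
        pred_err[horizon:] += np.sum((seg[mid][horizon:] - pred[:-horizon]) ** 2, axis=1)
    time_base = np.arange(horizon, K)
    return EventTrace(loss1=recon_err[horizon:], loss2=pred_err[horizon:],
                      stimulus_index=stimulus_index - horizon,
                      time_base=time_base)


def detect_reaction_time(trace: EventTrace, ratio: float | None = None,
                         consec_len: int | None = None) -> int | None:
    """First step t >= stimulus at which loss1 and loss2 both exceed
    `ratio` times their own pre-stimulus baselines for `consec_len`
    consecutive steps.  Baselines are per-series means over the strictly
    pre-stimulus window.  Returns the index on the trace's time base, or
    None when no qualifying window exists.  Exceedances that begin before
    the stimulus are flagged on the trace as a data-quality warning.
    """
    ratio = trace.ratio if ratio is None else ratio
    consec = trace.consec_len if consec_len is None else consec_len
    if consec < 1:
        raise ValueError("consec_len must be >= 1")
    s = trace.stimulus_index
    if s <= 0:
        raise ValueError("empty pre-stimulus window: no baseline")
    trace.ratio, trace.consec_len = ratio, consec
    trace.baseline1 = float(np.mean(trace.loss1[:s]))
    trace.baseline2 = float(np.mean(trace.loss2[:s]))
    above = ((trace.loss1 > ratio * trace.baseline1)
             & (trace.loss2 > ratio * trace.baseline2))
    if bool(above[:s].any()):
        trace.prestimulus_warning = True
        warnings.warn("losses exceed threshold before the stimulus")
    n = len(above)
    for t in range(s, n - consec + 1):
        if above[t:t + consec].all():
            trace.reaction_index = t
            return t
    trace.reaction_index = None
    return None
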