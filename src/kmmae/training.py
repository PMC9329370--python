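"""Data splitting, augmentation and the optimization loop.

Training minimizes the combined objective with Adam.  Each step draws a
batch of aligned windows, adds white Gaussian noise at the configured SNR
(fresh draw every step, so the network learns to denoise), occasionally
masks one whole modality with the sentinel value (so the network learns to
restore a missing modality from the others), computes the combined loss and
takes an Adam step.  The checkpoint with the best validation total is
returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import autodiff as ad
from .embedding import (StandardizationParams, apply_standardizer, delay_embed,
                        fit_standardizer)
from .losses import LossReport, LossWeights, compute_batch_losses, regularization, total_loss
from .model import KoopmanModel
from .synth_dynamics import ModalSeries

__all__ = ["TrainingConfig", "TrainingHistory", "split_dataset",
           "make_training_windows", "gather_windows", "align_embedded",
           "prepare_series", "train", "Adam"]


@dataclass(frozen=True)
class TrainingConfig:
    """Hyper-parameters of the optimization loop.

    snr_db: noise-augmentation level (None disables augmentation).
    mask_probability: chance per batch of masking one random modality.
    """

    learning_rate: float = 1e-3
    epochs: int = 1000
    batch_size: int = 64
    seed: int = 0
    snr_db: float | None = 10.0
    mask_probability: float = 0.5
    sentinel: float = -1.0
    weights: LossWeights = field(default_factory=LossWeights)
    patience: int = 50
    grad_clip: float = 10.0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 <= self.mask_probability <= 1:
            raise ValueError("mask_probability must be in [0, 1]")


@dataclass
class TrainingHistory:
    train: list = field(default_factory=list)   # LossReport per epoch
    val: list = field(default_factory=list)     # LossReport per epoch
    best_epoch: int = -1

    def as_rows(self) -> list:
        rows = []
        for i, (tr, va) in enumerate(zip(self.train, self.val)):
            row = {"epoch": i}
            row.update({f"train_{k}": v for k, v in tr.as_row().items()})
            row.update({f"val_{k}": v for k, v in va.as_row().items()})
            rows.append(row)
        return rows


def split_dataset(sessions: list, mode: str = "random",
                  fractions: tuple = None, seed: int = 0,
                  labels: list | None = None):
    """Split sessions (random mode) or a single time axis (temporal mode).

    random mode (default fractions 0.8/0.1/0.1): shuffles session indices
    deterministically; when condition labels are supplied the split is
    stratified so train/val/test each contain at least one session per label.
    temporal mode (default fractions 0.7/0.1/0.2): `sessions` is interpreted
    as one time-ordered sequence (or an integer length) and cut at the
    stated fractions; returns three index arrays.
    """
    if mode == "temporal":
        fractions = fractions or (0.7, 0.1, 0.2)
        _check_fractions(fractions)
        n = sessions if isinstance(sessions, int) else len(sessions)
        n_train = int(np.floor(n * fractions[0]))
        n_val = int(np.floor(n * fractions[1]))
        idx = np.arange(n)
        return idx[:n_train], idx[n_train:n_train + n_val], idx[n_train + n_val:]
    if mode != "random":
        raise ValueError(f"unknown split mode {mode!r}")
    fractions = fractions or (0.8, 0.1, 0.1)
    _check_fractions(fractions)
    n = len(sessions)
    if n < 3:
        raise ValueError("random split needs at least 3 sessions")
    rng = np.random.default_rng(seed)
    n_train = max(1, int(round(n * fractions[0])))
    n_val = max(1, int(round(n * fractions[1])))
    n_train = min(n_train, n - 2)
    n_val = min(n_val, n - n_train - 1)
    for _ in range(1000):
        perm = rng.permutation(n)
        tr, va, te = (perm[:n_train], perm[n_train:n_train + n_val],
                      perm[n_train + n_val:])
        if labels is None or _stratified(labels, tr, va, te):
            return np.sort(tr), np.sort(va), np.sort(te)
    missing = _missing_labels(labels, tr, va, te)
    raise ValueError(f"stratification infeasible for condition(s) {missing}")


def _check_fractions(fractions):
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")


def _stratified(labels, *splits) -> bool:
    all_labels = set(labels)
    return all(all_labels <= {labels[i] for i in s} for s in splits)


def _missing_labels(labels, *splits):
    all_labels = set(labels)
    out = set()
    for s in splits:
        out |= all_labels - {labels[i] for i in s}
    return sorted(out)


def align_embedded(embs: dict) -> dict:
    """Truncate delay-embedded matrices to a common (trailing) time range so
    row i refers to the same source time step in every modality."""
    n = min(e.vectors.shape[0] for e in embs.values())
    return {mid: e.vectors[-n:] for mid, e in embs.items()}


def prepare_series(series_list: list, embed_params: dict,
                   standardizers: dict | None = None,
                   fit_indices: np.ndarray | None = None) -> tuple[dict, dict]:
    """Standardize and delay-embed a list of ModalSeries; returns the aligned
    embedded matrices and the standardizers used.

    Standardizers are fitted on `fit_indices` (the training rows) when not
    supplied, so statistics never leak from validation or test data.
    """
    standardizers = dict(standardizers or {})
    embs = {}
    for s in series_list:
        if s.modality_id not in standardizers:
            fit_view = s.values if fit_indices is None else s.values[fit_indices]
            standardizers[s.modality_id] = fit_standardizer(fit_view)
        z = apply_standardizer(s, standardizers[s.modality_id])
        d, tau = embed_params[s.modality_id]
        embs[s.modality_id] = delay_embed(z, d, tau)
    return align_embedded(embs), standardizers


def make_training_windows(embedded: dict, m: int) -> np.ndarray:
    """Window start indices k such that the m-step targets k+1..k+m exist in
    every (aligned) modality."""
    if m < 0:
        raise ValueError("m must be >= 0")
    lengths = {mid: arr.shape[0] for mid, arr in embedded.items()}
    n = min(lengths.values())
    if max(lengths.values()) != n:
        raise ValueError("modalities are not aligned; use align_embedded first")
    if n <= m:
        raise ValueError(f"series of length {n} cannot host m={m} targets")
    return np.arange(n - m)


def gather_windows(embedded: dict, ks: np.ndarray, m: int) -> dict:
    """Stack windows: modality -> (m+1, B, width), index j = rows at k+j."""
    return {mid: np.stack([arr[ks + j] for j in range(m + 1)])
            for mid, arr in embedded.items()}


class Adam:
    """Adam optimizer over a dict of named numpy parameters (in-place)."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def _clip_grads(grads: dict, max_norm: float):
    total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
    if max_norm and total > max_norm:
        scale = max_norm / total
        for g in grads.values():
            g *= scale


def _noise_for(shape, col_std, snr_db, rng):
    sigma = col_std / np.sqrt(10.0 ** (snr_db / 10.0))
    return rng.standard_normal(shape) * sigma


def _epoch_report(model: KoopmanModel, data: dict, m: int,
                  weights: LossWeights) -> LossReport:
    """Full-batch loss report without augmentation (used for validation)."""
    ks = make_training_windows(data, m)
    windows = gather_windows(data, ks, m)
    inputs = {mid: w[0] for mid, w in windows.items()}
    params_t = {k: ad.constant(v) for k, v in model.params.items()}
    comp = compute_batch_losses(params_t, model.arch, inputs, windows, m)
    comps = {k: comp[k].item() for k in ("recon", "predict", "linear", "modality")}
    comps["per_modality"] = comp["per_modality_recon"]
    return total_loss(comps, weights, model)


def train(model: KoopmanModel, train_data: dict, config: TrainingConfig,
          val_data: dict | None = None) -> tuple[KoopmanModel, TrainingHistory]:
    """Optimize the model on aligned embedded matrices.

    train_data / val_data: modality -> (K, width) standardized embedded rows.
    Returns the best-validation checkpoint (a copy) and the history.  The
    whole run is a pure function of (model, data, config.seed).
    """
    m = config.weights.m
    history = TrainingHistory()
    if config.epochs == 0:
        history.best_epoch = -1
        return model.copy(), history
    rng = np.random.default_rng(config.seed)
    ks_all = make_training_windows(train_data, m)
    col_std = {mid: arr.std(axis=0) for mid, arr in train_data.items()}
    opt = Adam(model.params, lr=config.learning_rate)
    mids = list(train_data)
    sel_data = val_data if val_data is not None else train_data

    best = model.copy()
    best_total = np.inf
    best_epoch = -1
    since_best = 0
    n_batches = max(1, len(ks_all) // config.batch_size)

    for epoch in range(config.epochs):
        order = rng.permutation(len(ks_all))
        for b in range(n_batches):
            ks = ks_all[order[b * config.batch_size:(b + 1) * config.batch_size]]
            if len(ks) == 0:
                continue
            windows = gather_windows(train_data, ks, m)
            inputs = {mid: w[0].copy() for mid, w in windows.items()}
            if config.snr_db is not None and np.isfinite(config.snr_db):
                for mid in mids:
                    inputs[mid] += _noise_for(inputs[mid].shape, col_std[mid],
                                              config.snr_db, rng)
            missing = frozenset()
            if len(mids) > 1 and rng.random() < config.mask_probability:
                masked = mids[rng.integers(len(mids))]
                inputs[masked][:] = config.sentinel
                missing = frozenset([masked])

            params_t = {k: ad.parameter(v) for k, v in model.params.items()}
            comp = compute_batch_losses(params_t, model.arch, inputs, windows,
                                        m, missing)
            w = config.weights
            reg_t = regularization(params_t, model.weight_names())
            loss_t = (w.lambda_recon * (comp["recon"] + w.lambda_predict * comp["predict"])
                      + w.lambda_linear * comp["linear"]
                      + w.lambda_modality * comp["modality"]
                      + w.lambda_reg * reg_t)
            if not np.isfinite(loss_t.value):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: "
                    + str({k: comp[k].item() for k in ("recon", "predict", "linear", "modality")}))
            loss_t.backward()
            grads = {k: t.grad for k, t in params_t.items() if t.grad is not None}
            _clip_grads(grads, config.grad_clip)
            opt.step(model.params, grads)

        history.train.append(_epoch_report(model, train_data, m, config.weights))
        val_report = _epoch_report(model, sel_data, m, config.weights)
        history.val.append(val_report)
        if val_report.total < best_total:
            best_total = val_report.total
            best = model.copy()
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if config.patience and since_best >= config.patience:
                break
    history.best_epoch = best_epoch
    return best, history
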