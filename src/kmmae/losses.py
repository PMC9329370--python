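"""Loss terms of the Koopman multi-modal auto-encoder.

Four custom terms shape the joint latent space:

* reconstruction  — each modality must decode back from its own encoding;
* prediction      — each modality (including a masked one) must decode from
                    the fused latent state propagated j = 1..m steps by A;
* linearity       — each modality's own latent trajectory must follow the
                    linear dynamics A in latent space;
* modality (center) — the per-modality encodings are pulled toward their
                    mean, enforcing one shared latent trajectory.

All residuals use the squared L2 norm so gradients stay smooth and the
terms remain commensurate under a single reconstruction weight.  Every term
is a mean over the batch (and, where applicable, over modalities), which
keeps the weights lambda independent of batch size.  A masked modality is
excluded from the reconstruction, linearity and modality sums and from the
fusion mean, but its decoder still receives gradients through the
prediction term — that is what trains the network to restore a missing
modality from the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .model import KoopmanModel, ModelArch, decode_t, encode_t, step_linear_t

__all__ = ["LossWeights", "LossReport", "compute_batch_losses", "recon_loss",
           "predict_loss", "linear_loss", "modality_loss", "regularization",
           "total_loss"]


@dataclass(frozen=True)
class LossWeights:
    """Weights of the combined objective and the rollout horizon m.

    total = lambda_recon * (L_recon + lambda_predict * L_predict)
          + lambda_linear * L_linear + lambda_modality * L_modality
          + lambda_reg * ||W||^2.

    lambda_predict is an extra multiplier on the prediction term (default 1,
    in which case the prediction loss simply shares lambda_recon).
    """

    lambda_recon: float = 1.0
    lambda_predict: float = 1.0
    lambda_linear: float = 1.0
    lambda_modality: float = 1.0
    lambda_reg: float = 1e-8
    m: int = 1

    def __post_init__(self):
        lams = (self.lambda_recon, self.lambda_predict, self.lambda_linear,
                self.lambda_modality, self.lambda_reg)
        if any(l < 0 for l in lams):
            raise ValueError("loss weights must be nonnegative")
        if self.m < 1:
            raise ValueError("horizon m must be >= 1")


@dataclass
class LossReport:
    recon: float
    predict: float
    linear: float
    modality: float
    reg: float
    total: float
    per_modality: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        return {"recon": self.recon, "predict": self.predict,
                "linear": self.linear, "modality": self.modality,
                "reg": self.reg, "total": self.total}


def _sq_norm_rows(t: Tensor) -> Tensor:
    """Per-row squared L2 norm, then mean over rows -> scalar tensor."""
    return t.square().sum(axis=1).mean()


def compute_batch_losses(params: dict, arch: ModelArch, inputs: dict,
                         targets: dict, m: int,
                         missing: frozenset = frozenset()) -> dict:
    """Tensor-valued loss components on one batch of aligned windows.

    inputs:  modality -> (B, width) embedded rows at time k (possibly noisy).
    targets: modality -> (m+1, B, width) clean rows at k, k+1, ..., k+m.
    missing: modalities masked for this batch (excluded from fusion and from
             the recon/linear/modality sums).
    Returns a dict of scalar Tensors: recon, predict, linear, modality.
    """
    mids = list(inputs)
    present = [mid for mid in mids if mid not in missing]
    if not present:
        raise ValueError("all modalities missing in batch")
    x_in = {mid: ad.constant(inputs[mid]) for mid in mids}
    enc = {mid: encode_t(params, arch, mid, x_in[mid]) for mid in present}
    fused = ad.stack_mean([enc[mid] for mid in present])

    # reconstruction: own-encoding round trip, masked modalities excluded
    recon_terms = []
    per_mod_recon = {}
    for mid in present:
        res = ad.constant(targets[mid][0]) - decode_t(params, arch, mid, enc[mid])
        term = _sq_norm_rows(res)
        recon_terms.append(term)
        per_mod_recon[mid] = term.item()
    recon = ad.stack_mean(recon_terms)

    # prediction: fused state propagated by A^j, decoded per modality
    pred_sum = None
    y = fused
    for j in range(1, m + 1):
        y = step_linear_t(params, y, 1)
        for mid in mids:
            res = ad.constant(targets[mid][j]) - decode_t(params, arch, mid, y)
            term = _sq_norm_rows(res)
            pred_sum = term if pred_sum is None else pred_sum + term
    predict = pred_sum * (1.0 / m) if pred_sum is not None else ad.constant(0.0)

    # linearity: per-modality latent trajectory follows A
    lin_sum = None
    for mid in present:
        y_l = enc[mid]
        for j in range(1, m + 1):
            y_l = step_linear_t(params, y_l, 1)
            res = encode_t(params, arch, mid, ad.constant(targets[mid][j])) - y_l
            term = _sq_norm_rows(res)
            lin_sum = term if lin_sum is None else lin_sum + term
    linear = lin_sum * (1.0 / m) if lin_sum is not None else ad.constant(0.0)

    # modality (center) loss: encodings pulled toward the fused mean
    mod_terms = [_sq_norm_rows(fused - enc[mid]) for mid in present]
    modality = ad.stack_mean(mod_terms)

    return {"recon": recon, "predict": predict, "linear": linear,
            "modality": modality, "per_modality_recon": per_mod_recon}


def regularization(params: dict, weight_names: list) -> Tensor | float:
    """Sum of squared weight-matrix entries (biases excluded)."""
    acc = None
    for name in weight_names:
        w = params[name]
        term = w.square().sum() if isinstance(w, Tensor) else float(np.sum(w ** 2))
        acc = term if acc is None else acc + term
    return acc


# ------------------------------------------------------------ numpy wrappers

def _tensorize(model: KoopmanModel) -> dict:
    return {k: ad.constant(v) for k, v in model.params.items()}


def _stack_windows(windows: dict, m: int) -> tuple[dict, dict]:
    """windows: modality -> (m+1, B, w) array; returns (inputs, targets)."""
    inputs, targets = {}, {}
    for mid, arr in windows.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 3 or arr.shape[0] < m + 1:
            raise ValueError(f"modality {mid!r}: windows must be (>=m+1, B, w), "
                             f"got {arr.shape} for m={m}")
        inputs[mid] = arr[0]
        targets[mid] = arr
    return inputs, targets


def recon_loss(model: KoopmanModel, batch: dict,
               missing: frozenset = frozenset()) -> float:
    """Mean over batch and non-missing modalities of the squared
    reconstruction error ||x - decode(encode(x))||^2."""
    batch = {mid: np.atleast_2d(np.asarray(v, dtype=float)) for mid, v in batch.items()}
    if not batch or any(v.shape[0] == 0 for v in batch.values()):
        raise ValueError("empty batch")
    targets = {mid: v[None] for mid, v in batch.items()}
    comp = compute_batch_losses(_tensorize(model), model.arch, batch, targets,
                                m=0, missing=missing)
    return comp["recon"].item()


def predict_loss(model: KoopmanModel, windows: dict, m: int) -> float:
    """(1/m) * mean over batch of sum_l sum_{j=1..m}
    ||x_l(k+j) - decode_l(A^j fused(k))||^2."""
    inputs, targets = _stack_windows(windows, m)
    comp = compute_batch_losses(_tensorize(model), model.arch, inputs, targets, m)
    return comp["predict"].item()


def linear_loss(model: KoopmanModel, windows: dict, m: int) -> float:
    """(1/m) * mean over batch of sum_l sum_{j=1..m}
    ||encode_l(x_l(k+j)) - A^j encode_l(x_l(k))||^2."""
    inputs, targets = _stack_windows(windows, m)
    comp = compute_batch_losses(_tensorize(model), model.arch, inputs, targets, m)
    return comp["linear"].item()


def modality_loss(encodings: dict, fused: np.ndarray | None = None,
                  missing: frozenset = frozenset()) -> float:
    """Center loss: mean over non-missing modalities of ||y - y_l||^2."""
    keep = [mid for mid in encodings if mid not in missing]
    if not keep:
        raise ValueError("all modalities missing")
    encs = {mid: np.atleast_2d(np.asarray(encodings[mid], dtype=float)) for mid in keep}
    if fused is None:
        fused = np.mean([encs[mid] for mid in keep], axis=0)
    fused = np.atleast_2d(np.asarray(fused, dtype=float))
    per = [np.mean(np.sum((fused - encs[mid]) ** 2, axis=1)) for mid in keep]
    return float(np.mean(per))


def total_loss(components: dict, weights: LossWeights,
               model: KoopmanModel | None = None,
               reg: float | None = None) -> LossReport:
    """Combine components into the weighted objective.

    components: dict with recon/predict/linear/modality (floats).  The
    regularization term is computed from `model` unless `reg` is given.
    """
    if reg is None:
        reg = float(regularization(model.params, model.weight_names())) if model else 0.0
    recon = float(components.get("recon", 0.0))
    predict = float(components.get("predict", 0.0))
    linear = float(components.get("linear", 0.0))
    modality = float(components.get("modality", 0.0))
    total = (weights.lambda_recon * (recon + weights.lambda_predict * predict)
             + weights.lambda_linear * linear
             + weights.lambda_modality * modality
             + weights.lambda_reg * reg)
    return LossReport(recon, predict, linear, modality, reg, total,
                      dict(components.get("per_modality", {})))
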