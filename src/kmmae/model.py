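"""Multi-modal auto-encoder with a shared latent layer and a linear
Koopman propagator.

Each modality l has its own encoder phi_l (an inverse-observation function)
mapping the delay-embedded input into a joint latent space of width p, and a
mirror decoder phi_l^{-1} mapping latent states back to that modality.  The
per-modality encodings are fused by an arithmetic mean over the non-missing
modalities, and a single bias-free, activation-free p x p matrix A — the
finite approximation of the Koopman operator — advances the fused state one
step: y(k+1) = A y(k).

Architecture: two ReLU hidden layers (20 then 15 nodes by default), a linear
projection into the joint layer (width p, default 20), and mirror decoders
(15 then 20, ReLU) with a linear output layer.  The projection and output
layers are linear so the latent space and the standardized signals can take
negative values, which linear dynamics with oscillatory or sign-changing
eigenvalues require.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["ModelArch", "KoopmanModel", "init_params", "encode", "fuse",
           "step_linear", "decode", "koopman_spectrum"]


@dataclass(frozen=True)
class ModelArch:
    """Widths and activation of the multi-modal auto-encoder.

    input_widths: modality_id -> embedded input width (d * C).
    hidden: encoder hidden-layer widths (decoders mirror them).
    p: joint (Koopman) layer width.
    activation: 'relu' for the standard network, 'identity' for the fully
        linear variant used to study the linear-system limit.
    """

    input_widths: dict
    hidden: tuple = (20, 15)
    p: int = 20
    activation: str = "relu"

    def __post_init__(self):
        if self.activation not in ("relu", "identity"):
            raise ValueError("activation must be 'relu' or 'identity'")
        if self.p < 1 or any(w < 1 for w in self.hidden):
            raise ValueError("layer widths must be positive")

    @property
    def modality_ids(self) -> list:
        return list(self.input_widths)


@dataclass
class KoopmanModel:
    """The trained artifact: per-modality encoder/decoder weights plus A.

    params maps names like ``hr/enc/W0`` to float64 arrays; ``A`` is the
    p x p linear Koopman approximation.  Optional preprocessing metadata
    (standardizers, embedding parameters) travels with the model so that
    evaluation can map back to original units.
    """

    arch: ModelArch
    params: dict
    standardizers: dict = field(default_factory=dict)   # modality -> StandardizationParams
    embed_params: dict = field(default_factory=dict)    # modality -> (d, tau)

    @property
    def p(self) -> int:
        return self.arch.p

    @property
    def A(self) -> np.ndarray:
        return self.params["A"]

    @property
    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def copy(self) -> "KoopmanModel":
        return KoopmanModel(self.arch, {k: v.copy() for k, v in self.params.items()},
                            dict(self.standardizers), dict(self.embed_params))

    def weight_names(self) -> list:
        """Names of weight matrices (biases excluded), including A."""
        return [k for k in self.params if not k.split("/")[-1].startswith("b")]


def _xavier(rng: np.random.Generator, fan_out: int, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_out, fan_in))


def init_params(arch: ModelArch, seed: int = 0) -> KoopmanModel:
    """Xavier-initialized weights, zero biases, A = identity.

    A starts at the identity so the initial latent dynamics is stable and
    norm-preserving; training then bends its spectrum toward the system's.
    """
    rng = np.random.default_rng(seed)
    params: dict = {}
    for mid, w_in in arch.input_widths.items():
        widths_enc = [w_in, *arch.hidden, arch.p]
        for i, (a, b) in enumerate(zip(widths_enc[:-1], widths_enc[1:])):
            params[f"{mid}/enc/W{i}"] = _xavier(rng, b, a)
            params[f"{mid}/enc/b{i}"] = np.zeros(b)
        widths_dec = [arch.p, *arch.hidden[::-1], w_in]
        for i, (a, b) in enumerate(zip(widths_dec[:-1], widths_dec[1:])):
            params[f"{mid}/dec/W{i}"] = _xavier(rng, b, a)
            params[f"{mid}/dec/b{i}"] = np.zeros(b)
    params["A"] = np.eye(arch.p)
    return KoopmanModel(arch, params)


# --------------------------------------------------------------------- forward
# The same forward definitions serve training (Tensor parameters, gradients
# recorded) and inference (plain arrays wrapped as constants).

def _act(t: Tensor, kind: str) -> Tensor:
    return t.relu() if kind == "relu" else t


def _mlp(params: dict, prefix: str, x: Tensor, n_layers: int, kind: str,
         linear_last: bool = True) -> Tensor:
    h = x
    for i in range(n_layers):
        h = h @ params[f"{prefix}/W{i}"].T + params[f"{prefix}/b{i}"]
        if not (linear_last and i == n_layers - 1):
            h = _act(h, kind)
    return h


def encode_t(params: dict, arch: ModelArch, modality_id: str, x: Tensor) -> Tensor:
    return _mlp(params, f"{modality_id}/enc", x, len(arch.hidden) + 1, arch.activation)


def decode_t(params: dict, arch: ModelArch, modality_id: str, y: Tensor) -> Tensor:
    return _mlp(params, f"{modality_id}/dec", y, len(arch.hidden) + 1, arch.activation)


def step_linear_t(params: dict, y: Tensor, j: int = 1) -> Tensor:
    for _ in range(j):
        y = y @ params["A"].T
    return y


def _as_tensor_params(model: KoopmanModel) -> dict:
    return {k: ad.constant(v) for k, v in model.params.items()}


def encode(model: KoopmanModel, modality_id: str, x: np.ndarray) -> np.ndarray:
    """Encode embedded input rows (n x d*C, or a single row) to latent p-vectors."""
    x = np.asarray(x, dtype=float)
    w = model.arch.input_widths[modality_id]
    if x.shape[-1] != w:
        raise ValueError(f"input width {x.shape[-1]} != expected {w} "
                         f"for modality {modality_id!r}")
    return encode_t(_as_tensor_params(model), model.arch, modality_id,
                    ad.constant(x)).value


def decode(model: KoopmanModel, modality_id: str, y: np.ndarray) -> np.ndarray:
    """Decode latent p-vectors back to the modality's embedded input space."""
    y = np.asarray(y, dtype=float)
    if y.shape[-1] != model.p:
        raise ValueError(f"latent width {y.shape[-1]} != p={model.p}")
    return decode_t(_as_tensor_params(model), model.arch, modality_id,
                    ad.constant(y)).value


def fuse(encodings: dict, missing: set | frozenset = frozenset()) -> np.ndarray:
    """Arithmetic mean of the per-modality encodings over non-missing
    modalities — the shared latent state y(k)."""
    keep = [mid for mid in encodings if mid not in missing]
    if not keep:
        raise ValueError("all modalities missing: cannot fuse")
    return np.mean([np.asarray(encodings[mid], dtype=float) for mid in keep], axis=0)


def step_linear(model: KoopmanModel, y: np.ndarray, j: int = 1) -> np.ndarray:
    """Advance a latent state j steps under the linear dynamics: A^j y."""
    if j < 0:
        raise ValueError("j must be >= 0")
    y = np.asarray(y, dtype=float)
    for _ in range(j):
        y = y @ model.A.T
    return y


def koopman_spectrum(model: KoopmanModel) -> tuple[np.ndarray, float]:
    """Eigenvalues of A sorted by modulus (descending) and the spectral radius."""
    eig = np.linalg.eigvals(model.A)
    order = np.argsort(-np.abs(eig), kind="stable")
    eig = eig[order]
    return eig, float(np.abs(eig[0]))
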