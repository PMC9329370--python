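import numpy as np
import pytest

import kmmae as K
from kmmae.losses import LossWeights
from kmmae.model import ModelArch, init_params
from kmmae.training import TrainingConfig, prepare_series, train


@pytest.fixture(scope="session")
def rotation_series():
    """Two noiseless modalities observing a 2-D latent rotation, with a
    5-step observation delay on the second modality."""
    pre = K.LatentSystemSpec("linear_discrete", {"M": K.rotation_matrix(0.15)},
                             1.0, [1.0, 0.0])
    obs = K.ObservationSpec((
        K.ModalityObservation("A", "identity", channels=2, delay_steps=0),
        K.ModalityObservation("B", "identity", channels=2, delay_steps=5),
    ))
    latent = K.simulate_latent(pre, 600)
    return K.observe_modalities(latent, obs, seed=3)


@pytest.fixture(scope="session")
def linear_benchmark_model():
    """Small fully linear model trained on a noiseless 2-D diagonal linear
    system observed identically — the analytically solvable limit."""
    spec = K.LatentSystemSpec("linear_discrete", {"M": np.diag([0.9, 0.5])},
                              1.0, [1.0, 1.0])
    latent = K.simulate_latent(spec, 500)
    obs = K.ObservationSpec((K.ModalityObservation("x", "identity", channels=2),))
    series = K.observe_modalities(latent, obs)
    d_tau = {"x": (1, 1)}
    n_tr, n_va = 350, 50
    data, st = prepare_series(series, d_tau, fit_indices=np.arange(n_tr))
    arch = ModelArch({"x": 2}, hidden=(10, 10), p=2, activation="identity")
    model = init_params(arch, 0)
    model.standardizers, model.embed_params = st, d_tau
    cfg = TrainingConfig(epochs=250, batch_size=64, seed=0, snr_db=None,
                         mask_probability=0.0, weights=LossWeights(m=3),
                         patience=10_000)
    trained, hist = train(model, {m: v[:n_tr] for m, v in data.items()}, cfg,
                          {m: v[n_tr:n_tr + n_va] for m, v in data.items()})
    test = {m: v[n_tr + n_va:] for m, v in data.items()}
    return {"model": trained, "history": hist, "data": data, "test": test,
            "M": np.diag([0.9, 0.5]), "n_train": n_tr}
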