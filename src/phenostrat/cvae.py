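"""Site-conditioned variational autoencoder on curated phenome matrices.

The model is a conditional VAE with an optional linear (PCA) front-end
projection: the curated matrix X is optionally projected to ``frontend_dim``
principal components (fit on the training split only), the encoder is a
one-hidden-layer MLP mapping [x, c] -> (mu, log sigma^2) of the diagonal
Gaussian posterior q(z | x, c), and the decoder maps [z, c] -> x with a
linear output layer. The condition c is the one-of-n data-collection-site
vector, appended to both the encoder input and the latent before decoding,
so the latent space need not encode site. Training maximizes the evidence
lower bound: squared-error reconstruction (Gaussian likelihood up to
constants) plus the closed-form KL divergence from q to the standard normal
prior, optimized with Adam and early stopping on validation loss.

Implemented directly on NumPy (explicit backpropagation); the networks are
small enough that hand-derived gradients for the two-layer encoder/decoder
are simpler and faster here than a framework dependency.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from typing import Optional

import numpy as np
from sklearn.decomposition import PCA

from .splits import SplitAssignment

_LOGVAR_CLIP = 12.0


class TrainingDivergedError(RuntimeError):
    pass


@dataclass(frozen=True)
class CVAEConfig:
    """Architecture and optimization settings for one CVAE."""

    frontend_dim: Optional[int] = None  # PCA projection size; None = raw input
    hidden_dim: int = 150
    latent_dim: int = 100
    condition_on_site: bool = True
    beta: float = 1.0  # KL weight; 1 recovers the plain ELBO
    learning_rate: float = 1e-3
    max_epochs: int = 300
    patience: int = 10
    batch_size: int = 128
    activation: str = "relu"  # "relu" | "linear"
    seed: int = 0

    def __post_init__(self):
        if self.frontend_dim is not None and self.latent_dim > self.frontend_dim:
            raise ValueError("latent_dim must not exceed frontend_dim")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.activation not in ("relu", "linear"):
            raise ValueError(f"activation must be 'relu' or 'linear', got {self.activation!r}")


# Candidate grid of the architecture comparison: (frontend PCA dim, hidden
# width). The first three ingest the curated matrix directly.
CANDIDATE_GRID: tuple[tuple[Optional[int], int], ...] = (
    (None, 200),
    (None, 400),
    (None, 800),
    (400, 200),
    (200, 150),
    (150, 125),
)


def candidate_configs(latent_dim: int = 100, grid=CANDIDATE_GRID, **kwargs) -> list[CVAEConfig]:
    return [CVAEConfig(frontend_dim=fe, hidden_dim=h, latent_dim=latent_dim, **kwargs) for fe, h in grid]


class _Frontend:
    """Linear projection front-end (PCA basis + mean), or identity."""

    def __init__(self, mean: np.ndarray | None, components: np.ndarray | None):
        self.mean = mean
        self.components = components  # frontend_dim x ambient_dim, orthonormal rows

    @classmethod
    def identity(cls) -> "_Frontend":
        return cls(None, None)

    @classmethod
    def fit(cls, x_train: np.ndarray, dim: int, seed: int) -> "_Frontend":
        if dim > min(x_train.shape):
            raise ValueError(f"frontend_dim={dim} exceeds training data rank bound {min(x_train.shape)}")
        pca = PCA(n_components=dim, random_state=seed)
        pca.fit(x_train)
        return cls(pca.mean_.copy(), pca.components_.copy())

    @property
    def is_identity(self) -> bool:
        return self.components is None

    def project(self, x: np.ndarray) -> np.ndarray:
        if self.is_identity:
            return x
        return (x - self.mean) @ self.components.T

    def invert(self, xf: np.ndarray) -> np.ndarray:
        if self.is_identity:
            return xf
        return xf @ self.components + self.mean


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


@dataclass
class CVAEModel:
    """Trained (or initialized) conditional VAE.

    ``params`` holds the eight weight/bias arrays of the two-layer encoder
    and decoder; ``site_categories`` fixes the one-of-n condition encoding
    learned at training time.
    """

    config: CVAEConfig
    params: dict[str, np.ndarray]
    frontend: _Frontend
    site_categories: np.ndarray | None  # None when unconditioned
    ambient_dim: int
    history: dict[str, list] = field(default_factory=dict)

    # -- condition encoding -------------------------------------------
    def onehot(self, site_labels) -> np.ndarray:
        if self.site_categories is None:
            return np.zeros((len(site_labels), 0))
        labels = np.asarray(site_labels)
        cat_index = {c: i for i, c in enumerate(self.site_categories)}
        try:
            cols = np.array([cat_index[s] for s in labels])
        except KeyError as e:
            raise ValueError(f"site label {e.args[0]!r} not seen during training") from None
        c = np.zeros((len(labels), len(self.site_categories)))
        c[np.arange(len(labels)), cols] = 1.0
        return c

    @property
    def n_condition(self) -> int:
        return 0 if self.site_categories is None else len(self.site_categories)

    # -- network pieces ------------------------------------------------
    def _hidden(self, pre: np.ndarray) -> np.ndarray:
        return np.maximum(pre, 0.0) if self.config.activation == "relu" else pre

    def encode_frontend(self, xf: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        p = self.params
        pre = np.concatenate([xf, c], axis=1) @ p["eW1"] + p["eb1"]
        h = self._hidden(pre)
        out = h @ p["eW2"] + p["eb2"]
        k = self.config.latent_dim
        mu, logvar = out[:, :k], np.clip(out[:, k:], -_LOGVAR_CLIP, _LOGVAR_CLIP)
        return mu, logvar

    def decode_frontend(self, z: np.ndarray, c: np.ndarray) -> np.ndarray:
        p = self.params
        pre = np.concatenate([z, c], axis=1) @ p["dW1"] + p["db1"]
        return self._hidden(pre) @ p["dW2"] + p["db2"]

    def _cond(self, n_rows: int, site_labels) -> np.ndarray:
        if self.site_categories is None:
            return np.zeros((n_rows, 0))
        if site_labels is None:
            raise ValueError("model is site-conditioned; site_labels required")
        return self.onehot(site_labels)

    # -- ambient-space interface ----------------------------------------
    def encode(self, x: np.ndarray, site_labels=None) -> tuple[np.ndarray, np.ndarray]:
        x = np.asarray(x, dtype=float)
        return self.encode_frontend(self.frontend.project(x), self._cond(x.shape[0], site_labels))

    def decode(self, z: np.ndarray, site_labels=None) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        return self.frontend.invert(self.decode_frontend(z, self._cond(z.shape[0], site_labels)))

    def reconstruct(self, x: np.ndarray, site_labels=None, mode: str = "posterior_mean",
                    rng: np.random.Generator | None = None) -> np.ndarray:
        """Encode then decode; ``mode`` 'posterior_mean' (default, deterministic)
        or 'sample' (seeded draw from q)."""
        mu, logvar = self.encode(x, site_labels)
        if mode == "posterior_mean":
            z = mu
        elif mode == "sample":
            rng = rng or np.random.default_rng(self.config.seed)
            z = mu + np.exp(0.5 * logvar) * rng.standard_normal(mu.shape)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        return self.decode(z, site_labels)


def save_model(model: CVAEModel, path) -> None:
    """Checkpoint: parameters + config + front-end + condition vocabulary."""
    import json

    payload = {f"param_{k}": v for k, v in model.params.items()}
    payload["config_json"] = np.array(json.dumps(asdict(model.config)))
    payload["ambient_dim"] = np.array(model.ambient_dim)
    payload["history_train"] = np.array(model.history.get("train_loss", []))
    payload["history_val"] = np.array(model.history.get("val_loss", []))
    if model.site_categories is not None:
        payload["site_categories"] = model.site_categories
    if not model.frontend.is_identity:
        payload["frontend_mean"] = model.frontend.mean
        payload["frontend_components"] = model.frontend.components
    np.savez(path, **payload)


def load_model(path) -> CVAEModel:
    import json

    z = np.load(path, allow_pickle=False)
    cfg_dict = json.loads(str(z["config_json"]))
    cfg = CVAEConfig(**cfg_dict)
    params = {k[len("param_"):]: z[k] for k in z.files if k.startswith("param_")}
    frontend = (
        _Frontend(z["frontend_mean"], z["frontend_components"])
        if "frontend_mean" in z.files else _Frontend.identity()
    )
    sites = z["site_categories"] if "site_categories" in z.files else None
    return CVAEModel(
        config=cfg, params=params, frontend=frontend, site_categories=sites,
        ambient_dim=int(z["ambient_dim"]),
        history={"train_loss": z["history_train"].tolist(),
                 "val_loss": z["history_val"].tolist()},
    )


def reconstruct(model: CVAEModel, x, c=None, mode: str = "posterior_mean",
                rng: np.random.Generator | None = None) -> np.ndarray:
    """Functional alias for :meth:`CVAEModel.reconstruct`."""
    return model.reconstruct(x, c, mode=mode, rng=rng)


def elbo_loss(x_batch: np.ndarray, c_batch: np.ndarray | None, model: CVAEModel,
              beta: float | None = None, rng: np.random.Generator | None = None
              ) -> tuple[float, float, float]:
    """Evaluate (total, reconstruction, KL) on a batch in model input space.

    Reconstruction is the per-sample summed squared error between decoder
    output and input, averaged over the batch; KL is the closed-form
    divergence of the diagonal Gaussian posterior from the standard normal
    prior, 0.5 * sum(mu^2 + sigma^2 - log sigma^2 - 1). With ``rng`` None the
    posterior mean is decoded (deterministic); otherwise one reparameterized
    sample is drawn.
    """
    beta = model.config.beta if beta is None else beta
    x = np.asarray(x_batch, dtype=float)
    c = np.zeros((x.shape[0], 0)) if c_batch is None else np.asarray(c_batch, dtype=float)
    mu, logvar = model.encode_frontend(x, c)
    z = mu if rng is None else mu + np.exp(0.5 * logvar) * rng.standard_normal(mu.shape)
    xhat = model.decode_frontend(z, c)
    recon = float(np.mean(np.sum((x - xhat) ** 2, axis=1)))
    kl = float(np.mean(0.5 * np.sum(mu ** 2 + np.exp(logvar) - logvar - 1.0, axis=1)))
    total = recon + beta * kl
    if not np.isfinite(total):
        raise TrainingDivergedError("non-finite loss on batch; inspect activations / lower the learning rate")
    return total, recon, kl


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray],
             b1: float = 0.9, b2: float = 0.999, eps: float = 1e-8) -> None:
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)


def _init_params(config: CVAEConfig, input_dim: int, n_cond: int,
                 rng: np.random.Generator) -> dict[str, np.ndarray]:
    k, h = config.latent_dim, config.hidden_dim
    return {
        "eW1": _glorot(rng, input_dim + n_cond, h),
        "eb1": np.zeros(h),
        "eW2": _glorot(rng, h, 2 * k),
        "eb2": np.zeros(2 * k),
        "dW1": _glorot(rng, k + n_cond, h),
        "db1": np.zeros(h),
        "dW2": _glorot(rng, h, input_dim),
        "db2": np.zeros(input_dim),
    }


def _batch_grads(model: CVAEModel, x: np.ndarray, c: np.ndarray,
                 rng: np.random.Generator) -> tuple[dict[str, np.ndarray], float]:
    """Forward + hand-derived backward pass for one minibatch.

    Overflow is not trapped here — the caller checks the returned loss for
    finiteness and raises a diagnosis.
    """
    p = model.params
    cfg = model.config
    k = cfg.latent_dim
    n = x.shape[0]
    relu = cfg.activation == "relu"

    xin = np.concatenate([x, c], axis=1)
    pre1 = xin @ p["eW1"] + p["eb1"]
    h1 = np.maximum(pre1, 0.0) if relu else pre1
    out = h1 @ p["eW2"] + p["eb2"]
    mu, logvar = out[:, :k], np.clip(out[:, k:], -_LOGVAR_CLIP, _LOGVAR_CLIP)
    eps = rng.standard_normal(mu.shape)
    sig = np.exp(0.5 * logvar)
    z = mu + sig * eps
    zin = np.concatenate([z, c], axis=1)
    pre2 = zin @ p["dW1"] + p["db1"]
    h2 = np.maximum(pre2, 0.0) if relu else pre2
    xhat = h2 @ p["dW2"] + p["db2"]

    recon = float(np.mean(np.sum((x - xhat) ** 2, axis=1)))
    kl = float(np.mean(0.5 * np.sum(mu ** 2 + np.exp(logvar) - logvar - 1.0, axis=1)))
    loss = recon + cfg.beta * kl

    dxhat = 2.0 * (xhat - x) / n
    gdW2 = h2.T @ dxhat
    gdb2 = dxhat.sum(axis=0)
    dh2 = dxhat @ p["dW2"].T
    if relu:
        dh2 = dh2 * (pre2 > 0)
    gdW1 = zin.T @ dh2
    gdb1 = dh2.sum(axis=0)
    dzin = dh2 @ p["dW1"].T
    dz = dzin[:, :k]

    dmu = dz + cfg.beta * mu / n
    dlogvar = dz * eps * 0.5 * sig + cfg.beta * 0.5 * (np.exp(logvar) - 1.0) / n
    dout = np.concatenate([dmu, dlogvar], axis=1)
    geW2 = h1.T @ dout
    geb2 = dout.sum(axis=0)
    dh1 = dout @ p["eW2"].T
    if relu:
        dh1 = dh1 * (pre1 > 0)
    geW1 = xin.T @ dh1
    geb1 = dh1.sum(axis=0)

    grads = {
        "eW1": geW1, "eb1": geb1, "eW2": geW2, "eb2": geb2,
        "dW1": gdW1, "db1": gdb1, "dW2": gdW2, "db2": gdb2,
    }
    return grads, loss


def train_cvae(x, site_labels, split: SplitAssignment, config: CVAEConfig) -> CVAEModel:
    """Train a CVAE on the train split with early stopping on validation loss.

    ``x`` is the curated matrix (array or anything with ``as_array``);
    ``site_labels`` the per-participant condition labels (ignored when the
    config is unconditioned). The PCA front-end, when configured, is fit on
    the training rows only. Best-validation parameters are restored at the
    end; validation loss is evaluated at the posterior mean (deterministic).
    """
    x = x.as_array() if hasattr(x, "as_array") else np.asarray(x, dtype=float)
    rng = np.random.default_rng(config.seed)

    if config.condition_on_site:
        if site_labels is None:
            raise ValueError("condition_on_site=True requires site labels")
        site_labels = np.asarray(site_labels)
        site_categories = np.unique(site_labels)
    else:
        site_categories = None

    x_train = x[split.train]
    frontend = (
        _Frontend.fit(x_train, config.frontend_dim, config.seed)
        if config.frontend_dim is not None
        else _Frontend.identity()
    )
    input_dim = config.frontend_dim if config.frontend_dim is not None else x.shape[1]
    n_cond = 0 if site_categories is None else len(site_categories)

    model = CVAEModel(
        config=config,
        params=_init_params(config, input_dim, n_cond, rng),
        frontend=frontend,
        site_categories=site_categories,
        ambient_dim=x.shape[1],
        history={"train_loss": [], "val_loss": []},
    )

    xf_train = frontend.project(x_train)
    xf_val = frontend.project(x[split.val])
    c_train = model.onehot(site_labels[split.train]) if n_cond else np.zeros((len(split.train), 0))
    c_val = model.onehot(site_labels[split.val]) if n_cond else np.zeros((len(split.val), 0))

    opt = _Adam(model.params, config.learning_rate)
    best_val = np.inf
    best_params = {k: v.copy() for k, v in model.params.items()}
    stall = 0
    n_train = xf_train.shape[0]

    for epoch in range(config.max_epochs):
        order = rng.permutation(n_train)
        epoch_loss = 0.0
        for start in range(0, n_train, config.batch_size):
            sel = order[start : start + config.batch_size]
            with np.errstate(over="ignore", invalid="ignore"):
                grads, loss = _batch_grads(model, xf_train[sel], c_train[sel], rng)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"loss diverged at epoch {epoch}; lower the learning rate "
                    f"(currently {config.learning_rate})"
                )
            opt.step(model.params, grads)
            epoch_loss += loss * len(sel)
        val_loss, _, _ = elbo_loss(xf_val, c_val, model)
        model.history["train_loss"].append(epoch_loss / n_train)
        model.history["val_loss"].append(val_loss)
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_params = {k: v.copy() for k, v in model.params.items()}
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break

    model.params = best_params
    return model
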