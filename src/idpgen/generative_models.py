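"""Autoencoder and variational-autoencoder generators of protein conformations.

The model operates on MinMax-normalized flattened heavy-atom coordinate
vectors (see :mod:`idpgen.preprocess`).  The encoder is a stack of dense
ReLU layers that bottlenecks the 3N-dimensional input x into a
low-dimensional latent space; for the VAE the bottleneck parameterizes a
diagonal Gaussian posterior (mu, log sigma^2) from which a latent vector
is drawn via the reparameterization z' = mu + sigma * eps, eps ~ N(0, I).
The decoder mirrors the encoder and maps z' back to a reconstructed
vector x'.  Training minimizes

    L_VAE = L_R + L_KL

where L_R = E[||x' - x||^2] is the squared reconstruction error (summed
over the 3N features, averaged over the batch) and L_KL is the
closed-form KL divergence between the posterior N(mu, sigma^2) and the
unit-Gaussian prior,

    L_KL = -1/2 * sum_j (1 + log sigma_j^2 - mu_j^2 - sigma_j^2),

averaged over the batch.  The plain AE minimizes L_R only, with a linear
bottleneck; new conformations are then sampled by fitting a multivariate
Gaussian to the encoded training data (:meth:`TrainedModel.fit_latent_gaussian`).

Networks are small dense stacks (default VAE encoder 1024-256-64-16 with
a 2-D latent space) and are implemented directly on numpy with a
hand-written backward pass and Adam, which keeps training fully
deterministic under a seed and fast on a single CPU at the problem sizes
this package targets.

The API follows the model/results idiom: :class:`ConformationalAutoencoder`
is built from data, its :meth:`~ConformationalAutoencoder.fit` returns a
:class:`TrainedModel` carrying the fitted weights, the per-epoch loss
history and all sampling/diagnostic methods.
"""

from __future__ import annotations

import io
import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, NumericalError
from .preprocess import FlatDataset, ScalingParams, inverse_minmax, unflatten
from .trajectory_io import Ensemble, Topology

__all__ = [
    "ModelConfig",
    "LatentBatch",
    "ConformationalAutoencoder",
    "TrainedModel",
    "reconstruction_loss",
    "kl_loss",
]

_DEFAULT_VAE_LAYERS = (1024, 256, 64, 16)
_DEFAULT_AE_LAYERS = (1024, 512, 256)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyperparameters.

    The decoder always mirrors the encoder (reversed layer list).  The
    default VAE uses a four-layer 1024-256-64-16 encoder with a 2-D latent
    space; the plain-AE convention ties the latent width to protein size,
    ceil(2/3 * n_residues).
    """

    model_kind: str = "vae"
    encoder_layers: tuple[int, ...] = _DEFAULT_VAE_LAYERS
    latent_dim: int = 2
    epochs: int = 10
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        kind = self.model_kind.lower()
        if kind not in ("ae", "vae"):
            raise DataError(f"model_kind must be 'ae' or 'vae', got {self.model_kind!r}")
        object.__setattr__(self, "model_kind", kind)
        layers = tuple(int(u) for u in self.encoder_layers)
        if not layers or any(u < 1 for u in layers):
            raise DataError("encoder_layers must be a non-empty list of positive unit counts")
        object.__setattr__(self, "encoder_layers", layers)
        if self.latent_dim < 1:
            raise DataError("latent_dim must be a positive integer")
        if self.epochs < 1 or self.batch_size < 1:
            raise DataError("epochs and batch_size must be positive")
        if self.learning_rate <= 0:
            raise DataError("learning_rate must be positive")

    @property
    def decoder_layers(self) -> tuple[int, ...]:
        return tuple(reversed(self.encoder_layers))

    @classmethod
    def vae_default(cls, **overrides) -> "ModelConfig":
        return cls(model_kind="vae", encoder_layers=_DEFAULT_VAE_LAYERS, latent_dim=2, **overrides)

    @classmethod
    def ae_default(cls, n_residues: int, **overrides) -> "ModelConfig":
        """Plain-AE defaults with latent dimension ceil(2/3 * n_residues)."""
        if n_residues < 1:
            raise DataError("n_residues must be positive")
        latent = math.ceil(2 * n_residues / 3)
        return cls(
            model_kind="ae", encoder_layers=_DEFAULT_AE_LAYERS, latent_dim=latent, **overrides
        )

    def to_dict(self) -> dict:
        return {
            "model_kind": self.model_kind,
            "encoder_layers": list(self.encoder_layers),
            "latent_dim": self.latent_dim,
            "epochs": self.epochs,
            "batch_size": self.batch_size,
            "learning_rate": self.learning_rate,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(
            model_kind=d["model_kind"],
            encoder_layers=tuple(d["encoder_layers"]),
            latent_dim=int(d["latent_dim"]),
            epochs=int(d["epochs"]),
            batch_size=int(d["batch_size"]),
            learning_rate=float(d["learning_rate"]),
            seed=int(d["seed"]),
        )


@dataclass(frozen=True)
class LatentBatch:
    """A batch of latent vectors with its provenance."""

    vectors: np.ndarray
    provenance: str  # "encoded" | "prior-sampled"

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=np.float64)
        if v.ndim != 2:
            raise DataError("latent vectors must form a 2-D [n_samples, latent_dim] array")
        object.__setattr__(self, "vectors", v)


def reconstruction_loss(x: np.ndarray, x_prime: np.ndarray) -> float:
    """Reconstruction error E[||x' - x||^2]: per-sample squared Euclidean
    norm over features, averaged over the batch.

    For 1-D inputs each entry is treated as a scalar sample, so the value
    reduces to the plain mean of squared differences.  Summing (not
    averaging) over features keeps the reconstruction term on the same
    per-sample scale as the KL term, as in the Gaussian-decoder evidence
    lower bound; a feature-averaged variant would down-weight
    reconstruction by 3N and drive the posterior to collapse onto the
    prior.
    """
    x = np.asarray(x, dtype=np.float64)
    x_prime = np.asarray(x_prime, dtype=np.float64)
    if x.shape != x_prime.shape:
        raise DataError(f"shape mismatch: {x.shape} vs {x_prime.shape}")
    sq = (x_prime - x) ** 2
    if sq.ndim == 1:
        return float(np.mean(sq))
    return float(np.mean(np.sum(sq, axis=tuple(range(1, sq.ndim)))))


def kl_loss(mu: np.ndarray, log_var: np.ndarray) -> float:
    """Closed-form KL divergence from N(mu, sigma^2) to the unit Gaussian.

    Per sample -1/2 * sum_j (1 + log sigma_j^2 - mu_j^2 - sigma_j^2),
    averaged over the batch.  Non-negative; zero iff mu = 0 and sigma = 1.
    """
    mu = np.atleast_2d(np.asarray(mu, dtype=np.float64))
    log_var = np.atleast_2d(np.asarray(log_var, dtype=np.float64))
    if mu.shape != log_var.shape:
        raise DataError(f"shape mismatch: {mu.shape} vs {log_var.shape}")
    if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(log_var))):
        raise NumericalError("non-finite latent statistics passed to kl_loss")
    per_sample = -0.5 * np.sum(1.0 + log_var - mu**2 - np.exp(log_var), axis=1)
    return float(np.mean(per_sample))


# ---------------------------------------------------------------------------
# dense-network internals


def _relu(a: np.ndarray) -> np.ndarray:
    return np.maximum(a, 0.0)


def _he_init(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))


class _DenseStack:
    """A stack of dense layers, ReLU on all but (optionally) the last."""

    def __init__(self, rng, sizes: list[int], final_linear: bool):
        self.W = [_he_init(rng, a, b) for a, b in zip(sizes[:-1], sizes[1:])]
        self.b = [np.zeros(b) for b in sizes[1:]]
        self.final_linear = final_linear

    def forward(self, x: np.ndarray, cache: list | None = None) -> np.ndarray:
        h = x
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            pre = h @ W + b
            last = i == len(self.W) - 1
            out = pre if (last and self.final_linear) else _relu(pre)
            if cache is not None:
                cache.append((h, pre))
            h = out
        return h

    def backward(self, d_out: np.ndarray, cache: list, grads_W: list, grads_b: list) -> np.ndarray:
        d = d_out
        for i in range(len(self.W) - 1, -1, -1):
            h_in, pre = cache[i]
            last = i == len(self.W) - 1
            if not (last and self.final_linear):
                d = d * (pre > 0)
            grads_W[i] += h_in.T @ d
            grads_b[i] += d.sum(axis=0)
            d = d @ self.W[i].T
        return d

    @property
    def params(self) -> list[np.ndarray]:
        return self.W + self.b


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


_LOGVAR_CLIP = 15.0  # keep exp(log_var) finite during early training


class _Network:
    """Encoder + (variational or linear) bottleneck + mirrored decoder."""

    def __init__(self, config: ModelConfig, input_dim: int, rng: np.random.Generator):
        if input_dim < 1:
            raise DataError("input_dim must be >= 1")
        self.config = config
        self.input_dim = input_dim
        enc_sizes = [input_dim, *config.encoder_layers]
        self.encoder = _DenseStack(rng, enc_sizes, final_linear=False)
        top = config.encoder_layers[-1]
        if config.model_kind == "vae":
            self.W_mu = _he_init(rng, top, config.latent_dim)
            self.b_mu = np.zeros(config.latent_dim)
            self.W_lv = _he_init(rng, top, config.latent_dim)
            self.b_lv = np.zeros(config.latent_dim)
        else:
            self.W_mu = _he_init(rng, top, config.latent_dim)
            self.b_mu = np.zeros(config.latent_dim)
            self.W_lv = None
            self.b_lv = None
        dec_sizes = [config.latent_dim, *config.decoder_layers, input_dim]
        # final decoder layer is linear: outputs live in (and may exceed) [0, 1]
        self.decoder = _DenseStack(rng, dec_sizes, final_linear=True)

    # -- forward passes ----------------------------------------------------
    def encode(self, x: np.ndarray, cache: list | None = None):
        h = self.encoder.forward(x, cache)
        mu = h @ self.W_mu + self.b_mu
        if self.config.model_kind == "vae":
            lv = np.clip(h @ self.W_lv + self.b_lv, -_LOGVAR_CLIP, _LOGVAR_CLIP)
            return h, mu, lv
        return h, mu, None

    def decode(self, z: np.ndarray, cache: list | None = None) -> np.ndarray:
        return self.decoder.forward(z, cache)

    # -- one training step -------------------------------------------------
    def loss_and_grads(self, x: np.ndarray, rng: np.random.Generator):
        enc_cache: list = []
        dec_cache: list = []
        h, mu, lv = self.encode(x, enc_cache)
        if self.config.model_kind == "vae":
            eps = rng.standard_normal(mu.shape)
            sigma = np.exp(0.5 * lv)
            z = mu + sigma * eps
        else:
            z = mu
        x_prime = self.decode(z, dec_cache)

        n_batch = x.shape[0]
        lr_val = float(np.mean(np.sum((x_prime - x) ** 2, axis=1)))
        kl_val = (
            kl_loss(mu, lv) if self.config.model_kind == "vae" else 0.0
        )

        gW_dec = [np.zeros_like(W) for W in self.decoder.W]
        gb_dec = [np.zeros_like(b) for b in self.decoder.b]
        gW_enc = [np.zeros_like(W) for W in self.encoder.W]
        gb_enc = [np.zeros_like(b) for b in self.encoder.b]

        d_out = 2.0 * (x_prime - x) / n_batch
        d_z = self.decoder.backward(d_out, dec_cache, gW_dec, gb_dec)

        if self.config.model_kind == "vae":
            d_mu = d_z + mu / n_batch
            d_lv = d_z * eps * 0.5 * sigma - 0.5 * (1.0 - np.exp(lv)) / n_batch
            g_Wmu = h.T @ d_mu
            g_bmu = d_mu.sum(axis=0)
            g_Wlv = h.T @ d_lv
            g_blv = d_lv.sum(axis=0)
            d_h = d_mu @ self.W_mu.T + d_lv @ self.W_lv.T
            head_params = [self.W_mu, self.b_mu, self.W_lv, self.b_lv]
            head_grads = [g_Wmu, g_bmu, g_Wlv, g_blv]
        else:
            d_mu = d_z
            g_Wmu = h.T @ d_mu
            g_bmu = d_mu.sum(axis=0)
            d_h = d_mu @ self.W_mu.T
            head_params = [self.W_mu, self.b_mu]
            head_grads = [g_Wmu, g_bmu]

        self.encoder.backward(d_h, enc_cache, gW_enc, gb_enc)
        params = self.encoder.params + head_params + self.decoder.params
        grads = gW_enc + gb_enc + head_grads + gW_dec + gb_dec
        return lr_val, kl_val, params, grads

    # -- (de)serialization -------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, (W, b) in enumerate(zip(self.encoder.W, self.encoder.b)):
            out[f"enc_W{i}"], out[f"enc_b{i}"] = W, b
        out["W_mu"], out["b_mu"] = self.W_mu, self.b_mu
        if self.W_lv is not None:
            out["W_lv"], out["b_lv"] = self.W_lv, self.b_lv
        for i, (W, b) in enumerate(zip(self.decoder.W, self.decoder.b)):
            out[f"dec_W{i}"], out[f"dec_b{i}"] = W, b
        return out

    def load_state(self, arrays: dict[str, np.ndarray]) -> None:
        for i in range(len(self.encoder.W)):
            self.encoder.W[i] = arrays[f"enc_W{i}"]
            self.encoder.b[i] = arrays[f"enc_b{i}"]
        self.W_mu, self.b_mu = arrays["W_mu"], arrays["b_mu"]
        if self.config.model_kind == "vae":
            self.W_lv, self.b_lv = arrays["W_lv"], arrays["b_lv"]
        for i in range(len(self.decoder.W)):
            self.decoder.W[i] = arrays[f"dec_W{i}"]
            self.decoder.b[i] = arrays[f"dec_b{i}"]


# ---------------------------------------------------------------------------
# public model / results objects


class ConformationalAutoencoder:
    """Generative model of protein conformations, built from a FlatDataset.

    Parameters
    ----------
    train_data
        Normalized training dataset (scaling fitted on these frames).
    config
        Architecture/training hyperparameters; defaults to the standard
        VAE (encoder 1024-256-64-16, 2-D latent space).
    topology
        Heavy-atom topology of the system; required for
        :meth:`TrainedModel.generate` to emit :class:`Ensemble` objects.
    """

    def __init__(
        self,
        train_data: FlatDataset,
        config: ModelConfig | None = None,
        topology: Topology | None = None,
    ):
        if train_data.n_frames < 1:
            raise DataError("training data is empty")
        self.train_data = train_data
        self.config = config or ModelConfig.vae_default()
        self.topology = topology
        if topology is not None and 3 * topology.heavy_mask.sum() != train_data.n_features:
            raise DataError("topology heavy-atom count does not match dataset width")

    @classmethod
    def from_ensemble(
        cls,
        ensemble: Ensemble,
        train_fraction: float = 0.5,
        config: ModelConfig | None = None,
        align: bool = True,
    ) -> tuple["ConformationalAutoencoder", FlatDataset]:
        """Build a model from an ensemble; returns (model, test FlatDataset).

        Runs the standard preprocessing chain: backbone alignment to the
        first frame, heavy-atom flattening, chronological train/test split
        with MinMax scaling fitted on the training part.
        """
        from .preprocess import chronological_split, flatten
        from .trajectory_io import align_ensemble

        if align:
            ensemble = align_ensemble(ensemble)
        raw, amap = flatten(ensemble)
        train, test = chronological_split(raw, train_fraction, amap)
        model = cls(train, config=config, topology=ensemble.topology.heavy_subset())
        return model, test

    def fit(self, verbose: bool = False) -> "TrainedModel":
        """Train by minibatch Adam on L_R (+ L_KL for the VAE).

        Deterministic under ``config.seed`` on a given platform.  Raises
        :class:`NumericalError` if the loss turns non-finite.
        """
        cfg = self.config
        x_all = self.train_data.matrix
        rng = np.random.default_rng(cfg.seed)
        net = _Network(cfg, x_all.shape[1], rng)
        opt = _Adam(
            net.encoder.params
            + ([net.W_mu, net.b_mu] if cfg.model_kind == "ae" else [net.W_mu, net.b_mu, net.W_lv, net.b_lv])
            + net.decoder.params,
            cfg.learning_rate,
        )
        history = []
        n = x_all.shape[0]
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            lr_sum = kl_sum = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                lr_val, kl_val, params, grads = net.loss_and_grads(x_all[idx], rng)
                if not (np.isfinite(lr_val) and np.isfinite(kl_val)):
                    raise NumericalError(
                        f"non-finite loss at epoch {epoch + 1} "
                        f"(reconstruction={lr_val}, kl={kl_val}); "
                        "try a lower learning rate"
                    )
                opt.step(params, grads)
                lr_sum += lr_val * len(idx)
                kl_sum += kl_val * len(idx)
            lr_epoch = lr_sum / n
            kl_epoch = kl_sum / n
            history.append((epoch + 1, lr_epoch, kl_epoch, lr_epoch + kl_epoch))
            if verbose:
                print(
                    f"epoch {epoch + 1:3d}  L_R={lr_epoch:.6f}  "
                    f"L_KL={kl_epoch:.6f}  total={lr_epoch + kl_epoch:.6f}"
                )
        loss_history = pd.DataFrame(
            history, columns=["epoch", "reconstruction", "kl", "total"]
        )
        return TrainedModel(
            config=cfg,
            network=net,
            scaling=self.train_data.scaling,
            atom_index_map=self.train_data.atom_index_map,
            input_dim=x_all.shape[1],
            loss_history=loss_history,
            topology=self.topology,
        )


@dataclass
class TrainedModel:
    """Fitted generator: weights, scaling state and per-epoch loss history."""

    config: ModelConfig
    network: _Network
    scaling: ScalingParams
    atom_index_map: np.ndarray
    input_dim: int
    loss_history: pd.DataFrame
    topology: Topology | None = None

    # -- inference ---------------------------------------------------------
    def _check_width(self, matrix: np.ndarray) -> np.ndarray:
        matrix = np.atleast_2d(np.asarray(matrix, dtype=np.float64))
        if matrix.shape[1] != self.input_dim:
            raise DataError(
                f"input width {matrix.shape[1]} does not match model input_dim {self.input_dim}"
            )
        return matrix

    def encode(self, matrix: np.ndarray):
        """Deterministic encoder pass.

        Returns ``(LatentBatch, mu, log_var)`` for a VAE (the batch holds
        mu) and ``(LatentBatch, codes, None)`` for an AE.
        """
        matrix = self._check_width(matrix)
        _, mu, lv = self.network.encode(matrix)
        return LatentBatch(mu, "encoded"), mu, lv

    def decode(self, z: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, dtype=np.float64))
        if z.shape[1] != self.config.latent_dim:
            raise DataError(
                f"latent width {z.shape[1]} does not match latent_dim {self.config.latent_dim}"
            )
        return self.network.decode(z)

    def reconstruct(self, matrix: np.ndarray) -> np.ndarray:
        """Deterministic decode(encode(x)) without latent noise."""
        _, mu, _ = self.encode(matrix)
        return self.decode(mu)

    def fit_latent_gaussian(self, matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Maximum-likelihood multivariate Gaussian over encoded data.

        This is the sampling route for the plain AE, whose latent space
        has no built-in prior.  A singular covariance is regularized with
        a small diagonal jitter (with a warning).
        """
        matrix = self._check_width(matrix)
        if matrix.shape[0] < self.config.latent_dim + 1:
            raise DataError(
                f"need at least latent_dim+1 = {self.config.latent_dim + 1} rows "
                f"to fit a latent Gaussian, got {matrix.shape[0]}"
            )
        _, mu, _ = self.encode(matrix)
        mean = mu.mean(axis=0)
        cov = np.cov(mu, rowvar=False)
        cov = np.atleast_2d(cov)
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            jitter = 1e-6 * max(np.trace(cov) / cov.shape[0], 1e-12)
            warnings.warn(
                f"singular latent covariance; adding diagonal jitter {jitter:.3g}",
                stacklevel=2,
            )
            cov = cov + jitter * np.eye(cov.shape[0])
        return mean, cov

    def generate(
        self,
        source: FlatDataset | np.ndarray | None = None,
        mode: str = "paired",
        n: int | None = None,
        seed: int = 0,
        noise_scale: float = 1.0,
    ) -> Ensemble:
        """Generate new conformations and return them as an :class:`Ensemble`.

        mode="paired"
            One generated conformation per source frame: z' = mu + sigma*eps
            for the VAE (``noise_scale`` rescales eps; 0 gives the
            deterministic reconstruction), plain reconstruction for the AE.
        mode="prior"
            VAE only: decode n samples z' ~ N(0, I).
        mode="latent_gaussian"
            AE route: fit a Gaussian to the encoded source data, sample n
            latent vectors from it and decode.

        Decoded normalized vectors are back-transformed through the stored
        scaling and unflattened into heavy-atom coordinates.
        """
        if self.topology is None:
            raise DataError("model carries no topology; cannot emit an Ensemble")
        rng = np.random.default_rng(seed)
        if isinstance(source, FlatDataset):
            matrix = source.matrix
        elif source is not None:
            matrix = np.atleast_2d(np.asarray(source, dtype=np.float64))
        else:
            matrix = None

        if mode == "paired":
            if matrix is None:
                raise DataError("paired generation requires source data")
            _, mu, lv = self.encode(matrix)
            if self.config.model_kind == "vae":
                eps = rng.standard_normal(mu.shape)
                z = mu + noise_scale * np.exp(0.5 * lv) * eps
            else:
                z = mu
        elif mode == "prior":
            if self.config.model_kind != "vae":
                raise DataError(
                    "prior-mode sampling requires a VAE; for an AE fit a latent "
                    "Gaussian instead (mode='latent_gaussian' or fit_latent_gaussian)"
                )
            if n is None:
                raise DataError("prior mode requires n")
            z = rng.standard_normal((n, self.config.latent_dim))
        elif mode == "latent_gaussian":
            if matrix is None or n is None:
                raise DataError("latent_gaussian mode requires source data and n")
            mean, cov = self.fit_latent_gaussian(matrix)
            z = rng.multivariate_normal(mean, cov, size=n, method="cholesky")
        else:
            raise DataError(f"unknown generation mode {mode!r}")

        decoded = self.decode(z)
        coords = unflatten(inverse_minmax(decoded, self.scaling))
        return Ensemble(self.topology, coords)

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        """Self-contained checkpoint: weights + config + scaling + atom map."""
        meta = {
            "config": self.config.to_dict(),
            "input_dim": self.input_dim,
            "has_topology": self.topology is not None,
        }
        arrays = dict(self.network.state_arrays())
        arrays["feature_min"] = self.scaling.feature_min
        arrays["feature_max"] = self.scaling.feature_max
        arrays["atom_index_map"] = self.atom_index_map
        arrays["loss_history"] = self.loss_history.to_numpy()
        if self.topology is not None:
            arrays["topo_atom_names"] = self.topology.atom_names.astype("U8")
            arrays["topo_residue_ids"] = self.topology.residue_ids
            arrays["topo_residue_names"] = self.topology.residue_names.astype("U8")
            arrays["topo_elements"] = self.topology.elements.astype("U4")
            arrays["topo_masses"] = self.topology.masses
        arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta_json"].tobytes()).decode())
            config = ModelConfig.from_dict(meta["config"])
            net = _Network(config, int(meta["input_dim"]), np.random.default_rng(0))
            net.load_state({k: data[k] for k in data.files})
            topo = None
            if meta["has_topology"]:
                topo = Topology(
                    atom_names=data["topo_atom_names"],
                    residue_ids=data["topo_residue_ids"],
                    residue_names=data["topo_residue_names"],
                    elements=data["topo_elements"],
                    masses=data["topo_masses"],
                )
            return cls(
                config=config,
                network=net,
                scaling=ScalingParams(data["feature_min"], data["feature_max"]),
                atom_index_map=data["atom_index_map"],
                input_dim=int(meta["input_dim"]),
                loss_history=pd.DataFrame(
                    data["loss_history"], columns=["epoch", "reconstruction", "kl", "total"]
                ),
                topology=topo,
            )

    def summary(self) -> str:
        """Human-readable description of the fitted model."""
        cfg = self.config
        buf = io.StringIO()
        last = self.loss_history.iloc[-1]
        arch = " -> ".join(
            str(u)
            for u in (
                self.input_dim,
                *cfg.encoder_layers,
                cfg.latent_dim,
                *cfg.decoder_layers,
                self.input_dim,
            )
        )
        print(f"{cfg.model_kind.upper()} conformational generator", file=buf)
        print(f"  architecture : {arch}", file=buf)
        print(f"  latent dim   : {cfg.latent_dim}", file=buf)
        print(f"  input dim    : {self.input_dim} (3 x heavy atoms)", file=buf)
        print(f"  epochs       : {cfg.epochs}  batch {cfg.batch_size}  lr {cfg.learning_rate}", file=buf)
        print(
            f"  final losses : reconstruction {last['reconstruction']:.6f}  "
            f"kl {last['kl']:.6f}  total {last['total']:.6f}",
            file=buf,
        )
        return buf.getvalue()
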