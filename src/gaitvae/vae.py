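"""Convolutional variational autoencoder over 512 x 6 gait epochs.

The encoder is three strided (stride 2, kernel 3, tanh) convolution blocks
producing temporal lengths 256, 128 and 64 with 32, 64 and 128 filters;
linear heads emit the 12-dimensional posterior mean and log-variance. The
decoder mirrors the encoder with transposed convolutions and a tanh output,
range-compatible with the normalized input. The loss combines the
reconstruction error with the KL divergence of the Gaussian posterior from
the standard-normal prior; the KL term is summed over the latent dimensions
and averaged over the batch.

Reported metrics follow the convention mse = mean over all 512 x 6 elements
and total = mse + kl_weight * kl. The default *training* objective uses the
Gaussian-decoder evidence bound, i.e. the squared error summed over the
512 x 6 elements plus the KL term (``recon_reduction="sum"``): with a
per-element-mean reconstruction term the KL penalty outweighs the
reconstruction signal by orders of magnitude and the posterior collapses
onto the prior before anything is learned. ``recon_reduction="mean"``
remains available for experiments.

At inference the latent "score" of an epoch is the posterior mean (no
sampling), so downstream feature tables and psychometrics are deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _nn
from ._nn import Adam, Conv1d, ConvTranspose1d, Dense, Sequential, Tanh
from .core import EPOCH_SAMPLES


@dataclass
class VaeConfig:
    input_shape: Tuple[int, int] = (EPOCH_SAMPLES, 6)
    filters: Tuple[int, int, int] = (32, 64, 128)
    kernel_size: int = 3
    latent_dim: int = 12
    learning_rate: float = 0.001
    batch_size: int = 64
    max_epochs: int = 200
    early_stop_patience: int = 10
    early_stop_min_delta: float = 1e-5
    kl_weight: float = 1.0
    recon_reduction: str = "sum"  # "sum" (evidence-bound scaling) or "mean"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.input_shape[0] % 8 != 0:
            raise ValueError("input length must be divisible by 8 (three stride-2 blocks)")
        if self.recon_reduction not in ("sum", "mean"):
            raise ValueError("recon_reduction must be 'sum' or 'mean'")

    @property
    def encoder_layer_nodes(self) -> Tuple[int, int, int]:
        """Temporal lengths after each encoder block (256, 128, 64 for 512)."""
        l = self.input_shape[0]
        return (l // 2, l // 4, l // 8)


@dataclass
class LatentCode:
    mu: np.ndarray
    logvar: np.ndarray

    @property
    def score(self) -> np.ndarray:
        """The downstream feature value of an epoch: the posterior mean."""
        return self.mu


@dataclass
class LossBreakdown:
    mse: float  # mean over all 512 x 6 elements
    kl: float  # nats, summed over latent dims, averaged over batch
    total: float  # mse + kl_weight * kl

    def as_dict(self) -> Dict[str, float]:
        return asdict(self)


@dataclass
class SplitPlan:
    fold_id: int
    train_subjects: Tuple[str, ...]
    test_subjects: Tuple[str, ...]
    validation_subjects: Tuple[str, ...]

    def __post_init__(self) -> None:
        sets = [set(self.train_subjects), set(self.test_subjects),
                set(self.validation_subjects)]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValueError("participant-level leakage: subject in two sets")


class VaeModel:
    """Encoder + reparameterized latent + decoder, all numpy."""

    def __init__(self, config: VaeConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        f1, f2, f3 = config.filters
        k = config.kernel_size
        c_in = config.input_shape[1]
        self.flat_len = config.encoder_layer_nodes[-1]  # 64
        self.encoder = Sequential(
            Conv1d(rng, c_in, f1, k=k, stride=2), Tanh(),
            Conv1d(rng, f1, f2, k=k, stride=2), Tanh(),
            Conv1d(rng, f2, f3, k=k, stride=2), Tanh(),
        )
        d_flat = self.flat_len * f3
        self.head_mu = Dense(rng, d_flat, config.latent_dim)
        self.head_logvar = Dense(rng, d_flat, config.latent_dim)
        self.dec_dense = Sequential(Dense(rng, config.latent_dim, d_flat), Tanh())
        self.decoder = Sequential(
            ConvTranspose1d(rng, f3, f2, k=k), Tanh(),
            ConvTranspose1d(rng, f2, f1, k=k), Tanh(),
            ConvTranspose1d(rng, f1, c_in, k=k), Tanh(),
        )
        self._f3 = f3

    # --- forward pieces -------------------------------------------------
    def encode_raw(self, x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        h = self.encoder.forward(x.astype(_nn.DTYPE))
        hf = h.reshape(h.shape[0], -1)
        self._enc_hf = hf
        return self.head_mu.forward(hf), self.head_logvar.forward(hf)

    def decode_raw(self, z: np.ndarray) -> np.ndarray:
        h = self.dec_dense.forward(z.astype(_nn.DTYPE))
        h = h.reshape(h.shape[0], self.flat_len, self._f3)
        return self.decoder.forward(h)

    def forward(self, x: np.ndarray, eps: np.ndarray = None):
        """Full pass. ``eps`` standard-normal noise; zeros => z = mu."""
        mu, logvar = self.encode_raw(x)
        if eps is None:
            eps = np.zeros_like(mu)
        z = mu + np.exp(0.5 * logvar) * eps.astype(_nn.DTYPE)
        x_hat = self.decode_raw(z)
        return x_hat, mu, logvar, z, eps

    def parameters(self):
        return (self.encoder.parameters() + self.head_mu.parameters()
                + self.head_logvar.parameters() + self.dec_dense.parameters()
                + self.decoder.parameters())

    # --- persistence ----------------------------------------------------
    def get_weights(self) -> List[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        for p, w in zip(self.parameters(), weights):
            p.value[...] = w

    def save(self, path: str) -> None:
        np.savez(path, *[p.value for p in self.parameters()],
                 config=json.dumps(asdict(self.config)))

    @classmethod
    def load(cls, path: str) -> "VaeModel":
        data = np.load(path, allow_pickle=False)
        cfg = json.loads(str(data["config"]))
        cfg["input_shape"] = tuple(cfg["input_shape"])
        cfg["filters"] = tuple(cfg["filters"])
        model = cls(VaeConfig(**cfg))
        weights = [data[f"arr_{i}"] for i in range(len(model.parameters()))]
        model.set_weights(weights)
        return model


def build_model(config: VaeConfig) -> VaeModel:
    """Construct the VAE for a config (shape checks in ``VaeConfig``)."""
    return VaeModel(config)


def vae_loss(x: np.ndarray, x_hat: np.ndarray, mu: np.ndarray,
             logvar: np.ndarray, kl_weight: float = 1.0) -> LossBreakdown:
    """Reported loss breakdown: element-mean MSE, batch-mean dim-sum KL."""
    x = np.atleast_3d(x)
    x_hat = np.atleast_3d(x_hat)
    mu = np.atleast_2d(mu)
    logvar = np.atleast_2d(logvar)
    mse = float(np.mean((x - x_hat) ** 2))
    kl = float(np.mean(np.sum(0.5 * (np.exp(logvar) + mu ** 2 - 1.0 - logvar), axis=1)))
    return LossBreakdown(mse=mse, kl=kl, total=mse + kl_weight * kl)


@dataclass
class TrainReport:
    train_mse: List[float] = field(default_factory=list)
    train_kl: List[float] = field(default_factory=list)
    train_total: List[float] = field(default_factory=list)
    test_mse: List[float] = field(default_factory=list)
    test_kl: List[float] = field(default_factory=list)
    test_total: List[float] = field(default_factory=list)
    objective: List[float] = field(default_factory=list)  # monitored test objective
    best_epoch: int = -1
    n_epochs: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


def _batch_losses(model: VaeModel, x: np.ndarray, cfg: VaeConfig,
                  batch: int = 256) -> Tuple[LossBreakdown, float]:
    """Deterministic (eps = 0) evaluation over a dataset; returns the
    reported breakdown and the training-objective value."""
    n = x.shape[0]
    mses, kls = [], []
    for i in range(0, n, batch):
        xb = x[i:i + batch]
        x_hat, mu, logvar, _, _ = model.forward(xb)
        lb = vae_loss(xb, x_hat, mu, logvar, cfg.kl_weight)
        mses.append(lb.mse * xb.shape[0])
        kls.append(lb.kl * xb.shape[0])
    mse = sum(mses) / n
    kl = sum(kls) / n
    n_el = np.prod(model.config.input_shape)
    rec = mse * n_el if cfg.recon_reduction == "sum" else mse
    return LossBreakdown(mse=mse, kl=kl, total=mse + cfg.kl_weight * kl), rec + cfg.kl_weight * kl


def train(model: VaeModel, epochs_train: np.ndarray, epochs_test: np.ndarray,
          config: VaeConfig = None) -> Tuple[VaeModel, TrainReport]:
    """Adam-train the VAE with early stopping on the test-set objective.

    ``epochs_train`` / ``epochs_test`` are (n, 512, 6) arrays of normalized
    epochs from disjoint subjects. Early stopping uses the configured
    patience and minimum improvement; the best weights are restored.
    """
    cfg = config or model.config
    if epochs_train.shape[0] == 0:
        raise ValueError("empty training set")
    x_train = epochs_train.astype(_nn.DTYPE)
    x_test = epochs_test.astype(_nn.DTYPE)
    rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    n = x_train.shape[0]
    n_el = float(np.prod(cfg.input_shape))
    report = TrainReport()
    best = np.inf
    best_weights = model.get_weights()
    wait = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        for i in range(0, n, cfg.batch_size):
            xb = x_train[order[i:i + cfg.batch_size]]
            nb = xb.shape[0]
            eps = rng.standard_normal((nb, cfg.latent_dim)).astype(_nn.DTYPE)
            x_hat, mu, logvar, z, eps = model.forward(xb, eps)
            opt.zero_grad()
            # d(recon)/d(x_hat)
            if cfg.recon_reduction == "sum":
                dxh = 2.0 * (x_hat - xb) / nb
            else:
                dxh = 2.0 * (x_hat - xb) / (nb * n_el)
            dz = model.decoder.backward(dxh)
            dz = model.dec_dense.backward(dz.reshape(nb, -1))
            dmu = dz + cfg.kl_weight * mu / nb
            dlogvar = dz * eps * 0.5 * np.exp(0.5 * logvar) \
                + cfg.kl_weight * 0.5 * (np.exp(logvar) - 1.0) / nb
            dhf = _backward_heads(model, dmu, dlogvar)
            model.encoder.backward(dhf.reshape(nb, model.flat_len, -1))
            opt.step()
        tr_lb, _ = _batch_losses(model, x_train, cfg)
        te_lb, te_obj = _batch_losses(model, x_test, cfg)
        report.train_mse.append(tr_lb.mse)
        report.train_kl.append(tr_lb.kl)
        report.train_total.append(tr_lb.total)
        report.test_mse.append(te_lb.mse)
        report.test_kl.append(te_lb.kl)
        report.test_total.append(te_lb.total)
        report.objective.append(te_obj)
        if te_obj < best - cfg.early_stop_min_delta:
            best = te_obj
            best_weights = model.get_weights()
            report.best_epoch = epoch
            wait = 0
        else:
            wait += 1
            if wait >= cfg.early_stop_patience:
                break
    model.set_weights(best_weights)
    report.n_epochs = len(report.train_mse)
    return model, report


def _backward_heads(model: VaeModel, dmu: np.ndarray, dlogvar: np.ndarray) -> np.ndarray:
    return model.head_mu.backward(dmu) + model.head_logvar.backward(dlogvar)


def encode(model: VaeModel, epochs: np.ndarray) -> LatentCode:
    """Posterior mean/log-variance for one (512, 6) epoch or an (n, 512, 6) batch."""
    x = np.asarray(epochs, dtype=_nn.DTYPE)
    single = x.ndim == 2
    if single:
        x = x[None]
    mu, logvar = model.encode_raw(x)
    if single:
        mu, logvar = mu[0], logvar[0]
    return LatentCode(mu=np.asarray(mu, dtype=float), logvar=np.asarray(logvar, dtype=float))


def reconstruct(model: VaeModel, epochs: np.ndarray) -> np.ndarray:
    """Deterministic reconstruction (decode the posterior mean)."""
    x = np.asarray(epochs, dtype=_nn.DTYPE)
    single = x.ndim == 2
    if single:
        x = x[None]
    x_hat, _, _, _, _ = model.forward(x)
    return np.asarray(x_hat[0] if single else x_hat, dtype=float)


def perturb_and_decode(model: VaeModel, code: LatentCode, dim: int,
                       delta: float) -> np.ndarray:
    """Decode a latent code with ``mu[dim]`` shifted by ``delta``.

    The latent-exploration primitive: nudge one latent feature and inspect
    the change in the decoded IMU signal.
    """
    mu = np.atleast_2d(np.array(code.mu, dtype=float, copy=True))
    mu[:, dim] += delta
    out = model.decode_raw(mu)
    return np.asarray(out[0] if np.asarray(code.mu).ndim == 1 else out, dtype=float)


def make_split_plan(subject_ids: Sequence[str], seed: int,
                    n_folds: int = 10) -> List[SplitPlan]:
    """Participant-level 70/20/10 splits, each subject validated exactly once.

    Subjects are shuffled once and partitioned into ``n_folds`` validation
    folds; within each fold the remaining subjects are split 7:2 into train
    and test.
    """
    ids = list(dict.fromkeys(subject_ids))
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    folds = [list(f) for f in np.array_split(np.array(order, dtype=object), n_folds)]
    plans = []
    for fold_id, val in enumerate(folds):
        rest = [s for s in order if s not in set(val)]
        n_train = int(round(len(rest) * 7.0 / 9.0))
        plans.append(SplitPlan(fold_id=fold_id,
                               train_subjects=tuple(rest[:n_train]),
                               test_subjects=tuple(rest[n_train:]),
                               validation_subjects=tuple(val)))
    return plans


def reconstruction_error_by_group(model: VaeModel, epochs: np.ndarray,
                                  groups: Sequence[str],
                                  z_normalize: bool = False) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-epoch reconstruction MSE with a per-group summary.

    Returns ``(table, summary)``; ``table`` has columns ``group, mse`` (plus
    ``mse_z`` when ``z_normalize``), ``summary`` group mean/median/sd/n.
    """
    groups = np.asarray(groups)
    if epochs.shape[0] != groups.size:
        raise ValueError("groups must match the number of epochs")
    if epochs.shape[0] == 0 or any((groups == g).sum() == 0 for g in np.unique(groups)):
        raise ValueError("empty group")
    mses = []
    for i in range(0, epochs.shape[0], 256):
        xb = epochs[i:i + 256].astype(_nn.DTYPE)
        x_hat, _, _, _, _ = model.forward(xb)
        mses.append(np.mean((xb - x_hat) ** 2, axis=(1, 2)))
    table = pd.DataFrame({"group": groups, "mse": np.concatenate(mses).astype(float)})
    if z_normalize:
        table["mse_z"] = table.groupby("group")["mse"].transform(
            lambda s: (s - s.mean()) / s.std(ddof=0))
    summary = table.groupby("group")["mse"].agg(["mean", "median", "std", "count"])
    return table, summary


def reconstruction_mae_units(x: np.ndarray, x_hat: np.ndarray) -> Dict[str, float]:
    """Mean absolute reconstruction error, normalized and in physical units.

    Returns the per-epoch MAE on the normalized scale plus the
    unstandardized values (x 8 g for the accelerometer channels, x 500 deg/s
    for the gyroscope channels).
    """
    err = np.abs(np.asarray(x) - np.asarray(x_hat))
    acc = float(err[..., :3].mean())
    gyr = float(err[..., 3:].mean())
    return {"mae_normalized": float(err.mean()),
            "mae_acc_g": acc * 8.0, "mae_gyro_dps": gyr * 500.0}
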