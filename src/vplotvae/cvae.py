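"""Conditional variational autoencoder over per-region V-plots.

Each genomic region contributes one training example: the V-plots of the
``S`` samples at that region, stacked on the channel axis.  A trainable
embedding maps each sample index to a fragment-size offset vector ``g``
(broadcast along the genomic axis) that is added to the input, so the
encoder sees the sample-specific fragment-size profile explicitly; the
decoder receives the latent vector concatenated with a one-hot sample
indicator.  Replacing the true indicator with a fixed reference sample at
decode time yields batch-free estimated V-plots.

The posterior is a diagonal Gaussian per region and sample; training
maximises the ELBO (pixel-wise binary cross-entropy reconstruction plus
the closed-form KL to a standard normal prior) with Adam under a
warmup-then-cosine learning-rate schedule.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import h5py
import numpy as np

from . import _nn
from .vplots import VPlot

_CLAMP = 1e-7


@dataclass
class ModelConfig:
    """Hyperparameters of the V-plot CVAE.

    ``K`` is the latent dimension per sample, ``S`` the number of samples
    stacked on the channel axis.  ``shared_sigma`` switches the posterior
    standard deviation from per-sample (K x S) to a single K x 1 vector
    shared across samples.  ``s0`` is the reference sample index used for
    batch-free decoding.
    """

    S: int = 1
    K: int = 5
    W: int = 128
    H: int = 64
    n_blocks: int = 4
    filters: int = 16
    kernel: int = 3
    stride: int = 2
    learning_rate: float = 0.01
    warmup_steps: int = 100
    epochs: int = 100
    batch_size: int = 64
    kl_weight: float = 1.0
    shared_sigma: bool = False
    s0: int = 0
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self):
        if self.K < 1 or self.S < 1:
            raise ValueError("K and S must be >= 1")
        if self.W % (self.stride ** self.n_blocks) or self.H % (self.stride ** self.n_blocks):
            raise ValueError(
                f"W={self.W}, H={self.H} must be divisible by "
                f"stride^n_blocks = {self.stride ** self.n_blocks}")
        if not 0 <= self.s0 < self.S:
            raise ValueError(f"s0={self.s0} outside [0, {self.S})")

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)


@dataclass
class VPlotStack:
    """Density V-plots of all samples at a set of regions: ``(n, S, W, H)``."""

    x: np.ndarray
    region_ids: np.ndarray | None = None
    n_reads: np.ndarray | None = None  # (n, S) fragments per V-plot

    def __post_init__(self):
        if self.x.ndim != 4:
            raise ValueError("stack must be (n_regions, S, W, H)")
        if self.region_ids is None:
            self.region_ids = np.arange(self.x.shape[0])

    @property
    def n_regions(self) -> int:
        return self.x.shape[0]

    @property
    def S(self) -> int:
        return self.x.shape[1]

    @classmethod
    def from_vplots(cls, vplots_per_sample: list[list[VPlot]]) -> "VPlotStack":
        """Build a stack from per-sample lists of V-plots (same region order)."""
        n = len(vplots_per_sample[0])
        if any(len(v) != n for v in vplots_per_sample):
            raise ValueError("samples must cover the same regions")
        x = np.stack([np.stack([vp.density for vp in vps]) for vps in vplots_per_sample],
                     axis=1)
        n_reads = np.array([[vp.n_reads for vp in vps] for vps in vplots_per_sample]).T
        return cls(x=x, n_reads=n_reads)


@dataclass
class LatentPosterior:
    """Diagonal-Gaussian posterior per region and sample.

    ``mean`` and ``std`` have shape ``(n_regions, K, S)``; in shared-sigma
    mode ``std`` is broadcast from ``(n_regions, K, 1)``.
    """

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self):
        if np.any(self.std <= 0):
            raise ValueError("posterior std must be strictly positive")

    def sample_slice(self, s: int) -> tuple[np.ndarray, np.ndarray]:
        """Posterior (mean, std) of sample ``s``: two ``(n, K)`` arrays."""
        std = self.std if self.std.shape[2] > 1 else np.broadcast_to(
            self.std, self.mean.shape)
        return self.mean[:, :, s], std[:, :, s]


class CVAE:
    """Encoder/decoder pair plus the fragment-size sample embedding."""

    def __init__(self, config: ModelConfig, seed: int | None = None):
        self.config = config
        if seed is None:
            seed = config.seed
        rng = np.random.default_rng(seed)
        dt = config.np_dtype
        S, K, F = config.S, config.K, config.filters
        enc = []
        cin = S
        for _ in range(config.n_blocks):
            enc += [_nn.Conv2d(cin, F, rng, dtype=dt),
                    _nn.BatchNorm2d(F, dtype=dt), _nn.ReLU()]
            cin = F
        self.encoder = _nn.Sequential(enc)
        self._wb = config.W // config.stride ** config.n_blocks
        self._hb = config.H // config.stride ** config.n_blocks
        flat = F * self._wb * self._hb
        self.head_mu = _nn.Dense(flat, K * S, rng, dtype=dt)
        n_logvar = K if config.shared_sigma else K * S
        self.head_logvar = _nn.Dense(flat, n_logvar, rng, scale=1e-3, dtype=dt)
        # decoder: (z, one-hot s) -> dense 128 -> 4 channels at the bottleneck
        # spatial grid -> transposed conv blocks; the last block emits the
        # single output plane fed to the per-genomic-bin softmax.
        self._dec_c0 = 128 // (self._wb * self._hb)
        self.dec_dense = _nn.Dense(K + S, 128, rng, dtype=dt)
        dec = [_nn.ReLU()]
        cin = self._dec_c0
        for _ in range(config.n_blocks - 1):
            dec += [_nn.ConvTranspose2d(cin, F, rng, dtype=dt),
                    _nn.BatchNorm2d(F, dtype=dt), _nn.ReLU()]
            cin = F
        dec += [_nn.ConvTranspose2d(cin, 1, rng, dtype=dt)]
        self.decoder = _nn.Sequential(dec)
        self.embedding = np.zeros((S, config.H), dtype=dt)  # g, per sample
        self._g_grad = np.zeros_like(self.embedding)
        self.trained = False

    # --- parameter bookkeeping -------------------------------------------
    @property
    def params(self) -> list[np.ndarray]:
        return (self.encoder.params + self.head_mu.params + self.head_logvar.params
                + self.dec_dense.params + self.decoder.params + [self.embedding])

    @property
    def grads(self) -> list[np.ndarray]:
        return (self.encoder.grads + self.head_mu.grads + self.head_logvar.grads
                + self.dec_dense.grads + self.decoder.grads + [self._g_grad])

    def checksum(self) -> float:
        return float(sum(np.abs(p).sum() for p in self.params))

    # --- forward pieces ---------------------------------------------------
    def _encode_arrays(self, x: np.ndarray, train: bool):
        cfg = self.config
        xin = x.astype(cfg.np_dtype) + self.embedding[None, :, None, :]
        h = self.encoder.forward(xin, train=train)
        hf = h.reshape(h.shape[0], -1)
        mu = self.head_mu.forward(hf, train=train)
        logvar = self.head_logvar.forward(hf, train=train)
        return xin, hf, mu, logvar

    def _posterior(self, mu: np.ndarray, logvar: np.ndarray) -> LatentPosterior:
        cfg = self.config
        n = mu.shape[0]
        mean = mu.reshape(n, cfg.K, cfg.S)
        if cfg.shared_sigma:
            std = np.exp(0.5 * logvar).reshape(n, cfg.K, 1)
        else:
            std = np.exp(0.5 * logvar).reshape(n, cfg.K, cfg.S)
        return LatentPosterior(mean=mean.astype(np.float64),
                               std=std.astype(np.float64))

    def _decode_logits(self, dec_in: np.ndarray, train: bool) -> np.ndarray:
        cfg = self.config
        h = self.dec_dense.forward(dec_in, train=train)
        h = h.reshape(h.shape[0], self._dec_c0, self._wb, self._hb)
        logits = self.decoder.forward(h, train=train)
        return logits[:, 0]  # (n, W, H)

    def _decoder_backward(self, dlogits: np.ndarray) -> np.ndarray:
        dh = self.decoder.backward(dlogits[:, None])
        dh = dh.reshape(dh.shape[0], -1)
        return self.dec_dense.backward(dh)

    def loss_and_grads(self, xb: np.ndarray, eps: np.ndarray,
                       onehot_all: np.ndarray) -> float:
        """One training step's loss; fills ``self.grads`` by backprop.

        ``xb`` is a ``(b, S, W, H)`` density batch, ``eps`` the
        reparameterization noise ``(b, K, S)``.
        """
        cfg = self.config
        b = xb.shape[0]
        xin, hf, mu, logvar = self._encode_arrays(xb, train=True)
        if cfg.shared_sigma:
            lv = np.repeat(logvar, cfg.S, axis=1).reshape(b, cfg.K, cfg.S)
        else:
            lv = logvar.reshape(b, cfg.K, cfg.S)
        muks = mu.reshape(b, cfg.K, cfg.S)
        std = np.exp(0.5 * lv)
        z = muks + std * eps.astype(cfg.np_dtype)
        zf = z.transpose(0, 2, 1).reshape(b * cfg.S, cfg.K)
        oh = np.tile(onehot_all, (b, 1))
        logits = self._decode_logits(np.concatenate([zf, oh], axis=1), train=True)
        y = _softmax_h(logits)
        target = xb.astype(np.float64).reshape(b * cfg.S, cfg.W, cfg.H)
        yc = np.clip(y, _CLAMP, 1.0 - _CLAMP)
        bce = float(-(target * np.log(yc) + (1 - target) * np.log1p(-yc)).sum())
        kl = float((0.5 * (muks.astype(np.float64) ** 2
                           + std.astype(np.float64) ** 2
                           - 1.0 - lv.astype(np.float64))).sum())
        loss = (bce + cfg.kl_weight * kl) / b
        # backward
        unclamped = (y > _CLAMP) & (y < 1.0 - _CLAMP)
        dy = np.where(unclamped, -target / yc + (1 - target) / (1 - yc), 0.0)
        dlogits = y * (dy - (y * dy).sum(axis=-1, keepdims=True))
        dlogits = (dlogits / b).astype(cfg.np_dtype)
        ddec_in = self._decoder_backward(dlogits)
        dz = ddec_in[:, :cfg.K].reshape(b, cfg.S, cfg.K).transpose(0, 2, 1)
        dmu = dz + cfg.kl_weight * muks / b
        dstd_kl = cfg.kl_weight * (std - 1.0 / std) / b
        dlv = (dz * eps + dstd_kl) * std * 0.5
        if cfg.shared_sigma:
            dlv_head = dlv.sum(axis=2)
        else:
            dlv_head = dlv.reshape(b, cfg.K * cfg.S)
        dhf = self.head_mu.backward(
            dmu.reshape(b, cfg.K * cfg.S).astype(cfg.np_dtype))
        dhf = dhf + self.head_logvar.backward(dlv_head.astype(cfg.np_dtype))
        dh = dhf.reshape(b, self.config.filters, self._wb, self._hb)
        dxin = self.encoder.backward(dh)
        self._g_grad[...] = dxin.sum(axis=(0, 2))
        return loss


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def init_model(config: ModelConfig, seed: int | None = None) -> CVAE:
    """Build a model with freshly initialized parameters (seed-deterministic)."""
    return CVAE(config, seed=seed)


def encode(stack: VPlotStack, model: CVAE) -> LatentPosterior:
    """Posterior q(z | x, s) for every region in the stack (inference mode)."""
    cfg = model.config
    if stack.x.shape[1:] != (cfg.S, cfg.W, cfg.H):
        raise ValueError(
            f"stack shape {stack.x.shape[1:]} does not match model "
            f"({cfg.S}, {cfg.W}, {cfg.H})")
    _, _, mu, logvar = model._encode_arrays(stack.x, train=False)
    return model._posterior(mu, logvar)


def _softmax_h(logits: np.ndarray) -> np.ndarray:
    m = logits.max(axis=-1, keepdims=True)
    e = np.exp(logits - m)
    return e / e.sum(axis=-1, keepdims=True)


def decode(z: np.ndarray, sample_id: int, model: CVAE) -> np.ndarray:
    """Estimated V-plot(s) for latent vector(s) ``z`` under sample ``sample_id``.

    Accepts ``(K,)`` or ``(n, K)``; returns ``(W, H)`` or ``(n, W, H)`` with
    every genomic-bin column summing to one.
    """
    cfg = model.config
    z = np.asarray(z, dtype=cfg.np_dtype)
    single = z.ndim == 1
    if single:
        z = z[None]
    if not np.all(np.isfinite(z)):
        raise ValueError("latent z contains non-finite values")
    if not 0 <= sample_id < cfg.S:
        raise ValueError(f"sample_id {sample_id} outside [0, {cfg.S})")
    onehot = np.zeros((z.shape[0], cfg.S), dtype=cfg.np_dtype)
    onehot[:, sample_id] = 1.0
    logits = model._decode_logits(np.concatenate([z, onehot], axis=1), train=False)
    xhat = _softmax_h(logits.astype(np.float64))
    return xhat[0] if single else xhat


def _bce(x: np.ndarray, xhat: np.ndarray) -> float:
    xc = np.clip(xhat, _CLAMP, 1.0 - _CLAMP)
    return float(-(x * np.log(xc) + (1.0 - x) * np.log1p(-xc)).sum())


def _kl(mean: np.ndarray, std: np.ndarray) -> float:
    var = std ** 2
    return float(0.5 * (mean ** 2 + var - 1.0 - np.log(var)).sum())


def elbo_loss(stack: VPlotStack, xhat: np.ndarray, posterior: LatentPosterior,
              kl_weight: float = 1.0) -> float:
    """Negative ELBO per region: summed BCE + KL, averaged over regions.

    ``xhat`` has shape ``(n, S, W, H)`` matching the stack.
    """
    n = stack.n_regions
    bce = _bce(stack.x, xhat)
    kl = _kl(posterior.mean, np.broadcast_to(posterior.std, posterior.mean.shape))
    return (bce + kl_weight * kl) / n


def train(stack: VPlotStack, config: ModelConfig) -> tuple[CVAE, list[float]]:
    """Fit the CVAE on a region stack; returns the model and per-epoch loss.

    One Monte-Carlo sample of z per region per step (reparameterization
    trick); the recorded history is the mean per-region loss of each epoch.
    """
    if stack.n_regions < 1:
        raise ValueError("empty training stack")
    if stack.S != config.S:
        raise ValueError(f"stack has S={stack.S}, config S={config.S}")
    bs = min(config.batch_size, stack.n_regions)
    model = CVAE(config)
    rng = np.random.default_rng(config.seed)
    cfg = config
    n = stack.n_regions
    steps_per_epoch = (n + bs - 1) // bs
    opt = _nn.Adam(model.params, model.grads, lr=cfg.learning_rate,
                   total_steps=cfg.epochs * steps_per_epoch,
                   warmup_steps=cfg.warmup_steps)
    onehot_all = np.eye(cfg.S, dtype=cfg.np_dtype)
    history: list[float] = []
    for epoch in range(cfg.epochs):
        perm = rng.permutation(n)
        total = 0.0
        for bi in range(steps_per_epoch):
            idx = perm[bi * bs:(bi + 1) * bs]
            xb = stack.x[idx]
            b = len(idx)
            eps = rng.standard_normal((b, cfg.K, cfg.S))
            loss = model.loss_and_grads(xb, eps, onehot_all)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {bi}")
            total += loss * b
            opt.step()
        history.append(total / n)
    model.trained = True
    return model, history


def batch_free_vplot(stack: VPlotStack, model: CVAE) -> np.ndarray:
    """Batch-free estimated V-plots: encode with the true sample indicator,
    decode every sample's posterior mean under the reference sample ``s0``.

    Returns ``(n_regions, S, W, H)``; every genomic-bin column sums to one.
    """
    cfg = model.config
    post = encode(stack, model)
    out = np.empty((stack.n_regions, cfg.S, cfg.W, cfg.H))
    for s in range(cfg.S):
        mean, _ = post.sample_slice(s)
        out[:, s] = decode(mean, cfg.s0, model)
    return out


def reconstruct(stack: VPlotStack, model: CVAE) -> np.ndarray:
    """Ordinary reconstruction: decode each sample's posterior mean with its
    own sample indicator. Returns ``(n, S, W, H)``."""
    cfg = model.config
    post = encode(stack, model)
    out = np.empty((stack.n_regions, cfg.S, cfg.W, cfg.H))
    for s in range(cfg.S):
        mean, _ = post.sample_slice(s)
        out[:, s] = decode(mean, s, model)
    return out


def extract_features(stack: VPlotStack, model: CVAE) -> np.ndarray:
    """Latent feature matrix: row i = flattened posterior means (K*S)."""
    import warnings
    if not model.trained:
        warnings.warn("extracting features from an untrained model")
    post = encode(stack, model)
    n = stack.n_regions
    return post.mean.transpose(0, 2, 1).reshape(n, -1)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_model(model: CVAE, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["config"] = json.dumps(dataclasses.asdict(model.config))
        f.attrs["trained"] = model.trained
        for i, p in enumerate(model.params):
            f.create_dataset(f"param_{i}", data=p)
        bns = [lyr for lyr in model.encoder.layers + model.decoder.layers
               if isinstance(lyr, _nn.BatchNorm2d)]
        for i, bn in enumerate(bns):
            f.create_dataset(f"bn_{i}_mean", data=bn.running_mean)
            f.create_dataset(f"bn_{i}_var", data=bn.running_var)


def load_model(path) -> CVAE:
    with h5py.File(path, "r") as f:
        config = ModelConfig(**json.loads(f.attrs["config"]))
        model = CVAE(config)
        for i, p in enumerate(model.params):
            p[...] = f[f"param_{i}"][...]
        bns = [lyr for lyr in model.encoder.layers + model.decoder.layers
               if isinstance(lyr, _nn.BatchNorm2d)]
        for i, bn in enumerate(bns):
            bn.running_mean[...] = f[f"bn_{i}_mean"][...]
            bn.running_var[...] = f[f"bn_{i}_var"][...]
        model.trained = bool(f.attrs["trained"])
    return model
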