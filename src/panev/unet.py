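"""Compact U-Net for needle isolation, in pure NumPy.

The architecture follows the classic encoder/decoder with skip connections:
each encoder scale is two 3x3 convolutions (batch norm + ReLU) followed by
2x2 max pooling; each decoder scale is a 2x2 transposed convolution
(upsampling factor 2), concatenation with the same-scale encoder features,
and two further convolutions.  A 1x1 convolution with a sigmoid produces a
single-channel output in [0, 1], trained against [0, 1] ground-truth maps
with an MSE loss, the Adam optimiser and cosine-annealed learning rate.

Layers carry their own forward/backward passes; convolutions are evaluated
as nine shifted tensor contractions so the heavy lifting stays in BLAS.
Everything is float32 and seeded, so runs are reproducible on fixed hardware.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ConfigError, ReconImage


@dataclass(frozen=True)
class ModelConfig:
    scales: int = 4          # number of pooling steps
    base_filters: int = 16   # doubled at each deeper scale
    batchnorm: bool = True
    head_bias: float = -3.0  # output-layer bias init: sigmoid(-3) ~ the
                             # foreground fraction of sparse needle targets

    def __post_init__(self) -> None:
        if self.scales < 1 or self.base_filters < 1:
            raise ConfigError("scales and base_filters must be positive")


@dataclass(frozen=True)
class TrainConfig:
    iterations: int = 5000
    batch: int = 4
    learning_rate: float = 0.001
    seed: int = 0
    val_every: int = 50

    def __post_init__(self) -> None:
        if self.iterations < 1 or self.batch < 1:
            raise ConfigError("iterations and batch must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")


def cosine_lr(t: int, total: int, lr0: float) -> float:
    """Cosine annealing from lr0 to 0 over ``total`` iterations."""
    return 0.5 * lr0 * (1.0 + np.cos(np.pi * t / total))


# --------------------------------------------------------------------------
# layers
# --------------------------------------------------------------------------

class Conv3x3:
    """Same-padded 3x3 convolution, evaluated as 9 shifted contractions."""

    def __init__(self, c_in, c_out, rng):
        scale = np.sqrt(2.0 / (c_in * 9))  # He initialisation
        self.w = (rng.standard_normal((c_out, c_in, 3, 3)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        n, c, h, wd = x.shape
        self._x = x
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        out = np.zeros((n, self.w.shape[0], h, wd), dtype=np.float32)
        for dy in range(3):
            for dx in range(3):
                patch = xp[:, :, dy:dy + h, dx:dx + wd]
                out += np.einsum("fc,nchw->nfhw", self.w[:, :, dy, dx], patch,
                                 optimize=True)
        return out + self.b[None, :, None, None]

    def backward(self, dout):
        x = self._x
        n, c, h, wd = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        dxp = np.zeros_like(xp)
        dw = np.zeros_like(self.w)
        for dy in range(3):
            for dx in range(3):
                patch = xp[:, :, dy:dy + h, dx:dx + wd]
                dw[:, :, dy, dx] = np.einsum("nfhw,nchw->fc", dout, patch,
                                             optimize=True)
                dxp[:, :, dy:dy + h, dx:dx + wd] += np.einsum(
                    "fc,nfhw->nchw", self.w[:, :, dy, dx], dout, optimize=True)
        self.dw = dw
        self.db = dout.sum(axis=(0, 2, 3))
        return dxp[:, :, 1:-1, 1:-1]

    def grads(self):
        return [self.dw, self.db]


class Conv1x1:
    def __init__(self, c_in, c_out, rng):
        scale = np.sqrt(2.0 / c_in)
        self.w = (rng.standard_normal((c_out, c_in)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        self._x = x
        return (np.einsum("fc,nchw->nfhw", self.w, x, optimize=True)
                + self.b[None, :, None, None])

    def backward(self, dout):
        self.dw = np.einsum("nfhw,nchw->fc", dout, self._x, optimize=True)
        self.db = dout.sum(axis=(0, 2, 3))
        return np.einsum("fc,nfhw->nchw", self.w, dout, optimize=True)

    def grads(self):
        return [self.dw, self.db]


class ConvTranspose2x2:
    """2x2 transposed convolution with stride 2 (upsampling factor 2)."""

    def __init__(self, c_in, c_out, rng):
        scale = np.sqrt(2.0 / c_in)
        self.w = (rng.standard_normal((c_in, c_out, 2, 2)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        self._x = x
        n, c, h, wd = x.shape
        out = np.zeros((n, self.w.shape[1], 2 * h, 2 * wd), dtype=np.float32)
        for dy in range(2):
            for dx in range(2):
                out[:, :, dy::2, dx::2] = np.einsum(
                    "cf,nchw->nfhw", self.w[:, :, dy, dx], x, optimize=True)
        return out + self.b[None, :, None, None]

    def backward(self, dout):
        x = self._x
        dw = np.zeros_like(self.w)
        dx_ = np.zeros_like(x)
        for dy in range(2):
            for dx in range(2):
                sub = dout[:, :, dy::2, dx::2]
                dw[:, :, dy, dx] = np.einsum("nfhw,nchw->cf", sub, x,
                                             optimize=True)
                dx_ += np.einsum("cf,nfhw->nchw", self.w[:, :, dy, dx], sub,
                                 optimize=True)
        self.dw = dw
        self.db = dout.sum(axis=(0, 2, 3))
        return dx_

    def grads(self):
        return [self.dw, self.db]


class BatchNorm:
    def __init__(self, channels, momentum=0.9, eps=1e-5):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.run_mean = np.zeros(channels, dtype=np.float32)
        self.run_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) / self._std[None, :, None, None]
        return (self.gamma[None, :, None, None] * self._xhat
                + self.beta[None, :, None, None])

    def backward(self, dout):
        xhat, std = self._xhat, self._std
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.dgamma = (dout * xhat).sum(axis=(0, 2, 3))
        self.dbeta = dout.sum(axis=(0, 2, 3))
        g = self.gamma[None, :, None, None]
        dxhat = dout * g
        mean_dxhat = dxhat.mean(axis=(0, 2, 3))[None, :, None, None]
        mean_dxhat_x = (dxhat * xhat).mean(axis=(0, 2, 3))[None, :, None, None]
        return (dxhat - mean_dxhat - xhat * mean_dxhat_x) / std[None, :, None, None]

    def grads(self):
        return [self.dgamma, self.dbeta]


class ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2x2:
    def forward(self, x):
        n, c, h, w = x.shape
        view = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = view.max(axis=(3, 5))
        self._mask = view == out[:, :, :, None, :, None]
        # break ties deterministically: keep only the first max per window
        flat = self._mask.reshape(n, c, h // 2, w // 2, 4)
        first = np.cumsum(flat, axis=-1) == 1
        self._mask = (flat & first).reshape(n, c, h // 2, 2, w // 2, 2)
        self._shape = x.shape
        return out

    def backward(self, dout):
        n, c, h, w = self._shape
        dx = self._mask * dout[:, :, :, None, :, None]
        return dx.reshape(n, c, h, w)


class _ConvBlock:
    """conv -> (BN) -> ReLU, twice."""

    def __init__(self, c_in, c_out, rng, batchnorm):
        self.layers = []
        for cin in (c_in, c_out):
            self.layers.append(Conv3x3(cin, c_out, rng))
            if batchnorm:
                self.layers.append(BatchNorm(c_out))
            self.layers.append(ReLU())

    def forward(self, x, train):
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                x = layer.forward(x, train=train)
            else:
                x = layer.forward(x)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def trainables(self):
        return [l for l in self.layers if hasattr(l, "params")]


class UNet:
    """Encoder-decoder with skip connections; see module docstring."""

    def __init__(self, mcfg: ModelConfig | None = None, seed: int = 0):
        self.cfg = mcfg or ModelConfig()
        rng = np.random.default_rng(seed)
        f = self.cfg.base_filters
        self.enc = []
        c_in = 1
        filters = [f * 2 ** s for s in range(self.cfg.scales)]
        for c_out in filters:
            self.enc.append((_ConvBlock(c_in, c_out, rng, self.cfg.batchnorm),
                             MaxPool2x2()))
            c_in = c_out
        bottom = f * 2 ** self.cfg.scales
        self.bottleneck = _ConvBlock(c_in, bottom, rng, self.cfg.batchnorm)
        self.dec = []
        c_in = bottom
        for c_out in reversed(filters):
            up = ConvTranspose2x2(c_in, c_out, rng)
            block = _ConvBlock(2 * c_out, c_out, rng, self.cfg.batchnorm)
            self.dec.append((up, block))
            c_in = c_out
        self.head = Conv1x1(c_in, 1, rng)
        self.head.b[:] = self.cfg.head_bias
        self.trained = False

    # -- plumbing ----------------------------------------------------------
    def _modules(self):
        mods = []
        for block, _ in self.enc:
            mods.extend(block.trainables())
        mods.extend(self.bottleneck.trainables())
        for up, block in self.dec:
            mods.append(up)
            mods.extend(block.trainables())
        mods.append(self.head)
        return mods

    def parameters(self):
        out = []
        for m in self._modules():
            out.extend(m.params())
        return out

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def gradients(self):
        out = []
        for m in self._modules():
            out.extend(m.grads())
        return out

    def state_dict(self):
        params = [p.copy() for p in self.parameters()]
        bn = [(m.run_mean.copy(), m.run_var.copy())
              for m in self._modules() if isinstance(m, BatchNorm)]
        return (params, bn)

    def load_state(self, state):
        params, bn = state
        for p, s in zip(self.parameters(), params):
            p[...] = s
        bn_mods = [m for m in self._modules() if isinstance(m, BatchNorm)]
        for m, (mean, var) in zip(bn_mods, bn):
            m.run_mean = mean.copy()
            m.run_var = var.copy()

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (N, H, W) or (N, 1, H, W) in [0, 1]; returns (N, H, W) in (0, 1)."""
        if x.ndim == 3:
            x = x[:, None]
        x = x.astype(np.float32)
        size = x.shape[-1]
        if x.shape[-2] != size:
            raise ConfigError("input must be square")
        if size % (2 ** self.cfg.scales):
            raise ConfigError(
                f"input size {size} not divisible by 2^{self.cfg.scales}")
        skips = []
        for block, pool in self.enc:
            x = block.forward(x, train)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x, train)
        self._skip_channels = []
        for (up, block), skip in zip(self.dec, reversed(skips)):
            x = up.forward(x)
            self._skip_channels.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = block.forward(x, train)
        logits = self.head.forward(x)
        from scipy.special import expit  # overflow-safe sigmoid

        self._out = expit(logits)
        return self._out[:, 0]

    def backward(self, dout: np.ndarray) -> None:
        """dout: gradient of the loss w.r.t. the sigmoid output, (N, H, W)."""
        d = dout[:, None] * self._out * (1.0 - self._out)  # sigmoid'
        d = self.head.backward(d.astype(np.float32))
        skip_grads = []
        for (up, block), c_skip in zip(reversed(self.dec),
                                       reversed(self._skip_channels)):
            d = block.backward(d)
            skip_grads.append(d[:, :c_skip])
            d = up.backward(d[:, c_skip:])
        d = self.bottleneck.backward(d)
        for (block, pool), dskip in zip(reversed(self.enc), reversed(skip_grads)):
            d = pool.backward(d)
            d = d + dskip
            d = block.backward(d)


def build_model(mcfg: ModelConfig | None = None, seed: int = 0) -> UNet:
    return UNet(mcfg, seed=seed)


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

class Adam:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass
class TrainHistory:
    loss: list = field(default_factory=list)
    lr: list = field(default_factory=list)
    val_iter: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    best_iter: int = -1
    best_val: float = np.inf

    def save_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as f:
            w = csv.writer(f)
            w.writerow(["iteration", "loss", "lr"])
            for i, (l, r) in enumerate(zip(self.loss, self.lr)):
                w.writerow([i, l, r])


def _mse(pred, target):
    diff = pred - target
    return float(np.mean(diff * diff)), 2.0 * diff / diff.size


def train(model: UNet, x_train, y_train, x_val, y_val,
          tcfg: TrainConfig | None = None) -> TrainHistory:
    """Train with MSE / Adam / cosine annealing; keep the best-validation weights.

    Arrays are (N, H, W) float in [0, 1].  Raises on empty splits or a
    non-finite loss.  Deterministic for a fixed ``tcfg.seed``.
    """
    tcfg = tcfg or TrainConfig()
    if len(x_train) == 0 or len(x_val) == 0:
        raise ConfigError("train and validation splits must be non-empty")
    rng = np.random.default_rng(tcfg.seed)
    opt = Adam(model.parameters(), lr=tcfg.learning_rate)
    hist = TrainHistory()
    best_state = model.state_dict()

    for it in range(tcfg.iterations):
        idx = rng.integers(0, len(x_train), tcfg.batch)
        xb = x_train[idx]
        yb = y_train[idx]
        pred = model.forward(xb, train=True)
        loss, dloss = _mse(pred, yb)
        if not np.isfinite(loss):
            raise ConfigError(f"non-finite training loss at iteration {it}")
        model.backward(dloss)
        opt.lr = cosine_lr(it, tcfg.iterations, tcfg.learning_rate)
        opt.step(model.gradients())
        hist.loss.append(loss)
        hist.lr.append(opt.lr)

        if it % tcfg.val_every == 0 or it == tcfg.iterations - 1:
            val = _validate(model, x_val, y_val, tcfg.batch)
            hist.val_iter.append(it)
            hist.val_loss.append(val)
            if val < hist.best_val:
                hist.best_val = val
                hist.best_iter = it
                best_state = model.state_dict()

    model.load_state(best_state)
    model.trained = True
    return hist


def _validate(model: UNet, x_val, y_val, batch: int) -> float:
    total = 0.0
    n = 0
    for i in range(0, len(x_val), batch):
        xb = x_val[i:i + batch]
        pred = model.forward(xb, train=False)
        diff = pred - y_val[i:i + batch]
        total += float(np.sum(diff * diff))
        n += diff.size
    return total / n


def enhance(model: UNet, img: ReconImage) -> ReconImage:
    """Run a single image through the network; output tagged ``enhanced``.

    The image is rescaled to the network's native input range ([0, 1] by its
    max), resized to a supported square size internally if needed, and the
    output is returned at the input's resolution.
    """
    if not model.trained:
        raise ConfigError("model has not been trained")
    from .recon import _resize_square

    px = img.pixels
    size = px.shape[0]
    factor = 2 ** model.cfg.scales
    work = img
    net_size = size
    if px.shape[0] != px.shape[1] or size % factor:
        raise ConfigError("enhance expects a square input divisible by 2^scales")
    x = work.pixels
    peak = x.max()
    x = (x / peak if peak > 0 else x)[None].astype(np.float32)
    out = model.forward(x, train=False)[0]
    out = np.clip(out, 0.0, 1.0)
    result = ReconImage(pixels=out.astype(np.float64),
                        pixel_size_um=img.pixel_size_um, kind="enhanced")
    if net_size != size:
        result = _resize_square(result, size)
        result.pixels = np.clip(result.pixels, 0.0, 1.0)
    return result


def save_checkpoint(path, model: UNet, tcfg: TrainConfig, seed: int) -> None:
    import json

    import h5py

    with h5py.File(path, "w") as f:
        for i, p in enumerate(model.parameters()):
            f.create_dataset(f"param_{i:04d}", data=p)
        bn_state = []
        for m in model._modules():
            if isinstance(m, BatchNorm):
                bn_state.append(np.stack([m.run_mean, m.run_var]))
        for i, s in enumerate(bn_state):
            f.create_dataset(f"bn_{i:04d}", data=s)
        f.attrs["model_cfg"] = json.dumps(
            {"scales": model.cfg.scales, "base_filters": model.cfg.base_filters,
             "batchnorm": model.cfg.batchnorm})
        f.attrs["train_cfg"] = json.dumps(
            {"iterations": tcfg.iterations, "batch": tcfg.batch,
             "learning_rate": tcfg.learning_rate, "seed": tcfg.seed,
             "val_every": tcfg.val_every})
        f.attrs["seed"] = seed


def load_checkpoint(path) -> UNet:
    import json

    import h5py

    with h5py.File(path, "r") as f:
        mcfg = ModelConfig(**json.loads(f.attrs["model_cfg"]))
        model = UNet(mcfg, seed=int(f.attrs["seed"]))
        params = model.parameters()
        for i, p in enumerate(params):
            p[...] = f[f"param_{i:04d}"][()]
        bn = [m for m in model._modules() if isinstance(m, BatchNorm)]
        for i, m in enumerate(bn):
            s = f[f"bn_{i:04d}"][()]
            m.run_mean, m.run_var = s[0].copy(), s[1].copy()
    model.trained = True
    return model
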