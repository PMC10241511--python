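"""The beta-VAE over reformatted cortical grid frames.

Architecture: five strided convolutions (kernel 4, stride 2, leaky-ReLU)
compress a two-channel H x W grid frame to a 256-dimensional Gaussian
posterior N(mu_z, sigma_z); a dense layer and five transposed convolutions
mirror the encoder back to a grid frame.  Counting the two dense bottleneck
heads, the network has twelve layers.  Training minimizes

    L = ||x - x'||^2 + beta * D_KL( N(mu_z, sigma_z) || N(0, I) )

with the reparameterization trick (z = mu + sigma * eps during training) and
an Adam optimizer.  The KL weight beta trades reconstruction fidelity for a
disentangled, well-behaved latent space; the study default is beta = 9.

The network is implemented directly in NumPy (im2col convolutions, explicit
backpropagation).  Gradients are verified against finite differences in the
test suite.  Inference is deterministic: ``encode`` returns posterior means
(no sampling) and ``decode`` is a fixed function of the latent vector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .grid import GridSequence

__all__ = [
    "VAEConfig",
    "LatentTimeseries",
    "VAEModel",
    "build_vae",
    "vae_loss",
    "kl_divergence",
    "train_vae",
    "encode",
    "decode",
    "save_vae",
    "load_vae",
]


@dataclass
class VAEConfig:
    """Hyperparameters.  Defaults are the study settings; smaller channel
    widths and latent sizes are legitimate for desk-scale experiments."""

    n_latent: int = 256
    beta: float = 9.0
    learning_rate: float = 1e-4
    batch_size: int = 128
    epochs: int = 20
    seed: int = 0
    encoder_channels: tuple = (32, 64, 128, 256, 256)
    kernel_size: int = 4
    leak: float = 0.2

    def __post_init__(self):
        if self.n_latent < 1:
            raise ValueError("n_latent must be >= 1")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        self.encoder_channels = tuple(self.encoder_channels)

    @property
    def n_conv_layers(self) -> int:
        return len(self.encoder_channels)

    @property
    def total_layers(self) -> int:
        # conv + deconv stacks plus the two dense bottleneck layers
        return 2 * self.n_conv_layers + 2


@dataclass
class LatentTimeseries:
    """Posterior means and standard deviations of the latent code over time."""

    mu: np.ndarray  # (n_latent, T)
    sigma: np.ndarray  # (n_latent, T)
    subject_id: str = "sub-0"
    session_id: str = "ses-0"
    age_weeks: float = float("nan")
    dataset_tag: str = "synthetic"

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=np.float64)
        self.sigma = np.asarray(self.sigma, dtype=np.float64)
        if self.mu.shape != self.sigma.shape:
            raise ValueError("mu and sigma must have equal shapes")
        if not np.all(np.isfinite(self.mu)) or not np.all(self.sigma > 0):
            raise ValueError("latent posteriors must be finite with sigma > 0")

    @property
    def n_latent(self) -> int:
        return self.mu.shape[0]

    @property
    def n_frames(self) -> int:
        return self.mu.shape[1]


# ---------------------------------------------------------------------------
# conv primitives (im2col)
# ---------------------------------------------------------------------------


def _im2col(xp: np.ndarray, k: int, stride: int, ho: int, wo: int) -> np.ndarray:
    """(N, C, Hp, Wp) padded input -> (N*ho*wo, C*k*k) patch matrix."""
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N, C, ho, wo, k, k)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        xp.shape[0] * ho * wo, -1
    )


def _col2im(dcols: np.ndarray, shape, k: int, stride: int, pad: int,
            ho: int, wo: int) -> np.ndarray:
    """Scatter-add (N, ho, wo, C, k, k) patch values back to (N, C, H, W).

    Inverse of :func:`_im2col` in the adjoint sense; also serves as the
    forward pass of the transposed convolution.
    """
    n, c, h, w = shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d = dcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for di in range(k):
        for dj in range(k):
            dxp[:, :, di:di + stride * ho:stride, dj:dj + stride * wo:stride] += \
                d[:, :, :, :, di, dj]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


class _Conv:
    """Strided convolution, kernel k, stride 2, padding 1 (halves H and W)."""

    def __init__(self, c_in, c_out, k, rng, dtype):
        fan_in = c_in * k * k
        self.W = (rng.standard_normal((fan_in, c_out)) * np.sqrt(2.0 / fan_in)
                  ).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.k, self.stride, self.pad = k, 2, 1
        self.c_in, self.c_out = c_in, c_out

    def out_hw(self, h, w):
        return ((h + 2 * self.pad - self.k) // self.stride + 1,
                (w + 2 * self.pad - self.k) // self.stride + 1)

    def forward(self, x):
        n, c, h, w = x.shape
        ho, wo = self.out_hw(h, w)
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad,) * 2, (self.pad,) * 2))
        cols = _im2col(xp, self.k, self.stride, ho, wo)
        out = cols @ self.W + self.b
        self._cache = (cols, x.shape, ho, wo)
        return out.reshape(n, ho, wo, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dout):
        cols, xshape, ho, wo = self._cache
        n = xshape[0]
        dr = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(
            n * ho * wo, self.c_out)
        self.dW = cols.T @ dr
        self.db = dr.sum(axis=0)
        dcols = dr @ self.W.T
        return _col2im(dcols, xshape, self.k, self.stride, self.pad, ho, wo)

    def params(self):
        return ["W", "b"]


class _Deconv:
    """Transposed convolution, kernel k, stride 2, padding 1 (doubles H, W)."""

    def __init__(self, c_in, c_out, k, rng, dtype):
        fan_in = c_in * (k // 2) ** 2  # contributions per output cell
        self.W = (rng.standard_normal((c_in, c_out * k * k)) *
                  np.sqrt(2.0 / max(fan_in, 1))).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.k, self.stride, self.pad = k, 2, 1
        self.c_in, self.c_out = c_in, c_out

    def forward(self, z):
        n, c, h, w = z.shape
        ho, wo = 2 * h, 2 * w
        zc = np.ascontiguousarray(z.transpose(0, 2, 3, 1)).reshape(n * h * w, c)
        cols = zc @ self.W  # (n*h*w, c_out*k*k)
        out = _col2im(cols.reshape(n, h, w, self.c_out, self.k, self.k),
                      (n, self.c_out, ho, wo), self.k, self.stride, self.pad,
                      h, w)
        self._cache = (zc, z.shape, h, w)
        return out + self.b[None, :, None, None]

    def backward(self, dout):
        zc, zshape, h, w = self._cache
        n = zshape[0]
        self.db = dout.sum(axis=(0, 2, 3))
        dp = np.pad(dout, ((0, 0), (0, 0), (self.pad,) * 2, (self.pad,) * 2))
        dcols = _im2col(dp, self.k, self.stride, h, w)  # (n*h*w, c_out*k*k)
        self.dW = zc.T @ dcols
        dz = dcols @ self.W.T
        return np.ascontiguousarray(
            dz.reshape(n, h, w, self.c_in).transpose(0, 3, 1, 2))

    def params(self):
        return ["W", "b"]


class _Dense:
    def __init__(self, d_in, d_out, rng, dtype):
        self.W = (rng.standard_normal((d_in, d_out)) * np.sqrt(1.0 / d_in)
                  ).astype(dtype)
        self.b = np.zeros(d_out, dtype=dtype)

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    def params(self):
        return ["W", "b"]


class _LeakyReLU:
    def __init__(self, leak):
        self.leak = leak

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.leak * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.leak * dout)

    def params(self):
        return []


class VAEModel:
    """Encoder/decoder stacks plus posterior heads; see the module docstring.

    ``dtype`` defaults to float32 for speed; float64 is used by the
    finite-difference gradient tests.
    """

    def __init__(self, config: VAEConfig, grid_shape: tuple, dtype=np.float32):
        h, w = grid_shape
        down = 2 ** config.n_conv_layers
        if h % down or w % down:
            need_h = (h + down - 1) // down * down
            need_w = (w + down - 1) // down * down
            raise ValueError(
                f"grid shape {grid_shape} not divisible by {down}; pad to "
                f"({need_h}, {need_w})"
            )
        self.config = config
        self.grid_shape = (h, w)
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(config.seed)
        k = config.kernel_size
        chans = (2,) + config.encoder_channels

        self.enc = []
        for c_in, c_out in zip(chans[:-1], chans[1:]):
            self.enc.append(_Conv(c_in, c_out, k, rng, self.dtype))
            self.enc.append(_LeakyReLU(config.leak))
        self._hb = h // down
        self._wb = w // down
        bottleneck = chans[-1] * self._hb * self._wb
        self.fc_mu = _Dense(bottleneck, config.n_latent, rng, self.dtype)
        self.fc_logvar = _Dense(bottleneck, config.n_latent, rng, self.dtype)

        self.dec_fc = _Dense(config.n_latent, bottleneck, rng, self.dtype)
        self.dec = []
        rev = chans[::-1]
        for c_in, c_out in zip(rev[:-1], rev[1:]):
            self.dec.append(_LeakyReLU(config.leak))
            self.dec.append(_Deconv(c_in, c_out, k, rng, self.dtype))
        self._bottleneck_channels = chans[-1]

    # -- forward -----------------------------------------------------------

    def encode_arr(self, x: np.ndarray):
        """x: (N, 2, H, W) -> (mu, logvar), each (N, n_latent)."""
        out = x.astype(self.dtype, copy=False)
        for layer in self.enc:
            out = layer.forward(out)
        self._enc_flat_shape = out.shape
        flat = out.reshape(out.shape[0], -1)
        return self.fc_mu.forward(flat), self.fc_logvar.forward(flat)

    def decode_arr(self, z: np.ndarray) -> np.ndarray:
        """z: (N, n_latent) -> (N, 2, H, W)."""
        out = self.dec_fc.forward(z.astype(self.dtype, copy=False))
        out = out.reshape(z.shape[0], self._bottleneck_channels, self._hb, self._wb)
        for layer in self.dec:
            out = layer.forward(out)
        return out

    # -- backward ----------------------------------------------------------

    def backward_decoder(self, dxrec: np.ndarray) -> np.ndarray:
        """Gradient w.r.t. the decoder input z; accumulates parameter grads."""
        d = dxrec.astype(self.dtype, copy=False)
        for layer in reversed(self.dec):
            d = layer.backward(d)
        return self.dec_fc.backward(d.reshape(d.shape[0], -1))

    def backward_encoder(self, dmu: np.ndarray, dlogvar: np.ndarray) -> np.ndarray:
        """Backpropagate posterior-head gradients; returns dL/dx."""
        dflat = (self.fc_mu.backward(dmu.astype(self.dtype, copy=False)) +
                 self.fc_logvar.backward(dlogvar.astype(self.dtype, copy=False)))
        d = dflat.reshape(self._enc_flat_shape)
        for layer in reversed(self.enc):
            d = layer.backward(d)
        return d

    # -- parameter plumbing --------------------------------------------------

    def parameters(self):
        layers = [*self.enc, self.fc_mu, self.fc_logvar, self.dec_fc, *self.dec]
        out = []
        for i, layer in enumerate(layers):
            for name in layer.params():
                out.append((f"layer{i}_{name}", layer, name))
        return out

    def state_dict(self) -> dict:
        return {key: getattr(owner, name).copy()
                for key, owner, name in self.parameters()}

    def load_state_dict(self, state: dict) -> None:
        for key, owner, name in self.parameters():
            setattr(owner, name, state[key].astype(self.dtype))


def build_vae(config: VAEConfig, grid_shape: tuple, dtype=np.float32) -> VAEModel:
    """Construct a seeded model for the given grid shape."""
    return VAEModel(config, tuple(grid_shape), dtype=dtype)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------


def kl_divergence(mu: np.ndarray, sigma: np.ndarray) -> float:
    """KL( N(mu, diag sigma^2) || N(0, I) ), summed over latent dimensions.

    Zero iff mu = 0 and sigma = 1; nonnegative always.
    """
    mu = np.asarray(mu, dtype=np.float64)
    sigma = np.asarray(sigma, dtype=np.float64)
    return float(0.5 * np.sum(mu**2 + sigma**2 - np.log(sigma**2) - 1.0))


def vae_loss(x, x_rec, mu, sigma, beta: float = 9.0, mask=None) -> float:
    """Single-frame loss ||x - x'||^2 + beta * KL, optionally masked.

    ``mask`` restricts the reconstruction term to valid grid cells so that
    unassigned cells contribute nothing.
    """
    x = np.asarray(x, dtype=np.float64)
    x_rec = np.asarray(x_rec, dtype=np.float64)
    sigma = np.asarray(sigma, dtype=np.float64)
    if x.shape != x_rec.shape:
        raise ValueError("x and x_rec shapes differ")
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    for arr in (x, x_rec, np.asarray(mu, dtype=np.float64), sigma):
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite inputs to vae_loss")
    diff = x - x_rec
    if mask is not None:
        diff = diff * np.asarray(mask, dtype=np.float64)
    return float(np.sum(diff**2) + beta * kl_divergence(mu, sigma))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


class _Adam:
    def __init__(self, model: VAEModel, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(getattr(o, n)) for k, o, n in model.parameters()}
        self.v = {k: np.zeros_like(getattr(o, n)) for k, o, n in model.parameters()}

    def step(self, model: VAEModel):
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for key, owner, name in model.parameters():
            g = getattr(owner, "d" + name)
            m = self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            v = self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            w = getattr(owner, name)
            update = self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            setattr(owner, name, w - update.astype(w.dtype))


def _frames_to_nchw(frames, dtype) -> tuple:
    """Accept a GridSequence or (N, H, W, 2) array; return (N,2,H,W) + mask."""
    if isinstance(frames, GridSequence):
        mask = frames.validity.astype(dtype).transpose(2, 0, 1)[None]
        arr = frames.frames
    else:
        arr = np.asarray(frames)
        mask = None
    if arr.ndim != 4 or arr.shape[-1] != 2:
        raise ValueError(f"expected (N, H, W, 2) frames, got {arr.shape}")
    return np.ascontiguousarray(arr.transpose(0, 3, 1, 2)).astype(dtype), mask


def train_batch(model: VAEModel, x: np.ndarray, beta: float,
                eps: np.ndarray, mask=None) -> float:
    """One forward/backward pass on (N, 2, H, W) frames with fixed noise.

    Computes the mean per-frame loss, leaves the gradients of that mean on
    the layers, and returns it.  Exposed separately so the gradient tests
    can drive it with deterministic epsilon.
    """
    nb = x.shape[0]
    mu, logvar = model.encode_arr(x)
    sigma = np.exp(0.5 * logvar)
    z = mu + sigma * eps
    xrec = model.decode_arr(z)

    diff = xrec - x
    if mask is not None:
        diff = diff * mask
    recon = float(np.sum(diff.astype(np.float64) ** 2))
    kl = kl_divergence(mu, sigma)
    loss = (recon + beta * kl) / nb

    # gradients of the mean-per-frame loss
    dxrec = (2.0 / nb) * diff
    dz = model.backward_decoder(dxrec)
    dmu = (beta / nb) * mu + dz
    dlogvar = (0.5 * beta / nb) * (sigma**2 - 1.0) + dz * (0.5 * sigma * eps)
    model.backward_encoder(dmu, dlogvar)
    return loss


def train_vae(model: VAEModel, frames, config: VAEConfig | None = None):
    """Train with Adam and the reparameterization trick.

    Returns ``(model, loss_curve)`` where ``loss_curve[e]`` is the mean
    per-frame loss over epoch ``e``.  ``epochs=0`` leaves parameters
    unchanged.  Sampling, shuffling, and initialization all derive from
    ``config.seed``.
    """
    config = config or model.config
    x_all, mask = _frames_to_nchw(frames, model.dtype)
    n = x_all.shape[0]
    if n == 0:
        raise ValueError("empty training dataset")
    if x_all.shape[2:] != model.grid_shape:
        raise ValueError(
            f"frames {x_all.shape[2:]} do not match model grid {model.grid_shape}"
        )
    rng = np.random.default_rng(config.seed + 1)
    opt = _Adam(model, config.learning_rate)
    curve = []
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            x = x_all[idx]
            eps = rng.standard_normal(
                (len(idx), config.n_latent)).astype(model.dtype)
            total += len(idx) * train_batch(model, x, config.beta, eps, mask=mask)
            opt.step(model)
        curve.append(total / n)
    return model, curve


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def encode(model: VAEModel, grids, chunk: int = 256, **metadata) -> LatentTimeseries:
    """Posterior means and sds for every frame; deterministic (no sampling)."""
    x, _ = _frames_to_nchw(grids, model.dtype)
    if x.shape[2:] != model.grid_shape:
        raise ValueError(
            f"frames {x.shape[2:]} do not match model grid {model.grid_shape}"
        )
    mus, sigmas = [], []
    for start in range(0, x.shape[0], chunk):
        mu, logvar = model.encode_arr(x[start:start + chunk])
        logvar = np.clip(logvar, -20.0, 20.0)
        mus.append(mu)
        sigmas.append(np.exp(0.5 * logvar))
    return LatentTimeseries(
        mu=np.concatenate(mus).T, sigma=np.concatenate(sigmas).T, **metadata
    )


def decode(model: VAEModel, z: np.ndarray, chunk: int = 256) -> np.ndarray:
    """Map latent vectors to grid frames.

    ``z`` may be a single latent vector or an (n_latent, n) matrix of column
    vectors (the LatentTimeseries layout); returns (n, H, W, 2).
    """
    z = np.asarray(z, dtype=np.float64)
    if z.ndim == 1:
        zn = z[None]
    elif z.ndim == 2:
        if z.shape[0] != model.config.n_latent:
            raise ValueError(
                f"latent dimension {z.shape[0]} != {model.config.n_latent}"
            )
        zn = z.T
    else:
        raise ValueError("z must be 1-D or 2-D")
    outs = []
    for start in range(0, zn.shape[0], chunk):
        out = model.decode_arr(zn[start:start + chunk])
        outs.append(out.transpose(0, 2, 3, 1))
    return np.concatenate(outs).astype(np.float64)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------


def save_vae(model: VAEModel, path) -> None:
    """Weights as .npz next to a JSON config sidecar (bit-exact round trip)."""
    path = str(path)
    stem = path[:-4] if path.endswith(".npz") else path
    np.savez(stem + ".npz", **model.state_dict())
    with open(stem + ".json", "w") as f:
        json.dump({"config": asdict(model.config),
                   "grid_shape": list(model.grid_shape),
                   "dtype": model.dtype.name}, f)


def load_vae(path) -> VAEModel:
    path = str(path)
    stem = path[:-4] if path.endswith(".npz") else path
    with open(stem + ".json") as f:
        meta = json.load(f)
    cfg = VAEConfig(**{**meta["config"],
                       "encoder_channels": tuple(meta["config"]["encoder_channels"])})
    model = VAEModel(cfg, tuple(meta["grid_shape"]), dtype=meta.get("dtype", "float32"))
    with np.load(stem + ".npz") as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
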