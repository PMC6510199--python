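"""The upscaling network: three convolutions separated by two ReLUs.

An 11-row input patch is mapped to ``n_out`` channels of 10 intermediate
rows.  The first layer extracts a bank of local features, the second mixes
them non-linearly, and the third linearly combines feature maps into the
predicted intermediate rows (no final ReLU).  Zero padding is chosen per
layer so every hidden feature map already has the output's size: height
``input − 1`` and preserved width.  The network is fully convolutional, so
inputs taller than 11 rows are accepted at inference.

Convolutions are cross-correlations (the learned kernels make the two
orientations equivalent) evaluated in the frequency domain — the kernels
are large relative to the patches, so FFT evaluation is the cheap route —
with hand-derived gradients for training.  All tensors are 32-bit floats.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import h5py
import numpy as np
import scipy.fft as sfft

from . import sampling


@dataclass(frozen=True)
class UDNNConfig:
    """Architecture hyperparameters.

    ``n1``/``n2`` are the feature-map counts of the two hidden layers;
    ``k*``/``p*`` are per-layer kernel sizes and zero paddings
    (height, width); ``n_out`` is the number of output channels, i.e. the
    upscaling factor minus one.
    """

    n1: int = 64
    n2: int = 32
    k1: tuple[int, int] = (10, 17)
    k2: tuple[int, int] = (7, 13)
    k3: tuple[int, int] = (7, 13)
    p1: tuple[int, int] = (4, 8)
    p2: tuple[int, int] = (3, 6)
    p3: tuple[int, int] = (3, 6)
    n_out: int = 1
    in_rows: int = 11
    name: str = "udnn"

    def __post_init__(self) -> None:
        if self.n1 < 1 or self.n2 < 1 or self.n_out < 1:
            raise ValueError("feature and output channel counts must be positive")
        h = self.in_rows
        for i, (k, p) in enumerate([(self.k1, self.p1), (self.k2, self.p2),
                                    (self.k3, self.p3)], start=1):
            h_out = h + 2 * p[0] - k[0] + 1
            expected = self.in_rows - 1  # all layers produce output-sized maps
            if h_out != expected:
                raise ValueError(
                    f"layer {i}: height {h} + 2·{p[0]} − {k[0]} + 1 = {h_out}, "
                    f"expected {expected} (every feature map must match the output)")
            if 2 * p[1] - k[1] + 1 != 0:
                raise ValueError(f"layer {i}: padding {p[1]} does not preserve width "
                                 f"for kernel width {k[1]}")
            h = h_out

    @property
    def factor(self) -> int:
        """Upscaling factor implied by the output channel count."""
        return self.n_out + 1


def default_configs(n_out: int = 1) -> dict[str, UDNNConfig]:
    """The named architecture variants.

    The base model uses 64/32 feature maps and kernels 10×17, 7×13, 7×13;
    the variants double or halve the feature counts (``udnn128`` /
    ``udnn32``) or grow/shrink every kernel by two rows and columns
    (``udnn-lk`` / ``udnn-sk``), with paddings re-solved to keep the
    height-minus-one / width-preserving contract.
    """
    return {
        "udnn": UDNNConfig(n_out=n_out, name="udnn"),
        "udnn128": UDNNConfig(n1=128, n2=64, n_out=n_out, name="udnn128"),
        "udnn32": UDNNConfig(n1=32, n2=16, n_out=n_out, name="udnn32"),
        "udnn-lk": UDNNConfig(k1=(12, 19), k2=(9, 15), k3=(9, 15),
                              p1=(5, 9), p2=(4, 7), p3=(4, 7),
                              n_out=n_out, name="udnn-lk"),
        "udnn-sk": UDNNConfig(k1=(8, 15), k2=(5, 11), k3=(5, 11),
                              p1=(3, 7), p2=(2, 5), p3=(2, 5),
                              n_out=n_out, name="udnn-sk"),
    }


def scaled_config(base: UDNNConfig, scale: int) -> UDNNConfig:
    """Divide the feature-map counts by ``scale`` (kernels unchanged)."""
    if scale < 1:
        raise ValueError("scale must be a positive integer")
    return replace(base, n1=max(1, base.n1 // scale), n2=max(1, base.n2 // scale),
                   name=f"{base.name}/{scale}")


@dataclass
class UDNNParams:
    """Learnable tensors: kernels ``w1..w3`` and biases ``b1..b3``."""

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    w3: np.ndarray
    b3: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"w1": self.w1, "b1": self.b1, "w2": self.w2, "b2": self.b2,
                "w3": self.w3, "b3": self.b3}

    def copy(self) -> "UDNNParams":
        return UDNNParams(**{k: v.copy() for k, v in self.as_dict().items()})

    def check_finite(self) -> None:
        for k, v in self.as_dict().items():
            if not np.isfinite(v).all():
                raise FloatingPointError(f"parameter {k} contains non-finite values")


def init_params(config: UDNNConfig, seed: int = 0) -> UDNNParams:
    """Seeded He initialization: kernels ~ N(0, 2/fan_in), biases zero.

    Variance scaling keeps activation magnitudes of the ReLU layers near
    the input's, which lets Adam make progress immediately at the schedule's
    starting learning rates; a fixed tiny kernel scale stalls the first
    hundreds of updates in practice.
    """
    rng = np.random.default_rng(seed)

    def w(shape):
        fan_in = int(np.prod(shape[1:]))
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)

    return UDNNParams(
        w1=w((config.n1, 1, *config.k1)), b1=np.zeros(config.n1, dtype=np.float32),
        w2=w((config.n2, config.n1, *config.k2)), b2=np.zeros(config.n2, dtype=np.float32),
        w3=w((config.n_out, config.n2, *config.k3)), b3=np.zeros(config.n_out, dtype=np.float32),
    )


# ---------------------------------------------------------------------------
# FFT-based convolution with explicit gradients
#
# The kernels are large relative to the patches (10×17 on an 11-row input),
# so frequency-domain evaluation is far cheaper than sliding-window matrix
# assembly: each layer is two real FFTs, one batched complex matrix product
# contracting the channel axis, and one inverse FFT.


def _rfft2(x: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    return sfft.rfft2(x, s=shape, axes=(-2, -1))


def _freq_contract(Fa: np.ndarray, Fb: np.ndarray) -> np.ndarray:
    """Contract ``(A, C, S1, F) × (B, C, S1, F) → (A, B, S1, F)`` over C."""
    out = np.matmul(Fa.transpose(2, 3, 0, 1), Fb.transpose(2, 3, 1, 0))
    return out.transpose(2, 3, 0, 1)


def _corr_valid(xp: np.ndarray, w: np.ndarray, block: int = 384) -> np.ndarray:
    """Valid cross-correlation of a padded batch with a kernel bank.

    Wide inputs are processed in overlap-save blocks along the width so the
    kernel FFTs stay small and are reused across blocks.
    """
    co, ci, kh, kw = w.shape
    B, C, Hp, Wp = xp.shape
    Ho, Wo = Hp - kh + 1, Wp - kw + 1
    L = min(Wo, block)
    s = (sfft.next_fast_len(Hp + kh - 1), sfft.next_fast_len(L + 2 * (kw - 1)))
    Fw = _rfft2(w[:, :, ::-1, ::-1], s)  # flip: correlation via convolution
    out = np.empty((B, co, Ho, Wo), dtype=np.float32)
    for j0 in range(0, Wo, L):
        j1 = min(j0 + L, Wo)
        Fx = _rfft2(xp[..., j0:j1 + kw - 1], s)
        full = sfft.irfft2(_freq_contract(Fx, Fw), s=s, axes=(-2, -1))
        out[..., j0:j1] = full[:, :, kh - 1:kh - 1 + Ho, kw - 1:kw - 1 + (j1 - j0)]
    return out


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray,
                  pad: tuple[int, int]):
    """Cross-correlate a zero-padded batch; returns output and backward cache.

    ``x`` is ``(B, C_in, H, W)``; the layer's padding sets the output size.
    """
    ph, pw = pad
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    Ho = xp.shape[2] - w.shape[2] + 1
    Wo = xp.shape[3] - w.shape[3] + 1
    out = _corr_valid(xp, w) + b[None, :, None, None]
    return out.astype(np.float32), (xp, (Ho, Wo))


def _conv_backward(dout: np.ndarray, w: np.ndarray, cache,
                   pad: tuple[int, int], need_dx: bool = True):
    """Gradients of a cross-correlation layer given upstream ``dout``."""
    xp, (Ho, Wo) = cache
    co, ci, kh, kw = w.shape
    ph, pw = pad
    Hp, Wp = xp.shape[2:]
    db = dout.sum(axis=(0, 2, 3))

    # dW[o,c] = Σ_b valid-correlation(xp[b,c], dout[b,o])
    s_w = (sfft.next_fast_len(Hp + Ho - 1), sfft.next_fast_len(Wp + Wo - 1))
    Fx = _rfft2(xp, s_w)
    Fd = _rfft2(dout[:, :, ::-1, ::-1], s_w)
    # contract over the batch axis: (O,B,S) × (C,B,S) → (O,C,S)
    full = sfft.irfft2(_freq_contract(Fd.transpose(1, 0, 2, 3),
                                      Fx.transpose(1, 0, 2, 3)),
                       s=s_w, axes=(-2, -1))
    dw = np.ascontiguousarray(
        full[:, :, Ho - 1:Ho - 1 + kh, Wo - 1:Wo - 1 + kw]).astype(np.float32)

    dx = None
    if need_dx:
        # dxp[b,c] = Σ_o full-convolution(dout[b,o], w[o,c]); size is exactly
        # the padded input, so cropping the padding recovers dx.
        s_x = (sfft.next_fast_len(Ho + kh - 1), sfft.next_fast_len(Wo + kw - 1))
        Fd2 = _rfft2(dout, s_x)
        Fw = _rfft2(w, s_x).transpose(1, 0, 2, 3)  # (C, O, S1, F)
        full = sfft.irfft2(_freq_contract(Fd2, Fw), s=s_x, axes=(-2, -1))
        dxp = full[:, :, :Hp, :Wp]
        H, W = Hp - 2 * ph, Wp - 2 * pw
        dx = np.ascontiguousarray(dxp[:, :, ph:ph + H, pw:pw + W]).astype(np.float32)
    return dx, dw, db


def _as_batch(x: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 2:  # single (H, W) patch
        return x[None, None], True
    if x.ndim == 3:  # batch of (H, W) patches
        return x[:, None], False
    if x.ndim == 4:
        if x.shape[1] != 1:
            raise ValueError("input must have a single channel")
        return x, False
    raise ValueError(f"input rank {x.ndim} not understood")


def forward(params: UDNNParams, config: UDNNConfig, x: np.ndarray,
            return_cache: bool = False):
    """Run the network on one patch ``(H, W)`` or a batch ``(B, H, W)``.

    ``H`` may exceed ``config.in_rows`` (fully convolutional); the output
    has height ``H − 1`` and the input's width.  For a single patch the
    result is ``(n_out, H−1, W)``; for a batch ``(B, n_out, H−1, W)``.
    """
    xb, single = _as_batch(x)
    if xb.shape[2] < config.in_rows:
        raise ValueError(f"input height {xb.shape[2]} is below the minimum "
                         f"{config.in_rows}")
    z1, c1 = _conv_forward(xb, params.w1, params.b1, config.p1)
    a1 = np.maximum(z1, 0.0)
    z2, c2 = _conv_forward(a1, params.w2, params.b2, config.p2)
    a2 = np.maximum(z2, 0.0)
    out, c3 = _conv_forward(a2, params.w3, params.b3, config.p3)
    result = out[0] if single else out
    if return_cache:
        return result, (c1, z1, c2, z2, c3)
    return result


def backward(params: UDNNParams, config: UDNNConfig, cache,
             dout: np.ndarray) -> dict[str, np.ndarray]:
    """Parameter gradients for a batched forward pass (``dout`` is d loss/d out)."""
    c1, z1, c2, z2, c3 = cache
    if dout.ndim == 3:
        dout = dout[None]
    d3, dw3, db3 = _conv_backward(dout.astype(np.float32), params.w3, c3, config.p3)
    d3 = d3 * (z2 > 0)
    d2, dw2, db2 = _conv_backward(d3, params.w2, c2, config.p2)
    d2 = d2 * (z1 > 0)
    _, dw1, db1 = _conv_backward(d2, params.w1, c1, config.p1, need_dx=False)
    return {"w1": dw1, "b1": db1, "w2": dw2, "b2": db2, "w3": dw3, "b3": db3}


# ---------------------------------------------------------------------------
# checkpoints


_CONFIG_ATTRS = ("n1", "n2", "k1", "k2", "k3", "p1", "p2", "p3", "n_out",
                 "in_rows", "name")


def save_checkpoint(path: str | Path, params: UDNNParams, config: UDNNConfig,
                    group: str = "udnn", extra: dict | None = None) -> None:
    """Store parameters as one HDF5 dataset per tensor plus config attributes."""
    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        for k, v in params.as_dict().items():
            g.create_dataset(k, data=v)
        for a in _CONFIG_ATTRS:
            v = getattr(config, a)
            g.attrs[a] = v if isinstance(v, (int, str)) else list(v)
        for k, v in (extra or {}).items():
            g.attrs[k] = v


def load_checkpoint(path: str | Path, group: str = "udnn") -> tuple[UDNNParams, UDNNConfig]:
    with h5py.File(path, "r") as f:
        if group not in f:
            raise KeyError(f"checkpoint group {group!r} not found in {path}")
        g = f[group]
        params = UDNNParams(**{k: g[k][()] for k in
                               ("w1", "b1", "w2", "b2", "w3", "b3")})
        kwargs = {}
        for a in _CONFIG_ATTRS:
            v = g.attrs[a]
            if a in ("n1", "n2", "n_out", "in_rows"):
                kwargs[a] = int(v)
            elif a == "name":
                kwargs[a] = str(v)
            else:
                kwargs[a] = tuple(int(e) for e in v)
        return params, UDNNConfig(**kwargs)


# ---------------------------------------------------------------------------
# whole-sinogram upscaling


def upscale_sinogram(params: UDNNParams, config: UDNNConfig, sino: np.ndarray,
                     normalize: bool = True, batch_size: int = 256) -> np.ndarray:
    """Upscale an undersampled ``(L, W)`` sinogram by ``config.factor``.

    Pipeline: tile into overlapping 11-row windows, normalize each window
    to [0, 1], run the network, invert the normalization, overlap-average
    the per-window predictions, and interlace them with the input rows.
    The output has ``factor·(L−1)+1`` rows with the input rows verbatim at
    their slots.
    """
    sino = np.asarray(sino, dtype=np.float32)
    windows, starts = sampling.tile_inference_patches(sino, config.in_rows)
    if normalize:
        lo = windows.min(axis=(1, 2), keepdims=True)
        hi = windows.max(axis=(1, 2), keepdims=True)
        scale = hi - lo
        degenerate = scale <= 1.0e-12
        safe = np.where(degenerate, 1.0, scale)
        net_in = np.where(degenerate, 0.0, (windows - lo) / safe).astype(np.float32)
    else:
        lo = np.zeros((windows.shape[0], 1, 1), dtype=np.float32)
        safe = np.ones_like(lo)
        net_in = windows
    preds = np.empty((windows.shape[0], config.n_out, config.in_rows - 1,
                      sino.shape[1]), dtype=np.float32)
    for b0 in range(0, net_in.shape[0], batch_size):
        b1 = min(b0 + batch_size, net_in.shape[0])
        preds[b0:b1] = forward(params, config, net_in[b0:b1])
    preds = preds * safe[:, :, None] + lo[:, :, None]
    intermediate = sampling.merge_patch_predictions(preds, starts, sino.shape[0])
    return sampling.interlace(sino, intermediate, config.n_out)
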