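"""A 3D U-Net for voxel-wise tissue segmentation, implemented on numpy.

The network is the classic encoder/decoder with skip connections: five
resolution levels with feature counts 8, 16, 32, 64, 128; each level applies
[3x3x3 conv -> ReLU -> batch norm] twice; encoder levels end in 2x max
pooling, decoder levels concatenate the skip tensor with the upsampled tensor
from below; a final 1x1x1 convolution maps to the 5 tissue channels.  The
loss is plain mean squared error against the one-hot tissue encoding.

Forward and backward passes are written out by hand: 3D convolutions are
evaluated as 27 shifted (C_out x C_in) BLAS matmuls, pooling/upsampling are
explicit linear operators with exact adjoints, and optimization uses Adam.
Everything runs in float32; a model is a plain Python object whose parameters
live in numpy arrays, serialized with ``numpy.savez``.  Spatial dims that are
not divisible by 2^(levels-1) are zero-padded internally and the output is
cropped back, so output dims always equal input dims.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

# --------------------------------------------------------------------------- #
# spec
# --------------------------------------------------------------------------- #


@dataclass
class UNetSpec:
    """Architecture hyperparameters. Feature counts must double level-to-level."""

    levels: int = 5
    features: tuple[int, ...] = (8, 16, 32, 64, 128)
    in_channels: int = 1
    out_channels: int = 5
    kernel: int = 3
    final_kernel: int = 1
    upsample: str = "trilinear"  # or "nearest"

    def __post_init__(self) -> None:
        self.features = tuple(int(f) for f in self.features)
        if len(self.features) != self.levels:
            raise ValueError(f"need {self.levels} feature counts, got {self.features}")
        for a, b in zip(self.features, self.features[1:]):
            if b != 2 * a:
                raise ValueError(f"features must double per level, got {self.features}")
        if self.upsample not in ("trilinear", "nearest"):
            raise ValueError(f"unknown upsample mode {self.upsample!r}")

    @property
    def divisor(self) -> int:
        return 2 ** (self.levels - 1)


# --------------------------------------------------------------------------- #
# layers
# --------------------------------------------------------------------------- #


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray) -> None:
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


class Conv3d:
    """3D convolution with 'same' padding (kernel 3) or pointwise (kernel 1)."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator) -> None:
        self.cin, self.cout, self.k = cin, cout, k
        fan_in = cin * k**3
        std = np.sqrt(2.0 / fan_in)
        self.weight = Param(rng.normal(0.0, std, (cout, cin, k, k, k)))
        self.bias = Param(np.zeros(cout))
        self._xf: tuple | None = None

    def params(self):
        return [self.weight, self.bias]

    @staticmethod
    def _shift_slices(shift, dims):
        """(dst, src) index tuples so that dst[v] aligns with src[v + shift]."""
        dst, src = [], []
        for s, nn in zip(shift, dims):
            dst.append(slice(max(0, -s), nn - max(0, s)))
            src.append(slice(max(0, s), nn - max(0, -s)))
        return tuple(dst), tuple(src)

    def forward(self, x: np.ndarray, record: bool = True) -> np.ndarray:
        """'Same' convolution as k^3 channel-mixing matmuls on the flat input.

        Each kernel offset contributes W_o @ x, accumulated into the output
        with the corresponding spatial shift; this streams the input once per
        offset through BLAS without materializing an im2col buffer.
        """
        c, d, h, w = x.shape
        n = d * h * w
        xf = np.ascontiguousarray(x.reshape(c, n), dtype=np.float32)
        if record:
            self._xf = (xf, (d, h, w))
        if self.k == 1:
            y = self.weight.value.reshape(self.cout, self.cin) @ xf
            y += self.bias.value[:, None]
            return y.reshape(self.cout, d, h, w)
        p = self.k // 2
        y = np.zeros((self.cout, d, h, w), dtype=np.float32)
        wv = self.weight.value
        for dz in range(self.k):
            for dyy in range(self.k):
                for dxx in range(self.k):
                    z = (wv[:, :, dz, dyy, dxx] @ xf).reshape(self.cout, d, h, w)
                    dst, src = self._shift_slices((dz - p, dyy - p, dxx - p),
                                                  (d, h, w))
                    y[(slice(None),) + dst] += z[(slice(None),) + src]
        y += self.bias.value[:, None, None, None]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cout, d, h, w = dy.shape
        n = d * h * w
        xf, dims = self._xf
        self._xf = None
        dyf = np.ascontiguousarray(dy.reshape(cout, n), dtype=np.float32)
        self.bias.grad += dyf.sum(axis=1)
        if self.k == 1:
            self.weight.grad += (dyf @ xf.T).reshape(self.weight.value.shape)
            dx = self.weight.value.reshape(cout, self.cin).T @ dyf
            return dx.reshape(self.cin, d, h, w)
        p = self.k // 2
        dy4 = dyf.reshape(cout, d, h, w)
        dxf = np.zeros((self.cin, n), dtype=np.float32)
        wv = self.weight.value
        buf = np.empty((cout, d, h, w), dtype=np.float32)
        for dz in range(self.k):
            for dyy in range(self.k):
                for dxx in range(self.k):
                    # dys[v] = dy[v - shift], aligned with x[v]
                    dst, src = self._shift_slices((dz - p, dyy - p, dxx - p),
                                                  (d, h, w))
                    buf[...] = 0.0
                    buf[(slice(None),) + src] = dy4[(slice(None),) + dst]
                    ds = buf.reshape(cout, n)
                    self.weight.grad[:, :, dz, dyy, dxx] += ds @ xf.T
                    dxf += wv[:, :, dz, dyy, dxx].T @ ds
        return dxf.reshape(self.cin, d, h, w)


class ReLU:
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, record: bool = True) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if record:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class BatchNorm3d:
    """Per-channel normalization: batch statistics in training, running at eval.

    With one image per forward pass the 'batch' statistics are the statistics
    of that single volume; gradient accumulation across images does not share
    statistics between them.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.eps, self.momentum = eps, momentum
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool, record: bool = True) -> np.ndarray:
        c = x.shape[0]
        xf = x.reshape(c, -1)
        if training:
            mu = xf.mean(axis=1)
            var = xf.var(axis=1)
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (xf - mu[:, None]) * inv[:, None]
        y = self.gamma.value[:, None] * xhat + self.beta.value[:, None]
        if record:
            self._cache = (xhat, inv.astype(np.float32), training)
        return y.reshape(x.shape).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, training = self._cache
        self._cache = None
        c = dy.shape[0]
        dyf = dy.reshape(c, -1)
        self.gamma.grad += (dyf * xhat).sum(axis=1)
        self.beta.grad += dyf.sum(axis=1)
        g = self.gamma.value[:, None] * inv[:, None]
        if not training:
            return (dyf * g).reshape(dy.shape)
        m = dyf.shape[1]
        dxhat = dyf * self.gamma.value[:, None]
        dx = inv[:, None] * (
            dxhat
            - dxhat.mean(axis=1, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=1, keepdims=True) / m
        )
        return dx.reshape(dy.shape).astype(np.float32)


class MaxPool2:
    """2x max pooling along each spatial axis (dims must be even)."""

    def __init__(self) -> None:
        self._cache = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, record: bool = True) -> np.ndarray:
        c, d, h, w = x.shape
        xr = (x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
               .transpose(0, 1, 3, 5, 2, 4, 6)
               .reshape(c, d // 2, h // 2, w // 2, 8))
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if record:
            self._cache = (idx, x.shape)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, shape = self._cache
        self._cache = None
        c, d, h, w = shape
        dxr = np.zeros((c, d // 2, h // 2, w // 2, 8), dtype=dy.dtype)
        np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=-1)
        return (dxr.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2)
                   .transpose(0, 1, 4, 2, 5, 3, 6)
                   .reshape(c, d, h, w))


def _upsample_matrix(n: int, mode: str) -> np.ndarray:
    """(2n x n) linear operator doubling one axis."""
    out = np.zeros((2 * n, n), dtype=np.float32)
    for i in range(2 * n):
        if mode == "nearest":
            out[i, i // 2] = 1.0
            continue
        src = min(max((i + 0.5) / 2.0 - 0.5, 0.0), n - 1.0)
        i0 = int(np.floor(src))
        i1 = min(i0 + 1, n - 1)
        f = src - i0
        out[i, i0] += 1.0 - f
        out[i, i1] += f
    return out


class Upsample2:
    """2x upsampling (trilinear or nearest) as a separable linear operator."""

    def __init__(self, mode: str = "trilinear") -> None:
        self.mode = mode
        self._mats: dict[int, np.ndarray] = {}
        self._in_shape = None

    def params(self):
        return []

    def _mat(self, n: int) -> np.ndarray:
        if n not in self._mats:
            self._mats[n] = _upsample_matrix(n, self.mode)
        return self._mats[n]

    def forward(self, x: np.ndarray, record: bool = True) -> np.ndarray:
        if record:
            self._in_shape = x.shape
        y = x
        for axis in (1, 2, 3):
            m = self._mat(x.shape[axis])
            y = np.moveaxis(np.tensordot(m, y, axes=(1, axis)), 0, axis)
        return np.ascontiguousarray(y, dtype=np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy
        for axis in (1, 2, 3):
            m = self._mat(self._in_shape[axis])
            dx = np.moveaxis(np.tensordot(m.T, dx, axes=(1, axis)), 0, axis)
        self._in_shape = None
        return np.ascontiguousarray(dx, dtype=np.float32)


class ConvBlock:
    """[conv3 -> ReLU -> batch norm] x2, the per-level processing unit."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator) -> None:
        self.conv1 = Conv3d(cin, cout, k, rng)
        self.relu1 = ReLU()
        self.bn1 = BatchNorm3d(cout)
        self.conv2 = Conv3d(cout, cout, k, rng)
        self.relu2 = ReLU()
        self.bn2 = BatchNorm3d(cout)

    def params(self):
        return (self.conv1.params() + self.bn1.params()
                + self.conv2.params() + self.bn2.params())

    def forward(self, x: np.ndarray, training: bool, record: bool = True) -> np.ndarray:
        x = self.bn1.forward(self.relu1.forward(self.conv1.forward(x, record), record),
                             training, record)
        x = self.bn2.forward(self.relu2.forward(self.conv2.forward(x, record), record),
                             training, record)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = self.conv2.backward(self.relu2.backward(self.bn2.backward(dy)))
        dy = self.conv1.backward(self.relu1.backward(self.bn1.backward(dy)))
        return dy


# --------------------------------------------------------------------------- #
# the network
# --------------------------------------------------------------------------- #


class UNet3D:
    def __init__(self, spec: UNetSpec, seed: int = 0) -> None:
        self.spec = spec
        rng = np.random.default_rng(seed)
        L = spec.levels
        f = spec.features
        self.enc = []
        cin = spec.in_channels
        for i in range(L):
            self.enc.append(ConvBlock(cin, f[i], spec.kernel, rng))
            cin = f[i]
        self.pools = [MaxPool2() for _ in range(L - 1)]
        self.ups = [Upsample2(spec.upsample) for _ in range(L - 1)]
        self.dec = [ConvBlock(f[i] + f[i + 1], f[i], spec.kernel, rng)
                    for i in range(L - 1)]
        self.head = Conv3d(f[0], spec.out_channels, spec.final_kernel, rng)
        self._skip_channels = [f[i] for i in range(L - 1)]
        self._crop = None

    # -- parameters ---------------------------------------------------------

    def params(self) -> list[Param]:
        out: list[Param] = []
        for block in self.enc + self.dec:
            out.extend(block.params())
        out.extend(self.head.params())
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    # -- forward / backward -------------------------------------------------

    def _pad_input(self, x: np.ndarray) -> np.ndarray:
        d = self.spec.divisor
        pads = [(0, (-s) % d) for s in x.shape[1:]]
        self._crop = tuple(slice(0, s) for s in x.shape[1:])
        if any(p[1] for p in pads):
            x = np.pad(x, [(0, 0)] + pads)
        return x

    def forward(self, image: np.ndarray, training: bool = False,
                record: bool | None = None) -> np.ndarray:
        """Run the network on one volume; returns a (5, D, H, W) field.

        ``image`` is a 3D array (a single input channel is added) or an
        already-channeled 4D array.  In eval mode (training=False) the pass is
        deterministic given the weights.
        """
        image = np.asarray(image)
        if image.ndim == 3:
            image = image[None]
        if image.ndim != 4:
            raise ValueError(f"expected a 3D volume, got shape {image.shape}")
        if record is None:
            record = training
        x = self._pad_input(image.astype(np.float32))
        skips = []
        L = self.spec.levels
        for i in range(L - 1):
            x = self.enc[i].forward(x, training, record)
            skips.append(x)
            x = self.pools[i].forward(x, record)
        x = self.enc[L - 1].forward(x, training, record)
        for i in reversed(range(L - 1)):
            up = self.ups[i].forward(x, record)
            x = np.concatenate([skips[i], up], axis=0)
            x = self.dec[i].forward(x, training, record)
        y = self.head.forward(x, record)
        crop = self._crop
        return y[(slice(None),) + crop]

    def backward(self, dy: np.ndarray) -> None:
        """Accumulate parameter gradients for the last recorded forward pass."""
        d = self.spec.divisor
        full = [dy.shape[0]] + [s + ((-s) % d) for s in dy.shape[1:]]
        if tuple(full) != dy.shape:
            buf = np.zeros(full, dtype=np.float32)
            buf[(slice(None),) + self._crop] = dy
            dy = buf
        dy = dy.astype(np.float32)
        L = self.spec.levels
        dskips = [None] * (L - 1)
        d_cur = self.head.backward(dy)
        for i in range(L - 1):
            d_cur = self.dec[i].backward(d_cur)
            nskip = self._skip_channels[i]
            dskips[i] = d_cur[:nskip]
            d_cur = self.ups[i].backward(d_cur[nskip:])
        d_cur = self.enc[L - 1].backward(d_cur)
        for i in reversed(range(L - 1)):
            d_cur = self.pools[i].backward(d_cur) + dskips[i]
            d_cur = self.enc[i].backward(d_cur)

    # -- serialization ------------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for j, p in enumerate(self.params()):
            out[f"param_{j}"] = p.value
        bns = [m for blk in self.enc + self.dec
               for m in (blk.bn1, blk.bn2)]
        for j, bn in enumerate(bns):
            out[f"running_mean_{j}"] = bn.running_mean
            out[f"running_var_{j}"] = bn.running_var
        return out

    def save(self, path) -> None:
        spec_json = json.dumps({
            "levels": self.spec.levels, "features": list(self.spec.features),
            "in_channels": self.spec.in_channels,
            "out_channels": self.spec.out_channels,
            "kernel": self.spec.kernel, "final_kernel": self.spec.final_kernel,
            "upsample": self.spec.upsample,
        })
        np.savez(path, __spec__=np.frombuffer(spec_json.encode(), dtype=np.uint8),
                 **self.state_arrays())

    @classmethod
    def load(cls, path) -> "UNet3D":
        with np.load(path) as data:
            spec_d = json.loads(bytes(data["__spec__"]).decode())
            spec_d["features"] = tuple(spec_d["features"])
            model = cls(UNetSpec(**spec_d))
            for j, p in enumerate(model.params()):
                p.value[...] = data[f"param_{j}"]
            bns = [m for blk in model.enc + model.dec
                   for m in (blk.bn1, blk.bn2)]
            for j, bn in enumerate(bns):
                bn.running_mean[...] = data[f"running_mean_{j}"]
                bn.running_var[...] = data[f"running_var_{j}"]
        return model


def build(spec: UNetSpec | None = None, seed: int = 0) -> UNet3D:
    """Construct a randomly initialized (Kaiming normal, seed-pinned) network."""
    return UNet3D(spec or UNetSpec(), seed=seed)


def forward(model: UNet3D, image: np.ndarray) -> np.ndarray:
    """Deterministic eval-mode pass: raw 5-channel field, dims equal input."""
    return model.forward(image, training=False)


def loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean squared error over all voxels and channels."""
    pred = np.asarray(pred)
    target = np.asarray(target)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    diff = pred.astype(np.float64) - target.astype(np.float64)
    return float(np.mean(diff * diff))


def loss_grad(pred: np.ndarray, target: np.ndarray) -> np.ndarray:
    """d(MSE)/d(pred)."""
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    return (2.0 / pred.size) * (pred - target).astype(np.float32)


class Adam:
    """Adam with the canonical defaults (b1=0.9, b2=0.999, eps=1e-8)."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (p.grad - m)
            v += (1.0 - self.b2) * (p.grad * p.grad - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def expected_parameter_count(spec: UNetSpec) -> int:
    """Closed-form parameter total from the layer catalogue (used as an oracle)."""

    def conv(cin, cout, k):
        return cout * cin * k**3 + cout

    def bn(c):
        return 2 * c

    def block(cin, cout, k):
        return conv(cin, cout, k) + bn(cout) + conv(cout, cout, k) + bn(cout)

    total = 0
    cin = spec.in_channels
    for i in range(spec.levels):
        total += block(cin, spec.features[i], spec.kernel)
        cin = spec.features[i]
    for i in range(spec.levels - 1):
        total += block(spec.features[i] + spec.features[i + 1], spec.features[i],
                       spec.kernel)
    total += conv(spec.features[0], spec.out_channels, spec.final_kernel)
    return total
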