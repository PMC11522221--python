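"""A parameterized 2D U-Net for binary segmentation, in pure numpy.

The architecture is the classic encoder–decoder with skip connections:
five resolution levels whose feature-map channel counts follow the schedule
F, 2F, 4F, 8F, 16F, four 2x2 max-pool downsamplings on the contractive path
and four 2x2 transposed-convolution upsamplings on the expansive path, two
3x3 "same"-padded convolutions with ReLU per level, and a 1x1 sigmoid head
producing a per-pixel probability of belonging to the skeleton mask.
Padded convolutions keep the output resolution equal to the input, so the
input size only needs to be divisible by 16.

Forward and backward passes are written by hand on top of numpy (im2col
convolutions); training uses Adam on a pixel-wise binary cross-entropy.
Everything is float64 and seeded, so training is bit-deterministic on a
given platform.  This is deliberately a desk-scale engine: at 64x64 and
F in {2, 4, 8} a full training fits in CPU minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["UNetSpec", "UNet2D", "build_unet", "binarize_prediction", "DEFAULT_CUT"]

DEFAULT_CUT = 0.5
N_LEVELS = 5  # F, 2F, 4F, 8F, 16F
_DOWN = N_LEVELS - 1  # number of pool/upsample stages


@dataclass(frozen=True)
class UNetSpec:
    """Architecture hyper-parameters.

    ``f_channels`` is the first feature-map channel count F; deeper levels
    double it up to 16F.  ``input_size`` must be divisible by 16 (four 2x2
    poolings).
    """

    f_channels: int = 2
    input_size: tuple[int, int] = (64, 64)
    in_channels: int = 1

    def __post_init__(self) -> None:
        if self.f_channels < 1:
            raise ValueError("f_channels must be >= 1")
        if any(s % 2**_DOWN for s in self.input_size):
            raise ValueError(
                f"input size {self.input_size} must be divisible by {2 ** _DOWN}"
            )

    @property
    def channel_schedule(self) -> tuple[int, ...]:
        return tuple(self.f_channels * 2**k for k in range(N_LEVELS))


# ---------------------------------------------------------------------------
# layers


class _Conv2D:
    """3x3 (or 1x1) stride-1 'same' convolution, NCHW."""

    def __init__(self, cin: int, cout: int, ksize: int, rng: np.random.Generator):
        fan_in = cin * ksize * ksize
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, ksize, ksize))
        self.b = np.zeros(cout)
        self.k = ksize
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cols = None

    @property
    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        p = self.k // 2
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        return np.lib.stride_tricks.sliding_window_view(x, (self.k, self.k), axis=(2, 3))

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        cols = self._im2col(x)  # (N, C, H, W, k, k)
        if train:
            self._cols = cols
        out = np.tensordot(cols, self.w, axes=([1, 4, 5], [1, 2, 3]))  # (N, H, W, O)
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2)) + self.b[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        # grad: (N, O, H, W)
        self.db[...] = grad.sum(axis=(0, 2, 3))
        self.dw[...] = np.tensordot(
            grad, self._cols, axes=([0, 2, 3], [0, 2, 3])
        )  # (O, C, k, k)
        # dx = 'full' correlation of grad with spatially flipped kernels
        w_flip = self.w[:, :, ::-1, ::-1]
        p = self.k // 2
        g = grad
        if p:
            g = np.pad(grad, ((0, 0), (0, 0), (p, p), (p, p)))
        gcols = np.lib.stride_tricks.sliding_window_view(g, (self.k, self.k), axis=(2, 3))
        dx = np.tensordot(gcols, w_flip, axes=([1, 4, 5], [0, 2, 3]))  # (N, H, W, C)
        self._cols = None
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))


class _ReLU:
    def __init__(self):
        self._mask = None

    params: list = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out = grad * self._mask
        self._mask = None
        return out


class _MaxPool2:
    """2x2 max pooling, stride 2."""

    def __init__(self):
        self._argmax = None
        self._shape = None

    params: list = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(n, c, h // 2, w // 2, 4)
        if train:
            self._argmax = flat.argmax(axis=-1)
            self._shape = x.shape
        return flat.max(axis=-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        flat = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(flat, self._argmax[..., None], grad[..., None], axis=-1)
        out = (
            flat.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )
        self._argmax = None
        return out


class _UpConv2:
    """2x2 stride-2 transposed convolution (learned upsampling)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        fan_in = cin  # each output pixel sees exactly one input pixel
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cin, cout, 2, 2))
        self.b = np.zeros(cout)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x = None

    @property
    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        n, c, h, w = x.shape
        out = np.einsum("nchw,coab->nohawb", x, self.w, optimize=True)
        out = out.reshape(n, self.w.shape[1], 2 * h, 2 * w)
        return out + self.b[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, o, h2, w2 = grad.shape
        g = grad.reshape(n, o, h2 // 2, 2, w2 // 2, 2)
        self.db[...] = grad.sum(axis=(0, 2, 3))
        self.dw[...] = np.einsum("nchw,nohawb->coab", self._x, g, optimize=True)
        dx = np.einsum("nohawb,coab->nchw", g, self.w, optimize=True)
        self._x = None
        return dx


# ---------------------------------------------------------------------------
# the network


class UNet2D:
    """2D U-Net assembled from the layers above.

    Use :func:`build_unet` to construct one from a :class:`UNetSpec`.
    """

    def __init__(self, spec: UNetSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        ch = spec.channel_schedule

        def block(cin, cout):
            return [_Conv2D(cin, cout, 3, rng), _ReLU(), _Conv2D(cout, cout, 3, rng), _ReLU()]

        self.enc_blocks = []
        cin = spec.in_channels
        for k in range(_DOWN):
            self.enc_blocks.append(block(cin, ch[k]))
            cin = ch[k]
        self.pools = [_MaxPool2() for _ in range(_DOWN)]
        self.bottleneck = block(ch[_DOWN - 1], ch[_DOWN])
        self.upconvs = [
            _UpConv2(ch[k + 1], ch[k], rng) for k in reversed(range(_DOWN))
        ]
        self.dec_blocks = [block(2 * ch[k], ch[k]) for k in reversed(range(_DOWN))]
        self.head = _Conv2D(ch[0], 1, 1, rng)

    # -- plumbing ---------------------------------------------------------

    def _layers(self):
        for blk in self.enc_blocks:
            yield from blk
        yield from self.pools
        yield from self.bottleneck
        for up, blk in zip(self.upconvs, self.dec_blocks):
            yield up
            yield from blk
        yield self.head

    def parameters(self):
        """Yield (param, grad) array pairs."""
        for layer in self._layers():
            yield from layer.params

    def parameter_count(self) -> int:
        return int(sum(p.size for p, _ in self.parameters()))

    def level_channels(self) -> tuple[int, ...]:
        """Actual first-conv output channels per encoder level + bottleneck."""
        convs = [blk[0] for blk in self.enc_blocks] + [self.bottleneck[0]]
        return tuple(c.w.shape[0] for c in convs)

    # -- forward / backward ----------------------------------------------

    @staticmethod
    def _run(block, x, train):
        for layer in block:
            x = layer.forward(x, train)
        return x

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 3:
            x = x[:, None]  # (N, H, W) -> (N, 1, H, W)
        if x.shape[2:] != tuple(self.spec.input_size):
            raise ValueError(
                f"input spatial size {x.shape[2:]} != spec {self.spec.input_size}"
            )
        skips = []
        for blk, pool in zip(self.enc_blocks, self.pools):
            x = self._run(blk, x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self._run(self.bottleneck, x, train)
        self._skip_channels = []
        for up, blk, skip in zip(self.upconvs, self.dec_blocks, reversed(skips)):
            x = up.forward(x, train)
            self._skip_channels.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = self._run(blk, x, train)
        return self.head.forward(x, train)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Per-pixel probability map in [0, 1], shape (N, H, W)."""
        z = self.forward_logits(x, train)
        return _sigmoid(z)[:, 0]

    predict_proba = forward

    def backward(self, dlogits: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the head logits; fills layer grads."""
        g = self.head.backward(dlogits)
        # dec_blocks[i] decodes encoder level (n-1-i); collect the gradient
        # flowing into each skip connection, indexed by encoder level.
        skip_grads: dict[int, np.ndarray] = {}
        n = len(self.dec_blocks)
        for i in range(n - 1, -1, -1):
            for layer in reversed(self.dec_blocks[i]):
                g = layer.backward(g)
            c_skip = self._skip_channels[i]
            skip_grads[n - 1 - i] = g[:, :c_skip]
            g = self.upconvs[i].backward(g[:, c_skip:])
        for layer in reversed(self.bottleneck):
            g = layer.backward(g)
        for i in range(len(self.enc_blocks) - 1, -1, -1):
            g = self.pools[i].backward(g)
            g = g + skip_grads[i]
            for layer in reversed(self.enc_blocks[i]):
                g = layer.backward(g)

    def train_step_grads(self, x: np.ndarray, y: np.ndarray) -> float:
        """One forward/backward pass of pixel-wise BCE; returns the loss."""
        z = self.forward_logits(x, train=True)
        y = np.asarray(y, dtype=np.float64)
        if y.ndim == 3:
            y = y[:, None]
        p = _sigmoid(z)
        eps = 1e-12
        loss = float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
        self.backward((p - y) / y.size)
        return loss

    # -- (de)serialization -------------------------------------------------

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.parameters()]

    def set_state(self, state) -> None:
        for (p, _), s in zip(self.parameters(), state):
            p[...] = s

    def save(self, path: str) -> None:
        arrays = {f"p{i}": p for i, (p, _) in enumerate(self.parameters())}
        np.savez(
            path,
            f_channels=self.spec.f_channels,
            input_rows=self.spec.input_size[0],
            input_cols=self.spec.input_size[1],
            in_channels=self.spec.in_channels,
            **arrays,
        )

    @classmethod
    def load(cls, path: str) -> "UNet2D":
        data = np.load(path)
        spec = UNetSpec(
            f_channels=int(data["f_channels"]),
            input_size=(int(data["input_rows"]), int(data["input_cols"])),
            in_channels=int(data["in_channels"]),
        )
        model = cls(spec, seed=0)
        model.set_state([data[f"p{i}"] for i in range(sum(1 for _ in model.parameters()))])
        return model


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Adam:
    """Adam optimizer over a model's (param, grad) pairs."""

    def __init__(self, model: UNet2D, lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in model.parameters()]
        self.v = [np.zeros_like(p) for p, _ in model.parameters()]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for (p, g), m, v in zip(self.model.parameters(), self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def build_unet(spec: UNetSpec, seed: int = 0) -> UNet2D:
    """Construct a seeded, He-initialized U-Net from its spec."""
    return UNet2D(spec, seed=seed)


def binarize_prediction(prob: np.ndarray, cut: float = DEFAULT_CUT) -> np.ndarray:
    """Probability map -> binary mask: 1 iff probability >= cut."""
    prob = np.asarray(prob)
    if prob.size and (prob.min() < 0 or prob.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return (prob >= cut).astype(np.uint8)
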