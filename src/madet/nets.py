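"""Patch classifiers: declarative CNN specs and a compact CPU training engine.

Two network shapes are used by the detector:

* a *basic* net — three convolution+maxpool stages (16 filters of side
  7, 5, 3) followed by fully-connected layers of 200, 100 and 2 units —
  cheap enough to scan whole images and produce a per-pixel probability
  map; and
* a *final* net — five convolution+maxpool stages (kernel sides 7, 5, 3,
  2, 2, all 16 filters) followed by fully-connected layers of 100 and 2
  units — the deeper classifier trained on the hard examples the basic
  net flags.

Activations are leaky rectifiers ``f(x) = x if x >= 0 else a*x`` with
``a = 0.01`` (channel-pairwise maxout is available as an option); pooling
is 2x2 with stride 2; regularisation is dropout with keep probability
0.75 after selected layers; the loss is binary cross-entropy and the
optimiser plain stochastic gradient descent.

Networks are described by :class:`NetworkSpec` (an ordered list of
:class:`LayerSpec`) and compiled to an internal numpy engine (im2col
convolution, explicit backprop).  Training is deterministic given the
seed.  Published layer tables for such patch networks are not always
internally consistent about intermediate spatial sizes; here convolutions
are valid (no padding) except where noted in the builders, pooling uses
floor division, and the resulting shape chain can be inspected with
:func:`output_shapes`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

from .patches import MA, PatchRecord

__all__ = [
    "LayerSpec",
    "NetworkSpec",
    "TrainConfig",
    "TrainedNet",
    "leaky_relu",
    "binary_cross_entropy",
    "build_basic_cnn",
    "build_final_cnn",
    "output_shapes",
    "count_parameters",
    "train",
    "predict_proba",
    "save_net",
    "load_net",
]


# --------------------------------------------------------------------------
# closed-form pieces


def leaky_relu(x, a: float = 0.01):
    """Leaky rectifier: identity for x >= 0, slope *a* otherwise."""
    if not np.isfinite(a):
        raise ValueError("slope a must be finite")
    x = np.asarray(x)
    return np.where(x >= 0, x, a * x)


def binary_cross_entropy(t, p, eps: float = 1e-7) -> float:
    """Mean binary cross-entropy  L = -t log p - (1-t) log(1-p).

    *p* must lie in [0, 1] and is clipped to ``(eps, 1-eps)`` before the
    logarithms; *t* may be hard {0,1} or soft targets in [0,1].
    """
    t = np.asarray(t, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    p = np.clip(p, eps, 1.0 - eps)
    return float(np.mean(-t * np.log(p) - (1.0 - t) * np.log(1.0 - p)))


# --------------------------------------------------------------------------
# declarative specs


@dataclass
class LayerSpec:
    """One layer: operation, size parameters, attached dropout/activation.

    ``dropout_p`` is the probability of zeroing an output unit during
    training (0 disables); ``activation`` is applied to the layer output
    before dropout.
    """

    op: str  # convolution | max_pool | fully_connected | softmax
    n_units: int = 0  # conv filters or FC units
    kernel_side: int = 0
    stride: int = 1
    padding: str = "valid"  # conv only: valid | same
    dropout_p: float = 0.0
    activation: str = "none"  # leaky_relu | maxout | none

    def __post_init__(self) -> None:
        if self.op not in {"convolution", "max_pool", "fully_connected", "softmax"}:
            raise ValueError(f"unknown op {self.op!r}")
        if self.op in {"convolution", "max_pool"} and self.kernel_side < 1:
            raise ValueError("spatial ops need kernel_side >= 1")
        if not 0.0 <= self.dropout_p <= 1.0:
            raise ValueError("dropout_p must be in [0, 1]")
        if self.activation not in {"leaky_relu", "maxout", "none"}:
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass
class NetworkSpec:
    """Ordered layer list plus the input shape ``(channels, side, side)``."""

    input_shape: tuple[int, int, int]
    layers: list[LayerSpec]
    name: str = "net"

    def __post_init__(self) -> None:
        self.input_shape = tuple(int(v) for v in self.input_shape)
        if not self.layers or self.layers[-1].op != "softmax":
            raise ValueError("final layer must be a softmax")
        if self.layers[-1].n_units != 2:
            raise ValueError("softmax must be over exactly 2 classes")
        output_shapes(self)  # raises if any spatial size degenerates

    @property
    def patch_side(self) -> int:
        return self.input_shape[1]

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "name": self.name,
                "input_shape": list(self.input_shape),
                "layers": [asdict(l) for l in self.layers],
            },
            sort_keys=False,
        )

    @classmethod
    def from_yaml(cls, text: str) -> "NetworkSpec":
        d = yaml.safe_load(text)
        return cls(
            input_shape=tuple(d["input_shape"]),
            layers=[LayerSpec(**l) for l in d["layers"]],
            name=d.get("name", "net"),
        )


def output_shapes(spec: NetworkSpec) -> list[tuple]:
    """Shape after each layer; raises if any spatial extent drops below 1."""
    shapes: list[tuple] = []
    shape: tuple = spec.input_shape
    for i, layer in enumerate(spec.layers):
        if layer.op == "convolution":
            c, h, w = shape
            if layer.padding == "same":
                ho, wo = h, w
            else:
                ho, wo = h - layer.kernel_side + 1, w - layer.kernel_side + 1
            cout = layer.n_units
            shape = (cout, ho, wo)
        elif layer.op == "max_pool":
            c, h, w = shape
            k, s = layer.kernel_side, layer.stride
            shape = (c, (h - k) // s + 1, (w - k) // s + 1)
        elif layer.op == "fully_connected":
            shape = (layer.n_units,)
        elif layer.op == "softmax":
            shape = shape
        if layer.activation == "maxout":
            if shape[0] % 2:
                raise ValueError("maxout needs an even number of channels/units")
            shape = (shape[0] // 2, *shape[1:])
        if any(v < 1 for v in shape):
            raise ValueError(
                f"layer {i} ({layer.op}) degenerates to shape {shape}"
            )
        shapes.append(shape)
    return shapes


def count_parameters(spec: NetworkSpec) -> int:
    """Total trainable parameter count (weights + biases)."""
    n = 0
    shape = spec.input_shape
    shapes = output_shapes(spec)
    for layer, out in zip(spec.layers, shapes):
        if layer.op == "convolution":
            n += layer.n_units * (shape[0] * layer.kernel_side**2) + layer.n_units
        elif layer.op == "fully_connected":
            n += layer.n_units * int(np.prod(shape)) + layer.n_units
        shape = out
    return n


def build_basic_cnn(
    input_side: int = 101,
    fc_dropout: float = 0.25,
    activation: str = "leaky_relu",
) -> NetworkSpec:
    """The candidate-screening net: 3 conv+pool stages, then FC 200/100/2.

    Convolutions are valid; each pool carries dropout 0.25 and the stage
    activation.  Dropout on the first hidden FC layer is configurable.
    For small inputs a convolution that would exhaust the spatial extent
    switches to same-padding and a pool on a 1-pixel map is skipped, so
    the same stage structure compiles at any ``input_side`` >= 9.
    """
    layers: list[LayerSpec] = []
    s = input_side
    for n_f, k in [(16, 7), (16, 5), (16, 3)]:
        padding = "valid" if s - k + 1 >= 1 else "same"
        layers.append(
            LayerSpec("convolution", n_units=n_f, kernel_side=k, padding=padding)
        )
        s = s - k + 1 if padding == "valid" else s
        if s >= 2:
            layers.append(
                LayerSpec(
                    "max_pool",
                    kernel_side=2,
                    stride=2,
                    dropout_p=0.25,
                    activation=activation,
                )
            )
            s = (s - 2) // 2 + 1
    layers.append(
        LayerSpec(
            "fully_connected",
            n_units=200,
            dropout_p=fc_dropout,
            activation=activation,
        )
    )
    layers.append(LayerSpec("fully_connected", n_units=100, activation=activation))
    layers.append(LayerSpec("fully_connected", n_units=2))
    layers.append(LayerSpec("softmax", n_units=2))
    return NetworkSpec((3, input_side, input_side), layers, name="basic")


def build_final_cnn(
    input_side: int = 101, activation: str = "leaky_relu"
) -> NetworkSpec:
    """The hard-example classifier: 5 conv+pool stages, then FC 100/2.

    The first convolution uses same-padding (it preserves the input side),
    later ones are valid; dropout 0.25 sits on the first and third pools.
    The same underflow rules as :func:`build_basic_cnn` apply, so the
    stage structure also compiles at small ``input_side``.
    """
    layers: list[LayerSpec] = []
    s = input_side
    for i, k in enumerate([7, 5, 3, 2, 2]):
        padding = "same" if i == 0 or s - k + 1 < 1 else "valid"
        layers.append(
            LayerSpec("convolution", n_units=16, kernel_side=k, padding=padding)
        )
        s = s - k + 1 if padding == "valid" else s
        if s >= 2:
            layers.append(
                LayerSpec(
                    "max_pool",
                    kernel_side=2,
                    stride=2,
                    dropout_p=0.25 if i in (0, 2) else 0.0,
                    activation=activation,
                )
            )
            s = (s - 2) // 2 + 1
    layers.append(LayerSpec("fully_connected", n_units=100, activation=activation))
    layers.append(LayerSpec("fully_connected", n_units=2))
    layers.append(LayerSpec("softmax", n_units=2))
    return NetworkSpec((3, input_side, input_side), layers, name="final")


# --------------------------------------------------------------------------
# compiled engine (private)


class _Conv:
    """Valid/same convolution by im2col in channels-last layout.

    The engine runs internally in NHWC order (contiguous channels make the
    im2col gather and the BLAS matmul cache-friendly); the declarative
    specs keep the conventional (C, H, W) bookkeeping.
    """

    def __init__(self, c_in, n_f, k, padding, rng):
        fan_in = c_in * k * k
        # weight layout (k, k, c_in, n_f), matching the im2col column order
        self.W = (
            rng.standard_normal((k, k, c_in, n_f)) * np.sqrt(2.0 / fan_in)
        ).astype(np.float32)
        self.b = np.zeros(n_f, dtype=np.float32)
        self.vW = np.zeros_like(self.W)
        self.vb = np.zeros_like(self.b)
        self.k, self.padding = k, padding
        self.cache = None

    def _pad(self, x):
        if self.padding == "same":
            pl = (self.k - 1) // 2
            pr = self.k - 1 - pl
            return np.pad(x, ((0, 0), (pl, pr), (pl, pr), (0, 0)))
        return x

    def forward(self, x, train):
        xp = self._pad(x)
        n, hp, wp, c = xp.shape
        k = self.k
        ho, wo = hp - k + 1, wp - k + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        # (n, ho, wo, c, k, k) -> columns ordered (k, k, c)
        cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
            n * ho * wo, k * k * c
        )
        out = cols @ self.W.reshape(-1, self.W.shape[-1]) + self.b
        if train:
            self.cache = (cols, xp.shape, (ho, wo))
        return out.reshape(n, ho, wo, -1)

    def backward(self, dout, lr, momentum=0.0):
        cols, xp_shape, (ho, wo) = self.cache
        n, hp, wp, c = xp_shape
        k = self.k
        f = self.W.shape[-1]
        dmat = dout.reshape(-1, f)
        dW = (cols.T @ dmat).reshape(self.W.shape)
        db = dmat.sum(axis=0)
        dcols = (dmat @ self.W.reshape(-1, f).T).reshape(n, ho, wo, k, k, c)
        dxp = np.zeros(xp_shape, dtype=np.float32)
        for di in range(k):
            for dj in range(k):
                dxp[:, di : di + ho, dj : dj + wo, :] += dcols[:, :, :, di, dj, :]
        self.vW = momentum * self.vW - lr * dW
        self.vb = momentum * self.vb - lr * db
        self.W += self.vW
        self.b += self.vb
        if self.padding == "same":
            pl = (k - 1) // 2
            h, w = hp - (k - 1), wp - (k - 1)
            return dxp[:, pl : pl + h, pl : pl + w, :]
        return dxp

    @property
    def params(self):
        return [self.W, self.b]


class _Pool2:
    """2x2 max pooling with stride 2 (trailing odd row/col dropped)."""

    def forward(self, x, train):
        n, h, w, c = x.shape
        ho, wo = (h - 2) // 2 + 1, (w - 2) // 2 + 1
        xr = (
            x[:, : 2 * ho, : 2 * wo, :]
            .reshape(n, ho, 2, wo, 2, c)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(n, ho, wo, c, 4)
        )
        arg = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, arg[..., None], axis=-1)[..., 0]
        if train:
            self.cache = (arg, x.shape)
        return out

    def backward(self, dout, lr, momentum=0.0):
        arg, xshape = self.cache
        n, h, w, c = xshape
        ho, wo = dout.shape[1], dout.shape[2]
        dslot = np.zeros((n, ho, wo, c, 4), dtype=np.float32)
        np.put_along_axis(dslot, arg[..., None], dout[..., None], axis=-1)
        dxc = (
            dslot.reshape(n, ho, wo, c, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, 2 * ho, 2 * wo, c)
        )
        dx = np.zeros(xshape, dtype=np.float32)
        dx[:, : 2 * ho, : 2 * wo, :] = dxc
        return dx

    params: list = []


class _LeakyReLU:
    def __init__(self, a):
        self.a = a

    def forward(self, x, train):
        if train:
            self.mask = x >= 0
        return np.where(x >= 0, x, self.a * x)

    def backward(self, dout, lr, momentum=0.0):
        return np.where(self.mask, dout, self.a * dout)

    params: list = []


class _Maxout:
    """Pairwise maxout along the channel/unit axis (halves its size)."""

    def forward(self, x, train):
        shp = x.shape
        xr = x.reshape(*shp[:-1], shp[-1] // 2, 2)
        arg = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, arg[..., None], axis=-1)[..., 0]
        if train:
            self.cache = (arg, shp)
        return out

    def backward(self, dout, lr, momentum=0.0):
        arg, shp = self.cache
        dxr = np.zeros((*shp[:-1], shp[-1] // 2, 2), dtype=np.float32)
        np.put_along_axis(dxr, arg[..., None], dout[..., None], axis=-1)
        return dxr.reshape(shp)

    params: list = []


class _Dropout:
    def __init__(self, p):
        self.p = p

    def forward(self, x, train, rng=None):
        if not train or self.p == 0.0:
            return x
        self.mask = (rng.random(x.shape) >= self.p).astype(np.float32) / (1.0 - self.p)
        return x * self.mask

    def backward(self, dout, lr, momentum=0.0):
        return dout * self.mask

    params: list = []


class _Flatten:
    def forward(self, x, train):
        self.shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout, lr, momentum=0.0):
        return dout.reshape(self.shape)

    params: list = []


class _Dense:
    def __init__(self, d_in, d_out, rng):
        self.W = (rng.standard_normal((d_out, d_in)) * np.sqrt(2.0 / d_in)).astype(
            np.float32
        )
        self.b = np.zeros(d_out, dtype=np.float32)
        self.vW = np.zeros_like(self.W)
        self.vb = np.zeros_like(self.b)

    def forward(self, x, train):
        if train:
            self.cache = x
        return x @ self.W.T + self.b

    def backward(self, dout, lr, momentum=0.0):
        x = self.cache
        dW = dout.T @ x
        db = dout.sum(axis=0)
        dx = dout @ self.W
        self.vW = momentum * self.vW - lr * dW.astype(np.float32)
        self.vb = momentum * self.vb - lr * db.astype(np.float32)
        self.W += self.vW
        self.b += self.vb
        return dx

    @property
    def params(self):
        return [self.W, self.b]


def _compile(spec: NetworkSpec, leaky_a: float, rng) -> list:
    """Build the engine layer list from a declarative spec."""
    layers: list = []
    shape = spec.input_shape
    flattened = False
    for lspec, out in zip(spec.layers, output_shapes(spec)):
        if lspec.op == "convolution":
            layers.append(_Conv(shape[0], lspec.n_units, lspec.kernel_side, lspec.padding, rng))
        elif lspec.op == "max_pool":
            if lspec.kernel_side != 2 or lspec.stride != 2:
                raise ValueError("engine supports 2x2 stride-2 pooling")
            layers.append(_Pool2())
        elif lspec.op == "fully_connected":
            if not flattened:
                layers.append(_Flatten())
                flattened = True
            layers.append(_Dense(int(np.prod(shape)), lspec.n_units, rng))
        elif lspec.op == "softmax":
            pass  # fused with the loss / applied at prediction time
        if lspec.activation == "leaky_relu":
            layers.append(_LeakyReLU(leaky_a))
        elif lspec.activation == "maxout":
            layers.append(_Maxout())
        if lspec.dropout_p > 0:
            layers.append(_Dropout(lspec.dropout_p))
        shape = out
    return layers


def _forward(layers, x, train, rng=None):
    for layer in layers:
        if isinstance(layer, _Dropout):
            x = layer.forward(x, train, rng)
        else:
            x = layer.forward(x, train)
    return x


def _softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# --------------------------------------------------------------------------
# training


@dataclass
class TrainConfig:
    """Stochastic-gradient-descent settings.

    ``leaky_a`` is the negative-side slope of the leaky rectifier (0.01).
    ``momentum`` is the classical velocity coefficient of SGD (0.9; set 0
    for plain SGD).  Defaults suit full-size 101-pixel patches;
    scaled-down runs typically use fewer epochs.
    """

    learning_rate: float = 0.005
    momentum: float = 0.95
    batch_size: int = 64
    epochs: int = 30
    leaky_a: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class TrainedNet:
    """A fitted classifier: spec, engine layers (weights) and loss log."""

    spec: NetworkSpec
    layers: list
    training_log: list[float]
    config: TrainConfig

    def predict_proba(self, patches, batch_size: int = 512) -> np.ndarray:
        return predict_proba(self, patches, batch_size=batch_size)


def _to_array(patches) -> np.ndarray:
    """Stack patches to (N, s, s, 3) float32 scaled to [-0.5, 0.5]."""
    if isinstance(patches, np.ndarray):
        arr = patches
    else:
        px = []
        for p in patches:
            if isinstance(p, PatchRecord):
                if p.pixels is None:
                    raise ValueError("patch record has no pixels")
                px.append(p.pixels)
            else:
                px.append(np.asarray(p))
        arr = np.stack(px)
    if arr.ndim == 3:
        arr = arr[None]
    arr = arr.astype(np.float32)
    if arr.shape[-1] != 3:
        raise ValueError("patches must be channels-last (H, W, 3)")
    return arr / 255.0 - 0.5


def train(
    spec: NetworkSpec,
    patches: list[PatchRecord],
    cfg: TrainConfig | None = None,
) -> TrainedNet:
    """Fit *spec* on labeled patches with SGD and cross-entropy loss.

    Both classes must be present.  The per-epoch mean loss is logged;
    training is fully reproducible from ``cfg.seed``.
    """
    cfg = cfg or TrainConfig()
    if not patches:
        raise ValueError("no training patches")
    y = np.array([p.label for p in patches], dtype=np.int64)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    X = _to_array(patches)
    if (X.shape[3], X.shape[1], X.shape[2]) != tuple(spec.input_shape):
        raise ValueError(
            f"patch shape {X.shape[1:]} does not match spec input "
            f"{spec.input_shape}"
        )
    rng = np.random.default_rng(cfg.seed)
    layers = _compile(spec, cfg.leaky_a, rng)
    n = len(y)
    log: list[float] = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = X[idx], y[idx]
            logits = _forward(layers, xb, train=True, rng=rng)
            p = _softmax(logits)
            losses.append(binary_cross_entropy(yb, p[:, MA]))
            # fused softmax + cross-entropy gradient
            grad = p
            grad[np.arange(len(yb)), yb] -= 1.0
            grad /= len(yb)
            d = grad.astype(np.float32)
            for layer in reversed(layers):
                d = layer.backward(d, cfg.learning_rate, cfg.momentum)
        log.append(float(np.mean(losses)))
    return TrainedNet(spec=spec, layers=layers, training_log=log, config=cfg)


def predict_proba(
    net: TrainedNet, patches, batch_size: int = 512
) -> np.ndarray:
    """Microaneurysm probability for each patch (inference mode, no dropout)."""
    X = _to_array(patches)
    if (X.shape[3], X.shape[1], X.shape[2]) != tuple(net.spec.input_shape):
        raise ValueError(
            f"patch shape {X.shape[1:]} does not match spec input "
            f"{net.spec.input_shape}"
        )
    out = np.empty(len(X), dtype=np.float64)
    for start in range(0, len(X), batch_size):
        xb = X[start : start + batch_size]
        logits = _forward(net.layers, xb, train=False)
        out[start : start + len(xb)] = _softmax(logits)[:, MA]
    return out


# --------------------------------------------------------------------------
# persistence


def save_net(net: TrainedNet, path: str | Path) -> None:
    """Write weights (npz) plus a JSON sidecar with spec YAML and config."""
    path = Path(path)
    arrays = {}
    for i, layer in enumerate(net.layers):
        for j, p in enumerate(layer.params):
            arrays[f"l{i}_p{j}"] = p
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {
        "spec_yaml": net.spec.to_yaml(),
        "config": asdict(net.config),
        "training_log": net.training_log,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_net(path: str | Path) -> TrainedNet:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    spec = NetworkSpec.from_yaml(sidecar["spec_yaml"])
    cfg = TrainConfig(**sidecar["config"])
    layers = _compile(spec, cfg.leaky_a, np.random.default_rng(cfg.seed))
    data = np.load(path.with_suffix(".npz"))
    for i, layer in enumerate(layers):
        for j, p in enumerate(layer.params):
            p[...] = data[f"l{i}_p{j}"]
    return TrainedNet(
        spec=spec, layers=layers, training_log=list(sidecar["training_log"]), config=cfg
    )
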