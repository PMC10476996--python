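"""Desk-scale classifier backbone: a compact 3D CNN in plain numpy.

The backbone is a contract — anything that maps a two-channel 3D tensor
to a probability vector can be plugged into the training loop.  This
reference implementation uses two stride-2 3D convolutions, coarse
adaptive average pooling (keeps left/right and inferior/superior
information), one hidden dense layer, and a softmax head.  Forward and
backward passes are hand-written; parameters are updated with Adam.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

EPS = 1e-12


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class _Conv3d:
    """3x3x3 convolution, stride 2, padding 1, via batched im2col."""

    def __init__(self, rng, c_in: int, c_out: int):
        self.c_in, self.c_out = c_in, c_out
        self.w = _he_init(rng, (c_in * 27, c_out), fan_in=c_in * 27)
        self.b = np.zeros(c_out, dtype=np.float32)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        # x: (B, C, D, H, W)
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3, 3), axis=(2, 3, 4))
        win = win[:, :, ::2, ::2, ::2]  # stride 2
        b, c, do, ho, wo = win.shape[:5]
        cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(b, do * ho * wo, c * 27)
        out = cols @ self.w + self.b
        self._cache = (cols, x.shape, (do, ho, wo))
        return np.ascontiguousarray(
            out.reshape(b, do, ho, wo, self.c_out).transpose(0, 4, 1, 2, 3)
        )

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape, (do, ho, wo) = self._cache
        b = x_shape[0]
        dflat = dout.transpose(0, 2, 3, 4, 1).reshape(b, do * ho * wo, self.c_out)
        self.dw = np.tensordot(cols, dflat, axes=([0, 1], [0, 1])).astype(np.float32)
        self.db = dflat.sum(axis=(0, 1)).astype(np.float32)
        dcols = (dflat @ self.w.T).reshape(b, do, ho, wo, self.c_in, 3, 3, 3)
        dxp = np.zeros((b, self.c_in, x_shape[2] + 2, x_shape[3] + 2, x_shape[4] + 2),
                       dtype=np.float32)
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    dxp[:, :, i:i + 2 * do:2, j:j + 2 * ho:2, k:k + 2 * wo:2] += \
                        dcols[:, :, :, :, :, i, j, k].transpose(0, 4, 1, 2, 3)
        return dxp[:, :, 1:-1, 1:-1, 1:-1]

    @property
    def params(self):
        return {"w": self.w, "b": self.b}


class _Dense:
    def __init__(self, rng, n_in: int, n_out: int):
        self.w = _he_init(rng, (n_in, n_out), fan_in=n_in)
        self.b = np.zeros(n_out, dtype=np.float32)
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dw = (self._x.T @ dout).astype(np.float32)
        self.db = dout.sum(axis=0).astype(np.float32)
        return dout @ self.w.T

    @property
    def params(self):
        return {"w": self.w, "b": self.b}


def _pool_bins(n: int, bins: int) -> list[slice]:
    edges = np.linspace(0, n, bins + 1).round().astype(int)
    return [slice(edges[i], max(edges[i + 1], edges[i] + 1)) for i in range(bins)]


class CompactCNN3D:
    """Two conv blocks -> adaptive (2,2,2) average pool -> MLP -> softmax."""

    def __init__(self, n_classes: int, in_channels: int = 2,
                 conv_channels: tuple[int, int] = (12, 24), hidden: int = 64,
                 pool_grid: tuple[int, int, int] = (3, 3, 3),
                 input_pool: tuple[int, int, int] = (1, 1, 1), seed: int = 0):
        self.n_classes = n_classes
        self.config = dict(n_classes=n_classes, in_channels=in_channels,
                           conv_channels=list(conv_channels), hidden=hidden,
                           pool_grid=list(pool_grid), input_pool=list(input_pool),
                           seed=seed)
        self.input_pool = tuple(input_pool)
        rng = np.random.default_rng(seed)
        self.conv1 = _Conv3d(rng, in_channels, conv_channels[0])
        self.conv2 = _Conv3d(rng, conv_channels[0], conv_channels[1])
        self.pool_grid = pool_grid
        n_feat = conv_channels[1] * int(np.prod(pool_grid))
        self.fc1 = _Dense(rng, n_feat, hidden)
        self.fc2 = _Dense(rng, hidden, n_classes)
        self._layers = {"conv1": self.conv1, "conv2": self.conv2,
                        "fc1": self.fc1, "fc2": self.fc2}
        self._cache = {}

    # -- forward / backward -------------------------------------------------

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        x = self._downsample(x)
        a1 = self.conv1.forward(x)
        r1 = np.maximum(a1, 0.0)
        a2 = self.conv2.forward(r1)
        r2 = np.maximum(a2, 0.0)
        pooled, pool_cache = self._adaptive_pool(r2)
        h = self.fc1.forward(pooled)
        hr = np.maximum(h, 0.0)
        logits = self.fc2.forward(hr)
        if train:
            self._cache = {"a1": a1, "a2": a2, "h": h, "pool": pool_cache,
                           "r2_shape": r2.shape}
        return logits

    def _downsample(self, x: np.ndarray) -> np.ndarray:
        """Fixed average pooling in front of the convolutions (no params;
        gradients never flow into the input, so no backward needed)."""
        pd, ph, pw = self.input_pool
        if (pd, ph, pw) == (1, 1, 1):
            return x
        b, c, d, h, w = x.shape
        d2, h2, w2 = d // pd, h // ph, w // pw
        x = x[:, :, :d2 * pd, :h2 * ph, :w2 * pw]
        return x.reshape(b, c, d2, pd, h2, ph, w2, pw).mean(axis=(3, 5, 7))

    def _adaptive_pool(self, x: np.ndarray):
        b, c = x.shape[:2]
        bins = [_pool_bins(n, g) for n, g in zip(x.shape[2:], self.pool_grid)]
        out = np.empty((b, c, *self.pool_grid), dtype=np.float32)
        for i, si in enumerate(bins[0]):
            for j, sj in enumerate(bins[1]):
                for k, sk in enumerate(bins[2]):
                    out[:, :, i, j, k] = x[:, :, si, sj, sk].mean(axis=(2, 3, 4))
        return out.reshape(b, -1), bins

    def _adaptive_pool_backward(self, dpooled: np.ndarray, r2_shape, bins):
        b = r2_shape[0]
        d = dpooled.reshape(b, r2_shape[1], *self.pool_grid)
        dx = np.zeros(r2_shape, dtype=np.float32)
        for i, si in enumerate(bins[0]):
            for j, sj in enumerate(bins[1]):
                for k, sk in enumerate(bins[2]):
                    count = ((si.stop - si.start) * (sj.stop - sj.start)
                             * (sk.stop - sk.start))
                    dx[:, :, si, sj, sk] += d[:, :, i, j, k, None, None, None] / count
        return dx

    def backward(self, dlogits: np.ndarray) -> None:
        dh = self.fc2.backward(dlogits)
        dh = dh * (self._cache["h"] > 0)
        dpooled = self.fc1.backward(dh)
        dr2 = self._adaptive_pool_backward(
            dpooled, self._cache["r2_shape"], self._cache["pool"]
        )
        dr2 = dr2 * (self._cache["a2"] > 0)
        dr1 = self.conv2.backward(dr2)
        dr1 = dr1 * (self._cache["a1"] > 0)
        self.conv1.backward(dr1)

    def predict_proba(self, x: np.ndarray, batch_size: int = 16) -> np.ndarray:
        probs = []
        for i in range(0, x.shape[0], batch_size):
            logits = self.forward_logits(x[i:i + batch_size])
            probs.append(softmax(logits))
        return np.concatenate(probs, axis=0)

    # -- parameter plumbing -------------------------------------------------

    def named_params(self):
        for lname, layer in self._layers.items():
            for pname, arr in layer.params.items():
                yield f"{lname}.{pname}", layer, pname, arr

    def grads(self):
        return {f"{l}.{p}": getattr(layer, "d" + p)
                for l, layer in self._layers.items() for p in ("w", "b")}

    def get_weights(self) -> dict[str, np.ndarray]:
        return {name: arr.copy() for name, _, _, arr in self.named_params()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for name, layer, pname, _ in self.named_params():
            setattr(layer, pname, weights[name].copy())

    def save(self, path: Path | str) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path, __config__=json.dumps(self.config), **self.get_weights())

    @classmethod
    def load(cls, path: Path | str) -> "CompactCNN3D":
        with np.load(path, allow_pickle=False) as data:
            config = json.loads(str(data["__config__"]))
            weights = {k: data[k] for k in data.files if k != "__config__"}
        model = cls(
            n_classes=config["n_classes"], in_channels=config["in_channels"],
            conv_channels=tuple(config["conv_channels"]), hidden=config["hidden"],
            pool_grid=tuple(config["pool_grid"]), seed=config["seed"],
        )
        model.set_weights(weights)
        return model


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Adam:
    """Adam with a mutable learning rate (for plateau scheduling)."""

    def __init__(self, model: CompactCNN3D, lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {name: np.zeros_like(arr) for name, _, _, arr in model.named_params()}
        self.v = {name: np.zeros_like(arr) for name, _, _, arr in model.named_params()}

    def step(self) -> None:
        self.t += 1
        grads = self.model.grads()
        for name, layer, pname, arr in self.model.named_params():
            g = grads[name]
            self.m[name] = self.beta1 * self.m[name] + (1 - self.beta1) * g
            self.v[name] = self.beta2 * self.v[name] + (1 - self.beta2) * g * g
            mhat = self.m[name] / (1 - self.beta1 ** self.t)
            vhat = self.v[name] / (1 - self.beta2 ** self.t)
            arr -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)
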