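"""A compact 1-D convolutional rhythm classifier, implemented in numpy.

Architecture (nine weight layers): seven 1-D convolutions with kernel
width 7 and channel widths doubling 8 -> 8 -> 16 -> 16 -> 32 -> 32 -> 64,
downsampling by 2 (stride-2 convolution) after every second convolution,
ReLU nonlinearities, global average pooling, then two fully connected
layers (64 -> 32 -> 2 logits) with dropout.  Global average pooling makes
one architecture serve every input length from 5-s to 30-s segments.

Training: Adam, softmax cross-entropy, L2 penalty on all weight matrices,
inverted dropout on the fully connected stage.  Everything runs in float32
and is deterministic given the seed.
"""

from __future__ import annotations

import numpy as np

from .base import ModelConfig

KERNEL = 7
CHANNELS = (8, 8, 16, 16, 32, 32, 64)
STRIDES = (1, 2, 1, 2, 1, 2, 1)  # x2 downsampling after convs 2, 4, 6
HIDDEN = 32
N_CLASSES = 2


class _Conv1d:
    """Channels-last 1-D convolution computed as a sum over kernel taps:
    out[:, j, :] = sum_t x_pad[:, j*s + t, :] @ W[t] + b, which keeps every
    inner product a plain matmul and avoids im2col buffers."""

    def __init__(self, c_in: int, c_out: int, stride: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * KERNEL))
        self.W = rng.normal(0, scale, size=(KERNEL, c_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.stride = stride
        self.pad = (KERNEL - 1) // 2

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        # x: (N, L, C_in) -> (N, Lo, C_out)
        n, L, c_in = x.shape
        s = self.stride
        xp = np.pad(x, ((0, 0), (self.pad, self.pad), (0, 0)))
        lo = (L + 2 * self.pad - KERNEL) // s + 1
        out = np.broadcast_to(self.b, (n, lo, self.W.shape[2])).copy()
        for t in range(KERNEL):
            out += xp[:, t : t + s * (lo - 1) + 1 : s] @ self.W[t]
        self._xp = xp
        self._in_len = L
        return out

    def backward(self, dout: np.ndarray):
        # dout: (N, Lo, C_out) -> (N, L, C_in)
        n, lo, c_out = dout.shape
        s = self.stride
        self.db = dout.sum(axis=(0, 1))
        self.dW = np.empty_like(self.W)
        d2 = dout.reshape(-1, c_out)
        dxp = np.zeros_like(self._xp)
        for t in range(KERNEL):
            sl = slice(t, t + s * (lo - 1) + 1, s)
            xs = self._xp[:, sl].reshape(-1, self.W.shape[1])
            self.dW[t] = xs.T @ d2
            dxp[:, sl] += dout @ self.W[t].T
        self._xp = None
        return dxp[:, self.pad : self.pad + self._in_len]

    @property
    def grads(self):
        return [self.dW, self.db]


class _Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / d_in)
        self.W = rng.normal(0, scale, size=(d_in, d_out)).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray):
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        dx = dout @ self.W.T
        self._x = None
        return dx

    @property
    def grads(self):
        return [self.dW, self.db]


class _Adam:
    def __init__(self, params, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


class CNNClassifier:
    """Trained-parameter container with forward/backward passes."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.convs = []
        c_in = 1
        for c_out, s in zip(CHANNELS, STRIDES):
            self.convs.append(_Conv1d(c_in, c_out, s, rng))
            c_in = c_out
        self.fc1 = _Dense(CHANNELS[-1], HIDDEN, rng)
        self.fc2 = _Dense(HIDDEN, N_CLASSES, rng)
        self._rng = rng

    # -- passes --------------------------------------------------------

    @staticmethod
    def _standardize(X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return (X - mu) / sd

    def _forward(self, X: np.ndarray, train: bool):
        x = self._standardize(X)[:, :, None]                 # (N, L, 1)
        self._relu_masks = []
        for conv in self.convs:
            x = conv.forward(x)
            mask = x > 0
            x *= mask
            self._relu_masks.append(mask)
        self._gap_len = x.shape[1]
        g = x.mean(axis=1)                                   # (N, C)
        h = self.fc1.forward(g)
        hmask = h > 0
        h = h * hmask
        self._fc1_mask = hmask
        if train and self.config.dropout_rate > 0:
            keep = 1.0 - self.config.dropout_rate
            drop = (self._rng.random(h.shape) < keep).astype(np.float32) / keep
            h = h * drop
            self._drop_mask = drop
        else:
            self._drop_mask = None
        z = self.fc2.forward(h)
        self._penultimate = h
        return z

    def _backward(self, dz: np.ndarray):
        dh = self.fc2.backward(dz)
        if self._drop_mask is not None:
            dh = dh * self._drop_mask
        dh = dh * self._fc1_mask
        dg = self.fc1.backward(dh)
        dx = np.broadcast_to(
            dg[:, None, :] / self._gap_len, (dg.shape[0], self._gap_len, dg.shape[1])
        )
        for conv, mask in zip(reversed(self.convs), reversed(self._relu_masks)):
            dx = dx * mask
            dx = conv.backward(dx)

    def _layers(self):
        return [*self.convs, self.fc1, self.fc2]

    # -- training ------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> list[float]:
        """Train on segments X (n, L) and integer labels y; returns the
        per-epoch mean training loss."""
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        cfg = self.config
        params = [p for layer in self._layers() for p in layer.params]
        opt = _Adam(params, cfg.learning_rate)
        n = X.shape[0]
        losses = []
        decay_at = int(np.ceil(0.7 * cfg.epochs))  # step decay stabilizes the tail
        for _epoch in range(cfg.epochs):
            if _epoch == 0:
                opt.lr = cfg.learning_rate * 0.3  # warmup epoch
            else:
                opt.lr = cfg.learning_rate * (0.3 if _epoch >= decay_at else 1.0)
            order = self._rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                z = self._forward(X[idx], train=True)
                zmax = z.max(axis=1, keepdims=True)
                e = np.exp(z - zmax)
                p = e / e.sum(axis=1, keepdims=True)
                nll = -np.log(np.clip(p[np.arange(len(idx)), y[idx]], 1e-12, None))
                loss = float(nll.mean())
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {_epoch}; "
                        f"lr={cfg.learning_rate}, batch={cfg.batch_size}"
                    )
                epoch_loss += loss * len(idx)
                dz = p.copy()
                dz[np.arange(len(idx)), y[idx]] -= 1.0
                dz /= len(idx)
                self._backward(dz.astype(np.float32))
                grads = []
                for layer in self._layers():
                    gW, gb = layer.grads
                    grads.append(gW + cfg.l2_weight * layer.params[0])
                    grads.append(gb)
                opt.step(grads)
            losses.append(epoch_loss / n)
        return losses

    # -- inference -----------------------------------------------------

    def logits(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        for start in range(0, X.shape[0], batch_size):
            out.append(self._forward(X[start : start + batch_size], train=False))
        return np.concatenate(out).astype(float)

    def embed(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Penultimate-layer (post-ReLU hidden) activations, for
        visualization of the learned feature space."""
        out = []
        for start in range(0, X.shape[0], batch_size):
            self._forward(X[start : start + batch_size], train=False)
            out.append(self._penultimate.copy())
        return np.concatenate(out).astype(float)
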