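"""3-D convolutional regression network, implemented on NumPy.

Architecture: one 3-D convolution layer (70 filters of size 7 x 6 x 8,
stride 1, ReLU) -> 2 x 2 x 2 max-pooling with stride 1 -> flatten -> one
hidden fully connected layer (ReLU) -> single linear output neuron.  The
input tensors are channel x lag x feature (8 x 10 x 7), which the stated
filter cannot slide over without padding, so both convolution and pooling
use same-size zero padding and preserve the 8 x 10 x 7 spatial extent.

Training minimises mean squared error plus an L2 weight penalty with
stochastic gradient descent with momentum.  The target is standardised
internally with training statistics; predictions are returned on the
original scale.

Convolution is evaluated as a GEMM over pre-extracted patches; pooling is a
separable chain of pairwise maxima whose selectors are kept for the backward
pass.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["CNNConfig", "CNN3DRegressor"]


@dataclass
class CNNConfig:
    """Hyperparameters of the 3-D CNN decoder."""

    n_filters: int = 70
    filter_size: tuple[int, int, int] = (7, 6, 8)
    conv_stride: tuple[int, int, int] = (1, 1, 1)
    pool_size: tuple[int, int, int] = (2, 2, 2)
    pool_stride: int = 1
    hidden_units: int = 64
    l2: float = 0.3
    momentum: float = 0.75
    batch_size: int = 128
    max_epochs: int = 10
    learning_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_filters, self.hidden_units, self.batch_size, self.max_epochs) < 1:
            raise ValueError("counts must be positive")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must lie in [0, 1)")
        if self.conv_stride != (1, 1, 1) or self.pool_stride != 1:
            raise ValueError("only stride 1 is supported")

    def with_seed(self, seed: int) -> "CNNConfig":
        return replace(self, seed=seed)


def _sepmax_fwd(a: np.ndarray, axis: int):
    """Windowed max (window 2, stride 1, truncated at the end) along one axis.

    Returns the maxima and the boolean selector (True where the right-hand
    neighbour won); a 2x2x2 max pool decomposes into one such pass per axis.
    """
    lead = a.shape[axis] - 1
    body = tuple(slice(0, lead) if i == axis else slice(None) for i in range(a.ndim))
    shift = tuple(slice(1, lead + 1) if i == axis else slice(None) for i in range(a.ndim))
    edge = tuple(slice(lead, lead + 1) if i == axis else slice(None) for i in range(a.ndim))
    left = a[body]
    right = a[shift]
    sel = right > left
    m = np.empty_like(a)
    np.maximum(left, right, out=m[body])
    m[edge] = a[edge]
    return m, sel


def _sepmax_bwd(d: np.ndarray, sel: np.ndarray, axis: int) -> np.ndarray:
    """Route gradients back through one :func:`_sepmax_fwd` pass."""
    lead = d.shape[axis] - 1
    body = tuple(slice(0, lead) if i == axis else slice(None) for i in range(d.ndim))
    shift = tuple(slice(1, lead + 1) if i == axis else slice(None) for i in range(d.ndim))
    edge = tuple(slice(lead, lead + 1) if i == axis else slice(None) for i in range(d.ndim))
    out = np.empty_like(d)
    d_body = d[body]
    routed = d_body * sel
    np.subtract(d_body, routed, out=out[body])  # gradient kept by the left winner
    out[edge] = d[edge]
    out[shift] += routed
    return out


def _pool_forward(conv: np.ndarray, pool_size: tuple[int, int, int]):
    """Max pool with stride 1 and same-size output (input is (n, d, h, w, f)).

    A window of ``k`` along one axis is ``k - 1`` composed pairwise passes;
    the separable decomposition over the three spatial axes reproduces the
    full-window maximum.
    """
    out = conv
    trace: list[tuple[np.ndarray, int]] = []
    for axis, k in zip((1, 2, 3), pool_size):
        for _ in range(k - 1):
            out, sel = _sepmax_fwd(out, axis)
            trace.append((sel, axis))
    return out, trace


def _pool_backward(grad_out: np.ndarray, trace) -> np.ndarray:
    d = grad_out
    for sel, axis in reversed(trace):
        d = _sepmax_bwd(d, sel, axis)
    return d


class CNN3DRegressor:
    """Single-output 3-D CNN trained with SGD + momentum.

    Attributes
    ----------
    loss_history_ : list of float
        Mean training MSE (standardised target) per epoch; index 0 is the
        loss evaluated before any parameter update.
    """

    def __init__(self, config: CNNConfig | None = None):
        self.config = config or CNNConfig()
        self._fitted = False

    # -- geometry -----------------------------------------------------------
    def _pads(self, shape: tuple[int, int, int]):
        """Symmetric 'same' padding for the configured filter size."""
        pads = []
        for k in self.config.filter_size:
            total = k - 1
            pads.append((total // 2, total - total // 2))
        return tuple(pads)

    def _extract_patches(self, X: np.ndarray) -> np.ndarray:
        """(N, d, h, w) -> (N, d*h*w, prod(filter_size)) float32 patches."""
        kd, kh, kw = self.config.filter_size
        (p0, p1), (q0, q1), (r0, r1) = self._pads(X.shape[1:])
        Xp = np.zeros(
            (
                X.shape[0],
                X.shape[1] + p0 + p1,
                X.shape[2] + q0 + q1,
                X.shape[3] + r0 + r1,
            ),
            dtype=np.float32,
        )
        Xp[:, p0 : p0 + X.shape[1], q0 : q0 + X.shape[2], r0 : r0 + X.shape[3]] = X
        win = np.lib.stride_tricks.sliding_window_view(Xp, (kd, kh, kw), axis=(1, 2, 3))
        n, d, h, w = X.shape
        return np.ascontiguousarray(win.reshape(n, d * h * w, kd * kh * kw))

    # -- forward pieces -----------------------------------------------------
    def _forward(self, patches: np.ndarray, spatial: tuple[int, int, int], want_grads: bool):
        n = patches.shape[0]
        d, h, w = spatial
        nf = self.config.n_filters
        conv = patches.reshape(n * d * h * w, -1) @ self.Wc + self.bc
        conv = conv.reshape(n, d, h, w, nf)
        relu_mask = conv > 0
        np.maximum(conv, 0.0, out=conv)
        pooled, pool_trace = _pool_forward(conv, self.config.pool_size)
        flat = pooled.reshape(n, -1)
        hid = flat @ self.Wf + self.bf
        hid_mask = hid > 0
        np.maximum(hid, 0.0, out=hid)
        out = hid @ self.wo + self.bo
        if not want_grads:
            return out
        return out, (relu_mask, pool_trace, flat, hid, hid_mask)

    # -- training -----------------------------------------------------------
    def fit(
        self, X: np.ndarray, y: np.ndarray, patches: np.ndarray | None = None
    ) -> "CNN3DRegressor":
        """Train on tensors ``X`` (n, channel, lag, feature) and targets ``y``.

        ``patches`` may carry pre-extracted convolution patches for ``X``
        (as returned by :meth:`_extract_patches`) so that several networks
        trained on the same fold share the extraction cost.
        """
        cfg = self.config
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.float64)
        if X.ndim != 4:
            raise ValueError("X must be (n_samples, channel, lag, feature)")
        n, d, h, w = X.shape
        self.input_shape_ = (d, h, w)
        kd, kh, kw = cfg.filter_size
        self.y_mean_ = float(y.mean())
        self.y_sd_ = float(y.std()) or 1.0
        yt = ((y - self.y_mean_) / self.y_sd_).astype(np.float32)

        rng = np.random.default_rng(cfg.seed)
        k_in = kd * kh * kw
        nf = cfg.n_filters
        flat_dim = d * h * w * nf
        self.Wc = (rng.standard_normal((k_in, nf)) * np.sqrt(2.0 / k_in)).astype(np.float32)
        self.bc = np.zeros(nf, dtype=np.float32)
        self.Wf = (
            rng.standard_normal((flat_dim, cfg.hidden_units))
            * np.sqrt(2.0 / flat_dim)
        ).astype(np.float32)
        self.bf = np.zeros(cfg.hidden_units, dtype=np.float32)
        # zero-initialised readout: the first update only moves the output
        # layer, which keeps the early SGD steps stable at lr ~ 0.01
        self.wo = np.zeros(cfg.hidden_units, dtype=np.float32)
        self.bo = np.float32(0.0)

        if patches is None:
            patches = self._extract_patches(X)
        vel = [np.zeros_like(p) for p in (self.Wc, self.bc, self.Wf, self.bf, self.wo)]
        vbo = 0.0
        # loss before any update, evaluated in batches to bound memory
        sse0 = 0.0
        for start in range(0, n, 512):
            out0 = self._forward(patches[start : start + 512], (d, h, w), False)
            sse0 += float(np.sum((out0 - yt[start : start + 512]) ** 2))
        self.loss_history_ = [sse0 / n]

        for _ in range(cfg.max_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                # sorted gather is cache-friendlier; within-batch order is
                # irrelevant to the summed gradient
                idx = np.sort(order[start : start + cfg.batch_size])
                pb = patches[idx]
                yb = yt[idx]
                m = len(idx)
                out, (relu_mask, pool_trace, flat, hid, hid_mask) = self._forward(
                    pb, (d, h, w), True
                )
                err = (out - yb).astype(np.float32)
                epoch_loss += float(err @ err)
                dout = (2.0 / m) * err
                # output layer
                dwo = hid.T @ dout
                dbo = dout.sum()
                dhid = np.outer(dout, self.wo)
                dhid *= hid_mask
                # hidden layer
                dWf = flat.T @ dhid
                dbf = dhid.sum(axis=0)
                dflat = dhid @ self.Wf.T
                dpool = dflat.reshape(m, d, h, w, nf)
                dconv = _pool_backward(dpool, pool_trace)
                dconv *= relu_mask
                dc2 = dconv.reshape(m * d * h * w, nf)
                dWc = pb.reshape(m * d * h * w, -1).T @ dc2
                dbc = dc2.sum(axis=0)
                # L2 penalty on weight matrices (not biases)
                dWc += cfg.l2 * self.Wc
                dWf += cfg.l2 * self.Wf
                dwo += cfg.l2 * self.wo
                grads = (dWc, dbc, dWf, dbf, dwo)
                params = (self.Wc, self.bc, self.Wf, self.bf, self.wo)
                for v, g, p in zip(vel, grads, params):
                    v *= cfg.momentum
                    v -= cfg.learning_rate * g
                    p += v
                vbo = cfg.momentum * vbo - cfg.learning_rate * float(dbo)
                self.bo += np.float32(vbo)
            self.loss_history_.append(epoch_loss / n)
        self._fitted = True
        return self

    def predict(
        self,
        X: np.ndarray,
        batch_size: int = 512,
        patches: np.ndarray | None = None,
    ) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 3:
            X = X[None]
        if X.shape[1:] != self.input_shape_:
            raise ValueError(
                f"tensor geometry {X.shape[1:]} does not match the trained "
                f"geometry {self.input_shape_}"
            )
        outs = []
        for start in range(0, X.shape[0], batch_size):
            if patches is None:
                pb = self._extract_patches(X[start : start + batch_size])
            else:
                pb = patches[start : start + batch_size]
            outs.append(self._forward(pb, self.input_shape_, False))
        out = np.concatenate(outs).astype(np.float64)
        return out * self.y_sd_ + self.y_mean_
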