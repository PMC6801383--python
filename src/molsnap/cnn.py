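"""A compact reference CNN for snapshot classification, implemented in numpy.

The network is deliberately small — two convolution/pooling stages and two
dense layers — sized to learn color/shape cues from rendered ball-and-stick
snapshots in CPU minutes. It follows the scikit-learn estimator protocol
(fit / predict / predict_proba, fitted attributes with trailing underscores)
so it composes with sklearn model selection, and it is deterministic under a
fixed seed up to floating-point reduction order.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score
from sklearn.utils.validation import check_is_fitted


def _downsample(X: np.ndarray, size: int) -> np.ndarray:
    """Extreme-preserving downsample: per-block max and min of each channel.

    (N, H, W, C) -> (N, size, size, 2C). Mean pooling would dilute small
    high-chroma features (a lone colored atom sphere) into the background;
    keeping each block's channel extremes preserves them undiminished.
    """
    n, h, w, c = X.shape
    fh, fw = h // size, w // size
    if fh < 1 or fw < 1:
        raise ValueError(f"images of size {h}x{w} cannot be downsampled to {size}")
    Xc = X[:, : fh * size, : fw * size, :].astype(np.float32)
    Xc = Xc.reshape(n, size, fh, size, fw, c)
    return np.concatenate([Xc.max(axis=(2, 4)), Xc.min(axis=(2, 4))], axis=-1)


def _chroma_channels(X: np.ndarray) -> np.ndarray:
    """RGB -> (chromaticity - 1/3, brightness - 1/2) channels.

    Rendered snapshots are lit multiplicatively (base color x shading), so
    the RGB *ratios*, not the raw values, identify an element's depiction
    color; chromaticity factors the shading out, and a white background maps
    exactly to zero signal. Computed at native resolution so downsampling
    (a linear operation) preserves small colored features.
    """
    X = X.astype(np.float32)
    s = X.sum(axis=-1, keepdims=True)
    chroma = X / np.maximum(s, 1e-6) - 1.0 / 3.0
    bright = s / (3.0 * 255.0) - 0.5
    return np.concatenate([chroma, bright], axis=-1)


def _conv_forward(X, W, b, stride):
    kh, kw = W.shape[0], W.shape[1]
    win = sliding_window_view(X, (kh, kw), axis=(1, 2))[:, ::stride, ::stride]
    # win: (N, oh, ow, C, kh, kw) -> columns (N, oh, ow, C*kh*kw)
    n, oh, ow = win.shape[:3]
    col = win.reshape(n, oh, ow, -1)
    Wc = W.transpose(2, 0, 1, 3).reshape(-1, W.shape[3])  # (C*kh*kw, F)
    out = col @ Wc + b
    return out, col


def _conv_backward(dout, col, X_shape, W, stride):
    n, h, w, c = X_shape
    kh, kw, _, f = W.shape
    oh, ow = dout.shape[1], dout.shape[2]
    Wc = W.transpose(2, 0, 1, 3).reshape(-1, f)
    dW = col.reshape(-1, Wc.shape[0]).T @ dout.reshape(-1, f)
    dW = dW.reshape(c, kh, kw, f).transpose(1, 2, 0, 3)
    db = dout.sum(axis=(0, 1, 2))
    dcol = (dout @ Wc.T).reshape(n, oh, ow, c, kh, kw)
    dX = np.zeros(X_shape, dtype=np.float32)
    for a in range(kh):
        for bb in range(kw):
            dX[:, a : a + oh * stride : stride, bb : bb + ow * stride : stride, :] += dcol[:, :, :, :, a, bb]
    return dX, dW, db


def _pool_forward(X):
    n, h, w, c = X.shape
    oh, ow = h // 2, w // 2
    Xc = X[:, : oh * 2, : ow * 2, :].reshape(n, oh, 2, ow, 2, c)
    out = Xc.max(axis=(2, 4))
    mask = Xc == out[:, :, None, :, None, :]
    return out, (mask, X.shape)


def _pool_backward(dout, cache):
    mask, shape = cache
    n, h, w, c = shape
    oh, ow = h // 2, w // 2
    dX = np.zeros(shape, dtype=np.float32)
    dXc = mask * dout[:, :, None, :, None, :]
    dX[:, : oh * 2, : ow * 2, :] = dXc.reshape(n, oh * 2, ow * 2, c)
    return dX


class SmallCNNClassifier(BaseEstimator, ClassifierMixin):
    """Binary snapshot classifier:
    conv(1x1,16) - pool - pool - conv(3x3,16) - global max+avg pool - fc32 - fc1.

    Input images are converted to shading-invariant chromaticity+brightness
    channels and downsampled preserving per-block extremes (see
    ``_chroma_channels`` / ``_downsample``), giving 8 input channels. The
    1x1 first layer is a bank of learned per-pixel color detectors — in a
    CPK-colored depiction the element palette is a color code, so the
    discriminative cue is chromatic, not textural — and the global-pooling
    head makes the decision translation-invariant: a colored atom sphere
    counts wherever it appears in the frame.

    Training runs ``n_restarts`` independent seeded restarts and keeps the
    weights with the best validation ROC AUC (training loss when no
    validation set is given), mirroring monitor-and-select practice.

    Parameters
    ----------
    lr : peak Adam learning rate (cosine-decayed to zero over the epochs).
    batch_size : minibatch size.
    epochs : training epochs per restart.
    seed : RNG seed for weight init and shuffling.
    input_size : images are downsampled to this edge length.
    n_restarts : independent training restarts; best kept.

    Fitted attributes: ``params_`` (weight arrays), ``history_`` (per-epoch
    train loss / validation loss / validation accuracy of the selected
    restart, plus per-restart selection scores), ``classes_``.
    """

    def __init__(self, lr: float = 0.003, batch_size: int = 32, epochs: int = 120,
                 seed: int = 0, input_size: int = 64, n_restarts: int = 3):
        self.lr = lr
        self.batch_size = batch_size
        self.epochs = epochs
        self.seed = seed
        self.input_size = input_size
        self.n_restarts = n_restarts

    # -- architecture ------------------------------------------------------
    def _init_params(self, rng: np.random.RandomState) -> dict[str, np.ndarray]:
        if self.input_size // 4 - 2 < 1:
            raise ValueError(f"input_size {self.input_size} too small for the architecture")

        def he(shape, fan_in):
            return (rng.randn(*shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)

        return {
            "W1": he((1, 1, 8, 16), 8), "b1": np.zeros(16, np.float32),
            "W2": he((3, 3, 16, 16), 3 * 3 * 16), "b2": np.zeros(16, np.float32),
            "W3": he((32, 32), 32), "b3": np.zeros(32, np.float32),
            "W4": he((32, 1), 32), "b4": np.zeros(1, np.float32),
        }

    def _forward(self, X, params, cache=False):
        c1, col1 = _conv_forward(X, params["W1"], params["b1"], stride=1)
        a1 = np.maximum(c1, 0)
        q1, qc1 = _pool_forward(a1)
        p1, pc1 = _pool_forward(q1)
        c2, col2 = _conv_forward(p1, params["W2"], params["b2"], stride=1)
        a2 = np.maximum(c2, 0)
        # global max + average pooling over the spatial grid
        gmax = a2.max(axis=(1, 2))
        gavg = a2.mean(axis=(1, 2))
        flat = np.concatenate([gmax, gavg], axis=1)
        z3 = flat @ params["W3"] + params["b3"]
        a3 = np.maximum(z3, 0)
        z4 = a3 @ params["W4"] + params["b4"]
        prob = 1.0 / (1.0 + np.exp(-z4[:, 0]))
        if not cache:
            return prob
        return prob, (X, col1, c1, a1, qc1, q1, pc1, p1, col2, c2, a2, gmax, flat, z3, a3)

    def _backward(self, prob, y, cache, params):
        X, col1, c1, a1, qc1, q1, pc1, p1, col2, c2, a2, gmax, flat, z3, a3 = cache
        n = len(y)
        dz4 = ((prob - y) / n)[:, None].astype(np.float32)
        g = {}
        g["W4"] = a3.T @ dz4
        g["b4"] = dz4.sum(axis=0)
        da3 = dz4 @ params["W4"].T
        dz3 = da3 * (z3 > 0)
        g["W3"] = flat.T @ dz3
        g["b3"] = dz3.sum(axis=0)
        dflat = dz3 @ params["W3"].T
        dmax, davg = dflat[:, :16], dflat[:, 16:]
        spatial = a2.shape[1] * a2.shape[2]
        da2 = np.broadcast_to(
            (davg / spatial)[:, None, None, :], a2.shape
        ).astype(np.float32).copy()
        # route the max-pool gradient to the arg-max locations (ties split)
        maxmask = a2 == gmax[:, None, None, :]
        counts = maxmask.sum(axis=(1, 2), keepdims=True)
        da2 += maxmask * (dmax[:, None, None, :] / counts)
        dc2 = da2 * (c2 > 0)
        dp1, g["W2"], g["b2"] = _conv_backward(dc2, col2, p1.shape, params["W2"], stride=1)
        dq1 = _pool_backward(dp1, pc1)
        da1 = _pool_backward(dq1, qc1)
        dc1 = da1 * (c1 > 0)
        _, g["W1"], g["b1"] = _conv_backward(dc1, col1, X.shape, params["W1"], stride=1)
        return g

    # -- estimator API -----------------------------------------------------
    def _prepare(self, X) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 4 or X.shape[3] != 3:
            raise ValueError("X must be (n_images, height, width, 3)")
        return _downsample(_chroma_channels(X), self.input_size)

    def _train_once(self, Xp, yb, Xv, yv, seed):
        rng = np.random.RandomState(seed & 0x7FFFFFFF)
        params = self._init_params(rng)
        m = {k: np.zeros_like(v) for k, v in params.items()}
        v = {k: np.zeros_like(vv) for k, vv in params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        history = {"train_loss": [], "val_loss": [], "val_accuracy": []}

        for epoch in range(self.epochs):
            # cosine-decayed learning rate
            lr_t = self.lr * 0.5 * (1.0 + np.cos(np.pi * epoch / max(1, self.epochs)))
            order = rng.permutation(len(Xp))
            losses = []
            for start in range(0, len(Xp), self.batch_size):
                idx = order[start : start + self.batch_size]
                prob, cache = self._forward(Xp[idx], params, cache=True)
                p = np.clip(prob, 1e-7, 1 - 1e-7)
                losses.append(float(-np.mean(yb[idx] * np.log(p) + (1 - yb[idx]) * np.log(1 - p))))
                grads = self._backward(prob, yb[idx], cache, params)
                step += 1
                for k in params:
                    m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                    v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
                    mhat = m[k] / (1 - beta1 ** step)
                    vhat = v[k] / (1 - beta2 ** step)
                    params[k] = params[k] - lr_t * mhat / (np.sqrt(vhat) + eps)
            history["train_loss"].append(float(np.mean(losses)) if losses else float("nan"))
            if Xv is not None and len(Xv):
                pv = np.clip(self._forward(Xv, params), 1e-7, 1 - 1e-7)
                history["val_loss"].append(float(-np.mean(yv * np.log(pv) + (1 - yv) * np.log(1 - pv))))
                history["val_accuracy"].append(float(np.mean((pv >= 0.5) == yv)))

        # restart-selection score: validation ROC AUC, else -training loss
        if Xv is not None and len(Xv) and len(np.unique(yv)) == 2:
            score = float(roc_auc_score(yv, self._forward(Xv, params)))
        elif history["train_loss"]:
            score = -history["train_loss"][-1]
        else:
            score = 0.0
        return params, history, score

    def fit(self, X, y, X_val=None, y_val=None):
        """Train on images X (N, H, W, 3) with binary labels y.

        Runs ``n_restarts`` seeded restarts and keeps the best by validation
        ROC AUC (training loss without a validation set). The history of the
        selected restart records per-epoch training loss and, when a
        validation set is given, validation loss and accuracy.
        """
        Xp = self._prepare(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(f"need exactly two classes in y, got {list(self.classes_)}")
        yb = (y == self.classes_[1]).astype(np.float32)
        Xv = yv = None
        if X_val is not None:
            Xv = self._prepare(X_val)
            yv = (np.asarray(y_val) == self.classes_[1]).astype(np.float32)

        best = None
        scores = []
        for r in range(max(1, self.n_restarts)):
            params, history, score = self._train_once(Xp, yb, Xv, yv, self.seed + 1000 * r)
            scores.append(score)
            if best is None or score > best[2]:
                best = (params, history, score)

        self.params_, self.history_, _ = best
        self.history_["restart_scores"] = scores
        self.n_features_in_ = Xp.shape[1] * Xp.shape[2] * Xp.shape[3]
        self.input_shape_ = tuple(np.asarray(X).shape[1:])
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        X = np.asarray(X)
        if tuple(X.shape[1:]) != self.input_shape_ and len(X):
            raise ValueError(f"image shape {X.shape[1:]} differs from training shape {self.input_shape_}")
        if len(X) == 0:
            return np.zeros((0, 2))
        probs = []
        Xp = self._prepare(X)
        for start in range(0, len(Xp), 256):
            probs.append(self._forward(Xp[start : start + 256], self.params_))
        p1 = np.concatenate(probs)
        return np.column_stack([1 - p1, p1])

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[(proba[:, 1] >= 0.5).astype(int)]

    # -- persistence (plain arrays, no pickled code) -----------------------
    def save(self, path) -> None:
        check_is_fitted(self, "params_")
        meta = np.array([self.lr, self.batch_size, self.epochs, self.seed, self.input_size,
                         self.n_restarts])
        np.savez(
            path, _meta=meta, _classes=self.classes_,
            _input_shape=np.array(self.input_shape_), **self.params_,
        )

    @classmethod
    def load(cls, path) -> "SmallCNNClassifier":
        data = np.load(path, allow_pickle=False)
        meta = data["_meta"]
        est = cls(lr=float(meta[0]), batch_size=int(meta[1]), epochs=int(meta[2]),
                  seed=int(meta[3]), input_size=int(meta[4]),
                  n_restarts=int(meta[5]) if len(meta) > 5 else 1)
        est.params_ = {k: data[k] for k in data.files if not k.startswith("_")}
        est.classes_ = data["_classes"]
        est.input_shape_ = tuple(int(x) for x in data["_input_shape"])
        est.history_ = {"train_loss": [], "val_loss": [], "val_accuracy": []}
        return est
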