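"""A compact numpy implementation of the dual-branch 1D convolutional
network used by the dynamic branch.

Two input branches process the raw 12x128 pressure block and the raw
12x128 Euler-angle block independently.  Each branch stacks two
convolutional blocks (Conv1D -> batch normalization -> ReLU -> max pooling),
followed by global average pooling; the two branch embeddings are
concatenated and fed to a fully connected softmax layer with dropout 0.4.
Training uses categorical cross-entropy with Adam (learning rate 0.001,
batch size 64) and early stopping (patience 10, at most 100 epochs).

The network is deliberately small (16 filters, kernel 5, pool 2 per block
by default) and runs on a single CPU; it is an optional component of the
ensemble, enabled through the pipeline configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["DualBranchNetSpec", "DualBranchNet1D"]

_EPS = 1e-5


@dataclass(frozen=True)
class DualBranchNetSpec:
    n_filters: int = 16
    kernel: int = 5
    pool: int = 2
    dropout: float = 0.4
    lr: float = 1e-3
    batch_size: int = 64
    patience: int = 10
    max_epochs: int = 100
    val_fraction: float = 0.15


# ---------------------------------------------------------------------------
# layers (forward + backward as plain functions over parameter dicts)
# ---------------------------------------------------------------------------

def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """x (B,C,L), w (O,C,K) -> y (B,O,L-K+1); returns cache for backward."""
    xs = sliding_window_view(x, w.shape[2], axis=2)  # (B,C,Lout,K)
    y = np.einsum("bclk,ock->bol", xs, w, optimize=True) + b[None, :, None]
    return y, xs


def _conv_backward(dy: np.ndarray, xs: np.ndarray, w: np.ndarray):
    dw = np.einsum("bol,bclk->ock", dy, xs, optimize=True)
    db = dy.sum(axis=(0, 2))
    k = w.shape[2]
    dy_pad = np.pad(dy, ((0, 0), (0, 0), (k - 1, k - 1)))
    dys = sliding_window_view(dy_pad, k, axis=2)  # (B,O,Lin,K)
    dx = np.einsum("bolk,ock->bcl", dys, w[:, :, ::-1], optimize=True)
    return dx, dw, db


def _bn_forward(x, gamma, beta, running, training: bool, momentum=0.1):
    """Per-channel batchnorm over (B, L); running = [mean, var] arrays."""
    if training:
        mean = x.mean(axis=(0, 2))
        var = x.var(axis=(0, 2))
        running[0] = (1 - momentum) * running[0] + momentum * mean
        running[1] = (1 - momentum) * running[1] + momentum * var
    else:
        mean, var = running
    inv = 1.0 / np.sqrt(var + _EPS)
    xhat = (x - mean[None, :, None]) * inv[None, :, None]
    y = gamma[None, :, None] * xhat + beta[None, :, None]
    return y, (xhat, inv)


def _bn_backward(dy, cache, gamma):
    xhat, inv = cache
    m = dy.shape[0] * dy.shape[2]
    dgamma = (dy * xhat).sum(axis=(0, 2))
    dbeta = dy.sum(axis=(0, 2))
    dxhat = dy * gamma[None, :, None]
    dx = (inv[None, :, None] / m) * (
        m * dxhat
        - dxhat.sum(axis=(0, 2), keepdims=True)
        - xhat * (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
    )
    return dx, dgamma, dbeta


def _pool_forward(x, pool: int):
    b, c, l = x.shape
    l2 = l - l % pool
    xr = x[:, :, :l2].reshape(b, c, l2 // pool, pool)
    idx = xr.argmax(axis=3)
    return xr.max(axis=3), (idx, x.shape, pool)


def _pool_backward(dy, cache):
    idx, shape, pool = cache
    b, c, l = shape
    dx = np.zeros((b, c, l // pool, pool))
    np.put_along_axis(dx, idx[..., None], dy[..., None], axis=3)
    out = np.zeros(shape)
    out[:, :, : (l - l % pool)] = dx.reshape(b, c, -1)
    return out


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

class DualBranchNet1D:
    """Dual-branch 1D CNN classifier over (pressure, euler) raw windows."""

    def __init__(self, spec: DualBranchNetSpec = DualBranchNetSpec(),
                 seed: int = 0):
        self.spec = spec
        self.seed = seed
        self.params: dict[str, np.ndarray] = {}
        self.running: dict[str, list[np.ndarray]] = {}
        self.classes_: np.ndarray | None = None
        self._adam_m: dict[str, np.ndarray] = {}
        self._adam_v: dict[str, np.ndarray] = {}
        self._adam_t = 0
        self.history: list[dict[str, float]] = []

    # -- initialization ------------------------------------------------------

    def _init_params(self, in_channels: int, n_classes: int,
                     rng: np.random.Generator) -> None:
        f, k = self.spec.n_filters, self.spec.kernel

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), shape)

        for br in ("p", "e"):
            self.params[f"{br}_w1"] = he((f, in_channels, k), in_channels * k)
            self.params[f"{br}_b1"] = np.zeros(f)
            self.params[f"{br}_w2"] = he((f, f, k), f * k)
            self.params[f"{br}_b2"] = np.zeros(f)
            for blk in (1, 2):
                self.params[f"{br}_g{blk}"] = np.ones(f)
                self.params[f"{br}_be{blk}"] = np.zeros(f)
                self.running[f"{br}_{blk}"] = [np.zeros(f), np.ones(f)]
        self.params["fc_w"] = he((2 * f, n_classes), 2 * f)
        self.params["fc_b"] = np.zeros(n_classes)

    # -- forward -------------------------------------------------------------

    def _branch_forward(self, x, br: str, training: bool):
        p = self.params
        caches = []
        for blk in (1, 2):
            y, xs = _conv_forward(x, p[f"{br}_w{blk}"], p[f"{br}_b{blk}"])
            y, bn_cache = _bn_forward(y, p[f"{br}_g{blk}"], p[f"{br}_be{blk}"],
                                      self.running[f"{br}_{blk}"], training)
            mask = y > 0
            y = y * mask
            y, pool_cache = _pool_forward(y, self.spec.pool)
            caches.append((xs, bn_cache, mask, pool_cache))
            x = y
        gap = x.mean(axis=2)
        caches.append(x.shape[2])
        return gap, caches

    def _branch_backward(self, dgap, caches, br: str, grads):
        l_last = caches[-1]
        dy = np.repeat(dgap[:, :, None], l_last, axis=2) / l_last
        p = self.params
        for blk in (2, 1):
            xs, bn_cache, mask, pool_cache = caches[blk - 1]
            dy = _pool_backward(dy, pool_cache)
            dy = dy * mask
            dy, dg, dbe = _bn_backward(dy, bn_cache, p[f"{br}_g{blk}"])
            grads[f"{br}_g{blk}"] = dg
            grads[f"{br}_be{blk}"] = dbe
            dy, dw, db = _conv_backward(dy, xs, p[f"{br}_w{blk}"])
            grads[f"{br}_w{blk}"] = dw
            grads[f"{br}_b{blk}"] = db
        return dy

    def _forward(self, xp, xe, training: bool,
                 rng: np.random.Generator | None = None):
        gp, cp = self._branch_forward(xp, "p", training)
        ge, ce = self._branch_forward(xe, "e", training)
        h = np.concatenate([gp, ge], axis=1)
        if training and self.spec.dropout > 0:
            keep = 1.0 - self.spec.dropout
            drop_mask = (rng.random(h.shape) < keep) / keep
            h = h * drop_mask
        else:
            drop_mask = None
        logits = h @ self.params["fc_w"] + self.params["fc_b"]
        return logits, (cp, ce, h, drop_mask)

    @staticmethod
    def _softmax(logits):
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    # -- optimization --------------------------------------------------------

    def _adam_step(self, grads):
        lr, b1, b2, eps = self.spec.lr, 0.9, 0.999, 1e-8
        self._adam_t += 1
        t = self._adam_t
        for key, g in grads.items():
            m = self._adam_m.setdefault(key, np.zeros_like(g))
            v = self._adam_v.setdefault(key, np.zeros_like(g))
            m[:] = b1 * m + (1 - b1) * g
            v[:] = b2 * v + (1 - b2) * g * g
            mh = m / (1 - b1**t)
            vh = v / (1 - b2**t)
            self.params[key] -= lr * mh / (np.sqrt(vh) + eps)

    def _loss_and_grads(self, xp, xe, y_onehot, rng):
        logits, (cp, ce, h, drop_mask) = self._forward(xp, xe, True, rng)
        probs = self._softmax(logits)
        n = xp.shape[0]
        loss = -np.mean(np.sum(y_onehot * np.log(probs + 1e-12), axis=1))
        dlogits = (probs - y_onehot) / n
        grads = {
            "fc_w": h.T @ dlogits,
            "fc_b": dlogits.sum(axis=0),
        }
        dh = dlogits @ self.params["fc_w"].T
        if drop_mask is not None:
            dh = dh * drop_mask
        f = self.spec.n_filters
        self._branch_backward(dh[:, :f], cp, "p", grads)
        self._branch_backward(dh[:, f:], ce, "e", grads)
        return loss, grads

    # -- public API ----------------------------------------------------------

    def fit(self, pressure: np.ndarray, euler: np.ndarray, labels) -> "DualBranchNet1D":
        """Train on raw windows: pressure (n, 12, 128), euler (n, 12, 128)."""
        xp = np.asarray(pressure, dtype=float)
        xe = np.asarray(euler, dtype=float)
        y = np.asarray(labels)
        if xp.shape != xe.shape or xp.shape[0] != y.shape[0]:
            raise ValueError("misaligned inputs")
        self.classes_ = np.unique(y)
        n_classes = self.classes_.size
        y_idx = np.searchsorted(self.classes_, y)

        # per-channel standardization fitted on the training data
        self._mu_p = xp.mean(axis=(0, 2), keepdims=True)
        self._sd_p = xp.std(axis=(0, 2), keepdims=True) + 1e-9
        self._mu_e = xe.mean(axis=(0, 2), keepdims=True)
        self._sd_e = xe.std(axis=(0, 2), keepdims=True) + 1e-9
        xp = (xp - self._mu_p) / self._sd_p
        xe = (xe - self._mu_e) / self._sd_e

        rng = np.random.default_rng(self.seed)
        self._init_params(xp.shape[1], n_classes, rng)

        n = xp.shape[0]
        n_val = max(1, int(round(self.spec.val_fraction * n)))
        perm = rng.permutation(n)
        val, train = perm[:n_val], perm[n_val:]
        if train.size == 0:
            train, val = perm, perm
        onehot = np.eye(n_classes)[y_idx]

        best_loss = np.inf
        best_params = None
        patience_left = self.spec.patience
        for epoch in range(self.spec.max_epochs):
            order = rng.permutation(train)
            losses = []
            for start in range(0, order.size, self.spec.batch_size):
                idx = order[start:start + self.spec.batch_size]
                if idx.size < 2:
                    continue  # batchnorm needs more than one sample
                loss, grads = self._loss_and_grads(xp[idx], xe[idx],
                                                   onehot[idx], rng)
                self._adam_step(grads)
                losses.append(loss)
            val_probs = self._predict_std(xp[val], xe[val])
            val_loss = -np.mean(np.log(val_probs[np.arange(val.size),
                                                 y_idx[val]] + 1e-12))
            self.history.append({"epoch": epoch,
                                 "train_loss": float(np.mean(losses)),
                                 "val_loss": float(val_loss)})
            if val_loss < best_loss - 1e-5:
                best_loss = val_loss
                best_params = {k: v.copy() for k, v in self.params.items()}
                best_running = {k: [a.copy() for a in v]
                                for k, v in self.running.items()}
                patience_left = self.spec.patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break
        if best_params is not None:
            self.params = best_params
            self.running = best_running
        return self

    def _predict_std(self, xp, xe):
        logits, _ = self._forward(xp, xe, training=False)
        return self._softmax(logits)

    def predict_logits(self, pressure, euler) -> np.ndarray:
        if self.classes_ is None:
            raise ValueError("network is not trained")
        xp = (np.asarray(pressure, dtype=float) - self._mu_p) / self._sd_p
        xe = (np.asarray(euler, dtype=float) - self._mu_e) / self._sd_e
        logits, _ = self._forward(xp, xe, training=False)
        return logits

    def predict_proba(self, pressure, euler) -> np.ndarray:
        return self._softmax(self.predict_logits(pressure, euler))

    def predict(self, pressure, euler) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(pressure, euler),
                                       axis=1)]
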