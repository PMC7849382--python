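"""A small 1-D convolutional regressor implemented in numpy.

Architecture: conv1d (valid padding, ReLU) -> max-pool -> dropout -> dense
ReLU -> linear scalar output, trained with MSE, Adam, and early stopping on a
held-out validation split. Input is a length-L position axis with C channels
(here: 20 promoter bins x {cpg_ratio, meth_rate}).

Single-threaded numpy arithmetic makes fixed-seed runs reproducible to
floating-point exactness on a given platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Conv1DRegressor"]


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


@dataclass
class Conv1DRegressor:
    seq_len: int = 20
    n_channels: int = 2
    n_filters: int = 50
    kernel: int = 5
    pool: int = 4
    dropout: float = 0.2
    dense_units: int = 64
    lr: float = 1e-2
    lr_decay: float = 0.5  # reduce-on-plateau factor
    lr_patience: int = 3  # epochs without val improvement before decay
    min_lr: float = 1e-4
    batch_size: int = 64
    max_epochs: int = 200
    patience: int = 10
    val_frac: float = 0.1
    seed: int = 0

    params_: dict = field(default_factory=dict, repr=False)
    history_: list = field(default_factory=list, repr=False)

    # ---- layout -----------------------------------------------------------
    @property
    def conv_out(self) -> int:
        return self.seq_len - self.kernel + 1

    @property
    def pool_out(self) -> int:
        return self.conv_out // self.pool

    @property
    def flat_dim(self) -> int:
        return self.pool_out * self.n_filters

    def _reshape(self, X: np.ndarray) -> np.ndarray:
        """(n, seq_len * n_channels) flat layout -> (n, seq_len, n_channels)."""
        n = X.shape[0]
        return np.stack(
            [X[:, c * self.seq_len : (c + 1) * self.seq_len] for c in range(self.n_channels)],
            axis=2,
        ).reshape(n, self.seq_len, self.n_channels)

    def _im2col(self, Xs: np.ndarray) -> np.ndarray:
        """(n, L, C) -> (n, conv_out, kernel * C) sliding windows."""
        n = Xs.shape[0]
        cols = np.empty((n, self.conv_out, self.kernel * self.n_channels))
        for t in range(self.conv_out):
            cols[:, t, :] = Xs[:, t : t + self.kernel, :].reshape(n, -1)
        return cols

    def _init_params(self, rng: np.random.Generator) -> None:
        k_in = self.kernel * self.n_channels
        self.params_ = {
            "Wc": rng.normal(0, np.sqrt(2.0 / k_in), (k_in, self.n_filters)),
            "bc": np.zeros(self.n_filters),
            "W1": rng.normal(0, np.sqrt(2.0 / self.flat_dim), (self.flat_dim, self.dense_units)),
            "b1": np.zeros(self.dense_units),
            "W2": rng.normal(0, np.sqrt(1.0 / self.dense_units), (self.dense_units, 1)),
            "b2": np.zeros(1),
        }

    # ---- forward / backward ----------------------------------------------
    def _forward(self, X: np.ndarray, rng: np.random.Generator | None = None) -> tuple:
        """Returns (prediction, cache). ``rng`` enables (inverted) dropout."""
        p = self.params_
        cols = self._im2col(self._reshape(X))  # (n, T, kC)
        z_conv = cols @ p["Wc"] + p["bc"]  # (n, T, F)
        a_conv = _relu(z_conv)
        n, T, F = a_conv.shape
        P = self.pool_out
        windows = a_conv[:, : P * self.pool, :].reshape(n, P, self.pool, F)
        arg = windows.argmax(axis=2)  # (n, P, F)
        pooled = np.take_along_axis(windows, arg[:, :, None, :], axis=2)[:, :, 0, :]
        flat = pooled.reshape(n, -1)
        if rng is not None and self.dropout > 0:
            keep = (rng.random(flat.shape) >= self.dropout).astype(flat.dtype)
            flat_d = flat * keep / (1.0 - self.dropout)
        else:
            keep = None
            flat_d = flat
        z1 = flat_d @ p["W1"] + p["b1"]
        a1 = _relu(z1)
        out = (a1 @ p["W2"] + p["b2"]).ravel()
        cache = (cols, z_conv, arg, flat_d, keep, z1, a1)
        return out, cache

    def _backward(self, X: np.ndarray, y: np.ndarray, out: np.ndarray, cache) -> dict:
        p = self.params_
        cols, z_conv, arg, flat_d, keep, z1, a1 = cache
        n = X.shape[0]
        d_out = (2.0 / n) * (out - y)  # d MSE / d out
        gW2 = a1.T @ d_out[:, None]
        gb2 = np.array([d_out.sum()])
        d_a1 = d_out[:, None] @ p["W2"].T
        d_z1 = d_a1 * (z1 > 0)
        gW1 = flat_d.T @ d_z1
        gb1 = d_z1.sum(axis=0)
        d_flat = d_z1 @ p["W1"].T
        if keep is not None:
            d_flat = d_flat * keep / (1.0 - self.dropout)
        P, F = self.pool_out, self.n_filters
        d_pooled = d_flat.reshape(n, P, F)
        d_conv = np.zeros_like(z_conv)
        d_windows = d_conv[:, : P * self.pool, :].reshape(n, P, self.pool, F)
        np.put_along_axis(d_windows, arg[:, :, None, :], d_pooled[:, :, None, :], axis=2)
        d_conv[:, : P * self.pool, :] = d_windows.reshape(n, P * self.pool, F)
        d_conv *= z_conv > 0
        gWc = np.tensordot(cols, d_conv, axes=([0, 1], [0, 1]))
        gbc = d_conv.sum(axis=(0, 1))
        return {"Wc": gWc, "bc": gbc, "W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2}

    # ---- training ---------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "Conv1DRegressor":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).ravel()
        if X.shape[1] != self.seq_len * self.n_channels:
            raise ValueError(
                f"expected {self.seq_len * self.n_channels} columns, got {X.shape[1]}"
            )
        rng = np.random.default_rng(self.seed)
        self._init_params(rng)
        n = X.shape[0]
        n_val = max(1, int(round(self.val_frac * n))) if n >= 10 else 0
        perm = rng.permutation(n)
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        if len(train_idx) == 0:
            train_idx = perm
        Xt, yt = X[train_idx], y[train_idx]
        Xv, yv = X[val_idx], y[val_idx]

        adam_m = {k: np.zeros_like(v) for k, v in self.params_.items()}
        adam_v = {k: np.zeros_like(v) for k, v in self.params_.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        best_val = np.inf
        best_params = {k: v.copy() for k, v in self.params_.items()}
        stale = 0
        lr_stale = 0
        lr = self.lr
        self.history_ = []

        for epoch in range(self.max_epochs):
            order = rng.permutation(len(Xt))
            for start in range(0, len(Xt), self.batch_size):
                batch = order[start : start + self.batch_size]
                out, cache = self._forward(Xt[batch], rng=rng)
                grads = self._backward(Xt[batch], yt[batch], out, cache)
                step += 1
                for k in self.params_:
                    adam_m[k] = beta1 * adam_m[k] + (1 - beta1) * grads[k]
                    adam_v[k] = beta2 * adam_v[k] + (1 - beta2) * grads[k] ** 2
                    m_hat = adam_m[k] / (1 - beta1**step)
                    v_hat = adam_v[k] / (1 - beta2**step)
                    self.params_[k] -= lr * m_hat / (np.sqrt(v_hat) + eps)
            monitor_X, monitor_y = (Xv, yv) if n_val else (Xt, yt)
            val_pred = self.predict(monitor_X)
            val_mse = float(np.mean((val_pred - monitor_y) ** 2))
            if not np.isfinite(val_mse):
                raise FloatingPointError(
                    f"non-finite validation loss at epoch {epoch}; "
                    "inputs may be unscaled or learning rate too high"
                )
            self.history_.append(val_mse)
            if val_mse < best_val - 1e-12:
                best_val = val_mse
                best_params = {k: v.copy() for k, v in self.params_.items()}
                stale = 0
                lr_stale = 0
            else:
                stale += 1
                lr_stale += 1
                if stale >= self.patience:
                    break
                if lr_stale >= self.lr_patience and lr > self.min_lr:
                    lr = max(lr * self.lr_decay, self.min_lr)
                    lr_stale = 0
        self.params_ = best_params
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        out = np.empty(X.shape[0])
        for start in range(0, X.shape[0], 4096):
            chunk = X[start : start + 4096]
            out[start : start + len(chunk)], _ = self._forward(chunk, rng=None)
        return out

    # ---- (de)serialization ------------------------------------------------
    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params_.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        self.params_ = {k: np.asarray(v, dtype=np.float64) for k, v in weights.items()}
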