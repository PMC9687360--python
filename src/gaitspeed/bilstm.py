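"""A small bidirectional LSTM sequence classifier, implemented in NumPy.

The network is deliberately minimal — the architecture the task needs and
nothing more: one LSTM layer per direction, the two final hidden states
concatenated and passed through a dense softmax layer. Training is
mini-batch Adam on the mean cross-entropy, with optional early stopping on
a training-loss plateau. Forward and backward passes are exact
(backpropagation through time), verified against numerical gradients in
the test suite. Everything is deterministic given the seed.

Shapes: inputs are ``(batch, time, channels)``; hidden size ``H`` is per
direction, so the classifier head sees ``2H`` features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BiLSTMNet", "TrainSettings"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape: tuple) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


@dataclass
class TrainSettings:
    """Optimization settings for :meth:`BiLSTMNet.fit`."""

    learning_rate: float = 1e-3
    batch_size: int = 16
    max_epochs: int = 100
    early_stop_patience: int = 5
    early_stop_tol: float = 1e-4
    shuffle: bool = True
    clip_norm: float | None = 2.0  # global gradient-norm clip; None disables


class _LSTMDirection:
    """One direction's parameters: W (D,4H), U (H,4H), b (4H); gate order i,f,g,o."""

    def __init__(self, input_dim: int, hidden: int, rng: np.random.Generator):
        self.h = hidden
        self.W = _glorot(rng, input_dim + hidden, 4 * hidden, (input_dim, 4 * hidden))
        self.U = _glorot(rng, input_dim + hidden, 4 * hidden, (hidden, 4 * hidden))
        self.b = np.zeros(4 * hidden)
        self.b[hidden : 2 * hidden] = 1.0  # forget-gate bias

    def params(self) -> list[np.ndarray]:
        return [self.W, self.U, self.b]

    def forward(self, xs: np.ndarray):
        """xs: (T, B, D) -> final hidden state (B, H) plus cache for BPTT."""
        t_len, b, d = xs.shape
        hsz = self.h
        hs = np.zeros((t_len + 1, b, hsz))
        cs = np.zeros((t_len + 1, b, hsz))
        gates = np.zeros((t_len, b, 4 * hsz))
        # input projection for all timesteps in one matmul
        xw = (xs.reshape(t_len * b, d) @ self.W).reshape(t_len, b, 4 * hsz) + self.b
        for t in range(t_len):
            z = xw[t] + hs[t] @ self.U
            gt = gates[t]
            gt[:, : 2 * hsz] = _sigmoid(z[:, : 2 * hsz])
            gt[:, 2 * hsz : 3 * hsz] = np.tanh(z[:, 2 * hsz : 3 * hsz])
            gt[:, 3 * hsz :] = _sigmoid(z[:, 3 * hsz :])
            np.multiply(gt[:, hsz : 2 * hsz], cs[t], out=cs[t + 1])
            cs[t + 1] += gt[:, :hsz] * gt[:, 2 * hsz : 3 * hsz]
            np.multiply(gt[:, 3 * hsz :], np.tanh(cs[t + 1]), out=hs[t + 1])
        return hs[-1], (xs, hs, cs, gates)

    def backward(self, cache, dh_last: np.ndarray, dh_every: np.ndarray | None = None):
        """Parameter gradients given d(loss)/d(hidden state).

        ``dh_last`` is injected at the final step (last-state readout);
        ``dh_every``, when given, is additionally injected at every step
        (mean-pooled readout passes the same dL/dh / T to all steps).
        """
        xs, hs, cs, gates = cache
        t_len, b, _ = xs.shape
        hsz = self.h
        dz_all = np.zeros((t_len, b, 4 * hsz))
        dh = dh_last.copy()
        if dh_every is not None:
            dh += dh_every
        dc = np.zeros((b, hsz))
        for t in range(t_len - 1, -1, -1):
            i = gates[t][:, :hsz]
            f = gates[t][:, hsz : 2 * hsz]
            g = gates[t][:, 2 * hsz : 3 * hsz]
            o = gates[t][:, 3 * hsz :]
            tc = np.tanh(cs[t + 1])
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            dz = dz_all[t]
            np.multiply(dc * g, i * (1.0 - i), out=dz[:, :hsz])
            np.multiply(dc * cs[t], f * (1.0 - f), out=dz[:, hsz : 2 * hsz])
            np.multiply(dc * i, 1.0 - g * g, out=dz[:, 2 * hsz : 3 * hsz])
            np.multiply(do, o * (1.0 - o), out=dz[:, 3 * hsz :])
            dh = dz @ self.U.T
            if dh_every is not None and t > 0:
                dh = dh + dh_every
            dc = dc * f
        flat_x = xs.reshape(t_len * b, -1)
        flat_h = hs[:-1].reshape(t_len * b, hsz)
        flat_dz = dz_all.reshape(t_len * b, 4 * hsz)
        return [flat_x.T @ flat_dz, flat_h.T @ flat_dz, flat_dz.sum(axis=0)]


class BiLSTMNet:
    """Bidirectional LSTM + dense softmax classifier over fixed-length sequences.

    ``pool`` selects the sequence readout: ``"mean"`` (default) averages the
    hidden states over time, which keeps gradients flowing to every step
    and trains reliably on long sequences; ``"last"`` concatenates the two
    directions' final states, the textbook readout.
    """

    def __init__(
        self, input_dim: int, hidden: int, n_classes: int, seed: int = 0, pool: str = "mean"
    ):
        if hidden < 1 or n_classes < 2:
            raise ValueError("need hidden >= 1 and n_classes >= 2")
        if pool not in ("mean", "last"):
            raise ValueError(f"unknown pool mode: {pool!r}")
        rng = np.random.default_rng(seed)
        self.input_dim = input_dim
        self.hidden = hidden
        self.n_classes = n_classes
        self.pool = pool
        self.fwd = _LSTMDirection(input_dim, hidden, rng)
        self.bwd = _LSTMDirection(input_dim, hidden, rng)
        self.Wd = _glorot(rng, 2 * hidden, n_classes, (2 * hidden, n_classes))
        self.bd = np.zeros(n_classes)

    # -- inference ---------------------------------------------------------

    def _params(self) -> list[np.ndarray]:
        return self.fwd.params() + self.bwd.params() + [self.Wd, self.bd]

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """x: (B, T, D) -> class probabilities (B, n_classes)."""
        probs, _ = self._forward(np.asarray(x, dtype=float))
        return probs

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    def _forward(self, x: np.ndarray):
        xs = np.transpose(x, (1, 0, 2))  # (T, B, D)
        h_f, cache_f = self.fwd.forward(xs)
        h_b, cache_b = self.bwd.forward(xs[::-1])
        if self.pool == "mean":
            z = np.concatenate(
                [cache_f[1][1:].mean(axis=0), cache_b[1][1:].mean(axis=0)], axis=1
            )
        else:
            z = np.concatenate([h_f, h_b], axis=1)
        probs = _softmax(z @ self.Wd + self.bd)
        return probs, (cache_f, cache_b, z)

    # -- training ----------------------------------------------------------

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        """Mean cross-entropy and exact gradients for one batch."""
        probs, (cache_f, cache_b, z) = self._forward(x)
        b = x.shape[0]
        eps = 1e-12
        loss = -float(np.mean(np.log(probs[np.arange(b), y] + eps)))
        dlogits = probs.copy()
        dlogits[np.arange(b), y] -= 1.0
        dlogits /= b
        d_wd = z.T @ dlogits
        d_bd = dlogits.sum(axis=0)
        dz = dlogits @ self.Wd.T
        if self.pool == "mean":
            t_len = x.shape[1]
            zero = np.zeros((x.shape[0], self.hidden))
            grads_f = self.fwd.backward(cache_f, zero, dz[:, : self.hidden] / t_len)
            grads_b = self.bwd.backward(cache_b, zero, dz[:, self.hidden :] / t_len)
        else:
            grads_f = self.fwd.backward(cache_f, dz[:, : self.hidden])
            grads_b = self.bwd.backward(cache_b, dz[:, self.hidden :])
        return loss, grads_f + grads_b + [d_wd, d_bd]

    def fit(self, x: np.ndarray, y: np.ndarray, settings: TrainSettings, seed: int = 0) -> list[float]:
        """Adam on mini-batches; returns the per-epoch mean training loss."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=int)
        n = x.shape[0]
        rng = np.random.default_rng(seed)
        params = self._params()
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        history: list[float] = []
        best = np.inf
        stale = 0
        bs = min(settings.batch_size, n) if settings.batch_size else n
        for _epoch in range(settings.max_epochs):
            order = rng.permutation(n) if settings.shuffle else np.arange(n)
            losses = []
            for start in range(0, n, bs):
                idx = order[start : start + bs]
                loss, grads = self.loss_and_grads(x[idx], y[idx])
                losses.append(loss)
                if settings.clip_norm is not None:
                    gnorm = np.sqrt(sum(float((g * g).sum()) for g in grads))
                    if gnorm > settings.clip_norm:
                        grads = [g * (settings.clip_norm / gnorm) for g in grads]
                step += 1
                for p, g, mi, vi in zip(params, grads, m, v):
                    mi *= beta1
                    mi += (1 - beta1) * g
                    vi *= beta2
                    vi += (1 - beta2) * g * g
                    m_hat = mi / (1 - beta1**step)
                    v_hat = vi / (1 - beta2**step)
                    p -= settings.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
            epoch_loss = float(np.mean(losses))
            history.append(epoch_loss)
            if best - epoch_loss > settings.early_stop_tol:
                best = epoch_loss
                stale = 0
            else:
                stale += 1
                if stale >= settings.early_stop_patience:
                    break
        return history
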