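"""A compact multilayer perceptron with one or more softmax output heads.

Architecture: standardized inputs, fully-connected ReLU hidden layers with
inverted dropout, and one softmax head per categorical output sharing the
hidden trunk.  Trained with Adam on the sum of per-head cross-entropies plus
L2 weight decay; when a validation set is supplied, training stops early on
stalled validation loss and the best weights are restored.  Deterministic
given the seed.
"""

from __future__ import annotations

import numpy as np


def _relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class MultiHeadMLP:
    """Shared-trunk MLP with H softmax heads (H=1 gives a plain classifier).

    Parameters
    ----------
    hidden_layer_sizes : trunk widths, default (64, 32)
    dropout : inverted-dropout rate on hidden activations during training
    epochs, batch_size, learning_rate, weight_decay : Adam training schedule
    patience : early-stopping patience (epochs) when a validation set is given
    """

    def __init__(
        self,
        hidden_layer_sizes: tuple[int, ...] = (64, 32),
        dropout: float = 0.3,
        epochs: int = 300,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        weight_decay: float = 1e-4,
        patience: int = 25,
        seed: int = 0,
    ) -> None:
        self.hidden_layer_sizes = tuple(hidden_layer_sizes)
        self.dropout = float(dropout)
        self.epochs = int(epochs)
        self.batch_size = int(batch_size)
        self.learning_rate = float(learning_rate)
        self.weight_decay = float(weight_decay)
        self.patience = int(patience)
        self.seed = int(seed)

    # ------------------------------------------------------------------ fit

    def fit(self, X, y, X_val=None, y_val=None) -> "MultiHeadMLP":
        rng = np.random.default_rng(self.seed)
        X = np.asarray(X, dtype=float)
        Y = np.asarray(y)
        self._single_head = Y.ndim == 1
        if self._single_head:
            Y = Y[:, None]
        n, p = X.shape
        n_heads = Y.shape[1]

        self.classes_ = [np.unique(Y[:, h]) for h in range(n_heads)]
        y_idx = np.column_stack(
            [np.searchsorted(self.classes_[h], Y[:, h]) for h in range(n_heads)]
        )

        self._mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        self._sd = sd
        Xs = (X - self._mu) / self._sd

        have_val = X_val is not None and len(np.asarray(X_val)) > 0
        if have_val:
            Xv = (np.asarray(X_val, dtype=float) - self._mu) / self._sd
            Yv = np.asarray(y_val)
            if Yv.ndim == 1:
                Yv = Yv[:, None]
            yv_idx = np.column_stack(
                [np.searchsorted(self.classes_[h], Yv[:, h])
                 for h in range(n_heads)]
            )

        dims = [p, *self.hidden_layer_sizes]
        self._W = [
            rng.normal(0.0, np.sqrt(2.0 / dims[i]), size=(dims[i], dims[i + 1]))
            for i in range(len(dims) - 1)
        ]
        self._b = [np.zeros(d) for d in dims[1:]]
        self._Wh = [
            rng.normal(0.0, np.sqrt(2.0 / dims[-1]),
                       size=(dims[-1], len(self.classes_[h])))
            for h in range(n_heads)
        ]
        self._bh = [np.zeros(len(self.classes_[h])) for h in range(n_heads)]

        params = self._W + self._b + self._Wh + self._bh
        m = [np.zeros_like(q) for q in params]
        v = [np.zeros_like(q) for q in params]
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = 0

        best_loss, best_state, wait = np.inf, None, 0
        batch = max(2, min(self.batch_size, n))

        for _epoch in range(self.epochs):
            perm = rng.permutation(n)
            for start in range(0, n, batch):
                idx = perm[start:start + batch]
                grads = self._backward(Xs[idx], y_idx[idx], rng)
                t += 1
                lr_t = self.learning_rate * np.sqrt(1 - b2**t) / (1 - b1**t)
                for q, g, mi, vi in zip(params, grads, m, v):
                    mi += (1 - b1) * (g - mi)
                    vi += (1 - b2) * (g * g - vi)
                    q -= lr_t * mi / (np.sqrt(vi) + eps)
            if have_val:
                vl = self._loss(Xv, yv_idx)
                if vl < best_loss - 1e-6:
                    best_loss, wait = vl, 0
                    best_state = [q.copy() for q in params]
                else:
                    wait += 1
                    if wait > self.patience:
                        break
        if have_val and best_state is not None:
            for q, s in zip(params, best_state):
                q[...] = s
        return self

    # -------------------------------------------------------------- forward

    def _forward(self, Xs, rng=None):
        acts = [Xs]
        a = Xs
        masks = []
        for W, b in zip(self._W, self._b):
            a = _relu(a @ W + b)
            if rng is not None and self.dropout > 0:
                mask = (rng.random(a.shape) >= self.dropout) / (1 - self.dropout)
                a = a * mask
                masks.append(mask)
            acts.append(a)
        probs = [_softmax(a @ Wh + bh) for Wh, bh in zip(self._Wh, self._bh)]
        return acts, masks, probs

    def _loss(self, Xs, y_idx) -> float:
        _, _, probs = self._forward(Xs)
        total = 0.0
        for h, ph in enumerate(probs):
            pt = np.clip(ph[np.arange(len(Xs)), y_idx[:, h]], 1e-12, None)
            total -= float(np.mean(np.log(pt)))
        return total

    def _backward(self, Xb, yb_idx, rng):
        B = len(Xb)
        acts, masks, probs = self._forward(Xb, rng=rng)
        a_last = acts[-1]

        gWh, gbh = [], []
        d_last = np.zeros_like(a_last)
        for h, ph in enumerate(probs):
            delta = ph.copy()
            delta[np.arange(B), yb_idx[:, h]] -= 1.0
            delta /= B
            gWh.append(a_last.T @ delta + self.weight_decay * self._Wh[h])
            gbh.append(delta.sum(axis=0))
            d_last += delta @ self._Wh[h].T

        gW = [None] * len(self._W)
        gb = [None] * len(self._b)
        d = d_last
        for layer in range(len(self._W) - 1, -1, -1):
            if masks:
                # where the mask dropped a unit d is zeroed, so the post-dropout
                # activation is a valid ReLU gate for the surviving units
                d = d * masks[layer]
            d = d * (acts[layer + 1] > 0)
            gW[layer] = acts[layer].T @ d + self.weight_decay * self._W[layer]
            gb[layer] = d.sum(axis=0)
            if layer > 0:
                d = d @ self._W[layer].T
        return gW + gb + gWh + gbh

    # -------------------------------------------------------------- predict

    def predict_proba(self, X) -> list[np.ndarray]:
        Xs = (np.asarray(X, dtype=float) - self._mu) / self._sd
        _, _, probs = self._forward(Xs)
        return probs

    def predict(self, X):
        probs = self.predict_proba(X)
        cols = [self.classes_[h][np.argmax(ph, axis=1)]
                for h, ph in enumerate(probs)]
        if self._single_head:
            return cols[0]
        return np.column_stack(cols)
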