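"""Sequential model container, loss, and the Adam optimizer.

Models output *logits*; the softmax is folded into the loss for
numerical stability and applied explicitly in ``predict_proba``.
Per-position (FCN) outputs of shape (N, W, K) are supported throughout:
the subject label is broadcast to every position, and an optional
position weight (e.g. the availability mask) can weight the loss.
"""

from __future__ import annotations

import numpy as np

from trajheat.nn.layers import Conv1D, Dense, Layer

__all__ = ["softmax", "softmax_cross_entropy", "Adam", "Sequential"]


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray,
                          position_weights: np.ndarray | None = None):
    """Mean cross-entropy and its gradient w.r.t. the logits.

    ``logits`` is (N, K) or (N, W, K); ``labels`` is (N,) integer class
    ids (broadcast over positions for 3-D logits).  ``position_weights``
    (N, W) optionally reweights positions; zero-weight inputs fall back
    to uniform weighting to keep the loss defined.
    """
    p = softmax(logits)
    labels = np.asarray(labels, dtype=int)
    if logits.ndim == 2:
        n = logits.shape[0]
        picked = p[np.arange(n), labels]
        loss = float(-np.log(np.maximum(picked, 1e-12)).mean())
        grad = p.copy()
        grad[np.arange(n), labels] -= 1.0
        grad /= n
        return loss, grad
    n, w, k = logits.shape
    onehot = np.zeros((n, 1, k))
    onehot[np.arange(n), 0, labels] = 1.0
    if position_weights is None:
        wts = np.full((n, w), 1.0 / (n * w))
    else:
        pw = np.asarray(position_weights, dtype=float)
        total = pw.sum()
        wts = pw / total if total > 0 else np.full((n, w), 1.0 / (n * w))
    picked = np.take_along_axis(p, labels[:, None, None], axis=2)[:, :, 0]
    loss = float(-(wts * np.log(np.maximum(picked, 1e-12))).sum())
    grad = (p - onehot) * wts[:, :, None]
    return loss, grad


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 0.001, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7):
        self.params, self.grads = params, grads
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0


class Sequential:
    """A feed-forward stack of layers ending in logits."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    @property
    def params(self) -> list[np.ndarray]:
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for l in self.layers for g in l.grads]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x))

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0

    # -- pieces used by Grad-CAM ------------------------------------
    def forward_collect(self, x: np.ndarray) -> list[np.ndarray]:
        """Forward pass returning every layer's output (last = logits)."""
        outs = []
        for l in self.layers:
            x = l.forward(x)
            outs.append(x)
        return outs

    def backward_to(self, grad: np.ndarray, layer_index: int) -> np.ndarray:
        """Backprop an output-side gradient down to the *output* of
        ``layers[layer_index]`` (forward must have just been run)."""
        for l in reversed(self.layers[layer_index + 1:]):
            grad = l.backward(grad)
        return grad

    def reinitialize(self, rng: np.random.Generator) -> "Sequential":
        """Fresh copy with the same architecture and new random weights."""
        import copy

        other = copy.deepcopy(self)
        for l in other.layers:
            if isinstance(l, Conv1D):
                fan_in = l.in_channels * l.kernel_size
                from trajheat.nn.layers import glorot_uniform

                l.W[...] = glorot_uniform(rng, fan_in, l.out_channels, l.W.shape)
                l.b[...] = 0.0
            elif isinstance(l, Dense):
                from trajheat.nn.layers import glorot_uniform

                l.W[...] = glorot_uniform(rng, l.W.shape[0], l.W.shape[1], l.W.shape)
                l.b[...] = 0.0
        return other

    # -- training ----------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray, *, epochs: int, batch_size: int = 32,
            lr: float = 0.001, seed: int = 0,
            position_weights: np.ndarray | None = None,
            validation: tuple[np.ndarray, np.ndarray] | None = None) -> dict:
        """Train with Adam on softmax cross-entropy.

        Samples are first brought into a canonical order (lexicographic
        by label then input bytes), so training is invariant to the
        order in which the dataset was assembled; epoch shuffles then
        come from a generator seeded with ``seed``.  Raises on NaN loss.

        Returns a history dict with per-epoch ``loss`` and ``accuracy``
        (and ``val_loss``/``val_accuracy`` when a validation set is given).
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        order = np.lexsort(np.vstack([X.reshape(len(X), -1).T, y]))
        X, y = X[order], y[order]
        pw = position_weights[order] if position_weights is not None else None

        rng = np.random.default_rng(seed)
        opt = Adam(self.params, self.grads, lr=lr)
        history: dict[str, list[float]] = {"loss": [], "accuracy": []}
        if validation is not None:
            history["val_loss"] = []
            history["val_accuracy"] = []
        n = len(X)
        for epoch in range(epochs):
            perm = rng.permutation(n)
            losses, correct, seen = [], 0, 0
            for start in range(0, n, batch_size):
                idx = perm[start:start + batch_size]
                xb, yb = X[idx], y[idx]
                wb = pw[idx] if pw is not None else None
                logits = self.forward(xb)
                loss, grad = softmax_cross_entropy(logits, yb, wb)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}: {loss}; "
                        "check input scaling and learning rate"
                    )
                opt.zero_grad()
                self.backward(grad)
                opt.step()
                losses.append(loss * len(idx))
                pred = self._subject_pred(logits)
                correct += int((pred == yb).sum())
                seen += len(idx)
            history["loss"].append(float(np.sum(losses) / seen))
            history["accuracy"].append(correct / seen)
            if validation is not None:
                xv, yv = validation
                logits = self.forward(xv)
                vloss, _ = softmax_cross_entropy(logits, yv)
                history["val_loss"].append(vloss)
                history["val_accuracy"].append(
                    float((self._subject_pred(logits) == yv).mean()))
        return history

    @staticmethod
    def _subject_pred(logits: np.ndarray) -> np.ndarray:
        """Subject-level argmax: per-position outputs are averaged
        (probability mean over positions) before the argmax."""
        if logits.ndim == 3:
            return softmax(logits).mean(axis=1).argmax(axis=1)
        return logits.argmax(axis=1)
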