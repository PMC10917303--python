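"""Minimal feedforward networks for the geometry surrogates.

Two hidden tanh layers, trained with Adam on a mean-squared-error loss.
The implementation is deliberately small and self-contained: the
forward pass must be evaluable with complex inputs (for complex-step
differentiation through a trained surrogate) and must expose analytic
input gradients of a designated output (the muscle-tendon length head,
whose pose gradient supplies muscle-tendon velocities), which rules out
off-the-shelf estimators' opaque predict paths.  Training is exactly
reproducible for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MLP", "train_mlp"]


@dataclass
class MLP:
    """weights[i], biases[i] for layers i = 0, 1, 2 (two hidden + linear out)."""

    weights: list
    biases: list
    loss_curve: np.ndarray | None = None

    def forward(self, x):
        """x (..., n_in) -> (..., n_out); complex-safe."""
        h = x
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.tanh(h @ w + b)
        return h @ self.weights[-1] + self.biases[-1]

    def forward_with_input_grad(self, x, output_index: int = 0):
        """(outputs, d outputs[output_index] / d x) by analytic backprop."""
        h = x
        hs = [h]
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.tanh(h @ w + b)
            hs.append(h)
        out = h @ self.weights[-1] + self.biases[-1]
        # backprop a unit seed on the selected output
        g = self.weights[-1][:, output_index]
        g = np.broadcast_to(g, hs[-1].shape).copy()
        for i in range(len(self.weights) - 2, -1, -1):
            g = (g * (1.0 - hs[i + 1] ** 2)) @ self.weights[i].T
        return out, g


def _init_params(sizes, rng):
    ws, bs = [], []
    for n_in, n_out in zip(sizes[:-1], sizes[1:]):
        limit = np.sqrt(6.0 / (n_in + n_out))
        ws.append(rng.uniform(-limit, limit, (n_in, n_out)))
        bs.append(np.zeros(n_out))
    return ws, bs


def train_mlp(X, Y, hidden: int, epochs: int, batch_size: int, seed: int,
              lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8,
              lr_decay: tuple = (0.7, 0.2)) -> MLP:
    """Adam on MSE; two hidden layers of the given width; deterministic.

    ``lr_decay = (frac, factor)`` drops the learning rate to
    ``factor * lr`` after ``frac`` of the epochs (step decay), the usual
    refinement phase for small regression networks."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    n, n_in = X.shape
    n_out = Y.shape[1]
    rng = np.random.default_rng(seed)
    ws, bs = _init_params([n_in, hidden, hidden, n_out], rng)
    m_w = [np.zeros_like(w) for w in ws]
    v_w = [np.zeros_like(w) for w in ws]
    m_b = [np.zeros_like(b) for b in bs]
    v_b = [np.zeros_like(b) for b in bs]
    b1, b2 = betas
    t = 0
    losses = np.empty(epochs)
    for epoch in range(epochs):
        lr_t = lr if epoch < lr_decay[0] * epochs else lr * lr_decay[1]
        order = rng.permutation(n)
        ep_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb, yb = X[idx], Y[idx]
            # forward
            hs = [xb]
            h = xb
            for w, b in zip(ws[:-1], bs[:-1]):
                h = np.tanh(h @ w + b)
                hs.append(h)
            pred = h @ ws[-1] + bs[-1]
            err = pred - yb
            ep_loss += float(np.sum(err**2))
            # backward
            g = 2.0 * err / (len(idx) * n_out)
            grads_w, grads_b = [None] * len(ws), [None] * len(bs)
            for i in range(len(ws) - 1, -1, -1):
                grads_w[i] = hs[i].T @ g
                grads_b[i] = g.sum(axis=0)
                if i > 0:
                    g = (g @ ws[i].T) * (1.0 - hs[i] ** 2)
            # adam
            t += 1
            corr1 = 1.0 - b1**t
            corr2 = 1.0 - b2**t
            for i in range(len(ws)):
                m_w[i] = b1 * m_w[i] + (1 - b1) * grads_w[i]
                v_w[i] = b2 * v_w[i] + (1 - b2) * grads_w[i] ** 2
                ws[i] -= lr_t * (m_w[i] / corr1) / (np.sqrt(v_w[i] / corr2) + eps)
                m_b[i] = b1 * m_b[i] + (1 - b1) * grads_b[i]
                v_b[i] = b2 * v_b[i] + (1 - b2) * grads_b[i] ** 2
                bs[i] -= lr_t * (m_b[i] / corr1) / (np.sqrt(v_b[i] / corr2) + eps)
        losses[epoch] = ep_loss / (n * n_out)
        if not np.isfinite(losses[epoch]):
            raise FloatingPointError(
                f"non-finite training loss at epoch {epoch}: {losses[epoch]}")
    return MLP(weights=ws, biases=bs, loss_curve=losses)
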