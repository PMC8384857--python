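"""A small feedforward energy regressor with hand-written differentiation.

The network maps a flat coordinate vector to a scalar energy through softplus
hidden layers and a linear output.  Three derivative routines are provided,
all vectorized over a batch:

``param_grads``
    reverse-mode gradients of the energy/force-matching loss with respect to
    the weights (training);
``input_grad``
    dE/dx, whose negative is the predicted force (smooth because softplus is
    smooth);
``dgrad``
    reverse-over-forward differentiation of the directional derivative
    (dE/dx) . c.  Its input part is the Hessian-vector product H c needed by
    attack gradients through the force variance; its parameter part is the
    force-matching contribution to training gradients.

Everything is float64 numpy; determinism follows from the construction seed.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import expit as _sigmoid

__all__ = ["MLP", "Adam", "softplus"]


def softplus(z: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, z)


def softplus_and_sigmoid(z: np.ndarray):
    """Stable softplus(z) and logistic(z) sharing a single exponential."""
    e = np.exp(-np.abs(z))
    sp = np.maximum(z, 0.0) + np.log1p(e)
    one_plus = 1.0 + e
    sig = np.where(z >= 0.0, 1.0 / one_plus, e / one_plus)
    return sp, sig


class MLP:
    """Feedforward scalar regressor: softplus hidden layers, linear output."""

    def __init__(self, n_inputs: int, hidden: Sequence[int], seed: int = 0):
        sizes = [int(n_inputs)] + [int(h) for h in hidden] + [1]
        rng = np.random.default_rng(seed)
        self.W: List[np.ndarray] = []
        self.b: List[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            bound = np.sqrt(6.0 / (fan_in + fan_out))
            self.W.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))
        self.sizes = sizes

    # ----------------------------------------------------------- forward

    def _forward(self, X: np.ndarray):
        """Activations and pre-activations for a (N, d) batch."""
        a = [np.atleast_2d(np.asarray(X, float))]
        zs = []
        for W, b in zip(self.W[:-1], self.b[:-1]):
            z = a[-1] @ W + b
            zs.append(z)
            a.append(softplus(z))
        E = (a[-1] @ self.W[-1] + self.b[-1]).ravel()
        return E, a, zs

    def energy(self, X: np.ndarray) -> np.ndarray:
        """Predicted energies, shape (N,)."""
        return self._forward(X)[0]

    def input_grad(self, X: np.ndarray) -> np.ndarray:
        """dE/dx for each sample, shape (N, d); forces are its negative."""
        _, a, zs = self._forward(X)
        bar = np.repeat(self.W[-1].T, a[0].shape[0], axis=0)  # (N, h)
        for W, z in zip(reversed(self.W[:-1]), reversed(zs)):
            bar = (bar * _sigmoid(z)) @ W.T
        return bar

    # ---------------------------------------------------------- training

    def param_grads(
        self,
        X: np.ndarray,
        E_target: np.ndarray,
        F_target: Optional[np.ndarray] = None,
        alpha_E: float = 1.0,
        alpha_F: float = 0.0,
    ) -> Tuple[float, List[np.ndarray], List[np.ndarray]]:
        """Batch loss (1/N) sum [alpha_E ||E - Ehat||^2 + alpha_F ||F - Fhat||^2]
        and its parameter gradients.
        """
        X = np.atleast_2d(np.asarray(X, float))
        N = X.shape[0]
        if N == 0:
            raise ValueError("empty batch")
        E_target = np.asarray(E_target, float).ravel()
        E, a, zs = self._forward(X)
        res_E = E - E_target
        loss = alpha_E * float(res_E @ res_E) / N

        gW = [np.zeros_like(W) for W in self.W]
        gb = [np.zeros_like(b) for b in self.b]

        # energy term: standard reverse pass
        if alpha_E > 0:
            bar_E = (2.0 * alpha_E / N) * res_E  # (N,)
            gW[-1] += a[-1].T @ bar_E[:, None]
            gb[-1] += np.array([bar_E.sum()])
            bar = bar_E[:, None] @ self.W[-1].T
            for l in range(len(self.W) - 2, -1, -1):
                bar_z = bar * _sigmoid(zs[l])
                gW[l] += a[l].T @ bar_z
                gb[l] += bar_z.sum(axis=0)
                bar = bar_z @ self.W[l].T

        # force term via reverse-over-forward on (dE/dx) . c
        if alpha_F > 0 and F_target is not None:
            g = self.input_grad(X)
            F_hat = -g
            res_F = F_hat - np.asarray(F_target, float)
            loss += alpha_F * float(np.sum(res_F * res_F)) / N
            # d loss / d g = (2 alpha_F / N) (g + F_target)
            C = (2.0 * alpha_F / N) * (-res_F)
            _, pW, pb = self.dgrad(X, C, want_params=True)
            for l in range(len(self.W)):
                gW[l] += pW[l]
                gb[l] += pb[l]
        return loss, gW, gb

    # -------------------------------------------------- second derivatives

    def dgrad(self, X: np.ndarray, C: np.ndarray, want_params: bool = False):
        """Differentiate J_n = (dE_n/dx_n) . c_n once more.

        Returns ``(hvp, gW, gb)`` where ``hvp[n] = H(x_n) c_n`` (input part)
        and the parameter lists hold d(sum_n J_n)/d(theta) when requested
        (``None`` otherwise).  Implemented as a reverse pass over the
        forward-tangent computation, i.e. forward-over-reverse second-order
        differentiation specialized to this architecture.
        """
        X = np.atleast_2d(np.asarray(X, float))
        C = np.atleast_2d(np.asarray(C, float))
        L = len(self.W)

        # primal + tangent forward
        a = [X]
        t = [C]
        zs, tzs, sigs = [], [], []
        for W, b in zip(self.W[:-1], self.b[:-1]):
            z = a[-1] @ W + b
            tz = t[-1] @ W
            s = _sigmoid(z)
            zs.append(z)
            tzs.append(tz)
            sigs.append(s)
            a.append(softplus(z))
            t.append(s * tz)

        gW = [np.zeros_like(W) for W in self.W] if want_params else None
        gb = [np.zeros_like(b) for b in self.b] if want_params else None

        # output layer: J = t_{L-1} @ W_L  (per sample scalar)
        bar_t = np.repeat(self.W[-1].T, X.shape[0], axis=0)  # (N, h)
        bar_a = np.zeros_like(bar_t)
        if want_params:
            gW[-1] += t[-1].T @ np.ones((X.shape[0], 1))

        for l in range(L - 2, -1, -1):
            s = sigs[l]
            ds = s * (1.0 - s)
            # t_{l+1} = s(z_l) * tz_l
            bar_tz = bar_t * s
            bar_z = bar_t * tzs[l] * ds
            # a_{l+1} = softplus(z_l)
            bar_z += bar_a * s
            # z_l = a_l W + b ; tz_l = t_l W
            if want_params:
                gW[l] += a[l].T @ bar_z + t[l].T @ bar_tz
                gb[l] += bar_z.sum(axis=0)
            bar_a = bar_z @ self.W[l].T
            bar_t = bar_tz @ self.W[l].T
        return bar_a, gW, gb

    # -------------------------------------------------------- serialization

    def get_params(self) -> List[np.ndarray]:
        return self.W + self.b

    def set_params(self, params: Sequence[np.ndarray]) -> None:
        n = len(self.W)
        self.W = [np.asarray(p, float) for p in params[:n]]
        self.b = [np.asarray(p, float) for p in params[n:]]

    def to_dict(self) -> dict:
        return {
            "sizes": self.sizes,
            "W": [W.tolist() for W in self.W],
            "b": [b.tolist() for b in self.b],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLP":
        net = cls.__new__(cls)
        net.sizes = list(d["sizes"])
        net.W = [np.array(W, float) for W in d["W"]]
        net.b = [np.array(b, float) for b in d["b"]]
        return net


class Adam:
    """Adaptive-moment stochastic gradient optimizer over a list of arrays.

    Uses the standard reformulation with the bias corrections folded into a
    per-step effective learning rate, and in-place array updates.
    """

    def __init__(self, shapes, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8, dtype=np.float64):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s, dtype=dtype) for s in shapes]
        self.v = [np.zeros(s, dtype=dtype) for s in shapes]
        self._buf = [np.empty(s, dtype=dtype) for s in shapes]
        self.t = 0

    def step(self, params: Sequence[np.ndarray], grads: Sequence[np.ndarray], sign: float = -1.0) -> None:
        """In-place update; ``sign=-1`` descends, ``+1`` ascends."""
        self.t += 1
        b2t = 1.0 - self.beta2**self.t
        lr_t = self.lr * np.sqrt(b2t) / (1.0 - self.beta1**self.t)
        eps_t = self.eps * np.sqrt(b2t)
        for p, g, m, v, buf in zip(params, grads, self.m, self.v, self._buf):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            np.multiply(g, g, out=buf)
            buf *= 1.0 - self.beta2
            v += buf
            np.sqrt(v, out=buf)
            buf += eps_t
            np.divide(m, buf, out=buf)
            buf *= sign * lr_t
            p += buf
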