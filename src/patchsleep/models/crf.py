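"""Linear-chain conditional random field over real-valued window features.

Binary states (wake=0, sleep=1) on each night segment. The score of a label
sequence y for features x is

    S(y, x) = sum_t W[y_t] . phi_t  +  sum_{t>=1} A[y_{t-1}, y_t]

with phi_t the standardized feature vector plus an intercept, W the 2xD state
weights and A the 2x2 transition weights. Training maximizes the L2-penalized
conditional log-likelihood with L-BFGS; per-window marginals P(y_t | x) come
from the forward-backward recursions in log space.

Training and prediction batch all sequences into zero-padded (B, T, 2)
arrays: padded positions carry zero node potentials (their feature rows,
intercept included, are zero) and zero transition potentials, which
multiplies each sequence's partition function and every path weight by the
same constant, so marginals and gradients over the real prefix are exact.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

from .base import Sequence, TrainedClassifier

N_STATES = 2


def _augment(X: np.ndarray) -> np.ndarray:
    return np.hstack([X, np.ones((X.shape[0], 1))])


def _node_potentials(X1: np.ndarray, W: np.ndarray) -> np.ndarray:
    """(T, 2) log node potentials."""
    return X1 @ W.T


def forward_backward(
    node: np.ndarray, A: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Log-space forward/backward messages and the log partition function.

    ``node`` is (T, 2); ``A`` is the (2, 2) transition log-potential matrix.
    Returns (alpha, beta, logZ) with alpha/beta of shape (T, 2).
    """
    T = node.shape[0]
    alpha = np.empty((T, N_STATES))
    beta = np.empty((T, N_STATES))
    alpha[0] = node[0]
    for t in range(1, T):
        prev = alpha[t - 1][:, None] + A  # (from, to)
        alpha[t] = node[t] + np.logaddexp(prev[0], prev[1])
    beta[T - 1] = 0.0
    for t in range(T - 2, -1, -1):
        nxt = A + (node[t + 1] + beta[t + 1])[None, :]
        beta[t] = np.logaddexp(nxt[:, 0], nxt[:, 1])
    log_z = float(np.logaddexp(alpha[T - 1, 0], alpha[T - 1, 1]))
    return alpha, beta, log_z


def marginals(node: np.ndarray, A: np.ndarray) -> np.ndarray:
    """(T, 2) posterior state marginals P(y_t | x)."""
    alpha, beta, log_z = forward_backward(node, A)
    return np.exp(alpha + beta - log_z)


def pairwise_marginals(node: np.ndarray, A: np.ndarray) -> np.ndarray:
    """(T-1, 2, 2) posterior edge marginals P(y_t, y_{t+1} | x)."""
    alpha, beta, log_z = forward_backward(node, A)
    return np.exp(
        alpha[:-1, :, None] + A[None, :, :] + (node[1:] + beta[1:])[:, None, :] - log_z
    )


def _pack(sequences: list[Sequence]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Zero-padded (B, T, D+1) features, (B, T) labels, (B, T) mask."""
    B = len(sequences)
    T = max(s.X.shape[0] for s in sequences)
    D = sequences[0].X.shape[1] + 1
    X1 = np.zeros((B, T, D))
    Y = np.zeros((B, T), dtype=int)
    mask = np.zeros((B, T))
    for i, s in enumerate(sequences):
        n = s.X.shape[0]
        X1[i, :n] = _augment(s.X)
        if s.y is not None:
            Y[i, :n] = s.y
        mask[i, :n] = 1.0
    return X1, Y, mask


def _batch_forward_backward(
    node: np.ndarray, A: np.ndarray, edge: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward/backward for a padded batch.

    ``node`` is (B, T, 2); ``edge`` is (B, T-1) with 1 where the transition
    between t and t+1 is real. Returns alpha, beta (B, T, 2) and the padded
    logZ (B,) — exact up to the shared padding constant, which cancels in
    marginals and in gradients.
    """
    B, T, _ = node.shape
    alpha = np.empty_like(node)
    beta = np.empty_like(node)
    alpha[:, 0] = node[:, 0]
    for t in range(1, T):
        At = A[None, :, :] * edge[:, t - 1][:, None, None]  # (B, from, to)
        prev = alpha[:, t - 1][:, :, None] + At
        alpha[:, t] = node[:, t] + np.logaddexp(prev[:, 0, :], prev[:, 1, :])
    beta[:, T - 1] = 0.0
    for t in range(T - 2, -1, -1):
        At = A[None, :, :] * edge[:, t][:, None, None]
        nxt = At + (node[:, t + 1] + beta[:, t + 1])[:, None, :]
        beta[:, t] = np.logaddexp(nxt[:, :, 0], nxt[:, :, 1])
    log_z = np.logaddexp(alpha[:, T - 1, 0], alpha[:, T - 1, 1])
    return alpha, beta, log_z


class CrfClassifier(TrainedClassifier):
    """Linear-chain CRF back-end."""

    def __init__(self, spec, feature_names):
        super().__init__(spec, feature_names)
        hp = dict(spec.hyperparameters)
        self.l2 = float(hp.get("l2", 1.0))
        self.maxiter = int(hp.get("maxiter", 200))
        self.W: np.ndarray | None = None
        self.A: np.ndarray | None = None

    # --- parameter packing -------------------------------------------------
    def _unpack(self, theta: np.ndarray, d: int) -> tuple[np.ndarray, np.ndarray]:
        W = theta[: N_STATES * d].reshape(N_STATES, d)
        A = theta[N_STATES * d :].reshape(N_STATES, N_STATES)
        return W, A

    def _nll_grad(
        self,
        theta: np.ndarray,
        X1: np.ndarray,
        Y: np.ndarray,
        mask: np.ndarray,
    ) -> tuple[float, np.ndarray]:
        B, T, d = X1.shape
        W, A = self._unpack(theta, d)
        edge = mask[:, 1:] * mask[:, :-1]
        node = X1 @ W.T  # (B, T, 2); zero rows at padding
        alpha, beta, log_z = _batch_forward_backward(node, A, edge)

        # observed score (padded node rows are zero; padded edges excluded)
        b_idx, t_idx = np.nonzero(mask)
        score = node[b_idx, t_idx, Y[b_idx, t_idx]].sum()
        score += (A[Y[:, :-1], Y[:, 1:]] * edge).sum()
        # the padding constant sum(n_pad)*log 2 in logZ does not depend on theta
        nll = float(log_z.sum() - score)

        post = np.exp(alpha + beta - log_z[:, None, None])  # (B, T, 2)
        gW = np.einsum("bts,btd->sd", post, X1)
        np.subtract.at(gW, Y[b_idx, t_idx], X1[b_idx, t_idx])

        xi = np.exp(
            alpha[:, :-1, :, None]
            + A[None, None, :, :] * edge[:, :, None, None]
            + (node[:, 1:] + beta[:, 1:])[:, :, None, :]
            - log_z[:, None, None, None]
        )
        gA = np.einsum("btij,bt->ij", xi, edge)
        eb, et = np.nonzero(edge)
        np.subtract.at(gA, (Y[eb, et], Y[eb, et + 1]), 1.0)

        n = mask.sum()
        nll = nll / n + 0.5 * self.l2 * float(theta @ theta) / n
        grad = np.concatenate([gW.ravel(), gA.ravel()]) / n + self.l2 * theta / n
        return nll, grad

    # --- back-end API ------------------------------------------------------
    def _fit(self, sequences: list[Sequence]) -> None:
        X1, Y, mask = _pack(sequences)
        d = X1.shape[2]
        theta0 = np.zeros(N_STATES * d + N_STATES * N_STATES)
        res = optimize.minimize(
            self._nll_grad,
            theta0,
            args=(X1, Y, mask),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": self.maxiter, "ftol": 1e-10, "gtol": 1e-7},
        )
        self.W, self.A = self._unpack(res.x, d)
        self.metadata["converged"] = bool(res.success)
        self.metadata["nll"] = float(res.fun)

    def _predict(self, sequences: list[Sequence]) -> list[np.ndarray]:
        if self.W is None:
            raise RuntimeError("model is not fitted")
        X1, _, mask = _pack(sequences)
        edge = mask[:, 1:] * mask[:, :-1]
        node = X1 @ self.W.T
        alpha, beta, log_z = _batch_forward_backward(node, self.A, edge)
        post = np.exp(alpha + beta - log_z[:, None, None])
        return [post[i, : s.X.shape[0], 1] for i, s in enumerate(sequences)]
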