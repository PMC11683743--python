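"""Compact recurrent (LSTM) back-end, implemented directly in numpy.

One LSTM layer (default 32 units) reads each night segment in time order and
a shared sigmoid readout emits per-window P(sleep). Training is full-batch
backpropagation-through-time with Adam, gradient clipping, and early stopping
on a held-out participant split of the training set. All randomness is
seeded, so training is deterministic on a single thread.
"""

from __future__ import annotations

import numpy as np

from .base import Sequence, TrainedClassifier


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _pad(sequences: list[Sequence]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    B = len(sequences)
    T = max(s.X.shape[0] for s in sequences)
    D = sequences[0].X.shape[1]
    X = np.zeros((B, T, D))
    Y = np.zeros((B, T))
    mask = np.zeros((B, T))
    for i, s in enumerate(sequences):
        n = s.X.shape[0]
        X[i, :n] = s.X
        if s.y is not None:
            Y[i, :n] = s.y
        mask[i, :n] = 1.0
    return X, Y, mask


class _Params(dict):
    """Named parameter arrays with elementwise helpers for Adam."""


class LstmClassifier(TrainedClassifier):
    def __init__(self, spec, feature_names):
        super().__init__(spec, feature_names)
        hp = dict(spec.hyperparameters)
        self.hidden = int(hp.get("hidden", 32))
        self.lr = float(hp.get("lr", 0.05))  # full-batch Adam tolerates a large step
        self.max_epochs = int(hp.get("max_epochs", 50))
        self.patience = int(hp.get("patience", 8))
        self.val_fraction = float(hp.get("val_fraction", 0.2))
        self.clip = float(hp.get("clip", 5.0))
        self.params: _Params | None = None

    # --- forward / backward ------------------------------------------------
    def _init_params(self, d: int, rng: np.random.Generator) -> _Params:
        H = self.hidden
        p = _Params()
        p["Wx"] = rng.normal(0.0, 1.0 / np.sqrt(d), size=(d, 4 * H))
        p["Wh"] = rng.normal(0.0, 1.0 / np.sqrt(H), size=(H, 4 * H))
        b = np.zeros(4 * H)
        b[H : 2 * H] = 1.0  # forget-gate bias
        p["b"] = b
        p["w_out"] = rng.normal(0.0, 1.0 / np.sqrt(H), size=H)
        p["b_out"] = np.zeros(1)
        return p

    def _forward(self, X: np.ndarray, p: _Params):
        B, T, D = X.shape
        H = self.hidden
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        cache = []
        logits = np.zeros((B, T))
        for t in range(T):
            z = X[:, t] @ p["Wx"] + h @ p["Wh"] + p["b"]
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_prev, h_prev = c, h
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            logits[:, t] = h @ p["w_out"] + p["b_out"]
            cache.append((i, f, g, o, c_prev, h_prev, c, tc, h))
        return logits, cache

    def _loss_grad(self, X, Y, mask, p: _Params):
        B, T, D = X.shape
        H = self.hidden
        logits, cache = self._forward(X, p)
        probs = _sigmoid(logits)
        n = mask.sum()
        eps = 1e-12
        loss = -np.sum(mask * (Y * np.log(probs + eps) + (1 - Y) * np.log(1 - probs + eps))) / n

        g = {k: np.zeros_like(v) for k, v in p.items()}
        dlogit = (probs - Y) * mask / n  # (B, T)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            i, f, gg, o, c_prev, h_prev, c, tc, h = cache[t]
            g["w_out"] += h.T @ dlogit[:, t]
            g["b_out"] += dlogit[:, t].sum()
            dh = dh_next + dlogit[:, t][:, None] * p["w_out"][None, :]
            do = dh * tc
            dc = dh * o * (1 - tc**2) + dc_next
            di = dc * gg
            dg = dc * i
            df = dc * c_prev
            dc_next = dc * f
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - gg**2), do * o * (1 - o)],
                axis=1,
            )
            dz *= mask[:, t][:, None]
            g["Wx"] += X[:, t].T @ dz
            g["Wh"] += h_prev.T @ dz
            g["b"] += dz.sum(axis=0)
            dh_next = dz @ p["Wh"].T
        return loss, g

    # --- training ----------------------------------------------------------
    def _fit(self, sequences: list[Sequence]) -> None:
        rng = np.random.default_rng(self.spec.seed)
        participants = sorted({s.participant for s in sequences})
        n_val = int(np.ceil(self.val_fraction * len(participants)))
        if len(participants) > 2 and n_val >= 1:
            val_ids = set(rng.permutation(participants)[:n_val])
        else:
            val_ids = set()
        train_seqs = [s for s in sequences if s.participant not in val_ids] or sequences
        val_seqs = [s for s in sequences if s.participant in val_ids]

        Xtr, Ytr, Mtr = _pad(train_seqs)
        if val_seqs:
            Xva, Yva, Mva = _pad(val_seqs)

        d = Xtr.shape[2]
        p = self._init_params(d, rng)
        m = {k: np.zeros_like(v) for k, v in p.items()}
        v = {k: np.zeros_like(v_) for k, v_ in p.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8

        best_loss = np.inf
        best_params = {k: a.copy() for k, a in p.items()}
        stall = 0
        for epoch in range(1, self.max_epochs + 1):
            loss, grads = self._loss_grad(Xtr, Ytr, Mtr, p)
            norm = np.sqrt(sum(float((g_**2).sum()) for g_ in grads.values()))
            scale = min(1.0, self.clip / (norm + 1e-12))
            for k in p:
                g_ = grads[k] * scale
                m[k] = beta1 * m[k] + (1 - beta1) * g_
                v[k] = beta2 * v[k] + (1 - beta2) * g_**2
                mhat = m[k] / (1 - beta1**epoch)
                vhat = v[k] / (1 - beta2**epoch)
                p[k] = p[k] - self.lr * mhat / (np.sqrt(vhat) + eps)
            if val_seqs:
                logits, _ = self._forward(Xva, p)
                probs = _sigmoid(logits)
                e = 1e-12
                monitor = -np.sum(
                    Mva * (Yva * np.log(probs + e) + (1 - Yva) * np.log(1 - probs + e))
                ) / Mva.sum()
            else:
                monitor = loss
            if monitor < best_loss - 1e-5:
                best_loss = monitor
                best_params = {k: a.copy() for k, a in p.items()}
                stall = 0
            else:
                stall += 1
                if stall >= self.patience:
                    break
        self.params = _Params(best_params)
        self.metadata["epochs_run"] = epoch
        self.metadata["best_monitor_loss"] = float(best_loss)

    def _predict(self, sequences: list[Sequence]) -> list[np.ndarray]:
        if self.params is None:
            raise RuntimeError("model is not fitted")
        X, _, mask = _pad(sequences)
        logits, _ = self._forward(X, self.params)
        probs = _sigmoid(logits)
        return [probs[i, : s.X.shape[0]] for i, s in enumerate(sequences)]
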