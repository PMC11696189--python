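"""Gated recurrent sequence network over tokenised daily windows, in NumPy.

Architecture (one stay = one sequence of daily windows):

1. each window's unique tokens are looked up in a learned embedding table;
   the vectors are averaged, each weighted by the token's learned positive
   relevance weight (positivity enforced by a softplus transform);
2. the per-day vectors feed a gated RNN (GRU or LSTM);
3. each hidden state is decoded by a multinomial (softmax) layer into a
   probability vector over next-day TIL-Basic 0-4.

Training minimises the mean categorical cross-entropy over labelled
patient-days (days without a next-day assessment are masked), with Adam
and early stopping on validation loss.  Forward and backward passes are
written out by hand; the backward pass is verified against finite
differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .tokenizer import TokenizedStay, TokenVocabulary

__all__ = ["SequenceNet", "TrainingError"]

N_CLASSES = 5


class TrainingError(ValueError):
    """Training is impossible (e.g. no labelled days)."""


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class SequenceNet:
    """Embedding-bag + gated RNN + softmax head with manual gradients."""

    vocab: TokenVocabulary
    rnn_type: str = "GRU"
    hidden_dim: int = 32
    seed: int = 0
    params: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.rnn_type not in ("GRU", "LSTM"):
            raise ValueError("rnn_type must be 'GRU' or 'LSTM'")
        if not self.params:
            self._init_params()

    # ------------------------------------------------------------------
    def _init_params(self) -> None:
        rng = np.random.default_rng(self.seed)
        d, h = self.vocab.embed_dim, self.hidden_dim
        n_gates = 3 if self.rnn_type == "GRU" else 4
        scale = 1.0 / np.sqrt(d + h)
        if self.vocab.embeddings is None:
            self.vocab.init_parameters(rng)
        # own copies so concurrently tuned candidate nets do not interfere;
        # synced back to the vocabulary after training by the caller
        self.params = {
            "E": self.vocab.embeddings.copy(),
            "rho": self.vocab.relevance_raw.copy(),
            "W": rng.normal(0.0, scale, size=(d + h, n_gates * h)),
            "b": np.zeros(n_gates * h),
            "Wy": np.zeros((h, N_CLASSES)),  # zero head -> uniform start
            "by": np.zeros(N_CLASSES),
        }

    def clone(self) -> "SequenceNet":
        net = SequenceNet(
            vocab=self.vocab,
            rnn_type=self.rnn_type,
            hidden_dim=self.hidden_dim,
            seed=self.seed,
            params={k: v.copy() for k, v in self.params.items()},
        )
        return net

    def relevance_weights(self) -> np.ndarray:
        """Positive per-token relevance weights (softplus of free params)."""
        return _softplus(self.params["rho"])

    # ------------------------------------------------------------------
    def embed_window(self, token_idx: np.ndarray) -> np.ndarray:
        """Relevance-weighted average of the window's token embeddings."""
        if len(token_idx) == 0:
            raise ValueError("empty token set: windows must carry tokens")
        E, rho = self.params["E"], self.params["rho"]
        r = _softplus(rho[token_idx])
        return (r @ E[token_idx]) / r.sum()

    def forward(self, token_sets: Sequence[np.ndarray],
                cache: Optional[list] = None) -> np.ndarray:
        """Probabilities (T, 5), one row per daily window, causal in t."""
        d, h = self.vocab.embed_dim, self.hidden_dim
        P = self.params
        E, rho = P["E"], P["rho"]
        h_prev = np.zeros(h)
        c_prev = np.zeros(h)
        probs = np.empty((len(token_sets), N_CLASSES))
        for t, toks in enumerate(token_sets):
            r = _softplus(rho[toks])
            R = r.sum()
            v = (r @ E[toks]) / R
            a = np.concatenate([v, h_prev])
            if self.rnn_type == "GRU":
                zr = _sigmoid(a @ P["W"][:, : 2 * h] + P["b"][: 2 * h])
                z, rg = zr[:h], zr[h:]
                a2 = np.concatenate([v, rg * h_prev])
                hc = np.tanh(a2 @ P["W"][:, 2 * h:] + P["b"][2 * h:])
                h_new = (1.0 - z) * h_prev + z * hc
                step_cache = (toks, r, R, v, h_prev, z, rg, a2, hc)
                c_new = c_prev
            else:
                gates = a @ P["W"] + P["b"]
                i = _sigmoid(gates[:h])
                f = _sigmoid(gates[h: 2 * h])
                o = _sigmoid(gates[2 * h: 3 * h])
                g = np.tanh(gates[3 * h:])
                c_new = f * c_prev + i * g
                tc = np.tanh(c_new)
                h_new = o * tc
                step_cache = (toks, r, R, v, h_prev, c_prev, i, f, o, g, c_new, tc)
            logits = h_new @ P["Wy"] + P["by"]
            probs[t] = _softmax(logits)
            if cache is not None:
                cache.append((step_cache, h_new, probs[t]))
            h_prev, c_prev = h_new, c_new
        return probs

    # ------------------------------------------------------------------
    def loss_and_grads(
        self, stays: Sequence[TokenizedStay]
    ) -> tuple[float, dict, int]:
        """Mean cross-entropy over labelled days and parameter gradients."""
        P = self.params
        grads = {k: np.zeros_like(v) for k, v in P.items()}
        n_labels = sum(1 for s in stays for y in s.labels if y is not None)
        if n_labels == 0:
            raise TrainingError("no labelled patient-days in the batch")
        total = 0.0
        for stay in stays:
            total += self._stay_backward(stay, grads, 1.0 / n_labels)
        return total, grads, n_labels

    def _stay_backward(self, stay: TokenizedStay, grads: dict,
                       w: float) -> float:
        d, h = self.vocab.embed_dim, self.hidden_dim
        P = self.params
        cache: list = []
        probs = self.forward(stay.token_sets, cache=cache)
        T = len(stay.token_sets)

        loss = 0.0
        dh_next = np.zeros(h)
        dc_next = np.zeros(h)
        for t in range(T - 1, -1, -1):
            step_cache, h_t, p_t = cache[t]
            y = stay.labels[t]
            dh = dh_next.copy()
            if y is not None:
                loss += -np.log(max(p_t[y], 1e-12)) * w
                dlogit = p_t.copy()
                dlogit[y] -= 1.0
                dlogit *= w
                grads["Wy"] += np.outer(h_t, dlogit)
                grads["by"] += dlogit
                dh += P["Wy"] @ dlogit
            if self.rnn_type == "GRU":
                toks, r, R, v, h_prev, z, rg, a2, hc = step_cache
                dz = dh * (hc - h_prev)
                dhc = dh * z
                dh_prev = dh * (1.0 - z)
                dhc_pre = dhc * (1.0 - hc * hc)
                grads["W"][:, 2 * h:] += np.outer(a2, dhc_pre)
                grads["b"][2 * h:] += dhc_pre
                da2 = P["W"][:, 2 * h:] @ dhc_pre
                dv = da2[:d].copy()
                drg = da2[d:] * h_prev
                dh_prev += da2[d:] * rg
                dz_pre = dz * z * (1.0 - z)
                drg_pre = drg * rg * (1.0 - rg)
                dzr_pre = np.concatenate([dz_pre, drg_pre])
                a = np.concatenate([v, h_prev])
                grads["W"][:, : 2 * h] += np.outer(a, dzr_pre)
                grads["b"][: 2 * h] += dzr_pre
                da = P["W"][:, : 2 * h] @ dzr_pre
                dv += da[:d]
                dh_prev += da[d:]
                dc_prev = dc_next  # unused for GRU
            else:
                (toks, r, R, v, h_prev, c_prev, i, f, o, g, c_new, tc) = step_cache
                do = dh * tc
                dc = dh * o * (1.0 - tc * tc) + dc_next
                di = dc * g
                df = dc * c_prev
                dg = dc * i
                dc_prev = dc * f
                dgates = np.concatenate(
                    [
                        di * i * (1.0 - i),
                        df * f * (1.0 - f),
                        do * o * (1.0 - o),
                        dg * (1.0 - g * g),
                    ]
                )
                a = np.concatenate([v, h_prev])
                grads["W"] += np.outer(a, dgates)
                grads["b"] += dgates
                da = P["W"] @ dgates
                dv = da[:d].copy()
                dh_prev = da[d:]
            # embedding bag backward: v = (sum r_i e_i) / R
            E = P["E"]
            e = E[toks]
            de = np.outer(r, dv) / R
            np.add.at(grads["E"], toks, de)
            dr = (e @ dv - v @ dv) / R
            grads["rho"][toks] += dr * _sigmoid(P["rho"][toks])
            dh_next = dh_prev
            dc_next = dc_prev
        return loss

    # ------------------------------------------------------------------
    def fit(
        self,
        train_stays: Sequence[TokenizedStay],
        val_stays: Sequence[TokenizedStay],
        learning_rate: float = 1e-3,
        max_epochs: int = 100,
        patience: int = 5,
        batch_size: int = 32,
        weight_decay: float = 1e-4,
        seed: int = 0,
        verbose: bool = False,
    ) -> list[float]:
        """Adam training with early stopping on validation loss.

        Returns the per-epoch validation loss trajectory.  Restores the
        best-validation parameters on exit.  Deterministic given seed.
        """
        if not any(y is not None for s in train_stays for y in s.labels):
            raise TrainingError("training set has no labelled patient-days")
        rng = np.random.default_rng(seed)
        P = self.params
        m = {k: np.zeros_like(v) for k, v in P.items()}
        v_ = {k: np.zeros_like(v) for k, v in P.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0

        best_val = np.inf
        best_params: Optional[dict] = None
        bad_epochs = 0
        trajectory: list[float] = []
        order = np.arange(len(train_stays))
        for epoch in range(max_epochs):
            rng.shuffle(order)
            for start in range(0, len(order), batch_size):
                batch = [train_stays[i] for i in order[start: start + batch_size]]
                if not any(y is not None for s in batch for y in s.labels):
                    continue
                _, grads, _ = self.loss_and_grads(batch)
                step += 1
                for k in P:
                    g = grads[k]
                    if weight_decay and k in ("W", "Wy", "E"):
                        g = g + weight_decay * P[k]
                    m[k] = beta1 * m[k] + (1 - beta1) * g
                    v_[k] = beta2 * v_[k] + (1 - beta2) * g * g
                    mhat = m[k] / (1 - beta1**step)
                    vhat = v_[k] / (1 - beta2**step)
                    P[k] -= learning_rate * mhat / (np.sqrt(vhat) + eps)
            val = self.evaluate_loss(val_stays)
            trajectory.append(val)
            if verbose:
                print(f"epoch {epoch + 1}: val loss {val:.4f}")
            if val < best_val - 1e-6:
                best_val = val
                best_params = {k: p.copy() for k, p in P.items()}
                bad_epochs = 0
            else:
                bad_epochs += 1
                # halve the learning rate mid-plateau, stop at patience
                if bad_epochs == max(1, patience // 2):
                    learning_rate *= 0.5
                if bad_epochs >= patience:
                    break
        if best_params is not None:
            for k in P:
                P[k][...] = best_params[k]
        return trajectory

    def evaluate_loss(self, stays: Sequence[TokenizedStay]) -> float:
        total, n = 0.0, 0
        for stay in stays:
            probs = self.forward(stay.token_sets)
            for t, y in enumerate(stay.labels):
                if y is not None:
                    total += -np.log(max(probs[t, y], 1e-12))
                    n += 1
        return total / max(n, 1)
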