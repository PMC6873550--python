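"""Autoregressive token-level sequence model for SMILES strings.

Architecture: an embedding layer of ``m`` dimensions feeds ``l`` stacked
LSTM or GRU layers of width ``w`` (optional dropout between recurrent
layers, none after the last), followed by a linear projection to the
vocabulary size ``v`` and a softmax giving the next-token distribution.
The constraint ``m <= w`` avoids squeezing the encoded input.

The model is NumPy end to end: forward, backpropagation through time and
sampling are implemented here, which keeps every number bit-reproducible
from a single integer seed on one platform.  At the desk scales this
package targets (vocabularies of a few dozen tokens, widths up to a few
hundred) dense BLAS matmuls are entirely adequate.

Training loss is the batch-mean negative log-likelihood over *all* matrix
positions, with no mask after a sequence's first end token — the padding
symbol is the end token itself, so the extra positions only teach
"end predicts end".  Reporting NLLs (everything fed to the coverage
metrics) instead truncate at the first end token, because they concern
whole-molecule probabilities.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .rngutil import rng_for
from .tokenizer import TokenVocabulary, encode_sequence, pad_batch

LSTM = "lstm"
GRU = "gru"


@dataclass(frozen=True)
class ModelHyperparams:
    """Hyperparameters of the sequence model.

    ``layers`` (l), ``width`` (w), ``embedding`` (m, defaults to w),
    ``dropout`` (d, fraction in [0,1)), ``cell`` and the vocabulary size v.
    """

    layers: int = 2
    width: int = 128
    embedding: int | None = None
    dropout: float = 0.0
    cell: str = LSTM
    vocab_size: int = 0

    def __post_init__(self) -> None:
        if self.layers < 1 or self.width < 1:
            raise ValueError("layers and width must be >= 1")
        m = self.embedding if self.embedding is not None else self.width
        if m > self.width:
            raise ValueError(
                f"embedding dimension {m} exceeds recurrent width {self.width}"
            )
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.cell not in (LSTM, GRU):
            raise ValueError(f"unknown cell {self.cell!r}")
        if self.vocab_size < 2:
            raise ValueError("vocab_size must be >= 2 (begin and end tokens)")

    @property
    def embedding_dim(self) -> int:
        return self.embedding if self.embedding is not None else self.width


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class SmilesRNN:
    """The sequence model, with NLL computation and autoregressive sampling."""

    def __init__(
        self,
        hparams: ModelHyperparams,
        vocab: TokenVocabulary,
        seed: int = 0,
        dtype=np.float32,
    ) -> None:
        if hparams.vocab_size != vocab.size:
            hparams = ModelHyperparams(**{**asdict(hparams), "vocab_size": vocab.size})
        self.hparams = hparams
        self.vocab = vocab
        self.dtype = np.dtype(dtype)
        self._gates = 4 if hparams.cell == LSTM else 3
        self.params = self._init_params(seed)

    # -- initialization ----------------------------------------------------
    def _init_params(self, seed: int) -> dict[str, np.ndarray]:
        hp = self.hparams
        w, m, v = hp.width, hp.embedding_dim, hp.vocab_size
        bound = np.sqrt(1.0 / w)
        rng = rng_for(seed, "init")

        def U(*shape):
            return rng.uniform(-bound, bound, size=shape).astype(self.dtype)

        params: dict[str, np.ndarray] = {"E": U(v, m)}
        g = self._gates
        for layer in range(hp.layers):
            in_dim = m if layer == 0 else w
            params[f"Wx{layer}"] = U(in_dim, g * w)
            params[f"Wh{layer}"] = U(w, g * w)
            params[f"b{layer}"] = np.zeros(g * w, dtype=self.dtype)
        params["Wo"] = U(w, v)
        params["bo"] = np.zeros(v, dtype=self.dtype)
        return params

    # -- single step (inference) ------------------------------------------
    def zero_state(self, batch: int) -> list[tuple[np.ndarray, np.ndarray]]:
        w = self.hparams.width
        return [
            (np.zeros((batch, w), dtype=self.dtype), np.zeros((batch, w), dtype=self.dtype))
            for _ in range(self.hparams.layers)
        ]

    def _cell_step(self, layer: int, x, h, c):
        """One recurrent step; returns (out, h_new, c_new, cache)."""
        w = self.hparams.width
        P = self.params
        if self.hparams.cell == LSTM:
            z = x @ P[f"Wx{layer}"] + h @ P[f"Wh{layer}"] + P[f"b{layer}"]
            i = _sigmoid(z[:, :w])
            f = _sigmoid(z[:, w : 2 * w])
            g = np.tanh(z[:, 2 * w : 3 * w])
            o = _sigmoid(z[:, 3 * w :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            return h_new, h_new, c_new, (x, h, c, i, f, g, o, tc)
        zx = x @ P[f"Wx{layer}"] + P[f"b{layer}"]
        zh = h @ P[f"Wh{layer}"]
        r = _sigmoid(zx[:, :w] + zh[:, :w])
        u = _sigmoid(zx[:, w : 2 * w] + zh[:, w : 2 * w])
        n = np.tanh(zx[:, 2 * w :] + r * zh[:, 2 * w :])
        h_new = (1.0 - u) * n + u * h
        return h_new, h_new, c, (x, h, r, u, n, zh[:, 2 * w :])

    def forward_step(self, indices: Sequence[int], state=None):
        """Next-token probability distribution for one input column.

        Returns ``(probs, new_state)`` with ``probs`` rows summing to one.
        Dropout is inactive (inference mode), so the step is deterministic.
        """
        idx = np.asarray(indices, dtype=np.int64)
        if idx.ndim != 1:
            raise ValueError("indices must be a 1-D batch column")
        if np.any(idx < 0) or np.any(idx >= self.hparams.vocab_size):
            raise ValueError("token index outside vocabulary")
        if state is None:
            state = self.zero_state(len(idx))
        if len(state) != self.hparams.layers or state[0][0].shape[0] != len(idx):
            raise ValueError("state shape mismatch")
        x = self.params["E"][idx]
        new_state = []
        for layer in range(self.hparams.layers):
            h, c = state[layer]
            x, h_new, c_new, _ = self._cell_step(layer, x, h, c)
            new_state.append((h_new, c_new))
        logits = x @ self.params["Wo"] + self.params["bo"]
        probs = _softmax(logits)
        return probs, new_state

    # -- full-sequence forward/backward ------------------------------------
    def _forward(self, X: np.ndarray, train: bool, dropout_rng=None):
        """Teacher-forced forward over a padded index matrix ``X`` (B, T).

        Inputs are ``X[:, :-1]``, targets ``X[:, 1:]``.  Returns per-position
        log-probabilities of the targets plus caches for backprop.
        """
        hp = self.hparams
        B, T = X.shape
        steps = T - 1
        state = self.zero_state(B)
        caches = []
        logps = np.empty((B, steps), dtype=np.float64)
        probs_all = []
        drop = hp.dropout if train else 0.0
        for t in range(steps):
            x = self.params["E"][X[:, t]]
            step_cache = []
            masks = []
            for layer in range(hp.layers):
                h, c = state[layer]
                x, h_new, c_new, cache = self._cell_step(layer, x, h, c)
                state[layer] = (h_new, c_new)
                step_cache.append(cache)
                if drop > 0.0 and layer < hp.layers - 1:
                    mask = (
                        dropout_rng.random(x.shape) >= drop
                    ).astype(self.dtype) / self.dtype.type(1.0 - drop)
                    x = x * mask
                    masks.append(mask)
                else:
                    masks.append(None)
            logits = x @ self.params["Wo"] + self.params["bo"]
            p = _softmax(logits)
            probs_all.append(p)
            tgt = X[:, t + 1]
            logps[:, t] = np.log(np.maximum(p[np.arange(B), tgt], 1e-300))
            caches.append((step_cache, masks, x))
        return logps, probs_all, caches

    def batch_loss(self, X: np.ndarray) -> float:
        """Unmasked batch-mean NLL over every position of the padded matrix."""
        logps, _, _ = self._forward(np.asarray(X, dtype=np.int64), train=False)
        return float(-logps.sum(axis=1).mean())

    def loss_and_grads(self, X: np.ndarray, dropout_rng=None):
        """Training loss and parameter gradients for one padded batch."""
        hp = self.hparams
        X = np.asarray(X, dtype=np.int64)
        B, T = X.shape
        steps = T - 1
        w = hp.width
        train = hp.dropout > 0.0 and dropout_rng is not None
        logps, probs_all, caches = self._forward(X, train=train, dropout_rng=dropout_rng)
        loss = float(-logps.sum(axis=1).mean())

        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        P = self.params
        # running gradients wrt recurrent states, per layer
        dh_next = [np.zeros((B, w), dtype=self.dtype) for _ in range(hp.layers)]
        dc_next = [np.zeros((B, w), dtype=self.dtype) for _ in range(hp.layers)]
        scale = 1.0 / B
        for t in range(steps - 1, -1, -1):
            step_cache, masks, top = caches[t]
            p = probs_all[t].copy()
            p[np.arange(B), X[:, t + 1]] -= 1.0
            dlogits = (p * scale).astype(self.dtype)
            grads["Wo"] += top.T @ dlogits
            grads["bo"] += dlogits.sum(axis=0)
            dx = dlogits @ P["Wo"].T
            for layer in range(hp.layers - 1, -1, -1):
                if masks[layer] is not None:
                    dx = dx * masks[layer]
                dh = dx + dh_next[layer]
                cache = step_cache[layer]
                if hp.cell == LSTM:
                    x_in, h_prev, c_prev, i, f, g, o, tc = cache
                    dc = dh * o * (1.0 - tc * tc) + dc_next[layer]
                    do = dh * tc
                    di = dc * g
                    df = dc * c_prev
                    dg = dc * i
                    dz = np.concatenate(
                        [
                            di * i * (1.0 - i),
                            df * f * (1.0 - f),
                            dg * (1.0 - g * g),
                            do * o * (1.0 - o),
                        ],
                        axis=1,
                    )
                    grads[f"Wx{layer}"] += x_in.T @ dz
                    grads[f"Wh{layer}"] += h_prev.T @ dz
                    grads[f"b{layer}"] += dz.sum(axis=0)
                    dx = dz @ P[f"Wx{layer}"].T
                    dh_next[layer] = dz @ P[f"Wh{layer}"].T
                    dc_next[layer] = dc * f
                else:
                    x_in, h_prev, r, u, n, zh_n = cache
                    du = dh * (h_prev - n)
                    dn = dh * (1.0 - u)
                    dh_prev = dh * u
                    dn_pre = dn * (1.0 - n * n)
                    dr = dn_pre * zh_n
                    dzh_n = dn_pre * r
                    du_pre = du * u * (1.0 - u)
                    dr_pre = dr * r * (1.0 - r)
                    dzx = np.concatenate([dr_pre, du_pre, dn_pre], axis=1)
                    dzh = np.concatenate([dr_pre, du_pre, dzh_n], axis=1)
                    grads[f"Wx{layer}"] += x_in.T @ dzx
                    grads[f"Wh{layer}"] += h_prev.T @ dzh
                    grads[f"b{layer}"] += dzx.sum(axis=0)
                    dx = dzx @ P[f"Wx{layer}"].T
                    dh_next[layer] = dh_prev + dzh @ P[f"Wh{layer}"].T
            np.add.at(grads["E"], X[:, t], dx)
        return loss, grads

    # -- NLL reporting ------------------------------------------------------
    def sequence_nlls(self, smiles: Sequence[str]) -> np.ndarray:
        """Teacher-forced NLL of each string, truncated at its first end token.

        The sum runs from the prediction following the begin token through
        the first end token inclusive, i.e. it is -ln P(string).
        """
        if len(smiles) == 0:
            return np.zeros(0)
        encoded = [encode_sequence(s, self.vocab) for s in smiles]
        return self.encoded_nlls(encoded)

    def encoded_nlls(self, encoded: Sequence[np.ndarray]) -> np.ndarray:
        X = pad_batch(list(encoded), self.vocab)
        logps, _, _ = self._forward(X, train=False)
        B, steps = logps.shape
        nlls = np.empty(B)
        for r, seq in enumerate(encoded):
            if seq[0] != self.vocab.begin_index:
                raise ValueError("sequence does not start with the begin token")
            ends = np.nonzero(seq == self.vocab.end_index)[0]
            if len(ends) == 0:
                raise ValueError("sequence has no end token")
            # predictions for positions 1..first_end
            nlls[r] = -logps[r, : ends[0]].sum()
        return nlls

    def sequence_nll(self, smiles: str) -> float:
        return float(self.sequence_nlls([smiles])[0])

    # -- sampling -----------------------------------------------------------
    def sample(
        self,
        n: int,
        max_len: int = 128,
        seed: int = 0,
        batch_size: int = 4096,
        include_nonterminated: bool = True,
    ) -> list[tuple[str, float, bool]]:
        """Draw ``n`` strings autoregressively at temperature 1.

        Returns ``(payload_text, nll, terminated)`` triples.  ``nll`` is the
        reporting NLL of the emitted tokens (through the end token when one
        was produced).  Sequences still unfinished after ``max_len``
        generated tokens are flagged ``terminated=False``; downstream
        evaluation counts them as invalid.
        """
        if n < 1:
            raise ValueError("n must be >= 1")
        if max_len < 2:
            raise ValueError("max_len must be >= 2")
        rng = rng_for(seed, "sample")
        out: list[tuple[str, float, bool]] = []
        remaining = n
        while remaining > 0:
            b = min(batch_size, remaining)
            out.extend(self._sample_batch(b, max_len, rng))
            remaining -= b
        return out

    def _sample_batch(self, b: int, max_len: int, rng) -> list[tuple[str, float, bool]]:
        vocab = self.vocab
        state = self.zero_state(b)
        current = np.full(b, vocab.begin_index, dtype=np.int64)
        alive = np.ones(b, dtype=bool)
        nll = np.zeros(b)
        tokens: list[list[str]] = [[] for _ in range(b)]
        terminated = np.zeros(b, dtype=bool)
        for _ in range(max_len):
            probs, state = self.forward_step(current, state)
            cdf = np.cumsum(probs.astype(np.float64), axis=1)
            cdf[:, -1] = 1.0
            u = rng.random(b)
            choice = (cdf < u[:, None]).sum(axis=1)
            logp = np.log(np.maximum(probs[np.arange(b), choice], 1e-300))
            nll[alive] -= logp[alive]
            for rix in np.nonzero(alive)[0]:
                tok = vocab.tokens[choice[rix]]
                if tok == vocab.tokens[vocab.end_index]:
                    terminated[rix] = True
                    alive[rix] = False
                else:
                    tokens[rix].append(tok)
            current = choice
            if not alive.any():
                break
        return [
            ("".join(tokens[r]), float(nll[r]), bool(terminated[r])) for r in range(b)
        ]

    # -- checkpointing ------------------------------------------------------
    def save(self, path: str | Path, epoch: int | None = None) -> None:
        """Serialize parameters, hyperparameters and vocabulary to one file."""
        meta = {
            "format": "smilesrnn-ckpt-1",
            "hparams": asdict(self.hparams),
            "vocab": list(self.vocab.tokens),
            "dtype": self.dtype.name,
            "epoch": epoch,
        }
        with open(path, "wb") as fh:
            np.savez(fh, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "SmilesRNN":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta.get("format") != "smilesrnn-ckpt-1":
                raise ValueError("unrecognized checkpoint format")
            model = cls.__new__(cls)
            model.hparams = ModelHyperparams(**meta["hparams"])
            model.vocab = TokenVocabulary(tuple(meta["vocab"]))
            model.dtype = np.dtype(meta["dtype"])
            model._gates = 4 if model.hparams.cell == LSTM else 3
            model.params = {
                k: data[k].copy() for k in data.files if k != "__meta__"
            }
        return model

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        self.params = {k: v.copy() for k, v in params.items()}


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)
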