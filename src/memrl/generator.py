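"""SMILES language model: embedding -> stacked GRU -> linear head.

The model is an autoregressive token-level language model over a SMILES
vocabulary, trained by negative log-likelihood with Adam. The default
architecture is three GRU layers of 256 units; smaller configurations are
available for quick experiments. The implementation is pure NumPy: the
forward pass caches all gate activations and ``backward_loglik`` runs
backpropagation through time for any objective that is a weighted sum of
per-sequence log-likelihoods, which covers both maximum-likelihood training
and the policy-update loss of the RL engine.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Vocabulary",
    "build_vocabulary",
    "GeneratorModel",
    "GeneratedBatch",
    "Adam",
    "sequence_nll",
    "sequence_nll_many",
    "train_lm",
    "fine_tune",
    "sample_batch",
    "save_model",
    "load_model",
]

PAD, START, END = "<pad>", "^", "$"

# Multi-character tokens first: bracket atoms, two-letter halogens/organics,
# two-digit ring closures; everything else is a single character.
_TOKEN_RE = re.compile(r"\[[^\]]+\]|Br|Cl|%\d{2}|.")


@dataclass(frozen=True)
class Vocabulary:
    """Bijective token <-> index mapping with pad/start/end specials."""

    tokens: tuple[str, ...]
    index: dict = field(hash=False, compare=False, default=None)

    def __post_init__(self):
        object.__setattr__(self, "index", {t: i for i, t in enumerate(self.tokens)})

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def pad(self) -> int:
        return self.index[PAD]

    @property
    def start(self) -> int:
        return self.index[START]

    @property
    def end(self) -> int:
        return self.index[END]

    def tokenize(self, smiles: str) -> list[str]:
        toks = _TOKEN_RE.findall(smiles)
        if "".join(toks) != smiles:
            raise ValueError(f"cannot tokenize SMILES: {smiles!r}")
        unknown = [t for t in toks if t not in self.index]
        if unknown:
            raise ValueError(f"tokens not in vocabulary: {sorted(set(unknown))}")
        return toks

    def encode(self, smiles: str) -> np.ndarray:
        """Token indices bracketed by start and end markers."""
        toks = self.tokenize(smiles)
        return np.array(
            [self.start] + [self.index[t] for t in toks] + [self.end], dtype=np.int64
        )

    def decode(self, ids: Sequence[int]) -> str:
        out = []
        for i in ids:
            tok = self.tokens[int(i)]
            if tok in (PAD, START, END):
                continue
            out.append(tok)
        return "".join(out)


def build_vocabulary(corpus: Sequence[str]) -> Vocabulary:
    """Deterministic vocabulary: specials plus lexicographically sorted tokens."""
    if not corpus:
        raise ValueError("empty corpus")
    seen: set[str] = set()
    for smiles in corpus:
        toks = _TOKEN_RE.findall(smiles)
        if "".join(toks) != smiles:
            raise ValueError(f"cannot tokenize SMILES: {smiles!r}")
        seen.update(toks)
    return Vocabulary(tokens=(PAD, START, END, *sorted(seen)))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class GeneratorModel:
    """Stacked-GRU SMILES language model with explicit parameter arrays.

    Parameters live in ``self.params`` (dict of float64 arrays); gate weights
    are stored concatenated as [reset | update | candidate] blocks.
    """

    def __init__(
        self,
        vocabulary: Vocabulary,
        embedding_dim: int = 128,
        hidden_size: int = 256,
        n_layers: int = 3,
        seed: int = 0,
    ) -> None:
        self.vocabulary = vocabulary
        self.embedding_dim = embedding_dim
        self.hidden_size = hidden_size
        self.n_layers = n_layers
        self.seed = seed
        rng = np.random.default_rng(seed)
        v = len(vocabulary)
        p: dict[str, np.ndarray] = {}
        p["E"] = rng.normal(0.0, 0.1, size=(v, embedding_dim))
        for layer in range(n_layers):
            d_in = embedding_dim if layer == 0 else hidden_size
            s_in = 1.0 / np.sqrt(d_in)
            s_h = 1.0 / np.sqrt(hidden_size)
            p[f"Wx{layer}"] = rng.uniform(-s_in, s_in, size=(d_in, 3 * hidden_size))
            p[f"Wh{layer}"] = rng.uniform(-s_h, s_h, size=(hidden_size, 3 * hidden_size))
            p[f"bx{layer}"] = np.zeros(3 * hidden_size)
            p[f"bh{layer}"] = np.zeros(3 * hidden_size)
        s_o = 1.0 / np.sqrt(hidden_size)
        p["Wo"] = rng.uniform(-s_o, s_o, size=(hidden_size, v))
        p["bo"] = np.zeros(v)
        self.params = p

    # -- utilities ---------------------------------------------------------

    def clone(self) -> "GeneratorModel":
        dup = GeneratorModel.__new__(GeneratorModel)
        dup.vocabulary = self.vocabulary
        dup.embedding_dim = self.embedding_dim
        dup.hidden_size = self.hidden_size
        dup.n_layers = self.n_layers
        dup.seed = self.seed
        dup.params = {k: v.copy() for k, v in self.params.items()}
        return dup

    def _gru_cell(self, layer: int, x: np.ndarray, h_prev: np.ndarray):
        """One GRU step for a batch; returns h and the cache for backward."""
        H = self.hidden_size
        p = self.params
        gx = x @ p[f"Wx{layer}"] + p[f"bx{layer}"]
        gh = h_prev @ p[f"Wh{layer}"] + p[f"bh{layer}"]
        r = _sigmoid(gx[:, :H] + gh[:, :H])
        z = _sigmoid(gx[:, H : 2 * H] + gh[:, H : 2 * H])
        m = gh[:, 2 * H :]  # hidden-side candidate preactivation
        n = np.tanh(gx[:, 2 * H :] + r * m)
        h = (1.0 - z) * n + z * h_prev
        return h, (x, h_prev, r, z, n, m)

    def step(self, token_ids: np.ndarray, hidden: Optional[list[np.ndarray]]):
        """Single autoregressive step: logits for the next token.

        ``hidden`` is a list of per-layer states (or None to start); used for
        sampling, no caches kept.
        """
        B = len(token_ids)
        if hidden is None:
            hidden = [np.zeros((B, self.hidden_size)) for _ in range(self.n_layers)]
        x = self.params["E"][token_ids]
        new_hidden = []
        for layer in range(self.n_layers):
            h, _ = self._gru_cell(layer, x, hidden[layer])
            new_hidden.append(h)
            x = h
        logits = x @ self.params["Wo"] + self.params["bo"]
        return logits, new_hidden

    # -- teacher-forced forward / backward ---------------------------------

    def forward(self, inputs: np.ndarray):
        """Teacher-forced forward over a padded batch (B, T).

        Returns logits (B, T, V) and the cache needed by backward.
        """
        B, T = inputs.shape
        H = self.hidden_size
        embedded = self.params["E"][inputs]  # (B, T, E)
        h = [np.zeros((B, H)) for _ in range(self.n_layers)]
        caches: list[list] = [[] for _ in range(self.n_layers)]
        tops = np.empty((B, T, H))
        for t in range(T):
            x = embedded[:, t]
            for layer in range(self.n_layers):
                h_new, cache = self._gru_cell(layer, x, h[layer])
                caches[layer].append(cache)
                h[layer] = h_new
                x = h_new
            tops[:, t] = x
        logits = tops @ self.params["Wo"] + self.params["bo"]
        return logits, {"inputs": inputs, "caches": caches, "tops": tops}

    def loglik(self, sequences: np.ndarray) -> np.ndarray:
        """Per-sequence log-likelihood of padded encoded sequences (B, T+1)."""
        logits, _ = self.forward(sequences[:, :-1])
        return _gather_loglik(logits, sequences[:, 1:], self.vocabulary.pad)

    def backward_loglik(self, cache: dict, targets: np.ndarray, coeff: np.ndarray):
        """Gradients of J = sum_i coeff_i * loglik_i w.r.t. all parameters."""
        p = self.params
        H = self.hidden_size
        inputs = cache["inputs"]
        B, T = inputs.shape
        tops = cache["tops"]
        caches = cache["caches"]
        logits = tops @ p["Wo"] + p["bo"]
        probs = _softmax(logits)
        mask = targets != self.vocabulary.pad
        # dJ/dlogits = coeff * (onehot(target) - p)
        dlogits = -probs
        rows = np.repeat(np.arange(B), T)
        cols = np.tile(np.arange(T), B)
        dlogits[rows, cols, targets.ravel()] += 1.0
        dlogits *= (coeff[:, None] * mask)[:, :, None]

        grads = {k: np.zeros_like(v) for k, v in p.items()}
        grads["Wo"] = np.einsum("bth,btv->hv", tops, dlogits)
        grads["bo"] = dlogits.sum(axis=(0, 1))
        dtops = dlogits @ p["Wo"].T  # (B, T, H)

        d_embedded = np.zeros((B, T, self.embedding_dim))
        # backprop layers top-down; dx of layer l feeds layer l-1's dh stream
        dx_stream = dtops
        for layer in range(self.n_layers - 1, -1, -1):
            Wh = p[f"Wh{layer}"]
            Wx = p[f"Wx{layer}"]
            dWx = grads[f"Wx{layer}"]
            dWh = grads[f"Wh{layer}"]
            dbx = grads[f"bx{layer}"]
            dbh = grads[f"bh{layer}"]
            dh_next = np.zeros((B, H))
            dx_out = np.empty((B, T, Wx.shape[0]))
            layer_cache = caches[layer]
            for t in range(T - 1, -1, -1):
                x, h_prev, r, z, n, m = layer_cache[t]
                dh = dx_stream[:, t] + dh_next
                dn = dh * (1.0 - z)
                dz = dh * (h_prev - n)
                dh_prev = dh * z
                da_n = dn * (1.0 - n * n)
                da_z = dz * z * (1.0 - z)
                dr = da_n * m
                dm = da_n * r
                da_r = dr * r * (1.0 - r)
                dgx = np.concatenate([da_r, da_z, da_n], axis=1)
                dgh = np.concatenate([da_r, da_z, dm], axis=1)
                dWx += x.T @ dgx
                dWh += h_prev.T @ dgh
                dbx += dgx.sum(axis=0)
                dbh += dgh.sum(axis=0)
                dh_prev += dgh @ Wh.T
                dx_out[:, t] = dgx @ Wx.T
                dh_next = dh_prev
            dx_stream = dx_out
        d_embedded = dx_stream  # gradient w.r.t. the embedding lookups
        np.add.at(grads["E"], inputs.ravel(), d_embedded.reshape(B * T, -1))
        return grads


def _softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def _gather_loglik(logits: np.ndarray, targets: np.ndarray, pad: int) -> np.ndarray:
    logp = logits - logits.max(axis=-1, keepdims=True)
    logp = logp - np.log(np.exp(logp).sum(axis=-1, keepdims=True))
    B, T = targets.shape
    picked = logp[np.repeat(np.arange(B), T), np.tile(np.arange(T), B), targets.ravel()]
    picked = picked.reshape(B, T)
    picked[targets == pad] = 0.0
    return picked.sum(axis=1)


def pad_sequences(sequences: Sequence[np.ndarray], pad: int) -> np.ndarray:
    T = max(len(s) for s in sequences)
    out = np.full((len(sequences), T), pad, dtype=np.int64)
    for i, s in enumerate(sequences):
        out[i, : len(s)] = s
    return out


class Adam:
    """Adam with global-norm gradient clipping (clip at norm 3 by default)."""

    def __init__(self, params: dict, lr: float, betas=(0.9, 0.999), eps=1e-8, clip_norm=3.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict) -> None:
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                grads = {k: g * scale for k, g in grads.items()}
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class GeneratedBatch:
    """Sampled SMILES with per-sequence likelihoods and validity flags."""

    smiles: list[str]
    agent_nll: np.ndarray
    prior_nll: Optional[np.ndarray]
    is_valid: np.ndarray
    token_ids: list[np.ndarray] = field(repr=False, default_factory=list)


def sequence_nll(model: GeneratorModel, smiles: str) -> float:
    """NLL of one SMILES under the model (includes the end token)."""
    seq = model.vocabulary.encode(smiles)
    return float(-model.loglik(seq[None, :])[0])


def sequence_nll_many(model: GeneratorModel, smiles: Sequence[str]) -> np.ndarray:
    seqs = [model.vocabulary.encode(s) for s in smiles]
    padded = pad_sequences(seqs, model.vocabulary.pad)
    return -model.loglik(padded)


def _mean_nll(model: GeneratorModel, padded: np.ndarray) -> float:
    return float(-model.loglik(padded).mean())


def train_lm(
    model: GeneratorModel,
    corpus: Sequence[str],
    epochs: int = 10,
    learning_rate: float = 0.01,
    batch_size: int = 32,
    seed: int = 0,
) -> list[float]:
    """Maximum-likelihood training; returns the mean-NLL trace.

    The trace has ``epochs + 1`` entries: the mean corpus NLL before training
    and after each epoch. A NaN loss aborts with a diagnostic.
    """
    if not corpus:
        raise ValueError("empty corpus")
    seqs = [model.vocabulary.encode(s) for s in corpus]
    padded_all = pad_sequences(seqs, model.vocabulary.pad)
    optimizer = Adam(model.params, lr=learning_rate)
    rng = np.random.default_rng(seed)
    trace = [_mean_nll(model, padded_all)]
    order = np.arange(len(seqs))
    for _ in range(epochs):
        rng.shuffle(order)
        for lo in range(0, len(order), batch_size):
            idx = order[lo : lo + batch_size]
            batch = pad_sequences([seqs[i] for i in idx], model.vocabulary.pad)
            inputs, targets = batch[:, :-1], batch[:, 1:]
            logits, cache = model.forward(inputs)
            loglik = _gather_loglik(logits, targets, model.vocabulary.pad)
            loss = float(-loglik.mean())
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged: mean NLL = {loss}")
            coeff = np.full(len(idx), -1.0 / len(idx))
            grads = model.backward_loglik(cache, targets, coeff)
            optimizer.step(grads)
        trace.append(_mean_nll(model, padded_all))
    return trace


def fine_tune(
    model: GeneratorModel,
    focus_set: Sequence[str],
    epochs: int = 20,
    learning_rate: float = 0.01,
    batch_size: int = 32,
    seed: int = 0,
) -> list[float]:
    """Transfer learning: continue NLL training on a focused compound set."""
    if not focus_set:
        raise ValueError("empty focus set")
    return train_lm(model, focus_set, epochs, learning_rate, batch_size, seed)


def sample_batch(
    model: GeneratorModel,
    n: int,
    temperature: float = 1.0,
    max_len: int = 140,
    seed: int | np.random.Generator = 0,
) -> GeneratedBatch:
    """Sample n sequences token-by-token from softmax(logits / temperature).

    The recorded ``agent_nll`` is always the untempered (temperature 1)
    likelihood of the sampled tokens, so downstream RL arithmetic does not
    depend on the sampling temperature. Validity flags come from RDKit
    canonicalization of the decoded strings.
    """
    from .chem import canonicalize  # local import to avoid cycle at load

    if n <= 0:
        raise ValueError("n must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vocab = model.vocabulary
    tokens = np.full((n,), vocab.start, dtype=np.int64)
    hidden = None
    finished = np.zeros(n, dtype=bool)
    nll = np.zeros(n)
    sampled: list[list[int]] = [[] for _ in range(n)]
    for _ in range(max_len):
        logits, hidden = model.step(tokens, hidden)
        logp1 = np.log(_softmax(logits) + 1e-300)  # untempered model log-probs
        logits[:, vocab.pad] = -1e30  # specials are never sampled
        logits[:, vocab.start] = -1e30
        probs_t = _softmax(logits / temperature)
        u = rng.random(n)
        choices = (probs_t.cumsum(axis=1) < u[:, None]).sum(axis=1)
        choices = np.minimum(choices, len(vocab) - 1)
        for i in range(n):
            if finished[i]:
                continue
            c = int(choices[i])
            nll[i] -= logp1[i, c]
            sampled[i].append(c)
            if c == vocab.end:
                finished[i] = True
        tokens = np.where(finished, vocab.end, choices).astype(np.int64)
        if finished.all():
            break
    smiles = [vocab.decode(s) for s in sampled]
    records = [canonicalize(s) for s in smiles]
    # sequences truncated at max_len carry no end token, so a teacher-forced
    # pass over token_ids reproduces the recorded agent_nll exactly
    token_ids = [np.array([vocab.start] + s, dtype=np.int64) for s in sampled]
    return GeneratedBatch(
        smiles=smiles,
        agent_nll=nll,
        prior_nll=None,
        is_valid=np.array([r.is_valid for r in records]),
        token_ids=token_ids,
    )


def save_model(model: GeneratorModel, path) -> None:
    """Checkpoint: .npz weight archive plus a JSON architecture sidecar."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.params)
    sidecar = {
        "tokens": list(model.vocabulary.tokens),
        "embedding_dim": model.embedding_dim,
        "hidden_size": model.hidden_size,
        "n_layers": model.n_layers,
        "seed": model.seed,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_model(path) -> GeneratorModel:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    vocab = Vocabulary(tokens=tuple(sidecar["tokens"]))
    model = GeneratorModel(
        vocab,
        embedding_dim=sidecar["embedding_dim"],
        hidden_size=sidecar["hidden_size"],
        n_layers=sidecar["n_layers"],
        seed=sidecar["seed"],
    )
    with np.load(path.with_suffix(".npz")) as data:
        model.params = {k: data[k].copy() for k in data.files}
    return model
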