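"""Autoregressive SMILES language models: GRU/LSTM RNNs, a causal
transformer encoder (Tr) and its gated variant (GTr).

All models share one contract: given a token sequence
``START x_1 ... x_L END`` they emit, at each position, a probability
distribution over the next token; the sequence log-likelihood
``logP(A) = sum_t log P(x_t | x_<t)`` includes the END token and excludes
padding. Maximum-likelihood training minimises the mean negative
log-likelihood; sampling draws tokens autoregressively until END.

The gated transformer follows the stabilised-transformer recipe for RL:
layer normalisation is moved before each sub-layer and the residual
connection is replaced by a GRU-style gate whose bias is initialised
positive so the layer starts close to the identity map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .autodiff import Adam, Module, Parameter, Tensor, no_grad, stack
from .chem import MoleculeRecord
from .vocabulary import DEFAULT_MAX_LEN, TokenSequence, Vocabulary

ARCHS = ("gru_rnn", "lstm_rnn", "transformer", "gated_transformer")

CHECKPOINT_FORMAT = "smilesrl-checkpoint-1"


@dataclass(frozen=True)
class ModelConfig:
    arch: str = "lstm_rnn"
    embedding_dim: int = 128
    hidden_dim: int = 512
    n_layers: int = 3
    n_heads: int = 8          # transformers only
    ffn_dim: int = 1024       # transformers only
    dropout: float = 0.0
    max_len: int = DEFAULT_MAX_LEN
    gate_bias: float = 2.0    # gated transformer only

    def __post_init__(self):
        if self.arch not in ARCHS:
            raise ValueError(f"unknown arch {self.arch!r}; expected one of {ARCHS}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


#: Published configurations (layer sizes, dropout) plus a desk-scale preset.
PRESETS: dict[str, ModelConfig] = {
    # embedding 128 + three GRU layers of 512, no dropout
    "reinvent_gru": ModelConfig(arch="gru_rnn", embedding_dim=128,
                                hidden_dim=512, n_layers=3, dropout=0.0),
    # embedding 256 + three LSTM layers of 512, no dropout
    "reinvent2_lstm": ModelConfig(arch="lstm_rnn", embedding_dim=256,
                                  hidden_dim=512, n_layers=3, dropout=0.0),
    # three LSTM layers of 512 with dropout 0.2 (embedding size is this
    # package's choice; the source configuration does not state one)
    "guacamol_lstm": ModelConfig(arch="lstm_rnn", embedding_dim=256,
                                 hidden_dim=512, n_layers=3, dropout=0.2),
    # 4 encoder layers, model dim 512, 8 heads, FFN 1024, dropout 0.1
    "transformer": ModelConfig(arch="transformer", embedding_dim=512,
                               hidden_dim=512, n_layers=4, n_heads=8,
                               ffn_dim=1024, dropout=0.1),
    "gated_transformer": ModelConfig(arch="gated_transformer",
                                     embedding_dim=512, hidden_dim=512,
                                     n_layers=4, n_heads=8, ffn_dim=1024,
                                     dropout=0.1),
    # small enough to train in seconds-to-minutes on one CPU
    "toy_lstm": ModelConfig(arch="lstm_rnn", embedding_dim=64, hidden_dim=128,
                            n_layers=2, dropout=0.0),
}


@dataclass(frozen=True)
class SequenceLikelihood:
    """Total log-likelihood logP(A) of one molecule under one model."""

    total_logp: float
    per_step_logp: tuple[float, ...] | None = None


@dataclass
class GenerationBatch:
    sequences: list[TokenSequence]
    smiles: list[str]
    agent_likelihoods: list[SequenceLikelihood]

    @property
    def batch_size(self) -> int:
        return len(self.sequences)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

def _init(rng: np.random.Generator, *shape, scale: float | None = None) -> np.ndarray:
    scale = scale if scale is not None else 1.0 / np.sqrt(shape[0])
    return rng.uniform(-scale, scale, size=shape)


class Linear(Module):
    def __init__(self, rng, d_in: int, d_out: int, bias: bool = True):
        self.W = Parameter(_init(rng, d_in, d_out))
        self.b = Parameter(np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        return out if self.b is None else out + self.b


class Embedding(Module):
    def __init__(self, rng, n_tokens: int, dim: int):
        self.W = Parameter(rng.normal(0, 0.1, size=(n_tokens, dim)))

    def __call__(self, indices: np.ndarray) -> Tensor:
        return self.W[(indices,)]


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centred = x - mu
        var = (centred ** 2).mean(axis=-1, keepdims=True)
        return centred / ((var + self.eps) ** 0.5) * self.gamma + self.beta


class GRUCell(Module):
    def __init__(self, rng, d_in: int, d_hid: int):
        self.d_hid = d_hid
        self.Wx = Parameter(_init(rng, d_in, 3 * d_hid))
        self.Wh = Parameter(_init(rng, d_hid, 3 * d_hid))
        self.b = Parameter(np.zeros(3 * d_hid))

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        H = self.d_hid
        gx = x @ self.Wx + self.b
        gh = h @ self.Wh
        r = (gx[:, :H] + gh[:, :H]).sigmoid()
        z = (gx[:, H:2 * H] + gh[:, H:2 * H]).sigmoid()
        n = (gx[:, 2 * H:] + r * gh[:, 2 * H:]).tanh()
        return (1.0 - z) * n + z * h


class LSTMCell(Module):
    def __init__(self, rng, d_in: int, d_hid: int):
        self.d_hid = d_hid
        self.Wx = Parameter(_init(rng, d_in, 4 * d_hid))
        self.Wh = Parameter(_init(rng, d_hid, 4 * d_hid))
        self.b = Parameter(np.zeros(4 * d_hid))

    def __call__(self, x: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        H = self.d_hid
        g = x @ self.Wx + h @ self.Wh + self.b
        i = g[:, :H].sigmoid()
        f = g[:, H:2 * H].sigmoid()
        o = g[:, 2 * H:3 * H].sigmoid()
        u = g[:, 3 * H:].tanh()
        c_new = f * c + i * u
        return o * c_new.tanh(), c_new


def sinusoidal_positions(max_len: int, dim: int) -> np.ndarray:
    pos = np.arange(max_len)[:, None]
    div = np.exp(np.arange(0, dim, 2) * (-np.log(10000.0) / dim))
    pe = np.zeros((max_len, dim))
    pe[:, 0::2] = np.sin(pos * div)
    pe[:, 1::2] = np.cos(pos * div)[:, : dim // 2]
    return pe


class MultiHeadSelfAttention(Module):
    def __init__(self, rng, dim: int, n_heads: int):
        if dim % n_heads:
            raise ValueError("dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = dim // n_heads
        self.q = Linear(rng, dim, dim)
        self.k = Linear(rng, dim, dim)
        self.v = Linear(rng, dim, dim)
        self.out = Linear(rng, dim, dim)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        # Autoregression depends on the causal mask: refuse to run without it.
        if mask is None:
            raise ValueError("causal mask is required for autoregressive attention")
        B, T, D = x.shape
        nh, dh = self.n_heads, self.d_head

        def split(t: Tensor) -> Tensor:  # (B,T,D) -> (B,nh,T,dh)
            return t.reshape(B, T, nh, dh).transpose(0, 2, 1, 3)

        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        scores = scores + Tensor(mask)          # additive -inf style mask
        attn = scores.softmax(axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, T, D)
        return self.out(ctx)


class TransformerLayer(Module):
    """Original post-norm encoder layer with residual connections."""

    def __init__(self, rng, dim: int, n_heads: int, ffn_dim: int):
        self.attn = MultiHeadSelfAttention(rng, dim, n_heads)
        self.ln1 = LayerNorm(dim)
        self.ff1 = Linear(rng, dim, ffn_dim)
        self.ff2 = Linear(rng, ffn_dim, dim)
        self.ln2 = LayerNorm(dim)

    def __call__(self, x: Tensor, mask: np.ndarray, dropout_fn) -> Tensor:
        x = self.ln1(x + dropout_fn(self.attn(x, mask)))
        x = self.ln2(x + dropout_fn(self.ff2(self.ff1(x).relu())))
        return x


class GRUGate(Module):
    """GRU-style gate replacing a residual connection: combines the stream
    input x with the sub-layer output y. With the update gate shut (large
    bias, zero gate weights) the gate passes x through unchanged."""

    def __init__(self, rng, dim: int, bias: float):
        self.Wr = Linear(rng, dim, dim, bias=False)
        self.Ur = Linear(rng, dim, dim, bias=False)
        self.Wz = Linear(rng, dim, dim, bias=False)
        self.Uz = Linear(rng, dim, dim, bias=False)
        self.Wg = Linear(rng, dim, dim, bias=False)
        self.Ug = Linear(rng, dim, dim, bias=False)
        self.bg = Parameter(np.full(dim, float(bias)))

    def __call__(self, x: Tensor, y: Tensor) -> Tensor:
        r = (self.Wr(y) + self.Ur(x)).sigmoid()
        z = (self.Wz(y) + self.Uz(x) - self.bg).sigmoid()
        h = (self.Wg(y) + self.Ug(r * x)).tanh()
        return (1.0 - z) * x + z * h


class GatedTransformerLayer(Module):
    """Pre-norm encoder layer with GRU-style gating in place of residuals."""

    def __init__(self, rng, dim: int, n_heads: int, ffn_dim: int, gate_bias: float):
        self.attn = MultiHeadSelfAttention(rng, dim, n_heads)
        self.ln1 = LayerNorm(dim)
        self.gate1 = GRUGate(rng, dim, gate_bias)
        self.ff1 = Linear(rng, dim, ffn_dim)
        self.ff2 = Linear(rng, ffn_dim, dim)
        self.ln2 = LayerNorm(dim)
        self.gate2 = GRUGate(rng, dim, gate_bias)

    def __call__(self, x: Tensor, mask: np.ndarray, dropout_fn) -> Tensor:
        x = self.gate1(x, dropout_fn(self.attn(self.ln1(x), mask)).relu())
        x = self.gate2(x, dropout_fn(self.ff2(self.ff1(self.ln2(x)).relu())).relu())
        return x


# ---------------------------------------------------------------------------
# The language model
# ---------------------------------------------------------------------------

class SmilesLM(Module):
    """Autoregressive SMILES language model over a fixed vocabulary."""

    def __init__(self, vocab: Vocabulary, config: ModelConfig | str = "toy_lstm",
                 seed: int = 0):
        if isinstance(config, str):
            config = PRESETS[config]
        self.vocab = vocab
        self.config = config
        self.seed = seed
        self.training = False
        rng = np.random.default_rng(seed)
        V, E, H = len(vocab), config.embedding_dim, config.hidden_dim
        self.embedding = Embedding(rng, V, E)
        if config.arch in ("gru_rnn", "lstm_rnn"):
            cell_cls = GRUCell if config.arch == "gru_rnn" else LSTMCell
            self.cells = [cell_cls(rng, E if i == 0 else H, H)
                          for i in range(config.n_layers)]
            self.head = Linear(rng, H, V)
        else:
            D = E
            self.pos = sinusoidal_positions(config.max_len, D)
            layer_cls = (TransformerLayer if config.arch == "transformer"
                         else GatedTransformerLayer)
            extra = () if config.arch == "transformer" else (config.gate_bias,)
            self.layers = [layer_cls(rng, D, config.n_heads, config.ffn_dim, *extra)
                           for _ in range(config.n_layers)]
            self.final_ln = LayerNorm(D)
            self.head = Linear(rng, D, V)
        self._dropout_rng = np.random.default_rng(seed + 1)

    # -- utilities ------------------------------------------------------------

    def clone(self, requires_grad: bool = True) -> "SmilesLM":
        """Deep copy with identical parameters (e.g. agent from prior)."""
        other = SmilesLM(self.vocab, self.config, seed=self.seed)
        other.load_state_arrays([a.copy() for a in self.state_arrays()])
        return other

    def param_checksum(self) -> float:
        return float(sum(np.abs(a).sum() for a in self.state_arrays()))

    def _dropout(self, x: Tensor) -> Tensor:
        p = self.config.dropout
        if not self.training or p == 0.0:
            return x
        mask = (self._dropout_rng.random(x.shape) >= p) / (1.0 - p)
        return x * Tensor(mask)

    def _pad_batch(self, sequences: Sequence[TokenSequence]) -> np.ndarray:
        T = max(len(s) for s in sequences)
        if T > self.config.max_len:
            raise ValueError(f"sequence length {T} exceeds max_len {self.config.max_len}")
        out = np.full((len(sequences), T), self.vocab.pad, dtype=np.int64)
        for i, s in enumerate(sequences):
            out[i, :len(s)] = s.indices
        return out

    # -- forward --------------------------------------------------------------

    def logits(self, token_matrix: np.ndarray) -> Tensor:
        """Next-token logits at every position of (B, T) input tokens -> (B, T, V)."""
        if self.config.arch in ("gru_rnn", "lstm_rnn"):
            return self._rnn_logits(token_matrix)
        return self._transformer_logits(token_matrix)

    def _rnn_logits(self, tokens: np.ndarray) -> Tensor:
        B, T = tokens.shape
        H = self.config.hidden_dim
        emb = self._dropout(self.embedding(tokens))  # (B,T,E)
        hs = [Tensor(np.zeros((B, H))) for _ in self.cells]
        cs = [Tensor(np.zeros((B, H))) for _ in self.cells]
        outputs: list[Tensor] = []
        lstm = self.config.arch == "lstm_rnn"
        for t in range(T):
            x = emb[:, t, :]
            for i, cell in enumerate(self.cells):
                if lstm:
                    hs[i], cs[i] = cell(x, hs[i], cs[i])
                else:
                    hs[i] = cell(x, hs[i])
                x = self._dropout(hs[i])
            outputs.append(self.head(x))
        return stack(outputs, axis=1)  # (B,T,V)

    def _transformer_logits(self, tokens: np.ndarray) -> Tensor:
        B, T = tokens.shape
        x = self.embedding(tokens) + Tensor(self.pos[:T])
        x = self._dropout(x)
        mask = np.triu(np.full((T, T), -1e9), k=1)  # causal: no peeking ahead
        for layer in self.layers:
            x = layer(x, mask, self._dropout)
        if self.config.arch == "gated_transformer":
            x = self.final_ln(x)
        return self.head(x)

    # -- likelihood -----------------------------------------------------------

    def sequence_logps(self, sequences: Sequence[TokenSequence]) -> Tensor:
        """Gradient-capable total logP(A) per sequence, teacher-forced -> (B,)."""
        mat = self._pad_batch(sequences)
        inputs, targets = mat[:, :-1], mat[:, 1:]
        mask = (targets != self.vocab.pad).astype(np.float64)
        logp = self.logits(inputs).log_softmax(axis=-1)  # (B,T,V)
        B, T = targets.shape
        bidx = np.repeat(np.arange(B), T)
        tidx = np.tile(np.arange(T), B)
        picked = logp[(bidx, tidx, targets.ravel())].reshape(B, T)
        return (picked * Tensor(mask)).sum(axis=1)

    def likelihood(self, sequences: Sequence[TokenSequence],
                   per_step: bool = False) -> list[SequenceLikelihood]:
        """Per-molecule logP(A); END included, PAD excluded."""
        with no_grad():
            mat = self._pad_batch(sequences)
            inputs, targets = mat[:, :-1], mat[:, 1:]
            logp = self.logits(inputs).log_softmax(axis=-1).data
            out = []
            for i, seq in enumerate(sequences):
                L = len(seq) - 1  # decisions: every token after START, incl END
                steps = tuple(float(logp[i, t, targets[i, t]]) for t in range(L))
                out.append(SequenceLikelihood(
                    total_logp=float(sum(steps)),
                    per_step_logp=steps if per_step else None))
        return out

    def step_distributions(self, sequences: Sequence[TokenSequence],
                           grad: bool = False) -> tuple[Tensor, np.ndarray]:
        """Full per-step next-token distributions P(.|x_<t) -> ((B,T,V), mask)."""
        mat = self._pad_batch(sequences)
        inputs, targets = mat[:, :-1], mat[:, 1:]
        mask = (targets != self.vocab.pad).astype(np.float64)
        if grad:
            probs = self.logits(inputs).softmax(axis=-1)
        else:
            with no_grad():
                probs = self.logits(inputs).softmax(axis=-1)
        return probs, mask

    # -- sampling -------------------------------------------------------------

    def sample_batch(self, n: int, max_len: int | None = None,
                     temperature: float = 1.0,
                     seed: int | None = None,
                     rng: np.random.Generator | None = None) -> GenerationBatch:
        """Sample ``n`` sequences autoregressively.

        Sequences that hit ``max_len`` without emitting END are kept
        (truncated); they typically decode to invalid SMILES and are scored
        accordingly downstream. ``temperature`` scales logits at draw time;
        the recorded likelihood is always the model's own (temperature-1)
        log-probability of the realized tokens.
        """
        if n < 1:
            raise ValueError("n must be >= 1")
        if temperature <= 0:
            raise ValueError("temperature must be positive (use a small value for near-greedy)")
        max_len = max_len or self.config.max_len
        rng = rng if rng is not None else np.random.default_rng(seed)
        with no_grad():
            if self.config.arch in ("gru_rnn", "lstm_rnn"):
                tokens = self._sample_rnn(n, max_len, temperature, rng)
            else:
                tokens = self._sample_transformer(n, max_len, temperature, rng)
        sequences = [TokenSequence(indices=tuple(row)) for row in tokens]
        smiles = [self.vocab.decode(s) for s in sequences]
        lls = self.likelihood(sequences)
        return GenerationBatch(sequences=sequences, smiles=smiles,
                               agent_likelihoods=lls)

    def _draw(self, logits: np.ndarray, temperature: float,
              rng: np.random.Generator) -> np.ndarray:
        z = logits / temperature
        z = z - z.max(axis=-1, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=-1, keepdims=True)
        cum = p.cumsum(axis=-1)
        u = rng.random((logits.shape[0], 1))
        return (u > cum).sum(axis=-1).astype(np.int64)

    def _sample_rnn(self, n, max_len, temperature, rng) -> list[list[int]]:
        H = self.config.hidden_dim
        hs = [Tensor(np.zeros((n, H))) for _ in self.cells]
        cs = [Tensor(np.zeros((n, H))) for _ in self.cells]
        lstm = self.config.arch == "lstm_rnn"
        current = np.full(n, self.vocab.start, dtype=np.int64)
        seqs = [[self.vocab.start] for _ in range(n)]
        done = np.zeros(n, dtype=bool)
        for _ in range(max_len - 1):
            x = self.embedding(current)
            for i, cell in enumerate(self.cells):
                if lstm:
                    hs[i], cs[i] = cell(x, hs[i], cs[i])
                else:
                    hs[i] = cell(x, hs[i])
                x = hs[i]
            nxt = self._draw(self.head(x).data, temperature, rng)
            nxt[done] = self.vocab.pad
            for j in range(n):
                if not done[j]:
                    seqs[j].append(int(nxt[j]))
            done |= nxt == self.vocab.end
            if done.all():
                break
            current = np.where(done, self.vocab.pad, nxt)
        return seqs

    def _sample_transformer(self, n, max_len, temperature, rng) -> list[list[int]]:
        tokens = np.full((n, 1), self.vocab.start, dtype=np.int64)
        done = np.zeros(n, dtype=bool)
        seqs = [[self.vocab.start] for _ in range(n)]
        for _ in range(max_len - 1):
            logits = self.logits(tokens).data[:, -1, :]
            nxt = self._draw(logits, temperature, rng)
            nxt[done] = self.vocab.pad
            for j in range(n):
                if not done[j]:
                    seqs[j].append(int(nxt[j]))
            done |= nxt == self.vocab.end
            if done.all():
                break
            tokens = np.concatenate([tokens, nxt[:, None]], axis=1)
        return seqs

    # -- maximum-likelihood training -------------------------------------------

    def mean_nll(self, sequences: Sequence[TokenSequence],
                 batch_size: int = 128) -> float:
        """Mean per-sequence negative log-likelihood over a corpus."""
        total = 0.0
        with no_grad():
            for i in range(0, len(sequences), batch_size):
                chunk = sequences[i:i + batch_size]
                total += float(-self.sequence_logps(chunk).data.sum())
        return total / len(sequences)

    def train_mle(self, corpus: Sequence[MoleculeRecord | str],
                  epochs: int = 5, batch_size: int = 128,
                  learning_rate: float = 1e-3, seed: int = 0,
                  verbose: bool = False) -> list[float]:
        """Fit by maximum likelihood; returns the per-epoch mean NLL."""
        smiles = [m if isinstance(m, str) else m.smiles for m in corpus]
        if not smiles:
            raise ValueError("corpus is empty")
        # every molecule must tokenize/encode before any update happens
        sequences = [self.vocab.encode_smiles(s, max_len=self.config.max_len)
                     for s in smiles]
        rng = np.random.default_rng(seed)
        opt = Adam(self.parameters(), lr=learning_rate)
        history: list[float] = []
        self.training = True
        try:
            for epoch in range(epochs):
                order = rng.permutation(len(sequences))
                epoch_nll, count = 0.0, 0
                for i in range(0, len(order), batch_size):
                    batch = [sequences[j] for j in order[i:i + batch_size]]
                    loss = (-self.sequence_logps(batch)).mean()
                    opt.zero_grad()
                    loss.backward()
                    opt.step()
                    epoch_nll += loss.item() * len(batch)
                    count += len(batch)
                history.append(epoch_nll / count)
                if verbose:
                    print(f"epoch {epoch + 1}/{epochs}: mean NLL {history[-1]:.3f}")
        finally:
            self.training = False
        return history

    # -- persistence -----------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Versioned checkpoint: parameters + config + vocabulary in one file."""
        meta = {"format": CHECKPOINT_FORMAT,
                "config": asdict(self.config),
                "vocab": list(self.vocab.tokens),
                "seed": self.seed}
        arrays = {f"param_{i}": a for i, a in enumerate(self.state_arrays())}
        with open(path, "wb") as fh:
            np.savez(fh, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "SmilesLM":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            if meta.get("format") != CHECKPOINT_FORMAT:
                raise ValueError(f"unrecognised checkpoint format in {path}")
            vocab = Vocabulary(tokens=tuple(meta["vocab"]))
            model = cls(vocab, ModelConfig(**meta["config"]), seed=meta["seed"])
            n = sum(1 for k in data.files if k.startswith("param_"))
            model.load_state_arrays([data[f"param_{i}"] for i in range(n)])
        return model
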