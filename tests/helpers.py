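"""Shared model-contract checks used by unit and acceptance tests."""

from __future__ import annotations

import numpy as np

from smilesrl.models import ModelConfig, SmilesLM
from smilesrl.vocabulary import Vocabulary

TINY_CONFIGS = {
    "gru_rnn": ModelConfig(arch="gru_rnn", embedding_dim=16, hidden_dim=24,
                           n_layers=2),
    "lstm_rnn": ModelConfig(arch="lstm_rnn", embedding_dim=16, hidden_dim=24,
                            n_layers=2),
    "transformer": ModelConfig(arch="transformer", embedding_dim=16,
                               hidden_dim=16, n_layers=2, n_heads=2,
                               ffn_dim=32, dropout=0.0),
    "gated_transformer": ModelConfig(arch="gated_transformer",
                                     embedding_dim=16, hidden_dim=16,
                                     n_layers=2, n_heads=2, ffn_dim=32,
                                     dropout=0.0),
}


def tiny_model(arch: str, vocab: Vocabulary, seed: int = 0) -> SmilesLM:
    return SmilesLM(vocab, TINY_CONFIGS[arch], seed=seed)


def assert_step_distributions_normalized(model: SmilesLM, vocab: Vocabulary,
                                         smiles: list[str],
                                         tol: float = 1e-5) -> None:
    seqs = [vocab.encode_smiles(x) for x in smiles]
    probs, mask = model.step_distributions(seqs)
    sums = probs.data.sum(axis=-1)
    assert np.all(np.abs(sums[mask.astype(bool)] - 1.0) < tol)


def assert_causal(model: SmilesLM, vocab: Vocabulary) -> None:
    """Distributions at step t must not change when tokens after t change."""
    a = vocab.encode_smiles("CCOCC")
    b = vocab.encode_smiles("CCOOO")  # same first two body tokens
    pa, _ = model.step_distributions([a])
    pb, _ = model.step_distributions([b])
    # inputs agree at positions 0..2 (START, C, C) so steps 0..2 must match
    np.testing.assert_allclose(pa.data[0, :3], pb.data[0, :3], atol=1e-10)
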