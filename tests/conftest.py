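"""Shared fixtures: the toy study conditions.

The expensive fixtures are session-scoped: a 500-molecule synthetic corpus,
a toy LSTM prior trained on it by maximum likelihood, and the
AHC-vs-REINVENT comparison runs that both the learning-sanity test and the
sample-efficiency acceptance test read their curves from.
"""

from __future__ import annotations

import numpy as np
import pytest

import smilesrl as s
from smilesrl.models import SmilesLM
from smilesrl.rl import RLConfig, rl_run
from smilesrl.scoring import TanimotoSimilarityTask

CORPUS_SIZE = 500
CORPUS_SEED = 7
PRIOR_EPOCHS = 150
PRIOR_SEED = 0
COMPARISON_SEEDS = (101, 102, 103)
COMPARISON_STEP_CAP = 150


@pytest.fixture(scope="session")
def toy_corpus() -> list[s.MoleculeRecord]:
    return s.generate_corpus(s.SyntheticCorpusSpec(
        n_molecules=CORPUS_SIZE, seed=CORPUS_SEED))


@pytest.fixture(scope="session")
def mini_corpus() -> list[s.MoleculeRecord]:
    return s.generate_corpus(s.SyntheticCorpusSpec(n_molecules=60, seed=3))


@pytest.fixture(scope="session")
def vocab(toy_corpus) -> s.Vocabulary:
    return s.Vocabulary.from_corpus(m.smiles for m in toy_corpus)


@pytest.fixture(scope="session")
def toy_prior(toy_corpus, vocab) -> SmilesLM:
    """The toy prior: 2x128 LSTM trained to convergence on the corpus."""
    model = SmilesLM(vocab, "toy_lstm", seed=PRIOR_SEED)
    model.train_mle(toy_corpus, epochs=PRIOR_EPOCHS, batch_size=64,
                    learning_rate=1e-3, seed=PRIOR_SEED)
    return model


@pytest.fixture(scope="session")
def held_out_reference(toy_corpus) -> str:
    """A generator molecule outside the training corpus, of median size."""
    known = {m.smiles for m in toy_corpus}
    extra = s.generate_corpus(s.SyntheticCorpusSpec(
        n_molecules=CORPUS_SIZE + 20, seed=CORPUS_SEED))
    held = [m for m in extra if m.smiles not in known]
    sizes = sorted(m.heavy_atom_count for m in held)
    median = sizes[len(sizes) // 2]
    return next(m.smiles for m in held if m.heavy_atom_count == median)


@pytest.fixture(scope="session")
def comparison_curves(toy_prior, held_out_reference):
    """AHC and REINVENT runs (sigma=60, DF2, 3 seeds each) on the held-out
    similarity task; returns {strategy: {seed: list[CurveRecord]}}."""
    curves: dict[str, dict[int, list]] = {}
    for strategy in ("ahc", "reinvent"):
        curves[strategy] = {}
        for seed in COMPARISON_SEEDS:
            cfg = RLConfig(strategy=strategy, sigma=60.0, batch_size=64,
                           topk_fraction=0.5, n_steps=COMPARISON_STEP_CAP,
                           seed=seed)
            run = rl_run(toy_prior, TanimotoSimilarityTask(held_out_reference),
                         "DF2", cfg, stop_at_mean_reward=0.5)
            curves[strategy][seed] = run.records
    return curves


def first_step_reaching(records, threshold: float) -> float:
    """First RL step whose batch-mean reward reaches threshold; inf if never."""
    for rec in records:
        if rec.mean_reward >= threshold:
            return rec.step
    return float("inf")
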