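"""Generative-model contracts: presets, likelihoods, sampling, training."""

import numpy as np
import pytest

import smilesrl as s
from smilesrl.autodiff import Tensor
from smilesrl.models import (PRESETS, GatedTransformerLayer, ModelConfig,
                             SmilesLM)
from smilesrl.vocabulary import Vocabulary

from helpers import TINY_CONFIGS, assert_causal, \
    assert_step_distributions_normalized, tiny_model

ARCHS = list(TINY_CONFIGS)


class TestPresets:
    def test_published_layer_dimensions(self):
        g = PRESETS["reinvent_gru"]
        assert (g.arch, g.embedding_dim, g.hidden_dim, g.n_layers,
                g.dropout) == ("gru_rnn", 128, 512, 3, 0.0)
        l2 = PRESETS["reinvent2_lstm"]
        assert (l2.arch, l2.embedding_dim, l2.hidden_dim, l2.n_layers,
                l2.dropout) == ("lstm_rnn", 256, 512, 3, 0.0)
        gm = PRESETS["guacamol_lstm"]
        assert (gm.arch, gm.hidden_dim, gm.n_layers, gm.dropout) == \
            ("lstm_rnn", 512, 3, 0.2)
        tr = PRESETS["transformer"]
        assert (tr.n_layers, tr.hidden_dim, tr.n_heads, tr.ffn_dim,
                tr.dropout) == (4, 512, 8, 1024, 0.1)

    def test_presets_are_immutable(self):
        with pytest.raises(AttributeError):
            PRESETS["transformer"].dropout = 0.5

    def test_unknown_arch_rejected(self):
        with pytest.raises(ValueError, match="arch"):
            ModelConfig(arch="mamba")


class TestLikelihood:
    def test_uniform_model_has_closed_form_likelihood(self, vocab):
        # zeroing the output head makes every next-token distribution uniform
        model = tiny_model("lstm_rnn", vocab)
        model.head.W.data[:] = 0.0
        model.head.b.data[:] = 0.0
        seq = vocab.encode_smiles("CCO")
        (ll,) = model.likelihood([seq])
        L = len(seq) - 1  # decisions: C, C, O, END
        assert ll.total_logp == pytest.approx(-L * np.log(len(vocab)))

    def test_per_step_terms_sum_to_total(self, vocab):
        model = tiny_model("gru_rnn", vocab)
        seq = vocab.encode_smiles("CC(N)=O")
        (ll,) = model.likelihood([seq], per_step=True)
        assert sum(ll.per_step_logp) == pytest.approx(ll.total_logp)
        assert ll.total_logp < 0

    def test_total_sequence_mass_is_at_most_one(self):
        # brute-force enumeration of the sequence tree on a 2-letter alphabet
        vocab = Vocabulary(tokens=("<pad>", "<start>", "<end>", "C", "O"))
        model = tiny_model("lstm_rnn", vocab)
        import itertools
        mass = 0.0
        for L in range(0, 4):
            for body in itertools.product("CO", repeat=L):
                seq = vocab.encode(list(body))
                (ll,) = model.likelihood([seq])
                mass += np.exp(ll.total_logp)
        assert mass <= 1.0 + 1e-9

    def test_gradients_flow_through_sequence_logps(self, vocab):
        model = tiny_model("lstm_rnn", vocab)
        loss = (-model.sequence_logps([vocab.encode_smiles("CCO")])).mean()
        loss.backward()
        assert any(p.grad is not None and np.abs(p.grad).sum() > 0
                   for p in model.parameters())

    def test_overlong_sequence_raises(self, vocab):
        model = SmilesLM(vocab, ModelConfig(arch="lstm_rnn", embedding_dim=8,
                                            hidden_dim=8, n_layers=1,
                                            max_len=6))
        with pytest.raises(ValueError, match="max_len"):
            model.sequence_logps([vocab.encode_smiles("CCCCCCCCCC", max_len=20)])


@pytest.mark.parametrize("arch", ARCHS)
class TestArchitectureInvariants:
    def test_step_distributions_normalize(self, arch, vocab):
        model = tiny_model(arch, vocab)
        assert_step_distributions_normalized(
            model, vocab, ["CCO", "NC(=O)C1CCCC1", "c1ccncc1"])

    def test_future_tokens_cannot_influence_past_steps(self, arch, vocab):
        assert_causal(tiny_model(arch, vocab), vocab)

    def test_sampling_is_reproducible_per_seed(self, arch, vocab):
        model = tiny_model(arch, vocab)
        a = model.sample_batch(6, max_len=20, seed=9)
        b = model.sample_batch(6, max_len=20, seed=9)
        assert a.smiles == b.smiles
        c = model.sample_batch(6, max_len=20, seed=10)
        assert a.smiles != c.smiles


class TestSampling:
    def test_batch_contract(self, toy_prior):
        batch = toy_prior.sample_batch(16, max_len=40, seed=4)
        assert batch.batch_size == 16
        assert all(seq.indices[0] == toy_prior.vocab.start
                   for seq in batch.sequences)
        assert all(len(seq) <= 40 for seq in batch.sequences)
        assert len(batch.agent_likelihoods) == 16

    def test_near_zero_temperature_is_greedy(self, toy_prior):
        batch = toy_prior.sample_batch(5, max_len=60, temperature=1e-4, seed=1)
        assert len(set(batch.smiles)) == 1

    def test_nonpositive_temperature_rejected(self, toy_prior):
        with pytest.raises(ValueError):
            toy_prior.sample_batch(2, temperature=0.0)

    def test_trained_prior_beats_untrained_on_validity(self, toy_prior, vocab):
        from smilesrl.benchmark import batch_metrics
        untrained = SmilesLM(vocab, "toy_lstm", seed=123)
        wins = 0
        for seed in (1, 2, 3):
            v_trained, _ = batch_metrics(toy_prior.sample_batch(64, seed=seed))
            v_raw, _ = batch_metrics(untrained.sample_batch(64, seed=seed))
            wins += v_trained > v_raw
        assert wins == 3

    def test_sampled_likelihood_matches_teacher_forcing(self, toy_prior):
        # the likelihood attached at sampling time must equal an independent
        # teacher-forced evaluation of the same realized tokens
        batch = toy_prior.sample_batch(8, max_len=40, seed=2)
        again = toy_prior.likelihood(batch.sequences)
        got = [ll.total_logp for ll in batch.agent_likelihoods]
        exp = [ll.total_logp for ll in again]
        np.testing.assert_allclose(got, exp, rtol=1e-12)


class TestTrainMLE:
    def test_training_reduces_corpus_nll(self):
        corpus = s.generate_corpus(s.SyntheticCorpusSpec(n_molecules=200, seed=11))
        vocab = s.Vocabulary.from_corpus(m.smiles for m in corpus)
        model = SmilesLM(vocab, "toy_lstm", seed=0)
        seqs = [vocab.encode_smiles(m.smiles) for m in corpus]
        before = model.mean_nll(seqs)
        model.train_mle(corpus, epochs=10, batch_size=64, seed=0)
        assert model.mean_nll(seqs) < before

    def test_single_molecule_corpus_collapses_to_it(self, vocab):
        model = tiny_model("lstm_rnn", vocab)
        model.train_mle(["CCO"] * 8, epochs=400, batch_size=8,
                        learning_rate=5e-3, seed=0)
        batch = model.sample_batch(30, max_len=20, seed=5)
        assert sum(x == "CCO" for x in batch.smiles) > 15

    def test_same_seed_gives_identical_parameters(self, mini_corpus):
        vocab = s.Vocabulary.from_corpus(m.smiles for m in mini_corpus)

        def train():
            m = SmilesLM(vocab, "toy_lstm", seed=1)
            m.train_mle(mini_corpus, epochs=2, batch_size=16, seed=1)
            return m

        a, b = train(), train()
        for x, y in zip(a.state_arrays(), b.state_arrays()):
            np.testing.assert_array_equal(x, y)

    def test_untokenizable_molecule_fails_before_training(self, vocab):
        model = tiny_model("lstm_rnn", vocab)
        before = model.param_checksum()
        with pytest.raises(KeyError):
            model.train_mle(["CCO", "C[Se]C"], epochs=1)
        assert model.param_checksum() == before

    def test_gated_transformer_trains_below_initial_nll(self, mini_corpus):
        vocab = s.Vocabulary.from_corpus(m.smiles for m in mini_corpus)
        model = tiny_model("gated_transformer", vocab)
        seqs = [vocab.encode_smiles(m.smiles) for m in mini_corpus]
        before = model.mean_nll(seqs)
        model.train_mle(mini_corpus, epochs=4, batch_size=16, seed=0)
        assert model.mean_nll(seqs) < before


class TestGatedLayer:
    def test_zeroed_sublayers_and_shut_gate_pass_input_through(self, vocab):
        model = tiny_model("gated_transformer", vocab)
        layer: GatedTransformerLayer = model.layers[0]
        for lin in (layer.attn.out, layer.ff2):
            lin.W.data[:] = 0.0
            lin.b.data[:] = 0.0
        for gate in (layer.gate1, layer.gate2):
            gate.Wz.W.data[:] = 0.0
            gate.Uz.W.data[:] = 0.0
            gate.bg.data[:] = 30.0  # update gate shut: carry path fully open
        x = Tensor(np.random.default_rng(0).normal(size=(2, 5, 16)))
        mask = np.triu(np.full((5, 5), -1e9), k=1)
        out = layer(x, mask, lambda t: t)
        np.testing.assert_allclose(out.data, x.data, atol=1e-10)

    def test_attention_without_mask_is_refused(self, vocab):
        model = tiny_model("gated_transformer", vocab)
        x = Tensor(np.zeros((1, 4, 16)))
        with pytest.raises(ValueError, match="mask"):
            model.layers[0].attn(x, None)


class TestCheckpoint:
    def test_save_load_round_trip(self, toy_prior, tmp_path):
        path = tmp_path / "prior.npz"
        toy_prior.save(path)
        loaded = SmilesLM.load(path)
        seq = [toy_prior.vocab.encode_smiles("CCO")]
        assert loaded.likelihood(seq)[0].total_logp == \
            pytest.approx(toy_prior.likelihood(seq)[0].total_logp)
        assert loaded.config == toy_prior.config

    def test_wrong_format_rejected(self, tmp_path):
        path = tmp_path / "bad.npz"
        np.savez(path, meta='{"format": "other"}')
        with pytest.raises(ValueError, match="format"):
            SmilesLM.load(path)
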