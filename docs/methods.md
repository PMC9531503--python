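# Methods

This note records the models and procedures the package implements, the
parameters that matter, the numerical choices, and what the toy-scale test
conditions do and do not demonstrate.

## Autoregressive SMILES language models

A molecule is a token sequence `START x_1 … x_L END` over a corpus-derived
vocabulary (longest-match tokenization: bracket atoms, two-letter organic
symbols, `%nn` ring labels are atomic; joining tokens reproduces the string
exactly, so encode/decode is the identity). A model assigns

```
logP(A) = Σ_t log P(x_t | x_<t)
```

including the END decision and excluding padding. Three families share this
contract:

- **RNNs** — stacked GRU or LSTM cells. Published-scale presets:
  `reinvent_gru` (embedding 128, 3×GRU-512, no dropout), `reinvent2_lstm`
  (embedding 256, 3×LSTM-512, no dropout), `guacamol_lstm` (3×LSTM-512,
  dropout 0.2; the embedding size is not stated by the source
  configuration — we use 256).
- **Transformer (Tr)** — post-norm encoder with causal masking used
  GPT-style: 4 layers, model dim 512, 8 heads, FFN 1024, dropout 0.1,
  sinusoidal positions.
- **Gated transformer (GTr)** — the RL-stabilised variant: layer
  normalisation moved before each sub-layer and the residual connection
  replaced by a GRU-style gate
  `out = (1−z)⊙x + z⊙h` with `z = σ(W_z y + U_z x − b_g)`,
  `h = tanh(W_g y + U_g (r⊙x))`, `r = σ(W_r y + U_r x)`. The gate bias
  `b_g` (default 2.0, configurable) biases `z` towards 0 at initialisation
  so each layer starts near the identity map; with sub-layer output zeroed
  and the update gate shut the layer passes its input through exactly,
  which the tests assert. Attention refuses to run without its causal
  mask.

A `toy_lstm` preset (embedding 64, 2×LSTM-128) exists so priors train in
minutes on one CPU; it is the model used throughout the test suite.

All models run on `smilesrl.autodiff`, a small reverse-mode automatic
differentiation engine over numpy arrays written for this package (dynamic
graph, broadcasting-aware backward rules, ADAM/SGD optimizers). Every
backward rule is verified against central finite differences in the test
suite. This keeps the package dependency-light; the cost is that
paper-scale training (10⁶-molecule corpora) is out of reach — the code
paths are identical, only the problem sizes differ.

**Training.** Maximum likelihood with ADAM (lr 1e-3, the published value),
seeded shuffling; training is bit-reproducible per seed on fixed hardware.
**Sampling.** Autoregressive multinomial sampling at temperature 1.0
(configurable; near-zero temperature degenerates to greedy argmax).
Sequences that hit `max_len` (default 128 tokens, covering the typical
20–100-character SMILES range) without END are kept and score as invalid
downstream — the RL loop needs a reward for every sampled item.

## Reinforcement-learning strategies

Per step: sample a batch of S molecules from the agent, score to rewards
`R_T ∈ [0,1]` (invalid molecules score 0), pass through the diversity
filter, compute one strategy loss, take one ADAM step (lr 5e-4 by
default; higher rates mode-collapse small agents). The prior is never
updated — a parameter checksum before/after any run is asserted identical.

| strategy | loss (batch mean) |
|---|---|
| REINFORCE | `(−logP_agent)·R_T` |
| REINVENT | `[logP_prior + σR_T − logP_agent]²` |
| BAR | `(1−α)·`REINVENT term `+ α·`same term anchored to a frozen *best agent* |
| HC | mean NLL of the top-k reward-ranked molecules (pure fine-tuning) |
| AHC | REINVENT's loss restricted to the top-k reward-ranked molecules |

Defaults: σ = 60 (the original published default), top-k fraction 0.5,
batch 64 (AHC; 256 for classic HC), α = 0.5, best-agent update period 5
(replace iff the current mean reward beats the best so far — the
acceptance rule is not fully specified by the source and is our
documented choice). Ties at the top-k boundary break by batch order for
determinism. Losses are per-sequence scalars, squared and batch-mean
reduced. An optional KL cost
`λ_KL · E[Σ_t Σ_a P_agent log(P_agent/P_prior)]` over full per-step
distributions can be attached to the unregularized strategies (REINFORCE,
HC) only; config validation rejects it elsewhere. Probabilities are
epsilon-clamped symmetrically (1e-10) so KL(P‖P) is exactly zero; a clamp
on the prior side logs a warning.

Why AHC works: at `R_T → 0` the augmented likelihood collapses onto the
prior's, and REINVENT's squared distance actively pulls the agent back to
the prior — the dominant term early in training or under hard objectives.
Restricting the loss to the top-k removes exactly those terms while the
surviving high-reward molecules remain prior-regularized. The suite
verifies both halves: one zero-reward REINVENT gradient step strictly
shrinks mean `|logP_agent − logP_prior|`, and the AHC loss on a
half-zero-reward batch equals the REINVENT loss of its top half.

## Diversity filters

A run-scoped memory penalizes repeat chemistry. Bin-based kinds (compound
ECFP4 similarity; identical/topological Murcko scaffolds; scaffold
atom-pair/ECFP similarity) record every molecule whose reward reaches the
*minimum score threshold* into the first bin whose key matches (exact
scaffold match, or Tanimoto ≥ 0.4 for similarity kinds; fingerprints
ECFP4/2048); occupancy then rolls the reward off by the *output mode*:
binary (full reward up to *bin size*, zero after), linear
(`reward·max(0, 1 − occ/bin)`), or sigmoid (logistic roll-off centred on
the bin size; the shape parameter is unstated anywhere, we use
bin_size/4). *unique* zeroes any repeated canonical SMILES; *occurrence*
decays linearly from full reward at `Occ ≤ Tol` to zero at
`Occ ≥ Tol+Buff`. (The printed piecewise form of the occurrence rule in
the source is internally inconsistent — its middle branch is negative just
above Tol — so the implementation follows the prose: linear decay between
the two stated endpoints.)

Presets: **DF1** = threshold 0.8, binary, bin 25 (strict; appropriate when
only the very top of the score distribution matters), **DF2** = threshold
0.5, linear, bin 50 (the compromise setting), **DF3** = threshold 0.0
(records everything). The bin kind behind DF1/DF2 is reconstructed as
compound similarity; the exact kinds are not recoverable from the source.

## Scoring tasks

All tasks map SMILES → reward ∈ [0,1]; invalid molecules score 0; a
scoring failure zeroes that molecule and the run continues. Heavy-atom
count normalizes by a cap (default 60 — raw counts are unbounded and RL
needs bounded rewards). Tanimoto similarity uses Morgan radius-2
fingerprints, 1024 bits (ECFP4). The isomer score is a geometric mean of
per-element Gaussian count agreements (σ = 1 atom) plus a total-atom term,
exactly 1.0 iff the molecular formula matches. Thresholded similarity
ramps linearly to 1 at the threshold, stays flat to a cap, and decays
beyond it (the too-close penalty). The MPO task combines thresholded
similarity with logP and TPSA windows (defaults 1–4 and 40–100 Å²,
Gaussian shoulders) by geometric mean; every constant is a named config
value in the spirit of the goal-directed benchmark conventions. Dual and
selective activity objectives take any probability-emitting predictor
(`(p₁+p₂)/2` and `(p₁+(1−p₂))/2`); the shipped predictor is a synthetic
seeded fingerprint-logistic model, a deterministic stand-in for a trained
QSAR classifier. Open-ended external scores (docking-like) enter through a
batch-scorer interface with running min–max normalization over all values
observed so far (first value maps to 0.5 by convention); the shipped mock
docking scorer is a deterministic structure-derived pseudo-affinity.

## Benchmarking

Curves log, per step: batch-mean/max task reward, the diversity-filtered
mean (what the loss saw), validity, uniqueness and cumulative molecules
sampled. Cross-strategy comparisons require equal sample budgets and plot
against cumulative molecules, not steps, since batch sizes differ. AUC is
trapezoidal over a normalized step axis (a constant endpoint c gives
exactly c, making runs of different lengths comparable).
Optimization-% is `100·mean/prior_mean` on the raw score scale — for
negative-better scores a mean twice as negative as the prior's reads
200 %. Threshold tables report the first step whose batch mean (and whose
best single sample) crosses a level, with "> n_steps" bounds when never
crossed.

## The synthetic corpus and what the toy study shows

The generator emulates a desk-scale "drug-like" corpus: decorated alkane
chains and 5–7-membered (hetero)cycles with O/N/F-bearing substituents,
8–25 heavy atoms, charge- and stereo-free, deduplicated by canonical
SMILES, byte-identical per seed. It does **not** reproduce real training
sets' scale (10⁶ molecules), elemental breadth (S, Br, I…), scaffold
diversity, or property filters (logP/PAINS/medchem rules); conclusions
about absolute scores do not transfer to real corpora.

Test-suite study conditions (chosen once): 500-molecule corpus (seed 7),
`toy_lstm` prior trained 150 epochs (mean NLL 10.1, sample validity
≈ 0.91), similarity task to a held-out generator molecule of median size,
DF2, σ = 60, batch 64, step cap 150, seeds 101–103.

Two findings from these conditions are worth recording:

1. **AHC's sample-efficiency advantage reproduces at toy scale.** AHC
   reaches any fixed sub-threshold reward level before REINVENT in every
   seed tested (e.g. level 0.4: steps 45/43/47 vs 48/56/60).
2. **The batch-mean reward converges to just below the diversity filter's
   minimum score threshold and stays there.** Only molecules scoring
   ≥ 0.5 enter DF2's memory; in a 500-molecule toy chemistry every such
   molecule falls into a handful of similarity bins, which saturate within
   a few steps, so the filtered reward repels the policy from the ≥ 0.5
   region and the mean plateaus at ≈ 0.47 for AHC and REINVENT alike, in
   every run across references, seeds and bin-based DF kinds. This is
   the known convergence-to-threshold pathology of strict filters,
   surfacing for DF2 at toy scale because the accessible chemistry is many
   orders of magnitude smaller than a real training domain. Consequently a
   batch-mean target of exactly 0.5 under DF2 is structurally unattainable
   in these conditions — the corresponding end-to-end test documents this
   honestly rather than relaxing the bar — while an occurrence-kind
   filter at the same threshold (which penalizes only exact repeats) does
   let AHC cross 0.5 where REINVENT does not within the step cap.

## Numerical choices and degenerate inputs

- Likelihoods are float64 throughout; per-step distributions sum to 1
  within 1e-5 (asserted for all three architectures).
- Log-softmax subtracts a detached row maximum (standard stabilisation).
- Uniqueness of an all-invalid batch is reported as 1.0 and flagged
  vacuous; validity handles empty batches as 0.
- Empty top-k subsets, mismatched BAR batch sizes, out-of-range rewards,
  σ/λ < 0, and unknown tokens at RL time raise immediately — a vocabulary
  mismatch between prior and task chemistry should fail loudly, not be
  skipped.
- Acyclic molecules have empty Murcko scaffolds and bin as singletons.
- Checkpoints are single-file `.npz` archives (versioned format tag,
  config, vocabulary, parameter arrays); loading rejects unknown formats.

## Known limitations

- No GPU path and no minibatch parallelism: paper-scale priors
  (3×512 LSTM on 10⁶ molecules) are supported by the code but not by a
  desk-scale time budget.
- The transformer samples by full-prefix recomputation (no KV cache);
  fine at toy lengths, quadratic waste at scale.
- BAR's best-agent acceptance rule and HC's inner-epoch count are
  documented choices where the sources are silent.
- Stereochemistry and charged species are out of corpus scope; the
  tokenizer handles them, the generator never emits them.
- The DF1/DF2 bin kinds and the MPO window constants are reconstructions;
  each is a named, overridable config value.
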