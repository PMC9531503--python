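"""Reinforcement-learning strategies for SMILES language models.

Five policy-based strategies share one loop: sample a batch from the agent,
score it, pass rewards through a diversity filter, take one gradient step.

* REINFORCE — episodic policy gradient: loss = (-logP_agent) * R_T.
* REINVENT — squared distance between the agent likelihood and the
  *augmented likelihood* logP_U(A) = logP_prior(A) + sigma * R_T; the frozen
  prior regularises the agent towards valid, in-distribution chemistry.
* BAR (best agent reminder) — REINVENT's loss averaged (weight alpha)
  over the current-agent batch and a batch from a periodically updated
  frozen copy of the best agent so far.
* HC (Hill-Climb) — maximum-likelihood fine-tuning on the top-k
  reward-ranked molecules of each batch.
* AHC (Augmented Hill-Climb) — REINVENT's augmented-likelihood loss
  computed only on the top-k reward-ranked molecules. Dropping the
  low-reward remainder removes the terms that would otherwise pull the
  agent straight back to the prior (at R_T -> 0 the augmented likelihood
  collapses onto the prior likelihood), which is where its
  sample-efficiency comes from.

An optional KL-divergence cost (agent||prior over per-step token
distributions) can regularise the otherwise unregularized REINFORCE and HC.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .autodiff import Adam, Tensor, no_grad
from .chem import canonicalize
from .filters import DiversityFilter, DiversityFilterConfig
from .models import GenerationBatch, SmilesLM
from .scoring import ScoringTask

logger = logging.getLogger(__name__)

STRATEGIES = ("reinforce", "reinvent", "bar", "hc", "ahc")


@dataclass
class RLConfig:
    strategy: str = "ahc"
    sigma: float = 60.0              # reward scaling in the augmented likelihood
    topk_fraction: float = 0.5       # HC/AHC: fraction of the batch kept
    batch_size: int = 64
    alpha: float = 0.5               # BAR: weight of the best-agent term
    best_update_period: int = 5      # BAR: steps between best-agent updates
    kl_lambda: float = 0.0           # KL cost weight (REINFORCE/HC only)
    n_steps: int = 100
    learning_rate: float = 5e-4
    temperature: float = 1.0
    inner_epochs: int = 1            # HC updates per sampled batch
    seed: int = 0

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if not 0.0 < self.topk_fraction <= 1.0:
            raise ValueError("topk_fraction must be in (0, 1]")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.sigma < 0 or self.kl_lambda < 0:
            raise ValueError("sigma and kl_lambda must be >= 0")
        if self.kl_lambda > 0 and self.strategy not in ("reinforce", "hc"):
            raise ValueError(
                "KL cost attaches only to the non-regularized strategies "
                "(reinforce, hc); REINVENT-family losses already carry the prior")


@dataclass
class RewardVector:
    """Raw task values, normalized rewards R_T in [0,1], and the rewards
    after diversity filtering."""

    raw: list[float | None]
    normalized: np.ndarray
    filtered: np.ndarray

    def __post_init__(self):
        self.normalized = np.asarray(self.normalized, dtype=float)
        self.filtered = np.asarray(self.filtered, dtype=float)
        for arr in (self.normalized, self.filtered):
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError("normalized/filtered rewards must be in [0, 1]")


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def _check_rewards(rewards: np.ndarray) -> np.ndarray:
    rewards = np.asarray(rewards, dtype=float)
    if np.any((rewards < 0) | (rewards > 1)):
        raise ValueError("rewards must be in [0, 1]")
    return rewards


def reinforce_loss(agent_logps: Tensor, rewards: Sequence[float]) -> Tensor:
    """Batch-mean of (-logP_agent) * R_T."""
    rewards = _check_rewards(rewards)
    return ((-agent_logps) * Tensor(rewards)).mean()


def augmented_likelihood(prior_logp: float, reward: float, sigma: float) -> float:
    """logP_U(A) = logP_prior(A) + sigma * R_T (no gradient: prior is frozen)."""
    return prior_logp + sigma * reward


def reinvent_loss(agent_logps: Tensor, prior_logps: Sequence[float],
                  rewards: Sequence[float], sigma: float) -> Tensor:
    """Batch-mean of [logP_U(A) - logP_agent(A)]^2."""
    rewards = _check_rewards(rewards)
    aug = np.asarray(prior_logps, dtype=float) + sigma * rewards
    return ((Tensor(aug) - agent_logps) ** 2).mean()


def select_topk(rewards: np.ndarray, topk_fraction: float) -> np.ndarray:
    """Indices of the ceil(S*f) highest-reward molecules, ties broken by
    original batch order (stable sort on descending reward)."""
    rewards = np.asarray(rewards, dtype=float)
    k = int(np.ceil(len(rewards) * topk_fraction))
    order = np.argsort(-rewards, kind="stable")
    return np.sort(order[:k])  # keep original batch order within the subset


def hc_loss(top_agent_logps: Tensor) -> Tensor:
    """Mean NLL of the top-k subset (one MLE step on those molecules)."""
    if top_agent_logps.data.size == 0:
        raise ValueError("empty top-k subset")
    return (-top_agent_logps).mean()


def ahc_loss(agent_logps: Tensor, prior_logps: Sequence[float],
             rewards: Sequence[float], sigma: float,
             topk_fraction: float) -> Tensor:
    """REINVENT's loss restricted to the top-k reward-ranked molecules."""
    rewards = _check_rewards(rewards)
    idx = select_topk(rewards, topk_fraction)
    prior_logps = np.asarray(prior_logps, dtype=float)
    return reinvent_loss(agent_logps[(idx,)], prior_logps[idx], rewards[idx], sigma)


def bar_loss(agent_logps_agent_batch: Tensor, prior_logps_agent_batch,
             rewards_agent, agent_logps_best_batch: Tensor,
             best_logps_best_batch, rewards_best,
             sigma: float, alpha: float) -> Tensor:
    """(1-alpha) * REINVENT term on the agent batch (prior-anchored)
    + alpha * REINVENT term on the best-agent batch (best-anchored)."""
    if agent_logps_agent_batch.shape != agent_logps_best_batch.shape:
        raise ValueError("agent and best batches must have the same size")
    term_agent = reinvent_loss(agent_logps_agent_batch, prior_logps_agent_batch,
                               rewards_agent, sigma)
    term_best = reinvent_loss(agent_logps_best_batch, best_logps_best_batch,
                              rewards_best, sigma)
    return (1.0 - alpha) * term_agent + alpha * term_best


_KL_EPS = 1e-10


def kl_cost(agent_probs: Tensor, prior_probs: np.ndarray, mask: np.ndarray,
            kl_lambda: float) -> Tensor:
    """lambda * mean over sequences of sum_t sum_a P_agent log(P_agent/P_prior).

    Probabilities are clamped at a small epsilon; a clamp on the prior side
    (agent mass where the prior has none) is logged as a warning.
    """
    if np.any(prior_probs[mask.astype(bool)] < _KL_EPS):
        logger.warning("prior assigns ~zero probability where the agent has "
                       "mass; clamping at %.0e", _KL_EPS)
    # symmetric epsilon so KL(agent || prior) is exactly 0 at agent == prior
    agent_ratio = (agent_probs + _KL_EPS).log() - Tensor(np.log(prior_probs + _KL_EPS))
    per_step = (agent_probs * agent_ratio).sum(axis=-1)      # (B, T)
    per_seq = (per_step * Tensor(mask)).sum(axis=-1)         # (B,)
    return kl_lambda * per_seq.mean()


# ---------------------------------------------------------------------------
# Best-agent bookkeeping (BAR)
# ---------------------------------------------------------------------------

def update_best_agent(current_agent: SmilesLM, best_agent: SmilesLM,
                      current_mean_reward: float, best_mean_reward: float,
                      step: int, period: int) -> tuple[SmilesLM, float]:
    """Every ``period`` steps, replace the best agent by a frozen copy of the
    current agent iff the current mean reward beats the best one."""
    if period < 1:
        raise ValueError("period must be >= 1")
    if step % period == 0 and current_mean_reward > best_mean_reward:
        return current_agent.clone(), current_mean_reward
    return best_agent, best_mean_reward


# ---------------------------------------------------------------------------
# The RL loop
# ---------------------------------------------------------------------------

@dataclass
class CurveRecord:
    """One RL step. ``mean_reward``/``max_reward`` are the task's normalized
    rewards R_T (what optimization progress is judged on);
    ``mean_filtered_reward`` is after diversity-filter penalization (what the
    loss saw)."""

    step: int
    n_sampled_cum: int
    mean_raw: float
    mean_reward: float
    max_reward: float
    mean_filtered_reward: float
    validity: float
    uniqueness: float
    wall_time_s: float


@dataclass
class RLRun:
    agent: SmilesLM
    records: list[CurveRecord] = field(default_factory=list)


def score_batch(task: ScoringTask, batch: GenerationBatch,
                dfilter: DiversityFilter) -> RewardVector:
    results = task.score_batch(batch.smiles)
    raw = [r.raw for r in results]
    normalized = np.array([r.reward for r in results])
    filtered = dfilter.apply(batch.smiles, normalized)
    return RewardVector(raw=raw, normalized=normalized, filtered=filtered)


def _batch_validity_uniqueness(smiles: list[str]) -> tuple[float, float]:
    canon = [canonicalize(s) for s in smiles]
    valid = [c for c in canon if c is not None]
    validity = len(valid) / len(smiles) if smiles else 0.0
    uniqueness = len(set(valid)) / len(valid) if valid else 1.0
    return validity, uniqueness


def rl_run(prior: SmilesLM, task: ScoringTask,
           dfilter: DiversityFilter | DiversityFilterConfig | str | None,
           cfg: RLConfig, stop_at_mean_reward: float | None = None) -> RLRun:
    """Run one RL optimization; the prior is never modified.

    Per step: sample a batch from the agent, score it, diversity-filter the
    rewards, compute the strategy loss (+ optional KL cost), take one
    optimizer step, append a curve record. ``stop_at_mean_reward`` ends the
    run early once the batch mean (filtered) reward crosses it.
    """
    if not isinstance(dfilter, DiversityFilter):
        dfilter = DiversityFilter(dfilter)
    agent = prior.clone()
    best_agent = prior.clone()
    best_mean_reward = -np.inf
    opt = Adam(agent.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    run = RLRun(agent=agent)
    t0 = time.monotonic()

    for step in range(1, cfg.n_steps + 1):
        batch = agent.sample_batch(cfg.batch_size,
                                   temperature=cfg.temperature, rng=rng)
        rewards = score_batch(task, batch, dfilter)
        filtered = rewards.filtered

        agent_logps = agent.sequence_logps(batch.sequences)
        need_prior = cfg.strategy in ("reinvent", "bar", "ahc")
        prior_logps = None
        if need_prior:
            prior_logps = np.array(
                [ll.total_logp for ll in prior.likelihood(batch.sequences)])

        if cfg.strategy == "reinforce":
            loss = reinforce_loss(agent_logps, filtered)
        elif cfg.strategy == "reinvent":
            loss = reinvent_loss(agent_logps, prior_logps, filtered, cfg.sigma)
        elif cfg.strategy == "ahc":
            loss = ahc_loss(agent_logps, prior_logps, filtered,
                            cfg.sigma, cfg.topk_fraction)
        elif cfg.strategy == "hc":
            idx = select_topk(filtered, cfg.topk_fraction)
            loss = hc_loss(agent_logps[(idx,)])
        elif cfg.strategy == "bar":
            best_batch = best_agent.sample_batch(cfg.batch_size,
                                                 temperature=cfg.temperature,
                                                 rng=rng)
            rewards_best = score_batch(task, best_batch, dfilter)
            agent_logps_best = agent.sequence_logps(best_batch.sequences)
            best_logps = np.array(
                [ll.total_logp for ll in best_agent.likelihood(best_batch.sequences)])
            loss = bar_loss(agent_logps, prior_logps, filtered,
                            agent_logps_best, best_logps,
                            rewards_best.filtered, cfg.sigma, cfg.alpha)

        if cfg.kl_lambda > 0:
            agent_probs, mask = agent.step_distributions(batch.sequences, grad=True)
            prior_probs, _ = prior.step_distributions(batch.sequences)
            loss = loss + kl_cost(agent_probs, prior_probs.data, mask, cfg.kl_lambda)

        opt.zero_grad()
        loss.backward()
        opt.step()

        if cfg.strategy == "hc" and cfg.inner_epochs > 1:
            idx = select_topk(filtered, cfg.topk_fraction)
            top_seqs = [batch.sequences[i] for i in idx]
            for _ in range(cfg.inner_epochs - 1):
                extra = hc_loss(agent.sequence_logps(top_seqs))
                opt.zero_grad()
                extra.backward()
                opt.step()

        mean_reward = float(rewards.normalized.mean())
        if cfg.strategy == "bar":
            best_agent, best_mean_reward = update_best_agent(
                agent, best_agent, mean_reward, best_mean_reward,
                step, cfg.best_update_period)

        raw_vals = [r for r in rewards.raw if r is not None]
        validity, uniqueness = _batch_validity_uniqueness(batch.smiles)
        run.records.append(CurveRecord(
            step=step,
            n_sampled_cum=step * cfg.batch_size,
            mean_raw=float(np.mean(raw_vals)) if raw_vals else float("nan"),
            mean_reward=mean_reward,
            max_reward=float(rewards.normalized.max()),
            mean_filtered_reward=float(filtered.mean()),
            validity=validity,
            uniqueness=uniqueness,
            wall_time_s=time.monotonic() - t0,
        ))
        if stop_at_mean_reward is not None and mean_reward >= stop_at_mean_reward:
            break
    return run
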