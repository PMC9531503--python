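"""Scoring tasks: the reward functions that drive reinforcement learning.

Every task maps a SMILES string to a raw value in task units and a
normalized reward R_T in [0, 1]; invalid SMILES always score 0. Multi-part
objectives combine component scores by arithmetic or geometric mean;
open-ended values (e.g. docking scores from an external scorer) are mapped
to [0, 1] by a running min-max normalizer over everything observed so far.

External predictors plug in through two small contracts:

* an *external scorer* is any callable taking a batch of SMILES and
  returning one float (or None) per molecule — the shape a docking wrapper
  has; a deterministic mock is shipped for end-to-end runs;
* an *activity predictor* is any callable returning a probability of
  activity per molecule — the shape a QSAR classifier has; a synthetic
  fingerprint-logistic predictor is shipped so dual/selective objectives
  are exercisable without real assay data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import Crippen, rdFingerprintGenerator, rdMolDescriptors

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoreResult:
    raw: float | None
    reward: float
    components: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.reward <= 1.0:
            raise ValueError("reward must be in [0, 1]")


_INVALID = ScoreResult(raw=None, reward=0.0)


def _mol(smiles: str):
    return Chem.MolFromSmiles(smiles)


def _morgan_fp(mol, radius: int = 2, n_bits: int = 1024):
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return gen.GetFingerprint(mol)


# ---------------------------------------------------------------------------
# Elementary tasks
# ---------------------------------------------------------------------------

HEAVY_ATOM_CAP = 60  # reward saturates here; raw counts are unbounded


def heavy_atom_score(smiles: str, cap: int = HEAVY_ATOM_CAP) -> ScoreResult:
    """Maximize the number of non-hydrogen atoms (reward = raw/cap, clamped)."""
    mol = _mol(smiles)
    if mol is None:
        return _INVALID
    raw = mol.GetNumHeavyAtoms()
    return ScoreResult(raw=float(raw), reward=min(raw / cap, 1.0))


def tanimoto_similarity_score(smiles: str, reference: str,
                              fp_radius: int = 2,
                              fp_bits: int = 1024) -> ScoreResult:
    """Tanimoto similarity over circular (ECFP-style) fingerprints;
    radius 2 / 1024 bits corresponds to ECFP4 with a 1024-bit fold."""
    ref_mol = _mol(reference)
    if ref_mol is None:
        raise ValueError(f"invalid reference SMILES {reference!r}")
    mol = _mol(smiles)
    if mol is None:
        return _INVALID
    sim = DataStructs.TanimotoSimilarity(
        _morgan_fp(mol, fp_radius, fp_bits), _morgan_fp(ref_mol, fp_radius, fp_bits))
    return ScoreResult(raw=float(sim), reward=float(sim))


def parse_formula(formula: str) -> dict[str, int]:
    """Hill-notation molecular formula -> element counts."""
    import re
    counts: dict[str, int] = {}
    for sym, num in re.findall(r"([A-Z][a-z]?)(\d*)", formula):
        if sym:
            counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
    if not counts:
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


ISOMER_GAUSSIAN_SIGMA = 1.0  # per-element count tolerance width


def isomer_score(smiles: str, formula: str) -> ScoreResult:
    """Geometric-mean Gaussian agreement between the molecule's element
    counts (hydrogens included) and a target formula, with an extra
    total-atom term. Exactly 1.0 iff the molecular formula matches."""
    target = parse_formula(formula)
    mol = _mol(smiles)
    if mol is None:
        return _INVALID
    molh = Chem.AddHs(mol)
    counts: dict[str, int] = {}
    for atom in molh.GetAtoms():
        counts[atom.GetSymbol()] = counts.get(atom.GetSymbol(), 0) + 1
    terms: dict[str, float] = {}
    for el in sorted(set(target) | set(counts)):
        diff = counts.get(el, 0) - target.get(el, 0)
        terms[el] = math.exp(-0.5 * (diff / ISOMER_GAUSSIAN_SIGMA) ** 2)
    total_diff = sum(counts.values()) - sum(target.values())
    terms["total_atoms"] = math.exp(-0.5 * (total_diff / ISOMER_GAUSSIAN_SIGMA) ** 2)
    reward = float(np.prod(list(terms.values())) ** (1.0 / len(terms)))
    return ScoreResult(raw=reward, reward=min(reward, 1.0), components=terms)


def mpo_combine(components: dict[str, float], mode: str = "arithmetic") -> float:
    """Aggregate component scores in [0,1] into one reward."""
    if not components:
        raise ValueError("empty component map")
    vals = np.array(list(components.values()), dtype=float)
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("all components must be in [0, 1]")
    if mode == "arithmetic":
        return float(vals.mean())
    if mode == "geometric":
        return float(np.prod(vals) ** (1.0 / len(vals)))
    raise ValueError(f"unknown mode {mode!r}")


def similarity_task_with_threshold(smiles: str, reference: str,
                                   threshold: float, cap: float = 1.0,
                                   fp_radius: int = 2,
                                   fp_bits: int = 1024) -> ScoreResult:
    """Thresholded similarity: linear ramp 0 -> 1 up to ``threshold``, flat 1
    on [threshold, cap], linear decay beyond ``cap`` (the too-close penalty;
    cap=1 disables it)."""
    if not 0.0 <= threshold <= cap <= 1.0:
        raise ValueError("need 0 <= threshold <= cap <= 1")
    res = tanimoto_similarity_score(smiles, reference, fp_radius, fp_bits)
    if res.raw is None:
        return _INVALID
    sim = res.raw
    if sim < threshold:
        reward = sim / threshold if threshold > 0 else 1.0
    elif sim <= cap:
        reward = 1.0
    else:
        reward = max(0.0, 1.0 - (sim - cap) / (1.0 - cap)) if cap < 1 else 1.0
    return ScoreResult(raw=sim, reward=float(reward))


# ---------------------------------------------------------------------------
# Running min-max normalization (for open-ended scores such as docking)
# ---------------------------------------------------------------------------

@dataclass
class RunningNormalizer:
    """Maps raw scores to [0,1] against everything observed so far."""

    direction: str = "minimize"
    observed_min: float = math.inf
    observed_max: float = -math.inf

    def update(self, value: float) -> None:
        self.observed_min = min(self.observed_min, value)
        self.observed_max = max(self.observed_max, value)

    def normalize(self, value: float) -> float:
        """Update with ``value`` first, then map it. A degenerate history
        (single distinct value) maps to 0.5 by convention."""
        self.update(value)
        span = self.observed_max - self.observed_min
        if span == 0:
            return 0.5
        if self.direction == "maximize":
            frac = (value - self.observed_min) / span
        else:
            frac = (self.observed_max - value) / span
        return float(np.clip(frac, 0.0, 1.0))


def normalize(value: float, norm: RunningNormalizer) -> float:
    return norm.normalize(value)


# ---------------------------------------------------------------------------
# Pluggable predictors and built-in synthetic stand-ins
# ---------------------------------------------------------------------------

class ExternalScorer(Protocol):
    def __call__(self, smiles_batch: Sequence[str]) -> list[float | None]: ...


_SCORER_REGISTRY: dict[str, ExternalScorer] = {}


def register_scorer(name: str, scorer: ExternalScorer) -> None:
    _SCORER_REGISTRY[name] = scorer


def get_scorer(name: str) -> ExternalScorer:
    return _SCORER_REGISTRY[name]


def mock_docking_scorer(smiles_batch: Sequence[str]) -> list[float | None]:
    """Deterministic structure-derived pseudo-affinity (synthetic stand-in
    for an external docking program): more negative is better, rewarding
    size, rings and moderate lipophilicity."""
    out: list[float | None] = []
    for smi in smiles_batch:
        mol = _mol(smi)
        if mol is None:
            out.append(None)
            continue
        hac = mol.GetNumHeavyAtoms()
        rings = rdMolDescriptors.CalcNumRings(mol)
        logp = Crippen.MolLogP(mol)
        out.append(-(0.25 * hac + 1.5 * rings - 0.3 * abs(logp - 2.0)))
    return out


register_scorer("mock_docking", mock_docking_scorer)


class SyntheticActivityPredictor:
    """Synthetic probability-of-activity predictor: a fixed, seeded logistic
    model over Morgan fingerprint bits. Deterministic; stands in for a
    trained QSAR classifier in dual/selective objectives."""

    def __init__(self, seed: int = 0, n_bits: int = 1024):
        rng = np.random.default_rng(seed)
        self.weights = rng.normal(0, 1.0, size=n_bits)
        self.bias = -0.5
        self.n_bits = n_bits

    def __call__(self, smiles: str) -> float:
        mol = _mol(smiles)
        if mol is None:
            return 0.0
        fp = _morgan_fp(mol, 2, self.n_bits)
        bits = np.zeros(self.n_bits)
        DataStructs.ConvertToNumpyArray(fp, bits)
        z = bits @ self.weights / max(bits.sum(), 1.0) + self.bias
        return float(1.0 / (1.0 + np.exp(-z)))


def dual_activity_score(smiles: str, predictor_a, predictor_b) -> ScoreResult:
    """Mean probability of activity against two targets."""
    pa, pb = predictor_a(smiles), predictor_b(smiles)
    if _mol(smiles) is None:
        return _INVALID
    comps = {"p_a": pa, "p_b": pb}
    return ScoreResult(raw=None, reward=mpo_combine(comps), components=comps)


def selective_activity_score(smiles: str, predictor_on, predictor_off) -> ScoreResult:
    """Mean of on-target activity and one minus off-target activity."""
    if _mol(smiles) is None:
        return _INVALID
    p_on, p_off = predictor_on(smiles), predictor_off(smiles)
    comps = {"p_on": p_on, "one_minus_p_off": 1.0 - p_off}
    return ScoreResult(raw=None, reward=mpo_combine(comps), components=comps)


# ---------------------------------------------------------------------------
# Batch-level task objects (what the RL loop consumes)
# ---------------------------------------------------------------------------

class ScoringTask:
    """Base: a named reward function over batches of SMILES.

    A failure scoring one molecule is logged and yields reward 0 for that
    molecule only; the batch (and the run) continues.
    """

    name = "task"

    def score_one(self, smiles: str) -> ScoreResult:  # pragma: no cover
        raise NotImplementedError

    def score_batch(self, smiles_batch: Sequence[str]) -> list[ScoreResult]:
        out = []
        for smi in smiles_batch:
            try:
                out.append(self.score_one(smi))
            except Exception:
                logger.warning("scoring failed for %r; reward set to 0",
                               smi, exc_info=True)
                out.append(_INVALID)
        return out


class HeavyAtomTask(ScoringTask):
    name = "heavy_atoms"

    def __init__(self, cap: int = HEAVY_ATOM_CAP):
        self.cap = cap

    def score_one(self, smiles):
        return heavy_atom_score(smiles, cap=self.cap)


class TanimotoSimilarityTask(ScoringTask):
    name = "tanimoto_similarity"

    def __init__(self, reference: str, fp_radius: int = 2, fp_bits: int = 1024):
        self.reference = reference
        self.fp_radius = fp_radius
        self.fp_bits = fp_bits

    def score_one(self, smiles):
        return tanimoto_similarity_score(smiles, self.reference,
                                         self.fp_radius, self.fp_bits)


class IsomerTask(ScoringTask):
    name = "isomer"

    def __init__(self, formula: str):
        self.formula = formula

    def score_one(self, smiles):
        return isomer_score(smiles, self.formula)


class ThresholdSimilarityTask(ScoringTask):
    name = "threshold_similarity"

    def __init__(self, reference: str, threshold: float, cap: float = 1.0):
        self.reference = reference
        self.threshold = threshold
        self.cap = cap

    def score_one(self, smiles):
        return similarity_task_with_threshold(smiles, self.reference,
                                              self.threshold, self.cap)


class MpoTask(ScoringTask):
    """Similarity-to-an-extent plus physicochemical windows: thresholded
    similarity with a too-close cap, a logP window and a TPSA window,
    combined by geometric mean. The window constants are named defaults in
    the style of goal-directed generation benchmarks."""

    name = "mpo"

    def __init__(self, reference: str, sim_threshold: float = 0.5,
                 sim_cap: float = 0.8, logp_window: tuple[float, float] = (1.0, 4.0),
                 tpsa_window: tuple[float, float] = (40.0, 100.0),
                 window_sigma: float = 1.0, tpsa_sigma: float = 20.0):
        self.reference = reference
        self.sim_threshold = sim_threshold
        self.sim_cap = sim_cap
        self.logp_window = logp_window
        self.tpsa_window = tpsa_window
        self.window_sigma = window_sigma
        self.tpsa_sigma = tpsa_sigma

    @staticmethod
    def _window(value: float, lo: float, hi: float, sigma: float) -> float:
        if lo <= value <= hi:
            return 1.0
        d = (lo - value) if value < lo else (value - hi)
        return math.exp(-0.5 * (d / sigma) ** 2)

    def score_one(self, smiles):
        mol = _mol(smiles)
        if mol is None:
            return _INVALID
        sim = similarity_task_with_threshold(
            smiles, self.reference, self.sim_threshold, self.sim_cap)
        comps = {
            "similarity": sim.reward,
            "logp": self._window(Crippen.MolLogP(mol), *self.logp_window,
                                 self.window_sigma),
            "tpsa": self._window(rdMolDescriptors.CalcTPSA(mol),
                                 *self.tpsa_window, self.tpsa_sigma),
        }
        return ScoreResult(raw=sim.raw, reward=mpo_combine(comps, "geometric"),
                           components=comps)


class DualActivityTask(ScoringTask):
    name = "dual_activity"

    def __init__(self, predictor_a=None, predictor_b=None):
        self.predictor_a = predictor_a or SyntheticActivityPredictor(seed=1)
        self.predictor_b = predictor_b or SyntheticActivityPredictor(seed=2)

    def score_one(self, smiles):
        return dual_activity_score(smiles, self.predictor_a, self.predictor_b)


class SelectiveActivityTask(ScoringTask):
    name = "selective_activity"

    def __init__(self, predictor_on=None, predictor_off=None):
        self.predictor_on = predictor_on or SyntheticActivityPredictor(seed=1)
        self.predictor_off = predictor_off or SyntheticActivityPredictor(seed=2)

    def score_one(self, smiles):
        return selective_activity_score(smiles, self.predictor_on,
                                        self.predictor_off)


class ExternalScorerTask(ScoringTask):
    """Wraps a registered batch scorer (e.g. docking) with running min-max
    normalization of its open-ended raw values into rewards."""

    name = "external"

    def __init__(self, scorer: str | ExternalScorer = "mock_docking",
                 direction: str = "minimize"):
        self.scorer = get_scorer(scorer) if isinstance(scorer, str) else scorer
        self.normalizer = RunningNormalizer(direction=direction)

    def score_batch(self, smiles_batch):
        try:
            raws = self.scorer(smiles_batch)
        except Exception:
            logger.warning("external scorer failed for whole batch", exc_info=True)
            raws = [None] * len(smiles_batch)
        out = []
        for raw in raws:
            if raw is None:
                out.append(_INVALID)
            else:
                out.append(ScoreResult(raw=float(raw),
                                       reward=self.normalizer.normalize(float(raw))))
        return out

    def score_one(self, smiles):
        return self.score_batch([smiles])[0]


TASKS: dict[str, Callable[..., ScoringTask]] = {
    "heavy_atoms": HeavyAtomTask,
    "tanimoto_similarity": TanimotoSimilarityTask,
    "isomer": IsomerTask,
    "threshold_similarity": ThresholdSimilarityTask,
    "mpo": MpoTask,
    "dual_activity": DualActivityTask,
    "selective_activity": SelectiveActivityTask,
    "external": ExternalScorerTask,
}


def make_task(name: str, **params) -> ScoringTask:
    if name not in TASKS:
        raise KeyError(f"unknown task {name!r}; available: {sorted(TASKS)}")
    return TASKS[name](**params)
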