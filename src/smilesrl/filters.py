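"""Memory-based diversity filters that penalize rewards of molecules
similar to previously generated ones.

A filter keeps a run-scoped :class:`FilterMemory`. Molecules whose reward
reaches the *minimum score threshold* are recorded into bins keyed by a
similarity or scaffold criterion; once a bin fills past *bin size* the
reward of further members is rolled off by a binary, linear or sigmoid
*output mode*. The *unique* and *occurrence* filters instead count exact
canonical-SMILES repeats: *unique* zeroes any repeat, *occurrence* decays
linearly from full reward at ``Occ <= Tol`` to zero at ``Occ >= Tol + Buff``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.AtomPairs import Pairs
from rdkit.Chem.Scaffolds import MurckoScaffold

FILTER_KINDS = ("none", "unique", "occurrence", "compoundsimilarity",
                "identicalmurckoscaffold", "identicaltopologicalscaffold",
                "scaffoldsimilarityatompair", "scaffoldsimilarityecfp")
OUTPUT_MODES = ("binary", "sigmoid", "linear")

_SIMILARITY_KINDS = ("compoundsimilarity", "scaffoldsimilarityatompair",
                     "scaffoldsimilarityecfp")

_ecfp_gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


@dataclass(frozen=True)
class DiversityFilterConfig:
    kind: str = "compoundsimilarity"
    min_score_threshold: float = 0.5
    bin_size: int = 25
    output_mode: str = "binary"
    similarity_threshold: float = 0.4
    tolerance: int = 0      # occurrence filter only (Tol)
    buffer: int = 0         # occurrence filter only (Buff)

    def __post_init__(self):
        if self.kind not in FILTER_KINDS:
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.output_mode not in OUTPUT_MODES:
            raise ValueError(f"unknown output mode {self.output_mode!r}")
        if not 0.0 <= self.min_score_threshold <= 1.0:
            raise ValueError("min_score_threshold must be in [0, 1]")


#: Named presets. DF1 is the strict filter (threshold 0.8, binary, bin 25),
#: DF2 the softer one (threshold 0.5, linear, bin 50), DF3 records every
#: molecule regardless of score (threshold 0.0).
PRESETS: dict[str, DiversityFilterConfig] = {
    "DF1": DiversityFilterConfig(kind="compoundsimilarity",
                                 min_score_threshold=0.8,
                                 output_mode="binary", bin_size=25),
    "DF2": DiversityFilterConfig(kind="compoundsimilarity",
                                 min_score_threshold=0.5,
                                 output_mode="linear", bin_size=50),
    "DF3": DiversityFilterConfig(kind="compoundsimilarity",
                                 min_score_threshold=0.0,
                                 output_mode="binary", bin_size=25),
}


def get_config(name_or_cfg: str | DiversityFilterConfig | None) -> DiversityFilterConfig:
    if name_or_cfg is None:
        return DiversityFilterConfig(kind="none")
    if isinstance(name_or_cfg, DiversityFilterConfig):
        return name_or_cfg
    if name_or_cfg in PRESETS:
        return replace(PRESETS[name_or_cfg])  # copy: presets stay immutable
    return DiversityFilterConfig(kind=name_or_cfg)


# ---------------------------------------------------------------------------
# Scaffold / similarity keys
# ---------------------------------------------------------------------------

def scaffold_key(smiles: str, kind: str):
    """Bin key for a molecule under the given filter kind.

    Murcko kinds return scaffold SMILES (empty string for acyclic
    molecules, which then bin as singletons); similarity kinds return a
    fingerprint of the molecule or of its Murcko scaffold.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES {smiles!r}")
    if kind == "identicalmurckoscaffold":
        return Chem.MolToSmiles(MurckoScaffold.GetScaffoldForMol(mol))
    if kind == "identicaltopologicalscaffold":
        scaffold = MurckoScaffold.GetScaffoldForMol(mol)
        return Chem.MolToSmiles(MurckoScaffold.MakeScaffoldGeneric(scaffold))
    if kind == "compoundsimilarity":
        return _ecfp_gen.GetFingerprint(mol)
    if kind in ("scaffoldsimilarityatompair", "scaffoldsimilarityecfp"):
        scaffold = MurckoScaffold.GetScaffoldForMol(mol)
        if scaffold.GetNumAtoms() == 0:
            return None  # acyclic: no scaffold, treated as singleton bin
        if kind == "scaffoldsimilarityecfp":
            return _ecfp_gen.GetFingerprint(scaffold)
        return Pairs.GetAtomPairFingerprint(scaffold)
    raise ValueError(f"kind {kind!r} has no bin key")


@dataclass
class _Bin:
    key: object
    members: list[str] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.members)


@dataclass
class FilterMemory:
    """Per-run record of generated molecules grouped into similarity bins."""

    bins: list[_Bin] = field(default_factory=list)
    occurrence_counts: dict[str, int] = field(default_factory=dict)
    _first_seen: dict[str, int] = field(default_factory=dict)
    step: int = 0

    def note_seen(self, smiles: str) -> int:
        """Record one observation; returns the count *before* it."""
        prior = self.occurrence_counts.get(smiles, 0)
        self.occurrence_counts[smiles] = prior + 1
        self._first_seen.setdefault(smiles, self.step)
        return prior

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["smiles", "bin_index", "step_first_seen"])
            for i, b in enumerate(self.bins):
                for smi in b.members:
                    writer.writerow([smi, i, self._first_seen.get(smi, "")])


def assign_and_count(smiles: str, reward: float, memory: FilterMemory,
                     cfg: DiversityFilterConfig) -> int:
    """Insert an above-threshold molecule into its bin; returns the bin
    occupancy after insertion (0 if nothing was recorded)."""
    if not 0.0 <= reward <= 1.0:
        raise ValueError("reward must be in [0, 1]")
    if reward < cfg.min_score_threshold:
        return 0
    try:
        key = scaffold_key(smiles, cfg.kind)
    except ValueError:
        return 0  # invalid SMILES: no-op
    if cfg.kind in _SIMILARITY_KINDS:
        if key is not None:
            for b in memory.bins:
                if b.key is None:
                    continue
                if DataStructs.TanimotoSimilarity(key, b.key) >= cfg.similarity_threshold:
                    b.members.append(smiles)
                    memory._first_seen.setdefault(smiles, memory.step)
                    return b.count
    else:
        for b in memory.bins:
            if b.key == key:
                b.members.append(smiles)
                memory._first_seen.setdefault(smiles, memory.step)
                return b.count
    new_bin = _Bin(key=key, members=[smiles])
    memory.bins.append(new_bin)
    memory._first_seen.setdefault(smiles, memory.step)
    return 1


def penalize(reward: float, occupancy: int, cfg: DiversityFilterConfig) -> float:
    """Roll the reward off as bin occupancy grows; monotone non-increasing."""
    if not 0.0 <= reward <= 1.0:
        raise ValueError("reward must be in [0, 1]")
    if occupancy <= 0:
        return reward
    if cfg.output_mode == "binary" or cfg.bin_size == 0:
        return reward if occupancy <= cfg.bin_size else 0.0
    if cfg.output_mode == "linear":
        return float(np.clip(reward * (1.0 - occupancy / cfg.bin_size), 0.0, 1.0))
    # sigmoid roll-off centred on bin_size; shape parameter bin_size/4
    s = cfg.bin_size / 4.0
    logistic = 1.0 / (1.0 + np.exp(-(occupancy - cfg.bin_size) / s))
    return float(np.clip(reward * (1.0 - logistic), 0.0, 1.0))


def unique_filter(smiles: str, reward: float, memory: FilterMemory) -> float:
    """Zero the reward of any canonical SMILES seen before in the run."""
    if Chem.MolFromSmiles(smiles) is None:
        return 0.0
    occ = memory.note_seen(smiles)
    return reward if occ == 0 else 0.0


def occurrence_filter(smiles: str, reward: float, memory: FilterMemory,
                      tolerance: int, buffer: int) -> float:
    """Linear decay with repeat count: full reward while the prior
    occurrence count Occ <= Tol, zero once Occ >= Tol + Buff, linear
    in between. Buff = 0 degenerates to a hard cutoff at Tol."""
    if tolerance < 0 or buffer < 0:
        raise ValueError("tolerance and buffer must be >= 0")
    if Chem.MolFromSmiles(smiles) is None:
        return 0.0
    occ = memory.note_seen(smiles)
    if occ <= tolerance:
        return reward
    if buffer == 0 or occ >= tolerance + buffer:
        return 0.0
    return reward * (1.0 - (occ - tolerance) / buffer)


class DiversityFilter:
    """Stateful filter applying one configuration over a molecule stream."""

    def __init__(self, cfg: str | DiversityFilterConfig | None = None):
        self.cfg = get_config(cfg)
        self.memory = FilterMemory()

    def filter_one(self, smiles: str, reward: float) -> float:
        cfg = self.cfg
        if cfg.kind == "none":
            return reward
        if Chem.MolFromSmiles(smiles) is None:
            return 0.0
        smiles = Chem.CanonSmiles(smiles)
        if cfg.kind == "unique":
            return unique_filter(smiles, reward, self.memory)
        if cfg.kind == "occurrence":
            return occurrence_filter(smiles, reward, self.memory,
                                     cfg.tolerance, cfg.buffer)
        occupancy = assign_and_count(smiles, reward, self.memory, cfg)
        return penalize(reward, occupancy, cfg) if occupancy else reward

    def apply(self, smiles_list: list[str], rewards) -> np.ndarray:
        """Filter a batch in order: earlier molecules raise the occupancy
        seen by later ones."""
        out = np.array([self.filter_one(s, float(r))
                        for s, r in zip(smiles_list, rewards)])
        self.memory.step += 1
        return out
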