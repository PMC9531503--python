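"""SMILES I/O, canonicalization, synthetic corpora and alkane enumeration.

The synthetic corpus generator emulates a desk-scale "drug-like" training
set: decorated alkane chains and small rings bearing O/N/F substituents in
the 8-25 heavy-atom range. It exists so priors can be trained and the RL
loop exercised without any external dataset download.

`enumerate_alkane_isomers` is the exhaustive oracle behind the isomer
benchmark task: the constitutional isomers of C_nH_{2n+2} are exactly the
unlabeled trees on n vertices with maximum degree 4, grown here one carbon
at a time and deduplicated by canonical SMILES.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdMolDescriptors

RDLogger.DisableLog("rdApp.*")  # parse failures are data, not log spam


@dataclass(frozen=True)
class MoleculeRecord:
    """One molecule of a corpus; invalid inputs are kept, flagged not dropped."""

    smiles: str
    valid: bool
    mol_formula: str | None = None
    heavy_atom_count: int | None = None


@dataclass(frozen=True)
class SyntheticCorpusSpec:
    n_molecules: int
    seed: int
    generator_family: Literal["alkanes", "decorated_scaffolds"] = "decorated_scaffolds"
    max_heavy_atoms: int = 25


def canonicalize(smiles: str) -> str | None:
    """Canonical SMILES, or None if the string does not parse."""
    mol = Chem.MolFromSmiles(smiles)
    return None if mol is None else Chem.MolToSmiles(mol)


def make_record(smiles: str) -> MoleculeRecord:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return MoleculeRecord(smiles=smiles, valid=False)
    return MoleculeRecord(
        smiles=Chem.MolToSmiles(mol),
        valid=True,
        mol_formula=rdMolDescriptors.CalcMolFormula(mol),
        heavy_atom_count=mol.GetNumHeavyAtoms(),
    )


def read_smiles_file(path: str | Path) -> list[MoleculeRecord]:
    """Read a `.smi` file (SMILES per line, optional name column) or a CSV
    with a `smiles` column. Invalid lines yield valid=False records."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".csv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "smiles" not in reader.fieldnames:
                raise ValueError(f"{path}: CSV must contain a 'smiles' column")
            return [make_record(row["smiles"].strip()) for row in reader]
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            records.append(make_record(line.split()[0]))
    return records


def write_smiles_file(records: Iterable[MoleculeRecord | str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write((rec if isinstance(rec, str) else rec.smiles) + "\n")


# ---------------------------------------------------------------------------
# Alkane isomer enumeration
# ---------------------------------------------------------------------------

_MAX_ENUM_CARBONS = 14


def enumerate_alkane_isomers(n_carbons: int) -> set[str]:
    """All constitutional isomers of C_nH_{2n+2} as canonical SMILES.

    Grows every tree on ``n`` carbons (degree <= 4) by attaching one carbon
    to each attachable position of each (n-1)-carbon tree, deduplicating at
    every level by canonical SMILES — canonicalization is the graph
    isomorphism test.
    """
    if n_carbons < 1:
        raise ValueError("n_carbons must be >= 1")
    if n_carbons > _MAX_ENUM_CARBONS:
        raise ValueError(
            f"n_carbons={n_carbons} exceeds the enumeration bound "
            f"({_MAX_ENUM_CARBONS})")
    level = {"C"}
    for _ in range(n_carbons - 1):
        grown: set[str] = set()
        for smi in level:
            mol = Chem.MolFromSmiles(smi)
            for atom in mol.GetAtoms():
                if atom.GetDegree() >= 4:
                    continue
                rw = Chem.RWMol(mol)
                new_idx = rw.AddAtom(Chem.Atom(6))
                rw.AddBond(atom.GetIdx(), new_idx, Chem.BondType.SINGLE)
                grown.add(Chem.MolToSmiles(rw.GetMol()))
        level = grown
    return level


def _alkane_space_size(max_heavy_atoms: int) -> int:
    n = 0
    for k in range(1, min(max_heavy_atoms, _MAX_ENUM_CARBONS) + 1):
        n += len(enumerate_alkane_isomers(k))
    return n


# ---------------------------------------------------------------------------
# Synthetic corpus
# ---------------------------------------------------------------------------

_SCAFFOLDS = ["C1CCCCC1", "C1CCCC1", "c1ccccc1", "C1CCOCC1", "C1CCNCC1",
              "c1ccncc1", "C1CCCCCC1"]
_SUBSTITUENTS = ["O", "N", "F", "C", "CC", "CO", "CN", "C(C)C", "C(=O)O",
                 "C(=O)N", "OC", "CF"]


def _random_alkane(rng: np.random.Generator, max_heavy: int) -> str:
    n = int(rng.integers(3, max_heavy + 1))
    # random tree on n carbons with degree cap 4
    mol = Chem.RWMol()
    mol.AddAtom(Chem.Atom(6))
    for _ in range(n - 1):
        candidates = [a.GetIdx() for a in mol.GetAtoms() if a.GetDegree() < 4]
        parent = int(rng.choice(candidates))
        idx = mol.AddAtom(Chem.Atom(6))
        mol.AddBond(parent, idx, Chem.BondType.SINGLE)
    return Chem.MolToSmiles(mol.GetMol())


def _random_decorated(rng: np.random.Generator, max_heavy: int) -> str | None:
    scaffold = _SCAFFOLDS[int(rng.integers(len(_SCAFFOLDS)))]
    mol = Chem.RWMol(Chem.MolFromSmiles(scaffold))
    n_sub = int(rng.integers(1, 5))
    for _ in range(n_sub):
        sub = _SUBSTITUENTS[int(rng.integers(len(_SUBSTITUENTS)))]
        frag = Chem.MolFromSmiles(sub)
        sites = [a.GetIdx() for a in mol.GetAtoms()
                 if a.GetTotalNumHs() > 0 and a.GetDegree() < 4]
        if not sites:
            break
        site = int(rng.choice(sites))
        offset = mol.GetNumAtoms()
        mol = Chem.RWMol(Chem.CombineMols(mol.GetMol(), frag))
        mol.AddBond(site, offset, Chem.BondType.SINGLE)
    out = mol.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception:
        return None
    if not (8 <= out.GetNumHeavyAtoms() <= max_heavy):
        return None
    return Chem.MolToSmiles(out)


def generate_corpus(spec: SyntheticCorpusSpec) -> list[MoleculeRecord]:
    """Deterministic synthetic corpus: exactly ``n_molecules`` unique,
    valid, canonical SMILES with at most ``max_heavy_atoms`` heavy atoms."""
    if spec.n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    if spec.generator_family == "alkanes" and spec.max_heavy_atoms <= _MAX_ENUM_CARBONS:
        bound = _alkane_space_size(spec.max_heavy_atoms)
        if spec.n_molecules > bound:
            raise ValueError(
                f"requested {spec.n_molecules} alkanes but only {bound} exist "
                f"with <= {spec.max_heavy_atoms} heavy atoms")
    rng = np.random.default_rng(spec.seed)
    seen: set[str] = set()
    out: list[MoleculeRecord] = []
    attempts = 0
    max_attempts = 2000 * spec.n_molecules
    while len(out) < spec.n_molecules:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not generate {spec.n_molecules} unique molecules "
                f"(family={spec.generator_family}, max_heavy={spec.max_heavy_atoms})")
        if spec.generator_family == "alkanes":
            smi = _random_alkane(rng, spec.max_heavy_atoms)
        else:
            smi = _random_decorated(rng, spec.max_heavy_atoms)
        if smi is None or smi in seen:
            continue
        seen.add(smi)
        out.append(make_record(smi))
    return out
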