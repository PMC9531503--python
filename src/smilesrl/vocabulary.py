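"""SMILES tokenization and integer encoding shared by all generative models.

Tokenization is longest-match over the SMILES grammar: bracket atoms
``[...]`` are atomic, two-letter organic-subset symbols (Cl, Br) are single
tokens, as are ring-closure digits and ``%nn`` two-digit labels. Joining the
tokens reproduces the input string exactly, so encode/decode round-trips are
the identity on any tokenizable SMILES.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

PAD, START, END = "<pad>", "<start>", "<end>"
SPECIALS = (PAD, START, END)
PAD_INDEX = 0

_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]"      # bracket atom, atomic
    r"|Br|Cl"           # two-letter organic subset
    r"|%\d{2}"          # two-digit ring label
    r"|[BCNOPSFI]"      # aliphatic organic subset
    r"|[bcnops]"        # aromatic organic subset
    r"|[=#/\\.\-+()0-9*:~$])"  # bonds, branches, ring digits
)

DEFAULT_MAX_LEN = 128  # SMILES are typically 20-100 characters


class TokenizationError(ValueError):
    def __init__(self, smiles: str, position: int):
        self.position = position
        super().__init__(
            f"cannot tokenize {smiles!r}: unexpected character "
            f"{smiles[position]!r} at position {position}")


def tokenize(smiles: str) -> list[str]:
    """Split a SMILES string into grammar tokens; join(tokens) == smiles."""
    if not smiles:
        raise ValueError("empty SMILES string")
    tokens: list[str] = []
    pos = 0
    while pos < len(smiles):
        m = _TOKEN_RE.match(smiles, pos)
        if m is None:
            raise TokenizationError(smiles, pos)
        tokens.append(m.group(0))
        pos = m.end()
    return tokens


@dataclass(frozen=True)
class TokenSequence:
    """Integer-encoded SMILES: START ... tokens ... END, no interior PAD."""

    indices: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class Vocabulary:
    """Bijective token <-> index map with PAD/START/END specials.

    Built deterministically from a corpus: specials first (PAD at index 0),
    then the sorted set of corpus tokens.
    """

    tokens: tuple[str, ...]
    index_of: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(
            self, "index_of", {t: i for i, t in enumerate(self.tokens)})
        if len(self.index_of) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")
        if self.tokens[:3] != SPECIALS:
            raise ValueError("vocabulary must start with PAD, START, END")

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def pad(self) -> int:
        return PAD_INDEX

    @property
    def start(self) -> int:
        return 1

    @property
    def end(self) -> int:
        return 2

    @classmethod
    def from_corpus(cls, smiles_iter: Iterable[str]) -> "Vocabulary":
        seen: set[str] = set()
        for smi in smiles_iter:
            seen.update(tokenize(smi))
        return cls(tokens=SPECIALS + tuple(sorted(seen)))

    def encode(self, tokens: Sequence[str],
               max_len: int = DEFAULT_MAX_LEN) -> TokenSequence:
        try:
            body = [self.index_of[t] for t in tokens]
        except KeyError as exc:
            raise KeyError(f"token {exc.args[0]!r} not in vocabulary") from None
        seq = (self.start, *body, self.end)
        if len(seq) > max_len:
            raise ValueError(f"sequence length {len(seq)} exceeds max_len {max_len}")
        return TokenSequence(indices=seq)

    def encode_smiles(self, smiles: str,
                      max_len: int = DEFAULT_MAX_LEN) -> TokenSequence:
        return self.encode(tokenize(smiles), max_len=max_len)

    def decode(self, seq: TokenSequence | Sequence[int]) -> str:
        indices = seq.indices if isinstance(seq, TokenSequence) else seq
        out: list[str] = []
        for idx in indices:
            if idx == self.start or idx == self.pad:
                continue
            if idx == self.end:
                break
            out.append(self.tokens[idx])
        return "".join(out)

    # plain-text serialization: one token per line, order = index
    def save(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.tokens) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        return cls(tokens=tuple(Path(path).read_text().splitlines()))
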