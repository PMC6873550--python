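"""SMILES tokenization, vocabulary handling and integer encoding.

Tokenization is character based with three multi-character exceptions:

* the two-letter halogens ``Cl`` and ``Br`` are single tokens,
* a bracket atom expression ``[...]`` (e.g. ``[nH]``, ``[O-]``) is a single
  token,
* ``%`` followed by exactly two digits (a ring-closure number above 9,
  e.g. ``%10``) is a single token.

The begin token ``^`` is prepended and the end token ``$`` appended to every
sequence.  The end token doubles as the padding symbol when sequences are
batched into a matrix, so a decoded sequence stops at the first end token.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

BEGIN_TOKEN = "^"
END_TOKEN = "$"


class TokenizationError(ValueError):
    """Raised for untokenizable input (unterminated bracket, bad ``%`` ref)."""


def tokenize(smiles: str) -> list[str]:
    """Split a SMILES-like string into tokens, framed by ``^`` and ``$``.

    Validity of the molecule is not checked here; any character outside the
    special cases is its own token.
    """
    tokens: list[str] = [BEGIN_TOKEN]
    i = 0
    n = len(smiles)
    while i < n:
        ch = smiles[i]
        if ch == "[":
            j = smiles.find("]", i)
            if j < 0:
                raise TokenizationError(f"unterminated bracket atom in {smiles!r}")
            tokens.append(smiles[i : j + 1])
            i = j + 1
        elif ch == "%":
            if i + 2 >= n or not smiles[i + 1 : i + 3].isdigit():
                raise TokenizationError(
                    f"'%' not followed by two digits in {smiles!r}"
                )
            tokens.append(smiles[i : i + 3])
            i += 3
        elif smiles[i : i + 2] in ("Cl", "Br"):
            tokens.append(smiles[i : i + 2])
            i += 2
        else:
            tokens.append(ch)
            i += 1
    tokens.append(END_TOKEN)
    return tokens


def detokenize(tokens: Sequence[str]) -> str:
    """Concatenate the payload between ``^`` and the *first* ``$``.

    Inverse of :func:`tokenize` for any tokenizable string.  Tokens after the
    first end token (padding) are ignored.
    """
    if not tokens or tokens[0] != BEGIN_TOKEN:
        raise ValueError("token sequence does not start with the begin token")
    out: list[str] = []
    for tok in tokens[1:]:
        if tok == END_TOKEN:
            return "".join(out)
        out.append(tok)
    raise ValueError("token sequence has no end token")


@dataclass(frozen=True)
class TokenVocabulary:
    """Bijection between tokens and contiguous integer indices.

    The begin and end tokens are always present; the end-token index is also
    the padding index.  Token order is lexicographic so that the indexing is
    reproducible regardless of corpus line order.
    """

    tokens: tuple[str, ...]
    token_to_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if BEGIN_TOKEN not in self.tokens or END_TOKEN not in self.tokens:
            raise ValueError("vocabulary must contain the begin and end tokens")
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")
        object.__setattr__(
            self, "token_to_index", {t: i for i, t in enumerate(self.tokens)}
        )

    @property
    def size(self) -> int:
        return len(self.tokens)

    @property
    def begin_index(self) -> int:
        return self.token_to_index[BEGIN_TOKEN]

    @property
    def end_index(self) -> int:
        return self.token_to_index[END_TOKEN]

    # padding uses the end token
    @property
    def pad_index(self) -> int:
        return self.token_to_index[END_TOKEN]

    def index_to_token(self, index: int) -> str:
        return self.tokens[index]

    def encode(self, tokens: Sequence[str]) -> np.ndarray:
        """Map a token sequence to an integer vector; unknown tokens are a hard error."""
        try:
            return np.array([self.token_to_index[t] for t in tokens], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"token {exc.args[0]!r} not in vocabulary") from None

    def decode(self, indices: Iterable[int]) -> list[str]:
        toks = []
        for i in indices:
            if not 0 <= int(i) < self.size:
                raise IndexError(f"index {i} outside vocabulary of size {self.size}")
            toks.append(self.tokens[int(i)])
        return toks

    def save(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.tokens) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "TokenVocabulary":
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        return cls(tuple(lines))


def build_vocabulary(corpus: Iterable[str]) -> TokenVocabulary:
    """Vocabulary of all distinct tokens of a corpus, lexicographically ordered.

    Tokenization errors propagate annotated with the offending line number.
    """
    seen: set[str] = set()
    n_lines = 0
    for lineno, smiles in enumerate(corpus, start=1):
        n_lines += 1
        try:
            seen.update(tokenize(smiles))
        except TokenizationError as exc:
            raise TokenizationError(f"line {lineno}: {exc}") from None
    if n_lines == 0:
        raise ValueError("empty corpus")
    return TokenVocabulary(tuple(sorted(seen)))


def encode_sequence(smiles: str, vocab: TokenVocabulary) -> np.ndarray:
    """Tokenize and encode one SMILES string."""
    return vocab.encode(tokenize(smiles))


def pad_batch(sequences: Sequence[np.ndarray], vocab: TokenVocabulary) -> np.ndarray:
    """Stack encoded sequences into a matrix right-padded with the end token."""
    if len(sequences) == 0:
        raise ValueError("empty batch")
    width = max(len(s) for s in sequences)
    out = np.full((len(sequences), width), vocab.pad_index, dtype=np.int64)
    for r, seq in enumerate(sequences):
        out[r, : len(seq)] = seq
    return out
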