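"""Utility surface: string helpers, alphabets, ML encodings, random sampling.

* :func:`len_selfies` / :func:`split_selfies` - symbol-level length and
  tokenization (the dot and ``[nop]`` each count as one symbol).
* :func:`get_alphabet_from_selfies` - minimal vocabulary of a corpus
  (``[nop]`` excluded; callers add it back for padding).
* :func:`selfies_to_encoding` / :func:`encoding_to_selfies` - label and
  one-hot encodings over a symbol-to-index vocabulary, padding with ``[nop]``.
* :func:`get_semantic_robust_alphabet` - every atom symbol admissible under a
  constraint table (each listed (element, charge) with every bond prefix whose
  order fits the valence) plus the branch and ring symbol families; 69 symbols
  under the default constraints.
* :func:`get_chain_growth_alphabet` - the multi-bond-free, monovalent-free
  filtering of the alphabet (19 symbols under the defaults) that biases random
  sampling toward long chains and larger molecules.
* :func:`sample_random_selfies` - i.i.d. uniform symbol sampling; by
  construction every sample decodes to a valence-satisfying molecule.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .constraints import ConstraintsLike, _coerce
from .exceptions import EncodingError, MalformedStringError
from .selfies_syntax import (
    BOND_ORDER,
    AtomType,
    tokenize_selfies,
)

__all__ = [
    "len_selfies",
    "split_selfies",
    "get_alphabet_from_selfies",
    "get_semantic_robust_alphabet",
    "get_chain_growth_alphabet",
    "sample_random_selfies",
    "selfies_to_encoding",
    "encoding_to_selfies",
    "EncodingVocabulary",
]

NOP = "[nop]"


def len_selfies(selfies: str) -> int:
    """Number of symbols in a SELFIES string (dots and ``[nop]`` included)."""
    return len(tokenize_selfies(selfies))


def split_selfies(selfies: str) -> list[str]:
    """Tokenize a SELFIES string into its constituent symbols."""
    return tokenize_selfies(selfies)


def get_alphabet_from_selfies(corpus: Iterable[str]) -> set[str]:
    """Minimal vocabulary: the distinct tokens of a corpus, minus ``[nop]``."""
    alphabet: set[str] = set()
    for s in corpus:
        try:
            alphabet.update(tokenize_selfies(s))
        except MalformedStringError as exc:
            raise MalformedStringError(f"in corpus string {s!r}: {exc}") from exc
    alphabet.discard(NOP)
    return alphabet


def get_semantic_robust_alphabet(constraints: ConstraintsLike = None) -> set[str]:
    """Semantically constrained symbol alphabet for a constraint table.

    Contains, for every (element, charge) listed explicitly in the table
    (catch-all excluded), the atom symbols with bond prefixes '', '=', '#'
    whose order does not exceed the entry's maximum; plus branch symbols for
    all prefixes and sizes and ring symbols with prefixes '' and '=' (sizes
    1-3).  The default table yields 69 symbols: 54 atom + 9 branch + 6 ring.
    """
    cs = _coerce(constraints)
    alphabet: set[str] = set()
    for (element, charge), nu in cs.entries.items():
        atom = AtomType(element=element, charge=charge)
        for prefix in ("", "=", "#"):
            if BOND_ORDER[prefix] <= nu:
                alphabet.add(f"[{prefix}{atom.spec()}]")
    for prefix in ("", "=", "#"):
        for size in (1, 2, 3):
            alphabet.add(f"[{prefix}Branch{size}]")
    for prefix in ("", "="):
        for size in (1, 2, 3):
            alphabet.add(f"[{prefix}Ring{size}]")
    return alphabet


def get_chain_growth_alphabet(constraints: ConstraintsLike = None) -> set[str]:
    """Filtered alphabet biased toward large molecules.

    Drops every atom symbol with a '=' or '#' prefix or a monovalent atom
    type, and every branch/ring symbol except ``[Branch1]`` and ``[Ring1]``.
    Multi-bonds and low-valence atoms exhaust valences quickly and terminate
    the derivation early; without them random strings grow long chains.
    19 symbols under the default constraints.
    """
    cs = _coerce(constraints)
    from .selfies_syntax import parse_symbol

    filtered: set[str] = set()
    for token in get_semantic_robust_alphabet(cs):
        symbol = parse_symbol(token)
        if symbol.variant == "atom":
            if symbol.bond in ("=", "#"):
                continue
            if cs.get(symbol.atom_type.element, symbol.atom_type.charge) == 1:
                continue
            filtered.add(token)
        elif token in ("[Branch1]", "[Ring1]"):
            filtered.add(token)
    return filtered


def sample_random_selfies(
    alphabet: Iterable[str],
    length: int,
    count: int = 1,
    seed: Optional[int] = None,
    rng: Optional[random.Random] = None,
) -> list[str]:
    """Sample ``count`` SELFIES strings of ``length`` i.i.d. uniform symbols.

    Deterministic under ``seed`` (or an explicit ``rng``); the alphabet is
    sorted first so reproducibility does not depend on set iteration order.
    """
    pool = sorted(alphabet)
    if not pool:
        raise ValueError("alphabet must be non-empty")
    if length < 0 or count < 0:
        raise ValueError("length and count must be >= 0")
    if rng is None:
        rng = random.Random(seed)
    return ["".join(rng.choice(pool) for _ in range(length)) for _ in range(count)]


@dataclass
class EncodingVocabulary:
    """Bijective symbol <-> label mapping used for ML encodings.

    Must contain ``[nop]`` before use for padding.
    """

    stoi: dict[str, int]
    itos: dict[int, str] = field(init=False)

    def __post_init__(self) -> None:
        if len(set(self.stoi.values())) != len(self.stoi):
            raise EncodingError("vocabulary labels must be distinct (bijective mapping)")
        self.itos = {i: s for s, i in self.stoi.items()}

    @classmethod
    def from_alphabet(cls, alphabet: Iterable[str], include_nop: bool = True):
        symbols = sorted(alphabet)
        if include_nop and NOP not in symbols:
            symbols.insert(0, NOP)
        return cls(stoi={s: i for i, s in enumerate(symbols)})

    @property
    def size(self) -> int:
        return len(self.stoi)


VocabLike = Union[EncodingVocabulary, Mapping[str, int]]


def _stoi(vocab: VocabLike) -> Mapping[str, int]:
    return vocab.stoi if isinstance(vocab, EncodingVocabulary) else vocab


def selfies_to_encoding(
    selfies: str,
    vocab: VocabLike,
    pad_to_len: int = -1,
    enc_type: str = "both",
):
    """Convert a SELFIES string into label and/or one-hot encodings.

    The string is first padded with ``[nop]`` to ``pad_to_len`` symbols (no
    padding when -1).  ``enc_type`` selects ``"label"``, ``"one_hot"`` or
    ``"both"``; labels are a list of ints, the one-hot form a (length, vocab
    size) integer array.
    """
    stoi = _stoi(vocab)
    tokens = tokenize_selfies(selfies)
    if pad_to_len >= 0:
        if len(tokens) > pad_to_len:
            raise EncodingError(
                f"string has {len(tokens)} symbols, longer than pad_to_len={pad_to_len}"
            )
        if NOP not in stoi:
            raise EncodingError("vocabulary must contain '[nop]' to pad")
        tokens = tokens + [NOP] * (pad_to_len - len(tokens))
    try:
        labels = [stoi[t] for t in tokens]
    except KeyError as exc:
        raise EncodingError(f"symbol {exc.args[0]!r} is not in the vocabulary") from exc
    if enc_type == "label":
        return labels
    one_hot = np.zeros((len(labels), len(stoi)), dtype=int)
    for row, label in enumerate(labels):
        one_hot[row, label] = 1
    if enc_type == "one_hot":
        return one_hot
    if enc_type == "both":
        return labels, one_hot
    raise ValueError("enc_type must be 'label', 'one_hot' or 'both'")


def encoding_to_selfies(
    encoding,
    vocab: VocabLike,
    enc_type: str = "label",
) -> str:
    """Invert :func:`selfies_to_encoding`, stripping trailing ``[nop]``."""
    stoi = _stoi(vocab)
    itos = (
        vocab.itos
        if isinstance(vocab, EncodingVocabulary)
        else {i: s for s, i in stoi.items()}
    )
    if len(itos) != len(stoi):
        raise EncodingError("vocabulary labels must be distinct (bijective mapping)")
    if enc_type == "one_hot":
        arr = np.asarray(encoding)
        if arr.ndim != 2 or not ((arr.sum(axis=1) == 1).all() and set(np.unique(arr)) <= {0, 1}):
            raise EncodingError("one-hot encoding rows must be unit vectors")
        labels = [int(i) for i in arr.argmax(axis=1)]
    elif enc_type == "label":
        labels = [int(i) for i in encoding]
    else:
        raise ValueError("enc_type must be 'label' or 'one_hot'")
    try:
        tokens = [itos[i] for i in labels]
    except KeyError as exc:
        raise EncodingError(f"label {exc.args[0]!r} is not in the vocabulary") from exc
    while tokens and tokens[-1] == NOP:
        tokens.pop()
    return "".join(tokens)
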