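"""Tokenization and parsing of SELFIES symbols, and the overloaded index code.

A SELFIES string is a sequence of square-bracketed symbols (plus the bare dot
separating fragments).  Symbols come in six variants:

* atom      ``[beta alpha]``  - bond prefix beta in {'', '=', '#', '/', '\\'}
  followed by an atom specification (isotope, element, chirality, H count,
  charge), e.g. ``[C]``, ``[=O]``, ``[#13C]``, ``[C@@H1]``, ``[N+1]``
* branch    ``[beta Branch l]`` with beta in {'', '=', '#'}, l in {1, 2, 3}
* ring      ``[beta Ring l]``  with the same beta and l
* stereo ring ``[b1 b2 Ring l]`` with b1, b2 in {'-', '/', '\\'}, not both '-'
  (stereo markers for the two ring-closure tags)
* dot       ``.`` (fragment delimiter)
* nop       ``[nop]`` (padding; ignored by the decoder)

Atom symbols are semantically unique: the charge always carries an explicit
magnitude (``[N+1]``, never ``[N+]``) and an H count always carries a digit
(``[CH1]``, never ``[CH]``); non-canonical spellings are rejected rather than
normalised.

Symbols following a branch or ring symbol are overloaded as hexadecimal
digits through a fixed 16-entry symbol-to-index table; ``l`` of them encode a
number N = 1 + sum(c_k * 16**(l-k)), used as a branch payload length or a
ring-closure offset.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

from .constraints import PERIODIC_TABLE
from .exceptions import EncodingError, InvalidSymbolError, MalformedStringError

__all__ = [
    "AtomType",
    "SelfiesSymbol",
    "tokenize_selfies",
    "parse_symbol",
    "write_symbol",
    "symbol_index",
    "decode_index",
    "encode_index",
    "INDEX_ALPHABET",
    "ORGANIC_SUBSET",
    "BOND_ORDER",
]

#: Elements SMILES may write without brackets (implicit-hydrogen atoms).
ORGANIC_SUBSET = frozenset({"B", "C", "N", "O", "S", "P", "F", "Cl", "Br", "I"})

#: d(beta): the bond order represented by each bond prefix.
BOND_ORDER = {"": 1, "=": 2, "#": 3, "/": 1, "\\": 1}

#: Canonical representative symbol for each index digit 0..15.  This is the
#: inverse of the symbol-to-index table; all sixteen are distinct symbols.
INDEX_ALPHABET: tuple[str, ...] = (
    "[C]",
    "[Ring1]",
    "[Ring2]",
    "[Branch1]",
    "[=Branch1]",
    "[#Branch1]",
    "[Branch2]",
    "[=Branch2]",
    "[#Branch2]",
    "[O]",
    "[N]",
    "[=N]",
    "[=C]",
    "[#C]",
    "[S]",
    "[P]",
)

_INDEX_OF = {tok: i for i, tok in enumerate(INDEX_ALPHABET)}


@dataclass(frozen=True)
class AtomType:
    """An atom specification: isotope, element, chirality, H count, charge.

    ``h_count is None`` means the symbol carries no explicit hydrogen count;
    for a bare organic-subset atom this leaves hydrogens implicit in SMILES.
    """

    element: str
    isotope: Optional[int] = None
    chirality: Optional[str] = None  # '@' or '@@'
    h_count: Optional[int] = None
    charge: int = 0

    @property
    def is_bare_organic(self) -> bool:
        """True when the atom writes as a plain organic-subset SMILES atom."""
        return (
            self.element in ORGANIC_SUBSET
            and self.isotope is None
            and self.chirality is None
            and self.h_count is None
            and self.charge == 0
        )

    def key(self) -> tuple:
        """Equality key for molecular-graph comparison.

        For decorated (bracket-form) atoms an absent H count is equivalent to
        an explicit 0 (neither adds hydrogens); bare organic atoms keep the
        implicit-hydrogen distinction.
        """
        h = self.h_count
        if not self.is_bare_organic:
            h = h or 0
        return (self.element, self.isotope, self.chirality, h, self.charge)

    def spec(self) -> str:
        """The inner text of this atom's SELFIES symbol (without bond prefix)."""
        if self.is_bare_organic:
            return self.element
        parts = []
        if self.isotope is not None:
            parts.append(str(self.isotope))
        parts.append(self.element)
        if self.chirality:
            parts.append(self.chirality)
        # An explicit H0 is redundant once another decoration forces bracket
        # form, but it is what distinguishes e.g. [CH0] from the bare,
        # implicit-hydrogen [C].
        other_decoration = (
            self.isotope is not None
            or self.chirality
            or self.charge != 0
            or self.element not in ORGANIC_SUBSET
        )
        if self.h_count is not None and not (self.h_count == 0 and other_decoration):
            parts.append(f"H{self.h_count}")
        if self.charge:
            parts.append(f"{self.charge:+d}")
        return "".join(parts)


@dataclass(frozen=True)
class SelfiesSymbol:
    """A parsed SELFIES symbol (tagged union over the six variants)."""

    variant: str  # 'atom' | 'branch' | 'ring' | 'stereo_ring' | 'dot' | 'nop'
    bond: str = ""  # beta (atom/branch/ring variants)
    size: int = 0  # l (branch/ring/stereo_ring variants)
    stereo: Optional[tuple[str, str]] = None  # (b1, b2) for stereo_ring
    atom_type: Optional[AtomType] = None

    @property
    def raw(self) -> str:
        return write_symbol(self)


_TOKEN_RE = re.compile(r"\[[^\[\]]*\]|\.")

_ATOM_RE = re.compile(
    r"""^(?P<bond>[=\#/\\]?)
         (?P<isotope>\d+)?
         (?P<element>[A-Z][a-z]?)
         (?P<chirality>@{1,2})?
         (?:H(?P<hcount>\d+))?
         (?:(?P<sign>[+-])(?P<magnitude>\d+))?$""",
    re.VERBOSE,
)
_BRANCH_RE = re.compile(r"^(?P<bond>[=\#]?)Branch(?P<size>[123])$")
_RING_RE = re.compile(r"^(?P<bond>[=\#]?)Ring(?P<size>[123])$")
_STEREO_RING_RE = re.compile(r"^(?P<b1>[-/\\])(?P<b2>[-/\\])Ring(?P<size>[123])$")

# Tell-tale substrings of non-canonical atom tokens, reported specially.
_BAD_CHARGE_RE = re.compile(r"(\+\+|--|[+-]$|[+-][^\d])")


def tokenize_selfies(selfies: str) -> list[str]:
    """Split a SELFIES string into its tokens (bracketed symbols and dots).

    Concatenating the returned tokens reproduces the input.  Unbalanced or
    nested brackets, and any character outside a bracket other than ``.``,
    raise :class:`MalformedStringError`.
    """
    tokens = []
    pos = 0
    for m in _TOKEN_RE.finditer(selfies):
        if m.start() != pos:
            raise MalformedStringError(
                f"unexpected character(s) {selfies[pos:m.start()]!r} at position "
                f"{pos} of {selfies!r}"
            )
        tokens.append(m.group())
        pos = m.end()
    if pos != len(selfies):
        raise MalformedStringError(
            f"unexpected character(s) {selfies[pos:]!r} at position {pos} of {selfies!r}"
        )
    return tokens


def parse_symbol(token: str) -> SelfiesSymbol:
    """Parse a single bracketed token (or ``.``) into a :class:`SelfiesSymbol`.

    Non-canonical atom tokens (``[N+]``, ``[CH]``, ``[Fe++]``) are rejected,
    not normalised.  The unicode minus (U+2212), a typographic variant of
    ``-`` in stereo ring symbols, is accepted and normalised.
    """
    if token == ".":
        return SelfiesSymbol(variant="dot")
    if not (token.startswith("[") and token.endswith("]") and len(token) >= 2):
        raise InvalidSymbolError(f"not a bracketed SELFIES token: {token!r}")
    body = token[1:-1].replace("−", "-")
    if body == "nop":
        return SelfiesSymbol(variant="nop")

    m = _STEREO_RING_RE.match(body)
    if m:
        b1, b2 = m.group("b1"), m.group("b2")
        if b1 == "-" and b2 == "-":
            raise InvalidSymbolError(
                f"stereo ring symbol {token!r} must carry at least one of '/' or '\\'"
            )
        return SelfiesSymbol(
            variant="stereo_ring", size=int(m.group("size")), stereo=(b1, b2)
        )
    m = _BRANCH_RE.match(body)
    if m:
        return SelfiesSymbol(
            variant="branch", bond=m.group("bond"), size=int(m.group("size"))
        )
    m = _RING_RE.match(body)
    if m:
        return SelfiesSymbol(
            variant="ring", bond=m.group("bond"), size=int(m.group("size"))
        )

    m = _ATOM_RE.match(body)
    if m is None:
        hint = ""
        if "Branch" in body or "Ring" in body:
            hint = " (branch/ring symbols only admit bond prefixes '=' and '#')"
        elif _BAD_CHARGE_RE.search(body):
            hint = " (charge must be written with an explicit magnitude, e.g. '+1')"
        elif re.search(r"H(?!\d)", body):
            hint = " (hydrogen count must be written with an explicit digit, e.g. 'H1')"
        raise InvalidSymbolError(f"unrecognised SELFIES symbol {token!r}{hint}")
    element = m.group("element")
    if element not in PERIODIC_TABLE:
        raise InvalidSymbolError(f"unknown element {element!r} in symbol {token!r}")
    atom = AtomType(
        element=element,
        isotope=int(m.group("isotope")) if m.group("isotope") else None,
        chirality=m.group("chirality"),
        h_count=int(m.group("hcount")) if m.group("hcount") is not None else None,
        charge=int(m.group("sign") + m.group("magnitude")) if m.group("sign") else 0,
    )
    return SelfiesSymbol(variant="atom", bond=m.group("bond"), atom_type=atom)


def write_symbol(symbol: SelfiesSymbol) -> str:
    """Render a symbol in canonical text form (inverse of :func:`parse_symbol`)."""
    if symbol.variant == "dot":
        return "."
    if symbol.variant == "nop":
        return "[nop]"
    if symbol.variant == "atom":
        return f"[{symbol.bond}{symbol.atom_type.spec()}]"
    if symbol.variant == "branch":
        return f"[{symbol.bond}Branch{symbol.size}]"
    if symbol.variant == "ring":
        return f"[{symbol.bond}Ring{symbol.size}]"
    if symbol.variant == "stereo_ring":
        b1, b2 = symbol.stereo
        return f"[{b1}{b2}Ring{symbol.size}]"
    raise ValueError(f"unknown symbol variant {symbol.variant!r}")


def symbol_index(token: str) -> int:
    """Index digit (0..15) of a token under the symbol-to-index table.

    Total: every token not listed in the table has index 0.
    """
    return _INDEX_OF.get(token, 0)


def decode_index(tokens: Sequence[str], size: int) -> int:
    """Decode up to ``size`` index tokens as hexadecimal digits into N.

    Missing digits (exhausted queue) default to 0, so
    N = 1 + sum(c_k * 16**(size-k)) is always in 1..16**size.
    """
    digits = [symbol_index(t) for t in tokens[:size]]
    digits += [0] * (size - len(digits))
    n = 0
    for c in digits:
        n = n * 16 + c
    return n + 1


def encode_index(n: int, size: int) -> list[str]:
    """Encode N (1..16**size) as ``size`` canonical index-digit tokens.

    Inverse of :func:`decode_index` on its range.
    """
    if not 1 <= n <= 16**size:
        raise EncodingError(f"index {n} out of range 1..{16 ** size} for size {size}")
    value = n - 1
    digits = []
    for _ in range(size):
        digits.append(value % 16)
        value //= 16
    return [INDEX_ALPHABET[d] for d in reversed(digits)]
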