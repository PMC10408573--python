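"""Exception hierarchy for selgram.

All user-facing errors derive from :class:`SelgramError` so callers can catch
one type.  Lexical errors (malformed tokens) are distinct from semantic ones
(valence violations) because the decoder is total over well-formed symbol
sequences: only the former can make :func:`selgram.decode` fail.
"""


class SelgramError(Exception):
    """Base class for all selgram errors."""


class ConfigurationError(SelgramError):
    """Invalid valence-constraint configuration (bad preset name, missing
    catch-all, negative or non-integer maximum bond counts, bad element)."""


class MalformedStringError(SelgramError):
    """A SELFIES string that does not tokenize (unbalanced brackets, stray
    characters outside brackets)."""


class InvalidSymbolError(SelgramError):
    """A bracketed token that is not a well-formed SELFIES symbol, or an atom
    symbol whose explicit hydrogen count exceeds its maximum bond count."""


class DecodeError(SelgramError):
    """Raised by the decoder for lexical failures only; every well-formed
    symbol sequence decodes successfully."""


class EncodeError(SelgramError):
    """Raised by the encoder when the input SMILES cannot be translated
    (propagates parse/kekulization/valence failures, oversized indices)."""


class SmilesSyntaxError(EncodeError):
    """Syntactically invalid SMILES (unmatched branch bracket or ring number,
    dangling bond, bad bracket atom)."""


class UnsupportedFeatureError(EncodeError):
    """Valid SMILES using a feature outside the supported subset (wildcard
    ``*``, quadruple bond ``$``, extended chirality tags, cross-fragment
    ring closures)."""


class SemanticError(EncodeError):
    """SMILES whose molecular graph violates the active valence constraints."""


class KekulizationError(EncodeError):
    """No consistent alternating single/double bond assignment exists for the
    aromatic subgraph."""


class EncodingError(SelgramError):
    """Label/one-hot encoding failure (unknown token, missing ``[nop]``,
    over-length input, out-of-range index code)."""
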