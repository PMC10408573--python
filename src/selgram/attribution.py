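"""Attribution: tracing output tokens back to the input tokens that caused them.

Both translation directions can report, for every output token, the input
token(s) responsible for it.  An output symbol may have several sources: the
SMILES parentheses of a branch trace back to the branch symbol and its index
digits; a ring-closure tag traces back to the ring symbol and its digits; a
demoted bond token traces to the atom symbol that carried the bond prefix.
Input symbols that produce no output (padding, symbols discarded after the
derivation terminates, rejected ring closures) are reported separately in an
``unconsumed`` list.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

from .constraints import ConstraintsLike
from .decoder import decode_to_graph
from .encoder import encode_to_graph
from .smiles_io import write_smiles_attributed

__all__ = [
    "Attribution",
    "AttributionMap",
    "AttributedTranslation",
    "translate_attributed",
    "decode_attributed",
    "encode_attributed",
]


@dataclass(frozen=True)
class Attribution:
    """One input token (text and 0-based position) responsible for an output."""

    token: str
    index: int


@dataclass(frozen=True)
class AttributionMap:
    """Sources of one output token at one output position."""

    output_token: str
    output_index: int
    sources: tuple[Attribution, ...]

    def to_dict(self) -> dict:
        return {
            "output_index": self.output_index,
            "output_token": self.output_token,
            "sources": [
                {"token": s.token, "index": s.index} for s in self.sources
            ],
        }


class AttributedTranslation(NamedTuple):
    output: str
    attributions: list[AttributionMap]
    unconsumed: list[Attribution]


def _maps(tokens) -> list[AttributionMap]:
    return [
        AttributionMap(
            output_token=text,
            output_index=i,
            sources=tuple(Attribution(tok, idx) for tok, idx in sources),
        )
        for i, (text, sources) in enumerate(tokens)
    ]


def decode_attributed(
    selfies: str, constraints: ConstraintsLike = None
) -> AttributedTranslation:
    """Decode with per-output-token attribution (SELFIES -> SMILES)."""
    graph, unconsumed = decode_to_graph(selfies, constraints)
    tokens = write_smiles_attributed(graph)
    return AttributedTranslation(
        output="".join(text for text, _ in tokens),
        attributions=_maps(tokens),
        unconsumed=[Attribution(tok, idx) for tok, idx in unconsumed],
    )


def encode_attributed(
    smiles: str, constraints: ConstraintsLike = None
) -> AttributedTranslation:
    """Encode with per-output-symbol attribution (SMILES -> SELFIES)."""
    _, tokens = encode_to_graph(smiles, constraints)
    return AttributedTranslation(
        output="".join(text for text, _ in tokens),
        attributions=_maps(tokens),
        unconsumed=[],
    )


def translate_attributed(
    s: str, direction: str, constraints: ConstraintsLike = None
) -> AttributedTranslation:
    """Attributed translation in either direction.

    ``direction`` is ``"selfies->smiles"`` or ``"smiles->selfies"``.  The
    output string is identical to the non-attributed translation.
    """
    if direction == "selfies->smiles":
        return decode_attributed(s, constraints)
    if direction == "smiles->selfies":
        return encode_attributed(s, constraints)
    raise ValueError(
        f"direction must be 'selfies->smiles' or 'smiles->selfies', got {direction!r}"
    )


def attribution_report(result: AttributedTranslation) -> str:
    """Line-oriented text report of an attributed translation."""
    lines = [f"output: {result.output}"]
    for m in result.attributions:
        srcs = ", ".join(f"{s.token}@{s.index}" for s in m.sources) or "-"
        lines.append(f"{m.output_index:4d}  {m.output_token:<10s} <- {srcs}")
    if result.unconsumed:
        lines.append("unconsumed input:")
        for s in result.unconsumed:
            lines.append(f"      {s.token}@{s.index}")
    return "\n".join(lines) + "\n"
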