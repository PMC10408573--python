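"""SMILES -> SELFIES translation.

The input is parsed, kekulized if it contains aromatic symbols, and validated
against the active valence constraints; translation then walks the molecular
graph in traversal order.  Each atom becomes one symbol grouping the atom with
its incoming bond token.  A branch (every non-final child of an atom) becomes
``[beta Branch l]`` followed by the index code of its payload length and the
recursively translated payload; the bond prefix appears on both the branch
symbol (which reserves capacity at the parent) and the payload's first atom
symbol (which realises the bond order under the derivation rules).  A ring
closure becomes ``[beta Ring l]`` (or the stereo form when either closure tag
carries ``/`` or ``\\``) followed by the index code of the offset between its
two endpoints in traversal order.  ``l`` is always the smallest size whose
index range covers the value, and ``beta`` is taken verbatim from the input
bond, so the translation inverts the decoder exactly:
``decode(encode(s))`` is graph-equal to ``kekulize(parse_smiles(s))`` and
preserves the atom traversal order.
"""

from __future__ import annotations

from typing import Optional

from .constraints import ConstraintsLike, _coerce
from .exceptions import EncodeError, SemanticError
from .molgraph import DirectedBond, MolecularGraph, Source, check_valences
from .selfies_syntax import AtomType, encode_index
from .smiles_io import kekulize, parse_smiles

__all__ = ["encode", "encode_to_graph", "encode_atom_symbol"]

_ORDER_TOKEN = {1: "", 2: "=", 3: "#"}

_SelfiesToken = tuple[str, list[Source]]  # (symbol text, input-token sources)


def _min_size(n: int, what: str) -> int:
    for size in (1, 2, 3):
        if n <= 16**size:
            return size
    raise EncodeError(f"{what} {n} exceeds the maximum index value 16**3")


def encode_atom_symbol(atom_type: AtomType, incoming_bond: str = "") -> str:
    """Canonical SELFIES atom symbol for an atom and its incoming bond token.

    Organic-subset atoms with no decorations write bare (``[O]``, ``[=N]``);
    anything else carries the full canonical decoration with explicit H digit
    and signed-magnitude charge (``[13CH1]``, ``[N+1]``).
    """
    return f"[{incoming_bond}{atom_type.spec()}]"


def _bond_prefix(bond: DirectedBond) -> str:
    return bond.stereo or _ORDER_TOKEN[bond.order]


def encode_to_graph(
    smiles: str, constraints: ConstraintsLike = None
) -> tuple[MolecularGraph, list[_SelfiesToken]]:
    """Parse, kekulize and validate a SMILES string, then translate it.

    Returns the (kekulized) graph and the emitted SELFIES tokens with their
    input-token sources.
    """
    cs = _coerce(constraints)
    graph = kekulize(parse_smiles(smiles))
    violations = check_valences(graph, cs)
    if violations:
        v = violations[0]
        atom = graph.atoms[v.atom_index]
        raise SemanticError(
            f"SMILES {smiles!r} violates the valence constraints: atom "
            f"{v.atom_index} ({atom.atom_type.element}) makes {v.total_order} "
            f"bonds but at most {v.capacity} are allowed"
        )
    tokens: list[_SelfiesToken] = []
    for i, root in enumerate(graph.roots):
        if i:
            tokens.append((".", graph.atoms[root].sources))
        tokens.extend(_emit_chain(graph, root, incoming=None))
    return graph, tokens


def encode(smiles: str, constraints: ConstraintsLike = None) -> str:
    """Translate a SMILES string into a SELFIES string."""
    _, tokens = encode_to_graph(smiles, constraints)
    return "".join(text for text, _ in tokens)


def _emit_chain(
    graph: MolecularGraph, atom_idx: int, incoming: Optional[DirectedBond]
) -> list[_SelfiesToken]:
    """Translate the subtree rooted at ``atom_idx`` (with its incoming bond).

    The chain continuation is iterated rather than recursed so long chains
    stay within the recursion limit; recursion depth tracks branch nesting.
    """
    out: list[_SelfiesToken] = []
    while True:
        atom = graph.atoms[atom_idx]
        prefix = _bond_prefix(incoming) if incoming is not None else ""
        atom_sources = list(incoming.sources) if incoming is not None else list(atom.sources)
        out.append((encode_atom_symbol(atom.atom_type, prefix), atom_sources))

        # Ring closures are emitted at the atom where the input closed them
        # (the right atom), keeping the input digit order.
        for bond in graph.ring_bonds(atom_idx):
            if bond.dst != atom_idx:
                continue
            offset = bond.dst - bond.src
            size = _min_size(offset, "ring-closure offset")
            if bond.stereo_pair is not None:
                b1 = bond.stereo_pair[0] or "-"
                b2 = bond.stereo_pair[1] or "-"
                symbol = f"[{b1}{b2}Ring{size}]"
            else:
                symbol = f"[{_ORDER_TOKEN[bond.order]}Ring{size}]"
            out.append((symbol, bond.sources))
            for digit in encode_index(offset, size):
                out.append((digit, bond.sources))

        children = graph.out_bonds(atom_idx)
        for bond in children[:-1]:
            payload = _emit_chain(graph, bond.dst, incoming=bond)
            size = _min_size(len(payload), "branch payload length")
            branch_symbol = f"[{_ORDER_TOKEN[bond.order]}Branch{size}]"
            branch_sources = (bond.branch_sources or []) + list(
                graph.atoms[bond.dst].sources
            )
            out.append((branch_symbol, branch_sources))
            for digit in encode_index(len(payload), size):
                out.append((digit, branch_sources))
            out.extend(payload)
        if not children:
            return out
        incoming = children[-1]
        atom_idx = incoming.dst
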