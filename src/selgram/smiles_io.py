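"""SMILES reading, kekulization, and traversal-order-preserving writing.

The reader supports organic-subset atoms (with their aromatic lowercase
forms), bracket atoms with isotope / @ or @@ chirality / H count / charge,
bond tokens ``- = # / \\``, nested branches, numeric ring closures (including
the two-digit ``%nn`` form), and dots.  Wildcard ``*``, quadruple bond ``$``
and extended chirality tags are rejected as unsupported.  Traversal order and
aromatic flags are recorded on the graph.

Kekulization replaces aromatic bond markers with an alternating single/double
assignment: every aromatic atom with leftover valence (capacity beyond its
sigma bonds and hydrogens) must receive exactly one double bond, which is a
perfect-matching problem on the aromatic subgraph; matched edges become double
bonds and the aromatic flags are cleared.

The writer re-emits a graph in stored traversal order, parenthesising every
non-final child and transcribing ring bonds as paired numeric tags (smallest
free number, reused after closure, ``%nn`` from 10 up).
"""

from __future__ import annotations

import re
from typing import Optional

import networkx as nx

from .constraints import PERIODIC_TABLE
from .exceptions import (
    KekulizationError,
    SmilesSyntaxError,
    UnsupportedFeatureError,
)
from .molgraph import DirectedBond, MolecularGraph, Source
from .selfies_syntax import AtomType, ORGANIC_SUBSET

__all__ = ["parse_smiles", "kekulize", "write_smiles", "write_smiles_attributed"]

_ORDER_TOKEN = {1: "", 2: "=", 3: "#"}
_TOKEN_ORDER = {"-": 1, "=": 2, "#": 3, "/": 1, "\\": 1}

#: Valence model used only to decide which aromatic atoms need a double bond.
_AROMATIC_VALENCE = {"B": 3, "C": 4, "N": 3, "O": 2, "P": 3, "S": 2}

_AROMATIC_ORGANIC = {"b", "c", "n", "o", "p", "s"}
_ORGANIC_TOKENS = ("Cl", "Br", "B", "C", "N", "O", "S", "P", "F", "I")

_BRACKET_RE = re.compile(
    r"""^\[(?P<isotope>\d+)?
          (?P<element>[A-Z][a-z]?|[bcnops])
          (?P<chirality>@{1,2})?
          (?:(?P<h>H)(?P<hcount>\d+)?)?
          (?P<charge>\+\d+|-\d+|\++|-+)?
        \]$""",
    re.VERBOSE,
)


def _tokenize_smiles(s: str) -> list[str]:
    """Split a SMILES string into atom / bond / paren / ring-tag / dot tokens."""
    tokens = []
    i = 0
    n = len(s)
    while i < n:
        c = s[i]
        if c == "[":
            j = s.find("]", i)
            if j < 0:
                raise SmilesSyntaxError(f"unclosed bracket atom at position {i} in {s!r}")
            tokens.append(s[i : j + 1])
            i = j + 1
        elif c == "%":
            if i + 2 >= n or not s[i + 1 : i + 3].isdigit():
                raise SmilesSyntaxError(f"bad %nn ring tag at position {i} in {s!r}")
            tokens.append(s[i : i + 3])
            i += 3
        elif c in "*$":
            raise UnsupportedFeatureError(
                f"SMILES feature {c!r} (wildcard/quadruple bond) is not supported"
            )
        elif c in "-=#/\\().":
            tokens.append(c)
            i += 1
        elif c.isdigit():
            tokens.append(c)
            i += 1
        else:
            matched = None
            for tok in _ORGANIC_TOKENS:
                if s.startswith(tok, i):
                    matched = tok
                    break
            if matched is None and c in _AROMATIC_ORGANIC:
                matched = c
            if matched is None:
                raise SmilesSyntaxError(f"unexpected character {c!r} at position {i} in {s!r}")
            tokens.append(matched)
            i += len(matched)
    return tokens


def _parse_bracket_atom(token: str) -> tuple[AtomType, bool]:
    """Parse a bracket atom token into (AtomType, aromatic flag)."""
    if "@" in token and not re.search(r"@{1,2}(?=[H\d+\-\]])", token):
        raise UnsupportedFeatureError(
            f"extended chirality tag in {token!r} is not supported"
        )
    m = _BRACKET_RE.match(token)
    if m is None:
        raise SmilesSyntaxError(f"malformed bracket atom {token!r}")
    element = m.group("element")
    aromatic = element in _AROMATIC_ORGANIC
    if aromatic:
        element = element.upper()
    if element not in PERIODIC_TABLE:
        raise SmilesSyntaxError(f"unknown element in bracket atom {token!r}")
    charge = 0
    ctext = m.group("charge")
    if ctext:
        if ctext in ("+", "-") or set(ctext) in ({"+"}, {"-"}):
            charge = len(ctext) if ctext[0] == "+" else -len(ctext)
        else:
            charge = int(ctext)
    h_count = 0
    if m.group("h"):
        h_count = int(m.group("hcount")) if m.group("hcount") else 1
    atom = AtomType(
        element=element,
        isotope=int(m.group("isotope")) if m.group("isotope") else None,
        chirality=m.group("chirality"),
        h_count=h_count,
        charge=charge,
    )
    return atom, aromatic


class _OpenRing:
    __slots__ = ("atom", "bond_char", "token_idx", "paren_depth", "fragment")

    def __init__(self, atom, bond_char, token_idx, fragment):
        self.atom = atom
        self.bond_char = bond_char
        self.token_idx = token_idx
        self.fragment = fragment


def parse_smiles(s: str) -> MolecularGraph:
    """Parse a SMILES string into a molecular graph.

    Aromatic atoms/bonds are flagged but not kekulized (see :func:`kekulize`);
    no valence validation is performed here.
    """
    tokens = _tokenize_smiles(s)
    graph = MolecularGraph()
    graph.smiles_tokens = tokens  # kept for attribution reporting

    stack: list[int] = []
    prev: Optional[int] = None
    pending_bond: Optional[tuple[str, int]] = None  # (bond char, token idx)
    pending_paren: Optional[int] = None  # token idx of the '(' just opened
    open_rings: dict[int, _OpenRing] = {}
    fragment = 0
    aromatic_bonds: list[DirectedBond] = []

    def take_bond() -> tuple[str, int, Optional[int]]:
        nonlocal pending_bond, pending_paren
        char, cidx = ("", -1)
        if pending_bond is not None:
            char, cidx = pending_bond
            pending_bond = None
        paren = pending_paren
        pending_paren = None
        return char, cidx, paren

    def add_parsed_atom(atom_type: AtomType, aromatic: bool, idx: int) -> None:
        nonlocal prev
        char, cidx, paren = take_bond()
        sources = [(tokens[idx], idx)]
        new = graph.add_atom(
            atom_type, root=prev is None, aromatic=aromatic, sources=sources
        )
        if prev is not None:
            order = _TOKEN_ORDER.get(char, 1)
            stereo = char if char in ("/", "\\") else ""
            bond_sources = list(sources)
            if cidx >= 0:
                bond_sources.append((tokens[cidx], cidx))
            bond = graph.add_bond(prev, new, order, stereo=stereo, sources=bond_sources)
            if char == "" and aromatic and graph.atoms[prev].aromatic:
                aromatic_bonds.append(bond)
            if paren is not None:
                bond.branch_sources = [(tokens[paren], paren)]
        prev = new

    def close_ring(number: int, idx: int) -> None:
        char, cidx, _ = take_bond()
        if prev is None:
            raise SmilesSyntaxError(f"ring tag before any atom at token {idx} in {s!r}")
        if number not in open_rings:
            open_rings[number] = _OpenRing(prev, char, idx, fragment)
            return
        entry = open_rings.pop(number)
        if entry.fragment != fragment:
            raise UnsupportedFeatureError(
                f"ring closure {number} spans a dot-separated fragment in {s!r}"
            )
        left, right = entry.atom, prev
        if left == right:
            raise SmilesSyntaxError(f"ring closure {number} forms a self-loop in {s!r}")
        c1, c2 = entry.bond_char, char
        stereo_markers = {m for m in (c1, c2) if m in ("/", "\\")}
        if stereo_markers:
            if (c1 and c1 not in ("/", "\\")) or (c2 and c2 not in ("/", "\\")):
                raise SmilesSyntaxError(
                    f"conflicting bond tokens {c1!r}/{c2!r} on ring closure {number}"
                )
            order, stereo_pair = 1, (c1 or "-", c2 or "-")
        else:
            o1 = _TOKEN_ORDER.get(c1) if c1 else None
            o2 = _TOKEN_ORDER.get(c2) if c2 else None
            if o1 is not None and o2 is not None and o1 != o2:
                raise SmilesSyntaxError(
                    f"conflicting bond orders on ring closure {number} in {s!r}"
                )
            order, stereo_pair = (o1 or o2 or 1), None
        sources: list[Source] = [(tokens[entry.token_idx], entry.token_idx), (tokens[idx], idx)]
        if cidx >= 0:
            sources.append((tokens[cidx], cidx))
        existing = graph.find_bond(left, right)
        if existing is not None:
            graph.promote_bond(existing, min(3, existing.order + order))
            return
        bond = graph.add_bond(
            left, right, order, ring_bond=True, stereo_pair=stereo_pair, sources=sources
        )
        if (
            not c1
            and not c2
            and graph.atoms[left].aromatic
            and graph.atoms[right].aromatic
        ):
            aromatic_bonds.append(bond)

    for idx, tok in enumerate(tokens):
        if tok == "(":
            if prev is None:
                raise SmilesSyntaxError(f"branch before any atom in {s!r}")
            if pending_bond is not None:
                raise SmilesSyntaxError(f"bond token before '(' in {s!r}")
            stack.append(prev)
            pending_paren = idx
        elif tok == ")":
            if not stack:
                raise SmilesSyntaxError(f"unmatched ')' in {s!r}")
            if pending_bond is not None or pending_paren is not None:
                raise SmilesSyntaxError(f"dangling token before ')' in {s!r}")
            prev = stack.pop()
        elif tok in "-=#/\\":
            if pending_bond is not None:
                raise SmilesSyntaxError(f"two consecutive bond tokens in {s!r}")
            pending_bond = (tok, idx)
        elif tok == ".":
            if stack or pending_bond is not None or pending_paren is not None:
                raise SmilesSyntaxError(f"misplaced '.' in {s!r}")
            prev = None
            fragment += 1
        elif tok.isdigit():
            close_ring(int(tok), idx)
        elif tok.startswith("%"):
            close_ring(int(tok[1:]), idx)
        elif tok.startswith("["):
            atom, aromatic = _parse_bracket_atom(tok)
            add_parsed_atom(atom, aromatic, idx)
        elif tok in _AROMATIC_ORGANIC:
            add_parsed_atom(AtomType(element=tok.upper()), True, idx)
        else:  # organic-subset atom
            add_parsed_atom(AtomType(element=tok), False, idx)

    if stack:
        raise SmilesSyntaxError(f"unclosed branch bracket in {s!r}")
    if open_rings:
        raise SmilesSyntaxError(
            f"unclosed ring number(s) {sorted(open_rings)} in {s!r}"
        )
    if pending_bond is not None:
        raise SmilesSyntaxError(f"dangling bond token at end of {s!r}")
    if not graph.atoms and s.strip("."):
        raise SmilesSyntaxError(f"no atoms in {s!r}")
    graph.aromatic_bonds = aromatic_bonds
    return graph


def kekulize(graph: MolecularGraph) -> MolecularGraph:
    """Assign alternating single/double orders to aromatic bonds, in place.

    Every aromatic atom whose valence model leaves room beyond its sigma
    bonds and hydrogens must gain exactly one double bond; a maximum
    matching over the aromatic bonds realises this or fails with
    :class:`KekulizationError`.  Non-aromatic portions are untouched.
    Idempotent on already-Kekule graphs.
    """
    aromatic_atoms = [a for a in graph.atoms if a.aromatic]
    if not aromatic_atoms:
        return graph
    aromatic_bonds = getattr(graph, "aromatic_bonds", [])

    needs_double = set()
    for a in aromatic_atoms:
        t = a.atom_type
        base = _AROMATIC_VALENCE.get(t.element)
        if base is None:
            raise KekulizationError(
                f"no aromatic valence model for element {t.element!r} (atom {a.index})"
            )
        val = base + t.charge
        leftover = val - graph.bond_order_sum(a.index) - (t.h_count or 0)
        if leftover >= 1:
            needs_double.add(a.index)

    g = nx.Graph()
    g.add_nodes_from(needs_double)
    for bond in aromatic_bonds:
        if bond.src in needs_double and bond.dst in needs_double:
            g.add_edge(bond.src, bond.dst, bond=bond)
    matching = nx.max_weight_matching(g, maxcardinality=True)
    matched_atoms = {a for edge in matching for a in edge}
    if matched_atoms != needs_double:
        missing = sorted(needs_double - matched_atoms)
        raise KekulizationError(
            f"no consistent Kekule assignment: atom(s) {missing} cannot be "
            "given a double bond"
        )
    matched_pairs = {frozenset(edge) for edge in matching}
    for bond in aromatic_bonds:
        if frozenset((bond.src, bond.dst)) in matched_pairs:
            graph.promote_bond(bond, 2)
    for a in aromatic_atoms:
        a.aromatic = False
    graph.aromatic_bonds = []
    return graph


# ---------------------------------------------------------------------------
# Writer
# ---------------------------------------------------------------------------


def _atom_text(atom) -> str:
    t = atom.atom_type
    if atom.aromatic:
        raise ValueError(
            "cannot write aromatic atoms; kekulize the graph first"
        )
    if t.is_bare_organic:
        return t.element
    parts = ["["]
    if t.isotope is not None:
        parts.append(str(t.isotope))
    parts.append(t.element)
    if t.chirality:
        parts.append(t.chirality)
    if t.h_count:
        parts.append(f"H{t.h_count}")
    if t.charge:
        parts.append(f"{t.charge:+d}")
    parts.append("]")
    return "".join(parts)


def _ring_tag(number: int) -> str:
    if number < 10:
        return str(number)
    if number < 100:
        return f"%{number:02d}"
    raise ValueError("more than 99 simultaneously open ring tags")


def write_smiles_attributed(graph: MolecularGraph) -> list[tuple[str, list[Source]]]:
    """Emit the graph as a list of (SMILES token, input sources) pairs."""
    out: list[tuple[str, list[Source]]] = []
    ring_numbers: dict[int, int] = {}  # id(bond) -> allocated tag number
    open_numbers: set[int] = set()

    def alloc() -> int:
        n = 1
        while n in open_numbers:
            n += 1
        if n > 99:
            raise ValueError("more than 99 simultaneously open ring tags")
        open_numbers.add(n)
        return n

    def ring_tag_text(bond: DirectedBond, at_src: bool, number: int) -> str:
        marker = ""
        if bond.stereo_pair is not None:
            m = bond.stereo_pair[0 if at_src else 1]
            marker = m if m in ("/", "\\") else ""
        elif bond.order > 1:
            marker = _ORDER_TOKEN[bond.order]
        return marker + _ring_tag(number)

    def visit(atom_idx: int, incoming: Optional[DirectedBond]) -> None:
        # the chain continuation (last child) is iterated, not recursed, so
        # arbitrarily long chains stay within the recursion limit; recursion
        # depth is bounded by the branch nesting depth only
        while True:
            if incoming is not None:
                token = incoming.stereo or _ORDER_TOKEN[incoming.order]
                if token:
                    out.append((token, incoming.sources))
            a = graph.atoms[atom_idx]
            out.append((_atom_text(a), a.sources))
            for bond in graph.ring_bonds(atom_idx):
                if bond.src == atom_idx:
                    number = ring_numbers[id(bond)] = alloc()
                    out.append((ring_tag_text(bond, True, number), bond.sources))
                else:
                    number = ring_numbers.pop(id(bond))
                    open_numbers.discard(number)
                    out.append((ring_tag_text(bond, False, number), bond.sources))
            children = graph.out_bonds(atom_idx)
            for bond in children[:-1]:
                par_src = bond.branch_sources or bond.sources
                out.append(("(", par_src))
                visit(bond.dst, bond)
                out.append((")", par_src))
            if not children:
                return
            incoming = children[-1]
            atom_idx = incoming.dst

    first = True
    for root in graph.roots:
        mark = len(out)
        visit(root, None)
        if len(out) == mark:
            continue
        if not first:
            out.insert(mark, (".", out[mark][1]))
        first = False
    return out


def write_smiles(graph: MolecularGraph) -> str:
    """Write a molecular graph as a SMILES string in stored traversal order."""
    return "".join(text for text, _ in write_smiles_attributed(graph))
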