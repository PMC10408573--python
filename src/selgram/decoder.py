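"""Grammar-driven derivation of a molecular graph from any SELFIES string.

The derivation treats the symbol sequence as a queue of instructions.  A
nonterminal state X_i records how much bond order the current attachment atom
(the head) can still accept; X_0 terminates the fragment and discards the
remaining symbols.  The rules, with d(beta) the order of a bond prefix and
nu the capacity of an atom type:

* atom [beta a] at the start S: place the atom, go to state X_nu(a).
* atom [beta a] at X_i (i >= 1): bond the new atom to the head with order
  d0 = min(nu(a), i, d(beta)) (the bond prefix is demoted as needed), then go
  to X_{nu(a) - d0} with the new atom as head.
* branch [beta Branch l] at S or X_1: skipped (only the branch symbol itself
  is consumed).  At X_i (i >= 2): reserve d0 = min(i - 1, d(beta)); read l
  index symbols giving N, take the next N symbols as the branch payload and
  derive it recursively from state X_{d0} rooted at the head; resume at
  X_{i - d0}.
* ring [beta Ring l] at S: skipped.  At X_i (i >= 1): read l index symbols
  giving N and enqueue a ring-closure candidate (head, N, beta); resume at
  X_{i - min(i, d(beta))}.

Ring closures are deferred: after the fragment's symbols are exhausted the
candidates are finalised first-to-last against the *actual* remaining
capacities, rejecting self-loops and saturated endpoints and promoting
duplicate closures to higher bond orders (capped at triple).  This final
check, not the derivation-time reservation, is what guarantees validity.

Because every rule either consumes symbols without effect or adds bonds that
provably fit the remaining capacities, every well-formed symbol sequence
decodes to a valence-satisfying molecule - the robustness property.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Deque, Optional

from .constraints import ConstraintsLike, _coerce, bond_capacity
from .exceptions import DecodeError, InvalidSymbolError, MalformedStringError
from .molgraph import MolecularGraph, Source
from .selfies_syntax import (
    BOND_ORDER,
    SelfiesSymbol,
    decode_index,
    parse_symbol,
    tokenize_selfies,
)

__all__ = ["decode", "decode_to_graph", "demote_bond", "finalize_rings"]

_ORDER_TOKEN = {1: "", 2: "=", 3: "#"}


def demote_bond(bond: str, order: int) -> str:
    """Demote a bond prefix to a SMILES token of order ``order`` <= d(beta).

    Stereo prefixes '/' and '\\' are already of order 1 and pass through
    unchanged; '=', '#' and the empty prefix map to the plain SMILES token of
    the demoted order ('' for 1).
    """
    d = BOND_ORDER[bond]
    if not 1 <= order <= d:
        raise AssertionError(f"cannot demote {bond!r} (order {d}) to order {order}")
    if bond in ("/", "\\"):
        return bond
    return _ORDER_TOKEN[order]


@dataclass
class _RingCandidate:
    right: int  # ring-initiating (right) atom index
    offset: int  # N: how many atoms back the left atom lies
    order: int  # d(beta) of the ring symbol
    stereo: Optional[tuple[str, str]]  # (b1, b2) markers, stereo form only
    fragment_first: int
    sources: list[Source] = field(default_factory=list)


_QItem = tuple[str, SelfiesSymbol, int]  # (token text, parsed symbol, input index)


def _parse_queue(selfies: str) -> tuple[list[list[_QItem]], list[Source], int]:
    """Tokenize, parse, strip [nop], and split on dots.

    Returns (fragments, dot sources, token count).  Lexical failures raise
    MalformedStringError / InvalidSymbolError via the syntax layer.
    """
    tokens = tokenize_selfies(selfies)
    fragments: list[list[_QItem]] = [[]]
    dots: list[Source] = []
    for idx, text in enumerate(tokens):
        symbol = parse_symbol(text)
        if symbol.variant == "dot":
            dots.append((text, idx))
            fragments.append([])
        elif symbol.variant == "nop":
            continue
        else:
            fragments[-1].append((text, symbol, idx))
    return fragments, dots, len(tokens)


def decode_to_graph(
    selfies: str, constraints: ConstraintsLike = None
) -> tuple[MolecularGraph, list[Source]]:
    """Decode a SELFIES string into a molecular graph.

    Returns the graph and the list of unconsumed input tokens (symbols
    discarded at X_0, skipped branch/ring symbols, rejected ring closures).
    Raises :class:`DecodeError` only for lexical failures; every well-formed
    symbol sequence succeeds.
    """
    cs = _coerce(constraints)
    try:
        fragments, _, _ = _parse_queue(selfies)
    except (MalformedStringError, InvalidSymbolError) as exc:
        raise DecodeError(str(exc)) from exc

    graph = MolecularGraph()
    unconsumed: list[Source] = []
    for fragment in fragments:
        queue: Deque[_QItem] = deque(fragment)
        rings: list[_RingCandidate] = []
        first_atom = len(graph)
        try:
            _derive(queue, graph, cs, rings, unconsumed, head=None, budget=0)
        except InvalidSymbolError as exc:  # H count exceeding the valence
            raise DecodeError(str(exc)) from exc
        unconsumed.extend((text, idx) for text, _, idx in queue)
        finalize_rings(graph, rings, cs, unconsumed)
    return graph, unconsumed


def decode(selfies: str, constraints: ConstraintsLike = None) -> str:
    """Translate a SELFIES string into a (Kekule-form) SMILES string."""
    from .smiles_io import write_smiles

    graph, _ = decode_to_graph(selfies, constraints)
    return write_smiles(graph)


def _pop_index(queue: Deque[_QItem], size: int) -> tuple[int, list[Source]]:
    taken = [queue.popleft() for _ in range(min(size, len(queue)))]
    n = decode_index([text for text, _, _ in taken], size)
    return n, [(text, idx) for text, _, idx in taken]


def _derive(
    queue: Deque[_QItem],
    graph: MolecularGraph,
    cs,
    rings: list[_RingCandidate],
    unconsumed: list[Source],
    head: Optional[int],
    budget: int,
    branch_sources: Optional[list[Source]] = None,
) -> None:
    """Derive one fragment (head=None: start state S) or one branch payload
    (head given: start state X_budget rooted at the head atom).

    ``branch_sources`` are attached to the first bond the payload creates so
    the SMILES writer can attribute the branch parentheses.
    """
    at_start = head is None
    fragment_first = len(graph) if at_start else graph.fragment_of(head)
    pending_branch = list(branch_sources) if branch_sources else None

    while queue:
        if not at_start and budget == 0:  # X_0 = epsilon: fragment finished
            return
        text, symbol, idx = queue.popleft()

        if symbol.variant == "atom":
            cap = bond_capacity(cs, symbol.atom_type)
            src = [(text, idx)]
            if at_start:
                graph.add_atom(symbol.atom_type, root=True, sources=src)
                head = len(graph) - 1
                budget = cap
                at_start = False
            else:
                d0 = min(cap, budget, BOND_ORDER[symbol.bond])
                stereo = symbol.bond if symbol.bond in ("/", "\\") else ""
                new = graph.add_atom(symbol.atom_type, sources=src)
                bond = graph.add_bond(head, new, d0, stereo=stereo, sources=src)
                if pending_branch is not None:
                    bond.branch_sources = pending_branch
                    pending_branch = None
                head, budget = new, cap - d0

        elif symbol.variant == "branch":
            if at_start or budget <= 1:
                unconsumed.append((text, idx))
                continue
            d0 = min(budget - 1, BOND_ORDER[symbol.bond])
            n, idx_sources = _pop_index(queue, symbol.size)
            payload: Deque[_QItem] = deque(
                queue.popleft() for _ in range(min(n, len(queue)))
            )
            _derive(
                payload,
                graph,
                cs,
                rings,
                unconsumed,
                head=head,
                budget=d0,
                branch_sources=[(text, idx)] + idx_sources,
            )
            unconsumed.extend((t, i) for t, _, i in payload)
            budget -= d0

        else:  # ring or stereo_ring
            if at_start:
                unconsumed.append((text, idx))
                continue
            n, idx_sources = _pop_index(queue, symbol.size)
            order = 1 if symbol.variant == "stereo_ring" else BOND_ORDER[symbol.bond]
            rings.append(
                _RingCandidate(
                    right=head,
                    offset=n,
                    order=order,
                    stereo=symbol.stereo,
                    fragment_first=fragment_first,
                    sources=[(text, idx)] + idx_sources,
                )
            )
            budget -= min(budget, order)


def finalize_rings(
    graph: MolecularGraph,
    candidates: list[_RingCandidate],
    constraints: ConstraintsLike = None,
    unconsumed: Optional[list[Source]] = None,
) -> MolecularGraph:
    """Execute or reject deferred ring closures, strictly first-to-last.

    For each candidate the left atom is the N-th previously derived atom
    (clamped to the fragment's first atom).  Remaining capacities m1, m2 are
    recomputed from the actual bonds, including closures made by earlier
    candidates.  A candidate is silently rejected when either capacity is
    exhausted or the two atoms coincide; otherwise a new ring bond of order
    min(d(beta), m1, m2) is added, or an existing bond between the pair is
    promoted to order min(3, existing + new).
    """
    cs = _coerce(constraints)
    for cand in candidates:
        left = max(cand.fragment_first, cand.right - cand.offset)
        right = cand.right
        if left == right:
            if unconsumed is not None:
                unconsumed.extend(cand.sources)
            continue
        m1 = bond_capacity(cs, graph.atoms[left].atom_type) - graph.bond_order_sum(left)
        m2 = bond_capacity(cs, graph.atoms[right].atom_type) - graph.bond_order_sum(right)
        if m1 <= 0 or m2 <= 0:
            if unconsumed is not None:
                unconsumed.extend(cand.sources)
            continue
        d0 = min(cand.order, m1, m2)
        existing = graph.find_bond(left, right)
        if existing is None:
            graph.add_bond(
                left,
                right,
                d0,
                ring_bond=True,
                stereo_pair=cand.stereo,
                sources=cand.sources,
            )
        else:
            graph.promote_bond(existing, min(3, existing.order + d0))
    return graph
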