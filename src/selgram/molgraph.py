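"""Directed molecular graph shared by the encoder and decoder.

Atoms are stored in derivation/traversal order (dense 0-based indices); bonds
are directed parent -> child for tree bonds and left -> right for ring-closure
bonds, mirroring the order in which a SMILES writer must emit them.  The graph
also records the fragment structure induced by dot separators (one root atom
per fragment).

:func:`check_valences` is an independent validity oracle: it recomputes every
atom's total incident bond order from the stored bonds and compares it against
the constraint table, without consulting any decoder bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

from .constraints import ConstraintsLike, bond_capacity
from .selfies_syntax import AtomType

__all__ = [
    "Atom",
    "DirectedBond",
    "MolecularGraph",
    "Violation",
    "check_valences",
]

Source = tuple[str, int]  # (input token text, input token index)


@dataclass
class Atom:
    index: int
    atom_type: AtomType
    aromatic: bool = False
    sources: list[Source] = field(default_factory=list)


@dataclass
class DirectedBond:
    src: int
    dst: int
    order: int
    stereo: str = ""  # '/' or '\\' on a chain bond (order 1 only)
    ring_bond: bool = False
    # (left marker, right marker) decorating the two ring-closure tags;
    # each is '', '-', '/' or '\\'.
    stereo_pair: Optional[tuple[str, str]] = None
    sources: list[Source] = field(default_factory=list)
    branch_sources: list[Source] = field(default_factory=list)

    def pair(self) -> tuple[int, int]:
        return (self.src, self.dst) if self.src <= self.dst else (self.dst, self.src)


class Violation(NamedTuple):
    atom_index: int
    capacity: int
    total_order: int


class MolecularGraph:
    """Ordered atoms plus directed bonds, partitioned into dot-fragments."""

    def __init__(self) -> None:
        self.atoms: list[Atom] = []
        self.bonds: list[DirectedBond] = []
        self.roots: list[int] = []  # first atom of each fragment, in order
        self._out: list[list[DirectedBond]] = []  # tree bonds, per source atom
        self._in: list[Optional[DirectedBond]] = []  # tree bond into each atom
        self._rings: list[list[DirectedBond]] = []  # ring bonds, per endpoint
        self._order_sum: list[int] = []

    def __len__(self) -> int:
        return len(self.atoms)

    # -- construction --------------------------------------------------------

    def add_atom(
        self,
        atom_type: AtomType,
        root: bool = False,
        aromatic: bool = False,
        sources: Optional[list[Source]] = None,
    ) -> int:
        idx = len(self.atoms)
        self.atoms.append(Atom(idx, atom_type, aromatic, list(sources or [])))
        self._out.append([])
        self._in.append(None)
        self._rings.append([])
        self._order_sum.append(0)
        if root:
            self.roots.append(idx)
        return idx

    def add_bond(
        self,
        src: int,
        dst: int,
        order: int,
        stereo: str = "",
        ring_bond: bool = False,
        stereo_pair: Optional[tuple[str, str]] = None,
        sources: Optional[list[Source]] = None,
    ) -> DirectedBond:
        if src == dst:
            raise ValueError("self-loops are not representable")
        bond = DirectedBond(
            src, dst, order, stereo, ring_bond, stereo_pair, list(sources or [])
        )
        self.bonds.append(bond)
        if ring_bond:
            self._rings[src].append(bond)
            self._rings[dst].append(bond)
        else:
            self._out[src].append(bond)
            self._in[dst] = bond
        self._order_sum[src] += order
        self._order_sum[dst] += order
        return bond

    def add_bonded_atom(
        self,
        head: Optional[int],
        atom_type: AtomType,
        order: int = 1,
        stereo: str = "",
        constraints: ConstraintsLike = None,
        sources: Optional[list[Source]] = None,
    ) -> int:
        """Append an atom, bonded to ``head`` when given.

        Guards the invariant the decoder maintains: the new bond must fit in
        the remaining capacity of both endpoints.  A violation here is an
        internal error, not a user error.
        """
        cap_new = bond_capacity(constraints, atom_type)
        if head is None:
            return self.add_atom(atom_type, root=True, sources=sources)
        head_cap = bond_capacity(constraints, self.atoms[head].atom_type)
        if order > head_cap - self._order_sum[head] or order > cap_new:
            raise AssertionError(
                f"bond of order {order} from atom {head} to new {atom_type!r} "
                "exceeds a bond capacity (derivation invariant broken)"
            )
        idx = self.add_atom(atom_type, sources=sources)
        self.add_bond(head, idx, order, stereo=stereo)
        return idx

    def promote_bond(self, bond: DirectedBond, new_order: int) -> None:
        delta = new_order - bond.order
        bond.order = new_order
        if new_order > 1:  # stereo markers only decorate single bonds
            bond.stereo = ""
            bond.stereo_pair = None
        self._order_sum[bond.src] += delta
        self._order_sum[bond.dst] += delta

    # -- queries -------------------------------------------------------------

    def out_bonds(self, atom: int) -> list[DirectedBond]:
        return self._out[atom]

    def in_bond(self, atom: int) -> Optional[DirectedBond]:
        return self._in[atom]

    def ring_bonds(self, atom: int) -> list[DirectedBond]:
        return self._rings[atom]

    def bond_order_sum(self, atom: int) -> int:
        return self._order_sum[atom]

    def find_bond(self, a: int, b: int) -> Optional[DirectedBond]:
        key = (a, b) if a <= b else (b, a)
        incident = self._out[a] + self._rings[a]
        if self._in[a] is not None:
            incident.append(self._in[a])
        for bond in incident:
            if bond.pair() == key:
                return bond
        return None

    def fragment_of(self, atom: int) -> int:
        """Index of the first atom of the fragment containing ``atom``."""
        first = 0
        for r in self.roots:
            if r <= atom:
                first = r
            else:
                break
        return first

    # -- equality & debugging ------------------------------------------------

    def _bond_key(self, bond: DirectedBond):
        a, b = bond.pair()
        stereo = bond.stereo
        if stereo and bond.src > bond.dst:
            stereo = "/" if stereo == "\\" else "\\"
        pair = bond.stereo_pair
        if pair is not None:
            pair = tuple(m if m in ("/", "\\") else "" for m in pair)
            if bond.src > bond.dst:
                pair = (pair[1], pair[0])
        return (a, b, bond.order, stereo, pair)

    def graph_equal(self, other: "MolecularGraph") -> bool:
        """Same atom sequence and same bond multiset up to bond direction."""
        if len(self.atoms) != len(other.atoms):
            return False
        for a, b in zip(self.atoms, other.atoms):
            if a.atom_type.key() != b.atom_type.key():
                return False
        mine = sorted(self._bond_key(b) for b in self.bonds)
        theirs = sorted(other._bond_key(b) for b in other.bonds)
        return mine == theirs

    def dump(self) -> str:
        """Edge-list debug dump (atom lines then bond lines)."""
        lines = []
        for a in self.atoms:
            t = a.atom_type
            lines.append(
                f"atom {a.index} {t.element} {t.charge:+d} "
                f"{t.h_count if t.h_count is not None else '-'}"
            )
        for b in self.bonds:
            lines.append(
                f"bond {b.src} {b.dst} {b.order} {b.stereo or '-'} "
                f"{'ring' if b.ring_bond else 'tree'}"
            )
        return "\n".join(lines) + ("\n" if lines else "")


def check_valences(
    graph: MolecularGraph, constraints: ConstraintsLike = None
) -> list[Violation]:
    """Independent valence oracle.

    Recomputes each atom's total incident bond order directly from the bond
    list and reports every atom whose total exceeds its bond capacity.  Kept
    deliberately free of decoder bookkeeping so it can serve as a test oracle
    for the robustness guarantee.
    """
    totals = [0] * len(graph.atoms)
    for bond in graph.bonds:
        totals[bond.src] += bond.order
        totals[bond.dst] += bond.order
    violations = []
    for atom, total in zip(graph.atoms, totals):
        cap = bond_capacity(constraints, atom.atom_type)
        if total > cap:
            violations.append(Violation(atom.index, cap, total))
    return violations
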