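"""Valence constraints: the maximum number of bonds each atom type may form.

A :class:`ConstraintSet` realises the constraint function nu mapping an
(element, formal charge) pair to a maximum total bond order, with a catch-all
value for unlisted atom types so lookups are total.  The derivation engine
consults these values to guarantee that every decoded molecule satisfies them.

The default table targets organic molecules with single, double and triple
bonds: C 4/5/3 (neutral/+1/-1), N 3/4/2, O 2/3/1, B 3/2/4, P 5/6/4, S 6/7/5,
the monovalent H/F/Cl/Br/I at 1, and a catch-all of 8.  Two presets modify it:
``octet_rule`` forbids hypervalent P and S, while ``hypervalent`` additionally
admits 7-bond halogens and 5-bond nitrogen.

A process-wide active set (used by default throughout the package) is managed
with :func:`configure_constraints` / :func:`get_constraints`; the replacement
is total, never a merge.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Union

from .exceptions import ConfigurationError, InvalidSymbolError

if TYPE_CHECKING:  # pragma: no cover
    from .selfies_syntax import AtomType

__all__ = [
    "ConstraintSet",
    "preset_constraints",
    "default_constraints",
    "configure_constraints",
    "get_constraints",
    "bond_capacity",
]

#: All recognised element symbols (IUPAC periodic table, Z = 1..118).
PERIODIC_TABLE = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co Ni "
    "Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te I "
    "Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir Pt "
    "Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No Lr "
    "Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og".split()
)

_DEFAULT_ENTRIES: dict[tuple[str, int], int] = {
    ("H", 0): 1,
    ("F", 0): 1,
    ("Cl", 0): 1,
    ("Br", 0): 1,
    ("I", 0): 1,
    ("B", 0): 3,
    ("B", +1): 2,
    ("B", -1): 4,
    ("C", 0): 4,
    ("C", +1): 5,
    ("C", -1): 3,
    ("N", 0): 3,
    ("N", +1): 4,
    ("N", -1): 2,
    ("O", 0): 2,
    ("O", +1): 3,
    ("O", -1): 1,
    ("P", 0): 5,
    ("P", +1): 6,
    ("P", -1): 4,
    ("S", 0): 6,
    ("S", +1): 7,
    ("S", -1): 5,
}

_OCTET_OVERRIDES = {
    ("P", 0): 3,
    ("P", +1): 4,
    ("P", -1): 2,
    ("S", 0): 2,
    ("S", +1): 3,
    ("S", -1): 1,
}

_HYPERVALENT_OVERRIDES = {
    ("Cl", 0): 7,
    ("Br", 0): 7,
    ("I", 0): 7,
    ("N", 0): 5,
}

_DEFAULT_CATCH_ALL = 8


@dataclass
class ConstraintSet:
    """Mapping from (element symbol, formal charge) to maximum bond count.

    ``catch_all`` resolves every pair not listed in ``entries``, so
    :meth:`get` never fails.
    """

    entries: dict[tuple[str, int], int] = field(default_factory=dict)
    catch_all: int = _DEFAULT_CATCH_ALL

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not isinstance(self.catch_all, int) or isinstance(self.catch_all, bool):
            raise ConfigurationError("catch-all maximum bond count must be an integer")
        if self.catch_all < 0:
            raise ConfigurationError("catch-all maximum bond count must be >= 0")
        for key, value in self.entries.items():
            try:
                element, charge = key
            except (TypeError, ValueError):
                raise ConfigurationError(f"malformed constraint key: {key!r}") from None
            if element not in PERIODIC_TABLE:
                raise ConfigurationError(f"unknown element symbol: {element!r}")
            if not isinstance(charge, int) or isinstance(charge, bool):
                raise ConfigurationError(f"charge must be an integer: {charge!r}")
            if not isinstance(value, int) or isinstance(value, bool) or value < 0:
                raise ConfigurationError(
                    f"maximum bond count for {key!r} must be a non-negative "
                    f"integer, got {value!r}"
                )

    def get(self, element: str, charge: int = 0) -> int:
        """Return the maximum bond count for ``(element, charge)``.

        Unlisted pairs resolve to the catch-all value; this lookup is total.
        """
        return self.entries.get((element, charge), self.catch_all)

    def copy(self) -> "ConstraintSet":
        return ConstraintSet(entries=dict(self.entries), catch_all=self.catch_all)

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self.entries

    # -- flat text serialization: "element charge max_bonds" + "* * n" -------

    def to_text(self) -> str:
        lines = [
            f"{el} {chg:+d} {val}" if chg else f"{el} 0 {val}"
            for (el, chg), val in sorted(self.entries.items())
        ]
        lines.append(f"* * {self.catch_all}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ConstraintSet":
        entries: dict[tuple[str, int], int] = {}
        catch_all = None
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ConfigurationError(
                    f"line {lineno}: expected 'element charge max_bonds', got {line!r}"
                )
            el, chg, val = parts
            if not re.fullmatch(r"\d+", val):
                raise ConfigurationError(f"line {lineno}: bad max_bonds {val!r}")
            if el == "*" and chg == "*":
                catch_all = int(val)
                continue
            if not re.fullmatch(r"[+-]?\d+", chg):
                raise ConfigurationError(f"line {lineno}: bad charge {chg!r}")
            entries[(el, int(chg))] = int(val)
        if catch_all is None:
            raise ConfigurationError("constraint file is missing the '* * n' catch-all line")
        return cls(entries=entries, catch_all=catch_all)


def preset_constraints(name: str = "default") -> ConstraintSet:
    """Return a fresh copy of a named preset: ``default``, ``octet_rule``
    (non-hypervalent P and S) or ``hypervalent`` (7-bond halogens, 5-bond N).
    """
    entries = dict(_DEFAULT_ENTRIES)
    if name == "default":
        pass
    elif name == "octet_rule":
        entries.update(_OCTET_OVERRIDES)
    elif name == "hypervalent":
        entries.update(_HYPERVALENT_OVERRIDES)
    else:
        raise ConfigurationError(
            f"unknown preset {name!r}; expected 'default', 'octet_rule' or 'hypervalent'"
        )
    return ConstraintSet(entries=entries, catch_all=_DEFAULT_CATCH_ALL)


def default_constraints() -> ConstraintSet:
    return preset_constraints("default")


_active: ConstraintSet = default_constraints()

ConstraintsLike = Union[ConstraintSet, Mapping[tuple[str, int], int], None]


def _coerce(constraints: ConstraintsLike) -> ConstraintSet:
    """Resolve an optional constraints argument to a ConstraintSet (the active
    configuration when None; a mapping is interpreted with default catch-all)."""
    if constraints is None:
        return _active
    if isinstance(constraints, ConstraintSet):
        return constraints
    return ConstraintSet(entries=dict(constraints))


def configure_constraints(constraints: ConstraintSet) -> None:
    """Replace the active constraint set (no merging with previous values)."""
    global _active
    if not isinstance(constraints, ConstraintSet):
        raise ConfigurationError(
            "configure_constraints expects a ConstraintSet (use ConstraintSet(entries=..., catch_all=...))"
        )
    constraints.validate()
    _active = constraints.copy()


def get_constraints() -> ConstraintSet:
    """Return a copy of the active constraint set."""
    return _active.copy()


def bond_capacity(constraints: ConstraintsLike, atom_type: "AtomType") -> int:
    """Remaining bond capacity of an atom type: nu(element, charge) minus the
    explicit hydrogen count.  Isotope labels share the element's valence.
    """
    cs = _coerce(constraints)
    nu = cs.get(atom_type.element, atom_type.charge)
    h = atom_type.h_count or 0
    if h > nu:
        raise InvalidSymbolError(
            f"atom type {atom_type!r} specifies {h} hydrogens but at most "
            f"{nu} bonds are allowed for ({atom_type.element}, {atom_type.charge:+d})"
        )
    return nu - h
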