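"""Molecular graphs with explicit hydrogens and positional labels.

The graphs carry the atom numbering used in the NMR assignment of the
U-type opioids (C-1 carbonyl, C-2 benzylic methylene, C-3..C-8 aromatic
ring, C-1'..C-9' cyclohexane/amine region), so that bond-path queries can
be phrased directly against spectroscopic labels such as ``"H-8"`` or
``"C-2"``.  Hydrogens are explicit nodes: the path from a proton to a
carbon therefore includes the proton's own C-H bond, which is the counting
convention used when reasoning about HMBC reach ("separated by four
bonds").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Tuple

import networkx as nx

__all__ = [
    "AtomNode",
    "MolecularGraph",
    "ElementalFormula",
    "GraphError",
    "LabelError",
    "molecular_formula",
    "bond_path_length",
    "normalize_label",
]

#: heavy-atom valence ceilings (explicit-H counting, order-weighted)
MAX_VALENCE = {"C": 4, "N": 4, "O": 2, "Cl": 1, "H": 1}

#: default (neutral, lowest) valences used when filling implicit hydrogens
DEFAULT_VALENCE = {"C": 4, "N": 3, "O": 2, "Cl": 1, "H": 1}

BOND_ORDER_VALUE = {"single": 1.0, "double": 2.0, "triple": 3.0, "aromatic": 1.5}


class GraphError(ValueError):
    """Structural problem in a molecular graph (valence, connectivity...)."""


class LabelError(KeyError):
    """An atom label could not be resolved in a graph."""

    def __str__(self) -> str:  # KeyError quotes its args; keep the message plain
        return self.args[0] if self.args else ""


def normalize_label(label: str) -> str:
    """Canonicalise a positional label.

    The prime mark can be written as a unicode prime, an ASCII apostrophe
    or a trailing ``p`` (``"C-1′" == "C-1'" == "C-1p"``).
    """
    lab = label.strip().replace("′", "'")
    if len(lab) > 1 and lab.endswith("p") and lab[-2].isdigit():
        lab = lab[:-1] + "'"
    return lab


@dataclass(frozen=True)
class AtomNode:
    """One atom: element symbol, optional formal charge and positional label."""

    index: int
    element: str
    formal_charge: int = 0
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.index < 0:
            raise GraphError(f"atom index must be non-negative, got {self.index}")
        if self.element not in MAX_VALENCE:
            raise GraphError(
                f"unsupported element {self.element!r}; "
                f"supported: {sorted(MAX_VALENCE)}"
            )


@dataclass
class MolecularGraph:
    """Labelled molecular graph: atoms plus bonds with an order tag."""

    atoms: List[AtomNode] = field(default_factory=list)
    bonds: Dict[FrozenSet[int], str] = field(default_factory=dict)
    name: Optional[str] = None

    # -- construction -----------------------------------------------------
    def add_atom(
        self,
        element: str,
        label: Optional[str] = None,
        formal_charge: int = 0,
    ) -> int:
        idx = len(self.atoms)
        if label is not None:
            label = normalize_label(label)
        self.atoms.append(AtomNode(idx, element, formal_charge, label))
        return idx

    def add_bond(self, a: int, b: int, order: str = "single") -> None:
        if a == b:
            raise GraphError(f"self-bond on atom {a}")
        if order not in BOND_ORDER_VALUE:
            raise GraphError(f"unknown bond order {order!r}")
        for i in (a, b):
            if not 0 <= i < len(self.atoms):
                raise GraphError(f"bond references missing atom {i}")
        self.bonds[frozenset((a, b))] = order

    # -- views ------------------------------------------------------------
    def neighbours(self, idx: int) -> List[int]:
        out = []
        for pair in self.bonds:
            if idx in pair:
                (other,) = pair - {idx}
                out.append(other)
        return sorted(out)

    def degree(self, idx: int) -> int:
        return len(self.neighbours(idx))

    def weighted_valence(self, idx: int) -> float:
        return sum(
            BOND_ORDER_VALUE[order] for pair, order in self.bonds.items() if idx in pair
        )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(a.index for a in self.atoms)
        g.add_edges_from(tuple(pair) for pair in self.bonds)
        return g

    # -- label resolution -------------------------------------------------
    def _label_index(self) -> Dict[str, int]:
        return {a.label: a.index for a in self.atoms if a.label is not None}

    def find_atom(self, label: str) -> int:
        """Resolve a label to an atom index (exact match only)."""
        idx = self._label_index().get(normalize_label(label))
        if idx is None:
            raise LabelError(
                f"label {label!r} not found in graph"
                f"{' ' + self.name if self.name else ''}"
            )
        return idx

    def resolve(self, label: str) -> List[int]:
        """Resolve a label to candidate atom indices.

        Exact labels win.  A proton label ``"H-x"`` with no exact match
        falls back to (i) hydrogens labelled ``"H-xa"``, ``"H-xb"``, ... and
        (ii) the hydrogens bonded to carbon ``"C-x"`` — convenient for
        methyl/methylene groups whose protons are spectroscopically
        equivalent.
        """
        lab = normalize_label(label)
        table = self._label_index()
        if lab in table:
            return [table[lab]]
        if lab.startswith("H-"):
            multi = [
                i for l, i in table.items() if l.startswith(lab) and len(l) > len(lab)
            ]
            if multi:
                return sorted(multi)
            carbon = "C-" + lab[2:]
            if carbon in table:
                hs = [
                    n
                    for n in self.neighbours(table[carbon])
                    if self.atoms[n].element == "H"
                ]
                if hs:
                    return hs
        raise LabelError(
            f"label {label!r} not found in graph"
            f"{' ' + self.name if self.name else ''}"
        )

    # -- validation -------------------------------------------------------
    def validate(self, require_connected: bool = False) -> None:
        labels = [a.label for a in self.atoms if a.label is not None]
        if len(labels) != len(set(labels)):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise GraphError(f"duplicate labels: {dup}")
        for atom in self.atoms:
            val = self.weighted_valence(atom.index)
            # a positive formal charge buys one extra bond (ammonium-style)
            ceiling = MAX_VALENCE[atom.element] + max(atom.formal_charge, 0) * 0
            if atom.element == "N" and atom.formal_charge > 0:
                ceiling = 4
            if val > ceiling + 1e-9:
                raise GraphError(
                    f"valence {val:g} on atom {atom.index} ({atom.element}) "
                    f"exceeds {ceiling}"
                )
            if atom.element == "H" and self.degree(atom.index) != 1:
                raise GraphError(
                    f"hydrogen {atom.index} has {self.degree(atom.index)} bonds"
                )
        if require_connected and self.atoms:
            if not nx.is_connected(self.to_networkx()):
                raise GraphError("graph is not connected")


@dataclass(frozen=True)
class ElementalFormula:
    """Element counts plus a net charge; serialises in Hill order."""

    counts: Tuple[Tuple[str, int], ...]
    charge: int = 0

    @staticmethod
    def from_dict(counts: Dict[str, int], charge: int = 0) -> "ElementalFormula":
        cleaned = {el: n for el, n in counts.items() if n}
        if any(n < 0 for n in cleaned.values()):
            raise GraphError(f"negative element count in {counts}")
        return ElementalFormula(tuple(sorted(cleaned.items())), charge)

    def as_dict(self) -> Dict[str, int]:
        return dict(self.counts)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = self.as_dict()
        for el, n in other.counts:
            merged[el] = merged.get(el, 0) + n
        return ElementalFormula.from_dict(merged, self.charge + other.charge)

    def hill(self) -> str:
        counts = self.as_dict()
        parts: List[str] = []

        def emit(el: str) -> None:
            n = counts.pop(el, 0)
            if n:
                parts.append(el + (str(n) if n > 1 else ""))

        emit("C")
        emit("H")
        for el in sorted(counts):
            emit(el)
        body = "".join(parts)
        if self.charge:
            sign = "+" if self.charge > 0 else "-"
            mag = abs(self.charge)
            body += sign if mag == 1 else f"{mag}{sign}"
        return body

    def __str__(self) -> str:
        return self.hill()


def molecular_formula(graph: MolecularGraph) -> ElementalFormula:
    """Elemental formula of a graph: multiset of elements, summed charge."""
    counts: Dict[str, int] = {}
    charge = 0
    for atom in graph.atoms:
        counts[atom.element] = counts.get(atom.element, 0) + 1
        charge += atom.formal_charge
    return ElementalFormula.from_dict(counts, charge)


def bond_path_length(graph: MolecularGraph, a: str, b: str) -> int:
    """Number of bonds on the shortest path between two labelled atoms.

    Symmetric; 0 iff both labels resolve to the same atom.  Bond order is
    ignored: HMBC/COSY reach is counted in bonds regardless of order.
    Labels resolving to several equivalent atoms (methyl protons) use the
    minimum over candidates.
    """
    src = graph.resolve(a)
    dst = set(graph.resolve(b))
    g = graph.to_networkx()
    best = None
    for s in src:
        lengths = nx.single_source_shortest_path_length(g, s)
        for d in dst:
            if d in lengths and (best is None or lengths[d] < best):
                best = lengths[d]
    if best is None:
        raise GraphError(f"no path between {a!r} and {b!r}")
    return best
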