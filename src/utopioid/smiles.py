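"""Minimal SMILES reader/writer for C/H/N/O/Cl chemistry.

Covers exactly what candidate structures for this compound class need:
organic-subset atoms (C, N, O, Cl and their aromatic lowercase forms),
branches, numeric ring closures (including %nn), single/double/triple
bonds and bracket atoms with explicit hydrogen counts and charges.  No
stereochemistry, no wildcard atoms, no dot-disconnected fragments.
Implicit hydrogens are materialised as explicit graph nodes so that the
output plugs straight into bond-path queries.
"""

from __future__ import annotations

import re
from typing import Dict, List, Optional, Tuple

from .graph import BOND_ORDER_VALUE, DEFAULT_VALENCE, GraphError, MolecularGraph

__all__ = ["parse_smiles", "to_smiles", "SmilesError"]


class SmilesError(ValueError):
    """Tokenisation/syntax problem; carries the 0-based position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (position {position})")
        self.position = position


_ORGANIC = {"Cl": "Cl", "C": "C", "N": "N", "O": "O"}
_AROMATIC = {"c": "C", "n": "N", "o": "O"}
_BRACKET_RE = re.compile(
    r"\[(?P<element>Cl|C|N|O|H|c|n|o)(?P<hcount>H\d*)?(?P<charge>\+\d*|-\d*|\++|-+)?\]"
)
_BOND_ORDERS = {"-": "single", "=": "double", "#": "triple", ":": "aromatic"}


def parse_smiles(text: str) -> MolecularGraph:
    """Parse a minimal-dialect SMILES string into a molecular graph.

    Implicit hydrogens are added to reach the default valence (C 4, N 3,
    O 2, Cl 1), with aromatic atoms consuming one extra valence unit for
    the ring pi system.  Raises :class:`SmilesError` on unsupported
    tokens and :class:`~utopioid.graph.GraphError` on valence violations.
    """
    if not text or not text.strip():
        raise SmilesError("empty SMILES", 0)
    text = text.strip()

    g = MolecularGraph(name=None)
    aromatic_atoms: set[int] = set()
    explicit_h: Dict[int, int] = {}  # bracket atoms: pinned hydrogen count
    stack: List[int] = []
    prev: Optional[int] = None
    pending_bond: Optional[str] = None
    ring_open: Dict[str, Tuple[int, Optional[str], int]] = {}

    def attach(idx: int, pos: int) -> None:
        nonlocal prev, pending_bond
        if prev is not None:
            order = pending_bond
            if order is None:
                order = (
                    "aromatic"
                    if prev in aromatic_atoms and idx in aromatic_atoms
                    else "single"
                )
            g.add_bond(prev, idx, order)
        pending_bond = None
        prev = idx

    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "[":
            m = _BRACKET_RE.match(text, i)
            if not m:
                raise SmilesError(f"malformed bracket atom {text[i:i+6]!r}", i)
            sym = m.group("element")
            aromatic = sym in _AROMATIC
            element = _AROMATIC.get(sym, sym)
            hnum = 0
            if m.group("hcount"):
                hs = m.group("hcount")[1:]
                hnum = int(hs) if hs else 1
            charge = 0
            if m.group("charge"):
                cs = m.group("charge")
                if cs[1:].isdigit():
                    charge = int(cs[1:]) * (1 if cs[0] == "+" else -1)
                else:
                    charge = cs.count("+") - cs.count("-")
            idx = g.add_atom(element, formal_charge=charge)
            if aromatic:
                aromatic_atoms.add(idx)
            explicit_h[idx] = hnum
            attach(idx, i)
            i = m.end()
        elif text.startswith("Cl", i):
            idx = g.add_atom("Cl")
            attach(idx, i)
            i += 2
        elif ch in _ORGANIC:
            idx = g.add_atom(ch)
            attach(idx, i)
            i += 1
        elif ch in _AROMATIC:
            idx = g.add_atom(_AROMATIC[ch])
            aromatic_atoms.add(idx)
            attach(idx, i)
            i += 1
        elif ch in _BOND_ORDERS:
            pending_bond = _BOND_ORDERS[ch]
            i += 1
        elif ch == "(":
            if prev is None:
                raise SmilesError("branch before any atom", i)
            stack.append(prev)
            i += 1
        elif ch == ")":
            if not stack:
                raise SmilesError("unmatched ')'", i)
            prev = stack.pop()
            i += 1
        elif ch.isdigit() or ch == "%":
            if ch == "%":
                if i + 2 >= len(text) or not text[i + 1 : i + 3].isdigit():
                    raise SmilesError("malformed %nn ring closure", i)
                key, step = text[i + 1 : i + 3], 3
            else:
                key, step = ch, 1
            if prev is None:
                raise SmilesError("ring closure before any atom", i)
            if key in ring_open:
                other, bond0, _ = ring_open.pop(key)
                order = pending_bond or bond0
                if order is None:
                    order = (
                        "aromatic"
                        if prev in aromatic_atoms and other in aromatic_atoms
                        else "single"
                    )
                if other == prev:
                    raise SmilesError(f"ring closure {key} bonds atom to itself", i)
                g.add_bond(prev, other, order)
                pending_bond = None
            else:
                ring_open[key] = (prev, pending_bond, i)
                pending_bond = None
            i += step
        else:
            raise SmilesError(f"unsupported token {ch!r}", i)

    if stack:
        raise SmilesError("unclosed branch", len(text))
    if ring_open:
        key, (_, _, pos) = next(iter(ring_open.items()))
        raise SmilesError(f"unclosed ring bond {key}", pos)

    _add_implicit_hydrogens(g, aromatic_atoms, explicit_h)
    g.validate()
    return g


def _add_implicit_hydrogens(
    g: MolecularGraph, aromatic_atoms: set[int], explicit_h: Dict[int, int]
) -> None:
    for atom in list(g.atoms):
        if atom.element == "H":
            continue
        idx = atom.index
        if idx in explicit_h:
            n_h = explicit_h[idx]
        else:
            # aromatic bonds count 1 each; the delocalised pi system adds one
            used = sum(
                1.0 if order == "aromatic" else BOND_ORDER_VALUE[order]
                for pair, order in g.bonds.items()
                if idx in pair
            )
            if idx in aromatic_atoms:
                used += 1
            target = DEFAULT_VALENCE[atom.element] + atom.formal_charge
            n_h = int(round(target - used))
            if n_h < -1e-9:
                raise GraphError(
                    f"valence violation on atom {idx} ({atom.element}): "
                    f"{used:g} bonds exceed default valence {target}"
                )
            n_h = max(n_h, 0)
        for _ in range(n_h):
            h = g.add_atom("H")
            g.add_bond(idx, h)


def to_smiles(graph: MolecularGraph) -> str:
    """Serialise a graph to SMILES (non-canonical DFS order).

    Hydrogens become implicit except where the implied count would be
    wrong (charged atoms always get brackets).  Aromatic bonds map to
    lowercase atoms.
    """
    heavy = [a for a in graph.atoms if a.element != "H"]
    if not heavy:
        n_h = sum(1 for a in graph.atoms if a.element == "H")
        if n_h == 2:
            return "[H][H]"
        raise GraphError("cannot serialise a hydrogen-only graph")

    aromatic_atoms = {
        i
        for pair, order in graph.bonds.items()
        if order == "aromatic"
        for i in pair
    }
    h_count = {
        a.index: sum(
            1 for n in graph.neighbours(a.index) if graph.atoms[n].element == "H"
        )
        for a in heavy
    }

    # assign ring-closure digits on non-tree edges of a DFS forest
    visited: set[int] = set()
    tree_edges: set[frozenset] = set()
    order_visit: List[int] = []

    def dfs(u: int) -> None:
        visited.add(u)
        order_visit.append(u)
        for v in graph.neighbours(u):
            if graph.atoms[v].element == "H":
                continue
            if v not in visited:
                tree_edges.add(frozenset((u, v)))
                dfs(v)

    roots = [a.index for a in heavy if a.index not in visited]
    start = roots[0]
    dfs(start)
    if len(order_visit) != len(heavy):
        raise GraphError("disconnected heavy-atom graph cannot be serialised")

    closures: Dict[int, List[Tuple[int, str]]] = {a.index: [] for a in heavy}
    digit = 1
    for pair, order in graph.bonds.items():
        a, b = tuple(pair)
        if graph.atoms[a].element == "H" or graph.atoms[b].element == "H":
            continue
        if pair not in tree_edges:
            tag = str(digit) if digit < 10 else f"%{digit:02d}"
            closures[a].append((digit, order))
            closures[b].append((digit, order))
            digit += 1

    def atom_token(idx: int) -> str:
        atom = graph.atoms[idx]
        aromatic = idx in aromatic_atoms
        sym = atom.element.lower() if aromatic and atom.element != "Cl" else atom.element
        n_h = h_count[idx]
        needs_bracket = atom.formal_charge != 0
        if not needs_bracket:
            # bare atom only if the implicit-H rule regenerates n_h on re-parse
            heavy_val = sum(
                1.0 if o == "aromatic" else BOND_ORDER_VALUE[o]
                for pair, o in graph.bonds.items()
                if idx in pair and all(graph.atoms[j].element != "H" for j in pair)
            )
            implied = DEFAULT_VALENCE[atom.element] - heavy_val - (1 if aromatic else 0)
            needs_bracket = implied < -1e-9 or int(round(implied)) != n_h
        if not needs_bracket:
            return sym
        body = sym
        if n_h:
            body += "H" + (str(n_h) if n_h > 1 else "")
        ch = atom.formal_charge
        if ch:
            sign = "+" if ch > 0 else "-"
            body += sign if abs(ch) == 1 else f"{sign}{abs(ch)}"
        return f"[{body}]"

    bond_token = {"single": "", "double": "=", "triple": "#", "aromatic": ""}
    written: set[int] = set()

    def emit(u: int, via: Optional[str]) -> str:
        written.add(u)
        out = (bond_token[via] if via else "") + atom_token(u)
        for d, o in closures[u]:
            tag = str(d) if d < 10 else f"%{d:02d}"
            out += bond_token[o] + tag
        children = [
            v
            for v in graph.neighbours(u)
            if graph.atoms[v].element != "H"
            and frozenset((u, v)) in tree_edges
            and v not in written
        ]
        for k, v in enumerate(children):
            sub = emit(v, graph.bonds[frozenset((u, v))])
            if k < len(children) - 1:
                out += f"({sub})"
            else:
                out += sub
        return out

    return emit(start, None)
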