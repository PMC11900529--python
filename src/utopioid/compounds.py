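"""Built-in U-type opioid structures.

U-48800 and U-51754 are positional isomers (C17H24Cl2N2O, benzyl-type
U-opioids): a 1,2,4-trisubstituted benzene carries a benzylic methylene
(C-2) attached to an amide carbonyl (C-1); the amide nitrogen bears an
N-methyl (C-9') and the cyclohexane methine C-1'; the adjacent ring
methine C-6' carries a dimethylamino group (C-7'/C-8').  The two isomers
differ only in the aromatic chlorine placement: C-4 and C-6 in U-48800
versus C-5 and C-6 in U-51754.
"""

from __future__ import annotations

from .graph import MolecularGraph

__all__ = ["SUPPORTED_COMPOUNDS", "build_utopioid", "BUILTIN_SMILES"]

SUPPORTED_COMPOUNDS = ("U-48800", "U-51754")

#: chlorinated aromatic positions per compound
_CL_POSITIONS = {"U-48800": (4, 6), "U-51754": (5, 6)}

#: minimal SMILES for the same connectivities (aromatic ring written from C-3)
BUILTIN_SMILES = {
    "U-48800": "O=C(Cc1c(Cl)cc(Cl)cc1)N(C)C1CCCCC1N(C)C",
    "U-51754": "O=C(Cc1cc(Cl)c(Cl)cc1)N(C)C1CCCCC1N(C)C",
}


def build_utopioid(name: str) -> MolecularGraph:
    """Fully labelled graph (explicit hydrogens) for a built-in compound.

    Carbons follow the published numbering: 1 (carbonyl), 2 (benzylic
    CH2), 3-8 (aromatic ring, C-3 bearing the methylene), 1'-6'
    (cyclohexane), 7'/8' (N,N-dimethyl), 9' (amide N-methyl).  Aromatic
    protons are labelled after their carbon (H-5/H-7/H-8 in U-48800,
    H-4/H-7/H-8 in U-51754); methylene and methyl protons get a/b/c
    suffixes and resolve collectively through ``MolecularGraph.resolve``.
    """
    key = name.strip().upper().replace("U", "U-").replace("U--", "U-")
    if key not in _CL_POSITIONS:
        raise ValueError(
            f"unknown compound {name!r}; supported: {', '.join(SUPPORTED_COMPOUNDS)}"
        )
    cl_positions = _CL_POSITIONS[key]

    g = MolecularGraph(name=key)
    c1 = g.add_atom("C", "C-1")
    o1 = g.add_atom("O", "O-1")
    c2 = g.add_atom("C", "C-2")
    ring = {pos: g.add_atom("C", f"C-{pos}") for pos in range(3, 9)}
    n1 = g.add_atom("N", "N-1")  # amide nitrogen
    c9p = g.add_atom("C", "C-9'")
    cy = {pos: g.add_atom("C", f"C-{pos}'") for pos in range(1, 7)}
    n2 = g.add_atom("N", "N-2")  # dimethylamino nitrogen
    c7p = g.add_atom("C", "C-7'")
    c8p = g.add_atom("C", "C-8'")

    g.add_bond(c1, o1, "double")
    g.add_bond(c1, c2)
    g.add_bond(c2, ring[3])
    for pos in range(3, 9):
        nxt = ring[3] if pos == 8 else ring[pos + 1]
        g.add_bond(ring[pos], nxt, "aromatic")
    g.add_bond(c1, n1)
    g.add_bond(n1, c9p)
    g.add_bond(n1, cy[1])
    for pos in range(1, 7):
        nxt = cy[1] if pos == 6 else cy[pos + 1]
        g.add_bond(cy[pos], nxt)
    g.add_bond(cy[6], n2)
    g.add_bond(n2, c7p)
    g.add_bond(n2, c8p)

    for pos in cl_positions:
        cl = g.add_atom("Cl", f"Cl-{pos}")
        g.add_bond(ring[pos], cl)

    def add_hydrogens(carbon: int, labels: list[str]) -> None:
        for lab in labels:
            h = g.add_atom("H", lab)
            g.add_bond(carbon, h)

    add_hydrogens(c2, ["H-2a", "H-2b"])
    for pos in range(4, 9):
        if pos not in cl_positions:
            add_hydrogens(ring[pos], [f"H-{pos}"])
    add_hydrogens(c9p, ["H-9'a", "H-9'b", "H-9'c"])
    add_hydrogens(cy[1], ["H-1'"])
    for pos in range(2, 6):
        add_hydrogens(cy[pos], [f"H-{pos}'a", f"H-{pos}'b"])
    add_hydrogens(cy[6], ["H-6'"])
    add_hydrogens(c7p, ["H-7'a", "H-7'b", "H-7'c"])
    add_hydrogens(c8p, ["H-8'a", "H-8'b", "H-8'c"])

    g.validate(require_connected=True)
    return g
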