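"""Bond-path compatibility scoring of 2-D NMR correlations.

An HMBC cross-peak links a proton to a carbon 2-3 bonds away; 4-bond
correlations are normally invisible.  Scoring a candidate structure
therefore reduces to graph arithmetic: resolve the observed proton and
carbon to atoms of the candidate, count bonds on the shortest path, and
ask whether that path length is spectroscopically plausible.  For the
U-48800 / U-51754 pair this single idea is decisive: the aromatic
ortho-doublet proton correlates with the benzylic methylene carbon over
3 bonds in U-48800 but would need 4 bonds in U-51754.

Observations may be keyed either by concrete atom labels ("H-8", "C-2")
or by spectral tags ("H_A") that a per-candidate label map resolves —
the same multiplet maps onto different ring positions in different
isomers.  An observation may also carry alternative partners (for
assignments the spectroscopist marked as interchangeable); the
least-violating alternative counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

from .graph import LabelError, MolecularGraph, bond_path_length

__all__ = [
    "NmrCorrelation",
    "CorrelationSet",
    "CorrelationVerdict",
    "CompatibilityReport",
    "hmbc_verdict",
    "cosy_verdict",
    "score_candidates",
    "key_hmbc_correlations",
    "default_label_maps",
]

KINDS = ("HMBC", "COSY", "HSQC")

COMPATIBLE = "compatible"
WEAK_COMPATIBLE = "weak-compatible"
INCOMPATIBLE = "incompatible"
EXCLUDED = "excluded"


@dataclass(frozen=True)
class NmrCorrelation:
    """One observed cross-peak.

    ``partner`` (and, for tagged data, ``proton``) may list alternatives;
    the best-scoring alternative is used.
    """

    kind: str
    proton: Union[str, Tuple[str, ...]]
    partner: Union[str, Tuple[str, ...]]
    J: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown correlation kind {self.kind!r}; use {KINDS}")

    def proton_options(self) -> Tuple[str, ...]:
        return (self.proton,) if isinstance(self.proton, str) else tuple(self.proton)

    def partner_options(self) -> Tuple[str, ...]:
        return (self.partner,) if isinstance(self.partner, str) else tuple(self.partner)

    def key(self) -> Tuple[str, Tuple[str, ...], Tuple[str, ...]]:
        return (self.kind, self.proton_options(), self.partner_options())


@dataclass
class CorrelationSet:
    """A deduplicated list of observed correlations with a provenance note."""

    correlations: List[NmrCorrelation] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for corr in self.correlations:
            if corr.key() in seen:
                raise ValueError(f"duplicate correlation {corr.key()}")
            seen.add(corr.key())

    def __len__(self) -> int:
        return len(self.correlations)

    def __iter__(self):
        return iter(self.correlations)


@dataclass(frozen=True)
class CorrelationVerdict:
    correlation: NmrCorrelation
    path: Optional[int]
    verdict: str
    resolved_proton: Optional[str] = None
    resolved_partner: Optional[str] = None


@dataclass
class CompatibilityReport:
    candidate: str
    verdicts: List[CorrelationVerdict]

    @property
    def satisfied(self) -> int:
        return sum(
            1 for v in self.verdicts if v.verdict in (COMPATIBLE, WEAK_COMPATIBLE)
        )

    @property
    def violated(self) -> int:
        return sum(1 for v in self.verdicts if v.verdict == INCOMPATIBLE)

    @property
    def excluded(self) -> int:
        return sum(1 for v in self.verdicts if v.verdict == EXCLUDED)


def _map_label(
    label: str, label_map: Optional[Mapping[str, Union[str, Sequence[str]]]]
) -> Tuple[str, ...]:
    if label_map and label in label_map:
        mapped = label_map[label]
        return (mapped,) if isinstance(mapped, str) else tuple(mapped)
    return (label,)


def _best_path_verdict(
    graph: MolecularGraph,
    corr: NmrCorrelation,
    window: Tuple[int, int],
    weak_window: Optional[Tuple[int, int]] = None,
    label_map: Optional[Mapping[str, Union[str, Sequence[str]]]] = None,
) -> CorrelationVerdict:
    """Evaluate all (proton, partner) alternatives; keep the best verdict.

    Verdict preference: compatible > weak-compatible > excluded >
    incompatible (an observation marked with interchangeable assignments
    only counts as a violation if every alternative violates).
    """
    rank = {COMPATIBLE: 0, WEAK_COMPATIBLE: 1, EXCLUDED: 2, INCOMPATIBLE: 3}
    lo, hi = window
    best: Optional[CorrelationVerdict] = None
    errors: List[str] = []
    for proton_tag in corr.proton_options():
        for proton in _map_label(proton_tag, label_map):
            for partner_tag in corr.partner_options():
                for partner in _map_label(partner_tag, label_map):
                    try:
                        path = bond_path_length(graph, proton, partner)
                    except (LabelError, KeyError) as exc:
                        errors.append(str(exc))
                        continue
                    if path <= 1:
                        verdict = EXCLUDED
                    elif lo <= path <= hi:
                        verdict = COMPATIBLE
                    elif weak_window and weak_window[0] <= path <= weak_window[1]:
                        verdict = WEAK_COMPATIBLE
                    else:
                        verdict = INCOMPATIBLE
                    cand = CorrelationVerdict(corr, path, verdict, proton, partner)
                    if best is None or rank[verdict] < rank[best.verdict]:
                        best = cand
    if best is None:
        raise LabelError(
            f"correlation {corr.key()} unresolvable in candidate "
            f"{graph.name or '<unnamed>'}: " + "; ".join(errors)
        )
    return best


def hmbc_verdict(
    graph: MolecularGraph,
    corr: NmrCorrelation,
    window: Tuple[int, int] = (2, 3),
    label_map: Optional[Mapping[str, Union[str, Sequence[str]]]] = None,
) -> CorrelationVerdict:
    """Is an HMBC cross-peak compatible with a structure?

    Compatible iff the H-to-C bond path lies within ``window`` (default
    2-3 bonds, the standard long-range reach).  A 1-bond path is
    "excluded" — that is HSQC territory, not evidence either way.
    """
    if corr.kind != "HMBC":
        raise ValueError(f"hmbc_verdict got a {corr.kind} correlation")
    return _best_path_verdict(graph, corr, window, None, label_map)


def cosy_verdict(
    graph: MolecularGraph,
    corr: NmrCorrelation,
    window: Tuple[int, int] = (2, 3),
    weak_window: Tuple[int, int] = (4, 4),
    weak_j_max: float = 3.0,
    label_map: Optional[Mapping[str, Union[str, Sequence[str]]]] = None,
) -> CorrelationVerdict:
    """Is a COSY cross-peak compatible with a structure?

    2-3 bond H-H paths are compatible; a 4-bond path is accepted as
    "weak-compatible" only when a small recorded coupling (J <=
    ``weak_j_max`` Hz, typical of meta/W couplings) justifies it.
    """
    if corr.kind != "COSY":
        raise ValueError(f"cosy_verdict got a {corr.kind} correlation")
    weak = weak_window if (corr.J is not None and corr.J <= weak_j_max) else None
    return _best_path_verdict(graph, corr, window, weak, label_map)


def _verdict_for(graph, corr, window, label_map):
    if corr.kind == "HMBC":
        return hmbc_verdict(graph, corr, window, label_map)
    if corr.kind == "COSY":
        return cosy_verdict(graph, corr, window, label_map=label_map)
    # HSQC: one-bond check, informational
    return _best_path_verdict(graph, corr, (1, 1), None, label_map)


def score_candidates(
    candidates: Sequence[MolecularGraph],
    obs: CorrelationSet,
    window: Tuple[int, int] = (2, 3),
    label_maps: Optional[Mapping[str, Mapping[str, Union[str, Sequence[str]]]]] = None,
) -> List[CompatibilityReport]:
    """Rank candidate structures by compatibility with observed correlations.

    Returns one report per candidate, ordered by (violations ascending,
    satisfactions descending, name ascending).  ``label_maps`` maps
    candidate name -> {spectral tag -> label or alternatives}.
    """
    reports: List[CompatibilityReport] = []
    for graph in candidates:
        name = graph.name or "<unnamed>"
        lmap = (label_maps or {}).get(name)
        verdicts = []
        for corr in obs:
            try:
                verdicts.append(_verdict_for(graph, corr, window, lmap))
            except LabelError as exc:
                raise LabelError(f"candidate {name}: {exc}") from exc
        reports.append(CompatibilityReport(name, verdicts))
    reports.sort(key=lambda r: (r.violated, -r.satisfied, r.candidate))
    return reports


# ---------------------------------------------------------------------------
# Built-in fixture: the key HMBC set of the published U-48800 assignment.
# ---------------------------------------------------------------------------

# Spectral tags for the aromatic ABX system (same observed multiplets in
# both isomer hypotheses, but mapped to different ring positions):
#   H_X  meta-only doublet (J ~1.9 Hz);  H_A  ortho-only doublet (J ~8.2 Hz);
#   H_B  doublet of doublets;  C_X/C_A/C_B their HSQC carbons;
#   Cq1/Cq2/Cq3 the three quaternary aromatic carbons (136.6/134.6/134.0 ppm).


def key_hmbc_correlations() -> CorrelationSet:
    """Key HMBC correlations of the published assignment, as tagged data.

    Aliphatic positions share numbering between the two isomers and are
    keyed by label directly; aromatic signals are keyed by ABX tags.  The
    two 134.x quaternary signals whose assignment may be reversed carry
    both alternatives.
    """
    c = [
        # carbonyl C-1 <- methylene and amide N-methyl protons
        NmrCorrelation("HMBC", "H-2a", "C-1"),
        NmrCorrelation("HMBC", "H-2b", "C-1"),
        NmrCorrelation("HMBC", "H-9'", "C-1"),
        # the decisive cross-peak: ortho doublet <-> benzylic methylene
        NmrCorrelation("HMBC", "H_A", "C-2"),
        # 134.6 ppm quaternary (C-3 or C-6)
        NmrCorrelation("HMBC", "H_X", "Cq2"),
        NmrCorrelation("HMBC", "H_A", "Cq2"),
        NmrCorrelation("HMBC", "H-2a", "Cq2"),
        NmrCorrelation("HMBC", "H-2b", "Cq2"),
        # 136.6 ppm quaternary
        NmrCorrelation("HMBC", "H_X", "Cq1"),
        NmrCorrelation("HMBC", "H_A", "Cq1"),
        NmrCorrelation("HMBC", "H-2a", "Cq1"),
        NmrCorrelation("HMBC", "H-2b", "Cq1"),
        # methine carbon of H_X <- H_B
        NmrCorrelation("HMBC", "H_B", "C_X"),
        # 134.0 ppm quaternary
        NmrCorrelation("HMBC", "H_X", "Cq3"),
        NmrCorrelation("HMBC", "H_B", "Cq3"),
        # methine carbon of H_B <- H_X
        NmrCorrelation("HMBC", "H_X", "C_B"),
        # methine carbon of H_A <- H_B and the methylene protons
        NmrCorrelation("HMBC", "H_B", "C_A"),
        NmrCorrelation("HMBC", "H-2a", "C_A"),
        NmrCorrelation("HMBC", "H-2b", "C_A"),
        # cyclohexane/amine region (labels shared by both isomers)
        NmrCorrelation("HMBC", "H-9'", "C-1'"),
        NmrCorrelation("HMBC", "H-7'", "C-6'"),
        NmrCorrelation("HMBC", "H-8'", "C-6'"),
        NmrCorrelation("HMBC", "H-8'", "C-7'"),
        NmrCorrelation("HMBC", "H-7'", "C-8'"),
    ]
    return CorrelationSet(c, provenance="published key HMBC set (tagged ABX)")


def default_label_maps() -> Dict[str, Dict[str, Union[str, Tuple[str, ...]]]]:
    """Spectral-tag resolution for the two built-in candidates.

    The ABX multiplet logic fixes the proton tags per isomer: the
    meta-only doublet H_X sits between the two chlorines' neighbours
    (H-5 in U-48800, H-4 in U-51754), the ortho-only doublet H_A is the
    proton with a single ortho neighbour (H-8 / H-7), and H_B is the
    doublet of doublets (H-7 / H-8).  Quaternary-carbon tags carry the
    printed assignment for U-48800 (with the documented C-3/C-6
    interchange) and the full quaternary set for U-51754, which has no
    published assignment.
    """
    return {
        "U-48800": {
            "H_X": "H-5",
            "H_A": "H-8",
            "H_B": "H-7",
            "C_X": "C-5",
            "C_A": "C-8",
            "C_B": "C-7",
            "Cq1": "C-4",
            "Cq2": ("C-3", "C-6"),
            "Cq3": ("C-6", "C-3"),
        },
        "U-51754": {
            "H_X": "H-4",
            "H_A": "H-7",
            "H_B": "H-8",
            "C_X": "C-4",
            "C_A": "C-7",
            "C_B": "C-8",
            "Cq1": ("C-3", "C-5", "C-6"),
            "Cq2": ("C-3", "C-5", "C-6"),
            "Cq3": ("C-3", "C-5", "C-6"),
        },
    }
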