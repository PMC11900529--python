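"""Ensemble-level conformer analysis.

The analysis chain mirrors the trajectory post-processing used to
characterise the flexible rings of a benzyl U-opioid: align every frame
to the first on the ring carbons, build the pairwise RMSD matrix over
the ring carbons plus their bonded atoms, cut it into an initial set of
agglomerative clusters, merge clusters whose medoids nearly coincide,
and report per-cluster populations, ring-conformation consensus and
signed C-H/plane angle statistics with axial/equatorial calls.  A
separate, cheaper route clusters frames by the sign of one exocyclic
dihedral.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering

from .geometry import (
    AngleMeasurement,
    Frame,
    GeometryError,
    RingSelection,
    ch_plane_angle,
    classify_position,
    dihedral,
    fit_plane,
    pucker_coords,
)

__all__ = [
    "Ensemble",
    "DihedralClusterReport",
    "ClusterStats",
    "ConformerClusterReport",
    "kabsch_align",
    "align_ensemble",
    "rmsd_matrix",
    "cluster_dihedral",
    "cluster_conformers",
    "cluster_angle_stats",
]


@dataclass
class Ensemble:
    """Ordered conformer frames sharing one atom table."""

    coords: np.ndarray  # (n_frames, n_atoms, 3)
    elements: List[str]
    labels: Optional[List[str]] = None
    ring: Optional[RingSelection] = None
    ground_truth: Optional[np.ndarray] = None
    component_names: Optional[List[str]] = None
    metadata: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must be (frames, atoms, 3), got {self.coords.shape}")
        if self.coords.shape[0] == 0:
            raise ValueError("empty ensemble")
        if self.coords.shape[1] != len(self.elements):
            raise ValueError("atom-table / coordinate shape mismatch")

    @staticmethod
    def from_frames(
        frames: Sequence[Frame],
        ring: Optional[RingSelection] = None,
        ground_truth: Optional[np.ndarray] = None,
        component_names: Optional[List[str]] = None,
        metadata: Optional[Dict[str, str]] = None,
    ) -> "Ensemble":
        if not frames:
            raise ValueError("empty ensemble")
        first = frames[0]
        for k, f in enumerate(frames):
            if f.elements != first.elements or (f.labels or None) != (first.labels or None):
                raise ValueError(f"frame {k} atom table differs from frame 0")
        return Ensemble(
            np.stack([f.coords for f in frames]),
            list(first.elements),
            list(first.labels) if first.labels else None,
            ring,
            ground_truth,
            component_names,
            dict(metadata or {}),
        )

    @property
    def n_frames(self) -> int:
        return int(self.coords.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.coords.shape[1])

    def frame(self, k: int) -> Frame:
        return Frame(self.coords[k], self.elements, self.labels)

    def index_of(self, label: str) -> int:
        if self.labels is None:
            raise KeyError("ensemble has no atom labels")
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"label {label!r} not found in ensemble") from None

    def bonded_selection(self, ring: Optional[RingSelection] = None, cutoff: float = 1.8) -> List[int]:
        """Ring carbons plus every atom bonded to them (distance criterion).

        Bonding is inferred from the first frame: any atom within
        ``cutoff`` Angstrom of a ring carbon counts as bonded.
        """
        ring = ring or self.ring
        if ring is None:
            raise ValueError("no ring selection available")
        base = self.coords[0]
        sel = set(ring.ring)
        for idx in ring.ring:
            d = np.linalg.norm(base - base[idx], axis=1)
            sel.update(int(i) for i in np.where((d > 1e-9) & (d <= cutoff))[0])
        return sorted(sel)


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------


def _kabsch_rotation(ref: np.ndarray, mob: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal proper rotation mapping centred ``mob`` onto centred ``ref``."""
    rc, mc = ref.mean(axis=0), mob.mean(axis=0)
    h = (mob - mc).T @ (ref - rc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    return rot, rc, mc


def kabsch_align(
    ref: Frame, mobile: Frame, selection: Sequence[int]
) -> Tuple[Frame, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``ref``.

    The rotation is fitted on ``selection`` (same size and order in both
    frames, >= 3 atoms); reflections are never allowed.  The whole
    mobile frame is transformed and the RMSD over the selection
    returned.
    """
    sel = list(selection)
    if len(sel) < 3:
        raise ValueError(f"selection needs >= 3 atoms, got {len(sel)}")
    if ref.n_atoms != mobile.n_atoms:
        raise ValueError("frame size mismatch")
    rot, rc, mc = _kabsch_rotation(ref.coords[sel], mobile.coords[sel])
    moved = (mobile.coords - mc) @ rot.T + rc
    rmsd = float(np.sqrt(np.mean(np.sum((moved[sel] - ref.coords[sel]) ** 2, axis=1))))
    return Frame(moved, mobile.elements, mobile.labels), rmsd


def align_ensemble(ensemble: Ensemble, selection: Sequence[int]) -> Ensemble:
    """Align every frame to frame 0 on ``selection`` (single pass)."""
    ref = ensemble.frame(0)
    out = np.empty_like(ensemble.coords)
    out[0] = ensemble.coords[0]
    for k in range(1, ensemble.n_frames):
        aligned, _ = kabsch_align(ref, ensemble.frame(k), selection)
        out[k] = aligned.coords
    return Ensemble(
        out,
        ensemble.elements,
        ensemble.labels,
        ensemble.ring,
        ensemble.ground_truth,
        ensemble.component_names,
        dict(ensemble.metadata),
    )


def rmsd_matrix(
    ensemble: Ensemble,
    selection: Optional[Sequence[int]] = None,
    superpose: bool = True,
    chunk: int = 256,
) -> np.ndarray:
    """Symmetric pairwise RMSD matrix over a selection.

    With ``superpose=True`` (default) every pair is optimally superposed
    (proper rotations only) before the deviation is measured, using the
    closed form RMSD^2 = (T_i + T_j - 2 max_R tr(R C_ij)) / m evaluated
    with batched 3x3 SVDs.  ``superpose=False`` measures deviations in
    the frames' current (pre-aligned) orientations.
    """
    if ensemble.n_frames == 0:
        raise ValueError("empty ensemble")
    sel = list(selection) if selection is not None else ensemble.bonded_selection()
    x = ensemble.coords[:, sel, :]
    n, m, _ = x.shape
    xc = x - x.mean(axis=1, keepdims=True)

    if not superpose:
        out = np.empty((n, n))
        for i0 in range(0, n, chunk):
            blk = x[i0 : i0 + chunk, None, :, :] - x[None, :, :, :]
            out[i0 : i0 + chunk] = np.sqrt(np.mean(np.sum(blk**2, axis=3), axis=2))
        np.fill_diagonal(out, 0.0)
        return out

    traces = np.einsum("nmk,nmk->n", xc, xc)
    flat = xc.transpose(0, 2, 1).reshape(n * 3, m)  # (n*3, m)
    out = np.empty((n, n))
    for i0 in range(0, n, chunk):
        i1 = min(i0 + chunk, n)
        cov = (flat[i0 * 3 : i1 * 3] @ flat.T).reshape(i1 - i0, 3, n, 3)
        cov = cov.transpose(0, 2, 1, 3).reshape(-1, 3, 3)  # (blk*n, 3, 3)
        s = np.linalg.svd(cov, compute_uv=False)
        sign = np.sign(np.linalg.det(cov))
        sign[sign == 0] = 1.0
        best = s[:, 0] + s[:, 1] + sign * s[:, 2]
        best = best.reshape(i1 - i0, n)
        sq = (traces[i0:i1, None] + traces[None, :] - 2.0 * best) / m
        out[i0:i1] = np.sqrt(np.clip(sq, 0.0, None))
    out = 0.5 * (out + out.T)  # enforce exact symmetry
    np.fill_diagonal(out, 0.0)
    return out


# ---------------------------------------------------------------------------
# dihedral-sign clustering
# ---------------------------------------------------------------------------


@dataclass
class DihedralClusterReport:
    angles: np.ndarray  # per-frame signed dihedral, deg
    assignments: np.ndarray  # +1 positive cluster, -1 negative cluster
    cutoff: float
    counts: Tuple[int, int]  # (positive, negative)

    @property
    def fractions(self) -> Tuple[float, float]:
        n = len(self.angles)
        return (self.counts[0] / n, self.counts[1] / n)

    def to_dict(self) -> Dict:
        return {
            "cutoff_deg": self.cutoff,
            "n_frames": int(len(self.angles)),
            "positive": {"count": self.counts[0], "fraction": self.fractions[0]},
            "negative": {"count": self.counts[1], "fraction": self.fractions[1]},
        }


def cluster_dihedral(
    ensemble: Ensemble,
    atom_labels: Sequence[str],
    cutoff: float = 0.0,
) -> DihedralClusterReport:
    """Two-way clustering of frames by the sign of one torsion angle.

    Frames with dihedral >= ``cutoff`` fall in the positive cluster
    (ties go positive), the rest in the negative cluster.
    """
    if len(atom_labels) != 4:
        raise ValueError(f"need exactly 4 atom labels, got {len(atom_labels)}")
    idx = [ensemble.index_of(lab) for lab in atom_labels]
    angles = np.array(
        [
            dihedral(*(ensemble.coords[k, i] for i in idx))
            for k in range(ensemble.n_frames)
        ]
    )
    assignments = np.where(angles >= cutoff, 1, -1)
    pos = int(np.sum(assignments == 1))
    return DihedralClusterReport(angles, assignments, cutoff, (pos, len(angles) - pos))


# ---------------------------------------------------------------------------
# conformer clustering
# ---------------------------------------------------------------------------


@dataclass
class ChAngleStat:
    carbon_label: str
    hydrogen_slot: int
    mean: float
    sd: float
    position: str  # axial | equatorial

    def to_dict(self) -> Dict:
        return asdict(self)


@dataclass
class ClusterStats:
    label: int
    count: int
    fraction: float
    conformation: str  # modal pucker class
    ch_angles: List[ChAngleStat]
    medoid_frame: int

    def to_dict(self) -> Dict:
        return {
            "cluster": self.label,
            "count": self.count,
            "fraction": self.fraction,
            "conformation": self.conformation,
            "medoid_frame": self.medoid_frame,
            "ch_angles": [s.to_dict() for s in self.ch_angles],
        }


@dataclass
class ConformerClusterReport:
    frame_labels: np.ndarray
    clusters: List[ClusterStats]
    k_init: int
    merge_threshold: float
    linkage: str = "average"

    def to_dict(self) -> Dict:
        return {
            "n_frames": int(len(self.frame_labels)),
            "k_init": self.k_init,
            "merge_threshold_A": self.merge_threshold,
            "linkage": self.linkage,
            "n_clusters": len(self.clusters),
            "clusters": [c.to_dict() for c in self.clusters],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)

    def cluster_table(self) -> pd.DataFrame:
        rows = []
        for c in self.clusters:
            row = {
                "cluster": c.label,
                "count": c.count,
                "fraction": c.fraction,
                "conformation": c.conformation,
            }
            for s in c.ch_angles:
                key = f"{s.carbon_label}-H-{s.hydrogen_slot}"
                row[f"{key}_mean"] = s.mean
                row[f"{key}_sd"] = s.sd
                row[f"{key}_position"] = s.position
            rows.append(row)
        return pd.DataFrame(rows)


def cluster_angle_stats(
    ensemble: Ensemble,
    frame_indices: Sequence[int],
    ring: Optional[RingSelection] = None,
    axial_threshold: float = 45.0,
) -> Tuple[List[ChAngleStat], str]:
    """Signed C-H/plane angle statistics and pucker consensus of a subset.

    Means and SDs (ddof=1 when more than one frame) are taken over
    frames of the signed per-frame angle; the positional call applies
    the axial threshold to the mean.  The conformation consensus is the
    modal pucker class.
    """
    ring = ring or ensemble.ring
    if ring is None:
        raise ValueError("no ring selection available")
    idxs = list(frame_indices)
    if not idxs:
        raise ValueError("empty frame subset")

    per_ch: Dict[Tuple[int, int], List[float]] = {}
    classes: List[str] = []
    for k in idxs:
        frame = ensemble.frame(k)
        plane = fit_plane(frame, ring)
        classes.append(pucker_coords(frame, ring).conformation)
        for slot_pos, carbon in enumerate(ring.ring):
            for slot, h_idx in enumerate(ring.h_map.get(carbon, []), start=1):
                ang = ch_plane_angle(plane, frame.coords[carbon], frame.coords[h_idx])
                per_ch.setdefault((slot_pos, slot), []).append(ang)

    stats: List[ChAngleStat] = []
    for (slot_pos, slot), vals in sorted(per_ch.items()):
        arr = np.asarray(vals)
        mean = float(arr.mean())
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        carbon = ring.ring[slot_pos]
        label = (
            ensemble.labels[carbon]
            if ensemble.labels is not None
            else f"ring[{slot_pos}]"
        )
        stats.append(
            ChAngleStat(label, slot, mean, sd, classify_position(mean, axial_threshold))
        )
    values, counts = np.unique(classes, return_counts=True)
    consensus = str(values[np.argmax(counts)])
    return stats, consensus


def _medoid(frames: np.ndarray, dm: np.ndarray) -> int:
    sub = dm[np.ix_(frames, frames)]
    return int(frames[np.argmin(sub.sum(axis=1))])


def cluster_conformers(
    ensemble: Ensemble,
    ring: Optional[RingSelection] = None,
    k_init: int = 14,
    merge_threshold: float = 0.3,
    axial_threshold: float = 45.0,
    precomputed_rmsd: Optional[np.ndarray] = None,
) -> ConformerClusterReport:
    """Agglomerative conformer clustering with a medoid-merge step.

    The ensemble is aligned to frame 0 on the ring carbons, the pairwise
    RMSD matrix computed over the ring carbons plus bonded atoms, and
    average-linkage agglomerative clustering cuts it into ``k_init``
    groups.  Groups whose medoid-to-medoid RMSD falls below
    ``merge_threshold`` (Angstrom) are merged transitively — the
    automated stand-in for merging near-duplicate clusters by visual
    inspection.  Final clusters are relabelled by descending population.
    """
    ring = ring or ensemble.ring
    if ring is None:
        raise ValueError("no ring selection available")
    n = ensemble.n_frames
    if k_init > n:
        raise ValueError(f"k_init={k_init} exceeds the {n} available frames")

    aligned = align_ensemble(ensemble, list(ring.ring))
    dm = (
        precomputed_rmsd
        if precomputed_rmsd is not None
        else rmsd_matrix(aligned, aligned.bonded_selection(ring))
    )

    model = AgglomerativeClustering(
        n_clusters=k_init, metric="precomputed", linkage="average"
    )
    raw = model.fit_predict(dm)

    # transitive medoid merge
    groups = [np.where(raw == g)[0] for g in range(k_init)]
    medoids = [_medoid(g, dm) for g in groups]
    parent = list(range(k_init))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(k_init):
        for j in range(i + 1, k_init):
            if dm[medoids[i], medoids[j]] < merge_threshold:
                parent[find(i)] = find(j)

    merged = np.array([find(raw[k]) for k in range(n)])
    # relabel by descending population (ties: lower original root first)
    roots, counts = np.unique(merged, return_counts=True)
    order = sorted(range(len(roots)), key=lambda r: (-counts[r], roots[r]))
    relabel = {roots[r]: new for new, r in enumerate(order)}
    final = np.array([relabel[g] for g in merged])

    clusters: List[ClusterStats] = []
    for label in range(len(roots)):
        members = np.where(final == label)[0]
        stats, consensus = cluster_angle_stats(aligned, members, ring, axial_threshold)
        clusters.append(
            ClusterStats(
                label,
                int(len(members)),
                float(len(members) / n),
                consensus,
                stats,
                _medoid(members, dm),
            )
        )
    return ConformerClusterReport(final, clusters, k_init, merge_threshold)
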