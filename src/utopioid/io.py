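"""File formats: multi-frame XYZ, multi-model PDB, peak-list and
correlation CSV, and run configuration with a stable hash.

Readers are strict: structurally invalid files (bad count lines,
inconsistent atom counts between frames, empty input) are rejected with
errors naming the offending frame rather than silently repaired.
Coordinates are Angstrom throughout; pass ``units="nm"`` to convert
GROMACS-style exports on read.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .ensemble import Ensemble
from .geometry import Frame
from .ms import Peak, PeakList
from .nmr import CorrelationSet, NmrCorrelation

__all__ = [
    "FormatError",
    "read_xyz",
    "write_xyz",
    "read_pdb_models",
    "write_pdb_models",
    "read_peaklist_csv",
    "write_peaklist_csv",
    "read_correlations_csv",
    "write_correlations_csv",
    "RunConfig",
]

logger = logging.getLogger("utopioid")

NM_TO_ANGSTROM = 10.0


class FormatError(ValueError):
    """Structurally invalid input file."""


def _unit_factor(units: str) -> float:
    if units == "angstrom":
        return 1.0
    if units == "nm":
        return NM_TO_ANGSTROM
    raise ValueError(f"unknown units {units!r}; use 'angstrom' or 'nm'")


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------


def read_xyz(path: Union[str, Path], units: str = "angstrom") -> Ensemble:
    """Read a (multi-frame) XYZ file into an ensemble.

    Standard layout per frame: atom-count line, comment line, then
    ``element x y z`` rows; frames are concatenated.
    """
    factor = _unit_factor(units)
    lines = Path(path).read_text().splitlines()
    pos = 0
    frames: List[Frame] = []
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            count = int(lines[pos].strip())
        except ValueError:
            raise FormatError(
                f"{path}: malformed atom-count line {pos + 1}: {lines[pos]!r}"
            ) from None
        body = lines[pos + 2 : pos + 2 + count]
        if len(body) < count:
            raise FormatError(
                f"{path}: frame {len(frames)} truncated "
                f"(expected {count} atoms, file ended)"
            )
        elements, coords = [], []
        for k, row in enumerate(body):
            parts = row.split()
            if len(parts) < 4:
                raise FormatError(
                    f"{path}: frame {len(frames)}, atom {k}: bad row {row!r}"
                )
            elements.append(parts[0])
            try:
                coords.append([float(v) for v in parts[1:4]])
            except ValueError:
                raise FormatError(
                    f"{path}: frame {len(frames)}, atom {k}: non-numeric coordinates"
                ) from None
        if frames and elements != frames[0].elements:
            raise FormatError(
                f"{path}: frame {len(frames)} atom table differs from frame 0"
            )
        frames.append(Frame(np.array(coords) * factor, elements))
        pos += 2 + count
    if not frames:
        raise FormatError(f"{path}: empty XYZ input")
    return Ensemble.from_frames(frames, metadata={"source": str(path)})


def write_xyz(path: Union[str, Path], ensemble: Ensemble, comment: str = "") -> None:
    with open(path, "w") as fh:
        for k in range(ensemble.n_frames):
            fh.write(f"{ensemble.n_atoms}\n")
            fh.write(f"{comment or f'frame {k}'}\n")
            for el, (x, y, z) in zip(ensemble.elements, ensemble.coords[k]):
                fh.write(f"{el:<2s} {x:14.6f} {y:14.6f} {z:14.6f}\n")


# ---------------------------------------------------------------------------
# PDB (multi-model)
# ---------------------------------------------------------------------------

_KNOWN_ELEMENTS = ("CL", "C", "H", "N", "O")


def _element_from_name(name: str) -> str:
    stripped = "".join(ch for ch in name if ch.isalpha()).upper()
    if stripped.startswith("CL"):
        return "Cl"
    for el in _KNOWN_ELEMENTS:
        if stripped.startswith(el):
            return el.capitalize() if len(el) > 1 else el
    return stripped[:1] or "X"


def read_pdb_models(path: Union[str, Path], units: str = "angstrom") -> Ensemble:
    """Read a multi-model PDB into an ensemble.

    Elements come from columns 77-78 when present, otherwise they are
    inferred from the atom name (with a logged warning).  Atom names are
    kept as frame labels.
    """
    factor = _unit_factor(units)
    text = Path(path).read_text().splitlines()
    frames: List[Tuple[List[str], List[str], List[List[float]]]] = []
    current: Optional[Tuple[List[str], List[str], List[List[float]]]] = None
    saw_model = False
    warned = False

    def flush() -> None:
        nonlocal current
        if current is not None and current[0]:
            frames.append(current)
        current = None

    for line in text:
        rec = line[:6].strip()
        if rec == "MODEL":
            saw_model = True
            flush()
            current = ([], [], [])
        elif rec == "ENDMDL":
            flush()
        elif rec in ("ATOM", "HETATM"):
            if current is None:
                current = ([], [], [])
            name = line[12:16].strip()
            try:
                xyz = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            except ValueError:
                raise FormatError(
                    f"{path}: unparsable coordinates in record {line!r}"
                ) from None
            element = line[76:78].strip() if len(line) >= 78 else ""
            if not element:
                element = _element_from_name(name)
                if not warned:
                    logger.warning(
                        "%s: missing element columns; inferring from atom names", path
                    )
                    warned = True
            else:
                element = element.capitalize() if len(element) > 1 else element
            current[0].append(element)
            current[1].append(name)
            current[2].append(xyz)
    flush()
    if not frames:
        raise FormatError(f"{path}: no MODEL or ATOM records found")
    n0 = len(frames[0][0])
    out = []
    for k, (elements, names, coords) in enumerate(frames):
        if len(elements) != n0:
            raise FormatError(
                f"{path}: model {k} has {len(elements)} atoms, model 0 has {n0}"
            )
        out.append(Frame(np.array(coords) * factor, elements, names))
    if saw_model and len(out) == 0:
        raise FormatError(f"{path}: MODEL records contained no atoms")
    return Ensemble.from_frames(out, metadata={"source": str(path)})


def write_pdb_models(path: Union[str, Path], ensemble: Ensemble) -> None:
    """Write an ensemble as a fixed-column multi-model PDB.

    Frame labels become atom names (unicode primes mapped to ASCII
    apostrophes, truncated to 4 characters).
    """
    labels = ensemble.labels or [
        f"{el}{i + 1}" for i, el in enumerate(ensemble.elements)
    ]
    with open(path, "w") as fh:
        for k in range(ensemble.n_frames):
            fh.write(f"MODEL     {k + 1:4d}\n")
            for i, (el, lab) in enumerate(zip(ensemble.elements, labels)):
                name = lab.replace("′", "'").replace("-", "")[:4]
                x, y, z = ensemble.coords[k, i]
                fh.write(
                    f"HETATM{i + 1:5d} {name:<4s} LIG A   1    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {el:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# CSV: peak lists and correlations
# ---------------------------------------------------------------------------


def read_peaklist_csv(path: Union[str, Path]) -> PeakList:
    """Two-column CSV (mz, intensity); a non-numeric first row is a header."""
    df = pd.read_csv(path, header=None, comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need two columns (mz, intensity)")
    try:
        float(df.iloc[0, 0])
    except (TypeError, ValueError):
        df = df.iloc[1:]
    if df.empty:
        raise FormatError(f"{path}: no peaks")
    pairs = [(float(r.iloc[0]), float(r.iloc[1])) for _, r in df.iterrows()]
    return PeakList.from_pairs(pairs, source=str(path))


def write_peaklist_csv(path: Union[str, Path], peaks: PeakList) -> None:
    pd.DataFrame(
        [(p.mz, p.intensity) for p in peaks], columns=["mz", "intensity"]
    ).to_csv(path, index=False)


def read_correlations_csv(path: Union[str, Path]) -> CorrelationSet:
    """CSV with columns kind, proton_label, partner_label[, J_Hz].

    Alternative partners may be separated by ``|`` within a cell.
    """
    df = pd.read_csv(path)
    required = {"kind", "proton_label", "partner_label"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: need columns {sorted(required)}, got {list(df.columns)}"
        )
    corrs = []
    for _, row in df.iterrows():
        j = None
        if "J_Hz" in df.columns and pd.notna(row.get("J_Hz")):
            j = float(row["J_Hz"])

        def split(cell: str) -> Union[str, Tuple[str, ...]]:
            parts = tuple(p.strip() for p in str(cell).split("|"))
            return parts[0] if len(parts) == 1 else parts

        corrs.append(
            NmrCorrelation(
                str(row["kind"]).strip().upper(),
                split(row["proton_label"]),
                split(row["partner_label"]),
                j,
            )
        )
    return CorrelationSet(corrs, provenance=str(path))


def write_correlations_csv(path: Union[str, Path], obs: CorrelationSet) -> None:
    rows = []
    for c in obs:
        rows.append(
            {
                "kind": c.kind,
                "proton_label": "|".join(c.proton_options()),
                "partner_label": "|".join(c.partner_options()),
                "J_Hz": c.J if c.J is not None else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Subcommand parameters with a key-order-independent hash."""

    params: Dict[str, object] = field(default_factory=dict)
    version: str = ""

    def __post_init__(self) -> None:
        if not self.version:
            from . import __version__

            self.version = __version__

    @property
    def config_hash(self) -> str:
        payload = json.dumps(
            {"params": self.params, "version": self.version},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def log_banner(self) -> str:
        return (
            f"utopioid {self.version} | config {self.config_hash} | "
            f"seed {self.params.get('seed', 'n/a')}"
        )
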