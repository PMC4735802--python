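"""Load, filter, parameterize and orient channel structures.

Structures are stored column-wise in numpy arrays (one row per atom) with an
``atoms`` view for record-oriented access.  All coordinates are in ångström.
The orientation convention used throughout the package is: pore axis along
+z, cytosolic side at low z, extracellular side (selectivity filter) at
high z.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import (
    AlignmentError,
    EmptySelectionError,
    ParseError,
    RadiusLookupError,
)

logger = logging.getLogger(__name__)

WATER_RESNAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})

#: Bondi (1964) van der Waals radii, Å, heavy atoms plus common hetero elements.
BONDI_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "NA": 2.27,
    "K": 2.75,
    "MG": 1.73,
    "ZN": 1.39,
    "CA": 2.31,
    "SE": 1.90,
}

#: United-atom style radii (heavy atoms implicitly carry their hydrogens),
#: after the AMBER united-atom parameterization.  Selectable for sensitivity
#: analysis; Bondi is the default everywhere.
AMBER_UNITED_RADII = {
    "H": 1.00,
    "C": 1.85,
    "N": 1.75,
    "O": 1.60,
    "F": 1.47,
    "P": 2.10,
    "S": 2.00,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "NA": 2.27,
    "K": 2.75,
    "MG": 1.73,
    "ZN": 1.39,
    "CA": 2.31,
    "SE": 1.90,
}

RADII_SETS = {"bondi": BONDI_RADII, "amber_united": AMBER_UNITED_RADII}

DEFAULT_UNKNOWN_RADIUS = 1.80


@dataclass
class Atom:
    """A single atom record."""

    element: str
    position: np.ndarray
    vdw_radius: Optional[float]
    chain_id: str
    residue_name: str
    residue_number: int
    is_hetero: bool
    atom_name: str = ""


@dataclass
class ChannelStructure:
    """Column-wise atom container with a pore-axis orientation flag.

    ``axis_aligned`` is set once :func:`align_pore_axis` has mapped the pore
    axis onto +z with the cytosolic side at low z; re-aligning an aligned
    structure is a no-op up to numerical noise.
    """

    elements: np.ndarray            # (n,) str
    positions: np.ndarray           # (n, 3) float64, Å
    chain_ids: np.ndarray           # (n,) str
    residue_names: np.ndarray       # (n,) str
    residue_numbers: np.ndarray     # (n,) int
    hetero: np.ndarray              # (n,) bool
    atom_names: np.ndarray          # (n,) str
    vdw_radii: Optional[np.ndarray] = None  # (n,) float64, Å
    source_id: str = ""
    axis_aligned: bool = False

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (n, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite atom coordinates")
        if self.vdw_radii is not None:
            self.vdw_radii = np.asarray(self.vdw_radii, dtype=np.float64)
            if np.any(self.vdw_radii <= 0):
                raise ValueError("vdW radii must be positive")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    @property
    def atoms(self) -> list[Atom]:
        """Record-oriented view (copies; intended for small structures)."""
        radii: Sequence[Optional[float]]
        if self.vdw_radii is None:
            radii = [None] * len(self)
        else:
            radii = self.vdw_radii
        return [
            Atom(
                element=self.elements[i],
                position=self.positions[i].copy(),
                vdw_radius=radii[i],
                chain_id=self.chain_ids[i],
                residue_name=self.residue_names[i],
                residue_number=int(self.residue_numbers[i]),
                is_hetero=bool(self.hetero[i]),
                atom_name=self.atom_names[i],
            )
            for i in range(len(self))
        ]

    def subset(self, mask: np.ndarray) -> "ChannelStructure":
        return ChannelStructure(
            elements=self.elements[mask],
            positions=self.positions[mask],
            chain_ids=self.chain_ids[mask],
            residue_names=self.residue_names[mask],
            residue_numbers=self.residue_numbers[mask],
            hetero=self.hetero[mask],
            atom_names=self.atom_names[mask],
            vdw_radii=None if self.vdw_radii is None else self.vdw_radii[mask],
            source_id=self.source_id,
            axis_aligned=self.axis_aligned,
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ChannelStructure":
        """Return a copy with positions mapped through x -> R x + t."""
        new = replace(self)
        new.positions = self.positions @ np.asarray(rotation).T + np.asarray(translation)
        return new

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(c, None)
        return list(seen)


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "r")


def _from_atom_array(arr, source_id: str) -> ChannelStructure:
    elements = np.array([e.upper() if e else "?" for e in arr.element], dtype=object)
    return ChannelStructure(
        elements=elements,
        positions=np.asarray(arr.coord, dtype=np.float64),
        chain_ids=np.array([str(c) for c in arr.chain_id], dtype=object),
        residue_names=np.array([str(r) for r in arr.res_name], dtype=object),
        residue_numbers=np.asarray(arr.res_id, dtype=np.int64),
        hetero=np.asarray(arr.hetero, dtype=bool),
        atom_names=np.array([str(a) for a in arr.atom_name], dtype=object),
        source_id=source_id,
    )


def load_structure(
    path,
    chain_filter: Optional[Iterable[str]] = None,
    het_policy: str = "strip_all",
) -> ChannelStructure:
    """Read a PDB (or gzipped PDB) file into a :class:`ChannelStructure`.

    Parameters
    ----------
    path:
        ``.pdb`` or ``.pdb.gz`` file path.
    chain_filter:
        Optional list of chain identifiers to keep; every named chain must
        be present in the file.
    het_policy:
        ``"keep"`` retains all records, ``"strip_all"`` removes every
        HETATM record (waters, ions, lipids, toxins), ``"strip_waters"``
        removes water records only.  ATOM records are always retained.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties broken by file order); only the first model of multi-model files
    is used.
    """
    from biotite.structure.io.pdb import PDBFile

    if het_policy not in ("keep", "strip_all", "strip_waters"):
        raise ValueError(f"unknown het_policy {het_policy!r}")
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        with _open_text(path) as fh:
            pdb_file = PDBFile.read(fh)
        arr = pdb_file.get_structure(model=1, altloc="occupancy")
    except Exception as exc:  # biotite raises various error types
        raise ParseError(f"cannot parse PDB file {path}: {exc}") from exc
    if arr.array_length() == 0:
        raise ParseError(f"no atom records in {path}")

    structure = _from_atom_array(arr, source_id=path.name.split(".")[0])

    if het_policy == "strip_all":
        structure = structure.subset(~structure.hetero)
    elif het_policy == "strip_waters":
        is_water = np.isin(structure.residue_names.astype(str), list(WATER_RESNAMES))
        structure = structure.subset(~(structure.hetero & is_water))

    if chain_filter is not None:
        wanted = [str(c) for c in chain_filter]
        present = set(structure.chain_ids)
        missing = [c for c in wanted if c not in present]
        if missing:
            raise EmptySelectionError(
                f"chains {missing} not present in {path} (have {sorted(present)})"
            )
        structure = structure.subset(np.isin(structure.chain_ids.astype(str), wanted))

    if len(structure) == 0:
        raise EmptySelectionError(f"selection left no atoms in {path}")
    return structure


def write_structure(structure: ChannelStructure, path) -> None:
    """Write a structure as fixed-format PDB (deterministic ordering)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    if len(structure) == 0:
        raise EmptySelectionError("refusing to write an empty structure")
    arr = struc.AtomArray(len(structure))
    arr.coord = structure.positions.astype(np.float32)
    arr.chain_id = structure.chain_ids.astype("U4")
    arr.res_id = structure.residue_numbers
    arr.res_name = structure.residue_names.astype("U5")
    arr.atom_name = structure.atom_names.astype("U6")
    arr.element = structure.elements.astype("U2")
    arr.hetero = structure.hetero
    pdb_file = PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(str(path))


def assign_radii(
    structure: ChannelStructure,
    radii_set: str = "bondi",
    default_radius: float = DEFAULT_UNKNOWN_RADIUS,
    strict: bool = False,
) -> ChannelStructure:
    """Attach van der Waals radii from a named published set.

    Unknown elements receive ``default_radius`` with a logged warning, or
    raise :class:`RadiusLookupError` when ``strict`` is set.  Idempotent:
    reassigning the same set leaves radii unchanged.
    """
    try:
        table = RADII_SETS[radii_set]
    except KeyError:
        raise ValueError(f"unknown radii set {radii_set!r}; choose from {sorted(RADII_SETS)}")
    radii = np.empty(len(structure), dtype=np.float64)
    unknown: set[str] = set()
    for i, element in enumerate(structure.elements):
        r = table.get(element)
        if r is None:
            unknown.add(element)
            r = default_radius
        radii[i] = r
    if unknown:
        if strict:
            raise RadiusLookupError(
                f"elements {sorted(unknown)} not in radii set {radii_set!r}"
            )
        logger.warning(
            "elements %s not in radii set %r; using default %.2f Å",
            sorted(unknown), radii_set, default_radius,
        )
    new = replace(structure)
    new.vdw_radii = radii
    return new


def _chain_residue_sequence(structure: ChannelStructure, chain: str):
    """Residues of one chain in residue-number order: (number, name, atom-index-array)."""
    mask = structure.chain_ids == chain
    numbers = structure.residue_numbers[mask]
    names = structure.residue_names[mask]
    idx = np.nonzero(mask)[0]
    order: dict[int, tuple[str, list[int]]] = {}
    for i, num, name in zip(idx, numbers, names):
        entry = order.setdefault(int(num), (str(name), []))
        entry[1].append(int(i))
    return sorted((num, name, np.array(ats)) for num, (name, ats) in order.items())


_FILTER_MOTIFS = (
    ("THR", "VAL", "GLY", "TYR", "GLY"),
    ("THR", "VAL", "GLY", "PHE", "GLY"),
)


def chains_with_filter_motif(structure: ChannelStructure) -> list[str]:
    """Chains carrying a T-V-G-Y-G / T-V-G-F-G signature (the pore-forming
    chains of a K-channel; useful for dropping Fab/toxin/beta chains)."""
    found = []
    for chain in structure.chains():
        residues = _chain_residue_sequence(structure, chain)
        for i in range(len(residues) - 4):
            window = residues[i:i + 5]
            numbers = [w[0] for w in window]
            names = tuple(w[1] for w in window)
            if numbers == list(range(numbers[0], numbers[0] + 5)) and names in _FILTER_MOTIFS:
                found.append(chain)
                break
    return found


def detect_filter_anchor(structure: ChannelStructure) -> Optional[float]:
    """Locate the selectivity filter along z.

    Returns the mean z of the Thr residues of a T-V-G-Y-G (or T-V-G-F-G)
    signature found in any chain, or the mean z of retained pore potassium
    ions when no motif is present, or ``None`` when neither is found.
    """
    thr_z: list[float] = []
    for chain in structure.chains():
        residues = _chain_residue_sequence(structure, chain)
        for i in range(len(residues) - 4):
            window = residues[i:i + 5]
            numbers = [w[0] for w in window]
            names = tuple(w[1] for w in window)
            if numbers != list(range(numbers[0], numbers[0] + 5)):
                continue
            if names in _FILTER_MOTIFS:
                thr_z.append(float(structure.positions[window[0][2], 2].mean()))
    if thr_z:
        return float(np.mean(thr_z))
    ion_mask = structure.hetero & (structure.elements == "K")
    if np.any(ion_mask):
        return float(structure.positions[ion_mask, 2].mean())
    return None


def _rotation_to_z(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping the unit vector ``axis`` onto +z."""
    axis = axis / np.linalg.norm(axis)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    c = float(np.dot(axis, z))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        return np.diag([1.0, -1.0, -1.0])  # 180° about x
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


_FLIP_X = np.diag([1.0, -1.0, -1.0])


def _symmetry_axis(structure: ChannelStructure) -> np.ndarray:
    """Axis of a pseudo-symmetric oligomer: normal of the best-fit plane
    through the chain centroids (the centroids of symmetry-related chains
    lie on a circle perpendicular to the rotation axis)."""
    chains = structure.chains()
    counts = {c: len(set(structure.residue_numbers[structure.chain_ids == c])) for c in chains}
    modal = max(set(counts.values()), key=lambda v: sum(1 for c in counts.values() if c == v))
    core = [c for c in chains if abs(counts[c] - modal) <= max(2, 0.05 * modal)]
    if len(core) < 3:
        raise AlignmentError(
            f"symmetry mode needs ≥3 chains with matching residue counts; "
            f"chain residue counts are {counts}"
        )
    centroids = np.array([
        structure.positions[structure.chain_ids == c].mean(axis=0) for c in core
    ])
    deviations = centroids - centroids.mean(axis=0)
    # smallest right-singular vector = plane normal
    _, s, vt = np.linalg.svd(deviations)
    if s[1] < 1e-6:
        raise AlignmentError("chain centroids are collinear; cannot infer symmetry axis")
    return vt[2]


def _principal_axis(structure: ChannelStructure) -> np.ndarray:
    """Eigenvector of the coordinate covariance whose eigenvalue is most
    isolated from the other two (the unique direction of a pseudo-symmetric
    assembly)."""
    deviations = structure.positions - structure.positions.mean(axis=0)
    cov = deviations.T @ deviations / len(deviations)
    w, v = np.linalg.eigh(cov)
    gaps = [abs(w[0] - w[1]) + abs(w[0] - w[2]),
            abs(w[1] - w[0]) + abs(w[1] - w[2]),
            abs(w[2] - w[0]) + abs(w[2] - w[1])]
    return v[:, int(np.argmax(gaps))]


def align_pore_axis(
    structure: ChannelStructure,
    mode: str = "symmetry",
    manual_spec: Optional[tuple] = None,
) -> ChannelStructure:
    """Rotate/translate a copy so the pore axis runs along +z through x=y=0
    with the cytosolic side at low z.

    Modes: ``symmetry`` (≥3 equal chains; axis from the chain-centroid
    plane), ``principal`` (isolated inertia eigenvector), ``manual``
    (pair of points, cytosolic anchor first).  For the automatic modes the
    up/down orientation is resolved by placing the selectivity-filter
    anchor (see :func:`detect_filter_anchor`) at high z; when no anchor is
    detectable the orientation is left as inferred, with a warning.
    """
    if len(structure) == 0:
        raise EmptySelectionError("cannot align an empty structure")
    if mode == "manual":
        if manual_spec is None:
            raise AlignmentError("manual mode requires a pair of anchor points")
        p_cyto, p_extra = (np.asarray(p, dtype=float) for p in manual_spec)
        axis = p_extra - p_cyto
        if np.linalg.norm(axis) < 1e-9:
            raise AlignmentError("degenerate manual anchors (coincident points)")
        axis = axis / np.linalg.norm(axis)
    elif mode == "symmetry":
        axis = _symmetry_axis(structure)
    elif mode == "principal":
        axis = _principal_axis(structure)
    else:
        raise ValueError(f"unknown alignment mode {mode!r}")

    rotation = _rotation_to_z(axis)
    centroid = structure.positions.mean(axis=0)
    aligned = structure.transformed(rotation, -rotation @ centroid)

    if mode == "manual":
        anchor = None  # manual_spec already fixes the orientation
    else:
        anchor = detect_filter_anchor(aligned)
    if anchor is not None:
        if anchor < aligned.positions[:, 2].mean():
            aligned = aligned.transformed(_FLIP_X, np.zeros(3))
    elif mode != "manual":
        logger.warning(
            "no selectivity-filter anchor found; cytosolic/extracellular "
            "orientation left as inferred by %s mode", mode,
        )
    # re-center the axis on x = y = 0 using the aligned centroid
    c = aligned.positions.mean(axis=0)
    aligned = aligned.transformed(np.eye(3), np.array([-c[0], -c[1], 0.0]))
    aligned.axis_aligned = True
    return aligned
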