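"""Synthetic channel fixtures with analytically known pore geometry.

A fixture is a stack of atom rings along +z.  At each plane the inner ring
sits at the lumen radius R(z) (piecewise-linear in z) and further rings
fill a sealing "washer" out to ``wall_radius``, so the only route from the
bottom of the grid to the top is through the lumen.  Ring atoms are spaced
closer than their own vdW radius, which makes the scalloped gaps between
neighbors shallower than the on-axis clearance; the widest seed->target
path therefore runs along the axis and its exact value is

    b = min over planes of ( R(z) - r_atom ).

``closed`` fixtures additionally fill one plane wall-to-wall (b = 0).
Each fixture plants a T-V-G-Y-G residue signature on its five topmost
planes so selectivity-filter anchoring and target defaulting can be
exercised end to end.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import numpy as np

from .accessibility import GridSpec
from .errors import FixtureSpecError
from .structure_model import BONDI_RADII, ChannelStructure, write_structure

_CHAIN_IDS = ("A", "B", "C", "D")
_FILTER_NAMES = ("THR", "VAL", "GLY", "TYR", "GLY")  # ascending z


@dataclass
class FixtureSpec:
    """Parameters of a ring-stack fixture.

    ``control_points`` are (z, R) pairs in Å defining the lumen radius
    profile by linear interpolation.  ``kind`` is one of ``cylinder``,
    ``hourglass``, ``closed`` (the kind is descriptive except for
    ``closed``, which inserts a wall-to-wall cap plane).
    """

    kind: str
    control_points: list            # [(z, R), ...]
    atom_element: str = "O"
    atoms_per_ring: int = 24
    ring_spacing: float = 1.4
    wall_radius: Optional[float] = None
    label: str = "fixture"

    def __post_init__(self) -> None:
        if self.kind not in ("cylinder", "hourglass", "closed"):
            raise FixtureSpecError(f"unknown fixture kind {self.kind!r}")
        if self.atoms_per_ring < 12:
            raise FixtureSpecError("atoms_per_ring must be >= 12")
        pts = sorted((float(z), float(r)) for z, r in self.control_points)
        if len(pts) < 2:
            raise FixtureSpecError("need at least two control points")
        if any(r <= 0 for _, r in pts):
            raise FixtureSpecError("lumen radii must be positive")
        self.control_points = pts
        r_atom = self.atom_radius
        if self.ring_spacing <= 0 or self.ring_spacing > 1.1 * r_atom:
            raise FixtureSpecError(
                f"ring_spacing must be in (0, {1.1 * r_atom:.2f}] Å to keep "
                f"the wall sealed for a {r_atom:.2f} Å atom"
            )
        if self.length < 4 * self.ring_spacing:
            raise FixtureSpecError("fixture length must be >= 4 ring spacings")

    @property
    def atom_radius(self) -> float:
        try:
            return BONDI_RADII[self.atom_element.upper()]
        except KeyError:
            raise FixtureSpecError(f"no vdW radius for element {self.atom_element!r}")

    @property
    def length(self) -> float:
        return self.control_points[-1][0] - self.control_points[0][0]

    def lumen_radius(self, z: float) -> float:
        zs = [p[0] for p in self.control_points]
        rs = [p[1] for p in self.control_points]
        return float(np.interp(z, zs, rs))


@dataclass
class Fixture:
    """A generated fixture with its analytic ground truth."""

    spec: FixtureSpec
    structure: ChannelStructure
    analytic_bottleneck: float      # Å; exact widest-path value of the lumen
    anchor_z: float                 # planted selectivity-filter anchor
    target_z: float                 # default inner-cavity target depth
    grid: GridSpec                  # confinement matched to the wall radius


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Generate the atom stack and its exact analytic bottleneck value."""
    r_atom = spec.atom_radius
    step = min(spec.ring_spacing, 0.9 * r_atom)  # radial & arc pitch
    z_lo = spec.control_points[0][0]
    z_hi = spec.control_points[-1][0]
    n_planes = int(math.floor((z_hi - z_lo) / spec.ring_spacing)) + 1
    plane_z = z_lo + spec.ring_spacing * np.arange(n_planes)
    wall = spec.wall_radius
    if wall is None:
        wall = max(r for _, r in spec.control_points) + 3.0

    anchor_z = float(plane_z[-5]) if n_planes >= 5 else float(plane_z[-1])
    target_z = anchor_z - 5.0
    cap_plane = None
    if spec.kind == "closed":
        # the cap must sit cytosolic of the default target so every
        # seed->target path crosses it
        cap_plane = int(np.argmin(np.abs(plane_z - (target_z - 3.0))))

    elements, positions, chain_ids = [], [], []
    res_names, res_numbers, atom_names = [], [], []

    bottleneck = math.inf
    for plane_idx, z in enumerate(plane_z):
        res_name = "GLY"
        if n_planes >= 5 and plane_idx >= n_planes - 5:
            res_name = _FILTER_NAMES[plane_idx - (n_planes - 5)]
        inner = spec.lumen_radius(z)
        if cap_plane is not None and plane_idx == cap_plane:
            radii = np.concatenate(([0.0], np.arange(step, wall + 1e-9, step)))
            bottleneck = 0.0
        else:
            radii = np.arange(inner, wall + 1e-9, step)
            if wall - radii[-1] > 1e-6:
                radii = np.append(radii, wall)
            bottleneck = min(bottleneck, inner - r_atom)
        for ring_idx, rho in enumerate(radii):
            if rho < 1e-9:
                n = 1
            else:
                n = max(spec.atoms_per_ring, int(math.ceil(2 * math.pi * rho / step)))
                n = 4 * ((n + 3) // 4)  # multiple of 4: chains are exact 90° copies
            offset = 2 * math.pi * (0.13 * plane_idx + 0.31 * ring_idx)
            for j in range(n):
                angle = offset + 2 * math.pi * j / n
                elements.append(spec.atom_element.upper())
                positions.append((rho * math.cos(angle), rho * math.sin(angle), float(z)))
                chain_ids.append(_CHAIN_IDS[(4 * j) // n] if n > 1 else "A")
                res_names.append(res_name)
                res_numbers.append(plane_idx + 1)
                atom_names.append("O")

    n_atoms = len(positions)
    structure = ChannelStructure(
        elements=np.array(elements, dtype=object),
        positions=np.array(positions, dtype=np.float64),
        chain_ids=np.array(chain_ids, dtype=object),
        residue_names=np.array(res_names, dtype=object),
        residue_numbers=np.array(res_numbers, dtype=np.int64),
        hetero=np.zeros(n_atoms, dtype=bool),
        atom_names=np.array(atom_names, dtype=object),
        vdw_radii=np.full(n_atoms, r_atom),
        source_id=spec.label,
        axis_aligned=True,
    )
    grid = GridSpec(cylinder_radius=float(wall))
    return Fixture(
        spec=spec,
        structure=structure,
        analytic_bottleneck=float(max(bottleneck, 0.0)),
        anchor_z=anchor_z,
        target_z=target_z,
        grid=grid,
    )


def write_fixture_pdb(structure: ChannelStructure, path) -> None:
    """Write a fixture as fixed-format PDB (deterministic byte output)."""
    write_structure(structure, path)


def cylinder_spec(bottleneck: float, label: Optional[str] = None,
                  length: float = 20.0, element: str = "O") -> FixtureSpec:
    """Cylinder whose analytic bottleneck is exactly ``bottleneck`` Å."""
    r_atom = BONDI_RADII[element.upper()]
    ring_r = bottleneck + r_atom
    half = length / 2.0
    return FixtureSpec(
        kind="cylinder",
        control_points=[(-half, ring_r), (half, ring_r)],
        atom_element=element,
        label=label or f"cyl_b{bottleneck:g}",
    )


def hourglass_spec(waist_bottleneck: float = 3.0, mouth_radius: float = 8.0,
                   waist_z: float = -4.4, label: str = "hourglass") -> FixtureSpec:
    # default waist_z sits exactly on a ring plane (z = -10 + 4 * 1.4) so the
    # analytic bottleneck equals waist_bottleneck exactly
    r_atom = BONDI_RADII["O"]
    waist_r = waist_bottleneck + r_atom
    return FixtureSpec(
        kind="hourglass",
        control_points=[(-10.0, mouth_radius), (waist_z, waist_r), (10.0, mouth_radius)],
        label=label,
    )


def closed_spec(lumen_radius: float = 8.0, label: str = "closed") -> FixtureSpec:
    return FixtureSpec(
        kind="closed",
        control_points=[(-10.0, lumen_radius), (10.0, lumen_radius)],
        label=label,
    )


STANDARD_SUITE_BOTTLENECKS = (2.0, 3.5, 5.0, 6.5)


def standard_suite() -> list[FixtureSpec]:
    """Cylinders with bottlenecks 2.0/3.5/5.0/6.5 Å, an hourglass, a closed tube."""
    specs = [cylinder_spec(b) for b in STANDARD_SUITE_BOTTLENECKS]
    specs.append(hourglass_spec())
    specs.append(closed_spec())
    return specs


def write_fixture_suite(out_dir) -> dict:
    """Write the standard fixture suite plus a JSON manifest; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"fixtures": []}
    for spec in standard_suite():
        fixture = make_fixture(spec)
        filename = f"{spec.label}.pdb"
        write_fixture_pdb(fixture.structure, out_dir / filename)
        manifest["fixtures"].append({
            "label": spec.label,
            "file": filename,
            "kind": spec.kind,
            "analytic_bottleneck": fixture.analytic_bottleneck,
            "anchor_z": fixture.anchor_z,
            "target_z": fixture.target_z,
            "n_atoms": fixture.structure.n_atoms,
            "grid": {
                "spacing": fixture.grid.spacing,
                "padding": fixture.grid.padding,
                "cylinder_radius": fixture.grid.cylinder_radius,
            },
        })
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
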