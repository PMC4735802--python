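"""Cubic-grid clearance field and probe-passage connectivity.

The clearance at a lattice point is the largest probe radius whose center
can sit there without overlapping any atom's van der Waals sphere:

    c(x) = min_i ( ||x - x_i|| - r_i )

clamped below at -spacing (only the sign matters inside atoms) and above at
``clearance_cap`` (only radii up to the search maximum matter).  A probe of
radius r "fits" at a lattice point iff c >= r; it "passes" from a seed
region to a target region iff a connected component of fitting points
(26-neighbor connectivity by default) touches both.  The flood fill is
confined to a cylinder about the pore axis so that it cannot detour around
the protein exterior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import EmptySelectionError, GridError, RegionError
from .structure_model import ChannelStructure

logger = logging.getLogger(__name__)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT_6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class GridSpec:
    """Geometry of the cubic clearance lattice.

    ``cylinder_radius`` is the lateral confinement about the pore axis
    (x = y = 0 after alignment); ``clearance_cap`` bounds stored clearance
    values from above and must exceed the largest probe radius searched.
    """

    spacing: float = 0.25
    padding: float = 6.0
    cylinder_radius: float = 15.0
    clearance_cap: float = 14.0
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise GridError(f"spacing must be positive, got {self.spacing}")
        if not 0.2 <= self.spacing <= 0.5:
            logger.warning(
                "grid spacing %.3g Å outside the recommended 0.2–0.5 Å range",
                self.spacing,
            )
        if self.padding <= 0 or self.cylinder_radius <= 0:
            raise GridError("padding and cylinder_radius must be positive")
        if self.connectivity not in (6, 26):
            raise GridError("connectivity must be 6 or 26")

    @property
    def structuring_element(self) -> np.ndarray:
        return _STRUCT_26 if self.connectivity == 26 else _STRUCT_6


@dataclass
class ClearanceField:
    """Clearance values on a cubic lattice, plus the confinement mask."""

    spec: GridSpec
    origin: np.ndarray          # (3,) Å, coordinates of lattice index (0,0,0)
    values: np.ndarray          # (nx, ny, nz) float32, Å
    in_cylinder: np.ndarray     # (nx, ny, nz) bool

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def axis_coords(self, axis: int) -> np.ndarray:
        n = self.values.shape[axis]
        return self.origin[axis] + self.spec.spacing * np.arange(n)

    @property
    def axis_z_range(self) -> tuple[float, float]:
        z = self.axis_coords(2)
        return float(z[0]), float(z[-1])

    def point_index(self, point) -> tuple[int, int, int]:
        """Index of the lattice point nearest to a Cartesian point."""
        idx = np.rint((np.asarray(point, dtype=float) - self.origin) / self.spec.spacing)
        idx = np.clip(idx, 0, np.array(self.values.shape) - 1)
        return tuple(int(i) for i in idx)

    def max_clearance(self) -> float:
        inside = self.values[self.in_cylinder]
        return float(inside.max()) if inside.size else 0.0


@dataclass
class RegionSpec:
    """Seed/target region on the lattice.

    ``boundary_slab``: all points with z <= ``z_max`` within ``cap_radius``
    of the axis (the cytosolic bulk face).  ``axis_sphere``: points within
    ``radius`` of the on-axis point (0, 0, ``z_center``).
    """

    kind: str
    z_max: Optional[float] = None       # boundary_slab
    cap_radius: Optional[float] = None  # boundary_slab
    z_center: Optional[float] = None    # axis_sphere
    radius: float = 1.0                 # axis_sphere

    def __post_init__(self) -> None:
        if self.kind not in ("boundary_slab", "axis_sphere"):
            raise RegionError(f"unknown region kind {self.kind!r}")
        if self.kind == "boundary_slab" and self.z_max is None:
            raise RegionError("boundary_slab requires z_max")
        if self.kind == "axis_sphere" and self.z_center is None:
            raise RegionError("axis_sphere requires z_center")

    def mask(self, field: ClearanceField) -> np.ndarray:
        x = field.axis_coords(0)[:, None, None]
        y = field.axis_coords(1)[None, :, None]
        z = field.axis_coords(2)[None, None, :]
        if self.kind == "boundary_slab":
            cap = self.cap_radius if self.cap_radius is not None else field.spec.cylinder_radius
            m = (z <= self.z_max) & (x**2 + y**2 <= cap**2)
        else:
            r2 = (x**2 + y**2 + (z - self.z_center) ** 2)
            m = r2 <= self.radius**2
        m = np.broadcast_to(m, field.values.shape).copy()
        if not m.any():
            raise RegionError(f"region {self} does not intersect the grid")
        return m

    def to_dict(self) -> dict:
        d = {"kind": self.kind}
        if self.kind == "boundary_slab":
            d.update(z_max=self.z_max, cap_radius=self.cap_radius)
        else:
            d.update(z_center=self.z_center, radius=self.radius)
        return d


def default_seed(field: ClearanceField) -> RegionSpec:
    """Cytosolic boundary slab: the bottom two lattice planes of the grid."""
    z0 = field.origin[2]
    return RegionSpec(
        kind="boundary_slab",
        z_max=float(z0 + 1.01 * field.spec.spacing),
        cap_radius=field.spec.cylinder_radius,
    )


def default_target(filter_anchor_z: float, depth_below_filter: float = 5.0) -> RegionSpec:
    """Inner-cavity target: 1 Å axis sphere a fixed depth cytosolic of the
    selectivity-filter anchor."""
    return RegionSpec(kind="axis_sphere", z_center=filter_anchor_z - depth_below_filter, radius=1.0)


def _clearance_chunk(
    points: np.ndarray,
    tree: cKDTree,
    radii: np.ndarray,
    r_max_vdw: float,
    k: int,
) -> np.ndarray:
    """Exact min_i(d_i - r_i) for a chunk of query points.

    k-nearest neighbors suffice unless an atom beyond the k-th neighbor
    could still win, i.e. when the candidate minimum exceeds
    d_k - r_max_vdw; those rare points are finished with a ball query.
    """
    n_atoms = len(radii)
    k = min(k, n_atoms)
    dist, idx = tree.query(points, k=k)
    if k == 1:
        dist = dist[:, None]
        idx = idx[:, None]
    clear = (dist - radii[idx]).min(axis=1)
    if k < n_atoms:
        unresolved = np.nonzero(clear > dist[:, -1] - r_max_vdw)[0]
        for i in unresolved:
            neighbors = tree.query_ball_point(points[i], float(clear[i]) + r_max_vdw)
            if neighbors:
                d = np.linalg.norm(tree.data[neighbors] - points[i], axis=1)
                clear[i] = min(clear[i], float((d - radii[neighbors]).min()))
    return clear


def build_clearance_field(
    structure: ChannelStructure,
    spec: Optional[GridSpec] = None,
    chunk_size: int = 262144,
    k_neighbors: int = 24,
) -> ClearanceField:
    """Compute the clearance field of an aligned, radius-assigned structure.

    The lattice covers the atom bounding box plus ``spec.padding``,
    restricted laterally to ``spec.cylinder_radius`` about the z axis.
    Deterministic for fixed input.
    """
    spec = spec if spec is not None else GridSpec()
    if len(structure) == 0:
        raise EmptySelectionError("cannot build a clearance field for an empty structure")
    if structure.vdw_radii is None:
        raise GridError("structure has no vdW radii; call assign_radii first")
    if not structure.axis_aligned:
        logger.warning("structure is not axis-aligned; cylinder confinement assumes +z pore axis")

    pos = structure.positions
    radii = structure.vdw_radii
    lo = pos.min(axis=0) - spec.padding
    hi = pos.max(axis=0) + spec.padding
    # lateral extent never needs to exceed the confinement cylinder
    lo[:2] = np.maximum(lo[:2], -spec.cylinder_radius - spec.spacing)
    hi[:2] = np.minimum(hi[:2], spec.cylinder_radius + spec.spacing)
    if np.any(hi <= lo):
        raise GridError("degenerate grid extent")

    counts = np.floor((hi - lo) / spec.spacing).astype(int) + 1
    origin = lo
    axes = [origin[d] + spec.spacing * np.arange(counts[d]) for d in range(3)]
    shape = tuple(counts)

    tree = cKDTree(pos)
    r_max_vdw = float(radii.max())
    values = np.empty(shape, dtype=np.float32)

    xx, yy = np.meshgrid(axes[0], axes[1], indexing="ij")
    in_cyl_2d = (xx**2 + yy**2) <= spec.cylinder_radius**2
    in_cylinder = np.broadcast_to(in_cyl_2d[:, :, None], shape).copy()

    grid_pts = np.stack(
        np.meshgrid(axes[0], axes[1], axes[2], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    flat = values.reshape(-1)
    for start in range(0, len(grid_pts), chunk_size):
        chunk = grid_pts[start:start + chunk_size]
        flat[start:start + chunk_size] = _clearance_chunk(
            chunk, tree, radii, r_max_vdw, k_neighbors
        )
    np.clip(values, -spec.spacing, spec.clearance_cap, out=values)
    return ClearanceField(spec=spec, origin=np.asarray(origin, dtype=float),
                          values=values, in_cylinder=in_cylinder)


@dataclass
class CavityHandle:
    """Reachable-region handle produced by :func:`probe_passes`."""

    field: ClearanceField
    r_probe: float
    visited: np.ndarray     # bool, lattice points reachable from the seed
    passed: bool
    reason: str = ""


def _connected_masks(field: ClearanceField, universe: np.ndarray,
                     seed_mask: np.ndarray, target_mask: np.ndarray):
    """Label the universe and test whether any component meets both masks.

    Returns (passed, visited) where visited is the union of seed-connected
    components.
    """
    labels, n = ndimage.label(universe, structure=field.spec.structuring_element)
    seed_labels = np.unique(labels[seed_mask & universe])
    seed_labels = seed_labels[seed_labels != 0]
    if seed_labels.size == 0:
        return False, np.zeros_like(universe)
    visited = np.isin(labels, seed_labels)
    passed = bool((visited & target_mask).any())
    return passed, visited


def probe_passes(
    field: ClearanceField,
    r_probe: float,
    seed: RegionSpec,
    target: RegionSpec,
) -> tuple[bool, CavityHandle]:
    """True iff a probe of radius ``r_probe`` can travel from seed to target.

    A connected component of lattice points with clearance >= r_probe
    (within the confinement cylinder) must intersect both regions.
    """
    if r_probe <= 0:
        raise RegionError(f"probe radius must be positive, got {r_probe}")
    seed_mask = seed.mask(field)
    target_mask = target.mask(field)
    universe = (field.values >= r_probe) & field.in_cylinder
    if not (seed_mask & universe).any():
        logger.info("probe %.2f Å: seed region fully blocked", r_probe)
        handle = CavityHandle(field, r_probe, np.zeros_like(universe), False, "seed blocked")
        return False, handle
    passed, visited = _connected_masks(field, universe, seed_mask, target_mask)
    reason = "" if passed else "no path"
    if not passed:
        logger.info("probe %.2f Å: seed accessible but no path to target", r_probe)
    return passed, CavityHandle(field, r_probe, visited, passed, reason)


@dataclass
class BottleneckResult:
    """Widest-path value from seed to target, with censoring flag."""

    value: float
    reachable: bool


def maximin_bottleneck(
    field: ClearanceField,
    seed: RegionSpec,
    target: RegionSpec,
) -> BottleneckResult:
    """Max over seed→target lattice paths of the min clearance en route.

    Equals the supremum of r for which :func:`probe_passes` is true,
    exactly on the lattice.  Computed by bisection over the sorted distinct
    clearance values (connectivity at threshold t is monotone in t).
    Returns 0 with ``reachable=False`` when the target cannot be reached at
    any positive clearance.
    """
    seed_mask = seed.mask(field)
    target_mask = target.mask(field)
    base = field.in_cylinder & (field.values > 0)

    def connected_at(t: float) -> bool:
        universe = base & (field.values >= t)
        passed, _ = _connected_masks(field, universe, seed_mask, target_mask)
        return passed

    candidates = np.unique(field.values[base])
    candidates = candidates[candidates > 0]
    if candidates.size == 0 or not connected_at(float(candidates[0])):
        return BottleneckResult(0.0, False)
    lo, hi = 0, candidates.size - 1  # connected_at(candidates[lo]) is True
    if connected_at(float(candidates[hi])):
        return BottleneckResult(float(candidates[hi]), True)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if connected_at(float(candidates[mid])):
            lo = mid
        else:
            hi = mid
    return BottleneckResult(float(candidates[lo]), True)


def export_cavity_pdb(handle: CavityHandle, path) -> int:
    """Write the reachable lattice points as HETATM oxygen pseudo-atoms.

    Residue name CAV, occupancy 1.00, B-factor = clearance; ordered by
    lattice index so re-export is byte-identical.  Returns the number of
    pseudo-atoms written.
    """
    field = handle.field
    idx = np.argwhere(handle.visited)
    if idx.size == 0:
        logger.warning("cavity export: no reachable lattice points at r=%.2f Å", handle.r_probe)
    coords = field.origin + idx * field.spec.spacing
    bvals = field.values[tuple(idx.T)] if idx.size else np.empty(0)
    lines = []
    for n, (xyz, b) in enumerate(zip(coords, bvals), start=1):
        serial = n % 100000
        resid = ((n - 1) // 4 + 1) % 10000
        lines.append(
            f"HETATM{serial:5d}  O   CAV A{resid:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{min(float(b), 99.99):6.2f}"
            f"          {'O':>2s}\n"
        )
    lines.append("END\n")
    with open(path, "w") as fh:
        fh.writelines(lines)
    return len(idx)
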