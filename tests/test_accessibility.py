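"""Clearance-field construction, probe passage and widest-path search."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from channelpore.accessibility import (
    GridSpec,
    RegionSpec,
    build_clearance_field,
    default_seed,
    default_target,
    export_cavity_pdb,
    maximin_bottleneck,
    probe_passes,
)
from channelpore.errors import EmptySelectionError, GridError, RegionError
from channelpore.structure_model import ChannelStructure


def _atoms(positions, radii, element="O"):
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    return ChannelStructure(
        elements=np.array([element] * n, dtype=object),
        positions=positions,
        chain_ids=np.array(["A"] * n, dtype=object),
        residue_names=np.array(["GLY"] * n, dtype=object),
        residue_numbers=np.arange(1, n + 1),
        hetero=np.zeros(n, dtype=bool),
        atom_names=np.array([element] * n, dtype=object),
        vdw_radii=np.asarray(radii, dtype=float),
        source_id="ad-hoc",
        axis_aligned=True,
    )


class TestGridSpec:
    def test_bad_spacing(self):
        with pytest.raises(GridError):
            GridSpec(spacing=0.0)

    def test_out_of_band_spacing_warns_not_raises(self, caplog):
        GridSpec(spacing=0.6)  # allowed with a warning

    def test_bad_connectivity(self):
        with pytest.raises(GridError):
            GridSpec(connectivity=18)


class TestClearanceField:
    def test_single_atom_clearance_definition(self):
        s = _atoms([[0.0, 0.0, 0.0]], [1.5])
        spec = GridSpec(spacing=0.25, padding=6.0, cylinder_radius=6.0)
        field = build_clearance_field(s, spec)
        idx = field.point_index([4.0, 0.0, 0.0])
        point = field.origin + np.array(idx) * spec.spacing
        expected = np.linalg.norm(point) - 1.5
        assert field.values[idx] == pytest.approx(expected, abs=1e-5)

    def test_clamped_at_atom_center(self):
        s = _atoms([[0.0, 0.0, 0.0]], [1.5])
        spec = GridSpec(spacing=0.25, padding=4.0, cylinder_radius=5.0)
        field = build_clearance_field(s, spec)
        idx = field.point_index([0.0, 0.0, 0.0])
        assert field.values[idx] == pytest.approx(-spec.spacing)

    def test_ring_on_axis_clearance(self):
        # 24 oxygen-radius atoms on a ring of radius 8: on-axis clearance 6.48
        angles = 2 * np.pi * np.arange(24) / 24
        pos = np.stack([8 * np.cos(angles), 8 * np.sin(angles), np.zeros(24)], axis=1)
        field = build_clearance_field(
            _atoms(pos, [1.52] * 24), GridSpec(spacing=0.25, padding=4.0, cylinder_radius=10.0)
        )
        idx = field.point_index([0.0, 0.0, 0.0])
        assert field.values[idx] == pytest.approx(6.48, abs=0.25)

    def test_empty_structure_errors(self):
        s = _atoms([[0.0, 0.0, 0.0]], [1.5]).subset(np.zeros(1, dtype=bool))
        with pytest.raises(EmptySelectionError):
            build_clearance_field(s, GridSpec())

    def test_missing_radii_errors(self):
        s = _atoms([[0.0, 0.0, 0.0]], [1.5])
        s.vdw_radii = None
        with pytest.raises(GridError):
            build_clearance_field(s, GridSpec())

    def test_lipschitz_along_lattice(self, cyl20_bundle):
        field = cyl20_bundle["field"]
        spacing = field.spec.spacing
        v = field.values
        for axis in range(3):
            diff = np.abs(np.diff(v, axis=axis))
            assert float(diff.max()) <= spacing + 1e-5

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000_000), st.integers(0, 10_000_000))
    def test_lipschitz_random_pairs(self, cyl20_bundle, i, j):
        field = cyl20_bundle["field"]
        flat = field.values.reshape(-1)
        a, b = i % flat.size, j % flat.size
        ia = np.unravel_index(a, field.values.shape)
        ib = np.unravel_index(b, field.values.shape)
        dist = np.linalg.norm((np.array(ia) - np.array(ib)) * field.spec.spacing)
        assert abs(float(flat[a]) - float(flat[b])) <= dist + 1e-4


class TestRegions:
    def test_unknown_kind(self):
        with pytest.raises(RegionError):
            RegionSpec(kind="blob")

    def test_sphere_off_grid(self, cyl20_bundle):
        field = cyl20_bundle["field"]
        region = RegionSpec(kind="axis_sphere", z_center=1e4, radius=1.0)
        with pytest.raises(RegionError):
            region.mask(field)


class TestProbePasses:
    def test_open_cylinder_pass_and_block(self, cyl65_bundle):
        b = cyl65_bundle
        ok, _ = probe_passes(b["field"], 5.0, b["seed"], b["target"])
        assert ok
        ok, _ = probe_passes(b["field"], 7.0, b["seed"], b["target"])
        assert not ok

    def test_probe_larger_than_any_clearance(self, cyl20_bundle):
        b = cyl20_bundle
        huge = b["field"].max_clearance() + 1.0
        ok, handle = probe_passes(b["field"], huge, b["seed"], b["target"])
        assert not ok
        assert handle.reason == "seed blocked"

    def test_monotone_over_radius_ladder(self, hourglass_bundle):
        b = hourglass_bundle
        results = [probe_passes(b["field"], r, b["seed"], b["target"])[0]
                   for r in np.arange(0.5, 7.1, 0.5)]
        # all passes precede all failures
        assert results == sorted(results, reverse=True)

    def test_nonpositive_probe(self, cyl20_bundle):
        b = cyl20_bundle
        with pytest.raises(RegionError):
            probe_passes(b["field"], 0.0, b["seed"], b["target"])


class TestMaximinBottleneck:
    def test_open_cylinder_value(self, cyl65_bundle):
        b = cyl65_bundle
        bn = maximin_bottleneck(b["field"], b["seed"], b["target"])
        assert bn.reachable
        assert bn.value == pytest.approx(6.5, abs=b["field"].spec.spacing)

    def test_blocked_fixture_censored(self, closed_bundle):
        b = closed_bundle
        bn = maximin_bottleneck(b["field"], b["seed"], b["target"])
        assert bn.value == 0.0
        assert not bn.reachable

    @pytest.mark.parametrize("bundle_name", ["cyl65_bundle", "hourglass_bundle"])
    def test_consistency_with_probe_passes(self, bundle_name, request):
        b = request.getfixturevalue(bundle_name)
        bn = maximin_bottleneck(b["field"], b["seed"], b["target"])
        spacing = b["field"].spec.spacing
        assert probe_passes(b["field"], bn.value - spacing, b["seed"], b["target"])[0]
        assert not probe_passes(b["field"], bn.value + spacing, b["seed"], b["target"])[0]
        # the lattice-exact value itself passes
        assert probe_passes(b["field"], bn.value, b["seed"], b["target"])[0]


def _bfs_reachable(universe, seed_mask, connectivity):
    """Independent oracle: plain breadth-first search over lattice points."""
    from collections import deque

    if connectivity == 26:
        neighbors = [(i, j, k)
                     for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
                     if (i, j, k) != (0, 0, 0)]
    else:
        neighbors = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    shape = universe.shape
    visited = np.zeros(shape, dtype=bool)
    queue = deque(map(tuple, np.argwhere(universe & seed_mask)))
    for p in queue:
        visited[p] = True
    while queue:
        x, y, z = queue.popleft()
        for dx, dy, dz in neighbors:
            q = (x + dx, y + dy, z + dz)
            if (0 <= q[0] < shape[0] and 0 <= q[1] < shape[1] and 0 <= q[2] < shape[2]
                    and universe[q] and not visited[q]):
                visited[q] = True
                queue.append(q)
    return visited


class TestFloodFillOracle:
    @pytest.mark.parametrize("connectivity", [6, 26])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bfs_on_small_grids(self, connectivity, seed):
        # random blocked/open universes on <= 20^3 grids
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(6, 20, size=3))
        universe = rng.random(shape) < 0.55
        seed_mask = np.zeros(shape, dtype=bool)
        seed_mask[0, :, :] = True
        from scipy import ndimage
        struct = np.ones((3, 3, 3), bool) if connectivity == 26 else \
            ndimage.generate_binary_structure(3, 1)
        labels, _ = ndimage.label(universe, structure=struct)
        seed_labels = np.unique(labels[seed_mask & universe])
        seed_labels = seed_labels[seed_labels != 0]
        flood = np.isin(labels, seed_labels)
        bfs = _bfs_reachable(universe, seed_mask, connectivity)
        np.testing.assert_array_equal(flood, bfs)


class TestCavityExport:
    def test_pseudo_atom_count_matches_visited(self, tmp_path, cyl65_bundle):
        b = cyl65_bundle
        ok, handle = probe_passes(b["field"], 5.0, b["seed"], b["target"])
        assert ok
        path = tmp_path / "cavity.pdb"
        n = export_cavity_pdb(handle, path)
        assert n == int(handle.visited.sum())
        text = path.read_text()
        assert text.count("HETATM") == n
        assert "CAV" in text

    def test_blocked_export_is_empty(self, tmp_path, closed_bundle):
        b = closed_bundle
        _, handle = probe_passes(b["field"], 2.0, b["seed"], b["target"])
        # seed side is reachable but we export only when asked; count matches
        path = tmp_path / "cavity.pdb"
        n = export_cavity_pdb(handle, path)
        assert n == int(handle.visited.sum())

    def test_re_export_byte_identical(self, tmp_path, cyl65_bundle):
        b = cyl65_bundle
        _, handle = probe_passes(b["field"], 5.0, b["seed"], b["target"])
        p1, p2 = tmp_path / "c1.pdb", tmp_path / "c2.pdb"
        export_cavity_pdb(handle, p1)
        export_cavity_pdb(handle, p2)
        assert p1.read_bytes() == p2.read_bytes()
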