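"""Equivolume layering: SDF oracles, closed-form boundaries, volume fractions."""

import numpy as np
import pytest
import trimesh

from conftest import analytic_sdfs
from laminar.grid import Grid
from laminar.layering import (LevelSet, compute_sdf, equivolume_surfaces,
                              layer_volume_distribution)
from laminar.phantom import PhantomSpec, make_cortical_phantom


def _point_triangle_distance(p, a, b, c):
    """Exact distance from point to one triangle (Ericson's regions)."""
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return np.linalg.norm(ap)
    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return np.linalg.norm(bp)
    vc = d1 * d4 - d3 * d2
    if vc <= 0 <= d1 and d3 <= 0:
        v = d1 / (d1 - d3)
        return np.linalg.norm(p - (a + v * ab))
    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return np.linalg.norm(cp)
    vb = d5 * d2 - d1 * d6
    if vb <= 0 <= d2 and d6 <= 0:
        w = d2 / (d2 - d6)
        return np.linalg.norm(p - (a + w * ac))
    va = d3 * d6 - d5 * d4
    if va <= 0 and d4 - d3 >= 0 and d5 - d6 >= 0:
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return np.linalg.norm(p - (b + w * (c - b)))
    denom = 1.0 / (va + vb + vc)
    v, w = vb * denom, vc * denom
    return np.linalg.norm(p - (a + ab * v + ac * w))


class TestComputeSDF:
    def test_plane_distance_and_on_surface_zero(self):
        spec = PhantomSpec(shape="flat-slab", wm_radius_mm=0.0, pial_radius_mm=2.4,
                           grid_shape=(6, 6, 6), origin_mm=(-2.4, -2.4, -2.4))
        surfaces, _, _ = make_cortical_phantom(spec)
        grid = spec.make_grid()
        sdf = compute_sdf(surfaces.wm, grid)
        centers = grid.voxel_centers()[:, 2].reshape(grid.shape)
        np.testing.assert_allclose(sdf, centers, atol=1e-9)
        vertex = np.asarray(surfaces.wm.vertices)[50]
        g = Grid(shape=(1, 1, 1), voxel_size_mm=1.0,
                 origin_mm=tuple(vertex - 0.5))
        assert abs(compute_sdf(surfaces.wm, g)[0, 0, 0]) < 1e-9

    def test_matches_brute_force_nearest_triangle(self):
        mesh = trimesh.creation.icosphere(subdivisions=2, radius=2.0)
        rng = np.random.default_rng(0)
        pts = rng.uniform(-3, 3, size=(200, 3))
        tris = np.asarray(mesh.triangles)
        for p in pts[:40]:  # brute force is O(points x faces)
            expected = min(_point_triangle_distance(p, *t) for t in tris)
            g = Grid(shape=(1, 1, 1), voxel_size_mm=1.0, origin_mm=tuple(p - 0.5))
            assert abs(abs(compute_sdf(mesh, g)[0, 0, 0]) - expected) < 1e-6

    def test_degenerate_triangles_rejected(self):
        bad = trimesh.Trimesh(vertices=[[0, 0, 0], [1, 0, 0], [2, 0, 0]],
                              faces=[[0, 1, 2]], process=False)
        with pytest.raises(ValueError, match="degenerate"):
            compute_sdf(bad, Grid(shape=(2, 2, 2)))


class TestEquivolumeSurfaces:
    def test_flat_slab_boundaries_equidistant(self, slab_phantom):
        _, _, truth = slab_phantom
        grid = truth.grid
        wm, pial = analytic_sdfs(truth)
        ls = equivolume_surfaces(wm, pial, grid)
        # zero curvature: boundary SDFs are linear interpolations at 1/3, 2/3
        for bi, f in ((1, 1 / 3), (2, 2 / 3)):
            expected = (1 - f) * wm + f * pial
            np.testing.assert_allclose(ls.boundaries[bi], expected, atol=1e-9)

    @pytest.mark.parametrize("fixture,closed_form", [
        ("cylinder_phantom", lambda rw, rp, f: np.sqrt((1 - f) * rw**2 + f * rp**2)),
        ("sphere_phantom", lambda rw, rp, f: ((1 - f) * rw**3 + f * rp**3) ** (1 / 3)),
    ])
    def test_curved_boundaries_match_closed_form(self, request, fixture, closed_form):
        _, _, truth = request.getfixturevalue(fixture)
        grid = truth.grid
        wm, pial = analytic_sdfs(truth)
        ls = equivolume_surfaces(wm, pial, grid)
        pts = grid.voxel_centers()
        r = (np.linalg.norm(pts, axis=1) if truth.spec.shape == "sphere-shell"
             else np.hypot(pts[:, 0], pts[:, 1])).reshape(grid.shape)
        for bi, f in ((1, 1 / 3), (2, 2 / 3)):
            expected = closed_form(truth.spec.wm_radius_mm, truth.spec.pial_radius_mm, f)
            b = ls.boundaries[bi]
            near = np.abs(b) < 0.5 * grid.voxel_size_mm
            # |grad SDF| ~ 1 radially, so r - b estimates the zero-crossing radius
            estimate = (r[near] - b[near]).mean()
            assert estimate == pytest.approx(expected, rel=0.01)

    def test_boundaries_are_depth_ordered(self, cylinder_phantom):
        _, _, truth = cylinder_phantom
        wm, pial = analytic_sdfs(truth)
        ls = equivolume_surfaces(wm, pial, truth.grid)
        assert np.all(np.diff(ls.boundaries, axis=0) <= 1e-9)

    def test_thin_ribbon_errors_with_location(self):
        grid = Grid(shape=(4, 4, 4), voxel_size_mm=0.8)
        pts = grid.voxel_centers()
        wm = pts[:, 2].reshape(grid.shape) - 1.0
        pial = pts[:, 2].reshape(grid.shape) - 1.4   # 0.4 mm ribbon < voxel
        with pytest.raises(ValueError, match="thinner"):
            equivolume_surfaces(wm, pial, grid)


class TestLayerVolumeDistribution:
    def test_single_compartment_and_half_split(self, slab_phantom):
        _, _, truth = slab_phantom
        grid = truth.grid
        wm, pial = analytic_sdfs(truth)
        ls = equivolume_surfaces(wm, pial, grid)
        lvm = layer_volume_distribution(ls, grid, subdivision=4)
        z = grid.voxel_centers()[:, 2]
        deep_wm_voxel = np.flatnonzero(z < -0.6)[0]
        np.testing.assert_allclose(lvm.fractions[deep_wm_voxel], [1, 0, 0, 0, 0],
                                   atol=1e-12)
        # slab boundaries sit at z = 0, 0.8, 1.6, 2.4; voxel centred at 0 is
        # bisected by the WM boundary
        split_voxel = np.flatnonzero(np.abs(z - 0.0) < 1e-9)[0]
        np.testing.assert_allclose(lvm.fractions[split_voxel], [0.5, 0.5, 0, 0, 0],
                                   atol=1e-12)

    def test_monte_carlo_oracle_on_curved_phantom(self, cylinder_phantom):
        _, _, truth = cylinder_phantom
        grid = truth.grid
        wm, pial = analytic_sdfs(truth)
        ls = equivolume_surfaces(wm, pial, grid)
        rng = np.random.default_rng(11)
        pts = grid.voxel_centers()
        band = np.flatnonzero((np.abs(wm.reshape(-1)) < 0.5))[:12]
        lvm = layer_volume_distribution(ls, grid, subdivision=4)
        from scipy import ndimage

        for flat in band:
            ijk = np.unravel_index(flat, grid.shape)
            samples = np.asarray(ijk) + rng.uniform(-0.5, 0.5, size=(100_000, 3))
            counts = np.zeros(5)
            cls = np.zeros(len(samples), dtype=int)
            for b in range(4):
                vals = ndimage.map_coordinates(ls.boundaries[b], samples.T, order=1,
                                               mode="nearest")
                cls += (vals >= 0).astype(int)
            counts = np.bincount(cls, minlength=5) / len(samples)
            np.testing.assert_allclose(lvm.fractions[flat], counts, atol=0.02)

    def test_deep_fraction_monotone_toward_pia(self, slab_phantom):
        _, _, truth = slab_phantom
        grid = truth.grid
        wm, pial = analytic_sdfs(truth)
        ls = equivolume_surfaces(wm, pial, grid)
        lvm = layer_volume_distribution(ls, grid, subdivision=4)
        deep = lvm.fractions[:, 1].reshape(grid.shape)
        gm_started = False
        col = deep[3, 3, :]
        peak = col.argmax()
        assert np.all(np.diff(col[peak:]) <= 1e-12)

    def test_subdivision_validation(self, slab_phantom):
        _, _, truth = slab_phantom
        wm, pial = analytic_sdfs(truth)
        ls = equivolume_surfaces(wm, pial, truth.grid)
        with pytest.raises(ValueError, match="subdivision"):
            layer_volume_distribution(ls, truth.grid, subdivision=1)


def test_volume_conservation_and_equal_layers(cylinder_phantom):
    _, _, truth = cylinder_phantom
    grid = truth.grid
    wm, pial = analytic_sdfs(truth)
    ls = equivolume_surfaces(wm, pial, grid)
    lvm = layer_volume_distribution(ls, grid, subdivision=4)
    analytic = truth.ribbon_volume_mm3()
    gm_total = lvm.fractions[:, 1:4].sum() * grid.voxel_volume_mm3
    assert gm_total == pytest.approx(analytic, rel=0.02)
    layer_vols = lvm.fractions[:, 1:4].sum(axis=0) * grid.voxel_volume_mm3
    np.testing.assert_allclose(layer_vols, analytic / 3, rtol=0.01)
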