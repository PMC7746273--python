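"""Boundary-based registration: cost properties and transform recovery."""

import numpy as np
import pytest

from laminar.grid import Grid
from laminar.registration import (AffineTransform7, _split_indices, bbr_cost,
                                  boundary_contrast, fit_bbr, median_displacement)


@pytest.fixture(scope="module")
def edge_phantom_factory():
    """Curved-sheet boundary with rich structure: WM below, GM above."""

    def surf(x, y):
        return (0.12 * x + 0.8 * np.sin(2 * np.pi * x / 12.8)
                + 0.5 * np.sin(2 * np.pi * x / 5.3 + 1.0)
                + 0.6 * np.sin(2 * np.pi * y / 10.0)
                + 0.4 * np.sin(2 * np.pi * y / 4.1 + 0.5))

    def dsurf(x, y):
        dx = (0.12 + 0.8 * 2 * np.pi / 12.8 * np.cos(2 * np.pi * x / 12.8)
              + 0.5 * 2 * np.pi / 5.3 * np.cos(2 * np.pi * x / 5.3 + 1.0))
        dy = (0.6 * 2 * np.pi / 10.0 * np.cos(2 * np.pi * y / 10.0)
              + 0.4 * 2 * np.pi / 4.1 * np.cos(2 * np.pi * y / 4.1 + 0.5))
        return dx, dy

    def make(voxel_size_mm=0.8):
        shape = tuple(int(round(s * 0.8 / voxel_size_mm)) for s in (32, 32, 20))
        grid = Grid.centered(shape, voxel_size_mm)
        pts = grid.voxel_centers()

        def volume(warp=lambda x, y: 0.0, scale_y=1.0):
            s = surf(pts[:, 0], pts[:, 1] / scale_y) + np.asarray(
                warp(pts[:, 0], pts[:, 1]))
            return (430 + 30.0 / (1 + np.exp(-(pts[:, 2] - s) / 0.5))).reshape(grid.shape)

        xs = np.linspace(-9, 9, 26)
        ys = np.linspace(-9, 9, 26)
        xx, yy = np.meshgrid(xs, ys, indexing="ij")
        verts = np.column_stack([xx.ravel(), yy.ravel(), surf(xx, yy).ravel()])
        dx, dy = dsurf(xx, yy)
        nrm = np.column_stack([-dx.ravel(), -dy.ravel(), np.ones(xx.size)])
        nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
        return grid, volume, verts, nrm

    return make


@pytest.fixture(scope="module")
def edge_phantom(edge_phantom_factory):
    return edge_phantom_factory(0.8)


@pytest.fixture(scope="module")
def fine_edge_phantom(edge_phantom_factory):
    """Half-voxel grid: interpolation artifacts in the cost are negligible."""
    return edge_phantom_factory(0.4)


class TestCost:
    def test_aligned_beats_shifted(self, edge_phantom):
        grid, volume, verts, nrm = edge_phantom
        vol = volume()
        ident = AffineTransform7(center_mm=tuple(verts.mean(0)))
        shifted = AffineTransform7(translation_mm=(0, 0, 1.6),
                                   center_mm=tuple(verts.mean(0)))
        assert bbr_cost(vol, grid, verts, nrm, ident) < bbr_cost(vol, grid, verts, nrm, shifted)

    def test_shift_correcting_transform_beats_identity(self, edge_phantom):
        grid, volume, verts, nrm = edge_phantom
        vol = volume(warp=lambda x, y: np.full_like(x, 1.6))
        ident = AffineTransform7(center_mm=tuple(verts.mean(0)))
        corrector = AffineTransform7(translation_mm=(0, 0, 1.6),
                                     center_mm=tuple(verts.mean(0)))
        assert bbr_cost(vol, grid, verts, nrm, corrector) < bbr_cost(vol, grid, verts, nrm, ident)

    def test_intensity_scale_invariance(self, edge_phantom):
        grid, volume, verts, nrm = edge_phantom
        vol = volume()
        t = AffineTransform7(translation_mm=(0.3, -0.2, 0.5),
                             center_mm=tuple(verts.mean(0)))
        assert bbr_cost(vol, grid, verts, nrm, t) == pytest.approx(
            bbr_cost(vol * 10, grid, verts, nrm, t), abs=1e-12)

    def test_out_of_volume_sampling_rejected(self, edge_phantom):
        grid, volume, verts, nrm = edge_phantom
        t = AffineTransform7(translation_mm=(100.0, 0, 0), center_mm=(0, 0, 0))
        with pytest.raises(ValueError, match="outside the volume"):
            bbr_cost(volume(), grid, verts, nrm, t)


class TestFit:
    def test_recovers_known_translation(self, edge_phantom):
        grid, volume, verts, nrm = edge_phantom
        vol = volume(warp=lambda x, y: np.full_like(x, 0.8))
        vol = np.roll(vol, 2, axis=0)  # +1.6 mm along x via grid shift
        res = fit_bbr(vol, grid, verts, nrm, maxfev=800)
        t = np.asarray(res.transform.translation_mm)
        # displacement recovery within 0.1 voxel on the constrained axes
        assert abs(t[0] - 1.6) < 0.08 and abs(t[2] - 0.8) < 0.08

    def test_recovers_phase_axis_scale(self, edge_phantom):
        grid, volume, verts, nrm = edge_phantom
        res = fit_bbr(volume(scale_y=1.03), grid, verts, nrm, maxfev=800)
        assert res.transform.phase_scale == pytest.approx(1.03, abs=0.005)

    def test_already_aligned_returns_near_identity(self, fine_edge_phantom):
        grid, volume, verts, nrm = fine_edge_phantom
        res = fit_bbr(volume(), grid, verts, nrm, maxfev=800)
        # near-identity in displacement space: a small translation trading
        # off against a small rotation is the sheet's soft mode, so the
        # per-vertex displacement is the meaningful null-registration metric
        disp = res.transform.apply(verts) - verts
        assert np.linalg.norm(disp, axis=1).max() < 0.06
        assert res.transform.phase_scale == pytest.approx(1.0, abs=0.005)


class TestRecursive:
    def test_equal_vertex_splits(self):
        rng = np.random.default_rng(0)
        subset = np.arange(101)
        a, b = _split_indices(subset, rng.normal(size=101))
        assert abs(len(a) - len(b)) <= 1
        assert np.array_equal(np.sort(np.concatenate([a, b])), subset)
        # ties broken deterministically by vertex index
        a2, b2 = _split_indices(subset, np.zeros(101))
        assert np.array_equal(a2, subset[:50])

    def test_median_robust_to_outlier_ordering(self):
        rng = np.random.default_rng(1)
        good = rng.normal(0, 0.01, size=(1, 200, 3)) + [[[0, 0, 0.8]]]
        per_ordering = np.repeat(good, 6, axis=0)
        clean = median_displacement(per_ordering)
        per_ordering[3] += 5.0  # one ordering latches onto the wrong edge
        robust = median_displacement(per_ordering)
        np.testing.assert_allclose(robust, clean, atol=1e-12)

    def test_homogeneous_displacement_matches_global(self, fine_edge_phantom):
        from laminar.registration import recursive_bbr

        grid, volume, verts, nrm = fine_edge_phantom
        vol = volume(warp=lambda x, y: np.full_like(x, 0.8))
        res = fit_bbr(vol, grid, verts, nrm, maxfev=800)
        global_disp = res.transform.apply(verts) - verts
        field = recursive_bbr(vol, grid, verts, nrm, n_iterations=2, n_orderings=2)
        diff = np.linalg.norm(field.displacement - global_disp, axis=1)
        assert np.median(diff) < 0.05
        assert field.contrast_recursive >= field.contrast_global - 0.05


def test_boundary_contrast_sign_convention(edge_phantom):
    grid, volume, verts, nrm = edge_phantom
    q = boundary_contrast(volume(), grid, verts, nrm)
    assert q.mean() > 0  # GM (outside) brighter than WM (inside)


def test_transform_roundtrip_and_validation():
    t = AffineTransform7(rotation_rad=(0.02, -0.01, 0.03), translation_mm=(1, 2, 3),
                         phase_scale=1.05, center_mm=(0.5, 0.5, 0.5))
    p = np.random.default_rng(0).normal(size=(10, 3))
    back = AffineTransform7.from_params(t.to_params(), t.phase_axis, t.center_mm)
    np.testing.assert_allclose(t.apply(p), back.apply(p), atol=1e-12)
    with pytest.raises(ValueError, match="positive"):
        AffineTransform7(phase_scale=0.0)
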