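"""Synthetic cortical ribbon phantoms with analytic ground truth.

A phantom stands in for a reconstructed cortical surface pair (pial and
white-matter boundary meshes) plus the functional voxel grid they are
registered to.  Four families of geometry are provided:

``flat-slab``
    Two parallel planes; zero curvature, so equivolume and equidistant
    layering coincide and every layering quantity has a trivial closed form.
``cylinder-annulus``
    Concentric cylinders; the cumulative grey-matter volume between radii
    grows with r^2, giving the closed-form equal-area boundary
    ``r_f = sqrt((1-f) r_wm^2 + f r_pial^2)`` for volume fraction ``f``
    measured from the white-matter surface.
``sphere-shell``
    Concentric spheres; volume grows with r^3 and
    ``r_f = ((1-f) r_wm^3 + f r_pial^3)^(1/3)``.
``folded-sheet``
    A sinusoidally folded slab with alternating gyral/sulcal curvature; no
    closed form, used for Monte-Carlo and qualitative checks.

Every phantom also carries a voxel-wise orientation-preference label map
(alternating 45/135 degree columns) so that downstream region-of-interest
selection has a recoverable answer, mimicking the interleaved orientation
columnar organisation that makes voxel-level orientation preference
detectable at sub-millimetre resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import trimesh

from .grid import Grid

PhantomShape = Literal["flat-slab", "folded-sheet", "cylinder-annulus", "sphere-shell"]

#: fixed compartment order used throughout the package
COMPARTMENTS = ("wm", "deep", "middle", "superficial", "csf")
GM_LAYERS = ("deep", "middle", "superficial")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic cortical ribbon.

    For the curved shapes ``wm_radius_mm``/``pial_radius_mm`` are radii; for
    the planar shapes they are the z positions of the two boundary planes
    (so the cortical thickness is their difference in every case).  The
    default voxel size matches sub-millimetre laminar acquisitions
    (0.8 mm isotropic).
    """

    shape: PhantomShape = "flat-slab"
    wm_radius_mm: float = 0.0
    pial_radius_mm: float = 2.4
    grid_shape: tuple[int, int, int] = (24, 24, 12)
    voxel_size_mm: float = 0.8
    origin_mm: tuple[float, float, float] | None = None
    fold_amplitude_mm: float = 1.2
    fold_wavelength_mm: float = 12.8
    column_width_voxels: int = 2
    #: fraction of voxels with no orientation preference (label 0); useful for
    #: studying how adding unselective voxels dilutes ROI-average responses
    nonselective_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in ("flat-slab", "folded-sheet", "cylinder-annulus", "sphere-shell"):
            raise ValueError(f"unknown phantom shape {self.shape!r}")
        if self.thickness_mm <= self.voxel_size_mm:
            raise ValueError(
                f"cortical thickness {self.thickness_mm:.3f} mm must exceed one voxel "
                f"({self.voxel_size_mm} mm)"
            )
        if self.shape in ("cylinder-annulus", "sphere-shell") and self.wm_radius_mm <= 0:
            raise ValueError("curved phantoms need a positive white-matter radius")
        if self.column_width_voxels < 1:
            raise ValueError("preference column width must be >= 1 voxel")

    @property
    def thickness_mm(self) -> float:
        return float(self.pial_radius_mm - self.wm_radius_mm)

    def make_grid(self) -> Grid:
        if self.origin_mm is not None:
            return Grid(self.grid_shape, self.voxel_size_mm, tuple(self.origin_mm))
        if self.shape in ("flat-slab", "folded-sheet"):
            center = (0.0, 0.0, 0.5 * (self.wm_radius_mm + self.pial_radius_mm))
        else:
            center = (0.0, 0.0, 0.0)
        return Grid.centered(self.grid_shape, self.voxel_size_mm, center)


@dataclass(frozen=True)
class SurfacePair:
    """Pial and white-matter boundary meshes in world mm, normals toward CSF."""

    wm: trimesh.Trimesh
    pial: trimesh.Trimesh


class TruthGeometry:
    """Analytic geometry backing a phantom.

    Provides signed distances (negative toward white matter, positive toward
    CSF — the sign convention used for every boundary in this package),
    analytic cumulative-volume depth fractions, and exact compartment
    classification used by the forward BOLD model.
    """

    def __init__(self, spec: PhantomSpec, grid: Grid):
        self.spec = spec
        self.grid = grid

    # -- signed distances -------------------------------------------------
    def sdf_wm(self, points: np.ndarray) -> np.ndarray:
        return self._sdf(points, self.spec.wm_radius_mm)

    def sdf_pial(self, points: np.ndarray) -> np.ndarray:
        return self._sdf(points, self.spec.pial_radius_mm)

    def _coordinate(self, points: np.ndarray) -> np.ndarray:
        """Scalar geometry coordinate: z for planar, radius for curved shapes."""
        points = np.atleast_2d(points)
        s = self.spec.shape
        if s == "flat-slab":
            return points[:, 2]
        if s == "cylinder-annulus":
            return np.hypot(points[:, 0], points[:, 1])
        if s == "sphere-shell":
            return np.linalg.norm(points, axis=1)
        # folded sheet: distance above the folded WM plane, see _sdf
        raise NotImplementedError

    def _sdf(self, points: np.ndarray, level: float) -> np.ndarray:
        points = np.atleast_2d(points)
        if self.spec.shape == "folded-sheet":
            return _folded_sdf(points, level, self.spec)
        return self._coordinate(points) - level

    # -- depth ------------------------------------------------------------
    def depth_fraction(self, points: np.ndarray) -> np.ndarray:
        """Cumulative GM volume fraction below each point (0 at WM, 1 at pial)."""
        spec = self.spec
        if spec.shape == "flat-slab":
            z = np.atleast_2d(points)[:, 2]
            return (z - spec.wm_radius_mm) / spec.thickness_mm
        if spec.shape == "cylinder-annulus":
            r = self._coordinate(points)
            return (r**2 - spec.wm_radius_mm**2) / (spec.pial_radius_mm**2 - spec.wm_radius_mm**2)
        if spec.shape == "sphere-shell":
            r = self._coordinate(points)
            return (r**3 - spec.wm_radius_mm**3) / (spec.pial_radius_mm**3 - spec.wm_radius_mm**3)
        dw = self.sdf_wm(points)
        dp = self.sdf_pial(points)
        return dw / np.where(dw - dp == 0, np.inf, dw - dp)

    def equivolume_coordinate(self, f: float) -> float:
        """Closed-form position (z or r) of the surface at GM volume fraction f.

        ``f`` is measured from the white-matter boundary toward the pia.
        Not defined for the folded sheet.
        """
        spec = self.spec
        rw, rp = spec.wm_radius_mm, spec.pial_radius_mm
        if spec.shape in ("flat-slab", "folded-sheet"):
            if spec.shape == "folded-sheet":
                raise ValueError("folded sheet has no closed-form equivolume surface")
            return rw + f * (rp - rw)
        if spec.shape == "cylinder-annulus":
            return float(np.sqrt((1 - f) * rw**2 + f * rp**2))
        return float(((1 - f) * rw**3 + f * rp**3) ** (1.0 / 3.0))

    def ribbon_volume_mm3(self) -> float:
        """Analytic GM volume inside the grid bounding box (exact for planar,
        closed-form per unit length/area for curved shapes clipped in z)."""
        spec, grid = self.spec, self.grid
        ext = np.asarray(grid.shape) * grid.voxel_size_mm
        if spec.shape == "flat-slab":
            return float(ext[0] * ext[1] * spec.thickness_mm)
        if spec.shape == "cylinder-annulus":
            return float(np.pi * (spec.pial_radius_mm**2 - spec.wm_radius_mm**2) * ext[2])
        if spec.shape == "sphere-shell":
            return float(4.0 / 3.0 * np.pi * (spec.pial_radius_mm**3 - spec.wm_radius_mm**3))
        raise ValueError("folded sheet ribbon volume has no closed form")

    # -- compartment classification --------------------------------------
    def region_of(self, points: np.ndarray) -> np.ndarray:
        """Compartment index per point: 0 WM, 1 deep, 2 middle, 3 superficial, 4 CSF.

        Intermediate boundaries are the analytic equivolume surfaces at GM
        volume fractions 1/3 and 2/3.
        """
        if self.spec.shape == "folded-sheet":
            dw = self.sdf_wm(points)
            dp = self.sdf_pial(points)
            frac = self.depth_fraction(points)
            region = 1 + (frac >= 1.0 / 3.0).astype(int) + (frac >= 2.0 / 3.0).astype(int)
            region[dw < 0] = 0
            region[dp >= 0] = 4
            return region
        c = self._coordinate(points)
        bounds = [self.spec.wm_radius_mm,
                  self.equivolume_coordinate(1.0 / 3.0),
                  self.equivolume_coordinate(2.0 / 3.0),
                  self.spec.pial_radius_mm]
        return np.searchsorted(np.asarray(bounds), c, side="right")

    def compartment_fractions(self, subdivision: int = 4) -> np.ndarray:
        """Ground-truth (n_voxels, 5) volume-fraction matrix on the phantom grid.

        Computed by classifying ``subdivision**3`` regular sub-voxel sample
        points per voxel with the analytic equivolume boundaries.  This is
        the generator-side truth the analysis pipeline should recover; it
        shares no code with the layering module.
        """
        if subdivision < 1:
            raise ValueError("subdivision must be >= 1")
        grid = self.grid
        centers = grid.voxel_centers()
        offsets = _subvoxel_offsets(subdivision) * grid.voxel_size_mm
        frac = np.zeros((grid.n_voxels, 5))
        for off in offsets:
            region = self.region_of(centers + off)
            frac[np.arange(grid.n_voxels), region] += 1.0
        return frac / len(offsets)

    def gm_fraction_volume(self, subdivision: int = 4) -> np.ndarray:
        f = self.compartment_fractions(subdivision)
        return f[:, 1:4].sum(axis=1).reshape(self.grid.shape)


def _subvoxel_offsets(subdivision: int) -> np.ndarray:
    """Regular sample offsets in voxel units, centred on the voxel centre."""
    s = (np.arange(subdivision) + 0.5) / subdivision - 0.5
    return np.stack(np.meshgrid(s, s, s, indexing="ij"), axis=-1).reshape(-1, 3)


# ---------------------------------------------------------------------------
# folded-sheet numeric signed distance
# ---------------------------------------------------------------------------

def _folded_sdf(points: np.ndarray, level: float, spec: PhantomSpec) -> np.ndarray:
    """Signed distance to the surface z = level + A sin(2 pi x / wavelength).

    Coarse nearest-sample search along the curve followed by a few Newton
    iterations on the squared-distance objective; sign is positive above the
    surface (toward CSF).
    """
    a = spec.fold_amplitude_mm
    k = 2.0 * np.pi / spec.fold_wavelength_mm
    x0 = points[:, 0]
    z0 = points[:, 2] - level

    span = spec.fold_wavelength_mm
    xs = np.linspace(x0.min() - span, x0.max() + span, 1024)
    zs = a * np.sin(k * xs)
    # coarse: nearest curve sample per point (chunked to bound memory)
    xc = np.empty_like(x0)
    for lo in range(0, len(x0), 20000):
        sl = slice(lo, lo + 20000)
        d2 = (x0[sl, None] - xs[None, :]) ** 2 + (z0[sl, None] - zs[None, :]) ** 2
        xc[sl] = xs[np.argmin(d2, axis=1)]
    # Newton refinement of g(x) = (x-x0)^2 + (A sin(kx) - z0)^2
    for _ in range(8):
        s, c = np.sin(k * xc), np.cos(k * xc)
        g1 = 2 * (xc - x0) + 2 * (a * s - z0) * a * k * c
        g2 = 2 + 2 * (a * k * c) ** 2 - 2 * (a * s - z0) * a * k * k * s
        step = g1 / np.where(np.abs(g2) < 1e-9, 1e-9, g2)
        xc = xc - np.clip(step, -0.5 * span, 0.5 * span)
    dist = np.hypot(xc - x0, a * np.sin(k * xc) - z0)
    return np.where(z0 >= a * np.sin(k * x0), dist, -dist)


# ---------------------------------------------------------------------------
# mesh construction
# ---------------------------------------------------------------------------

def _sheet_mesh(xs: np.ndarray, ys: np.ndarray, zfun) -> trimesh.Trimesh:
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    zz = zfun(xx)
    verts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    nx, ny = len(xs), len(ys)
    i, j = np.meshgrid(np.arange(nx - 1), np.arange(ny - 1), indexing="ij")
    a = (i * ny + j).ravel()
    b = ((i + 1) * ny + j).ravel()
    c = (i * ny + j + 1).ravel()
    d = ((i + 1) * ny + j + 1).ravel()
    faces = np.concatenate([np.column_stack([a, b, d]), np.column_stack([a, d, c])])
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


def _tube_mesh(radius: float, z0: float, z1: float, n_theta: int, n_z: int) -> trimesh.Trimesh:
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    z = np.linspace(z0, z1, n_z)
    tt, zz = np.meshgrid(theta, z, indexing="ij")
    verts = np.column_stack([radius * np.cos(tt).ravel(),
                             radius * np.sin(tt).ravel(),
                             zz.ravel()])
    faces = []
    for it in range(n_theta):
        itn = (it + 1) % n_theta
        for iz in range(n_z - 1):
            a = it * n_z + iz
            b = itn * n_z + iz
            c = it * n_z + iz + 1
            d = itn * n_z + iz + 1
            faces.append([a, b, d])
            faces.append([a, d, c])
    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)
    return _orient_outward(mesh, lambda p: np.column_stack(
        [p[:, 0], p[:, 1], np.zeros(len(p))]))


def _orient_outward(mesh: trimesh.Trimesh, outward_fn) -> trimesh.Trimesh:
    centers = mesh.triangles_center
    out = outward_fn(centers)
    norm = np.linalg.norm(out, axis=1, keepdims=True)
    out = out / np.where(norm == 0, 1, norm)
    if float(np.mean(np.einsum("ij,ij->i", mesh.face_normals, out))) < 0:
        mesh.invert()
    return mesh


def _make_surface(spec: PhantomSpec, grid: Grid, level: float) -> trimesh.Trimesh:
    pad = 2.0 * grid.voxel_size_mm
    lo = np.asarray(grid.origin_mm) - pad
    hi = np.asarray(grid.origin_mm) + np.asarray(grid.shape) * grid.voxel_size_mm + pad
    # mesh resolution ~= half a voxel keeps chord error well below tolerance
    step = 0.5 * grid.voxel_size_mm
    if spec.shape == "flat-slab":
        xs = np.arange(lo[0], hi[0] + step, step)
        ys = np.arange(lo[1], hi[1] + step, step)
        return _sheet_mesh(xs, ys, lambda xx: np.full_like(xx, level))
    if spec.shape == "folded-sheet":
        a, k = spec.fold_amplitude_mm, 2 * np.pi / spec.fold_wavelength_mm
        xs = np.arange(lo[0], hi[0] + step, step)
        ys = np.arange(lo[1], hi[1] + step, step)
        return _sheet_mesh(xs, ys, lambda xx: level + a * np.sin(k * xx))
    if spec.shape == "cylinder-annulus":
        n_theta = max(64, int(np.ceil(2 * np.pi * level / step)))
        n_z = max(2, int(np.ceil((hi[2] - lo[2]) / step)) + 1)
        return _tube_mesh(level, lo[2], hi[2], n_theta, n_z)
    subdiv = 4 if level < 6 else 5
    mesh = trimesh.creation.icosphere(subdivisions=subdiv, radius=level)
    return mesh


def make_preference_map(spec: PhantomSpec, grid: Grid) -> np.ndarray:
    """Voxel orientation-preference labels (45 or 135), alternating columns.

    Columns run along the first grid axis in blocks of
    ``spec.column_width_voxels`` voxels, so both orientation populations
    sample all cortical depths of the phantom.
    """
    i = np.arange(grid.shape[0])
    col = (i // spec.column_width_voxels) % 2
    labels = np.where(col == 0, 45, 135).astype(np.int16)
    out = np.broadcast_to(labels[:, None, None], grid.shape).copy()
    if spec.nonselective_fraction > 0:
        rng = np.random.default_rng(spec.seed)
        blank = rng.random(grid.shape) < spec.nonselective_fraction
        out[blank] = 0
    return out


def make_cortical_phantom(spec: PhantomSpec) -> tuple[SurfacePair, np.ndarray, TruthGeometry]:
    """Build a cortical ribbon phantom.

    Returns the boundary surface pair (normals pointing toward CSF), the
    voxel orientation-preference label map, and the analytic truth geometry
    (which also carries the voxel grid).
    """
    grid = spec.make_grid()
    truth = TruthGeometry(spec, grid)
    wm_mesh = _make_surface(spec, grid, spec.wm_radius_mm)
    pial_mesh = _make_surface(spec, grid, spec.pial_radius_mm)
    if spec.shape == "sphere-shell":
        wm_mesh = _orient_outward(wm_mesh, lambda p: p)
        pial_mesh = _orient_outward(pial_mesh, lambda p: p)
    preference = make_preference_map(spec, grid)
    return SurfacePair(wm=wm_mesh, pial=pial_mesh), preference, truth
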