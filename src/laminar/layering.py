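"""Equivolume cortical layering on a voxel grid.

The cortical ribbon between the white-matter (WM) and pial boundary is
divided into three grey-matter layers (deep, middle, superficial) whose
volumes are locally equal.  Surfaces are represented implicitly as signed
distance functions (SDFs) sampled on the functional voxel grid: a boundary
is the zero level set, values are negative on the WM side and positive
toward CSF.

Equivolume placement follows the principle that cortical layers keep their
volume fraction through gyral and sulcal folds: a target volume fraction is
converted into a *distance* fraction using the local curvature of the
bounding surfaces.  Writing ``t`` for distance from the WM surface along the
column and ``k1, k2`` for the WM surface's principal curvatures there, the
cross-sectional area of the column grows as ``A(t) = (1 + k1 t)(1 + k2 t)``,
so the cumulative volume is

    V(t) = t + H t^2 + K t^3 / 3,      H = (k1+k2)/2,  K = k1 k2,

and the boundary enclosing GM volume fraction ``f`` solves
``V(t_f) = f V(h)`` with ``h`` the local thickness.  On zero-curvature
geometry this reduces to the equidistant rule ``t_f = f h``; on a cylinder
or sphere it reproduces the equal-area/equal-volume closed forms exactly.

Principal curvatures are estimated from the WM SDF's Hessian (the second
fundamental form of its level sets) and transported to the boundary's zero
level set along the surface normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import Grid
from .phantom import COMPARTMENTS, _subvoxel_offsets

__all__ = ["LevelSet", "LayerVolumeMatrix", "compute_sdf", "equivolume_surfaces",
           "layer_volume_distribution"]


@dataclass
class LevelSet:
    """Four boundary SDFs separating the five cortical compartments.

    ``boundaries[0]`` is WM|deep, ``boundaries[3]`` is superficial|CSF.
    All share the sign convention negative-toward-WM.
    """

    boundaries: np.ndarray  # (4, nx, ny, nz)
    grid: Grid

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        if self.boundaries.shape != (4, *self.grid.shape):
            raise ValueError("level set must hold 4 volumes matching the grid shape")
        if not np.all(np.diff(self.boundaries, axis=0) <= 1e-9):
            raise ValueError("boundary SDFs are not depth-ordered")


@dataclass
class LayerVolumeMatrix:
    """Per-voxel volume fractions over (WM, deep, middle, superficial, CSF).

    This is the spatial design matrix X of the laminar regression: row i
    gives the distribution of voxel i's volume over the five compartments.
    """

    fractions: np.ndarray       # (n_voxels, 5)
    voxel_indices: np.ndarray   # (n_voxels, 3) integer grid indices
    voxel_volume_mm3: float
    grid_shape: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if f.ndim != 2 or f.shape[1] != 5:
            raise ValueError("fractions must be (n_voxels, 5)")
        if np.any(f < -1e-9) or np.any(f > 1 + 1e-9):
            raise ValueError("volume fractions must lie in [0, 1]")
        if not np.allclose(f.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("volume fractions must sum to 1 per voxel")
        self.fractions = f
        self.voxel_indices = np.asarray(self.voxel_indices, dtype=int)

    @property
    def gm_fraction(self) -> np.ndarray:
        return self.fractions[:, 1:4].sum(axis=1)

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.voxel_indices, columns=["i", "j", "k"])
        for c, name in enumerate(COMPARTMENTS):
            df[name] = self.fractions[:, c]
        return df


def compute_sdf(mesh, grid: Grid) -> np.ndarray:
    """Signed distance from every voxel centre to a boundary mesh.

    The magnitude is the exact Euclidean distance to the nearest point on
    the triangulated surface; the sign is taken from the side of the nearest
    triangle (mesh normals must point toward CSF, giving the package's
    negative-toward-WM convention).

    Candidate triangles are pre-filtered with a KD tree on triangle
    centroids: any triangle whose centroid lies farther than the nearest
    centroid distance plus twice the largest triangle circumradius cannot
    contain the closest point, so the exact paired point-triangle distance
    is only evaluated on that (small) candidate set.
    """
    from scipy.spatial import cKDTree
    from trimesh.triangles import closest_point as tri_closest_point

    if len(mesh.faces) == 0:
        raise ValueError("empty mesh")
    if float(mesh.area_faces.min()) <= 1e-12:
        raise ValueError("mesh contains degenerate (zero-area) triangles")
    points = grid.voxel_centers()
    tris = np.asarray(mesh.triangles)
    centroids = tris.mean(axis=1)
    r_max = float(np.linalg.norm(tris - centroids[:, None, :], axis=2).max())
    tree = cKDTree(centroids)
    d0, _ = tree.query(points)

    sdf = np.empty(len(points))
    normals = np.asarray(mesh.face_normals)
    chunk = 4096
    for lo in range(0, len(points), chunk):
        pts = points[lo:lo + chunk]
        cand = tree.query_ball_point(pts, r=d0[lo:lo + chunk] + 2.0 * r_max + 1e-9)
        p_idx = np.concatenate([np.full(len(c), i) for i, c in enumerate(cand)])
        t_idx = np.concatenate([np.asarray(c, dtype=int) for c in cand])
        closest = tri_closest_point(tris[t_idx], pts[p_idx])
        dist = np.linalg.norm(pts[p_idx] - closest, axis=1)
        order = np.argsort(dist, kind="stable")
        first = np.full(len(pts), -1)
        uniq, pos = np.unique(p_idx[order], return_index=True)
        first[uniq] = order[pos]
        side = np.einsum("ij,ij->i", pts - closest[first],
                         normals[t_idx[first]])
        sdf[lo:lo + chunk] = np.where(side >= 0, dist[first], -dist[first])
    return sdf.reshape(grid.shape)


def _principal_curvatures(sdf: np.ndarray, spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """Principal curvatures of the SDF's level set through each voxel."""
    grads = np.gradient(sdf, spacing)
    g = np.stack(grads, axis=-1)
    gnorm = np.linalg.norm(g, axis=-1, keepdims=True)
    n = g / np.where(gnorm == 0, 1, gnorm)
    hess = np.empty(sdf.shape + (3, 3))
    for i in range(3):
        gi = np.gradient(grads[i], spacing)
        for j in range(3):
            hess[..., i, j] = gi[j]
    hess = 0.5 * (hess + np.swapaxes(hess, -1, -2))
    # project onto the tangent plane: M = (I - n n^T) H (I - n n^T)
    hn = np.einsum("...ij,...j->...i", hess, n)
    nhn = np.einsum("...i,...i->...", hn, n)
    m = (hess
         - np.einsum("...i,...j->...ij", n, hn)
         - np.einsum("...i,...j->...ij", hn, n)
         + nhn[..., None, None] * np.einsum("...i,...j->...ij", n, n))
    tr = np.einsum("...ii->...", m)
    tr2 = np.einsum("...ij,...ji->...", m, m)
    det2 = 0.5 * (tr**2 - tr2)  # product of the two in-plane eigenvalues
    disc = np.sqrt(np.maximum(tr**2 - 4 * det2, 0.0))
    return 0.5 * (tr + disc), 0.5 * (tr - disc)


def equivolume_surfaces(wm_sdf: np.ndarray, pial_sdf: np.ndarray, grid: Grid,
                        n_layers: int = 3) -> LevelSet:
    """Place the two intermediate equivolume surfaces between WM and pia.

    Parameters are the two bounding SDFs sampled on ``grid``.  Returns the
    full four-boundary :class:`LevelSet`.  Only the three-layer model used
    for laminar analysis is supported.
    """
    if n_layers != 3:
        raise ValueError("only the 3-layer equivolume model is supported")
    wm_sdf = np.asarray(wm_sdf, dtype=float)
    pial_sdf = np.asarray(pial_sdf, dtype=float)
    if wm_sdf.shape != tuple(grid.shape) or pial_sdf.shape != tuple(grid.shape):
        raise ValueError("SDF arrays must match the grid shape")

    h = wm_sdf - pial_sdf  # local thickness along the column
    ribbon = (wm_sdf >= 0) & (pial_sdf <= 0)
    if ribbon.any():
        thin = ribbon & (h < grid.voxel_size_mm)
        if thin.any():
            idx = np.argwhere(thin)[0]
            raise ValueError(
                f"cortical ribbon thinner than the grid resolution near voxel "
                f"{tuple(idx)} (thickness {h[tuple(idx)]:.3f} mm)"
            )

    k1, k2 = _principal_curvatures(wm_sdf, grid.voxel_size_mm)
    # transport curvature from the voxel's level set back to the WM surface:
    # k(t) = k0 / (1 + t k0)  =>  k0 = k / (1 - t k)
    t0 = wm_sdf
    den1 = np.clip(1.0 - t0 * k1, 0.1, None)
    den2 = np.clip(1.0 - t0 * k2, 0.1, None)
    k01 = k1 / den1
    k02 = k2 / den2
    hs = np.maximum(h, 1e-6)
    # keep A(t) = (1+k1 t)(1+k2 t) positive over the full thickness
    k01 = np.clip(k01, -0.95 / hs, None)
    k02 = np.clip(k02, -0.95 / hs, None)
    h0 = 0.5 * (k01 + k02)
    g0 = k01 * k02

    def cumvol(t: np.ndarray) -> np.ndarray:
        return t + h0 * t**2 + g0 * t**3 / 3.0

    vh = cumvol(hs)
    boundaries = [wm_sdf]
    for f in (1.0 / 3.0, 2.0 / 3.0):
        target = f * vh
        lo = np.zeros_like(hs)
        hi = hs.copy()
        for _ in range(48):  # bisection: V is monotone on [0, h]
            mid = 0.5 * (lo + hi)
            below = cumvol(mid) < target
            lo = np.where(below, mid, lo)
            hi = np.where(below, hi, mid)
        t_f = 0.5 * (lo + hi)
        gfrac = t_f / hs
        boundaries.append((1.0 - gfrac) * wm_sdf + gfrac * pial_sdf)
    boundaries.append(pial_sdf)
    stack = np.stack(boundaries)
    # enforce exact ordering against rounding at the bisection tolerance
    stack = np.minimum.accumulate(stack, axis=0)
    return LevelSet(boundaries=stack, grid=grid)


def layer_volume_distribution(level_set: LevelSet, grid: Grid, subdivision: int = 4,
                              mask: np.ndarray | None = None) -> LayerVolumeMatrix:
    """Distribute each voxel's volume over the five compartments.

    ``subdivision**3`` regular sample points per voxel are classified by the
    sign pattern of the four boundary SDFs (trilinearly interpolated between
    voxel centres); the per-compartment sample counts give the volume
    fractions.  ``mask`` restricts the output to a voxel subset.
    """
    if subdivision < 2:
        raise ValueError("subdivision must be >= 2")
    if grid.shape != level_set.grid.shape:
        raise ValueError("level set and grid shapes differ")
    if mask is None:
        voxels = np.indices(grid.shape).reshape(3, -1).T
    else:
        if mask.shape != tuple(grid.shape):
            raise ValueError("mask shape must match the grid")
        voxels = np.argwhere(mask)
    offsets = _subvoxel_offsets(subdivision)  # in voxel units
    n = len(voxels)
    region = np.zeros((n, 5))
    rows = np.arange(n)
    for off in offsets:
        coords = (voxels + off).T.astype(float)
        count = np.zeros(n, dtype=int)
        for b in range(4):
            vals = ndimage.map_coordinates(level_set.boundaries[b], coords,
                                           order=1, mode="nearest")
            count += (vals >= 0).astype(int)
        region[rows, count] += 1.0
    fractions = region / len(offsets)
    return LayerVolumeMatrix(fractions=fractions, voxel_indices=voxels,
                             voxel_volume_mm3=grid.voxel_volume_mm3,
                             grid_shape=tuple(grid.shape))
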