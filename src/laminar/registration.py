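"""Boundary-based registration (BBR) of cortical surfaces to a functional volume.

BBR aligns the white-matter boundary mesh with the intensity edge between
white and grey matter in the (mean) EPI volume: at every vertex the volume
is sampled a fixed distance along the surface normal on both sides, and the
transform is chosen to maximise the signed percent contrast across the
boundary.  The affine has 7 degrees of freedom — rotation and translation
in all three dimensions plus a scale factor along the phase-encoding axis,
where EPI distortions compress or stretch the image.

The recursive variant (RBR) corrects *local* distortions: after the global
fit, the mesh is repeatedly bisected into equal-vertex partitions along the
cardinal axes (the cut axis cycling through a permutation of x, y, z) and
each partition is re-registered, down to a minimum partition size.  The
whole recursion is repeated for each axis-order permutation and the final
per-vertex displacement is the median over those runs, which suppresses
the occasional partition that latches onto the wrong edge.

Cost convention: ``1 - mean(tanh(slope * Q))`` with ``Q`` the percent
contrast between the outside and inside samples, so perfect positive
(GM-bright) contrast drives the cost toward 0 and the cost is invariant to
global intensity scaling.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .grid import Grid

logger = logging.getLogger(__name__)

MIN_PARTITION_VERTICES = 50


@dataclass(frozen=True)
class AffineTransform7:
    """Rigid body + phase-axis scale: p' = R S (p - c) + c + t."""

    rotation_rad: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    phase_scale: float = 1.0
    phase_axis: int = 1
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.phase_scale <= 0:
            raise ValueError("phase-axis scale must be positive")
        if self.phase_axis not in (0, 1, 2):
            raise ValueError("phase axis must be 0, 1 or 2")

    @property
    def _linear(self) -> np.ndarray:
        s = np.ones(3)
        s[self.phase_axis] = self.phase_scale
        return Rotation.from_euler("xyz", self.rotation_rad).as_matrix() @ np.diag(s)

    def apply(self, points: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center_mm)
        return (np.atleast_2d(points) - c) @ self._linear.T + c + np.asarray(self.translation_mm)

    def apply_normals(self, normals: np.ndarray) -> np.ndarray:
        """Transform surface normals (inverse-transpose of the linear part)."""
        lin_it = np.linalg.inv(self._linear).T
        n = np.atleast_2d(normals) @ lin_it.T
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    def to_params(self) -> np.ndarray:
        return np.array([*self.rotation_rad, *self.translation_mm, np.log(self.phase_scale)])

    @classmethod
    def from_params(cls, params: np.ndarray, phase_axis: int,
                    center_mm: tuple[float, float, float]) -> "AffineTransform7":
        p = np.asarray(params, dtype=float)
        return cls(rotation_rad=tuple(p[:3]), translation_mm=tuple(p[3:6]),
                   phase_scale=float(np.exp(p[6])), phase_axis=phase_axis,
                   center_mm=tuple(center_mm))


def _sample_volume(volume: np.ndarray, grid: Grid, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear samples at world points, plus an in-bounds mask."""
    ijk = grid.world_to_index(points)
    inb = np.all((ijk >= 0) & (ijk <= np.asarray(volume.shape) - 1), axis=1)
    vals = ndimage.map_coordinates(volume, ijk.T, order=1, mode="nearest")
    return vals, inb


def boundary_contrast(volume: np.ndarray, grid: Grid, vertices: np.ndarray,
                      normals: np.ndarray, sample_dist_mm: float = 1.0) -> np.ndarray:
    """Signed percent contrast across the boundary at each vertex.

    Positive when the outside (pial-direction) sample is brighter than the
    inside (WM-direction) sample, as expected for GM-bright EPI.
    """
    if sample_dist_mm <= 0:
        raise ValueError("sampling distance must be positive")
    outside, in_o = _sample_volume(volume, grid, vertices + sample_dist_mm * normals)
    inside, in_i = _sample_volume(volume, grid, vertices - sample_dist_mm * normals)
    inb = in_o & in_i
    if inb.mean() < 0.5:
        raise ValueError("more than half of the boundary samples fall outside the volume")
    denom = 0.5 * (np.abs(outside) + np.abs(inside)) + 1e-12
    q = 100.0 * (outside - inside) / denom
    return np.where(inb, q, 0.0)


def bbr_cost(volume: np.ndarray, grid: Grid, vertices: np.ndarray, normals: np.ndarray,
             transform: AffineTransform7, sample_dist_mm: float = 1.0,
             slope: float = 0.5) -> float:
    """BBR objective for a candidate transform (lower is better)."""
    v = transform.apply(vertices)
    n = transform.apply_normals(normals)
    q = boundary_contrast(volume, grid, v, n, sample_dist_mm)
    return float(1.0 - np.mean(np.tanh(slope * q)))


@dataclass
class BBRResult:
    transform: AffineTransform7
    cost: float
    contrast: float          # mean signed GM-WM percent contrast
    converged: bool


def fit_bbr(volume: np.ndarray, grid: Grid, vertices: np.ndarray, normals: np.ndarray,
            init: AffineTransform7 | None = None, phase_axis: int = 1,
            sample_dist_mm: float = 1.0, slope: float = 0.5,
            fit_scale: bool = True, maxfev: int = 400,
            bounds_mm: float | None = None) -> BBRResult:
    """Fit the 7-DOF boundary-based registration by derivative-free search.

    Two Nelder-Mead passes (coarse then fine simplex) from the initial
    transform; non-convergence is flagged on the result, never silent.
    ``bounds_mm`` caps the translation search around the initialisation
    (with proportionate rotation/scale caps), which keeps partition-level
    refits from latching onto a distant, aliased intensity edge.
    """
    center = tuple(vertices.mean(axis=0))
    if init is None:
        init = AffineTransform7(phase_axis=phase_axis, center_mm=center)
    else:
        init = replace(init, center_mm=center)
    x0 = init.to_params()
    free = np.arange(7) if fit_scale else np.arange(6)
    if bounds_mm is not None:
        span = np.array([0.2, 0.2, 0.2, bounds_mm, bounds_mm, bounds_mm, 0.1])
        lo, hi = x0 - span, x0 + span

    def cost_fn(x_free: np.ndarray) -> float:
        x = x0.copy()
        x[free] = x_free
        if bounds_mm is not None and (np.any(x < lo) or np.any(x > hi)):
            return 2.0  # worse than any attainable cost (cost is in [0, 2])
        t = AffineTransform7.from_params(x, phase_axis, center)
        return bbr_cost(volume, grid, vertices, normals, t, sample_dist_mm, slope)

    steps = np.array([0.03, 0.03, 0.03, 1.0, 1.0, 1.0, 0.02])[free]
    x = x0[free]
    converged = True
    for scale in (1.0, 0.25, 0.06):
        simplex = np.vstack([x, x + np.diag(steps * scale)])
        res = minimize(cost_fn, x, method="Nelder-Mead",
                       options={"initial_simplex": simplex, "maxfev": maxfev,
                                "xatol": 3e-4, "fatol": 1e-10})
        x = res.x
        converged = bool(res.success)
    if not converged:
        warnings.warn("BBR optimiser did not fully converge; result is flagged")
    xb = x0.copy()
    xb[free] = x
    best = AffineTransform7.from_params(xb, phase_axis, center)
    q = boundary_contrast(volume, grid, best.apply(vertices),
                          best.apply_normals(normals), sample_dist_mm)
    return BBRResult(transform=best, cost=cost_fn(x), contrast=float(q.mean()),
                     converged=converged)


@dataclass
class DisplacementField:
    """Per-vertex displacement of the registered mesh (mm, world axes)."""

    displacement: np.ndarray        # (n_vertices, 3), median over orderings
    vertices: np.ndarray            # final vertex positions
    contrast_global: float          # |mean contrast| after global BBR
    contrast_recursive: float       # |mean contrast| after RBR
    per_ordering: np.ndarray | None = None  # (n_orderings, n_vertices, 3)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.displacement)):
            raise ValueError("displacement field must be finite")


def median_displacement(per_ordering: np.ndarray) -> np.ndarray:
    """Component-wise median of per-vertex displacements over ordering runs.

    The median makes the combined field robust to a single ordering whose
    partitions latched onto the wrong intensity edge.
    """
    per_ordering = np.asarray(per_ordering, dtype=float)
    if per_ordering.ndim != 3 or per_ordering.shape[2] != 3:
        raise ValueError("expected (n_orderings, n_vertices, 3)")
    return np.median(per_ordering, axis=0)


def _split_indices(subset: np.ndarray, coord: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Equal-vertex bisection along one axis (ties broken by vertex index)."""
    order = np.lexsort((subset, coord))
    half = len(subset) // 2
    return subset[order[:half]], subset[order[half:]]


def recursive_bbr(volume: np.ndarray, grid: Grid, vertices: np.ndarray,
                  normals: np.ndarray, n_iterations: int = 6, n_orderings: int = 6,
                  phase_axis: int = 1, sample_dist_mm: float = 1.0, slope: float = 0.5,
                  refit_scale: bool = True, partition_maxfev: int = 400,
                  partition_bounds_mm: float = 2.0) -> DisplacementField:
    """Recursive boundary registration.

    Runs the global 7-DOF BBR first, then for each of the first
    ``n_orderings`` axis-order permutations recursively bisects the mesh
    (cut axis cycling through the permutation, repeating after three
    levels), re-registering every partition.  Partitions smaller than 50
    vertices are not registered or split further.  The per-vertex
    displacement is the component-wise median over the ordering runs.
    """
    if not 1 <= n_orderings <= 6:
        raise ValueError("n_orderings must be between 1 and 6")
    global_fit = fit_bbr(volume, grid, vertices, normals, phase_axis=phase_axis,
                         sample_dist_mm=sample_dist_mm, slope=slope)
    p0 = global_fit.transform.apply(vertices)
    n0 = global_fit.transform.apply_normals(normals)

    orderings = list(itertools.permutations((0, 1, 2)))[:n_orderings]
    all_disp = np.empty((len(orderings), len(vertices), 3))
    for oi, order in enumerate(orderings):
        pos = p0.copy()
        nrm = n0.copy()

        def recurse(subset: np.ndarray, depth: int) -> None:
            if depth >= n_iterations:
                return
            axis = order[depth % 3]
            for half in _split_indices(subset, pos[subset, axis]):
                if len(half) < MIN_PARTITION_VERTICES:
                    logger.info("ordering %s depth %d: partition of %d vertices "
                                "too small, not refined", order, depth, len(half))
                    continue
                fit = fit_bbr(volume, grid, pos[half], nrm[half],
                              phase_axis=phase_axis, sample_dist_mm=sample_dist_mm,
                              slope=slope, fit_scale=refit_scale,
                              maxfev=partition_maxfev, bounds_mm=partition_bounds_mm)
                pos[half] = fit.transform.apply(pos[half])
                nrm[half] = fit.transform.apply_normals(nrm[half])
                recurse(half, depth + 1)

        recurse(np.arange(len(vertices)), 0)
        all_disp[oi] = pos - vertices

    median_disp = median_displacement(all_disp)
    final = vertices + median_disp
    q_final = boundary_contrast(volume, grid, final, n0, sample_dist_mm)
    return DisplacementField(displacement=median_disp, vertices=final,
                             contrast_global=abs(global_fit.contrast),
                             contrast_recursive=abs(float(q_final.mean())),
                             per_ordering=all_disp)
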