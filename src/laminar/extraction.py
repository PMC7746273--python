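"""Partial-volume unmixing of laminar time courses.

At 0.8 mm, most voxels mix signal from several cortical depths.  Writing
``Y`` for the (n_voxels x T) ROI data and ``X`` for the (n_voxels x 5)
layer-volume design matrix, the spatial GLM ``Y = X B + e`` is solved per
functional volume by ordinary least squares, yielding one time course per
compartment (WM, deep, middle, superficial, CSF).  The interpolation
control estimator ``B = X' Y / N`` (a depth-weighted voxel average) does
not unmix partial volumes and is kept for comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import qr, solve_triangular

from .phantom import COMPARTMENTS

logger = logging.getLogger(__name__)


@dataclass
class LayerTimecourses:
    """5 x T compartment time courses for one ROI and run."""

    values: np.ndarray
    estimator: str                     # "glm" or "interpolation"
    absent: tuple[str, ...] = ()       # compartments with no volume support

    def __post_init__(self) -> None:
        if self.values.shape[0] != 5:
            raise ValueError("expected 5 compartment rows")

    def gm(self) -> np.ndarray:
        """The three grey-matter layer courses (deep, middle, superficial)."""
        return self.values[1:4]


def spatial_glm(y: np.ndarray, x: np.ndarray, cond_warn: float = 1e3) -> LayerTimecourses:
    """OLS unmixing of layer time courses, solved via QR.

    Compartments with no volume in any ROI voxel (an all-zero column) are
    dropped from the fit and flagged; their rows are returned as NaN.  The
    residuals of every volume are orthogonal to the retained columns.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape[0] != x.shape[0]:
        raise ValueError("Y and X must agree on the number of voxels")
    norms = np.linalg.norm(x, axis=0)
    keep = norms > 1e-12
    absent = tuple(np.asarray(COMPARTMENTS)[~keep])
    if absent:
        logger.info("spatial GLM: compartments absent from the ROI: %s", absent)
    xk = x[:, keep]
    if np.linalg.matrix_rank(xk) < xk.shape[1]:
        raise np.linalg.LinAlgError(
            "layer design matrix is rank deficient beyond empty compartments")
    cond = np.linalg.cond(xk)
    if cond > cond_warn:
        warnings.warn(f"layer design matrix is ill-conditioned (cond = {cond:.1e})")
    q, r = qr(xk, mode="economic")
    b = solve_triangular(r, q.T @ y)
    values = np.full((5, y.shape[1]), np.nan)
    values[keep] = b
    return LayerTimecourses(values=values, estimator="glm", absent=absent)


def interpolation_extract(y: np.ndarray, x: np.ndarray) -> LayerTimecourses:
    """Depth-weighted voxel average ``B = X' Y / N`` (interpolation control)."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape[0] != x.shape[0]:
        raise ValueError("Y and X must agree on the number of voxels")
    return LayerTimecourses(values=x.T @ y / x.shape[0], estimator="interpolation")


def compartment_intensity(mean_image: np.ndarray, x: np.ndarray,
                          voxel_idx: np.ndarray | None = None) -> np.ndarray:
    """Volume-weighted mean intensity of each of the 5 compartments.

    Used as a sanity check that the layering identified grey matter: in the
    mean EPI the three GM compartments should be brighter than WM and CSF.
    Compartments without volume support come back NaN.
    """
    img = np.asarray(mean_image, dtype=float).reshape(-1)
    if not np.all(np.isfinite(img)):
        raise ValueError("mean image must be finite")
    if voxel_idx is not None:
        img = img[np.asarray(voxel_idx)]
    if img.shape[0] != x.shape[0]:
        raise ValueError("image voxels and design rows must align")
    w = x.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (x.T @ img) / w
    out[w <= 1e-12] = np.nan
    return out
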