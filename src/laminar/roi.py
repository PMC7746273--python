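"""Region-of-interest selection from the orientation localizer.

A temporal GLM on the localizer run yields, per voxel, a T statistic for
responding to gratings at all (both orientations against baseline) and a T
statistic for the 45-vs-135-degree orientation contrast.  Voxels inside the
anatomical mask that pass the activation threshold (t > 2.3 by default) are
ranked on the orientation contrast and the strongest 45-preferring and
135-preferring populations are retained (500 voxels each by default).
Selected voxel time courses are z-scored per run and weighted by |T| of
the orientation contrast so that robustly tuned voxels dominate the
laminar regression; a raw mode bypasses both steps for control analyses.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import f_oneway

from .bold import BOLDRun
from .hrf import block_regressor
from .layering import LayerVolumeMatrix

logger = logging.getLogger(__name__)


@dataclass
class VoxelStatMap:
    """Voxel-wise localizer statistics on the full grid (flattened)."""

    t_stimulus: np.ndarray   # (45 + 135) vs baseline
    t_orientation: np.ndarray  # 45 vs 135
    df: int
    excluded: np.ndarray     # zero-variance voxels, excluded from selection
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.df <= 0:
            raise ValueError("degrees of freedom must be positive")


@dataclass
class ROISet:
    """Orientation-preferring voxel populations with their |T| weights."""

    idx_45: np.ndarray
    idx_135: np.ndarray
    weight_45: np.ndarray
    weight_135: np.ndarray

    def __post_init__(self) -> None:
        if np.intersect1d(self.idx_45, self.idx_135).size:
            raise ValueError("the two orientation ROIs must be disjoint")

    def indices(self, preference: int) -> np.ndarray:
        return self.idx_45 if preference == 45 else self.idx_135

    def weights(self, preference: int) -> np.ndarray:
        return self.weight_45 if preference == 45 else self.weight_135

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "idx_45": self.idx_45.tolist(), "idx_135": self.idx_135.tolist(),
            "weight_45": self.weight_45.tolist(), "weight_135": self.weight_135.tolist(),
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "ROISet":
        d = json.loads(Path(path).read_text())
        return cls(*(np.asarray(d[k]) for k in ("idx_45", "idx_135", "weight_45", "weight_135")))


def localizer_glm(localizer_run: BOLDRun, blocks: pd.DataFrame) -> VoxelStatMap:
    """Per-voxel OLS fit of the two orientation block regressors.

    Returns T maps for the joint stimulus-vs-baseline contrast and the
    orientation-preference contrast.  Voxels with zero temporal variance
    are excluded (T undefined) and logged.
    """
    n_vols = localizer_run.n_vols
    tr = localizer_run.tr_s
    regs = []
    for orient in (45, 135):
        b = blocks[blocks["orientation_deg"] == orient]
        if not len(b):
            raise ValueError(f"no {orient}-degree blocks in the localizer design")
        if b["onset_s"].max() + b["duration_s"].max() > n_vols * tr + tr:
            raise ValueError("block design exceeds the run length")
        regs.append(block_regressor(b["onset_s"].to_numpy(), float(b["duration_s"].iloc[0]),
                                    n_vols, tr))
    x = np.column_stack([regs[0], regs[1], np.ones(n_vols)])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("rank-deficient localizer design")

    y = localizer_run.data.reshape(-1, n_vols).T  # (T, n_vox)
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    df = n_vols - x.shape[1]
    sigma2 = (resid**2).sum(axis=0) / df

    excluded = y.var(axis=0) < 1e-12
    n_exc = int(excluded.sum())
    if n_exc:
        logger.info("localizer GLM: excluding %d zero-variance voxels", n_exc)

    def contrast_t(c: np.ndarray) -> np.ndarray:
        num = c @ beta
        var = float(c @ xtx_inv @ c) * sigma2
        with np.errstate(divide="ignore", invalid="ignore"):
            t = num / np.sqrt(var)
            t = np.where(var == 0, np.sign(num) * np.inf, t)
        t[excluded] = np.nan
        return t

    return VoxelStatMap(
        t_stimulus=contrast_t(np.array([1.0, 1.0, 0.0])),
        t_orientation=contrast_t(np.array([1.0, -1.0, 0.0])),
        df=df, excluded=excluded, shape=localizer_run.data.shape[:3],
    )


def select_rois(stats: VoxelStatMap, v1_mask: np.ndarray, activation_t: float = 2.3,
                n_per_orientation: int = 500) -> ROISet:
    """Pick the strongest 45- and 135-preferring voxels.

    Eligibility: inside the mask, activation T above threshold, and a
    defined orientation T.  Ranking is by orientation T (descending for 45,
    ascending for 135) with ties broken by voxel index, so selection is
    deterministic.
    """
    mask = np.asarray(v1_mask, dtype=bool).reshape(-1)
    if not mask.any():
        raise ValueError("empty V1 mask")
    with np.errstate(invalid="ignore"):
        eligible = mask & ~stats.excluded & (stats.t_stimulus > activation_t) \
            & ~np.isnan(stats.t_orientation)
    idx = np.flatnonzero(eligible)
    t_or = stats.t_orientation[idx]

    def top(sign: float) -> tuple[np.ndarray, np.ndarray]:
        pos = idx[sign * t_or > 0]
        tv = sign * stats.t_orientation[pos]
        order = np.lexsort((pos, -tv))  # strongest first, index breaks ties
        if len(pos) < n_per_orientation:
            warnings.warn(f"only {len(pos)} eligible voxels for the "
                          f"{'45' if sign > 0 else '135'}-preferring ROI "
                          f"(requested {n_per_orientation})")
        sel = pos[order][:n_per_orientation]
        return sel, np.abs(stats.t_orientation[sel])

    i45, w45 = top(+1.0)
    i135, w135 = top(-1.0)
    if not len(i45) and not len(i135):
        warnings.warn("ROI selection produced no voxels")
    return ROISet(idx_45=i45, idx_135=i135, weight_45=w45, weight_135=w135)


@dataclass
class VoxelTimecoursePanel:
    """Time courses of one ROI's voxels for one run (n_voxels x T)."""

    values: np.ndarray
    voxel_idx: np.ndarray
    run: int
    mode: str = "weighted"


def weight_timecourses(runs: list[BOLDRun], roi_idx: np.ndarray, weights: np.ndarray,
                       mode: str = "weighted") -> list[VoxelTimecoursePanel]:
    """Normalise and weight ROI voxel time courses, per run.

    ``weighted``: z-score each voxel's course over time within the run,
    then multiply by its |T| weight.  ``raw``: pass the intensities through
    untouched (the control analysis).  Zero-variance voxels cannot be
    z-scored and are dropped (with a log entry) in weighted mode.
    """
    if mode not in ("weighted", "raw"):
        raise ValueError("mode must be 'weighted' or 'raw'")
    roi_idx = np.asarray(roi_idx)
    panels = []
    for r, run in enumerate(runs):
        y = run.data.reshape(-1, run.n_vols)[roi_idx].astype(float)
        keep = np.arange(len(roi_idx))
        if mode == "weighted":
            sd = y.std(axis=1)
            bad = sd < 1e-12
            if bad.any():
                logger.info("run %d: dropping %d zero-variance voxels from panel",
                            r, int(bad.sum()))
                keep = keep[~bad]
                y = y[~bad]
                sd = sd[~bad]
            if np.any(np.isinf(weights[keep])):
                raise ValueError("infinite |T| weights; use raw mode for noiseless data")
            y = (y - y.mean(axis=1, keepdims=True)) / sd[:, None]
            y = y * weights[keep][:, None]
        panels.append(VoxelTimecoursePanel(values=y, voxel_idx=roi_idx[keep],
                                           run=r, mode=mode))
    return panels


def balance_layers(roi_idx: np.ndarray, layer_matrix: LayerVolumeMatrix,
                   alpha: float = 0.1) -> tuple[np.ndarray, dict]:
    """Equalise the ROI's representation of the three GM layers.

    Iteratively removes, from the currently most overrepresented layer, the
    member voxel with the largest volume fraction in that layer, until a
    one-way ANOVA over per-voxel GM-layer fractions (factor: layer) no
    longer signals an imbalance (p > alpha), or the ROI would shrink below
    3 voxels per layer.  Returns the reduced index list and a small report.
    """
    roi_idx = np.asarray(roi_idx)
    if not len(roi_idx):
        raise ValueError("empty ROI")
    if layer_matrix.grid_shape is None:
        raise ValueError("layer matrix must carry its grid shape to map ROI indices")
    flat = np.ravel_multi_index(layer_matrix.voxel_indices.T, layer_matrix.grid_shape)
    row_of = {f: i for i, f in enumerate(flat)}
    rows = np.array([row_of[f] for f in roi_idx])
    frac = layer_matrix.fractions[rows][:, 1:4]

    keep = np.ones(len(rows), dtype=bool)
    history = []
    while True:
        g = frac[keep]
        p = f_oneway(g[:, 0], g[:, 1], g[:, 2]).pvalue
        history.append(float(p))
        if p > alpha:
            converged = True
            break
        if keep.sum() <= 9:  # 3 voxels per layer floor
            converged = False
            warnings.warn("layer balancing hit the size floor before p > alpha")
            break
        over = int(np.argmax(g.sum(axis=0)))
        cand = np.flatnonzero(keep)
        worst = cand[np.argmax(frac[cand, over])]
        keep[worst] = False
    report = {"removed": int((~keep).sum()), "p_final": history[-1],
              "converged": converged, "p_history": history}
    return roi_idx[keep], report
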