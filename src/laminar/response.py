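"""Temporal GLM on laminar time courses and reduction to condition amplitudes.

One GLM is fitted per task over that task's runs.  Regressors of interest
are the four (presented/omitted) x (45/135 degree) event types, built as
stick functions at the expected first-grating onset convolved with the
canonical double-gamma HRF.  Nuisance regressors are the six rigid-body
motion parameters, their backward-difference derivatives, and the squared
derivatives, per run; a 128-s discrete-cosine high-pass is applied to both
the data and the design, and run intercepts absorb baseline offsets.

The interest betas of the two orientation-preference ROIs are reduced to
orientation-specific amplitudes by subtracting, per layer and condition,
the response to the non-preferred orientation from the response to the
preferred orientation, then averaging over the two ROIs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hrf import dct_highpass_basis, event_regressor, residualize

logger = logging.getLogger(__name__)

INTEREST_CONDITIONS = (("present", 45), ("present", 135), ("omission", 45), ("omission", 135))


@dataclass
class TemporalDesign:
    """Concatenated per-task design with interest/nuisance separation."""

    interest: np.ndarray          # (T_total, 4), high-pass filtered
    interest_names: tuple[str, ...]
    nuisance: np.ndarray          # (T_total, p), filtered, per-run blocks
    nuisance_names: tuple[str, ...]
    intercepts: np.ndarray        # (T_total, n_runs) run indicator columns
    run_slices: tuple[slice, ...]
    hp_bases: tuple[np.ndarray, ...]
    tr_s: float

    @property
    def n_vols(self) -> int:
        return self.interest.shape[0]

    def matrix(self) -> np.ndarray:
        return np.column_stack([self.interest, self.nuisance, self.intercepts])

    def column_names(self) -> tuple[str, ...]:
        return (*self.interest_names, *self.nuisance_names,
                *(f"intercept_run{r}" for r in range(self.intercepts.shape[1])))

    def filter_data(self, course: np.ndarray) -> np.ndarray:
        """Apply the same per-run cosine high-pass that the design received."""
        course = np.asarray(course, dtype=float)
        out = course.copy()
        for sl, basis in zip(self.run_slices, self.hp_bases):
            out[sl] = residualize(course[sl], basis)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix(), columns=list(self.column_names()))


def _motion_nuisance(motion: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Motion params + backward-difference derivatives + squared derivatives."""
    m = motion.to_numpy(dtype=float)
    d = np.diff(m, axis=0, prepend=m[:1])  # first volume: zero derivative
    cols = np.column_stack([m, d, d**2])
    names = ([f"motion_{c}" for c in motion.columns]
             + [f"dmotion_{c}" for c in motion.columns]
             + [f"dmotion2_{c}" for c in motion.columns])
    return cols, names


def build_design(session_design: pd.DataFrame, motion_by_run: dict[int, pd.DataFrame],
                 n_vols_by_run: dict[int, int], tr_s: float, task: str,
                 hp_cutoff_s: float | None = 128.0) -> TemporalDesign:
    """Assemble the temporal design for one task across its runs.

    Interest regressors model each condition's events at the expected
    first-grating onset (cue onset + SOA) as unit sticks; omission trials
    are modelled at the same latency their grating would have appeared.
    All-zero nuisance columns (e.g. a motionless session) are dropped with
    a log entry.
    """
    d = session_design[session_design["task"] == task]
    if not len(d):
        raise ValueError(f"no trials for task {task!r}")
    runs = sorted(d["run"].unique())

    interest_blocks, nuisance_blocks, bases, slices = [], [], [], []
    nuisance_names: list[str] = []
    offset = 0
    for run in runs:
        dr = d[d["run"] == run]
        n_vols = n_vols_by_run[run]
        late = dr[dr["grating_onset_s"] >= n_vols * tr_s]
        if len(late):
            raise ValueError(f"run {run}: events after run end at "
                             f"{late['grating_onset_s'].tolist()} s")
        cols = []
        for trial_type, orient in INTEREST_CONDITIONS:
            rows = dr[(dr["trial_type"] == trial_type)
                      & (dr["cued_orientation_deg"] == orient)]
            cols.append(event_regressor(rows["grating_onset_s"].to_numpy(), n_vols, tr_s)
                        if len(rows) else np.zeros(n_vols))
        interest_blocks.append(np.column_stack(cols))

        motion = motion_by_run.get(run)
        if motion is None:
            raise ValueError(f"no motion table for run {run}")
        if len(motion) != n_vols:
            raise ValueError(f"run {run}: motion table has {len(motion)} rows, "
                             f"expected {n_vols}")
        mcols, mnames = _motion_nuisance(motion)
        nuisance_blocks.append(mcols)
        nuisance_names.append([f"run{run}_{n}" for n in mnames])
        bases.append(dct_highpass_basis(n_vols, tr_s, hp_cutoff_s))
        slices.append(slice(offset, offset + n_vols))
        offset += n_vols

    t_total = offset
    interest = np.vstack(interest_blocks)
    nuisance = np.zeros((t_total, sum(b.shape[1] for b in nuisance_blocks)))
    names_flat: list[str] = []
    c0 = 0
    for sl, block, names in zip(slices, nuisance_blocks, nuisance_names):
        nuisance[sl, c0:c0 + block.shape[1]] = block
        names_flat.extend(names)
        c0 += block.shape[1]

    # high-pass the design the same way the data will be filtered
    for sl, basis in zip(slices, bases):
        interest[sl] = residualize(interest[sl], basis)
        nuisance[sl] = residualize(nuisance[sl], basis)

    zero = np.linalg.norm(nuisance, axis=0) < 1e-12
    if zero.any():
        dropped = [n for n, z in zip(names_flat, zero) if z]
        logger.info("temporal design: dropping %d all-zero nuisance columns (%s%s)",
                    len(dropped), ", ".join(dropped[:4]), "..." if len(dropped) > 4 else "")
        nuisance = nuisance[:, ~zero]
        names_flat = [n for n, z in zip(names_flat, zero) if not z]

    intercepts = np.zeros((t_total, len(runs)))
    for i, sl in enumerate(slices):
        intercepts[sl, i] = 1.0

    names = tuple(f"{tt}_{o}" for tt, o in INTEREST_CONDITIONS)
    return TemporalDesign(interest=interest, interest_names=names,
                          nuisance=nuisance, nuisance_names=tuple(names_flat),
                          intercepts=intercepts, run_slices=tuple(slices),
                          hp_bases=tuple(bases), tr_s=tr_s)


@dataclass
class GLMFit:
    betas: dict[str, float]
    intercepts: np.ndarray
    r_squared: float
    residual: np.ndarray
    t_values: dict[str, float] = field(default_factory=dict)
    df: int = 0


def fit_temporal_glm(course: np.ndarray, design: TemporalDesign) -> GLMFit:
    """OLS fit of one laminar time course against the temporal design.

    R^2 is computed on the high-pass-filtered data around per-run means.
    Raises on rank deficiency, naming the collinear columns.
    """
    course = np.asarray(course, dtype=float)
    if course.shape != (design.n_vols,):
        raise ValueError("course length does not match the design")
    y = design.filter_data(course)
    x = design.matrix()
    q, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    bad = diag < 1e-10 * max(diag.max(), 1.0)
    if bad.any():
        cols = [design.column_names()[i] for i in np.flatnonzero(bad)]
        raise np.linalg.LinAlgError(f"temporal design is rank deficient; "
                                    f"collinear columns: {cols}")
    beta = np.linalg.solve(r, q.T @ y)
    resid = y - x @ beta
    y_centered = y.copy()
    for sl in design.run_slices:
        y_centered[sl] -= y[sl].mean()
    ss_tot = float((y_centered**2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else np.nan
    n_int = len(design.interest_names)
    betas = dict(zip(design.interest_names, beta[:n_int]))
    # per-regressor t statistics (the filtered cosine dofs are not discounted,
    # which is immaterial for the null-calibration checks these serve)
    df = design.n_vols - x.shape[1]
    sigma2 = float((resid**2).sum()) / df if df > 0 else np.nan
    rinv = np.linalg.inv(r)
    var_beta = sigma2 * np.einsum("ij,ij->i", rinv, rinv)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / np.sqrt(var_beta)
    t_values = dict(zip(design.interest_names, tvals[:n_int]))
    return GLMFit(betas=betas, intercepts=beta[-design.intercepts.shape[1]:],
                  r_squared=r2, residual=resid, t_values=t_values, df=df)


def orientation_specific_response(betas_by_roi: dict[int, dict[str, dict[str, float]]],
                                  ) -> pd.DataFrame:
    """Preferred-minus-nonpreferred subtraction, averaged over the two ROIs.

    ``betas_by_roi[preference][layer]`` maps interest-regressor names (e.g.
    ``present_45``) to betas.  Returns tidy rows (layer, stimulus, amplitude).
    """
    for pref in (45, 135):
        if pref not in betas_by_roi:
            raise ValueError(f"missing betas for the {pref}-preferring ROI")
    layers = list(next(iter(betas_by_roi.values())).keys())
    rows = []
    for layer in layers:
        for stim in ("present", "omission"):
            vals = []
            for pref in (45, 135):
                b = betas_by_roi[pref][layer]
                nonpref = 135 if pref == 45 else 45
                for key in (f"{stim}_{pref}", f"{stim}_{nonpref}"):
                    if key not in b:
                        raise ValueError(f"missing condition {key} for ROI {pref}")
                vals.append(b[f"{stim}_{pref}"] - b[f"{stim}_{nonpref}"])
            rows.append({"layer": layer, "stimulus": stim,
                         "amplitude": float(np.mean(vals))})
    return pd.DataFrame(rows)
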