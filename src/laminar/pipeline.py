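"""End-to-end orchestration of the synthetic laminar analysis.

A :class:`PipelineConfig` fully determines a run: phantom geometry, session
design, ground-truth amplitudes, and the analysis parameters (activation
threshold t > 2.3, 500 voxels per orientation, 128-s high-pass, ...).  The
pipeline executes simulate -> layer -> (register) -> select -> extract ->
fit -> reduce, is deterministic given the master seed, and can archive every
stage's outputs with a manifest.

Group-level analysis helpers reduce many subjects' effect tables with the
repeated-measures testing scheme (3-way stimulus x layer x task ANOVA,
2-way follow-ups, per-layer paired t tests).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import design as design_mod
from .bold import (DEFAULT_TR_S, BOLDRun, GroundTruthAmplitudes, default_truth,
                   simulate_bold, simulate_localizer)
from .design import simulate_design, write_events_tsv
from .extraction import compartment_intensity, interpolation_extract, spatial_glm
from .layering import (LayerVolumeMatrix, compute_sdf, equivolume_surfaces,
                       layer_volume_distribution)
from .phantom import GM_LAYERS, PhantomSpec, make_cortical_phantom
from .response import build_design, fit_temporal_glm, orientation_specific_response
from .roi import balance_layers, localizer_glm, select_rois, weight_timecourses
from .stats import paired_t, rm_anova, within_subject_sem

logger = logging.getLogger(__name__)

STAGES = ("simulate", "layer", "register", "select", "extract", "fit")


@dataclass
class PipelineConfig:
    """Resolved configuration of a synthetic pipeline run."""

    seed: int = 0
    #: default geometry is a curved ribbon: voxels then sample the layers at
    #: all phases, which keeps the 5-compartment design matrix well conditioned
    phantom: dict = field(default_factory=lambda: {
        "shape": "cylinder-annulus", "wm_radius_mm": 4.0, "pial_radius_mm": 6.4,
        "grid_shape": (20, 20, 8)})
    design: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)
    localizer: dict = field(default_factory=dict)
    tr_s: float = DEFAULT_TR_S
    subdivision: int = 4
    sdf_source: str = "analytic"        # "analytic" | "mesh"
    registration_enabled: bool = False
    registration: dict = field(default_factory=dict)   # recursive_bbr options
    activation_t: float = 2.3
    n_per_orientation: int = 500
    balance: bool = False
    weighting: str = "weighted"         # "weighted" | "raw"
    estimator: str = "glm"              # "glm" | "interpolation"
    scale: str = "au"                   # "au" | "percent"
    hp_cutoff_s: float | None = 128.0

    def __post_init__(self) -> None:
        if self.sdf_source not in ("analytic", "mesh"):
            raise ValueError("sdf_source must be 'analytic' or 'mesh'")
        if self.weighting not in ("weighted", "raw"):
            raise ValueError("weighting must be 'weighted' or 'raw'")
        if self.estimator not in ("glm", "interpolation"):
            raise ValueError("estimator must be 'glm' or 'interpolation'")
        if self.scale not in ("au", "percent"):
            raise ValueError("scale must be 'au' or 'percent'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")

        def tuplify(v):
            if isinstance(v, list):
                return tuple(tuplify(x) for x in v)
            if isinstance(v, dict):
                return {k: tuplify(x) for k, x in v.items()}
            return v

        return cls(**{k: tuplify(v) for k, v in raw.items()})

    def to_yaml(self, path: str | Path) -> None:
        def listify(v):
            if isinstance(v, tuple):
                return [listify(x) for x in v]
            if isinstance(v, dict):
                return {k: listify(x) for k, x in v.items()}
            return v

        payload = {k: listify(v) for k, v in dataclasses.asdict(self).items()}
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    effects: pd.DataFrame            # layer x stimulus x task orientation-specific amplitude
    r_squared: dict[str, float]      # per layer, pooled over ROIs/tasks
    roi_sizes: dict[int, int]
    compartment_intensity: np.ndarray
    layer_matrix: LayerVolumeMatrix
    truth: GroundTruthAmplitudes
    manifest: list[dict]


class SyntheticSession:
    """Caches the simulated session so selection-stage parameters can be
    varied (e.g. the voxel-count sweep) without re-simulating."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.manifest: list[dict] = []
        self._simulated = False
        self._layered = False

    # -- stages -----------------------------------------------------------
    def _record(self, stage: str, t0: float, **info) -> None:
        self.manifest.append({"stage": stage, "wall_s": round(time.time() - t0, 3),
                              "seed": self.config.seed, "config": self.config.digest(),
                              **info})

    def simulate(self) -> None:
        if self._simulated:
            return
        cfg = self.config
        t0 = time.time()
        ss = np.random.SeedSequence(cfg.seed)
        seeds = [int(s) for s in ss.generate_state(8) % (2**31)]
        self.spec = PhantomSpec(**{"seed": seeds[0], **cfg.phantom})
        self.surfaces, self.preference, self.geometry = make_cortical_phantom(self.spec)
        self.design = simulate_design(seed=seeds[1], **cfg.design)
        self.truth = default_truth() if not cfg.truth else _truth_from_dict(cfg.truth)
        self.fractions_true = self.geometry.compartment_fractions(cfg.subdivision)
        self.runs: list[BOLDRun] = []
        for i, run in enumerate(sorted(self.design["run"].unique())):
            rows = self.design[self.design["run"] == run]
            self.runs.append(simulate_bold(self.geometry, self.preference, rows,
                                           self.truth, tr_s=cfg.tr_s, seed=seeds[2 + i],
                                           fractions=self.fractions_true))
        self.localizer_run, self.localizer_blocks = simulate_localizer(
            self.geometry, self.preference, tr_s=cfg.tr_s, seed=seeds[7],
            fractions=self.fractions_true, noise_sd=self.truth.noise_sd,
            **cfg.localizer)
        self._simulated = True
        self._record("simulate", t0, n_runs=len(self.runs),
                     n_trials=len(self.design))

    def layer(self) -> None:
        if self._layered:
            return
        self.simulate()
        cfg = self.config
        t0 = time.time()
        grid = self.geometry.grid
        wm_mesh, pial_mesh = self.surfaces.wm, self.surfaces.pial
        if cfg.registration_enabled:
            from scipy.spatial import cKDTree

            from .registration import recursive_bbr

            mean_epi = np.mean([r.mean_volume() for r in self.runs], axis=0)
            verts = np.asarray(wm_mesh.vertices)
            # register only vertices whose boundary samples stay inside the
            # volume (phantom meshes pad past the grid for SDF accuracy);
            # uncovered vertices keep zero displacement
            margin = 1.5
            lo = np.asarray(grid.origin_mm) + margin
            hi = lo + np.asarray(grid.shape) * grid.voxel_size_mm - 2 * margin
            inside = np.all((verts > lo) & (verts < hi), axis=1)
            field_ = recursive_bbr(mean_epi, grid, verts[inside],
                                   np.asarray(wm_mesh.vertex_normals)[inside],
                                   **cfg.registration)
            self.displacement_field = field_
            self._record("register", t0,
                         contrast_global=field_.contrast_global,
                         contrast_recursive=field_.contrast_recursive)
            disp = np.zeros_like(verts)
            disp[inside] = field_.displacement
            wm_mesh = wm_mesh.copy()
            wm_mesh.vertices = verts + disp
            # carry the WM displacement to the nearest pial vertices
            _, nearest = cKDTree(verts).query(np.asarray(pial_mesh.vertices))
            pial_mesh = pial_mesh.copy()
            pial_mesh.vertices = np.asarray(pial_mesh.vertices) + disp[nearest]
        if cfg.sdf_source == "mesh" or cfg.registration_enabled:
            wm_sdf = compute_sdf(wm_mesh, grid)
            pial_sdf = compute_sdf(pial_mesh, grid)
        else:
            pts = grid.voxel_centers()
            wm_sdf = self.geometry.sdf_wm(pts).reshape(grid.shape)
            pial_sdf = self.geometry.sdf_pial(pts).reshape(grid.shape)
        self.level_set = equivolume_surfaces(wm_sdf, pial_sdf, grid)
        self.layer_matrix = layer_volume_distribution(self.level_set, grid,
                                                      cfg.subdivision)
        self._layered = True
        self._record("layer", t0, sdf_source=cfg.sdf_source)

    def select(self, n_per_orientation: int | None = None):
        self.layer()
        cfg = self.config
        t0 = time.time()
        stats = localizer_glm(self.localizer_run, self.localizer_blocks)
        gm_mask = (self.layer_matrix.gm_fraction > 0).reshape(self.geometry.grid.shape)
        rois = select_rois(stats, gm_mask, activation_t=cfg.activation_t,
                           n_per_orientation=n_per_orientation or cfg.n_per_orientation)
        if cfg.balance:
            from .roi import ROISet

            i45, _ = balance_layers(rois.idx_45, self.layer_matrix)
            i135, _ = balance_layers(rois.idx_135, self.layer_matrix)
            keep45 = np.isin(rois.idx_45, i45)
            keep135 = np.isin(rois.idx_135, i135)
            rois = ROISet(idx_45=rois.idx_45[keep45], idx_135=rois.idx_135[keep135],
                          weight_45=rois.weight_45[keep45],
                          weight_135=rois.weight_135[keep135])
        self._record("select", t0, n_45=len(rois.idx_45), n_135=len(rois.idx_135))
        return stats, rois

    def effects(self, n_per_orientation: int | None = None) -> PipelineResult:
        """Run selection through temporal-GLM reduction; returns the result."""
        cfg = self.config
        _, rois = self.select(n_per_orientation)
        t0 = time.time()
        extract = spatial_glm if cfg.estimator == "glm" else interpolation_extract
        n_vols_by_run = {r: run.n_vols for r, run in enumerate(self.runs)}
        motion_by_run = {r: run.motion for r, run in enumerate(self.runs)}

        effects_frames = []
        r2_acc: dict[str, list[float]] = {lay: [] for lay in GM_LAYERS}
        for task in design_mod.TASKS:
            tdesign = build_design(self.design, motion_by_run, n_vols_by_run,
                                   cfg.tr_s, task, cfg.hp_cutoff_s)
            task_runs = sorted(self.design[self.design["task"] == task]["run"].unique())
            betas_by_roi: dict[int, dict[str, dict[str, float]]] = {}
            for pref in (45, 135):
                panels = weight_timecourses(self.runs, rois.indices(pref),
                                            rois.weights(pref), mode=cfg.weighting)
                courses = []
                for r in task_runs:
                    panel = panels[r]
                    x = self.layer_matrix.fractions[_rows_for(self.layer_matrix,
                                                              panel.voxel_idx)]
                    courses.append(extract(panel.values, x).gm())
                course_cat = np.concatenate(courses, axis=1)  # (3, T_task)
                layer_betas: dict[str, dict[str, float]] = {}
                for li, layer in enumerate(GM_LAYERS):
                    fit = fit_temporal_glm(course_cat[li], tdesign)
                    betas = fit.betas
                    if cfg.scale == "percent":
                        b0 = float(np.mean(fit.intercepts))
                        betas = {k: 100.0 * v / b0 for k, v in betas.items()}
                    layer_betas[layer] = betas
                    r2_acc[layer].append(fit.r_squared)
                betas_by_roi[pref] = layer_betas
            frame = orientation_specific_response(betas_by_roi)
            frame["task"] = task
            effects_frames.append(frame)
        effects = pd.concat(effects_frames, ignore_index=True)

        mean_epi = np.mean([r.mean_volume() for r in self.runs], axis=0)
        comp_int = compartment_intensity(mean_epi, self.layer_matrix.fractions)
        self._record("fit", t0, estimator=cfg.estimator, scale=cfg.scale)
        return PipelineResult(
            effects=effects,
            r_squared={lay: float(np.mean(v)) for lay, v in r2_acc.items()},
            roi_sizes={45: len(rois.idx_45), 135: len(rois.idx_135)},
            compartment_intensity=comp_int,
            layer_matrix=self.layer_matrix,
            truth=self.truth,
            manifest=self.manifest,
        )


def _rows_for(matrix: LayerVolumeMatrix, flat_idx: np.ndarray) -> np.ndarray:
    # full-grid matrices are stored in C order, so flat index == row index
    if matrix.grid_shape is None:
        raise ValueError("layer matrix lacks grid shape")
    n = int(np.prod(matrix.grid_shape))
    if len(matrix.fractions) == n:
        return np.asarray(flat_idx)
    flat = np.ravel_multi_index(matrix.voxel_indices.T, matrix.grid_shape)
    lookup = {f: i for i, f in enumerate(flat)}
    return np.array([lookup[f] for f in np.asarray(flat_idx)])


def _truth_from_dict(d: dict) -> GroundTruthAmplitudes:
    base = default_truth()
    kwargs = {"amplitude": np.asarray(d.get("amplitude", base.amplitude)),
              "bias_gain": np.asarray(d.get("bias_gain", base.bias_gain)),
              "noise_sd": d.get("noise_sd", base.noise_sd),
              "drift_pct": d.get("drift_pct", base.drift_pct)}
    unknown = set(d) - {"amplitude", "bias_gain", "noise_sd", "drift_pct"}
    if unknown:
        raise ValueError(f"unknown truth keys: {sorted(unknown)}")
    return GroundTruthAmplitudes(**kwargs)


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute the full synthetic pipeline; optionally archive outputs."""
    session = SyntheticSession(config)
    result = session.effects()
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")
        write_events_tsv(session.design, out / "events.tsv")
        session.truth.to_json(out / "truth.json")
        result.effects.to_csv(out / "effects.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
    return result


def voxel_count_sweep(config: PipelineConfig,
                      n_list: tuple[int, ...] = tuple(range(100, 1001, 100)),
                      ) -> pd.DataFrame:
    """Orientation-specific amplitudes as a function of ROI size.

    Simulation and layering are shared across sweep points; only the
    selection-onward stages are repeated per requested voxel count.
    """
    session = SyntheticSession(config)
    frames = []
    for n in n_list:
        res = session.effects(n_per_orientation=n)
        f = res.effects.copy()
        f["n_per_orientation"] = n
        f["n_selected"] = min(res.roi_sizes.values())
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def analyze_group(tables: pd.DataFrame) -> dict:
    """The repeated-measures testing scheme on a stacked group effects table.

    Expects tidy columns (subject, layer, stimulus, task, amplitude).
    Returns the 3-way ANOVA, the stimulus x layer 2-way ANOVA, the per-layer
    omission and presentation t tests against zero, and within-subject SEMs.
    """
    res: dict = {}
    res["anova_3way"] = rm_anova(tables, within=["stimulus", "layer", "task"])
    res["anova_stimulus_by_layer"] = rm_anova(tables, within=["stimulus", "layer"])
    for stim in ("present", "omission"):
        sub = tables[tables["stimulus"] == stim]
        res[f"anova_task_by_layer_{stim}"] = rm_anova(sub, within=["task", "layer"])
        res[f"t_{stim}"] = {}
        for layer in GM_LAYERS:
            cell = (sub[sub["layer"] == layer]
                    .groupby("subject")["amplitude"].mean().to_numpy())
            res[f"t_{stim}"][layer] = paired_t(cell, np.zeros_like(cell))
    wide = tables.pivot_table(index="subject", values="amplitude",
                              columns=["stimulus", "layer"], observed=True)
    res["within_subject_sem"] = {f"{s}_{l}": float(v)
                                 for (s, l), v in within_subject_sem(wide).items()}
    return res
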