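"""Forward BOLD simulation on cortical phantoms with known laminar truth.

Each voxel's signal is a baseline intensity determined by its compartment
mix (grey matter brighter than white matter and CSF in the mean EPI),
modulated by layer-specific, condition-specific percent-signal-change
amplitudes convolved with the canonical HRF, plus slow drift and Gaussian
thermal noise.  Layer mixing uses the phantom's *analytic* compartment
fractions, so the simulator shares no geometry code with the layering
module it is used to validate.

The condition structure mirrors the cued-orientation paradigm: amplitudes
are indexed by layer (deep/middle/superficial), stimulus (present/omitted),
voxel preference (preferred/non-preferred orientation) and task
(orientation/contrast).  The default truth injects an orientation-specific
response in all layers when a grating is presented and a deep-layer-only
orientation-specific response when it is merely expected (and only while
orientation is task relevant), with a multiplicative superficial sampling
bias on top.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import design as design_mod
from .grid import Grid
from .hrf import event_regressor
from .phantom import GM_LAYERS, TruthGeometry

#: default volume acquisition time of the 3D EPI sequence (s)
DEFAULT_TR_S = 3.583

#: mean EPI intensity per compartment (WM, deep, middle, superficial, CSF):
#: grey matter sits ~455-461, white matter and out-of-brain signal ~430
DEFAULT_INTENSITY = (427.0, 455.0, 456.0, 461.0, 430.0)

STIMULI = ("present", "omitted")
PREFERENCE = ("preferred", "nonpreferred")


@dataclass
class GroundTruthAmplitudes:
    """Injected laminar response amplitudes, in percent signal change.

    ``amplitude[layer, stimulus, preference, task]`` with axes ordered
    (deep, middle, superficial) x (present, omitted) x (preferred,
    nonpreferred) x (orientation, contrast).  ``bias_gain`` multiplies the
    response per layer to emulate the draining-vein bias toward the
    cortical surface; ``noise_sd`` is the thermal noise SD in raw intensity
    units (the default puts grey-matter tSNR near 12.5).
    """

    amplitude: np.ndarray
    bias_gain: np.ndarray = field(default_factory=lambda: np.array([0.9, 1.0, 1.2]))
    noise_sd: float = 36.6
    drift_pct: float = 0.5

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.bias_gain = np.asarray(self.bias_gain, dtype=float)
        if self.amplitude.shape != (3, 2, 2, 2):
            raise ValueError("amplitude must have shape (3 layers, 2 stimuli, "
                             "2 preferences, 2 tasks)")
        if not np.all(np.isfinite(self.amplitude)):
            raise ValueError("amplitudes must be finite")
        if self.bias_gain.shape != (3,) or np.any(self.bias_gain <= 0):
            raise ValueError("bias gains must be three positive values")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")

    def orientation_specific(self) -> np.ndarray:
        """(layer, stimulus, task) preferred-minus-nonpreferred amplitude,
        including the per-layer bias gain — the quantity the analysis
        pipeline estimates."""
        diff = self.amplitude[:, :, 0, :] - self.amplitude[:, :, 1, :]
        return diff * self.bias_gain[:, None, None]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "amplitude": self.amplitude.tolist(),
            "bias_gain": self.bias_gain.tolist(),
            "noise_sd": self.noise_sd,
            "drift_pct": self.drift_pct,
            "axes": ["layer(deep,middle,superficial)", "stimulus(present,omitted)",
                     "preference(preferred,nonpreferred)", "task(orientation,contrast)"],
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthAmplitudes":
        d = json.loads(Path(path).read_text())
        return cls(amplitude=np.asarray(d["amplitude"]), bias_gain=np.asarray(d["bias_gain"]),
                   noise_sd=d["noise_sd"], drift_pct=d.get("drift_pct", 0.0))


def default_truth(noise_sd: float = 36.6) -> GroundTruthAmplitudes:
    """Effect structure emulating the study's findings: presented gratings
    drive orientation-specific responses in every layer; omitted-but-expected
    gratings drive a deep-layer-only orientation-specific response, and only
    when orientation is the task-relevant feature.  Omission responses are
    mildly negative overall (no-stimulus trials in a stimulus-rich run)."""
    amp = np.zeros((3, 2, 2, 2))
    amp[:, 0, 0, :] = 1.2    # present, preferred, both tasks
    amp[:, 0, 1, :] = 1.0    # present, non-preferred
    amp[:, 1, :, :] = -0.2   # omissions slightly below baseline
    amp[0, 1, 0, 0] += 0.12  # deep-layer expectation signal, orientation task only
    return GroundTruthAmplitudes(amplitude=amp, noise_sd=noise_sd)


@dataclass
class BOLDRun:
    """A single 4D functional run with its acquisition metadata."""

    data: np.ndarray              # (nx, ny, nz, T)
    tr_s: float
    affine: np.ndarray
    motion: pd.DataFrame          # T rows x 6 rigid-body parameters

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise ValueError("TR must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data must be finite")
        if abs(np.linalg.det(np.asarray(self.affine)[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")

    @property
    def n_vols(self) -> int:
        return self.data.shape[-1]

    def mean_volume(self) -> np.ndarray:
        return self.data.mean(axis=-1)

    def to_nifti(self):
        import nibabel as nib

        img = nib.Nifti1Image(self.data.astype(np.float32), np.asarray(self.affine))
        img.header.set_zooms((*img.header.get_zooms()[:3], self.tr_s))
        return img

    def save(self, bold_path: str | Path, motion_path: str | Path | None = None) -> None:
        self.to_nifti().to_filename(str(bold_path))
        if motion_path is not None:
            self.motion.to_csv(motion_path, sep="\t", index=False)

    @classmethod
    def load(cls, bold_path: str | Path, motion_path: str | Path | None = None) -> "BOLDRun":
        import nibabel as nib

        img = nib.load(str(bold_path))
        tr = float(img.header.get_zooms()[3])
        if motion_path is not None:
            motion = pd.read_csv(motion_path, sep="\t")
        else:
            motion = _zero_motion(img.shape[-1])
        return cls(data=np.asarray(img.dataobj, dtype=float), tr_s=tr,
                   affine=img.affine, motion=motion)


def _zero_motion(n_vols: int) -> pd.DataFrame:
    cols = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    return pd.DataFrame(np.zeros((n_vols, 6)), columns=cols)


def _condition_amplitude_map(fractions: np.ndarray, preference_flat: np.ndarray,
                             truth: GroundTruthAmplitudes, stim: int, orient: int,
                             task: int) -> np.ndarray:
    """Per-voxel percent amplitude for one (stimulus, orientation) condition."""
    gains = truth.bias_gain
    amp_pref = fractions[:, 1:4] @ (gains * truth.amplitude[:, stim, 0, task])
    amp_nonpref = fractions[:, 1:4] @ (gains * truth.amplitude[:, stim, 1, task])
    return np.where(preference_flat == orient, amp_pref, amp_nonpref)


def simulate_bold(geometry: TruthGeometry, preference_map: np.ndarray,
                  run_design: pd.DataFrame, truth: GroundTruthAmplitudes,
                  tr_s: float = DEFAULT_TR_S, seed: int = 0,
                  intensity=DEFAULT_INTENSITY, subdivision: int = 4,
                  fractions: np.ndarray | None = None,
                  motion_sd_mm: float = 0.0, apply_motion: bool = False) -> BOLDRun:
    """Simulate one functional run for the trials in ``run_design``.

    Motion, when requested, is a bounded random walk of rigid translations
    (|shift| <= 1 voxel); by default it is recorded in the motion table but
    not applied to the data, since volume realignment is treated as an
    upstream preprocessing step.
    """
    grid = geometry.grid
    if preference_map.shape != tuple(grid.shape):
        raise ValueError("preference map shape does not match the phantom grid")
    tasks = run_design["task"].unique()
    if len(tasks) != 1:
        raise ValueError("a run must contain a single task")
    task = list(design_mod.TASKS).index(tasks[0])
    rng = np.random.default_rng(seed)

    if fractions is None:
        fractions = geometry.compartment_fractions(subdivision)
    baseline = fractions @ np.asarray(intensity, dtype=float)

    run = run_design["run"].iloc[0]
    duration = design_mod.run_duration_s(run_design, run)
    n_vols = int(np.ceil(duration / tr_s))
    if run_design["grating_onset_s"].max() >= n_vols * tr_s:
        raise ValueError("design onsets do not fit within the run duration")

    pref_flat = preference_map.reshape(-1)
    pct = np.zeros((grid.n_voxels, n_vols))
    for stim, stim_name in enumerate(("present", "omission")):
        for orient in (45, 135):
            rows = run_design[(run_design["trial_type"] == stim_name)
                              & (run_design["cued_orientation_deg"] == orient)]
            if not len(rows):
                continue
            reg = event_regressor(rows["grating_onset_s"].to_numpy(), n_vols, tr_s)
            amp = _condition_amplitude_map(fractions, pref_flat, truth, stim, orient, task)
            pct += np.outer(amp, reg)

    t = np.arange(n_vols) * tr_s
    drift = truth.drift_pct * ((t / t[-1] - 0.5) + 0.3 * np.cos(2 * np.pi * t / 300.0)) \
        if n_vols > 1 else np.zeros(1)
    data = baseline[:, None] * (1.0 + pct / 100.0 + drift[None, :] / 100.0)
    if truth.noise_sd > 0:
        data = data + rng.normal(0.0, truth.noise_sd, size=data.shape)
    data = data.reshape(*grid.shape, n_vols)

    motion = _zero_motion(n_vols)
    if motion_sd_mm > 0:
        walk = np.cumsum(rng.normal(0, motion_sd_mm, size=(n_vols, 3)), axis=0)
        walk = np.clip(walk, -grid.voxel_size_mm, grid.voxel_size_mm)
        motion.iloc[:, :3] = walk
        if apply_motion:
            shift_vox = walk / grid.voxel_size_mm
            for v in range(n_vols):
                data[..., v] = ndimage.shift(data[..., v], shift_vox[v], order=1,
                                             mode="nearest")
    return BOLDRun(data=data, tr_s=tr_s, affine=grid.affine, motion=motion)


def simulate_localizer(geometry: TruthGeometry, preference_map: np.ndarray,
                       n_blocks: int = 16, block_vols: int = 4,
                       tr_s: float = DEFAULT_TR_S, seed: int = 0,
                       amp_preferred: float = 2.0, amp_nonpreferred: float = 1.0,
                       noise_sd: float = 36.6, intensity=DEFAULT_INTENSITY,
                       subdivision: int = 4, fractions: np.ndarray | None = None,
                       ) -> tuple[BOLDRun, pd.DataFrame]:
    """Simulate the orientation localizer: alternating blocks of flickering
    45/135-degree gratings (default 16 blocks of 4 volumes, ~14.3 s)
    separated by equal rest, in pseudorandom order with equal counts."""
    if n_blocks % 2:
        raise ValueError("n_blocks must be even so both orientations appear equally")
    grid = geometry.grid
    if preference_map.shape != tuple(grid.shape):
        raise ValueError("preference map shape does not match the phantom grid")
    rng = np.random.default_rng(seed)
    if fractions is None:
        fractions = geometry.compartment_fractions(subdivision)
    baseline = fractions @ np.asarray(intensity, dtype=float)

    orients = np.repeat([45, 135], n_blocks // 2)
    rng.shuffle(orients)
    n_vols = (2 * n_blocks + 1) * block_vols  # rest-block alternation plus lead-in
    onsets = (np.arange(n_blocks) * 2 + 1) * block_vols * tr_s
    blocks = pd.DataFrame({"onset_s": onsets,
                           "duration_s": block_vols * tr_s,
                           "orientation_deg": orients})

    gm = fractions[:, 1:4].sum(axis=1)
    pref_flat = preference_map.reshape(-1)
    pct = np.zeros((grid.n_voxels, n_vols))
    t = np.arange(n_vols) * tr_s
    for orient in (45, 135):
        from .hrf import block_regressor

        onsets = blocks[blocks["orientation_deg"] == orient]["onset_s"].to_numpy()
        reg = block_regressor(onsets, block_vols * tr_s, n_vols, tr_s)
        amp = gm * np.where(pref_flat == orient, amp_preferred, amp_nonpreferred)
        pct += np.outer(amp, reg)

    data = baseline[:, None] * (1.0 + pct / 100.0)
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    run = BOLDRun(data=data.reshape(*grid.shape, n_vols), tr_s=tr_s,
                  affine=grid.affine, motion=_zero_motion(n_vols))
    return run, blocks


def simulate_group_effects(truth: GroundTruthAmplitudes, n_subjects: int = 18,
                           target_deep_omission_t: float = 3.0, seed: int = 0,
                           ) -> pd.DataFrame:
    """Per-subject orientation-specific amplitude tables for group inference.

    Each subject's (layer x stimulus x task) cell gets the ground-truth
    orientation-specific amplitude plus i.i.d. Gaussian between-trial noise
    whose SD is calibrated so the expected group-level t statistic of the
    task-averaged deep-layer omission effect equals the target (default 3,
    emulating the effect size the method is meant to resolve)."""
    mean = truth.orientation_specific()  # (layer, stimulus, task)
    deep_omission = float(mean[0, 1, :].mean())
    if deep_omission == 0:
        raise ValueError("truth has no deep-layer omission effect to calibrate against")
    # task-averaged cell noise has sd sigma/sqrt(2); t = mu sqrt(n) / (sigma/sqrt(2))
    sigma = deep_omission * np.sqrt(2 * n_subjects) / target_deep_omission_t
    rng = np.random.default_rng(seed)
    layers = ("deep", "middle", "superficial")
    stimuli = ("present", "omission")
    tasks = ("orientation", "contrast")
    rows = []
    for s in range(n_subjects):
        noise = rng.normal(0.0, sigma, size=mean.shape)
        for li, layer in enumerate(layers):
            for si, stim in enumerate(stimuli):
                for ti, task in enumerate(tasks):
                    rows.append({"subject": s, "layer": layer, "stimulus": stim,
                                 "task": task,
                                 "amplitude": float(mean[li, si, ti] + noise[li, si, ti])})
    return pd.DataFrame(rows)
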