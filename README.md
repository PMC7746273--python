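# laminar

Layer-specific fMRI analysis with a fully synthetic validation path.

At sub-millimetre resolution (0.8 mm isotropic), fMRI can distinguish the
signals of the deep, middle and superficial layers of human cortex — but no
single voxel respects the laminar boundaries, so every voxel mixes signal
from several depths. This package implements the analysis chain used to ask
*which cortical layers carry top-down expectation signals in V1*: a
participant is cued to expect a grating of a particular orientation; on a
quarter of trials the grating is omitted, isolating the expectation from any
visual input; the laminar profile of the orientation-specific BOLD response
is then compared between presented and merely expected gratings.

Because every stage of such a pipeline is hard to validate on real data,
the package ships a synthetic counterpart for each one: cortical ribbon
phantoms with closed-form geometry, a session/design generator, a
psychophysical staircase simulator, and a forward BOLD model with known
laminar ground truth, so that each analysis stage can be checked against
an exact answer.

## The analysis chain

1. **Equivolume layering** (`laminar.layering`). The white-matter and pial
   surfaces are represented as signed distance functions (SDFs) on the
   functional grid; two intermediate surfaces split grey matter into three
   layers of locally equal volume, converting a volume fraction `f` into a
   distance fraction using the local curvature of the bounding surfaces
   (on a cylinder this reproduces `r_f = sqrt((1-f) r_wm² + f r_pial²)`
   exactly). Sub-voxel sampling of the four boundary SDFs yields each
   voxel's volume distribution over the five compartments
   (WM, deep, middle, superficial, CSF).
2. **Boundary registration** (`laminar.registration`). Affine
   boundary-based registration (BBR) with 7 degrees of freedom (rigid body
   + scale along the phase-encoding axis) maximises the WM/GM intensity
   contrast across the white-matter surface; the recursive variant (RBR)
   re-fits on successively bisected mesh partitions (six iterations, cut
   axes cycling through all six x/y/z orderings) and takes the per-vertex
   median displacement, correcting local EPI distortions.
3. **ROI selection** (`laminar.roi`). A temporal GLM on an orientation
   localizer gives per-voxel T statistics; voxels responding to gratings
   (t > 2.3) are ranked by their 45°-vs-135° preference and the strongest
   500 voxels per orientation are retained, their time courses z-scored
   per run and weighted by |T|.
4. **Laminar unmixing** (`laminar.extraction`). For each functional volume
   the spatial GLM `Y = X·B + ε` regresses the ROI voxel values `Y` on the
   n-voxel × 5-compartment volume matrix `X`, unmixing one time course per
   compartment; the interpolation control `B = XᵀY/N` is available for
   comparison.
5. **Response estimation** (`laminar.response`). A temporal GLM per task
   (events convolved with the canonical double-gamma HRF; motion,
   derivative and squared-derivative nuisance regressors; 128-s
   discrete-cosine high-pass applied to data and design) yields amplitudes
   for presented/omitted × 45°/135° conditions; subtracting the
   non-preferred from the preferred orientation per ROI and averaging over
   the two ROIs gives layer-specific, orientation-specific responses.
6. **Inference** (`laminar.stats`). Repeated-measures ANOVAs (3-way
   stimulus × layer × task and 2-way reductions), paired t tests, and
   within-subject SEMs (Cousineau–Morey) reproduce the testing scheme.

## Worked example

Noiseless end-to-end recovery on a voxel-aligned slab phantom. The injected
truth has an orientation-specific response to *presented* gratings in all
three layers (0.18 / 0.20 / 0.24 % signal change after the superficial-bias
gain) and a deep-layer-only response to *omitted-but-expected* gratings
(0.108 %), present only while orientation is the task-relevant feature:

```python
from laminar.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    seed=7,
    phantom={"shape": "flat-slab", "wm_radius_mm": 0.0, "pial_radius_mm": 2.4,
             "grid_shape": (16, 16, 8), "voxel_size_mm": 0.8,
             "origin_mm": (-6.4, -6.4, -2.4)},
    design={"n_runs": 2, "blocks_per_run": 1, "trials_per_block": 32},
    truth={"noise_sd": 0.0, "drift_pct": 0.0},
    weighting="raw", scale="percent", hp_cutoff_s=None)
result = run_pipeline(cfg)
print(result.effects.pivot_table(index="layer", columns=["stimulus", "task"],
                                 values="amplitude").round(3))
```

prints

```
stimulus    omission              present
task        contrast orientation contrast orientation
layer
deep             0.0       0.108     0.18        0.18
middle          -0.0      -0.000     0.20        0.20
superficial     -0.0       0.000     0.24        0.24
```

i.e. the pipeline recovers the injected laminar amplitude structure exactly
(to numerical precision): presented gratings drive all layers, the
expectation signal appears only in the deep layer and only in the
orientation task.

The same machinery runs from the shell: `laminar run --config cfg.yaml
--out out/` executes the full pipeline and archives events, ground truth,
effects and a stage manifest; `laminar simulate | layer | register |
select | extract | fit | stats | sweep` run individual stages with
standard-format outputs (NIfTI, GIFTI, TSV events, CSV/JSON).

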