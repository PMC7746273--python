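"""Shared fixtures: phantoms, noiseless sessions, and oracle helpers."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from laminar.grid import Grid
from laminar.phantom import PhantomSpec, make_cortical_phantom
from laminar.pipeline import PipelineConfig


@pytest.fixture(scope="session")
def cylinder_phantom():
    """Annulus r_wm = 2, r_pial = 4 mm on a fine grid (closed-form oracles)."""
    spec = PhantomSpec(shape="cylinder-annulus", wm_radius_mm=2.0, pial_radius_mm=4.0,
                       grid_shape=(28, 28, 8), voxel_size_mm=0.4)
    return make_cortical_phantom(spec)


@pytest.fixture(scope="session")
def sphere_phantom():
    spec = PhantomSpec(shape="sphere-shell", wm_radius_mm=2.0, pial_radius_mm=3.0,
                       grid_shape=(24, 24, 24), voxel_size_mm=0.35)
    return make_cortical_phantom(spec)


@pytest.fixture(scope="session")
def slab_phantom():
    spec = PhantomSpec(shape="flat-slab", wm_radius_mm=0.0, pial_radius_mm=2.4,
                       grid_shape=(12, 12, 10), voxel_size_mm=0.8,
                       origin_mm=(-4.8, -4.8, -2.8))
    return make_cortical_phantom(spec)


@pytest.fixture()
def noiseless_config():
    """Voxel-aligned slab, noiseless, raw/percent analysis: exact geometry."""
    return PipelineConfig(
        seed=7,
        phantom={"shape": "flat-slab", "wm_radius_mm": 0.0, "pial_radius_mm": 2.4,
                 "grid_shape": (16, 16, 8), "voxel_size_mm": 0.8,
                 "origin_mm": (-6.4, -6.4, -2.4)},
        design={"n_runs": 2, "blocks_per_run": 1, "trials_per_block": 32},
        truth={"noise_sd": 0.0, "drift_pct": 0.0},
        weighting="raw", scale="percent", hp_cutoff_s=None,
    )


def analytic_sdfs(truth):
    """Evaluate a phantom's analytic boundary SDFs on its own grid."""
    grid = truth.grid
    pts = grid.voxel_centers()
    return (truth.sdf_wm(pts).reshape(grid.shape),
            truth.sdf_pial(pts).reshape(grid.shape))


def rm_anova_oracle(data: np.ndarray) -> dict[tuple[int, ...], dict[str, float]]:
    """Brute-force sums-of-squares partition for a fully within-subject ANOVA.

    ``data`` has the subject on axis 0 and one axis per factor.  For every
    non-empty factor subset A the effect estimate at each A-cell is the
    inclusion-exclusion combination of marginal means, SS is the squared
    estimate summed and scaled by the collapsed cell count, and the error
    term is the matching A-by-subject interaction.  Returns
    ``{factor-axis tuple: {"F", "df_num", "df_den", "p"}}``.
    """
    from scipy.stats import f as f_dist

    data = np.asarray(data, dtype=float)
    n_axes = data.ndim
    factor_axes = tuple(range(1, n_axes))

    def ss_and_df(axes: tuple[int, ...]) -> tuple[float, int]:
        # inclusion-exclusion effect estimate, broadcast to the full array so
        # summing the squares counts each cell its collapsed number of times
        est = np.zeros(data.shape)
        for r in range(len(axes) + 1):
            for sub in itertools.combinations(axes, r):
                other = tuple(a for a in range(n_axes) if a not in sub)
                term = data.mean(axis=other, keepdims=True) if other else data
                est = est + (-1) ** (len(axes) - len(sub)) * term
        df = int(np.prod([data.shape[a] - 1 for a in axes]))
        return float((est**2).sum()), df

    out = {}
    for r in range(1, len(factor_axes) + 1):
        for effect in itertools.combinations(factor_axes, r):
            ss_e, df_e = ss_and_df(effect)
            ss_err, df_err = ss_and_df((0, *effect))
            f = (ss_e / df_e) / (ss_err / df_err)
            out[effect] = {"F": f, "df_num": df_e, "df_den": df_err,
                           "p": float(f_dist.sf(f, df_e, df_err))}
    return out
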