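"""Standard-format I/O: NIfTI volumes, GIFTI surfaces, CSV/TSV tables."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import trimesh

from .grid import Grid
from .layering import LayerVolumeMatrix, LevelSet
from .phantom import COMPARTMENTS


def save_surface_gifti(mesh: trimesh.Trimesh, path: str | Path) -> None:
    img = nib.gifti.GiftiImage(darrays=[
        nib.gifti.GiftiDataArray(np.asarray(mesh.vertices, dtype=np.float32),
                                 intent="NIFTI_INTENT_POINTSET"),
        nib.gifti.GiftiDataArray(np.asarray(mesh.faces, dtype=np.int32),
                                 intent="NIFTI_INTENT_TRIANGLE"),
    ])
    img.to_filename(str(path))


def load_surface_gifti(path: str | Path) -> trimesh.Trimesh:
    img = nib.load(str(path))
    verts = img.darrays[0].data.astype(float)
    faces = img.darrays[1].data.astype(int)
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


def save_surface_csv(mesh: trimesh.Trimesh, vertices_path: str | Path,
                     faces_path: str | Path) -> None:
    pd.DataFrame(mesh.vertices, columns=["x", "y", "z"]).to_csv(vertices_path, index=False)
    pd.DataFrame(mesh.faces, columns=["v0", "v1", "v2"]).to_csv(faces_path, index=False)


def save_level_set(level_set: LevelSet, path: str | Path) -> None:
    """All four boundary SDFs as one 4-volume NIfTI."""
    data = np.moveaxis(level_set.boundaries, 0, -1).astype(np.float32)
    nib.Nifti1Image(data, level_set.grid.affine).to_filename(str(path))


def load_level_set(path: str | Path, grid: Grid) -> LevelSet:
    img = nib.load(str(path))
    return LevelSet(boundaries=np.moveaxis(np.asarray(img.dataobj), -1, 0), grid=grid)


def save_layer_matrix(matrix: LayerVolumeMatrix, path: str | Path) -> None:
    matrix.to_dataframe().to_csv(path, index=False)


def load_layer_matrix(path: str | Path, voxel_volume_mm3: float,
                      grid_shape: tuple[int, int, int] | None = None) -> LayerVolumeMatrix:
    df = pd.read_csv(path)
    return LayerVolumeMatrix(fractions=df[list(COMPARTMENTS)].to_numpy(),
                             voxel_indices=df[["i", "j", "k"]].to_numpy(),
                             voxel_volume_mm3=voxel_volume_mm3, grid_shape=grid_shape)
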