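"""Readers/writers for the pipeline's standard artifact formats.

Volumes go to NIfTI-1 with an RAS affine whose origin places voxel centers at
``(index + 0.5) * voxel_size``, matching the package's geometry convention,
so mesh coordinates and NIfTI world coordinates agree without registration.
Meshes go to OBJ and PLY; per-vertex scalars to CSV keyed by vertex index.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import trimesh


def volume_affine(voxel_size_mm: float) -> np.ndarray:
    aff = np.diag([voxel_size_mm] * 3 + [1.0])
    aff[:3, 3] = 0.5 * voxel_size_mm
    return aff


def save_volume(path, vol: np.ndarray, voxel_size_mm: float) -> Path:
    path = Path(path)
    data = np.asarray(vol)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, volume_affine(voxel_size_mm))
    img.header.set_zooms((voxel_size_mm,) * 3 + (1.0,) * (data.ndim - 3))
    nib.save(img, str(path))
    return path


def load_volume(path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    vs = float(img.header.get_zooms()[0])
    return np.asarray(img.dataobj), vs


def save_mesh(path_stem, surf) -> list[Path]:
    """Export a surface to both OBJ and PLY next to the given stem."""
    out = []
    for ext in ("obj", "ply"):
        p = Path(f"{path_stem}.{ext}")
        surf.mesh.export(str(p))
        out.append(p)
    return out


def load_mesh(path) -> trimesh.Trimesh:
    return trimesh.load_mesh(str(path), process=False)


def save_vertex_table(path, surf, extra: dict | None = None) -> Path:
    """Per-vertex scalar table (CSV keyed by vertex index)."""
    df = pd.DataFrame(
        {
            "vertex": np.arange(surf.n_vertices),
            "x_mm": surf.vertices[:, 0],
            "y_mm": surf.vertices[:, 1],
            "z_mm": surf.vertices[:, 2],
            "area_mm2": surf.vertex_area,
            "mean_curvature": surf.mean_curvature,
            "region": surf.region_mask.astype(int)
            if surf.region_mask is not None
            else 0,
        }
    )
    for k, v in (extra or {}).items():
        df[k] = v
    df.to_csv(path, index=False)
    return Path(path)


def save_json(path, obj) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def load_json(path):
    return json.loads(Path(path).read_text())
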