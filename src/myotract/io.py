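"""File I/O: NIfTI volumes, bval/bvec encoding tables, TRK streamlines, CSV.

Arrays are kept in (row, col, slice) index order; the NIfTI affine is
diagonal in the voxel dimensions so physical coordinates follow the same
axes.  Streamlines are written both as TRK (for tractography viewers) and
as plain CSV (tract id, point index, row, col, slice), since many muscle
architecture workflows have no tractography readers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import EncodingScheme
from .seeding import SeedSet
from .tracking import SmoothedStreamline, Streamline

__all__ = [
    "save_volume",
    "load_volume",
    "save_encoding",
    "load_encoding",
    "save_trk",
    "load_trk",
    "seeds_to_csv",
    "seeds_from_csv",
    "tracts_to_csv",
    "tracts_from_csv",
]


def _affine(voxel_dims_mm) -> np.ndarray:
    return np.diag([voxel_dims_mm[0], voxel_dims_mm[1], voxel_dims_mm[2], 1.0])


def save_volume(path, array: np.ndarray, voxel_dims_mm) -> None:
    """Write an array as NIfTI with voxel dimensions in the header."""
    img = nib.Nifti1Image(np.asarray(array, dtype=np.float32), _affine(voxel_dims_mm))
    img.header.set_zooms(tuple(voxel_dims_mm) + (1.0,) * (array.ndim - 3))
    nib.save(img, str(path))


def load_volume(path):
    """Read a NIfTI volume; returns (array, voxel_dims_mm, affine)."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such volume: {p}")
    img = nib.load(str(p))
    arr = np.asarray(img.dataobj, dtype=float)
    zooms = img.header.get_zooms()[:3]
    return arr, tuple(float(z) for z in zooms), img.affine


def save_encoding(prefix, scheme: EncodingScheme) -> None:
    """Write the scheme as a bval/bvec plain-text pair.

    ``<prefix>.bval`` holds one line of b-values; ``<prefix>.bvec`` holds
    three lines (x, y, z components), one column per image.
    """
    prefix = Path(prefix)
    np.savetxt(prefix.with_suffix(".bval"), scheme.b_values[None, :], fmt="%.6g")
    np.savetxt(prefix.with_suffix(".bvec"), scheme.directions.T, fmt="%.9f")


def load_encoding(prefix) -> EncodingScheme:
    prefix = Path(prefix)
    bvals = np.loadtxt(prefix.with_suffix(".bval")).ravel()
    bvecs = np.loadtxt(prefix.with_suffix(".bvec"))
    if bvecs.shape[0] != 3:
        raise ValueError("bvec table must have 3 rows")
    if bvecs.shape[1] != len(bvals):
        raise ValueError(
            f"encoding mismatch: {len(bvals)} b-values vs {bvecs.shape[1]} directions"
        )
    return EncodingScheme(directions=bvecs.T.copy(), b_values=bvals)


def _points_to_xyz_mm(points_vox: np.ndarray, voxel_dims_mm) -> np.ndarray:
    """(row, col, slice) voxel coords -> (x, y, z) mm for TRK export."""
    out = np.empty_like(points_vox, dtype=float)
    out[:, 0] = points_vox[:, 0] * voxel_dims_mm[0]
    out[:, 1] = points_vox[:, 1] * voxel_dims_mm[1]
    out[:, 2] = points_vox[:, 2] * voxel_dims_mm[2]
    return out


def save_trk(path, tracts_points_vox: Sequence[np.ndarray], voxel_dims_mm, shape) -> None:
    """Write streamlines in TRK with the volume's voxel-to-mm affine."""
    streams = [_points_to_xyz_mm(np.asarray(p, dtype=float), voxel_dims_mm) for p in tracts_points_vox]
    tractogram = nib.streamlines.Tractogram(streams, affine_to_rasmm=np.eye(4))
    header = {
        "voxel_sizes": tuple(float(v) for v in voxel_dims_mm),
        "dimensions": tuple(int(s) for s in shape),
        "voxel_to_rasmm": _affine(voxel_dims_mm).astype(np.float32),
        "voxel_order": "RAS",
    }
    nib.streamlines.save(nib.streamlines.TrkFile(tractogram, header), str(path))


def load_trk(path, voxel_dims_mm) -> list[np.ndarray]:
    """Read TRK streamlines back into (row, col, slice) voxel coordinates."""
    trk = nib.streamlines.load(str(path))
    out = []
    for s in trk.tractogram.streamlines:
        p = np.asarray(s, dtype=float)
        vox = np.column_stack(
            [p[:, 0] / voxel_dims_mm[0], p[:, 1] / voxel_dims_mm[1], p[:, 2] / voxel_dims_mm[2]]
        )
        out.append(vox)
    return out


def seeds_to_csv(path, seeds: SeedSet) -> None:
    df = pd.DataFrame(
        {
            "scheme": seeds.scheme,
            "row": seeds.points[:, 0],
            "col": seeds.points[:, 1],
            "slice": seeds.points[:, 2],
        }
    )
    if seeds.lookup_voxels is not None:
        df["lookup_row"] = seeds.lookup_voxels[:, 0]
        df["lookup_col"] = seeds.lookup_voxels[:, 1]
        df["lookup_slice"] = seeds.lookup_voxels[:, 2]
    df["skipped"] = seeds.skipped if seeds.skipped is not None else False
    if seeds.normals is not None:
        df[["normal_x", "normal_y", "normal_z"]] = seeds.normals
    if seeds.mesh_index is not None:
        df[["mesh_row", "mesh_col"]] = seeds.mesh_index
    df.to_csv(path, index=False)


def seeds_from_csv(path) -> SeedSet:
    df = pd.read_csv(path)
    points = df[["row", "col", "slice"]].to_numpy(dtype=float)
    lookup = (
        df[["lookup_row", "lookup_col", "lookup_slice"]].to_numpy(dtype=int)
        if "lookup_row" in df
        else None
    )
    normals = (
        df[["normal_x", "normal_y", "normal_z"]].to_numpy(dtype=float)
        if "normal_x" in df
        else None
    )
    mesh_index = (
        df[["mesh_row", "mesh_col"]].to_numpy(dtype=int) if "mesh_row" in df else None
    )
    return SeedSet(
        scheme=str(df["scheme"].iloc[0]) if len(df) else "VXL",
        points=points,
        lookup_voxels=lookup,
        skipped=df["skipped"].to_numpy(dtype=bool) if "skipped" in df else None,
        mesh_index=mesh_index,
        normals=normals,
    )


def tracts_to_csv(path, tracts: Sequence[Streamline] | Sequence[np.ndarray]) -> None:
    """One row per tract point: tract id, point index, row, col, slice."""
    rows = []
    for tid, t in enumerate(tracts):
        pts = t.points if isinstance(t, Streamline) else np.asarray(t)
        for k, p in enumerate(pts):
            rows.append((tid, k, p[0], p[1], p[2]))
    pd.DataFrame(rows, columns=["tract_id", "point", "row", "col", "slice"]).to_csv(
        path, index=False
    )


def tracts_from_csv(path) -> list[np.ndarray]:
    df = pd.read_csv(path)
    return [
        g.sort_values("point")[["row", "col", "slice"]].to_numpy(dtype=float)
        for _, g in df.groupby("tract_id", sort=True)
    ]
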