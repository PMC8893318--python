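"""File I/O for the formats the pipeline touches.

Volumes and masks are NIfTI-1 (``.nii``/``.nii.gz``) or MetaImage
(``.mhd``/``.mha``) read through SimpleITK; arrays are transposed to the
package's (x, y, z) axis order.  Surface meshes are STL, binary or ASCII,
parsed by trimesh and then deduplicated here (STL stores a facet soup; we
merge vertices coincident within 1e-6 mm so faces share vertices).  Cohorts
are described by a CSV manifest; feature tables are CSV and cross-validation
reports JSON, both round-tripping to 1e-12.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import SimpleITK as sitk
import trimesh

from .types import ClinicalRecord, FormatError, SegMask, SurfaceMesh, ValidationError, VolumeImage

VERTEX_MERGE_TOL = 1e-6  # mm; far below voxel scale, removes facet-soup duplicates only

_VOLUME_SUFFIXES = (".nii", ".nii.gz", ".mhd", ".mha")


def _check_volume_path(path: str) -> None:
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    low = str(path).lower()
    if not any(low.endswith(s) for s in _VOLUME_SUFFIXES):
        raise FormatError(f"unsupported volume format (want .nii/.nii.gz/.mhd/.mha): {path}")


def read_volume(path: str) -> VolumeImage:
    """Read a 3-D scalar volume from NIfTI or MetaImage.

    Spacing and origin come from the header.  Raises :class:`FormatError` for
    unreadable or non-3-D files and :class:`ValidationError` for invalid
    header spacing.
    """
    _check_volume_path(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # SimpleITK wraps all reader failures
        raise FormatError(f"could not read volume {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise FormatError(f"expected a 3-D image, got {img.GetDimension()}-D: {path}")
    # sitk arrays are (z, y, x); transpose to this package's (x, y, z)
    data = sitk.GetArrayFromImage(img).astype(float).transpose(2, 1, 0)
    return VolumeImage(data=data, spacing=np.array(img.GetSpacing()), origin=np.array(img.GetOrigin()))


def write_volume(volume: VolumeImage, path: str) -> None:
    img = sitk.GetImageFromArray(volume.data.transpose(2, 1, 0))
    img.SetSpacing(tuple(volume.spacing))
    img.SetOrigin(tuple(volume.origin))
    sitk.WriteImage(img, str(path))


def read_mask(path: str) -> SegMask:
    """Read a binary segmentation mask; any non-zero voxel is foreground."""
    vol = read_volume(path)
    return SegMask(data=(vol.data > 0.5).astype(np.uint8), spacing=vol.spacing, origin=vol.origin)


def write_mask(mask: SegMask, path: str) -> None:
    img = sitk.GetImageFromArray(mask.data.astype(np.uint8).transpose(2, 1, 0))
    img.SetSpacing(tuple(mask.spacing))
    img.SetOrigin(tuple(mask.origin))
    sitk.WriteImage(img, str(path))


def merge_duplicate_vertices(
    vertices: np.ndarray, faces: np.ndarray, tol: float = VERTEX_MERGE_TOL
) -> SurfaceMesh:
    """Merge vertices coincident within ``tol`` so faces share vertices.

    Vertices are snapped to a grid of pitch ``tol``; exact duplicates (the STL
    facet-soup case) land in the same cell and are unified.  Face orientation
    is preserved; faces that collapse to fewer than 3 distinct vertices are
    dropped.
    """
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    key = np.round(vertices / tol).astype(np.int64)
    _, first_idx, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    # keep original coordinates of the first representative of each cell
    new_vertices = vertices[first_idx]
    new_faces = inverse[faces]
    keep = (
        (new_faces[:, 0] != new_faces[:, 1])
        & (new_faces[:, 1] != new_faces[:, 2])
        & (new_faces[:, 0] != new_faces[:, 2])
    )
    new_faces = new_faces[keep]
    if len(new_faces) == 0:
        raise ValidationError("mesh degenerate after vertex merging")
    return SurfaceMesh(vertices=new_vertices, faces=new_faces)


def read_mesh_stl(path: str) -> SurfaceMesh:
    """Read an STL surface (binary or ASCII) and merge duplicate vertices."""
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    try:
        tm = trimesh.load(str(path), file_type="stl", process=False)
    except Exception as exc:
        raise FormatError(f"could not parse STL {path}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise ValidationError(f"STL contains no faces: {path}")
    return merge_duplicate_vertices(np.asarray(tm.vertices), np.asarray(tm.faces))


def write_mesh_stl(mesh: SurfaceMesh, path: str, ascii: bool = False) -> None:
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    if ascii:
        with open(path, "wb") as fh:
            fh.write(trimesh.exchange.stl.export_stl_ascii(tm).encode())
    else:
        tm.export(str(path), file_type="stl")


@dataclass
class CohortEntry:
    case_id: str
    volume_path: str
    mask_path: str
    mesh_path: str
    record: ClinicalRecord


MANIFEST_COLUMNS = ["case_id", "volume", "mask", "mesh", "sex", "age", "ruptured"]


def read_cohort(manifest: str, check_files: bool = True) -> list[CohortEntry]:
    """Read and validate a cohort manifest CSV.

    Columns: case_id, volume, mask, mesh, sex, age, ruptured.  Paths are
    resolved relative to the manifest's directory.  Raises
    :class:`ValidationError` on duplicate ids, unparseable ages, labels
    outside {0, 1}, or (when ``check_files``) missing files, naming the
    offending case ids.
    """
    df = pd.read_csv(manifest, dtype=str)
    missing_cols = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"manifest missing columns: {missing_cols}")
    dup = df["case_id"][df["case_id"].duplicated()].tolist()
    if dup:
        raise ValidationError(f"duplicated case_id in manifest: {sorted(set(dup))}")
    base = os.path.dirname(os.path.abspath(manifest))
    entries = []
    missing_files = []
    for _, row in df.iterrows():
        cid = str(row["case_id"])
        try:
            age = float(row["age"])
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"unparseable age {row['age']!r} for case {cid}") from exc
        lab = str(row["ruptured"]).strip()
        if lab not in ("0", "1"):
            raise ValidationError(f"ruptured label must be 0 or 1, got {lab!r} for case {cid}")
        record = ClinicalRecord(case_id=cid, sex=str(row["sex"]), age=age, ruptured=int(lab))
        paths = {
            kind: os.path.join(base, str(row[kind])) if not os.path.isabs(str(row[kind])) else str(row[kind])
            for kind in ("volume", "mask", "mesh")
        }
        if check_files:
            for kind, p in paths.items():
                if not os.path.exists(p):
                    missing_files.append((cid, kind, p))
        entries.append(
            CohortEntry(
                case_id=cid,
                volume_path=paths["volume"],
                mask_path=paths["mask"],
                mesh_path=paths["mesh"],
                record=record,
            )
        )
    if missing_files:
        detail = "; ".join(f"{cid}: missing {kind} file {p}" for cid, kind, p in missing_files)
        raise ValidationError(f"manifest references missing files: {detail}")
    return entries


def write_feature_table(table: pd.DataFrame, path: str) -> None:
    """Write a per-case feature table (index = case_id) to CSV.

    Values survive a write/read round trip to 1e-12 (full float precision).
    """
    if table.shape[0] == 0 or table.shape[1] == 0:
        raise ValidationError("refusing to write an empty feature table")
    table.to_csv(path, index=True, index_label="case_id", float_format="%.17g")


def read_feature_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, index_col="case_id")


def write_report(report: dict, path: str) -> None:
    """Write a cross-validation report (plain dict of metrics/ROC points) as JSON."""
    if not report:
        raise ValidationError("refusing to write an empty report")

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_default)


def read_report(path: str) -> dict:
    with open(path) as fh:
        return json.load(fh)
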