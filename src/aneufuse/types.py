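"""Core domain containers shared across the pipeline.

All geometry is in millimetres.  Voxel grids use axis order (x, y, z) with
0-based indices; the world position of voxel (i, j, k) is
``origin + index * spacing``.  Surface meshes are plain vertex/face arrays in
the same world frame, so mask-derived and STL-derived geometry are directly
comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ValidationError(ValueError):
    """An input object violates a documented invariant."""


class FormatError(ValueError):
    """A file could not be parsed as the expected format."""


class GeometryError(ValueError):
    """A mesh or mask is geometrically unsuitable for the requested operation."""


@dataclass
class VolumeImage:
    """3-D scalar intensity grid with physical spacing.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Intensity values, arbitrary units.
    spacing : array-like of 3 floats
        Voxel edge lengths in mm per axis; all > 0.
    origin : array-like of 3 floats
        World position (mm) of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError(
                f"volume must be 3-D, got {self.data.ndim}-D shape {self.data.shape}"
            )
        if min(self.data.shape) < 1:
            raise ValidationError(f"all dimensions must be >= 1, got {self.data.shape}")
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValidationError(f"spacing must be 3 positive floats, got {self.spacing}")
        if self.origin.shape != (3,):
            raise ValidationError("origin must be a 3-vector")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class SegMask:
    """Binary lesion mask aligned to a :class:`VolumeImage`."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValidationError(f"mask values must be 0/1, found {uniq[:10]}")
        self.data = arr.astype(bool)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError(f"mask must be 3-D, got shape {arr.shape}")
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValidationError(f"spacing must be 3 positive floats, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_foreground(self) -> int:
        return int(self.data.sum())

    def check_aligned(self, volume: VolumeImage) -> None:
        if self.shape != volume.shape:
            raise ValidationError(
                f"mask shape {self.shape} does not match volume shape {volume.shape}"
            )


@dataclass
class SurfaceMesh:
    """Triangle surface mesh: ``vertices`` (N, 3) in mm, ``faces`` (M, 3) indices."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValidationError(f"vertices must be (N, 3), got {self.vertices.shape}")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValidationError(f"faces must be (M, 3), got {self.faces.shape}")
        if len(self.faces) == 0:
            raise ValidationError("mesh has zero faces")
        n = len(self.vertices)
        if self.faces.min() < 0 or self.faces.max() >= n:
            raise ValidationError("face index out of range")
        f = self.faces
        if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
            raise ValidationError("a face repeats a vertex")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_normals_and_areas(self) -> tuple[np.ndarray, np.ndarray]:
        """Unit face normals and triangle areas (mm^2)."""
        v = self.vertices
        f = self.faces
        cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        norms = np.linalg.norm(cross, axis=1)
        areas = 0.5 * norms
        with np.errstate(invalid="ignore", divide="ignore"):
            normals = cross / norms[:, None]
        return normals, areas

    def edge_manifold_counts(self) -> dict[tuple[int, int], int]:
        """Undirected edge → number of incident faces."""
        f = self.faces
        edges = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        edges = np.sort(edges, axis=1)
        uniq, counts = np.unique(edges, axis=0, return_counts=True)
        return {tuple(e): int(c) for e, c in zip(uniq, counts)}

    def open_edge_count(self) -> int:
        f = self.faces
        edges = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        edges = np.sort(edges, axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return int(np.sum(counts != 2))

    @property
    def is_watertight(self) -> bool:
        """True when every undirected edge is shared by exactly two faces."""
        return self.open_edge_count() == 0


@dataclass
class ClinicalRecord:
    """Per-case clinical covariates and rupture label."""

    case_id: str
    sex: str  # "female" | "male"
    age: float  # years
    ruptured: int  # 0/1

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValidationError(f"sex must be 'female' or 'male', got {self.sex!r}")
        self.age = float(self.age)
        if not np.isfinite(self.age) or self.age < 0:
            raise ValidationError(f"age must be a non-negative number, got {self.age}")
        if self.ruptured not in (0, 1):
            raise ValidationError(f"ruptured label must be 0 or 1, got {self.ruptured!r}")

    @property
    def sex_code(self) -> int:
        """Numeric encoding used at the feature boundary: female=0, male=1."""
        return 0 if self.sex == "female" else 1
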