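"""Synthetic aneurysm-like phantoms with a planted morphology→label signal.

Each case is a randomly oriented ellipsoid whose radius field is perturbed
by a low-order (degree <= 2) real-spherical-harmonic "lobulation", rendered
three ways from the same implicit function:

* a binary mask (voxels inside the implicit surface),
* a grayscale volume (bright lesion on dark background, 1-voxel Gaussian
  smoothing to mimic contrast falloff, additive Gaussian noise),
* a watertight triangle mesh: the exact zero-isosurface of the noise-free
  implicit function, meshed in closed form as a radially deformed icosphere
  (the lesion is star-shaped), in mm.

Rupture labels are drawn from a logistic model on normalized lesion size and
lobulation amplitude, with the intercept bisected so the realized prevalence
lands near the requested target.  The whole cohort is a pure function of
(n, params): per-case randomness comes from ``SeedSequence([seed, case_index])``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import sph_harm_y

from . import io_core
from .types import ClinicalRecord, SegMask, SurfaceMesh, ValidationError, VolumeImage


@dataclass
class PhantomParams:
    """Cohort-level generator settings.

    Defaults emulate the scale of clinical aneurysm data: a 48^3 grid at
    0.5 mm isotropic spacing, lesion semi-axes 3–7 mm, moderate lobulation,
    bright lesion (intensity 100) on dark background (10) with noise sd 2.
    ``signal_coefficients`` are the logistic weights on (normalized max
    radius, normalized lobulation amplitude); the default (20, 10) makes the
    planted signal strong — labels are close to a deterministic threshold on
    the morphology (Bayes-level AUC ~0.98), leaving a label-noise band only
    near the decision boundary.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing: float = 0.5  # mm, isotropic
    lesion_radii: tuple[float, float] = (3.0, 7.0)  # mm, semi-axis range
    lobulation_amplitude: float = 0.25  # max per-case amplitude, dimensionless
    intensity_fg: float = 100.0
    intensity_bg: float = 10.0
    noise_sd: float = 2.0
    signal_coefficients: tuple[float, float] = (20.0, 10.0)
    prevalence_target: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lesion_radii[0] <= 0 or self.lesion_radii[1] < self.lesion_radii[0]:
            raise ValidationError(f"invalid lesion radius range {self.lesion_radii}")
        half_extent = min(self.grid_shape) * self.spacing / 2.0
        # worst case: max radius inflated by lobulation must still fit with margin
        if self.lesion_radii[1] * (1 + self.lobulation_amplitude) >= half_extent - 2 * self.spacing:
            raise ValidationError(
                f"lesion (max radius {self.lesion_radii[1]} mm) does not fit inside "
                f"the grid (half-extent {half_extent} mm)"
            )
        if not 0 <= self.lobulation_amplitude < 1:
            raise ValidationError("lobulation_amplitude must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not 0 < self.prevalence_target < 1:
            raise ValidationError("prevalence_target must be in (0, 1)")


@dataclass
class _CaseGeometry:
    radii: np.ndarray  # 3 semi-axes, mm
    rotation: np.ndarray  # 3x3
    lobulation: float  # realized amplitude
    sh_coeffs: np.ndarray  # real SH coefficients, degree<=2 (ell=2 only), 5 values
    age: float
    sex: str
    label_u: float  # uniform draw consumed by the cohort-level label model


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform rotation via QR of a Gaussian matrix."""
    a = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _draw_geometry(params: PhantomParams, case_seed) -> _CaseGeometry:
    rng = np.random.default_rng(np.random.SeedSequence(case_seed))
    radii = rng.uniform(*params.lesion_radii, size=3)
    rotation = _random_rotation(rng)
    lob = rng.uniform(0.0, params.lobulation_amplitude) if params.lobulation_amplitude > 0 else 0.0
    coeffs = rng.standard_normal(5)
    nrm = np.linalg.norm(coeffs)
    coeffs = coeffs / nrm if nrm > 0 else coeffs
    age = rng.uniform(30.0, 80.0)
    sex = "male" if rng.random() < 0.5 else "female"
    label_u = rng.random()
    return _CaseGeometry(
        radii=radii, rotation=rotation, lobulation=lob, sh_coeffs=coeffs,
        age=age, sex=sex, label_u=label_u,
    )


def _real_sh2_raw(coeffs: np.ndarray, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    vals = np.zeros(theta.shape)
    for i, m in enumerate(range(-2, 3)):
        y = sph_harm_y(2, abs(m), theta, phi)
        if m < 0:
            comp = np.sqrt(2) * (-1) ** m * y.imag
        elif m == 0:
            comp = y.real
        else:
            comp = np.sqrt(2) * (-1) ** m * y.real
        vals += coeffs[i] * comp
    return vals


def _fibonacci_directions(n: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """Fixed quasi-uniform (theta, phi) sample used to normalize lobulation."""
    i = np.arange(n) + 0.5
    theta = np.arccos(1 - 2 * i / n)
    phi = (np.pi * (1 + np.sqrt(5)) * i) % (2 * np.pi)
    return theta, phi


_NORM_THETA, _NORM_PHI = _fibonacci_directions()


def _real_sh2(coeffs: np.ndarray, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Random combination of the five real ell=2 harmonics, rescaled so its
    realized sup-norm over the sphere is ~1; ``1 + amplitude * Y`` then has
    true relative amplitude ``amplitude`` (and stays positive for
    amplitude < 1).

    ``theta`` is the polar angle from +z, ``phi`` the azimuth.  The sup is
    estimated on a fixed quasi-uniform direction sample, so the rescaling is
    deterministic in the coefficients.
    """
    sup = float(np.max(np.abs(_real_sh2_raw(coeffs, _NORM_THETA, _NORM_PHI))))
    return _real_sh2_raw(coeffs, theta, phi) / max(sup, 1e-12)


def _implicit(params: PhantomParams, geom: _CaseGeometry, points: np.ndarray) -> np.ndarray:
    """Signed implicit function; negative inside the lesion.

    ``points`` is (..., 3) in mm relative to the lesion centre.
    """
    local = points @ geom.rotation  # rotate into lesion frame
    s = local / geom.radii
    r = np.linalg.norm(s, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arccos(np.clip(np.where(r > 0, s[..., 2] / np.maximum(r, 1e-12), 1.0), -1, 1))
    phi = np.arctan2(s[..., 1], s[..., 0])
    target = 1.0 + geom.lobulation * _real_sh2(geom.sh_coeffs, theta, phi)
    return r - target


_ICOSPHERE_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _unit_icosphere(subdivisions: int = 4) -> tuple[np.ndarray, np.ndarray]:
    if subdivisions not in _ICOSPHERE_CACHE:
        import trimesh

        tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
        _ICOSPHERE_CACHE[subdivisions] = (np.asarray(tm.vertices), np.asarray(tm.faces))
    return _ICOSPHERE_CACHE[subdivisions]


def _surface_mesh(geom: _CaseGeometry, centre: np.ndarray, subdivisions: int = 4) -> SurfaceMesh:
    """Exact zero-isosurface of the implicit lesion as a radially deformed
    icosphere.

    The lesion is star-shaped about its centre, so the surface point along a
    unit direction u solves in closed form: with v = (u R)/radii the implicit
    gives t|v| = 1 + amplitude*Y(v/|v|), hence t = target/|v|.  This yields a
    watertight mesh with well-shaped triangles, emulating the high-quality
    modelling meshes of clinical data (a raw marching-cubes isosurface has
    staircase-grade triangles whose discrete-curvature noise swamps the
    lobulation geometry).
    """
    units, faces = _unit_icosphere(subdivisions)
    v = (units @ geom.rotation) / geom.radii
    nv = np.linalg.norm(v, axis=1)
    shat = v / nv[:, None]
    theta = np.arccos(np.clip(shat[:, 2], -1, 1))
    phi = np.arctan2(shat[:, 1], shat[:, 0])
    target = 1.0 + geom.lobulation * _real_sh2(geom.sh_coeffs, theta, phi)
    t = target / nv
    return SurfaceMesh(vertices=centre + t[:, None] * units, faces=faces.copy())


def generate_case(
    params: PhantomParams, case_seed
) -> tuple[VolumeImage, SegMask, SurfaceMesh, ClinicalRecord]:
    """Generate one phantom case; byte-deterministic in (params, case_seed).

    The returned :class:`ClinicalRecord` carries a placeholder label 0 —
    rupture labels are a cohort-level construct (the logistic intercept is
    tuned against the whole cohort); :func:`generate_cohort` assigns them.
    """
    geom = _draw_geometry(params, case_seed)
    shape = tuple(params.grid_shape)
    sp = params.spacing
    centre = (np.array(shape) - 1) * sp / 2.0
    axes = [np.arange(n) * sp for n in shape]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1) - centre
    f = _implicit(params, geom, grid)

    mask = SegMask(data=(f < 0).astype(np.uint8), spacing=[sp] * 3, origin=[0.0] * 3)

    clean = np.where(f < 0, params.intensity_fg, params.intensity_bg).astype(float)
    smooth = gaussian_filter(clean, sigma=1.0)  # sigma in voxels
    noise_rng = np.random.default_rng(np.random.SeedSequence([*_as_entropy(case_seed), 7]))
    noisy = smooth + noise_rng.normal(0.0, params.noise_sd, size=shape) if params.noise_sd > 0 else smooth
    volume = VolumeImage(data=noisy, spacing=[sp] * 3, origin=[0.0] * 3)

    mesh = _surface_mesh(geom, centre)

    record = ClinicalRecord(
        case_id=str(case_seed), sex=geom.sex, age=geom.age, ruptured=0
    )
    return volume, mask, mesh, record


def _as_entropy(case_seed) -> list[int]:
    if isinstance(case_seed, (list, tuple)):
        return list(case_seed)
    return [int(case_seed)]


def _case_signal(params: PhantomParams, geom: _CaseGeometry) -> float:
    """Linear predictor (without intercept) of the label-generating logistic."""
    r_lo, r_hi = params.lesion_radii
    span = max(r_hi - r_lo, 1e-12)
    size_norm = (float(np.max(geom.radii)) - r_lo) / span
    lob_norm = geom.lobulation / max(params.lobulation_amplitude, 1e-12)
    w1, w2 = params.signal_coefficients
    return w1 * size_norm + w2 * lob_norm


def _tune_intercept(z: np.ndarray, u: np.ndarray, target: float) -> float:
    """Bisection on the intercept so the realized prevalence hits the target.

    Labels are ``u < sigmoid(z + b)``; prevalence is monotone increasing in b.
    """
    lo, hi = -50.0, 50.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        prev = float(np.mean(u < 1.0 / (1.0 + np.exp(-(z + mid)))))
        if prev < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def cohort_labels(params: PhantomParams, geometries: list[_CaseGeometry]) -> np.ndarray:
    z = np.array([_case_signal(params, g) for g in geometries])
    u = np.array([g.label_u for g in geometries])
    if all(abs(c) < 1e-12 for c in params.signal_coefficients):
        # null signal: labels independent of morphology
        b = _tune_intercept(np.zeros_like(z), u, params.prevalence_target)
        p = np.full_like(z, 1.0 / (1.0 + np.exp(-b)))
    else:
        b = _tune_intercept(z, u, params.prevalence_target)
        p = 1.0 / (1.0 + np.exp(-(z + b)))
    return (u < p).astype(int)


def generate_cohort(n: int, params: PhantomParams, out_dir: str) -> str:
    """Generate ``n`` cases, write volumes/masks/meshes + manifest, return the
    manifest path.

    Requires ``n >= 16`` so stratified 8-fold cross-validation downstream can
    place both classes in every fold.  The realized prevalence is within 0.05
    of ``params.prevalence_target`` (intercept bisection), except in the
    null-signal edge case at very small n.
    """
    if n < 16:
        raise ValidationError(f"need n >= 16 for stratified 8-fold CV, got {n}")
    os.makedirs(out_dir, exist_ok=True)
    seeds = [[int(params.seed), i] for i in range(n)]
    geoms = [_draw_geometry(params, s) for s in seeds]
    labels = cohort_labels(params, geoms)

    rows = []
    for i, (s, lab) in enumerate(zip(seeds, labels)):
        cid = f"case_{i:04d}"
        volume, mask, mesh, record = generate_case(params, s)
        vol_name, mask_name, mesh_name = f"{cid}_vol.mhd", f"{cid}_mask.mhd", f"{cid}.stl"
        io_core.write_volume(volume, os.path.join(out_dir, vol_name))
        io_core.write_mask(mask, os.path.join(out_dir, mask_name))
        io_core.write_mesh_stl(mesh, os.path.join(out_dir, mesh_name))
        rows.append(
            dict(
                case_id=cid, volume=vol_name, mask=mask_name, mesh=mesh_name,
                sex=record.sex, age=f"{record.age:.2f}", ruptured=int(lab),
            )
        )
    import pandas as pd

    manifest = os.path.join(out_dir, "manifest.csv")
    pd.DataFrame(rows, columns=io_core.MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest
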