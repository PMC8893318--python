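"""Texture-matrix builders: GLCM, GLRLM, GLSZM, NGTDM, GLDM.

All builders consume a :class:`DiscretizedROI` (levels 1..Ng inside the
mask, 0 outside) and count only in-mask voxels; out-of-mask neighbours are
ignored (they break runs, bound zones, and are excluded from neighbourhood
averages and dependence counts).

Conventions (documented defaults of this package):

* GLCM / GLRLM: the 13 unique 3-D directions at Chebyshev distance 1
  (first non-zero component positive); matrices are accumulated ("merged")
  over directions.  The GLCM is symmetrized (P + P^T) before normalization.
* GLSZM: zones are 26-connected components of equal gray level.
* NGTDM: 26-neighbourhood (Chebyshev distance 1) gray-tone averages.
* GLDM: a neighbour is dependent when |level difference| <= alpha (default
  0); the dependence size of a voxel is 1 + its dependent-neighbour count
  (the centre counts), so sizes lie in [1, 27].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .preprocess import DiscretizedROI

# 13 unique direction vectors: first non-zero component positive
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0) and ((dx, dy, dz) > (0, 0, 0))
)
assert len(DIRECTIONS_3D) == 13

# all 26 neighbour offsets
OFFSETS_26: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
)


@dataclass
class TextureMatrix:
    """A built texture matrix plus the bookkeeping its features need."""

    family: str  # glcm | glrlm | glszm | ngtdm | gldm
    matrix: np.ndarray
    n_levels: int
    params: dict = field(default_factory=dict)
    # family-specific extras
    n_voxels: int = 0  # in-mask voxel count
    n_directions: int = 1


def _shifted_views(shape, offset):
    """Slices (src, dst) so that src voxel v pairs with dst voxel v + offset."""
    src, dst = [], []
    for n, d in zip(shape, offset):
        if d == 0:
            src.append(slice(None))
            dst.append(slice(None))
        elif d > 0:
            src.append(slice(0, n - d))
            dst.append(slice(d, n))
        else:
            src.append(slice(-d, n))
            dst.append(slice(0, n + d))
    return tuple(src), tuple(dst)


def glcm_matrix(roi: DiscretizedROI, directions=None, symmetric: bool = True) -> TextureMatrix:
    """Gray-level co-occurrence counts at distance 1, merged over directions
    and symmetrized; ``matrix`` is normalized to sum to 1."""
    directions = DIRECTIONS_3D if directions is None else tuple(directions)
    ng = roi.n_levels
    lev = roi.levels
    counts = np.zeros((ng, ng), dtype=np.int64)
    for off in directions:
        src, dst = _shifted_views(lev.shape, off)
        a, b = lev[src], lev[dst]
        valid = (a > 0) & (b > 0)
        np.add.at(counts, (a[valid] - 1, b[valid] - 1), 1)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    prob = counts / total if total > 0 else counts.astype(float)
    return TextureMatrix(
        family="glcm", matrix=prob, n_levels=ng,
        params={"distance": 1, "directions": directions, "raw_counts": counts},
        n_voxels=int(roi.mask.sum()), n_directions=len(directions),
    )


def glrlm_matrix(roi: DiscretizedROI, directions=None) -> TextureMatrix:
    """Gray-level run-length counts, merged over directions.

    ``matrix[i, j]`` is the number of maximal runs of level i+1 and length
    j+1; out-of-mask voxels break runs.
    """
    directions = DIRECTIONS_3D if directions is None else tuple(directions)
    ng = roi.n_levels
    lev = roi.levels
    shape = lev.shape
    max_len = max(shape)
    counts = np.zeros((ng, max_len), dtype=np.int64)
    coords = np.indices(shape).reshape(3, -1)  # (3, N)
    flat = lev.reshape(-1)
    dims = np.array(shape)
    for off in directions:
        d = np.array(off)
        # steps already taken along the direction before reaching this voxel
        t_candidates = [
            coords[a] if d[a] == 1 else dims[a] - 1 - coords[a]
            for a in range(3)
            if d[a] != 0
        ]
        t = np.minimum.reduce(t_candidates)
        line = coords - t[None, :] * d[:, None]  # line identifier (entry voxel)
        line_id = (line[0] * (2 * dims[1]) + line[1]) * (2 * dims[2]) + line[2]
        order = np.lexsort((t, line_id))
        v = flat[order]
        lid = line_id[order]
        new_run = np.ones(len(v), dtype=bool)
        new_run[1:] = (v[1:] != v[:-1]) | (lid[1:] != lid[:-1])
        run_id = np.cumsum(new_run) - 1
        run_len = np.bincount(run_id)
        run_level = v[new_run]
        keep = run_level > 0
        np.add.at(counts, (run_level[keep] - 1, run_len[keep] - 1), 1)
    return TextureMatrix(
        family="glrlm", matrix=counts.astype(float), n_levels=ng,
        params={"directions": directions},
        n_voxels=int(roi.mask.sum()), n_directions=len(directions),
    )


def glszm_matrix(roi: DiscretizedROI) -> TextureMatrix:
    """Gray-level size-zone counts; zones are 26-connected components of a
    single gray level.  ``matrix[i, s]`` counts zones of level i+1, size s+1."""
    ng = roi.n_levels
    lev = roi.levels
    n_vox = int(roi.mask.sum())
    structure = np.ones((3, 3, 3), dtype=int)
    counts = np.zeros((ng, n_vox), dtype=np.int64)
    for g in range(1, ng + 1):
        lab, n_lab = ndimage.label(lev == g, structure=structure)
        if n_lab == 0:
            continue
        sizes = np.bincount(lab.reshape(-1))[1:]
        np.add.at(counts, (g - 1, sizes - 1), 1)
    # trim trailing all-zero size columns (keep at least one)
    nz = np.nonzero(counts.sum(axis=0))[0]
    last = nz[-1] + 1 if len(nz) else 1
    return TextureMatrix(
        family="glszm", matrix=counts[:, :last].astype(float), n_levels=ng,
        params={"connectivity": 26}, n_voxels=n_vox,
    )


def ngtdm_matrix(roi: DiscretizedROI) -> TextureMatrix:
    """Neighbouring gray-tone difference table.

    ``matrix`` has one row per gray level: columns (n_i, p_i, s_i) where n_i
    counts in-mask voxels of level i with at least one in-mask neighbour,
    p_i = n_i / N, and s_i is the summed absolute difference between i and
    the mean level of each such voxel's in-mask 26-neighbourhood.
    """
    ng = roi.n_levels
    lev = roi.levels.astype(float)
    inmask = roi.levels > 0
    nbr_sum = np.zeros(lev.shape)
    nbr_cnt = np.zeros(lev.shape)
    for off in OFFSETS_26:
        src, dst = _shifted_views(lev.shape, off)
        nbr_sum[src] += np.where(inmask[dst], lev[dst], 0.0)
        nbr_cnt[src] += inmask[dst]
    valid = inmask & (nbr_cnt > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        avg = np.where(valid, nbr_sum / np.maximum(nbr_cnt, 1), 0.0)
    diff = np.abs(lev - avg)
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    lv = roi.levels[valid]
    np.add.at(n_i, lv - 1, 1)
    np.add.at(s_i, lv - 1, diff[valid])
    total = n_i.sum()
    p_i = n_i / total if total > 0 else n_i
    return TextureMatrix(
        family="ngtdm", matrix=np.stack([n_i, p_i, s_i], axis=1), n_levels=ng,
        params={"neighborhood": "chebyshev-1"}, n_voxels=int(total),
    )


def gldm_matrix(roi: DiscretizedROI, alpha: int = 0) -> TextureMatrix:
    """Gray-level dependence counts.

    A neighbour is dependent when |level difference| <= ``alpha``; dependence
    size = 1 + dependent-neighbour count.  ``matrix[i, j]`` counts in-mask
    voxels with level i+1 and dependence size j+1.
    """
    ng = roi.n_levels
    lev = roi.levels
    inmask = lev > 0
    dep = np.zeros(lev.shape, dtype=np.int64)
    for off in OFFSETS_26:
        src, dst = _shifted_views(lev.shape, off)
        ok = inmask[src] & inmask[dst] & (np.abs(lev[src] - lev[dst]) <= alpha)
        dep[src] += ok
    counts = np.zeros((ng, 27), dtype=np.int64)
    np.add.at(counts, (lev[inmask] - 1, dep[inmask]), 1)
    nz = np.nonzero(counts.sum(axis=0))[0]
    last = nz[-1] + 1 if len(nz) else 1
    return TextureMatrix(
        family="gldm", matrix=counts[:, :last].astype(float), n_levels=ng,
        params={"alpha": alpha}, n_voxels=int(inmask.sum()),
    )
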