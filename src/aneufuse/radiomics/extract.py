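"""Top-level radiomics extraction: preprocess → discretize → all families.

Produces exactly 107 named, finite features per case, tagged by family:
18 first-order + 14 shape + 24 GLCM + 16 GLRLM + 16 GLSZM + 5 NGTDM +
14 GLDM.  Feature names follow the stable ``family_featureName`` scheme
(e.g. ``glcm_contrast``, ``shape_sphericity``).
"""

from __future__ import annotations

import numpy as np

from ..types import SegMask, VolumeImage
from .features import (
    GLCM_NAMES,
    GLDM_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    NGTDM_NAMES,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)
from .firstorder import FIRSTORDER_NAMES, first_order_features
from .matrices import glcm_matrix, gldm_matrix, glrlm_matrix, glszm_matrix, ngtdm_matrix
from .preprocess import DEFAULT_BINS, discretize, preprocess
from .shape import SHAPE_NAMES, shape3d_features

FAMILY_COUNTS = {
    "firstorder": 18,
    "shape": 14,
    "glcm": 24,
    "glrlm": 16,
    "glszm": 16,
    "ngtdm": 5,
    "gldm": 14,
}

RADIOMICS_FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"firstorder_{n}" for n in FIRSTORDER_NAMES)
    + tuple(f"shape_{n}" for n in SHAPE_NAMES)
    + tuple(f"glcm_{n}" for n in GLCM_NAMES)
    + tuple(f"glrlm_{n}" for n in GLRLM_NAMES)
    + tuple(f"glszm_{n}" for n in GLSZM_NAMES)
    + tuple(f"ngtdm_{n}" for n in NGTDM_NAMES)
    + tuple(f"gldm_{n}" for n in GLDM_NAMES)
)
assert len(RADIOMICS_FEATURE_NAMES) == 107


def extract_radiomics(
    volume: VolumeImage, mask: SegMask, n_bins: int = DEFAULT_BINS
) -> dict[str, float]:
    """Run the full 107-feature battery on an aligned raw volume/mask pair."""
    vol_pp, mask_pp = preprocess(volume, mask)
    roi = discretize(vol_pp, mask_pp, n_bins=n_bins)

    out: dict[str, float] = {}
    for name, val in first_order_features(vol_pp, mask_pp, roi).items():
        out[f"firstorder_{name}"] = val
    for name, val in shape3d_features(mask_pp).items():
        out[f"shape_{name}"] = val
    for fam, builder, featfn in (
        ("glcm", glcm_matrix, glcm_features),
        ("glrlm", glrlm_matrix, glrlm_features),
        ("glszm", glszm_matrix, glszm_features),
        ("ngtdm", ngtdm_matrix, ngtdm_features),
        ("gldm", gldm_matrix, gldm_features),
    ):
        for name, val in featfn(builder(roi)).items():
            out[f"{fam}_{name}"] = val

    assert tuple(out) == RADIOMICS_FEATURE_NAMES
    bad = [k for k, v in out.items() if not np.isfinite(v)]
    if bad:  # degenerate rules should make this unreachable
        raise AssertionError(f"non-finite radiomics features: {bad}")
    return out
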