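"""Deep-feature output transforms over a pluggable 2-score extractor.

A trained 3-D CNN feature extractor produces, per case, the two raw outputs
of its final fully connected layer.  Three published transforms of those
outputs are supported:

1. ``no_sigmoid`` — the raw scores;
2. ``sigmoid``    — elementwise logistic 1/(1 + e^(-x));
3. ``binarize``   — threshold the sigmoid outputs at 0.5 (the boundary
   x = 0.5 maps to 1).

Training such a network is out of scope here; the extractor is a contract —
any callable ``(VolumeImage, SegMask) -> (s0, s1)`` — and
:func:`stub_extractor` provides a deterministic stand-in built from cheap
summary statistics.  It is NOT a learned model; it exists so the fused
pipeline can be exercised and tested end to end.
"""

from __future__ import annotations

import subprocess
from dataclasses import dataclass

import numpy as np

from .types import SegMask, ValidationError, VolumeImage

VARIANTS = ("no_sigmoid", "sigmoid", "binarization")


class ContractError(ValueError):
    """The extractor or transform received/produced the wrong arity."""


@dataclass
class DeepFeaturePair:
    """Exactly two scalar deep-feature values plus their variant tag."""

    values: tuple[float, float]
    variant: str

    def __post_init__(self) -> None:
        if len(self.values) != 2:
            raise ContractError(f"expected 2 values, got {len(self.values)}")
        self.values = (float(self.values[0]), float(self.values[1]))
        if self.variant not in VARIANTS:
            raise ValidationError(f"unknown variant {self.variant!r}")
        if self.variant == "sigmoid" and not all(0 < v < 1 for v in self.values):
            raise ValidationError("sigmoid variant values must lie in (0, 1)")
        if self.variant == "binarization" and not all(v in (0.0, 1.0) for v in self.values):
            raise ValidationError("binarization variant values must be 0 or 1")


def _check_arity(scores) -> tuple[float, float]:
    scores = tuple(float(s) for s in np.atleast_1d(np.asarray(scores, dtype=float)))
    if len(scores) != 2:
        raise ContractError(f"extractor contract is 2 scores, got {len(scores)}")
    if not all(np.isfinite(scores)):
        raise ContractError(f"non-finite scores {scores}")
    return scores


def no_sigmoid(scores) -> DeepFeaturePair:
    """Identity pass-through of the raw final-layer outputs."""
    return DeepFeaturePair(values=_check_arity(scores), variant="no_sigmoid")


def sigmoid(scores) -> DeepFeaturePair:
    """Elementwise logistic transform.

    Mathematically the output lies in the open interval (0, 1); in floating
    point, large |x| saturates to exactly 0 or 1, so outputs are clamped to
    the nearest representable interior values.
    """
    s = _check_arity(scores)
    lo, hi = np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0)
    vals = tuple(float(np.clip(1.0 / (1.0 + np.exp(-v)), lo, hi)) for v in s)
    return DeepFeaturePair(values=vals, variant="sigmoid")


def binarize(probabilities) -> DeepFeaturePair:
    """Threshold probabilities at 0.5; the boundary 0.5 maps to 1."""
    s = _check_arity(probabilities)
    if not all(0.0 <= v <= 1.0 for v in s):
        raise ValidationError(f"binarize expects values in [0, 1], got {s}")
    vals = tuple(1.0 if v >= 0.5 else 0.0 for v in s)
    return DeepFeaturePair(values=vals, variant="binarization")


def transform_scores(scores, variant: str) -> DeepFeaturePair:
    if variant == "no_sigmoid":
        return no_sigmoid(scores)
    if variant == "sigmoid":
        return sigmoid(scores)
    if variant == "binarization":
        return binarize(sigmoid(scores).values)
    raise ValidationError(f"unknown variant {variant!r}")


def stub_extractor(volume: VolumeImage, mask: SegMask, seed: int = 0) -> tuple[float, float]:
    """Deterministic stand-in extractor (not a learned model).

    Score 0: scaled mean in-mask intensity; score 1: z-score of the mask
    volume against the generator's nominal lesion-size scale, plus a small
    seeded perturbation so the two scores are not exact functions of other
    features in the fused table.
    """
    mask.check_aligned(volume)
    if mask.n_foreground == 0:
        raise ValidationError("empty mask")
    inmask = volume.data[mask.data]
    mean_intensity = float(inmask.mean())
    vol_mm3 = mask.n_foreground * float(np.prod(mask.spacing))
    # nominal scale: an ~5 mm-semi-axis lesion, sd one order of magnitude below
    vol_z = (vol_mm3 - 500.0) / 250.0
    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, mask.n_foreground])
    )
    jitter = rng.normal(0.0, 0.05, size=2)
    return (mean_intensity / 50.0 - 1.0 + jitter[0], vol_z + jitter[1])


def external_extractor(command: str):
    """Wrap an external command as an extractor.

    The command receives the volume and mask paths as two arguments and must
    print exactly two numbers to stdout.
    """

    def run(volume_path: str, mask_path: str) -> tuple[float, float]:
        out = subprocess.run(
            [*command.split(), str(volume_path), str(mask_path)],
            capture_output=True, text=True, check=True,
        ).stdout.split()
        return _check_arity([float(v) for v in out])

    return run
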