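"""End-to-end orchestration: cohort manifest → fused 136-feature table →
selection → nested cross-validation."""

from __future__ import annotations

import logging

import pandas as pd

from . import dl_transforms, io_core, morphometrics
from .radiomics import extract_radiomics
from .selection import FeatureTable, fuse_features

log = logging.getLogger(__name__)


def extract_cohort_features(
    manifest: str,
    n_bins: int = 32,
    deep_variant: str = "sigmoid",
    extractor: str = "stub",
    seed: int = 0,
) -> FeatureTable:
    """Compute all four feature groups for every case in a manifest and fuse
    them into the 136-column table.

    ``extractor`` is either ``"stub"`` (the deterministic summary-statistic
    stand-in) or ``"external:<command>"`` (a command printing two scores
    given volume and mask paths).
    """
    entries = io_core.read_cohort(manifest)
    morph_rows, radio_rows, deep_rows, clin_rows, labels = {}, {}, {}, {}, {}
    external = None
    if extractor.startswith("external:"):
        external = dl_transforms.external_extractor(extractor.split(":", 1)[1])
    elif extractor != "stub":
        raise ValueError(f"unknown extractor {extractor!r}")

    for entry in entries:
        volume = io_core.read_volume(entry.volume_path)
        mask = io_core.read_mask(entry.mask_path)
        mesh = io_core.read_mesh_stl(entry.mesh_path)
        morph_rows[entry.case_id] = morphometrics.morphological_features(mesh)
        radio_rows[entry.case_id] = extract_radiomics(volume, mask, n_bins=n_bins)
        if external is not None:
            scores = external(entry.volume_path, entry.mask_path)
        else:
            scores = dl_transforms.stub_extractor(volume, mask, seed=seed)
        pair = dl_transforms.transform_scores(scores, deep_variant)
        deep_rows[entry.case_id] = {"score0": pair.values[0], "score1": pair.values[1]}
        clin_rows[entry.case_id] = {"sex": entry.record.sex_code, "age": entry.record.age}
        labels[entry.case_id] = entry.record.ruptured
        log.info("extracted case %s", entry.case_id)

    def _frame(rows: dict) -> pd.DataFrame:
        return pd.DataFrame.from_dict(rows, orient="index")

    return fuse_features(
        _frame(morph_rows), _frame(radio_rows), _frame(deep_rows), _frame(clin_rows),
        pd.Series(labels, name="ruptured"),
    )


def table_to_frame(table: FeatureTable) -> pd.DataFrame:
    """Feature table plus a trailing label column, ready for CSV export."""
    df = table.features.copy()
    df["ruptured"] = table.labels
    return df


def frame_to_table(df: pd.DataFrame) -> FeatureTable:
    if "ruptured" not in df.columns:
        raise ValueError("feature table is missing the 'ruptured' label column")
    return FeatureTable(features=df.drop(columns=["ruptured"]), labels=df["ruptured"].astype(int))
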