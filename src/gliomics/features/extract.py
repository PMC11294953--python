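"""Full radiomics extraction for a study: 1197 features per ROI per sequence.

Per (ROI, sequence): 14 shape features from the ROI geometry (once, on the
original image only) plus 18 first-order and 22+16+16+14+5 texture features
on the original image and each of the 12 derived images:
14 + 91 × 13 = 1197. Column names follow
``{ROI1|ROI2}_{sequence}_{imagetype}_{class}_{feature}``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..cohort import ROI_TAG, MRIStudy, ROIKind, SEQUENCES, UnsupportedROIError, make_roi
from ..config import RunConfig
from ..filters import IMAGE_TYPES, derive_images
from .discretize import discretize
from .firstorder import FIRSTORDER_NAMES, first_order_features
from .shape import SHAPE_NAMES, shape_features
from .texture import (
    GLCM_NAMES, GLDM_NAMES, GLRLM_NAMES, GLSZM_NAMES, NGTDM_NAMES,
    glcm_features, gldm_features, glrlm_features, glszm_features,
    ngtdm_features,
)

INTENSITY_CLASSES = (
    ("firstorder", FIRSTORDER_NAMES),
    ("glcm", GLCM_NAMES),
    ("glrlm", GLRLM_NAMES),
    ("glszm", GLSZM_NAMES),
    ("gldm", GLDM_NAMES),
    ("ngtdm", NGTDM_NAMES),
)

#: 14 + (18+22+16+16+14+5) * 13 image types
FEATURES_PER_ROI_SEQUENCE = len(SHAPE_NAMES) + sum(
    len(names) for _, names in INTENSITY_CLASSES
) * len(IMAGE_TYPES)


def feature_columns(roi_kind: ROIKind, sequence: str) -> list[str]:
    """Deterministic column order for one (ROI, sequence) block."""
    tag = ROI_TAG[ROIKind(roi_kind)]
    cols = [f"{tag}_{sequence}_original_shape_{n}" for n in SHAPE_NAMES]
    for image_type in IMAGE_TYPES:
        for cls, names in INTENSITY_CLASSES:
            cols.extend(f"{tag}_{sequence}_{image_type}_{cls}_{n}" for n in names)
    return cols


def _bbox_crop(volume: np.ndarray, roi: np.ndarray, margin: int = 0):
    idx = np.nonzero(roi)
    sl = tuple(
        slice(max(int(i.min()) - margin, 0), min(int(i.max()) + 1 + margin, n))
        for i, n in zip(idx, roi.shape)
    )
    return volume[sl], roi[sl]


def intensity_features(volume: np.ndarray, roi: np.ndarray, bin_width: float,
                       spacing_mm=(1.0, 1.0, 1.0)) -> dict:
    """The 91 intensity features (first-order + 5 texture classes) on one image."""
    disc = discretize(volume, roi, bin_width)
    feats = {
        "firstorder": first_order_features(volume, roi, disc, spacing_mm),
        "glcm": glcm_features(disc),
        "glrlm": glrlm_features(disc),
        "glszm": glszm_features(disc),
        "gldm": gldm_features(disc),
        "ngtdm": ngtdm_features(disc),
    }
    return feats


def extract_roi_sequence(volume: np.ndarray, roi, spacing_mm,
                         config: RunConfig, roi_kind: ROIKind,
                         sequence: str) -> dict:
    """All 1197 features for one ROI on one sequence volume."""
    tag = ROI_TAG[ROIKind(roi_kind)]
    roi_arr = roi.voxels if hasattr(roi, "voxels") else np.asarray(roi, dtype=bool)
    values: dict[str, float] = {}
    shp = shape_features(roi_arr, spacing_mm)
    for name in SHAPE_NAMES:
        values[f"{tag}_{sequence}_original_shape_{name}"] = shp[name]

    vol_c, roi_c = _bbox_crop(np.asarray(volume, dtype=np.float64), roi_arr, margin=2)
    images = [("original", vol_c)]
    images += [
        (im.image_type, im.voxels)
        for im in derive_images(vol_c, spacing_mm, wavelet=config.wavelet,
                                log_sigmas_mm=config.log_sigmas_mm)
    ]
    for image_type, img in images:
        feats = intensity_features(img, roi_c, config.bin_width, spacing_mm)
        for cls, names in INTENSITY_CLASSES:
            for name in names:
                values[f"{tag}_{sequence}_{image_type}_{cls}_{name}"] = feats[cls][name]
    return values


def extract_all(study: MRIStudy, roi_kinds=(ROIKind.WT, ROIKind.NONENH),
                config: RunConfig | None = None) -> pd.Series:
    """One feature row for a study over the requested ROIs and all sequences.

    ROIs that cannot be built under the study's label scheme (the
    nonenhancing ROI for whole-tumor-only masks) are skipped; their columns
    are absent from the row and the skip is recorded in ``row.attrs``-like
    metadata via the returned series name.
    """
    config = config or RunConfig()
    values: dict[str, float] = {}
    skipped = []
    for roi_kind in roi_kinds:
        try:
            roi = make_roi(study.segmentation, roi_kind, study.spacing_mm)
        except UnsupportedROIError:
            skipped.append(ROIKind(roi_kind).value)
            continue
        for sequence in SEQUENCES:
            values.update(
                extract_roi_sequence(study.sequences[sequence], roi,
                                     study.spacing_mm, config, roi_kind, sequence)
            )
    row = pd.Series(values, name=study.patient_id)
    row.attrs["skipped_rois"] = skipped
    return row


def extract_cohort(studies, labels=None, roi_kinds=(ROIKind.WT, ROIKind.NONENH),
                   config: RunConfig | None = None) -> pd.DataFrame:
    """Feature table for a list of studies; optional IDH label column."""
    rows = [extract_all(s, roi_kinds, config) for s in studies]
    table = pd.DataFrame(rows)
    table.index.name = "patient_id"
    if labels is not None:
        table["IDH"] = np.asarray(labels, dtype=int)
    return table
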