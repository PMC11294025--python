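"""Assembly of the full 234-feature panel per ROI and per cohort.

Features that cannot be computed for a given ROI (empty mask, single pixel,
constant intensities) are recorded as NaN together with a textual reason in
``FeatureTable.na_reasons`` — missingness is always explicit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..prep import CTSlice, LoGImage, ROIMask, log_response, threshold_segment
from .discretize import discretize_fbn
from .firstorder import extract_first_order
from .manifest import FEATURE_NAMES, MANIFEST, N_BINS_DEFAULT
from .morphology import extract_morphology
from .texture import extract_texture


@dataclass
class FeatureTable:
    """Patients x features with per-cell missingness reasons.

    ``frame`` is indexed by patient id; ``na_reasons`` maps
    ``(patient_id, column)`` to the reason a value is NaN.
    """

    frame: pd.DataFrame
    tissue: str
    na_reasons: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert list(self.frame.columns) == list(FEATURE_NAMES)


def extract_roi_features(
    image: np.ndarray,
    log_values: np.ndarray,
    mask: np.ndarray,
    spacing: float,
    n_bins: int = N_BINS_DEFAULT,
) -> tuple[dict[str, float], dict[str, str]]:
    """All 234 features for one ROI of one slice.

    An empty ROI yields all-NaN values with reason ``empty ROI``; texture
    features of a single-pixel ROI (no neighbour pairs) are NaN with reason.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return (
            {name: np.nan for name in FEATURE_NAMES},
            {name: "empty ROI" for name in FEATURE_NAMES},
        )

    values: dict[str, float] = {}
    reasons: dict[str, str] = {}

    def _store(shorts_to_vals: dict[str, float], shorts_to_na: dict[str, str], source: str) -> None:
        lookup = {(d.short, d.source): d.name for d in MANIFEST}
        for short, val in shorts_to_vals.items():
            values[lookup[short, source]] = val
        for short, why in shorts_to_na.items():
            if (short, source) in lookup:
                reasons[lookup[short, source]] = why

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-ROI warnings recorded as reasons
        morph_vals, morph_na = extract_morphology(mask, spacing)
        _store(morph_vals, morph_na, "base")

        disc = discretize_fbn(image, mask, n_bins)
        fo_vals, fo_na = extract_first_order(np.asarray(image, float), mask, disc, spacing)
        _store(fo_vals, fo_na, "base")

        try:
            tex_vals, tex_na = extract_texture(disc)
            _store(tex_vals, tex_na, "base")
        except ValueError as err:
            tex_names = [d.name for d in MANIFEST
                         if d.family in ("cm", "rlm", "szm", "dzm", "ngt", "ngl")]
            for name in tex_names:
                values[name] = np.nan
                reasons[name] = f"texture undefined: {err}"

        disc_log = discretize_fbn(log_values, mask, n_bins)
        lo_vals, lo_na = extract_first_order(np.asarray(log_values, float), mask, disc_log, spacing)
        _store(lo_vals, lo_na, "log")

    assert set(values) == set(FEATURE_NAMES)
    return values, reasons


def extract_panel(
    ct: CTSlice,
    log_image: LoGImage,
    masks: dict[str, ROIMask],
    n_bins: int = N_BINS_DEFAULT,
) -> tuple[pd.Series, dict[str, dict[str, str]]]:
    """Feature rows for all ROIs of one slice.

    Returns a Series with a (tissue, feature) MultiIndex plus the per-tissue
    NA reasons.
    """
    rows = {}
    na: dict[str, dict[str, str]] = {}
    for tissue, roi in masks.items():
        if roi.mask.shape != ct.values.shape:
            raise ValueError(f"{tissue} mask not aligned with slice")
        vals, reasons = extract_roi_features(
            ct.values, log_image.values, roi.mask, ct.spacing[0], n_bins
        )
        rows[tissue] = vals
        na[tissue] = reasons
    combined = pd.concat(
        {t: pd.Series(v, index=FEATURE_NAMES) for t, v in rows.items()}
    )
    return combined, na


def build_feature_table(
    slices: list[CTSlice],
    compartments: list[ROIMask | np.ndarray],
    tissue: str,
    n_bins: int = N_BINS_DEFAULT,
) -> FeatureTable:
    """Extract the 234-feature panel for one tissue across a cohort.

    Each slice is segmented by HU thresholding inside its muscle
    compartment, LoG-filtered, and run through the full extractor.
    """
    records = {}
    na_reasons: dict[tuple[str, str], str] = {}
    for ct, comp in zip(slices, compartments):
        roi = threshold_segment(ct, comp, tissue)
        log_img = log_response(ct)
        vals, reasons = extract_roi_features(
            ct.values, log_img.values, roi.mask, ct.spacing[0], n_bins
        )
        records[ct.patient_id] = vals
        for col, why in reasons.items():
            na_reasons[(ct.patient_id, col)] = why
    frame = pd.DataFrame.from_dict(records, orient="index")[list(FEATURE_NAMES)]
    frame.index.name = "patient_id"
    return FeatureTable(frame=frame, tissue=tissue, na_reasons=na_reasons)
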