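"""Shared fixtures: tiny synthetic slices and cohorts, generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from peradiomics.prep import CTSlice, ROIMask, log_response, threshold_segment
from peradiomics.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-patient default-calibration cohort (session-cached)."""
    return generate_cohort(CohortConfig(n_patients=60, seed=123))


@pytest.fixture()
def ring_slice():
    """One synthetic slice with an annular muscle compartment and fat speckles."""
    rng = np.random.default_rng(5)
    n = 96
    yy, xx = np.mgrid[:n, :n] - n / 2
    outer = (xx / 40) ** 2 + (yy / 26) ** 2 <= 1
    inner = (xx / 24) ** 2 + (yy / 15.6) ** 2 <= 1
    comp = outer & ~inner
    img = np.full((n, n), -350.0)
    img[comp] = rng.normal(45, 23, comp.sum())
    fat = comp & (rng.random((n, n)) < 0.12)
    img[fat] = rng.normal(-55, 12, fat.sum())
    ct = CTSlice(values=img, spacing=(1.0, 1.0), patient_id="ring")
    roi = threshold_segment(ct, comp, "SM_IMAT")
    return ct, ROIMask(mask=comp, tissue="SM_IMAT", window=(-190.0, 150.0)), roi


@pytest.fixture()
def ring_features(ring_slice):
    from peradiomics.features import extract_roi_features

    ct, comp, roi = ring_slice
    log_img = log_response(ct)
    return extract_roi_features(ct.values, log_img.values, roi.mask, 1.0)
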