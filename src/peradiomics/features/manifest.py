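"""Frozen manifest of the 234-feature panel.

Per ROI the panel decomposes as 25 morphology + 57 first-order on the base
image + 95 second-order texture + 57 first-order on the averaged
Laplacian-of-Gaussian image.  Column names follow the MIRP-style convention
of the field (e.g. ``szm_sze_2d_fbn_n24``, ``cm_sum_avg_d1_2d_s_mrg_fbn``):
texture suffixes record the aggregation (distance 1, 2D, symmetric merged
directions) and the fixed-bin-number discretization at 24 levels; features
from the LoG image carry the ``log_avg_`` prefix.

The manifest is data: its counts (25/57/95/57 and the 25/16/16/16/5/17
texture split) are enforced at import time and by tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .firstorder import FIRST_ORDER_FEATURES, IH_FEATURES
from .morphology import MORPH_FEATURES
from .texture import (
    GLCM_FEATURES,
    GLDZM_FEATURES,
    GLRLM_FEATURES,
    GLSZM_FEATURES,
    NGLDM_FEATURES,
    NGTDM_FEATURES,
)

N_BINS_DEFAULT = 24

#: IBSI codes for features where the code is established in the field.
IBSI_CODES = {
    "stat_skew": "C317",
    "morph_pca_elongation": "Q3CK",
    "szm_sze_2d_fbn_n24": "5QRC",
}


@dataclass(frozen=True)
class FeatureDescriptor:
    """One column of the feature panel."""

    name: str        # full column name
    short: str       # family-internal key used by the extractors
    family: str      # morph | local | stat | ih | ivh | cm | rlm | szm | dzm | ngt | ngl
    source: str      # base | log
    ibsi_code: str = ""


def _texture_column(short: str) -> str:
    family, key = short.split("_", 1)
    if family == "cm":
        return f"cm_{key}_d1_2d_s_mrg_fbn"
    if family == "rlm":
        return f"rlm_{key}_2d_s_mrg_fbn_n{N_BINS_DEFAULT}"
    if family in ("szm", "dzm"):
        return f"{family}_{key}_2d_fbn_n{N_BINS_DEFAULT}"
    if family == "ngt":
        return f"ngt_{key}_d1_2d_fbn_n{N_BINS_DEFAULT}"
    if family == "ngl":
        return f"ngl_{key}_d1_a0_0_2d_fbn_n{N_BINS_DEFAULT}"
    raise ValueError(short)


def _first_order_column(short: str, source: str) -> str:
    name = f"{short}_fbn_n{N_BINS_DEFAULT}" if short in IH_FEATURES else short
    return f"log_avg_{name}" if source == "log" else name


def _first_order_family(short: str) -> str:
    return "local" if short.startswith("loc_") else short.split("_", 1)[0]


def build_manifest() -> list[FeatureDescriptor]:
    """The ordered 234-column manifest."""
    descriptors: list[FeatureDescriptor] = []
    for short in MORPH_FEATURES:
        descriptors.append(
            FeatureDescriptor(short, short, "morph", "base", IBSI_CODES.get(short, ""))
        )
    for short in FIRST_ORDER_FEATURES:
        name = _first_order_column(short, "base")
        descriptors.append(
            FeatureDescriptor(name, short, _first_order_family(short), "base",
                              IBSI_CODES.get(name, ""))
        )
    for shorts in (GLCM_FEATURES, GLRLM_FEATURES, GLSZM_FEATURES,
                   GLDZM_FEATURES, NGTDM_FEATURES, NGLDM_FEATURES):
        for short in shorts:
            name = _texture_column(short)
            descriptors.append(
                FeatureDescriptor(name, short, short.split("_", 1)[0], "base",
                                  IBSI_CODES.get(name, ""))
            )
    for short in FIRST_ORDER_FEATURES:
        name = _first_order_column(short, "log")
        descriptors.append(
            FeatureDescriptor(name, short, _first_order_family(short), "log",
                              IBSI_CODES.get(name, ""))
        )
    return descriptors


MANIFEST: tuple[FeatureDescriptor, ...] = tuple(build_manifest())
FEATURE_NAMES: tuple[str, ...] = tuple(d.name for d in MANIFEST)

FAMILY_COUNTS = {
    "morph": 25, "stat": 18, "local": 2, "ih": 24, "ivh": 13,
    "cm": 25, "rlm": 16, "szm": 16, "dzm": 16, "ngt": 5, "ngl": 17,
}


def _check_manifest() -> None:
    assert len(MANIFEST) == 234, len(MANIFEST)
    assert len(set(FEATURE_NAMES)) == 234, "duplicate feature names"
    base = [d for d in MANIFEST if d.source == "base"]
    log = [d for d in MANIFEST if d.source == "log"]
    assert len(log) == 57
    counts: dict[str, int] = {}
    for d in base:
        counts[d.family] = counts.get(d.family, 0) + 1
    assert counts == FAMILY_COUNTS, counts


_check_manifest()


def manifest_frame() -> pd.DataFrame:
    """The manifest as a DataFrame (column, short key, family, source, IBSI code)."""
    return pd.DataFrame(
        [(d.name, d.short, d.family, d.source, d.ibsi_code) for d in MANIFEST],
        columns=["name", "short", "family", "source", "ibsi_code"],
    )
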