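"""Fixed-bin-number (FBN) grey-level discretization.

All texture and intensity-histogram features operate on grey levels
``1..n_bins`` assigned inside the region of interest by the fixed-bin-number
rule: the in-mask intensity range is split into ``n_bins`` equal-width bins
between the in-mask minimum and maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class DiscretizedROI:
    """Grey-level map of a region of interest.

    Attributes
    ----------
    levels : 2D int array, 0 outside the mask, 1..n_bins inside.
    mask : boolean array marking the region of interest.
    n_bins : number of grey levels requested.
    """

    levels: np.ndarray
    mask: np.ndarray
    n_bins: int

    @property
    def in_mask(self) -> np.ndarray:
        """Grey levels of in-mask pixels (1D)."""
        return self.levels[self.mask]


def discretize_fbn(image: np.ndarray, mask: np.ndarray, n_bins: int = 24) -> DiscretizedROI:
    """Discretize in-mask intensities with the fixed-bin-number rule.

    level = 1 + floor(n_bins * (x - min) / (max - min)), with x == max
    mapped to n_bins; min and max are taken over in-mask pixels only.
    A constant region maps every pixel to level 1 (with a warning).
    """
    mask = np.asarray(mask, dtype=bool)
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    if not mask.any():
        raise ValueError("mask is empty")
    vals = np.asarray(image, dtype=float)
    lo = vals[mask].min()
    hi = vals[mask].max()
    levels = np.zeros(mask.shape, dtype=np.int32)
    if hi == lo:
        warnings.warn("constant ROI: all pixels assigned grey level 1", stacklevel=2)
        levels[mask] = 1
    else:
        lv = 1 + np.floor(n_bins * (vals[mask] - lo) / (hi - lo))
        levels[mask] = np.minimum(lv, n_bins).astype(np.int32)
    return DiscretizedROI(levels=levels, mask=mask, n_bins=int(n_bins))
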