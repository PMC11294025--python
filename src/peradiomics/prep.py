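"""Slice-level image preparation.

A single axial CT slice (HU values on a regular grid with known pixel
spacing) is resampled to isotropic spacing, segmented into skeletal muscle
(SM), intramuscular adipose tissue (IMAT) and the combined compartment
(SM+IMAT) by Hounsfield-unit thresholding inside a given muscle-compartment
mask, and band-pass filtered with an averaged Laplacian-of-Gaussian (LoG)
filter bank.

HU windows (closed on both ends):

===========  ================
tissue       window (HU)
===========  ================
SM           [-29, 150]
IMAT         [-190, -30]
SM_IMAT      [-190, 150]
===========  ================
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

#: Closed HU windows per tissue compartment.
TISSUE_WINDOWS: dict[str, tuple[float, float]] = {
    "SM": (-29.0, 150.0),
    "IMAT": (-190.0, -30.0),
    "SM_IMAT": (-190.0, 150.0),
}

TISSUES = tuple(TISSUE_WINDOWS)


@dataclass
class CTSlice:
    """A 2D axial CT slice in Hounsfield units.

    Attributes
    ----------
    values : 2D float array of HU.
    spacing : (row_mm, col_mm) pixel spacing.
    patient_id : identifier of the patient the slice belongs to.
    """

    values: np.ndarray
    spacing: tuple[float, float]
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("CTSlice values must be 2D")
        sr, sc = self.spacing
        if sr <= 0 or sc <= 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("CTSlice contains non-finite HU values")
        self.spacing = (float(sr), float(sc))

    @property
    def is_isotropic(self) -> bool:
        return np.isclose(self.spacing[0], self.spacing[1])


@dataclass
class ROIMask:
    """Boolean region-of-interest mask aligned with a :class:`CTSlice`."""

    mask: np.ndarray
    tissue: str
    window: tuple[float, float]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class LoGImage:
    """Pixel-wise average of Laplacian-of-Gaussian responses."""

    values: np.ndarray
    kernel_widths_mm: tuple[float, ...]


DEFAULT_LOG_WIDTHS_MM = (1.0, 2.0, 3.0, 4.0, 5.0)


def resample_isotropic(ct: CTSlice, target_mm: float = 1.0) -> CTSlice:
    """Resample a slice to isotropic ``target_mm`` spacing with cubic splines.

    The physical extent of the grid is preserved to within one pixel; output
    pixel centres are mapped back into the input index space and intensities
    are interpolated with an order-3 spline (mirror boundary). A slice that
    is already at the target spacing is returned unchanged (copy).
    """
    if target_mm <= 0:
        raise ValueError(f"target_mm must be positive, got {target_mm}")
    sr, sc = ct.spacing
    if np.isclose(sr, target_mm) and np.isclose(sc, target_mm):
        return replace(ct, values=ct.values.copy(), spacing=(target_mm, target_mm))
    nr, nc = ct.values.shape
    out_nr = max(1, int(round(nr * sr / target_mm)))
    out_nc = max(1, int(round(nc * sc / target_mm)))
    # centre-aligned grids: pixel i covers [i*t, (i+1)*t), centre (i+.5)*t
    rows = (np.arange(out_nr) + 0.5) * target_mm / sr - 0.5
    cols = (np.arange(out_nc) + 0.5) * target_mm / sc - 0.5
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    vals = ndimage.map_coordinates(ct.values, [rr, cc], order=3, mode="mirror")
    return replace(ct, values=vals, spacing=(target_mm, target_mm))


def threshold_segment(ct: CTSlice, compartment: ROIMask | np.ndarray, tissue: str) -> ROIMask:
    """Derive a tissue mask by HU thresholding inside the muscle compartment.

    The resulting mask is ``compartment AND lo <= HU <= hi`` with the window
    closed on both ends, so -30 HU belongs to IMAT and -29 HU to SM.
    """
    if tissue not in TISSUE_WINDOWS:
        raise ValueError(f"unknown tissue {tissue!r}; expected one of {TISSUES}")
    comp = compartment.mask if isinstance(compartment, ROIMask) else np.asarray(compartment, bool)
    if comp.shape != ct.values.shape:
        raise ValueError("compartment mask shape does not match slice")
    if not comp.any():
        raise ValueError("compartment mask is empty")
    lo, hi = TISSUE_WINDOWS[tissue]
    mask = comp & (ct.values >= lo) & (ct.values <= hi)
    return ROIMask(mask=mask, tissue=tissue, window=(lo, hi))


def log_response(ct: CTSlice, widths_mm: Sequence[float] = DEFAULT_LOG_WIDTHS_MM) -> LoGImage:
    """Average Laplacian-of-Gaussian response over a bank of scales.

    Each width is the Gaussian sigma in mm, converted to pixels through the
    slice spacing; the responses of all scales are averaged pixel-wise.
    Mirror padding avoids spurious edge response near the image border.
    """
    widths = tuple(float(w) for w in widths_mm)
    if not widths or any(w <= 0 for w in widths):
        raise ValueError("widths_mm must be a non-empty list of positive scales")
    if not ct.is_isotropic:
        raise ValueError("log_response requires an isotropic slice; resample first")
    px = ct.spacing[0]
    acc = np.zeros_like(ct.values)
    for w in widths:
        sigma = w / px
        resp = ndimage.gaussian_laplace(ct.values, sigma=sigma, mode="mirror")
        # truncated discrete kernels have a small non-zero DC gain; remove it
        # so constant and affine images map to exactly zero response
        resp -= _log_dc_gain(sigma) * ct.values
        acc += resp
    return LoGImage(values=acc / len(widths), kernel_widths_mm=widths)


def _log_dc_gain(sigma: float) -> float:
    """Response of the discrete LoG operator to a unit constant image."""
    m = 2 * int(4.0 * sigma + 1) + 1
    probe = ndimage.gaussian_laplace(np.ones((m, m)), sigma=sigma, mode="mirror")
    return float(probe[m // 2, m // 2])
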