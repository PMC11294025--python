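"""First-order intensity features: statistics, local intensity peaks,
intensity-histogram features on the fixed-bin-number discretization, and
intensity-volume-histogram (IVH) features.

The family totals 57 values: 18 statistical features on raw HU, 2 local
intensity peaks, 24 intensity-histogram features on the 24-level
discretization and 13 IVH features on continuous intensities.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .discretize import DiscretizedROI

STAT_FEATURES = (
    "stat_mean", "stat_var", "stat_skew", "stat_kurt", "stat_median",
    "stat_min", "stat_p10", "stat_p90", "stat_max", "stat_iqr", "stat_range",
    "stat_mad", "stat_rmad", "stat_medad", "stat_cv", "stat_qcod",
    "stat_energy", "stat_rms",
)

LOCAL_FEATURES = ("loc_peak_local", "loc_peak_global")

IH_FEATURES = (
    "ih_mean", "ih_var", "ih_skew", "ih_kurt", "ih_median", "ih_min",
    "ih_p10", "ih_p90", "ih_max", "ih_mode", "ih_iqr", "ih_range", "ih_mad",
    "ih_rmad", "ih_medad", "ih_cv", "ih_qcod", "ih_entropy", "ih_uniformity",
    "ih_energy", "ih_max_grad", "ih_max_grad_g", "ih_min_grad", "ih_min_grad_g",
)

IVH_FEATURES = (
    "ivh_v10", "ivh_v25", "ivh_v50", "ivh_v75", "ivh_v90",
    "ivh_i10", "ivh_i25", "ivh_i50", "ivh_i75", "ivh_i90",
    "ivh_diff_v10_v90", "ivh_diff_i10_i90", "ivh_auc",
)

FIRST_ORDER_FEATURES = STAT_FEATURES + LOCAL_FEATURES + IH_FEATURES + IVH_FEATURES

#: Disc radius (mm) whose area is 100 mm^2 — 2D analogue of the IBSI 1 cm^3
#: intensity-peak neighbourhood.
PEAK_RADIUS_MM = float(np.sqrt(100.0 / np.pi))

IVH_GRID_POINTS = 1000


def _moments(x: np.ndarray) -> tuple[float, float, float, float]:
    """mean, population variance, biased skewness, biased excess kurtosis."""
    mu = float(x.mean())
    d = x - mu
    var = float(np.mean(d**2))
    if var == 0:
        return mu, 0.0, np.nan, np.nan
    skew = float(np.mean(d**3) / var**1.5)
    kurt = float(np.mean(d**4) / var**2 - 3.0)
    return mu, var, skew, kurt


def _dispersion_stats(x: np.ndarray, prefix: str) -> tuple[dict[str, float], dict[str, str]]:
    """Shared location/spread statistics for raw and discretized intensities."""
    out: dict[str, float] = {}
    na: dict[str, str] = {}
    mu, var, skew, kurt = _moments(x)
    p10, p25, med, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    out[f"{prefix}_mean"] = mu
    out[f"{prefix}_var"] = var
    out[f"{prefix}_skew"] = skew
    out[f"{prefix}_kurt"] = kurt
    if var == 0:
        na[f"{prefix}_skew"] = "zero variance"
        na[f"{prefix}_kurt"] = "zero variance"
    out[f"{prefix}_median"] = float(med)
    out[f"{prefix}_min"] = float(x.min())
    out[f"{prefix}_p10"] = float(p10)
    out[f"{prefix}_p90"] = float(p90)
    out[f"{prefix}_max"] = float(x.max())
    out[f"{prefix}_iqr"] = float(p75 - p25)
    out[f"{prefix}_range"] = float(x.max() - x.min())
    out[f"{prefix}_mad"] = float(np.abs(x - mu).mean())
    inner = x[(x >= p10) & (x <= p90)]
    out[f"{prefix}_rmad"] = float(np.abs(inner - inner.mean()).mean()) if inner.size else np.nan
    out[f"{prefix}_medad"] = float(np.abs(x - med).mean())
    if mu != 0 and var > 0:
        out[f"{prefix}_cv"] = float(np.sqrt(var) / mu)
    else:
        out[f"{prefix}_cv"] = np.nan
        na[f"{prefix}_cv"] = "zero mean" if mu == 0 else "zero variance"
    if p75 + p25 != 0:
        out[f"{prefix}_qcod"] = float((p75 - p25) / (p75 + p25))
    else:
        out[f"{prefix}_qcod"] = np.nan
        na[f"{prefix}_qcod"] = "zero quartile sum"
    return out, na


def extract_statistics(image: np.ndarray, mask: np.ndarray) -> tuple[dict[str, float], dict[str, str]]:
    """18 statistical features on raw in-mask intensities."""
    x = np.asarray(image, float)[np.asarray(mask, bool)]
    if x.size == 0:
        raise ValueError("mask is empty")
    out, na = _dispersion_stats(x, "stat")
    out["stat_energy"] = float(np.sum(x**2))
    out["stat_rms"] = float(np.sqrt(np.mean(x**2)))
    return out, na


def extract_local_intensity(
    image: np.ndarray, mask: np.ndarray, spacing: float
) -> tuple[dict[str, float], dict[str, str]]:
    """Local and global intensity peaks over a 100 mm^2 disc neighbourhood.

    The disc mean at every pixel uses all image pixels inside the disc
    (ROI membership is not required for neighbours); pixels outside the
    image do not contribute.
    """
    image = np.asarray(image, float)
    mask = np.asarray(mask, bool)
    r_px = PEAK_RADIUS_MM / float(spacing)
    n = int(np.floor(r_px))
    dy, dx = np.mgrid[-n : n + 1, -n : n + 1]
    disc = (dy**2 + dx**2) <= r_px**2
    ksum = ndimage.correlate(image, disc.astype(float), mode="constant", cval=0.0)
    kcnt = ndimage.correlate(np.ones_like(image), disc.astype(float), mode="constant", cval=0.0)
    disc_mean = ksum / kcnt
    in_vals = image[mask]
    peak_global = float(disc_mean[mask].max())
    at_max = mask & (image == in_vals.max())
    peak_local = float(disc_mean[at_max].max())
    return {"loc_peak_local": peak_local, "loc_peak_global": peak_global}, {}


def extract_intensity_histogram(disc: DiscretizedROI) -> tuple[dict[str, float], dict[str, str]]:
    """24 features of the discretized grey-level histogram."""
    g = disc.in_mask.astype(float)
    out, na = _dispersion_stats(g, "ih")
    ng = disc.n_bins
    counts = np.bincount(disc.in_mask, minlength=ng + 1)[1:]
    p = counts / counts.sum()
    nz = p > 0
    out["ih_mode"] = float(np.argmax(counts) + 1)  # lowest level on ties
    out["ih_entropy"] = float(-np.sum(p[nz] * np.log2(p[nz])))
    out["ih_uniformity"] = float(np.sum(p**2))
    out["ih_energy"] = float(np.sum(g**2))
    # histogram gradient: central differences, one-sided at the ends
    grad = np.gradient(counts.astype(float))
    out["ih_max_grad"] = float(grad.max())
    out["ih_max_grad_g"] = float(np.argmax(grad) + 1)
    out["ih_min_grad"] = float(grad.min())
    out["ih_min_grad_g"] = float(np.argmin(grad) + 1)
    return out, na


def extract_ivh(image: np.ndarray, mask: np.ndarray) -> tuple[dict[str, float], dict[str, str]]:
    """13 intensity-volume-histogram features on continuous intensities.

    nu(i) is the fraction of ROI pixels with intensity >= i.  V_x is nu at
    the intensity fraction x of the in-ROI range; I_x is the intensity at
    which the volume fraction reaches x, linearly interpolated on a
    1000-point grid.
    """
    x = np.sort(np.asarray(image, float)[np.asarray(mask, bool)])
    if x.size == 0:
        raise ValueError("mask is empty")
    lo, hi = x[0], x[-1]
    out: dict[str, float] = {}
    fracs = (10, 25, 50, 75, 90)
    if hi == lo:
        for f in fracs:
            out[f"ivh_v{f}"] = 1.0
            out[f"ivh_i{f}"] = float(lo)
        out["ivh_diff_v10_v90"] = 0.0
        out["ivh_diff_i10_i90"] = 0.0
        out["ivh_auc"] = 1.0
        return out, {}
    grid = np.linspace(lo, hi, IVH_GRID_POINTS)
    # fraction of pixels with value >= threshold
    nu = 1.0 - np.searchsorted(x, grid, side="left") / x.size
    for f in fracs:
        thr = lo + (hi - lo) * f / 100.0
        out[f"ivh_v{f}"] = float(1.0 - np.searchsorted(x, thr, side="left") / x.size)
    # I_x: smallest grid intensity where nu drops to <= x, linear interp.
    # nu is non-increasing; interpolate on the reversed arrays.
    for f in fracs:
        target = f / 100.0
        if nu[0] <= target:
            out[f"ivh_i{f}"] = float(lo)
        elif nu[-1] >= target:
            out[f"ivh_i{f}"] = float(hi)
        else:
            k = int(np.argmax(nu <= target))
            n1, n0 = nu[k - 1], nu[k]
            g1, g0 = grid[k - 1], grid[k]
            w = (n1 - target) / (n1 - n0) if n1 > n0 else 1.0
            out[f"ivh_i{f}"] = float(g1 + w * (g0 - g1))
    out["ivh_diff_v10_v90"] = out["ivh_v10"] - out["ivh_v90"]
    out["ivh_diff_i10_i90"] = out["ivh_i10"] - out["ivh_i90"]
    gamma = (grid - lo) / (hi - lo)
    out["ivh_auc"] = float(np.trapezoid(nu, gamma))
    return out, {}


def extract_first_order(
    image: np.ndarray,
    mask: np.ndarray,
    disc: DiscretizedROI,
    spacing: float,
) -> tuple[dict[str, float], dict[str, str]]:
    """All 57 first-order features for one ROI."""
    out: dict[str, float] = {}
    na: dict[str, str] = {}
    for vals, reasons in (
        extract_statistics(image, mask),
        extract_local_intensity(image, mask, spacing),
        extract_intensity_histogram(disc),
        extract_ivh(image, mask),
    ):
        out.update(vals)
        na.update(reasons)
    assert set(out) == set(FIRST_ORDER_FEATURES)
    return out, na
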