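"""2D morphological features of a region-of-interest mask.

The 25-item manifest covers size (area, perimeter), compactness and
circularity variants, principal-component axis descriptors (elongation,
eccentricity), convex-hull densities, bounding-box densities, approximate
enclosing ellipse densities and topology (components, Euler number).
All lengths are in mm and areas in mm^2; the pixel grid must be isotropic.

``morph_pca_elongation`` is sqrt(lambda_minor / lambda_major) of the in-mask
pixel-centre coordinates: 1 for a perfectly circular ROI, smaller values for
more elongated ROIs, and 0 for a degenerate single-line ROI.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import euler_number, perimeter as _sk_perimeter
from skimage.morphology import convex_hull_image

MORPH_FEATURES = (
    "morph_area",
    "morph_n_pixels",
    "morph_perim",
    "morph_pa_ratio",
    "morph_comp_1",
    "morph_comp_2",
    "morph_circularity",
    "morph_sph_dispr",
    "morph_asphericity",
    "morph_equiv_diam",
    "morph_diam",
    "morph_pca_maj_axis",
    "morph_pca_min_axis",
    "morph_pca_elongation",
    "morph_pca_eccentricity",
    "morph_area_convex",
    "morph_perim_convex",
    "morph_solidity",
    "morph_convexity",
    "morph_area_dens_aabb",
    "morph_perim_dens_aabb",
    "morph_area_dens_aee",
    "morph_perim_dens_aee",
    "morph_n_components",
    "morph_euler",
)

_EIGHT = np.ones((3, 3), dtype=int)


def _ellipse_perimeter(a: float, b: float) -> float:
    """Ramanujan's second approximation to the perimeter of an ellipse."""
    if a + b == 0:
        return 0.0
    h = ((a - b) / (a + b)) ** 2
    return float(np.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + np.sqrt(4.0 - 3.0 * h))))


def _max_diameter(coords_mm: np.ndarray) -> float:
    """Largest pairwise distance between pixel centres (hull-accelerated)."""
    pts = coords_mm
    if len(pts) > 10:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:  # collinear masks
            pass
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def extract_morphology(
    mask: np.ndarray, spacing: float | tuple[float, float]
) -> tuple[dict[str, float], dict[str, str]]:
    """Compute the 25 morphology features for a boolean mask.

    Returns ``(values, na_reasons)``; features that are undefined for the
    given mask (e.g. axis densities of a single pixel) are NaN with a reason.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    s = spacing if np.isscalar(spacing) else spacing[0]
    if not np.isscalar(spacing) and not np.isclose(spacing[0], spacing[1]):
        raise ValueError("morphology requires isotropic spacing; resample first")
    s = float(s)
    px_area = s * s

    out: dict[str, float] = {}
    na: dict[str, str] = {}
    n_px = int(mask.sum())
    area = n_px * px_area
    perim = float(_sk_perimeter(mask, neighborhood=4)) * s

    out["morph_area"] = area
    out["morph_n_pixels"] = float(n_px)
    out["morph_perim"] = perim
    out["morph_pa_ratio"] = perim / area
    if perim > 0:
        out["morph_comp_1"] = area / perim**2
        out["morph_comp_2"] = 4.0 * np.pi * area / perim**2
        circ = 2.0 * np.sqrt(np.pi * area) / perim
        out["morph_circularity"] = circ
        out["morph_sph_dispr"] = 1.0 / circ
        out["morph_asphericity"] = 1.0 / circ - 1.0
    else:
        for k in ("morph_comp_1", "morph_comp_2", "morph_circularity",
                  "morph_sph_dispr", "morph_asphericity"):
            out[k] = np.nan
            na[k] = "zero perimeter"
    out["morph_equiv_diam"] = 2.0 * np.sqrt(area / np.pi)

    coords = np.argwhere(mask).astype(float) * s
    out["morph_diam"] = _max_diameter(coords)

    # principal-component axes of the pixel-centre point cloud
    if n_px == 1:
        # degenerate: a single pixel is treated as perfectly circular
        out["morph_pca_maj_axis"] = 0.0
        out["morph_pca_min_axis"] = 0.0
        out["morph_pca_elongation"] = 1.0
        out["morph_pca_eccentricity"] = 0.0
        na["morph_pca_elongation"] = "single-pixel mask; elongation fixed at 1"
        lam_min = lam_maj = 0.0
    else:
        cov = np.cov(coords.T, ddof=0)
        lam_min, lam_maj = np.maximum(np.linalg.eigvalsh(cov), 0.0)
        out["morph_pca_maj_axis"] = 4.0 * np.sqrt(lam_maj)
        out["morph_pca_min_axis"] = 4.0 * np.sqrt(lam_min)
        out["morph_pca_elongation"] = float(np.sqrt(lam_min / lam_maj)) if lam_maj > 0 else 1.0
        out["morph_pca_eccentricity"] = (
            float(np.sqrt(1.0 - lam_min / lam_maj)) if lam_maj > 0 else 0.0
        )

    hull_img = convex_hull_image(mask)
    area_conv = float(hull_img.sum()) * px_area
    perim_conv = float(_sk_perimeter(hull_img, neighborhood=4)) * s
    out["morph_area_convex"] = area_conv
    out["morph_perim_convex"] = perim_conv
    out["morph_solidity"] = area / area_conv if area_conv > 0 else np.nan
    if perim > 0 and perim_conv > 0:
        out["morph_convexity"] = perim_conv / perim
    else:
        out["morph_convexity"] = np.nan
        na["morph_convexity"] = "zero perimeter"

    rows, cols = np.nonzero(mask)
    bb_h = (rows.max() - rows.min() + 1) * s
    bb_w = (cols.max() - cols.min() + 1) * s
    out["morph_area_dens_aabb"] = area / (bb_h * bb_w)
    out["morph_perim_dens_aabb"] = perim / (2.0 * (bb_h + bb_w))

    # approximate enclosing ellipse from the PCA axes (semi-axes 2*sqrt(lam))
    a_semi, b_semi = 2.0 * np.sqrt(lam_maj), 2.0 * np.sqrt(lam_min)
    if a_semi > 0 and b_semi > 0:
        out["morph_area_dens_aee"] = area / (np.pi * a_semi * b_semi)
        out["morph_perim_dens_aee"] = _ellipse_perimeter(a_semi, b_semi) / perim
    else:
        out["morph_area_dens_aee"] = np.nan
        out["morph_perim_dens_aee"] = np.nan
        na["morph_area_dens_aee"] = "degenerate PCA axis"
        na["morph_perim_dens_aee"] = "degenerate PCA axis"

    _, n_comp = ndimage.label(mask, structure=_EIGHT)
    out["morph_n_components"] = float(n_comp)
    out["morph_euler"] = float(euler_number(mask, connectivity=2))

    assert set(out) == set(MORPH_FEATURES)
    return out, na
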