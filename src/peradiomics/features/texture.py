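"""Second-order texture features on the 24-level discretized ROI.

Six matrix families are computed in 2D:

* GLCM  — grey level co-occurrence, distance 1, the four planar directions
  merged into a single symmetric matrix before feature computation (25).
* GLRLM — grey level run lengths, four directions merged (16).
* GLSZM — grey level size zones, 8-connected zones (16).
* GLDZM — grey level distance zones; the zone distance is the smallest
  city-block distance of any zone pixel to the ROI edge, border pixels
  having distance 1 (16).
* NGTDM — neighbourhood grey tone difference, distance 1 (5).
* NGLDM — neighbouring grey level dependence, distance 1, coarseness
  parameter a = 0; the dependence index j is the count of level-matching
  neighbours plus one (17).

Features undefined on degenerate matrices (e.g. correlation of a
single-level ROI) are returned as NaN with a reason.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .discretize import DiscretizedROI

_EIGHT = np.ones((3, 3), dtype=int)
_DIRECTIONS = ((0, 1), (1, 0), (1, 1), (1, -1))

GLCM_FEATURES = (
    "cm_joint_max", "cm_joint_avg", "cm_joint_var", "cm_joint_entr",
    "cm_diff_avg", "cm_diff_var", "cm_diff_entr",
    "cm_sum_avg", "cm_sum_var", "cm_sum_entr",
    "cm_energy", "cm_contrast", "cm_dissimilarity",
    "cm_inv_diff", "cm_inv_diff_norm", "cm_inv_diff_mom",
    "cm_inv_diff_mom_norm", "cm_inv_var", "cm_corr", "cm_auto_corr",
    "cm_clust_tend", "cm_clust_shade", "cm_clust_prom",
    "cm_info_corr1", "cm_info_corr2",
)

GLRLM_FEATURES = (
    "rlm_sre", "rlm_lre", "rlm_lgre", "rlm_hgre",
    "rlm_srlge", "rlm_srhge", "rlm_lrlge", "rlm_lrhge",
    "rlm_glnu", "rlm_glnu_norm", "rlm_rlnu", "rlm_rlnu_norm",
    "rlm_r_perc", "rlm_gl_var", "rlm_rl_var", "rlm_rl_entr",
)

GLSZM_FEATURES = (
    "szm_sze", "szm_lze", "szm_lgze", "szm_hgze",
    "szm_szlge", "szm_szhge", "szm_lzlge", "szm_lzhge",
    "szm_glnu", "szm_glnu_norm", "szm_zsnu", "szm_zsnu_norm",
    "szm_z_perc", "szm_gl_var", "szm_zs_var", "szm_zs_entr",
)

GLDZM_FEATURES = (
    "dzm_sde", "dzm_lde", "dzm_lgze", "dzm_hgze",
    "dzm_sdlge", "dzm_sdhge", "dzm_ldlge", "dzm_ldhge",
    "dzm_glnu", "dzm_glnu_norm", "dzm_zdnu", "dzm_zdnu_norm",
    "dzm_z_perc", "dzm_gl_var", "dzm_zd_var", "dzm_zd_entr",
)

NGTDM_FEATURES = (
    "ngt_coarseness", "ngt_contrast", "ngt_busyness",
    "ngt_complexity", "ngt_strength",
)

NGLDM_FEATURES = (
    "ngl_lde", "ngl_hde", "ngl_lgce", "ngl_hgce",
    "ngl_ldlge", "ngl_ldhge", "ngl_hdlge", "ngl_hdhge",
    "ngl_glnu", "ngl_glnu_norm", "ngl_dcnu", "ngl_dcnu_norm",
    "ngl_dc_perc", "ngl_gl_var", "ngl_dc_var", "ngl_dc_entr",
    "ngl_dc_energy",
)

TEXTURE_FEATURES = (
    GLCM_FEATURES + GLRLM_FEATURES + GLSZM_FEATURES
    + GLDZM_FEATURES + NGTDM_FEATURES + NGLDM_FEATURES
)


# ---------------------------------------------------------------- matrices

def glcm_matrix(disc: DiscretizedROI) -> np.ndarray:
    """Symmetric distance-1 co-occurrence matrix merged over 4 directions."""
    lv, ng = disc.levels, disc.n_bins
    m = np.zeros((ng, ng), dtype=float)
    nr, nc = lv.shape
    for dr, dc in _DIRECTIONS:
        r0, r1 = max(0, -dr), min(nr, nr - dr)
        c0, c1 = max(0, -dc), min(nc, nc - dc)
        a = lv[r0:r1, c0:c1]
        b = lv[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        ok = (a > 0) & (b > 0)
        np.add.at(m, (a[ok] - 1, b[ok] - 1), 1.0)
    return m + m.T  # symmetric merged counts


def glrlm_matrix(disc: DiscretizedROI) -> np.ndarray:
    """Run-length matrix merged over 4 directions; rows = level, cols = length."""
    lv = disc.levels
    nr, nc = lv.shape
    lines: list[np.ndarray] = []
    lines.extend(lv)                       # horizontal
    lines.extend(lv.T)                     # vertical
    for off in range(-(nr - 1), nc):       # diagonal (1,1)
        lines.append(np.diagonal(lv, off))
    flipped = np.fliplr(lv)
    for off in range(-(nr - 1), nc):       # anti-diagonal (1,-1)
        lines.append(np.diagonal(flipped, off))
    # one RLE pass over all lines joined by out-of-mask separators
    sep = np.zeros(1, dtype=lv.dtype)
    joined = np.concatenate([np.concatenate([ln, sep]) for ln in lines])
    change = np.flatnonzero(np.diff(joined) != 0) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [joined.size]))
    levels = joined[starts]
    lengths = ends - starts
    keep = levels > 0
    levels, lengths = levels[keep], lengths[keep]
    max_len = int(lengths.max()) if lengths.size else 1
    m = np.zeros((disc.n_bins, max_len), dtype=float)
    np.add.at(m, (levels - 1, lengths - 1), 1.0)
    return m


def zone_table(disc: DiscretizedROI) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """8-connected same-level zones as parallel arrays (level, size, distance).

    The zone distance is the smallest city-block distance of any zone pixel
    to the first pixel outside the ROI (image borders count as outside), so
    ROI-edge pixels have distance 1.
    """
    pad = np.pad(disc.mask, 1, constant_values=False)
    dist = ndimage.distance_transform_cdt(pad, metric="taxicab")[1:-1, 1:-1]
    levels_out: list[np.ndarray] = []
    sizes_out: list[np.ndarray] = []
    dists_out: list[np.ndarray] = []
    for level in np.unique(disc.in_mask):
        lab, n = ndimage.label(disc.levels == level, structure=_EIGHT)
        if n == 0:
            continue
        idx = np.arange(1, n + 1)
        sizes_out.append(np.bincount(lab.ravel(), minlength=n + 1)[1:])
        dists_out.append(ndimage.minimum(dist, labels=lab, index=idx))
        levels_out.append(np.full(n, level, dtype=int))
    return (
        np.concatenate(levels_out),
        np.concatenate(sizes_out).astype(int),
        np.concatenate(dists_out).astype(int),
    )


def glszm_matrix(disc: DiscretizedROI) -> np.ndarray:
    """Size-zone matrix; rows = level, cols = zone size."""
    levels, sizes, _ = zone_table(disc)
    m = np.zeros((disc.n_bins, int(sizes.max())), dtype=float)
    np.add.at(m, (levels - 1, sizes - 1), 1.0)
    return m


def gldzm_matrix(disc: DiscretizedROI) -> np.ndarray:
    """Distance-zone matrix; rows = level, cols = zone distance."""
    levels, _, dists = zone_table(disc)
    m = np.zeros((disc.n_bins, int(dists.max())), dtype=float)
    np.add.at(m, (levels - 1, dists - 1), 1.0)
    return m


def _neighbour_stats(disc: DiscretizedROI) -> tuple[np.ndarray, np.ndarray]:
    """In-mask 8-neighbour sum of levels and neighbour counts per pixel."""
    lv = disc.levels.astype(float)
    inm = disc.mask.astype(float)
    kern = _EIGHT.astype(float).copy()
    kern[1, 1] = 0.0
    nsum = ndimage.correlate(lv * inm, kern, mode="constant", cval=0.0)
    ncnt = ndimage.correlate(inm, kern, mode="constant", cval=0.0)
    return nsum, ncnt


def ngtdm_table(disc: DiscretizedROI) -> tuple[np.ndarray, np.ndarray]:
    """Per-level occurrence counts n_i and summed tone differences s_i."""
    ng = disc.n_bins
    nsum, ncnt = _neighbour_stats(disc)
    valid = disc.mask & (ncnt > 0)
    diff = np.zeros_like(nsum)
    diff[valid] = np.abs(disc.levels[valid] - nsum[valid] / ncnt[valid])
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    np.add.at(n_i, disc.levels[valid] - 1, 1.0)
    np.add.at(s_i, disc.levels[valid] - 1, diff[valid])
    return n_i, s_i


def ngldm_matrix(disc: DiscretizedROI) -> np.ndarray:
    """Dependence matrix; rows = level, cols = dependence count + 1."""
    lv = disc.levels
    nr, nc = lv.shape
    dep = np.zeros(lv.shape, dtype=int)
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1), (0, -1), (-1, 0), (-1, -1), (-1, 1)):
        r0, r1 = max(0, -dr), min(nr, nr - dr)
        c0, c1 = max(0, -dc), min(nc, nc - dc)
        a = lv[r0:r1, c0:c1]
        b = lv[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        dep[r0:r1, c0:c1] += ((a > 0) & (a == b)).astype(int)
    j = dep[disc.mask] + 1
    m = np.zeros((disc.n_bins, int(j.max())), dtype=float)
    np.add.at(m, (lv[disc.mask] - 1, j - 1), 1.0)
    return m


# ---------------------------------------------------------------- features

def _entropy(p: np.ndarray) -> float:
    nz = p > 0
    return float(-np.sum(p[nz] * np.log2(p[nz])))


def glcm_features(m: np.ndarray) -> tuple[dict[str, float], dict[str, str]]:
    total = m.sum()
    if total == 0:
        raise ValueError("empty co-occurrence matrix (no neighbour pairs)")
    p = m / total
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    out: dict[str, float] = {}
    na: dict[str, str] = {}

    out["cm_joint_max"] = float(p.max())
    mu = float((ii * p).sum())
    out["cm_joint_avg"] = mu
    out["cm_joint_var"] = float(((ii - mu) ** 2 * p).sum())
    out["cm_joint_entr"] = _entropy(p.ravel())

    k_diff = np.arange(ng)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])
    da = float((k_diff * p_diff).sum())
    out["cm_diff_avg"] = da
    out["cm_diff_var"] = float((((k_diff - da) ** 2) * p_diff).sum())
    out["cm_diff_entr"] = _entropy(p_diff)

    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.array([p[ii + jj == k].sum() for k in k_sum])
    sa = float((k_sum * p_sum).sum())
    out["cm_sum_avg"] = sa
    out["cm_sum_var"] = float((((k_sum - sa) ** 2) * p_sum).sum())
    out["cm_sum_entr"] = _entropy(p_sum)

    out["cm_energy"] = float((p**2).sum())
    out["cm_contrast"] = float((((ii - jj) ** 2) * p).sum())
    out["cm_dissimilarity"] = float((np.abs(ii - jj) * p).sum())
    out["cm_inv_diff"] = float((p / (1.0 + np.abs(ii - jj))).sum())
    out["cm_inv_diff_norm"] = float((p / (1.0 + np.abs(ii - jj) / ng)).sum())
    out["cm_inv_diff_mom"] = float((p / (1.0 + (ii - jj) ** 2)).sum())
    out["cm_inv_diff_mom_norm"] = float((p / (1.0 + (ii - jj) ** 2 / ng**2)).sum())
    off = ii != jj
    out["cm_inv_var"] = float((p[off] / (ii[off] - jj[off]) ** 2).sum())

    var_x = float(((i - mu) ** 2 * px).sum())
    auto = float((ii * jj * p).sum())
    out["cm_auto_corr"] = auto
    if var_x > 0:
        out["cm_corr"] = (auto - mu * mu) / var_x  # symmetric: mu_x = mu_y
    else:
        out["cm_corr"] = np.nan
        na["cm_corr"] = "single grey level (zero marginal variance)"
    out["cm_clust_tend"] = float((((ii + jj - 2 * mu) ** 2) * p).sum())
    out["cm_clust_shade"] = float((((ii + jj - 2 * mu) ** 3) * p).sum())
    out["cm_clust_prom"] = float((((ii + jj - 2 * mu) ** 4) * p).sum())

    hxy = out["cm_joint_entr"]
    hx = _entropy(px)
    pxpy = np.outer(px, px)
    nz = (p > 0) & (pxpy > 0)
    hxy1 = float(-np.sum(p[nz] * np.log2(pxpy[nz])))
    nz2 = pxpy > 0
    hxy2 = float(-np.sum(pxpy[nz2] * np.log2(pxpy[nz2])))
    if hx > 0:
        out["cm_info_corr1"] = (hxy - hxy1) / hx
    else:
        out["cm_info_corr1"] = np.nan
        na["cm_info_corr1"] = "single grey level (zero marginal entropy)"
    out["cm_info_corr2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    return out, na


def _run_style_features(
    m: np.ndarray, prefix: str, axis_names: tuple[str, ...], n_vox: float
) -> tuple[dict[str, float], dict[str, str]]:
    """Shared feature formulas for GLRLM/GLSZM/GLDZM-style matrices.

    ``axis_names`` supplies the family-specific feature keys in the order:
    (small, large, low-grey, high-grey, small-low, small-high, large-low,
    large-high, glnu, glnu_norm, axisnu, axisnu_norm, perc, gl_var,
    axis_var, axis_entr).
    """
    ns = m.sum()
    p = m / ns
    ng, nl = m.shape
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, nl + 1)[None, :]
    out: dict[str, float] = {}
    keys = [f"{prefix}_{k}" for k in axis_names]
    out[keys[0]] = float((p / j**2).sum())
    out[keys[1]] = float((p * j**2).sum())
    out[keys[2]] = float((p / i**2).sum())
    out[keys[3]] = float((p * i**2).sum())
    out[keys[4]] = float((p / (i**2 * j**2)).sum())
    out[keys[5]] = float((p * i**2 / j**2).sum())
    out[keys[6]] = float((p * j**2 / i**2).sum())
    out[keys[7]] = float((p * i**2 * j**2).sum())
    out[keys[8]] = float((m.sum(axis=1) ** 2).sum() / ns)
    out[keys[9]] = float((p.sum(axis=1) ** 2).sum())
    out[keys[10]] = float((m.sum(axis=0) ** 2).sum() / ns)
    out[keys[11]] = float((p.sum(axis=0) ** 2).sum())
    out[keys[12]] = float(ns / n_vox)
    mu_i = float((i * p).sum())
    out[keys[13]] = float((((i - mu_i) ** 2) * p).sum())
    mu_j = float((j * p).sum())
    out[keys[14]] = float((((j - mu_j) ** 2) * p).sum())
    out[keys[15]] = _entropy(p.ravel())
    return out, {}


_RLM_KEYS = ("sre", "lre", "lgre", "hgre", "srlge", "srhge", "lrlge", "lrhge",
             "glnu", "glnu_norm", "rlnu", "rlnu_norm", "r_perc", "gl_var",
             "rl_var", "rl_entr")
_SZM_KEYS = ("sze", "lze", "lgze", "hgze", "szlge", "szhge", "lzlge", "lzhge",
             "glnu", "glnu_norm", "zsnu", "zsnu_norm", "z_perc", "gl_var",
             "zs_var", "zs_entr")
_DZM_KEYS = ("sde", "lde", "lgze", "hgze", "sdlge", "sdhge", "ldlge", "ldhge",
             "glnu", "glnu_norm", "zdnu", "zdnu_norm", "z_perc", "gl_var",
             "zd_var", "zd_entr")
_NGL_KEYS = ("lde", "hde", "lgce", "hgce", "ldlge", "ldhge", "hdlge", "hdhge",
             "glnu", "glnu_norm", "dcnu", "dcnu_norm", "dc_perc", "gl_var",
             "dc_var", "dc_entr")


def ngtdm_features(n_i: np.ndarray, s_i: np.ndarray) -> tuple[dict[str, float], dict[str, str]]:
    n_vox = n_i.sum()
    p_i = n_i / n_vox
    i = np.arange(1, len(n_i) + 1).astype(float)
    nz = p_i > 0
    ngp = int(nz.sum())
    out: dict[str, float] = {}
    na: dict[str, str] = {}
    dens = float((p_i * s_i).sum())
    out["ngt_coarseness"] = 1.0 / dens if dens > 0 else 1e6
    if ngp > 1:
        pij = np.subtract.outer(i[nz], i[nz]) ** 2
        w = np.outer(p_i[nz], p_i[nz])
        out["ngt_contrast"] = float(
            (w * pij).sum() / (ngp * (ngp - 1)) * s_i.sum() / n_vox
        )
        ipn = i[nz] * p_i[nz]
        denom_b = float(np.abs(np.subtract.outer(ipn, ipn)).sum())
        out["ngt_busyness"] = dens / denom_b if denom_b > 0 else 0.0
        pi_nz, si_nz = p_i[nz], s_i[nz]
        num = np.abs(np.subtract.outer(i[nz], i[nz])) * (
            np.add.outer(pi_nz * si_nz, pi_nz * si_nz)
        ) / np.add.outer(pi_nz, pi_nz)
        out["ngt_complexity"] = float(num.sum() / n_vox)
        s_sum = s_i.sum()
        strength_num = float((np.add.outer(pi_nz, pi_nz) * pij).sum())
        out["ngt_strength"] = strength_num / s_sum if s_sum > 0 else 0.0
    else:
        out["ngt_contrast"] = 0.0
        out["ngt_busyness"] = 0.0
        out["ngt_complexity"] = 0.0
        out["ngt_strength"] = 0.0
        na.update({k: "single grey level" for k in
                   ("ngt_contrast", "ngt_busyness", "ngt_complexity", "ngt_strength")})
    return out, na


def extract_texture(disc: DiscretizedROI) -> tuple[dict[str, float], dict[str, str]]:
    """All 95 texture features for one discretized ROI."""
    n_vox = float(disc.mask.sum())
    out: dict[str, float] = {}
    na: dict[str, str] = {}

    vals, reasons = glcm_features(glcm_matrix(disc))
    out.update(vals), na.update(reasons)

    vals, _ = _run_style_features(glrlm_matrix(disc), "rlm", _RLM_KEYS, 4.0 * n_vox)
    out.update(vals)
    levels, sizes, dists = zone_table(disc)
    szm = np.zeros((disc.n_bins, int(sizes.max())), dtype=float)
    np.add.at(szm, (levels - 1, sizes - 1), 1.0)
    vals, _ = _run_style_features(szm, "szm", _SZM_KEYS, n_vox)
    out.update(vals)
    dzm = np.zeros((disc.n_bins, int(dists.max())), dtype=float)
    np.add.at(dzm, (levels - 1, dists - 1), 1.0)
    vals, _ = _run_style_features(dzm, "dzm", _DZM_KEYS, n_vox)
    out.update(vals)

    vals, reasons = ngtdm_features(*ngtdm_table(disc))
    out.update(vals), na.update(reasons)

    ngl = ngldm_matrix(disc)
    vals, _ = _run_style_features(ngl, "ngl", _NGL_KEYS, n_vox)
    vals["ngl_dc_energy"] = float(((ngl / ngl.sum()) ** 2).sum())
    out.update(vals)
    assert set(out) == set(TEXTURE_FEATURES)
    return out, na
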