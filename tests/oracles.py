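"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as plain loops over pixels, pairs,
runs and zones — no shared code with the package implementation — so that
agreement between the two is meaningful.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np

# ------------------------------------------------------------------ GLCM


def bf_glcm(levels: np.ndarray, ng: int) -> np.ndarray:
    """Distance-1 symmetric co-occurrence counts merged over 4 directions.

    Scans every in-mask pixel and, for each of the four planar directions,
    counts the ordered pair in both orientations.
    """
    m = np.zeros((ng, ng))
    nr, nc = levels.shape
    for r in range(nr):
        for c in range(nc):
            a = levels[r, c]
            if a == 0:
                continue
            for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < nr and 0 <= cc < nc and levels[rr, cc] > 0:
                    b = levels[rr, cc]
                    m[a - 1, b - 1] += 1
                    m[b - 1, a - 1] += 1
    return m


def bf_glcm_sum_average(levels: np.ndarray, ng: int) -> float:
    """Sum average from exhaustive pair counting."""
    m = bf_glcm(levels, ng)
    p = m / m.sum()
    out = 0.0
    for i in range(ng):
        for j in range(ng):
            out += (i + 1 + j + 1) * p[i, j]
    return out


# ----------------------------------------------------------------- GLRLM


def bf_glrlm(levels: np.ndarray, ng: int, max_len: int) -> np.ndarray:
    """Run-length counts merged over 4 directions via explicit line walks."""
    nr, nc = levels.shape
    m = np.zeros((ng, max_len))

    def walk(line: list[int]) -> None:
        run_level, run_len = 0, 0
        for v in line + [0]:
            if v == run_level:
                run_len += 1
            else:
                if run_level > 0:
                    m[run_level - 1, run_len - 1] += 1
                run_level, run_len = v, 1

    for r in range(nr):
        walk([int(levels[r, c]) for c in range(nc)])
    for c in range(nc):
        walk([int(levels[r, c]) for r in range(nr)])
    # diagonals direction (1, 1)
    for s in range(-(nr - 1), nc):
        walk([int(levels[r, r + s]) for r in range(nr) if 0 <= r + s < nc])
    # anti-diagonals direction (1, -1)
    for s in range(nr + nc - 1):
        walk([int(levels[r, s - r]) for r in range(nr) if 0 <= s - r < nc])
    return m


# ------------------------------------------------------------- zones


def bf_zone_list(levels: np.ndarray) -> list[tuple[int, list[tuple[int, int]]]]:
    """8-connected same-level zones by explicit flood fill."""
    nr, nc = levels.shape
    seen = np.zeros_like(levels, dtype=bool)
    zones = []
    for r in range(nr):
        for c in range(nc):
            if levels[r, c] == 0 or seen[r, c]:
                continue
            level = int(levels[r, c])
            stack = [(r, c)]
            seen[r, c] = True
            pix = []
            while stack:
                y, x = stack.pop()
                pix.append((y, x))
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        yy, xx = y + dy, x + dx
                        if (
                            0 <= yy < nr and 0 <= xx < nc
                            and not seen[yy, xx] and levels[yy, xx] == level
                        ):
                            seen[yy, xx] = True
                            stack.append((yy, xx))
            zones.append((level, pix))
    return zones


def bf_glszm(levels: np.ndarray, ng: int, max_size: int) -> np.ndarray:
    m = np.zeros((ng, max_size))
    for level, pix in bf_zone_list(levels):
        m[level - 1, len(pix) - 1] += 1
    return m


def bf_distance_map(mask: np.ndarray) -> np.ndarray:
    """City-block steps to outside the ROI by breadth-first search;
    border pixels get distance 1, image edges count as outside."""
    nr, nc = mask.shape
    dist = np.full(mask.shape, -1, dtype=int)
    q: deque[tuple[int, int]] = deque()
    for r in range(nr):
        for c in range(nc):
            if mask[r, c]:
                at_edge = r in (0, nr - 1) or c in (0, nc - 1)
                if at_edge or not all(
                    mask[r + dr, c + dc] for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0))
                ):
                    dist[r, c] = 1
                    q.append((r, c))
    while q:
        r, c = q.popleft()
        for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < nr and 0 <= cc < nc and mask[rr, cc] and dist[rr, cc] < 0:
                dist[rr, cc] = dist[r, c] + 1
                q.append((rr, cc))
    return dist


def bf_gldzm(levels: np.ndarray, ng: int, max_dist: int) -> np.ndarray:
    dist = bf_distance_map(levels > 0)
    m = np.zeros((ng, max_dist))
    for level, pix in bf_zone_list(levels):
        d = min(dist[r, c] for r, c in pix)
        m[level - 1, d - 1] += 1
    return m


# ------------------------------------------------------------- NGTDM/NGLDM


def bf_ngtdm(levels: np.ndarray, ng: int) -> tuple[np.ndarray, np.ndarray]:
    nr, nc = levels.shape
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    for r in range(nr):
        for c in range(nc):
            g = levels[r, c]
            if g == 0:
                continue
            neigh = []
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < nr and 0 <= cc < nc and levels[rr, cc] > 0:
                        neigh.append(levels[rr, cc])
            if neigh:
                n_i[g - 1] += 1
                s_i[g - 1] += abs(g - sum(neigh) / len(neigh))
    return n_i, s_i


def bf_ngldm(levels: np.ndarray, ng: int, max_dep: int) -> np.ndarray:
    """Dependence counts (same level, distance 1, a=0); column = count + 1."""
    nr, nc = levels.shape
    m = np.zeros((ng, max_dep))
    for r in range(nr):
        for c in range(nc):
            g = levels[r, c]
            if g == 0:
                continue
            k = 0
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < nr and 0 <= cc < nc and levels[rr, cc] == g:
                        k += 1
            m[g - 1, k] += 1
    return m


# ------------------------------------------------------------- evaluation


def bf_auc(scores, labels) -> float:
    """Pair-counting AUC with half credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def bf_delong_variance(x, y):
    """Variance of a single AUC from DeLong structural components."""
    x, y = list(x), list(y)
    m, n = len(x), len(y)

    def psi(a, b):
        return 1.0 if a > b else (0.5 if a == b else 0.0)

    auc = sum(psi(a, b) for a in x for b in y) / (m * n)
    v10 = [sum(psi(a, b) for b in y) / n for a in x]
    v01 = [sum(psi(a, b) for a in x) / m for b in y]
    s10 = sum((v - auc) ** 2 for v in v10) / (m - 1)
    s01 = sum((v - auc) ** 2 for v in v01) / (n - 1)
    return auc, s10 / m + s01 / n


def bf_icc_oneway(values: np.ndarray) -> float:
    """ICC(1,1) from explicitly assembled one-way ANOVA sums of squares."""
    values = np.asarray(values, float)
    n, k = values.shape
    grand = values.mean()
    ss_between = k * sum((row.mean() - grand) ** 2 for row in values)
    ss_within = sum((v - row.mean()) ** 2 for row in values for v in row)
    msb = ss_between / (n - 1)
    msw = ss_within / (n * (k - 1))
    return (msb - msw) / (msb + (k - 1) * msw)


def bf_mutual_information(cells: np.ndarray) -> float:
    """Plug-in MI in bits from a contingency table by direct summation."""
    cells = np.asarray(cells, float)
    n = cells.sum()
    mi = 0.0
    for i in range(cells.shape[0]):
        for j in range(cells.shape[1]):
            pij = cells[i, j] / n
            if pij > 0:
                pi = cells[i, :].sum() / n
                pj = cells[:, j].sum() / n
                mi += pij * math.log2(pij / (pi * pj))
    return mi


def bf_spearman(x, y) -> float:
    """Spearman rho via explicit average ranks and Pearson on ranks."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for t in range(i, j + 1):
                r[order[t]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


# ----------------------------------------------- feature-level oracles


def bf_glcm_features(m: np.ndarray) -> dict[str, float]:
    """All 25 co-occurrence features by explicit summation loops."""
    ng = m.shape[0]
    total = m.sum()
    p = m / total
    out: dict[str, float] = {}
    out["cm_joint_max"] = float(p.max())
    mu = sum((i + 1) * p[i, j] for i in range(ng) for j in range(ng))
    out["cm_joint_avg"] = mu
    out["cm_joint_var"] = sum((i + 1 - mu) ** 2 * p[i, j]
                              for i in range(ng) for j in range(ng))
    out["cm_joint_entr"] = -sum(p[i, j] * math.log2(p[i, j])
                                for i in range(ng) for j in range(ng) if p[i, j] > 0)
    p_diff = [sum(p[i, j] for i in range(ng) for j in range(ng) if abs(i - j) == k)
              for k in range(ng)]
    da = sum(k * pk for k, pk in enumerate(p_diff))
    out["cm_diff_avg"] = da
    out["cm_diff_var"] = sum((k - da) ** 2 * pk for k, pk in enumerate(p_diff))
    out["cm_diff_entr"] = -sum(pk * math.log2(pk) for pk in p_diff if pk > 0)
    p_sum = {k: sum(p[i, j] for i in range(ng) for j in range(ng) if i + j + 2 == k)
             for k in range(2, 2 * ng + 1)}
    sa = sum(k * pk for k, pk in p_sum.items())
    out["cm_sum_avg"] = sa
    out["cm_sum_var"] = sum((k - sa) ** 2 * pk for k, pk in p_sum.items())
    out["cm_sum_entr"] = -sum(pk * math.log2(pk) for pk in p_sum.values() if pk > 0)
    out["cm_energy"] = sum(p[i, j] ** 2 for i in range(ng) for j in range(ng))
    out["cm_contrast"] = sum((i - j) ** 2 * p[i, j]
                             for i in range(ng) for j in range(ng))
    out["cm_dissimilarity"] = sum(abs(i - j) * p[i, j]
                                  for i in range(ng) for j in range(ng))
    out["cm_inv_diff"] = sum(p[i, j] / (1 + abs(i - j))
                             for i in range(ng) for j in range(ng))
    out["cm_inv_diff_norm"] = sum(p[i, j] / (1 + abs(i - j) / ng)
                                  for i in range(ng) for j in range(ng))
    out["cm_inv_diff_mom"] = sum(p[i, j] / (1 + (i - j) ** 2)
                                 for i in range(ng) for j in range(ng))
    out["cm_inv_diff_mom_norm"] = sum(p[i, j] / (1 + (i - j) ** 2 / ng**2)
                                      for i in range(ng) for j in range(ng))
    out["cm_inv_var"] = sum(p[i, j] / (i - j) ** 2
                            for i in range(ng) for j in range(ng) if i != j)
    px = [sum(p[i, j] for j in range(ng)) for i in range(ng)]
    var_x = sum((i + 1 - mu) ** 2 * px[i] for i in range(ng))
    auto = sum((i + 1) * (j + 1) * p[i, j] for i in range(ng) for j in range(ng))
    out["cm_auto_corr"] = auto
    out["cm_corr"] = (auto - mu * mu) / var_x if var_x > 0 else float("nan")
    out["cm_clust_tend"] = sum((i + j + 2 - 2 * mu) ** 2 * p[i, j]
                               for i in range(ng) for j in range(ng))
    out["cm_clust_shade"] = sum((i + j + 2 - 2 * mu) ** 3 * p[i, j]
                                for i in range(ng) for j in range(ng))
    out["cm_clust_prom"] = sum((i + j + 2 - 2 * mu) ** 4 * p[i, j]
                               for i in range(ng) for j in range(ng))
    hxy = out["cm_joint_entr"]
    hx = -sum(v * math.log2(v) for v in px if v > 0)
    hxy1 = -sum(p[i, j] * math.log2(px[i] * px[j])
                for i in range(ng) for j in range(ng)
                if p[i, j] > 0 and px[i] * px[j] > 0)
    hxy2 = -sum(px[i] * px[j] * math.log2(px[i] * px[j])
                for i in range(ng) for j in range(ng) if px[i] * px[j] > 0)
    out["cm_info_corr1"] = (hxy - hxy1) / hx if hx > 0 else float("nan")
    out["cm_info_corr2"] = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))
    return out


def bf_run_features(m: np.ndarray, prefix: str, keys: tuple[str, ...],
                    n_vox: float) -> dict[str, float]:
    """The 16 shared run/zone/dependence formulas by explicit loops."""
    ng, nl = m.shape
    ns = m.sum()
    p = m / ns
    out: dict[str, float] = {}
    k = [f"{prefix}_{s}" for s in keys]
    out[k[0]] = sum(p[i, j] / (j + 1) ** 2 for i in range(ng) for j in range(nl))
    out[k[1]] = sum(p[i, j] * (j + 1) ** 2 for i in range(ng) for j in range(nl))
    out[k[2]] = sum(p[i, j] / (i + 1) ** 2 for i in range(ng) for j in range(nl))
    out[k[3]] = sum(p[i, j] * (i + 1) ** 2 for i in range(ng) for j in range(nl))
    out[k[4]] = sum(p[i, j] / ((i + 1) ** 2 * (j + 1) ** 2)
                    for i in range(ng) for j in range(nl))
    out[k[5]] = sum(p[i, j] * (i + 1) ** 2 / (j + 1) ** 2
                    for i in range(ng) for j in range(nl))
    out[k[6]] = sum(p[i, j] * (j + 1) ** 2 / (i + 1) ** 2
                    for i in range(ng) for j in range(nl))
    out[k[7]] = sum(p[i, j] * (i + 1) ** 2 * (j + 1) ** 2
                    for i in range(ng) for j in range(nl))
    out[k[8]] = sum(m[i, :].sum() ** 2 for i in range(ng)) / ns
    out[k[9]] = sum(p[i, :].sum() ** 2 for i in range(ng))
    out[k[10]] = sum(m[:, j].sum() ** 2 for j in range(nl)) / ns
    out[k[11]] = sum(p[:, j].sum() ** 2 for j in range(nl))
    out[k[12]] = ns / n_vox
    mu_i = sum((i + 1) * p[i, j] for i in range(ng) for j in range(nl))
    out[k[13]] = sum((i + 1 - mu_i) ** 2 * p[i, j]
                     for i in range(ng) for j in range(nl))
    mu_j = sum((j + 1) * p[i, j] for i in range(ng) for j in range(nl))
    out[k[14]] = sum((j + 1 - mu_j) ** 2 * p[i, j]
                     for i in range(ng) for j in range(nl))
    out[k[15]] = -sum(p[i, j] * math.log2(p[i, j])
                      for i in range(ng) for j in range(nl) if p[i, j] > 0)
    return out


def bf_ngtdm_features(n_i: np.ndarray, s_i: np.ndarray) -> dict[str, float]:
    ng = len(n_i)
    n_vox = n_i.sum()
    p = n_i / n_vox
    present = [i for i in range(ng) if p[i] > 0]
    ngp = len(present)
    out: dict[str, float] = {}
    dens = sum(p[i] * s_i[i] for i in range(ng))
    out["ngt_coarseness"] = 1.0 / dens if dens > 0 else 1e6
    if ngp > 1:
        out["ngt_contrast"] = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in present for j in present)
            / (ngp * (ngp - 1)) * sum(s_i) / n_vox
        )
        denom = sum(abs((i + 1) * p[i] - (j + 1) * p[j])
                    for i in present for j in present)
        out["ngt_busyness"] = dens / denom if denom > 0 else 0.0
        out["ngt_complexity"] = sum(
            abs(i - j) * (p[i] * s_i[i] + p[j] * s_i[j]) / (p[i] + p[j])
            for i in present for j in present
        ) / n_vox
        s_sum = sum(s_i)
        out["ngt_strength"] = (
            sum((p[i] + p[j]) * (i - j) ** 2 for i in present for j in present)
            / s_sum if s_sum > 0 else 0.0
        )
    else:
        out.update({"ngt_contrast": 0.0, "ngt_busyness": 0.0,
                    "ngt_complexity": 0.0, "ngt_strength": 0.0})
    return out
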