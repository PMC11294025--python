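"""Perturbation-based feature robustness screening.

Each training slice is perturbed five times: Gaussian noise with the
standard deviation present in the compartment is added to the image, and
the compartment area is changed by one of {-10%, -5%, 0%, +5%, +10%}.
Features are re-extracted from every perturbed slice; a feature is kept
only if the lower bound of the 95% confidence interval of its one-way
intraclass correlation coefficient across the replicates is at least 0.8.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .features import N_BINS_DEFAULT, build_feature_table
from .prep import CTSlice, ROIMask

VOLUME_CHANGES = (-0.10, -0.05, 0.0, 0.05, 0.10)
ICC_CI_THRESHOLD = 0.8


@dataclass(frozen=True)
class PerturbationSpec:
    """Joint noise + ROI-volume perturbation, five replicates per slice."""

    volume_changes: tuple[float, ...] = VOLUME_CHANGES
    seed: int = 0

    @property
    def n_replicates(self) -> int:
        return len(self.volume_changes)


@dataclass
class RobustnessResult:
    """Per-feature ICC with confidence bounds and the keep decision."""

    table: pd.DataFrame  # columns: icc, ci_low, ci_high, keep
    threshold: float = ICC_CI_THRESHOLD
    flags: dict[str, str] = field(default_factory=dict)

    @property
    def kept(self) -> list[str]:
        return list(self.table.index[self.table["keep"]])


def _resize_mask(mask: np.ndarray, target: int, rng: np.random.Generator) -> np.ndarray:
    """Shrink or grow a mask to ``target`` pixels along its distance contours.

    Erosion removes the shallowest in-mask pixels (smallest Euclidean
    distance to the boundary); dilation adds the nearest outside pixels —
    the limit of iterated one-pixel morphological steps, but able to stop
    at the exact pixel count. Ties are broken randomly (reproducibly).
    """
    area = int(mask.sum())
    if target == area:
        return mask.copy()
    if target <= 0:
        raise ValueError("target area must be positive")
    out = mask.copy()
    if target < area:
        dist = ndimage.distance_transform_edt(mask)
        coords = np.argwhere(mask)
        d = dist[mask]
        order = np.lexsort((rng.random(len(d)), d))
        n_remove = min(area - target, max(0, area - 1))  # never empty the mask
        drop = coords[order[:n_remove]]
        out[drop[:, 0], drop[:, 1]] = False
    else:
        dist = ndimage.distance_transform_edt(~mask)
        coords = np.argwhere(~mask)
        d = dist[~mask]
        order = np.lexsort((rng.random(len(d)), d))
        add = coords[order[: target - area]]
        out[add[:, 0], add[:, 1]] = True
    return out


def perturb(
    ct: CTSlice,
    compartment: ROIMask,
    spec: PerturbationSpec,
    replicate_index: int,
) -> tuple[CTSlice, ROIMask]:
    """One perturbed (slice, compartment) replicate.

    ``replicate_index`` runs 1..5 and selects the volume change; the noise
    draw is deterministic given the spec seed, slice id and replicate.
    """
    if not 1 <= replicate_index <= spec.n_replicates:
        raise ValueError(
            f"replicate_index must be in 1..{spec.n_replicates}, got {replicate_index}"
        )
    frac = spec.volume_changes[replicate_index - 1]
    key = [spec.seed, replicate_index, zlib.crc32(ct.patient_id.encode())]
    rng = np.random.default_rng(np.random.SeedSequence(key))
    sd = float(ct.values[compartment.mask].std())
    noisy = ct.values + rng.normal(0.0, sd, ct.values.shape)
    target = int(round(compartment.mask.sum() * (1.0 + frac)))
    if frac == 0.0:
        new_mask = compartment.mask.copy()
    else:
        new_mask = _resize_mask(compartment.mask, target, rng)
    new_ct = CTSlice(values=noisy, spacing=ct.spacing, patient_id=ct.patient_id)
    new_roi = ROIMask(mask=new_mask, tissue=compartment.tissue, window=compartment.window)
    return new_ct, new_roi


def icc_oneway(values: np.ndarray) -> tuple[float, float, float]:
    """One-way random-effects ICC(1,1) with exact F-based 95% bounds.

    ``values`` is patients x replicates. A table with zero total variance
    has ICC 1 by convention (degenerate CI [1, 1]).
    """
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    if n < 5 or k < 2:
        raise ValueError(f"need >= 5 patients and >= 2 replicates, got {values.shape}")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite values in ICC input")
    if np.ptp(values) == 0:
        return 1.0, 1.0, 1.0
    row_means = values.mean(axis=1)
    grand = values.mean()
    msb = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msw = np.sum((values - row_means[:, None]) ** 2) / (n * (k - 1))
    if msw == 0:
        return 1.0, 1.0, 1.0
    icc = (msb - msw) / (msb + (k - 1) * msw)
    f_obs = msb / msw
    df1, df2 = n - 1, n * (k - 1)
    f_low = f_obs / stats.f.ppf(0.975, df1, df2)
    f_up = f_obs * stats.f.ppf(0.975, df2, df1)
    ci_low = (f_low - 1.0) / (f_low + k - 1.0)
    ci_high = (f_up - 1.0) / (f_up + k - 1.0)
    return float(icc), float(ci_low), float(ci_high)


def perturbed_feature_tables(
    slices: list[CTSlice],
    compartments: list[ROIMask],
    tissue: str,
    spec: PerturbationSpec,
    n_bins: int = N_BINS_DEFAULT,
) -> list[pd.DataFrame]:
    """Feature tables of the five perturbed replicates of a cohort."""
    tables = []
    for rep in range(1, spec.n_replicates + 1):
        pert = [perturb(ct, comp, spec, rep) for ct, comp in zip(slices, compartments)]
        tab = build_feature_table([p[0] for p in pert], [p[1] for p in pert],
                                  tissue, n_bins)
        tables.append(tab.frame)
    return tables


def filter_robust(
    baseline: pd.DataFrame,
    replicate_frames: list[pd.DataFrame],
    threshold: float = ICC_CI_THRESHOLD,
) -> tuple[pd.DataFrame, RobustnessResult]:
    """Drop features whose ICC lower confidence bound falls below ``threshold``.

    Returns the filtered baseline table and the per-feature report.
    Features with missing values in any replicate are assessed on complete
    patients only; features with fewer than 5 complete patients are dropped
    with a flag.
    """
    rows = {}
    flags: dict[str, str] = {}
    for feat in baseline.columns:
        mat = np.column_stack([f[feat].to_numpy(dtype=float) for f in replicate_frames])
        ok = np.all(np.isfinite(mat), axis=1)
        if ok.sum() < 5:
            rows[feat] = (np.nan, np.nan, np.nan, False)
            flags[feat] = "fewer than 5 patients with complete replicates"
            continue
        icc, lo, hi = icc_oneway(mat[ok])
        if lo == hi == 1.0:
            flags[feat] = "zero variance across patients and replicates; ICC 1 by convention"
        rows[feat] = (icc, lo, hi, lo >= threshold)
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["icc", "ci_low", "ci_high", "keep"]
    ).loc[list(baseline.columns)]
    kept = baseline[table.index[table["keep"]]]
    return kept, RobustnessResult(table=table, threshold=threshold, flags=flags)


__all__ = [
    "PerturbationSpec", "RobustnessResult", "VOLUME_CHANGES", "ICC_CI_THRESHOLD",
    "perturb", "icc_oneway", "perturbed_feature_tables", "filter_robust",
]
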