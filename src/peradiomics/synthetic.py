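"""Synthetic CT-slice cohort generator.

Real patient imaging for this analysis is not publicly available, so every
downstream stage is exercised on a generated cohort that reproduces the
statistical structure the analysis assumes:

* a muscle compartment rendered as an elliptical band whose HU content is a
  mixture of muscle-attenuation pixels and spatially clustered
  intramuscular-fat speckles (Poisson-seeded discs of 1–4 px radius, so
  small same-grey zones exist);
* outcome-dependent fat burden (default 20% of compartment pixels in
  decedents vs 6% in survivors) and compartment elongation;
* muscle attenuation whose distribution shifts down and skews positive in
  decedents (myosteatosis) and sits high with a negative tail in survivors,
  so the in-ROI intensity skewness separates the groups in the direction
  seen clinically;
* 30-day mortality ≈ 14.6% with 7-day deaths a nested subset (≈ 8.4%);
* sPESI components driven by the same latent frailty that drives mortality,
  so clinical and radiomic signals are correlated but not identical.

All randomness derives from one integer seed through per-patient
substreams, so a cohort is reproducible and extensible without
reshuffling existing patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import brentq

from .prep import CTSlice, ROIMask

MIN_COMPARTMENT_PIXELS = 100

SPESI_COMPONENTS = (
    "age_gt_80",
    "cancer",
    "chronic_cardiopulmonary",
    "hr_ge_110",
    "sbp_lt_100",
    "sao2_lt_90",
)

# latent-frailty loadings of the five non-age sPESI components
_COMPONENT_INTERCEPTS = {
    "cancer": -1.9,
    "chronic_cardiopulmonary": -1.1,
    "hr_ge_110": -1.3,
    "sbp_lt_100": -1.6,
    "sao2_lt_90": -1.4,
}
_COMPONENT_SLOPE = 0.8


@dataclass(frozen=True)
class CohortConfig:
    """Generator calibration.

    Rates and fat fractions are probabilities in [0, 1]; HU parameters are
    in Hounsfield units; elongations are minor/major axis ratios of the
    muscle compartment; ``pixel_spacing`` is in mm.
    """

    n_patients: int = 200
    seed: int = 0
    mort30_rate: float = 0.146
    mort7_rate: float = 0.084
    fat_fraction_dead: float = 0.20
    fat_fraction_alive: float = 0.06
    elongation_dead: float = 0.50
    elongation_alive: float = 0.65
    # survivor muscle: high attenuation with a negative (myosteatotic) tail,
    # ~59% of muscle pixels above 30 HU; decedent muscle: low attenuation
    # with a positive tail of residual normal muscle, ~24% above 30 HU
    muscle_hu_mean: float = 33.0        # survivors
    muscle_hu_sd: float = 20.0
    muscle_hu_skew: float = -1.15
    muscle_hu_mean_dead: float = 18.0
    muscle_hu_sd_dead: float = 26.0
    muscle_hu_skew_dead: float = 1.6
    # between-patient heterogeneity of muscle attenuation (location/scale),
    # emulating contrast-phase and calibration variability across scanners;
    # the distribution *shape* stays outcome-linked, its location does not
    muscle_mu_jitter_sd: float = 10.0
    muscle_sd_jitter: float = 0.12      # lognormal sigma on the scale
    fat_hu_mean: float = -48.0
    fat_hu_sd: float = 9.0
    image_size: int = 96
    pixel_spacing: float = 1.0
    spesi_noise: float = 0.05
    frailty_coef: float = 1.2           # log-odds of death per frailty SD
    fat_z_coef: float = 0.01            # frailty leakage into fat fraction
    fat_jitter_sd: float = 0.025
    elong_jitter_sd: float = 0.04
    background_hu: float = -350.0

    def __post_init__(self) -> None:
        for name in ("mort30_rate", "mort7_rate", "fat_fraction_dead",
                     "fat_fraction_alive", "spesi_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mort7_rate > self.mort30_rate:
            raise ValueError(
                f"mort7_rate ({self.mort7_rate}) must not exceed "
                f"mort30_rate ({self.mort30_rate}): 7-day deaths are nested"
            )
        if self.fat_fraction_dead < self.fat_fraction_alive:
            raise ValueError("fat_fraction_dead must be >= fat_fraction_alive")
        if not -29.0 <= self.muscle_hu_mean <= 150.0:
            raise ValueError("muscle_hu_mean must lie in the SM window [-29, 150]")
        if not -190.0 <= self.fat_hu_mean <= -30.0:
            raise ValueError("fat_hu_mean must lie in the IMAT window [-190, -30]")
        if self.n_patients < 20:
            raise ValueError(f"n_patients must be >= 20, got {self.n_patients}")
        for name in ("elongation_dead", "elongation_alive"):
            v = getattr(self, name)
            if not 0.2 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0.2, 1], got {v}")

    def null_signal(self) -> "CohortConfig":
        """A copy with all image-outcome coupling removed.

        Decedent fat fraction, elongation and muscle attenuation are set to
        the survivor values and the frailty leakage into fat is zeroed, so
        slices carry no information about the endpoint while the clinical
        components remain frailty-driven.
        """
        return replace(
            self,
            fat_fraction_dead=self.fat_fraction_alive,
            elongation_dead=self.elongation_alive,
            muscle_hu_mean_dead=self.muscle_hu_mean,
            muscle_hu_sd_dead=self.muscle_hu_sd,
            muscle_hu_skew_dead=self.muscle_hu_skew,
            fat_z_coef=0.0,
        )


@dataclass
class PatientRecord:
    """Clinical record of one synthetic patient (plus generator truth)."""

    patient_id: str
    age: int
    sex: str
    age_gt_80: bool
    cancer: bool
    chronic_cardiopulmonary: bool
    hr_ge_110: bool
    sbp_lt_100: bool
    sao2_lt_90: bool
    dead7: bool
    dead30: bool
    # generator ground truth, used by calibration tests only
    frailty: float = 0.0
    fat_fraction: float = 0.0
    elongation: float = 0.0
    # per-patient muscle HU distribution (0 sd -> use config group values)
    muscle_mu: float = 0.0
    muscle_sd: float = 0.0
    muscle_skew: float = 0.0

    def __post_init__(self) -> None:
        if self.dead7 and not self.dead30:
            raise ValueError("dead7 implies dead30")
        if self.age_gt_80 != (self.age > 80):
            raise ValueError("age_gt_80 inconsistent with age")


@dataclass
class Cohort:
    """Slices, compartment masks and the clinical table of one cohort."""

    config: CohortConfig
    slices: list[CTSlice]
    compartments: list[ROIMask]
    records: list[PatientRecord]

    @property
    def clinical(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({
                "patient_id": r.patient_id, "age": r.age, "sex": r.sex,
                **{c: getattr(r, c) for c in SPESI_COMPONENTS},
                "dead7": r.dead7, "dead30": r.dead30,
            })
        return pd.DataFrame(rows).set_index("patient_id")

    @property
    def truth(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frailty": [r.frailty for r in self.records],
                "fat_fraction": [r.fat_fraction for r in self.records],
                "elongation": [r.elongation for r in self.records],
            },
            index=[r.patient_id for r in self.records],
        )

    def labels(self, endpoint: str) -> pd.Series:
        if endpoint not in ("7d", "30d"):
            raise ValueError(f"endpoint must be '7d' or '30d', got {endpoint!r}")
        col = "dead7" if endpoint == "7d" else "dead30"
        return self.clinical[col].astype(int)

    def __iter__(self) -> Iterator[tuple[CTSlice, ROIMask, PatientRecord]]:
        return iter(zip(self.slices, self.compartments, self.records))


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


def _calibrate_intercept(rate: float, slope: float) -> float:
    """Intercept a such that E_z~N(0,1)[sigmoid(a + slope*z)] == rate."""
    nodes, weights = hermgauss(64)
    z = np.sqrt(2.0) * nodes
    w = weights / np.sqrt(np.pi)

    def marginal(a: float) -> float:
        return float(np.sum(w * _sigmoid(a + slope * z))) - rate

    return brentq(marginal, -30.0, 30.0)


def _skewed_draws(rng: np.random.Generator, mean: float, sd: float,
                  skew: float, size: int,
                  hi: float = 150.0) -> np.ndarray:
    """Location-scale gamma draws with given mean, sd and skewness sign.

    Draws are truncated below ``hi`` (the ceiling of the muscle HU window)
    by rejection: muscle attenuation does not straddle the window top, and
    an untruncated tail would punch spurious out-of-window holes into the
    combined-tissue ROI.
    """
    def draw(n: int) -> np.ndarray:
        if abs(skew) < 0.05:
            return rng.normal(mean, sd, n)
        shape = 4.0 / skew**2
        scale = sd / np.sqrt(shape)
        g = rng.gamma(shape, scale, n)
        return mean - shape * scale + g if skew > 0 else mean + shape * scale - g

    out = draw(size)
    for _ in range(100):
        bad = out >= hi
        n_bad = int(bad.sum())
        if n_bad == 0:
            break
        out[bad] = draw(n_bad)
    return np.minimum(out, hi - 1e-6)


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    """Stable per-patient substream independent of cohort size."""
    return np.random.default_rng(np.random.SeedSequence([seed, index]))


def _draw_record(index: int, config: CohortConfig, intercept: float) -> PatientRecord:
    rng = _patient_rng(config.seed, index)
    z = float(rng.standard_normal())
    p30 = float(_sigmoid(intercept + config.frailty_coef * z))
    dead30 = bool(rng.uniform() < p30)
    p7_given_30 = config.mort7_rate / config.mort30_rate if config.mort30_rate > 0 else 0.0
    dead7 = bool(dead30 and rng.uniform() < p7_given_30)

    fat_base = config.fat_fraction_dead if dead30 else config.fat_fraction_alive
    fat = float(np.clip(
        fat_base + config.fat_z_coef * z + rng.normal(0.0, config.fat_jitter_sd), 0.0, 1.0
    ))
    elong_base = config.elongation_dead if dead30 else config.elongation_alive
    elong = float(np.clip(elong_base + rng.normal(0.0, config.elong_jitter_sd), 0.25, 0.95))

    if dead30:
        mu_g, sd_g, sk_g = (config.muscle_hu_mean_dead, config.muscle_hu_sd_dead,
                            config.muscle_hu_skew_dead)
    else:
        mu_g, sd_g, sk_g = (config.muscle_hu_mean, config.muscle_hu_sd,
                            config.muscle_hu_skew)
    muscle_mu = mu_g + rng.normal(0.0, config.muscle_mu_jitter_sd)
    muscle_sd = sd_g * float(np.exp(rng.normal(0.0, config.muscle_sd_jitter)))

    age = int(np.clip(round(66.0 + 8.0 * z + rng.normal(0.0, 10.0)), 18, 100))
    sex = "M" if rng.uniform() < 0.54 else "F"
    components = {"age_gt_80": age > 80}
    for name, a in _COMPONENT_INTERCEPTS.items():
        v = bool(rng.uniform() < _sigmoid(a + _COMPONENT_SLOPE * z))
        if rng.uniform() < config.spesi_noise:  # label noise decoupled from outcome
            v = not v
        components[name] = v

    return PatientRecord(
        patient_id=f"P{index:05d}", age=age, sex=sex, **components,
        dead7=dead7, dead30=dead30, frailty=z, fat_fraction=fat, elongation=elong,
        muscle_mu=muscle_mu, muscle_sd=muscle_sd, muscle_skew=sk_g,
    )


def _stamp_fat_speckles(rng: np.random.Generator, band: np.ndarray,
                        target: int) -> np.ndarray:
    """Poisson-seeded discs of 1-4 px radius until exactly ``target`` pixels."""
    fat = np.zeros_like(band)
    if target <= 0:
        return fat
    coords = np.argwhere(band)
    radii = np.array([1, 2, 3, 4])
    radius_p = np.array([0.45, 0.30, 0.15, 0.10])
    n = band.shape[0]
    yy, xx = np.mgrid[:n, :n]
    count = 0
    while count < target:
        cy, cx = coords[rng.integers(len(coords))]
        r = rng.choice(radii, p=radius_p)
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        new = disc & band & ~fat
        n_new = int(new.sum())
        if count + n_new > target:  # trim the last disc to hit the target exactly
            keep = np.argwhere(new)
            drop = keep[rng.permutation(len(keep))[: count + n_new - target]]
            new[drop[:, 0], drop[:, 1]] = False
            n_new = target - count
        fat |= new
        count += n_new
    return fat


def render_slice(
    record: PatientRecord, config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> tuple[CTSlice, ROIMask]:
    """Render the CT slice and muscle-compartment mask of one patient.

    The compartment is an elliptical band with the record's elongation; a
    fraction ``record.fat_fraction`` of its pixels is covered by clustered
    fat speckles, the rest draws from the outcome-specific muscle HU
    distribution.
    """
    if rng is None:
        rng = _patient_rng(config.seed, int(record.patient_id.lstrip("P")) + 2**20)
    n = config.image_size
    e = record.elongation
    # outer ellipse sized for a roughly constant band area across elongations
    outer_area = 0.32 * n * n
    a_out = min(np.sqrt(outer_area / (np.pi * e)), n / 2.0 - 2.0)
    b_out = e * a_out
    cy = n / 2.0 + rng.uniform(-2.0, 2.0)
    cx = n / 2.0 + rng.uniform(-2.0, 2.0)
    theta = np.deg2rad(rng.uniform(-15.0, 15.0))
    yy, xx = np.mgrid[:n, :n]
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    outer = (u / a_out) ** 2 + (v / b_out) ** 2 <= 1.0
    inner = (u / (0.6 * a_out)) ** 2 + (v / (0.6 * b_out)) ** 2 <= 1.0
    band = outer & ~inner
    n_band = int(band.sum())
    if n_band < MIN_COMPARTMENT_PIXELS:
        raise ValueError(
            f"muscle compartment has {n_band} pixels "
            f"(< {MIN_COMPARTMENT_PIXELS}); increase image_size"
        )

    fat = _stamp_fat_speckles(rng, band, int(round(record.fat_fraction * n_band)))
    muscle = band & ~fat

    img = np.full((n, n), config.background_hu, dtype=float)
    img += rng.normal(0.0, 10.0, (n, n)) * ~band  # background texture
    if record.muscle_sd > 0:
        mu, sd, sk = record.muscle_mu, record.muscle_sd, record.muscle_skew
    elif record.dead30:
        mu, sd, sk = (config.muscle_hu_mean_dead, config.muscle_hu_sd_dead,
                      config.muscle_hu_skew_dead)
    else:
        mu, sd, sk = config.muscle_hu_mean, config.muscle_hu_sd, config.muscle_hu_skew
    img[muscle] = _skewed_draws(rng, mu, sd, sk, int(muscle.sum()))
    img[fat] = rng.normal(config.fat_hu_mean, config.fat_hu_sd, int(fat.sum()))

    ct = CTSlice(values=img, spacing=(config.pixel_spacing, config.pixel_spacing),
                 patient_id=record.patient_id)
    roi = ROIMask(mask=band, tissue="SM_IMAT", window=(-190.0, 150.0))
    return ct, roi


def draw_records(config: CohortConfig) -> list[PatientRecord]:
    """Clinical records only (no image rendering); same streams as
    :func:`generate_cohort`, so record ``i`` is identical in both."""
    intercept = _calibrate_intercept(config.mort30_rate, config.frailty_coef)
    return [_draw_record(i, config, intercept) for i in range(config.n_patients)]


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate slices, compartment masks and clinical records.

    Fully reproducible from ``config.seed``; patient ``i`` depends only on
    the seed and ``i``.
    """
    records = draw_records(config)
    slices: list[CTSlice] = []
    compartments: list[ROIMask] = []
    for rec in records:
        ct, roi = render_slice(rec, config)
        slices.append(ct)
        compartments.append(roi)
    return Cohort(config=config, slices=slices, compartments=compartments, records=records)
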