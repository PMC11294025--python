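"""Synthetic cohort generator: calibration, determinism, limiting cases."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from peradiomics.prep import threshold_segment
from peradiomics.synthetic import (
    CohortConfig,
    PatientRecord,
    draw_records,
    generate_cohort,
    render_slice,
)


class TestConfigValidation:
    @pytest.mark.parametrize("field,value", [
        ("mort30_rate", 1.5),
        ("mort7_rate", -0.1),
        ("fat_fraction_dead", 2.0),
        ("spesi_noise", 1.2),
    ])
    def test_rates_outside_unit_interval_name_the_field(self, field, value):
        with pytest.raises(ValueError, match=field):
            CohortConfig(**{field: value})

    def test_nested_endpoints_enforced(self):
        with pytest.raises(ValueError, match="mort7"):
            CohortConfig(mort7_rate=0.3, mort30_rate=0.1)

    def test_hu_windows_enforced(self):
        with pytest.raises(ValueError, match="muscle_hu_mean"):
            CohortConfig(muscle_hu_mean=-100.0)
        with pytest.raises(ValueError, match="fat_hu_mean"):
            CohortConfig(fat_hu_mean=10.0)

    def test_minimum_cohort_size(self):
        with pytest.raises(ValueError, match="n_patients"):
            CohortConfig(n_patients=5)


class TestDeterminism:
    def test_same_config_same_bytes(self, small_cohort):
        again = generate_cohort(small_cohort.config)
        for a, b in zip(small_cohort.slices, again.slices):
            np.testing.assert_array_equal(a.values, b.values)
        assert small_cohort.clinical.equals(again.clinical)

    def test_per_patient_substreams_extensible(self, small_cohort):
        bigger = generate_cohort(
            dataclasses.replace(small_cohort.config, n_patients=70)
        )
        np.testing.assert_array_equal(
            small_cohort.slices[10].values, bigger.slices[10].values
        )


class TestCalibration:
    def test_mortality_rate_within_exact_binomial_band(self):
        # binomial 99% interval oracle around the configured rate
        cfg = CohortConfig(n_patients=2000, seed=21)
        records = draw_records(cfg)
        dead = sum(r.dead30 for r in records)
        lo = stats.binom.ppf(0.005, 2000, cfg.mort30_rate)
        hi = stats.binom.ppf(0.995, 2000, cfg.mort30_rate)
        assert lo <= dead <= hi

    def test_seven_day_deaths_nested(self):
        records = draw_records(CohortConfig(n_patients=1000, seed=3))
        assert all(r.dead30 for r in records if r.dead7)
        d7 = sum(r.dead7 for r in records) / 1000
        assert 0.05 < d7 < 0.12  # around the configured 8.4%

    def test_fat_fraction_recovered_per_outcome_group(self):
        cfg = CohortConfig(n_patients=800, seed=17)
        cohort = generate_cohort(cfg)
        fracs = {True: [], False: []}
        for ct, comp, rec in cohort:
            imat = threshold_segment(ct, comp, "IMAT")
            fracs[rec.dead30].append(imat.n_pixels / comp.n_pixels)
        assert len(fracs[True]) >= 100 and len(fracs[False]) >= 100
        assert np.mean(fracs[True]) == pytest.approx(cfg.fat_fraction_dead, abs=0.02)
        assert np.mean(fracs[False]) == pytest.approx(cfg.fat_fraction_alive, abs=0.02)

    def test_skewness_direction_separates_outcomes(self):
        # decedents: myosteatosis, positive in-ROI skewness; survivors negative
        cohort = generate_cohort(CohortConfig(n_patients=400, seed=29))
        skews = {True: [], False: []}
        for ct, comp, rec in cohort:
            if len(skews[rec.dead30]) >= 50:
                continue
            roi = threshold_segment(ct, comp, "SM_IMAT")
            x = ct.values[roi.mask]
            d = x - x.mean()
            skews[rec.dead30].append((d**3).mean() / (d**2).mean() ** 1.5)
        assert len(skews[True]) >= 40 and len(skews[False]) == 50
        assert np.mean(skews[True]) > 0 > np.mean(skews[False])
        assert np.mean(skews[True]) > np.mean(skews[False])

    def test_latent_frailty_drives_clinical_components(self):
        records = draw_records(CohortConfig(n_patients=2000, seed=5))
        z = np.array([r.frailty for r in records])
        cancer = np.array([r.cancer for r in records])
        assert z[cancer].mean() > z[~cancer].mean()


class TestRenderSlice:
    def _record(self, **kw):
        base = dict(
            patient_id="P00000", age=70, sex="M", age_gt_80=False, cancer=False,
            chronic_cardiopulmonary=False, hr_ge_110=False, sbp_lt_100=False,
            sao2_lt_90=False, dead7=False, dead30=False, frailty=0.0,
            fat_fraction=0.1, elongation=0.6,
        )
        base.update(kw)
        return PatientRecord(**base)

    def test_fat_fraction_zero_imat_nearly_empty(self):
        cfg = CohortConfig()
        ct, comp = render_slice(self._record(fat_fraction=0.0), cfg,
                                np.random.default_rng(0))
        imat = threshold_segment(ct, comp, "IMAT")
        assert imat.n_pixels / comp.n_pixels < 0.03  # noise tails only

    def test_fat_fraction_one_sm_nearly_empty(self):
        cfg = CohortConfig()
        ct, comp = render_slice(self._record(fat_fraction=1.0), cfg,
                                np.random.default_rng(0))
        sm = threshold_segment(ct, comp, "SM")
        assert sm.n_pixels / comp.n_pixels < 0.03

    def test_compartment_minimum_size_enforced(self):
        cfg = CohortConfig(image_size=16)
        with pytest.raises(ValueError, match="compartment"):
            render_slice(self._record(), cfg, np.random.default_rng(0))

    def test_elongation_reflected_in_compartment(self):
        cfg = CohortConfig()
        _, round_comp = render_slice(self._record(elongation=0.9), cfg,
                                     np.random.default_rng(1))
        _, long_comp = render_slice(self._record(elongation=0.4), cfg,
                                    np.random.default_rng(1))

        def pca_ratio(mask):
            coords = np.argwhere(mask).astype(float)
            lam = np.linalg.eigvalsh(np.cov(coords.T, ddof=0))
            return np.sqrt(lam[0] / lam[1])

        assert pca_ratio(long_comp.mask) < pca_ratio(round_comp.mask)

    def test_record_invariants(self):
        with pytest.raises(ValueError, match="dead7"):
            self._record(dead7=True, dead30=False)
        with pytest.raises(ValueError, match="age"):
            self._record(age=85, age_gt_80=False)
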