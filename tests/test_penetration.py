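"""Image reduction, activity calibration, time integration and blending."""

import numpy as np
import pandas as pd
import pytest

from spheradose.penetration import (CellActivityProfile, CumulatedDecayProfile,
                                    SpatioTemporalProfile, blend_profiles,
                                    calibrate, radial_profile_from_image,
                                    scale_amount, time_integrate)
from spheradose.units import decay_constant_per_s


def flat_profile(level=5.0, schedule=(0.0, 24.0), n_t=25, r_max=350.0,
                 drug="test"):
    times = np.linspace(schedule[0], schedule[1], n_t)
    radii = np.arange(1.25, r_max, 2.5)
    values = np.full((n_t, radii.size), level)
    return SpatioTemporalProfile(times_h=times, radii_um=radii, values=values,
                                 drug_id=drug, schedule=schedule)


def make_decays(values, width=2.5, spheroid_radius=200.0, drug="test"):
    values = np.asarray(values, dtype=float)
    radii = (np.arange(values.size) + 0.5) * width
    region = np.where(radii <= spheroid_radius, "spheroid", "medium")
    return CumulatedDecayProfile(radii_um=radii, shell_width=width,
                                 decays_per_cell=values, region=region,
                                 drug_id=drug)


class TestRadialProfileFromImage:
    def test_uniform_image(self):
        img = np.full((101, 101), 3.5)
        prof = radial_profile_from_image(img, (50, 50), ring_width_um=2.5,
                                         pixel_size_um=1.0)
        filled = prof["mean_intensity"].dropna()
        assert np.allclose(filled, 3.5)

    def test_synthetic_annulus_recovered(self):
        # intensity 1 between 50 and 52.5 um, 0 elsewhere, 1-um pixels
        n = 161
        yy, xx = np.indices((n, n))
        dist = np.hypot(yy - 80, xx - 80)
        img = ((dist >= 50) & (dist < 52.5)).astype(float)
        prof = radial_profile_from_image(img, (80, 80), 2.5, 1.0)
        ring = prof.set_index(prof.index)["mean_intensity"]
        assert ring[20] > 0.95          # the 50-52.5 um ring
        assert ring[18] < 0.05 and ring[22] < 0.05

    def test_rings_partition_pixels(self):
        img = np.random.default_rng(0).random((80, 120))
        prof = radial_profile_from_image(img, (40, 60), 5.0, 2.0)
        assert prof["n_pixels"].sum() == img.size

    def test_empty_ring_is_missing_not_zero(self):
        img = np.ones((11, 11))
        prof = radial_profile_from_image(img, (5, 5), ring_width_um=0.4,
                                         pixel_size_um=1.0)
        empty = prof[prof["n_pixels"] == 0]
        assert len(empty) > 0
        assert empty["mean_intensity"].isna().all()

    def test_center_outside_image_rejected(self):
        with pytest.raises(ValueError):
            radial_profile_from_image(np.ones((10, 10)), (20, 5), 2.5, 1.0)


class TestCalibrate:
    def test_plateau_scaling_ratio(self):
        prof = flat_profile(level=5.0)
        act = calibrate(prof, 13.75, 12.0**3, 200.0, decay_correct=False)
        # scale factor 13.75/5 = 2.75 kBq/mL per a.u.; per-site activity:
        # 13.75 kBq/mL * 1728 um^3 = 2.376e-5 Bq
        assert act.activity_bq[0, 0] == pytest.approx(2.376e-5, rel=1e-3)

    def test_linearity_in_applied_activity(self):
        prof = flat_profile()
        a1 = calibrate(prof, 10.0, 12.0**3, 200.0)
        a2 = calibrate(prof, 20.0, 12.0**3, 200.0)
        assert np.allclose(a2.activity_bq, 2.0 * a1.activity_bq)

    def test_decay_correction_applied(self):
        prof = flat_profile()
        act = calibrate(prof, 13.75, 12.0**3, 200.0, decay_correct=True)
        lam = decay_constant_per_s(9.92)
        expected = 2.376e-5 * np.exp(-lam * 24 * 3600)
        assert act.activity_bq[-1, 0] == pytest.approx(expected, rel=1e-3)

    def test_zero_plateau_rejected(self):
        prof = flat_profile(level=0.0)
        with pytest.raises(ValueError):
            calibrate(prof, 13.75, 12.0**3, 200.0)

    def test_no_medium_region_rejected(self):
        prof = flat_profile(r_max=150.0)
        with pytest.raises(ValueError):
            calibrate(prof, 13.75, 12.0**3, 200.0)


class TestTimeIntegrate:
    def test_constant_activity_no_decay_no_tail(self):
        # medium shells get no washout tail; with negligible decay the
        # integral is A*T
        times = np.linspace(0, 24, 25)
        radii = np.array([250.0, 300.0])
        act = CellActivityProfile(times_h=times, radii_um=radii,
                                  activity_bq=np.full((25, 2), 2.0),
                                  drug_id="t", schedule=(0.0, 24.0))
        dec = time_integrate(act, half_life_days=1e9, spheroid_radius=200.0)
        assert np.allclose(dec.decays_per_cell, 2.0 * 24 * 3600, rtol=1e-9)
        assert list(dec.region) == ["medium", "medium"]

    def test_physical_decay_closed_form(self):
        # A0 exp(-lambda t) over 24 h integrates to (A0/lambda)(1-e^(-24h l))
        lam = decay_constant_per_s(9.92)
        times = np.linspace(0, 24, 97)
        a0 = 1.0
        act = CellActivityProfile(
            times_h=times, radii_um=np.array([250.0]),
            activity_bq=(a0 * np.exp(-lam * times * 3600))[:, None],
            drug_id="t", schedule=(0.0, 24.0))
        dec = time_integrate(act, half_life_days=9.92, spheroid_radius=200.0)
        closed = a0 / lam * (1 - np.exp(-lam * 24 * 3600))
        assert closed == pytest.approx(83_460, rel=1e-3)  # ~ A0 x 83,400 s
        assert dec.decays_per_cell[0] == pytest.approx(closed, rel=1e-4)

    def test_spheroid_shells_get_retention_tail(self):
        lam = decay_constant_per_s(9.92)
        times = np.linspace(0, 24, 25)
        act = CellActivityProfile(times_h=times,
                                  radii_um=np.array([50.0, 250.0]),
                                  activity_bq=np.full((25, 2), 3.0),
                                  drug_id="t", schedule=(0.0, 24.0))
        dec = time_integrate(act, half_life_days=9.92, spheroid_radius=200.0)
        assert dec.decays_per_cell[0] == pytest.approx(
            3.0 * 24 * 3600 + 3.0 / lam, rel=1e-3)
        assert dec.decays_per_cell[1] == pytest.approx(3.0 * 24 * 3600,
                                                       rel=1e-3)

    def test_biological_clearance_shortens_tail(self):
        times = np.linspace(0, 24, 25)
        act = CellActivityProfile(times_h=times, radii_um=np.array([50.0]),
                                  activity_bq=np.full((25, 1), 1.0),
                                  drug_id="t", schedule=(0.0, 24.0))
        full = time_integrate(act, 9.92, 200.0)
        cleared = time_integrate(act, 9.92, 200.0,
                                 biological_half_life_days=1.0)
        assert cleared.decays_per_cell[0] < full.decays_per_cell[0]

    def test_zero_profile_zero_decays(self):
        times = np.linspace(0, 6, 7)
        act = CellActivityProfile(times_h=times,
                                  radii_um=np.array([50.0, 250.0]),
                                  activity_bq=np.zeros((7, 2)),
                                  drug_id="t", schedule=(0.0, 6.0))
        dec = time_integrate(act, 9.92, 200.0)
        assert np.all(dec.decays_per_cell == 0.0)

    def test_non_monotone_time_grid_rejected(self):
        act = CellActivityProfile(times_h=np.array([0.0, 2.0, 1.0]),
                                  radii_um=np.array([50.0]),
                                  activity_bq=np.ones((3, 1)),
                                  drug_id="t", schedule=(0.0, 2.0))
        with pytest.raises(ValueError):
            time_integrate(act, 9.92, 200.0)


class TestScaleAndBlend:
    def test_scale_amount(self):
        prof = make_decays([4.0, 2.0, 1.0])
        assert np.allclose(scale_amount(prof, 0.5).decays_per_cell,
                           [2.0, 1.0, 0.5])
        assert np.allclose(scale_amount(prof, 1.0).decays_per_cell,
                           prof.decays_per_cell)
        assert np.all(scale_amount(prof, 0.0).decays_per_cell == 0.0)
        with pytest.raises(ValueError):
            scale_amount(prof, -1.0)

    def test_blend_anchors_reproduce_inputs(self):
        base = make_decays([1.0, 2.0, 3.0])
        pre = make_decays([2.0, 2.5, 3.0])
        # no preirradiation: pure base scaled by the liposome fraction
        b0 = blend_profiles(base, pre, antibody_fraction=0.0,
                            liposome_fraction=1.0)
        assert np.allclose(b0.decays_per_cell, base.decays_per_cell)
        # reference recovery at the measured 50% antibody case
        b5 = blend_profiles(base, pre, antibody_fraction=0.5,
                            liposome_fraction=0.5)
        assert np.allclose(b5.decays_per_cell, 0.5 * pre.decays_per_cell)

    def test_blend_extrapolation_arithmetic(self):
        # core 0.050 -> 0.071 at the reference; f_ab = 0.7 extrapolates to
        # 0.050 + 1.4 * 0.021 = 0.0794 before liposome scaling
        base = make_decays([0.050])
        pre = make_decays([0.071])
        out = blend_profiles(base, pre, antibody_fraction=0.7,
                             liposome_fraction=1.0)
        assert out.decays_per_cell[0] == pytest.approx(0.0794, abs=1e-6)

    def test_blend_clips_negative_extrapolation(self, caplog):
        base = make_decays([1.0])
        pre = make_decays([0.1])
        out = blend_profiles(base, pre, antibody_fraction=1.0,
                             liposome_fraction=1.0)
        assert out.decays_per_cell[0] == 0.0

    def test_blend_grid_mismatch_rejected(self):
        base = make_decays([1.0, 2.0])
        pre = make_decays([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            blend_profiles(base, pre, 0.5, 0.5)

    def test_value_at_maps_shells(self):
        prof = make_decays([10.0, 20.0, 30.0])
        assert np.allclose(prof.value_at([0.0, 3.0, 6.9]), [10.0, 20.0, 30.0])
        with pytest.raises(ValueError):
            prof.value_at([100.0])
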