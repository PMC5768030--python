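"""Generator contracts: phantoms, anatomy profiles, ATCM emulator, cohort."""

import math

import numpy as np
import pytest

import dwmetrics as dm
from dwmetrics.cohort_stats import records_to_frame
from dwmetrics.dw_core import dw_metrics


class TestPhantomSeries:
    @pytest.mark.parametrize("diameter", [32.0, 24.0])
    def test_disk_ground_truth(self, diameter):
        series = dm.make_phantom_series(dm.PhantomSpec("disk", (diameter,)), n_slices=2)
        assert series.ground_truth["dw_cm"] == pytest.approx(diameter)

    def test_ellipse_ground_truth(self):
        series = dm.make_phantom_series(dm.PhantomSpec("ellipse", (15.0, 10.0)), n_slices=1)
        assert series.ground_truth["dw_cm"] == pytest.approx(2.0 * math.sqrt(150.0))

    def test_nonwater_material_scales_truth(self):
        # a -500 HU disk is half water-equivalent: D_w shrinks by sqrt(0.5)
        series = dm.make_phantom_series(
            dm.PhantomSpec("disk", (20.0,), uniform_hu=-500.0), n_slices=1
        )
        assert series.ground_truth["dw_cm"] == pytest.approx(20.0 * math.sqrt(0.5))

    def test_geometry_must_fit_image(self):
        with pytest.raises(ValueError, match="exceeds"):
            dm.make_phantom_series(dm.PhantomSpec("disk", (45.0,)), n_slices=1)

    def test_same_seed_identical_noise(self):
        spec = dm.PhantomSpec("disk", (24.0,), noise_sd=10.0, image_size=128, pixel_spacing=3.0)
        a = dm.make_phantom_series(spec, n_slices=3, seed=5)
        b = dm.make_phantom_series(spec, n_slices=3, seed=5)
        for sa, sb in zip(a.slices, b.slices):
            np.testing.assert_array_equal(sa.pixels, sb.pixels)

    def test_table_truth_matches_calibration(self):
        series = dm.make_phantom_series(dm.PhantomSpec("disk", (24.0,), include_table=True), 1)
        cal = dm.calibrate_table(series.slices[0], series.ground_truth["table_mask"])
        assert cal.aw_table == pytest.approx(series.ground_truth["aw_table_cm2"], rel=0.02)


class TestAnatomyProfile:
    @pytest.mark.parametrize("exam", ["chest", "CAP"])
    def test_mean_hits_target(self, exam):
        p = dm.anatomy_profile(exam, 25.0)
        assert dm.dw_average(p) == pytest.approx(25.0, abs=0.05)

    def test_chest_midscan_below_mean(self):
        m = dw_metrics(dm.anatomy_profile("chest", 25.0))
        assert m.dw_c < m.dw_ave

    def test_cap_midscan_above_mean(self):
        m = dw_metrics(dm.anatomy_profile("CAP", 25.0))
        assert m.dw_c > m.dw_ave

    @pytest.mark.parametrize("exam", ["chest", "CAP"])
    def test_range_fraction_default(self, exam):
        m = dw_metrics(dm.anatomy_profile(exam, 25.0))
        assert m.dw_range / m.dw_ave == pytest.approx(0.23, abs=0.01)

    def test_window_shift_moves_midscan_more_than_mean(self):
        base = dw_metrics(dm.anatomy_profile("CAP", 25.0))
        shifted = dw_metrics(dm.anatomy_profile("CAP", 25.0, window_shift=0.08))
        assert abs(shifted.dw_c - base.dw_c) > 3.0 * abs(shifted.dw_ave - base.dw_ave)

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            dm.anatomy_profile("chest", -1.0)
        with pytest.raises(ValueError):
            dm.anatomy_profile("head", 25.0)


class TestProfileToSeries:
    def test_constant_curve_renders_to_its_dw(self):
        p = dm.DwProfile(z=[0.0, 5.0, 10.0], dw=[24.0, 24.0, 24.0])
        series = dm.profile_to_series(p)
        for sl in series.slices:
            assert dm.slice_dw(sl) == pytest.approx(24.0, abs=0.2)

    def test_couch_correction_matches_tablefree_twin(self):
        p = dm.DwProfile(z=[0.0, 5.0], dw=[26.0, 28.0])
        plain = dm.profile_to_series(p)
        couched = dm.profile_to_series(p, include_table=True)
        cal = dm.calibrate_table(couched.slices[0], couched.ground_truth["table_mask"])
        for sp, sc in zip(plain.slices, couched.slices):
            assert dm.slice_dw(sc, cal) == pytest.approx(dm.slice_dw(sp), abs=0.1)

    def test_seed_determinism(self):
        p = dm.DwProfile(z=[0.0, 5.0], dw=[22.0, 24.0])
        a = dm.profile_to_series(p, seed=9, noise_sd=10.0, image_size=160, pixel_spacing=2.5)
        b = dm.profile_to_series(p, seed=9, noise_sd=10.0, image_size=160, pixel_spacing=2.5)
        for sa, sb in zip(a.slices, b.slices):
            np.testing.assert_array_equal(sa.pixels, sb.pixels)

    def test_currents_carried_onto_slices(self):
        p = dm.DwProfile(z=[0.0, 5.0], dw=[22.0, 24.0], current=[120.0, 140.0])
        series = dm.profile_to_series(p, image_size=160, pixel_spacing=2.5)
        assert [s.tube_current for s in series.slices] == [120.0, 140.0]


class TestAtcmEmulator:
    def test_constant_curve_constant_current(self):
        cfg = dm.CohortConfig()
        current, _ = dm.emulate_atcm(np.full(40, cfg.dw_ref), cfg)
        assert np.ptp(current) == 0.0
        assert current[0] == pytest.approx(cfg.i_ref)

    def test_size_doubling_constant(self):
        # D_w_ave difference of ln2/k doubles CTDI_vol when unclamped
        cfg = dm.CohortConfig()
        _, low = dm.emulate_atcm(np.full(40, 24.0), cfg)
        _, high = dm.emulate_atcm(np.full(40, 24.0 + math.log(2.0) / cfg.k), cfg)
        assert high / low == pytest.approx(2.0, abs=0.001)

    def test_small_patient_pinned_at_floor(self):
        cfg = dm.CohortConfig()
        current, ctdi = dm.emulate_atcm(np.full(40, 10.0), cfg)
        assert np.all(current == cfg.i_min)
        assert ctdi == pytest.approx(cfg.dose_const * cfg.i_min)


class TestSampleCohort:
    def test_seed_determinism(self):
        a = records_to_frame(dm.sample_cohort(dm.CohortConfig(seed=4)))
        b = records_to_frame(dm.sample_cohort(dm.CohortConfig(seed=4)))
        assert a.equals(b)

    def test_membership_stable_as_cohort_grows(self):
        small = dm.sample_cohort(dm.CohortConfig(n_per_exam={"CAP": 15, "chest": 5}))
        large = dm.sample_cohort(dm.CohortConfig(n_per_exam={"CAP": 40, "chest": 12}))
        df_s = records_to_frame(small)
        df_l = records_to_frame(large)
        for exam, n in (("CAP", 15), ("chest", 5)):
            a = df_s[df_s.exam_type == exam].head(n).reset_index(drop=True)
            b = df_l[df_l.exam_type == exam].head(n).reset_index(drop=True)
            assert a.equals(b)

    def test_weights_respect_truncation(self):
        recs = dm.sample_cohort(dm.CohortConfig(n_per_exam={"CAP": 1000}, seed=2))
        w = np.array([r.patient.weight for r in recs])
        assert w.min() >= 43.0 and w.max() <= 117.0

    def test_metrics_recomputed_from_profile(self, default_cohort):
        for r in default_cohort[:10]:
            assert r.dw_min - 1e-9 <= r.dw_c <= r.dw_max + 1e-9
            assert r.dw_min - 1e-9 <= r.dw_ave <= r.dw_max + 1e-9
            assert r.ssde == pytest.approx(dm.ssde(r.ctdi_vol, r.dw_c), abs=1e-9)

    def test_dose_constant_recovered_from_unclamped_records(self, cap_records):
        # log-linear fit of CTDI_vol on D_w_ave over unclamped records
        # recovers the emulator's exponential constant k within 10%
        cfg = dm.CohortConfig()
        free = [r for r in cap_records
                if r.currents.min() > cfg.i_min + 1e-6 and r.currents.max() < cfg.i_max - 1e-6]
        assert len(free) > 30
        x = np.array([r.dw_ave for r in free])
        y = np.log([r.ctdi_vol for r in free])
        slope = dm.linear_fit(x, y).slope
        assert slope == pytest.approx(cfg.k, rel=0.10)

    def test_floor_flattens_small_patient_doses(self):
        # with a raised floor, records below the activation size have
        # near-constant CTDI_vol (coefficient of variation < 5%)
        cfg = dm.CohortConfig(i_min=180.0)
        recs = dm.sample_cohort(cfg)
        ctdi = np.array([r.ctdi_vol for r in recs if r.dw_ave < 23.0])
        assert len(ctdi) > 10
        assert np.std(ctdi, ddof=0) / ctdi.mean() < 0.05

    def test_invalid_config_rejected_before_sampling(self):
        with pytest.raises(ValueError):
            dm.CohortConfig(k=-0.1)
        with pytest.raises(ValueError):
            dm.CohortConfig(jitter_sd=-1.0)
        with pytest.raises(ValueError):
            dm.CohortConfig(i_min=600.0)


class TestEndToEndRendering:
    def test_pipeline_recovers_generator_dw(self):
        # render a few exams to images and push them through the imaging
        # pipeline: recovered D_w_ave within 0.2 cm of the generator's curve
        pairs = dm.sample_cohort(
            dm.CohortConfig(n_per_exam={"CAP": 2, "chest": 2}, seed=1), with_profiles=True
        )
        errors = []
        for record, profile in pairs:
            coarse = dm.DwProfile(
                z=profile.z[::5], dw=profile.dw[::5], exam_type=profile.exam_type
            )
            series = dm.profile_to_series(coarse, pixel_spacing=1.5, image_size=320)
            recovered = dm.dw_profile(series)
            per_slice = np.abs(recovered.dw - coarse.dw)
            assert per_slice.max() < 0.2
            errors.append(abs(dm.dw_average(recovered) - dm.dw_average(coarse)))
        assert np.median(errors) < 0.2
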