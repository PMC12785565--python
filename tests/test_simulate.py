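"""Synthetic trial and study generation."""

import json

import numpy as np
import pytest
from scipy.spatial import ConvexHull

from sockcop.geometry import cop_series, default_geometry
from sockcop.simulate import (
    BOTH_LEG,
    SINGLE_LEG,
    PlatformModel,
    SensorModel,
    SideStep,
    StudyDesign,
    TrajectoryParams,
    TrialSpec,
    distribute_load,
    generate_study,
    simulate_platform,
    simulate_sock,
    simulate_true_cop,
)


class TestTrialSpec:
    def test_single_leg_duration_from_tempo(self):
        spec = TrialSpec.single_leg(repetitions=10, tempo_bpm=60)
        assert spec.exercise_duration_s == pytest.approx(10.0)

    def test_both_leg_fixed_duration(self):
        assert TrialSpec.both_leg().exercise_duration_s == 30.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(exercise=SINGLE_LEG, duration_s=10.0),
            dict(exercise=BOTH_LEG, repetitions=5),
            dict(exercise="jumping_jacks", repetitions=5),
            dict(exercise=SINGLE_LEG, repetitions=0),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TrialSpec(**kwargs)


class TestSimulateTrueCop:
    def test_zero_amplitudes_and_noise_give_constant_origin(self):
        truth = simulate_true_cop(
            TrialSpec.single_leg(), params=TrajectoryParams.silent(), seed=0
        )
        np.testing.assert_allclose(truth.xy, 0.0)

    def test_duration_and_dominant_frequency(self):
        spec = TrialSpec.single_leg(repetitions=10, tempo_bpm=60)
        truth = simulate_true_cop(spec, seed=0, rate_hz=125.0)
        assert truth.t[-1] == pytest.approx(13.0, abs=0.02)  # 3 s marker + 10 s
        y = truth.y[truth.valid]
        freqs = np.fft.rfftfreq(y.size, 1 / 125.0)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(y - y.mean())))]
        assert peak == pytest.approx(1.0, abs=0.05)

    def test_marker_window_invalid_and_unloaded(self):
        truth = simulate_true_cop(TrialSpec.single_leg(), seed=1)
        marker = truth.t < 3.0 - 1e-9
        assert not truth.valid[marker].any()
        assert truth.valid[~marker].all()

    def test_excursion_bounds_respected(self):
        for spec in (TrialSpec.single_leg(), TrialSpec.both_leg()):
            p = TrajectoryParams.for_exercise(spec.exercise)
            truth = simulate_true_cop(spec, seed=2)
            assert truth.x.min() >= p.x_bounds[0] and truth.x.max() <= p.x_bounds[1]
            assert truth.y.min() >= p.y_bounds[0] and truth.y.max() <= p.y_bounds[1]

    def test_seed_determinism(self):
        a = simulate_true_cop(TrialSpec.single_leg(), seed=5)
        b = simulate_true_cop(TrialSpec.single_leg(), seed=5)
        c = simulate_true_cop(TrialSpec.single_leg(), seed=6)
        np.testing.assert_array_equal(a.x, b.x)
        assert not np.array_equal(a.x, c.x)


class TestDistributeLoad:
    def test_centroid_round_trip(self, geometry):
        p = distribute_load(np.array([0.0, 0.0]), 1.0, geometry)
        assert p.shape == (6,) and np.all(p >= 0)
        cop = p @ geometry.positions_mm / p.sum()
        np.testing.assert_allclose(cop, 0.0, atol=1e-12)

    def test_interior_point_round_trip_and_mass_conservation(self, geometry):
        p = distribute_load(np.array([10.0, 20.0]), 1.0, geometry)
        assert np.all(p >= 0) and p.sum() == pytest.approx(1.0, abs=1e-12)
        cop = p @ geometry.positions_mm / p.sum()
        np.testing.assert_allclose(cop, [10.0, 20.0], atol=1e-9)

    def test_vertex_gets_all_pressure(self, geometry):
        p = distribute_load(np.array([50.0, 100.0]), 2.0, geometry)
        np.testing.assert_allclose(p, [2, 0, 0, 0, 0, 0], atol=1e-9)

    def test_outside_hull_rejected(self, geometry):
        with pytest.raises(ValueError, match="outside"):
            distribute_load(np.array([80.0, 0.0]), 1.0, geometry)

    def test_bulk_round_trip_exact(self, geometry, rng):
        hull = ConvexHull(geometry.positions_mm)
        pts = rng.uniform([-20, -50], [20, 60], size=(500, 2))
        margins = pts @ hull.equations[:, :2].T + hull.equations[:, 2]
        pts = pts[np.all(margins <= -1e-9, axis=1)]
        p = distribute_load(pts, 5.0, geometry)
        cop = (p @ geometry.positions_mm) / p.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(cop, pts, atol=1e-9)

    def test_gaussian_scheme_spreads_load_inexactly(self, geometry):
        p = distribute_load(np.array([10.0, 20.0]), 1.0, geometry, scheme="gaussian")
        assert np.all(p > 0) and p.sum() == pytest.approx(1.0)
        cop = p @ geometry.positions_mm / p.sum()
        assert not np.allclose(cop, [10.0, 20.0], atol=1e-3)


class TestSimulateSock:
    def test_noiseless_round_trip_is_exact(self):
        truth = simulate_true_cop(TrialSpec.single_leg(), seed=3, rate_hz=125.0)
        sock = simulate_sock(truth, SensorModel.ideal(), rate_hz=125.0, seed=0)
        rec = cop_series(sock)
        m = rec.valid & truth.valid
        assert m.sum() > 1000
        err = max(np.abs(rec.x[m] - truth.x[m]).max(), np.abs(rec.y[m] - truth.y[m]).max())
        assert err < 1e-9

    def test_conductances_nonnegative_with_noise(self):
        truth = simulate_true_cop(TrialSpec.single_leg(), seed=3)
        sock = simulate_sock(truth, SensorModel(noise_sd_uS=5.0), seed=1)
        assert np.all(sock.values >= 0)

    def test_unequal_sensitivities_keep_high_centered_concordance(self):
        from sockcop.agreement import lin_ccc

        cccs = []
        for seed in range(5):
            truth = simulate_true_cop(TrialSpec.single_leg(), seed=seed, rate_hz=125.0)
            sock = simulate_sock(truth, SensorModel(), rate_hz=125.0, seed=100 + seed)
            rec = cop_series(sock)
            m = rec.valid & truth.valid
            s = rec.y[m] - rec.y[m].mean()
            p = truth.y[m] - truth.y[m].mean()
            cccs.append(lin_ccc((s, p)).ccc)
        assert np.median(cccs) >= 0.8

    def test_low_saturation_compresses_reconstructed_range(self):
        truth = simulate_true_cop(TrialSpec.single_leg(), seed=4, rate_hz=125.0)
        model_ok = SensorModel(sensitivity_range=(1.5, 1.5), noise_sd_uS=0.0,
                               placement_jitter_sd_mm=0.0, baseline_uS=0.0)
        model_sat = SensorModel(sensitivity_range=(1.5, 1.5), noise_sd_uS=0.0,
                                placement_jitter_sd_mm=0.0, baseline_uS=0.0,
                                saturation_uS=40.0)
        rec_ok = cop_series(simulate_sock(truth, model_ok, seed=0))
        rec_sat = cop_series(simulate_sock(truth, model_sat, seed=0))
        m = rec_ok.valid & rec_sat.valid
        range_ok = rec_ok.x[m].max() - rec_ok.x[m].min()
        range_sat = rec_sat.x[m].max() - rec_sat.x[m].min()
        assert range_sat < range_ok

    def test_sock_rate_capped_at_200_hz(self):
        truth = simulate_true_cop(TrialSpec.single_leg(), seed=0)
        with pytest.raises(ValueError, match="200"):
            simulate_sock(truth, SensorModel.ideal(), rate_hz=500.0)


class TestSimulatePlatform:
    def test_noise_free_platform_equals_truth_at_platform_times(self):
        truth = simulate_true_cop(TrialSpec.single_leg(), seed=5, rate_hz=125.0)
        plat = simulate_platform(truth, PlatformModel(noise_sd_mm=0.0), lag_s=0.0)
        m = plat.valid
        np.testing.assert_allclose(plat.x[m], np.interp(plat.t[m], truth.t, truth.x),
                                   atol=1e-9)

    def test_placement_offset_shifts_mean(self):
        truth = simulate_true_cop(TrialSpec.single_leg(), seed=6)
        plat = simulate_platform(
            truth, PlatformModel(offset_mm=(30.0, -15.0), noise_sd_mm=0.0)
        )
        mt, mp = truth.valid, plat.valid
        assert plat.x[mp].mean() - truth.x[mt].mean() == pytest.approx(30.0, abs=0.5)
        assert plat.y[mp].mean() - truth.y[mt].mean() == pytest.approx(-15.0, abs=0.5)

    def test_lag_shifts_timestamps(self):
        truth = simulate_true_cop(TrialSpec.single_leg(), seed=7)
        plat = simulate_platform(truth, PlatformModel(noise_sd_mm=0.0), lag_s=0.4)
        assert plat.t[0] >= truth.t[0] + 0.4 - 1e-6

    def test_sidestep_adds_offset_after_onset(self):
        truth = simulate_true_cop(TrialSpec.single_leg(), seed=8)
        model = PlatformModel(noise_sd_mm=0.0,
                              sidestep=SideStep(time_s=8.0, offset_mm=(40.0, 0.0)))
        plat = simulate_platform(truth, model)
        ref = simulate_platform(truth, PlatformModel(noise_sd_mm=0.0))
        before = plat.t < 8.0
        np.testing.assert_allclose(plat.x[before], ref.x[before], atol=1e-9)
        np.testing.assert_allclose(plat.x[~before] - ref.x[~before], 40.0, atol=1e-9)


class TestGenerateStudy:
    def test_default_design_enumerates_160_waveform_pairs(self):
        design = StudyDesign()
        assert design.n_trials == 80
        assert design.n_waveform_pairs == 160

    def test_minimal_design_yields_two_pairs(self):
        design = StudyDesign(n_participants=1, exercises=(SINGLE_LEG,),
                             feet=("right",), n_applications=1)
        study = generate_study(design, seed=0)
        assert len(study.trials) == 1
        assert study.manifest()["n_waveform_pairs"] == 2

    def test_same_seed_reproduces_identical_study(self):
        design = StudyDesign(n_participants=1, n_applications=1)
        a = generate_study(design, seed=9)
        b = generate_study(design, seed=9)
        assert json.dumps(a.manifest(), sort_keys=True) == json.dumps(
            b.manifest(), sort_keys=True
        )
        for ta, tb in zip(a.trials, b.trials):
            np.testing.assert_array_equal(ta.sock.values, tb.sock.values)
            np.testing.assert_array_equal(ta.platform.x, tb.platform.x)

    def test_truth_stays_inside_sensor_hull(self):
        design = StudyDesign(n_participants=1, n_applications=1)
        study = generate_study(design, seed=3)
        hull = ConvexHull(default_geometry().scaled(0.9).positions_mm)
        for trial in study.trials:
            pts = trial.truth.xy[trial.truth.valid]
            margins = pts @ hull.equations[:, :2].T + hull.equations[:, 2]
            assert np.all(margins <= 1e-9)

    def test_rising_sensor_noise_degrades_concordance(self):
        """Median centered CCC vs truth decreases as sensor noise grows."""
        from sockcop.agreement import lin_ccc

        spec = TrialSpec.single_leg()
        medians = []
        for noise in (0.5, 30.0, 120.0):
            cccs = []
            for rep in range(20):
                rng = np.random.default_rng(10_000 + rep)
                truth = simulate_true_cop(spec, seed=rng, rate_hz=125.0)
                model = SensorModel(noise_sd_uS=noise)
                sock = simulate_sock(truth, model, rate_hz=125.0, seed=rng)
                rec = cop_series(sock)
                m = rec.valid & truth.valid
                s = rec.y[m] - rec.y[m].mean()
                p = truth.y[m] - truth.y[m].mean()
                cccs.append(lin_ccc((s, p)).ccc)
            medians.append(np.median(cccs))
        assert medians[0] > medians[1] > medians[2]
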