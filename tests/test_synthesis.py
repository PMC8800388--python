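"""Temperature programs, trajectory generation and image rendering."""

import numpy as np
import pandas as pd
import pytest

from coralbti.imaging import extract_measurements
from coralbti.modelfit import predict
from coralbti.synthesis import (
    FHP_PROGRAM,
    SHP_PROGRAM,
    RenderClippingError,
    SpeciesProfile,
    StudyDesign,
    gen_trajectory,
    generate_study,
    paper_like_profiles,
    ranking_benchmark_profiles,
    render_image_series,
    render_study,
    temperature_at,
    true_threshold_time,
)


class TestTemperatureProgram:
    def test_fast_ramp_reaches_cap_after_day_7(self):
        # 1 deg C per day from 27: the 8th increment lands on day 7
        assert temperature_at(FHP_PROGRAM, 7.2) == 35.0
        assert temperature_at(FHP_PROGRAM, 6.5) == 34.0

    def test_slow_first_step(self):
        assert temperature_at(SHP_PROGRAM, 0.6) == 28.0
        assert temperature_at(SHP_PROGRAM, 3.5) == 29.0

    def test_acclimation_holds_start(self):
        assert temperature_at(SHP_PROGRAM, -2.0) == 27.0
        with pytest.raises(ValueError):
            temperature_at(SHP_PROGRAM, -4.0)

    @pytest.mark.parametrize("prog", [FHP_PROGRAM, SHP_PROGRAM])
    def test_capped_and_nondecreasing(self, prog):
        t = np.linspace(-prog.acclimation_days, 60, 400)
        temps = [temperature_at(prog, ti) for ti in t]
        assert max(temps) <= 35.0
        assert np.all(np.diff(temps) >= 0)


class TestGenTrajectory:
    def _profile(self, noise_sd=3.0, **kw):
        from coralbti.modelfit import ModGaussParams
        defaults = dict(
            name="sp", mean=ModGaussParams(2.0, 98.0, 1.0, 6.0, 3.0),
            noise_sd=noise_sd,
        )
        defaults.update(kw)
        return SpeciesProfile(**defaults)

    def test_zero_noise_equals_prediction(self):
        prof = self._profile(noise_sd=0.0)
        t = np.arange(0, 20, 0.5)
        series, truth = gen_trajectory(prof, 0, t, seed=1)
        np.testing.assert_allclose(series.rg_values,
                                   np.asarray(predict(truth, t)))

    def test_zero_spread_shares_truth_params(self):
        prof = self._profile(y0_sd=0.0, a_sd=0.0, x0_sd=0.0, b_sd=0.0,
                             c_sd=0.0)
        t = np.arange(0, 20, 0.5)
        truths = [gen_trajectory(prof, i, t, seed=1)[1] for i in range(4)]
        for tr in truths[1:]:
            np.testing.assert_allclose(tr.as_array(), truths[0].as_array())

    def test_deterministic_per_key(self):
        prof = self._profile()
        t = np.arange(0, 20, 0.5)
        s1, p1 = gen_trajectory(prof, 2, t, seed=9, regime="SHP")
        s2, p2 = gen_trajectory(prof, 2, t, seed=9, regime="SHP")
        np.testing.assert_array_equal(s1.rg_values, s2.rg_values)
        assert p1 == p2
        s3, _ = gen_trajectory(prof, 2, t, seed=10, regime="SHP")
        assert not np.array_equal(s1.rg_values, s3.rg_values)

    def test_time_shifted_profile_shifts_true_bti(self):
        """Moving the peak +5 days moves the true BTI30 by exactly +5."""
        from coralbti.modelfit import ModGaussParams
        base = ModGaussParams(2.0, 98.0, 1.0, 6.0, 3.0)
        moved = ModGaussParams(2.0, 98.0, 6.0, 6.0, 3.0)
        t0 = true_threshold_time(base, 30.0)
        t1 = true_threshold_time(moved, 30.0)
        assert t1 - t0 == pytest.approx(5.0, abs=1e-12)


class TestStudyGeneration:
    def test_same_seed_bit_exact(self):
        d = StudyDesign(seed=4, n_colonies=2)
        s1, s2 = generate_study(d), generate_study(d)
        pd.testing.assert_frame_equal(s1.truth, s2.truth)
        for a, b in zip(s1.rg_series, s2.rg_series):
            np.testing.assert_array_equal(a.rg_values, b.rg_values)

    def test_default_study_layout(self):
        study = generate_study(StudyDesign(seed=0))
        assert len(study.rg_series) == 2 * 5 * 5
        assert set(study.truth["regime"]) == {"FHP", "SHP"}
        assert study.truth.groupby(["regime", "species"]).size().eq(5).all()

    def test_colony_susceptibility_shared_across_regimes(self):
        """The same colony's two fragments draw the same width factor:
        within a species, colony BTI ranks agree between regimes."""
        study = generate_study(StudyDesign(seed=2))
        tr = study.truth
        for sp, grp in tr.groupby("species"):
            piv = grp.pivot_table(index="colony", columns="regime",
                                  values="b")
            rank_f = piv["FHP"].rank()
            rank_s = piv["SHP"].rank()
            assert (rank_f == rank_s).all()

    def test_benchmark_profiles_separated(self):
        for regime in ("FHP", "SHP"):
            profs = ranking_benchmark_profiles(regime)
            t30 = [true_threshold_time(p.mean, 30.0) for p in profs]
            assert np.all(np.diff(t30) >= 2.0)

    def test_paper_like_start_days_ordering(self):
        """Fast-regime bleaching starts (5% criterion) sit in the 3-9 day
        band and the Millepora-like species is last to start."""
        profs = paper_like_profiles("FHP")
        t5 = {p.name: true_threshold_time(p.mean, 5.0) for p in profs}
        assert t5["Seriatopora caliendrum"] == pytest.approx(3.2, abs=0.05)
        assert t5["Millepora intricata"] == pytest.approx(8.4, abs=0.05)
        assert max(t5, key=t5.get) == "Millepora intricata"
        assert all(3.0 <= v <= 9.0 for v in t5.values())


class TestRendering:
    def test_round_trip_recovers_g0(self, tmp_path):
        g0 = np.linspace(0.9, 0.1, 12)
        t = np.arange(12) * 0.5
        manifest = render_image_series(g0, t, tmp_path, fragment_id="rt",
                                       seed=3)
        df = extract_measurements(manifest, base_dir=tmp_path)
        assert np.abs(df["g0"].to_numpy() - g0).max() < 1 / 255

    def test_affine_jitter_invariance(self, tmp_path):
        g0 = np.linspace(0.9, 0.1, 12)
        t = np.arange(12) * 0.5
        clean = render_image_series(g0, t, tmp_path / "a",
                                    fragment_id="x", seed=3)
        jit = render_image_series(
            g0, t, tmp_path / "b", fragment_id="x", seed=3,
            alpha_range=(0.95, 1.03), beta_range=(-10.0, 10.0),
        )
        g_clean = extract_measurements(clean, base_dir=tmp_path / "a")["g0"]
        g_jit = extract_measurements(jit, base_dir=tmp_path / "b")["g0"]
        assert np.abs(g_clean.to_numpy() - g_jit.to_numpy()).max() < 1 / 255

    def test_constant_integer_shift_identical_g0(self, tmp_path):
        """alpha=1 with an integer brightness offset cancels exactly."""
        g0 = np.array([0.8, 0.5, 0.2])
        t = np.arange(3) * 0.5
        a = render_image_series(g0, t, tmp_path / "a", fragment_id="x",
                                seed=1)
        b = render_image_series(g0, t, tmp_path / "b", fragment_id="x",
                                seed=1, alpha_range=(1.0, 1.0),
                                beta_range=(20.0, 20.0))
        ga = extract_measurements(a, base_dir=tmp_path / "a")["g0"]
        gb = extract_measurements(b, base_dir=tmp_path / "b")["g0"]
        np.testing.assert_allclose(ga, gb, atol=1e-12)

    def test_clipping_raises(self, tmp_path):
        with pytest.raises(RenderClippingError):
            render_image_series(
                np.array([0.5]), np.array([0.0]), tmp_path,
                alpha_range=(1.4, 1.4), beta_range=(0.0, 0.0), seed=0,
            )

    def test_render_study_manifest_consumable(self, tmp_path):
        design = StudyDesign(
            seed=6,
            profiles={"FHP": paper_like_profiles("FHP")[:1]},
            n_colonies=1,
            durations={"FHP": 6.0},
        )
        study = generate_study(design)
        manifest_path = render_study(study, tmp_path)
        df = extract_measurements(manifest_path)
        assert len(df) == 13  # 6 days twice daily, inclusive endpoints
        assert (df["warnings"] == "").all()
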