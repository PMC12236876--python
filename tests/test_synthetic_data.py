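"""Synthetic cohort generator: determinism, ground truth, effect model."""

import numpy as np
import pytest
from scipy import stats

from atload import (
    Artifact,
    EffectSpec,
    GroundTruthSummary,
    LoadThresholds,
    ParticipantProfile,
    estimate_tendon_load,
    inject_artifacts,
    make_bout,
    simulate_cohort,
    simulate_day,
    simulate_stance_profile,
    summarize_series,
)
from atload.cumulative_load import combine_summaries
from atload.insole_io import CLINICAL_MEASURES
from atload.signal_qc import flag_erroneous
from atload.synthetic_data import Bout, bout_ground_truth

from conftest import BW_N


def _profile(pid="S01", mass=67.28, volume=0.5):
    return ParticipantProfile(
        participant_id=pid, mass_kg=mass, height_m=1.7, age=40.0,
        visa_a=60.0, pas=3.0, latent_volume=volume,
    )


class TestStanceProfile:
    def test_zero_peak_gives_zero_channels(self, geometry):
        rec = simulate_stance_profile("walk", 0.0, 0.6, geometry, BW_N)
        assert np.all(rec.channels() == 0)

    def test_nonpositive_duration_rejected(self, geometry):
        with pytest.raises(ValueError):
            simulate_stance_profile("walk", 2.0, 0.0, geometry, BW_N)

    def test_forces_nonnegative_and_forefoot_dominant_at_pushoff(self, geometry):
        rec = simulate_stance_profile("walk", 2.5, 0.8, geometry, BW_N)
        assert np.all(rec.channels() >= 0)
        # push-off: last loaded samples carry more forefoot than heel
        loaded = rec.f_fore > 0
        assert rec.f_fore[loaded][-1] > rec.f_heel[loaded][-1]


class TestBouts:
    def test_bout_validation(self):
        with pytest.raises(ValueError, match="duration"):
            make_bout("walk", 0.0)
        with pytest.raises(ValueError, match="kind"):
            make_bout("swim", 60.0)
        with pytest.raises(ValueError, match="intensity"):
            Bout("walk", 60.0, -1.0, 50.0, 0.6)
        with pytest.raises(ValueError, match="fit cycle period"):
            Bout("walk", 60.0, 2.0, 120.0, 0.6)  # 0.5 s period < stance

    def test_constant_bout_ground_truth_hand_integration(self):
        # 36 s at constant 4.0 xBW: 0.01 h and 4.0*0.01 = 0.04 xBW*h at both levels
        bout = make_bout("walk", 36.0, intensity_bw=4.0, cadence_per_min=0)
        gt = bout_ground_truth(bout)
        assert gt.t_load_h == pytest.approx(0.01)
        assert gt.i_overall == pytest.approx(0.04)
        assert gt.t_high_h == pytest.approx(0.01)
        assert gt.i_high == pytest.approx(0.04)

    def test_subthreshold_constant_bout_counts_nothing(self):
        bout = make_bout("walk", 3600.0, intensity_bw=0.2, cadence_per_min=0)
        gt = bout_ground_truth(bout)
        assert gt.t_load_h == 0 and gt.i_overall == 0

    def test_ground_truth_invariants_enforced(self):
        with pytest.raises(ValueError):
            GroundTruthSummary(t_load_h=1.0, i_overall=1.0, t_high_h=2.0)


class TestSimulateDay:
    def test_same_seed_identical_recordings(self, geometry):
        sched = [make_bout("walk", 120.0), make_bout("rest", 30.0)]
        a, _ = simulate_day(_profile(), sched, seed=42, geometry=geometry)
        b, _ = simulate_day(_profile(), sched, seed=42, geometry=geometry)
        assert len(a) == len(b) == 1
        np.testing.assert_array_equal(a[0].channels(), b[0].channels())

    def test_different_seed_differs(self, geometry):
        sched = [make_bout("walk", 120.0)]
        a, _ = simulate_day(_profile(), sched, seed=1, geometry=geometry)
        b, _ = simulate_day(_profile(), sched, seed=2, geometry=geometry)
        assert not np.array_equal(a[0].channels(), b[0].channels())

    def test_empty_schedule(self, geometry):
        recs, gt = simulate_day(_profile(), [], seed=0, geometry=geometry)
        assert recs == []
        assert gt.t_load_h == 0 and gt.i_overall == 0

    def test_pure_nonwear_zero_ground_truth(self, geometry):
        recs, gt = simulate_day(
            _profile(), [make_bout("nonwear", 3600.0)], seed=0, geometry=geometry
        )
        assert gt.t_load_h == 0
        assert all(np.all(r.channels() == 0) for r in recs)

    def test_long_nonwear_splits_sessions(self, geometry):
        sched = [
            make_bout("walk", 300.0),
            make_bout("nonwear", 2000.0),
            make_bout("walk", 300.0),
        ]
        recs, _ = simulate_day(_profile(), sched, seed=3, geometry=geometry)
        assert [r.session for r in recs] == [1, 2]

    def test_day_metrics_match_analytic_ground_truth(self, geometry):
        """20 Hz pipeline recovers the continuous-schedule ground truth
        within sampling tolerance on a mixed walking/running day."""
        profile = _profile()
        sched = [
            make_bout("walk", 1800.0, intensity_bw=2.4),
            make_bout("rest", 120.0),
            make_bout("run", 600.0, intensity_bw=4.6),
            make_bout("jump", 120.0, intensity_bw=5.0),
        ]
        recs, gt = simulate_day(profile, sched, seed=9, geometry=geometry)
        parts = [
            summarize_series(estimate_tendon_load(r, geometry, profile.bw_n))
            for r in recs
        ]
        total = combine_summaries(parts, scope="day")
        assert total.t_load_h == pytest.approx(gt.t_load_h, rel=0.02)
        assert total.i_overall == pytest.approx(gt.i_overall, rel=0.02)
        assert total.t_high_h == pytest.approx(gt.t_high_h, rel=0.02)
        assert total.i_high == pytest.approx(gt.i_high, rel=0.02)


class TestArtifacts:
    def _walk_recording(self, geometry):
        profile = _profile()
        recs, _ = simulate_day(
            profile, [make_bout("walk", 300.0), make_bout("rest", 60.0)],
            seed=5, geometry=geometry,
        )
        return profile, recs[0]

    def test_empty_spec_identity(self, geometry):
        profile, rec = self._walk_recording(geometry)
        out = inject_artifacts(rec, [], geometry, profile.bw_n)
        np.testing.assert_array_equal(out.channels(), rec.channels())
        assert out is not rec

    def test_drift_offset_shows_in_unloaded_segments(self, geometry):
        profile, rec = self._walk_recording(geometry)
        out = inject_artifacts(
            rec, [Artifact("drift", offset_bw=0.1)], geometry, profile.bw_n
        )
        load = estimate_tendon_load(out, geometry, profile.bw_n).load_bw
        clean = estimate_tendon_load(rec, geometry, profile.bw_n).load_bw
        unloaded = clean == 0
        assert unloaded.any()
        np.testing.assert_allclose(load[unloaded], 0.1, rtol=1e-6)

    def test_original_untouched(self, geometry):
        profile, rec = self._walk_recording(geometry)
        before = rec.channels().copy()
        inject_artifacts(rec, [Artifact("drift", 0.2)], geometry, profile.bw_n)
        np.testing.assert_array_equal(rec.channels(), before)

    def test_erroneous_mode_is_flagged_downstream(self, geometry):
        profile, rec = self._walk_recording(geometry)
        bad = inject_artifacts(
            rec, [Artifact("erroneous", offset_bw=0.8)], geometry, profile.bw_n
        )
        report = flag_erroneous(bad, profile.bw_n, geometry=geometry)
        assert "constant_offset" in report.flags
        assert report.disposition == "drop"

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="artifact kind"):
            Artifact("gremlin")


class TestEffectModel:
    def test_noiseless_linear_map_gives_unit_correlation(self):
        spec = EffectSpec().scaled_noise(0.0)
        bundle = simulate_cohort(
            n_participants=30, n_days=1, effect_spec=spec, seed=8, day_scale=0.02
        )
        v = np.array([p.latent_volume for p in bundle.profiles])
        for measure in CLINICAL_MEASURES:
            r = stats.pearsonr(v, bundle.clinical[measure])[0]
            assert abs(r) == pytest.approx(1.0, abs=1e-9)

    def test_sampled_r_matches_closed_form(self):
        """Sample correlation approaches the generative closed form
        r = b*sd_v / sqrt(b^2 sd_v^2 + sd^2) at large n."""
        spec = EffectSpec()
        bundle = simulate_cohort(
            n_participants=600, n_days=1, effect_spec=spec, seed=15, day_scale=0.02
        )
        v = np.array([p.latent_volume for p in bundle.profiles])
        for measure in ("moment_isometric", "heel_raise_reps", "age"):
            r = stats.pearsonr(v, bundle.clinical[measure])[0]
            assert r == pytest.approx(spec.implied_r(measure), abs=0.08)


class TestCohort:
    def test_zero_volume_cohort_has_zero_high_level_truth(self):
        bundle = simulate_cohort(
            n_participants=3, n_days=2, seed=4, volume_range=(0.0, 0.0),
            day_scale=0.1,
        )
        for p in bundle.profiles:
            gt = bundle.participant_truth(p.participant_id)
            assert gt.i_high == 0.0 and gt.t_high_h == 0.0

    def test_cohort_determinism(self):
        a = simulate_cohort(n_participants=2, n_days=2, seed=6, day_scale=0.05)
        b = simulate_cohort(n_participants=2, n_days=2, seed=6, day_scale=0.05)
        assert a.clinical.equals(b.clinical)
        ra = a.recordings_for("P01", 1)
        rb = b.recordings_for("P01", 1)
        for x, y in zip(ra, rb):
            np.testing.assert_array_equal(x.channels(), y.channels())

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(n_participants=0)
        with pytest.raises(ValueError):
            simulate_cohort(n_days=0)

    def test_profile_validation(self):
        with pytest.raises(ValueError, match="mass"):
            _profile(mass=-1.0)
        with pytest.raises(ValueError, match="VISA"):
            ParticipantProfile("x", 70, 1.7, 40, 120.0, 3.0, 0.5)

    def test_thresholds_respected_in_truth(self):
        """High-level metrics never exceed overall metrics per day."""
        bundle = simulate_cohort(n_participants=3, n_days=3, seed=12, day_scale=0.05)
        for (pid, day), gt in bundle.day_truth.items():
            assert gt.t_high_h <= gt.t_load_h + 1e-12
            assert gt.i_high <= gt.i_overall + 1e-12

    def test_custom_thresholds_flow_into_truth(self):
        th = LoadThresholds(overall=0.5, high=2.0)
        bout = make_bout("walk", 36.0, intensity_bw=1.0, cadence_per_min=0)
        gt = bout_ground_truth(bout, th)
        assert gt.t_load_h == pytest.approx(0.01)
        assert gt.t_high_h == 0.0
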