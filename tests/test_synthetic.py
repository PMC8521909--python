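"""Generator contracts: shapes, determinism, moments, class separation."""

import numpy as np
import pytest
from scipy import stats as sp_stats

from jae.preprocessing import bandpass
from jae.synthetic import (
    ClassProfile,
    CohortSpec,
    followup_from,
    generate_audio,
    generate_cohort,
    generate_motion_trace,
)

from conftest import SMALL_CLICK_BAND, SMALL_FS, make_profiles


class TestMotionTrace:
    def test_counts_and_duration(self):
        motion, starts = generate_motion_trace(10, 4.0, 50.0, seed=0)
        assert len(motion.angle) == 2000  # 10 cycles x 4 s x 50 Hz
        assert motion.duration == pytest.approx(40.0)
        assert len(starts) == 10
        assert starts[0] == 0

    def test_single_cycle_periodicity(self):
        motion, starts = generate_motion_trace(1, 4.0, 50.0, seed=0,
                                               angle_noise_deg=0.0)
        assert len(starts) == 1
        # first and last samples sit at the same phase (within one sample)
        assert abs(motion.angle[0] - motion.angle[-1]) <= abs(
            motion.angle[1] - motion.angle[0]) + 1e-9

    def test_seeded_determinism(self):
        a, sa = generate_motion_trace(5, 4.0, 50.0, seed=7, period_jitter=0.05)
        b, sb = generate_motion_trace(5, 4.0, 50.0, seed=7, period_jitter=0.05)
        np.testing.assert_array_equal(a.angle, b.angle)
        np.testing.assert_array_equal(sa, sb)

    @pytest.mark.parametrize("bad", [dict(n_cycles=0), dict(cycle_period=-1.0),
                                     dict(fs_motion=0.0)])
    def test_invalid_arguments(self, bad):
        kwargs = dict(n_cycles=5, cycle_period=4.0, fs_motion=50.0)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            generate_motion_trace(**kwargs)


class TestAudio:
    def test_pure_noise_is_gaussian(self):
        motion, starts = generate_motion_trace(10, 4.0, 50.0, seed=0)
        prof = ClassProfile(label="healthy", noise_rms=1.0)
        rec = generate_audio(prof, motion, SMALL_FS, seed=0, cycle_starts=starts)
        assert len(rec.samples) >= 1e5
        assert sp_stats.kurtosis(rec.samples) == pytest.approx(0.0, abs=0.2)
        assert np.std(rec.samples) == pytest.approx(1.0, rel=0.02)

    def test_clicks_exceed_noise_floor(self):
        """With amplitude 10 and ~5 clicks/cycle, nearly every cycle's peak
        clears 5x the noise RMS."""
        prof = ClassProfile(label="jia", clicks_per_cycle=5.0,
                            click_amplitude=10.0,
                            click_freq_range=SMALL_CLICK_BAND)
        exceed = total = 0
        for seed in range(100):
            motion, starts = generate_motion_trace(10, 4.0, 50.0, seed=seed)
            rec = generate_audio(prof, motion, SMALL_FS, seed=seed,
                                 cycle_starts=starts)
            edges = np.round(np.r_[starts, len(motion.angle)]
                             * SMALL_FS / 50.0).astype(int)
            for a, b in zip(edges[:-1], edges[1:]):
                total += 1
                exceed += np.max(np.abs(rec.samples[a:b])) > 5.0
        assert exceed / total > 0.99

    def test_seeded_determinism(self):
        motion, starts = generate_motion_trace(2, 4.0, 50.0, seed=3)
        prof = ClassProfile(label="jia", clicks_per_cycle=4.0,
                            click_amplitude=8.0,
                            click_freq_range=SMALL_CLICK_BAND)
        a = generate_audio(prof, motion, SMALL_FS, seed=5, cycle_starts=starts)
        b = generate_audio(prof, motion, SMALL_FS, seed=5, cycle_starts=starts)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_nyquist_violation_rejected(self):
        motion, _ = generate_motion_trace(2, 4.0, 50.0, seed=0)
        prof = ClassProfile(label="jia", clicks_per_cycle=1.0,
                            click_amplitude=1.0,
                            click_freq_range=(500.0, 3000.0))
        with pytest.raises(ValueError, match="Nyquist"):
            generate_audio(prof, motion, SMALL_FS, seed=0)


def _small_spec(**kwargs) -> CohortSpec:
    profiles = make_profiles(click_amplitude=8.0)
    defaults = dict(n_jia=3, n_healthy=2, n_followup=2,
                    cycles_per_recording=2, fs_audio=SMALL_FS,
                    channels_per_subject=4, profiles=profiles,
                    followup_profile=followup_from(profiles["jia"]), seed=0)
    defaults.update(kwargs)
    return CohortSpec(**defaults)


class TestCohort:
    def test_session_and_channel_counts(self):
        spec = _small_spec()
        sessions = generate_cohort(spec)
        assert len(sessions) == 5 + 2  # baselines + follow-ups
        assert all(len(s.recordings) == 4 for s in sessions)
        followups = [s for s in sessions if s.visit == "followup"]
        assert len(followups) == 2
        assert all(s.group_label == "unknown" for s in followups)
        baseline_ids = {s.subject_id for s in sessions if s.visit == "baseline"}
        assert all(s.subject_id in baseline_ids for s in followups)

    def test_recordings_share_length_and_motion(self):
        for sess in generate_cohort(_small_spec()):
            lengths = {len(r.samples) for r in sess.recordings}
            assert len(lengths) == 1
            dur = sess.recordings[0].duration
            assert abs(dur - sess.motion.duration) <= 1.0 / sess.motion.fs

    def test_default_study_layout(self):
        spec = CohortSpec(fs_audio=25_000.0)
        assert spec.n_jia == 25 and spec.n_healthy == 18 and spec.n_followup == 10
        assert spec.channels_per_subject == 4

    def test_seed_changes_waveforms_not_shapes(self):
        a = generate_cohort(_small_spec(seed=0))
        b = generate_cohort(_small_spec(seed=1))
        assert len(a) == len(b)
        assert all(len(x.samples) == len(y.samples)
                   for sa, sb in zip(a, b)
                   for x, y in zip(sa.recordings, sb.recordings))
        assert not np.array_equal(a[0].recordings[0].samples,
                                  b[0].recordings[0].samples)

    def test_bit_reproducible(self):
        a = generate_cohort(_small_spec())
        b = generate_cohort(_small_spec())
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.motion.angle, sb.motion.angle)
            for x, y in zip(sa.recordings, sb.recordings):
                np.testing.assert_array_equal(x.samples, y.samples)

    def test_adding_subjects_preserves_existing(self):
        small = generate_cohort(_small_spec(n_jia=3))
        big = generate_cohort(_small_spec(n_jia=5))
        np.testing.assert_array_equal(small[0].recordings[0].samples,
                                      big[0].recordings[0].samples)

    def test_followup_exceeding_jia_rejected(self):
        with pytest.raises(ValueError, match="n_followup"):
            _small_spec(n_jia=1, n_followup=2)

    def test_energy_ordering_jia_above_healthy(self):
        """Band-limited per-cycle energy separates the classes (rank test)."""
        profiles = make_profiles(click_amplitude=8.0)
        energies = {"jia": [], "healthy": []}
        spec = CohortSpec(n_jia=10, n_healthy=10, n_followup=0,
                          cycles_per_recording=3, fs_audio=SMALL_FS,
                          channels_per_subject=1, profiles=profiles,
                          followup_profile=followup_from(profiles["jia"]),
                          seed=42)
        for sess in generate_cohort(spec):
            rec = bandpass(sess.recordings[0], 250.0, 1800.0)
            edges = np.r_[sess.true_cycle_boundaries, len(rec.samples)]
            e = [float(np.sum(rec.samples[a:b].astype(float) ** 2))
                 for a, b in zip(edges[:-1], edges[1:])]
            energies[sess.group_label].append(np.mean(e))
        stat = sp_stats.mannwhitneyu(energies["jia"], energies["healthy"],
                                     alternative="greater")
        assert stat.pvalue < 0.01


class TestProfiles:
    def test_followup_attenuation(self):
        jia = ClassProfile(label="jia", clicks_per_cycle=6.0, click_amplitude=8.0)
        fu = followup_from(jia, 5.0)
        assert fu.clicks_per_cycle == pytest.approx(1.2)
        assert fu.click_amplitude == pytest.approx(1.6)

    @pytest.mark.parametrize("bad", [dict(noise_rms=-1.0),
                                     dict(clicks_per_cycle=-0.1),
                                     dict(click_freq_range=(500.0, 100.0)),
                                     dict(click_decay=0.0)])
    def test_invalid_profiles_rejected(self, bad):
        with pytest.raises(ValueError):
            ClassProfile(label="jia", **bad)
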