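"""Feature definitions against closed forms and brute-force DFT oracles."""

import warnings

import numpy as np
import pytest

from jae.features import (
    FeatureMatrix,
    FrameContext,
    build_feature_matrix,
    cycle_features,
    default_registry,
    frame_features,
    standardize_apply,
    standardize_fit,
)
from jae.synthetic import ClassProfile, CohortSpec, followup_from, generate_cohort

from _oracles import spectral_features_bruteforce
from conftest import SMALL_FS, make_profiles

FS = 25_000.0
REG = default_registry(band=(250.0, 10_000.0))
NAMES = REG.base_names


def _sine(freq, fs=FS, duration=0.4, amp=1.0):
    t = np.arange(int(duration * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def _base(frame, fs=FS, prev=None, reg=REG):
    vals, ctx = frame_features(frame, fs, reg, prev=prev)
    return dict(zip(reg.base_names, vals)), ctx


class TestFrameFeatures:
    def test_pure_tone_centroid_and_spread(self):
        feats, _ = _base(_sine(1000.0))
        assert feats["spectral_centroid"] == pytest.approx(1000.0, rel=0.01)
        assert feats["spectral_spread"] < 50.0

    def test_pure_tone_zcr(self):
        feats, _ = _base(_sine(1000.0))
        # 2 crossings per period -> 2000 /s (one-sample edge effect allowed)
        assert feats["zcr"] == pytest.approx(2000.0, abs=2 * FS / (0.4 * FS))

    def test_energy_and_rms_definitions(self):
        x = _sine(500.0, amp=2.0)
        feats, _ = _base(x)
        assert feats["energy"] == pytest.approx(float(np.sum(x ** 2)), rel=1e-12)
        assert feats["rms"] == pytest.approx(np.sqrt(np.mean(x ** 2)), rel=1e-12)

    def test_white_noise_spectral_entropy_near_maximal(self):
        n_bins = int(0.4 * FS) // 2 + 1
        vals = []
        for seed in range(50):
            x = np.random.default_rng(seed).standard_normal(int(0.4 * FS))
            feats, _ = _base(x)
            vals.append(feats["spectral_entropy"])
        assert np.mean(vals) == pytest.approx(np.log2(n_bins), rel=0.05)

    def test_click_lowers_signal_entropy(self):
        rng = np.random.default_rng(0)
        noise = rng.standard_normal(1600)
        clicky = noise.copy()
        clicky[300:340] += 30.0 * np.sin(2 * np.pi * 900 * np.arange(40) / SMALL_FS)
        h_noise, _ = _base(noise, fs=SMALL_FS)
        h_click, _ = _base(clicky, fs=SMALL_FS)
        assert h_click["signal_entropy"] < h_noise["signal_entropy"]

    def test_flux_zero_on_first_frame_and_positive_after(self):
        a, ctx = _base(_sine(900.0))
        b, _ = _base(np.random.default_rng(0).standard_normal(int(0.4 * FS)),
                     prev=ctx)
        assert a["spectral_flux"] == 0.0
        assert b["spectral_flux"] > 0.0

    def test_all_zero_frame_is_finite(self):
        feats, _ = _base(np.zeros(4096))
        assert all(np.isfinite(v) for v in feats.values())

    def test_short_or_nonfinite_frames_rejected(self):
        with pytest.raises(ValueError):
            frame_features(np.zeros(4), FS, REG)
        bad = np.zeros(64)
        bad[10] = np.nan
        with pytest.raises(ValueError):
            frame_features(bad, FS, REG)

    def test_scale_covariance(self):
        """Scaling the signal scales energy by c^2 and leaves the shape
        features untouched."""
        x = np.random.default_rng(3).standard_normal(int(0.4 * SMALL_FS))
        f1, _ = _base(x, fs=SMALL_FS)
        f2, _ = _base(np.float64(5.0) * x, fs=SMALL_FS)
        assert f2["energy"] == pytest.approx(25.0 * f1["energy"], rel=1e-9)
        assert f2["rms"] == pytest.approx(5.0 * f1["rms"], rel=1e-9)
        for name in ("zcr", "spectral_centroid", "spectral_spread",
                     "spectral_rolloff", "spectral_entropy", "signal_entropy"):
            assert f2[name] == pytest.approx(f1[name], rel=1e-6), name


class TestDftOracle:
    @pytest.mark.parametrize("seed", range(20))
    def test_spectral_features_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = 512  # explicit DFT summation is O(n^2); small frames suffice
        fs = SMALL_FS
        prev = rng.standard_normal(n)
        x = rng.standard_normal(n) * rng.uniform(0.5, 2.0)
        reg = default_registry(band=(250.0, 10_000.0))
        _, prev_ctx = frame_features(prev, fs, reg)
        feats, _ = _base(x, fs=fs, prev=prev_ctx, reg=reg)
        oracle = spectral_features_bruteforce(x, fs, prev=prev,
                                              band=(250.0, 10_000.0))
        for name, want in oracle.items():
            assert feats[name] == pytest.approx(want, rel=1e-8), name


class TestCycleFeatures:
    def test_hand_arithmetic(self):
        reg = default_registry()
        fm = np.tile([[1.0] * 10, [3.0] * 10], (1, 1)).reshape(2, 10)
        out = dict(zip(reg.column_names, cycle_features(fm, reg)))
        assert out["zcr_mean"] == pytest.approx(2.0)
        assert out["zcr_sd"] == pytest.approx(1.0)  # population SD
        assert out["zcr_cov"] == pytest.approx(0.5)

    def test_identical_frames_zero_dispersion(self):
        reg = default_registry()
        fm = np.tile(np.arange(10.0), (4, 1))
        out = cycle_features(fm, reg)
        named = dict(zip(reg.column_names, out))
        assert all(named[f"{n}_sd"] == 0.0 for n in reg.base_names)
        assert all(named[f"{n}_cov"] == 0.0 for n in reg.base_names)

    def test_single_frame(self):
        reg = default_registry()
        fm = np.arange(10.0)[None, :]
        named = dict(zip(reg.column_names, cycle_features(fm, reg)))
        assert named["energy_mean"] == pytest.approx(fm[0, 1])
        assert named["energy_sd"] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cycle_features(np.empty((0, 10)), default_registry())


class TestMatrixAssembly:
    def _sessions(self, n_jia=1, n_healthy=1, channels=4, cycles=10, seed=0):
        profiles = make_profiles(click_amplitude=8.0)
        spec = CohortSpec(n_jia=n_jia, n_healthy=n_healthy, n_followup=0,
                          cycles_per_recording=cycles, fs_audio=SMALL_FS,
                          channels_per_subject=channels, profiles=profiles,
                          followup_profile=followup_from(profiles["jia"]),
                          seed=seed)
        return generate_cohort(spec)

    def test_row_and_column_counts(self):
        X = build_feature_matrix(self._sessions(n_jia=1, n_healthy=0),
                                 cycle_period=4.0)
        assert X.values.shape == (40, REG.n_columns)  # 4 ch x 10 cycles
        assert list(X.column_names) == REG.column_names
        assert (X.meta.groupby("channel").size() == 10).all()

    def test_assembly_deterministic(self):
        a = build_feature_matrix(self._sessions(), cycle_period=4.0)
        b = build_feature_matrix(self._sessions(), cycle_period=4.0)
        np.testing.assert_array_equal(a.values, b.values)
        assert a.meta.equals(b.meta)

    def test_labels_follow_groups(self):
        X = build_feature_matrix(self._sessions(n_jia=2, n_healthy=1,
                                                channels=1, cycles=3),
                                 cycle_period=4.0)
        lab = X.meta.groupby("subject_id")["label"].first()
        assert set(lab[lab.index.str.startswith("jia")]) == {1}
        assert set(lab[lab.index.str.startswith("ctl")]) == {0}

    def test_csv_round_trip(self, tmp_path):
        X = build_feature_matrix(self._sessions(channels=1, cycles=3),
                                 cycle_period=4.0)
        path = tmp_path / "X.csv"
        X.to_csv(path)
        Y = FeatureMatrix.from_csv(path)
        np.testing.assert_allclose(Y.values, X.values, rtol=0, atol=0)
        assert list(Y.column_names) == list(X.column_names)


class TestStandardization:
    def _matrix(self, n=40, d=6, seed=0):
        rng = np.random.default_rng(seed)
        import pandas as pd
        meta = pd.DataFrame({"subject_id": [f"s{i % 5}" for i in range(n)],
                             "visit": "baseline", "channel": "left_medial",
                             "cycle": range(n), "label": [i % 2 for i in range(n)]})
        return FeatureMatrix(rng.standard_normal((n, d)) * 3 + 1, meta,
                             [f"f{i}" for i in range(d)])

    def test_self_application_zero_mean_unit_variance(self):
        X = self._matrix()
        Z = standardize_apply(standardize_fit(X), X)
        assert np.all(np.abs(Z.values.mean(axis=0)) < 1e-9)
        assert np.all(np.abs(Z.values.var(axis=0) - 1) < 1e-9)

    def test_constant_column_warns_and_zeroes(self):
        X = self._matrix()
        X.values[:, 2] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            stats = standardize_fit(X)
        Z = standardize_apply(stats, X)
        np.testing.assert_array_equal(Z.values[:, 2], 0.0)

    def test_heldout_shift_linearity(self):
        """Shifting held-out rows by +c moves transformed rows by c/sd and
        never touches the training stats."""
        X_train, X_hold = self._matrix(seed=1), self._matrix(seed=2)
        stats = standardize_fit(X_train)
        base = standardize_apply(stats, X_hold)
        shifted = FeatureMatrix(X_hold.values + 2.5, X_hold.meta,
                                X_hold.column_names)
        out = standardize_apply(stats, shifted)
        want = np.broadcast_to(2.5 / stats.column_sds, out.values.shape)
        np.testing.assert_allclose(out.values - base.values, want, rtol=1e-10)
        stats2 = standardize_fit(X_train)
        np.testing.assert_array_equal(stats.column_means, stats2.column_means)

    def test_too_few_rows_rejected(self):
        X = self._matrix(n=1)
        with pytest.raises(ValueError):
            standardize_fit(X)
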