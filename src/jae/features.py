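"""Per-frame signal features and the cycle-level feature matrix X.

Each 400 ms frame of a flexion/extension cycle is described by time-domain
features (zero-crossing rate, energy, RMS, signal entropy) and spectral
features (centroid, spread, flux, roll-off, spectral entropy, mean band
power spectral density) computed from the Hann-windowed magnitude spectrum.
Per cycle, the mean, the population standard deviation and the coefficient
of variation of every base feature across that cycle's frames are assembled
into one row of the matrix X; a row therefore represents one cycle of
movement as seen by one accelerometer.

The registry is the extension point: the clinical study used 49 features
(its full list is not public); the default registry here carries the 10
named base features x {mean, sd, cov} = 30 columns, and every downstream
stage is dimension-agnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy.fft import rfft, rfftfreq

from .preprocessing import SegmentationError, bandpass, clamp_band, frame_cycle, segment_cycles
from .synthetic import SubjectSession

__all__ = [
    "FrameContext",
    "FeatureRegistry",
    "FeatureMatrix",
    "StandardizationStats",
    "default_registry",
    "frame_features",
    "cycle_features",
    "build_feature_matrix",
    "standardize_fit",
    "standardize_apply",
]

_COV_EPS = 1e-12  # |mean| guard in the coefficient of variation
_STD_EPS = 1e-12  # zero-variance column guard in standardization

LABEL_UNKNOWN = -1  # follow-up rows carry no ground-truth class


class FrameContext:
    """Shared per-frame quantities (one FFT per frame, reused by every
    spectral feature)."""

    def __init__(self, x: np.ndarray, fs: float,
                 prev: "FrameContext | None" = None):
        self.x = np.asarray(x, dtype=np.float64)
        self.fs = float(fs)
        self.n = len(self.x)
        self.window = sp_signal.get_window("hann", self.n, fftbins=True)
        self.mag = np.abs(rfft(self.x * self.window))
        self.power = self.mag ** 2
        self.freqs = rfftfreq(self.n, d=1.0 / fs)
        self.total_power = float(self.power.sum())
        self.prev = prev


# ---------------------------------------------------------------- time domain

def zero_crossing_rate(ctx: FrameContext) -> float:
    """Sign changes per second."""
    x = ctx.x
    crossings = int(np.count_nonzero(x[:-1] * x[1:] < 0))
    return crossings * ctx.fs / ctx.n


def frame_energy(ctx: FrameContext) -> float:
    return float(np.sum(ctx.x ** 2))


def frame_rms(ctx: FrameContext) -> float:
    return float(np.sqrt(np.mean(ctx.x ** 2)))


def signal_entropy(ctx: FrameContext, n_subframes: int = 32) -> float:
    """Shannon entropy (bits) of the energy distribution over equal
    subframes — low when energy is concentrated in transient clicks."""
    m = ctx.n // n_subframes
    if m < 1:
        n_subframes, m = ctx.n, 1
    e = (ctx.x[: n_subframes * m].reshape(n_subframes, m) ** 2).sum(axis=1)
    total = e.sum()
    if total <= 0:
        return 0.0
    p = e / total
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


# ------------------------------------------------------------ spectral domain

def spectral_centroid(ctx: FrameContext) -> float:
    """Power-weighted mean frequency (Hz)."""
    if ctx.total_power <= 0:
        return 0.0
    return float((ctx.freqs * ctx.power).sum() / ctx.total_power)


def spectral_spread(ctx: FrameContext) -> float:
    """Power-weighted SD of frequency about the centroid (Hz)."""
    if ctx.total_power <= 0:
        return 0.0
    c = spectral_centroid(ctx)
    var = ((ctx.freqs - c) ** 2 * ctx.power).sum() / ctx.total_power
    return float(np.sqrt(var))


def spectral_rolloff(ctx: FrameContext, fraction: float = 0.85) -> float:
    """Frequency below which ``fraction`` of the spectral power lies."""
    if ctx.total_power <= 0:
        return 0.0
    cum = np.cumsum(ctx.power)
    idx = int(np.searchsorted(cum, fraction * cum[-1]))
    return float(ctx.freqs[min(idx, len(ctx.freqs) - 1)])


def spectral_entropy(ctx: FrameContext) -> float:
    """Shannon entropy (bits) of the normalized power spectrum; maximal
    (log2 n_bins) for a flat spectrum."""
    if ctx.total_power <= 0:
        return 0.0
    p = ctx.power / ctx.total_power
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def spectral_flux(ctx: FrameContext) -> float:
    """Sum of squared differences of successive sum-normalized magnitude
    spectra; 0 for a cycle's first frame."""
    if ctx.prev is None:
        return 0.0
    s1, s0 = ctx.mag.sum(), ctx.prev.mag.sum()
    m1 = ctx.mag / s1 if s1 > 0 else ctx.mag
    m0 = ctx.prev.mag / s0 if s0 > 0 else ctx.prev.mag
    return float(np.sum((m1 - m0) ** 2))


def spectral_density(ctx: FrameContext,
                     band: tuple[float, float] = (250.0, 10_000.0)) -> float:
    """Mean power spectral density (periodogram scaling) over the analysis
    band."""
    scale = ctx.fs * float(np.sum(ctx.window ** 2))
    psd = ctx.power / scale
    lo, hi = band
    mask = (ctx.freqs >= lo) & (ctx.freqs <= min(hi, ctx.fs / 2))
    if not mask.any():
        return 0.0
    return float(psd[mask].mean())


# ------------------------------------------------------------------- registry

@dataclass
class FeatureRegistry:
    """Ordered feature definitions; registry order fixes column order."""

    base_features: list[tuple[str, object]]
    statistics: tuple[str, ...] = ("mean", "sd", "cov")
    extra_cycle_features: list[tuple[str, object]] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [n for n, _ in self.base_features] + [n for n, _ in self.extra_cycle_features]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")

    @property
    def base_names(self) -> list[str]:
        return [n for n, _ in self.base_features]

    @property
    def column_names(self) -> list[str]:
        cols = [f"{name}_{stat}" for name, _ in self.base_features
                for stat in self.statistics]
        cols += [n for n, _ in self.extra_cycle_features]
        return cols

    @property
    def n_columns(self) -> int:
        return len(self.base_features) * len(self.statistics) + len(self.extra_cycle_features)


def default_registry(band: tuple[float, float] = (250.0, 10_000.0),
                     rolloff_fraction: float = 0.85,
                     n_subframes: int = 32) -> FeatureRegistry:
    """The 10 named base features, each summarized by mean/SD/CoV per cycle."""
    return FeatureRegistry(base_features=[
        ("zcr", zero_crossing_rate),
        ("energy", frame_energy),
        ("rms", frame_rms),
        ("signal_entropy", lambda c: signal_entropy(c, n_subframes)),
        ("spectral_centroid", spectral_centroid),
        ("spectral_spread", spectral_spread),
        ("spectral_flux", spectral_flux),
        ("spectral_rolloff", lambda c: spectral_rolloff(c, rolloff_fraction)),
        ("spectral_entropy", spectral_entropy),
        ("spectral_density", lambda c: spectral_density(c, band)),
    ])


def frame_features(frame: np.ndarray, fs: float, registry: FeatureRegistry,
                   prev: FrameContext | None = None) -> tuple[np.ndarray, FrameContext]:
    """One value per base feature for a single frame.

    Returns the vector (registry order) and the frame's context, which the
    caller threads through as ``prev`` for flux on the next frame.
    """
    frame = np.asarray(frame)
    if len(frame) < 8:
        raise ValueError("frame must hold at least 8 samples")
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite samples")
    ctx = FrameContext(frame, fs, prev=prev)
    vals = np.array([fn(ctx) for _, fn in registry.base_features], dtype=float)
    return vals, ctx


def cycle_features(frame_matrix: np.ndarray, registry: FeatureRegistry,
                   cycle_samples: np.ndarray | None = None,
                   fs: float | None = None) -> np.ndarray:
    """Summarize per-frame base features over one cycle.

    ``frame_matrix`` is (n_frames, n_base).  For each base feature the mean,
    population SD and CoV = SD / (|mean| + eps) across frames are emitted, in
    registry column order, followed by any extra whole-cycle features.
    """
    fm = np.atleast_2d(np.asarray(frame_matrix, dtype=float))
    if fm.size == 0:
        raise ValueError("cycle has no frames")
    if fm.shape[1] != len(registry.base_features):
        raise ValueError("frame matrix width != number of base features")
    mean = fm.mean(axis=0)
    sd = fm.std(axis=0)  # population (n) denominator
    cov = sd / (np.abs(mean) + _COV_EPS)
    stat_map = {"mean": mean, "sd": sd, "cov": cov}
    out = np.empty(registry.n_columns, dtype=float)
    k = 0
    for i in range(fm.shape[1]):
        for stat in registry.statistics:
            out[k] = stat_map[stat][i]
            k += 1
    for _, fn in registry.extra_cycle_features:
        out[k] = fn(cycle_samples, fs)
        k += 1
    return out


# ------------------------------------------------------------- feature matrix

@dataclass
class FeatureMatrix:
    """The row matrix X: one row per (subject, channel, cycle).

    ``meta`` columns: subject_id, visit, channel, cycle, label
    (1 = jia, 0 = healthy, -1 = unknown / follow-up).
    """

    values: np.ndarray
    meta: pd.DataFrame
    column_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if len(self.meta) != self.values.shape[0]:
            raise ValueError("meta rows != value rows")
        if len(self.column_names) != self.values.shape[1]:
            raise ValueError("column_names != value columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def select_rows(self, mask: np.ndarray) -> "FeatureMatrix":
        mask = np.asarray(mask)
        return FeatureMatrix(self.values[mask],
                             self.meta.loc[mask].reset_index(drop=True),
                             list(self.column_names))

    def select_columns(self, names: list[str]) -> "FeatureMatrix":
        idx = [self.column_names.index(n) for n in names]
        return FeatureMatrix(self.values[:, idx], self.meta.copy(), list(names))

    def baseline(self) -> "FeatureMatrix":
        return self.select_rows((self.meta["visit"] == "baseline").to_numpy())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.concat(
            [self.meta.reset_index(drop=True),
             pd.DataFrame(self.values, columns=self.column_names)], axis=1)

    def to_csv(self, path) -> None:
        # %.17g + round_trip parsing keeps the matrix bit-exact on disk
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, float_precision="round_trip")
        meta_cols = ["subject_id", "visit", "channel", "cycle", "label"]
        feat_cols = [c for c in df.columns if c not in meta_cols]
        return cls(df[feat_cols].to_numpy(dtype=float),
                   df[meta_cols].copy(), feat_cols)


def build_feature_matrix(
    sessions: list[SubjectSession],
    *,
    band: tuple[float, float] = (250.0, 10_000.0),
    lowpass_cutoff: float = 5.0,
    frame_len: float = 0.4,
    cycle_period: float | None = 4.0,
    registry: FeatureRegistry | None = None,
) -> FeatureMatrix:
    """Run filtering, segmentation and feature extraction over a cohort.

    Rows are ordered (session, channel, cycle); the result is a pure
    function of the sessions and parameters.  The band's upper edge is
    clamped below Nyquist at desk-scale sampling rates.
    """
    rows, meta = [], []
    label_map = {"healthy": 0, "jia": 1, "unknown": LABEL_UNKNOWN}
    for sess in sessions:
        made_rows = False
        for rec in sess.recordings:
            lo, hi = clamp_band(rec.fs, *band)
            filtered = bandpass(rec, lo, hi)
            if registry is None:
                reg = default_registry(band=(lo, hi))
            else:
                reg = registry
            try:
                seg_result = segment_cycles(filtered, sess.motion,
                                            lowpass_cutoff=lowpass_cutoff,
                                            expected_period=cycle_period)
            except SegmentationError as exc:
                raise SegmentationError(
                    f"session {sess.subject_id}/{sess.visit} channel "
                    f"{rec.channel}: {exc}") from exc
            for ci, seg in enumerate(seg_result):
                try:
                    frame_cycle(seg, frame_len, rec.fs)
                except SegmentationError:
                    continue  # cycle shorter than one frame
                fm = np.empty((len(seg.frames), len(reg.base_features)))
                prev = None
                for fi, fr in enumerate(seg.frames):
                    fm[fi], prev = frame_features(fr, rec.fs, reg, prev=prev)
                rows.append(cycle_features(fm, reg, seg.samples, rec.fs))
                meta.append((sess.subject_id, sess.visit, rec.channel, ci,
                             label_map[sess.group_label]))
                made_rows = True
        if not made_rows:
            raise SegmentationError(
                f"session {sess.subject_id}/{sess.visit} produced no cycles")
    reg = registry if registry is not None else default_registry()
    meta_df = pd.DataFrame(meta, columns=["subject_id", "visit", "channel",
                                          "cycle", "label"])
    return FeatureMatrix(np.vstack(rows), meta_df, reg.column_names)


# -------------------------------------------------------------- standardizing

@dataclass
class StandardizationStats:
    """Training-fold column means and SDs (the held-out subject is never
    part of these)."""

    column_means: np.ndarray
    column_sds: np.ndarray

    def __post_init__(self) -> None:
        self.column_means = np.asarray(self.column_means, dtype=float)
        self.column_sds = np.asarray(self.column_sds, dtype=float)
        if self.column_means.shape != self.column_sds.shape:
            raise ValueError("means and sds must have equal length")


def standardize_fit(X_train: FeatureMatrix) -> StandardizationStats:
    """Column means/SDs of the training rows only (population SD)."""
    if X_train.n_rows < 2:
        raise ValueError("need at least 2 rows to standardize")
    means = X_train.values.mean(axis=0)
    sds = X_train.values.std(axis=0)
    zero = sds <= 0
    if zero.any():
        bad = [X_train.column_names[i] for i in np.flatnonzero(zero)]
        warnings.warn(f"zero-variance columns {bad}: SD replaced by epsilon",
                      stacklevel=2)
        sds = np.where(zero, _STD_EPS, sds)
    return StandardizationStats(means, sds)


def standardize_apply(stats: StandardizationStats, X: FeatureMatrix) -> FeatureMatrix:
    """Transform any matrix with frozen training statistics."""
    if X.values.shape[1] != len(stats.column_means):
        raise ValueError("column count mismatch")
    vals = (X.values - stats.column_means) / stats.column_sds
    return FeatureMatrix(vals, X.meta.copy(), list(X.column_names))
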