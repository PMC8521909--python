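"""Pre-processing of raw joint-vibration recordings.

Three stages: a linear-phase FIR band-pass (the clinical protocol uses
250 Hz–10 kHz to strip muscle-sound artifacts below and sensor artifacts
above the informative band), segmentation of each recording into individual
flexion/extension cycles driven by the synchronized knee-angle (IMU) trace,
and partitioning of each cycle into fixed-length analysis frames (400 ms in
the protocol).

Cycle boundaries are taken from local minima of the low-passed knee angle
(the knee is fully extended at the start of every cycle).  A 5 Hz low-passed
envelope of the audio itself is computed alongside and correlated with the
motion trace as a QC number — the two independent views of the movement
should agree for a well-synchronized session.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .synthetic import AudioRecording, MotionTrace

__all__ = [
    "CycleSegment",
    "SegmentationResult",
    "SegmentationError",
    "design_bandpass",
    "bandpass",
    "segment_cycles",
    "frame_cycle",
]


class SegmentationError(RuntimeError):
    """Raised when no valid flexion/extension cycle can be delimited."""


@dataclass
class CycleSegment:
    """One flexion/extension cycle of filtered audio, 0-based half-open
    ``[start, end)`` in audio samples; ``frames`` filled by `frame_cycle`."""

    start: int
    end: int
    samples: np.ndarray
    frames: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must exceed start")


@dataclass
class SegmentationResult:
    """Sequence of detected cycles plus QC metadata."""

    segments: list[CycleSegment]
    qc_correlation: float  # motion vs. audio-envelope agreement, [-1, 1]
    motion_boundaries: np.ndarray  # motion-rate indices of cycle edges

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def __getitem__(self, i):
        return self.segments[i]


def design_bandpass(fs: float, low: float, high: float) -> np.ndarray:
    """Windowed-sinc (Hamming) linear-phase FIR band-pass.

    Order 4·fs/low rounded to even, so the filter holds ~4 periods of the
    low cutoff; the odd tap count keeps the group delay at an integer
    number of samples.
    """
    if not (0 < low < high):
        raise ValueError(f"need 0 < low < high, got ({low}, {high})")
    if high >= fs / 2:
        raise ValueError(
            f"upper cutoff {high:g} Hz reaches the Nyquist frequency "
            f"{fs / 2:g} Hz at fs={fs:g} Hz"
        )
    order = int(round(4 * fs / low / 2) * 2)
    return signal.firwin(order + 1, [low, high], fs=fs, pass_zero=False,
                         window="hamming")


def bandpass(rec: AudioRecording, low: float, high: float) -> AudioRecording:
    """Apply the band-pass with group-delay compensation (centered
    convolution), so output aligns in time with input and keeps its length."""
    taps = design_bandpass(rec.fs, low, high)
    x = np.asarray(rec.samples, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty recording")
    # odd-length kernel + mode="same" == forward filter shifted by the group delay
    y = signal.oaconvolve(x, taps, mode="same")
    return AudioRecording(samples=y.astype(np.float32), fs=rec.fs,
                          channel=rec.channel, subject_id=rec.subject_id,
                          visit=rec.visit)


def _lowpass_fir(x: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    """Zero-delay FIR low-pass (centered Hamming windowed-sinc)."""
    order = min(int(round(2 * fs / cutoff / 2) * 2), 2 * (len(x) // 2) - 2)
    if order < 2:
        return x.copy()
    taps = signal.firwin(order + 1, cutoff, fs=fs)
    return signal.oaconvolve(x, taps, mode="same")


def _audio_envelope_at_motion_rate(rec: AudioRecording, motion: MotionTrace,
                                   cutoff: float) -> np.ndarray:
    """Rectified audio envelope, block-averaged down to the motion rate and
    low-passed at ``cutoff`` — the audio's own low-rate view of the movement."""
    block = max(1, int(round(rec.fs / motion.fs)))
    n_blocks = len(rec.samples) // block
    env = np.abs(np.asarray(rec.samples[: n_blocks * block], dtype=np.float64))
    env = env.reshape(n_blocks, block).mean(axis=1)
    return _lowpass_fir(env, motion.fs, cutoff)


def segment_cycles(
    rec: AudioRecording,
    motion: MotionTrace,
    *,
    lowpass_cutoff: float = 5.0,
    expected_period: float | None = None,
) -> SegmentationResult:
    """Delimit flexion/extension cycles from the knee-angle minima.

    The angle trace is low-passed, its local minima (full knee extension)
    become cycle boundaries, and boundaries are mapped onto audio sample
    indices.  The first/last samples are accepted as boundaries when the
    nearest interior minimum sits about one full period away.

    Raises
    ------
    SegmentationError
        If fewer than one complete cycle is found.
    ValueError
        If audio and motion durations disagree by more than one motion
        sample.
    """
    if abs(rec.duration - motion.duration) > 1.0 / motion.fs + 1e-9:
        raise ValueError(
            f"audio duration {rec.duration:.3f}s and motion duration "
            f"{motion.duration:.3f}s disagree by more than one motion sample"
        )

    angle = _lowpass_fir(motion.angle, motion.fs, lowpass_cutoff)
    if expected_period is not None:
        min_distance = int(0.5 * expected_period * motion.fs)
    else:
        min_distance = max(1, int(0.1 * len(angle)))
    prominence = 0.1 * max(np.ptp(angle), 1e-12)
    minima, _ = signal.find_peaks(-angle, distance=min_distance,
                                  prominence=prominence)

    if len(minima) == 0:
        raise SegmentationError("no interior angle minima: cannot delimit cycles")
    # re-estimate the cycle period from the detected minima and re-detect,
    # so closely spaced spurious minima are suppressed
    if len(minima) >= 2:
        est_period = float(np.median(np.diff(minima)))
        minima, _ = signal.find_peaks(-angle, distance=max(1, int(0.5 * est_period)),
                                      prominence=prominence)
    gap = float(np.median(np.diff(minima))) if len(minima) >= 2 else float(minima[0])

    boundaries = list(minima)
    if boundaries[0] >= 0.6 * gap:
        boundaries.insert(0, 0)
    if len(angle) - 1 - boundaries[-1] >= 0.6 * gap:
        boundaries.append(len(angle) - 1)
    boundaries = np.asarray(boundaries, dtype=int)
    if len(boundaries) < 2:
        raise SegmentationError("fewer than one complete cycle detected")

    env = _audio_envelope_at_motion_rate(rec, motion, lowpass_cutoff)
    m = min(len(env), len(angle))
    if m >= 2 and np.std(env[:m]) > 0 and np.std(angle[:m]) > 0:
        qc = float(np.corrcoef(env[:m], angle[:m])[0, 1])
    else:
        qc = 0.0

    ratio = rec.fs / motion.fs
    audio_bounds = np.round(boundaries * ratio).astype(int)
    audio_bounds[-1] = min(audio_bounds[-1], len(rec.samples))
    segments = [
        CycleSegment(start=int(a), end=int(b),
                     samples=np.asarray(rec.samples[a:b]))
        for a, b in zip(audio_bounds[:-1], audio_bounds[1:])
        if b > a
    ]
    if not segments:
        raise SegmentationError("fewer than one complete cycle detected")
    return SegmentationResult(segments=segments, qc_correlation=qc,
                              motion_boundaries=boundaries)


def frame_cycle(seg: CycleSegment, frame_len: float, fs: float) -> CycleSegment:
    """Split a cycle into non-overlapping contiguous frames of
    ``round(frame_len * fs)`` samples; the trailing remainder is discarded."""
    n = int(round(frame_len * fs))
    if n < 8:
        raise ValueError(f"frame of {n} samples is too short (< 8)")
    total = len(seg.samples)
    if total < n:
        raise SegmentationError(
            f"cycle of {total} samples shorter than one {n}-sample frame"
        )
    n_frames = total // n
    seg.frames = [seg.samples[i * n:(i + 1) * n] for i in range(n_frames)]
    return seg


def clamp_band(fs: float, low: float, high: float,
               fraction: float = 0.45) -> tuple[float, float]:
    """Clamp the upper band edge to ``fraction * fs`` when the configured
    band does not fit under Nyquist (desk-scale sampling rates)."""
    if high >= fs / 2:
        clamped = fraction * fs
        warnings.warn(
            f"band upper edge {high:g} Hz >= Nyquist at fs={fs:g} Hz; "
            f"clamped to {clamped:g} Hz",
            stacklevel=2,
        )
        high = clamped
    return low, high
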