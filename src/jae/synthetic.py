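"""Synthetic joint-acoustic-emission (JAE) cohorts.

Real JAE recordings from pediatric knees are not publicly deposited, so this
module generates seeded stand-in cohorts whose statistical structure follows
the qualitative picture reported for juvenile idiopathic arthritis (JIA):
healthy knees emit broadband noise-like vibrations, while actively inflamed
knees add periodic, high-energy clicks to every flexion/extension cycle, and
successful treatment strongly attenuates those clicks.

Each subject session consists of several audio-rate accelerometer channels
(two per knee in the clinical protocol), one low-rate knee-angle trace from
an ankle IMU, and ground-truth cycle boundaries that only a simulator can
provide.  Per-subject random streams are derived by hashing
``(seed, subject_id)`` so that enlarging a cohort never perturbs the signals
of existing subjects.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ClassProfile",
    "CohortSpec",
    "AudioRecording",
    "MotionTrace",
    "SubjectSession",
    "HEALTHY_PROFILE",
    "JIA_PROFILE",
    "followup_from",
    "generate_motion_trace",
    "generate_audio",
    "generate_cohort",
]

CHANNEL_NAMES = ("left_medial", "left_lateral", "right_medial", "right_lateral")


@dataclass(frozen=True)
class ClassProfile:
    """Acoustic emission profile of one diagnostic class.

    Parameters
    ----------
    label : str
        ``"healthy"`` or ``"jia"``.
    noise_rms : float
        RMS of the Gaussian background vibration, in acceleration a.u.
    clicks_per_cycle : float
        Mean number of transient clicks per flexion/extension cycle
        (Poisson-distributed per cycle); 0 yields pure noise.
    click_amplitude : float
        Peak click amplitude as a multiple of ``noise_rms``.
    click_freq_range : tuple of float
        (low, high) Hz; each click's carrier frequency is drawn uniformly
        from this range.  Must stay below the audio Nyquist frequency.
    click_decay : float
        Exponential envelope time constant of a click, seconds.
    """

    label: str
    noise_rms: float = 1.0
    clicks_per_cycle: float = 0.0
    click_amplitude: float = 0.0
    click_freq_range: tuple[float, float] = (2000.0, 8000.0)
    click_decay: float = 0.003

    def __post_init__(self) -> None:
        if self.noise_rms < 0 or self.clicks_per_cycle < 0 or self.click_amplitude < 0:
            raise ValueError("profile rates and amplitudes must be >= 0")
        lo, hi = self.click_freq_range
        if not (0 < lo < hi):
            raise ValueError(f"invalid click_freq_range {self.click_freq_range}")
        if self.click_decay <= 0:
            raise ValueError("click_decay must be positive")

    @property
    def emits_clicks(self) -> bool:
        return self.clicks_per_cycle > 0 and self.click_amplitude > 0


# Defaults mirror the study's qualitative description: healthy joints sound
# like white noise; inflamed joints add several high-energy mid/high-frequency
# clicks per movement cycle.
HEALTHY_PROFILE = ClassProfile(label="healthy")
JIA_PROFILE = ClassProfile(
    label="jia", clicks_per_cycle=6.0, click_amplitude=8.0,
    click_freq_range=(2000.0, 8000.0), click_decay=0.003,
)


def followup_from(profile: ClassProfile, attenuation: float = 5.0) -> ClassProfile:
    """Follow-up (post-treatment) profile: click rate and amplitude reduced
    ``attenuation``-fold, emulating successful therapy."""
    return replace(
        profile,
        clicks_per_cycle=profile.clicks_per_cycle / attenuation,
        click_amplitude=profile.click_amplitude / attenuation,
    )


@dataclass(frozen=True)
class CohortSpec:
    """Full description of one synthetic cohort.

    Defaults reproduce the clinical study layout: 25 JIA + 18 healthy
    baseline subjects, 10 JIA follow-ups, 4 accelerometer channels each,
    10 flexion/extension cycles at ~4 s per cycle.  The audio rate defaults
    to a desk-scale 25 kHz — the analysis band tops out at 10 kHz, so this
    preserves every downstream quantity while keeping a full cohort in
    memory; it is a configuration knob, not a constant.
    """

    n_jia: int = 25
    n_healthy: int = 18
    n_followup: int = 10
    cycles_per_recording: int = 10
    cycle_period: float = 4.0
    fs_audio: float = 25_000.0
    fs_motion: float = 50.0
    channels_per_subject: int = 4
    profiles: dict[str, ClassProfile] = field(
        default_factory=lambda: {"healthy": HEALTHY_PROFILE, "jia": JIA_PROFILE}
    )
    followup_profile: ClassProfile = field(
        default_factory=lambda: followup_from(JIA_PROFILE)
    )
    period_jitter: float = 0.02
    amplitude_jitter: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_jia < 0 or self.n_healthy < 0 or self.n_followup < 0:
            raise ValueError("cohort counts must be >= 0")
        if self.n_followup > self.n_jia:
            raise ValueError(
                f"n_followup ({self.n_followup}) exceeds n_jia ({self.n_jia})"
            )
        if self.channels_per_subject < 1:
            raise ValueError("channels_per_subject must be >= 1")
        if self.cycles_per_recording < 1 or self.cycle_period <= 0:
            raise ValueError("need >= 1 cycle of positive duration")
        used = list(self.profiles.values())
        if self.n_followup > 0:
            used.append(self.followup_profile)
        for prof in used:
            if prof.emits_clicks and prof.click_freq_range[1] >= self.fs_audio / 2:
                raise ValueError(
                    f"click_freq_range {prof.click_freq_range} reaches the "
                    f"Nyquist frequency {self.fs_audio / 2:g} Hz"
                )


@dataclass
class AudioRecording:
    """One channel of skin-surface vibration samples."""

    samples: np.ndarray
    fs: float
    channel: str = "left_medial"
    subject_id: str = ""
    visit: str = "baseline"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class MotionTrace:
    """Low-rate knee-angle signal (degrees) from the ankle IMU."""

    angle: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.angle = np.asarray(self.angle, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def duration(self) -> float:
        return len(self.angle) / self.fs


@dataclass
class SubjectSession:
    """All synchronized signals from one subject visit."""

    subject_id: str
    visit: str  # "baseline" | "followup"
    group_label: str  # "healthy" | "jia" | "unknown"
    recordings: list[AudioRecording]
    motion: MotionTrace
    true_cycle_boundaries: np.ndarray  # audio-rate sample indices, ground truth


def _subject_rng(seed: int, subject_id: str, stream: str = "") -> np.random.Generator:
    """Deterministic per-subject stream from (seed, subject_id, stream)."""
    digest = hashlib.sha256(f"{subject_id}/{stream}".encode()).digest()
    key = int.from_bytes(digest[:4], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))


def generate_motion_trace(
    n_cycles: int,
    cycle_period: float,
    fs_motion: float,
    seed: int | np.random.Generator = 0,
    *,
    period_jitter: float = 0.0,
    amplitude_jitter: float = 0.0,
    angle_noise_deg: float = 0.3,
    rom_deg: float = 90.0,
    baseline_deg: float = 5.0,
) -> tuple[MotionTrace, np.ndarray]:
    """Smooth periodic knee-angle trace plus ground-truth cycle starts.

    The angle follows a raised-cosine per cycle (minimum = fully extended at
    each cycle start), with optional per-cycle jitter in period and range of
    motion and a little measurement noise.

    Returns
    -------
    (MotionTrace, ndarray)
        The trace and the 0-based motion-sample indices of each cycle start.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if cycle_period <= 0 or fs_motion <= 0:
        raise ValueError("cycle_period and fs_motion must be positive")
    if fs_motion <= 2.0 / cycle_period:
        raise ValueError("fs_motion must exceed 2 / cycle_period")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    periods = cycle_period * (1.0 + period_jitter * rng.standard_normal(n_cycles))
    periods = np.clip(periods, 0.5 * cycle_period, 1.5 * cycle_period)
    # keep the session length exact so shapes depend only on the layout,
    # never on the seed; jitter moves interior boundaries only
    periods *= n_cycles * cycle_period / periods.sum()
    amps = rom_deg * (1.0 + amplitude_jitter * rng.standard_normal(n_cycles))
    starts_t = np.concatenate([[0.0], np.cumsum(periods)])  # n_cycles + 1 edges

    n_samples = int(round(starts_t[-1] * fs_motion))
    t = np.arange(n_samples) / fs_motion
    cycle_idx = np.clip(np.searchsorted(starts_t, t, side="right") - 1, 0, n_cycles - 1)
    phase = (t - starts_t[cycle_idx]) / periods[cycle_idx]
    angle = baseline_deg + amps[cycle_idx] * 0.5 * (1.0 - np.cos(2 * np.pi * phase))
    if angle_noise_deg > 0:
        angle = angle + angle_noise_deg * rng.standard_normal(n_samples)

    start_idx = np.round(starts_t[:-1] * fs_motion).astype(int)
    return MotionTrace(angle=angle, fs=fs_motion), start_idx


def generate_audio(
    profile: ClassProfile,
    motion: MotionTrace,
    fs_audio: float,
    seed: int | np.random.Generator = 0,
    *,
    cycle_starts: np.ndarray | None = None,
) -> AudioRecording:
    """Synthesize one accelerometer channel aligned with a motion trace.

    Gaussian background noise at ``profile.noise_rms``; per cycle, a Poisson
    number of clicks (mean ``clicks_per_cycle``) at uniform phases, each an
    exponentially decaying sinusoid with a carrier drawn from
    ``click_freq_range``.
    """
    if profile.emits_clicks and profile.click_freq_range[1] >= fs_audio / 2:
        raise ValueError(
            f"click frequencies {profile.click_freq_range} reach the Nyquist "
            f"frequency {fs_audio / 2:g} Hz"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n = int(round(motion.duration * fs_audio))
    x = rng.standard_normal(n).astype(np.float32) * np.float32(profile.noise_rms)

    if cycle_starts is None:
        edges = np.array([0, len(motion.angle)])
    else:
        edges = np.concatenate([cycle_starts, [len(motion.angle)]])
    edges_audio = np.round(edges * fs_audio / motion.fs).astype(int)

    if profile.clicks_per_cycle > 0 and profile.click_amplitude > 0:
        n_click_samples = int(round(5 * profile.click_decay * fs_audio))
        tt = np.arange(n_click_samples) / fs_audio
        env = np.exp(-tt / profile.click_decay)
        lo_f, hi_f = profile.click_freq_range
        amp = profile.click_amplitude * profile.noise_rms
        for c0, c1 in zip(edges_audio[:-1], edges_audio[1:]):
            for _ in range(rng.poisson(profile.clicks_per_cycle)):
                pos = rng.integers(c0, max(c0 + 1, c1 - n_click_samples))
                f = rng.uniform(lo_f, hi_f)
                click = amp * env * np.sin(2 * np.pi * f * tt + rng.uniform(0, 2 * np.pi))
                stop = min(pos + n_click_samples, n)
                x[pos:stop] += click[: stop - pos].astype(np.float32)

    return AudioRecording(samples=x, fs=fs_audio)


def generate_cohort(spec: CohortSpec) -> list[SubjectSession]:
    """Generate the full seeded cohort: baseline sessions for every subject
    plus attenuated follow-up sessions for the first ``n_followup`` JIA
    subjects (their training labels are withheld — marked ``unknown``)."""
    sessions: list[SubjectSession] = []
    subjects = [(f"jia{i:03d}", "jia") for i in range(spec.n_jia)]
    subjects += [(f"ctl{i:03d}", "healthy") for i in range(spec.n_healthy)]

    for subject_id, group in subjects:
        sessions.append(_make_session(spec, subject_id, "baseline", group,
                                      spec.profiles[group], group_label=group))
    for i in range(spec.n_followup):
        subject_id = f"jia{i:03d}"
        sessions.append(_make_session(spec, subject_id, "followup", "jia",
                                      spec.followup_profile, group_label="unknown"))
    return sessions


def _make_session(
    spec: CohortSpec,
    subject_id: str,
    visit: str,
    group: str,
    profile: ClassProfile,
    group_label: str,
) -> SubjectSession:
    rng_motion = _subject_rng(spec.seed, subject_id, f"{visit}/motion")
    motion, starts = generate_motion_trace(
        spec.cycles_per_recording,
        spec.cycle_period,
        spec.fs_motion,
        rng_motion,
        period_jitter=spec.period_jitter,
        amplitude_jitter=spec.amplitude_jitter,
    )
    recordings = []
    for ch in range(spec.channels_per_subject):
        name = CHANNEL_NAMES[ch] if ch < len(CHANNEL_NAMES) else f"ch{ch}"
        rng_audio = _subject_rng(spec.seed, subject_id, f"{visit}/audio/{name}")
        rec = generate_audio(profile, motion, spec.fs_audio, rng_audio,
                             cycle_starts=starts)
        rec.channel = name
        rec.subject_id = subject_id
        rec.visit = visit
        recordings.append(rec)
    boundaries = np.round(starts * spec.fs_audio / spec.fs_motion).astype(int)
    return SubjectSession(
        subject_id=subject_id,
        visit=visit,
        group_label=group_label,
        recordings=recordings,
        motion=motion,
        true_cycle_boundaries=boundaries,
    )
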