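"""Minimal static plot helpers (session overview, accuracy heatmap)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .importance import HeatmapResult  # noqa: E402
from .synthetic import SubjectSession  # noqa: E402

__all__ = ["plot_session", "plot_heatmap"]


def plot_session(session: SubjectSession, path=None):
    """First audio channel over the knee-angle trace, with ground-truth
    cycle boundaries when available."""
    fig, (ax0, ax1) = plt.subplots(2, 1, sharex=True, figsize=(10, 5))
    rec = session.recordings[0]
    t_a = np.arange(len(rec.samples)) / rec.fs
    ax0.plot(t_a, rec.samples, lw=0.3)
    ax0.set_ylabel("acceleration (a.u.)")
    ax0.set_title(f"{session.subject_id} / {session.visit} ({session.group_label})")
    t_m = np.arange(len(session.motion.angle)) / session.motion.fs
    ax1.plot(t_m, session.motion.angle, color="tab:orange")
    ax1.set_ylabel("knee angle (deg)")
    ax1.set_xlabel("time (s)")
    for b in np.asarray(session.true_cycle_boundaries) / rec.fs:
        ax0.axvline(b, color="k", lw=0.5, alpha=0.4)
        ax1.axvline(b, color="k", lw=0.5, alpha=0.4)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_heatmap(result: HeatmapResult, path=None):
    """Accuracy as a function of top-k features (y) and test cycles (x)."""
    fig, ax = plt.subplots(figsize=(8, 5))
    im = ax.imshow(result.accuracy, origin="lower", aspect="auto",
                   vmin=0.0, vmax=1.0, cmap="viridis",
                   extent=(result.cycle_counts[0] - 0.5, result.cycle_counts[-1] + 0.5,
                           result.feature_counts[0] - 0.5, result.feature_counts[-1] + 0.5))
    ax.set_xlabel("cycles used at test time")
    ax.set_ylabel("top-ranked features used")
    fig.colorbar(im, ax=ax, label="subject-level accuracy")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
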