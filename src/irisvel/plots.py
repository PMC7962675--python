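"""Presentation figures: speed trace with event shading, main sequence, rates."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .detect import EventRecord


def plot_speed_trace(
    speed: np.ndarray,
    fps: float,
    events: list[EventRecord],
    threshold: float | None = None,
    saccade_cut: float = 50.0,
    path: str | Path | None = None,
):
    """Absolute cyclopean speed vs time with detected events shaded.

    Microsaccades are shaded green, saccades red, mirroring the standard
    presentation of velocity-threshold detections.
    """
    t = (np.arange(len(speed)) + 0.5) / fps
    fig, ax = plt.subplots(figsize=(10, 3.2))
    ax.plot(t, speed, lw=0.7, color="tab:blue")
    for ev in events:
        color = "tab:green" if ev.label == "microsaccade" else "tab:red"
        ax.axvspan(ev.onset / fps, (ev.offset + 1) / fps, color=color, alpha=0.3)
    if threshold is not None:
        ax.axhline(threshold, color="k", ls="--", lw=0.8, label=f"threshold {threshold:.2f}")
        ax.legend(loc="upper right", fontsize=8)
    ax.axhline(saccade_cut, color="tab:red", ls=":", lw=0.8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("cyclopean speed (deg/s)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=130)
        plt.close(fig)
    return fig


def plot_main_sequence(
    events: list[EventRecord], slope: float | None = None, path: str | Path | None = None
):
    """Peak speed vs amplitude (arcmin), log-log, with the fitted slope."""
    amps = np.array([e.amplitude for e in events]) * 60.0  # arcmin
    peaks = np.array([e.peak_speed for e in events])
    labels = np.array([e.label for e in events])
    fig, ax = plt.subplots(figsize=(4.5, 4))
    for lbl, marker, color in [("microsaccade", "o", "tab:red"), ("saccade", "*", "tab:blue")]:
        sel = labels == lbl
        ax.loglog(amps[sel], peaks[sel], marker, ms=5, ls="", label=lbl, color=color)
    if slope is not None:
        xs = np.linspace(max(amps.min(), 1e-2), amps.max(), 50)
        ax.loglog(xs, slope * xs / 60.0, "k-", lw=0.8, label=f"slope {slope:.1f} /s")
    ax.axhline(50.0, color="grey", ls=":", lw=0.8)
    ax.set_xlabel("amplitude (arcmin)")
    ax.set_ylabel("peak speed (deg/s)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=130)
        plt.close(fig)
    return fig


def plot_rate_box(rates_per_window: np.ndarray, path: str | Path | None = None):
    """Box plot of per-window microsaccade rates."""
    fig, ax = plt.subplots(figsize=(3.2, 4))
    ax.boxplot(np.asarray(rates_per_window, dtype=float))
    ax.set_ylabel("microsaccades / s")
    ax.set_xticks([])
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=130)
        plt.close(fig)
    return fig
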