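"""ERP preprocessing: band-pass filter, epoching, artifact rejection,
mastoid re-referencing, baseline correction and trial averaging.

The canonical order is fixed: filter -> epoch -> reject -> rereference ->
baseline -> average.  All operations are deterministic; filtering is
zero-phase (forward-backward) 4th-order Butterworth, the standard ERP
realization with no group delay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .containers import ERP, EpochSet
from .errors import EmptyResultError, InvalidArgumentError
from .montage import Montage

__all__ = [
    "bandpass",
    "epoch",
    "reject_artifacts",
    "rereference_mastoid",
    "baseline_correct",
    "average_erp",
    "preprocess_epochs",
    "PreprocessResult",
]

PIPELINE_ORDER = ("filter", "epoch", "reject", "rereference", "baseline", "average")


def bandpass(
    data: np.ndarray, fs: float, low: float, high: float, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last (time) axis."""
    if not (0.0 < low < high < fs / 2.0):
        raise InvalidArgumentError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < fs/2 = {fs / 2}"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(data, dtype=float), axis=-1)


def epoch(
    continuous: np.ndarray,
    fs: float,
    onsets: np.ndarray,
    window_ms: tuple[float, float] = (-200.0, 500.0),
    *,
    channel_labels: list[str] | None = None,
    subject_id: str = "",
    group_label: int | None = None,
) -> tuple[EpochSet, int]:
    """Cut ``(channels, samples)`` continuous data into onset-locked epochs.

    Windows are half-open ``[start, end)`` in ms relative to each onset, so
    the default −200…+500 ms window at 1 kHz yields 700 samples.  Onsets whose
    window does not fit in the recording are dropped with a warning; the count
    of dropped onsets is returned alongside the epochs.
    """
    continuous = np.asarray(continuous, dtype=float)
    if continuous.ndim != 2:
        raise InvalidArgumentError("continuous data must be (channels, samples)")
    start_ms, end_ms = window_ms
    pre = int(round(-start_ms * fs / 1000.0))
    post = int(round(end_ms * fs / 1000.0))
    n_total = continuous.shape[1]
    trials = []
    dropped = 0
    for onset in np.sort(np.asarray(onsets, dtype=int)):
        lo, hi = onset - pre, onset + post
        if lo < 0 or hi > n_total:
            dropped += 1
            continue
        trials.append(continuous[:, lo:hi])
    if dropped:
        warnings.warn(f"dropped {dropped} onset(s) with out-of-bounds windows")
    stacked = (
        np.stack(trials) if trials else np.empty((0, continuous.shape[0], pre + post))
    )
    es = EpochSet(
        data=stacked,
        fs=fs,
        window_ms=window_ms,
        channel_labels=channel_labels or [],
        subject_id=subject_id,
        group_label=group_label,
    )
    return es, dropped


def default_p2p_threshold(epochs: EpochSet, factor: float = 6.0) -> float:
    """Heuristic rejection threshold: ``factor`` x the median (over trials)
    of the worst per-channel peak-to-peak amplitude."""
    p2p = epochs.data.max(axis=2) - epochs.data.min(axis=2)  # (trials, channels)
    return factor * float(np.median(p2p.max(axis=1)))


def reject_artifacts(
    epochs: EpochSet, p2p_threshold: float | None = None
) -> tuple[EpochSet, np.ndarray]:
    """Drop every trial in which any channel's peak-to-peak amplitude exceeds
    the threshold.  Returns (clean epochs, keep mask over input trials)."""
    if p2p_threshold is None:
        p2p_threshold = default_p2p_threshold(epochs)
    if p2p_threshold <= 0:
        raise InvalidArgumentError("p2p_threshold must be positive")
    p2p = epochs.data.max(axis=2) - epochs.data.min(axis=2)
    keep = (p2p <= p2p_threshold).all(axis=1)
    if not keep.any():
        raise EmptyResultError("artifact rejection removed every trial")
    return epochs.with_data(epochs.data[keep]), keep


def rereference_mastoid(epochs: EpochSet, montage: Montage) -> EpochSet:
    """Subtract the mean of the two mastoid channels from every channel."""
    if epochs.channel_labels and list(epochs.channel_labels) != list(montage.channel_labels):
        raise InvalidArgumentError("epoch channel order does not match the montage")
    if epochs.n_channels != montage.n_channels:
        raise InvalidArgumentError("channel count does not match the montage")
    i, j = montage.mastoid_indices
    ref = 0.5 * (epochs.data[:, i, :] + epochs.data[:, j, :])
    return epochs.with_data(epochs.data - ref[:, None, :])


def baseline_correct(
    epochs: EpochSet, baseline_window_ms: tuple[float, float] = (-200.0, 0.0)
) -> EpochSet:
    """Per trial and channel, subtract the mean over the baseline window
    (half-open ``[start, end)``; default is the full pre-stimulus segment)."""
    b0, b1 = baseline_window_ms
    if not (epochs.window_ms[0] <= b0 < b1 <= epochs.window_ms[1]):
        raise InvalidArgumentError(
            f"baseline {baseline_window_ms} must be a non-empty sub-window of {epochs.window_ms}"
        )
    lo, hi = epochs.sample_at(b0), epochs.sample_at(b1)
    if hi <= lo:
        raise InvalidArgumentError("baseline window contains no samples")
    mean = epochs.data[:, :, lo:hi].mean(axis=2, keepdims=True)
    return epochs.with_data(epochs.data - mean)


def average_erp(epochs: EpochSet) -> ERP:
    """Arithmetic mean across retained trials."""
    if epochs.n_trials < 1:
        raise EmptyResultError("cannot average zero trials")
    return ERP(
        data=epochs.data.mean(axis=0),
        fs=epochs.fs,
        window_ms=epochs.window_ms,
        n_trials_used=epochs.n_trials,
        channel_labels=list(epochs.channel_labels),
        subject_id=epochs.subject_id,
        group_label=epochs.group_label,
    )


@dataclass
class PreprocessResult:
    epochs: EpochSet
    erp: ERP
    keep_mask: np.ndarray
    n_dropped: int


def preprocess_epochs(
    epochs: EpochSet,
    montage: Montage,
    band: tuple[float, float] = (1.0, 20.0),
    baseline_window_ms: tuple[float, float] = (-200.0, 0.0),
    p2p_threshold: float | None = None,
) -> PreprocessResult:
    """Run the epoched part of the canonical chain on one subject:
    filter -> reject -> rereference -> baseline (+ the trial-average ERP)."""
    filtered = epochs.with_data(bandpass(epochs.data, epochs.fs, *band))
    clean, keep = reject_artifacts(filtered, p2p_threshold)
    reref = rereference_mastoid(clean, montage)
    corrected = baseline_correct(reref, baseline_window_ms)
    return PreprocessResult(
        epochs=corrected,
        erp=average_erp(corrected),
        keep_mask=keep,
        n_dropped=int((~keep).sum()),
    )
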