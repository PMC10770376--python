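"""In-memory containers for epoched EEG and trial-averaged ERPs.

The whole pipeline moves ``(trials, channels, samples)`` arrays around; these
dataclasses bind the array to its sampling rate, epoch window and subject
metadata, and enforce the shape invariants every stage relies on.

Group labels follow the convention 0 = patient (PD), 1 = healthy control.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np

from .errors import EmptyResultError, InvalidArgumentError

__all__ = ["EpochSet", "ERP", "write_cohort", "read_cohort"]


def _expected_samples(window_ms: tuple[float, float], fs: float) -> int:
    start, end = window_ms
    return int(round((end - start) * fs / 1000.0))


@dataclass
class EpochSet:
    """Epoched multi-trial EEG for one subject.

    data
        ``(n_trials, n_channels, n_samples)`` array, arbitrary (z-like) units.
    fs
        Sampling rate in Hz.
    window_ms
        ``(start, end)`` of the epoch relative to perturbation onset, in ms.
        The window is half-open ``[start, end)``; sample 0 sits at ``start``.
    channel_labels
        One label per channel, bound to a montage.
    group_label
        0 = PD, 1 = healthy control (None for unlabeled data).
    """

    data: np.ndarray
    fs: float
    window_ms: tuple[float, float]
    channel_labels: list[str] = field(default_factory=list)
    subject_id: str = ""
    group_label: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise InvalidArgumentError(
                f"data must be (trials, channels, samples), got shape {self.data.shape}"
            )
        start, end = self.window_ms
        if not (start < 0.0 < end):
            raise InvalidArgumentError(f"epoch window must straddle onset, got {self.window_ms}")
        n_expected = _expected_samples(self.window_ms, self.fs)
        if self.data.shape[2] != n_expected:
            raise InvalidArgumentError(
                f"window {self.window_ms} ms at fs={self.fs} implies {n_expected} samples, "
                f"data has {self.data.shape[2]}"
            )
        if self.channel_labels and len(self.channel_labels) != self.data.shape[1]:
            raise InvalidArgumentError("channel_labels length must match channel axis")
        if not np.isfinite(self.data).all():
            raise InvalidArgumentError("data contains non-finite values")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def times_ms(self) -> np.ndarray:
        """Per-sample time stamps in ms relative to onset."""
        start = self.window_ms[0]
        return start + np.arange(self.n_samples) * 1000.0 / self.fs

    def sample_at(self, t_ms: float) -> int:
        """Index of the first sample at or after ``t_ms``."""
        return int(np.ceil((t_ms - self.window_ms[0]) * self.fs / 1000.0 - 1e-9))

    def with_data(self, data: np.ndarray) -> "EpochSet":
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass
class ERP:
    """Trial-averaged evoked response: ``(n_channels, n_samples)``."""

    data: np.ndarray
    fs: float
    window_ms: tuple[float, float]
    n_trials_used: int
    channel_labels: list[str] = field(default_factory=list)
    subject_id: str = ""
    group_label: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidArgumentError("ERP data must be (channels, samples)")
        if self.n_trials_used < 1:
            raise EmptyResultError("an ERP requires at least one retained trial")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def times_ms(self) -> np.ndarray:
        return self.window_ms[0] + np.arange(self.n_samples) * 1000.0 / self.fs


def write_cohort(path: str | Path, epoch_sets: list[EpochSet]) -> None:
    """Write a cohort to HDF5 as ``/subjects/<id>/epochs`` plus attributes."""
    with h5py.File(path, "w") as f:
        subj = f.create_group("subjects")
        for es in epoch_sets:
            g = subj.create_group(es.subject_id)
            g.create_dataset("epochs", data=es.data)
            g.attrs["fs"] = es.fs
            g.attrs["window_ms"] = np.array(es.window_ms, dtype=float)
            g.attrs["group"] = -1 if es.group_label is None else int(es.group_label)
            g.attrs["channel_labels"] = [str(c) for c in es.channel_labels]


def read_cohort(path: str | Path) -> list[EpochSet]:
    out: list[EpochSet] = []
    with h5py.File(path, "r") as f:
        for sid in sorted(f["subjects"]):
            g = f["subjects"][sid]
            group = int(g.attrs["group"])
            out.append(
                EpochSet(
                    data=g["epochs"][()],
                    fs=float(g.attrs["fs"]),
                    window_ms=tuple(float(v) for v in g.attrs["window_ms"]),
                    channel_labels=[str(c) for c in g.attrs["channel_labels"]],
                    subject_id=sid,
                    group_label=None if group < 0 else group,
                )
            )
    return out
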