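"""Deterministic sensor-net montage.

Emulates a 64-channel geodesic sensor net: scalp channels E1..E(n-2) laid out
on the unit sphere by a Fibonacci spiral over the upper head surface, plus two
mastoid channels M1 (left) and M2 (right) below the temporal line.  Axes
follow the usual EEG convention: +x right, +y anterior, +z up.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import InvalidArgumentError

__all__ = [
    "Montage",
    "generate_montage",
    "spatial_weights",
    "LEFT_FRONTOTEMPORAL",
    "write_montage_csv",
    "read_montage_csv",
]

# Canonical direction of the left fronto-temporal scalp patch (between
# F7/FT7-like sites) used as the default center of the enhanced-P2 topography.
LEFT_FRONTOTEMPORAL = np.array([-0.80, 0.50, 0.33])
LEFT_FRONTOTEMPORAL = LEFT_FRONTOTEMPORAL / np.linalg.norm(LEFT_FRONTOTEMPORAL)

_GOLDEN = (1.0 + np.sqrt(5.0)) / 2.0


@dataclass(frozen=True)
class Montage:
    channel_labels: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3), unit norm
    mastoid_labels: tuple[str, str]

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(self.channel_labels), 3):
            raise InvalidArgumentError("positions must be (n_channels, 3)")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise InvalidArgumentError("channel labels must be unique")
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise InvalidArgumentError("positions must lie on the unit sphere")
        for m in self.mastoid_labels:
            if m not in self.channel_labels:
                raise InvalidArgumentError(f"mastoid label {m!r} not in channel_labels")
        object.__setattr__(self, "positions", pos)

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    def index(self, label: str) -> int:
        return self.channel_labels.index(label)

    @property
    def mastoid_indices(self) -> tuple[int, int]:
        return (self.index(self.mastoid_labels[0]), self.index(self.mastoid_labels[1]))


def generate_montage(n_channels: int = 64) -> Montage:
    """Build the deterministic montage with ``n_channels - 2`` scalp sites
    plus left/right mastoids.

    Pure function: the same ``n_channels`` always yields the same montage.
    """
    if n_channels < 4:
        raise InvalidArgumentError("a montage needs at least 4 channels (2 scalp + 2 mastoids)")
    n_scalp = n_channels - 2
    # Fibonacci spiral over z in [0.05, 1.0): covers vertex down to the
    # temporal line without colliding with the mastoid sites.
    i = np.arange(n_scalp)
    z = 1.0 - (i + 0.5) * (0.95 / n_scalp)
    phi = 2.0 * np.pi * i / _GOLDEN
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, 1.0))
    scalp = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    scalp /= np.linalg.norm(scalp, axis=1, keepdims=True)
    mastoids = np.array([[-0.87, -0.21, -0.45], [0.87, -0.21, -0.45]])
    mastoids /= np.linalg.norm(mastoids, axis=1, keepdims=True)
    labels = tuple(f"E{k + 1}" for k in range(n_scalp)) + ("M1", "M2")
    return Montage(
        channel_labels=labels,
        positions=np.vstack([scalp, mastoids]),
        mastoid_labels=("M1", "M2"),
    )


def spatial_weights(montage: Montage, center: np.ndarray, sigma: float = 0.6) -> np.ndarray:
    """Gaussian bump on the sensor sphere: exp(-|p - c|^2 / (2 sigma^2)).

    ``center`` is a unit direction; distance is chordal, which is monotone in
    great-circle distance and cheap.
    """
    c = np.asarray(center, dtype=float)
    c = c / np.linalg.norm(c)
    d2 = np.sum((montage.positions - c) ** 2, axis=1)
    return np.exp(-d2 / (2.0 * sigma**2))


def write_montage_csv(path: str | Path, montage: Montage) -> None:
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["label", "x", "y", "z", "is_mastoid"])
        for lab, pos in zip(montage.channel_labels, montage.positions):
            w.writerow([lab, f"{pos[0]:.10f}", f"{pos[1]:.10f}", f"{pos[2]:.10f}",
                        int(lab in montage.mastoid_labels)])


def read_montage_csv(path: str | Path) -> Montage:
    labels: list[str] = []
    pos: list[list[float]] = []
    mastoids: list[str] = []
    with open(path, newline="") as f:
        for row in csv.DictReader(f):
            labels.append(row["label"])
            pos.append([float(row["x"]), float(row["y"]), float(row["z"])])
            if int(row["is_mastoid"]):
                mastoids.append(row["label"])
    if len(mastoids) != 2:
        raise InvalidArgumentError("montage file must designate exactly two mastoids")
    return Montage(tuple(labels), np.asarray(pos), (mastoids[0], mastoids[1]))
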