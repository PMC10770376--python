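"""Synthetic two-group voice-perturbation ERP cohorts.

The generator emulates the statistical structure the classification pipeline
assumes in event-related EEG from a frequency-altered-feedback task: a
P1-N1-P2 evoked sequence with spatially smooth component topographies, a
group-enhanced P2 over left fronto-temporal electrodes in the patient group,
1/f background noise with alpha-band (10 Hz) oscillation, and (optionally)
occasional high-amplitude artifact trials.

Units are arbitrary z-like amplitudes; no microvolt calibration is attempted.
All randomness flows from ``CohortConfig.seed`` so identical configurations
produce bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import EpochSet
from .errors import InvalidArgumentError
from .montage import LEFT_FRONTOTEMPORAL, Montage, spatial_weights

__all__ = ["ErpComponent", "CohortConfig", "simulate_cohort", "inject_artifacts",
           "p2_target_channels"]

# Component latencies: P1 = 80 ms, N1 = 150 ms, P2 = 260 ms; the P2 sits in
# the 205-315 ms window where the patient-group enhancement is expressed.
_VERTEX_FRONTAL = np.array([0.0, 0.4, 0.9165151389911680])
_CENTRAL = np.array([0.0, 0.2, 0.9797958971132712])


@dataclass(frozen=True)
class ErpComponent:
    """One evoked component: a temporal Gaussian times a scalp topography."""

    name: str
    latency_ms: float
    width_ms: float
    amplitude: float
    center: np.ndarray  # unit direction of the topography peak
    sigma: float = 0.6


def _default_components(p2_latency_ms: float) -> tuple[ErpComponent, ...]:
    return (
        ErpComponent("P1", 80.0, 15.0, 1.0, _VERTEX_FRONTAL),
        ErpComponent("N1", 150.0, 20.0, -1.5, _CENTRAL),
        ErpComponent("P2", p2_latency_ms, 40.0, 1.2, LEFT_FRONTOTEMPORAL, sigma=0.5),
    )


@dataclass
class CohortConfig:
    """Study conditions for one simulated cohort.

    p2_effect multiplies the P2 amplitude in the patient (PD) group only;
    1.0 is the null condition (groups identically distributed).
    """

    n_subjects_per_group: int = 20
    n_trials: int = 100
    fs: float = 1000.0
    epoch_window_ms: tuple[float, float] = (-200.0, 500.0)
    p2_latency_ms: float = 260.0
    p2_effect: float = 2.5
    noise_scale: float = 1.0
    alpha_amplitude: float = 0.5
    amp_jitter: float = 0.1
    latency_jitter_ms: float = 0.0
    artifact_rate: float = 0.0
    artifact_amplitude: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects_per_group < 1 or self.n_trials < 1:
            raise InvalidArgumentError("cohort needs >= 1 subject per group and >= 1 trial")
        if self.p2_effect <= 0:
            raise InvalidArgumentError("p2_effect must be positive")
        if not (0.0 <= self.artifact_rate < 1.0):
            raise InvalidArgumentError("artifact_rate must be in [0, 1)")
        if self.noise_scale < 0:
            raise InvalidArgumentError("noise_scale must be non-negative")
        start, end = self.epoch_window_ms
        if not (start < 0.0 < end):
            raise InvalidArgumentError("epoch window must straddle the perturbation onset")

    @property
    def n_samples(self) -> int:
        start, end = self.epoch_window_ms
        return int(round((end - start) * self.fs / 1000.0))


def p2_target_channels(montage: Montage, n_top: int = 3, sigma: float = 0.5) -> list[int]:
    """Channel indices carrying the strongest planted P2 loading.

    The ground truth the saliency analysis is expected to recover.
    """
    w = spatial_weights(montage, LEFT_FRONTOTEMPORAL, sigma=sigma)
    return list(np.argsort(-w)[:n_top])


def _pink_noise(rng: np.random.Generator, n_series: int, n_samples: int, fs: float) -> np.ndarray:
    """Unit-variance 1/f noise via spectral shaping of white noise."""
    white = rng.standard_normal((n_series, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shaping = np.zeros_like(freqs)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])
    pink = np.fft.irfft(spec * shaping, n=n_samples, axis=-1)
    sd = pink.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return pink / sd


def _spatial_mixer(montage: Montage, length_scale: float = 0.5) -> np.ndarray:
    """Row-normalized channel-mixing kernel giving spatially smooth noise."""
    d2 = np.sum(
        (montage.positions[:, None, :] - montage.positions[None, :, :]) ** 2, axis=-1
    )
    k = np.exp(-d2 / (2.0 * length_scale**2))
    # preserve per-channel variance approximately
    return k / np.sqrt(np.sum(k**2, axis=1, keepdims=True))


def _component_template(
    cfg: CohortConfig, montage: Montage, comp: ErpComponent
) -> tuple[np.ndarray, np.ndarray]:
    """(topography over channels, temporal Gaussian over samples)."""
    topo = comp.amplitude * spatial_weights(montage, comp.center, comp.sigma)
    t_ms = cfg.epoch_window_ms[0] + np.arange(cfg.n_samples) * 1000.0 / cfg.fs
    wave = np.exp(-((t_ms - comp.latency_ms) ** 2) / (2.0 * comp.width_ms**2))
    return topo, wave


def simulate_cohort(
    cfg: CohortConfig, montage: Montage
) -> tuple[list[EpochSet], np.ndarray]:
    """Simulate both groups; returns (epoch sets, group labels).

    Group 0 (PD) receives ``cfg.p2_effect`` times the P2 amplitude; group 1
    (healthy controls) receives the baseline amplitude.
    """
    components = _default_components(cfg.p2_latency_ms)
    templates = [_component_template(cfg, montage, c) for c in components]
    alpha_topo = spatial_weights(montage, np.array([0.0, -0.6, 0.8]), sigma=0.7)
    mixer = _spatial_mixer(montage)
    n_ch, n_s = montage.n_channels, cfg.n_samples
    t = np.arange(n_s) / cfg.fs

    root = np.random.SeedSequence(cfg.seed)
    epoch_sets: list[EpochSet] = []
    labels: list[int] = []
    subject_seeds = root.spawn(2 * cfg.n_subjects_per_group)
    idx = 0
    for group, prefix in ((0, "pd"), (1, "hc")):
        for s in range(cfg.n_subjects_per_group):
            rng = np.random.default_rng(subject_seeds[idx])
            idx += 1
            data = np.zeros((cfg.n_trials, n_ch, n_s))
            for comp, (topo, wave) in zip(components, templates):
                scale = cfg.p2_effect if (comp.name == "P2" and group == 0) else 1.0
                amp = scale * np.maximum(
                    rng.normal(1.0, cfg.amp_jitter, size=cfg.n_trials), 0.0
                )
                if cfg.latency_jitter_ms > 0:
                    shift = rng.normal(0.0, cfg.latency_jitter_ms, size=cfg.n_trials)
                    t_ms = cfg.epoch_window_ms[0] + np.arange(n_s) * 1000.0 / cfg.fs
                    waves = np.exp(
                        -((t_ms[None, :] - comp.latency_ms - shift[:, None]) ** 2)
                        / (2.0 * comp.width_ms**2)
                    )
                else:
                    waves = np.broadcast_to(wave, (cfg.n_trials, n_s))
                data += amp[:, None, None] * topo[None, :, None] * waves[:, None, :]
            if cfg.noise_scale > 0:
                pink = _pink_noise(rng, cfg.n_trials * n_ch, n_s, cfg.fs)
                pink = pink.reshape(cfg.n_trials, n_ch, n_s)
                pink = np.einsum("cd,tds->tcs", mixer, pink)
                phase = rng.uniform(0.0, 2.0 * np.pi, size=cfg.n_trials)
                alpha = np.sin(2.0 * np.pi * 10.0 * t[None, :] + phase[:, None])
                data += cfg.noise_scale * pink
                data += (
                    cfg.noise_scale
                    * cfg.alpha_amplitude
                    * alpha_topo[None, :, None]
                    * alpha[:, None, :]
                )
            es = EpochSet(
                data=data,
                fs=cfg.fs,
                window_ms=cfg.epoch_window_ms,
                channel_labels=list(montage.channel_labels),
                subject_id=f"{prefix}{s + 1:03d}",
                group_label=group,
            )
            if cfg.artifact_rate > 0:
                es, _ = inject_artifacts(
                    es,
                    rate=cfg.artifact_rate,
                    amplitude=cfg.artifact_amplitude * max(cfg.noise_scale, 1e-12),
                    seed=int(rng.integers(2**31)),
                )
            epoch_sets.append(es)
            labels.append(group)
    return epoch_sets, np.asarray(labels)


def inject_artifacts(
    epochs: EpochSet, rate: float, amplitude: float, seed: int
) -> tuple[EpochSet, np.ndarray]:
    """Add step-plus-drift artifacts to a random subset of trials.

    Returns the contaminated epochs and a boolean ground-truth mask (True =
    trial was contaminated).  ``rate=0`` returns the input unchanged.
    """
    if not (0.0 <= rate < 1.0):
        raise InvalidArgumentError("rate must be in [0, 1)")
    if amplitude <= 0:
        raise InvalidArgumentError("artifact amplitude must be positive")
    rng = np.random.default_rng(seed)
    mask = rng.random(epochs.n_trials) < rate
    if not mask.any():
        return epochs.with_data(epochs.data.copy()), mask
    data = epochs.data.copy()
    n_s = epochs.n_samples
    for trial in np.flatnonzero(mask):
        n_bad = max(1, epochs.n_channels // 4)
        bad_channels = rng.choice(epochs.n_channels, size=n_bad, replace=False)
        onset = int(rng.integers(n_s // 4, 3 * n_s // 4))
        step = np.zeros(n_s)
        step[onset:] = amplitude
        drift = amplitude * np.arange(n_s) / n_s
        data[trial, bad_channels, :] += step + drift
    return epochs.with_data(data), mask
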