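"""ERP microstate analysis.

Global field power (GFP) is the per-sample standard deviation of the scalp
topography.  Topographies at GFP local maxima are unit-normalised and
clustered with polarity-SENSITIVE k-means (ERP components carry meaningful
polarity, unlike resting-state maps, so no sign folding is applied).  The
number of states is selected by the Krzanowski-Lai criterion

    DIFF(k) = (k-1)^{2/p} W_{k-1} - k^{2/p} W_k,   KL(k) = |DIFF(k)| / |DIFF(k+1)|,

where W_k is the within-cluster dispersion and p the map dimension; the
scanned k maximising KL(k) is chosen.  Segmentation back-fits the templates
by maximal spatial correlation, merging runs shorter than a minimum duration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from sklearn.cluster import KMeans

from .containers import ERP
from .errors import InvalidArgumentError

__all__ = [
    "gfp",
    "gfp_peak_maps",
    "cluster_topographies",
    "segment",
    "transition_summary",
    "MicrostateResult",
    "microstate_analysis",
]


def gfp(erp: ERP | np.ndarray) -> np.ndarray:
    """Global field power: per-sample population sd across channels."""
    data = erp.data if isinstance(erp, ERP) else np.asarray(erp, float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise InvalidArgumentError("GFP needs a (channels >= 2, samples) array")
    return data.std(axis=0)


def gfp_peak_maps(erp: ERP | np.ndarray) -> np.ndarray:
    """Unit-normalised topographies at GFP local maxima, (n_peaks, n_channels)."""
    data = erp.data if isinstance(erp, ERP) else np.asarray(erp, float)
    g = gfp(data)
    peaks, _ = find_peaks(g)
    if len(peaks) == 0:  # flat or monotone GFP: fall back to the global max
        peaks = np.array([int(np.argmax(g))])
    maps = data[:, peaks].T
    norms = np.linalg.norm(maps, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return maps / norms


def _dispersion(maps: np.ndarray, labels: np.ndarray, centers: np.ndarray) -> float:
    return float(np.sum((maps - centers[labels]) ** 2))


def cluster_topographies(
    maps: np.ndarray,
    k_range: tuple[int, int] = (2, 10),
    n_init: int = 50,
    seed: int = 0,
) -> tuple[dict[int, np.ndarray], np.ndarray, int]:
    """Polarity-sensitive k-means over unit maps plus Krzanowski-Lai selection.

    Returns (templates per k, KL curve aligned with the scanned ks, chosen k).
    Templates are unit-normalised centroids.  If there are fewer maps than
    the largest candidate k, the range shrinks with a warning.
    """
    maps = np.asarray(maps, float)
    kmin, kmax = k_range
    if kmin < 2:
        raise InvalidArgumentError("k-range must start at 2 (the KL criterion needs neighbours)")
    n_maps, p = maps.shape
    if n_maps <= kmax + 1:
        kmax = max(kmin, n_maps - 2)
        warnings.warn(f"fewer maps than candidate clusters: shrinking k-range to (2, {kmax})")
    # dispersion for k in [kmin-1, kmax+1] so KL(k) exists at the range edges
    disp: dict[int, float] = {}
    templates: dict[int, np.ndarray] = {}
    for k in range(max(1, kmin - 1), kmax + 2):
        if k == 1:
            center = maps.mean(axis=0, keepdims=True)
            disp[1] = _dispersion(maps, np.zeros(n_maps, int), center)
            continue
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(maps)
        disp[k] = float(km.inertia_)
        cents = km.cluster_centers_
        norms = np.linalg.norm(cents, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        templates[k] = cents / norms
    expo = 2.0 / p
    diff = {
        k: (k - 1) ** expo * disp[k - 1] - k**expo * disp[k]
        for k in range(kmin, kmax + 2)
        if (k - 1) in disp and k in disp
    }
    ks = np.arange(kmin, kmax + 1)
    kl = np.array(
        [
            abs(diff[k]) / abs(diff[k + 1]) if abs(diff.get(k + 1, 0.0)) > 1e-30 else 0.0
            for k in ks
        ]
    )
    chosen = int(ks[int(np.argmax(kl))])
    return templates, kl, chosen


def _spatial_corr(maps: np.ndarray, templates: np.ndarray) -> np.ndarray:
    """Signed Pearson correlation (across channels) between each sample map
    and each template: (n_samples, k)."""
    X = maps - maps.mean(axis=1, keepdims=True)
    T = templates - templates.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(X, axis=1, keepdims=True)
    tn = np.linalg.norm(T, axis=1, keepdims=True)
    xn[xn == 0] = 1.0
    tn[tn == 0] = 1.0
    return (X / xn) @ (T / tn).T


def segment(
    erp: ERP | np.ndarray,
    templates: np.ndarray,
    fs: float | None = None,
    min_duration_ms: float = 10.0,
) -> tuple[np.ndarray, dict[int, float]]:
    """Label every sample with the best-correlating template.

    Runs shorter than ``min_duration_ms`` are merged into the neighbouring
    state with the higher mean correlation over the run.  Returns the label
    sequence and each state's time coverage fraction.
    """
    if isinstance(erp, ERP):
        data, fs = erp.data, erp.fs
    else:
        data = np.asarray(erp, float)
        if fs is None:
            raise InvalidArgumentError("fs is required when passing a bare array")
    corr = _spatial_corr(data.T, np.asarray(templates, float))
    labels = corr.argmax(axis=1)
    min_len = max(1, int(round(min_duration_ms * fs / 1000.0)))
    labels = _merge_short_runs(labels, corr, min_len)
    coverage = {
        int(s): float((labels == s).mean()) for s in range(templates.shape[0])
    }
    return labels, coverage


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """(state, start, stop) runs; stop exclusive."""
    out = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append((int(labels[start]), start, i))
            start = i
    return out


def _merge_short_runs(labels: np.ndarray, corr: np.ndarray, min_len: int) -> np.ndarray:
    labels = labels.copy()
    while True:
        runs = _runs(labels)
        if len(runs) == 1:
            return labels
        short = [
            (stop - start, idx)
            for idx, (_, start, stop) in enumerate(runs)
            if stop - start < min_len
        ]
        if not short:
            return labels
        _, idx = min(short)
        state, start, stop = runs[idx]
        candidates = []
        if idx > 0:
            candidates.append(runs[idx - 1][0])
        if idx < len(runs) - 1:
            candidates.append(runs[idx + 1][0])
        best = max(candidates, key=lambda s: corr[start:stop, s].mean())
        labels[start:stop] = best
    return labels


def transition_summary(
    labels: np.ndarray, times_ms: np.ndarray | None = None
) -> list[tuple[int, int, float]]:
    """Ordered (from_state, to_state, time) tuples at every label switch."""
    labels = np.asarray(labels)
    if times_ms is None:
        times_ms = np.arange(len(labels), dtype=float)
    switches = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    return [
        (int(labels[i - 1]), int(labels[i]), float(times_ms[i])) for i in switches
    ]


@dataclass
class MicrostateResult:
    templates: np.ndarray  # (k, channels), unit norm
    labels_per_erp: list[np.ndarray]
    coverage_per_erp: list[dict[int, float]]
    gfp_per_erp: list[np.ndarray]
    kl_curve: np.ndarray
    chosen_k: int
    transitions_per_erp: list[list[tuple[int, int, float]]] = field(default_factory=list)


def microstate_analysis(
    erps: list[ERP],
    k_range: tuple[int, int] = (2, 10),
    n_init: int = 50,
    seed: int = 0,
    min_duration_ms: float = 10.0,
) -> MicrostateResult:
    """Group-level analysis: cluster the pooled GFP-peak maps of the supplied
    (typically group-grand-average) ERPs jointly, then back-fit each ERP."""
    if not erps:
        raise InvalidArgumentError("need at least one ERP")
    maps = np.vstack([gfp_peak_maps(e) for e in erps])
    templates_by_k, kl, chosen = cluster_topographies(maps, k_range, n_init, seed)
    templates = templates_by_k[chosen]
    labels_list, cov_list, gfp_list, trans_list = [], [], [], []
    for e in erps:
        labels, cov = segment(e, templates, min_duration_ms=min_duration_ms)
        labels_list.append(labels)
        cov_list.append(cov)
        gfp_list.append(gfp(e))
        trans_list.append(transition_summary(labels, e.times_ms()))
    return MicrostateResult(
        templates=templates,
        labels_per_erp=labels_list,
        coverage_per_erp=cov_list,
        gfp_per_erp=gfp_list,
        kl_curve=kl,
        chosen_k=chosen,
        transitions_per_erp=trans_list,
    )
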