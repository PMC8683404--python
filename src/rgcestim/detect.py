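"""Spike detection and simplified unit separation for raw MEA traces.

The chain mirrors the standard extracellular workflow: zero-phase 100 Hz
high-pass, noise SD estimation, threshold crossing at a multiple of the
noise SD (4x by default), snippet extraction, then PCA + k-means to split
multiunit activity.  The default noise estimator is the robust MAD
(median absolute deviation / 0.6745) because the plain sample SD is biased
upward by the spikes themselves; plain mode is retained and the choice is
recorded on the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

log = logging.getLogger("rgcestim")

#: Minimum silhouette score at which a multi-cluster split is accepted;
#: below it a single unit is declared.
SILHOUETTE_MIN = 0.5

#: Snippet window around the spike trough: 0.6 ms pre, 1.0 ms post.
SNIPPET_PRE_S = 0.6e-3
SNIPPET_POST_S = 1.0e-3


class DegenerateTraceError(ValueError):
    """The trace has zero noise SD; thresholding is undefined."""


def highpass(trace: np.ndarray, cutoff: float, sampling_rate: float) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth high-pass filter.

    Zero-phase filtering preserves spike timing; DC and slow drift are
    removed.  Output length equals input length.
    """
    nyquist = sampling_rate / 2.0
    if cutoff >= nyquist:
        raise ValueError(
            f"cutoff {cutoff} Hz must be below the Nyquist frequency {nyquist} Hz"
        )
    sos = butter(4, cutoff, btype="highpass", fs=sampling_rate, output="sos")
    return sosfiltfilt(sos, np.asarray(trace, dtype=float))


def estimate_noise_sd(trace: np.ndarray, method: str = "mad") -> float:
    """Background-noise SD in the trace's units (uV).

    "plain" is the sample standard deviation; "mad" is the robust estimate
    median(|x|) / 0.6745, which large spikes barely perturb.
    """
    x = np.asarray(trace, dtype=float)
    if x.size < 1000:
        raise ValueError("need at least 1000 samples to estimate noise SD")
    if method == "plain":
        return float(np.std(x))
    if method == "mad":
        return float(np.median(np.abs(x)) / 0.6745)
    raise ValueError(f"unknown noise method {method!r}")


@dataclass
class DetectionResult:
    channel_id: int
    spike_sample_indices: np.ndarray
    waveforms: np.ndarray  # (n_events, snippet_len)
    noise_sd_estimate: float
    threshold_used: float  # signed; |threshold| = sd_multiple * noise_sd
    sampling_rate: float
    noise_method: str = "mad"

    @property
    def spike_times(self) -> np.ndarray:
        return self.spike_sample_indices / self.sampling_rate


def _crossing_extrema(x: np.ndarray, threshold: float, polarity: str) -> np.ndarray:
    """Index of the extremal sample within each suprathreshold run."""
    if polarity == "neg":
        below = x < -abs(threshold)
        depth = -x
    elif polarity == "both":
        below = np.abs(x) > abs(threshold)
        depth = np.abs(x)
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    if not below.any():
        return np.empty(0, dtype=np.int64)
    padded = np.concatenate([[False], below, [False]])
    d = np.diff(padded.astype(np.int8))
    run_starts = np.flatnonzero(d == 1)
    run_ends = np.flatnonzero(d == -1)  # exclusive
    peaks = [s + int(np.argmax(depth[s:e])) for s, e in zip(run_starts, run_ends)]
    return np.asarray(peaks, dtype=np.int64)


def _apply_refractory(
    peaks: np.ndarray, depth: np.ndarray, refractory_samples: int
) -> np.ndarray:
    """Keep only the most extreme event within each refractory window."""
    if peaks.size == 0:
        return peaks
    kept: list[int] = [int(peaks[0])]
    for p in peaks[1:]:
        if p - kept[-1] < refractory_samples:
            if depth[p] > depth[kept[-1]]:
                kept[-1] = int(p)
        else:
            kept.append(int(p))
    return np.asarray(kept, dtype=np.int64)


def detect(
    filtered_trace: np.ndarray,
    sampling_rate: float,
    sd_multiple: float = 4.0,
    refractory: float = 1e-3,
    polarity: str = "neg",
    noise_method: str = "mad",
    channel_id: int = 0,
) -> DetectionResult:
    """Threshold-crossing spike detection on a filtered trace.

    The threshold is sd_multiple times the estimated noise SD; by default
    only negative-going crossings are detected (extracellular somatic spikes
    are negative-first).  Within each refractory window only the extremal
    crossing is kept.  Fixed-length snippets are extracted around each
    event; events too close to the trace edges for a full snippet are
    dropped.
    """
    x = np.asarray(filtered_trace, dtype=float)
    noise_sd = estimate_noise_sd(x, method=noise_method)
    if noise_sd == 0.0:
        raise DegenerateTraceError("degenerate trace: noise SD is zero")
    threshold = sd_multiple * noise_sd
    peaks = _crossing_extrema(x, threshold, polarity)
    depth = -x if polarity == "neg" else np.abs(x)
    peaks = _apply_refractory(peaks, depth, int(round(refractory * sampling_rate)))
    pre = int(round(SNIPPET_PRE_S * sampling_rate))
    post = int(round(SNIPPET_POST_S * sampling_rate))
    keep = (peaks >= pre) & (peaks + post <= x.size)
    peaks = peaks[keep]
    waveforms = (
        np.stack([x[p - pre : p + post] for p in peaks])
        if peaks.size
        else np.empty((0, pre + post))
    )
    return DetectionResult(
        channel_id=channel_id,
        spike_sample_indices=peaks,
        waveforms=waveforms,
        noise_sd_estimate=noise_sd,
        threshold_used=-threshold if polarity == "neg" else threshold,
        sampling_rate=sampling_rate,
        noise_method=noise_method,
    )


def sort_units(
    waveforms: np.ndarray, max_units: int = 3, seed: int = 0
) -> np.ndarray:
    """Separate multiunit snippets into units by PCA + k-means.

    Snippets are projected onto the first two principal components and
    clustered with k-means for k = 1..max_units; k is chosen by silhouette
    score, falling back to a single unit when no split scores at least
    SILHOUETTE_MIN.  Deterministic given the seed.
    """
    w = np.asarray(waveforms, dtype=float)
    n = w.shape[0]
    if n < max(10, max_units):
        log.warning("too few events (%d) for unit separation; labelling unit 0", n)
        return np.zeros(n, dtype=int)
    n_comp = min(2, w.shape[1])
    scores = PCA(n_components=n_comp, random_state=seed).fit_transform(w)
    best_k, best_score, best_labels = 1, -1.0, np.zeros(n, dtype=int)
    for k in range(2, max_units + 1):
        if k >= n:
            break
        labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(
            scores
        )
        if len(np.unique(labels)) < 2:
            continue
        s = silhouette_score(scores, labels)
        if s > best_score:
            best_k, best_score, best_labels = k, s, labels
    if best_k == 1 or best_score < SILHOUETTE_MIN:
        return np.zeros(n, dtype=int)
    return best_labels
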