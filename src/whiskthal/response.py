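"""Event-aligned response quantification.

PSTHs are built in 1-ms bins relative to deflection onset and converted to
rate by dividing by bin width and trial count.  For display they are
normalized by the mean rate in the 25 ms before the deflection (log2
scale).  Responsiveness is tested by a Wilcoxon signed-rank test over
per-trial spike counts in paired 50-ms windows before/after onset
(one-sided for puffs, two-sided for touches); the modulation index is
(post - pre)/(post + pre).  First-spike latency is measured within a 75-ms
post-onset window.  Population PSTHs are converted to spike probability
per neuron, averaged, and smoothed with a Gaussian over a 10-ms window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "PSTH",
    "ResponseStats",
    "compute_psth",
    "normalize_psth",
    "response_test",
    "modulation_index",
    "first_spike_latency",
    "population_psth",
    "trial_counts",
]

DEFAULT_WINDOW = (-0.025, 0.075)   # s, display default
DEFAULT_BINWIDTH = 0.001           # s
RESPONSE_WINDOW = 0.050            # s pre and post for rates / MI
NORM_PRE_WINDOW = 0.025            # s for PSTH normalization
LATENCY_HORIZON = 0.075            # s


@dataclass
class PSTH:
    bin_edges: np.ndarray   # s relative to onset
    counts: np.ndarray
    n_trials: int

    @property
    def binwidth(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def rate(self) -> np.ndarray:
        return self.counts / (self.n_trials * self.binwidth)


@dataclass
class ResponseStats:
    baseline_rate: float
    response_rate: float
    mi: float
    p_value: float
    sidedness: str
    n_events: int
    latency_mean_ms: Optional[float] = None
    latency_sd_ms: Optional[float] = None
    flags: list = field(default_factory=list)


def compute_psth(spike_times, onsets, window=DEFAULT_WINDOW,
                 binwidth: float = DEFAULT_BINWIDTH) -> PSTH:
    """Spike counts in half-open 1-ms bins aligned to event onsets."""
    spike_times = np.asarray(spike_times, float)
    onsets = np.asarray(onsets, float)
    if onsets.size == 0:
        raise ValueError("compute_psth requires at least one onset")
    edges = np.arange(window[0], window[1] + 0.5 * binwidth, binwidth)
    rel = []
    for on in onsets:
        i0 = np.searchsorted(spike_times, on + edges[0], side="left")
        i1 = np.searchsorted(spike_times, on + edges[-1], side="left")
        rel.append(spike_times[i0:i1] - on)
    rel = np.concatenate(rel) if rel else np.empty(0)
    counts, _ = np.histogram(rel, bins=edges)
    return PSTH(bin_edges=edges, counts=counts, n_trials=int(onsets.size))


def normalize_psth(psth: PSTH, pre_window: float = NORM_PRE_WINDOW):
    """Divide by the mean rate in the ``pre_window`` before onset.

    Returns (norm_rate, flag); with a zero pre-onset rate the normalization
    is undefined and flagged (norm_rate None) -- the neuron is then shown
    unnormalized.  log2 of norm_rate is the display scale.
    """
    centers = psth.bin_centers
    if psth.bin_edges[0] > -pre_window + 1e-9:
        raise ValueError("PSTH window too short for the normalization pre-window")
    pre = (centers >= -pre_window) & (centers < 0)
    pre_mean = psth.rate[pre].mean()
    if pre_mean == 0:
        return None, "zero_baseline"
    return psth.rate / pre_mean, None


def trial_counts(spike_times, onsets, pre: float = RESPONSE_WINDOW,
                 post: float = RESPONSE_WINDOW) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial spike counts in [-pre, 0) and [0, post) around each onset."""
    spike_times = np.asarray(spike_times, float)
    onsets = np.asarray(onsets, float)
    lo = np.searchsorted(spike_times, onsets - pre, side="left")
    mid = np.searchsorted(spike_times, onsets, side="left")
    hi = np.searchsorted(spike_times, onsets + post, side="left")
    return (mid - lo).astype(float), (hi - mid).astype(float)


def _wilcoxon(post, pre, alternative: str) -> float:
    """Signed-rank p with zero differences dropped; exact for small n."""
    diffs = np.asarray(post) - np.asarray(pre)
    diffs = diffs[diffs != 0]
    if diffs.size == 0:
        return 1.0
    try:
        res = stats.wilcoxon(diffs, zero_method="wilcox", alternative=alternative,
                             correction=True, method="auto")
    except ValueError:
        return 1.0
    return float(res.pvalue)


def response_test(spike_times, onsets, *, pre: float = RESPONSE_WINDOW,
                  post: float = RESPONSE_WINDOW,
                  sidedness: str = "greater") -> ResponseStats:
    """Wilcoxon signed-rank test of per-trial pre/post spike counts.

    ``sidedness`` is 'greater' for puff responsiveness (rate increase only,
    to include only neurons aligned to the stimulated whisker) or
    'two-sided' for touch responses.
    """
    onsets = np.asarray(onsets, float)
    if onsets.size < 2:
        raise ValueError("response_test requires at least 2 events")
    pre_counts, post_counts = trial_counts(spike_times, onsets, pre, post)
    flags = []
    if np.all(post_counts - pre_counts == 0):
        flags.append("all_zero_differences")
    p = _wilcoxon(post_counts, pre_counts, sidedness)
    baseline = pre_counts.sum() / (onsets.size * pre)
    resp = post_counts.sum() / (onsets.size * post)
    return ResponseStats(
        baseline_rate=float(baseline), response_rate=float(resp),
        mi=modulation_index(baseline, resp), p_value=p, sidedness=sidedness,
        n_events=int(onsets.size), flags=flags,
    )


def modulation_index(pre_rate: float, post_rate: float) -> float:
    """(post - pre)/(post + pre); MI(0, 0) = 0 by convention."""
    if pre_rate < 0 or post_rate < 0:
        raise ValueError("rates must be non-negative")
    total = pre_rate + post_rate
    if total == 0:
        return 0.0
    return float((post_rate - pre_rate) / total)


def first_spike_latency(spike_times, onsets, horizon: float = LATENCY_HORIZON):
    """Per-trial first-spike latency within ``horizon`` after onset.

    Trials with no spike in the horizon are excluded (first-spike, not
    censored-time, statistics).  Returns (mean_ms, sd_ms, latencies_ms);
    all None/empty when no trial has a spike.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    spike_times = np.asarray(spike_times, float)
    onsets = np.asarray(onsets, float)
    if onsets.size == 0:
        raise ValueError("first_spike_latency requires at least one onset")
    idx = np.searchsorted(spike_times, onsets, side="right")
    lat = []
    for on, i in zip(onsets, idx):
        if i < spike_times.size and spike_times[i] - on <= horizon:
            lat.append((spike_times[i] - on) * 1000.0)
    if not lat:
        return None, None, np.empty(0)
    lat = np.asarray(lat)
    return float(lat.mean()), float(lat.std(ddof=1)) if lat.size > 1 else 0.0, lat


def population_psth(psths: Sequence[PSTH], smooth_window: float = 0.010,
                    *, window_is_sd: bool = False) -> np.ndarray:
    """Mean spike-probability trace across neurons, Gaussian smoothed.

    Each PSTH is converted to spike probability by dividing by its total
    spike count (zero-spike PSTHs are excluded with a warning).  The
    population mean is smoothed with a Gaussian kernel; "over a 10 ms
    window" is interpreted as a kernel spanning the window at +-2 s.d.
    (s.d. = window/4) unless ``window_is_sd``.  Total probability is
    preserved exactly by renormalizing after the reflected-edge smoothing.
    """
    probs = []
    for p in psths:
        total = p.counts.sum()
        if total == 0:
            warnings.warn("zero-spike PSTH excluded from population average")
            continue
        probs.append(p.counts / total)
    if not probs:
        raise ValueError("population_psth requires at least one PSTH with spikes")
    mean = np.mean(probs, axis=0)
    binwidth = psths[0].binwidth
    sd_s = smooth_window if window_is_sd else smooth_window / 4.0
    smoothed = gaussian_filter1d(mean, sd_s / binwidth, mode="reflect", truncate=2.0)
    total = mean.sum()
    if smoothed.sum() > 0:
        smoothed *= total / smoothed.sum()
    return smoothed
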