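"""Whisking-state rates, shuffle null, amplitude tuning and phase locking.

Firing rates during whisking vs. quiescence are computed over *steady
state* time only: the 50-ms period around each state transition, 500 ms
around every whisker deflection, and (for laser-off assignment) the laser
transitions are excluded, and the residual time is stratified by
(state x laser).  Rate differences are deemed significant when the
observed rate falls outside the 95% confidence interval of a 10,000-fold
spike-time shuffle null built from circular time shifts (preserving the
ISI structure of the train).

During whisking, spike rates are analyzed in 5-degree whisking-amplitude
bins (Pearson correlation, t-distribution p), and whisk-phase tuning is
quantified in 16 occupancy-normalized phase bins fitted by least squares
with f = <Rate> + Amp * cos(phase - phase_pref).  The tuning
signal-to-noise ratio is SNR = (2 * Amp / <Rate>) * sqrt(<Rate> * T) with
T one mean whisk-cycle duration (0.111 s).  Significance of phase locking
is a circular Kuiper test of the spike-phase distribution against the
*occupancy* distribution, so tuning is tested beyond mere phase occupancy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .whisking import WhiskingTrace, STATE_WHISKING

__all__ = [
    "StateRates",
    "PhaseTuning",
    "steady_state_mask",
    "state_rates",
    "shuffle_test",
    "rate_vs_amplitude",
    "phase_tuning",
    "kuiper_test",
    "tuning_snr",
]

TRANSITION_PAD_S = 0.025
EVENT_PAD_S = 0.5
N_SHUFFLES = 10_000
N_PHASE_BINS = 16
CYCLE_T_S = 0.111
AMP_BIN_DEG = 5.0


@dataclass
class StateRates:
    rates: dict                      # stratum -> Hz (None if stratum absent)
    durations: dict                  # stratum -> s
    shuffle_ci: dict = field(default_factory=dict)   # stratum -> (lo, hi)
    significant: dict = field(default_factory=dict)  # stratum -> bool


@dataclass
class PhaseTuning:
    bin_centers: np.ndarray   # rad, 16 bins over (-pi, pi]
    occupancy: np.ndarray     # s per bin
    rates: np.ndarray         # Hz per bin
    fit_mean: float           # <Rate>, Hz
    fit_amp: float            # Amp_Tuning, Hz (>= 0)
    fit_phase: float          # preferred phase, rad
    snr: float
    kuiper_v: float
    kuiper_p: float
    n_spikes: int
    T_window: float = CYCLE_T_S
    flags: list = field(default_factory=list)


# ---------------------------------------------------------------------- #
# steady-state strata
# ---------------------------------------------------------------------- #

def _mask_out(time: np.ndarray, mask: np.ndarray, centers, pad: float) -> None:
    for c in np.atleast_1d(np.asarray(centers, float)):
        i0 = np.searchsorted(time, c - pad, side="left")
        i1 = np.searchsorted(time, c + pad, side="right")
        mask[i0:i1] = False


def steady_state_mask(
    trace: WhiskingTrace,
    deflection_onsets=None,
    laser_intervals=None,
    *,
    transition_pad: float = TRANSITION_PAD_S,
    event_pad: float = EVENT_PAD_S,
) -> dict:
    """Boolean sample masks for each steady-state (state x laser) stratum.

    Keys are ('Q'|'W', None) without laser data, else ('Q'|'W', 'off'|'on').
    """
    t = trace.time
    ok = np.ones(t.size, bool)
    transitions = t[np.nonzero(np.diff(trace.state) != 0)[0] + 1]
    _mask_out(t, ok, transitions, transition_pad)
    if deflection_onsets is not None:
        _mask_out(t, ok, deflection_onsets, event_pad)

    w = trace.state == STATE_WHISKING
    if laser_intervals is None or len(laser_intervals) == 0:
        return {("Q", None): ok & ~w, ("W", None): ok & w}

    iv = np.asarray(laser_intervals, float)
    edges = iv.ravel()
    inside = np.searchsorted(edges, t, side="right") % 2 == 1
    off_ok = ok.copy()
    _mask_out(t, off_ok, edges, transition_pad)  # laser transitions, off-assignment only
    return {
        ("Q", "off"): off_ok & ~w & ~inside,
        ("W", "off"): off_ok & w & ~inside,
        ("Q", "on"): ok & ~w & inside,
        ("W", "on"): ok & w & inside,
    }


def _spike_sample_idx(spike_times: np.ndarray, time: np.ndarray) -> np.ndarray:
    return np.clip(np.searchsorted(time, spike_times, side="right") - 1, 0, time.size - 1)


def state_rates(spike_times, strata: dict, time, *, min_duration: float = 1.0) -> StateRates:
    """Spikes counted within each stratum divided by its total duration.

    Strata with less than ``min_duration`` seconds of residual time are
    flagged absent (rate None).
    """
    spike_times = np.asarray(spike_times, float)
    time = np.asarray(time, float)
    dt = float(np.median(np.diff(time)))
    idx = _spike_sample_idx(spike_times, time)
    rates, durations = {}, {}
    for key, mask in strata.items():
        dur = float(mask.sum()) * dt
        durations[key] = dur
        rates[key] = float(mask[idx].sum()) / dur if dur >= min_duration else None
    return StateRates(rates=rates, durations=durations)


def _mask_intervals(time: np.ndarray, mask: np.ndarray, dt: float) -> np.ndarray:
    """Half-open [on, off) interval edges of a boolean sample mask."""
    d = np.diff(np.concatenate([[0], mask.astype(np.int8), [0]]))
    starts = np.nonzero(d == 1)[0]
    stops = np.nonzero(d == -1)[0]
    edges = np.empty(2 * starts.size)
    edges[0::2] = time[starts]
    edges[1::2] = time[stops - 1] + dt
    return edges


def shuffle_test(
    spike_times,
    strata: dict,
    time,
    span: tuple[float, float],
    *,
    n_shuffles: int = N_SHUFFLES,
    rng=None,
    ci: float = 95.0,
    chunk: int = 500,
) -> StateRates:
    """Shuffle null for state rates from circular spike-time shifts.

    Each shuffle shifts all spike times by one uniform random offset,
    wrapping within the recording span (ISI structure preserved).  The
    per-stratum rate distribution over shuffles gives a central ``ci``%
    interval; the observed rate is significant when outside it.
    """
    if n_shuffles <= 0:
        raise ValueError("n_shuffles must be positive")
    rng = np.random.default_rng(rng)
    spike_times = np.asarray(spike_times, float)
    time = np.asarray(time, float)
    dt = float(np.median(np.diff(time)))
    t0, t1 = float(span[0]), float(span[1])
    length = t1 - t0
    if length < 10.0:
        warnings.warn("recording shorter than 10 s; circular-shift null is weak")

    result = state_rates(spike_times, strata, time)
    edges = {k: _mask_intervals(time, m, dt) for k, m in strata.items()}
    alpha = (100.0 - ci) / 2.0

    null_counts = {k: np.empty(n_shuffles) for k in strata}
    done = 0
    rel = spike_times - t0
    while done < n_shuffles:
        m = min(chunk, n_shuffles - done)
        offsets = rng.uniform(0.0, length, m)
        shifted = t0 + np.mod(rel[None, :] + offsets[:, None], length)
        for k, e in edges.items():
            if e.size == 0:
                null_counts[k][done:done + m] = 0.0
                continue
            pos = np.searchsorted(e, shifted)
            null_counts[k][done:done + m] = (pos % 2 == 1).sum(axis=1)
        done += m

    for k in strata:
        dur = result.durations[k]
        if result.rates[k] is None or dur <= 0:
            result.shuffle_ci[k] = (None, None)
            result.significant[k] = False
            continue
        null_rates = null_counts[k] / dur
        lo, hi = np.percentile(null_rates, [alpha, 100.0 - alpha])
        result.shuffle_ci[k] = (float(lo), float(hi))
        result.significant[k] = bool(result.rates[k] < lo or result.rates[k] > hi)
    return result


# ---------------------------------------------------------------------- #
# amplitude tuning
# ---------------------------------------------------------------------- #

def rate_vs_amplitude(
    spike_times, trace: WhiskingTrace, *, bin_deg: float = AMP_BIN_DEG,
    min_occupancy: float = 0.25,
):
    """Spike rate per 5-degree whisking-amplitude bin + Pearson correlation.

    Returns (bin_centers, rates, r, p); r/p are None (flagged) with fewer
    than 3 occupied bins.  p is two-sided from the t distribution with
    n_bins - 2 degrees of freedom.
    """
    spike_times = np.asarray(spike_times, float)
    w = trace.whisking_mask
    dt = trace.dt
    amp = trace.amplitude
    edges = np.arange(0.0, amp[w].max() + bin_deg, bin_deg) if w.any() else np.array([0, bin_deg])
    nb = edges.size - 1

    samp_bin = np.clip(np.digitize(amp, edges) - 1, 0, nb - 1)
    occupancy = np.bincount(samp_bin[w], minlength=nb) * dt

    idx = _spike_sample_idx(spike_times, trace.time)
    sel = w[idx]
    spike_counts = np.bincount(samp_bin[idx[sel]], minlength=nb)

    valid = occupancy >= min_occupancy
    centers = 0.5 * (edges[:-1] + edges[1:])
    rates = np.full(nb, np.nan)
    rates[valid] = spike_counts[valid] / occupancy[valid]
    if valid.sum() < 3:
        return centers, rates, None, None
    r, p = stats.pearsonr(centers[valid], rates[valid])
    return centers, rates, float(r), float(p)


# ---------------------------------------------------------------------- #
# phase tuning
# ---------------------------------------------------------------------- #

def kuiper_test(spike_phases, occupancy: Optional[np.ndarray] = None,
                bin_edges: Optional[np.ndarray] = None,
                *, min_spikes: int = 10):
    """Kuiper test of spike phases against the occupancy-weighted null.

    The null CDF is piecewise linear over the phase-bin edges with slopes
    proportional to occupancy (uniform circle when occupancy is None), so
    phase locking is tested beyond mere occupancy.  V = D+ + D-; the
    p-value uses the standard asymptotic series with Stephens' effective-n
    correction.  Returns (V, p, flag); flag 'low_n' below ``min_spikes``.
    """
    phases = np.sort(np.asarray(spike_phases, float))
    n = phases.size
    if n == 0:
        return None, None, "no_spikes"
    if occupancy is None:
        u = (phases + np.pi) / (2.0 * np.pi)
    else:
        occupancy = np.asarray(occupancy, float)
        if bin_edges is None:
            bin_edges = np.linspace(-np.pi, np.pi, occupancy.size + 1)
        cdf = np.concatenate([[0.0], np.cumsum(occupancy)])
        cdf = cdf / cdf[-1]
        u = np.interp(phases, bin_edges, cdf)
    u = np.sort(u)
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - u)
    d_minus = np.max(u - (i - 1) / n)
    v = float(d_plus + d_minus)
    lam = (np.sqrt(n) + 0.155 + 0.24 / np.sqrt(n)) * v
    p = _kuiper_fpp(lam)
    flag = "low_n" if n < min_spikes else None
    return v, float(p), flag


def _kuiper_fpp(lam: float) -> float:
    """Asymptotic Kuiper false-positive probability (Stephens 1970)."""
    if lam < 0.4:
        return 1.0
    k = np.arange(1, 101)
    a = 2.0 * (k * lam) ** 2
    terms = 2.0 * (2.0 * a - 1.0) * np.exp(-a)
    return float(np.clip(terms.sum(), 0.0, 1.0))


def tuning_snr(amp: float, mean_rate: float, T: float = CYCLE_T_S) -> float:
    """SNR = (2 * Amp / <Rate>) * sqrt(<Rate> * T); 0 when <Rate> = 0."""
    if mean_rate <= 0:
        return 0.0
    return float((2.0 * amp / mean_rate) * np.sqrt(mean_rate * T))


def phase_tuning(
    spike_times, trace: WhiskingTrace, *, n_bins: int = N_PHASE_BINS,
    T: float = CYCLE_T_S, min_spikes: int = 10,
    exclude_times=None, exclude_pad_s: float = EVENT_PAD_S,
) -> PhaseTuning:
    """Occupancy-normalized 16-bin phase tuning with cosine fit and SNR.

    Spikes whose enclosing video sample is whisking are assigned a phase by
    interpolation; bin rates are spike counts divided by per-bin occupancy
    time.  The cosine fit is linear least squares on (1, cos, sin)
    regressors; a negative amplitude is resolved by a pi phase shift.
    ``exclude_times`` (typically deflection onsets) masks ``exclude_pad_s``
    around each from both occupancy and spikes, restricting the tuning to
    free whisking.
    """
    spike_times = np.asarray(spike_times, float)
    w = trace.whisking_mask.copy()
    dt = trace.dt
    if exclude_times is not None and len(exclude_times):
        ex = np.sort(np.asarray(exclude_times, float))
        _mask_out(trace.time, w, ex, exclude_pad_s)
        near = np.searchsorted(ex, spike_times)
        dist = np.minimum(
            np.abs(spike_times - ex[np.clip(near - 1, 0, ex.size - 1)]),
            np.abs(ex[np.clip(near, 0, ex.size - 1)] - spike_times))
        spike_times = spike_times[dist >= exclude_pad_s]
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    samp_bin = np.clip(np.digitize(trace.phase, edges) - 1, 0, n_bins - 1)
    occupancy = np.bincount(samp_bin[w], minlength=n_bins) * dt

    idx = _spike_sample_idx(spike_times, trace.time)
    sel = w[idx]
    from .whisking import phase_at
    phases = phase_at(trace, spike_times[sel], require_whisking=True)
    phases = np.atleast_1d(phases)
    phases = phases[~np.isnan(phases)]

    flags = []
    if phases.size == 0:
        flags.append("no_whisking_spikes")
        return PhaseTuning(bin_centers=centers, occupancy=occupancy,
                           rates=np.full(n_bins, np.nan), fit_mean=0.0, fit_amp=0.0,
                           fit_phase=0.0, snr=0.0, kuiper_v=None, kuiper_p=None,
                           n_spikes=0, T_window=T, flags=flags)

    spk_bin = np.clip(np.digitize(phases, edges) - 1, 0, n_bins - 1)
    spike_counts = np.bincount(spk_bin, minlength=n_bins)
    valid = occupancy > 0
    rates = np.full(n_bins, np.nan)
    rates[valid] = spike_counts[valid] / occupancy[valid]

    X = np.column_stack([np.ones(valid.sum()), np.cos(centers[valid]), np.sin(centers[valid])])
    beta, *_ = np.linalg.lstsq(X, rates[valid], rcond=None)
    mean_fit, b, c = beta
    amp = float(np.hypot(b, c))
    pref = float(np.arctan2(c, b))

    v, p, kflag = kuiper_test(phases, occupancy, edges, min_spikes=min_spikes)
    if kflag:
        flags.append(f"kuiper_{kflag}")
    return PhaseTuning(
        bin_centers=centers, occupancy=occupancy, rates=rates,
        fit_mean=float(mean_fit), fit_amp=amp, fit_phase=pref,
        snr=tuning_snr(amp, float(mean_fit), T), kuiper_v=v, kuiper_p=p,
        n_spikes=int(phases.size), T_window=T, flags=flags,
    )
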