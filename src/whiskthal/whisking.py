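"""Hilbert decomposition of the whisker angle and whisking/quiescence segmentation.

The angle trace (positive = protraction) is band-pass filtered in the
whisking band (3-30 Hz, zero-phase 5th-order Butterworth) and the analytic
signal of the filtered trace gives the instantaneous whisk phase, with the
convention phase 0 = fully protracted, +-pi = fully retracted.  Whisk-cycle
extrema are located at phase transitions through 0 (protraction peak) and
+-pi (retraction trough).  Whisking amplitude is the absolute difference of
consecutive extrema (peak-to-trough, degrees) and setpoint their mean,
assigned piecewise-constant per half cycle.  Samples belonging to maximal
runs with amplitude > 3 deg lasting > 200 ms are labeled ``whisking``,
everything else ``quiescence``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt, hilbert

__all__ = ["WhiskingTrace", "normalize_angle", "decompose", "segment_states",
           "phase_at", "label_states"]

WHISK_BAND_HZ = (3.0, 30.0)
FILTER_ORDER = 5
AMP_THRESHOLD_DEG = 3.0
MIN_WHISK_DURATION_S = 0.2

STATE_QUIESCENCE = 0
STATE_WHISKING = 1


@dataclass
class WhiskingTrace:
    """Decomposed whisker signal on the video time base."""

    time: np.ndarray          # s
    angle_norm: np.ndarray    # deg, median-stationary-subtracted
    angle_band: np.ndarray    # deg, 3-30 Hz band-passed
    phase: np.ndarray         # rad in (-pi, pi], 0 = fully protracted
    amplitude: np.ndarray     # deg, |difference of consecutive extrema|
    setpoint: np.ndarray      # deg, mean of consecutive extrema (+ slow residual)
    state: np.ndarray         # per-sample {0 quiescence, 1 whisking}

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.time)))

    @property
    def whisking_mask(self) -> np.ndarray:
        return self.state == STATE_WHISKING


def normalize_angle(angle, stationary_mask=None) -> np.ndarray:
    """Subtract the median angular position while stationary.

    With no stationary samples (or no mask on a first pass) the global
    median is used instead, with a warning in the former case.
    """
    angle = np.asarray(angle, dtype=float)
    if stationary_mask is None:
        return angle - np.median(angle)
    stationary_mask = np.asarray(stationary_mask, dtype=bool)
    if not stationary_mask.any():
        warnings.warn("no stationary samples; normalizing by global median")
        return angle - np.median(angle)
    return angle - np.median(angle[stationary_mask])


def _wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    out = np.mod(phi + np.pi, 2.0 * np.pi) - np.pi
    if np.ndim(out) == 0:
        return np.pi if out == -np.pi else out
    out[out == -np.pi] = np.pi
    return out


def _find_extrema(phase: np.ndarray):
    """Indices and kinds of whisk-cycle extrema from phase transitions.

    Returns (indices, is_peak) where peaks are phase upward crossings of 0
    (fully protracted) and troughs are wraps through +-pi (fully retracted).
    """
    dph = np.diff(phase)
    cross0 = np.nonzero((phase[:-1] < 0.0) & (phase[1:] >= 0.0) & (np.abs(dph) < np.pi))[0] + 1
    wrap = np.nonzero(dph < -np.pi)[0] + 1
    idx = np.concatenate([cross0, wrap])
    is_peak = np.concatenate([np.ones(cross0.size, bool), np.zeros(wrap.size, bool)])
    order = np.argsort(idx, kind="stable")
    return idx[order], is_peak[order]


def decompose(
    angle_norm,
    time,
    *,
    band_hz: tuple[float, float] = WHISK_BAND_HZ,
    order: int = FILTER_ORDER,
    amp_threshold_deg: float = AMP_THRESHOLD_DEG,
    min_whisk_duration_s: float = MIN_WHISK_DURATION_S,
    amplitude_source: str = "band",
) -> WhiskingTrace:
    """Band-pass + Hilbert decomposition into phase/amplitude/setpoint/state.

    Parameters
    ----------
    amplitude_source : {"band", "raw"}
        Which signal to read extrema values from.  "band" (default) is robust
        to setpoint drift; the low-frequency residual (angle_norm - band) is
        then added back into the setpoint.
    """
    angle_norm = np.asarray(angle_norm, dtype=float)
    time = np.asarray(time, dtype=float)
    if angle_norm.shape != time.shape:
        raise ValueError("angle_norm and time must have the same shape")
    n = angle_norm.size
    dt = np.diff(time)
    dt0 = float(np.median(dt))
    if np.any(np.abs(dt - dt0) > 0.01 * dt0):
        raise ValueError("time base not uniform within 1%")
    fs = 1.0 / dt0

    sos = butter(order, band_hz, btype="bandpass", fs=fs, output="sos")
    # reflect padding, 3x the effective filter order
    padlen = min(n - 1, 3 * 2 * order)
    if n <= padlen or n < 3 * 2 * order:
        raise ValueError(f"series too short for filter warm-up (n={n})")
    band = sosfiltfilt(sos, angle_norm, padtype="even", padlen=padlen)

    phase = np.angle(hilbert(band))
    phase = _wrap_phase(phase)

    src = band if amplitude_source == "band" else angle_norm
    if amplitude_source not in ("band", "raw"):
        raise ValueError("amplitude_source must be 'band' or 'raw'")
    slow = angle_norm - band

    ext_idx, _ = _find_extrema(phase)
    amplitude = np.zeros(n)
    setpoint = np.full(n, float(np.mean(angle_norm)))
    if ext_idx.size >= 2:
        vals = src[ext_idx]
        amp_seg = np.abs(np.diff(vals))
        set_seg = 0.5 * (vals[1:] + vals[:-1])
        # piecewise-constant per half-cycle, sampled forward; edges take the
        # nearest half-cycle's values
        for k in range(ext_idx.size - 1):
            i0, i1 = ext_idx[k], ext_idx[k + 1]
            amplitude[i0:i1] = amp_seg[k]
            sp = set_seg[k]
            if amplitude_source == "band":
                sp = sp + float(np.mean(slow[i0:i1]))
            setpoint[i0:i1] = sp
        amplitude[: ext_idx[0]] = amplitude[ext_idx[0]]
        amplitude[ext_idx[-1]:] = amplitude[ext_idx[-1] - 1]
        setpoint[: ext_idx[0]] = setpoint[ext_idx[0]]
        setpoint[ext_idx[-1]:] = setpoint[ext_idx[-1] - 1]

    state = label_states(amplitude, dt0, amp_threshold_deg, min_whisk_duration_s)
    return WhiskingTrace(
        time=time, angle_norm=angle_norm, angle_band=band, phase=phase,
        amplitude=amplitude, setpoint=setpoint, state=state,
    )


def label_states(amplitude, dt: float, amp_threshold: float = AMP_THRESHOLD_DEG,
                 min_duration: float = MIN_WHISK_DURATION_S) -> np.ndarray:
    """Per-sample whisking/quiescence labels from the amplitude signal.

    Maximal runs with amplitude above ``amp_threshold`` lasting more than
    ``min_duration`` are whisking; shorter above-threshold runs remain
    quiescence.
    """
    amplitude = np.asarray(amplitude, float)
    above = amplitude > amp_threshold
    state = np.zeros(amplitude.size, dtype=np.int8)
    for i0, i1 in _runs(above):
        if (i1 - i0) * dt > min_duration:
            state[i0:i1] = STATE_WHISKING
    return state


def _runs(mask: np.ndarray):
    """Maximal True runs of a boolean mask as (start, stop) index pairs."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.nonzero(d == 1)[0]
    stops = np.nonzero(d == -1)[0]
    return list(zip(starts, stops))


def segment_states(trace: WhiskingTrace):
    """Maximal (state, t_on, t_off) intervals partitioning the recording.

    Intervals are half-open [t_on, t_off); the last interval ends one sample
    step past the final timestamp so that the segmentation is a partition.
    """
    t = trace.time
    dt = trace.dt
    edges = np.nonzero(np.diff(trace.state) != 0)[0] + 1
    bounds = np.concatenate([[0], edges, [t.size]])
    out = []
    for i0, i1 in zip(bounds[:-1], bounds[1:]):
        t_off = t[i1] if i1 < t.size else t[-1] + dt
        label = "whisking" if trace.state[i0] == STATE_WHISKING else "quiescence"
        out.append((label, float(t[i0]), float(t_off)))
    return out


def phase_at(trace: WhiskingTrace, query_times, *, require_whisking: bool = True) -> np.ndarray:
    """Phase at arbitrary times by unwrap-interpolate-rewrap.

    Linear interpolation on the unwrapped phase avoids averaging across the
    +-pi wrap.  Queries whose enclosing video sample is quiescent are
    returned as NaN when ``require_whisking`` (phase is undefined outside
    whisking).  Out-of-span queries raise.
    """
    q = np.atleast_1d(np.asarray(query_times, dtype=float))
    t = trace.time
    if q.size and (q.min() < t[0] or q.max() > t[-1] + trace.dt):
        raise ValueError("query time outside trace span")
    unwrapped = np.unwrap(trace.phase)
    out = _wrap_phase(np.interp(q, t, unwrapped))
    if require_whisking:
        idx = np.clip(np.searchsorted(t, q, side="right") - 1, 0, t.size - 1)
        out = np.where(trace.state[idx] == STATE_WHISKING, out, np.nan)
    return out if np.ndim(query_times) else float(out[0]) if out.size == 1 else out
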