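"""Deflection-event table: touch detection, puff-onset correction, labeling.

A *deflection event* is either an air puff (passive) or a pole touch
(active).  Puff command times are corrected for the pneumatic line delay by
locating the onset of the mean backward (retraction) deflection on the
command-aligned whisker trace.  Touches are extracted from the touch-area
brightness trace, whose summed brightness drops while the whisker occludes
the pole profile.  Each event carries its inter-deflection interval on the
joint puff+touch sequence, the whisking state in the 500 ms before onset,
a laser label (on only if the laser covers at least 5 ms before to 35 ms
after onset), and for touches the bout structure (bouts separated by at
least 500 ms).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .whisking import WhiskingTrace

__all__ = [
    "DeflectionEvent",
    "detect_touches",
    "correct_puff_onsets",
    "build_event_table",
]

BOUT_GAP_S = 0.5
LASER_PRE_S = 0.005
LASER_POST_S = 0.035
PRE_STATE_WINDOW_S = 0.5
AMP_THRESHOLD_DEG = 3.0


@dataclass
class DeflectionEvent:
    kind: str            # "puff" | "touch"
    onset: float         # s, corrected
    offset: float        # s
    interval_prev: float  # s since previous event of the joint set
    pre_state: str       # "Q" | "W"
    laser_on: bool
    bout_id: int = -1            # touches only
    within_bout_index: int = -1  # 1 = first touch in bout
    overlap: bool = False        # flagged when puff and touch overlap


# ---------------------------------------------------------------------- #

def _two_means(x: np.ndarray, n_iter: int = 64):
    """1-D two-means clustering; returns (lo_center, hi_center, labels)."""
    c0, c1 = float(x.min()), float(x.max())
    labels = None
    for _ in range(n_iter):
        mid = 0.5 * (c0 + c1)
        lab = x > mid
        if not lab.any() or lab.all():
            break
        n0, n1 = float(x[~lab].mean()), float(x[lab].mean())
        if n0 == c0 and n1 == c1:
            labels = lab
            break
        c0, c1, labels = n0, n1, lab
    return c0, c1, labels


def detect_touches(brightness_trace, time, *, min_separation_std: float = 3.0) -> np.ndarray:
    """Touch intervals from a bimodal touch-area brightness trace.

    The threshold is the midpoint between the two modes of the brightness
    distribution (two-means clustering).  If the histogram is effectively
    unimodal -- the mode separation does not exceed ``min_separation_std``
    pooled within-mode standard deviations -- no touches are returned, with
    a warning.  Intervals are maximal half-open [on, off) runs below
    threshold; anything shorter than one video frame is dropped.
    """
    b = np.asarray(brightness_trace, float)
    t = np.asarray(time, float)
    dt = float(np.median(np.diff(t)))
    if b.max() - b.min() <= 0:
        warnings.warn("brightness trace is constant; no touches detected")
        return np.empty((0, 2))
    c0, c1, labels = _two_means(b)
    if labels is None:
        warnings.warn("brightness histogram unimodal; no touches detected")
        return np.empty((0, 2))
    s0 = b[~labels].std()
    s1 = b[labels].std()
    pooled = max(0.5 * (s0 + s1), 1e-12)
    if (c1 - c0) < min_separation_std * pooled:
        warnings.warn("brightness histogram unimodal; no touches detected")
        return np.empty((0, 2))

    thresh = 0.5 * (c0 + c1)
    mask = b < thresh
    d = np.diff(np.concatenate([[0], mask.astype(np.int8), [0]]))
    starts = np.nonzero(d == 1)[0]
    stops = np.nonzero(d == -1)[0]
    out = [(t[i0], t[i1 - 1] + dt) for i0, i1 in zip(starts, stops)
           if (i1 - i0) * dt >= dt]  # at least one video frame
    return np.asarray(out).reshape(-1, 2)


def correct_puff_onsets(
    puff_command_times,
    trace: WhiskingTrace,
    *,
    window: tuple[float, float] = (-0.05, 0.10),
    noise_sd_factor: float = 3.0,
    min_run_samples: int = 3,
    plausible_delay: tuple[float, float] = (0.0, 0.05),
    fallback_delay: float = 0.019,
) -> tuple[np.ndarray, float]:
    """Correct command times for the line delay; returns (onsets, delay).

    The command-aligned mean angle trace is scanned for the first sustained
    backward (negative) deflection exceeding ``noise_sd_factor`` standard
    deviations of the pre-command baseline; that single scalar delay is
    added to every command time.  Estimates outside ``plausible_delay``
    fall back to ``fallback_delay`` with a warning.
    """
    cmds = np.asarray(puff_command_times, float)
    t, angle = trace.time, trace.angle_norm
    dt = trace.dt
    offs = np.arange(int(round(window[0] / dt)), int(round(window[1] / dt)))
    i0 = np.searchsorted(t, cmds)
    valid = (i0 + offs[0] >= 0) & (i0 + offs[-1] < t.size)
    i0 = i0[valid]

    delay = None
    if i0.size:
        aligned = angle[i0[:, None] + offs[None, :]]
        mtrace = aligned.mean(axis=0)
        pre = offs < 0
        mu, sd = mtrace[pre].mean(), mtrace[pre].std()
        sd = max(sd, 1e-12)
        below = (mtrace < mu - noise_sd_factor * sd) & (offs >= 0)
        # first run of min_run_samples consecutive below-threshold samples
        run = 0
        for j in range(offs.size):
            run = run + 1 if below[j] else 0
            if run >= min_run_samples:
                j0 = j - min_run_samples + 1
                # back off to the deflection foot (last sample within 1 s.d.)
                while j0 > 0 and offs[j0 - 1] >= 0 and mtrace[j0 - 1] < mu - sd:
                    j0 -= 1
                delay = float(offs[j0] * dt)
                break
    if delay is None:
        warnings.warn("no detectable puff deflection; using fallback delay")
        delay = fallback_delay
    elif not plausible_delay[0] <= delay <= plausible_delay[1]:
        warnings.warn(
            f"estimated line delay {delay * 1e3:.1f} ms outside plausibility "
            f"window; using fallback delay")
        delay = fallback_delay
    return cmds + delay, delay


def _mean_amplitude_before(trace: WhiskingTrace, onset: float, window: float) -> float:
    i1 = np.searchsorted(trace.time, onset, side="left")
    i0 = np.searchsorted(trace.time, onset - window, side="left")
    if i1 <= i0:
        return 0.0
    return float(trace.amplitude[i0:i1].mean())


def _laser_covers(laser_intervals, onset: float) -> bool:
    if laser_intervals is None or len(laser_intervals) == 0:
        return False
    iv = np.asarray(laser_intervals, float)
    return bool(np.any((iv[:, 0] <= onset - LASER_PRE_S) & (iv[:, 1] >= onset + LASER_POST_S)))


def _intersects(a0: float, a1: float, intervals) -> bool:
    if intervals is None or len(intervals) == 0:
        return False
    iv = np.asarray(intervals, float)
    return bool(np.any((iv[:, 0] < a1) & (iv[:, 1] > a0)))


def build_event_table(
    trace: WhiskingTrace,
    puff_onsets,
    touch_intervals=None,
    *,
    puff_duration: float = 0.03,
    laser_intervals=None,
    exclusion_intervals=None,
    recording_start: Optional[float] = None,
    bout_gap: float = BOUT_GAP_S,
    pre_state_window: float = PRE_STATE_WINDOW_S,
    amp_threshold: float = AMP_THRESHOLD_DEG,
) -> pd.DataFrame:
    """Merged, time-sorted DeflectionEvent table as a DataFrame.

    interval_prev is computed on the joint puff+touch sequence; the first
    event's interval is measured from the recording start (unadapted by
    construction, so it lands in the longest-interval group).  Events whose
    analysis window intersects a user-supplied exclusion interval (manual
    curation of grooming / stuck-whisker periods) are dropped.  Overlapping
    puffs and touches are both kept and flagged.
    """
    puff_onsets = np.asarray(puff_onsets, float)
    t0 = float(trace.time[0]) if recording_start is None else float(recording_start)

    rows = []
    for on in puff_onsets:
        rows.append(["puff", float(on), float(on + puff_duration)])
    if touch_intervals is not None:
        for on, off in np.asarray(touch_intervals, float).reshape(-1, 2):
            rows.append(["touch", float(on), float(off)])
    df = pd.DataFrame(rows, columns=["kind", "onset", "offset"])
    df = df.sort_values("onset", kind="stable").reset_index(drop=True)

    if exclusion_intervals is not None and len(df):
        keep = [not _intersects(on - 0.05, off + 0.075, exclusion_intervals)
                for on, off in zip(df["onset"], df["offset"])]
        df = df[keep].reset_index(drop=True)

    onsets = df["onset"].to_numpy()
    df["interval_prev"] = np.concatenate([[onsets[0] - t0], np.diff(onsets)]) \
        if len(df) else np.empty(0)
    df["pre_state"] = [
        "W" if _mean_amplitude_before(trace, on, pre_state_window) > amp_threshold else "Q"
        for on in onsets
    ]
    df["laser_on"] = [_laser_covers(laser_intervals, on) for on in onsets]

    # overlap flag: a puff inside a touch (or vice versa)
    overlap = np.zeros(len(df), bool)
    for i in range(len(df)):
        others = df[(df["kind"] != df.loc[i, "kind"])]
        overlap[i] = _intersects(df.loc[i, "onset"], df.loc[i, "offset"],
                                 others[["onset", "offset"]].to_numpy())
    df["overlap"] = overlap

    # bout structure on touches only (invariant to adding puffs)
    df["bout_id"] = -1
    df["within_bout_index"] = -1
    tmask = df["kind"] == "touch"
    t_on = df.loc[tmask, "onset"].to_numpy()
    if t_on.size:
        new_bout = np.concatenate([[True], np.diff(t_on) >= bout_gap])
        bout_ids = np.cumsum(new_bout) - 1
        within = np.ones(t_on.size, int)
        for b in np.unique(bout_ids):
            sel = bout_ids == b
            within[sel] = np.arange(1, sel.sum() + 1)
        df.loc[tmask, "bout_id"] = bout_ids
        df.loc[tmask, "within_bout_index"] = within
    return df
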