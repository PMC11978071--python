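"""Per-event whisker kinematics and joint-distribution tertile matching.

To ask whether response differences between active touches and passive
puffs are explained by stimulus kinematics, each deflection gets a set of
kinematic features (mean angle/velocity/|acceleration|/phase/setpoint/
amplitude in 50-ms windows around onset, curvature after onset, and the
inter-deflection interval).  The *joint* puff+touch distribution of a
feature is split into tertiles, and response modulation (50-ms pre/post
windows) is compared within matched tertiles, so puff and touch trials
with the same kinematics are compared directly.

Derivatives use central differences on the raw 625 Hz angle.  Curvature is
normalized by subtracting the per-session median curvature during
quiescence (removes intrinsic whisker shape).  Phase features use circular
means; phase tertiles use circular quantiles anchored at -pi.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .whisking import WhiskingTrace
from .response import trial_counts, modulation_index, _wilcoxon

__all__ = [
    "event_features",
    "tertile_split",
    "per_tertile_modulation",
    "first_vs_later_touch",
    "NeuronEvents",
]

FEATURES = [
    "accel_25", "accel_50", "curv_post_25", "curv_post_50", "curv_change_50",
    "vel_50", "abs_vel_50", "setpoint_pre", "amplitude_pre", "angle_pre",
    "phase_pre", "interval_prev",
]

CIRCULAR_FEATURES = {"phase_pre"}


def _window_mean(x, time, lo, hi):
    i0 = np.searchsorted(time, lo, side="left")
    i1 = np.searchsorted(time, hi, side="left")
    if i1 <= i0:
        return np.nan
    return float(np.nanmean(x[i0:i1]))


def _circular_mean(phi, time, lo, hi):
    i0 = np.searchsorted(time, lo, side="left")
    i1 = np.searchsorted(time, hi, side="left")
    seg = phi[i0:i1]
    seg = seg[~np.isnan(seg)]
    if seg.size == 0:
        return np.nan
    return float(np.angle(np.exp(1j * seg).mean()))


def event_features(events: pd.DataFrame, trace: WhiskingTrace,
                   curvature) -> pd.DataFrame:
    """Kinematic feature table aligned to the event table (row for row).

    Events within 50 ms of the recording edges get a ``partial`` flag
    rather than silently truncated windows.
    """
    t = trace.time
    angle = trace.angle_norm
    vel = np.gradient(angle, t)          # deg/s, central differences
    acc = np.gradient(vel, t)            # deg/s^2
    curv = np.asarray(curvature, float)
    q = ~trace.whisking_mask
    curv_norm = curv - (np.median(curv[q]) if q.any() else np.median(curv))

    rows = []
    for _, ev in events.iterrows():
        on = float(ev["onset"])
        partial = (on - 0.05 < t[0]) or (on + 0.05 > t[-1])
        rows.append({
            "accel_25": _window_mean(np.abs(acc), t, on - 0.025, on + 0.025),
            "accel_50": _window_mean(np.abs(acc), t, on - 0.05, on + 0.05),
            "curv_post_25": _window_mean(curv_norm, t, on, on + 0.025),
            "curv_post_50": _window_mean(curv_norm, t, on, on + 0.05),
            "curv_change_50": (_window_mean(curv_norm, t, on, on + 0.05)
                               - _window_mean(curv_norm, t, on - 0.05, on)),
            "vel_50": _window_mean(vel, t, on - 0.05, on + 0.05),
            "abs_vel_50": abs(_window_mean(vel, t, on - 0.05, on + 0.05)),
            "setpoint_pre": _window_mean(trace.setpoint, t, on - 0.05, on),
            "amplitude_pre": _window_mean(trace.amplitude, t, on - 0.05, on),
            "angle_pre": _window_mean(angle, t, on - 0.05, on),
            "phase_pre": _circular_mean(
                np.where(trace.whisking_mask, trace.phase, np.nan), t, on - 0.05, on),
            "interval_prev": float(ev["interval_prev"]),
            "partial": partial,
        })
    return pd.DataFrame(rows, index=events.index)


def tertile_split(values, *, circular: bool = False):
    """Assign pooled feature values to tertiles of their joint distribution.

    Returns (labels in {0, 1, 2}, edges, degenerate_flag).  Assignment is
    rank-based with stable tie-breaking, so tertile counts differ by at
    most the tie spill-over.  Circular features are ranked after anchoring
    at -pi.  A constant feature yields a degenerate single-tertile split,
    flagged rather than raised.
    """
    v = np.asarray(values, float)
    if v.size < 3:
        raise ValueError("tertile_split requires at least 3 values")
    if np.nanmax(v) == np.nanmin(v):
        return np.zeros(v.size, int), np.array([np.nan, np.nan]), True
    key = np.mod(v + np.pi, 2.0 * np.pi) if circular else v
    order = np.argsort(key, kind="stable")
    labels = np.empty(v.size, int)
    ranks = np.empty(v.size, int)
    ranks[order] = np.arange(v.size)
    labels = np.minimum(ranks * 3 // v.size, 2)
    edges = np.quantile(key, [1.0 / 3.0, 2.0 / 3.0])
    return labels, edges, False


@dataclass
class NeuronEvents:
    """One neuron's event table + spikes, the unit of population analyses."""
    neuron_id: str
    events: pd.DataFrame      # from events.build_event_table (+ features merged)
    spike_times: np.ndarray


def _cell_mi(spikes, onsets, window=0.05):
    pre, post = trial_counts(spikes, onsets, window, window)
    n = len(onsets)
    return modulation_index(pre.sum() / (n * window), post.sum() / (n * window))


def per_tertile_modulation(
    neurons: Sequence[NeuronEvents],
    feature: str,
    *,
    min_events_per_cell: int = 5,
    window: float = 0.05,
) -> pd.DataFrame:
    """Population modulation per (kind x tertile) of a joint kinematic split.

    Tertile edges are computed per neuron from that neuron's pooled
    puff+touch feature values (matched within recording).  For each
    (kind, tertile) cell a neuron contributes one MI from its pooled events
    (cells with fewer than ``min_events_per_cell`` events are excluded).
    The returned long-format table carries, per cell: n_neurons, mean MI,
    sem, the within-condition one-sided signed-rank p (MI > 0), and the
    1st-vs-3rd-tertile and puff-vs-touch two-sided signed-rank p values.
    """
    circular = feature in CIRCULAR_FEATURES
    per_neuron: dict[tuple, dict[str, float]] = {}
    for ne in neurons:
        ev = ne.events
        vals = ev[feature].to_numpy(float)
        ok = ~np.isnan(vals)
        if ok.sum() < 3:
            continue
        labels = np.full(len(ev), -1)
        labels[ok], _, degen = tertile_split(vals[ok], circular=circular)
        for kind in ("puff", "touch"):
            for tert in (0, 1, 2):
                sel = (ev["kind"] == kind).to_numpy() & (labels == tert)
                if sel.sum() < min_events_per_cell:
                    continue
                onsets = ev.loc[sel, "onset"].to_numpy()
                per_neuron.setdefault((kind, tert), {})[ne.neuron_id] = \
                    _cell_mi(ne.spike_times, onsets, window)

    rows = []
    for kind in ("puff", "touch"):
        for tert in (0, 1, 2):
            mis = per_neuron.get((kind, tert), {})
            vals = np.array(list(mis.values()))
            row = {"feature": feature, "kind": kind, "tertile": tert + 1,
                   "n_neurons": vals.size,
                   "mi_mean": float(vals.mean()) if vals.size else np.nan,
                   "mi_sem": float(vals.std(ddof=1) / np.sqrt(vals.size))
                   if vals.size > 1 else np.nan,
                   "p_within": _wilcoxon(vals, np.zeros(vals.size), "greater")
                   if vals.size >= 2 else np.nan}
            # paired comparisons on neurons present in both cells
            row["p_t1_vs_t3"] = _paired_p(per_neuron.get((kind, 0), {}),
                                          per_neuron.get((kind, 2), {}))
            row["p_puff_vs_touch"] = _paired_p(per_neuron.get(("puff", tert), {}),
                                               per_neuron.get(("touch", tert), {}))
            rows.append(row)
    return pd.DataFrame(rows)


def _paired_p(a: dict, b: dict) -> float:
    common = sorted(set(a) & set(b))
    if len(common) < 2:
        return np.nan
    x = np.array([a[k] for k in common])
    y = np.array([b[k] for k in common])
    return _wilcoxon(x, y, "two-sided")


def first_vs_later_touch(
    neurons: Sequence[NeuronEvents], *, min_touches: int = 10, window: float = 0.05,
) -> pd.DataFrame:
    """Per-neuron response to 1st vs. subsequent touches within a bout.

    The baseline window precedes the *first* touch of the bout for both
    classes; the response window follows the respective touch.  Neurons
    need at least ``min_touches`` touches in each class.  Returns one row
    per included neuron with MI_first / MI_later, plus a population row
    with the paired two-sided signed-rank p.
    """
    rows = []
    for ne in neurons:
        ev = ne.events
        touches = ev[ev["kind"] == "touch"]
        first = touches[touches["within_bout_index"] == 1]
        later = touches[touches["within_bout_index"] > 1]
        if len(first) < min_touches or len(later) < min_touches:
            continue
        bout_first_onset = {int(b): float(o) for b, o in
                            zip(first["bout_id"], first["onset"])}

        def class_mi(sub):
            base_on = np.array([bout_first_onset.get(int(b), np.nan)
                                for b in sub["bout_id"]])
            resp_on = sub["onset"].to_numpy()
            ok = ~np.isnan(base_on)
            pre, _ = trial_counts(ne.spike_times, base_on[ok], window, window)
            _, post = trial_counts(ne.spike_times, resp_on[ok], window, window)
            n = ok.sum()
            return modulation_index(pre.sum() / (n * window), post.sum() / (n * window))

        rows.append({"neuron_id": ne.neuron_id,
                     "mi_first": class_mi(first), "mi_later": class_mi(later),
                     "n_first": len(first), "n_later": len(later)})
    df = pd.DataFrame(rows)
    if len(df) >= 2:
        df.attrs["p_first_vs_later"] = _wilcoxon(
            df["mi_first"].to_numpy(), df["mi_later"].to_numpy(), "two-sided")
    else:
        df.attrs["p_first_vs_later"] = np.nan
    return df
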