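"""End-to-end session and cohort analysis.

``analyze_session`` runs the full chain on one RecordingSession: angle
normalization and Hilbert decomposition, touch detection / puff-onset
correction, event-table construction, the puff-responsiveness inclusion
test (one-sided signed rank, p < 0.05), event-aligned response statistics
per condition (puff, touch, Q-puff, W-puff, laser on/off), steady-state
rates with the shuffle null, amplitude and phase tuning, and per-event
kinematics.  ``run_cohort`` aggregates per-neuron records into population
tables with paired (within-neuron signed-rank) and between-nuclei
(rank-sum) comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import whisking, events as ev_mod, response, state_phase, kinematics
from .session_io import RecordingSession

__all__ = ["RunConfig", "SessionResult", "analyze_session", "run_cohort"]


@dataclass
class RunConfig:
    """All analysis parameters with their standard defaults."""

    band_hz: tuple = (3.0, 30.0)
    filter_order: int = 5
    amp_threshold_deg: float = 3.0
    min_whisk_duration_s: float = 0.2
    response_window_s: float = 0.05     # pre and post for rates / MI
    norm_pre_window_s: float = 0.025
    latency_horizon_s: float = 0.075
    psth_binwidth_s: float = 0.001
    psth_window_s: tuple = (-0.025, 0.075)
    n_phase_bins: int = 16
    cycle_T_s: float = 0.111
    n_shuffles: int = 10_000
    n_permutations: int = 256
    bout_gap_s: float = 0.5
    laser_pre_s: float = 0.005
    laser_post_s: float = 0.035
    pre_state_window_s: float = 0.5
    transition_pad_s: float = 0.025
    event_pad_s: float = 0.5
    amp_bin_deg: float = 5.0
    inclusion_alpha: float = 0.05
    min_touch_events: int = 10
    min_events_per_cell: int = 5
    fallback_line_delay_s: float = 0.019
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        return cfg


@dataclass
class SessionResult:
    neuron_id: str
    nucleus_label: str
    included: bool
    exclusion_reason: Optional[str]
    record: dict                      # flat per-neuron statistics
    trace: object = None
    event_table: Optional[pd.DataFrame] = None
    psths: dict = field(default_factory=dict)
    stage_status: dict = field(default_factory=dict)


def _resp_record(spikes, onsets, rec, prefix, cfg: RunConfig, sidedness):
    if len(onsets) < 2:
        return
    st = response.response_test(spikes, onsets, pre=cfg.response_window_s,
                                post=cfg.response_window_s, sidedness=sidedness)
    rec[f"{prefix}_baseline_hz"] = st.baseline_rate
    rec[f"{prefix}_response_hz"] = st.response_rate
    rec[f"{prefix}_mi"] = st.mi
    rec[f"{prefix}_p"] = st.p_value
    rec[f"{prefix}_n"] = st.n_events
    mean, sd, _ = response.first_spike_latency(spikes, onsets, cfg.latency_horizon_s)
    rec[f"{prefix}_latency_ms"] = mean
    rec[f"{prefix}_latency_sd_ms"] = sd
    return st


def analyze_session(session: RecordingSession, config: RunConfig = RunConfig(),
                    *, exclusion_intervals=None) -> SessionResult:
    """Run all stages on one session; failures yield per-stage status."""
    rec: dict = {"neuron_id": session.neuron_id, "animal_id": session.animal_id,
                 "nucleus": session.nucleus_label}
    status: dict = {}
    spikes = session.spike_times

    # ---- whisking decomposition (two-pass stationary normalization) ----
    angle0 = whisking.normalize_angle(session.whisker_angle)
    trace0 = whisking.decompose(angle0, session.whisker_time,
                                band_hz=config.band_hz, order=config.filter_order,
                                amp_threshold_deg=config.amp_threshold_deg,
                                min_whisk_duration_s=config.min_whisk_duration_s)
    angle = whisking.normalize_angle(session.whisker_angle, ~trace0.whisking_mask)
    trace = whisking.decompose(angle, session.whisker_time,
                               band_hz=config.band_hz, order=config.filter_order,
                               amp_threshold_deg=config.amp_threshold_deg,
                               min_whisk_duration_s=config.min_whisk_duration_s)
    status["whisking"] = "ok"

    # ---- events ----
    if session.touch_intervals is not None:
        touches = session.touch_intervals
    elif session.brightness_trace is not None:
        touches = ev_mod.detect_touches(session.brightness_trace, session.whisker_time)
    else:
        touches = None
    puff_onsets, delay = ev_mod.correct_puff_onsets(
        session.puff_command_times, trace,
        fallback_delay=config.fallback_line_delay_s)
    rec["line_delay_ms"] = delay * 1000.0
    table = ev_mod.build_event_table(
        trace, puff_onsets, touches,
        laser_intervals=session.laser_intervals,
        exclusion_intervals=exclusion_intervals,
        recording_start=session.recording_span[0],
        bout_gap=config.bout_gap_s, pre_state_window=config.pre_state_window_s,
        amp_threshold=config.amp_threshold_deg)
    feats = kinematics.event_features(table, trace, session.whisker_curvature)
    table = pd.concat([table, feats], axis=1)
    status["events"] = "ok"

    # ---- inclusion: significant rate increase to air puffs ----
    puffs = table.loc[table["kind"] == "puff", "onset"].to_numpy()
    psths: dict = {}
    included, reason = True, None
    if puffs.size < 2:
        included, reason = False, "too_few_puffs"
    else:
        st = _resp_record(spikes, puffs, rec, "puff", config, "greater")
        psths["puff"] = response.compute_psth(spikes, puffs, config.psth_window_s,
                                              config.psth_binwidth_s)
        if st.p_value >= config.inclusion_alpha:
            included, reason = False, "no_significant_puff_response"
    rec["included"] = included

    touch_on = table.loc[table["kind"] == "touch", "onset"].to_numpy()
    rec["n_touches"] = int(touch_on.size)
    if touch_on.size >= config.min_touch_events:
        _resp_record(spikes, touch_on, rec, "touch", config, "two-sided")
        psths["touch"] = response.compute_psth(spikes, touch_on, config.psth_window_s,
                                               config.psth_binwidth_s)
    else:
        status["touch"] = "skipped_fewer_than_min_touches"

    # Q- vs W-puff split (mean amplitude in the 500 ms before the puff)
    for state in ("Q", "W"):
        sel = (table["kind"] == "puff") & (table["pre_state"] == state)
        if session.laser_intervals is not None:
            sel &= ~table["laser_on"]
        if sel.sum() >= 2:
            _resp_record(spikes, table.loc[sel, "onset"].to_numpy(), rec,
                         f"{state.lower()}_puff", config, "greater")
    if session.laser_intervals is not None:
        for lab, lz in (("laser_off", False), ("laser_on", True)):
            sel = (table["kind"] == "puff") & (table["laser_on"] == lz)
            if sel.sum() >= 2:
                _resp_record(spikes, table.loc[sel, "onset"].to_numpy(), rec,
                             f"{lab}_puff", config, "greater")
    status["response"] = "ok"

    # ---- steady-state rates + shuffle null ----
    onsets_all = table["onset"].to_numpy()
    strata = state_phase.steady_state_mask(
        trace, onsets_all, session.laser_intervals,
        transition_pad=config.transition_pad_s, event_pad=config.event_pad_s)
    rng = np.random.default_rng(config.seed)
    sr = state_phase.shuffle_test(spikes, strata, trace.time, session.recording_span,
                                  n_shuffles=config.n_shuffles, rng=rng)
    for (state, laser), rate in sr.rates.items():
        suffix = "" if laser is None else f"_laser_{laser}"
        rec[f"rate_{state.lower()}{suffix}_hz"] = rate
        rec[f"rate_{state.lower()}{suffix}_sig"] = sr.significant[(state, laser)]
    status["state_rates"] = "ok"

    # ---- amplitude + phase tuning (per laser condition when present) ----
    _, _, r, p = state_phase.rate_vs_amplitude(spikes, trace, bin_deg=config.amp_bin_deg)
    rec["amp_corr_r"], rec["amp_corr_p"] = r, p
    pt = state_phase.phase_tuning(spikes, trace, n_bins=config.n_phase_bins,
                                  T=config.cycle_T_s, exclude_times=onsets_all,
                                  exclude_pad_s=config.event_pad_s)
    rec["phase_snr"] = pt.snr
    rec["phase_pref"] = pt.fit_phase
    rec["phase_amp_hz"] = pt.fit_amp
    rec["kuiper_p"] = pt.kuiper_p
    if session.laser_intervals is not None and len(session.laser_intervals):
        for lab, inside in (("off", False), ("on", True)):
            mask = np.searchsorted(
                np.asarray(session.laser_intervals, float).ravel(),
                spikes, side="right") % 2 == 1
            sel_spikes = spikes[mask] if inside else spikes[~mask]
            sub = state_phase.phase_tuning(sel_spikes, trace,
                                           n_bins=config.n_phase_bins,
                                           T=config.cycle_T_s, exclude_times=onsets_all,
                                           exclude_pad_s=config.event_pad_s)
            rec[f"phase_snr_laser_{lab}"] = sub.snr
            rec[f"kuiper_p_laser_{lab}"] = sub.kuiper_p
    status["tuning"] = "ok"

    return SessionResult(
        neuron_id=session.neuron_id, nucleus_label=session.nucleus_label,
        included=included, exclusion_reason=reason, record=rec, trace=trace,
        event_table=table, psths=psths, stage_status=status,
    )


def run_cohort(results: Sequence[SessionResult], config: RunConfig = RunConfig()):
    """Population tables + paired / between-nuclei comparisons.

    Returns (per_neuron DataFrame, population summary DataFrame).  Paired
    comparisons (e.g., puff vs. touch MI within neurons) use the two-sided
    Wilcoxon signed-rank test over pairwise-complete neurons; VPM-vs-POm
    comparisons use the two-sided rank-sum test.  No multiple-testing
    correction is applied (per-test p-values are reported as such).
    """
    if not results:
        raise ValueError("empty cohort")
    df = pd.DataFrame([r.record for r in results])
    inc = df[df["included"]] if "included" in df else df

    rows = []

    def add(name, series_by_nuc=None, paired=None):
        row = {"comparison": name}
        if paired is not None:
            a, b = paired
            both = inc[[a, b]].dropna()
            row["n"] = len(both)
            if len(both) >= 2:
                row["p"] = kinematics._wilcoxon(both[a].to_numpy(),
                                                both[b].to_numpy(), "two-sided")
                row["mean_a"], row["mean_b"] = both[a].mean(), both[b].mean()
                row["sem_a"] = both[a].std(ddof=1) / np.sqrt(len(both))
                row["sem_b"] = both[b].std(ddof=1) / np.sqrt(len(both))
        if series_by_nuc is not None:
            col = series_by_nuc
            vpm = inc.loc[inc["nucleus"] == "VPM", col].dropna()
            pom = inc.loc[inc["nucleus"] == "POm", col].dropna()
            row["n"] = (len(vpm), len(pom))
            if len(vpm) >= 2 and len(pom) >= 2:
                row["p"] = float(sps.ranksums(vpm, pom).pvalue)
                row["mean_a"], row["mean_b"] = vpm.mean(), pom.mean()
        rows.append(row)

    for col_pair, name in [
        (("puff_mi", "touch_mi"), "puff_vs_touch_mi_paired"),
        (("q_puff_mi", "w_puff_mi"), "q_vs_w_puff_mi_paired"),
        (("rate_q_hz", "rate_w_hz"), "q_vs_w_rate_paired"),
    ]:
        if all(c in inc.columns for c in col_pair):
            add(name, paired=col_pair)
    for col in ("puff_mi", "touch_mi", "puff_latency_ms", "phase_snr"):
        if col in inc.columns:
            add(f"vpm_vs_pom_{col}", series_by_nuc=col)

    return df, pd.DataFrame(rows)
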