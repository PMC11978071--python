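"""Statistical calibration and parameter-recovery experiments.

These experiments validate the pipeline's statistics on ground-truth
synthetic data: type-I error of the responsiveness test, of the
spike-time-shuffle null and of the occupancy-null Kuiper test; recovery of
generator parameters (first-spike latency, whisking gain, preferred phase,
modulation index) from full synthetic sessions; the short-term-depression
interval-sensitivity contrast; and nucleus classification on separable
cohorts.  Each function seeds all randomness from its ``seed`` argument.
"""

from __future__ import annotations

import numpy as np

from . import response, state_phase, whisking, classify
from .events import build_event_table, correct_puff_onsets
from .kinematics import NeuronEvents, tertile_split, first_vs_later_touch
from .response import first_spike_latency, trial_counts, modulation_index
from .synthetic import (NeuronParams, SyntheticConfig, generate_session,
                        generate_whisking_trace, generate_spike_train)

__all__ = [
    "wilcoxon_type1_rate",
    "shuffle_type1_rate",
    "kuiper_type1_rate",
    "recover_session_params",
    "recover_modulation_index",
    "interval_sensitivity",
    "classifier_experiment",
]


# ---------------------------------------------------------------------- #
# type-I calibration
# ---------------------------------------------------------------------- #

def wilcoxon_type1_rate(n_runs: int = 1000, n_trials: int = 100,
                        rate_hz: float = 6.0, alpha: float = 0.05,
                        seed: int = 0) -> float:
    """Rejection rate of the one-sided responsiveness test under the null.

    Homogeneous Poisson spike trains with event onsets that do not modulate
    the rate: the paired 50-ms pre/post counts are exchangeable, so the
    rejection rate should equal ``alpha``.
    """
    rng = np.random.default_rng(seed)
    onsets = 0.2 + 0.2 * np.arange(n_trials)
    span = onsets[-1] + 0.2
    rejections = 0
    for _ in range(n_runs):
        n_sp = rng.poisson(rate_hz * span)
        spikes = np.sort(rng.uniform(0.0, span, n_sp))
        st = response.response_test(spikes, onsets, sidedness="greater")
        rejections += st.p_value < alpha
    return rejections / n_runs


def shuffle_type1_rate(n_runs: int = 1000, n_shuffles: int = 1000,
                       duration: float = 60.0, rate_hz: float = 6.0,
                       seed: int = 0) -> float:
    """Per-stratum significance rate of the shuffle test under the null.

    One whisking trace defines the Q/W steady-state strata; spike trains
    are homogeneous Poisson (no state dependence), so each stratum's
    observed rate should fall outside the shuffle 95% CI 5% of the time.
    """
    rng = np.random.default_rng(seed)
    cfg = SyntheticConfig(duration=duration, block_cycle=("free",))
    truth = generate_whisking_trace(cfg, rng)
    trace = whisking.decompose(truth.angle, truth.time)
    strata = state_phase.steady_state_mask(trace)
    span = (0.0, duration)
    hits = total = 0
    for _ in range(n_runs):
        n_sp = rng.poisson(rate_hz * duration)
        spikes = np.sort(rng.uniform(0.0, duration, n_sp))
        sr = state_phase.shuffle_test(spikes, strata, trace.time, span,
                                      n_shuffles=n_shuffles, rng=rng)
        for k, sig in sr.significant.items():
            if sr.rates[k] is not None:
                hits += sig
                total += 1
    return hits / total


def kuiper_type1_rate(n_runs: int = 1000, n_spikes: int = 100,
                      alpha: float = 0.05, seed: int = 0,
                      n_bins: int = 16) -> float:
    """Rejection rate of the occupancy-null Kuiper test when spikes follow
    the occupancy distribution exactly (no phase tuning)."""
    rng = np.random.default_rng(seed)
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    # non-uniform occupancy (protraction-heavy, as for real whisking)
    occupancy = 1.0 + 0.8 * np.cos(0.5 * (edges[:-1] + edges[1:]))
    p_bin = occupancy / occupancy.sum()
    rejections = 0
    for _ in range(n_runs):
        bins = rng.choice(n_bins, size=n_spikes, p=p_bin)
        phases = edges[bins] + rng.uniform(0.0, np.diff(edges)[0], n_spikes)
        _, p, _ = state_phase.kuiper_test(phases, occupancy, edges)
        rejections += p < alpha
    return rejections / n_runs


# ---------------------------------------------------------------------- #
# parameter recovery
# ---------------------------------------------------------------------- #

def _decompose_session(session):
    angle = whisking.normalize_angle(session.whisker_angle)
    trace0 = whisking.decompose(angle, session.whisker_time)
    angle = whisking.normalize_angle(session.whisker_angle, ~trace0.whisking_mask)
    return whisking.decompose(angle, session.whisker_time)


def recover_session_params(nucleus: str, seed: int, duration: float = 300.0) -> dict:
    """Recover latency, whisking gain and preferred phase from one session.

    First-spike latency is measured on unadapted puffs (inter-deflection
    interval >= 0.65 s, where the relay resource has recovered), matching
    how long-interval responses are analyzed.  The preferred phase is
    recovered from a free-whisking session of the same duration (several
    hundred whisk cycles, no deflection responses to contaminate the
    tuning), emulating the free-whisking periods of the paradigm.
    """
    params = NeuronParams.vpm_like() if nucleus == "VPM" else NeuronParams.pom_like()
    cfg = SyntheticConfig(duration=duration)
    session, truth = generate_session(cfg, params, seed, neuron_id=f"rec-{nucleus}-{seed}",
                                      nucleus_label=nucleus)
    trace = _decompose_session(session)
    puffs, delay = correct_puff_onsets(session.puff_command_times, trace)
    table = build_event_table(trace, puffs, session.touch_intervals,
                              recording_start=0.0)

    sel = (table["kind"] == "puff") & (table["interval_prev"] >= 0.65)
    lat_mean, lat_sd, _ = first_spike_latency(
        session.spike_times, table.loc[sel, "onset"].to_numpy())

    strata = state_phase.steady_state_mask(trace, table["onset"].to_numpy())
    sr = state_phase.state_rates(session.spike_times, strata, trace.time)
    rate_q = sr.rates[("Q", None)]
    rate_w = sr.rates[("W", None)]

    free_cfg = SyntheticConfig(duration=duration, block_cycle=("free",))
    free_session, _ = generate_session(free_cfg, params, seed,
                                       neuron_id=f"free-{nucleus}-{seed}",
                                       nucleus_label=nucleus)
    free_trace = _decompose_session(free_session)
    pt = state_phase.phase_tuning(free_session.spike_times, free_trace)
    pref_err = np.angle(np.exp(1j * (pt.fit_phase - params.phase_pref)))

    return {
        "latency_ms": lat_mean, "latency_sd_ms": lat_sd,
        "true_latency_ms": params.latency_ms,
        "rate_q_hz": rate_q, "rate_w_hz": rate_w,
        "gain_ratio": rate_w / rate_q if rate_q else None,
        "true_gain": params.whisking_gain,
        "phase_pref": pt.fit_phase, "phase_pref_err_rad": float(pref_err),
        "line_delay_ms": delay * 1000.0,
        "true_line_delay_ms": cfg.line_delay_ms,
        "n_long_interval_puffs": int(sel.sum()),
    }


def recover_first_spike_latency(nucleus: str, seed: int,
                                duration: float = 300.0) -> dict:
    """First-spike latency on ~300 unadapted quiescent puffs.

    A quiescent-background puff stream at long intervals (650/1,250 ms)
    keeps the relay resource recovered and the baseline at its quiescent
    rate, so the first-spike statistics reflect the response volley.
    """
    params = NeuronParams.vpm_like() if nucleus == "VPM" else NeuronParams.pom_like()
    cfg = SyntheticConfig(duration=duration, bout_rate=0.0,
                          puff_intervals_ms=(650.0, 1250.0),
                          block_cycle=("puff",))
    session, _ = generate_session(cfg, params, seed, neuron_id=f"lat-{nucleus}-{seed}")
    trace = _decompose_session(session)
    puffs, _ = correct_puff_onsets(session.puff_command_times, trace)
    mean, sd, lats = first_spike_latency(session.spike_times, puffs)
    return {"latency_ms": mean, "latency_sd_ms": sd, "n_events": int(puffs.size),
            "n_trials_with_spikes": int(lats.size),
            "true_latency_ms": params.latency_ms,
            "true_jitter_ms": params.jitter_ms}


def expected_quiescent_mi(params: NeuronParams, interval_s: float) -> float:
    """Closed-form expected quiescent-puff MI at a fixed inter-puff interval.

    The relay resource reaches the fixed point of
    r -> 1 - (1 - (1 - u) r) exp(-interval/tau); the 50-ms post window then
    holds base + deflection_rate * r_ss Hz against a base-only pre window.
    """
    decay = np.exp(-interval_s / params.depression_tau_s)
    r_ss = (1.0 - decay) / (1.0 - (1.0 - params.depression_u) * decay)
    post = params.base_rate_q + params.deflection_rate_hz * r_ss
    pre = params.base_rate_q
    return (post - pre) / (post + pre)


def recover_modulation_index(nucleus: str, seed: int, duration: float = 300.0,
                             interval_ms: float = 1250.0) -> dict:
    """Measured vs. expected quiescent-puff MI at a single long interval.

    A single candidate interval keeps the previous response out of the
    baseline window, so the measured MI can be compared with the
    closed-form expectation from the generator parameters.
    """
    params = NeuronParams.vpm_like() if nucleus == "VPM" else NeuronParams.pom_like()
    cfg = SyntheticConfig(duration=duration, puff_intervals_ms=(interval_ms,),
                          block_cycle=("puff",))
    session, _ = generate_session(cfg, params, seed, neuron_id=f"mi-{nucleus}-{seed}",
                                  nucleus_label=nucleus)
    trace = _decompose_session(session)
    puffs, _ = correct_puff_onsets(session.puff_command_times, trace)
    table = build_event_table(trace, puffs, recording_start=0.0)
    q_puffs = table.loc[table["pre_state"] == "Q", "onset"].to_numpy()
    st = response.response_test(session.spike_times, q_puffs, sidedness="greater")
    return {
        "mi": st.mi,
        "expected_mi": expected_quiescent_mi(params, interval_ms / 1000.0),
        "n_events": st.n_events,
    }


# ---------------------------------------------------------------------- #
# interval sensitivity (short-term depression contrast)
# ---------------------------------------------------------------------- #

def interval_sensitivity(depression_u: float, seed: int,
                         duration: float = 600.0) -> dict:
    """Depression signatures: interval-tertile MI and first-vs-later touches.

    The tertile contrast isolates the relay mechanism: a puff stream on a
    quiescent background, with candidate intervals of at least 150 ms so
    that one event's 50-ms response window never leaks into the next
    event's baseline window (in full sessions short intervals co-vary with
    whisking state and with such leakage, confounding the MI).  With a
    strongly depressing relay the longest-interval tertile responds while
    the shortest does not; without depression the tertile MIs are flat.
    First-vs-later-touch MIs come from a full default session, where the
    bout baseline (before the bout's first touch) is shared by both
    classes.
    """
    params = NeuronParams.pom_like(depression_u=depression_u,
                                   cortical_dependence=0.0)
    out: dict = {}

    # controlled puff stream, quiescent background
    cfg_q = SyntheticConfig(duration=duration, bout_rate=0.0,
                            puff_intervals_ms=(150.0, 350.0, 650.0, 1250.0),
                            block_cycle=("puff",))
    session, _ = generate_session(cfg_q, params, seed,
                                  neuron_id=f"dep-q-{depression_u}-{seed}")
    trace = _decompose_session(session)
    puffs, _ = correct_puff_onsets(session.puff_command_times, trace)
    table = build_event_table(trace, puffs, recording_start=0.0)
    labels, _, _ = tertile_split(table["interval_prev"].to_numpy())
    for tert in (0, 2):
        onsets = table.loc[labels == tert, "onset"].to_numpy()
        pre, post = trial_counts(session.spike_times, onsets)
        n = onsets.size
        out[f"mi_t{tert + 1}"] = modulation_index(pre.sum() / (n * 0.05),
                                                  post.sum() / (n * 0.05))

    # full session for the touch-bout contrast
    cfg = SyntheticConfig(duration=duration)
    session, _ = generate_session(cfg, params, seed,
                                  neuron_id=f"dep-{depression_u}-{seed}")
    trace = _decompose_session(session)
    puffs, _ = correct_puff_onsets(session.puff_command_times, trace)
    table = build_event_table(trace, puffs, session.touch_intervals,
                              recording_start=0.0)
    fl = first_vs_later_touch(
        [NeuronEvents("n", table, session.spike_times)], min_touches=10)
    if len(fl):
        out["mi_first"] = float(fl["mi_first"].iloc[0])
        out["mi_later"] = float(fl["mi_later"].iloc[0])
    return out


# ---------------------------------------------------------------------- #
# classification
# ---------------------------------------------------------------------- #

def classifier_cohort(n_per_class: int = 20, seed: int = 0,
                      duration: float = 120.0):
    """Puff/touch PSTH features for a separable VPM-like/POm-like cohort."""
    cfg = SyntheticConfig(duration=duration, block_cycle=("puff", "touch"))
    psths = {"puff": {}, "touch": {}}
    labels = {}
    for nuc, maker in (("VPM", NeuronParams.vpm_like), ("POm", NeuronParams.pom_like)):
        for i in range(n_per_class):
            nid = f"{nuc.lower()}-{i:02d}"
            session, _ = generate_session(cfg, maker(), seed + i,
                                          neuron_id=nid, nucleus_label=nuc)
            trace = _decompose_session(session)
            puffs, _ = correct_puff_onsets(session.puff_command_times, trace)
            psths["puff"][nid] = response.compute_psth(session.spike_times, puffs).rate
            t_on = (session.touch_intervals[:, 0]
                    if session.touch_intervals is not None else np.empty(0))
            if t_on.size >= 5:
                psths["touch"][nid] = response.compute_psth(session.spike_times, t_on).rate
            labels[nid] = nuc
    return psths, labels


def classifier_experiment(n_per_class: int = 20, seed: int = 0,
                          duration: float = 120.0, n_perm: int = 256,
                          n_seeds: int = 5, n_null: int = 5) -> dict:
    """Accuracy, permutation p and label-shuffle control on a synthetic cohort."""
    psths, labels = classifier_cohort(n_per_class, seed, duration)
    X, ids = classify.build_feature_matrix(psths, ["puff", "touch"])
    y = np.array([labels[i] for i in ids])

    accs = [classify.train_and_test(X, y, seed + k).test_accuracy
            for k in range(n_seeds)]
    perm_p = classify.permutation_significance(X, y, seed, n_perm=n_perm,
                                               observed=accs[0])
    rng = np.random.default_rng(seed)
    null_accs = [classify.train_and_test(X, rng.permutation(y), seed + 1000 + k
                                         ).test_accuracy for k in range(n_null)]
    return {
        "mean_accuracy": float(np.mean(accs)),
        "min_accuracy": float(np.min(accs)),
        "permutation_p": float(perm_p),
        "null_accuracy": float(np.mean(null_accs)),
    }
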