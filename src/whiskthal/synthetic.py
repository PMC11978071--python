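"""Synthetic recording sessions with the statistical structure the analysis assumes.

The generator emulates an awake head-fixed mouse whisking freely against an
occasional pole while a single whisker receives 30-ms air puffs:

* bout-structured whisking: a 3-30 Hz band sinusoid (default 9 Hz, i.e., a
  ~111 ms whisk cycle) whose peak-to-trough envelope turns on and off in
  bouts, riding on an elevated setpoint, plus sub-threshold angle noise;
* air puffs at intervals drawn from a small candidate set spanning
  50-1,250 ms, reaching the whisker after a fixed command-line delay and
  adding a brief retraction transient to the angle;
* touches only when the protracted whisker crosses a pole angle that only
  large-amplitude whisks reach; touches bend the whisker (curvature rises
  with over-protraction) and darken a synthetic touch-area brightness trace;
* spikes from an inhomogeneous Poisson baseline whose rate depends on
  whisking state, whisking amplitude and whisk phase, plus per-deflection
  response volleys whose gain passes through a single depressing relay
  (resource u/tau dynamics) so that responses vanish at short
  inter-deflection intervals when depression is strong (POm-like), and a
  "cortical dependence" factor that removes baseline and deflection gain
  while the laser silences cortex.

Every generator returns its ground truth (per-sample state/phase/amplitude,
true event times, per-event relay resource) so each analysis stage can be
tested against known parameters.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .session_io import RecordingSession

__all__ = [
    "SyntheticConfig",
    "NeuronParams",
    "WhiskingGroundTruth",
    "DeflectionGroundTruth",
    "generate_whisking_trace",
    "generate_deflection_events",
    "generate_laser_intervals",
    "generate_spike_train",
    "generate_session",
]


class ConfigError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic session.

    Defaults follow the recorded paradigm: 625 Hz video, ~9 Hz whisking
    (111 ms cycles), 30 ms puffs at five candidate intervals between 50 and
    1,250 ms, a pole reachable only by large-amplitude whisks, and an
    18-20 ms puff command line delay.
    """

    duration: float = 300.0           # s
    fs: float = 625.0                 # video rate, Hz
    block_cycle: tuple[str, ...] = ("puff", "touch", "free")
    block_duration_s: float = 60.0    # puff / touch / free-whisking periods alternate
    whisk_freq_hz: float = 9.0        # mean whisking frequency
    bout_rate: float = 0.3            # bout onsets per second of quiescence
    bout_duration: tuple[float, float] = (1.0, 3.0)   # s, uniform
    bout_amplitude: float = 20.0      # deg peak-to-trough, mean across bouts
    bout_amplitude_jitter: float = 0.4  # relative half-range of per-bout amplitude
    setpoint_shift: float = 5.0       # deg setpoint elevation at full envelope
    ramp_s: float = 0.15              # envelope on/off ramp
    quiescent_noise_deg: float = 0.3  # s.d. of sub-threshold angle noise
    puff_intervals_ms: tuple[float, ...] = (50.0, 150.0, 350.0, 650.0, 1250.0)
    puff_duration_ms: float = 30.0
    puff_deflection_deg: float = 8.0  # magnitude of the puff retraction transient
    line_delay_ms: float = 19.0       # command-to-whisker delay
    pole_angle_deg: float = 10.0      # protraction threshold at which touch occurs
    curvature_gain: float = 0.05      # 1/mm per degree of over-protraction
    curvature_noise: float = 0.002    # 1/mm baseline curvature noise s.d.

    def validate(self) -> None:
        if not self.duration > 0:
            raise ConfigError("duration must be positive")
        iv = np.asarray(self.puff_intervals_ms, float)
        if np.any(iv < 50.0) or np.any(iv > 1250.0):
            raise ConfigError("puff intervals must lie within [50, 1250] ms")
        if not self.bout_amplitude > 3.0:
            raise ConfigError("bout_amplitude must exceed the 3 deg whisking threshold")
        if self.bout_rate > 0 and self.pole_angle_deg <= 5.0 * self.quiescent_noise_deg:
            raise ConfigError("pole_angle_deg within the quiescent noise range: "
                              "touches would be continuous")


@dataclass
class NeuronParams:
    """Generative rate model for one neuron.

    Baseline (Hz): base_rate_q * whisking_gain**[whisking] *
    (1 + amp_slope * amplitude / base_rate_q), scaled by
    (1 - cortical_dependence) while the laser is on.  A phase drive
    phase_mod_depth * base * cos(phase - phase_pref) is added during
    whisking and is NOT gated by the laser (phase information arrives from
    the brainstem, not the cortex).  Each deflection releases a response
    volley of Poisson(nu * resource) spikes at a shared latency
    N(latency_ms, jitter_ms), with nu = deflection_rate_hz * 50 ms; the
    relay resource depletes by fraction ``u`` per deflection and recovers
    with time constant ``depression_tau_s``.
    """

    base_rate_q: float = 6.0          # Hz during quiescence
    whisking_gain: float = 2.0        # x rate during whisking
    amp_slope: float = 0.0            # Hz per degree of whisking amplitude
    phase_pref: float = 0.0           # rad, 0 = fully protracted
    phase_mod_depth: float = 0.3      # in [0, 1]
    deflection_rate_hz: float = 42.0  # added rate over the 50-ms response window
    latency_ms: float = 15.0          # mean response latency
    jitter_ms: float = 10.0           # s.d. of response latency
    depression_u: float = 0.3         # resource fraction used per relayed deflection
    depression_tau_s: float = 0.3     # resource recovery time constant
    cortical_dependence: float = 0.0  # fraction of baseline removed during silencing
    deflection_cortical_dependence: Optional[float] = None
    # fraction of the deflection volley removed during silencing; defaults to
    # cortical_dependence.  For a higher-order (POm-like) relay the deflection
    # response arrives through cortex and is nearly abolished by silencing,
    # while the baseline has mixed cortical/brainstem origin and only drops
    # partially -- scaling both by the same factor would leave the (scale
    # invariant) modulation index untouched.

    def validate(self) -> None:
        if min(self.base_rate_q, self.deflection_rate_hz) < 0:
            raise ConfigError("rates must be >= 0")
        if not 0.0 <= self.depression_u <= 1.0:
            raise ConfigError("depression_u must be in [0, 1]")
        if not self.depression_tau_s > 0:
            raise ConfigError("depression_tau_s must be positive")
        if not 0.0 <= self.cortical_dependence <= 1.0:
            raise ConfigError("cortical_dependence must be in [0, 1]")
        if self.deflection_cortical_dependence is not None and \
                not 0.0 <= self.deflection_cortical_dependence <= 1.0:
            raise ConfigError("deflection_cortical_dependence must be in [0, 1]")

    @property
    def deflection_dependence(self) -> float:
        if self.deflection_cortical_dependence is None:
            return self.cortical_dependence
        return self.deflection_cortical_dependence

    @classmethod
    def vpm_like(cls, **kw) -> "NeuronParams":
        """First-order relay: fast, precise, kinematics-faithful, weakly depressing."""
        return cls(**{**dict(deflection_rate_hz=42.0, latency_ms=15.0, jitter_ms=10.0,
                             depression_u=0.3, depression_tau_s=0.3,
                             cortical_dependence=0.0, phase_pref=0.5), **kw})

    @classmethod
    def pom_like(cls, **kw) -> "NeuronParams":
        """Higher-order relay: slower, strongly depressing, cortex-dependent."""
        return cls(**{**dict(deflection_rate_hz=21.0, latency_ms=27.0, jitter_ms=15.0,
                             depression_u=0.8, depression_tau_s=1.5,
                             cortical_dependence=0.6,
                             deflection_cortical_dependence=0.95,
                             phase_pref=-2.0), **kw})


@dataclass
class WhiskingGroundTruth:
    time: np.ndarray
    angle: np.ndarray         # behavior-only angle (no puff transients)
    angle_clean: np.ndarray   # noiseless angle for touch geometry
    phase: np.ndarray         # rad, wrapped, 0 = fully protracted
    amplitude: np.ndarray     # deg peak-to-trough envelope
    setpoint: np.ndarray      # deg
    state: np.ndarray         # bool, True = whisking (amplitude > 3 deg)
    bouts: list = field(default_factory=list)   # (t_on, t_off, amp)


@dataclass
class DeflectionGroundTruth:
    puff_command_times: np.ndarray
    puff_onsets: np.ndarray           # command + line delay
    touch_intervals: np.ndarray       # (n, 2)
    brightness: np.ndarray
    angle: np.ndarray                 # angle with puff transients added
    curvature: np.ndarray


def generate_whisking_trace(config: SyntheticConfig, rng) -> WhiskingGroundTruth:
    """Bout-gated sinusoidal whisking with ground-truth decomposition."""
    config.validate()
    rng = np.random.default_rng(rng)
    n = int(round(config.duration * config.fs))
    time = np.arange(n) / config.fs

    env = np.zeros(n)
    bouts = []
    if config.bout_rate > 0:
        t = rng.exponential(1.0 / config.bout_rate)
        while t < config.duration:
            dur = rng.uniform(*config.bout_duration)
            j = config.bout_amplitude_jitter
            amp = config.bout_amplitude * rng.uniform(1.0 - j, 1.0 + j)
            i0 = int(t * config.fs)
            i1 = min(n, int((t + dur) * config.fs))
            if i1 > i0:
                seg = np.ones(i1 - i0)
                nr = max(1, int(config.ramp_s * config.fs))
                nr = min(nr, seg.size // 2)
                ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(nr) / nr))
                seg[:nr] = ramp
                seg[seg.size - nr:] = ramp[::-1]
                env[i0:i1] = np.maximum(env[i0:i1], amp * seg)
                bouts.append((time[i0], time[i1 - 1] + 1.0 / config.fs, amp))
            t = t + dur + rng.exponential(1.0 / config.bout_rate)

    phi = 2.0 * np.pi * config.whisk_freq_hz * time + rng.uniform(0.0, 2.0 * np.pi)
    setpoint = config.setpoint_shift * env / max(config.bout_amplitude, 1e-9)
    angle_clean = setpoint + 0.5 * env * np.cos(phi)
    angle = angle_clean + rng.normal(0.0, config.quiescent_noise_deg, n)

    phase = np.mod(phi + np.pi, 2.0 * np.pi) - np.pi
    return WhiskingGroundTruth(
        time=time, angle=angle, angle_clean=angle_clean, phase=phase,
        amplitude=env, setpoint=setpoint, state=env > 3.0, bouts=bouts,
    )


def _block_schedule(config: SyntheticConfig):
    """(start, stop, kind) stimulation blocks cycling through block_cycle."""
    out, t, k = [], 0.0, 0
    if not config.block_cycle:
        return [(0.0, config.duration, "puff")]
    while t < config.duration:
        t1 = min(t + config.block_duration_s, config.duration)
        out.append((t, t1, config.block_cycle[k % len(config.block_cycle)]))
        t, k = t1, k + 1
    return out


def _alpha_kernel(t: np.ndarray, tau: float) -> np.ndarray:
    out = np.zeros_like(t)
    pos = t > 0
    out[pos] = (t[pos] / tau) * np.exp(1.0 - t[pos] / tau)
    return out


def generate_deflection_events(
    truth: WhiskingGroundTruth, config: SyntheticConfig, rng
) -> DeflectionGroundTruth:
    """Puff times, touch intervals, brightness and kinematic consequences.

    Puff inter-command intervals are sampled uniformly from the candidate
    set; each puff adds a fast retraction (negative-angle) alpha transient
    after the line delay.  Touches are the maximal intervals where the
    noiseless protraction exceeds the pole angle during whisking; curvature
    rises proportionally to the over-protraction during touch and the
    touch-area brightness drops by a fixed amount (pole occlusion stand-in).
    """
    config.validate()
    rng = np.random.default_rng(rng)
    fs, n = config.fs, truth.time.size
    intervals_s = np.asarray(config.puff_intervals_ms, float) / 1000.0

    # stimulation blocks alternate: puffs, pole-in-reach (touch), free whisking
    blocks = _block_schedule(config)

    cmds = []
    for b0, b1, kind in blocks:
        if kind != "puff":
            continue
        t = b0 + 0.5
        while t < b1 - 0.05:
            cmds.append(t)
            t += float(rng.choice(intervals_s))
    cmds = np.asarray(cmds)
    onsets = cmds + config.line_delay_ms / 1000.0

    angle = truth.angle.copy()
    kern_t = np.arange(0, int(0.08 * fs)) / fs
    kern = _alpha_kernel(kern_t, 0.010)
    for on in onsets:
        i0 = int(round(on * fs))
        i1 = min(n, i0 + kern.size)
        if i0 < n:
            angle[i0:i1] -= config.puff_deflection_deg * kern[: i1 - i0]

    pole_in = np.zeros(n, bool)
    for b0, b1, kind in blocks:
        if kind == "touch":
            pole_in[int(b0 * fs): int(b1 * fs)] = True
    touch_mask = truth.state & pole_in & (truth.angle_clean > config.pole_angle_deg)
    ivals = []
    d = np.diff(np.concatenate([[0], touch_mask.astype(np.int8), [0]]))
    for i0, i1 in zip(np.nonzero(d == 1)[0], np.nonzero(d == -1)[0]):
        ivals.append((truth.time[i0], truth.time[i1 - 1] + 1.0 / fs))
    touch_intervals = np.asarray(ivals).reshape(-1, 2)

    brightness = np.full(n, 100.0) - 40.0 * touch_mask
    curvature = rng.normal(0.0, config.curvature_noise, n)
    over = np.clip(truth.angle_clean - config.pole_angle_deg, 0.0, None)
    curvature += config.curvature_gain * over * touch_mask
    # puffs bend the whisker passively as well (larger curvature, opposite sign)
    for on in onsets:
        i0 = int(round(on * fs))
        i1 = min(n, i0 + kern.size)
        if i0 < n:
            curvature[i0:i1] -= 1.5 * config.curvature_gain * \
                config.puff_deflection_deg * kern[: i1 - i0]

    return DeflectionGroundTruth(
        puff_command_times=cmds, puff_onsets=onsets, touch_intervals=touch_intervals,
        brightness=brightness, angle=angle, curvature=curvature,
    )


def generate_laser_intervals(duration: float, rng, *,
                             on_range=(0.11, 2.0), off_range=(0.24, 5.0)) -> np.ndarray:
    """Randomized cortical-silencing laser schedule (on/off second pairs)."""
    rng = np.random.default_rng(rng)
    out = []
    t = float(rng.uniform(*off_range))
    while t < duration:
        dur = float(rng.uniform(*on_range))
        out.append((t, min(t + dur, duration)))
        t += dur + float(rng.uniform(*off_range))
    return np.asarray(out).reshape(-1, 2)


def _in_intervals(times: np.ndarray, intervals: Optional[np.ndarray]) -> np.ndarray:
    if intervals is None or len(intervals) == 0:
        return np.zeros(np.size(times), dtype=bool)
    edges = np.asarray(intervals, float).ravel()
    return np.searchsorted(edges, times, side="right") % 2 == 1


def generate_spike_train(
    truth: WhiskingGroundTruth,
    events: Optional[DeflectionGroundTruth],
    params: NeuronParams,
    rng,
    laser_intervals: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, dict]:
    """Sample a spike train; returns (spike_times, ground_truth_record).

    The baseline is sampled bin-wise as an inhomogeneous Poisson process on
    the video grid; deflection volleys are added per event with the
    depression-gated gain.  Negative instantaneous rates (deep troughs of
    the phase drive) are clipped at zero and counted; >1% clipped samples
    triggers a warning.
    """
    params.validate()
    rng = np.random.default_rng(rng)
    t = truth.time
    dt = float(t[1] - t[0])

    w = truth.state
    base = params.base_rate_q * np.where(w, params.whisking_gain, 1.0)
    if params.base_rate_q > 0:
        base = base * (1.0 + params.amp_slope * truth.amplitude / params.base_rate_q)
    laser_on = _in_intervals(t, laser_intervals)
    base = base * np.where(laser_on, 1.0 - params.cortical_dependence, 1.0)

    phase_amp = params.phase_mod_depth * params.base_rate_q * \
        np.where(w, params.whisking_gain, 0.0)
    rate = base + phase_amp * np.cos(truth.phase - params.phase_pref) * w

    clipped = rate < 0
    if clipped.mean() > 0.01:
        warnings.warn(f"{clipped.mean():.1%} of rate samples clipped at zero")
    rate = np.clip(rate, 0.0, None)

    counts = rng.poisson(rate * dt)
    idx = np.repeat(np.arange(t.size), counts)
    spikes = t[idx] + rng.uniform(0.0, dt, idx.size)

    event_record = []
    if events is not None:
        onsets = np.sort(np.concatenate([
            events.puff_onsets,
            events.touch_intervals[:, 0] if events.touch_intervals.size else np.empty(0),
        ]))
        # resource is shared across puffs and touches (single depressing relay)
        ev_laser = _in_intervals(onsets, laser_intervals)
        nu_full = params.deflection_rate_hz * 0.050
        resource = 1.0
        t_prev = None
        ev_spikes = []
        for on, lz in zip(onsets, ev_laser):
            if t_prev is not None:
                resource = 1.0 - (1.0 - resource) * np.exp(-(on - t_prev) / params.depression_tau_s)
            gain = (1.0 - params.deflection_dependence) if lz else 1.0
            nu = nu_full * resource * gain
            k = rng.poisson(nu)
            if k:
                # right-skewed latency with mean latency_ms and s.d. jitter_ms
                shape = (params.latency_ms / params.jitter_ms) ** 2
                scale = params.jitter_ms ** 2 / params.latency_ms
                lat = max(0.002, rng.gamma(shape, scale) / 1000.0)
                ev_spikes.append(on + lat + rng.normal(0.0, 0.001, k))
            event_record.append({"onset": float(on), "resource": float(resource),
                                 "laser_on": bool(lz), "n_spikes": int(k)})
            resource *= (1.0 - params.depression_u)
            t_prev = on
        if ev_spikes:
            spikes = np.concatenate([spikes] + ev_spikes)

    spikes = np.sort(spikes)
    spikes = spikes[(spikes >= t[0]) & (spikes <= t[-1] + dt)]
    # enforce strictly increasing times (ties have measure zero but guard anyway)
    if spikes.size > 1:
        dup = np.diff(spikes) <= 0
        while dup.any():
            spikes[1:][dup] += 1e-9
            spikes = np.sort(spikes)
            dup = np.diff(spikes) <= 0

    record = {"events": event_record, "clipped_fraction": float(clipped.mean())}
    return spikes, record


def generate_session(
    config: SyntheticConfig,
    params: NeuronParams,
    seed,
    *,
    neuron_id: str = "syn-000",
    animal_id: str = "mouse-0",
    nucleus_label: str = "unknown",
    with_laser: bool = False,
) -> tuple[RecordingSession, dict]:
    """Compose the generators into a validated RecordingSession + ground truth.

    One random generator per session is keyed by (seed, neuron_id) so
    cohorts of neurons are independent yet reproducible.
    """
    rng = np.random.default_rng([int(seed) % (2**31), zlib.crc32(neuron_id.encode())])
    truth = generate_whisking_trace(config, rng)
    events = generate_deflection_events(truth, config, rng)
    laser = generate_laser_intervals(config.duration, rng) if with_laser else None
    spikes, spike_truth = generate_spike_train(truth, events, params, rng,
                                               laser_intervals=laser)

    session = RecordingSession(
        neuron_id=neuron_id,
        animal_id=animal_id,
        nucleus_label=nucleus_label,
        spike_times=spikes,
        whisker_time=truth.time,
        whisker_angle=events.angle,
        whisker_curvature=events.curvature,
        brightness_trace=events.brightness,
        puff_command_times=events.puff_command_times,
        touch_intervals=events.touch_intervals if events.touch_intervals.size else None,
        laser_intervals=laser,
        recording_span=(0.0, config.duration),
    )
    ground_truth = {
        "state": truth.state,
        "phase": truth.phase,
        "amplitude": truth.amplitude,
        "setpoint": truth.setpoint,
        "bouts": truth.bouts,
        "puff_onsets": events.puff_onsets,
        "line_delay_s": config.line_delay_ms / 1000.0,
        "touch_intervals": events.touch_intervals,
        "spike_truth": spike_truth,
        "params": params,
        "config": config,
    }
    return session, ground_truth
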