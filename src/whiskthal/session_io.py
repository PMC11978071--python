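"""Session data model and on-disk bundle format.

A recording session is the pipeline's unit of work: one neuron's spike
times (seconds, from 20 kHz electrophysiology) together with the whisker
angle/curvature time series (nominal 625 Hz video), air-puff command times,
touch on/off intervals (or a raw touch-area brightness trace), optional
laser on/off intervals, and metadata.

On disk a session is a plain directory of CSV tables plus ``metadata.json``
so bundles are inspectable and diff-able:

    spikes.csv    one column ``t``
    whisker.csv   ``time, angle, curvature`` and optionally ``brightness``
    events.csv    ``kind, on, off`` with kind in {puff_command, touch}
    laser.csv     ``on, off`` (optional)
    metadata.json ids, nucleus label, recording span

All times are seconds (float64).  Intervals are half-open ``[on, off)``.
Floats are serialized with 17 significant digits so a write/read round trip
is bit exact.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "RecordingSession",
    "SessionValidationError",
    "SessionLoadError",
    "read_session",
    "write_session",
    "write_results",
]

_FLOAT_FMT = "%.17g"
_VIDEO_RATE = 625.0

NUCLEI = ("VPM", "POm", "unknown")


class SessionValidationError(ValueError):
    """An invariant of the session data model is violated."""


class SessionLoadError(IOError):
    """A mandatory table or field is missing from a session bundle."""


def _as_float_array(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        raise SessionValidationError(f"{name} must be 1-D, got shape {a.shape}")
    return a


def _as_intervals(x, name: str) -> Optional[np.ndarray]:
    if x is None:
        return None
    a = np.asarray(x, dtype=float)
    if a.size == 0:
        return np.empty((0, 2), dtype=float)
    if a.ndim != 2 or a.shape[1] != 2:
        raise SessionValidationError(f"{name} must be an (n, 2) array of (on, off) pairs")
    return a


@dataclass
class RecordingSession:
    """One neuron's spikes + behavior + event streams + metadata.

    Positive whisker angle is protraction (rostral movement); curvature is
    stored signed in 1/mm, absolute values are taken downstream where needed.
    """

    neuron_id: str
    animal_id: str
    nucleus_label: str
    spike_times: np.ndarray
    whisker_time: np.ndarray
    whisker_angle: np.ndarray
    whisker_curvature: np.ndarray
    puff_command_times: np.ndarray
    recording_span: tuple[float, float]
    touch_intervals: Optional[np.ndarray] = None
    brightness_trace: Optional[np.ndarray] = None
    laser_intervals: Optional[np.ndarray] = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spike_times = _as_float_array(self.spike_times, "spike_times")
        self.whisker_time = _as_float_array(self.whisker_time, "whisker_time")
        self.whisker_angle = _as_float_array(self.whisker_angle, "whisker_angle")
        self.whisker_curvature = _as_float_array(self.whisker_curvature, "whisker_curvature")
        self.puff_command_times = _as_float_array(self.puff_command_times, "puff_command_times")
        self.touch_intervals = _as_intervals(self.touch_intervals, "touch_intervals")
        self.laser_intervals = _as_intervals(self.laser_intervals, "laser_intervals")
        if self.brightness_trace is not None:
            self.brightness_trace = _as_float_array(self.brightness_trace, "brightness_trace")
        self.recording_span = (float(self.recording_span[0]), float(self.recording_span[1]))
        self.validate()

    # ------------------------------------------------------------------ #
    def validate(self) -> None:
        """Check all data-model invariants; raise SessionValidationError."""
        if self.nucleus_label not in NUCLEI:
            raise SessionValidationError(
                f"nucleus_label must be one of {NUCLEI}, got {self.nucleus_label!r}"
            )
        t0, t1 = self.recording_span
        if not t1 > t0:
            raise SessionValidationError("recording_span must satisfy t0 < t1")

        for name in ("spike_times", "puff_command_times"):
            a = getattr(self, name)
            if a.size > 1:
                bad = np.nonzero(np.diff(a) <= 0)[0]
                if bad.size:
                    raise SessionValidationError(
                        f"{name} not strictly increasing at index {int(bad[0]) + 1}"
                    )
            if a.size and (a[0] < t0 or a[-1] > t1):
                idx = 0 if a[0] < t0 else int(a.size - 1)
                raise SessionValidationError(
                    f"{name}[{idx}] outside recording_span {self.recording_span}"
                )

        wt = self.whisker_time
        n = wt.size
        if n < 2:
            raise SessionValidationError("whisker_time needs at least 2 samples")
        for name in ("whisker_angle", "whisker_curvature"):
            if getattr(self, name).size != n:
                raise SessionValidationError(f"{name} length differs from whisker_time")
        if self.brightness_trace is not None and self.brightness_trace.size != n:
            raise SessionValidationError("brightness_trace length differs from whisker_time")
        dt = np.diff(wt)
        nominal = 1.0 / _VIDEO_RATE
        if np.any(np.abs(dt - nominal) > 0.01 * nominal):
            idx = int(np.argmax(np.abs(dt - nominal)))
            raise SessionValidationError(
                f"whisker_time not uniform at 625 Hz within 1% (sample {idx})"
            )
        if wt[0] < t0 - nominal or wt[-1] > t1 + nominal:
            raise SessionValidationError("whisker_time outside recording_span")

        for name in ("touch_intervals", "laser_intervals"):
            iv = getattr(self, name)
            if iv is None or iv.size == 0:
                continue
            if np.any(iv[:, 0] >= iv[:, 1]):
                idx = int(np.nonzero(iv[:, 0] >= iv[:, 1])[0][0])
                raise SessionValidationError(f"{name}[{idx}] has on >= off")
            if np.any(iv[1:, 0] < iv[:-1, 1]):
                idx = int(np.nonzero(iv[1:, 0] < iv[:-1, 1])[0][0])
                raise SessionValidationError(f"{name} overlaps/unsorted at pair {idx + 1}")

    @property
    def video_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.whisker_time)))

    @property
    def duration(self) -> float:
        return self.recording_span[1] - self.recording_span[0]


# ---------------------------------------------------------------------- #
# bundle I/O
# ---------------------------------------------------------------------- #

def write_session(session: RecordingSession, path) -> Path:
    """Write a session bundle directory; returns the bundle path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    meta = {
        "neuron_id": session.neuron_id,
        "animal_id": session.animal_id,
        "nucleus_label": session.nucleus_label,
        "recording_span": list(session.recording_span),
        "has_brightness": session.brightness_trace is not None,
        "has_touches": session.touch_intervals is not None,
        "has_laser": session.laser_intervals is not None,
    }
    (path / "metadata.json").write_text(json.dumps(meta, indent=2))

    pd.DataFrame({"t": session.spike_times}).to_csv(
        path / "spikes.csv", index=False, float_format=_FLOAT_FMT
    )

    wcols = {
        "time": session.whisker_time,
        "angle": session.whisker_angle,
        "curvature": session.whisker_curvature,
    }
    if session.brightness_trace is not None:
        wcols["brightness"] = session.brightness_trace
    pd.DataFrame(wcols).to_csv(path / "whisker.csv", index=False, float_format=_FLOAT_FMT)

    rows = [("puff_command", t, t) for t in session.puff_command_times]
    if session.touch_intervals is not None:
        rows += [("touch", on, off) for on, off in session.touch_intervals]
    pd.DataFrame(rows, columns=["kind", "on", "off"]).to_csv(
        path / "events.csv", index=False, float_format=_FLOAT_FMT
    )

    if session.laser_intervals is not None:
        pd.DataFrame(session.laser_intervals, columns=["on", "off"]).to_csv(
            path / "laser.csv", index=False, float_format=_FLOAT_FMT
        )
    return path


def read_session(path) -> RecordingSession:
    """Read and validate a session bundle written by :func:`write_session`."""
    path = Path(path)
    for fname in ("metadata.json", "spikes.csv", "whisker.csv", "events.csv"):
        if not (path / fname).exists():
            raise SessionLoadError(f"session bundle {path} is missing {fname}")

    meta = json.loads((path / "metadata.json").read_text())
    for key in ("neuron_id", "animal_id", "nucleus_label", "recording_span"):
        if key not in meta:
            raise SessionLoadError(f"metadata.json is missing field {key!r}")

    spikes = pd.read_csv(path / "spikes.csv", float_precision="round_trip")
    if "t" not in spikes.columns:
        raise SessionLoadError("spikes.csv must have a column 't'")

    whisker = pd.read_csv(path / "whisker.csv", float_precision="round_trip")
    for col in ("time", "angle", "curvature"):
        if col not in whisker.columns:
            raise SessionLoadError(f"whisker.csv must have a column {col!r}")

    events = pd.read_csv(path / "events.csv", float_precision="round_trip")
    if events.empty:
        puffs = np.empty(0)
        touches = None
    else:
        puffs = events.loc[events["kind"] == "puff_command", "on"].to_numpy(float)
        tmask = events["kind"] == "touch"
        touches = events.loc[tmask, ["on", "off"]].to_numpy(float) if tmask.any() else None
    if touches is None and meta.get("has_touches"):
        touches = np.empty((0, 2))

    laser = None
    if (path / "laser.csv").exists():
        laser = pd.read_csv(path / "laser.csv", float_precision="round_trip")[["on", "off"]].to_numpy(float)

    return RecordingSession(
        neuron_id=str(meta["neuron_id"]),
        animal_id=str(meta["animal_id"]),
        nucleus_label=str(meta["nucleus_label"]),
        spike_times=spikes["t"].to_numpy(float),
        whisker_time=whisker["time"].to_numpy(float),
        whisker_angle=whisker["angle"].to_numpy(float),
        whisker_curvature=whisker["curvature"].to_numpy(float),
        brightness_trace=(
            whisker["brightness"].to_numpy(float) if "brightness" in whisker.columns else None
        ),
        puff_command_times=puffs,
        touch_intervals=touches,
        laser_intervals=laser,
        recording_span=tuple(meta["recording_span"]),
    )


# ---------------------------------------------------------------------- #
# result tables
# ---------------------------------------------------------------------- #

def write_results(results, path, *, config: Optional[dict] = None,
                  seed: Optional[int] = None) -> Path:
    """Write flat result tables plus a machine-readable run manifest.

    ``results`` is a list of per-neuron record dicts (one row per neuron x
    condition x statistic after flattening); an empty list writes the
    manifest only.
    """
    from whiskthal import __version__

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "whiskthal",
        "version": __version__,
        "seed": seed,
        "config": config,
        "n_records": len(results),
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    if results:
        pd.DataFrame(results).to_csv(path / "results.csv", index=False, float_format=_FLOAT_FMT)
    return path
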