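"""Domain types, the canonical joint-torque load set, and session/report I/O.

A *session* is one recorded hemisphere's worth of trials: every trial applies
one of eight step-torque load combinations to either the contralateral or the
ipsilateral limb (relative to the recorded hemisphere).  Spike times are stored
per neuron per trial at 1 ms resolution; optional EMG and hand-kinematic
channels ride along as long-format series.

On-disk layout (UTF-8 CSV, header row required):

``trials.csv``
    trial_id,context,shoulder_torque_nm,elbow_torque_nm,perturb_time_ms,trial_end_ms
``spikes.csv``
    neuron_id,trial_id,spike_time_ms        (one row per spike)
``emg.csv`` / ``kin.csv`` (optional)
    channel,trial_id,time_ms,value          (plus a sidecar ``*_rate.json``)
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CONTEXTS = ("contra", "ipsi")

#: torque magnitude (Nm) of single-joint loads
SINGLE_JOINT_NM = 0.20
#: torque magnitude (Nm) at each joint for multi-joint loads
MULTI_JOINT_NM = 0.14


class SessionFormatError(ValueError):
    """Raised when on-disk session data violates the documented layout."""


@dataclass(frozen=True)
class LoadCombination:
    """One of the eight step-torque loads, a point in joint-torque space.

    Flexion torques are positive at both joints; ``angle`` is measured
    counter-clockwise from the shoulder-torque axis (elbow axis = 90 deg).
    """

    index: int
    shoulder_torque: float  # Nm
    elbow_torque: float  # Nm

    @property
    def angle(self) -> float:
        """Direction in joint-torque space, degrees in [0, 360)."""
        return math.degrees(
            math.atan2(self.elbow_torque, self.shoulder_torque)
        ) % 360.0

    @property
    def torque_vector(self) -> np.ndarray:
        return np.array([self.shoulder_torque, self.elbow_torque])


def canonical_load_set() -> list[LoadCombination]:
    """The eight load combinations, ordered by angle (0, 45, ..., 315 deg).

    Single-joint loads (SF, EF, SE, EE) have |torque| = 0.20 Nm at one joint;
    multi-joint loads have |torque| = 0.14 Nm at both joints.
    """
    loads = []
    for i in range(8):
        angle = 45.0 * i
        if i % 2 == 0:  # single joint: on an axis
            s = SINGLE_JOINT_NM * round(math.cos(math.radians(angle)))
            e = SINGLE_JOINT_NM * round(math.sin(math.radians(angle)))
        else:  # multi joint: diagonal
            s = MULTI_JOINT_NM * round(math.copysign(1.0, math.cos(math.radians(angle))))
            e = MULTI_JOINT_NM * round(math.copysign(1.0, math.sin(math.radians(angle))))
        loads.append(LoadCombination(index=i, shoulder_torque=s + 0.0, elbow_torque=e + 0.0))
    return loads


def match_load(shoulder_nm: float, elbow_nm: float, tol: float = 1e-9) -> LoadCombination:
    """Map a torque pair to the canonical load set, or raise."""
    for load in canonical_load_set():
        if (
            abs(load.shoulder_torque - shoulder_nm) <= tol
            and abs(load.elbow_torque - elbow_nm) <= tol
        ):
            return load
    raise SessionFormatError(
        f"torque pair ({shoulder_nm}, {elbow_nm}) Nm does not match any "
        "canonical load combination"
    )


@dataclass(frozen=True)
class TrialRecord:
    """Metadata for one trial; times in ms from trial start."""

    trial_id: int
    context: str  # "contra" | "ipsi"
    load: LoadCombination
    perturb_time_ms: int
    trial_end_ms: int

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS:
            raise SessionFormatError(
                f"trial {self.trial_id}: context {self.context!r} not in {CONTEXTS}"
            )
        if self.perturb_time_ms < 500:
            raise SessionFormatError(
                f"trial {self.trial_id}: perturbation at {self.perturb_time_ms} ms "
                "precedes the minimum 500 ms unloaded hold"
            )
        if self.trial_end_ms - self.perturb_time_ms < 1300:
            raise SessionFormatError(
                f"trial {self.trial_id}: only {self.trial_end_ms - self.perturb_time_ms} ms "
                "follow the perturbation; >= 1300 ms required for the "
                "perturbation and steady-state epochs"
            )


@dataclass(frozen=True)
class EpochWindows:
    """Analysis epochs relative to load onset (half-open [start, end) ms).

    ``steady_state_ms`` is the duration of the steady-state epoch, anchored to
    the *end* of each trial (the last 1000 ms by default).
    """

    baseline: tuple[int, int] = (-200, 0)
    perturbation: tuple[int, int] = (0, 300)
    steady_state_ms: int = 1000

    def __post_init__(self) -> None:
        if self.baseline[1] - self.baseline[0] != 200:
            raise ValueError("baseline window must span exactly 200 ms")
        if self.perturbation[1] - self.perturbation[0] != 300:
            raise ValueError("perturbation window must span exactly 300 ms")
        if self.steady_state_ms != 1000:
            raise ValueError("steady-state window must span exactly 1000 ms")


@dataclass
class Session:
    """All trials of one recording, with per-neuron per-trial spike times (ms).

    ``spikes[neuron_id][trial_id]`` is a sorted int array of spike times within
    [0, trial_end).  Optional peripheral channels: ``emg[channel][trial_id]``
    and ``kinematics[channel][trial_id]`` are sampled series at ``emg_rate_hz``
    / ``kin_rate_hz``.
    """

    trials: list[TrialRecord]
    spikes: dict[int, dict[int, np.ndarray]]
    emg: dict[str, dict[int, np.ndarray]] | None = None
    emg_rate_hz: float | None = None
    kinematics: dict[str, dict[int, np.ndarray]] | None = None
    kin_rate_hz: float | None = None

    def __post_init__(self) -> None:
        self.validate()

    @property
    def neuron_ids(self) -> list[int]:
        return sorted(self.spikes)

    @property
    def trial_index(self) -> dict[int, TrialRecord]:
        return {t.trial_id: t for t in self.trials}

    def trials_for(self, context: str, load_index: int) -> list[TrialRecord]:
        return [
            t for t in self.trials
            if t.context == context and t.load.index == load_index
        ]

    def validate(self) -> None:
        ids = {t.trial_id for t in self.trials}
        if len(ids) != len(self.trials):
            raise SessionFormatError("duplicate trial_ids in trial table")
        by_id = self.trial_index
        for context in CONTEXTS:
            for load in canonical_load_set():
                if not self.trials_for(context, load.index):
                    raise SessionFormatError(
                        f"no trials for (context={context}, load={load.index})"
                    )
        for nid, per_trial in self.spikes.items():
            for tid, times in per_trial.items():
                if tid not in by_id:
                    raise SessionFormatError(
                        f"spikes reference unknown trial {tid} (neuron {nid})"
                    )
                times = np.asarray(times)
                if times.size and (np.any(np.diff(times) < 0)):
                    raise SessionFormatError(
                        f"spike times for neuron {nid}, trial {tid} are not sorted"
                    )
                if times.size and (
                    times[0] < 0 or times[-1] > by_id[tid].trial_end_ms
                ):
                    raise SessionFormatError(
                        f"spike times for neuron {nid}, trial {tid} fall outside "
                        f"[0, {by_id[tid].trial_end_ms}] ms"
                    )


# ---------------------------------------------------------------------------
# readers / writers


_TRIAL_COLS = [
    "trial_id", "context", "shoulder_torque_nm", "elbow_torque_nm",
    "perturb_time_ms", "trial_end_ms",
]
_SPIKE_COLS = ["neuron_id", "trial_id", "spike_time_ms"]
_LONG_COLS = ["channel", "trial_id", "time_ms", "value"]


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SessionFormatError(f"{path}: missing columns {missing}")


def _read_long(path, rate_path) -> tuple[dict[str, dict[int, np.ndarray]], float]:
    df = pd.read_csv(path)
    _require_columns(df, _LONG_COLS, path)
    with open(rate_path) as fh:
        rate = float(json.load(fh)["rate_hz"])
    out: dict[str, dict[int, np.ndarray]] = {}
    for (ch, tid), grp in df.groupby(["channel", "trial_id"], sort=True):
        grp = grp.sort_values("time_ms")
        out.setdefault(str(ch), {})[int(tid)] = grp["value"].to_numpy(float)
    return out, rate


def read_session(
    trials_path,
    spikes_path,
    emg_path=None,
    kin_path=None,
) -> Session:
    """Read and validate a session from the documented CSV layout."""
    tdf = pd.read_csv(trials_path)
    _require_columns(tdf, _TRIAL_COLS, trials_path)
    trials = [
        TrialRecord(
            trial_id=int(r.trial_id),
            context=str(r.context),
            load=match_load(float(r.shoulder_torque_nm), float(r.elbow_torque_nm)),
            perturb_time_ms=int(r.perturb_time_ms),
            trial_end_ms=int(r.trial_end_ms),
        )
        for r in tdf.itertuples()
    ]

    sdf = pd.read_csv(spikes_path)
    _require_columns(sdf, _SPIKE_COLS, spikes_path)
    spikes: dict[int, dict[int, np.ndarray]] = {}
    if len(sdf):
        for (nid, tid), grp in sdf.groupby(["neuron_id", "trial_id"], sort=True):
            t = grp["spike_time_ms"].to_numpy(np.int64)
            if np.any(np.diff(t) < 0):
                raise SessionFormatError(
                    f"{spikes_path}: spike times for neuron {nid}, trial {tid} "
                    "are not monotone"
                )
            spikes.setdefault(int(nid), {})[int(tid)] = t

    kwargs = {}
    if emg_path is not None:
        emg_path = Path(emg_path)
        kwargs["emg"], kwargs["emg_rate_hz"] = _read_long(
            emg_path, emg_path.with_suffix(".rate.json")
        )
    if kin_path is not None:
        kin_path = Path(kin_path)
        kwargs["kinematics"], kwargs["kin_rate_hz"] = _read_long(
            kin_path, kin_path.with_suffix(".rate.json")
        )
    return Session(trials=trials, spikes=spikes, **kwargs)


def _fmt(x: float) -> str:
    # shortest repr round-trips exactly; keeps write->read->write byte-stable
    return repr(float(x))


def write_session(session: Session, out_dir) -> dict[str, Path]:
    """Write a session to ``out_dir`` in the documented CSV layout."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"trials": out_dir / "trials.csv", "spikes": out_dir / "spikes.csv"}

    rows = ["{}".format(",".join(_TRIAL_COLS))]
    for t in sorted(session.trials, key=lambda t: t.trial_id):
        rows.append(
            f"{t.trial_id},{t.context},{_fmt(t.load.shoulder_torque)},"
            f"{_fmt(t.load.elbow_torque)},{t.perturb_time_ms},{t.trial_end_ms}"
        )
    paths["trials"].write_text("\n".join(rows) + "\n")

    rows = ["{}".format(",".join(_SPIKE_COLS))]
    for nid in sorted(session.spikes):
        for tid in sorted(session.spikes[nid]):
            for st in session.spikes[nid][tid]:
                rows.append(f"{nid},{tid},{int(st)}")
    paths["spikes"].write_text("\n".join(rows) + "\n")

    for name, channels, rate in (
        ("emg", session.emg, session.emg_rate_hz),
        ("kin", session.kinematics, session.kin_rate_hz),
    ):
        if channels is None:
            continue
        path = out_dir / f"{name}.csv"
        rows = ["{}".format(",".join(_LONG_COLS))]
        for ch in sorted(channels):
            for tid in sorted(channels[ch]):
                series = channels[ch][tid]
                dt_ms = 1000.0 / rate
                for i, v in enumerate(series):
                    rows.append(f"{ch},{tid},{_fmt(i * dt_ms)},{_fmt(v)}")
        path.write_text("\n".join(rows) + "\n")
        path.with_suffix(".rate.json").write_text(
            json.dumps({"rate_hz": rate}) + "\n"
        )
        paths[name] = path
    return paths


# ---------------------------------------------------------------------------
# reports


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(type(obj).__name__)


def _find_unserializable(obj, prefix="") -> list[str]:
    try:
        json.dumps(obj, default=_jsonable)
        return []
    except TypeError:
        pass
    bad = []
    if isinstance(obj, dict):
        for k, v in obj.items():
            bad += _find_unserializable(v, f"{prefix}.{k}" if prefix else str(k))
    elif isinstance(obj, (list, tuple)):
        for i, v in enumerate(obj):
            bad += _find_unserializable(v, f"{prefix}[{i}]")
    else:
        bad.append(prefix or "<root>")
    return bad


def write_report(results: dict, path) -> None:
    """Serialize an analysis report to JSON.

    Every statistic is expected to carry its null-distribution summary and the
    seed that produced it; unserializable entries fail with the offending keys
    listed.
    """
    bad = _find_unserializable(results)
    if bad:
        raise TypeError(f"report entries not JSON-serializable: {bad}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(results, fh, indent=1, sort_keys=True, default=_jsonable)
        fh.write("\n")
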