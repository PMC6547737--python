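"""Readers and writers for the tabular dialects the pipeline consumes and emits.

All dialects are long-format CSV with a one-line column header, optionally
preceded by ``# polyhand key=value`` metadata comment lines (written by the
writers, parsed back by the readers so that read-after-write is the identity
on every container, metadata included). Floats are serialized with shortest
round-trip precision, so positions survive a round trip bit-exactly.

An HDF5 container is also supported for large hand recordings with layout
``/<subject>/<hand>/<task>/<finger>/<sensor>`` -> (T, 3) array and the
sampling rate stored as an attribute.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, FormatError
from .recordings import (
    LEVELS,
    SENSORS,
    ForceRecording,
    ForceTrial,
    GameSessionLog,
    HandRecording,
    LocalizationDataset,
)

KNOWN_FINGERS = {"T", "S", "I", "M", "R", "L"}

_HAND_COLUMNS = ["time_s", "finger", "sensor", "x_cm", "y_cm", "z_cm"]


def _read_metadata(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if body.startswith("polyhand "):
                key, _, value = body[len("polyhand "):].partition("=")
                meta[key.strip()] = value.strip()
    return meta


def _write_metadata(fh, meta: dict[str, object]) -> None:
    for key, value in meta.items():
        fh.write(f"# polyhand {key}={value}\n")


def _fmt(x: float) -> str:
    return repr(float(x))


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")


# ---------------------------------------------------------------------------
# Hand recordings
# ---------------------------------------------------------------------------

def read_hand_recording(path, dialect: dict | None = None) -> HandRecording:
    """Read a long-format motion-capture CSV into a :class:`HandRecording`.

    Expected columns: time_s, finger, sensor in {distal, proximal, ref},
    x_cm, y_cm, z_cm. If a ``ref`` sensor stream is present, distal/proximal
    positions are re-expressed relative to it and the ref stream is dropped.
    ``dialect`` entries override file metadata (subject_id, hand, task_label,
    sampling_rate).
    """
    path = Path(path)
    meta = _read_metadata(path)
    if dialect:
        meta.update({k: v for k, v in dialect.items() if v is not None})

    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    _require_columns(df, _HAND_COLUMNS, path)
    if not np.all(np.isfinite(df[["x_cm", "y_cm", "z_cm"]].to_numpy(dtype=float))):
        raise DataError(f"{path}: non-finite position values")

    bad = set(df["finger"].unique()) - KNOWN_FINGERS
    if bad:
        raise DataError(f"{path}: unknown finger label(s) {sorted(bad)}")
    bad_sensor = set(df["sensor"].unique()) - (set(SENSORS) | {"ref"})
    if bad_sensor:
        raise DataError(f"{path}: unknown sensor token(s) {sorted(bad_sensor)}")

    positions: dict[str, dict[str, np.ndarray]] = {}
    times_seen: np.ndarray | None = None
    ref = df[df["sensor"] == "ref"]
    ref_xyz = None
    if len(ref):
        t_ref = ref["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(t_ref) <= 0):
            raise DataError(f"{path}: non-monotone time in reference stream")
        ref_xyz = ref[["x_cm", "y_cm", "z_cm"]].to_numpy(dtype=float)

    order_from_file: list[str] = []
    for finger in df["finger"].unique():
        if finger == "ref":
            continue
        sub = df[df["finger"] == finger]
        if set(sub["sensor"]) - {"ref"} != set(SENSORS):
            continue
        order_from_file.append(finger)
        positions[finger] = {}
        for sensor in SENSORS:
            rows = sub[sub["sensor"] == sensor]
            t = rows["time_s"].to_numpy(dtype=float)
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise DataError(f"{path}: non-monotone time for finger {finger} sensor {sensor}")
            if len(dt):
                step = float(np.median(dt))
                # analyses assume uniform sampling; fail fast on gross jitter
                if np.any(np.abs(dt - step) > 0.5 * step):
                    raise DataError(
                        f"{path}: time jitter exceeds half a sample for finger "
                        f"{finger} sensor {sensor}")
            xyz = rows[["x_cm", "y_cm", "z_cm"]].to_numpy(dtype=float)
            if ref_xyz is not None:
                if len(ref_xyz) != len(xyz):
                    raise DataError(f"{path}: ref stream length differs from finger {finger}")
                xyz = xyz - ref_xyz
            positions[finger][sensor] = xyz
            if times_seen is None:
                times_seen = t

    if not positions:
        raise DataError(f"{path}: no complete finger sensor streams found")

    if "sampling_rate" in meta:
        rate = float(meta["sampling_rate"])
    elif times_seen is not None and len(times_seen) > 1:
        rate = 1.0 / float(np.median(np.diff(times_seen)))
    else:
        rate = 120.0

    fingers = _canonical_order(order_from_file)
    return HandRecording(
        subject_id=str(meta.get("subject_id", "unknown")),
        hand=str(meta.get("hand", "right")),
        fingers=fingers,
        sampling_rate=rate,
        positions={f: positions[f] for f in fingers},
        task_label=str(meta.get("task_label", "object_manipulation")),
    )


def _canonical_order(labels: list[str]) -> list[str]:
    radial_to_ulnar = ["T", "S", "I", "M", "R", "L"]
    known = [f for f in radial_to_ulnar if f in labels]
    extra = [f for f in labels if f not in radial_to_ulnar]
    return known + extra


def write_hand_recording(rec: HandRecording, path) -> None:
    path = Path(path)
    n = rec.n_samples
    times = np.arange(n) / rec.sampling_rate
    with open(path, "w", newline="") as fh:
        _write_metadata(fh, {
            "subject_id": rec.subject_id,
            "hand": rec.hand,
            "task_label": rec.task_label,
            "sampling_rate": _fmt(rec.sampling_rate),
        })
        writer = csv.writer(fh)
        writer.writerow(_HAND_COLUMNS)
        for i in range(n):
            for finger in rec.fingers:
                for sensor in SENSORS:
                    x, y, z = rec.positions[finger][sensor][i]
                    writer.writerow([_fmt(times[i]), finger, sensor, _fmt(x), _fmt(y), _fmt(z)])


def write_hand_recording_hdf5(rec: HandRecording, path) -> None:
    import h5py

    with h5py.File(path, "w") as h5:
        grp = h5.require_group(f"{rec.subject_id}/{rec.hand}/{rec.task_label}")
        grp.attrs["sampling_rate"] = rec.sampling_rate
        grp.attrs["fingers"] = ",".join(rec.fingers)
        for finger in rec.fingers:
            for sensor in SENSORS:
                grp.create_dataset(f"{finger}/{sensor}", data=rec.positions[finger][sensor])


def read_hand_recording_hdf5(path) -> HandRecording:
    import h5py

    with h5py.File(path, "r") as h5:
        subject = next(iter(h5))
        hand = next(iter(h5[subject]))
        task = next(iter(h5[subject][hand]))
        grp = h5[subject][hand][task]
        fingers = grp.attrs["fingers"].split(",")
        positions = {
            f: {s: np.asarray(grp[f][s]) for s in SENSORS} for f in fingers
        }
        return HandRecording(
            subject_id=subject,
            hand=hand,
            fingers=fingers,
            sampling_rate=float(grp.attrs["sampling_rate"]),
            positions=positions,
            task_label=task,
        )


# ---------------------------------------------------------------------------
# Force recordings
# ---------------------------------------------------------------------------

def read_force_trials(path) -> ForceRecording:
    """Read a long-format force CSV into a :class:`ForceRecording`.

    Expected columns: trial_id, instructed_finger, level, time_s and one
    ``f_<finger>`` column per finger (newtons). Trials are grouped and
    ordered by trial_id.
    """
    path = Path(path)
    meta = _read_metadata(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip",
                     dtype={"level": str})
    _require_columns(df, ["trial_id", "instructed_finger", "level", "time_s"], path)
    force_cols = [c for c in df.columns if c.startswith("f_")]
    if not force_cols:
        raise FormatError(f"{path}: no per-finger force columns (f_<finger>)")
    fingers = [c[2:] for c in force_cols]

    levels = set(df["level"].astype(str).unique())
    bad = levels - set(LEVELS)
    if bad:
        raise FormatError(f"{path}: level token(s) {sorted(bad)} outside {LEVELS}")

    trials = []
    for trial_id in sorted(df["trial_id"].unique()):
        sub = df[df["trial_id"] == trial_id].sort_values("time_s", kind="stable")
        instructed = sub["instructed_finger"].iloc[0]
        if instructed not in fingers:
            raise DataError(
                f"{path}: trial {trial_id} instructed finger '{instructed}' not in {fingers}"
            )
        force = sub[force_cols].to_numpy(dtype=float)
        if not np.all(np.isfinite(force)):
            raise DataError(f"{path}: trial {trial_id} contains non-finite forces")
        t = sub["time_s"].to_numpy(dtype=float)
        duration = float(t[-1] - t[0]) + (t[1] - t[0] if len(t) > 1 else 0.0)
        trials.append(ForceTrial(
            instructed_finger=str(instructed),
            level=str(sub["level"].iloc[0]),
            force=force,
            duration=duration,
        ))

    rate = float(meta.get("sampling_rate", 128.0))
    return ForceRecording(
        subject_id=str(meta.get("subject_id", "unknown")),
        fingers=fingers,
        sampling_rate=rate,
        trials=trials,
    )


def write_force_trials(rec: ForceRecording, path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        _write_metadata(fh, {
            "subject_id": rec.subject_id,
            "sampling_rate": _fmt(rec.sampling_rate),
        })
        writer = csv.writer(fh)
        writer.writerow(["trial_id", "instructed_finger", "level", "time_s"]
                        + [f"f_{f}" for f in rec.fingers])
        for tid, trial in enumerate(rec.trials):
            times = np.arange(trial.n_samples) / rec.sampling_rate
            for i in range(trial.n_samples):
                writer.writerow(
                    [tid, trial.instructed_finger, trial.level, _fmt(times[i])]
                    + [_fmt(v) for v in trial.force[i]]
                )


# ---------------------------------------------------------------------------
# Localization datasets
# ---------------------------------------------------------------------------

_LOC_COLUMNS = ["finger", "landmark", "rep",
                "reported_x_cm", "reported_y_cm", "true_x_cm", "true_y_cm"]


def read_localization(path) -> LocalizationDataset:
    path = Path(path)
    meta = _read_metadata(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    _require_columns(df, _LOC_COLUMNS, path)
    coords = df[_LOC_COLUMNS[3:]].to_numpy(dtype=float)
    if not np.all(np.isfinite(coords)):
        raise DataError(f"{path}: non-finite coordinates")
    points: dict[tuple[str, str], list] = {}
    for _, row in df.iterrows():
        key = (str(row["finger"]), str(row["landmark"]))
        points.setdefault(key, []).append((
            np.array([row["reported_x_cm"], row["reported_y_cm"]], dtype=float),
            np.array([row["true_x_cm"], row["true_y_cm"]], dtype=float),
        ))
    return LocalizationDataset(points=points, cue_mode=str(meta.get("cue_mode", "tactile")))


def write_localization(data: LocalizationDataset, path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        _write_metadata(fh, {"cue_mode": data.cue_mode})
        writer = csv.writer(fh)
        writer.writerow(_LOC_COLUMNS)
        for (finger, landmark), pairs in data.points.items():
            for rep, (reported, true) in enumerate(pairs):
                writer.writerow([finger, landmark, rep,
                                 _fmt(reported[0]), _fmt(reported[1]),
                                 _fmt(true[0]), _fmt(true[1])])


# ---------------------------------------------------------------------------
# Game session logs
# ---------------------------------------------------------------------------

_GAME_COLUMNS = ["condition", "practice_min", "level", "accuracy", "error_rate"]


def read_game_log(path) -> GameSessionLog:
    path = Path(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    _require_columns(df, _GAME_COLUMNS, path)
    t = df["practice_min"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise DataError(f"{path}: practice time not strictly increasing")
    levels = df["level"].to_numpy()
    if np.any(levels < 1) or not np.allclose(levels, np.round(levels)):
        raise DataError(f"{path}: level indices must be positive integers")
    return GameSessionLog(
        condition=str(df["condition"].iloc[0]),
        events=[(float(ti), int(lv)) for ti, lv in zip(t, levels)],
        accuracy=[float(a) for a in df["accuracy"]],
        error_rate=[float(e) for e in df["error_rate"]],
    )


def write_game_log(log: GameSessionLog, path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_GAME_COLUMNS)
        for (t, lv), acc, err in zip(log.events, log.accuracy, log.error_rate):
            writer.writerow([log.condition, _fmt(t), lv, _fmt(acc), _fmt(err)])
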