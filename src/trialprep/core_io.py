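"""Domain containers and on-disk formats for trial-based fMRI sessions.

The pipeline operates on four kinds of objects:

* :class:`VolumeSeries` — a 4D functional series with voxel geometry,
  per-volume acquisition times and run membership.
* :class:`TrialTable` — the trial records (volume spans, task events,
  accept/reject status) that drive selection and regressor construction.
* :class:`ConcatIndex` — the bijection between a concatenated
  (trial-pruned) series and the original volume grid, including gap
  metadata needed for interpolation-based filtering.
* :class:`TransformSet` — per-volume 1-DOF phase-axis shifts and
  per-trial 12-parameter affines produced by realignment.

Volumes are stored NIfTI-1 (via nibabel) with a JSON sidecar carrying the
acquisition metadata NIfTI has no standard slot for (inter-volume time,
phase-encode axis, run boundaries).  Trial/event tables are tab-separated
with BIDS-events-like columns.  Transforms and logs serialize to JSON.

Conventions used throughout the package: volume indices are 0-based;
trial ``start_vol``/``end_vol`` are inclusive and expressed within the
trial's run; times are seconds from run start.
"""

from __future__ import annotations

import json
import math
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VolumeSeries",
    "Event",
    "Trial",
    "TrialTable",
    "GapRecord",
    "ConcatIndex",
    "AffineParams",
    "TransformSet",
    "SensorTrace",
    "StepLogger",
    "read_volume_series",
    "write_volume_series",
    "read_trial_table",
    "write_trial_table",
    "read_sensor_trace",
    "write_sensor_trace",
]

_AXES = {"x": 0, "y": 1, "z": 2}

ACCEPTED = "accepted"
AUTO_FLAGGED = "auto_flagged"
MANUALLY_REJECTED = "manually_rejected"
_STATUSES = (ACCEPTED, AUTO_FLAGGED, MANUALLY_REJECTED)


def _axis_index(phase_axis: int | str) -> int:
    if isinstance(phase_axis, str):
        try:
            return _AXES[phase_axis.lower()]
        except KeyError:
            raise ValueError(f"phase_axis must be one of x/y/z, got {phase_axis!r}")
    if phase_axis not in (0, 1, 2):
        raise ValueError(f"phase_axis index must be 0, 1 or 2, got {phase_axis}")
    return int(phase_axis)


# ---------------------------------------------------------------------------
# VolumeSeries
# ---------------------------------------------------------------------------


@dataclass
class VolumeSeries:
    """A 4D functional series (x, y, z, t) with acquisition metadata.

    ``run_id`` labels each volume with its acquisition run; ``acq_time``
    is seconds from the start of that volume's run.  The phase-encode
    axis (where B0-induced apparent shifts occur, anterior–posterior for
    the sessions modelled here) is carried as a spatial axis index.
    """

    data: np.ndarray
    voxel_size: np.ndarray
    intervolume_time: float
    phase_axis: int
    run_id: np.ndarray
    acq_time: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"volume series must be 4D, got {self.data.ndim}D")
        self.voxel_size = np.asarray(self.voxel_size, dtype=float).reshape(3)
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size must be strictly positive")
        if self.intervolume_time <= 0:
            raise ValueError("intervolume_time must be positive")
        self.phase_axis = _axis_index(self.phase_axis)
        self.run_id = np.asarray(self.run_id, dtype=int).reshape(-1)
        self.acq_time = np.asarray(self.acq_time, dtype=float).reshape(-1)
        n = self.data.shape[3]
        if len(self.run_id) != n or len(self.acq_time) != n:
            raise ValueError("run_id/acq_time length must equal number of volumes")
        if np.any(np.diff(self.run_id) < 0):
            raise ValueError("run_id must be non-decreasing along t")
        for rid in np.unique(self.run_id):
            t = self.acq_time[self.run_id == rid]
            if len(t) > 1 and np.any(np.diff(t) <= 0):
                raise ValueError(f"acq_time must be strictly increasing within run {rid}")

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_runs(
        cls,
        data: np.ndarray,
        voxel_size: Sequence[float],
        intervolume_time: float,
        phase_axis: int | str,
        run_lengths: Sequence[int],
    ) -> "VolumeSeries":
        """Build a series from per-run volume counts, deriving times/ids."""
        data = np.asarray(data)
        if data.ndim != 4:
            raise ValueError(f"volume series must be 4D, got {data.ndim}D")
        run_lengths = [int(n) for n in run_lengths]
        if sum(run_lengths) != data.shape[3]:
            raise ValueError("run_lengths must sum to the number of volumes")
        run_id = np.concatenate([np.full(n, i, dtype=int) for i, n in enumerate(run_lengths)])
        acq_time = np.concatenate(
            [np.arange(n, dtype=float) * intervolume_time for n in run_lengths]
        )
        return cls(data, np.asarray(voxel_size, float), float(intervolume_time),
                   _axis_index(phase_axis), run_id, acq_time)

    # -- helpers -----------------------------------------------------------

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def runs(self) -> list[int]:
        return list(dict.fromkeys(self.run_id.tolist()))

    def run_slice(self, run: int) -> slice:
        idx = np.flatnonzero(self.run_id == run)
        if len(idx) == 0:
            raise KeyError(f"run {run} not present")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def run_length(self, run: int) -> int:
        return int(np.sum(self.run_id == run))

    def with_data(self, data: np.ndarray) -> "VolumeSeries":
        """Same metadata, new voxel data (shape must match)."""
        if data.shape != self.data.shape:
            raise ValueError("replacement data must have the same shape")
        return VolumeSeries(data, self.voxel_size.copy(), self.intervolume_time,
                            self.phase_axis, self.run_id.copy(), self.acq_time.copy())

    def subset(self, indices: np.ndarray) -> "VolumeSeries":
        indices = np.asarray(indices, dtype=int)
        return VolumeSeries(
            self.data[..., indices],
            self.voxel_size.copy(),
            self.intervolume_time,
            self.phase_axis,
            self.run_id[indices],
            self.acq_time[indices],
        )


def write_volume_series(series: VolumeSeries, path: str | Path) -> None:
    """Write NIfTI-1 plus a JSON sidecar with timing/run metadata."""
    path = Path(path)
    affine = np.diag(list(series.voxel_size) + [1.0])
    img = nib.Nifti1Image(np.asarray(series.data, dtype=np.float32), affine)
    img.header.set_zooms(tuple(series.voxel_size) + (series.intervolume_time,))
    nib.save(img, str(path))
    run_lengths = [series.run_length(r) for r in series.runs()]
    sidecar = {
        "intervolume_time": series.intervolume_time,
        "phase_axis": "xyz"[series.phase_axis],
        "run_lengths": run_lengths,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def read_volume_series(path: str | Path, sidecar: str | Path | None = None) -> VolumeSeries:
    """Read a 4D NIfTI-1 file; the sidecar supplies timing/run metadata."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D NIfTI file, got {data.ndim}D: {path}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"non-positive voxel size in header of {path}")
    sidecar_path = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("intervolume_time", "phase_axis", "run_lengths"):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar_path} missing required key {key!r}")
    return VolumeSeries.from_runs(
        data, np.asarray(zooms, float), float(meta["intervolume_time"]),
        meta["phase_axis"], meta["run_lengths"],
    )


# ---------------------------------------------------------------------------
# TrialTable
# ---------------------------------------------------------------------------


@dataclass
class Event:
    condition: str
    onset: float  # s from run start
    duration: float  # s


@dataclass
class Trial:
    trial_id: int
    run_id: int
    start_vol: int  # 0-based, inclusive, within run
    end_vol: int  # 0-based, inclusive, within run
    events: list[Event] = field(default_factory=list)
    status: str = ACCEPTED

    @property
    def n_vols(self) -> int:
        return self.end_vol - self.start_vol + 1


@dataclass
class TrialTable:
    trials: list[Trial]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        by_run: dict[int, list[Trial]] = {}
        for t in self.trials:
            if t.status not in _STATUSES:
                raise ValueError(f"trial {t.trial_id}: unknown status {t.status!r}")
            if t.start_vol > t.end_vol:
                raise ValueError(f"trial {t.trial_id}: start_vol > end_vol")
            if t.start_vol < 0:
                raise ValueError(f"trial {t.trial_id}: negative start_vol")
            if t.trial_id in seen:
                raise ValueError(f"duplicate trial_id {t.trial_id}")
            seen.add(t.trial_id)
            by_run.setdefault(t.run_id, []).append(t)
        for run, ts in by_run.items():
            ts = sorted(ts, key=lambda t: t.start_vol)
            for a, b in zip(ts, ts[1:]):
                if b.start_vol <= a.end_vol:
                    raise ValueError(
                        f"trials {a.trial_id} and {b.trial_id} overlap in run {run}"
                    )

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def get(self, trial_id: int) -> Trial:
        for t in self.trials:
            if t.trial_id == trial_id:
                return t
        raise KeyError(f"unknown trial_id {trial_id}")

    def accepted(self) -> list[Trial]:
        return [t for t in self.trials if t.status == ACCEPTED]

    def validate_against(self, series: VolumeSeries) -> None:
        """Check volume spans and event windows against a series."""
        for t in self.trials:
            n = series.run_length(t.run_id)
            if t.end_vol >= n:
                raise ValueError(
                    f"trial {t.trial_id}: end_vol {t.end_vol} beyond run "
                    f"{t.run_id} length {n}"
                )
            t0 = t.start_vol * series.intervolume_time
            t1 = (t.end_vol + 1) * series.intervolume_time
            for ev in t.events:
                if ev.onset < t0 - 1e-9 or ev.onset + ev.duration > t1 + 1e-9:
                    raise ValueError(
                        f"trial {t.trial_id}: event {ev.condition!r} outside trial span"
                    )

    def with_status(self, updates: Mapping[int, str]) -> "TrialTable":
        for tid, status in updates.items():
            if status not in _STATUSES:
                raise ValueError(f"unknown status {status!r} for trial {tid}")
            self.get(tid)  # raises on unknown id
        trials = [
            Trial(t.trial_id, t.run_id, t.start_vol, t.end_vol,
                  list(t.events), updates.get(t.trial_id, t.status))
            for t in self.trials
        ]
        return TrialTable(trials)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            base = dict(trial_id=t.trial_id, run_id=t.run_id,
                        start_vol=t.start_vol, end_vol=t.end_vol, status=t.status)
            if t.events:
                for ev in t.events:
                    rows.append(dict(base, condition=ev.condition,
                                     onset=ev.onset, duration=ev.duration))
            else:
                rows.append(dict(base, condition="", onset=np.nan, duration=np.nan))
        return pd.DataFrame(rows, columns=[
            "trial_id", "run_id", "start_vol", "end_vol", "status",
            "condition", "onset", "duration",
        ])


def write_trial_table(table: TrialTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_trial_table(path: str | Path) -> TrialTable:
    df = pd.read_csv(path, sep="\t", na_values=["n/a"], keep_default_na=True)
    required = {"trial_id", "run_id", "start_vol", "end_vol", "status"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    trials = []
    for tid, grp in df.groupby("trial_id", sort=True):
        head = grp.iloc[0]
        events = []
        if "condition" in grp.columns:
            for _, row in grp.iterrows():
                cond = row.get("condition")
                if isinstance(cond, str) and cond and not pd.isna(row.get("onset")):
                    events.append(Event(cond, float(row["onset"]), float(row["duration"])))
        trials.append(Trial(int(tid), int(head["run_id"]), int(head["start_vol"]),
                            int(head["end_vol"]), events, str(head["status"])))
    return TrialTable(trials)


# ---------------------------------------------------------------------------
# ConcatIndex
# ---------------------------------------------------------------------------


@dataclass
class GapRecord:
    """Volumes removed between two kept blocks (or at a run edge)."""

    run_id: int
    after_kept_position: int  # index into kept, -1 if gap precedes all kept vols
    indices: list[int]  # within-run original indices, ascending
    acq_times: list[float]


@dataclass
class ConcatIndex:
    """Maps concatenated positions back to (run, original index).

    ``kept[i] = (run_id, original_index)`` for concatenated volume ``i``;
    ``gaps`` record every removed volume together with its original
    acquisition time, so the original evenly-sampled grid of each run can
    be reconstituted for filtering.
    """

    kept: list[tuple[int, int]]
    gaps: list[GapRecord]
    run_lengths: dict[int, int]

    def __post_init__(self) -> None:
        prev = None
        for rid, idx in self.kept:
            key = (rid, idx)
            if prev is not None and key <= prev:
                raise ValueError("kept must be strictly ordered by (run, index)")
            prev = key
        for run, length in self.run_lengths.items():
            kept_idx = {i for r, i in self.kept if r == run}
            gap_idx: set[int] = set()
            for g in self.gaps:
                if g.run_id == run:
                    gap_idx.update(g.indices)
            if kept_idx & gap_idx:
                raise ValueError(f"run {run}: kept and gap indices overlap")
            if kept_idx | gap_idx != set(range(length)):
                raise ValueError(f"run {run}: kept+gaps do not partition 0..{length - 1}")

    @property
    def n_kept(self) -> int:
        return len(self.kept)

    @classmethod
    def identity(cls, series: VolumeSeries) -> "ConcatIndex":
        """Index for a series in which nothing was removed."""
        kept = []
        run_lengths: dict[int, int] = {}
        for rid in series.runs():
            n = series.run_length(rid)
            run_lengths[rid] = n
            kept.extend((rid, i) for i in range(n))
        return cls(kept, [], run_lengths)

    def kept_positions(self, run: int) -> list[tuple[int, int]]:
        """(concatenated position, original index) pairs for one run."""
        return [(pos, idx) for pos, (rid, idx) in enumerate(self.kept) if rid == run]

    def to_json(self) -> str:
        return json.dumps({
            "kept": [[int(r), int(i)] for r, i in self.kept],
            "gaps": [
                {"run_id": int(g.run_id), "after_kept_position": int(g.after_kept_position),
                 "indices": [int(i) for i in g.indices],
                 "acq_times": [float(t) for t in g.acq_times]}
                for g in self.gaps
            ],
            "run_lengths": {str(k): int(v) for k, v in self.run_lengths.items()},
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ConcatIndex":
        obj = json.loads(text)
        return cls(
            kept=[(int(r), int(i)) for r, i in obj["kept"]],
            gaps=[GapRecord(g["run_id"], g["after_kept_position"],
                            list(g["indices"]), list(g["acq_times"]))
                  for g in obj["gaps"]],
            run_lengths={int(k): int(v) for k, v in obj["run_lengths"].items()},
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "ConcatIndex":
        return cls.from_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# TransformSet
# ---------------------------------------------------------------------------


@dataclass
class AffineParams:
    """12-parameter affine: translations (mm), rotations (rad), scales, shears.

    The full 4x4 matrix factors as T·R·Z·S in millimetre coordinates about
    the volume centre: R applies intrinsic rotations about x, then y, then
    z; Z is the diagonal scale; S is a unit upper-triangular shear
    (xy, xz, yz).  The matrix is used as a pull-back sampling map: the
    resampled image evaluates the moving image at ``A·x`` for each
    reference-grid coordinate ``x`` (offsets from the grid centre, mm).
    """

    translation: np.ndarray  # (3,), mm
    rotation: np.ndarray  # (3,), rad
    scale: np.ndarray  # (3,)
    shear: np.ndarray  # (3,) = (xy, xz, yz)

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, float).reshape(3)
        self.rotation = np.asarray(self.rotation, float).reshape(3)
        self.scale = np.asarray(self.scale, float).reshape(3)
        self.shear = np.asarray(self.shear, float).reshape(3)

    @classmethod
    def identity(cls) -> "AffineParams":
        return cls(np.zeros(3), np.zeros(3), np.ones(3), np.zeros(3))

    @classmethod
    def from_vector(cls, v: Sequence[float]) -> "AffineParams":
        v = np.asarray(v, float).reshape(12)
        return cls(v[0:3], v[3:6], v[6:9], v[9:12])

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.translation, self.rotation, self.scale, self.shear])

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix T·R·Z·S in mm coordinates."""
        rx, ry, rz = self.rotation
        cx, sx = math.cos(rx), math.sin(rx)
        cy, sy = math.cos(ry), math.sin(ry)
        cz, sz = math.cos(rz), math.sin(rz)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        R = Rx @ Ry @ Rz
        Z = np.diag(self.scale)
        S = np.array([[1.0, self.shear[0], self.shear[1]],
                      [0.0, 1.0, self.shear[2]],
                      [0.0, 0.0, 1.0]])
        M = np.eye(4)
        M[:3, :3] = R @ Z @ S
        M[:3, 3] = self.translation
        return M

    @classmethod
    def from_matrix(cls, M: np.ndarray) -> "AffineParams":
        """Decompose a T·R·Z·S matrix back into the 12 parameters."""
        M = np.asarray(M, float)
        A = M[:3, :3]
        Q, U = np.linalg.qr(A)
        signs = np.sign(np.diag(U))
        signs[signs == 0] = 1.0
        Q = Q * signs[np.newaxis, :]
        U = U * signs[:, np.newaxis]
        if np.linalg.det(Q) < 0:  # proper rotation required
            Q = -Q
            U = -U
        scale = np.diag(U).copy()
        S = U / scale[:, np.newaxis]
        # intrinsic x-y-z Euler angles of Q = Rx·Ry·Rz
        ry = math.asin(np.clip(Q[0, 2], -1.0, 1.0))
        if abs(math.cos(ry)) > 1e-8:
            rx = math.atan2(-Q[1, 2], Q[2, 2])
            rz = math.atan2(-Q[0, 1], Q[0, 0])
        else:  # gimbal lock, never hit for small motions
            rx = math.atan2(Q[1, 0], Q[1, 1])
            rz = 0.0
        return cls(M[:3, 3].copy(), np.array([rx, ry, rz]), scale,
                   np.array([S[0, 1], S[0, 2], S[1, 2]]))

    def to_dict(self) -> dict:
        return {
            "translation_mm": self.translation.tolist(),
            "rotation_rad": self.rotation.tolist(),
            "scale": self.scale.tolist(),
            "shear": self.shear.tolist(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AffineParams":
        return cls(np.asarray(d["translation_mm"]), np.asarray(d["rotation_rad"]),
                   np.asarray(d["scale"]), np.asarray(d["shear"]))


@dataclass
class TransformSet:
    """Realignment output: per-volume 1-DOF shifts plus per-trial affines."""

    shift1d: np.ndarray  # mm along the phase axis, one entry per kept volume
    affines: dict[int, AffineParams]  # trial_id -> affine
    reference: str = "mean of first accepted trial"

    def __post_init__(self) -> None:
        self.shift1d = np.asarray(self.shift1d, float).reshape(-1)

    def to_json(self) -> str:
        return json.dumps({
            "reference": self.reference,
            "shift1d_mm": self.shift1d.tolist(),
            "affines": {str(tid): p.to_dict() for tid, p in self.affines.items()},
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TransformSet":
        obj = json.loads(text)
        return cls(np.asarray(obj["shift1d_mm"], float),
                   {int(k): AffineParams.from_dict(v) for k, v in obj["affines"].items()},
                   obj.get("reference", ""))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "TransformSet":
        return cls.from_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# SensorTrace
# ---------------------------------------------------------------------------


@dataclass
class SensorTrace:
    """Jaw/body motion-sensor traces (arbitrary units) over session time."""

    time: np.ndarray
    jaw: np.ndarray
    body: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float).reshape(-1)
        self.jaw = np.asarray(self.jaw, float).reshape(-1)
        self.body = np.asarray(self.body, float).reshape(-1)
        if len(self.time) > 1 and np.any(np.diff(self.time) <= 0):
            raise ValueError("sensor time must be strictly increasing")
        if not (len(self.time) == len(self.jaw) == len(self.body)):
            raise ValueError("sensor trace columns must have equal length")


def write_sensor_trace(trace: SensorTrace, path: str | Path) -> None:
    pd.DataFrame({"time": trace.time, "jaw": trace.jaw, "body": trace.body}).to_csv(
        path, sep="\t", index=False)


def read_sensor_trace(path: str | Path) -> SensorTrace:
    df = pd.read_csv(path, sep="\t")
    return SensorTrace(df["time"].to_numpy(), df["jaw"].to_numpy(), df["body"].to_numpy())


# ---------------------------------------------------------------------------
# Step logging
# ---------------------------------------------------------------------------


class StepLogger:
    """Append-only JSON-lines log of every processing step.

    Each entry records a wall-clock timestamp, the action label and its
    full parameter set, so a session can be audited or replayed.
    """

    def __init__(self, path: str | Path | None = None):
        self.path = Path(path) if path is not None else None
        self.entries: list[dict] = []
        if self.path is not None and self.path.exists():
            for line in self.path.read_text().splitlines():
                if line.strip():
                    self.entries.append(json.loads(line))

    def log(self, action: str, **params) -> dict:
        entry = {"timestamp": _time.time(), "action": action,
                 "params": _jsonable(params)}
        self.entries.append(entry)
        if self.path is not None:
            with open(self.path, "a") as fh:
                fh.write(json.dumps(entry) + "\n")
        return entry

    def actions(self) -> list[str]:
        return [e["action"] for e in self.entries]

    def replay_commands(self) -> list[str]:
        """Render the log as the equivalent CLI invocation sequence."""
        cmds = []
        for e in self.entries:
            parts = [e["action"]]
            for k, v in sorted(e["params"].items()):
                parts.append(f"--{k.replace('_', '-')}" if v is True else
                             f"--{k.replace('_', '-')} {v}")
            cmds.append(" ".join(parts))
        return cmds


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj


def write_mask(mask: np.ndarray, voxel_size: Sequence[float], path: str | Path) -> None:
    """Write a boolean 3D mask as NIfTI uint8."""
    affine = np.diag(list(voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))


def read_mask(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0
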