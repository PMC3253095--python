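"""Per-volume quality control, trial rejection and concatenation.

QC rests on two cheap per-volume statistics: the ghost ratio (mean
intensity of a brain region over mean intensity of the region outside
the brain most affected by N/2 ghosting — higher is cleaner) and the
centre-of-mass shift relative to a reference volume.  Volumes failing
either check are flagged; any trial containing a flagged volume is
rejected as a whole, since movement that ghosts one volume also perturbs
the B0 field for the rest of the trial.  Manual review is represented by
explicit per-trial overrides, which always win — the subjectivity of eye
inspection is kept auditable rather than hidden.

Concatenation then removes everything outside accepted trials, yielding
a temporally discontinuous series plus a :class:`ConcatIndex` recording
the removed volumes and their original acquisition times.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core_io import (
    ACCEPTED,
    AUTO_FLAGGED,
    ConcatIndex,
    GapRecord,
    StepLogger,
    Trial,
    TrialTable,
    VolumeSeries,
)

__all__ = [
    "QCStats",
    "com_shift",
    "ghost_ratio",
    "default_ghost_roi",
    "compute_qc",
    "auto_flag",
    "reject_trials",
    "concatenate",
]


@dataclass
class QCStats:
    """Per-volume QC statistics plus the thresholds that produced the flags."""

    ghost_ratio: np.ndarray  # (n,)
    com_shift: np.ndarray  # (n, 3) mm relative to the reference volume
    auto_flag: np.ndarray  # (n,) bool
    ratio_threshold: float | str = "adaptive"
    com_threshold_mm: float = np.nan
    run_id: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "volume": np.arange(len(self.ghost_ratio)),
            "ghost_ratio": self.ghost_ratio,
            "com_x": self.com_shift[:, 0],
            "com_y": self.com_shift[:, 1],
            "com_z": self.com_shift[:, 2],
            "flag": self.auto_flag.astype(int),
        })
        if self.run_id is not None:
            df.insert(1, "run_id", self.run_id)
        return df


def com_shift(series: VolumeSeries, reference_index: int = 0) -> np.ndarray:
    """Intensity-weighted centroid of each volume minus the reference's, mm."""
    n = series.n_volumes
    if not 0 <= reference_index < n:
        raise IndexError(f"reference_index {reference_index} out of range")
    sums = series.data.reshape(-1, n).sum(axis=0)
    if np.any(sums == 0):
        raise ValueError("all-zero volume: centre of mass undefined")
    coms = np.empty((n, 3))
    for ax in range(3):
        idx = np.arange(series.data.shape[ax], dtype=float)
        shape = [1, 1, 1, 1]
        shape[ax] = -1
        weighted = (series.data * idx.reshape(shape)).reshape(-1, n).sum(axis=0)
        coms[:, ax] = weighted / sums * series.voxel_size[ax]
    return coms - coms[reference_index]


def ghost_ratio(volume: np.ndarray, brain_roi: np.ndarray,
                ghost_roi: np.ndarray) -> float:
    """mean(brain ROI) / mean(ghost ROI); higher means cleaner."""
    brain_roi = np.asarray(brain_roi, bool)
    ghost_roi = np.asarray(ghost_roi, bool)
    if not brain_roi.any() or not ghost_roi.any():
        raise ValueError("QC ROIs must be nonempty")
    if (brain_roi & ghost_roi).any():
        raise ValueError("brain and ghost ROIs must be disjoint")
    eps = 1e-12 * float(np.max(np.abs(volume)))
    return float(volume[brain_roi].mean() / (volume[ghost_roi].mean() + eps))


def default_ghost_roi(brain_mask: np.ndarray, phase_axis: int) -> np.ndarray:
    """Half-FOV-shifted brain footprint outside the brain: where the N/2
    ghost lands for this phase-encode axis."""
    brain_mask = np.asarray(brain_mask, bool)
    if not brain_mask.any():
        raise ValueError("brain mask is empty")
    n = brain_mask.shape[phase_axis]
    roi = np.roll(brain_mask, n // 2, axis=phase_axis) & ~brain_mask
    if not roi.any():
        raise ValueError("ghost ROI is empty (brain fills the field of view)")
    return roi


def compute_qc(
    series: VolumeSeries,
    brain_roi: np.ndarray,
    ghost_roi: np.ndarray | None = None,
    reference_index: int = 0,
    logger: StepLogger | None = None,
) -> QCStats:
    """Ghost ratios and CoM shifts for every volume (flags left unset)."""
    if ghost_roi is None:
        ghost_roi = default_ghost_roi(brain_roi, series.phase_axis)
    brain_roi = np.asarray(brain_roi, bool)
    ghost_roi = np.asarray(ghost_roi, bool)
    if not brain_roi.any() or not ghost_roi.any():
        raise ValueError("QC ROIs must be nonempty")
    if (brain_roi & ghost_roi).any():
        raise ValueError("brain and ghost ROIs must be disjoint")
    n = series.n_volumes
    flat = series.data.reshape(-1, n)
    brain_means = flat[brain_roi.reshape(-1)].mean(axis=0)
    ghost_means = flat[ghost_roi.reshape(-1)].mean(axis=0)
    eps = 1e-12 * np.max(np.abs(flat), axis=0)
    ratios = brain_means / (ghost_means + eps)
    shifts = com_shift(series, reference_index)
    if logger is not None:
        logger.log("qc", reference_index=reference_index,
                   n_volumes=series.n_volumes)
    return QCStats(ratios, shifts, np.zeros(series.n_volumes, bool),
                   run_id=series.run_id.copy())


def auto_flag(
    stats: QCStats,
    ratio_threshold: float | str = "adaptive",
    com_threshold_mm: float = 0.3,
    logger: StepLogger | None = None,
) -> np.ndarray:
    """Flag volumes whose ghost ratio is low or CoM shift is large.

    ``ratio_threshold='adaptive'`` sets the cut to median - 3*MAD of the
    ghost ratios within each run — a robust, scale-free stand-in for a
    manually tuned threshold.  A volume is flagged when its ghost ratio
    falls strictly below the cut or its CoM shift norm exceeds
    ``com_threshold_mm``.
    """
    if com_threshold_mm <= 0:
        raise ValueError("com_threshold_mm must be positive")
    ratios = stats.ghost_ratio
    n = len(ratios)
    if ratio_threshold == "adaptive":
        thr = np.empty(n)
        run_id = stats.run_id if stats.run_id is not None else np.zeros(n, int)
        for rid in np.unique(run_id):
            sel = run_id == rid
            med = np.median(ratios[sel])
            mad = np.median(np.abs(ratios[sel] - med))
            thr[sel] = med - 3.0 * mad
    else:
        if ratio_threshold <= 0:
            raise ValueError("ratio_threshold must be positive")
        thr = np.full(n, float(ratio_threshold))
    com_norm = np.linalg.norm(stats.com_shift, axis=1)
    flags = (ratios < thr) | (com_norm > com_threshold_mm)
    stats.auto_flag = flags
    stats.ratio_threshold = ratio_threshold
    stats.com_threshold_mm = com_threshold_mm
    if logger is not None:
        logger.log("auto_flag", ratio_threshold=ratio_threshold,
                   com_threshold_mm=com_threshold_mm, n_flagged=int(flags.sum()))
    return flags


def _global_span(trial: Trial, series: VolumeSeries) -> tuple[int, int]:
    offset = series.run_slice(trial.run_id).start
    return offset + trial.start_vol, offset + trial.end_vol


def reject_trials(
    trials: TrialTable,
    flags: np.ndarray,
    series: VolumeSeries,
    manual_overrides: Iterable[Mapping] | Mapping[int, str] = (),
    logger: StepLogger | None = None,
) -> TrialTable:
    """Whole-trial rejection from per-volume flags, then manual overrides.

    Any trial containing at least one flagged volume becomes
    ``auto_flagged``; overrides (``{trial_id: status}`` or records with
    those keys) are applied last and win unconditionally.
    """
    flags = np.asarray(flags, bool)
    if len(flags) != series.n_volumes:
        raise ValueError("flag vector length must equal series length")
    updates: dict[int, str] = {}
    for t in trials:
        a, b = _global_span(t, series)
        updates[t.trial_id] = AUTO_FLAGGED if flags[a:b + 1].any() else ACCEPTED
    if isinstance(manual_overrides, Mapping):
        overrides = dict(manual_overrides)
    else:
        overrides = {int(o["trial_id"]): str(o["status"]) for o in manual_overrides}
    updates.update(overrides)
    out = trials.with_status(updates)
    if logger is not None:
        logger.log("reject_trials", n_overrides=len(overrides),
                   n_accepted=len(out.accepted()))
    return out


def concatenate(
    series: VolumeSeries,
    trials: TrialTable,
    logger: StepLogger | None = None,
) -> tuple[VolumeSeries, ConcatIndex]:
    """Keep exactly the volumes of accepted trials, in original order.

    Returns the pruned series (original acquisition times and run labels
    preserved) together with the :class:`ConcatIndex` that records every
    removed volume and its original acquisition time.
    """
    trials.validate_against(series)
    accepted = trials.accepted()
    if not accepted:
        raise ValueError("no accepted trials to concatenate")
    kept: list[tuple[int, int]] = []
    keep_global: list[int] = []
    run_lengths = {rid: series.run_length(rid) for rid in series.runs()}
    accepted_by_run: dict[int, list[Trial]] = {}
    for t in sorted(accepted, key=lambda t: (t.run_id, t.start_vol)):
        accepted_by_run.setdefault(t.run_id, []).append(t)
    gaps: list[GapRecord] = []
    for rid in series.runs():
        offset = series.run_slice(rid).start
        length = run_lengths[rid]
        keep_idx = np.zeros(length, bool)
        for t in accepted_by_run.get(rid, []):
            keep_idx[t.start_vol:t.end_vol + 1] = True
        gap_run_start = len(kept)  # kept position before this run's volumes
        pending: list[int] = []
        for i in range(length):
            if keep_idx[i]:
                if pending:
                    gaps.append(GapRecord(rid, len(kept) - 1, pending,
                                          [series.acq_time[offset + j] for j in pending]))
                    pending = []
                kept.append((rid, i))
                keep_global.append(offset + i)
            else:
                pending.append(i)
        if pending:
            gaps.append(GapRecord(rid, len(kept) - 1, pending,
                                  [series.acq_time[offset + j] for j in pending]))
    index = ConcatIndex(kept, gaps, run_lengths)
    out = series.subset(np.asarray(keep_global, int))
    if logger is not None:
        logger.log("concatenate", n_kept=index.n_kept,
                   n_removed=series.n_volumes - index.n_kept)
    return out, index
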