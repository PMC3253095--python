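"""Gap-interpolated high-pass filtering for concatenated trial data.

A concatenated series is temporally discontinuous: filtering it directly
would treat samples separated by long real-time gaps as adjacent and
smear trial-boundary steps into the data.  Instead, each run is first
reconstituted on its original evenly-sampled time grid by linear
interpolation across the removed epochs: the anchor on each side of a
gap is the voxelwise average of the two trial volumes nearest the gap
(placed at the midpoint of their acquisition times), and each missing
volume is read off the straight line between the two anchors.  Runs are
then high-pass filtered one by one, and finally the interpolated samples
are discarded again, leaving filtered values only at the kept volumes.

The filter itself is a discrete-cosine-basis projection (the convention
of SPM-style fMRI analysis): the K non-constant DCT vectors with period
longer than the cutoff are projected out, with K = floor(2·N·TR/cutoff).
This is zero-phase, exactly idempotent and keeps the DC component — run
means are handled later by per-run intercepts in the GLM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_io import ConcatIndex, StepLogger, VolumeSeries

__all__ = [
    "FilterSettings",
    "interpolate_gaps",
    "highpass",
    "drop_interpolated",
    "gap_filtered_highpass",
]


@dataclass
class FilterSettings:
    cutoff_s: float = 96.0
    anchor_pair_size: int = 2

    def __post_init__(self) -> None:
        if self.anchor_pair_size < 1:
            raise ValueError("anchor_pair_size must be >= 1")


def _run_layout(index: ConcatIndex, run: int):
    """(kept concat positions, kept original indices) for one run."""
    pairs = index.kept_positions(run)
    pos = np.array([p for p, _ in pairs], int)
    idx = np.array([i for _, i in pairs], int)
    return pos, idx


def _segments(idx: np.ndarray) -> list[np.ndarray]:
    """Split kept original indices into contiguous blocks (= trials)."""
    if len(idx) == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1) + 1
    return np.split(np.arange(len(idx)), breaks)


def interpolate_gaps(
    concat: VolumeSeries,
    index: ConcatIndex,
    settings: FilterSettings | None = None,
    logger: StepLogger | None = None,
) -> VolumeSeries:
    """Reconstitute every run on its original time grid.

    Kept volumes are copied verbatim.  A gap between two kept blocks is
    filled by evaluating the line through the two anchors — the averages
    of the ``anchor_pair_size`` volumes adjacent to the gap on each side,
    placed at the midpoint of their acquisition times — at each missing
    volume's original acquisition time.  Gaps before the first (after the
    last) block of a run are filled by constant extension of the nearest
    anchor.  Single-volume blocks serve as their own anchor pair.
    """
    settings = settings or FilterSettings()
    if concat.n_volumes != index.n_kept:
        raise ValueError("series length does not match index.kept")
    tr = concat.intervolume_time
    m = settings.anchor_pair_size
    full_runs = []
    run_ids = []
    for run in sorted(index.run_lengths):
        pos, idx = _run_layout(index, run)
        if len(pos) == 0:
            raise ValueError(f"run {run} has no kept volumes to anchor on")
        length = index.run_lengths[run]
        full = np.empty(concat.spatial_shape + (length,))
        full[..., idx] = concat.data[..., pos]
        segs = _segments(idx)
        anchors = []  # (t_anchor_start, t_anchor_end, img_start, img_end) per segment
        for seg in segs:
            k = min(m, len(seg))
            head, tail = seg[:k], seg[-k:]
            t_head = float(np.mean(idx[head])) * tr
            t_tail = float(np.mean(idx[tail])) * tr
            img_head = concat.data[..., pos[head]].mean(axis=-1)
            img_tail = concat.data[..., pos[tail]].mean(axis=-1)
            anchors.append((t_head, t_tail, img_head, img_tail))
        kept_set = set(idx.tolist())
        missing = [i for i in range(length) if i not in kept_set]
        seg_first = [idx[s[0]] for s in segs]
        seg_last = [idx[s[-1]] for s in segs]
        for i in missing:
            t = i * tr
            after = None  # last segment ending before i
            before = None  # first segment starting after i
            for s, (first, last) in enumerate(zip(seg_first, seg_last)):
                if last < i:
                    after = s
                elif first > i and before is None:
                    before = s
            if after is not None and before is not None:
                t_a, img_a = anchors[after][1], anchors[after][3]
                t_b, img_b = anchors[before][0], anchors[before][2]
                w = (t - t_a) / (t_b - t_a)
                full[..., i] = (1.0 - w) * img_a + w * img_b
            elif before is not None:  # leading gap: constant extension
                full[..., i] = anchors[before][2]
            else:  # trailing gap
                full[..., i] = anchors[after][3]
        full_runs.append(full)
        run_ids.append(run)
    data = np.concatenate(full_runs, axis=-1)
    out = VolumeSeries.from_runs(data, concat.voxel_size, tr, concat.phase_axis,
                                 [index.run_lengths[r] for r in run_ids])
    # preserve the original run labels (from_runs numbers them 0..)
    out.run_id = np.concatenate([np.full(index.run_lengths[r], r, int)
                                 for r in run_ids])
    if logger is not None:
        logger.log("interpolate_gaps", anchor_pair_size=m,
                   n_filled=data.shape[-1] - concat.n_volumes)
    return out


def _dct_basis(n: int, k_max: int) -> np.ndarray:
    """Orthonormal non-constant DCT-II vectors 1..k_max, shape (n, k_max)."""
    ns = np.arange(n)
    B = np.cos(np.pi * (ns[:, None] + 0.5) * np.arange(1, k_max + 1)[None, :] / n)
    B *= np.sqrt(2.0 / n)
    return B


def highpass(
    series: VolumeSeries,
    settings: FilterSettings | None = None,
    logger: StepLogger | None = None,
) -> VolumeSeries:
    """Run-wise DCT high-pass filter.

    Per run and voxel, the projection onto the K non-constant cosine
    vectors with period > cutoff (K = floor(2·N·TR/cutoff)) is removed;
    the constant component is retained.  With cutoff <= 2·TR there is
    nothing to remove and the input is returned with a warning.
    """
    settings = settings or FilterSettings()
    tr = series.intervolume_time
    if settings.cutoff_s <= 2.0 * tr:
        warnings.warn("high-pass cutoff <= 2*TR removes no components; "
                      "returning input unchanged")
        return series.with_data(series.data.copy())
    out = np.empty_like(series.data)
    for run in series.runs():
        sl = series.run_slice(run)
        block = series.data[..., sl]
        n = block.shape[-1]
        k = int(np.floor(2.0 * n * tr / settings.cutoff_s))
        if k < 1:
            out[..., sl] = block
            continue
        B = _dct_basis(n, k)
        flat = block.reshape(-1, n)
        out[..., sl] = (flat - (flat @ B) @ B.T).reshape(block.shape)
    if logger is not None:
        logger.log("highpass", cutoff_s=settings.cutoff_s)
    return series.with_data(out)


def drop_interpolated(
    filtered: VolumeSeries,
    index: ConcatIndex,
    logger: StepLogger | None = None,
) -> VolumeSeries:
    """Discard interpolated samples, returning exactly the kept volumes."""
    total = sum(index.run_lengths.values())
    if filtered.n_volumes != total:
        raise ValueError(
            f"series length {filtered.n_volumes} does not match the original "
            f"grid length {total}")
    keep = []
    for run in sorted(index.run_lengths):
        offset = filtered.run_slice(run).start
        _, idx = _run_layout(index, run)
        keep.extend((offset + i) for i in idx)
    out = filtered.subset(np.asarray(keep, int))
    if logger is not None:
        logger.log("drop_interpolated", n_kept=index.n_kept)
    return out


def gap_filtered_highpass(
    concat: VolumeSeries,
    index: ConcatIndex,
    settings: FilterSettings | None = None,
    logger: StepLogger | None = None,
) -> VolumeSeries:
    """interpolate → run-wise high-pass → drop interpolated samples."""
    settings = settings or FilterSettings()
    full = interpolate_gaps(concat, index, settings, logger=logger)
    filtered = highpass(full, settings, logger=logger)
    out = drop_interpolated(filtered, index, logger=logger)
    if logger is not None:
        logger.log("gap_filtered_highpass", cutoff_s=settings.cutoff_s,
                   anchor_pair_size=settings.anchor_pair_size)
    return out
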