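"""Seeded generator of awake-NHP-like fMRI sessions with ground truth.

Real awake-monkey sessions at high field show a characteristic artefact
phenomenology: the animal holds still during short task trials and moves
(jaw, body) between them, producing N/2 ghosts in segmented EPI volumes,
apparent shifts along the phase-encode axis, and between-trial changes of
brain position and shape; on top of that sit slow scanner drifts,
stepwise intensity offsets between runs and a receive-coil bias field.
No such dataset ships with this package — the simulator emulates those
features on an ellipsoidal phantom with brain-adjacent "muscle" tissue,
and records everything it injected so every downstream module can be
scored against a known truth.

The geometric corruption model deliberately mirrors what the 2-step
realignment corrects: a pure sinusoidal translation along the phase axis
within trials (respiration-like; B0-induced apparent shifts and true
motion are not distinguished — the correction is the same for both) and
a small 12-parameter affine per trial for every trial after the first.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from . import geometry
from .core_io import (
    AffineParams,
    Event,
    SensorTrace,
    Trial,
    TrialTable,
    VolumeSeries,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "make_phantom",
    "apply_bias_field",
    "inject_ghost",
    "simulate_session",
]

BRAIN_INTENSITY = 1000.0
MUSCLE_INTENSITY = 1030.0
BACKGROUND_INTENSITY = 80.0


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """All knobs of the session simulator; ``seed`` fixes every random draw.

    Amplitudes expressed as fractions are relative to the mean brain
    intensity of the phantom.  The default layout mirrors a two-run
    awake-macaque session at desk scale: 64x64x11 grid, 2 runs of 150
    volumes at a 2 s inter-volume time, five 15-volume trials per run
    separated by 10-volume inter-trial gaps.
    """

    shape: tuple[int, int, int] = (64, 64, 11)
    voxel_size: tuple[float, float, float] = (1.5, 1.5, 2.0)
    phase_axis: str = "y"
    n_runs: int = 2
    volumes_per_run: int = 150
    intervolume_time: float = 2.0
    n_trials_per_run: int = 5
    trial_length_vols: int = 15
    gap_length_vols: int = 10
    # task & activation
    fixation_duration_s: float = 6.0
    stimulation_duration_s: float = 2.0
    blob_centers_mm: tuple[tuple[float, float, float], ...] | None = None
    blob_radius_mm: float = 4.0
    activation_amplitude: float = 0.03  # fractional signal change at regressor peak
    # nuisance structure
    drift_linear: float = 0.02  # fractional drift over one run
    drift_cosine_period_s: float = 180.0
    drift_cosine_amplitude: float = 0.015
    run_step_offset: float = 0.03  # fractional step added per run index
    noise_sd: float = 0.01  # white noise, fraction of brain mean
    # geometric corruption
    shift_amplitude_mm: float = 0.2  # within-trial respiratory-like shift
    shift_period_s: float = 3.0
    affine_max_translation_mm: float = 1.0
    affine_max_rotation_rad: float = 0.015
    affine_max_scale_dev: float = 0.01
    affine_max_shear: float = 0.01
    gap_shift_mm: float = 1.0  # between-trial repositioning, per gap volume
    # ghosting
    ghost_fraction: float = 0.1  # fraction of inter-trial volumes ghosted
    ghost_amplitude: float = 0.3
    bad_trial_ids: tuple[int, ...] = ()  # trials seeded with in-trial ghosts
    # bias field
    bias_strength: float = 1.0
    bias_center_vox: tuple[float, float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("activation_amplitude", "drift_cosine_amplitude", "noise_sd",
                     "shift_amplitude_mm", "affine_max_translation_mm",
                     "affine_max_rotation_rad", "affine_max_scale_dev",
                     "affine_max_shear", "gap_shift_mm", "ghost_fraction",
                     "ghost_amplitude", "bias_strength"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        need = (self.gap_length_vols
                + self.n_trials_per_run * self.trial_length_vols
                + (self.n_trials_per_run - 1) * self.gap_length_vols)
        if need > self.volumes_per_run:
            raise ValueError(
                f"trial layout needs {need} volumes but runs have {self.volumes_per_run}"
            )
        ev = self.fixation_duration_s + self.stimulation_duration_s
        if ev > self.trial_length_vols * self.intervolume_time + 1e-9:
            raise ValueError("fixation+stimulation events do not fit within a trial")

    def replace(self, **kw) -> "SimConfig":
        return replace(self, **kw)

    @classmethod
    def default(cls, seed: int = 0) -> "SimConfig":
        return cls(seed=seed)

    @classmethod
    def small(cls, seed: int = 0) -> "SimConfig":
        """Reduced grid/run length for optimization-heavy comparisons."""
        return cls(shape=(32, 32, 8), voxel_size=(2.0, 2.0, 2.0), n_runs=2,
                   volumes_per_run=100, n_trials_per_run=4, trial_length_vols=12,
                   gap_length_vols=8, blob_radius_mm=5.0, seed=seed)


@dataclass
class GroundTruth:
    """Everything the simulator injected, for use as a test oracle."""

    brain_mask: np.ndarray
    muscle_mask: np.ndarray
    activation_map: np.ndarray
    injected_shift1d: np.ndarray  # mm per volume (global index)
    injected_affine: dict[int, AffineParams]  # trial_id -> corruption map
    artefact_volumes: set[int]  # global indices of ghost-corrupted volumes
    bad_trials: set[int]
    trial_of_volume: np.ndarray  # trial_id per global volume, -1 for gaps
    clean_baseline: np.ndarray  # phantom x bias field
    clean_series: VolumeSeries  # signal before geometry/noise/ghosts


# ---------------------------------------------------------------------------
# Phantom
# ---------------------------------------------------------------------------


def make_phantom(
    shape: Sequence[int],
    voxel_size: Sequence[float],
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ellipsoidal brain with smooth texture plus a partial muscle shell.

    The muscle shell sits posterior to the brain (positive y) with a mean
    intensity close to the brain mean, emulating the jaw musculature that
    defeats naive intensity-threshold extraction.  Background is a dim
    noise-floor plateau rather than true zero, as in magnitude EPI.
    """
    shape = tuple(int(s) for s in shape)
    voxel_size = np.asarray(voxel_size, float).reshape(3)
    if shape[0] < 16 or shape[1] < 16 or shape[2] < 4:
        raise ValueError(f"grid too small for a phantom: {shape}")
    rng = np.random.default_rng(seed)
    c = geometry.grid_center(shape)
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    mm = [(g - ci) * vi for g, ci, vi in zip(grids, c, voxel_size)]
    half_extent = np.asarray(shape, float) * voxel_size / 2.0
    semi = np.array([0.62 * half_extent[0], 0.62 * half_extent[1],
                     0.80 * half_extent[2]])
    r2 = sum((m / s) ** 2 for m, s in zip(mm, semi))
    brain_mask = r2 <= 1.0
    # the skull/CSF gap between brain and muscle is a few millimetres;
    # jaw/neck muscle runs alongside the imaged slab (posterior, in-plane),
    # not above or below the slice stack
    shell = (r2 <= 1.45 ** 2) & (r2 > 1.18 ** 2)
    muscle_mask = shell & (mm[1] > 0) & (np.abs(mm[2]) <= 0.9 * semi[2])
    muscle_mask &= ~brain_mask

    def _texture(scale: float, sigma: float) -> np.ndarray:
        t = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
        sd = t.std()
        if sd > 0:
            t = t / sd
        return 1.0 + scale * t

    baseline = np.full(shape, BACKGROUND_INTENSITY)
    baseline[brain_mask] = (BRAIN_INTENSITY * _texture(0.10, 2.5))[brain_mask]
    baseline[muscle_mask] = (MUSCLE_INTENSITY * _texture(0.05, 2.0))[muscle_mask]
    # acquisition point-spread function: in-plane readout blur plus slight
    # slice cross-talk (2D multislice acquisition, so z stays nearly sharp)
    baseline = ndimage.gaussian_filter(baseline, (0.8, 0.8, 0.65))
    return baseline, brain_mask, muscle_mask


def apply_bias_field(
    image: np.ndarray,
    center: Sequence[float],
    strength: float,
) -> np.ndarray:
    """Multiply by a radial receive-coil-like bias field.

    ``b(x) = 1 + strength * (1 - d(x, center)/d_max)`` with ``d`` in mm and
    ``d_max`` the distance from the centre to the farthest grid corner, so
    ``1 <= b <= 1 + strength`` and ``strength = 0`` is the identity.
    """
    if strength < 0:
        raise ValueError("strength must be >= 0")
    center = np.asarray(center, float).reshape(3)
    shape = image.shape[:3]
    if np.any(center < 0) or np.any(center > np.asarray(shape) - 1):
        raise ValueError(f"bias center {center} outside grid {shape}")
    if strength == 0:
        return image.copy()
    field = bias_field(shape, np.ones(3), center, strength)
    return image * field


def bias_field(shape, voxel_size, center, strength) -> np.ndarray:
    voxel_size = np.asarray(voxel_size, float).reshape(3)
    center = np.asarray(center, float).reshape(3)
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    d = np.sqrt(sum(((g - ci) * vi) ** 2
                    for g, ci, vi in zip(grids, center, voxel_size)))
    corners = np.array(np.meshgrid(*[[0, s - 1] for s in shape],
                                   indexing="ij")).reshape(3, -1).T
    d_max = max(np.sqrt(np.sum(((corner - center) * voxel_size) ** 2))
                for corner in corners)
    return 1.0 + strength * (1.0 - d / d_max)


def inject_ghost(volume: np.ndarray, phase_axis: int, amplitude: float) -> np.ndarray:
    """Add an N/2 ghost: a half-field-of-view circularly shifted copy.

    This is the dominant artefact of segmented EPI under inter-shot
    inconsistency (movement); ``amplitude`` is the fraction of the source
    image added at the shifted position.
    """
    if amplitude < 0:
        raise ValueError("ghost amplitude must be >= 0")
    if amplitude == 0:
        return volume.copy()
    n = volume.shape[phase_axis]
    return volume + amplitude * np.roll(volume, n // 2, axis=phase_axis)


# ---------------------------------------------------------------------------
# Session assembly
# ---------------------------------------------------------------------------


def _trial_layout(config: SimConfig) -> TrialTable:
    trials = []
    tid = 0
    for run in range(config.n_runs):
        start = config.gap_length_vols
        for _ in range(config.n_trials_per_run):
            end = start + config.trial_length_vols - 1
            t0 = start * config.intervolume_time
            events = [
                Event("fixation", t0, config.fixation_duration_s),
                Event("stimulation", t0 + config.fixation_duration_s,
                      config.stimulation_duration_s),
            ]
            trials.append(Trial(tid, run, start, end, events))
            tid += 1
            start = end + 1 + config.gap_length_vols
    return TrialTable(trials)


def _activation_map(config: SimConfig, brain_mask: np.ndarray) -> np.ndarray:
    voxel_size = np.asarray(config.voxel_size, float)
    c = geometry.grid_center(config.shape)
    if config.blob_centers_mm is None:
        centers = [(-10.0, -4.0, 0.0), (10.0, -4.0, 0.0)]
    else:
        centers = [tuple(b) for b in config.blob_centers_mm]
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in config.shape],
                        indexing="ij")
    mm = [(g - ci) * vi for g, ci, vi in zip(grids, c, voxel_size)]
    act = np.zeros(config.shape, dtype=bool)
    for bx, by, bz in centers:
        d2 = (mm[0] - bx) ** 2 + (mm[1] - by) ** 2 + (mm[2] - bz) ** 2
        act |= d2 <= config.blob_radius_mm ** 2
    act &= brain_mask
    if not act.any():
        raise ValueError("activation blobs fall entirely outside the brain")
    return act


def simulate_session(
    config: SimConfig,
) -> tuple[VolumeSeries, TrialTable, SensorTrace, GroundTruth]:
    """Generate one multi-run session plus its ground truth.

    Signal model per volume ``t``:
    ``baseline x bias x (1 + activation·r(t) + drift(t) + step(run))``
    with ``r`` the HRF-convolved stimulation regressor (peak-normalized),
    followed by per-volume geometric corruption (within-trial sinusoidal
    phase-axis shift, per-trial affine jitter for trials after the first,
    random phase-axis repositioning during gaps), white noise, and N/2
    ghosts on a seeded subset of inter-trial volumes and on every volume
    of ``bad_trial_ids``.
    """
    from .glm_eval import build_regressors  # late import, avoids a cycle

    rng = np.random.default_rng(config.seed)
    phase = "xyz".index(config.phase_axis.lower()) if isinstance(config.phase_axis, str) \
        else int(config.phase_axis)
    voxel_size = np.asarray(config.voxel_size, float)
    tr = config.intervolume_time
    n_total = config.n_runs * config.volumes_per_run

    baseline, brain_mask, muscle_mask = make_phantom(config.shape, voxel_size,
                                                     seed=config.seed)
    if config.bias_center_vox is None:
        bias_center = geometry.grid_center(config.shape) + np.array(
            [0.0, -0.2 * config.shape[1], 0.0])
    else:
        bias_center = np.asarray(config.bias_center_vox, float)
    bias = bias_field(config.shape, voxel_size, bias_center, config.bias_strength)
    clean_baseline = baseline * bias
    brain_mean = baseline[brain_mask].mean()

    trials = _trial_layout(config)
    unknown_bad = set(config.bad_trial_ids) - {t.trial_id for t in trials}
    if unknown_bad:
        raise ValueError(f"bad_trial_ids not in layout: {sorted(unknown_bad)}")

    act_map = _activation_map(config, brain_mask)
    run_lengths = [config.volumes_per_run] * config.n_runs
    reg = build_regressors(trials, run_lengths, tr, ["stimulation"])
    r_t = reg["stimulation"].to_numpy()

    # per-volume bookkeeping on the global index
    trial_of_volume = np.full(n_total, -1, dtype=int)
    for t in trials:
        off = t.run_id * config.volumes_per_run
        trial_of_volume[off + t.start_vol: off + t.end_vol + 1] = t.trial_id
    gap_vols = np.flatnonzero(trial_of_volume < 0)

    # geometric truth ------------------------------------------------------
    shift1d = np.zeros(n_total)
    for t in trials:
        off = t.run_id * config.volumes_per_run
        for k in range(t.n_vols):
            tt = k * tr
            shift1d[off + t.start_vol + k] = config.shift_amplitude_mm * np.sin(
                2.0 * np.pi * tt / config.shift_period_s)
    if config.gap_shift_mm > 0:
        shift1d[gap_vols] = rng.uniform(-config.gap_shift_mm, config.gap_shift_mm,
                                        size=len(gap_vols))

    injected_affine: dict[int, AffineParams] = {}
    for i, t in enumerate(trials):
        if i == 0:
            injected_affine[t.trial_id] = AffineParams.identity()
            continue
        u = lambda m: rng.uniform(-m, m, size=3)
        injected_affine[t.trial_id] = AffineParams(
            u(config.affine_max_translation_mm),
            u(config.affine_max_rotation_rad),
            1.0 + u(config.affine_max_scale_dev),
            u(config.affine_max_shear),
        )

    # ghost selection ------------------------------------------------------
    n_ghost = int(round(config.ghost_fraction * len(gap_vols)))
    ghosted_gaps = set(rng.choice(gap_vols, size=n_ghost, replace=False).tolist()) \
        if n_ghost > 0 else set()
    bad_trial_vols: set[int] = set()
    for t in trials:
        if t.trial_id in config.bad_trial_ids:
            off = t.run_id * config.volumes_per_run
            bad_trial_vols.update(range(off + t.start_vol, off + t.end_vol + 1))
    artefact_volumes = ghosted_gaps | bad_trial_vols

    # assemble -------------------------------------------------------------
    act = act_map.astype(float) * config.activation_amplitude
    noise_sd = config.noise_sd * brain_mean
    run_of_volume = np.repeat(np.arange(config.n_runs), config.volumes_per_run)
    t_in_run = np.tile(np.arange(config.volumes_per_run) * tr, config.n_runs)
    drift_t = (config.drift_linear * (t_in_run / (config.volumes_per_run * tr))
               + config.drift_cosine_amplitude
               * np.cos(2.0 * np.pi * t_in_run / config.drift_cosine_period_s))
    mod_t = 1.0 + drift_t + config.run_step_offset * run_of_volume
    clean = (clean_baseline[..., np.newaxis]
             * (mod_t[np.newaxis, np.newaxis, np.newaxis, :]
                + act[..., np.newaxis] * r_t[np.newaxis, np.newaxis, np.newaxis, :]))
    data = clean.copy()
    identity = np.eye(4)
    for g in range(n_total):
        tid = trial_of_volume[g]
        M = injected_affine[tid].matrix() if tid >= 0 else identity
        s_vox = shift1d[g] / voxel_size[phase]
        if np.allclose(M, identity) and abs(s_vox) < 1e-14:
            continue
        pre = np.zeros(3)
        pre[phase] = s_vox
        data[..., g] = geometry.resample(clean[..., g], M, voxel_size,
                                         pre_translation_vox=pre, order=3)
    if noise_sd > 0:
        data += rng.normal(0.0, noise_sd, size=data.shape)
    if artefact_volumes and config.ghost_amplitude > 0:
        idx = sorted(artefact_volumes)
        block = data[..., idx]
        n_half = config.shape[phase] // 2
        data[..., idx] = block + config.ghost_amplitude * np.roll(
            block, n_half, axis=phase)

    series = VolumeSeries.from_runs(data, voxel_size, tr, phase, run_lengths)
    clean_series = VolumeSeries.from_runs(clean, voxel_size, tr, phase, run_lengths)

    # motion-sensor trace: elevated during inter-trial windows -------------
    t_global = np.arange(n_total) * tr
    jaw = 0.05 + 0.01 * rng.standard_normal(n_total)
    body = 0.05 + 0.01 * rng.standard_normal(n_total)
    jaw[gap_vols] += 1.0
    body[gap_vols] += 0.8
    sensor = SensorTrace(t_global, jaw, body)

    truth = GroundTruth(
        brain_mask=brain_mask,
        muscle_mask=muscle_mask,
        activation_map=act_map,
        injected_shift1d=shift1d,
        injected_affine=injected_affine,
        artefact_volumes=artefact_volumes,
        bad_trials=set(config.bad_trial_ids),
        trial_of_volume=trial_of_volume,
        clean_baseline=clean_baseline,
        clean_series=clean_series,
    )
    return series, trials, sensor, truth
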