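"""Regressor construction, OLS GLM with t-maps, and the method-comparison
harness.

Regressors are built on the *original* (pre-concatenation) time grid of
each run — event boxcars sampled at a fine grid (TR/16), convolved with
the canonical double-gamma hemodynamic response and read off at the
volume acquisition times — and any concatenation applied to the data is
applied to the regressor rows as well, keeping data and model temporally
coherent.  Runs are modelled as separate sessions: each gets its own
intercept column, which absorbs the stepwise intensity offsets that
remain between runs after filtering.

The model is ordinary least squares per voxel (no autocorrelation
correction — the simulated noise is white), with optional grand-mean
scaling of the whole dataset to 100 and t-statistics for a contrast of
the condition columns.  Map quality is summarized, as in the evaluation
this package is built around, by the number and proportion of voxels
whose t exceeds a fixed threshold (default 3.11, i.e. p < 0.001
uncorrected at the degrees of freedom of the reference analyses).

Five analysis presets are compared:

1. rigid 6-DOF realignment of the full series, standard GLM;
2. method 1 plus a one-hot artefact regressor per flagged volume;
3. trial concatenation, then rigid realignment and per-run sessions;
4. concatenation with the 2-step (1-DOF + per-trial affine) realignment;
5. method 4 plus gap-interpolated 96 s high-pass filtering.

All presets share 2 mm FWHM smoothing and an SPM-convention 128 s
high-pass applied to data and condition regressors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from . import brain_extract, qc_select, realign, temporal_filter
from .core_io import ConcatIndex, StepLogger, TrialTable, VolumeSeries

__all__ = [
    "EvalConfig",
    "DesignMatrix",
    "GLMResult",
    "canonical_hrf",
    "build_regressors",
    "select_regressor_rows",
    "smooth_spatial",
    "build_design",
    "fit_glm",
    "count_suprathreshold",
    "run_method",
    "compare_methods",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


# ---------------------------------------------------------------------------
# HRF and regressors
# ---------------------------------------------------------------------------


def canonical_hrf(dt: float, length_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at ``dt`` seconds.

    Peak delay 6 s, undershoot delay 16 s, unit dispersions, undershoot
    ratio 1/6; peak-normalized to 1.  The kernel starts at t = 0 (value
    exactly 0) and runs for 32 s.
    """
    from scipy.stats import gamma

    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, length_s + dt / 2, dt)
    h = gamma.pdf(t, a=6.0, scale=1.0) - gamma.pdf(t, a=16.0, scale=1.0) / 6.0
    peak = h.max()
    return h / peak if peak > 0 else h


def _run_offsets(run_lengths) -> tuple[list[int], dict[int, int], dict[int, int]]:
    """Sorted run ids, per-run global offset, per-run length."""
    if isinstance(run_lengths, Mapping):
        runs = sorted(run_lengths)
        lengths = {r: int(run_lengths[r]) for r in runs}
    else:
        runs = list(range(len(run_lengths)))
        lengths = {r: int(n) for r, n in enumerate(run_lengths)}
    offsets = {}
    acc = 0
    for r in runs:
        offsets[r] = acc
        acc += lengths[r]
    return runs, offsets, lengths


def build_regressors(
    trials: TrialTable,
    run_lengths,
    tr: float,
    conditions: Sequence[str],
    oversample: int = 16,
) -> pd.DataFrame:
    """Condition regressors on the original volume grid of every run.

    Event boxcars (onset/duration in seconds from run start) are laid on
    a grid of ``tr/oversample``, convolved with :func:`canonical_hrf`
    and sampled at the volume times; each condition is then normalized
    to unit peak over the session so amplitudes read as fractional
    signal change at the regressor peak.  Rows cover all runs in global
    volume order.  Requesting a condition that appears in no event of a
    non-empty table is an error.
    """
    runs, offsets, lengths = _run_offsets(run_lengths)
    total = sum(lengths.values())
    seen = {ev.condition for t in trials for ev in t.events}
    for cond in conditions:
        if seen and cond not in seen:
            raise KeyError(f"condition {cond!r} not present in any trial event")
    dt = tr / oversample
    hrf = canonical_hrf(dt)
    out = np.zeros((total, len(conditions)))
    for r in runs:
        n = lengths[r]
        fine_n = n * oversample + len(hrf)
        fine_t = np.arange(fine_n) * dt
        for j, cond in enumerate(conditions):
            box = np.zeros(fine_n)
            for t in trials:
                if t.run_id != r:
                    continue
                for ev in t.events:
                    if ev.condition == cond:
                        box[(fine_t >= ev.onset) & (fine_t < ev.onset + ev.duration)] = 1.0
            conv = np.convolve(box, hrf)[:fine_n] * dt
            sample = conv[(np.arange(n) * oversample)]
            out[offsets[r]:offsets[r] + n, j] = sample
    peaks = out.max(axis=0)
    for j in range(len(conditions)):
        if peaks[j] > 0:
            out[:, j] /= peaks[j]
    return pd.DataFrame(out, columns=list(conditions))


def select_regressor_rows(regressors: pd.DataFrame, index: ConcatIndex) -> pd.DataFrame:
    """Apply a concatenation to regressors: keep the rows of kept volumes."""
    runs, offsets, lengths = _run_offsets(index.run_lengths)
    total = sum(lengths.values())
    if len(regressors) != total:
        raise ValueError(
            f"regressors have {len(regressors)} rows but the original grid "
            f"has {total} volumes")
    rows = [offsets[r] + i for r, i in index.kept]
    return regressors.iloc[rows].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Design and GLM
# ---------------------------------------------------------------------------


@dataclass
class DesignMatrix:
    X: np.ndarray  # (n, p)
    names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, float)
        if self.X.shape[1] != len(self.names):
            raise ValueError("names must match design columns")

    def contrast(self, weights: Mapping[str, float]) -> np.ndarray:
        unknown = set(weights) - set(self.names)
        if unknown:
            raise KeyError(f"unknown design columns: {sorted(unknown)}")
        return np.array([weights.get(nm, 0.0) for nm in self.names])


def build_design(
    regressors: pd.DataFrame,
    run_id: np.ndarray,
    artefact_rows: Sequence[int] = (),
) -> DesignMatrix:
    """Condition columns + one-hot artefact columns + per-run intercepts."""
    n = len(regressors)
    run_id = np.asarray(run_id, int)
    if len(run_id) != n:
        raise ValueError("run_id length must match regressor rows")
    cols = [regressors.to_numpy()]
    names = list(regressors.columns)
    for v in sorted(set(int(v) for v in artefact_rows)):
        if not 0 <= v < n:
            raise IndexError(f"artefact row {v} out of range")
        onehot = np.zeros((n, 1))
        onehot[v, 0] = 1.0
        cols.append(onehot)
        names.append(f"artefact_{v}")
    for r in sorted(set(run_id.tolist())):
        cols.append((run_id == r).astype(float)[:, None])
        names.append(f"run_{r}")
    return DesignMatrix(np.hstack(cols), names)


@dataclass
class GLMResult:
    beta: np.ndarray  # (*spatial, p)
    sigma2: np.ndarray  # (*spatial,)
    t: np.ndarray  # (*spatial,)
    df: int
    names: list[str]
    degenerate: np.ndarray  # (*spatial,) bool: near-zero residual variance


def fit_glm(
    series: VolumeSeries,
    design: DesignMatrix,
    contrast: np.ndarray,
    grand_mean_scale: bool = True,
    mask: np.ndarray | None = None,
    logger: StepLogger | None = None,
) -> GLMResult:
    """Voxelwise OLS with a t-map for one contrast.

    With ``grand_mean_scale`` the whole dataset is scaled so the grand
    mean (within ``mask`` if given) equals 100 before fitting; this
    rescales betas and residuals jointly and leaves t-maps unchanged.
    Voxels with residual variance below 1e-12 x grand mean are flagged
    degenerate and given t = 0.
    """
    X = design.X
    n, p = X.shape
    if series.n_volumes != n:
        raise ValueError("design rows must equal series length")
    contrast = np.asarray(contrast, float).reshape(p)
    rank = int(np.linalg.matrix_rank(X))
    df = n - rank
    if df <= 0:
        raise ValueError(f"no residual degrees of freedom (n={n}, rank={rank})")
    if rank < p:
        import warnings

        warnings.warn("rank-deficient design; using the pseudo-inverse")
    data = series.data
    spatial = data.shape[:3]
    y = data.reshape(-1, n)
    if grand_mean_scale:
        sel = mask.reshape(-1) if mask is not None else slice(None)
        gm = float(y[sel].mean())
        if gm != 0:
            y = y * (100.0 / gm)
        grand_mean = 100.0
    else:
        grand_mean = float(y.mean())
    pinvX = np.linalg.pinv(X)
    beta = y @ pinvX.T  # (V, p)
    resid = y - beta @ X.T
    rss = np.einsum("vn,vn->v", resid, resid)
    sigma2 = rss / df
    xtx_pinv = np.linalg.pinv(X.T @ X)
    c_var = float(contrast @ xtx_pinv @ contrast)
    degenerate = sigma2 < 1e-12 * abs(grand_mean)
    denom = np.sqrt(np.maximum(sigma2, 1e-300) * c_var)
    t = (beta @ contrast) / denom
    t[degenerate] = 0.0
    if logger is not None:
        logger.log("fit_glm", n=n, p=p, df=df,
                   grand_mean_scale=grand_mean_scale)
    return GLMResult(beta.reshape(spatial + (p,)), sigma2.reshape(spatial),
                     t.reshape(spatial), df, list(design.names),
                     degenerate.reshape(spatial))


def count_suprathreshold(
    result: GLMResult,
    mask: np.ndarray,
    threshold: float,
) -> tuple[int, float]:
    """In-mask voxels with t strictly above the threshold, and proportion."""
    mask = np.asarray(mask, bool)
    total = int(mask.sum())
    if total == 0:
        raise ValueError("empty mask")
    count = int(np.sum(result.t[mask] > threshold))
    return count, count / total


def smooth_spatial(series: VolumeSeries, fwhm_mm) -> VolumeSeries:
    """Per-volume Gaussian smoothing, FWHM given in mm per axis."""
    fwhm = np.asarray(fwhm_mm, float).reshape(3)
    if np.any(fwhm < 0):
        raise ValueError("fwhm must be >= 0 per axis")
    if np.all(fwhm == 0):
        return series.with_data(series.data.copy())
    sigma_vox = fwhm * _FWHM_TO_SIGMA / series.voxel_size
    out = ndimage.gaussian_filter(series.data, sigma=tuple(sigma_vox) + (0.0,))
    return series.with_data(out)


# ---------------------------------------------------------------------------
# Method comparison harness
# ---------------------------------------------------------------------------


@dataclass
class EvalConfig:
    """Parameters of the method-comparison presets."""

    threshold: float = 3.11
    smooth_fwhm_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    spm_cutoff_s: float = 128.0  # applied in every preset, data + regressors
    gap_cutoff_s: float = 96.0  # method 5 only, gap-interpolated, data only
    contrast: tuple[str, str] = ("stimulation", "fixation")
    ratio_threshold: float | str = "adaptive"
    # between-trial repositioning is expected and corrected by realignment,
    # so the harness flags on CoM only for gross (super-repositioning) motion
    com_threshold_mm: float = 2.0
    grand_mean_scale: bool = True
    manual_overrides: tuple = ()
    mask: np.ndarray | None = None  # analysis mask; None = extract per method
    extraction: brain_extract.ExtractionParams | None = None
    registration: realign.RegistrationSettings = field(
        default_factory=realign.RegistrationSettings)


def _naive_highpass(series: VolumeSeries, cutoff_s: float) -> VolumeSeries:
    """Run-wise DCT high-pass applied directly to (possibly concatenated)
    samples, the way an SPM-style model-side filter would see them."""
    return temporal_filter.highpass(
        series, temporal_filter.FilterSettings(cutoff_s=cutoff_s))


def _filter_regressors(reg: pd.DataFrame, run_id: np.ndarray, tr: float,
                       cutoff_s: float) -> pd.DataFrame:
    """Apply the model-side high-pass to the condition regressors."""
    x = reg.to_numpy().copy()
    for r in sorted(set(run_id.tolist())):
        sel = run_id == r
        n = int(sel.sum())
        k = int(np.floor(2.0 * n * tr / cutoff_s))
        if k < 1:
            continue
        B = temporal_filter._dct_basis(n, k)
        block = x[sel]
        x[sel] = block - B @ (B.T @ block)
    return pd.DataFrame(x, columns=reg.columns)


class _SessionAnalysis:
    """Caches the preprocessing stages shared between method presets."""

    def __init__(self, series: VolumeSeries, trials: TrialTable,
                 config: EvalConfig | None = None,
                 brain_roi: np.ndarray | None = None):
        self.series = series
        self.trials = trials
        self.config = config or EvalConfig()
        self._brain_roi = brain_roi
        self._cache: dict[str, object] = {}

    def _get(self, key: str, fn):
        if key not in self._cache:
            self._cache[key] = fn()
        return self._cache[key]

    # -- QC ---------------------------------------------------------------

    def brain_roi(self) -> np.ndarray:
        def make():
            if self._brain_roi is not None:
                return self._brain_roi
            mean_img = self.series.data.mean(axis=-1)
            params = self.config.extraction or brain_extract.ExtractionParams(
                center=brain_extract.default_center(mean_img))
            weighted = brain_extract.radial_weight(mean_img, params,
                                                   self.series.voxel_size)
            return brain_extract.threshold_and_fill(weighted, params)
        return self._get("brain_roi", make)

    def flags(self) -> np.ndarray:
        def make():
            # CoM is referenced to the first trial volume, not the first
            # (inter-trial, possibly shifted) volume of the session
            first = sorted(self.trials, key=lambda t: (t.run_id, t.start_vol))[0]
            ref = self.series.run_slice(first.run_id).start + first.start_vol
            stats = qc_select.compute_qc(self.series, self.brain_roi(),
                                         reference_index=ref)
            return qc_select.auto_flag(stats, self.config.ratio_threshold,
                                       self.config.com_threshold_mm)
        return self._get("flags", make)

    def trials_selected(self) -> TrialTable:
        return self._get("trials_selected", lambda: qc_select.reject_trials(
            self.trials, self.flags(), self.series,
            list(self.config.manual_overrides)))

    def concat(self) -> tuple[VolumeSeries, ConcatIndex]:
        return self._get("concat", lambda: qc_select.concatenate(
            self.series, self.trials_selected()))

    # -- realignment variants ---------------------------------------------

    def rigid_full(self) -> VolumeSeries:
        def make():
            params = realign.rigid_realign_series(
                self.series, 0, self.config.registration)
            return realign.reslice_rigid(self.series, params,
                                         self.config.registration)
        return self._get("rigid_full", make)

    def rigid_concat(self) -> VolumeSeries:
        def make():
            concat, _ = self.concat()
            params = realign.rigid_realign_series(concat, 0,
                                                  self.config.registration)
            return realign.reslice_rigid(concat, params, self.config.registration)
        return self._get("rigid_concat", make)

    def twostep_concat(self) -> VolumeSeries:
        def make():
            concat, index = self.concat()
            tf = realign.two_step_realign(concat, self.trials_selected(), index,
                                          self.config.registration)
            return realign.compose_and_reslice(concat, tf, self.trials_selected(),
                                               index, self.config.registration)
        return self._get("twostep_concat", make)

    # -- regressors --------------------------------------------------------

    def regressors_full(self) -> pd.DataFrame:
        def make():
            run_lengths = {r: self.series.run_length(r) for r in self.series.runs()}
            conds = sorted({ev.condition for t in self.trials for ev in t.events})
            return build_regressors(self.trials, run_lengths,
                                    self.series.intervolume_time, conds)
        return self._get("regressors_full", make)

    def _analysis_mask(self, realigned: VolumeSeries) -> np.ndarray:
        if self.config.mask is not None:
            return self.config.mask
        mean_img = realigned.data.mean(axis=-1)
        params = self.config.extraction or brain_extract.ExtractionParams(
            center=brain_extract.default_center(mean_img))
        weighted = brain_extract.radial_weight(mean_img, params,
                                               realigned.voxel_size)
        return brain_extract.threshold_and_fill(weighted, params)

    def _artefact_rows_full(self) -> list[int]:
        """Flagged volumes plus every volume of a non-accepted trial."""
        flags = self.flags().copy()
        for t in self.trials_selected():
            if t.status != "accepted":
                off = self.series.run_slice(t.run_id).start
                flags[off + t.start_vol: off + t.end_vol + 1] = True
        return np.flatnonzero(flags).tolist()

    # -- the presets -------------------------------------------------------

    def _finish(self, realigned: VolumeSeries, reg: pd.DataFrame,
                artefact_rows: Sequence[int]) -> tuple[GLMResult, int, float]:
        cfg = self.config
        tr = realigned.intervolume_time
        mask = self._analysis_mask(realigned)
        data_f = _naive_highpass(realigned, cfg.spm_cutoff_s)
        reg_f = _filter_regressors(reg, realigned.run_id, tr, cfg.spm_cutoff_s)
        smoothed = smooth_spatial(data_f, cfg.smooth_fwhm_mm)
        design = build_design(reg_f, realigned.run_id, artefact_rows)
        cvec = design.contrast({cfg.contrast[0]: 1.0, cfg.contrast[1]: -1.0})
        result = fit_glm(smoothed, design, cvec, cfg.grand_mean_scale, mask)
        count, prop = count_suprathreshold(result, mask, cfg.threshold)
        return result, count, prop

    def run(self, method: int) -> tuple[GLMResult, int, float]:
        cfg = self.config
        if method == 1:
            return self._finish(self.rigid_full(), self.regressors_full(), [])
        if method == 2:
            return self._finish(self.rigid_full(), self.regressors_full(),
                                self._artefact_rows_full())
        if method in (3, 4, 5):
            _, index = self.concat()
            reg = select_regressor_rows(self.regressors_full(), index)
            if method == 3:
                return self._finish(self.rigid_concat(), reg, [])
            realigned = self.twostep_concat()
            if method == 5:
                realigned = temporal_filter.gap_filtered_highpass(
                    realigned, index,
                    temporal_filter.FilterSettings(cutoff_s=cfg.gap_cutoff_s))
            return self._finish(realigned, reg, [])
        raise ValueError(f"unknown method {method}; expected 1..5")


def run_method(
    series: VolumeSeries,
    trials: TrialTable,
    method: int,
    config: EvalConfig | None = None,
    brain_roi: np.ndarray | None = None,
    logger: StepLogger | None = None,
) -> tuple[GLMResult, int, float]:
    """Run one analysis preset end to end; returns (result, count, proportion)."""
    analysis = _SessionAnalysis(series, trials, config, brain_roi)
    out = analysis.run(method)
    if logger is not None:
        logger.log("run_method", method=method, count=out[1], proportion=out[2])
    return out


def compare_methods(
    sim_config,
    methods: Sequence[int] = (1, 2, 3, 4, 5),
    seeds: Sequence[int] = (0,),
    config: EvalConfig | None = None,
    logger: StepLogger | None = None,
) -> pd.DataFrame:
    """Run the presets on fresh simulated sessions, sharing preprocessing
    within a seed; returns rows of (method, seed, count, proportion)."""
    from .synthetic import simulate_session

    rows = []
    for seed in seeds:
        series, trials, _, truth = simulate_session(sim_config.replace(seed=seed))
        analysis = _SessionAnalysis(series, trials, config,
                                    brain_roi=truth.brain_mask)
        for m in methods:
            _, count, prop = analysis.run(m)
            rows.append({"method": m, "seed": seed, "count": count,
                         "proportion": prop})
            if logger is not None:
                logger.log("compare", method=m, seed=seed, count=count,
                           proportion=prop)
    return pd.DataFrame(rows)
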