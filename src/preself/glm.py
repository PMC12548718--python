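"""GLM machinery: HRF, design matrices, nuisance residualization, betas.

The residualization stage removes task-evoked and nuisance variance from a
voxel time series so that rest-period activity can be analyzed on the saved
residuals.  Beta extraction for pretrial-rest epochs and task contrasts, plus
the univariate parametric-modulation group analysis, live here too.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.ndimage
import scipy.stats

from .types import GroupTestResult, PatternMap, VolumeSeries

__all__ = [
    "HrfKernel",
    "NuisanceSet",
    "DesignMatrix",
    "ResidualSeries",
    "canonical_hrf",
    "convolve_events",
    "detect_outlier_trs",
    "build_design",
    "residualize",
    "smooth_gaussian",
    "pretrial_rest_betas",
    "contrast_map",
    "parametric_modulation_group",
]

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ~2.3548

# Canonical double-gamma parameters: response peak 6 s, undershoot peak 16 s,
# peak-to-undershoot amplitude ratio 6 (gamma densities with unit scale).
_PEAK_DELAY = 6.0
_UNDERSHOOT_DELAY = 16.0
_UNDERSHOOT_RATIO = 6.0


@dataclass
class HrfKernel:
    """Unit-peak canonical hemodynamic response sampled at the TR."""

    tr: float
    samples: np.ndarray
    hires_dt: float
    hires: np.ndarray

    def __len__(self) -> int:
        return len(self.samples)


def _double_gamma(t: np.ndarray) -> np.ndarray:
    g1 = scipy.stats.gamma.pdf(t, _PEAK_DELAY, scale=1.0)
    g2 = scipy.stats.gamma.pdf(t, _UNDERSHOOT_DELAY, scale=1.0)
    return g1 - g2 / _UNDERSHOOT_RATIO


def canonical_hrf(tr: float, duration: float = 32.0, oversampling: int = 16) -> HrfKernel:
    """Canonical double-gamma HRF, scaled to unit peak.

    Parameters
    ----------
    tr : float
        Sampling interval, seconds.
    duration : float
        Kernel support, seconds (default 32, enough for the undershoot to
        decay below 1% of peak).
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    if duration < _PEAK_DELAY:
        raise ValueError(f"duration {duration} s is shorter than the response peak")
    dt = tr / oversampling
    t_hi = np.arange(0.0, duration + dt / 2, dt)
    peak = _double_gamma(t_hi).max()
    hires = _double_gamma(t_hi) / peak
    t_lo = np.arange(0.0, duration + tr / 2, tr)
    samples = _double_gamma(t_lo) / peak
    return HrfKernel(tr=tr, samples=samples, hires_dt=dt, hires=hires)


def convolve_events(
    onsets: np.ndarray,
    durations: np.ndarray,
    amplitudes: np.ndarray,
    n_trs: int,
    hrf: HrfKernel,
) -> np.ndarray:
    """Boxcar-convolve events with the HRF, sampled at TR resolution.

    Events are half-open intervals ``[onset, onset + duration)`` in seconds
    from run start; the convolution runs on the kernel's oversampled grid and
    is then decimated to the acquisition times.
    """
    dt = hrf.hires_dt
    n_hi = int(np.ceil(n_trs * hrf.tr / dt)) + len(hrf.hires)
    box = np.zeros(n_hi)
    for on, dur, amp in zip(np.atleast_1d(onsets), np.atleast_1d(durations),
                            np.atleast_1d(amplitudes)):
        i0 = int(round(on / dt))
        i1 = int(round((on + dur) / dt))
        box[i0:min(i1, n_hi)] += amp
    conv = np.convolve(box, hrf.hires)[:n_hi] * dt
    frame_idx = np.round(np.arange(n_trs) * hrf.tr / dt).astype(int)
    return conv[frame_idx]


# ---------------------------------------------------------------------------
# nuisance model


@dataclass
class NuisanceSet:
    """Nuisance regressors: motion (+derivatives and squared derivatives),
    spike and non-steady-state indicators, per-run linear drift and constants.
    """

    run_lengths: tuple
    motion: Optional[pd.DataFrame] = None
    spike_trs: Sequence[int] = field(default_factory=tuple)
    n_nonsteady: int = 0

    MOTION_COLS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")

    def __post_init__(self):
        self.run_lengths = tuple(int(n) for n in self.run_lengths)
        spikes = sorted(int(t) for t in self.spike_trs)
        if len(set(spikes)) != len(spikes):
            raise ValueError("duplicate spike TRs")
        n = sum(self.run_lengths)
        if spikes and (spikes[0] < 0 or spikes[-1] >= n):
            raise ValueError("spike TR outside series")
        self.spike_trs = tuple(spikes)
        if self.motion is not None and len(self.motion) != n:
            raise ValueError("motion table length does not match run lengths")

    def _run_slices(self):
        edges = np.cumsum((0,) + self.run_lengths)
        return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]

    def to_frame(self) -> pd.DataFrame:
        n = sum(self.run_lengths)
        cols: dict[str, np.ndarray] = {}
        if self.motion is not None:
            m = self.motion[list(self.MOTION_COLS)].to_numpy(dtype=float)
            dm = np.zeros_like(m)
            for sl in self._run_slices():  # derivative restarts at run breaks
                dm[sl][1:] = np.diff(m[sl], axis=0)
            for j, name in enumerate(self.MOTION_COLS):
                cols[name] = m[:, j]
            for j, name in enumerate(self.MOTION_COLS):
                cols[f"{name}_deriv"] = dm[:, j]
            for j, name in enumerate(self.MOTION_COLS):
                cols[f"{name}_deriv_sq"] = dm[:, j] ** 2
        for t in self.spike_trs:
            col = np.zeros(n)
            col[t] = 1.0
            cols[f"spike_{t:04d}"] = col
        for r, sl in enumerate(self._run_slices()):
            for k in range(min(self.n_nonsteady, sl.stop - sl.start)):
                col = np.zeros(n)
                col[sl.start + k] = 1.0
                cols[f"nonsteady_run{r}_{k}"] = col
        for r, sl in enumerate(self._run_slices()):
            drift = np.zeros(n)
            drift[sl] = np.linspace(-0.5, 0.5, sl.stop - sl.start)
            cols[f"drift_run{r}"] = drift
        for r, sl in enumerate(self._run_slices()):
            const = np.zeros(n)
            const[sl] = 1.0
            cols[f"const_run{r}"] = const
        return pd.DataFrame(cols)


@dataclass
class DesignMatrix:
    """Named design matrix with task-column bookkeeping."""

    frame: pd.DataFrame
    task_columns: tuple
    run_lengths: tuple

    def __post_init__(self):
        zero = [c for c in self.frame.columns if not np.any(self.frame[c].to_numpy())]
        if zero:
            raise ValueError(f"all-zero design columns: {zero}")

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def n_trs(self) -> int:
        return len(self.frame)


def build_design(
    events: pd.DataFrame,
    nuisance: NuisanceSet,
    hrf: HrfKernel,
    conditions: Optional[Sequence[str]] = None,
) -> DesignMatrix:
    """One HRF-convolved column per condition, then the nuisance block.

    Onsets in ``events`` are seconds from the start of their own run; runs are
    laid out consecutively following ``nuisance.run_lengths``.
    """
    run_lengths = nuisance.run_lengths
    tr = hrf.tr
    if conditions is None:
        conditions = list(pd.unique(events["trial_type"])) if len(events) else []
    cols: dict[str, np.ndarray] = {}
    offsets = np.cumsum((0,) + run_lengths[:-1])
    n = sum(run_lengths)
    for cond in conditions:
        ev = events[events["trial_type"] == cond]
        if not len(ev):
            raise ValueError(f"no events of condition {cond!r}")
        col = np.zeros(n)
        for r, (off, n_run) in enumerate(zip(offsets, run_lengths)):
            ev_r = ev[ev["run"] == r]
            if not len(ev_r):
                continue
            last = (ev_r["onset"] + ev_r["duration"]).max()
            if last > n_run * tr + 1e-9:
                raise ValueError(
                    f"condition {cond!r}: event offset {last:.1f}s beyond run {r} "
                    f"({n_run * tr:.1f}s)"
                )
            col[off:off + n_run] = convolve_events(
                ev_r["onset"].to_numpy(), ev_r["duration"].to_numpy(),
                np.ones(len(ev_r)), n_run, hrf)
        cols[cond] = col
    if not cols:
        warnings.warn("no task events: building a nuisance-only design")
    frame = pd.DataFrame(cols)
    frame = pd.concat([frame, nuisance.to_frame()], axis=1)
    return DesignMatrix(frame=frame, task_columns=tuple(cols), run_lengths=run_lengths)


# ---------------------------------------------------------------------------
# outliers / residuals / smoothing


def detect_outlier_trs(series: VolumeSeries, n_nonsteady: int = 0,
                       threshold_sd: float = 3.0) -> list[int]:
    """TRs flagged as global-signal outliers, frame-difference outliers, or
    non-steady-state volumes (the first ``n_nonsteady`` of each run).

    Global signal is flagged two-sided (deviation from its mean beyond
    ``threshold_sd`` SDs); the RMS frame-to-frame difference is flagged when it
    exceeds its mean by more than ``threshold_sd`` SDs.
    """
    flat = series.flat()
    n = flat.shape[0]
    if n <= 10:
        raise ValueError("series too short for outlier detection")
    out: set[int] = set()
    g = flat.mean(axis=1)
    sd = g.std()
    if sd > 0:
        out |= set(np.flatnonzero(np.abs(g - g.mean()) > threshold_sd * sd).tolist())
    d = np.sqrt(np.mean(np.diff(flat, axis=0) ** 2, axis=1))
    sd_d = d.std()
    if sd_d > 0:
        bad = np.flatnonzero(d > d.mean() + threshold_sd * sd_d) + 1
        out |= set(bad.tolist())
    runs = series.run_lengths or (n,)
    start = 0
    for n_run in runs:
        out |= set(range(start, start + min(n_nonsteady, n_run)))
        start += n_run
    return sorted(out)


@dataclass
class ResidualSeries(VolumeSeries):
    """Residual volume series; per voxel, residuals are orthogonal to every
    design column (relative tolerance 1e-6)."""

    design: Optional[DesignMatrix] = None
    fwhm: float = 0.0


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    _, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    return [names[piv[i]] for i in range(len(diag)) if diag[i] < tol]


def residualize(series: VolumeSeries, design: DesignMatrix) -> ResidualSeries:
    """Per-voxel OLS fit of the design; returns data minus fitted values."""
    X = design.matrix
    if X.shape[0] != series.n_trs:
        raise ValueError("design and series lengths differ")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _collinear_columns(X, list(design.frame.columns))
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    Y = series.flat()
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    data = resid.T.reshape(series.data.shape)
    return ResidualSeries(data=data, grid=series.grid, affine=series.affine,
                          run_lengths=series.run_lengths, design=design)


def smooth_gaussian(obj, fwhm_mm: float, voxel_size: Optional[float] = None):
    """3D Gaussian smoothing (per volume for 4D input), reflected boundaries.

    ``fwhm_mm = 0`` is the identity.  Accepts a VolumeSeries, a ResidualSeries,
    or a bare array (then ``voxel_size`` is required).
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if isinstance(obj, VolumeSeries):
        if fwhm_mm == 0:
            return obj
        sm = smooth_gaussian(obj.data, fwhm_mm, obj.grid.voxel_size)
        out = ResidualSeries(data=sm, grid=obj.grid, affine=obj.affine,
                             run_lengths=obj.run_lengths,
                             design=getattr(obj, "design", None), fwhm=fwhm_mm)
        return out
    arr = np.asarray(obj, dtype=float)
    if fwhm_mm == 0:
        return arr
    if voxel_size is None:
        raise ValueError("voxel_size required for array input")
    sigma_vox = fwhm_mm / FWHM_TO_SIGMA / voxel_size
    sigma = (sigma_vox,) * 3 + (0.0,) * (arr.ndim - 3)
    return scipy.ndimage.gaussian_filter(arr, sigma=sigma, mode="reflect")


# ---------------------------------------------------------------------------
# beta / contrast extraction


def _ols_betas(series: VolumeSeries, frame: pd.DataFrame) -> dict[str, np.ndarray]:
    X = frame.to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _collinear_columns(X, list(frame.columns))
        raise ValueError(f"rank-deficient model; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(X, series.flat(), rcond=None)
    shape = series.data.shape[:3]
    return {c: beta[j].reshape(shape) for j, c in enumerate(frame.columns)}


def _rest_epochs(schedule: pd.DataFrame, choices: pd.DataFrame) -> pd.DataFrame:
    rest = schedule[schedule["trial_type"] == "pretrial_rest"]
    keep = [c for c in ("trial_index", "chosen_target", "rt") if c in choices.columns]
    merged = rest.merge(choices[keep], on="trial_index")
    return merged.dropna(subset=["chosen_target"])


def pretrial_rest_betas(residuals: VolumeSeries, schedule: pd.DataFrame,
                        choices: pd.DataFrame, hrf: HrfKernel,
                        subject: str = "") -> dict[str, PatternMap]:
    """First-level model of the pretrial-rest epochs on residual images.

    Three HRF-convolved regressors code the rest periods preceding self,
    friend, and known-other choices; friend and known-other betas are averaged
    into the ``other`` class.  Returns per-class whole-grid beta maps.
    """
    epochs = _rest_epochs(schedule, choices)
    run_lengths = residuals.run_lengths or (residuals.n_trs,)
    offsets = np.cumsum((0,) + tuple(run_lengths[:-1]))
    n = residuals.n_trs
    cols = {}
    for target in ("self", "friend", "known_other"):
        ev = epochs[epochs["chosen_target"] == target]
        if not len(ev):
            raise ValueError(
                f"subject {subject or '<unnamed>'}: no pretrial epochs for "
                f"class {target!r}")
        col = np.zeros(n)
        for r, (off, n_run) in enumerate(zip(offsets, run_lengths)):
            ev_r = ev[ev["run"] == r]
            if len(ev_r):
                col[off:off + n_run] = convolve_events(
                    ev_r["onset"].to_numpy(), ev_r["duration"].to_numpy(),
                    np.ones(len(ev_r)), n_run, hrf)
        cols[f"rest_{target}"] = col
    frame = pd.DataFrame(cols)
    for r, (off, n_run) in enumerate(zip(offsets, run_lengths)):
        const = np.zeros(n)
        const[off:off + n_run] = 1.0
        frame[f"const_run{r}"] = const
    betas = _ols_betas(residuals, frame)
    full = np.ones(residuals.data.shape[:3], dtype=bool)
    self_map = betas["rest_self"]
    other_map = 0.5 * (betas["rest_friend"] + betas["rest_known_other"])
    counts = epochs["chosen_target"].value_counts().to_dict()
    out = {
        "self": PatternMap(self_map, full, source="rest_beta", label="rest_self"),
        "other": PatternMap(other_map, full, source="rest_beta", label="rest_other"),
    }
    out["self"].n_epochs = counts.get("self", 0)  # type: ignore[attr-defined]
    out["other"].n_epochs = counts.get("friend", 0) + counts.get("known_other", 0)  # type: ignore[attr-defined]
    return out


def contrast_map(series: VolumeSeries, events: pd.DataFrame, hrf: HrfKernel,
                 contrast, nuisance: Optional[NuisanceSet] = None,
                 fwhm: float = 6.0, mask: Optional[np.ndarray] = None) -> PatternMap:
    """Per-voxel contrast of HRF-convolved task betas against the implicit
    baseline, optionally smoothed and masked.

    ``contrast`` is a mapping or sequence of ``(condition, weight)`` pairs.
    """
    pairs = list(contrast.items()) if hasattr(contrast, "items") else list(contrast)
    conditions = list(pd.unique(events["trial_type"]))
    for cond, _ in pairs:
        if cond not in conditions:
            raise KeyError(f"unknown condition {cond!r}; have {conditions}")
    if nuisance is None:
        nuisance = NuisanceSet(run_lengths=series.run_lengths or (series.n_trs,))
    design = build_design(events, nuisance, hrf, conditions=conditions)
    betas = _ols_betas(series, design.frame)
    shape = series.data.shape[:3]
    cmap = np.zeros(shape)
    for cond, w in pairs:
        cmap = cmap + w * betas[cond]
    if fwhm:
        cmap = smooth_gaussian(cmap, fwhm, series.grid.voxel_size)
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    return PatternMap(np.where(mask, cmap, np.nan), mask, source="contrast",
                      label="+".join(f"{w:+g}*{c}" for c, w in pairs))


def parametric_modulation_group(subject_data: Sequence[tuple],
                                roi_masks: dict[str, np.ndarray],
                                hrf: HrfKernel) -> dict[str, GroupTestResult]:
    """RT parametric modulation of pretrial rest, tested at the group level.

    For each subject (``(residuals, schedule, choices)``), the model contains
    the pretrial-rest regressor plus mean-centered trial-wise RT modulators
    built separately for self and other trials.  The subject-level contrast
    (self-RT-mod minus other-RT-mod) is averaged within each ROI and taken to
    a one-sample t-test across subjects; with more than one ROI the p-values
    are Bonferroni corrected.
    """
    if len(subject_data) < 2:
        raise ValueError("need at least two subjects")
    for name, m in roi_masks.items():
        if not np.any(m):
            raise ValueError(f"ROI {name!r} is empty")
    roi_values: dict[str, list[float]] = {name: [] for name in roi_masks}
    for residuals, schedule, choices in subject_data:
        epochs = _rest_epochs(schedule, choices).dropna(subset=["rt"])
        run_lengths = residuals.run_lengths or (residuals.n_trs,)
        offsets = np.cumsum((0,) + tuple(run_lengths[:-1]))
        n = residuals.n_trs

        def _col(ev: pd.DataFrame, amps: np.ndarray) -> np.ndarray:
            col = np.zeros(n)
            amps = np.atleast_1d(amps)
            for r, (off, n_run) in enumerate(zip(offsets, run_lengths)):
                sel = (ev["run"] == r).to_numpy()
                if sel.any():
                    col[off:off + n_run] = convolve_events(
                        ev["onset"].to_numpy()[sel], ev["duration"].to_numpy()[sel],
                        amps[sel], n_run, hrf)
            return col

        is_self = (epochs["chosen_target"] == "self").to_numpy()
        frame = {"pretrial": _col(epochs, np.ones(len(epochs)))}
        for name, sel in (("rt_mod_self", is_self), ("rt_mod_other", ~is_self)):
            ev = epochs[sel]
            rt_c = ev["rt"].to_numpy() - ev["rt"].mean()  # mean-centered in class
            frame[name] = _col(ev, rt_c)
        fr = pd.DataFrame(frame)
        for r, (off, n_run) in enumerate(zip(offsets, run_lengths)):
            const = np.zeros(n)
            const[off:off + n_run] = 1.0
            fr[f"const_run{r}"] = const
        betas = _ols_betas(residuals, fr)
        cmap = betas["rt_mod_self"] - betas["rt_mod_other"]
        for name, m in roi_masks.items():
            roi_values[name].append(float(cmap[np.asarray(m, bool)].mean()))
    results = {}
    for name, vals in roi_values.items():
        arr = np.asarray(vals)
        t, p = scipy.stats.ttest_1samp(arr, 0.0)
        n_sub = len(arr)
        res = GroupTestResult(roi=name, t=float(t), df=n_sub - 1, p=float(p),
                              cohens_d=float(t) / np.sqrt(n_sub))
        if len(roi_masks) > 1:
            res.p_corrected = min(1.0, float(p) * len(roi_masks))
        results[name] = res
    return results
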