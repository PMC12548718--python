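"""Forward simulator: task schedules, choices, 4D runs, ratings, cohorts.

The generator embeds known ground-truth structure — spatial patterns whose
pretrial amplitude drives choices, lagged coupling between two patterns during
rest, and trait-structured cohorts — so that every downstream analysis stage
can be exercised, and its parameter recovery checked, at desk scale.

Timing defaults mirror the study design: a choice task of 108 trials split
over two runs (jittered pretrial rest 2.5-6 s with mean 4.5 s, 5 s choices,
a 2-4.5 s shape-matching interlude with mean 3 s, TR 1 s), an 8-minute rest
run of four 2-minute blocks each followed by a 32 s rating window, and a
self-reflection task of 2 x 101 four-second trials with 1-3 s jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
from scipy.special import expit, logit

from . import glm
from .types import AcquisitionGrid, Cohort, GroundTruth, PatternMap, VolumeSeries

__all__ = [
    "ScheduleConfig",
    "ConfigError",
    "make_task_schedule",
    "simulate_choices",
    "simulate_task_run",
    "simulate_rest_run",
    "simulate_ratings",
    "simulate_cohort",
    "simulate_beta_maps",
    "default_grid",
    "default_masks",
    "make_ground_truth",
    "rest_block_windows",
    "BASE_PROBS",
    "REST_AR1",
]

#: Baseline choice probabilities (self, friend, known other), matching the
#: observed choice proportions 1696:1127:624.
BASE_PROBS = (1696 / 3447, 1127 / 3447, 624 / 3447)

#: Lag-1 autocorrelation of the latent rest-state amplitude process.  Low
#: enough that an 8-TR coupling is resolvable at 1-TR resolution and that
#: reverse-direction leakage through state memory (~ REST_AR1**(8+L)) is
#: negligible.
REST_AR1 = 0.6

#: Median RT (s) per choice target; self decisions are fastest.
RT_MEDIANS = {"self": 1.8, "friend": 1.95, "known_other": 2.0}
RT_LOG_SD = 0.3

DIMENSIONS = ("social_roles", "preferences", "physical_traits",
              "personality_traits", "future", "past")


class ConfigError(ValueError):
    """Invalid or infeasible schedule configuration."""


@dataclass(frozen=True)
class ScheduleConfig:
    """Timing layout of one task; see the classmethod defaults."""

    task_kind: str = "choice"
    n_runs: int = 2
    trials_per_run: int = 54
    jitter_range: tuple = (2.5, 6.0)
    jitter_mean: float = 4.5
    trial_duration: float = 5.0
    interlude_range: Optional[tuple] = (2.0, 4.5)
    interlude_mean: Optional[float] = 3.0
    dimensions: tuple = DIMENSIONS
    rest_block_length: float = 120.0
    rating_window: float = 32.0
    n_rest_blocks: int = 4
    initial_rest: float = 10.0
    jitter_step: float = 0.5
    run_length_s: Optional[float] = None

    def __post_init__(self):
        if self.task_kind not in ("choice", "reflection", "rest"):
            raise ConfigError(f"unknown task_kind {self.task_kind!r}")
        lo, hi = self.jitter_range
        if not (lo <= self.jitter_mean <= hi):
            raise ConfigError("jitter_mean outside jitter_range")
        if self.task_kind == "choice" and self.trials_per_run % len(self.dimensions):
            raise ConfigError("trials_per_run must divide evenly over dimensions")

    @classmethod
    def choice_default(cls) -> "ScheduleConfig":
        return cls()

    @classmethod
    def reflection_default(cls) -> "ScheduleConfig":
        return cls(task_kind="reflection", n_runs=2, trials_per_run=101,
                   jitter_range=(1.0, 3.0), jitter_mean=2.0, trial_duration=4.0,
                   interlude_range=None, interlude_mean=None, dimensions=())

    @classmethod
    def rest_default(cls) -> "ScheduleConfig":
        return cls(task_kind="rest", n_runs=1, trials_per_run=0, dimensions=())


def _discrete_trunc_exp(values: np.ndarray, target_mean: float) -> np.ndarray:
    """Weights of a discretized truncated-exponential with the given mean.

    The weight of value v is proportional to exp(-rate * v); the rate is
    solved so the weighted mean hits ``target_mean`` (rate 0 recovers the
    uniform distribution; a negative rate skews toward the upper end).
    """
    values = np.asarray(values, dtype=float)
    if len(values) == 1:
        return np.ones(1)

    def mean_at(rate: float) -> float:
        w = np.exp(-rate * (values - values.mean()))
        return float(np.sum(values * w) / np.sum(w))

    lo, hi = values.min(), values.max()
    if not (lo <= target_mean <= hi):
        raise ConfigError("target mean outside value range")
    f = lambda r: mean_at(r) - target_mean
    rate = scipy.optimize.brentq(f, -50.0, 50.0, xtol=1e-12)
    w = np.exp(-rate * (values - values.mean()))
    return w / w.sum()


def _jitter_values(rng_range: tuple, step: float) -> np.ndarray:
    lo, hi = rng_range
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


def sample_jitters(n: int, rng_range: tuple, mean: float, step: float,
                   rng: np.random.Generator) -> np.ndarray:
    values = _jitter_values(rng_range, step)
    weights = _discrete_trunc_exp(values, mean)
    return rng.choice(values, size=n, p=weights)


def make_task_schedule(cfg: ScheduleConfig, seed: int) -> pd.DataFrame:
    """Generate one task's event table.

    Choice runs alternate pretrial rest (jittered), the 5 s choice, and the
    shape-matching interlude; reflection runs alternate jitter and trial;
    rest runs contain rating-window events after each rest block.  Onsets are
    seconds from run start, intervals are half-open and non-overlapping.
    """
    rng = np.random.default_rng(seed)
    rows = []
    if cfg.task_kind == "rest":
        for b in range(cfg.n_rest_blocks):
            onset = (b + 1) * cfg.rest_block_length + b * cfg.rating_window
            rows.append((0, b, onset, cfg.rating_window, "rating", ""))
        sched = pd.DataFrame(rows, columns=["run", "trial_index", "onset",
                                            "duration", "trial_type", "dimension"])
        return sched
    trial = 0
    for run in range(cfg.n_runs):
        jit = sample_jitters(cfg.trials_per_run, cfg.jitter_range,
                             cfg.jitter_mean, cfg.jitter_step, rng)
        if cfg.interlude_range is not None:
            inter = sample_jitters(cfg.trials_per_run, cfg.interlude_range,
                                   cfg.interlude_mean, cfg.jitter_step, rng)
        else:
            inter = np.zeros(cfg.trials_per_run)
        if cfg.run_length_s is not None:
            worst = cfg.initial_rest + cfg.trials_per_run * (
                cfg.jitter_range[1] + cfg.trial_duration
                + (cfg.interlude_range[1] if cfg.interlude_range else 0.0))
            if worst > cfg.run_length_s:
                raise ConfigError(
                    f"run_length_s={cfg.run_length_s} cannot hold "
                    f"{cfg.trials_per_run} trials at maximal durations ({worst:.1f}s)")
        if cfg.dimensions:
            per_dim = cfg.trials_per_run // len(cfg.dimensions)
            dims = np.repeat(cfg.dimensions, per_dim)
            rng.shuffle(dims)
        else:
            dims = [""] * cfg.trials_per_run
        t = cfg.initial_rest
        for i in range(cfg.trials_per_run):
            rows.append((run, trial, t, jit[i], "pretrial_rest", dims[i]))
            t += jit[i]
            name = "choice" if cfg.task_kind == "choice" else "reflect"
            rows.append((run, trial, t, cfg.trial_duration, name, dims[i]))
            t += cfg.trial_duration
            if cfg.interlude_range is not None:
                rows.append((run, trial, t, inter[i], "shape", dims[i]))
                t += inter[i]
            trial += 1
    sched = pd.DataFrame(rows, columns=["run", "trial_index", "onset",
                                        "duration", "trial_type", "dimension"])
    for run, grp in sched.groupby("run"):
        if not np.all(np.diff(grp["onset"]) > 0):
            raise AssertionError("onsets not strictly increasing")
    return sched


def run_lengths_for(schedule: pd.DataFrame, tr: float, pad: float = 15.0) -> tuple:
    """TRs per run: last event offset plus padding, rounded up to whole TRs."""
    out = []
    for run in sorted(schedule["run"].unique()):
        grp = schedule[schedule["run"] == run]
        end = (grp["onset"] + grp["duration"]).max() + pad
        out.append(int(np.ceil(end / tr)))
    return tuple(out)


# ---------------------------------------------------------------------------
# choices and RTs


def simulate_choices(truth: GroundTruth, amplitudes: np.ndarray,
                     base_probs: Sequence[float] = BASE_PROBS, seed: int = 0,
                     rt_gain: Optional[float] = None,
                     omit_prob: float = 0.0) -> pd.DataFrame:
    """Choices and RTs driven by the pretrial pattern amplitude.

    P(self on trial i) follows a logistic in ``choice_gain * amplitude`` with
    an offset matching ``base_probs``; non-self trials split between friend
    and known other in their baseline proportion.  RTs are lognormal with
    target-specific medians (self fastest); on self trials the log-RT
    decreases by ``rt_gain`` per unit amplitude.
    """
    p = np.asarray(base_probs, dtype=float)
    if np.any(p < 0):
        raise ValueError("negative base probabilities")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("base_probs must sum to 1")
    if rt_gain is None:
        rt_gain = truth.rt_gain
    rng = np.random.default_rng(seed)
    a = np.asarray(amplitudes, dtype=float)
    n = len(a)
    if 0.0 < p[0] < 1.0:
        p_self = expit(truth.choice_gain * a + logit(p[0]))
    else:  # degenerate baseline: the logistic offset is at +/- infinity
        p_self = np.full(n, p[0])
    is_self = rng.random(n) < p_self
    targets = np.where(is_self, "self", "")
    rest = ~is_self
    if rest.any():
        denom = p[1] + p[2]
        p_friend = p[1] / denom if denom > 0 else 0.5
        friend = rng.random(n) < p_friend
        targets = np.where(rest & friend, "friend", targets)
        targets = np.where(rest & ~friend, "known_other", targets)
    log_rt = np.array([np.log(RT_MEDIANS[t]) for t in targets])
    log_rt = log_rt + RT_LOG_SD * rng.standard_normal(n)
    log_rt = np.where(is_self, log_rt - rt_gain * a, log_rt)
    rt = np.clip(np.exp(log_rt), 0.2, 4.95)
    out = pd.DataFrame({"trial_index": np.arange(n), "chosen_target": targets,
                        "rt": rt})
    if omit_prob > 0:
        omit = rng.random(n) < omit_prob
        out.loc[omit, "chosen_target"] = pd.NA
        out.loc[omit, "rt"] = np.nan
    return out


# ---------------------------------------------------------------------------
# volume simulation


def _smooth_blob(dims: tuple, center_frac: tuple, width_frac: float = 0.25) -> np.ndarray:
    """Deterministic smooth activation bump used for generic task responses."""
    grids = np.meshgrid(*[np.arange(d) for d in dims], indexing="ij")
    r2 = sum(((g - f * (d - 1)) / (width_frac * d)) ** 2
             for g, f, d in zip(grids, center_frac, dims))
    return np.exp(-0.5 * r2)


def _motion_table(n_trs: int, run: int, rng: np.random.Generator,
                  spike_trs: Sequence[int] = ()) -> pd.DataFrame:
    steps = rng.normal(0.0, 0.02, size=(n_trs, 6))
    m = np.cumsum(steps, axis=0)
    for t in spike_trs:
        if 0 <= t < n_trs:
            m[t] += 1.0
    df = pd.DataFrame(m, columns=list(glm.NuisanceSet.MOTION_COLS))
    df.insert(0, "run", run)
    return df


def simulate_task_run(schedule: pd.DataFrame, choices: pd.DataFrame,
                      truth: GroundTruth, grid: AcquisitionGrid,
                      noise_sd: float = 1.0, seed: int = 0,
                      amplitudes: Optional[np.ndarray] = None,
                      spike_trs: Sequence[int] = (),
                      spike_sd: float = 10.0) -> tuple[VolumeSeries, pd.DataFrame]:
    """Forward model of the choice (or reflection) task.

    The neural signal is the sum of HRF-convolved event responses: choice and
    shape events drive fixed smooth activation maps, and each pretrial-rest
    epoch adds ``pattern_snr * noise_sd * amplitude_i`` times the embedded
    pre-self pattern.  Reflection trials drive the reflection pattern.  White
    voxel noise at ``noise_sd``, a per-voxel linear drift, and a synthetic
    motion table (with optional injected spikes) complete the run.
    """
    if truth.preself_pattern.mask.shape != tuple(grid.dims):
        raise ValueError("ground-truth pattern does not lie on the grid")
    rng = np.random.default_rng(seed)
    hrf = glm.canonical_hrf(grid.tr)
    # signal units follow the noise scale; the noiseless limit keeps unit scale
    scale = noise_sd if noise_sd > 0 else 1.0
    run_lengths = run_lengths_for(schedule, grid.tr)
    n_total = sum(run_lengths)
    n_trials = schedule["trial_index"].nunique()
    if amplitudes is None:
        amplitudes = rng.standard_normal(n_trials)
    amplitudes = np.asarray(amplitudes, dtype=float)

    task_map = _smooth_blob(tuple(grid.dims), (0.5, 0.35, 0.5))
    shape_map = _smooth_blob(tuple(grid.dims), (0.5, 0.75, 0.4))
    flat = np.zeros((n_total, grid.n_voxels))

    pre_mask = truth.preself_pattern.mask
    pre_vals = truth.preself_pattern.in_mask()
    refl_mask = truth.reflection_pattern.mask
    refl_vals = truth.reflection_pattern.in_mask()
    pre_idx = np.flatnonzero(pre_mask.ravel())
    refl_idx = np.flatnonzero(refl_mask.ravel())

    offsets = np.cumsum((0,) + run_lengths[:-1])
    motions = []
    for r, (off, n_run) in enumerate(zip(offsets, run_lengths)):
        sched_r = schedule[schedule["run"] == r]
        sl = slice(off, off + n_run)
        for cond, gmap, amp in (("choice", task_map, 1.0), ("shape", shape_map, 0.8),
                                ("reflect", None, 1.0)):
            ev = sched_r[sched_r["trial_type"] == cond]
            if not len(ev):
                continue
            reg = glm.convolve_events(ev["onset"].to_numpy(),
                                      ev["duration"].to_numpy(),
                                      amp * np.ones(len(ev)), n_run, hrf)
            if cond == "reflect":
                flat[sl][:, refl_idx] += np.outer(
                    reg, truth.pattern_snr * scale * refl_vals)
            else:
                flat[sl] += np.outer(reg, scale * gmap.ravel())
        rest = sched_r[sched_r["trial_type"] == "pretrial_rest"]
        if len(rest):
            amps = amplitudes[rest["trial_index"].to_numpy()]
            reg = glm.convolve_events(rest["onset"].to_numpy(),
                                      rest["duration"].to_numpy(),
                                      amps, n_run, hrf)
            flat[sl][:, pre_idx] += np.outer(
                reg, truth.pattern_snr * scale * pre_vals)
        drift = np.linspace(-0.5, 0.5, n_run)
        slopes = rng.normal(0.0, 0.3 * noise_sd, grid.n_voxels)
        flat[sl] += np.outer(drift, slopes)
        run_spikes = [t - off for t in spike_trs if off <= t < off + n_run]
        motions.append(_motion_table(n_run, r, rng, run_spikes))
    if noise_sd > 0:
        flat += rng.normal(0.0, noise_sd, size=flat.shape)
    for t in spike_trs:
        flat[t] += spike_sd * scale
    data = flat.T.reshape(tuple(grid.dims) + (n_total,))
    series = VolumeSeries(data=data, grid=grid, run_lengths=run_lengths)
    motion = pd.concat(motions, ignore_index=True)
    return series, motion


def default_rest_noise_sd(mask: np.ndarray) -> float:
    """Moderate rest noise: per-TR instatement correlates ~0.7 with the
    latent state for a unit-RMS pattern on this mask."""
    return float(np.sqrt(np.asarray(mask, bool).sum()))


def _ar1(n: int, rho: float, rng: np.random.Generator) -> np.ndarray:
    x = np.empty(n)
    x[0] = rng.standard_normal()
    innov_sd = np.sqrt(1.0 - rho ** 2)
    eps = rng.standard_normal(n - 1) * innov_sd
    for t in range(1, n):
        x[t] = rho * x[t - 1] + eps[t - 1]
    return x


def simulate_rest_run(truth: GroundTruth, grid: AcquisitionGrid, n_trs: int,
                      noise_sd: Optional[float] = None, seed: int = 0,
                      return_latents: bool = False):
    """Resting run with lagged coupling between two embedded patterns.

    The latent pre-self amplitude a(t) is a stationary AR(1) process
    (unit variance, lag-1 autocorrelation ``REST_AR1``); the reflection
    amplitude is ``b(t) = coupling_strength * a(t - coupling_lag) + noise``
    scaled to unit variance.  The voxel series is
    ``a(t) * preself + b(t) * reflection + white noise``.
    """
    lag = int(truth.coupling_lag)
    if n_trs <= lag:
        raise ValueError(f"n_trs={n_trs} must exceed coupling_lag={lag}")
    rng = np.random.default_rng(seed)
    if noise_sd is None:
        noise_sd = default_rest_noise_sd(truth.preself_pattern.mask)
    a_ext = _ar1(n_trs + lag, REST_AR1, rng)
    a = a_ext[lag:]
    c = truth.coupling_strength
    resid_sd = np.sqrt(max(0.0, 1.0 - c ** 2))
    b = c * a_ext[:n_trs] + resid_sd * rng.standard_normal(n_trs)

    flat = rng.normal(0.0, noise_sd, size=(n_trs, grid.n_voxels))
    pre_idx = np.flatnonzero(truth.preself_pattern.mask.ravel())
    refl_idx = np.flatnonzero(truth.reflection_pattern.mask.ravel())
    flat[:, pre_idx] += np.outer(a, truth.preself_pattern.in_mask())
    flat[:, refl_idx] += np.outer(b, truth.reflection_pattern.in_mask())
    drift = np.linspace(-0.5, 0.5, n_trs)
    flat += np.outer(drift, rng.normal(0.0, 0.3 * noise_sd, grid.n_voxels))
    data = flat.T.reshape(tuple(grid.dims) + (n_trs,))
    series = VolumeSeries(data=data, grid=grid, run_lengths=(n_trs,))
    if return_latents:
        return series, a, b
    return series


def rest_block_windows(cfg: Optional[ScheduleConfig] = None) -> list[tuple]:
    """Half-open (start_s, end_s) windows of the rest blocks, rating periods
    excluded by construction."""
    cfg = cfg or ScheduleConfig.rest_default()
    wins = []
    for b in range(cfg.n_rest_blocks):
        start = b * (cfg.rest_block_length + cfg.rating_window)
        wins.append((start, start + cfg.rest_block_length))
    return wins


def simulate_ratings(block_values: np.ndarray, coupling: float = 0.5,
                     seed: int = 0, noise_sd: float = 0.5,
                     intercept: float = 3.0) -> pd.DataFrame:
    """Thought-probe ratings for one subject's rest blocks.

    The self rating is an affine function of the block-mean pre-self
    instatement plus noise; other/future/past ratings are independent noise.
    All ratings are clipped to the 1-5 scale.
    """
    v = np.asarray(block_values, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(v)
    out = {"block": np.arange(n),
           "self": intercept + coupling * v + rng.normal(0, noise_sd, n)}
    for name in ("other", "future", "past"):
        out[name] = intercept + rng.normal(0, noise_sd, n)
    df = pd.DataFrame(out)
    for name in ("self", "other", "future", "past"):
        df[name] = np.clip(df[name], 1.0, 5.0)
    return df


# ---------------------------------------------------------------------------
# cohorts


def simulate_cohort(n_subjects: int = 60, n_trs: int = 300, ak_share: float = 0.5,
                    threshold_quantile: float = 0.5, seed: int = 0,
                    tc_ar1: float = 0.3) -> Cohort:
    """Cohort with trait-keyed shared dynamics among high scorers.

    Internalizing totals are drawn from a right-skewed (gamma) distribution
    and rounded to integers (ties are possible, as with real symptom scores).
    Subjects above the threshold quantile have instatement time course
    ``ak_share * shared + (1 - ak_share) * idiosyncratic``; the rest are fully
    idiosyncratic.  Subscales are the total plus rounded noise.
    """
    if n_subjects < 4:
        raise ValueError("need at least 4 subjects")
    if not 0.0 <= ak_share <= 1.0:
        raise ValueError("ak_share must be in [0, 1]")
    rng = np.random.default_rng(seed)
    total = np.round(rng.gamma(2.0, 6.0, n_subjects)).astype(int)
    thresh = np.quantile(total, threshold_quantile)
    high = total > thresh
    shared = _ar1(n_trs, tc_ar1, rng)
    tcs = np.empty((n_subjects, n_trs))
    for i in range(n_subjects):
        idio = _ar1(n_trs, tc_ar1, rng)
        if high[i]:
            tcs[i] = ak_share * shared + (1.0 - ak_share) * idio
        else:
            tcs[i] = idio
    scores = pd.DataFrame({
        "subject": [f"sub-{i:04d}" for i in range(n_subjects)],
        "internalizing_total": total,
    })
    for sub in ("anx_dep", "withdrawal", "somatic"):
        scores[sub] = np.maximum(0, np.round(total + rng.normal(0, 4.0, n_subjects))
                                 ).astype(int)
    return Cohort(scores=scores, timecourses=tcs)


# ---------------------------------------------------------------------------
# fast beta-domain generator


def simulate_beta_maps(n_subjects: int, pattern: PatternMap,
                       class_separation: float, seed: int = 0,
                       noise_sd: float = 1.0) -> list[tuple[PatternMap, PatternMap]]:
    """Per-subject (self, other) beta-map pairs generated in the beta domain.

    A shortcut for calibration studies that do not need the volumetric
    forward model: the class means sit at +/- class_separation/2 along the
    embedded pattern, with white voxel noise.  ``class_separation = 0`` gives
    pure-noise features.
    """
    rng = np.random.default_rng(seed)
    mask = pattern.mask
    vals = np.nan_to_num(pattern.values)
    out = []
    for _ in range(n_subjects):
        eps1 = rng.normal(0.0, noise_sd, mask.shape)
        eps2 = rng.normal(0.0, noise_sd, mask.shape)
        m_self = np.where(mask, +0.5 * class_separation * vals + eps1, np.nan)
        m_other = np.where(mask, -0.5 * class_separation * vals + eps2, np.nan)
        out.append((PatternMap(m_self, mask, source="rest_beta", label="self"),
                    PatternMap(m_other, mask, source="rest_beta", label="other")))
    return out


# ---------------------------------------------------------------------------
# default geometry and ground truth


def default_grid(tr: float = 1.0) -> AcquisitionGrid:
    """Desk-scale grid: 36 x 26 x 12 voxels of 2.5 mm."""
    return AcquisitionGrid(dims=(36, 26, 12), voxel_size=2.5, tr=tr)


def ellipsoid_mask(dims: tuple, center: tuple, semiaxes: tuple) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(d) for d in dims], indexing="ij")
    r2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semiaxes))
    return r2 <= 1.0


def default_masks(grid: AcquisitionGrid) -> dict[str, np.ndarray]:
    """Two disjoint ellipsoid ROIs standing in for network nodes."""
    nx, ny, nz = grid.dims
    semi = (0.235 * nx, 0.42 * ny, 0.46 * nz)
    a = ellipsoid_mask(grid.dims, (0.26 * nx, 0.5 * (ny - 1), 0.5 * (nz - 1)), semi)
    b = ellipsoid_mask(grid.dims, (0.74 * nx, 0.5 * (ny - 1), 0.5 * (nz - 1)), semi)
    if np.any(a & b):
        raise AssertionError("default ROI masks overlap")
    return {"core": a, "reflection": b}


def make_ground_truth(grid: Optional[AcquisitionGrid] = None, seed: int = 0,
                      **overrides) -> GroundTruth:
    """Embedded ground-truth patterns on the default (or given) grid.

    Patterns are unit-RMS Gaussian maps with a positive spatial mean
    component (so univariate ROI analyses see net activation) on two
    disjoint ellipsoid masks.
    """
    grid = grid or default_grid()
    masks = default_masks(grid)
    rng = np.random.default_rng(seed)

    def _pattern(mask: np.ndarray, label: str) -> PatternMap:
        raw = 0.5 + rng.standard_normal(int(mask.sum()))
        raw = raw / np.sqrt(np.mean(raw ** 2))
        vals = np.full(mask.shape, np.nan)
        vals[mask] = raw
        return PatternMap(vals, mask, source="ground_truth", label=label)

    return GroundTruth(preself_pattern=_pattern(masks["core"], "preself"),
                       reflection_pattern=_pattern(masks["reflection"], "reflection"),
                       **overrides)
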