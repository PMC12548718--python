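"""End-to-end pipeline driver: simulate -> residualize -> decode -> instate
-> IS-RSA, at desk scale, with a written manifest.

All randomness flows from the config seed; rerunning with the same config
reproduces every number.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import behavior, decode, glm, instate, io, isrsa, simcore
from .types import AcquisitionGrid

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Desk-scale defaults; every stochastic stage draws from ``seed``."""

    seed: int = 0
    n_subjects: int = 6
    grid_dims: tuple = (20, 16, 10)
    voxel_size: float = 2.5
    tr: float = 1.0
    trials_per_run: int = 18
    n_runs: int = 2
    reflection_trials: int = 30
    pattern_snr: float = 0.5
    coupling_lag: int = 8
    coupling_strength: float = 0.5
    rest_trs: int = 160
    rest_block_s: float = 30.0
    rating_window_s: float = 10.0
    max_lag: int = 20
    k_folds: int = 3
    n_perm: int = 199
    fwhm: float = 6.0
    n_nonsteady: int = 4
    spike_sd: float = 3.0
    cohort_n: int = 24
    cohort_trs: int = 120
    ak_share: float = 0.5
    mantel_perms: int = 499

    def __post_init__(self):
        if self.rest_trs <= self.coupling_lag:
            raise ValueError("rest_trs must exceed coupling_lag")
        n_blocks = 4
        if self.rest_trs * self.tr < n_blocks * (self.rest_block_s
                                                 + self.rating_window_s):
            raise ValueError("rest run too short for 4 blocks + ratings")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "grid_dims" in d:
            d["grid_dims"] = tuple(d["grid_dims"])
        return cls(**d)


def _stage_seed(base: int, stage: int, unit: int = 0) -> int:
    ss = np.random.SeedSequence([int(base), int(stage), int(unit)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_pipeline(config: PipelineConfig, out_dir: Optional[str] = None) -> dict:
    """Run every stage in order and return (and optionally write) a report.

    The manifest lists, per stage, the seed, wall time, headline numbers, and
    any files written.
    """
    t_start = time.time()
    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    grid = AcquisitionGrid(dims=tuple(config.grid_dims),
                           voxel_size=config.voxel_size, tr=config.tr)
    truth = simcore.make_ground_truth(
        grid, seed=_stage_seed(config.seed, 0),
        pattern_snr=config.pattern_snr, coupling_lag=config.coupling_lag,
        coupling_strength=config.coupling_strength)
    masks = simcore.default_masks(grid)
    hrf = glm.canonical_hrf(config.tr)
    manifest: dict = {"config": dataclasses.asdict(config), "stages": {}, "outputs": []}

    def _log(stage: str, t0: float, **info):
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3), **info}

    # --- study-1 style subjects: choice task -> residuals -> rest betas ----
    t0 = time.time()
    cfg = simcore.ScheduleConfig(trials_per_run=config.trials_per_run,
                                 n_runs=config.n_runs)
    subjects = []
    for s in range(config.n_subjects):
        seed_s = _stage_seed(config.seed, 1, s)
        rng = np.random.default_rng(seed_s)
        schedule = simcore.make_task_schedule(cfg, seed=seed_s)
        n_trials = schedule["trial_index"].nunique()
        amplitudes = rng.standard_normal(n_trials)
        choices = simcore.simulate_choices(truth, amplitudes, seed=seed_s + 1)
        series, motion = simcore.simulate_task_run(
            schedule, choices, truth, grid, seed=seed_s + 2, amplitudes=amplitudes)
        spikes = glm.detect_outlier_trs(series, n_nonsteady=config.n_nonsteady,
                                        threshold_sd=config.spike_sd)
        nuis = glm.NuisanceSet(run_lengths=series.run_lengths, motion=motion,
                               spike_trs=[t for t in spikes], n_nonsteady=0)
        design = glm.build_design(schedule, nuis, hrf,
                                  conditions=["choice", "shape"])
        residuals = glm.residualize(series, design)
        betas = glm.pretrial_rest_betas(residuals, schedule, choices, hrf,
                                        subject=f"sub-{s:02d}")
        subjects.append({"schedule": schedule, "choices": choices,
                         "betas": betas, "seed": seed_s})
    _log("simulate_choice_task", t0, n_subjects=config.n_subjects)

    # --- decode -----------------------------------------------------------
    t0 = time.time()
    pairs = [(d["betas"]["self"], d["betas"]["other"]) for d in subjects]
    feats = decode.assemble_features(pairs, masks["core"])
    cv = decode.crossval_accuracy(feats, k=config.k_folds,
                                  seed=_stage_seed(config.seed, 2))
    null = decode.permutation_null(feats, k=config.k_folds, n_perm=config.n_perm,
                                   seed=_stage_seed(config.seed, 2, 1),
                                   observed=cv.accuracy)
    pattern = decode.derive_pattern(feats)
    if out:
        manifest["outputs"].append(str(io.write_map(pattern, out / "preself_pattern.nii.gz",
                                                    voxel_size=config.voxel_size)))
    _log("decode", t0, accuracy=cv.accuracy, p=null.p)

    # --- per-subject reflection pattern + rest instatement ----------------
    t0 = time.time()
    refl_cfg = simcore.ScheduleConfig(
        task_kind="reflection", n_runs=1, trials_per_run=config.reflection_trials,
        jitter_range=(1.0, 3.0), jitter_mean=2.0, trial_duration=4.0,
        interlude_range=None, interlude_mean=None, dimensions=())
    tcs_a, tcs_b = [], []
    block_rows, rating_rows = [], []
    windows = [(b * (config.rest_block_s + config.rating_window_s),
                b * (config.rest_block_s + config.rating_window_s)
                + config.rest_block_s) for b in range(4)]
    for s, dat in enumerate(subjects):
        seed_s = _stage_seed(config.seed, 3, s)
        refl_sched = simcore.make_task_schedule(refl_cfg, seed=seed_s)
        refl_choices = pd.DataFrame({
            "trial_index": np.arange(config.reflection_trials),
            "chosen_target": "self", "rt": 1.0})
        refl_series, _ = simcore.simulate_task_run(
            refl_sched, refl_choices, truth, grid, seed=seed_s + 1)
        refl_pattern = glm.contrast_map(refl_series, refl_sched, hrf,
                                        {"reflect": 1.0}, fwhm=0.0,
                                        mask=masks["reflection"])
        rest = simcore.simulate_rest_run(truth, grid, config.rest_trs,
                                         seed=seed_s + 2)
        nuis = glm.NuisanceSet(run_lengths=(config.rest_trs,))
        empty_events = pd.DataFrame(columns=["run", "trial_index", "onset",
                                             "duration", "trial_type"])
        with np.errstate(all="ignore"):
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                design = glm.build_design(empty_events, nuis, hrf, conditions=[])
        rest_resid = glm.residualize(rest, design)
        tc_a = instate.instatement_timecourse(rest_resid, pattern,
                                              mask=masks["core"],
                                              subject=f"sub-{s:02d}")
        tc_b = instate.instatement_timecourse(rest_resid, refl_pattern,
                                              mask=masks["reflection"],
                                              subject=f"sub-{s:02d}")
        tcs_a.append(tc_a.z)
        tcs_b.append(tc_b.z)
        blocks = instate.block_summary(tc_a, windows)
        ratings = simcore.simulate_ratings(blocks, seed=seed_s + 3)
        for b, v in enumerate(blocks):
            block_rows.append({"subject": f"sub-{s:02d}", "block": b, "value": v})
        ratings.insert(0, "subject", f"sub-{s:02d}")
        rating_rows.append(ratings)
    _log("instatement", t0)

    # --- temporal prediction and report linkage ---------------------------
    t0 = time.time()
    sweep = instate.lag_sweep(tcs_a, tcs_b, max_lag=config.max_lag, tr=config.tr)
    best = sweep[sweep.direction == "A->B"].nsmallest(1, "p").iloc[0]
    if out:
        sweep.to_csv(out / "lag_sweep.csv", index=False)
        manifest["outputs"].append(str(out / "lag_sweep.csv"))
    link, vif = instate.link_reports(pd.DataFrame(block_rows),
                                     pd.concat(rating_rows, ignore_index=True))
    _log("temporal", t0, best_lag=int(best["lag"]), best_lag_p=float(best["p"]),
         self_beta=link["self"].beta, max_vif=vif.max_vif())

    # --- behavior ---------------------------------------------------------
    t0 = time.time()
    all_choices = pd.concat(
        [d["choices"].assign(subject=f"sub-{i:02d}") for i, d in enumerate(subjects)],
        ignore_index=True)
    counts = all_choices["chosen_target"].value_counts()
    counts3 = [int(counts.get(k, 0)) for k in ("self", "friend", "known_other")]
    chi = behavior.chisq_gof(counts3)
    rt = behavior.rt_model(all_choices)
    _log("behavior", t0, counts=counts3, chi2=chi.statistic, chi2_p=chi.p,
         rt_friend_beta=rt["friend"].beta)

    # --- study-2 style cohort ---------------------------------------------
    t0 = time.time()
    cohort = simcore.simulate_cohort(config.cohort_n, config.cohort_trs,
                                     ak_share=config.ak_share,
                                     seed=_stage_seed(config.seed, 4))
    model = isrsa.ak_matrix(cohort.scores["internalizing_total"].to_numpy())
    sim = isrsa.tc_similarity(cohort)
    mantel = isrsa.mantel(model, sim, n_perm=config.mantel_perms,
                          seed=_stage_seed(config.seed, 4, 1))
    deg = isrsa.degree_model(cohort)
    subs = isrsa.subscale_battery(cohort, n_perm=config.mantel_perms,
                                  seed=_stage_seed(config.seed, 4, 2),
                                  tc_matrix=sim)
    if out:
        io.write_cohort(cohort, out / "cohort_scores.csv", out / "cohort_timecourses.csv")
        manifest["outputs"] += [str(out / "cohort_scores.csv"),
                                str(out / "cohort_timecourses.csv")]
    _log("isrsa", t0, mantel_rho=mantel.rho, mantel_p=mantel.p,
         degree_p=deg.p, subscale_p={k: v.p for k, v in subs.items()})

    manifest["total_seconds"] = round(time.time() - t_start, 3)
    if out:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        manifest["outputs"].append(str(out / "manifest.json"))
    return manifest
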