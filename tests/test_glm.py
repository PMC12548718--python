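"""GLM stage: HRF shape, designs, residual orthogonality, smoothing, betas."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from preself import glm, simcore
from preself.types import AcquisitionGrid, VolumeSeries
from conftest import simulate_subject


class TestHrf:
    @pytest.mark.parametrize("tr", [1.0, 0.72])
    def test_double_gamma_shape(self, tr):
        h = glm.canonical_hrf(tr)
        t_peak = np.argmax(h.samples) * tr
        assert 4.0 <= t_peak <= 6.0
        assert h.samples[0] == pytest.approx(0.0, abs=1e-12)
        assert abs(h.samples[-1]) < 0.01          # decayed tail at 32 s
        assert h.hires.max() == pytest.approx(1.0)  # unit peak

    def test_finer_sampling_same_shape(self):
        coarse = glm.canonical_hrf(1.0)
        fine = glm.canonical_hrf(0.5)
        # every other fine sample sits on the coarse grid
        assert np.allclose(fine.samples[::2], coarse.samples[:len(fine.samples[::2])])

    def test_too_short_duration_raises(self):
        with pytest.raises(ValueError):
            glm.canonical_hrf(1.0, duration=4.0)


class TestOutliers:
    def test_constant_series(self, small_grid):
        data = np.ones(tuple(small_grid.dims) + (20,))
        s = VolumeSeries(data=data, grid=small_grid)
        assert glm.detect_outlier_trs(s, n_nonsteady=0) == []
        assert glm.detect_outlier_trs(s, n_nonsteady=4) == [0, 1, 2, 3]

    def test_spike_flagged_by_both_criteria(self, small_grid):
        rng = np.random.default_rng(0)
        data = rng.normal(0, 1, tuple(small_grid.dims) + (100,))
        data[..., 50] += 10.0
        s = VolumeSeries(data=data, grid=small_grid)
        out = glm.detect_outlier_trs(s, n_nonsteady=0)
        assert 50 in out

    def test_too_short_raises(self, small_grid):
        s = VolumeSeries(np.zeros(tuple(small_grid.dims) + (5,)), small_grid)
        with pytest.raises(ValueError):
            glm.detect_outlier_trs(s)


def _events(rows):
    return pd.DataFrame(rows, columns=["run", "trial_index", "onset",
                                       "duration", "trial_type"])


class TestDesign:
    def test_single_impulse_is_hrf(self, hrf):
        # one hires-bin event approximates a delta: the column is the kernel
        ev = _events([(0, 0, 0.0, 1.0 / 16, "choice")])
        nuis = glm.NuisanceSet(run_lengths=(40,))
        d = glm.build_design(ev, nuis, hrf, conditions=["choice"])
        col = d.frame["choice"].to_numpy()
        ref = hrf.samples[:40]
        r = np.corrcoef(col[:len(ref)], ref)[0, 1]
        assert r > 0.999

    def test_run_structure_columns(self, hrf):
        ev = _events([(0, 0, 5.0, 2.0, "a"), (0, 1, 12.0, 2.0, "b"),
                      (1, 2, 5.0, 2.0, "a"), (1, 3, 12.0, 2.0, "b")])
        nuis = glm.NuisanceSet(run_lengths=(40, 40))
        d = glm.build_design(ev, nuis, hrf)
        names = list(d.frame.columns)
        assert sum(c.startswith("const_run") for c in names) == 2
        assert sum(c.startswith("drift_run") for c in names) == 2
        assert d.task_columns == ("a", "b")

    def test_full_rank_on_default_schedule(self, small_study):
        d = small_study[0]["residuals"].design
        X = d.matrix
        assert np.linalg.matrix_rank(X) == X.shape[1]

    def test_empty_events_warns(self, hrf):
        nuis = glm.NuisanceSet(run_lengths=(30,))
        with pytest.warns(UserWarning, match="nuisance-only"):
            d = glm.build_design(_events([]), nuis, hrf, conditions=[])
        assert d.task_columns == ()

    def test_event_beyond_run_raises(self, hrf):
        ev = _events([(0, 0, 35.0, 10.0, "a")])
        nuis = glm.NuisanceSet(run_lengths=(40,))
        with pytest.raises(ValueError, match="beyond run"):
            glm.build_design(ev, nuis, hrf)

    def test_nuisance_spike_columns_one_hot(self):
        nuis = glm.NuisanceSet(run_lengths=(20,), spike_trs=[3, 7])
        f = nuis.to_frame()
        for c in ("spike_0003", "spike_0007"):
            col = f[c].to_numpy()
            assert col.sum() == 1 and set(np.unique(col)) == {0.0, 1.0}
        with pytest.raises(ValueError, match="duplicate"):
            glm.NuisanceSet(run_lengths=(20,), spike_trs=[3, 3])


class TestResidualize:
    def test_perfect_fit_gives_zero_residuals(self, small_grid, hrf):
        nuis = glm.NuisanceSet(run_lengths=(40,))
        ev = _events([(0, 0, 2.0, 3.0, "a")])
        d = glm.build_design(ev, nuis, hrf)
        col = d.frame["a"].to_numpy()
        data = np.tile(col, tuple(small_grid.dims) + (1,))
        r = glm.residualize(VolumeSeries(data, small_grid), d)
        assert np.max(np.abs(r.data)) < 1e-10

    def test_intercept_only_mean_centers(self, small_grid):
        rng = np.random.default_rng(1)
        data = rng.normal(0, 1, tuple(small_grid.dims) + (25,))
        frame = pd.DataFrame({"const_run0": np.ones(25)})
        d = glm.DesignMatrix(frame=frame, task_columns=(), run_lengths=(25,))
        r = glm.residualize(VolumeSeries(data, small_grid), d)
        expected = data - data.mean(axis=-1, keepdims=True)
        assert np.allclose(r.data, expected)

    def test_orthogonality_on_simulated_run(self, small_study):
        res = small_study[0]["residuals"]
        X = res.design.matrix
        R = res.flat()
        rel = np.max(np.abs(X.T @ R)) / (np.linalg.norm(X) * np.linalg.norm(R))
        assert rel < 1e-6

    def test_rank_deficient_names_columns(self, small_grid):
        frame = pd.DataFrame({"a": np.arange(20.0), "b": 2 * np.arange(20.0),
                              "const_run0": np.ones(20)})
        d = glm.DesignMatrix.__new__(glm.DesignMatrix)
        d.frame, d.task_columns, d.run_lengths = frame, ("a", "b"), (20,)
        s = VolumeSeries(np.zeros(tuple(small_grid.dims) + (20,)), small_grid)
        with pytest.raises(ValueError, match="collinear"):
            glm.residualize(s, d)


class TestSmoothing:
    def test_zero_fwhm_identity(self, small_grid):
        rng = np.random.default_rng(2)
        data = rng.normal(size=tuple(small_grid.dims) + (3,))
        s = VolumeSeries(data, small_grid)
        assert glm.smooth_gaussian(s, 0.0) is s

    def test_mean_conserved(self):
        rng = np.random.default_rng(3)
        vol = rng.normal(size=(20, 20, 12))
        sm = glm.smooth_gaussian(vol, 6.0, voxel_size=2.5)
        assert abs(sm.mean() - vol.mean()) < 1e-6

    def test_kernel_width_matches_fwhm(self):
        # second moment of a smoothed delta equals (fwhm / 2.3548)^2 in mm
        vol = np.zeros((41, 41, 41))
        vol[20, 20, 20] = 1.0
        sm = glm.smooth_gaussian(vol, 6.0, voxel_size=2.5)
        x = (np.arange(41) - 20) * 2.5
        marg = sm.sum(axis=(1, 2))
        sd = np.sqrt(np.sum(marg * x ** 2) / marg.sum())
        assert abs(sd - 6.0 / glm.FWHM_TO_SIGMA) < 0.1

    def test_translation_equivariance_interior(self):
        vol = np.zeros((31, 31, 31))
        vol[12, 15, 15] = 1.0
        shifted = np.roll(vol, 3, axis=0)
        a = glm.smooth_gaussian(vol, 6.0, voxel_size=2.5)
        b = glm.smooth_gaussian(shifted, 6.0, voxel_size=2.5)
        assert np.allclose(np.roll(a, 3, axis=0)[6:-6], b[6:-6], atol=1e-10)


class TestRestBetas:
    def test_noiseless_recovery(self, small_grid, hrf):
        truth = simcore.make_ground_truth(small_grid, seed=11, pattern_snr=1.0)
        cfg = simcore.ScheduleConfig(trials_per_run=18, n_runs=2)
        sched = simcore.make_task_schedule(cfg, seed=12)
        rng = np.random.default_rng(13)
        amp = rng.standard_normal(36)
        ch = simcore.simulate_choices(truth, amp, seed=14)
        series, motion = simcore.simulate_task_run(
            sched, ch, truth, small_grid, noise_sd=0.0, seed=15, amplitudes=amp)
        nuis = glm.NuisanceSet(run_lengths=series.run_lengths, motion=motion)
        d = glm.build_design(sched, nuis, hrf, conditions=["choice", "shape"])
        betas = glm.pretrial_rest_betas(glm.residualize(series, d), sched, ch, hrf)
        mask = truth.preself_pattern.mask
        diff = (betas["self"].values - betas["other"].values)[mask]
        gt = truth.preself_pattern.in_mask()
        cos = diff @ gt / (np.linalg.norm(diff) * np.linalg.norm(gt))
        assert cos > 0.95

    def test_recovery_monotone_in_snr(self, small_grid, hrf):
        # class-difference map converges to the embedded pattern as SNR grows
        cos_by_snr = []
        for snr in (0.0, 0.25, 0.5, 1.0):
            cos_seeds = []
            for seed in (21, 22, 23):
                truth = simcore.make_ground_truth(small_grid, seed=11,
                                                  pattern_snr=snr)
                dat = simulate_subject(truth, small_grid, hrf,
                                       seed=3000 + seed, trials_per_run=18)
                mask = truth.preself_pattern.mask
                diff = (dat["betas"]["self"].values
                        - dat["betas"]["other"].values)[mask]
                gt = truth.preself_pattern.in_mask()
                cos_seeds.append(diff @ gt / (np.linalg.norm(diff)
                                              * np.linalg.norm(gt)))
            cos_by_snr.append(np.mean(cos_seeds))
        assert abs(cos_by_snr[0]) < 0.35          # no signal, no alignment
        assert np.all(np.diff(cos_by_snr) > -0.02)  # non-decreasing
        assert cos_by_snr[-1] > 0.9

    def test_missing_class_raises(self, small_grid, hrf, small_truth):
        cfg = simcore.ScheduleConfig(trials_per_run=6, n_runs=1)
        sched = simcore.make_task_schedule(cfg, seed=16)
        ch = pd.DataFrame({"trial_index": np.arange(6),
                           "chosen_target": ["self"] * 6, "rt": 1.0})
        series, motion = simcore.simulate_task_run(
            sched, ch, small_truth, small_grid, seed=17)
        nuis = glm.NuisanceSet(run_lengths=series.run_lengths, motion=motion)
        d = glm.build_design(sched, nuis, hrf, conditions=["choice", "shape"])
        with pytest.raises(ValueError, match="no pretrial epochs"):
            glm.pretrial_rest_betas(glm.residualize(series, d), sched, ch, hrf,
                                    subject="sub-x")

    def test_epoch_bookkeeping(self, small_study):
        betas = small_study[0]["betas"]
        choices = small_study[0]["choices"]
        n_self = (choices.chosen_target == "self").sum()
        assert betas["self"].n_epochs == n_self
        assert betas["other"].n_epochs == len(choices) - n_self


class TestContrast:
    def test_reflection_pattern_recovery(self, small_grid, hrf):
        truth = simcore.make_ground_truth(small_grid, seed=31, pattern_snr=1.0)
        cfg = simcore.ScheduleConfig(task_kind="reflection", n_runs=1,
                                     trials_per_run=40, jitter_range=(1.0, 3.0),
                                     jitter_mean=2.0, trial_duration=4.0,
                                     interlude_range=None, interlude_mean=None,
                                     dimensions=())
        sched = simcore.make_task_schedule(cfg, seed=32)
        ch = pd.DataFrame({"trial_index": np.arange(40),
                           "chosen_target": "self", "rt": 1.0})
        series, _ = simcore.simulate_task_run(sched, ch, truth, small_grid,
                                              noise_sd=0.5, seed=33)
        cmap = glm.contrast_map(series, sched, hrf, {"reflect": 1.0},
                                fwhm=0.0, mask=truth.reflection_pattern.mask)
        gt = truth.reflection_pattern.in_mask()
        v = cmap.in_mask()
        assert v @ gt / (np.linalg.norm(v) * np.linalg.norm(gt)) > 0.9

    def test_unknown_condition_raises(self, small_grid, hrf):
        ev = _events([(0, 0, 2.0, 3.0, "a")])
        s = VolumeSeries(np.random.default_rng(0).normal(
            size=tuple(small_grid.dims) + (30,)), small_grid)
        with pytest.raises(KeyError):
            glm.contrast_map(s, ev, hrf, {"missing": 1.0})

    def test_self_canceling_contrast_is_zero(self, small_grid, hrf):
        ev = _events([(0, 0, 2.0, 3.0, "a")])
        s = VolumeSeries(np.random.default_rng(1).normal(
            size=tuple(small_grid.dims) + (30,)), small_grid)
        cmap = glm.contrast_map(s, ev, hrf, [("a", 1.0), ("a", -1.0)], fwhm=0.0)
        assert np.nanmax(np.abs(cmap.values)) < 1e-12


class TestParametricModulation:
    def test_roi_errors(self, small_study, hrf, small_masks):
        subs = [(d["residuals"], d["schedule"], d["choices"])
                for d in small_study[:2]]
        with pytest.raises(ValueError, match="empty"):
            glm.parametric_modulation_group(
                subs, {"bad": np.zeros_like(small_masks["core"])}, hrf)
        with pytest.raises(ValueError, match="two subjects"):
            glm.parametric_modulation_group(subs[:1], small_masks, hrf)

    def test_group_result_identities(self, small_study, hrf, small_masks):
        subs = [(d["residuals"], d["schedule"], d["choices"])
                for d in small_study]
        res = glm.parametric_modulation_group(
            subs, {"core": small_masks["core"],
                   "reflection": small_masks["reflection"]}, hrf)
        for r in res.values():
            assert r.df == len(subs) - 1
            assert r.cohens_d == pytest.approx(r.t / np.sqrt(len(subs)))
            assert r.p_corrected == pytest.approx(min(1.0, r.p * 2))

    def test_directional_recovery(self, small_grid, hrf, small_masks):
        # faster self choices follow stronger pretrial pattern amplitude,
        # so the group self-vs-other RT-modulation contrast is negative
        truth = simcore.make_ground_truth(small_grid, seed=7)  # rt_gain 0.15
        neg = 0
        n_seeds = 20
        for seed in range(n_seeds):
            subs = []
            for s in range(8):
                dat = simulate_subject(truth, small_grid, hrf,
                                       seed=50_000 + 1000 * seed + 41 * s,
                                       trials_per_run=18)
                subs.append((dat["residuals"], dat["schedule"], dat["choices"]))
            res = glm.parametric_modulation_group(
                subs, {"core": small_masks["core"]}, hrf)
            neg += res["core"].t < 0
        assert neg >= 0.8 * n_seeds
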