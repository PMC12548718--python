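"""Pattern-instatement time courses and their temporal/behavioral linkage.

Instatement is the per-TR spatial Pearson correlation between a brain volume
and a template pattern, Fisher z-transformed (arctanh).  Block summaries link
instatement to thought-probe ratings through a random-intercept mixed model
with collinearity diagnostics; the lag sweep tests whether one pattern's
instatement predicts another's 0-20 TRs later, in both directions, with
Bonferroni correction over the 41-test family.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .types import (CollinearityReport, InstatementTimecourse, MixedModelResult,
                    PatternMap, VolumeSeries)

__all__ = [
    "Z_CAP_R",
    "instatement_timecourse",
    "block_summary",
    "link_reports",
    "lag_sweep",
    "lag_family_alpha",
]

#: |r| is clipped to this before arctanh so degenerate TRs stay finite.
Z_CAP_R = 1.0 - 1e-6


def fisher_z(r: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(r, -Z_CAP_R, Z_CAP_R))


def instatement_timecourse(series: VolumeSeries, pattern: PatternMap,
                           mask: Optional[np.ndarray] = None,
                           subject: str = "") -> InstatementTimecourse:
    """TR-to-TR pattern matching: correlate each masked volume with the
    masked pattern, then Fisher z-transform.

    A zero-variance TR inside the mask has no defined correlation; it is
    recorded as NaN with a warning.
    """
    mask = np.asarray(mask, dtype=bool) if mask is not None else pattern.mask
    if not mask.any():
        raise ValueError("empty mask")
    if pattern.values.shape != tuple(series.grid.dims):
        raise ValueError("pattern and series do not share a grid")
    p = pattern.values[mask]
    if np.any(~np.isfinite(p)):
        raise ValueError("pattern undefined on part of the mask")
    V = series.data[mask, :]                     # (m, T)
    pc = p - p.mean()
    pn = np.linalg.norm(pc)
    Vc = V - V.mean(axis=0, keepdims=True)
    vn = np.linalg.norm(Vc, axis=0)
    bad = (vn == 0) | (pn == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (pc @ Vc) / (pn * vn)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} zero-variance TR(s); recorded as missing")
        r[bad] = np.nan
    z = np.where(np.isnan(r), np.nan, fisher_z(r))
    return InstatementTimecourse(r=r, z=z, tr=series.grid.tr, subject=subject,
                                 pattern=pattern.label, mask="custom")


def block_summary(tc: InstatementTimecourse,
                  windows: Sequence[tuple[float, float]]) -> np.ndarray:
    """Mean Fisher-z instatement per block, z-scored across blocks.

    Windows are half-open (start_s, end_s) intervals; they must be
    non-overlapping and lie within the series.  A zero-variance set of block
    means z-scores to all zeros.
    """
    t = np.arange(len(tc)) * tc.tr
    ends = sorted(windows)
    for (a0, a1), (b0, b1) in zip(ends[:-1], ends[1:]):
        if b0 < a1:
            raise ValueError("overlapping block windows")
    means = []
    for (w0, w1) in windows:
        sel = (t >= w0) & (t < w1)
        if not sel.any():
            raise ValueError(f"empty block window ({w0}, {w1})")
        vals = tc.z[sel]
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            raise ValueError(f"block window ({w0}, {w1}) has no valid TRs")
        means.append(float(vals.mean()))
    means = np.asarray(means)
    sd = means.std(ddof=0)
    if sd == 0:
        return np.zeros_like(means)
    return (means - means.mean()) / sd


def _fit_mixed(frame: pd.DataFrame, outcome: str, fixed: Sequence[str],
               group: str) -> tuple[dict, "MixedLM"]:
    X = sm.add_constant(frame[list(fixed)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        model = MixedLM(frame[outcome].to_numpy(), X.to_numpy(),
                        groups=frame[group].to_numpy())
        fit = None
        errors = []
        for method in ("lbfgs", "powell", "nm"):
            try:
                fit = model.fit(reml=True, method=method)
                break
            except (np.linalg.LinAlgError, ValueError) as exc:  # boundary fits
                errors.append(f"{method}: {exc}")
        if fit is None:
            raise RuntimeError("mixed model failed to fit; " + "; ".join(errors))
        params = np.asarray(fit.params[:X.shape[1]])
        tvals = np.asarray(fit.tvalues[:X.shape[1]])
        pvals = np.asarray(fit.pvalues[:X.shape[1]])
        group_var = float(np.asarray(fit.cov_re).ravel()[0])
        if np.any(~np.isfinite(tvals)):
            # boundary fit (random-intercept variance ~ 0): the GLS estimator
            # reduces exactly to OLS, whose standard errors are well defined
            ols = sm.OLS(frame[outcome].to_numpy(), X.to_numpy()).fit()
            params, tvals, pvals = ols.params, ols.tvalues, ols.pvalues
            group_var = 0.0
    sd_y = frame[outcome].std(ddof=0)
    results = {}
    df_resid = len(frame) - X.shape[1] - 1
    for j, name in enumerate(X.columns):
        if name == "const":
            continue
        beta = float(params[j])
        sd_x = frame[name].std(ddof=0)
        results[name] = MixedModelResult(
            term=name, beta=beta,
            beta_std=beta * sd_x / sd_y if sd_y > 0 else np.nan,
            t=float(tvals[j]), df=float(df_resid), p=float(pvals[j]),
            group_var=group_var)
    return results, fit


def collinearity_report(frame: pd.DataFrame, fixed: Sequence[str]) -> CollinearityReport:
    X = sm.add_constant(frame[list(fixed)]).to_numpy(dtype=float)
    vifs = {}
    for j, name in enumerate(fixed, start=1):
        vifs[name] = float(variance_inflation_factor(X, j))
    return CollinearityReport(vif=vifs)


def link_reports(block_values: pd.DataFrame, ratings: pd.DataFrame,
                 extra: Optional[pd.DataFrame] = None
                 ) -> tuple[dict[str, MixedModelResult], CollinearityReport]:
    """Mixed model of block instatement on thought-probe ratings.

    ``block_values`` has columns (subject, block, value); ``ratings`` has
    (subject, block, self, other, future, past).  Fixed effects are the four
    ratings plus the block index (and any extra predictors); the random
    effect is a per-subject intercept.  Returns per-effect results and a
    VIF/tolerance report on the fixed-effects design.
    """
    frame = block_values.merge(ratings, on=["subject", "block"])
    if frame["subject"].nunique() < 2 or frame["block"].nunique() < 2:
        raise ValueError("need at least 2 subjects x 2 blocks")
    fixed = ["self", "other", "future", "past", "block"]
    if extra is not None:
        frame = frame.merge(extra, on=["subject", "block"])
        fixed += [c for c in extra.columns if c not in ("subject", "block")]
    for name in fixed:
        if frame[name].std(ddof=0) == 0:
            raise ValueError(f"degenerate predictor {name!r} (zero variance)")
    results, _ = _fit_mixed(frame, "value", fixed, "subject")
    return results, collinearity_report(frame, fixed)


def lag_family_alpha(max_lag: int = 20, alpha: float = 0.05) -> float:
    """Bonferroni threshold for the bidirectional lag family.

    The family counts (max_lag + 1) forward tests and max_lag reverse tests:
    the lag-0 test is the same model in either direction and enters once
    (41 tests for lags 0-20).
    """
    n_tests = 2 * (max_lag + 1) - 1
    return alpha / n_tests


def lag_sweep(tc_a: Sequence[np.ndarray], tc_b: Sequence[np.ndarray],
              max_lag: int = 20, alpha: float = 0.05,
              tr: float = 1.0) -> pd.DataFrame:
    """Bidirectional lagged prediction between two instatement time courses.

    For each lag L, a random-intercept mixed model regresses the target
    instatement at t+L on the predictor instatement at t, pooling subjects.
    Direction ``A->B`` uses A as predictor; ``B->A`` the converse; lag 0 is
    tested once.  ``passes_bonferroni`` applies alpha / 41 (for max_lag 20).
    """
    tc_a = [np.asarray(x, dtype=float) for x in tc_a]
    tc_b = [np.asarray(x, dtype=float) for x in tc_b]
    if len(tc_a) != len(tc_b):
        raise ValueError("need both time courses per subject")
    n_t = len(tc_a[0])
    if any(len(x) != n_t for x in tc_a + tc_b):
        raise ValueError("unequal time-course lengths")
    if n_t < max_lag + 2:
        raise ValueError(f"series length {n_t} too short for max_lag {max_lag}")
    thresh = lag_family_alpha(max_lag, alpha)
    rows = []
    for direction, pred, outc in (("A->B", tc_a, tc_b), ("B->A", tc_b, tc_a)):
        lag0 = 0 if direction == "A->B" else 1
        for lag in range(lag0, max_lag + 1):
            xs, ys, gs = [], [], []
            for g, (x, y) in enumerate(zip(pred, outc)):
                xv = x[:n_t - lag] if lag else x
                yv = y[lag:]
                ok = np.isfinite(xv) & np.isfinite(yv)
                xs.append(xv[ok])
                ys.append(yv[ok])
                gs.append(np.full(ok.sum(), g))
            frame = pd.DataFrame({"x": np.concatenate(xs),
                                  "value": np.concatenate(ys),
                                  "group": np.concatenate(gs)})
            res, _ = _fit_mixed(frame, "value", ["x"], "group")
            r = res["x"]
            rows.append({"direction": direction, "lag": lag, "beta": r.beta,
                         "beta_std": r.beta_std, "t": r.t, "df": r.df,
                         "p": r.p, "passes_bonferroni": r.p < thresh})
    out = pd.DataFrame(rows)
    out.attrs["corrected_alpha"] = thresh
    out.attrs["n_tests"] = 2 * (max_lag + 1) - 1
    return out
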