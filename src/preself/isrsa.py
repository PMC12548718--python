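"""Intersubject representational similarity analysis (Anna Karenina model).

The trait model matrix holds, for every subject pair, the mean of the two
subjects' trait ranks — high scorers are predicted to be alike, low scorers
idiosyncratic.  It is compared with the pairwise Pearson similarity of
instatement time courses by Spearman-correlating the strictly-lower
triangles, with significance from a Mantel permutation test that shuffles
subject identities jointly over rows and columns.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .types import Cohort, LinearModelResult, MantelResult

__all__ = [
    "mean_instatement",
    "degree_model",
    "ak_matrix",
    "tc_similarity",
    "isrsa_corr",
    "mantel",
    "subscale_battery",
]


def mean_instatement(timecourse: np.ndarray) -> float:
    """Average instatement across TRs, missing TRs excluded."""
    x = np.asarray(timecourse, dtype=float)
    if x.size == 0:
        raise ValueError("empty time course")
    ok = np.isfinite(x)
    if not ok.any():
        raise ValueError("all TRs missing")
    return float(x[ok].mean())


def degree_model(cohort: Cohort, score_col: str = "internalizing_total"
                 ) -> LinearModelResult:
    """OLS of mean instatement on the trait score ("degree" hypothesis)."""
    if cohort.n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    x = cohort.scores[score_col].to_numpy(dtype=float)
    if x.std(ddof=0) == 0:
        raise ValueError("zero-variance predictor")
    y = np.array([mean_instatement(tc) for tc in cohort.timecourses])
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    beta = float(fit.params[1])
    beta_std = beta * x.std(ddof=0) / y.std(ddof=0) if y.std(ddof=0) > 0 else np.nan
    return LinearModelResult(beta=beta, beta_std=beta_std, t=float(fit.tvalues[1]),
                             df=int(fit.df_resid), p=float(fit.pvalues[1]))


def ak_matrix(scores: np.ndarray) -> np.ndarray:
    """Mean-rank model matrix: entry (i, j) = (rank(i) + rank(j)) / 2.

    Scores are ranked ascending from 0; ties receive average ranks.  The
    matrix is invariant under any strictly monotone transform of the scores.
    """
    s = np.asarray(scores, dtype=float)
    if len(s) < 2:
        raise ValueError("need at least 2 subjects")
    if np.any(~np.isfinite(s)):
        raise ValueError("non-finite scores")
    ranks = scipy.stats.rankdata(s, method="average") - 1.0
    return 0.5 * (ranks[:, None] + ranks[None, :])


def tc_similarity(cohort_or_tcs) -> np.ndarray:
    """Pairwise Pearson similarity of instatement time courses.

    Accepts a Cohort or an (n_subjects, n_trs) array.  A zero-variance time
    course is an error naming the subject.
    """
    if isinstance(cohort_or_tcs, Cohort):
        tcs = cohort_or_tcs.timecourses
        names = list(cohort_or_tcs.scores["subject"])
    else:
        tcs = np.asarray(cohort_or_tcs, dtype=float)
        names = [f"sub-{i:04d}" for i in range(tcs.shape[0])]
    if tcs.ndim != 2:
        raise ValueError("expected (n_subjects, n_trs)")
    sds = tcs.std(axis=1, ddof=0)
    bad = np.flatnonzero(sds == 0)
    if bad.size:
        raise ValueError(f"zero-variance time course for subject {names[bad[0]]}")
    mat = np.corrcoef(tcs)
    np.fill_diagonal(mat, 1.0)
    return mat


def _lower(mat: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(mat.shape[0], k=-1)
    return mat[i, j]


def isrsa_corr(model_matrix: np.ndarray, tc_matrix: np.ndarray) -> float:
    """Spearman correlation of the strictly-lower triangles."""
    if model_matrix.shape != tc_matrix.shape:
        raise ValueError("matrix shapes differ")
    a, b = _lower(model_matrix), _lower(tc_matrix)
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("degenerate (constant) matrix")
    rho = scipy.stats.spearmanr(a, b).statistic
    return float(rho)


def mantel(model_matrix: np.ndarray, tc_matrix: np.ndarray, n_perm: int = 5000,
           seed: int = 0, return_null: bool = False):
    """Mantel permutation test of the Anna Karenina IS-RSA correlation.

    Each permutation relabels subjects by shuffling the time-course
    similarity matrix jointly over rows and columns — mathematically
    identical to relabeling the time courses and recomputing all pairwise
    correlations, since each entry depends only on its pair — and recomputes
    the lower-triangle Spearman correlation.  One-sided add-one p (null >=
    observed); z is the observed correlation standardized by the null.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    n = model_matrix.shape[0]
    isrsa_corr(model_matrix, tc_matrix)  # shape / degeneracy checks
    rng = np.random.default_rng(seed)

    # Spearman = Pearson on ranks; under a joint row/column shuffle the
    # multiset of lower-triangle values is unchanged, so each pair's rank can
    # be computed once and gathered per permutation.
    il, jl = np.tril_indices(n, k=-1)
    model_ranks = scipy.stats.rankdata(model_matrix[il, jl])
    tc_ranks_flat = scipy.stats.rankdata(tc_matrix[il, jl])
    R = np.zeros((n, n))
    R[il, jl] = tc_ranks_flat
    R[jl, il] = tc_ranks_flat

    mz = (model_ranks - model_ranks.mean())
    mnorm = np.linalg.norm(mz)
    t_mean = tc_ranks_flat.mean()
    t_norm = np.linalg.norm(tc_ranks_flat - t_mean)
    # observed statistic through the same rank-Pearson route as the null, so
    # the identity permutation reproduces it bit for bit
    observed = float(mz @ (tc_ranks_flat - t_mean) / (mnorm * t_norm))

    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)
        vals = R[np.ix_(perm, perm)][il, jl]
        null[i] = float(mz @ (vals - t_mean) / (mnorm * t_norm))
    p = (np.sum(null >= observed) + 1.0) / (n_perm + 1.0)
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=0))
    z = (observed - null_mean) / null_sd if null_sd > 0 else np.nan
    result = MantelResult(rho=observed, null_mean=null_mean, null_sd=null_sd,
                          z=float(z), p=float(p), n_perm=n_perm, seed=seed)
    if return_null:
        return result, null
    return result


def subscale_battery(cohort: Cohort, subscales=("anx_dep", "withdrawal", "somatic"),
                     n_perm: int = 5000, seed: int = 0,
                     tc_matrix: Optional[np.ndarray] = None
                     ) -> dict[str, MantelResult]:
    """Repeat the Anna Karenina IS-RSA per trait subscale.

    Each subscale gets an independent permutation stream derived from
    ``seed``; the stream seeds are recorded on the results.
    """
    for sub in subscales:
        if sub not in cohort.scores.columns:
            raise ValueError(f"missing subscale column {sub!r}")
    if tc_matrix is None:
        tc_matrix = tc_similarity(cohort)
    out = {}
    for i, sub in enumerate(subscales):
        model = ak_matrix(cohort.scores[sub].to_numpy())
        out[sub] = mantel(model, tc_matrix, n_perm=n_perm, seed=seed + i)
    return out
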