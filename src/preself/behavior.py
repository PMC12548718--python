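"""Behavioral statistics of the choice task.

Choice-count tests are goodness-of-fit chi-squares against a uniform (or
supplied) expectation; per-target counts can be recovered from pairwise
totals when only those are available.  RT effects use a random-intercept
mixed model with treatment-coded targets.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .instate import _fit_mixed
from .types import ChiSquareResult, MixedModelResult

__all__ = [
    "chisq_gof",
    "recover_counts",
    "pairwise_tests",
    "rt_model",
]


def chisq_gof(counts: Sequence[int],
              expected: Optional[Sequence[float]] = None) -> ChiSquareResult:
    """Goodness-of-fit chi-square, sum (O - E)^2 / E, df = cells - 1.

    ``expected`` defaults to a uniform split of the total.
    """
    obs = np.asarray(counts, dtype=float)
    if obs.size < 2:
        raise ValueError("need at least 2 cells")
    if np.any(obs < 0):
        raise ValueError("negative counts")
    n = obs.sum()
    if expected is None:
        expected = np.full(obs.size, n / obs.size)
    else:
        expected = np.asarray(expected, dtype=float)
    if np.any(expected <= 0):
        raise ValueError("zero or negative expected cell")
    stat, p = scipy.stats.chisquare(obs, expected)
    return ChiSquareResult(statistic=float(stat), df=obs.size - 1, n=int(n),
                           p=float(p))


def recover_counts(pairwise_totals: Sequence[int], grand_total: int) -> tuple:
    """Per-target counts from the three pairwise Ns.

    ``pairwise_totals`` is (self+friend, self+known_other, friend+known_other).
    Solves the 3x3 linear system and checks that the solution is a consistent
    nonnegative integer triple.
    """
    sf, sk, fk = (float(v) for v in pairwise_totals)
    if max(sf, sk, fk) >= grand_total:
        raise ValueError("each pairwise total must be below the grand total")
    A = np.array([[1.0, 1.0, 0.0], [1.0, 0.0, 1.0], [0.0, 1.0, 1.0]])
    x = np.linalg.solve(A, np.array([sf, sk, fk]))
    counts = np.round(x)
    if np.max(np.abs(counts - x)) > 1e-9 or np.any(counts < 0):
        raise ValueError(f"inconsistent pairwise totals (solution {x})")
    if counts.sum() != grand_total:
        raise ValueError(
            f"recovered counts sum to {int(counts.sum())}, not {grand_total}")
    check = A @ counts
    if not np.allclose(check, [sf, sk, fk]):
        raise ValueError("recovered counts do not reproduce the pairwise totals")
    return tuple(int(c) for c in counts)


def pairwise_tests(counts: Sequence[int]) -> dict[str, ChiSquareResult]:
    """Two-cell goodness-of-fit tests (vs an equal split) for each pair."""
    counts = [int(c) for c in counts]
    if len(counts) != 3:
        raise ValueError("expected 3 counts (self, friend, known_other)")
    names = ("self", "friend", "known_other")
    out = {}
    for (i, j) in ((0, 1), (0, 2), (1, 2)):
        out[f"{names[i]}_vs_{names[j]}"] = chisq_gof([counts[i], counts[j]])
    return out


def rt_model(choices: pd.DataFrame) -> dict[str, MixedModelResult]:
    """RT ~ target (treatment-coded, self as reference) with per-subject
    random intercepts.

    ``choices`` needs columns (subject, chosen_target, rt); omitted-response
    trials (missing rt) are dropped.  Positive contrasts mean slower
    responses than to the self target.
    """
    frame = choices.dropna(subset=["chosen_target", "rt"]).copy()
    if frame["subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    frame["friend"] = (frame["chosen_target"] == "friend").astype(float)
    frame["known_other"] = (frame["chosen_target"] == "known_other").astype(float)
    frame = frame.rename(columns={"rt": "value"})
    results, _ = _fit_mixed(frame, "value", ["friend", "known_other"], "subject")
    return results
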