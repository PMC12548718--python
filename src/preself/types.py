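"""Shared containers for volumes, patterns, and statistical results.

Conventions used throughout the package: voxel indices and TR indices are
0-based, onsets are seconds from run start, and event intervals are half-open
``[onset, onset + duration)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AcquisitionGrid",
    "VolumeSeries",
    "PatternMap",
    "GroundTruth",
    "Cohort",
    "InstatementTimecourse",
    "CvResult",
    "PermutationNull",
    "GroupTestResult",
    "ChiSquareResult",
    "LinearModelResult",
    "MixedModelResult",
    "CollinearityReport",
    "MantelResult",
    "EVENT_COLUMNS",
]

#: Required columns of an event table (BIDS-adjacent dialect).
EVENT_COLUMNS = ("run", "trial_index", "onset", "duration", "trial_type")


@dataclass(frozen=True)
class AcquisitionGrid:
    """Voxel grid and temporal sampling of an fMRI acquisition.

    Parameters
    ----------
    dims : tuple of int
        Voxels along each spatial axis.
    voxel_size : float
        Isotropic voxel edge in mm.
    tr : float
        Repetition time in seconds.
    """

    dims: tuple[int, int, int]
    voxel_size: float = 2.5
    tr: float = 1.0

    def __post_init__(self):
        if len(self.dims) != 3 or any(int(d) < 1 for d in self.dims):
            raise ValueError(f"dims must be three integers >= 1, got {self.dims}")
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if self.voxel_size <= 0:
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    def affine(self) -> np.ndarray:
        """Scaled-identity affine placing the volume at the origin."""
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size
        return aff


@dataclass
class VolumeSeries:
    """A 4D voxel time series (x, y, z, t) with acquisition metadata."""

    data: np.ndarray
    grid: AcquisitionGrid
    affine: Optional[np.ndarray] = None
    #: TRs per concatenated run; None means a single run.
    run_lengths: Optional[tuple] = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"expected a 4D array, got shape {self.data.shape}")
        if tuple(self.data.shape[:3]) != tuple(self.grid.dims):
            raise ValueError(
                f"data spatial shape {self.data.shape[:3]} does not match "
                f"grid dims {tuple(self.grid.dims)}"
            )
        if self.affine is None:
            self.affine = self.grid.affine()
        if self.run_lengths is not None:
            self.run_lengths = tuple(int(n) for n in self.run_lengths)
            if sum(self.run_lengths) != self.data.shape[3]:
                raise ValueError("run_lengths do not sum to the series length")

    @property
    def n_trs(self) -> int:
        return self.data.shape[3]

    def frame_times(self) -> np.ndarray:
        """Acquisition time of each volume, seconds from run start."""
        return np.arange(self.n_trs) * self.grid.tr

    def flat(self) -> np.ndarray:
        """View of the data as (n_trs, n_voxels)."""
        return self.data.reshape(-1, self.n_trs).T


@dataclass
class PatternMap:
    """A spatial weight / beta map defined over a voxel mask.

    ``values`` holds the full 3D volume; entries outside ``mask`` are NaN by
    contract.  ``source`` records provenance: ``svm_weights``, ``contrast``,
    ``rest_beta``, or ``ground_truth``.
    """

    values: np.ndarray
    mask: np.ndarray
    source: str = "ground_truth"
    label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        out = ~self.mask
        if np.any(np.isfinite(self.values[out])):
            vals = self.values.copy()
            vals[out] = np.nan
            self.values = vals

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def in_mask(self) -> np.ndarray:
        """Pattern values at mask voxels, fixed C-scan order."""
        return self.values[self.mask]


@dataclass
class GroundTruth:
    """Latent structure embedded by the simulator.

    ``pattern_snr`` is the pretrial signal amplitude per unit latent state,
    expressed as a multiple of the voxelwise noise SD.  ``choice_gain`` is the
    logistic slope linking pretrial pattern amplitude to P(choose self), and
    ``rt_gain`` the log-RT decrease per unit amplitude on self trials.
    """

    preself_pattern: PatternMap
    reflection_pattern: PatternMap
    pattern_snr: float = 0.5
    coupling_lag: int = 8
    coupling_strength: float = 0.5
    choice_gain: float = 1.5
    rt_gain: float = 0.15

    def __post_init__(self):
        if self.coupling_lag < 0:
            raise ValueError("coupling_lag must be >= 0")
        if self.pattern_snr < 0:
            raise ValueError("pattern_snr must be >= 0")


@dataclass
class Cohort:
    """Subjects with internalizing scores and instatement time courses.

    ``scores`` has columns ``subject, internalizing_total, anx_dep,
    withdrawal, somatic``; ``timecourses`` is (n_subjects, n_trs) aligned to
    the row order of ``scores``.
    """

    scores: pd.DataFrame
    timecourses: np.ndarray

    def __post_init__(self):
        self.timecourses = np.asarray(self.timecourses, dtype=float)
        if len(self.scores) != self.timecourses.shape[0]:
            raise ValueError("scores and timecourses disagree on subject count")
        if not np.all(np.isfinite(self.scores["internalizing_total"])):
            raise ValueError("non-finite internalizing scores")

    @property
    def n_subjects(self) -> int:
        return len(self.scores)


@dataclass
class InstatementTimecourse:
    """Per-TR pattern-brain correlations for one (subject, pattern, mask)."""

    r: np.ndarray
    z: np.ndarray
    tr: float
    subject: str = ""
    pattern: str = ""
    mask: str = ""

    def __len__(self) -> int:
        return len(self.z)


@dataclass
class CvResult:
    """Subject-level k-fold cross-validation outcome."""

    folds: list
    fold_accuracies: np.ndarray
    accuracy: float
    k: int


@dataclass
class PermutationNull:
    """Label-flip permutation null for a cross-validated accuracy."""

    n_perm: int
    null_accuracies: np.ndarray
    observed: float
    p: float
    seed: int

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_accuracies))


@dataclass
class GroupTestResult:
    """One-sample group t-test on an ROI summary statistic."""

    roi: str
    t: float
    df: int
    p: float
    cohens_d: float
    p_corrected: Optional[float] = None


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    n: int
    p: float


@dataclass
class LinearModelResult:
    beta: float
    beta_std: float
    t: float
    df: int
    p: float


@dataclass
class MixedModelResult:
    """Fixed-effect estimate from a random-intercept mixed model."""

    term: str
    beta: float
    beta_std: float
    t: float
    df: float
    p: float
    group_var: float = np.nan


@dataclass
class CollinearityReport:
    """VIF and tolerance (=100/VIF, percent) per fixed-effect predictor."""

    vif: dict
    tolerance_pct: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.tolerance_pct:
            self.tolerance_pct = {k: 100.0 / v for k, v in self.vif.items()}

    def max_vif(self) -> float:
        return max(self.vif.values())


@dataclass
class MantelResult:
    """Mantel permutation test of two subject-by-subject matrices."""

    rho: float
    null_mean: float
    null_sd: float
    z: float
    p: float
    n_perm: int
    seed: int
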