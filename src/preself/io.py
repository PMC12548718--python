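"""File I/O: NIfTI volumes and masks, BIDS-style event tables, ratings,
cohort tables, and JSON sidecars.

Every table is written with a header; column dictionaries are given in the
writer docstrings.  NIfTI round trips are bit-exact for the data array.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import nibabel as nib
import numpy as np
import pandas as pd

from .types import AcquisitionGrid, Cohort, InstatementTimecourse, PatternMap, VolumeSeries

__all__ = [
    "read_volume", "write_volume", "read_mask", "write_map", "read_map",
    "read_events", "write_events", "write_motion", "read_motion",
    "write_ratings", "read_ratings", "write_cohort", "read_cohort",
    "write_timecourse", "read_timecourse", "write_sidecar", "read_sidecar",
]

PathLike = Union[str, Path]


def write_volume(series: VolumeSeries, path: PathLike) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(series.data, series.affine)
    img.header.set_zooms((series.grid.voxel_size,) * 3 + (series.grid.tr,))
    nib.save(img, path)
    return path


def read_volume(path: PathLike, grid: Optional[AcquisitionGrid] = None) -> VolumeSeries:
    """Load a 4D NIfTI as a VolumeSeries; a 3D file is an error."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D series, got shape {data.shape}")
    zooms = img.header.get_zooms()
    if grid is None:
        grid = AcquisitionGrid(dims=tuple(int(d) for d in data.shape[:3]),
                               voxel_size=float(zooms[0]),
                               tr=float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0
                               else 1.0)
    elif tuple(grid.dims) != tuple(data.shape[:3]):
        raise ValueError(f"{path}: shape {data.shape[:3]} does not match "
                         f"declared grid {tuple(grid.dims)}")
    return VolumeSeries(data=data, grid=grid, affine=np.asarray(img.affine))


def read_mask(path: PathLike, label: Optional[int] = None) -> np.ndarray:
    """Boolean mask from a (possibly integer-labeled) 3D NIfTI.

    With ``label`` given, select that atlas label; otherwise any nonzero
    voxel is in the mask.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D mask, got shape {data.shape}")
    if label is None:
        return data != 0
    mask = data == label
    if not mask.any():
        raise ValueError(f"{path}: label {label} selects no voxels")
    return mask


def write_map(pattern: PatternMap, path: PathLike,
              voxel_size: float = 2.5) -> Path:
    """Save a pattern map; out-of-mask voxels are NaN in the file."""
    path = Path(path)
    aff = np.eye(4) * voxel_size
    aff[3, 3] = 1.0
    nib.save(nib.Nifti1Image(pattern.values, aff), path)
    return path


def read_map(path: PathLike, source: str = "unknown", label: str = "") -> PatternMap:
    img = nib.load(str(path))
    vals = np.asarray(img.dataobj, dtype=float)
    if vals.ndim != 3:
        raise ValueError(f"{path}: expected a 3D map")
    return PatternMap(vals, np.isfinite(vals), source=source, label=label)


# ---------------------------------------------------------------------------
# tables


def write_events(events: pd.DataFrame, path: PathLike) -> Path:
    """BIDS-style events TSV.

    Columns: onset (s), duration (s), trial_type, run, trial_index,
    dimension, and optionally response / response_time for choice events.
    """
    path = Path(path)
    cols = ["onset", "duration", "trial_type", "run", "trial_index"]
    cols += [c for c in events.columns if c not in cols]
    events[cols].to_csv(path, sep="\t", index=False, na_rep="n/a")
    return path


def read_events(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    for run, grp in df.groupby("run"):
        on = grp["onset"].to_numpy()
        if not np.all(np.diff(on) > 0):
            raise ValueError(f"{path}: onsets not strictly increasing in run {run}")
    if (df["duration"] <= 0).any():
        raise ValueError(f"{path}: non-positive durations")
    return df


def write_motion(motion: pd.DataFrame, path: PathLike) -> Path:
    """Motion TSV: run + 6 rigid-body parameters per TR."""
    motion.to_csv(Path(path), sep="\t", index=False)
    return Path(path)


def read_motion(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_ratings(ratings: pd.DataFrame, path: PathLike) -> Path:
    """Ratings TSV: subject (optional), block, self, other, future, past on
    the 1-5 probe scale."""
    ratings.to_csv(Path(path), sep="\t", index=False)
    return Path(path)


def read_ratings(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_cohort(cohort: Cohort, scores_path: PathLike,
                 timecourses_path: PathLike) -> tuple[Path, Path]:
    """Cohort CSVs: scores (subject, internalizing_total, anx_dep,
    withdrawal, somatic) and wide time courses (subject, tr_0000, ...)."""
    cohort.scores.to_csv(Path(scores_path), index=False)
    tc = pd.DataFrame(cohort.timecourses,
                      columns=[f"tr_{t:04d}" for t in range(cohort.timecourses.shape[1])])
    tc.insert(0, "subject", list(cohort.scores["subject"]))
    tc.to_csv(Path(timecourses_path), index=False)
    return Path(scores_path), Path(timecourses_path)


def read_cohort(scores_path: PathLike, timecourses_path: PathLike) -> Cohort:
    scores = pd.read_csv(scores_path)
    tc = pd.read_csv(timecourses_path)
    tc = tc.set_index("subject").loc[scores["subject"]]
    return Cohort(scores=scores, timecourses=tc.to_numpy(dtype=float))


def write_timecourse(tc: InstatementTimecourse, path: PathLike) -> Path:
    """Instatement CSV: tr_index, r (Pearson), z (Fisher)."""
    pd.DataFrame({"tr_index": np.arange(len(tc)), "r": tc.r, "z": tc.z}
                 ).to_csv(Path(path), index=False)
    return Path(path)


def read_timecourse(path: PathLike, tr: float = 1.0) -> InstatementTimecourse:
    df = pd.read_csv(path)
    return InstatementTimecourse(r=df["r"].to_numpy(), z=df["z"].to_numpy(), tr=tr)


def write_sidecar(path: PathLike, seed: int, config: dict) -> Path:
    """JSON sidecar recording the seed and full generating configuration."""
    payload = {"seed": int(seed), "config": config}
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
    return Path(path)


def read_sidecar(path: PathLike) -> dict:
    return json.loads(Path(path).read_text())
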