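"""Voxelwise seed connectivity and the signed CNM target map.

For each seed, connectivity is the Pearson correlation between the seed's
mean time course and every voxel's time course, over retained (uncensored)
volumes.  The target map averages the eight seed maps after multiplying
regulated-region maps (amygdala, sgACC) by −1, so that positive and
negative couplings reinforce instead of cancelling.  Voxels with zero
temporal variance are flagged undefined (NaN), never silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

from .preprocess import BoldSeries
from .seeds import SeedSet, build_seed_masks
from .volumes import BrainMask, VolumeGrid

__all__ = [
    "ConnectivityMap",
    "TargetMap",
    "seed_timecourse",
    "seed_connectivity_map",
    "cnm_target_map",
    "save_map",
    "load_map",
]


@dataclass
class ConnectivityMap:
    """Per-voxel Pearson r for one seed; undefined voxels are NaN."""

    grid: VolumeGrid
    values: np.ndarray
    seed_name: str = ""
    n_volumes_used: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("map shape does not match grid")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("correlation values outside [-1, 1]")

    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class TargetMap:
    """Signed mean connectivity across a seed set; the individual's
    voxelwise TMS-targeting map."""

    grid: VolumeGrid
    values: np.ndarray
    seed_names: tuple[str, ...] = ()
    n_volumes_used: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("map shape does not match grid")

    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)


def _retained(series: BoldSeries) -> np.ndarray:
    idx = series.retained_indices()
    if idx.size == 0:
        raise ValueError("all volumes are censored")
    return idx


def seed_timecourse(series: BoldSeries, seed: BrainMask) -> np.ndarray:
    """Unweighted mean signal over the seed voxels, retained volumes only."""
    if not seed.grid.same_grid(series.grid):
        raise ValueError("seed mask is on a different grid than the series")
    seed.require_nonempty("seed mask")
    idx = _retained(series)
    return series.voxel_matrix()[seed.voxels.ravel()][:, idx].mean(axis=0)


def _center_rows(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-centered matrix and per-row sums of squares (one data pass each)."""
    Yc = Y - Y.mean(axis=1, keepdims=True)
    row_ss = np.einsum("ij,ij->i", Yc, Yc)
    return Yc, row_ss


def _pearson_rows_vs(Yc: np.ndarray, row_ss: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Pearson r of each pre-centered row against s; zero-variance rows → NaN."""
    s_c = s - s.mean()
    s_ss = float(s_c @ s_c)
    denom = np.sqrt(row_ss * s_ss)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Yc @ s_c) / denom
    r[denom == 0] = np.nan
    return np.clip(r, -1.0, 1.0)


def _pearson_to_columns(Y: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Pearson r of each row of Y against s; zero-variance rows → NaN."""
    return _pearson_rows_vs(*_center_rows(Y), s)


def seed_connectivity_map(series: BoldSeries, seed: BrainMask,
                          seed_name: str = "") -> ConnectivityMap:
    """Whole-volume Pearson correlation with the seed mean time course.

    Requires at least 3 retained volumes and a non-constant seed course.
    """
    idx = _retained(series)
    if idx.size < 3:
        raise ValueError(f"only {idx.size} retained volumes; need at least 3")
    s = seed_timecourse(series, seed)
    if np.ptp(s) == 0:
        raise ValueError(f"seed {seed_name or seed.name!r} time course has zero variance")
    Y = series.voxel_matrix()[:, idx]
    r = _pearson_to_columns(Y, s)
    return ConnectivityMap(series.grid, r.reshape(series.grid.shape),
                           seed_name=seed_name or seed.name, n_volumes_used=int(idx.size))


def cnm_target_map(
    series: BoldSeries,
    seed_set: SeedSet,
    seed_masks: dict[str, BrainMask] | None = None,
    fisher_average: bool = False,
) -> TargetMap:
    """Signed average of the per-seed connectivity maps.

    value(v) = (1/N) Σ_k sign_k · r_k(v).  With ``fisher_average`` the
    signed maps are averaged in Fisher-z space and transformed back — a
    methods-comparison variant; the default averages r directly.  A voxel
    undefined in any component map is undefined in the result.
    """
    if seed_masks is None:
        seed_masks = build_seed_masks(seed_set, series.grid)
    idx = _retained(series)
    if idx.size < 3:
        raise ValueError(f"only {idx.size} retained volumes; need at least 3")
    Y = series.voxel_matrix()[:, idx]
    Yc, row_ss = _center_rows(Y)  # centered once, shared by all seeds

    signed = np.empty((len(seed_set), Y.shape[0]))
    for k, spec in enumerate(seed_set):
        mask = seed_masks[spec.name]
        if not mask.grid.same_grid(series.grid):
            raise ValueError(f"seed mask {spec.name} is on a different grid")
        mask.require_nonempty(f"seed {spec.name}")
        s = Y[mask.voxels.ravel()].mean(axis=0)
        if np.ptp(s) == 0:
            raise ValueError(f"seed {spec.name!r} time course has zero variance")
        signed[k] = spec.sign * _pearson_rows_vs(Yc, row_ss, s)

    if fisher_average:
        with np.errstate(divide="ignore"):
            z = np.arctanh(np.clip(signed, -1 + 1e-15, 1 - 1e-15))
        values = np.tanh(z.mean(axis=0))
    else:
        values = signed.mean(axis=0)
    return TargetMap(series.grid, values.reshape(series.grid.shape),
                     seed_names=tuple(seed_set.names()), n_volumes_used=int(idx.size))


# ----------------------------------------------------------------------
# NIfTI I/O for maps
# ----------------------------------------------------------------------

def save_map(m: ConnectivityMap | TargetMap, path) -> None:
    nib.save(nib.Nifti1Image(m.values.astype(np.float32), m.grid.affine), str(path))


def load_map(path) -> TargetMap:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 3:
        raise ValueError(f"{path} is not a 3-D map")
    return TargetMap(VolumeGrid(tuple(data.shape), img.affine), data)
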