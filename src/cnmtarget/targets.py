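"""From target maps to individual TMS targets and group statistics.

An individual target is the set of the K (default 100) strongest DLPFC
voxels of a subject's target map, per hemisphere.  Group analyses cover
the overlap percentage map across subjects, pairwise Euclidean distances
between per-subject peak voxels, extraction of group-mean connectivity at
externally stimulated coordinates, and covariate-adjusted correlation of
connectivity strength with clinical outcome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import TargetMap
from .seeds import split_hemispheres
from .volumes import BrainMask, VolumeGrid

__all__ = [
    "TargetSet",
    "OverlapMap",
    "OutcomeRecord",
    "CorrelationResult",
    "select_top_k",
    "target_connectivity_strength",
    "group_overlap_map",
    "peak_distances",
    "extract_at_coordinates",
    "adjusted_outcome_correlation",
]

logger = logging.getLogger(__name__)


@dataclass
class TargetSet:
    """The K strongest DLPFC voxels of one hemisphere for one subject."""

    grid: VolumeGrid
    hemisphere: str
    voxel_indices: np.ndarray       # (n, 3) voxel index triples
    k: int
    mean_connectivity: float
    peak_voxel: tuple[int, int, int]

    @property
    def n_voxels(self) -> int:
        return self.voxel_indices.shape[0]

    def as_mask(self) -> BrainMask:
        vox = np.zeros(self.grid.shape, dtype=bool)
        vox[tuple(self.voxel_indices.T)] = True
        return BrainMask(self.grid, vox, name=f"target_{self.hemisphere}")

    def peak_mni(self) -> np.ndarray:
        return self.grid.voxel_to_mni(np.asarray(self.peak_voxel, dtype=float))


@dataclass
class OverlapMap:
    """Per-voxel percentage of subjects whose target set contains the voxel."""

    grid: VolumeGrid
    values: np.ndarray
    n_subjects: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("overlap map shape does not match grid")

    def argmax_voxel(self) -> tuple[int, int, int]:
        return tuple(int(i) for i in np.unravel_index(np.argmax(self.values), self.values.shape))

    def max_percentage(self) -> float:
        return float(self.values.max())


@dataclass(frozen=True)
class OutcomeRecord:
    """One treated subject: stimulated MNI coordinate, outcome (% change in
    a symptom score), and treatment covariates."""

    subject: str
    stim_mni: tuple[float, float, float]
    outcome: float
    device: str = ""
    protocol: str = ""
    n_sessions: int = 0


def records_to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([
        {"subject": r.subject, "x": r.stim_mni[0], "y": r.stim_mni[1], "z": r.stim_mni[2],
         "outcome": r.outcome, "device": r.device, "protocol": r.protocol,
         "n_sessions": r.n_sessions}
        for r in records
    ])


def _hemisphere_mask(dlpfc: BrainMask, hemisphere: str) -> BrainMask:
    left, right = split_hemispheres(dlpfc)
    if hemisphere == "left":
        return left
    if hemisphere == "right":
        return right
    raise ValueError(f"hemisphere must be 'left' or 'right', got {hemisphere!r}")


def select_top_k(tmap: TargetMap, dlpfc: BrainMask, hemisphere: str,
                 k: int = 100) -> TargetSet:
    """Select the k largest-valued defined DLPFC voxels of one hemisphere.

    Ties at the k-th rank break deterministically: by value descending,
    then by linear (C-order) voxel index ascending.  If fewer than k
    defined voxels exist, all of them are returned with a warning.
    """
    if not tmap.grid.same_grid(dlpfc.grid):
        raise ValueError("target map and DLPFC mask are on different grids")
    if k < 1:
        raise ValueError("k must be >= 1")
    hemi = _hemisphere_mask(dlpfc, hemisphere).require_nonempty(f"{hemisphere} DLPFC mask")
    flat_vals = tmap.values.ravel()
    candidates = np.flatnonzero(hemi.voxels.ravel() & np.isfinite(flat_vals))
    if candidates.size < k:
        logger.warning("only %d defined %s-DLPFC voxels available for k=%d",
                       candidates.size, hemisphere, k)
    # sort by (-value, linear index); mergesort keeps index order among ties
    order = candidates[np.argsort(-flat_vals[candidates], kind="stable")]
    chosen = order[:k]
    vox = np.column_stack(np.unravel_index(chosen, tmap.grid.shape))
    peak = tuple(int(i) for i in np.unravel_index(order[0], tmap.grid.shape))
    return TargetSet(
        grid=tmap.grid,
        hemisphere=hemisphere,
        voxel_indices=vox,
        k=k,
        mean_connectivity=float(flat_vals[chosen].mean()),
        peak_voxel=peak,
    )


def target_connectivity_strength(tmap: TargetMap, left: TargetSet, right: TargetSet,
                                 pool: bool = True):
    """Mean target-map value over each hemisphere's target voxels.

    With ``pool`` (the default, matching the strong left/right
    intercorrelation rationale) returns the mean of the two hemisphere
    values; otherwise the (left, right) pair.
    """
    values = []
    for ts in (left, right):
        if ts.n_voxels == 0:
            raise ValueError(f"{ts.hemisphere} target set is empty")
        values.append(float(tmap.values[tuple(ts.voxel_indices.T)].mean()))
    return float(np.mean(values)) if pool else tuple(values)


def group_overlap_map(target_sets) -> OverlapMap:
    """Percentage map of common target voxels across subjects.

    Each subject's set is binarized; the counts are divided by the number
    of subjects and scaled to percent.
    """
    target_sets = list(target_sets)
    if not target_sets:
        raise ValueError("need at least one target set")
    grid = target_sets[0].grid
    counts = np.zeros(grid.shape, dtype=int)
    for ts in target_sets:
        if not ts.grid.same_grid(grid):
            raise ValueError("target sets are on different grids")
        counts[tuple(ts.voxel_indices.T)] += 1
    return OverlapMap(grid, 100.0 * counts / len(target_sets), n_subjects=len(target_sets))


def peak_distances(tmaps, mask: BrainMask) -> dict:
    """Pairwise Euclidean distances (mm) between per-subject peak voxels.

    For each subject's map the argmax voxel within ``mask`` (typically one
    hemisphere's DLPFC) is converted to MNI mm; returns the peaks, the
    condensed pairwise distances, and their mean ± SD.
    """
    tmaps = list(tmaps)
    if len(tmaps) < 2:
        raise ValueError("need at least 2 subjects for peak distances")
    mask.require_nonempty("peak-search mask")
    peaks_mm = []
    flat_mask = mask.voxels.ravel()
    for i, tm in enumerate(tmaps):
        if not tm.grid.same_grid(mask.grid):
            raise ValueError("map and mask are on different grids")
        vals = tm.values.ravel()
        inside = np.flatnonzero(flat_mask & np.isfinite(vals))
        if inside.size == 0:
            raise ValueError(f"map {i} is undefined over the whole mask")
        peak_flat = inside[np.argmax(vals[inside])]
        ijk = np.unravel_index(peak_flat, tm.grid.shape)
        peaks_mm.append(tm.grid.voxel_to_mni(np.asarray(ijk, dtype=float)))
    peaks_mm = np.asarray(peaks_mm)
    n = len(peaks_mm)
    dists = np.array([
        np.linalg.norm(peaks_mm[i] - peaks_mm[j])
        for i in range(n) for j in range(i + 1, n)
    ])
    return {
        "peaks_mm": peaks_mm,
        "distances_mm": dists,
        "mean_mm": float(dists.mean()),
        "sd_mm": float(dists.std(ddof=1)) if dists.size > 1 else 0.0,
    }


def extract_at_coordinates(group_maps, coords) -> np.ndarray:
    """Group-mean map value at the voxel nearest each MNI coordinate.

    The maps are averaged voxelwise (NaN-propagating) and sampled at the
    nearest voxel; out-of-bounds coordinates raise, naming the offender.
    """
    group_maps = list(group_maps)
    if not group_maps:
        raise ValueError("need at least one map")
    grid = group_maps[0].grid
    for m in group_maps[1:]:
        if not m.grid.same_grid(grid):
            raise ValueError("group maps are on different grids")
    mean_map = np.mean([m.values for m in group_maps], axis=0)
    coords = list(coords)
    out = np.empty(len(coords))
    for i, c in enumerate(coords):
        ijk = grid.mni_to_voxel(c)  # raises with the coordinate on failure
        out[i] = mean_map[ijk]
    return out


@dataclass
class CorrelationResult:
    """Plain and covariate-adjusted correlation of connectivity strength
    with outcome."""

    r: float
    p: float
    n: int
    partial_r: float | None = None
    partial_p: float | None = None
    df_partial: int | None = None


def _residualize(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def adjusted_outcome_correlation(strengths, records, adjust: bool = True) -> CorrelationResult:
    """Correlate per-subject connectivity strengths with treatment outcome.

    The plain value is the two-sided Pearson correlation.  With ``adjust``
    a partial correlation controlling for device, stimulation protocol and
    number of sessions is added: both variables are residualized on the
    one-hot-encoded covariate design and the residuals correlated, with p
    from the t distribution at n − 2 − k degrees of freedom (k covariate
    columns).
    """
    frame = records_to_frame(records)
    x = np.asarray(strengths, dtype=float)
    y = frame["outcome"].to_numpy(float)
    if x.shape != y.shape:
        raise ValueError("strengths and records differ in length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant variable: correlation undefined")
    r, p = stats.pearsonr(x, y)
    result = CorrelationResult(r=float(r), p=float(p), n=n)
    if not adjust:
        return result

    cov = pd.get_dummies(frame[["device", "protocol"]].astype(str), drop_first=True)
    cov["n_sessions"] = frame["n_sessions"].to_numpy(float)
    C = cov.to_numpy(float)
    k = C.shape[1]
    design = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate design is rank-deficient")
    df = n - 2 - k
    if df < 1:
        raise ValueError(f"not enough subjects ({n}) for {k} covariates")
    rx = _residualize(x, design)
    ry = _residualize(y, design)
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise ValueError("a variable is fully explained by the covariates; "
                         "partial correlation undefined")
    pr = float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
    pr = float(np.clip(pr, -1.0, 1.0))
    if abs(pr) == 1.0:
        pp = 0.0
    else:
        tstat = pr * np.sqrt(df / (1 - pr ** 2))
        pp = float(2 * stats.t.sf(abs(tstat), df))
    result.partial_r = pr
    result.partial_p = pp
    result.df_partial = df
    return result
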