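"""Per-subject BOLD denoising: nuisance regression, bandpass, FD scrubbing.

The pipeline mirrors a standard seed-connectivity preparation: regress out
head-motion parameters (plus their squares), CSF and white-matter mean
signals; bandpass the residuals to 0.01–0.1 Hz; then censor volumes around
framewise-displacement (FD, Power convention) spikes.  Censoring is a mask
— flagged volumes are excluded from every later fit and correlation but
never deleted, so indices stay aligned with the motion trace.  No spatial
smoothing is applied anywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .volumes import BrainMask, VolumeGrid

__all__ = [
    "MotionTrace",
    "BoldSeries",
    "ScrubConfig",
    "PreprocessConfig",
    "compute_fd_power",
    "scrub",
    "regress_nuisance",
    "extract_tissue_signal",
    "bandpass",
    "motion_design",
    "preprocess_bold",
    "load_bold",
    "save_bold",
    "read_motion_tsv",
    "write_motion_tsv",
]

logger = logging.getLogger(__name__)

MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


@dataclass
class MotionTrace:
    """Six rigid-body motion parameters per volume.

    ``params`` has shape (n_volumes, 6): three translations in mm followed
    by three rotations in radians (SPM column order).  A trace whose
    rotation columns exceed 2π is rejected loudly — such values cannot be
    radians and usually indicate degrees.
    """

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError(f"motion trace must be (n_volumes, 6), got {self.params.shape}")
        max_rot = np.abs(self.params[:, 3:]).max(initial=0.0)
        if max_rot > 2 * np.pi:
            raise ValueError(
                f"rotation columns reach {max_rot:.3g}, which is not a plausible "
                "radian value; are the rotations in degrees?"
            )
        if max_rot > 0.2:
            logger.warning("large rotation values (max %.3g rad); check units", max_rot)

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]

    @property
    def translations(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def rotations(self) -> np.ndarray:
        return self.params[:, 3:]


@dataclass
class BoldSeries:
    """A 4-D BOLD series on a voxel grid with censoring and provenance.

    ``data`` has shape ``grid.shape + (n_volumes,)``.  ``censor`` is True
    for retained volumes.  ``steps_applied`` records the denoising steps in
    order; idempotent steps are recorded once.
    """

    grid: VolumeGrid
    data: np.ndarray
    tr: float
    censor: np.ndarray = None
    steps_applied: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4-D, got shape {self.data.shape}")
        if tuple(self.data.shape[:3]) != self.grid.shape:
            raise ValueError(
                f"BOLD spatial shape {self.data.shape[:3]} does not match grid {self.grid.shape}"
            )
        if self.tr <= 0:
            raise ValueError(f"TR must be positive, got {self.tr}")
        if self.censor is None:
            self.censor = np.ones(self.data.shape[3], dtype=bool)
        self.censor = np.asarray(self.censor, dtype=bool)
        if self.censor.shape != (self.data.shape[3],):
            raise ValueError("censor length must equal the number of volumes")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def n_retained(self) -> int:
        return int(self.censor.sum())

    @property
    def nyquist(self) -> float:
        return 1.0 / (2.0 * self.tr)

    def retained_indices(self) -> np.ndarray:
        return np.flatnonzero(self.censor)

    def voxel_matrix(self) -> np.ndarray:
        """View of the data as (n_voxels, n_volumes), C-order voxels."""
        return self.data.reshape(-1, self.n_volumes)

    def with_step(self, step: str, **changes) -> "BoldSeries":
        steps = list(self.steps_applied)
        if step not in steps:
            steps = steps + [step]
        return replace(self, steps_applied=steps, **changes)


@dataclass(frozen=True)
class ScrubConfig:
    """Motion-censoring rule: flag every volume whose FD exceeds
    ``fd_threshold`` mm, plus ``n_before`` earlier and ``n_after`` later
    volumes."""

    fd_threshold: float = 0.5
    n_before: int = 1
    n_after: int = 2

    def __post_init__(self) -> None:
        if self.fd_threshold <= 0:
            raise ValueError("fd_threshold must be > 0")
        if self.n_before < 0 or self.n_after < 0:
            raise ValueError("n_before and n_after must be >= 0")


@dataclass(frozen=True)
class PreprocessConfig:
    """Denoising settings: passband in Hz, head radius (mm) for converting
    rotations to arc displacement in FD, and whether squared motion
    parameters join the nuisance design."""

    band: tuple[float, float] = (0.01, 0.1)
    head_radius: float = 50.0
    include_motion_squares: bool = True

    def __post_init__(self) -> None:
        low, high = self.band
        if not (0 < low < high):
            raise ValueError(f"invalid band {self.band}: need 0 < low < high")
        if self.head_radius <= 0:
            raise ValueError("head_radius must be > 0")

    @classmethod
    def from_yaml(cls, path) -> tuple["PreprocessConfig", ScrubConfig]:
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        pre = cls(
            band=tuple(cfg.get("band", (0.01, 0.1))),
            head_radius=float(cfg.get("head_radius", 50.0)),
            include_motion_squares=bool(cfg.get("include_motion_squares", True)),
        )
        scrub_cfg = ScrubConfig(
            fd_threshold=float(cfg.get("fd_threshold", 0.5)),
            n_before=int(cfg.get("n_before", 1)),
            n_after=int(cfg.get("n_after", 2)),
        )
        return pre, scrub_cfg


# ----------------------------------------------------------------------
# operations
# ----------------------------------------------------------------------

def compute_fd_power(motion: MotionTrace, head_radius: float = 50.0) -> np.ndarray:
    """Framewise displacement, Power convention.

    FD(i) = Σ|Δtranslation| + head_radius · Σ|Δrotation| between volumes
    i−1 and i; FD(0) = 0.  Rotations (radians) are converted to arc length
    on a sphere of ``head_radius`` mm.
    """
    if motion.n_volumes < 2:
        raise ValueError("FD requires at least 2 volumes")
    d = np.diff(motion.params, axis=0)
    fd = np.abs(d[:, :3]).sum(axis=1) + head_radius * np.abs(d[:, 3:]).sum(axis=1)
    return np.concatenate([[0.0], fd])


def scrub(series: BoldSeries, fd: np.ndarray, cfg: ScrubConfig = ScrubConfig()) -> BoldSeries:
    """Censor volumes around FD spikes; data values are untouched.

    Every volume i with fd(i) > threshold censors volumes
    i − n_before … i + n_after (clipped to the series bounds).  Already
    censored volumes stay censored, so lowering the threshold can only
    censor more.
    """
    fd = np.asarray(fd, dtype=float)
    if fd.shape != (series.n_volumes,):
        raise ValueError("fd length must equal the number of volumes")
    bad = np.zeros(series.n_volumes, dtype=bool)
    for i in np.flatnonzero(fd > cfg.fd_threshold):
        bad[max(0, i - cfg.n_before): min(series.n_volumes, i + cfg.n_after + 1)] = True
    censor = series.censor & ~bad
    if not censor.any():
        logger.warning("scrubbing censored every volume")
    return series.with_step("scrub", censor=censor)


def extract_tissue_signal(series: BoldSeries, mask: BrainMask) -> np.ndarray:
    """Unweighted mean signal over the mask voxels, one value per volume."""
    if not mask.grid.same_grid(series.grid):
        raise ValueError("tissue mask is on a different grid than the series")
    mask.require_nonempty("tissue mask")
    return series.voxel_matrix()[mask.voxels.ravel()].mean(axis=0)


def motion_design(motion: MotionTrace, include_squares: bool = True) -> np.ndarray:
    """Nuisance design from motion: the 6 parameters, plus their
    element-wise squares when ``include_squares`` (the standard expansion
    of 'parameters and their exponentials')."""
    cols = [motion.params]
    if include_squares:
        cols.append(motion.params ** 2)
    return np.hstack(cols)


def _check_design_rank(design: np.ndarray) -> None:
    """Raise naming the first column that is collinear with its
    predecessors (intercept included)."""
    rank = 0
    for j in range(design.shape[1]):
        new_rank = np.linalg.matrix_rank(design[:, : j + 1])
        if new_rank == rank:
            label = "intercept" if j == 0 else f"regressor column {j - 1}"
            raise ValueError(f"nuisance design is rank-deficient: {label} is collinear "
                             "with the preceding columns")
        rank = new_rank


def regress_nuisance(series: BoldSeries, regressors: np.ndarray | None) -> BoldSeries:
    """Replace each voxel series by its OLS residual against
    [intercept | regressors].

    The fit uses retained volumes only; the fitted model is then evaluated
    on all volumes so censored time points are residualized consistently.
    Residuals are orthogonal to every regressor over the retained volumes.
    """
    n = series.n_volumes
    if regressors is None:
        regressors = np.empty((n, 0))
    regressors = np.asarray(regressors, dtype=float)
    if regressors.ndim == 1:
        regressors = regressors[:, None]
    if regressors.shape[0] != n:
        raise ValueError(
            f"design has {regressors.shape[0]} rows but the series has {n} volumes"
        )
    design = np.column_stack([np.ones(n), regressors])
    keep = series.censor
    if keep.sum() <= design.shape[1]:
        raise ValueError("not enough retained volumes for the nuisance design")
    _check_design_rank(design[keep])

    X = design[keep]
    Y = series.voxel_matrix()[:, keep].T            # (n_retained, n_voxels)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid_full = series.voxel_matrix().T - design @ beta  # evaluate on all volumes
    out = resid_full.T.reshape(series.data.shape).astype(series.data.dtype, copy=False)
    return series.with_step("nuisance_regression", data=out)


def bandpass(series: BoldSeries, cfg: PreprocessConfig = PreprocessConfig()) -> BoldSeries:
    """Bandpass each voxel series with a frequency-domain mask.

    The series is linearly detrended, transformed with an rFFT, and every
    frequency bin outside [low, high] Hz — including DC — is zeroed.  A
    passband sinusoid retains ≥ 90% of its variance; stopband sinusoids
    (≤ low/2 or ≥ 2·high) keep ≤ 10%.
    """
    low, high = cfg.band
    if high >= series.nyquist:
        raise ValueError(
            f"band upper edge {high} Hz is not below the Nyquist frequency "
            f"{series.nyquist:.4g} Hz for TR {series.tr}"
        )
    n = series.n_volumes
    Y = series.voxel_matrix().astype(float)
    # linear detrend (closed-form projection on [1, t])
    t = np.arange(n, dtype=float)
    t_c = t - t.mean()
    slope = (Y @ t_c) / (t_c @ t_c)
    Y = Y - Y.mean(axis=1, keepdims=True) - slope[:, None] * t_c
    freqs = np.fft.rfftfreq(n, d=series.tr)
    keep = (freqs >= low) & (freqs <= high)
    spec = np.fft.rfft(Y, axis=1)
    spec[:, ~keep] = 0.0
    out = np.fft.irfft(spec, n=n, axis=1).reshape(series.data.shape)
    out = out.astype(series.data.dtype, copy=False)
    return series.with_step("bandpass", data=out)


def preprocess_bold(
    series: BoldSeries,
    motion: MotionTrace,
    csf: BrainMask | None = None,
    wm: BrainMask | None = None,
    cfg: PreprocessConfig = PreprocessConfig(),
    scrub_cfg: ScrubConfig = ScrubConfig(),
) -> BoldSeries:
    """Full denoising pipeline in the fixed default order:
    nuisance regression → bandpass → FD scrubbing."""
    if motion.n_volumes != series.n_volumes:
        raise ValueError("motion trace and series differ in volume count")
    cols = [motion_design(motion, cfg.include_motion_squares)]
    for tissue in (csf, wm):
        if tissue is not None:
            cols.append(extract_tissue_signal(series, tissue)[:, None])
    out = regress_nuisance(series, np.hstack(cols))
    out = bandpass(out, cfg)
    fd = compute_fd_power(motion, cfg.head_radius)
    return scrub(out, fd, scrub_cfg)


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

def load_bold(path, tr: float | None = None) -> BoldSeries:
    """Load a 4-D NIfTI BOLD series; TR is taken from the header zooms
    unless given explicitly."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{path} is not a 4-D series (shape {data.shape})")
    if tr is None:
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else None
        if not tr:
            raise ValueError(f"{path} has no TR in its header; pass tr= explicitly")
    return BoldSeries(VolumeGrid(tuple(data.shape[:3]), img.affine), data, tr=tr)


def save_bold(series: BoldSeries, path) -> None:
    img = nib.Nifti1Image(np.asarray(series.data, dtype=np.float32), series.grid.affine)
    img.header.set_zooms((*series.grid.voxel_size, series.tr))
    nib.save(img, str(path))


def read_motion_tsv(path) -> MotionTrace:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MOTION_COLUMNS if c not in df.columns]
    if missing:
        if df.shape[1] == 6:  # headerless 6-column file
            df = pd.read_csv(path, sep="\t", header=None, names=MOTION_COLUMNS)
        else:
            raise ValueError(f"motion TSV {path} lacks columns {missing}")
    return MotionTrace(df[MOTION_COLUMNS].to_numpy(float))


def write_motion_tsv(motion: MotionTrace, path) -> None:
    pd.DataFrame(motion.params, columns=MOTION_COLUMNS).to_csv(path, sep="\t", index=False)
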