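"""Within-subject repeatability of target maps.

A subject's series is split into contiguous equal-length segments; a
target map is computed from each segment; repeatability is the mean
pairwise spatial Pearson correlation (r_spat) of those maps inside the
bilateral DLPFC mask.  r_spat as a function of scan time t (minutes) is
summarized by the saturating exponential

    r_spat(t) = r_spatmax − exp(−t / a),

where r_spatmax ∈ (0, 1] is the asymptotic repeatability reachable with
the data at hand and a > 0 the time constant.  Fisher's z transform is
applied to correlations before t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

from .connectivity import TargetMap
from .preprocess import BoldSeries
from .volumes import BrainMask

__all__ = [
    "SegmentPlan",
    "RepeatabilityCurve",
    "ExponentialFit",
    "plan_segments",
    "split_segments",
    "spatial_correlation",
    "rspat",
    "fisher_z",
    "fisher_z_inv",
    "paired_rspat_test",
    "variance_fold",
    "fit_exponential",
    "repeatability_curve",
]


@dataclass(frozen=True)
class SegmentPlan:
    """Contiguous equal-length split of a series; tail volumes that do not
    fill a segment are dropped (floor rule)."""

    n_volumes: int
    segment_length: int

    def __post_init__(self) -> None:
        if self.segment_length < 1:
            raise ValueError("segment_length must be >= 1")
        if self.segment_length > self.n_volumes:
            raise ValueError(
                f"segment_length {self.segment_length} exceeds series length {self.n_volumes}"
            )

    @property
    def n_segments(self) -> int:
        return self.n_volumes // self.segment_length

    def bounds(self) -> list[tuple[int, int]]:
        L = self.segment_length
        return [(i * L, (i + 1) * L) for i in range(self.n_segments)]


def plan_segments(n_volumes: int, segment_length: int) -> SegmentPlan:
    return SegmentPlan(n_volumes, segment_length)


def split_segments(series: BoldSeries, segment_length: int) -> list[BoldSeries]:
    """Split a series into floor(n/length) equal-length segments, each
    carrying its slice of data and censor flags plus provenance."""
    plan = plan_segments(series.n_volumes, segment_length)
    out = []
    for i, (lo, hi) in enumerate(plan.bounds()):
        seg = replace(
            series,
            data=series.data[..., lo:hi],
            censor=series.censor[lo:hi],
            steps_applied=list(series.steps_applied) + [f"segment[{lo}:{hi}]"],
        )
        out.append(seg)
    return out


def spatial_correlation(map_a: TargetMap, map_b: TargetMap, mask: BrainMask) -> float:
    """Pearson correlation of two maps over jointly defined mask voxels."""
    if not map_a.grid.same_grid(map_b.grid) or not map_a.grid.same_grid(mask.grid):
        raise ValueError("maps and mask must share one grid")
    joint = mask.voxels & map_a.defined() & map_b.defined()
    if joint.sum() < 3:
        raise ValueError(f"only {int(joint.sum())} jointly defined mask voxels; need >= 3")
    a = map_a.values[joint]
    b = map_b.values[joint]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance within the mask; spatial correlation undefined")
    return float(stats.pearsonr(a, b)[0])


def rspat(maps, mask: BrainMask, fisher_average: bool = False) -> tuple[float, np.ndarray]:
    """Mean pairwise spatial correlation over all C(n, 2) map pairs.

    Returns (summary, per-pair values).  The summary is the arithmetic
    mean in r-space by default; ``fisher_average`` switches to averaging
    in Fisher-z space and transforming back.
    """
    maps = list(maps)
    if len(maps) < 2:
        raise ValueError("need at least 2 maps")
    pairs = np.array([
        spatial_correlation(maps[i], maps[j], mask)
        for i in range(len(maps)) for j in range(i + 1, len(maps))
    ])
    if fisher_average:
        summary = float(np.tanh(np.mean(np.arctanh(pairs))))
    else:
        summary = float(pairs.mean())
    return summary, pairs


def fisher_z(r):
    """Fisher's variance-stabilizing transform, z = atanh(r); |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("Fisher z requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def fisher_z_inv(z):
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


def paired_rspat_test(z_a, z_b) -> tuple[float, float]:
    """Paired two-sided t-test on per-subject Fisher-z repeatability values.

    Returns (t, p) with n − 1 degrees of freedom; all-zero differences are
    rejected because t is undefined there.
    """
    a = np.asarray(z_a, dtype=float)
    b = np.asarray(z_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D arrays")
    if a.size < 2:
        raise ValueError("need at least 2 paired values")
    d = a - b
    if np.ptp(d) == 0:
        raise ValueError("paired differences have zero variance; t undefined")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def variance_fold(r_a: float, r_b: float) -> float:
    """Fold change in explained variance between two repeatability values,
    (r_a / r_b)², reading r² as the variance of one segment's map
    explained by another's."""
    if r_b == 0:
        raise ValueError("r_b must be nonzero")
    return (r_a / r_b) ** 2


@dataclass
class ExponentialFit:
    """Result of fitting r_spat(t) = r_spatmax − exp(−t/a)."""

    rspat_max: float
    a: float
    residuals: np.ndarray
    converged: bool
    message: str = ""

    def predict(self, t):
        return self.rspat_max - np.exp(-np.asarray(t, dtype=float) / self.a)


@dataclass
class RepeatabilityCurve:
    """Mean r_spat (± SD) at each scan time, with the optional
    exponential fit."""

    scan_minutes: np.ndarray
    mean_rspat: np.ndarray
    sd_rspat: np.ndarray
    fit: ExponentialFit | None = None

    def __post_init__(self) -> None:
        self.scan_minutes = np.asarray(self.scan_minutes, dtype=float)
        if np.any(np.diff(self.scan_minutes) <= 0):
            raise ValueError("scan times must be strictly increasing")


def _exp_model(t, rmax, a):
    return rmax - np.exp(-t / a)


def fit_exponential(t_minutes, r_values) -> ExponentialFit:
    """Nonlinear least squares for the scan-time model.

    r_spatmax is constrained to (0, 1] and a to (0, ∞).  Initialization:
    r_spatmax₀ = max observed r + 0.05 (clipped to 1), a₀ = median t.
    Non-convergence is reported in the returned status, never silently.
    """
    t = np.asarray(t_minutes, dtype=float)
    r = np.asarray(r_values, dtype=float)
    if t.shape != r.shape or t.ndim != 1:
        raise ValueError("t and r must be equal-length 1-D arrays")
    if np.unique(t).size < 2:
        raise ValueError("need at least 2 distinct scan times")
    p0 = (min(1.0, float(r.max()) + 0.05), float(np.median(t)))
    try:
        import warnings
        with warnings.catch_warnings():
            # covariance is inestimable for exact 2-point interpolation;
            # only the parameters are used
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                _exp_model, t, r, p0=p0,
                bounds=([1e-9, 1e-9], [1.0, np.inf]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14, maxfev=20000,
            )
        resid = r - _exp_model(t, *popt)
        return ExponentialFit(float(popt[0]), float(popt[1]), resid, converged=True)
    except RuntimeError as exc:  # optimizer failure is an explicit status
        return ExponentialFit(np.nan, np.nan, np.full_like(r, np.nan),
                              converged=False, message=str(exc))


def repeatability_curve(series: BoldSeries, segment_lengths, make_map, mask: BrainMask,
                        fit: bool = True, fisher_average: bool = False) -> RepeatabilityCurve:
    """Convenience: split at each segment length, map each segment with
    ``make_map`` (a BoldSeries → TargetMap callable), and assemble the
    r_spat-versus-scan-time curve.

    Scan time per segment is segment_length × TR / 60 minutes, from
    nominal (not censoring-adjusted) volume counts.
    """
    lengths = sorted(set(int(L) for L in segment_lengths))
    times, means, sds = [], [], []
    for L in lengths:
        maps = [make_map(seg) for seg in split_segments(series, L)]
        mean_r, pairs = rspat(maps, mask, fisher_average=fisher_average)
        times.append(L * series.tr / 60.0)
        means.append(mean_r)
        sds.append(float(pairs.std(ddof=1)) if pairs.size > 1 else 0.0)
    curve_fit_result = fit_exponential(times, means) if fit and len(times) >= 2 else None
    return RepeatabilityCurve(np.asarray(times), np.asarray(means), np.asarray(sds),
                              fit=curve_fit_result)
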