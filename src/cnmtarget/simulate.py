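"""Synthetic cohorts with a planted regulation network and ground truth.

The generator emulates the statistical structure the signed-average target
map assumes: one shared band-limited latent signal u(t) drives regulatory
seed regions and a planted DLPFC target cluster with weight +snr, and
regulated seed regions with weight −snr, on top of unit-variance white
Gaussian noise:

    x_v(t) = w_v · u(t) + ε_v(t),   ε iid N(0, 1)

Seed regions carry flat weights ±snr; planted target clusters carry a
Gaussian-tapered weight snr·exp(−d²/(2σ²)) (σ = radius/2, zero outside
the radius) so that connectivity — and hence the simulated treatment
outcome — varies smoothly in space.  Under this model the expected
correlation between a voxel with weight w and the mean course of an
m-voxel seed with weight ±snr has the closed form
w·snr / sqrt((w² + 1)(snr² + 1/m)); every test expectation derives from
it.  Each subject gets independently jittered target clusters,
motion traces with configurable FD spikes, and a simulated outcome that
is linear in the ground-truth connectivity at a per-subject "stimulated"
coordinate plus covariate effects and noise.

Cohorts are bit-reproducible: subject i draws from an RNG seeded with
SeedSequence([cohort_seed, i]), so adding subjects never perturbs
existing ones.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import BoldSeries, MotionTrace, save_bold, write_motion_tsv
from .seeds import SeedSet, build_seed_masks, default_cnm_seed_set
from .volumes import BrainMask, VolumeGrid, save_mask

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SubjectData",
    "Cohort",
    "synthetic_grid",
    "synthetic_dlpfc_mask",
    "synthetic_csf_mask",
    "synthetic_wm_mask",
    "generate_latent",
    "generate_subject",
    "generate_cohort",
    "expected_target_map_value",
    "expected_seed_voxel_correlation",
]

#: Group-level DLPFC target locations used as planted-cluster centres
#: (left: a previously suggested connectivity-based group target; right:
#: its x-mirror).
DEFAULT_TARGET_CENTERS = ((-38.0, 44.0, 26.0), (38.0, 44.0, 26.0))


def synthetic_grid() -> VolumeGrid:
    """A 31×28×26 grid of 3 mm voxels with origin (−45, −24, −30) mm —
    the smallest box containing all eight default seed peaks and the
    bilateral DLPFC target region."""
    affine = np.array([
        [3.0, 0, 0, -45.0],
        [0, 3.0, 0, -24.0],
        [0, 0, 3.0, -30.0],
        [0, 0, 0, 1.0],
    ])
    return VolumeGrid((31, 28, 26), affine)


def _box_mask(grid: VolumeGrid, xlim, ylim, zlim, name: str,
              abs_x: bool = False) -> BrainMask:
    mm = grid.mm_coordinates()
    x = np.abs(mm[..., 0]) if abs_x else mm[..., 0]
    vox = (
        (x >= xlim[0]) & (x <= xlim[1])
        & (mm[..., 1] >= ylim[0]) & (mm[..., 1] <= ylim[1])
        & (mm[..., 2] >= zlim[0]) & (mm[..., 2] <= zlim[1])
    )
    return BrainMask(grid, vox, name=name)


def synthetic_dlpfc_mask(grid: VolumeGrid | None = None) -> BrainMask:
    """Stand-in bilateral DLPFC mask: mirrored boxes over the middle
    frontal region (24 ≤ |x| ≤ 45, 30 ≤ y ≤ 56, 14 ≤ z ≤ 40 mm)."""
    grid = grid or synthetic_grid()
    return _box_mask(grid, (24, 45), (30, 56), (14, 40), "dlpfc", abs_x=True)


def synthetic_csf_mask(grid: VolumeGrid | None = None) -> BrainMask:
    """Stand-in CSF compartment: a small midline box near the ventricles."""
    grid = grid or synthetic_grid()
    return _box_mask(grid, (-6, 6), (-18, -6), (6, 18), "csf")


def synthetic_wm_mask(grid: VolumeGrid | None = None) -> BrainMask:
    """Stand-in white-matter compartment: a deep box away from all seeds."""
    grid = grid or synthetic_grid()
    return _box_mask(grid, (12, 24), (-18, -6), (18, 30), "wm")


@dataclass
class SimConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror the acquisition the pipeline is designed for: 1000
    volumes at TR 1.68 s (so 125-volume segments are 3.5 minutes), 6 mm
    seed spheres at the eight default peaks, bilateral 7.5 mm target
    clusters jittered per subject with SD 3 mm, and snr 0.3 — giving
    seed-to-target correlations around 0.25, the magnitude typical of
    seed-based connectivity.
    """

    n_volumes: int = 1000
    tr: float = 1.68
    seed_radius: float = 6.0
    target_centers: tuple = DEFAULT_TARGET_CENTERS
    target_radius: float = 7.5
    jitter_sd: float = 3.0
    snr: float = 0.3
    n_subjects: int = 10
    rng_seed: int = 0
    band: tuple[float, float] = (0.01, 0.1)
    motion_noise_sd: float = 0.02
    spike_times: tuple[int, ...] = ()
    spike_amplitude: float = 1.0
    outcome_slope: float = 100.0
    outcome_noise_sd: float = 5.0
    stim_scatter_sd: float = 2.0
    device_effect: float = 5.0
    protocol_effect: float = 3.0
    session_effect: float = 0.5

    def __post_init__(self) -> None:
        if self.snr < 0:
            raise ValueError("snr must be >= 0")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if self.n_volumes < 2:
            raise ValueError("need at least 2 volumes")

    def seed_set(self) -> SeedSet:
        return default_cnm_seed_set(self.seed_radius)

    def grid(self) -> VolumeGrid:
        return synthetic_grid()


@dataclass
class GroundTruth:
    """Everything needed to recompute expected values without rerunning
    the generator."""

    target_centers_mni: list            # jittered per-cluster centres (mm)
    target_voxels: list                 # per-cluster (n, 3) voxel index lists
    target_weights: list                # per-cluster per-voxel mixing weights
    seed_sizes: dict                    # seed name → voxel count
    snr: float
    expected_peak_value: float          # closed-form map value at a w=+snr voxel
    stim_mni: tuple | None = None
    stim_true_value: float | None = None
    outcome: float | None = None

    def to_json(self) -> dict:
        d = asdict(self)
        d["target_voxels"] = [np.asarray(v).tolist() for v in self.target_voxels]
        d["target_weights"] = [np.asarray(w).tolist() for w in self.target_weights]
        d["target_centers_mni"] = [list(map(float, c)) for c in self.target_centers_mni]
        return d


@dataclass
class SubjectData:
    bold: BoldSeries
    motion: MotionTrace
    truth: GroundTruth


@dataclass
class Cohort:
    config: SimConfig
    subjects: list
    seed_masks: dict
    dlpfc: BrainMask
    csf: BrainMask
    wm: BrainMask
    outcomes: pd.DataFrame


# ----------------------------------------------------------------------
# closed-form expectations under the generator
# ----------------------------------------------------------------------

def expected_seed_voxel_correlation(w: float, snr: float, seed_size: int) -> float:
    """E[Pearson r] between a voxel with mixing weight ``w`` and the mean
    course of a seed of ``seed_size`` voxels each carrying weight ±snr
    (sign folded into the caller's bookkeeping)."""
    return w * snr / np.sqrt((w ** 2 + 1.0) * (snr ** 2 + 1.0 / seed_size))


def expected_target_map_value(w: float, snr: float, seed_sizes) -> float:
    """Closed-form signed-average target-map value at a voxel of weight
    ``w``: the per-seed expected correlations, sign-reversed for the
    regulated seeds, averaged over the seed set."""
    return float(np.mean([
        expected_seed_voxel_correlation(w, snr, m) for m in seed_sizes
    ]))


# ----------------------------------------------------------------------
# generation
# ----------------------------------------------------------------------

def generate_latent(n_volumes: int, tr: float, band=(0.01, 0.1),
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Zero-mean, unit-variance, band-limited Gaussian latent signal.

    White Gaussian noise is masked to the band in the rFFT domain and
    standardized; reproducible from the generator's state.
    """
    rng = rng or np.random.default_rng()
    low, high = band
    nyquist = 1.0 / (2.0 * tr)
    if not (0 < low < high <= nyquist):
        raise ValueError(f"band {band} invalid for TR {tr} (Nyquist {nyquist:.4g} Hz)")
    freqs = np.fft.rfftfreq(n_volumes, d=tr)
    keep = (freqs >= low) & (freqs <= high)
    if not keep.any():
        raise ValueError(f"band {band} contains no resolvable frequency at n={n_volumes}")
    white = rng.standard_normal(n_volumes)
    spec = np.fft.rfft(white)
    spec[~keep] = 0.0
    u = np.fft.irfft(spec, n=n_volumes)
    u -= u.mean()
    sd = u.std()
    if sd == 0:
        raise ValueError("degenerate latent signal (zero variance)")
    return u / sd


def _jitter_center(center, cfg: SimConfig, grid: VolumeGrid,
                   rng: np.random.Generator) -> np.ndarray:
    """Per-subject target-centre jitter; resampled (up to 100 draws) if it
    leaves the grid."""
    center = np.asarray(center, dtype=float)
    for _ in range(100):
        c = center + rng.normal(0.0, cfg.jitter_sd, size=3)
        if grid.contains_mni(c):
            return c
    raise RuntimeError(f"could not place jittered target near {tuple(center)}")


def target_kernel_weight(dist_mm, snr: float, radius: float) -> np.ndarray:
    """Gaussian-tapered target-cluster weight: snr·exp(−d²/(2σ²)) with
    σ = radius/2, zero beyond the radius."""
    d = np.asarray(dist_mm, dtype=float)
    sigma = radius / 2.0
    w = snr * np.exp(-d ** 2 / (2.0 * sigma ** 2))
    return np.where(d <= radius + 1e-9, w, 0.0)


def _target_cluster(grid: VolumeGrid, center, radius: float,
                    snr: float) -> tuple[np.ndarray, np.ndarray]:
    """Voxel indices and tapered weights of a planted target cluster."""
    mm = grid.mm_coordinates()
    dist = np.sqrt(((mm - np.asarray(center, dtype=float)) ** 2).sum(axis=-1))
    mask = dist <= radius + 1e-9
    mask[grid.mni_to_voxel(center)] = True
    vox = np.argwhere(mask)
    w = target_kernel_weight(dist[mask], snr, radius)
    return vox, w


def _subject_rng(cohort_seed: int, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cohort_seed, subject_index]))


def generate_subject(cfg: SimConfig, subject_index: int = 0,
                     seed_masks: dict | None = None) -> SubjectData:
    """Generate one subject's BOLD series, motion trace and ground truth.

    The series is w·u(t) + noise with weights +snr in the regulatory seeds
    and the jittered target clusters, −snr in the regulated seeds, and 0
    elsewhere.  The motion trace is small Gaussian wobble plus the
    configured displacement spikes.
    """
    grid = cfg.grid()
    rng = _subject_rng(cfg.rng_seed, subject_index)
    seed_set = cfg.seed_set()
    if seed_masks is None:
        seed_masks = build_seed_masks(seed_set, grid)

    weights = np.zeros(grid.shape, dtype=np.float32)
    seed_sizes = {}
    for spec in seed_set:
        m = seed_masks[spec.name]
        weights[m.voxels] = spec.sign * cfg.snr
        seed_sizes[spec.name] = m.n_voxels

    centers, clusters, cluster_weights = [], [], []
    for base in cfg.target_centers:
        c = _jitter_center(base, cfg, grid, rng)
        vox, w = _target_cluster(grid, c, cfg.target_radius, cfg.snr)
        weights[tuple(vox.T)] = w.astype(np.float32)
        centers.append(c)
        clusters.append(vox)
        cluster_weights.append(w)

    u = generate_latent(cfg.n_volumes, cfg.tr, cfg.band, rng)
    noise = rng.standard_normal((*grid.shape, cfg.n_volumes), dtype=np.float32)
    data = weights[..., None] * u.astype(np.float32) + noise
    bold = BoldSeries(grid, data, tr=cfg.tr, steps_applied=["synthetic"])

    params = rng.normal(0.0, cfg.motion_noise_sd, size=(cfg.n_volumes, 6))
    params[:, 3:] *= 0.01  # rotations (rad) are ~100× smaller than translations (mm)
    for t in cfg.spike_times:
        if 0 <= t < cfg.n_volumes:
            params[t, 0] += cfg.spike_amplitude  # one-volume displacement
    motion = MotionTrace(params)

    truth = GroundTruth(
        target_centers_mni=[c for c in centers],
        target_voxels=clusters,
        target_weights=cluster_weights,
        seed_sizes=seed_sizes,
        snr=cfg.snr,
        expected_peak_value=expected_target_map_value(
            cfg.snr, cfg.snr, list(seed_sizes.values())),
    )
    return SubjectData(bold=bold, motion=motion, truth=truth)


def generate_cohort(cfg: SimConfig, out_dir=None) -> Cohort:
    """Generate ``cfg.n_subjects`` independent subjects plus a simulated
    outcome table, optionally writing everything to ``out_dir``.

    The outcome for subject s is
    slope · (ground-truth map value at the stimulated voxel) + covariate
    effects (device, protocol, sessions) + N(0, outcome_noise_sd); the
    stimulated coordinate scatters around the subject's first (left)
    planted target centre.
    """
    grid = cfg.grid()
    seed_masks = build_seed_masks(cfg.seed_set(), grid)
    dlpfc = synthetic_dlpfc_mask(grid)
    csf = synthetic_csf_mask(grid)
    wm = synthetic_wm_mask(grid)

    subjects, rows = [], []
    for i in range(cfg.n_subjects):
        sub = generate_subject(cfg, subject_index=i, seed_masks=seed_masks)
        rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, i, 1]))
        # stimulated coordinate: scatter around the subject's left target
        for _ in range(100):
            stim = np.asarray(sub.truth.target_centers_mni[0]) + rng.normal(
                0.0, cfg.stim_scatter_sd, size=3)
            if grid.contains_mni(stim):
                break
        # ground-truth connectivity at the voxel actually sampled downstream
        stim_vox = grid.mni_to_voxel(stim)
        stim_vox_mm = grid.voxel_to_mni(np.asarray(stim_vox, dtype=float))
        d = np.linalg.norm(stim_vox_mm - np.asarray(sub.truth.target_centers_mni[0]))
        w_here = float(target_kernel_weight(d, cfg.snr, cfg.target_radius))
        true_val = expected_target_map_value(w_here, cfg.snr,
                                             list(sub.truth.seed_sizes.values()))
        device = "Magstim" if rng.random() < 0.5 else "Neuronetics"
        protocol = "10Hz" if rng.random() < 0.7 else "20Hz"
        n_sessions = int(rng.integers(20, 33))
        outcome = (
            cfg.outcome_slope * true_val
            + cfg.device_effect * (device == "Magstim")
            + cfg.protocol_effect * (protocol == "20Hz")
            + cfg.session_effect * (n_sessions - 26)
            + rng.normal(0.0, cfg.outcome_noise_sd)
        )
        sub.truth.stim_mni = tuple(float(c) for c in stim)
        sub.truth.stim_true_value = float(true_val)
        sub.truth.outcome = float(outcome)
        subjects.append(sub)
        rows.append({
            "subject": f"sub-{i:03d}", "x": stim[0], "y": stim[1], "z": stim[2],
            "outcome": outcome, "device": device, "protocol": protocol,
            "n_sessions": n_sessions, "true_value": true_val,
        })
    outcomes = pd.DataFrame(rows)
    cohort = Cohort(config=cfg, subjects=subjects, seed_masks=seed_masks,
                    dlpfc=dlpfc, csf=csf, wm=wm, outcomes=outcomes)
    if out_dir is not None:
        _write_cohort(cohort, Path(out_dir))
    return cohort


def _write_cohort(cohort: Cohort, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    save_mask(cohort.dlpfc, out_dir / "dlpfc.nii.gz")
    save_mask(cohort.csf, out_dir / "csf.nii.gz")
    save_mask(cohort.wm, out_dir / "wm.nii.gz")
    seeds_dir = out_dir / "seeds"
    seeds_dir.mkdir(exist_ok=True)
    for name, mask in cohort.seed_masks.items():
        save_mask(mask, seeds_dir / f"{name}.nii.gz")
    truth = {}
    for i, sub in enumerate(cohort.subjects):
        sid = f"sub-{i:03d}"
        save_bold(sub.bold, out_dir / f"{sid}_bold.nii.gz")
        write_motion_tsv(sub.motion, out_dir / f"{sid}_motion.tsv")
        truth[sid] = sub.truth.to_json()
    cohort.outcomes.to_csv(out_dir / "outcomes.tsv", sep="\t", index=False)
    (out_dir / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    (out_dir / "sim_config.json").write_text(
        json.dumps(asdict(cohort.config), indent=2, default=list))
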