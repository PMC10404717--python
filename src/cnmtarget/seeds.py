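"""Seed regions of the core network model (CNM).

The CNM combines eight seed regions in two sign classes: "regulatory"
regions (bilateral anterior insula and dorsal anterior cingulate cortex,
sign +1) whose connectivity with the DLPFC is positive, and "regulated"
emotion-processing regions (bilateral amygdala and subgenual anterior
cingulate cortex, sign −1) whose connectivity is negative and is
sign-reversed before averaging.  Seeds are spheres around fixed MNI peak
coordinates by default; arbitrary NIfTI cluster masks can be substituted
per seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .volumes import BrainMask, VolumeGrid

__all__ = [
    "SeedSpec",
    "SeedSet",
    "default_cnm_seed_set",
    "sgacc_seed_set",
    "build_sphere_seed",
    "build_seed_masks",
    "split_hemispheres",
    "read_seed_table",
    "write_seed_table",
]

logger = logging.getLogger(__name__)

REGULATORY = 1
REGULATED = -1

#: Peak MNI coordinates of the eight CNM seeds ("major depression"
#: association peaks) with their DLPFC-connectivity sign class.
CNM_SEED_PEAKS: tuple[tuple[str, tuple[float, float, float], int], ...] = (
    ("L_anterior_insula", (-34.0, 20.0, 4.0), REGULATORY),
    ("R_anterior_insula", (36.0, 20.0, -4.0), REGULATORY),
    ("L_dACC", (-2.0, 24.0, 40.0), REGULATORY),
    ("R_dACC", (2.0, 20.0, 36.0), REGULATORY),
    ("L_amygdala", (-22.0, -6.0, -16.0), REGULATED),
    ("R_amygdala", (22.0, -2.0, -16.0), REGULATED),
    ("L_sgACC", (-6.0, 16.0, -10.0), REGULATED),
    ("R_sgACC", (6.0, 16.0, -10.0), REGULATED),
)


@dataclass(frozen=True)
class SeedSpec:
    """One seed region: a named MNI peak with a sphere radius and sign class.

    ``sign`` is +1 for regulatory regions (connectivity enters the target
    map as-is) and −1 for regulated regions (connectivity is sign-reversed
    before averaging).
    """

    name: str
    peak_mni: tuple[float, float, float]
    sign: int
    radius: float = 6.0
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.sign not in (1, -1):
            raise ValueError(f"seed sign must be +1 or -1, got {self.sign}")
        if self.radius < 0:
            raise ValueError(f"seed radius must be >= 0, got {self.radius}")
        if len(self.peak_mni) != 3:
            raise ValueError("peak_mni must be an (x, y, z) triple")
        object.__setattr__(self, "peak_mni", tuple(float(c) for c in self.peak_mni))


@dataclass
class SeedSet:
    """An ordered collection of uniquely named seeds."""

    seeds: list[SeedSpec]

    def __post_init__(self) -> None:
        names = [s.name for s in self.seeds]
        if len(set(names)) != len(names):
            raise ValueError(f"seed names must be unique, got {names}")

    def __len__(self) -> int:
        return len(self.seeds)

    def __iter__(self):
        return iter(self.seeds)

    def names(self) -> list[str]:
        return [s.name for s in self.seeds]

    def subset(self, names) -> "SeedSet":
        wanted = list(names)
        by_name = {s.name: s for s in self.seeds}
        missing = [n for n in wanted if n not in by_name]
        if missing:
            raise KeyError(f"unknown seed names: {missing}")
        return SeedSet([by_name[n] for n in wanted])

    def with_flipped_signs(self) -> "SeedSet":
        return SeedSet([
            SeedSpec(s.name, s.peak_mni, -s.sign, s.radius, s.provenance) for s in self.seeds
        ])


def default_cnm_seed_set(radius: float = 6.0) -> SeedSet:
    """The eight-seed core network model.

    Four regulatory seeds (bilateral anterior insula, bilateral dACC,
    sign +1) and four regulated seeds (bilateral amygdala, bilateral
    sgACC, sign −1), as spheres of ``radius`` mm around the fixed peaks.
    Pure: identical inputs give identical, order-stable output.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    return SeedSet([
        SeedSpec(name, peak, sign, radius=radius, provenance="CNM default peak")
        for name, peak, sign in CNM_SEED_PEAKS
    ])


def sgacc_seed_set(radius: float = 6.0) -> SeedSet:
    """The bilateral sgACC-only comparison model (a 2-seed special case)."""
    full = default_cnm_seed_set(radius)
    return full.subset(["L_sgACC", "R_sgACC"])


def build_sphere_seed(spec: SeedSpec, grid: VolumeGrid) -> BrainMask:
    """Binarize a spherical seed on ``grid``.

    The mask contains every voxel whose centre lies within ``spec.radius``
    mm (Euclidean) of the peak, and always contains the voxel nearest the
    peak even for radius 0.
    """
    peak_vox = grid.mni_to_voxel(spec.peak_mni)  # raises if out of bounds
    mm = grid.mm_coordinates()
    dist2 = ((mm - np.asarray(spec.peak_mni)) ** 2).sum(axis=-1)
    vox = dist2 <= spec.radius ** 2 + 1e-9
    vox[peak_vox] = True
    return BrainMask(grid, vox, name=spec.name)


def build_seed_masks(seed_set: SeedSet, grid: VolumeGrid,
                     overrides: dict[str, BrainMask] | None = None) -> dict[str, BrainMask]:
    """Build one mask per seed; ``overrides`` substitutes explicit cluster
    masks (e.g. loaded from NIfTI) for selected seed names."""
    overrides = overrides or {}
    unknown = set(overrides) - set(seed_set.names())
    if unknown:
        raise KeyError(f"override masks for unknown seeds: {sorted(unknown)}")
    masks: dict[str, BrainMask] = {}
    for spec in seed_set:
        if spec.name in overrides:
            m = overrides[spec.name]
            if not m.grid.same_grid(grid):
                raise ValueError(f"override mask for {spec.name} is on a different grid")
            masks[spec.name] = m.require_nonempty(f"seed {spec.name}")
        else:
            masks[spec.name] = build_sphere_seed(spec, grid)
    return masks


def split_hemispheres(mask: BrainMask) -> tuple[BrainMask, BrainMask]:
    """Split a mask at the midsagittal plane into (left, right) parts.

    Left collects voxels whose MNI x < 0, right those with x > 0.  Voxels
    exactly on the midline (x = 0 mm) belong to neither hemisphere so that
    hemisphere-specific outputs never double-count.
    """
    mask.require_nonempty("mask to split")
    mm = mask.grid.mm_coordinates()
    x = mm[..., 0]
    left = BrainMask(mask.grid, mask.voxels & (x < -1e-9), name=f"{mask.name}_left")
    right = BrainMask(mask.grid, mask.voxels & (x > 1e-9), name=f"{mask.name}_right")
    for hemi, name in ((left, "left"), (right, "right")):
        if hemi.is_empty:
            logger.warning("hemisphere split: %s part of mask %r is empty", name, mask.name)
    return left, right


# ----------------------------------------------------------------------
# Seed table I/O (TSV and JSON)
# ----------------------------------------------------------------------

_TSV_COLUMNS = ["name", "x", "y", "z", "sign", "radius"]


def write_seed_table(seed_set: SeedSet, path) -> None:
    """Serialize a seed set to TSV (columns name, x, y, z, sign, radius)
    or JSON, chosen by file extension."""
    path = Path(path)
    rows = [
        {"name": s.name, "x": s.peak_mni[0], "y": s.peak_mni[1], "z": s.peak_mni[2],
         "sign": s.sign, "radius": s.radius}
        for s in seed_set
    ]
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(rows, indent=2) + "\n")
    else:
        pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_seed_table(path) -> SeedSet:
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
    else:
        rows = pd.read_csv(path, sep="\t").to_dict("records")
    seeds = [
        SeedSpec(str(r["name"]), (float(r["x"]), float(r["y"]), float(r["z"])),
                 int(r["sign"]), radius=float(r.get("radius", 6.0)))
        for r in rows
    ]
    return SeedSet(seeds)
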