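"""Synthetic CT phantoms for the five body-part classes.

Real hospital CT series cannot ship with the package, so every downstream
stage (projection, training, ensembling, evaluation) is exercised on
procedurally generated phantoms. Each phantom is a coarse anatomical cartoon
built from ellipsoids and cylinders on an air background (−1000 HU) with soft
tissue ≈ 40 HU, lung ≈ −700 HU and bone ≈ 700 HU:

* ``brain`` — ellipsoidal high-HU skull shell enclosing soft tissue, short
  longitudinal extent.
* ``neck`` — narrow soft-tissue cylinder with a single posterior bone column.
* ``chest`` — broad torso with two low-HU lung ellipsoids and a rib shell.
* ``abdomen`` — broad torso, no lungs, a large 60-HU liver-like blob.
* ``abdomen_pelvis`` — abdomen plus paired high-HU iliac-wing structures in
  the caudal third (slice index increases cranial → caudal).

Contrast enhancement adds a bright tubular vessel (≈ 300 HU) along the
longitudinal axis and raises the liver blob to ≈ 120 HU. Gaussian HU noise is
added last. The geometry is designed so a simple rule-based oracle
(:func:`classify_phantom_rule_based`) recovers both labels perfectly at noise
levels up to ~20 HU — the classes are separable *by construction*, before any
learning.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volume_io import CTVolume, write_dicom_series

__all__ = [
    "BODY_PARTS",
    "PhantomSpec",
    "generate_phantom",
    "generate_labeled_volumes",
    "generate_dataset",
    "classify_phantom_rule_based",
]

BODY_PARTS = ("brain", "neck", "chest", "abdomen", "abdomen_pelvis")

HU_AIR = -1000.0
HU_SOFT = 40.0
HU_LUNG = -700.0
HU_BONE = 700.0
HU_LIVER = 60.0
HU_LIVER_CE = 120.0
HU_VESSEL = 300.0

DEFAULT_GRID = (64, 96, 96)
DEFAULT_NOISE_SIGMA = 10.0

# per-series seed mixing rule: reproducible yet distinct series
_SEED_MIX = 10007


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one phantom volume."""

    body_part: str
    contrast: bool
    grid: tuple[int, int, int] = DEFAULT_GRID
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.body_part not in BODY_PARTS:
            raise ValueError(f"unknown body_part {self.body_part!r}; expected one of {BODY_PARTS}")
        if len(self.grid) != 3 or min(self.grid) < 16:
            raise ValueError("grid must have three dimensions, each >= 16")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def _coords(grid: tuple[int, int, int]):
    """Normalized coordinates: zf in [0,1] cranial→caudal; u,v in [-1,1] in-plane."""
    nz, ny, nx = grid
    zf = (np.arange(nz) + 0.5)[:, None, None] / nz
    v = (np.arange(ny) + 0.5)[None, :, None] / ny * 2 - 1  # anterior(−) → posterior(+)
    u = (np.arange(nx) + 0.5)[None, None, :] / nx * 2 - 1  # left(−) → right(+)
    return zf, v, u


def _ellipsoid(zf, v, u, zc, vc, uc, az, av, au):
    return ((zf - zc) / az) ** 2 + ((v - vc) / av) ** 2 + ((u - uc) / au) ** 2


def generate_phantom(spec: PhantomSpec) -> CTVolume:
    """Generate a deterministic labeled phantom volume from *spec*."""
    zf, v, u = _coords(spec.grid)

    def full(mask):
        return np.ascontiguousarray(np.broadcast_to(mask, spec.grid))
    hu = np.full(spec.grid, HU_AIR)
    body = np.zeros(spec.grid, dtype=bool)
    vessel_allowed = np.zeros(spec.grid, dtype=bool)

    part = spec.body_part
    if part == "brain":
        # skull shell: ellipsoid annulus; interior brain tissue; short z extent
        r2 = _ellipsoid(zf, v, u, 0.5, 0.0, 0.0, 0.30, 0.70, 0.70)
        shell = (r2 <= 1.0) & (r2 > 0.85**2)
        interior = r2 <= 0.85**2
        body = r2 <= 1.0
        hu[interior] = HU_SOFT
        hu[shell] = HU_BONE
        vessel_allowed = interior
    elif part == "neck":
        cyl = full((v / 0.30) ** 2 + (u / 0.30) ** 2 <= 1.0)
        body = cyl
        hu[cyl] = HU_SOFT
        column = full(((v - 0.15) / 0.08) ** 2 + (u / 0.08) ** 2 <= 1.0)
        hu[cyl & column] = HU_BONE
        vessel_allowed = cyl & ~column
    else:
        torso = full((v / 0.75) ** 2 + (u / 0.85) ** 2 <= 1.0)
        body = torso
        hu[torso] = HU_SOFT
        if part == "chest":
            rib = full((v / 0.75) ** 2 + (u / 0.85) ** 2 > 0.90**2) & torso
            lungL = _ellipsoid(zf, v, u, 0.5, -0.05, -0.42, 0.38, 0.45, 0.26) <= 1.0
            lungR = _ellipsoid(zf, v, u, 0.5, -0.05, 0.42, 0.38, 0.45, 0.26) <= 1.0
            lungs = (lungL | lungR) & torso & ~rib
            hu[lungs] = HU_LUNG
            hu[rib] = HU_BONE
            vessel_allowed = torso & ~lungs & ~rib
        else:
            liver = _ellipsoid(zf, v, u, 0.45, 0.0, -0.30, 0.28, 0.50, 0.42) <= 1.0
            liver &= torso
            hu[liver] = HU_LIVER_CE if spec.contrast else HU_LIVER
            vessel_allowed = torso
            if part == "abdomen_pelvis":
                caudal = zf[:, 0, 0] > 2.0 / 3.0
                wingL = ((v - 0.10) / 0.35) ** 2 + ((u + 0.52) / 0.18) ** 2 <= 1.0
                wingR = ((v - 0.10) / 0.35) ** 2 + ((u - 0.52) / 0.18) ** 2 <= 1.0
                wings = full(wingL | wingR) & torso
                wings &= caudal[:, None, None]
                hu[wings] = HU_BONE
                vessel_allowed &= ~wings

    if spec.contrast:
        vessel = full((v / 0.08) ** 2 + (u / 0.08) ** 2 <= 1.0)
        hu[vessel & vessel_allowed] = HU_VESSEL

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + rng.normal(0.0, spec.noise_sigma, size=spec.grid)
        # clamp to the 12-bit CT storage range, as scanners do
        hu = np.clip(hu, -1024.0, 3071.0)

    label = f"{part}_{'ce' if spec.contrast else 'nc'}"
    return CTVolume(
        voxels=hu,
        spacing=(2.0, 1.0, 1.0),
        series_id=f"phantom_{label}_s{spec.seed}",
    )


def generate_labeled_volumes(
    n_per_class_per_contrast: int,
    grid: tuple[int, int, int] = DEFAULT_GRID,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    seed: int = 0,
) -> list[tuple[CTVolume, str, bool]]:
    """Generate ``10·n`` labeled phantoms in memory.

    Per-series seeds are derived deterministically from the master seed as
    ``(master * 10007 + ordinal) mod 2**31``, so each series is distinct yet
    the whole set is reproducible from one integer.
    """
    if n_per_class_per_contrast < 1:
        raise ValueError("n_per_class_per_contrast must be >= 1")
    out = []
    ordinal = 0
    for rep in range(n_per_class_per_contrast):
        for part in BODY_PARTS:
            for contrast in (False, True):
                sub_seed = (seed * _SEED_MIX + ordinal) % (2**31)
                spec = PhantomSpec(part, contrast, grid, noise_sigma, seed=sub_seed)
                vol = generate_phantom(spec)
                vol.series_id = f"{vol.series_id}_r{rep}"
                out.append((vol, part, contrast))
                ordinal += 1
    return out


def generate_dataset(
    n_per_class_per_contrast: int,
    out_dir: str | Path,
    grid: tuple[int, int, int] = DEFAULT_GRID,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    seed: int = 0,
) -> tuple[list[Path], Path]:
    """Write ``10·n`` phantom DICOM series plus a label manifest CSV.

    Returns the list of series directories and the manifest path. The
    manifest has columns ``series_id,body_part,contrast``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dirs: list[Path] = []
    rows: list[tuple[str, str, str]] = []
    for vol, part, contrast in generate_labeled_volumes(
        n_per_class_per_contrast, grid, noise_sigma, seed
    ):
        series_dir = out_dir / vol.series_id
        write_dicom_series(vol, series_dir)
        dirs.append(series_dir)
        rows.append((vol.series_id, part, "1" if contrast else "0"))
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["series_id", "body_part", "contrast"])
        writer.writerows(rows)
    return dirs, manifest


def classify_phantom_rule_based(volume: CTVolume) -> tuple[str, bool]:
    """Recover (body_part, contrast) from phantom geometry without learning.

    Decision rules, applied in order:

    1. ≥ 2 sizeable 26-connected components below −400 HU inside the body
       mask → ``chest`` (lungs).
    2. body longitudinal extent < 90% of slices → ``brain``.
    3. mean in-plane body area fraction < 20% → ``neck``.
    4. caudal-third maximum HU > 400 → ``abdomen_pelvis``.
    5. otherwise → ``abdomen``.

    Contrast is flagged when the maximum HU over non-bone body voxels
    (HU < 500) exceeds 200 — only the vessel structure reaches that range.
    This oracle certifies label separability of the generator; it is
    deliberately independent of the learned classifiers.
    """
    hu = volume.voxels
    body = hu > -500.0
    body = ndimage.binary_fill_holes(body)

    lung_voxels = body & (hu < -400.0)
    labels, n_comp = ndimage.label(lung_voxels, structure=np.ones((3, 3, 3), dtype=int))
    if n_comp:
        sizes = np.bincount(labels.ravel())[1:]
        n_comp = int(np.sum(sizes >= 20))
    slice_has_body = body.any(axis=(1, 2))
    extent = slice_has_body.mean()
    area_frac = body[slice_has_body].mean() if slice_has_body.any() else 0.0
    caudal = hu[int(hu.shape[0] * 2 / 3):]

    if n_comp >= 2:
        part = "chest"
    elif extent < 0.9:
        part = "brain"
    elif area_frac < 0.20:
        part = "neck"
    elif caudal.max() > 400.0:
        part = "abdomen_pelvis"
    else:
        part = "abdomen"

    soft = body & (hu < 500.0)
    contrast = bool(soft.any() and hu[soft].max() > 200.0)
    return part, contrast
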