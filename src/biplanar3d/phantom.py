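"""Procedural spine phantoms: CT-like volumes with paired bone masks.

The generator builds a torso (soft-tissue ellipse with two lung ellipsoids)
containing a vertebral column: elliptic-cylinder vertebral bodies with a
trabecular core and a one-voxel cortical shell, soft disc gaps between bodies,
and a thin posterior spinous process per vertebra.  Per-phantom jitter
(radii +-15 %, a mild sinusoidal lateral curve) creates inter-subject
variation so a learned model faces a non-degenerate distribution.

Axis convention (fixed package-wide): x = left->right, y = posterior->anterior,
z = inferior->superior; voxel physical position = index * spacing (corner
anchored).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DEFAULT_HU_LEVELS",
    "PhantomSpec",
    "CTVolume",
    "SegmentationVolume",
    "generate_phantom",
    "generate_dataset",
]

#: Default tissue Hounsfield levels: bone sits inside the empirical bone
#: window, soft tissue and disc just outside the amplification range.
DEFAULT_HU_LEVELS = {
    "air": -1024.0,
    "lung": -800.0,
    "soft_tissue": 40.0,
    "disc": 80.0,
    "trabecular_bone": 400.0,
    "cortical_bone": 1200.0,
}

_REQUIRED_TISSUES = frozenset(DEFAULT_HU_LEVELS)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one procedural spine phantom.

    Lengths are millimetres; ``hu_levels`` maps the six tissue classes to
    Hounsfield values.  The default grid (64 x 64 x 128 at 2 mm isotropic)
    is the desk-scale setting; 128 x 128 x 256 at 1 mm is the full-scale one.
    """

    n_vertebrae: int = 9
    vertebra_height_mm: float = 20.0
    disc_height_mm: float = 6.0
    body_radius_mm: float = 14.0
    process_length_mm: float = 24.0
    hu_levels: dict = field(default_factory=lambda: dict(DEFAULT_HU_LEVELS))
    noise_sd: float = 15.0
    grid_shape: tuple = (64, 64, 128)
    spacing_mm: tuple = (2.0, 2.0, 2.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_vertebrae < 1:
            raise ValueError("n_vertebrae must be >= 1")
        for name in ("vertebra_height_mm", "disc_height_mm", "body_radius_mm",
                     "process_length_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        missing = _REQUIRED_TISSUES - set(self.hu_levels)
        if missing:
            raise ValueError(f"hu_levels missing tissue classes: {sorted(missing)}")
        for k, v in self.hu_levels.items():
            if not (-1024.0 <= v <= 3000.0):
                raise ValueError(f"hu_levels[{k!r}]={v} outside [-1024, 3000]")
        if len(self.grid_shape) != 3 or any(int(s) <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be 3 positive lengths")
        self._check_fits()

    def _check_fits(self) -> None:
        nx, ny, nz = self.grid_shape
        sx, sy, sz = self.spacing_mm
        column_mm = (self.n_vertebrae * self.vertebra_height_mm
                     + (self.n_vertebrae - 1) * self.disc_height_mm)
        # 15 % jitter headroom plus one voxel of margin at each end.
        if column_mm > nz * sz - 2 * sz:
            raise ValueError(
                f"grid too small along z: column needs {column_mm:.1f} mm, "
                f"grid provides {nz * sz:.1f} mm")
        max_r = 1.15 * self.body_radius_mm
        if 2 * max_r > nx * sx - 2 * sx:
            raise ValueError("grid too small along x for the vertebral body")
        if max_r + 1.15 * self.process_length_mm > ny * sy - 2 * sy:
            raise ValueError("grid too small along y for body plus process")


@dataclass
class CTVolume:
    """A CT volume in Hounsfield units with DICOM-style rescale metadata."""

    voxels: np.ndarray
    spacing_mm: tuple
    rescale_slope: float = 1.0
    rescale_intercept: float = -1024.0

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxels must be finite")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be 3 positive lengths")


@dataclass
class SegmentationVolume:
    """A binary spine mask on the same grid as its paired CT volume."""

    mask: np.ndarray
    spacing_mm: tuple

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 3:
            raise ValueError("mask must be a 3D array")
        vals = np.unique(self.mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be strictly binary")
        self.mask = self.mask.astype(np.uint8)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)


def _coordinate_grids(spec: PhantomSpec):
    nx, ny, nz = spec.grid_shape
    sx, sy, sz = spec.spacing_mm
    x = (np.arange(nx) + 0.5) * sx
    y = (np.arange(ny) + 0.5) * sy
    z = (np.arange(nz) + 0.5) * sz
    return np.meshgrid(x, y, z, indexing="ij"), (nx * sx, ny * sy, nz * sz)


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, SegmentationVolume]:
    """Generate one spine phantom and its paired ground-truth bone mask.

    Deterministic for a given ``spec`` (including ``spec.seed``).  The mask is
    1 exactly where bone-class tissue (vertebral body or spinous process) was
    painted.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    hu = spec.hu_levels
    (X, Y, Z), (ex, ey, ez) = _coordinate_grids(spec)
    sx, sy, sz = spec.spacing_mm

    ct = np.full(spec.grid_shape, hu["air"], dtype=np.float32)
    mask = np.zeros(spec.grid_shape, dtype=bool)

    # Torso: elliptic cylinder of soft tissue filling most of the grid.
    cx, cy = ex / 2.0, ey / 2.0
    torso_rx, torso_ry = 0.46 * ex, 0.42 * ey
    torso = ((X - cx) / torso_rx) ** 2 + ((Y - cy) / torso_ry) ** 2 <= 1.0
    ct[torso] = hu["soft_tissue"]

    # Two lung ellipsoids, anterior-lateral of the spine.
    lung_cy = cy + 0.12 * ey
    for side in (-1.0, 1.0):
        lung = (((X - (cx + side * 0.22 * ex)) / (0.16 * ex)) ** 2
                + ((Y - lung_cy) / (0.22 * ey)) ** 2
                + ((Z - ez / 2.0) / (0.42 * ez)) ** 2) <= 1.0
        ct[lung & torso] = hu["lung"]

    # Per-phantom jitter: radii +-15 %, mild sinusoidal lateral curve.
    r_jit = 1.0 + 0.3 * (rng.random() - 0.5)        # in [0.85, 1.15)
    h_jit = 1.0 + 0.2 * (rng.random() - 0.5)        # in [0.90, 1.10)
    curve_amp = rng.uniform(0.0, 0.06) * ex          # lateral bow, mm
    curve_phase = rng.uniform(0.0, 2.0 * np.pi)

    rx = spec.body_radius_mm * r_jit
    ry = 0.85 * rx
    vert_h = spec.vertebra_height_mm * h_jit
    disc_h = spec.disc_height_mm
    column_mm = spec.n_vertebrae * vert_h + (spec.n_vertebrae - 1) * disc_h
    if column_mm > ez - 2 * sz:     # jitter pushed the column out of the grid
        vert_h = (ez - 2 * sz - (spec.n_vertebrae - 1) * disc_h) / spec.n_vertebrae
        column_mm = spec.n_vertebrae * vert_h + (spec.n_vertebrae - 1) * disc_h
    z0 = (ez - column_mm) / 2.0
    spine_cy = cy - 0.22 * ey       # posterior third of the torso

    shell = max(sx, sy)             # one-voxel cortical shell
    curve = curve_amp * np.sin(2.0 * np.pi * Z / ez + curve_phase)
    r2_outer = ((X - cx - curve) / rx) ** 2 + ((Y - spine_cy) / ry) ** 2
    r2_inner = (((X - cx - curve) / max(rx - shell, shell)) ** 2
                + ((Y - spine_cy) / max(ry - shell, shell)) ** 2)

    for i in range(spec.n_vertebrae):
        zlo = z0 + i * (vert_h + disc_h)
        zhi = zlo + vert_h
        in_z = (Z >= zlo) & (Z < zhi)
        body = in_z & (r2_outer <= 1.0)
        core = in_z & (r2_inner <= 1.0)
        ct[body] = hu["cortical_bone"]
        ct[core] = hu["trabecular_bone"]
        mask |= body
        # Disc between this vertebra and the next.
        if i + 1 < spec.n_vertebrae:
            in_disc = (Z >= zhi) & (Z < zhi + disc_h)
            ct[in_disc & (r2_outer <= 1.0)] = hu["disc"]
        # Posterior spinous process: thin cortical slab, shorter than the
        # body so neighbouring processes never merge across the disc.
        proc = ((Z >= zlo + 0.15 * vert_h) & (Z < zhi - 0.15 * vert_h)
                & (np.abs(X - cx - curve) <= max(sx, 0.1 * rx))
                & (Y <= spine_cy) & (Y >= spine_cy - spec.process_length_mm))
        ct[proc] = hu["cortical_bone"]
        mask |= proc

    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)
        np.clip(noise, -6.0 * spec.noise_sd, 6.0 * spec.noise_sd, out=noise)
        ct = ct + noise.astype(np.float32)
        np.clip(ct, -1024.0, None, out=ct)

    return (CTVolume(ct, spec.spacing_mm),
            SegmentationVolume(mask.astype(np.uint8), spec.spacing_mm))


def generate_dataset(n: int, spec: PhantomSpec, seed: int
                     ) -> list[tuple[CTVolume, SegmentationVolume]]:
    """Generate ``n`` phantoms with per-item seeds derived from ``seed``.

    Item ``i`` is a pure function of (spec, seed, i): it is identical across
    runs and independent of ``n``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out = []
    for i in range(n):
        child = np.random.SeedSequence(entropy=int(seed), spawn_key=(i,))
        item_seed = int(child.generate_state(1)[0] % (2 ** 31))
        out.append(generate_phantom(replace(spec, seed=item_seed)))
    return out
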