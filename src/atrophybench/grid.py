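"""Sampling grid, phantom geometry and smooth random fields.

The phantom lives on a regular 3D grid in a common analysis space (the
stand-in for an SPM-style template space).  Brain support is an axis-aligned
ellipsoid occupying ~60% of each grid dimension; named regions are geometric
sectors of it and a face-exterior slab sits anterior-inferior to it, outside
the brain.  Axis convention: x = left-right, y = posterior-anterior
(+y anterior), z = inferior-superior (+z superior).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "GridSpec",
    "RegionAtlas",
    "fwhm_to_sigma",
    "ellipsoid_profile",
    "build_region_atlas",
    "smooth_noise_field",
]

#: FWHM = sigma * 2*sqrt(2*ln 2)
_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: Fraction of each grid dimension spanned by the brain ellipsoid (diameter).
BRAIN_FRACTION = 0.6

#: Squared normalized radius of the central "deep gray" ball.
DEEP_R2 = 0.10


def fwhm_to_sigma(fwhm: float) -> float:
    """Convert a Gaussian full width at half maximum to its SD (same units)."""
    return float(fwhm) / _FWHM_FACTOR


@dataclass(frozen=True)
class GridSpec:
    """Regular 3D sampling grid.

    Parameters
    ----------
    shape
        Number of voxels along each axis; every dimension must be >= 8.
    voxel_size
        Voxel edge length in mm along each axis; all > 0.
    """

    shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size: tuple[float, float, float] = (4.0, 4.0, 4.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.voxel_size) != 3:
            raise ValueError("GridSpec requires 3 dimensions")
        if any(int(s) < 8 for s in self.shape):
            raise ValueError(f"all grid dimensions must be >= 8, got {self.shape}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be > 0, got {self.voxel_size}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))

    @property
    def center(self) -> np.ndarray:
        """Grid center in voxel coordinates."""
        return (np.asarray(self.shape, dtype=float) - 1.0) / 2.0

    @property
    def semi_axes(self) -> np.ndarray:
        """Brain-ellipsoid semi-axes in voxel units."""
        return np.asarray(self.shape, dtype=float) * (BRAIN_FRACTION / 2.0)

    def sigma_voxels(self, fwhm_mm: float) -> tuple[float, float, float]:
        """Gaussian SD in voxel units per axis for a smoothing FWHM in mm."""
        s = fwhm_to_sigma(fwhm_mm)
        return tuple(s / v for v in self.voxel_size)

    def affine(self) -> np.ndarray:
        """NIfTI affine: voxel-size scaling, origin at the corner voxel."""
        aff = np.diag(list(self.voxel_size) + [1.0])
        return aff


def _normalized_r2(grid: GridSpec) -> np.ndarray:
    """Squared normalized ellipsoidal radius (1.0 on the brain boundary)."""
    idx = np.indices(grid.shape, dtype=float)
    c = grid.center
    a = grid.semi_axes
    r2 = np.zeros(grid.shape, dtype=float)
    for ax in range(3):
        r2 += ((idx[ax] - c[ax]) / a[ax]) ** 2
    return r2


def ellipsoid_profile(grid: GridSpec) -> np.ndarray:
    """Unit-peak parabolic GM profile on the brain ellipsoid.

    1 at the center, falling to 0 on the ellipsoid boundary, 0 outside.
    This is the spatial shape shared by the baseline GM field, the
    age-decline field and the sex-offset field.
    """
    r2 = _normalized_r2(grid)
    return np.clip(1.0 - r2, 0.0, None)


@dataclass
class RegionAtlas:
    """Named boolean voxel masks over a grid.

    Brain regions (frontal, frontobasal, temporal, occipital, deep,
    cerebellum) are mutually disjoint sectors of the ellipsoidal brain
    support; ``face_exterior`` is disjoint from the brain support entirely.
    """

    grid: GridSpec
    labels: dict[str, np.ndarray] = field(default_factory=dict)

    BRAIN_REGIONS = ("frontal", "frontobasal", "temporal", "occipital", "deep", "cerebellum")

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.labels[name]
        except KeyError:
            raise KeyError(
                f"unknown region {name!r}; available: {sorted(self.labels)}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self.labels

    def centroid(self, name: str) -> np.ndarray:
        """Voxel-coordinate centroid of a region."""
        mask = self[name]
        return np.mean(np.argwhere(mask), axis=0)


def build_region_atlas(grid: GridSpec) -> RegionAtlas:
    """Construct the geometric region atlas for a grid.

    Sectors of the brain ellipsoid (all excluding the central deep ball):

    - ``deep``        central ball, r^2 < 0.1 (normalized)
    - ``frontal``     anterior-superior quadrant
    - ``frontobasal`` anterior-inferior quadrant
    - ``occipital``   posterior-superior quadrant
    - ``temporal``    posterior-inferior, lateral thirds
    - ``cerebellum``  posterior-inferior, medial third

    ``face_exterior`` is a slab anterior-inferior to the brain, strictly
    outside 1.2x the brain ellipsoid.
    """
    r2 = _normalized_r2(grid)
    brain = r2 < 1.0
    c = grid.center
    a = grid.semi_axes
    idx = np.indices(grid.shape, dtype=float)
    x, y, z = idx[0], idx[1], idx[2]

    deep = r2 < DEEP_R2
    shell = brain & ~deep
    anterior = y >= c[1]
    superior = z >= c[2]
    lateral = np.abs(x - c[0]) >= 0.4 * a[0]

    labels = {
        "deep": deep,
        "frontal": shell & anterior & superior,
        "frontobasal": shell & anterior & ~superior,
        "occipital": shell & ~anterior & superior,
        "temporal": shell & ~anterior & ~superior & lateral,
        "cerebellum": shell & ~anterior & ~superior & ~lateral,
        "face_exterior": (r2 > 1.2) & (y >= c[1] + 0.6 * a[1]) & ~superior,
    }
    for name, mask in labels.items():
        if not mask.any():
            raise ValueError(f"region {name!r} is empty on grid {grid.shape}")
    return RegionAtlas(grid=grid, labels=labels)


def smooth_noise_field(
    rng: np.random.Generator,
    grid: GridSpec,
    fwhm_mm: float,
    point_sd: float,
) -> np.ndarray:
    """Stationary smooth Gaussian random field with a given point SD.

    White noise is convolved with a Gaussian kernel of the stated FWHM and
    rescaled so its empirical voxel SD equals ``point_sd`` — the standard way
    to emulate the spatial-smoothing character of preprocessed VBM-style maps.
    """
    if point_sd < 0:
        raise ValueError("point_sd must be >= 0")
    if point_sd == 0:
        return np.zeros(grid.shape, dtype=float)
    white = rng.standard_normal(grid.shape)
    if fwhm_mm > 0:
        field_ = gaussian_filter(white, sigma=grid.sigma_voxels(fwhm_mm))
    else:
        field_ = white
    sd = field_.std()
    if sd > 0:
        field_ = field_ * (point_sd / sd)
    return field_
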