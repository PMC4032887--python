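"""3D image stacks: loading, normalization, and seed-point generation.

A stack is a 3D grid of intensities with anisotropic voxel sizes
``(s_x, s_y, s_z)``; confocal and two-photon stacks typically have coarser
z-resolution than x/y. Intensities are normalized to [0, 1] because they act
as the propagation speed in the Eikonal equation solved downstream.

Axis convention: the in-memory array is indexed ``voxels[i, j, k]`` with
``i`` along x, ``j`` along y, ``k`` along z. Multi-page TIFFs store one z-slice
per page as (row=y, col=x), so a file of shape (z, y, x) maps to
``voxels = pages.transpose(2, 1, 0)``. The physical position of voxel
(i, j, k) is ``origin + (i*s_x, j*s_y, k*s_z)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy import ndimage


class NormalizationError(ValueError):
    """Raised when a stack has zero dynamic range (all voxels equal)."""


@dataclass
class ImageStack:
    """A normalized 3D intensity grid with physical voxel sizes.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Intensities in [0, 1].
    voxel_size : tuple of float
        Physical size of one voxel along (x, y, z); all positive.
    origin : ndarray, shape (3,)
        Physical coordinate of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.voxels.ndim}")
        self.voxel_size = tuple(float(s) for s in self.voxel_size)
        if len(self.voxel_size) != 3 or any(s <= 0 for s in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive lengths, got {self.voxel_size}")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Physical coordinates of (fractional) voxel indices, shape (..., 3)."""
        return self.origin + np.asarray(idx, dtype=float) * np.array(self.voxel_size)

    def physical_to_index(self, pos: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of physical coordinates, shape (..., 3)."""
        return (np.asarray(pos, dtype=float) - self.origin) / np.array(self.voxel_size)

    def interpolate(self, pos: np.ndarray) -> np.ndarray:
        """Trilinearly interpolated intensity at physical positions (n, 3)."""
        idx = np.atleast_2d(self.physical_to_index(pos))
        return ndimage.map_coordinates(self.voxels, idx.T, order=1, mode="nearest")


@dataclass
class SeedSet:
    """Seed voxels for Fast Marching, ordered by decreasing intensity."""

    points: list[tuple[int, int, int]]
    intensities: list[float]

    def __len__(self) -> int:
        return len(self.points)


def normalize(voxels: np.ndarray) -> np.ndarray:
    """Min–max normalize intensities to [0, 1]; idempotent.

    Raises
    ------
    NormalizationError
        If all voxels are equal (zero dynamic range).
    """
    voxels = np.asarray(voxels, dtype=float)
    lo, hi = float(voxels.min()), float(voxels.max())
    if hi == lo:
        raise NormalizationError("stack has zero dynamic range (all voxels equal)")
    return (voxels - lo) / (hi - lo)


def load_stack(path, voxel_size=(1.0, 1.0, 1.0)) -> ImageStack:
    """Load a single- or multi-page grayscale TIFF as a normalized ImageStack.

    Pages are z-slices; the returned array is indexed (x, y, z).

    Raises
    ------
    ValueError
        For non-grayscale (e.g. RGB) data.
    NormalizationError
        For zero dynamic range.
    """
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        if getattr(page, "samplesperpixel", 1) != 1:
            raise ValueError("expected grayscale data, got multi-sample (color) pages")
        data = tf.asarray()
    if data.ndim == 2:
        data = data[None, ...]
    if data.ndim != 3:
        raise ValueError(f"expected grayscale pages, got array of shape {data.shape}")
    return ImageStack(normalize(data.transpose(2, 1, 0)), voxel_size)


def save_stack(stack: ImageStack, path) -> None:
    """Write a stack as a multi-page 32-bit float TIFF (pages = z-slices)."""
    tifffile.imwrite(path, stack.voxels.transpose(2, 1, 0).astype(np.float32),
                     photometric="minisblack")


def generate_seeds(
    stack: ImageStack,
    threshold: float = 0.3,
    min_separation: float | None = None,
    smoothing_sigma: float = 1.0,
) -> SeedSet:
    """Generate seed points along bright structures.

    Local intensity maxima of the Gaussian-smoothed stack (sigma in voxels)
    above ``threshold`` are thinned greedily, brightest first, so that no two
    seeds lie within ``min_separation`` (physical units; default ``10*s_x``).
    Plateau voxels (ties with neighbors) count as maxima so that ridge lines
    of constant intensity are seeded along their whole length.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    if min_separation is None:
        min_separation = 10.0 * stack.voxel_size[0]

    smooth = ndimage.gaussian_filter(stack.voxels, sigma=smoothing_sigma)
    is_max = (
        (ndimage.maximum_filter(smooth, size=3) == smooth)
        & (smooth > threshold)
        & (stack.voxels > threshold)
    )
    cand = np.argwhere(is_max)
    if len(cand) == 0:
        return SeedSet([], [])
    vals = smooth[tuple(cand.T)]
    order = np.argsort(-vals, kind="stable")
    cand, vals = cand[order], vals[order]

    svec = np.array(stack.voxel_size)
    kept: list[np.ndarray] = []
    kept_vals: list[float] = []
    for p, v in zip(cand, vals):
        phys = p * svec
        if all(np.linalg.norm(phys - q) >= min_separation for q in
               (np.asarray(k) * svec for k in kept)):
            kept.append(p)
            kept_vals.append(float(stack.voxels[tuple(p)]))
    return SeedSet([tuple(int(c) for c in p) for p in kept], kept_vals)
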