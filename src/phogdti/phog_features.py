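"""Pyramid Histogram of Oriented Gradients (PHOG) over a PSSM image.

The L x 20 scoring matrix of a protein is treated as a grayscale image.  The
descriptor is built in four stages:

1. Sobel edge image: true 2-D convolution of the matrix with the horizontal
   and vertical Sobel kernels (replicate padding), combined as the Euclidean
   magnitude.
2. Gradient field of the edge image by central differences, giving per-pixel
   magnitude g and orientation theta in [0, 360).
3. A spatial pyramid: at level l the image is tiled into 2^l x 2^l cells
   (floor boundaries), so levels 0..3 give 1 + 4 + 16 + 64 = 85 cells.
4. Per-cell m-bin orientation histograms (magnitude-weighted by default),
   each normalised as V / sqrt(||V||^2 + eps^2), concatenated level by level
   in row-major cell order.

At the defaults (3 pyramid levels beyond the root, 8 bins) the descriptor has
85 * 8 = 680 dimensions.  Pixels with zero gradient magnitude carry no
orientation and cast no vote.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import ndimage

from .pssm_io import Pssm

# Outer products [1, 0, -1]^T x [1, 2, 1] and its transpose: the horizontal
# (row-direction) and vertical (column-direction) Sobel kernels.
SOBEL_X = np.array([[1, 2, 1], [0, 0, 0], [-1, -2, -1]], dtype=float)
SOBEL_Y = SOBEL_X.T.copy()


@dataclass(frozen=True)
class PhogConfig:
    """Parameters of the PHOG descriptor.

    levels
        Pyramid depth: levels ``0..levels`` are used, level l contributing
        ``4**l`` cells.  Default 3 (85 cells).
    bins
        Number of orientation bins over [0, 360).  Default 8.
    epsilon
        The small constant in the histogram normalisation
        ``V / sqrt(||V||^2 + eps^2)``; keeps empty histograms at zero.
    magnitude_weighted
        If True (default) each pixel votes with weight g; otherwise each
        oriented pixel counts 1.
    """

    levels: int = 3
    bins: int = 8
    epsilon: float = 1e-5
    magnitude_weighted: bool = True

    def __post_init__(self) -> None:
        if self.levels < 0:
            raise ValueError("levels must be >= 0")
        if self.bins < 1:
            raise ValueError("bins must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")

    @property
    def n_cells(self) -> int:
        """Total cell count across the pyramid: (4^(levels+1) - 1) / 3."""
        return (4 ** (self.levels + 1) - 1) // 3

    @property
    def n_features(self) -> int:
        """Descriptor length: bins * n_cells (680 at defaults)."""
        return self.bins * self.n_cells


@dataclass
class GradientField:
    """Per-pixel gradient magnitude and orientation of an edge image.

    ``orientation`` is in degrees in [0, 360); pixels with zero magnitude
    have no defined direction — they are flagged in ``orientation_free`` and
    their orientation is stored as 0.
    """

    magnitude: np.ndarray
    orientation: np.ndarray
    orientation_free: np.ndarray

    def __post_init__(self) -> None:
        if self.magnitude.shape != self.orientation.shape:
            raise ValueError("magnitude and orientation shapes differ")
        if np.any(self.magnitude < 0):
            raise ValueError("gradient magnitude must be nonnegative")


def sobel_edge_image(F: np.ndarray) -> np.ndarray:
    """Edge-magnitude image ``I = sqrt((F * Sx)^2 + (F * Sy)^2)``.

    ``*`` is true 2-D convolution (kernel flipped) with replicate padding,
    so the output has the input's shape and a constant input yields exactly
    zero.  Requires at least a 3 x 3 input.
    """
    F = np.asarray(F, dtype=float)
    if F.ndim != 2 or F.shape[0] < 3 or F.shape[1] < 3:
        raise ValueError(
            f"input must be at least 3 x 3 to convolve with a Sobel kernel, "
            f"got shape {F.shape}"
        )
    gx = ndimage.convolve(F, SOBEL_X, mode="nearest")
    gy = ndimage.convolve(F, SOBEL_Y, mode="nearest")
    return np.hypot(gx, gy)


def gradient_field(I: np.ndarray) -> GradientField:
    """Central-difference gradient of an image, replicate-padded.

    ``g_x(r, c) = I(r+1, c) - I(r-1, c)`` and
    ``g_y(r, c) = I(r, c+1) - I(r, c-1)``; magnitude is the Euclidean norm
    and orientation the four-quadrant arctangent mapped into [0, 360).
    """
    I = np.asarray(I, dtype=float)
    if I.ndim != 2 or I.size == 0:
        raise ValueError(f"expected a nonempty 2-D array, got shape {I.shape}")
    Ip = np.pad(I, 1, mode="edge")
    gx = Ip[2:, 1:-1] - Ip[:-2, 1:-1]
    gy = Ip[1:-1, 2:] - Ip[1:-1, :-2]
    g = np.hypot(gx, gy)
    theta = np.degrees(np.arctan2(gy, gx)) % 360.0
    free = g == 0
    theta[free] = 0.0
    return GradientField(magnitude=g, orientation=theta, orientation_free=free)


def grid_partition(
    shape: tuple[int, int], level: int
) -> list[tuple[int, int, int, int]]:
    """Tile ``shape`` into ``2**level x 2**level`` cells with floor boundaries.

    Returns ``4**level`` rectangles ``(r0, r1, c0, c1)`` (half-open) in
    row-major order; they are pairwise disjoint and cover the whole matrix.
    """
    rows, cols = shape
    n = 2 ** level
    if rows < n or cols < n:
        raise ValueError(
            f"shape {shape} too small for pyramid level {level}: "
            f"needs at least {n} rows and {n} columns"
        )
    rb = [(r * rows) // n for r in range(n + 1)]
    cb = [(c * cols) // n for c in range(n + 1)]
    return [
        (rb[r], rb[r + 1], cb[c], cb[c + 1])
        for r in range(n)
        for c in range(n)
    ]


def cell_hog(
    field: GradientField,
    cell: tuple[int, int, int, int],
    m: int,
    epsilon: float = 1e-5,
    magnitude_weighted: bool = True,
) -> np.ndarray:
    """Normalised m-bin orientation histogram of one cell.

    Each oriented pixel votes into bin ``floor(theta / (360 / m))`` with
    weight g (or 1 in count mode); orientation-free pixels are skipped.  The
    histogram is normalised as ``V / sqrt(||V||^2 + eps^2)``, which leaves an
    empty histogram at exactly zero instead of NaN.
    """
    r0, r1, c0, c1 = cell
    theta = field.orientation[r0:r1, c0:c1]
    g = field.magnitude[r0:r1, c0:c1]
    free = field.orientation_free[r0:r1, c0:c1]
    voting = ~free
    bins = np.floor(theta[voting] * m / 360.0).astype(np.intp)
    np.clip(bins, 0, m - 1, out=bins)  # guard against fp rounding at 360
    weights = g[voting] if magnitude_weighted else None
    V = np.bincount(bins, weights=weights, minlength=m).astype(float)
    return V / np.sqrt(V @ V + epsilon * epsilon)


def phog(pssm: Pssm | np.ndarray, config: PhogConfig = PhogConfig()) -> np.ndarray:
    """Full PHOG descriptor of a PSSM (or any 2-D matrix).

    Pipeline: Sobel edge image -> gradient field -> per-level grid partition
    -> per-cell normalised histograms, concatenated level 0 first, cells in
    row-major order within a level.  Length ``config.n_features`` (680 at
    defaults).  Requires at least ``2**levels`` rows and columns (protein
    length >= 8 at defaults; the 20 PSSM columns always suffice).
    """
    F = pssm.scores if isinstance(pssm, Pssm) else np.asarray(pssm, dtype=float)
    need = 2 ** config.levels
    if F.shape[0] < need or F.shape[1] < need:
        raise ValueError(
            f"matrix of shape {F.shape} is too small for {config.levels} "
            f"pyramid levels: needs at least {need} rows and {need} columns "
            f"(protein length >= {need})"
        )
    field = gradient_field(sobel_edge_image(F))
    blocks = [
        cell_hog(field, cell, config.bins, config.epsilon,
                 config.magnitude_weighted)
        for level in range(config.levels + 1)
        for cell in grid_partition(F.shape, level)
    ]
    return np.concatenate(blocks)


def phog_feature_names(config: PhogConfig = PhogConfig()) -> list[str]:
    """Stable column names ``phog_L<level>_g<cell>_b<bin>`` for the layout."""
    names = []
    for level in range(config.levels + 1):
        for cell in range(4 ** level):
            for b in range(config.bins):
                names.append(f"phog_L{level}_g{cell}_b{b}")
    return names


def phog_table(
    pssms: dict[str, Pssm] | Iterable[tuple[str, Pssm]],
    config: PhogConfig = PhogConfig(),
) -> dict[str, np.ndarray]:
    """PHOG descriptors for a collection of proteins, keyed by protein id."""
    items = pssms.items() if isinstance(pssms, dict) else pssms
    return {pid: phog(p, config) for pid, p in items}
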