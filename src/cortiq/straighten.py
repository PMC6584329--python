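"""Cortex straightening: image + contour -> circumference x perpendicular matrix.

A band of configurable width (default 50 samples) centered on the contour is
sampled along the inward normal at every resampled contour vertex.  Row ``i``
of the result is the perpendicular intensity profile at circumference
position ``i``; columns are ordered exterior -> interior, so a profile
traverses extracellular medium, cortex, then cytoplasm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .contour import Contour, resample_contour

DEFAULT_BAND_WIDTH = 50  # samples across the cortex


@dataclass
class StraightenedCortex:
    """Matrix of perpendicular profiles C[i, j].

    ``i`` indexes circumference positions at fixed arc-length spacing and
    wraps circularly when the source contour was closed; ``j`` indexes
    perpendicular offsets ordered exterior -> interior.
    """

    values: np.ndarray  # (N, W)
    arc_length_per_step: float  # pixels between consecutive rows
    perpendicular_spacing: float = 1.0  # pixels between consecutive columns
    closed: bool = True

    @property
    def n_positions(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def band_center(self) -> float:
        """Column coordinate of the contour itself: (W-1)/2."""
        return (self.width - 1) / 2.0

    def positions(self) -> np.ndarray:
        """Arc-length fractions s in [0, 1) of each row (closed contours)."""
        return np.arange(self.n_positions) / self.n_positions

    def copy_with(self, values: np.ndarray) -> "StraightenedCortex":
        return StraightenedCortex(values, self.arc_length_per_step,
                                  self.perpendicular_spacing, self.closed)


def _inward_normals(vertices: np.ndarray, closed: bool) -> np.ndarray:
    """Unit inward normals from central-difference tangents.

    For a counter-clockwise (positively oriented) contour the interior lies
    to the left of travel, so the inward normal is the tangent rotated +90
    degrees: (tx, ty) -> (-ty, tx).
    """
    if closed:
        tang = (np.roll(vertices, -1, axis=0) - np.roll(vertices, 1, axis=0)) / 2.0
    else:
        tang = np.gradient(vertices, axis=0)
    norms = np.linalg.norm(tang, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("degenerate contour: repeated vertices give zero tangent")
    tang = tang / norms
    return np.column_stack([-tang[:, 1], tang[:, 0]])


def straighten_cortex(image: np.ndarray, contour: Contour,
                      width: int = DEFAULT_BAND_WIDTH,
                      perpendicular_spacing: float = 1.0,
                      resample_spacing: float | None = 1.0) -> StraightenedCortex:
    """Sample a band centered on the contour into a straightened matrix.

    Parameters
    ----------
    image : 2D array
        Fluorescence frame; pixel centers at integer (row, col).
    contour : Contour
        Cortex outline; resampled at ``resample_spacing`` pixels of arc
        length first (pass None to use the vertices as given).
    width : int
        Number of perpendicular samples (band width); the band is centered
        on the contour, offsets running from -(width-1)/2 (exterior) to
        +(width-1)/2 (interior) in units of ``perpendicular_spacing``.

    Returns
    -------
    StraightenedCortex
        ``values[i, j]`` is the bilinear interpolation of ``image`` at
        ``vertex_i + (j - (width-1)/2) * perpendicular_spacing * inward_normal_i``.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2D")
    if width < 2:
        raise ValueError("width must be at least 2 samples")
    if perpendicular_spacing <= 0:
        raise ValueError("perpendicular_spacing must be positive")

    if contour.closed:
        if not contour.is_simple():
            raise ValueError("contour is self-intersecting (not a simple polygon)")
        contour = contour.ensure_counterclockwise()
    if resample_spacing is not None:
        contour = resample_contour(contour, resample_spacing)
        arc_step = contour.perimeter() / contour.n_vertices if contour.closed \
            else resample_spacing
    else:
        arc_step = float(np.mean(contour.segment_lengths()))

    normals = _inward_normals(contour.vertices, contour.closed)
    offsets = (np.arange(width) - (width - 1) / 2.0) * perpendicular_spacing

    # sample coordinates: (N, W) grids of x and y
    sx = contour.vertices[:, 0][:, None] + offsets[None, :] * normals[:, 0][:, None]
    sy = contour.vertices[:, 1][:, None] + offsets[None, :] * normals[:, 1][:, None]

    rows, cols = image.shape
    bad = (sx < 0) | (sx > cols - 1) | (sy < 0) | (sy > rows - 1)
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"band sample outside image at circumference position {i}, "
            f"offset index {j} (x={sx[i, j]:.1f}, y={sy[i, j]:.1f})")

    values = map_coordinates(image, [sy.ravel(), sx.ravel()], order=1,
                             mode="nearest").reshape(sx.shape)
    return StraightenedCortex(values, arc_length_per_step=arc_step,
                              perpendicular_spacing=perpendicular_spacing,
                              closed=contour.closed)


def save_straightened_tiff(path, straightened: StraightenedCortex) -> None:
    """Write the straightened matrix as 32-bit float TIFF for inspection."""
    import tifffile

    tifffile.imwrite(path, straightened.values.astype(np.float32))
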