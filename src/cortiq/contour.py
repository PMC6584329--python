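"""Embryo contours: ordered polylines outlining the cortex in pixel coordinates.

Coordinates follow the image convention used throughout the package:
``x`` is the column index, ``y`` the row index, both 0-based with pixel
centers at integer coordinates.  A closed contour must be simple and
positively oriented (counter-clockwise in the (x, y) plane, i.e. positive
shoelace area), so that the interior lies to the left of the direction of
travel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class Contour:
    """Ordered polyline outlining the embryo cortex in one frame.

    Parameters
    ----------
    vertices : (N, 2) array of float
        Ordered (x, y) vertex coordinates in pixels.
    closed : bool
        Whether the last vertex connects back to the first.
    frame : int
        Frame index the contour belongs to.
    """

    vertices: np.ndarray
    closed: bool = True
    frame: int = 0

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (N, 2) array of (x, y)")
        if len(self.vertices) < 3:
            raise ValueError("a contour needs at least 3 vertices")

    # -- geometry ---------------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def segment_lengths(self) -> np.ndarray:
        """Lengths of consecutive edges (including the closing edge if closed)."""
        v = self.vertices
        if self.closed:
            d = np.diff(np.vstack([v, v[:1]]), axis=0)
        else:
            d = np.diff(v, axis=0)
        return np.hypot(d[:, 0], d[:, 1])

    def perimeter(self) -> float:
        return float(self.segment_lengths().sum())

    def signed_area(self) -> float:
        """Shoelace area; positive for counter-clockwise orientation."""
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return float(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def is_counterclockwise(self) -> bool:
        return self.signed_area() > 0

    def ensure_counterclockwise(self) -> "Contour":
        """Return a contour with positive orientation, reversing if needed."""
        if self.closed and not self.is_counterclockwise():
            return Contour(self.vertices[::-1].copy(), closed=True, frame=self.frame)
        return self

    def is_simple(self) -> bool:
        """True when the polygon has no self-intersections."""
        try:
            from shapely.geometry import LinearRing, LineString
        except ImportError:  # pragma: no cover - shapely is a hard dep of skimage envs
            return True
        if self.closed:
            return LinearRing(self.vertices).is_simple
        return LineString(self.vertices).is_simple

    def principal_axis_endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        """Endpoints of the contour's long (principal) axis.

        Returns the two vertices extremal along the first principal component
        of the vertex cloud; used for default anterior/posterior pole
        placement.
        """
        v = self.vertices - self.vertices.mean(axis=0)
        _, _, vt = np.linalg.svd(v, full_matrices=False)
        proj = v @ vt[0]
        return (self.vertices[int(np.argmax(proj))].copy(),
                self.vertices[int(np.argmin(proj))].copy())

    def arc_fraction_of_point(self, point: np.ndarray) -> float:
        """Arc-length fraction s in [0, 1) of the vertex nearest to ``point``."""
        d2 = np.sum((self.vertices - np.asarray(point, float)) ** 2, axis=1)
        i = int(np.argmin(d2))
        lengths = self.segment_lengths()
        cum = np.concatenate([[0.0], np.cumsum(lengths)])
        return float(cum[i] / self.perimeter())


def resample_contour(contour: Contour, spacing: float) -> Contour:
    """Resample a contour at equal arc-length steps.

    The returned vertices lie exactly on the input polyline, spaced by
    ``spacing`` pixels of arc length.  For closed contours the vertex count is
    ``round(perimeter / spacing)`` so the final (closing) step may differ
    slightly from ``spacing``; orientation is preserved.

    Raises
    ------
    ValueError
        If ``spacing`` is not positive or the contour has zero perimeter.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    perim = contour.perimeter()
    if perim <= 0:
        raise ValueError("degenerate contour: zero perimeter")

    v = contour.vertices
    if contour.closed:
        pts = np.vstack([v, v[:1]])
    else:
        pts = v
    seg = np.hypot(*np.diff(pts, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]

    if contour.closed:
        n = max(3, int(round(total / spacing)))
        # vertices at exact `spacing` steps; the closing gap absorbs the remainder
        targets = np.arange(n) * spacing
    else:
        n = max(2, int(round(total / spacing)) + 1)
        targets = np.linspace(0.0, total, n)

    x = np.interp(targets, cum, pts[:, 0])
    y = np.interp(targets, cum, pts[:, 1])
    return Contour(np.column_stack([x, y]), closed=contour.closed, frame=contour.frame)


# -- CSV round trip -------------------------------------------------------

_CSV_COLUMNS = ["frame", "vertex_index", "x", "y"]


def write_contours_csv(path, contours: "list[Contour] | Contour") -> None:
    """Write contours to CSV with columns frame, vertex_index, x, y."""
    if isinstance(contours, Contour):
        contours = [contours]
    rows = []
    for c in contours:
        for i, (x, y) in enumerate(c.vertices):
            rows.append((c.frame, i, x, y))
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def read_contours_csv(path, closed: bool = True) -> list[Contour]:
    """Read per-frame contours from a CSV written by :func:`write_contours_csv`."""
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"contour CSV missing columns: {sorted(missing)}")
    out = []
    for frame, grp in df.groupby("frame", sort=True):
        grp = grp.sort_values("vertex_index")
        out.append(Contour(grp[["x", "y"]].to_numpy(float), closed=closed,
                           frame=int(frame)))
    return out
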