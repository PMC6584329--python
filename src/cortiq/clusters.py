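"""Punctate cluster detection and quantification in near-membrane images.

Detection follows the Crocker-Grier scheme: band-pass the image (short-scale
Gaussian smooth minus a boxcar background of roughly the feature diameter),
find local maxima separated by at least the feature diameter, refine centers
by intensity centroid, and keep candidates whose integrated mass clears a
user-set threshold.  Each candidate is then fit with an isotropic 2D
Gaussian point-spread function plus a constant local offset; the cluster's
integrated intensity is the analytic integral of the fitted Gaussian,
``2 * pi * amplitude * sigma**2``, which is robust to the local offset.  The
per-frame statistic is the sum of integrated intensities over all clusters,
normalized to the analyzed area.

The detection threshold has no universal default — it must be set for the
imaging conditions at hand — so ``mass_threshold`` is a required argument
and is echoed into all outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, maximum_filter, uniform_filter
from scipy.optimize import curve_fit

DEFAULT_DIAMETER = 7  # documented starting point; tune per dataset


@dataclass
class ClusterRecord:
    """One detected cluster and its Gaussian PSF fit."""

    x: float
    y: float
    amplitude: float
    sigma: float
    local_offset: float
    integrated_intensity: float  # 2*pi*amplitude*sigma**2 when fit_ok
    fit_ok: bool
    reason: str = ""


@dataclass
class ClusterSummary:
    """Area-normalized total cluster intensity for one frame."""

    n_clusters: int
    total_intensity_per_area: float
    frame: int = 0
    time_min: float = 0.0


def _bandpass(image: np.ndarray, diameter: int, noise_sigma: float = 1.0
              ) -> np.ndarray:
    smooth = gaussian_filter(image.astype(float), noise_sigma)
    background = uniform_filter(image.astype(float), size=2 * diameter + 1)
    return np.clip(smooth - background, 0, None)


def detect_clusters(image: np.ndarray, diameter: int,
                    mass_threshold: float) -> "list[tuple[float, float, float]]":
    """Candidate peaks as (x, y, mass), ordered by (y, x).

    ``diameter`` is the expected feature size in pixels (odd, >= 3);
    ``mass_threshold`` is the minimum integrated band-passed intensity over
    the feature footprint.  Centers are refined to sub-pixel precision by
    the intensity centroid within a ``diameter``-sized footprint.
    """
    if diameter < 3 or diameter % 2 == 0:
        raise ValueError("diameter must be an odd integer >= 3")
    image = np.asarray(image, dtype=float)
    bp = _bandpass(image, diameter)
    radius = diameter // 2

    # local maxima with minimum separation = diameter
    footprint = np.ones((diameter, diameter), dtype=bool)
    is_max = (bp == maximum_filter(bp, footprint=footprint)) & (bp > 0)
    ys, xs = np.nonzero(is_max)

    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    disk = (yy ** 2 + xx ** 2) <= radius ** 2
    rows, cols = image.shape
    candidates = []
    for y0, x0 in zip(ys, xs):
        if not (radius <= y0 < rows - radius and radius <= x0 < cols - radius):
            continue
        patch = bp[y0 - radius:y0 + radius + 1, x0 - radius:x0 + radius + 1] * disk
        mass = float(patch.sum())
        if mass < mass_threshold:
            continue
        cy = float((patch * yy).sum() / mass) + y0
        cx = float((patch * xx).sum() / mass) + x0
        candidates.append((cx, cy, mass))
    candidates.sort(key=lambda c: (c[1], c[0]))
    return candidates


def _gauss2d(coords, amplitude, x0, y0, sigma, offset):
    x, y = coords
    return (offset + amplitude
            * np.exp(-((x - x0) ** 2 + (y - y0) ** 2) / (2 * sigma ** 2))).ravel()


def fit_cluster(image: np.ndarray, peak, fit_halfwidth: int = DEFAULT_DIAMETER
                ) -> ClusterRecord:
    """Isotropic 2D Gaussian + constant offset fit around one candidate peak.

    ``fit_ok`` is False when the window clips the image edge, the optimizer
    fails, sigma leaves (0.5, fit_halfwidth), or the amplitude is
    non-positive; such records carry zero integrated intensity.
    """
    x0, y0 = float(peak[0]), float(peak[1])
    image = np.asarray(image, dtype=float)
    rows, cols = image.shape
    h = int(fit_halfwidth)
    xi, yi = int(round(x0)), int(round(y0))
    if not (h <= xi < cols - h and h <= yi < rows - h):
        return ClusterRecord(x0, y0, 0.0, 0.0, 0.0, 0.0, False,
                             reason="fit window clipped at image edge")
    win = image[yi - h:yi + h + 1, xi - h:xi + h + 1]
    if np.ptp(win) == 0:
        return ClusterRecord(x0, y0, 0.0, 0.0, float(win.flat[0]), 0.0, False,
                             reason="degenerate constant window")
    yy, xx = np.mgrid[yi - h:yi + h + 1, xi - h:xi + h + 1]
    p0 = [max(win.max() - win.min(), 1e-6), x0, y0, 2.0, float(win.min())]
    try:
        popt, _ = curve_fit(_gauss2d, (xx, yy), win.ravel(), p0=p0, maxfev=5000)
    except (RuntimeError, ValueError):
        return ClusterRecord(x0, y0, 0.0, 0.0, 0.0, 0.0, False,
                             reason="optimizer failed")
    amp, cx, cy, sigma, offset = popt
    sigma = abs(float(sigma))
    if amp <= 0:
        return ClusterRecord(cx, cy, float(amp), sigma, float(offset), 0.0,
                             False, reason="non-positive amplitude")
    if not (0.5 < sigma < h):
        return ClusterRecord(cx, cy, float(amp), sigma, float(offset), 0.0,
                             False, reason="sigma outside (0.5, fit_halfwidth)")
    integrated = 2.0 * np.pi * float(amp) * sigma ** 2
    return ClusterRecord(float(cx), float(cy), float(amp), sigma,
                         float(offset), integrated, True)


def summarize_clusters(records: "list[ClusterRecord]", area_pixels: float,
                       frame: int = 0, time_min: float = 0.0) -> ClusterSummary:
    """Sum of integrated intensities over fit_ok clusters, per unit area."""
    if area_pixels <= 0:
        raise ValueError("area_pixels must be positive")
    ok = [r for r in records if r.fit_ok]
    total = sum(r.integrated_intensity for r in ok)
    return ClusterSummary(n_clusters=len(ok),
                          total_intensity_per_area=total / area_pixels,
                          frame=frame, time_min=time_min)


def quantify_cluster_frame(image: np.ndarray, diameter: int,
                           mass_threshold: float, frame: int = 0,
                           time_min: float = 0.0):
    """Detect, fit and summarize clusters in one frame.

    Returns ``(records, summary)``; the analyzed area is the full image.
    """
    peaks = detect_clusters(image, diameter, mass_threshold)
    records = [fit_cluster(image, p, fit_halfwidth=diameter) for p in peaks]
    summary = summarize_clusters(records, float(image.size), frame, time_min)
    return records, summary


def records_to_frame(records: "list[ClusterRecord]", frame: int = 0) -> pd.DataFrame:
    return pd.DataFrame({
        "frame": frame,
        "x": [r.x for r in records],
        "y": [r.y for r in records],
        "amplitude": [r.amplitude for r in records],
        "sigma": [r.sigma for r in records],
        "offset": [r.local_offset for r in records],
        "integrated_intensity": [r.integrated_intensity for r in records],
        "fit_ok": [r.fit_ok for r in records],
    })
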