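"""Synthetic midplane fluorescence images of an ellipsoidal embryo.

The generator renders the three intensity sources the quantification
pipeline must disentangle:

* a thin membrane shell whose fluorophore surface density varies with
  arc-length position around the cell outline (a.u. per pixel of contour),
* a uniform cytoplasmic level inside the cell,
* a uniform extracellular background outside it,

blurs the composite scene once with a Gaussian point-spread function, and
adds mixed Poisson/Gaussian acquisition noise.  Ground truth (the density
actually rendered at each contour position, per frame) is returned
alongside every image so downstream stages can be validated by parameter
recovery.

Conventions: arc-length fraction s = 0 sits on the positive major axis of
the ellipse and increases counter-clockwise; the emitted ground-truth
contour is a 360-vertex polygon at equal arc-length spacing.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.ndimage import gaussian_filter

from .contour import Contour

SUPERSAMPLE = 4  # sub-pixel rendering factor for the thin shell
CONTOUR_VERTICES = 360


@dataclass
class EmbryoGeometry:
    """Ellipse standing in for the midplane outline of the embryo."""

    center: tuple[float, float]  # (x, y) pixels
    semi_axes: tuple[float, float]  # (a, b) pixels, a >= b
    rotation: float = 0.0  # radians, CCW from +x
    membrane_thickness: float = 3.0  # pre-blur shell width, pixels

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        if not (a >= b > 0):
            raise ValueError("semi-axes must satisfy a >= b > 0")
        if self.membrane_thickness <= 0:
            raise ValueError("membrane_thickness must be positive")

    def check_margin(self, image_shape: tuple[int, int], margin: float = 30.0) -> None:
        """Raise if the ellipse comes within ``margin`` pixels of the image edge."""
        rows, cols = image_shape
        cx, cy = self.center
        a = self.semi_axes[0]
        if (cx - a < margin or cx + a > cols - 1 - margin
                or cy - a < margin or cy + a > rows - 1 - margin):
            raise ValueError("band would exit image: ellipse too close to the border")


@dataclass
class SyntheticGroundTruth:
    """Scene parameters for one rendered frame.

    ``membrane_density`` maps arc-length fraction s in [0, 1) to fluorophore
    surface density in a.u. per pixel of contour length.
    """

    membrane_density: Callable[[np.ndarray], np.ndarray]
    cytoplasm_level: float = 100.0
    background_level: float = 10.0
    psf_sigma: float = 1.2
    # Out-of-focus glow from the cell volume: a midplane image of a thick
    # cell collects defocused light from the cytoplasm above and below the
    # focal plane, so the edge of the cytoplasmic signal has long soft
    # shoulders rather than a pure in-focus edge-spread.  The volume
    # (cytoplasm + background) composite is therefore blurred with a
    # core + halo mixture, while the thin equatorial membrane shell — which
    # contributes essentially no defocused light at the midplane — is
    # blurred with the in-focus core PSF only.  These shoulders are what
    # real cytoplasmic reference profiles show, and what the
    # reference-fitting step uses to register the cytoplasm edge
    # independently of the narrow membrane peak.
    psf_halo_sigma: float = 6.0
    psf_halo_fraction: float = 0.25
    gaussian_sd: float = 2.0
    poisson_gain: float = 0.5  # a.u. per photon; 0 disables shot noise
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cytoplasm_level", "background_level", "gaussian_sd",
                     "poisson_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.psf_sigma <= 0 or self.psf_halo_sigma <= 0:
            raise ValueError("PSF widths must be positive")
        if not (0 <= self.psf_halo_fraction < 1):
            raise ValueError("psf_halo_fraction must lie in [0, 1)")


# -- ellipse parametrization ----------------------------------------------

def _ellipse_points(geom: EmbryoGeometry, s: np.ndarray) -> np.ndarray:
    """(x, y) points at arc-length fractions ``s`` (s=0 on +major axis, CCW)."""
    a, b = geom.semi_axes
    # dense parameter grid -> cumulative arc length -> invert
    t = np.linspace(0.0, 2 * np.pi, 4096, endpoint=False)
    x, y = a * np.cos(t), b * np.sin(t)
    dx, dy = np.diff(np.append(x, x[0])), np.diff(np.append(y, y[0]))
    seg = np.hypot(dx, dy)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    t_ext = np.append(t, 2 * np.pi)
    t_of_s = np.interp(np.asarray(s, float) % 1.0 * total, cum, t_ext)
    xe, ye = a * np.cos(t_of_s), b * np.sin(t_of_s)
    c, sn = np.cos(geom.rotation), np.sin(geom.rotation)
    cx, cy = geom.center
    return np.column_stack([cx + c * xe - sn * ye, cy + sn * xe + c * ye])


def ellipse_perimeter(geom: EmbryoGeometry) -> float:
    a, b = geom.semi_axes
    t = np.linspace(0.0, 2 * np.pi, 4096, endpoint=False)
    x, y = a * np.cos(t), b * np.sin(t)
    dx, dy = np.diff(np.append(x, x[0])), np.diff(np.append(y, y[0]))
    return float(np.hypot(dx, dy).sum())


def ground_truth_contour(geom: EmbryoGeometry, frame: int = 0,
                         n_vertices: int = CONTOUR_VERTICES) -> Contour:
    """Equal-arc-length polygon on the ellipse, counter-clockwise, s=0 at +major axis."""
    s = np.arange(n_vertices) / n_vertices
    return Contour(_ellipse_points(geom, s), closed=True, frame=frame)


# -- rendering ------------------------------------------------------------

def _render_scene(geom: EmbryoGeometry, truth: SyntheticGroundTruth,
                  image_shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Noise-free blurred scene plus the arc-length grid and density rendered on it."""
    rows, cols = image_shape
    ss = SUPERSAMPLE

    # interior mask on the supersampled grid (pixel centers of fine pixels)
    fy, fx = np.meshgrid(np.arange(rows * ss) / ss - 0.5 + 0.5 / ss,
                         np.arange(cols * ss) / ss - 0.5 + 0.5 / ss,
                         indexing="ij")
    c, sn = np.cos(geom.rotation), np.sin(geom.rotation)
    cx, cy = geom.center
    u = (fx - cx) * c + (fy - cy) * sn
    v = -(fx - cx) * sn + (fy - cy) * c
    a, b = geom.semi_axes
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    scene = np.where(inside, truth.cytoplasm_level, truth.background_level).astype(float)

    # membrane shell: deposit density along fine arc samples, spread over the
    # shell thickness along the outward/inward normal, bilinear sub-pixel drop
    perim = ellipse_perimeter(geom)
    ds = 0.5 / ss  # arc step, fine-grid pixels
    n_arc = int(np.ceil(perim / ds))
    s_grid = np.arange(n_arc) / n_arc
    pts = _ellipse_points(geom, s_grid)
    dens = np.asarray(truth.membrane_density(s_grid), dtype=float)
    if dens.shape != s_grid.shape:
        raise ValueError("membrane_density must return one value per input s")
    if np.any(dens < 0):
        raise ValueError("membrane_density must be non-negative")

    shell = np.zeros_like(scene)
    if np.any(dens > 0):
        # normals from the analytic tangent of the arc-length parametrization
        tang = np.gradient(pts, axis=0)
        tang /= np.linalg.norm(tang, axis=1, keepdims=True)
        normal = np.column_stack([-tang[:, 1], tang[:, 0]])  # inward for CCW

        half = geom.membrane_thickness / 2.0
        n_off = max(3, int(np.ceil(geom.membrane_thickness * ss * 2)))
        offsets = np.linspace(-half, half, n_off)
        arc_mass = dens * (perim / n_arc) / n_off  # a.u. per deposited point

        px = (pts[:, 0][:, None] + offsets[None, :] * normal[:, 0][:, None]).ravel()
        py = (pts[:, 1][:, None] + offsets[None, :] * normal[:, 1][:, None]).ravel()
        mass = np.repeat(arc_mass, n_off)

        # bilinear deposition onto the fine grid (fine-pixel units)
        gx = (px + 0.5 - 0.5 / ss) * ss
        gy = (py + 0.5 - 0.5 / ss) * ss
        x0 = np.floor(gx).astype(int)
        y0 = np.floor(gy).astype(int)
        wx = gx - x0
        wy = gy - y0
        H, W = shell.shape
        for ddy, ddx, w in ((0, 0, (1 - wy) * (1 - wx)), (0, 1, (1 - wy) * wx),
                            (1, 0, wy * (1 - wx)), (1, 1, wy * wx)):
            yy, xx = y0 + ddy, x0 + ddx
            ok = (yy >= 0) & (yy < H) & (xx >= 0) & (xx < W)
            np.add.at(shell, (yy[ok], xx[ok]), mass[ok] * w[ok])
        # deposited mass is a.u. per fine pixel; convert to a.u. per native px area
        shell *= ss * ss

    # downsample to native resolution by block averaging, then blur:
    # volume fluorescence (cytoplasm + background) gets the core + halo
    # mixture, the thin in-plane shell the core PSF only
    native_volume = scene.reshape(rows, ss, cols, ss).mean(axis=(1, 3))
    native_shell = shell.reshape(rows, ss, cols, ss).mean(axis=(1, 3))
    blurred = gaussian_filter(native_volume, truth.psf_sigma, mode="nearest")
    if truth.psf_halo_fraction > 0:
        halo = gaussian_filter(native_volume, truth.psf_halo_sigma, mode="nearest")
        blurred = (1 - truth.psf_halo_fraction) * blurred \
            + truth.psf_halo_fraction * halo
    blurred = blurred + gaussian_filter(native_shell, truth.psf_sigma,
                                        mode="nearest")
    return blurred, s_grid, dens


def _add_noise(image: np.ndarray, truth: SyntheticGroundTruth,
               rng: np.random.Generator) -> np.ndarray:
    out = image
    if truth.poisson_gain > 0:
        out = rng.poisson(np.clip(out, 0, None) / truth.poisson_gain) * truth.poisson_gain
    if truth.gaussian_sd > 0:
        out = out + rng.normal(0.0, truth.gaussian_sd, size=image.shape)
    return out.astype(float)


def generate_frame(geometry: EmbryoGeometry, truth: SyntheticGroundTruth,
                   image_shape: tuple[int, int] = (512, 512),
                   rng: np.random.Generator | None = None,
                   frame: int = 0) -> tuple[np.ndarray, Contour, dict]:
    """Render one synthetic midplane frame.

    Returns
    -------
    image : (rows, cols) float array
        Blurred scene plus noise.
    contour : Contour
        Exact ground-truth ellipse polygon (360 vertices, equal arc length,
        counter-clockwise).
    truth_record : dict
        ``s`` (arc-length grid actually rendered), ``membrane_density`` on
        that grid, and the scalar scene parameters.
    """
    geometry.check_margin(image_shape)
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    clean, s_grid, dens = _render_scene(geometry, truth, image_shape)
    image = _add_noise(clean, truth, rng)
    record = {
        "s": s_grid,
        "membrane_density": dens,
        "cytoplasm_level": truth.cytoplasm_level,
        "background_level": truth.background_level,
        "psf_sigma": truth.psf_sigma,
        "perimeter": ellipse_perimeter(geometry),
    }
    return image, ground_truth_contour(geometry, frame=frame), record


# -- kinetic templates ----------------------------------------------------

TEMPLATE_NAMES = ("uniform", "refractory", "accumulation", "transient_dip",
                  "polarized_domain")


@dataclass
class KineticTemplate:
    """Temporal/spatial program of membrane density for a synthetic movie.

    Templates emulate the qualitative stages of the cortical polarity
    program: a refractory period with no membrane loading, uniform
    accumulation, a transient dip, and a polarized domain occupying part of
    the circumference.

    Parameters (minutes / a.u. / arc-length fractions), with defaults:

    * ``level``: plateau density (all templates).
    * ``onset``, ``offset``: rise window for ``refractory``/``accumulation``.
    * ``dip_time``, ``dip_width``, ``dip_level``: for ``transient_dip``.
    * ``domain_center``, ``domain_width``: for ``polarized_domain``.
    """

    name: str
    parameters: dict = field(default_factory=dict)

    _DEFAULTS = {
        "level": 200.0, "onset": 10.0, "offset": 25.0,
        "dip_time": 20.0, "dip_width": 8.0, "dip_level": 0.35,
        "domain_center": 0.5, "domain_width": 0.5,
    }

    def __post_init__(self) -> None:
        if self.name not in TEMPLATE_NAMES:
            raise ValueError(
                f"unknown template {self.name!r}; choose from {TEMPLATE_NAMES}")
        p = dict(self._DEFAULTS)
        p.update(self.parameters)
        unknown = set(self.parameters) - set(self._DEFAULTS)
        if unknown:
            raise ValueError(f"unknown template parameters: {sorted(unknown)}")
        if p["offset"] < p["onset"]:
            raise ValueError("offset time must be >= onset time")
        if not (0 < p["domain_width"] <= 1):
            raise ValueError("domain_width must be in (0, 1]")
        self.parameters = p

    def temporal_level(self, t_min: float) -> float:
        """Spatial-mean plateau level at time ``t_min`` (minutes)."""
        p = self.parameters
        L = p["level"]
        if self.name in ("uniform", "polarized_domain"):
            return L
        if self.name in ("refractory", "accumulation"):
            if t_min <= p["onset"]:
                return 0.0
            if t_min >= p["offset"]:
                return L
            return L * (t_min - p["onset"]) / (p["offset"] - p["onset"])
        if self.name == "transient_dip":
            dip = (1.0 - p["dip_level"]) * np.exp(
                -0.5 * ((t_min - p["dip_time"]) / (p["dip_width"] / 2.355)) ** 2)
            return L * (1.0 - dip)
        raise AssertionError(self.name)

    def density_fn(self, t_min: float) -> Callable[[np.ndarray], np.ndarray]:
        """Arc-length density function for the frame at ``t_min``."""
        level = self.temporal_level(t_min)
        p = self.parameters
        if self.name == "polarized_domain":
            c, w = p["domain_center"], p["domain_width"]

            def fn(s: np.ndarray) -> np.ndarray:
                d = np.abs((np.asarray(s, float) - c + 0.5) % 1.0 - 0.5)
                return np.where(d <= w / 2, level, 0.0)
            return fn
        return lambda s: np.full_like(np.asarray(s, float), level)


def generate_timecourse(geometry: EmbryoGeometry, template: KineticTemplate,
                        truth: SyntheticGroundTruth, n_frames: int,
                        frame_interval_min: float = 1.5,
                        image_shape: tuple[int, int] = (512, 512)):
    """Render a synthetic movie following a kinetic template.

    Returns ``(stack, contours, truth_series)`` where ``stack`` is
    (n_frames, rows, cols), ``contours`` one ground-truth polygon per frame
    and ``truth_series`` a list of per-frame truth records (each with the
    frame time in minutes attached).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(truth.seed)
    frames, contours, series = [], [], []
    for f in range(n_frames):
        t_min = f * frame_interval_min
        frame_truth = SyntheticGroundTruth(
            membrane_density=template.density_fn(t_min),
            cytoplasm_level=truth.cytoplasm_level,
            background_level=truth.background_level,
            psf_sigma=truth.psf_sigma,
            gaussian_sd=truth.gaussian_sd,
            poisson_gain=truth.poisson_gain,
            seed=truth.seed,
        )
        image, contour, record = generate_frame(
            geometry, frame_truth, image_shape, rng=rng, frame=f)
        record["time_min"] = t_min
        record["mean_density"] = float(np.mean(record["membrane_density"]))
        frames.append(image)
        contours.append(contour)
        series.append(record)
    return np.stack(frames), contours, series


# -- cluster fields -------------------------------------------------------

def generate_cluster_field(image_shape: tuple[int, int],
                           spots: "list[tuple[float, float, float, float]]",
                           background: float = 10.0,
                           noise_sd: float = 0.0,
                           seed: int = 0):
    """Render a field of isotropic 2D Gaussian spots on a flat background.

    ``spots`` is a list of (x, y, amplitude, sigma).  Returns ``(image,
    truth)`` where truth records per spot the analytic integrated intensity
    ``2*pi*amplitude*sigma**2`` and flags pairs closer than twice the sum of
    their sigmas as overlapping.
    """
    rows, cols = image_shape
    img = np.full((rows, cols), float(background))
    yy, xx = np.mgrid[0:rows, 0:cols]
    records = []
    for (x, y, amp, sig) in spots:
        if sig <= 0 or amp < 0:
            raise ValueError("spot sigma must be > 0 and amplitude >= 0")
        if not (3 * sig <= x <= cols - 1 - 3 * sig
                and 3 * sig <= y <= rows - 1 - 3 * sig):
            raise ValueError(f"spot at ({x}, {y}) closer than 3*sigma to the edge")
        img += amp * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * sig ** 2))
        records.append({"x": x, "y": y, "amplitude": amp, "sigma": sig,
                        "integrated_intensity": 2 * np.pi * amp * sig ** 2,
                        "overlapping": False})
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            sep = np.hypot(records[i]["x"] - records[j]["x"],
                           records[i]["y"] - records[j]["y"])
            if sep < 2 * (records[i]["sigma"] + records[j]["sigma"]):
                records[i]["overlapping"] = records[j]["overlapping"] = True
    if noise_sd > 0:
        img = img + np.random.default_rng(seed).normal(0, noise_sd, img.shape)
    truth = {"spots": records,
             "total_intensity": float(sum(r["integrated_intensity"] for r in records)),
             "background": background, "noise_sd": noise_sd}
    return img, truth


# -- TIFF / JSON export ---------------------------------------------------

def save_stack_tiff(path, stack: np.ndarray) -> None:
    """Write a movie as multi-page 16-bit TIFF, warning when clipping saturates."""
    import tifffile

    if stack.ndim == 2:
        stack = stack[None]
    if stack.max() > 65535 or stack.min() < 0:
        warnings.warn("intensity values clipped to the 16-bit range on save")
    tifffile.imwrite(path, np.clip(np.round(stack), 0, 65535).astype(np.uint16),
                     photometric="minisblack")


def save_truth_json(path, series) -> None:
    def convert(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))
    with open(path, "w") as fh:
        json.dump(series, fh, default=convert, indent=1)
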