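"""Cortical fluorescence quantification from straightened cortex matrices.

The measurement problem: a perpendicular intensity profile across the cell
edge mixes three sources — extracellular background, cytoplasmic
fluorescence (a smoothed step rising from outside to inside), and the
membrane-localized signal of interest (a near-Gaussian bump sitting on the
step).  The pipeline refines profiles (rolling average along the cortex,
Savitzky-Golay across it), registers them by the maximum slope of the
rising edge, fits and subtracts a scaled/shifted cytoplasmic reference
profile, and integrates the residual bump to give total cortical
fluorescence per position or per time point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import savgol_filter

from .straighten import StraightenedCortex, straighten_cortex

DEFAULT_ROLLING_WINDOW = 50
DEFAULT_SG_WINDOW = 11
DEFAULT_SG_ORDER = 3
DEFAULT_SHIFT_RANGE = 5.0  # px, reference alignment search
# The fit window must exclude the full smoothed support of the membrane
# peak, including the side lobes the SG filter spreads out to half a window
# beyond it (~2.5 sigma of the blurred peak + (sg_window-1)/2 samples);
# leakage into the window biases the fitted shift in proportion to the
# cortical signal.  11 samples covers the defaults with margin.
DEFAULT_EXCLUSION_HALFWIDTH = 11
DEFAULT_INTEGRATION_HALFWIDTH = 10  # samples integrated around band center
PLATEAU_SAMPLES = 10  # innermost samples defining the cytoplasmic plateau


# -- profile containers ---------------------------------------------------

@dataclass
class ReferenceProfile:
    """Normalized cytoplasmic perpendicular profile.

    Aligned so its maximum slope sits at the band center, and scaled so the
    cytoplasmic plateau (mean of the innermost ``PLATEAU_SAMPLES`` samples)
    equals 1.  Captures every fluorescence source except bona fide cortical
    signal, so scaling/shifting it onto a cortical profile and subtracting
    isolates the membrane component.
    """

    intensities: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        plateau = self.intensities[-PLATEAU_SAMPLES:].mean()
        if not np.isclose(plateau, 1.0, atol=1e-6):
            raise ValueError(
                f"reference plateau must equal 1 (got {plateau:.6g}); "
                "use derive_reference_profile to construct one")
        self._shift_cache: dict[float, np.ndarray] = {}

    def __len__(self) -> int:
        return len(self.intensities)

    def shifted(self, shift: float) -> np.ndarray:
        """Reference resampled at a sub-pixel shift (cached per shift)."""
        key = round(float(shift), 6)
        if key not in self._shift_cache:
            self._shift_cache[key] = _shift_profile(self.intensities, key)
        return self._shift_cache[key]


@dataclass
class ReferenceFit:
    """Result of fitting the cytoplasmic reference to one cortical profile."""

    scale: float  # reference magnitude (>= 0)
    shift: float  # reference alignment, pixels
    residual: np.ndarray  # profile - scale * shifted(reference), full band
    sse: float  # sum of squared errors over the fit window
    sample_spacing: float = 1.0


@dataclass
class CorticalTrace:
    """Normalized cortical fluorescence versus time for one movie."""

    times: np.ndarray  # minutes (relative to ovulation when timing given)
    values: np.ndarray  # dimensionless, normalized
    raw_integrals: np.ndarray  # a.u. * pixel, before normalization
    normalization_reference: float
    normalization_provenance: str = ""
    scales: np.ndarray | None = None
    shifts: np.ndarray | None = None
    flags: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "frame": np.arange(len(self.values)),
            "time_min": self.times,
            "raw_integral": self.raw_integrals,
            "normalized_value": self.values,
        })
        if self.scales is not None:
            df["scale"] = self.scales
        if self.shifts is not None:
            df["shift"] = self.shifts
        df["flags"] = [";".join(f) if f else "" for f in self.flags] \
            if self.flags else ""
        return df


# -- smoothing ------------------------------------------------------------

def rolling_average_along_cortex(straightened: StraightenedCortex,
                                 window: int = DEFAULT_ROLLING_WINDOW
                                 ) -> StraightenedCortex:
    """Rolling average over circumference positions (rows).

    Row ``i`` becomes the mean over rows ``i - floor(w/2) .. i + ceil(w/2) - 1``,
    wrapping circularly for closed contours and reflecting at the ends of
    open arcs.  The perpendicular dimension is untouched.
    """
    n = straightened.n_positions
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > n:
        if not straightened.closed:
            raise ValueError(f"window {window} exceeds the {n} rows of an open arc")
        window = min(window, n)
    if window == 1:
        return straightened.copy_with(straightened.values.copy())
    mode = "wrap" if straightened.closed else "reflect"
    out = uniform_filter1d(straightened.values, size=window, axis=0, mode=mode)
    return straightened.copy_with(out)


def smooth_profile(profile: np.ndarray, sg_window: int = DEFAULT_SG_WINDOW,
                   sg_order: int = DEFAULT_SG_ORDER) -> np.ndarray:
    """Savitzky-Golay smoothing of perpendicular profiles.

    Accepts a single profile (1D, ordered exterior -> interior) or a
    straightened matrix (2D; smoothing runs across the perpendicular axis,
    i.e. along each row).  Edge windows are handled by the filter's
    polynomial extrapolation.
    """
    arr = np.asarray(profile, dtype=float)
    if sg_window % 2 == 0 or sg_window <= sg_order:
        raise ValueError("sg_window must be odd and greater than sg_order")
    if arr.shape[-1] < sg_window:
        raise ValueError("profile shorter than the smoothing window")
    return savgol_filter(arr, sg_window, sg_order, axis=-1, mode="interp")


def smooth_straightened(straightened: StraightenedCortex,
                        sg_window: int = DEFAULT_SG_WINDOW,
                        sg_order: int = DEFAULT_SG_ORDER) -> StraightenedCortex:
    """SG-smooth every perpendicular profile of a straightened matrix."""
    return straightened.copy_with(
        smooth_profile(straightened.values, sg_window, sg_order))


# -- alignment ------------------------------------------------------------

def _shift_profile(profile: np.ndarray, shift: float) -> np.ndarray:
    """Resample ``profile`` shifted by ``shift`` samples (positive moves the
    profile toward the interior); out-of-band samples take the edge value."""
    j = np.arange(len(profile), dtype=float) - shift
    return np.interp(j, np.arange(len(profile)), profile)


def max_slope_position(profile: np.ndarray) -> float:
    """Sub-pixel position of the maximum forward difference.

    The discrete argmax of the first difference is refined by a quadratic
    fit through the three differences around it; differences live at
    half-integer offsets j + 1/2.
    """
    d = np.diff(np.asarray(profile, dtype=float))
    k = int(np.argmax(d))
    pos = k + 0.5
    if 0 < k < len(d) - 1:
        denom = d[k - 1] - 2 * d[k] + d[k + 1]
        if denom < 0:
            pos += 0.5 * (d[k - 1] - d[k + 1]) / denom
    return float(pos)


def align_to_max_slope(profiles: np.ndarray, target_offset: float | None = None,
                       flat_tolerance: float = 1e-12):
    """Register profiles so their maximum rising slope sits at the band center.

    Parameters
    ----------
    profiles : (W,) or (N, W) array
        Smoothed perpendicular profiles, exterior -> interior.
    target_offset : float, optional
        Column where the max slope should land; defaults to the band
        center (W-1)/2.

    Returns
    -------
    aligned : array, same shape
    shifts : float or (N,) array
        Shift applied to each profile, in samples (positive = profile moved
        toward the interior).
    flags : list of str per profile; "flat" marks profiles without a
        detectable rising edge, which pass through unshifted.
    """
    arr = np.atleast_2d(np.asarray(profiles, dtype=float))
    W = arr.shape[1]
    target = (W - 1) / 2.0 if target_offset is None else float(target_offset)

    aligned = np.empty_like(arr)
    shifts = np.zeros(arr.shape[0])
    flags: list[str] = []
    for i, p in enumerate(arr):
        d = np.diff(p)
        if d.max() <= flat_tolerance:
            aligned[i] = p
            flags.append("flat")
            continue
        pos = max_slope_position(p)
        shift = target - pos
        aligned[i] = _shift_profile(p, shift)
        shifts[i] = shift
        flags.append("")
    if np.asarray(profiles).ndim == 1:
        return aligned[0], float(shifts[0]), flags
    return aligned, shifts, flags


# -- cytoplasmic reference ------------------------------------------------

def derive_reference_profile(cytoplasmic_profiles: np.ndarray,
                             provenance: str = "") -> ReferenceProfile:
    """Collapse cytoplasmic profiles into one normalized reference.

    Each profile is aligned to its maximum slope, divided by its cytoplasmic
    plateau (mean of the innermost ``PLATEAU_SAMPLES`` samples), and the
    pointwise mean is renormalized so the plateau equals exactly 1.  The
    shape of cytoplasmic profiles is insensitive to absolute signal, which
    is what makes this collapse meaningful.
    """
    arr = np.atleast_2d(np.asarray(cytoplasmic_profiles, dtype=float))
    if arr.shape[0] < 1:
        raise ValueError("need at least one cytoplasmic profile")
    aligned, _, flags = align_to_max_slope(arr)
    if all(f == "flat" for f in flags):
        raise ValueError("no cytoplasmic profile has a detectable rising edge")
    plateaus = aligned[:, -PLATEAU_SAMPLES:].mean(axis=1)
    if np.any(plateaus <= 0):
        raise ValueError("cytoplasmic plateau must be positive")
    mean = (aligned / plateaus[:, None]).mean(axis=0)
    mean = mean / mean[-PLATEAU_SAMPLES:].mean()
    return ReferenceProfile(mean, provenance=provenance)


def fit_and_subtract_reference(profile: np.ndarray, reference: ReferenceProfile,
                               shift_range: float = DEFAULT_SHIFT_RANGE,
                               exclusion_halfwidth: float = DEFAULT_EXCLUSION_HALFWIDTH,
                               sample_spacing: float = 1.0,
                               fixed_shift: float | None = None) -> ReferenceFit:
    """Fit the reference's magnitude and alignment to a profile, subtract it.

    The scale is the closed-form non-negative least-squares solution on a
    fit window that excludes ``band_center +/- exclusion_halfwidth`` samples,
    so the membrane bump cannot bias the cytoplasm estimate.  The shift is
    searched on a 0.1-px grid over ``+/- shift_range`` with quadratic
    refinement around the grid minimum; pass ``fixed_shift`` to skip the
    search and fit the scale at a known registration (e.g. one shared by
    all frames of a movie).
    """
    p = np.asarray(profile, dtype=float)
    r = reference.intensities
    if len(p) != len(r):
        raise ValueError("profile and reference must have the same length")
    W = len(p)
    center = (W - 1) / 2.0
    window = np.abs(np.arange(W) - center) > exclusion_halfwidth
    if not np.any(window):
        raise ValueError("exclusion window leaves no samples to fit")

    def scale_and_sse(s: float) -> tuple[float, float]:
        rs = reference.shifted(s)
        rw, pw = rs[window], p[window]
        denom = float(rw @ rw)
        if denom == 0:
            raise ValueError("reference is zero everywhere in the fit window")
        a = max(0.0, float(pw @ rw) / denom)
        resid = pw - a * rw
        return a, float(resid @ resid)

    if fixed_shift is not None:
        s_best = float(fixed_shift)
    else:
        grid = np.arange(-shift_range, shift_range + 1e-9, 0.1)
        sses = np.array([scale_and_sse(s)[1] for s in grid])
        k = int(np.argmin(sses))
        s_best = grid[k]
        if 0 < k < len(grid) - 1:
            denom = sses[k - 1] - 2 * sses[k] + sses[k + 1]
            if denom > 0:
                s_ref = grid[k] + 0.05 * (sses[k - 1] - sses[k + 1]) / denom
                # keep the refinement only if it actually improves the fit
                if scale_and_sse(s_ref)[1] <= sses[k]:
                    s_best = s_ref
    a_best, sse = scale_and_sse(s_best)
    residual = p - a_best * reference.shifted(s_best)
    return ReferenceFit(scale=a_best, shift=float(s_best), residual=residual,
                        sse=sse, sample_spacing=sample_spacing)


def integrate_cortical_signal(fit: ReferenceFit,
                              integration_halfwidth: float = DEFAULT_INTEGRATION_HALFWIDTH
                              ) -> float:
    """Integrate the residual near-Gaussian bump around the band center.

    Sums ``residual[j] * sample_spacing`` over offsets within
    ``integration_halfwidth`` samples of the band center.  Negative residual
    values are kept: under a zero-signal null the integral then averages to
    zero instead of being positively biased.
    """
    W = len(fit.residual)
    center = (W - 1) / 2.0
    if integration_halfwidth > center:
        raise ValueError("integration window exceeds the band")
    sel = np.abs(np.arange(W) - center) <= integration_halfwidth
    return float(fit.residual[sel].sum() * fit.sample_spacing)


def normalize_trace(values: np.ndarray, maintenance_measurement: float) -> np.ndarray:
    """Express raw integrals relative to the maintenance-phase cortical signal."""
    if maintenance_measurement <= 0:
        raise ValueError("maintenance measurement must be positive")
    return np.asarray(values, dtype=float) / maintenance_measurement


# -- per-movie driver -----------------------------------------------------

def quantify_frame(image: np.ndarray, contour, reference: ReferenceProfile,
                   band_width: int = 50, rolling_window: int = DEFAULT_ROLLING_WINDOW,
                   sg_window: int = DEFAULT_SG_WINDOW, sg_order: int = DEFAULT_SG_ORDER,
                   shift_range: float = DEFAULT_SHIFT_RANGE,
                   exclusion_halfwidth: float = DEFAULT_EXCLUSION_HALFWIDTH,
                   integration_halfwidth: float = DEFAULT_INTEGRATION_HALFWIDTH,
                   fixed_shift: float | None = None):
    """Whole-cortex cortical fluorescence of one frame.

    straighten -> rolling average -> SG smooth -> average all circumference
    positions into one mean perpendicular profile -> fit/subtract the
    cytoplasmic reference (the fit's shift search registers the profile to
    the reference) -> integrate.

    On profiles that carry membrane signal, the maximum slope sits on the
    rising flank of the membrane peak itself, so registering by max slope
    would displace the cytoplasm edge by an amount that grows with the
    cortical signal and the subtraction would then cancel part of it.  The
    reference fit's shift search is the peak-robust registration instead:
    its fit window excludes the peak but sees the soft shoulders of the
    cytoplasmic edge.

    Returns ``(raw_integral, fit, flags)``.
    """
    st = straighten_cortex(image, contour, width=band_width)
    st = rolling_average_along_cortex(st, rolling_window)
    st = smooth_straightened(st, sg_window, sg_order)
    mean_profile = st.values.mean(axis=0)
    flags: list[str] = []
    fit = fit_and_subtract_reference(
        mean_profile, reference, shift_range=shift_range,
        exclusion_halfwidth=exclusion_halfwidth,
        sample_spacing=st.perpendicular_spacing, fixed_shift=fixed_shift)
    value = integrate_cortical_signal(fit, integration_halfwidth)
    return value, fit, flags


def quantify_timecourse(stack: np.ndarray, contours, reference: ReferenceProfile,
                        maintenance_measurement: float | None = None,
                        times_min: np.ndarray | None = None,
                        shared_shift: bool = True,
                        **frame_kwargs) -> CorticalTrace:
    """Cortical fluorescence trace for a movie.

    Parameters
    ----------
    stack : (T, rows, cols) array
    contours : sequence of Contour, one per frame
    reference : ReferenceProfile
    maintenance_measurement : float, optional
        Normalization reference: the cortical signal of the protein within
        its domain at maintenance phase, measured through the same
        integration pathway on user-designated frames.  Defaults to the
        mean raw integral of the final 3 frames.
    times_min : array, optional
        Frame times in minutes; defaults to the frame index.
    shared_shift : bool
        The registration offset between band and reference is one physical
        quantity per movie (it reflects the contour convention, not the
        frame), while per-frame shift estimates carry noise that couples
        into the integral through the edge profile.  When True (default),
        per-frame shifts are estimated in a first pass, their median is
        taken as the movie's registration, and every frame is refit with
        that shift held fixed.

    Per-frame failures are recorded in ``flags`` and the frame's value is
    NaN; the run continues.
    """
    if len(contours) != len(stack):
        raise ValueError("need exactly one contour per frame")
    raw = np.full(len(stack), np.nan)
    scales = np.full(len(stack), np.nan)
    shifts = np.full(len(stack), np.nan)
    flags: list[list[str]] = []

    def run_pass(fixed: float | None):
        for f, (img, contour) in enumerate(zip(stack, contours)):
            try:
                value, fit, frame_flags = quantify_frame(
                    img, contour, reference, fixed_shift=fixed, **frame_kwargs)
                raw[f] = value
                scales[f] = fit.scale
                shifts[f] = fit.shift
                if len(flags) <= f:
                    flags.append(frame_flags)
            except ValueError as exc:
                if len(flags) <= f:
                    flags.append([f"failed: {exc}"])

    run_pass(None)
    if shared_shift and np.any(np.isfinite(shifts)):
        run_pass(float(np.nanmedian(shifts)))
    if maintenance_measurement is None:
        tail = raw[-3:][np.isfinite(raw[-3:])]
        if len(tail) == 0 or tail.mean() <= 0:
            raise ValueError("cannot derive maintenance normalization from the "
                             "final frames; pass maintenance_measurement")
        maintenance_measurement = float(tail.mean())
        provenance = "mean raw integral of final 3 frames"
    else:
        provenance = "user-supplied maintenance measurement"
    values = normalize_trace(np.where(np.isfinite(raw), raw, np.nan),
                             maintenance_measurement)
    times = np.arange(len(stack), dtype=float) if times_min is None \
        else np.asarray(times_min, dtype=float)
    return CorticalTrace(times=times, values=values, raw_integrals=raw,
                         normalization_reference=maintenance_measurement,
                         normalization_provenance=provenance,
                         scales=scales, shifts=shifts, flags=flags)


# -- reference CSV round trip --------------------------------------------

def write_reference_csv(path, reference: ReferenceProfile) -> None:
    W = len(reference)
    offsets = np.arange(W) - (W - 1) / 2.0
    pd.DataFrame({"offset_px": offsets,
                  "normalized_intensity": reference.intensities}
                 ).to_csv(path, index=False)


def read_reference_csv(path) -> ReferenceProfile:
    df = pd.read_csv(path)
    return ReferenceProfile(df["normalized_intensity"].to_numpy(float),
                            provenance=str(path))
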