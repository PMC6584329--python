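"""Run orchestration: wire the pipeline stages per a RunConfig and write
all outputs plus a machine-readable manifest."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import tifffile

from . import __version__
from .config import RunConfig
from .contour import read_contours_csv
from .polarity import (asi_series_to_frame, circumferential_profile,
                       compute_asi, normalize_asi)
from .quantify import (derive_reference_profile, quantify_timecourse,
                       read_reference_csv, rolling_average_along_cortex,
                       smooth_straightened, write_reference_csv)
from .straighten import straighten_cortex
from .timing import ensure_ovulation, read_events_csv, to_relative_times

log = logging.getLogger("cortiq")


def _load_inputs(config: RunConfig):
    if config.image_path is None or config.contour_path is None:
        raise ValueError("run requires image_path and contour_path")
    stack = tifffile.imread(config.image_path).astype(float)
    if stack.ndim == 2:
        stack = stack[None]
    contours = read_contours_csv(config.contour_path)
    if len(contours) != len(stack):
        raise ValueError(f"{len(contours)} contours for {len(stack)} frames")
    return stack, contours


def _times(config: RunConfig, n_frames: int):
    if config.events_path is None:
        return np.arange(n_frames) * config.frame_interval_min, None
    timeline = read_events_csv(config.events_path, config.frame_interval_min)
    timeline = ensure_ovulation(timeline, config.ovulation_sb_interval_min)
    return to_relative_times(timeline, np.arange(n_frames)), timeline


def _reference(config: RunConfig, stack, contours):
    if config.reference_path is not None:
        return read_reference_csv(config.reference_path)
    # derive from the first frame's whole-cortex mean profile: valid only
    # for cytoplasmic-marker movies; a warning makes the assumption loud
    log.warning("no reference profile given; deriving one from frame 0 "
                "(assumes a cytoplasm-only channel)")
    st = straighten_cortex(stack[0], contours[0], width=config.band_width,
                           perpendicular_spacing=config.perpendicular_spacing,
                           resample_spacing=config.resample_spacing)
    st = rolling_average_along_cortex(st, config.rolling_window)
    st = smooth_straightened(st, config.sg_window, config.sg_order)
    return derive_reference_profile(st.values.mean(axis=0)[None, :],
                                    provenance="derived from frame 0")


def run_pipeline(config: RunConfig, stages=("quantify",)) -> dict:
    """Execute the configured stages and write CSV outputs plus a manifest.

    Returns a result bundle: {"trace": DataFrame, "asi": DataFrame,
    "manifest": dict} with keys present per requested stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stack, contours = _load_inputs(config)
    times, _ = _times(config, len(stack))
    reference = _reference(config, stack, contours)

    bundle: dict = {}
    outputs: dict[str, str] = {}

    if "quantify" in stages:
        trace = quantify_timecourse(
            stack, contours, reference, times_min=times,
            band_width=config.band_width, rolling_window=config.rolling_window,
            sg_window=config.sg_window, sg_order=config.sg_order,
            shift_range=config.shift_range,
            exclusion_halfwidth=config.exclusion_halfwidth,
            integration_halfwidth=config.integration_halfwidth,
            shared_shift=config.shared_shift)
        df = trace.to_frame()
        path = out_dir / "trace.csv"
        df.to_csv(path, index=False)
        outputs["trace"] = str(path)
        bundle["trace"] = df

    if "asi" in stages:
        series = []
        poles_used = (0.0, 0.5)
        for f, (img, contour) in enumerate(zip(stack, contours)):
            st = straighten_cortex(img, contour, width=config.band_width,
                                   perpendicular_spacing=config.perpendicular_spacing,
                                   resample_spacing=config.resample_spacing)
            anterior = config.anterior_s
            posterior = config.posterior_s
            if anterior is None or posterior is None:
                a_pt, p_pt = contour.principal_axis_endpoints()
                anterior = contour.arc_fraction_of_point(a_pt)
                posterior = contour.arc_fraction_of_point(p_pt)
                log.info("frame %d: poles defaulted to long-axis endpoints "
                         "(s=%.3f, %.3f); override with anterior_s/posterior_s",
                         f, anterior, posterior)
            prof = circumferential_profile(
                st, reference, rolling_window=config.rolling_window,
                sg_window=config.sg_window, sg_order=config.sg_order,
                pole_anterior=anterior, pole_posterior=posterior,
                shared_shift=config.shared_shift,
                shift_range=config.shift_range,
                exclusion_halfwidth=config.exclusion_halfwidth)
            r = compute_asi(prof, config.window_fraction)
            r.frame = f
            r.time_min = float(times[f])
            series.append(r)
            poles_used = (anterior, posterior)
        series = normalize_asi(series, config.reference_frame)
        df = asi_series_to_frame(series, pole_anterior=poles_used[0],
                                 pole_posterior=poles_used[1])
        path = out_dir / "asi.csv"
        df.to_csv(path, index=False)
        outputs["asi"] = str(path)
        bundle["asi"] = df

    write_reference_csv(out_dir / "reference_profile.csv", reference)
    outputs["reference_profile"] = str(out_dir / "reference_profile.csv")

    manifest = {
        "software": "cortiq",
        "version": __version__,
        "config": config.to_dict(),
        "stages": list(stages),
        "n_frames": int(len(stack)),
        "outputs": outputs,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    bundle["manifest"] = manifest
    return bundle
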