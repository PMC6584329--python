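"""Run configuration: every tunable parameter of the pipeline in one place.

Defaults mirror the published analysis constants where those exist (50-sample
band, 50-position rolling average, 30% ASI windows, 56-minute
ovulation-to-symmetry-breaking interval); the remaining knobs are documented
package choices.  Unknown keys in a config file are rejected so typos cannot
silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml


@dataclass
class RunConfig:
    # cortex band
    band_width: int = 50  # perpendicular samples across the cortex
    perpendicular_spacing: float = 1.0  # px between perpendicular samples
    resample_spacing: float = 1.0  # px between circumference positions
    # smoothing
    rolling_window: int = 50  # positions averaged along the cortex
    sg_window: int = 11
    sg_order: int = 3
    # reference fit / integration
    shift_range: float = 5.0  # px, reference alignment search
    exclusion_halfwidth: float = 11.0  # samples around band center excluded
    shared_shift: bool = True  # one registration shift per movie/contour
    integration_halfwidth: float = 10.0  # samples integrated
    # polarity
    window_fraction: float = 0.30  # circumference fraction per ASI window
    anterior_s: float | None = None  # arc fraction; None -> long-axis pole
    posterior_s: float | None = None
    reference_frame: int = 0  # ASI normalization frame
    # timing
    frame_interval_min: float = 1.5
    ovulation_sb_interval_min: float = 56.0
    # clusters
    cluster_diameter: int = 7
    cluster_mass_threshold: float | None = None  # must be set per dataset
    # io / reproducibility
    seed: int = 0
    image_path: str | None = None
    contour_path: str | None = None
    events_path: str | None = None
    reference_path: str | None = None
    out_dir: str = "."

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must hold a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
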