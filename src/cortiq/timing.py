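"""Event-time bookkeeping on the relative-to-ovulation convention.

All times are expressed in minutes relative to ovulation.  For dissected
(ex utero) embryos ovulation cannot be observed, so it is inferred by
subtracting the mean in-utero interval between ovulation and polarity
symmetry breaking (56 minutes by default — a measured cohort mean, kept
configurable because other strains and conditions differ) from the
annotated symmetry-breaking time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

OVULATION_SB_INTERVAL_MIN = 56.0


@dataclass
class EventTimeline:
    """Named event times for one movie, in minutes on a common clock.

    ``events`` maps event names (ovulation, NEBD, anaphase_I, anaphase_II,
    symmetry_breaking, treatment, ...) to absolute times in minutes;
    ``frame_interval_min`` converts frame indices to minutes.
    """

    events: dict = field(default_factory=dict)
    frame_interval_min: float = 1.5
    ovulation_inferred: bool = False

    def __post_init__(self) -> None:
        for name, t in self.events.items():
            if not np.isfinite(t):
                raise ValueError(f"event {name!r} has a non-finite time")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be positive")
        if self.ovulation_inferred and "symmetry_breaking" not in self.events:
            raise ValueError("inferred ovulation requires a symmetry_breaking event")


def infer_ovulation_time(sb_time_min: float,
                         interval_min: float = OVULATION_SB_INTERVAL_MIN) -> float:
    """Ovulation time inferred from the symmetry-breaking annotation.

    Returns ``sb_time_min - interval_min``; by construction the inferred
    ovulation-to-symmetry-breaking interval equals ``interval_min``.
    """
    if sb_time_min is None or not np.isfinite(sb_time_min):
        raise ValueError("symmetry_breaking time is required to infer ovulation")
    return float(sb_time_min) - float(interval_min)


def ensure_ovulation(timeline: EventTimeline,
                     interval_min: float = OVULATION_SB_INTERVAL_MIN
                     ) -> EventTimeline:
    """Return a timeline that has an ovulation event, inferring it if needed."""
    if "ovulation" in timeline.events:
        return timeline
    if "symmetry_breaking" not in timeline.events:
        raise ValueError("no ovulation annotation and no symmetry_breaking "
                         "event to infer it from")
    events = dict(timeline.events)
    events["ovulation"] = infer_ovulation_time(events["symmetry_breaking"],
                                               interval_min)
    return EventTimeline(events=events,
                         frame_interval_min=timeline.frame_interval_min,
                         ovulation_inferred=True)


def to_relative_times(timeline: EventTimeline, frames) -> np.ndarray:
    """Frame times in minutes relative to ovulation.

    ``time[f] = (f - frame_of(ovulation)) * frame_interval_min`` with the
    ovulation frame derived from the ovulation event time.  The product is
    taken per frame (exact rational arithmetic on the frame offset), so
    times never accumulate floating-point drift.
    """
    timeline = ensure_ovulation(timeline)
    interval = Fraction(str(timeline.frame_interval_min))
    f0 = Fraction(str(timeline.events["ovulation"])) / interval
    frames = np.asarray(frames)
    return np.array([float((Fraction(int(f)) - f0) * interval) for f in frames])


def shift_events_to_ovulation(timeline: EventTimeline) -> dict:
    """Event times shifted so ovulation sits at 0 minutes."""
    timeline = ensure_ovulation(timeline)
    t0 = timeline.events["ovulation"]
    return {name: t - t0 for name, t in timeline.events.items()}


def read_events_csv(path, frame_interval_min: float = 1.5) -> EventTimeline:
    """Read event annotations from CSV with columns (event, time_min) or
    (event, frame); frames convert via ``frame_interval_min``."""
    import pandas as pd

    df = pd.read_csv(path)
    if "event" not in df.columns:
        raise ValueError("events CSV needs an 'event' column")
    events = {}
    for _, row in df.iterrows():
        if "time_min" in df.columns and np.isfinite(row.get("time_min", np.nan)):
            events[str(row["event"])] = float(row["time_min"])
        elif "frame" in df.columns:
            events[str(row["event"])] = float(row["frame"]) * frame_interval_min
        else:
            raise ValueError("events CSV needs a 'time_min' or 'frame' column")
    return EventTimeline(events=events, frame_interval_min=frame_interval_min)
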