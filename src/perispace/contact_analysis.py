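"""First limb-rod contact detection and contact-location statistics.

During rod-climbing, a stick insect first touches the horizontal rod with an
antenna or a front leg.  The detector scans each frame of a trial, samples
the limb as a polyline at ~1 mm arc-length resolution, and reports the
earliest frame at which the limb comes within the rod radius, together with
the arc-length location of the closest limb point (ties broken toward the
most distal point).  Only the initial contact is recorded per trial and
limb, so that successive location records are statistically independent.

Leg contact locations are standardized to a common axis: the femur maps to
[0, 0.5], the tibia to [0.5, 1.0), and any tarsus contact counts as exactly
1.0 (100% leg length).  Antennal locations are plain flagellum fractions
(0 = base, 1 = tip).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .body_model import fk_antenna, fk_leg
from .synthetic_data import RodSpec, Trial

logger = logging.getLogger(__name__)

__all__ = [
    "ContactEvent",
    "ContactSummary",
    "NoEventsError",
    "detect_first_contact",
    "standardize_leg_location",
    "summarize_contacts",
    "write_events",
]


class NoEventsError(ValueError):
    """Summary requested for an empty event list."""


@dataclass(frozen=True)
class ContactEvent:
    """First contact of one limb with the rod in one trial."""

    trial_id: str
    limb: str
    frame: int
    fraction: float          # standardized location in [0, 1]
    point: Tuple[float, float, float]   # head-centered coordinates, mm
    rod_height_mm: float
    leg_state: Optional[str] = None     # 'swing' | 'stance' of the front leg


@dataclass(frozen=True)
class ContactSummary:
    """Per-rod-height order statistics plus pooled distribution."""

    heights: np.ndarray          # (H,) sorted rod heights
    medians: np.ndarray          # (H,)
    iqr_low: np.ndarray          # (H,) 25th percentile
    iqr_high: np.ndarray         # (H,) 75th percentile
    minima: np.ndarray           # (H,)
    maxima: np.ndarray           # (H,)
    counts: np.ndarray           # (H,) events per height
    hist_edges: np.ndarray       # (B+1,) pooled histogram bin edges on [0, 1]
    hist_counts: np.ndarray      # (B,)
    cumulative: np.ndarray       # (B,) non-decreasing, ends at 1
    distal_third_fraction: float  # share of events with fraction > 2/3


def _leg_polyline(trial: Trial, limb: str, frame: int,
                  spacing: float = 1.0,
                  ) -> Tuple[np.ndarray, np.ndarray]:
    """World polyline points and standardized leg fractions for one frame.

    The polyline runs coxa -> femur -> straight tibia+tarsus at ~``spacing``
    mm arc-length resolution.  Standardization: coxa points map to 0, femur
    to [0, 0.5], tibia to [0.5, 1.0), tarsus to exactly 1.0.
    """
    m = trial.model
    lm = m.limb(limb)
    jp = fk_leg(m, limb, trial.leg_angles_at(limb, frame))
    pts: List[np.ndarray] = []
    fracs: List[np.ndarray] = []

    def piece(start, end, length):
        npts = int(math.ceil(length / spacing)) + 1
        s = np.linspace(0.0, 1.0, npts)
        pts.append(np.asarray(start)
                   + s[:, None] * (np.asarray(end) - np.asarray(start)))
        return s

    s = piece(jp.thorax_coxa, jp.coxa_trochanter, lm.coxa)
    fracs.append(np.zeros_like(s))                       # coxa -> 0
    s = piece(jp.coxa_trochanter, jp.femur_tibia, lm.femur)
    fracs.append(0.5 * s)                                # femur -> [0, 0.5]
    s = piece(jp.femur_tibia, jp.tarsus_tip, lm.tibia + lm.tarsus)
    arc = s * (lm.tibia + lm.tarsus)
    f = np.where(arc <= lm.tibia, 0.5 + 0.5 * arc / lm.tibia, 1.0)
    fracs.append(f)
    local = np.vstack(pts)
    world = trial.segment_pose(lm.carrying_segment, frame).to_world(local)
    return world, np.concatenate(fracs)


def _antenna_polyline(trial: Trial, limb: str, frame: int,
                      spacing: float = 1.0,
                      ) -> Tuple[np.ndarray, np.ndarray]:
    lm = trial.model.limb(limb)
    npts = int(math.ceil(lm.total_length / spacing)) + 1
    fr = np.linspace(0.0, 1.0, npts)
    local = fk_antenna(trial.model, limb,
                       trial.antenna_angles_at(limb, frame), fr)
    world = trial.segment_pose("head", frame).to_world(local)
    return world, fr


def limb_polyline(trial: Trial, limb: str, frame: int,
                  spacing: float = 1.0) -> Tuple[np.ndarray, np.ndarray]:
    """World sample points and standardized location fractions of a limb."""
    if trial.model.limb(limb).is_leg:
        return _leg_polyline(trial, limb, frame, spacing)
    return _antenna_polyline(trial, limb, frame, spacing)


def standardize_leg_location(segment: str, within_fraction: float) -> float:
    """Map a (segment, within-segment fraction) contact onto the common axis.

    Femur contacts map proportionally onto [0, 0.5], tibia onto [0.5, 1.0),
    any tarsus contact is exactly 1.0.  Coxa contacts fall outside the
    standardized axis and map to 0 with a warning.
    """
    if not (0.0 <= within_fraction <= 1.0):
        raise ValueError("within-segment fraction must lie in [0, 1]")
    if segment == "femur":
        return 0.5 * within_fraction
    if segment == "tibia":
        return min(0.5 + 0.5 * within_fraction, 1.0 - 1e-12)
    if segment == "tarsus":
        return 1.0
    if segment == "coxa":
        logger.warning("coxa contact mapped to 0 (outside standardized axis)")
        return 0.0
    raise ValueError(f"unknown leg segment {segment!r}")


def detect_first_contact(trial: Trial, rod: Optional[RodSpec] = None,
                         limb: str = "LA", spacing: float = 1.0,
                         ) -> Optional[ContactEvent]:
    """Earliest frame at which the limb polyline enters the rod radius.

    Returns ``None`` when the limb never touches the rod.  The contact
    location is the standardized fraction of the closest sampled limb
    point, ties within a frame broken toward the most distal point.  For
    antennal contacts the swing/stance state of the ipsilateral front leg
    is recorded; for leg contacts the leg's own state.
    """
    rod = trial.rod if rod is None else rod
    if rod is None:
        raise ValueError("trial has no rod and none was given")
    is_leg = trial.model.limb(limb).is_leg
    for frame in range(trial.n_frames):
        pts, fr = limb_polyline(trial, limb, frame, spacing)
        d = rod.distance(pts)
        dmin = float(d.min())
        if dmin <= rod.radius_mm:
            idx = int(np.flatnonzero(d == dmin)[-1])
            head_pose = trial.segment_pose("head", frame)
            point = tuple(head_pose.to_local(pts[idx]))
            state_leg = limb if is_leg else ("L1" if limb[0] == "L" else "R1")
            state = ("swing" if trial.leg_swing[state_leg][frame]
                     else "stance")
            return ContactEvent(trial_id=trial.animal_id, limb=limb,
                                frame=frame, fraction=float(fr[idx]),
                                point=point, rod_height_mm=rod.height_mm,
                                leg_state=state)
    return None


def summarize_contacts(events: Sequence[ContactEvent],
                       n_bins: int = 20) -> ContactSummary:
    """Order statistics per rod height plus the pooled distribution."""
    if not events:
        raise NoEventsError("no contact events to summarize")
    fractions = np.array([e.fraction for e in events])
    heights = np.array(sorted({e.rod_height_mm for e in events}))
    med, q1, q3, lo, hi, cnt = ([] for _ in range(6))
    for h in heights:
        f = np.array([e.fraction for e in events if e.rod_height_mm == h])
        med.append(np.median(f))
        q1.append(np.percentile(f, 25))
        q3.append(np.percentile(f, 75))
        lo.append(f.min())
        hi.append(f.max())
        cnt.append(len(f))
    hist, edges = np.histogram(fractions, bins=n_bins, range=(0.0, 1.0))
    cum = np.cumsum(hist) / len(fractions)
    return ContactSummary(
        heights=heights, medians=np.array(med), iqr_low=np.array(q1),
        iqr_high=np.array(q3), minima=np.array(lo), maxima=np.array(hi),
        counts=np.array(cnt), hist_edges=edges, hist_counts=hist,
        cumulative=cum,
        distal_third_fraction=float(np.mean(fractions > 2.0 / 3.0)))


def write_events(events: Sequence[ContactEvent], path) -> None:
    """Export events as delimited text, one row per event."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("trial,limb,frame,fraction,x,y,z,rod_height_mm,leg_state\n")
        for e in events:
            x, y, z = e.point
            fh.write(f"{e.trial_id},{e.limb},{e.frame},{e.fraction!r},"
                     f"{x!r},{y!r},{z!r},{e.rod_height_mm!r},"
                     f"{e.leg_state or ''}\n")
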