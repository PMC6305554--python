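"""Standardized stick-insect body model and limb kinematics.

The model describes an adult female *Carausius morosus* as a rigid, straight
chain of four body segments (head, pro-, meso-, metathorax), each carrying a
pair of limbs: two antennae on the head and six legs on the thorax segments.
Every limb is parameterized by its insertion point in the carrying-segment
frame, the slanted rotation axis of its basal (thorax-coxa) joint, and its
segment lengths.

Coordinate convention: x forward, y left, z up.  Right limbs have negative y
insertion coordinates and mirrored joint axes, so that identical joint-angle
triplets produce bilaterally mirrored limb postures.

A leg is modeled as a 3-DoF chain: protraction/retraction (alpha) rotates the
whole leg plane about the fixed slanted thorax-coxa axis; levation/depression
(beta) elevates the femur within that plane; extension/flexion (gamma) is the
interior femur-tibia angle.  The coxa is a fixed-length offset along the
leg-plane base direction, and the tarsus is treated as a straight extension
of the tibia (the tibia-tarsus angle is fixed at 0 deg, maximally extending
the radial working range).  An antenna is a straight flagellum with two
rotational DoF (azimuth, elevation) at its head insertion.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import numpy as np

__all__ = [
    "BodyModel",
    "Limb",
    "LegAngles",
    "AntennaAngles",
    "SegmentPose",
    "LegJointPositions",
    "InvalidLimbError",
    "OutOfWorkspaceError",
    "InvalidMeasurementError",
    "LEG_IDS",
    "ANTENNA_IDS",
    "LIMB_IDS",
    "JOINT_RANGES_DEG",
    "MIDDLE_LEG_RANGE_FRONT_SET",
    "MIDDLE_LEG_RANGE_HIND_SET",
    "standard_body",
    "affordance_joint_ranges",
    "fk_leg",
    "ik_leg",
    "ik_leg_batch",
    "fk_antenna",
    "leg_joint_ranges",
    "size_scaling_factor",
    "length_ratio_percent",
]


class InvalidLimbError(KeyError):
    """Unknown limb identifier."""


class OutOfWorkspaceError(ValueError):
    """Inverse kinematics target outside the leg's reachable workspace."""


class InvalidMeasurementError(ValueError):
    """Non-positive length or other invalid body measurement."""


LEG_IDS: Tuple[str, ...] = ("L1", "R1", "L2", "R2", "L3", "R3")
ANTENNA_IDS: Tuple[str, ...] = ("LA", "RA")
LIMB_IDS: Tuple[str, ...] = ANTENNA_IDS + LEG_IDS

#: Physiological joint-angle bounds per leg class, degrees, as
#: (min, max) per DoF (alpha, beta, gamma).  Front and hind legs take the
#: ranges observed inside their respective affordance volumes; the middle
#: leg uses the per-DoF union of its two affordance-volume range sets.
MIDDLE_LEG_RANGE_FRONT_SET: Dict[str, Tuple[float, float]] = {
    "alpha": (-76.6, -1.4),
    "beta": (-114.6, 26.4),
    "gamma": (0.3, 136.3),
}
MIDDLE_LEG_RANGE_HIND_SET: Dict[str, Tuple[float, float]] = {
    "alpha": (-4.6, 62.4),
    "beta": (-95.6, 22.5),
    "gamma": (2.0, 113.1),
}
JOINT_RANGES_DEG: Dict[str, Dict[str, Tuple[float, float]]] = {
    "front": {
        "alpha": (-22.9, 72.5),
        "beta": (-114.1, -1.3),
        "gamma": (42.9, 158.9),
    },
    "middle": {
        "alpha": (-76.6, 62.4),
        "beta": (-114.6, 26.4),
        "gamma": (0.3, 136.3),
    },
    "hind": {
        "alpha": (-52.8, 10.6),
        "beta": (-120.7, 7.8),
        "gamma": (59.2, 153.8),
    },
}

_LEG_CLASS = {"L1": "front", "R1": "front", "L2": "middle", "R2": "middle",
              "L3": "hind", "R3": "hind"}

_SEGMENT_OF_LIMB = {
    "LA": "head", "RA": "head",
    "L1": "prothorax", "R1": "prothorax",
    "L2": "mesothorax", "R2": "mesothorax",
    "L3": "metathorax", "R3": "metathorax",
}


def leg_class(leg_id: str) -> str:
    """Return 'front' | 'middle' | 'hind' for a leg id."""
    try:
        return _LEG_CLASS[leg_id]
    except KeyError:
        raise InvalidLimbError(leg_id) from None


def leg_joint_ranges(leg_id: str) -> Dict[str, Tuple[float, float]]:
    """Physiological (min, max) bounds in degrees for each DoF of a leg."""
    return JOINT_RANGES_DEG[leg_class(leg_id)]


def affordance_joint_ranges(leg_id: str, partner_id: str,
                            ) -> Dict[str, Tuple[float, float]]:
    """Joint bounds of a leg conditioned on its affordance-volume partner.

    The middle leg occupies different parts of its working range depending
    on whether it shares an affordance volume with the front or the hind
    leg; the corresponding observed range set applies.  All other legs use
    their standard physiological bounds.
    """
    if leg_class(leg_id) == "middle":
        partner = leg_class(partner_id)
        if partner == "front":
            return MIDDLE_LEG_RANGE_FRONT_SET
        if partner == "hind":
            return MIDDLE_LEG_RANGE_HIND_SET
    return leg_joint_ranges(leg_id)


@dataclass(frozen=True)
class LegAngles:
    """Leg joint angles in degrees.

    alpha: protraction/retraction about the slanted thorax-coxa axis.
    beta:  levation/depression of the femur within the leg plane.
    gamma: extension/flexion, the interior femur-tibia angle in (0, 180].
    """

    alpha: float
    beta: float
    gamma: float

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma], dtype=float)

    @staticmethod
    def from_array(a: Sequence[float]) -> "LegAngles":
        return LegAngles(float(a[0]), float(a[1]), float(a[2]))

    def within(self, bounds: Mapping[str, Tuple[float, float]],
               tol: float = 1e-9) -> bool:
        for name, value in (("alpha", self.alpha), ("beta", self.beta),
                            ("gamma", self.gamma)):
            lo, hi = bounds[name]
            if not (lo - tol <= value <= hi + tol):
                return False
        return True


@dataclass(frozen=True)
class AntennaAngles:
    """Antennal pointing angles in degrees.

    azimuth: rotation of the flagellum from straight-forward toward the
        antenna's own side (positive = outward for both antennae).
    elevation: rotation above the horizontal plane.
    """

    azimuth: float
    elevation: float

    def as_array(self) -> np.ndarray:
        return np.array([self.azimuth, self.elevation], dtype=float)


@dataclass(frozen=True)
class SegmentPose:
    """World-frame pose of a body segment (position mm + yaw/pitch/roll deg)."""

    position: Tuple[float, float, float]
    yaw: float = 0.0
    pitch: float = 0.0
    roll: float = 0.0

    def rotation(self) -> np.ndarray:
        """World-from-segment rotation matrix, R = Rz(yaw) Ry(pitch) Rx(roll)."""
        return _rot_z(self.yaw) @ _rot_y(self.pitch) @ _rot_x(self.roll)

    def to_world(self, pts: np.ndarray) -> np.ndarray:
        """Map points (..., 3) from segment frame to world frame."""
        return np.asarray(pts, dtype=float) @ self.rotation().T + np.asarray(
            self.position, dtype=float)

    def to_local(self, pts: np.ndarray) -> np.ndarray:
        """Map points (..., 3) from world frame to segment frame."""
        return (np.asarray(pts, dtype=float)
                - np.asarray(self.position, dtype=float)) @ self.rotation()


@dataclass(frozen=True)
class Limb:
    """Geometry of one limb in its carrying-segment frame."""

    limb_id: str
    carrying_segment: str
    insertion: Tuple[float, float, float]  # mm
    total_length: float                    # mm
    yaw: float | None = None               # deg, thorax-coxa axis (legs)
    pitch: float | None = None             # deg, thorax-coxa axis (legs)
    coxa: float | None = None              # mm
    femur: float | None = None             # mm
    tibia: float | None = None             # mm
    tarsus: float | None = None            # mm

    @property
    def is_leg(self) -> bool:
        return self.coxa is not None

    @property
    def handedness(self) -> int:
        """+1 for left limbs, -1 for right limbs."""
        return 1 if self.limb_id.startswith("L") else -1

    @property
    def insertion_array(self) -> np.ndarray:
        return np.asarray(self.insertion, dtype=float)

    def segment_lengths(self) -> Dict[str, float]:
        if self.is_leg:
            return {"coxa": self.coxa, "femur": self.femur,
                    "tibia": self.tibia, "tarsus": self.tarsus}
        return {"flagellum": self.total_length}


@dataclass(frozen=True)
class BodyModel:
    """Rigid straight body: segment lengths plus per-limb geometry.

    Segment frames share the world orientation of a straight body; each
    segment frame's origin sits at the posterior boundary of the segment,
    x pointing forward.  The body frame coincides with the metathorax frame.
    """

    segments: Mapping[str, float]          # segment name -> length mm
    limbs: Mapping[str, Limb]

    def __post_init__(self):
        for name, length in self.segments.items():
            if length <= 0:
                raise InvalidMeasurementError(f"segment {name}: {length}")

    def limb(self, limb_id: str) -> Limb:
        try:
            return self.limbs[limb_id]
        except KeyError:
            raise InvalidLimbError(limb_id) from None

    def segment_origin(self, segment: str) -> np.ndarray:
        """Origin of a segment frame in the body (metathorax) frame."""
        order = ("metathorax", "mesothorax", "prothorax", "head")
        x = 0.0
        for name in order:
            if name == segment:
                return np.array([x, 0.0, 0.0])
            x += self.segments[name]
        raise KeyError(segment)

    def limb_base(self, limb_id: str) -> np.ndarray:
        """Limb base (insertion point) position in the body frame."""
        limb = self.limb(limb_id)
        return self.segment_origin(limb.carrying_segment) + limb.insertion_array

    def limb_pair_segment_sum(self, limb_id: str) -> float:
        """Size reference sum for the limb's pair, used for standardization.

        Legs: both femora + both tibiae + carrying segment length.
        Antennae: both antenna lengths + head length.
        """
        limb = self.limb(limb_id)
        seg_len = self.segments[limb.carrying_segment]
        if limb.is_leg:
            mate = self.limb(_mate_id(limb_id))
            return limb.femur + limb.tibia + mate.femur + mate.tibia + seg_len
        mate = self.limb(_mate_id(limb_id))
        return limb.total_length + mate.total_length + seg_len

    def scaled(self, factor: float) -> "BodyModel":
        """Uniformly scaled copy (all lengths and insertion coordinates)."""
        if factor <= 0:
            raise InvalidMeasurementError(f"scale factor {factor}")
        segs = {k: v * factor for k, v in self.segments.items()}
        limbs = {}
        for lid, lm in self.limbs.items():
            limbs[lid] = replace(
                lm,
                insertion=tuple(c * factor for c in lm.insertion),
                total_length=lm.total_length * factor,
                coxa=None if lm.coxa is None else lm.coxa * factor,
                femur=None if lm.femur is None else lm.femur * factor,
                tibia=None if lm.tibia is None else lm.tibia * factor,
                tarsus=None if lm.tarsus is None else lm.tarsus * factor,
            )
        return BodyModel(segments=segs, limbs=limbs)

    # -- serialization (structured text config) -----------------------------

    def to_dict(self) -> dict:
        return {
            "segments": dict(self.segments),
            "limbs": {
                lid: {k: v for k, v in {
                    "limb_id": lm.limb_id,
                    "carrying_segment": lm.carrying_segment,
                    "insertion": list(lm.insertion),
                    "total_length": lm.total_length,
                    "yaw": lm.yaw, "pitch": lm.pitch,
                    "coxa": lm.coxa, "femur": lm.femur,
                    "tibia": lm.tibia, "tarsus": lm.tarsus,
                }.items() if v is not None}
                for lid, lm in self.limbs.items()
            },
        }

    @staticmethod
    def from_dict(d: Mapping) -> "BodyModel":
        limbs = {}
        for lid, ld in d["limbs"].items():
            ld = dict(ld)
            ld["insertion"] = tuple(ld["insertion"])
            limbs[lid] = Limb(**ld)
        return BodyModel(segments=dict(d["segments"]), limbs=limbs)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @staticmethod
    def from_json(s: str) -> "BodyModel":
        return BodyModel.from_dict(json.loads(s))

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json() + "\n")

    @staticmethod
    def read(path) -> "BodyModel":
        with open(path, "r", encoding="utf-8") as fh:
            return BodyModel.from_json(fh.read())


def _mate_id(limb_id: str) -> str:
    side = "R" if limb_id[0] == "L" else "L"
    return side + limb_id[1:]


# --------------------------------------------------------------------------
# Standard body constants
# --------------------------------------------------------------------------

_STANDARD_SEGMENTS = {
    "head": 4.30,
    "prothorax": 3.76,
    "mesothorax": 17.45,
    "metathorax": 11.87,
}

_STANDARD_LIMBS = (
    # id, segment, insertion, yaw, pitch, total, coxa, femur, tibia, tarsus
    ("LA", "head", (3.88, 0.95, 0.84), None, None, 34.42, None, None, None, None),
    ("RA", "head", (3.87, -0.95, 0.84), None, None, 34.44, None, None, None, None),
    ("L1", "prothorax", (2.03, 1.33, -0.73), 84.0, 34.0, 38.67, 1.32, 16.57, 15.13, 5.24),
    ("R1", "prothorax", (2.03, -1.33, -0.73), -84.0, 34.0, 38.60, 1.32, 16.48, 15.61, 5.18),
    ("L2", "mesothorax", (1.03, 1.70, -1.11), 92.0, 37.0, 29.68, 1.42, 12.12, 11.64, 4.51),
    ("R2", "mesothorax", (1.03, -1.70, -1.11), -92.0, 37.0, 29.76, 1.42, 12.16, 11.75, 4.44),
    ("L3", "metathorax", (1.34, 1.67, -1.05), 114.0, 29.0, 35.64, 1.54, 14.55, 14.65, 4.77),
    ("R3", "metathorax", (1.34, -1.67, -1.05), -114.0, 29.0, 35.51, 1.54, 15.60, 14.71, 4.79),
)


def standard_body() -> BodyModel:
    """The standardized adult female body used for all volume gridding."""
    limbs = {}
    for (lid, seg, ins, yaw, pitch, total, coxa, femur, tibia, tarsus) \
            in _STANDARD_LIMBS:
        limbs[lid] = Limb(limb_id=lid, carrying_segment=seg, insertion=ins,
                          total_length=total, yaw=yaw, pitch=pitch,
                          coxa=coxa, femur=femur, tibia=tibia, tarsus=tarsus)
    return BodyModel(segments=dict(_STANDARD_SEGMENTS), limbs=limbs)


# --------------------------------------------------------------------------
# Rotation helpers (degrees in, matrices out)
# --------------------------------------------------------------------------

def _rot_x(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_z(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def _rodrigues(axis: np.ndarray, deg: float) -> np.ndarray:
    """Rotation matrix about a unit axis by an angle in degrees."""
    a = math.radians(deg)
    c, s = math.cos(a), math.sin(a)
    x, y, z = axis
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(axis, axis)


def _leg_frame(limb: Limb) -> Tuple[np.ndarray, np.ndarray]:
    """Thorax-coxa rotation axis u and the alpha=0 leg-plane base direction r0.

    u is the carrying-segment-frame unit vector obtained by tilting the
    vertical axis by the limb's pitch and yaw; r0 is the lateral direction
    (toward the limb's own side) projected perpendicular to u.
    """
    u = _rot_z(limb.yaw) @ _rot_y(limb.pitch) @ np.array([0.0, 0.0, 1.0])
    lateral = np.array([0.0, float(limb.handedness), 0.0])
    r0 = lateral - (lateral @ u) * u
    r0 /= np.linalg.norm(r0)
    return u, r0


@dataclass(frozen=True)
class LegJointPositions:
    """Ordered joint positions of one leg in its carrying-segment frame."""

    thorax_coxa: np.ndarray
    coxa_trochanter: np.ndarray
    femur_tibia: np.ndarray      # the "knee"
    tibia_tarsus: np.ndarray
    tarsus_tip: np.ndarray

    def as_array(self) -> np.ndarray:
        return np.stack([self.thorax_coxa, self.coxa_trochanter,
                         self.femur_tibia, self.tibia_tarsus,
                         self.tarsus_tip])


def fk_leg(model: BodyModel, leg_id: str, angles: LegAngles) -> LegJointPositions:
    """Forward kinematics of a leg, in its carrying-segment frame.

    The leg plane is spanned by the rotated base direction r(alpha) and the
    thorax-coxa axis u.  beta measures femur elevation from r(alpha) toward
    u; the tibia lies at the interior angle gamma from the femur, bending
    toward the r axis ("knee up"); the tarsus extends the tibia.
    """
    limb = model.limb(leg_id)
    if not limb.is_leg:
        raise InvalidLimbError(f"{leg_id} is not a leg")
    if not all(map(math.isfinite, (angles.alpha, angles.beta, angles.gamma))):
        raise ValueError("non-finite joint angles")
    u, r0 = _leg_frame(limb)
    r = _rodrigues(u, limb.handedness * angles.alpha) @ r0
    ins = limb.insertion_array
    ctr = ins + limb.coxa * r

    b = math.radians(angles.beta)
    femur_dir = math.cos(b) * r + math.sin(b) * u
    knee = ctr + limb.femur * femur_dir

    t = math.radians(angles.beta + angles.gamma - 180.0)
    tibia_dir = math.cos(t) * r + math.sin(t) * u
    tita = knee + limb.tibia * tibia_dir
    tip = tita + limb.tarsus * tibia_dir
    return LegJointPositions(ins, ctr, knee, tita, tip)


def ik_leg(model: BodyModel, leg_id: str, target: Sequence[float],
           bounds: Mapping[str, Tuple[float, float]] | None = None,
           ) -> LegAngles:
    """Inverse kinematics: joint angles placing the tibia-tarsus joint at target.

    ``target`` is a point in the carrying-segment frame.  Of the two
    geometric leg-plane branches the one whose angles fall within the leg's
    physiological bounds is returned (gamma always in (0, 180], "knee up");
    if neither branch is within bounds the positive-radial branch wins.
    Raises :class:`OutOfWorkspaceError` when the target is unreachable.
    """
    limb = model.limb(leg_id)
    if not limb.is_leg:
        raise InvalidLimbError(f"{leg_id} is not a leg")
    if bounds is None:
        bounds = leg_joint_ranges(leg_id)
    u, r0 = _leg_frame(limb)
    e2 = np.cross(u, r0)
    v = np.asarray(target, dtype=float) - limb.insertion_array
    w = float(v @ u)                      # in-plane "up" coordinate
    v_perp = v - w * u
    rho = float(np.linalg.norm(v_perp))

    lf, lt = limb.femur, limb.tibia
    eps = 1e-9
    candidates = []
    for sgn in (1.0, -1.0):
        if rho > 1e-12:
            phi = math.degrees(math.atan2(sgn * (v_perp @ e2),
                                          sgn * (v_perp @ r0)))
        else:
            phi = 0.0
        alpha = _wrap_deg(limb.handedness * phi)
        dx = sgn * rho - limb.coxa
        d = math.hypot(dx, w)
        if d < abs(lf - lt) - 1e-9 or d > lf + lt + 1e-9:
            continue
        d = min(max(d, abs(lf - lt)), lf + lt)
        cos_g = (lf * lf + lt * lt - d * d) / (2.0 * lf * lt)
        gamma = math.degrees(math.acos(min(1.0, max(-1.0, cos_g))))
        cos_p = (lf * lf + d * d - lt * lt) / (2.0 * lf * d) if d > eps else 0.0
        phi_off = math.degrees(math.acos(min(1.0, max(-1.0, cos_p))))
        beta = _wrap_deg(math.degrees(math.atan2(w, dx)) + phi_off)
        candidates.append((sgn, LegAngles(alpha, beta, gamma)))

    if not candidates:
        raise OutOfWorkspaceError(
            f"{leg_id}: target {np.asarray(target)} unreachable")
    for _, ang in candidates:
        if ang.within(bounds):
            return ang
    return candidates[0][1]


def _wrap_deg(a: float) -> float:
    """Wrap an angle to (-180, 180]."""
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def ik_leg_batch(model: BodyModel, leg_id: str, targets: np.ndarray,
                 bounds: Mapping[str, Tuple[float, float]] | None = None,
                 ) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized inverse kinematics restricted to in-bounds solutions.

    Solves both leg-plane branches for all targets (N, 3) at once and keeps
    the branch whose triplet lies within the physiological bounds
    (positive-radial branch preferred when both qualify).  Returns
    ``(angles (N, 3) deg, ok (N,) bool)``; rows with no reachable in-bounds
    branch have ``ok`` False.
    """
    limb = model.limb(leg_id)
    if not limb.is_leg:
        raise InvalidLimbError(f"{leg_id} is not a leg")
    if bounds is None:
        bounds = leg_joint_ranges(leg_id)
    u, r0 = _leg_frame(limb)
    e2 = np.cross(u, r0)
    t = np.asarray(targets, dtype=float)
    v = t - limb.insertion_array
    w = v @ u
    v_perp = v - w[:, None] * u
    rho = np.linalg.norm(v_perp, axis=1)
    lf, lt = limb.femur, limb.tibia
    lo = np.array([bounds["alpha"][0], bounds["beta"][0], bounds["gamma"][0]])
    hi = np.array([bounds["alpha"][1], bounds["beta"][1], bounds["gamma"][1]])

    n = len(t)
    out = np.zeros((n, 3))
    ok = np.zeros(n, dtype=bool)
    for sgn in (1.0, -1.0):
        phi = np.degrees(np.arctan2(sgn * (v_perp @ e2), sgn * (v_perp @ r0)))
        alpha = (limb.handedness * phi + 180.0) % 360.0 - 180.0
        alpha[alpha == -180.0] = 180.0
        dx = sgn * rho - limb.coxa
        d = np.hypot(dx, w)
        feasible = (d >= abs(lf - lt) - 1e-9) & (d <= lf + lt + 1e-9)
        d = np.clip(d, abs(lf - lt), lf + lt)
        cos_g = np.clip((lf * lf + lt * lt - d * d) / (2 * lf * lt), -1, 1)
        gamma = np.degrees(np.arccos(cos_g))
        with np.errstate(divide="ignore", invalid="ignore"):
            cos_p = np.clip((lf * lf + d * d - lt * lt) / (2 * lf * d), -1, 1)
        cos_p = np.nan_to_num(cos_p)
        beta = np.degrees(np.arctan2(w, dx)) + np.degrees(np.arccos(cos_p))
        beta = (beta + 180.0) % 360.0 - 180.0
        beta[beta == -180.0] = 180.0
        ang = np.stack([alpha, beta, gamma], axis=1)
        in_bounds = feasible & np.all((ang >= lo - 1e-9)
                                      & (ang <= hi + 1e-9), axis=1)
        take = in_bounds & ~ok
        out[take] = ang[take]
        ok |= in_bounds
    return out, ok


def fk_antenna(model: BodyModel, antenna_id: str, angles: AntennaAngles,
               fractions: Iterable[float] = (1.0,)) -> np.ndarray:
    """Points along the straight flagellum, in the head frame.

    ``fractions`` are arc-length fractions of the flagellum (0 = base,
    1 = tip); returns an (n, 3) array.
    """
    limb = model.limb(antenna_id)
    if limb.is_leg:
        raise InvalidLimbError(f"{antenna_id} is not an antenna")
    az = math.radians(angles.azimuth)
    el = math.radians(angles.elevation)
    d = np.array([
        math.cos(el) * math.cos(az),
        limb.handedness * math.cos(el) * math.sin(az),
        math.sin(el),
    ])
    fr = np.asarray(list(fractions), dtype=float)
    return limb.insertion_array + fr[:, None] * (limb.total_length * d)


def size_scaling_factor(ref_sum: float, cur_sum: float) -> float:
    """B_ref / B_curr standardization factor for body-centered coordinates."""
    if ref_sum <= 0 or cur_sum <= 0:
        raise InvalidMeasurementError(
            f"segment sums must be positive, got {ref_sum}, {cur_sum}")
    return ref_sum / cur_sum


def length_ratio_percent(a: float, b: float) -> int:
    """round(100 * a / b) as an integer percentage."""
    if b <= 0:
        raise InvalidMeasurementError(f"denominator must be positive, got {b}")
    return int(round(100.0 * a / b))
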