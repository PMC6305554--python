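"""Synthetic motion-capture-like trial generation.

Real whole-body kinematics of walking and climbing stick insects are sampled
at 200 frames per second with a marker-based system.  This module emulates
such recordings parametrically: periodic swing/stance joint-angle patterns
for the six legs, rhythmic antennal sweeps, forward body translation along a
walkway, band-limited joint-space noise, and per-animal body-size variation.
Every trial carries its generating body model and, for rod-climbing trials,
the ground-truth first limb-rod contact, so all downstream stages (volume
densities, contact detection, posture mapping) can be tested against known
truth without any experimental data.

Paradigms:

* ``walk``   - steady forward walking on a flat walkway; all legs step.
* ``search`` - body stationary at the walkway edge; front legs and antennae
  perform large-amplitude rhythmic searching, other legs keep stance.
* ``rod``    - forward walking toward a horizontal rod that spans the
  walkway at height ``h``; antennae sweep and may strike the rod.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
from scipy import signal

from .body_model import (
    ANTENNA_IDS,
    LEG_IDS,
    AntennaAngles,
    BodyModel,
    LegAngles,
    SegmentPose,
    fk_antenna,
    fk_leg,
    leg_joint_ranges,
    standard_body,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Trial",
    "RodSpec",
    "TrueContact",
    "GeneratorConfig",
    "ConfigError",
    "TrialParseError",
    "generate_walk_trial",
    "generate_search_trial",
    "generate_rod_trial",
    "write_trial",
    "read_trial",
]

_SEGMENTS = ("head", "prothorax", "mesothorax", "metathorax")


class ConfigError(ValueError):
    """Invalid generator configuration."""


class TrialParseError(ValueError):
    """Malformed trial file; message names the offending line."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


@dataclass(frozen=True)
class RodSpec:
    """Horizontal rod spanning the walkway, axis along y (perpendicular to
    the walking direction), at height ``height_mm`` above the walkway and
    longitudinal position ``x_mm``."""

    height_mm: float
    x_mm: float
    radius_mm: float = 1.0

    def distance(self, points: np.ndarray) -> np.ndarray:
        """Distance of world points (..., 3) to the rod axis."""
        p = np.asarray(points, dtype=float)
        return np.hypot(p[..., 0] - self.x_mm, p[..., 2] - self.height_mm)


@dataclass(frozen=True)
class TrueContact:
    """Generator-recorded ground truth of the first limb-rod contact."""

    limb: str
    frame: int
    fraction: float  # arc-length fraction along the limb, 0 = base, 1 = tip


@dataclass
class GeneratorConfig:
    """Tunable study conditions of the synthetic gait generator.

    Joint-angle bounds default to the per-leg physiological ranges; walking
    and searching use a fraction of each range's half-width as oscillation
    amplitude.  Noise is white Gaussian joint-angle noise low-pass filtered
    at ``noise_cutoff_hz`` (smooth, physically plausible at 200 fps).
    """

    duration_s: float = 6.0
    fps: float = 200.0
    step_freq_hz: float = 1.0
    walk_speed_mm_s: float = 20.0
    body_height_mm: float = 10.0
    walk_amplitude_frac: float = 0.35
    search_amplitude_frac: float = 0.8
    antenna_azimuth_bounds: Tuple[float, float] = (5.0, 50.0)
    antenna_elevation_bounds: Tuple[float, float] = (-10.0, 45.0)
    antenna_sweep_hz: float = 1.4
    noise_sd_deg: float = 2.0
    noise_cutoff_hz: float = 5.0
    size_jitter: float = 0.1
    rod_heights_mm: Tuple[float, ...] = (5.0, 10.0, 14.0, 18.0, 22.0, 27.0,
                                         32.0, 36.0, 43.0, 50.0)
    rod_approach_mm: float = 12.0
    n_walk_trials: int = 3
    n_search_trials: int = 2
    n_rod_trials_per_height: int = 1
    leg_ranges: Optional[Mapping[str, Mapping[str, Tuple[float, float]]]] = None

    def validate(self) -> None:
        if self.duration_s <= 0 or self.fps <= 0:
            raise ConfigError("duration and fps must be positive")
        if not (0.0 <= self.size_jitter <= 0.2):
            raise ConfigError("size_jitter must lie in [0, 0.2]")
        for frac in (self.walk_amplitude_frac, self.search_amplitude_frac):
            if not (0.0 < frac <= 1.0):
                raise ConfigError("amplitude fractions must lie in (0, 1]")
        if self.noise_cutoff_hz >= self.fps / 2:
            raise ConfigError("noise cutoff must be below Nyquist")
        for lo, hi in (self.antenna_azimuth_bounds,
                       self.antenna_elevation_bounds):
            if lo >= hi:
                raise ConfigError("antenna bounds must be increasing")

    def ranges_for(self, leg_id: str) -> Mapping[str, Tuple[float, float]]:
        if self.leg_ranges is not None and leg_id in self.leg_ranges:
            return self.leg_ranges[leg_id]
        return leg_joint_ranges(leg_id)


@dataclass
class Trial:
    """One synthetic locomotion episode.

    Per-frame content: world pose of each body segment, the three leg joint
    angles plus swing flag per leg, and the two antennal angles per antenna.
    The generating (possibly size-jittered) body model travels with the
    trial so that downstream standardization can compute the current
    animal's segment sums.
    """

    animal_id: str
    paradigm: str
    fps: float
    seed: int
    model: BodyModel
    times: np.ndarray                       # (n,) seconds
    segment_poses: Dict[str, np.ndarray]    # segment -> (n, 6) x y z yaw pitch roll
    leg_angles: Dict[str, np.ndarray]       # leg id -> (n, 3) alpha beta gamma deg
    leg_swing: Dict[str, np.ndarray]        # leg id -> (n,) bool, True = swing
    antenna_angles: Dict[str, np.ndarray]   # antenna id -> (n, 2) azimuth elevation
    rod: Optional[RodSpec] = None
    true_contact: Optional[TrueContact] = None

    def __post_init__(self):
        n = self.n_frames
        if n < 1:
            raise ValueError("trial must contain at least one frame")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        for name, arr in self.leg_angles.items():
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite angles for {name}")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def segment_pose(self, segment: str, frame: int) -> SegmentPose:
        x, y, z, yaw, pitch, roll = self.segment_poses[segment][frame]
        return SegmentPose((x, y, z), yaw, pitch, roll)

    def leg_angles_at(self, leg_id: str, frame: int) -> LegAngles:
        return LegAngles.from_array(self.leg_angles[leg_id][frame])

    def antenna_angles_at(self, antenna_id: str, frame: int) -> AntennaAngles:
        az, el = self.antenna_angles[antenna_id][frame]
        return AntennaAngles(az, el)

    def leg_boundary_positions(self, leg_id: str) -> np.ndarray:
        """World positions (n, 5, 3) of ThCx, CTr, knee, TiTa joint, tip."""
        seg = self.model.limb(leg_id).carrying_segment
        out = np.empty((self.n_frames, 5, 3))
        for i in range(self.n_frames):
            local = fk_leg(self.model, leg_id,
                           self.leg_angles_at(leg_id, i)).as_array()
            out[i] = self.segment_pose(seg, i).to_world(local)
        return out

    def antenna_tip_positions(self, antenna_id: str) -> np.ndarray:
        """World positions (n, 3) of the flagellum tip."""
        out = np.empty((self.n_frames, 3))
        for i in range(self.n_frames):
            local = fk_antenna(self.model, antenna_id,
                               self.antenna_angles_at(antenna_id, i))[0]
            out[i] = self.segment_pose("head", i).to_world(local)
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, Trial):
            return NotImplemented
        scalar = (self.animal_id == other.animal_id
                  and self.paradigm == other.paradigm
                  and self.fps == other.fps and self.seed == other.seed
                  and self.model == other.model and self.rod == other.rod
                  and self.true_contact == other.true_contact)
        if not scalar:
            return False
        if not np.array_equal(self.times, other.times):
            return False
        for a, b in ((self.segment_poses, other.segment_poses),
                     (self.leg_angles, other.leg_angles),
                     (self.leg_swing, other.leg_swing),
                     (self.antenna_angles, other.antenna_angles)):
            if a.keys() != b.keys():
                return False
            if not all(np.array_equal(a[k], b[k]) for k in a):
                return False
        return True


# --------------------------------------------------------------------------
# generation internals
# --------------------------------------------------------------------------

def _lowpass_noise(rng: np.random.Generator, n: int, fps: float,
                   cutoff_hz: float, sd: float) -> np.ndarray:
    """Band-limited Gaussian noise with the requested standard deviation."""
    if sd == 0.0 or n < 20:
        return np.zeros(n)
    white = rng.standard_normal(n)
    b, a = signal.butter(2, cutoff_hz / (fps / 2.0))
    smooth = signal.filtfilt(b, a, white)
    s = smooth.std()
    return smooth * (sd / s) if s > 0 else np.zeros(n)


_LEG_PHASE = {"L1": 0.0, "L2": 2 * math.pi / 3, "L3": 4 * math.pi / 3,
              "R1": math.pi, "R2": math.pi + 2 * math.pi / 3,
              "R3": math.pi + 4 * math.pi / 3}
_DOF_PHASE = {"alpha": 0.0, "beta": math.pi / 2, "gamma": math.pi}
_SWING_FRACTION = 1.0 / 3.0


def _leg_trajectories(cfg: GeneratorConfig, rng: np.random.Generator,
                      t: np.ndarray, legs: Tuple[str, ...],
                      amplitude_frac: float,
                      ) -> Tuple[Dict[str, np.ndarray], Dict[str, np.ndarray]]:
    """Sinusoid-plus-noise joint-angle patterns, clipped to the leg bounds."""
    omega = 2 * math.pi * cfg.step_freq_hz
    angles: Dict[str, np.ndarray] = {}
    swing: Dict[str, np.ndarray] = {}
    for leg in LEG_IDS:
        bounds = cfg.ranges_for(leg)
        out = np.empty((len(t), 3))
        for j, dof in enumerate(("alpha", "beta", "gamma")):
            lo, hi = bounds[dof]
            mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0
            if leg in legs:
                carrier = mid + amplitude_frac * half * np.sin(
                    omega * t + _LEG_PHASE[leg] + _DOF_PHASE[dof])
                carrier = carrier + _lowpass_noise(
                    rng, len(t), cfg.fps, cfg.noise_cutoff_hz, cfg.noise_sd_deg)
            else:
                # resting stance posture, slightly below mid-range
                carrier = np.full(len(t), mid - 0.2 * half)
            out[:, j] = np.clip(carrier, lo, hi)
        angles[leg] = out
        if leg in legs:
            swing[leg] = np.sin(omega * t + _LEG_PHASE[leg]) \
                > math.cos(math.pi * _SWING_FRACTION)
        else:
            swing[leg] = np.zeros(len(t), dtype=bool)
    return angles, swing


def _antenna_trajectories(cfg: GeneratorConfig, rng: np.random.Generator,
                          t: np.ndarray, amplitude_frac: float = 1.0,
                          ) -> Dict[str, np.ndarray]:
    omega = 2 * math.pi * cfg.antenna_sweep_hz
    out: Dict[str, np.ndarray] = {}
    for k, ant in enumerate(ANTENNA_IDS):
        phase = k * math.pi   # anti-phase left/right
        arr = np.empty((len(t), 2))
        for j, (lo, hi) in enumerate((cfg.antenna_azimuth_bounds,
                                      cfg.antenna_elevation_bounds)):
            mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0
            carrier = mid + amplitude_frac * half * np.sin(
                omega * t + phase + j * math.pi / 2)
            carrier = carrier + _lowpass_noise(
                rng, len(t), cfg.fps, cfg.noise_cutoff_hz,
                0.5 * cfg.noise_sd_deg)
            arr[:, j] = np.clip(carrier, lo, hi)
        out[ant] = arr
    return out


def _segment_pose_arrays(model: BodyModel, t: np.ndarray, x0: float,
                         speed: float, height: float) -> Dict[str, np.ndarray]:
    poses: Dict[str, np.ndarray] = {}
    x_body = x0 + speed * t
    for seg in _SEGMENTS:
        offset = model.segment_origin(seg)[0]
        arr = np.zeros((len(t), 6))
        arr[:, 0] = x_body + offset
        arr[:, 2] = height
        poses[seg] = arr
    return poses


def _jittered_model(base: BodyModel, cfg: GeneratorConfig,
                    rng: np.random.Generator) -> BodyModel:
    if cfg.size_jitter == 0:
        return base
    s = 1.0 + rng.uniform(-cfg.size_jitter, cfg.size_jitter)
    return base.scaled(s)


def generate_walk_trial(model: Optional[BodyModel] = None,
                        cfg: Optional[GeneratorConfig] = None,
                        seed: int = 0, animal_id: str = "synthetic",
                        ) -> Trial:
    """Steady forward walking along the walkway; all six legs step."""
    model = standard_body() if model is None else model
    cfg = GeneratorConfig() if cfg is None else cfg
    cfg.validate()
    rng = np.random.default_rng(seed)
    m = _jittered_model(model, cfg, rng)
    n = int(round(cfg.duration_s * cfg.fps))
    t = np.arange(n) / cfg.fps
    leg_angles, swing = _leg_trajectories(cfg, rng, t, LEG_IDS,
                                          cfg.walk_amplitude_frac)
    ant = _antenna_trajectories(cfg, rng, t, amplitude_frac=0.5)
    poses = _segment_pose_arrays(m, t, 0.0, cfg.walk_speed_mm_s,
                                 cfg.body_height_mm)
    return Trial(animal_id=animal_id, paradigm="walk", fps=cfg.fps, seed=seed,
                 model=m, times=t, segment_poses=poses, leg_angles=leg_angles,
                 leg_swing=swing, antenna_angles=ant)


def generate_search_trial(model: Optional[BodyModel] = None,
                          cfg: Optional[GeneratorConfig] = None,
                          seed: int = 0, animal_id: str = "synthetic",
                          ) -> Trial:
    """Stationary searching at the walkway edge: only front legs and
    antennae oscillate, with larger amplitude than during walking."""
    model = standard_body() if model is None else model
    cfg = GeneratorConfig() if cfg is None else cfg
    cfg.validate()
    rng = np.random.default_rng(seed)
    m = _jittered_model(model, cfg, rng)
    n = int(round(cfg.duration_s * cfg.fps))
    t = np.arange(n) / cfg.fps
    leg_angles, swing = _leg_trajectories(cfg, rng, t, ("L1", "R1"),
                                          cfg.search_amplitude_frac)
    ant = _antenna_trajectories(cfg, rng, t, amplitude_frac=1.0)
    poses = _segment_pose_arrays(m, t, 0.0, 0.0, cfg.body_height_mm)
    return Trial(animal_id=animal_id, paradigm="search", fps=cfg.fps,
                 seed=seed, model=m, times=t, segment_poses=poses,
                 leg_angles=leg_angles, leg_swing=swing, antenna_angles=ant)


def generate_rod_trial(model: Optional[BodyModel] = None,
                       cfg: Optional[GeneratorConfig] = None,
                       rod: Optional[RodSpec] = None,
                       seed: int = 0, animal_id: str = "synthetic",
                       rod_height_mm: float = 18.0,
                       ) -> Trial:
    """Walking toward a horizontal rod across the walkway.

    The rod's longitudinal position defaults to just beyond the antennal
    reach at trial start, so that the approach brings the sweeping antennae
    (or a front leg) into contact mid-trial.  The trial records the
    ground-truth first frame and arc-length location at which any sampled
    antennal or front-leg point comes within the rod radius (or ``None``
    when no contact occurs).
    """
    model = standard_body() if model is None else model
    cfg = GeneratorConfig() if cfg is None else cfg
    cfg.validate()
    rng = np.random.default_rng(seed)
    m = _jittered_model(model, cfg, rng)
    n = int(round(cfg.duration_s * cfg.fps))
    t = np.arange(n) / cfg.fps
    leg_angles, swing = _leg_trajectories(cfg, rng, t, LEG_IDS,
                                          cfg.walk_amplitude_frac)
    ant = _antenna_trajectories(cfg, rng, t, amplitude_frac=1.0)
    poses = _segment_pose_arrays(m, t, 0.0, cfg.walk_speed_mm_s,
                                 cfg.body_height_mm)
    if rod is None:
        head_x0 = poses["head"][0, 0]
        ant_reach = max(m.limb(a).insertion[0] + m.limb(a).total_length
                        for a in ANTENNA_IDS)
        rod = RodSpec(height_mm=rod_height_mm,
                      x_mm=head_x0 + ant_reach + cfg.rod_approach_mm)
    trial = Trial(animal_id=animal_id, paradigm="rod", fps=cfg.fps, seed=seed,
                  model=m, times=t, segment_poses=poses,
                  leg_angles=leg_angles, leg_swing=swing, antenna_angles=ant,
                  rod=rod)
    trial.true_contact = _ground_truth_contact(trial, rod)
    return trial


def _limb_sample_points(trial: Trial, limb: str, frame: int,
                        ) -> Tuple[np.ndarray, np.ndarray]:
    """World sample points and location fractions, ~1 mm resolution.

    Antennae: points along the straight flagellum, fraction 0 = base,
    1 = tip.  Legs: points along the coxa, femur, and the straight
    tibia+tarsus piece, with locations on the standardized leg axis
    (coxa = 0, femur spans [0, 0.5], tibia [0.5, 1.0), tarsus = 1.0).
    """
    m = trial.model
    lm = m.limb(limb)
    if not lm.is_leg:
        npts = int(math.ceil(lm.total_length)) + 1
        fr = np.linspace(0.0, 1.0, npts)
        local = fk_antenna(m, limb, trial.antenna_angles_at(limb, frame), fr)
        world = trial.segment_pose("head", frame).to_world(local)
        return world, fr
    jp = fk_leg(m, limb, trial.leg_angles_at(limb, frame))
    pts, fracs = [], []
    for start, end, length in ((jp.thorax_coxa, jp.coxa_trochanter, lm.coxa),
                               (jp.coxa_trochanter, jp.femur_tibia, lm.femur),
                               (jp.femur_tibia, jp.tarsus_tip,
                                lm.tibia + lm.tarsus)):
        npts = int(math.ceil(length)) + 1
        s = np.linspace(0.0, 1.0, npts)
        pts.append(start + s[:, None] * (np.asarray(end) - np.asarray(start)))
        if length == lm.coxa:
            fracs.append(np.zeros_like(s))
        elif length == lm.femur:
            fracs.append(0.5 * s)
        else:
            arc = s * length
            fracs.append(np.where(arc <= lm.tibia,
                                  0.5 + 0.5 * arc / lm.tibia, 1.0))
    local = np.vstack(pts)
    seg = lm.carrying_segment
    world = trial.segment_pose(seg, frame).to_world(local)
    return world, np.concatenate(fracs)


_CONTACT_LIMBS = ("LA", "RA", "L1", "R1")


def _ground_truth_contact(trial: Trial, rod: RodSpec) -> Optional[TrueContact]:
    """Brute-force first-contact scan over antennae and front legs."""
    for frame in range(trial.n_frames):
        best = None  # (distance, limb, fraction)
        for limb in _CONTACT_LIMBS:
            pts, fr = _limb_sample_points(trial, limb, frame)
            d = rod.distance(pts)
            dmin = d.min()
            if dmin <= rod.radius_mm:
                # ties within a limb resolved toward the most distal point
                idx = np.flatnonzero(d == dmin)[-1]
                cand = (dmin, limb, float(fr[idx]))
                if best is None or cand[0] < best[0]:
                    best = cand
        if best is not None:
            return TrueContact(limb=best[1], frame=frame, fraction=best[2])
    return None


# --------------------------------------------------------------------------
# trial files: delimited text, '#'-prefixed header, one row per frame
# --------------------------------------------------------------------------

_FORMAT_VERSION = 1


def _columns() -> Tuple[str, ...]:
    cols = ["frame", "time_s"]
    for seg in _SEGMENTS:
        cols += [f"{seg}_{c}" for c in ("x", "y", "z", "yaw", "pitch", "roll")]
    for leg in LEG_IDS:
        cols += [f"{leg}_{c}" for c in ("alpha", "beta", "gamma", "swing")]
    for a in ANTENNA_IDS:
        cols += [f"{a}_azimuth", f"{a}_elevation"]
    return tuple(cols)


def write_trial(trial: Trial, path) -> None:
    """Write a trial as commented-header CSV (lossless round trip)."""
    cols = _columns()
    with open(path, "w", encoding="utf-8") as fh:
        def meta(key, value):
            fh.write(f"# {key} = {value}\n")

        meta("format_version", _FORMAT_VERSION)
        meta("animal_id", trial.animal_id)
        meta("paradigm", trial.paradigm)
        meta("fps", repr(trial.fps))
        meta("seed", trial.seed)
        meta("n_frames", trial.n_frames)
        rod = ("none" if trial.rod is None else json.dumps(
            {"height_mm": trial.rod.height_mm, "x_mm": trial.rod.x_mm,
             "radius_mm": trial.rod.radius_mm}))
        meta("rod", rod)
        tc = ("none" if trial.true_contact is None else json.dumps(
            {"limb": trial.true_contact.limb,
             "frame": trial.true_contact.frame,
             "fraction": trial.true_contact.fraction}))
        meta("true_contact", tc)
        meta("model", trial.model.to_json())
        fh.write(",".join(cols) + "\n")
        for i in range(trial.n_frames):
            row = [str(i), _fmt(trial.times[i])]
            for seg in _SEGMENTS:
                row += [_fmt(v) for v in trial.segment_poses[seg][i]]
            for leg in LEG_IDS:
                row += [_fmt(v) for v in trial.leg_angles[leg][i]]
                row.append("1" if trial.leg_swing[leg][i] else "0")
            for a in ANTENNA_IDS:
                row += [_fmt(v) for v in trial.antenna_angles[a][i]]
            fh.write(",".join(row) + "\n")


def _fmt(v: float) -> str:
    return f"{float(v):.17g}"


def read_trial(path) -> Trial:
    """Read a trial file written by :func:`write_trial`.

    Raises :class:`TrialParseError` naming the offending line on malformed
    headers or rows.  A file whose fps differs from the canonical 200 Hz is
    accepted but flagged in the log.
    """
    meta: Dict[str, str] = {}
    cols = None
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if "=" not in line:
                    raise TrialParseError(lineno, "header line without '='")
                key, _, value = line[1:].partition("=")
                meta[key.strip()] = value.strip()
                continue
            if cols is None:
                cols = tuple(line.split(","))
                expected = _columns()
                if cols != expected:
                    missing = set(expected) - set(cols)
                    raise TrialParseError(
                        lineno, f"unexpected column header"
                        + (f" (missing: {sorted(missing)})" if missing else ""))
                continue
            parts = line.split(",")
            if len(parts) != len(cols):
                raise TrialParseError(
                    lineno, f"expected {len(cols)} fields, got {len(parts)}")
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise TrialParseError(lineno, str(exc)) from None
    for key in ("animal_id", "paradigm", "fps", "seed", "n_frames", "model"):
        if key not in meta:
            raise TrialParseError(0, f"missing header key '{key}'")
    data = np.asarray(rows, dtype=float)
    n = int(meta["n_frames"])
    if len(data) != n:
        raise TrialParseError(0, f"expected {n} rows, got {len(data)}")
    fps = float(meta["fps"])
    if fps != 200.0:
        logger.warning("trial %s has fps=%s (canonical is 200)", path, fps)

    c = 2
    poses = {}
    for seg in _SEGMENTS:
        poses[seg] = data[:, c:c + 6].copy()
        c += 6
    leg_angles, leg_swing = {}, {}
    for leg in LEG_IDS:
        leg_angles[leg] = data[:, c:c + 3].copy()
        leg_swing[leg] = data[:, c + 3].astype(bool)
        c += 4
    ant = {}
    for a in ANTENNA_IDS:
        ant[a] = data[:, c:c + 2].copy()
        c += 2

    rod = None
    if meta.get("rod", "none") != "none":
        rod = RodSpec(**json.loads(meta["rod"]))
    tc = None
    if meta.get("true_contact", "none") != "none":
        d = json.loads(meta["true_contact"])
        tc = TrueContact(limb=d["limb"], frame=int(d["frame"]),
                         fraction=float(d["fraction"]))
    return Trial(animal_id=meta["animal_id"], paradigm=meta["paradigm"],
                 fps=fps, seed=int(meta["seed"]),
                 model=BodyModel.from_json(meta["model"]),
                 times=data[:, 1].copy(), segment_poses=poses,
                 leg_angles=leg_angles, leg_swing=leg_swing,
                 antenna_angles=ant, rod=rod, true_contact=tc)
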