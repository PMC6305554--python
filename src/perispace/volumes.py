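"""Occupancy-volume estimation on a 1 mm grid.

The movement range of a limb is charted as a density over an orthogonal 3D
grid of 1 mm spacing (90x90x90 nodes, centered on the limb base).  For every
frame, a discrete set of points along the limb is computed by forward
kinematics, expressed in the carrying-segment frame relative to the limb
base, standardized by the body-size factor B_ref/B_curr, rounded to the
nearest millimeter and counted on the grid.  Distal points travel longer
arcs per joint excursion than proximal ones; to avoid overestimating
proximal densities, point k of n carries weight 2k/(n(n+1)) (proximal to
distal), so each frame contributes a total weight of 1.

Three point schemes exist per limb: the *action* scheme covers the whole
limb (8 femur + 8 tibia + 4 tarsus points for legs, 20 flagellum points for
antennae), the *contact* scheme covers the contact-prone distal part (10
points from scaling 0.67 of the tibia/flagellum out to the tarsus tip or
flagellum tip), and the *tip* scheme is the single most distal tracked point
(tibia-tarsus joint or antennal tip).

Densities are smoothed with a normalized 5x5x5 Gaussian kernel (sigma = 1
node) and thresholded at a fraction (default 1%) of the maximum density to
yield a binary volume.  Affordance volumes are node-wise intersections of
two limbs' binary volumes after registration into the common body frame of
the standardized, straight body.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .body_model import (
    BodyModel,
    InvalidLimbError,
    affordance_joint_ranges,
    fk_antenna,
    fk_leg,
    ik_leg_batch,
    size_scaling_factor,
    standard_body,
)
from .synthetic_data import Trial

__all__ = [
    "SamplingScheme",
    "VolumeGrid",
    "BinaryVolume",
    "AffordanceVolume",
    "EmptyVolumeError",
    "IncompatibleGridsError",
    "GRID_NODES",
    "GRID_SPACING_MM",
    "make_scheme",
    "point_weights",
    "gaussian_kernel",
    "limb_points",
    "accumulate_density",
    "smooth_density",
    "extract_volume",
    "intersect_volumes",
    "reachable_affordance_volume",
    "volume_ratio_percent",
    "write_grid",
    "write_binary_volume",
]

GRID_NODES = 90          # nodes per axis
GRID_SPACING_MM = 1.0
_GRID_OFFSET = 44        # node coordinate = index - offset, so coords -44..45

VOLUME_TYPES = ("action", "contact", "tip")
CONTACT_PROXIMAL_LIMIT = 0.67


class EmptyVolumeError(ValueError):
    """All-zero density grid cannot be thresholded."""


class IncompatibleGridsError(ValueError):
    """Volumes with different grid spacing cannot be intersected."""


def point_weights(n: int) -> np.ndarray:
    """Arc-length compensation weights 2k/(n(n+1)), k = 1..n; sums to 1."""
    k = np.arange(1, n + 1, dtype=float)
    return 2.0 * k / (n * (n + 1))


@dataclass(frozen=True)
class SamplingScheme:
    """Discrete limb point scheme for one volume type of one limb.

    For legs, ``femur_fractions`` / ``tibia_fractions`` / ``tarsus_fractions``
    hold per-segment arc fractions of the action scheme, while
    ``tibia_scalings`` holds the tibia-vector scaling factors of the contact
    scheme (values > 1 extend beyond the tibia onto the straight tarsus).
    Antenna schemes use ``flagellum_fractions``.  ``weights`` are ordered
    proximal to distal and sum to 1 exactly.
    """

    volume_type: str
    limb_id: str
    n: int
    weights: np.ndarray
    femur_fractions: Optional[np.ndarray] = None
    tibia_fractions: Optional[np.ndarray] = None
    tarsus_fractions: Optional[np.ndarray] = None
    tibia_scalings: Optional[np.ndarray] = None
    flagellum_fractions: Optional[np.ndarray] = None


def make_scheme(volume_type: str, limb_id: str,
                model: Optional[BodyModel] = None) -> SamplingScheme:
    """Build the point scheme of one volume type for one limb.

    Contact schemes for legs need the body model: their distal limit is
    (tibia + tarsus) / tibia, the factor by which the tibia must be scaled
    to reach the tarsus tip (between 1.33 and 1.39 depending on the leg).
    """
    if volume_type not in VOLUME_TYPES:
        raise ValueError(f"unknown volume type {volume_type!r}")
    model = standard_body() if model is None else model
    limb = model.limb(limb_id)
    if limb.is_leg:
        if volume_type == "action":
            return SamplingScheme(
                volume_type, limb_id, 20, point_weights(20),
                femur_fractions=np.linspace(0.1, 1.0, 8),
                tibia_fractions=np.linspace(0.1, 1.0, 8),
                tarsus_fractions=np.linspace(0.25, 1.0, 4))
        if volume_type == "contact":
            distal = (limb.tibia + limb.tarsus) / limb.tibia
            return SamplingScheme(
                volume_type, limb_id, 10, point_weights(10),
                tibia_scalings=np.linspace(CONTACT_PROXIMAL_LIMIT, distal, 10))
        return SamplingScheme(volume_type, limb_id, 1, point_weights(1))
    if volume_type == "action":
        return SamplingScheme(
            volume_type, limb_id, 20, point_weights(20),
            flagellum_fractions=np.linspace(0.1, 1.0, 20))
    if volume_type == "contact":
        return SamplingScheme(
            volume_type, limb_id, 10, point_weights(10),
            flagellum_fractions=np.linspace(CONTACT_PROXIMAL_LIMIT, 1.0, 10))
    return SamplingScheme(volume_type, limb_id, 1, point_weights(1),
                          flagellum_fractions=np.array([1.0]))


def limb_points(model: BodyModel, scheme: SamplingScheme, trial: Trial,
                frame: int) -> np.ndarray:
    """Scheme points (n, 3) in the carrying-segment frame for one frame."""
    limb = model.limb(scheme.limb_id)
    if limb.is_leg:
        jp = fk_leg(model, scheme.limb_id,
                    trial.leg_angles_at(scheme.limb_id, frame))
        if scheme.volume_type == "action":
            femur_vec = jp.femur_tibia - jp.coxa_trochanter
            tibia_vec = jp.tibia_tarsus - jp.femur_tibia
            tarsus_vec = jp.tarsus_tip - jp.tibia_tarsus
            return np.vstack([
                jp.coxa_trochanter + scheme.femur_fractions[:, None] * femur_vec,
                jp.femur_tibia + scheme.tibia_fractions[:, None] * tibia_vec,
                jp.tibia_tarsus + scheme.tarsus_fractions[:, None] * tarsus_vec,
            ])
        if scheme.volume_type == "contact":
            tibia_vec = jp.tibia_tarsus - jp.femur_tibia
            return jp.femur_tibia + scheme.tibia_scalings[:, None] * tibia_vec
        return jp.tibia_tarsus[None, :]
    return fk_antenna(model, scheme.limb_id,
                      trial.antenna_angles_at(scheme.limb_id, frame),
                      scheme.flagellum_fractions)


@dataclass
class VolumeGrid:
    """Weighted occupancy density on the limb-base-centered 1 mm grid."""

    limb_id: str
    scheme: SamplingScheme
    density: np.ndarray                     # (90, 90, 90) float64, >= 0
    frames_accumulated: int = 0
    leakage_weight: float = 0.0             # weight fallen outside the extent
    smoothed: bool = False
    spacing_mm: float = GRID_SPACING_MM

    @property
    def total_density(self) -> float:
        return float(self.density.sum())

    def node_coords(self) -> np.ndarray:
        """Integer mm coordinates (N, 3) of the nonzero nodes."""
        idx = np.argwhere(self.density > 0)
        return idx - _GRID_OFFSET

    def copy(self) -> "VolumeGrid":
        return VolumeGrid(self.limb_id, self.scheme, self.density.copy(),
                          self.frames_accumulated, self.leakage_weight,
                          self.smoothed, self.spacing_mm)


@dataclass(frozen=True)
class BinaryVolume:
    """Suprathreshold node set of one limb volume, in limb-base coordinates."""

    limb_id: str
    volume_type: str
    nodes: np.ndarray                       # (N, 3) integer mm coordinates
    threshold: float
    retained_fraction: float
    spacing_mm: float = GRID_SPACING_MM

    @property
    def size_ccm(self) -> float:
        """Volume in cubic centimeters (1 mm^3 per node)."""
        return len(self.nodes) * self.spacing_mm ** 3 / 1000.0

    def node_set(self) -> set:
        return set(map(tuple, np.asarray(self.nodes, dtype=int)))


@dataclass(frozen=True)
class AffordanceVolume:
    """Intersection of two limbs' volumes, in common body-frame coordinates."""

    limb_pair: Tuple[str, str]
    nodes: np.ndarray                       # (N, 3) integer mm, body frame
    spacing_mm: float = GRID_SPACING_MM

    @property
    def size_ccm(self) -> float:
        return len(self.nodes) * self.spacing_mm ** 3 / 1000.0

    def node_set(self) -> set:
        return set(map(tuple, np.asarray(self.nodes, dtype=int)))


def accumulate_density(trials: Sequence[Trial], limb_id: str,
                       scheme: Optional[SamplingScheme] = None,
                       ref_model: Optional[BodyModel] = None,
                       volume_type: str = "action") -> VolumeGrid:
    """Accumulate weighted limb-point counts over all frames of all trials.

    Points are computed in the carrying-segment frame of each trial's own
    (current-animal) model, taken relative to the limb base, standardized by
    B_ref/B_curr, rounded to the nearest millimeter and added to the grid.
    Weight falling outside the 90^3 extent is counted as leakage.
    """
    if not trials:
        raise ValueError("need at least one trial")
    ref_model = standard_body() if ref_model is None else ref_model
    if scheme is None:
        scheme = make_scheme(volume_type, limb_id, ref_model)
    density = np.zeros((GRID_NODES,) * 3)
    frames = 0
    leak = 0.0
    ref_sum = ref_model.limb_pair_segment_sum(limb_id)
    for trial in trials:
        try:
            m = trial.model
            m.limb(limb_id)
        except InvalidLimbError:
            raise InvalidLimbError(
                f"limb {limb_id} missing from trial {trial.animal_id}")
        factor = size_scaling_factor(ref_sum, m.limb_pair_segment_sum(limb_id))
        base = m.limb(limb_id).insertion_array
        for i in range(trial.n_frames):
            pts = (limb_points(m, scheme, trial, i) - base) * factor
            nodes = np.rint(pts).astype(int) + _GRID_OFFSET
            inside = np.all((nodes >= 0) & (nodes < GRID_NODES), axis=1)
            if not inside.all():
                leak += float(scheme.weights[~inside].sum())
            sel = nodes[inside]
            np.add.at(density, (sel[:, 0], sel[:, 1], sel[:, 2]),
                      scheme.weights[inside])
            frames += 1
    return VolumeGrid(limb_id=limb_id, scheme=scheme, density=density,
                      frames_accumulated=frames, leakage_weight=leak)


def gaussian_kernel(size: int = 5, sigma: float = 1.0) -> np.ndarray:
    """Normalized cubic Gaussian kernel (size^3 support, unit weight sum)."""
    half = (size - 1) / 2.0
    ax = np.arange(size) - half
    g1 = np.exp(-0.5 * (ax / sigma) ** 2)
    k = g1[:, None, None] * g1[None, :, None] * g1[None, None, :]
    return k / k.sum()


def smooth_density(grid: VolumeGrid, size: int = 5,
                   sigma: float = 1.0) -> VolumeGrid:
    """Convolve the density with the normalized Gaussian kernel.

    The kernel is truncated at the grid edge without renormalization; any
    density smoothed out of the extent is added to the grid's leakage.
    """
    before = grid.total_density
    smoothed = ndimage.convolve(grid.density, gaussian_kernel(size, sigma),
                                mode="constant", cval=0.0)
    out = grid.copy()
    out.density = smoothed
    out.smoothed = True
    out.leakage_weight = grid.leakage_weight + (before - float(smoothed.sum()))
    return out


def extract_volume(grid: VolumeGrid, frac: float = 0.01) -> BinaryVolume:
    """Threshold a smoothed density at ``frac`` of its maximum.

    Nodes with density >= frac * max are retained (ties kept).  Reports the
    retained-density fraction, i.e. the share of the summed density carried
    by the suprathreshold nodes.
    """
    if not (0.0 < frac < 1.0):
        raise ValueError("frac must lie in (0, 1)")
    total = grid.total_density
    if total <= 0.0:
        raise EmptyVolumeError(f"{grid.limb_id}: all-zero density grid")
    threshold = frac * float(grid.density.max())
    mask = grid.density >= threshold
    retained = float(grid.density[mask].sum()) / total
    nodes = np.argwhere(mask) - _GRID_OFFSET
    return BinaryVolume(limb_id=grid.limb_id,
                        volume_type=grid.scheme.volume_type, nodes=nodes,
                        threshold=threshold, retained_fraction=retained,
                        spacing_mm=grid.spacing_mm)


def intersect_volumes(a: BinaryVolume, b: BinaryVolume,
                      model: Optional[BodyModel] = None) -> AffordanceVolume:
    """Affordance volume: node-wise intersection in the common body frame.

    Each volume's limb-base-centered nodes are translated by the
    standardized insertion position of its limb (rigid straight body) and
    re-gridded onto the integer body-frame lattice before intersecting.
    """
    if a.spacing_mm != b.spacing_mm:
        raise IncompatibleGridsError(
            f"spacing {a.spacing_mm} != {b.spacing_mm}")
    model = standard_body() if model is None else model
    set_a = _body_frame_nodes(a, model)
    set_b = _body_frame_nodes(b, model)
    common = set_a & set_b
    nodes = (np.array(sorted(common), dtype=int)
             if common else np.empty((0, 3), dtype=int))
    return AffordanceVolume(limb_pair=(a.limb_id, b.limb_id), nodes=nodes,
                            spacing_mm=a.spacing_mm)


def _body_frame_nodes(vol: BinaryVolume, model: BodyModel) -> set:
    base = model.limb_base(vol.limb_id)
    shifted = np.rint(np.asarray(vol.nodes, dtype=float) + base).astype(int)
    return set(map(tuple, shifted))


def reachable_affordance_volume(leg_a: str, leg_b: str,
                                model: Optional[BodyModel] = None,
                                spacing: float = GRID_SPACING_MM,
                                ) -> AffordanceVolume:
    """Geometric affordance volume of two legs of the standardized body.

    The set of body-frame grid nodes (``spacing`` mm apart) reachable by
    the tibia-tarsus joint of *both* legs with joint angles inside their
    affordance-conditioned bounds.  This is the idealized counterpart of
    the occupancy-based affordance volume: it depends only on the
    kinematics and the joint ranges, not on any recorded posture
    distribution, and is the natural sampling domain for posture-pair
    datasets (a sub-millimeter spacing densifies the dataset without
    changing the volume).
    """
    model = standard_body() if model is None else model
    bases = {}
    reach = {}
    for leg in (leg_a, leg_b):
        lm = model.limb(leg)
        if not lm.is_leg:
            raise InvalidLimbError(f"{leg} is not a leg")
        bases[leg] = model.limb_base(leg)
        reach[leg] = lm.coxa + lm.femur + lm.tibia
    lo = np.floor(np.minimum(bases[leg_a], bases[leg_b])
                  - max(reach.values())).astype(int)
    hi = np.ceil(np.maximum(bases[leg_a], bases[leg_b])
                 + max(reach.values())).astype(int)
    axes = [np.arange(lo[i], hi[i] + spacing, spacing) for i in range(3)]
    nodes = np.stack(np.meshgrid(*axes, indexing="ij"),
                     axis=-1).reshape(-1, 3).astype(float)
    # cheap prefilter: inside both legs' outer reach spheres
    mask = np.ones(len(nodes), dtype=bool)
    for leg in (leg_a, leg_b):
        mask &= np.linalg.norm(nodes - bases[leg], axis=1) <= reach[leg] + 1.0
    nodes = nodes[mask]
    ok = np.ones(len(nodes), dtype=bool)
    for leg, partner in ((leg_a, leg_b), (leg_b, leg_a)):
        lm = model.limb(leg)
        targets = nodes - bases[leg] + lm.insertion_array
        _, leg_ok = ik_leg_batch(model, leg, targets,
                                 bounds=affordance_joint_ranges(leg, partner))
        ok &= leg_ok
    return AffordanceVolume(limb_pair=(leg_a, leg_b), nodes=nodes[ok],
                            spacing_mm=spacing)


def volume_ratio_percent(part, whole) -> int:
    """round(100 * size(part) / size(whole)) as an integer percentage."""
    if whole.size_ccm <= 0:
        raise ValueError("whole volume is empty")
    return int(round(100.0 * part.size_ccm / whole.size_ccm))


# --------------------------------------------------------------------------
# text export
# --------------------------------------------------------------------------

def write_grid(grid: VolumeGrid, path) -> None:
    """Export nonzero grid nodes as '# header' + 'x y z density' rows."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# limb = {grid.limb_id}\n")
        fh.write(f"# volume_type = {grid.scheme.volume_type}\n")
        fh.write(f"# spacing_mm = {grid.spacing_mm}\n")
        fh.write(f"# extent = {GRID_NODES}\n")
        fh.write(f"# frames = {grid.frames_accumulated}\n")
        fh.write(f"# leakage_weight = {grid.leakage_weight!r}\n")
        fh.write(f"# smoothed = {grid.smoothed}\n")
        fh.write("x y z density\n")
        for (i, j, k) in np.argwhere(grid.density > 0):
            fh.write(f"{i - _GRID_OFFSET} {j - _GRID_OFFSET} "
                     f"{k - _GRID_OFFSET} {grid.density[i, j, k]!r}\n")


def write_binary_volume(vol: BinaryVolume, path) -> None:
    """Export a binary volume in the grid text format with density 1."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# limb = {vol.limb_id}\n")
        fh.write(f"# volume_type = {vol.volume_type}\n")
        fh.write(f"# spacing_mm = {vol.spacing_mm}\n")
        fh.write(f"# threshold = {vol.threshold!r}\n")
        fh.write(f"# retained_fraction = {vol.retained_fraction!r}\n")
        fh.write(f"# size_ccm = {vol.size_ccm!r}\n")
        fh.write("x y z density\n")
        for (x, y, z) in np.asarray(vol.nodes, dtype=int):
            fh.write(f"{x} {y} {z} 1\n")
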