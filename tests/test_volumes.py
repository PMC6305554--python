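"""Volume-density engine: weights, accumulation, smoothing, thresholding,
intersection — each checked against naive reference implementations."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perispace.body_model import LEG_IDS, standard_body
from perispace.synthetic_data import GeneratorConfig, generate_walk_trial
from perispace.volumes import (
    GRID_NODES,
    AffordanceVolume,
    BinaryVolume,
    EmptyVolumeError,
    IncompatibleGridsError,
    VolumeGrid,
    accumulate_density,
    extract_volume,
    gaussian_kernel,
    intersect_volumes,
    limb_points,
    make_scheme,
    point_weights,
    reachable_affordance_volume,
    smooth_density,
    volume_ratio_percent,
)

_OFFSET = 44  # node coordinate = index - offset


# --------------------------------------------------------------------------
# weights and schemes
# --------------------------------------------------------------------------

@given(st.integers(min_value=1, max_value=100))
@settings(deadline=None)
def test_weight_normalization_closed_form(n):
    w = point_weights(n)
    assert len(w) == n
    assert abs(w.sum() - 1.0) < 1e-12
    assert np.all(np.diff(w) > 0) or n == 1   # distal points weigh more


def test_weights_example_n10():
    w = point_weights(10)
    assert np.allclose(w, 2 * np.arange(1, 11) / 110.0)


def test_make_scheme_point_counts(model):
    for leg in ("L1", "L3"):
        assert make_scheme("action", leg, model).n == 20
        assert make_scheme("contact", leg, model).n == 10
        tip = make_scheme("tip", leg, model)
        assert tip.n == 1 and np.array_equal(tip.weights, [1.0])
    ant = make_scheme("action", "LA", model)
    assert ant.n == 20 and len(ant.flagellum_fractions) == 20


def test_contact_scheme_distal_limit(model):
    """The tibia must be scaled by (tibia+tarsus)/tibia to reach the
    tarsus tip; for the left middle leg that is 1.387."""
    s = make_scheme("contact", "L2", model)
    assert s.tibia_scalings[0] == pytest.approx(0.67)
    assert s.tibia_scalings[-1] == pytest.approx((11.64 + 4.51) / 11.64)
    assert s.tibia_scalings[-1] == pytest.approx(1.387, abs=5e-4)


# --------------------------------------------------------------------------
# accumulation
# --------------------------------------------------------------------------

def _static_trial(model, n_frames, angles=None):
    """A trial holding one posture for n frames (no noise, no motion)."""
    cfg = GeneratorConfig(duration_s=n_frames / 200.0, noise_sd_deg=0.0,
                          size_jitter=0.0)
    t = generate_walk_trial(model, cfg, seed=0)
    for leg in LEG_IDS:
        t.leg_angles[leg][:] = t.leg_angles[leg][0] if angles is None \
            else angles
    return t


def test_single_frame_tip_density(model):
    t = _static_trial(model, 1)
    grid = accumulate_density([t], "L1", ref_model=model, volume_type="tip")
    assert grid.total_density == pytest.approx(1.0)
    assert (grid.density > 0).sum() == 1
    assert grid.density.max() == pytest.approx(1.0)


def test_static_posture_conserves_density(model):
    f = 17
    t = _static_trial(model, f)
    grid = accumulate_density([t], "L2", ref_model=model,
                              volume_type="action")
    assert grid.total_density == pytest.approx(f)
    assert grid.frames_accumulated == f
    single = accumulate_density([_static_trial(model, 1)], "L2",
                                ref_model=model, volume_type="action")
    assert np.array_equal(grid.density > 0, single.density > 0)


def test_accumulation_matches_brute_force_tally(model, walk_trial):
    """Node densities equal an independent per-point python tally."""
    scheme = make_scheme("action", "L1", model)
    grid = accumulate_density([walk_trial], "L1", scheme, model)
    base = walk_trial.model.limb("L1").insertion_array
    ref_sum = model.limb_pair_segment_sum("L1")
    factor = ref_sum / walk_trial.model.limb_pair_segment_sum("L1")
    tally = {}
    for i in range(walk_trial.n_frames):
        pts = (limb_points(walk_trial.model, scheme, walk_trial, i)
               - base) * factor
        for p, w in zip(pts, scheme.weights):
            key = tuple(int(v) for v in np.rint(p))
            tally[key] = tally.get(key, 0.0) + w
    assert grid.leakage_weight == 0.0
    for key, val in tally.items():
        idx = tuple(k + _OFFSET for k in key)
        assert grid.density[idx] == pytest.approx(val, abs=1e-9)
    assert grid.total_density == pytest.approx(sum(tally.values()))


def test_scale_invariance_under_standardization(model, small_cfg):
    """A uniformly scaled animal yields the identical standardized grid."""
    cfg = dataclasses.replace(small_cfg, size_jitter=0.0)
    t = generate_walk_trial(model, cfg, seed=4)
    t_big = dataclasses.replace(t, model=t.model.scaled(1.17))
    g1 = accumulate_density([t], "L3", ref_model=model, volume_type="action")
    g2 = accumulate_density([t_big], "L3", ref_model=model,
                            volume_type="action")
    assert np.array_equal(g1.density, g2.density)


# --------------------------------------------------------------------------
# smoothing
# --------------------------------------------------------------------------

def test_kernel_center_weight_closed_form():
    k = gaussian_kernel(5, 1.0)
    ax = np.arange(5) - 2.0
    g = np.exp(-0.5 * ax ** 2)
    total = g.sum() ** 3
    assert k[2, 2, 2] == pytest.approx(1.0 / total)
    assert k.sum() == pytest.approx(1.0)


def test_interior_point_mass_conserved(model):
    scheme = make_scheme("tip", "L1", model)
    grid = VolumeGrid("L1", scheme, np.zeros((GRID_NODES,) * 3))
    grid.density[40, 40, 40] = 1.0
    sm = smooth_density(grid)
    assert sm.total_density == pytest.approx(1.0, abs=1e-9)
    assert sm.leakage_weight == pytest.approx(0.0, abs=1e-9)
    # edge mass leaks and the leakage is reported
    grid2 = VolumeGrid("L1", scheme, np.zeros((GRID_NODES,) * 3))
    grid2.density[0, 0, 0] = 1.0
    sm2 = smooth_density(grid2)
    assert sm2.total_density < 1.0
    assert sm2.leakage_weight == pytest.approx(1.0 - sm2.total_density)


def test_uniform_grid_unchanged_in_interior(model):
    scheme = make_scheme("tip", "L1", model)
    grid = VolumeGrid("L1", scheme, np.full((GRID_NODES,) * 3, 0.37))
    sm = smooth_density(grid)
    interior = sm.density[5:-5, 5:-5, 5:-5]
    assert np.max(np.abs(interior - 0.37)) < 1e-12


# --------------------------------------------------------------------------
# thresholding
# --------------------------------------------------------------------------

def test_uniform_grid_fully_retained(model):
    scheme = make_scheme("tip", "L1", model)
    grid = VolumeGrid("L1", scheme, np.full((GRID_NODES,) * 3, 0.2),
                      smoothed=True)
    bv = extract_volume(grid)
    assert len(bv.nodes) == GRID_NODES ** 3
    assert bv.retained_fraction == pytest.approx(1.0)
    assert bv.size_ccm == pytest.approx(GRID_NODES ** 3 / 1000.0)


def test_threshold_matches_brute_force_on_point_mass(model):
    scheme = make_scheme("tip", "L1", model)
    grid = VolumeGrid("L1", scheme, np.zeros((GRID_NODES,) * 3))
    grid.density[44, 44, 44] = 1.0
    sm = smooth_density(grid)
    bv = extract_volume(sm, frac=0.01)
    kernel = gaussian_kernel(5, 1.0)
    expected = {(dx, dy, dz)
                for dx in range(-2, 3) for dy in range(-2, 3)
                for dz in range(-2, 3)
                if kernel[dx + 2, dy + 2, dz + 2] >= 0.01 * kernel.max()}
    assert bv.node_set() == expected


def test_threshold_monotonicity(model):
    rng = np.random.default_rng(0)
    scheme = make_scheme("tip", "L1", model)
    grid = VolumeGrid("L1", scheme, rng.random((GRID_NODES,) * 3) ** 4,
                      smoothed=True)
    sizes = [len(extract_volume(grid, f).nodes)
             for f in (0.001, 0.01, 0.1, 0.5, 0.9)]
    assert sizes == sorted(sizes, reverse=True)


def test_empty_grid_raises(model):
    scheme = make_scheme("tip", "L1", model)
    grid = VolumeGrid("L1", scheme, np.zeros((GRID_NODES,) * 3))
    with pytest.raises(EmptyVolumeError):
        extract_volume(grid)


# --------------------------------------------------------------------------
# whole-chain oracle on a tiny fixture
# --------------------------------------------------------------------------

def _naive_chain(points_per_frame, weights, frac=0.01):
    """Reference accumulate->smooth->threshold on a dict, pure python."""
    density = {}
    for pts in points_per_frame:
        for p, w in zip(pts, weights):
            key = tuple(int(v) for v in np.rint(p))
            density[key] = density.get(key, 0.0) + w
    ax = np.arange(5) - 2.0
    g1 = np.exp(-0.5 * ax ** 2)
    kern = g1[:, None, None] * g1[None, :, None] * g1[None, None, :]
    kern /= kern.sum()
    smoothed = {}
    for (x, y, z), w in density.items():
        for dx in range(-2, 3):
            for dy in range(-2, 3):
                for dz in range(-2, 3):
                    key = (x + dx, y + dy, z + dz)
                    smoothed[key] = smoothed.get(key, 0.0) \
                        + w * kern[dx + 2, dy + 2, dz + 2]
    mx = max(smoothed.values())
    return {k: v for k, v in smoothed.items() if v >= frac * mx}


def test_full_chain_matches_naive_reference(model, small_cfg):
    """accumulate -> smooth -> threshold agrees node-for-node with the
    naive per-point reference implementation on a 5-frame fixture."""
    cfg = dataclasses.replace(small_cfg, duration_s=5 / 200.0,
                              size_jitter=0.0)
    t = generate_walk_trial(model, cfg, seed=8)
    scheme = make_scheme("action", "L2", model)
    grid = accumulate_density([t], "L2", scheme, model)
    sm = smooth_density(grid)
    bv = extract_volume(sm, frac=0.01)
    base = t.model.limb("L2").insertion_array
    factor = (model.limb_pair_segment_sum("L2")
              / t.model.limb_pair_segment_sum("L2"))
    frames = [(limb_points(t.model, scheme, t, i) - base) * factor
              for i in range(t.n_frames)]
    expected = _naive_chain(frames, scheme.weights, frac=0.01)
    assert bv.node_set() == set(expected)
    for key, val in expected.items():
        idx = tuple(k + _OFFSET for k in key)
        assert sm.density[idx] == pytest.approx(val, abs=1e-9)


# --------------------------------------------------------------------------
# intersection / affordance volumes
# --------------------------------------------------------------------------

def _bv(limb, nodes):
    return BinaryVolume(limb_id=limb, volume_type="action",
                        nodes=np.asarray(nodes, dtype=int), threshold=0.1,
                        retained_fraction=0.99)


def test_intersection_idempotent_commutative_and_subset(model):
    rng = np.random.default_rng(1)
    a_nodes = rng.integers(-10, 10, size=(200, 3))
    b_nodes = rng.integers(-10, 10, size=(200, 3))
    a, b = _bv("L2", a_nodes), _bv("L3", b_nodes)
    ab = intersect_volumes(a, b, model)
    ba = intersect_volumes(b, a, model)
    assert ab.node_set() == ba.node_set()
    # subset of both parents after registration
    for v in (a, b):
        base = model.limb_base(v.limb_id)
        parent = set(map(tuple, np.rint(v.nodes + base).astype(int)))
        assert ab.node_set() <= parent
    same = intersect_volumes(a, _bv("L2", a_nodes), model)
    base = model.limb_base("L2")
    assert same.node_set() == set(map(tuple,
                                      np.rint(a_nodes + base).astype(int)))


def test_disjoint_volumes_give_empty_affordance(model):
    a = _bv("L2", [[30, 30, 30]])
    b = _bv("L3", [[-30, -30, -30]])
    ab = intersect_volumes(a, b, model)
    assert len(ab.nodes) == 0 and ab.size_ccm == 0.0


def test_incompatible_spacing_rejected(model):
    a = _bv("L2", [[0, 0, 0]])
    b = BinaryVolume(limb_id="L3", volume_type="action",
                     nodes=np.zeros((1, 3), dtype=int), threshold=0.1,
                     retained_fraction=0.99, spacing_mm=2.0)
    with pytest.raises(IncompatibleGridsError):
        intersect_volumes(a, b, model)


def test_volume_ratio_percent_published_examples(model):
    """The ratio operator reproduces the published table percentages."""
    whole = _bv("L1", np.zeros((60786, 3)))
    part = _bv("LA", np.zeros((8736, 3)))
    assert volume_ratio_percent(part, whole) == 14
    whole2 = _bv("L2", np.zeros((19937, 3)))
    part2 = _bv("L1", np.zeros((6423, 3)))
    assert volume_ratio_percent(part2, whole2) == 32
    assert volume_ratio_percent(whole, whole) == 100
    with pytest.raises(ValueError):
        volume_ratio_percent(part, _bv("L1", np.zeros((0, 3))))


def test_reachable_affordance_volume_basic(model):
    av = reachable_affordance_volume("L2", "L3", model)
    assert len(av.nodes) > 500
    assert av.limb_pair == ("L2", "L3")
    # every node within both legs' outer reach spheres
    for leg in ("L2", "L3"):
        lm = model.limb(leg)
        d = np.linalg.norm(av.nodes - model.limb_base(leg), axis=1)
        assert d.max() <= lm.coxa + lm.femur + lm.tibia + 1e-9
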