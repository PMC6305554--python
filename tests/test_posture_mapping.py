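"""Posture-pair datasets, the regression baseline, and the hidden-layer
network: parameter recovery, gradient correctness, containment, determinism."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LinearRegression

from perispace.body_model import (
    LegAngles,
    affordance_joint_ranges,
    fk_leg,
    ik_leg,
    standard_body,
)
from perispace.posture_mapping import (
    MLP,
    EmptyDatasetError,
    MLPConfig,
    PosturePairDataset,
    TrainResult,
    build_pairs,
    complexity_sweep,
    fit_linear,
    split_dataset,
    train_mlp,
)
from perispace.volumes import AffordanceVolume, reachable_affordance_volume


@pytest.fixture(scope="module")
def affordance(model):
    """A thinned middle-hind affordance volume (fast unit-test fixture)."""
    av = reachable_affordance_volume("L2", "L3", model)
    return AffordanceVolume(limb_pair=av.limb_pair, nodes=av.nodes[::3],
                            spacing_mm=av.spacing_mm)


@pytest.fixture(scope="module")
def pair_dataset(model, affordance):
    return build_pairs(affordance, "L2", "L3", model)


def _synthetic_dataset(n, seed=0, W=None, b=None, noise=0.0):
    """Dataset with a planted affine (or noisy affine) sender->receiver map."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(-60, 60, size=(n, 3))
    W = np.eye(3) if W is None else np.asarray(W)
    b = np.zeros(3) if b is None else np.asarray(b)
    Y = X @ W + b + noise * rng.standard_normal((n, 3))
    return PosturePairDataset("L2", "L3", X, Y, np.zeros((n, 3)),
                              np.zeros((n, 3), dtype=int))


class TestBuildPairs:
    def test_pairs_share_the_foot_position(self, model, pair_dataset):
        """fk of both triplets places the tibia-tarsus joint on the node."""
        ds = pair_dataset
        for i in range(0, len(ds), 29):
            node = ds.foot_positions[i]
            for leg, ang in (("L2", ds.sender_angles[i]),
                             ("L3", ds.receiver_angles[i])):
                local = fk_leg(model, leg, LegAngles(*ang)).tibia_tarsus
                world = local - model.limb(leg).insertion_array \
                    + model.limb_base(leg)
                assert np.linalg.norm(world - node) < 1e-6

    def test_angles_within_affordance_bounds(self, pair_dataset):
        for leg, arr in (("L2", pair_dataset.sender_angles),
                         ("L3", pair_dataset.receiver_angles)):
            b = affordance_joint_ranges(leg, "L3" if leg == "L2" else "L2")
            for j, dof in enumerate(("alpha", "beta", "gamma")):
                lo, hi = b[dof]
                assert arr[:, j].min() >= lo - 1e-6
                assert arr[:, j].max() <= hi + 1e-6
            assert np.all(arr[:, 2] > 0) and np.all(arr[:, 2] < 180)

    def test_size_equals_independent_reachability_scan(self, model,
                                                       affordance,
                                                       pair_dataset):
        """Dataset size equals a scalar per-node double-reachability scan."""
        count = 0
        for node in affordance.nodes:
            ok = True
            for leg, partner in (("L2", "L3"), ("L3", "L2")):
                target = (np.asarray(node) - model.limb_base(leg)
                          + model.limb(leg).insertion_array)
                try:
                    ang = ik_leg(model, leg, target,
                                 bounds=affordance_joint_ranges(leg, partner))
                except Exception:
                    ok = False
                    break
                if not ang.within(affordance_joint_ranges(leg, partner),
                                  tol=1e-9):
                    ok = False
                    break
            count += ok
        assert len(pair_dataset) == count
        assert len(pair_dataset) + pair_dataset.dropped_nodes == \
            len(affordance.nodes)

    def test_empty_affordance_raises(self, model):
        empty = AffordanceVolume(limb_pair=("L2", "L3"),
                                 nodes=np.empty((0, 3)))
        with pytest.raises(EmptyDatasetError):
            build_pairs(empty, "L2", "L3", model)

    def test_reversed_swaps_direction(self, pair_dataset):
        rev = pair_dataset.reversed()
        assert len(rev) == len(pair_dataset)
        assert rev.sender_leg == "L3" and rev.receiver_leg == "L2"
        assert pair_dataset.direction == "front-to-back"
        assert rev.direction == "back-to-front"
        assert np.array_equal(rev.sender_angles,
                              pair_dataset.receiver_angles)


class TestSplit:
    @pytest.mark.parametrize("n,expected", [(5500, 4400), (8382, 6705),
                                            (10, 8)])
    def test_train_size_is_floor_of_80_percent(self, n, expected):
        ds = _synthetic_dataset(n)
        train, test = split_dataset(ds, seed=1)
        assert len(train) == expected
        assert len(train) + len(test) == n

    def test_partition_is_disjoint_and_complete(self):
        ds = _synthetic_dataset(10, seed=3)
        train, test = split_dataset(ds, seed=5)
        rows = {tuple(r) for r in np.vstack([train.sender_angles,
                                             test.sender_angles])}
        assert rows == {tuple(r) for r in ds.sender_angles}

    def test_too_small_dataset_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(_synthetic_dataset(4), seed=0)


class TestLinear:
    def test_planted_affine_map_recovered(self):
        W = np.array([[0.8, -0.3, 0.1], [0.2, 1.1, -0.4], [0.0, 0.5, 0.9]])
        b = np.array([5.0, -12.0, 3.3])
        ds = _synthetic_dataset(400, seed=2, W=W, b=b)
        train, test = split_dataset(ds, seed=0)
        lin, res = fit_linear(train, test)
        assert np.max(np.abs(lin.W - W)) < 1e-8
        assert np.max(np.abs(lin.b - b)) < 1e-8
        assert res.mean_mse < 1e-12

    def test_matches_sklearn(self):
        ds = _synthetic_dataset(300, seed=4, W=np.eye(3), b=None, noise=8.0)
        train, test = split_dataset(ds, seed=0)
        lin, res = fit_linear(train, test)
        sk = LinearRegression().fit(train.sender_angles,
                                    train.receiver_angles)
        assert np.allclose(lin.W, sk.coef_.T, atol=1e-8)
        assert np.allclose(lin.b, sk.intercept_, atol=1e-8)
        sk_mse = np.mean((sk.predict(test.sender_angles)
                          - test.receiver_angles) ** 2)
        assert res.mean_mse == pytest.approx(sk_mse, rel=1e-10)

    def test_constant_target_gives_mean_and_variance(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(-50, 50, (200, 3))
        Y = np.tile([10.0, -20.0, 35.0], (200, 1))
        ds = PosturePairDataset("L2", "L3", X, Y, np.zeros((200, 3)),
                                np.zeros((200, 3), dtype=int))
        train, test = split_dataset(ds, seed=0)
        lin, res = fit_linear(train, test)
        assert np.max(np.abs(lin.W)) < 1e-10
        assert np.allclose(lin.b, [10.0, -20.0, 35.0])
        assert res.mean_mse < 1e-18

    def test_result_consistency_mean_and_rmse(self):
        res = TrainResult.from_per_dof(np.array([34.5, 45.3, 103.1]),
                                       pd.DataFrame())
        assert res.mean_mse == pytest.approx((34.5 + 45.3 + 103.1) / 3)
        assert round(res.mean_mse, 1) == 61.0
        assert res.rmse == math.sqrt(res.mean_mse)


class TestMLP:
    def test_gradients_match_finite_differences(self):
        """Backprop gradients agree with central differences to 1e-5
        (checked at unit scale where the difference quotient is accurate)."""
        rng = np.random.default_rng(0)
        X = rng.uniform(-2, 2, (5, 3))
        Y = rng.uniform(-2, 2, (5, 3))
        net = MLP(4, True, X.mean(0), X.std(0), rng,
                  y_mean=Y.mean(0), y_std=Y.std(0))
        _, grads = net.gradients(X, Y)
        params = net.parameters()
        eps = 1e-6
        for p, g in zip(params, grads):
            it = np.nditer(p, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = p[idx]
                p[idx] = orig + eps
                lp, _ = net.gradients(X, Y)
                p[idx] = orig - eps
                lm, _ = net.gradients(X, Y)
                p[idx] = orig
                num = (lp - lm) / (2 * eps)
                denom = max(abs(num), abs(g[idx]), 1e-2)
                assert abs(num - g[idx]) / denom < 1e-5

    def test_seeded_training_is_bitwise_deterministic(self):
        ds = _synthetic_dataset(80, seed=1, noise=5.0)
        train, test = split_dataset(ds, seed=0)
        cfg = MLPConfig(hidden_size=3, epochs=20, seed=9, curve_stride=5)
        net1, r1 = train_mlp(train, test, cfg)
        net2, r2 = train_mlp(train, test, cfg)
        assert r1.learning_curve.equals(r2.learning_curve)
        for p1, p2 in zip(net1.parameters(), net2.parameters()):
            assert np.array_equal(p1, p2)

    def test_skip_network_contains_the_regression_solution(self,
                                                           pair_dataset):
        """With hidden->output weights zeroed and the skip path set to the
        fitted affine map, the network reproduces the regression MSE."""
        train, test = split_dataset(pair_dataset, seed=0)
        lin, res = fit_linear(train, test)
        rng = np.random.default_rng(0)
        net = MLP(4, True, train.sender_angles.mean(0),
                  train.sender_angles.std(0), rng,
                  y_mean=train.receiver_angles.mean(0),
                  y_std=train.receiver_angles.std(0))
        net.set_affine(lin)
        mse = np.mean((net.forward(test.sender_angles)
                       - test.receiver_angles) ** 2)
        assert mse == pytest.approx(res.mean_mse, rel=1e-9)

    def test_skip_net_reaches_regression_floor_on_linear_target(self):
        """On a noiseless affine target a fully trained skip network
        matches the (here ~zero) regression floor within 0.1 deg^2."""
        W = np.array([[1.2, 0.1, 0.0], [-0.2, 0.9, 0.3], [0.1, 0.0, 1.1]])
        ds = _synthetic_dataset(150, seed=5, W=W, b=np.array([3.0, -4, 8]))
        train, test = split_dataset(ds, seed=0)
        _, lin_res = fit_linear(train, test)
        cfg = MLPConfig(hidden_size=8, skip_connections=True, epochs=5000,
                        seed=2, curve_stride=1000)
        _, res = train_mlp(train, test, cfg)
        assert res.mean_mse < lin_res.mean_mse + 0.1
        assert res.mean_mse < 0.1

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            MLPConfig(hidden_size=0, skip_connections=False)
        with pytest.raises(ValueError):
            MLPConfig(epochs=0)


class TestSweep:
    def test_summary_rows_match_recomputation(self):
        ds = _synthetic_dataset(120, seed=8, noise=10.0)
        cfg = MLPConfig(epochs=15, seed=3, curve_stride=15)
        table = complexity_sweep(ds, hidden_sizes=(2,), reps=3, cfg=cfg)
        reps = table[(table.hidden_size == 2) & (table.rep >= 0)]
        summary = table[(table.hidden_size == 2) & (table.rep == -1)]
        assert len(reps) == 3 and len(summary) == 1
        assert summary.mean_mse.iloc[0] == pytest.approx(
            reps.mean_mse.mean())
        assert summary.sd_mse.iloc[0] == pytest.approx(
            reps.mean_mse.std(ddof=0))
        baseline = table[table.hidden_size == -1]
        assert len(baseline) == 1
        assert (table.direction == "front-to-back").all()
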