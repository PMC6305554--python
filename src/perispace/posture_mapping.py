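"""Inter-leg posture mapping inside affordance volumes.

Every grid node of an affordance volume is a foot position reachable by two
neighboring legs, hence one matched pair of joint-angle triplets (sender
posture -> receiver posture with identical tibia-tarsus-joint position).
This module builds such posture-pair datasets by inverse kinematics, and
quantifies how complex a feed-forward mapping must be to transfer postures
between legs:

* an optimal affine map fit by least squares (normal equation /
  pseudo-inverse) as the baseline;
* a single-hidden-layer network (sigmoid hidden units, linear outputs,
  Glorot-uniform init, Adam, mini-batches of 10), optionally with skip
  connections that shortcut the hidden layer so the network strictly
  contains the affine baseline.

Errors are reported as per-output-DoF and mean squared error in deg^2 on a
held-out test split, so a mean MSE of 61.0 corresponds to a root mean
squared error of about 7.8 degrees per leg joint.  Inputs and outputs are
z-scored internally on training statistics for conditioning; predictions
and all reported errors are de-standardized back to degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .body_model import (
    BodyModel,
    LegAngles,
    OutOfWorkspaceError,
    affordance_joint_ranges,
    fk_leg,
    ik_leg,
    standard_body,
)
from .volumes import AffordanceVolume

__all__ = [
    "PosturePairDataset",
    "MLPConfig",
    "TrainResult",
    "LinearMap",
    "MLP",
    "EmptyDatasetError",
    "build_pairs",
    "split_dataset",
    "fit_linear",
    "train_mlp",
    "complexity_sweep",
]


class EmptyDatasetError(ValueError):
    """No doubly-reachable grid nodes in the affordance volume."""


@dataclass
class PosturePairDataset:
    """Matched (sender, receiver) joint-angle triplets with one common foot
    position per affordance-volume grid node."""

    sender_leg: str
    receiver_leg: str
    sender_angles: np.ndarray      # (N, 3) deg
    receiver_angles: np.ndarray    # (N, 3) deg
    foot_positions: np.ndarray     # (N, 3) mm, body frame
    nodes: np.ndarray              # (N, 3) source grid nodes, body frame mm
    dropped_nodes: int = 0         # nodes where either leg's ik failed

    def __len__(self) -> int:
        return len(self.sender_angles)

    @property
    def direction(self) -> str:
        """'front-to-back' when the sender is the more anterior leg."""
        order = {"1": 0, "2": 1, "3": 2}
        s, r = order[self.sender_leg[1]], order[self.receiver_leg[1]]
        return "front-to-back" if s < r else "back-to-front"

    def reversed(self) -> "PosturePairDataset":
        """Swap sender and receiver (the reverse mapping direction)."""
        return PosturePairDataset(
            sender_leg=self.receiver_leg, receiver_leg=self.sender_leg,
            sender_angles=self.receiver_angles,
            receiver_angles=self.sender_angles,
            foot_positions=self.foot_positions, nodes=self.nodes,
            dropped_nodes=self.dropped_nodes)

    def subset(self, idx: np.ndarray) -> "PosturePairDataset":
        return PosturePairDataset(
            sender_leg=self.sender_leg, receiver_leg=self.receiver_leg,
            sender_angles=self.sender_angles[idx],
            receiver_angles=self.receiver_angles[idx],
            foot_positions=self.foot_positions[idx], nodes=self.nodes[idx],
            dropped_nodes=self.dropped_nodes)


@dataclass(frozen=True)
class MLPConfig:
    """Training configuration of the hidden-layer network."""

    hidden_size: int = 8
    skip_connections: bool = False
    epochs: int = 5000
    batch_size: int = 10
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    curve_stride: int = 10          # record the learning curve every k epochs
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch size must be >= 1")
        if self.hidden_size < 0:
            raise ValueError("hidden size must be >= 0")
        if self.hidden_size == 0 and not self.skip_connections:
            raise ValueError("hidden_size 0 requires skip connections")


@dataclass
class TrainResult:
    """Per-DoF and mean test MSE (deg^2) of one fitted posture mapping."""

    per_dof_mse: np.ndarray        # (3,) deg^2, test set
    mean_mse: float                # arithmetic mean of the three
    rmse: float                    # sqrt(mean_mse), deg
    learning_curve: pd.DataFrame   # columns: epoch, train_mse, test_mse
    config: Optional[MLPConfig] = None
    seed: Optional[int] = None

    @staticmethod
    def from_per_dof(per_dof: np.ndarray, curve: pd.DataFrame,
                     config: Optional[MLPConfig] = None,
                     seed: Optional[int] = None) -> "TrainResult":
        per_dof = np.asarray(per_dof, dtype=float)
        mean = float(per_dof.mean())
        return TrainResult(per_dof_mse=per_dof, mean_mse=mean,
                           rmse=math.sqrt(mean), learning_curve=curve,
                           config=config, seed=seed)


def build_pairs(affordance: AffordanceVolume, sender: str, receiver: str,
                model: Optional[BodyModel] = None) -> PosturePairDataset:
    """One posture pair per affordance grid node reachable by both legs.

    Node coordinates (body frame) are converted into each leg's
    carrying-segment frame and solved by inverse kinematics; nodes where
    either solve fails, or where a solution violates the leg's
    affordance-conditioned joint bounds, are dropped and counted.
    """
    model = standard_body() if model is None else model
    if set(affordance.limb_pair) != {sender, receiver}:
        raise ValueError(
            f"{sender}/{receiver} do not match affordance pair "
            f"{affordance.limb_pair}")
    if len(affordance.nodes) == 0:
        raise EmptyDatasetError("affordance volume is empty")
    bases = {leg: model.limb_base(leg) for leg in (sender, receiver)}
    ins = {leg: model.limb(leg).insertion_array for leg in (sender, receiver)}
    bounds = {sender: affordance_joint_ranges(sender, receiver),
              receiver: affordance_joint_ranges(receiver, sender)}
    s_ang, r_ang, feet, nodes = [], [], [], []
    dropped = 0
    for node in np.asarray(affordance.nodes, dtype=float):
        try:
            pair = {}
            for leg in (sender, receiver):
                # body frame -> carrying-segment frame (straight rigid body)
                target = node - bases[leg] + ins[leg]
                ang = ik_leg(model, leg, target, bounds=bounds[leg])
                if not ang.within(bounds[leg]):
                    raise OutOfWorkspaceError("solution out of bounds")
                pair[leg] = ang
        except OutOfWorkspaceError:
            dropped += 1
            continue
        s_ang.append(pair[sender].as_array())
        r_ang.append(pair[receiver].as_array())
        feet.append(node)
        nodes.append(node)
    if not s_ang:
        raise EmptyDatasetError("no doubly-reachable nodes")
    return PosturePairDataset(
        sender_leg=sender, receiver_leg=receiver,
        sender_angles=np.array(s_ang), receiver_angles=np.array(r_ang),
        foot_positions=np.array(feet), nodes=np.array(nodes),
        dropped_nodes=dropped)


def split_dataset(ds: PosturePairDataset, train_frac: float = 0.8,
                  seed: int = 0) -> Tuple[PosturePairDataset,
                                          PosturePairDataset]:
    """Uniform random split; |train| = floor(train_frac * |ds|)."""
    n = len(ds)
    if n < 5:
        raise ValueError("dataset too small to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(math.floor(train_frac * n))
    return ds.subset(perm[:n_train]), ds.subset(perm[n_train:])


# --------------------------------------------------------------------------
# linear baseline
# --------------------------------------------------------------------------

@dataclass
class LinearMap:
    """Affine map y = x @ W + b fit by least squares."""

    W: np.ndarray                  # (3, 3)
    b: np.ndarray                  # (3,)
    rank_deficient: bool = False

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float) @ self.W + self.b


def _per_dof_mse(pred: np.ndarray, target: np.ndarray) -> np.ndarray:
    return np.mean((pred - target) ** 2, axis=0)


def fit_linear(train: PosturePairDataset, test: PosturePairDataset,
               ) -> Tuple[LinearMap, TrainResult]:
    """Optimal affine sender->receiver map via the pseudo-inverse.

    Rank-deficient designs fall back to the minimum-norm least-squares
    solution and are flagged on the returned map.
    """
    if len(train) < 4:
        raise ValueError("need at least 4 training pairs (3 inputs + bias)")
    X = np.hstack([train.sender_angles, np.ones((len(train), 1))])
    Y = train.receiver_angles
    coef, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    lin = LinearMap(W=coef[:3], b=coef[3], rank_deficient=rank < 4)
    per_dof = _per_dof_mse(lin.predict(test.sender_angles),
                           test.receiver_angles)
    train_mse = float(_per_dof_mse(lin.predict(train.sender_angles),
                                   train.receiver_angles).mean())
    curve = pd.DataFrame({"epoch": [0], "train_mse": [train_mse],
                          "test_mse": [float(per_dof.mean())]})
    return lin, TrainResult.from_per_dof(per_dof, curve)


# --------------------------------------------------------------------------
# hidden-layer network (native implementation)
# --------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class MLP:
    """3 -> hidden (sigmoid) -> 3 (linear), optional input->output skips.

    Inputs and outputs are standardized internally on training statistics
    (fixed at construction); predictions are de-standardized back to raw
    degrees, so reported errors stay in deg^2.  All weights are public
    attributes (W1, b1, W2, b2, Ws) so a skip network can be set to an
    affine solution via :meth:`set_affine`.
    """

    def __init__(self, hidden_size: int, skip: bool,
                 x_mean: np.ndarray, x_std: np.ndarray,
                 rng: np.random.Generator,
                 n_in: int = 3, n_out: int = 3,
                 y_mean: np.ndarray | float = 0.0,
                 y_std: np.ndarray | float = 1.0):
        self.hidden_size = hidden_size
        self.skip = skip
        self.x_mean = np.asarray(x_mean, dtype=float)
        self.x_std = np.asarray(x_std, dtype=float)
        self.y_mean = np.asarray(y_mean, dtype=float)
        self.y_std = np.asarray(y_std, dtype=float)

        def glorot(fan_in, fan_out):
            limit = math.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-limit, limit, size=(fan_in, fan_out))

        if hidden_size > 0:
            self.W1 = glorot(n_in, hidden_size)
            self.b1 = np.zeros(hidden_size)
            self.W2 = glorot(hidden_size, n_out)
        else:
            self.W1 = np.zeros((n_in, 0))
            self.b1 = np.zeros(0)
            self.W2 = np.zeros((0, n_out))
        self.b2 = np.zeros(n_out)
        self.Ws = glorot(n_in, n_out) if skip else None

    # -- inference ----------------------------------------------------------

    def _standardize(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.x_mean) / self.x_std

    def forward(self, x_raw: np.ndarray) -> np.ndarray:
        z = self._standardize(x_raw)
        h = _sigmoid(z @ self.W1 + self.b1) if self.hidden_size else None
        y = (h @ self.W2 if h is not None else 0.0) + self.b2
        if self.skip:
            y = y + z @ self.Ws
        return self.y_mean + self.y_std * y

    predict = forward

    def set_affine(self, lin: "LinearMap") -> None:
        """Configure a skip network to realize an affine map exactly.

        Hidden->output weights are zeroed and the skip path set so the
        network computes ``x @ lin.W + lin.b`` (up to floating-point
        rounding of the standardization algebra).
        """
        if not self.skip:
            raise ValueError("affine containment requires skip connections")
        self.W2 = np.zeros_like(self.W2)
        # y_mean + y_std * (z @ Ws + b2) == (x_mean + x_std * z) @ W + b
        self.Ws = (self.x_std[:, None] * lin.W) / self.y_std[None, :]
        self.b2 = (self.x_mean @ lin.W + lin.b - self.y_mean) / self.y_std

    # -- training -----------------------------------------------------------

    def parameters(self) -> List[np.ndarray]:
        ps = [self.W1, self.b1, self.W2, self.b2]
        if self.skip:
            ps.append(self.Ws)
        return ps

    def gradients(self, x_raw: np.ndarray, y: np.ndarray,
                  ) -> Tuple[float, List[np.ndarray]]:
        """Mean-squared-error loss (deg^2) and its gradients for one batch."""
        z = self._standardize(x_raw)
        h = _sigmoid(z @ self.W1 + self.b1) if self.hidden_size else None
        raw = (h @ self.W2 if h is not None else 0.0) + self.b2
        if self.skip:
            raw = raw + z @ self.Ws
        err = self.y_mean + self.y_std * raw - y
        loss = float(np.mean(err ** 2))
        # d loss / d raw network output
        g = 2.0 * err * self.y_std / err.size
        if self.hidden_size:
            gW2 = h.T @ g
            gb2 = g.sum(axis=0)
            gh = g @ self.W2.T
            gpre = gh * h * (1.0 - h)
            gW1 = z.T @ gpre
            gb1 = gpre.sum(axis=0)
        else:
            gW1 = np.zeros_like(self.W1)
            gb1 = np.zeros_like(self.b1)
            gW2 = np.zeros_like(self.W2)
            gb2 = g.sum(axis=0)
        grads = [gW1, gb1, gW2, gb2]
        if self.skip:
            grads.append(z.T @ g)
        return loss, grads


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


def _mse(model, x, y) -> float:
    return float(np.mean((model.forward(x) - y) ** 2))


def train_mlp(train: PosturePairDataset, test: PosturePairDataset,
              cfg: MLPConfig) -> Tuple[MLP, TrainResult]:
    """Mini-batch Adam training of the hidden-layer network.

    Deterministic for a fixed config and seed (weight init and epoch-end
    batch shuffling both derive from ``cfg.seed``).  The learning curve
    records train/test MSE every ``cfg.curve_stride`` epochs.  A non-finite
    loss aborts with :class:`DivergenceError`.
    """
    rng = np.random.default_rng(cfg.seed)
    x_mean = train.sender_angles.mean(axis=0)
    x_std = train.sender_angles.std(axis=0)
    x_std = np.where(x_std > 0, x_std, 1.0)
    y_mean = train.receiver_angles.mean(axis=0)
    y_std = train.receiver_angles.std(axis=0)
    y_std = np.where(y_std > 0, y_std, 1.0)
    net = MLP(cfg.hidden_size, cfg.skip_connections, x_mean, x_std, rng,
              y_mean=y_mean, y_std=y_std)

    X, Y = train.sender_angles, train.receiver_angles
    Xt, Yt = test.sender_angles, test.receiver_angles
    n = len(X)
    m_state = [np.zeros_like(p) for p in net.parameters()]
    v_state = [np.zeros_like(p) for p in net.parameters()]
    step = 0
    epochs_logged, train_curve, test_curve = [], [], []
    for epoch in range(1, cfg.epochs + 1):
        perm = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            loss, grads = net.gradients(X[idx], Y[idx])
            if not math.isfinite(loss):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch} "
                    f"(hidden={cfg.hidden_size}, skip={cfg.skip_connections})")
            step += 1
            params = net.parameters()
            for p, g, m, v in zip(params, grads, m_state, v_state):
                m *= cfg.beta1
                m += (1 - cfg.beta1) * g
                v *= cfg.beta2
                v += (1 - cfg.beta2) * g * g
                mhat = m / (1 - cfg.beta1 ** step)
                vhat = v / (1 - cfg.beta2 ** step)
                p -= cfg.learning_rate * mhat / (np.sqrt(vhat) + cfg.eps)
        if epoch % cfg.curve_stride == 0 or epoch == cfg.epochs:
            epochs_logged.append(epoch)
            train_curve.append(_mse(net, X, Y))
            test_curve.append(_mse(net, Xt, Yt))
    curve = pd.DataFrame({"epoch": epochs_logged, "train_mse": train_curve,
                          "test_mse": test_curve})
    per_dof = _per_dof_mse(net.forward(Xt), Yt)
    return net, TrainResult.from_per_dof(per_dof, curve, config=cfg,
                                         seed=cfg.seed)


def complexity_sweep(ds: PosturePairDataset, hidden_sizes: Sequence[int],
                     reps: int = 5, cfg: Optional[MLPConfig] = None,
                     train_frac: float = 0.8, split_seed: int = 0,
                     skip_connections: bool = False) -> pd.DataFrame:
    """Mean +/- SD test MSE as a function of hidden-layer size.

    The train/test split is fixed (``split_seed``); each repetition
    re-initializes weights and batch order with a distinct derived seed.
    The affine regression baseline is included as hidden size -1.
    Columns: direction, hidden_size, rep, mse_alpha, mse_beta, mse_gamma,
    mean_mse; repetition rows plus per-size summary rows (rep = -1) with
    mean and SD over repetitions.
    """
    cfg = MLPConfig() if cfg is None else cfg
    train, test = split_dataset(ds, train_frac, seed=split_seed)
    rows = []
    direction = ds.direction
    _, lin_res = fit_linear(train, test)
    rows.append({"direction": direction, "hidden_size": -1, "rep": 0,
                 "mse_alpha": lin_res.per_dof_mse[0],
                 "mse_beta": lin_res.per_dof_mse[1],
                 "mse_gamma": lin_res.per_dof_mse[2],
                 "mean_mse": lin_res.mean_mse, "sd_mse": 0.0})
    for size in hidden_sizes:
        reps_mse = []
        for rep in range(reps):
            rep_cfg = replace(cfg, hidden_size=size,
                              skip_connections=skip_connections,
                              seed=cfg.seed * 1000 + size * 10 + rep)
            _, res = train_mlp(train, test, rep_cfg)
            reps_mse.append(res.mean_mse)
            rows.append({"direction": direction, "hidden_size": size,
                         "rep": rep, "mse_alpha": res.per_dof_mse[0],
                         "mse_beta": res.per_dof_mse[1],
                         "mse_gamma": res.per_dof_mse[2],
                         "mean_mse": res.mean_mse, "sd_mse": np.nan})
        rows.append({"direction": direction, "hidden_size": size, "rep": -1,
                     "mse_alpha": np.nan, "mse_beta": np.nan,
                     "mse_gamma": np.nan,
                     "mean_mse": float(np.mean(reps_mse)),
                     "sd_mse": float(np.std(reps_mse))})
    return pd.DataFrame(rows)
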