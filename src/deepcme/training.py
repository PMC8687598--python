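"""Martingale-identity loss and the gradient training loop.

For every simulated path the terminal output obeys, almost surely,

    g(X(T)) = Y + sum_k int_0^T V_k(t, X(t)) dR~_k(t)

with ``Y = E[g(X(T))]`` and ``V`` the exact policy map -- and this pair is
the *unique* solution.  On the training grid the stochastic integral is
evaluated by the left-endpoint recursion

    Y_j = Y_{j-1} + V(t_{j-1}, X(t_{j-1})) (R~(t_j) - R~(t_{j-1})),  Y_0 = Y,

and the loss is the batch mean of ``sum_i phi((g_i(X(T)) - Y_J,i)/Delta_i)``
where ``phi`` is quadratic below one and linear above (a smooth Huber-like
junction), the thresholds ``Delta_i = 1 + |mean| + 2 sd`` equalise output
scales, and an optional ``mu * sum |W| + |b|`` sparsity penalty may be
added.  Minimising over (Y, policy parameters) with adaptive-moment
gradient descent recovers the expectation and the policy map from a small
fixed batch of trajectories.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

import numpy as np

from .networks import ReactionNetwork
from .outputs import OutputSpec
from .policy import PolicyConfig, PolicyNetwork, init_policy, segment_backward, segment_forward
from .simulate import GridTrajectory, TrajectoryBatch

__all__ = [
    "LossConfig",
    "TrainingConfig",
    "TrainingResult",
    "TrainingDivergedError",
    "phi",
    "phi_prime",
    "thresholds_from_batch",
    "pathwise_terminal",
    "batch_terminal",
    "empirical_loss",
    "train",
]


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite during training."""


def phi(x):
    """Huber-like penalty: x^2 for |x| < 1, else 2|x| - 1 (C^1 at the junction)."""
    x = np.asarray(x, dtype=float)
    return np.where(np.abs(x) < 1.0, x * x, 2.0 * np.abs(x) - 1.0)


def phi_prime(x):
    """Derivative of :func:`phi`: 2x inside the quadratic region, else 2 sign(x)."""
    x = np.asarray(x, dtype=float)
    return np.where(np.abs(x) < 1.0, 2.0 * x, 2.0 * np.sign(x))


@dataclass(frozen=True)
class LossConfig:
    """Thresholds and sparsity penalty of the loss."""

    thresholds: np.ndarray      # (R,) positive scales Delta_i
    mu: float = 0.0             # sparsity penalty weight (off by default)

    def __post_init__(self):
        t = np.asarray(self.thresholds, dtype=float)
        if np.any(t <= 0):
            raise ValueError("thresholds must be positive")
        if self.mu < 0:
            raise ValueError("mu must be nonnegative")
        object.__setattr__(self, "thresholds", t)


def thresholds_from_batch(batch: TrajectoryBatch) -> np.ndarray:
    """Per-output loss scale Delta_j = 1 + |sample mean| + 2 * sample SD of g_j(X(T))."""
    if batch.M < 2:
        raise ValueError("need at least 2 trajectories")
    g = batch.terminal_outputs
    return 1.0 + np.abs(g.mean(axis=0)) + 2.0 * g.std(axis=0, ddof=1)


@dataclass(frozen=True)
class TrainingConfig:
    """Optimiser settings of the training loop.

    Adaptive-moment gradient descent (Adam) with initial rate 0.01 decayed
    by 0.2 at 60% and 85% of the iteration budget; full-batch gradients over
    the fixed training set; validation logged every ``val_cadence`` steps.
    """

    iterations: int = 10_000
    learning_rate: float = 0.01
    decay_factor: float = 0.2
    decay_milestones: tuple = (0.6, 0.85)
    val_cadence: int = 100
    seed: int = 0
    policy: PolicyConfig = field(default_factory=PolicyConfig)

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class TrainingResult:
    """Trained state plus loss histories."""

    Y: np.ndarray                 # (R,) moment estimates
    policy: PolicyNetwork
    output_names: list
    thresholds: np.ndarray
    train_history: list           # [(iteration, loss), ...]
    val_history: list             # [(iteration, loss), ...]
    config: TrainingConfig

    @property
    def normalized_val_trace(self) -> np.ndarray:
        """Validation losses divided by the first logged value (starts at 1).

        A zero initial loss (degenerate data) leaves the trace unnormalised.
        """
        vals = np.array([v for _, v in self.val_history])
        return vals / vals[0] if vals[0] > 0 else vals


# ---------------------------------------------------------------------------
# pathwise recursion

def pathwise_terminal(policy, Y: np.ndarray, traj: GridTrajectory) -> np.ndarray:
    """Run the left-endpoint recursion along one grid trajectory; returns Y_J."""
    Y_j = np.array(Y, dtype=float)
    for j in range(1, len(traj.times)):
        V = policy(traj.times[j - 1], traj.states[j - 1])  # (R, K)
        Y_j = Y_j + V @ (traj.centred[j] - traj.centred[j - 1])
    return Y_j


def batch_terminal(policy, Y: np.ndarray, batch: TrajectoryBatch) -> np.ndarray:
    """Vectorised Y_J over all trajectories of a batch; returns (M, R)."""
    M, Jp1, n = batch.states.shape
    J = Jp1 - 1
    trows = np.tile(batch.times[:-1], M)
    Xrows = batch.states[:, :-1, :].reshape(M * J, n)
    V = policy.forward_rows(trows, Xrows).reshape(M, J, policy.R, policy.K)
    dR = np.diff(batch.centred, axis=1)  # (M, J, K)
    return np.asarray(Y, dtype=float) + np.einsum("mjrk,mjk->mr", V, dR)


def empirical_loss(policy, Y: np.ndarray, batch: TrajectoryBatch,
                   lossconfig: LossConfig):
    """Loss over a batch: mean_q sum_i phi(residual_i / Delta_i) + mu * P.

    Returns ``(loss, diagnostics)`` with per-path residuals in the
    diagnostics dict.
    """
    YJ = batch_terminal(policy, Y, batch)
    res = batch.terminal_outputs - YJ  # (M, R)
    data = float(phi(res / lossconfig.thresholds).sum(axis=1).mean())
    penalty = lossconfig.mu * policy.weight_l1() if lossconfig.mu else 0.0
    return data + penalty, {"residuals": res, "terminal": YJ, "data_loss": data,
                            "penalty": penalty}


# ---------------------------------------------------------------------------
# training loop

class _Adam:
    """Minimal Adam optimiser over a dict of parameter arrays."""

    def __init__(self, params: dict, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1 - b1 ** self.t
        c2 = 1 - b2 ** self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            p -= lr * (self.m[k] / c1) / (np.sqrt(self.v[k] / c2) + self.eps)


def _forward_backward(policy: PolicyNetwork, Y: np.ndarray, batch, rows_by_seg,
                      trows, Xrows, dR, gT, thresholds, mu: float):
    """One full-batch loss evaluation with exact gradients.

    Returns (loss, grads dict including "Y").
    """
    M, J = dR.shape[0], dR.shape[1]
    RK = policy.R * policy.K
    V_flat = np.empty((M * J, RK))
    caches = []
    for m_idx, rows in rows_by_seg:
        out, cache = segment_forward(policy.segments[m_idx], trows[rows], Xrows[rows])
        V_flat[rows] = out
        caches.append((m_idx, rows, cache))
    V = V_flat.reshape(M, J, policy.R, policy.K)
    YJ = Y + np.einsum("mjrk,mjk->mr", V, dR)
    res = gT - YJ
    u = res / thresholds
    loss = float(phi(u).sum(axis=1).mean())

    dYJ = -(phi_prime(u) / thresholds) / M  # (M, R): d loss / d YJ
    grads: dict = {"Y": dYJ.sum(axis=0)}
    dV = np.einsum("mr,mjk->mjrk", dYJ, dR).reshape(M * J, RK)
    for m_idx, rows, cache in caches:
        seg_grads = segment_backward(policy.segments[m_idx], cache, dV[rows])
        for name, gval in seg_grads.items():
            grads[f"seg{m_idx}/{name}"] = gval

    if mu:
        loss += mu * policy.weight_l1()
        for m_idx, seg in enumerate(policy.segments):
            for l in range(len(seg.weights)):
                grads[f"seg{m_idx}/W{l}"] = grads[f"seg{m_idx}/W{l}"] + mu * np.sign(seg.weights[l])
                grads[f"seg{m_idx}/b{l}"] = grads[f"seg{m_idx}/b{l}"] + mu * np.sign(seg.biases[l])
    return loss, grads


def train(network: ReactionNetwork, train_batch: TrajectoryBatch,
          val_batch: TrajectoryBatch, outputs: OutputSpec,
          trainconfig: TrainingConfig | None = None,
          lossconfig: LossConfig | None = None,
          log_path=None) -> TrainingResult:
    """Minimise the martingale loss over (Y, policy parameters) on a fixed batch.

    The training batch stays fixed for all iterations; gradients are
    full-batch.  ``Y`` starts at the training-batch sample mean of the
    outputs (an unbiased warm start for the identity Y = E[g(X(T))]).
    Validation loss is logged every ``val_cadence`` iterations; the
    normalised trace divides by its first logged value.
    """
    if trainconfig is None:
        trainconfig = TrainingConfig()
    if not np.allclose(train_batch.times, val_batch.times):
        raise ValueError("training and validation batches must share the grid")
    thresholds = (np.asarray(lossconfig.thresholds, dtype=float)
                  if lossconfig is not None else thresholds_from_batch(train_batch))
    mu = lossconfig.mu if lossconfig is not None else 0.0
    R = train_batch.terminal_outputs.shape[1]

    pc = trainconfig.policy
    if pc.seed != trainconfig.seed:
        pc = PolicyConfig(L=pc.L, N_H=pc.N_H, r=pc.r, N_T=pc.N_T,
                          seed=trainconfig.seed,
                          standardize_states=pc.standardize_states)
    policy = init_policy(network.n, network.K, R, train_batch.T, pc)
    if pc.standardize_states:
        flat = train_batch.states.reshape(-1, network.n).astype(float)
        policy.state_shift = flat.mean(axis=0)
        policy.state_scale = np.maximum(flat.std(axis=0), 1e-8)

    Y = train_batch.terminal_outputs.mean(axis=0).astype(float)

    # fixed training tensors, flattened once
    M, Jp1, n = train_batch.states.shape
    J = Jp1 - 1
    trows = np.tile(train_batch.times[:-1], M)
    Xrows = policy._scale_states(train_batch.states[:, :-1, :].reshape(M * J, n))
    dR = np.diff(train_batch.centred, axis=1)
    gT = train_batch.terminal_outputs
    seg_idx = policy.segment_of(trows)
    rows_by_seg = [(m, np.nonzero(seg_idx == m)[0]) for m in np.unique(seg_idx)]

    params = dict(policy.parameters())
    params["Y"] = Y
    opt = _Adam(params)
    milestones = {int(f * trainconfig.iterations) for f in trainconfig.decay_milestones}
    lr = trainconfig.learning_rate
    val_lc = LossConfig(thresholds=thresholds, mu=mu)

    train_hist: list = []
    val_hist: list = []
    log_rows: list = []

    for it in range(trainconfig.iterations):
        if it in milestones:
            lr *= trainconfig.decay_factor
        loss, grads = _forward_backward(policy, Y, train_batch, rows_by_seg, trows,
                                        Xrows, dR, gT, thresholds, mu)
        if not math.isfinite(loss):
            raise TrainingDivergedError(
                f"non-finite loss at iteration {it}; last Y = {Y.tolist()}"
            )
        if it % trainconfig.val_cadence == 0:
            val_loss, _ = empirical_loss(policy, Y, val_batch, val_lc)
            train_hist.append((it, loss))
            val_hist.append((it, val_loss))
            norm = val_loss / val_hist[0][1] if val_hist[0][1] > 0 else val_loss
            log_rows.append((it, loss, val_loss, norm, *Y))
        opt.step(grads, lr)

    # final log point after the last update
    final_loss, _ = _loss_only(policy, Y, rows_by_seg, trows, Xrows, dR, gT,
                               thresholds, mu)
    val_loss, _ = empirical_loss(policy, Y, val_batch, val_lc)
    it = trainconfig.iterations
    train_hist.append((it, final_loss))
    val_hist.append((it, val_loss))
    norm = val_loss / val_hist[0][1] if val_hist[0][1] > 0 else val_loss
    log_rows.append((it, final_loss, val_loss, norm, *Y))

    if log_path is not None:
        with open(log_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["iteration", "train_loss", "val_loss", "norm_val_loss",
                        *[f"Y_{i+1}" for i in range(R)]])
            w.writerows(log_rows)

    return TrainingResult(Y=Y.copy(), policy=policy,
                          output_names=list(train_batch.output_names),
                          thresholds=thresholds, train_history=train_hist,
                          val_history=val_hist, config=trainconfig)


def _loss_only(policy, Y, rows_by_seg, trows, Xrows, dR, gT, thresholds, mu):
    loss, _ = _forward_backward(policy, Y, None, rows_by_seg, trows, Xrows, dR,
                                gT, thresholds, mu)
    return loss, None
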