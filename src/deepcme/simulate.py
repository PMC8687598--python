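"""Exact CTMC trajectory simulation via the modified next reaction method (mNRM).

The simulator drives each reaction channel by an independent unit-rate
Poisson clock: reaction k fires when its internal time
``int_0^t lambda_k(X(s)) ds`` reaches the next point of its clock.  This
representation yields, for free, the per-reaction counting processes
``R_k(t)`` and their compensators ``int_0^t lambda_k(X(s)) ds`` (integrated
exactly, since propensities are piecewise constant between jumps).  The
centred counters ``R~_k(t) = R_k(t) - compensator`` are mean-zero local
martingales and are the training signal of the martingale loss.

Paths are cadlag; grid restriction samples the post-jump state at each grid
point.  Batches are reproducible: trajectory ``i`` of a batch with seed
``s`` uses the dedicated random stream seeded by ``(s, i)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .networks import ReactionNetwork, evaluate_propensity, network_from_dict, network_to_dict
from .outputs import OutputSpec

__all__ = [
    "JumpTrajectory",
    "GridTrajectory",
    "TrajectoryBatch",
    "ExplosionSuspectedError",
    "simulate_mnrm",
    "compensator",
    "compensators_at",
    "grid_restrict",
    "simulate_batch",
    "save_batch",
    "load_batch",
]

DEFAULT_MAX_JUMPS = 10**7


class ExplosionSuspectedError(RuntimeError):
    """Jump-count safety cap exceeded; the chain may violate non-explosivity."""


@dataclass
class JumpTrajectory:
    """Exact jump record of one CTMC path on [0, T].

    ``states[0]`` is the initial state; ``states[j]`` is the state right of
    jump ``j`` (the path is right-continuous).  ``reactions[j]`` is the
    0-based index of the reaction firing at ``times[j]``.
    """

    times: np.ndarray       # (num_jumps,) strictly increasing in (0, T]
    states: np.ndarray      # (num_jumps + 1, n) nonnegative integers
    reactions: np.ndarray   # (num_jumps,) 0-based firing reaction indices
    T: float

    @property
    def num_jumps(self) -> int:
        return len(self.times)

    def state_at(self, t: float) -> np.ndarray:
        """Right-continuous state at time t."""
        j = int(np.searchsorted(self.times, t, side="right"))
        return self.states[j]

    def counts_at(self, times) -> np.ndarray:
        """R_k(t): firings of each reaction up to (and including) each time."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        K = _num_reactions_hint(self)
        counts = np.zeros((len(times), K))
        if self.num_jumps:
            onehot = np.zeros((self.num_jumps, K))
            onehot[np.arange(self.num_jumps), self.reactions] = 1.0
            cum = np.cumsum(onehot, axis=0)
            idx = np.searchsorted(self.times, times, side="right")
            nz = idx > 0
            counts[nz] = cum[idx[nz] - 1]
        return counts


def _num_reactions_hint(traj: JumpTrajectory) -> int:
    return int(traj.reactions.max()) + 1 if traj.num_jumps else 1


@dataclass
class GridTrajectory:
    """Restriction of a jump path to the J+1 training grid points.

    Carries the sampled states, the centred reaction counters
    ``R~_k(t_j) = R_k(t_j) - int_0^{t_j} lambda_k(X(s)) ds`` (the integral
    computed exactly over the piecewise-constant path) and the terminal
    outputs g(X(T)).
    """

    times: np.ndarray      # (J+1,) grid 0 = t_0 < ... < t_J = T
    states: np.ndarray     # (J+1, n)
    centred: np.ndarray    # (J+1, K) centred counters
    terminal_outputs: np.ndarray  # (R,)


@dataclass
class TrajectoryBatch:
    """M grid trajectories sharing (network, x0, T, J), stacked as arrays."""

    network: ReactionNetwork
    times: np.ndarray        # (J+1,)
    states: np.ndarray       # (M, J+1, n)
    centred: np.ndarray      # (M, J+1, K)
    terminal_outputs: np.ndarray  # (M, R)
    output_names: list
    seed: int
    role: str = "training"
    T: float = field(init=False)
    J: int = field(init=False)

    def __post_init__(self):
        self.T = float(self.times[-1])
        self.J = len(self.times) - 1

    @property
    def M(self) -> int:
        return self.states.shape[0]

    def trajectory(self, q: int) -> GridTrajectory:
        return GridTrajectory(self.times, self.states[q], self.centred[q],
                              self.terminal_outputs[q])


def _compile_propensities(network: ReactionNetwork):
    """Per-reaction fast closures state-tuple -> rate, for the inner simulation loop."""
    funcs = []
    for r in network.reactions:
        spec = r.propensity
        if spec.kind == "mass_action":
            c = float(network.params[spec.params["rate"]])
            active = [(i, nu) for i, nu in enumerate(r.consume) if nu > 0]
            if not active:
                funcs.append(lambda x, c=c: c)
            elif len(active) == 1 and active[0][1] == 1:
                i = active[0][0]
                funcs.append(lambda x, c=c, i=i: c * x[i])
            elif len(active) == 1 and active[0][1] == 2:
                i = active[0][0]
                funcs.append(lambda x, c=c, i=i: c * x[i] * (x[i] - 1) * 0.5)
            else:
                def general(x, c=c, active=tuple(active)):
                    lam = c
                    for i, nu in active:
                        xi = x[i]
                        if xi < nu:
                            return 0.0
                        f = 1.0
                        for d in range(nu):
                            f *= xi - d
                        for d in range(2, nu + 1):
                            f /= d
                        lam *= f
                    return lam
                funcs.append(general)
        elif spec.kind in ("hill_activating", "hill_repressing"):
            b = float(network.params[spec.params["basal"]])
            km = float(network.params[spec.params["gain"]])
            k0 = float(network.params[spec.params["half_saturation"]])
            H = float(network.params[spec.params["exponent"]])
            i = spec.regulator
            if spec.kind == "hill_activating":
                def act(x, b=b, km=km, k0=k0, H=H, i=i):
                    s = x[i]
                    sH = s ** H if s > 0 else 0.0
                    return b + km * sH / (k0 + sH)
                funcs.append(act)
            else:
                def rep(x, b=b, km=km, k0=k0, H=H, i=i):
                    s = x[i]
                    sH = s ** H if s > 0 else 0.0
                    return b + km / (k0 + sH)
                funcs.append(rep)
        else:
            theta = dict(network.params)
            fn = spec.rate_fn
            funcs.append(lambda x, fn=fn, theta=theta: float(fn(np.asarray(x, dtype=float), theta)))
    return funcs


class _ExpStream:
    """Buffered stream of unit-rate exponential variates."""

    __slots__ = ("rng", "buf", "pos")

    def __init__(self, rng: np.random.Generator, block: int = 256):
        self.rng = rng
        self.buf = rng.exponential(size=block)
        self.pos = 0

    def next(self) -> float:
        if self.pos >= len(self.buf):
            self.buf = self.rng.exponential(size=len(self.buf))
            self.pos = 0
        v = self.buf[self.pos]
        self.pos += 1
        return v


def simulate_mnrm(network: ReactionNetwork, T: float,
                  rng: np.random.Generator | int,
                  max_jumps: int = DEFAULT_MAX_JUMPS) -> JumpTrajectory:
    """Sample one statistically exact CTMC path on [0, T] with mNRM.

    Each reaction carries an internal clock consuming time at its propensity;
    the next firing is the channel whose clock reaches its next unit-rate
    exponential arrival first.

    Raises
    ------
    ExplosionSuspectedError
        if more than ``max_jumps`` firings occur (non-explosivity of the
        chain is an assumption of the method, not a checked property).
    """
    if T <= 0:
        raise ValueError("horizon T must be positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    lam_funcs = _compile_propensities(network)
    K = network.K
    zetas = [tuple(int(v) for v in r.zeta) for r in network.reactions]
    exp = _ExpStream(rng)

    x = list(network.x0)
    t = 0.0
    Tk = [0.0] * K                      # internal time consumed per channel
    Pk = [exp.next() for _ in range(K)]  # next internal arrival per channel
    times: list = []
    reactions: list = []
    states = [tuple(x)]

    while True:
        lams = [f(x) for f in lam_funcs]
        # time to each channel's next firing
        best_dt = np.inf
        best_k = -1
        for k in range(K):
            lk = lams[k]
            if lk > 0.0:
                dt = (Pk[k] - Tk[k]) / lk
                if dt < best_dt:
                    best_dt = dt
                    best_k = k
        if best_k < 0 or t + best_dt > T:
            break
        t += best_dt
        for k in range(K):
            Tk[k] += lams[k] * best_dt
        Pk[best_k] += exp.next()
        z = zetas[best_k]
        for i in range(len(x)):
            x[i] += z[i]
        times.append(t)
        reactions.append(best_k)
        states.append(tuple(x))
        if len(times) > max_jumps:
            raise ExplosionSuspectedError(
                f"more than {max_jumps} jumps before t={t:.4g}; "
                "the chain may be explosive"
            )

    return JumpTrajectory(
        times=np.asarray(times, dtype=float),
        states=np.asarray(states, dtype=int).reshape(len(states), network.n),
        reactions=np.asarray(reactions, dtype=int),
        T=float(T),
    )


def compensators_at(traj: JumpTrajectory, network: ReactionNetwork, times) -> np.ndarray:
    """Exact integrated propensities ``int_0^t lambda_k(X(s)) ds`` at the given times.

    The path is piecewise constant, so each integral is a finite sum of
    (interval length) x (propensity on the interval).

    Returns a (len(times), K) array.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(times < 0) or np.any(times > traj.T + 1e-12):
        raise ValueError("query times must lie in [0, T]")
    K = network.K
    # propensities on each constant segment; segment e spans [edges[e], edges[e+1])
    edges = np.concatenate(([0.0], traj.times, [traj.T]))
    from .networks import propensity_matrix

    lams = propensity_matrix(network, traj.states)  # (num_jumps+1, K)
    seg_len = np.diff(edges)  # (num_segments,)
    cum = np.concatenate([np.zeros((1, K)), np.cumsum(lams * seg_len[:, None], axis=0)])
    # integral up to t: full segments before t plus the partial current one
    seg_idx = np.clip(np.searchsorted(edges, times, side="right") - 1, 0, len(seg_len) - 1)
    out = cum[seg_idx] + (times - edges[seg_idx])[:, None] * lams[seg_idx]
    return out


def compensator(traj: JumpTrajectory, network: ReactionNetwork, k: int, t: float) -> float:
    """Compensator of reaction ``k`` (1-based) at time ``t``."""
    if not 1 <= k <= network.K:
        raise ValueError(f"reaction index {k} outside 1..{network.K}")
    return float(compensators_at(traj, network, [t])[0, k - 1])


def grid_restrict(traj: JumpTrajectory, network: ReactionNetwork, J: int,
                  outputs: OutputSpec) -> GridTrajectory:
    """Restrict a jump path to the uniform grid t_j = jT/J with centred counters."""
    if J < 1:
        raise ValueError("J must be >= 1")
    times = np.linspace(0.0, traj.T, J + 1)
    idx = np.searchsorted(traj.times, times, side="right")
    states = traj.states[idx]
    K = network.K
    counts = np.zeros((J + 1, K))
    if traj.num_jumps:
        onehot = np.zeros((traj.num_jumps, K))
        onehot[np.arange(traj.num_jumps), traj.reactions] = 1.0
        cum = np.concatenate([np.zeros((1, K)), np.cumsum(onehot, axis=0)])
        counts = cum[idx]
    centred = counts - compensators_at(traj, network, times)
    centred[0] = 0.0
    gT = outputs.evaluate(states[-1])
    return GridTrajectory(times=times, states=states, centred=centred, terminal_outputs=gT)


def trajectory_rng(seed: int, index: int) -> np.random.Generator:
    """Independent stream for trajectory ``index`` of a batch with base seed ``seed``."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(index)]))


def simulate_batch(network: ReactionNetwork, T: float, J: int, M: int, seed: int,
                   outputs: OutputSpec, role: str = "training",
                   max_jumps: int = DEFAULT_MAX_JUMPS) -> TrajectoryBatch:
    """Simulate M independent grid trajectories with reproducible per-path streams."""
    if M < 1:
        raise ValueError("batch size M must be >= 1")
    times = np.linspace(0.0, T, J + 1)
    n, K, R = network.n, network.K, outputs.R
    states = np.empty((M, J + 1, n), dtype=int)
    centred = np.empty((M, J + 1, K))
    gT = np.empty((M, R))
    for q in range(M):
        traj = simulate_mnrm(network, T, trajectory_rng(seed, q), max_jumps=max_jumps)
        g = grid_restrict(traj, network, J, outputs)
        states[q] = g.states
        centred[q] = g.centred
        gT[q] = g.terminal_outputs
    return TrajectoryBatch(network=network, times=times, states=states, centred=centred,
                           terminal_outputs=gT, output_names=outputs.names,
                           seed=int(seed), role=role)


# ---------------------------------------------------------------------------
# batch archive (HDF5)

def save_batch(batch: TrajectoryBatch, path) -> None:
    import json

    with h5py.File(path, "w") as fh:
        fh.create_dataset("times", data=batch.times)
        fh.create_dataset("states", data=batch.states)
        fh.create_dataset("centred", data=batch.centred)
        fh.create_dataset("terminal_outputs", data=batch.terminal_outputs)
        fh.attrs["seed"] = batch.seed
        fh.attrs["role"] = batch.role
        fh.attrs["output_names"] = json.dumps(batch.output_names)
        fh.attrs["network"] = json.dumps(network_to_dict(batch.network))


def load_batch(path) -> TrajectoryBatch:
    import json

    with h5py.File(path, "r") as fh:
        return TrajectoryBatch(
            network=network_from_dict(json.loads(fh.attrs["network"])),
            times=fh["times"][:],
            states=fh["states"][:],
            centred=fh["centred"][:],
            terminal_outputs=fh["terminal_outputs"][:],
            output_names=json.loads(fh.attrs["output_names"]),
            seed=int(fh.attrs["seed"]),
            role=str(fh.attrs["role"]),
        )
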