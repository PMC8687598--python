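"""Trainable policy map (t, x) -> V(t, x), an R x K matrix-valued network.

The map is a fully connected feed-forward ReLU network whose time input is
replaced by *temporal features*

    ( e^{a_1 (T-t)}, ..., e^{a_r (T-t)},
      sin(w_1 (T-t) + psi_1), ..., sin(w_r (T-t) + psi_r) )

with trainable decay rates ``a_i``, frequencies ``w_i`` and phases
``psi_i``.  The rationale: on a finite state space the backward value
function is a matrix exponential in the remaining horizon ``T - t``, so its
time dependence is a combination of decaying and oscillating modes, and the
features let the network learn the dominant ones directly.  The state
vector is passed through unchanged (optional affine standardisation behind
a config flag).

For long horizons the map may be segmented into ``N_T`` structurally
identical networks, the m-th covering ``t in [(m-1) T/N_T, m T/N_T)``;
segments are independent (no continuity across boundaries is imposed).

Because the network is tiny (default: two hidden layers of width four),
forward evaluation and exact reverse-mode gradients are implemented
directly in numpy; gradient correctness is property-tested against central
finite differences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "TemporalFeatureParams",
    "PolicyConfig",
    "PolicySegment",
    "PolicyNetwork",
    "temporal_features",
    "select_segment",
    "policy_forward",
    "init_policy",
    "save_policy",
    "load_policy",
]


@dataclass
class TemporalFeatureParams:
    """Trainable parameters of the 2r temporal features."""

    decay: np.ndarray   # (r,) exponential rates a_i
    freq: np.ndarray    # (r,) angular frequencies w_i
    phase: np.ndarray   # (r,) phases psi_i
    T: float

    @property
    def r(self) -> int:
        return len(self.decay)


def temporal_features(t: float, params: TemporalFeatureParams) -> np.ndarray:
    """Feature vector (length 2r) at a single time t in [0, T]."""
    if t < -1e-12 or t > params.T + 1e-12:
        raise ValueError(f"time {t} outside [0, {params.T}]")
    s = params.T - t
    return np.concatenate([np.exp(params.decay * s),
                           np.sin(params.freq * s + params.phase)])


@dataclass(frozen=True)
class PolicyConfig:
    """Architecture hyperparameters of the policy network."""

    L: int = 2          # hidden layers
    N_H: int = 4        # nodes per hidden layer
    r: int = 1          # temporal feature pairs
    N_T: int = 1        # temporal segments
    seed: int = 0
    standardize_states: bool = False

    def __post_init__(self):
        if min(self.L, self.N_H, self.r, self.N_T) < 1:
            raise ValueError("all architecture counts must be >= 1")


@dataclass
class PolicySegment:
    """One temporal segment: feature parameters plus an affine-ReLU chain.

    ``weights[l]`` has shape (N_l, N_{l-1}); hidden activations are ReLU and
    the output layer is linear with R*K units.
    """

    features: TemporalFeatureParams
    weights: list
    biases: list


@dataclass
class PolicyNetwork:
    """N_T structurally identical segment networks mapping (t, x) to an R x K matrix."""

    n: int
    K: int
    R: int
    T: float
    config: PolicyConfig
    segments: list
    state_shift: np.ndarray | None = None
    state_scale: np.ndarray | None = None

    @property
    def N_T(self) -> int:
        return self.config.N_T

    @property
    def delta(self) -> float:
        return self.T / self.config.N_T

    def num_parameters(self) -> int:
        """Trainable parameter count: per segment, sum_l N_l (N_{l-1} + 1) plus 3r."""
        count = 0
        for seg in self.segments:
            count += 3 * seg.features.r
            for W, b in zip(seg.weights, seg.biases):
                count += W.size + b.size
        return count

    # -- parameter access for the optimiser ---------------------------------
    def parameters(self) -> dict:
        """Flat name -> array mapping (views into the live parameter arrays)."""
        out: dict = {}
        for m, seg in enumerate(self.segments):
            out[f"seg{m}/decay"] = seg.features.decay
            out[f"seg{m}/freq"] = seg.features.freq
            out[f"seg{m}/phase"] = seg.features.phase
            for l, (W, b) in enumerate(zip(seg.weights, seg.biases)):
                out[f"seg{m}/W{l}"] = W
                out[f"seg{m}/b{l}"] = b
        return out

    def weight_l1(self) -> float:
        """Sum of absolute weights and biases (the sparsity penalty P)."""
        return float(sum(np.abs(W).sum() + np.abs(b).sum()
                         for seg in self.segments
                         for W, b in zip(seg.weights, seg.biases)))

    # -- evaluation ----------------------------------------------------------
    def _scale_states(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.state_shift is None:
            return X
        return (X - self.state_shift) / self.state_scale

    def segment_of(self, tvals: np.ndarray) -> np.ndarray:
        """0-based segment index per time; t = T closes into the last segment."""
        tvals = np.asarray(tvals, dtype=float)
        idx = np.floor(tvals / self.delta).astype(int)
        return np.clip(idx, 0, self.N_T - 1)

    def forward_rows(self, tvals: np.ndarray, X: np.ndarray) -> np.ndarray:
        """(B,) times and (B, n) states -> (B, R, K) policy matrices."""
        tvals = np.asarray(tvals, dtype=float)
        X = np.asarray(X, dtype=float)
        out = np.empty((len(tvals), self.R, self.K))
        seg_idx = self.segment_of(tvals)
        for m in np.unique(seg_idx):
            rows = np.nonzero(seg_idx == m)[0]
            o, _ = segment_forward(self.segments[m], tvals[rows],
                                   self._scale_states(X[rows]))
            out[rows] = o.reshape(len(rows), self.R, self.K)
        return out

    def __call__(self, t: float, x) -> np.ndarray:
        return self.forward_rows(np.array([t]), np.asarray(x, dtype=float)[None, :])[0]


def select_segment(t: float, policy: PolicyNetwork) -> int:
    """1-based segment index m with t in [(m-1) delta, m delta); t = T -> N_T."""
    if t < -1e-12 or t > policy.T + 1e-12:
        raise ValueError(f"time {t} outside [0, {policy.T}]")
    return int(policy.segment_of(np.array([t]))[0]) + 1


def policy_forward(policy: PolicyNetwork, t: float, x) -> np.ndarray:
    """Single-point evaluation V(t, x) as an (R, K) matrix."""
    return policy(t, x)


# ---------------------------------------------------------------------------
# segment forward / backward (exact reverse-mode gradients)

def segment_forward(seg: PolicySegment, tvals: np.ndarray, Xs: np.ndarray):
    """Batched forward pass of one segment.

    Parameters
    ----------
    tvals : (B,) times; Xs : (B, n) (already standardised) states.

    Returns
    -------
    out : (B, R*K) flattened policy values.
    cache : intermediates needed by :func:`segment_backward`.
    """
    f = seg.features
    s = f.T - tvals  # (B,) remaining horizon
    exp_feat = np.exp(np.outer(s, f.decay))          # (B, r)
    arg = np.outer(s, f.freq) + f.phase              # (B, r)
    sin_feat = np.sin(arg)
    z = np.concatenate([exp_feat, sin_feat, Xs], axis=1)  # (B, 2r + n)

    acts = [z]
    pres = []
    h = z
    last = len(seg.weights) - 1
    for l, (W, b) in enumerate(zip(seg.weights, seg.biases)):
        pre = h @ W.T + b
        pres.append(pre)
        h = pre if l == last else np.maximum(pre, 0.0)
        acts.append(h)
    cache = {"s": s, "exp_feat": exp_feat, "arg": arg, "acts": acts, "pres": pres}
    return h, cache


def segment_backward(seg: PolicySegment, cache: dict, dout: np.ndarray) -> dict:
    """Gradients of sum(dout * out) w.r.t. every parameter of the segment.

    ``dout`` is the upstream gradient on the flattened (B, R*K) output.
    Returns a dict keyed like the segment's entries in
    :meth:`PolicyNetwork.parameters` (without the ``segM/`` prefix).
    """
    acts, pres = cache["acts"], cache["pres"]
    grads: dict = {}
    dh = dout
    last = len(seg.weights) - 1
    for l in range(last, -1, -1):
        if l != last:
            dh = dh * (pres[l] > 0)
        grads[f"W{l}"] = dh.T @ acts[l]
        grads[f"b{l}"] = dh.sum(axis=0)
        dh = dh @ seg.weights[l]
    dz = dh  # (B, 2r + n)
    r = seg.features.r
    s = cache["s"]
    grads["decay"] = np.einsum("bi,b,bi->i", dz[:, :r], s, cache["exp_feat"])
    cos_arg = np.cos(cache["arg"])
    grads["freq"] = np.einsum("bi,b,bi->i", dz[:, r:2 * r], s, cos_arg)
    grads["phase"] = np.einsum("bi,bi->i", dz[:, r:2 * r], cos_arg)
    return grads


# ---------------------------------------------------------------------------
# initialisation and checkpointing

def init_policy(n: int, K: int, R: int, T: float,
                config: PolicyConfig | None = None) -> PolicyNetwork:
    """Fresh policy network with fan-in-scaled symmetric uniform weights.

    Weights of layer l are drawn from U(-sqrt(6/N_{l-1}), +sqrt(6/N_{l-1}))
    and biases start at zero.  Temporal decays start in (-1, 0) (decaying
    modes), frequencies in (0, 1), phases at zero.  Fully reproducible from
    ``config.seed``.
    """
    if config is None:
        config = PolicyConfig()
    if min(n, K, R) < 1:
        raise ValueError("n, K, R must all be >= 1")
    rng = np.random.default_rng(config.seed)
    widths = [2 * config.r + n] + [config.N_H] * config.L + [R * K]
    segments = []
    for _ in range(config.N_T):
        feats = TemporalFeatureParams(
            decay=rng.uniform(-1.0, 0.0, size=config.r),
            freq=rng.uniform(0.0, 1.0, size=config.r),
            phase=np.zeros(config.r),
            T=float(T),
        )
        weights, biases = [], []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            limit = np.sqrt(6.0 / fan_in)
            weights.append(rng.uniform(-limit, limit, size=(fan_out, fan_in)))
            biases.append(np.zeros(fan_out))
        segments.append(PolicySegment(features=feats, weights=weights, biases=biases))
    return PolicyNetwork(n=n, K=K, R=R, T=float(T), config=config, segments=segments)


def save_policy(policy: PolicyNetwork, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["meta"] = json.dumps({
            "n": policy.n, "K": policy.K, "R": policy.R, "T": policy.T,
            "L": policy.config.L, "N_H": policy.config.N_H, "r": policy.config.r,
            "N_T": policy.config.N_T, "seed": policy.config.seed,
            "standardize_states": policy.config.standardize_states,
        })
        for name, arr in policy.parameters().items():
            fh.create_dataset(name, data=arr)
        if policy.state_shift is not None:
            fh.create_dataset("state_shift", data=policy.state_shift)
            fh.create_dataset("state_scale", data=policy.state_scale)


def load_policy(path) -> PolicyNetwork:
    with h5py.File(path, "r") as fh:
        meta = json.loads(fh.attrs["meta"])
        config = PolicyConfig(L=meta["L"], N_H=meta["N_H"], r=meta["r"],
                              N_T=meta["N_T"], seed=meta["seed"],
                              standardize_states=meta["standardize_states"])
        policy = init_policy(meta["n"], meta["K"], meta["R"], meta["T"], config)
        for name, arr in policy.parameters().items():
            arr[...] = fh[name][:]
        if "state_shift" in fh:
            policy.state_shift = fh["state_shift"][:]
            policy.state_scale = fh["state_scale"][:]
    return policy
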