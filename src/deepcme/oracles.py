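"""Ground-truth machinery: finite state projection, moment ODEs, closed forms.

These solvers provide deterministic reference values for the quantities the
deep solver estimates:

* forward FSP -- the master equation restricted to a finite box of states,
  ``dp/dt = Q^T p``, solved by sparse matrix-exponential action; probability
  flowing out of the box accumulates in a tracked *leak* term, never
  silently renormalised,
* backward FSP -- the value function ``V_g(t) = exp(Q(T-t)) g`` with
  ``V_g(t, x) = E[g(X(T)) | X(t) = x]``, together with the jump differences
  ``Delta_k V_g(t, x) = V_g(t, x + zeta_k) - V_g(t, x)`` (the exact policy
  map),
* exactly-closed first/second moment ODEs for networks whose propensities
  are affine in the state, with forward-mode parameter sensitivities,
* closed-form moments and sensitivities of the single-species birth-death
  process,
* the deterministic evaluation of the sensitivity integral
  ``S_theta = sum_k int_0^T sum_x p(t,x) dlambda_k/dtheta Delta_k V_g dt``
  plus its central-finite-difference cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import expm_multiply

from .networks import (
    ReactionNetwork,
    propensity_matrix,
    propensity_parameter_gradient_tensor,
)
from .outputs import OutputSpec
from .simulate import TrajectoryBatch, simulate_mnrm, trajectory_rng

__all__ = [
    "FspTruncation",
    "FspSolution",
    "FspBackwardSolution",
    "McEstimate",
    "BirthDeathMoments",
    "AffineMomentSolution",
    "default_truncation",
    "fsp_solve_forward",
    "fsp_solve_backward",
    "fsp_expectation",
    "fsp_sensitivity",
    "fsp_sensitivity_fd",
    "affine_moment_odes",
    "birth_death_closed_form",
    "mc_estimate",
    "TabularPolicy",
]

MAX_FSP_STATES = 200_000


class TruncationError(ValueError):
    """Truncated state space too large or infeasible."""


@dataclass(frozen=True)
class FspTruncation:
    """Box truncation 0 <= x_i <= bounds[i] with a fixed state enumeration.

    States are enumerated in C order over the box, so the bijection between
    states and indices is ``index = sum_i x_i * strides[i]``.
    """

    bounds: tuple

    def __post_init__(self):
        b = tuple(int(v) for v in self.bounds)
        if any(v < 0 for v in b):
            raise TruncationError("bounds must be nonnegative")
        object.__setattr__(self, "bounds", b)

    @property
    def n(self) -> int:
        return len(self.bounds)

    @property
    def num_states(self) -> int:
        out = 1
        for b in self.bounds:
            out *= b + 1
        return out

    @property
    def strides(self) -> np.ndarray:
        dims = np.array(self.bounds) + 1
        s = np.ones(self.n, dtype=np.int64)
        for i in range(self.n - 2, -1, -1):
            s[i] = s[i + 1] * dims[i + 1]
        return s

    def states(self) -> np.ndarray:
        """(m, n) array of all box states in enumeration order."""
        grids = np.indices([b + 1 for b in self.bounds])
        return grids.reshape(self.n, -1).T.astype(np.int64)

    def index_of(self, X: np.ndarray) -> np.ndarray:
        """Indices of states ``X`` (..., n); -1 for states outside the box."""
        X = np.asarray(X, dtype=np.int64)
        inside = np.all((X >= 0) & (X <= np.array(self.bounds)), axis=-1)
        idx = X @ self.strides
        return np.where(inside, idx, -1)


def default_truncation(network: ReactionNetwork, T: float, seed: int = 0,
                       presample: int = 200, num_sd: float = 10.0,
                       min_bound: int = 15) -> FspTruncation:
    """Truncation bounds from a quick Monte-Carlo pre-run: mean + 10 SD per species."""
    maxima = np.zeros((presample, network.n))
    sums = np.zeros((presample, network.n))
    for q in range(presample):
        traj = simulate_mnrm(network, T, trajectory_rng(seed, q))
        maxima[q] = traj.states.max(axis=0)
        sums[q] = traj.states[-1]
    mean = sums.mean(axis=0)
    sd = sums.std(axis=0, ddof=1)
    bounds = np.maximum(np.ceil(mean + num_sd * sd), min_bound)
    bounds = np.maximum(bounds, maxima.max(axis=0))
    return FspTruncation(tuple(int(b) for b in bounds))


def _generator(network: ReactionNetwork, trunc: FspTruncation) -> sp.csr_matrix:
    """Truncated transition rate matrix Q.

    ``Q[i, j] = lambda_k(x(i))`` where ``x(j) = x(i) + zeta_k`` lies in the
    box; the diagonal carries the *full* outflow ``-sum_k lambda_k(x(i))``,
    so probability leaving the box leaks out of the system (sum p decays).
    """
    m = trunc.num_states
    if m > MAX_FSP_STATES:
        raise TruncationError(f"{m} states exceeds the FSP guard of {MAX_FSP_STATES}")
    X = trunc.states()
    lams = propensity_matrix(network, X)  # (m, K)
    rows, cols, vals = [], [], []
    diag = -lams.sum(axis=1)
    for k, r in enumerate(network.reactions):
        tgt = trunc.index_of(X + r.zeta)
        ok = (tgt >= 0) & (lams[:, k] > 0)
        rows.append(np.nonzero(ok)[0])
        cols.append(tgt[ok])
        vals.append(lams[ok, k])
    rows.append(np.arange(m))
    cols.append(np.arange(m))
    vals.append(diag)
    Q = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(m, m),
    )
    return Q


@dataclass
class FspSolution:
    """Forward FSP solution: probability over the box plus the leaked mass."""

    trunc: FspTruncation
    times: np.ndarray       # (nt,)
    p: np.ndarray           # (nt, m) probabilities
    leak: np.ndarray        # (nt,) 1 - sum(p)

    def probabilities(self, t_index: int = -1) -> np.ndarray:
        """Probability vector at a stored time, clipped to be nonnegative."""
        q = self.p[t_index]
        if q.min() < -1e-12:
            raise RuntimeError("FSP probabilities significantly negative; solver failure")
        return np.clip(q, 0.0, None)

    def expectation(self, g_values: np.ndarray, t_index: int = -1) -> float:
        return float(self.probabilities(t_index) @ np.asarray(g_values, dtype=float))


def _propagate(Q: sp.csr_matrix, v0: np.ndarray, spans: np.ndarray) -> np.ndarray:
    """exp(s Q) v0 for increasing spans s (sequential matrix-exponential action)."""
    out = np.empty((len(spans), len(v0)))
    v = np.asarray(v0, dtype=float)
    prev = 0.0
    for i, s in enumerate(spans):
        ds = s - prev
        if ds > 0:
            v = expm_multiply(Q * ds, v)
        out[i] = v
        prev = s
    return out


def fsp_solve_forward(network: ReactionNetwork, x0, T: float, trunc: FspTruncation,
                      times=None, leak_tol: float = 1e-3) -> FspSolution:
    """Forward master-equation solve p(t) = exp(t Q^T) p(0) on the truncated box."""
    if times is None:
        times = [T]
    times = np.asarray(sorted(set(float(t) for t in times)))
    if times[0] < 0 or times[-1] > T + 1e-12:
        raise ValueError("query times must lie in [0, T]")
    idx0 = trunc.index_of(np.asarray(x0, dtype=int))
    if np.ndim(idx0) or idx0 < 0:
        raise TruncationError("initial state outside the truncated box")
    p0 = np.zeros(trunc.num_states)
    p0[int(idx0)] = 1.0
    Q = _generator(network, trunc)
    p = _propagate(Q.T.tocsr(), p0, times)
    leak = 1.0 - p.sum(axis=1)
    if leak[-1] > leak_tol:
        import warnings

        warnings.warn(
            f"FSP leak {leak[-1]:.3g} exceeds {leak_tol}; enlarge the truncation",
            RuntimeWarning,
            stacklevel=2,
        )
    return FspSolution(trunc=trunc, times=times, p=p, leak=leak)


@dataclass
class FspBackwardSolution:
    """Backward FSP solve: value function and its jump differences on the box."""

    trunc: FspTruncation
    T: float
    times: np.ndarray       # (nt,) query times in [0, T]
    V: np.ndarray           # (nt, m) value function V_g(t, x)
    delta_V: np.ndarray     # (nt, K, m) jump differences, 0 where x+zeta leaves the box

    def value_at_state(self, t_index: int, x) -> float:
        idx = self.trunc.index_of(np.asarray(x, dtype=int))
        return float(self.V[t_index, int(idx)])


def fsp_solve_backward(network: ReactionNetwork, g_values: np.ndarray, T: float,
                       trunc: FspTruncation, query_times) -> FspBackwardSolution:
    """Value function V_g(t) = exp(Q(T - t)) g and jump differences Delta_k V_g.

    ``g_values`` is the output function tabulated on the box enumeration.
    """
    query_times = np.asarray(sorted(set(float(t) for t in query_times)))
    if query_times[0] < 0 or query_times[-1] > T + 1e-12:
        raise ValueError("query times must lie in [0, T]")
    Q = _generator(network, trunc)
    spans = T - query_times[::-1]  # increasing remaining-horizon values
    V_rev = _propagate(Q, np.asarray(g_values, dtype=float), spans)
    V = V_rev[::-1]  # back to query-time order

    m = trunc.num_states
    X = trunc.states()
    delta = np.zeros((len(query_times), network.K, m))
    for k, r in enumerate(network.reactions):
        tgt = trunc.index_of(X + r.zeta)
        ok = tgt >= 0
        delta[:, k, ok] = V[:, tgt[ok]] - V[:, ok]
    return FspBackwardSolution(trunc=trunc, T=float(T), times=query_times, V=V, delta_V=delta)


def fsp_expectation(network: ReactionNetwork, g, T: float, trunc: FspTruncation) -> float:
    """E[g(X(T))] by forward FSP from the network's initial state."""
    sol = fsp_solve_forward(network, network.x0, T, trunc)
    g_values = np.asarray(g(trunc.states()), dtype=float)
    return sol.expectation(g_values)


def fsp_sensitivity(network: ReactionNetwork, g, param: str, T: float,
                    trunc: FspTruncation, n_time: int = 200) -> float:
    """Deterministic sensitivity dE[g(X(T))]/d(param) via the policy-map integral.

    Evaluates ``sum_k int_0^T sum_x p(t,x) dlambda_k(x)/dtheta Delta_k V_g(t,x) dt``
    with trapezoidal time quadrature on ``n_time`` uniform steps, using the
    forward and backward FSP solutions on the same time grid.
    """
    times = np.linspace(0.0, T, n_time + 1)
    fwd = fsp_solve_forward(network, network.x0, T, trunc, times=times)
    X = trunc.states()
    g_values = np.asarray(g(X), dtype=float)
    bwd = fsp_solve_backward(network, g_values, T, trunc, times)
    names = network.param_names
    dlam = propensity_parameter_gradient_tensor(network, X)[:, :, names.index(param)]  # (m, K)
    # integrand(t) = sum_x p(t,x) sum_k dlam_k(x) Delta_k V(t,x)
    integrand = np.einsum("tm,mk,tkm->t", fwd.p, dlam, bwd.delta_V)
    return float(np.trapezoid(integrand, times))


def fsp_sensitivity_fd(network: ReactionNetwork, g, param: str, T: float,
                       trunc: FspTruncation, rel_step: float = 1e-4) -> float:
    """Central finite difference of the forward-FSP expectation (independent cross-check)."""
    theta = network.params[param]
    h = rel_step * max(1.0, abs(theta))
    hi = fsp_expectation(network.with_params(**{param: theta + h}), g, T, trunc)
    lo = fsp_expectation(network.with_params(**{param: theta - h}), g, T, trunc)
    return (hi - lo) / (2 * h)


# ---------------------------------------------------------------------------
# exactly-closed moment equations for affine propensities

class NotAffineError(ValueError):
    """Raised when a network has non-affine propensities (use FSP instead)."""


def _affine_representation(network: ReactionNetwork):
    """lambda_k(x) = a_k + b_k . x for every k, or raise NotAffineError."""
    n, K = network.n, network.K
    probes = np.vstack([np.zeros(n), np.eye(n), 2 * np.eye(n)]).astype(int)
    lams = propensity_matrix(network, probes)
    a = lams[0]
    b = lams[1:n + 1] - a  # rows: unit states
    # affinity check: lambda(2 e_i) must equal a + 2 b_i
    pred = a + 2 * b
    if not np.allclose(lams[n + 1:], pred, rtol=1e-9, atol=1e-9):
        raise NotAffineError("propensities are not affine in the state")
    for r in network.reactions:
        if r.propensity.kind == "mass_action" and sum(r.consume) > 1:
            raise NotAffineError("mass-action order > 1 is not affine")
        if r.propensity.kind not in ("mass_action",):
            raise NotAffineError(f"{r.propensity.kind} propensity is not affine")
    return a, b  # b as (n, K): column k is the state-gradient of lambda_k


@dataclass
class AffineMomentSolution:
    """First/second moments at T and their parameter sensitivities."""

    mean: np.ndarray              # (n,) E[X(T)]
    second: np.ndarray            # (n, n) E[X(T) X(T)^T]
    dmean: dict = field(default_factory=dict)    # param -> (n,)
    dsecond: dict = field(default_factory=dict)  # param -> (n, n)

    def species_moments(self, i: int) -> tuple:
        """(E[X_i], E[X_i^2]) for species index i (0-based)."""
        return float(self.mean[i]), float(self.second[i, i])


def affine_moment_odes(network: ReactionNetwork, T: float,
                       n_steps: int = 2000) -> AffineMomentSolution:
    """Integrate the exactly-closed moment ODEs of an affine-propensity network.

    For ``lambda_k(x) = a_k + b_k . x`` the mean and second-moment matrix obey

        m' = Z (a + B^T m)
        S' = sum_k [ (a_k m + S b_k) zeta_k^T + transpose + zeta_k zeta_k^T (a_k + b_k . m) ]

    with Z the (n, K) stoichiometry.  The system is closed (no higher moments
    appear), so the only error is the fixed-step RK4 time discretisation
    (step T / n_steps).  Parameter sensitivities are propagated alongside by
    forward-mode differentiation of the same ODEs.
    """
    a, B = _affine_representation(network)  # a: (K,), B: (n, K)
    Z = network.stoichiometry.T.astype(float)  # (n, K)
    n, K = network.n, network.K
    names = network.param_names
    X_probe = np.vstack([np.zeros(n), np.eye(n)]).astype(int)
    dlam = propensity_parameter_gradient_tensor(network, X_probe)  # (n+1, K, P)
    da = {p: dlam[0, :, i] for i, p in enumerate(names)}
    dB = {p: (dlam[1:, :, i] - dlam[0, :, i]).reshape(n, K) for i, p in enumerate(names)}

    def rhs(m, S, a_, B_):
        lam_mean = a_ + B_.T @ m  # (K,)
        dm = Z @ lam_mean
        ELX = np.outer(m, a_) + S @ B_  # (n, K): column k = E[lambda_k X]
        dS = ELX @ Z.T + Z @ ELX.T + Z @ (lam_mean[:, None] * Z.T)
        return dm, dS

    def rhs_sens(m, S, u, U, a_, B_, da_, dB_):
        # directional derivative of rhs w.r.t. the parameter
        lam_mean = a_ + B_.T @ m
        dlam_mean = da_ + dB_.T @ m + B_.T @ u
        du = Z @ dlam_mean
        ELX = np.outer(m, a_) + S @ B_
        dELX = np.outer(u, a_) + np.outer(m, da_) + U @ B_ + S @ dB_
        dU = dELX @ Z.T + Z @ dELX.T + Z @ (dlam_mean[:, None] * Z.T)
        return du, dU

    h = T / n_steps
    m = np.asarray(network.x0, dtype=float)
    S = np.outer(m, m)
    sens = {p: (np.zeros(n), np.zeros((n, n))) for p in names}
    for _ in range(n_steps):
        # RK4 on the coupled (m, S, sensitivities) system
        k1 = rhs(m, S, a, B)
        s1 = {p: rhs_sens(m, S, *sens[p], a, B, da[p], dB[p]) for p in names}
        m2, S2 = m + 0.5 * h * k1[0], S + 0.5 * h * k1[1]
        k2 = rhs(m2, S2, a, B)
        s2 = {p: rhs_sens(m2, S2, sens[p][0] + 0.5 * h * s1[p][0],
                          sens[p][1] + 0.5 * h * s1[p][1], a, B, da[p], dB[p]) for p in names}
        m3, S3 = m + 0.5 * h * k2[0], S + 0.5 * h * k2[1]
        k3 = rhs(m3, S3, a, B)
        s3 = {p: rhs_sens(m3, S3, sens[p][0] + 0.5 * h * s2[p][0],
                          sens[p][1] + 0.5 * h * s2[p][1], a, B, da[p], dB[p]) for p in names}
        m4, S4 = m + h * k3[0], S + h * k3[1]
        k4 = rhs(m4, S4, a, B)
        s4 = {p: rhs_sens(m4, S4, sens[p][0] + h * s3[p][0],
                          sens[p][1] + h * s3[p][1], a, B, da[p], dB[p]) for p in names}
        m = m + (h / 6) * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        S = S + (h / 6) * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        sens = {
            p: (
                sens[p][0] + (h / 6) * (s1[p][0] + 2 * s2[p][0] + 2 * s3[p][0] + s4[p][0]),
                sens[p][1] + (h / 6) * (s1[p][1] + 2 * s2[p][1] + 2 * s3[p][1] + s4[p][1]),
            )
            for p in names
        }
    return AffineMomentSolution(
        mean=m, second=S,
        dmean={p: sens[p][0] for p in names},
        dsecond={p: sens[p][1] for p in names},
    )


# ---------------------------------------------------------------------------
# closed forms for the single-species birth-death process

@dataclass(frozen=True)
class BirthDeathMoments:
    """Closed-form terminal moments and sensitivities of the birth-death process.

    With birth rate k and per-molecule degradation rate gamma started from
    zero copies, X(T) ~ Poisson(m) with m = (k/gamma)(1 - exp(-gamma T)).
    """

    mean: float
    second_moment: float
    dmean_dk: float
    dmean_dgamma: float
    dsecond_dk: float
    dsecond_dgamma: float


def birth_death_closed_form(k_rate: float, gamma: float, T: float) -> BirthDeathMoments:
    if k_rate <= 0 or gamma <= 0:
        raise ValueError("rates must be positive")
    e = math.exp(-gamma * T)
    m = (k_rate / gamma) * (1.0 - e)
    dm_dk = (1.0 - e) / gamma
    dm_dg = -m / gamma + (k_rate * T / gamma) * e
    # Poisson second moment m + m^2; chain rule for its sensitivities
    return BirthDeathMoments(
        mean=m,
        second_moment=m + m * m,
        dmean_dk=dm_dk,
        dmean_dgamma=dm_dg,
        dsecond_dk=(1 + 2 * m) * dm_dk,
        dsecond_dgamma=(1 + 2 * m) * dm_dg,
    )


# ---------------------------------------------------------------------------
# Monte-Carlo baseline

@dataclass(frozen=True)
class McEstimate:
    """Sample mean with standard error and 95% confidence half-width."""

    estimate: float
    stderr: float
    halfwidth: float
    n: int

    @property
    def ci(self) -> tuple:
        return (self.estimate - self.halfwidth, self.estimate + self.halfwidth)


def mc_estimate(batch: TrajectoryBatch) -> list:
    """Per-output sample mean, SE and 95% CI of g_i(X(T)) over a batch."""
    M = batch.M
    if M < 2:
        raise ValueError("need at least 2 trajectories for a standard error")
    out = []
    for i in range(batch.terminal_outputs.shape[1]):
        vals = batch.terminal_outputs[:, i]
        se = float(vals.std(ddof=1) / math.sqrt(M))
        out.append(McEstimate(estimate=float(vals.mean()), stderr=se,
                              halfwidth=1.96 * se, n=M))
    return out


# ---------------------------------------------------------------------------
# exact policy map as a lookup table

class TabularPolicy:
    """Policy map tabulated from backward FSP solves: V_{i,k}(t, x) = Delta_k V_{g_i}.

    Presents the same evaluation interface as the trainable policy network,
    so it can be substituted wherever a policy is consumed (pathwise
    recursion, sensitivity estimator).  Query times must coincide with the
    tabulated grid; states outside the truncation box evaluate to zero.
    """

    def __init__(self, network: ReactionNetwork, outputs: OutputSpec, T: float,
                 trunc: FspTruncation, times):
        self.network = network
        self.T = float(T)
        self.trunc = trunc
        self.times = np.asarray(sorted(set(float(t) for t in times)))
        X = trunc.states()
        tables = []
        for g in outputs.outputs:
            bwd = fsp_solve_backward(network, g(X), T, trunc, self.times)
            tables.append(bwd.delta_V)  # (nt, K, m)
        # (nt, R, K, m)
        self.tables = np.stack(tables, axis=1)
        self.R = outputs.R
        self.K = network.K

    def _time_index(self, tvals: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.times, tvals - 1e-9)
        idx = np.clip(idx, 0, len(self.times) - 1)
        if not np.allclose(self.times[idx], tvals, atol=1e-8):
            raise ValueError("query times must lie on the tabulated grid")
        return idx

    def forward_rows(self, tvals: np.ndarray, X: np.ndarray) -> np.ndarray:
        """(B,) times and (B, n) states -> (B, R, K) policy matrices."""
        ti = self._time_index(np.asarray(tvals, dtype=float))
        si = self.trunc.index_of(np.asarray(X, dtype=int))
        out = np.zeros((len(ti), self.R, self.K))
        ok = si >= 0
        out[ok] = self.tables[ti[ok], :, :, si[ok]]
        return out

    def __call__(self, t: float, x) -> np.ndarray:
        return self.forward_rows(np.array([t]), np.asarray(x)[None, :])[0]
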