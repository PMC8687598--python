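"""End-to-end estimation: moments, one-shot sensitivity tables, oracle comparison.

A trained policy yields two deliverables:

* the trained ``Y`` vector -- the estimates of ``E[g_i(X(T))]``,
* the full sensitivity table ``S[i, p] = d E[g_i(X(T))] / d theta_p`` for
  *every* registered parameter at once, by the Monte-Carlo estimator

      S[i, p] ~= (1/M) sum_q trapz_j( sum_k dlambda_k/dtheta_p (X^q(t_j))
                                        * V_{i,k}(t_j, X^q(t_j)) )

  over the same trajectory batch used for training.  The time integral is
  evaluated by the trapezoidal rule on the trajectory grid: the integrand's
  expectation is smooth in t, and a one-sided rule would leave a
  deterministic O(1/J) bias that dominates the Monte-Carlo error for
  sensitivity components whose integrand is state-independent.  No
  additional simulation per parameter is needed.

:func:`run_deepcme` drives the whole protocol from a config mapping:
simulate batches, train, estimate, baseline against an independent
Monte-Carlo batch, and attach whichever oracle applies (closed form for the
birth-death family, exact moment ODEs for affine networks, finite state
projection when the truncated state space is tractable).
"""

from __future__ import annotations

import csv
import json
import time
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import oracles as orc
from .networks import (
    ReactionNetwork,
    build_example_network,
    load_network,
    network_to_dict,
    propensity_parameter_gradient_tensor,
)
from .outputs import OutputSpec, SpeciesMoment, default_outputs
from .policy import PolicyConfig
from .simulate import TrajectoryBatch, simulate_batch
from .training import TrainingConfig, TrainingResult, train

__all__ = [
    "SensitivityTable",
    "EstimateReport",
    "estimate_sensitivities",
    "extract_estimates",
    "run_deepcme",
    "compare_to_oracle",
]


@dataclass
class SensitivityTable:
    """Estimated dE[g_i(X(T))]/d(theta_p) with per-entry Monte-Carlo standard errors."""

    output_names: list
    param_names: list
    values: np.ndarray   # (R, P)
    stderr: np.ndarray   # (R, P)

    def entry(self, output: str, param: str) -> tuple:
        i = self.output_names.index(output)
        p = self.param_names.index(param)
        return float(self.values[i, p]), float(self.stderr[i, p])


def estimate_sensitivities(policy, batch: TrajectoryBatch, network: ReactionNetwork,
                           outputs: OutputSpec, chunk: int = 1000) -> SensitivityTable:
    """One-shot sensitivity table from a policy and a trajectory batch.

    Works with any policy exposing ``forward_rows`` (trained network or
    exact tabular policy).  Processes trajectories in chunks to bound
    memory at large batch sizes.
    """
    if abs(getattr(policy, "T", batch.T) - batch.T) > 1e-9:
        raise ValueError("policy and batch horizons differ")
    M, Jp1, n = batch.states.shape
    # trapezoidal weights over the grid (w = dt/2 at the ends)
    w = np.zeros(Jp1)
    dt = np.diff(batch.times)
    w[:-1] += dt / 2
    w[1:] += dt / 2
    P = len(network.param_names)
    R = outputs.R
    per_path = np.empty((M, R, P))
    for lo in range(0, M, chunk):
        hi = min(lo + chunk, M)
        m = hi - lo
        Xrows = batch.states[lo:hi].reshape(m * Jp1, n)
        trows = np.tile(batch.times, m)
        V = policy.forward_rows(trows, Xrows).reshape(m, Jp1, R, policy.K)
        dlam = propensity_parameter_gradient_tensor(network, Xrows).reshape(m, Jp1, policy.K, P)
        per_path[lo:hi] = np.einsum("mjkp,mjrk,j->mrp", dlam, V, w)
    values = per_path.mean(axis=0)
    stderr = per_path.std(axis=0, ddof=1) / np.sqrt(M) if M > 1 else np.zeros_like(values)
    return SensitivityTable(output_names=outputs.names,
                            param_names=list(network.param_names),
                            values=values, stderr=stderr)


def extract_estimates(result: TrainingResult) -> dict:
    """Trained Y labelled by output name."""
    return {name: float(y) for name, y in zip(result.output_names, result.Y)}


# ---------------------------------------------------------------------------
# report container

@dataclass
class EstimateReport:
    """All numbers of one end-to-end run, each row tagged by its method.

    ``estimates`` rows: {output, method, value, stderr?, halfwidth?}.
    ``sensitivities`` rows: {output, parameter, method, value, stderr?}.
    Methods: deepcme, mc, closed_form, moment_ode, fsp.
    """

    network: dict
    config: dict
    estimates: list = field(default_factory=list)
    sensitivities: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def rows(self, kind: str = "estimates", method: str | None = None) -> list:
        rows = self.estimates if kind == "estimates" else self.sensitivities
        if method is None:
            return list(rows)
        return [r for r in rows if r["method"] == method]

    def value(self, output: str, method: str, parameter: str | None = None) -> float:
        rows = self.sensitivities if parameter is not None else self.estimates
        for r in rows:
            if r["output"] == output and r["method"] == method and \
                    r.get("parameter") == parameter:
                return r["value"]
        raise KeyError(f"no {method} row for {output!r}/{parameter!r}")

    def oracle_methods(self) -> list:
        present = {r["method"] for r in self.estimates}
        return [m for m in ("closed_form", "moment_ode", "fsp") if m in present]

    # -- serialisation -------------------------------------------------------
    def to_dict(self) -> dict:
        return {"network": self.network, "config": self.config,
                "estimates": self.estimates, "sensitivities": self.sensitivities,
                "metadata": self.metadata}

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path_or_text) -> "EstimateReport":
        text = str(path_or_text)
        if not text.lstrip().startswith("{"):
            with open(text) as fh:
                text = fh.read()
        d = json.loads(text)
        return cls(network=d["network"], config=d["config"],
                   estimates=d["estimates"], sensitivities=d["sensitivities"],
                   metadata=d["metadata"])

    def to_csv(self, path) -> None:
        cols = ["kind", "output", "parameter", "method", "value", "stderr", "halfwidth"]
        with open(path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=cols)
            w.writeheader()
            for r in self.estimates:
                w.writerow({"kind": "estimate", "parameter": "", **r})
            for r in self.sensitivities:
                w.writerow({"kind": "sensitivity", **r})


# ---------------------------------------------------------------------------
# oracle attachment

def _closed_form_rows(network, outputs, T):
    """Closed-form rows for the birth-death family (terminal species is an
    independent birth-death process started at zero)."""
    cf = orc.birth_death_closed_form(network.params["k"], network.params["gamma"], T)
    vals = {outputs.names[0]: cf.mean}
    sens = {(outputs.names[0], "k"): cf.dmean_dk, (outputs.names[0], "gamma"): cf.dmean_dgamma}
    if outputs.R > 1:
        vals[outputs.names[1]] = cf.second_moment
        sens[(outputs.names[1], "k")] = cf.dsecond_dk
        sens[(outputs.names[1], "gamma")] = cf.dsecond_dgamma
    est = [{"output": o, "method": "closed_form", "value": float(v)} for o, v in vals.items()]
    sen = [{"output": o, "parameter": p, "method": "closed_form", "value": float(v)}
           for (o, p), v in sens.items()]
    return est, sen


def _moment_ode_rows(network, outputs, T, species_index):
    sol = orc.affine_moment_odes(network, T)
    m1, m2 = sol.species_moments(species_index)
    vals = {outputs.names[0]: m1}
    if outputs.R > 1:
        vals[outputs.names[1]] = m2
    est = [{"output": o, "method": "moment_ode", "value": float(v)} for o, v in vals.items()]
    sen = []
    for p in network.param_names:
        sen.append({"output": outputs.names[0], "parameter": p, "method": "moment_ode",
                    "value": float(sol.dmean[p][species_index])})
        if outputs.R > 1:
            sen.append({"output": outputs.names[1], "parameter": p, "method": "moment_ode",
                        "value": float(sol.dsecond[p][species_index, species_index])})
    return est, sen


def _fsp_rows(network, outputs, T, trunc, n_time=200):
    X = trunc.states()
    fwd = orc.fsp_solve_forward(network, network.x0, T, trunc,
                                times=np.linspace(0.0, T, n_time + 1))
    dlam_all = propensity_parameter_gradient_tensor(network, X)  # (m, K, P)
    est, sen = [], []
    for g in outputs.outputs:
        gv = np.asarray(g(X), dtype=float)
        est.append({"output": g.name, "method": "fsp", "value": fwd.expectation(gv)})
        bwd = orc.fsp_solve_backward(network, gv, T, trunc, fwd.times)
        for p_idx, p in enumerate(network.param_names):
            integrand = np.einsum("tm,mk,tkm->t", fwd.p, dlam_all[:, :, p_idx], bwd.delta_V)
            sen.append({"output": g.name, "parameter": p, "method": "fsp",
                        "value": float(np.trapezoid(integrand, fwd.times))})
    return est, sen, float(fwd.leak[-1])


# ---------------------------------------------------------------------------
# protocol driver

DEFAULT_CONFIG = {
    "family": "birth_death",
    "n": 5,
    "T": 1.0,
    "J": 50,
    "M": 100,
    "M_val": 100,
    "M_mc": 1000,
    "seed": 0,
    "iterations": 10_000,
    "policy": {"L": 2, "N_H": 4, "r": 1},  # N_T defaults to 1 (5 for feedback_cascade)
    "mu": 0.0,
    "oracles": True,
    "fsp_max_states": 100_000,
}


def _subseeds(seed: int, count: int) -> list:
    base = np.random.SeedSequence(int(seed))
    return [int(c.generate_state(1)[0] % (2**31)) for c in base.spawn(count)]


def run_deepcme(config) -> EstimateReport:
    """Run the full protocol from a config mapping or YAML/JSON config file.

    Stages: simulate training and validation batches, train the policy,
    extract moment estimates and the one-shot sensitivity table, estimate a
    Monte-Carlo baseline on an independent fresh batch, and attach oracle
    rows where an oracle applies.  Fully reproducible from ``seed``.
    """
    if not isinstance(config, dict):
        with open(str(config)) as fh:
            config = yaml.safe_load(fh)
    cfg = {**DEFAULT_CONFIG, **config}
    pol_cfg = {**DEFAULT_CONFIG["policy"], **cfg.get("policy", {})}

    if "network_file" in cfg:
        network = load_network(cfg["network_file"])
        family = "custom"
    else:
        family = cfg["family"]
        network = build_example_network(family, cfg["n"])
    if "N_T" not in pol_cfg:
        pol_cfg["N_T"] = 5 if family == "feedback_cascade" else 1
    n, T, J = network.n, float(cfg["T"]), int(cfg["J"])
    outputs = default_outputs(n)

    seed_train, seed_val, seed_mc = _subseeds(cfg["seed"], 3)
    t0 = time.time()
    train_batch = simulate_batch(network, T, J, int(cfg["M"]), seed_train, outputs,
                                 role="training")
    val_batch = simulate_batch(network, T, J, int(cfg["M_val"]), seed_val, outputs,
                               role="validation")
    t_sim = time.time() - t0

    tc = TrainingConfig(
        iterations=int(cfg["iterations"]), seed=int(cfg["seed"]),
        policy=PolicyConfig(L=pol_cfg["L"], N_H=pol_cfg["N_H"], r=pol_cfg["r"],
                            N_T=pol_cfg["N_T"], seed=int(cfg["seed"])),
    )
    t0 = time.time()
    result = train(network, train_batch, val_batch, outputs, tc)
    t_train = time.time() - t0

    report = EstimateReport(network=network_to_dict(network),
                            config={k: v for k, v in cfg.items()})
    for name, y in extract_estimates(result).items():
        report.estimates.append({"output": name, "method": "deepcme", "value": y})
    table = estimate_sensitivities(result.policy, train_batch, network, outputs)
    for i, o in enumerate(table.output_names):
        for p, pname in enumerate(table.param_names):
            report.sensitivities.append({
                "output": o, "parameter": pname, "method": "deepcme",
                "value": float(table.values[i, p]), "stderr": float(table.stderr[i, p]),
            })

    mc_batch = simulate_batch(network, T, J, int(cfg["M_mc"]), seed_mc, outputs,
                              role="validation")
    for name, est in zip(outputs.names, orc.mc_estimate(mc_batch)):
        report.estimates.append({"output": name, "method": "mc", "value": est.estimate,
                                 "stderr": est.stderr, "halfwidth": est.halfwidth})

    leak = None
    if cfg["oracles"]:
        if family == "birth_death":
            est, sen = _closed_form_rows(network, outputs, T)
            report.estimates += est
            report.sensitivities += sen
        try:
            est, sen = _moment_ode_rows(network, outputs, T, n - 1)
            report.estimates += est
            report.sensitivities += sen
        except orc.NotAffineError:
            pass
        trunc = orc.default_truncation(network, T, seed=seed_mc)
        if trunc.num_states <= int(cfg["fsp_max_states"]):
            est, sen, leak = _fsp_rows(network, outputs, T, trunc)
            report.estimates += est
            report.sensitivities += sen

    report.metadata = {
        "family": family,
        "policy_config": dict(pol_cfg),
        "seed": int(cfg["seed"]),
        "subseeds": {"train": seed_train, "val": seed_val, "mc": seed_mc},
        "validation_loss_initial": float(result.val_history[0][1]),
        "validation_loss_final": float(result.val_history[-1][1]),
        "normalized_val_final": float(result.normalized_val_trace[-1]),
        "thresholds": [float(v) for v in result.thresholds],
        "fsp_leak": leak,
        "runtime_seconds": {"simulate": round(t_sim, 3), "train": round(t_train, 3)},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    return report


def compare_to_oracle(report: EstimateReport) -> list:
    """Per-quantity error table of the deep estimates against the best oracle.

    Oracle preference order: closed_form, then moment_ode, then fsp.  Also
    reports whether the Monte-Carlo confidence interval covers the oracle.
    Raises if the report carries no oracle rows.
    """
    methods = report.oracle_methods()
    if not methods:
        raise ValueError("report contains no oracle rows")
    rows = []
    for kind in ("estimates", "sensitivities"):
        for r in report.rows(kind, method="deepcme"):
            oracle_val = None
            oracle_method = None
            for m in methods:
                try:
                    oracle_val = report.value(r["output"], m, r.get("parameter"))
                    oracle_method = m
                    break
                except KeyError:
                    continue
            entry = {"kind": kind[:-1], "output": r["output"],
                     "parameter": r.get("parameter"), "deepcme": r["value"]}
            if oracle_val is None:
                entry.update({"oracle": None, "abs_error": None, "rel_error": None,
                              "mc_covers_oracle": None, "note": "not applicable"})
            else:
                abs_err = abs(r["value"] - oracle_val)
                entry.update({
                    "oracle": oracle_val,
                    "oracle_method": oracle_method,
                    "abs_error": abs_err,
                    "rel_error": abs_err / abs(oracle_val) if oracle_val else None,
                })
                if kind == "estimates":
                    try:
                        mc_rows = [e for e in report.estimates
                                   if e["method"] == "mc" and e["output"] == r["output"]]
                        mc = mc_rows[0]
                        entry["mc_covers_oracle"] = bool(
                            abs(mc["value"] - oracle_val) <= mc["halfwidth"])
                    except IndexError:
                        entry["mc_covers_oracle"] = None
            rows.append(entry)
    return rows
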