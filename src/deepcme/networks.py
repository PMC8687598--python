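"""Stochastic reaction networks with differentiable propensity functions.

A reaction network couples ``n`` chemical species through ``K`` reactions.
Each reaction ``k`` consumes ``nu_k`` and produces ``nu'_k`` molecules, so a
firing displaces the copy-number state ``x`` by the stoichiometric vector
``zeta_k = nu'_k - nu_k``.  Firings occur at the state-dependent rate
``lambda_k(x)`` (the propensity).  Three builtin propensity kinds are
provided:

* ``mass_action`` -- ``lambda_k(x) = c_k * prod_i C(x_i, nu_ki)`` with rate
  constant ``c_k`` and binomial coefficients of the reactant counts,
* ``hill_activating`` -- ``b + k_m * x^H / (k_0 + x^H)`` of a regulator
  species' copy-number ``x``,
* ``hill_repressing`` -- ``b + k_m / (k_0 + x^H)``,

plus a ``custom`` kind wrapping a user callable.  All rate constants are
referenced *by name* in a per-network parameter registry so that parameter
sensitivities are self-describing.  Analytic gradients of every builtin
propensity with respect to every registered parameter are available;
``custom`` propensities fall back to central finite differences.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import yaml

__all__ = [
    "PropensitySpec",
    "Reaction",
    "ReactionNetwork",
    "NetworkDiagnostics",
    "evaluate_propensity",
    "propensity_parameter_gradient",
    "propensity_matrix",
    "propensity_parameter_gradient_tensor",
    "build_example_network",
    "validate_network",
    "network_to_dict",
    "network_from_dict",
    "save_network",
    "load_network",
]

EXAMPLE_FAMILIES = ("birth_death", "linear_cascade", "nonlinear_cascade", "feedback_cascade")

_BUILTIN_KINDS = ("mass_action", "hill_activating", "hill_repressing", "custom")

# central-difference step for custom propensity parameter gradients
_FD_REL_STEP = 1e-6


class ConfigurationError(ValueError):
    """Raised for ill-formed network specifications (unknown kinds, missing parameters)."""


@dataclass(frozen=True)
class PropensitySpec:
    """Propensity kind plus the registry names of the parameters it uses.

    ``params`` maps a *role* (``rate`` for mass action; ``basal``, ``gain``,
    ``half_saturation``, ``exponent`` for Hill kinds) to a parameter name in
    the owning network's registry.  ``regulator`` is the 0-based species
    index whose copy-number enters a Hill function.  ``rate_fn`` implements
    the ``custom`` kind with signature ``(state, params: dict) -> rate``.
    """

    kind: str
    params: dict = field(default_factory=dict)
    regulator: int | None = None
    rate_fn: Callable | None = None

    def __post_init__(self):
        if self.kind not in _BUILTIN_KINDS:
            raise ConfigurationError(f"unknown propensity kind {self.kind!r}")
        if self.kind == "mass_action" and "rate" not in self.params:
            raise ConfigurationError("mass_action propensity needs a 'rate' parameter")
        if self.kind in ("hill_activating", "hill_repressing"):
            missing = {"basal", "gain", "half_saturation", "exponent"} - set(self.params)
            if missing:
                raise ConfigurationError(f"hill propensity missing roles {sorted(missing)}")
            if self.regulator is None:
                raise ConfigurationError("hill propensity needs a regulator species index")
        if self.kind == "custom" and self.rate_fn is None:
            raise ConfigurationError("custom propensity needs a rate_fn")


@dataclass(frozen=True)
class Reaction:
    """One reaction channel: consumption/production vectors and a propensity."""

    consume: tuple
    produce: tuple
    propensity: PropensitySpec

    def __post_init__(self):
        c = np.asarray(self.consume, dtype=int)
        p = np.asarray(self.produce, dtype=int)
        if c.shape != p.shape:
            raise ConfigurationError("consume/produce vectors differ in length")
        if (c < 0).any() or (p < 0).any():
            raise ConfigurationError("stoichiometric coefficients must be nonnegative")
        if (c == p).all():
            raise ConfigurationError("reaction has all-zero net stoichiometry")
        object.__setattr__(self, "consume", tuple(int(v) for v in c))
        object.__setattr__(self, "produce", tuple(int(v) for v in p))

    @property
    def zeta(self) -> np.ndarray:
        """Net stoichiometric displacement ``nu' - nu``."""
        return np.asarray(self.produce, dtype=int) - np.asarray(self.consume, dtype=int)


@dataclass
class ReactionNetwork:
    """``n`` species, an ordered list of reactions, and a named parameter registry.

    Reaction order is fixed: it indexes the columns of the policy-map matrix
    and the reaction counters of simulated trajectories.
    """

    n: int
    reactions: list
    params: dict
    x0: tuple
    species_names: list | None = None

    def __post_init__(self):
        if self.n < 1:
            raise ConfigurationError("need at least one species")
        if len(self.reactions) < 1:
            raise ConfigurationError("need at least one reaction")
        self.x0 = tuple(int(v) for v in self.x0)
        if len(self.x0) != self.n or any(v < 0 for v in self.x0):
            raise ConfigurationError("x0 must be n nonnegative integers")
        self.params = dict(self.params)
        if self.species_names is None:
            self.species_names = [f"X{i+1}" for i in range(self.n)]
        for i, r in enumerate(self.reactions):
            if len(r.consume) != self.n:
                raise ConfigurationError(f"reaction {i+1} has wrong species count")
            for name in r.propensity.params.values():
                if name not in self.params:
                    raise ConfigurationError(
                        f"reaction {i+1} references unregistered parameter {name!r}"
                    )

    @property
    def K(self) -> int:
        return len(self.reactions)

    @property
    def param_names(self) -> list:
        return list(self.params)

    @property
    def stoichiometry(self) -> np.ndarray:
        """(K, n) array of net stoichiometric vectors."""
        return np.stack([r.zeta for r in self.reactions])

    def with_params(self, **updates) -> "ReactionNetwork":
        """Copy of the network with some registry values replaced."""
        unknown = set(updates) - set(self.params)
        if unknown:
            raise ConfigurationError(f"unregistered parameters {sorted(unknown)}")
        new = dict(self.params)
        new.update(updates)
        return ReactionNetwork(self.n, list(self.reactions), new, self.x0,
                               list(self.species_names))


def _check_state(x, n: int) -> np.ndarray:
    x = np.asarray(x)
    if x.shape != (n,):
        raise ValueError(f"state must have {n} entries, got shape {x.shape}")
    if np.any(x < 0):
        raise ValueError("state entries must be nonnegative")
    if not np.all(np.equal(np.mod(x, 1), 0)):
        raise ValueError("state entries must be integers")
    return x.astype(float)


def _mass_action_factor(x: np.ndarray, consume) -> float:
    """prod_i C(x_i, nu_i), zero on reactant shortage."""
    out = 1.0
    for xi, nu in zip(x, consume):
        if nu == 0:
            continue
        if xi < nu:
            return 0.0
        out *= math.comb(int(xi), nu)
    return out


def evaluate_propensity(network: ReactionNetwork, k: int, x) -> float:
    """Propensity ``lambda_k(x)`` of reaction ``k`` (1-based) at state ``x``."""
    if not 1 <= k <= network.K:
        raise ValueError(f"reaction index {k} outside 1..{network.K}")
    x = _check_state(x, network.n)
    r = network.reactions[k - 1]
    spec = r.propensity
    theta = {role: network.params[name] for role, name in spec.params.items()}
    if spec.kind == "mass_action":
        return theta["rate"] * _mass_action_factor(x, r.consume)
    if spec.kind in ("hill_activating", "hill_repressing"):
        s = float(x[spec.regulator])
        b, km, k0, H = theta["basal"], theta["gain"], theta["half_saturation"], theta["exponent"]
        sH = s ** H if s > 0 else (1.0 if H == 0 else 0.0)
        if spec.kind == "hill_activating":
            return b + km * sH / (k0 + sH)
        return b + km / (k0 + sH)
    # custom: pass the full registry under its own names
    val = float(spec.rate_fn(x, dict(network.params)))
    if val < 0:
        raise ValueError(f"custom propensity of reaction {k} returned negative rate {val}")
    return val


def _hill_role_gradients(spec: PropensitySpec, theta: dict, s: float) -> dict:
    """Analytic d(lambda)/d(role) for a Hill propensity at regulator copy-number s."""
    b, km, k0, H = theta["basal"], theta["gain"], theta["half_saturation"], theta["exponent"]
    sH = s ** H if s > 0 else (1.0 if H == 0 else 0.0)
    den = k0 + sH
    dsH_dH = sH * math.log(s) if s > 0 else 0.0
    if spec.kind == "hill_activating":
        return {
            "basal": 1.0,
            "gain": sH / den,
            "half_saturation": -km * sH / den**2,
            "exponent": km * k0 * dsH_dH / den**2,
        }
    return {
        "basal": 1.0,
        "gain": 1.0 / den,
        "half_saturation": -km / den**2,
        "exponent": -km * dsH_dH / den**2,
    }


def propensity_parameter_gradient(network: ReactionNetwork, k: int, x, param: str) -> float:
    """Partial derivative of ``lambda_k(x)`` w.r.t. the registered parameter ``param``.

    Analytic for all builtin kinds; central finite differences (relative step
    1e-6) for ``custom`` propensities.  Zero when the propensity does not
    reference the parameter.
    """
    if param not in network.params:
        raise ConfigurationError(f"parameter {param!r} not registered")
    r = network.reactions[k - 1]
    spec = r.propensity
    if spec.kind == "custom":
        theta = network.params[param]
        h = _FD_REL_STEP * max(1.0, abs(theta))
        hi = network.with_params(**{param: theta + h})
        lo = network.with_params(**{param: theta - h})
        return (evaluate_propensity(hi, k, x) - evaluate_propensity(lo, k, x)) / (2 * h)
    if param not in spec.params.values():
        return 0.0
    x = _check_state(x, network.n)
    theta = {role: network.params[name] for role, name in spec.params.items()}
    if spec.kind == "mass_action":
        # the same registry name could in principle fill several roles; here
        # mass action has a single role, so the gradient is the binomial factor
        return _mass_action_factor(x, r.consume)
    grads = _hill_role_gradients(spec, theta, float(x[spec.regulator]))
    return sum(g for role, g in grads.items() if spec.params[role] == param)


# ---------------------------------------------------------------------------
# vectorised evaluation over state batches (used by FSP and the Eq-16 estimator)

def propensity_matrix(network: ReactionNetwork, X: np.ndarray) -> np.ndarray:
    """Propensities of all reactions at a batch of states.

    Parameters
    ----------
    X : (B, n) array of nonnegative integer states.

    Returns
    -------
    (B, K) array with entry [q, k-1] = lambda_k(X[q]).
    """
    X = np.asarray(X, dtype=float)
    B = X.shape[0]
    out = np.empty((B, network.K))
    for j, r in enumerate(network.reactions):
        spec = r.propensity
        if spec.kind == "mass_action":
            c = network.params[spec.params["rate"]]
            lam = np.full(B, c)
            for i, nu in enumerate(r.consume):
                if nu == 1:
                    lam *= X[:, i]
                elif nu > 1:
                    fac = np.ones(B)
                    for d in range(nu):
                        fac *= X[:, i] - d
                    lam *= np.clip(fac, 0.0, None) / math.factorial(nu)
            out[:, j] = lam
        elif spec.kind in ("hill_activating", "hill_repressing"):
            theta = {role: network.params[name] for role, name in spec.params.items()}
            s = X[:, spec.regulator]
            H = theta["exponent"]
            with np.errstate(divide="ignore"):
                sH = np.where(s > 0, s ** H, 1.0 if H == 0 else 0.0)
            den = theta["half_saturation"] + sH
            if spec.kind == "hill_activating":
                out[:, j] = theta["basal"] + theta["gain"] * sH / den
            else:
                out[:, j] = theta["basal"] + theta["gain"] / den
        else:
            out[:, j] = [evaluate_propensity(network, j + 1, x) for x in X]
    return out


def propensity_parameter_gradient_tensor(network: ReactionNetwork, X: np.ndarray) -> np.ndarray:
    """d(lambda_k)/d(theta_p) for all reactions and registered parameters.

    Returns a (B, K, P) array with P = number of registered parameters, in
    registry order.  Used by the one-shot sensitivity estimator, which needs
    the gradient of every propensity at every visited state.
    """
    X = np.asarray(X, dtype=float)
    B = X.shape[0]
    names = network.param_names
    out = np.zeros((B, network.K, len(names)))
    for j, r in enumerate(network.reactions):
        spec = r.propensity
        if spec.kind == "mass_action":
            p = names.index(spec.params["rate"])
            # d(lambda)/d(c) is the product of binomial factors of the reactants
            fac = np.ones(B)
            for i, nu in enumerate(r.consume):
                if nu >= 1:
                    f = np.ones(B)
                    for d in range(nu):
                        f *= X[:, i] - d
                    fac *= np.clip(f, 0.0, None) / math.factorial(nu)
            out[:, j, p] = fac
        elif spec.kind in ("hill_activating", "hill_repressing"):
            theta = {role: network.params[name] for role, name in spec.params.items()}
            s = X[:, spec.regulator]
            H = theta["exponent"]
            sH = np.where(s > 0, s ** H, 1.0 if H == 0 else 0.0)
            den = theta["half_saturation"] + sH
            logs = np.where(s > 0, np.log(np.where(s > 0, s, 1.0)), 0.0)
            dsH_dH = sH * logs
            if spec.kind == "hill_activating":
                role_grads = {
                    "basal": np.ones(B),
                    "gain": sH / den,
                    "half_saturation": -theta["gain"] * sH / den**2,
                    "exponent": theta["gain"] * theta["half_saturation"] * dsH_dH / den**2,
                }
            else:
                role_grads = {
                    "basal": np.ones(B),
                    "gain": 1.0 / den,
                    "half_saturation": -theta["gain"] / den**2,
                    "exponent": -theta["gain"] * dsH_dH / den**2,
                }
            for role, name in spec.params.items():
                out[:, j, names.index(name)] += role_grads[role]
        else:
            for p, name in enumerate(names):
                out[:, j, p] = [
                    propensity_parameter_gradient(network, j + 1, x, name) for x in X
                ]
    return out


# ---------------------------------------------------------------------------
# example families

def build_example_network(family: str, n: int) -> ReactionNetwork:
    """The four example network families, each with ``n`` species and ``2n`` reactions.

    * ``birth_death`` -- n independent birth-death pairs, birth rate k=10,
      degradation rate gamma=1.
    * ``linear_cascade`` -- constitutive production of X1 at beta0=10, linear
      catalysis X_i -> X_i + X_{i+1} at rate k=5 per catalyst molecule,
      degradation gamma=1 for every species.
    * ``nonlinear_cascade`` -- like the linear cascade but catalysis follows
      an activating Hill law b + k_m x^H / (k_0 + x^H) with b=1, k_m=100,
      k_0=10, H=1.
    * ``feedback_cascade`` -- linear cascade whose production of X1 is
      repressed by X_n through b + k_m / (k_0 + x_n^H), same Hill constants;
      catalysis rate k=5, degradation gamma=1.

    Production reactions come first (in species order), then one degradation
    per species.  All species start at zero copies.  Each rate constant is a
    single shared registry entry across its reactions, so sensitivity tables
    report one column per named constant.
    """
    if family not in EXAMPLE_FAMILIES:
        raise ConfigurationError(f"unknown example family {family!r}")
    if n < 1 or (family != "birth_death" and n < 2):
        raise ConfigurationError(f"family {family!r} needs n >= {1 if family == 'birth_death' else 2}")

    def unit(i):
        v = [0] * n
        v[i] = 1
        return tuple(v)

    zero = tuple([0] * n)
    hill_params = {"basal": "b", "gain": "km", "half_saturation": "k0", "exponent": "H"}
    hill_values = {"b": 1.0, "km": 100.0, "k0": 10.0, "H": 1.0}
    reactions: list = []

    if family == "birth_death":
        params = {"k": 10.0, "gamma": 1.0}
        for i in range(n):
            reactions.append(Reaction(zero, unit(i), PropensitySpec("mass_action", {"rate": "k"})))
    elif family == "linear_cascade":
        params = {"beta0": 10.0, "k": 5.0, "gamma": 1.0}
        reactions.append(Reaction(zero, unit(0), PropensitySpec("mass_action", {"rate": "beta0"})))
        for i in range(n - 1):
            reactions.append(
                Reaction(unit(i), tuple(np.array(unit(i)) + np.array(unit(i + 1))),
                         PropensitySpec("mass_action", {"rate": "k"}))
            )
    elif family == "nonlinear_cascade":
        params = {"beta0": 10.0, "gamma": 1.0, **hill_values}
        reactions.append(Reaction(zero, unit(0), PropensitySpec("mass_action", {"rate": "beta0"})))
        for i in range(n - 1):
            reactions.append(
                Reaction(zero, unit(i + 1),
                         PropensitySpec("hill_activating", dict(hill_params), regulator=i))
            )
    else:  # feedback_cascade
        params = {"k": 5.0, "gamma": 1.0, **hill_values}
        reactions.append(
            Reaction(zero, unit(0),
                     PropensitySpec("hill_repressing", dict(hill_params), regulator=n - 1))
        )
        for i in range(n - 1):
            reactions.append(
                Reaction(unit(i), tuple(np.array(unit(i)) + np.array(unit(i + 1))),
                         PropensitySpec("mass_action", {"rate": "k"}))
            )

    for i in range(n):
        reactions.append(Reaction(unit(i), zero, PropensitySpec("mass_action", {"rate": "gamma"})))

    return ReactionNetwork(n=n, reactions=reactions, params=params, x0=zero)


# ---------------------------------------------------------------------------
# diagnostics

@dataclass
class NetworkDiagnostics:
    """Result of :func:`validate_network`: per-check messages plus an overall flag."""

    ok: bool
    issues: list
    checks_run: int


def validate_network(network: ReactionNetwork, probe_states: Sequence | None = None,
                     rng: np.random.Generator | None = None) -> NetworkDiagnostics:
    """Sanity-check a network on a probe set of states.

    Checks that propensities are nonnegative on the probes, that no reaction
    with positive propensity would drive a species negative (closure of the
    state space under the dynamics), and that every referenced parameter is
    registered.  Diagnostics only -- never raises for a flagged network.
    """
    issues: list = []
    checks = 0
    if rng is None:
        rng = np.random.default_rng(0)
    if probe_states is None:
        probes = [np.array(network.x0, dtype=int)]
        probes += [rng.integers(0, 30, size=network.n) for _ in range(50)]
    else:
        probes = [np.asarray(p, dtype=int) for p in probe_states]

    for k, r in enumerate(network.reactions, start=1):
        for name in r.propensity.params.values():
            checks += 1
            if name not in network.params:
                issues.append(f"reaction {k}: unregistered parameter {name!r}")
        zeta = r.zeta
        for x in probes:
            checks += 1
            try:
                lam = evaluate_propensity(network, k, x)
            except Exception as exc:  # noqa: BLE001 - diagnostics collect, not raise
                issues.append(f"reaction {k}: propensity failed at {tuple(x)}: {exc}")
                continue
            if lam < 0:
                issues.append(f"reaction {k}: negative propensity {lam} at {tuple(x)}")
            if lam > 0 and np.any(x + zeta < 0):
                issues.append(
                    f"reaction {k}: positive propensity at {tuple(x)} but firing "
                    f"drives a species negative (zeta={tuple(zeta)})"
                )
    return NetworkDiagnostics(ok=not issues, issues=issues, checks_run=checks)


# ---------------------------------------------------------------------------
# definition-file round trip (YAML / JSON)

def network_to_dict(network: ReactionNetwork) -> dict:
    reactions = []
    for r in network.reactions:
        spec = r.propensity
        if spec.kind == "custom":
            raise ConfigurationError("custom propensities are not serialisable")
        entry = {
            "consume": list(r.consume),
            "produce": list(r.produce),
            "kind": spec.kind,
            "params": dict(spec.params),
        }
        if spec.regulator is not None:
            entry["regulator"] = spec.regulator
        reactions.append(entry)
    return {
        "species": list(network.species_names),
        "parameters": {k: float(v) for k, v in network.params.items()},
        "initial_state": list(network.x0),
        "reactions": reactions,
    }


def network_from_dict(data: dict) -> ReactionNetwork:
    species = list(data["species"])
    reactions = [
        Reaction(
            tuple(e["consume"]),
            tuple(e["produce"]),
            PropensitySpec(e["kind"], dict(e["params"]), regulator=e.get("regulator")),
        )
        for e in data["reactions"]
    ]
    return ReactionNetwork(
        n=len(species),
        reactions=reactions,
        params=dict(data["parameters"]),
        x0=tuple(data["initial_state"]),
        species_names=species,
    )


def save_network(network: ReactionNetwork, path) -> None:
    data = network_to_dict(network)
    path = str(path)
    with open(path, "w") as fh:
        if path.endswith(".json"):
            json.dump(data, fh, indent=2)
        else:
            yaml.safe_dump(data, fh, sort_keys=False)


def load_network(path) -> ReactionNetwork:
    path = str(path)
    with open(path) as fh:
        data = json.load(fh) if path.endswith(".json") else yaml.safe_load(fh)
    return network_from_dict(data)
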