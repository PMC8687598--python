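"""Reaction network construction, propensity evaluation and parameter gradients."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from deepcme.networks import (
    ConfigurationError,
    PropensitySpec,
    Reaction,
    ReactionNetwork,
    build_example_network,
    evaluate_propensity,
    load_network,
    network_from_dict,
    network_to_dict,
    propensity_matrix,
    propensity_parameter_gradient,
    propensity_parameter_gradient_tensor,
    save_network,
    validate_network,
)


def _single_reaction_net(consume, produce, spec, params, n=None):
    n = n if n is not None else len(consume)
    return ReactionNetwork(n=n, reactions=[Reaction(consume, produce, spec)],
                           params=params, x0=(0,) * n)


class TestEvaluatePropensity:
    @pytest.mark.parametrize(
        "consume,c,x,expected",
        [
            ((2,), 1.0, (3,), 3.0),    # C(3,2) = 3
            ((2,), 5.0, (1,), 0.0),    # reactant shortage
            ((1,), 2.5, (4,), 10.0),
            ((0,), 7.0, (0,), 7.0),    # zeroth order
        ],
    )
    def test_mass_action(self, consume, c, x, expected):
        net = _single_reaction_net(consume, (0,) if consume != (0,) else (1,),
                                   PropensitySpec("mass_action", {"rate": "c"}), {"c": c})
        assert evaluate_propensity(net, 1, x) == pytest.approx(expected)

    def test_hill_activating(self):
        spec = PropensitySpec("hill_activating",
                              {"basal": "b", "gain": "km", "half_saturation": "k0",
                               "exponent": "H"}, regulator=0)
        net = _single_reaction_net((0,), (1,), spec,
                                   {"b": 1.0, "km": 100.0, "k0": 10.0, "H": 1.0})
        # b + km*x/(k0+x) at x=10: 1 + 1000/20 = 51
        assert evaluate_propensity(net, 1, (10,)) == pytest.approx(51.0)

    def test_hill_repressing_at_zero(self):
        spec = PropensitySpec("hill_repressing",
                              {"basal": "b", "gain": "km", "half_saturation": "k0",
                               "exponent": "H"}, regulator=0)
        net = _single_reaction_net((0,), (1,), spec,
                                   {"b": 1.0, "km": 100.0, "k0": 10.0, "H": 1.0})
        # b + km/k0 at x=0: 1 + 10 = 11
        assert evaluate_propensity(net, 1, (0,)) == pytest.approx(11.0)

    def test_rejects_bad_states(self, bd1):
        with pytest.raises(ValueError):
            evaluate_propensity(bd1, 1, (-1,))
        with pytest.raises(ValueError):
            evaluate_propensity(bd1, 1, (1.5,))
        with pytest.raises(ValueError):
            evaluate_propensity(bd1, 99, (0,))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigurationError):
            PropensitySpec("michaelis", {"rate": "c"})

    def test_matrix_matches_scalar(self, rng):
        net = build_example_network("nonlinear_cascade", 3)
        X = rng.integers(0, 25, size=(40, 3))
        mat = propensity_matrix(net, X)
        for q in range(8):
            for k in range(1, net.K + 1):
                assert mat[q, k - 1] == pytest.approx(
                    evaluate_propensity(net, k, X[q]), rel=1e-12)


class TestParameterGradient:
    def test_mass_action_rate_gradient(self):
        net = _single_reaction_net((2,), (0,), PropensitySpec("mass_action", {"rate": "c"}),
                                   {"c": 1.0})
        assert propensity_parameter_gradient(net, 1, (3,), "c") == pytest.approx(3.0)

    def test_hill_basal_and_gain(self):
        spec = PropensitySpec("hill_activating",
                              {"basal": "b", "gain": "km", "half_saturation": "k0",
                               "exponent": "H"}, regulator=0)
        net = _single_reaction_net((0,), (1,), spec,
                                   {"b": 1.0, "km": 100.0, "k0": 10.0, "H": 1.0})
        assert propensity_parameter_gradient(net, 1, (5,), "b") == pytest.approx(1.0)
        # d/d(km) = x/(k0+x) = 10/20
        assert propensity_parameter_gradient(net, 1, (10,), "km") == pytest.approx(0.5)

    def test_unreferenced_param_zero(self, bd1):
        assert propensity_parameter_gradient(bd1, 1, (4,), "gamma") == 0.0

    def test_unregistered_param_rejected(self, bd1):
        with pytest.raises(ConfigurationError):
            propensity_parameter_gradient(bd1, 1, (4,), "nope")

    def test_custom_finite_difference(self):
        spec = PropensitySpec("custom", rate_fn=lambda x, p: p["theta"] ** 2)
        net = _single_reaction_net((0,), (1,), spec, {"theta": 3.0})
        g = propensity_parameter_gradient(net, 1, (0,), "theta")
        assert g == pytest.approx(6.0, rel=1e-6)

    @given(
        c=st.floats(0.1, 50),
        x=st.integers(0, 40),
        nu=st.integers(0, 3),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_mass_action_identity(self, c, x, nu):
        """lambda(x) = c * d(lambda)/dc exactly, for any order."""
        net = _single_reaction_net((nu,), (nu + 1,),
                                   PropensitySpec("mass_action", {"rate": "c"}), {"c": c})
        lam = evaluate_propensity(net, 1, (x,))
        grad = propensity_parameter_gradient(net, 1, (x,), "c")
        assert lam == pytest.approx(c * grad, rel=1e-12, abs=1e-12)

    @given(
        kind=st.sampled_from(["hill_activating", "hill_repressing"]),
        b=st.floats(0.1, 5),
        km=st.floats(1, 200),
        k0=st.floats(1, 50),
        H=st.floats(0.5, 3),
        x=st.integers(0, 60),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_hill_gradients_match_finite_differences(self, kind, b, km, k0, H, x):
        spec = PropensitySpec(kind, {"basal": "b", "gain": "km",
                                     "half_saturation": "k0", "exponent": "H"},
                              regulator=0)
        net = _single_reaction_net((0,), (1,), spec,
                                   {"b": b, "km": km, "k0": k0, "H": H})
        for p in ("b", "km", "k0", "H"):
            theta = net.params[p]
            h = 1e-6 * max(1.0, abs(theta))
            hi = evaluate_propensity(net.with_params(**{p: theta + h}), 1, (x,))
            lo = evaluate_propensity(net.with_params(**{p: theta - h}), 1, (x,))
            fd = (hi - lo) / (2 * h)
            an = propensity_parameter_gradient(net, 1, (x,), p)
            assert an == pytest.approx(fd, rel=1e-5, abs=1e-7)

    def test_gradient_tensor_matches_scalar(self, rng):
        net = build_example_network("feedback_cascade", 2)
        X = rng.integers(0, 20, size=(10, 2))
        ten = propensity_parameter_gradient_tensor(net, X)
        names = net.param_names
        for q in range(10):
            for k in range(1, net.K + 1):
                for p_idx, p in enumerate(names):
                    assert ten[q, k - 1, p_idx] == pytest.approx(
                        propensity_parameter_gradient(net, k, X[q], p), rel=1e-9, abs=1e-12)


class TestExampleFamilies:
    def test_birth_death_structure(self):
        net = build_example_network("birth_death", 5)
        assert net.K == 10
        assert len(net.params) == 2
        assert net.x0 == (0,) * 5

    def test_linear_cascade_catalysis(self):
        net = build_example_network("linear_cascade", 2)
        assert net.K == 4
        # reaction 2 is X1 -> X1 + X2 at rate k * x1 = 5 * 3
        r = net.reactions[1]
        assert tuple(r.zeta) == (0, 1)
        assert evaluate_propensity(net, 2, (3, 0)) == pytest.approx(15.0)

    def test_feedback_first_reaction(self):
        net = build_example_network("feedback_cascade", 2)
        assert evaluate_propensity(net, 1, (0, 0)) == pytest.approx(11.0)

    def test_nonlinear_production(self):
        net = build_example_network("nonlinear_cascade", 2)
        # production of X2 at x1=10: 1 + 100*10/20 = 51
        assert evaluate_propensity(net, 2, (10, 0)) == pytest.approx(51.0)

    def test_unknown_family(self):
        with pytest.raises(ConfigurationError):
            build_example_network("oscillator", 2)

    @pytest.mark.parametrize("family", ["linear_cascade", "nonlinear_cascade",
                                        "feedback_cascade"])
    def test_cascades_need_two_species(self, family):
        with pytest.raises(ConfigurationError):
            build_example_network(family, 1)

    @pytest.mark.parametrize("family,n", [("birth_death", 3), ("linear_cascade", 3),
                                          ("nonlinear_cascade", 2), ("feedback_cascade", 4)])
    def test_propensities_nonnegative_on_probes(self, family, n, rng):
        net = build_example_network(family, n)
        X = rng.integers(0, 50, size=(60, n))
        assert (propensity_matrix(net, X) >= 0).all()


class TestValidateNetwork:
    def test_examples_pass(self):
        for family in ("birth_death", "linear_cascade"):
            diag = validate_network(build_example_network(family, 2))
            assert diag.ok, diag.issues

    def test_closure_violation_flagged(self):
        # constant-rate degradation fires at x=0 and drives the count negative
        spec = PropensitySpec("custom", rate_fn=lambda x, p: p["c"])
        net = _single_reaction_net((1,), (0,), spec, {"c": 2.0})
        diag = validate_network(net, probe_states=[(0,), (3,)])
        assert not diag.ok
        assert any("negative" in msg for msg in diag.issues)


class TestSerialisation:
    @pytest.mark.parametrize("family", ["birth_death", "nonlinear_cascade",
                                        "feedback_cascade"])
    def test_round_trip(self, family, tmp_path):
        net = build_example_network(family, 2)
        back = network_from_dict(network_to_dict(net))
        assert network_to_dict(back) == network_to_dict(net)
        for ext in ("yaml", "json"):
            path = tmp_path / f"net.{ext}"
            save_network(net, path)
            loaded = load_network(path)
            assert network_to_dict(loaded) == network_to_dict(net)

    def test_unregistered_parameter_rejected(self):
        data = network_to_dict(build_example_network("birth_death", 1))
        del data["parameters"]["gamma"]
        with pytest.raises(ConfigurationError):
            network_from_dict(data)
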