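"""Martingale loss, pathwise recursion and the training loop."""

import math

import numpy as np
import pytest

from deepcme.networks import build_example_network
from deepcme.oracles import FspTruncation, TabularPolicy, birth_death_closed_form
from deepcme.policy import PolicyConfig, init_policy
from deepcme.simulate import TrajectoryBatch, simulate_batch
from deepcme.training import (
    LossConfig,
    TrainingConfig,
    batch_terminal,
    empirical_loss,
    pathwise_terminal,
    phi,
    phi_prime,
    thresholds_from_batch,
    train,
)

CF = birth_death_closed_form(10.0, 1.0, 1.0)


def zero_policy(n, K, R, T=1.0, seed=0):
    pol = init_policy(n, K, R, T, PolicyConfig(seed=seed))
    for seg in pol.segments:
        for W in seg.weights:
            W[:] = 0.0
    return pol


def fake_batch(network, terminal_outputs, J=1):
    """Batch with motionless paths and zero counters; only g(X(T)) matters."""
    g = np.atleast_2d(np.asarray(terminal_outputs, dtype=float))
    M, R = g.shape
    return TrajectoryBatch(
        network=network,
        times=np.linspace(0, 1, J + 1),
        states=np.zeros((M, J + 1, network.n), dtype=int),
        centred=np.zeros((M, J + 1, network.K)),
        terminal_outputs=g,
        output_names=[f"g{i+1}" for i in range(R)],
        seed=0,
    )


class TestPhi:
    @pytest.mark.parametrize("x,expected", [(0.5, 0.25), (-3.0, 5.0), (0.0, 0.0),
                                            (1.0, 1.0), (-1.0, 1.0), (2.0, 3.0)])
    def test_values(self, x, expected):
        assert phi(x) == pytest.approx(expected)

    def test_continuously_differentiable_junction(self):
        eps = 1e-8
        assert phi(1 - eps) == pytest.approx(phi(1 + eps), abs=1e-6)
        assert phi_prime(1 - eps) == pytest.approx(2.0, abs=1e-6)
        assert phi_prime(1 + eps) == pytest.approx(2.0, abs=1e-6)
        assert phi_prime(-1 - eps) == pytest.approx(-2.0, abs=1e-6)


class TestThresholds:
    def test_mean_and_sd_rule(self, bd1):
        d = 2.5 / math.sqrt(2)  # two-point sample with SD 2.5
        batch = fake_batch(bd1, [[6.3 - d], [6.3 + d]])
        assert thresholds_from_batch(batch)[0] == pytest.approx(1 + 6.3 + 5.0)

    def test_constant_output(self, bd1):
        batch = fake_batch(bd1, [[4.0], [4.0], [4.0]])
        assert thresholds_from_batch(batch)[0] == pytest.approx(5.0)

    def test_negative_mean_uses_absolute_value(self, bd1):
        d = 0.5 / math.sqrt(2)
        batch = fake_batch(bd1, [[-2 - d], [-2 + d]])
        assert thresholds_from_batch(batch)[0] == pytest.approx(4.0)

    def test_single_path_rejected(self, bd1):
        with pytest.raises(ValueError):
            thresholds_from_batch(fake_batch(bd1, [[1.0]]))


class TestPathwiseTerminal:
    def test_zero_policy_returns_y(self, bd1, outs1, bd1_batch):
        pol = zero_policy(1, 2, 2)
        Y = np.array([3.0, -1.0])
        traj = bd1_batch.trajectory(0)
        np.testing.assert_allclose(pathwise_terminal(pol, Y, traj), Y)

    def test_unit_policy_telescopes_centred_counter(self, outs1):
        """With R=K=1 and V = 1 the recursion sums to R~_1(T)."""
        from deepcme.networks import PropensitySpec, Reaction, ReactionNetwork
        from deepcme.outputs import OutputSpec, SpeciesMoment

        net = ReactionNetwork(
            1, [Reaction((0,), (1,), PropensitySpec("mass_action", {"rate": "k"}))],
            {"k": 5.0}, (0,))
        outs = OutputSpec((SpeciesMoment(0, 1),))
        batch = simulate_batch(net, 1.0, 20, 5, 3, outs)
        pol = zero_policy(1, 1, 1)
        pol.segments[0].biases[-1][:] = 1.0
        for q in range(batch.M):
            traj = batch.trajectory(q)
            out = pathwise_terminal(pol, np.zeros(1), traj)
            assert out[0] == pytest.approx(traj.centred[-1, 0], abs=1e-10)

    def test_batch_matches_per_path(self, bd1, bd1_batch):
        pol = init_policy(1, 2, 2, 1.0, PolicyConfig(seed=4))
        Y = np.array([1.0, 2.0])
        YJ = batch_terminal(pol, Y, bd1_batch)
        for q in (0, 3, 17):
            np.testing.assert_allclose(
                YJ[q], pathwise_terminal(pol, Y, bd1_batch.trajectory(q)), atol=1e-9)

    def test_exact_policy_residual_shrinks_with_grid(self, bd1, outs1):
        """With the exact policy the residual is pure grid error, O(1/J)."""
        from deepcme.simulate import grid_restrict, simulate_mnrm

        trunc = FspTruncation((60,))
        trajs = [simulate_mnrm(bd1, 1.0, np.random.default_rng([9, q])) for q in range(200)]
        Y = np.array([CF.mean, CF.second_moment])
        means = []
        for J in (25, 50, 100):
            pol = TabularPolicy(bd1, outs1, 1.0, trunc, np.linspace(0, 1, J + 1))
            res = []
            for traj in trajs:
                g = grid_restrict(traj, bd1, J, outs1)
                YJ = pathwise_terminal(pol, Y, g)
                res.append(abs(g.terminal_outputs[0] - YJ[0]))
            means.append(np.mean(res))
        assert means[0] > means[1] > means[2]


class TestEmpiricalLoss:
    def test_half_threshold_residual(self, bd1):
        lc = LossConfig(thresholds=np.array([2.0]))
        batch = fake_batch(bd1, [[1.0]])  # residual = Delta/2
        pol = zero_policy(1, 2, 1)
        loss, diag = empirical_loss(pol, np.zeros(1), batch, lc)
        assert loss == pytest.approx(0.25)
        assert diag["residuals"][0, 0] == pytest.approx(1.0)

    def test_perfect_fit_zero_loss(self, bd1):
        lc = LossConfig(thresholds=np.array([1.0, 1.0]))
        batch = fake_batch(bd1, [[2.0, 5.0], [2.0, 5.0]])
        pol = zero_policy(1, 2, 2)
        loss, _ = empirical_loss(pol, np.array([2.0, 5.0]), batch, lc)
        assert loss == pytest.approx(0.0)

    def test_penalty_only_when_residuals_vanish(self, bd1):
        lc = LossConfig(thresholds=np.array([1.0]), mu=0.01)
        batch = fake_batch(bd1, [[3.0]])
        pol = init_policy(1, 2, 1, 1.0, PolicyConfig(seed=1))
        # zero hidden+output weights: residual fit is exact with Y = g
        for seg in pol.segments:
            for W in seg.weights:
                W[:] = 0.0
        loss, diag = empirical_loss(pol, np.array([3.0]), batch, lc)
        assert loss == pytest.approx(0.0)  # all weights are zero too
        pol.segments[0].biases[0][:] = 2.0  # hidden bias: still zero output
        loss, diag = empirical_loss(pol, np.array([3.0]), batch, lc)
        assert loss == pytest.approx(0.01 * 8.0)
        assert diag["penalty"] == pytest.approx(0.01 * 8.0)

    def test_nonpositive_thresholds_rejected(self):
        with pytest.raises(ValueError):
            LossConfig(thresholds=np.array([1.0, 0.0]))

    def test_y_gradient_closed_form(self, bd1, bd1_batch):
        """dL/dY = -(1/M) sum_q phi'(res/Delta)/Delta, verified numerically."""
        pol = init_policy(1, 2, 2, 1.0, PolicyConfig(seed=8))
        lc = LossConfig(thresholds=thresholds_from_batch(bd1_batch))
        Y = np.array([5.0, 40.0])
        _, diag = empirical_loss(pol, Y, bd1_batch, lc)
        closed = -(phi_prime(diag["residuals"] / lc.thresholds)
                   / lc.thresholds).mean(axis=0)
        h = 1e-6
        for i in range(2):
            Yp, Ym = Y.copy(), Y.copy()
            Yp[i] += h
            Ym[i] -= h
            fd = (empirical_loss(pol, Yp, bd1_batch, lc)[0]
                  - empirical_loss(pol, Ym, bd1_batch, lc)[0]) / (2 * h)
            assert closed[i] == pytest.approx(fd, rel=1e-5, abs=1e-8)


class TestExactPolicySubstitution:
    def test_exact_policy_loss_is_small(self, bd1, outs1):
        """Plugging the exact (Y, V) into the loss leaves only grid error."""
        J = 200
        batch = simulate_batch(bd1, 1.0, J, 1000, 17, outs1)
        pol = TabularPolicy(bd1, outs1, 1.0, FspTruncation((60,)),
                            np.linspace(0, 1, J + 1))
        Y = np.array([CF.mean, CF.second_moment])
        lc = LossConfig(thresholds=thresholds_from_batch(batch))
        loss, _ = empirical_loss(pol, Y, batch, lc)
        assert loss < 0.05

    def test_y_minimisation_recovers_expectation(self, bd1, outs1):
        """With the policy frozen at the exact map, the optimal Y is the exact
        expectation up to Monte-Carlo error of the variance-reduced mean."""
        J = 100
        batch = simulate_batch(bd1, 1.0, J, 1000, 23, outs1)
        pol = TabularPolicy(bd1, outs1, 1.0, FspTruncation((60,)),
                            np.linspace(0, 1, J + 1))
        corr = batch_terminal(pol, np.zeros(2), batch)
        resid = batch.terminal_outputs - corr  # g - martingale correction
        y_star = resid.mean(axis=0)            # minimiser in the quadratic regime
        se = resid.std(axis=0, ddof=1) / math.sqrt(batch.M)
        assert abs(y_star[0] - CF.mean) <= 3 * se[0] + 0.02  # + grid bias at J=100
        assert abs(y_star[1] - CF.second_moment) <= 3 * se[1] + 0.2
        # the control variate must actually reduce variance
        assert (resid.std(axis=0) < batch.terminal_outputs.std(axis=0)).all()


class TestTrain:
    def test_zero_rate_network_degenerate(self, outs1):
        net = build_example_network("birth_death", 1).with_params(k=0.0, gamma=0.0)
        tb = simulate_batch(net, 1.0, 5, 20, 1, outs1)
        vb = simulate_batch(net, 1.0, 5, 20, 2, outs1, role="validation")
        res = train(net, tb, vb, outs1, TrainingConfig(iterations=300, seed=0))
        np.testing.assert_allclose(res.Y, 0.0, atol=1e-3)

    def test_short_run_improves_validation(self, bd1, outs1):
        tb = simulate_batch(bd1, 1.0, 20, 50, 5, outs1)
        vb = simulate_batch(bd1, 1.0, 20, 50, 6, outs1, role="validation")
        res = train(bd1, tb, vb, outs1, TrainingConfig(iterations=800, seed=5))
        trace = res.normalized_val_trace
        assert trace[0] == pytest.approx(1.0)
        assert trace[-1] < 1.0
        assert len(res.train_history) == len(res.val_history)

    def test_training_determinism(self, bd1, outs1):
        tb = simulate_batch(bd1, 1.0, 10, 30, 5, outs1)
        vb = simulate_batch(bd1, 1.0, 10, 30, 6, outs1, role="validation")
        r1 = train(bd1, tb, vb, outs1, TrainingConfig(iterations=200, seed=9))
        r2 = train(bd1, tb, vb, outs1, TrainingConfig(iterations=200, seed=9))
        np.testing.assert_array_equal(r1.Y, r2.Y)
        assert r1.val_history == r2.val_history

    def test_mismatched_grids_rejected(self, bd1, outs1):
        tb = simulate_batch(bd1, 1.0, 10, 10, 1, outs1)
        vb = simulate_batch(bd1, 1.0, 20, 10, 2, outs1)
        with pytest.raises(ValueError):
            train(bd1, tb, vb, outs1, TrainingConfig(iterations=10))

    def test_training_log_written(self, bd1, outs1, tmp_path):
        tb = simulate_batch(bd1, 1.0, 10, 20, 1, outs1)
        vb = simulate_batch(bd1, 1.0, 10, 20, 2, outs1)
        log = tmp_path / "log.csv"
        train(bd1, tb, vb, outs1, TrainingConfig(iterations=100, seed=1), log_path=log)
        lines = log.read_text().strip().splitlines()
        assert lines[0].startswith("iteration,train_loss,val_loss")
        assert len(lines) >= 2
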