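"""RBF/MLP networks, analytic derivatives, losses, and the trainer."""

import numpy as np
import pytest

from turinverse.rbf_pinn import (Adam, MLPNet, RBFNet, TrainConfig,
                                 interior_mask, losses, mlp_pinn_baseline,
                                 rbf_eval, rbf_laplacian, train)
from turinverse.simulate import Pattern


def single_kernel(w=1.0, beta=1.0, c=(0.0, 0.0)):
    return RBFNet(centers=np.array([c], float), log_widths=np.log([beta]),
                  weights=np.array([w], float))


class TestRBFEvaluation:
    def test_unit_kernel_at_center(self):
        assert rbf_eval(single_kernel(), [(0.0, 0.0)])[0] == \
            pytest.approx(1.0)

    def test_unit_kernel_one_unit_away(self):
        assert rbf_eval(single_kernel(), [(1.0, 0.0)])[0] == \
            pytest.approx(np.exp(-1.0))

    def test_zero_weights_vanish(self):
        net = RBFNet.init(10, 5.0, 1.0, np.random.default_rng(0))
        net.weights[:] = 0.0
        assert np.all(rbf_eval(net, np.random.uniform(0, 5, (7, 2))) == 0.0)

    def test_sum_over_kernels(self):
        rng = np.random.default_rng(4)
        net = RBFNet.init(6, 3.0, 0.8, rng)
        pts = rng.uniform(0, 3, (5, 2))
        expected = np.zeros(5)
        for w, lb, c in zip(net.weights, net.log_widths, net.centers):
            expected += w * np.exp(-np.exp(lb)
                                   * np.sum((pts - c) ** 2, axis=1))
        np.testing.assert_allclose(rbf_eval(net, pts), expected, rtol=1e-12)


class TestRBFLaplacian:
    def test_value_at_kernel_center(self):
        assert rbf_laplacian(single_kernel(), [(0.0, 0.0)])[0] == \
            pytest.approx(-4.0)

    def test_zero_crossing_at_beta_r2_equal_one(self):
        assert rbf_laplacian(single_kernel(), [(1.0, 0.0)])[0] == \
            pytest.approx(0.0, abs=1e-14)

    def test_second_order_convergence_to_finite_differences(self):
        """Centered-stencil error of the analytic Laplacian shrinks as h^2."""
        rng = np.random.default_rng(1)
        net = RBFNet.init(12, 4.0, 0.7, rng)
        pts = rng.uniform(0.5, 3.5, (20, 2))
        lap = rbf_laplacian(net, pts)
        errs = []
        for h in (1e-1, 1e-2, 1e-3):
            fd = (sum(net.eval(pts + h * np.array(o))
                      for o in ((1, 0), (-1, 0), (0, 1), (0, -1)))
                  - 4 * net.eval(pts)) / h ** 2
            errs.append(np.max(np.abs(fd - lap)))
        order = np.polyfit(np.log([1e-1, 1e-2, 1e-3]), np.log(errs), 1)[0]
        assert order == pytest.approx(2.0, abs=0.3)


class TestAnalyticGradients:
    @pytest.mark.parametrize("field", ["weights", "log_widths", "centers"])
    def test_rbf_parameter_gradients_match_numeric(self, field):
        rng = np.random.default_rng(0)
        net = RBFNet.init(5, 4.0, 0.8, rng)
        pts = rng.uniform(0, 4, (8, 2))
        cv = rng.standard_normal(8)
        cl = rng.standard_normal(8)
        g = net.grads(net._cache(pts), cot_val=cv, cot_lap=cl)[field]
        arr = getattr(net, field)
        num = np.zeros_like(arr)
        eps = 1e-6
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            orig = arr[i]
            arr[i] = orig + eps
            jp = cv @ net.eval(pts) + cl @ net.laplacian(pts)
            arr[i] = orig - eps
            jm = cv @ net.eval(pts) + cl @ net.laplacian(pts)
            arr[i] = orig
            num[i] = (jp - jm) / (2 * eps)
        np.testing.assert_allclose(g, num, rtol=1e-5, atol=1e-7)

    def test_mlp_gradients_match_numeric(self):
        rng = np.random.default_rng(2)
        net = MLPNet.init(hidden=6, depth=2, h=0.4, rng=rng)
        pts = rng.uniform(0, 2, (5, 2))
        cv = rng.standard_normal(5)
        cl = rng.standard_normal(5)
        _, _, cache = net.eval_lap(pts)
        g = net.grads(cache, cot_val=cv, cot_lap=cl)
        eps = 1e-6
        for name, arr in net.params().items():
            num = np.zeros_like(arr)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                orig = arr[i]
                arr[i] = orig + eps
                p1, l1, _ = net.eval_lap(pts)
                arr[i] = orig - eps
                p2, l2, _ = net.eval_lap(pts)
                arr[i] = orig
                num[i] = (cv @ (p1 - p2) + cl @ (l1 - l2)) / (2 * eps)
            np.testing.assert_allclose(g[name], num, atol=5e-6)


class TestAdam:
    def test_minimizes_quadratic(self):
        params = {"x": np.array([5.0, -3.0])}
        opt = Adam(params, lr=0.1)
        for _ in range(2000):
            opt.step({"x": 2.0 * params["x"]})
        np.testing.assert_allclose(params["x"], 0.0, atol=1e-4)


class TestLossContracts:
    def test_interior_trim_is_44x44_for_default_grid(self):
        mask = interior_mask(50, 3)
        assert mask.sum() == 44 * 44
        assert not mask[0].any() and not mask[:, -1].any()

    def test_zero_network_approximation_loss_is_mean_square(self,
                                                            schnak_pattern):
        rng = np.random.default_rng(0)
        nets = [RBFNet.init(5, 49.0, 2.0, rng) for _ in range(2)]
        for n in nets:
            n.weights[:] = 0.0
        la_u, la_v, _, _ = losses(nets[0], nets[1], schnak_pattern,
                                  "schnakenberg_nd", [0.1, 1, 0.9, 40])
        assert la_u == pytest.approx(np.mean(schnak_pattern.u ** 2))
        assert la_v == pytest.approx(np.mean(schnak_pattern.v ** 2))

    def test_approximation_loss_scales_quadratically(self, schnak_pattern):
        rng = np.random.default_rng(0)
        net_u = RBFNet.init(5, 49.0, 2.0, rng)
        net_v = RBFNet.init(5, 49.0, 2.0, rng)
        net_u.weights[:] = 0.0
        net_v.weights[:] = 0.0
        base = losses(net_u, net_v, schnak_pattern, "schnakenberg_nd",
                      [0.1, 1, 0.9, 40])[0]
        scaled_pattern = Pattern(u=3.0 * schnak_pattern.u,
                                 v=3.0 * schnak_pattern.v,
                                 dx=schnak_pattern.dx, bc=schnak_pattern.bc)
        scaled = losses(net_u, net_v, scaled_pattern, "schnakenberg_nd",
                        [0.1, 1, 0.9, 40])[0]
        assert scaled == pytest.approx(9.0 * base, rel=1e-9)

    def test_pde_and_diffusion_losses_ignore_boundary_pixels(self,
                                                             schnak_pattern):
        rng = np.random.default_rng(1)
        net_u = RBFNet.init(20, 49.0, 2.5, rng)
        net_v = RBFNet.init(20, 49.0, 2.5, rng)
        ref = losses(net_u, net_v, schnak_pattern, "schnakenberg_nd",
                     [0.1, 1, 0.9, 40], trim=3)
        tampered = schnak_pattern.copy()
        tampered.u[0, :] += 5.0
        tampered.u[-1, :] -= 5.0
        tam = losses(net_u, net_v, tampered, "schnakenberg_nd",
                     [0.1, 1, 0.9, 40], trim=3)
        assert tam[0] != ref[0]                  # approximation loss sees it
        assert tam[2] == pytest.approx(ref[2])   # PDE loss does not
        assert tam[3] == pytest.approx(ref[3])   # diffusion loss does not


class TestTraining:
    @pytest.fixture(scope="class")
    def short_run(self, schnak_pattern):
        cfg = TrainConfig(nodes=30, iters=1500, warmup=500, batch=64,
                          seed=0, log_every=100)
        return train(schnak_pattern, "schnakenberg_nd", cfg), cfg

    def test_losses_decrease_and_stay_finite(self, short_run):
        (history, result), _ = short_run
        app = np.array(history["l_app_u"])
        assert np.all(np.isfinite(app))
        assert np.mean(app[-3:]) < np.mean(app[:3])
        assert np.all(np.isfinite(result.beta_hat))

    def test_pde_parameters_move_only_after_warmup(self, short_run):
        (history, _), cfg = short_run
        its = np.array(history["iteration"])
        thetas = np.array(history["theta"])
        before = thetas[its < cfg.warmup]
        np.testing.assert_array_equal(before, np.ones_like(before))
        assert not np.allclose(thetas[-1], 1.0)

    def test_seed_reproducibility(self, schnak_pattern, short_run):
        (history, result), cfg = short_run
        history2, result2 = train(schnak_pattern, "schnakenberg_nd", cfg)
        np.testing.assert_array_equal(result.beta_hat, result2.beta_hat)
        np.testing.assert_array_equal(np.array(history["l_app_u"]),
                                      np.array(history2["l_app_u"]))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(iters=100, warmup=100)
        with pytest.raises(ValueError):
            TrainConfig(trim=9)


class TestMLPBaseline:
    def test_constant_output_gives_variance_like_loss(self, schnak_pattern):
        rng = np.random.default_rng(0)
        net_u = MLPNet.init(hidden=8, depth=2, h=1.0, rng=rng)
        net_v = MLPNet.init(hidden=8, depth=2, h=1.0, rng=rng)
        for net in (net_u, net_v):
            for w in net.weights_:
                w[:] = 0.0
        la_u, _, _, _ = losses(net_u, net_v, schnak_pattern,
                               "schnakenberg_nd", [0.1, 1, 0.9, 40])
        assert la_u == pytest.approx(np.mean(schnak_pattern.u ** 2))

    def test_parameter_count_gap(self):
        rbf = RBFNet.init(80, 50.0, 2.0, np.random.default_rng(0))
        mlp = MLPNet.init(hidden=80, depth=5)
        assert rbf.n_params == 4 * 80
        assert mlp.n_params > 50 * rbf.n_params

    def test_short_training_runs(self, schnak_pattern):
        cfg = TrainConfig(nodes=8, iters=300, warmup=100, batch=32, seed=0,
                          log_every=50)
        history, result = mlp_pinn_baseline(schnak_pattern, "schnakenberg_nd",
                                            cfg, hidden=16, depth=2)
        assert result.method == "mlp_pinn"
        assert np.all(np.isfinite(result.beta_hat))
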