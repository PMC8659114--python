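import numpy as np
import pytest
from sklearn.base import clone

from microdisk import (
    Dataset,
    LMConfig,
    MLPSurrogate,
    MLPSurrogateRegressor,
    forward,
    init_network,
    lm_train,
    split_dataset,
)
from microdisk.surrogate import _forward_jacobian


class TestInitNetwork:
    def test_deterministic_given_seed(self):
        a = init_network(60, 5.0, seed=1)
        b = init_network(60, 5.0, seed=1)
        assert np.array_equal(a.w_in, b.w_in)
        assert np.array_equal(a.b_hidden, b.b_hidden)
        assert np.array_equal(a.w_out, b.w_out)
        assert a.b_out == b.b_out

    def test_different_seed_differs(self):
        a = init_network(10, 5.0, seed=1)
        b = init_network(10, 5.0, seed=2)
        assert not np.array_equal(a.w_in, b.w_in)

    @pytest.mark.parametrize("n_hidden,expected", [(1, 4), (60, 181)])
    def test_parameter_count(self, n_hidden, expected):
        net = init_network(n_hidden, 2.0, seed=7)
        assert net.n_params == expected
        assert net.pack().size == expected

    def test_input_scaling_maps_domain_to_unit_interval(self):
        net = init_network(5, 4.0, seed=0)
        a, b = net.input_scale
        assert a * 1.0 + b == pytest.approx(-1.0)
        assert a * 4.0 + b == pytest.approx(1.0)


class TestForward:
    def test_zero_weights_return_output_bias(self):
        net = MLPSurrogate(w_in=np.zeros(3), b_hidden=np.zeros(3),
                           w_out=np.zeros(3), b_out=2.5,
                           input_scale=(1.0, 0.0))
        assert np.allclose(forward(net, np.linspace(1, 5, 7)), 2.5)

    def test_zero_output_layer_ignores_hidden(self):
        net = MLPSurrogate(w_in=np.array([3.0, -2.0]),
                           b_hidden=np.array([0.5, 1.0]),
                           w_out=np.zeros(2), b_out=0.0,
                           input_scale=(1.0, 0.0))
        assert np.allclose(forward(net, np.linspace(-2, 2, 9)), 0.0)

    def test_single_unit_logsig_midpoint(self):
        net = MLPSurrogate(w_in=np.array([0.0]), b_hidden=np.array([0.0]),
                           w_out=np.array([2.0]), b_out=-1.0,
                           input_scale=(1.0, 0.0))
        assert np.allclose(forward(net, np.array([0.3, 7.0])), 0.0)

    def test_pack_unpack_round_trip(self):
        net = init_network(4, 3.0, seed=5)
        theta = net.pack()
        back = net.unpack(theta)
        assert np.allclose(forward(net, np.linspace(1, 3, 11)),
                           forward(back, np.linspace(1, 3, 11)))


class TestSplitDataset:
    def _ds(self, n=100):
        x = np.linspace(1, 5, n)
        return Dataset(inputs=x, targets=np.sin(x))

    def test_counts(self):
        out = split_dataset(self._ds(100), (0.70, 0.15, 0.15), seed=3)
        labels, counts = np.unique(out.split.astype(str), return_counts=True)
        assert dict(zip(labels, counts)) == {"test": 15, "train": 70, "val": 15}

    def test_deterministic(self):
        a = split_dataset(self._ds(), (0.70, 0.15, 0.15), seed=11)
        b = split_dataset(self._ds(), (0.70, 0.15, 0.15), seed=11)
        assert np.array_equal(a.split.astype(str), b.split.astype(str))

    def test_partition_property(self):
        out = split_dataset(self._ds(97), (0.6, 0.2, 0.2), seed=5)
        assert set(out.split) == {"train", "val", "test"}
        assert out.split.size == 97  # every point labelled exactly once

    def test_unnormalized_fractions_accepted(self):
        # the printed 75/15/15 split sums to 105%; normalize it
        out = split_dataset(self._ds(100), (0.75, 0.15, 0.15), seed=1)
        n_train = int(np.sum(out.split == "train"))
        assert n_train == pytest.approx(100 * 75 / 105, abs=1)

    def test_tiny_dataset_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(Dataset(inputs=np.array([1.0, 2.0]),
                                  targets=np.array([0.0, 1.0])),
                          (0.7, 0.15, 0.15), seed=0)


def _toy_split(n=60, seed=0, q=5.0, fn=np.sin):
    x = np.linspace(1, q, n)
    return split_dataset(Dataset(inputs=x, targets=fn(x)),
                         (0.70, 0.15, 0.15), seed=seed)


class TestLMTrain:
    def test_constant_target_fits_immediately(self):
        x = np.linspace(1, 5, 60)
        ds = split_dataset(Dataset(inputs=x, targets=np.full(60, 0.37)),
                           (0.70, 0.15, 0.15), seed=0)
        net0 = init_network(3, 5.0, seed=0)
        net, rec = lm_train(net0, ds, LMConfig(max_epochs=10,
                                               grad_tol=1e-30))
        assert rec.mse_train[-1] <= 1e-20

    def test_teacher_student_recovery(self):
        teacher = init_network(3, 5.0, seed=9)
        x = np.linspace(1, 5, 80)
        y = forward(teacher, x)
        ds = split_dataset(Dataset(inputs=x, targets=y),
                           (0.70, 0.15, 0.15), seed=2)
        # init near the teacher
        theta0 = teacher.pack() + 1e-3
        near = teacher.unpack(theta0)
        net, rec = lm_train(near, ds, LMConfig(max_epochs=100,
                                               grad_tol=1e-16))
        assert min(rec.mse_train) <= 1e-18

    def test_training_mse_never_increases(self):
        ds = _toy_split()
        net0 = init_network(8, 5.0, seed=1)
        _, rec = lm_train(net0, ds, LMConfig(max_epochs=50))
        mt = np.array(rec.mse_train)
        assert np.all(np.diff(mt) <= 0)

    def test_best_validation_mse_nonincreasing_over_checkpoints(self):
        ds = _toy_split(seed=4)
        net0 = init_network(8, 5.0, seed=4)
        _, rec = lm_train(net0, ds, LMConfig(max_epochs=50))
        best_so_far = np.minimum.accumulate(rec.mse_val)
        assert rec.best_val_mse == pytest.approx(best_so_far[-1])

    def test_reproducible(self):
        for _ in range(2):
            ds = _toy_split(seed=6)
            net0 = init_network(8, 5.0, seed=6)
            net, rec = lm_train(net0, ds, LMConfig(max_epochs=30))
            try:
                assert np.array_equal(prev_theta, net.pack())
                assert prev_record == (rec.epochs, rec.stop_reason,
                                       tuple(rec.mse_train))
            except NameError:
                prev_theta = net.pack()
                prev_record = (rec.epochs, rec.stop_reason,
                               tuple(rec.mse_train))

    def test_gradient_at_stop_below_tolerance(self):
        cfg = LMConfig(max_epochs=2000, grad_tol=1e-7)
        ds = _toy_split(seed=3)
        net0 = init_network(8, 5.0, seed=3)
        _, rec = lm_train(net0, ds, cfg)
        if rec.stop_reason == "grad_tol":
            assert rec.final_gradient <= cfg.grad_tol

    def test_smooth_profile_reaches_tight_validation_mse(self,
                                                         smooth_s_dataset):
        ds_S, _ = smooth_s_dataset
        split = split_dataset(ds_S, (0.70, 0.15, 0.15), seed=1)
        net0 = init_network(60, 5.0, seed=1)
        _, rec = lm_train(net0, split, LMConfig())
        assert rec.best_val_mse <= 1e-9


class TestLMStepLimits:
    """The LM step interpolates gradient descent and Gauss-Newton."""

    def _jacobian_setup(self):
        net = init_network(2, 5.0, seed=0)
        x = np.linspace(-1, 1, 40)
        theta = net.pack()
        pred, Jf = _forward_jacobian(theta, net, x)
        e = np.sin(2 * x) - pred
        return Jf, e

    def test_large_mu_approaches_gradient_direction(self):
        Jf, e = self._jacobian_setup()
        A = Jf.T @ Jf
        g = Jf.T @ e
        mu = 1e12
        delta = np.linalg.solve(A + mu * np.eye(g.size), g)
        cos = delta @ g / (np.linalg.norm(delta) * np.linalg.norm(g))
        assert cos > 0.99

    def test_zero_mu_is_gauss_newton(self):
        Jf, e = self._jacobian_setup()
        delta = np.linalg.solve(Jf.T @ Jf, Jf.T @ e)
        gn, *_ = np.linalg.lstsq(Jf, e, rcond=None)
        assert np.allclose(delta, gn, rtol=1e-6)

    def test_jacobian_matches_finite_differences(self):
        net = init_network(3, 5.0, seed=2)
        x = np.linspace(-1, 1, 7)
        theta = net.pack()
        pred, J = _forward_jacobian(theta, net, x)
        eps = 1e-7
        for k in range(theta.size):
            tp = theta.copy()
            tp[k] += eps
            pp, _ = _forward_jacobian(tp, net, x)
            fd = (pp - pred) / eps
            assert np.allclose(J[:, k], fd, atol=1e-5)


class TestEstimator:
    def test_fit_predict_round_trip(self):
        x = np.linspace(1, 5, 200)
        y = 1.0 / x
        est = MLPSurrogateRegressor(n_hidden=10, max_epochs=200,
                                    random_state=0)
        est.fit(x, y)
        assert est.best_val_mse_ <= 1e-8
        assert np.max(np.abs(est.predict(x) - y)) <= 1e-3
        assert est.stop_reason_ in {"grad_tol", "mu_max", "max_epochs",
                                    "val_fail"}

    def test_two_dimensional_single_column_input(self):
        x = np.linspace(1, 3, 100)
        est = MLPSurrogateRegressor(n_hidden=5, max_epochs=50, random_state=1)
        est.fit(x[:, None], x**2)
        assert est.predict(x[:, None]).shape == x.shape

    def test_clone_and_get_params(self):
        est = MLPSurrogateRegressor(n_hidden=7, mu0=1e-2, random_state=3)
        c = clone(est)
        assert c.get_params()["n_hidden"] == 7
        assert c.get_params()["mu0"] == 1e-2

    def test_unfitted_predict_raises(self):
        with pytest.raises(AttributeError):
            MLPSurrogateRegressor().predict(np.linspace(1, 2, 5))
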