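"""Emulator-core contracts: normalization, architecture, gradients, Eq.-style
decomposition, serialization."""

import numpy as np
import pytest

from apemu.dataset import CANONICAL_GRID
from apemu.emulator import (DEC_SIZES, ENC_SIZES, EmulatorWeights, LatentCode,
                            NormalizedConductances, backward, decoder_output,
                            denormalize, depolarization_term, emulate_ap,
                            emulate_vm, encode, forward, normalize)
from apemu.errors import ValidationError
from apemu.simulator import ConductanceSet


@pytest.fixture(scope="module")
def weights():
    return EmulatorWeights.initialize(seed=7)


class TestNormalization:
    def test_baseline_maps_to_zero(self):
        assert np.allclose(normalize(ConductanceSet()).x, 0.0)

    def test_zero_conductance_maps_to_lower_bound(self):
        g = ConductanceSet.from_array(np.zeros(9))
        assert np.allclose(normalize(g).x, -0.5)

    def test_round_trip_bijection(self, rng):
        for _ in range(100):
            g = ConductanceSet.from_array(rng.uniform(0.0, 2.0, 9))
            back = denormalize(normalize(g))
            assert np.allclose(back.as_array(), g.as_array(), atol=1e-14)

    def test_nonpositive_reference_rejected(self):
        ref = ConductanceSet.from_array(np.r_[0.0, np.ones(8)])
        with pytest.raises(ValidationError):
            normalize(ConductanceSet(), ref)

    def test_out_of_box_coordinates_rejected(self):
        with pytest.raises(ValidationError):
            NormalizedConductances(np.full(9, 0.6))


class TestArchitecture:
    def test_layer_shapes(self, weights):
        for layers, sizes in ((weights.theta1, ENC_SIZES), (weights.theta2, DEC_SIZES)):
            for k, (W, b) in enumerate(layers):
                assert W.shape == (sizes[k], sizes[k + 1])
                assert b.shape == (sizes[k + 1],)

    def test_shape_invariants_enforced(self, weights):
        broken = weights.copy()
        broken.theta2[0] = (np.zeros((3, 3)), np.zeros(3))
        with pytest.raises(ValidationError):
            EmulatorWeights(broken.theta1, broken.theta2)

    def test_nonfinite_weights_rejected(self, weights):
        broken = weights.copy()
        broken.theta1[0][0][0, 0] = np.nan
        with pytest.raises(ValidationError):
            EmulatorWeights(broken.theta1, broken.theta2)

    def test_encode_is_deterministic(self, weights, rng):
        x = NormalizedConductances(rng.uniform(-0.5, 0.5, 9))
        a, b = encode(x, weights), encode(x, weights)
        assert np.array_equal(a.theta, b.theta)
        assert (a.d1, a.d2, a.d3) == (b.d1, b.d2, b.d3)
        assert a.d1 > 0 and a.d3 > 0  # positive slope and amplitude


class TestGradients:
    def test_input_gradient_matches_finite_differences(self, weights, rng):
        x = rng.uniform(-0.4, 0.4, (2, 9))
        t = np.array([-5.0, 1.0, 50.0, 400.0, 950.0])
        vm, cache = forward(weights, x, t, with_cache=True)
        gv = rng.standard_normal(vm.shape)
        gx = backward(weights, cache, gv, need_weight_grads=False,
                      need_input_grads=True)["x"]
        eps = 1e-6
        for i in range(2):
            for j in range(9):
                xp, xm = x.copy(), x.copy()
                xp[i, j] += eps
                xm[i, j] -= eps
                fd = ((forward(weights, xp, t) * gv).sum()
                      - (forward(weights, xm, t) * gv).sum()) / (2 * eps)
                assert gx[i, j] == pytest.approx(fd, rel=1e-4, abs=1e-8)

    def test_time_gradient_matches_finite_differences(self, weights, rng):
        """d Vm/dt is exact: the emulated AP has an analytic time derivative."""
        x = rng.uniform(-0.4, 0.4, (1, 9))
        t = np.sort(rng.uniform(-9.0, 999.0, 100))
        vm, cache = forward(weights, x, t, with_cache=True)
        gt = backward(weights, cache, np.ones_like(vm), need_weight_grads=False,
                      need_input_grads=True)["t"]
        eps = 1e-5
        fd = (forward(weights, x, t + eps) - forward(weights, x, t - eps)) / (2 * eps)
        assert np.allclose(gt, fd, rtol=1e-3, atol=1e-9)

    def test_weight_gradient_matches_finite_differences(self, weights, rng):
        x = rng.uniform(-0.4, 0.4, (2, 9))
        t = np.array([0.0, 30.0, 600.0])
        vm, cache = forward(weights, x, t, with_cache=True)
        gv = rng.standard_normal(vm.shape)
        grads = backward(weights, cache, gv)
        eps = 1e-6
        for layers, glist, picks in ((weights.theta1, grads["theta1"], [(1, 3, 5)]),
                                     (weights.theta2, grads["theta2"], [(2, 10, 20)])):
            for (k, i, j) in picks:
                W = layers[k][0]
                W[i, j] += eps
                lp = float((forward(weights, x, t) * gv).sum())
                W[i, j] -= 2 * eps
                lm = float((forward(weights, x, t) * gv).sum())
                W[i, j] += eps
                assert glist[k][0][i, j] == pytest.approx((lp - lm) / (2 * eps),
                                                          rel=1e-4, abs=1e-8)


class TestEmulateVm:
    def test_depolarization_term_closed_form(self):
        """With f_theta absent, (d1,d2,d3)=(2,10,100) gives the plain tanh step."""
        code = LatentCode(theta=np.zeros(256), d1=2.0, d2=10.0, d3=100.0)
        assert depolarization_term(code, 10.0) == pytest.approx(0.0)
        assert depolarization_term(code, 1e6) == pytest.approx(50.0)
        assert depolarization_term(code, -1e6) == pytest.approx(-50.0)

    def test_decomposition_is_exact(self, weights, rng):
        """Vm minus the tanh term equals the decoder output f_theta exactly."""
        x = NormalizedConductances(rng.uniform(-0.5, 0.5, 9))
        t = np.linspace(-10.0, 1000.0, 57)
        code = encode(x, weights)
        total = emulate_vm(x, t, weights)
        assert np.allclose(total - depolarization_term(code, t),
                           decoder_output(x, t, weights), atol=1e-9)

    def test_resolution_independence(self, weights, rng):
        """A time evaluated alone equals the same time inside a batch."""
        x = NormalizedConductances(rng.uniform(-0.5, 0.5, 9))
        t = np.array([0.5, 123.4, 777.7])
        batch = emulate_vm(x, t, weights)
        singles = [emulate_vm(x, float(tt), weights) for tt in t]
        assert np.allclose(batch, singles, atol=0)

    def test_out_of_domain_warns_but_returns(self, weights):
        x = NormalizedConductances(np.zeros(9))
        with pytest.warns(UserWarning):
            v = emulate_vm(x, 1500.0, weights)
        assert np.isfinite(v)

    def test_finite_on_whole_domain(self, weights, rng):
        """No NaN/Inf anywhere on the trained domain for random inputs."""
        x = rng.uniform(-0.5, 0.5, (20, 9))
        vm = forward(weights, x, CANONICAL_GRID)
        assert np.all(np.isfinite(vm))
        # Lipschitz sanity on the grid: bounded increments
        assert np.max(np.abs(np.diff(vm, axis=1))) < 200.0


class TestEmulateAP:
    def test_canonical_grid_length(self, weights):
        tr = emulate_ap(NormalizedConductances(np.zeros(9)), CANONICAL_GRID, weights)
        assert len(tr) == 4191

    def test_subgrid_is_restriction(self, weights, rng):
        x = NormalizedConductances(rng.uniform(-0.5, 0.5, 9))
        full = emulate_ap(x, CANONICAL_GRID, weights)
        sub = emulate_ap(x, CANONICAL_GRID[::7], weights)
        assert np.allclose(sub.vm, full.vm[::7], atol=0)


class TestSerialization:
    def test_save_load_round_trip(self, weights, tmp_path, rng):
        p = tmp_path / "weights.npz"
        weights.save(p)
        back = EmulatorWeights.load(p)
        x = rng.uniform(-0.5, 0.5, (3, 9))
        t = np.linspace(-10, 1000, 33)
        assert np.array_equal(forward(weights, x, t), forward(back, x, t))
        assert np.allclose(back.g_ref.as_array(), weights.g_ref.as_array())
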