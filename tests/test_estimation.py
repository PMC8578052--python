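"""Cost, adjoint gradient, and the conjugate-gradient fitting engine."""

import numpy as np
import pytest

import fmtpk as F
from fmtpk.estimation import ForwardOperator
from fmtpk.layout import COMPARTMENTS, PARAM_NAMES, PARAM_TARGETS
from fmtpk.model import rk4_propagator


@pytest.fixture(scope="module")
def op(mix, scheme7, known):
    return ForwardOperator(mix, scheme7, known=known)


def complex_step_gradient(k, y, c, mix, scheme, known, h_im=1e-30):
    """Independent gradient oracle: complex-step through a naive forward.

    Re-implements the whole chain (propagator polynomial, step-by-step
    state recursion, linear interpolation at sample times, mixing, SSE and
    penalty) in complex arithmetic; the imaginary part of the perturbed
    cost is the exact derivative to machine precision.
    """
    m = mix.matrix
    grad = np.empty(len(k))
    t_pos = scheme.times_min  # 1-min grid: positions in steps
    n_steps = int(np.ceil(t_pos.max() + 1e-9))
    i_blood = COMPARTMENTS.index("Blood")
    for p in range(len(k)):
        kc = k.astype(complex).copy()
        kc[p] += 1j * h_im
        a = np.zeros((11, 11), complex)
        for name, rate in zip(PARAM_NAMES, kc):
            j = COMPARTMENTS.index(PARAM_TARGETS[name])
            a[j, i_blood] += rate
            a[i_blood, i_blood] -= rate
        for (src, dst), rate in known.edges.items():
            i, j = COMPARTMENTS.index(src), COMPARTMENTS.index(dst)
            a[j, i] += rate
            a[i, i] -= rate
        phi = np.eye(11, dtype=complex) + a + a @ a / 2 + a @ a @ a / 6 + a @ a @ a @ a / 24
        x = np.zeros(11, complex)
        x[i_blood] = 100.0
        hist = [x]
        for _ in range(n_steps):
            x = phi @ x
            hist.append(x)
        hist = np.array(hist).T  # 11 x (n_steps+1)
        lo = np.floor(t_pos + 1e-9).astype(int)
        w = t_pos - lo
        w[np.abs(w) < 1e-9] = 0.0
        coarse = hist[:, lo] * (1 - w) + hist[:, np.minimum(lo + 1, n_steps)] * w
        r = m @ coarse - y
        f = np.sum(r * r) + c * np.sum(kc * kc)
        grad[p] = f.imag / h_im
    return grad


class TestCost:
    def test_noise_free_self_consistency(self, op, known, mix, scheme7, rng):
        truth = F.KineticParameters(rng.uniform(0.001, 0.02, 8))
        meas = F.simulate_measurements(truth, known, mix, scheme7, noise_level=0.0)
        cb = F.cost(truth, meas, known, mix, scheme7, c=0.0)
        assert cb.total < 1e-12

    def test_penalty_arithmetic(self, known, mix, scheme7):
        params = F.KineticParameters(np.full(8, 0.01))
        meas = F.simulate_measurements(params, known, mix, scheme7, noise_level=0.0)
        cb = F.cost(params, meas, known, mix, scheme7, c=1.0)
        assert np.isclose(cb.total, 8e-4, rtol=1e-9)
        assert np.isclose(cb.penalty, 8e-4)
        assert cb.total == cb.sse + cb.penalty

    def test_sse_matches_loop_oracle(self, op, known, mix, scheme7, rng):
        k = rng.uniform(0.001, 0.02, 8)
        truth = F.KineticParameters(rng.uniform(0.001, 0.02, 8))
        meas = F.simulate_measurements(truth, known, mix, scheme7,
                                       noise_level=0.1, seed=4)
        cb = F.cost(F.KineticParameters(k), meas, known, mix, scheme7, c=0.0)
        pred = op.predict(k)
        sse = 0.0
        for i in range(9):
            for t in range(len(scheme7)):
                sse += (pred[i, t] - meas.values[i, t]) ** 2
        assert np.isclose(cb.sse, sse, rtol=1e-12)

    def test_shape_mismatch_rejected(self, known, mix, scheme7, rng):
        truth = F.KineticParameters(rng.uniform(0.001, 0.02, 8))
        meas = F.simulate_measurements(
            truth, known, mix, F.make_scheme("7-early"), noise_level=0.0
        )
        with pytest.raises(ValueError, match="match"):
            F.cost(truth, meas, known, mix, scheme7)


class TestGradient:
    def test_zero_residual_gradient_is_penalty_only(self, known, mix, scheme7, rng):
        truth = F.KineticParameters(rng.uniform(0.002, 0.019, 8))
        meas = F.simulate_measurements(truth, known, mix, scheme7, noise_level=0.0)
        g0 = F.gradient(truth, meas, known, mix, scheme7, c=0.0)
        assert np.linalg.norm(g0) < 1e-8
        c = 0.37
        g = F.gradient(truth, meas, known, mix, scheme7, c=c)
        assert np.allclose(g, 2.0 * c * truth.values, rtol=1e-9)

    def test_matches_central_finite_differences(self, op, known, mix, scheme7):
        rng = np.random.default_rng(77)
        truth = F.KineticParameters(rng.uniform(0.001, 0.02, 8))
        meas = F.simulate_measurements(truth, known, mix, scheme7,
                                       noise_level=0.1, seed=9)
        y = meas.values
        for _ in range(20):
            k = rng.uniform(0.001, 0.02, 8)
            _, g = op.cost_gradient(k, y, 1e-4)
            gfd = np.empty(8)
            for p in range(8):
                e = np.zeros(8)
                e[p] = 1e-6
                gfd[p] = (
                    op.cost(k + e, y, 1e-4).total - op.cost(k - e, y, 1e-4).total
                ) / 2e-6
            assert np.max(np.abs(g - gfd) / np.maximum(np.abs(gfd), 1e-8)) < 1e-5

    def test_matches_complex_step_oracle(self, op, known, mix, scheme7):
        rng = np.random.default_rng(123)
        truth = F.KineticParameters(rng.uniform(0.001, 0.02, 8))
        meas = F.simulate_measurements(truth, known, mix, scheme7,
                                       noise_level=0.1, seed=11)
        k = rng.uniform(0.001, 0.02, 8)
        _, g = op.cost_gradient(k, meas.values, 1e-4)
        g_ref = complex_step_gradient(k, meas.values, 1e-4, mix, scheme7, known)
        assert np.max(np.abs(g - g_ref) / np.abs(g_ref)) < 1e-10

    def test_gradient_with_interpolated_sample_times(self, known, mix):
        # off-grid times exercise the interpolation branch of the adjoint
        sch = F.custom_scheme([0.3, 1.7, 7.77, 30.123, 71.5])
        op = ForwardOperator(mix, sch, known=known)
        rng = np.random.default_rng(5)
        y = op.predict(rng.uniform(0.001, 0.02, 8)) * 1.05
        k = rng.uniform(0.001, 0.02, 8)
        _, g = op.cost_gradient(k, y, 0.0)
        g_ref = complex_step_gradient(k, y, 0.0, mix, sch, known)
        assert np.max(np.abs(g - g_ref) / np.abs(g_ref)) < 1e-10


class TestFit:
    def test_noise_free_recovery_within_one_percent(self, known, mix, scheme7):
        rng = np.random.default_rng(42)
        for _ in range(2):
            truth = F.KineticParameters(rng.uniform(0.002, 0.019, 8))
            meas = F.simulate_measurements(truth, known, mix, scheme7, noise_level=0.0)
            res = F.fit(meas, known, mix, scheme7, F.FitConfig())
            rel = F.relative_error(res.params, truth)
            assert np.max(rel) < 0.01
            assert res.converged

    def test_truth_at_lower_bound_attained(self, known, mix, scheme7):
        cfg = F.FitConfig()
        truth = F.KineticParameters(np.full(8, cfg.lo))
        meas = F.simulate_measurements(truth, known, mix, scheme7, noise_level=0.0)
        res = F.fit(meas, known, mix, scheme7, cfg)
        assert np.all(res.params.values <= cfg.lo + 1e-4)

    def test_estimates_within_bounds_and_descending_trace(self, known, mix, scheme7):
        rng = np.random.default_rng(8)
        truth = F.KineticParameters(rng.uniform(0.001, 0.02, 8))
        meas = F.simulate_measurements(truth, known, mix, scheme7,
                                       noise_level=0.1, seed=2)
        res = F.fit(meas, known, mix, scheme7, F.FitConfig())
        assert res.params.within_bounds(0.001, 0.02)
        assert np.all(np.diff(res.cost_trace) <= 1e-12)

    def test_determinism(self, known, mix, scheme7):
        truth = F.KineticParameters(np.linspace(0.002, 0.018, 8))
        meas = F.simulate_measurements(truth, known, mix, scheme7,
                                       noise_level=0.1, seed=3)
        cfg = F.FitConfig(init="random", n_starts=3, seed=17)
        r1 = F.fit(meas, known, mix, scheme7, cfg)
        r2 = F.fit(meas, known, mix, scheme7, cfg)
        assert np.array_equal(r1.params.values, r2.params.values)
        assert r1.cost.total == r2.cost.total
        assert r1.n_iter == r2.n_iter

    def test_regularization_vanishing_bias(self, known, mix, scheme7):
        truth = F.KineticParameters(np.linspace(0.003, 0.018, 8))
        meas = F.simulate_measurements(truth, known, mix, scheme7, noise_level=0.0)
        errs = []
        for c in (1e-2, 1e-4, 1e-6):
            res = F.fit(meas, known, mix, scheme7, F.FitConfig(c=c))
            errs.append(F.relative_error(res.params, truth).mean())
        assert errs[0] >= errs[1] >= errs[2]
        assert errs[2] < 1e-4

    def test_projection_mode_noise_free_recovery(self, known, mix, scheme7):
        truth = F.KineticParameters(np.linspace(0.004, 0.017, 8))
        meas = F.simulate_measurements(truth, known, mix, scheme7, noise_level=0.0)
        res = F.fit(meas, known, mix, scheme7, F.FitConfig(constraint="projection"))
        assert np.max(F.relative_error(res.params, truth)) < 0.01


class TestFitUncorrected:
    def test_model_match_recovery(self, known, scheme7):
        # data generated without mixing: the collapse-only model is correct
        truth = F.KineticParameters(np.linspace(0.002, 0.018, 8))
        meas = F.simulate_measurements(
            truth, known, F.collapse_map(), scheme7, noise_level=0.0
        )
        res = F.fit_uncorrected(meas, known, scheme7, F.FitConfig())
        assert np.max(F.relative_error(res.params, truth)) < 0.01
        assert not res.corrected

    def test_corrected_fit_beats_uncorrected_on_mixed_data(self, known, mix, scheme7):
        rng = np.random.default_rng(31)
        cost_diffs = []
        for i in range(20):
            truth = F.KineticParameters(rng.uniform(0.001, 0.02, 8))
            meas = F.simulate_measurements(
                truth, known, mix, scheme7, noise_level=0.1, seed=1000 + i
            )
            rc = F.fit(meas, known, mix, scheme7, F.FitConfig())
            ru = F.fit_uncorrected(meas, known, scheme7, F.FitConfig())
            cost_diffs.append(ru.cost.total - rc.cost.total)
        assert np.median(cost_diffs) > 0
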