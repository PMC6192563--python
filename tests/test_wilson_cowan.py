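import numpy as np
import pytest

from conndyn import (
    IntegrationError,
    Pulse,
    RegionSet,
    StimulusSchedule,
    StructuralConnectome,
    WilsonCowanParams,
    sigmoid,
    sigmoid_max,
    simulate,
)
from conndyn.wilson_cowan import derivatives, region_noise_streams


def scalar_rhs(E, I, p: WilsonCowanParams, P=0.0, coupling_E=0.0, coupling_I=0.0):
    """Independent single-region implementation used as an oracle."""
    import math

    def S(x, a, th):
        return 1.0 / (1.0 + math.exp(-a * (x - th))) - 1.0 / (1.0 + math.exp(a * th))

    SEm = 1.0 - 1.0 / (1.0 + math.exp(p.a_E * p.theta_E))
    SIm = 1.0 - 1.0 / (1.0 + math.exp(p.a_I * p.theta_I))
    dE = (-E + (SEm - E) * S(p.c1 * E - p.c2 * I + coupling_E + P, p.a_E, p.theta_E)) / p.tau
    dI = (-I + (SIm - I) * S(p.c3 * E - p.c4 * I + coupling_I, p.a_I, p.theta_I)) / p.tau
    return dE, dI


class TestSigmoid:
    def test_zero_is_pinned_to_zero(self):
        assert sigmoid(0.0, 1.3, 4.0) == pytest.approx(0.0, abs=1e-15)
        assert sigmoid(0.0, 2.0, 3.7) == pytest.approx(0.0, abs=1e-15)

    def test_value_at_threshold(self):
        # S(theta) = 1/2 - 1/(1+e^{a*theta}) for the shifted logistic
        assert sigmoid(4.0, 1.3, 4.0) == pytest.approx(0.5 - 1.0 / (1.0 + np.exp(5.2)))
        assert sigmoid(4.0, 1.3, 4.0) == pytest.approx(0.4945137, abs=1e-6)

    def test_saturates_at_sigmoid_max(self):
        assert sigmoid(50.0, 1.3, 4.0) == pytest.approx(sigmoid_max(1.3, 4.0), abs=1e-12)

    def test_strictly_increasing(self):
        x = np.linspace(-20, 20, 400)
        assert np.all(np.diff(sigmoid(x, 1.3, 4.0)) > 0)


class TestParams:
    def test_defaults_validated(self):
        with pytest.raises(ValueError):
            WilsonCowanParams(tau=0.0)
        with pytest.raises(ValueError):
            WilsonCowanParams(sigma=-1.0)

    def test_sigmoid_ceilings_derived(self):
        p = WilsonCowanParams()
        assert p.S_E_max == pytest.approx(1.0 - 1.0 / (1.0 + np.exp(1.3 * 4.0)))
        assert p.S_I_max == pytest.approx(1.0 - 1.0 / (1.0 + np.exp(2.0 * 3.7)))


class TestDerivatives:
    def test_origin_is_equilibrium(self, small_conn, params_nonoise):
        n = small_conn.n_regions
        hist = np.zeros((n, 2000))
        dE, dI = derivatives(np.zeros(n), np.zeros(n), hist, hist,
                             small_conn, c5=0.2, params=params_nonoise)
        np.testing.assert_allclose(dE, 0.0, atol=1e-15)
        np.testing.assert_allclose(dI, 0.0, atol=1e-15)

    def test_uncoupled_matches_scalar_oracle(self, params_nonoise):
        conn = StructuralConnectome(["a", "b"], np.zeros((2, 2)),
                                    np.zeros((2, 3)), np.ones(2))
        E = np.array([0.12, 0.31])
        I = np.array([0.05, 0.22])
        hist = np.tile(E[:, None], 10)
        dE, dI = derivatives(E, I, hist, hist, conn, c5=0.7,
                             params=params_nonoise, P=[0.3, 0.0])
        for i, P in enumerate((0.3, 0.0)):
            eE, eI = scalar_rhs(E[i], I[i], params_nonoise, P=P)
            assert dE[i] == pytest.approx(eE, rel=1e-12)
            assert dI[i] == pytest.approx(eI, rel=1e-12)

    def test_coupling_scales_linearly_in_c5(self, params_nonoise):
        A = np.array([[0.0, 2.0], [2.0, 0.0]])
        conn = StructuralConnectome(["a", "b"], A, np.zeros((2, 3)), np.ones(2))
        E = np.array([0.1, 0.2])
        I = np.zeros(2)
        hist = np.tile(E[:, None], 5)
        # with zero delay the coupling term is c5 * A @ E; doubling c5 must
        # reproduce the derivative computed with a pre-doubled coupling input
        dE2, _ = derivatives(E, I, hist, hist, conn, c5=0.8, params=params_nonoise)
        coup = 0.8 * A @ E
        for i in range(2):
            eE, _ = scalar_rhs(E[i], I[i], params_nonoise,
                               coupling_E=coup[i], coupling_I=0.25 * 0.8 * (A @ E)[i])
            assert dE2[i] == pytest.approx(eE, rel=1e-12)

    def test_history_must_cover_max_delay(self, params_nonoise):
        cent = np.zeros((2, 3))
        cent[1, 0] = 500.0  # 50 ms delay = 500 steps
        conn = StructuralConnectome(["a", "b"], np.ones((2, 2)) - np.eye(2),
                                    cent, np.ones(2))
        hist = np.zeros((2, 100))
        with pytest.raises(ValueError, match="history"):
            derivatives(np.zeros(2), np.zeros(2), hist, hist, conn,
                        c5=0.1, params=params_nonoise)


class TestSimulate:
    def test_quiescent_convergence_matches_fine_step_reference(
            self, single_node, params_nonoise):
        trace = simulate(single_node, params_nonoise, c5=0.0,
                         duration_ms=1000.0, stabilization_ms=0.0)
        # independent fine-step (h = 0.001 ms) midpoint reference
        h = 0.001
        E, I = 0.1, 0.1
        for _ in range(int(1000 / h)):
            dE1, dI1 = scalar_rhs(E, I, params_nonoise)
            dE2, dI2 = scalar_rhs(E + h / 2 * dE1, I + h / 2 * dI1, params_nonoise)
            E, I = E + h * dE2, I + h * dI2
        mask = trace.time_ms > 800.0
        assert np.all(np.abs(trace.E[0, mask] - E) < 1e-6)

    def test_constant_drive_sustains_limit_cycle(self, single_node, params_nonoise):
        sch = StimulusSchedule.single_pulse(RegionSet("t", ("R000",)), 1.15,
                                            0.0, 2000.0)
        trace = simulate(single_node, params_nonoise, c5=0.0, schedule=sch,
                         duration_ms=2000.0)
        tail = trace.E[0, trace.time_ms >= 1500.0]
        assert np.ptp(tail) > 0.1
        # non-decaying: successive 250 ms windows keep their amplitude
        wins = [np.ptp(tail[i * 2500:(i + 1) * 2500]) for i in range(2)]
        assert wins[1] > 0.8 * wins[0]

    def test_zero_coupling_decouples_into_single_node_runs(self, params_nonoise):
        params = WilsonCowanParams(sigma=1e-5)
        conn2 = StructuralConnectome(["a", "b"], np.zeros((2, 2)),
                                     np.zeros((2, 3)), np.ones(2))
        n_steps = int(round(1500 / params.step_h))
        wE, wI = region_noise_streams(123, 2, n_steps)
        tr2 = simulate(conn2, params, c5=0.0, duration_ms=500.0, noise=(wE, wI))
        single = StructuralConnectome(["x"], np.zeros((1, 1)),
                                      np.zeros((1, 3)), np.ones(1))
        for i in range(2):
            tr1 = simulate(single, params, c5=0.0, duration_ms=500.0,
                           noise=(wE[i:i + 1], wI[i:i + 1]))
            np.testing.assert_array_equal(tr2.E[i], tr1.E[0])
            np.testing.assert_array_equal(tr2.I[i], tr1.I[0])

    def test_seed_determinism(self, small_conn):
        params = WilsonCowanParams()
        a = simulate(small_conn, params, c5=0.05, duration_ms=50.0,
                     stabilization_ms=0.0, seed=11)
        b = simulate(small_conn, params, c5=0.05, duration_ms=50.0,
                     stabilization_ms=0.0, seed=11)
        np.testing.assert_array_equal(a.E, b.E)
        c = simulate(small_conn, params, c5=0.05, duration_ms=50.0,
                     stabilization_ms=0.0, seed=12)
        assert not np.array_equal(a.E, c.E)

    def test_step_halving_order_of_convergence(self, single_node):
        # deterministic integrator should show second-order accuracy
        ends = []
        for h in (0.2, 0.1, 0.05):
            p = WilsonCowanParams(sigma=0.0, step_h=h)
            sch = StimulusSchedule.single_pulse(RegionSet("t", ("R000",)), 0.9,
                                                0.0, 100.0)
            tr = simulate(single_node, p, c5=0.0, schedule=sch,
                          duration_ms=100.0, stabilization_ms=0.0)
            ends.append(tr.E[0, -1])
        e01 = abs(ends[0] - ends[1])
        e12 = abs(ends[1] - ends[2])
        order = np.log2(e01 / e12)  # successive-difference order estimate
        assert order >= 1.8 or e12 < 1e-12

    def test_blowup_raises_with_step_number(self, single_node):
        p = WilsonCowanParams(sigma=0.0, tau=1e-4)  # stiff: explicit RK2 unstable
        with pytest.raises(IntegrationError, match="step"):
            simulate(single_node, p, c5=0.0, duration_ms=100.0,
                     stabilization_ms=0.0)

    def test_trace_bounds_and_grid(self, small_conn):
        params = WilsonCowanParams()
        tr = simulate(small_conn, params, c5=0.05, duration_ms=200.0, seed=0)
        assert np.all(np.diff(tr.time_ms) == pytest.approx(params.step_h))
        assert tr.E.min() > -1e-3
        assert tr.E.max() < params.S_E_max + 1e-3

    def test_invalid_pulse(self):
        with pytest.raises(ValueError, match="onset"):
            Pulse(("a",), 1.0, 10.0, 5.0)


class TestTraceIO:
    def test_tsv_and_hdf5_roundtrip(self, single_node, params_nonoise, tmp_path):
        tr = simulate(single_node, params_nonoise, c5=0.0, duration_ms=10.0,
                      stabilization_ms=0.0)
        tr.to_tsv(tmp_path / "trace.tsv")
        import pandas as pd

        df = pd.read_csv(tmp_path / "trace.tsv", sep="\t")
        assert list(df.columns) == ["time_ms", "R000"]
        np.testing.assert_allclose(df["R000"], tr.E[0], rtol=1e-6)
        tr.to_hdf5(tmp_path / "trace.h5")
        import h5py

        with h5py.File(tmp_path / "trace.h5") as f:
            np.testing.assert_array_equal(f["E"][:], tr.E)
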