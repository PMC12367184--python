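"""Spiking and rate network simulators and their shared random structure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spikeforce.netmodels as nm
from spikeforce._kernels import RATE_SCALE

DT = 0.05  # ms


class TestReservoir:
    def test_row_sums_vanish_after_balancing(self):
        w = nm.sample_reservoir(300, 0.3, seed=0, row_balanced=True)
        sums = np.asarray(w.sum(axis=1)).ravel()
        np.testing.assert_allclose(sums, 0.0, atol=1e-12)

    def test_sparsity_and_entry_variance(self):
        N, p = 2000, 0.4
        w = nm.sample_reservoir(N, p, seed=1, row_balanced=False)
        frac = w.nnz / N**2
        assert frac == pytest.approx(p, abs=3 * np.sqrt(p * (1 - p) / N**2) + 1e-3)
        # variance over ALL entries (zeros included) is p/(N p^2) = 1/(N p)
        var_all = (w.data**2).sum() / N**2
        assert var_all == pytest.approx(1.0 / (N * p), rel=0.02)

    def test_balancing_preserves_sparsity_pattern(self):
        a = nm.sample_reservoir(200, 0.3, seed=5, row_balanced=False)
        b = nm.sample_reservoir(200, 0.3, seed=5, row_balanced=True)
        np.testing.assert_array_equal(a.indices, b.indices)
        np.testing.assert_array_equal(a.indptr, b.indptr)

    def test_invalid_sparsity_rejected(self):
        with pytest.raises(ValueError):
            nm.sample_reservoir(10, 0.0, seed=0)


class TestEncoder:
    def test_range_determinism_and_mean(self):
        e = nm.sample_encoder(3000, 2, seed=2)
        assert e.shape == (3000, 2)
        assert e.min() >= -1.0 and e.max() <= 1.0
        assert abs(e.mean()) < 3 / np.sqrt(3 * 6000)
        np.testing.assert_array_equal(e, nm.sample_encoder(3000, 2, seed=2))


class TestInputCurrent:
    def test_low_rank_form_matches_dense_oracle(self, params, rng):
        init = nm.make_network(40, 2, 0.5, 0.12, 7.0, seed=3)
        phi = rng.normal(size=(40, 2)) * 1e-3
        r = rng.uniform(0, 60, size=40)
        dense_w = init.G * init.omega0.toarray() + init.Q * init.eta @ phi.T
        expected = dense_w @ r + params.i_bias
        np.testing.assert_allclose(
            nm.input_current(r, init, phi, params), expected, rtol=1e-12
        )

    def test_zero_inputs_give_bias(self, params):
        init = nm.make_network(20, 1, 0.5, 0.0, 5.0, seed=0)
        I = nm.input_current(np.zeros(20), init, np.zeros((20, 1)), params)
        np.testing.assert_allclose(I, params.i_bias)


class TestRateTransfer:
    def test_threshold_and_known_value(self, params):
        assert nm.rate_transfer(np.array([params.v_th]), params)[0] == 0.0
        # closed form at I = -20 mV: 1 / (2 + 10 ln(45/20)) spikes/ms
        expected = 1.0 / (2.0 + 10.0 * np.log(45.0 / 20.0))
        assert nm.rate_transfer(np.array([-20.0]), params)[0] == pytest.approx(
            expected, rel=1e-12
        )
        assert expected == pytest.approx(0.0989, abs=2e-4)

    @given(st.floats(min_value=-39.9, max_value=1e4))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_bounded(self, I):
        params = nm.NeuronParams()
        R = nm.rate_transfer(np.array([I, I + 1.0]), params)
        assert 0.0 <= R[0] <= R[1] < 1.0 / params.tau_ref

    def test_saturates_at_inverse_refractory(self, params):
        R = nm.rate_transfer(np.array([1e12]), params)[0]
        assert R == pytest.approx(1.0 / params.tau_ref, rel=1e-6)


def _run_constant_current_lif(I_vals, params, t_ms, dt=DT):
    state = nm.LifState(
        np.full(len(I_vals), params.v_reset),
        np.zeros(len(I_vals)),
        np.zeros(len(I_vals)),
        np.zeros(len(I_vals)),
    )
    I = np.asarray(I_vals, dtype=float)
    counts = np.zeros(len(I_vals))
    spike_steps = [[] for _ in I_vals]
    for k in range(int(round(t_ms / dt))):
        state, spiked = nm.lif_step(state, I, params, dt)
        counts += spiked
        for i in np.nonzero(spiked)[0]:
            spike_steps[i].append(k)
    return counts, spike_steps, state


class TestLifStep:
    def test_rheobase_bias_never_spikes(self, params):
        counts, _, _ = _run_constant_current_lif([params.i_bias], params, 500.0)
        assert counts[0] == 0

    def test_interspike_interval_matches_closed_form(self, params):
        # I = -20 mV: ISI = tau_ref + tau_m ln(45/20) ~ 10.109 ms
        _, steps, _ = _run_constant_current_lif([-20.0], params, 200.0)
        isis = np.diff(steps[0]) * DT
        expected = params.tau_ref + params.tau_m * np.log(45.0 / 20.0)
        assert np.all(np.abs(isis - expected) <= DT + 1e-12)

    def test_refractory_gap_between_spikes(self, params):
        _, steps, _ = _run_constant_current_lif([-5.0, -20.0, -30.0], params, 300.0)
        for s in steps:
            if len(s) > 1:
                assert np.diff(s).min() * DT >= params.tau_ref

    def test_single_spike_filter_follows_double_exponential(self, params):
        # inject one spike by hand, then let the filter ring down
        state = nm.LifState(
            np.array([params.v_reset]), np.array([params.tau_ref]),
            np.array([RATE_SCALE / (params.tau_r * params.tau_d)]), np.array([0.0]),
        )
        I = np.array([params.i_bias])
        t_grid, r_trace = [], []
        for k in range(int(round(40.0 / DT))):
            t_grid.append(state.t)
            r_trace.append(state.r[0])
            state, _ = nm.lif_step(state, I, params, DT)
        t = np.array(t_grid)
        tr, td = params.tau_r, params.tau_d
        analytic = RATE_SCALE * (np.exp(-t / td) - np.exp(-t / tr)) / (td - tr)
        # forward Euler carries an O(dt/tau_r) = 2.5% bias on the rise
        assert np.max(np.abs(np.array(r_trace) - analytic)) < 3e-2 * analytic.max()
        # peak location: tau_r tau_d / (tau_d - tau_r) * ln(tau_d / tau_r)
        t_peak = t[np.argmax(r_trace)]
        expected_peak = tr * td / (td - tr) * np.log(td / tr)
        assert t_peak == pytest.approx(expected_peak, abs=3 * DT)

    def test_filter_linearity_in_spike_trains(self, params):
        # response to two spikes equals the sum of single-spike responses
        def ring_down(initial_h, steps=4000):
            st_ = nm.LifState(np.array([params.v_reset]), np.array([1e9]),
                              np.array([initial_h]), np.array([0.0]))
            out = []
            for _ in range(steps):
                out.append(st_.r[0])
                nm.lif_step(st_, np.array([params.i_bias]), params, DT)
            return np.array(out)

        h1 = RATE_SCALE / (params.tau_r * params.tau_d)
        np.testing.assert_allclose(
            ring_down(2 * h1), 2 * ring_down(h1), rtol=1e-12, atol=1e-12
        )


class TestRateStep:
    def test_steady_state_equals_transfer_rate_in_hz(self, params):
        I = np.array([-20.0])
        state = nm.RateState(np.zeros(1), np.zeros(1))
        for _ in range(int(round(400.0 / DT))):
            nm.rate_step(state, I, params, DT)
        expected_hz = RATE_SCALE * nm.rate_transfer(I, params)[0]
        assert state.r[0] == pytest.approx(expected_hz, rel=1e-3)

    def test_decay_to_zero_without_drive(self, params):
        state = nm.RateState(np.array([5.0]), np.array([40.0]))
        for _ in range(int(round(400.0 / DT))):
            nm.rate_step(state, np.array([params.i_bias]), params, DT)
        assert abs(state.r[0]) < 1e-6

    def test_lif_mean_rate_matches_transfer_function(self, params):
        # time-averaged spike count at constant current vs the f-I curve
        I_vals = [-30.0, -25.0, -20.0]
        window = 2000.0  # ms
        counts, _, _ = _run_constant_current_lif(I_vals, params, window)
        for I, c in zip(I_vals, counts):
            predicted = nm.rate_transfer(np.array([I]), params)[0] * window
            assert c == pytest.approx(predicted, rel=0.02)


class TestRunNetwork:
    def test_zero_gain_network_is_silent_at_rheobase(self, params):
        init = nm.make_network(50, 1, 0.5, 0.0, 0.0, seed=0)
        # voltages all start below threshold here, so nothing ever fires
        state = nm.initial_state("spiking", 50, params, seed=0)
        state.v[:] = params.v_reset
        trace = nm.run_network(
            "spiking", init, params, None, 0.2, state=state,
            record=nm.RecordSpec(spikes=True),
        )
        assert trace.n_spikes == 0
        np.testing.assert_array_equal(trace.readout, 0.0)

    def test_chaotic_regime_twin_runs_diverge(self, params):
        # spontaneous activity with G > 0: perturbed initial states separate
        init = nm.make_network(200, 1, 0.4, 0.12, 20.0, seed=4)
        s1 = nm.initial_state("rate", 200, params, seed=7)
        s2 = nm.initial_state("rate", 200, params, seed=7)
        s2.r[0] += 1e-6
        rec = nm.RecordSpec(sample_idx=np.arange(10))
        t1 = nm.run_network("rate", init, params, None, 1.0, state=s1, record=rec)
        t2 = nm.run_network("rate", init, params, None, 1.0, state=s2, record=rec)
        d = np.abs(t1.sampled_r - t2.sampled_r).max(axis=0)
        assert d[-1] > 1e3 * max(d[1], 1e-12)

    def test_kernel_matches_numpy_reference_steps(self, params, rng):
        # G = 0 keeps the float32 reservoir path exactly zero, so the
        # compiled kernel and the pure-numpy step functions must agree
        N, M = 30, 1
        init = nm.make_network(N, M, 0.5, 0.0, 8.0, seed=6)
        phi = rng.normal(size=(N, M)) * 1e-3
        n_steps = 2000
        for kind in ("spiking", "rate"):
            state_k = nm.initial_state(kind, N, params, seed=9)
            trace = nm.run_network(
                kind, init, params, phi, n_steps * DT * 1e-3, state=state_k
            )
            state_n = nm.initial_state(kind, N, params, seed=9)
            readout = np.empty(n_steps)
            for k in range(n_steps):
                readout[k] = (phi.T @ state_n.r).item()
                I = nm.input_current(state_n.r, init, phi, params)
                if kind == "spiking":
                    nm.lif_step(state_n, I, params, DT)
                else:
                    nm.rate_step(state_n, I, params, DT)
            np.testing.assert_allclose(
                trace.readout[0], readout, rtol=1e-9, atol=1e-12
            )

    def test_spike_raster_respects_refractory_contract(self, params):
        init = nm.make_network(100, 1, 0.4, 0.1, 20.0, seed=8)
        trace = nm.run_network(
            "spiking", init, params, None, 0.5,
            record=nm.RecordSpec(spikes=True), seed=1,
        )
        assert trace.n_spikes > 0
        for times in trace.spike_times:
            if len(times) > 1:
                assert np.diff(times).min() >= params.tau_ref - 1e-9

    def test_matched_pair_shares_structure(self):
        init = nm.make_network(50, 2, 0.5, 0.1, 10.0, seed=11)
        init2 = nm.make_network(50, 2, 0.5, 0.1, 10.0, seed=11)
        np.testing.assert_array_equal(init.omega0.toarray(), init2.omega0.toarray())
        np.testing.assert_array_equal(init.eta, init2.eta)

    def test_trace_export_roundtrip(self, params, tmp_path):
        init = nm.make_network(40, 1, 0.5, 0.1, 10.0, seed=1)
        trace = nm.run_network(
            "spiking", init, params, None, 0.1,
            record=nm.RecordSpec(spikes=True, sample_idx=np.arange(3)), seed=2,
        )
        nm.save_trace(trace, tmp_path / "trace", {"note": "unit"})
        arch = np.load(tmp_path / "trace.npz")
        np.testing.assert_array_equal(arch["readout"], trace.readout)
        assert (tmp_path / "trace.json").exists()
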