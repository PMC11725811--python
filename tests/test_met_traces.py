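"""MET current analysis: cycle averaging, peak-to-peak extraction,
resting open probability, I-V / reversal, and saturation detection."""

import numpy as np
import pytest

from metkit.met_traces import (
    AperiodicDriverError,
    CurrentTrace,
    build_iv_and_reversal,
    cycle_average,
    detect_saturation,
    met_summary,
    peak_to_peak_current,
    resting_open_probability,
    summaries_to_frame,
)
from metkit.synthetic import (
    ChannelModel,
    Sinusoid,
    TraceProtocol,
    simulate_met_traces,
)

FS = 50_000.0


def _sine_driver(n_cycles=10, period=1000, pre=500):
    dv = np.zeros(pre + n_cycles * period + pre)
    t = np.arange(n_cycles * period)
    dv[pre : pre + n_cycles * period] = 0.005 * np.sin(2 * np.pi * t / period)
    return dv


def _trace(samples, driver, v_m=-84.0):
    return CurrentTrace(samples, FS, driver, v_m, stim_onset_s=500 / FS)


class TestCycleAverage:
    def test_constant_current_gives_flat_cycle(self):
        dv = _sine_driver()
        ca = cycle_average(_trace(np.full(dv.size, -20.0), dv))
        assert ca.period_samples == 1000
        assert ca.n_cycles == 10
        assert np.allclose(ca.current, -20.0)

    def test_noise_shrinks_by_sqrt_n_cycles(self):
        rng = np.random.default_rng(0)
        dv = _sine_driver(n_cycles=10)
        signal = np.zeros(dv.size)
        noise = rng.normal(0, 10.0, dv.size)
        ca = cycle_average(_trace(signal + noise, dv))
        # oracle: the SD of the averaged cycle is the per-sample SD / sqrt(10)
        sd = ca.current.std()
        assert sd == pytest.approx(10.0 / np.sqrt(10), rel=0.15)

    def test_noise_free_average_equals_any_single_cycle(self):
        from metkit.synthetic import FluidJetModel

        # instantaneous mechanics: every cycle is identical (no transient)
        jet = FluidJetModel(tau_jet=0.0, c_drag=0.0)
        sim = simulate_met_traces(
            ChannelModel(noise_sd=0.0), jet,
            TraceProtocol(voltage_steps=(-84.0,)), seed=0,
        )
        tr = sim.traces[0]
        ca = cycle_average(tr)
        start = int(round(tr.stim_onset_s * tr.sample_rate))
        one = tr.samples[start + ca.period_samples : start + 2 * ca.period_samples]
        assert np.allclose(ca.current, one, atol=1e-9)

    def test_aperiodic_driver_directs_to_step_mode(self):
        dv = np.zeros(5000)
        dv[1000:4000] = 0.005  # single step
        with pytest.raises(AperiodicDriverError, match="step-mode"):
            cycle_average(_trace(np.zeros(5000), dv))

    def test_fewer_than_two_cycles_rejected(self):
        dv = _sine_driver(n_cycles=1)
        with pytest.raises(AperiodicDriverError):
            cycle_average(_trace(np.zeros(dv.size), dv))


class TestPeakToPeak:
    def test_generator_ground_truth_recovered_noise_free(self, noise_free_met_sim):
        sim = noise_free_met_sim
        for tr, (_, row) in zip(sim.traces, sim.ground_truth.iterrows()):
            _, _, i_max = peak_to_peak_current(tr)
            assert i_max == pytest.approx(row.i_pp_pA, abs=0.01 * abs(row.i_pp_pA) + 1.0)

    def test_no_channels_gives_near_zero_i_max(self, default_jet):
        ch = ChannelModel(n_channels=0, noise_sd=15.0)
        sim = simulate_met_traces(ch, default_jet,
                                  TraceProtocol(voltage_steps=(-124.0,)), seed=1)
        s = met_summary(sim.traces[0])
        assert abs(s.i_max) < 3 * 15.0 / np.sqrt(10)
        assert "low_met_current" in s.flags

    def test_i_max_invariant_to_added_leak(self, noise_free_met_sim):
        tr = noise_free_met_sim.traces[0]
        shifted = CurrentTrace(tr.samples + 500.0, tr.sample_rate, tr.driver,
                               tr.v_m, stim_onset_s=tr.stim_onset_s)
        assert met_summary(shifted).i_max == pytest.approx(
            met_summary(tr).i_max, abs=1e-9
        )


class TestRestingOpenProbability:
    def test_boundary_values(self):
        # channels fully shut at rest: i_hold = i_inhib -> 0
        dv = _sine_driver()
        sig = np.where(dv > 0, -1000.0, 0.0)  # opens only in excitatory phase
        assert resting_open_probability(_trace(sig, dv)) == pytest.approx(0.0, abs=1e-9)
        # fully open at rest: i_hold = i_exc -> 1
        sig2 = np.where(dv < 0, 0.0, -1000.0)
        sig2[:500] = -1000.0
        tr2 = _trace(sig2, dv)
        assert resting_open_probability(tr2) == pytest.approx(1.0, abs=1e-9)

    def test_recovery_of_half_open_rest(self, default_jet):
        ch = ChannelModel(p_rest=0.5, adapt_gain=0.0, noise_sd=0.0)
        sim = simulate_met_traces(ch, default_jet,
                                  TraceProtocol(voltage_steps=(-84.0,)), seed=0)
        assert resting_open_probability(sim.traces[0]) == pytest.approx(0.50, abs=0.01)

    def test_recovery_across_p_rest_and_buffers(self, default_jet):
        # parameter recovery against the generator's analytic ground truth
        errs = []
        for p_rest in (0.05, 0.1, 0.3, 0.5):
            for buffer_label in ("EGTA_1mM", "BAPTA_5mM"):
                for seed in range(5):
                    ch = ChannelModel(p_rest=p_rest)
                    pr = TraceProtocol(voltage_steps=(-84.0,),
                                       buffer_label=buffer_label)
                    sim = simulate_met_traces(ch, default_jet, pr, seed=seed)
                    truth = sim.ground_truth["p_open_rest"].iloc[0]
                    est = met_summary(sim.traces[0]).p_open_rest
                    errs.append(abs(est - truth))
        assert np.median(errs) <= 0.02
        assert max(errs) <= 0.05

    def test_bapta_raises_p_open_over_egta(self, default_jet):
        wins = 0
        for seed in range(10):
            ch = ChannelModel()
            ests = {}
            for buf in ("EGTA_1mM", "BAPTA_5mM"):
                pr = TraceProtocol(voltage_steps=(-84.0,), buffer_label=buf)
                sim = simulate_met_traces(ch, default_jet, pr, seed=seed)
                ests[buf] = met_summary(sim.traces[0]).p_open_rest
            wins += ests["BAPTA_5mM"] > ests["EGTA_1mM"]
        assert wins >= 9


class TestIVAndReversal:
    def test_generator_reversal_near_zero(self, noise_free_met_sim):
        iv = build_iv_and_reversal(noise_free_met_sim.traces)
        assert iv.reversal_mV == pytest.approx(0.0, abs=2.0)
        assert np.all(np.diff(iv.v_mV) > 0)

    def test_ohmic_series_reverses_exactly_at_e_rev(self):
        # fixed P_open: I-V is linear and the interpolation is exact
        dv = _sine_driver()
        e_rev = 4.0
        traces = []
        for v in (-40.0, -20.0, 20.0, 40.0):
            g = 10.0 * (v - e_rev) / 1000.0  # nS*mV -> pA per unit P
            sig = np.where(dv > 0, 1000 * g, 0.0)
            sig[:500] = 0.0
            traces.append(_trace(sig, dv, v_m=v))
        iv = build_iv_and_reversal(traces)
        assert iv.reversal_mV == pytest.approx(e_rev, abs=1e-9)

    def test_reversal_agrees_with_dense_grid_zero_search(self, noise_free_met_sim):
        iv = build_iv_and_reversal(noise_free_met_sim.traces)
        # oracle: brute-force zero crossing on a dense linear interpolation
        grid = np.linspace(iv.v_mV[0], iv.v_mV[-1], 20001)
        vals = np.interp(grid, iv.v_mV, iv.i_pp_pA)
        zero = grid[np.argmin(np.abs(vals))]
        step = grid[1] - grid[0]
        assert abs(iv.reversal_mV - zero) <= step

    def test_single_voltage_reports_absent_reversal(self, default_jet):
        sim = simulate_met_traces(ChannelModel(noise_sd=0.0), default_jet,
                                  TraceProtocol(voltage_steps=(-84.0,)), 0)
        with pytest.warns(UserWarning, match="fewer than two"):
            iv = build_iv_and_reversal(sim.traces)
        assert iv.reversal_mV is None

    def test_no_sign_change_reports_absent_reversal(self, default_jet):
        sim = simulate_met_traces(
            ChannelModel(noise_sd=0.0), default_jet,
            TraceProtocol(voltage_steps=(-124.0, -84.0, -64.0)), 0,
        )
        with pytest.warns(UserWarning, match="reversal"):
            iv = build_iv_and_reversal(sim.traces)
        assert iv.reversal_mV is None


class TestSaturation:
    def _series(self, default_jet, amplitudes, **channel_kwargs):
        traces = []
        for amp in amplitudes:
            pr = TraceProtocol(waveform=Sinusoid(amplitude=amp),
                               voltage_steps=(-84.0,))
            sim = simulate_met_traces(ChannelModel(noise_sd=0.0, **channel_kwargs),
                                      default_jet, pr, 0)
            traces.append(sim.traces[0])
        return traces

    def test_saturating_amplitudes_detected(self, default_jet):
        # displacements far past x_half + 5 lambda: Boltzmann asymptote
        res = detect_saturation(self._series(default_jet, [0.004, 0.005, 0.006]))
        assert res.saturated

    def test_subsaturating_amplitudes_not_saturated(self, default_jet):
        # tiny displacements stay on the quasi-linear part of the Boltzmann
        res = detect_saturation(self._series(default_jet, [0.0001, 0.0002]))
        assert not res.saturated

    def test_identical_repeated_amplitude_is_saturated(self, default_jet):
        res = detect_saturation(self._series(default_jet, [0.005, 0.005]))
        assert res.saturated

    def test_decreasing_amplitudes_rejected(self, default_jet):
        with pytest.raises(ValueError, match="non-decreasing"):
            detect_saturation(self._series(default_jet, [0.005, 0.002]))


def test_summary_frame_has_per_cell_rows(noise_free_met_sim):
    df = summaries_to_frame(noise_free_met_sim.traces)
    assert len(df) == len(noise_free_met_sim.traces)
    assert {"cell_id", "genotype", "age", "v_mV", "i_max_pA", "p_open",
            "flags"} <= set(df.columns)
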