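"""Generator-level invariants: determinism, physics of the damped spring,
Boltzmann ground truth, and error handling."""

import numpy as np
import pytest

from metkit.met_traces import met_summary
from metkit.synthetic import (
    ChannelModel,
    FluidJetModel,
    GeneSetSpec,
    GeneUniverseSpec,
    MovieSpec,
    Sinusoid,
    StackSpec,
    Step,
    TraceProtocol,
    boltzmann_open_probability,
    simulate_bundle_movie,
    simulate_confocal_stack,
    simulate_gene_tables,
    simulate_met_traces,
)


class TestMETTraces:
    def test_identical_seed_gives_bit_identical_traces(self, default_jet):
        p = TraceProtocol(voltage_steps=(-84.0,))
        a = simulate_met_traces(ChannelModel(), default_jet, p, seed=7)
        b = simulate_met_traces(ChannelModel(), default_jet, p, seed=7)
        assert np.array_equal(a.traces[0].samples, b.traces[0].samples)
        c = simulate_met_traces(ChannelModel(), default_jet, p, seed=8)
        assert not np.array_equal(a.traces[0].samples, c.traces[0].samples)

    def test_no_channels_leaves_only_leak_and_noise(self, default_jet):
        ch = ChannelModel(n_channels=0, noise_sd=0.0, i_leak=-20.0)
        sim = simulate_met_traces(ch, default_jet,
                                  TraceProtocol(voltage_steps=(-124.0,)), seed=0)
        assert np.allclose(sim.traces[0].samples, -20.0)
        assert sim.ground_truth["i_pp_pA"].iloc[0] == 0.0

    def test_trace_at_reversal_has_no_stimulus_correlation(self, default_jet):
        ch = ChannelModel(noise_sd=0.0)
        sim = simulate_met_traces(ch, default_jet,
                                  TraceProtocol(voltage_steps=(0.0,)), seed=0)
        tr = sim.traces[0]
        # zero driving force: current is pure leak, flat despite P_open(t)
        assert np.ptp(tr.samples) == 0.0
        demeaned = tr.samples - tr.samples.mean()
        assert abs(np.dot(demeaned, tr.driver)) < 1e-3

    def test_ground_truth_matches_analytic_boltzmann(self, default_jet):
        ch = ChannelModel(p_rest=0.3, noise_sd=0.0)
        p = TraceProtocol(voltage_steps=(-84.0, 96.0))
        sim = simulate_met_traces(ch, default_jet, p, seed=0)
        for _, row in sim.ground_truth.iterrows():
            shift = ch.set_point_shift(row.v_mV, p.buffer_label)
            expected = boltzmann_open_probability(
                np.zeros(1), ch.x_half + shift, ch.lambda_slope
            )[0]
            assert row.p_open_rest == expected

    def test_bapta_zeroes_the_adaptation_shift(self):
        ch = ChannelModel(p_rest=0.4, adapt_gain=0.35)
        assert ch.set_point_shift(-84.0, "BAPTA_5mM") == 0.0
        assert ch.set_point_shift(-84.0, "EGTA_1mM") == pytest.approx(0.35 * 124)
        # no shift at potentials positive to the Ca2+ reversal
        assert ch.set_point_shift(96.0, "EGTA_1mM") == 0.0

    def test_closed_loop_p_open_recovery_noise_free(self, default_jet):
        # saturating sinusoid, no adaptation: the analysis recovers p_rest
        ch = ChannelModel(p_rest=0.10, adapt_gain=0.0, noise_sd=0.0)
        sim = simulate_met_traces(ch, default_jet,
                                  TraceProtocol(voltage_steps=(-84.0,)), seed=0)
        est = met_summary(sim.traces[0]).p_open_rest
        assert est == pytest.approx(0.100, abs=0.005)

    def test_invalid_parameters_rejected(self, default_jet):
        with pytest.raises(ValueError):
            ChannelModel(g_single=float("nan"))
        with pytest.raises(ValueError):
            ChannelModel(p_rest=1.5)
        with pytest.raises(ValueError):
            ChannelModel(lambda_slope=0.0)
        with pytest.raises(ValueError):
            TraceProtocol(sample_rate=0.0)
        with pytest.raises(ValueError):
            TraceProtocol(voltage_steps=())
        with pytest.raises(ValueError):
            FluidJetModel(k_true=0.0)

    def test_step_waveform_produces_plateau(self, default_jet):
        p = TraceProtocol(waveform=Step(amplitude=0.005, duration_ms=50.0),
                          voltage_steps=(-84.0,))
        sim = simulate_met_traces(ChannelModel(noise_sd=0.0), default_jet, p, 0)
        dv = sim.traces[0].driver
        assert dv.max() == 0.005 and dv.min() == 0.0


class TestSpringPhysics:
    def test_steady_state_displacement_is_hookes_law(self):
        # k = 3 mN/m, F = 300 pN -> 100 nm
        jet = FluidJetModel(k_true=3.0)
        sim = simulate_bundle_movie(MovieSpec(photon_scale=np.inf), jet,
                                    [(0.3, 60.0, 90.0)], seed=0)
        assert sim.truth_steady_nm[0] == pytest.approx(100.0)
        # late in the step (t >> tau_jet, c/k) the simulated spring settles
        t_ms = np.arange(sim.spec.n_frames) / sim.spec.frame_rate * 1000
        late = (t_ms > 120) & (t_ms < 150)
        assert np.allclose(sim.truth_x[late], 100.0, rtol=1e-3)

    def test_zero_force_keeps_bundle_at_rest(self):
        jet = FluidJetModel()
        sim = simulate_bundle_movie(MovieSpec(photon_scale=np.inf), jet, [], 0)
        assert np.all(sim.truth_x == 0.0)
        rows = sim.movie.frames[:, 0, :]
        assert np.allclose(rows, rows[0])  # static movie

    def test_out_of_field_displacement_names_the_frame(self):
        jet = FluidJetModel(k_true=1.0)
        with pytest.raises(ValueError, match="frame"):
            simulate_bundle_movie(MovieSpec(), jet, [(5.0, 60.0, 90.0)], 0)

    def test_step_outside_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            simulate_bundle_movie(MovieSpec(), FluidJetModel(),
                                  [(0.3, 150.0, 90.0)], 0)

    def test_movie_determinism(self):
        a = simulate_bundle_movie(MovieSpec(), FluidJetModel(),
                                  [(0.3, 60.0, 90.0)], 5)
        b = simulate_bundle_movie(MovieSpec(), FluidJetModel(),
                                  [(0.3, 60.0, 90.0)], 5)
        assert np.array_equal(a.movie.frames, b.movie.frames)


class TestConfocalStacks:
    def test_zero_ratio_gives_pure_noise_myo7a(self, default_stack_spec):
        spec = default_stack_spec.scaled_ratios(0.0)
        sim = simulate_confocal_stack(spec, seed=0)
        assert abs(sim.stack.myo7a.mean()) < 1.0  # zero-mean noise only
        assert sim.stack.actin.mean() > 50.0

    def test_noise_free_constant_fields_are_exact(self):
        spec = StackSpec(noise_sd=0.0)
        sim = simulate_confocal_stack(spec, seed=0)
        # within each compartment, myo7a / actin equals the true ratio
        names = list(spec.landmarks)
        for name in names:
            lx, ly, lz = spec.landmarks[name]
            iz = int(round(lz / spec.voxel_size[2]))
            iy = int(round(ly / spec.voxel_size[1]))
            ix = int(round(lx / spec.voxel_size[0]))
            r = sim.stack.myo7a[iz, iy, ix] / sim.stack.actin[iz, iy, ix]
            assert r == pytest.approx(spec.true_ratio[name])

    def test_landmark_outside_bounds_named(self):
        with pytest.raises(ValueError, match="stereocilia_tips"):
            StackSpec(landmarks={
                "stereocilia_tips": (-100.0, 0.0, 0.0),
                "stereocilia_bases": (0.0, 0.0, 500.0),
                "cuticular_plate": (0.0, 0.0, 2000.0),
                "cytoplasm_apex": (0.0, 0.0, 4000.0),
                "cytoplasm_base": (0.0, 0.0, 6000.0),
            })

    def test_five_landmarks_required(self):
        with pytest.raises(ValueError, match="five"):
            StackSpec(landmarks={"stereocilia_tips": (0.0, 0.0, 0.0)})


class TestGeneTables:
    def test_filterable_rows_match_ground_truth_membership(self):
        from metkit.genesets import filter_degs

        spec = GeneUniverseSpec(universe_size=500,
                                sets=(GeneSetSpec("a", 60),),
                                overlaps={}, seed=11)
        sim = simulate_gene_tables(spec)
        res = filter_degs(sim.tables["a"])
        assert res.genes.members == frozenset(
            g.casefold() for g in sim.truth_sets["a"]
        )

    def test_direction_ground_truth_consistent_with_sign(self):
        spec = GeneUniverseSpec(universe_size=300,
                                sets=(GeneSetSpec("a", 40, frac_down=0.9),),
                                overlaps={}, seed=4)
        sim = simulate_gene_tables(spec)
        t = sim.tables["a"].set_index("gene_id")
        for g, d in sim.truth_directions["a"].items():
            assert (t.loc[g, "log2FC"] < 0) == (d == "down")

    def test_infeasible_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            GeneUniverseSpec(universe_size=100,
                             sets=(GeneSetSpec("a", 10), GeneSetSpec("b", 5)),
                             overlaps={("a", "b"): 8})

    def test_sets_must_fit_in_universe(self):
        with pytest.raises(ValueError):
            GeneUniverseSpec(universe_size=10,
                             sets=(GeneSetSpec("a", 8), GeneSetSpec("b", 8)),
                             overlaps={("a", "b"): 2})

    def test_determinism_by_seed(self):
        spec = GeneUniverseSpec(universe_size=200, sets=(GeneSetSpec("a", 20),),
                                overlaps={}, seed=9)
        a = simulate_gene_tables(spec)
        b = simulate_gene_tables(spec)
        assert a.tables["a"].equals(b.tables["a"])
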