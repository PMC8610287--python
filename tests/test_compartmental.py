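"""Passive compartmental model: synapse kinetics, cable solver oracles and
the tone-combination experiment."""

import numpy as np
import pytest
from scipy import stats

from icxfreq.compartmental import (
    Cylinder,
    Morphology,
    SimConfig,
    SynapseSpec,
    ampa_conductance,
    build_cell,
    combination_experiment,
    input_rate,
    matched_mismatch_split,
    mg_block,
    nmda_bound_fraction,
    nmda_conductance,
    place_synapses,
    poisson_train,
    simulate,
    stimulus_trains,
    _median_soma_psp,
)


@pytest.fixture(scope="module")
def syn():
    return SynapseSpec("ampa", 1e-3, (0, 0.5), 4.0)


class TestInputRate:
    def test_floor_only(self, syn):
        assert input_rate(syn, 0.0, 4.0, 6.0, 0.0, 0.0) == pytest.approx(0.01)

    def test_preferred_everything(self, syn):
        assert input_rate(syn, 0.0, 4.0, 6.0, 0.15, 0.0) == pytest.approx(0.16)

    def test_anti_preferred_is_floor(self, syn):
        # half period of 4 kHz = 125 us
        assert input_rate(syn, 125.0, 4.0, 6.0, 0.15, 0.0) == pytest.approx(0.01, abs=1e-9)


class TestPoissonTrain:
    def test_zero_rate_empty(self):
        assert poisson_train(0.0, 100.0, seed=1).size == 0

    def test_mean_count(self):
        counts = [poisson_train(0.1, 100.0, seed=s).size for s in range(1000)]
        se = np.std(counts) / np.sqrt(1000)
        assert np.mean(counts) == pytest.approx(10.0, abs=3 * se)

    def test_exponential_intervals(self):
        rng = np.random.default_rng(8)
        isis = []
        for _ in range(30):
            # long windows keep the right-censoring of intervals negligible
            t = poisson_train(0.2, 500.0, seed=rng)
            isis.extend(np.diff(t))
        _, p = stats.kstest(isis, "expon", args=(0, 1 / 0.2))
        assert p > 0.01


class TestSynapseKinetics:
    def test_ampa_jump_decay_causality(self):
        assert ampa_conductance(5.0, 5.0, 2.0, 4.5) == pytest.approx(2.0)
        assert ampa_conductance(9.5, 5.0, 2.0, 4.5) == pytest.approx(2.0 * np.exp(-1))
        assert ampa_conductance(4.9, 5.0, 2.0, 4.5) == 0.0

    def test_ampa_superposition(self):
        g = ampa_conductance(10.0, np.array([5.0, 10.0]), 1.0, 4.5)
        assert g == pytest.approx(1.0 + np.exp(-5 / 4.5))

    def test_mg_block_values(self):
        assert mg_block(0.0, 1.0) == pytest.approx(1 / (1 + 1 / 3.57), rel=1e-9)
        assert mg_block(-70.0, 0.0) == 1.0
        assert mg_block(-120.0, 1.0) < 0.003

    def test_nmda_conductance_composition(self):
        g = nmda_conductance(0.0, 1.0, 0.5, 2.0)
        assert g == pytest.approx(2.0 * 0.5 * mg_block(0.0, 1.0))

    def test_nmda_bound_fraction_pulse_scheme(self):
        t = np.arange(0, 100, 0.025)
        r = nmda_bound_fraction(t, np.array([10.0]))
        assert np.all(r[t <= 10.0] == 0.0)
        r_inf = 0.35 / (0.35 + 0.015)
        peak = r[np.searchsorted(t, 11.0)]
        expected = r_inf * (1 - np.exp(-1.0 * (0.35 + 0.015)))
        assert peak == pytest.approx(expected, rel=1e-2)
        # decay afterwards at rate beta
        i1, i2 = np.searchsorted(t, [20.0, 60.0])
        assert r[i2] == pytest.approx(r[i1] * np.exp(-0.015 * 40.0), rel=1e-6)


class TestMorphologyValidation:
    def test_extreme_spine_shapes_rejected(self):
        with pytest.raises(ValueError, match="spine"):
            Morphology(spine=Cylinder(0.1, 80.0))
        with pytest.raises(ValueError, match="spine"):
            Morphology(spine=Cylinder(0.4, 2.0))

    def test_out_of_range_dendrite_rejected(self):
        with pytest.raises(ValueError):
            Morphology(dendrites=(Cylinder(2.0, 150.0),))

    def test_g_pas_range_enforced(self):
        with pytest.raises(ValueError):
            SimConfig(g_pas=0.02)


class TestCableSolver:
    def test_resting_equilibrium_without_synapses(self):
        cell = build_cell(Morphology(), [], SimConfig())
        _, v = simulate(cell, [])
        assert np.allclose(v, -65.0, atol=1e-12)

    def test_input_resistance_matches_cable_closed_form(self):
        """Steady soma current on a soma+single-dendrite reduction matches
        the sealed-end finite-cable input resistance within 2%."""
        m = Morphology(dendrites=(Cylinder(5.0, 150.0),))
        cfg = SimConfig(nseg_dend=41, duration=400.0)
        cell = build_cell(m, [], cfg)
        _, v = simulate(cell, [], i_inj_soma_nA=0.01)
        dv = v[-1] - cfg.e_pas
        d = m.dendrites[0]
        gm = (cfg.g_pas * 1e-6) / (d.length_um * 1e-4)  # S/cm
        ra = cfg.ra_ohm_cm / d.cross_cm2  # ohm/cm
        lam = 1.0 / np.sqrt(gm * ra)
        g_in = cfg.g_pas * 1e-6 + np.sqrt(gm / ra) * np.tanh(d.length_um * 1e-4 / lam)
        dv_analytic = 0.01e-9 / g_in * 1e3  # nA / S -> mV
        assert dv == pytest.approx(dv_analytic, rel=0.02)

    def test_small_signal_peak_proportional_to_weight(self):
        """A single weak AMPA event produces a soma deflection proportional
        to weight within 2% over a decade."""
        m = Morphology()
        cfg = SimConfig(duration=60.0)
        peaks = []
        for w in (1e-6, 1e-5):
            syn = (SynapseSpec("ampa", w, (0, 0.5), 4.0),)
            cell = build_cell(m, syn, cfg)
            _, v = simulate(cell, [np.array([5.0])])
            peaks.append(v.max() - cfg.e_pas)
        assert peaks[1] / peaks[0] == pytest.approx(10.0, rel=0.02)

    def test_dt_halving_convergence(self):
        m = Morphology()
        cfg = SimConfig(g_pas=0.001)
        syn = place_synapses(kind="nmda", weight=1.8e-2, on_spine=True)
        cell = build_cell(m, syn, cfg, seed=0)
        trains = stimulus_trains(syn, "stack", 4.0, 6.0, 0.0, cfg, seed=0)
        _, v1 = simulate(cell, trains, dt=0.025)
        _, v2 = simulate(cell, trains, dt=0.0125)
        rms = np.sqrt(np.mean((v1 - v2[::2]) ** 2))
        assert rms < 0.1


class TestMatchedMismatch:
    def test_threshold_is_strict(self):
        v1 = np.array([0.0, 3.0, 5.9])
        v2 = np.array([0.0, 0.0, 3.0])
        m = matched_mismatch_split(v1, v2, threshold=3.0)
        assert m.tolist() == [True, False, True]


class TestCombinationExperiment:
    def test_small_signal_superposition(self):
        """With tiny weights, the stack deflection equals the sum of the
        single-tone deflections (shared component trains) within 5%."""
        m = Morphology()
        cfg = SimConfig(g_pas=0.001)
        syn = place_synapses(kind="ampa", weight=1e-6, on_spine=True)
        cell = build_cell(m, syn, cfg, seed=0)
        resp = {}
        for cond in ("f1", "f2", "stack"):
            trains = stimulus_trains(syn, cond, 4.0, 6.0, 0.0, cfg, seed=0)
            t, v = simulate(cell, trains)
            resp[cond] = _median_soma_psp(t, v) - cfg.e_pas
        assert resp["stack"] == pytest.approx(resp["f1"] + resp["f2"], rel=0.05)

    def test_mismatch_concentrates_on_side_peaks(self):
        """The two frequency channels are matched in strength at the main
        peak and mismatched at the side peaks."""
        from icxfreq.compartmental import reference_configurations

        cfg = reference_configurations()["quadratic"]
        r = combination_experiment(
            cfg["morph"], cfg["synapses"], cfg["config"], n_trials=4, seed=0
        )
        main = np.abs(r.itds) <= 60
        side = np.abs(r.itds) >= 140
        assert np.mean(~r.matched[side]) > np.mean(~r.matched[main])

    def test_clustering_makes_no_difference(self):
        """Clustered vs interleaved frequency placement: same class and
        V_stack curves within 1 mV RMS."""
        m = Morphology()
        out = {}
        for arr in ("interleaved", "clustered"):
            syn = place_synapses(kind="ampa", weight=2e-3, on_spine=True, arrangement=arr)
            out[arr] = combination_experiment(
                m, syn, SimConfig(g_pas=0.001), n_trials=4, seed=0
            )
        assert out["interleaved"].winner == out["clustered"].winner
        rms = np.sqrt(
            np.mean((out["interleaved"].v_stack - out["clustered"].v_stack) ** 2)
        )
        assert rms < 1.0

    def test_weight_sweep_never_reverts_to_linear(self):
        """Increasing synaptic weight increases saturation: once the
        classification leaves 'linear' it does not return."""
        m = Morphology()
        seen_nonlinear = False
        for w in (2e-4, 1e-3, 3e-3):
            syn = place_synapses(kind="ampa", weight=w, on_spine=True)
            r = combination_experiment(m, syn, SimConfig(g_pas=0.001), n_trials=4, seed=0)
            if r.winner in ("quadratic", "stack_sigmoid"):
                seen_nonlinear = True
            if seen_nonlinear:
                assert r.winner != "linear"
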