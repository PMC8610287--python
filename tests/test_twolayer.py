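"""Two-layer dendritic-subunit model and its parameter-space maps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from icxfreq.iccl import build_population
from icxfreq.twolayer import (
    DEFAULT_ITD_GRID,
    LinearNL,
    PowerNL,
    SigmoidNL,
    SpikingNL,
    SubunitSpec,
    TwoLayerNeuron,
    connection_weights,
    evaluate_subunit_curve,
    map_subunit_space,
    psp_itd_curve,
    sigmoid_subunit_feasibility,
    spike_rate,
    subunit_response,
)


class TestConnectionWeights:
    def test_peak_and_width(self, pop):
        sub = SubunitSpec(cf=5.0, sigma=0.7)
        w = connection_weights(sub, pop)
        j = int(np.argmin(np.abs(pop.bf - 5.0)))
        assert w[j] == pytest.approx(1.0)
        k = int(np.argmin(np.abs(pop.bf - 5.7)))
        assert w[k] == pytest.approx(np.exp(-0.5), rel=1e-9)

    def test_total_weight_grows_with_sigma(self, pop):
        sums = [
            connection_weights(SubunitSpec(cf=5.0, sigma=s), pop).sum()
            for s in (0.2, 0.5, 1.0, 2.0, 4.0)
        ]
        assert np.all(np.diff(sums) > 0)


class TestSubunitResponse:
    def test_power_identity_and_sqrt(self, pop):
        rates = np.full(len(pop), 0.5)
        sub1 = SubunitSpec(cf=5.0, sigma=1.0, nonlinearity=PowerNL(1.0))
        drive = float(rates @ connection_weights(sub1, pop))
        assert subunit_response(sub1, pop, rates) == pytest.approx(drive)
        sub2 = SubunitSpec(cf=5.0, sigma=1.0, nonlinearity=PowerNL(0.5))
        assert subunit_response(sub2, pop, rates) == pytest.approx(np.sqrt(drive))

    def test_sigmoid_midpoint(self, pop):
        nl = SigmoidNL(s0=2.0, s1=1.0, s2=0.25, s3=0.1)
        assert nl(np.array(0.25)) == pytest.approx(0.1 + 1.0)

    def test_negative_drive_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            PowerNL(2.0)(np.array([-0.1]))


class TestPspItdCurve:
    def test_linear_partition_equivalence(self, pop):
        """Any partition of the same total weights into linear subunits gives
        the same curve as the direct single weighted sum."""
        itds = DEFAULT_ITD_GRID
        rates = pop.rates(itds)
        total_w = connection_weights(SubunitSpec(cf=5.0, sigma=1.5), pop)
        direct = rates @ total_w
        # partition: ten identical subunits at a tenth of the weight each is
        # realized by ten subunits whose outputs sum linearly
        neuron = TwoLayerNeuron(
            subunits=tuple(
                SubunitSpec(cf=5.0, sigma=1.5, nonlinearity=LinearNL())
                for _ in range(10)
            )
        )
        curve = psp_itd_curve(neuron, pop, itds)
        assert np.allclose(curve.values, 10.0 * direct, atol=1e-10 * direct.max())

    def test_identical_power_subunits_scale(self, pop):
        itds = DEFAULT_ITD_GRID
        rates = pop.rates(itds)
        sub = SubunitSpec(cf=5.0, sigma=1.0, nonlinearity=PowerNL(2.0))
        drive = rates @ connection_weights(sub, pop)
        neuron = TwoLayerNeuron(subunits=tuple(sub for _ in range(10)))
        curve = psp_itd_curve(neuron, pop, itds)
        assert np.allclose(curve.values, 10.0 * drive**2, rtol=1e-12)

    def test_coarse_grid_warns(self, pop):
        neuron = TwoLayerNeuron(subunits=(SubunitSpec(cf=5.0, sigma=1.0),))
        coarse = np.arange(-250.0, 250.0 + 1e-9, 50.0)
        with pytest.warns(UserWarning, match="spacing"):
            psp_itd_curve(neuron, pop, coarse)

    def test_grid_must_include_zero(self, pop):
        neuron = TwoLayerNeuron(subunits=(SubunitSpec(cf=5.0, sigma=1.0),))
        with pytest.raises(ValueError, match="0 us"):
            psp_itd_curve(neuron, pop, np.arange(5.0, 500.0, 5.0))


class TestSpikeRate:
    def test_relu_threshold_and_affine(self):
        relu = SpikingNL(kind="relu", a0=1.0, a1=2.0)
        assert spike_rate(relu, -0.5) == 0.0
        assert spike_rate(relu, 3.0) == pytest.approx(7.0)

    def test_sigmoid_midpoint_and_threshold(self):
        sig = SpikingNL(kind="sigmoid", c0=10.0, c1=1.0, c2=0.0, alpha=-5.0)
        assert spike_rate(sig, 0.0) == pytest.approx(5.0)
        assert spike_rate(sig, -5.1) == 0.0

    @settings(max_examples=50, deadline=None)
    @given(
        a0=st.floats(-10, 10),
        a1=st.floats(0.01, 10),
        c0=st.floats(0.1, 50),
        c1=st.floats(0.01, 5),
        c2=st.floats(-70, -40),
        alpha=st.floats(-75, -45),
        data=st.data(),
    )
    def test_nondecreasing_in_v(self, a0, a1, c0, c1, c2, alpha, data):
        vs = np.sort(
            np.array(
                data.draw(
                    st.lists(st.floats(-90, -20), min_size=2, max_size=20)
                )
            )
        )
        for nl in (
            SpikingNL(kind="relu", a0=a0, a1=a1),
            SpikingNL(kind="sigmoid", c0=c0, c1=c1, c2=c2, alpha=alpha),
        ):
            rates = spike_rate(nl, vs)
            assert np.all(np.diff(rates) >= -1e-12)


@pytest.fixture(scope="module")
def small_map(pop):
    return map_subunit_space(
        pop,
        sigma_grid=np.array([0.5, 1.0, 2.0, 4.0]),
        power_grid=np.logspace(-1, 1, 7),
        cf_spreads=(0.0, 2.5),
    )


class TestMapSubunitSpace:
    def test_deterministic(self, pop, small_map):
        again = map_subunit_space(
            pop,
            sigma_grid=np.array([0.5, 1.0, 2.0, 4.0]),
            power_grid=np.logspace(-1, 1, 7),
            cf_spreads=(0.0, 2.5),
        )
        assert np.array_equal(small_map.sps_z, again.sps_z, equal_nan=True)
        assert np.array_equal(small_map.hw_z, again.hw_z, equal_nan=True)

    def test_sps_z_nondecreasing_in_sigma(self, small_map):
        """Broader frequency integration suppresses side peaks more."""
        for a in range(small_map.cf_spreads.size):
            for c in range(small_map.power_grid.size):
                col = small_map.sps_z[a, :, c]
                ok = ~np.isnan(col)
                assert np.all(np.diff(col[ok]) >= -1e-9)

    def test_long_frame_shape(self, small_map):
        df = small_map.to_frame()
        assert len(df) == 2 * 4 * 7
        assert set(df.columns) >= {"sigma_khz", "log10_power", "cf_spread_khz", "sps_z", "hw_z"}

    def test_grid_density_robustness(self):
        """Power-law z-scores barely move when the bf grid is twice as fine
        (drive rescaling cancels in the affine-invariant metrics)."""
        fine = build_population(bf_step=0.05)
        coarse = build_population(bf_step=0.1)
        args = dict(
            sigma_grid=np.array([1.0, 3.0]),
            power_grid=np.array([0.3, 1.0, 3.0]),
            cf_spreads=(0.0,),
        )
        zf = map_subunit_space(fine, **args)
        zc = map_subunit_space(coarse, **args)
        assert np.allclose(zf.sps_z, zc.sps_z, atol=0.1)
        assert np.allclose(zf.hw_z, zc.hw_z, atol=0.1)


class TestSigmoidFeasibility:
    def test_singleton_search_returns_it(self, pop):
        cand = SigmoidNL(s0=1.0, s1=0.08, s2=3.0, s3=0.0)
        best, score = sigmoid_subunit_feasibility(
            pop, sigma_grid=np.array([1.0, 2.0]), search_space=[cand]
        )
        assert best is cand
        assert np.isfinite(score)

    def test_empty_search_space_rejected(self, pop):
        with pytest.raises(ValueError, match="empty"):
            sigmoid_subunit_feasibility(pop, search_space=[])

    def test_near_linear_sigmoid_matches_power_one(self, pop):
        """A logistic that is locally linear over the drive range reproduces
        the p = 1 metrics."""
        sigma = 1.5
        _, _, z_sps_lin, z_hw_lin = evaluate_subunit_curve(
            pop, sigma, PowerNL(1.0)
        )
        flat = SigmoidNL(s0=1.0, s1=1e-4, s2=0.0, s3=0.0)
        _, _, z_sps_sig, z_hw_sig = evaluate_subunit_curve(pop, sigma, flat)
        assert z_sps_sig == pytest.approx(z_sps_lin, abs=1e-3)
        assert z_hw_sig == pytest.approx(z_hw_lin, abs=1e-3)
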