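"""Component metrics (amplitude, latency) and irradiance sensitivity."""

import math

import numpy as np
import pytest

from lightresp import (
    PSTH,
    BaselineStats,
    ResponseClass,
    RunConfig,
    StimulusProtocol,
    assign_components,
    component_amplitude,
    component_latency,
    compute_fine_psth,
    sensitivity_curve,
    simulate_sensitivity_series,
    simulate_unit,
    unit_metrics,
)
from lightresp.synthetic import default_archetype

BASE = BaselineStats(mean_hz=5.0, sd_hz=1.0, window_s=10.0)


def fine_psth(rate, t_start=0.0, bw=0.01):
    rate = np.asarray(rate, dtype=float)
    edges = t_start + bw * np.arange(len(rate) + 1)
    return PSTH(edges, rate, np.zeros_like(rate), n_trials=20)


def coarse_psth(rate, t_start=-1.0, bw=0.1):
    return fine_psth(rate, t_start, bw)


class TestAssignComponents:
    @pytest.mark.parametrize(
        "cls, expected",
        [
            (ResponseClass.ON, {"ON"}),
            (ResponseClass.ON_SUPPRESSED_BY_DARK, {"ON"}),
            (ResponseClass.ON_OFF, {"ON", "OFF"}),
            (ResponseClass.OFF, {"OFF"}),
            (ResponseClass.OFF_SUPPRESSED_BY_LIGHT, {"OFF"}),
            (ResponseClass.SLOW_SUSTAINED, set()),
            (ResponseClass.SUPPRESSED_ON, set()),
            (ResponseClass.SUPPRESSED_OFF, set()),
            (ResponseClass.SUPPRESSED_ON_OFF, set()),
            (ResponseClass.NON_LIGHT_RESPONSIVE, set()),
        ],
    )
    def test_component_membership(self, cls, expected):
        assert assign_components(cls) == frozenset(expected)


class TestComponentLatency:
    def test_peak_position_recovered(self):
        centers = 0.01 * np.arange(100) + 0.005
        rate = 5 + 15 * np.exp(-((centers - 0.32) ** 2) / (2 * 0.05**2))
        lat = component_latency(fine_psth(rate), 0.0, (0.0, 1.0))
        assert lat == pytest.approx(0.32, abs=0.011)

    def test_peak_in_first_bin_reports_bin_center(self):
        rate = np.zeros(100)
        rate[0] = 10.0
        lat = component_latency(fine_psth(rate), 0.0, (0.0, 1.0))
        assert lat == pytest.approx(0.005)

    def test_flat_window_is_missing(self):
        assert math.isnan(component_latency(fine_psth(np.full(100, 4.0)), 0.0, (0.0, 1.0)))

    def test_tie_breaks_to_earliest_bin(self):
        rate = np.zeros(100)
        rate[[30, 60]] = 7.0
        lat = component_latency(fine_psth(rate), 0.0, (0.0, 1.0))
        assert lat == pytest.approx(0.305)


class TestComponentAmplitude:
    def test_edge_to_peak_difference(self):
        rate = np.full(30, 5.0)
        rate[14] = 15.0  # window max; edge bin [0.0, 0.1) holds 5
        amp = component_amplitude(coarse_psth(rate), BASE, 0.0, (0.0, 1.0))
        assert amp == pytest.approx(10.0)

    def test_monotone_decay_from_edge_gives_zero(self):
        rate = np.concatenate([np.full(10, 5.0), np.linspace(12, 2, 20)])
        amp = component_amplitude(coarse_psth(rate), BASE, 0.0, (0.0, 1.0))
        assert amp == 0.0

    def test_invariant_to_additive_offset(self):
        rng = np.random.default_rng(0)
        rate = 5 + rng.uniform(0, 10, 30)
        a0 = component_amplitude(coarse_psth(rate), BASE, 0.0, (0.0, 1.0))
        a1 = component_amplitude(coarse_psth(rate + 7.5), BASE, 0.0, (0.0, 1.0))
        assert a1 == pytest.approx(a0)

    def test_baseline_reference_switch(self):
        rate = np.full(30, 5.0)
        rate[10] = 8.0  # edge bin itself elevated
        rate[15] = 20.0
        base = BaselineStats(mean_hz=5.0, sd_hz=1.0, window_s=10.0)
        edge_amp = component_amplitude(coarse_psth(rate), base, 0.0, (0.0, 1.0), "edge")
        base_amp = component_amplitude(coarse_psth(rate), base, 0.0, (0.0, 1.0), "baseline")
        assert edge_amp == pytest.approx(12.0)
        assert base_amp == pytest.approx(15.0)


class TestUnitMetrics:
    def test_on_unit_parameter_recovery(self, protocol, config):
        spec = default_archetype("ON", amplitude_hz=30.0)
        rng = np.random.default_rng(5)
        lat_err = []
        for _ in range(10):
            train = simulate_unit(spec, protocol, rng)
            (m,) = unit_metrics(train, ResponseClass.ON, protocol, config)
            lat_err.append(m.latency_s)
            assert m.amplitude_hz > 0
        # oracle: argmax of the smoothed generating profile
        fine_t = 0.005 + 0.01 * np.arange(100)
        from lightresp.synthetic import rate_profile
        from scipy.ndimage import gaussian_filter1d

        profile = gaussian_filter1d(
            rate_profile(spec, protocol, fine_t), 2.0, mode="nearest", truncate=3.0
        )
        t_star = fine_t[np.argmax(profile)]
        assert abs(np.mean(lat_err) - t_star) < 0.02

    def test_suppressed_classes_get_no_metrics(self, protocol, config):
        spec = default_archetype("SUPPRESSED_ON")
        train = simulate_unit(spec, protocol, 1)
        assert unit_metrics(train, ResponseClass.SUPPRESSED_ON, protocol, config) == []

    def test_on_off_unit_gets_both_components(self, protocol, config):
        spec = default_archetype("ON_OFF", amplitude_hz=30.0)
        train = simulate_unit(spec, protocol, 2)
        ms = unit_metrics(train, ResponseClass.ON_OFF, protocol, config)
        assert [m.component for m in ms] == ["OFF", "ON"] or [m.component for m in ms] == ["ON", "OFF"]


@pytest.fixture
def six_level_protocol():
    return StimulusProtocol(irradiance_levels=tuple(4.21e15 * 10.0**k for k in range(-5, 1)))


class TestSensitivityCurve:
    def test_silent_unit_excluded(self, six_level_protocol):
        from lightresp import SpikeTrain

        silent = SpikeTrain(trials=[np.empty(0)] * 20)
        curve = sensitivity_curve([silent] * 6, six_level_protocol)
        assert curve.included is False

    def test_graded_unit_included_and_recovered(self, six_level_protocol):
        spec = default_archetype("ON", baseline_hz=5.0, gain_profile=(0, 0, 1, 3, 6, 10))
        trains = simulate_sensitivity_series(spec, six_level_protocol, seed=11)
        curve = sensitivity_curve(trains, six_level_protocol)
        assert curve.included is True
        for delta, gain in zip(curve.delta_rate_hz, (0, 0, 1, 3, 6, 10)):
            assert delta == pytest.approx(gain, abs=2.0)

    def test_inclusion_decided_only_at_top_level(self, six_level_protocol):
        # responsive at level 4 of 6 but flat at the top level -> excluded
        spec = default_archetype("ON", gain_profile=(0, 0, 0, 20, 0, 0))
        trains = simulate_sensitivity_series(spec, six_level_protocol, seed=4)
        curve = sensitivity_curve(trains, six_level_protocol)
        assert curve.included is False
        assert curve.delta_rate_hz[3] > 10.0

    def test_top_only_gain_included_with_flat_lower_curve(self, six_level_protocol):
        spec = default_archetype("ON", gain_profile=(0, 0, 0, 0, 0, 25))
        trains = simulate_sensitivity_series(spec, six_level_protocol, seed=8)
        curve = sensitivity_curve(trains, six_level_protocol)
        assert curve.included is True
        assert max(abs(d) for d in curve.delta_rate_hz[:5]) < 2.0

    def test_missing_block_rejected(self, six_level_protocol):
        from lightresp import SpikeTrain

        silent = SpikeTrain(trials=[np.empty(0)] * 20)
        with pytest.raises(ValueError, match="6 irradiance"):
            sensitivity_curve([silent] * 5, six_level_protocol)
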