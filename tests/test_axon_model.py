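"""Axon morphology, cable dynamics and threshold physiology."""

import numpy as np
import pytest

from axonmetrics.axon import (AxonGeometryError, AxonModelSpec,
                              PulseWaveform, build_axon)
from axonmetrics.cable import (UnreachableThresholdError, adaptive_window,
                               find_threshold, simulate_axon, simulate_batch)
from axonmetrics.fh import FHKinetics
from axonmetrics.field_metrics import activating_function, pointwise_metrics
from axonmetrics.fibers import Fiber
from axonmetrics.pam import extracellular_drive, node_potentials_mv
from axonmetrics.volume_conductor import ContactSource, PointSourceField

from conftest import straight_fiber


class TestGeometry:
    def test_node_count_20mm_d2(self):
        f = straight_fiber(20.0, n_pts=201)
        g = build_axon(f, AxonModelSpec(diameter_um=2.0))
        assert g.n_nodes == 101  # internode 0.2 mm

    def test_node_count_20mm_d4(self):
        f = straight_fiber(20.0, n_pts=201)
        g = build_axon(f, AxonModelSpec(diameter_um=4.0))
        assert g.n_nodes == 51

    def test_too_short_fiber_rejected(self):
        f = straight_fiber(0.3, n_pts=4)
        with pytest.raises(AxonGeometryError):
            build_axon(f, AxonModelSpec(diameter_um=2.0))

    def test_internode_spacing_uniform(self):
        f = straight_fiber(17.3, n_pts=300)
        g = build_axon(f, AxonModelSpec(diameter_um=3.0))
        spacing = np.diff(g.node_arc_mm)
        np.testing.assert_allclose(spacing, 0.3, atol=1e-6)

    def test_chain_centred_on_midpoint(self):
        f = straight_fiber(20.0, n_pts=201)
        g = build_axon(f, AxonModelSpec(diameter_um=2.0))
        # odd node count: middle node exactly at mid-arc
        mid = g.node_arc_mm[g.n_nodes // 2]
        assert mid == pytest.approx(10.0, abs=1e-9)

    def test_waveform_window_floor(self):
        with pytest.raises(ValueError, match="3 ms"):
            PulseWaveform(pulse_width_us=60.0, sim_window_ms=1.0)

    def test_envelope_gates_pulse(self):
        wf = PulseWaveform(amplitude_scale=2.0, pulse_width_us=100.0,
                           onset_ms=0.1)
        t = np.array([0.0, 0.05, 0.1, 0.15, 0.2, 0.3])
        np.testing.assert_allclose(wf.envelope(t), [0, 0, 2, 2, 0, 0])


class TestMembraneKinetics:
    def test_rest_is_exact_equilibrium(self):
        kin = FHKinetics(temperature_c=37.0)
        g = kin.steady_gates(0.0)
        i = kin.ionic_current(np.asarray(0.0), g["m"], g["h"], g["n"],
                              g["p"], kin.rest_leak_reversal())
        assert abs(float(i)) < 1e-12

    def test_rates_positive_and_finite(self):
        kin = FHKinetics()
        v = np.linspace(-100, 150, 501)
        for a, b in kin.rates(v).values():
            assert np.all(np.isfinite(a)) and np.all(np.isfinite(b))
            assert np.all(a >= 0) and np.all(b >= 0)

    def test_sodium_activation_increases_with_depolarization(self):
        kin = FHKinetics()
        m_inf = [kin.steady_gates(v)["m"] for v in (0.0, 20.0, 60.0)]
        assert m_inf[0] < m_inf[1] < m_inf[2]


class TestCableDynamics:
    def test_resting_stability_zero_drive(self, fiber_x):
        spec = AxonModelSpec(diameter_um=3.0)
        geom = build_axon(fiber_x, spec)
        wf = PulseWaveform(amplitude_scale=0.0, pulse_width_us=60.0,
                           sim_window_ms=10.1)
        resp = simulate_axon(geom, spec, np.zeros(geom.n_nodes), wf)
        assert not resp.activated
        # peak stays within 1 mV of the -70 mV rest over 10 ms
        assert abs(resp.peak_membrane_potential_mv + 70.0) < 1.0

    def test_extracellular_drive_zero_amplitude(self, fiber_x,
                                                cathodic_field):
        spec = AxonModelSpec(diameter_um=3.0)
        geom = build_axon(fiber_x, spec)
        wf = PulseWaveform(amplitude_scale=0.0, pulse_width_us=60.0)
        ve = extracellular_drive(geom, cathodic_field, wf)
        assert np.all(ve == 0.0)

    def test_extracellular_drive_linear_in_current(self, fiber_x):
        spec = AxonModelSpec(diameter_um=3.0)
        geom = build_axon(fiber_x, spec)
        f1 = PointSourceField(sources=(ContactSource((0, 1, 0), -1.0),))
        f2 = PointSourceField(sources=(ContactSource((0, 1, 0), -2.0),))
        np.testing.assert_allclose(
            2.0 * node_potentials_mv(geom, f1),
            node_potentials_mv(geom, f2),
            rtol=1e-12,
        )

    def test_symmetric_bipolar_antisymmetric_profile(self, fiber_x):
        spec = AxonModelSpec(diameter_um=2.0)
        geom = build_axon(fiber_x, spec)
        field = PointSourceField(sources=(
            ContactSource((-2.0, 1.0, 0.0), 1.0),
            ContactSource((2.0, 1.0, 0.0), -1.0),
        ))
        ve = node_potentials_mv(geom, field)
        np.testing.assert_allclose(ve, -ve[::-1], atol=1e-9)

    def test_activation_above_not_below_threshold(
        self, fiber_x, cathodic_field, pulse_60us, threshold_cache
    ):
        spec = AxonModelSpec(diameter_um=3.0)
        geom = build_axon(fiber_x, spec)
        drive = node_potentials_mv(geom, cathodic_field)
        th = threshold_cache(3.0)
        from dataclasses import replace
        wf = adaptive_window(spec, fiber_x.length, pulse_60us)
        hot = simulate_axon(geom, spec, drive,
                            replace(wf, amplitude_scale=5.0 * th))
        cold = simulate_axon(geom, spec, drive,
                             replace(wf, amplitude_scale=0.5 * th))
        assert hot.activated and not cold.activated
        # AP overshoots 0 mV absolute
        assert hot.peak_membrane_potential_mv > 0.0

    def test_amplitude_monotonicity(self, fiber_x, cathodic_field,
                                    pulse_60us, threshold_cache):
        spec = AxonModelSpec(diameter_um=3.0)
        geom = build_axon(fiber_x, spec)
        drive = node_potentials_mv(geom, cathodic_field)
        th = threshold_cache(3.0)
        from dataclasses import replace
        wf = adaptive_window(spec, fiber_x.length, pulse_60us)
        ladder = [
            simulate_axon(geom, spec, drive,
                          replace(wf, amplitude_scale=a * th)).activated
            for a in (0.3, 0.7, 1.1, 2.0, 4.0)
        ]
        # once activated, stays activated at higher amplitude
        assert ladder == sorted(ladder)

    def test_batch_matches_single(self, fiber_x, cathodic_field, pulse_60us):
        spec = AxonModelSpec(diameter_um=3.0)
        geom = build_axon(fiber_x, spec)
        drive = node_potentials_mv(geom, cathodic_field)
        wf = adaptive_window(spec, fiber_x.length, pulse_60us)
        from dataclasses import replace
        wf = replace(wf, amplitude_scale=2.0)
        drives = np.stack([drive, 0.1 * drive, -drive])
        batch = simulate_batch(spec, drives, wf)
        singles = [simulate_axon(geom, spec, d, wf) for d in drives]
        for b, s in zip(batch, singles):
            assert b.activated == s.activated
            assert b.peak_membrane_potential_mv == pytest.approx(
                s.peak_membrane_potential_mv, abs=1e-9
            )

    def test_ap_initiation_near_activating_function_peak(
        self, fiber_x, cathodic_field, threshold_cache
    ):
        spec = AxonModelSpec(diameter_um=3.0)
        geom = build_axon(fiber_x, spec)
        drive = node_potentials_mv(geom, cathodic_field)
        th = threshold_cache(3.0)
        wf = PulseWaveform(amplitude_scale=1.05 * th, pulse_width_us=60.0)
        wf = adaptive_window(spec, fiber_x.length, wf)
        _, _, trace = simulate_batch(spec, drive[None, :], wf,
                                     return_trace=True)
        v = trace[:, 0, :]
        # first node to cross 0 mV absolute (+70 mV depolarization)
        crossed = np.argwhere(v >= 70.0)
        assert len(crossed) > 0
        first_t = crossed[:, 0].min()
        init_node = crossed[crossed[:, 0] == first_t][:, 1][0]
        series = pointwise_metrics(fiber_x, cathodic_field, step=0.3)
        af = activating_function(series)
        af_peak_arc = series.arc_positions[np.argmax(af)]
        init_arc = geom.node_arc_mm[init_node]
        assert abs(init_arc - af_peak_arc) <= 2 * 0.3 + 1e-9


class TestThresholds:
    def test_threshold_decreases_with_diameter(self, threshold_cache):
        th2, th3 = threshold_cache(2.0), threshold_cache(3.0)
        assert th3 < th2

    def test_threshold_decreases_with_pulse_width(self, threshold_cache):
        assert threshold_cache(3.0, 90.0) < threshold_cache(3.0, 30.0)

    def test_anodic_threshold_higher(self, threshold_cache):
        assert threshold_cache(3.0, anodic=True) > threshold_cache(3.0)

    def test_threshold_brackets_activation(self, fiber_x, cathodic_field,
                                           pulse_60us, threshold_cache):
        spec = AxonModelSpec(diameter_um=3.0)
        geom = build_axon(fiber_x, spec)
        drive = node_potentials_mv(geom, cathodic_field)
        th = threshold_cache(3.0)
        from dataclasses import replace
        wf = adaptive_window(spec, fiber_x.length, pulse_60us)
        assert simulate_axon(
            geom, spec, drive, replace(wf, amplitude_scale=th * 1.01)
        ).activated
        assert not simulate_axon(
            geom, spec, drive, replace(wf, amplitude_scale=th * 0.99)
        ).activated

    def test_unreachable_threshold(self, pulse_60us):
        f = straight_fiber(12.0, offset=(0.0, 30.0, 0.0))
        spec = AxonModelSpec(diameter_um=2.0)
        geom = build_axon(f, spec)
        field = PointSourceField(sources=(ContactSource((0, 0, 0), -1.0),))
        drive = node_potentials_mv(geom, field)
        with pytest.raises(UnreachableThresholdError):
            find_threshold(geom, spec, drive, pulse_60us,
                           bracket=(1e-3, 2.0))
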