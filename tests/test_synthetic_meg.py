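"""Synthetic-run generator: waveform morphology, event statistics,
propagation contract, determinism, and the noiseless-projection identity."""

import numpy as np
import pytest
from scipy import stats

from iedmap.containers import ConductorModel, EventSpec, PropagationSpec, Scenario
from iedmap.exceptions import ParameterError
from iedmap.synthetic_meg import (
    focal_spike_wave_scenario,
    propagating_burst_scenario,
    simulate_recording,
    synth_waveform,
)
from iedmap.forward import dipole_field


def _main_deflection_fwhm_ms(w, fs):
    peak = int(np.argmax(w))
    half = w[peak] / 2.0
    above = np.flatnonzero(w > half)
    runs = np.split(above, np.flatnonzero(np.diff(above) > 1) + 1)
    for r in runs:
        if r[0] <= peak <= r[-1]:
            return (r[-1] - r[0]) / fs * 1000.0
    raise AssertionError("no half-max run containing the peak")


class TestWaveforms:
    def test_spike_main_deflection_fwhm(self, rng):
        w = synth_waveform("spike_wave", 0.8, 1200.0, rng)
        assert abs(_main_deflection_fwhm_ms(w, 1200.0) - 70.0) <= 15.0

    def test_spike_has_unit_peak_and_slow_wave(self, rng):
        w = synth_waveform("spike_wave", 0.8, 1200.0, rng)
        assert np.max(np.abs(w)) == pytest.approx(1.0)
        assert w.min() < -0.1  # opposite-polarity slow wave present

    def test_polymorphic_bursts_differ_across_draws(self):
        r1, r2 = np.random.default_rng(1), np.random.default_rng(2)
        w1 = synth_waveform("polymorphic_burst", 0.4, 1200.0, r1)
        w2 = synth_waveform("polymorphic_burst", 0.4, 1200.0, r2)
        assert abs(np.corrcoef(w1, w2)[0, 1]) < 0.9

    def test_too_short_duration_rejected(self, rng):
        with pytest.raises(ParameterError):
            synth_waveform("spike_wave", 0.5 / 1200.0, 1200.0, rng)

    def test_unknown_kind_rejected(self, rng):
        with pytest.raises(ParameterError):
            synth_waveform("triangle", 0.5, 1200.0, rng)

    def test_burst_spec_must_resample(self):
        with pytest.raises(ParameterError):
            EventSpec(kind="polymorphic_burst", waveform_policy="fixed_template")


class TestSimulateRecording:
    def test_fixed_seed_bitwise_reproducible(self, sensors32, conductor):
        sc = focal_spike_wave_scenario(seed=3, duration=10.0)
        rec1, gt1 = simulate_recording(sc, sensors32, conductor)
        rec2, gt2 = simulate_recording(focal_spike_wave_scenario(seed=3, duration=10.0),
                                       sensors32, conductor)
        assert np.array_equal(rec1.data, rec2.data)
        assert gt1.event_intervals == gt2.event_intervals

    def test_event_count_within_poisson_99_interval(self, sensors32, conductor):
        sc = focal_spike_wave_scenario(seed=11, duration=120.0)
        _, gt = simulate_recording(sc, sensors32, conductor)
        lo, hi = stats.poisson.ppf([0.005, 0.995], 0.2 * 120.0)
        assert lo <= len(gt.event_intervals[0]) <= hi

    def test_noiseless_run_equals_projection(self, sensors32, conductor):
        """With zero noise the sensor data are exactly leadfield x source."""
        spec = EventSpec(kind="spike_wave", rate=0.3, duration=0.8, amplitude=40.0)
        pos = np.array([0.02, 0.035, 0.055])
        sc = Scenario(sources=[(pos, spec)], duration=20.0, fs=600.0, seed=5,
                      background_rms=0.0, sensor_noise_rms=0.0)
        rec, gt = simulate_recording(sc, sensors32, conductor)
        # reconstruct: the rank of the noiseless data must be 1 (one fixed
        # moment direction), and each channel proportional to the dipole field
        u, s, _ = np.linalg.svd(rec.data, full_matrices=False)
        assert s[1] <= 1e-10 * s[0]
        # the spatial pattern matches a tangential dipole at the true position
        from iedmap.forward import tangential_basis
        basis = tangential_basis(pos[None], conductor.center)[0]
        fields = np.stack([dipole_field(pos, basis[:, j], conductor, sensors32) for j in range(2)])
        resid = u[:, 0] - fields.T @ np.linalg.lstsq(fields.T, u[:, 0], rcond=None)[0]
        assert np.linalg.norm(resid) < 1e-10

    def test_ground_truth_intervals_sane(self, spike_run):
        rec, gt, scenario = spike_run
        gt.validate(scenario.duration)  # raises on overlap / out-of-bounds
        assert all(b > a for a, b in gt.event_intervals[0])

    def test_propagation_probability_one_links_every_event(self, sensors32, conductor):
        sc = propagating_burst_scenario(seed=2, duration=60.0)
        _, gt = simulate_recording(sc, sensors32, conductor)
        n_a = len(gt.event_intervals[0])
        assert n_a > 0
        assert len(gt.propagation_links) == n_a
        linked_a = sorted(a_evt for (src, a_evt), _ in gt.propagation_links)
        assert linked_a == list(range(n_a))

    def test_propagation_frequency_tracks_probability(self, sensors32, conductor):
        sc = propagating_burst_scenario(seed=9, duration=120.0, probability=0.5,
                                        b_solo_rate=0.0)
        _, gt = simulate_recording(sc, sensors32, conductor)
        n_a = len(gt.event_intervals[0])
        n_links = len(gt.propagation_links)
        lo, hi = stats.binom.ppf([0.005, 0.995], n_a, 0.5)
        assert lo <= n_links <= hi

    def test_source_outside_conductor_rejected(self, sensors32, conductor):
        spec = EventSpec(kind="spike_wave")
        sc = Scenario(sources=[(np.array([0.2, 0.0, 0.0]), spec)], duration=5.0, fs=600.0)
        from iedmap.exceptions import DomainError
        with pytest.raises(DomainError):
            simulate_recording(sc, sensors32, conductor)

    def test_background_noise_level_calibrated(self, sensors32, conductor):
        sc = focal_spike_wave_scenario(seed=4, duration=20.0)
        sc.sources = []  # background only
        rec, _ = simulate_recording(sc, sensors32, conductor)
        med = np.median(np.std(rec.data, axis=1))
        expected = np.hypot(sc.background_rms, sc.sensor_noise_rms)
        assert 0.5 * expected < med < 2.0 * expected
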