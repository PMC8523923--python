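"""Forward-model guarantees of the synthetic electrophysiology generator."""

import numpy as np
import pytest

from recruitpipe.core import ToneBurstSpec, ValidationError
from recruitpipe.synthgen import (
    CONTROL_THRESHOLD_DB,
    ScenarioConfig,
    control_amplitude_fn,
    control_scenario,
    gen_anow_epochs,
    gen_cap_epochs,
    gen_growth_series,
    hydropic_amplitude_fn,
    hydropic_scenario,
    inject_artifacts,
    simulate_cohort,
)


def _spec(**kw):
    base = dict(frequency=480.0, duration=25.0, rise_fall=0.0, level=60.0, n_repetitions=4)
    base.update(kw)
    return ToneBurstSpec(**base)


class TestAnowEpochs:
    def test_polarity_symmetry_pure_cm(self):
        """With no neural component and no noise, each +/− pair cancels."""
        sc = ScenarioConfig(cm_amplitude=10.0, noise_sigma=0.0,
                            neural_amplitude_fn=lambda L: 0.0)
        ep = gen_anow_epochs(_spec(), sc)
        pair_mean = ep.data.reshape(-1, 2, ep.n_samples).mean(axis=1)
        assert np.abs(pair_mean).max() == 0.0
        # and each epoch is a pure ±10 µV sinusoid at 480 Hz
        t = np.arange(ep.n_samples) / ep.sample_rate
        ref = 10.0 * np.sin(2 * np.pi * 480.0 * t)
        assert np.allclose(ep.data[0], ref, atol=1e-12)
        assert np.allclose(ep.data[1], -ref, atol=1e-12)

    def test_neural_only_single_spectral_line(self):
        """Noiseless neural-only epochs are identical with one line at 2f."""
        sc = ScenarioConfig(cm_amplitude=0.0, noise_sigma=0.0,
                            neural_amplitude_fn=lambda L: 1.0)
        ep = gen_anow_epochs(_spec(), sc)  # 25 ms = integer cycles of 960 Hz
        assert np.array_equal(ep.data[0], ep.data[1])
        spec_mag = np.abs(np.fft.rfft(ep.data[0])) * 2 / ep.n_samples
        k960 = int(round(960.0 * ep.n_samples / ep.sample_rate))
        assert spec_mag[k960] == pytest.approx(1.0, abs=1e-9)
        others = np.delete(spec_mag, k960)
        assert others.max() < 1e-9

    def test_seeded_generation_is_bit_reproducible(self):
        sc = control_scenario(seed=7)
        a = gen_anow_epochs(_spec(), sc)
        b = gen_anow_epochs(_spec(), sc)
        assert np.array_equal(a.data, b.data)

    def test_invalid_scenario_names_field(self):
        with pytest.raises(ValidationError, match="artifact_rate"):
            ScenarioConfig(artifact_rate=0.5)
        with pytest.raises(ValidationError, match="noise_sigma"):
            ScenarioConfig(noise_sigma=-1.0)

    @pytest.mark.parametrize(
        "field, value, match",
        [
            ("frequency", -5.0, "frequency"),
            ("rise_fall", 20.0, "rise_fall"),
            ("n_repetitions", 7, "n_repetitions"),
            ("sample_rate", 1000.0, "sample_rate"),
        ],
    )
    def test_invalid_stimulus_names_field(self, field, value, match):
        kw = {field: value}
        with pytest.raises(ValidationError, match=match):
            _spec(**kw)


class TestCapEpochs:
    def test_noiseless_trough_at_injected_latency(self):
        spec = ToneBurstSpec(frequency=3000.0, duration=13.9, rise_fall=1.0,
                             level=60.0, n_repetitions=4)
        sc = ScenarioConfig(cm_amplitude=0.0, noise_sigma=0.0,
                            cap_n1_amplitude_fn=lambda L: 5.0,
                            cap_n1_latency_fn=lambda L: 2.0)
        ep = gen_cap_epochs(spec, sc)
        wave = ep.data[0]
        t_min = np.argmin(wave) / ep.sample_rate * 1e3
        assert abs(t_min - 2.0) < 0.1
        assert wave.min() == pytest.approx(-5.0, rel=0.05)
        # silence appended: epoch is twice the burst duration
        assert ep.n_samples == int(round(2 * 13.9e-3 * 96000))

    def test_below_threshold_epochs_hold_only_noise(self):
        spec = ToneBurstSpec(frequency=3000.0, duration=13.9, rise_fall=1.0,
                             level=10.0, n_repetitions=4)
        sc = ScenarioConfig(cm_amplitude=0.0, noise_sigma=0.0)  # default fns: 0 below 20
        ep = gen_cap_epochs(spec, sc)
        assert np.abs(ep.data).max() == 0.0

    def test_seeded_runs_bit_identical(self, cap_spec):
        sc = ScenarioConfig(seed=3)
        assert np.array_equal(gen_cap_epochs(cap_spec, sc).data,
                              gen_cap_epochs(cap_spec, sc).data)


class TestInjectArtifacts:
    def test_rate_zero_is_identity(self):
        sc = ScenarioConfig(noise_sigma=1.0, seed=0)
        ep = gen_anow_epochs(_spec(), sc)
        out, locs = inject_artifacts(ep, rate=0.0, scale=50.0, sigma=1.0, seed=1)
        assert np.array_equal(out.data, ep.data)
        assert locs.shape == (0, 2)

    def test_exact_count_and_ground_truth_bookkeeping(self):
        sc = ScenarioConfig(noise_sigma=1.0, seed=0)
        ep = gen_anow_epochs(_spec(), sc)
        out, locs = inject_artifacts(ep, rate=0.01, scale=50.0, sigma=1.0, seed=1)
        expected = int(0.01 * ep.data.size)
        assert locs.shape == (expected, 2)
        changed = np.argwhere(out.data != ep.data)
        assert np.array_equal(np.sort(changed, axis=0), np.sort(locs, axis=0))
        deltas = np.abs(out.data[locs[:, 0], locs[:, 1]] - ep.data[locs[:, 0], locs[:, 1]])
        assert np.allclose(deltas, 50.0)

    def test_rate_out_of_range_rejected(self):
        sc = ScenarioConfig(noise_sigma=1.0)
        ep = gen_anow_epochs(_spec(), sc)
        with pytest.raises(ValidationError, match="artifact_rate"):
            inject_artifacts(ep, rate=0.3, scale=50.0, sigma=1.0, seed=0)


class TestGrowthShapes:
    def test_noiseless_log_linear_growth_gives_linear_db_series(self):
        sc = ScenarioConfig(noise_sigma=0.0,
                            neural_amplitude_fn=lambda L: 10.0 ** ((0.5 * L - 30) / 20))
        series = gen_growth_series(sc, np.arange(10.0, 81.0, 5.0))
        slopes = np.diff(series.response) / 5.0
        assert np.allclose(slopes, 0.5, atol=1e-9)

    def test_hydropic_and_control_converge_at_80_db(self):
        control = control_amplitude_fn()
        hydropic = hydropic_amplitude_fn(20.0)
        assert hydropic(80.0) == pytest.approx(control(80.0), rel=1e-12)
        # below its elevated threshold the impaired ear is silent
        assert hydropic(CONTROL_THRESHOLD_DB + 19.0) == 0.0
        assert control(CONTROL_THRESHOLD_DB + 19.0) > 0.0

    def test_default_hydropic_growth_rate_is_1_db_per_db(self):
        h = hydropic_amplitude_fn(20.0)
        levels = np.arange(45.0, 76.0, 5.0)
        db = 20 * np.log10([h(L) for L in levels])
        assert np.allclose(np.diff(db) / 5.0, 1.0, atol=1e-9)

    def test_levels_must_ascend(self):
        with pytest.raises(ValidationError, match="ascending"):
            gen_growth_series(control_scenario(), [10.0, 10.0, 20.0])


class TestCohort:
    def test_cohort_structure_and_determinism(self):
        ears = simulate_cohort(n_hydropic=2, n_control=1, seed=5)
        assert [e.group for e in ears] == ["hydropic", "hydropic", "control"]
        assert all(e.threshold_shift == 0 for e in ears if e.group == "control")
        ears2 = simulate_cohort(n_hydropic=2, n_control=1, seed=5)
        s1 = ears[0].series["480"]
        s2 = ears2[0].series["480"]
        assert np.array_equal(s1.response, s2.response)
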