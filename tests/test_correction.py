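import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qcmcorrect.correction import (
    StreamCorrector,
    correct_pair,
    correct_pair_streamed,
    derivative,
    integrate,
    project_and_cancel,
    windowed_correlation,
)
from qcmcorrect.signal_model import CorrectionParams, PairedRecord, ResonatorTrace
from qcmcorrect.synthetic import BindingStep, DriftSpec, SimConfig, simulate_pair
from qcmcorrect.wavelet_engine import dwt_decompose, idwt_reconstruct, threshold_for_params


class TestDerivativeIntegrate:
    def test_first_difference_example(self):
        np.testing.assert_array_equal(derivative([1.0, 3.0, 6.0]), [2.0, 3.0])

    def test_constant_series_derivative_is_zero(self):
        np.testing.assert_array_equal(derivative(np.full(10, 4.2)), np.zeros(9))

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            derivative([1.0])

    def test_integrate_example(self):
        np.testing.assert_array_equal(integrate([2.0, 3.0], 1.0), [1.0, 3.0, 6.0])
        np.testing.assert_array_equal(integrate(np.zeros(4), 0.0), np.zeros(5))

    def test_integer_telescoping_is_exact(self):
        s = np.array([3.0, -1.0, 4.0, 1.0, -5.0, 9.0])
        np.testing.assert_array_equal(integrate(derivative(s), s[0]), s)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=100), st.floats(-10, 10))
    def test_round_trips(self, data, initial):
        s = np.asarray(data)
        np.testing.assert_allclose(integrate(derivative(s), s[0]), s, atol=1e-12 * max(1, np.max(np.abs(s))))
        zd = np.asarray(data[:-1])
        np.testing.assert_allclose(derivative(integrate(zd, initial)), zd, atol=1e-12)


class TestWindowedCorrelation:
    def test_self_correlation(self, rng):
        xd = rng.standard_normal(200)
        tr = windowed_correlation(xd, xd, 32)
        assert np.all(tr.R[tr.defined] == pytest.approx(1.0))
        assert np.all(tr.P[tr.defined] < 1e-12)

    def test_anti_correlation(self, rng):
        xd = rng.standard_normal(200)
        tr = windowed_correlation(xd, -xd, 32)
        assert np.all(tr.R[tr.defined] == pytest.approx(-1.0))

    def test_zero_variance_flagged_not_numeric(self, rng):
        xd = rng.standard_normal(64)
        tr = windowed_correlation(xd, np.zeros(64), 32)
        assert not tr.defined.any()
        assert np.isnan(tr.R).all() and np.isnan(tr.P).all()

    def test_length_preconditions(self, rng):
        with pytest.raises(ValueError):
            windowed_correlation(rng.standard_normal(10), rng.standard_normal(11), 8)
        with pytest.raises(ValueError):
            windowed_correlation(rng.standard_normal(10), rng.standard_normal(10), 16)

    def test_bounds_where_defined(self, rng):
        xd, yd = rng.standard_normal(300), rng.standard_normal(300)
        tr = windowed_correlation(xd, yd, 32)
        assert np.all(np.abs(tr.R[tr.defined]) <= 1.0)
        assert np.all((tr.P[tr.defined] >= 0.0) & (tr.P[tr.defined] <= 1.0))

    def test_null_false_positive_rate_calibrated(self):
        """On independent white noise the t-test should flag ~alpha of the
        windows: Monte-Carlo estimate within 0.05 +/- 0.02."""
        fracs = []
        for seed in range(30):
            r = np.random.default_rng(seed)
            tr = windowed_correlation(r.standard_normal(1031), r.standard_normal(1031), 32)
            fracs.append(np.mean(tr.P[tr.defined] < 0.05))
        assert np.mean(fracs) == pytest.approx(0.05, abs=0.02)


class TestProjectAndCancel:
    def test_exact_linear_relation_cancelled(self, rng):
        yd = rng.standard_normal(200)
        xd = 2.0 + 3.0 * yd
        tr = windowed_correlation(xd, yd, 32)
        z = project_and_cancel(xd, yd, tr, 0.05)
        sig = tr.defined & (tr.P < 0.05)
        assert sig.any()
        assert np.max(np.abs(z[sig])) < 1e-9 * np.max(np.abs(xd))

    def test_zero_reference_passes_sensor_through(self, rng):
        xd = rng.standard_normal(100)
        yd = np.zeros(100)
        tr = windowed_correlation(xd, yd, 32)
        np.testing.assert_array_equal(project_and_cancel(xd, yd, tr, 0.05), xd)

    def test_projection_beats_direct_subtraction_under_gain_mismatch(self):
        """With a gain-1.3 common random walk, the projection residual
        tracks the small independent signal better than naive channel
        subtraction (Monte-Carlo, >= 95/100 seeds)."""
        wins = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            c = np.cumsum(r.standard_normal(800))
            sig = 0.3 * np.sin(2 * np.pi * np.arange(800) / 37.0)
            xd = np.diff(1.3 * c + sig)
            yd = np.diff(c)
            tr = windowed_correlation(xd, yd, 32)
            z = project_and_cancel(xd, yd, tr, 0.05)
            sd = np.diff(sig)
            wins += np.mean((z - sd) ** 2) < np.mean((xd - yd - sd) ** 2)
        assert wins >= 95


class TestCorrectPair:
    def test_zero_reference_yields_denoised_sensor(self, rng, default_params):
        x = np.cumsum(rng.standard_normal(1000))
        sensor = ResonatorTrace(x, 3.0)
        pair = PairedRecord(sensor, ResonatorTrace(np.zeros(1000), 3.0))
        z = correct_pair(pair, default_params)
        denoised = idwt_reconstruct(
            threshold_for_params(dwt_decompose(sensor, default_params), default_params)
        )
        np.testing.assert_allclose(z.values, denoised.values, atol=1e-9 * max(1, np.max(np.abs(x))))

    def test_identical_channels_fully_rejected(self, rng, default_params):
        x = np.cumsum(rng.standard_normal(2000)) + 5 * np.sin(np.arange(2000) / 30.0)
        pair = PairedRecord(ResonatorTrace(x, 3.0), ResonatorTrace(x.copy(), 3.0))
        z = correct_pair(pair, default_params).values
        assert np.max(np.abs(z - z[0])) < 1e-6 * max(1.0, np.max(np.abs(x)))

    def test_output_metadata_matches_sensor(self, default_params):
        pair, _ = simulate_pair(SimConfig(duration_s=600.0, seed=0))
        z = correct_pair(pair, default_params)
        assert len(z) == len(pair)
        assert z.sample_rate == pair.sample_rate
        assert z.channel_kind == "frequency"

    def test_binding_plateau_recovered_under_common_ramp(self):
        """Parameter-recovery oracle: a -3681 Hz saturating step (tau 300 s)
        riding a 200 Hz/h common ramp (reference gain 1.2, 2 Hz noise per
        channel) is recovered within 5% of truth."""
        errs = []
        for seed in range(3):
            cfg = SimConfig(
                duration_s=3600.0,
                drift=DriftSpec(rate_hz_per_h=200.0, walk_sd=0.0),
                gain_mismatch=1.2,
                binding_steps=(BindingStep(600.0, -3681.0, 300.0),),
                seed=seed,
            )
            pair, _ = simulate_pair(cfg)
            z = correct_pair(pair)
            t = pair.sensor.times
            base = z.values[(t > 300) & (t < 590)].mean()
            plateau = z.values[(t > 2700) & (t < 3300)].mean() - base
            errs.append(abs(plateau - (-3681.0)) / 3681.0)
        assert np.median(errs) < 0.05

    def test_gain_robustness_of_plateau_recovery(self):
        """The projection absorbs reference-response gain mismatch: the
        recovered step amplitude stays within 5% for gains 0.5-2."""
        for gain in (0.5, 1.0, 2.0):
            cfg = SimConfig(
                duration_s=3600.0,
                drift=DriftSpec(rate_hz_per_h=200.0, walk_sd=0.0),
                gain_mismatch=gain,
                binding_steps=(BindingStep(600.0, -3681.0, 300.0),),
                seed=7,
            )
            pair, _ = simulate_pair(cfg)
            z = correct_pair(pair)
            t = pair.sensor.times
            base = z.values[(t > 300) & (t < 590)].mean()
            plateau = z.values[(t > 2700) & (t < 3300)].mean() - base
            assert abs(plateau - (-3681.0)) / 3681.0 < 0.05

    def test_common_mode_disturbance_rejected(self):
        """Adding one shared smooth disturbance to both channels moves the
        output by well under 5% of the disturbance RMS."""
        from dataclasses import replace

        from qcmcorrect.synthetic import quiescent_config

        ratios = []
        for seed in range(3):
            cfg = replace(quiescent_config(seed=seed), gain_mismatch=1.0)
            pair, _ = simulate_pair(cfg)
            z0 = correct_pair(pair).values
            t = pair.sensor.times
            dist = 200.0 * np.sin(2 * np.pi * t / 300.0)
            shifted = PairedRecord(
                pair.sensor.with_values(pair.sensor.values + dist),
                pair.reference.with_values(pair.reference.values + dist),
            )
            z1 = correct_pair(shifted).values
            ratios.append(np.sqrt(np.mean((z1 - z0) ** 2) / np.mean(dist**2)))
        assert np.median(ratios) < 0.05

    def test_dissipation_channel_obeys_same_contract(self):
        """The algorithm is channel-agnostic: on a dissipation pair it
        removes most of the shared distortion while keeping the binding
        step visible."""
        from qcmcorrect.synthetic import adsorption_config

        pair, truth = simulate_pair(adsorption_config(seed=0), channel_kind="dissipation")
        z = correct_pair(pair)
        assert z.channel_kind == "dissipation"
        t = pair.sensor.times
        win_b, win_p = (t > 300) & (t < 590), (t > 2500) & (t < 3500)
        step = lambda v: v[win_p].mean() - v[win_b].mean()
        truth_step = step(truth.binding_sensor)
        raw_err = abs(step(pair.sensor.values) - truth_step)
        cor_err = abs(step(z.values) - truth_step)
        assert cor_err < 0.25 * abs(truth_step)
        assert cor_err < 0.25 * raw_err


class TestStreaming:
    def test_single_block_identical_to_batch(self, structured_pair):
        params = CorrectionParams()
        batch = correct_pair(structured_pair, params).values
        n = len(structured_pair)
        sc = StreamCorrector(params, block_length=n + 64, overlap=2048)
        out = sc.push(structured_pair.sensor.values, structured_pair.reference.values)
        out = np.concatenate([out, sc.finish()])
        np.testing.assert_array_equal(out, batch)

    def test_two_blocks_interior_matches_batch(self, structured_pair):
        batch = correct_pair(structured_pair).values
        streamed = correct_pair_streamed(structured_pair, block_length=8192, overlap=2048).values
        assert streamed.size == batch.size
        scale = np.ptp(batch)
        assert np.max(np.abs(streamed - batch)) < 1e-3 * scale

    def test_constant_pair_streams_to_constant(self):
        n = 9000
        pair = PairedRecord(
            ResonatorTrace(np.full(n, 3.0), 3.0), ResonatorTrace(np.full(n, 3.0), 3.0)
        )
        out = correct_pair_streamed(pair, block_length=6400, overlap=2048).values
        assert out.size == n
        assert np.max(np.abs(out - out[0])) < 1e-9

    def test_configuration_validation(self):
        with pytest.raises(ValueError, match="block_length"):
            StreamCorrector(CorrectionParams(), block_length=100, overlap=10)
        with pytest.raises(ValueError, match="overlap"):
            StreamCorrector(CorrectionParams(), block_length=4096, overlap=100)
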