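"""Decoding chain: filter response, windowing, CSP vs brute-force
eigendecomposition, LDA closed form, action power, triggers, CV."""

import numpy as np
import pytest
from scipy import linalg, signal

from gazebmi.eeg_decoding import (
    CSP,
    ActionPowerCalibration,
    BandpassSpec,
    DecodingError,
    MotorImageryDecoder,
    WindowSpec,
    action_power,
    bandpass_filter,
    crossvalidate,
    decode_stream,
    extract_features,
    fit_csp,
    fit_lda,
    slide_windows,
)
from gazebmi.synthetic_data import (
    MOTOR_IMAGERY,
    REST,
    EEGSession,
    SynthEEGConfig,
    TrialSchedule,
    generate_eeg_stream,
    generate_training_session,
)


def _session_from_array(data, fs=128.0):
    sched = TrialSchedule(labels=(REST,), onsets_s=(0.0,), task_duration_s=data.shape[1] / fs)
    return EEGSession(data=data, fs=fs, schedule=sched)


class TestBandpass:
    def test_zero_in_zero_out(self):
        s = _session_from_array(np.zeros((3, 512)))
        out = bandpass_filter(s)
        assert np.all(out.data == 0.0)
        assert out.data.shape == (3, 512)

    @pytest.mark.parametrize("freq,lo,hi", [(10.0, 0.7, 1.0), (50.0, 0.0, 0.05)])
    def test_steady_state_gain_matches_frequency_response_oracle(self, freq, lo, hi):
        """Measured sine gain agrees with the designed filter's transfer
        function evaluated independently via sosfreqz."""
        fs = 128.0
        spec = BandpassSpec()
        w, h = signal.sosfreqz(spec.sos(fs), worN=[2 * np.pi * freq / fs])
        oracle_gain = float(np.abs(h[0]))
        t = np.arange(int(8 * fs)) / fs
        s = _session_from_array(np.sin(2 * np.pi * freq * t)[None, :], fs)
        out = bandpass_filter(s, spec).data[0]
        measured = np.abs(out[len(out) // 2:]).max()  # steady-state half
        assert lo <= measured <= hi
        assert measured == pytest.approx(oracle_gain, rel=0.05, abs=1e-6)

    def test_band_above_nyquist_rejected(self):
        s = _session_from_array(np.zeros((1, 256)), fs=20.0)
        with pytest.raises(DecodingError):
            bandpass_filter(s, BandpassSpec(band=(8.0, 12.0)))


class TestWindows:
    @pytest.mark.parametrize("n_samples,expected", [(512, 49), (128, 1), (64, 0)])
    def test_window_count_formula(self, n_samples, expected):
        w, t = slide_windows(np.zeros((2, n_samples)), 128.0)
        assert len(w) == expected
        if expected:
            assert w.shape[1:] == (2, 128)

    def test_stride_and_end_times(self):
        data = np.arange(512)[None, :].astype(float)
        w, t = slide_windows(data, 128.0)
        assert w[1, 0, 0] - w[0, 0, 0] == 8  # 62.5 ms steps
        assert t[0] == pytest.approx(1.0)
        assert np.allclose(np.diff(t), 0.0625)


def _epochs_with_variance_contrast(rng, n=20, n_ch=4, n_s=256, boosted_channel=2, factor=4.0):
    rest = rng.standard_normal((n, n_ch, n_s))
    mi = rng.standard_normal((n, n_ch, n_s))
    mi[:, boosted_channel] *= factor
    return rest, mi


class TestCSP:
    def test_matches_bruteforce_generalized_eig_oracle(self, rng):
        """CSP filters reproduce a direct scipy.linalg.eigh solution of the
        two-covariance generalized eigenproblem to 6 decimals."""
        rest, mi = _epochs_with_variance_contrast(rng)
        csp = fit_csp(rest, mi, n_pairs=2)

        def avg_cov(eps):
            covs = [e @ e.T / np.trace(e @ e.T) for e in eps]
            c = np.mean(covs, axis=0)
            return c + 1e-6 * np.trace(c) / c.shape[0] * np.eye(c.shape[0])

        c_rest, c_mi = avg_cov(rest), avg_cov(mi)
        evals, _ = linalg.eigh(c_mi, c_rest + c_mi)
        oracle = np.sort(evals)[::-1]
        got = np.sort(csp.eigenvalues_)[::-1]
        assert np.allclose(got, np.r_[oracle[:2], oracle[-2:]], atol=1e-6)
        # the MI-extreme filter concentrates on the boosted channel
        top = csp.filters_[int(np.argmax(csp.eigenvalues_))]
        assert np.argmax(np.abs(top)) == 2

    def test_whitening_invariant(self, rng):
        rest, mi = _epochs_with_variance_contrast(rng)
        csp = fit_csp(rest, mi, n_pairs=2)
        gram = csp.filters_ @ csp.pooled_covariance_ @ csp.filters_.T
        assert np.allclose(gram, np.eye(len(gram)), atol=1e-6)

    def test_eigenvalue_complementarity(self, rng):
        """Per filter, the rest-class and MI-class variance ratios sum to 1."""
        rest, mi = _epochs_with_variance_contrast(rng)
        csp = fit_csp(rest, mi, n_pairs=2)

        def avg_cov(eps):
            covs = [e @ e.T / np.trace(e @ e.T) for e in eps]
            c = np.mean(covs, axis=0)
            return c + 1e-6 * np.trace(c) / c.shape[0] * np.eye(c.shape[0])

        c_rest, c_mi = avg_cov(rest), avg_cov(mi)
        pooled = c_rest + c_mi
        lam_mi = np.einsum("fi,ij,fj->f", csp.filters_, c_mi, csp.filters_)
        lam_rest = np.einsum("fi,ij,fj->f", csp.filters_, c_rest, csp.filters_)
        denom = np.einsum("fi,ij,fj->f", csp.filters_, pooled, csp.filters_)
        assert np.allclose(lam_mi / denom + lam_rest / denom, 1.0, atol=1e-8)

    def test_identical_covariances_give_half_eigenvalues(self, rng):
        eps = rng.standard_normal((30, 4, 512))
        csp = fit_csp(eps[:15], eps[15:], n_pairs=2)
        assert np.allclose(csp.eigenvalues_, 0.5, atol=0.05)

    def test_default_session_whitening(self, default_session):
        from gazebmi.eeg_decoding import _labeled_task_epochs

        filtered = bandpass_filter(default_session)
        epochs, labels = _labeled_task_epochs(filtered)
        csp = CSP(n_pairs=3).fit(epochs, labels)
        gram = csp.filters_ @ csp.pooled_covariance_ @ csp.filters_.T
        assert np.allclose(gram, np.eye(6), atol=1e-6)


class TestFeatures:
    def test_scale_invariance(self, rng):
        rest, mi = _epochs_with_variance_contrast(rng)
        csp = fit_csp(rest, mi, n_pairs=2)
        w = rng.standard_normal((4, 128))
        assert np.allclose(extract_features(w, csp), extract_features(10.0 * w, csp))

    def test_hand_computed_log_variance(self):
        """2-filter identity CSP on a 2-channel, 4-sample window matches
        pencil-and-paper normalised log-variance."""
        csp = CSP(n_pairs=1)
        csp.filters_ = np.eye(2)
        csp.eigenvalues_ = np.array([1.0, 0.0])
        csp.class_order_ = (REST, MOTOR_IMAGERY)
        w = np.array([[1.0, -1.0, 1.0, -1.0], [2.0, -2.0, 2.0, -2.0]])
        v1, v2 = 1.0, 4.0
        expected = np.log(np.array([v1, v2]) / (v1 + v2))
        assert np.allclose(extract_features(w, csp), expected)

    def test_zero_variance_window_rejected(self):
        csp = CSP(n_pairs=1)
        csp.filters_ = np.eye(2)
        with pytest.raises(DecodingError):
            extract_features(np.ones((2, 8)), csp)


class TestLDA:
    def test_two_gaussian_closed_form_boundary(self, rng):
        """1-D equal-variance classes: the decision boundary sits at the
        midpoint of the class means (closed-form Fisher solution)."""
        mu_a, mu_b, sd = -2.0, 3.0, 1.0
        a = rng.normal(mu_a, sd, 4000)[:, None]
        b = rng.normal(mu_b, sd, 4000)[:, None]
        X = np.vstack([a, b])
        y = np.array([REST] * 4000 + [MOTOR_IMAGERY] * 4000, dtype=object)
        model = fit_lda(X, y)
        boundary = -model.bias / model.weights[0]
        assert boundary == pytest.approx((mu_a + mu_b) / 2, abs=0.1)
        assert model.score(np.array([[10.0]]))[0] > 0  # positive toward MI

    def test_label_swap_negates_score(self, rng):
        X = rng.standard_normal((200, 3))
        y = np.array([REST, MOTOR_IMAGERY] * 100, dtype=object)
        y_sw = np.where(y == REST, MOTOR_IMAGERY, REST)
        m1, m2 = fit_lda(X, y), fit_lda(X, y_sw)
        assert np.allclose(m1.score(X), -m2.score(X), atol=1e-8)

    def test_equal_means_near_chance(self, rng):
        X = rng.standard_normal((400, 2))
        y = np.array([REST, MOTOR_IMAGERY] * 200, dtype=object)
        model = fit_lda(X, y)
        acc = np.mean((model.score(X) > 0) == (y == MOTOR_IMAGERY))
        assert 0.4 <= acc <= 0.6


class TestActionPower:
    def test_boundary_and_saturation(self):
        calib = ActionPowerCalibration(scale=1.0)
        assert action_power(0.0, calib) == pytest.approx(0.5)
        assert action_power(50.0, calib) == pytest.approx(1.0, abs=1e-9)
        assert action_power(-50.0, calib) == pytest.approx(0.0, abs=1e-9)

    def test_monotone_over_score_grid(self):
        calib = ActionPowerCalibration(scale=2.0)
        grid = np.linspace(-10, 10, 401)
        out = action_power(grid, calib)
        assert np.all(np.diff(out) >= 0)
        assert np.all((out >= 0) & (out <= 1))


class TestDecodeStream:
    def test_strict_threshold_rule(self, default_session):
        """TriggerEvents are exactly the windows with action power
        strictly above threshold."""
        decoder = MotorImageryDecoder().fit(default_session)
        stream = generate_eeg_stream(SynthEEGConfig(seed=8),
                                     [(MOTOR_IMAGERY, 4.0), (REST, 4.0)])
        outputs, triggers = decode_stream(stream, decoder)
        expected = [o.t_s for o in outputs if o.action_power > decoder.threshold]
        assert [t.t_s for t in triggers] == expected
        for o in outputs:
            assert o.state == (MOTOR_IMAGERY if o.action_power > decoder.threshold else REST)

    def test_trigger_rates_on_rest_and_strong_mi(self):
        cfg = SynthEEGConfig(seed=11)
        decoder = MotorImageryDecoder().fit(generate_training_session(cfg, 20))
        rest = generate_eeg_stream(cfg, [(REST, 20.0)], rng=np.random.default_rng(1))
        outs, trig = decoder.decode(rest)
        assert len(trig) / len(outs) < 0.20

        strong = SynthEEGConfig(seed=12, erd_depth=0.9, noise_sigma=0.1)
        dec2 = MotorImageryDecoder().fit(generate_training_session(strong, 20))
        mi = generate_eeg_stream(strong, [(MOTOR_IMAGERY, 20.0)], rng=np.random.default_rng(2))
        outs2, trig2 = dec2.decode(mi)
        assert len(trig2) / len(outs2) > 0.80

    def test_channel_mismatch_rejected(self, default_session):
        decoder = MotorImageryDecoder().fit(default_session)
        bad = generate_eeg_stream(SynthEEGConfig(n_channels=8, modulated_channels=(2, 3),
                                                 seed=0), [(REST, 2.0)])
        with pytest.raises(DecodingError):
            decoder.decode(bad)

    def test_model_json_roundtrip(self, default_session):
        import json

        decoder = MotorImageryDecoder().fit(default_session)
        stream = generate_eeg_stream(SynthEEGConfig(seed=13), [(MOTOR_IMAGERY, 3.0)])
        restored = MotorImageryDecoder.from_dict(json.loads(json.dumps(decoder.to_dict())))
        o1, _ = decoder.decode(stream)
        o2, _ = restored.decode(stream)
        assert np.allclose([o.action_power for o in o1], [o.action_power for o in o2])


class TestCrossValidation:
    def test_chance_level_without_erd(self):
        sess = generate_training_session(SynthEEGConfig(seed=3, erd_depth=0.0), 20)
        cv = crossvalidate(sess, k=5, seed=3)
        assert 0.40 <= cv.accuracy_total <= 0.60

    def test_default_session_beats_human_aggregate(self, default_session):
        cv = crossvalidate(default_session, k=5, seed=42)
        assert cv.accuracy_total >= 0.8516

    def test_fold_hygiene(self, default_session):
        """Replacing the test-fold trials by noise must not change the
        models fitted on the training folds (no leakage)."""
        from gazebmi.eeg_decoding import _labeled_task_epochs

        filtered = bandpass_filter(default_session)
        epochs, labels = _labeled_task_epochs(filtered)
        rng = np.random.default_rng(0)
        fold = [0, 1, 2, 3]
        train = np.setdiff1d(np.arange(len(labels)), fold)
        csp_a = CSP(n_pairs=3).fit(epochs[train], labels[train])
        corrupted = epochs.copy()
        corrupted[fold] = rng.standard_normal(corrupted[fold].shape)
        csp_b = CSP(n_pairs=3).fit(corrupted[train], labels[train])
        assert np.array_equal(csp_a.filters_, csp_b.filters_)

    def test_k_too_small_rejected(self, default_session):
        with pytest.raises(DecodingError):
            crossvalidate(default_session, k=1)
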