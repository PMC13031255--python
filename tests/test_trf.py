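"""Temporal response function: design construction, ridge, CV, ablation."""

import numpy as np
import pytest
from scipy import stats

from compslide.simulate import (
    WordEvent,
    make_participant,
    simulate_surprisal_story,
    simulate_trf_subject,
)
from compslide.trf import (
    FEATURES,
    SURPRISAL_FEATURES,
    AnnotationSet,
    DegenerateDataError,
    LagWindow,
    TemporalResponseModel,
    ablation_compare,
    build_annotation_vectors,
    build_lagged_design,
    concatenate_sessions,
    crossval_trf,
    kernel_peak_latency,
    ridge_fit,
)


def _simple_events(onsets, surprisals, chunk=None):
    out = []
    for i, (t, s) in enumerate(zip(onsets, surprisals)):
        kw = {}
        if chunk is not None:
            kw = {"chunk_index": chunk[i][0], "chunk_level": chunk[i][1]}
        out.append(WordEvent(word=f"w{i}", onset_s=t, surprisal=s, **kw))
    return out


class TestBuildAnnotationVectors:
    def test_alternating_story_onset_counts(self):
        events = simulate_surprisal_story(n_chunks=4, words_per_chunk=10, seed=0)
        n = int(events[-1].onset_s * 100) + 200
        ann = build_annotation_vectors(events, n, fs=100.0, rate=1.0)
        assert ann.channel("low_surprisal_onset").sum() == 2
        assert ann.channel("high_surprisal_onset").sum() == 2
        assert ann.channel("segment_onset")[0] == 1.0
        assert ann.channel("rate_x1_onset")[0] == 1.0
        assert ann.channel("rate_x2p5_onset").sum() == 0.0

    def test_word_impulse_index_arithmetic(self):
        events = _simple_events([1.000], [4.2])
        ann = build_annotation_vectors(events, 500, fs=250.0, rate=2.5)
        chan = ann.channel("word_surprisal")
        assert chan[250] == pytest.approx(4.2)
        assert np.count_nonzero(chan) == 1

    def test_colliding_words_sum_surprisal(self, caplog):
        events = _simple_events([1.000, 1.001], [2.0, 3.0])
        with caplog.at_level("WARNING", logger="compslide.trf"):
            ann = build_annotation_vectors(events, 500, fs=250.0)
        assert ann.channel("word_surprisal")[250] == pytest.approx(5.0)
        assert any("summed" in r.message for r in caplog.records)

    def test_event_beyond_trace_end_named(self):
        events = _simple_events([3.0], [1.0])
        with pytest.raises(IndexError, match="w0"):
            build_annotation_vectors(events, 100, fs=100.0)

    def test_unknown_rate_rejected(self):
        with pytest.raises(ValueError):
            build_annotation_vectors([], 100, fs=100.0, rate=3.0)


class TestConcatenateSessions:
    @staticmethod
    def _pair(n, fs=50.0):
        chan = np.zeros((6, n))
        chan[3, 0] = 1.0
        return np.random.default_rng(n).random(n), AnnotationSet(chan, fs=fs)

    def test_lengths_add_up(self):
        pairs = [self._pair(n) for n in (100, 150, 120, 90)]
        y, ann = concatenate_sessions(pairs)
        assert len(y) == ann.n_samples == 460

    def test_story_bounds_partition_exactly(self):
        pairs = [self._pair(n) for n in (100, 150, 120)]
        _, ann = concatenate_sessions(pairs)
        assert ann.story_bounds == (0, 100, 250, 370)

    def test_order_sensitivity(self):
        a, b = self._pair(100), self._pair(150)
        y1, _ = concatenate_sessions([a, b])
        y2, _ = concatenate_sessions([b, a])
        assert not np.array_equal(y1, y2)

    def test_fs_mismatch_rejected(self):
        with pytest.raises(ValueError):
            concatenate_sessions([self._pair(100, fs=50.0), self._pair(100, fs=25.0)])


class TestBuildLaggedDesign:
    def test_single_impulse_shift_identity(self):
        chan = np.zeros((6, 60))
        chan[0, 20] = 1.0
        ann = AnnotationSet(chan, fs=10.0)
        window = LagWindow(tmin=-0.2, tmax=1.0, fs=10.0)
        X = build_lagged_design(ann, window)
        lags = window.lag_samples
        for j, lag in enumerate(lags):
            col = X[:, j]
            expected = np.zeros(60)
            if 0 <= 20 + lag < 60:
                expected[20 + lag] = 1.0
            assert np.array_equal(col, expected)

    def test_default_window_at_250hz_has_1301_lags(self):
        window = LagWindow(fs=250.0)
        assert window.n_lags == 1301
        chan = np.zeros((6, 2000))
        chan[2, 100] = 1.0
        X = build_lagged_design(AnnotationSet(chan, fs=250.0), window)
        assert X.shape == (2000, 6 * 1301)

    def test_zero_channels_give_zero_columns(self):
        ann = AnnotationSet(np.zeros((6, 100)), fs=10.0)
        X = build_lagged_design(ann, LagWindow(-0.2, 1.0, 10.0))
        assert not X.any()

    def test_matches_brute_force_convolution_oracle(self):
        rng = np.random.default_rng(0)
        chan = (rng.random((6, 400)) < 0.05).astype(float) * rng.random((6, 400))
        ann = AnnotationSet(chan, fs=20.0)
        window = LagWindow(tmin=-0.1, tmax=0.8, fs=20.0)
        X = build_lagged_design(ann, window)
        kernels = rng.standard_normal((6, window.n_lags))
        via_design = X @ kernels.ravel()
        # oracle: y[t] = sum_f sum_l k[f, l] * x[f, t - l]
        oracle = np.zeros(400)
        for f in range(6):
            for j, lag in enumerate(window.lag_samples):
                shifted = np.zeros(400)
                if lag >= 0:
                    shifted[lag:] = chan[f, : 400 - lag] if lag else chan[f]
                else:
                    shifted[:lag] = chan[f, -lag:]
                oracle += kernels[f, j] * shifted
        assert np.allclose(via_design, oracle)

    def test_window_longer_than_signal_rejected(self):
        ann = AnnotationSet(np.zeros((6, 5)), fs=10.0)
        with pytest.raises(ValueError):
            build_lagged_design(ann, LagWindow(-0.2, 5.0, 10.0))


class TestRidgeFit:
    def test_alpha_zero_limit_matches_ols_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((200, 12))
        y = rng.standard_normal(200)
        res = ridge_fit(X, y, alpha=1e-10)
        Z = np.column_stack([np.ones(200), X])
        beta = np.linalg.lstsq(Z, y, rcond=None)[0]
        assert res.coefficients.ravel() == pytest.approx(beta[1:], abs=1e-6)
        assert res.intercept == pytest.approx(beta[0], abs=1e-6)

    def test_known_kernel_recovered_from_convolution(self):
        rng = np.random.default_rng(2)
        window = LagWindow(tmin=0.0, tmax=1.0, fs=20.0)
        chan = np.zeros((6, 2000))
        for f in range(6):
            chan[f, rng.choice(2000, 40, replace=False)] = 1.0
        ann = AnnotationSet(chan, fs=20.0)
        X = build_lagged_design(ann, window)
        true = rng.standard_normal((6, window.n_lags)) * np.hanning(window.n_lags)
        y = X @ true.ravel()
        res = ridge_fit(X, y, alpha=1e-6, window=window)
        for f in range(6):
            assert np.corrcoef(res.coefficients[f], true[f])[0, 1] > 0.99

    def test_shrinkage_monotone_in_alpha(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((100, 12))
        y = X @ rng.standard_normal(12) + 0.1 * rng.standard_normal(100)
        norms = [
            np.linalg.norm(ridge_fit(X, y, alpha=a).coefficients)
            for a in (0.1, 10.0, 1000.0, 1e5)
        ]
        assert all(a > b for a, b in zip(norms, norms[1:]))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            ridge_fit(np.array([[np.nan]]), np.array([1.0]))


class TestCrossvalTrf:
    @staticmethod
    def _subject(seed=0, **kw):
        kw.setdefault("n_stories", 8)
        return simulate_trf_subject(seed, **kw)

    def test_monotone_transform_of_truth_gives_rho_one(self):
        # Spearman is rank-invariant: predicting any monotone transform is perfect
        pred = np.linspace(0, 1, 500)
        y = np.exp(3 * pred)
        assert stats.spearmanr(pred, y).statistic == pytest.approx(1.0)

    def test_high_snr_simulation_predicts_well(self):
        rhos = []
        for seed in range(3):
            s = self._subject(seed, snr=20.0)
            res = crossval_trf(s.trace, s.annotations, window=s.window, alpha=1.0, k=3)
            rhos.append(res.mean_rho)
        assert np.mean(rhos) > 0.8

    def test_constant_story_triggers_twofold_fallback(self, caplog):
        s = self._subject(4)
        y = s.trace.copy()
        a, b = s.annotations.story_bounds[0], s.annotations.story_bounds[3]
        # three folds over stories; make the first fold's trace constant
        y[a:b] = 0.5
        with caplog.at_level("INFO", logger="compslide.trf"):
            res = crossval_trf(y, s.annotations, window=s.window, k=3)
        assert res.k_used == 2
        assert any("2-fold" in r.message for r in caplog.records)

    def test_all_constant_trace_rejected(self):
        s = self._subject(5)
        with pytest.raises(DegenerateDataError):
            crossval_trf(np.full(len(s.trace), 0.3), s.annotations, window=s.window)

    def test_translation_equivariance(self):
        # shifting events and trace by a whole-sample offset leaves kernels
        # unchanged up to edge effects
        rng = np.random.default_rng(6)
        window = LagWindow(tmin=0.0, tmax=0.5, fs=20.0)
        chan = np.zeros((6, 800))
        for f in range(6):
            chan[f, rng.choice(np.arange(100, 700), 25, replace=False)] = 1.0
        true = rng.standard_normal((6, window.n_lags))
        X = build_lagged_design(AnnotationSet(chan, fs=20.0), window)
        y = X @ true.ravel() + 0.01 * rng.standard_normal(800)
        shift = 40
        chan2 = np.roll(chan, shift, axis=1)
        y2 = np.roll(y, shift)
        res1 = TemporalResponseModel(y, AnnotationSet(chan, fs=20.0), window=window).fit()
        res2 = TemporalResponseModel(y2, AnnotationSet(chan2, fs=20.0), window=window).fit()
        assert np.corrcoef(res1.coefficients.ravel(), res2.coefficients.ravel())[0, 1] > 0.99


class TestAblation:
    def test_dropping_nothing_is_exact_identity(self):
        subs = [simulate_trf_subject(i, n_stories=8) for i in range(2)]
        res = ablation_compare(
            [(s.trace, s.annotations) for s in subs],
            window=subs[0].window,
            features_to_drop=(),
        )
        assert np.all(res.delta_rho == 0.0)
        assert res.p_value == 1.0

    def test_surprisal_ablation_reduces_accuracy_when_effect_present(self):
        subs = [simulate_trf_subject(i, n_stories=8) for i in range(3)]
        res = ablation_compare(
            [(s.trace, s.annotations) for s in subs], window=subs[0].window
        )
        assert res.mean_delta > 0
        assert res.dropped == SURPRISAL_FEATURES


class TestKernelPeakLatency:
    def test_earlier_peak_wins_ties(self):
        window = LagWindow(tmin=0.0, tmax=1.0, fs=10.0)
        coef = np.zeros((6, window.n_lags))
        coef[0, 2] = 0.5
        coef[0, 7] = 0.5
        res = ridge_fit(np.zeros((20, 6 * window.n_lags)), np.zeros(20), window=window)
        res.coefficients = coef
        assert kernel_peak_latency(res, "low_surprisal_onset") == pytest.approx(0.2)

    def test_all_zero_kernel_is_error_not_zero(self):
        window = LagWindow(tmin=0.0, tmax=1.0, fs=10.0)
        res = ridge_fit(np.zeros((20, 6 * window.n_lags)), np.zeros(20), window=window)
        with pytest.raises(DegenerateDataError):
            kernel_peak_latency(res, "segment_onset")

    def test_unknown_feature_rejected(self):
        window = LagWindow(tmin=0.0, tmax=1.0, fs=10.0)
        res = ridge_fit(np.zeros((20, 6 * window.n_lags)), np.zeros(20), window=window)
        with pytest.raises(KeyError):
            kernel_peak_latency(res, "nope")

    def test_negative_lags_excluded_from_peak_search(self):
        window = LagWindow(tmin=-0.5, tmax=1.0, fs=10.0)
        coef = np.zeros((6, window.n_lags))
        coef[1, 0] = 9.0  # artifact mass at -0.5 s
        coef[1, 10] = 1.0  # genuine causal peak at 0.5 s
        res = ridge_fit(np.zeros((30, 6 * window.n_lags)), np.zeros(30), window=window)
        res.coefficients = coef
        assert kernel_peak_latency(res, "high_surprisal_onset") == pytest.approx(0.5)

    def test_simulated_delay_recovered(self):
        s = simulate_trf_subject(7, n_stories=16)
        res = TemporalResponseModel(s.trace, s.annotations, window=s.window).fit()
        est = res.peak_latency("segment_onset")
        assert abs(est - s.profile.delay_peak_s) <= 0.1


class TestAgainstMneOracle:
    def test_kernel_agrees_with_receptive_field(self):
        """Independent cross-check: MNE's ReceptiveField on the same data
        should learn essentially the same kernels."""
        mne = pytest.importorskip("mne")
        from mne.decoding import ReceptiveField

        s = simulate_trf_subject(8, n_stories=8, snr=20.0)
        ours = TemporalResponseModel(s.trace, s.annotations, window=s.window).fit()
        rf = ReceptiveField(
            tmin=s.window.tmin, tmax=s.window.tmax, sfreq=s.window.fs,
            estimator=1.0, feature_names=list(FEATURES),
        )
        rf.fit(s.annotations.channels.T, s.trace)
        theirs = rf.coef_.reshape(len(FEATURES), -1)
        for f in range(len(FEATURES)):
            c = np.corrcoef(ours.coefficients[f], theirs[f])[0, 1]
            assert c > 0.95
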