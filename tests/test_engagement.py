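"""Filter-bank CSP + LDA engagement decoder."""

import numpy as np
import pytest
from scipy import linalg
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from wearbci.engagement import (
    DEFAULT_BANDS,
    CalibrationProtocol,
    EngagementClassifier,
    FilterBankCSP,
    _class_covariance,
    fit_csp,
    fit_lda,
    run_calibration,
)
from wearbci.signal_core import bandpass_array, notch_filter, segment
from wearbci.synth import generate_engagement_session


def dense_csp_oracle(ca: np.ndarray, cb: np.ndarray, n_pairs: int) -> np.ndarray:
    """Brute-force generalized eigensolver: eig(inv(Ca+Cb) @ Ca)."""
    evals, evecs = np.linalg.eig(np.linalg.solve(ca + cb, ca))
    order = np.argsort(evals.real)[::-1]
    keep = np.concatenate([order[:n_pairs], order[-n_pairs:]])
    return evecs[:, keep].real.T


class TestCSP:
    def test_identical_class_covariances_give_variance_ratio_half(self, rng):
        w = rng.standard_normal((40, 4, 100))
        W = fit_csp(w, w.copy(), n_pairs=2)
        ca = _class_covariance(w, 0.05)
        # whitened against Ca + Ca: each filter carries exactly half the variance
        assert np.allclose(np.diag(W @ ca @ W.T), 0.5, atol=1e-9)

    def test_two_channel_toy_matches_dense_oracle(self, rng):
        # class a varies only on channel 0, class b only on channel 1
        wa = np.zeros((30, 2, 200))
        wb = np.zeros((30, 2, 200))
        wa[:, 0] = rng.standard_normal((30, 200))
        wb[:, 1] = rng.standard_normal((30, 200))
        W = fit_csp(wa, wb, n_pairs=1, shrinkage=0.05)
        ca = _class_covariance(wa, 0.05)
        cb = _class_covariance(wb, 0.05)
        top = W[0]
        ratio = top @ ca @ top / (top @ (ca + cb) @ top)
        assert ratio > 0.9  # class-a variance fraction -> 1
        oracle = dense_csp_oracle(ca, cb, 1)
        for w_row, o_row in zip(W, oracle):
            cos = abs(w_row @ o_row) / (np.linalg.norm(w_row) * np.linalg.norm(o_row))
            assert cos > 1 - 1e-8

    def test_whitening_property(self, rng):
        wa = rng.standard_normal((25, 4, 150)) * 2.0
        wb = rng.standard_normal((25, 4, 150))
        W = fit_csp(wa, wb, n_pairs=2)
        composite = _class_covariance(wa, 0.05) + _class_covariance(wb, 0.05)
        assert np.allclose(W @ composite @ W.T, np.eye(4), atol=1e-6)

    @pytest.mark.parametrize("n_channels", [2, 4, 8])
    def test_matches_dense_oracle_on_random_windows(self, n_channels, rng):
        wa = rng.standard_normal((20, n_channels, 120)) * rng.uniform(0.5, 2, n_channels)[:, None]
        wb = rng.standard_normal((20, n_channels, 120)) * rng.uniform(0.5, 2, n_channels)[:, None]
        W = fit_csp(wa, wb, n_pairs=1)
        oracle = dense_csp_oracle(_class_covariance(wa, 0.05), _class_covariance(wb, 0.05), 1)
        for w_row, o_row in zip(W, oracle):
            cos = abs(w_row @ o_row) / (np.linalg.norm(w_row) * np.linalg.norm(o_row))
            assert cos > 1 - 1e-6

    def test_empty_class_rejected(self, rng):
        with pytest.raises(ValueError, match="at least one window"):
            fit_csp(np.empty((0, 2, 10)), rng.standard_normal((3, 2, 10)))


class TestFeatures:
    def test_zero_window_hits_variance_floor(self, rng):
        X = rng.standard_normal((10, 4, 250))
        y = np.r_[np.ones(5), -np.ones(5)]
        fb = FilterBankCSP(fs=250.0).fit(X, y)
        feats = fb.transform(np.zeros((1, 4, 250)))
        assert np.allclose(feats, np.log(1e-12))

    def test_amplitude_scaling_shifts_log_variance(self, rng):
        X = rng.standard_normal((10, 4, 250))
        y = np.r_[np.ones(5), -np.ones(5)]
        fb = FilterBankCSP(fs=250.0).fit(X, y)
        w = rng.standard_normal((4, 250))
        shift = fb.transform(3.0 * w) - fb.transform(w)
        assert np.allclose(shift, 2 * np.log(3.0), atol=1e-9)

    def test_matches_step_by_step_oracle(self, rng):
        X = rng.standard_normal((12, 4, 250))
        y = np.r_[np.ones(6), -np.ones(6)]
        fb = FilterBankCSP(fs=250.0).fit(X, y)
        w = rng.standard_normal((4, 250))
        expected = []
        for band, W in zip(DEFAULT_BANDS, fb.filters_):
            proj = W @ bandpass_array(w, band, 250.0)
            expected.append(np.log(np.maximum(proj.var(axis=1), 1e-12)))
        assert np.allclose(fb.transform(w), np.concatenate(expected), atol=1e-10)


class TestLDA:
    def test_symmetric_one_dimensional_boundary_at_zero(self, rng):
        f = np.r_[rng.normal(-1, 0.3, 200), rng.normal(1, 0.3, 200)][:, None]
        y = np.r_[-np.ones(200), np.ones(200)]
        w, b = fit_lda(f, y)
        boundary = -b / w[0]
        assert abs(boundary) < 0.1
        assert w[0] > 0  # larger label scores positive

    def test_separable_features_classified_perfectly(self, rng):
        f = np.r_[rng.normal(-5, 0.5, (50, 3)), rng.normal(5, 0.5, (50, 3))]
        y = np.r_[-np.ones(50), np.ones(50)]
        w, b = fit_lda(f, y)
        assert np.all(np.sign(f @ w + b) == y)

    def test_duplicated_columns_survive_shrinkage(self, rng):
        base = rng.standard_normal((60, 2))
        f = np.c_[base, base]  # rank-deficient pooled covariance
        y = np.r_[-np.ones(30), np.ones(30)]
        w, b = fit_lda(f, y)
        assert np.all(np.isfinite(w)) and np.isfinite(b)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            fit_lda(np.zeros((5, 2)), np.ones(5))

    def test_agrees_with_sklearn_on_balanced_gaussians(self, rng):
        f = np.r_[rng.normal(0, 1, (150, 4)) + [1, 0, -1, 0], rng.normal(0, 1, (150, 4))]
        y = np.r_[np.ones(150), -np.ones(150)]
        w, b = fit_lda(f, y)
        ours = np.sign(f @ w + b)
        ref = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=1e-4).fit(f, y)
        assert (ours == ref.predict(f)).mean() > 0.99


@pytest.fixture(scope="module")
def fitted():
    rec, train, _ = generate_engagement_session(effect_size=4.0, seed=3)
    model, _ = run_calibration(rec, intervals=train)
    seg = segment(notch_filter(rec), 1.0, labels=train)
    return model, seg


class TestScoring:
    def test_sign_convention_engage_positive(self, fitted):
        model, seg = fitted
        y = seg.labels.astype(int)
        s = model.decision_function(seg.windows)
        assert np.median(s[y == 1]) > 0 > np.median(s[y == -1])
        labels, scores = zip(*(model.score_window(w) for w in seg.windows[:5]))
        assert all(lab == (1 if sc >= 0 else -1) for lab, sc in zip(labels, scores))

    def test_scores_clipped_to_ten(self, fitted):
        model, seg = fitted
        model_small = EngagementClassifier()
        model_small.__dict__.update(model.__dict__)
        model_small.score_scale_ = 1e-6  # force raw scores beyond the scale
        s = model_small.decision_function(seg.windows)
        assert np.all(np.isin(np.abs(s), [10.0]))

    def test_scores_within_range(self, fitted):
        model, seg = fitted
        s = model.decision_function(seg.windows)
        assert np.all(s >= -10.0) and np.all(s <= 10.0)

    def test_antisymmetric_under_class_swap(self):
        rec, train, _ = generate_engagement_session(effect_size=2.0, seed=9)
        seg = segment(notch_filter(rec), 1.0, labels=train)
        y = seg.labels.astype(int)
        m1 = EngagementClassifier().fit(seg.windows, y)
        m2 = EngagementClassifier().fit(seg.windows, -y)
        s1 = m1.decision_function(seg.windows)
        s2 = m2.decision_function(seg.windows)
        assert np.allclose(s1, -s2, atol=1e-6)


class TestCalibration:
    def test_protocol_arithmetic(self):
        proto = CalibrationProtocol()
        assert proto.total_seconds == 240.0  # 4 minutes
        iv = proto.intervals()
        assert len(iv) == 4 and iv[-1][1] == 240.0
        assert sum(1 for *_, lab in iv if lab == 1) == 2

    def test_default_protocol_yields_240_training_windows(self):
        rec, train, _ = generate_engagement_session(effect_size=1.0, seed=2)
        model, summary = run_calibration(rec, intervals=train)
        assert summary["n_windows"] == 240
        assert summary["n_engage"] == summary["n_rest"] == 120

    def test_held_out_accuracy_on_separable_session(self):
        rec, train, evaluate = generate_engagement_session(effect_size=4.0, seed=1)
        model, _ = run_calibration(rec, intervals=train)
        seg = segment(notch_filter(rec), 1.0, labels=evaluate)
        acc = (model.predict(seg.windows) == seg.labels.astype(int)).mean()
        assert acc > 0.9

    def test_missing_protocol_labels_rejected(self):
        rec, train, _ = generate_engagement_session(effect_size=1.0, seed=2)
        only_engage = [iv for iv in train if iv[2] == 1]
        with pytest.raises(ValueError, match="labels"):
            run_calibration(rec, intervals=only_engage)
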