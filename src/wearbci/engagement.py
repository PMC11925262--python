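"""Filter-bank CSP + LDA engagement estimation for the 4-channel headband.

The engagement decoder distinguishes an "engaged" condition (a sustained
attention task, the d2 cancellation test) from rest (fixation cross).  Raw
EEG is notch-filtered, band-passed in three overlapping low-frequency bands
(4-8, 6-10, 8-12 Hz — chosen to stay clear of muscle artifacts), cut into
1-s windows, and projected through common spatial patterns (CSP) fitted per
band.  Log-variance features feed a linear discriminant whose signed output
is rescaled to an engagement score in [-10, +10]: positive means engaged,
negative means rest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .signal_core import (
    BandDefinition,
    Recording,
    SegmentedWindows,
    bandpass_array,
    notch_filter,
    segment,
)

__all__ = [
    "DEFAULT_BANDS",
    "CalibrationProtocol",
    "FilterBankCSP",
    "EngagementClassifier",
    "fit_csp",
    "fit_lda",
    "extract_features",
    "score_window",
    "run_calibration",
]

# Overlapping low-frequency filter bank of the engagement decoder.
DEFAULT_BANDS = (
    BandDefinition("low_theta", 4.0, 8.0),
    BandDefinition("theta_alpha", 6.0, 10.0),
    BandDefinition("alpha", 8.0, 12.0),
)

ENGAGE, REST = 1, -1


@dataclass(frozen=True)
class CalibrationProtocol:
    """Block structure of the calibration session.

    Two rounds of the attention task interleaved with two rest blocks, one
    minute each: 4 minutes of training data in total.
    """

    n_engage_blocks: int = 2
    n_rest_blocks: int = 2
    block_seconds: float = 60.0

    def __post_init__(self) -> None:
        if self.n_engage_blocks < 1 or self.n_rest_blocks < 1:
            raise ValueError("need at least one block per condition")
        if self.block_seconds <= 0:
            raise ValueError("block_seconds must be positive")

    @property
    def total_seconds(self) -> float:
        return (self.n_engage_blocks + self.n_rest_blocks) * self.block_seconds

    def intervals(self) -> list[tuple[float, float, int]]:
        """Labelled block sequence, engage and rest alternating (engage first)."""
        out, t = [], 0.0
        blocks = []
        for i in range(max(self.n_engage_blocks, self.n_rest_blocks)):
            if i < self.n_engage_blocks:
                blocks.append(ENGAGE)
            if i < self.n_rest_blocks:
                blocks.append(REST)
        for lab in blocks:
            out.append((t, t + self.block_seconds, lab))
            t += self.block_seconds
        return out


def _class_covariance(windows: np.ndarray, shrinkage: float) -> np.ndarray:
    """Average per-window trace-normalised covariance with identity shrinkage.

    Trace normalisation makes every 1-s window contribute equally regardless
    of its overall amplitude; the shrinkage keeps the composite covariance
    well-conditioned for short windows on few channels.
    """
    n_ch = windows.shape[1]
    cov = np.zeros((n_ch, n_ch))
    for w in windows:
        c = w @ w.T
        tr = np.trace(c)
        if tr > 0:
            cov += c / tr
    cov /= len(windows)
    return (1.0 - shrinkage) * cov + shrinkage * np.trace(cov) / n_ch * np.eye(n_ch)


def fit_csp(
    windows_a: np.ndarray,
    windows_b: np.ndarray,
    n_pairs: int = 1,
    shrinkage: float = 0.05,
) -> np.ndarray:
    """Common spatial patterns between two window classes.

    Solves the generalized eigenproblem ``C_a v = lambda (C_a + C_b) v`` and
    keeps the ``n_pairs`` filters with the largest eigenvalues (maximal
    class-a variance fraction) plus the ``n_pairs`` with the smallest.
    Eigenvectors are normalised so that ``W (C_a + C_b) W.T = I``.

    Parameters
    ----------
    windows_a, windows_b : ndarray, shape (n_windows, n_channels, n_samples)
    n_pairs : int
        Filter pairs retained; the returned matrix has ``2 * n_pairs`` rows.

    Returns
    -------
    W : ndarray, shape (2 * n_pairs, n_channels)
    """
    if len(windows_a) == 0 or len(windows_b) == 0:
        raise ValueError("both classes need at least one window")
    if windows_a.shape[1] != windows_b.shape[1]:
        raise ValueError("channel counts differ between classes")
    n_ch = windows_a.shape[1]
    if 2 * n_pairs > n_ch:
        raise ValueError(f"{n_pairs} pairs need {2 * n_pairs} filters but only {n_ch} channels")
    ca = _class_covariance(windows_a, shrinkage)
    cb = _class_covariance(windows_b, shrinkage)
    try:
        evals, evecs = linalg.eigh(ca, ca + cb)
    except linalg.LinAlgError as err:  # composite covariance singular
        raise linalg.LinAlgError(
            "composite covariance is singular even after shrinkage; "
            "check for all-zero channels"
        ) from err
    order = np.argsort(evals)[::-1]  # descending class-a variance fraction
    keep = np.concatenate([order[:n_pairs], order[-n_pairs:]])
    return evecs[:, keep].T


def _log_variance(projected: np.ndarray, var_floor: float) -> np.ndarray:
    return np.log(np.maximum(projected.var(axis=-1), var_floor))


class FilterBankCSP(TransformerMixin, BaseEstimator):
    """Per-band CSP spatial filtering with log-variance features.

    Fits one CSP filter set per frequency band on band-passed copies of the
    training windows; ``transform`` band-passes, projects and returns the
    concatenated log-variances, giving ``n_bands * 2 * n_pairs`` features per
    window.

    Parameters
    ----------
    fs : float
        Sampling rate of the windows, Hz.
    bands : sequence of BandDefinition
    n_pairs : int
        CSP filter pairs kept per band.
    shrinkage : float
        Covariance shrinkage toward the scaled identity.
    var_floor : float
        Lower bound on projected variance before the log.
    """

    def __init__(
        self,
        fs: float = 250.0,
        bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
        n_pairs: int = 1,
        shrinkage: float = 0.05,
        filter_order: int = 4,
        var_floor: float = 1e-12,
    ):
        self.fs = fs
        self.bands = bands
        self.n_pairs = n_pairs
        self.shrinkage = shrinkage
        self.filter_order = filter_order
        self.var_floor = var_floor

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("X must be (n_windows, n_channels, n_samples)")
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(f"CSP needs exactly two classes, got {list(classes)}")
        # Convention: the numerically larger class label plays the role of
        # class a (numerator of the variance ratio).
        a, b = classes.max(), classes.min()
        self.classes_ = np.array([b, a])
        self.filters_ = []
        for band in self.bands:
            xb = bandpass_array(X, band, self.fs, self.filter_order)
            self.filters_.append(fit_csp(xb[y == a], xb[y == b], self.n_pairs, self.shrinkage))
        return self

    def transform(self, X):
        check_is_fitted(self, "filters_")
        X = np.asarray(X, dtype=float)
        single = X.ndim == 2
        if single:
            X = X[None]
        feats = []
        for band, W in zip(self.bands, self.filters_):
            xb = bandpass_array(X, band, self.fs, self.filter_order)
            projected = np.einsum("fc,wct->wft", W, xb)
            feats.append(_log_variance(projected, self.var_floor))
        out = np.concatenate(feats, axis=1)
        return out[0] if single else out


def fit_lda(
    features: np.ndarray, labels: np.ndarray, shrinkage: float = 1e-4
) -> tuple[np.ndarray, float]:
    """Two-class LDA in closed form: ``w = S_pooled^-1 (mu_+ - mu_-)``.

    The bias places the decision boundary midway between the projected class
    means (equal priors); the sign convention makes the engaged class (the
    numerically larger label) score positive.

    Returns
    -------
    (weights, bias)
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"LDA needs exactly two classes, got {list(classes)}")
    pos, neg = classes.max(), classes.min()
    fp, fn = features[labels == pos], features[labels == neg]
    mu_p, mu_n = fp.mean(axis=0), fn.mean(axis=0)
    centered = np.concatenate([fp - mu_p, fn - mu_n])
    pooled = centered.T @ centered / max(len(centered) - 2, 1)
    d = pooled.shape[0]
    pooled += shrinkage * (np.trace(pooled) / d + 1e-12) * np.eye(d)
    w = linalg.solve(pooled, mu_p - mu_n, assume_a="pos")
    b = -float(w @ (mu_p + mu_n)) / 2.0
    return w, b


class EngagementClassifier(ClassifierMixin, BaseEstimator):
    """Filter-bank CSP + LDA engagement decoder with a signed score.

    ``fit`` consumes labelled 1-s windows (engaged vs. rest);
    ``decision_function`` returns the continuous engagement score in
    [-10, +10] (positive = engaged) and ``predict`` its sign.  Raw LDA scores
    are mapped to the display range by dividing by the 95th percentile of the
    absolute training scores and multiplying by 10, then clipping — so a
    typical strongly-engaged window saturates near +10.

    Parameters
    ----------
    fs : float
        Window sampling rate, Hz (250 for the headband).
    bands, n_pairs, shrinkage, filter_order, var_floor
        Passed to :class:`FilterBankCSP`.
    lda_shrinkage : float
        Diagonal loading of the pooled feature covariance.
    scale_percentile : float
        Percentile of \\|training scores\\| mapped to score 10.

    Attributes
    ----------
    csp_ : FilterBankCSP
    lda_weights_ : ndarray
    lda_bias_ : float
    score_scale_ : float
        Raw-score magnitude mapped to a displayed score of 10.
    classes_ : ndarray
        ``[rest_label, engage_label]`` sorted ascending.
    """

    def __init__(
        self,
        fs: float = 250.0,
        bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
        n_pairs: int = 1,
        shrinkage: float = 0.05,
        filter_order: int = 4,
        var_floor: float = 1e-12,
        lda_shrinkage: float = 1e-4,
        scale_percentile: float = 95.0,
    ):
        self.fs = fs
        self.bands = bands
        self.n_pairs = n_pairs
        self.shrinkage = shrinkage
        self.filter_order = filter_order
        self.var_floor = var_floor
        self.lda_shrinkage = lda_shrinkage
        self.scale_percentile = scale_percentile

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.csp_ = FilterBankCSP(
            fs=self.fs,
            bands=self.bands,
            n_pairs=self.n_pairs,
            shrinkage=self.shrinkage,
            filter_order=self.filter_order,
            var_floor=self.var_floor,
        ).fit(X, y)
        self.classes_ = self.csp_.classes_
        feats = self.csp_.transform(X)
        self.lda_weights_, self.lda_bias_ = fit_lda(feats, y, self.lda_shrinkage)
        raw = feats @ self.lda_weights_ + self.lda_bias_
        scale = np.percentile(np.abs(raw), self.scale_percentile)
        self.score_scale_ = float(scale) if scale > 0 else 1.0
        return self

    def _raw_scores(self, X) -> np.ndarray:
        check_is_fitted(self, "lda_weights_")
        feats = self.csp_.transform(np.asarray(X, dtype=float))
        return np.atleast_2d(feats) @ self.lda_weights_ + self.lda_bias_

    def decision_function(self, X) -> np.ndarray:
        """Engagement scores clipped to [-10, +10], one per window."""
        return np.clip(10.0 * self._raw_scores(X) / self.score_scale_, -10.0, 10.0)

    def predict(self, X) -> np.ndarray:
        s = self.decision_function(X)
        rest, engage = self.classes_
        return np.where(s >= 0, engage, rest)  # ties at 0 -> engaged

    def score_window(self, window: np.ndarray) -> tuple[int, float]:
        """(label, score) for a single channels x samples window."""
        window = np.asarray(window, dtype=float)
        s = float(self.decision_function(window[None])[0])
        rest, engage = self.classes_
        return (engage if s >= 0 else rest), s


def extract_features(windows: SegmentedWindows, model: FilterBankCSP | EngagementClassifier):
    """Log-variance filter-bank CSP features for labelled windows."""
    fb = model.csp_ if isinstance(model, EngagementClassifier) else model
    return fb.transform(windows.windows)


def score_window(model: EngagementClassifier, window: np.ndarray) -> tuple[int, float]:
    """Functional wrapper around :meth:`EngagementClassifier.score_window`."""
    return model.score_window(window)


def run_calibration(
    session: Recording,
    intervals: list[tuple[float, float, int]] | None = None,
    protocol: CalibrationProtocol = CalibrationProtocol(),
    apply_notch: bool = True,
    **model_params,
) -> tuple[EngagementClassifier, dict]:
    """Train an engagement model from a labelled calibration session.

    The default protocol is two 1-min task blocks and two 1-min rest blocks
    (4 min total), cut into 1-s windows.  Only a mains notch is applied
    before the filter bank; common average referencing is optional for the
    4-channel montage and off by default.

    Returns
    -------
    (model, summary)
        ``summary`` holds window counts and per-class feature means.
    """
    if intervals is None:
        intervals = protocol.intervals()
        if session.duration + 1e-9 < protocol.total_seconds:
            raise ValueError(
                f"session of {session.duration:.1f} s shorter than the "
                f"{protocol.total_seconds:.0f} s protocol"
            )
    present = {lab for _, _, lab in intervals}
    if not {ENGAGE, REST} <= present:
        raise ValueError(f"protocol needs labels {{+1, -1}}, got {sorted(present)}")
    rec = notch_filter(session) if apply_notch else session
    segmented = segment(rec, window_seconds=1.0, labels=intervals)
    model = EngagementClassifier(fs=session.fs, **model_params)
    model.fit(segmented.windows, segmented.labels.astype(int))
    feats = model.csp_.transform(segmented.windows)
    y = segmented.labels.astype(int)
    summary = {
        "n_windows": len(segmented),
        "n_engage": int((y == ENGAGE).sum()),
        "n_rest": int((y == REST).sum()),
        "feature_mean_engage": feats[y == ENGAGE].mean(axis=0).tolist(),
        "feature_mean_rest": feats[y == REST].mean(axis=0).tolist(),
        "training_accuracy": float((model.predict(segmented.windows) == y).mean()),
    }
    return model, summary
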