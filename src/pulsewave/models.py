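"""Classifiers over PCA mode features, plus heart-rate estimation.

The production classifier is linear discriminant analysis (LDA) on the
first three PCA modes: with class means ``mu0`` (no pulse), ``mu1``
(pulse) and pooled covariance ``S``, the score is the signed distance

    score(x) = w . x + b,   w = S^{-1} (mu1 - mu0),

monotone in the posterior log-odds of a pulse under the equal-covariance
Gaussian model; thresholding at ``b``'s decision boundary gives the binary
call.  LDA is deliberately implemented from its closed form here so the
fitted parameters (means, pooled covariance, weight vector, threshold)
stay inspectable; richer candidates (QDA, SVM, logistic regression,
random forest, Gaussian-mixture generative classifier) are fitted through
scikit-learn for the model-comparison harness.

Heart rate is estimated independently of the classifier: after the
8th-order 10-40 Hz QRS-emphasis filter, peaks of the rectified signal
above half its maximum, separated by a 0.25 s refractory interval
(240 bpm ceiling), mark QRS complexes, and the rate follows from the
first-to-last peak spacing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import signal as sps
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.mixture import GaussianMixture
from sklearn.model_selection import GridSearchCV
from sklearn.svm import SVC

from .segments import LABEL_PULSE, EcgSegment

CLASSIFIER_KINDS = ("lda", "qda", "svm", "gmm", "lr", "rf")

#: peak-finder settings: threshold fraction of max, refractory seconds
PEAK_THRESHOLD_FRAC = 0.5
PEAK_REFRACTORY_S = 0.25
MIN_HR_SEGMENT_S = 2.0


@dataclass
class HeartRateEstimate:
    bpm: float
    n_peaks: int
    peak_times: np.ndarray

    def __post_init__(self) -> None:
        if self.bpm < 0 or self.n_peaks != len(self.peak_times):
            raise ValueError("inconsistent heart-rate estimate")


def estimate_heart_rate(seg: EcgSegment) -> HeartRateEstimate:
    """Heart rate from QRS peak locations in a QRS-emphasis-filtered strip.

    Peaks are local maxima of the rectified signal above
    ``PEAK_THRESHOLD_FRAC`` of its maximum, at least ``PEAK_REFRACTORY_S``
    apart.  ``bpm = 60 (n_peaks - 1) / (t_last - t_first)`` for two or
    more peaks, else 0.
    """
    if seg.duration < MIN_HR_SEGMENT_S:
        raise ValueError(
            f"segment of {seg.duration:.2f} s is too short for rate "
            f"estimation (need >= {MIN_HR_SEGMENT_S} s)")
    env = np.abs(seg.samples)
    peak = env.max()
    if peak == 0.0:
        return HeartRateEstimate(0.0, 0, np.empty(0))
    locs, _ = sps.find_peaks(
        env,
        height=PEAK_THRESHOLD_FRAC * peak,
        distance=max(1, int(round(PEAK_REFRACTORY_S * seg.fs))),
    )
    times = locs / seg.fs
    if locs.size < 2:
        return HeartRateEstimate(0.0, locs.size, times)
    bpm = 60.0 * (locs.size - 1) / (times[-1] - times[0])
    return HeartRateEstimate(bpm, locs.size, times)


# -- classifiers -------------------------------------------------------------


@dataclass
class TrainedClassifier:
    """A fitted classifier with a continuous pulse score (higher = pulse).

    For ``kind="lda"`` the discriminant parameters are explicit; other
    kinds delegate scoring to the wrapped scikit-learn estimator.
    """

    kind: str
    threshold: float = 0.0
    # LDA parameters
    weights: np.ndarray | None = None
    bias: float = 0.0
    class_means: tuple[np.ndarray, np.ndarray] | None = None  # (mu0, mu1)
    pooled_cov: np.ndarray | None = None
    priors: tuple[float, float] = (0.5, 0.5)
    # non-LDA backend
    estimator: object | None = None

    @property
    def n_features(self) -> int:
        if self.weights is not None:
            return self.weights.size
        return int(self.estimator.n_features_in_)


def _as_xy(features, labels) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(features[0], "coords"):
        X = np.vstack([f.coords for f in features])
    else:
        X = np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
    y = np.asarray(
        [1 if lab in (1, True, LABEL_PULSE) else 0 for lab in labels])
    if X.shape[0] != y.size:
        raise ValueError("features and labels disagree in length")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to fit a classifier")
    return X, y


def fit_lda(features, labels) -> TrainedClassifier:
    """Fit LDA from class means and pooled covariance.

    A numerically singular pooled covariance is ridge-regularized by
    ``1e-6 * trace(S) * I`` with a warning rather than failing.
    """
    X, y = _as_xy(features, labels)
    d = X.shape[1]
    n0, n1 = int(np.sum(y == 0)), int(np.sum(y == 1))
    if min(n0, n1) < d + 1:
        raise ValueError(
            f"need at least {d + 1} samples per class for {d} features")
    mu0 = X[y == 0].mean(axis=0)
    mu1 = X[y == 1].mean(axis=0)
    R0 = X[y == 0] - mu0
    R1 = X[y == 1] - mu1
    S = (R0.T @ R0 + R1.T @ R1) / (n0 + n1 - 2)

    eigs = np.linalg.eigvalsh(S)
    if eigs.min() <= 1e-10 * max(eigs.max(), 1e-300):
        eps = 1e-6 * np.trace(S)
        warnings.warn(
            f"singular pooled covariance; applying ridge {eps:.3e}",
            RuntimeWarning, stacklevel=2)
        S = S + eps * np.eye(d)

    w = np.linalg.solve(S, mu1 - mu0)
    pi0, pi1 = n0 / (n0 + n1), n1 / (n0 + n1)
    bias = -0.5 * w @ (mu0 + mu1) + np.log(pi1 / pi0)
    return TrainedClassifier(
        kind="lda", threshold=0.0, weights=w, bias=float(bias),
        class_means=(mu0, mu1), pooled_cov=S, priors=(pi0, pi1),
    )


class _GmmClassifier:
    """Generative Gaussian-mixture classifier (one mixture per class)."""

    def __init__(self, n_components: int = 2, seed: int = 0):
        self.n_components = n_components
        self.seed = seed

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_GmmClassifier":
        self.n_features_in_ = X.shape[1]
        self.mixtures_ = {}
        self.log_priors_ = {}
        for c in (0, 1):
            Xc = X[y == c]
            k = min(self.n_components, max(1, Xc.shape[0] // 5))
            gm = GaussianMixture(n_components=k, covariance_type="full",
                                 reg_covar=1e-6, random_state=self.seed)
            self.mixtures_[c] = gm.fit(Xc)
            self.log_priors_[c] = np.log(Xc.shape[0] / X.shape[0])
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        # Bayes log-odds of the pulse class
        return (self.mixtures_[1].score_samples(X) + self.log_priors_[1]
                - self.mixtures_[0].score_samples(X) - self.log_priors_[0])


def _fit_one(kind: str, X: np.ndarray, y: np.ndarray,
             seed: int) -> TrainedClassifier:
    if kind == "lda":
        return fit_lda(X, y)
    if kind == "qda":
        est = QuadraticDiscriminantAnalysis(reg_param=1e-6).fit(X, y)
    elif kind == "lr":
        est = LogisticRegression(max_iter=2000).fit(X, y)
    elif kind == "svm":
        grid = {"C": [0.1, 1.0, 10.0], "gamma": ["scale", 0.1, 1.0]}
        search = GridSearchCV(SVC(kernel="rbf"), grid, cv=3,
                              scoring="roc_auc")
        est = search.fit(X, y).best_estimator_
    elif kind == "rf":
        # tree count chosen by out-of-bag error
        best, best_oob = None, -np.inf
        for n_trees in (50, 100, 200):
            rf = RandomForestClassifier(
                n_estimators=n_trees, oob_score=True, random_state=seed,
                n_jobs=1).fit(X, y)
            if rf.oob_score_ > best_oob:
                best, best_oob = rf, rf.oob_score_
        est = best
    elif kind == "gmm":
        est = _GmmClassifier(seed=seed).fit(X, y)
    else:
        raise ValueError(
            f"unknown classifier kind {kind!r}; known: {CLASSIFIER_KINDS}")
    return TrainedClassifier(kind=kind, estimator=est)


def fit_candidates(features, labels, kinds: Iterable[str] = CLASSIFIER_KINDS,
                   seed: int = 0) -> dict[str, TrainedClassifier]:
    """Fit the candidate-model comparison suite on one feature matrix."""
    kinds = list(kinds)
    if len(kinds) < 2:
        raise ValueError("candidate comparison needs at least 2 kinds")
    X, y = _as_xy(features, labels)
    return {kind: _fit_one(kind, X, y, seed) for kind in kinds}


def fit_classifier(kind: str, features, labels, seed: int = 0) -> TrainedClassifier:
    """Fit a single classifier of the given kind."""
    X, y = _as_xy(features, labels)
    return _fit_one(kind, X, y, seed)


def predict_score(model: TrainedClassifier, x) -> float | np.ndarray:
    """Continuous pulse score; scalar for one vector, array for a batch."""
    if hasattr(x, "coords"):
        x = x.coords
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = x[None, :] if single else x
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model "
            f"({model.n_features})")
    if model.kind == "lda":
        scores = X @ model.weights + model.bias
    elif hasattr(model.estimator, "decision_function"):
        scores = np.asarray(model.estimator.decision_function(X), float)
    else:
        p = model.estimator.predict_proba(X)[:, 1]
        p = np.clip(p, 1e-12, 1 - 1e-12)
        scores = np.log(p / (1 - p))
    return float(scores[0]) if single else scores


def predict_label(model: TrainedClassifier, x) -> int | np.ndarray:
    """Binary pulse call by thresholding the score."""
    s = predict_score(model, x)
    if np.isscalar(s):
        return int(s > model.threshold)
    return (s > model.threshold).astype(int)
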