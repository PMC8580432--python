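"""Classifier performance: ROC/AUC, bootstrap CIs, DeLong, grouped CV.

AUC is computed by the Mann-Whitney rank formulation (ties count 1/2), so
it is exactly the concordance probability and invariant under monotone
score transforms.  Confidence intervals use a stratified percentile
bootstrap (resampling within each class, preserving the test-set class
balance).  The operating point maximizes Youden's J = sensitivity +
specificity - 1, with ties broken toward higher specificity.  Correlated
AUCs (two scoring methods on identical cases) are compared with the
DeLong placement-value variance estimator.

Cross-validated AUC is *patient-grouped*: folds partition patients, never
segments, and the PCA basis and classifier are refit from scratch inside
each training fold so no test-fold statistic leaks into the fit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedGroupKFold

from .features import (
    DEFAULT_MAX_MODES,
    DEFAULT_R,
    DEFAULT_VARIANCE_CUTOFF,
    ScalogramMatrix,
    fit_feature_basis,
    project_matrix,
)
from .models import fit_classifier, predict_score
from .segments import LABEL_PULSE


def _as_binary(labels) -> np.ndarray:
    return np.asarray(
        [1 if lab in (1, True, LABEL_PULSE) else 0 for lab in labels])


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC: U / (n_pos * n_neg), ties counted 1/2."""
    s = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = stats.rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def bootstrap_auc_ci(scores, labels, B: int = 2000,
                     seed: int = 0) -> tuple[float, float]:
    """95% percentile bootstrap interval for the AUC.

    Resampling is stratified within class, so every resample retains both
    classes and the observed class balance; with B resamples the bounds
    are the empirical 2.5/97.5 percentiles.  Deterministic given seed.
    """
    s = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    pos, neg = s[y == 1], s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    rp = pos[rng.integers(0, pos.size, size=(B, pos.size))]
    rn = neg[rng.integers(0, neg.size, size=(B, neg.size))]
    # vectorized rank AUC over all resamples at once
    both = np.concatenate([rp, rn], axis=1)
    ranks = stats.rankdata(both, axis=1)
    u = ranks[:, :pos.size].sum(axis=1) - pos.size * (pos.size + 1) / 2.0
    aucs = u / (pos.size * neg.size)
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)


def optimal_operating_point(scores, labels) -> tuple[float, float, float]:
    """Threshold maximizing Youden's J; returns (threshold, sens, spec).

    Candidate thresholds are midpoints between adjacent distinct scores
    plus guards beyond the extremes; a positive call is ``score >
    threshold``.  Ties in J resolve toward higher specificity.  An
    anti-predictive score set degenerates to J = 0 at a threshold above
    every score (call everything negative) and triggers a warning.
    """
    s = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    pos, neg = s[y == 1], s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    uniq = np.unique(s)
    candidates = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]])
    sens = (pos[None, :] > candidates[:, None]).mean(axis=1)
    spec = (neg[None, :] <= candidates[:, None]).mean(axis=1)
    j = sens + spec - 1.0
    best = np.flatnonzero(j == j.max())
    idx = best[np.argmax(spec[best])]  # ties -> higher specificity
    if j[idx] <= 0:
        warnings.warn("scores are anti-predictive or uninformative; "
                      "operating point is degenerate", RuntimeWarning,
                      stacklevel=2)
    return float(candidates[idx]), float(sens[idx]), float(spec[idx])


def _placements(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong structural components via midranks."""
    pos, neg = scores[y == 1], scores[y == 0]
    m, n = pos.size, neg.size
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n        # per positive case
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m  # per negative case
    auc = v10.mean()
    return v10, v01, float(auc)


def delong_compare(scores_a, scores_b, labels) -> tuple[float, float, float]:
    """DeLong test for two correlated AUCs on identical cases.

    Returns ``(auc_a, auc_b, p)`` with a two-sided p-value from the
    normal approximation using the placement-value covariance of the
    paired AUC difference.  Identical (or rank-identical) score sets give
    a zero-variance zero difference, reported as p = 1 exactly.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = _as_binary(labels)
    if sa.size != sb.size or sa.size != y.size:
        raise ValueError("score sets and labels must share one case list")
    v10a, v01a, auc_a = _placements(sa, y)
    v10b, v01b, auc_b = _placements(sb, y)
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]))
    s01 = np.cov(np.vstack([v01a, v01b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return auc_a, auc_b, p


@dataclass
class EvalReport:
    """Test-set performance summary for one phase-specific model."""

    auc: float
    ci: tuple[float, float]
    sensitivity: float
    specificity: float
    operating_threshold: float
    n_pos: int
    n_neg: int
    bootstrap_B: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "ci_low": self.ci[0],
            "ci_high": self.ci[1],
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "operating_threshold": self.operating_threshold,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "bootstrap_B": self.bootstrap_B,
            "seed": self.seed,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def evaluate_scores(scores, labels, B: int = 2000, seed: int = 0) -> EvalReport:
    """AUC with bootstrap CI plus Youden operating point, in one report."""
    y = _as_binary(labels)
    auc = roc_auc(scores, labels)
    ci = bootstrap_auc_ci(scores, labels, B=B, seed=seed)
    thr, sens, spec = optimal_operating_point(scores, labels)
    return EvalReport(
        auc=auc, ci=ci, sensitivity=sens, specificity=spec,
        operating_threshold=thr, n_pos=int(y.sum()),
        n_neg=int(y.size - y.sum()), bootstrap_B=B, seed=seed,
    )


@dataclass
class CvResult:
    mean_auc: float
    fold_aucs: list[float]
    fold_of_group: dict


def cv_auc(features: np.ndarray, labels, groups: Sequence, k: int = 5,
           model_kind: str = "lda", seed: int = 0,
           cutoff: float = DEFAULT_VARIANCE_CUTOFF,
           max_modes: int = DEFAULT_MAX_MODES,
           r_fixed: int | None = DEFAULT_R,
           normalize: bool = True) -> CvResult:
    """Patient-grouped k-fold CV AUC of the PCA + classifier stage.

    ``features`` are raw scalogram pixel vectors (n_samples x m); the
    feature basis (centering, normalization, modes) and the classifier
    are refit inside every training fold, so validation folds see only a
    frozen transform.  Folds partition *groups* (patients), stratified by
    label where possible, with seeded shuffling.
    """
    X = np.asarray(features, dtype=float)
    y = _as_binary(labels)
    groups = np.asarray(groups)
    if len(np.unique(groups)) < k:
        raise ValueError(f"need at least {k} distinct groups for {k} folds")
    splitter = StratifiedGroupKFold(n_splits=k, shuffle=True,
                                    random_state=seed)
    fold_aucs: list[float] = []
    fold_of_group: dict = {}
    for fold, (tr, va) in enumerate(splitter.split(X, y, groups)):
        for g in np.unique(groups[va]):
            fold_of_group[g] = fold
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[va])) < 2:
            warnings.warn(f"fold {fold} is single-class; skipping its AUC",
                          RuntimeWarning, stacklevel=2)
            continue
        basis = fit_feature_basis(
            ScalogramMatrix(X[tr].T, [str(i) for i in tr]),
            cutoff=cutoff, max_modes=max_modes, r_fixed=r_fixed,
            normalize=normalize)
        model = fit_classifier(model_kind, project_matrix(basis, X[tr]),
                               y[tr], seed=seed)
        scores = predict_score(model, project_matrix(basis, X[va]))
        fold_aucs.append(roc_auc(scores, y[va]))
    if not fold_aucs:
        raise ValueError("no fold produced a defined AUC")
    return CvResult(mean_auc=float(np.mean(fold_aucs)),
                    fold_aucs=fold_aucs, fold_of_group=fold_of_group)
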