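"""PCA mode extraction from vectorized scalograms.

Vectorized scalograms are assembled column-wise into ``A`` (m pixels x n
segments).  After per-pixel centering and unit-variance normalization, the
singular value decomposition ``A = U S V^T`` ranks spatial modes (columns
of ``U``: time-frequency patterns) by explained variance.  Modes whose
variance fraction ``sigma_i^2 / sum sigma_j^2`` exceeds a 1% cutoff are
retained, at most 10, and the production model fixes r = 3 for parsimony.
A segment's classifier features are the coordinates of its (centered,
normalized) scalogram vector on the retained modes.

The rank-r truncation is least-squares optimal: its Frobenius
reconstruction error equals ``sqrt(sum_{i>r} sigma_i^2)`` (Eckart-Young),
which the tests assert.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

DEFAULT_VARIANCE_CUTOFF = 0.01
DEFAULT_MAX_MODES = 10
DEFAULT_R = 3


@dataclass
class ScalogramMatrix:
    """m x n matrix of vectorized scalograms (columns = segments)."""

    A: np.ndarray
    column_ids: list[str]

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2:
            raise ValueError("A must be 2-d (pixels x segments)")
        if len(self.column_ids) != self.A.shape[1]:
            raise ValueError("one column id per column required")
        if not np.all(np.isfinite(self.A)):
            raise ValueError("A must not contain missing values")

    @property
    def m(self) -> int:
        return self.A.shape[0]

    @property
    def n(self) -> int:
        return self.A.shape[1]


@dataclass
class FeatureBasis:
    """Centering/normalization statistics plus retained PCA modes."""

    mean: np.ndarray          # length m
    scale: np.ndarray         # length m normalization divisors
    U_r: np.ndarray           # m x r spatial modes, orthonormal columns
    singular_values: np.ndarray  # all n, descending
    variance_fractions: np.ndarray  # sigma_i^2 / sum sigma_j^2
    r: int
    Vt: np.ndarray | None = None  # n x n right singular vectors (training)

    def __post_init__(self) -> None:
        if self.r != self.U_r.shape[1]:
            raise ValueError("r must match U_r column count")


def center_and_normalize(
    A: ScalogramMatrix, normalize: bool = True
) -> tuple[ScalogramMatrix, np.ndarray, np.ndarray]:
    """Remove per-pixel means and (optionally) divide by per-pixel SD.

    Zero-variance pixels get a divisor of 1 so they pass through as exact
    zeros instead of NaNs.  Returns the transformed matrix plus the stored
    statistics needed to project new data identically.
    """
    if A.n < 2:
        raise ValueError("need at least 2 columns to center and normalize")
    mean = A.A.mean(axis=1)
    centered = A.A - mean[:, None]
    if normalize:
        scale = centered.std(axis=1)
        scale[scale == 0.0] = 1.0
    else:
        scale = np.ones(A.m)
    out = ScalogramMatrix(centered / scale[:, None], list(A.column_ids))
    return out, mean, scale


def _fix_signs(U: np.ndarray, Vt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orient each mode so its largest-magnitude pixel loading is positive.

    SVD signs are otherwise arbitrary, which would break byte-level
    reproducibility of archived bases.
    """
    idx = np.abs(U).argmax(axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs, Vt * signs[:, None]


def svd_decompose(A_centered: ScalogramMatrix, mean: np.ndarray | None = None,
                  scale: np.ndarray | None = None) -> FeatureBasis:
    """Economy SVD of the centered/normalized matrix; all modes retained."""
    M = A_centered.A
    if not np.all(np.isfinite(M)):
        raise ValueError("matrix contains non-finite entries")
    U, s, Vt = np.linalg.svd(M, full_matrices=False)  # raises LinAlgError on failure
    U, Vt = _fix_signs(U, Vt)
    total = float(np.sum(s ** 2))
    fractions = s ** 2 / total if total > 0 else np.zeros_like(s)
    m = M.shape[0]
    return FeatureBasis(
        mean=np.zeros(m) if mean is None else np.asarray(mean, float),
        scale=np.ones(m) if scale is None else np.asarray(scale, float),
        U_r=U,
        singular_values=s,
        variance_fractions=fractions,
        r=U.shape[1],
        Vt=Vt,
    )


def select_modes(basis: FeatureBasis,
                 cutoff: float = DEFAULT_VARIANCE_CUTOFF,
                 max_modes: int = DEFAULT_MAX_MODES) -> FeatureBasis:
    """Retain modes whose variance fraction exceeds ``cutoff`` (cap, floor 1)."""
    if not 0 <= cutoff < 1:
        raise ValueError("cutoff must lie in [0, 1)")
    if max_modes < 1:
        raise ValueError("max_modes must be >= 1")
    n_above = int(np.sum(basis.variance_fractions > cutoff))
    r = max(1, min(max_modes, n_above))
    return replace(basis, U_r=basis.U_r[:, :r], r=r)


def low_rank_approx(basis: FeatureBasis, A: np.ndarray) -> np.ndarray:
    """Rank-r reconstruction ``U_r U_r^T A`` of a centered/normalized matrix."""
    A = np.asarray(A, dtype=float)
    if basis.r > A.shape[1]:
        raise ValueError(f"rank {basis.r} exceeds column count {A.shape[1]}")
    return basis.U_r @ (basis.U_r.T @ A)


@dataclass
class FeatureVector:
    """Mode coordinates of one segment."""

    coords: np.ndarray
    segment_id: str = ""
    phase: str = ""


def project(basis: FeatureBasis, x: np.ndarray, segment_id: str = "",
            phase: str = "") -> FeatureVector:
    """Project one scalogram vector onto the retained modes.

    ``coords = U_r^T ((x - mean) / scale)``; training columns reproduce the
    corresponding rows of ``S_r V_r^T``.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != basis.mean.shape:
        raise ValueError(
            f"vector length {x.shape} does not match basis pixels "
            f"{basis.mean.shape}")
    coords = basis.U_r.T @ ((x - basis.mean) / basis.scale)
    return FeatureVector(coords=coords, segment_id=segment_id, phase=phase)


def project_matrix(basis: FeatureBasis, X: np.ndarray) -> np.ndarray:
    """Project rows of ``X`` (n_samples x m pixels) to (n_samples x r)."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != basis.mean.size:
        raise ValueError("pixel dimension mismatch")
    return ((X - basis.mean[None, :]) / basis.scale[None, :]) @ basis.U_r


def fit_feature_basis(A: ScalogramMatrix,
                      cutoff: float = DEFAULT_VARIANCE_CUTOFF,
                      max_modes: int = DEFAULT_MAX_MODES,
                      r_fixed: int | None = DEFAULT_R,
                      normalize: bool = True) -> FeatureBasis:
    """Center/normalize, decompose and select modes in one step.

    ``r_fixed`` caps the retained mode count after the variance-cutoff
    rule (the production model uses 3 for parsimony); pass ``None`` to
    keep the rule's count.
    """
    centered, mean, scale = center_and_normalize(A, normalize=normalize)
    basis = svd_decompose(centered, mean=mean, scale=scale)
    basis = select_modes(basis, cutoff=cutoff, max_modes=max_modes)
    if r_fixed is not None and basis.r > r_fixed:
        basis = replace(basis, U_r=basis.U_r[:, :r_fixed], r=r_fixed)
    return basis


# -- serialization -----------------------------------------------------------

def save_basis(basis: FeatureBasis, path: str | Path,
               config_hash: str = "") -> None:
    np.savez_compressed(
        path, mean=basis.mean, scale=basis.scale, U_r=basis.U_r,
        singular_values=basis.singular_values,
        variance_fractions=basis.variance_fractions, r=basis.r,
        config_hash=np.bytes_(config_hash.encode()),
    )


def load_basis(path: str | Path) -> tuple[FeatureBasis, str]:
    with np.load(path) as z:
        basis = FeatureBasis(
            mean=z["mean"], scale=z["scale"], U_r=z["U_r"],
            singular_values=z["singular_values"],
            variance_fractions=z["variance_fractions"], r=int(z["r"]),
        )
        config_hash = bytes(z["config_hash"]).decode()
    return basis, config_hash
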