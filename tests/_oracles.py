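"""Independent reference computations used as test oracles.

Everything here is deliberately naive — direct quadrature, brute-force
enumeration, explicit double loops — and shares no code path with the
package implementation it checks.
"""

from __future__ import annotations

import numpy as np


def bump_response_scalar(omega: float, mu: float, sigma: float) -> float:
    """Scalar closed-form bump window evaluation."""
    u = (omega - mu) / sigma
    if abs(u) >= 1.0:
        return 0.0
    return float(np.exp(1.0 - 1.0 / (1.0 - u * u)))


def mother_wavelet_time(tau: np.ndarray, mu: float, sigma: float,
                        n_quad: int = 8001) -> np.ndarray:
    """Time-domain bump wavelet by dense Riemann quadrature of the
    inverse Fourier integral over the compact support (mu-sigma, mu+sigma).
    """
    om = np.linspace(mu - sigma, mu + sigma, n_quad)
    dom = om[1] - om[0]
    resp = np.array([bump_response_scalar(o, mu, sigma) for o in om])
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    # (1/2pi) integral resp(om) e^{i om tau} dom
    return (resp[None, :] * np.exp(1j * om[None, :] * tau[:, None])
            ).sum(axis=1) * dom / (2.0 * np.pi)


def naive_cwt(x: np.ndarray, fs: float, scales: np.ndarray, mu: float,
              sigma: float) -> np.ndarray:
    """O(n^2) Riemann-sum wavelet transform with 1/a normalization.

    W(a, b_m) = dt * sum_n x[n] conj( (1/a) Psi((t_n - b_m)/a) ),
    with the mother wavelet evaluated by direct quadrature.
    """
    n = x.size
    dt = 1.0 / fs
    lags = np.arange(-(n - 1), n) * dt
    W = np.empty((scales.size, n), dtype=complex)
    idx = (np.arange(n)[None, :] - np.arange(n)[:, None]) + (n - 1)
    for j, a in enumerate(scales):
        psi = mother_wavelet_time(lags / a, mu, sigma) / a
        W[j] = dt * (psi[idx].conj() @ x)
    return W


def pairwise_auc(scores, labels) -> float:
    """Brute-force concordance over every (positive, negative) pair."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (pos.size * neg.size)


def delong_p_direct(sa, sb, labels) -> float:
    """DeLong p-value via explicit psi double loops (no midrank trick)."""
    from scipy.stats import norm

    sa = np.asarray(sa, float)
    sb = np.asarray(sb, float)
    y = np.asarray(labels)

    def components(s):
        pos, neg = s[y == 1], s[y == 0]
        psi = np.where(pos[:, None] > neg[None, :], 1.0,
                       np.where(pos[:, None] == neg[None, :], 0.5, 0.0))
        return psi.mean(axis=1), psi.mean(axis=0), psi.mean()

    v10a, v01a, auc_a = components(sa)
    v10b, v01b, auc_b = components(sb)
    m, n = v10a.size, v01a.size

    def cov(u, v):
        return ((u - u.mean()) * (v - v.mean())).sum() / (u.size - 1)

    var = (cov(v10a, v10a) + cov(v10b, v10b) - 2 * cov(v10a, v10b)) / m \
        + (cov(v01a, v01a) + cov(v01b, v01b) - 2 * cov(v01a, v01b)) / n
    diff = auc_a - auc_b
    if var <= 0:
        return 1.0 if diff == 0 else 0.0
    return float(2.0 * norm.sf(abs(diff) / np.sqrt(var)))


def count_halfmax_peaks(x: np.ndarray, min_sep: int = 1) -> int:
    """Count strict local maxima above half the global maximum."""
    thr = 0.5 * np.max(np.abs(x))
    count = 0
    last = -min_sep - 1
    for i in range(1, x.size - 1):
        if x[i] > thr and x[i] >= x[i - 1] and x[i] > x[i + 1]:
            if i - last > min_sep:
                count += 1
            last = i
    return count
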