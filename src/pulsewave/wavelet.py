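"""Continuous wavelet transform with a bump mother wavelet.

The pulse classifier's feature image is the *scalogram*: the squared
modulus ``E(a, b) = |W(a, b)|**2`` of the continuous wavelet transform

    W(a, b) = integral f(t) conj(Psi_{a,b}(t)) dt,
    Psi_{a,b}(t) = (1/a) Psi((t - b) / a),

where ``a`` is the dilation (scale) and ``b`` the translation, which sweeps
the full segment.  The ``1/a`` normalization is used by default; L2
(``1/sqrt(a)``) normalization is available as an option.

The mother wavelet is the *bump* wavelet, defined in the frequency domain
as a compactly supported, infinitely smooth window on positive frequencies:

    Psi_hat(omega) = exp(1 - 1 / (1 - ((omega - mu)/sigma)**2))
                     for |omega - mu| < sigma, else 0,

with center ``mu`` and half-width ``sigma`` in normalized angular
frequency.  Being analytic (zero at omega <= 0) it yields complex
coefficients whose modulus envelopes oscillatory bursts — QRS complexes —
cleanly.  Other mother wavelets can be registered for the wavelet-
comparison harness.

The transform is evaluated in the frequency domain: because the scaled
kernel ``Psi_hat(a * omega)`` is exactly band-limited, sampling it on the
FFT grid is exact, and the only approximation is circular wrap-around of
the wavelet's time-domain tails.  Zero-padding controls that truncation:
``pad_tail_mult`` multiples of the largest scale are appended (the bump's
tails decay faster than any polynomial but are long at sub-hertz scales).
The default is accurate to roughly 1e-4 of the peak coefficient, ample for
classification; raise it for strict quadrature-level agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
from scipy import fft as sfft

from .segments import EcgSegment

# -- mother wavelet registry -------------------------------------------------

#: name -> (frequency response factory, peak angular frequency fn)
_WAVELETS: dict[str, Callable[..., tuple[Callable[[np.ndarray], np.ndarray], float]]] = {}


def register_wavelet(name: str, factory) -> None:
    """Register a mother wavelet for use in WaveletSpec / the benchmark harness.

    ``factory(center, width)`` must return ``(response, peak_omega)`` where
    ``response(omega)`` is the nonnegative frequency response (zero for
    omega <= 0) and ``peak_omega`` its maximum location.
    """
    _WAVELETS[name] = factory


def bump_frequency_response(omega: np.ndarray, center: float = 5.0,
                            width: float = 0.6) -> np.ndarray:
    """Bump window on ``(center - width, center + width)``, peak value 1.

    Raises if the support would touch non-positive frequencies
    (``center <= width``), which would break analyticity.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    if center <= width:
        raise ValueError("need center > width so the support stays at omega > 0")
    omega = np.asarray(omega, dtype=float)
    out = np.zeros_like(omega)
    u = (omega - center) / width
    inside = np.abs(u) < 1.0
    out[inside] = np.exp(1.0 - 1.0 / (1.0 - u[inside] ** 2))
    return out


def _bump_factory(center: float, width: float):
    def response(omega: np.ndarray) -> np.ndarray:
        return bump_frequency_response(omega, center, width)
    return response, center


def _morlet_factory(center: float, width: float):
    # analytic (positive-frequency) Gaussian window
    def response(omega: np.ndarray) -> np.ndarray:
        omega = np.asarray(omega, dtype=float)
        out = np.exp(-0.5 * ((omega - center) / width) ** 2)
        out[omega <= 0] = 0.0
        return out
    return response, center


register_wavelet("bump", _bump_factory)
register_wavelet("morlet", _morlet_factory)


@dataclass(frozen=True)
class WaveletSpec:
    """Mother wavelet choice, scale grid and evaluation settings.

    freq_range         pseudo-frequency span of the scale grid, Hz
    voices_per_octave  scales per frequency octave (logarithmic grid)
    normalization      "1/a" (as used here) or "l2" (1/sqrt(a))
    pad_tail_mult      zero-padding, in multiples of the largest scale
    """

    name: str = "bump"
    center: float = 5.0
    width: float = 0.6
    voices_per_octave: int = 10
    freq_range: tuple[float, float] = (0.5, 40.0)
    normalization: str = "1/a"
    pad_tail_mult: float = 16.0

    def __post_init__(self) -> None:
        if self.name not in _WAVELETS:
            raise ValueError(f"unknown wavelet {self.name!r}; "
                             f"registered: {sorted(_WAVELETS)}")
        fmin, fmax = self.freq_range
        if not 0 < fmin < fmax:
            raise ValueError("freq_range must satisfy 0 < fmin < fmax")
        if self.voices_per_octave < 1:
            raise ValueError("voices_per_octave must be >= 1")
        if self.normalization not in ("1/a", "l2"):
            raise ValueError("normalization must be '1/a' or 'l2'")
        # validate shape parameters eagerly
        self.response()

    def response(self) -> tuple[Callable[[np.ndarray], np.ndarray], float]:
        return _WAVELETS[self.name](self.center, self.width)

    def scales(self) -> np.ndarray:
        """Strictly increasing dilation grid covering freq_range."""
        fmin, fmax = self.freq_range
        _, peak = self.response()
        n = int(np.ceil(self.voices_per_octave * np.log2(fmax / fmin))) + 1
        freqs = fmax * 2.0 ** (-np.arange(n) / self.voices_per_octave)
        return peak / (2.0 * np.pi * freqs)  # ascending

    def pseudo_frequencies(self) -> np.ndarray:
        """Hz at which each scale's response peaks (descending)."""
        _, peak = self.response()
        return peak / (2.0 * np.pi * self.scales())


@dataclass
class Scalogram:
    """CWT coefficients and energy on a (scales x times) grid."""

    coefficients: np.ndarray  # complex, (n_scales, n_times)
    scales: np.ndarray
    pseudo_frequencies: np.ndarray
    times: np.ndarray
    energy: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.coefficients.shape


_KERNEL_CACHE: dict[tuple, tuple[int, np.ndarray]] = {}
_KERNEL_CACHE_MAX = 8


def _kernels(spec: WaveletSpec, n: int, fs: float) -> tuple[int, np.ndarray]:
    """Padded FFT length and per-scale frequency-response kernels.

    Cached: every segment of a given shape/rate shares one kernel bank,
    which dominates the per-transform cost otherwise.
    """
    key = (spec, n, fs)
    hit = _KERNEL_CACHE.get(key)
    if hit is not None:
        return hit
    response, _ = spec.response()
    scales = spec.scales()
    pad = int(np.ceil(spec.pad_tail_mult * scales.max() * fs))
    nfft = sfft.next_fast_len(n + pad)
    omega = 2.0 * np.pi * sfft.fftfreq(nfft, 1.0 / fs)
    kernels = np.empty((scales.size, nfft))
    for j, a in enumerate(scales):
        kernels[j] = response(a * omega)
        if spec.normalization == "l2":
            kernels[j] *= np.sqrt(a)
    if len(_KERNEL_CACHE) >= _KERNEL_CACHE_MAX:
        _KERNEL_CACHE.pop(next(iter(_KERNEL_CACHE)))
    _KERNEL_CACHE[key] = (nfft, kernels)
    return nfft, kernels


def cwt(seg: EcgSegment, spec: WaveletSpec = WaveletSpec()) -> Scalogram:
    """Continuous wavelet transform of a segment on the spec's scale grid.

    Evaluated as a frequency-domain cross-correlation: for each scale,
    ``W = ifft(fft(x_padded) * Psi_hat(a * omega))`` truncated back to the
    signal support.  With the default ``1/a`` normalization no further
    amplitude factor appears.
    """
    if seg.n_samples == 0:
        raise ValueError("cannot transform an empty segment")
    fmin, fmax = spec.freq_range
    if fmax > seg.fs / 2.0:
        raise ValueError(
            f"scale grid reaches {fmax} Hz, above Nyquist {seg.fs / 2} Hz")

    scales = spec.scales()
    n = seg.n_samples
    nfft, kernels = _kernels(spec, n, seg.fs)
    x_hat = sfft.fft(seg.samples, nfft)
    coeffs = sfft.ifft(x_hat[None, :] * kernels, axis=1)[:, :n]

    return Scalogram(
        coefficients=coeffs,
        scales=scales,
        pseudo_frequencies=spec.pseudo_frequencies(),
        times=seg.times,
    )


def scalogram_energy(s: Scalogram) -> Scalogram:
    """Populate the energy surface ``E = |W|**2`` (squared modulus)."""
    if s.coefficients is None:
        raise ValueError("scalogram has no coefficients")
    return replace(s, energy=np.abs(s.coefficients) ** 2)


def _pool_axis(x: np.ndarray, n_blocks: int, axis: int) -> np.ndarray:
    """Mean over contiguous blocks (near-equal sizes) along one axis."""
    if x.shape[axis] == n_blocks:
        return x
    parts = np.array_split(x, n_blocks, axis=axis)
    return np.stack([p.mean(axis=axis) for p in parts], axis=axis)


def scalogram_to_vector(s: Scalogram,
                        target_shape: tuple[int, int] = (64, 128),
                        log_energy: bool = False,
                        log_eps: float = 1e-12) -> np.ndarray:
    """Mean-pool the energy surface to ``target_shape`` and flatten.

    Pooling to a fixed (scales x times) grid makes 10 s and 5 s segments,
    and 125 vs 250 Hz devices, comparable within one model while bounding
    the PCA pixel dimension.  Flattening is column-major (time-major
    blocks of scales), a bijection when ``target_shape`` equals the native
    shape.

    ``log_energy`` applies ``log(E + log_eps)`` cell-wise before pooling:
    scalogram energy is heavy-tailed (the compression-artifact band can
    exceed QRS-band energy by orders of magnitude), and the log compresses
    that range so PCA modes reflect morphology rather than the single
    loudest band.  The classification pipeline enables it by default.
    """
    if s.energy is None:
        s = scalogram_energy(s)
    n_scales, n_times = target_shape
    if n_scales > s.energy.shape[0] or n_times > s.energy.shape[1]:
        raise ValueError(
            f"target_shape {target_shape} exceeds native {s.energy.shape}")
    energy = np.log(s.energy + log_eps) if log_energy else s.energy
    pooled = _pool_axis(_pool_axis(energy, n_scales, 0), n_times, 1)
    return pooled.reshape(-1, order="F")


def scalogram_to_csv(s: Scalogram, path: str | Path) -> None:
    """Export the energy surface as a matrix CSV (rows = scales)."""
    if s.energy is None:
        s = scalogram_energy(s)
    import pandas as pd

    df = pd.DataFrame(s.energy, index=s.pseudo_frequencies, columns=s.times)
    df.index.name = "pseudo_freq_hz"
    df.to_csv(path)


def plot_scalogram(s: Scalogram, path: str | Path, title: str = "") -> None:
    """Render the energy surface to PNG for visual inspection."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if s.energy is None:
        s = scalogram_energy(s)
    fig, ax = plt.subplots(figsize=(8, 4))
    mesh = ax.pcolormesh(s.times, s.pseudo_frequencies, s.energy,
                         shading="auto", cmap="magma")
    ax.set_yscale("log")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("pseudo-frequency (Hz)")
    if title:
        ax.set_title(title)
    fig.colorbar(mesh, ax=ax, label="energy")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
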