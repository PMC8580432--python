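"""ECG conditioning: resampling and zero-phase Butterworth filtering.

Defibrillator ECGs arrive at 125 or 250 Hz.  The analysis chain fixes the
rate and bandwidth so that no device-dependent frequency content survives:

1. resample to the common 250 Hz rate (polyphase, exact rational factor);
2. low-pass at 40 Hz — the lowest-rate device has a 62.5 Hz Nyquist, so
   capping at 40 Hz guarantees identical usable bandwidth everywhere;
3. band-pass 1-40 Hz with a 4th-order Butterworth applied forward-backward
   (zero net phase), removing drift and high-frequency electrical noise.

Compression artifact (~2 Hz fundamental with harmonics to ~20 Hz) sits
inside the passband by design: it is left for the downstream wavelet/PCA
stages to separate, not filtered out here.

A separate 8th-order 10-40 Hz filter emphasizes QRS complexes for heart
rate estimation, suppressing both the compression fundamental and the slow
P/T waves.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .segments import COMMON_FS, EcgSegment


@dataclass(frozen=True)
class FilterSpec:
    """A Butterworth filter: order, band edges and phase handling.

    ``band`` is ``(low, high)`` in Hz; ``low = 0`` means a pure low-pass.
    ``zero_phase`` selects the forward-backward (filtfilt) implementation.
    """

    order: int = 4
    band: tuple[float, float] = (1.0, 40.0)
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        low, high = self.band
        if not 0 <= low < high:
            raise ValueError(f"band edges must satisfy 0 <= low < high, got {self.band}")

    def sos(self, fs: float) -> np.ndarray:
        low, high = self.band
        if high >= fs / 2.0:
            raise ValueError(
                f"band edge {high} Hz violates Nyquist for fs={fs} Hz")
        if low == 0:
            return signal.butter(self.order, high, btype="lowpass", fs=fs,
                                 output="sos")
        return signal.butter(self.order, [low, high], btype="bandpass", fs=fs,
                             output="sos")


#: default chain, in application order
BANDPASS_SPEC = FilterSpec(order=4, band=(1.0, 40.0))
LOWPASS_SPEC = FilterSpec(order=4, band=(0.0, 40.0))
QRS_EMPHASIS_SPEC = FilterSpec(order=8, band=(10.0, 40.0))


def _apply(seg: EcgSegment, spec: FilterSpec) -> EcgSegment:
    sos = spec.sos(seg.fs)
    if spec.zero_phase:
        # pad past the slowest corner's settle time: the 1 Hz edge rings
        # for ~2 s and the default 3x-order pad would leak transients
        low, high = spec.band
        corner = low if low > 0 else high
        padlen = min(seg.n_samples - 1,
                     max(3 * (2 * spec.order + 1), int(2.0 * seg.fs / corner)))
        y = signal.sosfiltfilt(sos, seg.samples, padlen=padlen)
    else:
        y = signal.sosfilt(sos, seg.samples)
    return seg.with_samples(y)


def resample_to_common_rate(seg: EcgSegment, target_fs: float = COMMON_FS) -> EcgSegment:
    """Polyphase-resample a segment to ``target_fs`` (exact rational factor).

    125 -> 250 Hz is an exact factor-2 upsample; an input already at the
    target rate passes through untouched.
    """
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if seg.fs == target_fs:
        return seg
    frac = Fraction(target_fs / seg.fs).limit_denominator(1000)
    # beta=8 Kaiser: passband ripple < 1e-4 through the 40 Hz analysis band
    y = signal.resample_poly(seg.samples, frac.numerator, frac.denominator,
                             window=("kaiser", 8.0))
    return seg.with_samples(y, fs=target_fs)


def lowpass_antialias(seg: EcgSegment, cutoff: float = 40.0,
                      order: int = 4) -> EcgSegment:
    """Zero-phase Butterworth low-pass bounding bandwidth at ``cutoff`` Hz."""
    if cutoff >= seg.fs / 2.0:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist for fs={seg.fs} Hz")
    return _apply(seg, FilterSpec(order=order, band=(0.0, cutoff)))


def bandpass_filter(seg: EcgSegment, spec: FilterSpec = BANDPASS_SPEC) -> EcgSegment:
    """Zero-phase band-pass; default 4th-order 1-40 Hz.

    Forward-backward application gives zero net phase shift, so in-band
    waveform timing (QRS onsets, peaks) is preserved while DC offset and
    sub-1 Hz drift are removed.
    """
    return _apply(seg, spec)


def qrs_emphasis_filter(seg: EcgSegment) -> EcgSegment:
    """8th-order 10-40 Hz band-pass isolating QRS energy for peak finding."""
    return _apply(seg, QRS_EMPHASIS_SPEC)


def preprocess_segment(seg: EcgSegment, target_fs: float = COMMON_FS,
                       lowpass_cutoff: float = 40.0,
                       bandpass: FilterSpec = BANDPASS_SPEC) -> EcgSegment:
    """Full conditioning chain: resample -> low-pass 40 Hz -> band-pass 1-40 Hz."""
    out = resample_to_common_rate(seg, target_fs)
    out = lowpass_antialias(out, lowpass_cutoff)
    return bandpass_filter(out, bandpass)
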