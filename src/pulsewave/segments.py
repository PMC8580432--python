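"""Core containers for labelled single-lead ECG segments.

A *segment* is a short strip of single-lead ECG (millivolt samples at a
known sampling rate) recorded either during ongoing chest compressions
(``phase="cpr"``) or during the compression pause of a manual pulse check
(``phase="pause"``).  Each pulse check contributes a *pair*: 10 s recorded
during CPR immediately followed by 5 s without CPR, sharing one binary
pulse label.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

PHASE_CPR = "cpr"
PHASE_PAUSE = "pause"
LABEL_PULSE = "pulse"
LABEL_NO_PULSE = "no_pulse"
LABEL_UNKNOWN = "unknown"

#: analysis durations, seconds: 10 s during CPR, 5 s pause
CPR_DURATION_S = 10.0
PAUSE_DURATION_S = 5.0

#: defibrillator sampling rates seen in the field, Hz
DEVICE_RATES = (125.0, 250.0)
#: common analysis rate everything is resampled to, Hz
COMMON_FS = 250.0


@dataclass
class EcgSegment:
    """Single-lead ECG strip with recording phase and pulse label."""

    samples: np.ndarray
    fs: float
    phase: str = PHASE_PAUSE
    label: str = LABEL_UNKNOWN
    patient_id: str = ""
    segment_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-d array")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Segment length in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_samples) / self.fs

    def with_samples(self, samples: np.ndarray, fs: float | None = None) -> "EcgSegment":
        """Copy of this segment with new samples (and optionally new fs)."""
        out = replace(self, samples=np.asarray(samples, dtype=float))
        if fs is not None:
            out.fs = float(fs)
        return out

    # -- CSV interchange ---------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write ``time_s, ecg_mv`` columns; metadata goes in the manifest."""
        pd.DataFrame({"time_s": self.times, "ecg_mv": self.samples}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        fs: float | None = None,
        phase: str = PHASE_PAUSE,
        label: str = LABEL_UNKNOWN,
        patient_id: str = "",
        segment_id: str = "",
    ) -> "EcgSegment":
        """Read a segment CSV; fs is inferred from the time column if omitted."""
        df = pd.read_csv(path)
        if "ecg_mv" not in df.columns:
            raise ValueError(f"{path}: expected an 'ecg_mv' column")
        if fs is None:
            t = df["time_s"].to_numpy()
            if t.size < 2:
                raise ValueError(f"{path}: cannot infer fs from <2 samples")
            fs = 1.0 / float(np.median(np.diff(t)))
        return cls(
            samples=df["ecg_mv"].to_numpy(),
            fs=float(fs),
            phase=phase,
            label=label,
            patient_id=patient_id,
            segment_id=segment_id,
        )


@dataclass
class SegmentPair:
    """One pulse check: 10 s during-CPR strip + adjacent 5 s pause strip.

    Both halves share the patient, the underlying rhythm morphology and the
    pulse label; the beat phase is continuous across the boundary.
    """

    cpr: EcgSegment
    pause: EcgSegment

    def __post_init__(self) -> None:
        if self.cpr.label != self.pause.label:
            raise ValueError("pair halves must share one pulse label")
        if self.cpr.phase != PHASE_CPR or self.pause.phase != PHASE_PAUSE:
            raise ValueError("pair must be (cpr, pause) in that order")

    @property
    def label(self) -> str:
        return self.cpr.label

    @property
    def patient_id(self) -> str:
        return self.cpr.patient_id

    def segments(self) -> tuple[EcgSegment, EcgSegment]:
        return (self.cpr, self.pause)
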