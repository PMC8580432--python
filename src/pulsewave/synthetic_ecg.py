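"""Synthetic ECG cohorts with CPR compression artifact.

The clinical recordings this pipeline was designed around — defibrillator
ECG from out-of-hospital cardiac arrest with paired during-CPR / pulse-check
segments — are not publicly deposited, so this module synthesizes cohorts
with the same structure:

* each pulse check yields a 10 s during-CPR strip immediately followed by a
  5 s compression-pause strip, with the beat train continuous across the
  boundary and a single pulse label shared by the pair;
* at most three periods per category (pulse / no-pulse) per patient;
* roughly 38% of checks carry a spontaneous pulse;
* device sampling rates of 125 or 250 Hz;
* a patient-level 60/40 train/test split.

The two classes differ in QRS width, amplitude and rate: perfusing rhythms
are rendered with narrower, taller QRS complexes at a faster rate than
pulseless electrical activity.  Chest-compression artifact is a quasi-
periodic harmonic series concentrated at the manual compression rate
(~2 Hz) with overtones reaching ~20 Hz, overlapping the QRS band.

Beat morphology is a sum of parametric waves per cardiac cycle: the QRS is
a biphasic Gaussian-derivative pulse, and P/T waves are Gaussian bumps at
fixed fractional offsets of the RR interval.  This captures the sharp QRS
deflection and the dome-like P/T structure without an electrophysiological
heart model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .segments import (
    COMMON_FS,
    CPR_DURATION_S,
    DEVICE_RATES,
    LABEL_NO_PULSE,
    LABEL_PULSE,
    PAUSE_DURATION_S,
    PHASE_CPR,
    PHASE_PAUSE,
    EcgSegment,
    SegmentPair,
)

# fractional RR offsets / widths of the P and T waves relative to the QRS
_P_OFFSET_FRAC = -0.20  # P wave precedes the QRS
_T_OFFSET_FRAC = 0.35  # T wave follows it
_P_SIGMA_S = 0.025
_T_SIGMA_S = 0.050


@dataclass(frozen=True)
class MorphologyParams:
    """Per-rhythm beat morphology.

    heart_rate          beats per minute
    qrs_width           full QRS duration, seconds
    qrs_amplitude       peak QRS deflection, mV
    p_amplitude         P-wave peak, mV
    t_amplitude         T-wave peak, mV
    rr_jitter_sd        SD of per-beat RR-interval jitter, seconds
    """

    heart_rate: float = 75.0
    qrs_width: float = 0.10
    qrs_amplitude: float = 1.0
    p_amplitude: float = 0.15
    t_amplitude: float = 0.30
    rr_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if not self.heart_rate > 0:
            raise ValueError("heart_rate must be positive")
        if not 0 < self.qrs_width < 60.0 / self.heart_rate:
            raise ValueError("qrs_width must lie in (0, RR interval)")
        for name in ("qrs_amplitude", "p_amplitude", "t_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.rr_jitter_sd < 0:
            raise ValueError("rr_jitter_sd must be >= 0")

    @property
    def rr_interval(self) -> float:
        return 60.0 / self.heart_rate


#: class presets: perfusing rhythms have narrow, tall, fast QRS complexes
PULSE_PRESET = MorphologyParams(
    heart_rate=90.0,
    qrs_width=0.08,
    qrs_amplitude=1.0,
    p_amplitude=0.15,
    t_amplitude=0.30,
    rr_jitter_sd=0.02,
)
#: pulseless electrical activity: wide, low-amplitude, slow
NO_PULSE_PRESET = MorphologyParams(
    heart_rate=45.0,
    qrs_width=0.16,
    qrs_amplitude=0.5,
    p_amplitude=0.10,
    t_amplitude=0.20,
    rr_jitter_sd=0.04,
)


@dataclass(frozen=True)
class ArtifactParams:
    """Chest-compression artifact: harmonic series at the compression rate.

    compression_rate      fundamental, Hz (manual CPR ~100-120/min => ~2 Hz)
    fundamental_amplitude amplitude of the fundamental, mV
    n_harmonics           number of overtones beyond the fundamental
    harmonic_decay        amplitude ratio between successive harmonics
    phase_jitter_sd       per-compression-cycle phase jitter, radians
    amplitude_jitter_sd   lognormal SD of per-cycle compression depth

    Phase and depth jitter model the rescuer's cycle-to-cycle variability;
    both vary smoothly between cycle centers, and zero jitter recovers an
    exactly periodic harmonic series.
    """

    compression_rate: float = 2.0
    fundamental_amplitude: float = 2.0
    n_harmonics: int = 9
    harmonic_decay: float = 0.5
    phase_jitter_sd: float = 0.3
    amplitude_jitter_sd: float = 0.15

    def __post_init__(self) -> None:
        if not self.compression_rate > 0:
            raise ValueError("compression_rate must be positive")
        if self.n_harmonics < 0:
            raise ValueError("n_harmonics must be >= 0")
        if not 0 <= self.harmonic_decay <= 1:
            raise ValueError("harmonic_decay must lie in [0, 1]")
        if min(self.fundamental_amplitude, self.phase_jitter_sd,
               self.amplitude_jitter_sd) < 0:
            raise ValueError("amplitudes and jitter must be >= 0")


@dataclass(frozen=True)
class NoiseParams:
    """Baseline wander plus white measurement noise."""

    baseline_drift_amplitude: float = 0.2
    baseline_drift_freq: float = 0.3
    white_noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if min(self.baseline_drift_amplitude, self.baseline_drift_freq,
               self.white_noise_sd) < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.baseline_drift_freq >= 1.0:
            raise ValueError("baseline drift must stay below the 1 Hz passband edge")


def _wave_shapes(times: np.ndarray, centers: np.ndarray, rr: float,
                 p: MorphologyParams) -> np.ndarray:
    """Sum P-QRS-T contributions of every beat onto the sample grid."""
    x = np.zeros_like(times)
    sigma_q = p.qrs_width / 4.0  # +-2 sigma spans the stated QRS width
    for tc in centers:
        if p.qrs_amplitude > 0:
            u = (times - tc) / sigma_q
            # biphasic Gaussian derivative, peak normalized to qrs_amplitude
            x += p.qrs_amplitude * (-u) * np.exp(0.5 * (1.0 - u * u))
        if p.p_amplitude > 0:
            up = (times - (tc + _P_OFFSET_FRAC * rr)) / _P_SIGMA_S
            x += p.p_amplitude * np.exp(-0.5 * up * up)
        if p.t_amplitude > 0:
            ut = (times - (tc + _T_OFFSET_FRAC * rr)) / _T_SIGMA_S
            x += p.t_amplitude * np.exp(-0.5 * ut * ut)
    return x


def generate_beat_train(
    params: MorphologyParams,
    duration: float,
    fs: float,
    rng_seed: int | np.random.Generator = 0,
) -> EcgSegment:
    """Synthesize ``duration`` seconds of organized rhythm at ``fs`` Hz.

    Beats are laid down at quasi-regular RR intervals (cumulative Gaussian
    jitter of SD ``rr_jitter_sd`` per interval), the first beat half an RR
    interval into the strip, giving ``floor(duration * heart_rate / 60)``
    (+-1 under jitter) QRS complexes.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator) else rng_seed

    n = int(round(duration * fs))
    times = np.arange(n) / fs
    rr = params.rr_interval

    centers = []
    t = rr / 2.0
    while t < duration:
        centers.append(t)
        step = rr
        if params.rr_jitter_sd > 0:
            step = max(0.2 * rr, step + rng.normal(0.0, params.rr_jitter_sd))
        t += step
    x = _wave_shapes(times, np.asarray(centers), rr, params)
    return EcgSegment(samples=x, fs=fs, phase=PHASE_PAUSE)


def add_cpr_artifact(
    seg: EcgSegment,
    params: ArtifactParams,
    rng_seed: int | np.random.Generator = 0,
) -> EcgSegment:
    """Superimpose quasi-periodic compression artifact on a segment.

    The artifact is ``sum_k A_k sin(2 pi k f0 t + k phi_c)`` over harmonics
    ``k = 1 .. n_harmonics + 1`` with geometrically decaying amplitudes
    ``A_k = A * decay**(k-1)``; the phase offset ``phi_c`` is redrawn every
    compression cycle so the artifact is quasi- rather than strictly
    periodic.  Harmonics at or above Nyquist are dropped.
    """
    if seg.n_samples == 0:
        raise ValueError("segment is empty")
    f0 = params.compression_rate
    if f0 >= seg.fs / 2.0:
        raise ValueError(
            f"compression rate {f0} Hz would alias at fs={seg.fs} Hz"
        )
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator) else rng_seed

    t = seg.times
    # one phase offset per compression cycle (quasi-periodicity), varied
    # smoothly between cycle centers: manual CPR drifts, it does not jump,
    # and stepped phases would inject non-physiologic broadband clicks
    n_cycles = int(np.floor(t[-1] * f0)) + 1
    base_phase = rng.uniform(0.0, 2.0 * np.pi)
    offsets = base_phase + rng.normal(0.0, params.phase_jitter_sd, size=n_cycles)
    centers = np.arange(n_cycles) + 0.5
    phi = np.interp(t * f0, centers, offsets)
    # per-cycle compression depth (lognormal), also smoothly varying
    depths = np.exp(rng.normal(0.0, params.amplitude_jitter_sd, size=n_cycles)) \
        if params.amplitude_jitter_sd > 0 else np.ones(n_cycles)
    envelope = np.interp(t * f0, centers, depths)

    artifact = np.zeros_like(t)
    for k in range(1, params.n_harmonics + 2):
        fk = k * f0
        if fk >= seg.fs / 2.0:
            break
        amp = params.fundamental_amplitude * params.harmonic_decay ** (k - 1)
        artifact += amp * np.sin(2.0 * np.pi * fk * t + k * phi)
    return seg.with_samples(seg.samples + envelope * artifact)


def _add_noise(x: np.ndarray, t: np.ndarray, noise: NoiseParams,
               rng: np.random.Generator) -> np.ndarray:
    out = x.copy()
    if noise.baseline_drift_amplitude > 0:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        out += noise.baseline_drift_amplitude * np.sin(
            2.0 * np.pi * noise.baseline_drift_freq * t + phase)
    if noise.white_noise_sd > 0:
        out += rng.normal(0.0, noise.white_noise_sd, size=t.size)
    return out


def generate_segment_pair(
    morph: MorphologyParams,
    artifact: ArtifactParams,
    noise: NoiseParams,
    fs: float = COMMON_FS,
    rng_seed: int | np.random.Generator = 0,
    label: str = LABEL_PULSE,
    patient_id: str = "",
    segment_id: str = "",
) -> SegmentPair:
    """One simulated pulse check: 10 s during CPR + adjacent 5 s pause.

    A single continuous 15 s beat train is synthesized and split, so the
    cardiac phase carries across the boundary; compression artifact is
    added only to the during-CPR half.
    """
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator) else rng_seed
    total = CPR_DURATION_S + PAUSE_DURATION_S
    train = generate_beat_train(morph, total, fs, rng)
    x = _add_noise(train.samples, train.times, noise, rng)

    n_cpr = int(round(CPR_DURATION_S * fs))
    cpr = EcgSegment(x[:n_cpr], fs, phase=PHASE_CPR, label=label,
                     patient_id=patient_id, segment_id=f"{segment_id}_cpr")
    cpr = add_cpr_artifact(cpr, artifact, rng)
    pause = EcgSegment(x[n_cpr:], fs, phase=PHASE_PAUSE, label=label,
                       patient_id=patient_id, segment_id=f"{segment_id}_pause")
    return SegmentPair(cpr=cpr, pause=pause)


@dataclass(frozen=True)
class CohortSpec:
    """Study-level simulation settings.

    Each simulated patient receives 1..2*max_periods_per_category pulse
    checks (mean ~2, matching the clinical median), each independently
    labelled pulse with probability ``pulse_fraction`` and capped at
    ``max_periods_per_category`` checks per label.  Patient morphology is
    the class preset perturbed by per-patient lognormal variation.
    """

    n_patients: int = 100
    max_periods_per_category: int = 3
    pulse_fraction: float = 0.38
    device_rates: tuple[float, ...] = DEVICE_RATES
    class_params: dict = field(default_factory=lambda: {
        LABEL_PULSE: PULSE_PRESET,
        LABEL_NO_PULSE: NO_PULSE_PRESET,
    })
    artifact: ArtifactParams = field(default_factory=ArtifactParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    morphology_variation_sd: float = 0.10  # lognormal sd of patient factors
    train_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0 <= self.pulse_fraction <= 1:
            raise ValueError("pulse_fraction must lie in [0, 1]")
        if self.max_periods_per_category < 1:
            raise ValueError("max_periods_per_category must be >= 1")
        if not set(self.device_rates) <= set(DEVICE_RATES):
            raise ValueError(f"device_rates must be a subset of {DEVICE_RATES}")


class CohortRecord(NamedTuple):
    patient_id: str
    pair: SegmentPair
    label: str


@dataclass
class Cohort:
    """Simulated study cohort with a patient-level train/test split."""

    records: list[CohortRecord]
    train_ids: set[str]
    test_ids: set[str]
    spec: CohortSpec

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def split_of(self, patient_id: str) -> str:
        return "train" if patient_id in self.train_ids else "test"


def _patient_morphology(base: MorphologyParams, factors: np.ndarray) -> MorphologyParams:
    """Apply per-patient lognormal factors to rate, width and amplitudes."""
    rate = base.heart_rate * factors[0]
    width = min(base.qrs_width * factors[1], 0.9 * 60.0 / rate)
    return replace(
        base,
        heart_rate=rate,
        qrs_width=width,
        qrs_amplitude=base.qrs_amplitude * factors[2],
        p_amplitude=base.p_amplitude * factors[2],
        t_amplitude=base.t_amplitude * factors[2],
    )


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Simulate a labelled cohort of segment pairs, reproducibly from seed."""
    root = np.random.SeedSequence(spec.seed)
    cohort_ss, *patient_ss = root.spawn(spec.n_patients + 1)
    cohort_rng = np.random.default_rng(cohort_ss)

    records: list[CohortRecord] = []
    patient_ids = [f"P{i:04d}" for i in range(spec.n_patients)]
    max_per = spec.max_periods_per_category
    for pid, ss in zip(patient_ids, patient_ss):
        rng = np.random.default_rng(ss)
        fs = float(rng.choice(np.asarray(spec.device_rates)))
        factors = np.exp(rng.normal(0.0, spec.morphology_variation_sd, size=3))
        n_checks = min(1 + rng.poisson(1.2), 2 * max_per)
        counts = {lab: 0 for lab in spec.class_params}
        for j in range(n_checks):
            label = (LABEL_PULSE if rng.uniform() < spec.pulse_fraction
                     else LABEL_NO_PULSE)
            if counts[label] >= max_per:
                continue
            counts[label] += 1
            morph = _patient_morphology(spec.class_params[label], factors)
            pair = generate_segment_pair(
                morph, spec.artifact, spec.noise, fs=fs, rng_seed=rng,
                label=label, patient_id=pid, segment_id=f"{pid}_c{j}",
            )
            records.append(CohortRecord(pid, pair, label))

    order = cohort_rng.permutation(spec.n_patients)
    n_train = int(round(spec.train_fraction * spec.n_patients))
    train_ids = {patient_ids[i] for i in order[:n_train]}
    test_ids = {patient_ids[i] for i in order[n_train:]}
    return Cohort(records=records, train_ids=train_ids, test_ids=test_ids,
                  spec=spec)


# -- CSV export / manifest ---------------------------------------------------

MANIFEST_COLUMNS = ["patient_id", "segment_id", "phase", "label", "fs_hz",
                    "split", "file"]


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write one CSV per segment plus a cohort manifest; returns manifest path."""
    out = Path(out_dir)
    seg_dir = out / "segments"
    seg_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for pid, pair, label in cohort.records:
        for seg in pair.segments():
            fname = f"{seg.segment_id}.csv"
            seg.to_csv(seg_dir / fname)
            rows.append({
                "patient_id": pid,
                "segment_id": seg.segment_id,
                "phase": seg.phase,
                "label": label,
                "fs_hz": seg.fs,
                "split": cohort.split_of(pid),
                "file": f"segments/{fname}",
            })
    manifest = out / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


def load_manifest(manifest_path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(manifest_path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


def load_segments(manifest_path: str | Path,
                  rows: pd.DataFrame | None = None) -> list[EcgSegment]:
    """Load the segments referenced by (a subset of) a cohort manifest."""
    root = Path(manifest_path).parent
    df = load_manifest(manifest_path) if rows is None else rows
    segs = []
    for _, r in df.iterrows():
        segs.append(EcgSegment.from_csv(
            root / r["file"], fs=float(r["fs_hz"]), phase=r["phase"],
            label=r["label"], patient_id=r["patient_id"],
            segment_id=r["segment_id"],
        ))
    return segs
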