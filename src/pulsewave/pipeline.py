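"""End-to-end pipeline: simulate -> preprocess -> featurize -> train ->
evaluate -> predict.

A cohort manifest CSV is the single source of truth for segment files,
phases, labels and the patient-level train/test split.  Training fits two
independent phase-specific models — one for 10 s during-CPR strips, one
for 5 s pause strips — each consisting of a PCA feature basis and a
classifier, and archives them together with the full configuration and
its hash.  Prediction re-runs the identical conditioning/featurization
chain (asserted via the config hash) and projects onto the archived
basis, so no test datum can influence any fitted statistic.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pickle
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import synthetic_ecg as synth
from .evaluation import CvResult, EvalReport, cv_auc, evaluate_scores, \
    optimal_operating_point, roc_auc
from .models import TrainedClassifier, fit_classifier, predict_score
from .preprocess import FilterSpec, preprocess_segment
from .segments import COMMON_FS, DEVICE_RATES, EcgSegment, PHASE_CPR, PHASE_PAUSE
from .wavelet import WaveletSpec, cwt, scalogram_to_vector

logger = logging.getLogger("pulsewave")

PHASES = (PHASE_CPR, PHASE_PAUSE)
MIN_PREDICT_DURATION_S = 2.0


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the pipeline, serializable to YAML and hashable."""

    target_fs: float = COMMON_FS
    lowpass_cutoff: float = 40.0
    lowpass_order: int = 4
    bandpass_order: int = 4
    bandpass_band: tuple[float, float] = (1.0, 40.0)
    wavelet_name: str = "bump"
    wavelet_center: float = 5.0
    wavelet_width: float = 0.6
    wavelet_voices: int = 10
    wavelet_freq_range: tuple[float, float] = (0.5, 40.0)
    wavelet_pad_tail_mult: float = 16.0
    pooling_shape: tuple[int, int] = (64, 128)
    log_energy: bool = True
    pca_cutoff: float = 0.01
    pca_max_modes: int = 10
    pca_r: int | None = 3
    pca_normalize: bool = True
    model_kind: str = "lda"
    eval_bootstrap_B: int = 2000
    eval_cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bandpass_band[1] >= self.target_fs / 2:
            raise ValueError("bandpass upper edge must stay below Nyquist")
        if self.wavelet_freq_range[1] > self.target_fs / 2:
            raise ValueError("wavelet grid must stay below Nyquist")
        if self.pca_r is not None and self.pca_r > self.pca_max_modes:
            raise ValueError("pca_r cannot exceed pca_max_modes")

    # -- derived specs ------------------------------------------------------

    def wavelet_spec(self) -> WaveletSpec:
        return WaveletSpec(
            name=self.wavelet_name, center=self.wavelet_center,
            width=self.wavelet_width, voices_per_octave=self.wavelet_voices,
            freq_range=tuple(self.wavelet_freq_range),
            pad_tail_mult=self.wavelet_pad_tail_mult,
        )

    def bandpass_spec(self) -> FilterSpec:
        return FilterSpec(order=self.bandpass_order,
                          band=tuple(self.bandpass_band))

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    # -- YAML ---------------------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("bandpass_band", "wavelet_freq_range", "pooling_shape"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def featurize_segment(seg: EcgSegment, config: PipelineConfig) -> np.ndarray:
    """Conditioning chain + scalogram + pooling for one segment."""
    if seg.fs < min(DEVICE_RATES) or seg.fs > max(DEVICE_RATES):
        raise ValueError(
            f"sampling rate {seg.fs} Hz outside supported device range "
            f"{DEVICE_RATES}")
    if seg.duration < MIN_PREDICT_DURATION_S:
        raise ValueError(
            f"segment of {seg.duration:.2f} s is insufficient "
            f"(need >= {MIN_PREDICT_DURATION_S} s)")
    clean = preprocess_segment(seg, target_fs=config.target_fs,
                               lowpass_cutoff=config.lowpass_cutoff,
                               bandpass=config.bandpass_spec())
    scal = cwt(clean, config.wavelet_spec())
    return scalogram_to_vector(scal, tuple(config.pooling_shape),
                               log_energy=config.log_energy)


@dataclass
class FeatureTable:
    """Featurized segments of one phase."""

    X: np.ndarray  # n_samples x m pixels
    segment_ids: list[str]
    labels: np.ndarray  # binary, 1 = pulse
    patients: np.ndarray


def featurize_phase(segments: list[EcgSegment],
                    config: PipelineConfig) -> FeatureTable:
    rows, ids, labels, patients = [], [], [], []
    for seg in segments:
        rows.append(featurize_segment(seg, config))
        ids.append(seg.segment_id)
        labels.append(1 if seg.label == "pulse" else 0)
        patients.append(seg.patient_id)
    return FeatureTable(X=np.vstack(rows), segment_ids=ids,
                        labels=np.asarray(labels),
                        patients=np.asarray(patients))


def _phase_segments(manifest_path: str | Path, split: str | None,
                    phase: str) -> list[EcgSegment]:
    df = synth.load_manifest(manifest_path)
    sel = df[df["phase"] == phase]
    if split is not None:
        sel = sel[sel["split"] == split]
    return synth.load_segments(manifest_path, sel)


@dataclass
class TrainResult:
    basis: dict
    model: dict
    cv: dict
    train_scores: dict
    archive_dir: Path


def run_train(config: PipelineConfig, manifest_path: str | Path,
              out_dir: str | Path) -> TrainResult:
    """Fit phase-specific feature bases + classifiers on the train split.

    Archives, per phase: the basis (``basis_<phase>.npz``), the classifier
    (``model_<phase>.pkl``), train-time scores and a CV report; plus the
    config YAML and a meta record with the config hash and class counts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    bases, mdls, cvs, scores_all = {}, {}, {}, {}
    meta = {"config_hash": chash, "seed": config.seed, "counts": {}}

    for phase in PHASES:
        segs = _phase_segments(manifest_path, "train", phase)
        if not segs:
            raise ValueError(f"train split has no {phase} segments")
        table = featurize_phase(segs, config)
        n_pos = int(table.labels.sum())
        if n_pos == 0 or n_pos == table.labels.size:
            raise ValueError(f"train split is single-class for {phase}")
        meta["counts"][phase] = {
            "n_segments": int(table.labels.size), "n_pulse": n_pos,
            "n_patients": int(len(np.unique(table.patients))),
        }
        logger.info("train %s: %d segments (%d pulse) from %d patients",
                    phase, table.labels.size, n_pos,
                    meta["counts"][phase]["n_patients"])

        basis = feat.fit_feature_basis(
            feat.ScalogramMatrix(table.X.T, table.segment_ids),
            cutoff=config.pca_cutoff, max_modes=config.pca_max_modes,
            r_fixed=config.pca_r, normalize=config.pca_normalize)
        coords = feat.project_matrix(basis, table.X)
        model = fit_classifier(config.model_kind, coords, table.labels,
                               seed=config.seed)
        train_scores = predict_score(model, coords)
        model.threshold, _, _ = optimal_operating_point(train_scores,
                                                        table.labels)
        cv = cv_auc(table.X, table.labels, table.patients,
                    k=config.eval_cv_folds, model_kind=config.model_kind,
                    seed=config.seed, cutoff=config.pca_cutoff,
                    max_modes=config.pca_max_modes, r_fixed=config.pca_r,
                    normalize=config.pca_normalize)
        logger.info("train %s: CV AUC %.3f (folds %s)", phase, cv.mean_auc,
                    [f"{a:.3f}" for a in cv.fold_aucs])

        feat.save_basis(basis, out / f"basis_{phase}.npz", config_hash=chash)
        with open(out / f"model_{phase}.pkl", "wb") as fh:
            pickle.dump(model, fh)
        pd.DataFrame({
            "segment_id": table.segment_ids,
            "patient_id": table.patients,
            "label": table.labels,
            "score": train_scores,
        }).to_csv(out / f"train_scores_{phase}.csv", index=False)
        with open(out / f"cv_{phase}.json", "w") as fh:
            json.dump({"mean_auc": cv.mean_auc, "fold_aucs": cv.fold_aucs},
                      fh, indent=2)
        bases[phase], mdls[phase], cvs[phase] = basis, model, cv
        scores_all[phase] = train_scores

    config.to_yaml(out / "config.yaml")
    with open(out / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    return TrainResult(basis=bases, model=mdls, cv=cvs,
                       train_scores=scores_all, archive_dir=out)


def load_archive(archive_dir: str | Path, phase: str):
    """Load (config, basis, model) for one phase from a train archive."""
    arch = Path(archive_dir)
    config = PipelineConfig.from_yaml(arch / "config.yaml")
    basis, stored_hash = feat.load_basis(arch / f"basis_{phase}.npz")
    if stored_hash != config.config_hash():
        raise ValueError("archive config hash mismatch; refusing to predict "
                         "with a different preprocessing chain")
    with open(arch / f"model_{phase}.pkl", "rb") as fh:
        model = pickle.load(fh)
    return config, basis, model


def run_predict(archive_dir: str | Path, segments: list[EcgSegment],
                phase: str, out_csv: str | Path | None = None) -> pd.DataFrame:
    """Score segments with an archived phase-specific model.

    Refuses segments whose recorded phase conflicts with the model's
    phase; featurization is identical to the training path.
    """
    if phase not in PHASES:
        raise ValueError(f"phase must be one of {PHASES}")
    config, basis, model = load_archive(archive_dir, phase)
    rows = []
    for seg in segments:
        if seg.phase and seg.phase != phase:
            raise ValueError(
                f"segment {seg.segment_id!r} is phase {seg.phase!r}; this "
                f"model was trained for {phase!r} segments")
        x = featurize_segment(seg, config)
        score = predict_score(model, feat.project(basis, x).coords)
        rows.append({
            "segment_id": seg.segment_id, "patient_id": seg.patient_id,
            "phase": phase, "score": score,
            "pulse_call": int(score > model.threshold),
        })
    df = pd.DataFrame(rows)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df


def run_evaluate(archive_dir: str | Path, manifest_path: str | Path,
                 split: str = "test", out_dir: str | Path | None = None
                 ) -> dict[str, EvalReport]:
    """Evaluate archived models on a manifest split; one report per phase."""
    reports = {}
    for phase in PHASES:
        config, basis, model = load_archive(archive_dir, phase)
        segs = _phase_segments(manifest_path, split, phase)
        if not segs:
            raise ValueError(f"{split} split has no {phase} segments")
        preds = run_predict(archive_dir, segs, phase)
        labels = [seg.label for seg in segs]
        report = evaluate_scores(preds["score"].to_numpy(), labels,
                                 B=config.eval_bootstrap_B, seed=config.seed)
        logger.info("%s %s: AUC %.3f (%.3f, %.3f) sens %.2f spec %.2f",
                    split, phase, report.auc, *report.ci,
                    report.sensitivity, report.specificity)
        if out_dir is not None:
            outp = Path(out_dir)
            outp.mkdir(parents=True, exist_ok=True)
            report.to_json(outp / f"eval_{phase}.json")
            preds.to_csv(outp / f"scores_{split}_{phase}.csv", index=False)
        reports[phase] = report
    return reports


def run_benchmark(config: PipelineConfig, manifest_path: str | Path,
                  wavelet_names: list[str] | None = None,
                  wavelet_specs: dict[str, WaveletSpec] | None = None,
                  model_kinds: list[str] = ("lda",),
                  out_csv: str | Path | None = None) -> pd.DataFrame:
    """Grid of train-split CV AUCs over wavelets x models x phases.

    ``wavelet_specs`` maps a display name to a full WaveletSpec (e.g. a
    degraded grid); ``wavelet_names`` is shorthand for registered mother
    wavelets at the config's grid settings.
    """
    specs: dict[str, WaveletSpec] = {}
    for name in (wavelet_names or []):
        specs[name] = replace(config.wavelet_spec(), name=name)
    specs.update(wavelet_specs or {})
    if not specs or not model_kinds:
        raise ValueError("need at least one wavelet and one model kind")

    rows = []
    for wname, wspec in specs.items():
        # narrow grids have fewer scales than the default pooling rows
        pool = (min(config.pooling_shape[0], wspec.scales().size),
                config.pooling_shape[1])
        cfg = replace(
            config, wavelet_name=wspec.name, wavelet_center=wspec.center,
            wavelet_width=wspec.width, wavelet_voices=wspec.voices_per_octave,
            wavelet_freq_range=tuple(wspec.freq_range),
            wavelet_pad_tail_mult=wspec.pad_tail_mult,
            pooling_shape=pool)
        for phase in PHASES:
            table = featurize_phase(
                _phase_segments(manifest_path, "train", phase), cfg)
            for kind in model_kinds:
                cv = cv_auc(table.X, table.labels, table.patients,
                            k=cfg.eval_cv_folds, model_kind=kind,
                            seed=cfg.seed, cutoff=cfg.pca_cutoff,
                            max_modes=cfg.pca_max_modes, r_fixed=cfg.pca_r,
                            normalize=cfg.pca_normalize)
                rows.append({"wavelet": wname, "model": kind, "phase": phase,
                             "cv_auc": cv.mean_auc, "seed": cfg.seed})
    df = pd.DataFrame(rows).sort_values(
        ["phase", "wavelet", "model"]).reset_index(drop=True)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df
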