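"""Synthetic ECG/CPR-artifact generator: structure, spectra, determinism."""

import numpy as np
import pytest
from scipy import signal as sps

import pulsewave as pw
from pulsewave.synthetic_ecg import (
    ArtifactParams,
    CohortSpec,
    MorphologyParams,
    NoiseParams,
    add_cpr_artifact,
    generate_beat_train,
    generate_cohort,
    generate_segment_pair,
)
from _oracles import count_halfmax_peaks

QUIET = NoiseParams(baseline_drift_amplitude=0.0, white_noise_sd=0.0)
NO_ARTIFACT = ArtifactParams(fundamental_amplitude=0.0, phase_jitter_sd=0.0)


class TestBeatTrain:
    def test_sample_count_matches_duration(self):
        seg = generate_beat_train(
            MorphologyParams(heart_rate=60, rr_jitter_sd=0.0), 10.0, 250.0)
        assert seg.n_samples == 2500
        assert seg.duration == 10.0

    def test_zero_amplitudes_give_flatline(self):
        p = MorphologyParams(qrs_amplitude=0, p_amplitude=0, t_amplitude=0)
        seg = generate_beat_train(p, 5.0, 250.0)
        assert np.all(seg.samples == 0.0)

    def test_qrs_count_matches_rate(self):
        # 90 bpm over 10 s -> 15 complexes, counted by a half-max peak scan
        p = MorphologyParams(heart_rate=90, qrs_width=0.08, qrs_amplitude=1.0,
                             p_amplitude=0.1, t_amplitude=0.2,
                             rr_jitter_sd=0.0)
        seg = generate_beat_train(p, 10.0, 250.0)
        assert count_halfmax_peaks(seg.samples, min_sep=25) == 15

    @pytest.mark.parametrize("duration,fs", [(0.0, 250.0), (-1.0, 250.0),
                                             (10.0, 0.0)])
    def test_invalid_arguments_rejected(self, duration, fs):
        with pytest.raises(ValueError):
            generate_beat_train(MorphologyParams(), duration, fs)

    def test_morphology_invariants_enforced(self):
        with pytest.raises(ValueError):
            MorphologyParams(heart_rate=0)
        with pytest.raises(ValueError):
            MorphologyParams(heart_rate=60, qrs_width=1.5)  # > RR interval
        with pytest.raises(ValueError):
            MorphologyParams(qrs_amplitude=-1)


class TestCprArtifact:
    def test_zero_amplitude_is_identity(self):
        seg = generate_beat_train(MorphologyParams(), 5.0, 250.0)
        out = add_cpr_artifact(seg, ArtifactParams(fundamental_amplitude=0.0))
        assert np.array_equal(out.samples, seg.samples)

    def test_spectral_peak_at_compression_rate(self):
        # pure artifact on a zero signal: periodogram argmax at 2 Hz
        seg = pw.EcgSegment(np.zeros(2500), 250.0)
        out = add_cpr_artifact(
            seg, ArtifactParams(compression_rate=2.0, n_harmonics=1,
                                phase_jitter_sd=0.0), rng_seed=3)
        f, pxx = sps.periodogram(out.samples, fs=250.0)
        assert abs(f[np.argmax(pxx)] - 2.0) < 0.2

    def test_artifact_preserves_qrs_count_after_bandpass(self):
        p = MorphologyParams(heart_rate=90, qrs_width=0.08, qrs_amplitude=1.0,
                             rr_jitter_sd=0.0)
        clean = generate_beat_train(p, 10.0, 250.0)
        n_before = count_halfmax_peaks(
            pw.qrs_emphasis_filter(clean).samples, min_sep=25)
        noisy = add_cpr_artifact(clean, ArtifactParams(), rng_seed=5)
        filtered = pw.qrs_emphasis_filter(pw.bandpass_filter(noisy))
        assert count_halfmax_peaks(filtered.samples, min_sep=25) == n_before

    def test_aliasing_rate_rejected(self):
        seg = generate_beat_train(MorphologyParams(), 5.0, 125.0)
        with pytest.raises(ValueError, match="alias"):
            add_cpr_artifact(seg, ArtifactParams(compression_rate=70.0))


class TestSegmentPair:
    def test_durations_and_sample_counts(self):
        pair = generate_segment_pair(MorphologyParams(), ArtifactParams(),
                                     NoiseParams(), fs=250.0, rng_seed=0)
        assert pair.cpr.n_samples == 2500
        assert pair.pause.n_samples == 1250
        assert pair.cpr.duration + pair.pause.duration == 15.0

    def test_clean_cpr_half_equals_pure_beat_train(self):
        p = MorphologyParams(rr_jitter_sd=0.0)
        pair = generate_segment_pair(p, NO_ARTIFACT, QUIET, fs=250.0,
                                     rng_seed=0)
        train = generate_beat_train(p, 15.0, 250.0, rng_seed=0)
        assert np.allclose(pair.cpr.samples, train.samples[:2500])
        assert np.allclose(pair.pause.samples, train.samples[2500:])

    def test_beat_phase_continuous_across_boundary(self):
        # beat centers continue at the same RR spacing across the split
        p = MorphologyParams(heart_rate=60, rr_jitter_sd=0.0,
                             p_amplitude=0.0, t_amplitude=0.0)
        pair = generate_segment_pair(p, NO_ARTIFACT, QUIET, fs=250.0)
        full = np.concatenate([pair.cpr.samples, pair.pause.samples])
        thr = 0.5 * np.abs(full).max()
        locs, _ = sps.find_peaks(full, height=thr, distance=100)
        assert np.allclose(np.diff(locs) / 250.0, 1.0, atol=0.01)

    def test_same_seed_reproduces_pair(self):
        a = generate_segment_pair(MorphologyParams(), ArtifactParams(),
                                  NoiseParams(), rng_seed=42)
        b = generate_segment_pair(MorphologyParams(), ArtifactParams(),
                                  NoiseParams(), rng_seed=42)
        assert np.array_equal(a.cpr.samples, b.cpr.samples)
        assert np.array_equal(a.pause.samples, b.pause.samples)


class TestCohort:
    def test_pulse_fraction_within_binomial_interval(self):
        cohort = generate_cohort(CohortSpec(n_patients=100,
                                            pulse_fraction=0.38, seed=11))
        frac = np.mean([r.label == "pulse" for r in cohort])
        assert 0.28 <= frac <= 0.48

    def test_per_patient_label_cap(self, small_cohort):
        counts: dict = {}
        for pid, _, label in small_cohort:
            counts[(pid, label)] = counts.get((pid, label), 0) + 1
        assert max(counts.values()) <= 3

    def test_split_partitions_patients(self, small_cohort, small_spec):
        assert small_cohort.train_ids.isdisjoint(small_cohort.test_ids)
        union = small_cohort.train_ids | small_cohort.test_ids
        assert len(union) == small_spec.n_patients
        assert {r.patient_id for r in small_cohort} <= union

    def test_byte_identical_given_seed(self, small_spec):
        a = generate_cohort(small_spec)
        b = generate_cohort(small_spec)
        assert a.train_ids == b.train_ids
        for ra, rb in zip(a.records, b.records):
            assert ra.patient_id == rb.patient_id and ra.label == rb.label
            assert np.array_equal(ra.pair.cpr.samples, rb.pair.cpr.samples)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_patients=0)

    def test_psd_peak_at_compression_rate_when_artifact_dominates(self):
        strong = ArtifactParams(compression_rate=2.0,
                                fundamental_amplitude=10.0)
        weak_heart = MorphologyParams(qrs_amplitude=0.1, p_amplitude=0.0,
                                      t_amplitude=0.0)
        pair = generate_segment_pair(weak_heart, strong, QUIET, rng_seed=1)
        f, pxx = sps.welch(pair.cpr.samples, fs=250.0, nperseg=2048)
        assert abs(f[np.argmax(pxx)] - 2.0) <= 0.2


def test_wider_amplitude_gap_does_not_hurt_discrimination():
    """Widening the between-class QRS-amplitude gap cannot reduce the
    end-to-end CPR-phase CV AUC (averaged over seeds)."""
    from pulsewave.evaluation import cv_auc

    cfg = pw.PipelineConfig()

    def mean_auc(no_pulse_amp: float) -> float:
        aucs = []
        for seed in range(10):
            spec = CohortSpec(
                n_patients=14, seed=seed,
                class_params={
                    "pulse": MorphologyParams(heart_rate=75, qrs_width=0.10,
                                              qrs_amplitude=1.0,
                                              rr_jitter_sd=0.02),
                    "no_pulse": MorphologyParams(heart_rate=75, qrs_width=0.10,
                                                 qrs_amplitude=no_pulse_amp,
                                                 rr_jitter_sd=0.02),
                })
            cohort = generate_cohort(spec)
            segs = [r.pair.cpr for r in cohort]
            table = pw.featurize_phase(segs, cfg)
            res = cv_auc(table.X, table.labels, table.patients, k=3,
                         seed=seed)
            aucs.append(res.mean_auc)
        return float(np.mean(aucs))

    narrow, wide = mean_auc(0.8), mean_auc(0.4)
    assert wide >= narrow - 0.02
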