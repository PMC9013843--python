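"""The synthetic cohort generator: structure, determinism, severity maps."""

import numpy as np
import pytest
from scipy import signal as sps

from hdwear.io import SENSOR_CHANNELS, TASK_LABELS
from hdwear.preprocessing import bandpass_filter, magnitude_combine
from hdwear.simulate import (
    BODY_SITES,
    CohortConfig,
    _rng,
    sample_subscores,
    severity_profile,
    simulate_cohort,
    simulate_subject,
    synth_task_signal,
)


@pytest.fixture(scope="module")
def config():
    return CohortConfig(master_seed=42)


class TestSampleSubscores:
    def test_controls_all_zero(self, config):
        subs, chorea, dystonia = sample_subscores(
            config, _rng(42, "t", 0), "control"
        )
        assert all(v == 0 for v in subs.values())
        assert all(v == 0 for v in chorea.values())

    def test_composite_is_sum_of_subscores(self, config):
        for i in range(10):
            subs, *_ = sample_subscores(config, _rng(42, "t", i), "hd")
            # composite is derived downstream as the plain sum
            assert sum(subs.values()) <= 60

    def test_degenerate_full_severity(self):
        cfg = CohortConfig(master_seed=1, severity_low=1.0, severity_high=1.0)
        subs, *_ = sample_subscores(cfg, _rng(1, "t", 0), "hd")
        assert sum(subs.values()) == 60

    def test_chorea_assembled_from_five_sites(self, config):
        subs, chorea, _ = sample_subscores(config, _rng(42, "t", 3), "hd")
        assert set(chorea) == set(BODY_SITES)
        assert subs["total_chorea"] == sum(chorea.values())


class TestSeverityMaps:
    def _profile(self, **overrides):
        subs = {
            "arm_rigidity_left": 0, "arm_rigidity_right": 0, "total_chorea": 0,
            "total_dystonia": 0, "bradykinesia": 0, "gait": 0, "tandem_gait": 0,
        }
        subs.update(overrides)
        sites = {s: 0 for s in BODY_SITES}
        return severity_profile(subs, sites, sites)

    def test_cadence_non_increasing_in_bradykinesia(self):
        cadences = [self._profile(bradykinesia=b).cadence_hz for b in range(5)]
        assert all(a >= b for a, b in zip(cadences, cadences[1:]))

    def test_stride_cv_non_decreasing_in_gait(self):
        cvs = [self._profile(gait=g).stride_cv for g in range(5)]
        assert all(a <= b for a, b in zip(cvs, cvs[1:]))

    def test_all_signal_parameters_non_negative(self):
        p = self._profile(bradykinesia=4, gait=4, arm_rigidity_left=4)
        assert p.cadence_hz > 0
        assert p.walk_amp_scale > 0
        assert all(g >= 0 for g in p.arm_swing_gain.values())


class TestSynthTaskSignal:
    def test_walking_thigh_peaks_at_cadence(self, config):
        subs = {n: 0 for n in (
            "arm_rigidity_left", "arm_rigidity_right", "total_chorea",
            "total_dystonia", "bradykinesia", "gait", "tandem_gait")}
        sites = {s: 0 for s in BODY_SITES}
        profile = severity_profile(subs, sites, sites)
        fs = config.sampling_rate
        sig = synth_task_signal(
            profile, "walk_1", "left_thigh", "accelerometer", config,
            _rng(42, "sig"), n_samples=int(30 * fs),
        )
        mag = magnitude_combine(*(bandpass_filter(sig[:, i], fs) for i in range(3)))
        f, pxx = sps.welch(mag - mag.mean(), fs=fs, nperseg=int(8 * fs))
        peak_freq = f[np.argmax(pxx)]
        # magnitude of a cadence oscillation concentrates at 2x cadence
        assert min(abs(peak_freq - profile.cadence_hz),
                   abs(peak_freq - 2 * profile.cadence_hz)) < 0.2

    def test_chorea_raises_bandpassed_rms(self, config):
        """Median over seeds: sitting forearm RMS grows with arm chorea."""
        fs = config.sampling_rate
        rms_by_score = {0: [], 4: []}
        for score in rms_by_score:
            for seed in range(7):
                sites = {s: 0 for s in BODY_SITES}
                sites["left_arm"] = score
                subs = {n: 0 for n in (
                    "arm_rigidity_left", "arm_rigidity_right", "total_dystonia",
                    "bradykinesia", "gait", "tandem_gait")}
                subs["total_chorea"] = sum(sites.values())
                profile = severity_profile(subs, sites, {s: 0 for s in BODY_SITES})
                sig = synth_task_signal(
                    profile, "sit", "left_forearm", "accelerometer", config,
                    _rng(seed, "chorea"), n_samples=int(30 * fs),
                )
                mag = magnitude_combine(
                    *(bandpass_filter(sig[:, i], fs) for i in range(3))
                )
                rms_by_score[score].append(np.sqrt(np.mean(mag[100:] ** 2)))
        assert np.median(rms_by_score[4]) > np.median(rms_by_score[0])

    def test_monotone_severity_to_feature_curve(self, config):
        """Sitting forearm RMS is non-decreasing across chorea scores 0-4
        (median over seeds)."""
        fs = config.sampling_rate
        medians = []
        for score in range(5):
            vals = []
            for seed in range(5):
                sites = {s: 0 for s in BODY_SITES}
                sites["left_arm"] = score
                subs = {n: 0 for n in (
                    "arm_rigidity_left", "arm_rigidity_right", "total_dystonia",
                    "bradykinesia", "gait", "tandem_gait")}
                subs["total_chorea"] = sum(sites.values())
                profile = severity_profile(subs, sites, {s: 0 for s in BODY_SITES})
                sig = synth_task_signal(
                    profile, "sit", "left_forearm", "accelerometer", config,
                    _rng(seed, "mono"), n_samples=int(30 * fs),
                )
                mag = magnitude_combine(
                    *(bandpass_filter(sig[:, i], fs) for i in range(3))
                )
                vals.append(np.sqrt(np.mean(mag[100:] ** 2)))
            medians.append(np.median(vals))
        assert all(a <= b + 1e-12 for a, b in zip(medians, medians[1:]))


class TestSimulateSubject:
    def test_eight_recordings_seven_annotations(self, config):
        manifest, recordings, record = simulate_subject("s1", "hd", config, 0)
        assert len(recordings) == 8
        assert len(manifest.task_annotations) == 7
        assert {a[0] for a in manifest.task_annotations} == set(TASK_LABELS)

    def test_fixed_seed_reproduces_bitwise(self, config):
        _, rec_a, _ = simulate_subject("s1", "hd", config, 0)
        _, rec_b, _ = simulate_subject("s1", "hd", config, 0)
        for key in SENSOR_CHANNELS:
            np.testing.assert_array_equal(rec_a[key].xyz, rec_b[key].xyz)

    def test_gyros_only_on_forearms_and_sacrum(self, config):
        _, recordings, _ = simulate_subject("s1", "control", config, 0)
        gyro_locs = {loc for (loc, kind) in recordings if kind == "gyroscope"}
        assert gyro_locs == {"left_forearm", "right_forearm", "sacrum"}


class TestSimulateCohort:
    def test_default_cohort_is_28_subjects(self):
        _, _, records = simulate_cohort(CohortConfig(master_seed=3))
        groups = [r.group for r in records]
        assert len(records) == 28
        assert groups.count("hd") == 14 and groups.count("control") == 14

    def test_counts_match_config(self):
        _, _, records = simulate_cohort(CohortConfig(master_seed=3, n_hd=3, n_control=2))
        groups = [r.group for r in records]
        assert groups.count("hd") == 3 and groups.count("control") == 2

    def test_same_seed_same_labels(self, tmp_path):
        cfg = CohortConfig(master_seed=5, n_hd=2, n_control=2)
        simulate_cohort(cfg, out_dir=tmp_path / "a")
        simulate_cohort(cfg, out_dir=tmp_path / "b")
        assert (tmp_path / "a" / "labels.csv").read_text() == (
            tmp_path / "b" / "labels.csv"
        ).read_text()

    def test_refuses_nonempty_output_dir(self, tmp_path):
        out = tmp_path / "c"
        out.mkdir()
        (out / "junk.txt").write_text("x")
        with pytest.raises(FileExistsError):
            simulate_cohort(CohortConfig(master_seed=5, n_hd=2, n_control=2), out_dir=out)

    def test_walk_annotations_are_turn_free_windows(self, config):
        manifest, _, _ = simulate_subject("s1", "hd", config, 0)
        walks = sorted(
            (s, e) for lab, s, e in manifest.task_annotations if lab.startswith("walk")
        )
        for (s0, e0), (s1, e1) in zip(walks, walks[1:]):
            assert s1 - e0 >= config.turn_gap_s - 1e-9  # turns excluded between passes

    def test_all_control_cohort_fails_stage1_downstream(self):
        from hdwear.models import ModelingError, loo_stage1
        from hdwear.pipeline import extract_cohort_features

        cfg = CohortConfig(master_seed=5, n_hd=0, n_control=4)
        manifests, recordings, records = simulate_cohort(cfg)
        X = extract_cohort_features(manifests, recordings)
        with pytest.raises(ModelingError):
            loo_stage1(X, [r.group for r in records], "lda")
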