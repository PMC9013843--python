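"""Synthetic wearable-sensor cohorts with severity-dependent signals.

No clinical recordings ship with this package, so every pipeline stage is
exercised on simulated cohorts that mirror the study structure: five
triaxial accelerometers (forearms, thighs, sacrum) and three gyroscopes
(forearms, sacrum) per subject, recorded over one sitting task (~30 s), one
standing task (~30 s) and five straight walking passes (~12 s each, turns
excluded by construction), plus seven clinician-style UHDRS-TMS subscores.

The measurement model maps each subscore monotonically onto a signal
parameter of the limb(s) it rates:

* bradykinesia — lower cadence and smaller walking amplitude;
* gait — stride-interval jitter (timing CV), step-amplitude variability
  and exaggerated mediolateral motion while walking;
* tandem gait — extra stride jitter and larger standing sway;
* arm rigidity (per arm) — damped arm-swing amplitude on that forearm;
* chorea (per body site) — Poisson-timed bursts of 3-10 Hz damped
  oscillation on that site's sensor, in every task;
* dystonia (per body site) — slow (0.1-0.5 Hz) one-sided amplitude drift
  of that sensor's postural-sway envelope (sitting and standing, where
  sustained posturing dominates) plus a sub-band offset drift.

Each sensor's axes are rotated by a random per-subject constant rotation so
that only orientation-invariant processing can succeed, and white Gaussian
noise is added throughout.  All randomness flows from a single master seed
through named sub-streams (subscores, rotations, bursts, noise, ...), so
cohorts are bitwise reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import signal as sps

from .io import (
    SENSOR_CHANNELS,
    SENSOR_LOCATIONS,
    SUBSCORE_NAMES,
    SessionManifest,
    SubjectRecord,
    TriaxialRecording,
    save_manifest,
    save_recording,
    write_labels,
)

__all__ = [
    "SeverityProfile",
    "CohortConfig",
    "sample_subscores",
    "severity_profile",
    "synth_task_signal",
    "simulate_subject",
    "simulate_cohort",
]

#: chorea / dystonia body sites (4 points each, range 20 in total)
BODY_SITES = ("left_arm", "right_arm", "left_leg", "right_leg", "trunk")
SENSOR_SITE = {
    "left_forearm": "left_arm",
    "right_forearm": "right_arm",
    "left_thigh": "left_leg",
    "right_thigh": "right_leg",
    "sacrum": "trunk",
}


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition defaults for the synthetic cohort.

    The cohort mirrors the clinical study design: 14 symptomatic subjects
    and 14 controls, three tasks.  Effect sizes below were calibrated once
    so that group separation and severity recovery are non-trivial (noise,
    per-subject sensor rotations, and one deliberately mild HD subject
    overlapping the control range) yet achievable.
    """

    master_seed: int
    n_hd: int = 14
    n_control: int = 14
    sampling_rate: float = 100.0
    sit_duration_s: float = 30.0
    stand_duration_s: float = 30.0
    walk_duration_s: float = 12.0
    n_walks: int = 5
    turn_gap_s: float = 5.0
    noise_sd_accel: float = 0.015  # g per axis
    noise_sd_gyro: float = 1.0  # deg/s per axis
    severity_low: float = 0.2
    severity_high: float = 0.8
    mild_severity: float = 0.08  # one HD subject drawn at the control boundary

    def __post_init__(self) -> None:
        for name in ("sit_duration_s", "stand_duration_s", "walk_duration_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sampling_rate <= 32:
            raise ValueError("sampling_rate must exceed 32 Hz")


@dataclass(frozen=True)
class SeverityProfile:
    """Subscores plus the signal parameters they drive (all monotone)."""

    subscores: Mapping[str, int]
    chorea_sites: Mapping[str, int]
    dystonia_sites: Mapping[str, int]
    cadence_hz: float
    stride_cv: float
    step_amp_cv: float
    walk_amp_scale: float
    arm_swing_gain: Mapping[str, float]  # per arm site
    chorea_burst_rate: Mapping[str, float]  # bursts/s per site
    chorea_burst_amp: float
    dystonia_drift_amp: Mapping[str, float]  # AM depth per site
    sway_amp_sit: float
    sway_amp_stand: float
    walk_ml_gain: float  # mediolateral walking amplitude gain, scales with gait
    postural_instability: float  # scales sway with overall severity


def _rng(master_seed: int, *keys: object) -> np.random.Generator:
    """Named, reproducible sub-stream of the master seed."""
    words = [int(master_seed) & 0x7FFFFFFF]
    for k in keys:
        words.append(zlib.crc32(str(k).encode()) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(words))


# ---------------------------------------------------------------------------
# subscores and derived signal parameters


def sample_subscores(
    config: CohortConfig, rng: np.random.Generator, group: str, mild: bool = False
) -> tuple[dict[str, int], dict[str, int], dict[str, int]]:
    """Draw the seven subscores (controls: all zero).

    HD subjects receive a latent severity p ~ U(low, high) (or the mild
    boundary value); every 0-4 item is Binomial(4, p).  Total chorea and
    total dystonia are each assembled from five body-site items.
    """
    if group == "control":
        zero_sites = {s: 0 for s in BODY_SITES}
        return {name: 0 for name in SUBSCORE_NAMES}, zero_sites, dict(zero_sites)
    p = (
        config.mild_severity
        if mild
        else float(rng.uniform(config.severity_low, config.severity_high))
    )
    item = lambda: int(rng.binomial(4, p))
    chorea_sites = {s: item() for s in BODY_SITES}
    dystonia_sites = {s: item() for s in BODY_SITES}
    subs = {
        "arm_rigidity_left": item(),
        "arm_rigidity_right": item(),
        "total_chorea": sum(chorea_sites.values()),
        "total_dystonia": sum(dystonia_sites.values()),
        "bradykinesia": item(),
        "gait": item(),
        "tandem_gait": item(),
    }
    return subs, chorea_sites, dystonia_sites


def severity_profile(
    subscores: Mapping[str, int],
    chorea_sites: Mapping[str, int],
    dystonia_sites: Mapping[str, int],
) -> SeverityProfile:
    """Map subscores to signal parameters (monotone by construction)."""
    brady = subscores["bradykinesia"]
    gait = subscores["gait"]
    tandem = subscores["tandem_gait"]
    composite = sum(subscores.values())
    return SeverityProfile(
        subscores=dict(subscores),
        chorea_sites=dict(chorea_sites),
        dystonia_sites=dict(dystonia_sites),
        cadence_hz=1.9 - 0.11 * brady - 0.04 * gait,
        stride_cv=0.02 + 0.04 * gait + 0.01 * tandem,
        step_amp_cv=0.04 + 0.06 * gait,
        walk_amp_scale=1.0 - 0.07 * brady,
        arm_swing_gain={
            "left_arm": 1.0 - 0.17 * subscores["arm_rigidity_left"],
            "right_arm": 1.0 - 0.17 * subscores["arm_rigidity_right"],
        },
        chorea_burst_rate={s: 0.12 * v for s, v in chorea_sites.items()},
        chorea_burst_amp=0.3,
        dystonia_drift_amp={s: min(0.3 * v, 1.2) for s, v in dystonia_sites.items()},
        sway_amp_sit=0.05,
        sway_amp_stand=0.05 * (1.0 + 0.35 * tandem),
        walk_ml_gain=1.0 + 0.35 * gait,
        postural_instability=1.0 + 0.05 * composite,
    )


# ---------------------------------------------------------------------------
# signal synthesis


def _smooth_noise(n: int, fs: float, cutoff_hz: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD low-pass noise used for stride-timing and amplitude jitter."""
    white = rng.standard_normal(n + int(4 * fs))
    sos = sps.butter(2, cutoff_hz, fs=fs, output="sos")
    smooth = sps.sosfilt(sos, white)[int(4 * fs):]
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def _chorea_bursts(
    n: int, fs: float, rate: float, amp: float, rng: np.random.Generator
) -> np.ndarray:
    """Poisson-timed damped 3-10 Hz oscillation bursts, random 3-D direction."""
    out = np.zeros((n, 3))
    duration_s = n / fs
    n_bursts = rng.poisson(rate * duration_s)
    for _ in range(n_bursts):
        t0 = rng.uniform(0, duration_s)
        f = rng.uniform(3.0, 10.0)
        tau = rng.uniform(0.08, 0.18)
        length = int(0.5 * fs)
        i0 = int(t0 * fs)
        t = np.arange(length) / fs
        osc = np.exp(-t / tau) * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        a = amp * rng.uniform(0.7, 1.3)
        seg = np.minimum(length, n - i0)
        if seg > 0:
            out[i0 : i0 + seg] += a * osc[:seg, None] * direction[None, :]
    return out


def _dystonia_envelope(
    n: int, fs: float, depth: float, rng: np.random.Generator
) -> np.ndarray:
    """Slow one-sided amplitude drift, 0.1-0.5 Hz, envelope in [1, 1+depth].

    Dystonic posturing sustains extra muscle activity, so the envelope
    drifts upward from the baseline rather than symmetrically around it;
    the mean amplitude then grows linearly with the drift depth.
    """
    if depth <= 0:
        return np.ones(n)
    f = rng.uniform(0.2, 0.5)
    phase = rng.uniform(0, 2 * np.pi)
    t = np.arange(n) / fs
    return 1.0 + 0.5 * depth * (1.0 + np.sin(2 * np.pi * f * t + phase))


def _walk_phase(
    n: int, fs: float, cadence: float, stride_cv: float, rng: np.random.Generator
) -> np.ndarray:
    """Integrated instantaneous phase with stride-frequency jitter."""
    jitter = _smooth_noise(n, fs, cutoff_hz=max(cadence / 2.0, 0.3), rng=rng)
    f_inst = cadence * (1.0 + stride_cv * jitter)
    return 2 * np.pi * np.cumsum(f_inst) / fs


def synth_task_signal(
    profile: SeverityProfile,
    task: str,
    sensor_location: str,
    kind: str,
    config: CohortConfig,
    rng: np.random.Generator,
    n_samples: int | None = None,
) -> np.ndarray:
    """One task's (n, 3) triaxial signal in the sensor's canonical frame.

    Accelerometer units are g; gyroscope units deg/s.  The per-subject
    mounting rotation is applied later by :func:`simulate_subject`.
    """
    fs = config.sampling_rate
    if n_samples is None:
        dur = {
            "sit": config.sit_duration_s,
            "stand": config.stand_duration_s,
        }.get(task, config.walk_duration_s)
        n_samples = int(round(dur * fs))
    n = n_samples
    t = np.arange(n) / fs
    site = SENSOR_SITE[sensor_location]
    is_gyro = kind == "gyroscope"
    unit = 40.0 if is_gyro else 1.0  # gyro amplitudes scale to tens of deg/s

    signal = np.zeros((n, 3))
    if task.startswith("walk"):
        phase = _walk_phase(n, fs, profile.cadence_hz, profile.stride_cv, rng)
        env = 1.0 + profile.step_amp_cv * _smooth_noise(
            n, fs, cutoff_hz=profile.cadence_hz, rng=rng
        )
        amp_scale = profile.walk_amp_scale
        if sensor_location in ("left_thigh", "right_thigh"):
            a = 0.45 * amp_scale * unit
            signal[:, 0] = a * env * np.sin(phase)
            signal[:, 1] = 0.35 * a * env * np.sin(2 * phase + 0.4)
            signal[:, 2] = 0.15 * a * env * np.sin(phase + 1.1)
        elif sensor_location == "sacrum":
            a = 0.30 * amp_scale * unit
            signal[:, 0] = a * env * np.sin(2 * phase)
            signal[:, 1] = 0.4 * a * env * np.sin(phase + 0.7)
            signal[:, 2] = 0.2 * a * env * np.sin(2 * phase + 1.9)
        else:  # forearms: arm swing, damped by rigidity
            gain = profile.arm_swing_gain[site]
            a = 0.32 * gain * amp_scale * unit * (1.5 if is_gyro else 1.0)
            signal[:, 0] = a * env * np.sin(phase + (0.0 if site == "left_arm" else np.pi))
            signal[:, 1] = 0.3 * a * env * np.sin(2 * phase + 0.2)
            signal[:, 2] = 0.2 * a * env * np.sin(phase + 2.0)
        if sensor_location in ("left_thigh", "right_thigh", "sacrum"):
            # impaired gait exaggerates mediolateral motion
            signal[:, 1] *= profile.walk_ml_gain
    else:  # sit / stand: low-amplitude postural sway, scaled by instability
        sway = profile.sway_amp_sit if task == "sit" else profile.sway_amp_stand
        sway *= profile.postural_instability
        if sensor_location in ("left_forearm", "right_forearm"):
            sway *= 0.8
        sway *= 0.5 * unit if is_gyro else 1.0
        for axis in range(3):
            f1, f2 = rng.uniform(1.2, 2.0, size=2)
            p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
            signal[:, axis] = sway * (
                np.sin(2 * np.pi * f1 * t + p1) + 0.5 * np.sin(2 * np.pi * f2 * t + p2)
            )

    # dystonia: slow amplitude drift of the postural envelope + offset drift
    depth = profile.dystonia_drift_amp[site] if not task.startswith("walk") else 0.0
    signal *= _dystonia_envelope(n, fs, depth, rng)[:, None]
    if depth > 0:
        f_off = rng.uniform(0.1, 0.5)
        offset = 0.1 * depth * unit * np.sin(2 * np.pi * f_off * t + rng.uniform(0, 2 * np.pi))
        signal += offset[:, None] * rng.standard_normal(3)[None, :] * 0.3

    # chorea bursts, present in every task
    rate = profile.chorea_burst_rate[site]
    if rate > 0:
        signal += _chorea_bursts(n, fs, rate, profile.chorea_burst_amp * unit, rng)

    noise_sd = config.noise_sd_gyro if is_gyro else config.noise_sd_accel
    signal += noise_sd * rng.standard_normal((n, 3))
    if not is_gyro:
        signal[:, 2] += 1.0  # gravity before mounting rotation
    return signal


# ---------------------------------------------------------------------------
# whole subjects and cohorts


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3-D rotation matrix (QR of a Gaussian matrix)."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _task_timeline(config: CohortConfig) -> list[tuple[str, float, float]]:
    annotations = []
    t = 2.0
    annotations.append(("sit", t, t + config.sit_duration_s))
    t += config.sit_duration_s + 4.0
    annotations.append(("stand", t, t + config.stand_duration_s))
    t += config.stand_duration_s + 4.0
    for k in range(config.n_walks):
        annotations.append((f"walk_{k + 1}", t, t + config.walk_duration_s))
        t += config.walk_duration_s + config.turn_gap_s
    return annotations


def simulate_subject(
    subject_id: str,
    group: str,
    config: CohortConfig,
    subject_index: int,
    mild: bool = False,
) -> tuple[SessionManifest, dict[tuple[str, str], TriaxialRecording], SubjectRecord]:
    """One subject: 8 recordings, 7 task annotations, labels."""
    rng_scores = _rng(config.master_seed, "subscores", subject_index)
    subs, chorea_sites, dystonia_sites = sample_subscores(
        config, rng_scores, group, mild
    )
    profile = severity_profile(subs, chorea_sites, dystonia_sites)

    annotations = _task_timeline(config)
    total_s = annotations[-1][2] + 2.0
    fs = config.sampling_rate
    n_total = int(round(total_s * fs))
    t = np.arange(n_total) / fs

    rng_rot = _rng(config.master_seed, "rotations", subject_index)
    rotations = {loc: _random_rotation(rng_rot) for loc in SENSOR_LOCATIONS}

    recordings: dict[tuple[str, str], TriaxialRecording] = {}
    for loc, kind in SENSOR_CHANNELS:
        rng_sig = _rng(config.master_seed, "signals", subject_index, loc, kind)
        noise_sd = config.noise_sd_gyro if kind == "gyroscope" else config.noise_sd_accel
        xyz = noise_sd * rng_sig.standard_normal((n_total, 3))
        if kind == "accelerometer":
            xyz[:, 2] += 1.0
        for label, start, end in annotations:
            i0, i1 = int(round(start * fs)), int(round(end * fs))
            xyz[i0:i1] = synth_task_signal(
                profile, label, loc, kind, config, rng_sig, n_samples=i1 - i0
            )
        xyz = xyz @ rotations[loc].T  # constant mounting rotation
        recordings[(loc, kind)] = TriaxialRecording(loc, kind, fs, t, xyz)

    manifest = SessionManifest(
        subject_id,
        {(loc, kind): f"{subject_id}_{loc}_{kind}.csv" for loc, kind in SENSOR_CHANNELS},
        annotations,
    )
    record = SubjectRecord(
        subject_id=subject_id,
        group=group,
        subscores=subs,
        composite=sum(subs.values()),
        age=float(np.round(_rng(config.master_seed, "age", subject_index).uniform(25, 70), 1)),
    )
    return manifest, recordings, record


def simulate_cohort(
    config: CohortConfig,
    out_dir: str | Path | None = None,
    force: bool = False,
) -> tuple[
    list[SessionManifest],
    list[dict[tuple[str, str], TriaxialRecording]],
    list[SubjectRecord],
]:
    """Simulate the full cohort; optionally write it in the on-disk layout.

    Subject ids are ``hd_01..`` and ``ctrl_01..``; HD subject ``hd_01`` is
    drawn at the mild-severity boundary so the two groups overlap at the
    low end.  With ``out_dir`` set, refuses to write into a non-empty
    directory unless ``force`` is given.
    """
    if out_dir is not None:
        out_dir = Path(out_dir)
        if out_dir.exists() and any(out_dir.iterdir()) and not force:
            raise FileExistsError(
                f"output directory {out_dir} is not empty (use force=True)"
            )
        out_dir.mkdir(parents=True, exist_ok=True)

    manifests, all_recordings, records = [], [], []
    roster = [("hd", f"hd_{i + 1:02d}") for i in range(config.n_hd)] + [
        ("control", f"ctrl_{i + 1:02d}") for i in range(config.n_control)
    ]
    for index, (group, sid) in enumerate(roster):
        mild = group == "hd" and index == 0
        manifest, recordings, record = simulate_subject(
            sid, group, config, subject_index=index, mild=mild
        )
        manifests.append(manifest)
        all_recordings.append(recordings)
        records.append(record)
        if out_dir is not None:
            sdir = out_dir / sid
            sdir.mkdir(exist_ok=True)
            for key, rec in recordings.items():
                save_recording(rec, sdir / manifest.recordings[key])
            save_manifest(manifest, sdir / "manifest.json")
    if out_dir is not None:
        write_labels(records, out_dir / "labels.csv")
    return manifests, all_recordings, records
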