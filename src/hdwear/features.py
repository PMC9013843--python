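"""The 13 per-signal summary statistics and the 312-entry feature vector.

For every orientation-invariant magnitude signal (8 sensor streams x 7 task
segments) thirteen statistics are computed:

* time domain: root mean square, absolute maximum, sample SD;
* peak shape: mean/SD/max/min peak height and mean/SD inter-peak interval,
  with peaks defined as strict local maxima (first sample of a plateau);
* spectral: average broadband power (1-16 Hz) and average power in three
  1-Hz bands centred 2 Hz below, at, and 2 Hz above the mean normalized
  frequency (the spectral centroid of the broadband periodogram).  A mean
  normalized frequency of 9.5 Hz therefore yields the 7-8, 9-10 and
  11-12 Hz bands.

The five walking straightaways are feature-averaged, so each subject ends
up with 104 features per task (13 x 8) and 312 in total across sitting,
standing and walking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import signal as sps

from .io import SENSOR_CHANNELS
from .preprocessing import MagnitudeSignal

__all__ = [
    "STATISTIC_NAMES",
    "FEATURE_TASKS",
    "FeatureVector",
    "SpectralBandSpec",
    "feature_names",
    "time_domain_stats",
    "peak_stats",
    "mean_normalized_frequency",
    "spectral_band_spec",
    "spectral_stats",
    "segment_features",
    "subject_feature_vector",
]

logger = logging.getLogger(__name__)

STATISTIC_NAMES = (
    "rms",
    "absmax",
    "sd",
    "peak_mean",
    "peak_sd",
    "peak_max",
    "peak_min",
    "ipi_mean",
    "ipi_sd",
    "power_broadband",
    "power_band1",
    "power_band2",
    "power_band3",
)
FEATURE_TASKS = ("sit", "stand", "walk")
WALK_SEGMENTS = ("walk_1", "walk_2", "walk_3", "walk_4", "walk_5")

BROADBAND_HZ = (1.0, 16.0)
BAND_WIDTH_HZ = 1.0
BAND_CENTER_OFFSETS_HZ = (-2.0, 0.0, 2.0)
WELCH_WINDOW_S = 4.0


@dataclass(frozen=True)
class FeatureVector:
    """Ordered 312-entry named feature map for one subject."""

    subject_id: str
    entries: Mapping[str, float]

    def __post_init__(self) -> None:
        expected = feature_names()
        if list(self.entries) != expected:
            raise ValueError(
                f"feature vector for {self.subject_id!r} must carry exactly the "
                f"{len(expected)} canonical features in canonical order"
            )
        vals = np.fromiter(self.entries.values(), dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError(f"non-finite feature values for {self.subject_id!r}")

    def to_array(self) -> np.ndarray:
        return np.fromiter(self.entries.values(), dtype=float)


@dataclass(frozen=True)
class SpectralBandSpec:
    """The three analysis bands around one mean normalized frequency."""

    center_freq: float
    band_edges: tuple[tuple[float, float], ...]


def feature_names() -> list[str]:
    """Canonical 312-name ordering: task, then sensor stream, then statistic."""
    names = []
    for task in FEATURE_TASKS:
        for loc, kind in SENSOR_CHANNELS:
            for stat in STATISTIC_NAMES:
                names.append(f"{task}.{loc}.{kind}.{stat}")
    return names


def time_domain_stats(values: np.ndarray) -> tuple[float, float, float]:
    """Root mean square, absolute maximum, and sample SD (n-1 denominator)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot compute statistics of an empty signal")
    rms = float(np.sqrt(np.mean(v * v)))
    absmax = float(np.max(np.abs(v)))
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return rms, absmax, sd


def _find_peaks(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Strict local maxima; a plateau counts once at its first sample."""
    idx, props = sps.find_peaks(values, plateau_size=(1, None))
    positions = props["left_edges"]
    return positions, values[idx]


def peak_stats(
    values: np.ndarray, sampling_rate: float
) -> tuple[float, float, float, float, float, float]:
    """Peak-height and inter-peak-interval statistics.

    Returns (peak_mean, peak_sd, peak_max, peak_min, ipi_mean, ipi_sd).
    Statistics that are undefined for the number of peaks found (all six
    for zero peaks; SDs and intervals for a single peak) are reported as 0
    and logged as degenerate.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot compute peak statistics of an empty signal")
    positions, heights = _find_peaks(v)
    n = heights.size
    if n == 0:
        logger.debug("degenerate peak statistics: no peaks found")
        return 0.0, 0.0, 0.0, 0.0, 0.0, 0.0
    peak_mean = float(np.mean(heights))
    peak_max = float(np.max(heights))
    peak_min = float(np.min(heights))
    if n == 1:
        logger.debug("degenerate peak statistics: single peak")
        return peak_mean, 0.0, peak_max, peak_min, 0.0, 0.0
    peak_sd = float(np.std(heights, ddof=1))
    ipi = np.diff(positions) / sampling_rate  # seconds
    ipi_mean = float(np.mean(ipi))
    ipi_sd = float(np.std(ipi, ddof=1)) if ipi.size > 1 else 0.0
    return peak_mean, peak_sd, peak_max, peak_min, ipi_mean, ipi_sd


def _welch_psd(values: np.ndarray, sampling_rate: float) -> tuple[np.ndarray, np.ndarray]:
    nperseg = min(values.size, int(round(WELCH_WINDOW_S * sampling_rate)))
    return sps.welch(values, fs=sampling_rate, window="hann", nperseg=nperseg)


def mean_normalized_frequency(
    values: np.ndarray, sampling_rate: float
) -> float:
    """Power-weighted mean frequency of the periodogram within 1-16 Hz.

    An all-zero (or out-of-band) signal has no spectral mass to average;
    the band midpoint 8.5 Hz is returned and the degeneracy logged.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2 * sampling_rate:
        raise ValueError("need at least 2 s of samples for the spectral centroid")
    f, pxx = _welch_psd(v, sampling_rate)
    band = (f >= BROADBAND_HZ[0]) & (f <= BROADBAND_HZ[1])
    total = float(np.sum(pxx[band]))
    if total <= 0.0:
        logger.debug("degenerate spectral centroid: no in-band power")
        return float(np.mean(BROADBAND_HZ))
    return float(np.sum(f[band] * pxx[band]) / total)


def spectral_band_spec(center_freq: float, convention: str = "gapped") -> SpectralBandSpec:
    """Analysis bands around the mean normalized frequency f.

    ``gapped`` (default): three 1-Hz windows centred at f-2, f and f+2 —
    reproducing 7-8 / 9-10 / 11-12 Hz for f = 9.5.  ``contiguous``: the
    6 Hz window [f-3, f+3] split into three 2-Hz bands.  Bands are clipped
    to the 1-16 Hz broadband range.
    """
    if convention == "gapped":
        half = BAND_WIDTH_HZ / 2.0
        edges = [(center_freq + off - half, center_freq + off + half)
                 for off in BAND_CENTER_OFFSETS_HZ]
    elif convention == "contiguous":
        edges = [(center_freq - 3.0 + 2.0 * i, center_freq - 1.0 + 2.0 * i)
                 for i in range(3)]
    else:
        raise ValueError(f"unknown band convention {convention!r}")
    clipped = tuple(
        (max(lo, BROADBAND_HZ[0]), min(hi, BROADBAND_HZ[1])) for lo, hi in edges
    )
    return SpectralBandSpec(center_freq, clipped)


def spectral_stats(
    values: np.ndarray,
    sampling_rate: float,
    band_convention: str = "gapped",
) -> tuple[float, float, float, float]:
    """Average broadband power and average power in the three analysis bands.

    Power is the mean Welch periodogram density within the band; a band
    clipped to zero width contributes 0 and is logged as degenerate.
    """
    v = np.asarray(values, dtype=float)
    f, pxx = _welch_psd(v, sampling_rate)
    broad = (f >= BROADBAND_HZ[0]) & (f <= BROADBAND_HZ[1])
    power_broadband = float(np.mean(pxx[broad])) if broad.any() else 0.0
    fbar = mean_normalized_frequency(v, sampling_rate)
    spec = spectral_band_spec(fbar, band_convention)
    band_powers = []
    for lo, hi in spec.band_edges:
        sel = (f >= lo) & (f <= hi)
        if hi <= lo or not sel.any():
            logger.debug("degenerate spectral band (%.2f, %.2f): empty after clipping", lo, hi)
            band_powers.append(0.0)
        else:
            band_powers.append(float(np.mean(pxx[sel])))
    return (power_broadband, *band_powers)


def segment_features(
    signal: MagnitudeSignal, band_convention: str = "gapped"
) -> np.ndarray:
    """All 13 statistics of one magnitude signal, in canonical order."""
    v = signal.values
    out = np.empty(13)
    out[0:3] = time_domain_stats(v)
    out[3:9] = peak_stats(v, signal.sampling_rate)
    out[9:13] = spectral_stats(v, signal.sampling_rate, band_convention)
    return out


def subject_feature_vector(
    subject_id: str,
    signals: Iterable[MagnitudeSignal],
    band_convention: str = "gapped",
) -> FeatureVector:
    """Assemble the 312-entry feature vector from 56 magnitude signals.

    Expects one signal per (task segment, sensor stream): 7 x 8.  The five
    walking straightaways are averaged feature-wise (arithmetic mean of each
    statistic across straightaways).
    """
    by_key: dict[tuple[str, str, str], MagnitudeSignal] = {}
    for sig in signals:
        key = (sig.task_label, sig.sensor_location, sig.signal_kind)
        if key in by_key:
            raise ValueError(f"duplicate signal for {key}")
        by_key[key] = sig
    expected_tasks = ("sit", "stand", *WALK_SEGMENTS)
    missing = [
        (task, loc, kind)
        for task in expected_tasks
        for loc, kind in SENSOR_CHANNELS
        if (task, loc, kind) not in by_key
    ]
    if missing:
        raise ValueError(f"missing magnitude signals for {subject_id!r}: {missing}")

    entries: dict[str, float] = {}
    for task in FEATURE_TASKS:
        for loc, kind in SENSOR_CHANNELS:
            if task == "walk":
                stats = np.mean(
                    [
                        segment_features(by_key[(w, loc, kind)], band_convention)
                        for w in WALK_SEGMENTS
                    ],
                    axis=0,
                )
            else:
                stats = segment_features(by_key[(task, loc, kind)], band_convention)
            for stat_name, value in zip(STATISTIC_NAMES, stats):
                entries[f"{task}.{loc}.{kind}.{stat_name}"] = float(value)
    return FeatureVector(subject_id, entries)
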