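"""Global field power, peak extraction, and minimal preprocessing.

GFP at a time point is the population standard deviation over electrodes
of the average-referenced topography; its local maxima are the moments
of highest topographic signal-to-noise and form the input to clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .io_formats import EEGRecording


@dataclass
class GFPSeries:
    """Per-sample GFP plus the retained / excluded peak indices."""

    values: np.ndarray
    fs: float
    peak_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    excluded_peak_indices: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=int)
    )


@dataclass
class TopographySet:
    """Average-referenced maps at retained GFP peaks, in temporal order."""

    maps: np.ndarray  # (n_peaks, n_channels)
    source_indices: np.ndarray
    subject_id: str = "s00"

    @property
    def n_peaks(self) -> int:
        return self.maps.shape[0]


def average_reference(data: np.ndarray) -> np.ndarray:
    """Subtract the per-sample channel mean (columns of channels x samples)."""
    return data - data.mean(axis=0, keepdims=True)


def preprocess(
    rec: EEGRecording,
    band: tuple[float, float] = (1.0, 40.0),
    target_fs: float = 125.0,
    order: int = 8,
) -> EEGRecording:
    """Zero-phase band-pass then polyphase resampling, average-referenced.

    Filtering precedes resampling so the band edges are defined on the
    original rate; the Butterworth filter is applied forward-backward
    (``sosfiltfilt``) to keep GFP peak latencies unshifted.
    """
    low, high = band
    if not (0 < low < high):
        raise ValueError("band must satisfy 0 < low < high")
    if high >= target_fs / 2 or target_fs > rec.fs:
        raise ValueError(
            f"band {band} / target_fs {target_fs} incompatible with fs {rec.fs}"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, rec.data, axis=1)
    if abs(target_fs - rec.fs) > 1e-9:
        frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
        filtered = sps.resample_poly(filtered, frac.numerator, frac.denominator, axis=1)
    out = average_reference(filtered)
    return EEGRecording(out, target_fs, rec.montage, rec.subject_id, rec.group)


def compute_gfp(rec: EEGRecording) -> GFPSeries:
    """Population standard deviation across channels, per sample."""
    if rec.data.shape[0] < 2:
        raise ValueError("GFP requires at least 2 channels")
    centered = average_reference(rec.data)
    values = np.sqrt(np.mean(centered**2, axis=0))
    return GFPSeries(values=values, fs=rec.fs)


def find_gfp_peaks(g: GFPSeries, exclusion_z: float = 5.0) -> GFPSeries:
    """Locate interior local maxima of the GFP curve.

    Plateaus count once, at their first sample; endpoints are never
    peaks.  Peaks whose GFP exceeds ``median + exclusion_z * scale``
    (MAD-based robust scale) are moved to ``excluded_peak_indices`` — an
    automated, deterministic surrogate for visual rejection of peaks
    contaminated by residual artifacts.
    """
    v = np.asarray(g.values)
    if v.size < 3:
        raise ValueError("need at least 3 samples to find peaks")
    # strict rise before, fall (possibly after a plateau) behind
    rising = np.diff(v) > 0
    falling = np.diff(v) < 0
    peaks = []
    i = 1
    n = v.size
    while i < n - 1:
        if rising[i - 1]:
            j = i
            while j < n - 1 and v[j + 1] == v[j]:
                j += 1
            if j < n - 1 and falling[j]:
                peaks.append(i)
            i = j + 1
        else:
            i += 1
    peaks = np.asarray(peaks, dtype=int)
    if peaks.size:
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        scale = 1.4826 * mad if mad > 0 else np.std(v)
        thresh = med + exclusion_z * scale
        noisy = v[peaks] > thresh
        excluded = peaks[noisy]
        peaks = peaks[~noisy]
    else:
        excluded = np.empty(0, dtype=int)
    return GFPSeries(values=v, fs=g.fs, peak_indices=peaks, excluded_peak_indices=excluded)


def extract_topographies(rec: EEGRecording, g: GFPSeries) -> TopographySet:
    """Average-referenced maps at the retained GFP peaks."""
    if g.peak_indices.size == 0:
        raise ValueError("no retained GFP peaks to extract")
    maps = average_reference(rec.data)[:, g.peak_indices].T.copy()
    return TopographySet(maps=maps, source_indices=g.peak_indices.copy(),
                         subject_id=rec.subject_id)
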