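"""Per-segment feature extraction: nine time-domain statistics and the
five canonical band powers.

The fifteen features computed for every 1 s window are mean, standard
deviation (sample, n-1), peak-to-peak, min, max, skewness, kurtosis
(non-excess: a Gaussian scores ~3), crest factor (peak absolute value over
RMS, here called ``p2rms``), root sum of squares, RMS, and the power in
the delta (1-4 Hz), theta (4-8), alpha (8-14), beta (14-30) and gamma
(30-100) bands.  Band powers integrate a Hamming-windowed periodogram
over half-open frequency intervals, so contiguous bands sum exactly.

Skewness, kurtosis and the crest factor are undefined on a constant
segment and are propagated as NaN rather than silently zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats

#: Canonical EEG bands in Hz.  Gamma, defined in the field only as
#: "above 30 Hz", is capped at 100 Hz here.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 14.0),
    "beta": (14.0, 30.0),
    "gamma": (30.0, 100.0),
}

#: The fifteen feature names in canonical order.
FEATURE_NAMES = (
    "mean", "std", "p2p", "min", "max", "skew", "kurt", "p2rms", "rss",
    "rms", "delta", "theta", "alpha", "beta", "gamma",
)


def band_power(
    segment: np.ndarray, band: tuple[float, float], fs: float
) -> float:
    """Power (uV^2) of ``segment`` in the half-open band [f_lo, f_hi).

    The one-sided PSD is a single modified periodogram (Hamming window,
    density scaling) and the band power is its rectangular-rule integral
    over the bins falling inside the band.
    """
    f_lo, f_hi = band
    if not 0.0 <= f_lo < f_hi:
        raise ValueError(f"need 0 <= f_lo < f_hi, got ({f_lo}, {f_hi})")
    if f_hi > fs / 2.0 + 1e-12:
        raise ValueError(
            f"band upper edge {f_hi} Hz exceeds the Nyquist rate {fs / 2.0} Hz"
        )
    x = np.asarray(segment, dtype=float)
    freqs, psd = sps.periodogram(
        x, fs=fs, window="hamming", scaling="density", detrend=False
    )
    return _integrate_band(freqs, psd, f_lo, f_hi)


def _integrate_band(freqs, psd, f_lo, f_hi) -> float:
    df = freqs[1] - freqs[0]
    mask = (freqs >= f_lo) & (freqs < f_hi)
    return float(np.sum(psd[mask]) * df)


@dataclass(frozen=True)
class FeatureVector:
    """The fifteen per-segment features; see the module docstring."""

    mean: float
    std: float
    p2p: float
    min: float
    max: float
    skew: float
    kurt: float
    p2rms: float
    rss: float
    rms: float
    delta: float
    theta: float
    alpha: float
    beta: float
    gamma: float

    def as_array(self, names=FEATURE_NAMES) -> np.ndarray:
        return np.array([getattr(self, n) for n in names], dtype=float)


def extract_features(segment, fs: float | None = None) -> FeatureVector:
    """Compute the fifteen features of one segment.

    ``segment`` is either a :class:`~epichannel.preprocessing.Segment`
    (its sampling rate is used) or a plain array with ``fs`` given.
    """
    if hasattr(segment, "samples"):
        x = np.asarray(segment.samples, dtype=float)
        fs = segment.fs if fs is None else fs
    else:
        x = np.asarray(segment, dtype=float)
    if fs is None:
        raise ValueError("fs is required when segment is a bare array")
    if x.size < 4:
        raise ValueError("need at least 4 samples (kurtosis)")
    if not np.all(np.isfinite(x)):
        raise ValueError("segment contains non-finite values")

    mean = float(np.mean(x))
    std = float(np.std(x, ddof=1))
    mn, mx = float(np.min(x)), float(np.max(x))
    rms = float(np.sqrt(np.mean(x**2)))
    rss = float(np.sqrt(np.sum(x**2)))
    if std > 0.0:
        skew = float(stats.skew(x, bias=True))
        kurt = float(stats.kurtosis(x, fisher=False, bias=True))
    else:
        skew = kurt = float("nan")
    p2rms = float(np.max(np.abs(x)) / rms) if rms > 0.0 else float("nan")
    freqs, psd = sps.periodogram(
        x, fs=fs, window="hamming", scaling="density", detrend=False
    )
    powers = {
        name: _integrate_band(freqs, psd, lo, min(hi, fs / 2.0))
        for name, (lo, hi) in BANDS.items()
    }
    return FeatureVector(
        mean=mean, std=std, p2p=mx - mn, min=mn, max=mx, skew=skew,
        kurt=kurt, p2rms=p2rms, rss=rss, rms=rms, **powers,
    )


@dataclass
class FeatureSequence:
    """Ordered per-segment feature vectors for one LB channel.

    This is the classifier's input: a (n_segments, n_features) matrix in
    segment order, plus the channel identity and the class label
    (``"epileptic"``, ``"normal"`` or ``"unknown"``).
    """

    channel_label: str
    feature_names: tuple[str, ...]
    vectors: np.ndarray
    label: str = "unknown"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[1] != len(self.feature_names):
            raise ValueError(
                f"vectors shape {self.vectors.shape} does not match "
                f"{len(self.feature_names)} feature names"
            )

    def __len__(self) -> int:
        return self.vectors.shape[0]


def build_sequence(
    segments,
    feature_subset=FEATURE_NAMES,
    channel_label: str = "",
    label: str = "unknown",
    subject_id: str = "",
) -> FeatureSequence:
    """Extract features from each segment and stack them into a sequence.

    ``feature_subset`` selects (and orders) the columns; it must be a
    non-empty subset of :data:`FEATURE_NAMES`.
    """
    subset = tuple(feature_subset)
    if not subset:
        raise ValueError("feature_subset must not be empty")
    unknown = [n for n in subset if n not in FEATURE_NAMES]
    if unknown:
        raise ValueError(
            f"unknown feature names {unknown}; valid names are "
            f"{list(FEATURE_NAMES)}"
        )
    if len(set(subset)) != len(subset):
        raise ValueError("feature_subset contains duplicates")
    rows = [extract_features(seg).as_array(subset) for seg in segments]
    if not rows:
        raise ValueError("no segments supplied")
    return FeatureSequence(
        channel_label=channel_label,
        feature_names=subset,
        vectors=np.vstack(rows),
        label=label,
        subject_id=subject_id,
    )
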