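"""Fractional amplitude of low-frequency fluctuations (fALFF).

fALFF of a time series is the fraction of its spectral power that falls in
the low-frequency band (0.01-0.08 Hz by default): band power divided by the
total power over all positive frequencies. Computed per component time
course and per subject, the 20 values of a subject are then standardized to
sum to one, which makes the feature vector a *relative* power profile and
removes global per-subject power scaling before regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .errors import ConfigurationError

DEFAULT_BAND_HZ = (0.01, 0.08)

__all__ = [
    "DEFAULT_BAND_HZ",
    "FalffFeatures",
    "component_falff",
    "normalize_subject",
    "falff_features",
]


def component_falff(
    timeseries: np.ndarray,
    tr_seconds: float,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
    mode: str = "power",
) -> float:
    """Band-power fraction of one time course.

    The series is linearly detrended (which also removes the mean), an
    unpadded, untapered periodogram is computed by discrete Fourier
    transform, and the ratio of in-band to total power over positive
    frequencies is returned. Band edges are inclusive.

    Parameters
    ----------
    timeseries : array-like, length >= 64
    tr_seconds : float
        Sampling interval in seconds; the band must lie below the Nyquist
        frequency ``1 / (2 * tr_seconds)``.
    band_hz : (low, high)
        Frequency band in Hz, default (0.01, 0.08).
    mode : {"power", "amplitude"}
        "power" (default) sums squared spectral magnitudes; "amplitude"
        sums their square roots' magnitudes (i.e. spectral amplitudes), the
        convention of the original low-frequency-fluctuation literature.

    Returns
    -------
    float in [0, 1]. A constant series has no spectral content and returns
    0.0 with a warning.
    """
    x = np.asarray(timeseries, dtype=np.float64).ravel()
    n = x.size
    if n < 64:
        raise ValueError(f"time series too short ({n} < 64 samples)")
    lo, hi = float(band_hz[0]), float(band_hz[1])
    if not 0 <= lo < hi:
        raise ConfigurationError(f"invalid band {band_hz}")
    nyquist = 0.5 / float(tr_seconds)
    if hi >= nyquist:
        raise ConfigurationError(
            f"band upper edge {hi} Hz is not below Nyquist {nyquist:.4g} Hz at TR={tr_seconds}s"
        )
    if mode not in ("power", "amplitude"):
        raise ValueError(f"unknown mode {mode!r}")

    if np.ptp(x) == 0:
        warnings.warn("constant time series: fALFF undefined, returning 0.0")
        return 0.0
    x = signal.detrend(x, type="linear")
    spectrum = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(n, d=float(tr_seconds))
    weight = spectrum**2 if mode == "power" else spectrum
    positive = freqs > 0
    total = weight[positive].sum()
    if total <= 0:
        warnings.warn("constant time series: fALFF undefined, returning 0.0")
        return 0.0
    in_band = positive & (freqs >= lo) & (freqs <= hi)
    return float(weight[in_band].sum() / total)


def normalize_subject(raw_vector: np.ndarray) -> np.ndarray:
    """Standardize one subject's component fALFF vector to sum to one."""
    v = np.asarray(raw_vector, dtype=np.float64)
    if (v < 0).any():
        raise ValueError("fALFF values must be nonnegative")
    total = v.sum()
    if total <= 0:
        raise ValueError("all-zero fALFF vector: no spectral content to normalize")
    return v / total


@dataclass
class FalffFeatures:
    """Subjects x components fALFF matrix, raw and sum-to-one standardized."""

    raw: np.ndarray
    normalized: np.ndarray
    subject_ids: list[str]
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ
    tr_by_subject: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_components(self) -> int:
        return self.raw.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"component_{k + 1:02d}" for k in range(self.n_components)]
        df = pd.DataFrame(self.normalized, columns=cols)
        df.insert(0, "subject_id", self.subject_ids)
        return df


def falff_features(
    decomp,
    tr_by_subject: np.ndarray | dict | None = None,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
    mode: str = "power",
) -> FalffFeatures:
    """fALFF of every subject-component time course, standardized per subject.

    Parameters
    ----------
    decomp : GroupDecomposition
        Must contain back-projected ``subject_timecourses`` (one t x k matrix
        per subject) and ``subject_ids``.
    tr_by_subject : array, dict subject_id -> TR, or None
        Repetition time per subject; defaults to the TRs recorded in the
        decomposition. A subject without a TR is an error.
    """
    ids = list(decomp.subject_ids)
    if tr_by_subject is None:
        trs = np.asarray(decomp.tr_by_subject, dtype=float)
    elif isinstance(tr_by_subject, dict):
        missing = [s for s in ids if s not in tr_by_subject]
        if missing:
            raise ValueError(f"missing TR for subjects: {missing}")
        trs = np.array([float(tr_by_subject[s]) for s in ids])
    else:
        trs = np.asarray(tr_by_subject, dtype=float)
    if trs.size != len(ids) or not np.all(np.isfinite(trs)):
        raise ValueError("need one finite TR per subject")

    raw = np.empty((len(ids), decomp.n_components))
    for i, tcs in enumerate(decomp.subject_timecourses):
        for k in range(decomp.n_components):
            raw[i, k] = component_falff(tcs[:, k], trs[i], band_hz=band_hz, mode=mode)
    normalized = np.vstack([normalize_subject(row) for row in raw])
    return FalffFeatures(
        raw=raw, normalized=normalized, subject_ids=ids, band_hz=band_hz, tr_by_subject=trs
    )
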