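"""Sedation depth from frontal EEG: SEF95 on 2-s epochs.

The spectral edge frequency at 95% (SEF95) is the frequency below which
95% of the EEG band power lies; lower SEF95 indicates deeper sedation.
The pipeline mirrors standard intraoperative practice: non-overlapping
2-s epochs, amplitude-based artifact rejection, Hann-tapered periodograms
averaged over epochs and channels, normalisation to unit band power, then
the 95% edge with linear interpolation between frequency bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .exceptions import InsufficientDataError

__all__ = [
    "EEGRecord",
    "SedationIndex",
    "epoch",
    "reject_artifacts",
    "normalized_psd",
    "sef95",
    "sedation_for_mer",
]

EPOCH_S = 2.0
BAND = (0.5, 30.0)  # Hz; typical frontal sedation-monitoring band
AMP_MAX_UV = 100.0
PTP_MAX_UV = 200.0
MIN_EPOCHS = 15  # >= 30 s of clean data


@dataclass
class EEGRecord:
    """Multichannel frontal EEG (µV) with its MER time window."""

    channels: np.ndarray  # (n_channels, n_samples)
    fs: float
    mer_window: tuple[float, float] | None = None

    def __post_init__(self):
        self.channels = np.atleast_2d(np.asarray(self.channels, dtype=float))
        if self.fs <= 2 * BAND[1]:
            raise ValueError(f"fs={self.fs} must exceed twice the band high edge")

    @property
    def duration(self) -> float:
        return self.channels.shape[1] / self.fs


@dataclass
class SedationIndex:
    sef95: float
    n_epochs_used: int
    n_epochs_rejected: int
    propofol_rate: float | None = None


def epoch(record: EEGRecord, window: tuple[float, float] | None = None) -> np.ndarray:
    """Cut a record into non-overlapping 2-s epochs.

    Returns an array of shape (n_epochs, n_channels, samples_per_epoch);
    a trailing partial window is dropped.
    """
    x = record.channels
    if window is not None:
        lo, hi = window
        if lo < 0 or hi > record.duration + 1e-9 or hi <= lo:
            raise ValueError(f"window {window} outside record [0, {record.duration:g}]")
        x = x[:, int(round(lo * record.fs)) : int(round(hi * record.fs))]
    nper = int(round(EPOCH_S * record.fs))
    n_epochs = x.shape[1] // nper
    if n_epochs < 1:
        raise InsufficientDataError("record shorter than one 2-s epoch")
    x = x[:, : n_epochs * nper]
    return np.swapaxes(x.reshape(x.shape[0], n_epochs, nper), 0, 1)


def reject_artifacts(
    epochs: np.ndarray,
    amp_max: float = AMP_MAX_UV,
    ptp_max: float = PTP_MAX_UV,
) -> tuple[np.ndarray, int]:
    """Drop epochs in which any channel exceeds the amplitude limits.

    An epoch is rejected when any sample magnitude exceeds ``amp_max`` µV
    or any channel's peak-to-peak excursion exceeds ``ptp_max`` µV.
    """
    if epochs.size == 0:
        return epochs, 0
    over_amp = np.abs(epochs).max(axis=(1, 2)) > amp_max
    over_ptp = (epochs.max(axis=2) - epochs.min(axis=2)).max(axis=1) > ptp_max
    bad = over_amp | over_ptp
    return epochs[~bad], int(bad.sum())


def normalized_psd(
    epochs: np.ndarray,
    fs: float,
    band: tuple[float, float] = BAND,
    min_epochs: int = MIN_EPOCHS,
) -> tuple[np.ndarray, np.ndarray]:
    """Band-restricted PSD, averaged over epochs/channels, unit total power.

    Hann-tapered periodogram per epoch and channel (2-s epochs give 0.5 Hz
    resolution); the average is restricted to ``band`` and scaled so the
    band power sums to one.  SEF95 is invariant to the normalisation
    constant, which is fixed here only so spectra are comparable.
    """
    if epochs.shape[0] < min_epochs:
        raise InsufficientDataError(
            f"{epochs.shape[0]} epochs retained; need {min_epochs}"
        )
    freqs, pxx = sp_signal.periodogram(epochs, fs=fs, window="hann", axis=2)
    mean_pxx = pxx.mean(axis=(0, 1))
    sel = (freqs >= band[0]) & (freqs <= band[1])
    f, p = freqs[sel], mean_pxx[sel]
    total = p.sum()
    if total <= 0:
        raise InsufficientDataError("zero band power")
    return f, p / total


def sef95(freqs: np.ndarray, psd: np.ndarray, q: float = 0.95) -> float:
    """Spectral edge: smallest frequency below which q of band power lies.

    Treats the discrete PSD as a density between bin centres and linearly
    interpolates the cumulative power, so analytic spectra sampled on a
    fine grid reproduce their closed-form edge frequencies.
    """
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    if freqs.size != psd.size or freqs.size < 2:
        raise ValueError("freqs and psd must be equal-length, size >= 2")
    # trapezoidal cumulative power over the band
    cum = np.concatenate([[0.0], np.cumsum((psd[1:] + psd[:-1]) / 2 * np.diff(freqs))])
    total = cum[-1]
    if total <= 0:
        raise ValueError("zero total power")
    cum /= total
    target = q
    i = int(np.searchsorted(cum, target))
    if i == 0:
        return float(freqs[0])
    if i >= freqs.size:
        return float(freqs[-1])
    # linear interpolation within the bin
    f = freqs[i - 1] + (target - cum[i - 1]) / (cum[i] - cum[i - 1]) * (
        freqs[i] - freqs[i - 1]
    )
    return float(f)


def sedation_for_mer(
    record: EEGRecord,
    propofol_rate: float | None = None,
    band: tuple[float, float] = BAND,
    amp_max: float = AMP_MAX_UV,
    ptp_max: float = PTP_MAX_UV,
    min_epochs: int = MIN_EPOCHS,
) -> SedationIndex:
    """SEF95 for the MER time window of a record.

    Runs epoch -> artifact rejection -> normalised PSD -> SEF95 on the
    record restricted to its ``mer_window`` (the whole record when no
    window is set).
    """
    eps = epoch(record, window=record.mer_window)
    kept, n_rej = reject_artifacts(eps, amp_max=amp_max, ptp_max=ptp_max)
    freqs, psd = normalized_psd(kept, record.fs, band=band, min_epochs=min_epochs)
    return SedationIndex(
        sef95=sef95(freqs, psd),
        n_epochs_used=int(kept.shape[0]),
        n_epochs_rejected=n_rej,
        propofol_rate=propofol_rate,
    )
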