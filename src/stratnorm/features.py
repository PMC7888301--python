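"""Band-power and differential-entropy feature extraction.

Each trial is reduced to one value per channel and per canonical EEG
rhythm — theta (4–7 Hz), alpha (8–13 Hz), beta (14–30 Hz), gamma
(31–50 Hz); delta is excluded — by one of three methods:

* ``welch``: Welch PSD (0.5 s Hann windows, 0.25 s overlap) integrated
  over the band with composite Simpson's rule,
* ``multitaper``: DPSS multitaper PSD of the whole trial, integrated the
  same way,
* ``de``: differential entropy of the band-limited signal under a
  Gaussian assumption, h = ½·ln(2πeσ²) in nats, with σ² the variance of
  the zero-phase band-passed trial.

For a 62-channel montage this yields the standard 248-dimensional
(62 × 4) feature vector per trial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, signal

from .io import EEGDataset, FeatureTable

__all__ = [
    "BandDefinition",
    "BANDS",
    "PSDEstimate",
    "BandSignalStats",
    "welch_psd",
    "multitaper_psd",
    "band_power",
    "bandpass",
    "differential_entropy",
    "extract_features",
]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self):
        if not self.f_lo < self.f_hi:
            raise ValueError(f"band {self.name}: f_lo must be < f_hi")


#: Canonical analysis bands, in fixed feature order.
BANDS = (
    BandDefinition("theta", 4.0, 7.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 14.0, 30.0),
    BandDefinition("gamma", 31.0, 50.0),
)

METHODS = ("welch", "multitaper", "de")


@dataclass
class PSDEstimate:
    """One-sided power spectral density on a uniform frequency grid."""

    freqs: np.ndarray  # (n_freqs,) Hz, ascending
    density: np.ndarray  # (n_channels, n_freqs), power per Hz


@dataclass
class BandSignalStats:
    """Variance and Gaussian differential entropy of a band-limited signal."""

    variance: float
    entropy: float  # nats; -inf when variance == 0

    @property
    def degenerate(self) -> bool:
        return not math.isfinite(self.entropy)


def _as_2d(signal_arr: np.ndarray) -> np.ndarray:
    x = np.asarray(signal_arr, dtype=np.float64)
    if x.ndim == 1:
        x = x[np.newaxis, :]
    if x.ndim != 2:
        raise ValueError(f"signal must be 1-D or 2-D, got shape {x.shape}")
    return x


def welch_psd(
    signal_arr: np.ndarray,
    fs: float,
    win_s: float = 0.5,
    overlap_s: float = 0.25,
    freq_resolution: float = 0.25,
) -> PSDEstimate:
    """Welch PSD with Hann-tapered, mean-detrended segments.

    Segments are zero-padded so the frequency grid spacing is at most
    ``freq_resolution`` Hz; the narrowest analysis band (theta, 3 Hz wide)
    then spans enough grid points for Simpson integration. Zero padding
    interpolates the spectrum and leaves the integrated power unchanged.
    """
    x = _as_2d(signal_arr)
    nperseg = int(round(win_s * fs))
    if x.shape[1] < nperseg:
        raise ValueError(
            f"trial of {x.shape[1]} samples is shorter than one "
            f"{win_s} s window ({nperseg} samples)"
        )
    noverlap = int(round(overlap_s * fs))
    nfft = max(nperseg, int(np.ceil(fs / freq_resolution)))
    freqs, density = signal.welch(
        x,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        nfft=nfft,
        detrend="constant",
        scaling="density",
        return_onesided=True,
        axis=-1,
    )
    return PSDEstimate(freqs=freqs, density=density)


def multitaper_psd(
    signal_arr: np.ndarray, fs: float, nw: float = 4.0
) -> PSDEstimate:
    """Multitaper PSD: DPSS tapers over the full trial, NW = ``nw``,
    2·NW−1 tapers, unit-weight average of the eigenspectra."""
    x = _as_2d(signal_arr)
    n = x.shape[1]
    k = int(2 * nw - 1)
    if n < 2 * k:
        raise ValueError(f"trial too short for {k} DPSS tapers ({n} samples)")
    tapers = signal.windows.dpss(n, nw, Kmax=k)  # (k, n), unit energy each
    x = x - x.mean(axis=-1, keepdims=True)
    # (k, n_channels, n) tapered copies -> one-sided eigenspectra
    tapered = tapers[:, np.newaxis, :] * x[np.newaxis, :, :]
    spec = np.fft.rfft(tapered, axis=-1)
    psd = (spec.real**2 + spec.imag**2) / fs
    psd[..., 1:] *= 2.0
    if n % 2 == 0:
        psd[..., -1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return PSDEstimate(freqs=freqs, density=psd.mean(axis=0))


def band_power(psd: PSDEstimate, band: BandDefinition) -> np.ndarray:
    """Integrate the PSD over ``band`` (inclusive edges) with Simpson's rule.

    Returns one value per channel.
    """
    if psd.freqs[0] > band.f_lo or psd.freqs[-1] < band.f_hi:
        raise ValueError(
            f"PSD grid [{psd.freqs[0]}, {psd.freqs[-1]}] does not cover "
            f"band {band.name} [{band.f_lo}, {band.f_hi}]"
        )
    mask = (psd.freqs >= band.f_lo) & (psd.freqs <= band.f_hi)
    if mask.sum() < 3:
        raise ValueError(
            f"only {int(mask.sum())} grid points inside {band.name}; "
            "need >= 3 for Simpson integration"
        )
    return integrate.simpson(psd.density[:, mask], x=psd.freqs[mask], axis=-1)


def bandpass(
    signal_arr: np.ndarray, fs: float, band: BandDefinition, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (order ``order``, applied
    forward-backward)."""
    if band.f_hi >= fs / 2:
        raise ValueError(
            f"band {band.name} upper edge {band.f_hi} Hz at or above "
            f"Nyquist ({fs / 2} Hz)"
        )
    sos = signal.butter(
        order, [band.f_lo, band.f_hi], btype="bandpass", fs=fs, output="sos"
    )
    if not np.isfinite(sos).all():
        raise RuntimeError(f"unstable band-pass design for {band.name}")
    return signal.sosfiltfilt(sos, np.asarray(signal_arr, dtype=np.float64), axis=-1)


def gaussian_entropy(variance: float) -> float:
    """Closed-form differential entropy of N(mu, variance), in nats."""
    if variance < 0:
        raise ValueError("variance must be >= 0")
    if variance == 0:
        return -math.inf
    return 0.5 * math.log(2 * math.pi * math.e * variance)


def differential_entropy(
    signal_channel: np.ndarray, fs: float, band: BandDefinition
) -> BandSignalStats:
    """Differential entropy of one channel restricted to ``band``.

    The channel is band-passed (zero phase), its variance over the whole
    trial taken as the Gaussian sigma^2, and h = 0.5 ln(2 pi e sigma^2)
    returned in nats. A zero-variance channel yields h = -inf, flagged
    degenerate; callers must reject such trials.
    """
    x = np.asarray(signal_channel, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("differential_entropy expects a single channel")
    filtered = bandpass(x, fs, band)
    var = float(np.var(filtered))
    return BandSignalStats(variance=var, entropy=gaussian_entropy(var))


def feature_names(n_channels: int) -> list[str]:
    """Column names, channel-major then band: c1_theta ... cN_gamma."""
    return [f"c{c + 1}_{b.name}" for c in range(n_channels) for b in BANDS]


def extract_features(d: EEGDataset, method: str = "multitaper", **kwargs) -> FeatureTable:
    """Extract the per-trial channels-x-bands feature matrix.

    ``method`` is one of ``welch``, ``multitaper``, ``de``. Extra keyword
    arguments are forwarded to the PSD estimator (``win_s``, ``overlap_s``
    for Welch; ``nw`` for multitaper).
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    d.validate()
    n_bands = len(BANDS)
    trials = d.iter_sorted()
    X = np.empty((len(trials), d.n_channels * n_bands), dtype=np.float64)
    for row, t in enumerate(trials):
        if method in ("welch", "multitaper"):
            psd = (
                welch_psd(t.signal, d.fs, **kwargs)
                if method == "welch"
                else multitaper_psd(t.signal, d.fs, **kwargs)
            )
            for b_idx, band in enumerate(BANDS):
                X[row, b_idx::n_bands] = band_power(psd, band)
        else:
            bad: list[str] = []
            for c in range(d.n_channels):
                for b_idx, band in enumerate(BANDS):
                    stats = differential_entropy(t.signal[c], d.fs, band)
                    if stats.degenerate:
                        bad.append(f"c{c + 1}_{band.name}")
                    X[row, c * n_bands + b_idx] = stats.entropy
            if bad:
                raise ValueError(
                    f"trial ({t.participant},{t.session},{t.trial}): zero "
                    f"band-limited variance in {bad}"
                )
    out = FeatureTable(
        X=X,
        participants=np.array([t.participant for t in trials]),
        sessions=np.array([t.session for t in trials]),
        trials=np.array([t.trial for t in trials]),
        labels=np.array([t.label for t in trials]),
        feature_names=feature_names(d.n_channels),
    )
    out.validate()
    return out
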