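"""Spectral-domain measures: centroid, band RMS, HNR, flatness, SSI.

All frame-based measures share one short-time magnitude spectrogram
(Hann window) and a uniform silence gate: frames whose RMS falls below
``silence_threshold`` times the loudest frame are excluded from frame
averages, so silent tails cannot dilute a measure.

The harmonics-to-noise ratio is computed natively with a frame-wise
normalized-autocorrelation peak method (the approach standard in the
phonetics literature): the height r of the autocorrelation peak in the
candidate pitch-lag range estimates the periodic power fraction, and
HNR = 10 log10(r / (1 - r)) dB.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import irfft, rfft, rfftfreq
from scipy.signal.windows import hann

from .signal_io import Waveform

__all__ = [
    "SpectralConfig",
    "Spectrogram",
    "SilentFramesError",
    "spectrogram",
    "mean_spectral_centroid",
    "band_rms",
    "harmonicity_hnr",
    "spectral_flatness",
    "power_spectrum_flatness",
    "spectral_structure_index",
    "adjacent_frame_decorrelation",
    "DEFAULT_BANDS",
]

DEFAULT_BANDS = ((0, 500), (500, 1000), (1000, 2000), (2000, 4000),
                 (4000, 8000))


class SilentFramesError(ValueError):
    """No frame passes the silence gate (or signal too short to frame)."""


@dataclass
class SpectralConfig:
    """Short-time analysis parameters.

    ``bands`` are half-open [low, high) frequency ranges in Hz (the top
    band includes the Nyquist bin when high equals Nyquist); they must be
    ascending, non-overlapping and within Nyquist for the analyzed file.
    ``hnr_fmin``/``hnr_fmax`` bound the candidate fundamental range of the
    autocorrelation search.  ``silence_threshold`` is the frame-RMS gate
    as a fraction of the loudest frame, applied uniformly to centroid,
    flatness, SSI and HNR.
    """

    frame_length: int = 2048
    hop: int = 512
    window: str = "hann"
    bands: tuple = DEFAULT_BANDS
    hnr_fmin: float = 75.0
    hnr_fmax: float = 600.0
    silence_threshold: float = 0.1

    def __post_init__(self):
        if self.frame_length < 2 * self.hop:
            raise ValueError("frame_length must be >= 2 * hop")
        prev_high = 0.0
        for low, high in self.bands:
            if low < prev_high or high <= low:
                raise ValueError("bands must be ascending and non-overlapping")
            prev_high = high

    def validate_rate(self, fs: float) -> None:
        nyq = fs / 2.0
        for low, high in self.bands:
            if high > nyq:
                raise ValueError(
                    f"band ({low}, {high}) exceeds Nyquist {nyq} Hz")


@dataclass
class Spectrogram:
    """Magnitude short-time spectra plus axes."""

    magnitudes: np.ndarray  # frames x bins, nonnegative
    bin_freqs: np.ndarray  # Hz, 0..Nyquist
    frame_times: np.ndarray  # s, frame centers
    sample_rate: float
    window_energy: float  # sum of squared window samples


def _frames(x: np.ndarray, frame: int, hop: int) -> np.ndarray:
    n = (len(x) - frame) // hop + 1
    if n < 1:
        raise SilentFramesError("signal shorter than one analysis frame")
    view = np.lib.stride_tricks.sliding_window_view(x, frame)
    return view[::hop][:n]


def spectrogram(w: Waveform, cfg: SpectralConfig | None = None) -> Spectrogram:
    cfg = cfg or SpectralConfig()
    frames = _frames(w.samples, cfg.frame_length, cfg.hop)
    win = hann(cfg.frame_length, sym=False)
    mags = np.abs(rfft(frames * win, axis=1))
    freqs = rfftfreq(cfg.frame_length, d=1.0 / w.sample_rate)
    times = (np.arange(len(frames)) * cfg.hop + cfg.frame_length / 2) \
        / w.sample_rate
    return Spectrogram(mags, freqs, times, float(w.sample_rate),
                       float((win**2).sum()))


def _frame_band_power(spec: Spectrogram,
                      mask: np.ndarray | None = None) -> np.ndarray:
    """Per-frame mean-square power attributable to the masked bins.

    One-sided spectra are folded back (interior bins doubled) and scaled
    by frame length and window energy so that, for stationary input,
    summing over all bins estimates the time-domain mean-square power
    (Parseval).
    """
    n = (len(spec.bin_freqs) - 1) * 2
    weights = np.full(len(spec.bin_freqs), 2.0)
    weights[0] = 1.0
    weights[-1] = 1.0 if n % 2 == 0 else 2.0
    if mask is not None:
        weights = weights * mask
    return (spec.magnitudes**2 * weights).sum(axis=1) / (n *
                                                         spec.window_energy)


def _voiced_mask(spec: Spectrogram, threshold: float) -> np.ndarray:
    power = _frame_band_power(spec)
    if power.max() == 0:
        raise SilentFramesError("all frames silent")
    mask = np.sqrt(power) >= threshold * np.sqrt(power.max())
    return mask


def mean_spectral_centroid(w: Waveform,
                           cfg: SpectralConfig | None = None) -> float:
    """Power-weighted mean frequency, averaged over non-silent frames."""
    cfg = cfg or SpectralConfig()
    spec = spectrogram(w, cfg)
    mask = _voiced_mask(spec, cfg.silence_threshold)
    p = spec.magnitudes[mask] ** 2
    centroids = (p * spec.bin_freqs).sum(axis=1) / p.sum(axis=1)
    return float(centroids.mean())


def band_rms(w: Waveform, low: float, high: float,
             cfg: SpectralConfig | None = None) -> float:
    """RMS of the signal component in [low, high) Hz, from spectral power.

    The band including Nyquist as its upper edge also claims the Nyquist
    bin, so a set of contiguous bands covering 0..Nyquist partitions the
    total power.
    """
    cfg = cfg or SpectralConfig()
    nyq = w.sample_rate / 2.0
    if not 0 <= low < high <= nyq:
        raise ValueError(f"band ({low}, {high}) invalid for Nyquist {nyq}")
    spec = spectrogram(w, cfg)
    mask = (spec.bin_freqs >= low) & (spec.bin_freqs < high)
    if high == nyq:
        mask |= spec.bin_freqs == nyq
    power = _frame_band_power(spec, mask.astype(float))
    return float(np.sqrt(power.mean()))


def harmonicity_hnr(w: Waveform, cfg: SpectralConfig | None = None) -> float:
    """Mean harmonics-to-noise ratio in dB over non-silent frames.

    Per frame the normalized cross-correlation r(tau) (autocorrelation
    divided by the energies of the two overlapping segments, so that an
    exactly periodic frame reaches r = 1 regardless of where the frame
    cuts the cycle) is evaluated over lags in [1/fmax, 1/fmin].  The
    candidate period is located on the frame-averaged curve — pooling
    suppresses the upward bias a per-frame max over hundreds of lags
    would pick up from noise fluctuations — then each frame's r is the
    parabolic-interpolated peak near that lag (interpolation recovers
    periods that fall between integer sample lags).  Frame values
    10 log10(r / (1 - r)) dB, with r clamped to [1e-6, 1-1e-6], are
    averaged.
    """
    cfg = cfg or SpectralConfig()
    fs = w.sample_rate
    min_lag = max(1, int(np.floor(fs / cfg.hnr_fmax)))
    max_lag = int(np.ceil(fs / cfg.hnr_fmin))
    frame_len = max(cfg.frame_length, int(np.ceil(2.5 * max_lag)))
    if len(w.samples) < frame_len:
        raise SilentFramesError(
            "signal shorter than two periods of hnr_fmin")
    frames = _frames(w.samples, frame_len, cfg.hop)
    rms = np.sqrt((frames**2).mean(axis=1))
    if rms.max() == 0:
        raise SilentFramesError("all frames silent")
    voiced = rms >= cfg.silence_threshold * rms.max()
    frames = frames[voiced] - frames[voiced].mean(axis=1, keepdims=True)
    nfft = 2 ** int(np.ceil(np.log2(2 * frame_len)))
    spectra = rfft(frames, n=nfft, axis=1)
    ac = irfft(np.abs(spectra) ** 2, axis=1)[:, : max_lag + 2]
    # NCCF normalization: energies of the leading and trailing segments
    sq = np.cumsum(frames**2, axis=1)
    total = sq[:, -1:]
    lags = np.arange(max_lag + 2)
    e_lead = sq[:, frame_len - 1 - lags]
    e_trail = np.concatenate(
        [total, total - sq[:, lags[1:] - 1]], axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = ac / np.sqrt(e_lead * e_trail)
    rho = np.nan_to_num(rho, nan=0.0)
    pooled = rho[:, min_lag: max_lag + 1].mean(axis=0)
    best = min_lag + int(np.argmax(pooled))
    lo = max(min_lag, best - 2)
    hi = min(max_lag, best + 2)
    idx = lo + rho[:, lo: hi + 1].argmax(axis=1)
    rows = np.arange(len(rho))
    r = rho[rows, idx]
    # parabolic refinement of the peak between integer lags
    interior = (idx > 0) & (idx < max_lag + 1)
    left = rho[rows, np.maximum(idx - 1, 0)]
    right = rho[rows, np.minimum(idx + 1, max_lag + 1)]
    curv = 2 * r - left - right
    with np.errstate(invalid="ignore", divide="ignore"):
        peak = r + (right - left) ** 2 / (8 * curv)
    r = np.where(interior & (curv > 0), peak, r)
    r = np.clip(r, 1e-6, 1 - 1e-6)
    return float(np.mean(10 * np.log10(r / (1 - r))))


def power_spectrum_flatness(p, floor_rel: float = 1e-12) -> float:
    """Geometric over arithmetic mean of one power spectrum, in [0, 1]."""
    p = np.asarray(p, dtype=np.float64)
    if p.max() <= 0:
        raise SilentFramesError("zero power spectrum")
    p = np.maximum(p, floor_rel * p.max())
    return float(np.exp(np.mean(np.log(p))) / p.mean())


def spectral_flatness(w: Waveform, cfg: SpectralConfig | None = None) -> float:
    """Mean spectral flatness (Wiener entropy) over non-silent frames."""
    cfg = cfg or SpectralConfig()
    spec = spectrogram(w, cfg)
    mask = _voiced_mask(spec, cfg.silence_threshold)
    return float(np.mean([power_spectrum_flatness(m**2)
                          for m in spec.magnitudes[mask]]))


def spectral_structure_index(w: Waveform,
                             cfg: SpectralConfig | None = None) -> float:
    """Mean decorrelation of adjacent log-magnitude spectra, in [0, 2].

    0 for a stationary spectrum; values near or above 1 indicate the
    short-time spectral shape changes substantially frame to frame.
    """
    cfg = cfg or SpectralConfig()
    spec = spectrogram(w, cfg)
    mask = _voiced_mask(spec, cfg.silence_threshold)
    return adjacent_frame_decorrelation(spec.magnitudes[mask])


def adjacent_frame_decorrelation(magnitudes) -> float:
    """Mean (1 - Pearson r) between adjacent log-magnitude spectra."""
    mags = np.asarray(magnitudes, dtype=np.float64)
    if len(mags) < 2:
        raise SilentFramesError("need at least 2 non-silent frames")
    logm = np.log(np.maximum(mags, 1e-10 * mags.max()))
    a = logm[:-1] - logm[:-1].mean(axis=1, keepdims=True)
    b = logm[1:] - logm[1:].mean(axis=1, keepdims=True)
    denom = np.sqrt((a**2).sum(axis=1) * (b**2).sum(axis=1))
    with np.errstate(invalid="ignore"):
        corr = (a * b).sum(axis=1) / denom
    corr = np.where(denom == 0, 1.0, corr)  # identical flat frames
    return float(np.mean(1.0 - corr))
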