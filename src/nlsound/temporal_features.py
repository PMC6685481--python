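"""Temporal-domain complexity measures of a sampled waveform.

The battery covers three families used to characterize complex signals:

* information-theoretic / algorithmic complexity — sample entropy,
  permutation entropy and Lempel–Ziv (LZ76) complexity of a binarized
  sequence (three binary codings);
* fractal-dimension estimates — the Higuchi curve-length method and the
  normalized-length-density (NLD) consecutive-differences method;
* envelope statistics — number of envelope peaks and the mean peak
  amplitude relative to the envelope maximum — plus plain duration.

All measures are invariant to positive affine rescaling of the waveform
(sample entropy when the tolerance is specified as a fraction of the
signal SD), so amplitude normalization upstream cannot affect them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, hilbert, resample_poly

from ._kernels import lz76_word_count, sampen_pair_counts

__all__ = [
    "TemporalConfig",
    "ShortSignalError",
    "DegenerateSignalError",
    "sample_entropy",
    "permutation_entropy",
    "binarize",
    "lz_complexity",
    "higuchi_fd",
    "nld_fd",
    "peak_measures",
    "duration_s",
    "NLD_CALIBRATION_DEFAULT",
    "LZ_CODINGS",
]

LZ_CODINGS = ("differential_binary", "average_binary", "modified_zone_binary")

# Two-anchor power-law calibration FD = a * NLD^k + b with k = 1/2:
# a z-scored smooth signal has NLD -> 0, so b = 1 (FD of a smooth curve);
# z-scored white noise has E|y_{i+1}-y_i| = 2/sqrt(pi), so a is chosen to
# give FD = 2 there.  Exposed as configuration for users with their own
# calibration.
NLD_CALIBRATION_DEFAULT = (1.0 / math.sqrt(2.0 / math.sqrt(math.pi)), 0.5, 1.0)


class ShortSignalError(ValueError):
    """Sequence shorter than the measure's minimum usable length."""


class DegenerateSignalError(ValueError):
    """Sequence has no usable variance for the requested measure."""


@dataclass
class TemporalConfig:
    """Parameters of the temporal measure battery.

    Defaults follow common practice in the nonlinear time-series
    literature: sample entropy with embedding ``m=2`` and tolerance
    ``0.2 * SD``; permutation entropy of order 3, delay 1; Higuchi with
    ``kmax=8``.  Entropic measures (sample/permutation entropy, LZ) are
    computed on a decimated, length-limited window (``analysis_fs``,
    ``entropy_max_seconds``) so the quadratic-cost estimators stay
    tractable for long recordings.
    """

    sampen_m: int = 2
    sampen_r_factor: float = 0.2
    pe_order: int = 3
    pe_delay: int = 1
    lz_zone_factor: float = 1.0
    higuchi_kmax: int = 8
    nld_window: int = 128
    nld_calibration: tuple[float, float, float] = NLD_CALIBRATION_DEFAULT
    peak_envelope_smooth_ms: float = 10.0
    peak_min_prominence: float = 0.1
    analysis_fs: int = 8000
    entropy_max_seconds: float = 10.0

    def __post_init__(self):
        if self.sampen_m < 1:
            raise ValueError("sampen_m must be >= 1")
        if self.sampen_r_factor <= 0:
            raise ValueError("sampen_r_factor must be positive")
        if not 2 <= self.pe_order <= 7:
            raise ValueError("pe_order must be in [2, 7]")
        if self.higuchi_kmax < 2:
            raise ValueError("higuchi_kmax must be >= 2")


def sample_entropy(x, m: int = 2, r: float | None = None) -> float:
    """Sample entropy: -ln(A/B) over Chebyshev template matches.

    B counts unordered pairs of length-``m`` templates within tolerance
    ``r`` (self-matches excluded), A the same at length ``m+1``; both
    template sets run over ``i = 0..n-m-1``.  Returns ``inf`` when no
    length-``m+1`` pair matches (A = 0), the conventional sentinel for an
    unobservable conditional probability.
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    n = len(x)
    if n <= m + 1:
        raise ShortSignalError(f"need more than m+1={m + 1} samples, got {n}")
    if r is None or r <= 0:
        raise ValueError("tolerance r must be positive")
    a, b = sampen_pair_counts(x, m, float(r))
    if b == 0:
        raise DegenerateSignalError("no length-m template matches (B = 0)")
    if a == 0:
        return float("inf")
    return float(-np.log(a / b))


def permutation_entropy(x, order: int = 3, delay: int = 1,
                        normalized: bool = True) -> float:
    """Shannon entropy (bits) of ordinal patterns of the given order/delay.

    Rank ties are resolved by order of appearance (argsort stability),
    which is measure-zero for real audio.  When ``normalized``, the value
    is divided by log2(order!) and lies in [0, 1].
    """
    x = np.asarray(x, dtype=np.float64)
    if order < 2:
        raise ValueError("order must be >= 2")
    n_patterns = len(x) - (order - 1) * delay
    if n_patterns < 2:
        raise ShortSignalError("sequence too short for this order/delay")
    idx = np.arange(n_patterns)[:, None] + np.arange(order)[None, :] * delay
    patterns = np.argsort(x[idx], axis=1, kind="stable")
    # encode each permutation as an integer in factorial-free base `order`
    codes = (patterns * (order ** np.arange(order))).sum(axis=1)
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    h = float(-(p * np.log2(p)).sum())
    if normalized:
        h /= math.log2(math.factorial(order))
    return h


def binarize(x, coding: str = "differential_binary",
             zone_factor: float = 1.0) -> np.ndarray:
    """Reduce a real sequence to a 0/1 sequence for LZ complexity.

    * ``differential_binary``: 1 where the next sample is strictly larger
      (ties coded 0); length n-1.
    * ``average_binary``: 1 where the sample exceeds the sequence mean.
    * ``modified_zone_binary``: 1 where the sample lies outside a zone of
      ``zone_factor`` SDs around the mean.
    """
    x = np.asarray(x, dtype=np.float64)
    if len(x) < 2:
        raise ShortSignalError("need at least 2 samples to binarize")
    if coding == "differential_binary":
        return (np.diff(x) > 0).astype(np.uint8)
    if coding == "average_binary":
        return (x > x.mean()).astype(np.uint8)
    if coding == "modified_zone_binary":
        sd = x.std()
        return (np.abs(x - x.mean()) > zone_factor * sd).astype(np.uint8)
    raise ValueError(f"unknown coding {coding!r}")


def lz_complexity(b, normalized: bool = False) -> float:
    """LZ76 complexity: word count of the exhaustive-history parsing.

    Each word is the shortest continuation not already present as a
    substring of the sequence up to (but excluding) the word's final
    symbol; the final, possibly incomplete word counts as one word.
    Normalized value is ``c(n) * log2(n) / n``.
    """
    if isinstance(b, str):
        arr = (np.frombuffer(b.encode(), dtype=np.uint8)
               - ord("0")).astype(np.uint8)
    else:
        arr = (np.asarray(b) != 0).astype(np.uint8)
    n = arr.size
    if n == 0:
        raise ShortSignalError("empty sequence")
    c = int(lz76_word_count(arr))
    if normalized:
        return c * math.log2(n) / n if n > 1 else float(c)
    return float(c)


def higuchi_fd(x, kmax: int = 8, clip: bool = True) -> float:
    """Higuchi fractal dimension from mean curve length scaling.

    Fits log L(k) against log(1/k) for k = 1..kmax; the slope is the FD
    (1 for a smooth curve, 2 for uncorrelated noise).  The reported value
    is clipped to [1, 2] unless ``clip`` is False.
    """
    x = np.asarray(x, dtype=np.float64)
    n = len(x)
    if kmax < 2:
        raise ValueError("kmax must be >= 2")
    if n < 2 * kmax:
        raise ShortSignalError(f"need at least 2*kmax={2 * kmax} samples")
    log_l = np.empty(kmax)
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if len(idx) < 2:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / ((len(idx) - 1) * k)
            lengths.append(dist * norm / k)
        log_l[k - 1] = np.log(np.mean(lengths))
    log_inv_k = -np.log(np.arange(1, kmax + 1))
    slope = np.polyfit(log_inv_k, log_l, 1)[0]
    return float(np.clip(slope, 1.0, 2.0)) if clip else float(slope)


def nld_fd(x, window: int = 128,
           calibration: tuple[float, float, float] = NLD_CALIBRATION_DEFAULT
           ) -> float:
    """Fractal dimension via normalized length density (NLD).

    Each window is z-scored; NLD is the mean absolute successive
    difference of the normalized window, mapped to an FD through the
    power law ``FD = a * NLD^k + b`` and averaged over windows.
    Zero-variance windows are skipped; an error is raised only if every
    window is degenerate.
    """
    x = np.asarray(x, dtype=np.float64)
    if window < 2:
        raise ValueError("window must be >= 2")
    if len(x) < window:
        raise ShortSignalError(f"need at least window={window} samples")
    a, k, b = calibration
    fds = []
    for start in range(0, len(x) - window + 1, window):
        seg = x[start:start + window]
        sd = seg.std()
        if sd == 0:
            continue
        y = (seg - seg.mean()) / sd
        nld = np.abs(np.diff(y)).mean()
        fds.append(a * nld**k + b)
    if not fds:
        raise DegenerateSignalError("all windows have zero variance")
    return float(np.mean(fds))


def amplitude_envelope(x, fs: float, smooth_ms: float = 10.0) -> np.ndarray:
    """Magnitude of the analytic signal, box-smoothed over ``smooth_ms``."""
    env = np.abs(hilbert(np.asarray(x, dtype=np.float64)))
    win = max(1, int(round(smooth_ms * fs / 1000.0)))
    if win > 1:
        env = np.convolve(env, np.ones(win) / win, mode="same")
    return env


def peak_measures(x, fs: float, cfg: TemporalConfig | None = None) -> dict:
    """Envelope peak count and mean peak amplitude relative to the maximum.

    Peaks are local maxima of the smoothed analytic-signal envelope with
    prominence at least ``peak_min_prominence`` of the envelope maximum.
    A signal whose envelope has no interior peak (steady tone, monotone
    ramp, plateau) is treated as a single peak with relative amplitude 1.
    """
    cfg = cfg or TemporalConfig()
    x = np.asarray(x, dtype=np.float64)
    if np.all(x == 0):
        raise DegenerateSignalError("silent input")
    min_len = 2 * cfg.peak_envelope_smooth_ms * fs / 1000.0
    if len(x) < min_len:
        raise ShortSignalError(
            "signal shorter than twice the envelope smoothing window")
    env = amplitude_envelope(x, fs, cfg.peak_envelope_smooth_ms)
    peak_idx, _ = find_peaks(env, prominence=cfg.peak_min_prominence *
                             env.max())
    if len(peak_idx) == 0:
        return {"num_peaks": 1, "mean_peak_relative_amplitude": 1.0}
    heights = env[peak_idx]
    return {
        "num_peaks": int(len(peak_idx)),
        "mean_peak_relative_amplitude": float(heights.mean() / env.max()),
    }


def duration_s(w) -> float:
    """Duration in seconds of a waveform (len(samples)/sample_rate)."""
    return len(w.samples) / w.sample_rate


def entropy_window(x, fs: float, cfg: TemporalConfig) -> np.ndarray:
    """Decimate to ``cfg.analysis_fs`` and truncate for entropic measures."""
    x = np.asarray(x, dtype=np.float64)
    if fs > cfg.analysis_fs:
        g = math.gcd(int(round(fs)), cfg.analysis_fs)
        x = resample_poly(x, cfg.analysis_fs // g, int(round(fs)) // g)
        fs = cfg.analysis_fs
    n_max = int(round(cfg.entropy_max_seconds * fs))
    return x[:n_max]
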