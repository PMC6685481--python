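"""Audio input/output and amplitude normalization.

All analysis operates on mono waveforms.  Stereo files are mixed down by
channel mean on read; integer PCM is rescaled to [-1, 1].  Banks of sounds
are equalized to a common RMS level (by default the level of the loudest
sound in the bank) so that level differences cannot drive any downstream
measure.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "Waveform",
    "SoundMeta",
    "WavFormatError",
    "EmptyAudioError",
    "SilentSignalError",
    "read_wav",
    "write_wav",
    "normalize_rms",
    "batch_normalize",
    "read_metadata_csv",
    "write_metadata_csv",
    "CATEGORIES",
]

#: Source categories used to group sounds (nine labels; "uncategorized"
#: collects sounds that fit none of the others).
CATEGORIES = (
    "primate",
    "non-primate animal",
    "tool/machine",
    "non-animal nature",
    "human non-vocal",
    "music",
    "insect",
    "explosions/guns",
    "uncategorized",
)


class WavFormatError(ValueError):
    """File is not a readable WAV or uses an unsupported encoding."""


class EmptyAudioError(ValueError):
    """WAV file contains zero samples."""


class SilentSignalError(ValueError):
    """Operation requires nonzero signal energy but RMS is 0."""


@dataclass(frozen=True)
class Waveform:
    """A mono sound: samples (dimensionless amplitude), rate and identity."""

    samples: np.ndarray
    sample_rate: int
    sound_id: str = ""
    category: str = "uncategorized"

    def __post_init__(self):
        object.__setattr__(
            self, "samples", np.asarray(self.samples, dtype=np.float64)
        )
        if self.samples.ndim != 1:
            raise ValueError("Waveform samples must be one-dimensional")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return len(self.samples) / self.sample_rate

    @property
    def rms(self) -> float:
        if len(self.samples) == 0:
            return 0.0
        return float(np.sqrt(np.mean(self.samples**2)))

    @property
    def meta(self) -> "SoundMeta":
        return SoundMeta(self.sound_id, self.category, self.duration)


@dataclass(frozen=True)
class SoundMeta:
    sound_id: str
    category: str
    duration: float = 0.0


_INT_SCALE = {np.dtype(np.int16): 2**15, np.dtype(np.int32): 2**31,
              np.dtype(np.uint8): 2**7}


def read_wav(path: str | os.PathLike, sound_id: str | None = None,
             category: str = "uncategorized") -> Waveform:
    """Read a WAV file to a mono, float64 waveform in [-1, 1].

    PCM 16/24/32-bit and IEEE float encodings are accepted; stereo is mixed
    to mono by channel mean.  Raises :class:`FileNotFoundError`,
    :class:`WavFormatError` or :class:`EmptyAudioError`.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        fs, data = wavfile.read(path)
    except Exception as exc:  # scipy raises bare ValueError on bad RIFF
        raise WavFormatError(f"unsupported/invalid WAV: {path}") from exc
    if data.size == 0:
        raise EmptyAudioError(f"zero-length audio: {path}")
    raw_dtype = data.dtype  # int16/int32 (24-bit widened to int32) or float
    if data.ndim == 2:
        if data.shape[1] > 2:
            raise WavFormatError(f"more than 2 channels: {path}")
        data = data.astype(np.float64).mean(axis=1)
    else:
        data = data.astype(np.float64)
    if raw_dtype.kind == "i":
        data = data / _INT_SCALE[np.dtype(raw_dtype)]
    elif raw_dtype.kind == "u":  # 8-bit unsigned
        data = (data - 128.0) / 128.0
    if sound_id is None:
        sound_id = os.path.splitext(os.path.basename(path))[0]
    return Waveform(data, int(fs), sound_id=sound_id, category=category)


def write_wav(path: str | os.PathLike, w: Waveform,
              encoding: str = "float32") -> None:
    """Write a waveform as WAV (``float32`` or ``pcm16``)."""
    if encoding == "float32":
        wavfile.write(path, w.sample_rate, w.samples.astype(np.float32))
    elif encoding == "pcm16":
        clipped = np.clip(w.samples, -1.0, 32767 / 32768)
        wavfile.write(path, w.sample_rate,
                      np.round(clipped * 32768).astype(np.int16))
    else:
        raise ValueError(f"unknown encoding {encoding!r}")


def normalize_rms(w: Waveform, target_rms: float) -> Waveform:
    """Rescale a waveform by a single positive constant to the target RMS."""
    if target_rms <= 0:
        raise ValueError("target_rms must be positive")
    rms = w.rms
    if rms == 0.0:
        raise SilentSignalError(
            f"cannot normalize silent sound {w.sound_id!r}")
    return replace(w, samples=w.samples * (target_rms / rms))


def batch_normalize(bank: list[Waveform],
                    target_rms: float | None = None) -> list[Waveform]:
    """Equalize a bank of sounds to one common RMS level.

    By default the common level is the RMS of the loudest sound in the bank;
    an absolute ``target_rms`` may be given instead.  Relative sample shapes
    (and hence zero crossings) are unchanged.
    """
    if not bank:
        return []
    silent = [w.sound_id for w in bank if w.rms == 0.0]
    if silent:
        raise SilentSignalError(f"silent sound(s) in bank: {silent}")
    level = max(w.rms for w in bank) if target_rms is None else target_rms
    return [normalize_rms(w, level) for w in bank]


def read_metadata_csv(path: str | os.PathLike) -> pd.DataFrame:
    """Read a sound metadata table: columns sound_id, category, path."""
    df = pd.read_csv(path, dtype=str)
    required = {"sound_id", "category", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata CSV missing columns: {sorted(missing)}")
    return df


def write_metadata_csv(path: str | os.PathLike,
                       entries: list[tuple[str, str, str]]) -> None:
    pd.DataFrame(entries, columns=["sound_id", "category", "path"]).to_csv(
        path, index=False)
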