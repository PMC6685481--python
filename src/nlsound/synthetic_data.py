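"""Synthetic sound banks and perceptual-rating tables.

The original rated sound database is not publicly deposited, so this
module supplies a controlled stand-in: banks of elementary test signals
(tones, harmonic complexes, noises, AM noise, chirps, click trains,
tone-plus-noise mixtures) with enough heterogeneity that every objective
measure varies across the bank, plus a rating model that plants a known
statistical link between measures and percepts.

The rating model mirrors the qualitative inter-percept structure reported
for real listeners: Complexity is tied (negatively) to Familiarity, and
Accuracy of Naming rises with Familiarity through a logistic link, so the
generated correlation matrix has the signs Complexity-Familiarity < 0,
Complexity-Accuracy < 0, Familiarity-Accuracy > 0, with Pleasantness only
weakly coupled to the rest.  Percept structure is planted on the
*measures* (not on raw audio parameters) so that recovery tests are
self-consistent end to end.

Every generator is a pure function of its spec/model and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import chirp as _chirp

from .perception_mapping import RatingsTable
from .salience import FeatureTable
from .signal_io import Waveform, batch_normalize

__all__ = [
    "SOUND_KINDS",
    "SoundSpec",
    "RatingModel",
    "make_sound",
    "make_sound_bank",
    "make_ratings",
]

SOUND_KINDS = (
    "pure_tone",
    "harmonic_complex",
    "white_noise",
    "pink_noise",
    "am_noise",
    "chirp",
    "click_train",
    "tone_plus_noise",
)

#: Pseudo-category assigned to each kind (drawn from the nine source
#: categories a curated sound database would use).
KIND_CATEGORY = {
    "pure_tone": "music",
    "harmonic_complex": "primate",
    "white_noise": "tool/machine",
    "pink_noise": "non-animal nature",
    "am_noise": "non-primate animal",
    "chirp": "insect",
    "click_train": "explosions/guns",
    "tone_plus_noise": "human non-vocal",
}


@dataclass
class SoundSpec:
    """Recipe for one synthetic sound."""

    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0
    duration: float = 1.0
    category: str | None = None
    sound_id: str = ""

    def __post_init__(self):
        if self.kind not in SOUND_KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


def _ramp(x: np.ndarray, fs: float, ms: float = 5.0) -> np.ndarray:
    """Raised-cosine onset/offset ramps to avoid broadband edge clicks."""
    n = min(int(fs * ms / 1000.0), len(x) // 2)
    if n > 0:
        env = 0.5 * (1 - np.cos(np.pi * np.arange(n) / n))
        x = x.copy()
        x[:n] *= env
        x[-n:] *= env[::-1]
    return x


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec /= np.sqrt(f)
    out = np.fft.irfft(spec, n)
    return out / out.std()


def make_sound(spec: SoundSpec, fs: int = 16000) -> Waveform:
    """Render a synthetic waveform; bit-identical for identical (spec, fs)."""
    rng = np.random.default_rng(spec.seed)
    t = np.arange(int(round(spec.duration * fs))) / fs
    p = spec.params
    nyq = fs / 2.0
    kind = spec.kind
    if kind == "pure_tone":
        f0 = p.get("f0", 1000.0)
        if f0 >= nyq:
            raise ValueError("f0 beyond Nyquist")
        x = np.sin(2 * np.pi * f0 * t + p.get("phase", 0.0))
    elif kind == "harmonic_complex":
        f0 = p.get("f0", 200.0)
        n_h = p.get("n_harmonics", 5)
        if f0 * n_h >= nyq:
            raise ValueError("highest harmonic beyond Nyquist")
        rolloff = p.get("rolloff", 1.0)  # amplitude ~ 1/h^rolloff
        x = sum(np.sin(2 * np.pi * f0 * h * t + rng.uniform(0, 2 * np.pi))
                / h**rolloff for h in range(1, n_h + 1))
    elif kind == "white_noise":
        x = rng.standard_normal(len(t))
    elif kind == "pink_noise":
        x = _pink_noise(len(t), rng)
    elif kind == "am_noise":
        fm = p.get("mod_rate", 8.0)
        depth = p.get("mod_depth", 0.8)
        x = rng.standard_normal(len(t)) * (1 + depth *
                                           np.sin(2 * np.pi * fm * t))
    elif kind == "chirp":
        f0 = p.get("f0", 200.0)
        f1 = min(p.get("f1", 4000.0), 0.95 * nyq)
        x = _chirp(t, f0, t[-1] if len(t) > 1 else 1.0, f1,
                   method="logarithmic")
    elif kind == "click_train":
        rate = p.get("rate", 4.0)
        width = max(1, int(fs * p.get("click_ms", 2.0) / 1000.0))
        x = np.zeros(len(t))
        period = int(fs / rate)
        for start in range(period // 2, len(t) - width, period):
            x[start:start + width] = rng.uniform(0.5, 1.0)
    elif kind == "tone_plus_noise":
        f0 = p.get("f0", 500.0)
        n_h = p.get("n_harmonics", 4)
        snr_db = p.get("snr_db", 0.0)
        tone = sum(np.sin(2 * np.pi * f0 * h * t) for h in
                   range(1, n_h + 1))
        tone /= np.sqrt(np.mean(tone**2))
        noise = rng.standard_normal(len(t))
        noise /= np.sqrt(np.mean(noise**2))
        x = 10 ** (snr_db / 20.0) * tone + noise
    else:  # pragma: no cover - guarded by SoundSpec
        raise ValueError(kind)
    x = _ramp(np.asarray(x, dtype=np.float64), fs)
    peak = np.abs(x).max()
    if peak > 0:
        x = x / peak * 0.9
    category = spec.category or KIND_CATEGORY[kind]
    return Waveform(x, fs, sound_id=spec.sound_id or
                    f"{kind}_{spec.seed}", category=category)


def _random_spec(kind: str, rng: np.random.Generator, index: int) -> SoundSpec:
    duration = float(rng.uniform(0.6, 1.4))
    seed = int(rng.integers(0, 2**31 - 1))
    if kind == "pure_tone":
        params = {"f0": float(np.exp(rng.uniform(np.log(200), np.log(4000))))}
    elif kind == "harmonic_complex":
        params = {"f0": float(rng.uniform(100, 400)),
                  "n_harmonics": int(rng.integers(3, 9)),
                  "rolloff": float(rng.uniform(0.5, 1.5))}
    elif kind == "am_noise":
        params = {"mod_rate": float(rng.uniform(2, 16)),
                  "mod_depth": float(rng.uniform(0.4, 1.0))}
    elif kind == "chirp":
        params = {"f0": float(rng.uniform(100, 400)),
                  "f1": float(rng.uniform(2000, 6000))}
    elif kind == "click_train":
        params = {"rate": float(rng.uniform(2, 10))}
        duration = float(rng.uniform(1.0, 2.0))
    elif kind == "tone_plus_noise":
        params = {"f0": float(rng.uniform(150, 800)),
                  "n_harmonics": int(rng.integers(3, 6)),
                  "snr_db": float(rng.uniform(-5, 15))}
    else:  # white_noise, pink_noise
        params = {}
    return SoundSpec(kind=kind, params=params, seed=seed, duration=duration,
                     sound_id=f"s{index:03d}_{kind}")


def make_sound_bank(n: int, seed: int, fs: int = 16000,
                    normalize: bool = True,
                    verify: bool = False) -> list[Waveform]:
    """Generate a stratified bank of ``n`` synthetic sounds.

    Kinds are cycled so each stratum holds roughly n/8 sounds with
    randomized parameters, which guarantees non-degenerate variance in
    every objective measure across the bank.  With ``verify`` the bank is
    additionally checked post hoc for coefficient of variation > 0.05 in
    every default measure (requires a feature-extraction pass; offending
    strata are regenerated with a stepped seed).
    """
    if n < 10:
        raise ValueError("need n >= 10 for a stratified bank")
    rng = np.random.default_rng(seed)
    bank = [make_sound(_random_spec(SOUND_KINDS[i % len(SOUND_KINDS)],
                                    rng, i), fs)
            for i in range(n)]
    if normalize:
        bank = batch_normalize(bank, target_rms=0.1)
    if verify:
        bank = _verify_variability(bank, n, seed, fs, normalize)
    return bank


def _verify_variability(bank, n, seed, fs, normalize, max_rounds: int = 3):
    from .pipeline import extract_features_from_bank

    for round_ in range(max_rounds):
        table = extract_features_from_bank(bank)
        cv = table.data.std() / table.data.mean().abs().clip(lower=1e-12)
        if (cv > 0.05).all():
            return bank
        bank = make_sound_bank(n, seed + 10_000 * (round_ + 1), fs,
                               normalize=normalize, verify=False)
    return bank


@dataclass
class RatingModel:
    """Linear measure-to-percept model with noise and inter-percept links.

    ``weights`` maps each of complexity/pleasantness to coefficients on
    standardized measure columns.  Familiarity is generated as
    ``familiarity_link * (-Complexity latent) + noise`` and Accuracy of
    Naming as a logistic function of the Familiarity latent, reproducing
    the qualitative correlation structure of listener data.  Likert
    percepts are affinely mapped into [1, 7] (linearly, so noiseless
    constructions keep r = 1) and optionally rounded to integers.
    """

    weights: dict = field(default_factory=lambda: {
        "complexity": {"mean_spectral_centroid": 0.8, "hnr": -0.6},
        "pleasantness": {"mean_peak_relative_amplitude": 0.7},
    })
    noise_sd: dict = field(default_factory=lambda: {
        "complexity": 0.5, "pleasantness": 0.5, "familiarity": 0.8,
        "accuracy": 0.8,
    })
    familiarity_link: float = 0.9
    accuracy_link: float = 1.5
    pleasantness_complexity_link: float = -0.3
    likert_quantize: bool = False
    seed: int = 0


def _to_likert(z: np.ndarray, quantize: bool) -> np.ndarray:
    """Affine map of a latent onto [1, 7] centred at 4, preserving order.

    The slope shrinks only as needed to fit the observed range, so the
    map is strictly linear over the sample and cannot distort planted
    correlations.
    """
    zmax = np.abs(z).max()
    slope = 1.2 if zmax <= 2.5 else 3.0 / zmax
    likert = np.clip(4.0 + slope * z, 1.0, 7.0)  # clip trims one ulp at most
    if quantize:
        likert = np.round(likert)
    return likert


def make_ratings(features: FeatureTable, model: RatingModel) -> RatingsTable:
    """Generate per-sound ratings from measures via the rating model."""
    df = features.data
    rng = np.random.default_rng(model.seed)

    def latent(percept: str) -> np.ndarray:
        z = np.zeros(len(df))
        for measure, w in model.weights.get(percept, {}).items():
            if measure not in df.columns:
                raise ValueError(f"unknown measure {measure!r} in weights")
            col = df[measure].to_numpy(dtype=float)
            sd = col.std()
            z += w * (col - col.mean()) / (sd if sd > 0 else 1.0)
        sd_noise = model.noise_sd.get(percept, 0.0)
        if sd_noise > 0:
            z = z + rng.normal(0, sd_noise, len(df))
        return z

    c = latent("complexity")
    p = latent("pleasantness") + model.pleasantness_complexity_link * c
    f = model.familiarity_link * (-c)
    sd_f = model.noise_sd.get("familiarity", 0.0)
    if sd_f > 0:
        f = f + rng.normal(0, sd_f, len(df))
    logit = model.accuracy_link * f
    sd_a = model.noise_sd.get("accuracy", 0.0)
    if sd_a > 0:
        logit = logit + rng.normal(0, sd_a, len(df))
    accuracy = 1.0 / (1.0 + np.exp(-logit))
    out = pd.DataFrame({
        "complexity": _to_likert(c, model.likert_quantize),
        "pleasantness": _to_likert(p, model.likert_quantize),
        "familiarity": _to_likert(f, model.likert_quantize),
        "accuracy": accuracy,
    }, index=df.index)
    ratings = RatingsTable(out)
    ratings.validate()
    return ratings
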