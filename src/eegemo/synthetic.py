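"""Synthetic multichannel EEG with controllable cross-subject emotion
structure.

Real EEG emotion datasets are license-gated, so every stage of the
pipeline is exercised on generated data whose ground truth is known.  A
trial is the sum of

* 1/f^β background noise (β = 1 by default, the canonical EEG spectral
  slope), and
* one sinusoidal oscillator per rhythm band (theta/alpha/beta/gamma) with
  a random phase per trial and channel.

The emotion effect is planted as a band-limited amplitude change:
positive-class trials multiply the chosen band's oscillator amplitude by
``effect_size`` on a designated subset of channels.  Cross-subject
variability — the difficulty the method targets — enters as a persistent
per-subject multiplicative amplitude offset drawn from
``Normal(1, subject_sd)``.

Two layout modes follow :class:`~eegemo.datasets.DatasetDescriptor`:
continuous-valence mode emits balanced ratings on both sides of the
binarization threshold (positive ~ U(6, 9), negative ~ U(1, 4)), and
categorical mode emits 5 positive / 5 neutral / 5 negative trials per
session in shuffled order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import DatasetDescriptor, TrialSet
from .features import FeatureMatrix

__all__ = ["EffectSpec", "generate_trialset", "generate_feature_table",
           "planted_recovery"]

#: representative oscillator frequency (Hz) and baseline amplitude per band
_BAND_OSCILLATORS = {
    "theta": (5.0, 4.0),
    "alpha": (10.0, 5.0),
    "beta": (21.0, 3.0),
    "gamma": (38.0, 2.0),
}
_NOISE_STD = 5.0  # microvolt-scale background level


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth description of the planted class effect."""

    discriminative_channels: tuple[int, ...] = (0,)
    band: str = "alpha"
    effect_size: float = 2.0     # amplitude multiplier for positive trials
    subject_sd: float = 0.1      # sd of per-subject amplitude offsets
    noise_exponent: float = 1.0  # 1/f^β slope
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size < 1:
            raise ValueError("effect_size must be >= 1")
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be >= 0")
        if self.band not in _BAND_OSCILLATORS:
            raise ValueError(f"unknown band {self.band!r}")
        if self.effect_size > 1 and not self.discriminative_channels:
            raise ValueError("discriminative_channels must be non-empty "
                             "when effect_size > 1")


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], fs: float,
                beta: float) -> np.ndarray:
    """1/f^β noise along the last axis, unit-variance before scaling."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    if beta == 0:
        return white
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    shaping[1:] = freqs[1:] ** (-beta / 2.0)
    shaping[0] = 0.0  # no DC drift
    x = np.fft.irfft(spec * shaping, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)


def generate_trialset(descriptor: DatasetDescriptor, effect: EffectSpec
                      ) -> tuple[TrialSet, np.ndarray]:
    """Generate a full TrialSet in the given layout.

    Returns the TrialSet and the ground-truth class array per trial:
    1 = positive, 0 = negative, −1 = neutral (categorical mode only).
    Ratings encode the class in the layout's native form, so downstream
    label processing recovers these labels exactly.
    """
    rng = np.random.default_rng(effect.seed)
    n_trials = descriptor.n_trials
    n_ch = descriptor.n_channels
    n_samp = descriptor.n_samples
    fs = descriptor.fs_hz
    per_block = descriptor.trials_per_subject_session
    categorical = descriptor.rating_kind == "categorical"

    subject_id = np.empty(n_trials, dtype=np.int64)
    session_id = np.empty(n_trials, dtype=np.int64)
    truth = np.empty(n_trials, dtype=np.int64)
    i = 0
    for subj in range(descriptor.n_subjects):
        for sess in range(descriptor.n_sessions):
            block = slice(i, i + per_block)
            subject_id[block] = subj
            session_id[block] = sess
            if categorical:
                if per_block % 3:
                    raise ValueError("categorical mode needs "
                                     "trials_per_subject_session % 3 == 0")
                k = per_block // 3
                classes = np.array([1] * k + [-1] * k + [0] * k)
            else:
                k = per_block // 2
                classes = np.array([1] * k + [0] * (per_block - k))
            rng.shuffle(classes)
            truth[block] = classes
            i += per_block

    if categorical:
        ratings = np.array(["positive", "neutral", "negative"])[
            np.select([truth == 1, truth == -1], [0, 1], default=2)]
    else:
        ratings = np.where(truth == 1, rng.uniform(6.0, 9.0, n_trials),
                           rng.uniform(1.0, 4.0, n_trials))

    subj_amp = 1.0 + rng.normal(0.0, effect.subject_sd,
                                descriptor.n_subjects)
    subj_amp = np.clip(subj_amp, 0.1, None)

    signals = _NOISE_STD * _pink_noise(rng, (n_trials, n_ch, n_samp), fs,
                                       effect.noise_exponent)
    t = np.arange(n_samp) / fs
    disc = np.zeros(n_ch, dtype=bool)
    disc[list(effect.discriminative_channels)] = True
    for band, (f0, amp0) in _BAND_OSCILLATORS.items():
        phases = rng.uniform(0.0, 2.0 * np.pi, (n_trials, n_ch))
        amp = np.full((n_trials, n_ch), amp0)
        if band == effect.band:
            amp[np.ix_(truth == 1, disc)] *= effect.effect_size
        signals += amp[:, :, None] * np.sin(
            2.0 * np.pi * f0 * t[None, None, :] + phases[:, :, None])
    signals *= subj_amp[subject_id][:, None, None]

    trialset = TrialSet(signals=signals, fs=fs, subject_id=subject_id,
                        session_id=session_id, ratings=ratings)
    return trialset, truth


def generate_feature_table(n_subjects: int = 8, n_trials: int = 20,
                           n_features: int = 50, n_informative: int = 5,
                           delta: float = 1.0, subject_sd: float = 0.5,
                           seed: int = 0) -> FeatureMatrix:
    """Direct tabular generator for fast selection/classification tests.

    ``n_trials`` is per subject, with balanced 0/1 labels.  Features are
    standard normal; the first ``n_informative`` columns are mean-shifted
    by ``delta`` for class-1 rows.  Each subject adds its own random
    intercept (``Normal(0, subject_sd)`` per subject and feature),
    emulating the cross-subject shift that breaks naive pooling.
    """
    if n_informative > n_features:
        raise ValueError("n_informative must be <= n_features")
    rng = np.random.default_rng(seed)
    n_rows = n_subjects * n_trials
    subject_id = np.repeat(np.arange(n_subjects), n_trials)
    labels = np.empty(n_rows, dtype=np.int64)
    for s in range(n_subjects):
        block = np.array([1] * (n_trials // 2)
                         + [0] * (n_trials - n_trials // 2))
        rng.shuffle(block)
        labels[s * n_trials:(s + 1) * n_trials] = block
    X = rng.standard_normal((n_rows, n_features))
    intercepts = rng.normal(0.0, subject_sd, (n_subjects, n_features))
    X += intercepts[subject_id]
    X[:, :n_informative] += delta * labels[:, None]
    names = [f"f{j:03d}" for j in range(n_features)]
    return FeatureMatrix(values=X, column_names=names, labels=labels,
                         subject_id=subject_id)


def planted_recovery(selected_columns, discriminative_channels,
                     channel_names) -> tuple[float, float]:
    """Score selected feature columns against the planted ground truth.

    The planted effect lives on whole channels (a band-amplitude change
    perturbs several features of the same channel), so recovery is scored
    at channel level: *precision* is the fraction of selected columns
    whose channel is discriminative, *recall* the fraction of
    discriminative channels represented by at least one selected column.
    Column names follow the ``"<channel>__<feature>"`` convention.
    """
    disc = {channel_names[i] for i in discriminative_channels}
    if not selected_columns:
        return 0.0, 0.0
    sel_channels = [name.rsplit("__", 1)[0] for name in selected_columns]
    precision = sum(ch in disc for ch in sel_channels) / len(sel_channels)
    recall = len(disc & set(sel_channels)) / len(disc)
    return float(precision), float(recall)
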