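"""Ten per-channel EEG features and assembly of the trial × feature matrix.

Per channel and trial the extractors are, in fixed column order:

1. Hjorth activity         variance of the signal
2. Hjorth mobility         sqrt(var(dx) / var(x))
3. Hjorth complexity       mobility(dx) / mobility(x)
4. Standard deviation      population convention (ddof=0) by default
5. PSD-alpha               mean Welch PSD over 8–13 Hz of the alpha-filtered signal
6. PSD-beta                14–29 Hz, beta-filtered
7. PSD-gamma               30–47 Hz, gamma-filtered
8. PSD-theta               3–7 Hz, theta-filtered
9. Sample entropy          −ln(A/B) template statistic (m=2, r=0.2·sd)
10. Wavelet entropy        Shannon entropy of relative wavelet energies

Hjorth parameters, standard deviation, sample entropy and wavelet entropy
are computed on the broadband (pre-cleaned) signal; the four band-power
features on the corresponding zero-phase band-filtered signal.  Stacking
all channels of all trials yields the high-dimensional feature matrix the
selection and classification stages consume (e.g. 1280 × 320 for a
40-trial × 32-subject, 32-channel layout; 450 × 620 for the 62-channel
positive/negative layout).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pywt
from scipy import signal as sps
from scipy.spatial import cKDTree

from .datasets import LabelVector, TrialSet

__all__ = [
    "RhythmBands",
    "FeatureConfig",
    "FeatureMatrix",
    "WaveletEnergyDistribution",
    "FEATURE_ORDER",
    "bandpass_rhythm",
    "hjorth_parameters",
    "standard_deviation",
    "psd_band_power",
    "sample_entropy",
    "wavelet_energy_distribution",
    "energy_entropy",
    "wavelet_entropy",
    "assemble_feature_matrix",
    "save_feature_matrix",
    "load_feature_matrix",
]


@dataclass(frozen=True)
class RhythmBands:
    """Canonical EEG rhythm bands in Hz (low, high), in ascending order."""

    theta: tuple[float, float] = (3.0, 7.0)
    alpha: tuple[float, float] = (8.0, 13.0)
    beta: tuple[float, float] = (14.0, 29.0)
    gamma: tuple[float, float] = (30.0, 47.0)

    def __post_init__(self) -> None:
        prev_high = 0.0
        for name in ("theta", "alpha", "beta", "gamma"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name}: low must be < high")
            if lo < prev_high:
                raise ValueError("bands must be non-overlapping and ordered")
            prev_high = hi

    def items(self):
        return [(n, getattr(self, n)) for n in ("theta", "alpha", "beta",
                                                "gamma")]


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable extraction parameters (all defaults are standard practice)."""

    bands: RhythmBands = field(default_factory=RhythmBands)
    filter_order: int = 4          # Butterworth order, applied zero-phase
    welch_window_s: float = 2.0    # Hann segment length for Welch PSD
    welch_overlap: float = 0.5
    sampen_m: int = 2
    sampen_r_factor: float = 0.2   # r = factor × per-signal std
    wavelet: str = "db4"
    wavelet_levels: int = 4
    std_ddof: int = 0              # population convention


#: per-channel feature column order
FEATURE_ORDER = ("activity", "mobility", "complexity", "std",
                 "psd_alpha", "psd_beta", "psd_gamma", "psd_theta",
                 "sampen", "we")


# ---------------------------------------------------------------------------
# individual extractors
# ---------------------------------------------------------------------------

def bandpass_rhythm(x: np.ndarray, fs: float, band: tuple[float, float],
                    order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    The filter is applied forward and backward (``sosfiltfilt``) so the
    passband gain is ~1 with no phase distortion.
    """
    lo, hi = band
    nyq = fs / 2.0
    if not 0 < lo < hi:
        raise ValueError(f"invalid band {band}")
    if hi >= nyq:
        raise ValueError(f"band edge {hi} Hz >= Nyquist {nyq} Hz")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=np.float64), axis=-1)


def hjorth_parameters(x: np.ndarray) -> tuple[np.ndarray, np.ndarray,
                                              np.ndarray]:
    """Hjorth activity, mobility and complexity along the last axis.

    activity = var(x); mobility = sqrt(var(dx)/var(x));
    complexity = mobility(dx)/mobility(x).  A constant signal maps to
    (0, 0, 0) by convention; a signal whose first difference is constant
    (zero) likewise gets zero mobility/complexity.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] < 3:
        raise ValueError("hjorth_parameters needs at least 3 samples")
    var0 = x.var(axis=-1)
    d1 = np.diff(x, axis=-1)
    var1 = d1.var(axis=-1)
    d2 = np.diff(d1, axis=-1)
    var2 = d2.var(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mobility = np.sqrt(np.where(var0 > 0, var1 / np.where(var0 > 0, var0, 1), 0.0))
        mob_d1 = np.sqrt(np.where(var1 > 0, var2 / np.where(var1 > 0, var1, 1), 0.0))
        complexity = np.where(mobility > 0, mob_d1 / np.where(mobility > 0, mobility, 1), 0.0)
    return var0, mobility, complexity


def standard_deviation(x: np.ndarray, ddof: int = 0) -> np.ndarray:
    """Standard deviation along the last axis (population, ddof=0, by default)."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] < 2:
        raise ValueError("standard_deviation needs at least 2 samples")
    return x.std(axis=-1, ddof=ddof)


def psd_band_power(x: np.ndarray, fs: float, band: tuple[float, float],
                   window_s: float = 2.0, overlap: float = 0.5) -> np.ndarray:
    """Mean Welch power-spectral density over the bins inside ``band``.

    Band edges are inclusive; units are (signal unit)²/Hz.  Welch uses
    Hann segments of ``window_s`` seconds with fractional ``overlap``.
    Raises if the signal is shorter than one segment or no frequency bin
    falls inside the band.
    """
    x = np.asarray(x, dtype=np.float64)
    nperseg = int(round(window_s * fs))
    if x.shape[-1] < nperseg:
        raise ValueError(
            f"signal ({x.shape[-1]} samples) shorter than one Welch segment "
            f"({nperseg} samples)")
    freqs, psd = sps.welch(x, fs=fs, window="hann", nperseg=nperseg,
                           noverlap=int(round(nperseg * overlap)), axis=-1)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any():
        raise ValueError(f"no PSD bin inside band {band} at resolution "
                         f"{freqs[1] - freqs[0]:g} Hz")
    return psd[..., sel].mean(axis=-1)


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None,
                   r_factor: float = 0.2) -> float:
    """Sample entropy of a 1-D signal.

    SampEn(m, r) = −ln(A/B) where B counts ordered template pairs
    (i ≠ j) of length ``m`` within Chebyshev distance ``r`` and A counts
    the same for length ``m+1``; self-matches are excluded.  Both counts
    use the same number of templates (n − m − 1 vectors per length, the
    Richman–Moorman convention).  ``r`` defaults to
    ``r_factor × std(x)``.  A constant signal returns 0; if no m+1
    template pair matches (A = 0) the value is capped at
    ``ln(B) + ln(n)``, and if not even an m-length pair matches (B = 0)
    at ``2 ln(n)``.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    n = x.size
    if n < m + 2:
        raise ValueError(f"sample_entropy needs at least m+2={m + 2} samples")
    sd = x.std()
    if sd == 0:
        return 0.0
    if r is None:
        r = r_factor * sd
    if r <= 0:
        raise ValueError("tolerance r must be positive")
    # n - m - 1 templates for each length, so A/B is a proper conditional
    # probability estimate
    n_templates = n - m - 1
    emb_m = np.lib.stride_tricks.sliding_window_view(x, m)[:n_templates]
    emb_m1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)[:n_templates]
    b = _count_pairs_within(emb_m, r)
    a = _count_pairs_within(emb_m1, r)
    if b == 0:
        return float(2.0 * np.log(n))
    if a == 0:
        return float(np.log(b) + np.log(n))
    return float(-np.log(a / b))


def _count_pairs_within(emb: np.ndarray, r: float) -> int:
    """Unordered template pairs within Chebyshev distance r (inclusive)."""
    tree = cKDTree(emb)
    # count_neighbors counts ordered pairs including self-pairs
    ordered = tree.count_neighbors(tree, r, p=np.inf)
    return int(ordered - len(emb)) // 2


@dataclass(frozen=True)
class WaveletEnergyDistribution:
    """Relative wavelet energy per decomposition component (sums to 1)."""

    p: np.ndarray
    levels: int

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=np.float64)
        if (p < -1e-12).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("relative energies must be >= 0 and sum to 1")
        object.__setattr__(self, "p", p)


def wavelet_energy_distribution(x: np.ndarray, wavelet: str = "db4",
                                levels: int = 4) -> WaveletEnergyDistribution:
    """Relative energy across the ``levels + 1`` wavelet components.

    The discrete wavelet transform at ``levels`` levels yields one
    approximation and ``levels`` detail coefficient sets; the energy of
    each is normalised by the total.  An all-zero signal has no energy to
    distribute and raises ``ValueError``.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    if x.size < 2 ** levels:
        raise ValueError(f"signal too short for {levels} wavelet levels")
    coeffs = pywt.wavedec(x, wavelet, level=levels)
    energies = np.array([float(np.sum(c ** 2)) for c in coeffs])
    total = energies.sum()
    if total == 0:
        raise ValueError("all-zero signal has a degenerate energy distribution")
    return WaveletEnergyDistribution(p=energies / total, levels=levels)


def energy_entropy(p: np.ndarray | WaveletEnergyDistribution) -> float:
    """Shannon entropy −Σ p_j ln p_j of a relative-energy distribution."""
    if isinstance(p, WaveletEnergyDistribution):
        p = p.p
    p = np.asarray(p, dtype=np.float64)
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz))) + 0.0  # avoid -0.0


def wavelet_entropy(x: np.ndarray, wavelet: str = "db4", levels: int = 4,
                    on_zero: str = "raise") -> float:
    """Total wavelet entropy of a 1-D signal.

    Shannon entropy of the relative wavelet energy distribution across the
    ``levels + 1`` decomposition components; ranges over
    ``[0, ln(levels + 1)]``.  A high value means energy is spread across
    scales (disorder); concentration in one component gives 0.
    ``on_zero="zero"`` returns 0 for an all-zero signal instead of raising.
    """
    try:
        dist = wavelet_energy_distribution(x, wavelet=wavelet, levels=levels)
    except ValueError:
        if on_zero == "zero" and np.all(np.asarray(x) == 0):
            return 0.0
        raise
    return energy_entropy(dist)


# ---------------------------------------------------------------------------
# feature matrix assembly
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Trials × features table with column names and per-row metadata."""

    values: np.ndarray
    column_names: list[str]
    labels: np.ndarray
    subject_id: np.ndarray
    session_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (trials × features)")
        if len(self.column_names) != self.values.shape[1]:
            raise ValueError("column_names length must match n_features")
        if len(set(self.column_names)) != len(self.column_names):
            raise ValueError("column_names must be unique")
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.subject_id = np.asarray(self.subject_id)
        if self.labels.shape[0] != self.values.shape[0]:
            raise ValueError("labels length must match n_trials")
        if self.subject_id.shape[0] != self.values.shape[0]:
            raise ValueError("subject_id length must match n_trials")
        if self.session_id is not None:
            self.session_id = np.asarray(self.session_id)
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite feature value at trial {bad[0]}, column "
                f"{self.column_names[bad[1]]!r}")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select_columns(self, mask_or_idx) -> "FeatureMatrix":
        idx = np.arange(self.n_features)[mask_or_idx]
        return FeatureMatrix(self.values[:, idx],
                             [self.column_names[i] for i in idx],
                             self.labels, self.subject_id, self.session_id)


def assemble_feature_matrix(trialset: TrialSet, labels: LabelVector | np.ndarray,
                            config: FeatureConfig | None = None,
                            extractors: Sequence[str] = FEATURE_ORDER,
                            ) -> FeatureMatrix:
    """Extract the per-channel features for every trial.

    One row per trial; for each channel the requested ``extractors``
    (default: all ten, in canonical order) form consecutive columns named
    ``"<channel>__<feature>"``.  Band-power features are computed on the
    band-filtered signal, everything else on the broadband signal.

    ``labels`` may be a :class:`LabelVector` (its ``kept_mask`` must match
    the TrialSet's trial count, i.e. apply it to the TrialSet first or pass
    a set whose trials are already the kept ones) or a plain 0/1 array of
    length ``n_trials``.
    """
    cfg = config or FeatureConfig()
    if isinstance(labels, LabelVector):
        y = labels.values
    else:
        y = np.asarray(labels, dtype=np.int64)
    if y.shape[0] != trialset.n_trials:
        raise ValueError("labels length must equal the TrialSet trial count")
    unknown = set(extractors) - set(FEATURE_ORDER)
    if unknown:
        raise ValueError(f"unknown extractors: {sorted(unknown)}")

    X = trialset.signals  # (T, C, S)
    fs = trialset.fs
    cols: dict[str, np.ndarray] = {}

    need = set(extractors)
    if need & {"activity", "mobility", "complexity"}:
        act, mob, comp = hjorth_parameters(X)
        cols["activity"], cols["mobility"], cols["complexity"] = act, mob, comp
    if "std" in need:
        cols["std"] = standard_deviation(X, ddof=cfg.std_ddof)
    band_feats = {"psd_alpha": "alpha", "psd_beta": "beta",
                  "psd_gamma": "gamma", "psd_theta": "theta"}
    bands = dict(cfg.bands.items())
    for feat, band_name in band_feats.items():
        if feat in need:
            band = bands[band_name]
            filtered = bandpass_rhythm(X, fs, band, order=cfg.filter_order)
            cols[feat] = psd_band_power(filtered, fs, band,
                                        window_s=cfg.welch_window_s,
                                        overlap=cfg.welch_overlap)
    if "sampen" in need:
        se = np.empty(X.shape[:2])
        for t in range(X.shape[0]):
            for c in range(X.shape[1]):
                se[t, c] = sample_entropy(X[t, c], m=cfg.sampen_m,
                                          r_factor=cfg.sampen_r_factor)
        cols["sampen"] = se
    if "we" in need:
        coeffs = pywt.wavedec(X, cfg.wavelet, level=cfg.wavelet_levels,
                              axis=-1)
        energies = np.stack([np.sum(c ** 2, axis=-1) for c in coeffs],
                            axis=-1)  # (T, C, L+1)
        total = energies.sum(axis=-1, keepdims=True)
        if (total == 0).any():
            t, c, _ = np.argwhere(total == 0)[0]
            raise ValueError(f"all-zero signal at trial {t}, channel "
                             f"{trialset.channel_names[c]!r}")
        p = energies / total
        with np.errstate(divide="ignore", invalid="ignore"):
            logp = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), 0.0)
        cols["we"] = -(p * logp).sum(axis=-1)

    order = [f for f in FEATURE_ORDER if f in need]
    values = np.empty((trialset.n_trials,
                       trialset.n_channels * len(order)))
    names: list[str] = []
    for c, ch in enumerate(trialset.channel_names):
        for k, feat in enumerate(order):
            values[:, c * len(order) + k] = cols[feat][:, c]
            names.append(f"{ch}__{feat}")
    return FeatureMatrix(values=values, column_names=names, labels=y,
                         subject_id=trialset.subject_id,
                         session_id=trialset.session_id)


def save_feature_matrix(fm: FeatureMatrix, csv_path: str | Path) -> None:
    """Write values to CSV (header = column names) plus a JSON sidecar
    carrying labels, subject and session ids."""
    import pandas as pd

    csv_path = Path(csv_path)
    pd.DataFrame(fm.values, columns=fm.column_names).to_csv(
        csv_path, index=False, float_format="%.17g")
    sidecar = {
        "labels": [int(v) for v in fm.labels],
        "subject_id": [int(v) for v in fm.subject_id],
        "session_id": (None if fm.session_id is None
                       else [int(v) for v in fm.session_id]),
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_feature_matrix(csv_path: str | Path) -> FeatureMatrix:
    import pandas as pd

    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path, float_precision="round_trip")
    sidecar = json.loads(csv_path.with_suffix(".json").read_text())
    session = sidecar.get("session_id")
    return FeatureMatrix(values=df.to_numpy(dtype=np.float64),
                         column_names=list(df.columns),
                         labels=np.asarray(sidecar["labels"]),
                         subject_id=np.asarray(sidecar["subject_id"]),
                         session_id=None if session is None
                         else np.asarray(session))
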