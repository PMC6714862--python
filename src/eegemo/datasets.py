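"""Trial containers, dataset layouts, label processing and I/O.

The central object is :class:`TrialSet`: a dense block of multichannel EEG
trials (``n_trials × n_channels × n_samples``) together with the per-trial
metadata the cross-subject pipeline needs (subject, session, emotion
rating).  Two canonical layouts are described by :class:`DatasetDescriptor`
factories: a 32-subject valence-rating layout (40 one-minute trials per
subject, 32 channels at 128 Hz, continuous 1–9 ratings) and a 15-subject
three-session layout (15 four-minute trials per session, 62 channels at
200 Hz, categorical positive/neutral/negative labels).

The real public datasets with these layouts are distributed under license;
this module only defines the shapes and the label-processing conventions,
and reads/writes portable containers (HDF5, EDF, CSV directory).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "TrialSet",
    "DatasetDescriptor",
    "LabelVector",
    "deap_layout",
    "seed_layout",
    "binarize_valence",
    "select_pos_neg",
    "extract_middle_window",
    "save_trialset",
    "load_trialset",
]

#: categorical label strings accepted in ``TrialSet.ratings``
CATEGORICAL_LABELS = ("positive", "neutral", "negative")


class FormatError(ValueError):
    """A container is missing metadata or uses an unknown layout."""


class ShapeError(ValueError):
    """Trial signals are inconsistent in shape."""


class DegenerateClassError(ValueError):
    """An operation requires both emotion classes to be present."""


@dataclass(frozen=True)
class DatasetDescriptor:
    """Static description of a dataset layout.

    Parameters
    ----------
    n_subjects : int
        Number of participants.
    trials_per_subject_session : int
        Trials recorded per subject per session.
    n_sessions : int
        Recording sessions per subject (1 for single-session designs).
    n_channels : int
        EEG channels.
    fs_hz : float
        Sampling rate in Hz.
    trial_duration_s : float
        Trial length in seconds.
    rating_kind : {"continuous_valence", "categorical"}
        Whether trials carry a continuous 1–9 valence score or a
        positive/neutral/negative category.
    """

    n_subjects: int
    trials_per_subject_session: int
    n_sessions: int
    n_channels: int
    fs_hz: float
    trial_duration_s: float
    rating_kind: str

    def __post_init__(self) -> None:
        for name in ("n_subjects", "trials_per_subject_session", "n_sessions",
                     "n_channels"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.fs_hz <= 0 or self.trial_duration_s <= 0:
            raise ValueError("fs_hz and trial_duration_s must be positive")
        if self.rating_kind not in ("continuous_valence", "categorical"):
            raise ValueError(f"unknown rating_kind {self.rating_kind!r}")

    @property
    def n_trials(self) -> int:
        return self.n_subjects * self.n_sessions * self.trials_per_subject_session

    @property
    def n_samples(self) -> int:
        return int(round(self.fs_hz * self.trial_duration_s))

    def with_duration(self, trial_duration_s: float) -> "DatasetDescriptor":
        """Same layout at a different trial duration (for desk-scale runs)."""
        return replace(self, trial_duration_s=trial_duration_s)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "DatasetDescriptor":
        return cls(**json.loads(Path(path).read_text()))


def deap_layout() -> DatasetDescriptor:
    """32 subjects × 40 trials, 32 channels, 128 Hz, 60 s, valence 1–9."""
    return DatasetDescriptor(32, 40, 1, 32, 128.0, 60.0, "continuous_valence")


def seed_layout() -> DatasetDescriptor:
    """15 subjects × 3 sessions × 15 trials, 62 channels, 200 Hz, 240 s."""
    return DatasetDescriptor(15, 15, 3, 62, 200.0, 240.0, "categorical")


@dataclass
class TrialSet:
    """Multichannel EEG trials plus per-trial metadata.

    ``signals`` is ``(n_trials, n_channels, n_samples)`` in microvolt-scale
    units.  ``ratings`` is either a float array (continuous valence, 1–9)
    or an object/str array of ``positive``/``neutral``/``negative``.
    """

    signals: np.ndarray
    fs: float
    subject_id: np.ndarray
    session_id: np.ndarray
    ratings: np.ndarray
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=np.float64)
        if self.signals.ndim != 3:
            raise ShapeError(
                f"signals must be 3-D (trials, channels, samples); got "
                f"shape {self.signals.shape}")
        n = self.n_trials
        self.subject_id = np.asarray(self.subject_id)
        self.session_id = np.asarray(self.session_id)
        self.ratings = np.asarray(self.ratings)
        for name, arr in (("subject_id", self.subject_id),
                          ("session_id", self.session_id),
                          ("ratings", self.ratings)):
            if arr.shape != (n,):
                raise ShapeError(f"{name} must have length n_trials={n}; "
                                 f"got shape {arr.shape}")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ShapeError("channel_names length must equal n_channels")
        if len(set(self.channel_names)) != self.n_channels:
            raise ValueError("channel_names contains duplicates")

    @property
    def n_trials(self) -> int:
        return self.signals.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signals.shape[1]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[2]

    @property
    def is_categorical(self) -> bool:
        return not np.issubdtype(self.ratings.dtype, np.number)

    def subset(self, mask: np.ndarray) -> "TrialSet":
        """Row-subset along trials (boolean mask or index array)."""
        return TrialSet(self.signals[mask], self.fs, self.subject_id[mask],
                        self.session_id[mask], self.ratings[mask],
                        list(self.channel_names))


@dataclass
class LabelVector:
    """Binary emotion labels after label processing.

    ``values[i]`` labels the i-th *kept* trial: 1 = positive, 0 = negative.
    ``kept_mask`` maps kept trials back to rows of the original TrialSet.
    """

    values: np.ndarray
    kept_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        self.kept_mask = np.asarray(self.kept_mask, dtype=bool)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("labels must be 0/1")
        if self.values.shape[0] != int(self.kept_mask.sum()):
            raise ShapeError("values length must equal number of kept trials")

    def __len__(self) -> int:
        return len(self.values)


def binarize_valence(ratings: Sequence[float] | np.ndarray,
                     threshold: float = 5.0,
                     on_threshold: str = "exclude") -> LabelVector:
    """Binarize continuous valence ratings around ``threshold``.

    Ratings above the threshold become positive (1), below negative (0).
    A rating exactly at the threshold is unassigned by the convention
    "higher than 5 → positive, below 5 → negative"; by default such trials
    are excluded (``on_threshold="exclude"``), or assigned to the negative
    class with ``on_threshold="negative"``.
    """
    r = np.asarray(ratings, dtype=np.float64)
    if r.ndim != 1:
        raise ShapeError("ratings must be 1-D")
    if np.any((r < 1.0) | (r > 9.0)) or np.any(~np.isfinite(r)):
        raise ValueError("ratings must lie within [1, 9]")
    if on_threshold not in ("exclude", "negative"):
        raise ValueError("on_threshold must be 'exclude' or 'negative'")
    at = r == threshold
    kept = ~at if on_threshold == "exclude" else np.ones_like(at)
    values = (r[kept] > threshold).astype(np.int64)
    return LabelVector(values=values, kept_mask=kept)


def select_pos_neg(trialset: TrialSet) -> tuple[TrialSet, LabelVector]:
    """Drop neutral trials from a categorically labelled TrialSet.

    Returns the positive/negative-only TrialSet and the matching binary
    labels (positive = 1, negative = 0).  Raises
    :class:`DegenerateClassError` if either class would be absent.
    """
    if not trialset.is_categorical:
        raise ValueError("select_pos_neg requires categorical ratings")
    cats = np.asarray([str(c) for c in trialset.ratings])
    unknown = set(cats) - set(CATEGORICAL_LABELS)
    if unknown:
        raise FormatError(f"unknown categorical labels: {sorted(unknown)}")
    kept = cats != "neutral"
    values = (cats[kept] == "positive").astype(np.int64)
    if len(values) == 0 or values.min() == values.max():
        raise DegenerateClassError(
            "both positive and negative trials are required")
    return trialset.subset(kept), LabelVector(values=values, kept_mask=kept)


def extract_middle_window(trialset: TrialSet, window_s: float = 60.0) -> TrialSet:
    """Crop every trial to a centered window of ``window_s`` seconds.

    The window is half-open ``[start, start + window_s*fs)`` in 0-based
    sample coordinates with ``start = floor((n_samples - win_len) / 2)``.
    """
    win_len = int(round(window_s * trialset.fs))
    if win_len > trialset.n_samples:
        raise ShapeError(
            f"window of {win_len} samples exceeds trial length "
            f"{trialset.n_samples}")
    start = (trialset.n_samples - win_len) // 2
    return TrialSet(trialset.signals[:, :, start:start + win_len],
                    trialset.fs, trialset.subject_id, trialset.session_id,
                    trialset.ratings, list(trialset.channel_names))


# ---------------------------------------------------------------------------
# I/O: HDF5 container, EDF (read-only), CSV directory
# ---------------------------------------------------------------------------

_H5_KEYS = ("signals", "fs", "subject_id", "session_id", "ratings",
            "channel_names")


def save_trialset(trialset: TrialSet, path: str | Path,
                  format: str = "container-hdf5") -> None:
    """Write a TrialSet to disk.

    ``container-hdf5`` is a single HDF5 file with datasets ``/signals``,
    ``/fs``, ``/subject_id``, ``/session_id``, ``/ratings`` and
    ``/channel_names``.  ``csv-directory`` writes one CSV per trial
    (channels as columns, header row of channel names) plus a
    ``metadata.json`` sidecar.
    """
    path = Path(path)
    if format == "container-hdf5":
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("signals", data=trialset.signals)
            f.create_dataset("fs", data=float(trialset.fs))
            f.create_dataset("subject_id",
                             data=np.asarray(trialset.subject_id, dtype=np.int64))
            f.create_dataset("session_id",
                             data=np.asarray(trialset.session_id, dtype=np.int64))
            if trialset.is_categorical:
                f.create_dataset(
                    "ratings",
                    data=np.array([str(c) for c in trialset.ratings],
                                  dtype=h5py.string_dtype()))
            else:
                f.create_dataset("ratings",
                                 data=np.asarray(trialset.ratings,
                                                 dtype=np.float64))
            f.create_dataset("channel_names",
                             data=np.array(trialset.channel_names,
                                           dtype=h5py.string_dtype()))
    elif format == "csv-directory":
        import pandas as pd

        path.mkdir(parents=True, exist_ok=True)
        ratings = ([str(c) for c in trialset.ratings] if trialset.is_categorical
                   else [float(v) for v in trialset.ratings])
        meta = {
            "fs": float(trialset.fs),
            "subject_id": [int(s) for s in trialset.subject_id],
            "session_id": [int(s) for s in trialset.session_id],
            "ratings": ratings,
            "channel_names": list(trialset.channel_names),
            "n_trials": trialset.n_trials,
        }
        (path / "metadata.json").write_text(json.dumps(meta, indent=2))
        width = len(str(trialset.n_trials - 1))
        for i in range(trialset.n_trials):
            df = pd.DataFrame(trialset.signals[i].T,
                              columns=trialset.channel_names)
            # %.17g round-trips float64 exactly
            df.to_csv(path / f"trial_{i:0{width}d}.csv", index=False,
                      float_format="%.17g")
    else:
        raise FormatError(f"unknown format {format!r}")


def load_trialset(path: str | Path, format: str = "container-hdf5") -> TrialSet:
    """Read a TrialSet from ``container-hdf5``, ``edf`` or ``csv-directory``.

    An EDF recording is read as a single trial (subject 0, session 0) with
    a mid-scale placeholder rating of 5.0, which the default binarization
    excludes — callers are expected to supply labels explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "container-hdf5":
        import h5py

        with h5py.File(path, "r") as f:
            missing = [k for k in _H5_KEYS if k not in f]
            if missing:
                raise FormatError(f"container missing datasets: {missing}")
            ratings = f["ratings"][()]
            if ratings.dtype.kind in ("O", "S"):
                ratings = np.array([r.decode() if isinstance(r, bytes) else r
                                    for r in ratings])
            return TrialSet(
                signals=f["signals"][()],
                fs=float(f["fs"][()]),
                subject_id=f["subject_id"][()],
                session_id=f["session_id"][()],
                ratings=ratings,
                channel_names=[c.decode() if isinstance(c, bytes) else c
                               for c in f["channel_names"][()]],
            )
    if format == "edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data()  # (n_channels, n_samples), volts for EEG kinds
        return TrialSet(signals=data[np.newaxis],
                        fs=float(raw.info["sfreq"]),
                        subject_id=np.zeros(1, dtype=np.int64),
                        session_id=np.zeros(1, dtype=np.int64),
                        ratings=np.array([5.0]),
                        channel_names=list(raw.ch_names))
    if format == "csv-directory":
        import pandas as pd

        meta_path = path / "metadata.json"
        if not meta_path.exists():
            raise FormatError("csv-directory is missing metadata.json")
        meta = json.loads(meta_path.read_text())
        missing = [k for k in ("fs", "subject_id", "session_id", "ratings",
                               "channel_names", "n_trials") if k not in meta]
        if missing:
            raise FormatError(f"metadata.json missing fields: {missing}")
        files = sorted(path.glob("trial_*.csv"))
        if len(files) != meta["n_trials"]:
            raise FormatError(
                f"expected {meta['n_trials']} trial CSVs, found {len(files)}")
        trials = []
        for fpath in files:
            df = pd.read_csv(fpath, float_precision="round_trip")
            if list(df.columns) != list(meta["channel_names"]):
                raise FormatError(f"{fpath.name}: channel header mismatch")
            trials.append(df.to_numpy(dtype=np.float64).T)
        lengths = {t.shape[1] for t in trials}
        if len(lengths) > 1:
            raise ShapeError(f"inconsistent trial lengths: {sorted(lengths)}")
        return TrialSet(signals=np.stack(trials),
                        fs=float(meta["fs"]),
                        subject_id=np.asarray(meta["subject_id"]),
                        session_id=np.asarray(meta["session_id"]),
                        ratings=np.asarray(meta["ratings"]),
                        channel_names=list(meta["channel_names"]))
    raise FormatError(f"unknown format {format!r}")
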