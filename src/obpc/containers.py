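"""Core in-memory containers and their HDF5/CSV serialization.

The pipeline operates on source-space epoched time courses from four
regions of interest (left/right olfactory bulb and piriform cortex),
sampled at 512 Hz over a 2 s window around odor onset, plus per-trial
behavioral ratings (valence and intensity, 0-100 visual analogue scale)
and optional nasal-breathing traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

#: Canonical ROI ordering used throughout the pipeline.
ROI_LABELS = ("OB_L", "OB_R", "PC_L", "PC_R")

#: Hemisphere-resolved node pairs whose communication is analyzed.
PAIRS = {"L": ("OB_L", "PC_L"), "R": ("OB_R", "PC_R")}

RATING_COLUMNS = ["participant_id", "trial_id", "valence", "intensity"]


@dataclass
class EpochSet:
    """Per-participant trial x ROI x time array with sampling metadata.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_roi, n_samples)
        Real-valued source time courses.
    roi_labels : tuple of str
        Unique channel labels, usually :data:`ROI_LABELS` (or ``("X", "Y")``
        for bivariate VAR validation sets).
    fs : float
        Sampling rate in Hz.
    t0 : float
        Time of the first sample in seconds relative to the event marker
        (odor onset; negative for pre-stimulus samples).
    participant_id : str
        Identifier of the participant the epochs belong to.
    onset_corrected : bool
        Whether the olfactometer delivery delay has already been removed
        from the time axis (guards against double correction).
    """

    data: np.ndarray
    roi_labels: tuple
    fs: float
    t0: float
    participant_id: str = "sim"
    onset_corrected: bool = False

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.roi_labels = tuple(str(r) for r in self.roi_labels)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_roi, n_samples)")
        if self.data.shape[1] != len(self.roi_labels):
            raise ValueError(
                f"{self.data.shape[1]} channels but {len(self.roi_labels)} labels"
            )
        if len(set(self.roi_labels)) != len(self.roi_labels):
            raise ValueError("roi_labels must be unique")
        if not np.isfinite(self.data).all():
            raise ValueError("epoch data contains non-finite values")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    # -- basic geometry -------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to the event marker."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    def roi_index(self, label: str) -> int:
        try:
            return self.roi_labels.index(label)
        except ValueError as exc:
            raise KeyError(f"unknown ROI {label!r}") from exc

    def get_roi(self, label: str) -> np.ndarray:
        """Return the (n_trials, n_samples) array for one ROI."""
        return self.data[:, self.roi_index(label), :]

    def select_trials(self, idx) -> "EpochSet":
        return replace(self, data=self.data[np.asarray(idx)])

    # -- serialization --------------------------------------------------
    def save(self, path) -> None:
        """Write to HDF5: /data, /time, /roi_labels + scalar attributes."""
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("time", data=self.times)
            f.create_dataset(
                "roi_labels",
                data=np.array([s.encode() for s in self.roi_labels]),
            )
            f.attrs["fs"] = self.fs
            f.attrs["t0"] = self.t0
            f.attrs["participant_id"] = self.participant_id
            f.attrs["onset_corrected"] = self.onset_corrected

    @classmethod
    def load(cls, path) -> "EpochSet":
        with h5py.File(path, "r") as f:
            return cls(
                data=f["data"][()],
                roi_labels=tuple(s.decode() for s in f["roi_labels"][()]),
                fs=float(f.attrs["fs"]),
                t0=float(f.attrs["t0"]),
                participant_id=str(f.attrs["participant_id"]),
                onset_corrected=bool(f.attrs["onset_corrected"]),
            )


@dataclass
class BreathTrace:
    """Per-trial nasal-temperature proxy traces for one participant.

    ``data`` is (n_trials, n_samples) sampled at ``fs`` starting at ``t0``
    seconds relative to odor onset; ``peak_times`` holds the per-trial
    inhalation peak in seconds.
    """

    data: np.ndarray
    fs: float
    t0: float
    peak_times: np.ndarray
    participant_id: str = "sim"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        if not np.isfinite(self.data).all():
            raise ValueError("breathing trace contains non-finite values")
        t_end = self.t0 + self.data.shape[1] / self.fs
        if ((self.peak_times < self.t0) | (self.peak_times > t_end)).any():
            raise ValueError("inhalation peak outside the epoch window")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.data.shape[1]) / self.fs

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("breath", data=self.data)
            f.create_dataset("peak_times", data=self.peak_times)
            f.attrs["fs"] = self.fs
            f.attrs["t0"] = self.t0
            f.attrs["participant_id"] = self.participant_id

    @classmethod
    def load(cls, path) -> "BreathTrace":
        with h5py.File(path, "r") as f:
            return cls(
                data=f["breath"][()],
                fs=float(f.attrs["fs"]),
                t0=float(f.attrs["t0"]),
                peak_times=f["peak_times"][()],
                participant_id=str(f.attrs["participant_id"]),
            )


# -- rating tables ------------------------------------------------------

def validate_ratings(ratings: pd.DataFrame) -> pd.DataFrame:
    """Validate a rating table (one row per retained trial)."""
    missing = [c for c in RATING_COLUMNS if c not in ratings.columns]
    if missing:
        raise ValueError(f"rating table missing columns {missing}")
    vals = ratings[["valence", "intensity"]].to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("ratings contain non-finite values")
    if (vals < 0).any() or (vals > 100).any():
        raise ValueError("ratings must lie in [0, 100]")
    return ratings


def save_ratings(ratings: pd.DataFrame, path) -> None:
    validate_ratings(ratings)
    ratings.to_csv(path, index=False, columns=RATING_COLUMNS)


def load_ratings(path) -> pd.DataFrame:
    return validate_ratings(pd.read_csv(path))
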