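"""In-memory containers for EEG data flowing through the pipeline.

All containers are thin dataclasses around numpy arrays with shape/finiteness
validation and HDF5 round-tripping. Units are microvolts for scalp data and
arbitrary (inverse-operator-scaled) units for source space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .exceptions import ShapeError


def _check_finite(arr: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise ShapeError(f"{what} contains non-finite values")


@dataclass
class EEGRecording:
    """Continuous multichannel recording: ``data`` is channels x samples (µV)."""

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ShapeError("EEGRecording.data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ShapeError("sampling rate must be positive")
        _check_finite(self.data, "EEGRecording.data")
        if not self.channel_labels:
            self.channel_labels = [f"E{i + 1}" for i in range(self.data.shape[0])]
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ShapeError("channel labels must be unique")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ShapeError("channel label count does not match data")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochSet:
    """Epoched EEG: ``data`` is epochs x channels x samples (µV)."""

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ShapeError("EpochSet.data must be 3-D (epochs x channels x samples)")
        if self.fs <= 0:
            raise ShapeError("sampling rate must be positive")
        _check_finite(self.data, "EpochSet.data")
        if not self.channel_labels:
            self.channel_labels = [f"E{i + 1}" for i in range(self.data.shape[1])]
        if len(self.channel_labels) != self.data.shape[1]:
            raise ShapeError("channel label count does not match data")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def save(self, path) -> None:
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("data", data=self.data)
            ds.attrs["dims"] = "epochs x channels x samples"
            fh.attrs["fs"] = float(self.fs)
            fh.attrs["channel_labels"] = [str(c) for c in self.channel_labels]

    @classmethod
    def load(cls, path) -> "EpochSet":
        with h5py.File(path, "r") as fh:
            data = fh["data"][()]
            fs = float(fh.attrs["fs"])
            labels = [
                c.decode() if isinstance(c, bytes) else str(c)
                for c in fh.attrs["channel_labels"]
            ]
        return cls(data=data, fs=fs, channel_labels=labels)


@dataclass
class SourceActivity:
    """Distributed source estimates: ``data`` is sources x samples x epochs."""

    data: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ShapeError("SourceActivity.data must be 3-D (sources x samples x epochs)")
        _check_finite(self.data, "SourceActivity.data")

    @property
    def n_sources(self) -> int:
        return self.data.shape[0]


@dataclass
class ROITimeSeries:
    """One representative series per parcel: ``data`` is rois x samples x epochs."""

    data: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ShapeError("ROITimeSeries.data must be 3-D (rois x samples x epochs)")
        _check_finite(self.data, "ROITimeSeries.data")

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]

    def save(self, path) -> None:
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("data", data=self.data)
            ds.attrs["dims"] = "rois x samples x epochs"
            fh.attrs["fs"] = float(self.fs)

    @classmethod
    def load(cls, path) -> "ROITimeSeries":
        with h5py.File(path, "r") as fh:
            data = fh["data"][()]
            fs = float(fh.attrs["fs"])
        return cls(data=data, fs=fs)
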