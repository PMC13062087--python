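"""ROI-level epoched time series and their HDF5 store."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np


@dataclass
class RoiEpochs:
    """Trial-segmented multichannel time series grouped into ROIs.

    ``data`` is (n_trials, n_channels, n_times). Each channel belongs to a
    named ROI (several channels per ROI, e.g. three principal components or
    three synthetic generators per region). ``times`` is the epoch time axis
    in seconds relative to target onset.
    """

    data: np.ndarray
    fs: float
    times: np.ndarray
    channel_rois: list[str]
    trial_index: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, times)")
        if self.data.shape[1] != len(self.channel_rois):
            raise ValueError("channel_rois length must match channel axis")
        if self.data.shape[2] != self.times.size:
            raise ValueError("times length must match time axis")
        if self.trial_index is None:
            self.trial_index = np.arange(self.data.shape[0])
        self.trial_index = np.asarray(self.trial_index, dtype=int)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def rois(self) -> list[str]:
        seen: list[str] = []
        for r in self.channel_rois:
            if r not in seen:
                seen.append(r)
        return seen

    def roi_channels(self, roi: str) -> np.ndarray:
        idx = np.array([i for i, r in enumerate(self.channel_rois) if r == roi])
        if idx.size == 0:
            raise KeyError(f"unknown ROI {roi!r}")
        return idx

    def roi_data(self, roi: str) -> np.ndarray:
        """(trials, channels-of-roi, times) view for one ROI."""
        return self.data[:, self.roi_channels(roi), :]

    def select_trials(self, mask_or_idx) -> "RoiEpochs":
        idx = np.asarray(mask_or_idx)
        return RoiEpochs(
            data=self.data[idx],
            fs=self.fs,
            times=self.times,
            channel_rois=list(self.channel_rois),
            trial_index=self.trial_index[idx],
        )

    def crop(self, tmin: float, tmax: float) -> "RoiEpochs":
        """Restrict the time axis to [tmin, tmax] (inclusive)."""
        m = (self.times >= tmin - 1e-9) & (self.times <= tmax + 1e-9)
        return RoiEpochs(self.data[:, :, m], self.fs, self.times[m],
                         list(self.channel_rois), self.trial_index)

    # ------------------------------------------------------------------ io
    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("times", data=self.times)
            f.create_dataset("trial_index", data=self.trial_index)
            f.create_dataset(
                "channel_rois",
                data=np.array(self.channel_rois, dtype=h5py.string_dtype()),
            )
            f.attrs["fs"] = self.fs

    @classmethod
    def load(cls, path: str | Path) -> "RoiEpochs":
        with h5py.File(path, "r") as f:
            return cls(
                data=f["data"][()],
                fs=float(f.attrs["fs"]),
                times=f["times"][()],
                channel_rois=[s.decode() if isinstance(s, bytes) else str(s)
                              for s in f["channel_rois"][()]],
                trial_index=f["trial_index"][()],
            )
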