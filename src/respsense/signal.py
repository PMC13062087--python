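"""Continuous physiological signals and their on-disk representation.

Signals are stored as delimited text (one sample per row) with a JSON
sidecar carrying sampling rate, units and start time, so that every
artefact in a run directory stays human-readable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class ContinuousSignal:
    """A uniformly sampled physiological trace.

    Parameters
    ----------
    samples : ndarray, shape (n,)
        Sample values.
    fs : float
        Sampling rate in Hz; must be positive.
    units : str
        Physical or derived units of the samples (e.g. ``"z"`` after
        normalisation).
    t0 : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float
    units: str = "a.u."
    t0: float = 0.0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    def copy_with(self, **changes) -> "ContinuousSignal":
        return replace(self, **changes)

    def time_to_sample(self, t: float | np.ndarray) -> np.ndarray:
        """Nearest sample index for a time (or array of times) in seconds."""
        return np.rint((np.asarray(t) - self.t0) * self.fs).astype(int)

    # ------------------------------------------------------------------ io
    def save(self, path: str | Path, column: str = "value") -> None:
        """Write samples as TSV plus a JSON sidecar ``<stem>.json``."""
        path = Path(path)
        pd.DataFrame({column: self.samples}).to_csv(path, sep="\t", index=False)
        sidecar = {"fs": self.fs, "units": self.units, "t0": self.t0, **self.extra}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path, column: str = "value") -> "ContinuousSignal":
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        meta = json.loads(path.with_suffix(".json").read_text())
        extra = {k: v for k, v in meta.items() if k not in ("fs", "units", "t0")}
        return cls(
            samples=df[column].to_numpy(float),
            fs=float(meta["fs"]),
            units=str(meta.get("units", "a.u.")),
            t0=float(meta.get("t0", 0.0)),
            extra=extra,
        )
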