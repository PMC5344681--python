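"""The centroided spectrum container shared by the simulator and the search."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = ["Spectrum"]


@dataclass
class Spectrum:
    """A centroided MS2 peak list with precursor information.

    Peaks are stored as parallel numpy arrays sorted by m/z; intensities are
    non-negative.  ``mode`` records the fragmentation type, which drives both
    simulation and hypothesis generation (HCD: b/y with neutral losses and
    diagnostic ions; ETD: intact c/z only).
    """

    title: str
    precursor_mz: float
    precursor_charge: int
    mode: Literal["HCD", "ETD"]
    mz: np.ndarray = field(default_factory=lambda: np.empty(0))
    intensity: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays must have equal length")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if self.precursor_charge < 1:
            raise ValueError("precursor charge must be >= 1")
        if self.mode not in ("HCD", "ETD"):
            raise ValueError(f"unknown fragmentation mode {self.mode!r}")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    @classmethod
    def from_peaks(
        cls,
        title: str,
        precursor_mz: float,
        precursor_charge: int,
        mode: Literal["HCD", "ETD"],
        peaks: Sequence[tuple[float, float]],
    ) -> "Spectrum":
        arr = np.asarray(list(peaks), dtype=float).reshape(-1, 2)
        return cls(title, precursor_mz, precursor_charge, mode,
                   mz=arr[:, 0], intensity=arr[:, 1])

    def __len__(self) -> int:
        return len(self.mz)

    @property
    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))

    @property
    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if len(self) else 0.0
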