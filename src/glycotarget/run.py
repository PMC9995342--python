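"""In-memory containers for centroided MS runs."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Spectrum", "Run"]


@dataclass
class Spectrum:
    """One centroided scan: retention time (minutes) plus peak arrays."""

    rt: float
    mz: np.ndarray
    intensity: np.ndarray
    ms_level: int = 1
    precursor_mz: float | None = None  # MS2 isolation target
    isolation_width: float | None = None  # full width, m/z

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays must have equal length")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be >= 0")


@dataclass
class Run:
    """A centroided run: SIM-style MS1 scans plus ddMS2 scans, rt-sorted."""

    ms1: list[Spectrum] = field(default_factory=list)
    ms2: list[Spectrum] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for scans, level in ((self.ms1, 1), (self.ms2, 2)):
            rts = [s.rt for s in scans]
            if rts != sorted(rts):
                raise ValueError(f"MS{level} scans must be sorted by retention time")
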