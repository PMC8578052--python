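"""Organ-level longitudinal fluorescence measurements."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import numpy.typing as npt

from .layout import CHANNELS, N_CHANNELS

__all__ = ["MeasurementSet"]


@dataclass(frozen=True)
class MeasurementSet:
    """Fluorescence (%ID) per measured organ channel over scheme times.

    ``values`` has one row per channel in canonical order
    (:data:`fmtpk.layout.CHANNELS`) and one column per time point.
    """

    times_h: npt.NDArray[np.float64]
    values: npt.NDArray[np.float64]
    provenance: str = "simulated"

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_CHANNELS, t.size):
            raise ValueError(
                f"values must be ({N_CHANNELS}, {t.size}), got {v.shape}"
            )
        if np.any(np.diff(t) <= 0):
            raise ValueError("measurement times must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("measurements must be nonnegative")
        if self.provenance not in ("simulated", "in_vivo"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "values", v)

    @property
    def channels(self) -> tuple[str, ...]:
        return CHANNELS

    def __len__(self) -> int:
        return self.times_h.size
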