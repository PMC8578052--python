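"""Temporal sampling schemes for longitudinal microCT-FMT measurements.

Six named schemes are provided.  The two 7-point schemes reproduce the
scan times used in vivo; the denser plain schemes spread 20 or 50 scans
uniformly over 0.25-72 h, and the "-early" variants concentrate points in
the first hour of probe distribution (geometric spacing on 0.05-48 h with
t=0 prepended), where compartment exchange is fastest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import numpy.typing as npt

__all__ = ["SamplingScheme", "make_scheme", "SCHEME_NAMES"]

SCHEME_NAMES = ("7", "20", "50", "7-early", "20-early", "50-early")


@dataclass(frozen=True)
class SamplingScheme:
    """Named set of post-injection measurement times in hours."""

    name: str
    times_h: npt.NDArray[np.float64]

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        if t.size < 2:
            raise ValueError("a sampling scheme needs at least two time points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("scheme times must be strictly increasing")
        if t[0] < 0:
            raise ValueError("scheme times must be nonnegative")
        object.__setattr__(self, "times_h", t)

    @property
    def times_min(self) -> npt.NDArray[np.float64]:
        return self.times_h * 60.0

    def __len__(self) -> int:
        return self.times_h.size


def _early(n: int) -> np.ndarray:
    pts = np.geomspace(0.05, 48.0, n - 1)
    return np.concatenate([[0.0], pts])


_NAMED: dict[str, np.ndarray] = {
    "7": np.array([0.25, 2.0, 4.0, 8.0, 24.0, 48.0, 72.0]),
    "7-early": np.array([0.0, 0.25, 0.5, 2.0, 12.0, 24.0, 48.0]),
    "20": np.linspace(0.25, 72.0, 20),
    "50": np.linspace(0.25, 72.0, 50),
    "20-early": _early(20),
    "50-early": _early(50),
}


def make_scheme(name: str) -> SamplingScheme:
    """Return one of the six named schemes by name."""
    try:
        times = _NAMED[name]
    except KeyError:
        raise KeyError(
            f"unknown scheme {name!r}; expected one of {', '.join(SCHEME_NAMES)}"
        ) from None
    return SamplingScheme(name=name, times_h=times.copy())


def custom_scheme(times_h, name: str = "custom") -> SamplingScheme:
    """Build a scheme from explicit times in hours."""
    return SamplingScheme(name=name, times_h=np.asarray(times_h, dtype=float))
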