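"""Kinetic model core: rate matrix, RK4 integration, coarse sampling.

The biodistribution obeys the linear mass-balance system ``dI/dt = A I``
where ``I`` holds the amount of compound per compartment (% of injected
dose) and ``A`` is built from eight unknown Blood-outflow rates plus a
small set of known transfer rates (hepatobiliary and renal excretion,
back-diffusion from the body remainder).  Columns of ``A`` sum to zero, so
total %ID is conserved; the intestine and bladder are absorbing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import numpy.typing as npt

from .layout import (
    DEFAULT_LAYOUT,
    N_STATES,
    PARAM_NAMES,
    PARAM_TARGETS,
    ConfigurationError,
    StateLayout,
)

__all__ = [
    "KineticParameters",
    "KnownRates",
    "TimeGrid",
    "Trajectory",
    "build_system_matrix",
    "rk4_propagator",
    "rk4_integrate",
    "sample_coarse",
    "initial_state",
]

#: Default physiological bounds on the unknown rates, 1/min.
DEFAULT_BOUNDS = (0.001, 0.02)

#: Known transfer rates (1/min) not estimated from data.  The excretion
#: rates and the back-diffusion rate are configuration values; the fourth
#: edge is an intestinal self-edge with rate zero, i.e. the excreta
#: compartments are absorbing and the system stays closed.
DEFAULT_KNOWN_RATES: dict[tuple[str, str], float] = {
    ("LiverElim", "Intestine"): 0.01,
    ("KidneyElim", "Bladder"): 0.01,
    ("Others", "Blood"): 0.005,
    ("Intestine", "Intestine"): 0.0,
}


class NumericalFailure(ArithmeticError):
    """Raised when integration produces non-finite values."""


@dataclass(frozen=True)
class KineticParameters:
    """The eight unknown first-order rates out of Blood, 1/min.

    Order follows :data:`fmtpk.layout.PARAM_NAMES`.
    """

    values: npt.NDArray[np.float64]

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.shape != (len(PARAM_NAMES),):
            raise ConfigurationError(
                f"expected {len(PARAM_NAMES)} rates, got shape {arr.shape}"
            )
        if np.any(arr < 0):
            raise ConfigurationError("kinetic rates must be nonnegative")
        object.__setattr__(self, "values", arr)

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "KineticParameters":
        missing = set(PARAM_NAMES) - set(d)
        if missing:
            raise ConfigurationError(f"missing rates: {sorted(missing)}")
        return cls(np.array([d[n] for n in PARAM_NAMES], dtype=float))

    def as_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(PARAM_NAMES, self.values)}

    def within_bounds(self, lo: float, hi: float) -> bool:
        return bool(np.all(self.values >= lo) and np.all(self.values <= hi))


@dataclass(frozen=True)
class KnownRates:
    """Known (fixed) transfer rates, edge ``(src, dst)`` -> rate in 1/min."""

    edges: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_KNOWN_RATES)
    )

    def __post_init__(self) -> None:
        for (src, dst), rate in self.edges.items():
            if rate < 0:
                raise ConfigurationError(f"known rate {src}->{dst} is negative")

    def validated(self, layout: StateLayout) -> "KnownRates":
        for src, dst in self.edges:
            layout.index(src)
            layout.index(dst)
        return self


def build_system_matrix(
    params: KineticParameters,
    known: KnownRates | None = None,
    layout: StateLayout = DEFAULT_LAYOUT,
) -> npt.NDArray[np.float64]:
    """Assemble the rate matrix ``A`` with ``A[j, i]`` = rate of edge i->j.

    Diagonal entries carry the negative total outflow of each compartment,
    so every column sums to zero (mass balance).  Self-edges are allowed
    and contribute nothing.
    """
    known = (known or KnownRates()).validated(layout)
    a = np.zeros((len(layout), len(layout)))
    i_blood = layout.index("Blood")
    for name, rate in zip(PARAM_NAMES, params.values):
        j = layout.index(PARAM_TARGETS[name])
        a[j, i_blood] += rate
        a[i_blood, i_blood] -= rate
    for (src, dst), rate in known.edges.items():
        i, j = layout.index(src), layout.index(dst)
        a[j, i] += rate
        a[i, i] -= rate
    return a


def initial_state(
    blood_pct: float = 100.0, layout: StateLayout = DEFAULT_LAYOUT
) -> npt.NDArray[np.float64]:
    """Intravenous bolus: all injected dose in Blood at t=0."""
    i0 = np.zeros(len(layout))
    i0[layout.index("Blood")] = blood_pct
    return i0


@dataclass(frozen=True)
class TimeGrid:
    """Uniform fine time grid in minutes, from 0 to ``end_min`` inclusive."""

    step_min: float = 1.0
    end_min: float = 4320.0

    def __post_init__(self) -> None:
        if self.step_min <= 0 or self.end_min <= 0:
            raise ConfigurationError("grid step and end must be positive")
        if self.n_steps < 1:
            raise ConfigurationError("grid must contain at least one step")

    @property
    def n_steps(self) -> int:
        return int(round(self.end_min / self.step_min))

    @property
    def times(self) -> npt.NDArray[np.float64]:
        return np.arange(self.n_steps + 1) * self.step_min


@dataclass(frozen=True)
class Trajectory:
    """Fine-grained prediction: compartment amounts (%ID) on a TimeGrid."""

    grid: TimeGrid
    states: npt.NDArray[np.float64]  # (n_states, n_steps + 1)

    @property
    def times(self) -> npt.NDArray[np.float64]:
        return self.grid.times

    def total(self) -> npt.NDArray[np.float64]:
        """Total %ID at each grid time (constant for a closed system)."""
        return self.states.sum(axis=0)


def rk4_propagator(a: npt.NDArray[np.float64], h: float) -> npt.NDArray[np.float64]:
    """One-step transition matrix of classic RK4 applied to ``dI/dt = A I``.

    For a constant linear system the four-stage update collapses exactly to
    the degree-4 Taylor polynomial of ``exp(hA)``.
    """
    ha = h * np.asarray(a, dtype=float)
    n = ha.shape[0]
    phi = np.eye(n) + ha
    term = ha
    for k in (2.0, 3.0, 4.0):
        term = term @ ha / k
        phi = phi + term
    return phi


def rk4_integrate(
    a: npt.NDArray[np.float64],
    i0: npt.NDArray[np.float64],
    grid: TimeGrid = TimeGrid(),
) -> Trajectory:
    """Integrate ``dI/dt = A I`` with classic fixed-step RK4 from ``i0``.

    Runs the explicit four-stage recursion; deterministic given (A, i0, h).

    Raises
    ------
    NumericalFailure
        If any state becomes non-finite, naming the failing step.
    """
    a = np.asarray(a, dtype=float)
    x = np.asarray(i0, dtype=float)
    if np.any(x < 0):
        raise ConfigurationError("initial state must be nonnegative")
    h = grid.step_min
    n = grid.n_steps
    out = np.empty((x.size, n + 1))
    out[:, 0] = x
    for step in range(1, n + 1):
        k1 = a @ x
        k2 = a @ (x + 0.5 * h * k1)
        k3 = a @ (x + 0.5 * h * k2)
        k4 = a @ (x + h * k3)
        x = x + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not np.all(np.isfinite(x)):
            raise NumericalFailure(f"non-finite state at step {step} (t={step * h} min)")
        out[:, step] = x
    return Trajectory(grid=grid, states=out)


def sample_coarse(traj: Trajectory, scheme) -> npt.NDArray[np.float64]:
    """Sample the fine trajectory at a scheme's time points (hours -> min).

    Scheme times that fall between grid nodes are linearly interpolated;
    times beyond the grid end raise ``ValueError``.
    """
    t_min = np.asarray(scheme.times_min, dtype=float)
    h = traj.grid.step_min
    if t_min.max() > traj.grid.end_min + 1e-9 or t_min.min() < -1e-9:
        raise ValueError("scheme time outside the integration grid")
    pos = t_min / h
    lo = np.clip(np.floor(pos).astype(int), 0, traj.grid.n_steps)
    hi = np.clip(lo + 1, 0, traj.grid.n_steps)
    w = pos - lo
    return traj.states[:, lo] * (1.0 - w) + traj.states[:, hi] * w
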