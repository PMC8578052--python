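"""Mixing matrix: from compartment amounts to measured organ fluorescence.

FMT resolves fluorescence only to 1-3 mm, so the signal measured in a
segmented organ is a blend of three effects:

* **intensity diffusion** -- blur of fluorescence between neighboring
  organs, summarized by a 9x9 matrix of contribution fractions (IDV);
* **vascular spillover** -- the blood inside an organ contributes the blood
  signal in proportion to the organ's relative blood volume (rBV);
* **sub-compartment fusion** -- the liver and kidney channels each report
  the sum of their retention and elimination sub-compartments.

The composed 9x11 operator ``M`` maps the model state to the measured
channels, ``I_m = M I``; the fitting engine inverts it implicitly by
including it in the forward model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import numpy.typing as npt
from scipy import ndimage

from .layout import (
    CHANNELS,
    CHANNEL_COMPARTMENTS,
    COMPARTMENTS,
    N_CHANNELS,
    N_STATES,
    ConfigurationError,
)

__all__ = [
    "printed_idv",
    "validate_idv",
    "compute_idv",
    "collapse_map",
    "default_rbv",
    "MixingMatrix",
    "assemble_mixing",
    "apply_mixing",
    "VoxelMaskSet",
]

#: FWHM of a Gaussian is 2*sqrt(2 ln 2) sigma.
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Default relative blood volume per measured channel.  The blood (heart)
#: channel is pure blood by convention; organ values are literature-style
#: perfusion fractions and are configuration, not measured here.
DEFAULT_RBV: dict[str, float] = {
    "lung": 0.50,
    "blood": 1.0,
    "liver": 0.30,
    "bone": 0.11,
    "spleen": 0.35,
    "intestine": 0.10,
    "kidneys": 0.24,
    "bladder": 0.05,
    "others": 0.05,
}


def printed_idv() -> npt.NDArray[np.float64]:
    """The published 9x9 intensity-diffusion matrix.

    ``idv[i, j]`` is the fraction of source channel *i*'s fluorescence
    measured in organ *j*; rows and columns follow
    :data:`fmtpk.layout.CHANNELS`.
    """
    ref = resources.files("fmtpk").joinpath("data/idv_printed.csv")
    with ref.open("r", encoding="utf-8") as fh:
        header = fh.readline().strip().split(",")
        assert tuple(header[1:]) == CHANNELS
        rows = []
        for line in fh:
            parts = line.strip().split(",")
            rows.append([float(v) for v in parts[1:]])
    idv = np.array(rows)
    assert idv.shape == (N_CHANNELS, N_CHANNELS)
    return idv


def validate_idv(idv: npt.NDArray[np.float64], warn: bool = True) -> None:
    """Check shape, nonnegativity and near-unity row sums of an IDV matrix."""
    idv = np.asarray(idv)
    if idv.shape != (N_CHANNELS, N_CHANNELS):
        raise ConfigurationError(f"IDV must be 9x9, got {idv.shape}")
    if np.any(idv < 0) or np.any(idv > 1):
        raise ConfigurationError("IDV entries must lie in [0, 1]")
    sums = idv.sum(axis=1)
    if warn and (np.any(sums < 0.90) or np.any(sums > 1.001)):
        warnings.warn(
            f"IDV row sums outside [0.90, 1.001]: {sums}", stacklevel=2
        )


def collapse_map() -> npt.NDArray[np.float64]:
    """9x11 0/1 matrix fusing model compartments into measured channels."""
    c = np.zeros((N_CHANNELS, N_STATES))
    for j, channel in enumerate(CHANNELS):
        for comp in CHANNEL_COMPARTMENTS[channel]:
            c[j, COMPARTMENTS.index(comp)] = 1.0
    return c


def default_rbv() -> npt.NDArray[np.float64]:
    """Default rBV fractions in channel order."""
    return np.array([DEFAULT_RBV[c] for c in CHANNELS])


@dataclass(frozen=True)
class MixingMatrix:
    """Composed measurement operator with its stored components."""

    matrix: npt.NDArray[np.float64]  # (9, 11)
    idv: npt.NDArray[np.float64]
    rbv: npt.NDArray[np.float64]
    collapse: npt.NDArray[np.float64]
    mode: str


def assemble_mixing(
    idv: npt.NDArray[np.float64] | None = None,
    rbv: npt.NDArray[np.float64] | None = None,
    collapse: npt.NDArray[np.float64] | None = None,
    mode: str = "blend",
) -> MixingMatrix:
    """Compose IDV blur, rBV spillover and sub-compartment fusion into M.

    The organ-level signal operator ``S`` first fuses sub-compartments and
    adds the vascular term: in ``blend`` mode (default) each non-blood
    channel is the convex combination ``(1-rBV)*tissue + rBV*blood``, which
    preserves signal scale; in ``additive`` mode the blood term is simply
    added.  The blood channel is pure blood either way.  Intensity
    diffusion then redistributes the organ signals: ``M = IDV^T S`` (IDV
    rows are sources, columns measured organs).
    """
    idv = printed_idv() if idv is None else np.asarray(idv, dtype=float)
    rbv = default_rbv() if rbv is None else np.asarray(rbv, dtype=float)
    collapse = collapse_map() if collapse is None else np.asarray(collapse, dtype=float)
    validate_idv(idv)
    if rbv.shape != (N_CHANNELS,) or np.any(rbv < 0) or np.any(rbv > 1):
        raise ConfigurationError("rBV must be 9 fractions in [0, 1]")
    if mode not in ("blend", "additive"):
        raise ConfigurationError(f"unknown mixing mode {mode!r}")

    e_blood = np.zeros(N_STATES)
    e_blood[COMPARTMENTS.index("Blood")] = 1.0
    i_blood_ch = CHANNELS.index("blood")

    s = np.empty_like(collapse)
    for j in range(N_CHANNELS):
        if j == i_blood_ch:
            s[j] = e_blood
        elif mode == "blend":
            s[j] = (1.0 - rbv[j]) * collapse[j] + rbv[j] * e_blood
        else:
            s[j] = collapse[j] + rbv[j] * e_blood
    m = idv.T @ s
    return MixingMatrix(matrix=m, idv=idv, rbv=rbv, collapse=collapse, mode=mode)


def apply_mixing(
    m: MixingMatrix | npt.NDArray[np.float64], coarse: npt.NDArray[np.float64]
) -> npt.NDArray[np.float64]:
    """Mixed prediction: matrix product of M with the coarse state columns."""
    mat = m.matrix if isinstance(m, MixingMatrix) else np.asarray(m)
    coarse = np.asarray(coarse)
    if coarse.shape[0] != mat.shape[1]:
        raise ValueError(
            f"state dimension {coarse.shape[0]} does not match M columns {mat.shape[1]}"
        )
    return mat @ coarse


@dataclass(frozen=True)
class VoxelMaskSet:
    """Disjoint binary organ masks on a common isotropic voxel grid."""

    masks: dict[str, npt.NDArray[np.bool_]]
    spacing_mm: float

    def __post_init__(self) -> None:
        if self.spacing_mm <= 0:
            raise ConfigurationError("voxel spacing must be positive")
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ConfigurationError("masks must share one grid shape")
        total = None
        for m in self.masks.values():
            if total is None:
                total = m.astype(int).copy()
            else:
                total += m
        if total is not None and np.any(total > 1):
            raise ConfigurationError("organ masks overlap")

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.masks.values())).shape

    def others_mask(self) -> npt.NDArray[np.bool_]:
        """Complement of the union of labeled masks."""
        union = np.zeros(self.shape, dtype=bool)
        for m in self.masks.values():
            union |= m
        return ~union


def compute_idv(
    masks: VoxelMaskSet,
    fwhm_mm: float = 0.5,
    order: tuple[str, ...] | None = None,
    include_others: bool = True,
) -> npt.NDArray[np.float64]:
    """Intensity-diffusion matrix from organ masks by 3D Gaussian blurring.

    Each organ's indicator is blurred with an isotropic Gaussian of the
    given FWHM (reflective boundaries, so total intensity is conserved on
    the grid); entry ``[i, j]`` is the fraction of source *i*'s blurred
    intensity that falls inside region *j*.  With ``include_others`` the
    complement of all masks forms the final row/column.
    """
    if fwhm_mm <= 0:
        raise ConfigurationError("FWHM must be positive")
    if fwhm_mm < 0.5 * masks.spacing_mm:
        warnings.warn("FWHM below half a voxel: blur is under-resolved", stacklevel=2)
    names = list(order) if order is not None else list(masks.masks)
    regions = [masks.masks[n] for n in names]
    if include_others:
        names.append("others")
        regions.append(masks.others_mask())
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / masks.spacing_mm
    n = len(regions)
    idv = np.zeros((n, n))
    for i, src in enumerate(regions):
        blurred = ndimage.gaussian_filter(src.astype(float), sigma_vox, mode="reflect")
        total = blurred.sum()
        if total <= 0:
            continue
        for j, dst in enumerate(regions):
            idv[i, j] = blurred[dst].sum() / total
    return idv
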