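"""Compartment topology of the whole-body model.

The model tracks a fluorescently labeled compound in eleven compartments.
Blood drives distribution; five retention sites (lung, liver, kidneys, bone,
spleen) trap the compound irreversibly; the liver and kidneys additionally
carry elimination sub-compartments feeding the hepatobiliary (intestine) and
renal (bladder) excretion routes; "others" is the exchangeable remainder of
the body.  Measurements resolve only nine organ channels: the liver and
kidney retention/elimination pairs are fused into single measured organs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Ordered model compartments. This order is fixed everywhere a state vector,
#: rate matrix or trajectory appears.
COMPARTMENTS: tuple[str, ...] = (
    "Lung",
    "Blood",
    "LiverRet",
    "LiverElim",
    "Bone",
    "Spleen",
    "Intestine",
    "KidneyRet",
    "KidneyElim",
    "Bladder",
    "Others",
)

#: Ordered measured organ channels (FMT segmentation), matching the intensity
#: diffusion matrix ordering.
CHANNELS: tuple[str, ...] = (
    "lung",
    "blood",
    "liver",
    "bone",
    "spleen",
    "intestine",
    "kidneys",
    "bladder",
    "others",
)

#: Measured channel -> contributing model compartments (sub-compartment fusion).
CHANNEL_COMPARTMENTS: dict[str, tuple[str, ...]] = {
    "lung": ("Lung",),
    "blood": ("Blood",),
    "liver": ("LiverRet", "LiverElim"),
    "bone": ("Bone",),
    "spleen": ("Spleen",),
    "intestine": ("Intestine",),
    "kidneys": ("KidneyRet", "KidneyElim"),
    "bladder": ("Bladder",),
    "others": ("Others",),
}

#: The eight unknown rates, all out of Blood, in their canonical order.
#: Values are first-order rate constants in 1/min.
PARAM_NAMES: tuple[str, ...] = (
    "kKidneyElimination",
    "kLiverElimination",
    "kKidney",
    "kLiver",
    "kBone",
    "kSpleen",
    "kLung",
    "kOthers",
)

#: Unknown-parameter name -> destination compartment (source is always Blood).
PARAM_TARGETS: dict[str, str] = {
    "kKidneyElimination": "KidneyElim",
    "kLiverElimination": "LiverElim",
    "kKidney": "KidneyRet",
    "kLiver": "LiverRet",
    "kBone": "Bone",
    "kSpleen": "Spleen",
    "kLung": "Lung",
    "kOthers": "Others",
}

N_STATES = len(COMPARTMENTS)
N_CHANNELS = len(CHANNELS)
N_PARAMS = len(PARAM_NAMES)


class ConfigurationError(ValueError):
    """Raised for invalid topology or configuration input."""


@dataclass(frozen=True)
class StateLayout:
    """Fixed ordering of the model compartments with name -> index lookup."""

    names: tuple[str, ...] = COMPARTMENTS
    _index: dict[str, int] = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ConfigurationError("compartment names must be unique")
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(self.names)})

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise ConfigurationError(f"unknown compartment {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._index


DEFAULT_LAYOUT = StateLayout()
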