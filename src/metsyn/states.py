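"""The 12-state space of metabolic-syndrome progression.

Metabolic syndrome (MS) under the Chinese Diabetes Society (CDS) criteria is
the co-occurrence of at least three of four components: overweight/obesity,
hypertension, dyslipidemia and hyperglycemia.  The 16 possible component
profiles collapse onto 12 mutually exclusive, collectively exhaustive states:
one no-component state, four isolated-component states, six two-component
states, and a single MS state absorbing every profile with >= 3 components.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterator

__all__ = [
    "Sex",
    "MetabolicState",
    "ComponentProfile",
    "COMPONENT_FIELDS",
    "STATE_ORDER",
    "STATE_INDEX",
    "ISOLATED_STATES",
    "PAIR_STATES",
    "state_of",
    "profile_of_state",
    "all_profiles",
]


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"

    @classmethod
    def parse(cls, value: "str | Sex") -> "Sex":
        if isinstance(value, Sex):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise InputError(f"unknown sex label: {value!r}") from None


class InputError(ValueError):
    """Raised for malformed input values (e.g. an unknown sex label)."""


#: Names of the four CDS components, in canonical order.
COMPONENT_FIELDS = (
    "overweight_obesity",
    "hypertension",
    "dyslipidemia",
    "hyperglycemia",
)


class MetabolicState(str, enum.Enum):
    """One of the 12 metabolic states.

    Short labels: OW = overweight/obesity, HTN = hypertension,
    DYS = dyslipidemia, HYP = hyperglycemia; pair states concatenate two
    component labels; MS = metabolic syndrome (>= 3 components).
    """

    NONE = "NONE"
    OW = "OW"
    HTN = "HTN"
    DYS = "DYS"
    HYP = "HYP"
    OW_HTN = "OW_HTN"
    OW_DYS = "OW_DYS"
    OW_HYP = "OW_HYP"
    HTN_DYS = "HTN_DYS"
    HTN_HYP = "HTN_HYP"
    DYS_HYP = "DYS_HYP"
    MS = "MS"

    @property
    def index(self) -> int:
        return STATE_INDEX[self]


#: Canonical state ordering used for every matrix row/column in the package.
STATE_ORDER: tuple[MetabolicState, ...] = tuple(MetabolicState)
STATE_INDEX: dict[MetabolicState, int] = {s: i for i, s in enumerate(STATE_ORDER)}

ISOLATED_STATES = (
    MetabolicState.OW,
    MetabolicState.HTN,
    MetabolicState.DYS,
    MetabolicState.HYP,
)
PAIR_STATES = (
    MetabolicState.OW_HTN,
    MetabolicState.OW_DYS,
    MetabolicState.OW_HYP,
    MetabolicState.HTN_DYS,
    MetabolicState.HTN_HYP,
    MetabolicState.DYS_HYP,
)

# component flag tuple (ow, htn, dys, hyp) -> state, for counts 1 and 2
_SINGLE = {
    (True, False, False, False): MetabolicState.OW,
    (False, True, False, False): MetabolicState.HTN,
    (False, False, True, False): MetabolicState.DYS,
    (False, False, False, True): MetabolicState.HYP,
}
_PAIR = {
    (True, True, False, False): MetabolicState.OW_HTN,
    (True, False, True, False): MetabolicState.OW_DYS,
    (True, False, False, True): MetabolicState.OW_HYP,
    (False, True, True, False): MetabolicState.HTN_DYS,
    (False, True, False, True): MetabolicState.HTN_HYP,
    (False, False, True, True): MetabolicState.DYS_HYP,
}


@dataclass(frozen=True)
class ComponentProfile:
    """The four CDS component indicators for one subject-visit."""

    overweight_obesity: bool
    hypertension: bool
    dyslipidemia: bool
    hyperglycemia: bool

    @property
    def flags(self) -> tuple[bool, bool, bool, bool]:
        return (
            self.overweight_obesity,
            self.hypertension,
            self.dyslipidemia,
            self.hyperglycemia,
        )

    @property
    def n_components(self) -> int:
        return sum(self.flags)

    @property
    def state(self) -> MetabolicState:
        return state_of(self)


def state_of(profile: ComponentProfile) -> MetabolicState:
    """Map a component profile to its metabolic state.

    The map is total: 0 components -> NONE, 1 -> the matching isolated state,
    2 -> the matching pair state, >= 3 -> MS.
    """
    n = profile.n_components
    if n == 0:
        return MetabolicState.NONE
    if n == 1:
        return _SINGLE[profile.flags]
    if n == 2:
        return _PAIR[profile.flags]
    return MetabolicState.MS


# representative flag tuples per state; MS lists all five >=3-component profiles
_STATE_PROFILES: dict[MetabolicState, tuple[tuple[bool, bool, bool, bool], ...]] = {
    MetabolicState.NONE: ((False, False, False, False),),
    **{s: (f,) for f, s in _SINGLE.items()},
    **{s: (f,) for f, s in _PAIR.items()},
    MetabolicState.MS: (
        (True, True, True, False),
        (True, True, False, True),
        (True, False, True, True),
        (False, True, True, True),
        (True, True, True, True),
    ),
}


def profile_of_state(state: MetabolicState) -> tuple[ComponentProfile, ...]:
    """Component profiles consistent with *state* (five of them for MS)."""
    return tuple(ComponentProfile(*f) for f in _STATE_PROFILES[state])


def all_profiles() -> Iterator[ComponentProfile]:
    """Iterate over all 16 component profiles."""
    for i in range(16):
        yield ComponentProfile(*(bool(i >> k & 1) for k in range(4)))
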