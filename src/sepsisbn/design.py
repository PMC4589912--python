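"""Experimental design encoding for the two-hit sepsis + aspiration study.

The study crosses an indirect septic insult (cecal ligation and puncture,
CLP) with a direct lung insult (aspiration of saline, acid, or acid with
gastric particles) delivered at one of three intervals after CLP (0, 12 or
48 h).  Animals without CLP receive the aspirate only.  This yields

    3 aspirates without CLP  +  3 aspirates x 3 intervals with CLP  =  12 groups

with ~10 animals per group.  Three fluid compartments are sampled from every
animal: peritoneal lavage, blood (plasma), and bronchoalveolar lavage (BAL).

Integer encodings used throughout the package (and in the discrete
Bayesian-network analysis):

``CLP``
    0 = no surgery, 1 = CLP performed.  2 states.
``LungInsult``
    0 = no injury, 1 = saline, 2 = acid, 3 = acid + particles.  4 states
    (state 0 is part of the encoding but unused by the in-study design,
    where every animal receives an aspirate).
``InjuryInterval``
    0 = none (no CLP, hence no CLP-to-insult interval), 1 = 0 h, 2 = 12 h,
    3 = 48 h.  4 states.
``type``
    Compartment of a sample in the combined analysis:
    0 = peritoneum, 1 = blood, 2 = BAL.  3 states.

Note on ``InjuryInterval = none``: the interval variable measures the time
between CLP and the aspirate, so it is undefined (encoded 0 = "none")
exactly for the groups without CLP, even though those groups did receive a
lung insult.
"""

from __future__ import annotations

from dataclasses import dataclass, field

CLP = "CLP"
LUNG_INSULT = "LungInsult"
INJURY_INTERVAL = "InjuryInterval"
TYPE = "type"

#: Condition columns in canonical order (per-compartment tables).
CONDITION_VARS: tuple[str, ...] = (CLP, LUNG_INSULT, INJURY_INTERVAL)

#: Declared state counts of the condition encodings.  These are properties
#: of the encoding, not of any particular data set: e.g. ``LungInsult`` has
#: four states even though the in-study design only exercises 1..3.
CONDITION_CARDINALITIES: dict[str, int] = {
    CLP: 2,
    LUNG_INSULT: 4,
    INJURY_INTERVAL: 4,
    TYPE: 3,
}

LUNG_INSULT_LABELS = {0: "none", 1: "saline", 2: "acid", 3: "particles"}
INTERVAL_LABELS = {0: "none", 1: "0h", 2: "12h", 3: "48h"}

PERITONEUM = "peritoneum"
BLOOD = "blood"
BAL = "bal"
COMPARTMENTS: tuple[str, ...] = (PERITONEUM, BLOOD, BAL)
COMPARTMENT_CODES: dict[str, int] = {PERITONEUM: 0, BLOOD: 1, BAL: 2}


@dataclass(frozen=True)
class ConditionEncoding:
    """One experimental condition combination, in integer encoding.

    ``compartment`` is optional: group membership is a property of the
    animal, while compartment is a property of the sample.
    """

    clp: int
    lung_insult: int
    injury_interval: int
    compartment: str | None = None

    def __post_init__(self) -> None:
        if self.clp not in (0, 1):
            raise ValueError(f"CLP must be 0 or 1, got {self.clp}")
        if self.lung_insult not in (0, 1, 2, 3):
            raise ValueError(f"LungInsult must be in 0..3, got {self.lung_insult}")
        if self.injury_interval not in (0, 1, 2, 3):
            raise ValueError(
                f"InjuryInterval must be in 0..3, got {self.injury_interval}"
            )
        if self.clp == 0 and self.injury_interval != 0:
            raise ValueError(
                "groups without CLP have no CLP-to-insult interval "
                "(InjuryInterval must be 0 = none when CLP = 0)"
            )
        if self.compartment is not None and self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.clp, self.lung_insult, self.injury_interval)


@dataclass(frozen=True)
class GroupSpec:
    """An experimental group: a condition combination plus its group size."""

    condition: ConditionEncoding
    n_animals: int = 10

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")


def enumerate_design(n_animals: int = 10) -> list[GroupSpec]:
    """Enumerate the full 12-group study design.

    Groups are the cross of {no CLP} x {saline, acid, particles} with
    {CLP} x {saline, acid, particles} x {0 h, 12 h, 48 h}, ordered
    lexicographically by (clp, lung_insult, injury_interval).
    """
    groups: list[GroupSpec] = []
    for clp in (0, 1):
        for insult in (1, 2, 3):
            intervals = (0,) if clp == 0 else (1, 2, 3)
            for interval in intervals:
                groups.append(
                    GroupSpec(ConditionEncoding(clp, insult, interval), n_animals)
                )
    return groups


@dataclass(frozen=True)
class MediatorPanel:
    """The measured mediator panel: cytokines, chemokines and cell counts.

    Albumin (a vascular-leak marker) is assayed in BAL fluid only.
    """

    pro_inflammatory: tuple[str, ...] = (
        "TNFa", "IL6", "IL1b", "IL12", "IFNg", "IL13", "IL4", "IL5", "IL18", "IL2",
    )
    anti_inflammatory: tuple[str, ...] = ("IL10", "TNFsr1", "TNFsr2", "IL1ra")
    chemokines: tuple[str, ...] = (
        "MIP2a", "KC", "LIX", "MCP1", "MIP1a", "RANTES", "Eotaxin",
    )
    cells: tuple[str, ...] = ("WBC", "NE", "MO", "LY", "EO")
    albumin: str = "Albumin"

    def __post_init__(self) -> None:
        names = self.common_variables()
        if len(names) != len(set(names)):
            raise ValueError("mediator names must be unique within the panel")

    def common_variables(self) -> tuple[str, ...]:
        """Mediators measured in every compartment (albumin excluded)."""
        return (
            self.pro_inflammatory
            + self.anti_inflammatory
            + self.chemokines
            + self.cells
        )

    def variables(self, compartment: str) -> tuple[str, ...]:
        """Mediators measured in one compartment (albumin only in BAL)."""
        if compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {compartment!r}")
        out = self.common_variables()
        if compartment == BAL:
            out = out + (self.albumin,)
        return out


DEFAULT_PANEL = MediatorPanel()
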