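"""Parameter and state containers for the coupled-conformation EGFR binding model.

The model tracks twelve receptor species on the cell surface.  Monomers are
named by the conformation of the extracellular domain (C = closed/tethered,
E = extended) and of the kinase domain (I = inactive, A = active); an ``L``
suffix marks a bound EGF.  Dimers (``D`` prefix) form only from extended
monomers and carry either a symmetric kinase dimer (``DES*``, built from
inactive-kinase monomers) or an asymmetric, activating kinase dimer
(``DEA*``, built from active-kinase monomers), with 0, 1 or 2 bound EGF.

Nine equilibrium constants govern the system:

=====  =======================================================  ==============
name   meaning                                                  unit
=====  =======================================================  ==============
K1     kinase-domain equilibrium, inactive/active (>1 favours   dimensionless
       the inactive conformation)
K2     extracellular-domain equilibrium, closed/extended (>1    dimensionless
       favours the closed conformation)
K3     EGF dissociation constant of an extended monomer         nM
K4     dissociation constant of the symmetric-kinase dimer      receptors/cell
K5,K6  EGF dissociation constants of the first and second       nM
       binding to a symmetric-kinase dimer
K7     dissociation constant of the asymmetric-kinase dimer     receptors/cell
K8,K9  EGF dissociation constants of the first and second       nM
       binding to an asymmetric-kinase dimer
=====  =======================================================  ==============

Receptor species are expressed in copies/cell (a dimer counts as one dimer
copy holding two receptors); ligand is in nM.  No conversion between the two
unit systems is attempted.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, fields, replace
from typing import NamedTuple

__all__ = [
    "SPECIES",
    "MONOMER_SPECIES",
    "DIMER_SPECIES",
    "LIGANDED_SPECIES",
    "PARAM_NAMES",
    "InvalidParameterError",
    "ParameterSet",
    "EquilibriumInput",
    "EquilibriumState",
    "reference_parameters",
    "REFERENCE_K1",
]

#: Species names, in the conventional order.
SPECIES = (
    "CI", "CA", "EI", "EA", "EIL", "EAL",
    "DES", "DESL", "DES2L", "DEA", "DEAL", "DEA2L",
)
MONOMER_SPECIES = SPECIES[:6]
DIMER_SPECIES = SPECIES[6:]
#: Species carrying at least one EGF.
LIGANDED_SPECIES = ("EIL", "EAL", "DESL", "DES2L", "DEAL", "DEA2L")

PARAM_NAMES = ("K1", "K2", "K3", "K4", "K5", "K6", "K7", "K8", "K9")


class InvalidParameterError(ValueError):
    """An equilibrium constant is non-positive or non-finite."""


@dataclass(frozen=True)
class ParameterSet:
    """The nine equilibrium constants of the binding model.

    All constants must be strictly positive and finite; see the module
    docstring for meanings and units.
    """

    K1: float
    K2: float
    K3: float
    K4: float
    K5: float
    K6: float
    K7: float
    K8: float
    K9: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise InvalidParameterError(
                    f"{f.name} must be a strictly positive finite number, got {v!r}"
                )
            object.__setattr__(self, f.name, float(v))

    def replace(self, **changes: float) -> "ParameterSet":
        """Return a copy with the given constants replaced."""
        return replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=2)

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ParameterSet":
        return cls(**{k: d[k] for k in PARAM_NAMES})

    @classmethod
    def from_json(cls, s: str) -> "ParameterSet":
        return cls.from_dict(json.loads(s))


class EquilibriumInput(NamedTuple):
    """One operating point: total receptor number and free EGF concentration.

    ``Rtot`` is receptors/cell (>= 0); ``L`` is free EGF in nM (>= 0).  Free
    ligand is identified with added ligand: depletion is assumed negligible
    (see :func:`egfrbind.simulate.depletion_check`).
    """

    Rtot: float
    L: float


@dataclass(frozen=True)
class EquilibriumState:
    """Equilibrium concentrations of the twelve species plus bound EGF.

    Monomer species are in receptors/cell, dimer species in dimers/cell and
    ``bound`` (total cell-associated EGF) in molecules/cell.
    """

    CI: float
    CA: float
    EI: float
    EA: float
    EIL: float
    EAL: float
    DES: float
    DESL: float
    DES2L: float
    DEA: float
    DEAL: float
    DEA2L: float
    bound: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=2)

    @classmethod
    def from_json(cls, s: str) -> "EquilibriumState":
        return cls(**json.loads(s))

    def total_receptors(self) -> float:
        """Reconstruct Rtot from the state (dimers count two receptors)."""
        monomers = sum(getattr(self, n) for n in MONOMER_SPECIES)
        dimers = sum(getattr(self, n) for n in DIMER_SPECIES)
        return monomers + 2.0 * dimers


#: Kinase-domain equilibrium constant per pharmacological condition, from the
#: published global fit (erlotinib stabilises the active, lapatinib the
#: inactive kinase conformation; only K1 shifts between conditions).
REFERENCE_K1 = {"untreated": 104.0, "erlotinib": 25.0, "lapatinib": 162.0}

_REFERENCE_GLOBAL = dict(
    K2=2.9, K3=1.3, K4=36_900.0, K5=95.0, K6=0.45,
    K7=480.0, K8=0.1, K9=2.96,
)


def reference_parameters(condition: str = "untreated") -> ParameterSet:
    """Published estimates of the nine constants for EGFR-GFP in CHO cells.

    ``condition`` selects the kinase-inhibitor treatment, which only changes
    the kinase-domain equilibrium K1 (untreated 104, erlotinib 25,
    lapatinib 162); K2-K9 are shared between conditions.
    """
    try:
        k1 = REFERENCE_K1[condition]
    except KeyError:
        raise ValueError(
            f"unknown condition {condition!r}; expected one of {sorted(REFERENCE_K1)}"
        ) from None
    return ParameterSet(K1=k1, **_REFERENCE_GLOBAL)
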