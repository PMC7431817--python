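"""Closed-form solver for the twelve-species EGFR binding equilibrium.

Mass action couples every species to the extended, inactive-kinase monomer
EI.  With L the free EGF concentration:

    CI    = K2*EI              CA    = K2*EI/K1         EA   = EI/K1
    EIL   = EI*L/K3            EAL   = EA*L/K3
    DES   = EI^2/K4            DESL  = DES*L/K5         DES2L = DESL*L/K6
    DEA   = EA^2/K7            DEAL  = DEA*L/K8         DEA2L = DEAL*L/K9

Substituting into receptor conservation (monomers + 2*dimers = Rtot) yields
a single quadratic a*EI^2 + b*EI - Rtot = 0 with a, b > 0, which has exactly
one positive root.  The root is evaluated as 2*Rtot/(b + sqrt(b^2 + 4*a*Rtot))
— algebraically equivalent to the textbook formula but free of cancellation
when a*Rtot << b^2 (low expression, weak dimerization).

Bound EGF counts one ligand per singly and two per doubly liganded dimer:

    bound = EIL + EAL + DESL + DEAL + 2*(DES2L + DEA2L)
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .parameters import (
    DIMER_SPECIES,
    MONOMER_SPECIES,
    SPECIES,
    EquilibriumState,
    InvalidParameterError,
    ParameterSet,
)

__all__ = [
    "solve_equilibrium",
    "binding_curve",
    "species_fractions",
    "dimer_fraction",
    "linkage_constants",
    "gauge_transform",
]


def _quadratic_coeffs(p: ParameterSet, L):
    """Coefficients (a, b) of a*EI^2 + b*EI - Rtot = 0, vectorised over L."""
    L = np.asarray(L, dtype=float)
    b = p.K2 + p.K2 / p.K1 + 1.0 + 1.0 / p.K1 + (L / p.K3) * (1.0 + 1.0 / p.K1)
    sym = (1.0 + L / p.K5 + L * L / (p.K5 * p.K6)) / p.K4
    asym = (1.0 + L / p.K8 + L * L / (p.K8 * p.K9)) / (p.K1 * p.K1 * p.K7)
    a = 2.0 * (sym + asym)
    return a, b


def _solve_EI(p: ParameterSet, Rtot: float, L) -> np.ndarray:
    """Positive root of the conservation quadratic (0 when Rtot = 0)."""
    a, b = _quadratic_coeffs(p, L)
    # b > 0 and the constant term -Rtot <= 0, so the positive root is unique;
    # this form is stable for a*Rtot << b^2.
    return 2.0 * Rtot / (b + np.sqrt(b * b + 4.0 * a * Rtot))


def _species_from_EI(p: ParameterSet, EI, L) -> dict[str, np.ndarray]:
    EI = np.asarray(EI, dtype=float)
    L = np.asarray(L, dtype=float)
    EA = EI / p.K1
    DES = EI * EI / p.K4
    DEA = EA * EA / p.K7
    out = {
        "CI": p.K2 * EI,
        "CA": p.K2 * EI / p.K1,
        "EI": EI,
        "EA": EA,
        "EIL": EI * L / p.K3,
        "EAL": EA * L / p.K3,
        "DES": DES,
        "DESL": DES * L / p.K5,
        "DEA": DEA,
        "DEAL": DEA * L / p.K8,
    }
    out["DES2L"] = out["DESL"] * L / p.K6
    out["DEA2L"] = out["DEAL"] * L / p.K9
    return out


def _bound(species: Mapping[str, np.ndarray]) -> np.ndarray:
    return (
        species["EIL"] + species["EAL"] + species["DESL"] + species["DEAL"]
        + 2.0 * (species["DES2L"] + species["DEA2L"])
    )


def _validate_point(Rtot: float, L: float) -> None:
    if not (np.isfinite(Rtot) and Rtot >= 0):
        raise ValueError(f"Rtot must be finite and >= 0, got {Rtot!r}")
    if not (np.isfinite(L) and L >= 0):
        raise ValueError(f"L must be finite and >= 0 nM, got {L!r}")


def solve_equilibrium(params: ParameterSet, Rtot: float, L: float) -> EquilibriumState:
    """Solve the equilibrium at one (Rtot, L) point.

    Parameters
    ----------
    params
        The nine equilibrium constants.
    Rtot
        Total receptor number, receptors/cell.  Rtot = 0 returns the all-zero
        state.
    L
        Free EGF concentration, nM (assumed equal to added EGF; no depletion).

    Returns
    -------
    EquilibriumState
        The unique solution with every concentration non-negative.
    """
    _validate_point(Rtot, L)
    if Rtot == 0.0:
        return EquilibriumState(**{n: 0.0 for n in SPECIES}, bound=0.0)
    if L == 0.0:
        # Ligand-free system: only the four unliganded monomers and the two
        # unliganded dimers are populated.
        a, b = _quadratic_coeffs(params, 0.0)
        EI = 2.0 * Rtot / (b + np.sqrt(b * b + 4.0 * a * Rtot))
        sp = _species_from_EI(params, EI, 0.0)
        return EquilibriumState(**{n: float(sp[n]) for n in SPECIES}, bound=0.0)
    EI = _solve_EI(params, Rtot, L)
    sp = _species_from_EI(params, EI, L)
    return EquilibriumState(
        **{n: float(sp[n]) for n in SPECIES}, bound=float(_bound(sp))
    )


def binding_curve(params: ParameterSet, Rtot: float, L_grid) -> np.ndarray:
    """Bound EGF (molecules/cell) on an ascending grid of concentrations.

    ``L_grid`` must be non-empty, non-negative and sorted ascending.  The
    returned curve is non-decreasing and bounded by Rtot.
    """
    L = np.asarray(L_grid, dtype=float)
    if L.ndim != 1 or L.size == 0:
        raise ValueError("L_grid must be a non-empty 1-D sequence")
    if np.any(~np.isfinite(L)) or np.any(L < 0):
        raise ValueError("L_grid values must be finite and >= 0 nM")
    if np.any(np.diff(L) < 0):
        raise ValueError("L_grid must be sorted ascending")
    _validate_point(Rtot, float(L[0]))
    if Rtot == 0.0:
        return np.zeros_like(L)
    EI = _solve_EI(params, Rtot, L)
    return np.asarray(_bound(_species_from_EI(params, EI, L)), dtype=float)


def species_fractions(params: ParameterSet, Rtot: float, L: float) -> dict[str, float]:
    """Fraction of all receptors residing in each species.

    Dimer species are weighted by two receptors per dimer, so the twelve
    fractions sum to 1.  Raises ``ValueError`` for Rtot = 0 (undefined).
    """
    if Rtot <= 0:
        raise ValueError("species fractions are undefined for Rtot <= 0")
    state = solve_equilibrium(params, Rtot, L)
    out = {n: getattr(state, n) / Rtot for n in MONOMER_SPECIES}
    out.update({n: 2.0 * getattr(state, n) / Rtot for n in DIMER_SPECIES})
    return out


def dimer_fraction(params: ParameterSet, Rtot: float, L: float) -> float:
    """Fraction of receptors incorporated in dimers (of either kinase type)."""
    if Rtot <= 0:
        raise ValueError("dimer fraction is undefined for Rtot <= 0")
    state = solve_equilibrium(params, Rtot, L)
    return 2.0 * sum(getattr(state, n) for n in DIMER_SPECIES) / Rtot


def linkage_constants(params: ParameterSet) -> tuple[float, float]:
    """Dissociation constants for dimerization of doubly *liganded* monomers.

    Thermodynamic linkage makes the dimerization constant of liganded
    monomers expressible through the constants of the unliganded path:
    K4*K5*K6/K3**2 for the inactive (symmetric-kinase) pathway and
    K7*K8*K9/K3**2 for the active (asymmetric-kinase) pathway, both in
    receptors/cell.  A value above (below) the corresponding unliganded
    dimerization constant K4 (K7) indicates negative (positive) linkage:
    ligand binding weakens (strengthens) the drive to dimerize.
    """
    k3sq = params.K3 * params.K3
    d_inactive = params.K4 * params.K5 * params.K6 / k3sq
    d_active = params.K7 * params.K8 * params.K9 / k3sq
    return d_inactive, d_active


def gauge_transform(params: ParameterSet, K2_new: float) -> ParameterSet:
    """Map a parameter set along the exact invariance of the binding curve.

    The amount of bound EGF as a function of (Rtot, L) is unchanged under

        K2 + 1 -> g*(K2 + 1),  K3 -> K3/g,  K4 -> K4/g**2,  K7 -> K7/g**2

    for any g > 0 (the internal monomer pool is relabelled; every observable
    product, including both linkage constants and all species *fractions
    involving liganded states summed appropriately*, is preserved).  Binding
    data alone therefore determine K2, K3, K4 and K7 only up to this gauge;
    this helper moves a parameter set to the representative with the given
    K2.  Species-resolved quantities (e.g. the CI/EI split) do depend on the
    gauge.
    """
    if not K2_new > 0:
        raise InvalidParameterError("K2_new must be > 0")
    g = (K2_new + 1.0) / (params.K2 + 1.0)
    return params.replace(
        K2=K2_new, K3=params.K3 / g, K4=params.K4 / (g * g),
        K7=params.K7 / (g * g),
    )
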