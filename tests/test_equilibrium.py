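"""Closed-form equilibrium solver vs independent root-finding oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq, root

from egfrbind import (
    InvalidParameterError,
    ParameterSet,
    binding_curve,
    dimer_fraction,
    linkage_constants,
    reference_parameters,
    solve_equilibrium,
    species_fractions,
)
from egfrbind.equilibrium import gauge_transform
from egfrbind.parameters import LIGANDED_SPECIES, SPECIES


def ladder_species(p, EI, L):
    """Build all species from EI via the mass-action ladder (test-side copy)."""
    EA = EI / p.K1
    DES = EI**2 / p.K4
    DEA = EA**2 / p.K7
    return {
        "CI": p.K2 * EI, "CA": p.K2 * EI / p.K1, "EI": EI, "EA": EA,
        "EIL": EI * L / p.K3, "EAL": EA * L / p.K3,
        "DES": DES, "DESL": DES * L / p.K5, "DES2L": DES * L**2 / (p.K5 * p.K6),
        "DEA": DEA, "DEAL": DEA * L / p.K8, "DEA2L": DEA * L**2 / (p.K8 * p.K9),
    }


def total_receptors(sp):
    return (sp["CI"] + sp["CA"] + sp["EI"] + sp["EA"] + sp["EIL"] + sp["EAL"]
            + 2.0 * (sp["DES"] + sp["DESL"] + sp["DES2L"]
                     + sp["DEA"] + sp["DEAL"] + sp["DEA2L"]))


def brentq_oracle(p, Rtot, L):
    """Scalar-bracketing oracle: find EI from receptor conservation alone."""
    f = lambda EI: total_receptors(ladder_species(p, EI, L)) - Rtot
    EI = brentq(f, 0.0, Rtot, xtol=1e-300, rtol=1e-15, maxiter=300)
    return ladder_species(p, EI, L)


def random_params(rng):
    ref = reference_parameters().as_dict()
    vals = {k: v * 10.0 ** rng.uniform(-3, 3) for k, v in ref.items()}
    return ParameterSet(**vals)


class TestSimultaneousRootOracle:
    """The closed form agrees with a direct 13-unknown numeric root solve."""

    @staticmethod
    def full_system(y, p, Rtot, L):
        """Residuals of the 13 simultaneous mass-action equations.

        Unknowns are the 12 species plus bound ligand, scaled by Rtot.
        """
        (CI, CA, EI, EA, EIL, EAL, DES, DESL, DES2L, DEA, DEAL, DEA2L,
         bound) = y * Rtot
        return [
            CI - p.K1 * CA,
            CI - p.K2 * EI,
            EI - p.K1 * EA,
            (EI * L - p.K3 * EIL) / max(L, 1.0),
            (EA * L - p.K3 * EAL) / max(L, 1.0),
            (EI * EI - p.K4 * DES) / Rtot,
            (DES * L - p.K5 * DESL) / max(L, 1.0),
            (DESL * L - p.K6 * DES2L) / max(L, 1.0),
            (EA * EA - p.K7 * DEA) / Rtot,
            (DEA * L - p.K8 * DEAL) / max(L, 1.0),
            (DEAL * L - p.K9 * DEA2L) / max(L, 1.0),
            bound - (EIL + EAL + DESL + DEAL + 2 * (DES2L + DEA2L)),
            Rtot - (CI + CA + EI + EA + EIL + EAL
                    + 2 * (DES + DESL + DES2L + DEA + DEAL + DEA2L)),
        ]

    @pytest.mark.parametrize(
        "condition,Rtot,L",
        [
            ("untreated", 560_000.0, 3.9),
            ("untreated", 1_070_000.0, 130.0),
            ("erlotinib", 390_000.0, 0.5),
            ("lapatinib", 630_000.0, 10.0),
        ],
    )
    def test_state_matches_13_unknown_root(self, condition, Rtot, L):
        p = reference_parameters(condition)
        sol = root(
            self.full_system, np.full(13, 1.0 / 14.0), args=(p, Rtot, L),
            method="hybr", tol=1e-13,
        )
        # hybr may flag xtol exhaustion even at machine-precision residuals,
        # so judge convergence by the residual itself
        resid = np.max(np.abs(self.full_system(sol.x, p, Rtot, L)))
        assert resid < 1e-8 * Rtot
        state = solve_equilibrium(p, Rtot, L)
        ours = np.array([getattr(state, n) for n in SPECIES] + [state.bound])
        theirs = sol.x * Rtot
        assert np.all(theirs > 0)
        np.testing.assert_allclose(ours, theirs, rtol=1e-8)


def test_closed_form_matches_bracketing_oracle_over_random_draws(ref_params):
    """1,000 random draws (+-3 decades, Rtot 1e3-1e7, L 0-1e3 nM) agree with
    an independent bracketing root solve to 1e-8 relative, conserve receptor
    number to 1e-8, and are non-negative throughout."""
    rng = np.random.default_rng(20240817)
    for _ in range(1000):
        p = random_params(rng)
        Rtot = 10.0 ** rng.uniform(3, 7)
        L = rng.uniform(0.0, 1e3) if rng.random() > 0.05 else 0.0
        state = solve_equilibrium(p, Rtot, L)
        vals = np.array([getattr(state, n) for n in SPECIES])
        assert np.all(vals >= 0)
        assert state.total_receptors() == pytest.approx(Rtot, rel=1e-8)
        oracle = brentq_oracle(p, Rtot, L)
        for n in SPECIES:
            assert getattr(state, n) == pytest.approx(
                oracle[n], rel=1e-8, abs=1e-250
            )


def test_no_ligand_gives_zero_bound(ref_params):
    state = solve_equilibrium(ref_params, 560_000.0, 0.0)
    assert state.bound == 0.0
    for name in LIGANDED_SPECIES:
        assert getattr(state, name) == 0.0


def test_zero_receptors_gives_all_zero_state(ref_params):
    state = solve_equilibrium(ref_params, 0.0, 10.0)
    assert state.bound == 0.0
    assert all(getattr(state, n) == 0.0 for n in SPECIES)


def test_mass_action_identity_holds_exactly(ref_params):
    state = solve_equilibrium(ref_params, 560_000.0, 3.9)
    assert state.DES * ref_params.K4 == pytest.approx(state.EI**2, rel=1e-12)


def test_invalid_parameters_rejected():
    with pytest.raises(InvalidParameterError):
        ParameterSet(K1=-1, K2=2.9, K3=1.3, K4=1, K5=1, K6=1, K7=1, K8=1, K9=1)
    with pytest.raises(InvalidParameterError):
        ParameterSet(K1=math.inf, K2=2.9, K3=1.3, K4=1, K5=1, K6=1, K7=1,
                     K8=1, K9=1)


class TestBindingCurve:
    def test_zero_grid(self, ref_params):
        assert binding_curve(ref_params, 560_000.0, [0.0]) == pytest.approx([0.0])

    def test_monotone_and_bounded(self, ref_params):
        L = np.logspace(-3, 5, 200)
        b = binding_curve(ref_params, 560_000.0, L)
        assert np.all(np.diff(b) >= 0)
        assert np.all(b <= 560_000.0)
        assert b[-1] / 560_000.0 > 0.999  # saturation: bound/Rtot -> 1

    def test_errors(self, ref_params):
        with pytest.raises(ValueError):
            binding_curve(ref_params, 1e5, [])
        with pytest.raises(ValueError):
            binding_curve(ref_params, 1e5, [2.0, 1.0])
        with pytest.raises(ValueError):
            binding_curve(ref_params, 1e5, [-1.0, 1.0])

    def test_no_dimer_limit_reduces_to_single_site_isotherm(self, ref_params):
        """With dimerization switched off the curve is the closed-form
        monomer isotherm."""
        p = ref_params.replace(K4=1e300, K7=1e300)
        K1, K2, K3 = p.K1, p.K2, p.K3
        L = np.logspace(-2, 3, 50)
        Rtot = 560_000.0
        expected = (Rtot * (L / K3) * (1 / K1 + 1)
                    / (K2 + K2 / K1 + 1 + 1 / K1 + L / K3 + L / (K1 * K3)))
        np.testing.assert_allclose(
            binding_curve(p, Rtot, L), expected, rtol=1e-10
        )


def test_detailed_balance_doubly_liganded_symmetric_dimer(ref_params):
    """DES2L computed by dimerizing liganded monomers through the linkage
    constant equals the sequential-binding value."""
    state = solve_equilibrium(ref_params, 560_000.0, 7.0)
    d_inactive, _ = linkage_constants(ref_params)
    assert state.DES2L == pytest.approx(state.EIL**2 / d_inactive, rel=1e-10)


class TestSpeciesFractions:
    def test_sum_to_one_and_range(self, ref_params):
        fr = species_fractions(ref_params, 560_000.0, 10.0)
        assert sum(fr.values()) == pytest.approx(1.0, abs=1e-10)
        assert all(0.0 <= v <= 1.0 for v in fr.values())

    def test_no_ligand_no_liganded_species(self, ref_params):
        fr = species_fractions(ref_params, 560_000.0, 0.0)
        for name in LIGANDED_SPECIES:
            assert fr[name] == 0.0

    def test_inactive_limit_removes_active_species(self, ref_params):
        fr = species_fractions(ref_params.replace(K1=1e12), 560_000.0, 10.0)
        for name in ("CA", "EA", "EAL", "DEA", "DEAL", "DEA2L"):
            assert fr[name] == pytest.approx(0.0, abs=1e-10)

    def test_lapatinib_monomer_is_dominant_binder(self, ref_params):
        """With the kinase locked inactive, the inactive-kinase monomer binds
        more EGF than asymmetric-kinase dimers."""
        fr = species_fractions(ref_params.replace(K1=162.0), 560_000.0, 10.0)
        assert fr["EIL"] > fr["DEAL"] + 2.0 * fr["DEA2L"]

    def test_zero_rtot_undefined(self, ref_params):
        with pytest.raises(ValueError):
            species_fractions(ref_params, 0.0, 1.0)


class TestDimerFraction:
    def test_no_dimerization_limit(self, ref_params):
        p = ref_params.replace(K4=1e250, K7=1e250)
        assert dimer_fraction(p, 560_000.0, 10.0) == pytest.approx(0.0, abs=1e-12)

    def test_mass_action_increases_with_expression(self, ref_params):
        low = dimer_fraction(ref_params, 390_000.0, 0.0)
        high = dimer_fraction(ref_params, 780_000.0, 0.0)
        assert high > low

    def test_egf_response_larger_with_active_kinase(self, ref_params):
        """EGF recruits receptors into dimers when the kinase is
        erlotinib-locked active but barely when lapatinib-locked inactive."""
        deltas = {}
        for k1 in (25.0, 162.0):
            p = ref_params.replace(K1=k1)
            deltas[k1] = abs(
                dimer_fraction(p, 560_000.0, 130.0)
                - dimer_fraction(p, 560_000.0, 0.0)
            )
        assert deltas[25.0] > deltas[162.0]

    def test_zero_rtot_error(self, ref_params):
        with pytest.raises(ValueError):
            dimer_fraction(ref_params, 0.0, 1.0)


class TestLinkageConstants:
    def test_reference_values(self, ref_params):
        d_inactive, d_active = linkage_constants(ref_params)
        assert d_inactive == pytest.approx(9.3e5, rel=0.02)
        assert d_active == pytest.approx(84.0, rel=0.02)

    def test_unit_linkage(self):
        p = ParameterSet(K1=10, K2=1, K3=2.0, K4=1.0, K5=4.0, K6=1.0,
                         K7=1, K8=1, K9=1)
        d_inactive, _ = linkage_constants(p)  # K5*K6 = K3^2, K4 = 1
        assert d_inactive == pytest.approx(1.0, rel=1e-12)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    g=st.floats(0.3, 20.0),  # g below 1/(K2+1) would need K2_new < 0
    rtot=st.floats(1e3, 1e7),
    L=st.floats(0.0, 1e3),
)
def test_gauge_transform_leaves_bound_invariant(g, rtot, L):
    """Bound EGF is exactly invariant under the K2/K3/K4/K7 gauge family."""
    p = reference_parameters()
    q = gauge_transform(p, g * (p.K2 + 1.0) - 1.0)
    b1 = solve_equilibrium(p, rtot, L).bound
    b2 = solve_equilibrium(q, rtot, L).bound
    assert b2 == pytest.approx(b1, rel=1e-12, abs=1e-12)
    d1, a1 = linkage_constants(p)
    d2, a2 = linkage_constants(q)
    assert d2 == pytest.approx(d1, rel=1e-12)
    assert a2 == pytest.approx(a1, rel=1e-12)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.integers(0, 10_000))
def test_random_states_conserve_and_stay_positive(seed):
    rng = np.random.default_rng(seed)
    p = random_params(rng)
    Rtot = 10.0 ** rng.uniform(3, 7)
    L = rng.uniform(0, 1e3)
    state = solve_equilibrium(p, Rtot, L)
    assert all(getattr(state, n) >= 0 for n in SPECIES)
    assert state.total_receptors() == pytest.approx(Rtot, rel=1e-8)
    liganded = (state.EIL + state.EAL + state.DESL + state.DEAL
                + 2 * (state.DES2L + state.DEA2L))
    assert state.bound == pytest.approx(liganded, rel=1e-12, abs=1e-12)
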