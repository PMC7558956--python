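"""Gastric acid-base chemistry: pH-solubility profile, equilibrium pH,
Mooney-Stella surface pH, all checked against independent bisection oracles."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gutfa import (DomainError, equilibrium_gastric_ph, intrinsic_solubility,
                   mooney_stella_surface_ph, ph_dependent_solubility)
from gutfa.gastric import diffusion_coefficient, drug_s0_molar

KW = 1e-14
D_H, D_OH = 9.31e-5, 5.28e-5

# cinnarizine: S_buffer 0.0014 mg/mL at pH 6.5, pKa 7.5, MW 369
CIN_S0 = 3.45e-7          # mol/L
CIN_KA = 10.0 ** -7.5


def bisect(f, lo, hi, n=200):
    """Sign-change bisection; f must be monotone increasing on [lo, hi]."""
    flo, fhi = f(lo), f(hi)
    assert flo < 0 < fhi
    for _ in range(n):
        mid = math.sqrt(lo * hi)  # geometric: roots span many decades
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def equilibrium_balance(s0, ka, h_ini, kw):
    """Unrearranged proton balance of the gastric equilibrium."""
    return lambda h: h + h * s0 / ka - kw / h - (h_ini - kw / h_ini)


def surface_balance(s0, ka, d_drug, h_b, d_h, d_oh, kw):
    """Unrearranged film flux balance at the dissolving solid surface."""
    return lambda h: (d_drug * s0 * h / ka
                      - d_h * (h_b - h) - d_oh * (kw / h - kw / h_b))


def test_ph_solubility_profile_limits():
    s0, ka = 1e-5, 1e-7
    assert ph_dependent_solubility(s0, ka, ka) == pytest.approx(2 * s0, rel=1e-12)
    assert ph_dependent_solubility(s0, ka, 1e-14) == pytest.approx(s0, rel=1e-6)
    with pytest.raises(DomainError):
        ph_dependent_solubility(-1.0, ka, 1e-3)


def test_intrinsic_solubility_roundtrip():
    s0 = intrinsic_solubility(3.79e-6, CIN_KA, 10 ** -6.5)
    assert s0 == pytest.approx(CIN_S0, rel=2e-2)
    # inverse pair at arbitrary pH
    s = ph_dependent_solubility(s0, CIN_KA, 10 ** -6.5)
    assert s == pytest.approx(3.79e-6, rel=1e-12)
    # negligible ionization far above pKa
    assert intrinsic_solubility(1e-4, 1e-5, 1e-12) == pytest.approx(1e-4, rel=1e-6)


def test_cinnarizine_intrinsic_solubility_mg():
    """Buffer datum 0.0014 mg/mL at pH 6.5 back-calculates to ~0.0014/11."""
    s0 = intrinsic_solubility(0.0014, CIN_KA, 10 ** -6.5)
    assert s0 == pytest.approx(0.0014 / 11.0, rel=1e-3)


def test_cinnarizine_gastric_equilibrium_ph():
    eq = equilibrium_gastric_ph(CIN_S0, CIN_KA, 2.0, KW)
    assert eq.pH_eq == pytest.approx(3.08, abs=0.02)
    assert eq.pH_eq > 3.0          # raised well above the initial pH 2.0
    assert eq.H_eq <= eq.H_ini


def test_cinnarizine_surface_solubility_near_reported():
    """At pH 2.6 the profile gives ~10-11 mg/mL for cinnarizine."""
    s = ph_dependent_solubility(CIN_S0, CIN_KA, 10 ** -2.6) * 369.0  # mg/mL
    assert 9.5 <= s <= 11.5


def test_no_base_leaves_ph_unchanged():
    eq = equilibrium_gastric_ph(1e-30, CIN_KA, 2.0, KW)
    assert eq.pH_eq == pytest.approx(2.0, abs=1e-6)
    surf = mooney_stella_surface_ph(1e-30, CIN_KA, 6.8e-6, 2.0, D_H, D_OH, KW)
    assert surf.pH_surface == pytest.approx(2.0, abs=1e-6)


def test_equal_diffusivity_reduces_to_equilibrium():
    """With D_H = D_OH = D_drug the film balance collapses to the bulk one."""
    for s0, pka, ph in [(1e-5, 7.5, 2.0), (1e-3, 5.0, 3.0), (1e-7, 9.0, 1.5)]:
        ka = 10.0 ** -pka
        d = 6.0e-6
        surf = mooney_stella_surface_ph(s0, ka, d, ph, d, d, KW)
        eq = equilibrium_gastric_ph(s0, ka, ph, KW)
        assert surf.H_surface == pytest.approx(eq.H_eq, rel=1e-9)


def test_charge_balance_at_equilibrium_root():
    eq = equilibrium_gastric_ph(CIN_S0, CIN_KA, 2.0, KW)
    h = eq.H_eq
    bh = CIN_S0 * h / CIN_KA
    cl = eq.H_ini - KW / eq.H_ini
    oh = KW / h
    assert h + bh == pytest.approx(cl + oh, rel=1e-10)


valid_chem = dict(
    s0=st.floats(1e-12, 1e-1),
    pka=st.floats(2.0, 12.0),
    ph=st.floats(1.0, 7.5),
)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(**valid_chem)
def test_equilibrium_root_matches_bisection(s0, pka, ph):
    ka = 10.0 ** -pka
    eq = equilibrium_gastric_ph(s0, ka, ph, KW)
    oracle = bisect(equilibrium_balance(s0, ka, 10.0 ** -ph, KW), 1e-14, 1.0)
    assert eq.H_eq == pytest.approx(oracle, rel=1e-9)
    assert eq.pH_eq >= ph - 1e-9


@settings(max_examples=200, derandomize=True, deadline=None)
@given(d_drug=st.floats(1e-7, 1e-4), **valid_chem)
def test_surface_root_matches_bisection(d_drug, s0, pka, ph):
    ka = 10.0 ** -pka
    surf = mooney_stella_surface_ph(s0, ka, d_drug, ph, D_H, D_OH, KW)
    oracle = bisect(surface_balance(s0, ka, d_drug, 10.0 ** -ph, D_H, D_OH, KW),
                    1e-14, 1.0)
    assert surf.H_surface == pytest.approx(oracle, rel=1e-9)
    assert surf.pH_surface >= ph - 1e-9      # a base consumes surface protons


@settings(max_examples=100, derandomize=True, deadline=None)
@given(s0=st.floats(1e-10, 1e-2), pka=st.floats(3.0, 11.0))
def test_monotone_in_s0_and_pka(s0, pka):
    """More base, or a stronger base, can only raise pH_eq and pH_surface."""
    ka = 10.0 ** -pka
    eq1 = equilibrium_gastric_ph(s0, ka, 2.0, KW)
    eq2 = equilibrium_gastric_ph(s0 * 3.0, ka, 2.0, KW)
    eq3 = equilibrium_gastric_ph(s0, 10.0 ** -(pka + 0.5), 2.0, KW)
    assert eq2.pH_eq >= eq1.pH_eq - 1e-12
    assert eq3.pH_eq >= eq1.pH_eq - 1e-12
    # the pH-solubility profile itself is strictly increasing in [H+]
    assert ph_dependent_solubility(s0, ka, 1e-2) > ph_dependent_solubility(s0, ka, 1e-3)
    s1 = mooney_stella_surface_ph(s0, ka, 6e-6, 2.0, D_H, D_OH, KW)
    s2 = mooney_stella_surface_ph(s0 * 3.0, ka, 6e-6, 2.0, D_H, D_OH, KW)
    assert s2.pH_surface >= s1.pH_surface - 1e-12


def test_cinnarizine_surface_ph_between_bounds(drugs):
    """Surface pH for cinnarizine at gastric bulk pH 2 sits between the bulk
    pH and the bulk equilibrium pH, in the band the sensitivity of the
    proton-diffusivity choice allows."""
    d = drugs["cinnarizine"]
    s0 = drug_s0_molar(d)
    surf = mooney_stella_surface_ph(s0, d.Ka, diffusion_coefficient(d.MW),
                                    2.0, D_H, D_OH, KW)
    assert 2.2 <= surf.pH_surface <= 3.1
    s_mg = surf.S_surface_molar * d.MW
    assert 11.0 / 3.0 <= s_mg <= 33.0   # within 3-fold of the ~11 mg/mL scale
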