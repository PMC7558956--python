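"""Gastric stage: particle distribution, dissolution, fraction dissolved.

The stomach is treated as a single well-mixed compartment with first-order
emptying (mean transit time T_ST = T_ST1/2 / ln 2).  The fraction of the dose
dissolved before transit, Fd_ST, follows from two dimensionless groups:

* the dose number ``Do_ST = Dose / (S_ST * V_ST)`` (how far the dose exceeds
  the gastric dissolved-capacity at the equilibrium pH), and
* the dissolution number ``Dn_ST = k_diss_ST * T_ST`` (how fast particles
  dissolve relative to emptying),

combined as ``Fd_ST = 1 / (Do_ST + 1 + 1/Dn_ST)``, whose two loss terms also
classify the limiting factor (solubility- vs dissolution-rate-limited).

Three scenarios differ in which pH drives the solubilities: (A) no gastric
dissolution at all; (B) the initial bulk pH for both S_ST and the surface
solubility; (C) the equilibrium bulk pH for S_ST and the Mooney-Stella surface
pH for the dissolution driving force.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .acid_base import (DomainError, equilibrium_gastric_ph, intrinsic_solubility,
                        mooney_stella_surface_ph, ph_dependent_solubility)
from .config import DEFAULT_CONFIG, ModelConfig
from .parameters_io import DoseScenario, DrugProperties, from_molar, to_molar

__all__ = [
    "ParticleDistribution", "GastricResult", "diffusion_coefficient",
    "make_particle_bins", "dissolution_rate_coefficient",
    "fraction_dissolved_stomach", "gastric_stage", "drug_s0_molar",
]


def diffusion_coefficient(mw: float) -> float:
    """Aqueous diffusivity of a drug monomer from molecular weight.

    Empirical power law ``D = 9.9e-5 * MW**-0.453`` (cm^2/s).
    """
    if mw <= 0:
        raise DomainError(f"MW must be > 0, got {mw}")
    return 9.9e-5 * mw ** -0.453


def drug_s0_molar(drug: DrugProperties) -> float:
    """Intrinsic solubility in mol/L back-calculated from the buffer datum."""
    s_buffer = to_molar(drug.S_buffer, drug.MW)
    return intrinsic_solubility(s_buffer, drug.Ka, 10.0 ** (-drug.pH_buffer))


@dataclass(frozen=True)
class ParticleDistribution:
    """Mass-fraction bins over particle radius (cm)."""

    fractions: tuple[float, ...]
    radii_cm: tuple[float, ...]
    d50_um: float
    ln_sd: float

    def sum_f_over_r2(self) -> float:
        """Second inverse moment sum_i f_i / r_i^2 (cm^-2)."""
        return sum(f / r ** 2 for f, r in zip(self.fractions, self.radii_cm))


def make_particle_bins(d50_um: float, ln_sd: float | None = None,
                       n_bins: int | None = None,
                       config: ModelConfig = DEFAULT_CONFIG) -> ParticleDistribution:
    """Discretize a log-normal (in radius) mass distribution into bins.

    The median radius is d50/2; bins span +-3 sigma of ln r; each bin carries
    the Gaussian probability mass of its interval, evaluated at the bin's
    geometric midpoint.  ``ln_sd == 0`` or ``n_bins == 1`` gives a monodisperse
    distribution at the median radius.
    """
    if d50_um <= 0:
        raise DomainError(f"d50 must be > 0, got {d50_um}")
    ln_sd = config.ln_sd if ln_sd is None else ln_sd
    n_bins = config.n_bins if n_bins is None else n_bins
    if n_bins < 1:
        raise DomainError(f"n_bins must be >= 1, got {n_bins}")
    r50_cm = d50_um / 2.0 * 1e-4
    if ln_sd == 0.0 or n_bins == 1:
        return ParticleDistribution((1.0,), (r50_cm,), d50_um, ln_sd)
    mu = math.log(r50_cm)
    lo, hi = mu - 3.0 * ln_sd, mu + 3.0 * ln_sd
    edges = [lo + (hi - lo) * i / n_bins for i in range(n_bins + 1)]
    cdf = lambda x: 0.5 * (1.0 + math.erf((x - mu) / (ln_sd * math.sqrt(2.0))))
    fracs, radii = [], []
    total = cdf(hi) - cdf(lo)
    for a, b in zip(edges[:-1], edges[1:]):
        fracs.append((cdf(b) - cdf(a)) / total)
        radii.append(math.exp(0.5 * (a + b)))
    return ParticleDistribution(tuple(fracs), tuple(radii), d50_um, ln_sd)


def dissolution_rate_coefficient(d_cm2_s: float, s_surface_mg_ml: float,
                                 rho_g_cm3: float, bins: ParticleDistribution,
                                 config: ModelConfig = DEFAULT_CONFIG) -> float:
    """Initial-rate Noyes-Whitney dissolution coefficient, 1/s.

    ``k_diss = (3 D S_surface / rho) * sum_i f_i / r_i^2`` with the diffusion
    layer equal to the particle radius (valid for the sub-100-um particles
    modeled here).  S in mg/mL == mg/cm^3; rho converted to mg/cm^3.
    """
    if d_cm2_s <= 0 or s_surface_mg_ml <= 0 or rho_g_cm3 <= 0:
        raise DomainError("dissolution inputs must be positive")
    rho_mg_cm3 = rho_g_cm3 * 1000.0
    if config.kdiss_sum_mode == "sum_fi_over_ri2":
        moment = bins.sum_f_over_r2()
    elif config.kdiss_sum_mode == "inv_sum_fi_ri2":
        moment = 1.0 / sum(f * r ** 2 for f, r in zip(bins.fractions, bins.radii_cm))
    else:
        raise ValueError(f"unknown kdiss_sum_mode {config.kdiss_sum_mode!r}")
    return 3.0 * d_cm2_s * s_surface_mg_ml / rho_mg_cm3 * moment


def fraction_dissolved_stomach(do_st: float, dn_st: float) -> tuple[float, str]:
    """Fraction dissolved in the stomach and its limiting factor.

    ``Fd_ST = 1/(Do_ST + 1 + 1/Dn_ST)``.  The label compares the two limiting
    closed forms — solubility-limited ``1/Do`` vs dissolution-rate-limited
    ``Dn/(1+Dn)`` — and names whichever is smaller (binds tighter): SL when
    ``Do > 1 + 1/Dn``, else DRL.
    """
    if dn_st <= 0:
        raise DomainError(f"Dn_ST must be > 0, got {dn_st}")
    if do_st < 0:
        raise DomainError(f"Do_ST must be >= 0, got {do_st}")
    fd = 1.0 / (do_st + 1.0 + 1.0 / dn_st)
    limiting = "SL" if do_st > 1.0 + 1.0 / dn_st else "DRL"
    return fd, limiting


@dataclass(frozen=True)
class GastricResult:
    scenario: str
    pH_eq: float            # bulk pH used for S_ST
    pH_surface: float       # surface pH used for the dissolution driving force
    S_ST: float             # mg/mL
    S_surface: float        # mg/mL
    Do_ST: float
    k_diss_ST: float        # 1/s
    Dn_ST: float
    Fd_ST: float
    limiting: str           # {"SL", "DRL", "none"}


def gastric_stage(scn: DoseScenario, config: ModelConfig = DEFAULT_CONFIG) -> GastricResult:
    """Run the gastric stage of one dose scenario."""
    drug, phys = scn.drug, scn.physiology
    if scn.scenario == "A":
        return GastricResult("A", phys.pH_STini, phys.pH_STini,
                             math.nan, math.nan, math.nan, math.nan, math.nan,
                             0.0, "none")

    s0 = drug_s0_molar(drug)
    d_mono = diffusion_coefficient(drug.MW)
    if scn.scenario == "B":
        h_ini = 10.0 ** (-phys.pH_STini)
        ph_eq = ph_surface = phys.pH_STini
        s_st = from_molar(ph_dependent_solubility(s0, drug.Ka, h_ini), drug.MW)
        s_surface = s_st
    else:  # scenario C
        eq = equilibrium_gastric_ph(s0, drug.Ka, phys.pH_STini, config.kw)
        surf = mooney_stella_surface_ph(s0, drug.Ka, d_mono, phys.pH_STini,
                                        config.d_h, config.d_oh, config.kw)
        ph_eq, ph_surface = eq.pH_eq, surf.pH_surface
        s_st = from_molar(eq.S_ST_molar, drug.MW)
        s_surface = from_molar(surf.S_surface_molar, drug.MW)

    do_st = scn.dose / (s_st * phys.V_ST)
    bins = make_particle_bins(scn.d50, config=config)
    k_diss = dissolution_rate_coefficient(d_mono, s_surface, config.rho, bins, config)
    dn_st = k_diss * phys.T_ST * 60.0
    fd_st, limiting = fraction_dissolved_stomach(do_st, dn_st)
    return GastricResult(scn.scenario, ph_eq, ph_surface, s_st, s_surface,
                         do_st, k_diss, dn_st, fd_st, limiting)
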