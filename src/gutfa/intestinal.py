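"""Small-intestinal stage: biorelevant solubility, permeability, closed-form Fa.

Solubility in intestinal fluid is split into a non-micellar (aqueous monomer)
part, set by the pH-solubility profile at the intestinal pH, and a bile-micelle
part that scales linearly with the bile micelle concentration.  The micellar
increment per mM bile is anchored to a measured biorelevant-medium solubility
(FaSSIF/FeSSIF-type) when one exists; otherwise it is estimated from logP_oct
through a micelle-water partition correlation.

Effective permeability composes, in series,

* the unstirred water layer (UWL): film diffusion of dissolved drug with a
  monomer-fraction-weighted diffusivity.  When undissolved particles are
  present they drift into the UWL and keep dissolving there, acting as a
  distributed source; the resulting reaction-diffusion enhancement is
  ``P_UWL = sqrt(D K) * coth(h sqrt(K/D))`` with volumetric redissolution
  constant ``K = Cpd * k_diss * C_solid / S_SI``, which reduces to the plain
  film ``D/h`` as the solid load vanishes;
* the epithelial membrane: transcellular permeation of the unionized monomer
  (intrinsic permeability correlated with logP_oct, or back-calculated from a
  measured cell-monolayer Papp) plus a small paracellular term (Renkin sieving
  with electrochemical attraction of the cation), both scaled by the monomer
  fraction and the villous surface expansion.

The fraction absorbed then follows the closed-form dose/dissolution/permeation
number equation with the dose number floored at one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .acid_base import DomainError, ph_dependent_solubility
from .config import DEFAULT_CONFIG, ModelConfig
from .gastric import (diffusion_coefficient, dissolution_rate_coefficient,
                      drug_s0_molar, make_particle_bins)
from .parameters_io import DoseScenario, DrugProperties, Physiology, from_molar

__all__ = [
    "IntestinalSolubility", "PermeabilityBreakdown", "IntestinalResult",
    "intestinal_solubility", "effective_permeability", "fa_si",
    "intestinal_stage",
]

_AVOGADRO = 6.02214076e23


def _unionized_fraction(pka: float, ph: float) -> float:
    """Fraction of the aqueous monomer pool that is unionized (free base)."""
    return 1.0 / (1.0 + 10.0 ** (pka - ph))


@dataclass(frozen=True)
class IntestinalSolubility:
    S_SI: float      # mg/mL, total dissolved capacity at (pH_SI, C_bm)
    S_aq: float      # mg/mL, non-micellar monomer part at pH_SI
    f_mono: float    # S_aq / S_SI

    def __post_init__(self):
        if not 0.0 < self.f_mono <= 1.0 or self.S_SI < self.S_aq:
            raise DomainError("inconsistent intestinal solubility split")


def _aqueous_solubility(drug: DrugProperties, ph: float) -> float:
    """pH-profile monomer solubility in mg/mL."""
    s0 = drug_s0_molar(drug)
    return from_molar(ph_dependent_solubility(s0, drug.Ka, 10.0 ** (-ph)), drug.MW)


def _biorelevant_anchor(drug: DrugProperties, phys: Physiology):
    """Choose the measured biorelevant medium closest to the target state.

    Returns (S_measured, pH_medium, C_bm_medium, fed_medium) or None.  Fed
    state prefers a fed-state medium; dog scenarios prefer the dog-bile-level
    medium.
    """
    candidates = []
    if phys.state == "fed" and drug.S_fessif is not None:
        candidates.append((drug.S_fessif, drug.pH_fessif, drug.Cbm_fessif, True))
    if phys.species == "dog" and drug.S_fassif_dog is not None:
        candidates.append((drug.S_fassif_dog, drug.pH_fassif_dog,
                           drug.Cbm_fassif_dog, False))
    if drug.S_fassif is not None:
        candidates.append((drug.S_fassif, drug.pH_fassif, drug.Cbm_fassif, False))
    return candidates[0] if candidates else None


def intestinal_solubility(drug: DrugProperties, phys: Physiology,
                          config: ModelConfig = DEFAULT_CONFIG) -> IntestinalSolubility:
    """Total and non-micellar solubility at the intestinal pH and bile level.

    The micellar increment per mM bile is anchored to the state-matched
    measured medium; a fed-state prediction that has to fall back on a
    fasted-medium measurement (or on the logP correlation) is scaled by the
    fed-state per-bile solubilization factor, since fed-state media solubilize
    more drug per bile molecule than fasted ones.
    """
    s_aq = _aqueous_solubility(drug, phys.pH_SI)
    anchor = _biorelevant_anchor(drug, phys)
    if anchor is not None:
        s_meas, ph_meas, cbm_meas, fed_medium = anchor
        increment_per_mm = max(0.0, s_meas - _aqueous_solubility(drug, ph_meas)) / cbm_meas
        if phys.state == "fed" and not fed_medium:
            increment_per_mm *= config.fed_bile_scale
    else:
        # micelle-water partitioning of the unionized species from logP
        kbm = 10.0 ** (config.kbm_slope * drug.logPoct + config.kbm_intercept)  # M^-1
        s0 = from_molar(drug_s0_molar(drug), drug.MW)
        increment_per_mm = s0 * kbm * 1e-3
        if phys.state == "fed":
            increment_per_mm *= config.fed_bile_scale
    s_si = s_aq + increment_per_mm * phys.C_bm
    return IntestinalSolubility(S_SI=s_si, S_aq=s_aq, f_mono=s_aq / s_si)


@dataclass(frozen=True)
class PermeabilityBreakdown:
    P_trans: float       # cm/s, transcellular, referenced to total dissolved
    P_para: float        # cm/s, paracellular, referenced to total dissolved
    P_UWL: float         # cm/s, unstirred water layer (incl. particle effect)
    P_eff: float         # cm/s, series composition (villous expansion applied)
    limiting_side: str   # {"epithelial", "UWL"}


def _molecular_radius_angstrom(mw: float, rho_g_cm3: float) -> float:
    """Equivalent-sphere molecular radius from MW and true density."""
    r_cm = (3.0 * mw / (4.0 * math.pi * rho_g_cm3 * _AVOGADRO)) ** (1.0 / 3.0)
    return r_cm * 1e8


def _renkin(lam: float) -> float:
    """Renkin hindrance factor for sieving through a cylindrical pore."""
    if lam >= 1.0:
        return 0.0
    return (1.0 - lam) ** 2 * (1.0 - 2.104 * lam + 2.09 * lam ** 3 - 0.95 * lam ** 5)


def intrinsic_transcellular_permeability(drug: DrugProperties,
                                         config: ModelConfig = DEFAULT_CONFIG) -> float:
    """P_trans0 of the unionized monomer, cm/s.

    Back-calculated from a measured cell-monolayer Papp when available
    (``P_trans0 = Papp / f0(assay pH)``), otherwise from the lipophilicity
    correlation ``log10 P_trans0 = slope * logPoct + intercept``.
    """
    if drug.Papp_measured is not None:
        if drug.Papp_pH is None:
            raise DomainError(f"{drug.name}: measured Papp requires its assay pH")
        f0 = _unionized_fraction(drug.pKa, drug.Papp_pH)
        return drug.Papp_measured / f0
    return 10.0 ** (config.ptrans0_slope * drug.logPoct + config.ptrans0_intercept)


def effective_permeability(drug: DrugProperties, phys: Physiology,
                           sol: IntestinalSolubility,
                           solid_conc_mg_ml: float = 0.0,
                           k_diss_si: float = 0.0,
                           r50_cm: float = 0.0,
                           config: ModelConfig = DEFAULT_CONFIG) -> PermeabilityBreakdown:
    """Series UWL + epithelial effective permeability, cm/s.

    ``solid_conc_mg_ml``, ``k_diss_si`` and ``r50_cm`` describe the suspended
    undissolved particles feeding the UWL (zero when fully dissolved).
    """
    d_mono = diffusion_coefficient(drug.MW)
    f0 = _unionized_fraction(drug.pKa, phys.pH_SI)
    f_cat = 1.0 - f0

    # epithelial side, referenced to total dissolved concentration
    p_trans0 = intrinsic_transcellular_permeability(drug, config)
    p_trans = sol.f_mono * f0 * p_trans0
    lam = _molecular_radius_angstrom(drug.MW, config.rho) / phys.R_ParaMW
    p_para = (sol.f_mono * config.para_scale * d_mono * _renkin(lam)
              * (f0 + config.para_cation_factor * f_cat))
    p_ep = p_trans + p_para

    # unstirred water layer, monomer/micelle-weighted diffusivity
    d_uwl = sol.f_mono * d_mono + (1.0 - sol.f_mono) * config.d_micelle
    p_uwl = d_uwl / phys.h_UWL
    if (config.uwl_particle_mode == "drift" and solid_conc_mg_ml > 0.0
            and k_diss_si > 0.0 and r50_cm > 0.0):
        # distributed dissolution source inside the film; the drifting
        # efficiency grows with particle size (sedimentation-like supply)
        eta = (r50_cm / (config.drift_ref_radius_um * 1e-4)) ** (2.0 / 3.0)
        k_vol = phys.C_pd * eta * k_diss_si * solid_conc_mg_ml / sol.S_SI  # 1/s
        phi = phys.h_UWL * math.sqrt(k_vol / d_uwl)
        p_uwl = max(p_uwl, math.sqrt(d_uwl * k_vol) / math.tanh(phi))

    p_eff = 1.0 / (1.0 / p_uwl + 1.0 / (phys.VE * p_ep))
    limiting = "UWL" if 1.0 / p_uwl >= 1.0 / (phys.VE * p_ep) else "epithelial"
    return PermeabilityBreakdown(P_trans=p_trans, P_para=p_para, P_UWL=p_uwl,
                                 P_eff=p_eff, limiting_side=limiting)


def fa_si(do_si: float, dn_si: float, pn_si: float, tn_si: float = 1.0) -> float:
    """Closed-form fraction absorbed in the small intestine.

    ``Fa_SI = 1 - exp(-1 / ((1/Dn + Do'/Pn) * Tn))`` with ``Do' = max(Do, 1)``:
    below saturation the dissolved concentration, not the dose, sets the
    permeation driving force.
    """
    if dn_si <= 0 or pn_si <= 0 or tn_si <= 0:
        raise DomainError("Dn, Pn and Tn must be positive")
    if do_si < 0:
        raise DomainError(f"Do_SI must be >= 0, got {do_si}")
    do_eff = max(do_si, 1.0)
    return 1.0 - math.exp(-1.0 / ((1.0 / dn_si + do_eff / pn_si) * tn_si))


@dataclass(frozen=True)
class IntestinalResult:
    Do_SI: float
    Dn_SI: float
    Pn_SI: float
    Tn_SI: float
    Fa_SI: float
    farls: str                # {"PL-E", "PL-U", "DRL", "SL"}
    solubility: IntestinalSolubility
    permeability: PermeabilityBreakdown
    k_diss_SI: float          # 1/s


def intestinal_stage(scn: DoseScenario, fd_st: float,
                     config: ModelConfig = DEFAULT_CONFIG) -> IntestinalResult:
    """Run the small-intestinal stage given the gastric fraction dissolved."""
    if not 0.0 <= fd_st < 1.0:
        raise DomainError(f"fd_st must be in [0, 1), got {fd_st}")
    drug, phys = scn.drug, scn.physiology
    sol = intestinal_solubility(drug, phys, config)

    # the full initial particle distribution enters with the undissolved mass
    bins = make_particle_bins(scn.d50, config=config)
    d_uwl = sol.f_mono * diffusion_coefficient(drug.MW) + (1.0 - sol.f_mono) * config.d_micelle
    k_diss = dissolution_rate_coefficient(d_uwl, sol.S_SI, config.rho, bins, config)

    dose_si = scn.dose * (1.0 - fd_st)
    do_si = dose_si / (sol.S_SI * phys.V_SI)
    solid_conc = max(0.0, dose_si / phys.V_SI - sol.S_SI)
    r50_cm = scn.d50 / 2.0 * 1e-4
    perm = effective_permeability(drug, phys, sol, solid_conc, k_diss, r50_cm,
                                  config)

    t_si_s = phys.T_SI * 60.0
    dn_si = k_diss * t_si_s
    pn_si = (2.0 * phys.DF / phys.R_GI) * phys.PE * perm.P_eff * t_si_s
    tn_si = 1.0
    fa = fa_si(do_si, dn_si, pn_si, tn_si)

    if do_si <= 1.0:
        if pn_si < dn_si:
            farls = "PL-U" if perm.limiting_side == "UWL" else "PL-E"
        else:
            farls = "DRL"
    else:
        farls = "SL" if pn_si / do_si < dn_si else "DRL"

    return IntestinalResult(Do_SI=do_si, Dn_SI=dn_si, Pn_SI=pn_si, Tn_SI=tn_si,
                            Fa_SI=fa, farls=farls, solubility=sol,
                            permeability=perm, k_diss_SI=k_diss)
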