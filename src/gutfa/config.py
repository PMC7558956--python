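"""Model configuration constants.

Everything that is neither a drug property nor a physiological parameter lives
here: water chemistry constants, the particle-bin discretization, and the
coefficients of the permeability / bile-solubilization correlations used by the
intestinal stage.  Values are frozen package defaults; they can be overridden
per-run through :func:`ModelConfig.from_file` (a flat ``key = value`` or
``key: value`` text file) or by constructing a ``ModelConfig`` directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from pathlib import Path


@dataclass(frozen=True)
class ModelConfig:
    # --- water / acid-base chemistry ---
    kw: float = 1.0e-14          # water ion product, mol^2/L^2 (25 C convention)
    d_h: float = 9.31e-5         # aqueous diffusivity of H+, cm^2/s
    d_oh: float = 5.28e-5        # aqueous diffusivity of OH-, cm^2/s

    # --- solid / particle model ---
    rho: float = 1.2             # true density of drug substance, g/cm^3
    n_bins: int = 20             # bins discretizing the log-normal size distribution
    ln_sd: float = math.log(2.0)  # sigma of ln(radius)
    # Noyes-Whitney polydisperse reading of the dissolution-rate sum:
    # "sum_fi_over_ri2" (mass-weighted per-bin rates) or "inv_sum_fi_ri2"
    # (reciprocal second moment); the former is the physically standard form.
    kdiss_sum_mode: str = "sum_fi_over_ri2"

    # --- bile micelles ---
    d_micelle: float = 7.4e-7    # diffusivity of a bile-salt/lecithin micelle, cm^2/s
    # log10 Kbm [M^-1] = kbm_slope * logPoct + kbm_intercept (micelle-water
    # partitioning of the unionized species); used only when no biorelevant
    # solubility was measured (palbociclib).
    kbm_slope: float = 0.74
    kbm_intercept: float = 2.29
    # per-bile-molecule solubilization in the fed state relative to the fasted
    # medium; applied only when a fed condition has to be anchored on a
    # fasted-medium measurement or on the correlation.
    fed_bile_scale: float = 1.5

    # --- epithelial permeability ---
    # log10 P_trans0 [cm/s] = ptrans0_slope * logPoct + ptrans0_intercept
    ptrans0_slope: float = 0.94
    ptrans0_intercept: float = -5.2
    # paracellular Renkin sieving: P_para = para_scale * D_mono * RK(r_mol/R_para)
    #                                       * (f0 + para_cation_factor * f_cation)
    para_scale: float = 15.0     # 1/cm, lumps pore fraction / path length
    para_cation_factor: float = 2.39  # electrochemical attraction of monovalent cations

    # --- unstirred water layer / particle drifting ---
    # "drift": undissolved particles act as a distributed dissolution source in
    # the UWL (reaction-diffusion enhancement, scaled by the physiology's Cpd
    # and a size-dependent drifting efficiency); "off": plain film D_eff/h_UWL.
    uwl_particle_mode: str = "drift"
    # reference radius of the drifting efficiency (r50 / r_ref)^(2/3): larger
    # particles are carried to the wall more efficiently (sedimentation-like
    # supply), partially offsetting their slower per-mass dissolution.
    drift_ref_radius_um: float = 40.0

    # Tn convention of the closed-form Fa equation: Dn and Pn are rate*T_SI, Tn == 1.
    tn_convention: str = "unity"

    def replace(self, **kw) -> "ModelConfig":
        return replace(self, **kw)

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelConfig":
        """Read overrides from a flat key/value text file.

        Lines look like ``kw = 1.4e-14`` or ``n_bins: 40``; ``#`` starts a
        comment.  Unknown keys raise ``ValueError``.
        """
        known = {f.name: f.type for f in fields(cls)}
        overrides: dict[str, object] = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            for sep in ("=", ":"):
                if sep in line:
                    key, val = (s.strip() for s in line.split(sep, 1))
                    break
            else:
                raise ValueError(f"cannot parse config line: {raw!r}")
            if key not in known:
                raise ValueError(f"unknown config key: {key!r}")
            if key in ("kdiss_sum_mode", "uwl_particle_mode", "tn_convention"):
                overrides[key] = val
            elif key == "n_bins":
                overrides[key] = int(val)
            else:
                overrides[key] = float(val)
        return cls(**overrides)  # type: ignore[arg-type]


DEFAULT_CONFIG = ModelConfig()
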