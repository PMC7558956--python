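"""Acid-base chemistry of a dissolving free weak base.

Three closed forms drive the gastric stage:

* the Henderson-Hasselbalch pH-solubility profile of a monoprotic base,
  ``S(pH) = S0 * (1 + [H+]/Ka)``;
* the bulk equilibrium pH after an excess of free base neutralizes the
  (unbuffered) HCl of gastric fluid — charge balance rearranges to a quadratic
  in [H+];
* the solid-surface pH during dissolution (Mooney-Stella film model): at the
  particle surface the acid-base reaction consumes protons faster than they
  diffuse in, so the surface sits at a higher pH than the bulk and the
  dissolution-driving solubility is the surface one.

All concentrations are mol/L here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


class DomainError(ValueError):
    """An argument is outside the physically meaningful domain."""


def _require_positive(**kw: float) -> None:
    for name, v in kw.items():
        if not (v > 0 and math.isfinite(v)):
            raise DomainError(f"{name} must be finite and > 0, got {v}")


def ph_dependent_solubility(s0: float, ka: float, h: float) -> float:
    """Total solubility of a monoprotic base at proton concentration ``h``.

    ``S = S0 * (1 + h/Ka)`` — the unionized part S0 plus the protonated part.
    Strictly increasing in ``h``.
    """
    _require_positive(s0=s0, ka=ka, h=h)
    return s0 * (1.0 + h / ka)


def intrinsic_solubility(s_buffer: float, ka: float, h_buffer: float) -> float:
    """Back-calculate the intrinsic solubility S0 from a buffer measurement.

    Inverse of :func:`ph_dependent_solubility`: ``S0 = S_buffer / (1 + h/Ka)``.
    """
    _require_positive(s_buffer=s_buffer, ka=ka, h_buffer=h_buffer)
    return s_buffer / (1.0 + h_buffer / ka)


def _stable_positive_quadratic_root(a: float, b: float, c: float) -> float:
    """Positive root of ``a x^2 + b x + c = 0`` with a > 0, c <= 0.

    With c < 0 the discriminant exceeds b^2, so exactly one positive root
    exists.  Uses the multiplication-free form q = -(b - sqrt(disc))/2 ... the
    citardauq variant to avoid cancellation when b^2 >> |4ac|.
    """
    disc = b * b - 4.0 * a * c
    if disc < 0:
        raise DomainError("negative discriminant; invalid chemistry inputs")
    sq = math.sqrt(disc)
    if b <= 0:
        x = (-b + sq) / (2.0 * a)
    else:
        # root via the conjugate form; c <= 0 makes this the positive root
        x = (2.0 * c) / (-b - sq)
    if not (x > 0 and math.isfinite(x)):
        raise DomainError("no positive root found")
    return x


@dataclass(frozen=True)
class GastricEquilibrium:
    H_ini: float      # mol/L
    H_eq: float       # mol/L
    pH_eq: float
    S_ST_molar: float  # mol/L, maximum gastric solubility at pH_eq


def equilibrium_gastric_ph(s0: float, ka: float, ph_ini: float,
                           kw: float = 1.0e-14) -> GastricEquilibrium:
    """Bulk gastric pH in equilibrium with an excess of dissolving free base.

    Charge neutrality with [BH+] = S0*[H+]/Ka and [Cl-] fixed by the initial
    HCl content gives

        [H+]^2 (1 + S0/Ka) - [H+]([H+]_ini - Kw/[H+]_ini) - Kw = 0

    whose positive root is [H+]_eq.  A dissolving base can only consume
    protons, so pH_eq >= pH_ini.
    """
    _require_positive(s0=s0, ka=ka, kw=kw)
    if not 0.0 < ph_ini < 14.0:
        raise DomainError(f"ph_ini must be in (0, 14), got {ph_ini}")
    h_ini = 10.0 ** (-ph_ini)
    a = 1.0 + s0 / ka
    b = -(h_ini - kw / h_ini)
    c = -kw
    h_eq = _stable_positive_quadratic_root(a, b, c)
    return GastricEquilibrium(
        H_ini=h_ini, H_eq=h_eq, pH_eq=-math.log10(h_eq),
        S_ST_molar=ph_dependent_solubility(s0, ka, h_eq),
    )


@dataclass(frozen=True)
class SurfaceState:
    H_surface: float   # mol/L
    pH_surface: float
    S_surface_molar: float  # mol/L, solubility at the solid surface


def mooney_stella_surface_ph(s0: float, ka: float, d_drug: float,
                             ph_bulk: float,
                             d_h: float = 9.31e-5, d_oh: float = 5.28e-5,
                             kw: float = 1.0e-14) -> SurfaceState:
    """Solid-surface pH of a dissolving monoprotic free base (film model).

    Steady-state flux balance across the diffusion film: the protonated base
    leaving the surface (flux D_drug * S0 * [H+]_s / Ka, with the bulk acting
    as a sink for dissolved drug) must be fed by protons diffusing in and
    hydroxide diffusing out,

        D_drug * S0 * [H+]_s / Ka
            = D_H * ([H+]_b - [H+]_s) + D_OH * (Kw/[H+]_s - Kw/[H+]_b)

    which rearranges to the quadratic

        (D_drug*S0/Ka + D_H) [H+]_s^2
            - (D_H*[H+]_b - D_OH*Kw/[H+]_b) [H+]_s - D_OH*Kw = 0.

    With equal diffusivities this collapses to the bulk-equilibrium quadratic,
    which serves as an internal consistency oracle.
    """
    _require_positive(s0=s0, ka=ka, d_drug=d_drug, d_h=d_h, d_oh=d_oh, kw=kw)
    if not 0.0 < ph_bulk < 14.0:
        raise DomainError(f"ph_bulk must be in (0, 14), got {ph_bulk}")
    h_b = 10.0 ** (-ph_bulk)
    a = d_drug * s0 / ka + d_h
    b = -(d_h * h_b - d_oh * kw / h_b)
    c = -d_oh * kw
    h_s = _stable_positive_quadratic_root(a, b, c)
    return SurfaceState(
        H_surface=h_s, pH_surface=-math.log10(h_s),
        S_surface_molar=ph_dependent_solubility(s0, ka, h_s),
    )
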