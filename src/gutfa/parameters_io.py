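"""Typed input records and packaged fixture tables.

Three tables drive every prediction:

* ``drugs.csv`` — measured physicochemical properties per drug (MW, basic pKa,
  logP_oct, buffer solubility at a stated pH, biorelevant solubilities with
  their medium pH and bile concentration, optional cell-monolayer permeability).
* ``physiology.csv`` — one parameter set per species x prandial state x
  acid-reducing-agent (ARA) flag: gastric pH/volume/emptying, intestinal pH,
  bile concentration, transit time, volume, and the anatomical surface-area
  and unstirred-water-layer parameters.
* ``scenarios.csv`` — one row per prediction task (drug, condition, dose,
  mass-median particle diameter) together with the literature-derived observed
  Fa / AUC-ratio where available.

All concentrations are mg/mL in the tables; chemistry converts to mol/L via
:func:`to_molar` / :func:`from_molar` only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd


class ValidationError(ValueError):
    """A fixture row or field violates its schema or a physical invariant."""


# ---------------------------------------------------------------------------
# unit conversions

def to_molar(conc_mg_ml: float, mw: float) -> float:
    """Convert mg/mL to mol/L.  mg/mL == g/L, so divide by MW (g/mol)."""
    if mw <= 0:
        raise ValidationError(f"MW must be positive, got {mw}")
    return conc_mg_ml / mw


def from_molar(conc_mol_l: float, mw: float) -> float:
    """Convert mol/L back to mg/mL (inverse of :func:`to_molar`)."""
    if mw <= 0:
        raise ValidationError(f"MW must be positive, got {mw}")
    return conc_mol_l * mw


# ---------------------------------------------------------------------------
# records

@dataclass(frozen=True)
class DrugProperties:
    """Measured inputs for one free weak base drug (monoprotic)."""

    name: str
    MW: float                       # g/mol
    pKa: float                      # basic dissociation constant, -log10 Ka
    logPoct: float
    S_buffer: float                 # mg/mL
    pH_buffer: float = 6.5          # pH at which S_buffer was measured
    S_fassif: Optional[float] = None    # mg/mL, fasted-state simulated fluid
    pH_fassif: float = 6.5
    Cbm_fassif: float = 3.0             # mM bile in the measurement medium
    S_fassif_dog: Optional[float] = None
    pH_fassif_dog: float = 6.5
    Cbm_fassif_dog: float = 5.0
    S_fessif: Optional[float] = None    # mg/mL, fed-state simulated fluid
    pH_fessif: float = 5.0
    Cbm_fessif: float = 15.0
    Papp_measured: Optional[float] = None  # cm/s, cell monolayer assay
    Papp_pH: Optional[float] = None

    def __post_init__(self):
        if self.MW <= 0:
            raise ValidationError(f"{self.name}: MW must be > 0")
        if not 0 < self.pKa < 14:
            raise ValidationError(f"{self.name}: pKa must be in (0, 14)")
        if self.S_buffer <= 0 or not math.isfinite(self.S_buffer):
            raise ValidationError(f"{self.name}: S_buffer must be finite and > 0")
        for fname in ("S_fassif", "S_fassif_dog", "S_fessif", "Papp_measured"):
            v = getattr(self, fname)
            if v is not None and (v <= 0 or not math.isfinite(v)):
                raise ValidationError(f"{self.name}: {fname} must be finite and > 0")

    @property
    def Ka(self) -> float:
        """Acid dissociation constant of the conjugate acid, mol/L."""
        return 10.0 ** (-self.pKa)


@dataclass(frozen=True)
class Physiology:
    """One species x prandial-state x ARA parameter block."""

    species: str                # {"human", "dog"}
    state: str                  # {"fasted", "fed"}
    ara: bool
    pH_STini: float             # initial gastric pH
    T_ST_half: float            # gastric emptying half-life, min
    V_ST: float                 # gastric fluid volume, mL
    pH_SI: float                # small-intestinal pH
    C_bm: float                 # bile micelle concentration, mM
    T_SI: float                 # small-intestinal transit time, min
    V_SI: float                 # small-intestinal fluid volume, mL
    PE: float                   # plicate surface expansion
    VE: float                   # villi surface expansion
    R_GI: float                 # intestinal radius, cm
    DF: float                   # degree of flatness of the tube
    R_ParaMW: float             # paracellular pore radius parameter, Angstrom
    h_UWL: float                # unstirred water layer thickness, cm
    C_pd: float                 # particle drifting coefficient
    R_mucus: float              # nominal mucus pore radius, um

    def __post_init__(self):
        if self.species not in ("human", "dog"):
            raise ValidationError(f"unknown species {self.species!r}")
        if self.state not in ("fasted", "fed"):
            raise ValidationError(f"unknown prandial state {self.state!r}")
        for fname in ("T_ST_half", "V_ST", "T_SI", "V_SI", "h_UWL", "R_GI"):
            if getattr(self, fname) <= 0:
                raise ValidationError(f"{fname} must be > 0")

    @property
    def T_ST(self) -> float:
        """Mean gastric transit time in min (= T_ST_half / ln 2)."""
        return self.T_ST_half / math.log(2.0)

    @property
    def k_tr_ST(self) -> float:
        """Gastric transit rate constant, 1/min."""
        return 1.0 / self.T_ST


@dataclass(frozen=True)
class DoseScenario:
    """One prediction task."""

    drug: DrugProperties
    physiology: Physiology
    dose: float                 # mg
    d50: float                  # mass-median particle diameter, um
    scenario: str = "C"         # gastric-dissolution scenario {A, B, C}
    observed_fa: Optional[float] = None
    observed_aucr: Optional[float] = None
    pair_id: Optional[str] = None
    # printed reference predictions carried along for validation work
    ref: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.dose <= 0:
            raise ValidationError(f"{self.drug.name}: dose must be > 0")
        if self.d50 <= 0:
            raise ValidationError(f"{self.drug.name}: d50 must be > 0")
        if self.scenario not in ("A", "B", "C"):
            raise ValidationError(f"scenario must be A, B or C, got {self.scenario!r}")
        if self.observed_fa is not None and not 0 < self.observed_fa <= 1.05:
            raise ValidationError(
                f"{self.drug.name}: observed Fa {self.observed_fa} outside (0, 1.05]")

    def with_scenario(self, scenario: str) -> "DoseScenario":
        return DoseScenario(self.drug, self.physiology, self.dose, self.d50,
                            scenario, self.observed_fa, self.observed_aucr,
                            self.pair_id, self.ref)


# ---------------------------------------------------------------------------
# fixture loading

_DATA_PKG = "gutfa.data"


def _data_path(name: str, directory: str | Path | None) -> Path:
    if directory is not None:
        return Path(directory) / name
    return Path(str(resources.files(_DATA_PKG) / name))


def _opt(row, col) -> Optional[float]:
    v = row.get(col)
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return float(v)


def load_drugs(path: str | Path | None = None) -> dict[str, DrugProperties]:
    """Load the drug-properties table; returns a name-keyed dict."""
    fp = _data_path("drugs.csv", path) if path is None or Path(path).is_dir() else Path(path)
    df = pd.read_csv(fp)
    required = {"name", "MW", "pKa", "logPoct", "S_buffer", "pH_buffer"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"drugs table missing columns: {sorted(missing)}")
    out: dict[str, DrugProperties] = {}
    for i, row in df.iterrows():
        try:
            d = DrugProperties(
                name=str(row["name"]),
                MW=float(row["MW"]), pKa=float(row["pKa"]),
                logPoct=float(row["logPoct"]),
                S_buffer=float(row["S_buffer"]), pH_buffer=float(row["pH_buffer"]),
                S_fassif=_opt(row, "S_fassif"),
                pH_fassif=_opt(row, "pH_fassif") or 6.5,
                Cbm_fassif=_opt(row, "Cbm_fassif") or 3.0,
                S_fassif_dog=_opt(row, "S_fassif_dog"),
                pH_fassif_dog=_opt(row, "pH_fassif_dog") or 6.5,
                Cbm_fassif_dog=_opt(row, "Cbm_fassif_dog") or 5.0,
                S_fessif=_opt(row, "S_fessif"),
                pH_fessif=_opt(row, "pH_fessif") or 5.0,
                Cbm_fessif=_opt(row, "Cbm_fessif") or 15.0,
                Papp_measured=_opt(row, "Papp"),
                Papp_pH=_opt(row, "Papp_pH"),
            )
        except (TypeError, ValueError) as e:
            raise ValidationError(f"drugs row {i}: {e}") from e
        out[d.name] = d
    return out


def load_physiology(path: str | Path | None = None) -> dict[tuple, Physiology]:
    """Load the physiology table keyed by (species, state, ara)."""
    fp = _data_path("physiology.csv", path) if path is None or Path(path).is_dir() else Path(path)
    df = pd.read_csv(fp)
    out: dict[tuple, Physiology] = {}
    for i, row in df.iterrows():
        try:
            p = Physiology(
                species=str(row["species"]), state=str(row["state"]),
                ara=bool(int(row["ara"])),
                pH_STini=float(row["pH_STini"]),
                T_ST_half=float(row["TST_half_min"]), V_ST=float(row["VST_mL"]),
                pH_SI=float(row["pH_SI"]), C_bm=float(row["Cbm_mM"]),
                T_SI=float(row["TSI_min"]), V_SI=float(row["VSI_mL"]),
                PE=float(row["PE"]), VE=float(row["VE"]),
                R_GI=float(row["RGI_cm"]), DF=float(row["DF"]),
                R_ParaMW=float(row["RParaMW"]), h_UWL=float(row["hUWL_cm"]),
                C_pd=float(row["Cpd"]), R_mucus=float(row["Rmucus_um"]),
            )
        except (KeyError, TypeError, ValueError) as e:
            raise ValidationError(f"physiology row {i}: {e}") from e
        out[(p.species, p.state, p.ara)] = p
    return out


_REF_COLS = ("pred_fa_A", "pred_fa_B", "pred_fa_C", "pred_aucr",
             "fa_fdst_pct", "gastric_limiting")


def load_scenarios(path: str | Path | None = None,
                   drugs: dict[str, DrugProperties] | None = None,
                   physiology: dict[tuple, Physiology] | None = None,
                   ) -> list[DoseScenario]:
    """Load the scenario table, resolving drug and physiology references."""
    fp = _data_path("scenarios.csv", path) if path is None or Path(path).is_dir() else Path(path)
    drugs = drugs if drugs is not None else load_drugs(
        path if path is not None and Path(path).is_dir() else None)
    physiology = physiology if physiology is not None else load_physiology(
        path if path is not None and Path(path).is_dir() else None)
    df = pd.read_csv(fp)
    required = {"drug", "species", "state", "ara", "dose_mg", "d50_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"scenario table missing columns: {sorted(missing)}")
    out: list[DoseScenario] = []
    for i, row in df.iterrows():
        name = str(row["drug"])
        if name not in drugs:
            raise ValidationError(f"scenario row {i}: unknown drug {name!r}")
        key = (str(row["species"]), str(row["state"]), bool(int(row["ara"])))
        if key not in physiology:
            raise ValidationError(f"scenario row {i}: unknown condition {key}")
        ref = {c: row[c] for c in _REF_COLS if c in df.columns and not _is_na(row[c])}
        pair = row.get("pair_id")
        out.append(DoseScenario(
            drug=drugs[name], physiology=physiology[key],
            dose=float(row["dose_mg"]), d50=float(row["d50_um"]),
            scenario="C",
            observed_fa=_opt(row, "observed_fa"),
            observed_aucr=_opt(row, "observed_aucr"),
            pair_id=None if _is_na(pair) else str(pair),
            ref=ref,
        ))
    return out


def _is_na(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v)) or v == ""


def load_fixture_tables(path: str | Path | None = None):
    """Load (drugs, physiology, scenarios) from ``path`` or the packaged data."""
    drugs = load_drugs(path)
    phys = load_physiology(path)
    scenarios = load_scenarios(path, drugs, phys)
    return drugs, phys, scenarios
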