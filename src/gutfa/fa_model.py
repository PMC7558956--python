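"""Compose the gastric and intestinal stages into a total fraction absorbed.

Drug dissolved in the stomach is assumed not to re-precipitate before
absorption, and gastric absorption itself is negligible, so the gastric
contribution is ``Fa_FdST = Fd_ST * (1 - exp(-Pn_SI))`` and

    Fa = Fa_FdST + (1 - Fd_ST) * Fa_SI.

Because intestinal particle growth and precipitation are neglected, the
composed Fa is a possible-maximum estimate; the ARA AUC ratio derived from it
(ratio of Fa with/without an acid-reducing agent, exposure assumed
absorption-proportional) is correspondingly a worst-case DDI estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .acid_base import DomainError
from .config import DEFAULT_CONFIG, ModelConfig
from .gastric import GastricResult, gastric_stage
from .intestinal import IntestinalResult, intestinal_stage
from .parameters_io import DoseScenario

__all__ = ["Prediction", "AucrPrediction", "predict_fa", "predict_aucr"]


@dataclass(frozen=True)
class Prediction:
    scenario: DoseScenario
    gastric: GastricResult
    intestinal: IntestinalResult
    Fd_ST: float
    Fa_FdST: float
    Fa_SI: float
    Fa: float

    @property
    def Fa_FdST_pct(self) -> float:
        """Percent of total Fa attributable to gastric dissolution."""
        return 100.0 * self.Fa_FdST / self.Fa

    @property
    def gastric_limiting(self) -> str:
        return self.gastric.limiting

    @property
    def farls(self) -> str:
        return self.intestinal.farls


def predict_fa(scn: DoseScenario, config: ModelConfig = DEFAULT_CONFIG) -> Prediction:
    """Predict total Fa for one dose scenario (deterministic)."""
    gast = gastric_stage(scn, config)
    intest = intestinal_stage(scn, gast.Fd_ST, config)
    fa_fdst = gast.Fd_ST * (1.0 - math.exp(-intest.Pn_SI))
    fa = fa_fdst + (1.0 - gast.Fd_ST) * intest.Fa_SI
    return Prediction(scenario=scn, gastric=gast, intestinal=intest,
                      Fd_ST=gast.Fd_ST, Fa_FdST=fa_fdst, Fa_SI=intest.Fa_SI,
                      Fa=fa)


@dataclass(frozen=True)
class AucrPrediction:
    pair_id: str | None
    fa_control: float
    fa_ara: float

    @property
    def aucr(self) -> float:
        return self.fa_ara / self.fa_control


def predict_aucr(control: DoseScenario, ara: DoseScenario,
                 config: ModelConfig = DEFAULT_CONFIG) -> AucrPrediction:
    """AUC ratio with/without an acid-reducing agent, from scenario-C Fa."""
    if control.physiology.ara or not ara.physiology.ara:
        raise DomainError("expected (control, ara) = (ara=False, ara=True)")
    same = (control.drug.name == ara.drug.name
            and control.dose == ara.dose and control.d50 == ara.d50
            and control.physiology.species == ara.physiology.species
            and control.physiology.state == ara.physiology.state)
    if not same:
        raise DomainError("control and ARA scenarios do not match")
    fa_c = predict_fa(control.with_scenario("C"), config).Fa
    fa_a = predict_fa(ara.with_scenario("C"), config).Fa
    return AucrPrediction(pair_id=control.pair_id, fa_control=fa_c, fa_ara=fa_a)
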