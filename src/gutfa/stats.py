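"""Fold-error validation metrics over prediction/observation pairs.

Fold errors live in log space: the absolute average fold error
``AAFE = 10 ** mean(|log10(pred/obs)|)`` measures spread (>= 1), the average
fold error ``AFE = 10 ** mean(log10(pred/obs))`` measures bias (AFE < 1 means
a trend to underpredict).  The percentage within twofold uses a closed bound
(a pair at exactly 2.0-fold counts as within).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["StatsReport", "aafe", "afe", "fold_error_metrics", "stats_report"]


def _validated_logratios(pred: Sequence[float], obs: Sequence[float]) -> np.ndarray:
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    if p.shape != o.shape or p.ndim != 1 or p.size < 1:
        raise ValueError("pred and obs must be equal-length 1-D sequences")
    if np.any(p <= 0) or np.any(o <= 0) or not (np.all(np.isfinite(p)) and np.all(np.isfinite(o))):
        raise ValueError("all predicted and observed values must be finite and > 0")
    return np.log10(p / o)


def aafe(pred: Sequence[float], obs: Sequence[float]) -> float:
    """Absolute average fold error, 10^mean(|log10(pred/obs)|)."""
    return float(10.0 ** np.mean(np.abs(_validated_logratios(pred, obs))))


def afe(pred: Sequence[float], obs: Sequence[float]) -> float:
    """Average (signed) fold error, 10^mean(log10(pred/obs))."""
    return float(10.0 ** np.mean(_validated_logratios(pred, obs)))


def fold_error_metrics(pred: Sequence[float], obs: Sequence[float]
                       ) -> tuple[float, float]:
    """(% of pairs within twofold, squared Pearson r of the log10 values).

    r^2 on log10(pred) vs log10(obs); for a degenerate (constant) vector a
    perfect prediction reports 1.0 and any other constant case nan.
    """
    lr = _validated_logratios(pred, obs)
    pct = float(100.0 * np.mean(np.abs(lr) <= math.log10(2.0) + 1e-12))
    lp = np.log10(np.asarray(pred, dtype=float))
    lo = np.log10(np.asarray(obs, dtype=float))
    if np.ptp(lp) == 0.0 or np.ptp(lo) == 0.0:
        r2 = 1.0 if np.allclose(lp, lo) else float("nan")
    else:
        r2 = float(np.corrcoef(lp, lo)[0, 1] ** 2)
    return pct, r2


def r2_identity_log(pred: Sequence[float], obs: Sequence[float]) -> float:
    """Alternative r^2: 1 - SSE/SST of log10 values about the identity line."""
    lr = _validated_logratios(pred, obs)
    lo = np.log10(np.asarray(obs, dtype=float))
    sst = float(np.sum((lo - lo.mean()) ** 2))
    if sst == 0.0:
        return 1.0 if float(np.sum(lr ** 2)) == 0.0 else float("nan")
    return 1.0 - float(np.sum(lr ** 2)) / sst


@dataclass(frozen=True)
class StatsReport:
    n: int
    aafe: float
    afe: float
    r2: float               # squared Pearson correlation of log10 values
    r2_identity: float      # 1 - SSE/SST variant, reported side by side
    pct_within_2fold: float
    subset_label: str = "all"

    def __post_init__(self):
        assert self.aafe >= max(self.afe, 1.0 / self.afe) - 1e-12

    def as_dict(self) -> dict:
        return {"subset": self.subset_label, "n": self.n, "aafe": self.aafe,
                "afe": self.afe, "r2": self.r2, "r2_identity": self.r2_identity,
                "pct_within_2fold": self.pct_within_2fold}


def stats_report(pred: Sequence[float], obs: Sequence[float],
                 subset_label: str = "all") -> StatsReport:
    """Bundle AAFE/AFE/r^2/%-within-twofold for one prediction set."""
    pct, r2 = fold_error_metrics(pred, obs)
    return StatsReport(n=len(list(pred)), aafe=aafe(pred, obs), afe=afe(pred, obs),
                       r2=r2, r2_identity=r2_identity_log(pred, obs),
                       pct_within_2fold=pct, subset_label=subset_label)
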