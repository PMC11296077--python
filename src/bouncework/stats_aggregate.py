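"""Stride aggregation and Pearson-correlation analysis.

Per-step and per-limb quantities are averaged first across the right and
left steps of each stride, then across strides, yielding one row per
subject × condition.  Associations between the spring-actuator quantities
(k, c, Δ_area) and the soft-tissue work are quantified by Pearson's r with
95% confidence intervals from the Fisher z-transform,
z = atanh(r) ± 1.96/√(n−3), and two-sided p-values from the t-distribution
with n−2 degrees of freedom.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError

#: Work columns carried per limb, averaged R/L within each stride.
_LIMB_PAIRS = {
    "W_int+": ("W_int_R+", "W_int_L+"),
    "W_int-": ("W_int_R-", "W_int_L-"),
    "W_j+": ("W_j_R+", "W_j_L+"),
    "W_j-": ("W_j_R-", "W_j_L-"),
}
_STRIDE_COLS = ("W_com+", "W_com-", "W_int_trunk+", "W_int_trunk-",
                "W_tot+", "W_tot-", "W_ST+", "W_ST-")
_SPRING_COLS = ("cst", "k", "c", "rmse", "r_squared", "delta_area")


@dataclass
class ConditionSummary:
    """Stride-averaged quantities for one subject × condition cell."""

    subject_id: str
    speed_kmh: float
    step_frequency: float
    n_strides: int
    values: Dict[str, float]

    def to_row(self) -> Dict[str, float]:
        row = {"subject_id": self.subject_id, "speed_kmh": self.speed_kmh,
               "step_frequency": self.step_frequency,
               "n_strides": self.n_strides}
        row.update(self.values)
        return row


def aggregate(work: pd.DataFrame, springs: Optional[pd.DataFrame],
              subject_id: str = "?", speed_kmh: float = float("nan"),
              step_frequency: float = float("nan")) -> ConditionSummary:
    """Average a trial's per-stride work table and per-step spring table.

    ``work`` is the per-stride breakdown (one row per stride, per-limb
    columns suffixed _R/_L); ``springs`` has one row per step with at least
    ``stride_id`` plus the fit columns.  Limb/step values are averaged
    within each stride first, then across strides, so the result is
    invariant to left/right ordering.
    """
    if len(work) == 0:
        raise ParameterError("empty condition: no strides to aggregate")
    values: Dict[str, float] = {}
    for out, (cr, cl) in _LIMB_PAIRS.items():
        values[out] = float(0.5 * (work[cr] + work[cl]).mean())
    for c in _STRIDE_COLS:
        values[c] = float(work[c].mean())
    values["W_ST_total"] = abs(values["W_ST+"]) + abs(values["W_ST-"])
    if springs is not None and len(springs):
        per_stride = springs.groupby("stride_id")[list(_SPRING_COLS)].mean()
        for c in _SPRING_COLS:
            values[c] = float(per_stride[c].mean())
    return ConditionSummary(subject_id=subject_id, speed_kmh=speed_kmh,
                            step_frequency=step_frequency,
                            n_strides=len(work), values=values)


@dataclass
class CorrelationResult:
    """Pearson r with Fisher-z 95% CI and two-sided p-value."""

    r: float
    df: int
    ci95: Tuple[float, float]
    p: float

    @property
    def n(self) -> int:
        return self.df + 2

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (f"r({self.df}) = {self.r:.2f} "
                f"(95% CI [{self.ci95[0]:.2f}, {self.ci95[1]:.2f}]); "
                f"p = {self.p:.3g}")


def fisher_ci(r: float, n: int, conf: float = 0.95) -> Tuple[float, float]:
    """Fisher z-transform CI for a correlation coefficient.

    z = atanh(r), half-width 1.96/√(n−3) at 95%, back-transformed by tanh.
    Degenerates to [r, r] (with a warning) when |r| = 1.
    """
    if n < 4:
        raise ParameterError("need n >= 4 for a Fisher interval")
    if abs(r) >= 1.0:
        warnings.warn("|r| = 1: confidence interval degenerates",
                      stacklevel=2)
        return (r, r)
    crit = 1.96 if conf == 0.95 else sps.norm.ppf(0.5 + conf / 2.0)
    z = math.atanh(r)
    hw = crit / math.sqrt(n - 3)
    return (math.tanh(z - hw), math.tanh(z + hw))


def pearson_p(r: float, n: int) -> float:
    """Two-sided p for H0: rho = 0, from t with n−2 df."""
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return 2.0 * sps.t.sf(abs(t), n - 2)


def pearson_ci(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation with Fisher-z 95% CI."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 4:
        raise ParameterError("need equal-length samples with n >= 4")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ParameterError("undefined correlation: zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    n = x.size
    return CorrelationResult(r=r, df=n - 2, ci95=fisher_ci(r, n),
                             p=pearson_p(r, n))


#: The correlation pairs of interest: Δ_area against total soft-tissue
#: work (|W_ST+| + |W_ST−|), the actuator coefficient and the stiffness.
DEFAULT_PAIRS = (("delta_area", "W_ST_total"),
                 ("delta_area", "c"),
                 ("delta_area", "k"))


def correlation_table(summaries: pd.DataFrame,
                      pairs: Sequence[Tuple[str, str]] = DEFAULT_PAIRS
                      ) -> pd.DataFrame:
    """Pearson correlations over subject × condition rows.

    One row per pair: r, df, ci_low, ci_high, p, n.
    """
    if len(summaries) < 4:
        raise ParameterError("need >= 4 summary rows for correlations")
    rows = []
    for a, b in pairs:
        res = pearson_ci(summaries[a].to_numpy(), summaries[b].to_numpy())
        rows.append({"pair": f"{a}~{b}", "r": res.r, "df": res.df,
                     "ci_low": res.ci95[0], "ci_high": res.ci95[1],
                     "p": res.p, "n": res.n})
    return pd.DataFrame(rows)


def summaries_frame(summaries: List[ConditionSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.to_row() for s in summaries])
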