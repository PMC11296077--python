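"""Spring-mass-actuator model of the bouncing leg.

During contact the leg is described by its length L_leg (COP-to-greater-
trochanter distance), its compression/decompression velocity V_leg = dL/dt,
and the mass-specific ground-reaction force projected along the leg axis.
The model is a linear spring in parallel with an actuator proportional to
the leg-length velocity,

    F_projected = cst + k·L_leg + c·V_leg ,

fitted per step by ordinary least squares; c < 0 means the actuator acts as
a damper absorbing energy.  The hysteresis area Δ_area is the area enclosed
by the force–length loop over the contact (work absorbed in compression
minus work returned in decompression, −∮F dL): zero for any conservative
F(L), positive when net energy is absorbed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .errors import DegenerateFitError, GeometryError, ParameterError
from .segmental_work import clamp_cop
from .trial_io import ForceSeries

COP_FORCE_THRESHOLD_N = 300.0


@dataclass
class LegSeries:
    """Force–length–velocity series of one leg over one contact.

    ``F_projected`` is mass-specific (N/kg); ``valid`` masks frames with
    F_z at or above the COP force threshold.
    """

    time: np.ndarray
    L_leg: np.ndarray
    V_leg: np.ndarray
    F_projected: np.ndarray
    leg_angle: np.ndarray
    valid: np.ndarray
    foot: str = "?"
    mass: float = float("nan")

    def __post_init__(self) -> None:
        if np.any(self.L_leg[self.valid] <= 0):
            raise GeometryError("non-positive leg length on valid frames")

    @property
    def n_valid(self) -> int:
        return int(np.sum(self.valid))


def leg_series(forces: ForceSeries, gt_traj: np.ndarray,
               contact: Tuple[int, int], mass: float, foot: str = "?",
               cop_threshold_n: float = COP_FORCE_THRESHOLD_N) -> LegSeries:
    """Build the leg force–length–velocity series for one contact.

    ``gt_traj`` is the greater-trochanter trajectory (n, 2) on the force
    grid.  The leg axis runs from the (clamped) COP on the belt surface to
    the GT marker; the GRF is projected onto the unit vector of that axis
    and normalized by body mass.  Frames with F_z below the threshold are
    masked out.
    """
    if mass <= 0:
        raise ParameterError("mass must be > 0")
    a, b = contact
    if np.any(np.isnan(gt_traj[a:b])):
        raise GeometryError("GT marker gap inside contact")
    cop_y, _ = clamp_cop(forces, [contact])
    t = forces.time[a:b]
    gt = gt_traj[a:b]
    leg = gt - np.column_stack([cop_y[a:b], np.zeros(b - a)])
    L = np.hypot(leg[:, 0], leg[:, 1])
    u = leg / L[:, None]
    F_proj = (forces.F_y[a:b] * u[:, 0] + forces.F_z[a:b] * u[:, 1]) / mass
    dt = float(np.mean(np.diff(t))) if t.size > 1 else 1.0
    V = np.gradient(L, dt) if t.size > 2 else np.zeros_like(L)
    angle = np.arctan2(leg[:, 0], leg[:, 1])  # from vertical, rad
    valid = forces.F_z[a:b] >= cop_threshold_n
    return LegSeries(time=t, L_leg=L, V_leg=V, F_projected=F_proj,
                     leg_angle=angle, valid=valid, foot=foot, mass=mass)


def compression_split(leg: LegSeries) -> Optional[Tuple[slice, slice]]:
    """Split the valid span at the global minimum of L_leg.

    Compression runs from touchdown to the minimum leg length,
    decompression from the minimum to the end; ties break to the earliest
    index.  A monotone L_leg (minimum at an edge: no rebound) is a
    degenerate contact — a warning is issued and ``None`` returned, and the
    contact is excluded from Δ_area.
    """
    idx = np.flatnonzero(leg.valid)
    if idx.size < 5:
        warnings.warn("contact has < 5 valid frames", stacklevel=2)
        return None
    lo, hi = idx[0], idx[-1] + 1
    i_min = lo + int(np.argmin(leg.L_leg[lo:hi]))
    if i_min == lo or i_min == hi - 1:
        warnings.warn("monotone leg length (no rebound): degenerate contact",
                      stacklevel=2)
        return None
    return slice(lo, i_min + 1), slice(i_min, hi)


def hysteresis_area(leg: LegSeries, literal: bool = False) -> float:
    """Δ_area of the force–length loop over one contact, J/kg.

    Default: the hysteresis loop area, absorbed-minus-returned work
    = −∮F dL by trapezoidal path integration — zero for a pure spring on a
    closed loop, positive for a damper.  The loop is closed with a straight
    chord from the last valid point back to the first, so a conservative
    F(L) integrates to exactly zero even when touchdown and toe-off leg
    lengths differ slightly (an endpoint-gap warning is attached when the
    mismatch exceeds 10% of the compression depth).  With ``literal=True``
    the signed two-branch integral (decompression minus compression,
    signed dL) is returned instead, for auditing.
    """
    split = compression_split(leg)
    if split is None:
        return float("nan")
    comp, decomp = split
    L = leg.L_leg
    F = leg.F_projected
    lo, hi = comp.start, decomp.stop
    depth = L[comp.start] - L[comp.stop - 1]
    gap = abs(L[hi - 1] - L[lo])
    if depth > 0 and gap > 0.10 * depth:
        warnings.warn(f"open force-length loop: endpoint gap {gap:.4f} m "
                      f"vs compression depth {depth:.4f} m", stacklevel=2)
    if literal:
        return float(np.trapezoid(F[decomp], L[decomp])
                     - np.trapezoid(F[comp], L[comp]))
    L_loop = np.append(L[lo:hi], L[lo])
    F_loop = np.append(F[lo:hi], F[lo])
    return float(-np.trapezoid(F_loop, L_loop))


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

_PARAM_NAMES = ("cst", "k", "c")


class SpringMassActuator:
    """Spring-with-parallel-actuator model of the leg, fitted by OLS.

    Parameters
    ----------
    F : array
        Mass-specific projected force, N/kg (the response).
    L : array
        Leg length, m.
    V : array
        Leg-length velocity, m/s.

    ``fit()`` regresses F on [1, L, V] and returns a
    :class:`SpringActuatorResults`.
    """

    def __init__(self, F: np.ndarray, L: np.ndarray, V: np.ndarray) -> None:
        F = np.asarray(F, float)
        L = np.asarray(L, float)
        V = np.asarray(V, float)
        if not (F.shape == L.shape == V.shape) or F.ndim != 1:
            raise ParameterError("F, L, V must be equal-length 1-D arrays")
        if F.size < 10:
            raise DegenerateFitError(f"need >= 10 frames, got {F.size}")
        self.endog = F
        self.exog = np.column_stack([np.ones(F.size), L, V])

    @classmethod
    def from_leg_series(cls, leg: LegSeries) -> "SpringMassActuator":
        m = leg.valid
        obj = cls(leg.F_projected[m], leg.L_leg[m], leg.V_leg[m])
        obj._leg = leg  # kept for Δ_area in fit results
        return obj

    def fit(self) -> "SpringActuatorResults":
        X, y = self.exog, self.endog
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            raise DegenerateFitError(
                f"design matrix rank {rank} < 3 (L and V collinear?)")
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        ssr = float(resid @ resid)
        sst = float(np.sum((y - y.mean()) ** 2))
        nobs, p = X.shape
        sigma2 = ssr / (nobs - p) if nobs > p else float("nan")
        cov = sigma2 * np.linalg.inv(X.T @ X)
        leg = getattr(self, "_leg", None)
        delta_area = hysteresis_area(leg) if leg is not None else float("nan")
        return SpringActuatorResults(
            model=self, params=beta, bse=np.sqrt(np.diag(cov)),
            resid=resid, rmse=float(np.sqrt(np.mean(resid ** 2))),
            rsquared=1.0 - ssr / sst if sst > 0 else float("nan"),
            nobs=nobs, delta_area=delta_area)


@dataclass
class SpringActuatorResults:
    """OLS estimates of (cst, k, c) with diagnostics.

    ``params`` is ordered (cst, k, c): intercept N/kg, leg stiffness
    N·kg⁻¹·m⁻¹, actuator coefficient N·s·kg⁻¹·m⁻¹ (negative = damper).
    """

    model: SpringMassActuator
    params: np.ndarray
    bse: np.ndarray
    resid: np.ndarray
    rmse: float
    rsquared: float
    nobs: int
    delta_area: float

    @property
    def cst(self) -> float:
        return float(self.params[0])

    @property
    def k(self) -> float:
        return float(self.params[1])

    @property
    def c(self) -> float:
        return float(self.params[2])

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.model.exog @ self.params

    def predict(self, L: np.ndarray, V: np.ndarray) -> np.ndarray:
        return self.cst + self.k * np.asarray(L) + self.c * np.asarray(V)

    def summary(self) -> str:
        lines = ["Spring-mass-actuator fit (OLS)",
                 "=" * 46,
                 f"{'n frames':<18}{self.nobs:>10d}",
                 f"{'R-squared':<18}{self.rsquared:>10.4f}",
                 f"{'RMSE (N/kg)':<18}{self.rmse:>10.4f}",
                 f"{'Δ_area (J/kg)':<18}{self.delta_area:>10.4f}",
                 "-" * 46,
                 f"{'param':<8}{'estimate':>14}{'std err':>14}"]
        units = ("N/kg", "N/kg/m", "N·s/kg/m")
        for name, b, se, u in zip(_PARAM_NAMES, self.params, self.bse, units):
            lines.append(f"{name:<8}{b:>14.4f}{se:>14.4f}  {u}")
        return "\n".join(lines)


@dataclass
class SpringFitResult:
    """Flat per-step record of the fit, as exported to the step table."""

    cst: float
    k: float
    c: float
    rmse: float
    r_squared: float
    delta_area: float
    n_frames: int
    foot: str = "?"


def fit_spring_actuator(leg: LegSeries) -> SpringFitResult:
    """Fit the spring-actuator law to one contact's leg series."""
    res = SpringMassActuator.from_leg_series(leg).fit()
    return SpringFitResult(cst=res.cst, k=res.k, c=res.c, rmse=res.rmse,
                           r_squared=res.rsquared, delta_area=res.delta_area,
                           n_frames=res.nobs, foot=leg.foot)
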