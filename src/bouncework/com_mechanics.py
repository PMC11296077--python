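"""Centre-of-mass mechanics from ground-reaction forces.

The CoM acceleration follows directly from Newton's law applied to the
whole body, a_f = F_y/m and a_v = F_z/m − g.  Velocities and the vertical
displacement are obtained by trapezoidal integration per stride, with the
integration constants chosen so each stride-mean velocity is zero in the
lab (treadmill-machine) frame.  The external energy is

    E_kf = ½ m (v_f − v_belt)²         (fore-aft, belt-relative)
    E_v  = ½ m v_v² + m g S_v          (vertical, kinetic + potential)
    E_com = E_kf + E_v

where v_belt = −V_avg is the belt velocity in the axis convention used
here (y positive in the direction of progression, so the belt surface
moves at −V_avg and the belt-relative CoM speed is v_f + V_avg).  The
belt-relative frame is the overground-equivalent one — the stance foot is
stationary in it — which is what makes the external work commensurable
with the joint work downstream.

and the positive/negative external work per stride is the sum of the
positive/negative sample-to-sample increments of E_com.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import ParameterError, SegmentationError
from .preprocess import StrideSegmentation
from .trial_io import ForceSeries


@dataclass
class ComKinematics:
    """Force-derived CoM state on the force grid, valid on ``span``.

    ``span`` is the [first stride start, last stride end) index range; all
    arrays are full length but only meaningful inside it.  Per stride,
    mean(v_f) = mean(v_v) = 0 (lab frame) and mean(S_v) = 0.
    """

    time: np.ndarray
    a_f: np.ndarray
    a_v: np.ndarray
    v_f: np.ndarray
    v_v: np.ndarray
    S_v: np.ndarray
    strides: List[Tuple[int, int]]

    @property
    def span(self) -> Tuple[int, int]:
        return self.strides[0][0], self.strides[-1][1]


@dataclass
class EnergyCurve:
    """An energy time series with a provenance label."""

    time: np.ndarray
    E: np.ndarray
    label: str


@dataclass
class WorkIncrements:
    """Signed work sums per stride: W_plus >= 0 >= W_minus, in J."""

    W_plus: np.ndarray
    W_minus: np.ndarray

    @property
    def n_strides(self) -> int:
        return self.W_plus.size


def com_acceleration(forces: ForceSeries, mass: float,
                     g: float = 9.81) -> Tuple[np.ndarray, np.ndarray]:
    """a_f = F_y/m, a_v = F_z/m − g (m/s²)."""
    if mass <= 0:
        raise ParameterError("mass must be > 0")
    return forces.F_y / mass, forces.F_z / mass - g


def integrate_com(time: np.ndarray, a_f: np.ndarray, a_v: np.ndarray,
                  strides: Sequence[Tuple[int, int]]) -> ComKinematics:
    """Trapezoidal integration of the CoM accelerations, per stride.

    Integration constants are applied per stride (not per trial) so that
    drift cannot accumulate: within each stride the mean of v_f and v_v is
    zero, and S_v (the integral of v_v) likewise has stride-mean zero.
    Velocity is integrated continuously across the analysed span before the
    per-stride constant is applied, so v and S_v stay continuous inside
    every stride.
    """
    strides = list(strides)
    if not strides:
        raise SegmentationError("no complete stride to integrate over")
    for s0, s1 in strides:
        if s1 - s0 < 3:
            raise SegmentationError(f"stride [{s0}, {s1}) shorter than "
                                    "3 samples")
    time = np.asarray(time, float)
    n = time.size
    v_f = np.full(n, np.nan)
    v_v = np.full(n, np.nan)
    S_v = np.full(n, np.nan)
    lo, hi = strides[0][0], strides[-1][1]
    vf_raw = cumulative_trapezoid(a_f[lo:hi], time[lo:hi], initial=0.0)
    vv_raw = cumulative_trapezoid(a_v[lo:hi], time[lo:hi], initial=0.0)
    for s0, s1 in strides:
        sl = slice(s0 - lo, s1 - lo)
        v_f[s0:s1] = vf_raw[sl] - np.mean(vf_raw[sl])
        v_v[s0:s1] = vv_raw[sl] - np.mean(vv_raw[sl])
        sv = cumulative_trapezoid(v_v[s0:s1], time[s0:s1], initial=0.0)
        S_v[s0:s1] = sv - np.mean(sv)
    return ComKinematics(time=time, a_f=np.asarray(a_f, float),
                         a_v=np.asarray(a_v, float), v_f=v_f, v_v=v_v,
                         S_v=S_v, strides=strides)


def external_energies(kin: ComKinematics, mass: float, g: float,
                      V_avg: float) -> Tuple[EnergyCurve, EnergyCurve,
                                             EnergyCurve]:
    """Closed-form E_kf, E_v and E_com from the integrated CoM state.

    ``V_avg`` is the belt speed magnitude; the belt moves against the
    direction of progression, so the belt-relative fore-aft velocity is
    v_f + V_avg.
    """
    E_kf = 0.5 * mass * (kin.v_f + V_avg) ** 2
    E_v = 0.5 * mass * kin.v_v ** 2 + mass * g * kin.S_v
    E_com = E_kf + E_v
    return (EnergyCurve(kin.time, E_kf, "E_kf"),
            EnergyCurve(kin.time, E_v, "E_v"),
            EnergyCurve(kin.time, E_com, "E_com"))


def work_increments(curve: EnergyCurve,
                    strides: Sequence[Tuple[int, int]]) -> WorkIncrements:
    """Sum of positive / negative sample increments of E per stride.

    No smoothing and no dead-band: W_plus + W_minus telescopes exactly to
    E(end) − E(start) on every stride.
    """
    W_plus = np.empty(len(strides))
    W_minus = np.empty(len(strides))
    for i, (s0, s1) in enumerate(strides):
        dE = np.diff(curve.E[s0:s1])
        if np.any(~np.isfinite(dE)):
            raise ParameterError(f"non-finite energy inside stride {i}")
        W_plus[i] = np.sum(dE[dE > 0])
        W_minus[i] = np.sum(dE[dE < 0])
    return WorkIncrements(W_plus=W_plus, W_minus=W_minus)
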