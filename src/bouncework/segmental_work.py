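"""Internal work, sagittal inverse dynamics and the soft-tissue partition.

Internal energy of a limb is the sum over its segments of
½(m_i V_i'² + I_i ω_i²); segments of the same limb are summed *before*
taking increments, so energy may transfer between ipsilateral segments but
not between limbs.  Joint moments come from bottom-up Newton–Euler in the
sagittal plane (foot → ankle, shank → knee, thigh → hip, hinge joints), and
joint powers of one limb are summed before integrating, allowing
ipsilateral inter-joint transfer.  The partition is then

    W_tot± = W_com± + W_int,R± + W_int,L± + W_int,trunk±
    W_ST±  = W_tot± − W_j,R± − W_j,L±

with the soft-tissue term the residual between the whole-body energy
bookkeeping and the rigid-linkage joint work.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .body_model import SegmentState, segment_relative_velocity
from .com_mechanics import EnergyCurve, WorkIncrements, work_increments
from .errors import AlignmentError
from .trial_io import ForceSeries

JOINTS = ("ankle", "knee", "hip")

#: Physics convention is counterclockwise-positive about the lab x-axis
#: (y forward, z up).  Reported convention: extension-positive for ankle
#: and hip, flexion-positive for knee — all three map to a sign flip in
#: this plane.
_REPORT_SIGN = {"ankle": -1.0, "knee": -1.0, "hip": -1.0}


def _cross2(d: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Out-of-plane (x) component of d × F for (n, 2) arrays of (y, z)."""
    return d[:, 0] * F[:, 1] - d[:, 1] * F[:, 0]


@dataclass
class JointKinetics:
    """Per-side net muscular joint moments, angular velocities and powers.

    Moments in N·m (extension-positive for ankle and hip, flexion-positive
    for knee), ω_j in rad/s in the matching convention, P_j = M_j·ω_j in W
    at every frame by construction.
    """

    side: str
    time: np.ndarray
    M: Dict[str, np.ndarray]
    omega: Dict[str, np.ndarray]
    n_cop_clamped: int = 0

    @property
    def P(self) -> Dict[str, np.ndarray]:
        return {j: self.M[j] * self.omega[j] for j in JOINTS}

    def limb_power(self) -> np.ndarray:
        P = self.P
        return P["ankle"] + P["knee"] + P["hip"]


def internal_energy(segments: Iterable[SegmentState], v_com: np.ndarray,
                    label: str, time: np.ndarray) -> EnergyCurve:
    """E(t) = Σ_segments ½(m_i V_i'² + I_i ω_i²), summed before increments."""
    segments = list(segments)
    E = np.zeros(time.size)
    for seg in segments:
        v_rel = segment_relative_velocity(seg, v_com)
        E = E + 0.5 * (seg.mass * v_rel ** 2 + seg.inertia * seg.omega ** 2)
    return EnergyCurve(time, E, label)


def clamp_cop(forces: ForceSeries,
              contact_intervals: Sequence[Tuple[int, int]]
              ) -> Tuple[np.ndarray, int]:
    """COP with low-load frames inside a contact clamped to the nearest
    valid sample of the same contact.

    Returns (cop, n_clamped).  Outside contacts the COP is irrelevant and
    set to the nearest contact's edge value to keep the array finite.
    """
    cop = forces.cop_y.copy()
    n_clamped = 0
    for a, b in contact_intervals:
        valid = forces.valid_cop[a:b]
        idx = np.flatnonzero(valid)
        if idx.size == 0:
            continue
        sub = cop[a:b]
        bad = np.flatnonzero(~valid)
        if bad.size:
            nearest = idx[np.argmin(np.abs(bad[:, None] - idx[None, :]),
                                    axis=1)]
            sub[bad] = sub[nearest]
            n_clamped += int(bad.size)
        cop[a:b] = sub
    cop[~np.isfinite(cop)] = 0.0
    return cop, n_clamped


def inverse_dynamics_limb(forces: ForceSeries, foot_mask: np.ndarray,
                          contact_intervals: Sequence[Tuple[int, int]],
                          segments: Dict[str, SegmentState], side: str,
                          trunk: SegmentState, g: float = 9.81
                          ) -> JointKinetics:
    """Bottom-up sagittal Newton–Euler for one limb.

    ``foot_mask`` assigns ground-reaction frames to this foot (zero force
    during its swing).  The foot segment receives the GRF at the (clamped)
    COP; the recursion then propagates joint reactions and net muscular
    moments through shank and thigh.
    """
    foot = segments[f"foot_{side}"]
    shank = segments[f"shank_{side}"]
    thigh = segments[f"thigh_{side}"]
    n = forces.time.size
    Fg = np.zeros((n, 2))
    Fg[foot_mask, 0] = forces.F_y[foot_mask]
    Fg[foot_mask, 1] = forces.F_z[foot_mask]
    cop_y, n_clamped = clamp_cop(forces, contact_intervals)
    r_cop = np.column_stack([cop_y, np.zeros(n)])

    def newton_euler(seg: SegmentState, r_dist_joint: np.ndarray,
                     F_dist: np.ndarray, M_dist: np.ndarray,
                     r_prox_joint: np.ndarray):
        """Reaction and net moment at the proximal joint of ``seg`` given
        the loads acting at its distal joint (physics sign convention)."""
        grav = np.zeros((n, 2))
        grav[:, 1] = -seg.mass * g
        F_prox = seg.mass * seg.acc - F_dist - grav
        M_prox = (seg.inertia * seg.alpha - M_dist
                  - _cross2(r_dist_joint - seg.com, F_dist)
                  - _cross2(r_prox_joint - seg.com, F_prox))
        return F_prox, M_prox

    ankle_pt = foot.proximal
    knee_pt = shank.proximal
    hip_pt = thigh.proximal

    # Foot: distal load is the GRF at the COP.
    R_ankle, M_ankle = newton_euler(foot, r_cop, Fg, np.zeros(n), ankle_pt)
    # Shank: distal load is the ankle reaction (reversed).
    R_knee, M_knee = newton_euler(shank, ankle_pt, -R_ankle, -M_ankle,
                                  knee_pt)
    # Thigh: distal load is the knee reaction (reversed).
    _, M_hip = newton_euler(thigh, knee_pt, -R_knee, -M_knee, hip_pt)

    M_phys = {"ankle": M_ankle, "knee": M_knee, "hip": M_hip}
    omega_phys = {"ankle": foot.omega - shank.omega,
                  "knee": shank.omega - thigh.omega,
                  "hip": thigh.omega - trunk.omega}
    M = {j: _REPORT_SIGN[j] * M_phys[j] for j in JOINTS}
    omega = {j: _REPORT_SIGN[j] * omega_phys[j] for j in JOINTS}
    return JointKinetics(side=side, time=forces.time, M=M, omega=omega,
                         n_cop_clamped=n_clamped)


def joint_power_work(kin: JointKinetics,
                     strides: Sequence[Tuple[int, int]]
                     ) -> Tuple[EnergyCurve, WorkIncrements]:
    """Sum joint powers of the limb, integrate, and take increments.

    P_limb = P_ankle + P_knee + P_hip (ipsilateral inter-joint transfer),
    E_j = trapezoidal ∫P_limb dt, then W_j± per stride from the increments
    of E_j.
    """
    P = kin.limb_power()
    E = cumulative_trapezoid(P, kin.time, initial=0.0)
    curve = EnergyCurve(kin.time, E, f"E_j,{kin.side}")
    return curve, work_increments(curve, strides)


@dataclass
class WorkBreakdown:
    """Per-stride signed work partition, J (divide by mass for J/kg).

    The two construction identities hold exactly:
    W_tot± = W_com± + W_int,R± + W_int,L± + W_int,trunk± and
    W_ST± = W_tot± − W_j,R± − W_j,L±.
    """

    mass: float
    W_com: WorkIncrements
    W_int_R: WorkIncrements
    W_int_L: WorkIncrements
    W_int_trunk: WorkIncrements
    W_j_R: WorkIncrements
    W_j_L: WorkIncrements
    W_tot: WorkIncrements = None  # type: ignore[assignment]
    W_ST: WorkIncrements = None   # type: ignore[assignment]

    def __post_init__(self) -> None:
        parts = [self.W_com, self.W_int_R, self.W_int_L, self.W_int_trunk,
                 self.W_j_R, self.W_j_L]
        n = {p.n_strides for p in parts}
        if len(n) != 1:
            raise AlignmentError(f"mismatched stride counts {sorted(n)}")
        tot_p = (self.W_com.W_plus + self.W_int_R.W_plus
                 + self.W_int_L.W_plus + self.W_int_trunk.W_plus)
        tot_m = (self.W_com.W_minus + self.W_int_R.W_minus
                 + self.W_int_L.W_minus + self.W_int_trunk.W_minus)
        self.W_tot = WorkIncrements(tot_p, tot_m)
        self.W_ST = WorkIncrements(
            tot_p - self.W_j_R.W_plus - self.W_j_L.W_plus,
            tot_m - self.W_j_R.W_minus - self.W_j_L.W_minus)

    @property
    def n_strides(self) -> int:
        return self.W_com.n_strides

    def to_frame(self, mass_specific: bool = True) -> pd.DataFrame:
        """Per-stride table; columns in J/kg when ``mass_specific``."""
        scale = 1.0 / self.mass if mass_specific else 1.0
        cols = {"stride_id": np.arange(self.n_strides)}
        for name in ("W_com", "W_int_R", "W_int_L", "W_int_trunk",
                     "W_j_R", "W_j_L", "W_tot", "W_ST"):
            inc: WorkIncrements = getattr(self, name)
            cols[f"{name}+"] = inc.W_plus * scale
            cols[f"{name}-"] = inc.W_minus * scale
        return pd.DataFrame(cols)


def partition_work(mass: float, W_com: WorkIncrements,
                   W_int_R: WorkIncrements, W_int_L: WorkIncrements,
                   W_int_trunk: WorkIncrements, W_j_R: WorkIncrements,
                   W_j_L: WorkIncrements) -> WorkBreakdown:
    """Assemble the total/soft-tissue partition from per-stride increments."""
    return WorkBreakdown(mass=mass, W_com=W_com, W_int_R=W_int_R,
                         W_int_L=W_int_L, W_int_trunk=W_int_trunk,
                         W_j_R=W_j_R, W_j_L=W_j_L)
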