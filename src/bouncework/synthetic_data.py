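"""Synthetic treadmill-running trials with known ground truth.

The generator is kinematics-first and CoM-prescribed, so that in rigid mode
the written ground-reaction force *exactly* equals the rigid-segment total:

1. the GRF is prescribed in closed form — half-sine vertical bursts with
   flight phases (impulse balancing body weight exactly), a braking→
   propulsion fore-aft sine with zero net impulse per contact;
2. the true CoM trajectory is the double time-integral of that force;
3. ankle trajectories follow the belt during stance and a smooth quintic
   swing; the pelvis is solved per frame so the segment-mass-weighted CoM
   equals the prescribed CoM exactly, and the knees follow by two-link
   inverse kinematics;
4. the COP is placed by the whole-body angular-momentum balance, making the
   force/COP/kinematics triplet dynamically consistent;
5. wobble mode adds the reaction of a damped point-mass oscillator riding
   on the trunk (driven by trunk acceleration) to the stance-phase GRF; its
   dissipated energy per stride is ledgered;
6. measurement noise is added last, from a single seeded generator.

This is not a physiologically validated gait model; it reproduces the
structural properties the analysis pipeline assumes (Newton consistency,
alternating flight/contact, ipsilateral energy flow), which is what makes
null tests and recovery tests meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sig
from scipy.integrate import cumulative_trapezoid

from .body_model import WINTER_TABLE
from .errors import InfeasibleParametersError, ParameterError
from .spring_actuator import LegSeries
from .trial_io import (
    ForceSeries,
    MarkerTrajectories,
    RawTrial,
    TrialMeta,
)

FORCE_RATE = 1000.0
MARKER_RATE = 200.0


@dataclass(frozen=True)
class WobbleParams:
    """Damped point-mass oscillator emulating wobbling soft tissue.

    The effective damping coefficient of the trunk-wobble coupling is
    c_w = 2·ζ·ω_n·m_red with m_red the reduced mass.  The default natural
    frequency (4.5 Hz, visceral-mass range) lies in the band excited by the
    loading bursts, giving per-stride dissipation of realistic magnitude;
    the default damping ratio sits on the rising branch of the dissipation-
    vs-damping curve.  Sweeping the mass fraction at fixed ζ sweeps c_w
    with dissipation monotone in it by construction.
    """

    mass_fraction: float = 0.15
    natural_freq_hz: float = 4.5
    damping_ratio: float = 0.25

    def __post_init__(self) -> None:
        if not (0.0 < self.mass_fraction < 0.3):
            raise ParameterError("wobble mass fraction must be in (0, 0.3)")
        if self.natural_freq_hz <= 0 or self.damping_ratio < 0:
            raise ParameterError("wobble frequency/damping out of range")


@dataclass(frozen=True)
class SimulationParams:
    """Trial-generation parameters (SI units).

    Defaults mirror a mid-range study condition: 73.7 kg, 1.84 m subject
    running at 11 km/h and 2.8 steps/s; duty factor 0.65 of the step period
    (flight phases present); instrument-grade noise (0.5 N force,
    0.2 mm markers).
    """

    mass: float = 73.7
    height: float = 1.84
    belt_speed: float = 3.06
    step_frequency: float = 2.8
    duty_factor: float = 0.65
    n_strides: int = 10
    spring: Tuple[float, float, float] = (2.0, 30.0, -5.0)
    wobble: Optional[WobbleParams] = None
    force_noise_sd: float = 0.5     # N
    marker_noise_sd: float = 0.0002  # m
    gravity: float = 9.81
    fore_aft_amplitude_bw: float = 0.20  # fore-aft force amplitude, x BW

    def __post_init__(self) -> None:
        if not (0.0 < self.duty_factor < 1.0):
            raise ParameterError("duty_factor must be in (0, 1)")
        if self.n_strides < 1:
            raise ParameterError("need n_strides >= 1")
        if self.mass <= 0 or self.height <= 0:
            raise ParameterError("mass and height must be > 0")


@dataclass
class GroundTruth:
    """Ledger of the quantities the generator knows exactly.

    ``com``/``v_com`` are (n, 2) (y, z) on the force grid; joint moments are
    in the reported convention (extension-positive ankle/hip, flexion-
    positive knee).  ``wobble_dissipation`` is per analysed stride, J;
    all-zero in rigid mode.
    """

    time: np.ndarray
    com: np.ndarray
    v_com: np.ndarray
    strides: List[Tuple[int, int]]
    contacts: List[Tuple[int, int, str]]
    joint_moments: Dict[str, Dict[str, np.ndarray]] = field(default_factory=dict)
    wobble_dissipation: np.ndarray = field(
        default_factory=lambda: np.zeros(0))
    spring: Optional[Tuple[float, float, float]] = None
    delta_area_per_contact: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# Direct spring-loop harness
# ---------------------------------------------------------------------------

def simulate_spring_loop(params: SimulationParams, seed: int,
                         n_steps: int = 50, L0: float = 1.0,
                         amplitude: float = 0.05,
                         contact_time: float = 0.3,
                         noise_sd: float = 0.0
                         ) -> Tuple[List[LegSeries], GroundTruth]:
    """Generate leg force–length loops from a known spring-actuator law.

    Per contact L(t) = L0 − A(1 − cos ωt) with ω = 2π/contact_time (one
    full compression–decompression cycle), V the exact derivative, and
    F = cst + k·L + c·V plus optional Gaussian noise (N/kg).  The true
    Δ_area of the law, −c∫V² dt, is ledgered per contact by quadrature.
    """
    cst, k, c = params.spring
    if k <= 0:
        raise ParameterError("spring stiffness k must be > 0")
    rng = np.random.default_rng(seed)
    omega = 2.0 * np.pi / contact_time
    n = int(round(contact_time * FORCE_RATE)) + 1
    t = np.arange(n) / FORCE_RATE
    L = L0 - amplitude * (1.0 - np.cos(omega * t))
    V = -amplitude * omega * np.sin(omega * t)
    F_clean = cst + k * L + c * V
    true_area = float(-c * np.trapezoid(V ** 2, t))
    series: List[LegSeries] = []
    for _ in range(n_steps):
        F = F_clean + (rng.normal(0.0, noise_sd, n) if noise_sd > 0 else 0.0)
        series.append(LegSeries(time=t, L_leg=L.copy(), V_leg=V.copy(),
                                F_projected=F, leg_angle=np.zeros(n),
                                valid=np.ones(n, bool), foot="R",
                                mass=params.mass))
    truth = GroundTruth(time=t, com=np.zeros((n, 2)), v_com=np.zeros((n, 2)),
                        strides=[], contacts=[], spring=(cst, k, c),
                        delta_area_per_contact=np.full(n_steps, true_area))
    return series, truth


# ---------------------------------------------------------------------------
# Full-trial generator
# ---------------------------------------------------------------------------

def _quintic_hermite(s: np.ndarray, p0: float, p1: float, v0: float,
                     v1: float) -> np.ndarray:
    """Quintic with endpoint positions/velocities and zero endpoint
    accelerations; ``s`` in [0, 1], velocities already scaled to s-units."""
    h0 = 1 - 10 * s**3 + 15 * s**4 - 6 * s**5
    h1 = s - 6 * s**3 + 8 * s**4 - 3 * s**5
    g1 = -4 * s**3 + 7 * s**4 - 3 * s**5
    g0 = 10 * s**3 - 15 * s**4 + 6 * s**5
    return p0 * h0 + v0 * h1 + p1 * g0 + v1 * g1


class _GaitPlan:
    """Timing and closed-form trajectories shared by the construction."""

    def __init__(self, p: SimulationParams):
        self.p = p
        self.T_step = 1.0 / p.step_frequency
        self.T_stride = 2.0 * self.T_step
        self.t_contact = p.duty_factor * self.T_step
        self.t_swing = self.T_stride - self.t_contact
        self.lead = 0.05
        self.duration = (self.lead + (p.n_strides + 0.5) * self.T_stride
                         + self.t_contact)
        self.td0 = {"R": self.lead, "L": self.lead + self.T_step}
        # generator geometry: slightly long-legged and low-slung so the
        # rigid straight-knee linkage can reach the belt-locked foot at
        # touchdown (real runners gain reach from plantarflexion, which the
        # flat-foot construction omits)
        h = p.height
        self.l_thigh = 0.255 * h
        self.l_shank = 0.255 * h
        self.l_trunk = 0.300 * h
        self.h_ankle = 0.07
        self.h_swing = 0.12
        self.z_com = 0.47 * h
        self.lean = 0.08  # trunk forward lean, rad
        # foot marker offsets from the ankle (flat foot, lab frame)
        self.heel_off = np.array([-0.06, -0.04])
        self.vm_off = np.array([0.12, -0.04])
        self.iim_off = np.array([0.14, -0.04])

    def contact_schedule(self, foot: str) -> List[Tuple[float, float]]:
        tds = []
        td = self.td0[foot] - self.T_stride  # one extra cycle either side
        while td < self.duration + self.T_stride:
            tds.append((td, td + self.t_contact))
            td += self.T_stride
        return tds

    def grf(self, t: np.ndarray) -> Tuple[np.ndarray, np.ndarray,
                                          np.ndarray, np.ndarray]:
        """(F_y, F_z, stance_R, stance_L) on grid t, noise-free, rigid."""
        p = self.p
        Az = np.pi * p.mass * p.gravity / (2.0 * p.duty_factor)
        Ay = p.fore_aft_amplitude_bw * p.mass * p.gravity
        F_y = np.zeros_like(t)
        F_z = np.zeros_like(t)
        stance = {"R": np.zeros_like(t, bool), "L": np.zeros_like(t, bool)}
        for foot in ("R", "L"):
            for td, to in self.contact_schedule(foot):
                m = (t >= td) & (t < to)
                tau = (t[m] - td) / self.t_contact
                F_z[m] += Az * np.sin(np.pi * tau)
                F_y[m] += -Ay * np.sin(2.0 * np.pi * tau)
                stance[foot] |= m
        return F_y, F_z, stance["R"], stance["L"]

    def ankle(self, t: np.ndarray, foot: str) -> np.ndarray:
        """Ankle (y, z) trajectory: belt-locked stance, quintic swing."""
        p = self.p
        V = p.belt_speed
        y_td = +V * self.t_contact / 2.0
        y_to = -V * self.t_contact / 2.0
        tau = np.mod(t - self.td0[foot], self.T_stride)
        y = np.empty_like(t)
        z = np.empty_like(t)
        st = tau < self.t_contact
        y[st] = y_td - V * tau[st]
        z[st] = self.h_ankle
        s = (tau[~st] - self.t_contact) / self.t_swing
        y[~st] = _quintic_hermite(s, y_to, y_td, -V * self.t_swing,
                                  -V * self.t_swing)
        z[~st] = self.h_ankle + self.h_swing * np.sin(np.pi * s) ** 2
        return np.column_stack([y, z])


def _solve_pelvis(plan: _GaitPlan, com: np.ndarray, ankle_R: np.ndarray,
                  ankle_L: np.ndarray, trunk_mass_deficit: float = 0.0
                  ) -> Tuple[np.ndarray, Dict[str, np.ndarray]]:
    """Solve the pelvis so the segment-mass-weighted CoM equals ``com``.

    ``trunk_mass_deficit`` removes a fraction of body mass from the trunk
    (the wobbling mass, which is not part of the rigid linkage); ``com`` is
    then the *rigid-part* CoM and the weighted sum targets (1 − deficit)
    of it.  Returns the pelvis trajectory and the knee positions per side.
    Raises :class:`InfeasibleParametersError` if a leg would overextend.
    """
    tab = WINTER_TABLE
    f_T = tab["trunk"].mass_fraction - trunk_mass_deficit
    c_T = tab["trunk"].com_fraction
    f_th, c_th = tab["thigh"].mass_fraction, tab["thigh"].com_fraction
    f_sh, c_sh = tab["shank"].mass_fraction, tab["shank"].com_fraction
    f_ft = tab["foot"].mass_fraction
    l_t, l_s = plan.l_thigh, plan.l_shank
    reach = l_t + l_s
    trunk_vec = plan.l_trunk * np.array([np.sin(plan.lean),
                                         np.cos(plan.lean)])
    # foot CoM offset from the ankle: com_fraction (0.5) of the way to the
    # distal point mid(heel, VM)
    foot_com_off = tab["foot"].com_fraction * 0.5 * (plan.heel_off
                                                     + plan.vm_off)

    ankles = {"R": ankle_R, "L": ankle_L}
    target = (1.0 - trunk_mass_deficit) * com
    p = com.copy()
    p[:, 1] -= 0.10  # initial guess: pelvis below CoM

    def knee_of(p_arr: np.ndarray, ank: np.ndarray) -> np.ndarray:
        d = ank - p_arr
        D = np.hypot(d[:, 0], d[:, 1])
        Dc = np.minimum(D, 0.9999 * reach)
        a = (l_t**2 - l_s**2 + Dc**2) / (2.0 * Dc)
        h = np.sqrt(np.maximum(l_t**2 - a**2, 0.0))
        u = d / Dc[:, None]
        n_hat = np.column_stack([-u[:, 1], u[:, 0]])  # anterior normal
        return p_arr + a[:, None] * u + h[:, None] * n_hat, D

    for _ in range(80):
        S = f_T * (p + c_T * trunk_vec)
        knees = {}
        max_D = 0.0
        for side, ank in ankles.items():
            knee, D = knee_of(p, ank)
            max_D = max(max_D, float(np.max(D)))
            knees[side] = knee
            S = S + f_th * (p + c_th * (knee - p))
            S = S + f_sh * (knee + c_sh * (ank - knee))
            S = S + f_ft * (ank + foot_com_off)
        resid = target - S
        p = p + resid / 0.85
        if np.max(np.abs(resid)) < 1e-12:
            break
    if max_D > 0.999 * reach:
        raise InfeasibleParametersError(
            f"leg overextension: hip-ankle distance {max_D:.3f} m vs leg "
            f"length {reach:.3f} m — reduce belt_speed or duty_factor, or "
            "raise step_frequency")
    if np.max(np.abs(resid)) > 1e-9:
        raise InfeasibleParametersError(
            "pelvis solve did not converge (residual "
            f"{np.max(np.abs(resid)):.2e} m)")
    return p, knees


def _segment_states_internal(plan: _GaitPlan, t: np.ndarray,
                             pelvis: np.ndarray,
                             knees: Dict[str, np.ndarray],
                             ankles: Dict[str, np.ndarray],
                             trunk_mass_deficit: float = 0.0):
    """(com, acc, I, alpha, mass) per segment for the balance equations."""
    p = plan.p
    tab = WINTER_TABLE
    dt = float(t[1] - t[0])
    trunk_vec = plan.l_trunk * np.array([np.sin(plan.lean),
                                         np.cos(plan.lean)])
    segs = []

    def add(name, prox, dist, frac, mass_fraction=None):
        com = prox + frac.com_fraction * (dist - prox)
        acc = np.gradient(np.gradient(com, dt, axis=0), dt, axis=0)
        vec = dist - prox
        length = float(np.mean(np.hypot(vec[:, 0], vec[:, 1])))
        angle = np.unwrap(np.arctan2(vec[:, 1], vec[:, 0]))
        alpha = np.gradient(np.gradient(angle, dt), dt)
        mass = (mass_fraction if mass_fraction is not None
                else frac.mass_fraction) * p.mass
        inertia = mass * (frac.gyration_fraction * length) ** 2
        segs.append({"name": name, "com": com, "acc": acc, "mass": mass,
                     "I": inertia, "alpha": alpha})

    add("trunk", pelvis, pelvis + trunk_vec, tab["trunk"],
        mass_fraction=tab["trunk"].mass_fraction - trunk_mass_deficit)
    for side in ("R", "L"):
        ank = ankles[side]
        foot_dist = ank + 0.5 * (plan.heel_off + plan.vm_off)
        add(f"thigh_{side}", pelvis, knees[side], tab["thigh"])
        add(f"shank_{side}", knees[side], ank, tab["shank"])
        add(f"foot_{side}", ank, foot_dist, tab["foot"])
    return segs


def _cop_from_balance(segs, F_y: np.ndarray, F_z: np.ndarray,
                      g: float) -> np.ndarray:
    """COP_y from the whole-body angular-momentum balance about the origin;
    valid where F_z is large, NaN elsewhere."""
    num = np.zeros_like(F_z)
    for s in segs:
        y, z = s["com"][:, 0], s["com"][:, 1]
        ay, az = s["acc"][:, 0], s["acc"][:, 1]
        num += s["mass"] * (y * az - z * ay) + s["I"] * s["alpha"]
        num += s["mass"] * g * y
    with np.errstate(divide="ignore", invalid="ignore"):
        cop = num / F_z
    cop[F_z < 300.0] = np.nan
    return cop


def _fill_cop(cop: np.ndarray) -> np.ndarray:
    """Hold-nearest fill of NaN COP samples so the written column is finite."""
    out = cop.copy()
    good = np.flatnonzero(np.isfinite(out))
    if good.size == 0:
        return np.zeros_like(out)
    bad = np.flatnonzero(~np.isfinite(out))
    nearest = good[np.searchsorted(good, bad).clip(0, good.size - 1)]
    left = good[(np.searchsorted(good, bad) - 1).clip(0, good.size - 1)]
    pick = np.where(np.abs(bad - left) <= np.abs(nearest - bad), left, nearest)
    out[bad] = out[pick]
    return out


def _joint_moments_dalembert(plan: _GaitPlan, segs, joints: Dict[str, np.ndarray],
                             stance: Dict[str, np.ndarray],
                             F_y: np.ndarray, F_z: np.ndarray,
                             cop: np.ndarray, g: float
                             ) -> Dict[str, Dict[str, np.ndarray]]:
    """Ledger joint moments by the d'Alembert sum over distal segments.

    Independent formulation from the package's recursive Newton–Euler:
    M_j = Σ_{i distal} [I_i·α_i + (r_i − r_j) × m_i(a_i − g_vec)]
          − (r_cop − r_j) × F_grf,
    evaluated in the physics (counterclockwise-positive) convention and
    then flipped to the reported convention.
    """
    by_name = {s["name"]: s for s in segs}
    out: Dict[str, Dict[str, np.ndarray]] = {}
    for side in ("R", "L"):
        Fg = np.zeros((F_y.size, 2))
        Fg[stance[side], 0] = F_y[stance[side]]
        Fg[stance[side], 1] = F_z[stance[side]]
        r_cop = np.column_stack([cop, np.zeros_like(cop)])
        distal_sets = {"ankle": [f"foot_{side}"],
                       "knee": [f"foot_{side}", f"shank_{side}"],
                       "hip": [f"foot_{side}", f"shank_{side}",
                               f"thigh_{side}"]}
        out[side] = {}
        for joint, names in distal_sets.items():
            r_j = joints[f"{joint}_{side}"]
            M = np.zeros(F_y.size)
            for nm in names:
                s = by_name[nm]
                rel = s["com"] - r_j
                a_eff_y = s["acc"][:, 0]
                a_eff_z = s["acc"][:, 1] + g
                M += s["I"] * s["alpha"] + s["mass"] * (
                    rel[:, 0] * a_eff_z - rel[:, 1] * a_eff_y)
            d = r_cop - r_j
            M -= d[:, 0] * Fg[:, 1] - d[:, 1] * Fg[:, 0]
            out[side][joint] = -M  # reported convention
    return out


def simulate_trial(params: SimulationParams, seed: int
                   ) -> Tuple[RawTrial, GroundTruth]:
    """Generate one synthetic treadmill trial plus its ground-truth ledger.

    Rigid mode (``params.wobble is None``) is exactly Newton-consistent;
    wobble mode injects a known soft-tissue-like dissipation.
    """
    plan = _GaitPlan(params)
    rng = np.random.default_rng(seed)
    g = params.gravity
    M = params.mass
    n = int(round(plan.duration * FORCE_RATE)) + 1
    t = np.arange(n) / FORCE_RATE

    F_y, F_z, stR, stL = plan.grf(t)

    # --- true CoM from the rigid force ------------------------------------
    a_f = F_y / M
    a_v = F_z / M - g
    v_f = cumulative_trapezoid(a_f, t, initial=0.0)
    v_v = cumulative_trapezoid(a_v, t, initial=0.0)

    # analysed span: the n_strides right-to-right strides of the plan
    tds_R = [plan.td0["R"] + k * plan.T_stride
             for k in range(params.n_strides + 1)]
    stride_bounds = [(int(round(tds_R[i] * FORCE_RATE)),
                      int(round(tds_R[i + 1] * FORCE_RATE)))
                     for i in range(params.n_strides)]
    lo, hi = stride_bounds[0][0], stride_bounds[-1][1]
    v_f -= np.mean(v_f[lo:hi])
    v_v -= np.mean(v_v[lo:hi])
    y_com = cumulative_trapezoid(v_f, t, initial=0.0)
    z_com = cumulative_trapezoid(v_v, t, initial=0.0)
    y_com -= np.mean(y_com[lo:hi])
    z_com += plan.z_com - np.mean(z_com[lo:hi])
    com = np.column_stack([y_com, z_com])

    # --- wobble: two-mass vertical split of the prescribed force ----------
    # The wobbling mass m_w is carved out of the trunk and coupled to the
    # rigid remainder m_r by a spring-damper.  The *measured* GRF stays the
    # prescribed one (the plate reads the total), the total CoM stays its
    # double integral, and the rigid part recoils: with x the relative
    # vertical coordinate about equilibrium,
    #     ẍ = −ω_n² x − 2ζ ω_n ẋ − F_z/m_r            (m_red = m_w·m_r/M)
    # and the rigid CoM acceleration is (F_z + k x + c ẋ)/m_r − g.  Energy
    # dissipated by the damper, c·ẋ², is the ledgered soft-tissue work.
    mu = params.wobble.mass_fraction if params.wobble is not None else 0.0
    wobble_diss_rate = np.zeros(n)
    wobble_z = None
    if params.wobble is not None:
        w = params.wobble
        m_w = mu * M
        m_r = M - m_w
        m_red = m_w * m_r / M
        wn = 2.0 * np.pi * w.natural_freq_hz
        k_w = m_red * wn ** 2
        c_w = 2.0 * w.damping_ratio * wn * m_red
        A = np.array([[0.0, 1.0],
                      [-wn ** 2, -2.0 * w.damping_ratio * wn]])
        B = np.array([[0.0], [1.0]])
        ss = sig.StateSpace(A, B, np.eye(2), np.zeros((2, 1)))
        _, x_state, _ = sig.lsim(ss, -F_z / m_r, t)
        x, xdot = x_state[:, 0], x_state[:, 1]
        wobble_diss_rate = c_w * xdot ** 2
        a_rz = (F_z + k_w * x + c_w * xdot) / m_r - g
        v_rz = cumulative_trapezoid(a_rz, t, initial=0.0)
        v_rz -= np.mean(v_rz[lo:hi])
        z_r = cumulative_trapezoid(v_rz, t, initial=0.0)
        z_r += plan.z_com - np.mean(z_r[lo:hi])
        com_rigid = np.column_stack([y_com, z_r])
        wobble_z = z_r + x  # attachment-relative constant dropped
    else:
        com_rigid = com

    # --- kinematics --------------------------------------------------------
    ankles = {"R": plan.ankle(t, "R"), "L": plan.ankle(t, "L")}
    pelvis, knees = _solve_pelvis(plan, com_rigid, ankles["R"], ankles["L"],
                                  trunk_mass_deficit=mu)
    segs = _segment_states_internal(plan, t, pelvis, knees, ankles,
                                    trunk_mass_deficit=mu)

    # --- COP and ledger moments -------------------------------------------
    balance_segs = list(segs)
    if wobble_z is not None:
        dt_f = t[1] - t[0]
        w_com = np.column_stack([com_rigid[:, 0], wobble_z])
        w_acc = np.gradient(np.gradient(w_com, dt_f, axis=0), dt_f, axis=0)
        balance_segs.append({"name": "wobble", "com": w_com, "acc": w_acc,
                             "mass": mu * M, "I": 0.0,
                             "alpha": np.zeros(n)})
    cop_raw = _cop_from_balance(balance_segs, F_y, F_z, g)
    cop = _fill_cop(cop_raw)
    joints = {f"ankle_{s}": ankles[s] for s in ("R", "L")}
    joints.update({f"knee_{s}": knees[s] for s in ("R", "L")})
    joints.update({f"hip_{s}": pelvis for s in ("R", "L")})
    moments = _joint_moments_dalembert(plan, segs, joints,
                                       {"R": stR, "L": stL},
                                       F_y, F_z, cop, g)

    # --- containers with noise --------------------------------------------
    F_y_out = F_y + rng.normal(0.0, params.force_noise_sd, n)
    F_z_out = np.maximum(F_z + rng.normal(0.0, params.force_noise_sd, n), 0.0)
    forces = ForceSeries(t, F_y_out, F_z_out, cop).with_cop_mask(300.0)

    step = int(round(FORCE_RATE / MARKER_RATE))
    mt = t[::step]
    trunk_vec = plan.l_trunk * np.array([np.sin(plan.lean),
                                         np.cos(plan.lean)])
    mk: Dict[str, np.ndarray] = {}
    pel = pelvis[::step]
    neck = pel + trunk_vec
    mk["waist"] = pel + np.array([0.08, 0.0])
    mk["backwaist"] = pel + np.array([-0.08, 0.0])
    mk["neck"] = neck
    mk["chest"] = pel + 0.7 * (neck - pel) + np.array([0.05, 0.0])
    for side in ("R", "L"):
        ank = ankles[side][::step]
        mk[f"GT_{side}"] = pel.copy()
        mk[f"knee_{side}"] = knees[side][::step]
        mk[f"ankle_{side}"] = ank
        mk[f"heel_{side}"] = ank + plan.heel_off
        mk[f"VM_{side}"] = ank + plan.vm_off
        mk[f"IIM_{side}"] = ank + plan.iim_off
        mk[f"thigh_{side}"] = 0.5 * (pel + knees[side][::step]) \
            + np.array([0.03, 0.0])
        mk[f"shank_{side}"] = 0.5 * (knees[side][::step] + ank) \
            + np.array([0.03, 0.0])
    if params.marker_noise_sd > 0:
        for name in mk:
            mk[name] = mk[name] + rng.normal(0.0, params.marker_noise_sd,
                                             mk[name].shape)
    markers = MarkerTrajectories(mt, mk)
    meta = TrialMeta(subject_id="synthetic", mass=M, height=params.height,
                     belt_speed=params.belt_speed,
                     target_step_frequency=params.step_frequency,
                     force_rate=FORCE_RATE, marker_rate=MARKER_RATE,
                     gravity=g)
    trial = RawTrial(meta=meta, forces=forces, markers=markers)

    contacts: List[Tuple[int, int, str]] = []
    for foot in ("R", "L"):
        for td, to in plan.contact_schedule(foot):
            a = int(round(td * FORCE_RATE))
            b = int(round(to * FORCE_RATE))
            if 0 <= a and b <= n:
                contacts.append((a, b, foot))
    contacts.sort()

    diss = np.array([np.trapezoid(wobble_diss_rate[a:b], t[a:b])
                     for a, b in stride_bounds])
    truth = GroundTruth(time=t, com=com,
                        v_com=np.column_stack([v_f, v_v]),
                        strides=stride_bounds, contacts=contacts,
                        joint_moments=moments, wobble_dissipation=diss)
    return trial, truth


def sweep(param_sets: Iterable[SimulationParams], seed: int
          ) -> Tuple[List[Tuple[RawTrial, GroundTruth]], pd.DataFrame]:
    """One trial per parameter set, with a ledger table.

    Trial i uses seed ``seed + i`` (deterministic: same inputs give
    bit-identical outputs).
    """
    param_sets = list(param_sets)
    if not param_sets:
        raise ParameterError("empty parameter grid")
    trials = []
    rows = []
    for i, p in enumerate(param_sets):
        trial, truth = simulate_trial(p, seed + i)
        trials.append((trial, truth))
        w = p.wobble
        if w:
            m_w = w.mass_fraction * p.mass
            m_red = m_w * (p.mass - m_w) / p.mass
            c_w = (2.0 * w.damping_ratio * 2.0 * np.pi
                   * w.natural_freq_hz * m_red)
        else:
            c_w = 0.0
        rows.append({
            "trial": i, "speed": p.belt_speed,
            "step_frequency": p.step_frequency,
            "duty_factor": p.duty_factor,
            "wobble_c": c_w,
            "wobble_zeta": w.damping_ratio if w else 0.0,
            "dissipation_per_stride":
                float(np.mean(truth.wobble_dissipation))
                if truth.wobble_dissipation.size else 0.0,
        })
    return trials, pd.DataFrame(rows)


def write_truth(truth: GroundTruth, path) -> None:
    """Write the per-stride ledger as TSV (stride bounds + dissipation)."""
    rows = []
    for i, (a, b) in enumerate(truth.strides):
        rows.append({"stride_id": i,
                     "t_start": truth.time[a],
                     "t_end": truth.time[b - 1],
                     "wobble_dissipation_J":
                         truth.wobble_dissipation[i]
                         if truth.wobble_dissipation.size else 0.0})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
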