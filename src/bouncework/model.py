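"""Whole-trial analysis: model object in, results object out.

:class:`RunningWorkPartition` wires the full pipeline together — filtering,
gait segmentation, CoM mechanics, segmental internal work, inverse-dynamics
joint work, the soft-tissue residual, and the per-step spring-mass-actuator
fits — and its :meth:`~RunningWorkPartition.fit` returns a
:class:`WorkPartitionResults` carrying the per-stride work breakdown, the
per-step spring fits, the energy curves, and a text ``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from . import body_model, com_mechanics, preprocess, segmental_work
from .errors import DegenerateFitError, SegmentationError
from .spring_actuator import fit_spring_actuator, hysteresis_area, leg_series
from .stats_aggregate import ConditionSummary, aggregate
from .trial_io import AnalysisConfig, ForceSeries, MarkerTrajectories, RawTrial


class RunningWorkPartition:
    """Mechanical work partition of one treadmill-running trial.

    Parameters
    ----------
    trial : RawTrial
        Forces, markers and metadata (see :mod:`bouncework.trial_io`).
    config : AnalysisConfig, optional
        Filtering cutoffs, thresholds and switches; defaults follow the
        standard processing conventions.
    """

    def __init__(self, trial: RawTrial,
                 config: Optional[AnalysisConfig] = None) -> None:
        self.trial = trial
        self.config = config or AnalysisConfig()

    @classmethod
    def from_files(cls, force_path, marker_path, meta_path,
                   config: Optional[AnalysisConfig] = None
                   ) -> "RunningWorkPartition":
        from .trial_io import read_trial
        return cls(read_trial(force_path, marker_path, meta_path,
                              config=config), config)

    # -- pipeline stages ----------------------------------------------------

    def _markers_on_force_grid(self, force_time: np.ndarray
                               ) -> MarkerTrajectories:
        cfg = self.config
        mk = preprocess.fill_gaps(self.trial.markers)
        data = {}
        for name, arr in mk.data.items():
            cs = CubicSpline(mk.time, arr, axis=0)
            data[name] = cs(force_time)
        dense = MarkerTrajectories(force_time, data)
        return preprocess.filter_markers(dense, cfg.marker_cutoff_hz,
                                         cfg.filter_order)

    def fit(self) -> "WorkPartitionResults":
        """Run the full partition; raises SegmentationError if the trial
        contains no complete stride."""
        cfg = self.config
        meta = self.trial.meta
        g = meta.gravity

        forces = preprocess.filter_forces(self.trial.forces,
                                          cfg.force_cutoff_hz,
                                          cfg.filter_order)
        forces = forces.with_cop_mask(cfg.cop_force_threshold_n)
        markers = self._markers_on_force_grid(forces.time)

        contacts = preprocess.detect_contacts(
            forces.F_z, meta.body_weight, forces.rate,
            cfg.contact_threshold_fraction)
        seg = preprocess.assign_feet_and_strides(contacts, forces, markers)
        if not seg.strides:
            raise SegmentationError("no complete right-to-right stride")
        strides = seg.strides

        a_f, a_v = com_mechanics.com_acceleration(forces, meta.mass, g)
        kin = com_mechanics.integrate_com(forces.time, a_f, a_v, strides)
        E_kf, E_v, E_com = com_mechanics.external_energies(
            kin, meta.mass, g, meta.belt_speed)
        W_com = com_mechanics.work_increments(E_com, strides)

        table = body_model.get_table(cfg.anthropometric_table_name)
        segments = body_model.build_segments(markers, meta, table)

        if cfg.kinematic_com:
            v_com = sum(table[s.name.split("_")[0]].mass_fraction * s.vel
                        for s in segments.values())
        else:
            v_com = np.column_stack([kin.v_f, kin.v_v])

        energies: Dict[str, com_mechanics.EnergyCurve] = {
            "E_kf": E_kf, "E_v": E_v, "E_com": E_com}
        W_int = {}
        for side in ("R", "L"):
            curve = segmental_work.internal_energy(
                [segments[f"{s}_{side}"] for s in ("thigh", "shank", "foot")],
                v_com, f"E_int,{side}", forces.time)
            energies[f"E_int_{side}"] = curve
            W_int[side] = com_mechanics.work_increments(curve, strides)
        trunk_curve = segmental_work.internal_energy(
            [segments["trunk"]], v_com, "E_int,trunk", forces.time)
        energies["E_int_trunk"] = trunk_curve
        W_int["trunk"] = com_mechanics.work_increments(trunk_curve, strides)

        kinetics = {}
        W_j = {}
        for side in ("R", "L"):
            jk = segmental_work.inverse_dynamics_limb(
                forces, seg.foot_force_mask(side), seg.contacts[side],
                segments, side, segments["trunk"], g)
            kinetics[side] = jk
            curve, w = segmental_work.joint_power_work(jk, strides)
            energies[f"E_j_{side}"] = curve
            W_j[side] = w

        breakdown = segmental_work.partition_work(
            meta.mass, W_com, W_int["R"], W_int["L"], W_int["trunk"],
            W_j["R"], W_j["L"])

        springs = self._fit_springs(forces, markers, seg)

        return WorkPartitionResults(
            model=self, forces=forces, markers=markers, segmentation=seg,
            com=kin, energies=energies, breakdown=breakdown,
            kinetics=kinetics, springs=springs)

    def _fit_springs(self, forces: ForceSeries,
                     markers: MarkerTrajectories,
                     seg: preprocess.StrideSegmentation) -> pd.DataFrame:
        cfg = self.config
        rows = []
        step_id = 0
        lo, hi = seg.strides[0][0], seg.strides[-1][1]
        for foot in ("R", "L"):
            gt = markers[f"GT_{foot}"]
            for a, b in seg.contacts[foot]:
                if a < lo or a >= hi:
                    continue
                stride_id = next(i for i, (s0, s1) in enumerate(seg.strides)
                                 if s0 <= a < s1)
                try:
                    ls = leg_series(forces, gt, (a, b), self.trial.meta.mass,
                                    foot, cfg.cop_force_threshold_n)
                    res = fit_spring_actuator(ls)
                    darea = (hysteresis_area(ls, literal=True)
                             if cfg.literal_delta_area else res.delta_area)
                except DegenerateFitError as exc:
                    warnings.warn(f"contact at sample {a}: {exc}",
                                  stacklevel=2)
                    continue
                rows.append({"step_id": step_id, "stride_id": stride_id,
                             "foot": foot, "cst": res.cst, "k": res.k,
                             "c": res.c, "rmse": res.rmse,
                             "r_squared": res.r_squared,
                             "delta_area": darea,
                             "n_frames": res.n_frames})
                step_id += 1
        return (pd.DataFrame(rows)
                .sort_values(["stride_id", "foot"])
                .reset_index(drop=True)
                if rows else pd.DataFrame(
                    columns=["step_id", "stride_id", "foot", "cst", "k", "c",
                             "rmse", "r_squared", "delta_area", "n_frames"]))


@dataclass
class WorkPartitionResults:
    """Results of :meth:`RunningWorkPartition.fit`."""

    model: RunningWorkPartition
    forces: ForceSeries
    markers: MarkerTrajectories
    segmentation: preprocess.StrideSegmentation
    com: com_mechanics.ComKinematics
    energies: Dict[str, com_mechanics.EnergyCurve]
    breakdown: segmental_work.WorkBreakdown
    kinetics: Dict[str, segmental_work.JointKinetics]
    springs: pd.DataFrame

    @property
    def work(self) -> pd.DataFrame:
        """Per-stride work breakdown in J/kg."""
        return self.breakdown.to_frame(mass_specific=True)

    def condition_summary(self, subject_id: Optional[str] = None
                          ) -> ConditionSummary:
        meta = self.model.trial.meta
        return aggregate(self.work, self.springs,
                         subject_id=subject_id or meta.subject_id,
                         speed_kmh=meta.belt_speed * 3.6,
                         step_frequency=meta.target_step_frequency)

    def summary(self) -> str:
        w = self.work
        s = self.springs
        lines = ["Running work partition",
                 "=" * 58,
                 f"strides analysed     {self.breakdown.n_strides}",
                 f"steps fitted         {len(s)}",
                 "-" * 58,
                 "per-stride work, J/kg (mean ± sd)      +          -"]
        for name in ("W_com", "W_tot", "W_j_R", "W_j_L", "W_ST"):
            p = w[f"{name}+"]
            m = w[f"{name}-"]
            lines.append(f"  {name:<12} {p.mean():>8.3f} ± {p.std():<6.3f} "
                         f"{m.mean():>8.3f} ± {m.std():<6.3f}")
        if len(s):
            lines += ["-" * 58,
                      "spring-mass-actuator fit (per step mean ± sd)",
                      f"  k      {s['k'].mean():>9.2f} ± {s['k'].std():<7.2f} N/kg/m",
                      f"  c      {s['c'].mean():>9.2f} ± {s['c'].std():<7.2f} N·s/kg/m",
                      f"  RMSE   {s['rmse'].mean():>9.3f} ± {s['rmse'].std():<7.3f} N/kg",
                      f"  R²     {s['r_squared'].mean():>9.3f} ± {s['r_squared'].std():<7.3f}",
                      f"  Δ_area {s['delta_area'].mean():>9.3f} ± {s['delta_area'].std():<7.3f} J/kg"]
        return "\n".join(lines)

    # -- plots --------------------------------------------------------------

    def plot_energies(self, ax=None):
        """External and internal energy traces over the analysed span."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        lo, hi = self.com.span
        t = self.com.time[lo:hi]
        for key in ("E_com", "E_int_R", "E_int_L", "E_int_trunk"):
            ax.plot(t, self.energies[key].E[lo:hi], label=key)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("energy (J)")
        ax.legend(fontsize="small")
        return ax

    def plot_force_length(self, step_id: int = 0, ax=None):
        """Force–length loop of one step with the fitted line."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        row = self.springs.iloc[step_id]
        foot = row["foot"]
        contact = self.segmentation.contacts[foot]
        # locate the matching contact by stride
        gt = self.markers[f"GT_{foot}"]
        lo = self.segmentation.strides[int(row["stride_id"])][0]
        hi = self.segmentation.strides[int(row["stride_id"])][1]
        iv = next((a, b) for a, b in contact if lo <= a < hi)
        ls = leg_series(self.forces, gt, iv, self.model.trial.meta.mass, foot)
        m = ls.valid
        ax.plot(ls.L_leg[m], ls.F_projected[m], ".", ms=2, label="data")
        pred = row["cst"] + row["k"] * ls.L_leg[m] + row["c"] * ls.V_leg[m]
        ax.plot(ls.L_leg[m], pred, "r--", lw=1, label="model")
        ax.set_xlabel("leg length (m)")
        ax.set_ylabel("projected force (N/kg)")
        ax.legend(fontsize="small")
        return ax
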