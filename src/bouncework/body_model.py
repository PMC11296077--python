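"""Anthropometry and planar rigid-segment kinematics.

Each lower limb is modelled as thigh (GT–knee), shank (knee–ankle) and foot
(ankle–midpoint of heel and fifth-metatarsal markers); the trunk (with head
and arms) is a single segment from the pelvis (midpoint of waist and
backwaist markers) to the neck marker.  Segment masses, CoM locations and
radii of gyration come from a named anthropometric table of body-mass and
segment-length fractions; the shipped default is Winter's standard table.
Velocities and accelerations are central finite differences on the
(filtered, oversampled) marker grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

from .errors import GeometryError, ParameterError
from .trial_io import MarkerTrajectories, TrialMeta


@dataclass(frozen=True)
class SegmentFractions:
    """Fractions for one segment: of body mass, and of segment length
    (CoM position from the proximal end; radius of gyration about the CoM).
    """

    mass_fraction: float
    com_fraction: float
    gyration_fraction: float

    def __post_init__(self) -> None:
        for f in (self.mass_fraction, self.com_fraction,
                  self.gyration_fraction):
            if not (0.0 < f < 1.0):
                raise ParameterError(f"fraction {f} outside (0, 1)")


#: Winter's standard anthropometric fractions.  The trunk entry is the
#: trunk-head-arms compound, with its CoM fraction measured from the hip.
WINTER_TABLE: Dict[str, SegmentFractions] = {
    "foot": SegmentFractions(0.0145, 0.50, 0.475),
    "shank": SegmentFractions(0.0465, 0.433, 0.302),
    "thigh": SegmentFractions(0.100, 0.433, 0.323),
    "trunk": SegmentFractions(0.678, 0.626, 0.496),
}

_TABLES: Dict[str, Dict[str, SegmentFractions]] = {"winter": WINTER_TABLE}


def get_table(name: str) -> Dict[str, SegmentFractions]:
    """Look up a registered anthropometric table by name."""
    try:
        return _TABLES[name]
    except KeyError:
        raise ParameterError(f"unknown anthropometric table {name!r}; "
                             f"registered: {sorted(_TABLES)}")


def register_table(name: str, table: Dict[str, SegmentFractions]) -> None:
    if sum(f.mass_fraction for f in table.values()) > 1.0 + 1e-9:
        raise ParameterError("modelled mass fractions sum above 1")
    _TABLES[name] = table


def load_table_tsv(path) -> Dict[str, SegmentFractions]:
    """Read a table from TSV: segment, mass_fraction, com_fraction,
    gyration_fraction."""
    table = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["segment", "mass_fraction", "com_fraction",
                          "gyration_fraction"]:
            raise ParameterError(f"unexpected table header {header}")
        for line in fh:
            seg, mf, cf, gf = line.rstrip("\n").split("\t")[:4]
            table[seg] = SegmentFractions(float(mf), float(cf), float(gf))
    return table


@dataclass
class SegmentState:
    """Planar rigid-segment state over time.

    Endpoint and CoM positions in m, velocities in m/s, the segment angle
    versus the horizontal in rad (unwrapped), its derivatives, and the
    inertial constants m_i (kg) and I_i (kg·m², about the segment CoM).
    """

    name: str
    proximal: np.ndarray   # (n, 2)
    distal: np.ndarray     # (n, 2)
    com: np.ndarray        # (n, 2)
    vel: np.ndarray        # (n, 2) CoM velocity
    acc: np.ndarray        # (n, 2) CoM acceleration
    angle: np.ndarray      # (n,)
    omega: np.ndarray      # (n,)
    alpha: np.ndarray      # (n,)
    mass: float
    inertia: float
    length: float


def _segment_from_endpoints(name: str, prox: np.ndarray, dist: np.ndarray,
                            time: np.ndarray, body_mass: float,
                            frac: SegmentFractions) -> SegmentState:
    vec = dist - prox
    lengths = np.hypot(vec[:, 0], vec[:, 1])
    length = float(np.mean(lengths))
    if length < 0.01:
        raise GeometryError(f"segment {name!r}: near-zero length "
                            f"{length * 100:.2f} cm")
    cv = float(np.std(lengths) / length)
    if cv > 0.05:
        raise GeometryError(f"segment {name!r}: length CV {cv:.1%} > 5% "
                            "(non-rigid marker pair)")
    dt = float(np.mean(np.diff(time)))
    com = prox + frac.com_fraction * vec
    vel = np.gradient(com, dt, axis=0)
    acc = np.gradient(vel, dt, axis=0)
    angle = np.unwrap(np.arctan2(vec[:, 1], vec[:, 0]))
    omega = np.gradient(angle, dt)
    alpha = np.gradient(omega, dt)
    mass = frac.mass_fraction * body_mass
    inertia = mass * (frac.gyration_fraction * length) ** 2
    return SegmentState(name=name, proximal=prox, distal=dist, com=com,
                        vel=vel, acc=acc, angle=angle, omega=omega,
                        alpha=alpha, mass=mass, inertia=inertia,
                        length=length)


def build_segments(markers: MarkerTrajectories, meta: TrialMeta,
                   table: Dict[str, SegmentFractions] | None = None
                   ) -> Dict[str, SegmentState]:
    """Build thigh/shank/foot per side plus the trunk from markers.

    Keys: ``thigh_R``, ``shank_R``, ``foot_R`` (and ``_L``), ``trunk``.
    """
    table = table or WINTER_TABLE
    t = markers.time
    m = meta.mass
    segs: Dict[str, SegmentState] = {}
    for side in ("R", "L"):
        gt = markers[f"GT_{side}"]
        knee = markers[f"knee_{side}"]
        ankle = markers[f"ankle_{side}"]
        foot_distal = 0.5 * (markers[f"heel_{side}"] + markers[f"VM_{side}"])
        segs[f"thigh_{side}"] = _segment_from_endpoints(
            f"thigh_{side}", gt, knee, t, m, table["thigh"])
        segs[f"shank_{side}"] = _segment_from_endpoints(
            f"shank_{side}", knee, ankle, t, m, table["shank"])
        segs[f"foot_{side}"] = _segment_from_endpoints(
            f"foot_{side}", ankle, foot_distal, t, m, table["foot"])
    pelvis = 0.5 * (markers["waist"] + markers["backwaist"])
    segs["trunk"] = _segment_from_endpoints(
        "trunk", pelvis, markers["neck"], t, m, table["trunk"])
    return segs


def segment_relative_velocity(seg: SegmentState, v_com: np.ndarray
                              ) -> np.ndarray:
    """|V_i'|: speed of the segment CoM relative to the body CoM.

    ``v_com`` is the (n, 2) force-derived CoM velocity (v_f, v_v) on the
    same grid.
    """
    rel = seg.vel - v_com
    return np.hypot(rel[:, 0], rel[:, 1])
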