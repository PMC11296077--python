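"""Trial containers and on-disk formats.

A *trial* is one treadmill recording: ground-reaction force and centre of
pressure sampled at the force rate (typically 1 kHz), sagittal-plane marker
trajectories at the camera rate (typically 200 Hz), and subject/belt
metadata.  Everything downstream of this module consumes only the in-memory
containers defined here; no other module touches files.

Coordinates are 2-D sagittal: ``y`` fore-aft, positive in the direction of
progression; ``z`` vertical, positive up; lab (treadmill-machine) frame;
SI units throughout.

The text format is three tab-separated files sharing a stem::

    <stem>_meta.tsv     key<TAB>value pairs
    <stem>_force.tsv    ``# key=value`` header lines, then  time  Fy  Fz  COPy
    <stem>_markers.tsv  ``# key=value`` header lines, then  time  <name>_y  <name>_z ...
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from .errors import (
    FormatError,
    MappingError,
    MissingDependencyError,
    ParameterError,
    SamplingError,
    UnitError,
)

#: Canonical marker names (sagittal), sided markers carry ``_R``/``_L``.
SIDED_MARKERS = ("shoulder", "elbow", "wrist", "GT", "thigh", "knee",
                 "shank", "ankle", "heel", "VM", "IIM")
UNSIDED_MARKERS = ("neck", "chest", "waist", "backwaist")

#: Markers that must be present for the lower-limb analysis.
REQUIRED_MARKERS = tuple(
    [f"{m}_{s}" for m in ("GT", "knee", "ankle", "heel", "VM") for s in "RL"]
    + ["waist", "backwaist", "neck", "chest"]
)

_REL_TIME_TOL = 1e-6  # 1 ppm uniform-sampling tolerance


@dataclass
class TrialMeta:
    """Subject and recording metadata.

    Parameters
    ----------
    mass : float
        Body mass in kg.
    height : float
        Stature in m.
    belt_speed : float
        Average treadmill belt speed ``V_avg`` in m/s.
    target_step_frequency : float
        Metronome-imposed step frequency in steps/s.
    force_rate, marker_rate : float
        Sampling rates in Hz; the force series is the master clock.
    gravity : float
        Gravitational acceleration in m/s².
    """

    subject_id: str
    mass: float
    height: float
    belt_speed: float
    target_step_frequency: float
    force_rate: float = 1000.0
    marker_rate: float = 200.0
    gravity: float = 9.81

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ParameterError("mass must be > 0")
        if self.belt_speed < 0:
            raise ParameterError("belt_speed must be >= 0")
        if not (self.force_rate >= self.marker_rate > 0):
            raise ParameterError("need force_rate >= marker_rate > 0")

    @property
    def body_weight(self) -> float:
        """Body weight m·g in N."""
        return self.mass * self.gravity


@dataclass
class ForceSeries:
    """Reduced ground-reaction force and centre of pressure.

    ``F_y`` fore-aft (positive = direction of progression), ``F_z`` vertical
    (positive up), ``cop_y`` fore-aft centre-of-pressure position in the lab
    frame.  ``valid_cop`` is False wherever ``F_z`` is below the COP force
    threshold (the COP is unreliable at low load).
    """

    time: np.ndarray
    F_y: np.ndarray
    F_z: np.ndarray
    cop_y: np.ndarray
    valid_cop: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.F_y = np.asarray(self.F_y, dtype=float)
        self.F_z = np.asarray(self.F_z, dtype=float)
        self.cop_y = np.asarray(self.cop_y, dtype=float)
        n = self.time.size
        if not (self.F_y.size == self.F_z.size == self.cop_y.size == n):
            raise FormatError("force columns have unequal lengths")
        _check_uniform(self.time, "force")
        if self.valid_cop is None:
            self.valid_cop = np.ones(n, dtype=bool)
        self.valid_cop = np.asarray(self.valid_cop, dtype=bool)

    @property
    def rate(self) -> float:
        return 1.0 / float(np.mean(np.diff(self.time)))

    def with_cop_mask(self, threshold_n: float) -> "ForceSeries":
        """Return a copy whose ``valid_cop`` applies ``F_z >= threshold_n``."""
        return replace(self, valid_cop=self.F_z >= threshold_n)


@dataclass
class MarkerTrajectories:
    """Named sagittal marker trajectories on a common time grid.

    ``data[name]`` is an (n, 2) array of (y, z) positions in m.
    """

    time: np.ndarray
    data: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        _check_uniform(self.time, "marker")
        for name, arr in self.data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (self.time.size, 2):
                raise FormatError(
                    f"marker {name!r}: expected shape {(self.time.size, 2)}, "
                    f"got {arr.shape}")
            self.data[name] = arr

    @property
    def rate(self) -> float:
        return 1.0 / float(np.mean(np.diff(self.time)))

    @property
    def names(self) -> List[str]:
        return list(self.data)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.data[name]

    def __contains__(self, name: str) -> bool:
        return name in self.data


@dataclass
class RawTrial:
    """One recording: forces + markers + metadata."""

    meta: TrialMeta
    forces: ForceSeries
    markers: MarkerTrajectories


@dataclass
class AnalysisConfig:
    """Tunable analysis parameters.

    Defaults follow the processing conventions of the analysis: zero-phase
    8th-order Bessel low-pass at 30 Hz on both force and marker data,
    foot-contact threshold at 10% of body weight, COP trusted only above
    300 N of vertical force.
    """

    force_cutoff_hz: float = 30.0
    marker_cutoff_hz: float = 30.0
    filter_order: int = 8
    contact_threshold_fraction: float = 0.10
    cop_force_threshold_n: float = 300.0
    anthropometric_table_name: str = "winter"
    kinematic_com: bool = False       # use marker-derived CoM for V_i' (audit)
    literal_delta_area: bool = False  # signed-integral Δ_area variant (audit)
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.contact_threshold_fraction < 1.0):
            raise ParameterError("contact_threshold_fraction must be in (0, 1)")
        if self.filter_order % 2 or self.filter_order <= 0:
            raise ParameterError("filter_order must be a positive even integer")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({f.name: getattr(self, f.name) for f in fields(self)}, fh)


@dataclass
class Finding:
    """One validation finding; ``severity`` is 'error' or 'warning'."""

    severity: str
    message: str
    location: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        loc = f" [{self.location}]" if self.location else ""
        return f"{self.severity}: {self.message}{loc}"


def _check_uniform(time: np.ndarray, what: str) -> None:
    if time.size < 2:
        return
    dt = np.diff(time)
    step = np.median(dt)
    if step <= 0:
        raise SamplingError(f"{what} time base not increasing")
    # 1 ppm of the record length, expressed per step
    if np.max(np.abs(dt - step)) > max(_REL_TIME_TOL * time[-1], 1e-9 * step):
        raise SamplingError(f"{what} timestamps non-uniform beyond 1 ppm")


# ---------------------------------------------------------------------------
# Text format
# ---------------------------------------------------------------------------

_FORCE_COLUMNS = ("time", "Fy", "Fz", "COPy")


def _read_headered_tsv(path) -> Tuple[Dict[str, str], List[str], np.ndarray]:
    """Read ``# key=value`` header lines + one column-header line + data."""
    header: Dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                header[k.strip()] = v.strip()
            pos = fh.tell()
            line = fh.readline()
        if not line:
            raise FormatError(f"{path}: empty file")
        columns = line.rstrip("\n").split("\t")
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    if data.size and data.shape[1] != len(columns):
        raise FormatError(f"{path}: {len(columns)} columns declared, "
                          f"{data.shape[1]} found")
    if header.get("units", "SI") != "SI":
        raise UnitError(f"{path}: units {header['units']!r}, expected SI")
    return header, columns, data


def _write_headered_tsv(path, header: Dict[str, str], columns: List[str],
                        data: np.ndarray) -> None:
    with open(path, "w") as fh:
        for k, v in header.items():
            fh.write(f"# {k}={v}\n")
        fh.write("\t".join(columns) + "\n")
        np.savetxt(fh, np.asarray(data), delimiter="\t", fmt="%.10g")


def read_trial(force_path, marker_path, meta_path,
               config: Optional[AnalysisConfig] = None) -> RawTrial:
    """Read a trial from the three-file text format.

    The COP validity mask is computed at load time from the configured
    vertical-force threshold (default 300 N).
    """
    config = config or AnalysisConfig()
    meta = _read_meta(meta_path)

    _, cols, data = _read_headered_tsv(force_path)
    for required in _FORCE_COLUMNS:
        if required not in cols:
            raise FormatError(f"{force_path}: missing column {required!r}")
    col = {c: data[:, i] for i, c in enumerate(cols)}
    forces = ForceSeries(col["time"], col["Fy"], col["Fz"], col["COPy"])
    forces = forces.with_cop_mask(config.cop_force_threshold_n)

    _, mcols, mdata = _read_headered_tsv(marker_path)
    if mcols[0] != "time":
        raise FormatError(f"{marker_path}: first column must be 'time'")
    names: List[str] = []
    for c in mcols[1:]:
        if not (c.endswith("_y") or c.endswith("_z")):
            raise FormatError(f"{marker_path}: column {c!r} not <name>_y/_z")
        base = c[:-2]
        if base not in names:
            names.append(base)
    markers: Dict[str, np.ndarray] = {}
    for name in names:
        try:
            iy = mcols.index(f"{name}_y")
            iz = mcols.index(f"{name}_z")
        except ValueError as exc:
            raise FormatError(f"{marker_path}: marker {name!r} lacks a "
                              "paired _y/_z column") from exc
        markers[name] = np.column_stack([mdata[:, iy], mdata[:, iz]])
    traj = MarkerTrajectories(mdata[:, 0], markers)
    _check_overlap(forces, traj)
    return RawTrial(meta=meta, forces=forces, markers=traj)


def _read_meta(meta_path) -> TrialMeta:
    kv: Dict[str, str] = {}
    with open(meta_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{meta_path}: bad meta line {line!r}")
            kv[parts[0]] = parts[1]
    try:
        return TrialMeta(
            subject_id=kv["subject_id"],
            mass=float(kv["mass"]),
            height=float(kv["height"]),
            belt_speed=float(kv["belt_speed"]),
            target_step_frequency=float(kv["target_step_frequency"]),
            force_rate=float(kv.get("force_rate", 1000.0)),
            marker_rate=float(kv.get("marker_rate", 200.0)),
            gravity=float(kv.get("gravity", 9.81)),
        )
    except KeyError as exc:
        raise FormatError(f"{meta_path}: missing meta key {exc.args[0]!r}")


def _check_overlap(forces: ForceSeries, markers: MarkerTrajectories) -> None:
    t0 = max(forces.time[0], markers.time[0])
    t1 = min(forces.time[-1], markers.time[-1])
    span = max(forces.time[-1] - forces.time[0],
               markers.time[-1] - markers.time[0])
    if span > 0 and (t1 - t0) < 0.95 * span:
        raise FormatError("force and marker time ranges overlap < 95%")


def write_trial(trial: RawTrial, out_dir, stem: str = "trial") -> Dict[str, Path]:
    """Write a trial in the three-file text format; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta_path = out / f"{stem}_meta.tsv"
    with open(meta_path, "w") as fh:
        for f in fields(trial.meta):
            fh.write(f"{f.name}\t{getattr(trial.meta, f.name)}\n")

    force_path = out / f"{stem}_force.tsv"
    fdata = np.column_stack([trial.forces.time, trial.forces.F_y,
                             trial.forces.F_z, trial.forces.cop_y])
    _write_headered_tsv(force_path,
                        {"rate_hz": f"{trial.meta.force_rate:g}", "units": "SI"},
                        list(_FORCE_COLUMNS), fdata)

    marker_path = out / f"{stem}_markers.tsv"
    cols = ["time"]
    arrs = [trial.markers.time]
    for name in trial.markers.names:
        cols += [f"{name}_y", f"{name}_z"]
        arrs += [trial.markers[name][:, 0], trial.markers[name][:, 1]]
    _write_headered_tsv(marker_path,
                        {"rate_hz": f"{trial.meta.marker_rate:g}", "units": "SI"},
                        cols, np.column_stack(arrs))
    return {"meta": meta_path, "force": force_path, "markers": marker_path}


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_trial(trial: RawTrial) -> List[Finding]:
    """Check the trial invariants; returns an empty list iff all hold.

    Errors: negative vertical force, missing required markers, COP mask
    inconsistent with the 300 N rule.  Warnings: marker gaps (NaN runs).
    """
    findings: List[Finding] = []
    f = trial.forces
    if np.any(f.F_z < 0):
        n = int(np.sum(f.F_z < 0))
        findings.append(Finding("error", f"negative vertical force "
                                f"({n} samples)", "forces.F_z"))
    if np.any(f.valid_cop & (f.F_z < 300.0)):
        findings.append(Finding("warning", "COP marked valid below 300 N",
                                "forces.valid_cop"))
    for name in REQUIRED_MARKERS:
        if name not in trial.markers:
            findings.append(Finding("error", f"missing required marker {name}",
                                    "markers"))
    for name, arr in trial.markers.data.items():
        bad = np.any(np.isnan(arr), axis=1)
        if bad.any():
            findings.append(Finding("warning",
                                    f"gap: {name}, {int(bad.sum())} frames",
                                    f"markers.{name}"))
    return findings


# ---------------------------------------------------------------------------
# C3D (optional convenience path)
# ---------------------------------------------------------------------------

#: Default alias table from common mocap labels to canonical names.
DEFAULT_C3D_ALIASES = {f"R{m}": f"{m}_R" for m in SIDED_MARKERS}
DEFAULT_C3D_ALIASES.update({f"L{m}": f"{m}_L" for m in SIDED_MARKERS})


def resolve_marker_aliases(labels: List[str],
                           aliases: Optional[Dict[str, str]] = None
                           ) -> Dict[str, str]:
    """Map raw point labels to canonical marker names.

    Labels already canonical pass through; others are looked up in
    ``aliases`` (merged over the built-in R/L-prefix table).  Raises
    :class:`MappingError` listing the unmatched labels if any required
    marker stays unresolved.
    """
    table = dict(DEFAULT_C3D_ALIASES)
    if aliases:
        table.update(aliases)
    canonical = set(UNSIDED_MARKERS) | {
        f"{m}_{s}" for m in SIDED_MARKERS for s in "RL"}
    mapping: Dict[str, str] = {}
    for lab in labels:
        if lab in canonical:
            mapping[lab] = lab
        elif lab in table:
            mapping[lab] = table[lab]
    resolved = set(mapping.values())
    missing = [m for m in REQUIRED_MARKERS if m not in resolved]
    if missing:
        unmatched = [l for l in labels if l not in mapping]
        raise MappingError(f"unresolved required markers {missing}; "
                           f"unmatched labels {unmatched}")
    return mapping


def read_c3d(path, meta: TrialMeta,
             aliases: Optional[Dict[str, str]] = None,
             analog_names: Tuple[str, str, str] = ("Fy", "Fz", "COPy"),
             config: Optional[AnalysisConfig] = None) -> RawTrial:
    """Read a trial from a C3D file (requires the optional ``ezc3d`` package).

    Labelled points are mapped to canonical marker names through
    :func:`resolve_marker_aliases`; the named analog channels provide the
    fore-aft force, vertical force and fore-aft COP.  Point X/Z axes are
    taken as the sagittal (y, z) pair.
    """
    try:
        import ezc3d
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise MissingDependencyError(
            "reading C3D files requires the optional 'ezc3d' package") from exc
    config = config or AnalysisConfig()
    c3d = ezc3d.c3d(str(path))
    labels = [l.strip() for l in
              c3d["parameters"]["POINT"]["LABELS"]["value"]]
    mapping = resolve_marker_aliases(labels, aliases)
    point_rate = float(c3d["parameters"]["POINT"]["RATE"]["value"][0])
    pts = c3d["data"]["points"]  # (4, n_markers, n_frames), mm by convention
    scale = 0.001
    n_frames = pts.shape[2]
    mtime = np.arange(n_frames) / point_rate
    data = {}
    for i, lab in enumerate(labels):
        if lab in mapping:
            data[mapping[lab]] = np.column_stack(
                [pts[0, i] * scale, pts[2, i] * scale])
    markers = MarkerTrajectories(mtime, data)

    analogs = c3d["data"]["analogs"]  # (1, n_channels, n_samples)
    alabels = [l.strip() for l in
               c3d["parameters"]["ANALOG"]["LABELS"]["value"]]
    try:
        idx = [alabels.index(name) for name in analog_names]
    except ValueError:
        raise MappingError(f"C3D lacks analog channels {analog_names}; "
                           f"found {alabels}")
    arate = float(c3d["parameters"]["ANALOG"]["RATE"]["value"][0])
    atime = np.arange(analogs.shape[2]) / arate
    forces = ForceSeries(atime, analogs[0, idx[0]], analogs[0, idx[1]],
                         analogs[0, idx[2]])
    forces = forces.with_cop_mask(config.cop_force_threshold_n)
    return RawTrial(meta=meta, forces=forces, markers=markers)
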