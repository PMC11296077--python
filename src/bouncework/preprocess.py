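"""Signal conditioning and gait-event segmentation.

Force and marker signals are low-pass filtered with a zero-phase (two-way)
8th-order Bessel filter; marker trajectories are oversampled to the force
grid with cubic splines.  Foot contacts are detected where the vertical
ground-reaction force exceeds 10% of body weight, feet are labelled by
ankle-to-COP proximity, and strides are built from right foot contact to the
next right foot contact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq

from .errors import (
    GaitAssumptionError,
    GeometryError,
    ParameterError,
)
from .trial_io import ForceSeries, MarkerTrajectories

#: contacts shorter than this are treated as threshold chatter and dropped
DEBOUNCE_S = 0.020


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def _bessel_sos(order: int, cutoff_hz: float, fs: float):
    """8th-order (or given order) Bessel SOS whose *two-pass* −3 dB point
    lands at ``cutoff_hz``.

    A forward-backward pass squares the magnitude response, moving the −3 dB
    point below the design cutoff; the design frequency is pre-warped (by a
    1-D root find on the realized response) so the two-pass half-power point
    is at the configured cutoff.
    """
    nyq = fs / 2.0
    target = 2.0 ** (-0.25)  # single-pass gain giving |H|² = 1/√2

    def single_pass_gain(wn: float) -> float:
        sos = signal.bessel(order, wn, "low", fs=fs, output="sos", norm="mag")
        _, h = signal.sosfreqz(sos, worN=[cutoff_hz], fs=fs)
        return float(np.abs(h[0]))

    lo, hi = cutoff_hz, min(cutoff_hz * 4.0, 0.999 * nyq)
    if single_pass_gain(hi) < target:
        wn = hi  # cutoff so close to Nyquist that pre-warping saturates
    else:
        wn = brentq(lambda w: single_pass_gain(w) - target, lo, hi, xtol=1e-6)
    return signal.bessel(order, wn, "low", fs=fs, output="sos", norm="mag")


def lowpass_zero_phase(series: np.ndarray, cutoff_hz: float, fs: float,
                       order: int = 8) -> np.ndarray:
    """Zero-phase low-pass of Bessel character; DC gain exactly 1.

    Applies the filter forward then backward (``sosfiltfilt``), cancelling
    phase lag.  Works along the last axis.
    """
    if cutoff_hz >= fs / 2.0:
        raise ParameterError(f"cutoff {cutoff_hz} Hz >= Nyquist {fs / 2} Hz")
    if order % 2 or order <= 0:
        raise ParameterError("order must be a positive even integer")
    series = np.asarray(series, dtype=float)
    sos = _bessel_sos(order, cutoff_hz, fs)
    return signal.sosfiltfilt(sos, series, axis=-1)


def filter_forces(forces: ForceSeries, cutoff_hz: float,
                  order: int = 8) -> ForceSeries:
    """Low-pass F_y and F_z; clamps filter-ringing negatives of F_z to 0.

    The COP position is left unfiltered (it is a quotient, not a load signal)
    and its validity mask is untouched.
    """
    fs = forces.rate
    fy = lowpass_zero_phase(forces.F_y, cutoff_hz, fs, order)
    fz = lowpass_zero_phase(forces.F_z, cutoff_hz, fs, order)
    fz = np.maximum(fz, 0.0)
    return ForceSeries(forces.time, fy, fz, forces.cop_y, forces.valid_cop)


def resample_spline(markers: MarkerTrajectories,
                    target_rate: float) -> MarkerTrajectories:
    """Cubic-spline oversampling of marker trajectories.

    Values at the original sample times are reproduced exactly (interpolating
    spline).  ``target_rate`` must be >= the source rate; NaNs (gaps) must be
    filled upstream.
    """
    src_rate = markers.rate
    if target_rate < src_rate * (1 - 1e-9):
        raise ParameterError("target_rate below source rate")
    if abs(target_rate - src_rate) / src_rate < 1e-9:
        return markers
    t = markers.time
    n_new = int(np.floor((t[-1] - t[0]) * target_rate)) + 1
    t_new = t[0] + np.arange(n_new) / target_rate
    data = {}
    for name, arr in markers.data.items():
        if np.any(np.isnan(arr)):
            raise GeometryError(f"marker {name!r} has gaps; fill before "
                                "resampling")
        cs = CubicSpline(t, arr, axis=0)
        data[name] = cs(t_new)
    return MarkerTrajectories(t_new, data)


def fill_gaps(markers: MarkerTrajectories) -> MarkerTrajectories:
    """Linear interpolation over NaN runs (short occlusions)."""
    data = {}
    t = markers.time
    for name, arr in markers.data.items():
        out = arr.copy()
        for k in range(2):
            col = out[:, k]
            bad = np.isnan(col)
            if bad.any():
                if bad.all():
                    raise GeometryError(f"marker {name!r} entirely missing")
                col[bad] = np.interp(t[bad], t[~bad], col[~bad])
        data[name] = out
    return MarkerTrajectories(t, data)


def filter_markers(markers: MarkerTrajectories, cutoff_hz: float,
                   order: int = 8) -> MarkerTrajectories:
    fs = markers.rate
    data = {name: lowpass_zero_phase(arr.T, cutoff_hz, fs, order).T
            for name, arr in markers.data.items()}
    return MarkerTrajectories(markers.time, data)


# ---------------------------------------------------------------------------
# Gait events
# ---------------------------------------------------------------------------

@dataclass
class ContactIntervals:
    """Half-open [touchdown, toeoff) sample intervals on the force grid."""

    intervals: List[Tuple[int, int]]
    rate: float

    def __post_init__(self) -> None:
        prev_end = -1
        for a, b in self.intervals:
            if b <= a:
                raise GaitAssumptionError(f"empty contact interval [{a}, {b})")
            if a < prev_end:
                raise GaitAssumptionError("contact intervals overlap")
            prev_end = b

    def __len__(self) -> int:
        return len(self.intervals)

    def durations(self) -> np.ndarray:
        return np.array([(b - a) / self.rate for a, b in self.intervals])


def detect_contacts(F_z: np.ndarray, body_weight: float, fs: float,
                    threshold_fraction: float = 0.10) -> ContactIntervals:
    """Maximal runs where F_z exceeds ``threshold_fraction`` of body weight.

    Runs shorter than 20 ms are discarded as threshold chatter.
    """
    if body_weight <= 0:
        raise ParameterError("body_weight must be > 0")
    above = np.asarray(F_z) > threshold_fraction * body_weight
    padded = np.concatenate([[False], above, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[::2], edges[1::2]
    min_len = int(round(DEBOUNCE_S * fs))
    intervals = [(int(a), int(b)) for a, b in zip(starts, stops)
                 if (b - a) >= min_len]
    if not intervals:
        warnings.warn("no foot contact found", stacklevel=2)
    return ContactIntervals(intervals, fs)


@dataclass
class StrideSegmentation:
    """Labelled contacts, strides and steps on the force grid.

    ``contacts[foot]`` holds that foot's [touchdown, toeoff) intervals;
    ``strides`` are [right touchdown, next right touchdown) intervals;
    ``steps`` are (start, stop, foot) with ``foot`` the foot touching down
    at ``start``.
    """

    contacts: Dict[str, List[Tuple[int, int]]]
    strides: List[Tuple[int, int]]
    steps: List[Tuple[int, int, str]]
    rate: float
    n_samples: int

    @property
    def n_strides(self) -> int:
        return len(self.strides)

    def foot_force_mask(self, foot: str) -> np.ndarray:
        """Boolean mask of frames assigned to ``foot`` ('R' or 'L')."""
        mask = np.zeros(self.n_samples, dtype=bool)
        for a, b in self.contacts[foot]:
            mask[a:b] = True
        return mask

    def to_table(self):
        """Audit table: one row per contact."""
        import pandas as pd
        rows = []
        for foot in ("R", "L"):
            for a, b in self.contacts[foot]:
                rows.append({"foot": foot, "t_touchdown": a / self.rate,
                             "t_toeoff": b / self.rate})
        return (pd.DataFrame(rows).sort_values("t_touchdown")
                .reset_index(drop=True))


def assign_feet_and_strides(contacts: ContactIntervals, forces: ForceSeries,
                            markers: MarkerTrajectories) -> StrideSegmentation:
    """Label contacts left/right and build right-to-right strides.

    Each contact is labelled by which ankle marker is nearer the COP at
    mid-contact (sagittal Euclidean distance, COP at belt height 0).
    Running is assumed: overlapping contacts raise
    :class:`GaitAssumptionError`.
    """
    n = forces.time.size
    labels: List[str] = []
    for a, b in contacts.intervals:
        mid = (a + b) // 2
        t_mid = forces.time[mid]
        cop = forces.cop_y[mid]
        d = {}
        for foot in ("R", "L"):
            ank = markers[f"ankle_{foot}"]
            ay = np.interp(t_mid, markers.time, ank[:, 0])
            az = np.interp(t_mid, markers.time, ank[:, 1])
            d[foot] = np.hypot(ay - cop, az)
        labels.append("R" if d["R"] <= d["L"] else "L")

    for prev, cur in zip(labels, labels[1:]):
        if prev == cur:
            warnings.warn("two consecutive contacts labelled "
                          f"{cur!r}; gait may not be alternating",
                          stacklevel=2)

    by_foot: Dict[str, List[Tuple[int, int]]] = {"R": [], "L": []}
    for lab, iv in zip(labels, contacts.intervals):
        by_foot[lab].append(iv)

    right_tds = [a for a, _ in by_foot["R"]]
    strides = [(right_tds[i], right_tds[i + 1])
               for i in range(len(right_tds) - 1)]
    if not strides:
        warnings.warn("fewer than two right contacts: zero complete strides",
                      stacklevel=2)

    steps: List[Tuple[int, int, str]] = []
    tds = sorted([(a, lab) for lab, ivs in by_foot.items() for a, _ in ivs])
    for (a, lab), (b, _) in zip(tds, tds[1:]):
        if strides and strides[0][0] <= a < strides[-1][1]:
            steps.append((a, b, lab))

    seg = StrideSegmentation(contacts=by_foot, strides=strides, steps=steps,
                             rate=contacts.rate, n_samples=n)
    for s0, s1 in strides:
        for foot in ("R", "L"):
            onsets = sum(1 for a, _ in by_foot[foot] if s0 <= a < s1)
            if onsets != 1:
                warnings.warn(f"stride [{s0}, {s1}) has {onsets} {foot} "
                              "contact onsets (expected 1)", stacklevel=2)
    return seg
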