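"""Couch-shift schedules and virtual fine-pitch merging.

A native 10 mm-pitch array acquires the same field several times under
small couch translations along one axis; re-expressing every sample in the
beam frame (nominal position + shift) and taking the union yields a single
measurement with a finer effective pitch along that axis.

For a target spacing t that divides the native pitch p the offsets
{0, t, 2t, ..., p - t} realise an exactly uniform virtual pitch t.  Target
spacings that do not divide the pitch (the 4 and 3 mm settings of a 10 mm
array) use the same rule, offsets {k*t : k*t < p}; the realised along-axis
spacing pattern is then periodic but not uniform (e.g. 4,4,2 mm for t=4)
and the schedule is marked ``uniform=False``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .detector import Measurement

__all__ = ["ShiftSchedule", "plan_shifts", "merge"]

logger = logging.getLogger(__name__)

#: positions closer than this (mm) are considered coincident and averaged
COINCIDENCE_TOL = 0.01

_AXES = ("SI", "RL")


@dataclass
class ShiftSchedule:
    """Ordered list of couch offsets realising a target virtual spacing."""

    axis: str
    offsets: tuple[float, ...]
    target_spacing: float
    native_pitch: float
    uniform: bool = True

    def __post_init__(self) -> None:
        if self.axis not in _AXES:
            raise ValueError(f"axis must be one of {_AXES}, got {self.axis!r}")
        if len(self.offsets) != len(set(self.offsets)):
            raise ValueError("schedule offsets must be unique")
        if self.offsets[0] != 0.0:
            raise ValueError("first schedule offset must be 0 (isocenter acquisition)")
        if any(abs(o) >= self.native_pitch for o in self.offsets[1:]):
            raise ValueError("all offsets must be smaller than the native pitch")

    def shift_vector(self, offset: float) -> tuple[float, float]:
        return (offset, 0.0) if self.axis == "SI" else (0.0, offset)


def plan_shifts(
    native_pitch_mm: float, target_spacing_mm: float, axis: str = "SI"
) -> ShiftSchedule:
    """Offsets {0, t, 2t, ...} below the native pitch for a virtual spacing t.

    Examples: (10, 5) -> {0, 5}; (10, 1) -> {0, 1, ..., 9}; (10, 10) -> {0}.
    Non-divisor spacings are planned with the same rule but flagged
    non-uniform, matching how 4 and 3 mm virtual spacings are built from
    1 mm couch steps on a 10 mm array.
    """
    if native_pitch_mm <= 0:
        raise ValueError("native pitch must be positive")
    if target_spacing_mm <= 0 or target_spacing_mm > native_pitch_mm:
        raise ValueError(
            f"target spacing must lie in (0, native pitch]; "
            f"got {target_spacing_mm} for pitch {native_pitch_mm}"
        )
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {_AXES}, got {axis!r}")
    n = int(np.ceil(native_pitch_mm / target_spacing_mm - 1e-12))
    offsets = tuple(float(k * target_spacing_mm) for k in range(n))
    ratio = native_pitch_mm / target_spacing_mm
    uniform = abs(ratio - round(ratio)) < 1e-9
    return ShiftSchedule(
        axis=axis,
        offsets=offsets,
        target_spacing=float(target_spacing_mm),
        native_pitch=float(native_pitch_mm),
        uniform=uniform,
    )


def _measurement_offset(m: Measurement, schedule: ShiftSchedule) -> float:
    shift = m.meta.get("shift", (0.0, 0.0))
    along = shift[0] if schedule.axis == "SI" else shift[1]
    across = shift[1] if schedule.axis == "SI" else shift[0]
    if abs(across) > 1e-9:
        raise ValueError(
            f"measurement shifted along {'RL' if schedule.axis == 'SI' else 'SI'} "
            f"cannot be merged on a {schedule.axis} schedule"
        )
    return float(along)


def merge(measurements: list[Measurement], schedule: ShiftSchedule) -> Measurement:
    """Union of shifted acquisitions on the virtual fine grid.

    Requires exactly one measurement per schedule offset (matched through
    each measurement's recorded shift).  Sample coordinates are already in
    the beam frame, so merging is a concatenation followed by lexicographic
    sorting; points coinciding within 0.01 mm are averaged with a logged
    warning.  The result is independent of the input ordering.
    """
    if len(measurements) != len(schedule.offsets):
        raise ValueError(
            f"schedule has {len(schedule.offsets)} offsets but "
            f"{len(measurements)} measurements were supplied"
        )
    seen: dict[float, Measurement] = {}
    for m in measurements:
        off = _measurement_offset(m, schedule)
        matches = [o for o in schedule.offsets if abs(o - off) < 1e-9]
        if not matches:
            raise ValueError(f"measurement shift {off} mm is not in the schedule")
        key = matches[0]
        if key in seen:
            raise ValueError(f"duplicate measurement for offset {key} mm")
        seen[key] = m

    pos_si = np.concatenate([seen[o].pos_si for o in schedule.offsets])
    pos_rl = np.concatenate([seen[o].pos_rl for o in schedule.offsets])
    dose = np.concatenate([seen[o].dose for o in schedule.offsets])

    # group coincident points on a COINCIDENCE_TOL lattice and average
    key_si = np.round(pos_si / COINCIDENCE_TOL).astype(np.int64)
    key_rl = np.round(pos_rl / COINCIDENCE_TOL).astype(np.int64)
    keys = np.stack([key_si, key_rl], axis=1)
    uniq, inverse, counts = np.unique(keys, axis=0, return_inverse=True, return_counts=True)
    n_coincident = int(np.sum(counts > 1))
    if n_coincident:
        logger.warning(
            "averaged %d coincident point group(s) within %.2f mm", n_coincident, COINCIDENCE_TOL
        )
    sum_si = np.bincount(inverse, weights=pos_si)
    sum_rl = np.bincount(inverse, weights=pos_rl)
    sum_dose = np.bincount(inverse, weights=dose)
    out_si = sum_si / counts
    out_rl = sum_rl / counts
    out_dose = sum_dose / counts

    order = np.lexsort((out_rl, out_si))
    return Measurement(
        pos_si=out_si[order],
        pos_rl=out_rl[order],
        dose=out_dose[order],
        meta={
            "merged": True,
            "axis": schedule.axis,
            "offsets": schedule.offsets,
            "target_spacing": schedule.target_spacing,
            "native_pitch": schedule.native_pitch,
            "uniform": schedule.uniform,
            "n_coincident_groups": n_coincident,
            "sources": [m.meta for m in measurements],
        },
    )
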