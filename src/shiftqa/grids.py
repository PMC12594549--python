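"""Synthetic steep-gradient SRS dose distributions.

Coordinate frame shared by every module: millimetres, origin at the machine
isocenter, axis 0 = superior-inferior (SI, positive = superior), axis 1 =
right-left (RL, positive = right).  A :class:`DoseGrid` stores a dense 2D
reference dose map (the role the treatment planning system plays for a real
measurement) on a regular grid, 1 mm pitch by default.

The dose model is an error-function (normal CDF) flat-top field,

    D(r) = b * Dmax + (1 - b) * Dmax * Phi((R - r) / sigma),

with R the target radius, sigma the penumbra width parameter and b a small
uniform background.  This places the 50% dose level exactly at the field
edge r = R and reproduces the few-mm 80-20 penumbra of small 6 MV FFF
fields.  Single-isocenter multiple-target (SIMT) distributions are pointwise
sums of single-target fields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import ndtr

__all__ = [
    "DoseGrid",
    "FieldSpec",
    "generate_single_field",
    "generate_simt",
]


@dataclass
class DoseGrid:
    """Dense 2D reference dose map with spacing/origin metadata.

    ``values[i, j]`` is the dose at SI position ``origin[0] + i*spacing[0]``
    and RL position ``origin[1] + j*spacing[1]``.  ``unit`` is carried as
    metadata only ("percent" of the global maximum, or "Gy"); all metrics
    normalise internally to percent of the global maximum.
    """

    values: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)
    origin: tuple[float, float] = (0.0, 0.0)
    unit: str = "percent"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 2:
            raise ValueError("dose grid must be 2D with at least 2 nodes per axis")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dose grid contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("dose values must be non-negative")
        if self.spacing[0] <= 0 or self.spacing[1] <= 0:
            raise ValueError(f"grid spacing must be positive, got {self.spacing}")

    # -- geometry ---------------------------------------------------------

    @property
    def n_si(self) -> int:
        return self.values.shape[0]

    @property
    def n_rl(self) -> int:
        return self.values.shape[1]

    @property
    def si_coords(self) -> np.ndarray:
        return self.origin[0] + self.spacing[0] * np.arange(self.n_si)

    @property
    def rl_coords(self) -> np.ndarray:
        return self.origin[1] + self.spacing[1] * np.arange(self.n_rl)

    @property
    def extent(self) -> tuple[tuple[float, float], tuple[float, float]]:
        """((si_min, si_max), (rl_min, rl_max)) covered by the grid nodes."""
        return (
            (self.origin[0], self.origin[0] + self.spacing[0] * (self.n_si - 1)),
            (self.origin[1], self.origin[1] + self.spacing[1] * (self.n_rl - 1)),
        )

    @property
    def max_dose(self) -> float:
        return float(self.values.max())

    def contains(self, pos_si, pos_rl, margin: float = 0.0) -> np.ndarray:
        """Boolean mask of positions inside the grid extent (inclusive).

        ``margin`` shrinks the extent on every side; used by the detector
        model to test whole footprints, not just centres.
        """
        (si_lo, si_hi), (rl_lo, rl_hi) = self.extent
        tol = 1e-9
        pos_si = np.asarray(pos_si, dtype=float)
        pos_rl = np.asarray(pos_rl, dtype=float)
        return (
            (pos_si >= si_lo + margin - tol)
            & (pos_si <= si_hi - margin + tol)
            & (pos_rl >= rl_lo + margin - tol)
            & (pos_rl <= rl_hi - margin + tol)
        )

    # -- interpolation ----------------------------------------------------

    def dose_at(self, pos_si, pos_rl):
        """Bilinear dose lookup at arbitrary positions inside the extent.

        Exact at grid nodes; raises for any position outside the extent
        (no extrapolation).  Accepts scalars or arrays and broadcasts.
        """
        pos_si = np.asarray(pos_si, dtype=float)
        pos_rl = np.asarray(pos_rl, dtype=float)
        scalar = pos_si.ndim == 0 and pos_rl.ndim == 0
        pos_si, pos_rl = np.broadcast_arrays(np.atleast_1d(pos_si), np.atleast_1d(pos_rl))
        if not bool(np.all(self.contains(pos_si, pos_rl))):
            raise ValueError("position outside grid extent; no extrapolation")

        fi = (pos_si - self.origin[0]) / self.spacing[0]
        fj = (pos_rl - self.origin[1]) / self.spacing[1]
        i0 = np.clip(np.floor(fi).astype(np.intp), 0, self.n_si - 2)
        j0 = np.clip(np.floor(fj).astype(np.intp), 0, self.n_rl - 2)
        wi = fi - i0
        wj = fj - j0
        v = self.values
        out = (
            v[i0, j0] * (1 - wi) * (1 - wj)
            + v[i0 + 1, j0] * wi * (1 - wj)
            + v[i0, j0 + 1] * (1 - wi) * wj
            + v[i0 + 1, j0 + 1] * wi * wj
        )
        return float(out[0]) if scalar else out


@dataclass
class FieldSpec:
    """Geometry and dose scale of one or more circular flat-top targets.

    centers           target centre positions in mm, (SI, RL)
    target_diameter   physical target diameter in mm (1 cm lesion default)
    penumbra_sigma    penumbra width parameter sigma in mm
    dose_max          nominal maximum dose (percent by convention)
    background        uniform out-of-field scatter, fraction of dose_max
    """

    centers: Sequence[tuple[float, float]] = ((0.0, 0.0),)
    target_diameter: float = 10.0
    penumbra_sigma: float = 2.0
    dose_max: float = 100.0
    background: float = 0.01

    def __post_init__(self) -> None:
        if self.target_diameter <= 0:
            raise ValueError("target_diameter must be positive")
        if self.penumbra_sigma <= 0:
            raise ValueError("penumbra_sigma must be positive")
        if not 0.0 <= self.background <= 0.05:
            raise ValueError("background must be within [0, 0.05]")
        if self.dose_max <= 0:
            raise ValueError("dose_max must be positive")
        self.centers = tuple((float(a), float(b)) for a, b in self.centers)
        if len(self.centers) == 0:
            raise ValueError("at least one target center required")

    @property
    def radius(self) -> float:
        return self.target_diameter / 2.0


def _centered_coords(extent_mm: float, spacing_mm: float) -> np.ndarray:
    if spacing_mm <= 0:
        raise ValueError("grid spacing must be positive")
    if extent_mm <= 0:
        raise ValueError("grid extent must be positive")
    half = extent_mm / 2.0
    n = int(round(extent_mm / spacing_mm))
    return -half + spacing_mm * np.arange(n + 1)


def _analytic_dose(spec: FieldSpec, si: np.ndarray, rl: np.ndarray) -> np.ndarray:
    """Evaluate the erf flat-top model (sum over targets) on a meshgrid."""
    acc = np.zeros((si.size, rl.size))
    SI, RL = np.meshgrid(si, rl, indexing="ij")
    for csi, crl in spec.centers:
        r = np.hypot(SI - csi, RL - crl)
        acc += ndtr((spec.radius - r) / spec.penumbra_sigma)
    return spec.background * spec.dose_max + (1.0 - spec.background) * spec.dose_max * acc


def generate_single_field(
    spec: FieldSpec, extent_mm: float = 200.0, spacing_mm: float = 1.0
) -> DoseGrid:
    """Steep single-field distribution for one circular target.

    The extent must cover the target plus at least a 3 cm margin on every
    side so the penumbra and analysis threshold region are fully contained.
    """
    if len(spec.centers) != 1:
        raise ValueError("generate_single_field requires exactly one target center")
    csi, crl = spec.centers[0]
    need = max(abs(csi), abs(crl)) + spec.radius + 30.0
    if extent_mm / 2.0 < need:
        raise ValueError(
            f"extent {extent_mm} mm too small: target plus 3 cm margin needs >= {2 * need:g} mm"
        )
    si = _centered_coords(extent_mm, spacing_mm)
    values = _analytic_dose(spec, si, si)
    return DoseGrid(
        values=values,
        spacing=(spacing_mm, spacing_mm),
        origin=(float(si[0]), float(si[0])),
        unit="percent" if spec.dose_max == 100.0 else "Gy",
        meta={"scenario": "single_field", "spec": spec},
    )


def generate_simt(
    spec: FieldSpec | None = None,
    extent_mm: float = 240.0,
    spacing_mm: float = 1.0,
) -> DoseGrid:
    """Single-isocenter multiple-target distribution (two 1 cm targets).

    Default geometry offsets the targets +-60 mm from the isocenter along
    SI, emulating two brain metastases treated around one isocenter.  The
    dose is the pointwise sum of the per-target profiles (no clipping or
    renormalisation); when targets are well separated each local maximum
    reaches the nominal Dmax.  Overlapping targets (separation smaller than
    diameter + 6 sigma) are flagged in ``meta['overlap_warning']``.
    """
    if spec is None:
        spec = FieldSpec(centers=((60.0, 0.0), (-60.0, 0.0)))
    if len(spec.centers) == 1:
        return generate_single_field(spec, extent_mm, spacing_mm)

    need = max(max(abs(a), abs(b)) for a, b in spec.centers) + spec.radius + 30.0
    if extent_mm / 2.0 < need:
        raise ValueError(
            f"extent {extent_mm} mm too small: targets plus 3 cm margin need >= {2 * need:g} mm"
        )
    overlap = False
    cs = spec.centers
    for i in range(len(cs)):
        for j in range(i + 1, len(cs)):
            sep = math.hypot(cs[i][0] - cs[j][0], cs[i][1] - cs[j][1])
            if sep < spec.target_diameter + 6.0 * spec.penumbra_sigma:
                overlap = True
    si = _centered_coords(extent_mm, spacing_mm)
    values = _analytic_dose(spec, si, si)
    return DoseGrid(
        values=values,
        spacing=(spacing_mm, spacing_mm),
        origin=(float(si[0]), float(si[0])),
        unit="percent" if spec.dose_max == 100.0 else "Gy",
        meta={"scenario": "simt", "spec": spec, "overlap_warning": overlap},
    )
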