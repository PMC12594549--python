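"""Diode-array and film measurement models.

A measurement samples a :class:`~shiftqa.grids.DoseGrid` at the diode
positions of a :class:`DetectorLayout`, optionally displaced by a couch
shift, averaging the dose over each diode's rectangular active footprint
and applying multiplicative Gaussian noise.

Shift sign convention (one convention, used everywhere): a couch
translation that displaces the detector by +d along an axis in the beam
frame makes the diode nominally at coordinate x sample the dose at x + d.
Merged virtual-grid coordinates are therefore nominal position + shift.

The array default mirrors a general-purpose diode array with 10 mm pitch
whose diode units are elongated in SI (7 x 3 mm^2); the partial-volume
averaging over that footprint is the mechanism that blurs steep gradients
anisotropically.  ``film`` mode is a fine-pitch (1 mm) point-detector
stand-in for radiochromic film.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .grids import DoseGrid

__all__ = ["DetectorLayout", "NoiseModel", "Measurement", "sample", "film_sample"]

logger = logging.getLogger(__name__)

#: maximum quadrature step (mm) for footprint averaging
_QUAD_STEP = 0.5


@dataclass
class DetectorLayout:
    """Rectangular lattice of diodes.

    pitch      centre-to-centre spacing (SI, RL) in mm
    n_diodes   diode count per axis (SI, RL)
    origin     position of the first diode; ``None`` centres the lattice
               on the isocenter
    footprint  active-area size (SI, RL) in mm; 0 means a point detector
    mode       "array" or "film"
    """

    pitch: tuple[float, float] = (10.0, 10.0)
    n_diodes: tuple[int, int] = (21, 21)
    origin: Optional[tuple[float, float]] = None
    footprint: tuple[float, float] = (7.0, 3.0)
    mode: str = "array"

    def __post_init__(self) -> None:
        if self.pitch[0] <= 0 or self.pitch[1] <= 0:
            raise ValueError("detector pitch must be positive")
        if self.n_diodes[0] < 1 or self.n_diodes[1] < 1:
            raise ValueError("need at least one diode per axis")
        if self.footprint[0] < 0 or self.footprint[1] < 0:
            raise ValueError("footprint must be non-negative")
        if self.mode not in ("array", "film"):
            raise ValueError(f"unknown detector mode {self.mode!r}")
        if self.origin is None:
            self.origin = (
                -self.pitch[0] * (self.n_diodes[0] - 1) / 2.0,
                -self.pitch[1] * (self.n_diodes[1] - 1) / 2.0,
            )

    @classmethod
    def film(cls, extent_mm: float = 200.0, pitch_mm: float = 1.0) -> "DetectorLayout":
        """Fine-pitch point-detector layout standing in for film."""
        n = int(round(extent_mm / pitch_mm)) + 1
        return cls(
            pitch=(pitch_mm, pitch_mm),
            n_diodes=(n, n),
            footprint=(0.0, 0.0),
            mode="film",
        )

    def positions(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened nominal (SI, RL) diode coordinates."""
        si = self.origin[0] + self.pitch[0] * np.arange(self.n_diodes[0])
        rl = self.origin[1] + self.pitch[1] * np.arange(self.n_diodes[1])
        SI, RL = np.meshgrid(si, rl, indexing="ij")
        return SI.ravel(), RL.ravel()


@dataclass
class NoiseModel:
    """Multiplicative Gaussian measurement noise: dose * (1 + N(0, sd)).

    The same seed and inputs always give the same measurement.
    """

    relative_sd: float = 0.005
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.relative_sd < 0:
            raise ValueError("relative_sd must be non-negative")


@dataclass
class Measurement:
    """Sparse set of (position, dose) samples in the beam frame."""

    pos_si: np.ndarray
    pos_rl: np.ndarray
    dose: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pos_si = np.asarray(self.pos_si, dtype=float)
        self.pos_rl = np.asarray(self.pos_rl, dtype=float)
        self.dose = np.asarray(self.dose, dtype=float)
        if not (self.pos_si.shape == self.pos_rl.shape == self.dose.shape):
            raise ValueError("position and dose arrays must have equal shape")
        if np.any(self.dose < 0):
            raise ValueError("measured doses must be non-negative")

    def __len__(self) -> int:
        return self.pos_si.size


def _quadrature_offsets(width: float) -> np.ndarray:
    """Midpoint-rule abscissae covering ``width`` mm at <= 0.5 mm step."""
    if width <= 0:
        return np.zeros(1)
    n = max(1, math.ceil(width / _QUAD_STEP))
    return ((np.arange(n) + 0.5) / n - 0.5) * width


def sample(
    grid: DoseGrid,
    layout: DetectorLayout,
    shift_mm: tuple[float, float] = (0.0, 0.0),
    noise: Optional[NoiseModel] = None,
    shift_error_sd: float = 0.0,
) -> Measurement:
    """Simulate one acquisition of ``grid`` by the array under a couch shift.

    Each diode's sample position is its nominal position plus the shift.
    The sampled dose is the mean of the bilinear dose over the diode's
    active footprint, evaluated by regular midpoint quadrature at <= 0.5 mm
    step (a single centre point for point detectors), then scaled by
    (1 + eps) with eps ~ Normal(0, relative_sd).

    ``shift_error_sd`` (mm, default off) perturbs the *executed* couch
    shift by Normal(0, sd) per axis while the recorded sample coordinates
    keep the commanded shift - an unquantified real-world error source that
    propagates into merged virtual data.  The perturbation draws from the
    NoiseModel's generator, so a seeded NoiseModel keeps it reproducible.

    Diodes whose shifted footprint extends beyond the grid extent are
    dropped (count logged and stored in ``meta['n_dropped']``).  An
    acquisition in which every diode is dropped raises ``ValueError``.
    """
    rng = None
    if (noise is not None and noise.relative_sd > 0) or shift_error_sd > 0:
        rng = np.random.default_rng(noise.seed if noise is not None else None)
    executed = np.asarray(shift_mm, dtype=float)
    if shift_error_sd > 0:
        executed = executed + rng.normal(0.0, shift_error_sd, size=2)

    nom_si, nom_rl = layout.positions()
    pos_si = nom_si + executed[0]
    pos_rl = nom_rl + executed[1]

    half_si = layout.footprint[0] / 2.0
    half_rl = layout.footprint[1] / 2.0
    (si_lo, si_hi), (rl_lo, rl_hi) = grid.extent
    tol = 1e-9
    keep = (
        (pos_si - half_si >= si_lo - tol)
        & (pos_si + half_si <= si_hi + tol)
        & (pos_rl - half_rl >= rl_lo - tol)
        & (pos_rl + half_rl <= rl_hi + tol)
    )
    n_dropped = int(np.count_nonzero(~keep))
    if n_dropped:
        logger.info("dropped %d diode(s) with footprint outside the grid extent", n_dropped)
    pos_si, pos_rl = pos_si[keep], pos_rl[keep]
    if pos_si.size == 0:
        raise ValueError("no diode footprint lies inside the grid extent")

    off_si = _quadrature_offsets(layout.footprint[0])
    off_rl = _quadrature_offsets(layout.footprint[1])
    OSI, ORL = np.meshgrid(off_si, off_rl, indexing="ij")
    sub_si = pos_si[:, None] + OSI.ravel()[None, :]
    sub_rl = pos_rl[:, None] + ORL.ravel()[None, :]
    dose = grid.dose_at(sub_si, sub_rl).mean(axis=1)

    seed = noise.seed if noise is not None else None
    if noise is not None and noise.relative_sd > 0:
        dose = dose * (1.0 + rng.normal(0.0, noise.relative_sd, size=dose.shape))
        dose = np.maximum(dose, 0.0)

    # recorded coordinates carry the *commanded* shift: a couch-positioning
    # error shows up as dose sampled slightly off the recorded position
    rec_si = nom_si[keep] + shift_mm[0]
    rec_rl = nom_rl[keep] + shift_mm[1]
    return Measurement(
        pos_si=rec_si,
        pos_rl=rec_rl,
        dose=dose,
        meta={
            "mode": layout.mode,
            "pitch": layout.pitch,
            "footprint": layout.footprint,
            "shift": (float(shift_mm[0]), float(shift_mm[1])),
            "noise_sd": noise.relative_sd if noise is not None else 0.0,
            "noise_seed": seed,
            "shift_error_sd": shift_error_sd,
            "n_dropped": n_dropped,
        },
    )


def film_sample(
    grid: DoseGrid,
    noise: Optional[NoiseModel] = None,
    extent_mm: float = 200.0,
    pitch_mm: float = 1.0,
) -> Measurement:
    """Fine-pitch point sampling at the isocenter: the film stand-in."""
    return sample(grid, DetectorLayout.film(extent_mm, pitch_mm), (0.0, 0.0), noise)
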