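"""Independent brute-force gamma oracle for the test suite.

Exhaustive dense-lattice search at a fixed step (0.05 mm by default) using
scipy's RegularGridInterpolator, written deliberately without reference to
the production gamma implementation: per-point Python loop, full square
candidate lattice clipped to the circular search region and the grid
extent, explicit minimum.
"""

import numpy as np
from scipy.interpolate import RegularGridInterpolator


def gamma_bruteforce(
    grid,
    pos_si,
    pos_rl,
    doses,
    dose_diff,
    dta,
    normalization="global",
    search_radius_factor=3.0,
    step=0.05,
):
    """Return the gamma value of each evaluated point by exhaustive search."""
    interp = RegularGridInterpolator(
        (grid.si_coords, grid.rl_coords), grid.values, method="linear", bounds_error=True
    )
    (si_lo, si_hi), (rl_lo, rl_hi) = grid.extent
    ref_max = float(grid.values.max())
    radius = search_radius_factor * dta
    k = int(np.floor(radius / step + 1e-9))
    line = step * np.arange(-k, k + 1)

    out = np.empty(len(doses))
    for idx, (psi, prl, dmeas) in enumerate(zip(pos_si, pos_rl, doses)):
        csi = psi + line[:, None] + np.zeros((1, line.size))
        crl = prl + np.zeros((line.size, 1)) + line[None, :]
        dist2 = (csi - psi) ** 2 + (crl - prl) ** 2
        ok = (
            (dist2 <= radius**2 + 1e-12)
            & (csi >= si_lo - 1e-9)
            & (csi <= si_hi + 1e-9)
            & (crl >= rl_lo - 1e-9)
            & (crl <= rl_hi + 1e-9)
        )
        pts = np.stack(
            [np.clip(csi[ok], si_lo, si_hi), np.clip(crl[ok], rl_lo, rl_hi)], axis=1
        )
        dref = interp(pts)
        if normalization == "global":
            dd_abs = dose_diff / 100.0 * ref_max
        else:
            dd_abs = dose_diff / 100.0 * float(interp([[psi, prl]])[0])
        g2 = dist2[ok] / dta**2 + (dref - dmeas) ** 2 / dd_abs**2
        out[idx] = np.sqrt(g2.min())
    return out
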