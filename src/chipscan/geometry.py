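"""Oscillation limits of a monocrystalline chip substrate.

Fixed-target serial-crystallography chips grown on a Z-cut alpha-quartz
wafer sit perpendicular to the X-ray beam.  During a monochromatic
oscillation the wafer itself is a single crystal with a ~5 Å cell, so a
substrate Bragg reflection eventually swings onto the Ewald sphere and
floods the detector.  This module computes how far the wafer may rotate
(±omega, from the perpendicular starting orientation) before the first
substrate reflection fires, as a function of X-ray wavelength and of the
resolution cutoff beyond which substrate reflections no longer overlap
protein diffraction.

Geometry
--------
For a trigonal cell the reciprocal vector of reflection (h, k, l) has an
in-plane magnitude j * a_star with joint index j = sqrt(h^2 + h*k + k^2),
and an out-of-plane (beam-parallel) component l * c_star.  Writing

    alpha = arctan(|l| * c_star / (j * a_star))      tilt out of the wafer plane
    psi   = arcsin(lambda * d_star / 2)              Bragg offset

with d_star = sqrt(j^2 a_star^2 + l^2 c_star^2), the reflection (or one of
its Friedel/azimuthal mates) first satisfies the Bragg condition at a
rotation of

    omega = |alpha - psi|

when the in-plane component lies in the rotation plane (the worst-case
azimuth, giving a conservative guarantee).  If lambda * d_star / 2 > 1 the
reciprocal point lies outside the Ewald sphere diameter and can never
diffract: the limit is infinite.

A brute-force rotation-scan oracle (:func:`ewald_first_crossing`) checks
the closed form numerically and is used throughout the test-suite.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ReciprocalCell",
    "Reflection",
    "OscillationLimit",
    "QUARTZ_CELL",
    "joint_index",
    "reciprocal_spacing",
    "d_spacing",
    "oscillation_limit",
    "ewald_first_crossing",
    "enumerate_reflections",
    "chip_oscillation_limit",
    "limit_curve",
    "reflection_curve",
]

#: keV * Angstrom conversion constant (E = KEV_ANGSTROM / lambda)
KEV_ANGSTROM = 12.3984


@dataclass(frozen=True)
class ReciprocalCell:
    """Trigonal reciprocal cell: a* = b* in-plane, c* along the wafer normal.

    Parameters are reciprocal lengths in 1/Angstrom.
    """

    a_star: float
    c_star: float

    def __post_init__(self) -> None:
        if self.a_star <= 0 or self.c_star <= 0:
            raise ValueError("reciprocal cell constants must be positive")


#: Alpha-quartz reciprocal cell of the chip substrate.
QUARTZ_CELL = ReciprocalCell(a_star=0.235, c_star=0.185)


def joint_index(h: int, k: int) -> float:
    """Joint in-plane index j = sqrt(h^2 + h*k + k^2) of a trigonal cell.

    The quadratic form is positive definite, so j >= 0 for all integer
    (h, k) and j = 0 only for h = k = 0.  Symmetric under h <-> k.
    """
    return math.sqrt(h * h + h * k + k * k)


@dataclass(frozen=True)
class Reflection:
    """A substrate reflection indexed by integer Miller indices."""

    h: int
    k: int
    l: int

    @property
    def j(self) -> float:
        """Joint in-plane index of this reflection."""
        return joint_index(self.h, self.k)

    @property
    def hkl(self) -> tuple[int, int, int]:
        return (self.h, self.k, self.l)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"({self.h}{self.k}{self.l})"


def reciprocal_spacing(refl: Reflection, cell: ReciprocalCell) -> float:
    """Reciprocal spacing d* = sqrt(j^2 a*^2 + l^2 c*^2) in 1/Angstrom.

    Raises ValueError for the all-zero reflection, which has no spacing.
    """
    if refl.h == 0 and refl.k == 0 and refl.l == 0:
        raise ValueError("reflection (000) has no reciprocal spacing")
    j = refl.j
    return math.hypot(j * cell.a_star, refl.l * cell.c_star)


def d_spacing(refl: Reflection, cell: ReciprocalCell) -> float:
    """Lattice spacing d = 1/d* in Angstrom."""
    return 1.0 / reciprocal_spacing(refl, cell)


@dataclass(frozen=True)
class OscillationLimit:
    """Half-range oscillation limit ±omega (degrees) at a given wavelength.

    ``infinite`` marks a reflection (or candidate set) that can never meet
    the Bragg condition at this wavelength; ``omega_deg`` is then +inf.
    """

    omega_deg: float
    wavelength: float
    reflection: Reflection | None
    infinite: bool = False


def oscillation_limit(
    refl: Reflection, wavelength: float, cell: ReciprocalCell = QUARTZ_CELL
) -> OscillationLimit:
    """Closed-form oscillation limit omega = |alpha - psi| for one reflection.

    alpha is the tilt of the reciprocal vector out of the wafer plane
    (90 deg for l-only reflections), psi = arcsin(lambda d*/2) the Bragg
    offset.  Returns an infinite limit when lambda d*/2 > 1.
    """
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    d_star = reciprocal_spacing(refl, cell)  # validates indices
    s = wavelength * d_star / 2.0
    if s > 1.0:
        return OscillationLimit(math.inf, wavelength, refl, infinite=True)
    j = refl.j
    alpha = math.atan2(abs(refl.l) * cell.c_star, j * cell.a_star)
    psi = math.asin(s)
    return OscillationLimit(math.degrees(abs(alpha - psi)), wavelength, refl)


def ewald_first_crossing(
    refl: Reflection,
    wavelength: float,
    cell: ReciprocalCell = QUARTZ_CELL,
    step: float = 0.001,
    tol: float = 1e-6,
) -> OscillationLimit:
    """Brute-force rotation-scan oracle for :func:`oscillation_limit`.

    The reciprocal vector is placed at the worst-case azimuth: in-plane
    component ``j * a_star`` along +x (the rotation plane is x-z, the beam
    along +z, rotation about y).  Both Friedel mates (±l c* along z) are
    rotated in both senses in ``step``-degree increments; the first sign
    change of

        f(w) = |R_y(w) P0 + s0/lambda| - 1/lambda

    is refined by bisection to ``tol`` degrees.  Returns an infinite limit
    when no crossing occurs below 90 degrees.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    reciprocal_spacing(refl, cell)  # validate
    x0 = refl.j * cell.a_star
    inv_lam = 1.0 / wavelength

    def f(omega_deg: np.ndarray | float, z0: float, sense: float):
        w = np.radians(np.asarray(omega_deg, dtype=float)) * sense
        x = x0 * np.cos(w) + z0 * np.sin(w)
        z = -x0 * np.sin(w) + z0 * np.cos(w)
        return np.sqrt(x * x + (z + inv_lam) ** 2) - inv_lam

    omegas = np.arange(0.0, 90.0 + step, step)
    best = math.inf
    z_values = {refl.l * cell.c_star, -refl.l * cell.c_star}
    for z0 in z_values:
        for sense in (1.0, -1.0):
            vals = f(omegas, z0, sense)
            signs = np.sign(vals)
            # first index where the sign differs from the previous sample
            change = np.nonzero(signs[1:] * signs[:-1] <= 0)[0]
            # ignore a crossing exactly at the start only if f(0) == 0
            # (the wafer is then already diffracting; omega = 0)
            if vals[0] == 0.0:
                return OscillationLimit(0.0, wavelength, refl)
            if change.size == 0:
                continue
            i = int(change[0])
            lo, hi = omegas[i], omegas[i + 1]
            flo = float(vals[i])
            while hi - lo > tol:
                mid = 0.5 * (lo + hi)
                fm = float(f(mid, z0, sense))
                if fm == 0.0:
                    lo = hi = mid
                    break
                if (fm > 0) == (flo > 0):
                    lo, flo = mid, fm
                else:
                    hi = mid
            best = min(best, 0.5 * (lo + hi))
    if math.isinf(best):
        return OscillationLimit(math.inf, wavelength, refl, infinite=True)
    return OscillationLimit(best, wavelength, refl)


def enumerate_reflections(max_index: int) -> list[Reflection]:
    """All reflections with |h|, |k|, |l| <= max_index, excluding (000)."""
    rng = range(-max_index, max_index + 1)
    return [
        Reflection(h, k, l)
        for h, k, l in itertools.product(rng, rng, rng)
        if (h, k, l) != (0, 0, 0)
    ]


def chip_oscillation_limit(
    wavelength: float,
    cell: ReciprocalCell = QUARTZ_CELL,
    resolution_cutoff: float = 1.55,
    max_index: int = 4,
    reflections: Sequence[Reflection] | None = None,
) -> OscillationLimit:
    """Minimum oscillation limit over all substrate reflections of concern.

    Candidates are reflections with lattice spacing d strictly greater than
    ``resolution_cutoff`` (substrate reflections at higher resolution than
    the protein data need not be avoided).  The default cutoff of 1.55 Å
    keeps (100) and (201) in play while excluding (211) (d = 1.5416 Å);
    protein diffraction rarely exceeds ~1.5 Å.

    An explicit ``reflections`` sequence overrides the enumeration (the
    cutoff still applies).  Raises ValueError if no candidate survives.
    """
    if resolution_cutoff <= 0:
        raise ValueError("resolution_cutoff must be positive")
    if reflections is None:
        if max_index < 2:
            raise ValueError("max_index must be at least 2")
        reflections = enumerate_reflections(max_index)
    candidates = [
        r for r in reflections if d_spacing(r, cell) > resolution_cutoff
    ]
    if not candidates:
        raise ValueError("no candidate reflections above the resolution cutoff")
    def canonical(r: Reflection):
        # prefer low, non-negative indices among symmetry-equivalent mates
        return (
            abs(r.h) + abs(r.k) + abs(r.l),
            r.h < 0,
            r.k < 0,
            r.l < 0,
            (-r.h, -r.k, -r.l),
        )

    best: OscillationLimit | None = None
    for r in sorted(candidates, key=canonical):
        lim = oscillation_limit(r, wavelength, cell)
        if best is None or lim.omega_deg < best.omega_deg:
            best = lim
    assert best is not None
    if math.isinf(best.omega_deg):
        return OscillationLimit(math.inf, wavelength, None, infinite=True)
    return best


def limit_curve(
    cell: ReciprocalCell,
    wavelengths: Iterable[float],
    resolution_cutoff: float = 1.55,
    max_index: int = 4,
) -> pd.DataFrame:
    """Envelope of the chip oscillation limit over a wavelength grid.

    Returns a DataFrame with one row per wavelength: ``wavelength_A``,
    ``energy_keV``, ``omega_deg`` and the limiting reflection's indices
    (NaN columns where no reflection can diffract).
    """
    grid = [float(w) for w in wavelengths]
    if not grid:
        raise ValueError("wavelength grid is empty")
    if any(w <= 0 for w in grid):
        raise ValueError("all wavelengths must be positive")
    rows = []
    for lam in grid:
        lim = chip_oscillation_limit(
            lam, cell, resolution_cutoff=resolution_cutoff, max_index=max_index
        )
        r = lim.reflection
        rows.append(
            {
                "wavelength_A": lam,
                "energy_keV": KEV_ANGSTROM / lam,
                "omega_deg": lim.omega_deg,
                "limiting_h": r.h if r else np.nan,
                "limiting_k": r.k if r else np.nan,
                "limiting_l": r.l if r else np.nan,
            }
        )
    return pd.DataFrame(rows)


def reflection_curve(
    refl: Reflection, cell: ReciprocalCell, wavelengths: Iterable[float]
) -> pd.DataFrame:
    """Per-reflection omega(lambda) curve, for plotting against the envelope."""
    rows = []
    for lam in wavelengths:
        lim = oscillation_limit(refl, float(lam), cell)
        rows.append(
            {
                "wavelength_A": float(lam),
                "energy_keV": KEV_ANGSTROM / float(lam),
                "omega_deg": lim.omega_deg,
            }
        )
    return pd.DataFrame(rows)
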