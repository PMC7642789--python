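"""Substrate oscillation-limit geometry.

Frozen expected values marked "oracle" below were computed with the
brute-force Ewald rotation-scan (ewald_first_crossing), which the
closed form is also checked against directly.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chipscan.geometry import (
    QUARTZ_CELL,
    ReciprocalCell,
    Reflection,
    chip_oscillation_limit,
    d_spacing,
    ewald_first_crossing,
    joint_index,
    limit_curve,
    oscillation_limit,
    reciprocal_spacing,
    reflection_curve,
)


@pytest.mark.parametrize(
    "h,k,expected",
    [(1, 0, 1.0), (0, 0, 0.0), (2, 1, math.sqrt(7)), (1, 1, math.sqrt(3))],
)
def test_joint_index(h, k, expected):
    assert joint_index(h, k) == pytest.approx(expected)
    assert joint_index(k, h) == pytest.approx(expected)


@pytest.mark.parametrize(
    "hkl,d_star",
    [
        ((1, 0, 0), 0.235),
        ((0, 0, 1), 0.185),
        ((2, 1, 1), 0.64869),
    ],
)
def test_reciprocal_spacing_quartz(hkl, d_star):
    refl = Reflection(*hkl)
    assert reciprocal_spacing(refl, QUARTZ_CELL) == pytest.approx(d_star, abs=1e-4)
    assert d_spacing(refl, QUARTZ_CELL) * reciprocal_spacing(refl, QUARTZ_CELL) == (
        pytest.approx(1.0)
    )


def test_quartz_211_d_spacing_is_1_54_angstrom():
    """The (211) substrate reflection sits at 1.54 Å resolution."""
    d = d_spacing(Reflection(2, 1, 1), QUARTZ_CELL)
    assert f"{d:.3g}" == "1.54"


def test_zero_reflection_rejected():
    with pytest.raises(ValueError):
        reciprocal_spacing(Reflection(0, 0, 0), QUARTZ_CELL)
    with pytest.raises(ValueError):
        oscillation_limit(Reflection(0, 0, 0), 1.0, QUARTZ_CELL)


def test_invalid_cell_and_wavelength():
    with pytest.raises(ValueError):
        ReciprocalCell(a_star=-1.0, c_star=0.2)
    with pytest.raises(ValueError):
        oscillation_limit(Reflection(1, 0, 0), -1.0, QUARTZ_CELL)


@pytest.mark.parametrize(
    "hkl,wavelength,omega",
    [
        ((1, 0, 0), 1.0, 6.7478),  # oracle
        ((2, 0, 1), 1.0, 6.8570),  # oracle
        ((2, 1, 1), 1.0, 2.3557),  # oracle; why (211) needs the cutoff
        ((2, 0, 1), 1.13, 4.9038),  # oracle
    ],
)
def test_oscillation_limit_quartz(hkl, wavelength, omega):
    lim = oscillation_limit(Reflection(*hkl), wavelength, QUARTZ_CELL)
    assert lim.omega_deg == pytest.approx(omega, abs=2e-3)
    assert not lim.infinite


def test_zero_wavelength_limit():
    """For an in-plane reflection the limit vanishes with the wavelength."""
    lim = oscillation_limit(Reflection(1, 0, 0), 1e-9, QUARTZ_CELL)
    assert lim.omega_deg == pytest.approx(0.0, abs=1e-6)


def test_never_diffracting_reflection_is_infinite():
    # lambda * d* / 2 = 9 * 0.235 / 2 > 1: outside the Ewald sphere diameter
    closed = oscillation_limit(Reflection(1, 0, 0), 9.0, QUARTZ_CELL)
    scanned = ewald_first_crossing(Reflection(1, 0, 0), 9.0, QUARTZ_CELL, step=0.05)
    assert closed.infinite and scanned.infinite
    assert math.isinf(closed.omega_deg)


@pytest.mark.parametrize("hkl", [(1, 0, 0), (1, 1, 0), (2, 0, 0)])
def test_in_plane_reflection_is_pure_bragg_offset(hkl):
    """For l = 0 the limit equals arcsin(lambda d*/2) exactly."""
    refl = Reflection(*hkl)
    lam = 1.1
    d_star = reciprocal_spacing(refl, QUARTZ_CELL)
    expected = math.degrees(math.asin(lam * d_star / 2.0))
    assert oscillation_limit(refl, lam, QUARTZ_CELL).omega_deg == pytest.approx(expected)


@pytest.mark.parametrize("hkl", [(1, 0, 0), (2, 0, 1), (2, 1, 1)])
@pytest.mark.parametrize("lam", [0.9, 1.2])
def test_closed_form_matches_rotation_scan(hkl, lam):
    refl = Reflection(*hkl)
    closed = oscillation_limit(refl, lam, QUARTZ_CELL)
    scanned = ewald_first_crossing(refl, lam, QUARTZ_CELL, step=0.01)
    assert closed.omega_deg == pytest.approx(scanned.omega_deg, abs=0.01)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    h=st.integers(-3, 3),
    k=st.integers(-3, 3),
    l=st.integers(-3, 3),
    lam=st.floats(0.5, 2.0),
)
def test_limit_symmetries(h, k, l, lam):
    """omega is invariant under Friedel inversion and the h<->k swap."""
    if (h, k, l) == (0, 0, 0):
        return
    base = oscillation_limit(Reflection(h, k, l), lam, QUARTZ_CELL).omega_deg
    friedel = oscillation_limit(Reflection(-h, -k, -l), lam, QUARTZ_CELL).omega_deg
    swapped = oscillation_limit(Reflection(k, h, l), lam, QUARTZ_CELL).omega_deg
    assert base == pytest.approx(friedel, abs=1e-9) or (
        math.isinf(base) and math.isinf(friedel)
    )
    assert base == pytest.approx(swapped, abs=1e-9) or (
        math.isinf(base) and math.isinf(swapped)
    )


class TestChipLimit:
    def test_one_angstrom(self):
        lim = chip_oscillation_limit(1.0, QUARTZ_CELL, resolution_cutoff=1.55)
        assert lim.omega_deg == pytest.approx(6.7478, abs=2e-3)  # oracle
        assert abs(lim.reflection.h) == 1 or abs(lim.reflection.k) == 1
        assert lim.reflection.l == 0  # the (100) family

    def test_eleven_kev(self):
        lim = chip_oscillation_limit(1.13, QUARTZ_CELL, resolution_cutoff=1.55)
        assert lim.omega_deg == pytest.approx(4.9038, abs=2e-3)  # oracle
        assert abs(lim.reflection.l) == 1  # the (201) family

    def test_singleton_candidate_set(self):
        only = [Reflection(1, 0, 0)]
        lim = chip_oscillation_limit(1.0, QUARTZ_CELL, reflections=only)
        assert lim.omega_deg == pytest.approx(6.7478, abs=2e-3)

    def test_lower_cutoff_never_raises_the_limit(self):
        loose = chip_oscillation_limit(1.0, QUARTZ_CELL, resolution_cutoff=1.55)
        tight = chip_oscillation_limit(1.0, QUARTZ_CELL, resolution_cutoff=1.40)
        assert tight.omega_deg <= loose.omega_deg + 1e-12

    def test_empty_candidate_set_raises(self):
        with pytest.raises(ValueError):
            chip_oscillation_limit(1.0, QUARTZ_CELL, resolution_cutoff=10.0)


class TestLimitCurve:
    def test_single_point_matches_chip_limit(self):
        table = limit_curve(QUARTZ_CELL, [1.0])
        lim = chip_oscillation_limit(1.0, QUARTZ_CELL)
        assert table.loc[0, "omega_deg"] == pytest.approx(lim.omega_deg)
        assert table.loc[0, "energy_keV"] == pytest.approx(12.3984)

    def test_known_rows(self):
        table = limit_curve(QUARTZ_CELL, [1.0, 1.13])
        assert table["omega_deg"].tolist() == pytest.approx(
            [6.7478, 4.9038], abs=2e-3
        )

    def test_in_plane_curve_is_strictly_monotone(self):
        # for l = 0 the limit equals the Bragg offset arcsin(lambda d*/2),
        # strictly increasing in wavelength over (0, 2/d*)
        refl = Reflection(1, 0, 0)
        d_star = reciprocal_spacing(refl, QUARTZ_CELL)
        grid = np.linspace(0.1, 2.0 / d_star - 0.1, 25)
        curve = reflection_curve(refl, QUARTZ_CELL, grid)
        assert np.all(np.diff(curve["omega_deg"].to_numpy()) > 0)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            limit_curve(QUARTZ_CELL, [])
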