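"""Closed-form wetting physics: Wenzel/Cassie-Baxter limits, the combined
two-tier model, hysteresis scaling, meniscus penetration, and the
tilted-plate droplet retention mechanics."""

import math

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

import leafwet as lw
from leafwet import (
    PINNED,
    DropletSpec,
    FlatWaxAngles,
    MeasuredTiltAngles,
    NanoWaxGeometry,
    NanoWettingState,
    SurfaceMorphology,
)

# ---------------------------------------------------------------- basic laws


@pytest.mark.parametrize(
    "r, theta, expected, tol",
    [
        (1.0, 101.0, 101.0, 1e-9),       # identity at r = 1
        (1.13, 101.0, 103.0, 2.0),       # heat-treated leaf, Wenzel limit
        (1.2, 90.0, 90.0, 1e-9),         # cos 90 = 0
    ],
)
def test_wenzel_angle(r, theta, expected, tol):
    assert lw.wenzel_angle(r, theta) == pytest.approx(expected, abs=tol)


def test_wenzel_nonphysical_raises_instead_of_clamping():
    with pytest.raises(lw.NonPhysicalRegimeError):
        lw.wenzel_angle(4.0, 160.0)


@pytest.mark.parametrize(
    "phi, theta, expected, tol",
    [
        (1.0, 101.0, 101.0, 1e-9),           # full contact recovers flat angle
        (0.0, 101.0, 180.0, 1e-9),           # pure air interface
        (0.0, 45.0, 180.0, 1e-9),
        (0.25, 101.0, 142.9037, 0.01),       # frozen direct evaluation
    ],
)
def test_cassie_baxter_angle(phi, theta, expected, tol):
    assert lw.cassie_baxter_angle(phi, theta) == pytest.approx(expected, abs=tol)


def test_cassie_baxter_matches_scalar_root():
    """Independent check: invert cos(theta*) numerically instead of acos."""
    phi, theta = 0.25, 101.0
    target = phi * (math.cos(math.radians(theta)) + 1) - 1
    star = brentq(lambda t: math.cos(math.radians(t)) - target, 1e-9, 180 - 1e-9)
    assert lw.cassie_baxter_angle(phi, theta) == pytest.approx(star, abs=1e-9)


@pytest.mark.parametrize(
    "r, phi, alpha, expected",
    [
        (1.16, 0.25, 1.0, 158.0),   # green leaf
        (1.07, 0.25, 0.46, 121.0),  # brown leaf
        (1.10, 0.25, 1.0, 152.0),   # vacuum-dried leaf
    ],
)
def test_combined_angle_reference_states(r, phi, alpha, expected):
    morph = SurfaceMorphology(r, phi, alpha)
    assert lw.combined_angle(morph, 101.0) == pytest.approx(expected, abs=2.0)


@given(
    r=st.floats(1.0, 1.5),
    phi=st.floats(0.0, 1.0),
    theta=st.floats(30.0, 150.0),
)
@settings(max_examples=200, deadline=None)
def test_combined_angle_limit_reductions(r, phi, theta):
    """alpha = 0 is Wenzel; alpha = 1 matches the uniformly waxed form and,
    at r = 1, plain Cassie-Baxter — all to 1e-12."""
    c = math.cos(math.radians(theta))
    assume(abs(r * c) <= 1 - 1e-9)
    wenzel = lw.combined_angle(SurfaceMorphology(r, phi, 0.0), theta)
    assert wenzel == pytest.approx(lw.wenzel_angle(r, theta), abs=1e-12)

    cos_green = r * phi * c - r * (1 - phi)  # uniformly waxed closed form
    assume(abs(cos_green) <= 1 - 1e-9)
    green = lw.combined_angle(SurfaceMorphology(r, phi, 1.0), theta)
    assert math.cos(math.radians(green)) == pytest.approx(cos_green, abs=1e-12)

    cb = lw.combined_angle(SurfaceMorphology(1.0, phi, 1.0), theta)
    assert cb == pytest.approx(lw.cassie_baxter_angle(phi, theta), abs=1e-12)


@given(
    r=st.floats(1.0, 1.3),
    alpha=st.floats(0.0, 1.0),
    theta=st.floats(80.0, 120.0),
    phi_lo=st.floats(0.0, 1.0),
    phi_hi=st.floats(0.0, 1.0),
)
@settings(max_examples=100, deadline=None)
def test_combined_angle_monotone_in_phi(r, alpha, theta, phi_lo, phi_hi):
    """More liquid/solid contact on the tips never raises the apparent angle."""
    phi_lo, phi_hi = sorted((phi_lo, phi_hi))
    try:
        lo = lw.combined_angle(SurfaceMorphology(r, phi_lo, alpha), theta)
        hi = lw.combined_angle(SurfaceMorphology(r, phi_hi, alpha), theta)
    except lw.NonPhysicalRegimeError:
        assume(False)
    assert hi <= lo + 1e-9


# ---------------------------------------------------------------- hysteresis


def test_hysteresis_structureless_surface_returns_flat_value(flat_wax):
    morph = SurfaceMorphology(1.0, 1.0, 1.0)
    dh = lw.hysteresis_leaf(morph, flat_wax, flat_wax.theta_mean)
    assert dh == pytest.approx(flat_wax.hysteresis, abs=1e-12)
    dh2 = lw.hysteresis_leaf_derivative(morph, flat_wax, flat_wax.theta_mean)
    assert dh2 == pytest.approx(flat_wax.hysteresis, abs=1e-12)


@pytest.mark.parametrize(
    "r, phi, alpha, theta_star, expected",
    [
        (1.16, 0.25, 1.0, 158.0, 3.431),    # 1.16*0.25*31*sin158/sin101
        (1.07, 0.25, 0.46, 121.0, 18.971),  # brown leaf, as-printed form
    ],
)
def test_hysteresis_as_printed_frozen_values(flat_wax, r, phi, alpha,
                                             theta_star, expected):
    morph = SurfaceMorphology(r, phi, alpha)
    assert lw.hysteresis_leaf(morph, flat_wax, theta_star) == pytest.approx(
        expected, abs=0.01
    )


def test_hysteresis_variants_are_sine_reciprocals(flat_wax):
    """The two exposed forms differ exactly by the squared sine ratio."""
    morph = SurfaceMorphology(1.07, 0.25, 0.46)
    ts = 121.0
    printed = lw.hysteresis_leaf(morph, flat_wax, ts)
    deriv = lw.hysteresis_leaf_derivative(morph, flat_wax, ts)
    ratio = (math.sin(math.radians(ts)) / math.sin(math.radians(101.0))) ** 2
    assert printed / deriv == pytest.approx(ratio, rel=1e-12)


def test_apparent_wetting_splits_hysteresis_symmetrically(flat_wax):
    aw = lw.apparent_wetting(SurfaceMorphology(1.07, 0.25, 0.46), flat_wax)
    assert aw.theta_star_adv - aw.theta_star_rec == pytest.approx(
        aw.hysteresis_leaf, abs=1e-12
    )
    assert aw.theta_star_adv + aw.theta_star_rec == pytest.approx(
        2 * aw.theta_star, abs=1e-9
    )


# ------------------------------------------------------- nanoscale meniscus


def test_meniscus_depth_closed_forms():
    # theta = 180: sin(90) = 1, bracket collapses to 1, so h = d_wax
    d = 40.0
    geom = NanoWaxGeometry(spacing=2 * d, tubule_height=1.0,
                           theta_adv_wall=180.0 - 1e-9)
    assert lw.meniscus_depth(geom) == pytest.approx(d, rel=1e-6)
    # theta = 135: h/d = sqrt(2) - 1
    geom = NanoWaxGeometry(spacing=2 * d, tubule_height=1.0, theta_adv_wall=135.0)
    assert lw.meniscus_depth(geom) / d == pytest.approx(math.sqrt(2) - 1, rel=1e-12)


def test_meniscus_depth_green_leaf_geometry():
    """Green-leaf tubules (spacing 75 nm, wall angle 117 deg) give ~9 nm."""
    geom = NanoWaxGeometry(spacing=75.0, tubule_height=1000.0, theta_adv_wall=117.0)
    assert lw.meniscus_depth(geom) == pytest.approx(9.003, abs=0.01)


def test_meniscus_requires_hydrophobic_wall():
    with pytest.raises(ValueError):
        NanoWaxGeometry(spacing=75.0, tubule_height=1000.0, theta_adv_wall=90.0)


@given(d=st.floats(1.0, 500.0), theta=st.floats(90.1, 180.0, exclude_max=False))
@settings(max_examples=100, deadline=None)
def test_meniscus_depth_bounded_by_half_spacing(d, theta):
    assume(theta < 180.0 or True)
    geom = NanoWaxGeometry(spacing=2 * d, tubule_height=1.0,
                           theta_adv_wall=min(theta, 180.0 - 1e-9))
    h = lw.meniscus_depth(geom)
    assert 0.0 < h <= d + 1e-9


@pytest.mark.parametrize(
    "h, height, state",
    [
        (25.0, 1000.0, NanoWettingState.CASSIE_BAXTER),  # green leaf
        (277.0, 134.0, NanoWettingState.WENZEL),         # brown leaf
        (100.0, 100.0, NanoWettingState.WENZEL),         # boundary is Wenzel
    ],
)
def test_classify_nano_state(h, height, state):
    assert lw.classify_nano_state(h, height) is state


# ------------------------------------------------- droplet retention mechanics


def test_cap_geometry_hemisphere_closed_form():
    V = 1e-8
    R, a = lw.cap_geometry(V, 90.0)
    assert R == pytest.approx((3 * V / (2 * math.pi)) ** (1 / 3), rel=1e-12)
    assert a == pytest.approx(R, rel=1e-12)


def test_cap_geometry_full_ball_limit():
    V = 1e-8
    _, a_179 = lw.cap_geometry(V, 179.0)
    _, a_1799 = lw.cap_geometry(V, 179.9)
    assert a_1799 < a_179 < 1e-3  # contact radius vanishes


def test_cap_geometry_against_numeric_root():
    """R must solve the cap-volume cubic; verify by brentq + re-substitution."""
    V, tb = 1e-8, 147.0
    c = math.cos(math.radians(tb))
    vol = lambda R: math.pi / 3 * R**3 * (1 - c) ** 2 * (2 + c) - V
    R_oracle = brentq(vol, 1e-6, 1e-1)
    R, a = lw.cap_geometry(V, tb)
    assert R == pytest.approx(R_oracle, rel=1e-9)
    assert R == pytest.approx(1.345e-3, rel=1e-3)
    assert a == pytest.approx(0.732e-3, rel=1e-3)
    assert vol(R) == pytest.approx(0.0, abs=V * 1e-12)


def test_critical_volume_zero_hysteresis(water_10ul):
    angles = MeasuredTiltAngles(theta_adv=140.0, theta_rec=140.0)
    assert lw.critical_volume(angles, water_10ul) == 0.0


def test_critical_volume_against_force_balance_oracle(water_10ul):
    """Independent bisection of the retention force balance for V."""
    angles = MeasuredTiltAngles(157.0, 137.0)
    dcos = math.cos(math.radians(137.0)) - math.cos(math.radians(157.0))
    g, rho, gam = water_10ul.g, water_10ul.rho, water_10ul.gamma_LA

    def residual(V):
        _, a = lw.cap_geometry(V, angles.theta_bar)
        return math.pi * a * gam * dcos - V * rho * g  # beta = 90

    V_oracle = brentq(residual, 1e-12, 1e-3)
    assert lw.critical_volume(angles, water_10ul) == pytest.approx(
        V_oracle, rel=1e-9
    )


def test_volume_ratio_brown_over_green(green, brown):
    ratio = lw.volume_ratio(brown.measured, green.measured)
    assert 16.5 <= ratio <= 16.7
    assert round(ratio) == 17


def test_volume_ratio_identity_and_zero_denominator(green):
    assert lw.volume_ratio(green.measured, green.measured) == pytest.approx(1.0)
    flat = MeasuredTiltAngles(120.0, 120.0)
    with pytest.raises(ValueError):
        lw.volume_ratio(green.measured, flat)


@given(
    scale=st.floats(0.1, 10.0),
    beta=st.floats(5.0, 90.0),
)
@settings(max_examples=50, deadline=None)
def test_volume_ratio_invariant_under_fluid_rescaling(scale, beta):
    """gamma, rho, g and beta cancel exactly in the critical-volume ratio."""
    g_ang = MeasuredTiltAngles(157.0, 137.0)
    b_ang = MeasuredTiltAngles(151.0, 96.0)
    base = DropletSpec(volume=1e-9, gamma_LA=0.072, rho=1000.0, g=9.81, beta=90.0)
    other = DropletSpec(
        volume=1e-9, gamma_LA=0.072 * scale, rho=1000.0 * scale,
        g=9.81 * scale, beta=beta,
    )
    r1 = lw.critical_volume(b_ang, base) / lw.critical_volume(g_ang, base)
    r2 = lw.critical_volume(b_ang, other) / lw.critical_volume(g_ang, other)
    assert r1 == pytest.approx(r2, rel=1e-12)
    assert lw.volume_ratio(b_ang, g_ang) == pytest.approx(r1, rel=1e-12)


def test_critical_volume_increasing_in_hysteresis(water_10ul):
    """At fixed mean angle, wider cos spread pins more volume."""
    mean = 130.0
    previous = 0.0
    for half in (2.0, 5.0, 10.0, 20.0, 30.0):
        angles = MeasuredTiltAngles(mean + half, mean - half)
        vc = lw.critical_volume(angles, water_10ul)
        assert vc > previous
        previous = vc


def test_rolloff_green_brown_contrast(green, brown):
    beta = lw.rolloff_tilt(1e-8, green.measured)
    assert beta == pytest.approx(18.63, abs=0.05)
    assert lw.rolloff_tilt(1e-8, brown.measured) is PINNED


def test_rolloff_monotone_decreasing_in_volume(green):
    tilts = [lw.rolloff_tilt(v, green.measured) for v in (1e-8, 3e-8, 1e-7, 1e-6)]
    assert all(t is not PINNED for t in tilts)
    assert all(a > b for a, b in zip(tilts, tilts[1:]))


@given(
    rec=st.floats(60.0, 140.0),
    dh=st.floats(0.5, 35.0),
    beta=st.floats(1.0, 90.0),
    vol_ul=st.floats(0.5, 100.0),
)
@settings(max_examples=200, deadline=None)
def test_critical_volume_rolloff_round_trip(rec, dh, beta, vol_ul):
    """Force balance and its closed-form inversion agree to 1e-9 relative."""
    angles = MeasuredTiltAngles(theta_adv=rec + dh, theta_rec=rec)
    assume(angles.theta_adv < 180.0)
    drop = DropletSpec.from_microliters(vol_ul, beta=beta)
    vc = lw.critical_volume(angles, drop)
    back = lw.rolloff_tilt(vc, angles, drop.gamma_LA, drop.rho, drop.g)
    assert back is not PINNED
    assert back == pytest.approx(beta, rel=1e-9)


@given(
    r=st.floats(1.0, 1.3),
    phi=st.floats(0.05, 1.0),
    alpha=st.floats(0.0, 1.0),
    theta=st.floats(80.0, 120.0),
)
@settings(max_examples=100, deadline=None)
def test_angle_outputs_in_physical_range(r, phi, alpha, theta):
    try:
        star = lw.combined_angle(SurfaceMorphology(r, phi, alpha), theta)
    except lw.NonPhysicalRegimeError:
        return
    assert 0.0 < star <= 180.0
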