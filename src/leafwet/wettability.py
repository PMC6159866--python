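"""Seasonal leaf wettability: hierarchical wetting model and SEM morphometry.

Deciduous leaves such as Katsura (*Cercidiphyllum japonicum*) carry a
two-tier surface: microscale papillose epidermal cells (bumps ~8 µm high,
~25 µm wide) covered by nanoscale epicuticular wax tubules.  A sessile
droplet sits in a *partial Wenzel* state — Wenzel over the micro-bumps,
Cassie-Baxter on the wax-tubule tips.  As leaves brown in fall the cells
deflate and the wax erodes, which lowers the apparent contact angle and
raises the contact-angle hysteresis, so brown leaves pin far larger drops.

This module implements, in the order the analysis runs:

1.  constants, configuration and errors;
2.  domain types (surface morphology, flat-wax angles, droplet spec, ...);
3.  the closed-form wetting physics: Wenzel, Cassie-Baxter, the combined
    two-tier model with an intact-wax areal fraction ``alpha``, hysteresis
    scaling, nanoscale meniscus penetration, spherical-cap geometry, and
    the tilt/critical-volume force balance;
4.  morphometry: estimating ``r_micro``, ``phi_nano`` and ``alpha`` from
    calibrated grayscale micrographs;
5.  synthetic micrograph/reading generators with recorded ground truth;
6.  the pipeline: leaf-state presets, headline-table reproduction,
    per-leaf prediction reports, end-to-end image-to-report runs, and
    file I/O helpers.

All angles cross module boundaries in **degrees**; conversion to radians
happens internally and only there.
"""

from __future__ import annotations

import enum
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter
from scipy.signal import find_peaks
from skimage.filters import threshold_otsu
from skimage.measure import label as _cc_label
from skimage.morphology import disk as _disk
from skimage.morphology import remove_small_objects

__all__ = [
    # constants / config
    "GAMMA_WATER",
    "RHO_WATER",
    "G_STANDARD",
    "MorphometryConfig",
    "configure_logging",
    # errors
    "LeafwetError",
    "NonPhysicalRegimeError",
    "UnimodalHistogramError",
    "ProfileExtractionError",
    "PackingError",
    "MorphometryError",
    "ManifestError",
    # types
    "SurfaceMorphology",
    "FlatWaxAngles",
    "ApparentWetting",
    "NanoWaxGeometry",
    "DropletSpec",
    "MeasuredTiltAngles",
    "GrayscaleImage",
    "SurfaceProfile",
    "MorphometryReport",
    "NanoWettingState",
    "PINNED",
    # wetting core
    "wenzel_angle",
    "cassie_baxter_angle",
    "combined_angle",
    "hysteresis_leaf",
    "hysteresis_leaf_derivative",
    "apparent_wetting",
    "meniscus_depth",
    "classify_nano_state",
    "cap_geometry",
    "critical_volume",
    "volume_ratio",
    "rolloff_tilt",
    # morphometry
    "extract_surface_profile",
    "roughness_from_profile",
    "phi_from_topview",
    "alpha_from_topview",
    "filter_small_regions",
    "morphometry_pipeline",
    # synthetic data
    "BumpFieldSpec",
    "WaxTipFieldSpec",
    "ErosionFieldSpec",
    "bump_height_for_roughness",
    "gen_bump_profile",
    "gen_waxtip_image",
    "gen_erosion_image",
    "gen_goniometer_readings",
    # pipeline
    "LeafStatePreset",
    "WettabilityReport",
    "PRESETS",
    "FLAT_WAX",
    "reproduce_table1",
    "predict_leaf",
    "run_end_to_end",
    "load_image",
    "read_manifest",
    "load_params",
    "read_morphology_table",
    "write_morphology_table",
]

# --------------------------------------------------------------------------
# 1. Constants, configuration, logging, errors
# --------------------------------------------------------------------------

logger = logging.getLogger("leafwet")

#: Surface tension of water at room temperature, N/m.
GAMMA_WATER = 0.072
#: Density of water, kg/m^3.
RHO_WATER = 1000.0
#: Standard gravity, m/s^2.
G_STANDARD = 9.81

#: Connected-component connectivity used everywhere (4-connectivity, so
#: diagonally touching speckles stay separate components).
_CONNECTIVITY = 1


def configure_logging(level: int | str = logging.INFO) -> None:
    """Attach a stderr handler to the package logger (used by the CLI)."""
    handler = logging.StreamHandler()
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    )
    logger.handlers[:] = [handler]
    logger.setLevel(level)


class LeafwetError(Exception):
    """Base class for package errors."""


class NonPhysicalRegimeError(LeafwetError, ValueError):
    """A wetting formula left the physical regime (|cos theta*| > 1)."""


class UnimodalHistogramError(LeafwetError, ValueError):
    """An intensity histogram lacks the two peaks the estimator needs."""


class ProfileExtractionError(LeafwetError, ValueError):
    """A surface profile could not be extracted from a cross-section image."""


class PackingError(LeafwetError, ValueError):
    """Requested disc coverage is not achievable without overlap."""


class MorphometryError(LeafwetError, ValueError):
    """A morphometry stage failed (carries image identity in the message)."""


class ManifestError(LeafwetError, ValueError):
    """An image manifest is missing a role or cannot be parsed."""


@dataclass(frozen=True)
class MorphometryConfig:
    """Tunable knobs of the micrograph estimators.

    threshold:
        Fixed global grayscale threshold; ``None`` selects an automatic
        bimodal (Otsu) split.
    foreground / intact:
        Polarity flags: which intensity class is leaf tissue in
        cross-sections and which is intact wax in top views.
    min_object_px:
        Small-object cleanup before profile extraction, in pixels.
    profile_smooth_window:
        Boxcar window (columns) applied to the extracted height profile to
        suppress the one-pixel quantisation staircase before arc-length
        measurement.
    hist_bins / hist_smooth_window / peak_min_separation:
        Histogram peak finding for ``phi_from_topview``: 256 bins, moving
        average of width 5, peaks at least 20 bins apart; ties broken
        toward the brighter bin.
    min_intact_area_um2 / min_eroded_area_um2:
        Physical area filters for ``alpha``: intact patches below 5 µm^2
        and eroded patches below 22.5 µm^2 are reassigned to the
        surrounding class.
    unimodal_separation_factor:
        ``alpha_from_topview`` declares an image single-class when the two
        Otsu classes' means are closer than this factor times the pooled
        within-class standard deviation; the lone class is then labelled
        by which side of the dtype midpoint it sits on.
    max_missing_column_frac:
        Profile extraction fails when more than this fraction of columns
        contain no foreground; below it, gaps are interpolated.
    """

    threshold: float | None = None
    foreground: str = "bright"
    intact: str = "bright"
    min_object_px: int = 16
    profile_smooth_window: int = 5
    hist_bins: int = 256
    hist_smooth_window: int = 5
    peak_min_separation: int = 20
    min_intact_area_um2: float = 5.0
    min_eroded_area_um2: float = 22.5
    unimodal_separation_factor: float = 3.0
    max_missing_column_frac: float = 0.10

    def __post_init__(self) -> None:
        if self.foreground not in ("bright", "dark"):
            raise ValueError("foreground must be 'bright' or 'dark'")
        if self.intact not in ("bright", "dark"):
            raise ValueError("intact must be 'bright' or 'dark'")


DEFAULT_CONFIG = MorphometryConfig()


def _deg2rad(x: float) -> float:
    return math.radians(x)


def _round_half_up(x: float) -> int:
    """Display rounding used in report tables (0.5 rounds up)."""
    return int(math.floor(x + 0.5))


# --------------------------------------------------------------------------
# 2. Domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SurfaceMorphology:
    """The three structural parameters of the two-tier leaf surface.

    r_micro:
        Microscale roughness, actual over projected surface area (>= 1).
    phi_nano:
        Areal fraction of liquid/solid contact on top of the wax-tubule
        tips, in [0, 1].
    alpha:
        Areal fraction of intact (non-eroded) wax coverage, in [0, 1];
        1 for green leaves, < 1 for brown.
    """

    r_micro: float
    phi_nano: float
    alpha: float

    def __post_init__(self) -> None:
        if not self.r_micro >= 1.0:
            raise ValueError(f"r_micro must be >= 1, got {self.r_micro}")
        if not 0.0 <= self.phi_nano <= 1.0:
            raise ValueError(f"phi_nano must be in [0, 1], got {self.phi_nano}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")


@dataclass(frozen=True)
class FlatWaxAngles:
    """Contact angles on a chemically identical flat wax film, degrees."""

    theta_mean: float
    theta_adv: float
    theta_rec: float

    def __post_init__(self) -> None:
        if not (0.0 < self.theta_rec <= self.theta_mean <= self.theta_adv < 180.0):
            raise ValueError(
                "require 0 < theta_rec <= theta_mean <= theta_adv < 180, got "
                f"{self.theta_rec}/{self.theta_mean}/{self.theta_adv}"
            )

    @property
    def hysteresis(self) -> float:
        return self.theta_adv - self.theta_rec


@dataclass(frozen=True)
class ApparentWetting:
    """Model outputs for one leaf: apparent angle and hysteresis, degrees.

    Predicted advancing/receding angles are reported as the apparent mean
    plus/minus half the predicted hysteresis.
    """

    theta_star: float
    theta_star_adv: float
    theta_star_rec: float
    hysteresis_leaf: float

    def __post_init__(self) -> None:
        if not 0.0 < self.theta_star < 180.0:
            raise ValueError(f"theta_star must be in (0, 180), got {self.theta_star}")
        if self.hysteresis_leaf < 0.0:
            raise ValueError("hysteresis_leaf must be >= 0")
        if abs((self.theta_star_adv - self.theta_star_rec) - self.hysteresis_leaf) > 1e-9:
            raise ValueError("adv - rec must equal hysteresis_leaf")


@dataclass(frozen=True)
class NanoWaxGeometry:
    """Geometry of the nano-wax tubule array for meniscus penetration.

    spacing:
        Center-to-center tubule spacing in nm (twice the half-spacing that
        sets the meniscus radius of curvature).
    tubule_height:
        Tubule height in nm.
    theta_adv_wall:
        Advancing contact angle on the tubule wall, degrees; must exceed
        90° for the meniscus to sag between tubules.
    """

    spacing: float
    tubule_height: float
    theta_adv_wall: float

    def __post_init__(self) -> None:
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")
        if not self.tubule_height > 0:
            raise ValueError("tubule_height must be positive")
        if not 90.0 < self.theta_adv_wall < 180.0:
            raise ValueError(
                f"theta_adv_wall must be in (90, 180), got {self.theta_adv_wall}"
            )

    @property
    def d_wax(self) -> float:
        """Half the tubule spacing, nm."""
        return self.spacing / 2.0


@dataclass(frozen=True)
class DropletSpec:
    """Droplet and fluid constants for tilt mechanics (SI units).

    volume is in m^3 (see :meth:`from_microliters`); beta is the substrate
    tilt in degrees.
    """

    volume: float
    gamma_LA: float = GAMMA_WATER
    rho: float = RHO_WATER
    g: float = G_STANDARD
    beta: float = 90.0

    def __post_init__(self) -> None:
        for name in ("volume", "gamma_LA", "rho", "g"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.beta <= 90.0:
            raise ValueError(f"beta must be in (0, 90], got {self.beta}")

    @classmethod
    def from_microliters(cls, volume_ul: float, **kwargs) -> "DropletSpec":
        return cls(volume=volume_ul * 1e-9, **kwargs)


@dataclass(frozen=True)
class MeasuredTiltAngles:
    """Advancing/receding contact angles from a tilting-plate run, degrees."""

    theta_adv: float
    theta_rec: float

    def __post_init__(self) -> None:
        if not (0.0 < self.theta_rec <= self.theta_adv < 180.0):
            raise ValueError(
                f"require 0 < rec <= adv < 180, got {self.theta_rec}/{self.theta_adv}"
            )

    @property
    def theta_bar(self) -> float:
        """Mean of advancing and receding angles, degrees."""
        return 0.5 * (self.theta_adv + self.theta_rec)

    @property
    def hysteresis(self) -> float:
        return self.theta_adv - self.theta_rec


@dataclass(frozen=True)
class GrayscaleImage:
    """Calibrated grayscale micrograph raster.

    pixels is a 2-D array (integer 8/16-bit or real); pixel_size_um is the
    physical size of one (square) pixel in µm, or None when uncalibrated.
    """

    pixels: np.ndarray
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if not np.all(np.isfinite(px.astype(np.float64))):
            raise ValueError("pixel intensities must be finite")
        if self.pixel_size_um is not None and not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class SurfaceProfile:
    """1-D surface height profile: heights (µm) at uniform spacing dx_um."""

    heights: np.ndarray
    dx_um: float

    def __post_init__(self) -> None:
        h = np.asarray(self.heights, dtype=np.float64)
        if h.ndim != 1 or h.size < 2:
            raise ValueError("heights must be 1-D with length >= 2")
        if not np.all(np.isfinite(h)):
            raise ValueError("heights must be finite")
        if not self.dx_um > 0:
            raise ValueError("dx_um must be positive")
        object.__setattr__(self, "heights", h)


@dataclass
class MorphometryReport:
    """Estimate for one morphology parameter with method metadata.

    parameter is one of ``r_micro``/``phi_nano``/``alpha``; metadata holds
    per-image estimator decisions (thresholds, peaks, reassigned
    components); qa_flags lists warnings and per-image failures.
    """

    parameter: str
    estimate: float
    dispersion: float | None = None
    n_images: int = 0
    metadata: dict = field(default_factory=dict)
    qa_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        lo, hi = (1.0, math.inf) if self.parameter == "r_micro" else (0.0, 1.0)
        if not lo <= self.estimate <= hi:
            raise ValueError(
                f"{self.parameter} estimate {self.estimate} outside [{lo}, {hi}]"
            )


class NanoWettingState(enum.Enum):
    CASSIE_BAXTER = "CASSIE_BAXTER"
    WENZEL = "WENZEL"


class _Pinned(enum.Enum):
    """Distinguished roll-off outcome: droplet stays pinned at any tilt."""

    PINNED = "PINNED"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "PINNED"


PINNED = _Pinned.PINNED


# --------------------------------------------------------------------------
# 3. Wetting core
# --------------------------------------------------------------------------


def _arccos_deg(cos_value: float, context: str) -> float:
    if abs(cos_value) > 1.0:
        raise NonPhysicalRegimeError(
            f"{context}: |cos theta*| = {abs(cos_value):.6g} > 1; the model "
            "leaves the physical regime for these parameters"
        )
    return math.degrees(math.acos(cos_value))


def wenzel_angle(r: float, theta: float) -> float:
    """Apparent angle of a fully wetted rough surface: cos θ* = r·cos θ.

    Raises :class:`NonPhysicalRegimeError` (rather than clamping) when
    r·|cos θ| exceeds 1.
    """
    if not r >= 1.0:
        raise ValueError(f"roughness must be >= 1, got {r}")
    if not 0.0 < theta < 180.0:
        raise ValueError(f"theta must be in (0, 180), got {theta}")
    return _arccos_deg(r * math.cos(_deg2rad(theta)), "wenzel_angle")


def cassie_baxter_angle(phi_s: float, theta: float) -> float:
    """Apparent angle on a composite surface: cos θ* = φ_s(cos θ + 1) − 1."""
    if not 0.0 <= phi_s <= 1.0:
        raise ValueError(f"phi_s must be in [0, 1], got {phi_s}")
    if not 0.0 < theta < 180.0:
        raise ValueError(f"theta must be in (0, 180), got {theta}")
    return _arccos_deg(
        phi_s * (math.cos(_deg2rad(theta)) + 1.0) - 1.0, "cassie_baxter_angle"
    )


def combined_angle(morph: SurfaceMorphology, theta: float) -> float:
    """Two-tier apparent contact angle with partial wax erosion.

    cos θ* = α·r·(φ(cos θ + 1) − 1) + (1 − α)·r·cos θ

    Intact regions (fraction ``alpha``) are micro-Wenzel with a nano
    Cassie-Baxter contact on the wax tips; eroded regions are plain
    Wenzel.  ``alpha = 1`` recovers the uniformly waxed (green-leaf) form
    r·φ·cosθ − r(1 − φ); ``alpha = 0`` recovers the Wenzel angle.
    """
    if not 0.0 < theta < 180.0:
        raise ValueError(f"theta must be in (0, 180), got {theta}")
    c = math.cos(_deg2rad(theta))
    r, phi, a = morph.r_micro, morph.phi_nano, morph.alpha
    cos_star = a * r * (phi * (c + 1.0) - 1.0) + (1.0 - a) * r * c
    return _arccos_deg(cos_star, "combined_angle")


def hysteresis_leaf(
    morph: SurfaceMorphology, flat: FlatWaxAngles, theta_star: float
) -> float:
    """Predicted contact-angle hysteresis on a leaf (as-printed form).

    Δθ*_leaf = r·(α(φ − 1) + 1) · Δθ_flat · sin θ* / sin θ_flat

    This is the relation as published; differentiating the combined-angle
    expression instead yields the sine factors in the reciprocal position
    (see :func:`hysteresis_leaf_derivative`).  Both are exposed; this
    as-printed form is the package default.
    """
    if not 0.0 < theta_star < 180.0:
        raise ValueError(f"theta_star must be in (0, 180), got {theta_star}")
    sin_flat = math.sin(_deg2rad(flat.theta_mean))
    if sin_flat == 0.0:
        raise ValueError("sin(theta_flat) is zero; hysteresis undefined")
    factor = morph.r_micro * (morph.alpha * (morph.phi_nano - 1.0) + 1.0)
    return factor * flat.hysteresis * math.sin(_deg2rad(theta_star)) / sin_flat


def hysteresis_leaf_derivative(
    morph: SurfaceMorphology, flat: FlatWaxAngles, theta_star: float
) -> float:
    """Hysteresis via direct differentiation of the combined-angle model.

    Δθ*_leaf = r·(α(φ − 1) + 1) · Δθ_flat · sin θ_flat / sin θ*

    Finite-difference of cos θ* = f(cos θ) gives sin θ*·Δθ* =
    r(αφ + 1 − α)·sin θ·Δθ, i.e. the sine ratio inverted relative to the
    as-printed form.
    """
    if not 0.0 < theta_star < 180.0:
        raise ValueError(f"theta_star must be in (0, 180), got {theta_star}")
    sin_star = math.sin(_deg2rad(theta_star))
    if sin_star == 0.0:
        raise ValueError("sin(theta_star) is zero; hysteresis undefined")
    factor = morph.r_micro * (morph.alpha * (morph.phi_nano - 1.0) + 1.0)
    return factor * flat.hysteresis * math.sin(_deg2rad(flat.theta_mean)) / sin_star


def apparent_wetting(
    morph: SurfaceMorphology, flat: FlatWaxAngles, variant: str = "as_printed"
) -> ApparentWetting:
    """Compose apparent angle and hysteresis into one prediction.

    The predicted hysteresis is split symmetrically around the apparent
    mean angle to report advancing/receding values.
    """
    theta_star = combined_angle(morph, flat.theta_mean)
    if variant == "as_printed":
        dh = hysteresis_leaf(morph, flat, theta_star)
    elif variant == "derivative":
        dh = hysteresis_leaf_derivative(morph, flat, theta_star)
    else:
        raise ValueError(f"unknown hysteresis variant: {variant!r}")
    return ApparentWetting(
        theta_star=theta_star,
        theta_star_adv=theta_star + dh / 2.0,
        theta_star_rec=theta_star - dh / 2.0,
        hysteresis_leaf=dh,
    )


def meniscus_depth(geom: NanoWaxGeometry) -> float:
    """Penetration depth (nm) of the air/water meniscus between tubules.

    h = d_wax · [ 1/sin(θ − 90°) − sqrt( (1/sin(θ − 90°))² − 1 ) ]

    with d_wax half the tubule spacing and θ the advancing angle on the
    tubule wall.  For θ in (90°, 180°] the depth satisfies 0 < h <= d_wax.
    """
    s = math.sin(_deg2rad(geom.theta_adv_wall - 90.0))
    inv = 1.0 / s
    return geom.d_wax * (inv - math.sqrt(inv * inv - 1.0))


def classify_nano_state(h: float, tubule_height: float) -> NanoWettingState:
    """Cassie-Baxter when the meniscus depth stays short of the tubule
    height; Wenzel otherwise (boundary counts as Wenzel, conservatively)."""
    if not (h > 0 and tubule_height > 0):
        raise ValueError("h and tubule_height must be positive")
    if h < tubule_height:
        return NanoWettingState.CASSIE_BAXTER
    return NanoWettingState.WENZEL


def cap_geometry(volume: float, theta_bar: float) -> tuple[float, float]:
    """Spherical-cap radius R and contact radius a for a sessile droplet.

    Solves V = (π/3)·R³·(1 − cos θ̄)²·(2 + cos θ̄) for R and returns
    (R, a = R·sin θ̄), all in SI units.
    """
    if not volume > 0:
        raise ValueError("volume must be positive")
    if not 0.0 < theta_bar < 180.0:
        raise ValueError(f"theta_bar must be in (0, 180), got {theta_bar}")
    c = math.cos(_deg2rad(theta_bar))
    shape = (1.0 - c) ** 2 * (2.0 + c)
    R = (3.0 * volume / (math.pi * shape)) ** (1.0 / 3.0)
    return R, R * math.sin(_deg2rad(theta_bar))


def critical_volume(angles: MeasuredTiltAngles, drop: DropletSpec) -> float:
    """Maximum droplet volume (m³) a tilted leaf can pin.

    Balancing the contact-line retention force against gravity along the
    incline and eliminating the contact radius through the spherical-cap
    relations gives

    V_c = ( π·γ_LA·sin θ̄·(cos θ_Rec − cos θ_Adv) / (ρ·g·sin β) )^{3/2}
          · ( 3 / (π·(1 − cos θ̄)²·(2 + cos θ̄)) )^{1/2}

    with θ̄ the mean of advancing and receding angles.  Zero hysteresis
    returns 0 (nothing pins).  ``drop.volume`` is not used.
    """
    dcos = math.cos(_deg2rad(angles.theta_rec)) - math.cos(_deg2rad(angles.theta_adv))
    if dcos == 0.0:
        return 0.0
    tb = angles.theta_bar
    c = math.cos(_deg2rad(tb))
    force = (
        math.pi
        * drop.gamma_LA
        * math.sin(_deg2rad(tb))
        * dcos
        / (drop.rho * drop.g * math.sin(_deg2rad(drop.beta)))
    )
    shape = 3.0 / (math.pi * (1.0 - c) ** 2 * (2.0 + c))
    return force**1.5 * math.sqrt(shape)


def volume_ratio(
    angles_num: MeasuredTiltAngles, angles_den: MeasuredTiltAngles
) -> float:
    """Ratio of critical volumes for two leaves with the same fluid/tilt.

    The fluid constants and tilt cancel exactly, so the ratio depends only
    on the two angle pairs.
    """
    if angles_den.hysteresis == 0.0:
        raise ValueError("denominator leaf has zero hysteresis; ratio undefined")
    unit = DropletSpec(volume=1e-9, gamma_LA=1.0, rho=1.0, g=1.0, beta=90.0)
    return critical_volume(angles_num, unit) / critical_volume(angles_den, unit)


def rolloff_tilt(
    volume: float,
    angles: MeasuredTiltAngles,
    gamma_LA: float = GAMMA_WATER,
    rho: float = RHO_WATER,
    g: float = G_STANDARD,
) -> float | _Pinned:
    """Critical tilt (degrees) at which a droplet of given volume rolls off.

    Inverts the retention force balance:
    sin β = π·a·γ_LA·(cos θ_Rec − cos θ_Adv) / (V·ρ·g), with the contact
    radius a from the spherical cap at the mean angle.  When the argument
    exceeds 1, gravity never wins and the distinguished value
    :data:`PINNED` is returned (a valid outcome, not an error).
    """
    if not volume > 0:
        raise ValueError("volume must be positive")
    _, a = cap_geometry(volume, angles.theta_bar)
    dcos = math.cos(_deg2rad(angles.theta_rec)) - math.cos(_deg2rad(angles.theta_adv))
    arg = math.pi * a * gamma_LA * dcos / (volume * rho * g)
    # tolerate float round-off at the beta = 90 deg boundary
    if arg > 1.0 + 1e-12:
        return PINNED
    return math.degrees(math.asin(min(arg, 1.0)))


# --------------------------------------------------------------------------
# 4. Morphometry
# --------------------------------------------------------------------------


def _as_float(pixels: np.ndarray) -> np.ndarray:
    return np.asarray(pixels, dtype=np.float64)


def _inverted(pixels: np.ndarray) -> np.ndarray:
    """Intensity inversion that is an exact involution for any dtype."""
    if np.issubdtype(pixels.dtype, np.integer):
        return np.iinfo(pixels.dtype).max - pixels
    f = _as_float(pixels)
    return (f.min() + f.max()) - f


def _dtype_midpoint(pixels: np.ndarray) -> float:
    if np.issubdtype(pixels.dtype, np.integer):
        return np.iinfo(pixels.dtype).max / 2.0
    f = _as_float(pixels)
    return 0.5 * (f.min() + f.max())


def _global_threshold(pixels: np.ndarray, config: MorphometryConfig) -> float:
    if config.threshold is not None:
        return float(config.threshold)
    return float(threshold_otsu(_as_float(pixels), nbins=config.hist_bins))


def _smooth1d(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return np.asarray(values, dtype=np.float64)
    pad = window // 2
    padded = np.pad(np.asarray(values, dtype=np.float64), pad, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def extract_surface_profile(
    image: GrayscaleImage, config: MorphometryConfig = DEFAULT_CONFIG
) -> SurfaceProfile:
    """Trace the top surface of a cross-section micrograph.

    The image is globally thresholded (automatic bimodal split unless a
    fixed threshold is configured), small objects are removed, and the
    topmost foreground row of each column becomes the surface height,
    measured upward from the bottom image edge in µm.  Columns with no
    foreground are interpolated from their neighbours when fewer than 10%,
    otherwise extraction fails.  The resulting profile is boxcar-smoothed
    to suppress the pixel staircase.
    """
    if image.pixel_size_um is None:
        raise MorphometryError("cross-section image needs pixel_size_um")
    px = image.pixels
    if config.foreground == "dark":
        px = _inverted(px)
    fmin, fmax = float(px.min()), float(px.max())
    if fmin == fmax:
        raise ProfileExtractionError("image has no contrast; no foreground found")
    thr = _global_threshold(px, config)
    mask = _as_float(px) > thr
    mask = remove_small_objects(mask, max_size=config.min_object_px - 1)
    nrows, ncols = mask.shape
    has_fg = mask.any(axis=0)
    missing = 1.0 - has_fg.mean()
    if missing > config.max_missing_column_frac:
        raise ProfileExtractionError(
            f"{missing:.0%} of columns have no foreground (limit "
            f"{config.max_missing_column_frac:.0%}); profile not extractable"
        )
    top_row = mask.argmax(axis=0).astype(np.float64)
    cols = np.arange(ncols)
    if not has_fg.all():
        top_row[~has_fg] = np.interp(
            cols[~has_fg], cols[has_fg], top_row[has_fg]
        )
    heights = (nrows - 1 - top_row) * image.pixel_size_um
    heights = _smooth1d(heights, config.profile_smooth_window)
    logger.debug(
        "profile: threshold=%.1f, %d/%d columns interpolated", thr,
        int((~has_fg).sum()), ncols,
    )
    return SurfaceProfile(heights=heights, dx_um=image.pixel_size_um)


def roughness_from_profile(profile: SurfaceProfile) -> float:
    """Microscale roughness as the arc-length / chord-length ratio.

    r = Σ sqrt(dx² + dh²) / (total horizontal extent); always >= 1, with
    equality exactly for a constant profile.  The 2-D profile ratio is
    used directly as the area roughness (not squared for isotropy).
    """
    dh = np.diff(profile.heights)
    arclen = np.hypot(profile.dx_um, dh).sum()
    return float(arclen / (profile.dx_um * dh.size))


def _phi_with_meta(
    image: GrayscaleImage, config: MorphometryConfig
) -> tuple[float, dict]:
    px = _as_float(image.pixels)
    if px.min() == px.max():
        raise UnimodalHistogramError("uniform image: no histogram peaks")
    hist, edges = np.histogram(px, bins=config.hist_bins)
    smoothed = _smooth1d(hist, config.hist_smooth_window)
    # zero-pad so peaks in the first/last bin are detectable
    padded = np.concatenate([[0.0], smoothed, [0.0]])
    peaks, _ = find_peaks(padded, distance=config.peak_min_separation)
    peaks -= 1
    if len(peaks) < 2:
        raise UnimodalHistogramError(
            f"found {len(peaks)} qualifying histogram peak(s); need 2"
        )
    # two dominant maxima; ties broken toward the brighter bin
    dominant = sorted(peaks, key=lambda p: (smoothed[p], p))[-2:]
    upper = max(dominant)
    centers = 0.5 * (edges[:-1] + edges[1:])
    threshold = float(centers[upper])
    phi = float((px > threshold).mean())
    meta = {
        "histogram_peaks": [int(p) for p in sorted(peaks)],
        "dominant_peaks": sorted(int(p) for p in dominant),
        "upper_peak_center": threshold,
    }
    logger.debug("phi: peaks=%s threshold=%.1f phi=%.4f", meta["histogram_peaks"],
                 threshold, phi)
    return phi, meta


def phi_from_topview(
    image: GrayscaleImage, config: MorphometryConfig = DEFAULT_CONFIG
) -> float:
    """Liquid/solid contact fraction on wax tips from a top-view image.

    Builds a 256-bin histogram, smooths it, locates the two dominant local
    maxima (separated by at least 20 bins) and returns the fraction of
    pixels strictly brighter than the upper peak's bin center — the
    regions where a droplet would meet the solid wax.
    """
    phi, _ = _phi_with_meta(image, config)
    return phi


def filter_small_regions(
    mask: np.ndarray,
    pixel_size_um: float,
    min_intact_area_um2: float = 5.0,
    min_eroded_area_um2: float = 22.5,
) -> tuple[np.ndarray, dict]:
    """Apply the physical-area cleanup to an intact/eroded mask.

    Connected intact (True) components smaller than 5 µm² are reassigned
    to eroded, then eroded components smaller than 22.5 µm² are reassigned
    to intact.  Reassignment (not deletion) keeps the total area, so the
    areal-fraction denominator is stable.  The operation is idempotent.
    Returns the cleaned mask and counts of reassigned components.
    """
    px_area = pixel_size_um**2

    def _reassign(m: np.ndarray, min_area_um2: float) -> tuple[np.ndarray, int]:
        lbl = _cc_label(m, connectivity=_CONNECTIVITY)
        if lbl.max() == 0:
            return m, 0
        sizes = np.bincount(lbl.ravel())
        small = sizes * px_area < min_area_um2
        small[0] = False
        out = m & ~small[lbl]
        return out, int(small.sum())

    intact = np.asarray(mask, dtype=bool)
    intact, n_intact_removed = _reassign(intact, min_intact_area_um2)
    eroded = ~intact
    eroded, n_eroded_removed = _reassign(eroded, min_eroded_area_um2)
    cleaned = ~eroded
    return cleaned, {
        "intact_reassigned": n_intact_removed,
        "eroded_reassigned": n_eroded_removed,
    }


def _alpha_with_meta(
    image: GrayscaleImage, config: MorphometryConfig
) -> tuple[float, dict, list[str]]:
    if image.pixel_size_um is None:
        raise MorphometryError("alpha estimation needs pixel_size_um (area "
                               "filters are in physical units)")
    px = image.pixels
    if config.intact == "dark":
        px = _inverted(px)
    f = _as_float(px)
    flags: list[str] = []
    if f.min() == f.max():
        # zero-contrast image: one class covering everything
        intact_mask = np.full(f.shape, f.min() > _dtype_midpoint(px), dtype=bool)
        thr = float("nan")
    else:
        thr = _global_threshold(px, config)
        intact_mask = f > thr
        lo, hi = f[~intact_mask], f[intact_mask]
        if lo.size and hi.size:
            pooled_sd = max(float(lo.std()), float(hi.std()), 1e-12)
            if (hi.mean() - lo.mean()) < config.unimodal_separation_factor * pooled_sd:
                # effectively single-class: label by dtype-midpoint side
                bright = f.mean() > _dtype_midpoint(px)
                intact_mask = np.full(f.shape, bright, dtype=bool)
                flags.append("unimodal_intensity: classified whole image as "
                             + ("intact" if bright else "eroded"))
    cleaned, reassigned = filter_small_regions(
        intact_mask,
        image.pixel_size_um,
        config.min_intact_area_um2,
        config.min_eroded_area_um2,
    )
    alpha = float(cleaned.mean())
    if alpha == 0.0:
        flags.append("intact_class_empty")
    elif alpha == 1.0:
        flags.append("eroded_class_empty")
    meta = {"threshold": thr, **reassigned}
    logger.debug("alpha: threshold=%s reassigned=%s alpha=%.4f", thr, reassigned,
                 alpha)
    return alpha, meta, flags


def alpha_from_topview(
    image: GrayscaleImage, config: MorphometryConfig = DEFAULT_CONFIG
) -> float:
    """Intact-wax areal fraction from a top-view image.

    Binarizes into intact (bright) vs eroded (dark) classes by a global
    contrast threshold (automatic bimodal split by default), applies the
    5 / 22.5 µm² area filters, and returns intact area over total area.
    """
    alpha, _, _ = _alpha_with_meta(image, config)
    return alpha


_ROLES = ("cross_section", "topview_wax", "topview_erosion")


def morphometry_pipeline(
    images: Iterable[tuple],
    config: MorphometryConfig = DEFAULT_CONFIG,
) -> tuple[SurfaceMorphology, list[MorphometryReport]]:
    """Estimate all three morphology parameters from a set of micrographs.

    ``images`` yields ``(image, role)`` or ``(image, role, name)`` tuples
    with role in ``cross_section`` / ``topview_wax`` / ``topview_erosion``.
    Replicates are averaged arithmetically (sample standard deviation
    reported); per-image failures become QA flags carrying the image
    identity, and a role whose images all fail raises
    :class:`MorphometryError`.
    """
    by_role: dict[str, list[tuple[GrayscaleImage, str]]] = {r: [] for r in _ROLES}
    items = list(images)
    if not items:
        raise MorphometryError("empty image set")
    for i, item in enumerate(items):
        img, role = item[0], item[1]
        name = item[2] if len(item) > 2 else f"{role}[{len(by_role.get(role, []))}]"
        if role not in by_role:
            raise MorphometryError(f"unknown role {role!r} for image {name!r}")
        by_role[role].append((img, name))
    for role in _ROLES:
        if not by_role[role]:
            raise MorphometryError(f"no image supplied for role {role!r}")

    def _collect(role: str, estimator) -> MorphometryReport:
        values, metas, flags = [], {}, []
        for img, name in by_role[role]:
            try:
                value, meta = estimator(img)
            except LeafwetError as exc:
                flags.append(f"{name}: {type(exc).__name__}: {exc}")
                continue
            values.append(value)
            metas[name] = meta
        if not values:
            raise MorphometryError(
                f"all images for role {role!r} failed: {'; '.join(flags)}"
            )
        arr = np.asarray(values)
        param = {"cross_section": "r_micro", "topview_wax": "phi_nano",
                 "topview_erosion": "alpha"}[role]
        return MorphometryReport(
            parameter=param,
            estimate=float(arr.mean()),
            dispersion=float(arr.std(ddof=1)) if arr.size > 1 else None,
            n_images=int(arr.size),
            metadata=metas,
            qa_flags=flags,
        )

    def _r(img: GrayscaleImage) -> tuple[float, dict]:
        profile = extract_surface_profile(img, config)
        return roughness_from_profile(profile), {"n_samples": profile.heights.size}

    def _phi(img: GrayscaleImage) -> tuple[float, dict]:
        return _phi_with_meta(img, config)

    def _alpha(img: GrayscaleImage) -> tuple[float, dict]:
        value, meta, aflags = _alpha_with_meta(img, config)
        meta = {**meta, "flags": aflags}
        return value, meta

    reports = [
        _collect("cross_section", _r),
        _collect("topview_wax", _phi),
        _collect("topview_erosion", _alpha),
    ]
    est = {rep.parameter: rep.estimate for rep in reports}
    morph = SurfaceMorphology(
        r_micro=max(est["r_micro"], 1.0),
        phi_nano=min(max(est["phi_nano"], 0.0), 1.0),
        alpha=min(max(est["alpha"], 0.0), 1.0),
    )
    logger.info(
        "morphometry: r_micro=%.4f phi_nano=%.4f alpha=%.4f",
        morph.r_micro, morph.phi_nano, morph.alpha,
    )
    return morph, reports


# --------------------------------------------------------------------------
# 5. Synthetic data generators
# --------------------------------------------------------------------------
#
# Each generator is driven by a single integer seed through an explicit
# per-call random state and emits its ground truth alongside the data; the
# truth is measured on the emitted object itself (mask pixel counts,
# high-resolution arc length), never taken from the request parameters.


@dataclass(frozen=True)
class BumpFieldSpec:
    """Cross-section profile of papillose epidermal cells.

    Defaults follow the measured summer-leaf cells: bumps 8 µm high and
    25 µm wide.  ``shape`` selects the bump template: ``sinusoid``
    (sin² train), ``gaussian``, or ``hemisphere`` (semi-ellipse; a true
    semicircle when height equals half the width).
    """

    bump_height_um: float = 8.0
    bump_width_um: float = 25.0
    shape: str = "sinusoid"
    count: int = 4
    dx_um: float = 0.02
    pixel_size_um: float = 0.1
    baseline_um: float = 2.0
    levels: tuple[float, float] = (6000.0, 52000.0)
    noise_sd: float = 800.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bump_height_um < 0 or self.bump_width_um <= 0:
            raise ValueError("bump dimensions must be positive (height >= 0)")
        if self.shape not in ("sinusoid", "gaussian", "hemisphere"):
            raise ValueError(f"unknown bump shape {self.shape!r}")
        if self.count < 1 or self.dx_um <= 0 or self.pixel_size_um <= 0:
            raise ValueError("count, dx_um, pixel_size_um must be positive")


@dataclass(frozen=True)
class WaxTipFieldSpec:
    """Top-view nano-wax image: dark floor, mid wax texture, bright tips.

    The default target liquid/solid fraction is 0.25.  The tip intensity
    level deliberately exceeds the 16-bit ceiling so tips render as
    saturated highlights (as SEM tubule tips do), giving the histogram a
    clean dominant peak at the top of the grayscale.
    """

    target_phi: float = 0.25
    tip_radius_px: int = 6
    levels: tuple[float, float, float] = (8000.0, 30000.0, 68000.0)
    wax_fraction: float = 0.40
    wax_blob_sigma_px: float = 12.0
    noise_sd: float = 300.0
    size: tuple[int, int] = (768, 768)
    pixel_size_um: float = 0.01
    seed: int = 0
    max_tries_per_disc: int = 500

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_phi < 1.0:
            raise ValueError("target_phi must be in [0, 1)")
        if not (self.levels[0] < self.levels[1] < self.levels[2]):
            raise ValueError("intensity levels must be strictly ordered")
        if self.tip_radius_px < 1:
            raise ValueError("tip_radius_px must be >= 1")


@dataclass(frozen=True)
class ErosionFieldSpec:
    """Partially eroded wax coverage map with sub-threshold speckle.

    The default intact fraction 0.46 matches a late-fall brown leaf.
    Speckles of both polarities (intact flecks below 5 µm², eroded
    pinholes below 22.5 µm²) are injected after ground-truth recording to
    exercise the area filters.
    """

    target_alpha: float = 0.46
    corr_len_um: float = 10.0
    n_intact_speckles: int = 30
    n_eroded_speckles: int = 30
    intact_speckle_radius_px: int = 2
    eroded_speckle_radius_px: int = 5
    levels: tuple[float, float] = (15000.0, 40000.0)
    noise_sd: float = 1500.0
    size: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_alpha <= 1.0:
            raise ValueError("target_alpha must be in [0, 1]")
        if self.levels[0] >= self.levels[1]:
            raise ValueError("eroded level must be darker than intact level")


def _bump_template(x: np.ndarray, h: float, w: float, shape: str) -> np.ndarray:
    """Height of a periodic bump train at positions x (one period = w)."""
    u = np.mod(x, w)
    if shape == "sinusoid":
        return h * np.sin(np.pi * u / w) ** 2
    if shape == "gaussian":
        sigma = w / 6.0
        return h * np.exp(-((u - w / 2.0) ** 2) / (2.0 * sigma**2))
    # hemisphere: semi-ellipse with semi-axes (w/2, h)
    R = w / 2.0
    return h * np.sqrt(np.maximum(1.0 - ((u - R) / R) ** 2, 0.0))


def _true_arc_ratio(h: float, w: float, shape: str, count: int, dx: float) -> float:
    """High-resolution numerical arc-length / chord ratio (10x density)."""
    L = w * count
    n = max(int(round(L / (dx / 10.0))), 1000) + 1
    x = np.linspace(0.0, L, n)
    z = _bump_template(x, h, w, shape)
    return float(np.hypot(np.diff(x), np.diff(z)).sum() / L)


def bump_height_for_roughness(
    target_r: float, width_um: float = 25.0, shape: str = "sinusoid"
) -> float:
    """Bump height (µm) whose profile arc-length ratio equals target_r."""
    from scipy.optimize import brentq

    if target_r < 1.0:
        raise ValueError("target_r must be >= 1")
    if target_r == 1.0:
        return 0.0
    f = lambda h: _true_arc_ratio(h, width_um, shape, 1, width_um / 2000.0) - target_r
    return float(brentq(f, 1e-6, 10.0 * width_um))


def gen_bump_profile(
    spec: BumpFieldSpec,
) -> tuple[SurfaceProfile, float, GrayscaleImage]:
    """Synthesize an epidermal-bump cross section.

    Returns the analytically sampled profile, the ground-truth roughness
    (arc length at 10x the emitted sampling density), and a rendered
    cross-section raster (solid tissue below the profile, bright on dark,
    Gaussian noise added last).
    """
    h, w, L = spec.bump_height_um, spec.bump_width_um, spec.bump_width_um * spec.count
    n = int(round(L / spec.dx_um)) + 1
    x = np.linspace(0.0, L, n)
    z = _bump_template(x, h, w, spec.shape)
    profile = SurfaceProfile(heights=z, dx_um=float(x[1] - x[0]))
    true_r = _true_arc_ratio(h, w, spec.shape, spec.count, spec.dx_um)

    px = spec.pixel_size_um
    ncols = int(round(L / px))
    nrows = int(math.ceil((h + spec.baseline_um) / px)) + 10
    xc = (np.arange(ncols) + 0.5) * px
    zc = _bump_template(xc, h, w, spec.shape) + spec.baseline_um
    rows = np.arange(nrows)[:, None]
    height_above_bottom = (nrows - 1 - rows) * px
    solid = height_above_bottom <= zc[None, :]
    bg, fg = spec.levels
    rng = np.random.default_rng(spec.seed)
    img = np.where(solid, fg, bg) + rng.normal(0.0, spec.noise_sd, solid.shape)
    raster = GrayscaleImage(
        pixels=np.clip(img, 0, 65535).astype(np.uint16), pixel_size_um=px
    )
    return profile, true_r, raster


def gen_waxtip_image(spec: WaxTipFieldSpec) -> tuple[GrayscaleImage, float]:
    """Synthesize a top-view wax-tip image with known tip coverage.

    Non-overlapping bright discs (tubule tips) are placed by rejection
    sampling on a dark floor with a mid-gray wax blob texture; the ground
    truth is the placed tip mask's pixel fraction (within 0.005 of the
    target by construction).  Raises :class:`PackingError` when the
    requested coverage cannot be packed at the given tip radius.
    """
    nrows, ncols = spec.size
    ss = np.random.SeedSequence(spec.seed)
    rng_field, rng_tips, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))

    floor_lvl, wax_lvl, tip_lvl = spec.levels
    blob = gaussian_filter(
        rng_field.standard_normal(spec.size), spec.wax_blob_sigma_px
    )
    wax_mask = blob >= np.quantile(blob, 1.0 - spec.wax_fraction)
    img = np.where(wax_mask, wax_lvl, floor_lvl).astype(np.float64)

    r = spec.tip_radius_px
    stamp = _disk(r).astype(bool)
    disc_area = int(stamp.sum())
    total = nrows * ncols
    n_discs = int(round(spec.target_phi * total / disc_area))
    tip_mask = np.zeros(spec.size, dtype=bool)
    # forbidden marks centers closer than 2r to a placed center
    forbidden = np.zeros(spec.size, dtype=bool)
    big_stamp = _disk(2 * r).astype(bool)
    placed, tries, max_tries = 0, 0, spec.max_tries_per_disc * max(n_discs, 1)
    while placed < n_discs:
        if tries >= max_tries:
            raise PackingError(
                f"placed only {placed}/{n_discs} tips of radius {r}px after "
                f"{tries} tries; target_phi={spec.target_phi} too dense"
            )
        batch = min(2048, max_tries - tries)
        ii = rng_tips.integers(r, nrows - r, size=batch)
        jj = rng_tips.integers(r, ncols - r, size=batch)
        tries += batch
        for i, j in zip(ii, jj):
            if forbidden[i, j]:
                continue
            tip_mask[i - r : i + r + 1, j - r : j + r + 1] |= stamp
            i0, i1 = max(i - 2 * r, 0), min(i + 2 * r + 1, nrows)
            j0, j1 = max(j - 2 * r, 0), min(j + 2 * r + 1, ncols)
            forbidden[i0:i1, j0:j1] |= big_stamp[
                i0 - (i - 2 * r) : i1 - (i - 2 * r),
                j0 - (j - 2 * r) : j1 - (j - 2 * r),
            ]
            placed += 1
            if placed == n_discs:
                break
    true_phi = float(tip_mask.mean())
    img[tip_mask] = tip_lvl
    img += rng_noise.normal(0.0, spec.noise_sd, img.shape)
    image = GrayscaleImage(
        pixels=np.clip(img, 0, 65535).astype(np.uint16),
        pixel_size_um=spec.pixel_size_um,
    )
    return image, true_phi


def gen_erosion_image(spec: ErosionFieldSpec) -> tuple[GrayscaleImage, float]:
    """Synthesize a partially eroded wax coverage map.

    A smooth correlated Gaussian field is thresholded at the quantile that
    leaves the target intact fraction; the ground truth is the resulting
    mask's pixel fraction, recorded *before* sub-threshold speckles of
    both polarities are injected (the macro-structure the area filters are
    meant to recover).
    """
    nrows, ncols = spec.size
    ss = np.random.SeedSequence(spec.seed)
    rng_field, rng_speckle, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))

    if spec.target_alpha >= 1.0:
        intact = np.ones(spec.size, dtype=bool)
    elif spec.target_alpha <= 0.0:
        intact = np.zeros(spec.size, dtype=bool)
    else:
        sigma = spec.corr_len_um / spec.pixel_size_um
        fld = gaussian_filter(rng_field.standard_normal(spec.size), sigma)
        intact = fld >= np.quantile(fld, 1.0 - spec.target_alpha)
    true_alpha = float(intact.mean())

    mask = intact.copy()

    def _inject(n: int, radius: int, host_intact: bool, value: bool) -> None:
        if n == 0:
            return
        stamp = _disk(radius).astype(bool)
        margin = radius + 2
        host = mask == host_intact
        # speckle must sit fully inside its host class, with a margin so it
        # forms its own connected component
        from scipy.ndimage import binary_erosion

        allowed = binary_erosion(host, _disk(margin))
        allowed[:margin, :] = allowed[-margin:, :] = False
        allowed[:, :margin] = allowed[:, -margin:] = False
        ii, jj = np.nonzero(allowed)
        if ii.size == 0:
            return
        order = rng_speckle.permutation(ii.size)
        placed = 0
        for k in order:
            if placed >= n:
                break
            i, j = int(ii[k]), int(jj[k])
            region = mask[i - radius : i + radius + 1, j - radius : j + radius + 1]
            if (region[stamp] == host_intact).all():
                region[stamp] = value
                placed += 1

    # intact flecks (< 5 um^2) inside eroded regions, then eroded pinholes
    # (< 22.5 um^2) inside intact regions
    _inject(spec.n_intact_speckles, spec.intact_speckle_radius_px, False, True)
    _inject(spec.n_eroded_speckles, spec.eroded_speckle_radius_px, True, False)

    eroded_lvl, intact_lvl = spec.levels
    img = np.where(mask, intact_lvl, eroded_lvl).astype(np.float64)
    img += rng_noise.normal(0.0, spec.noise_sd, img.shape)
    image = GrayscaleImage(
        pixels=np.clip(img, 0, 65535).astype(np.uint16),
        pixel_size_um=spec.pixel_size_um,
    )
    return image, true_alpha


def gen_goniometer_readings(
    true_adv: float,
    true_rec: float,
    sd: float,
    n: int,
    seed: int = 0,
) -> list[MeasuredTiltAngles]:
    """Simulate replicate tilting-goniometer angle readings.

    Gaussian noise of standard deviation ``sd`` degrees is added to both
    angles; draws violating 0 < rec < adv < 180 are redrawn.
    """
    if not true_rec < true_adv:
        raise ValueError("true_rec must be < true_adv")
    if sd < 0 or n < 1:
        raise ValueError("sd must be >= 0 and n >= 1")
    rng = np.random.default_rng(seed)
    out: list[MeasuredTiltAngles] = []
    while len(out) < n:
        adv = true_adv + rng.normal(0.0, sd)
        rec = true_rec + rng.normal(0.0, sd)
        if 0.0 < rec <= adv < 180.0:
            out.append(MeasuredTiltAngles(theta_adv=adv, theta_rec=rec))
    return out


# --------------------------------------------------------------------------
# 6. Pipeline: presets, headline tables, reports, I/O
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class LeafStatePreset:
    """One leaf state with its morphology and measured tilt angles."""

    name: str
    morphology: SurfaceMorphology
    flat: FlatWaxAngles
    measured: MeasuredTiltAngles


#: Flat extracted-wax reference surface: mean 101°, advancing/receding 117°/86°.
FLAT_WAX = FlatWaxAngles(theta_mean=101.0, theta_adv=117.0, theta_rec=86.0)

#: Measured leaf states: summer green, late-fall brown, and the two
#: lab treatments that selectively alter one roughness tier.
PRESETS: dict[str, LeafStatePreset] = {
    "green": LeafStatePreset(
        "green",
        SurfaceMorphology(r_micro=1.16, phi_nano=0.25, alpha=1.0),
        FLAT_WAX,
        MeasuredTiltAngles(theta_adv=157.0, theta_rec=137.0),
    ),
    "brown": LeafStatePreset(
        "brown",
        SurfaceMorphology(r_micro=1.07, phi_nano=0.25, alpha=0.46),
        FLAT_WAX,
        MeasuredTiltAngles(theta_adv=151.0, theta_rec=96.0),
    ),
    "heat_treated": LeafStatePreset(
        "heat_treated",
        SurfaceMorphology(r_micro=1.13, phi_nano=0.25, alpha=0.0),
        FLAT_WAX,
        MeasuredTiltAngles(theta_adv=127.0, theta_rec=86.0),
    ),
    "vacuum_dried": LeafStatePreset(
        "vacuum_dried",
        SurfaceMorphology(r_micro=1.10, phi_nano=0.25, alpha=1.0),
        FLAT_WAX,
        MeasuredTiltAngles(theta_adv=162.0, theta_rec=131.0),
    ),
}


def reproduce_table1(
    presets: Mapping[str, LeafStatePreset] | None = None,
) -> pd.DataFrame:
    """Theoretical vs experimental apparent contact angles per leaf state.

    The display columns are rounded half-up to integer degrees; the exact
    columns keep full precision.  The experimental angle is the mean of
    the measured advancing and receding angles.
    """
    presets = PRESETS if presets is None else presets
    rows = []
    for preset in presets.values():
        theo = combined_angle(preset.morphology, preset.flat.theta_mean)
        exp = preset.measured.theta_bar
        rows.append(
            {
                "state": preset.name,
                "theoretical_deg": _round_half_up(theo),
                "experimental_deg": _round_half_up(exp),
                "abs_difference_deg": _round_half_up(abs(theo - exp)),
                "theoretical_exact": theo,
                "experimental_exact": exp,
                "r_micro": preset.morphology.r_micro,
                "phi_nano": preset.morphology.phi_nano,
                "alpha": preset.morphology.alpha,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class WettabilityReport:
    """Full model output for one leaf state.

    Both hysteresis variants are reported: ``as_printed`` (the published
    relation) and ``derivative`` (the form differentiation of the
    combined-angle model gives), so the ambiguity between them is surfaced
    rather than hidden.  ``rolloff_tilt_deg`` is either degrees or the
    string "PINNED".
    """

    state: str
    r_micro: float
    phi_nano: float
    alpha: float
    theta_flat_mean: float
    theta_flat_adv: float
    theta_flat_rec: float
    theta_star: float
    hysteresis_as_printed: float
    hysteresis_derivative: float
    theta_star_adv: float
    theta_star_rec: float
    measured_adv: float | None = None
    measured_rec: float | None = None
    droplet_volume_ul: float | None = None
    critical_volume_ul: float | None = None
    rolloff_tilt_deg: float | str | None = None
    reference_state: str | None = None
    critical_volume_ratio: float | None = None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "WettabilityReport":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        return cls(**json.loads(text))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.to_dict()])


def _resolve_state(
    config: str | LeafStatePreset | Mapping,
) -> tuple[str, SurfaceMorphology, FlatWaxAngles, MeasuredTiltAngles | None]:
    """Resolve a preset name, preset, or flat mapping into model inputs."""
    if isinstance(config, str):
        if config not in PRESETS:
            raise KeyError(
                f"unknown preset {config!r}; available: {sorted(PRESETS)}"
            )
        config = PRESETS[config]
    if isinstance(config, LeafStatePreset):
        return config.name, config.morphology, config.flat, config.measured
    if isinstance(config, Mapping):
        missing = [k for k in ("r_micro", "phi_nano", "alpha") if k not in config]
        if missing:
            raise KeyError(f"state config missing key(s): {', '.join(missing)}")
        morph = SurfaceMorphology(
            r_micro=float(config["r_micro"]),
            phi_nano=float(config["phi_nano"]),
            alpha=float(config["alpha"]),
        )
        flat = FlatWaxAngles(
            theta_mean=float(config.get("theta_flat_mean", FLAT_WAX.theta_mean)),
            theta_adv=float(config.get("theta_flat_adv", FLAT_WAX.theta_adv)),
            theta_rec=float(config.get("theta_flat_rec", FLAT_WAX.theta_rec)),
        )
        measured = None
        if "measured_adv" in config and "measured_rec" in config:
            measured = MeasuredTiltAngles(
                theta_adv=float(config["measured_adv"]),
                theta_rec=float(config["measured_rec"]),
            )
        return str(config.get("name", "custom")), morph, flat, measured
    raise TypeError(f"cannot resolve state config of type {type(config)!r}")


def predict_leaf(
    state: str | LeafStatePreset | Mapping,
    droplet: DropletSpec | None = None,
    reference: str | LeafStatePreset | Mapping | None = None,
) -> WettabilityReport:
    """Predict apparent wetting, hysteresis and droplet retention.

    Tilt mechanics (critical volume, roll-off tilt, volume ratio against
    the reference state) use the measured tilt angles when the state
    carries them, otherwise the model-predicted advancing/receding pair.
    """
    name, morph, flat, measured = _resolve_state(state)
    if droplet is None:
        droplet = DropletSpec.from_microliters(10.0)
    aw = apparent_wetting(morph, flat, variant="as_printed")
    dh_deriv = hysteresis_leaf_derivative(morph, flat, aw.theta_star)
    tilt_angles = measured or MeasuredTiltAngles(
        theta_adv=aw.theta_star_adv, theta_rec=aw.theta_star_rec
    )
    vc = critical_volume(tilt_angles, droplet)
    beta = rolloff_tilt(
        droplet.volume, tilt_angles, droplet.gamma_LA, droplet.rho, droplet.g
    )
    report = WettabilityReport(
        state=name,
        r_micro=morph.r_micro,
        phi_nano=morph.phi_nano,
        alpha=morph.alpha,
        theta_flat_mean=flat.theta_mean,
        theta_flat_adv=flat.theta_adv,
        theta_flat_rec=flat.theta_rec,
        theta_star=aw.theta_star,
        hysteresis_as_printed=aw.hysteresis_leaf,
        hysteresis_derivative=dh_deriv,
        theta_star_adv=aw.theta_star_adv,
        theta_star_rec=aw.theta_star_rec,
        measured_adv=measured.theta_adv if measured else None,
        measured_rec=measured.theta_rec if measured else None,
        droplet_volume_ul=droplet.volume * 1e9,
        critical_volume_ul=vc * 1e9,
        rolloff_tilt_deg=beta.value if beta is PINNED else beta,
    )
    if reference is not None:
        ref_name, _, _, ref_measured = _resolve_state(reference)
        if ref_measured is None:
            raise KeyError(
                f"reference state {ref_name!r} carries no measured tilt angles"
            )
        report.reference_state = ref_name
        report.critical_volume_ratio = volume_ratio(tilt_angles, ref_measured)
    logger.info(
        "predict %s: theta*=%.1f deg, hysteresis=%.1f deg, rolloff=%s",
        name, aw.theta_star, aw.hysteresis_leaf, report.rolloff_tilt_deg,
    )
    return report


def load_image(path: str | Path, pixel_size_um: float | None = None) -> GrayscaleImage:
    """Read an 8/16-bit grayscale TIFF or PNG into a calibrated raster."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        pixels = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        pixels = iio.imread(path)
    pixels = np.asarray(pixels)
    if pixels.ndim == 3:  # collapse trivial channel axes
        pixels = pixels[..., 0]
    return GrayscaleImage(pixels=pixels, pixel_size_um=pixel_size_um)


def read_manifest(path: str | Path) -> list[tuple[GrayscaleImage, str, str]]:
    """Read a sidecar CSV manifest (filename, role, pixel_size_um).

    Paths are resolved relative to the manifest's directory.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - wrap parse failures
        raise ManifestError(f"cannot parse manifest {path}: {exc}") from exc
    required = {"filename", "role", "pixel_size_um"}
    if not required.issubset(df.columns):
        raise ManifestError(
            f"manifest {path} missing column(s): {sorted(required - set(df.columns))}"
        )
    items = []
    for _, row in df.iterrows():
        img = load_image(path.parent / str(row["filename"]),
                         float(row["pixel_size_um"]))
        items.append((img, str(row["role"]), str(row["filename"])))
    return items


def run_end_to_end(
    manifest: str | Path | Sequence[tuple],
    flat: FlatWaxAngles = FLAT_WAX,
    droplet: DropletSpec | None = None,
    reference: str | LeafStatePreset | Mapping | None = None,
    config: MorphometryConfig = DEFAULT_CONFIG,
    state_name: str = "from_images",
) -> tuple[WettabilityReport, list[MorphometryReport]]:
    """Full analysis: micrographs -> morphology -> wetting prediction.

    ``manifest`` is either a CSV path (filename, role, pixel_size_um) or
    an in-memory sequence of ``(image, role[, name])`` tuples; all three
    roles must be present.
    """
    if isinstance(manifest, (str, Path)):
        items: Sequence[tuple] = read_manifest(manifest)
    else:
        items = manifest
    morph, reports = morphometry_pipeline(items, config)
    state = {
        "name": state_name,
        "r_micro": morph.r_micro,
        "phi_nano": morph.phi_nano,
        "alpha": morph.alpha,
        "theta_flat_mean": flat.theta_mean,
        "theta_flat_adv": flat.theta_adv,
        "theta_flat_rec": flat.theta_rec,
    }
    return predict_leaf(state, droplet=droplet, reference=reference), reports


def load_params(path: str | Path) -> dict:
    """Load a flat key-value parameter file (YAML or JSON)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path} must contain a flat key-value mapping")
    return data


_TABLE_COLUMNS = [
    "leaf_state",
    "r_micro",
    "phi_nano",
    "alpha",
    "theta_flat_mean",
    "theta_flat_adv",
    "theta_flat_rec",
]


def read_morphology_table(path: str | Path) -> dict[str, LeafStatePreset]:
    """Read leaf states from a CSV with the standard parameter columns."""
    df = pd.read_csv(path)
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"morphology table missing column(s): {missing}")
    out: dict[str, LeafStatePreset] = {}
    for _, row in df.iterrows():
        name = str(row["leaf_state"])
        measured = (
            MeasuredTiltAngles(float(row["measured_adv"]), float(row["measured_rec"]))
            if {"measured_adv", "measured_rec"}.issubset(df.columns)
            and not (pd.isna(row.get("measured_adv")) or pd.isna(row.get("measured_rec")))
            else PRESETS[name].measured if name in PRESETS else None
        )
        out[name] = LeafStatePreset(
            name=name,
            morphology=SurfaceMorphology(
                float(row["r_micro"]), float(row["phi_nano"]), float(row["alpha"])
            ),
            flat=FlatWaxAngles(
                float(row["theta_flat_mean"]),
                float(row["theta_flat_adv"]),
                float(row["theta_flat_rec"]),
            ),
            measured=measured
            or MeasuredTiltAngles(float(row["theta_flat_adv"]),
                                  float(row["theta_flat_rec"])),
        )
    return out


def write_morphology_table(
    presets: Mapping[str, LeafStatePreset], path: str | Path
) -> None:
    """Write leaf states as the standard flat CSV."""
    rows = []
    for p in presets.values():
        rows.append(
            {
                "leaf_state": p.name,
                "r_micro": p.morphology.r_micro,
                "phi_nano": p.morphology.phi_nano,
                "alpha": p.morphology.alpha,
                "theta_flat_mean": p.flat.theta_mean,
                "theta_flat_adv": p.flat.theta_adv,
                "theta_flat_rec": p.flat.theta_rec,
                "measured_adv": p.measured.theta_adv,
                "measured_rec": p.measured.theta_rec,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
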