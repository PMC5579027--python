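"""Channel geometry, the pixel-to-channel coordinate transform, and the
closed-form resistive-pulse amplitude models.

A translocating insulating sphere of diameter ``d`` raises the resistance of
a conducting channel.  For a long cylindrical channel (length ``L``, diameter
``D``) the on-axis relative current blockade is Smythe's result

    dI/I_p = d^3 / (L D^2) * [1 - 0.8 (d/D)^3]^(-1)

and the *local* resistance increase, which depends only on the channel
cross-section at the particle's axial position, is

    dR = 4 rho d^3 / (pi D(x)^4) * [1 - 0.8 (d/D(x))^3]^(-1).

Off-axis passages blockade more current; the empirical correction of Berge is

    dI(y)/dI(0) = 1 + alpha * (y_norm * d / D)^3

with ``y_norm`` the lateral displacement of the particle centre normalised by
the channel radius and ``alpha`` an empirical coefficient (reported range
5-7.5 for micropores).

Rectangular microfluidic channels are mapped onto these cylindrical formulas
through the equal-cross-sectional-area equivalent diameter
``D_eq = sqrt(4 w h / pi)``.

All lengths are micrometres unless a name says otherwise; resistivity is in
ohm-metres and resistances in ohms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InvalidGeometryError",
    "ChannelGeometry",
    "ChannelFrame",
    "Particle",
    "TheoryParams",
    "make_frame",
    "to_channel_coords",
    "channel_to_pixel",
    "smythe_amplitude",
    "offaxis_factor",
    "local_delta_R",
    "amplitude_ratio",
    "equivalent_diameter",
    "width_profile",
]


class InvalidGeometryError(ValueError):
    """Raised for degenerate or physically impossible geometry."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChannelGeometry:
    """Physical description of a straight or cavity microfluidic channel.

    Parameters
    ----------
    kind:
        ``"straight"`` (constant width) or ``"cavity"`` (a wider central
        section between two narrow constrictions).
    length_um:
        Total axial extent ``L`` of the channel.
    height_um:
        Channel height ``h`` (the dimension not resolved by the camera).
    width_um:
        Width of a straight channel.
    width_narrow_um, width_wide_um:
        Widths of the narrow constrictions and the central cavity.
    cavity_start_um, cavity_end_um:
        Axial extent of the cavity, ``0 < start < end < L``.
    resistivity_ohm_m:
        Solution resistivity ``rho``.  Default is 1 M KCl (~0.092 ohm m).
    """

    kind: str
    length_um: float
    height_um: float
    width_um: float | None = None
    width_narrow_um: float | None = None
    width_wide_um: float | None = None
    cavity_start_um: float | None = None
    cavity_end_um: float | None = None
    resistivity_ohm_m: float = 0.092

    def __post_init__(self) -> None:
        if self.kind not in ("straight", "cavity"):
            raise InvalidGeometryError(f"unknown channel kind {self.kind!r}")
        if not self.length_um > 0:
            raise InvalidGeometryError("channel length must be positive")
        if not self.height_um > 0:
            raise InvalidGeometryError("channel height must be positive")
        if not self.resistivity_ohm_m > 0:
            raise InvalidGeometryError("resistivity must be positive")
        if self.kind == "straight":
            if self.width_um is None or not self.width_um > 0:
                raise InvalidGeometryError("straight channel needs width_um > 0")
        else:
            for name in ("width_narrow_um", "width_wide_um", "cavity_start_um", "cavity_end_um"):
                if getattr(self, name) is None:
                    raise InvalidGeometryError(f"cavity channel needs {name}")
            if not (self.width_narrow_um > 0 and self.width_wide_um > self.width_narrow_um):
                raise InvalidGeometryError("cavity channel needs width_wide_um > width_narrow_um > 0")
            if not (0 < self.cavity_start_um < self.cavity_end_um < self.length_um):
                raise InvalidGeometryError("cavity must satisfy 0 < start < end < L")

    # convenience constructors -------------------------------------------------

    @classmethod
    def straight(cls, length_um: float, width_um: float, height_um: float,
                 resistivity_ohm_m: float = 0.092) -> "ChannelGeometry":
        return cls(kind="straight", length_um=length_um, width_um=width_um,
                   height_um=height_um, resistivity_ohm_m=resistivity_ohm_m)

    @classmethod
    def with_cavity(cls, length_um: float, width_narrow_um: float, width_wide_um: float,
                    height_um: float, cavity_start_um: float, cavity_end_um: float,
                    resistivity_ohm_m: float = 0.092) -> "ChannelGeometry":
        return cls(kind="cavity", length_um=length_um, width_narrow_um=width_narrow_um,
                   width_wide_um=width_wide_um, height_um=height_um,
                   cavity_start_um=cavity_start_um, cavity_end_um=cavity_end_um,
                   resistivity_ohm_m=resistivity_ohm_m)

    @property
    def min_width_um(self) -> float:
        return self.width_um if self.kind == "straight" else self.width_narrow_um

    @property
    def max_width_um(self) -> float:
        return self.width_um if self.kind == "straight" else self.width_wide_um

    def baseline_resistance_ohm(self) -> float:
        """Series resistance R0 = rho * integral dx / A(x) over the channel."""
        rho = self.resistivity_ohm_m
        h = self.height_um * 1e-6
        if self.kind == "straight":
            return rho * (self.length_um * 1e-6) / (self.width_um * 1e-6 * h)
        l_narrow = (self.length_um - (self.cavity_end_um - self.cavity_start_um)) * 1e-6
        l_wide = (self.cavity_end_um - self.cavity_start_um) * 1e-6
        return rho * (l_narrow / (self.width_narrow_um * 1e-6 * h)
                      + l_wide / (self.width_wide_um * 1e-6 * h))


@dataclass(frozen=True)
class Particle:
    """A rigid spherical bead of diameter ``d`` (µm)."""

    diameter_um: float

    def __post_init__(self) -> None:
        if not self.diameter_um > 0:
            raise ValueError("particle diameter must be positive")


@dataclass(frozen=True)
class TheoryParams:
    """Parameters of the off-axis amplitude correction.

    ``alpha`` is the empirical off-axis coefficient; ``normalize_by_radius``
    records the convention that the lateral displacement entering the formula
    is the particle-centre displacement divided by the channel *radius*
    (0 on-axis, 1 at wall contact of a point particle).
    """

    alpha: float = 6.0
    normalize_by_radius: bool = True

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")


@dataclass(frozen=True)
class ChannelFrame:
    """Pixel-frame anchors of a channel: origin, orthonormal axes and scale.

    The origin is the midpoint of the two entrance-side corner points, the
    axial unit vector points from entrance to exit, and ``scale`` converts
    pixels to micrometres.
    """

    origin_px: np.ndarray
    x_hat: np.ndarray
    y_hat: np.ndarray
    scale_um_per_px: float
    entrance_corners_px: np.ndarray = field(default=None, repr=False)
    exit_corners_px: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for name in ("origin_px", "x_hat", "y_hat"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not self.scale_um_per_px > 0:
            raise InvalidGeometryError("scale must be positive")
        if abs(np.dot(self.x_hat, self.y_hat)) > 1e-6 or \
                abs(np.linalg.norm(self.x_hat) - 1) > 1e-6 or \
                abs(np.linalg.norm(self.y_hat) - 1) > 1e-6:
            raise InvalidGeometryError("frame axes must be orthonormal")


# ---------------------------------------------------------------------------
# coordinate transform
# ---------------------------------------------------------------------------


def make_frame(entrance_corners_px, exit_corners_px, physical_length_um: float) -> ChannelFrame:
    """Build a :class:`ChannelFrame` from the four clicked corner points.

    The axial direction is the normalised mean of the two entrance-to-exit
    corner vectors; the lateral axis is that direction rotated +90 degrees
    (so the frame is exactly orthonormal even for imperfect corner clicks).
    The scale is the physical channel length divided by the mean pixel
    distance between the entrance and exit corner pairs.
    """
    ent = np.asarray(entrance_corners_px, dtype=float).reshape(2, 2)
    exi = np.asarray(exit_corners_px, dtype=float).reshape(2, 2)
    if not physical_length_um > 0:
        raise InvalidGeometryError("physical length must be positive")
    vecs = exi - ent
    mean_vec = vecs.mean(axis=0)
    norm = np.linalg.norm(mean_vec)
    if norm < 1e-12:
        raise InvalidGeometryError("entrance and exit corner pairs are coincident")
    x_hat = mean_vec / norm
    y_hat = np.array([-x_hat[1], x_hat[0]])  # +90 deg rotation
    origin = ent.mean(axis=0)
    mean_span = np.linalg.norm(vecs, axis=1).mean()
    scale = physical_length_um / mean_span
    return ChannelFrame(origin_px=origin, x_hat=x_hat, y_hat=y_hat,
                        scale_um_per_px=scale, entrance_corners_px=ent,
                        exit_corners_px=exi)


def to_channel_coords(points_px, frame: ChannelFrame):
    """Map pixel points to channel coordinates (x_c, y_c) in µm.

    ``points_px`` may be a single (x, y) pair or an (N, 2) array.  The
    entrance plane maps to x_c = 0 and the channel axis to y_c = 0.
    """
    pts = np.asarray(points_px, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts) - frame.origin_px
    x_c = frame.scale_um_per_px * (pts @ frame.x_hat)
    y_c = frame.scale_um_per_px * (pts @ frame.y_hat)
    if single:
        return float(x_c[0]), float(y_c[0])
    return x_c, y_c


def channel_to_pixel(x_c_um, y_c_um, frame: ChannelFrame):
    """Inverse of :func:`to_channel_coords` (channel µm -> pixel)."""
    x = np.asarray(x_c_um, dtype=float) / frame.scale_um_per_px
    y = np.asarray(y_c_um, dtype=float) / frame.scale_um_per_px
    px = frame.origin_px[0] + x * frame.x_hat[0] + y * frame.y_hat[0]
    py = frame.origin_px[1] + x * frame.x_hat[1] + y * frame.y_hat[1]
    return px, py


# ---------------------------------------------------------------------------
# amplitude models
# ---------------------------------------------------------------------------


def _check_d_lt_D(d_um, D_um) -> None:
    if np.any(np.asarray(d_um) <= 0):
        raise ValueError("particle diameter must be positive")
    if np.any(np.asarray(d_um) >= np.asarray(D_um)):
        raise ValueError("particle diameter must be smaller than the channel diameter")


def smythe_amplitude(d_um, D_um, L_um):
    """On-axis relative blockade dI/I_p of a sphere in a cylindrical channel."""
    _check_d_lt_D(d_um, D_um)
    if np.any(np.asarray(L_um) <= 0):
        raise ValueError("channel length must be positive")
    d = np.asarray(d_um, dtype=float)
    D = np.asarray(D_um, dtype=float)
    L = np.asarray(L_um, dtype=float)
    out = d ** 3 / (L * D ** 2) / (1.0 - 0.8 * (d / D) ** 3)
    return out if out.ndim else float(out)

def offaxis_factor(y_norm, d_um, D_um, params: TheoryParams = TheoryParams()):
    """Off-axis amplitude excess factor 1 + alpha (y_norm d / D)^3 (>= 1).

    ``y_norm`` is the lateral displacement of the particle centre divided by
    the channel radius; the accessible range is [0, (D - d)/D] (beyond which
    the particle would intersect the wall).
    """
    _check_d_lt_D(d_um, D_um)
    y = np.asarray(y_norm, dtype=float)
    d = np.asarray(d_um, dtype=float)
    D = np.asarray(D_um, dtype=float)
    if np.any(y < 0) or np.any(y > (D - d) / D + 1e-12):
        raise ValueError("y_norm outside the accessible range [0, (D-d)/D]")
    out = 1.0 + params.alpha * (y * d / D) ** 3
    return out if out.ndim else float(out)


def local_delta_R(rho_ohm_m, d_um, D_um):
    """Local resistance increase dR (ohm) of a sphere in a section of
    diameter ``D`` — depends only on the geometry local to the particle."""
    _check_d_lt_D(d_um, D_um)
    if np.any(np.asarray(rho_ohm_m) <= 0):
        raise ValueError("resistivity must be positive")
    d = np.asarray(d_um, dtype=float) * 1e-6
    D = np.asarray(D_um, dtype=float) * 1e-6
    out = 4.0 * np.asarray(rho_ohm_m, dtype=float) * d ** 3 / (np.pi * D ** 4) \
        / (1.0 - 0.8 * (d / D) ** 3)
    return out if out.ndim else float(out)


def amplitude_ratio(d_um, D1_um, D2_um):
    """Predicted ratio of relative blockades between two channel sections,
    dR|_{D1} / dR|_{D2}; independent of the solution resistivity."""
    _check_d_lt_D(d_um, D1_um)
    _check_d_lt_D(d_um, D2_um)
    return local_delta_R(1.0, d_um, D1_um) / local_delta_R(1.0, d_um, D2_um)


def equivalent_diameter(w_um, h_um):
    """Diameter of the circle with the same area as a w x h rectangle."""
    w = np.asarray(w_um, dtype=float)
    h = np.asarray(h_um, dtype=float)
    if np.any(w <= 0) or np.any(h <= 0):
        raise ValueError("cross-section dimensions must be positive")
    out = np.sqrt(4.0 * w * h / np.pi)
    return out if out.ndim else float(out)


def width_profile(geom: ChannelGeometry, x_c_um):
    """Local channel width w(x_c) in µm; ``inf`` outside the channel
    (the unbounded reservoir)."""
    x = np.asarray(x_c_um, dtype=float)
    out = np.full(x.shape, np.inf)
    inside = (x >= 0) & (x <= geom.length_um)
    if geom.kind == "straight":
        out[inside] = geom.width_um
    else:
        out[inside] = geom.width_narrow_um
        in_cavity = inside & (x >= geom.cavity_start_um) & (x <= geom.cavity_end_um)
        out[in_cavity] = geom.width_wide_um
    return out if out.ndim else float(out)
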