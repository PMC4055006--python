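"""Analytic magnetostatics of an axially magnetized cylindrical permanent magnet.

The field source throughout this package is a uniformly magnetized NdFeB
cylinder, modelled with the equivalent-surface-charge picture: two uniformly
"charged" disks of density ±M = Br/mu0 at the pole faces. Outside the body the
field has the exact closed form of Derby & Olbert (Am. J. Phys. 78, 2010) in
terms of Bulirsch's generalized complete elliptic integral ``cel``, which we
evaluate with the vectorized Bulirsch iteration. This is mesh-free and exact,
so it can be validated against independent brute-force quadrature over the two
disk faces.

Canonical magnet frame: the pole-face center ``O`` is the origin, the magnet
axis is +z, the body occupies z in [-L, 0], and r is the cylindrical radius.
On the axis the flux density reduces to

    Bz(z) = (Br/2) * [ (z+L)/sqrt((z+L)^2 + R^2) - z/sqrt(z^2 + R^2) ]

which is also the calibration formula tying the remanence Br to the measured
pole-face field. Lab-frame placement is a rigid transform carried by
``MagnetSpec.pose``.

The ideal uniformly-magnetized model is singular on the pole-face edge ring;
points closer than ``EDGE_MARGIN_M`` to an edge are clamped outward to the
margin and flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MU0 = 4e-7 * np.pi  # vacuum permeability, T*m/A

#: exclusion margin around the singular pole-face edge ring, m
EDGE_MARGIN_M = 1e-4

#: default finite-difference step for gradients, m
DEFAULT_FD_STEP_M = 1e-6

__all__ = [
    "MagnetSpec",
    "FieldSample",
    "on_axis_field",
    "field_at",
    "gradient_at",
    "calibrate_remanence",
    "field_map",
    "b_field",
    "default_magnet",
    "UniformField",
    "EDGE_MARGIN_M",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MagnetSpec:
    """Axially magnetized cylindrical permanent magnet.

    Parameters
    ----------
    radius_m : float
        Cylinder radius R (m). The study magnet is 8 mm in diameter, R = 4 mm.
    length_m : float
        Cylinder length L along the axis (m).
    remanence_t : float
        Remanence Br (T), the source strength of the uniformly magnetized
        model; calibrate with :func:`calibrate_remanence`.
    origin_m : tuple
        Lab-frame position of the pole-face center O (m).
    axis : tuple
        Lab-frame unit vector of the magnet axis, pointing out of the pole
        face O (the body lies behind O along -axis).
    """

    radius_m: float = 4.0e-3
    length_m: float = 8.0e-3
    remanence_t: float = 1.0
    origin_m: tuple = (0.0, 0.0, 0.0)
    axis: tuple = (0.0, 0.0, 1.0)

    def __post_init__(self):
        if self.radius_m <= 0 or self.length_m <= 0:
            raise ValueError("magnet radius and length must be positive")
        if self.remanence_t <= 0:
            raise ValueError("remanence must be positive")
        ax = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(ax)
        if not np.isfinite(n) or n == 0:
            raise ValueError("axis must be a nonzero vector")
        object.__setattr__(self, "axis", tuple(ax / n))
        object.__setattr__(self, "origin_m", tuple(float(v) for v in self.origin_m))

    def with_pose(self, origin_m, axis) -> "MagnetSpec":
        """Return a copy rigidly placed at ``origin_m`` with the given axis."""
        return replace(self, origin_m=tuple(origin_m), axis=tuple(axis))


@dataclass
class FieldSample:
    """Flux density (and optionally its derivatives) at one exterior point.

    ``point_m`` is in lab coordinates. ``grad`` is the 3x3 Jacobian
    dB_i/dx_j (T/m); ``grad_bmag`` is the gradient of |B|, the quantity that
    drives the magnetophoretic force; ``dbmag_dr`` is the magnet-frame radial
    derivative of |B| (the field-gradient map of the study).
    """

    point_m: np.ndarray
    b_t: np.ndarray
    b_mag_t: float
    grad: np.ndarray | None = None
    grad_bmag: np.ndarray | None = None
    dbmag_dr: float | None = None
    clamped: bool = False


class UniformField:
    """Stub field source with a spatially constant flux density.

    Implements the duck-typed source interface (``b_field(points)``) used by
    :func:`b_field`; handy for zero-gradient tests and force stubs.
    """

    def __init__(self, b_vector_t):
        self.b_vector_t = np.asarray(b_vector_t, dtype=float)

    def b_field(self, points_m: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_m, dtype=float))
        return np.broadcast_to(self.b_vector_t, (pts.shape[0], 3)).copy()


# ---------------------------------------------------------------------------
# Bulirsch cel and the closed-form cylinder field
# ---------------------------------------------------------------------------

def _cel(kc, p, c, s, errtol=1e-10, max_iter=40):
    """Bulirsch's generalized complete elliptic integral, vectorized.

    cel(kc, p, c, s) = int_0^{pi/2} (c cos^2 t + s sin^2 t)
        / ((cos^2 t + p sin^2 t) sqrt(cos^2 t + kc^2 sin^2 t)) dt

    Only the p > 0 branch is needed for the exterior cylinder field; p is
    clamped away from zero by the caller.
    """
    kc = np.abs(np.asarray(kc, dtype=float))
    p = np.asarray(p, dtype=float)
    c = np.asarray(c, dtype=float)
    s = np.asarray(s, dtype=float)
    kc, p, c, s = np.broadcast_arrays(kc, p, c, s)
    kc = np.where(kc < 1e-14, 1e-14, kc)

    k = kc.copy()
    pp = np.sqrt(p)
    ss = s / pp
    cc = c.astype(float).copy()
    em = np.ones_like(k)

    f = cc.copy()
    cc = cc + ss / pp
    g = k / pp
    ss = 2.0 * (ss + f * g)
    pp = g + pp
    g = em.copy()
    em = k + em
    kk = k.copy()

    for _ in range(max_iter):
        active = np.abs(g - k) > g * errtol
        if not np.any(active):
            break
        k = 2.0 * np.sqrt(kk)
        kk = k * em
        f = cc.copy()
        cc = cc + ss / pp
        g = kk / pp
        ss = 2.0 * (ss + f * g)
        pp = g + pp
        g = em.copy()
        em = k + em
    return (np.pi / 2.0) * (ss + cc * em) / (em * (em + pp))


def _field_rz(rho, z, radius_m, length_m, remanence_t):
    """Closed-form (B_rho, B_z) of the cylinder in the magnet frame.

    Frame: pole face at z = 0, body in z in [-L, 0]. Valid outside the body
    (the formulas themselves hold everywhere, but interior use is out of
    contract at the call sites).
    """
    rho = np.asarray(rho, dtype=float)
    z = np.asarray(z, dtype=float)
    a = radius_m
    b = 0.5 * length_m
    # shift to the body-centered frame of the closed form
    zc = z + 0.5 * length_m
    b0 = remanence_t / np.pi

    zp = zc + b
    zm = zc - b
    rho_pa = rho + a
    denom_p = np.sqrt(zp * zp + rho_pa * rho_pa)
    denom_m = np.sqrt(zm * zm + rho_pa * rho_pa)
    alpha_p = a / denom_p
    alpha_m = a / denom_m
    beta_p = zp / denom_p
    beta_m = zm / denom_m
    gamma = (a - rho) / (a + rho)
    kp = np.sqrt((zp * zp + (a - rho) ** 2) / (zp * zp + rho_pa * rho_pa))
    km = np.sqrt((zm * zm + (a - rho) ** 2) / (zm * zm + rho_pa * rho_pa))

    b_rho = b0 * (alpha_p * _cel(kp, 1.0, 1.0, -1.0)
                  - alpha_m * _cel(km, 1.0, 1.0, -1.0))
    p = np.maximum(gamma * gamma, 1e-14)
    b_z = (b0 * a / (a + rho)) * (beta_p * _cel(kp, p, 1.0, gamma)
                                  - beta_m * _cel(km, p, 1.0, gamma))
    return b_rho, b_z


# ---------------------------------------------------------------------------
# frame handling
# ---------------------------------------------------------------------------

def _frame_decompose(points_m: np.ndarray, magnet: MagnetSpec):
    """Return (rho, z, rho_hat) of lab points in the magnet frame."""
    pts = np.atleast_2d(np.asarray(points_m, dtype=float))
    o = np.asarray(magnet.origin_m)
    n = np.asarray(magnet.axis)
    rel = pts - o
    z = rel @ n
    perp = rel - np.outer(z, n)
    rho = np.linalg.norm(perp, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho_hat = np.where(rho[:, None] > 0, perp / np.where(rho[:, None] > 0, rho[:, None], 1.0), 0.0)
    return rho, z, rho_hat


def _is_interior(rho, z, magnet: MagnetSpec, pad=0.0):
    return (rho <= magnet.radius_m + pad) & (z <= pad) & (z >= -magnet.length_m - pad)


def _edge_distance(rho, z, magnet: MagnetSpec):
    """Distance to the nearer of the two singular pole-face edge rings."""
    d_face = np.hypot(rho - magnet.radius_m, z)
    d_back = np.hypot(rho - magnet.radius_m, z + magnet.length_m)
    return np.minimum(d_face, d_back)


def _clamp_edge(rho, z, magnet: MagnetSpec, margin=EDGE_MARGIN_M):
    """Push points inside the edge exclusion zone out to the margin radius."""
    rho = np.array(rho, dtype=float, copy=True)
    z = np.array(z, dtype=float, copy=True)
    for ring_z in (0.0, -magnet.length_m):
        dr = rho - magnet.radius_m
        dz = z - ring_z
        d = np.hypot(dr, dz)
        close = d < margin
        if np.any(close):
            # degenerate exactly-on-ring points get pushed straight out radially
            dr = np.where(close & (d == 0), 1.0, dr)
            dz = np.where(close & (d == 0), 0.0, dz)
            d = np.where(d == 0, 1.0, d)
            scale = margin / d
            rho = np.where(close, magnet.radius_m + dr * scale, rho)
            z = np.where(close, ring_z + dz * scale, z)
    return rho, z


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def on_axis_field(z_m, magnet: MagnetSpec):
    """Axial flux density Bz (T) at distance ``z_m`` from the pole-face center.

    Closed-form special case of the cylinder field:
    Bz(z) = (Br/2) [ (z+L)/sqrt((z+L)^2+R^2) - z/sqrt(z^2+R^2) ].
    Strictly decreasing in z and -> 0 as z -> inf. Points behind the pole
    face (z < 0) are out of contract.
    """
    z = np.asarray(z_m, dtype=float)
    if np.any(z < 0):
        raise ValueError("on_axis_field requires z >= 0 (in front of the pole face)")
    R, L, Br = magnet.radius_m, magnet.length_m, magnet.remanence_t
    bz = 0.5 * Br * ((z + L) / np.hypot(z + L, R) - z / np.hypot(z, R))
    return bz if np.ndim(z_m) else float(bz)


def calibrate_remanence(target_surface_field_t: float, radius_m: float = 4.0e-3,
                        length_m: float = 8.0e-3, where: str = "center") -> float:
    """Remanence Br such that the modelled surface field equals the measured one.

    ``where='center'`` (default) matches the pole-face *center* field,
    Br = 2 * target * sqrt(L^2+R^2) / L. ``where='flank'`` matches |B| at the
    flank point (r = R, z = EDGE_MARGIN_M), just outside the edge exclusion
    zone where the ideal model is singular; the field is linear in Br, so the
    calibration is a single ratio either way.
    """
    if target_surface_field_t < 0:
        raise ValueError("target surface field must be >= 0")
    if target_surface_field_t == 0:
        return 0.0
    if where == "center":
        unit = 0.5 * length_m / np.hypot(length_m, radius_m)
    elif where == "flank":
        b_rho, b_z = _field_rz(radius_m, EDGE_MARGIN_M, radius_m, length_m, 1.0)
        unit = float(np.hypot(b_rho, b_z))
    else:
        raise ValueError("where must be 'center' or 'flank'")
    br = target_surface_field_t / unit
    if br > 2.0:
        warnings.warn(f"calibrated remanence {br:.3f} T exceeds 2 T: "
                      "non-physical for NdFeB", stacklevel=2)
    return float(br)


def default_magnet(surface_field_t: float = 0.600, radius_m: float = 4.0e-3,
                   length_m: float = 8.0e-3, where: str = "center") -> MagnetSpec:
    """The study magnet: 8-mm-diameter cylinder calibrated to a 600-mT face field."""
    br = calibrate_remanence(surface_field_t, radius_m, length_m, where=where)
    return MagnetSpec(radius_m=radius_m, length_m=length_m, remanence_t=br)


def b_field(points_m, source) -> np.ndarray:
    """Flux density vectors (n, 3) at lab-frame points, for any field source.

    ``source`` is a :class:`MagnetSpec` (closed-form cylinder field) or any
    object exposing ``b_field(points) -> (n, 3)`` (stub sources for tests).
    No interior/edge checking is done here; see :func:`field_at` for the
    checked single-point API.
    """
    if hasattr(source, "b_field"):
        return source.b_field(points_m)
    magnet: MagnetSpec = source
    pts = np.atleast_2d(np.asarray(points_m, dtype=float))
    rho, z, rho_hat = _frame_decompose(pts, magnet)
    b_rho, b_z = _field_rz(rho, z, magnet.radius_m, magnet.length_m, magnet.remanence_t)
    n = np.asarray(magnet.axis)
    return b_rho[:, None] * rho_hat + b_z[:, None] * n


def field_at(point_m, magnet: MagnetSpec) -> FieldSample:
    """Checked flux density at one exterior lab-frame point.

    Raises for points inside the magnet body; points within the edge
    exclusion margin of a pole-face edge ring are clamped outward to the
    margin and flagged (``FieldSample.clamped``).
    """
    pt = np.asarray(point_m, dtype=float).reshape(3)
    rho, z, _ = _frame_decompose(pt[None, :], magnet)
    rho_s, z_s = float(rho[0]), float(z[0])
    clamped = False
    if float(_edge_distance(rho_s, z_s, magnet)) < EDGE_MARGIN_M:
        warnings.warn("point within the pole-face edge exclusion margin; "
                      "field evaluated at the clamped point", stacklevel=2)
        rho_c, z_c = _clamp_edge(rho_s, z_s, magnet)
        rho_s, z_s = float(rho_c), float(z_c)
        clamped = True
    elif _is_interior(np.array([rho_s]), np.array([z_s]), magnet)[0]:
        raise ValueError("field evaluation inside the magnet body is out of contract")
    b_rho, b_z = _field_rz(rho_s, z_s, magnet.radius_m, magnet.length_m,
                           magnet.remanence_t)
    _, _, rho_hat = _frame_decompose(pt[None, :], magnet)
    b = float(b_rho) * rho_hat[0] + float(b_z) * np.asarray(magnet.axis)
    return FieldSample(point_m=pt, b_t=b, b_mag_t=float(np.linalg.norm(b)),
                       clamped=clamped)


def gradient_at(point_m, source, h_m: float = DEFAULT_FD_STEP_M) -> FieldSample:
    """Field sample with central-difference derivatives at one exterior point.

    Fills the 3x3 Jacobian dB_i/dx_j, the gradient of |B| (the force drive),
    and — for a :class:`MagnetSpec` source — the magnet-frame radial
    derivative d|B|/dr. The finite-difference stencil must lie entirely
    outside the magnet body.
    """
    pt = np.asarray(point_m, dtype=float).reshape(3)
    is_magnet = isinstance(source, MagnetSpec)
    offsets = np.concatenate([np.eye(3) * h_m, -np.eye(3) * h_m])
    stencil = pt[None, :] + offsets
    if is_magnet:
        rho, z, _ = _frame_decompose(np.vstack([pt, stencil]), source)
        if np.any(_is_interior(rho, z, source)) or np.any(
                _edge_distance(rho, z, source) < EDGE_MARGIN_M):
            raise ValueError("finite-difference stencil crosses the magnet "
                             "surface or edge exclusion zone")
    b_center = b_field(pt[None, :], source)[0]
    b_stencil = b_field(stencil, source)
    jac = np.empty((3, 3))
    for j in range(3):
        jac[:, j] = (b_stencil[j] - b_stencil[3 + j]) / (2.0 * h_m)
    bmag_plus = np.linalg.norm(b_stencil[:3], axis=1)
    bmag_minus = np.linalg.norm(b_stencil[3:], axis=1)
    grad_bmag = (bmag_plus - bmag_minus) / (2.0 * h_m)

    dbmag_dr = None
    if is_magnet:
        rho0, z0, rho_hat = _frame_decompose(pt[None, :], source)
        # radial |B| derivative in the magnet frame; antisymmetric about the axis
        rp, zp = _field_rz(rho0[0] + h_m, z0[0], source.radius_m, source.length_m,
                           source.remanence_t)
        rm_rho, rm_z = _field_rz(abs(rho0[0] - h_m), z0[0], source.radius_m,
                                 source.length_m, source.remanence_t)
        if rho0[0] - h_m < 0:
            rm_rho = -rm_rho  # B_r is odd in the signed radial coordinate
        bmag_p = float(np.hypot(rp, zp))
        bmag_m = float(np.hypot(rm_rho, rm_z))
        dbmag_dr = (bmag_p - bmag_m) / (2.0 * h_m)

    return FieldSample(point_m=pt, b_t=b_center,
                       b_mag_t=float(np.linalg.norm(b_center)),
                       grad=jac, grad_bmag=grad_bmag, dbmag_dr=dbmag_dr)


def field_map(r_values_m: Sequence[float], z_values_m: Sequence[float],
              magnet: MagnetSpec, h_m: float = DEFAULT_FD_STEP_M) -> pd.DataFrame:
    """Tabulate B and d|B|/dr over a rectangular (r, z) magnet-frame grid.

    ``r`` may be signed (profiles across the axis); symmetry gives
    B_r(-r) = -B_r(r). Interior or edge-margin grid points raise. Returns a
    DataFrame with columns r_m, z_m, Bx, By, Bz, Bmag, dB_dr where (Bx, By,
    Bz) are lab-frame components of the field at the magnet-frame point
    (r, 0, z) mapped through the pose.
    """
    r_vals = np.asarray(list(r_values_m), dtype=float)
    z_vals = np.asarray(list(z_values_m), dtype=float)
    cols = ["r_m", "z_m", "Bx", "By", "Bz", "Bmag", "dB_dr"]
    if r_vals.size == 0 or z_vals.size == 0:
        return pd.DataFrame(columns=cols)
    rr, zz = np.meshgrid(r_vals, z_vals, indexing="ij")
    rr = rr.ravel()
    zz = zz.ravel()
    rho = np.abs(rr)
    if np.any(_is_interior(rho, zz, magnet)) or np.any(
            _edge_distance(rho, zz, magnet) < EDGE_MARGIN_M):
        raise ValueError("field_map grid contains interior or edge-margin points")

    R, L, Br = magnet.radius_m, magnet.length_m, magnet.remanence_t
    b_rho, b_z = _field_rz(rho, zz, R, L, Br)
    b_rho = np.where(rr < 0, -b_rho, b_rho)
    bmag = np.hypot(b_rho, b_z)
    # signed radial derivative of |B| by central differences
    bp = np.hypot(*_field_rz(np.abs(rr + h_m), zz, R, L, Br))
    bm = np.hypot(*_field_rz(np.abs(rr - h_m), zz, R, L, Br))
    db_dr = (bp - bm) / (2.0 * h_m)

    # map magnet-frame (r, 0, z) to lab components through the pose
    n = np.asarray(magnet.axis)
    # any unit vector perpendicular to the axis serves as the r direction
    trial = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(trial, n)) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    e_r = trial - np.dot(trial, n) * n
    e_r /= np.linalg.norm(e_r)
    b_lab = b_rho[:, None] * e_r + b_z[:, None] * n
    return pd.DataFrame({
        "r_m": rr, "z_m": zz,
        "Bx": b_lab[:, 0], "By": b_lab[:, 1], "Bz": b_lab[:, 2],
        "Bmag": bmag, "dB_dr": db_dr,
    })
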