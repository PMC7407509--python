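"""Steady incompressible flow in the rotating (disk) frame.

The carrier fluid in a lab-on-a-CD device is driven purely by rotating-frame
body forces: the centrifugal force density ``-rho w x (w x r)`` and the
Coriolis force density ``-2 rho w x u``, with atmospheric (zero gauge)
pressure at every inlet and outlet.

Backends
--------
``solve_flow``
    Reference backend: a depth-averaged (2.5D) plan-view solve of the
    rotating-frame Navier-Stokes equations on the staggered structured mesh
    of :mod:`centrisim.geometry`.  The third dimension enters through a
    ``12 mu / H^2`` shallow-channel wall drag and through analytic closures:
    the mid-plane axial velocity is ``3/2`` of the depth average (parabolic
    profile), and the mid-plane lateral Coriolis secondary flow is the
    lubrication solution ``v_sec = rho w |u| H^2 / (80 mu)`` directed along
    ``z x u`` (see docs/methods.md for the derivation).  Steady state is
    reached by pseudo-time stepping: semi-Lagrangian advection, implicit
    viscous/drag solve, and a pressure projection that pins the gauge
    pressure of every port.

``analytic_duct_field`` / ``duct_cross_section_solve``
    Reduced backends for straight rectangular ducts: the classical Fourier
    series profile and a finite-volume Poisson solve of the fully developed
    axial momentum equation, used as mutual oracles and by the reduced
    particle-tracking backend.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .geometry import ChannelGeometry, ChannelSection, GeometryError, Mesh

__all__ = [
    "Fluid",
    "RotatingFrame",
    "BodyForceSample",
    "FlowField",
    "ConvergenceError",
    "DomainError",
    "body_force_density",
    "channel_reynolds",
    "analytic_duct_field",
    "AnalyticDuctProfile",
    "duct_cross_section_solve",
    "solve_flow",
    "sample_velocity",
]

RPM_TO_RAD = 2.0 * math.pi / 60.0


class ConvergenceError(RuntimeError):
    """Raised when an iterative solve fails to reach its tolerance."""

    def __init__(self, message: str, residuals: list[float] | None = None):
        super().__init__(message)
        self.residuals = residuals or []


class DomainError(ValueError):
    """Raised when a field is queried outside the fluid domain."""


@dataclass(frozen=True)
class Fluid:
    """Newtonian carrier fluid (defaults: water with a small-solute tracer).

    density : kg/m^3, dynamic viscosity : Pa s, diffusivity : m^2/s.
    """

    density: float = 1000.0
    viscosity: float = 1e-3
    diffusivity: float = 1.67e-9

    def __post_init__(self) -> None:
        if min(self.density, self.viscosity, self.diffusivity) <= 0:
            raise ValueError("fluid properties must be strictly positive")

    @property
    def kinematic_viscosity(self) -> float:
        return self.viscosity / self.density


@dataclass(frozen=True)
class RotatingFrame:
    """Rotation of the disk: angular speed (rad/s), sense, z spin axis.

    The disk lies in the x-y plane with its center at the origin; the
    default clockwise sense (viewed from +z) puts the angular-velocity
    vector along -z.
    """

    omega: float
    sense: str = "clockwise"

    def __post_init__(self) -> None:
        if self.omega < 0:
            raise ValueError("angular speed must be nonnegative")
        if self.sense not in ("clockwise", "counterclockwise"):
            raise ValueError(f"unknown rotation sense {self.sense!r}")

    @classmethod
    def from_rpm(cls, rpm: float, sense: str = "clockwise") -> "RotatingFrame":
        return cls(rpm * RPM_TO_RAD, sense)

    @property
    def rpm(self) -> float:
        return self.omega / RPM_TO_RAD

    @property
    def axis_sign(self) -> int:
        return -1 if self.sense == "clockwise" else +1

    @property
    def omega_vector(self) -> np.ndarray:
        return np.array([0.0, 0.0, self.axis_sign * self.omega])


@dataclass(frozen=True)
class BodyForceSample:
    """Centrifugal and Coriolis force densities (N/m^3) at one point."""

    centrifugal: np.ndarray
    coriolis: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.centrifugal + self.coriolis


def _as3(vec) -> np.ndarray:
    v = np.asarray(vec, dtype=float)
    if v.shape[-1] == 2:
        v = np.concatenate([v, np.zeros(v.shape[:-1] + (1,))], axis=-1)
    return v


def body_force_density(
    fluid: Fluid, frame: RotatingFrame, position, velocity
) -> BodyForceSample:
    """Rotating-frame body force densities on the fluid at ``position``
    (disk coordinates, m) moving at ``velocity`` (m/s)."""
    r = _as3(position)
    u = _as3(velocity)
    w = frame.omega_vector
    centrifugal = -fluid.density * np.cross(w, np.cross(w, r))
    coriolis = -2.0 * fluid.density * np.cross(w, u)
    return BodyForceSample(centrifugal=centrifugal, coriolis=coriolis)


def channel_reynolds(fluid: Fluid, u_mean: float, d_h: float) -> float:
    """Channel Reynolds number ``rho U_m D_h / mu``."""
    return fluid.density * u_mean * d_h / fluid.viscosity


# -- analytic rectangular-duct profile ------------------------------------


class AnalyticDuctProfile:
    """Fully developed laminar flow in a rectangular duct, scaled to a
    prescribed maximum velocity.

    The profile is the classical Fourier series for a duct of width W
    (coordinate ``y`` in [0, W]) and height H (coordinate ``z`` in [0, H]);
    the flow is along the duct axis.  ``velocity`` and its derivatives are
    exact series evaluations; no-slip holds exactly on all four walls.
    """

    def __init__(self, section: ChannelSection, u_max: float, n_terms: int = 40):
        self.section = section
        self.u_max = float(u_max)
        self._k = np.arange(1, 2 * n_terms, 2)  # odd harmonics
        self._scale = 1.0
        center = self._raw(section.width / 2, section.height / 2)
        self._scale = self.u_max / center

    @staticmethod
    def _cosh_ratio(a, yp, half):
        """cosh(a yp) / cosh(a half) for |yp| <= half, overflow-safe."""
        ay = np.abs(a * yp)
        ah = a * half
        return np.exp(ay - ah) * (1.0 + np.exp(-2.0 * ay)) / (
            1.0 + np.exp(-2.0 * ah)
        )

    @staticmethod
    def _sinh_ratio(a, yp, half):
        """sinh(a yp) / cosh(a half), overflow-safe."""
        ay = np.abs(a * yp)
        ah = a * half
        mag = np.exp(ay - ah) * (1.0 - np.exp(-2.0 * ay)) / (
            1.0 + np.exp(-2.0 * ah)
        )
        return np.sign(yp) * mag

    def _raw(self, y, z):
        W, H = self.section.width, self.section.height
        y = np.asarray(y, dtype=float)
        z = np.asarray(z, dtype=float)
        k = self._k.reshape((-1,) + (1,) * max(y.ndim, z.ndim))
        a = k * math.pi / H
        term = (1.0 - self._cosh_ratio(a, y - W / 2, W / 2)) * np.sin(
            a * z
        ) / k**3
        return term.sum(axis=0)

    def velocity(self, y, z):
        """Axial velocity at (y, z); y in [0, W], z in [0, H]."""
        return self._scale * self._raw(y, z)

    def dudy(self, y, z):
        W, H = self.section.width, self.section.height
        y = np.asarray(y, dtype=float)
        z = np.asarray(z, dtype=float)
        k = self._k.reshape((-1,) + (1,) * max(y.ndim, z.ndim))
        a = k * math.pi / H
        term = -a * self._sinh_ratio(a, y - W / 2, W / 2) * np.sin(a * z) / k**3
        return self._scale * term.sum(axis=0)

    def dudz(self, y, z):
        W, H = self.section.width, self.section.height
        y = np.asarray(y, dtype=float)
        z = np.asarray(z, dtype=float)
        k = self._k.reshape((-1,) + (1,) * max(y.ndim, z.ndim))
        a = k * math.pi / H
        term = a * (1.0 - self._cosh_ratio(a, y - W / 2, W / 2)) * np.cos(
            a * z
        ) / k**3
        return self._scale * term.sum(axis=0)

    def mean_velocity(self, n: int = 128) -> float:
        W, H = self.section.width, self.section.height
        y = (np.arange(n) + 0.5) * W / n
        z = (np.arange(n) + 0.5) * H / n
        return float(self.velocity(y[:, None], z[None, :]).mean())


def analytic_duct_field(section: ChannelSection, u_max: float) -> AnalyticDuctProfile:
    """Series-solution duct profile scaled so the center velocity is ``u_max``."""
    return AnalyticDuctProfile(section, u_max)


def duct_cross_section_solve(
    section: ChannelSection,
    pressure_gradient: float,
    fluid: Fluid | None = None,
    n: int = 64,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Finite-volume solve of fully developed duct flow.

    Solves ``mu (u_yy + u_zz) = dp/dx`` with no-slip walls on an ``n x n``
    cell-centered grid over the W x H cross-section.  Returns (y, z, u) with
    ``u`` shaped (n_z, n_y).  ``pressure_gradient`` is dp/dx (negative for
    flow in +x).
    """
    fluid = fluid or Fluid()
    W, H = section.width, section.height
    dy, dz = W / n, H / n
    y = (np.arange(n) + 0.5) * dy
    z = (np.arange(n) + 0.5) * dz
    idx = np.arange(n * n).reshape(n, n)  # (z, y)
    diag = np.zeros(n * n)
    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for j in range(n):
        for i in range(n):
            r = idx[j, i]
            for (jj, ii, h) in ((j, i - 1, dy), (j, i + 1, dy),
                                (j - 1, i, dz), (j + 1, i, dz)):
                if 0 <= ii < n and 0 <= jj < n:
                    add(r, idx[jj, ii], -1.0 / h**2)
                    diag[r] += 1.0 / h**2
                else:
                    diag[r] += 2.0 / h**2  # Dirichlet 0 at half spacing
    add_rows = np.concatenate([np.asarray(rows), np.arange(n * n)])
    add_cols = np.concatenate([np.asarray(cols), np.arange(n * n)])
    add_vals = np.concatenate([np.asarray(vals), diag])
    A = sp.csc_matrix((add_vals, (add_rows, add_cols)), shape=(n * n, n * n))
    rhs = np.full(n * n, -pressure_gradient / fluid.viscosity)
    u = splu(A).solve(rhs).reshape(n, n)
    return y, z, u


# -- 2.5D plan-view steady solver -----------------------------------------


@dataclass
class FlowField:
    """Steady depth-averaged velocity/pressure field on a structured mesh.

    ``u`` (ny, nx+1) and ``v`` (ny+1, nx) are depth-averaged face-normal
    velocities; ``p`` (ny, nx) the gauge pressure at cell centers.  Queries
    interpolate bilinearly; ``midplane=True`` scales in-plane components by
    3/2 (parabolic depth profile) for use at the channel mid-depth where
    particles are tracked.
    """

    mesh: Mesh
    fluid_props: Fluid
    frame: RotatingFrame
    u: np.ndarray
    v: np.ndarray
    p: np.ndarray
    u_mean: float
    u_max: float
    residuals: list[float]
    converged: bool
    metadata: dict = field(default_factory=dict)

    MIDPLANE_FACTOR = 1.5
    # Mid-plane Coriolis secondary-flow closure v_sec = K * (rho w H^2 / mu) |u|
    SECONDARY_COEFF = 1.0 / 80.0

    @property
    def geometry(self) -> ChannelGeometry:
        return self.mesh.geometry

    # -- interpolation ---------------------------------------------------

    def _sample(self, arr: np.ndarray, ox: float, oy: float, pts: np.ndarray):
        """Bilinear sample of a staggered array with node origin (ox, oy)."""
        dx = self.mesh.dx
        x0, y0 = self.mesh.origin
        fx = (pts[:, 0] - (x0 + ox)) / dx
        fy = (pts[:, 1] - (y0 + oy)) / dx
        ny, nx = arr.shape
        fx = np.clip(fx, 0.0, nx - 1.0 - 1e-12)
        fy = np.clip(fy, 0.0, ny - 1.0 - 1e-12)
        i = fx.astype(int)
        j = fy.astype(int)
        tx = fx - i
        ty = fy - j
        return (
            arr[j, i] * (1 - tx) * (1 - ty)
            + arr[j, i + 1] * tx * (1 - ty)
            + arr[j + 1, i] * (1 - tx) * ty
            + arr[j + 1, i + 1] * tx * ty
        )

    def velocity(self, points, midplane: bool = False, check: bool = True):
        """In-plane velocity at local points (N, 2) or (2,)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if check and not self.geometry.contains(pts).all():
            raise DomainError("velocity query outside the fluid domain")
        dx = self.mesh.dx
        uu = self._sample(self.u, 0.0, 0.5 * dx, pts)
        vv = self._sample(self.v, 0.5 * dx, 0.0, pts)
        out = np.column_stack([uu, vv])
        if midplane:
            out = out * self.MIDPLANE_FACTOR
        if np.ndim(points) == 1:
            return out[0]
        return out

    def velocity_gradient(self, points, midplane: bool = False):
        """In-plane velocity-gradient tensor d(u_i)/d(x_j), shape (..., 2, 2),
        by centered differencing of the interpolated field at dx/2."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        h = 0.5 * self.mesh.dx
        grad = np.empty((len(pts), 2, 2))
        for ax in range(2):
            dp = np.zeros(2)
            dp[ax] = h
            vp = self.velocity(pts + dp, midplane=midplane, check=False)
            vm = self.velocity(pts - dp, midplane=midplane, check=False)
            grad[:, :, ax] = (vp - vm) / (2 * h)
        if np.ndim(points) == 1:
            return grad[0]
        return grad

    def secondary_velocity(self, points):
        """Mid-plane lateral secondary-flow velocity (Coriolis closure).

        Lubrication solution of the cross-gap lateral momentum balance with
        zero net lateral flux: the mid-plane fluid moves along ``z_hat x u``
        (for the clockwise default this is toward the waste-outlet side)
        with magnitude ``rho w |u| H^2 / (80 mu)``; the near-wall return
        flow is not represented in this depth-averaged model.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        vel = self.velocity(pts, midplane=False, check=False)
        rho = self.fluid_props.density
        mu = self.fluid_props.viscosity
        H = self.geometry.height
        coeff = self.SECONDARY_COEFF * rho * self.frame.omega * H**2 / mu
        # z_hat x u for spin axis sign s is s * (-v, u)
        s = self.frame.axis_sign
        sec = -s * coeff * np.column_stack([-vel[:, 1], vel[:, 0]])
        if np.ndim(points) == 1:
            return sec[0]
        return sec

    # -- diagnostics -----------------------------------------------------

    def port_fluxes(self) -> dict[str, float]:
        """Signed outward volumetric flux (m^3/s) through each port."""
        dx = self.mesh.dx
        H = self.geometry.height
        out: dict[str, float] = {}
        for (i, j, side, tag) in self.mesh.facets:
            if tag in ("wall", "obstacle"):
                continue
            if side == "W":
                q = -self.u[j, i] * dx * H
            elif side == "E":
                q = self.u[j, i + 1] * dx * H
            elif side == "S":
                q = -self.v[j, i] * dx * H
            else:
                q = self.v[j + 1, i] * dx * H
            out[tag] = out.get(tag, 0.0) + q
        return out

    def wall_speed_max(self) -> float:
        """Largest velocity magnitude on a tagged wall facet (no-slip check)."""
        worst = 0.0
        for (i, j, side, tag) in self.mesh.facets:
            if tag not in ("wall", "obstacle"):
                continue
            val = {
                "W": self.u[j, i], "E": self.u[j, i + 1],
                "S": self.v[j, i], "N": self.v[j + 1, i],
            }[side]
            worst = max(worst, abs(float(val)))
        return worst

    def divergence_max(self) -> float:
        du = np.diff(self.u, axis=1)
        dv = np.diff(self.v, axis=0)
        div = np.where(self.mesh.fluid, du + dv, 0.0) / self.mesh.dx
        scale = max(self.u_max, 1e-300) / self.mesh.dx
        return float(np.abs(div).max() / scale)

    def reynolds(self, d_h: float | None = None) -> float:
        if d_h is None:
            inlet = self.geometry.inlets[0]
            d_h = 2 * inlet.width * self.geometry.height / (
                inlet.width + self.geometry.height
            )
        return channel_reynolds(self.fluid_props, self.u_mean, d_h)

    def summary(self) -> dict:
        return {
            "rpm": self.frame.rpm,
            "omega_rad_per_s": self.frame.omega,
            "u_mean": self.u_mean,
            "u_max": self.u_max,
            "reynolds": self.reynolds(),
            "converged": self.converged,
            "final_residual": self.residuals[-1] if self.residuals else None,
            "iterations": len(self.residuals),
            "port_fluxes_m3_per_s": self.port_fluxes(),
        }


def sample_velocity(field: FlowField, position) -> tuple[np.ndarray, np.ndarray]:
    """Interpolated velocity and velocity gradient at one interior point.

    Raises :class:`DomainError` outside the fluid.  Interpolation is
    bilinear (first order for the gradient).
    """
    vel = field.velocity(position)
    grad = field.velocity_gradient(position)
    return vel, grad


def solve_flow(
    mesh: Mesh,
    fluid: Fluid,
    frame: RotatingFrame,
    bc: dict[str, float] | None = None,
    *,
    dt: float = 5e-5,
    tol_rate: float = 0.5,
    max_steps: int = 8000,
    min_steps: int = 50,
    raise_on_nonconvergence: bool = True,
) -> FlowField:
    """Steady rotating-frame flow by pseudo-time projection stepping.

    ``bc`` maps port labels to gauge pressures (Pa); unlisted ports are at
    atmospheric (0 gauge).  Convergence is declared when the velocity change
    rate ``|du|_inf / (|u|_inf dt)`` drops below ``tol_rate`` (1/s).

    Each pseudo-step does semi-Lagrangian advection, adds centrifugal and
    (lagged) Coriolis accelerations, solves the implicit viscous +
    shallow-channel-drag Helmholtz problems, and projects onto the
    divergence-free space with port-pressure Dirichlet conditions.
    """
    geo = mesh.geometry
    if geo.placement is None:
        raise GeometryError("geometry must be placed on the disk before solving")
    bc = dict(bc or {})
    for label in geo.ports:
        bc.setdefault(label, 0.0)

    ny, nx = mesh.ny, mesh.nx
    dx = mesh.dx
    F = mesh.fluid
    rho, mu = fluid.density, fluid.viscosity
    nu = mu / rho
    H = geo.height
    k_drag = 12.0 * nu / H**2
    omega = frame.omega
    s_axis = frame.axis_sign

    # -- face classification --------------------------------------------
    Fpx = np.zeros((ny, nx + 2), dtype=bool)
    Fpx[:, 1:-1] = F
    u_int = Fpx[:, :-1] & Fpx[:, 1:]  # (ny, nx+1) both neighbors fluid
    Fpy = np.zeros((ny + 2, nx), dtype=bool)
    Fpy[1:-1, :] = F
    v_int = Fpy[:-1, :] & Fpy[1:, :]  # (ny+1, nx)

    u_port = np.zeros_like(u_int)
    v_port = np.zeros_like(v_int)
    u_port_p = np.zeros((ny, nx + 1))
    v_port_p = np.zeros((ny + 1, nx))
    for (i, j, side, tag) in mesh.facets:
        if tag in ("wall", "obstacle"):
            continue
        pval = bc[tag]
        if side == "W":
            u_port[j, i] = True
            u_port_p[j, i] = pval
        elif side == "E":
            u_port[j, i + 1] = True
            u_port_p[j, i + 1] = pval
        elif side == "S":
            v_port[j, i] = True
            v_port_p[j, i] = pval
        else:
            v_port[j + 1, i] = True
            v_port_p[j + 1, i] = pval
    u_unknown = u_int | u_port
    v_unknown = v_int | v_port

    uid = np.full((ny, nx + 1), -1, dtype=int)
    uid[u_unknown] = np.arange(int(u_unknown.sum()))
    vid = np.full((ny + 1, nx), -1, dtype=int)
    vid[v_unknown] = np.arange(int(v_unknown.sum()))
    n_u, n_v = int(u_unknown.sum()), int(v_unknown.sum())

    def helmholtz(unknown: np.ndarray, ids: np.ndarray) -> sp.csc_matrix:
        nny, nnx = unknown.shape
        jj, ii = np.nonzero(unknown)
        rows_l, cols_l, vals_l = [], [], []
        diag = np.full(len(jj), 1.0 + dt * k_drag)
        c = dt * nu / dx**2
        me = ids[jj, ii]
        for dj, di, kind in ((0, -1, "n"), (0, 1, "n"), (-1, 0, "t"), (1, 0, "t")):
            j2, i2 = jj + dj, ii + di
            inb = (0 <= j2) & (j2 < nny) & (0 <= i2) & (i2 < nnx)
            nb_id = np.full(len(jj), -1, dtype=int)
            nb_id[inb] = ids[j2[inb], i2[inb]]
            is_unknown = nb_id >= 0
            rows_l.append(me[is_unknown])
            cols_l.append(nb_id[is_unknown])
            vals_l.append(np.full(is_unknown.sum(), -c))
            diag[is_unknown] += c
            fixed = ~is_unknown
            if kind == "n":
                # normal-direction neighbor: fixed wall face (value 0) at
                # full spacing, or open (zero gradient) beyond a port
                open_bc = fixed & ~inb
                diag[fixed & inb] += c
                _ = open_bc  # open: no contribution
            else:
                # tangential: no-slip wall at half spacing (mirror ghost)
                diag[fixed] += 2.0 * c
        rows = np.concatenate(rows_l + [me])
        cols = np.concatenate(cols_l + [me])
        vals = np.concatenate(vals_l + [diag])
        return sp.csc_matrix((vals, (rows, cols)), shape=(len(jj), len(jj)))

    lu_u = splu(helmholtz(u_unknown, uid))
    lu_v = splu(helmholtz(v_unknown, vid))

    # -- pressure Poisson -------------------------------------------------
    pidx = np.full((ny, nx), -1, dtype=int)
    pidx[F] = np.arange(int(F.sum()))
    n_p = int(F.sum())
    jj, ii = np.nonzero(F)
    me = pidx[jj, ii]
    rows_l, cols_l, vals_l = [], [], []
    diag = np.zeros(n_p)
    dirich = np.zeros(n_p)  # sum of phi_ghost / dx^2 over port faces
    inv2 = 1.0 / dx**2
    face_specs = (
        ("u", 0, 0, -1, 0),   # west face of cell: u[j, i], neighbor (j, i-1)
        ("u", 0, 1, +1, 0),   # east face: u[j, i+1], neighbor (j, i+1)
        ("v", 0, 0, 0, -1),   # south face: v[j, i], neighbor (j-1, i)
        ("v", 1, 0, 0, +1),   # north face: v[j+1, i], neighbor (j+1, i)
    )
    for (comp, offj, offi, di, djc) in face_specs:
        if comp == "u":
            face_unknown = u_unknown[jj, ii + offi]
            face_is_port = u_port[jj, ii + offi]
            ghost = u_port_p[jj, ii + offi] / rho
        else:
            face_unknown = v_unknown[jj + offj, ii]
            face_is_port = v_port[jj + offj, ii]
            ghost = v_port_p[jj + offj, ii] / rho
        j2 = jj + djc
        i2 = ii + di
        inb = (0 <= j2) & (j2 < ny) & (0 <= i2) & (i2 < nx)
        nb = np.full(len(jj), -1, dtype=int)
        nb[inb] = pidx[j2[inb], i2[inb]]
        interior = face_unknown & (nb >= 0)
        portf = face_unknown & (nb < 0)
        rows_l.append(me[interior])
        cols_l.append(nb[interior])
        vals_l.append(np.full(int(interior.sum()), -inv2))
        diag[me[interior]] += inv2
        diag[me[portf]] += inv2
        dirich[me[portf]] += ghost[portf] * inv2
        _ = face_is_port
    rows = np.concatenate(rows_l + [me])
    cols = np.concatenate(cols_l + [me])
    vals = np.concatenate(vals_l + [diag])
    lu_p = splu(sp.csc_matrix((vals, (rows, cols)), shape=(n_p, n_p)))

    # -- body-force acceleration fields ----------------------------------
    x0, y0 = mesh.origin
    xu = x0 + np.arange(nx + 1) * dx
    yu = y0 + (np.arange(ny) + 0.5) * dx
    XU, YU = np.meshgrid(xu, yu)
    ru_x = geo.placement.radial_offset + XU  # disk x-coordinate at u faces
    xv = x0 + (np.arange(nx) + 0.5) * dx
    yv = y0 + np.arange(ny + 1) * dx
    XV, YV = np.meshgrid(xv, yv)
    rv_y = YV - geo.y_ref
    acc_cent_u = omega**2 * ru_x
    acc_cent_v = omega**2 * rv_y

    u = np.zeros((ny, nx + 1))
    v = np.zeros((ny + 1, nx))
    phi = np.zeros(n_p)

    def sample(arr, ox, oy, px, py):
        nyA, nxA = arr.shape
        fx = np.clip((px - (x0 + ox)) / dx, 0.0, nxA - 1.0 - 1e-12)
        fy = np.clip((py - (y0 + oy)) / dx, 0.0, nyA - 1.0 - 1e-12)
        i = fx.astype(int)
        j = fy.astype(int)
        tx = fx - i
        ty = fy - j
        return (
            arr[j, i] * (1 - tx) * (1 - ty)
            + arr[j, i + 1] * tx * (1 - ty)
            + arr[j + 1, i] * (1 - tx) * ty
            + arr[j + 1, i + 1] * tx * ty
        )

    ujj, uii = np.nonzero(u_unknown)
    vjj, vii = np.nonzero(v_unknown)
    xu_f, yu_f = XU[ujj, uii], YU[ujj, uii]
    xv_f, yv_f = XV[vjj, vii], YV[vjj, vii]

    # ghost-face masks for pressure gradients at ports / walls
    gl = ~Fpx[:, :-1] & u_unknown   # unknown u-face with no fluid cell left
    gr = ~Fpx[:, 1:] & u_unknown
    gs = ~Fpy[:-1, :] & v_unknown
    gn = ~Fpy[1:, :] & v_unknown

    def grad_faces(phi_grid: np.ndarray, with_port_ghosts: bool):
        """(d phi/dx at u-faces, d phi/dy at v-faces); ghost cells beyond a
        port face carry phi = p_port/rho (or 0 for increments)."""
        phi_w = np.zeros((ny, nx + 2))
        phi_w[:, 1:-1] = phi_grid
        phi_L = phi_w[:, :-1].copy()
        phi_R = phi_w[:, 1:].copy()
        if with_port_ghosts:
            phi_L[gl] = u_port_p[gl] / rho
            phi_R[gr] = u_port_p[gr] / rho
        gu = np.where(u_unknown, (phi_R - phi_L) / dx, 0.0)
        phi_s = np.zeros((ny + 2, nx))
        phi_s[1:-1, :] = phi_grid
        phi_S = phi_s[:-1, :].copy()
        phi_N = phi_s[1:, :].copy()
        if with_port_ghosts:
            phi_S[gs] = v_port_p[gs] / rho
            phi_N[gn] = v_port_p[gn] / rho
        gv = np.where(v_unknown, (phi_N - phi_S) / dx, 0.0)
        return gu, gv

    phi_grid = np.zeros((ny, nx))
    residuals: list[float] = []
    converged = False
    for step in range(max_steps):
        # semi-Lagrangian advection
        v_at_u = sample(v, 0.5 * dx, 0.0, xu_f, yu_f)
        u_at_v = sample(u, 0.0, 0.5 * dx, xv_f, yv_f)
        ubx = xu_f - dt * u[ujj, uii]
        uby = yu_f - dt * v_at_u
        vbx = xv_f - dt * u_at_v
        vby = yv_f - dt * v[vjj, vii]
        u_star = sample(u, 0.0, 0.5 * dx, ubx, uby)
        v_star = sample(v, 0.5 * dx, 0.0, vbx, vby)

        # body forces (centrifugal + lagged Coriolis, a = -2 s w z x u)
        # and the lagged pressure gradient (incremental projection)
        gphi_u, gphi_v = grad_faces(phi_grid, with_port_ghosts=True)
        u_star = u_star + dt * (
            acc_cent_u[ujj, uii]
            + 2.0 * (-s_axis) * omega * (-v_at_u)
            - gphi_u[ujj, uii]
        )
        v_star = v_star + dt * (
            acc_cent_v[vjj, vii]
            + 2.0 * (-s_axis) * omega * u_at_v
            - gphi_v[vjj, vii]
        )

        # implicit viscosity + shallow-channel drag
        u_new = np.zeros_like(u)
        v_new = np.zeros_like(v)
        u_new[ujj, uii] = lu_u.solve(u_star)
        v_new[vjj, vii] = lu_v.solve(v_star)

        # pressure-increment projection: (-lap) delta = -div/dt,
        # delta = 0 beyond port faces
        div = (np.diff(u_new, axis=1) + np.diff(v_new, axis=0))[F] / dx
        delta = lu_p.solve(-div / dt)
        delta_grid = np.zeros((ny, nx))
        delta_grid[F] = delta
        gdu, gdv = grad_faces(delta_grid, with_port_ghosts=False)
        u_new -= dt * gdu
        v_new -= dt * gdv
        phi_grid = phi_grid + delta_grid

        scale = max(np.abs(u_new).max(), np.abs(v_new).max(), 1e-12)
        res = max(
            np.abs(u_new - u).max(), np.abs(v_new - v).max()
        ) / (scale * dt)
        residuals.append(float(res))
        u, v = u_new, v_new
        if step >= min_steps and res < tol_rate:
            converged = True
            break

    if not converged and raise_on_nonconvergence:
        raise ConvergenceError(
            f"flow solve did not converge in {max_steps} steps "
            f"(last residual rate {residuals[-1]:.3g} 1/s, tol {tol_rate})",
            residuals,
        )

    p = np.zeros((ny, nx))
    p[F] = rho * phi_grid[F]

    # inlet-based mean speed
    q_in = 0.0
    a_in = 0.0
    for port in geo.inlets:
        q = 0.0
        for (i, j, side, tag) in mesh.facets:
            if tag != port.label:
                continue
            if side == "W":
                q += u[j, i] * dx * H
            elif side == "E":
                q += -u[j, i + 1] * dx * H
            elif side == "S":
                q += v[j, i] * dx * H
            else:
                q += -v[j + 1, i] * dx * H
        q_in += q
        a_in += port.width * H
    u_mean = q_in / a_in if a_in > 0 else 0.0
    u_max = float(max(np.abs(u).max(), np.abs(v).max()))

    out = FlowField(
        mesh=mesh, fluid_props=fluid, frame=frame, u=u, v=v, p=p,
        u_mean=float(u_mean), u_max=u_max, residuals=residuals,
        converged=converged,
        metadata={"dt": dt, "tol_rate": tol_rate, "bc": bc},
    )
    re = out.reynolds()
    if re >= 2300:
        warnings.warn(
            f"channel Reynolds number {re:.0f} exceeds the laminar regime",
            stacklevel=2,
        )
    return out
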