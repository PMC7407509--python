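"""Per-particle force models for rigid spherical cells in the rotating frame.

Forces on a particle of diameter ``d_p`` and density ``rho_p`` suspended in
the carrier fluid:

* Stokes drag ``3 pi mu d_p v_t`` with ``v_t`` the fluid-minus-particle
  relative velocity;
* net (buoyancy-corrected) centrifugal force
  ``-(rho_p - rho_f) (pi d_p^3 / 6) w x (w x r)``;
* net Coriolis force ``-(rho_p - rho_f) (pi d_p^3 / 3) w x v_p``;
* Dean (secondary-flow) drag, Stokes drag evaluated at the local secondary
  flow velocity — applied only by the reduced tracking backend, where the
  secondary flow is a closure rather than a resolved velocity;
* inertial lift ``rho_f U_max^2 d_p^4 / H^2 * C_L`` with
  ``C_L = C1 beta^2 G1(s) + C2 beta gamma G2(s)``: the wall-induced plus
  shear-gradient lift in the correction-coefficient form, where ``beta``
  and ``gamma`` are the dimensionless shear rate and shear gradient
  (normalized by ``U_max`` and the gap ``H``), ``s`` in (0, 1) is the wall
  distance normalized by the gap, and C1/C2 are tabulated against the
  channel aspect ratio AR = W/H.

The G1/G2 wall-distance weighting functions are published only as curves in
the DNS literature; the packaged default table is a synthetic Ho-Leal-type
surrogate (see ``data/lift_g_functions_synthetic.tsv``) constructed to
reproduce the documented qualitative structure: wall repulsion at both
walls, a centerline zero, and stable off-center equilibria near s = 0.2 and
0.8 for a square channel.  User tables load via :meth:`LiftModel.from_tables`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.interpolate import PchipInterpolator

from .flow import Fluid, RotatingFrame, _as3

__all__ = [
    "Particle",
    "LocalFlow",
    "LiftModel",
    "stokes_drag",
    "centrifugal_force",
    "coriolis_force",
    "dean_drag",
    "inertial_lift",
    "parabolic_local_flow",
    "force_ratio_report",
    "surrogate_g1",
    "surrogate_g2",
]


@dataclass(frozen=True)
class Particle:
    """A rigid spherical particle (cell surrogate).

    Defaults model blood cells: density 1050 kg/m^3; diameters of 10 um
    (white blood cells) and 15-20 um (circulating tumor cells) are the
    populations of interest.
    """

    diameter: float
    density: float = 1050.0
    label: str = "custom"

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.density <= 0:
            raise ValueError("particle diameter and density must be positive")

    @property
    def volume(self) -> float:
        return math.pi * self.diameter**3 / 6.0

    @property
    def mass(self) -> float:
        return self.density * self.volume

    def relaxation_time(self, fluid: Fluid) -> float:
        """Stokes relaxation time rho_p d_p^2 / (18 mu)."""
        return self.density * self.diameter**2 / (18.0 * fluid.viscosity)


@dataclass(frozen=True)
class LocalFlow:
    """Local flow state entering the lift model, for one lateral axis.

    ``s`` is the wall distance normalized by the gap (0 < s < 1 across the
    full gap, measured from the reference wall); ``wall_normal`` points from
    the reference wall into the channel; ``beta`` and ``gamma`` are the
    dimensionless shear rate and shear gradient normalized by ``u_max`` and
    ``gap``.
    """

    velocity: np.ndarray
    beta: float
    gamma: float
    s: float
    wall_normal: np.ndarray
    u_max: float
    gap: float

    def __post_init__(self) -> None:
        if not 0.0 < self.s < 1.0:
            raise ValueError(f"wall coordinate s={self.s} outside (0, 1)")
        if self.gap <= 0:
            raise ValueError("gap must be positive")


def stokes_drag(fluid: Fluid, particle: Particle, v_rel) -> np.ndarray:
    """Stokes drag ``3 pi mu d_p v_t``; ``v_rel`` = fluid minus particle."""
    return 3.0 * math.pi * fluid.viscosity * particle.diameter * np.asarray(
        v_rel, dtype=float
    )


def centrifugal_force(
    particle: Particle, fluid: Fluid, frame: RotatingFrame, position
) -> np.ndarray:
    """Net centrifugal force on the particle at disk position ``r``:
    ``-(rho_p - rho_f) V_p w x (w x r)`` (radially outward for dense
    particles)."""
    w = frame.omega_vector
    r = _as3(position)
    drho = particle.density - fluid.density
    return -drho * particle.volume * np.cross(w, np.cross(w, r))


def coriolis_force(
    particle: Particle, fluid: Fluid, frame: RotatingFrame, v_p
) -> np.ndarray:
    """Net Coriolis force ``-(rho_p - rho_f) (pi d_p^3 / 3) w x v_p``.

    The ``pi d_p^3 / 3`` prefactor is ``2 V_p``: the familiar factor of two
    of the Coriolis acceleration absorbed into the volume term.
    """
    w = frame.omega_vector
    drho = particle.density - fluid.density
    return -drho * (math.pi * particle.diameter**3 / 3.0) * np.cross(
        w, _as3(v_p)
    )


def dean_drag(fluid: Fluid, particle: Particle, u_dean) -> np.ndarray:
    """Drag from the secondary (Dean / Coriolis-driven) flow:
    ``3 pi mu U_Dean d_p``, identical in form to Stokes drag."""
    return stokes_drag(fluid, particle, u_dean)


# -- lift model -----------------------------------------------------------

_DELTA = 0.08  # wall-repulsion decay length of the surrogate G1
_G2_AMPL = 11.216351383963946  # calibrated: AR=1 equilibrium at s* = 0.2


def surrogate_g1(s):
    """Synthetic wall-induced weighting: repulsive boundary layers of decay
    length 0.08 at both walls, antisymmetric about the centerline."""
    s = np.asarray(s, dtype=float)
    return np.exp(-s / _DELTA) - np.exp(-(1.0 - s) / _DELTA)


def surrogate_g2(s):
    """Synthetic shear-gradient weighting ``~ [s(1-s)]^3``: positive,
    vanishing steeply at the walls.  The amplitude together with the G1
    decay length keeps the lift equilibria off the walls (s* in ~0.12-0.2)
    for every tabulated aspect ratio."""
    s = np.asarray(s, dtype=float)
    return _G2_AMPL * (s * (1.0 - s)) ** 3


class LiftModel:
    """Inertial lift in the correction-coefficient form.

    Holds the (C1, C2) table indexed by aspect ratio and the G1(s)/G2(s)
    weighting functions as monotone (PCHIP) splines through tabulated
    samples.  C1/C2 are interpolated piecewise-linearly in AR and clamped
    (with a warning) outside the tabulated range unless ``extrapolate``.
    """

    def __init__(
        self,
        s_table: np.ndarray,
        g1_table: np.ndarray,
        g2_table: np.ndarray,
        ar_table: np.ndarray,
        c1_table: np.ndarray,
        c2_table: np.ndarray,
        extrapolate: bool = False,
    ):
        s_table = np.asarray(s_table, dtype=float)
        if np.any(np.diff(s_table) <= 0):
            raise ValueError("s samples must be strictly increasing")
        if np.any(np.asarray(c1_table) <= 0) or np.any(np.asarray(c2_table) <= 0):
            raise ValueError("C1 and C2 must be positive")
        self._g1 = PchipInterpolator(s_table, g1_table)
        self._g2 = PchipInterpolator(s_table, g2_table)
        self.s_range = (float(s_table[0]), float(s_table[-1]))
        order = np.argsort(ar_table)
        self.ar_table = np.asarray(ar_table, dtype=float)[order]
        self.c1_table = np.asarray(c1_table, dtype=float)[order]
        self.c2_table = np.asarray(c2_table, dtype=float)[order]
        self.extrapolate = extrapolate

    # construction -------------------------------------------------------

    @classmethod
    def default(cls, extrapolate: bool = False) -> "LiftModel":
        """Packaged tables: printed (C1, C2) coefficients and the synthetic
        surrogate G functions."""
        g = _load_table("lift_g_functions_synthetic.tsv", 3)
        c = _load_table("lift_correction_coefficients.tsv", 3)
        return cls(g[:, 0], g[:, 1], g[:, 2], c[:, 0], c[:, 1], c[:, 2],
                   extrapolate=extrapolate)

    @classmethod
    def from_tables(
        cls, g_path, ar_path, extrapolate: bool = False
    ) -> "LiftModel":
        """Load from delimited text: ``g_path`` columns (s, G1, G2);
        ``ar_path`` columns (AR, C1, C2)."""
        g = np.loadtxt(g_path)
        c = np.loadtxt(ar_path)
        return cls(g[:, 0], g[:, 1], g[:, 2], c[:, 0], c[:, 1], c[:, 2],
                   extrapolate=extrapolate)

    # evaluation ---------------------------------------------------------

    def coefficients(self, ar: float) -> tuple[float, float]:
        """(C1, C2) at aspect ratio ``ar``, piecewise-linear in AR."""
        lo, hi = self.ar_table[0], self.ar_table[-1]
        if (ar < lo or ar > hi) and not self.extrapolate:
            warnings.warn(
                f"aspect ratio {ar:.3g} outside tabulated range "
                f"[{lo:g}, {hi:g}]; clamping",
                stacklevel=2,
            )
            ar = min(max(ar, lo), hi)
        c1 = float(np.interp(ar, self.ar_table, self.c1_table))
        c2 = float(np.interp(ar, self.ar_table, self.c2_table))
        return c1, c2

    def g1(self, s):
        return self._g1(s)

    def g2(self, s):
        return self._g2(s)

    def lift_coefficient(self, ar: float, s, beta, gamma):
        """C_L = C1 beta^2 G1(s) + C2 beta gamma G2(s)."""
        c1, c2 = self.coefficients(ar)
        return c1 * np.asarray(beta) ** 2 * self.g1(s) + c2 * np.asarray(
            beta
        ) * np.asarray(gamma) * self.g2(s)

    def force(
        self, fluid: Fluid, particle: Particle, local: LocalFlow, ar: float
    ) -> np.ndarray:
        """Lift force vector along the wall normal; positive C_L pushes the
        particle away from the reference wall."""
        cl = float(self.lift_coefficient(ar, local.s, local.beta, local.gamma))
        mag = (
            fluid.density
            * local.u_max**2
            * particle.diameter**4
            / local.gap**2
        )
        return mag * cl * _as3(local.wall_normal)


def inertial_lift(
    model: LiftModel,
    fluid: Fluid,
    particle: Particle,
    local: LocalFlow,
    ar: float,
) -> np.ndarray:
    """Functional wrapper over :meth:`LiftModel.force`."""
    return model.force(fluid, particle, local, ar)


def parabolic_local_flow(
    s: float, u_max: float, gap: float, wall_normal, velocity=None
) -> LocalFlow:
    """LocalFlow for a plane-Poiseuille profile ``u = 4 U_max s (1 - s)``:
    ``beta = 4 (1 - 2 s)``, ``gamma = -8`` (both normalized by U_max, gap)."""
    if velocity is None:
        velocity = np.zeros(3)
    return LocalFlow(
        velocity=_as3(velocity),
        beta=4.0 * (1.0 - 2.0 * s),
        gamma=-8.0,
        s=s,
        wall_normal=_as3(wall_normal),
        u_max=u_max,
        gap=gap,
    )


def _load_table(name: str, ncols: int) -> np.ndarray:
    with resources.files("centrisim.data").joinpath(name).open("r") as fh:
        arr = np.loadtxt(fh)
    if arr.ndim != 2 or arr.shape[1] != ncols:
        raise ValueError(f"table {name} must have {ncols} columns")
    return arr


# -- order-of-magnitude diagnostics ---------------------------------------


def force_ratio_report(
    particle: Particle,
    fluid: Fluid,
    frame: RotatingFrame,
    local: LocalFlow,
    position,
    v_p,
    model: LiftModel | None = None,
    ar: float = 1.0,
) -> dict:
    """Nondimensional groups of the centrifugal/lift and Coriolis/lift
    force-ratio estimates, plus the directly evaluated force-magnitude
    ratios.

    The three groups of each estimate are
    ``(rho_p - rho_f) H / (rho_f d_p)``, ``H w / U_max`` and
    ``r w / U_max`` (centrifugal) or ``v_p / U_max`` (Coriolis); in the
    device regime (U_max ~ r w, d_p < H) each is within an order of
    magnitude of unity.
    """
    model = model or LiftModel.default()
    drho = particle.density - fluid.density
    H = local.gap
    w = frame.omega
    u_max = local.u_max
    r_mag = float(np.linalg.norm(_as3(position)))
    vp_mag = float(np.linalg.norm(_as3(v_p)))
    groups = {
        "density_group": drho * H / (fluid.density * particle.diameter),
        "rotation_group": H * w / u_max if u_max > 0 else math.inf,
        "centrifugal_velocity_group": r_mag * w / u_max if u_max > 0 else math.inf,
        "coriolis_velocity_group": vp_mag / u_max if u_max > 0 else math.inf,
    }
    f_cent = float(np.linalg.norm(
        centrifugal_force(particle, fluid, frame, position)
    ))
    f_cor = float(np.linalg.norm(coriolis_force(particle, fluid, frame, v_p)))
    f_lift = float(np.linalg.norm(model.force(fluid, particle, local, ar)))
    if f_lift > 0:
        ratios = {
            "centrifugal_over_lift": f_cent / f_lift,
            "coriolis_over_lift": f_cor / f_lift,
            "lift_is_zero": False,
        }
    else:
        ratios = {
            "centrifugal_over_lift": math.inf,
            "coriolis_over_lift": math.inf,
            "lift_is_zero": True,
        }
    return {**groups, **ratios}
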