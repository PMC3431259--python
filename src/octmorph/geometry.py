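"""Parametric ground-truth eye model.

The synthetic eye is built from circular arcs in the physical (x, z) plane:

* an anterior corneal surface (circle of radius ``anterior_radius``),
* a posterior corneal surface (circle of radius ``posterior_radius`` —
  the "posterior curvature" parameter of the cohort tables),
* for grafted eyes, a posterior graft surface (its own circle), attached
  to the host posterior cornea and separated from it by the graft
  thickness at the apex.

The scleral spurs sit exactly on the posterior corneal circle, so the six
core morphometric parameters have closed forms: an arc subtending angle
``θ`` on a circle of radius ``R`` has length ``R·θ`` and chord
``2R·sin(θ/2)``.  The generator therefore treats the posterior corneal
arc length (PCAL), posterior curvature, anterior graft arc length (AGAL),
posterior graft arc (PGAL) and cord (PGCL) lengths and the graft
thickness as the primary quantities; the anterior chamber width (ACW,
spur-to-spur chord) and anterior graft cord length (AGCL) follow
analytically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .core import LandmarkSet

_CONSISTENCY_TOL = 1e-9


def solve_half_angle(cord_to_arc: float) -> float:
    """Half-angle h with sin(h)/h equal to the cord/arc ratio.

    Valid for ratios in (2/pi, 1), i.e. arcs subtending less than a
    half-circle.
    """
    if not 2 / math.pi < cord_to_arc < 1:
        raise ValueError(f"cord/arc ratio {cord_to_arc:.4f} outside (2/pi, 1)")
    return brentq(lambda h: math.sin(h) / h - cord_to_arc, 1e-12, math.pi / 2)


@dataclass(frozen=True)
class GroundTruthGeometry:
    """Analytic eye geometry rendered into B-scans and scored against.

    Circle centres are (x, z) points in mm; all the ``true_*`` fields are
    closed-form values of the parameters a perfect measurement would
    recover.  Graft fields are ``None``/NaN for an eye without a graft.
    """

    anterior_center: tuple
    anterior_radius: float
    posterior_center: tuple
    posterior_radius: float
    graft_center: Optional[tuple]
    graft_radius: Optional[float]
    graft_half_angle: Optional[float]
    graft_anterior_half_angle: Optional[float]
    graft_thickness_mm: float
    spur_left: tuple
    spur_right: tuple
    iris_plane_depth: float
    true_pcal: float
    true_acw: float
    true_agal: float
    true_agcl: float
    true_pgal: float
    true_pgcl: float

    def __post_init__(self):
        if self.anterior_radius <= 0 or self.posterior_radius <= 0:
            raise ValueError("radii must be positive")
        th = self.spur_half_angle
        R = self.posterior_radius
        if abs(self.true_pcal - 2 * th * R) > _CONSISTENCY_TOL:
            raise ValueError("true_pcal inconsistent with posterior circle and spurs")
        if abs(self.true_acw - 2 * R * math.sin(th)) > _CONSISTENCY_TOL:
            raise ValueError("true_acw inconsistent with posterior circle and spurs")
        if self.has_graft:
            if self.graft_radius <= 0:
                raise ValueError("graft radius must be positive")
            h, hg = self.graft_half_angle, self.graft_anterior_half_angle
            if abs(self.true_pgal - 2 * h * self.graft_radius) > _CONSISTENCY_TOL:
                raise ValueError("true_pgal inconsistent with graft circle")
            if abs(self.true_pgcl - 2 * self.graft_radius * math.sin(h)) > _CONSISTENCY_TOL:
                raise ValueError("true_pgcl inconsistent with graft circle")
            if abs(self.true_agal - 2 * hg * R) > _CONSISTENCY_TOL:
                raise ValueError("true_agal inconsistent with host posterior circle")
            if abs(self.true_agcl - 2 * R * math.sin(hg)) > _CONSISTENCY_TOL:
                raise ValueError("true_agcl inconsistent with host posterior circle")
            apex_gap = (self.graft_center[1] - self.graft_radius) - \
                       (self.posterior_center[1] - R)
            if abs(apex_gap - self.graft_thickness_mm) > 1e-6:
                raise ValueError("graft apex not separated from host posterior by graft thickness")
        # posterior surface strictly below anterior wherever both exist
        xs = np.linspace(-self.x_spur, self.x_spur, 101)
        if not np.all(self.posterior_surface(xs) > self.anterior_surface(xs)):
            raise ValueError("posterior surface not strictly below anterior surface")

    # -- derived scalars ------------------------------------------------

    @property
    def has_graft(self) -> bool:
        return self.graft_center is not None

    @property
    def spur_half_angle(self) -> float:
        """Half the angle the spur-to-spur posterior arc subtends."""
        cx, cz = self.posterior_center
        dx = self.spur_right[0] - cx
        dz = cz - self.spur_right[1]
        return math.atan2(dx, dz)

    @property
    def x_spur(self) -> float:
        return self.spur_right[0]

    @property
    def x_graft_posterior(self) -> float:
        return self.graft_radius * math.sin(self.graft_half_angle)

    @property
    def x_graft_anterior(self) -> float:
        return self.posterior_radius * math.sin(self.graft_anterior_half_angle)

    # -- surfaces (depth as a function of lateral position; NaN outside) --

    def _circle_upper(self, x, center, radius):
        x = np.asarray(x, dtype=float)
        with np.errstate(invalid="ignore"):
            z = center[1] - np.sqrt(radius ** 2 - (x - center[0]) ** 2)
        return z

    def anterior_surface(self, x):
        return self._circle_upper(x, self.anterior_center, self.anterior_radius)

    def posterior_surface(self, x):
        return self._circle_upper(x, self.posterior_center, self.posterior_radius)

    def graft_posterior_surface(self, x):
        """Graft posterior depth; NaN beyond the graft's posterior extent."""
        if not self.has_graft:
            return np.full_like(np.asarray(x, dtype=float), np.nan)
        x = np.asarray(x, dtype=float)
        z = self._circle_upper(x, self.graft_center, self.graft_radius)
        z = np.where(np.abs(x) <= self.x_graft_posterior, z, np.nan)
        return z

    def surface_polyline(self, which: str, x_min: float, x_max: float, n: int = 2001):
        """Dense polyline sample of a named surface over [x_min, x_max]."""
        xs = np.linspace(x_min, x_max, n)
        fn = {"anterior": self.anterior_surface,
              "posterior": self.posterior_surface,
              "graft_posterior": self.graft_posterior_surface}[which]
        zs = fn(xs)
        keep = np.isfinite(zs)
        return np.column_stack([xs[keep], zs[keep]])

    def landmarks(self) -> LandmarkSet:
        """True physical positions of the operator landmarks."""
        if not self.has_graft:
            return LandmarkSet(np.asarray(self.spur_left), np.asarray(self.spur_right))
        xg, xa = self.x_graft_posterior, self.x_graft_anterior
        return LandmarkSet(
            spur_left=np.asarray(self.spur_left),
            spur_right=np.asarray(self.spur_right),
            graft_ant_left=np.array([-xa, float(self.posterior_surface(-xa))]),
            graft_ant_right=np.array([xa, float(self.posterior_surface(xa))]),
            graft_post_left=np.array([-xg, float(self.graft_posterior_surface(-xg))]),
            graft_post_right=np.array([xg, float(self.graft_posterior_surface(xg))]),
        )

    # -- construction ----------------------------------------------------

    @classmethod
    def from_parameters(cls, pcal: float, posterior_radius: float,
                        agal: Optional[float], pgal: Optional[float],
                        pgcl: Optional[float], graft_thickness_um: float,
                        *, anterior_radius: float = 7.8,
                        anterior_apex_depth: float = 0.3,
                        central_cornea_thickness: float = 0.6,
                        iris_plane_depth: float = 3.8) -> "GroundTruthGeometry":
        """Assemble a geometry whose implied parameters equal the arguments.

        ``agal``/``pgal``/``pgcl`` of ``None`` build an eye without a graft.
        Raises ``ValueError`` when the requested parameters are not jointly
        realisable as circular arcs (callers doing rejection sampling catch
        this).
        """
        R = posterior_radius
        theta = pcal / R  # full spur-to-spur angle
        if not 0 < theta < 0.92 * math.pi:
            raise ValueError("PCAL/curvature imply an over-wrapped posterior arc")
        apex_post = anterior_apex_depth + central_cornea_thickness
        post_center = (0.0, apex_post + R)
        ant_center = (0.0, anterior_apex_depth + anterior_radius)
        th = theta / 2
        x_spur = R * math.sin(th)
        z_spur = post_center[1] - R * math.cos(th)
        if x_spur >= 0.97 * anterior_radius:
            raise ValueError("spur beyond the anterior circle's lateral reach")
        acw = 2 * R * math.sin(th)

        has_graft = agal is not None and pgal is not None and pgcl is not None
        if has_graft:
            t_g = graft_thickness_um / 1000.0
            if t_g <= 0:
                raise ValueError("graft thickness must be positive")
            h = solve_half_angle(pgcl / pgal)  # may raise ValueError
            R_g = pgal / (2 * h)
            hg = agal / (2 * R)  # graft anterior half-angle on host circle
            if not hg < th * 0.995:
                raise ValueError("graft anterior extent reaches the spurs")
            x_ga = R * math.sin(hg)
            x_gp = R_g * math.sin(h)
            if not x_gp < x_ga * 0.999:
                raise ValueError("graft posterior edge not inside anterior edge")
            graft_center = (0.0, apex_post + t_g + R_g)
            agcl = 2 * R * math.sin(hg)
            graft_max_depth = graft_center[1] - R_g * math.cos(h)
            iris_plane_depth = max(iris_plane_depth, graft_max_depth + 0.6)
            if iris_plane_depth > z_spur + 0.4:
                iris_plane_depth = min(iris_plane_depth, z_spur + 0.4)
            geom = cls(
                anterior_center=ant_center, anterior_radius=anterior_radius,
                posterior_center=post_center, posterior_radius=R,
                graft_center=graft_center, graft_radius=R_g,
                graft_half_angle=h, graft_anterior_half_angle=hg,
                graft_thickness_mm=t_g,
                spur_left=(-x_spur, z_spur), spur_right=(x_spur, z_spur),
                iris_plane_depth=iris_plane_depth,
                true_pcal=pcal, true_acw=acw, true_agal=agal, true_agcl=agcl,
                true_pgal=pgal, true_pgcl=pgcl,
            )
            # graft posterior must stay strictly below the host posterior
            xs = np.linspace(-x_gp, x_gp, 101)
            if not np.all(geom.graft_posterior_surface(xs) > geom.posterior_surface(xs)):
                raise ValueError("graft posterior surface intersects host posterior cornea")
            return geom
        return cls(
            anterior_center=ant_center, anterior_radius=anterior_radius,
            posterior_center=post_center, posterior_radius=R,
            graft_center=None, graft_radius=None,
            graft_half_angle=None, graft_anterior_half_angle=None,
            graft_thickness_mm=0.0,
            spur_left=(-x_spur, z_spur), spur_right=(x_spur, z_spur),
            iris_plane_depth=iris_plane_depth,
            true_pcal=pcal, true_acw=acw,
            true_agal=math.nan, true_agcl=math.nan,
            true_pgal=math.nan, true_pgcl=math.nan,
        )
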