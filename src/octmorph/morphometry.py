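"""Arc-length and chord morphometry of traced corneal boundaries.

The six core parameters of a post-keratoplasty eye:

* PCAL — posterior cornea arc length, along the host posterior surface
  from scleral spur to scleral spur;
* ACW — anterior chamber width, the spur-to-spur chord;
* AGAL/AGCL — anterior graft arc and cord lengths between the graft's
  anterior edge landmarks (measured along the host/graft interface);
* PGAL/PGCL — posterior graft arc and cord lengths between the graft's
  posterior edge landmarks.

Arc endpoints are attached by perpendicular projection of the landmark
onto its nearest polyline segment, so sub-pixel landmark placement is
respected; an arc is always at least as long as its chord.
"""

from __future__ import annotations

import math

import numpy as np

from .core import (BoundarySet, CollinearPointsError, LandmarkSet, MeasurementRecord,
                   OutOfSpanError, QCResult, as_polyline)


def cord_length(p1, p2) -> float:
    """Euclidean distance between two mm points."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    return float(np.hypot(*(p2 - p1)))


def _project_arcpos(poly: np.ndarray, p) -> float:
    """Cumulative arc-length position of the perpendicular projection of p
    onto its nearest polyline segment."""
    p = np.asarray(p, dtype=float)
    a = poly[:-1]
    b = poly[1:]
    ab = b - a
    seg_len2 = np.einsum("ij,ij->i", ab, ab)
    t = np.clip(np.einsum("ij,ij->i", p - a, ab) / np.where(seg_len2 == 0, 1, seg_len2),
                0.0, 1.0)
    proj = a + t[:, None] * ab
    d2 = np.einsum("ij,ij->i", p - proj, p - proj)
    i = int(np.argmin(d2))
    seg_lengths = np.sqrt(seg_len2)
    cum = np.concatenate([[0.0], np.cumsum(seg_lengths)])
    return float(cum[i] + t[i] * seg_lengths[i])


def arc_length(surface, p_start, p_end, *, span_tolerance: float = 0.1) -> float:
    """Length along a polyline between the projections of two endpoints.

    Raises :class:`OutOfSpanError` when an endpoint lies laterally outside
    the polyline's span by more than ``span_tolerance`` mm.
    """
    poly = as_polyline(surface)
    if len(poly) < 2:
        raise ValueError("surface polyline needs at least 2 vertices")
    x_lo, x_hi = poly[0, 0], poly[-1, 0]
    for p in (p_start, p_end):
        x = float(np.asarray(p, dtype=float)[0])
        if x < x_lo - span_tolerance or x > x_hi + span_tolerance:
            raise OutOfSpanError(
                f"endpoint x={x:.3f} outside polyline span [{x_lo:.3f}, {x_hi:.3f}]")
    s1 = _project_arcpos(poly, p_start)
    s2 = _project_arcpos(poly, p_end)
    return abs(s2 - s1)


def fit_circle(points):
    """Algebraic (Kasa) least-squares circle, refined by one Gauss-Newton
    step of the geometric problem.

    Returns ``(center, radius, rms_residual)``; exact on noise-free
    circular data.  Raises :class:`CollinearPointsError` on (near-)
    collinear input.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
        raise ValueError("need at least 3 (x, z) points")
    x, z = pts[:, 0], pts[:, 1]
    A = np.column_stack([2 * x, 2 * z, np.ones_like(x)])
    b = x ** 2 + z ** 2
    # collinearity check via the centred covariance
    c = pts - pts.mean(axis=0)
    sv = np.linalg.svd(c, compute_uv=False)
    if sv[-1] <= 1e-9 * max(sv[0], 1e-30):
        raise CollinearPointsError("points are collinear; radius is infinite")
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cz = sol[0], sol[1]
    r = math.sqrt(sol[2] + cx ** 2 + cz ** 2)
    # one Gauss-Newton step on sum (|p - c| - r)^2
    for _ in range(1):
        dx, dz = x - cx, z - cz
        dist = np.hypot(dx, dz)
        if np.any(dist == 0):
            break
        J = np.column_stack([-dx / dist, -dz / dist, -np.ones_like(dist)])
        res = dist - r
        step, *_ = np.linalg.lstsq(J, -res, rcond=None)
        cx, cz, r = cx + step[0], cz + step[1], r + step[2]
    dist = np.hypot(x - cx, z - cz)
    rms = float(np.sqrt(np.mean((dist - r) ** 2)))
    return (float(cx), float(cz)), float(r), rms


def _interp_point(poly, x):
    return np.array([x, float(np.interp(x, poly[:, 0], poly[:, 1]))])


def _point_to_polyline_distance(poly, p):
    p = np.asarray(p, dtype=float)
    a, b = poly[:-1], poly[1:]
    ab = b - a
    seg_len2 = np.einsum("ij,ij->i", ab, ab)
    t = np.clip(np.einsum("ij,ij->i", p - a, ab) / np.where(seg_len2 == 0, 1, seg_len2),
                0.0, 1.0)
    proj = a + t[:, None] * ab
    return float(np.sqrt(np.min(np.einsum("ij,ij->i", p - proj, p - proj))))


def measure_eye(boundaries: BoundarySet, landmarks: LandmarkSet, *,
                pcal_surface: str = "host", curvature_span_mm: float = 6.0,
                qc: QCResult = None) -> MeasurementRecord:
    """Compute the six core parameters plus curvature and graft thickness.

    ``pcal_surface`` selects the posterior corneal surface PCAL runs
    along through the grafted zone: ``"host"`` (default) follows the host
    endothelium; ``"graft"`` substitutes the graft posterior surface
    where present.  Curvature is the radius of a circle fitted to the
    central ``curvature_span_mm`` chord of the posterior cornea; graft
    thickness is the perpendicular distance from the graft posterior
    surface to the host/graft interface at the graft's lateral midpoint.
    Graft parameters are NaN when the eye carries no graft.
    """
    if not landmarks.has_spurs:
        raise ValueError("both scleral spurs are required")
    if pcal_surface not in ("host", "graft"):
        raise ValueError("pcal_surface must be 'host' or 'graft'")
    endo = boundaries.endothelium
    if len(endo) < 2:
        raise ValueError("endothelium polyline missing")

    if pcal_surface == "graft" and len(boundaries.graft_posterior) >= 2:
        gp = boundaries.graft_posterior
        inside = (endo[:, 0] >= gp[0, 0]) & (endo[:, 0] <= gp[-1, 0])
        z = endo[:, 1].copy()
        z[inside] = np.interp(endo[inside, 0], gp[:, 0], gp[:, 1])
        pcal_poly = np.column_stack([endo[:, 0], z])
    else:
        pcal_poly = endo

    pcal = arc_length(pcal_poly, landmarks.spur_left, landmarks.spur_right)
    acw = cord_length(landmarks.spur_left, landmarks.spur_right)

    agal = agcl = pgal = pgcl = thickness_um = float("nan")
    if landmarks.has_graft and len(boundaries.graft_posterior) >= 2:
        interface = (boundaries.graft_anterior_interface
                     if len(boundaries.graft_anterior_interface) >= 2 else endo)
        # the host/graft interface coincides with the endothelium; use the
        # full endothelium span when the cleft-detected polyline stops short
        # of the anterior edge landmarks (the graft tapers to nothing there)
        arc_iface = interface
        if (landmarks.graft_ant_left[0] < interface[0, 0] - 0.05 or
                landmarks.graft_ant_right[0] > interface[-1, 0] + 0.05):
            arc_iface = endo
        agal = arc_length(arc_iface, landmarks.graft_ant_left, landmarks.graft_ant_right)
        agcl = cord_length(landmarks.graft_ant_left, landmarks.graft_ant_right)
        gp = boundaries.graft_posterior
        pgal = arc_length(gp, landmarks.graft_post_left, landmarks.graft_post_right)
        pgcl = cord_length(landmarks.graft_post_left, landmarks.graft_post_right)
        agal = max(agal, agcl)  # projection quantisation guard
        pgal = max(pgal, pgcl)
        x_mid = 0.5 * (landmarks.graft_post_left[0] + landmarks.graft_post_right[0])
        p_mid = _interp_point(gp, x_mid)
        thickness_um = _point_to_polyline_distance(interface, p_mid) * 1000.0

    x_mid = 0.5 * (landmarks.spur_left[0] + landmarks.spur_right[0])
    central = endo[np.abs(endo[:, 0] - x_mid) <= curvature_span_mm / 2]
    _, radius, _ = fit_circle(central)

    return MeasurementRecord(
        pcal_mm=pcal, acw_mm=acw, agal_mm=agal, agcl_mm=agcl,
        pgal_mm=pgal, pgcl_mm=pgcl,
        posterior_curvature_mm=radius, graft_thickness_um=thickness_um,
        qc=qc if qc is not None else QCResult(True, "ok"))
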