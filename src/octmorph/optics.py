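"""Refraction warp and dewarp for layered anterior-segment media.

A time-domain B-scan records, for each vertical A-scan, optical path
length rather than geometric depth.  Below a refractive interface the
beam bends according to Snell's law at the local surface normal and the
recorded depth is stretched by the group index of the medium.  The
forward model here traces every A-scan through up to two interfaces
(air-tear, then cornea-aqueous) and maps physical points on the
refracted ray to apparent image coordinates ``(entry column, optical
path length)``.  The dewarp inverts the same construction: the air-tear
interface is imaged undistorted, so its traced polyline gives the
refraction normals directly, and the cornea-aqueous interface is first
mapped back to physical space before refracting across it.

With all indices equal to 1 both maps are the identity.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import map_coordinates

from .core import OCTImage, polyline_interp


def refract_directions(vx, vz, slope, n1, n2):
    """Vectorised Snell refraction of unit direction (vx, vz) at a surface
    with local slope dz/dx.  Returns (tx, tz, tir_mask)."""
    slope = np.asarray(slope, dtype=float)
    norm = np.sqrt(1.0 + slope ** 2)
    nx, nz = slope / norm, -1.0 / norm  # anterior-pointing normal
    cosi = -(nx * vx + nz * vz)
    r = n1 / n2
    sin2t = r ** 2 * (1.0 - cosi ** 2)
    tir = sin2t > 1.0
    cost = np.sqrt(np.clip(1.0 - sin2t, 0.0, None))
    tx = r * vx + (r * cosi - cost) * nx
    tz = r * vz + (r * cosi - cost) * nz
    return tx, tz, tir


def _poly_slope(poly, x):
    """Local slope of a polyline, linearly interpolated (0 outside span)."""
    if len(poly) < 2:
        return np.zeros_like(np.asarray(x, dtype=float))
    g = np.gradient(poly[:, 1], poly[:, 0])
    return np.interp(x, poly[:, 0], g, left=0.0, right=0.0)


def _first_crossing(zg, G, after=None):
    """First negative-to-positive sign change of G (K, W) along axis 0.

    Returns (found (W,), z_star (W,)) with linear interpolation between
    grid samples; ``after`` optionally masks out crossings at or above a
    per-column depth.
    """
    ok = np.isfinite(G[:-1]) & np.isfinite(G[1:]) & (G[:-1] < 0) & (G[1:] >= 0)
    if after is not None:
        ok &= zg[1:, None] > after[None, :]
    found = ok.any(axis=0)
    idx = np.argmax(ok, axis=0)
    cols = np.arange(G.shape[1])
    g0 = G[idx, cols]
    g1 = G[idx + 1, cols]
    denom = np.where(g1 - g0 == 0, 1.0, g1 - g0)
    frac = np.clip(-g0 / denom, 0.0, 1.0)
    z_star = zg[idx] + frac * (zg[idx + 1] - zg[idx])
    return found, np.where(found, z_star, np.nan)


class RayField:
    """Per-column refracted ray geometry (piecewise-linear in depth).

    Each A-scan is three segments: straight in air above the first
    interface, refracted once below it, refracted again below the second
    interface (where present).  ``opl`` is the optical path length, i.e.
    the apparent axial coordinate in the raw image.
    """

    def __init__(self, x0, z1, d1, z2, x2, d2, opl1, opl2, indices, z_max, tir):
        self.x0 = x0
        self.z1, self.d1x, self.d1z = z1, d1[0], d1[1]
        self.z2, self.x2 = z2, x2
        self.d2x, self.d2z = d2[0], d2[1]
        self.opl1, self.opl2 = opl1, opl2
        self.n_air, self.n_cornea, self.n_aqueous = indices
        self.z_max = z_max
        self.tir = tir

    # ------------------------------------------------------------------
    @classmethod
    def forward(cls, x_cols, interface1, interface2, indices, z_max, dz=0.004):
        """Build rays from *physical* interface polylines (rendering side)."""
        n_air, n_c, n_aq = indices
        x0 = np.asarray(x_cols, dtype=float)
        z1 = polyline_interp(interface1, x0)
        m1 = _poly_slope(interface1, x0)
        d1x, d1z, tir = refract_directions(0.0, 1.0, m1, n_air, n_c)
        no1 = ~np.isfinite(z1)
        z1 = np.where(no1, np.inf, z1)
        d1x = np.where(no1 | tir, 0.0, d1x)
        d1z = np.where(no1 | tir, 1.0, d1z)
        tir = tir & ~no1
        opl1 = np.where(np.isinf(z1), np.inf, n_air * z1)

        W = x0.size
        z2 = np.full(W, np.inf)
        x2 = x0.copy()
        d2x, d2z = np.zeros(W), np.ones(W)
        opl2 = np.full(W, np.inf)
        if interface2 is not None and len(interface2) >= 2:
            zg = np.arange(0.0, z_max + dz, dz)
            Xr = np.where(zg[:, None] < z1[None, :], x0[None, :],
                          x0[None, :] + (zg[:, None] - z1[None, :]) * (d1x / d1z)[None, :])
            G = zg[:, None] - polyline_interp(interface2, Xr)
            found, z_star = _first_crossing(zg, G, after=np.where(np.isinf(z1), np.inf, z1))
            found &= np.isfinite(z1) & ~tir
            z2 = np.where(found, z_star, np.inf)
            x2 = np.where(found, x0 + (z2 - z1) * d1x / d1z, x0)
            m2 = _poly_slope(interface2, x2)
            tx, tz, tir2 = refract_directions(d1x, d1z, m2, n_c, n_aq)
            good = found & ~tir2
            d2x = np.where(good, tx, 0.0)
            d2z = np.where(good, tz, 1.0)
            tir |= found & tir2
            opl2 = np.where(found, opl1 + n_c * (z2 - z1) / d1z, np.inf)
        return cls(x0, z1, (d1x, d1z), z2, x2, (d2x, d2z), opl1, opl2,
                   indices, z_max, tir)

    @classmethod
    def from_dewarp(cls, x_cols, interface1, interface2_apparent, indices, z_max):
        """Build rays from the *raw-image* interfaces (dewarping side).

        ``interface1`` is undistorted (air above), ``interface2_apparent``
        carries apparent (optical-path) depths and is mapped back to
        physical space along the stage-one refracted rays.
        """
        n_air, n_c, n_aq = indices
        x0 = np.asarray(x_cols, dtype=float)
        z1 = polyline_interp(interface1, x0)
        m1 = _poly_slope(interface1, x0)
        d1x, d1z, tir = refract_directions(0.0, 1.0, m1, n_air, n_c)
        no1 = ~np.isfinite(z1)
        z1 = np.where(no1, np.inf, z1)
        d1x = np.where(no1 | tir, 0.0, d1x)
        d1z = np.where(no1 | tir, 1.0, d1z)
        tir = tir & ~no1
        opl1 = np.where(np.isinf(z1), np.inf, n_air * z1)

        W = x0.size
        z2 = np.full(W, np.inf)
        x2 = x0.copy()
        d2x, d2z = np.zeros(W), np.ones(W)
        opl2 = np.full(W, np.inf)
        if interface2_apparent is not None and len(interface2_apparent) >= 2:
            za2 = polyline_interp(interface2_apparent, x0)
            valid = np.isfinite(za2) & np.isfinite(z1) & (za2 > opl1) & ~tir
            s = np.where(valid, (za2 - opl1) / n_c, np.nan)  # physical path length
            z2v = z1 + s * d1z
            x2v = x0 + s * d1x
            # physical second interface from the mapped points
            order = np.argsort(x2v[valid])
            pxs, pzs = x2v[valid][order], z2v[valid][order]
            if pxs.size >= 2:
                keep = np.concatenate([[True], np.diff(pxs) > 1e-12])
                phys2 = np.column_stack([pxs[keep], pzs[keep]])
                m2 = _poly_slope(phys2, x2v)
                tx, tz, tir2 = refract_directions(d1x, d1z, m2, n_c, n_aq)
                good = valid & ~tir2
                z2 = np.where(good, z2v, np.inf)
                x2 = np.where(good, x2v, x0)
                d2x = np.where(good, tx, 0.0)
                d2z = np.where(good, tz, 1.0)
                opl2 = np.where(good, za2, np.inf)
                tir |= valid & tir2
        return cls(x0, z1, (d1x, d1z), z2, x2, (d2x, d2z), opl1, opl2,
                   indices, z_max, tir)

    # ------------------------------------------------------------------
    def x_at_depth(self, z):
        """Lateral position of every ray at physical depth z (broadcasts)."""
        z = np.asarray(z, dtype=float)[..., None]
        seg3 = z >= self.z2
        seg2 = (z >= self.z1) & ~seg3
        with np.errstate(invalid="ignore"):
            x = np.where(seg3, self.x2 + (z - self.z2) * self.d2x / self.d2z,
                         np.where(seg2, self.x0 + (z - self.z1) * self.d1x / self.d1z,
                                  np.broadcast_to(self.x0,
                                                  np.broadcast_shapes(z.shape, self.x0.shape))))
        return x

    def opl_at_depth(self, z):
        """Optical path length (apparent depth) at physical depth z."""
        z = np.asarray(z, dtype=float)[..., None]
        seg3 = z >= self.z2
        seg2 = (z >= self.z1) & ~seg3
        with np.errstate(invalid="ignore"):
            opl = np.where(seg3, self.opl2 + self.n_aqueous * (z - self.z2) / self.d2z,
                           np.where(seg2, self.opl1 + self.n_cornea * (z - self.z1) / self.d1z,
                                    self.n_air * z))
        return opl

    def warp_polyline(self, poly, dz=0.004):
        """Apparent-image polyline of a physical surface.

        Total-internal-reflection columns are excluded from the output.
        """
        zg = np.arange(0.0, self.z_max + dz, dz)
        X = self.x_at_depth(zg)
        G = zg[:, None] - polyline_interp(poly, X)
        found, z_star = _first_crossing(zg, G)
        found &= ~self.tir
        cols = np.where(found)[0]
        if cols.size == 0:
            return np.empty((0, 2))
        opl = np.array([float(self.opl_at_depth(z_star[c])[c]) for c in cols])
        return np.column_stack([self.x0[cols], opl])

    def warp_points(self, pts):
        """Apparent (x, depth) of physical points (M, 2), via ray lookup."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        out = np.empty_like(pts)
        for i, (px, pz) in enumerate(pts):
            rx = self.x_at_depth(pz).ravel()
            ro = self.opl_at_depth(pz).ravel()
            good = ~self.tir
            out[i, 0] = np.interp(px, rx[good], self.x0[good])
            out[i, 1] = np.interp(px, rx[good], ro[good])
        return out


def dewarp_image(img: OCTImage, interfaces, indices) -> OCTImage:
    """Resample a raw B-scan onto the physical grid.

    ``interfaces`` is ``(air_tear, cornea_aqueous)``: mm polylines traced
    on the raw image, ordered top to bottom and single-valued per column
    (``cornea_aqueous`` may be None or empty).  Columns lacking the first
    interface are copied through unchanged and listed in
    ``meta['passthrough_columns']``; total-internal-reflection columns in
    ``meta['tir_columns']``.
    """
    n_air, n_c, n_aq = indices
    if min(indices) < 1.0:
        raise ValueError("refractive indices must be >= 1")
    f1, f2 = interfaces
    x = img.x_coords()
    z = img.z_coords()
    rays = RayField.from_dewarp(x, f1, f2, indices, img.axial_extent)

    # For every output (physical) pixel, locate the ray through it and the
    # apparent depth along that ray, then sample the raw image there.
    H, W = img.height, img.width
    RX = rays.x_at_depth(z)          # (H, W): lateral position of ray j at depth z_i
    RO = rays.opl_at_depth(z)        # (H, W): apparent depth of ray j at depth z_i
    good = ~rays.tir
    x_src = np.empty((H, W))
    z_src = np.empty((H, W))
    for i in range(H):
        rx, ro = RX[i, good], RO[i, good]
        x_src[i] = np.interp(x, rx, rays.x0[good])
        z_src[i] = np.interp(x, rx, ro)
    col_f, row_f = img.mm_to_px(x_src, z_src)
    out = map_coordinates(img.intensities.astype(float), [row_f, col_f],
                          order=1, mode="nearest")

    passthrough = np.where(~np.isfinite(polyline_interp(f1, x)))[0]
    out[:, passthrough] = img.intensities[:, passthrough]
    tir_cols = np.where(rays.tir)[0]
    out[:, tir_cols] = img.intensities[:, tir_cols]

    meta = dict(img.meta)
    meta["passthrough_columns"] = passthrough.tolist()
    meta["tir_columns"] = tir_cols.tolist()
    return OCTImage(np.clip(np.round(out), 0, 255).astype(np.uint8),
                    img.px_size_lateral, img.px_size_axial,
                    dewarped=True, source_id=img.source_id, meta=meta)
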