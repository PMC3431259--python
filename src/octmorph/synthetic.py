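"""Synthetic eyes, B-scans and measurement cohorts with known ground truth.

Three generators:

* :func:`generate_eye_geometry` — draws the morphometric parameters of a
  single post-keratoplasty eye from configured Gaussians (truncated at
  zero) and assembles the analytic :class:`~octmorph.geometry.GroundTruthGeometry`.
* :func:`render_bscan` — rasterises a geometry into an 8-bit greyscale
  B-scan: corneal tissue band, attached posterior lamellar graft
  (separated from the host by a thin dark interface cleft), scleral
  wedges with spur protrusions, an iris band, optional fully-developed
  (multiplicative exponential) speckle and optional refraction warp.
* :func:`generate_cohort` — a measurement-level cohort simulator: the
  trephine diameter is drawn from the 0.25 mm surgical grid and the
  posterior graft arc length follows a linear trephine link plus noise,
  with the remaining parameters coupled through the shared eye scale.
  A companion duplicate-session table adds per-observer Gaussian error
  for repeatability analyses.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core import InfeasibleConfigError, LandmarkSet, OCTImage, OutOfFieldError, polyline_interp
from .geometry import GroundTruthGeometry
from .optics import RayField

# Cohort-table parameter moments (mm except thickness in um): the study
# conditions the synthetic population reproduces.
PARAMETER_MEANS = {
    "pcal": 12.99, "curvature": 5.80, "agal": 9.69,
    "pgal": 9.24, "pgcl": 8.15, "thickness_um": 194.50,
    "acw": 11.16, "agcl": 8.65,
}
PARAMETER_SDS = {
    "pcal": 0.69, "curvature": 0.85, "agal": 0.66,
    "pgal": 0.72, "pgcl": 0.57, "thickness_um": 43.10,
    "acw": 0.57, "agcl": 0.48,
}

TREPHINE_LEVELS = tuple(np.round(np.arange(7.0, 9.51, 0.25), 2))


def _trephine_weights(levels) -> np.ndarray:
    """Discrete two-sided Gaussian around the 9.0 mm mode.

    A wider left shoulder reproduces the reported left-skewed surgical
    usage (mean ~8.6 mm, median and mode 9.0 mm, range 7.0-9.5 mm).
    """
    g = np.asarray(levels, dtype=float)
    sigma = np.where(g <= 9.0, 0.8, 0.2)
    w = np.exp(-0.5 * ((g - 9.0) / sigma) ** 2)
    return w / w.sum()


# Cross-parameter couplings for the measurement-level cohort generator,
# derived once from the target correlation structure (trephine->PGAL
# strongest, weak trephine->PCAL/ACW, near-independent curvature) and the
# parameter SDs above.
_PCAL_ON_PGAL = 0.36       # mm/mm; residual SD below keeps SD(pcal)=0.69
_PCAL_RESID_SD = 0.64
_ACW_ON_PCAL = 0.446
_ACW_RESID_SD = 0.48
_AGAL_ON_PGAL = 1.048      # anterior/posterior graft arc ratio
_AGAL_RESID_SD = 0.30
_ARC_TO_CORD_ANT = 1.122
_ARC_TO_CORD_POST = 1.134
_CORD_RESID_SD = 0.15

# Session-to-session observer noise (mm), set from the limits-of-agreement
# scale of the repeatability table: sigma_w = SD(difference)/sqrt(2).
OBSERVER_NOISE_SD = {
    "pcal_mm": 0.121, "acw_mm": 0.150, "agal_mm": 0.058,
    "agcl_mm": 0.041, "pgal_mm": 0.054, "pgcl_mm": 0.036,
}


@dataclass
class RenderConfig:
    """Rasterisation settings for synthetic B-scans."""

    image_width_px: int = 600
    image_height_px: int = 300
    lateral_extent_mm: float = 16.0
    axial_extent_mm: float = 6.0
    tissue_intensity_mean: float = 180.0
    background_intensity_mean: float = 40.0
    speckle_model: str = "multiplicative_exponential"  # or "none"
    refraction_warp: bool = False
    n_air: float = 1.000
    n_cornea: float = 1.388   # 1310-nm corneal group index
    n_aqueous: float = 1.343
    seed: int = 0
    spur_height_mm: float = 0.25
    seam_mm: float = 0.08     # dark host/graft interface cleft
    pupil_radius_mm: float = 1.75
    iris_thickness_mm: float = 0.35

    def __post_init__(self):
        if self.image_width_px <= 0 or self.image_height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.lateral_extent_mm <= 0 or self.axial_extent_mm <= 0:
            raise ValueError("physical extents must be positive")
        for v in (self.tissue_intensity_mean, self.background_intensity_mean):
            if not 0 <= v <= 255:
                raise ValueError("intensity means must lie in [0, 255]")
        if self.tissue_intensity_mean <= self.background_intensity_mean:
            raise ValueError("tissue mean must exceed background mean")
        if self.speckle_model not in ("none", "multiplicative_exponential"):
            raise ValueError(f"unknown speckle model {self.speckle_model!r}")
        if min(self.n_air, self.n_cornea, self.n_aqueous) < 1.0:
            raise ValueError("refractive indices must be >= 1")

    @property
    def indices(self):
        return (self.n_air, self.n_cornea, self.n_aqueous)

    @property
    def px_size_lateral(self):
        return self.lateral_extent_mm / self.image_width_px

    @property
    def px_size_axial(self):
        return self.axial_extent_mm / self.image_height_px


@dataclass
class CohortConfig:
    """Population and repeatability settings for cohort simulation."""

    n_eyes: int = 109
    parameter_means: dict = field(default_factory=lambda: dict(PARAMETER_MEANS))
    parameter_sds: dict = field(default_factory=lambda: dict(PARAMETER_SDS))
    trephine_levels: tuple = TREPHINE_LEVELS
    trephine_pgal_slope: float = 1.07        # mm graft arc per mm trephine
    trephine_pgal_intercept: Optional[float] = None  # None: match configured PGAL mean
    trephine_pgal_noise_sd: float = 0.43
    observer_noise_sd: dict = field(default_factory=lambda: dict(OBSERVER_NOISE_SD))
    seed: int = 0
    max_tries: int = 10_000

    def __post_init__(self):
        if self.n_eyes < 2:
            raise ValueError("n_eyes must be >= 2")
        if any(v < 0 for v in self.parameter_sds.values()):
            raise ValueError("parameter SDs must be >= 0")
        grid = set(np.round(np.arange(7.0, 9.51, 0.25), 2))
        if not set(np.round(self.trephine_levels, 2)) <= grid:
            raise ValueError("trephine levels must lie on the 7.00-9.50 mm, 0.25 mm grid")
        if self.trephine_pgal_noise_sd < 0 or any(v < 0 for v in self.observer_noise_sd.values()):
            raise ValueError("noise SDs must be >= 0")

    @property
    def trephine_weights(self) -> np.ndarray:
        return _trephine_weights(self.trephine_levels)

    @property
    def pgal_intercept(self) -> float:
        if self.trephine_pgal_intercept is not None:
            return self.trephine_pgal_intercept
        mean_t = float(np.dot(self.trephine_levels, self.trephine_weights))
        return self.parameter_means["pgal"] - self.trephine_pgal_slope * mean_t


def _truncated_normal(rng, mean, sd, max_tries=10_000):
    """Positive draw from N(mean, sd); bounded rejection at zero."""
    if sd == 0:
        if mean <= 0:
            raise InfeasibleConfigError("zero-SD parameter with non-positive mean")
        return float(mean)
    for _ in range(max_tries):
        v = rng.normal(mean, sd)
        if v > 0:
            return float(v)
    raise InfeasibleConfigError(f"truncation region for N({mean}, {sd}) has negligible mass")


def generate_eye_geometry(config: CohortConfig, seed: Optional[int] = None) -> GroundTruthGeometry:
    """Draw one eye's geometry from the configured parameter distributions.

    PCAL, PGAL and graft thickness are drawn once (their marginals are
    exactly the configured truncated Gaussians); curvature, PGCL and AGAL
    are redrawn under bounded rejection until the joint geometry is
    realisable as circular arcs.  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    m, s = config.parameter_means, config.parameter_sds
    pcal = _truncated_normal(rng, m["pcal"], s["pcal"], config.max_tries)
    pgal = _truncated_normal(rng, m["pgal"], s["pgal"], config.max_tries)
    thickness = _truncated_normal(rng, m["thickness_um"], s["thickness_um"], config.max_tries)
    last = None
    for _ in range(config.max_tries):
        curvature = _truncated_normal(rng, m["curvature"], s["curvature"], config.max_tries)
        pgcl = _truncated_normal(rng, m["pgcl"], s["pgcl"], config.max_tries)
        agal = _truncated_normal(rng, m["agal"], s["agal"], config.max_tries)
        try:
            return GroundTruthGeometry.from_parameters(
                pcal, curvature, agal, pgal, pgcl, thickness)
        except ValueError as exc:
            last = exc
    raise InfeasibleConfigError(
        f"no feasible geometry in {config.max_tries} tries (last: {last})")


# ---------------------------------------------------------------------------
# rendering

def _sclera_inner_profile(x_abs, x_spur, z_spur, spur_tangent, spur_height, z_cap):
    """Inner scleral wall depth beyond the spur.

    Continues along the posterior circle's tangent for a short ledge (the
    spur itself is the curvature change where circle becomes line), then
    descends steeply into the spur protrusion and flattens into a gentle
    posterior slope."""
    ledge = 0.25
    dx = x_abs - x_spur
    rise = np.where(dx <= ledge, spur_tangent * dx,
                    spur_tangent * ledge
                    + np.where(dx <= ledge + 0.15,
                               spur_height * (dx - ledge) / 0.15,
                               spur_height + 0.25 * (dx - ledge - 0.15)))
    return np.minimum(z_spur + rise, z_cap)


def _scene_polylines(geom: GroundTruthGeometry, cfg: RenderConfig):
    """Region (top, bottom) polyline pairs plus the two refractive interfaces."""
    half = cfg.lateral_extent_mm / 2
    xs = np.linspace(-half, half, 4 * cfg.image_width_px + 1)
    ax = np.abs(xs)
    x_spur = geom.x_spur
    z_spur = geom.spur_right[1]
    z_cap = cfg.axial_extent_mm - 0.25

    x_lim = min(x_spur + 0.3, 0.97 * geom.anterior_radius)
    top_tissue = np.where(ax <= x_lim, geom.anterior_surface(np.clip(xs, -x_lim, x_lim)),
                          float(geom.anterior_surface(x_lim)))
    posterior = geom.posterior_surface(xs)
    spur_tangent = x_spur / math.sqrt(max(geom.posterior_radius ** 2 - x_spur ** 2, 1e-9))
    sclera_inner = _sclera_inner_profile(ax, x_spur, z_spur, spur_tangent,
                                         cfg.spur_height_mm, z_cap)

    def poly(mask, z):
        return np.column_stack([xs[mask], np.asarray(z)[mask]])

    in_cornea = ax <= x_spur
    regions = [(poly(in_cornea, top_tissue), poly(in_cornea, posterior))]
    in_sclera = ax >= x_spur
    for side in (xs < 0, xs > 0):
        msk = in_sclera & side
        regions.append((poly(msk, top_tissue), poly(msk, sclera_inner)))

    bottom_tissue = np.where(in_cornea, posterior, sclera_inner)
    if geom.has_graft:
        x_gp, x_ga = geom.x_graft_posterior, geom.x_graft_anterior
        seam = cfg.seam_mm
        graft_top = posterior + seam
        circ = geom.graft_posterior_surface(xs)
        edge_z = float(geom.graft_posterior_surface(x_gp))
        with np.errstate(invalid="ignore"):
            taper = edge_z + (graft_top - edge_z) * (ax - x_gp) / max(x_ga - x_gp, 1e-9)
        graft_bottom = np.where(ax <= x_gp, circ, taper)
        # blunt cut edge in the taper: stop rendering where the tapering
        # sliver gets thinner than 0.1 mm so it cannot fuse across the cleft
        in_graft = (graft_bottom > graft_top + np.where(ax <= x_gp, 0.02, 0.1)) \
            & (ax <= x_ga)
        regions.append((poly(in_graft, graft_top), poly(in_graft, graft_bottom)))
        bottom_tissue = np.where(in_graft, graft_bottom, bottom_tissue)

    iris_top = np.full_like(xs, geom.iris_plane_depth)
    # iris wings stop short of the corneal flank: keep a clear angle recess
    # (at least 0.3 mm of aqueous) so blurring cannot fuse iris and cornea
    with np.errstate(invalid="ignore"):
        clearance = geom.iris_plane_depth - posterior - 0.3
    iris_in = (ax >= cfg.pupil_radius_mm) & (ax <= x_spur - 0.1) & \
        (np.isnan(clearance) | (clearance > 0))
    for side in (xs < 0, xs > 0):
        msk = iris_in & side
        regions.append((poly(msk, iris_top), poly(msk, iris_top + cfg.iris_thickness_mm)))

    interface1 = np.column_stack([xs, top_tissue])
    interface2 = np.column_stack([xs, bottom_tissue])
    return regions, interface1, interface2


def _occupancy_direct(regions, x_cols, z_rows):
    occ = np.zeros((z_rows.size, x_cols.size), dtype=bool)
    Z = z_rows[:, None]
    for top, bottom in regions:
        t = polyline_interp(top, x_cols)
        b = polyline_interp(bottom, x_cols)
        with np.errstate(invalid="ignore"):
            occ |= (Z >= t) & (Z <= b)
    return occ


def _occupancy_warped(regions, rays, cfg):
    """Paint region occupancy into apparent-image pixels along each ray."""
    px_ax = cfg.px_size_axial
    zg = np.arange(0.0, cfg.axial_extent_mm + px_ax / 2, px_ax / 2)
    X = rays.x_at_depth(zg)
    OPL = rays.opl_at_depth(zg)
    occ = np.zeros_like(X, dtype=bool)
    Z = zg[:, None]
    for top, bottom in regions:
        t = polyline_interp(top, X)
        b = polyline_interp(bottom, X)
        with np.errstate(invalid="ignore"):
            occ |= (Z >= t) & (Z <= b)
    H, W = cfg.image_height_px, cfg.image_width_px
    grid = np.zeros((H, W), dtype=bool)
    step = np.diff(occ.astype(np.int8), axis=0)
    for j in range(W):
        if rays.tir[j]:
            continue
        starts = np.where(step[:, j] == 1)[0] + 1
        ends = np.where(step[:, j] == -1)[0]
        if occ[0, j]:
            starts = np.r_[0, starts]
        if occ[-1, j]:
            ends = np.r_[ends, occ.shape[0] - 1]
        for a, b in zip(starts, ends):
            r0 = max(int(np.ceil(OPL[a, j] / px_ax - 0.5)), 0)
            r1 = min(int(np.floor(OPL[b, j] / px_ax - 0.5)), H - 1)
            if r1 >= r0:
                grid[r0:r1 + 1, j] = True
    return grid


def _check_in_field(geom: GroundTruthGeometry, cfg: RenderConfig):
    half = cfg.lateral_extent_mm / 2
    if geom.x_spur + 0.5 > half:
        raise OutOfFieldError("scleral spurs fall outside the lateral field")
    z_deep = geom.spur_right[1] + cfg.spur_height_mm
    if geom.has_graft:
        z_deep = max(z_deep, geom.graft_center[1] - geom.graft_radius *
                     math.cos(geom.graft_half_angle))
    z_deep = max(z_deep, geom.iris_plane_depth + cfg.iris_thickness_mm)
    if z_deep + 0.2 > cfg.axial_extent_mm:
        raise OutOfFieldError("geometry deeper than the axial field")
    if geom.anterior_center[1] - geom.anterior_radius < 0:
        raise OutOfFieldError("anterior surface above the top of the field")


def apply_refraction_warp(geom: GroundTruthGeometry, cfg: RenderConfig) -> dict:
    """Forward-warp the true surface polylines into apparent coordinates.

    Returns a dict of polylines keyed ``anterior``/``posterior``/
    ``graft_posterior`` (the latter empty for graftless eyes).  Columns hit
    by total internal reflection are excluded.  With unit indices the
    output equals the surfaces sampled at the A-scan columns.
    """
    _check_in_field(geom, cfg)
    half = cfg.lateral_extent_mm / 2
    x_cols = (np.arange(cfg.image_width_px) + 0.5) * cfg.px_size_lateral - half
    surfaces = {
        "anterior": geom.surface_polyline("anterior", -geom.x_spur, geom.x_spur),
        "posterior": geom.surface_polyline("posterior", -geom.x_spur, geom.x_spur),
        "graft_posterior": (geom.surface_polyline(
            "graft_posterior", -geom.x_graft_posterior, geom.x_graft_posterior)
            if geom.has_graft else np.empty((0, 2))),
    }
    if cfg.indices == (1.0, 1.0, 1.0):
        out = {}
        for name, poly in surfaces.items():
            if len(poly) == 0:
                out[name] = poly
                continue
            keep = (x_cols >= poly[0, 0]) & (x_cols <= poly[-1, 0])
            out[name] = np.column_stack([x_cols[keep],
                                         polyline_interp(poly, x_cols[keep])])
        return out
    _, interface1, interface2 = _scene_polylines(geom, cfg)
    rays = RayField.forward(x_cols, interface1, interface2, cfg.indices,
                            cfg.axial_extent_mm)
    return {name: (rays.warp_polyline(poly) if len(poly) else poly)
            for name, poly in surfaces.items()}


def render_bscan(geom: GroundTruthGeometry, cfg: RenderConfig):
    """Rasterise a geometry into an 8-bit B-scan.

    Returns ``(OCTImage, LandmarkSet)``; the landmarks carry the true
    physical (mm) positions of the spurs and graft edges, and the image
    ``meta['landmarks_px']`` their pixel positions in the rendered (possibly
    warped) image.
    """
    _check_in_field(geom, cfg)
    regions, interface1, interface2 = _scene_polylines(geom, cfg)
    half = cfg.lateral_extent_mm / 2
    x_cols = (np.arange(cfg.image_width_px) + 0.5) * cfg.px_size_lateral - half
    z_rows = (np.arange(cfg.image_height_px) + 0.5) * cfg.px_size_axial

    warped = cfg.refraction_warp and cfg.indices != (1.0, 1.0, 1.0)
    if warped:
        rays = RayField.forward(x_cols, interface1, interface2, cfg.indices,
                                cfg.axial_extent_mm)
        occ = _occupancy_warped(regions, rays, cfg)
    else:
        occ = _occupancy_direct(regions, x_cols, z_rows)

    base = np.where(occ, cfg.tissue_intensity_mean, cfg.background_intensity_mean)
    if cfg.speckle_model == "multiplicative_exponential":
        rng = np.random.default_rng(cfg.seed)
        base = base * rng.exponential(1.0, size=base.shape)
    arr = np.clip(np.round(base), 0, 255).astype(np.uint8)

    img = OCTImage(arr, cfg.px_size_lateral, cfg.px_size_axial,
                   dewarped=not warped, source_id="synthetic")
    landmarks = geom.landmarks()
    pts = [landmarks.spur_left, landmarks.spur_right]
    names = ["spur_left", "spur_right"]
    if landmarks.has_graft:
        pts += [landmarks.graft_ant_left, landmarks.graft_ant_right,
                landmarks.graft_post_left, landmarks.graft_post_right]
        names += ["graft_ant_left", "graft_ant_right",
                  "graft_post_left", "graft_post_right"]
    pts = np.asarray(pts)
    if warped:
        pts = rays.warp_points(pts)
    cols, rows = img.mm_to_px(pts[:, 0], pts[:, 1])
    img.meta["landmarks_px"] = {n: [float(c), float(r)]
                                for n, c, r in zip(names, cols, rows)}
    return img, landmarks


# ---------------------------------------------------------------------------
# measurement-level cohort simulation

COHORT_COLUMNS = ["eye_id", "age", "sex", "side", "trephine_mm",
                  "pcal_mm", "acw_mm", "agal_mm", "agcl_mm", "pgal_mm",
                  "pgcl_mm", "curvature_mm", "thickness_um",
                  "insertion_technique", "endothelial_cell_count"]


def generate_cohort(config: CohortConfig):
    """Simulate a cohort table and a duplicate-session table.

    Returns ``(cohort, duplicates)``: ``cohort`` has one row per eye with
    the schema of :data:`COHORT_COLUMNS`; ``duplicates`` is long-format
    (``subject_id, session, parameter, value``) with two measurement
    sessions per eye, each perturbed by the per-parameter observer noise.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_eyes
    m, s = config.parameter_means, config.parameter_sds

    levels = np.asarray(config.trephine_levels, dtype=float)
    t = rng.choice(levels, size=n, p=config.trephine_weights)
    pgal = config.pgal_intercept + config.trephine_pgal_slope * t \
        + rng.normal(0.0, config.trephine_pgal_noise_sd, n)
    pgal = np.clip(pgal, 1e-3, None)
    pcal = m["pcal"] + _PCAL_ON_PGAL * (pgal - m["pgal"]) + rng.normal(0, _PCAL_RESID_SD, n)
    acw = m["acw"] + _ACW_ON_PCAL * (pcal - m["pcal"]) + rng.normal(0, _ACW_RESID_SD, n)
    curvature = np.abs(rng.normal(m["curvature"], s["curvature"], n))
    agal = _AGAL_ON_PGAL * pgal + rng.normal(0, _AGAL_RESID_SD, n)
    agcl = np.minimum(agal / _ARC_TO_CORD_ANT + rng.normal(0, _CORD_RESID_SD, n), agal)
    pgcl = np.minimum(pgal / _ARC_TO_CORD_POST + rng.normal(0, _CORD_RESID_SD, n),
                      np.minimum(pgal, pcal))
    thickness = np.abs(rng.normal(m["thickness_um"], s["thickness_um"], n))

    cohort = pd.DataFrame({
        "eye_id": [f"eye{i:04d}" for i in range(n)],
        "age": np.clip(rng.normal(66.17, 11.58, n), 18, 95).round(1),
        "sex": np.where(rng.random(n) < 0.532, "M", "F"),
        "side": np.where(rng.random(n) < 0.514, "OD", "OS"),
        "trephine_mm": t,
        "pcal_mm": pcal, "acw_mm": acw, "agal_mm": agal, "agcl_mm": agcl,
        "pgal_mm": pgal, "pgcl_mm": pgcl,
        "curvature_mm": curvature, "thickness_um": thickness,
        "insertion_technique": np.where(rng.random(n) < 0.853, "glide", "taco"),
        "endothelial_cell_count": rng.normal(2881.54, 240.78, n).round(0),
    })[COHORT_COLUMNS]

    rows = []
    for param, sigma in config.observer_noise_sd.items():
        truth = cohort[param].to_numpy()
        for session in ("A", "B"):
            vals = truth + rng.normal(0.0, sigma, n)
            rows.append(pd.DataFrame({
                "subject_id": cohort["eye_id"], "session": session,
                "parameter": param, "value": vals}))
    duplicates = pd.concat(rows, ignore_index=True)
    return cohort, duplicates
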