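"""Shared containers and error types.

Coordinate conventions used throughout the package:

* Physical coordinates are millimetres. ``x`` is the lateral position,
  centred on the scan axis (negative = left); ``z`` is depth, increasing
  posteriorly, with ``z = 0`` at the top (most anterior) edge of the field.
* Image arrays are indexed ``[row, column]`` with row 0 at the top
  (anterior) and columns running left to right.  A pixel centre maps to
  ``x = (col + 0.5) * px_size_lateral - lateral_extent / 2`` and
  ``z = (row + 0.5) * px_size_axial``.
* Polylines are ``(N, 2)`` float arrays of ``[x_mm, z_mm]`` rows, strictly
  increasing in ``x``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

QC_REASONS = ("ok", "spur_not_identifiable", "segmentation_failed", "low_contrast")


class OutOfFieldError(ValueError):
    """Geometry does not fit inside the rendered field."""


class LowContrastError(ValueError):
    """Histogram too flat (constant or unimodal) to threshold."""


class SegmentationError(ValueError):
    """Boundary tracing failed (missing or discontinuous tissue band)."""


class OutOfSpanError(ValueError):
    """Arc endpoint lies outside the polyline's lateral span."""


class CollinearPointsError(ValueError):
    """Circle fit requested on (near-)collinear points."""


class InfeasibleConfigError(ValueError):
    """Rejection sampling exhausted: configured distributions leave negligible feasible mass."""


class ConstantInputError(ValueError):
    """Statistic undefined on a constant input sequence."""


class DegenerateDataError(ValueError):
    """Statistic undefined on degenerate data (e.g. zero between-subject variance)."""


class CollinearityError(ValueError):
    """Rank-deficient regression design."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"rank-deficient design; offending columns: {self.columns}")


def as_polyline(points) -> np.ndarray:
    """Coerce to an (N, 2) float array and check lateral monotonicity."""
    arr = np.asarray(points, dtype=float)
    if arr.size == 0:
        return arr.reshape(0, 2)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("polyline must be an (N, 2) array of [x, z]")
    if arr.shape[0] > 1 and not np.all(np.diff(arr[:, 0]) > 0):
        raise ValueError("polyline must be strictly increasing in x")
    return arr


def polyline_interp(poly: np.ndarray, x, left=np.nan, right=np.nan):
    """Depth of a polyline at lateral position(s) x (NaN outside its span)."""
    if len(poly) == 0:
        return np.full_like(np.asarray(x, dtype=float), np.nan)
    return np.interp(x, poly[:, 0], poly[:, 1], left=left, right=right)


@dataclass
class OCTImage:
    """A 2-D greyscale B-scan with physical pixel spacing."""

    intensities: np.ndarray
    px_size_lateral: float
    px_size_axial: float
    dewarped: bool = False
    source_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        arr = np.asarray(self.intensities)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("intensities must be a non-empty 2-D grid")
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        if self.px_size_lateral <= 0 or self.px_size_axial <= 0:
            raise ValueError("pixel sizes must be positive")
        self.intensities = arr

    @property
    def height(self) -> int:
        return self.intensities.shape[0]

    @property
    def width(self) -> int:
        return self.intensities.shape[1]

    @property
    def lateral_extent(self) -> float:
        return self.width * self.px_size_lateral

    @property
    def axial_extent(self) -> float:
        return self.height * self.px_size_axial

    def x_coords(self) -> np.ndarray:
        """Lateral mm coordinate of each column centre."""
        return (np.arange(self.width) + 0.5) * self.px_size_lateral - self.lateral_extent / 2

    def z_coords(self) -> np.ndarray:
        """Axial mm coordinate of each row centre."""
        return (np.arange(self.height) + 0.5) * self.px_size_axial

    def mm_to_px(self, x, z):
        """Map physical mm coordinates to fractional (col, row) pixel indices."""
        col = (np.asarray(x) + self.lateral_extent / 2) / self.px_size_lateral - 0.5
        row = np.asarray(z) / self.px_size_axial - 0.5
        return col, row


@dataclass
class BinaryMask:
    """Tissue/open-space classification of a B-scan (1 = tissue)."""

    values: np.ndarray
    threshold_used: float
    px_size_lateral: float = 1.0
    px_size_axial: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        arr = np.asarray(self.values)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("mask must be a non-empty 2-D grid")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        self.values = arr.astype(np.uint8)


@dataclass
class BoundarySet:
    """Traced tissue boundaries, all in physical mm (left to right)."""

    epithelium: np.ndarray
    endothelium: np.ndarray
    graft_anterior_interface: np.ndarray
    graft_posterior: np.ndarray
    iris_anterior: np.ndarray

    def __post_init__(self):
        for name in ("epithelium", "endothelium", "graft_anterior_interface",
                     "graft_posterior", "iris_anterior"):
            setattr(self, name, as_polyline(getattr(self, name)))

    def validate(self, atol: float = 1e-9):
        """Check vertical ordering: epithelium above endothelium above/equal graft posterior."""
        if len(self.epithelium) and len(self.endothelium):
            z_ep = polyline_interp(self.epithelium, self.endothelium[:, 0])
            ok = np.isnan(z_ep) | (z_ep <= self.endothelium[:, 1] + atol)
            if not ok.all():
                raise SegmentationError("endothelium above epithelium")
        if len(self.endothelium) and len(self.graft_posterior):
            z_en = polyline_interp(self.endothelium, self.graft_posterior[:, 0])
            ok = np.isnan(z_en) | (z_en <= self.graft_posterior[:, 1] + atol)
            if not ok.all():
                raise SegmentationError("graft posterior above endothelium")
        return self


@dataclass
class LandmarkSet:
    """Operator-identified anchor points (physical mm).

    Scleral spurs are mandatory; graft edge pairs are ``None`` for eyes
    without a graft.
    """

    spur_left: Optional[np.ndarray]
    spur_right: Optional[np.ndarray]
    graft_ant_left: Optional[np.ndarray] = None
    graft_ant_right: Optional[np.ndarray] = None
    graft_post_left: Optional[np.ndarray] = None
    graft_post_right: Optional[np.ndarray] = None

    def __post_init__(self):
        for name in ("spur_left", "spur_right", "graft_ant_left", "graft_ant_right",
                     "graft_post_left", "graft_post_right"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))
        for left, right in (("spur_left", "spur_right"),
                            ("graft_ant_left", "graft_ant_right"),
                            ("graft_post_left", "graft_post_right")):
            lv, rv = getattr(self, left), getattr(self, right)
            if lv is not None and rv is not None and not lv[0] < rv[0]:
                raise ValueError(f"{left} must lie laterally left of {right}")

    @property
    def has_spurs(self) -> bool:
        return self.spur_left is not None and self.spur_right is not None

    @property
    def has_graft(self) -> bool:
        return all(getattr(self, n) is not None for n in
                   ("graft_ant_left", "graft_ant_right", "graft_post_left", "graft_post_right"))


@dataclass
class QCResult:
    """Image-quality gate outcome; ``reason == 'ok'`` iff included."""

    included: bool
    reason: str = "ok"

    def __post_init__(self):
        if self.reason not in QC_REASONS:
            raise ValueError(f"unknown QC reason {self.reason!r}")
        if self.included != (self.reason == "ok"):
            raise ValueError("reason must be 'ok' iff included")


@dataclass
class MeasurementRecord:
    """One eye's morphometric parameters (the cohort-table row type).

    Arc lengths (``*al``) run along traced surfaces; cord lengths (``*cl``)
    are straight-line distances between the same landmarks, so every arc is
    at least as long as its cord.  Graft fields are NaN for eyes without a
    graft.
    """

    pcal_mm: float
    acw_mm: float
    agal_mm: float
    agcl_mm: float
    pgal_mm: float
    pgcl_mm: float
    posterior_curvature_mm: float
    graft_thickness_um: float
    qc: QCResult = field(default_factory=lambda: QCResult(True, "ok"))

    def __post_init__(self):
        if self.qc.included:
            for name in ("pcal_mm", "acw_mm", "posterior_curvature_mm"):
                if not np.asarray(getattr(self, name)) > 0:
                    raise ValueError(f"{name} must be positive on an included eye")
            for arc, cord in (("agal_mm", "agcl_mm"), ("pgal_mm", "pgcl_mm")):
                a, c = getattr(self, arc), getattr(self, cord)
                if np.isfinite(a) and np.isfinite(c) and a < c - 1e-9:
                    raise ValueError(f"{arc} smaller than {cord}")
            if np.isfinite(self.pgcl_mm) and self.pgcl_mm > self.pcal_mm + 1e-9:
                raise ValueError("pgcl exceeds pcal")

    def to_dict(self) -> dict:
        return {
            "pcal_mm": self.pcal_mm, "acw_mm": self.acw_mm,
            "agal_mm": self.agal_mm, "agcl_mm": self.agcl_mm,
            "pgal_mm": self.pgal_mm, "pgcl_mm": self.pgcl_mm,
            "curvature_mm": self.posterior_curvature_mm,
            "thickness_um": self.graft_thickness_um,
        }
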