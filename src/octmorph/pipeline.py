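"""B-scan processing chain: conditioning, dewarp, binarisation, boundary
tracing and the image-quality gate.

The chain mirrors how cross-sectional anterior-segment scans are prepared
for morphometry: impulse noise is removed and contrast stretched, the
image is refraction-corrected at the air-tear and cornea-aqueous
interfaces, a tissue/open-space mask is computed with Otsu's threshold,
and the corneal band (with any attached graft, distinguished by the dark
interface cleft) and iris band are traced column by column.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d, median_filter
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_holes, remove_small_objects

from . import optics
from .core import (BinaryMask, BoundarySet, LandmarkSet, LowContrastError, OCTImage,
                   QCResult, SegmentationError)

#: minimum intensity separation (out of 255) between Otsu classes for an
#: image to count as bimodal
_MIN_CLASS_SEPARATION = 10.0
#: 95th-5th percentile contrast floor for QC inclusion
DEFAULT_CONTRAST_FLOOR = 30.0


def condition_image(img: OCTImage) -> OCTImage:
    """3x3 median filter followed by a 1st-99th percentile contrast stretch.

    Near-idempotent on already conditioned images (re-application changes
    intensities by at most the quantisation step).  A constant image is
    returned unchanged with ``meta['constant_warning']`` set.
    """
    arr = img.intensities.astype(float)
    meta = dict(img.meta)
    if np.ptp(arr) == 0:
        meta["constant_warning"] = True
        return OCTImage(img.intensities.copy(), img.px_size_lateral, img.px_size_axial,
                        img.dewarped, img.source_id, meta)
    med = median_filter(arr, size=3, mode="nearest")
    p1, p99 = np.percentile(med, [1, 99])
    if p99 <= p1:
        meta["constant_warning"] = True
        out = med
    else:
        out = (med - p1) / (p99 - p1) * 255.0
    meta["conditioned"] = True
    return OCTImage(np.clip(np.round(out), 0, 255).astype(np.uint8),
                    img.px_size_lateral, img.px_size_axial,
                    img.dewarped, img.source_id, meta)


def despeckle_image(img: OCTImage, sigma_px=(1.5, 0.8)) -> OCTImage:
    """Gaussian spatial compounding for fully developed speckle.

    A multiplicative-exponential speckle field has unit contrast (SD equals
    the mean), so impulse filtering alone cannot separate tissue from open
    space; averaging over a small Gaussian window brings the intensity
    coefficient of variation down to a level where a global threshold
    cleanly splits the two classes.  The window is kept narrow laterally
    ``(sigma_axial, sigma_lateral)`` so that the thin host/graft interface
    cleft is not smeared shut where the surfaces run steeply.  Applied
    between conditioning and binarisation; harmless (slight edge softening)
    on noiseless images.
    """
    arr = img.intensities.astype(float)
    meta = dict(img.meta)
    # residual high-frequency energy after a 3x3 median estimates the
    # remaining speckle; clean images are passed through unchanged so their
    # sharp features (graft edge corners) are not needlessly rounded
    hf = float(np.median(np.abs(arr - median_filter(arr, size=3, mode="nearest"))))
    if hf < 1.0:
        meta["despeckled"] = False
        return OCTImage(img.intensities.copy(), img.px_size_lateral,
                        img.px_size_axial, img.dewarped, img.source_id, meta)
    arr = gaussian_filter(arr, sigma_px, mode="nearest")
    meta["despeckled"] = True
    return OCTImage(np.clip(np.round(arr), 0, 255).astype(np.uint8),
                    img.px_size_lateral, img.px_size_axial,
                    img.dewarped, img.source_id, meta)


def dewarp(img: OCTImage, interfaces, indices=(1.0, 1.388, 1.343)) -> OCTImage:
    """Refraction-correct a raw scan; see :func:`octmorph.optics.dewarp_image`."""
    return optics.dewarp_image(img, interfaces, indices)


def binarize(img: OCTImage) -> BinaryMask:
    """Tissue mask by Otsu's between-class-variance-maximising threshold.

    Raises :class:`LowContrastError` on constant or effectively unimodal
    images (for the QC gate to record).
    """
    arr = img.intensities
    if np.ptp(arr) == 0:
        raise LowContrastError("constant image cannot be thresholded")
    t = threshold_otsu(arr)
    mask = arr > t
    if mask.all() or not mask.any():
        raise LowContrastError("Otsu threshold produced a single class")
    # canonicalise to the midpoint of the empty intensity gap between the
    # two classes (same partition, but the reported threshold then lies
    # strictly between the class levels)
    t = (float(arr[~mask].max()) + float(arr[mask].min())) / 2.0
    sep = arr[mask].mean() - arr[~mask].mean()
    if sep < _MIN_CLASS_SEPARATION:
        raise LowContrastError(f"class separation {sep:.1f} below {_MIN_CLASS_SEPARATION}")
    return BinaryMask(mask.astype(np.uint8), float(t),
                      img.px_size_lateral, img.px_size_axial,
                      meta=dict(img.meta))


def _column_runs(col):
    """(start, end) inclusive row index pairs of 1-runs in a column."""
    d = np.diff(col.astype(np.int8))
    starts = np.where(d == 1)[0] + 1
    ends = np.where(d == -1)[0]
    if col[0]:
        starts = np.r_[0, starts]
    if col[-1]:
        ends = np.r_[ends, col.size - 1]
    return list(zip(starts.tolist(), ends.tolist()))


def _fill_small_gaps(vals, max_gap=25):
    """Linearly interpolate interior NaN runs up to ``max_gap`` columns.

    Scattered unresolved columns otherwise fragment a boundary into short
    segments whose independent smoothing end-effects corrugate the
    polyline and inflate arc lengths.
    """
    finite = np.isfinite(vals)
    idx = np.where(finite)[0]
    if idx.size < 2:
        return vals.copy()
    out = vals.copy()
    interp = np.interp(np.arange(vals.size), idx, vals[idx])
    gap_starts = idx[:-1][np.diff(idx) > 1] + 1
    gap_ends = idx[1:][np.diff(idx) > 1]  # exclusive
    for a, b in zip(gap_starts, gap_ends):
        if b - a <= max_gap:
            out[a:b] = interp[a:b]
    return out


def _lowpass_linear_padded(y, sigma):
    """Gaussian low-pass with linear-extrapolation end padding.

    Plain edge padding flattens the local slope over the last ~sigma
    samples, which visibly clips steep features such as the V-corner at a
    graft edge; extending each end along its fitted slope first keeps end
    gradients unbiased."""
    n = y.size
    k = int(3 * sigma) + 1
    m = min(5, n)
    il = np.arange(m)
    sl = np.polyfit(il, y[:m], 1)[0] if m >= 2 else 0.0
    sr = np.polyfit(il, y[-m:], 1)[0] if m >= 2 else 0.0
    left = y[0] + sl * np.arange(-k, 0)
    right = y[-1] + sr * np.arange(1, k + 1)
    ext = np.concatenate([left, y, right])
    return gaussian_filter1d(ext, sigma, mode="nearest")[k:-k]


def _smooth_moving_median(vals, window=5, subpixel_window=11, step_px=4.0):
    """Moving median, then a quadratic Savitzky-Golay pass, over contiguous
    finite segments of a per-column series.

    The median suppresses outlier columns; the polynomial pass removes the
    one-pixel staircase that row quantisation imprints on smooth surfaces
    (which would otherwise bias arc lengths upward by a few percent).  The
    polynomial pass is split at genuine steps (column-to-column jumps
    beyond ``step_px`` after the median) so sharp anatomical edges are not
    smeared into their neighbourhood.
    """
    out = vals.copy()
    finite = np.isfinite(vals)
    idx = np.where(finite)[0]
    if idx.size == 0:
        return out
    splits = np.where(np.diff(idx) > 1)[0] + 1
    for seg in np.split(idx, splits):
        if seg.size >= 2:
            out[seg] = median_filter(vals[seg], size=min(window, seg.size),
                                     mode="nearest")
        y = out[seg]
        brk = np.abs(np.diff(y)) > step_px
        km = np.zeros(seg.size, dtype=bool)
        if seg.size >= 7:
            # kinks: abrupt slope change (e.g. the V-corner at a graft
            # edge); the threshold adapts to the segment's own roughness so
            # residual speckle jitter is not mistaken for anatomy
            kink = np.abs(y[:-6] - 2 * y[3:-3] + y[6:]) / 3.0
            thr = max(1.5, 5.0 * float(np.median(kink)))
            local_max = kink >= np.maximum.reduce(
                [np.r_[kink[1:], 0], np.r_[0, kink[:-1]]])
            splits_m = np.zeros(seg.size, dtype=bool)
            splits_m[3:-3] = (kink > thr) & local_max
            brk |= splits_m[1:]
            # only unmistakable corners get their raw depth restored later
            km[3:-3] = (kink > max(1.5, 7.0 * float(np.median(kink)))) & local_max
        step_splits = np.where(brk)[0] + 1
        for sub in np.split(seg, step_splits):
            if sub.size >= 5:
                # Gaussian low-pass: strongly suppresses the sub-pixel ripple
                # that inflates arc lengths, while the curvature attenuation
                # bias (~sigma^2 * kappa / 2) is far below a micrometre for
                # corneal radii
                out[sub] = _lowpass_linear_padded(out[sub], subpixel_window / 5.0)
        # the wide median clips sharp vertices by a pixel or two, which a
        # spur-to-spur or edge-to-edge arc feels disproportionately; restore
        # near-raw values in a small neighbourhood of each detected kink
        if seg.size >= 7:
            raw = vals[seg]
            for p in np.where(km)[0]:
                a, b = max(p - 2, 0), min(p + 3, seg.size)
                out[seg[a:b]] = raw[a:b]
    return out


def _select_cleft(x, complex_bottom, gap_candidates, graft_zone, present,
                  px_axial, tol_mm=0.15, grow_mm=0.5):
    """Pick the host/graft cleft among per-column gap candidates.

    The host posterior cornea continues smoothly (circularly) under the
    graft, so selection grows inward from the zone edges: a circle is
    fitted to the corneal band bottom on the flanks, candidate gaps in a
    short strip inside the zone are accepted when they fall within
    ``tol_mm`` of the fit, the accepted points join the support, and the
    strip advances until the zone is covered.  Every prediction is then a
    short extrapolation from data, never a leap across the whole graft.

    Returns ``(endo_rows, resolved, z_pred_rows)``: the run-above-cleft
    bottom per column (NaN where unresolved), a boolean resolved mask, and
    the final support-circle prediction of the host posterior surface in
    row units (NaN outside the zone or when no circle could be fitted).
    """
    from .core import CollinearPointsError
    from .morphometry import fit_circle

    endo_rows = np.full_like(x, np.nan)
    resolved = np.zeros(x.size, dtype=bool)
    z_pred_rows = np.full_like(x, np.nan)
    zone = np.where(graft_zone)[0]
    if zone.size == 0:
        return endo_rows, resolved, z_pred_rows
    x_lo, x_hi = x[zone[0]], x[zone[-1]]
    flank = present & ~graft_zone & np.isfinite(complex_bottom) & \
        (x >= x_lo - 0.6) & (x <= x_hi + 0.6)
    sup_x = list(x[flank])
    sup_z = list((complex_bottom[flank] + 0.5) * px_axial)

    def fallback():
        # no usable flank: take the widest gap per column
        for j in zone:
            if gap_candidates[j]:
                endo_rows[j] = max(gap_candidates[j],
                                   key=lambda c: c[2])[1]
                resolved[j] = True
        return endo_rows, resolved, z_pred_rows

    if len(sup_x) < 10:
        return fallback()

    edge_dist = np.minimum(np.abs(x - x_lo), np.abs(x - x_hi))
    max_dist = edge_dist[zone].max()
    reach = grow_mm
    pending = set(zone.tolist())
    while True:
        try:
            (cx, cz), r, _ = fit_circle(np.column_stack([sup_x, sup_z]))
        except (CollinearPointsError, np.linalg.LinAlgError):
            return fallback()
        frontier = [j for j in pending if edge_dist[j] <= reach]
        for j in frontier:
            d2 = r ** 2 - (x[j] - cx) ** 2
            if d2 <= 0:
                pending.discard(j)
                continue
            z_pred = cz - np.sqrt(d2)
            z_pred_rows[j] = z_pred / px_axial - 0.5
            best, best_d = None, tol_mm
            for center, above, width in gap_candidates[j]:
                d = abs((center + 0.5) * px_axial - z_pred)
                if d <= best_d:
                    best, best_d = (center, above), d
            if best is not None:
                endo_rows[j] = best[1]
                resolved[j] = True
                sup_x.append(x[j])
                sup_z.append((best[0] + 0.5) * px_axial)
            pending.discard(j)
        if reach >= max_dist and not frontier:
            break
        reach += grow_mm
    return endo_rows, resolved, z_pred_rows


def trace_boundaries(mask: BinaryMask, roi_hints=None, *,
                     min_run_px: int = 3, max_seam_gap_px: int = 12,
                     max_discontinuity_cols: int = 10,
                     min_band_span: float = 0.6,
                     smooth_window: int = None,
                     subpixel_window: int = None,
                     cleft_tolerance_mm: float = 0.15,
                     despeckle: bool = True) -> BoundarySet:
    """Trace tissue boundaries from a binary mask, column by column.

    Per column the corneal complex is anchored on the longest tissue run
    and absorbs neighbouring runs across gaps no wider than
    ``max_seam_gap_px`` (the dark host/graft interface cleft).  The
    epithelium is the first tissue pixel of the complex and the graft
    posterior the last; the first run below a wider gap is the iris.
    Within the graft zone (``roi_hints = (x_left, x_right)`` mm when
    supplied, else the columns where a cleft was found), the host
    posterior surface (endothelium) is the run bottom just above the
    cleft; when a column offers several gap candidates, the one closest
    to a circle extrapolated from the endothelium flanking the zone wins,
    within ``cleft_tolerance_mm``.  Columns whose cleft is unresolved are
    omitted from the endothelium rather than filled with the graft
    posterior.  Boundaries are smoothed with a moving median plus a
    step-preserving Savitzky-Golay pass and returned in physical mm.
    """
    # noise-adaptive smoothing: speckled masks need wide windows to tame
    # boundary jitter, clean masks only need the quantisation staircase
    # removed (wide windows would clip sharp corners unnecessarily)
    flag = getattr(mask, "meta", {}).get("despeckled")
    if flag is None:
        # estimate noisiness from the mask itself: fraction of pixels a
        # 3x3 majority vote would flip
        flip = float(np.mean(mask.values != median_filter(
            mask.values, size=(3, 3), mode="nearest")))
        speckled = flip > 0.01
    else:
        speckled = bool(flag)
    if smooth_window is None:
        smooth_window = 9 if speckled else 5
    if subpixel_window is None:
        subpixel_window = 31 if speckled else 11
    values = mask.values
    if despeckle and speckled:
        # a 3x3 majority-vote pass knits residual speckle holes inside
        # tissue, then connected-component filtering drops isolated bright
        # speckle in open space and fills enclosed dark pockets; the
        # host/graft interface cleft survives both (it opens into the
        # anterior chamber at the graft edge, so it is not an enclosed hole)
        values = median_filter(values, size=(3, 3), mode="nearest")
        cleaned = remove_small_objects(values.astype(bool), max_size=50)
        values = remove_small_holes(cleaned, max_size=50).astype(np.uint8)
    H, W = values.shape
    epith = np.full(W, np.nan)
    complex_bottom = np.full(W, np.nan)
    iris = np.full(W, np.nan)
    gap_candidates = [[] for _ in range(W)]  # (gap_center_row, run_above_bottom)

    for j in range(W):
        runs = [r for r in _column_runs(values[:, j]) if r[1] - r[0] + 1 >= min_run_px]
        if not runs:
            continue
        # anchor the corneal complex on the longest run (robust to isolated
        # bright speckle above the cornea), then absorb neighbouring runs
        # across gaps no wider than the interface cleft
        anchor = int(np.argmax([r[1] - r[0] for r in runs]))
        lo = hi = anchor
        while lo > 0 and runs[lo][0] - runs[lo - 1][1] - 1 <= max_seam_gap_px:
            lo -= 1
        while hi < len(runs) - 1 and runs[hi + 1][0] - runs[hi][1] - 1 <= max_seam_gap_px:
            hi += 1
        band = runs[lo:hi + 1]
        epith[j] = band[0][0]
        complex_bottom[j] = band[-1][1]
        for a, b in zip(band[:-1], band[1:]):
            gap_candidates[j].append(((a[1] + b[0]) / 2.0, a[1], b[0] - a[1] - 1))
        if hi < len(runs) - 1:
            iris[j] = runs[hi + 1][0]

    present = np.isfinite(epith)
    if present.sum() < min_band_span * W:
        raise SegmentationError(
            f"tissue band spans {present.sum()}/{W} columns (< {min_band_span:.0%})")
    span = np.where(present)[0]
    gaps = np.diff(span) - 1
    if gaps.size and gaps.max() > max_discontinuity_cols:
        raise SegmentationError(
            f"band discontinuity of {gaps.max()} columns exceeds {max_discontinuity_cols}")

    x = (np.arange(W) + 0.5) * mask.px_size_lateral - W * mask.px_size_lateral / 2
    has_candidate = np.array([len(c) > 0 for c in gap_candidates])

    # graft zone: landmark-supplied lateral range when given, else the
    # columns where a cleft-separated second run was found
    if roi_hints is not None:
        x_left, x_right = roi_hints
        graft_zone = present & (x >= x_left) & (x <= x_right)
    else:
        graft_zone = present & has_candidate

    endo = np.where(present, complex_bottom, np.nan)
    has_second = np.zeros(W, dtype=bool)
    if graft_zone.any():
        cleft_rows, resolved, z_pred = _select_cleft(
            x, complex_bottom, gap_candidates, graft_zone, present,
            mask.px_size_axial, tol_mm=cleft_tolerance_mm)
        endo[graft_zone] = cleft_rows[graft_zone]
        has_second = resolved
        frac = resolved[graft_zone].mean()
        if frac < 0.4:
            raise SegmentationError(
                f"host/graft interface resolved in only {frac:.0%} of the graft zone")
        sel = graft_zone & resolved
        if sel.sum() >= 10:
            from .core import CollinearPointsError
            from .morphometry import fit_circle
            pts = np.column_stack([x[sel], (endo[sel] + 0.5) * mask.px_size_axial])
            try:
                _, _, rms = fit_circle(pts)
            except (CollinearPointsError, np.linalg.LinAlgError):
                rms = np.inf
            if rms > 0.06:
                raise SegmentationError(
                    f"host/graft interface selection inconsistent (rms {rms:.3f} mm)")
        # slab dropout: inside the zone, a column whose band bottom sits on
        # the host-posterior circle with no resolved cleft lost its graft
        # slab below threshold; excise it and interpolate from neighbours
        dropout = graft_zone & ~resolved & np.isfinite(z_pred) & \
            (complex_bottom - z_pred < 4)
        complex_bottom[dropout] = np.nan
        # and a band bottom much further below the host surface than any
        # graft is thick has chained into the iris through speckle bridges
        too_deep = graft_zone & np.isfinite(z_pred) & \
            (complex_bottom - z_pred > 1.5 / mask.px_size_axial)
        complex_bottom[too_deep] = np.nan
        # partial dropouts: the band bottom locally jumps up against its
        # own running median when the slab's lower half fades; the graft
        # edge dips DOWN, so upward outliers are safe to excise
        inz = np.where(graft_zone & np.isfinite(complex_bottom))[0]
        if inz.size > 40:
            trend = median_filter(complex_bottom[inz], size=31, mode="nearest")
            complex_bottom[inz[complex_bottom[inz] - trend < -8]] = np.nan

    epith = _smooth_moving_median(_fill_small_gaps(epith), smooth_window,
                                  subpixel_window)
    endo_s = _smooth_moving_median(_fill_small_gaps(endo), smooth_window,
                                   subpixel_window)
    # the endothelium spans the steep peri-spur flanks where threshold
    # noise is amplified by the surface slope; one more low-pass over the
    # joined series keeps the spur-to-spur arc length from inflating
    fin = np.where(np.isfinite(endo_s))[0]
    if fin.size >= 5:
        endo_s[fin] = _lowpass_linear_padded(endo_s[fin], subpixel_window / 5.0)
    complex_bottom = _smooth_moving_median(_fill_small_gaps(complex_bottom),
                                           smooth_window, subpixel_window)
    iris = _smooth_moving_median(iris, smooth_window, subpixel_window)
    # the graft posterior cannot physically lie above the host posterior
    # surface; interpolation across excised dropouts may locally cross it,
    # so clamp rather than fail
    both = np.isfinite(endo_s) & np.isfinite(complex_bottom)
    complex_bottom[both] = np.maximum(complex_bottom[both], endo_s[both])
    # a filled column counts as resolved: its value is interpolated from
    # resolved neighbours on the same smooth surface
    endo_cols = present & (~graft_zone | np.isfinite(endo_s))

    def to_poly(rows, keep):
        keep = keep & np.isfinite(rows)
        return np.column_stack([x[keep], (rows[keep] + 0.5) * mask.px_size_axial])

    bset = BoundarySet(
        epithelium=to_poly(epith, present),
        endothelium=to_poly(endo_s, endo_cols),
        graft_anterior_interface=to_poly(endo_s, graft_zone & np.isfinite(endo_s)),
        graft_posterior=to_poly(complex_bottom, graft_zone),
        iris_anterior=to_poly(iris, np.isfinite(iris)),
    )
    return bset.validate(atol=3 * mask.px_size_axial)


def qc_gate(img: OCTImage, boundaries=None, landmarks: LandmarkSet = None, *,
            contrast_floor: float = DEFAULT_CONTRAST_FLOOR) -> QCResult:
    """Inclusion gate; never raises.

    An eye is included iff both scleral spurs were identified, the image
    has usable contrast (95th-5th intensity percentile above the floor)
    and binarisation/tracing succeeded.  ``boundaries`` may be a
    BoundarySet, an exception instance, or None.
    """
    if landmarks is None or not landmarks.has_spurs:
        return QCResult(False, "spur_not_identifiable")
    p5, p95 = np.percentile(img.intensities, [5, 95])
    if p95 - p5 <= contrast_floor:
        return QCResult(False, "low_contrast")
    if boundaries is None or isinstance(boundaries, LowContrastError):
        return QCResult(False, "low_contrast")
    if isinstance(boundaries, Exception):
        return QCResult(False, "segmentation_failed")
    return QCResult(True, "ok")


def segment_image(img: OCTImage, landmarks: LandmarkSet = None, *,
                  indices=(1.0, 1.388, 1.343), do_dewarp: bool = None,
                  roi_hints=None, contrast_floor: float = DEFAULT_CONTRAST_FLOOR):
    """Full chain: condition, (dewarp), binarise, trace, QC.

    ``do_dewarp`` defaults to dewarping exactly when the image is not
    already flagged as dewarped.  Returns ``(BoundarySet | None, QCResult,
    OCTImage)`` where the image is the final conditioned (and possibly
    dewarped) scan the boundaries refer to.
    """
    if do_dewarp is None:
        do_dewarp = not img.dewarped
    work = despeckle_image(condition_image(img))
    result = None
    try:
        if do_dewarp:
            mask = binarize(work)
            pre = trace_boundaries(mask, roi_hints=roi_hints)
            # outer tissue envelope = cornea-aqueous interface for dewarping
            outer = pre.graft_posterior if len(pre.graft_posterior) else pre.endothelium
            lo = np.interp(pre.endothelium[:, 0], outer[:, 0], outer[:, 1],
                           left=np.nan, right=np.nan)
            comp = np.where(np.isfinite(lo), np.maximum(pre.endothelium[:, 1], lo),
                            pre.endothelium[:, 1])
            interface2 = np.column_stack([pre.endothelium[:, 0], comp])
            work = dewarp(work, (pre.epithelium, interface2), indices)
        mask = binarize(work)
        result = trace_boundaries(mask, roi_hints=roi_hints)
    except (LowContrastError, SegmentationError) as exc:
        result = exc
    qc = qc_gate(work, result, landmarks, contrast_floor=contrast_floor)
    return (result if qc.included else None), qc, work
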