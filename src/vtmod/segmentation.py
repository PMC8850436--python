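"""Semi-automatic vocal-tract segmentation from real-time MRI frames.

The pipeline mirrors a spatially constrained tissue-classification
approach: every frame is rigidly registered to a reference image using
only static structures (skull, vertebrae), the vocal tract is localized
as the region of high temporal intensity variance (air/tissue
alternation), air and soft tissue are separated by a between-class
variance threshold within that region, and the air boundary is traced to
a sub-pixel outline.  Manual trace correction is replaced by a
programmatic point-edit hook.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage, optimize
from shapely.geometry import LineString, Polygon
from skimage import measure

from .core import (
    EstimationError,
    ExtractionError,
    ImageFrame,
    ImageSeries,
    PixelMask,
    RigidTransform,
    VTOutline,
    ensure_ccw,
)

ROTATION_BOUND_DEG = 10.0
TRANSLATION_BOUND_MM = 20.0
DEFAULT_VARIANCE_QUANTILE = 0.85


def _resample(frame: ImageFrame, t: RigidTransform) -> tuple[np.ndarray, np.ndarray]:
    """Resample the frame so its content moves by ``t`` (bilinear).

    Output pixel p takes the input value at t^-1(p); rotation pivots at
    the image centre.  Returns the image and a validity weight map (1
    inside the source field of view).
    """
    nr, nc = frame.shape
    px = frame.pixel_size_mm
    cy = (nr - 1) / 2.0
    cx = (nc - 1) / 2.0
    rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    th = math.radians(t.rotation_deg)
    cos, sin = math.cos(th), math.sin(th)
    # inverse transform in pixel units
    x = cc - cx - t.translation_mm[0] / px
    y = rr - cy - t.translation_mm[1] / px
    xs = cos * x + sin * y + cx
    ys = -sin * x + cos * y + cy
    out = ndimage.map_coordinates(frame.intensities, [ys, xs], order=1, cval=0.0)
    valid = ndimage.map_coordinates(
        np.ones(frame.shape), [ys, xs], order=1, cval=0.0
    )
    return out, valid


def apply_transform(frame: ImageFrame, t: RigidTransform) -> ImageFrame:
    """Rigidly move the frame content; out-of-field pixels are set to 0."""
    out, _ = _resample(frame, t)
    return ImageFrame(
        out,
        frame.pixel_size_mm,
        frame_index=frame.frame_index,
        speaker_id=frame.speaker_id,
        word=frame.word,
        vt_condition=frame.vt_condition,
    )


def _masked_ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    av = a[mask]
    bv = b[mask]
    av = av - av.mean()
    bv = bv - bv.mean()
    na = np.linalg.norm(av)
    nb = np.linalg.norm(bv)
    if na == 0 or nb == 0:
        return -1.0
    return float(av @ bv) / (na * nb)


def estimate_rigid_transform(
    frame: ImageFrame,
    reference: ImageFrame,
    static_mask: PixelMask,
    rotation_bound_deg: float = ROTATION_BOUND_DEG,
    translation_bound_mm: float = TRANSLATION_BOUND_MM,
) -> RigidTransform:
    """Rigid transform aligning ``frame`` to ``reference``.

    The similarity metric is normalized cross-correlation restricted to
    the static-structure mask, so that labile vocal-tract changes cannot
    bias the estimate.  A coarse rotation/translation grid seeds a local
    Powell refinement; the search is bounded to +/-10 deg and +/-20 mm.
    """
    if frame.shape != reference.shape or static_mask.shape != frame.shape:
        raise ValueError("frame, reference and static mask must share one shape")
    mask = static_mask.mask
    ref = reference.intensities
    if mask.sum() < 10 or np.ptp(ref[mask]) == 0:
        raise EstimationError("static-structure region is empty or flat")

    def objective(p: np.ndarray) -> float:
        rot, tx, ty = p
        if abs(rot) > rotation_bound_deg or max(abs(tx), abs(ty)) > translation_bound_mm:
            return 1.0 + abs(rot) + abs(tx) + abs(ty)  # soft wall outside bounds
        moved, valid = _resample(frame, RigidTransform(rot, (tx, ty)))
        m = mask & (valid > 0.99)
        if m.sum() < 10:
            return 2.0
        return -_masked_ncc(moved, ref, m)

    coarse = [
        (rot, tx, ty)
        for rot in np.linspace(-9.0, 9.0, 13)
        for tx in (-10.0, 0.0, 10.0)
        for ty in (-10.0, 0.0, 10.0)
    ]
    scored = sorted(coarse, key=lambda p: objective(np.array(p)))
    best = None
    for start in scored[:2]:
        res = optimize.minimize(
            objective,
            np.array(start),
            method="Powell",
            options={"xtol": 1e-4, "ftol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
    rot, tx, ty = best.x
    return RigidTransform(float(rot), (float(tx), float(ty)))


def high_variance_mask(
    series: ImageSeries,
    quantile: float = DEFAULT_VARIANCE_QUANTILE,
    straddle_margin: float = 0.1,
) -> PixelMask:
    """Vocal-tract candidate pixels from temporal intensity alternation.

    A vocal-tract pixel alternates between low intensity (air) and high
    intensity (soft tissue).  Pixels qualify when (i) their temporal
    variance strictly exceeds the given quantile of the per-pixel
    variance distribution and (ii) their temporal min/max straddle the
    global air-tissue intensity threshold by ``straddle_margin`` of the
    intensity range — criterion (ii) rejects thermal noise and sub-pixel
    registration jitter at static edges, which never cross the contrast
    gap.  A morphological closing (4 px radius) then bridges quiescent
    stretches of the boundary, components touching the image border are
    discarded (out-of-field artifacts of registration), and the largest
    connected component is selected.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 frames to compute temporal variance")
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    arr = series.as_array()
    var = arr.var(axis=0)
    thr = float(np.quantile(var, quantile))
    raw = var > thr
    if raw.any() and np.ptp(arr) > 0:
        t_global = _exact_otsu(arr[:: max(len(arr) // 8, 1)].ravel())
        margin = straddle_margin * float(
            np.percentile(arr, 99) - np.percentile(arr, 1)
        )
        alternating = (arr.min(axis=0) < t_global - margin) & (
            arr.max(axis=0) > t_global + margin
        )
        raw = raw & alternating
    closed = ndimage.binary_closing(raw, structure=np.ones((9, 9)))
    border = np.zeros_like(closed)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    lab0, _ = ndimage.label(closed, structure=np.ones((3, 3)))
    for lbl in np.unique(lab0[border & closed]):
        if lbl:
            closed[lab0 == lbl] = False
    lab, n = ndimage.label(closed, structure=np.ones((3, 3)))
    if n == 0:
        return PixelMask(np.zeros_like(raw), kind="labile_candidates")
    sizes = ndimage.sum(closed, lab, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    return PixelMask(lab == keep, kind="labile_candidates")


def refine_candidates(
    mask: PixelMask, close_px: int = 2, dilate_px: int = 1, fill_holes: bool = True
) -> PixelMask:
    """Turn the high-variance estimate into a solid vocal-tract candidate
    region (the programmatic stand-in for the analyst's manual mask
    adjustment): morphological closing, hole filling, then a small
    dilation.  Pixels that are air in every frame have no temporal
    variance, so hole filling is what brings the channel core into the
    candidate set."""
    m = mask.mask
    if close_px > 0:
        m = ndimage.binary_closing(m, structure=np.ones((2 * close_px + 1,) * 2))
    if fill_holes:
        m = ndimage.binary_fill_holes(m)
    if dilate_px > 0:
        m = ndimage.binary_dilation(m, iterations=dilate_px)
    return PixelMask(m, kind="labile_candidates")


def _exact_otsu(values: np.ndarray) -> float:
    """Between-class variance maximizing threshold on the raw sample values.

    Scans every split between consecutive sorted values, so the result is
    exactly symmetric under intensity negation.
    """
    v = np.sort(values.astype(float))
    n = len(v)
    csum = np.cumsum(v)
    total = csum[-1]
    k = np.arange(1, n)  # split after the k-th smallest value
    mu0 = csum[:-1] / k
    mu1 = (total - csum[:-1]) / (n - k)
    w = k * (n - k) / n**2
    between = w * (mu1 - mu0) ** 2
    distinct = v[1:] > v[:-1]
    if not distinct.any():
        return float(v[0])
    between = np.where(distinct, between, -np.inf)
    kbest = int(np.argmax(between))
    return float(0.5 * (v[kbest] + v[kbest + 1]))


def classify_tissue(
    frame: ImageFrame, candidates: PixelMask, min_effectiveness: float = 0.75
) -> PixelMask:
    """Threshold the candidate region into air (dark) and tissue (bright).

    The threshold maximizes the between-class variance of the candidate
    intensities.  Contrast is judged by the effectiveness coefficient
    (between-class variance / total variance, 1 for two well-separated
    classes, ~0.64 for a unimodal normal); below ``min_effectiveness``
    the output carries a low-contrast warning flag.
    """
    if candidates.count() == 0:
        raise ValueError("candidate mask is empty")
    vals = frame.intensities[candidates.mask]
    thr = _exact_otsu(vals)
    tissue = candidates.mask & (frame.intensities > thr)
    air_vals = vals[vals <= thr]
    tis_vals = vals[vals > thr]
    total_var = vals.var()
    if len(air_vals) == 0 or len(tis_vals) == 0 or total_var == 0:
        low = True
    else:
        w0 = len(air_vals) / len(vals)
        between = w0 * (1 - w0) * (tis_vals.mean() - air_vals.mean()) ** 2
        low = between / total_var < min_effectiveness
    return PixelMask(tissue, kind="tissue", low_contrast=bool(low))


def _largest_air_component(tissue: PixelMask, candidates: PixelMask) -> np.ndarray:
    air = candidates.mask & ~tissue.mask
    lab, n = ndimage.label(air, structure=np.ones((3, 3)))
    if n == 0:
        raise ExtractionError("no air component inside the candidate region")
    sizes = ndimage.sum(air, lab, index=np.arange(1, n + 1))
    return lab == (int(np.argmax(sizes)) + 1)


def extract_outline(
    tissue: PixelMask,
    candidates: PixelMask,
    frame_index: int = 0,
    pixel_size_mm: float = 2.5,
    frame: ImageFrame | None = None,
    smoothing_sigma: float = 0.8,
) -> VTOutline:
    """Sub-pixel outline of the largest air component inside the candidates.

    The air region is the candidate area classified as non-tissue; its
    largest connected component's boundary is traced at the air/tissue
    class boundary, ordered counter-clockwise and converted to mm.
    Smaller air components (classification artifacts) are ignored.

    When the intensity ``frame`` is supplied, the boundary is the
    marching-squares level set of the intensities at the class threshold
    (sub-pixel by construction, since rendered and resampled edges are
    smooth ramps).  Without it, the binary component map is Gaussian
    smoothed (``smoothing_sigma`` px) and traced at the 0.5 level, which
    removes the staircase at the cost of slight corner rounding.
    """
    main = _largest_air_component(tissue, candidates)
    if frame is not None:
        xy = _trace_intensity_level_set(frame, candidates, main)
    else:
        padded = ndimage.gaussian_filter(
            np.pad(main.astype(float), 2), smoothing_sigma
        )
        contours = measure.find_contours(padded, 0.5)
        if not contours:
            raise ExtractionError("air component has no traceable boundary")
        boundary = max(contours, key=len)
        rc = boundary[:-1] if np.allclose(boundary[0], boundary[-1]) else boundary
        xy = np.column_stack([rc[:, 1] - 2.0, rc[:, 0] - 2.0])
    xy = ensure_ccw(xy * pixel_size_mm)
    if len(xy) < 20:
        raise ExtractionError("air boundary has fewer than 20 points")
    return VTOutline(xy, closed=True, frame_index=frame_index)


def _trace_intensity_level_set(
    frame: ImageFrame, candidates: PixelMask, main_air: np.ndarray
) -> np.ndarray:
    """Boundary of the main air component as an intensity iso-contour at
    the between-class threshold; returned in pixel units."""
    from shapely.geometry import Point, Polygon

    vals = frame.intensities[candidates.mask]
    thr = _exact_otsu(vals)
    img = frame.intensities.copy()
    img[~candidates.mask] = vals.max()  # close the level set at the mask border
    contours = measure.find_contours(
        np.pad(img, 1, constant_values=float(vals.max())), thr
    )
    # an interior point of the (C-shaped) component: the deepest pixel
    dt = ndimage.distance_transform_edt(main_air)
    ry, rx = np.unravel_index(int(np.argmax(dt)), dt.shape)
    best = None
    for c in contours:
        rc = c[:-1] if np.allclose(c[0], c[-1]) else c
        poly = Polygon(np.column_stack([rc[:, 1] - 1.0, rc[:, 0] - 1.0]))
        if poly.is_valid and poly.contains(Point(rx, ry)):
            if best is None or len(rc) > len(best):
                best = rc
    if best is None:
        raise ExtractionError("air component has no traceable boundary")
    return np.column_stack([best[:, 1] - 1.0, best[:, 0] - 1.0])


def correct_outline(
    outline: VTOutline, edits: Sequence[tuple[int, tuple[float, float]]]
) -> VTOutline:
    """Apply ordered point replacements (the programmatic stand-in for
    manual trace correction); edits that break simplicity are rejected."""
    pts = outline.points.copy()
    for idx, new_pt in edits:
        if not -len(pts) <= idx < len(pts):
            raise IndexError(f"edit index {idx} out of range for {len(pts)} points")
        pts[idx] = new_pt
    fixed = VTOutline(pts, closed=outline.closed, frame_index=outline.frame_index)
    if edits and not fixed.is_simple():
        raise ValueError("edit would make the outline self-intersecting; rejected")
    return fixed


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """2|A n B| / (|A| + |B|) for boolean masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom


def outline_hausdorff_mm(a: VTOutline, b: VTOutline, densify: float = 0.05) -> float:
    """Symmetric (discrete, densified) Hausdorff distance in mm."""
    import shapely

    ga = LineString(np.vstack([a.points, a.points[:1]]) if a.closed else a.points)
    gb = LineString(np.vstack([b.points, b.points[:1]]) if b.closed else b.points)
    return float(shapely.hausdorff_distance(ga, gb, densify=densify))


@dataclass
class SegmentationResult:
    """Registered series, masks, and per-frame outlines."""

    transforms: list[RigidTransform]
    registered: ImageSeries
    candidates: PixelMask
    outlines: list[VTOutline]
    tissue_masks: list[PixelMask]
    air_masks: list[np.ndarray]


def segment_series(
    series: ImageSeries,
    reference: ImageFrame,
    static_mask: PixelMask,
    variance_quantile: float = DEFAULT_VARIANCE_QUANTILE,
) -> SegmentationResult:
    """Full per-series pipeline: register, localize, classify, trace."""
    transforms = [
        estimate_rigid_transform(f, reference, static_mask) for f in series
    ]
    registered = ImageSeries(
        [apply_transform(f, t) for f, t in zip(series, transforms)]
    )
    candidates = refine_candidates(high_variance_mask(registered, variance_quantile))
    outlines: list[VTOutline] = []
    tissue_masks: list[PixelMask] = []
    air_masks: list[np.ndarray] = []
    for f in registered:
        tissue = classify_tissue(f, candidates)
        tissue_masks.append(tissue)
        air = candidates.mask & ~tissue.mask
        lab, n = ndimage.label(air, structure=np.ones((3, 3)))
        if n:
            sizes = ndimage.sum(air, lab, index=np.arange(1, n + 1))
            air = lab == (int(np.argmax(sizes)) + 1)
        air_masks.append(air)
        outlines.append(
            extract_outline(
                tissue,
                candidates,
                frame_index=f.frame_index,
                pixel_size_mm=f.pixel_size_mm,
                frame=f,
            )
        )
    return SegmentationResult(
        transforms=transforms,
        registered=registered,
        candidates=candidates,
        outlines=outlines,
        tissue_masks=tissue_masks,
        air_masks=air_masks,
    )
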