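"""Membrane-marker-driven myofibre segmentation.

The pipeline mirrors how whole-section analysis proceeds on real scans:

1. ``detect_tissue`` — find the section footprint in the membrane channel.
2. ``extract_candidates`` — ridge-enhance the membrane staining, binarise the
   rim network, close small interruptions, and take the connected components
   of (tissue minus network) as fibre candidates.
3. ``rim_completeness`` — measure, for every candidate, the fraction of its
   boundary arc supported by membrane signal within a perpendicular band.
4. ``filter_fibre_characteristics`` — reject structures without fibre
   characteristics (blood cells, vessel lumina, nerve profiles, connective
   expanses, folds, border-touching objects).
5. ``apply_gap_rule`` — reconstruct rims interrupted on less than the
   exclusion fraction (default 20%) of the perimeter; reject fibres missing
   at least that fraction, on the reading that such fibres are severely
   damaged or degenerating.
6. ``finalize_labels`` — relabel accepted fibres 1..N in raster order,
   snapping each interior outward onto the rim centreline.

Either spectrin or laminin staining may serve as the membrane channel; the
logic is identical.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import gaussian, sato, threshold_local, threshold_otsu
from skimage.measure import find_contours, label as cc_label, regionprops
from skimage.morphology import closing as morph_closing, disk, remove_small_objects
from skimage.restoration import estimate_sigma
from skimage.segmentation import expand_labels, watershed

from .geometry import resample_closed
from .io import SectionImage

log = logging.getLogger(__name__)

REJECTION_REASONS = (
    "none",
    "gap_gt_threshold",
    "too_small",
    "too_large",
    "low_solidity",
    "border",
    "interior_bright",
    "distractor_shape",
)


@dataclass
class SegmentationParams:
    """Tunable parameters of the fibre-recognition pipeline.

    ``gap_exclusion_fraction`` implements the rim-disruption rule: a fibre
    missing at least this fraction of its rim is excluded (the boundary case
    of exactly the threshold is rejected, giving a total ordering).
    All physical parameters are micrometres.
    """

    gap_exclusion_fraction: float = 0.20
    rim_band_um: float = 1.0  # outward reach of the perpendicular rim-support search
    min_area_um2: float = 200.0
    max_area_um2: float = 15000.0
    min_solidity: float = 0.80
    border_policy: str = "exclude_touching"
    threshold_method: str = "local"  # "local" (tile-based, global floor) or "global"
    threshold_offset: float = 0.0  # additive offset on the rim-network threshold
    threshold_block_um: float = 120.0  # tile size of the local threshold
    ridge_scale_um: float = 1.0  # ridge-filter scale ~ rim width
    closing_radius_um: float = 1.0  # morphological closure of the rim network
    boundary_snap_um: float = 1.2  # outward snap of interiors onto the rim centreline
    tissue_smooth_um: float = 1.0
    tissue_intensity_fraction: float = 0.15  # x rim level: tissue threshold
    tissue_erosion_um: float = 1.5  # retracts the smoothing glow past the rims
    boundary_smooth_um: float = 0.0  # optional opening radius before boundary tracing
    support_threshold_fraction: float = 0.5  # x rim level: boundary-support test
    fold_intensity_fraction: float = 0.6  # x rim level: bright-interior rejection
    min_interior_fraction: float = 0.10  # x rim level: empty-space rejection
    watershed_min_distance_um: float = 8.0

    def validate(self) -> None:
        if not 0 < self.gap_exclusion_fraction < 1:
            raise ValueError("gap_exclusion_fraction must be in (0, 1)")
        if self.min_area_um2 >= self.max_area_um2:
            raise ValueError("min_area_um2 must be below max_area_um2")
        if self.border_policy != "exclude_touching":
            raise ValueError(f"unknown border_policy {self.border_policy!r}")
        if self.threshold_method not in ("local", "global"):
            raise ValueError(f"unknown threshold method {self.threshold_method!r}")


@dataclass
class FibreCandidate:
    """One connected component proposed as a myofibre."""

    id: int
    bbox: tuple[slice, slice]
    mask: np.ndarray  # bool, within bbox
    boundary: np.ndarray  # (n, 2) closed polyline, full-image (row, col)
    area_px: int
    area_um2: float
    solidity: float
    centroid: tuple[float, float]
    touches_border: bool
    rim_completeness: float | None = None
    rejection_reason: str = "none"

    @property
    def accepted(self) -> bool:
        return self.rejection_reason == "none"


@dataclass
class FibreLabelMap:
    """Accepted-fibre label image plus the full candidate audit trail."""

    labels: np.ndarray  # int, 0 = background, 1..N accepted interiors
    candidates: list[FibreCandidate]

    @property
    def n_fibres(self) -> int:
        return int(self.labels.max())

    def audit_frame(self) -> pd.DataFrame:
        rows = [
            {
                "candidate_id": c.id,
                "centroid_row": c.centroid[0],
                "centroid_col": c.centroid[1],
                "area_um2": c.area_um2,
                "solidity": c.solidity,
                "rim_completeness": c.rim_completeness,
                "rejection_reason": c.rejection_reason,
            }
            for c in self.candidates
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "candidate_id",
                "centroid_row",
                "centroid_col",
                "area_um2",
                "solidity",
                "rim_completeness",
                "rejection_reason",
            ],
        )


@dataclass
class SegmentationResult:
    label_map: FibreLabelMap
    tissue_mask: np.ndarray
    rim_network: np.ndarray
    rim_level: float
    params: SegmentationParams

    @property
    def labels(self) -> np.ndarray:
        return self.label_map.labels


def _odd(n: int) -> int:
    return n if n % 2 else n + 1


def ridge_image(section: SectionImage, params: SegmentationParams | None = None) -> np.ndarray:
    """Ridge-enhanced membrane channel (tubular-structure response).

    Thin bright rims respond strongly; broad bright plateaus (folded tissue)
    and flat cytoplasm do not.  This is the expensive filter of the pipeline,
    so callers that need it twice compute it once and pass it along.
    """
    params = params or SegmentationParams()
    img = section.membrane.astype(float)
    return sato(
        img,
        sigmas=[params.ridge_scale_um / section.pixel_size_um],
        black_ridges=False,
        mode="reflect",
    )


def detect_tissue(
    section: SectionImage,
    params: SegmentationParams | None = None,
    ridge: np.ndarray | None = None,
) -> np.ndarray:
    """Binary mask of the section footprint.

    The threshold is anchored on the rim brightness rather than on the image
    histogram: tissue = pixels whose smoothed membrane intensity exceeds
    ``tissue_intensity_fraction`` of the median rim level, unioned with the
    rim network itself, holes filled (fibre interiors enclosed by their
    rims), then eroded by ``tissue_erosion_um`` to retract the smoothing glow
    around the outermost rims.  Anchoring on the rims keeps the mask correct
    whether background fills most of the frame or none of it.  A frame whose
    intensity histogram is a single noise mode yields an empty mask.
    """
    params = params or SegmentationParams()
    px = section.pixel_size_um
    img = section.membrane.astype(float)
    sm = gaussian(img, sigma=params.tissue_smooth_um / px, preserve_range=True)

    def _empty() -> np.ndarray:
        warnings.warn("empty tissue mask: no tissue detected in the image")
        return np.zeros(sm.shape, dtype=bool)

    if sm.max() <= sm.min():
        return _empty()
    # background-only guard: a genuine structure/background split separates
    # the Otsu classes by much more than the noise floor; on a blank frame
    # Otsu merely splits the noise distribution in half
    thr0 = threshold_otsu(sm)
    above, below = sm[sm > thr0], sm[sm <= thr0]
    if len(above) == 0 or len(below) == 0:
        return _empty()
    noise_sd = estimate_sigma(img)
    if above.mean() - below.mean() < max(2.0 * noise_sd, 1e-9):
        return _empty()

    net, rim_level = rim_network(section, None, params, ridge=ridge)
    if rim_level <= 0:
        return _empty()
    thr = params.tissue_intensity_fraction * rim_level
    mask = (sm > thr) | net
    mask = ndimage.binary_fill_holes(mask)
    ero_px = int(round(params.tissue_erosion_um / px))
    if ero_px > 0:
        mask = ndimage.binary_erosion(mask, structure=disk(ero_px))
    min_px = max(int(params.min_area_um2 / px**2), 1)
    mask = remove_small_objects(mask, max_size=min_px - 1)
    if not mask.any():
        warnings.warn("empty tissue mask: no tissue detected in the image")
    return mask


def rim_network(
    section: SectionImage,
    tissue_mask: np.ndarray | None = None,
    params: SegmentationParams | None = None,
    ridge: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Binarised membrane rim network and the estimated rim intensity level.

    The membrane channel is ridge-enhanced at ``ridge_scale_um`` (tubular
    structures respond; broad bright plateaus such as folded tissue do not),
    then thresholded either globally (Otsu) or tile-locally with a global
    floor at half the Otsu value, plus ``threshold_offset``.  With no tissue
    mask the whole frame is used.
    """
    params = params or SegmentationParams()
    px = section.pixel_size_um
    if ridge is None:
        ridge = ridge_image(section, params)
    region = tissue_mask if tissue_mask is not None else np.ones(ridge.shape, dtype=bool)
    vals = ridge[region]
    if vals.size == 0 or vals.max() <= vals.min():
        return np.zeros(ridge.shape, dtype=bool), 0.0
    floor = threshold_otsu(vals)
    if params.threshold_method == "global":
        net = ridge > (floor + params.threshold_offset)
    else:
        block = _odd(max(int(params.threshold_block_um / px), 3))
        local = threshold_local(ridge, block_size=block, method="gaussian")
        net = ridge > np.maximum(local + params.threshold_offset, 0.5 * floor)
    net &= region
    raw_on_net = section.membrane[net]
    rim_level = float(np.median(raw_on_net)) if raw_on_net.size else 0.0
    return net, rim_level


def _split_component(
    mask: np.ndarray, min_distance_px: int
) -> np.ndarray:
    """Watershed split of an oversized component on its distance transform.

    Returns an int label image over the mask (1..k).  If fewer than two
    distance maxima exist the mask is returned as a single label.
    """
    dist = ndimage.distance_transform_edt(mask)
    peaks = peak_local_max(
        dist, min_distance=max(min_distance_px, 1), labels=mask, exclude_border=False
    )
    if len(peaks) < 2:
        return mask.astype(np.int32)
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    return watershed(-dist, markers=markers, mask=mask)


def _trace_boundary(
    mask: np.ndarray, origin: tuple[int, int], opening_px: int = 0
) -> np.ndarray | None:
    """Closed sub-pixel outline of a component mask (longest 0.5-contour).

    With ``opening_px`` > 0 the mask is morphologically opened first: thin
    protrusions (interstitial corridors entered through a rim gap) are shaved
    off, so the traced boundary follows the fibre's own edge across the gap
    instead of wandering along the neighbouring rim.
    """
    if opening_px > 0:
        opened = ndimage.binary_opening(np.pad(mask, opening_px), disk(opening_px))
        opened = opened[opening_px:-opening_px, opening_px:-opening_px]
        if opened.any():
            # keep the largest opened piece; fall back to the raw mask
            pieces = cc_label(opened, connectivity=1)
            if pieces.max() > 1:
                largest = np.argmax(np.bincount(pieces.ravel())[1:]) + 1
                opened = pieces == largest
            mask = opened
    padded = np.pad(mask, 1)
    contours = find_contours(padded.astype(float), 0.5)
    if not contours:
        return None
    contour = max(contours, key=len)
    contour = contour - 1.0 + np.asarray(origin, dtype=float)
    # find_contours closes the loop by repeating the first point
    if len(contour) > 1 and np.allclose(contour[0], contour[-1]):
        contour = contour[:-1]
    return contour


def extract_candidates(
    section: SectionImage,
    tissue_mask: np.ndarray,
    params: SegmentationParams | None = None,
    ridge: np.ndarray | None = None,
) -> tuple[list[FibreCandidate], np.ndarray, float]:
    """Fibre candidates from the rim-network complement.

    Returns ``(candidates, network, rim_level)``.  The network is closed
    morphologically before taking components, so that rim interruptions up to
    the reconstructable range do not leak an interior into the interstitial
    space; the intensity-based completeness measurement (not the closure)
    decides acceptance.  Components larger than the maximum fibre area are
    split by watershed when they contain several distance-transform maxima.
    """
    params = params or SegmentationParams()
    params.validate()
    px = section.pixel_size_um
    px2 = px * px
    if not tissue_mask.any():
        return [], np.zeros(section.shape, dtype=bool), 0.0
    net, rim_level = rim_network(section, tissue_mask, params, ridge=ridge)
    closing_px = max(int(round(params.closing_radius_um / px)), 1)
    closed = morph_closing(net, disk(closing_px))
    interior_space = tissue_mask & ~closed
    lbl = cc_label(interior_space, connectivity=1)

    max_area_px = params.max_area_um2 / px2
    min_dist_px = max(int(params.watershed_min_distance_um / px), 1)
    candidates: list[FibreCandidate] = []
    cid = 0
    h, w = lbl.shape
    for prop in regionprops(lbl):
        sl = prop.slice
        mask = lbl[sl] == prop.label
        parts = (
            _split_component(mask, min_dist_px)
            if prop.area > max_area_px
            else mask.astype(np.int32)
        )
        for part_label in range(1, int(parts.max()) + 1):
            pmask = parts == part_label
            area = int(pmask.sum())
            if area < 4:
                continue
            cid += 1
            origin = (sl[0].start, sl[1].start)
            opening_px = max(int(round(params.boundary_smooth_um / px)), 0)
            boundary = _trace_boundary(pmask, origin, opening_px)
            sub = regionprops(pmask.astype(np.uint8))[0]
            cr, cc = sub.centroid
            centroid = (cr + origin[0], cc + origin[1])
            rows = np.nonzero(pmask.any(axis=1))[0]
            cols = np.nonzero(pmask.any(axis=0))[0]
            bbox = (
                slice(origin[0] + rows[0], origin[0] + rows[-1] + 1),
                slice(origin[1] + cols[0], origin[1] + cols[-1] + 1),
            )
            # the tissue-mask erosion retracts cut fibres from the frame,
            # so "touching" allows that margin
            border_px = int(np.ceil(params.tissue_erosion_um / px)) + 1
            touches = (
                bbox[0].start <= border_px
                or bbox[1].start <= border_px
                or bbox[0].stop >= h - border_px
                or bbox[1].stop >= w - border_px
            )
            cand = FibreCandidate(
                id=cid,
                bbox=bbox,
                mask=pmask[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1],
                boundary=boundary if boundary is not None else np.empty((0, 2)),
                area_px=area,
                area_um2=area * px2,
                solidity=float(sub.solidity),
                centroid=centroid,
                touches_border=bool(touches),
            )
            if boundary is None or len(boundary) < 10:
                cand.rejection_reason = "too_small"
            candidates.append(cand)
    return candidates, net, rim_level


def rim_completeness(
    candidate: FibreCandidate,
    membrane: np.ndarray,
    params: SegmentationParams,
    support_threshold: float,
    pixel_size_um: float,
    network: np.ndarray | None = None,
) -> float:
    """Fraction of the candidate boundary supported by membrane signal.

    The traced boundary is sampled at ~1-pixel arc steps; a sample counts as
    supported when, within ``rim_band_um`` *outward* along the boundary
    normal, the maximum membrane intensity exceeds the support threshold AND
    (when a rim ``network`` mask is given) a network pixel is present:
    diffuse bright regions without ridge response are not rims.  The search
    is outward-only and must stay shorter than the interstitial spacing: a
    symmetric or longer band would read the intact rim of the neighbouring
    fibre as support for a disrupted rim.
    """
    boundary = candidate.boundary
    if boundary is None or len(boundary) < 10:
        return 0.0
    samples, _, perim = resample_closed(boundary, 1.0)
    if perim <= 0 or len(samples) < 10:
        return 0.0
    # tangents from lightly smoothed central differences; normals perpendicular
    sm = samples.copy()
    for _ in range(2):
        sm = (np.roll(sm, 1, axis=0) + sm + np.roll(sm, -1, axis=0)) / 3.0
    tang = np.roll(sm, -1, axis=0) - np.roll(sm, 1, axis=0)
    norm = np.column_stack([-tang[:, 1], tang[:, 0]])
    lengths = np.hypot(*norm.T)
    lengths[lengths == 0] = 1.0
    norm /= lengths[:, None]
    # orient normals outward (away from the candidate interior)
    probe = samples + 1.5 * norm
    pr = np.clip(np.round(probe[:, 0]).astype(int) - candidate.bbox[0].start, -1, 10**9)
    pc = np.clip(np.round(probe[:, 1]).astype(int) - candidate.bbox[1].start, -1, 10**9)
    h_m, w_m = candidate.mask.shape
    inside = (
        (pr >= 0) & (pr < h_m) & (pc >= 0) & (pc < w_m)
    )
    inside[inside] = candidate.mask[pr[inside], pc[inside]]
    if inside.mean() > 0.5:
        norm = -norm
    band_px = params.rim_band_um / pixel_size_um
    offsets = np.arange(0.0, band_px + 0.25, 0.5)
    pos = samples[:, None, :] + offsets[None, :, None] * norm[:, None, :]
    rr = np.clip(np.round(pos[..., 0]).astype(int), 0, membrane.shape[0] - 1)
    cc = np.clip(np.round(pos[..., 1]).astype(int), 0, membrane.shape[1] - 1)
    support = membrane[rr, cc].max(axis=1)
    # adapt the threshold to this fibre's own rim brightness: rim intensities
    # vary severalfold between fibres, and a dim fibre's intact rim must not
    # read as a gap against a section-wide threshold.  The median band
    # maximum estimates the own-rim level as long as less than half the rim
    # is missing; the global threshold halved acts as a floor.
    own_level = float(np.median(support))
    thr = max(0.5 * own_level, 0.5 * support_threshold)
    supported = support > thr
    if network is not None:
        supported &= network[rr, cc].any(axis=1)
    return float(np.mean(supported))


def compute_completeness(
    candidates: Sequence[FibreCandidate],
    section: SectionImage,
    params: SegmentationParams,
    rim_level: float,
    network: np.ndarray | None = None,
) -> None:
    """Fill ``rim_completeness`` for all candidates still in play."""
    thr = params.support_threshold_fraction * rim_level
    membrane = section.membrane
    for cand in candidates:
        if cand.rejection_reason in ("none", "gap_gt_threshold"):
            cand.rim_completeness = rim_completeness(
                cand, membrane, params, thr, section.pixel_size_um, network
            )


def apply_gap_rule(
    candidates: Sequence[FibreCandidate], params: SegmentationParams
) -> list[FibreCandidate]:
    """Reconstruct-or-reject on rim disruption.

    A candidate missing less than ``gap_exclusion_fraction`` of its rim is
    retained with its traced closure standing in for the reconstructed rim; a
    candidate missing at least that fraction is rejected
    (``gap_gt_threshold``).  Only candidates with no prior rejection reason
    are touched.
    """
    for cand in candidates:
        if cand.rejection_reason != "none" or cand.rim_completeness is None:
            continue
        missing = 1.0 - cand.rim_completeness
        if missing >= params.gap_exclusion_fraction - 1e-9:
            cand.rejection_reason = "gap_gt_threshold"
    return list(candidates)


def filter_fibre_characteristics(
    candidates: Sequence[FibreCandidate],
    section: SectionImage,
    params: SegmentationParams,
    rim_level: float,
    background_level: float = 0.0,
) -> list[FibreCandidate]:
    """Reject structures without myofibre characteristics.

    Small profiles (blood cells, axons, vessel lumina) fail the minimum area;
    connective expanses the maximum; irregular connective/folded shapes the
    solidity gate; folded tissue shows rim-level intensity across its
    interior; enclosed spaces with no cytoplasmic signal at all (interstitial
    pockets, vessel surroundings) are not fibres either; border-touching
    components are excluded because completeness and area are undefined
    there.  Spindle/nerve clusters fall out through the area rule applied to
    their sub-minimum profiles.
    """
    membrane = section.membrane
    bright_thr = params.fold_intensity_fraction * rim_level
    dark_thr = background_level + params.min_interior_fraction * max(
        rim_level - background_level, 0.0
    )
    for cand in candidates:
        if cand.rejection_reason != "none":
            continue
        if cand.touches_border and params.border_policy == "exclude_touching":
            cand.rejection_reason = "border"
        elif cand.area_um2 < params.min_area_um2:
            cand.rejection_reason = "too_small"
        elif cand.area_um2 > params.max_area_um2:
            cand.rejection_reason = "too_large"
        elif cand.solidity < params.min_solidity:
            cand.rejection_reason = "low_solidity"
        else:
            interior = membrane[cand.bbox][cand.mask]
            if rim_level > 0 and interior.size:
                m = interior.mean()
                if m >= bright_thr:
                    cand.rejection_reason = "interior_bright"
                elif m <= dark_thr:
                    cand.rejection_reason = "distractor_shape"
    return list(candidates)


def finalize_labels(
    candidates: Sequence[FibreCandidate],
    shape: tuple[int, int],
    params: SegmentationParams,
    pixel_size_um: float,
) -> FibreLabelMap:
    """Relabel accepted candidates 1..N in raster order of centroid.

    Each accepted interior is then expanded outward by ``boundary_snap_um``
    (equidistantly, so neighbouring fibres never overlap) to place the label
    boundary on the rim centreline rather than the rim's inner edge.
    """
    accepted = sorted(
        (c for c in candidates if c.accepted),
        key=lambda c: (c.centroid[0], c.centroid[1]),
    )
    labels = np.zeros(shape, dtype=np.int32)
    for new_id, cand in enumerate(accepted, start=1):
        labels[cand.bbox][cand.mask] = new_id
    snap_px = params.boundary_snap_um / pixel_size_um
    if snap_px > 0 and accepted:
        labels = expand_labels(labels, distance=snap_px)
    return FibreLabelMap(labels=labels, candidates=list(candidates))


def segment_section(
    section: SectionImage, params: SegmentationParams | None = None
) -> SegmentationResult:
    """Run the full fibre-recognition pipeline on one section."""
    params = params or SegmentationParams()
    params.validate()
    ridge = ridge_image(section, params)
    tissue = detect_tissue(section, params, ridge=ridge)
    candidates, net, rim_level = extract_candidates(section, tissue, params, ridge=ridge)
    outside = section.membrane[~tissue]
    background = float(np.median(outside)) if outside.size else 0.0
    # structural gates first, then the completeness-based gap rule; each step
    # only touches candidates not already rejected
    filter_fibre_characteristics(candidates, section, params, rim_level, background)
    compute_completeness(candidates, section, params, rim_level, net)
    apply_gap_rule(candidates, params)
    label_map = finalize_labels(candidates, section.shape, params, section.pixel_size_um)
    n_acc = label_map.n_fibres
    log.info(
        "segmented %d candidates, accepted %d fibres", len(candidates), n_acc
    )
    return SegmentationResult(
        label_map=label_map,
        tissue_mask=tissue,
        rim_network=net,
        rim_level=rim_level,
        params=params,
    )
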