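"""Seeded synthetic two-channel muscle sections with full ground truth.

The generator emulates what the segmentation algorithm must recognise and
reject in a transverse section: a space-filling mosaic of polygonal myofibres
whose membranes (spectrin/laminin in the membrane channel, dystrophin in the
target channel) appear as bright thin rims; per-fibre rim intensities drawn
from group-specific distributions; rim gaps (damaged/degenerating membranes);
non-fibre distractor structures (vessels, nerve bundles, spindles, connective
patches, tissue folds); and photon + read noise on a constant background.

Geometry is a Voronoi tessellation of a Poisson-disc point process, with each
cell shrunk by a fixed interstitial margin so neighbouring rims stay
resolvable.  The rim cross-section is a flat plateau of width ``rim_width_um``
centred on the cell boundary with Gaussian shoulders: a plateau keeps the
mean intensity over the rim footprint equal to the drawn per-fibre intensity,
which is what makes the ground truth an exact bookkeeping oracle, while the
shoulders mimic diffraction blur.

Same spec + same seed => bit-identical images and ground truth.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import Voronoi
from scipy.stats import qmc
from shapely.geometry import Polygon, box
from skimage.draw import polygon as draw_polygon

from .geometry import (
    complement_circular_intervals,
    merge_circular_intervals,
    min_feret_diameter,
    resample_closed,
    total_interval_length,
)
from .io import ROLE_MEMBRANE, ROLE_TARGET, SectionImage

log = logging.getLogger(__name__)

DISTRACTOR_KINDS = ("vessel", "nerve_bundle", "spindle", "connective_patch", "fold")

#: Characteristic size (um) handed to render_distractor when a spec lists only
#: a count.  Semantics per kind: vessel = lumen radius; nerve_bundle = bundle
#: radius; spindle = capsule semi-major axis; connective_patch = mean blob
#: radius; fold = semi-major axis of the folded patch.
DISTRACTOR_DEFAULT_SIZE_UM = {
    "vessel": 4.0,
    "nerve_bundle": 15.0,
    "spindle": 25.0,
    "connective_patch": 75.0,
    "fold": 30.0,
}

# generous bound on the ground each kind may occupy, used to carve a fibre-free
# pocket in the tessellation before rendering
_POCKET_FACTOR = {
    "vessel": 2.5,
    "nerve_bundle": 1.4,
    "spindle": 1.3,
    "connective_patch": 1.35,
    "fold": 1.3,
}


def _default_rim_dist() -> dict:
    return {"name": "lognormal", "mean": 18000.0, "cv": 0.20}


def _default_membrane_dist() -> dict:
    return {"name": "lognormal", "mean": 20000.0, "cv": 0.10}


def _default_gap_dist() -> dict:
    # rim interruptions are rare in real sections (~1% of fibres)
    return {"name": "zero_inflated_uniform", "p_nonzero": 0.01, "low": 0.05, "high": 0.30}


def _default_distractors() -> tuple:
    return (
        ("vessel", 2),
        ("nerve_bundle", 1),
        ("spindle", 1),
        ("connective_patch", 1),
        ("fold", 1),
    )


def _default_noise() -> dict:
    # Poisson on signal then additive Gaussian read noise; sigma defaults to
    # 2% of the dynamic range at generation time (see SyntheticSpec.validate)
    return {"gaussian_sigma_au": None, "poisson_gain_au": 4.0}


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic section.

    Distributions are dicts with a ``name`` plus parameters; supported names:
    ``constant(value)``, ``uniform(low, high)``, ``normal(mean, sd)`` (clipped
    at 0), ``lognormal(mean, cv)``, ``zero_inflated_uniform(p_nonzero, low,
    high)``.
    """

    image_shape: tuple[int, int] = (1024, 1024)
    pixel_size_um: float = 0.5
    bit_depth: int = 16
    n_fibres_requested: int | None = None  # None: fill the frame
    fibre_area_range_um2: tuple[float, float] = (800.0, 4500.0)
    interstitial_margin_um: float = 3.0
    rim_width_um: float = 1.5
    rim_edge_sigma_um: float = 0.25
    rim_intensity_dist: dict = field(default_factory=_default_rim_dist)
    membrane_intensity_dist: dict = field(default_factory=_default_membrane_dist)
    cytoplasm_intensity_fraction: float = 0.25
    gap_fraction_dist: dict = field(default_factory=_default_gap_dist)
    gap_assignment: str = "independent"  # or "spaced": gapped fibres never adjacent
    distractors: Sequence[tuple[str, int]] = field(default_factory=_default_distractors)
    noise: dict = field(default_factory=_default_noise)
    background_level: float = 600.0
    seed: int = 0

    @property
    def intensity_max(self) -> int:
        return 2**self.bit_depth - 1

    def gaussian_sigma_au(self) -> float:
        sigma = self.noise.get("gaussian_sigma_au")
        return 0.02 * self.intensity_max if sigma is None else float(sigma)

    def validate(self) -> None:
        h, w = self.image_shape
        if h <= 0 or w <= 0:
            raise ValueError("image_shape must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.rim_width_um <= 0:
            raise ValueError("rim_width_um must be positive")
        lo, hi = self.fibre_area_range_um2
        if not 0 < lo < hi:
            raise ValueError("fibre_area_range_um2 must satisfy 0 < min < max")
        if not 0 <= self.cytoplasm_intensity_fraction < 1:
            raise ValueError("cytoplasm_intensity_fraction must be in [0, 1)")
        if self.background_level < 0 or self.background_level > self.intensity_max:
            raise ValueError("background_level outside dynamic range")
        if self.gap_assignment not in ("independent", "spaced"):
            raise ValueError(f"unknown gap_assignment {self.gap_assignment!r}")
        for kind, count in self.distractors:
            if kind not in DISTRACTOR_KINDS:
                raise ValueError(f"unknown distractor kind {kind!r}")
            if count < 0:
                raise ValueError("distractor counts must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["distractors"] = [list(x) for x in self.distractors]
        return d


@dataclass
class FibreTruth:
    """Ground truth for one rendered fibre."""

    fibre_id: int
    polygon: np.ndarray  # (k, 2) row/col pixel coordinates of the cell outline
    centroid: tuple[float, float]
    area_um2: float
    min_feret_um: float
    perimeter_um: float
    rim_intensity_target: float
    rim_intensity_membrane: float
    cyto_intensity_target: float
    cyto_intensity_membrane: float
    gap_fraction: float
    n_gap_arcs: int
    touches_border: bool
    #: cell adjacent to an unrendered region (frame margin, distractor pocket,
    #: skipped cell): a rim gap facing that region has no bounding neighbour
    #: rim, so completeness there reflects tissue-edge damage, not the gap
    on_tissue_edge: bool


@dataclass
class DistractorTruth:
    kind: str
    distractor_id: int
    center: tuple[float, float]
    area_um2: float
    n_profiles: int


@dataclass
class GroundTruth:
    """Per-fibre truth plus label rasters for oracle checks.

    ``interior_labels`` rasterises each fibre polygon (id at every interior
    pixel); ``rim_labels`` marks the true rim footprint (pixels within half a
    rim width of the retained boundary arcs); ``distractor_labels`` records
    every rendered distractor footprint.
    """

    fibres: list[FibreTruth]
    distractors: list[DistractorTruth]
    interior_labels: np.ndarray
    rim_labels: np.ndarray
    distractor_labels: np.ndarray

    @property
    def n_fibres(self) -> int:
        return len(self.fibres)

    def fibre(self, fibre_id: int) -> FibreTruth:
        return self.fibres[fibre_id - 1]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.fibres:
            rows.append(
                {
                    "fibre_id": f.fibre_id,
                    "centroid_row": f.centroid[0],
                    "centroid_col": f.centroid[1],
                    "area_um2": f.area_um2,
                    "min_feret_um": f.min_feret_um,
                    "perimeter_um": f.perimeter_um,
                    "rim_intensity_target": f.rim_intensity_target,
                    "rim_intensity_membrane": f.rim_intensity_membrane,
                    "cyto_intensity_target": f.cyto_intensity_target,
                    "cyto_intensity_membrane": f.cyto_intensity_membrane,
                    "gap_fraction": f.gap_fraction,
                    "n_gap_arcs": f.n_gap_arcs,
                    "touches_border": f.touches_border,
                    "on_tissue_edge": f.on_tissue_edge,
                    "polygon": ";".join(f"{r:.2f},{c:.2f}" for r, c in f.polygon),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "fibre_id",
                "centroid_row",
                "centroid_col",
                "area_um2",
                "min_feret_um",
                "perimeter_um",
                "rim_intensity_target",
                "rim_intensity_membrane",
                "cyto_intensity_target",
                "cyto_intensity_membrane",
                "gap_fraction",
                "n_gap_arcs",
                "touches_border",
                "on_tissue_edge",
                "polygon",
            ],
        )

    def distractor_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [asdict(d) for d in self.distractors],
            columns=["kind", "distractor_id", "center", "area_um2", "n_profiles"],
        )


def draw_from(dist: dict, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``size`` values from a named distribution spec."""
    name = dist["name"]
    if name == "constant":
        return np.full(size, float(dist["value"]))
    if name == "uniform":
        return rng.uniform(dist["low"], dist["high"], size)
    if name == "normal":
        return np.clip(rng.normal(dist["mean"], dist["sd"], size), 0.0, None)
    if name == "lognormal":
        mean, cv = float(dist["mean"]), float(dist["cv"])
        if cv <= 0:
            return np.full(size, mean)
        sigma2 = np.log1p(cv**2)
        mu = np.log(mean) - sigma2 / 2.0
        return rng.lognormal(mu, np.sqrt(sigma2), size)
    if name == "zero_inflated_uniform":
        vals = rng.uniform(dist["low"], dist["high"], size)
        mask = rng.uniform(size=size) < dist["p_nonzero"]
        return np.where(mask, vals, 0.0)
    raise ValueError(f"unknown distribution {name!r}")


# ---------------------------------------------------------------------------
# tessellation


def _poisson_disc_points(
    shape: tuple[int, int], spacing_px: float, rng: np.random.Generator
) -> np.ndarray:
    """Maximal Poisson-disc sample over the image frame, (n, 2) row/col."""
    h, w = shape
    scale = float(max(h, w))
    engine = qmc.PoissonDisk(
        d=2,
        radius=spacing_px / scale,
        seed=np.random.default_rng(int(rng.integers(2**31))),
    )
    pts = engine.fill_space() * scale
    keep = (pts[:, 0] < h) & (pts[:, 1] < w)
    return pts[keep]


def _bounded_voronoi(points: np.ndarray, shape: tuple[int, int]):
    """Voronoi diagram bounded to the image frame via mirrored guard points.

    Returns the Voronoi object plus the index count of the original points
    (regions of mirrored points are ignored).
    """
    h, w = shape
    mirrors = [
        points * [-1, 1],  # across row 0
        points * [1, -1],  # across col 0
        np.column_stack([2 * h - points[:, 0], points[:, 1]]),
        np.column_stack([points[:, 0], 2 * w - points[:, 1]]),
    ]
    allpts = np.vstack([points] + mirrors)
    return Voronoi(allpts), len(points)


def _cell_polygons(vor: Voronoi, n_original: int, shape: tuple[int, int]):
    """Shapely polygon of each original point's Voronoi cell, clipped."""
    h, w = shape
    frame = box(0, 0, h, w)  # shapely x := row, y := col (consistent use)
    polys: list[Polygon | None] = []
    for i in range(n_original):
        region = vor.regions[vor.point_region[i]]
        if not region or -1 in region:
            polys.append(None)
            continue
        verts = vor.vertices[region]
        poly = Polygon(verts)
        if not poly.is_valid or poly.area <= 0:
            polys.append(None)
            continue
        clipped = poly.intersection(frame)
        if clipped.is_empty:
            polys.append(None)
            continue
        if clipped.geom_type == "MultiPolygon":
            clipped = max(clipped.geoms, key=lambda g: g.area)
        elif clipped.geom_type != "Polygon":
            polys.append(None)
            continue
        polys.append(clipped)
    return polys


def _adjacency(vor: Voronoi, n_original: int) -> dict[int, set[int]]:
    adj: dict[int, set[int]] = {i: set() for i in range(n_original)}
    for a, b in vor.ridge_points:
        if a < n_original and b < n_original:
            adj[a].add(b)
            adj[b].add(a)
    return adj


# ---------------------------------------------------------------------------
# rim rendering


def _gap_intervals(
    gap_fraction: float, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Draw 1-3 gap arcs totalling ``gap_fraction`` of the perimeter.

    Overlapping arcs are merged, so the returned (disjoint) intervals may
    total slightly less than requested; the caller records the actual total.
    """
    if gap_fraction <= 0:
        return []
    k = int(rng.integers(1, 4))
    parts = rng.dirichlet(np.ones(k)) * gap_fraction
    starts = rng.uniform(0.0, 1.0, k)
    return merge_circular_intervals(
        [(float(s), float(s + p)) for s, p in zip(starts, parts)]
    )


def _stamp_rim(
    canvas_mem: np.ndarray,
    canvas_tgt: np.ndarray,
    boundary_pts: np.ndarray,
    retained: list[tuple[float, float]],
    perimeter_px: float,
    mem_level: float,
    tgt_level: float,
    half_width_px: float,
    edge_sigma_px: float,
) -> tuple[tuple[slice, slice], np.ndarray] | None:
    """Render one fibre's rim (plateau + Gaussian shoulders) into the canvases.

    ``boundary_pts`` are dense samples of the full boundary with arc positions
    implied by index order; ``retained`` are the kept arc intervals (fractions
    of perimeter).  Each retained arc is shrunk by half a rim width at its free
    ends before stamping so that the rendered support ends at the drawn gap
    boundary (the distance-transform stamp otherwise adds a round end cap).

    Returns the bbox slices and the local rim-footprint mask (pixels within
    half a rim width of the retained boundary), or None if nothing was drawn.
    """
    n = len(boundary_pts)
    if n == 0:
        return None
    arc_frac = np.arange(n) / n
    full_boundary = len(retained) == 1 and (
        retained[0][1] - retained[0][0] >= 1.0 - 1e-9
    )
    if full_boundary:
        keep = np.ones(n, dtype=bool)
    else:
        keep = np.zeros(n, dtype=bool)
        shrink = half_width_px / perimeter_px
        for a, b in retained:
            a2, b2 = a + shrink, b - shrink
            if b2 <= a2:
                continue
            keep |= (arc_frac - a2) % 1.0 < (b2 - a2)
    if not keep.any():
        return None
    pts = boundary_pts[keep]
    h, w = canvas_mem.shape
    pad = int(np.ceil(half_width_px + 4 * edge_sigma_px + 2))
    r0 = max(int(np.floor(pts[:, 0].min())) - pad, 0)
    r1 = min(int(np.ceil(pts[:, 0].max())) + pad + 1, h)
    c0 = max(int(np.floor(pts[:, 1].min())) - pad, 0)
    c1 = min(int(np.ceil(pts[:, 1].max())) + pad + 1, w)
    if r1 <= r0 or c1 <= c0:
        return None
    bmask = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    rr = np.clip(np.round(pts[:, 0]).astype(int) - r0, 0, r1 - r0 - 1)
    cc = np.clip(np.round(pts[:, 1]).astype(int) - c0, 0, c1 - c0 - 1)
    bmask[rr, cc] = True
    dist = ndimage.distance_transform_edt(~bmask)
    prof = np.where(
        dist <= half_width_px,
        1.0,
        np.exp(-0.5 * ((dist - half_width_px) / max(edge_sigma_px, 1e-6)) ** 2),
    )
    prof[dist > half_width_px + 4 * edge_sigma_px] = 0.0
    sl = (slice(r0, r1), slice(c0, c1))
    np.maximum(canvas_mem[sl], mem_level * prof, out=canvas_mem[sl])
    np.maximum(canvas_tgt[sl], tgt_level * prof, out=canvas_tgt[sl])
    return sl, dist <= half_width_px


# ---------------------------------------------------------------------------
# distractors


@dataclass
class DistractorRender:
    """One rendered distractor patch (full-image coordinates via ``bbox``)."""

    kind: str
    bbox: tuple[slice, slice]
    mask: np.ndarray  # footprint within bbox
    membrane: np.ndarray  # additive-max membrane-channel pixels within bbox
    target: np.ndarray
    n_profiles: int


def _ring_profile(dist_to_curve: np.ndarray, half_width: float, edge_sigma: float) -> np.ndarray:
    prof = np.where(
        dist_to_curve <= half_width,
        1.0,
        np.exp(-0.5 * ((dist_to_curve - half_width) / max(edge_sigma, 1e-6)) ** 2),
    )
    prof[dist_to_curve > half_width + 4 * edge_sigma] = 0.0
    return prof


def render_distractor(
    kind: str,
    location: tuple[float, float],
    size_um: float,
    *,
    pixel_size_um: float,
    rim_width_um: float,
    rim_edge_sigma_um: float,
    intensity: float,
    cytoplasm_fraction: float,
    image_shape: tuple[int, int],
    rng: np.random.Generator,
) -> DistractorRender:
    """Render one non-fibre structure as a bbox patch.

    Morphologies (all in the membrane channel; the target channel carries the
    same structure at reduced intensity):

    - ``vessel``: thick-walled annulus whose lumen is far below the minimum
      fibre area.
    - ``nerve_bundle``: cluster of tiny rimmed profiles (axon fascicle).
    - ``spindle``: capsule outline enclosing a cluster of tiny intrafusal
      profiles that occupy much of the capsule.
    - ``connective_patch``: irregular diffuse region with no closed rims,
      larger than any plausible fibre.
    - ``fold``: patch whose whole interior sits at rim-level intensity.
    """
    if kind not in DISTRACTOR_KINDS:
        raise ValueError(f"unknown distractor kind {kind!r}")
    px = pixel_size_um
    hw = 0.5 * rim_width_um / px
    esig = rim_edge_sigma_um / px
    size_px = size_um / px
    h, w = image_shape
    cr, cc = location

    ext = {
        "vessel": size_px + 3.0 / px + 4 * esig + 3,
        "nerve_bundle": size_px + 8,
        "spindle": size_px + 4 * esig + 4,
        "connective_patch": size_px * 1.6 + 4,
        "fold": size_px + 4 * esig + 4,
    }[kind]
    r0, r1 = max(int(cr - ext), 0), min(int(cr + ext) + 1, h)
    c0, c1 = max(int(cc - ext), 0), min(int(cc + ext) + 1, w)
    hh, ww = r1 - r0, c1 - c0
    rr, cc_grid = np.mgrid[r0:r1, c0:c1].astype(float)
    dr, dc = rr - cr, cc_grid - cc
    radius = np.hypot(dr, dc)

    mem = np.zeros((hh, ww))
    tgt = np.zeros((hh, ww))
    n_profiles = 0

    if kind == "vessel":
        # wall thickness 3 um: well above the rim-thickness bound
        lumen_r = size_px
        wall = 3.0 / px
        mid = lumen_r + wall / 2.0
        prof = _ring_profile(np.abs(radius - mid), wall / 2.0, esig)
        mem += intensity * prof
        tgt += 0.5 * intensity * prof
        mask = radius <= lumen_r + wall + 4 * esig
    elif kind == "nerve_bundle":
        n_profiles = int(rng.integers(8, 16))
        mask = np.zeros((hh, ww), dtype=bool)
        placed: list[tuple[float, float, float]] = []
        for _ in range(n_profiles):
            prof_r = rng.uniform(2.5, 3.8) / px  # 20-45 um^2 profiles
            for _attempt in range(40):
                ang = rng.uniform(0, 2 * np.pi)
                rad = rng.uniform(0, size_px - prof_r - 1)
                pr, pc = cr + rad * np.sin(ang), cc + rad * np.cos(ang)
                if all(
                    np.hypot(pr - q[0], pc - q[1]) > prof_r + q[2] + 2 * hw + 4
                    for q in placed
                ):
                    placed.append((pr, pc, prof_r))
                    break
        for pr, pc, prof_r in placed:
            d = np.hypot(rr - pr, cc_grid - pc)
            ring = _ring_profile(np.abs(d - prof_r), hw, esig)
            mem = np.maximum(mem, intensity * ring)
            tgt = np.maximum(tgt, 0.5 * intensity * ring)
            inner = d < prof_r - hw
            mem[inner] = np.maximum(mem[inner], cytoplasm_fraction * intensity)
            mask |= d <= prof_r + hw + 4 * esig
        n_profiles = len(placed)
    elif kind == "spindle":
        a, b = size_px, 0.6 * size_px
        theta = rng.uniform(0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        u = dr * ct + dc * st
        v = -dr * st + dc * ct
        # distance proxy to the ellipse boundary (good enough for stamping)
        rho = np.hypot(u / a, v / b)
        grad = np.hypot(u / a**2, v / b**2)
        d_ell = np.abs(rho - 1.0) / np.maximum(grad, 1e-9)
        ring = _ring_profile(d_ell, hw, esig)
        mem = np.maximum(mem, intensity * ring)
        tgt = np.maximum(tgt, 0.5 * intensity * ring)
        inside = rho < 1.0
        mem[inside & (d_ell > hw)] = np.maximum(
            mem[inside & (d_ell > hw)], cytoplasm_fraction * intensity
        )
        # intrafusal profiles on a jittered ring covering much of the capsule
        n_profiles = int(rng.integers(6, 11))
        for i in range(n_profiles):
            ang = 2 * np.pi * (i + rng.uniform(-0.2, 0.2)) / n_profiles
            pu = 0.45 * a * np.cos(ang) * rng.uniform(0.3, 1.0)
            pv = 0.45 * b * np.sin(ang) * rng.uniform(0.5, 1.0)
            pr = cr + pu * ct - pv * st
            pc = cc + pu * st + pv * ct
            prof_r = rng.uniform(3.2, 4.5) / px
            d = np.hypot(rr - pr, cc_grid - pc)
            pring = _ring_profile(np.abs(d - prof_r), hw, esig)
            mem = np.maximum(mem, intensity * pring)
            tgt = np.maximum(tgt, 0.5 * intensity * pring)
        mask = rho <= 1.0 + (hw + 4 * esig) * np.maximum(grad, 1e-9)
    elif kind == "connective_patch":
        # irregular blob, rescaled so its area always exceeds any fibre
        nharm = 4
        amps = rng.uniform(0.05, 0.18, nharm)
        phases = rng.uniform(0, 2 * np.pi, nharm)
        ang = np.arctan2(dr, dc)
        wobble = np.ones_like(ang)
        for k in range(nharm):
            wobble += amps[k] * np.cos((k + 2) * ang + phases[k])
        blob = radius <= size_px * wobble
        texture = ndimage.gaussian_filter(
            rng.standard_normal((hh, ww)), 4.0 / px
        )
        texture = 1.0 + 0.35 * texture / max(np.abs(texture).max(), 1e-9)
        level = 0.35 * intensity
        mem[blob] = np.maximum(mem[blob], level * texture[blob])
        tgt[blob] = np.maximum(tgt[blob], 0.3 * level * texture[blob])
        mask = blob
    else:  # fold
        a, b = size_px, rng.uniform(0.4, 0.7) * size_px
        theta = rng.uniform(0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        u = dr * ct + dc * st
        v = -dr * st + dc * ct
        inside = np.hypot(u / a, v / b) <= 1.0
        mem[inside] = intensity
        tgt[inside] = 0.8 * intensity
        mask = inside

    return DistractorRender(
        kind=kind,
        bbox=(slice(r0, r1), slice(c0, c1)),
        mask=mask,
        membrane=mem,
        target=tgt,
        n_profiles=n_profiles,
    )


# ---------------------------------------------------------------------------
# main entry point


def generate_section(spec: SyntheticSpec) -> tuple[SectionImage, GroundTruth]:
    """Render a synthetic section and its ground truth.

    Deterministic: the same spec (including seed) yields bit-identical arrays.
    Degenerate cells (empty after shrinking, outside the area range) are
    skipped and logged; intensities exceeding the dynamic range are clipped
    with a warning.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    px = spec.pixel_size_um
    px2 = px * px
    hw_px = 0.5 * spec.rim_width_um / px
    esig_px = spec.rim_edge_sigma_um / px

    mem = np.zeros((h, w))
    tgt = np.zeros((h, w))
    interior_labels = np.zeros((h, w), dtype=np.int32)
    rim_labels = np.zeros((h, w), dtype=np.int32)
    distractor_labels = np.zeros((h, w), dtype=np.int32)

    fibres: list[FibreTruth] = []
    distractor_truths: list[DistractorTruth] = []

    if spec.n_fibres_requested != 0:
        lo_px2 = spec.fibre_area_range_um2[0] / px2
        hi_px2 = spec.fibre_area_range_um2[1] / px2
        mean_area_px2 = 0.5 * (lo_px2 + hi_px2)
        # maximal Poisson-disc samples pack to a mean Voronoi cell area of
        # about 1.6 r^2 (r = minimum point distance), measured empirically
        spacing = float(np.sqrt(mean_area_px2 / 1.6))
        points = _poisson_disc_points((h, w), spacing, rng)
    else:
        points = np.empty((0, 2))

    cells: list[tuple[int, Polygon]] = []  # (point index, shrunk polygon)
    adjacency: dict[int, set[int]] = {}
    claimed: set[int] = set()
    sites: list[tuple[str, float, float, float]] = []  # kind, row, col, size_um

    if len(points) >= 4:
        vor, n_orig = _bounded_voronoi(points, (h, w))
        adjacency = _adjacency(vor, n_orig)
        polys = _cell_polygons(vor, n_orig, (h, w))

        # reserve fibre-free pockets for the distractors before choosing cells
        wanted = [
            (kind, DISTRACTOR_DEFAULT_SIZE_UM[kind])
            for kind, count in spec.distractors
            for _ in range(count)
        ]
        spacing_guard = spacing
        for kind, size_um in wanted:
            pocket_px = _POCKET_FACTOR[kind] * size_um / px
            placed = False
            for _attempt in range(60):
                cr = rng.uniform(pocket_px, max(h - pocket_px, pocket_px + 1))
                cc = rng.uniform(pocket_px, max(w - pocket_px, pocket_px + 1))
                if all(
                    np.hypot(cr - s[1], cc - s[2]) > pocket_px + _POCKET_FACTOR[s[0]] * s[3] / px + 4
                    for s in sites
                ):
                    placed = True
                    break
            if not placed:
                log.warning("could not place distractor %s; skipped", kind)
                continue
            sites.append((kind, cr, cc, size_um))
            d = np.hypot(points[:, 0] - cr, points[:, 1] - cc)
            claimed |= set(np.nonzero(d <= pocket_px + 0.8 * spacing_guard)[0].tolist())

        margin_px = spec.interstitial_margin_um / px
        frame_edge = box(0, 0, h, w).exterior
        for i, poly in enumerate(polys):
            if i in claimed or poly is None or poly.is_empty:
                continue
            if poly.exterior.distance(frame_edge) < 1.0:
                # frame-clipped cells would carry an artificial straight rim
                # along the image edge; a scanned section lies inside the
                # frame, so these are not rendered
                continue
            shrunk = poly.buffer(-margin_px)
            if shrunk.is_empty:
                log.debug("cell %d degenerate after shrinking; skipped", i)
                continue
            if shrunk.geom_type == "MultiPolygon":
                shrunk = max(shrunk.geoms, key=lambda g: g.area)
            if not (lo_px2 <= shrunk.area <= hi_px2):
                continue
            cells.append((i, shrunk))

        # deterministic raster order by centroid
        cells.sort(key=lambda t: (t[1].centroid.x, t[1].centroid.y))
        if spec.n_fibres_requested is not None and spec.n_fibres_requested < len(cells):
            pick = np.sort(
                rng.choice(len(cells), size=spec.n_fibres_requested, replace=False)
            )
            cells = [cells[int(i)] for i in pick]

    rendered_points = {i for i, _ in cells}
    n = len(cells)
    if spec.n_fibres_requested not in (None, 0) and n < spec.n_fibres_requested:
        log.info(
            "placed %d fibres of %d requested", n, spec.n_fibres_requested
        )

    # per-fibre draws (vectorised for determinism independent of render order)
    mem_levels = draw_from(spec.membrane_intensity_dist, n, rng)
    tgt_levels = draw_from(spec.rim_intensity_dist, n, rng)
    gap_draws = draw_from(spec.gap_fraction_dist, n, rng)
    if np.any(gap_draws >= 1.0):
        raise ValueError("gap fractions must be < 1")

    if spec.gap_assignment == "spaced" and n:
        point_to_fibre = {cells[j][0]: j for j in range(n)}
        gapped: set[int] = set()
        for j in range(n):
            if gap_draws[j] <= 0:
                continue
            neighbours = adjacency.get(cells[j][0], set())
            if any(point_to_fibre.get(p) in gapped for p in neighbours):
                gap_draws[j] = 0.0
            else:
                gapped.add(j)

    cyto_frac = spec.cytoplasm_intensity_fraction
    for j, (point_idx, poly) in enumerate(cells):
        fid = j + 1
        coords = np.asarray(poly.exterior.coords)[:-1]  # (row, col)
        samples, _, perim = resample_closed(coords, 0.25)
        if perim <= 0:
            log.debug("fibre %d degenerate boundary; skipped", fid)
            continue
        gaps = _gap_intervals(float(gap_draws[j]), rng)
        actual_gap = total_interval_length(gaps)
        retained = complement_circular_intervals(gaps)
        stamped = _stamp_rim(
            mem,
            tgt,
            samples,
            retained,
            perim,
            float(mem_levels[j]),
            float(tgt_levels[j]),
            hw_px,
            esig_px,
        )
        if stamped is not None:
            sl, rim_local = stamped
            patch = rim_labels[sl]
            patch[rim_local & (patch == 0)] = fid

        rr, cc = draw_polygon(coords[:, 0], coords[:, 1], shape=(h, w))
        interior_labels[rr, cc] = fid
        cyto_mem = cyto_frac * mem_levels[j]
        cyto_tgt = cyto_frac * tgt_levels[j]
        np.maximum.at(mem, (rr, cc), cyto_mem)
        np.maximum.at(tgt, (rr, cc), cyto_tgt)

        fibres.append(
            FibreTruth(
                fibre_id=fid,
                polygon=coords,
                centroid=(float(poly.centroid.x), float(poly.centroid.y)),
                area_um2=float(poly.area * px2),
                min_feret_um=float(min_feret_diameter(coords) * px),
                perimeter_um=float(perim * px),
                rim_intensity_target=float(tgt_levels[j]),
                rim_intensity_membrane=float(mem_levels[j]),
                cyto_intensity_target=float(max(cyto_tgt, spec.background_level)),
                cyto_intensity_membrane=float(max(cyto_mem, spec.background_level)),
                gap_fraction=float(actual_gap),
                n_gap_arcs=len(gaps),
                touches_border=False,
                on_tissue_edge=any(
                    nb not in rendered_points
                    for nb in adjacency.get(point_idx, ())
                )
                or not adjacency.get(point_idx),
            )
        )

    # distractors (clipped against fibre rims and interiors)
    occupied = (interior_labels > 0) | (rim_labels > 0)
    for did, (kind, cr, cc, size_um) in enumerate(sites, start=1):
        level = float(draw_from(spec.membrane_intensity_dist, 1, rng)[0])
        render = render_distractor(
            kind,
            (cr, cc),
            size_um,
            pixel_size_um=px,
            rim_width_um=spec.rim_width_um,
            rim_edge_sigma_um=spec.rim_edge_sigma_um,
            intensity=level,
            cytoplasm_fraction=cyto_frac,
            image_shape=(h, w),
            rng=rng,
        )
        sl = render.bbox
        free = ~occupied[sl]
        mask = render.mask & free
        mem[sl] = np.where(mask, np.maximum(mem[sl], render.membrane), mem[sl])
        tgt[sl] = np.where(mask, np.maximum(tgt[sl], render.target), tgt[sl])
        distractor_labels[sl][mask] = did
        distractor_truths.append(
            DistractorTruth(
                kind=kind,
                distractor_id=did,
                center=(cr, cc),
                area_um2=float(mask.sum() * px2),
                n_profiles=render.n_profiles,
            )
        )

    # background, noise, quantisation
    np.maximum(mem, spec.background_level, out=mem)
    np.maximum(tgt, spec.background_level, out=tgt)
    gain = float(spec.noise.get("poisson_gain_au") or 0.0)
    sigma = spec.gaussian_sigma_au()
    if gain > 0:
        mem = rng.poisson(mem / gain).astype(float) * gain
        tgt = rng.poisson(tgt / gain).astype(float) * gain
    if sigma > 0:
        mem = mem + rng.normal(0.0, sigma, mem.shape)
        tgt = tgt + rng.normal(0.0, sigma, tgt.shape)
    top = float(spec.intensity_max)
    if mem.max() > top or tgt.max() > top:
        warnings.warn("intensity overflow: values clipped to the dynamic range")
    mem = np.clip(np.rint(mem), 0, top).astype(np.uint16)
    tgt = np.clip(np.rint(tgt), 0, top).astype(np.uint16)

    section = SectionImage(
        channels={ROLE_MEMBRANE: mem, ROLE_TARGET: tgt},
        pixel_size_um=px,
        bit_depth=spec.bit_depth,
        provenance={"generator": "sarcoquant.synthetic", "seed": spec.seed},
    )
    truth = GroundTruth(
        fibres=fibres,
        distractors=distractor_truths,
        interior_labels=interior_labels,
        rim_labels=rim_labels,
        distractor_labels=distractor_labels,
    )
    return section, truth


def write_ground_truth(
    truth: GroundTruth, spec: SyntheticSpec, out_dir: str | Path
) -> dict[str, Path]:
    """Write ground truth CSVs plus a JSON manifest of the spec."""
    import json

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fibres": out_dir / "ground_truth_fibres.csv",
        "distractors": out_dir / "ground_truth_distractors.csv",
        "manifest": out_dir / "manifest.json",
    }
    truth.to_frame().to_csv(paths["fibres"], index=False)
    truth.distractor_frame().to_csv(paths["distractors"], index=False)
    paths["manifest"].write_text(json.dumps(spec.to_dict(), indent=2) + "\n")
    return paths
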