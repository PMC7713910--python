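"""Batch-image morphometry: from paired photographs to 68-variable feature vectors.

Specimens are photographed in bulk — many individuals from one trapping event
laid out on a light background, once dorsally and once ventrally.  This module
segments each image into per-specimen regions, measures the classic particle
descriptors (area, perimeter, Feret diameters, moment-equivalent ellipse,
circularity, solidity, ...) and per-channel RGB intensity statistics, then
matches dorsal to ventral regions to emit one 68-feature vector per specimen.

Conventions (stated once, used everywhere): pixel coordinates are 0-based,
row-major, origin top-left; bounding boxes are half-open; regions are
8-connected.  The perimeter follows the ImageJ traced-boundary convention:
the 8-direction chain code of the boundary (axial step 1, diagonal step
sqrt(2)) scaled by the 0.948 corner-correction factor that removes the
average chain-code overestimate for smooth outlines.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from scipy.spatial import ConvexHull
from skimage.color import rgb2gray
from skimage.filters import threshold_otsu

from .manifest import CHANNELS, COLOR_STATS, SHAPE_VARS, feature_names

_CHAIN_CORRECTION = 0.948
_EIGHT_CONN = np.ones((3, 3), dtype=bool)


class ImagingError(ValueError):
    """Segmentation or measurement failure."""


class DegenerateRegionError(ImagingError):
    """Region too thin (single pixel / collinear) for shape measurement."""


@dataclass
class BatchImage:
    """One batch photograph: 8-bit RGB pixels at a known physical scale."""

    pixels: np.ndarray  # H x W x 3 uint8
    resolution: float  # pixels per mm
    view: str  # "dorsal" | "ventral"
    image_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ImagingError("pixels must be an H x W x 3 array")
        if self.resolution <= 0:
            raise ImagingError("resolution (px/mm) must be positive")
        if px.min() < 0 or px.max() > 255:
            raise ImagingError("channel values must lie in [0, 255]")
        self.pixels = px.astype(np.uint8)


@dataclass
class RegionMask:
    """One connected component: its pixel set and half-open bounding box."""

    label_id: int
    coords: np.ndarray  # N x 2 (row, col)
    bbox: tuple[int, int, int, int]  # (r0, c0, r1, c1), half-open

    @property
    def n_pixels(self) -> int:
        return len(self.coords)

    @property
    def centroid(self) -> tuple[float, float]:
        r, c = self.coords.mean(axis=0)
        return float(r), float(c)


@dataclass
class MeasuredRegion:
    """A region with its per-view shape and color measurements attached."""

    region: RegionMask
    shape: dict[str, float]
    color: dict[str, float]
    image_id: str = ""

    def variables(self) -> dict[str, float]:
        out = dict(self.shape)
        out.update(self.color)
        return out


@dataclass
class SpecimenFeatureVector:
    """The canonical 68 features for one specimen plus provenance."""

    specimen_id: str
    features: dict[str, float]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        canon = feature_names()
        missing = [f for f in canon if f not in self.features]
        extra = [f for f in self.features if f not in canon]
        if missing or extra:
            raise ImagingError(
                f"feature vector mismatch: missing={missing[:4]} extra={extra[:4]}"
            )
        self.features = {name: float(self.features[name]) for name in canon}


# ---------------------------------------------------------------------------
# Segmentation


def binarize(image: BatchImage, params: dict | None = None) -> np.ndarray:
    """Threshold a batch image to a boolean foreground (specimen) mask.

    ``params={"mode": "otsu"}`` (default) applies a global Otsu threshold on
    luminance with dark-object polarity.  ``params={"mode": "manual",
    "bands": {"R": (lo, hi), ...}}`` selects pixels falling inside every
    given per-channel band, mirroring manual color thresholding.
    """
    params = params or {"mode": "otsu"}
    mode = params.get("mode", "otsu")
    px = image.pixels
    if mode == "otsu":
        gray = rgb2gray(px)  # in [0, 1]
        t = threshold_otsu(gray)
        mask = gray < t
    elif mode == "manual":
        bands = params.get("bands", {})
        if not bands:
            raise ImagingError("manual mode requires per-channel 'bands'")
        mask = np.ones(px.shape[:2], dtype=bool)
        for ch, (lo, hi) in bands.items():
            idx = CHANNELS.index(ch)
            vals = px[:, :, idx]
            mask &= (vals >= lo) & (vals <= hi)
    else:
        raise ImagingError(f"unknown threshold mode {mode!r}")
    frac = mask.mean()
    if frac > 0.5:
        warnings.warn(
            f"threshold selects {frac:.0%} of pixels as foreground; "
            "check object/background polarity",
            stacklevel=2,
        )
    if not mask.any():
        raise ImagingError("empty foreground: threshold selected no pixels")
    return mask


def find_regions(mask: np.ndarray, min_area_px: int = 50) -> list[RegionMask]:
    """8-connected components of ``mask`` with at least ``min_area_px`` pixels.

    Returned top-to-bottom then left-to-right by bounding-box origin; smaller
    components (debris, noise) are discarded.
    """
    labels, n = ndimage.label(mask, structure=_EIGHT_CONN)
    if n == 0:
        return []
    slices = ndimage.find_objects(labels)
    regions = []
    for lab, sl in enumerate(slices, start=1):
        coords = np.argwhere(labels == lab)
        if len(coords) < min_area_px:
            continue
        r0, c0 = sl[0].start, sl[1].start
        r1, c1 = sl[0].stop, sl[1].stop
        regions.append(RegionMask(label_id=lab, coords=coords, bbox=(r0, c0, r1, c1)))
    regions.sort(key=lambda reg: (reg.bbox[0], reg.bbox[1]))
    for new_id, reg in enumerate(regions, start=1):
        reg.label_id = new_id
    return regions


# ---------------------------------------------------------------------------
# Shape measurement

_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def _trace_boundary(submask: np.ndarray) -> np.ndarray:
    """Moore-neighbor trace of the outer boundary (8-connected, clockwise).

    ``submask`` must contain a single 8-connected component.  Returns the
    closed sequence of boundary pixel coordinates (first pixel repeated at
    the end).
    """
    padded = np.pad(submask, 1)
    start = tuple(np.argwhere(padded)[0])  # topmost, then leftmost
    backtrack = (start[0], start[1] - 1)  # background by construction
    path = [start]
    cur, prev_bg = start, backtrack
    first_move = None
    for _ in range(4 * int(padded.sum()) + 8):
        d0 = _MOORE.index((prev_bg[0] - cur[0], prev_bg[1] - cur[1]))
        nxt = None
        for k in range(1, 9):
            d = (d0 + k) % 8
            cand = (cur[0] + _MOORE[d][0], cur[1] + _MOORE[d][1])
            if padded[cand]:
                nxt = cand
                break
            prev_bg = cand
        if nxt is None:  # isolated pixel
            break
        path.append(nxt)
        if first_move is None:
            first_move = nxt
        elif cur == start and nxt == first_move and len(path) > 2:
            # Re-entered the start in the original direction: loop closed.
            path = path[:-1]
            break
        cur = nxt
    return np.asarray(path) - 1  # undo padding


def _chain_perimeter(boundary: np.ndarray) -> float:
    """Corner-corrected chain-code length of a closed boundary, in pixels."""
    if len(boundary) < 2:
        return 0.0
    steps = np.diff(boundary, axis=0)
    diag = np.all(np.abs(steps) == 1, axis=1)
    n_diag = int(diag.sum())
    n_axial = len(steps) - n_diag
    return _CHAIN_CORRECTION * (n_axial + math.sqrt(2.0) * n_diag)


def _corner_points(coords: np.ndarray) -> np.ndarray:
    """The four unit-square corners of every pixel, as (x=col, y=row) points."""
    offs = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])
    pts = (coords[:, None, :] + offs[None, :, :]).reshape(-1, 2)
    return pts[:, ::-1]  # (col, row) -> x, y


def _calipers(hull_xy: np.ndarray) -> tuple[float, float]:
    """(max, min) caliper diameters of a convex polygon (vertices in order)."""
    d2 = np.sum((hull_xy[:, None, :] - hull_xy[None, :, :]) ** 2, axis=-1)
    feret = math.sqrt(float(d2.max()))
    min_w = math.inf
    n = len(hull_xy)
    for i in range(n):
        p, q = hull_xy[i], hull_xy[(i + 1) % n]
        edge = q - p
        norm = math.hypot(*edge)
        if norm == 0:
            continue
        normal = np.array([-edge[1], edge[0]]) / norm
        widths = np.abs((hull_xy - p) @ normal)
        min_w = min(min_w, float(widths.max()))
    return feret, min_w


def measure_shape(region: RegionMask, resolution: float) -> dict[str, float]:
    """ImageJ Analyze-Particles-style size and shape descriptors, in mm units.

    Raises :class:`DegenerateRegionError` for single-pixel or collinear
    regions, whose ellipse and hull are ill-defined.
    """
    coords = region.coords
    n = len(coords)
    if n < 3:
        raise DegenerateRegionError(f"region {region.label_id}: {n} pixel(s)")
    rc = coords - coords.mean(axis=0)
    cov = rc.T @ rc / n  # [[var_r, cov_rc], [cov_rc, var_c]]
    if np.linalg.det(cov) < 1e-12:
        raise DegenerateRegionError(
            f"region {region.label_id}: collinear pixel set"
        )

    r0, c0, r1, c1 = region.bbox
    sub = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    sub[coords[:, 0] - r0, coords[:, 1] - c0] = True
    boundary = _trace_boundary(sub)
    perim_px = _chain_perimeter(boundary)

    corners = _corner_points(coords)
    hull = ConvexHull(corners)
    hull_xy = corners[hull.vertices]
    feret_px, min_feret_px = _calipers(hull_xy)
    hull_area_px = hull.volume  # 2-D hull: volume == area

    # Moment-equivalent ellipse; each pixel treated as a unit square (+1/12).
    var_r = cov[0, 0] + 1.0 / 12.0
    var_c = cov[1, 1] + 1.0 / 12.0
    cov_rc = cov[0, 1]
    # math orientation: x = col, y = -row
    sxy = -cov_rc
    common = math.hypot(var_c - var_r, 2.0 * sxy)
    lam1 = (var_c + var_r + common) / 2.0
    lam2 = (var_c + var_r - common) / 2.0
    major_px = 4.0 * math.sqrt(lam1)
    minor_px = 4.0 * math.sqrt(lam2)
    angle = math.degrees(0.5 * math.atan2(2.0 * sxy, var_c - var_r)) % 180.0

    res = resolution
    area_px = float(n)
    return {
        "area": area_px / res**2,
        "perimeter": perim_px / res,
        "width": (c1 - c0) / res,
        "height": (r1 - r0) / res,
        "feret": feret_px / res,
        "min_feret": min_feret_px / res,
        "major": major_px / res,
        "minor": minor_px / res,
        "angle": angle,
        "circularity": 4.0 * math.pi * area_px / perim_px**2,
        "aspect_ratio": major_px / minor_px,
        "roundness": 4.0 * area_px / (math.pi * major_px**2),
        "solidity": area_px / hull_area_px,
    }


# ---------------------------------------------------------------------------
# Color measurement


def measure_color(region: RegionMask, image: BatchImage) -> dict[str, float]:
    """Per-channel intensity statistics over the region's pixels.

    Population moments throughout; kurtosis is excess kurtosis; a
    zero-variance channel has skewness and kurtosis defined as 0.
    """
    rows, cols = region.coords[:, 0], region.coords[:, 1]
    h, w = image.pixels.shape[:2]
    if rows.max() >= h or cols.max() >= w:
        raise ImagingError("region extends beyond image bounds")
    out: dict[str, float] = {}
    n = len(rows)
    for idx, ch in enumerate(CHANNELS):
        vals = image.pixels[rows, cols, idx].astype(np.float64)
        mean = vals.mean()
        dev = vals - mean
        m2 = float((dev**2).mean())
        sd = math.sqrt(m2)
        if m2 > 0:
            skew = float((dev**3).mean()) / m2**1.5
            kurt = float((dev**4).mean()) / m2**2 - 3.0
        else:
            skew = kurt = 0.0
        out[f"{ch}_mean"] = float(mean)
        out[f"{ch}_sd"] = sd
        out[f"{ch}_integrated_density"] = n * float(mean)
        out[f"{ch}_skewness"] = skew
        out[f"{ch}_kurtosis"] = kurt
        out[f"{ch}_min"] = float(vals.min())
        out[f"{ch}_max"] = float(vals.max())
    return out


def measure_regions(
    image: BatchImage,
    threshold_params: dict | None = None,
    min_area_px: int = 50,
) -> list[MeasuredRegion]:
    """Segment one batch image and measure every retained region."""
    mask = binarize(image, threshold_params)
    regions = find_regions(mask, min_area_px=min_area_px)
    return [
        MeasuredRegion(
            region=reg,
            shape=measure_shape(reg, image.resolution),
            color=measure_color(reg, image),
            image_id=image.image_id,
        )
        for reg in regions
    ]


# ---------------------------------------------------------------------------
# Dorsal/ventral pairing


def pair_views(
    dorsal_regions: list[MeasuredRegion],
    ventral_regions: list[MeasuredRegion],
    ventral_image_width: int,
    event_id: str = "event",
) -> list[SpecimenFeatureVector]:
    """Match dorsal to ventral regions and emit 68-feature specimen vectors.

    The ventral image is the physical mirror of the dorsal layout, so ventral
    centroids are mirrored horizontally before a one-to-one assignment that
    minimizes total centroid distance.  A count mismatch raises an error
    naming the unmatched regions rather than dropping them silently.
    """
    nd, nv = len(dorsal_regions), len(ventral_regions)
    d_cent = np.array([m.region.centroid for m in dorsal_regions], dtype=float)
    v_cent = np.array([m.region.centroid for m in ventral_regions], dtype=float)
    if nv:
        v_cent = v_cent.copy()
        v_cent[:, 1] = (ventral_image_width - 1) - v_cent[:, 1]
    if nd == 0 or nv == 0 or nd != nv:
        k = min(nd, nv)
        matched_d: set[int] = set()
        matched_v: set[int] = set()
        if k:
            cost = np.linalg.norm(d_cent[:, None, :] - v_cent[None, :, :], axis=-1)
            ri, ci = linear_sum_assignment(cost)
            matched_d, matched_v = set(ri.tolist()), set(ci.tolist())
        lost_d = [m.region.label_id for i, m in enumerate(dorsal_regions) if i not in matched_d]
        lost_v = [m.region.label_id for i, m in enumerate(ventral_regions) if i not in matched_v]
        raise ImagingError(
            f"dorsal/ventral region count mismatch ({nd} vs {nv}); "
            f"unmatched dorsal regions {lost_d}, unmatched ventral regions {lost_v}"
        )
    cost = np.linalg.norm(d_cent[:, None, :] - v_cent[None, :, :], axis=-1)
    ri, ci = linear_sum_assignment(cost)
    order = np.argsort(ri)
    vectors = []
    for k, (di, vi) in enumerate(zip(ri[order], ci[order]), start=1):
        dm, vm = dorsal_regions[di], ventral_regions[vi]
        feats = {f"dorsal_{k2}": v for k2, v in dm.variables().items()}
        feats.update({f"ventral_{k2}": v for k2, v in vm.variables().items()})
        vectors.append(
            SpecimenFeatureVector(
                specimen_id=f"{event_id}_{k:03d}",
                features=feats,
                provenance={
                    "dorsal_image": dm.image_id,
                    "ventral_image": vm.image_id,
                    "dorsal_label": dm.region.label_id,
                    "ventral_label": vm.region.label_id,
                    "dorsal_centroid": dm.region.centroid,
                    "ventral_centroid": vm.region.centroid,
                },
            )
        )
    return vectors


def extract_event(
    dorsal: BatchImage,
    ventral: BatchImage,
    threshold_params: dict | None = None,
    min_area_px: int = 50,
    event_id: str | None = None,
) -> list[SpecimenFeatureVector]:
    """Full per-event pipeline: segment, measure and pair both views."""
    if event_id is None:
        event_id = dorsal.image_id.removesuffix("_dorsal") or "event"
    d_meas = measure_regions(dorsal, threshold_params, min_area_px)
    v_meas = measure_regions(ventral, threshold_params, min_area_px)
    return pair_views(d_meas, v_meas, ventral.pixels.shape[1], event_id=event_id)


def vectors_to_frame(vectors: list[SpecimenFeatureVector]):
    """Stack specimen vectors into a DataFrame in canonical column order."""
    import pandas as pd

    canon = feature_names()
    rows = [{"specimen_id": v.specimen_id, **v.features} for v in vectors]
    return pd.DataFrame(rows, columns=["specimen_id", *canon])


# re-export for introspection of the measurement schema
SHAPE_VARIABLES = SHAPE_VARS
COLOR_STATISTICS = COLOR_STATS
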