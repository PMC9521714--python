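"""Coordinate-based SMLM cluster analysis.

Detects high-density regions (HDRs) in 2D localization maps of synaptic
proteins.  The density cutoff is calibrated against a null obtained by
re-drawing the same number of localizations uniformly over the analysis
region: localizations whose neighbor count exceeds the null mean by a
configurable number of null standard deviations (default 2.5) are linked
into HDRs.  A companion routine delineates the postsynaptic density (PSD)
from the scaffold-marker channel by the same density construction, and HDR
centroids are classified as PSD-overlapping, peri-synaptic, or distal
relative to that outline.

All coordinates are in nanometres.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint, Point, Polygon

from ._linkage import link_components

log = logging.getLogger(__name__)

__all__ = [
    "LocalizationField",
    "DensityResult",
    "HDR",
    "HDRSet",
    "PsdOutline",
    "local_density",
    "randomization_null",
    "delineate_hdrs",
    "delineate_psd",
    "classify_hdr_positions",
]


@dataclass(frozen=True)
class LocalizationField:
    """A channel-tagged set of 2D localizations with an analysis ROI.

    Parameters
    ----------
    xy : (n, 2) array of coordinates in nm.
    channel : label of the imaging channel (e.g. ``"AKAP150"``, ``"PSD95"``).
    roi : analysis region polygon in nm; when ``None`` the convex hull of
        the localizations stands in (this fallback is logged by consumers
        that need an area).
    frame, uncertainty : optional per-localization metadata.
    n_rejected : localizations dropped at load (outside ROI / non-finite).
    """

    xy: np.ndarray
    channel: str = ""
    roi: Polygon | None = None
    frame: np.ndarray | None = None
    uncertainty: np.ndarray | None = None
    n_rejected: int = 0

    def __post_init__(self) -> None:
        xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        if xy.size and not np.all(np.isfinite(xy)):
            raise ValueError("localization coordinates must be finite")
        object.__setattr__(self, "xy", xy)
        if self.uncertainty is not None and np.any(np.asarray(self.uncertainty) < 0):
            raise ValueError("localization uncertainty must be >= 0")
        if self.roi is not None and len(xy):
            inside = shapely.intersects_xy(self.roi, xy[:, 0], xy[:, 1])
            if not np.all(inside):
                n_bad = int(np.sum(~inside))
                log.warning("%d localizations outside ROI rejected", n_bad)
                object.__setattr__(self, "xy", xy[inside])
                if self.frame is not None:
                    object.__setattr__(self, "frame", np.asarray(self.frame)[inside])
                if self.uncertainty is not None:
                    object.__setattr__(
                        self, "uncertainty", np.asarray(self.uncertainty)[inside]
                    )
                object.__setattr__(self, "n_rejected", self.n_rejected + n_bad)

    def __len__(self) -> int:
        return len(self.xy)

    def region(self) -> Polygon:
        """The randomization region: the ROI, else the convex hull."""
        if self.roi is not None:
            return self.roi
        if len(self.xy) < 3:
            raise ValueError("cannot derive a region from fewer than 3 points")
        log.info("no ROI supplied; using convex hull of localizations")
        hull = MultiPoint(self.xy).convex_hull
        if hull.area <= 0:
            raise ValueError("degenerate (zero-area) randomization region")
        return hull


@dataclass(frozen=True)
class DensityResult:
    """Per-localization neighbor counts plus the randomization-null cutoff."""

    radius: float
    counts: np.ndarray
    null_mean: float
    null_sd: float
    cutoff: float
    n_reps: int
    seed: int
    sd_multiplier: float = 2.5


@dataclass(frozen=True)
class HDR:
    """One delineated high-density region."""

    members: np.ndarray          # indices into the field's localizations
    centroid: tuple[float, float]
    diameter: float              # nm, area-equivalent circle of the hull
    n_points: int
    position_class: str | None = None  # psd-overlapping | peri-synaptic | distal


@dataclass(frozen=True)
class HDRSet:
    regions: tuple[HDR, ...]

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    @property
    def centroids(self) -> np.ndarray:
        return np.array([h.centroid for h in self.regions]).reshape(-1, 2)


@dataclass(frozen=True)
class PsdOutline:
    polygon: Polygon
    channel: str
    cutoff: float

    def __post_init__(self) -> None:
        if not self.polygon.is_valid or self.polygon.area <= 0:
            raise ValueError("PSD outline must be a simple polygon with area > 0")


def local_density(field: LocalizationField, radius: float) -> np.ndarray:
    """Number of other localizations within ``radius`` of each localization.

    The boundary is inclusive (distance <= radius) and the point itself is
    excluded.  Exactly equivalent to an all-pairs scan; a KD-tree is used
    for speed.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if len(field) == 0:
        raise ValueError("empty localization field")
    tree = cKDTree(field.xy)
    counts = tree.query_ball_point(field.xy, r=radius, return_length=True)
    return np.asarray(counts, dtype=int) - 1  # discount self


def _uniform_in_polygon(
    polygon: Polygon, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Rejection-sample ``n`` uniform points inside a polygon."""
    minx, miny, maxx, maxy = polygon.bounds
    out = np.empty((0, 2))
    # acceptance ratio bounded below by area/bbox-area
    frac = max(polygon.area / max((maxx - minx) * (maxy - miny), 1e-300), 1e-6)
    while len(out) < n:
        m = int((n - len(out)) / frac * 1.2) + 16
        cand = np.column_stack(
            [rng.uniform(minx, maxx, m), rng.uniform(miny, maxy, m)]
        )
        keep = shapely.contains_xy(polygon, cand[:, 0], cand[:, 1])
        out = np.vstack([out, cand[keep]])
    return out[:n]


def randomization_null(
    field: LocalizationField,
    radius: float,
    n_reps: int = 100,
    seed: int | None = None,
    sd_multiplier: float = 2.5,
) -> DensityResult:
    """Density cutoff from uniformly randomized localizations.

    For each replicate the same number of localizations is re-drawn
    uniformly over the field's region; per-localization neighbor counts are
    pooled across replicates and the cutoff set at
    ``null_mean + sd_multiplier * null_sd`` (2.5 by default).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if seed is None:
        raise ValueError("randomization requires an explicit seed")
    counts = local_density(field, radius)
    n = len(field)
    if n < 2:
        return DensityResult(radius, counts, 0.0, 0.0, 0.0, n_reps, seed, sd_multiplier)
    region = field.region()
    if region.area <= 0:
        raise ValueError("degenerate (zero-area) randomization region")
    rng = np.random.default_rng(seed)
    pooled = np.empty((n_reps, n), dtype=int)
    for rep in range(n_reps):
        pts = _uniform_in_polygon(region, n, rng)
        tree = cKDTree(pts)
        pooled[rep] = (
            np.asarray(tree.query_ball_point(pts, r=radius, return_length=True)) - 1
        )
    null_mean = float(pooled.mean())
    null_sd = float(pooled.std(ddof=1))
    cutoff = null_mean + sd_multiplier * null_sd
    return DensityResult(
        radius, counts, null_mean, null_sd, cutoff, n_reps, seed, sd_multiplier
    )


def _hull_diameter(points: np.ndarray) -> float:
    """Area-equivalent circle diameter of the convex hull of ``points``.

    Degenerate (collinear) member sets fall back to the maximum pairwise
    span so that the diameter stays positive.
    """
    hull = MultiPoint(points).convex_hull
    if hull.area > 0:
        return 2.0 * math.sqrt(hull.area / math.pi)
    d = float(hull.length)  # LineString/Point degenerate hull
    return max(d, 1e-9)


def delineate_hdrs(
    field: LocalizationField,
    density: DensityResult,
    link_radius: float | None = None,
    min_points: int = 10,
) -> HDRSet:
    """Link supra-cutoff localizations into high-density regions.

    Localizations with neighbor count strictly above the cutoff are linked
    into connected components at ``link_radius`` (default: the density
    radius); components with at least ``min_points`` members become HDRs.
    """
    if len(density.counts) != len(field):
        raise ValueError("density was not computed on this field")
    if link_radius is None:
        link_radius = density.radius
    supra = np.flatnonzero(density.counts > density.cutoff)
    regions: list[HDR] = []
    if len(supra):
        labels = link_components(field.xy[supra], link_radius)
        for lab in range(labels.max() + 1):
            members = supra[labels == lab]
            if len(members) < min_points:
                continue
            pts = field.xy[members]
            centroid = (float(pts[:, 0].mean()), float(pts[:, 1].mean()))
            regions.append(
                HDR(members, centroid, _hull_diameter(pts), len(members))
            )
    regions.sort(key=lambda h: (-h.n_points, h.centroid))
    return HDRSet(tuple(regions))


def delineate_psd(
    psd_field: LocalizationField,
    density_sd_cutoff: float = 2.0,
    radius: float = 50.0,
    n_reps: int = 100,
    seed: int | None = None,
    link_radius: float | None = None,
    concave_ratio: float = 0.5,
) -> PsdOutline:
    """Density-based outline of the PSD from the scaffold-marker channel.

    The channel is scored against its own uniform-randomization null at
    ``density_sd_cutoff`` standard deviations (default 2.0); the largest
    connected component of supra-cutoff localizations is enclosed by a
    concave hull.
    """
    if len(psd_field) == 0:
        raise ValueError("PSD channel is empty")
    density = randomization_null(
        psd_field, radius, n_reps=n_reps, seed=seed, sd_multiplier=density_sd_cutoff
    )
    supra = np.flatnonzero(density.counts > density.cutoff)
    if len(supra) < 3:
        raise ValueError("no supra-cutoff PSD localizations")
    if link_radius is None:
        link_radius = radius
    labels = link_components(psd_field.xy[supra], link_radius)
    sizes = np.bincount(labels)
    members = supra[labels == int(np.argmax(sizes))]
    pts = MultiPoint(psd_field.xy[members])
    poly = shapely.concave_hull(pts, ratio=concave_ratio)
    if not isinstance(poly, Polygon) or poly.area <= 0 or not poly.is_valid:
        poly = pts.convex_hull
    if not isinstance(poly, Polygon) or poly.area <= 0:
        raise ValueError("degenerate PSD outline")
    return PsdOutline(poly, psd_field.channel, density.cutoff)


def classify_hdr_positions(
    hdrs: HDRSet, psd: PsdOutline, peri_band: float = 100.0
) -> HDRSet:
    """Classify HDR centroids relative to the PSD outline.

    Inside the outline: ``psd-overlapping``; outside but within
    ``peri_band`` nm of its boundary: ``peri-synaptic``; else ``distal``.
    """
    if not psd.polygon.is_valid:
        raise ValueError("invalid PSD polygon")
    out: list[HDR] = []
    for h in hdrs:
        p = Point(h.centroid)
        if psd.polygon.covers(p):
            cls = "psd-overlapping"
        elif psd.polygon.exterior.distance(p) <= peri_band:
            cls = "peri-synaptic"
        else:
            cls = "distal"
        out.append(replace(h, position_class=cls))
    return HDRSet(tuple(out))
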