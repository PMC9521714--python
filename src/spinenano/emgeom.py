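"""Immunogold EM spatial statistics on annotated 2D membrane contours.

Works on per-spine annotations: a closed membrane contour (nm), an optional
PSD segment given as a contiguous vertex-index arc of that contour, gold
particle coordinates, and organelle records.  Provides particle-to-membrane
distances, zone assignment (synaptic / extrasynaptic / non-synaptic shaft /
cytoplasm), nearest-neighbor distances, single-linkage gold-cluster
detection, distance summaries with coefficient of variation, zone label
fractions, per-spine endosome label fractions, nonparametric group
comparisons, and an N- vs C-terminus conformation classifier.

Zones follow the standard immunogold convention for spine synapses: the
synaptic zone extends from the postsynaptic membrane under the PSD to
100 nm into the cytoplasm, the extrasynaptic zone covers any point within
100 nm of non-PSD spine membrane, and anything deeper is cytoplasm.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import shapely
from scipy import stats
from scipy.spatial import cKDTree
from shapely.geometry import LinearRing, LineString, Point, Polygon

from ._linkage import link_components

log = logging.getLogger(__name__)

ORGANELLE_KINDS = frozenset(
    {
        "large vesicle",
        "coated vesicle",
        "amorphous cistern",
        "tubular cistern",
        "MVB-tubule",
        "other",
    }
)

ZONES = ("synaptic", "extrasynaptic", "nonsynaptic-shaft", "cytoplasm", "outside")


@dataclass(frozen=True)
class MembraneContour:
    """Closed membrane polyline in nm, wound so the cytoplasm is inside."""

    vertices: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float).reshape(-1, 2)
        if self.closed and len(v) < 3:
            raise ValueError("a closed contour needs >= 3 vertices")
        seg = np.diff(np.vstack([v, v[:1]]) if self.closed else v, axis=0)
        if np.any(np.hypot(seg[:, 0], seg[:, 1]) <= 0):
            raise ValueError("zero-length contour segment")
        if self.closed and not LinearRing(v).is_valid:
            raise ValueError("self-intersecting contour")
        object.__setattr__(self, "vertices", v)

    def ring(self) -> LinearRing:
        return LinearRing(self.vertices)

    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    def cumulative_lengths(self) -> np.ndarray:
        """Arc-length position of each vertex along the (closed) contour."""
        v = self.vertices
        seg = np.hypot(*(np.roll(v, -1, axis=0) - v).T)
        return np.concatenate([[0.0], np.cumsum(seg)])  # length n+1; last = total

    @property
    def length(self) -> float:
        return float(self.ring().length)


@dataclass(frozen=True)
class PsdSegment:
    """Contiguous vertex-index arc of the contour occupied by the PSD."""

    start: int
    end: int  # inclusive vertex index; may wrap past vertex 0

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < 0:
            raise ValueError("PSD segment indices must be >= 0")


@dataclass(frozen=True)
class GoldParticle:
    x: float
    y: float
    id: int = 0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("gold particle coordinates must be finite")


@dataclass(frozen=True)
class OrganelleRecord:
    id: int
    kind: str
    labeled: bool

    def __post_init__(self) -> None:
        if self.kind not in ORGANELLE_KINDS:
            raise ValueError(f"unknown organelle kind: {self.kind!r}")


@dataclass(frozen=True)
class SpineAnnotation:
    """One annotated spine / synapse cross-section (all units nm)."""

    contour: MembraneContour
    psd: PsdSegment | None = None
    particles: tuple[GoldParticle, ...] = ()
    organelles: tuple[OrganelleRecord, ...] = ()
    compartment: str = "spine"  # or "dendrite-shaft"

    def __post_init__(self) -> None:
        if self.compartment not in ("spine", "dendrite-shaft"):
            raise ValueError("compartment must be 'spine' or 'dendrite-shaft'")
        object.__setattr__(self, "particles", tuple(self.particles))
        object.__setattr__(self, "organelles", tuple(self.organelles))

    def particle_xy(self) -> np.ndarray:
        return np.array([[p.x, p.y] for p in self.particles]).reshape(-1, 2)

    def psd_arc_interval(self) -> tuple[float, float]:
        """PSD arc as an arc-length interval [s0, s1] (s1 may exceed the
        contour length when the arc wraps past vertex 0)."""
        if self.psd is None:
            raise ValueError("annotation has no PSD segment")
        cum = self.contour.cumulative_lengths()
        total = cum[-1]
        s0 = cum[self.psd.start]
        s1 = cum[self.psd.end]
        if s1 < s0:
            s1 += total
        if s1 <= s0:
            raise ValueError("PSD arc length must be > 0")
        return float(s0), float(s1)


@dataclass(frozen=True)
class DistanceSummary:
    n: int
    mean: float
    sd: float
    median: float
    p25: float
    p75: float
    cv: float


@dataclass(frozen=True)
class GoldCluster:
    members: np.ndarray
    centroid: tuple[float, float]
    diameter: float  # nm, maximum pairwise member distance
    n_points: int


def point_to_contour_distance(
    p: Sequence[float] | np.ndarray, contour: MembraneContour
) -> float | np.ndarray:
    """Minimum Euclidean distance from point(s) to the contour polyline.

    Distances are point-to-segment, not vertex-only.  Accepts one point
    ``(x, y)`` or an ``(n, 2)`` array.
    """
    geom = contour.ring() if contour.closed else LineString(contour.vertices)
    arr = np.asarray(p, dtype=float)
    if arr.ndim == 1:
        return float(geom.distance(Point(arr)))
    pts = shapely.points(arr)
    return shapely.distance(pts, geom)


def _nearest_arc_position(p: Sequence[float], contour: MembraneContour) -> float:
    """Arc-length coordinate of the nearest contour point to ``p``."""
    return float(contour.ring().project(Point(p)))


def assign_zone(
    particle: GoldParticle | Sequence[float],
    annotation: SpineAnnotation,
    depth: float = 100.0,
) -> str:
    """Zone of a gold particle relative to the membrane contour.

    ``synaptic``: inside the contour, nearest membrane point on the PSD arc
    and within ``depth`` (100 nm default) of it.  ``extrasynaptic``: within
    ``depth`` of non-PSD spine membrane.  ``nonsynaptic-shaft``: the same
    for dendrite-shaft annotations.  ``cytoplasm``: deeper than ``depth``.
    ``outside``: not inside the contour.
    """
    if isinstance(particle, GoldParticle):
        xy = (particle.x, particle.y)
    else:
        xy = (float(particle[0]), float(particle[1]))
    poly = annotation.contour.polygon()
    if not poly.covers(Point(xy)):
        return "outside"
    d = point_to_contour_distance(xy, annotation.contour)
    if d > depth:
        return "cytoplasm"
    if annotation.compartment == "dendrite-shaft":
        return "nonsynaptic-shaft"
    if annotation.psd is None:
        raise ValueError(
            "synaptic/extrasynaptic assignment requires a PSD segment on spine "
            "annotations"
        )
    s = _nearest_arc_position(xy, annotation.contour)
    s0, s1 = annotation.psd_arc_interval()
    total = annotation.contour.length
    on_psd = s0 <= s <= s1 or s0 <= s + total <= s1
    return "synaptic" if on_psd else "extrasynaptic"


def zone_table(
    annotation: SpineAnnotation, depth: float = 100.0
) -> list[tuple[GoldParticle, str, float]]:
    """Per-particle (particle, zone, membrane distance) records."""
    out = []
    for p in annotation.particles:
        zone = assign_zone(p, annotation, depth=depth)
        d = float(point_to_contour_distance((p.x, p.y), annotation.contour))
        out.append((p, zone, d))
    return out


def nearest_neighbor_distances(
    points: np.ndarray, subset: np.ndarray | None = None
) -> np.ndarray:
    """Distance from each point to its nearest other point in the subset."""
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if subset is not None:
        points = points[np.asarray(subset)]
    if len(points) < 2:
        raise ValueError("nearest-neighbor distances need >= 2 points")
    dists, _ = cKDTree(points).query(points, k=2)
    return dists[:, 1]


def detect_gold_clusters(
    particles: np.ndarray | Iterable[GoldParticle],
    link_distance: float = 60.0,
    min_size: int = 4,
) -> tuple[GoldCluster, ...]:
    """Single-linkage gold-particle clusters.

    Components at ``link_distance`` (default 60 nm, about twice the ~30 nm
    minimum nearest-neighbor spacing seen for scaffold labels) with at
    least ``min_size`` members; the reported diameter is the maximum
    pairwise member distance.
    """
    if link_distance <= 0:
        raise ValueError("link_distance must be > 0")
    xy = (
        np.array([[p.x, p.y] for p in particles])
        if not isinstance(particles, np.ndarray)
        else particles
    ).reshape(-1, 2)
    if len(xy) == 0:
        return ()
    labels = link_components(xy, link_distance)
    clusters = []
    for lab in range(labels.max() + 1):
        members = np.flatnonzero(labels == lab)
        if len(members) < min_size:
            continue
        pts = xy[members]
        diff = pts[:, None, :] - pts[None, :, :]
        diameter = float(np.hypot(diff[..., 0], diff[..., 1]).max())
        clusters.append(
            GoldCluster(
                members,
                (float(pts[:, 0].mean()), float(pts[:, 1].mean())),
                diameter,
                len(members),
            )
        )
    clusters.sort(key=lambda c: -c.n_points)
    return tuple(clusters)


def summarize_distances(distances: Sequence[float]) -> DistanceSummary:
    """Mean, SD (n-1), median, quartiles, and CV of a distance sample."""
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("empty distance sample")
    mean = float(d.mean())
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    p25, med, p75 = (float(q) for q in np.percentile(d, [25, 50, 75]))
    cv = sd / mean if mean > 0 else 0.0
    return DistanceSummary(int(d.size), mean, sd, med, p25, p75, cv)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def zone_label_fractions(zone_counts: dict[str, int]) -> dict[str, dict[str, float]]:
    """Percentage of labels per zone.

    Returns per zone the raw percentage and its half-up integer rounding
    (the convention used in report tables).
    """
    total = sum(zone_counts.values())
    if total <= 0:
        raise ValueError("zone counts sum to zero")
    return {
        zone: {"raw": 100.0 * c / total, "percent": _round_half_up(100.0 * c / total)}
        for zone, c in zone_counts.items()
    }


def endosome_label_fraction(
    annotations: Iterable[SpineAnnotation],
) -> tuple[np.ndarray, float, float]:
    """Per-spine labeled-organelle percentage and the group mean +/- SD.

    Spines without organelle records are excluded (and logged).
    """
    per_spine = []
    n_excluded = 0
    for ann in annotations:
        if len(ann.organelles) == 0:
            n_excluded += 1
            continue
        labeled = sum(1 for o in ann.organelles if o.labeled)
        per_spine.append(100.0 * labeled / len(ann.organelles))
    if n_excluded:
        log.warning("%d spines without organelles excluded", n_excluded)
    if not per_spine:
        raise ValueError("no spine has organelle records")
    arr = np.asarray(per_spine)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return arr, float(arr.mean()), sd


def compare_groups(
    *groups: Sequence[float], test: str = "rank-sum"
) -> dict[str, object]:
    """Two-sided group comparison.

    ``rank-sum``: exact-when-possible Mann-Whitney U for two groups.
    ``kruskal-wallis``: omnibus Kruskal-Wallis, then pairwise rank-sum with
    Bonferroni adjustment.  ``anova-tukey``: one-way ANOVA with Tukey HSD
    pairwise adjusted p-values.
    """
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if test == "rank-sum":
        if len(arrays) != 2:
            raise ValueError("rank-sum compares exactly two groups")
        res = stats.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided")
        return {"test": test, "statistic": float(res.statistic), "p": float(res.pvalue)}
    if test == "kruskal-wallis":
        if len(arrays) < 2:
            raise ValueError("need >= 2 groups")
        res = stats.kruskal(*arrays)
        pairs = {}
        m = len(arrays) * (len(arrays) - 1) // 2
        for i in range(len(arrays)):
            for j in range(i + 1, len(arrays)):
                p = stats.mannwhitneyu(
                    arrays[i], arrays[j], alternative="two-sided"
                ).pvalue
                pairs[f"{i}-{j}"] = min(1.0, float(p) * m)
        return {
            "test": test,
            "statistic": float(res.statistic),
            "p": float(res.pvalue),
            "pairwise_p": pairs,
        }
    if test == "anova-tukey":
        res = stats.f_oneway(*arrays)
        tukey = stats.tukey_hsd(*arrays)
        pairs = {
            f"{i}-{j}": float(tukey.pvalue[i, j])
            for i in range(len(arrays))
            for j in range(i + 1, len(arrays))
        }
        return {
            "test": test,
            "statistic": float(res.statistic),
            "p": float(res.pvalue),
            "pairwise_p": pairs,
        }
    raise ValueError(f"unknown test: {test!r}")


def welch_p_from_summaries(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> float:
    """Two-sided Welch t-test p-value from summary statistics."""
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=False
    )
    return float(res.pvalue)


def conformation_classification(
    n_stats: tuple[float, float, int], c_stats: tuple[float, float, int]
) -> str:
    """Classify terminus geometry relative to the membrane.

    Takes ``(mean, sd, n)`` membrane-distance summaries for the N- and
    C-terminus labels.  ``vertical-extended`` when the C-terminus sits at
    least 1.5x farther from the membrane than the N-terminus with Welch
    p < 0.01; ``parallel-or-compact`` when the means are within 25% of each
    other or not significantly different (p >= 0.05); else
    ``indeterminate``.
    """
    mean_n, sd_n, n_n = n_stats
    mean_c, sd_c, n_c = c_stats
    if n_n < 10 or n_c < 10:
        raise ValueError("conformation call needs n >= 10 per terminus")
    if mean_n <= 0 or mean_c <= 0:
        raise ValueError("zero or negative mean distance")
    ratio = mean_c / mean_n
    if sd_n == 0 and sd_c == 0:
        p = 1.0 if mean_n == mean_c else 0.0
    else:
        p = welch_p_from_summaries(mean_c, sd_c, n_c, mean_n, sd_n, n_n)
    if ratio >= 1.5 and p < 0.01:
        return "vertical-extended"
    if 1.0 / 1.25 <= ratio <= 1.25 or p >= 0.05:
        return "parallel-or-compact"
    return "indeterminate"
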