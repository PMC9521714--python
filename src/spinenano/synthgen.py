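"""Seeded synthetic-data generators with ground truth.

Three generators emulate the statistical structure of the inputs the
analysis modules consume, so every stage of the pipeline can be exercised
and scored without any acquisition data:

* ``gen_smlm_synapse`` — a two-channel synapse localization field: a dense
  uniform disc of scaffold-marker (PSD) localizations, plus a target
  channel made of Poisson background and isotropic Gaussian nanocluster
  (HDR) blobs, typically placed peripherally just outside the PSD disc.
* ``gen_em_spine`` — an annotated spine cross-section: an elliptical
  membrane contour with a PSD arc, gold particles placed at truncated-
  normal inward offsets from zone-specific membrane stretches, and
  organelle records with Bernoulli labeled flags.
* ``gen_tracks`` — switching-state Brownian trajectories: per-step Markov
  state evolution over diffusion coefficients, geometric
  (photobleaching-like) track lengths, optional static localization error.

Every generator takes a mandatory seed and returns its ground truth, and
identical seeds give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from shapely.geometry import Polygon

from .emgeom import (
    GoldParticle,
    MembraneContour,
    OrganelleRecord,
    PsdSegment,
    SpineAnnotation,
)
from .smlm import LocalizationField
from .tracking import Track, TrackSet, stationary_distribution

__all__ = [
    "SmlmSimParams",
    "EmSimParams",
    "TrackSimParams",
    "gen_smlm_synapse",
    "gen_em_spine",
    "gen_tracks",
    "build_transition_matrix",
    "wt_reference_model",
    "cs_reference_model",
]

_MAX_POINTS = 10**7
_NM2_PER_UM2 = 1e6


# ---------------------------------------------------------------------------
# SMLM synapse fields


@dataclass(frozen=True, kw_only=True)
class SmlmSimParams:
    """Conditions for a two-channel synapse localization field (nm).

    Defaults describe a typical excitatory-synapse field: a 1 x 1 um ROI
    holding a 150 nm-radius PSD disc at 5000 localizations/um^2, three
    40 nm-sigma nanoclusters of 200 localizations each placed just outside
    the PSD, 200/um^2 background, and 10 nm localization uncertainty.
    """

    seed: int
    roi_width: float = 1000.0
    roi_height: float = 1000.0
    psd_center: tuple[float, float] = (500.0, 500.0)
    psd_radius: float = 150.0
    psd_density: float = 5000.0       # localizations/um^2
    n_hdrs: int = 3
    hdr_sigma: float = 40.0           # nm
    hdr_points: int = 200
    hdr_placement: str = "peripheral"  # or "uniform"
    background_density: float = 200.0  # localizations/um^2
    loc_uncertainty: float = 10.0      # nm
    blink_factor: float = 1.0          # mean localizations per emitter

    def __post_init__(self) -> None:
        if self.roi_width <= 0 or self.roi_height <= 0:
            raise ValueError("ROI dimensions must be > 0")
        if self.psd_radius <= 0:
            raise ValueError("psd_radius must be > 0")
        if min(self.psd_density, self.background_density) < 0:
            raise ValueError("densities must be >= 0")
        if self.n_hdrs < 0 or self.hdr_points < 0:
            raise ValueError("counts must be >= 0")
        if self.hdr_placement not in ("peripheral", "uniform"):
            raise ValueError("hdr_placement must be 'peripheral' or 'uniform'")
        if self.blink_factor < 1:
            raise ValueError("blink_factor must be >= 1")
        area_um2 = self.roi_width * self.roi_height / _NM2_PER_UM2
        expected = (
            (self.psd_density + self.background_density) * area_um2
            + self.n_hdrs * self.hdr_points
        ) * self.blink_factor
        if expected > _MAX_POINTS:
            raise ValueError("parameters would generate > 1e7 localizations")


def _blink_expand(
    xy: np.ndarray, params: SmlmSimParams, rng: np.random.Generator
) -> np.ndarray:
    """Duplicate emitters per the blink factor and add localization jitter.

    A blink factor of 1 (the default) means one localization per emitter;
    larger values add Poisson-distributed repeats.  Every localization gets
    independent Gaussian jitter of the stated uncertainty.
    """
    if len(xy) == 0:
        return xy
    if params.blink_factor > 1:
        reps = 1 + rng.poisson(params.blink_factor - 1, size=len(xy))
        xy = np.repeat(xy, reps, axis=0)
    if params.loc_uncertainty > 0:
        xy = xy + rng.normal(0.0, params.loc_uncertainty, size=xy.shape)
    return xy


def gen_smlm_synapse(
    params: SmlmSimParams,
) -> tuple[LocalizationField, LocalizationField, dict]:
    """Generate (PSD channel, target channel, ground truth).

    The PSD channel holds uniform localizations in the PSD disc at the
    stated density.  The target channel holds Poisson background over the
    ROI plus ``n_hdrs`` Gaussian clusters; with peripheral placement the
    cluster centers fall outside the PSD disc but within 100 nm of its
    boundary.  Ground truth records cluster centroids and per-localization
    provenance counts.
    """
    rng = np.random.default_rng(params.seed)
    area_um2 = params.roi_width * params.roi_height / _NM2_PER_UM2
    roi = Polygon(
        [
            (0.0, 0.0),
            (params.roi_width, 0.0),
            (params.roi_width, params.roi_height),
            (0.0, params.roi_height),
        ]
    )
    cx, cy = params.psd_center

    # PSD channel: uniform in disc
    psd_area_um2 = math.pi * params.psd_radius**2 / _NM2_PER_UM2
    n_psd = rng.poisson(params.psd_density * psd_area_um2)
    r = params.psd_radius * np.sqrt(rng.uniform(size=n_psd))
    th = rng.uniform(0, 2 * math.pi, size=n_psd)
    psd_xy = np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th)])
    psd_xy = _blink_expand(psd_xy, params, rng)

    # target channel: background + clusters
    n_bg = rng.poisson(params.background_density * area_um2)
    bg_xy = np.column_stack(
        [
            rng.uniform(0, params.roi_width, n_bg),
            rng.uniform(0, params.roi_height, n_bg),
        ]
    )
    centroids = np.empty((params.n_hdrs, 2))
    if params.hdr_placement == "peripheral":
        # arrayed around the PSD periphery: evenly spaced angles with
        # jitter, so planted clusters stay mutually distinct
        n = max(params.n_hdrs, 1)
        ang = (
            rng.uniform(0, 2 * math.pi)
            + 2 * math.pi * np.arange(params.n_hdrs) / n
            + rng.uniform(-0.15, 0.15, params.n_hdrs)
        )
        rad = params.psd_radius + rng.uniform(5.0, 95.0, params.n_hdrs)
        centroids[:, 0] = cx + rad * np.cos(ang)
        centroids[:, 1] = cy + rad * np.sin(ang)
    else:
        # planted clusters are kept distinct and inside the analyzed
        # region: 3 sigma margin from the ROI edge and >= 5 sigma mutual
        # separation, so each truth centroid marks one resolvable cluster
        mx = min(3.0 * params.hdr_sigma, params.roi_width / 4)
        my = min(3.0 * params.hdr_sigma, params.roi_height / 4)
        min_sep = 5.0 * params.hdr_sigma
        placed: list[np.ndarray] = []
        tries = 0
        while len(placed) < params.n_hdrs:
            cand = np.array(
                [
                    rng.uniform(mx, params.roi_width - mx),
                    rng.uniform(my, params.roi_height - my),
                ]
            )
            tries += 1
            if tries > 1000 * max(params.n_hdrs, 1):
                raise ValueError(
                    "cannot place distinct clusters; ROI too small for "
                    "n_hdrs at this hdr_sigma"
                )
            if placed and np.min(
                np.hypot(*(np.array(placed) - cand).T)
            ) < min_sep:
                continue
            placed.append(cand)
        centroids = np.array(placed).reshape(-1, 2)
    cluster_xy = [
        c + rng.normal(0.0, params.hdr_sigma, size=(params.hdr_points, 2))
        for c in centroids
    ]
    target_xy = np.vstack([bg_xy] + cluster_xy) if params.n_hdrs else bg_xy
    target_xy = _blink_expand(target_xy, params, rng)

    truth = {
        "hdr_centroids": centroids,
        "n_psd_emitters": int(n_psd),
        "n_background_emitters": int(n_bg),
        "n_cluster_emitters": int(params.n_hdrs * params.hdr_points),
    }
    psd_field = LocalizationField(psd_xy, channel="PSD95", roi=roi)
    target_field = LocalizationField(target_xy, channel="AKAP", roi=roi)
    return psd_field, target_field, truth


# ---------------------------------------------------------------------------
# EM spine annotations


@dataclass(frozen=True, kw_only=True)
class EmSimParams:
    """Conditions for an annotated spine cross-section (nm).

    The default contour is a 500 x 400 nm elliptical spine head with a
    300 nm PSD arc at the top.  Zone distance models are (mean, SD,
    (lo, hi)) truncated normals for the inward membrane offset; defaults
    are the synaptic 34 +/- 18 nm and extrasynaptic 13 +/- 5 nm immunogold
    offsets truncated to the 100 nm zone depth, with the 180:309 label
    split between zones.
    """

    seed: int
    head_width: float = 500.0
    head_height: float = 400.0
    n_contour_vertices: int = 256
    psd_arc_length: float = 300.0
    zone_distance_models: Mapping[str, tuple[float, float, tuple[float, float]]] = (
        field(
            default_factory=lambda: {
                "synaptic": (34.0, 18.0, (0.0, 100.0)),
                "extrasynaptic": (13.0, 5.0, (0.0, 100.0)),
            }
        )
    )
    zone_counts: Mapping[str, int] = field(
        default_factory=lambda: {"synaptic": 180, "extrasynaptic": 309}
    )
    organelle_count: int = 7
    organelle_labeled_fraction: float = 0.86
    compartment: str = "spine"

    def __post_init__(self) -> None:
        for zone, (mean, sd, (lo, hi)) in self.zone_distance_models.items():
            if mean < 0 or sd < 0 or lo < 0 or hi <= lo:
                raise ValueError(f"invalid distance model for zone {zone!r}")
        if any(c < 0 for c in self.zone_counts.values()):
            raise ValueError("zone counts must be >= 0")
        if not 0 <= self.organelle_labeled_fraction <= 1:
            raise ValueError("labeled fraction must be in [0, 1]")


def _ellipse_contour(params: EmSimParams) -> MembraneContour:
    n = params.n_contour_vertices
    th = np.linspace(0, 2 * math.pi, n, endpoint=False)
    a, b = params.head_width / 2.0, params.head_height / 2.0
    # counter-clockwise, starting at the rightmost point
    return MembraneContour(np.column_stack([a * np.cos(th), b * np.sin(th)]))


def _psd_segment(contour: MembraneContour, arc_length: float) -> PsdSegment:
    """Vertex range of the given arc length centered on the contour top."""
    cum = contour.cumulative_lengths()
    total = cum[-1]
    if arc_length >= total:
        raise ValueError("psd_arc_length exceeds contour length")
    v = contour.vertices
    top = int(np.argmax(v[:, 1]))
    s_top = cum[top]
    s0 = (s_top - arc_length / 2.0) % total
    s1 = (s_top + arc_length / 2.0) % total
    start = int(np.searchsorted(cum[:-1], s0, side="left")) % len(v)
    end = int(np.searchsorted(cum[:-1], s1, side="right") - 1) % len(v)
    return PsdSegment(start, end)


def _interp_on_contour(
    contour: MembraneContour, s: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Points and inward unit normals at arc positions ``s``."""
    v = contour.vertices
    cum = contour.cumulative_lengths()
    total = cum[-1]
    s = np.asarray(s) % total
    seg_idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(v) - 1)
    p0 = v[seg_idx]
    p1 = v[(seg_idx + 1) % len(v)]
    seg_len = cum[seg_idx + 1] - cum[seg_idx]
    t = ((s - cum[seg_idx]) / seg_len)[:, None]
    pts = p0 + t * (p1 - p0)
    tang = (p1 - p0) / seg_len[:, None]
    # CCW winding puts the interior to the left of the tangent
    normals = np.column_stack([-tang[:, 1], tang[:, 0]])
    # orient toward the centroid to be safe under either winding
    to_center = v.mean(axis=0)[None, :] - pts
    flip = np.sum(normals * to_center, axis=1) < 0
    normals[flip] *= -1
    return pts, normals


def gen_em_spine(params: EmSimParams) -> tuple[SpineAnnotation, dict]:
    """Generate an annotated spine with per-particle ground truth.

    Particles are placed by choosing a lateral position uniformly along
    the zone's membrane stretch (the PSD arc for the synaptic zone, its
    complement for the extrasynaptic zone) and stepping inward along the
    membrane normal by a truncated-normal offset.
    """
    rng = np.random.default_rng(params.seed)
    contour = _ellipse_contour(params)
    psd = _psd_segment(contour, params.psd_arc_length)
    cum = contour.cumulative_lengths()
    total = cum[-1]
    ann0 = SpineAnnotation(contour, psd)
    s0, s1 = ann0.psd_arc_interval()

    particles: list[GoldParticle] = []
    truth_rows: list[dict] = []
    pid = 0
    for zone, count in params.zone_counts.items():
        if count == 0:
            continue
        if zone not in params.zone_distance_models:
            raise ValueError(f"no distance model for zone {zone!r}")
        mean, sd, (lo, hi) = params.zone_distance_models[zone]
        a, b = (lo - mean) / sd, (hi - mean) / sd
        offsets = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=count,
                                      random_state=rng)
        # 2 nm lateral margin keeps ground-truth zones off the knife edge
        # where projection round-off could flip the assigned arc
        m = 2.0
        if zone == "synaptic":
            s = rng.uniform(s0 + m, s1 - m, size=count)
        else:
            s = (rng.uniform(s1 + m, s0 + total - m, size=count)) % total
        pts, normals = _interp_on_contour(contour, s)
        xy = pts + offsets[:, None] * normals
        for (x, y), d in zip(xy, offsets):
            particles.append(GoldParticle(float(x), float(y), id=pid))
            truth_rows.append({"id": pid, "zone": zone, "offset": float(d)})
            pid += 1

    kinds = sorted(
        {"large vesicle", "coated vesicle", "amorphous cistern", "tubular cistern"}
    )
    organelles = tuple(
        OrganelleRecord(
            id=i,
            kind=kinds[rng.integers(len(kinds))],
            labeled=bool(rng.uniform() < params.organelle_labeled_fraction),
        )
        for i in range(params.organelle_count)
    )
    annotation = SpineAnnotation(
        contour, psd, tuple(particles), organelles, params.compartment
    )
    truth = {
        "particles": truth_rows,
        "zone_counts": dict(params.zone_counts),
        "n_labeled_organelles": sum(1 for o in organelles if o.labeled),
    }
    return annotation, truth


# ---------------------------------------------------------------------------
# Switching-diffusion trajectories


@dataclass(frozen=True, kw_only=True)
class TrackSimParams:
    """Conditions for switching-state Brownian trajectories.

    ``D`` in um^2/s, ``A`` a per-time-step transition matrix, frame
    interval ``dt`` (0.022 s default), per-coordinate localization error in
    um, and a geometric track-length law with the given mean number of
    steps (minimum 2 positions), mimicking photobleaching-limited tracks.
    """

    seed: int
    D: Sequence[float]
    A: np.ndarray
    dt: float = 0.022
    loc_error: float = 0.0
    n_tracks: int = 1000
    mean_track_len: float = 6.0
    confinement_radius: float | None = None

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        A = np.asarray(self.A, dtype=float)
        if np.any(D < 0):
            raise ValueError("diffusion coefficients must be >= 0")
        if A.shape != (len(D), len(D)):
            raise ValueError("A must be K x K for K states")
        if not np.allclose(A.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("A rows must sum to 1 within 1e-12")
        if np.any(A < 0):
            raise ValueError("A entries must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.mean_track_len < 1:
            raise ValueError("mean_track_len must be >= 1")
        object.__setattr__(self, "D", D)
        object.__setattr__(self, "A", A)


def gen_tracks(params: TrackSimParams) -> tuple[TrackSet, list[np.ndarray]]:
    """Simulate switching-diffusion trajectories with ground-truth states.

    Initial state drawn from the stationary distribution of ``A``; the
    state evolves by ``A`` each step; per-coordinate displacements are
    Gaussian with variance ``2 D dt``; observed positions carry optional
    independent Gaussian localization error; lengths are geometric with
    the configured mean, clipped to >= 2 positions.  With a confinement
    radius, positions reflect at a disc boundary centered at the origin.
    """
    rng = np.random.default_rng(params.seed)
    D = np.asarray(params.D)
    A = np.asarray(params.A)
    K = len(D)
    pi = stationary_distribution(A) if K > 1 else np.ones(1)
    sigma = np.sqrt(2.0 * D * params.dt)

    # geometric number of steps (>= 1), i.e. >= 2 positions per track
    n_steps_all = rng.geometric(1.0 / params.mean_track_len, size=params.n_tracks)

    tracks: list[Track] = []
    states: list[np.ndarray] = []
    for i, n_steps in enumerate(n_steps_all):
        n_steps = int(n_steps)
        st = np.empty(n_steps, dtype=int)
        st[0] = rng.choice(K, p=pi)
        for t in range(1, n_steps):
            st[t] = rng.choice(K, p=A[st[t - 1]])
        steps = rng.normal(size=(n_steps, 2)) * sigma[st][:, None]
        pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        if params.confinement_radius is not None:
            pos = _reflect_disc(pos, params.confinement_radius)
        obs = pos
        if params.loc_error > 0:
            obs = pos + rng.normal(0.0, params.loc_error, size=pos.shape)
        tracks.append(
            Track(str(i), np.arange(len(obs)), obs, dt=params.dt)
        )
        states.append(st)
    return TrackSet(tuple(tracks), dt=params.dt), states


def _reflect_disc(pos: np.ndarray, radius: float) -> np.ndarray:
    """Radially reflect positions that left a disc centered at the origin."""
    out = pos.copy()
    r = np.hypot(out[:, 0], out[:, 1])
    over = r > radius
    if np.any(over):
        scale = (2 * radius - r[over]) / r[over]
        out[over] *= np.clip(scale, 0.0, None)[:, None]
    return out


# ---------------------------------------------------------------------------
# Transition-matrix construction


def build_transition_matrix(
    pi: Sequence[float], stay: Sequence[float | None]
) -> np.ndarray:
    """Row-stochastic matrix with given stationary occupancies and diagonal.

    Off-diagonal entries are solved from detailed balance: the symmetric
    probability flows ``F_ij = pi_i A_ij = pi_j A_ji`` must absorb each
    state's escape flow ``pi_i (1 - stay_i)``.  For two states one stay
    probability may be ``None`` (it is then determined); for three states
    the flow system is fully determined by the three stays.  Occupancies
    summing to 1 within +/- 0.02 are renormalized (and the adjustment
    logged).
    """
    import logging

    pi_arr = np.asarray(pi, dtype=float)
    if np.any(pi_arr <= 0):
        raise ValueError("occupancies must be > 0")
    s = pi_arr.sum()
    if abs(s - 1.0) > 0.02:
        raise ValueError("occupancies must sum to 1 within 0.02")
    if abs(s - 1.0) > 1e-12:
        logging.getLogger(__name__).info(
            "renormalizing occupancies summing to %.4f", s
        )
        pi_arr = pi_arr / s
    K = len(pi_arr)
    stay = list(stay)
    if len(stay) != K:
        raise ValueError("stay must have one entry per state")
    for v in stay:
        if v is not None and not (0.0 <= v < 1.0):
            raise ValueError("stay probabilities must be in [0, 1)")
    if K == 1:
        return np.ones((1, 1))
    if K == 2:
        known = [i for i, v in enumerate(stay) if v is not None]
        if len(known) == 0:
            raise ValueError("need at least one stay probability for 2 states")
        i = known[0]
        j = 1 - i
        flow = pi_arr[i] * (1.0 - stay[i])
        if len(known) == 2:
            flow_j = pi_arr[j] * (1.0 - stay[j])
            if not math.isclose(flow, flow_j, rel_tol=1e-9, abs_tol=1e-12):
                raise ValueError("(pi, stay) infeasible: unbalanced 2-state flows")
        a_ji = flow / pi_arr[j]
        if a_ji >= 1.0:
            raise ValueError("(pi, stay) infeasible: off-diagonal >= 1")
        A = np.empty((2, 2))
        A[i, i] = stay[i]
        A[i, j] = 1.0 - stay[i]
        A[j, i] = a_ji
        A[j, j] = 1.0 - a_ji
        return A
    if K == 3:
        if any(v is None for v in stay):
            raise ValueError("3-state construction needs all three stays")
        e = pi_arr * (1.0 - np.asarray(stay, dtype=float))
        # F12 + F13 = e1; F12 + F23 = e2; F13 + F23 = e3
        F12 = (e[0] + e[1] - e[2]) / 2.0
        F13 = (e[0] + e[2] - e[1]) / 2.0
        F23 = (e[1] + e[2] - e[0]) / 2.0
        if min(F12, F13, F23) < -1e-12:
            raise ValueError("(pi, stay) infeasible: negative flow")
        F = np.array([[0, F12, F13], [F12, 0, F23], [F13, F23, 0]])
        F = np.clip(F, 0.0, None)
        A = F / pi_arr[:, None]
        np.fill_diagonal(A, stay)
        if np.any(A < 0) or np.any(A > 1):
            raise ValueError("(pi, stay) infeasible: entries outside [0, 1]")
        return A / A.sum(axis=1, keepdims=True)
    raise ValueError("only K <= 3 supported")


def _detailed_balance_matrix(
    pi: Sequence[float], a12: float, a13: float, a32: float
) -> np.ndarray:
    """3-state matrix from occupancies plus three off-diagonal entries.

    The remaining off-diagonals follow from detailed balance
    ``pi_i A_ij = pi_j A_ji`` and the diagonals from row sums.
    """
    p = np.asarray(pi, dtype=float)
    p = p / p.sum()
    A = np.zeros((3, 3))
    A[0, 1], A[0, 2], A[2, 1] = a12, a13, a32
    A[1, 0] = p[0] * a12 / p[1]
    A[2, 0] = p[0] * a13 / p[2]
    A[1, 2] = p[2] * a32 / p[1]
    np.fill_diagonal(A, 1.0 - A.sum(axis=1))
    if np.any(np.diag(A) < 0):
        raise ValueError("infeasible printed entries: negative stay probability")
    return A


def wt_reference_model() -> dict:
    """Reference wild-type 3-state mobility model.

    Diffusion coefficients 0.02 / 0.12 / 0.47 um^2/s with occupancies
    0.11 / 0.62 / 0.28 (renormalized); bound->slow 0.10, bound->fast 0.05,
    fast->slow 0.39 per 22 ms step, remaining transitions closed by
    detailed balance.
    """
    pi = np.array([0.11, 0.62, 0.28])
    pi = pi / pi.sum()
    return {
        "D": np.array([0.02, 0.12, 0.47]),
        "pi": pi,
        "A": _detailed_balance_matrix(pi, a12=0.10, a13=0.05, a32=0.39),
        "dt": 0.022,
    }


def cs_reference_model() -> dict:
    """Reference palmitoylation-deficient (CS) 3-state mobility model.

    D 0.02 / 0.15 / 0.52 um^2/s (bound-state D shared with wild type),
    occupancies 0.11 / 0.55 / 0.34; bound->slow 0.24, bound->fast 0.05,
    fast->slow 0.27 per step.
    """
    pi = np.array([0.11, 0.55, 0.34])
    pi = pi / pi.sum()
    return {
        "D": np.array([0.02, 0.15, 0.52]),
        "pi": pi,
        "A": _detailed_balance_matrix(pi, a12=0.24, a13=0.05, a32=0.27),
        "dt": 0.022,
    }
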