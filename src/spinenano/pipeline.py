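"""Stage orchestration: run configured analyses and write a run report.

A :class:`RunConfig` names the stages to execute, their parameters, and a
seed registry; :func:`run_pipeline` runs the stages in dependency order,
writes every stage's outputs under the output directory, and returns a
:class:`RunReport` (also written as ``report.json``) that echoes the
configuration so a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import emgeom, io, smlm, synthgen, tracking

log = logging.getLogger(__name__)

KNOWN_STAGES = (
    "simulate-smlm",
    "simulate-em",
    "simulate-tracks",
    "hdr",
    "psd",
    "em-dist",
    "nnd",
    "clusters",
    "jumps",
    "hmm",
)


@dataclass
class RunConfig:
    """Parameters for one pipeline run.

    ``stages`` execute in the order given; each stage reads its parameters
    from ``params[stage]`` and every stochastic stage requires a seed there
    (or falls back to the global ``seed``).
    """

    stages: list[str] = field(default_factory=list)
    outdir: str = "spinenano_out"
    seed: int | None = None
    params: dict[str, dict[str, Any]] = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc)

    def stage_params(self, stage: str) -> dict[str, Any]:
        return dict(self.params.get(stage, {}))

    def stage_seed(self, stage: str) -> int:
        p = self.params.get(stage, {})
        seed = p.get("seed", self.seed)
        if seed is None:
            raise ValueError(f"stage {stage!r} needs a seed")
        return int(seed)


@dataclass
class RunReport:
    config: dict
    version: str
    stages: dict[str, dict] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "software_version": self.version,
                "config": self.config,
                "stages": self.stages,
                "warnings": self.warnings,
            },
            indent=2,
            default=_jsonable,
        )


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the configured stages and write outputs + report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=dataclasses.asdict(config), version=__version__)
    for stage in config.stages:
        if stage not in KNOWN_STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        runner = _STAGE_RUNNERS[stage]
        try:
            report.stages[stage] = runner(config, outdir, report)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    (outdir / "report.json").write_text(report.to_json())
    return report


# --- stage runners ---------------------------------------------------------


def _stage_simulate_smlm(config: RunConfig, outdir: Path, report: RunReport) -> dict:
    p = config.stage_params("simulate-smlm")
    p.setdefault("seed", config.stage_seed("simulate-smlm"))
    params = synthgen.SmlmSimParams(**p)
    psd_field, target_field, truth = synthgen.gen_smlm_synapse(params)
    io.write_localizations(psd_field, outdir / "psd_channel.csv")
    io.write_localizations(target_field, outdir / "target_channel.csv")
    io.write_roi(psd_field.roi, outdir / "roi.json")
    (outdir / "smlm_truth.json").write_text(json.dumps(truth, default=_jsonable))
    return {
        "params": dataclasses.asdict(params),
        "n_psd": len(psd_field),
        "n_target": len(target_field),
    }


def _stage_simulate_em(config: RunConfig, outdir: Path, report: RunReport) -> dict:
    p = config.stage_params("simulate-em")
    p.setdefault("seed", config.stage_seed("simulate-em"))
    params = synthgen.EmSimParams(**p)
    annotation, truth = synthgen.gen_em_spine(params)
    io.write_annotation(annotation, outdir / "spine_annotation.json")
    (outdir / "em_truth.json").write_text(json.dumps(truth, default=_jsonable))
    return {"n_particles": len(annotation.particles)}


def _stage_simulate_tracks(config: RunConfig, outdir: Path, report: RunReport) -> dict:
    p = config.stage_params("simulate-tracks")
    p.setdefault("seed", config.stage_seed("simulate-tracks"))
    model = p.pop("model", "wt")
    ref = (
        synthgen.wt_reference_model() if model == "wt"
        else synthgen.cs_reference_model()
    )
    p.setdefault("D", ref["D"])
    p.setdefault("A", ref["A"])
    p.setdefault("dt", ref["dt"])
    params = synthgen.TrackSimParams(**p)
    tracks, _states = synthgen.gen_tracks(params)
    io.write_tracks(tracks, outdir / "tracks.csv")
    return {"model": model, "n_tracks": len(tracks)}


def _stage_hdr(config: RunConfig, outdir: Path, report: RunReport) -> dict:
    p = config.stage_params("hdr")
    field_path = p.get("input", outdir / "target_channel.csv")
    roi_path = p.get("roi", outdir / "roi.json")
    roi = io.read_roi(roi_path) if Path(roi_path).exists() else None
    field = io.read_localizations(field_path, roi=roi)
    radius = p.get("radius", 50.0)
    density = smlm.randomization_null(
        field,
        radius,
        n_reps=p.get("n_reps", 100),
        seed=config.stage_seed("hdr"),
        sd_multiplier=p.get("sd_multiplier", 2.5),
    )
    hdrs = smlm.delineate_hdrs(
        field,
        density,
        link_radius=p.get("link_radius"),
        min_points=p.get("min_points", 10),
    )
    pd.DataFrame(
        {
            "count": density.counts,
            "x_nm": field.xy[:, 0],
            "y_nm": field.xy[:, 1],
        }
    ).to_csv(outdir / "density.csv", index=False)
    rows = [
        (i, h.centroid[0], h.centroid[1], h.diameter, h.n_points, h.position_class)
        for i, h in enumerate(hdrs)
    ]
    pd.DataFrame(
        rows,
        columns=["id", "centroid_x_nm", "centroid_y_nm", "diameter_nm",
                 "n_points", "class"],
    ).to_csv(outdir / "hdrs.csv", index=False)
    return {
        "n_hdrs": len(hdrs),
        "cutoff": density.cutoff,
        "null_mean": density.null_mean,
        "null_sd": density.null_sd,
    }


def _stage_psd(config: RunConfig, outdir: Path, report: RunReport) -> dict:
    p = config.stage_params("psd")
    field_path = p.get("input", outdir / "psd_channel.csv")
    roi_path = p.get("roi", outdir / "roi.json")
    roi = io.read_roi(roi_path) if Path(roi_path).exists() else None
    field = io.read_localizations(field_path, roi=roi)
    outline = smlm.delineate_psd(
        field,
        density_sd_cutoff=p.get("density_sd_cutoff", 2.0),
        radius=p.get("radius", 50.0),
        n_reps=p.get("n_reps", 100),
        seed=config.stage_seed("psd"),
    )
    io.write_roi(outline.polygon, outdir / "psd_outline.json")
    return {"area_nm2": outline.polygon.area, "cutoff": outline.cutoff}


def _stage_em_dist(config: RunConfig, outdir: Path, report: RunReport) -> dict:
    p = config.stage_params("em-dist")
    ann_path = p.get("input", outdir / "spine_annotation.json")
    annotation = io.read_annotation(ann_path)
    table = emgeom.zone_table(annotation, depth=p.get("depth", 100.0))
    rows = [(pt.id, pt.x, pt.y, zone, d) for pt, zone, d in table]
    pd.DataFrame(
        rows, columns=["id", "x_nm", "y_nm", "zone", "distance_nm"]
    ).to_csv(outdir / "particle_zones.csv", index=False)
    counts: dict[str, int] = {}
    for _, zone, _d in table:
        counts[zone] = counts.get(zone, 0) + 1
    membrane_zones = [z for z in ("synaptic", "extrasynaptic") if counts.get(z)]
    fractions = (
        emgeom.zone_label_fractions({z: counts[z] for z in membrane_zones})
        if membrane_zones
        else {}
    )
    summaries = {}
    for zone in membrane_zones:
        d = [dd for _, z, dd in table if z == zone]
        summaries[zone] = dataclasses.asdict(emgeom.summarize_distances(d))
    return {"zone_counts": counts, "zone_fractions": fractions,
            "summaries": summaries}


def _stage_nnd(config: RunConfig, outdir: Path, report: RunReport) -> dict:
    p = config.stage_params("nnd")
    ann_path = p.get("input", outdir / "spine_annotation.json")
    annotation = io.read_annotation(ann_path)
    xy = annotation.particle_xy()
    nnd = emgeom.nearest_neighbor_distances(xy)
    pd.DataFrame({"nnd_nm": nnd}).to_csv(outdir / "nnd.csv", index=False)
    return dataclasses.asdict(emgeom.summarize_distances(nnd))


def _stage_clusters(config: RunConfig, outdir: Path, report: RunReport) -> dict:
    p = config.stage_params("clusters")
    ann_path = p.get("input", outdir / "spine_annotation.json")
    annotation = io.read_annotation(ann_path)
    clusters = emgeom.detect_gold_clusters(
        annotation.particle_xy(),
        link_distance=p.get("link_distance", 60.0),
        min_size=p.get("min_size", 4),
    )
    rows = [
        (i, c.centroid[0], c.centroid[1], c.diameter, c.n_points)
        for i, c in enumerate(clusters)
    ]
    pd.DataFrame(
        rows, columns=["id", "centroid_x_nm", "centroid_y_nm", "diameter_nm",
                       "n_points"]
    ).to_csv(outdir / "gold_clusters.csv", index=False)
    return {"n_clusters": len(clusters)}


def _stage_jumps(config: RunConfig, outdir: Path, report: RunReport) -> dict:
    p = config.stage_params("jumps")
    tracks = io.read_tracks(
        p.get("input", outdir / "tracks.csv"), dt=p.get("dt", tracking.DEFAULT_DT)
    )
    jumps = tracking.compute_jumps(tracks)
    stats_ = tracking.jump_stats(
        jumps, short=p.get("short", 0.1), long=p.get("long", 0.2)
    )
    pd.DataFrame({"jump_um": jumps.magnitudes}).to_csv(
        outdir / "jumps.csv", index=False
    )
    (outdir / "jump_stats.json").write_text(
        json.dumps(dataclasses.asdict(stats_), default=_jsonable)
    )
    return dataclasses.asdict(stats_)


def _stage_hmm(config: RunConfig, outdir: Path, report: RunReport) -> dict:
    p = config.stage_params("hmm")
    tracks = io.read_tracks(
        p.get("input", outdir / "tracks.csv"), dt=p.get("dt", tracking.DEFAULT_DT)
    )
    model = tracking.fit_diffusion_hmm(
        tracks,
        k_max=p.get("k_max", 3),
        n_restarts=p.get("n_restarts", 10),
        tol=p.get("tol", 1e-8),
        max_iter=p.get("max_iter", 1000),
        seed=config.stage_seed("hmm"),
    )
    out = {
        "K": model.K,
        "D_um2_per_s": model.D.tolist(),
        "A": model.A.tolist(),
        "pi": model.pi.tolist(),
        "dwell_s": model.dwell.tolist(),
        "loglik": model.loglik,
        "bic": model.bic,
        "converged": model.converged,
        "seed": model.seed,
    }
    (outdir / "hmm.json").write_text(json.dumps(out, default=_jsonable))
    return out


_STAGE_RUNNERS = {
    "simulate-smlm": _stage_simulate_smlm,
    "simulate-em": _stage_simulate_em,
    "simulate-tracks": _stage_simulate_tracks,
    "hdr": _stage_hdr,
    "psd": _stage_psd,
    "em-dist": _stage_em_dist,
    "nnd": _stage_nnd,
    "clusters": _stage_clusters,
    "jumps": _stage_jumps,
    "hmm": _stage_hmm,
}
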