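"""File formats: localization CSV, track CSV, spine-annotation JSON.

Unit conventions follow each community's practice: localization and EM
annotation files are in nanometres, track files in micrometres.  The
localization reader accepts the native dialect (``x_nm``, ``y_nm``) and
the ThunderSTORM export dialect (``x [nm]``, ``y [nm]``).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, shape, mapping

from .emgeom import (
    GoldParticle,
    MembraneContour,
    OrganelleRecord,
    PsdSegment,
    SpineAnnotation,
)
from .smlm import LocalizationField
from .tracking import Track, TrackSet, DEFAULT_DT

log = logging.getLogger(__name__)

_NATIVE_COLS = {"x": "x_nm", "y": "y_nm", "frame": "frame",
                "uncertainty": "uncertainty_nm", "channel": "channel"}
_THUNDERSTORM_COLS = {"x": "x [nm]", "y": "y [nm]", "frame": "frame",
                      "uncertainty": "uncertainty [nm]", "channel": "channel"}


def read_localizations(
    path: str | Path,
    dialect: str = "auto",
    roi: Polygon | None = None,
    channel: str = "",
) -> LocalizationField:
    """Read a localization table (nm) in the native or ThunderSTORM dialect.

    Rows with non-finite coordinates are rejected and counted in the
    returned field's ``n_rejected``.
    """
    df = pd.read_csv(path)
    if dialect == "auto":
        if _NATIVE_COLS["x"] in df.columns:
            dialect = "native"
        elif _THUNDERSTORM_COLS["x"] in df.columns:
            dialect = "thunderstorm"
        else:
            raise ValueError(
                f"unrecognized localization header: {list(df.columns)!r}"
            )
    cols = _NATIVE_COLS if dialect == "native" else _THUNDERSTORM_COLS
    for key in ("x", "y"):
        if cols[key] not in df.columns:
            raise ValueError(f"missing required column {cols[key]!r}")
    x = pd.to_numeric(df[cols["x"]], errors="coerce")
    y = pd.to_numeric(df[cols["y"]], errors="coerce")
    ok = np.isfinite(x) & np.isfinite(y)
    n_rejected = int((~ok).sum())
    if n_rejected:
        log.warning("%d rows with invalid coordinates rejected", n_rejected)
    frame = None
    if cols["frame"] in df.columns:
        frame = pd.to_numeric(df[cols["frame"]], errors="coerce")[ok].to_numpy()
    unc = None
    if cols["uncertainty"] in df.columns:
        unc = pd.to_numeric(df[cols["uncertainty"]], errors="coerce")[ok].to_numpy()
    if not channel and cols["channel"] in df.columns:
        vals = df[cols["channel"]][ok].unique()
        channel = str(vals[0]) if len(vals) == 1 else ""
    return LocalizationField(
        np.column_stack([x[ok], y[ok]]),
        channel=channel,
        roi=roi,
        frame=frame,
        uncertainty=unc,
        n_rejected=n_rejected,
    )


def write_localizations(field: LocalizationField, path: str | Path) -> None:
    data = {"x_nm": field.xy[:, 0], "y_nm": field.xy[:, 1]}
    if field.frame is not None:
        data["frame"] = field.frame
    if field.uncertainty is not None:
        data["uncertainty_nm"] = field.uncertainty
    if field.channel:
        data["channel"] = field.channel
    pd.DataFrame(data).to_csv(path, index=False)


def read_roi(path: str | Path) -> Polygon:
    """Read an ROI polygon from GeoJSON-style or plain vertex-list JSON."""
    with open(path) as fh:
        data = json.load(fh)
    if isinstance(data, dict) and "type" in data:
        return shape(data)
    return Polygon(data)


def write_roi(polygon: Polygon, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(mapping(polygon), fh)


def read_tracks(path: str | Path, dt: float = DEFAULT_DT) -> TrackSet:
    """Assemble tracks from a CSV with track_id, frame, x_um, y_um.

    Tracks are sorted by frame; gapped tracks are split into gapless
    sub-tracks with suffixed ids (``7.1``, ``7.2`` ...), which is logged.
    Duplicate (track_id, frame) pairs are an error.
    """
    df = pd.read_csv(path)
    for col in ("track_id", "frame", "x_um", "y_um"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    if df.duplicated(["track_id", "frame"]).any():
        raise ValueError("duplicate (track_id, frame) pairs")
    tracks: list[Track] = []
    n_split = 0
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy(dtype=int)
        pos = grp[["x_um", "y_um"]].to_numpy(dtype=float)
        breaks = np.flatnonzero(np.diff(frames) != 1)
        pieces = np.split(np.arange(len(frames)), breaks + 1)
        if len(pieces) > 1:
            n_split += 1
        for j, idx in enumerate(pieces):
            if len(idx) < 2:
                continue
            tid_out = str(tid) if len(pieces) == 1 else f"{tid}.{j + 1}"
            tracks.append(Track(tid_out, frames[idx], pos[idx], dt=dt))
    if n_split:
        log.warning("%d gapped tracks split into gapless pieces", n_split)
    if not tracks:
        raise ValueError("no track with >= 2 gapless positions")
    return TrackSet(tuple(tracks), dt=dt)


def write_tracks(tracks: TrackSet, path: str | Path) -> None:
    rows = []
    for t in tracks:
        for f, (x, y) in zip(t.frames, t.positions):
            rows.append((t.id, int(f), x, y))
    pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um"]).to_csv(
        path, index=False
    )


ANNOTATION_SCHEMA_VERSION = 1


def write_annotation(annotation: SpineAnnotation, path: str | Path) -> None:
    """Write a spine annotation as versioned JSON (coordinates in nm)."""
    doc = {
        "schema_version": ANNOTATION_SCHEMA_VERSION,
        "compartment": annotation.compartment,
        "contour_nm": annotation.contour.vertices.tolist(),
        "psd": [annotation.psd.start, annotation.psd.end] if annotation.psd else None,
        "particles_nm": [
            {"id": p.id, "x": p.x, "y": p.y} for p in annotation.particles
        ],
        "organelles": [
            {"id": o.id, "kind": o.kind, "labeled": o.labeled}
            for o in annotation.organelles
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_annotation(path: str | Path) -> SpineAnnotation:
    with open(path) as fh:
        doc = json.load(fh)
    contour = MembraneContour(np.asarray(doc["contour_nm"], dtype=float))
    psd = PsdSegment(*doc["psd"]) if doc.get("psd") else None
    particles = tuple(
        GoldParticle(p["x"], p["y"], id=p.get("id", i))
        for i, p in enumerate(doc.get("particles_nm", []))
    )
    organelles = tuple(
        OrganelleRecord(o["id"], o["kind"], bool(o["labeled"]))
        for o in doc.get("organelles", [])
    )
    return SpineAnnotation(
        contour, psd, particles, organelles, doc.get("compartment", "spine")
    )
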