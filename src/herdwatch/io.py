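"""File interfaces: CSV tracks, TIFF rasters, GPX routes, YAML configs."""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from datetime import datetime, timezone

import numpy as np
import pandas as pd
import tifffile

from herdwatch.localize import ProbabilitySurface
from herdwatch.preprocess import RegularTrack
from herdwatch.synthetic import (SPECIES, TOD_BINS, IntrusionEvent, Landscape,
                                 RawSensorTrack, TrueTrack)

# local equirectangular anchor for GPX (projected meters <-> pseudo degrees)
_M_PER_DEG_LAT = 110574.0
_M_PER_DEG_LON = 111320.0


def save_model(obj, path, config_hash: str = "") -> None:
    """Serialize a fitted model object (reference set, PC stack, cluster
    model, classifier, detector) with a format version and config hash."""
    import pickle
    with open(path, "wb") as fh:
        pickle.dump({"format_version": 1, "config_hash": config_hash,
                     "model": obj}, fh)


def load_model(path, expect_config_hash: str | None = None):
    import pickle
    with open(path, "rb") as fh:
        blob = pickle.load(fh)
    if blob.get("format_version") != 1:
        raise ValueError(f"unsupported model file version: {blob.get('format_version')}")
    if expect_config_hash and blob.get("config_hash") != expect_config_hash:
        raise ValueError("model file was fitted under a different config")
    return blob["model"]


def spike_diagnostics_to_frame(diagnostics) -> pd.DataFrame:
    """Tabular spike report (one row per corrected fix) for CSV export."""
    from dataclasses import asdict
    return pd.DataFrame([asdict(d) for d in diagnostics])


def tracks_to_csv(tracks, path) -> None:
    pd.concat([t.to_frame() for t in tracks], ignore_index=True).to_csv(
        path, index=False)


def true_tracks_from_csv(path) -> list[TrueTrack]:
    df = pd.read_csv(path, parse_dates=["time"])
    return [TrueTrack.from_frame(g.reset_index(drop=True))
            for _, g in df.groupby("animal_id", sort=True)]


def regular_tracks_from_csv(path) -> list[RegularTrack]:
    df = pd.read_csv(path, parse_dates=["time"])
    return [RegularTrack.from_frame(g.reset_index(drop=True))
            for _, g in df.groupby("animal_id", sort=True)]


def sensor_track_to_frames(raw: RawSensorTrack):
    odba = raw.odba_windows.copy()
    odba.insert(0, "animal_id", raw.animal_id)
    return raw.to_frame(), odba


def landscape_to_tiff(landscape: Landscape, path) -> None:
    """Write all layers as a multi-band float32 TIFF.

    Georeferencing (origin, cell size) and band names travel in a JSON
    ImageDescription tag — a deliberately minimal GeoTIFF-style container
    that round-trips through :func:`landscape_from_tiff`.
    """
    bands = [landscape.tree_cover, landscape.elevation]
    names = ["tree_cover", "elevation"]
    for sp in SPECIES:
        for tod in TOD_BINS:
            key = (sp, tod)
            if key in landscape.suitability:
                bands.append(landscape.suitability[key])
                names.append(f"suitability:{sp}:{tod}")
    meta = {"origin": list(landscape.origin), "cell_size": landscape.cell_size,
            "bands": names}
    tifffile.imwrite(path, np.stack(bands).astype(np.float32),
                     description=json.dumps(meta))


def landscape_from_tiff(path) -> Landscape:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta = json.loads(tf.pages[0].description)
    named = dict(zip(meta["bands"], data.astype(float)))
    suit = {}
    for name, arr in named.items():
        if name.startswith("suitability:"):
            _, sp, tod = name.split(":")
            suit[(sp, tod)] = arr
    return Landscape(origin=tuple(meta["origin"]), cell_size=meta["cell_size"],
                     tree_cover=named["tree_cover"],
                     elevation=named["elevation"], suitability=suit)


def surface_to_tiff(surface: ProbabilitySurface, path) -> None:
    meta = {"origin": list(surface.origin), "cell_size": surface.cell_size,
            "alpha": surface.alpha, "time": surface.time}
    tifffile.imwrite(path, surface.density.astype(np.float32),
                     description=json.dumps(meta))


def surface_from_tiff(path) -> ProbabilitySurface:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray().astype(float)
        meta = json.loads(tf.pages[0].description)
    return ProbabilitySurface(origin=tuple(meta["origin"]),
                              cell_size=meta["cell_size"], density=data,
                              alpha=meta["alpha"], time=meta.get("time", 0.0))


def intrusion_to_gpx(event: IntrusionEvent, path) -> None:
    """Write the route as a GPX track (local equirectangular pseudo-degrees)."""
    gpx = ET.Element("gpx", version="1.1", creator="herdwatch")
    trk = ET.SubElement(gpx, "trk")
    ET.SubElement(trk, "name").text = event.intrusion_id
    ET.SubElement(trk, "type").text = event.mode
    seg = ET.SubElement(trk, "trkseg")
    for t, (x, y) in zip(event.route_times, event.route):
        pt = ET.SubElement(seg, "trkpt",
                           lat=f"{y / _M_PER_DEG_LAT:.8f}",
                           lon=f"{x / _M_PER_DEG_LON:.8f}")
        stamp = datetime.fromtimestamp(t, tz=timezone.utc)
        ET.SubElement(pt, "time").text = stamp.strftime("%Y-%m-%dT%H:%M:%SZ")
    ET.ElementTree(gpx).write(path, xml_declaration=True, encoding="unicode")


def intrusion_from_gpx(path, mode: str | None = None,
                       group_size: int = 1) -> IntrusionEvent:
    ns = {"g": "http://www.topografix.com/GPX/1/1"}
    root = ET.parse(path).getroot()
    # tolerate both namespaced and bare GPX
    trk = root.find("g:trk", ns) if root.find("g:trk", ns) is not None \
        else root.find("trk")
    find = (lambda el, tag: el.find(f"g:{tag}", ns)
            if el.find(f"g:{tag}", ns) is not None else el.find(tag))
    name_el = find(trk, "name")
    type_el = find(trk, "type")
    seg = find(trk, "trkseg")
    pts, times = [], []
    for pt in list(seg):
        pts.append([float(pt.attrib["lon"]) * _M_PER_DEG_LON,
                    float(pt.attrib["lat"]) * _M_PER_DEG_LAT])
        t_el = find(pt, "time")
        times.append(datetime.strptime(t_el.text, "%Y-%m-%dT%H:%M:%SZ")
                     .replace(tzinfo=timezone.utc).timestamp())
    return IntrusionEvent(
        intrusion_id=(name_el.text if name_el is not None else "gpx"),
        mode=mode or (type_el.text if type_el is not None else "foot"),
        group_size=group_size, t_start=times[0], t_end=times[-1],
        route=np.asarray(pts))
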