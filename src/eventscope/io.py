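"""Readers and writers: OME-TIFF stacks, event-log / feature / lineage CSV.

All tabular outputs are tidy CSV (one row per event, region or division);
image stacks are OME-TIFF with per-plane channel, simulated timestamp and
stage pose recorded in the OME metadata, one series per position.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .engine import EventLog
from .sample import SampleParams, init_colony


def write_frames_ome(frames, path) -> None:
    """Write a list of Frames for one position as an OME-TIFF stack."""
    if not frames:
        raise ValueError("no frames to write")
    stack = np.stack([f.pixels for f in frames])
    meta = {
        "axes": "TYX",
        "Description": json.dumps({"channels": [f.channel for f in frames]}),
        "Plane": {
            "DeltaT": [float(f.t_sim) for f in frames],
            "PositionX": [float(f.stage.x) for f in frames],
            "PositionY": [float(f.stage.y) for f in frames],
            "PositionZ": [float(f.stage.z) for f in frames],
        },
    }
    tifffile.imwrite(path, stack, ome=True, metadata=meta)


def read_frames_ome(path):
    """Read back pixels and per-plane metadata written by write_frames_ome.

    Returns (stack, channels, t_sim list, stage xyz array).
    """
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        import xml.etree.ElementTree as ET
        root = ET.fromstring(tf.ome_metadata)
        ns = {"ome": root.tag.split("}")[0].strip("{")}
        planes = root.findall(".//ome:Plane", ns)
        t_sim = [float(p.attrib["DeltaT"]) for p in planes]
        stage = np.array([[float(p.attrib["PositionX"]),
                           float(p.attrib["PositionY"]),
                           float(p.attrib["PositionZ"])] for p in planes])
        ann = root.findall(".//ome:Description", ns)
        channels = None
        for a in ann:
            if a.text:
                try:
                    channels = json.loads(a.text)["channels"]
                    break
                except (ValueError, KeyError):
                    continue
    return stack, channels, t_sim, stage


def write_label_stack(labels_list, path) -> None:
    """Ground-truth (or segmented) label masks as a 16-bit TIFF stack."""
    stack = np.stack([np.asarray(l) for l in labels_list]).astype(np.uint16)
    tifffile.imwrite(path, stack, photometric="minisblack")


def read_label_stack(path) -> np.ndarray:
    return tifffile.imread(path)


def eventlog_to_csv(log: EventLog, path) -> None:
    rows = [{"t_s": e.t_s, "kind": e.kind, "position_id": e.position_id,
             "data": json.dumps(e.data, sort_keys=True)} for e in log.events]
    pd.DataFrame(rows, columns=["t_s", "kind", "position_id", "data"]).to_csv(
        path, index=False)


def eventlog_from_csv(path) -> EventLog:
    df = pd.read_csv(path)
    log = EventLog()
    for _, row in df.iterrows():
        log.append(float(row.t_s), str(row.kind), int(row.position_id),
                   **json.loads(row.data))
    return log


def lineage_to_csv(state, path) -> None:
    """Division table: mother_id, daughter_id, division_time_s and the
    nuclear-separation onset the divisions were rendered with."""
    rows = [{"mother_id": r.mother_id, "daughter_id": r.daughter_id,
             "division_time_s": r.division_time_s,
             "sep_onset_time_s": r.sep_onset_time_s,
             "bud_start_time_s": r.bud_start_time_s} for r in state.lineage]
    pd.DataFrame(rows, columns=["mother_id", "daughter_id", "division_time_s",
                                "sep_onset_time_s", "bud_start_time_s"]
                 ).to_csv(path, index=False)


def features_to_csv(features: pd.DataFrame, path) -> None:
    features.to_csv(path, index=False)


def load_sim_config(path_or_text):
    """Build a SampleState from a simulator YAML config.

    Keys: chamber [x0,y0,x1,y1] um, seed, initial_count, open_side,
    tag_fraction, cycle_randomized, params {any SampleParams field}.
    """
    text = path_or_text
    p = Path(str(path_or_text))
    if p.exists():
        text = p.read_text()
    doc = yaml.safe_load(text) or {}
    allowed = {"chamber", "seed", "initial_count", "open_side", "tag_fraction",
               "cycle_randomized", "region", "params"}
    unknown = set(doc) - allowed
    if unknown:
        raise ValueError(f"simulator config: unknown key {sorted(unknown)[0]!r}")
    params = SampleParams(**(doc.get("params") or {}))
    return init_colony(
        n=int(doc.get("initial_count", 20)),
        chamber=tuple(doc.get("chamber", (-32, -32, 32, 32))),
        seed=int(doc.get("seed", 0)),
        params=params,
        tag_fraction=float(doc.get("tag_fraction", 0.0)),
        cycle_randomized=bool(doc.get("cycle_randomized", True)),
        region=tuple(doc["region"]) if "region" in doc else None,
        open_side=doc.get("open_side"),
    )
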