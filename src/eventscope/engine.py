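"""The scenario engine: YAML protocols, the acquisition loop, and triggers.

A *scenario* is an executable microscopy protocol: named multi-dimensional
acquisition (MDA) specs with per-position channel settings, a timeline of
scheduled device actions (valve switches, MDA changes, repeated every cycle
if asked), and conditional rules that convert real-time image features into
actions — switching the active MDA, actuating a valve, starting a tracked
single-cell timelapse, or running a temporary high-framerate "zoom" episode
on one position.

The engine runs against a simulated clock: acquisition and analysis take
zero simulated time and the sample advances only between scheduled acts, so
schedules are exact and runs are fully deterministic given the seeds.  The
append-only :class:`EventLog` records every acquisition, autofocus call,
stage move, valve switch, trigger and MDA transition, and is the primary
record a post-hoc analysis consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import segmentation as seg
from .devices import (BUD_LABEL_BASE, ChannelSettings, StagePose,
                      ValveRoute, VirtualMicroscope)
from .events import (ConditionSpec, TriggerRecord, auto_bud_a_min,
                     bud_a_min_from_regions, bud_mitosis_imminent,
                     eval_count_threshold, find_rfp_cell)
from .tracking import CellTracker, match_regions


class ScenarioError(ValueError):
    """Raised for schema violations; the message names the offending key."""


# ---------------------------------------------------------------------------
# scenario data model


@dataclass
class PositionSpec:
    id: int
    x: float
    y: float
    z: float = 0.0
    channels: list = field(default_factory=list)  # ordered ChannelSettings

    @property
    def pose(self) -> StagePose:
        return StagePose(self.x, self.y, self.z)


@dataclass
class MDASpec:
    name: str
    interval_s: float
    positions: list
    autofocus_enabled: bool = True

    def __post_init__(self):
        if not self.interval_s > 0:
            raise ScenarioError(f"mda.{self.name}.interval_s must be > 0")
        if not self.positions:
            raise ScenarioError(f"mda.{self.name}.positions must be nonempty")


@dataclass
class TimedAction:
    t_s: float
    action: dict                   # {"action": name, ...params}
    repeat_every_s: Optional[float] = None


@dataclass
class ConditionalRule:
    condition: ConditionSpec
    actions: list                  # list of action dicts


@dataclass
class Scenario:
    name: str
    mda: dict                      # name -> MDASpec
    initial_mda: str
    horizon_s: float
    timeline: list = field(default_factory=list)
    conditionals: list = field(default_factory=list)
    valves: list = field(default_factory=list)  # ValveRoute
    seeds: dict = field(default_factory=lambda: {"sample": 0, "noise": 0, "rng": 0})

    def __post_init__(self):
        self.seeds = {"sample": int(self.seeds.get("sample", 0)),
                      "noise": int(self.seeds.get("noise", 0)),
                      "rng": int(self.seeds.get("rng", 0))}
        if self.initial_mda not in self.mda:
            raise ScenarioError(f"initial_mda {self.initial_mda!r} is not a defined mda")
        for ta in self.timeline:
            name = ta.action.get("mda")
            if ta.action["action"] == "switch_mda" and name not in self.mda:
                raise ScenarioError(f"timeline references undefined mda {name!r}")
        for rule in self.conditionals:
            for act in rule.actions:
                name = act.get("mda")
                if act["action"] in ("switch_mda", "zoom", "follow_position") \
                        and name not in self.mda:
                    raise ScenarioError(
                        f"conditional action references undefined mda {name!r}")


# ---------------------------------------------------------------------------
# YAML parsing (strict: unknown keys are rejected with their path)

_TOP_KEYS = {"scenario_name", "mda", "initial_mda", "horizon_s", "seeds",
             "timeline", "conditionals", "valves"}
_MDA_KEYS = {"interval_s", "autofocus", "positions"}
_POS_KEYS = {"id", "x", "y", "z", "channels"}
_CH_KEYS = {"channel", "exposure_ms", "led_pct"}
_TIMED_KEYS = {"t_s", "action", "valve", "state", "mda", "repeat_every_s"}
_COND_KEYS = {"kind", "position_id", "repeating", "params", "actions"}
_ACT_KEYS = {"action", "valve", "state", "mda", "duration_s"}
_VALVE_KEYS = {"index", "chamber", "on_medium", "off_medium"}


def _check_keys(d: dict, allowed: set, path: str) -> None:
    if not isinstance(d, dict):
        raise ScenarioError(f"{path}: expected a mapping")
    unknown = set(d) - allowed
    if unknown:
        raise ScenarioError(f"{path}: unknown key {sorted(unknown)[0]!r}")


def parse_scenario(text: str) -> Scenario:
    """Parse and validate a scenario YAML document."""
    doc = yaml.safe_load(text)
    _check_keys(doc, _TOP_KEYS, "scenario")
    for req in ("scenario_name", "mda", "initial_mda", "horizon_s"):
        if req not in doc:
            raise ScenarioError(f"scenario: missing required key {req!r}")
    mdas = {}
    for name, m in doc["mda"].items():
        _check_keys(m, _MDA_KEYS, f"mda.{name}")
        positions = []
        for i, p in enumerate(m.get("positions", [])):
            _check_keys(p, _POS_KEYS, f"mda.{name}.positions[{i}]")
            channels = []
            for j, ch in enumerate(p.get("channels", [])):
                _check_keys(ch, _CH_KEYS, f"mda.{name}.positions[{i}].channels[{j}]")
                channels.append(ChannelSettings(
                    channel=ch["channel"],
                    exposure_ms=float(ch.get("exposure_ms", 150.0)),
                    led_intensity_pct=float(ch.get("led_pct", 100.0))))
            positions.append(PositionSpec(
                id=int(p["id"]), x=float(p.get("x", 0.0)),
                y=float(p.get("y", 0.0)), z=float(p.get("z", 0.0)),
                channels=channels))
        mdas[name] = MDASpec(name=name, interval_s=float(m["interval_s"]),
                             positions=positions,
                             autofocus_enabled=bool(m.get("autofocus", True)))
    timeline = []
    for i, ta in enumerate(doc.get("timeline", []) or []):
        _check_keys(ta, _TIMED_KEYS, f"timeline[{i}]")
        action = {k: ta[k] for k in ta if k not in ("t_s", "repeat_every_s")}
        timeline.append(TimedAction(t_s=float(ta["t_s"]), action=action,
                                    repeat_every_s=ta.get("repeat_every_s")))
    conditionals = []
    for i, c in enumerate(doc.get("conditionals", []) or []):
        _check_keys(c, _COND_KEYS, f"conditionals[{i}]")
        for j, a in enumerate(c.get("actions", [])):
            _check_keys(a, _ACT_KEYS, f"conditionals[{i}].actions[{j}]")
        conditionals.append(ConditionalRule(
            condition=ConditionSpec(kind=c["kind"],
                                    params=dict(c.get("params", {})),
                                    position_id=int(c.get("position_id", 0)),
                                    repeating=bool(c.get("repeating", False))),
            actions=[dict(a) for a in c.get("actions", [])]))
    valves = []
    for i, v in enumerate(doc.get("valves", []) or []):
        _check_keys(v, _VALVE_KEYS, f"valves[{i}]")
        valves.append(ValveRoute(index=int(v["index"]),
                                 chamber=int(v.get("chamber", 0)),
                                 on_medium=v.get("on_medium", "sucrose"),
                                 off_medium=v.get("off_medium", "glucose")))
    seeds = dict(doc.get("seeds", {}) or {})
    for k in seeds:
        if k not in ("sample", "noise", "rng"):
            raise ScenarioError(f"seeds: unknown key {k!r}")
    seeds = {"sample": int(seeds.get("sample", 0)),
             "noise": int(seeds.get("noise", 0)),
             "rng": int(seeds.get("rng", 0))}
    return Scenario(name=doc["scenario_name"], mda=mdas,
                    initial_mda=doc["initial_mda"],
                    horizon_s=float(doc["horizon_s"]), timeline=timeline,
                    conditionals=conditionals, valves=valves, seeds=seeds)


def serialize_scenario(sc: Scenario) -> str:
    """Serialize a Scenario back to its YAML document form."""
    doc = {
        "scenario_name": sc.name,
        "horizon_s": sc.horizon_s,
        "seeds": dict(sc.seeds),
        "initial_mda": sc.initial_mda,
        "mda": {
            name: {
                "interval_s": m.interval_s,
                "autofocus": m.autofocus_enabled,
                "positions": [
                    {"id": p.id, "x": p.x, "y": p.y, "z": p.z,
                     "channels": [{"channel": ch.channel,
                                   "exposure_ms": ch.exposure_ms,
                                   "led_pct": ch.led_intensity_pct}
                                  for ch in p.channels]}
                    for p in m.positions],
            } for name, m in sc.mda.items()},
    }
    if sc.timeline:
        doc["timeline"] = [
            {"t_s": ta.t_s, **ta.action,
             **({"repeat_every_s": ta.repeat_every_s}
                if ta.repeat_every_s is not None else {})}
            for ta in sc.timeline]
    if sc.conditionals:
        doc["conditionals"] = [
            {"kind": r.condition.kind, "position_id": r.condition.position_id,
             "repeating": r.condition.repeating,
             "params": dict(r.condition.params),
             "actions": [dict(a) for a in r.actions]}
            for r in sc.conditionals]
    if sc.valves:
        doc["valves"] = [
            {"index": v.index, "chamber": v.chamber, "on_medium": v.on_medium,
             "off_medium": v.off_medium} for v in sc.valves]
    return yaml.safe_dump(doc, sort_keys=False)


# ---------------------------------------------------------------------------
# event log


@dataclass
class Event:
    t_s: float
    kind: str
    position_id: int
    data: dict = field(default_factory=dict)


class EventLog:
    """Append-only, time-ordered record of everything the engine did.

    Timestamps are non-decreasing; simultaneous events (a valve switch and
    the frame it is synchronised with) keep their insertion order.
    """

    def __init__(self):
        self.events: list = []

    def append(self, t_s: float, kind: str, position_id: int = -1, **data):
        if self.events and t_s < self.events[-1].t_s - 1e-9:
            raise ValueError("event log must be time-ordered")
        self.events.append(Event(float(t_s), kind, int(position_id), data))

    def filter(self, kind: str, position_id: Optional[int] = None):
        return [e for e in self.events
                if e.kind == kind
                and (position_id is None or e.position_id == position_id)]

    def acquisition_times(self, position_id: Optional[int] = None,
                          channel: Optional[str] = None):
        return [e.t_s for e in self.filter("acquisition", position_id)
                if channel is None or e.data.get("channel") == channel]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [{"t_s": e.t_s, "kind": e.kind, "position_id": e.position_id,
                 **e.data} for e in self.events]
        return pd.DataFrame(rows)


@dataclass
class RunResult:
    log: EventLog
    features: pd.DataFrame
    tracks: pd.DataFrame
    frames: Optional[list]
    scenario: Scenario


# ---------------------------------------------------------------------------
# the runner


class _BudMonitor:
    """Per-position bookkeeping of bud-region area histories across frames.

    A region first seen as a bud candidate opens a bud track bound to its
    mother region, and keeps its identity while it persists, even after
    outgrowing the candidate filter.  With ``stable_labels`` (ground-truth
    masks) identity is the label itself, so a track ends exactly when the bud
    becomes a daughter cell; otherwise regions are matched frame to frame by
    proximity.
    """

    def __init__(self, stable_labels: bool = False):
        self.stable_labels = stable_labels
        self._prev_feats = None
        self._region_track = {}    # current label -> track key
        self._histories = {}       # track key -> {"areas": [...], "mother": label}
        self._next_key = 1

    def _open(self, f, new_map):
        key = self._next_key
        self._next_key += 1
        self._histories[key] = {"areas": [f.area_px], "mother": f.mother_label}
        new_map[f.label] = key

    def update(self, feats):
        new_map = {}
        if self.stable_labels:
            for f in feats:
                key = self._region_track.get(f.label)
                if key is not None:
                    self._histories[key]["areas"].append(f.area_px)
                    if f.mother_label is not None:
                        self._histories[key]["mother"] = f.mother_label
                    new_map[f.label] = key
                elif f.is_bud_candidate:
                    self._open(f, new_map)
        elif self._prev_feats is None:
            for f in feats:
                if f.is_bud_candidate:
                    self._open(f, new_map)
        else:
            assigned = match_regions(self._prev_feats, feats)
            for f in feats:
                prev_label = next((l0 for l0, l1 in assigned.items()
                                   if l1 == f.label), None)
                key = self._region_track.get(prev_label)
                if key is not None:
                    self._histories[key]["areas"].append(f.area_px)
                    if f.mother_label is not None:
                        self._histories[key]["mother"] = f.mother_label
                    new_map[f.label] = key
                elif f.is_bud_candidate:
                    self._open(f, new_map)
        self._region_track = new_map
        self._prev_feats = feats

    def firing_bud(self, a_min, k_frames: int, feats=None):
        """First bud track satisfying the mitosis rule, or None.

        ``a_min`` is a fixed px^2 threshold, or "auto" for the size-relative
        default (a fraction of the linked mother region's current area).
        """
        areas = {f.label: f.area_px for f in feats or []}
        for label, key in sorted(self._region_track.items()):
            h = self._histories[key]
            if a_min == "auto":
                if h["mother"] in areas:
                    thr = bud_a_min_from_regions(areas[h["mother"]],
                                                 h["areas"][-1])
                else:
                    thr = auto_bud_a_min(feats or [])
            else:
                thr = float(a_min)
            if bud_mitosis_imminent(h["areas"], thr, k_frames):
                return label, h["mother"]
        return None

    def forget(self, label):
        """Drop the history of a fired bud so it must re-qualify."""
        key = self._region_track.pop(label, None)
        if key is not None:
            self._histories.pop(key, None)


class ScenarioRunner:
    """Executes a :class:`Scenario` against a :class:`VirtualMicroscope`.

    ``seg_backend`` selects how frames are turned into label maps:
    ``"classical"`` runs the rule-based brightfield segmenter on the acquired
    pixels, ``"oracle"`` reads the simulator's ground-truth masks (used to
    test trigger/tracking semantics in isolation), or any callable
    ``Frame -> label map``.
    """

    def __init__(self, scenario: Scenario, microscope: VirtualMicroscope,
                 seg_backend="classical", seg_params=None,
                 label_buds: bool = False, keep_frames: bool = False,
                 compute_nls: bool = False, track_gate_px: Optional[float] = None):
        self.scenario = scenario
        self.mic = microscope
        self._oracle_labels = seg_backend == "oracle"
        # ground-truth masks with buds merged: every region is a whole cell
        self._size_flag_buds = not (self._oracle_labels and not label_buds)
        if seg_backend == "classical":
            self.backend = lambda fr: seg.segment_cells(fr, seg_params)
        elif seg_backend == "oracle":
            self.backend = seg.oracle_backend(microscope, label_buds=label_buds)
        else:
            self.backend = seg_backend
        self.keep_frames = keep_frames
        self.compute_nls = compute_nls
        self.rng = np.random.default_rng(scenario.seeds.get("rng", 0))
        self.log = EventLog()
        self.frames: list = []
        self._feature_rows: list = []
        self._track_rows: list = []
        self.tracker = CellTracker(microscope.camera, gate_px=track_gate_px)
        self._bud_monitors: dict = {}
        self._fired: set = set()
        self._episode: Optional[dict] = None
        self._recenter_offset: dict = {}   # position_id -> (dx_um, dy_um)
        self._track_position: Optional[int] = None

    # -- schedule state -------------------------------------------------
    def _reset_due(self, mda: MDASpec, t0: float):
        self._due = {p.id: t0 for p in mda.positions}

    def _expand_timeline(self, horizon: float):
        out = []
        for ta in self.scenario.timeline:
            t = ta.t_s
            if ta.repeat_every_s:
                while t <= horizon:
                    out.append((t, ta.action))
                    t += ta.repeat_every_s
            else:
                if t <= horizon:
                    out.append((t, ta.action))
        out.sort(key=lambda x: x[0])
        return out

    # -- main loop ------------------------------------------------------
    def run(self, horizon: Optional[float] = None) -> RunResult:
        sc = self.scenario
        horizon = sc.horizon_s if horizon is None else horizon
        for route in sc.valves:
            self.mic.valve_routes[route.index] = route
            while len(self.mic.valves.states) <= route.index:
                self.mic.valves.states.append(False)
        self.active_mda = sc.mda[sc.initial_mda]
        self._reset_due(self.active_mda, self.mic.t_sim)
        pending = self._expand_timeline(horizon)
        ti = 0
        while True:
            t_next = min(self._due.values()) if self._due else math.inf
            t_timed = pending[ti][0] if ti < len(pending) else math.inf
            if min(t_next, t_timed) >= horizon:
                break  # the horizon is exclusive: frames lie in [start, horizon)
            if t_timed <= t_next:
                self.mic.advance_to(t_timed)
                self._apply_action(pending[ti][1], t_timed, position_id=-1)
                ti += 1
                continue
            # earliest due position; ties follow MDA position order
            pos = next(p for p in self.active_mda.positions
                       if self._due[p.id] == t_next)
            self.mic.advance_to(t_next)
            self._visit(pos, t_next)
            if pos.id in self._due:
                self._due[pos.id] = t_next + self.active_mda.interval_s
            if self._episode is not None and self._episode["end_t"] < \
                    min(self._due.values(), default=math.inf):
                self._end_episode()
        features = pd.DataFrame(self._feature_rows)
        tracks = pd.DataFrame(self._track_rows)
        return RunResult(log=self.log, features=features, tracks=tracks,
                         frames=self.frames if self.keep_frames else None,
                         scenario=sc)

    # -- one position visit --------------------------------------------
    def _visit(self, pos: PositionSpec, t: float):
        mic = self.mic
        off = self._recenter_offset.get(pos.id, (0.0, 0.0))
        target = StagePose(pos.x + off[0], pos.y + off[1], pos.z)
        if (mic.pose.x, mic.pose.y, mic.pose.z) != (target.x, target.y, target.z):
            mic.move_stage(target)
            self.log.append(t, "stage_move", pos.id, x=target.x, y=target.y,
                            z=target.z)
        if self.active_mda.autofocus_enabled:
            mic.autofocus()
            self.log.append(t, "autofocus", pos.id, z=mic.pose.z)
        frames = {}
        bf_frame = None
        for ch in pos.channels:
            frame = mic.acquire(ch, position_id=pos.id)
            frames[ch.channel] = frame
            if ch.channel == "brightfield":
                bf_frame = frame
            self.log.append(t, "acquisition", pos.id, channel=ch.channel,
                            mda=self.active_mda.name,
                            exposure_ms=ch.exposure_ms,
                            led_pct=ch.led_intensity_pct,
                            autofocus=self.active_mda.autofocus_enabled)
            if self.keep_frames:
                self.frames.append(frame)
        if bf_frame is None:
            return
        labels = self.backend(bf_frame)
        feats = seg.extract_features(labels, frames,
                                     size_flag_buds=self._size_flag_buds)
        count = sum(1 for f in feats if not f.is_bud_candidate)
        self.log.append(t, "analysis", pos.id, count=count,
                        n_regions=len(feats))
        gfp = frames.get("GFP")
        for f in feats:
            row = {"t_s": t, "position_id": pos.id, "label": f.label,
                   "area_px": f.area_px, "cy": f.centroid[0],
                   "cx": f.centroid[1], "is_bud": f.is_bud_candidate,
                   "mother_label": f.mother_label}
            for chname, mean in f.mean_intensity.items():
                row[f"mean_{chname}"] = mean
            if self.compute_nls and gfp is not None and not f.is_bud_candidate:
                cell_mask = labels == f.label
                nuc = seg.top_quartile_nucleus_mask(cell_mask,
                                                    gfp.pixels.astype(float))
                row["nls"] = seg.nuclear_localization_score(
                    cell_mask, nuc, gfp.pixels.astype(float))
            self._feature_rows.append(row)
        # tracking + stage feedback
        if (self.tracker.track is not None and self.tracker.track.active
                and pos.id == self._track_position):
            feat = self.tracker.update(t, feats, bf_frame.pixels.astype(float),
                                       (mic.pose.x, mic.pose.y))
            if feat is not None:
                self._track_rows.append(
                    {"t_s": t, "position_id": pos.id, "label": feat.label,
                     "cy": feat.centroid[0], "cx": feat.centroid[1],
                     "area_px": feat.area_px})
                cmd = self.tracker.recenter_command()
                if cmd is not None:
                    dx, dy = cmd
                    off = self._recenter_offset.get(pos.id, (0.0, 0.0))
                    self._recenter_offset[pos.id] = (off[0] + dx, off[1] + dy)
                    self.log.append(t, "recenter", pos.id, dx_um=dx, dy_um=dy)
        self._eval_conditionals(pos, t, feats, labels, bf_frame, frames)

    # -- conditionals and actions ---------------------------------------
    def _eval_conditionals(self, pos, t, feats, labels, bf_frame, frames):
        # bud histories keep accumulating during zoom episodes (the zoom MDA
        # images the same position), but triggers stay suppressed
        if any(r.condition.kind == "bud_mitosis"
               and r.condition.position_id == pos.id
               for r in self.scenario.conditionals):
            self._bud_monitors.setdefault(
                pos.id, _BudMonitor(stable_labels=self._oracle_labels)
            ).update(feats)
        if self._episode is not None:
            return  # single-position exclusivity during a zoom episode
        for idx, rule in enumerate(self.scenario.conditionals):
            cond = rule.condition
            if cond.position_id != pos.id:
                continue
            key = (idx, pos.id)
            if key in self._fired and not cond.repeating:
                continue
            payload = None
            if cond.kind == "count_threshold":
                if eval_count_threshold(feats, int(cond.params["n"])):
                    payload = {"count": sum(1 for f in feats
                                            if not f.is_bud_candidate),
                               "n": int(cond.params["n"])}
            elif cond.kind == "rfp_positive":
                label = find_rfp_cell(feats,
                                      float(cond.params["intensity_threshold"]),
                                      self.rng)
                if label is not None:
                    payload = {"label": int(label)}
            elif cond.kind == "bud_mitosis":
                mon = self._bud_monitors[pos.id]
                hit = mon.firing_bud(cond.params["a_min_px"],
                                     int(cond.params.get("k_frames", 3)),
                                     feats=feats)
                if hit is not None:
                    payload = {"label": int(hit[0]),
                               "mother_label": (int(hit[1])
                                                if hit[1] is not None else -1)}
                    mon.forget(hit[0])
            if payload is None:
                continue
            self._fired.add(key)
            self.log.append(t, "trigger", pos.id, trigger=cond.kind, **payload)
            for act in rule.actions:
                self._apply_action(act, t, pos.id, payload=payload,
                                   feats=feats, bf_frame=bf_frame)

    def _apply_action(self, act: dict, t: float, position_id: int,
                      payload=None, feats=None, bf_frame=None):
        kind = act["action"]
        if kind == "set_valve":
            changed = len(self.mic.valves.switch_log)
            self.mic.set_valve(int(act["valve"]), bool(act["state"]))
            if len(self.mic.valves.switch_log) > changed:
                self.log.append(t, "valve", position_id,
                                valve=int(act["valve"]),
                                state=bool(act["state"]))
        elif kind == "switch_mda":
            self.active_mda = self.scenario.mda[act["mda"]]
            self._reset_due(self.active_mda, t)
            self.log.append(t, "mda_switch", position_id, mda=act["mda"])
        elif kind == "follow_position":
            template = self.scenario.mda[act["mda"]]
            pos = next(p for p in self.active_mda.positions
                       if p.id == position_id)
            follow = MDASpec(name=template.name,
                             interval_s=template.interval_s,
                             positions=[replace(pos,
                                                channels=template.positions[0].channels)],
                             autofocus_enabled=template.autofocus_enabled)
            self.active_mda = follow
            self._due = {pos.id: t + follow.interval_s}
            self.log.append(t, "mda_switch", position_id, mda=template.name,
                            follow=True)
        elif kind == "start_track":
            if payload and feats is not None and bf_frame is not None:
                self.tracker.start(t, payload["label"], feats,
                                   bf_frame.pixels.astype(float),
                                   (self.mic.pose.x, self.mic.pose.y))
                self._track_position = position_id
                feat = next(f for f in feats if f.label == payload["label"])
                self._track_rows.append(
                    {"t_s": t, "position_id": position_id,
                     "label": feat.label, "cy": feat.centroid[0],
                     "cx": feat.centroid[1], "area_px": feat.area_px})
                cmd = self.tracker.recenter_command()
                if cmd is not None:
                    dx, dy = cmd
                    off = self._recenter_offset.get(position_id, (0.0, 0.0))
                    self._recenter_offset[position_id] = (off[0] + dx,
                                                          off[1] + dy)
                    self.log.append(t, "recenter", position_id, dx_um=dx,
                                    dy_um=dy)
                self.log.append(t, "track_start", position_id,
                                label=payload["label"])
        elif kind == "zoom":
            template = self.scenario.mda[act["mda"]]
            pos = next(p for p in self.active_mda.positions
                       if p.id == position_id)
            zoom = MDASpec(name=template.name, interval_s=template.interval_s,
                           positions=[replace(pos,
                                              channels=template.positions[0].channels)],
                           autofocus_enabled=template.autofocus_enabled)
            self._episode = {"saved_mda": self.active_mda,
                             "end_t": t + float(act["duration_s"]),
                             "position_id": position_id}
            self.active_mda = zoom
            self._due = {pos.id: t + zoom.interval_s}
            self.log.append(t, "episode_start", position_id, mda=template.name,
                            duration_s=float(act["duration_s"]))
        else:
            raise ScenarioError(f"unknown action {kind!r}")

    def _end_episode(self):
        ep = self._episode
        self._episode = None
        end_t = ep["end_t"]
        self.log.append(end_t, "episode_end", ep["position_id"])
        self.active_mda = ep["saved_mda"]
        self._reset_due(self.active_mda, end_t + self.active_mda.interval_s)


def run(scenario: Scenario, microscope: VirtualMicroscope,
        horizon: Optional[float] = None, **runner_kwargs) -> RunResult:
    """Convenience wrapper: build a :class:`ScenarioRunner` and run it."""
    return ScenarioRunner(scenario, microscope, **runner_kwargs).run(horizon)
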