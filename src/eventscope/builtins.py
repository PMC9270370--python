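"""Built-in event-based protocols, as scenario factories.

Each factory returns a plain :class:`~eventscope.engine.Scenario`, so the
built-ins are ordinary protocols: they can be serialized to YAML, edited and
re-parsed.  The four cover the canonical closed-loop use cases:

* ``adaptive_stress`` — periodic osmotic stress with an acquisition burst
  synchronized to the valve: baseline one frame per 5 min, a 25 s-interval
  burst (12x faster) for the 4 min of fast Hog1 nuclear import with
  autofocus suspended, a 60 s-interval recovery for 20 min, then baseline
  until the next hourly cycle; the stress valve opens with the first burst
  frame and closes 30 min later.
* ``detect_and_track`` — scan until an RFP-positive cell appears, pick one
  at random, then follow it with per-frame stage recentering.
* ``count_and_switch`` — switch perfusion (glucose to sucrose) when the cell
  count in the field of view reaches a threshold.
* ``find_and_zoom`` — coarse 3 min brightfield search for a bud about to
  divide; on the trigger, image that position every 30 s with RFP added for
  20 min, then resume the coarse search.
"""

from __future__ import annotations

from .devices import ChannelSettings, ValveRoute
from .engine import (ConditionalRule, MDASpec, PositionSpec, Scenario,
                     TimedAction)
from .events import ConditionSpec

BF = ChannelSettings("brightfield", exposure_ms=50.0, led_intensity_pct=0.0)
GFP = ChannelSettings("GFP", exposure_ms=150.0, led_intensity_pct=100.0)
RFP = ChannelSettings("RFP", exposure_ms=150.0, led_intensity_pct=100.0)
# high-framerate episodes use a reduced LED intensity to limit photodose
ZOOM_RFP = ChannelSettings("RFP", exposure_ms=150.0, led_intensity_pct=10.0)


def _pos(pid, x=0.0, y=0.0, z=0.0, channels=(BF,)):
    return PositionSpec(id=pid, x=x, y=y, z=z, channels=list(channels))


def builtin_adaptive_stress(
    n_cycles: int = 3,
    cycle_period_s: float = 3600.0,
    first_stress_s: float = 900.0,
    baseline_interval_s: float = 300.0,
    burst_interval_s: float = 25.0,
    burst_duration_s: float = 240.0,
    recovery_interval_s: float = 60.0,
    recovery_duration_s: float = 1200.0,
    stress_duration_s: float = 1800.0,
    position: PositionSpec = None,
    valve_index: int = 0,
    seeds: dict = None,
) -> Scenario:
    """Adaptive-sampling osmotic-stress protocol (valve-synchronized burst)."""
    pos = position or _pos(0, channels=(BF, GFP))
    mda = {
        "baseline": MDASpec("baseline", baseline_interval_s, [pos], True),
        "burst": MDASpec("burst", burst_interval_s, [pos], False),
        "recovery": MDASpec("recovery", recovery_interval_s, [pos], True),
    }
    timeline = []
    for k in range(n_cycles):
        t0 = first_stress_s + k * cycle_period_s
        timeline += [
            TimedAction(t0, {"action": "set_valve", "valve": valve_index,
                             "state": True}),
            TimedAction(t0, {"action": "switch_mda", "mda": "burst"}),
            TimedAction(t0 + burst_duration_s,
                        {"action": "switch_mda", "mda": "recovery"}),
            TimedAction(t0 + burst_duration_s + recovery_duration_s,
                        {"action": "switch_mda", "mda": "baseline"}),
            TimedAction(t0 + stress_duration_s,
                        {"action": "set_valve", "valve": valve_index,
                         "state": False}),
        ]
    timeline.sort(key=lambda ta: ta.t_s)
    return Scenario(
        name="adaptive_stress",
        mda=mda, initial_mda="baseline",
        horizon_s=first_stress_s + n_cycles * cycle_period_s,
        timeline=timeline,
        valves=[ValveRoute(valve_index, chamber=0,
                           on_medium="sorbitol_stress", off_medium="glucose")],
        seeds=seeds or {},
    )


def builtin_detect_and_track(
    scan_positions=None,
    scan_interval_s: float = 180.0,
    follow_interval_s: float = 60.0,
    rfp_threshold: float = 160.0,
    horizon_s: float = 7200.0,
    seeds: dict = None,
) -> Scenario:
    """Scan for an RFP-tagged cell, then follow it with stage feedback."""
    positions = scan_positions or [_pos(0, channels=(BF, RFP))]
    mda = {
        "scan": MDASpec("scan", scan_interval_s, positions, True),
        "follow": MDASpec("follow", follow_interval_s,
                          [_pos(0, channels=(BF, RFP))], True),
    }
    rule = ConditionalRule(
        condition=ConditionSpec("rfp_positive",
                                {"intensity_threshold": rfp_threshold},
                                position_id=positions[0].id),
        actions=[{"action": "start_track"},
                 {"action": "follow_position", "mda": "follow"}])
    conditionals = [rule]
    for p in positions[1:]:
        conditionals.append(ConditionalRule(
            condition=ConditionSpec("rfp_positive",
                                    {"intensity_threshold": rfp_threshold},
                                    position_id=p.id),
            actions=[{"action": "start_track"},
                     {"action": "follow_position", "mda": "follow"}]))
    return Scenario(name="detect_and_track", mda=mda, initial_mda="scan",
                    horizon_s=horizon_s, conditionals=conditionals,
                    seeds=seeds or {})


def builtin_count_and_switch(
    thresholds,
    positions=None,
    interval_s: float = 180.0,
    horizon_s: float = 10800.0,
    shared_valve: bool = False,
    seeds: dict = None,
) -> Scenario:
    """Per-position count conditionals driving glucose-to-sucrose valves.

    ``thresholds`` maps position order to the cell count that triggers that
    position's valve (valve i routes to chamber i unless ``shared_valve``).
    """
    if positions is None:
        positions = [_pos(i, channels=(BF,)) for i in range(len(thresholds))]
    mda = {"count": MDASpec("count", interval_s, positions, True)}
    conditionals = []
    valves = []
    for i, (p, n) in enumerate(zip(positions, thresholds)):
        valve = 0 if shared_valve else i
        conditionals.append(ConditionalRule(
            condition=ConditionSpec("count_threshold", {"n": int(n)},
                                    position_id=p.id),
            actions=[{"action": "set_valve", "valve": valve, "state": True}]))
        if not shared_valve or i == 0:
            valves.append(ValveRoute(valve, chamber=i, on_medium="sucrose",
                                     off_medium="glucose"))
    return Scenario(name="count_and_switch", mda=mda, initial_mda="count",
                    horizon_s=horizon_s, conditionals=conditionals,
                    valves=valves, seeds=seeds or {})


def builtin_find_and_zoom(
    position: PositionSpec = None,
    coarse_interval_s: float = 180.0,
    zoom_interval_s: float = 30.0,
    zoom_duration_s: float = 1200.0,
    a_min_px="auto",
    k_frames: int = 3,
    horizon_s: float = 10800.0,
    seeds: dict = None,
) -> Scenario:
    """Coarse search for imminent mitosis; zoom in at 30 s with RFP added."""
    pos = position or _pos(0, channels=(BF,))
    mda = {
        "coarse": MDASpec("coarse", coarse_interval_s, [pos], True),
        "zoom": MDASpec("zoom", zoom_interval_s,
                        [_pos(0, channels=(BF, ZOOM_RFP))], True),
    }
    rule = ConditionalRule(
        condition=ConditionSpec("bud_mitosis",
                                {"a_min_px": a_min_px, "k_frames": k_frames},
                                position_id=pos.id, repeating=True),
        actions=[{"action": "zoom", "mda": "zoom",
                  "duration_s": zoom_duration_s}])
    return Scenario(name="find_and_zoom", mda=mda, initial_mda="coarse",
                    horizon_s=horizon_s, conditionals=[rule],
                    seeds=seeds or {})
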