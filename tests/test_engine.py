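"""Scenario parsing and the acquisition loop's scheduling semantics."""

import numpy as np
import pytest

from eventscope import (CameraConfig, ChannelSettings, MDASpec, PositionSpec,
                        Scenario, ScenarioError, ScenarioRunner,
                        VirtualMicroscope, parse_scenario, serialize_scenario)
from eventscope.builtins import (BF, GFP, builtin_adaptive_stress,
                                 builtin_count_and_switch,
                                 builtin_detect_and_track, _pos)

from conftest import make_colony

MINIMAL_YAML = """
scenario_name: minimal
horizon_s: 900
initial_mda: main
mda:
  main:
    interval_s: 300
    autofocus: false
    positions:
      - id: 0
        x: 0.0
        y: 0.0
        channels:
          - {channel: brightfield, exposure_ms: 50, led_pct: 0}
"""


class TestParsing:
    def test_minimal_document(self):
        sc = parse_scenario(MINIMAL_YAML)
        assert sc.name == "minimal"
        assert len(sc.mda["main"].positions) == 1
        assert sc.conditionals == []

    def test_unknown_key_rejected_with_its_name(self):
        bad = MINIMAL_YAML + "frame_rate: 10\n"
        with pytest.raises(ScenarioError, match="frame_rate"):
            parse_scenario(bad)

    def test_undefined_mda_reference_rejected_by_name(self):
        bad = MINIMAL_YAML + """
conditionals:
  - kind: count_threshold
    position_id: 0
    params: {n: 5}
    actions:
      - {action: switch_mda, mda: warp}
"""
        with pytest.raises(ScenarioError, match="warp"):
            parse_scenario(bad)

    def test_parse_serialize_parse_round_trip(self):
        sc1 = parse_scenario(MINIMAL_YAML)
        sc2 = parse_scenario(serialize_scenario(sc1))
        assert sc1 == sc2

    def test_builtins_survive_the_yaml_round_trip(self):
        for sc in (builtin_adaptive_stress(),
                   builtin_count_and_switch([20, 50])):
            assert parse_scenario(serialize_scenario(sc)) == sc


class TestScheduler:
    def test_three_positions_300s_over_1500s(self, camera):
        st = make_colony(4, seed=1, half_um=60.0)
        mic = VirtualMicroscope(st, camera, noise_seed=1)
        poss = [_pos(i, x=-40.0 + 40 * i, channels=[BF]) for i in range(3)]
        sc = Scenario(name="mda", mda={"m": MDASpec("m", 300.0, poss, False)},
                      initial_mda="m", horizon_s=1500.0)
        res = ScenarioRunner(sc, mic, seg_backend="oracle").run()
        for i in range(3):
            assert res.log.acquisition_times(i) == [0.0, 300.0, 600.0,
                                                    900.0, 1200.0]

    def test_adaptive_stress_schedule_and_valve_sync(self, camera):
        st = make_colony(8, seed=2, half_um=20.0)
        mic = VirtualMicroscope(st, camera, noise_seed=2)
        sc = builtin_adaptive_stress(n_cycles=1)
        res = ScenarioRunner(sc, mic, seg_backend="oracle").run(horizon=3000.0)
        acq = res.log.to_dataframe()
        acq = acq[(acq.kind == "acquisition") & (acq.channel == "brightfield")]
        for mda_name, expected in (("baseline", 300.0), ("burst", 25.0),
                                   ("recovery", 60.0)):
            ts = acq[acq.mda == mda_name].t_s.values
            assert len(ts) >= 2
            diffs = np.diff(ts)
            # within a phase the cadence is exact; baseline also shows the
            # gap where the stress cycle interleaves
            assert np.median(diffs) == expected
            assert all(d == expected or d > expected for d in diffs)
        # 12x speedup between baseline and burst cadence
        base = np.median(np.diff(acq[acq.mda == "baseline"].t_s.values))
        burst = np.median(np.diff(acq[acq.mda == "burst"].t_s.values))
        assert base / burst == 12.0
        # autofocus suspended during the burst only
        assert not acq[acq.mda == "burst"].autofocus.any()
        assert acq[acq.mda == "recovery"].autofocus.all()
        # the valve opens with the first burst frame
        valve_on = [e for e in res.log.filter("valve") if e.data["state"]][0]
        first_burst = acq[acq.mda == "burst"].t_s.min()
        assert valve_on.t_s == first_burst

    def test_count_trigger_and_valve_are_atomic_and_correct(self, camera):
        st = make_colony(14, seed=3, half_um=22.0)
        mic = VirtualMicroscope(st, camera, noise_seed=3)
        sc = builtin_count_and_switch([18], horizon_s=7200.0)
        res = ScenarioRunner(sc, mic, seg_backend="oracle").run()
        trig = res.log.filter("trigger")[0]
        valve = res.log.filter("valve")[0]
        assert valve.t_s == trig.t_s
        # no acquisition between the trigger and its action in log order
        i_trig = res.log.events.index(trig)
        i_valve = res.log.events.index(valve)
        assert i_trig < i_valve
        assert all(e.kind != "acquisition"
                   for e in res.log.events[i_trig + 1:i_valve])
        # fires at the first frame at-or-above threshold
        counts = {e.t_s: e.data["count"] for e in res.log.filter("analysis")}
        crossing = min(t for t, c in counts.items() if c >= 18)
        assert trig.t_s == crossing
        before = [c for t, c in counts.items() if t < crossing]
        assert all(c < 18 for c in before)

    def test_detect_and_track_without_tagged_cells_never_follows(self, camera):
        st = make_colony(8, seed=4, half_um=20.0)   # tag_fraction = 0
        mic = VirtualMicroscope(st, camera, noise_seed=4)
        sc = builtin_detect_and_track(horizon_s=1800.0)
        res = ScenarioRunner(sc, mic, seg_backend="oracle").run()
        assert res.log.filter("trigger") == []
        assert len(res.tracks) == 0
        acq = res.log.to_dataframe()
        assert set(acq[acq.kind == "acquisition"].mda) == {"scan"}

    def test_per_position_blue_light_doses_give_ordered_yfp(self):
        chambers = [make_colony(5, seed=30 + i, half_um=12.0,
                                cycle_randomized=False) for i in range(4)]
        for i, ch in enumerate(chambers):
            ch.chamber = (200.0 * i - 12, -12, 200.0 * i + 12, 12)
            for c in ch.cells:
                c.centroid = c.centroid + np.array([200.0 * i, 0.0])
        cam = CameraConfig(96, 96)
        mic = VirtualMicroscope(chambers, cam, noise_seed=5)
        intensities = [0.0, 5.0, 10.0, 20.0]
        poss = [PositionSpec(i, x=200.0 * i, y=0.0, channels=[
            ChannelSettings("blue_stim", 100.0, intensities[i]),
            ChannelSettings("YFP", 500.0, 100.0)]) for i in range(4)]
        sc = Scenario(name="dose", mda={"m": MDASpec("m", 600.0, poss, False)},
                      initial_mda="m", horizon_s=5400.0)
        res = ScenarioRunner(sc, mic, seg_backend="oracle",
                             keep_frames=True).run()
        means = []
        for i in range(4):
            yfp = [f for f in res.frames
                   if f.position_id == i and f.channel == "YFP"][-1]
            means.append(float(yfp.pixels.mean()))
        assert means[0] < means[1] < means[2] < means[3]
        # each chamber was stimulated only at its own intensity
        assert [ch.environment.light_dose_pct for ch in chambers] == intensities

    def test_run_is_deterministic_for_fixed_seeds(self, camera):
        logs = []
        for _ in range(2):
            st = make_colony(10, seed=6, half_um=20.0)
            mic = VirtualMicroscope(st, camera, noise_seed=6)
            sc = builtin_count_and_switch([14], horizon_s=3600.0)
            res = ScenarioRunner(sc, mic, seg_backend="oracle").run()
            logs.append([(e.t_s, e.kind, e.position_id, tuple(sorted(e.data)))
                         for e in res.log.events])
        assert logs[0] == logs[1]
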