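"""Post-hoc analysis (lag phase, field summaries, localization) and I/O."""

import numpy as np
import pandas as pd
import pytest

from eventscope import (CountSeries, field_fluorescence_summary,
                        lag_phase_duration, lag_threshold_count,
                        localization_timecourse, peak_time)
from eventscope.io import (eventlog_from_csv, eventlog_to_csv,
                           read_frames_ome, write_frames_ome)


class TestLagPhase:
    def test_threshold_count_rounds_up(self):
        assert lag_threshold_count(100) == 130
        assert lag_threshold_count(10) == 13
        assert lag_threshold_count(7) == 10   # ceil(9.1)

    def test_constant_population_never_ends_the_lag(self):
        s = CountSeries(np.arange(0, 3000, 300), np.full(10, 100),
                        switch_time=0.0)
        assert lag_phase_duration(s) is None

    def test_first_frame_at_or_above_rule(self):
        s = CountSeries([0.0, 600.0, 1200.0], [100, 110, 131],
                        switch_time=0.0)
        assert lag_phase_duration(s) == 1200.0

    def test_invariant_under_uniform_time_shift(self):
        t = np.array([0.0, 600.0, 1200.0, 1800.0])
        c = np.array([50, 55, 60, 70])
        lag0 = lag_phase_duration(CountSeries(t, c, switch_time=0.0))
        lag1 = lag_phase_duration(CountSeries(t + 7200.0, c,
                                              switch_time=7200.0))
        assert lag0 == lag1 == 1800.0

    def test_non_monotone_times_rejected(self):
        with pytest.raises(ValueError):
            CountSeries([0.0, 0.0, 10.0], [1, 2, 3])


class TestFieldSummary:
    def test_constant_frame(self):
        mean, sd = field_fluorescence_summary(np.full((32, 32), 7.0))
        assert (mean, sd) == (7.0, 0.0)

    def test_bimodal_frame_population_sd(self):
        px = np.zeros((10, 10))
        px[:5] = 10.0
        mean, sd = field_fluorescence_summary(px)
        assert mean == pytest.approx(5.0)
        assert sd == pytest.approx(5.0)   # population SD, no correction


class TestLocalizationTimecourse:
    def test_flat_series_for_uniform_gfp(self):
        rows = [{"t_s": t, "position_id": 0, "label": 1, "nls": 1.0}
                for t in (0.0, 60.0, 120.0)]
        tc = localization_timecourse(pd.DataFrame(rows))
        assert list(tc["mean"]) == [1.0, 1.0, 1.0]
        assert list(tc["sd"]) == [0.0, 0.0, 0.0]

    def test_gaps_stay_gaps(self):
        rows = [{"t_s": 0.0, "position_id": 0, "label": 1, "nls": 1.0},
                {"t_s": 60.0, "position_id": 0, "label": 2, "nls": 2.0},
                {"t_s": 60.0, "position_id": 0, "label": 1, "nls": 1.5}]
        tc = localization_timecourse(pd.DataFrame(rows))
        assert np.isnan(tc["cell_2"].iloc[0])
        assert tc["mean"].iloc[1] == pytest.approx(1.75)

    def test_peak_time_of_aggregate(self):
        rows = [{"t_s": t, "position_id": 0, "label": 1,
                 "nls": 1.0 + np.sin(t / 100.0)} for t in range(0, 400, 50)]
        tc = localization_timecourse(pd.DataFrame(rows))
        assert peak_time(tc) == 150.0


class TestRoundTrips:
    def test_eventlog_csv_round_trip(self, tmp_path):
        from eventscope import EventLog
        log = EventLog()
        log.append(0.0, "acquisition", 0, channel="brightfield", mda="m")
        log.append(0.0, "valve", -1, valve=0, state=True)
        log.append(25.0, "trigger", 0, trigger="count_threshold", count=50)
        path = tmp_path / "log.csv"
        eventlog_to_csv(log, path)
        log2 = eventlog_from_csv(path)
        assert [(e.t_s, e.kind, e.position_id, e.data) for e in log.events] \
            == [(e.t_s, e.kind, e.position_id, e.data) for e in log2.events]

    def test_ome_tiff_round_trip(self, tmp_path, quiet_camera):
        from conftest import make_colony, make_scope
        from eventscope import ChannelSettings
        state = make_colony(5, seed=1, half_um=14.0)
        mic = make_scope(state, quiet_camera)
        frames = []
        for t in (0.0, 300.0, 600.0):
            mic.advance_to(t)
            frames.append(mic.acquire(
                ChannelSettings("brightfield", 50.0, 0.0)))
            frames.append(mic.acquire(ChannelSettings("RFP", 150.0, 100.0)))
        path = tmp_path / "stack.ome.tif"
        write_frames_ome(frames, path)
        stack, channels, t_sim, stage = read_frames_ome(path)
        assert np.array_equal(stack, np.stack([f.pixels for f in frames]))
        assert channels == [f.channel for f in frames]
        assert t_sim == [f.t_sim for f in frames]
        assert np.allclose(stage[:, 0], [f.stage.x for f in frames])

    def test_cli_simulate_run_analyze(self, tmp_path):
        from click.testing import CliRunner
        from eventscope.cli import main
        runner = CliRunner()
        cfg = tmp_path / "sim.yaml"
        cfg.write_text("initial_count: 6\nchamber: [-16, -16, 16, 16]\n"
                       "seed: 3\n")
        sc = tmp_path / "scenario.yaml"
        sc.write_text("""
scenario_name: smoke
horizon_s: 600
initial_mda: main
mda:
  main:
    interval_s: 300
    autofocus: false
    positions:
      - id: 0
        channels:
          - {channel: brightfield, exposure_ms: 50, led_pct: 0}
""")
        r1 = runner.invoke(main, ["simulate", "--config", str(cfg),
                                  "--horizon", "600", "--out",
                                  str(tmp_path / "sim")])
        assert r1.exit_code == 0, r1.output
        assert (tmp_path / "sim" / "ground_truth_masks.tif").exists()
        r2 = runner.invoke(main, ["run", "--scenario", str(sc), "--config",
                                  str(cfg), "--out", str(tmp_path / "run")])
        assert r2.exit_code == 0, r2.output
        r3 = runner.invoke(main, ["analyze", "--log",
                                  str(tmp_path / "run" / "eventlog.csv"),
                                  "--no-plot", "--out",
                                  str(tmp_path / "ana")])
        assert r3.exit_code == 0, r3.output
        assert (tmp_path / "ana" / "counts.csv").exists()
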