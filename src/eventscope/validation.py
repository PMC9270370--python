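"""End-to-end validation studies of the closed-loop engine.

Each study builds a defined virtual-colony condition, runs the relevant
protocol through the full engine, and measures the quantities that
characterise correct closed-loop behaviour: schedule exactness and the
burst/baseline cadence ratio, valve/frame synchronization, count-trigger
timing and lag-phase ordering, tracking containment, mitosis-capture lead
times, the phototoxicity/sampling trade-off, Hog1 peak timing on rendered
images, and segmentation count accuracy.

The studies are deterministic given their seed and are shared between the
test suite and ``scripts/acceptance.py``.  Problem sizes are desk-scale:
camera 128-256 px, colonies of 8-80 cells, horizons of 1-3 simulated hours.
"""

from __future__ import annotations

import numpy as np

from . import sample as S
from .analysis import count_series_from_log, lag_phase_duration, \
    localization_timecourse, peak_time
from .builtins import BF, RFP, _pos, builtin_adaptive_stress, \
    builtin_count_and_switch, builtin_detect_and_track, builtin_find_and_zoom
from .devices import (BUD_LABEL_BASE, CameraConfig, ChannelSettings, Frame,
                      VirtualMicroscope, image_center_px)
from .engine import MDASpec, Scenario, ScenarioRunner
from .events import bud_a_min_for_mother
from .segmentation import count_cells, segment_cells
from .tracking import register_translation


# ---------------------------------------------------------------------------
# adaptive-sampling stress protocol: cadence, valve sync, Hog1 peak


def adaptive_stress_study(seed: int, n_cells: int = 13) -> dict:
    """One stress cycle with GFP imaging; cadence and Hog1 timing readouts."""
    state = S.init_colony(n_cells, (-14, -14, 14, 14), seed=seed)
    mic = VirtualMicroscope(state, CameraConfig(128, 128), noise_seed=seed + 1)
    sc = builtin_adaptive_stress(n_cycles=1)
    res = ScenarioRunner(sc, mic, seg_backend="oracle",
                         compute_nls=True).run(horizon=2760.0)
    acq = res.log.to_dataframe()
    acq = acq[(acq.kind == "acquisition") & (acq.channel == "brightfield")]
    by_mda = {m: np.asarray(sorted(acq[acq.mda == m].t_s)) for m in
              ("baseline", "burst", "recovery")}
    burst_diffs = np.diff(by_mda["burst"])
    recovery_diffs = np.diff(by_mda["recovery"])
    ratio = (float(np.median(np.diff(by_mda["baseline"])))
             / float(np.median(burst_diffs)))
    valves = res.log.filter("valve")
    t_on = next(e.t_s for e in valves if e.data["state"])
    t_off = next(e.t_s for e in valves if not e.data["state"])
    tc = localization_timecourse(res.features)
    tc = tc[tc.t_s >= t_on]
    return {
        "interval_ratio": ratio,
        "burst_interval_s": float(burst_diffs[0]),
        "burst_spacing_exact": bool(np.all(burst_diffs == burst_diffs[0])),
        "recovery_spacing_exact": bool(np.all(recovery_diffs
                                              == recovery_diffs[0])),
        "valve_on_minus_first_burst_s": float(t_on - by_mda["burst"][0]),
        "valve_off_minus_on_s": float(t_off - t_on),
        "hog1_peak_measured_s": float(peak_time(tc) - t_on),
        "hog1_peak_analytic_s": float(S.hog1_peak_time(state.params)),
        "n_frames": int(len(acq)),
    }


# ---------------------------------------------------------------------------
# plain multi-position schedule


def mda_schedule_study(seed: int) -> dict:
    """3 positions at 300 s over 1500 s: timestamps must be exact."""
    state = S.init_colony(4, (-60, -20, 60, 20), seed=seed)
    mic = VirtualMicroscope(state, CameraConfig(96, 96), noise_seed=seed)
    poss = [_pos(i, x=-40.0 + 40 * i, channels=[BF]) for i in range(3)]
    sc = Scenario(name="mda", mda={"m": MDASpec("m", 300.0, poss, False)},
                  initial_mda="m", horizon_s=1500.0)
    res = ScenarioRunner(sc, mic, seg_backend="oracle").run()
    expected = [0.0, 300.0, 600.0, 900.0, 1200.0]
    err = max(abs(t - e)
              for i in range(3)
              for t, e in zip(res.log.acquisition_times(i), expected))
    n_ok = all(len(res.log.acquisition_times(i)) == 5 for i in range(3))
    return {"max_timestamp_error_s": float(err), "visit_counts_ok": bool(n_ok)}


# ---------------------------------------------------------------------------
# count-triggered perfusion switching and the lag phase


def count_switch_study(seed: int, threshold: int, initial: int) -> dict:
    """Grow to ``threshold`` cells, switch to sucrose, measure the lag."""
    chamber = (-22.0, -22.0, 22.0, 22.0)
    state = S.init_colony(initial, chamber, seed=seed)
    mic = VirtualMicroscope(state, CameraConfig(192, 192), noise_seed=seed + 1)
    sc = builtin_count_and_switch([threshold], horizon_s=11400.0)
    res = ScenarioRunner(sc, mic, seg_backend="oracle").run()
    trig = res.log.filter("trigger")[0]
    # independent ground truth: advance an identical colony without imaging
    shadow = S.init_colony(initial, chamber, seed=seed)
    t, crossing = 0.0, None
    while crossing is None and t <= trig.t_s + 720.0:
        if shadow.count() >= threshold:
            crossing = t
        else:
            S.advance(shadow, 180.0)
            t += 180.0
    series = count_series_from_log(res.log, 0)
    lag = lag_phase_duration(series)
    return {
        "trigger_t_s": float(trig.t_s),
        "gt_crossing_t_s": float(crossing) if crossing is not None else None,
        "firing_error_frames": (abs(trig.t_s - crossing) / 180.0
                                if crossing is not None else float("inf")),
        "lag_s": float(lag) if lag is not None else None,
    }


def lag_monotonicity_study(seeds, thresholds=(20, 50, 100)) -> dict:
    """Criterion-level sweep: exact firing and lags decreasing in threshold."""
    initials = {20: 12, 50: 30, 100: 60}
    firing_errors = []
    lag_ordered = []
    lags_by_thr = {n: [] for n in thresholds}
    for seed in seeds:
        lags = []
        for n in thresholds:
            r = count_switch_study(seed, n, initials[n])
            firing_errors.append(r["firing_error_frames"])
            lags.append(r["lag_s"])
            lags_by_thr[n].append(r["lag_s"])
        lag_ordered.append(all(a is not None and b is not None and a > b
                               for a, b in zip(lags, lags[1:])))
    return {
        "max_firing_error_frames": float(max(firing_errors)),
        "all_lags_strictly_decreasing": bool(all(lag_ordered)),
        "mean_lag_s_by_threshold": {n: float(np.mean(v))
                                    for n, v in lags_by_thr.items()},
        "n_runs": len(seeds) * len(thresholds),
    }


# ---------------------------------------------------------------------------
# detect-and-track with stage feedback in a dead-end chamber


def tracking_study(seed: int, n_frames: int = 120,
                   follow_interval_s: float = 30.0) -> dict:
    """Crowded dead-end chamber; growth pushes the tagged target sideways."""
    params = S.SampleParams(relax_iters=25)
    state = S.init_colony(80, (0.0, -12.0, 150.0, 12.0), seed=seed,
                          params=params, region=(0.0, -12.0, 60.0, 12.0),
                          open_side="+x", tag_fraction=0.1,
                          tagged_region=(28.0, -12.0, 42.0, 12.0))
    cam = CameraConfig(128, 128)
    mic = VirtualMicroscope(state, cam, noise_seed=seed + 1)
    sc = builtin_detect_and_track(
        scan_positions=[_pos(0, x=34.0, y=0.0, channels=[BF, RFP])],
        follow_interval_s=follow_interval_s,
        horizon_s=follow_interval_s * n_frames + 1.0,
        seeds={"rng": seed + 2})
    res = ScenarioRunner(sc, mic, seg_backend="oracle", label_buds=True).run()
    target = res.log.filter("trigger")[0].data["label"]
    tr = res.tracks
    cy, cx = image_center_px(cam)
    offsets = np.hypot(tr.cy - cy, tr.cx - cx).values
    recenters = res.log.filter("recenter")
    drift_px = sum(np.hypot(e.data["dx_um"], e.data["dy_um"])
                   for e in recenters[1:]) / cam.pixel_size_um
    return {
        "n_frames": int(len(tr)),
        "max_center_offset_px": float(offsets[1:].max()),
        "identity_match_pct": float(100.0 * (tr.label == target).mean()),
        "cumulative_drift_px": float(drift_px),
        "target_in_fov_always": bool((offsets < cam.width / 2).all()),
    }


# ---------------------------------------------------------------------------
# mitosis capture: rule lead times and the find-and-zoom protocol


def mitosis_rule_study(seed: int, horizon_s: float = 10800.0,
                       interval_s: float = 180.0) -> dict:
    """Lead of the bud rule over nuclear-separation onset, on ground truth."""
    state = S.init_colony(8, (-20, -20, 20, 20), seed=seed)
    hist = {}
    for t in np.arange(0.0, horizon_s, interval_s):
        for c in state.cells:
            if c.bud_area > 0:
                hist.setdefault((c.id, c.bud_start_time), []).append(
                    (t, c.bud_area, c.area))
        S.advance(state, interval_s)
    leads = []
    unfired = 0
    for rec in state.lineage:
        if rec.bud_start_time_s <= 0:
            continue    # bud predates observation: censored
        h = hist.get((rec.mother_id, rec.bud_start_time_s), [])
        fire = None
        for i in range(3, len(h)):
            t, a, mother_area = h[i]
            if (a >= bud_a_min_for_mother(mother_area)
                    and all(h[j][1] < h[j + 1][1] for j in range(i - 3, i))):
                fire = t
                break
        if fire is None:
            unfired += 1
        else:
            leads.append(int((rec.sep_onset_time_s - fire) // interval_s))
    return {"leads_frames": leads, "n_divisions": len(leads),
            "unfired": unfired}


def find_and_zoom_study(seed: int, horizon_s: float = 9000.0) -> dict:
    """Full engine run: zoom cadence and separation capture per episode."""
    params = S.SampleParams(relax_iters=25)
    state = S.init_colony(8, (-20, -20, 20, 20), seed=seed, params=params)
    mic = VirtualMicroscope(state, CameraConfig(192, 192), noise_seed=seed + 1)
    sc = builtin_find_and_zoom(horizon_s=horizon_s)
    res = ScenarioRunner(sc, mic, seg_backend="oracle", label_buds=True).run()
    acq = res.log.to_dataframe()
    zoom = acq[(acq.kind == "acquisition") & (acq.mda == "zoom")
               & (acq.channel == "brightfield")]
    episodes = [e for e in res.log.filter("trigger")
                if e.t_s + 1200.0 <= horizon_s]   # fully observed episodes
    spacing_exact = True
    captured = []
    for tg in episodes:
        ts = np.asarray(sorted(zoom[(zoom.t_s > tg.t_s)
                                    & (zoom.t_s <= tg.t_s + 1200.0)].t_s))
        spacing_exact &= bool(len(ts) >= 2 and np.all(np.diff(ts) == 30.0))
        mother = tg.data["label"] - BUD_LABEL_BASE
        recs = [r for r in state.lineage
                if r.mother_id == mother and r.division_time_s > tg.t_s]
        if recs:
            rec = min(recs, key=lambda r: r.division_time_s)
            # separation spans [onset, division]; the episode must image it
            captured.append(bool(tg.t_s < rec.division_time_s
                                 and rec.sep_onset_time_s < tg.t_s + 1200.0))
        else:
            # the division itself lies past the horizon; the live cell still
            # carries its separation-onset timestamp
            cell = state.cell_by_id(mother)
            if cell.phase == "budded" and cell.sep_onset_time is not None:
                captured.append(bool(cell.sep_onset_time < tg.t_s + 1200.0))
            # onset also past the horizon: episode outcome unobserved, censor
    return {
        "n_episodes": len(episodes),
        "zoom_spacing_exact": bool(spacing_exact),
        "all_episodes_capture_separation": bool(all(captured)) if captured
        else False,
        "n_divisions_total": len(state.lineage),
    }


# ---------------------------------------------------------------------------
# phototoxicity A/B


def phototoxicity_ab_study(seed: int, horizon_s: float = 10800.0) -> dict:
    """Same colony, same seed: naive 25 s fluorescence MDA vs adaptive."""
    def colony():
        return S.init_colony(12, (-16, -16, 16, 16), seed=seed,
                             cycle_randomized=False)

    gfp = ChannelSettings("GFP", 150.0, 100.0)
    naive_state = colony()
    mic = VirtualMicroscope(naive_state, CameraConfig(128, 128),
                            noise_seed=seed + 1)
    naive = Scenario(name="naive",
                     mda={"fast": MDASpec("fast", 25.0,
                                          [_pos(0, channels=(BF, gfp))],
                                          False)},
                     initial_mda="fast", horizon_s=horizon_s)
    ScenarioRunner(naive, mic, seg_backend="oracle").run()

    adaptive_state = colony()
    mic2 = VirtualMicroscope(adaptive_state, CameraConfig(128, 128),
                             noise_seed=seed + 1)
    sc = builtin_adaptive_stress(n_cycles=3)
    ScenarioRunner(sc, mic2, seg_backend="oracle").run(horizon=horizon_s)
    return {
        "initial_count": 12,
        "naive_final_over_initial": naive_state.count() / 12.0,
        "adaptive_final_over_initial": adaptive_state.count() / 12.0,
    }


# ---------------------------------------------------------------------------
# segmentation accuracy and registration oracle


def _scatter_scene(seed: int, n: int, camera: CameraConfig):
    half = camera.width * camera.pixel_size_um / 2 - 4
    state = S.init_colony(n, (-half, -half, half, half), seed=seed,
                          cycle_randomized=False)
    for _ in range(30):
        S._relax(state)
    return state, VirtualMicroscope(state, camera, noise_seed=seed)


def segmentation_accuracy_study(seeds, n_cells: int = 24) -> dict:
    """Count error on noise-free and SNR-5 scenes (SNR = ring contrast /
    read-noise SD)."""
    bf = ChannelSettings("brightfield", 50.0, 0.0)
    nf_errors, snr5_errors = [], []
    for seed in seeds:
        cam = CameraConfig(256, 256, read_noise_sd=0.0, shot_noise=False)
        state, mic = _scatter_scene(seed, n_cells, cam)
        img = mic.render(bf, noise=False)
        fr = Frame(np.clip(np.round(img), 0, 65535).astype(np.uint16),
                   bf, mic.pose, 0.0)
        nf_errors.append(abs(count_cells(segment_cells(fr)) - state.count()))

        ring_amp = cam.ring_depth * cam.bf_background
        cam5 = CameraConfig(256, 256, read_noise_sd=ring_amp / 5.0)
        state, mic = _scatter_scene(seed, n_cells, cam5)
        img = mic.render(bf, noise=True)
        fr = Frame(np.clip(np.round(img), 0, 65535).astype(np.uint16),
                   bf, mic.pose, 0.0)
        snr5_errors.append(abs(count_cells(segment_cells(fr)) - state.count()))
    return {
        "n_scenes": len(seeds),
        "noise_free_max_error": int(max(nf_errors)),
        "snr5_max_error_pct": float(100.0 * max(snr5_errors) / n_cells),
    }


def registration_oracle_study(seed: int, n_instances: int = 4) -> dict:
    """FFT registration vs exhaustive circular search on 64x64 instances."""
    rng = np.random.default_rng(seed)
    mismatches = 0
    for _ in range(n_instances):
        a = rng.normal(0.0, 1.0, (64, 64))
        shift = (int(rng.integers(-12, 12)), int(rng.integers(-12, 12)))
        b = np.roll(a, shift, axis=(0, 1))
        est = register_translation(a, b)[0]
        a0, b0 = a - a.mean(), b - b.mean()
        best, arg = -np.inf, None
        for dy in range(-32, 32):
            for dx in range(-32, 32):
                s = (np.roll(a0, (dy, dx), axis=(0, 1)) * b0).sum()
                if s > best:
                    best, arg = s, (dy, dx)
        if est != arg or est != shift:
            mismatches += 1
    return {"n_instances": n_instances, "mismatches": mismatches}
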