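"""Unit and property tests for the virtual yeast colony."""

import copy
import math

import numpy as np
import pytest

from eventscope import (SampleParams, advance, accumulate_photodose,
                        hog1_fraction, hog1_peak_time, init_colony,
                        phototox_factor, set_medium, venus_induction,
                        venus_steady_state)
from eventscope.sample import (_base_growth_rate, max_pairwise_overlap)

from conftest import make_colony


def cells_equal(a, b):
    return (a.id == b.id and np.array_equal(a.centroid, b.centroid)
            and a.radius == b.radius and a.phase == b.phase
            and a.bud_area == b.bud_area and a.venus_level == b.venus_level)


class TestGrowthAndDivision:
    def test_zero_dt_is_identity(self):
        st = make_colony(5, seed=1)
        before = copy.deepcopy(st)
        advance(st, 0.0)
        assert st.environment.time == before.environment.time
        assert all(cells_equal(a, b) for a, b in zip(st.cells, before.cells))

    def test_negative_dt_rejected(self):
        st = make_colony(1, seed=1)
        with pytest.raises(ValueError):
            advance(st, -1.0)

    def test_area_doubles_over_one_doubling_time(self):
        st = make_colony(1, seed=1, cycle_randomized=False)
        cell = st.cells[0]
        cell.radius = 1.5           # keep the doubled area below the cap
        cell.t_g1 = 1e9             # suppress budding
        a0 = cell.area
        advance(st, st.params.doubling_time_s)
        assert cell.area == pytest.approx(2 * a0, rel=0.01)

    def test_overlapping_pair_is_pushed_apart(self):
        st = make_colony(2, seed=3, cycle_randomized=False)
        st.cells[0].centroid = np.array([-1.0, 0.0])
        st.cells[1].centroid = np.array([1.0, 0.0])
        st.cells[0].radius = st.cells[1].radius = 2.0
        st.cells[0].t_g1 = st.cells[1].t_g1 = 1e9
        advance(st, 1.0)
        d = np.linalg.norm(st.cells[0].centroid - st.cells[1].centroid)
        assert d >= 4.0 - st.params.relax_eps_um - 0.02  # ~sum of radii

    def test_divisions_append_lineage_and_unique_ids(self):
        st = make_colony(8, seed=4)
        advance(st, 3 * 3600.0)
        assert len(st.lineage) >= 5
        ids = [c.id for c in st.cells]
        assert len(ids) == len(set(ids))
        live_or_past = set(ids) | {r.daughter_id for r in st.lineage}
        assert all(r.mother_id in live_or_past for r in st.lineage)
        # separation onset precedes division by the rendering window
        for r in st.lineage:
            assert r.sep_onset_time_s <= r.division_time_s

    def test_count_never_decreases(self):
        st = make_colony(6, seed=5)
        counts = [st.count()]
        for _ in range(20):
            advance(st, 600.0)
            counts.append(st.count())
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_geometry_invariants_after_advance(self):
        st = make_colony(10, seed=6)
        advance(st, 2 * 3600.0)
        assert max_pairwise_overlap(st) <= st.params.relax_eps_um + 1e-9
        x0, y0, x1, y1 = st.chamber
        for c in st.cells:
            assert x0 <= c.centroid[0] <= x1 and y0 <= c.centroid[1] <= y1

    def test_determinism_bit_identical(self):
        a = make_colony(10, seed=7)
        b = make_colony(10, seed=7)
        advance(a, 5400.0)
        advance(b, 5400.0)
        assert len(a.cells) == len(b.cells)
        for ca, cb in zip(a.cells, b.cells):
            assert cells_equal(ca, cb)
        assert a.environment.time == b.environment.time


class TestMediumSwitching:
    def test_unknown_medium_rejected(self):
        st = make_colony(1, seed=1)
        with pytest.raises(ValueError):
            set_medium(st, "maltose")

    def test_same_medium_is_noop(self):
        st = make_colony(3, seed=2)
        before = copy.deepcopy(st)
        set_medium(st, "glucose")
        assert all(cells_equal(a, b) for a, b in zip(st.cells, before.cells))

    @pytest.mark.parametrize("n,expected_lag", [(100, 180.0), (500, 36.0)])
    def test_sucrose_lag_matches_shared_pool_closed_form(self, n, expected_lag):
        # h_min / (k_suc * N) with the worked-example constants
        p = SampleParams(h_min=18.0, t_g1_s=1e9)
        st = make_colony(n, seed=8, half_um=60.0, params=p,
                         cycle_randomized=False)
        set_medium(st, "sucrose")
        t = 0.0
        while _base_growth_rate(st.environment, p) == 0.0:
            advance(st, 1.0)
            t += 1.0
        assert t == pytest.approx(expected_lag, abs=1.0)

    def test_lag_strictly_shorter_with_more_cells(self):
        lags = []
        for n in (50, 100, 200):
            p = SampleParams(t_g1_s=1e9)
            st = make_colony(n, seed=9, half_um=60.0, params=p,
                             cycle_randomized=False)
            set_medium(st, "sucrose")
            t = 0.0
            while _base_growth_rate(st.environment, p) == 0.0:
                advance(st, 5.0)
                t += 5.0
            lags.append(t)
        assert lags[0] > lags[1] > lags[2]


class TestHog1:
    def test_fraction_is_base_at_stress_onset(self):
        p = SampleParams()
        assert hog1_fraction(0.0, p.hog1_base, p.hog1_amp, p.tau_in_s,
                             p.tau_adapt_s) == pytest.approx(p.hog1_base)

    def test_fraction_adapts_back_to_base(self):
        p = SampleParams()
        late = hog1_fraction(1e6, p.hog1_base, p.hog1_amp, p.tau_in_s,
                             p.tau_adapt_s)
        assert late == pytest.approx(p.hog1_base, abs=1e-9)

    def test_analytic_peak_time_in_physiological_window(self):
        p = SampleParams()
        t_star = hog1_peak_time(p)
        assert t_star == pytest.approx(p.tau_in_s * math.log(16), rel=1e-12)
        assert 60.0 <= t_star <= 120.0

    def test_simulated_fraction_tracks_closed_form(self):
        p = SampleParams(max_substep_s=1.0, t_g1_s=1e9)
        st = make_colony(3, seed=10, params=p, cycle_randomized=False)
        set_medium(st, "sorbitol_stress")
        for t_probe in (40.0, 111.0, 400.0):
            advance(st, t_probe - st.environment.time)
            expected = float(hog1_fraction(t_probe, p.hog1_base, p.hog1_amp,
                                           p.tau_in_s, p.tau_adapt_s))
            for c in st.cells:
                assert c.hog1_nuclear_fraction == pytest.approx(expected,
                                                                abs=1e-6)
        assert all(0.0 <= c.hog1_nuclear_fraction <= 1.0 for c in st.cells)


class TestPhotodose:
    def test_brightfield_contributes_nothing(self):
        st = make_colony(3, seed=11)
        accumulate_photodose(st, "brightfield", 150.0, 100.0)
        assert all(c.photodose == 0.0 for c in st.cells)

    def test_slow_sampling_keeps_growth_unaffected(self):
        # one 150 ms / 100% exposure per 5 min for 2 h
        p = SampleParams(t_g1_s=1e9)
        st = make_colony(3, seed=12, params=p, cycle_randomized=False)
        for k in range(24):
            accumulate_photodose(st, "GFP", 150.0, 100.0)
            advance(st, 300.0)
            assert all(phototox_factor(c, st.environment.time, p) == 1.0
                       for c in st.cells)

    def test_fast_sampling_arrests_growth(self):
        # one exposure per 25 s sustained: growth factor collapses to zero
        p = SampleParams(t_g1_s=1e9)
        st = make_colony(3, seed=13, params=p, cycle_randomized=False)
        for k in range(int(3600 / 25)):
            accumulate_photodose(st, "GFP", 150.0, 100.0)
            advance(st, 25.0)
        assert all(phototox_factor(c, st.environment.time, p) == 0.0
                   for c in st.cells)


class TestVenus:
    def test_dark_cells_stay_dark(self):
        st = make_colony(2, seed=14, cycle_randomized=False)
        venus_induction(st, 0.0, 3600.0)
        assert all(c.venus_level == 0.0 for c in st.cells)

    def test_steady_states_increase_with_intensity(self):
        p = SampleParams()
        ss = [venus_steady_state(i, p) for i in (5.0, 10.0, 20.0)]
        assert ss[0] < ss[1] < ss[2]

    def test_long_run_simulation_reaches_closed_form_steady_state(self):
        p = SampleParams(t_g1_s=1e9, max_substep_s=5.0)
        st = make_colony(2, seed=15, params=p, cycle_randomized=False)
        st.environment.light_dose_pct = 10.0
        advance(st, 8 * 3600.0)   # many decay times
        expected = venus_steady_state(10.0, p)
        for c in st.cells:
            assert c.venus_level == pytest.approx(expected, rel=0.01)
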