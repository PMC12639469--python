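"""Delivery timelines and the threshold-trimmed PBS dose-rate engine."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import sparse

from flashpbs.delivery import (DeliveryTimeline, DoseRateConfig,
                               ProtonMachineModel, VheeMachineModel,
                               flash_dose_map, pbs_dose_rate_map,
                               schedule_proton, schedule_vhee)
from flashpbs.grids import VoxelGrid
from flashpbs.optimize import ColumnSet
from flashpbs.spots import Spot


def _spots(weights, pitch=10.0):
    return [Spot(k * pitch, 0.0, w, "F") for k, w in enumerate(weights)]


def _grid(n=10):
    return VoxelGrid(np.zeros((n, n, n)), (1.0,) * 3, (0.0,) * 3)


def _column_set(M, grid=None):
    M = sparse.csc_matrix(M)
    grid = grid or _grid()
    return ColumnSet(M, np.arange(M.shape[0]), grid)


class TestProtonSchedule:
    def test_single_spot_dwell(self):
        tl = schedule_proton(_spots([100.0]), ProtonMachineModel(1000.0))
        assert tl.start_s[0] == 0.0
        assert tl.duration_s[0] == pytest.approx(0.1)

    def test_travel_time_between_spots(self):
        m = ProtonMachineModel(1000.0, (10000.0, 10000.0), 0.0)
        tl = schedule_proton(_spots([50.0, 50.0], pitch=10.0), m)
        first_end = tl.start_s[0] + tl.duration_s[0]
        assert tl.start_s[1] == pytest.approx(first_end + 0.001)

    def test_zero_weight_spot_still_incurs_travel(self):
        m = ProtonMachineModel(1000.0, (10000.0, 10000.0), 0.002)
        tl = schedule_proton(_spots([50.0, 0.0, 50.0], pitch=10.0), m)
        assert tl.duration_s[1] == 0.0
        # third spot delayed by two travel+overhead legs
        assert tl.start_s[2] == pytest.approx(0.05 + 2 * (0.001 + 0.002))

    def test_total_time_matches_independent_accumulation(self):
        rng = np.random.default_rng(0)
        w = rng.uniform(0, 80, 30)
        xs = rng.uniform(-40, 40, 30)
        ys = rng.uniform(-40, 40, 30)
        spots = [Spot(x, y, wk, "F") for x, y, wk in zip(xs, ys, w)]
        m = ProtonMachineModel(2000.0, (8000.0, 12000.0), 0.0015)
        tl = schedule_proton(spots, m)
        t = 0.0
        for k in range(30):
            if k:
                t += max(abs(xs[k] - xs[k - 1]) / 8000.0,
                         abs(ys[k] - ys[k - 1]) / 12000.0) + 0.0015
            t += w[k] / 2000.0
        assert tl.total_time_s == pytest.approx(t)


class TestVheeSchedule:
    def test_last_pulse_of_10_single_pulse_spots(self):
        tl = schedule_vhee(_spots([1.0] * 10), VheeMachineModel(100.0))
        assert tl.start_s[-1] == pytest.approx(0.09)

    def test_ceiling_pulse_count(self):
        m = VheeMachineModel(100.0, 4e-6, max_dose_per_pulse_MU=2.0)
        tl = schedule_vhee(_spots([5.0]), m)  # 2.5x capacity -> 3 pulses
        assert tl.n_emissions == 3
        assert tl.weight_MU.sum() == pytest.approx(5.0)

    def test_total_field_time_single_pulse_spots(self):
        m = VheeMachineModel(250.0, 4e-6)
        n = 17
        tl = schedule_vhee(_spots([1.0] * n), m)
        assert tl.total_time_s == pytest.approx((n - 1) / 250.0 + 4e-6)

    def test_pulse_width_must_fit_period(self):
        with pytest.raises(ValueError):
            VheeMachineModel(1000.0, pulse_width_s=2e-3)


class TestDoseRateEngine:
    def test_single_interval_rate_is_ramp_slope(self):
        """One emission of duration delta delivering D > 2*dhat: the trimmed
        window and trimmed dose cancel, leaving DR = D/delta."""
        M = np.array([[0.05]])  # Gy/MU
        cs = _column_set(M)
        tl = DeliveryTimeline([0], [0.0], [0.2], [100.0])
        dr = pbs_dose_rate_map(cs, np.array([100.0]), tl, DoseRateConfig())
        assert dr.values.ravel()[0] == pytest.approx(5.0 / 0.2)

    def test_two_pulse_closed_form(self):
        """1 Gy in each of two pulses of width tau, 1/PRF apart, dhat=0.1:
        DR = 1.8 / (1/PRF + 0.8*tau) by piecewise-linear inversion."""
        prf, tau = 100.0, 4e-6
        M = np.array([[0.01, 0.01]])
        cs = _column_set(M)
        tl = DeliveryTimeline([0, 1], [0.0, 1 / prf], [tau, tau], [100.0, 100.0])
        dr = pbs_dose_rate_map(cs, np.array([100.0, 100.0]), tl, DoseRateConfig())
        want = 1.8 / (1 / prf + 0.8 * tau)
        assert dr.values.ravel()[0] == pytest.approx(want, rel=1e-9)

    def test_low_dose_voxels_get_zero_rate(self):
        M = np.array([[0.001]])  # 0.1 Gy total = 2*dhat -> rate 0
        cs = _column_set(M)
        tl = DeliveryTimeline([0], [0.0], [0.01], [100.0])
        dr = pbs_dose_rate_map(cs, np.array([100.0]), tl, DoseRateConfig())
        assert dr.values.ravel()[0] == 0.0

    def test_matches_time_stepping_oracle_random_timelines(self):
        """Event-based inversion vs a brute-force 10 us accumulation oracle
        on random multi-interval voxel timelines: within 1%."""
        rng = np.random.default_rng(11)
        nv, ns = 300, 12
        M = sparse.random(nv, ns, density=0.5, random_state=1,
                          data_rvs=lambda n: rng.uniform(0.002, 0.05, n))
        cs = _column_set(M)
        w = rng.uniform(20.0, 120.0, ns)
        durs = rng.uniform(0.001, 0.004, ns)
        starts, t = [], 0.0
        for k in range(ns):
            t += rng.uniform(0.0005, 0.02)
            starts.append(t)
            t += durs[k]
        starts = np.array(starts)
        tl = DeliveryTimeline(np.arange(ns), starts, durs, w)
        got = pbs_dose_rate_map(cs, w, tl, DoseRateConfig()).values.ravel()[:nv]

        Md = M.toarray()
        dhat = 0.1
        for v in range(nv):
            doses = Md[v] * w
            T = (starts + durs).max()
            ts = np.arange(0.0, T + 2e-5, 1e-5)
            cum = np.zeros_like(ts)
            for de, s0, du in zip(doses, starts, durs):
                cum += de * np.clip((ts - s0) / du, 0.0, 1.0)
            D = cum[-1]
            if D <= 2 * dhat:
                assert got[v] == 0.0
                continue
            def tcross(thr):
                i = np.searchsorted(cum, thr)
                return np.interp(thr, cum[i - 1:i + 1], ts[i - 1:i + 1])
            want = (D - 2 * dhat) / (tcross(D - dhat) - tcross(dhat))
            assert got[v] == pytest.approx(want, rel=0.01)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_vhee_rate_non_decreasing_in_prf(self, seed):
        """At fixed weights, raising the PRF compresses the pulse lattice,
        so every voxel's PBS dose rate is non-decreasing in PRF."""
        rng = np.random.default_rng(seed)
        ns = int(rng.integers(3, 12))
        nv = 40
        M = rng.uniform(0, 0.03, (nv, ns)) * (rng.random((nv, ns)) < 0.6)
        cs = _column_set(M)
        w = rng.uniform(10.0, 100.0, ns)
        spots = _spots(w)
        cfg = DoseRateConfig()
        prev = None
        for prf in (100.0, 300.0, 1000.0):
            tl = schedule_vhee(spots, VheeMachineModel(prf))
            dr = pbs_dose_rate_map(cs, w, tl, cfg).values.ravel()[:nv]
            if prev is not None:
                assert np.all(dr >= prev * (1 - 1e-9) - 1e-9)
            prev = dr

    def test_rate_invariant_to_non_contributing_spot_order(self):
        """Permuting spots that deposit nothing in a voxel leaves that
        voxel's dose rate unchanged (only its own pulse times matter)."""
        nv, ns = 1, 6
        M = np.array([[0.02, 0.0, 0.03, 0.0, 0.0, 0.04]])
        w = np.full(ns, 50.0)
        cs = _column_set(M)
        m = VheeMachineModel(200.0)
        tl = schedule_vhee(_spots(w), m)
        base = pbs_dose_rate_map(cs, w, tl, DoseRateConfig()).values.ravel()[0]
        # swap weights of two non-contributing spots (indices 1 and 4)
        M2 = M.copy()
        tl2 = schedule_vhee(_spots(w), m)  # identical lattice
        got = pbs_dose_rate_map(_column_set(M2), w, tl2,
                                DoseRateConfig()).values.ravel()[0]
        assert got == pytest.approx(base)


class TestFlashDoseMap:
    def _maps(self, dose_vals, dr_vals):
        g = _grid(4)
        return [g.like(dose_vals)], [g.like(dr_vals)]

    def test_all_below_threshold_gives_zero(self):
        dose = np.full((4, 4, 4), 20.0)
        dr = np.full((4, 4, 4), 10.0)
        f = flash_dose_map(*self._maps(dose, dr), DoseRateConfig())
        assert not f.values.any()

    def test_all_above_threshold_equals_total_dose(self):
        dose = np.full((4, 4, 4), 20.0)
        dr = np.full((4, 4, 4), 80.0)
        f = flash_dose_map(*self._maps(dose, dr), DoseRateConfig())
        np.testing.assert_array_equal(f.values, dose)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_per_voxel_loop_and_bounded_by_total(self, seed):
        rng = np.random.default_rng(seed)
        g = _grid(4)
        doses = [g.like(rng.uniform(0, 30, g.dims)) for _ in range(2)]
        drs = [g.like(rng.uniform(0, 100, g.dims)) for _ in range(2)]
        cfg = DoseRateConfig(fractions=int(rng.integers(1, 4)))
        f = flash_dose_map(doses, drs, cfg)
        want = np.zeros(g.dims)
        for d, r in zip(doses, drs):
            for idx in np.ndindex(g.dims):
                if r.values[idx] >= 40.0:
                    want[idx] += d.values[idx]
        np.testing.assert_allclose(f.values, cfg.fractions * want, rtol=1e-12)
        total = cfg.fractions * (doses[0].values + doses[1].values)
        assert np.all(f.values <= total + 1e-9)

    def test_mismatched_grids_raise(self):
        g = _grid(4)
        other = VoxelGrid(np.zeros((4, 4, 4)), (2.0,) * 3, (0.0,) * 3)
        with pytest.raises(ValueError):
            flash_dose_map([g.zeros_like()], [other.zeros_like()],
                           DoseRateConfig())


def test_timeline_rejects_overlapping_emissions():
    with pytest.raises(ValueError):
        DeliveryTimeline([0, 1], [0.0, 0.05], [0.1, 0.1], [1.0, 1.0])
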