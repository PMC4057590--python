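"""Synthetic cine/cohort/strain generators: kinetics, rendering, determinism."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.integrate import quad

from mbceus import (
    GrowthParams,
    KineticParams,
    TreatmentSchedule,
    make_phantom,
    render_cine,
    simulate_bound,
    simulate_circulating,
    simulate_growth_cohort,
    simulate_strain_pair,
)
from mbceus.cohort import percent_delta, tumor_volume
from mbceus.errors import MaskError, ParameterError
from mbceus.synthetic_data import circulating_kernel


class TestCirculating:
    def test_zero_amplitude_gives_zero_curve(self, params, time_grid):
        p = replace(params, bolus_amplitude=0.0)
        assert np.all(simulate_circulating(p, time_grid) == 0)

    def test_peak_at_bolus_peak_time(self, params, time_grid):
        c = simulate_circulating(params, time_grid, apply_flash=False)
        assert time_grid[np.argmax(c)] == params.bolus_peak_time

    def test_single_interior_maximum(self, params):
        t = np.linspace(0.01, 350, 7000)
        c = simulate_circulating(params, np.insert(t, 0, 0.0), apply_flash=False)
        peaks = np.flatnonzero((c[1:-1] > c[:-2]) & (c[1:-1] >= c[2:]))
        assert len(peaks) == 1

    def test_flash_recovery_five_time_constants(self, params, time_grid):
        # 15 s after a flash at 360 s is ~5 replenishment time constants
        p = replace(params, replenish_tau=3.0)
        flashed = simulate_circulating(p, time_grid)
        unflashed = simulate_circulating(p, time_grid, apply_flash=False)
        i = np.flatnonzero(time_grid == 375.0)[0]
        assert flashed[i] == pytest.approx(unflashed[i], rel=0.01)

    def test_zero_during_flash(self, params, time_grid):
        c = simulate_circulating(params, time_grid)
        in_flash = (time_grid >= params.flash_onset) & (time_grid < params.flash_end)
        assert in_flash.any() and np.all(c[in_flash] == 0)

    def test_nonnegative(self, params, time_grid):
        assert np.all(simulate_circulating(params, time_grid) >= 0)

    def test_bad_parameters_rejected(self):
        with pytest.raises(ParameterError):
            KineticParams(washout_tau=-1.0)
        with pytest.raises(ParameterError):
            KineticParams(bolus_shape=0.0)
        with pytest.raises(ParameterError):
            KineticParams(flash_onset=1.0, bolus_peak_time=8.0)

    def test_grid_validation(self, params):
        with pytest.raises(ParameterError):
            simulate_circulating(params, [0.0, 1.0, 1.0])
        with pytest.raises(ParameterError):
            simulate_circulating(params, [-1.0, 0.0])


class TestBound:
    def test_zero_rho_gives_zero(self, params, time_grid):
        c = simulate_circulating(params, time_grid, apply_flash=False)
        assert np.all(simulate_bound(time_grid, c, 0.0, params.k_on) == 0)

    def test_linearity_in_rho(self, params, time_grid):
        c = simulate_circulating(params, time_grid, apply_flash=False)
        b1 = simulate_bound(time_grid, c, 1.0, params.k_on, params.flash_onset)
        b2 = simulate_bound(time_grid, c, 2.0, params.k_on, params.flash_onset)
        pre = time_grid < params.flash_onset
        assert np.allclose(b2[pre], 2.0 * b1[pre])

    def test_cumulative_integral_ratio_matches_quadrature(self, params):
        """Pre-flash bound ratio equals the kernel's integral ratio (quad oracle)."""
        t = np.arange(0, 3600) / 10.0
        c = simulate_circulating(params, t, apply_flash=False)
        b = simulate_bound(t, c, params.rho, params.k_on)
        i359 = np.flatnonzero(t == 359.0)[0]
        i180 = np.flatnonzero(t == 180.0)[0]
        pts = [params.bolus_peak_time, 2 * params.bolus_peak_time]
        q359 = quad(lambda s: circulating_kernel(params, s), 0, 359, points=pts, limit=200)[0]
        q180 = quad(lambda s: circulating_kernel(params, s), 0, 180, points=pts, limit=200)[0]
        assert b[i359] / b[i180] == pytest.approx(q359 / q180, rel=1e-4)

    def test_destroyed_at_flash_onset(self, params, time_grid):
        c = simulate_circulating(params, time_grid, apply_flash=False)
        b = simulate_bound(time_grid, c, 1.0, params.k_on, params.flash_onset)
        assert np.all(b[time_grid >= params.flash_onset] == 0)
        assert b[time_grid < params.flash_onset][-1] > 0

    def test_monotone_in_rho_and_kon(self, params, time_grid):
        c = simulate_circulating(params, time_grid, apply_flash=False)
        i = np.flatnonzero(time_grid < params.flash_onset)[-1]
        levels = [
            simulate_bound(time_grid, c, rho, k, params.flash_onset)[i]
            for rho, k in [(0.5, 0.01), (1.0, 0.01), (1.0, 0.02), (2.0, 0.02)]
        ]
        assert levels == sorted(levels)

    def test_negative_rho_rejected(self, params, time_grid):
        c = simulate_circulating(params, time_grid, apply_flash=False)
        with pytest.raises(ParameterError):
            simulate_bound(time_grid, c, -1.0, params.k_on)


class TestPhantom:
    def test_subset_and_disjointness_laws(self):
        ph = make_phantom(necrotic_fraction=0.3)
        assert not np.any(ph.necrotic_submask & ~ph.tumor_mask)
        assert not np.any(ph.pad_mask & ph.tumor_mask)
        assert np.all(ph.receptor_map[ph.necrotic_submask] == 0)

    def test_necrotic_count_is_exact(self):
        ph = make_phantom(necrotic_fraction=0.3)
        n = ph.tumor_mask.sum()
        assert ph.necrotic_submask.sum() == round(0.3 * n)

    def test_inconsistent_phantom_rejected(self):
        from mbceus.containers import TumorPhantom

        tumor = np.zeros((8, 8), bool)
        tumor[2:6, 2:6] = True
        stray = np.zeros((8, 8), bool)
        stray[0, 0] = True  # outside the tumor
        with pytest.raises(MaskError):
            TumorPhantom(tumor, stray, np.zeros((8, 8), bool), np.zeros((8, 8)))


class TestRenderCine:
    def test_same_seed_is_bit_identical(self, params, sim_law, small_phantom):
        a = render_cine(small_phantom, params, sim_law, noise_sd=0.1, seed=5)
        b = render_cine(small_phantom, params, sim_law, noise_sd=0.1, seed=5)
        assert np.array_equal(a.frames, b.frames)
        c = render_cine(small_phantom, params, sim_law, noise_sd=0.1, seed=6)
        assert not np.array_equal(a.frames, c.frames)

    def test_flash_frames_saturated(self, params, sim_law, small_phantom):
        cine = render_cine(small_phantom, params, sim_law)
        in_flash = (cine.times >= params.flash_onset) & (cine.times < params.flash_end)
        assert np.all(cine.frames[in_flash] == 255)

    def test_necrotic_pixels_at_background_at_peak(self, params, sim_law):
        ph = make_phantom(necrotic_fraction=0.3)
        cine = render_cine(ph, params, sim_law, noise_sd=0.0)
        peak = int(np.argmax(cine.times == params.bolus_peak_time))
        frame = cine.frames[np.flatnonzero(cine.times == params.bolus_peak_time)[0]]
        background_level = frame[~ph.tumor_mask & ~ph.pad_mask][0]
        at_background = frame[ph.tumor_mask] == background_level
        assert at_background.sum() == ph.necrotic_submask.sum()

    def test_conservation_rho_zero(self, params, sim_law):
        """Noise-free, unbound: ROI power tracks background + gain*C."""
        from mbceus import roi_tic

        ph = make_phantom(necrotic_fraction=0.0, rho=0.0)
        cine = render_cine(ph, params, sim_law, noise_sd=0.0, gain=1.0, background_power=1.0)
        c = simulate_circulating(params, cine.times)
        tic = roi_tic(cine, ph.tumor_mask, sim_law)
        ok = ~((cine.times >= params.flash_onset) & (cine.times < params.flash_end))
        expected = 1.0 + c[ok]
        assert np.allclose(tic.values[ok], expected, rtol=2 * sim_law.half_level_tolerance())

    def test_flash_outside_exam_rejected(self, params, sim_law, small_phantom):
        with pytest.raises(ParameterError):
            render_cine(small_phantom, params, sim_law, clips=((0.0, 30.0),))


class TestGrowthCohort:
    def schedules(self):
        return [
            TreatmentSchedule.placebo(),
            TreatmentSchedule.interrupted(),
            TreatmentSchedule.stopped(),
        ]

    def _median_deltas(self, table, start, final):
        out = {}
        for gid, sub in table.groupby("group"):
            deltas = []
            for _, animal in sub.groupby("animal_id"):
                vol = {
                    int(r.day): tumor_volume(r.height_mm, r.width_mm, r.thickness_mm)
                    for r in animal.itertuples()
                }
                deltas.append(percent_delta(vol[start], vol[final]))
            out[gid] = float(np.median(deltas))
        return out

    def test_noise_free_equal_rates_identical_groups(self):
        gp = GrowthParams(
            growth_rate_untreated=0.05,
            growth_rate_on_drug=0.0499999,
            rebound_multiplier=1.0,
            animal_noise_sd=0.0,
        )
        t = simulate_growth_cohort(gp, self.schedules(), [2, 2, 2], seed=0)
        piv = t.pivot_table(index="day", columns="group", values="height_mm")
        assert np.allclose(piv[1], piv[2], rtol=1e-4)
        assert np.allclose(piv[1], piv[3], rtol=1e-4)

    def test_response_ordering_day13_vs_day5(self):
        """Interrupted treatment regrows least; definitive stop matches placebo."""
        gp = GrowthParams(animal_noise_sd=0.0, measurement_noise_sd=0.0)
        t = simulate_growth_cohort(gp, self.schedules(), [4, 6, 4], seed=0)
        med = self._median_deltas(t, 5, 13)
        assert med[2] < med[1] and med[2] < med[3]
        assert med[1] == pytest.approx(med[3], rel=0.15)

    def test_seed_reproducibility(self):
        gp = GrowthParams()
        a = simulate_growth_cohort(gp, self.schedules(), [3, 3, 3], seed=11)
        b = simulate_growth_cohort(gp, self.schedules(), [3, 3, 3], seed=11)
        assert a.equals(b)

    def test_volume_recovered_from_diameter_triple(self):
        gp = GrowthParams(animal_noise_sd=0.0, measurement_noise_sd=0.0)
        t = simulate_growth_cohort(gp, [TreatmentSchedule.placebo()], [1], days=(0,), seed=0)
        r = t.iloc[0]
        assert tumor_volume(r.height_mm, r.width_mm, r.thickness_mm) == pytest.approx(
            gp.baseline_volume
        )

    def test_empty_schedule_list_rejected(self):
        with pytest.raises(ParameterError):
            simulate_growth_cohort(GrowthParams(), [], [], seed=0)

    def test_canonical_schedules_enforced(self):
        with pytest.raises(ParameterError):
            TreatmentSchedule(1, frozenset({0}))


class TestStrainPair:
    def test_unit_ratio_noise_free_fields_identical(self, small_phantom):
        pair = simulate_strain_pair(1.0, 0.0, small_phantom, seed=0)
        s = pair.strains[0]
        assert np.all(s[pair.tumor_mask] == s[pair.pad_mask][0])

    def test_exact_ratio_by_construction(self, small_phantom):
        from mbceus import strain_ratio

        pair = simulate_strain_pair(1.33, 0.0, small_phantom, seed=0)
        r = strain_ratio(pair.strains[0], pair.tumor_mask, pair.pad_mask)
        assert r == pytest.approx(1.33)

    def test_replicates_differ_only_by_noise(self, small_phantom):
        pair = simulate_strain_pair(1.2, 0.05, small_phantom, seed=3)
        assert pair.n_replicates == 3
        assert not np.array_equal(pair.strains[0], pair.strains[1])
        for s in pair.strains:
            assert np.all(s[pair.pad_mask] == s[pair.pad_mask][0])

    def test_nonpositive_ratio_rejected(self, small_phantom):
        with pytest.raises(ParameterError):
            simulate_strain_pair(0.0, 0.0, small_phantom, seed=0)
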