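"""Plant simulator: unit operations, tanks, deviations, campaign properties."""

import numpy as np
import pytest

from mabtrain.simulator import (
    DeviationSpec,
    ProcessConfig,
    SurgeTankState,
    default_phase_durations,
    inject_deviation,
    run_campaign,
    simulate_chrom_cycle,
    simulate_clarification,
    simulate_ufdf_cycle,
    simulate_vi,
    step_surge_tank,
)
from mabtrain.topology import SurgeTankSpec, build_topology, default_config

RNG = lambda s=0: np.random.default_rng(s)  # noqa: E731
PHASES = default_phase_durations()


class TestClarification:
    def test_zero_efficiency_no_separation(self):
        _, red = simulate_clarification(0.0, 4, 20.0, 100.0, RNG())
        assert red == 0.0

    def test_four_chambers_solve_90_percent(self):
        # per-chamber efficiency solving (1-e)^4 = 0.10 analytically
        e = 1.0 - 0.10 ** 0.25
        _, red = simulate_clarification(e, 4, 20.0, 100.0, RNG())
        assert abs(red - 0.90) < 5e-4

    def test_nominal_config_matches_90_percent(self):
        cfg = ProcessConfig()
        _, red = simulate_clarification(cfg.clar_chamber_efficiency, cfg.clar_chambers,
                                        20.0, 100.0, RNG())
        assert abs(red - 0.90) < 1e-12

    def test_efficiency_out_of_range(self):
        with pytest.raises(ValueError):
            simulate_clarification(1.0, 4, 20.0, 100.0, RNG())


class TestViralInactivation:
    def test_healthy_pump_holds_set_point(self):
        out = simulate_vi(None, True, 0.0, RNG(), noise_sd=0.0, n=50)
        np.testing.assert_allclose(out, 7.0)

    def test_pump_error_offsets_ph(self):
        out = simulate_vi(None, False, -1.5, RNG(), noise_sd=0.0, n=50)
        np.testing.assert_allclose(out, 5.5)

    def test_zero_magnitude_error_is_identity(self):
        ok = simulate_vi(None, True, 0.0, RNG(1), noise_sd=0.02, n=50)
        broken = simulate_vi(None, False, 0.0, RNG(1), noise_sd=0.02, n=50)
        np.testing.assert_allclose(ok, broken)


def _dev(type_, unit, lo=1, hi=1, **params):
    return DeviationSpec(scenario=9, type=type_, unit=unit, onset_cycle=lo,
                         end_cycle=hi, params=params)


class TestChromCycle:
    def test_noise_free_determinism(self):
        a, _ = simulate_chrom_cycle("protein_a", 1, PHASES, 2.0, [], RNG(0), noise=False)
        b, _ = simulate_chrom_cycle("protein_a", 1, PHASES, 2.0, [], RNG(99), noise=False)
        for sid in a.traces:
            np.testing.assert_array_equal(a.traces[sid][1], b.traces[sid][1])

    def test_buffer_tank_empty_truncates_gradient(self):
        dev = _dev("buffer_tank_empty", "cex", plateau_fraction=0.6)
        rec, _ = simulate_chrom_cycle("cex", 1, PHASES, 2.0, [dev], RNG(), noise=False)
        nominal, _ = simulate_chrom_cycle("cex", 1, PHASES, 2.0, [], RNG(), noise=False)
        assert rec.traces["cond"][1].max() < nominal.traces["cond"][1].max()
        # plateau sits at the level reached when the tank emptied
        assert abs(rec.traces["cond"][1].max() - (5.0 + 20.0 * 0.6)) < 0.5

    def test_valve_error_spikes_elution_ph(self):
        dev = _dev("valve_manifold_error", "proa", ph_spike=2.0, spike_minutes=3)
        rec, _ = simulate_chrom_cycle("protein_a", 1, PHASES, 2.0, [dev], RNG(), noise=False)
        nominal, _ = simulate_chrom_cycle("protein_a", 1, PHASES, 2.0, [], RNG(), noise=False)
        el = slice(204, 306)  # elution landmarks at 10 s sampling
        assert rec.traces["ph"][1][el].max() > nominal.traces["ph"][1][el].max() + 1.5

    def test_deviation_outside_window_inert(self):
        dev = _dev("column_pressure_buildup", "proa", lo=5, hi=6)
        rec, _ = simulate_chrom_cycle("protein_a", 1, PHASES, 2.0, [dev], RNG(), noise=False)
        nominal, _ = simulate_chrom_cycle("protein_a", 1, PHASES, 2.0, [], RNG(), noise=False)
        np.testing.assert_array_equal(rec.traces["press"][1], nominal.traces["press"][1])

    def test_monotone_deviation_response(self):
        """Larger fault magnitudes move the cycle further from the steady trace."""
        base, _ = simulate_chrom_cycle("protein_a", 1, PHASES, 2.0, [], RNG(), noise=False)
        dists = []
        for ramp in (0.01, 0.03, 0.05, 0.10):
            dev = _dev("column_pressure_buildup", "proa", ramp_bar_per_min=ramp)
            rec, _ = simulate_chrom_cycle("protein_a", 1, PHASES, 2.0, [dev], RNG(),
                                          noise=False)
            dists.append(np.linalg.norm(rec.traces["press"][1] - base.traces["press"][1]))
        assert all(b >= a for a, b in zip(dists, dists[1:]))

    def test_ph_penalty_reduces_cex_peak(self):
        good, _ = simulate_chrom_cycle("cex", 1, PHASES, 2.0, [], RNG(), noise=False,
                                       post_vi_ph=7.0)
        bad, info = simulate_chrom_cycle("cex", 1, PHASES, 2.0, [], RNG(), noise=False,
                                         post_vi_ph=5.5)
        assert info["yield_factor"] == pytest.approx(0.6)
        assert bad.traces["uv"][1].max() < good.traces["uv"][1].max()

    def test_unknown_unit_rejected(self):
        with pytest.raises(ValueError, match="unknown chromatography unit"):
            simulate_chrom_cycle("ufdf", 1, PHASES, 2.0, [], RNG())


class TestUfdfCycle:
    def test_closed_form_end_time(self):
        rec, info = simulate_ufdf_cycle(500.0, 20.0, 250.0, RNG(), draw_rate_g_min=2.0,
                                        noise_sd_bar=0.0)
        assert info["end_time_min"] == pytest.approx((500.0 - 250.0) / 2.0)
        assert rec.duration == pytest.approx(125.0 * 60.0)

    def test_dilute_load_gives_lower_tmp_throughout(self):
        rich, _ = simulate_ufdf_cycle(500.0, 20.0, 250.0, RNG(), noise_sd_bar=0.0)
        dilute, _ = simulate_ufdf_cycle(500.0, 10.0, 250.0, RNG(), noise_sd_bar=0.0)
        tmp_rich = rich.traces["press_feed"][1] - rich.traces["press_permeate"][1]
        tmp_dilute = dilute.traces["press_feed"][1] - dilute.traces["press_permeate"][1]
        assert np.all(tmp_dilute < tmp_rich)

    def test_same_seed_identical(self):
        a, _ = simulate_ufdf_cycle(500.0, 20.0, 250.0, RNG(5))
        b, _ = simulate_ufdf_cycle(500.0, 20.0, 250.0, RNG(5))
        for sid in a.traces:
            np.testing.assert_array_equal(a.traces[sid][1], b.traces[sid][1])

    def test_empty_cycle_rejected(self):
        with pytest.raises(ValueError, match="empty cycle"):
            simulate_ufdf_cycle(200.0, 20.0, 250.0, RNG())


def _tank(weight, **kw):
    spec = SurgeTankSpec(id="t", capacity=1200.0, w_max=1000.0, w_min=100.0,
                         w_restart_lo=300.0, w_restart_hi=600.0)
    return SurgeTankState(spec=spec, weight=weight, **kw)


class TestSurgeTank:
    def test_balanced_flows_hold_weight(self):
        st = _tank(500.0, inflow_rate=10.0, outflow_rate=10.0)
        new, events = step_surge_tank(st, 3600.0)
        assert new.weight == pytest.approx(500.0) and events == []

    def test_upward_crossing_emits_pause_upstream(self):
        st = _tank(995.0, inflow_rate=10.0, outflow_rate=0.0)
        new, events = step_surge_tank(st, 60.0)
        assert new.weight == pytest.approx(1005.0)
        assert "pause_upstream_request" in events

    def test_paused_downstream_forces_zero_outflow(self):
        st = _tank(500.0, inflow_rate=0.0, outflow_rate=50.0, paused_downstream=True)
        new, _ = step_surge_tank(st, 600.0)
        assert new.weight == pytest.approx(500.0)

    def test_downward_crossing_emits_pause_downstream(self):
        st = _tank(105.0, inflow_rate=0.0, outflow_rate=10.0)
        _, events = step_surge_tank(st, 60.0)
        assert "pause_downstream_request" in events

    def test_overflow_clamped_with_fault(self):
        st = _tank(1150.0, inflow_rate=100.0, outflow_rate=0.0)
        new, events = step_surge_tank(st, 60.0)
        assert "overflow_fault" in events and new.weight == 1200.0

    def test_restart_eligibility_on_entering_range(self):
        st = _tank(250.0, inflow_rate=60.0, outflow_rate=0.0)
        new, events = step_surge_tank(st, 60.0)
        assert new.weight == pytest.approx(310.0)
        assert "restart_eligible" in events

    def test_well_mixed_concentration(self):
        st = _tank(500.0, mab_mass=5.0, inflow_rate=10.0, outflow_rate=10.0,
                   inflow_conc=0.02)
        new, _ = step_surge_tank(st, 60.0)
        # 10 g in at 0.02, 10 g out at 0.01: net +0.1 g mAb
        assert new.mab_mass == pytest.approx(5.0 + 0.2 - 0.1)


class TestDeviationSchedule:
    def test_inject_extends(self):
        d = _dev("column_pressure_buildup", "proa")
        assert len(inject_deviation([], d)) == 1

    def test_overlapping_specs_compose(self):
        d1 = _dev("column_pressure_buildup", "proa", lo=43, hi=45)
        d2 = _dev("neutralization_pump_error", "vi", lo=43, hi=45, ph_offset=-1.5)
        rec, info = simulate_chrom_cycle("protein_a", 44, PHASES, 2.0, [d1, d2], RNG(),
                                         noise=False)
        nominal, _ = simulate_chrom_cycle("protein_a", 44, PHASES, 2.0, [], RNG(),
                                          noise=False)
        assert rec.traces["press"][1].max() > nominal.traces["press"][1].max() + 1.0
        assert info["area_factor"] < 1.0

    def test_onset_after_end_rejected(self):
        with pytest.raises(ValueError, match="onset"):
            DeviationSpec(scenario=1, type="buffer_tank_empty", unit="cex",
                          onset_cycle=5, end_cycle=4)

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError, match="unknown deviation type"):
            DeviationSpec(scenario=1, type="gremlins", unit="cex",
                          onset_cycle=1, end_cycle=1)

    def test_unknown_unit_rejected(self):
        d = _dev("buffer_tank_empty", "cex")
        bad = DeviationSpec(scenario=2, type="buffer_tank_empty", unit="mystery",
                            onset_cycle=1, end_cycle=1)
        with pytest.raises(ValueError, match="unknown target unit"):
            inject_deviation([d], bad)


class TestCampaign:
    def test_zero_duration_empty(self):
        cfg = default_config()
        cfg["campaign_duration_h"] = 0.0
        res = run_campaign(topology=build_topology(cfg), seed=0)
        assert len(res.historian) == 0 and res.events == []

    def test_nominal_counts(self, nominal_campaign):
        assert len(nominal_campaign.chrom_cycles["proa"]) == 53
        assert len(nominal_campaign.chrom_cycles["cex"]) == 53
        assert len(nominal_campaign.ufdf_cycles) == 5

    @pytest.mark.parametrize("campaign", ["nominal_campaign", "deviated_campaign"])
    def test_mass_conservation(self, campaign, request):
        res = request.getfixturevalue(campaign)
        assert res.mass_balance_error < 1e-6

    def test_seed_reproducibility(self, topology, deviation_schedule):
        a = run_campaign(topology=topology, schedule=deviation_schedule, seed=11)
        b = run_campaign(topology=topology, schedule=deviation_schedule, seed=11)
        assert a.historian.equals(b.historian)
        assert a.mass_audit == b.mass_audit
        assert [(e.t, e.source, e.action) for e in a.events] == \
               [(e.t, e.source, e.action) for e in b.events]

    def test_deviations_confined_to_listed_cycles(self, topology, deviation_schedule):
        dev = run_campaign(topology=topology, schedule=deviation_schedule, seed=3,
                           noise=False)
        nom = run_campaign(topology=topology, schedule=[], seed=3, noise=False)
        # pressure build-up is listed for cycles 43-45 only
        for c in (42, 46):
            np.testing.assert_array_equal(
                dev.chrom_cycles["proa"][c - 1].traces["press"][1],
                nom.chrom_cycles["proa"][c - 1].traces["press"][1])
        for c in (43, 44, 45):
            assert dev.chrom_cycles["proa"][c - 1].traces["press"][1].max() > \
                nom.chrom_cycles["proa"][c - 1].traces["press"][1].max() + 1.0

    def test_noise_free_steady_cycles_identical(self, topology):
        res = run_campaign(topology=topology, schedule=[], seed=0, noise=False)
        t20 = res.chrom_cycles["cex"][19].traces
        t35 = res.chrom_cycles["cex"][34].traces
        for sid in t20:
            np.testing.assert_allclose(t20[sid][1], t35[sid][1], atol=1e-9)

    def test_ufdf_cycle5_starved_under_schedule(self, deviated_campaign):
        summaries = {s["cycle"]: s for s in deviated_campaign.ufdf_summaries}
        assert summaries[5]["duration_h"] < 11.0  # ends early on the weight trigger
        assert summaries[5]["mean_conc_g_l"] < summaries[2]["mean_conc_g_l"]


class TestAtLine:
    def test_cqa_series_hourly_with_sd_bands(self):
        from mabtrain.monitor import univariate_limits
        from mabtrain.simulator import simulate_cqa_series

        series = simulate_cqa_series(48.0, RNG(0))
        titer = series["titer_g_l"]
        assert titer.t.size == 48 and titer.t[1] - titer.t[0] == 3600.0
        (mu, lo, hi), flags = univariate_limits(titer.values, k_sd=1.0)
        assert lo < mu < hi
        # roughly a third of points sit outside the +/-1 SD display band
        assert 0.1 < flags.mean() < 0.6

    def test_spectrum_shape_and_preprocessing(self):
        from mabtrain.historian import preprocess_spectrum
        from mabtrain.simulator import simulate_atline_spectrum

        spec = simulate_atline_spectrum(0.0, RNG(1))
        assert spec.axis.size == spec.intensity.size == 256
        out = preprocess_spectrum(spec)
        assert abs(out.intensity.mean()) < 1e-12
        assert "snv" in out.provenance
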