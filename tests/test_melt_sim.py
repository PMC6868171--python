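"""Melt simulator: geometry, Fe assignment, rates, stepping, ensembles."""

import numpy as np
import pytest

from bergfert.melt_sim import (
    FeScenarioConfig,
    GeometryRules,
    MeltCoefficients,
    MeltForcing,
    SimConfig,
    assign_fe,
    build_geometry,
    check_stability,
    melt_rates,
    run_ensemble,
    run_single,
    shell_thickness,
    step,
)
from _voxel import voxel_replay

#: forcing under which every melt term evaluates to zero (surface water at the
#: wave-erosion zero point, no relative velocity, no shortwave)
DEAD_CALM = MeltForcing(tw_surface=-2.0, tw_bottom=-2.0, u_rel=0.0, sw_flux=0.0)

NO_CAPSIZE = 1e-6  # disable instability removal for small-berg oracle tests


@pytest.fixture(scope="module")
def source(calibrated_set):
    return calibrated_set


class TestGeometry:
    def test_keel_power_law_and_flotation(self):
        g = build_geometry(500.0)
        assert g.keel == pytest.approx(2.91 * 500**0.71, rel=1e-12)
        assert g.height == pytest.approx(g.keel / 0.895, rel=1e-12)
        assert g.freeboard == pytest.approx(g.height - g.keel, rel=1e-9)
        assert g.width == pytest.approx(310.0)
        g100 = build_geometry(100.0)
        assert g100.keel == pytest.approx(76.55, abs=0.05)

    def test_max_keel_cap(self):
        g = build_geometry(1000.0, GeometryRules(max_keel=300.0))
        assert g.keel == 300.0

    def test_neutral_buoyancy_is_nonphysical(self):
        with pytest.raises(ValueError, match="freeboard"):
            build_geometry(500.0, GeometryRules(density_ratio=1.0))

    def test_layering_covers_height_with_fractional_bottom(self):
        g = build_geometry(500.0)
        assert g.z_edges[0] == 0.0
        assert g.z_edges[-1] == pytest.approx(g.height)
        assert (np.diff(g.z_edges)[:-1] == 1.0).all()


class TestAssignFe:
    def test_shell_thickness_solves_rind_volume(self):
        g = build_geometry(500.0)
        t = shell_thickness(g.length, g.width, g.height, 0.09)
        core = (g.length - 2 * t) * (g.width - 2 * t) * (g.height - 2 * t)
        assert (g.volume - core) / g.volume == pytest.approx(0.09, rel=1e-9)
        assert t == pytest.approx(5.1788, abs=1e-3)

    def test_basal_slab_thickness(self):
        g = build_geometry(500.0)
        state = assign_fe(g, FeScenarioConfig(scenario="basal"))
        slab = 0.09 * g.height
        high = state.c_int == 1.0e-4
        vol_high = (state.areas() * state.thickness())[high].sum()
        assert vol_high == pytest.approx(0.09 * g.volume, rel=1e-9)
        assert state.hi[high].max() - state.lo[high].min() == pytest.approx(slab, rel=1e-9)

    def test_all_scenarios_hold_equal_total_fe(self, source):
        g = build_geometry(200.0)
        target = 1000.0 * g.volume * (0.09 * 1e-4 + 0.91 * 1.7e-7)
        for name in ("shell", "basal", "monte_carlo"):
            cfg = FeScenarioConfig(
                scenario=name, sample_source=source if name == "monte_carlo" else None
            )
            state = assign_fe(g, cfg)
            tol = 1e-6 if name == "monte_carlo" else 1e-9
            assert state.initial_fe == pytest.approx(target, rel=tol)

    def test_monte_carlo_requires_source(self):
        with pytest.raises(ValueError, match="sample_source"):
            assign_fe(build_geometry(100.0), FeScenarioConfig(scenario="monte_carlo"))

    def test_monte_carlo_reproducible(self, source):
        g = build_geometry(100.0)
        cfg = FeScenarioConfig(scenario="monte_carlo", sample_source=source, seed=9)
        a, b = assign_fe(g, cfg), assign_fe(g, cfg)
        np.testing.assert_array_equal(a.c_int, b.c_int)


class TestMeltRates:
    def test_wave_erosion_hand_value(self):
        state = assign_fe(build_geometry(100.0), FeScenarioConfig(scenario="basal"))
        r = melt_rates(state, MeltForcing())  # Ss=1.5, IC=0, Tw(0)=3
        assert r.wave == pytest.approx(1.25, rel=1e-12)

    def test_full_sea_ice_kills_waves(self):
        state = assign_fe(build_geometry(100.0), FeScenarioConfig(scenario="basal"))
        r = melt_rates(state, MeltForcing(sea_ice=1.0))
        assert r.wave == 0.0

    def test_albedo_controls_surface_melt(self):
        expected_clean = 200 * (1 - 0.7) * 86400 / (917 * 3.34e5)
        expected_dirty = 200 * (1 - 0.3) * 86400 / (917 * 3.34e5)
        basal = assign_fe(build_geometry(100.0), FeScenarioConfig(scenario="basal"))
        shell = assign_fe(build_geometry(100.0), FeScenarioConfig(scenario="shell"))
        assert melt_rates(basal, MeltForcing()).surface == pytest.approx(expected_clean)
        assert melt_rates(shell, MeltForcing()).surface == pytest.approx(expected_dirty)
        assert expected_clean == pytest.approx(0.017, abs=5e-4)
        assert expected_dirty == pytest.approx(0.0395, abs=5e-4)

    def test_rates_clamped_nonnegative(self):
        state = assign_fe(build_geometry(100.0), FeScenarioConfig(scenario="basal"))
        r = melt_rates(state, DEAD_CALM)
        assert r.wave == 0.0 and r.basal == 0.0 and r.surface == 0.0
        assert (r.buoyant == 0.0).all()


class TestStep:
    def test_zero_rates_leave_state_unchanged(self):
        state = assign_fe(build_geometry(100.0), FeScenarioConfig(scenario="shell"))
        v0, f0 = state.total_volume(), state.remaining_fe()
        _, released, melted = step(state, DEAD_CALM)
        assert released == 0.0 and melted == 0.0
        assert state.total_volume() == v0 and state.remaining_fe() == f0

    def test_uniform_concentration_release_is_proportional(self):
        state = assign_fe(build_geometry(60.0), FeScenarioConfig(scenario="basal"))
        state.c_int[:] = 1.7e-7  # overwrite to a uniform berg
        state.h[:] = 0.0
        state.initial_fe = state.remaining_fe()
        sim = SimConfig(instability_threshold=NO_CAPSIZE)
        for _ in range(20):
            step(state, MeltForcing(), sim)
        fe_frac = state.released_fe / state.initial_fe
        vol_frac = state.melted_volume / state.initial_volume
        assert fe_frac == pytest.approx(vol_frac, rel=1e-9)

    def test_waterline_band_exhausts_shell_in_about_five_days(self):
        """With wave erosion only (1.25 m/day), the waterline band's shell
        rind (~5.2 m) is gone after ~4 days, after which the daily release
        drops to the background concentration."""
        wave_only = MeltCoefficients(buoyant_lin=0.0, buoyant_quad=0.0)
        forcing = MeltForcing(sw_flux=0.0, u_rel=0.0)
        state = assign_fe(build_geometry(500.0), FeScenarioConfig(scenario="shell"))
        sim = SimConfig(wave_mode="waterline")
        daily = []
        for _ in range(8):
            _, released, _ = step(state, forcing, sim, wave_only)
            daily.append(released)
        assert daily[0] / daily[6] > 5.0  # high-Fe rind phase vs background phase
        assert daily[1] == pytest.approx(daily[0], rel=0.05)

    def test_iron_conserved_over_a_full_run(self, source):
        for name in ("shell", "basal", "monte_carlo"):
            cfg = FeScenarioConfig(
                scenario=name, sample_source=source if name == "monte_carlo" else None
            )
            state = assign_fe(build_geometry(150.0), cfg)
            sim = SimConfig(instability_threshold=NO_CAPSIZE)
            for _ in range(120):
                if state.alive:
                    step(state, MeltForcing(), sim)
            total = state.released_fe + state.remaining_fe()
            assert total == pytest.approx(state.initial_fe, rel=1e-9)

    def test_volume_monotone_and_release_monotone(self):
        r = run_single(300.0, FeScenarioConfig(scenario="shell"))
        assert (np.diff(r.fe_fraction) >= -1e-15).all()
        assert (np.diff(r.volume_fraction) >= -1e-15).all()


class TestStability:
    def test_squat_berg_is_stable_tall_berg_is_not(self):
        state = assign_fe(build_geometry(500.0), FeScenarioConfig(scenario="basal"))
        assert check_stability(state)  # extents exceed height at t=0
        # erode until the widest extent is half the height
        state.e[:] = (state.length0 - 0.5 * state.height0) / 2.0
        assert not check_stability(state)

    def test_small_berg_capsizes_before_large_under_full_face_melt(self):
        small = run_single(50.0, FeScenarioConfig(scenario="shell"))
        large = run_single(1000.0, FeScenarioConfig(scenario="shell"))
        assert small.unstable_day is not None
        assert large.unstable_day is None
        assert not small.alive[-1]

    def test_frozen_after_removal(self):
        r = run_single(50.0, FeScenarioConfig(scenario="shell"))
        d = r.unstable_day
        assert (r.fe_fraction[d:] == r.fe_fraction[d]).all()


class TestVoxelOracle:
    @pytest.mark.parametrize("scenario", ["shell", "basal", "monte_carlo"])
    @pytest.mark.parametrize("wave_mode", ["waterline", "full_face"])
    def test_slab_model_matches_voxel_integration(self, scenario, wave_mode, source):
        """On a <=20 m berg the production slab model and an explicit 1 m³
        voxel integration agree on daily volume and Fe to within 2 %."""
        cfg = FeScenarioConfig(
            scenario=scenario,
            sample_source=source if scenario == "monte_carlo" else None,
            seed=4,
        )
        sim = SimConfig(duration_days=25, wave_mode=wave_mode,
                        record_history=True, instability_threshold=NO_CAPSIZE)
        rng = np.random.default_rng(4)
        reference = assign_fe(build_geometry(18.0), cfg, rng=np.random.default_rng(4))
        state = assign_fe(build_geometry(18.0), cfg, rng=rng)
        volumes = [state.total_volume()]
        irons = [state.remaining_fe()]
        for _ in range(sim.duration_days):
            if state.alive:
                step(state, MeltForcing(), sim)
            volumes.append(state.total_volume())
            irons.append(state.remaining_fe())
        vol_oracle, fe_oracle = voxel_replay(reference, state.history)
        n = len(vol_oracle)
        np.testing.assert_allclose(
            vol_oracle, volumes[:n], atol=0.02 * state.initial_volume)
        np.testing.assert_allclose(
            fe_oracle, irons[:n], atol=0.02 * state.initial_fe)


class TestRunSingle:
    def test_zero_duration_gives_zero_fractions(self):
        r = run_single(100.0, FeScenarioConfig(scenario="shell"),
                       sim=SimConfig(duration_days=0))
        assert len(r.days) == 1 and r.fe_fraction[0] == 0.0

    def test_monte_carlo_release_tracks_volume_loss(self, source):
        r = run_single(
            100.0,
            FeScenarioConfig(scenario="monte_carlo", sample_source=source, seed=0),
        )
        assert np.abs(r.fe_fraction - r.volume_fraction).max() < 0.05

    @pytest.mark.parametrize("wave_mode", ["waterline", "full_face"])
    def test_shell_and_basal_release_at_least_monte_carlo(self, wave_mode, source):
        sim = SimConfig(wave_mode=wave_mode)
        shell = run_single(500.0, FeScenarioConfig(scenario="shell"), sim=sim)
        basal = run_single(500.0, FeScenarioConfig(scenario="basal"), sim=sim)
        mc = run_single(
            500.0,
            FeScenarioConfig(scenario="monte_carlo", sample_source=source, seed=0),
            sim=sim,
        )
        assert (shell.fe_fraction >= mc.fe_fraction - 1e-9).all()
        assert (basal.fe_fraction >= mc.fe_fraction - 1e-9).all()

    def test_full_face_melts_at_least_waterline(self):
        wl = run_single(200.0, FeScenarioConfig(scenario="shell"),
                        sim=SimConfig(wave_mode="waterline"))
        ff = run_single(200.0, FeScenarioConfig(scenario="shell"),
                        sim=SimConfig(wave_mode="full_face"))
        assert (ff.volume_fraction >= wl.volume_fraction - 1e-12).all()

    def test_thinner_high_fe_layer_amplifies_scenario_gap(self, source):
        def gap(high_fraction):
            shell = run_single(
                100.0, FeScenarioConfig(scenario="shell", high_fraction=high_fraction))
            mc = run_single(
                100.0,
                FeScenarioConfig(scenario="monte_carlo", high_fraction=high_fraction,
                                 sample_source=source, seed=0),
            )
            return shell.fe_fraction[81] - mc.fe_fraction[81]

        assert gap(0.03) > gap(0.09)

    def test_monte_carlo_release_unbiased_over_seeds(self, source):
        """E[Fe-loss fraction] equals the volume-loss fraction: the seed-mean
        difference stays within 3 Monte Carlo standard errors."""
        diffs = []
        for seed in range(50):
            r = run_single(
                30.0,
                FeScenarioConfig(scenario="monte_carlo", sample_source=source, seed=seed),
                sim=SimConfig(duration_days=40, wave_mode="waterline",
                              instability_threshold=NO_CAPSIZE),
            )
            diffs.append(r.fe_fraction - r.volume_fraction)
        diffs = np.array(diffs)
        for day in (5, 20, 40):
            mean = diffs[:, day].mean()
            se = diffs[:, day].std(ddof=1) / np.sqrt(len(diffs))
            assert abs(mean) < 3 * max(se, 1e-12)


class TestRunEnsemble:
    def test_single_member_equals_run_single(self):
        cfg = FeScenarioConfig(scenario="shell")
        sim = SimConfig(duration_days=40)
        single = run_single(300.0, cfg, sim=sim)
        ens = run_ensemble([(300.0, 1.0)], cfg, sim=sim)
        np.testing.assert_allclose(ens.fe_loss, single.fe_fraction, rtol=1e-12)
        np.testing.assert_allclose(ens.volume_loss, single.volume_fraction, rtol=1e-12)

    def test_unnormalized_weights_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            run_ensemble([(300.0, 0.5)], FeScenarioConfig(scenario="shell"))

    def test_reports_residence_time_values(self):
        ens = run_ensemble([(300.0, 1.0)], FeScenarioConfig(scenario="shell"))
        assert set(ens.at_residence) == {"day_14", "day_81", "day_148"}
        assert ens.at_residence["day_14"] <= ens.at_residence["day_81"]
        assert ens.at_residence["day_81"] <= ens.at_residence["day_148"]

    def test_unstable_members_leave_the_mean(self):
        # 50 m capsizes almost immediately under full-face melt; afterwards the
        # ensemble mean reflects only the surviving 300 m berg
        ens = run_ensemble([(50.0, 0.5), (300.0, 0.5)],
                           FeScenarioConfig(scenario="shell"),
                           sim=SimConfig(duration_days=40))
        solo = run_single(300.0, FeScenarioConfig(scenario="shell"),
                          sim=SimConfig(duration_days=40))
        assert ens.n_active[-1] == 1
        assert ens.fe_loss[-1] == pytest.approx(solo.fe_fraction[-1], rel=1e-9)
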