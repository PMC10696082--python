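import numpy as np
import pytest
from scipy.integrate import solve_ivp

from whealsim.model_functions import ResponseParams
from whealsim.presets import base_config, pattern_preset
from whealsim.simulator import (
    DermisGrid, KineticParameters, SimConfig, build_domain, mass_ledger,
    run, stability_dt, step,
)


def quiet_config(**overrides):
    """Small deterministic config with every coupling switched off."""
    rp = ResponseParams(gamma_t=0.0, gamma_c=0.0)
    kp = KineticParameters(delta_b=0.02, delta_t=0.05, delta_m=0.04,
                           mu_b=1.0, mu_t=0.5, mu_m=0.4, mu_c=0.6,
                           gamma_b=0.0, gamma_m=0.0, d_c=0.3, d_m=0.1,
                           response=rp)
    base = dict(grid=DermisGrid(length_cm=6.4, n=16), kinetics=kp,
                n_sites=2, site_radius_px=1, mast_capacity=5.0,
                basophil_capacity=5.0, mast_heterogeneity=0.0,
                hb_stimulus=0.0, hm_noise=0.0, t_end=2.0,
                snapshot_interval=0.5, seed=0)
    base.update(overrides)
    return SimConfig(**base)


class TestBuildDomain:
    def test_fixed_seed_is_reproducible(self):
        cfg = base_config(seed=9)
        _, occ1, st1 = build_domain(cfg)
        _, occ2, st2 = build_domain(cfg)
        assert np.array_equal(occ1.site_map, occ2.site_map)
        assert np.array_equal(occ1.mast_reservoir, occ2.mast_reservoir)
        assert np.array_equal(st1.h_m, st2.h_m)

    def test_zero_sites_leaves_chi_b_empty(self):
        cfg = quiet_config(n_sites=0)
        _, occ, st = build_domain(cfg)
        assert occ.n_sites == 0
        assert not (occ.site_map >= 0).any()
        assert st.h_b.size == 0

    def test_infeasible_site_packing_rejected(self):
        cfg = quiet_config(n_sites=200, site_radius_px=3)
        with pytest.raises(ValueError, match="non-overlapping"):
            build_domain(cfg)

    def test_basal_state_is_fixed_point_with_couplings_off(self):
        cfg = quiet_config()
        _, _, st = build_domain(cfg)
        kp = cfg.kinetics
        before = (st.h_b.copy(), st.tf.copy(), st.c.copy(), st.h_m.copy())
        for _ in range(50):
            st = step(st, kp, 0.01)
        assert np.allclose(st.h_b, before[0], atol=1e-12)
        assert np.allclose(st.tf, before[1], atol=1e-12)
        assert np.allclose(st.c, before[2], atol=1e-12)
        assert np.allclose(st.h_m, before[3], atol=1e-12)


class TestStep:
    def test_all_rates_zero_leaves_state_unchanged(self):
        cfg = quiet_config()
        cfg.kinetics = KineticParameters(
            delta_b=0, delta_t=0, delta_m=0, mu_b=0, mu_t=0, mu_m=0,
            mu_c=0, gamma_b=0, gamma_m=0, d_c=1e-12, d_m=1e-12,
            response=ResponseParams(gamma_t=0.0, gamma_c=0.0))
        _, _, st = build_domain(cfg)
        st.c[:] = 1.7  # arbitrary uniform level
        new = step(st, cfg.kinetics, 0.01)
        assert np.array_equal(new.c, st.c)
        assert np.array_equal(new.h_m, st.h_m)

    def test_uniform_state_unmoved_by_diffusion(self):
        cfg = quiet_config()
        kp = cfg.kinetics
        _, _, st = build_domain(cfg)
        st.c[:] = 2.5
        st.h_m[:] = 1.5
        # sources/decay off so only diffusion acts on the uniform fields
        kp2 = KineticParameters(
            delta_b=0, delta_t=0, delta_m=0, mu_b=0, mu_t=0, mu_m=0,
            mu_c=0, gamma_b=0, gamma_m=0, d_c=kp.d_c, d_m=kp.d_m,
            response=ResponseParams(gamma_t=0.0, gamma_c=0.0))
        new = step(st, kp2, 0.01)
        assert np.allclose(new.c, 2.5, atol=1e-12)
        assert np.allclose(new.h_m, 1.5, atol=1e-12)

    def test_stability_bound_violation_names_admissible_dt(self):
        cfg = quiet_config()
        _, _, st = build_domain(cfg)
        bound = stability_dt(cfg.grid, cfg.kinetics)
        with pytest.raises(ValueError, match="maximal admissible"):
            step(st, cfg.kinetics, 2 * bound)

    def test_negative_field_guard_trips_on_stiff_decay(self):
        cfg = quiet_config()
        cfg.kinetics.mu_c = 300.0  # mu_c * dt > 2 overshoots below zero
        _, _, st = build_domain(cfg)
        st.c[:] = 1.0
        with pytest.raises(RuntimeError, match="reduce dt"):
            step(st, cfg.kinetics, 0.01)

    def test_pointwise_ode_matches_stiff_integrator(self):
        rp = ResponseParams(gamma_t=5.0, gamma_t0=8.0, gamma_c=10.0,
                            beta=4.0, t_sw=2.0, a_r=1.0)
        kp = KineticParameters(mu_t=0.6, gamma_m=2.0, mu_m=0.4, mu_c=1.0,
                               d_c=1e-9, d_m=1e-9, gamma_b=2.0, response=rp)
        cfg = SimConfig(grid=DermisGrid(length_cm=6.4, n=16), kinetics=kp,
                        n_sites=1, site_radius_px=2, mast_capacity=1e9,
                        basophil_capacity=1e9, mast_heterogeneity=0.0,
                        hm_noise=0.0, hb_stimulus=5.0, seed=0)
        _, occ, st = build_domain(cfg)
        px = occ.site_pixels[0][len(occ.site_pixels[0]) // 2]
        y0 = [st.h_b[0], st.tf.ravel()[px], st.c.ravel()[px],
              st.h_m.ravel()[px]]

        def g(h, a, a0):
            return a * h * h / (a0 + h * h)

        def rhs(t, y):
            hb, tf, c, hm = y
            act = rp.gamma_t * (hb + hm) / (rp.gamma_t0 + hb + hm)
            leak = rp.gamma_c / (1 + np.exp(-rp.beta * (tf - rp.t_sw)))
            return [
                kp.delta_b + kp.gamma_b * tf * (1 - g(hb, rp.alpha_b,
                                                      rp.alpha_b0))
                - kp.mu_b * hb,
                kp.delta_t + act * (1 - g(hb + hm, rp.alpha_t, rp.alpha_t0))
                - kp.mu_t * tf,
                leak - kp.mu_c * c,
                kp.delta_m + kp.gamma_m * c * (1 - g(hm, rp.alpha_m,
                                                     rp.alpha_m0))
                - kp.mu_m * hm,
            ]

        ref = solve_ivp(rhs, (0.0, 10.0), y0, rtol=1e-10, atol=1e-12)
        dt = 2e-3
        for _ in range(int(round(10.0 / dt))):
            st = step(st, kp, dt)
        got = np.array([st.h_b[0], st.tf.ravel()[px], st.c.ravel()[px],
                        st.h_m.ravel()[px]])
        rel = np.abs(got - ref.y[:, -1]) / np.abs(ref.y[:, -1])
        assert rel.max() < 1e-4


class TestRun:
    def test_identical_config_and_seed_bitwise_reproducible(self):
        cfg = pattern_preset("dot", seed=4)
        cfg.t_end = 8.0
        a = run(cfg)
        b = run(cfg)
        assert a.times == b.times
        for ma, mb in zip(a.fields, b.fields):
            assert np.array_equal(ma, mb)

    def test_subthreshold_basal_run_produces_no_wheal(self):
        cfg = quiet_config(t_end=4.0)
        series = run(cfg)
        assert not series.masks[-1].any()

    def test_reservoirs_monotone_and_chi_switches_once(self):
        cfg = pattern_preset("geographic", seed=1)
        cfg.t_end = 16.0
        _, _, st = build_domain(cfg)
        kp = cfg.kinetics
        dt = 0.02
        prev = st.occupancy.mast_reservoir.copy()
        prev_chi = st.occupancy.chi_m.copy()
        revived = 0
        for _ in range(600):
            st = step(st, kp, dt)
            res = st.occupancy.mast_reservoir
            assert (res <= prev + 1e-12).all()
            chi = st.occupancy.chi_m
            revived += int((chi & ~prev_chi).sum())
            prev, prev_chi = res.copy(), chi.copy()
        assert revived == 0

    def test_annular_preset_yields_boundary_class_in_most_seeds(self):
        from whealsim.classifier import WhealMask, classify_series
        hits = 0
        for seed in range(1, 11):
            series = run(pattern_preset("annular", seed=seed))
            masks = [WhealMask(m, series.pixel_size_cm, t)
                     for t, m in zip(series.times, series.masks)]
            try:
                if classify_series(masks).type_ in ("annular",
                                                    "broken-annular"):
                    hits += 1
            except ValueError:
                pass
        assert hits >= 7

    def test_grid_refinement_changes_area_fraction_under_5pct(self):
        areas = []
        for n, r in ((64, 2), (128, 4)):
            cfg = base_config(seed=5)
            cfg.grid.n = n
            cfg.site_radius_px = r
            cfg.mast_heterogeneity = 0.0
            cfg.mast_occupancy = 1.0
            cfg.hm_noise = 0.0
            cfg.kinetics.response.alpha_m = 0.3
            cfg.t_end = 30.0
            areas.append(run(cfg).masks[-1].mean())
        assert abs(areas[1] - areas[0]) / areas[0] < 0.05


class TestMassLedger:
    def test_diffusion_only_conserves_total_mass(self):
        cfg = quiet_config()
        kp = KineticParameters(
            delta_b=0, delta_t=0, delta_m=0, mu_b=0, mu_t=0, mu_m=0,
            mu_c=0, gamma_b=0, gamma_m=0, d_c=0.3, d_m=0.1,
            response=ResponseParams(gamma_t=0.0, gamma_c=0.0))
        _, _, st = build_domain(cfg)
        st.c[4:8, 4:8] = 7.0  # off-centre blob
        total0 = st.c.sum()
        for _ in range(200):
            st = step(st, kp, 0.01)
            assert abs(st.c.sum() - total0) < 1e-10 * total0

    def test_decay_only_total_follows_closed_form(self):
        cfg = quiet_config()
        kp = KineticParameters(
            delta_b=0, delta_t=0, delta_m=0, mu_b=0, mu_t=0, mu_m=0,
            mu_c=0.8, gamma_b=0, gamma_m=0, d_c=0.3, d_m=0.1,
            response=ResponseParams(gamma_t=0.0, gamma_c=0.0))
        _, _, st = build_domain(cfg)
        st.c[:] = 3.0
        total0 = st.c.sum()
        dt, n = 1e-4, 20_000
        for _ in range(n):
            st = step(st, kp, dt)
        # forward Euler of pure decay: (1 - mu dt)^n vs exp(-mu t)
        t = n * dt
        assert st.c.sum() / total0 == pytest.approx(np.exp(-0.8 * t),
                                                    rel=1e-3)

    def test_full_run_ledger_residual_at_machine_precision(self):
        series = run(pattern_preset("geographic", seed=2))
        report = mass_ledger(series, tol=1e-10)
        assert report["passed"]
        assert report["max_relative_residual"] < 1e-10


class TestSimConfig:
    def test_dict_round_trip(self):
        cfg = base_config(seed=3)
        back = SimConfig.from_dict(cfg.to_dict())
        assert back.to_dict() == cfg.to_dict()

    def test_unknown_keys_rejected(self):
        d = base_config().to_dict()
        d["wheal_speed"] = 1.0
        with pytest.raises(ValueError, match="unknown config keys"):
            SimConfig.from_dict(d)

    def test_grid_resolution_floor(self):
        with pytest.raises(ValueError):
            DermisGrid(length_cm=10.0, n=8)
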