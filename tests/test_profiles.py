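import numpy as np
import pytest

from berryflux import (
    AggregateGeometry,
    ProfileFormatError,
    RadialProfile,
    SourceSchedule,
    build_rate_table,
    carbon_fixation,
    generate_ld_trace,
    generate_profile,
    green_berry_scenario,
    gross_photosynthesis,
    light_dark_shift_rate,
    read_profile,
    read_trace,
    resp_to_gross_ratio,
    whole_aggregate_flux,
    write_profile,
    write_trace,
)


@pytest.fixture(scope="module")
def clean_scenario():
    return green_berry_scenario(seed=7, noise_sigma_umol_l=0.0)


class TestProfileIO:
    def test_round_trip_identical(self, clean_scenario, tmp_path):
        prof = generate_profile(clean_scenario, 170.0)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_profile(prof, p1)
        back = read_profile(p1)
        write_profile(back, p2)
        assert p1.read_bytes() == p2.read_bytes()
        np.testing.assert_array_equal(back.depth_um, prof.depth_um)
        assert back.light_ue == 170.0

    def test_non_numeric_cell_reported_with_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "# surface_depth_um=100\ndepth_um,o2_umol_l\n0,215\n50,oops\n"
        )
        with pytest.raises(ProfileFormatError, match="line 4"):
            read_profile(p)

    def test_missing_required_header(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("depth_um,o2_umol_l\n0,215\n50,210\n")
        with pytest.raises(ProfileFormatError, match="surface_depth_um"):
            read_profile(p)

    def test_non_monotone_depth_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "# surface_depth_um=50\ndepth_um,o2_umol_l\n0,215\n100,210\n50,200\n"
        )
        with pytest.raises(ProfileFormatError, match="increasing"):
            read_profile(p)

    def test_trace_round_trip(self, tmp_path):
        from berryflux import TransientTrace

        tr = TransientTrace(
            time_s=np.arange(5.0), o2_umol_l=np.linspace(500, 400, 5), dark_onset_s=1.0
        )
        p = tmp_path / "t.csv"
        write_trace(tr, p)
        back = read_trace(p)
        assert back.dark_onset_s == 1.0
        np.testing.assert_allclose(back.o2_umol_l, tr.o2_umol_l)


class TestWholeAggregateFlux:
    def test_flat_external_profile_gives_zero(self, table_geometry, medium24):
        depth = np.arange(0.0, 2100.0, 50.0)
        prof = RadialProfile(
            depth_um=depth, o2_umol_l=np.full_like(depth, 215.0), surface_depth_um=2000.0
        )
        assert whole_aggregate_flux(prof, table_geometry, medium24) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_dark_profile_recovers_total_respiration(self, clean_scenario):
        """Noise-free dark profile generated at 6.8 umol cm^-3 h^-1 in a
        2.8 mm^3 aggregate carries a 19 nmol/h uptake."""
        prof = generate_profile(clean_scenario, 0.0)
        flux = whole_aggregate_flux(prof, clean_scenario.geometry, clean_scenario.medium)
        assert flux == pytest.approx(-19.04, rel=0.02)
        assert round(abs(flux)) == 19

    @pytest.mark.parametrize("light, total", [(170.0, 13.44), (320.0, 30.8)])
    def test_lighted_profiles_recover_net_production(self, clean_scenario, light, total):
        prof = generate_profile(clean_scenario, light)
        flux = whole_aggregate_flux(prof, clean_scenario.geometry, clean_scenario.medium)
        assert flux == pytest.approx(total, rel=0.02)

    def test_sign_convention(self, clean_scenario):
        dark = generate_profile(clean_scenario, 0.0)
        light = generate_profile(clean_scenario, 320.0)
        geom, med = clean_scenario.geometry, clean_scenario.medium
        assert whole_aggregate_flux(dark, geom, med) < 0
        assert whole_aggregate_flux(light, geom, med) > 0

    def test_planar_estimator_sign_and_order_of_magnitude(self, clean_scenario):
        dark = generate_profile(clean_scenario, 0.0)
        geom, med = clean_scenario.geometry, clean_scenario.medium
        planar = whole_aggregate_flux(dark, geom, med, method="planar")
        radial = whole_aggregate_flux(dark, geom, med)
        assert planar < 0
        # the planar estimator ignores spherical spreading and is biased low
        # in magnitude, but stays within a factor of two
        assert 0.5 < planar / radial < 1.5

    def test_too_few_external_points_rejected(self, table_geometry, medium24):
        depth = np.array([0.0, 1000.0, 1990.0, 2100.0, 2500.0])
        prof = RadialProfile(
            depth_um=depth, o2_umol_l=np.full(5, 215.0), surface_depth_um=2000.0
        )
        with pytest.raises(ValueError, match="external points"):
            whole_aggregate_flux(
                prof, table_geometry, medium24, min_clearance_um=50, max_distance_um=300
            )

    def test_noisy_replicates_recover_mean(self, medium24):
        """sigma = 2 umol/L sensor noise: the mean of 30 seeded replicates
        recovers the generating total within 5%."""
        fluxes = []
        for seed in range(30):
            spec = green_berry_scenario(seed=seed, noise_sigma_umol_l=2.0)
            prof = generate_profile(spec, 0.0)
            fluxes.append(whole_aggregate_flux(prof, spec.geometry, spec.medium))
        assert np.mean(fluxes) == pytest.approx(-19.04, rel=0.05)


class TestRateArithmetic:
    @pytest.mark.parametrize(
        "net, resp, expected", [(13.0, 19.0, 32.0), (31.0, 19.0, 50.0), (0.0, 7.0, 7.0)]
    )
    def test_gross_is_net_plus_respiration(self, net, resp, expected):
        assert gross_photosynthesis(net, resp) == expected

    def test_negative_respiration_magnitude_rejected(self):
        with pytest.raises(ValueError):
            gross_photosynthesis(13.0, -19.0)

    @pytest.mark.parametrize(
        "gross, pq, expected, tol",
        [(32.0, 1.2, 320.29, 0.01), (50.0, 1.2, 500.46, 0.01), (0.0, 1.2, 0.0, 1e-12)],
    )
    def test_carbon_fixation(self, gross, pq, expected, tol):
        assert carbon_fixation(gross, pq) == pytest.approx(expected, abs=tol)

    def test_carbon_fixation_input_validation(self):
        with pytest.raises(ValueError):
            carbon_fixation(-1.0, 1.2)
        with pytest.raises(ValueError):
            carbon_fixation(32.0, 0.0)

    def test_respiration_to_gross_ratio(self):
        assert resp_to_gross_ratio(19.0, 50.0) == pytest.approx(0.38)
        assert resp_to_gross_ratio(19.0, 32.0) == pytest.approx(0.594, abs=1e-3)
        assert resp_to_gross_ratio(7.0, 7.0) == 1.0
        with pytest.raises(ValueError):
            resp_to_gross_ratio(19.0, 0.0)


class TestLightDarkShift:
    def test_constant_trace_gives_zero(self):
        from berryflux import TransientTrace

        tr = TransientTrace(
            time_s=np.arange(0.0, 60.0), o2_umol_l=np.full(60, 400.0), dark_onset_s=20.0
        )
        assert light_dark_shift_rate(tr) == pytest.approx(0.0, abs=1e-12)

    def test_recovers_local_gross_from_simulated_shift(self, medium24):
        """Darkening a lighted steady state: the initial decline equals the
        local gross photosynthesis (net + respiration)."""
        spec = green_berry_scenario(seed=0, noise_sigma_umol_l=0.0).with_(
            geometry=AggregateGeometry(esd_mm=1.7)  # no volume rescaling
        )
        q_light, resp = 11.0, 6.8
        gross = q_light + resp
        sched = SourceSchedule.from_steps([(0, 60, q_light), (60, 360, -resp)])
        tr = generate_ld_trace(spec, sched)
        assert tr.dark_onset_s == 60.0
        est = light_dark_shift_rate(tr)
        assert est == pytest.approx(gross, rel=0.05)

    def test_longer_windows_bias_low(self, medium24):
        """Diffusive relaxation makes long-window estimates smaller —
        the documented bias of core-point shift measurements."""
        spec = green_berry_scenario(seed=0, noise_sigma_umol_l=0.0).with_(
            geometry=AggregateGeometry(esd_mm=1.7)
        )
        sched = SourceSchedule.from_steps([(0, 60, 11.0), (60, 660, -6.8)])
        tr = generate_ld_trace(spec, sched)
        short = light_dark_shift_rate(tr, window_s=(2, 12))
        long = light_dark_shift_rate(tr, window_s=(2, 120))
        assert long < short

    def test_window_outside_trace_rejected(self):
        from berryflux import TransientTrace

        tr = TransientTrace(time_s=np.arange(10.0), o2_umol_l=np.full(10, 100.0))
        with pytest.raises(ValueError):
            light_dark_shift_rate(tr, dark_onset_s=50.0)
        with pytest.raises(ValueError):
            light_dark_shift_rate(tr)  # no onset anywhere


class TestBuildRateTable:
    def test_end_to_end_synthetic_recovery(self, clean_scenario):
        """Noise-free synthetic profiles rebuild the known generating rates
        within 5% in every cell."""
        spec = clean_scenario
        dark = generate_profile(spec, 0.0)
        lights = {lv: generate_profile(spec, lv) for lv in (170.0, 320.0)}
        rt = build_rate_table(dark, lights, spec.geometry, spec.medium, spec.model)
        assert rt.complete
        df = rt.to_dataframe().set_index("light_ue")
        assert df.loc[0.0, "dark_respiration_nmol_h"] == pytest.approx(19.04, rel=0.05)
        assert df.loc[0.0, "vol_dark_respiration_umol_cm3_h"] == pytest.approx(6.8, rel=0.05)
        assert df.loc[170.0, "net_photosynthesis_nmol_h"] == pytest.approx(13.44, rel=0.05)
        assert df.loc[170.0, "gross_photosynthesis_nmol_h"] == pytest.approx(32.48, rel=0.05)
        assert df.loc[320.0, "vol_net_photosynthesis_umol_cm3_h"] == pytest.approx(11.0, rel=0.05)
        assert df.loc[320.0, "carbon_fixation_ng_h"] == pytest.approx(
            carbon_fixation(49.84, 1.2), rel=0.05
        )

    def test_rate_table_identities_hold_unrounded(self, clean_scenario):
        spec = clean_scenario
        dark = generate_profile(spec, 0.0)
        lights = {170.0: generate_profile(spec, 170.0)}
        rt = build_rate_table(dark, lights, spec.geometry, spec.medium, spec.model)
        df = rt.to_dataframe().set_index("light_ue")
        resp = df.loc[0.0, "dark_respiration_nmol_h"]
        net = df.loc[170.0, "net_photosynthesis_nmol_h"]
        gross = df.loc[170.0, "gross_photosynthesis_nmol_h"]
        assert gross == pytest.approx(net + resp, rel=1e-12)
        assert df.loc[170.0, "vol_gross_photosynthesis_umol_cm3_h"] == pytest.approx(
            gross / spec.geometry.volume_mm3, rel=1e-12
        )
        assert df.loc[170.0, "carbon_fixation_ng_h"] == pytest.approx(
            gross / spec.model.pq * 12.011, rel=1e-12
        )

    def test_missing_dark_profile_flags_partial_table(self, clean_scenario):
        spec = clean_scenario
        lights = {170.0: generate_profile(spec, 170.0)}
        rt = build_rate_table(None, lights, spec.geometry, spec.medium, spec.model)
        assert not rt.complete
        assert any("dark" in n for n in rt.notes)
        df = rt.to_dataframe()
        assert "gross_photosynthesis_nmol_h" not in df.columns

    def test_flat_profiles_give_zero_table(self, table_geometry, medium24):
        depth = np.arange(0.0, 3800.0, 50.0)
        flat = RadialProfile(
            depth_um=depth, o2_umol_l=np.full_like(depth, 215.0), surface_depth_um=2000.0
        )
        rt = build_rate_table(flat, {170.0: flat}, table_geometry, medium24)
        df = rt.to_dataframe().set_index("light_ue")
        assert df.loc[0.0, "dark_respiration_nmol_h"] == pytest.approx(0.0, abs=1e-9)
        assert df.loc[170.0, "gross_photosynthesis_nmol_h"] == pytest.approx(0.0, abs=1e-9)
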