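"""Synthetic scan generator: protocol timing, determinism, ground truth."""

import dataclasses
import math

import numpy as np
import pytest

import sietflux as sf


class TestProtocolTiming:
    def test_cycle_time_matches_instrument(self, protocol):
        # 2 x (4.0 s wait + 0.5 s sample) + 0.5 s out-and-back travel
        assert protocol.cycle_time_s == pytest.approx(9.5)

    def test_standard_site_takes_57_seconds(self, protocol):
        assert sf.protocol_duration(protocol, 2) == pytest.approx(57.0)

    def test_single_cycle_measurement(self):
        p = sf.ScanProtocol(cycles_per_measurement=1)
        assert sf.protocol_duration(p, 1) == pytest.approx(9.5)

    def test_four_sites_two_measurements(self, protocol):
        assert 4 * sf.protocol_duration(protocol, 2) == pytest.approx(228.0)

    def test_zero_measurements_rejected(self, protocol):
        with pytest.raises(ValueError):
            sf.protocol_duration(protocol, 0)

    def test_zero_move_speed_rejected(self):
        with pytest.raises(sf.ProtocolError):
            sf.ScanProtocol(move_speed_um_s=0.0)


class TestSimulateCalibration:
    def test_noise_free_slopes_are_exact(self):
        pairs = sf.simulate_calibration(55_600.0, noise_sd=0.0, n=5, seed=0)
        for p in pairs:
            assert sf.fit_slope(*p) == 55_600.0

    def test_slope_scatter_matches_endpoint_noise(self):
        # Var(slope) = 2 sigma^2 for a one-decade pair, so SD ~ 950*sqrt(2).
        pairs = sf.simulate_calibration(55_600.0, noise_sd=950.0, n=20, seed=11)
        slopes = np.array([sf.fit_slope(*p) for p in pairs])
        expected_sd = 950.0 * math.sqrt(2.0)
        assert abs(slopes.std(ddof=1) - expected_sd) < 0.5 * expected_sd

    @pytest.mark.parametrize("kwargs", [{"n": 0}, {"noise_sd": -1.0}])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            sf.simulate_calibration(55_600.0, **kwargs)


class TestSimulateScan:
    def test_zero_flux_zero_noise_gives_zero_gradients(
        self, uniform_truth, protocol, k_calibration
    ):
        ds = sf.simulate_scan(
            uniform_truth(0.0), protocol, k_calibration, sf.K_SELECTIVITY,
            sf.DEFAULT_BATH["K"],
        )
        for rec in ds.site_recordings:
            assert sf.site_gradient(rec) == pytest.approx(0.0, abs=1e-12)

    def test_noise_free_recovery_of_control_potassium_flux(
        self, uniform_truth, protocol, k_calibration
    ):
        ds = sf.simulate_scan(
            uniform_truth(26.7), protocol, k_calibration, sf.K_SELECTIVITY,
            sf.DEFAULT_BATH["K"],
        )
        est = sf.estimate_fluxes(ds)
        for e in est:
            assert e.dv_corrected == pytest.approx(49.4, rel=0.01)
            assert e.flux == pytest.approx(26.7, rel=0.005)
            assert e.direction == "absorption"

    def test_noise_free_recovery_of_control_sodium_flux(
        self, uniform_truth, protocol, na_calibration
    ):
        truth = uniform_truth(-53.2)
        ds = sf.simulate_scan(
            truth, protocol, na_calibration, sf.NA_SELECTIVITY,
            sf.DEFAULT_BATH["Na"],
        )
        e = sf.estimate_fluxes(ds)[0]
        assert e.dv_corrected == pytest.approx(-22.0, rel=0.01)
        assert e.flux == pytest.approx(-53.2, rel=0.005)
        assert e.direction == "secretion"

    def test_common_mode_drift_is_removed_by_reference_correction(
        self, uniform_truth, protocol, k_calibration
    ):
        def fluxes(drift, cb_mode):
            ds = sf.simulate_scan(
                uniform_truth(26.7, drift_rate_uv_min=drift),
                protocol, k_calibration, sf.K_SELECTIVITY, sf.DEFAULT_BATH["K"],
            )
            return np.array(
                [e.flux for e in sf.estimate_fluxes(ds, cb_mode=cb_mode)]
            )

        # The reference subtraction cancels shared drift in the gradient
        # chain itself (nominal C_B isolates that chain).
        no_drift = fluxes(0.0, "nominal")
        with_drift = fluxes(60.0, "nominal")
        assert np.all(np.abs(with_drift - no_drift) / np.abs(no_drift) < 0.01)

    def test_drift_in_measured_background_is_a_small_common_scale(
        self, uniform_truth, protocol, k_calibration
    ):
        # Measured-mode C_B averages absolute (drifted) voltages, so drift
        # leaves a small multiplicative bias; at the default 30 uV/min it
        # stays within 2% and is shared by control and treatment scans.
        def fluxes(drift):
            ds = sf.simulate_scan(
                uniform_truth(26.7, drift_rate_uv_min=drift),
                protocol, k_calibration, sf.K_SELECTIVITY, sf.DEFAULT_BATH["K"],
            )
            return np.array([e.flux for e in sf.estimate_fluxes(ds)])

        ratio = fluxes(30.0) / fluxes(0.0)
        assert np.allclose(ratio, ratio[0], rtol=1e-9)
        assert abs(ratio[0] - 1.0) < 0.02

    def test_identical_seed_gives_identical_datasets(self, protocol, k_calibration):
        truth = sf.default_experiment_config("K", "control", seed=5)
        args = (truth, protocol, k_calibration, sf.K_SELECTIVITY, sf.DEFAULT_BATH["K"])
        ds1 = sf.simulate_scan(*args)
        ds2 = sf.simulate_scan(*args)
        assert ds1.site_recordings == ds2.site_recordings
        assert ds1.reference_recordings == ds2.reference_recordings

    def test_infeasible_truth_rejected(self, uniform_truth, protocol, k_calibration):
        # |J| dx / D = 2x bath concentration: gradient would be non-physical
        j_limit = 2 * 3.4 * sf.POTASSIUM.diffusion_coefficient / 0.005 * 1e6
        with pytest.raises(sf.InfeasibleTruthError):
            sf.simulate_scan(
                uniform_truth(j_limit * 1.01), protocol, k_calibration,
                sf.K_SELECTIVITY, sf.DEFAULT_BATH["K"],
            )

    def test_bath_must_contain_primary_ion(self, uniform_truth, protocol, k_calibration):
        with pytest.raises(ValueError):
            sf.simulate_scan(
                uniform_truth(10.0), protocol, k_calibration,
                sf.K_SELECTIVITY, {"Na": 150.0},
            )


class TestDefaultExperimentConfig:
    @pytest.mark.parametrize(
        "ion,region,scale",
        [("Na", "ileum", 0.25), ("K", "ileum", 0.32), ("K", "anterior_rectum", 0.21)],
    )
    def test_treatment_scales_affected_regions(self, ion, region, scale):
        control = sf.default_experiment_config(ion, "control")
        treated = sf.default_experiment_config(ion, "GPA2/GPB5")
        assert treated.region_flux[region] == pytest.approx(
            control.region_flux[region] * scale
        )

    def test_unaffected_regions_unchanged(self):
        control = sf.default_experiment_config("Na", "GPA2/GPB5")
        base = sf.default_experiment_config("Na", "control")
        for region in ("anterior_rectum", "posterior_rectum"):
            assert control.region_flux[region] == base.region_flux[region]

    def test_same_seed_same_condition_is_deterministic(self):
        t = sf.default_experiment_config("K", "control", seed=3)
        a = sf.simulate_condition(t, ion="K", treatment_label="control")
        b = sf.simulate_condition(t, ion="K", treatment_label="control")
        assert [d.site_recordings for d in a] == [d.site_recordings for d in b]

    @pytest.mark.parametrize("args", [("Cl", "control"), ("K", "mystery")])
    def test_unknown_ion_or_condition_rejected(self, args):
        with pytest.raises(ValueError):
            sf.default_experiment_config(*args)

    def test_sample_sizes_match_study_design(self):
        t = sf.default_experiment_config("K", "control")
        assert t.n_preparations == 10
        assert t.n_sites["ileum"] == 5
        assert t.n_sites["rectum"] == 10


class TestOracleEquivalence:
    @pytest.mark.parametrize("ion", ["K", "Na"])
    @pytest.mark.parametrize("magnitude", [1.0, 10.0, 100.0, 500.0])
    @pytest.mark.parametrize("sign", [1.0, -1.0])
    def test_inversion_consistency_over_flux_range(
        self, ion, magnitude, sign, uniform_truth, protocol
    ):
        """Pure-primary bath, nominal C_B: the analysis chain inverts the
        generator exactly, for both printed ion parameter sets."""
        cal = sf.default_calibration(ion)
        j_true = sign * magnitude
        ds = sf.simulate_scan(
            uniform_truth(j_true), protocol, cal,
            sf.SelectivityProfile(ion, {}), {ion: cal.ion.bath_concentration},
        )
        for e in sf.estimate_fluxes(ds, cb_mode="nominal"):
            assert e.flux == pytest.approx(j_true, rel=5e-3)

    @pytest.mark.parametrize("ion,j_true", [("K", 26.7), ("K", 120.0),
                                            ("Na", -53.2), ("Na", 120.0)])
    def test_default_configuration_recovery_at_study_fluxes(
        self, ion, j_true, uniform_truth, protocol
    ):
        """Full default configuration (interfering bath ions, measured C_B)
        stays within 0.5% at the flux magnitudes the hindgut produces."""
        ds = sf.simulate_scan(
            uniform_truth(j_true), protocol, sf.default_calibration(ion),
            sf.default_selectivity(ion), sf.DEFAULT_BATH[ion],
        )
        for e in sf.estimate_fluxes(ds):
            assert e.flux == pytest.approx(j_true, rel=5e-3)
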