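import pytest

import sietflux as sf


@pytest.fixture(scope="session")
def k_calibration() -> sf.ElectrodeCalibration:
    """K+ electrode at the mean measured slope, 15/150 mM points."""
    return sf.default_calibration("K")


@pytest.fixture(scope="session")
def na_calibration() -> sf.ElectrodeCalibration:
    return sf.default_calibration("Na")


@pytest.fixture(scope="session")
def protocol() -> sf.ScanProtocol:
    return sf.ScanProtocol()


def noise_free_truth(region_flux, **kwargs) -> sf.SyntheticTruth:
    defaults = dict(noise_sd_uv=0.0, drift_rate_uv_min=0.0)
    defaults.update(kwargs)
    return sf.SyntheticTruth(region_flux=region_flux, **defaults)


@pytest.fixture()
def uniform_truth():
    """Factory: same true flux everywhere, noise and drift off by default."""

    def make(flux: float, **kwargs) -> sf.SyntheticTruth:
        return noise_free_truth(
            {"ileum": flux, "anterior_rectum": flux, "posterior_rectum": flux},
            **kwargs,
        )

    return make
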