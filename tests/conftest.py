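import pytest

from nebudose import ImageCalibration, get_particle


@pytest.fixture(scope="session")
def nm100():
    return get_particle("NM-100")


@pytest.fixture(scope="session")
def nm101():
    return get_particle("NM-101")


@pytest.fixture(scope="session")
def field512():
    """5 µm × 5 µm at 512² px — same ~9.8 nm pitch as the default field,
    sized for fast repeated simulation."""
    return ImageCalibration(
        scan_width_nm=5000.0, scan_height_nm=5000.0, pixels_x=512, pixels_y=512
    )


@pytest.fixture(scope="session")
def field256():
    return ImageCalibration(
        scan_width_nm=2500.0, scan_height_nm=2500.0, pixels_x=256, pixels_y=256
    )
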