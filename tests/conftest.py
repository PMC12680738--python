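import numpy as np
import pytest
from shapely.geometry import LineString, Point, Polygon, box

from streamhab.centerline import medial_axis
from streamhab.model import AssessmentConfig, BankGeometry
from streamhab.parameters import extract_stations
from streamhab.synthetic import MeanderSpec, PiecewiseProfile, generate_site


@pytest.fixture(scope="session")
def default_spec() -> MeanderSpec:
    """A 200 m meander with two pool reaches and an eroded window."""
    return MeanderSpec(
        axis_length=200.0,
        amplitude=8.0,
        wavelength=100.0,
        pool_reaches=((60.0, 80.0), (140.0, 150.0)),
        erosion_left=PiecewiseProfile(0.0, ((90.0, 110.0, 0.8),)),
    )


@pytest.fixture(scope="session")
def meander_bundle(default_spec):
    """(site, banks, layers, truth) for the default meander."""
    return generate_site(default_spec)


@pytest.fixture(scope="session")
def meander_stations(meander_bundle):
    """(centerline, records) extracted from the default meander at 2 m."""
    _, banks, layers, _ = meander_bundle
    cl = medial_axis(banks, 2.0)
    records = extract_stations(cl, banks, layers, AssessmentConfig())
    return cl, records


@pytest.fixture()
def rect_banks() -> BankGeometry:
    """A straight 100 x 5 m rectangular channel along the x axis."""
    return BankGeometry(
        left_bank=LineString([(0, 5), (100, 5)]),
        right_bank=LineString([(0, 0), (100, 0)]),
        inlet=Point(0, 2.5),
        outlet=Point(100, 2.5),
        left_bank_top=LineString([(0, 7), (100, 7)]),
        right_bank_top=LineString([(0, -2), (100, -2)]),
    )
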