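"""Shared fixtures.

The expensive objects — the characterized reference session and the
default simulated machine — are session-scoped: the reference data is
produced once by actually running the characterization and MR extraction
chain on synthetic data, exactly as a site would bootstrap the test.
"""

import pytest

from mrlqc import (
    SyntheticPhantomSpec,
    ToleranceConfig,
    create_reference_data,
    default_geometry,
)
from mrlqc.mv_analysis import MVDetectorConfig, make_fiducial_templates
from mrlqc.synthetic import COUCH_MARKER_BASELINE_MM


@pytest.fixture(scope="session")
def spec():
    return SyntheticPhantomSpec.default()


@pytest.fixture(scope="session")
def geom():
    return default_geometry()


@pytest.fixture(scope="session")
def mv_cfg():
    return MVDetectorConfig()


@pytest.fixture(scope="session")
def templates(geom, mv_cfg):
    return make_fiducial_templates(geom, mv_cfg)


@pytest.fixture(scope="session")
def reference_data(spec):
    return create_reference_data(spec, seed=0)


@pytest.fixture(scope="session")
def tolerances():
    return ToleranceConfig(couch_baseline_mm=COUCH_MARKER_BASELINE_MM)
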