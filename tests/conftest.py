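import numpy as np
import pytest

from cororeg.carm import CArmGeometry
from cororeg.synthetic import SimConfig, make_case


@pytest.fixture(scope="session")
def geometry():
    return CArmGeometry(primary_angle_deg=0.0, secondary_angle_deg=0.0,
                        pixel_spacing_mm=0.279, sid_mm=1000.0, sod_mm=750.0)


@pytest.fixture(scope="session")
def angled_geometry():
    return CArmGeometry(primary_angle_deg=-29.3, secondary_angle_deg=-18.7,
                        pixel_spacing_mm=0.279, sid_mm=1100.0, sod_mm=780.0)


@pytest.fixture(scope="session")
def clean_case():
    """Aligned, uncorrupted, undeformed case: the pipeline's easiest input."""
    cfg = SimConfig(rigid_frac=0.0, field_amp_mm=0.0, gap_rate=0.0,
                    false_branch_rate=0.0)
    return make_case(cfg, seed=11)


@pytest.fixture(scope="session")
def corrupted_case():
    """Aligned, undeformed case with default gap/false-branch corruption."""
    cfg = SimConfig(rigid_frac=0.0, field_amp_mm=0.0)
    return make_case(cfg, seed=17)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
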