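import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=40,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")

from octmorph.synthetic import CohortConfig, RenderConfig, generate_eye_geometry, render_bscan


@pytest.fixture(scope="session")
def table1_config():
    """Cohort configuration at the study-population parameter moments."""
    return CohortConfig()


@pytest.fixture(scope="session")
def mean_eye():
    """Deterministic eye at the population means (all SDs zero)."""
    cfg = CohortConfig(parameter_sds={k: 0.0 for k in CohortConfig().parameter_sds})
    return generate_eye_geometry(cfg, seed=0)


@pytest.fixture(scope="session")
def noiseless_render(mean_eye):
    """Noiseless B-scan of the mean eye plus its true landmarks."""
    img, landmarks = render_bscan(mean_eye, RenderConfig(speckle_model="none"))
    return img, landmarks


def measurement_errors(geometry, record):
    """Relative errors (%) of the six core parameters against ground truth."""
    true = {"pcal_mm": geometry.true_pcal, "acw_mm": geometry.true_acw,
            "agal_mm": geometry.true_agal, "agcl_mm": geometry.true_agcl,
            "pgal_mm": geometry.true_pgal, "pgcl_mm": geometry.true_pgcl}
    meas = record.to_dict()
    return {k: 100.0 * (meas[k] - v) / v for k, v in true.items()}
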