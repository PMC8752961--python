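import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240229)


@pytest.fixture(scope="session")
def roidefs():
    from twroi import load_roi_definitions

    return load_roi_definitions()


@pytest.fixture(scope="session")
def small_cohort():
    """10-ROI, 8-vs-8 cohort reused by workflow tests (read-only)."""
    from twroi.simulate import default_config, simulate_cohort

    cfg = default_config(seed=11)
    # mixed periventricular / non-periventricular subset
    keep = {"GCC", "BCC", "SCC", "FX", "TAP-L", "CST-R", "CST-L",
            "SLF-R", "SLF-L", "PCT"}
    cfg.rois = [r for r in cfg.rois if r.abbreviation in keep]
    cfg.n_subjects = (8, 8)
    cfg.grid_shape = (24, 24, 24)
    cohort, truth, _ = simulate_cohort(cfg)
    return cohort, truth


def make_cohort_frame(rows):
    """Hand-built long-format cohort table for workflow unit tests."""
    from twroi.images import SUMMARY_COLUMNS

    df = pd.DataFrame(rows)
    for col in SUMMARY_COLUMNS:
        if col not in df.columns:
            df[col] = 0.0
    return df[SUMMARY_COLUMNS]
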