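import numpy as np
import pytest

import blogmood as bm


@pytest.fixture(scope="session")
def small_cohort() -> bm.LongitudinalDataset:
    """20 participants, 18 fortnights, default missingness and planted effects."""
    cfg = bm.SyntheticConfig(n_participants=20, seed=42)
    return bm.generate_cohort(cfg)


@pytest.fixture(scope="session")
def complete_cohort() -> bm.LongitudinalDataset:
    """30 participants with no missing assessments or blog windows."""
    cfg = bm.SyntheticConfig(
        n_participants=30,
        n_features=10,
        seed=7,
        p_missing_assessment=0.0,
        p_missing_blog=0.0,
    )
    return bm.generate_cohort(cfg)


@pytest.fixture(scope="session")
def cross_table(complete_cohort) -> bm.CrossSectionTable:
    return bm.cross_section(bm.filter_final_sample(complete_cohort))


def null_cross_table(seed: int, n: int = 38, n_features: int = 68) -> bm.CrossSectionTable:
    """Cross-section table with no feature-symptom association (global null)."""
    cfg = bm.SyntheticConfig(
        n_participants=n,
        n_windows=1,
        n_features=n_features,
        between_loadings=np.zeros(n_features),
        p_missing_assessment=0.0,
        p_missing_blog=0.0,
        seed=seed,
    )
    return bm.cross_section(bm.generate_cohort(cfg))
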