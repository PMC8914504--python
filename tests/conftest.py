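import pytest

from strokepatterns import (fixture_atlas, fit_nmf, generate_cohort,
                            paper_shape_config)
from strokepatterns.parcellation import region_columns
from strokepatterns.synthetic import clip_matrix_to_atlas


@pytest.fixture(scope="session")
def small_atlas():
    """24x24x18 three-layer fixture atlas (94/15/20 regions)."""
    return fixture_atlas()


@pytest.fixture(scope="session")
def small_cohort():
    """300-patient synthetic cohort with null pattern effects."""
    cfg = paper_shape_config(seed=3, n_patients=300)
    lesion, expressions, cohort = generate_cohort(cfg)
    return cfg, lesion, expressions, cohort


@pytest.fixture(scope="session")
def fitted_basis(small_cohort):
    cfg, lesion, _, _ = small_cohort
    X = lesion[region_columns(lesion)]
    expressions, basis = fit_nmf(X, k=10, seed=0)
    return expressions, basis


@pytest.fixture(scope="session")
def clipped_matrix(small_cohort, small_atlas):
    _, lesion, _, _ = small_cohort
    return clip_matrix_to_atlas(lesion.iloc[:8], small_atlas)
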