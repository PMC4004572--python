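"""Shared fixtures: one preprocessed synthetic study and a desk-scale cohort."""

import numpy as np
import pytest

import lesionbench as lb

DESK_COHORT_SEED = 7
DESK_EXPERIMENT_SEED = 11


@pytest.fixture(scope="session")
def default_config():
    return lb.GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def study(default_config):
    """One default-condition study with its brain-tissue mask."""
    return lb.add_brain_mask(lb.generate_study(default_config, 0))


@pytest.fixture(scope="session")
def derived(study):
    """All derived volumes of the shared study, computed once."""
    return lb.derive_volumes(study)


@pytest.fixture(scope="session")
def desk_cohort():
    """The 20-subject desk-scale cohort used for end-to-end experiments."""
    return lb.generate_cohort(lb.GeneratorConfig(seed=DESK_COHORT_SEED, n_subjects=20))


@pytest.fixture(scope="session")
def tiny_cohort():
    """Five small-grid subjects for fast experiment-harness tests."""
    cfg = lb.GeneratorConfig(seed=3, n_subjects=5, grid_shape=(40, 40, 40))
    return lb.generate_cohort(cfg)


def make_feature_matrix(X, y, columns=None, kind_name="unnormalized"):
    """Wrap a plain array as a FeatureMatrix for classifier-level tests."""
    import pandas as pd

    from lesionbench.features import FeatureMatrix, FeatureVectorKind

    X = np.asarray(X, dtype=float)
    columns = list(columns) if columns is not None else [f"f{i}" for i in range(X.shape[1])]
    kind = FeatureVectorKind(name=kind_name, uses_voxel_selection=False,
                             dimension=X.shape[1])
    return FeatureMatrix(kind=kind, X=pd.DataFrame(X, columns=columns),
                         y=np.asarray(y, dtype=np.int8),
                         voxels=np.zeros((len(X), 3), dtype=int),
                         subject_ids=np.full(len(X), "s0", dtype=object))
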