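import dataclasses

import numpy as np
import pytest

import corrgcn as cg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_fm(rng):
    """Random 6-feature, 40-frame table with nontrivial correlations."""
    base = rng.standard_normal((40, 3))
    X = np.hstack([base, base + 0.3 * rng.standard_normal((40, 3))])
    names = [f"f{i}" for i in range(6)]
    return cg.FeatureMatrix(X, names, np.array(["s0"] * 40, dtype=object))


@pytest.fixture
def tiny_graph(tiny_fm):
    return cg.select_neighborhoods(cg.similarity_matrix(tiny_fm), m=3)


@pytest.fixture
def tiny_cohort():
    """Small two-class cohort: 4 subjects/class, 150 frames each."""
    cfg = dataclasses.replace(
        cg.reference_scenarios()["separable"],
        n_subjects_per_class=(4, 4),
        frames_per_subject=150,
        seed=7,
    )
    tables, subjects = cg.generate_cohort(cfg)
    return cg.build_dataset(tables, subjects, cg.binary_scheme())


# The two confusion matrices printed by the reference study (binary and
# four-class speaker-dependent results); used as worked examples for the
# metric computations.
BINARY_CONFUSION = np.array(
    [[460129, 10150],
     [10593, 183106]]
)
FOURCLASS_CONFUSION = np.array(
    [[462138, 3887, 1673, 2581],
     [4097, 102225, 276, 442],
     [1762, 248, 36411, 150],
     [1868, 356, 97, 45767]]
)
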