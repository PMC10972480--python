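import numpy as np
import pandas as pd
import pytest

from dyadmet.core import MetabolomeMatrix
from dyadmet.preprocess import minmax_scale_within_group
from dyadmet import dyads as dy
from dyadmet.synthetic import SyntheticConfig, generate


def make_matrix(values, role, subjects=None, families=None, scaled=False, names=None):
    """Hand-rolled MetabolomeMatrix for small fixtures."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    subjects = subjects or [f"{role[0].upper()}{i}" for i in range(n)]
    families = families or [f"fam{i}" for i in range(n)]
    names = names or [f"met{j}" for j in range(m)]
    return MetabolomeMatrix(
        data=pd.DataFrame(values, index=pd.Index(subjects, name="subject_id"),
                          columns=names),
        family_ids=pd.Series(families, index=subjects),
        role=role,
        scaled=scaled,
    )


@pytest.fixture
def tiny_pair():
    """3 complete families x 4 metabolites, no missing values."""
    mothers = make_matrix(
        [[1.0, 2.0, 3.0, 1.0], [2.0, 4.0, 6.0, 1.0], [3.0, 8.0, 9.0, 1.0]], "mother"
    )
    children = make_matrix(
        [[2.0, 1.0, 4.0, 2.0], [4.0, 2.0, 8.0, 2.0], [6.0, 3.0, 12.0, 2.0]], "child"
    )
    return mothers, children


def scaled_synthetic_pair(seed=0, n_families=80, n_metabolites=40, n_heritable=5,
                          beta=0.9):
    cfg = SyntheticConfig(
        n_families=n_families, n_metabolites=n_metabolites, n_heritable=n_heritable,
        heritability=beta, missing_rate=0.0, seed=seed,
    )
    mothers, children, annotation, outcomes, truth = generate(cfg)
    return (
        minmax_scale_within_group(mothers),
        minmax_scale_within_group(children),
        annotation,
        outcomes,
        truth,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Scaled 80-family cohort with 5 strongly heritable metabolites."""
    return scaled_synthetic_pair(seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    """Labelled dyad table (true + random) from the small cohort."""
    mothers, children, *_ = small_cohort
    true_d = dy.build_true_dyads(mothers, children)
    rand_d = dy.build_random_dyads(mothers, children, seed=13)
    return dy.assemble_dataset(true_d, rand_d)


@pytest.fixture(scope="session")
def small_split(small_cohort):
    """Family-partitioned train/test tables from the small cohort."""
    mothers, children, *_ = small_cohort
    return dy.grouped_dyad_split(mothers, children, seed=21)
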