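"""Shared fixtures: study-scale objects are session-scoped because design
optimization and study-size simulation are the expensive steps."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import paypref as pp
from paypref.model import ConditionalLogit, ModelSpec
from paypref.schema import build_schema

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

#: seeds fixed for the whole suite (stochastic assertions use exact-binomial
#: bands wide enough that a correct implementation passes for any seed)
DESIGN_SEED = 7
PRIOR_SEED = 11
POP_SEED = 5
CHOICE_SEED = 9


def make_schema(K: int, ref_level: str = "negative"):
    """Toy schema with K attributes a1..aK, ranks 1..K."""
    return build_schema(
        {
            "attributes": [{"id": f"a{i + 1}", "rank": i + 1} for i in range(K)],
            "reference": {"attribute": "a1", "level": ref_level},
        }
    )


@pytest.fixture(scope="session")
def study_schema():
    return pp.study_schema()


@pytest.fixture(scope="session")
def toy2():
    return make_schema(2)


@pytest.fixture(scope="session")
def toy4():
    return make_schema(4)


@pytest.fixture(scope="session")
def study_prior(study_schema):
    return pp.build_ordered_prior(study_schema, draws=256, seed=PRIOR_SEED)


@pytest.fixture(scope="session")
def study_design(study_schema, study_prior):
    """The study-geometry design: 54 sets, max 5 varying, 3 blocks of 18."""
    return pp.optimize_design(
        study_schema,
        study_prior,
        n_sets=54,
        n_varying_max=5,
        n_blocks=3,
        restarts=4,
        seed=DESIGN_SEED,
    )


@pytest.fixture(scope="session")
def study_truth(study_schema):
    return pp.study_truth_default(study_schema)


@pytest.fixture(scope="session")
def study_dataset(study_design, study_truth):
    pop = pp.generate_population(547, seed=POP_SEED)
    return pp.simulate_choices(study_design, pop, study_truth, seed=CHOICE_SEED)


@pytest.fixture(scope="session")
def truth_spec_terms(study_truth):
    """ModelSpec whose interaction terms mirror the data-generating truth."""
    return ModelSpec(interactions=tuple(study_truth.interactions.keys()))


@pytest.fixture(scope="session")
def pooled_fit(study_dataset):
    return ConditionalLogit(study_dataset, ModelSpec()).fit()


@pytest.fixture(scope="session")
def full_fit(study_dataset, truth_spec_terms):
    return ConditionalLogit(study_dataset, truth_spec_terms).fit()


@pytest.fixture(scope="session")
def tiny_design(toy4):
    """Small design for fast estimation tests: 12 sets, 1 planned constant."""
    prior = pp.build_ordered_prior(toy4, draws=64, seed=PRIOR_SEED)
    return pp.optimize_design(
        toy4, prior, n_sets=12, n_varying_max=3, n_blocks=1, restarts=2, seed=DESIGN_SEED
    )
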