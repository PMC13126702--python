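import numpy as np
import pytest

from lockdownsim import (
    ActionCatalog,
    FeatureSchema,
    FixtureSpec,
    MarginalTable,
    ScenarioInputs,
    WeightTable,
    fit_ipf,
    generate_beta_matrices,
    generate_case_curve,
    generate_marginals,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_schema():
    """Two features, one with an 'unknown' level, with a baseline tag."""
    return FeatureSchema(
        features=(
            ("gender", ("female", "male")),
            ("education", ("low", "high", "unknown")),
            ("depressed", ("no", "yes")),
        ),
        baseline_feature="depressed",
        baseline_category="yes",
    )


@pytest.fixture
def catalog():
    return ActionCatalog()


@pytest.fixture(scope="session")
def fixture_spec():
    return FixtureSpec(seed=202)


@pytest.fixture(scope="session")
def fixture_inputs(fixture_spec):
    """Fully synthetic engine inputs, shared across tests (read-only)."""
    schema, marginals = generate_marginals(fixture_spec)
    weights = fit_ipf(WeightTable.uniform(schema), marginals)
    return ScenarioInputs(
        schema=schema,
        weights=weights,
        params=generate_beta_matrices(fixture_spec),
        cases=generate_case_curve(fixture_spec, days=366),
    )


@pytest.fixture(scope="session")
def fixture_marginals(fixture_spec):
    schema, marginals = generate_marginals(fixture_spec)
    return schema, marginals
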